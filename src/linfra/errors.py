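"""Exception hierarchy for linfra.

Every error carries enough context (the offending edge, reaction or cycle) to
be actionable from the CLI without a traceback.
"""


class LinfraError(Exception):
    """Base class for all linfra errors."""


class GraphError(LinfraError):
    pass


class DuplicateEdge(GraphError):
    def __init__(self, source, target):
        super().__init__(f"duplicate edge {source!r} -> {target!r}")
        self.edge = (source, target)


class SelfLoop(GraphError):
    def __init__(self, vertex):
        super().__init__(f"self loop on vertex {vertex!r}")
        self.vertex = vertex


class UnknownVertex(GraphError):
    def __init__(self, vertex, edge=None):
        msg = f"unknown vertex {vertex!r}"
        if edge is not None:
            msg += f" referenced by edge {edge[0]!r} -> {edge[1]!r}"
        super().__init__(msg)
        self.vertex = vertex


class UnparseableLabel(GraphError):
    def __init__(self, label, edge=None, reason=""):
        msg = f"label {label!r} violates the label grammar"
        if edge is not None:
            msg += f" on edge {edge[0]!r} -> {edge[1]!r}"
        if reason:
            msg += f": {reason}"
        super().__init__(msg)
        self.label = label


class UnboundParameter(LinfraError):
    def __init__(self, symbols):
        super().__init__(f"no numeric value bound for parameter(s): "
                         f"{', '.join(sorted(map(str, symbols)))}")
        self.symbols = symbols


class NotStronglyConnected(LinfraError):
    pass


class NotReversible(LinfraError):
    pass


class EmptyRootSet(LinfraError):
    pass


class NotSpanning(LinfraError):
    """Internal consistency failure in forest machinery."""


class IrreversibleStep(LinfraError):
    def __init__(self, i, j):
        super().__init__(f"no reverse edge for step {i!r} -> {j!r}")
        self.pair = (i, j)


class NotAtEquilibrium(LinfraError):
    def __init__(self, cycle=None, log_mu=None):
        msg = "graph does not satisfy the cycle condition"
        if cycle is not None:
            msg += f"; violating cycle {cycle} with |ln mu| = {log_mu}"
        super().__init__(msg)
        self.cycle = cycle
        self.log_mu = log_mu


class NoRoot(LinfraError):
    pass


class InvalidPartition(LinfraError):
    pass


class MissingAnnotation(LinfraError):
    pass


class ConstantFunction(LinfraError):
    pass


class NoInputSymbol(LinfraError):
    pass


class GrammarViolation(LinfraError):
    def __init__(self, reaction, reason):
        super().__init__(f"reaction {reaction} violates the mechanism grammar: {reason}")
        self.reaction = reaction


class LinearityViolation(LinfraError):
    """rho_Y not linear in substrate concentrations -- signals a grammar bug."""


class ZeroActivity(LinfraError):
    pass


class NoRootFound(LinfraError):
    pass


class NotConverged(LinfraError):
    pass
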