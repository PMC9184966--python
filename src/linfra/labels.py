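"""Edge-label algebra.

Labels are rates: positive sums of products of named positive parameters,
positive numeric literals and at most one designated input symbol.  The
grammar is deliberately restricted to {symbols, numbers, +, *, parentheses}
so that strict positivity for positive assignments is a syntactic fact —
no subtraction or division is allowed inside a label.  Rate expressions that
genuinely need ratios (aggregated parameters, Michaelis constants) live
outside labels.
"""

from __future__ import annotations

import sympy as sp

from .errors import UnparseableLabel

__all__ = ["parse_label", "validate_label_expr", "label_symbols"]


def _check_node(expr: sp.Expr) -> str | None:
    """Return a reason string if *expr* falls outside the label grammar."""
    if expr.is_Symbol:
        return None
    if expr.is_Number:
        if expr.is_negative or expr == 0:
            return f"non-positive literal {expr}"
        if not expr.is_real:
            return f"non-real literal {expr}"
        return None
    if isinstance(expr, (sp.Add, sp.Mul)):
        for arg in expr.args:
            reason = _check_node(arg)
            if reason is not None:
                return reason
        return None
    # Pow shows up when sympy folds k*k; integer exponents >= 1 are still
    # products, so admit them.
    if isinstance(expr, sp.Pow):
        base, exponent = expr.args
        if exponent.is_Integer and exponent >= 1:
            return _check_node(base)
        return f"disallowed power {expr}"
    return f"disallowed operation {type(expr).__name__} in {expr}"


def validate_label_expr(expr: sp.Expr, label=None, edge=None) -> sp.Expr:
    reason = _check_node(sp.sympify(expr))
    if reason is not None:
        raise UnparseableLabel(label if label is not None else str(expr),
                               edge=edge, reason=reason)
    return expr


def parse_label(label, edge=None) -> sp.Expr:
    """Parse a label string (or number/expression) under the label grammar.

    Raises :class:`UnparseableLabel` for anything outside positive sums of
    monomials.
    """
    if isinstance(label, sp.Expr):
        return validate_label_expr(label, label=str(label), edge=edge)
    if isinstance(label, (int, float)):
        if label <= 0:
            raise UnparseableLabel(label, edge=edge, reason="rates must be positive")
        return sp.Integer(label) if isinstance(label, int) else sp.Float(label)
    try:
        expr = sp.parse_expr(str(label), evaluate=True)
    except (sp.SympifyError, SyntaxError, TypeError) as exc:
        raise UnparseableLabel(label, edge=edge, reason=str(exc)) from None
    return validate_label_expr(expr, label=label, edge=edge)


def label_symbols(expr: sp.Expr) -> set[sp.Symbol]:
    return set(expr.free_symbols)
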