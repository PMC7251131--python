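"""Pearson and partial correlation.

The partial correlation coefficient ``Pcc(X, Y | Z^1..Z^s)`` measures the
association between X and Y with the linear information of the
conditioning set removed.  It satisfies the textbook recursion

    Pcc(X,Y|Z1)      = (r_XY - r_XZ1 r_YZ1) / sqrt((1-r_XZ1^2)(1-r_YZ1^2))
    Pcc(X,Y|Z1,Z2)   = (Pcc(X,Y|Z1) - Pcc(X,Z2|Z1) Pcc(Y,Z2|Z1)) / ...

and equals the correlation of the residuals of X and Y after least-squares
regression on the conditioners.  The residual form is numerically stabler
and is the default; the recursion is kept as an independent formulation
(the two must agree to ~1e-10 on well-conditioned data).
"""

from __future__ import annotations

import numpy as np

from .errors import UndefinedCorrelationError, ZeroDenominatorError

__all__ = ["corr", "partial_corr", "partial_corr_recursive"]

_COLLINEAR_TOL = 1e-10


def _validate(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 3:
        raise ValueError("corr requires two equal-length 1-D arrays of length >= 3")
    return a, b


def corr(a, b) -> float:
    """Pearson product-moment correlation in [-1, 1]."""
    a, b = _validate(a, b)
    if np.std(a) == 0.0 or np.std(b) == 0.0:
        raise UndefinedCorrelationError("correlation undefined for zero-variance input")
    return float(np.clip(np.corrcoef(a, b)[0, 1], -1.0, 1.0))


def _guard_collinear(x, y, conditioners, names=None) -> None:
    for j, z in enumerate(conditioners):
        label = names[j] if names else f"conditioner {j}"
        for side, s in (("x", x), ("y", y)):
            if abs(corr(s, z)) > 1 - _COLLINEAR_TOL:
                raise ZeroDenominatorError(
                    f"partial correlation denominator vanishes: {label} is "
                    f"perfectly collinear with {side}"
                )


def partial_corr(x, y, conditioners=(), names=None) -> float:
    """``Pcc(x, y | conditioners)`` via regression residuals.

    With an empty conditioning set this is ``corr(x, y)``.  The result is
    independent of conditioner order.  A conditioner perfectly collinear
    with ``x`` or ``y`` raises :class:`ZeroDenominatorError` naming the
    offending pair.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    conditioners = [np.asarray(z, dtype=float) for z in conditioners]
    if not conditioners:
        return corr(x, y)
    for z in conditioners:
        if z.shape != x.shape:
            raise ValueError("all conditioners must share the support of x and y")
    _guard_collinear(x, y, conditioners, names)
    design = np.column_stack([np.ones_like(x)] + conditioners)
    coef_x, *_ = np.linalg.lstsq(design, x, rcond=None)
    coef_y, *_ = np.linalg.lstsq(design, y, rcond=None)
    rx = x - design @ coef_x
    ry = y - design @ coef_y
    if np.std(rx) == 0.0 or np.std(ry) == 0.0:
        raise ZeroDenominatorError(
            "partial correlation undefined: residual variance is zero"
        )
    return float(np.clip(np.corrcoef(rx, ry)[0, 1], -1.0, 1.0))


def partial_corr_recursive(x, y, conditioners=()) -> float:
    """``Pcc(x, y | conditioners)`` by the defining recursion.

    Retained as an independent formulation of the same quantity; peels the
    last conditioner at each level.
    """
    conditioners = [np.asarray(z, dtype=float) for z in conditioners]

    def pcc(a, b, cond):
        if not cond:
            return corr(a, b)
        z, rest = cond[-1], cond[:-1]
        r_ab = pcc(a, b, rest)
        r_az = pcc(a, z, rest)
        r_bz = pcc(b, z, rest)
        denom_sq = (1.0 - r_az**2) * (1.0 - r_bz**2)
        if denom_sq <= _COLLINEAR_TOL**2:
            raise ZeroDenominatorError(
                "partial correlation denominator vanishes in the recursion"
            )
        return (r_ab - r_az * r_bz) / np.sqrt(denom_sq)

    return float(np.clip(pcc(np.asarray(x, float), np.asarray(y, float), conditioners), -1, 1))
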