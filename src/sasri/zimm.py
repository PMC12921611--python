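"""Classical and interaction-corrected Zimm forms.

The Zimm representation plots n/I(Q) — reciprocal intensity per particle —
which to leading order in Q² and n is linear in both:

    classical:  n/I(Q) ≈ (1 + 2 n B22)/P(0) · (1 + Q²R_g²/3)

    modified:   n/I(Q) ≈ (1 + 2 n B22)/P(0) · (1 + Q²R_g,0²/3)
                                            · (1 − n B22 Q² R_i²/3)

The modified form carries the structure-factor correction explicitly: the
apparent Q² slope acquires a concentration-dependent term −nB22·R_i²/3,
which is exactly the shift the two-stage Guinier route measures.  Fitting
the modified surface is an alternative estimator of (R_g,0, R_i, B22)
used as a cross-check of the primary route, not a replacement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .exceptions import FitError, ValidationError


def zimm_classic(q, n, p0: float, rg: float, b22_mL: float):
    """Classical Zimm reciprocal intensity n/I(Q)."""
    if p0 <= 0:
        raise ValidationError("P(0) must be positive")
    q = np.asarray(q, dtype=float)
    n = np.asarray(n, dtype=float)
    return (1.0 + 2.0 * n * b22_mL) / p0 * (1.0 + q**2 * rg**2 / 3.0)


def zimm_modified(q, n, p0: float, rg0: float, ri: float, b22_mL: float):
    """Interaction-corrected Zimm reciprocal intensity n/I(Q).

    Reduces exactly to :func:`zimm_classic` when ri = 0 or b22 = 0.
    """
    if p0 <= 0:
        raise ValidationError("P(0) must be positive")
    q = np.asarray(q, dtype=float)
    n = np.asarray(n, dtype=float)
    return (
        (1.0 + 2.0 * n * b22_mL)
        / p0
        * (1.0 + q**2 * rg0**2 / 3.0)
        * (1.0 - n * b22_mL * q**2 * ri**2 / 3.0)
    )


@dataclass(frozen=True)
class ZimmFit:
    """Fitted Zimm parameters with 1σ errors (NaN where not applicable).

    For the classical form ``rg`` is populated and ``ri`` is NaN; for the
    modified form ``rg`` holds R_g,0 and ``ri`` the interaction radius.
    """

    p0: float
    p0_err: float
    rg: float
    rg_err: float
    b22_mL: float
    b22_err_mL: float
    ri: float
    ri_err: float
    modified: bool
    cost: float


def fit_zimm(q, n, y, modified: bool = False) -> ZimmFit:
    """Least-squares fit of observed (q, n, n/I) triples to a Zimm form.

    The modified form's (b22, ri) product enters only through the
    n·Q²-cross term, so ≥ 3 distinct n values are required for it; the
    classical form needs ≥ 2 distinct n and both need ≥ 3 distinct q.
    """
    q = np.asarray(q, dtype=float).ravel()
    n = np.asarray(n, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if not (q.shape == n.shape == y.shape):
        raise ValidationError("q, n, y must have equal lengths")
    n_distinct_n = np.unique(n).size
    n_distinct_q = np.unique(q).size
    if n_distinct_q < 3:
        raise FitError(
            f"need ≥ 3 distinct Q values (got {n_distinct_q})"
        )
    need_n = 3 if modified else 2
    if n_distinct_n < need_n:
        raise FitError(
            f"need ≥ {need_n} distinct n values for the "
            f"{'modified' if modified else 'classical'} form "
            f"(got {n_distinct_n})"
        )
    if np.any(y <= 0):
        raise ValidationError("n/I must be positive")

    # initial guesses from the surface itself; residuals are relative
    # (model/y − 1) so the fit is insensitive to the absolute intensity
    # scale, which can be ~1e18 in per-particle units
    p0_guess = 1.0 / float(y.min())
    # crude Rg from the q² trend at the lowest concentration
    m0 = n == n.min()
    if np.unique(q[m0]).size >= 2:
        slope0 = np.polyfit(q[m0] ** 2, y[m0] / y[m0].min(), 1)[0]
        rg_guess = float(np.sqrt(max(3.0 * slope0, 1.0)))
    else:
        rg_guess = 15.0
    b22_scale = 1.0 / (2.0 * float(n.max()))  # makes n·b22 O(1) internally

    if modified:
        # params: (p0/p0_guess, rg0, ri, b22/b22_scale) — all O(1–10)
        def resid(p):
            return (
                zimm_modified(q, n, p0_guess * p[0], p[1], p[2],
                              p[3] * b22_scale) / y
                - 1.0
            )

        x0 = [1.0, rg_guess, rg_guess, 0.0]
        bounds = ([1e-12, 0.0, 0.0, -np.inf], np.inf)
    else:
        def resid(p):
            return (
                zimm_classic(q, n, p0_guess * p[0], p[1], p[2] * b22_scale)
                / y - 1.0
            )

        x0 = [1.0, rg_guess, 0.0]
        bounds = ([1e-12, 0.0, -np.inf], np.inf)

    sol = least_squares(resid, x0, bounds=bounds,
                        xtol=1e-12, ftol=1e-12, gtol=1e-12)
    if not sol.success:
        raise FitError(f"Zimm fit did not converge: {sol.message}")

    # covariance from the Jacobian, scaled by residual variance
    J = sol.jac
    dof = max(y.size - J.shape[1], 1)
    s2 = 2.0 * sol.cost / dof
    try:
        cov = np.linalg.inv(J.T @ J) * s2
    except np.linalg.LinAlgError:
        cov = np.full((J.shape[1], J.shape[1]), np.nan)
    perr = np.sqrt(np.abs(np.diag(cov)))

    if modified:
        return ZimmFit(
            p0=p0_guess * sol.x[0], p0_err=p0_guess * perr[0],
            rg=sol.x[1], rg_err=perr[1],
            ri=sol.x[2], ri_err=perr[2],
            b22_mL=sol.x[3] * b22_scale, b22_err_mL=perr[3] * b22_scale,
            modified=True, cost=float(sol.cost),
        )
    return ZimmFit(
        p0=p0_guess * sol.x[0], p0_err=p0_guess * perr[0],
        rg=sol.x[1], rg_err=perr[1],
        b22_mL=sol.x[2] * b22_scale, b22_err_mL=perr[2] * b22_scale,
        ri=float("nan"), ri_err=float("nan"),
        modified=False, cost=float(sol.cost),
    )
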