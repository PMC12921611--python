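"""Classical Guinier analysis of a single profile.

At low Q the form-factor scattering of a dilute solution follows
``I(Q) ≈ I(0) exp(−Q² R_g²/3)``, so a straight-line fit of ln I against Q²
yields the apparent radius of gyration R_g,obs = √(−3·slope) and the
forward intensity I(0) = exp(intercept).  At finite concentration the
structure factor shifts R_g,obs away from the true single-particle value;
that shift is what the series-level analysis in :mod:`sasri.interaction`
inverts.

The fit is performed in ln-space by weighted linear least squares with
σ_ln I = dI/I (delta method), the standard Guinier practice.  The
conventional validity guard Q_max·R_g ≤ 1.3 produces a warning, not an
error.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import FitError, NoGuinierDecayError, ValidationError
from .linfit import fit_line
from .profiles import ScatteringProfile

log = logging.getLogger(__name__)

#: Paper-of-record default fit window for a small globular protein, Å⁻¹.
DEFAULT_Q_LO = 0.015
DEFAULT_Q_HI = 0.07

#: Conventional Guinier validity bound on Q_max·R_g.
Q_RG_GUARD = 1.3


@dataclass(frozen=True)
class GuinierResult:
    """Output of a single Guinier fit.

    ``covariance`` is the 2×2 covariance of (ln I(0), R_g²) estimates;
    ``residuals`` are the standardized ln-space residuals over the window.
    """

    rg_obs: float          # Å
    rg_obs_err: float      # Å, 1σ
    i0: float              # intensity units
    i0_err: float          # intensity units, 1σ
    q_lo: float            # Å⁻¹
    q_hi: float            # Å⁻¹
    n_points: int
    n_excluded: int        # in-window points with I ≤ 0, excluded
    q_rg_max: float        # q_hi × rg_obs
    residuals: np.ndarray
    covariance: np.ndarray
    weighted: bool

    @property
    def rg_obs2(self) -> float:
        return self.rg_obs**2

    @property
    def rg_obs2_err(self) -> float:
        # first-order propagation σ(R²) = 2 R σ(R)
        return 2.0 * self.rg_obs * self.rg_obs_err


def guinier_fit(
    profile: ScatteringProfile,
    q_lo: float = DEFAULT_Q_LO,
    q_hi: float = DEFAULT_Q_HI,
    weighted: bool = True,
) -> GuinierResult:
    """Fit ln I vs Q² over [q_lo, q_hi] and return (R_g,obs, I(0)).

    Points with I ≤ 0 inside the window (possible after background
    subtraction) are excluded and counted; ≥ 5 usable points are required.
    When the profile carries no uncertainties the fit silently falls back
    to unweighted (logged).

    Raises
    ------
    NoGuinierDecayError
        If the fitted slope is non-negative (no decay: R_g undefined).
    FitError
        If fewer than 5 usable points lie in the window.
    """
    mask = profile.window(q_lo, q_hi)
    usable = mask & (profile.i > 0)
    n_excluded = int(mask.sum() - usable.sum())
    if usable.sum() < 5:
        raise FitError(
            f"only {int(usable.sum())} usable points in window "
            f"[{q_lo}, {q_hi}] Å⁻¹ (need ≥ 5; {n_excluded} had I ≤ 0)"
        )

    q = profile.q[usable]
    i = profile.i[usable]
    di = profile.di[usable]
    x = q**2
    y = np.log(i)

    use_weights = weighted and profile.has_uncertainties
    if weighted and not profile.has_uncertainties:
        log.info("%s: no uncertainties; falling back to unweighted Guinier fit",
                 profile.label)
    sigma = di / i if use_weights else None
    if sigma is not None and np.any(sigma <= 0):
        raise ValidationError("zero uncertainty on a positive-I point; "
                              "use weighted=False or supply full dI")

    fit = fit_line(x, y, sigma=sigma)
    if fit.slope >= 0:
        raise NoGuinierDecayError(
            f"no Guinier decay: ln I vs Q² slope {fit.slope:.3g} ≥ 0"
        )

    rg2 = -3.0 * fit.slope
    rg = math.sqrt(rg2)
    rg2_err = 3.0 * fit.slope_err
    rg_err = rg2_err / (2.0 * rg)
    i0 = math.exp(fit.intercept)
    i0_err = i0 * fit.intercept_err

    # covariance of (ln I0, Rg²) from (intercept, slope): Rg² = −3·slope
    cov = np.array(
        [
            [fit.cov[0, 0], -3.0 * fit.cov[0, 1]],
            [-3.0 * fit.cov[0, 1], 9.0 * fit.cov[1, 1]],
        ]
    )

    resid = y - fit.predict(x)
    if sigma is not None:
        std_resid = resid / sigma
    else:
        s = np.std(resid, ddof=2) if x.size > 2 else 0.0
        std_resid = resid / s if s > 0 else resid

    q_rg_max = q_hi * rg
    if q_rg_max > Q_RG_GUARD:
        warnings.warn(
            f"Q_max·R_g = {q_rg_max:.2f} exceeds {Q_RG_GUARD}; the Guinier "
            "approximation may be biased — consider lowering q_hi"
        )

    return GuinierResult(
        rg_obs=rg,
        rg_obs_err=rg_err,
        i0=i0,
        i0_err=i0_err,
        q_lo=q_lo,
        q_hi=q_hi,
        n_points=int(usable.sum()),
        n_excluded=n_excluded,
        q_rg_max=q_rg_max,
        residuals=std_resid,
        covariance=cov,
        weighted=bool(use_weights),
    )


def window_sweep(
    profile: ScatteringProfile,
    q_lo_grid,
    q_hi_grid,
    weighted: bool = True,
) -> pd.DataFrame:
    """Guinier fit over every (q_lo, q_hi) pair of the two grids.

    Windows failing the fit preconditions are kept as flagged rows rather
    than dropped, so the sweep table always has len(lo)×len(hi) rows.
    The frame carries the R_g spread across valid windows in ``attrs``.
    """
    q_lo_grid = np.atleast_1d(np.asarray(q_lo_grid, dtype=float))
    q_hi_grid = np.atleast_1d(np.asarray(q_hi_grid, dtype=float))
    if q_lo_grid.size == 0 or q_hi_grid.size == 0:
        raise ValidationError("window grids must be non-empty")

    rows = []
    for lo in q_lo_grid:
        for hi in q_hi_grid:
            row = {"q_lo": lo, "q_hi": hi, "ok": False, "reason": ""}
            if lo >= hi:
                row["reason"] = "q_lo >= q_hi"
            else:
                try:
                    res = guinier_fit(profile, lo, hi, weighted=weighted)
                except (FitError, ValidationError) as exc:
                    row["reason"] = str(exc)
                else:
                    row.update(
                        ok=True,
                        rg_obs=res.rg_obs,
                        rg_obs_err=res.rg_obs_err,
                        i0=res.i0,
                        i0_err=res.i0_err,
                        n_points=res.n_points,
                        q_rg_max=res.q_rg_max,
                    )
            rows.append(row)
    table = pd.DataFrame(rows)
    if table["ok"].any():
        rg = table.loc[table["ok"], "rg_obs"]
        table.attrs["rg_spread"] = float(rg.max() - rg.min())
    else:
        table.attrs["rg_spread"] = float("nan")
    return table


@dataclass(frozen=True)
class ResidualDiagnostics:
    """Qualitative health indicators of a Guinier fit's residuals."""

    mean: float
    runs_p: float          # Wald–Wolfowitz runs test on residual signs
    runs_degenerate: bool  # too few sign changes / all-equal residuals
    smile: bool            # aggregation indicator: ends up, center down


def residual_diagnostics(result: GuinierResult) -> ResidualDiagnostics:
    """Runs test and "smile" detection on standardized residuals.

    A smile — both window-end segments averaging above their standard
    error while the central segment averages below minus its standard
    error — is the classic qualitative signature of irreversible
    aggregates contaminating the low-Q region.
    """
    r = np.asarray(result.residuals, dtype=float)
    if r.size < 5:
        raise ValidationError("need ≥ 5 residuals for diagnostics")

    mean = float(np.mean(r))

    # Wald–Wolfowitz runs test on signs about zero (normal approximation)
    signs = np.sign(r)
    nonzero = signs[signs != 0]
    if nonzero.size < 2 or np.all(nonzero == nonzero[0]):
        runs_p, degenerate = 1.0, True
    else:
        n_pos = int((nonzero > 0).sum())
        n_neg = int((nonzero < 0).sum())
        runs = 1 + int((np.diff(nonzero) != 0).sum())
        n = n_pos + n_neg
        mu = 2.0 * n_pos * n_neg / n + 1.0
        var = (2.0 * n_pos * n_neg * (2.0 * n_pos * n_neg - n)) / (
            n**2 * (n - 1.0)
        )
        if var <= 0:
            runs_p, degenerate = 1.0, True
        else:
            z = (runs - mu) / math.sqrt(var)
            runs_p = float(2.0 * (1.0 - _norm_cdf(abs(z))))
            degenerate = False

    # smile: thirds of the window; residuals are already in units of σ,
    # so a segment mean is "beyond 1σ" when |mean|·√m > 1.
    k = r.size // 3
    left, center, right = r[:k], r[k: r.size - k], r[r.size - k:]

    def _z(seg):
        return float(np.mean(seg) * math.sqrt(seg.size))

    smile = _z(left) > 1.0 and _z(right) > 1.0 and _z(center) < -1.0

    return ResidualDiagnostics(
        mean=mean, runs_p=runs_p, runs_degenerate=degenerate, smile=smile
    )


def _norm_cdf(x: float) -> float:
    return 0.5 * (1.0 + math.erf(x / math.sqrt(2.0)))
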