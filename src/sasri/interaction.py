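"""Two-stage inversion of a concentration series.

The apparent Guinier radius measured at number density n obeys

    R_g,obs² = R_g,0² + ξ R_i²,     ξ = ½ (S(0) − 1)/S(0),

where R_g,0 is the infinite-dilution radius of gyration and R_i the
radius of interparticle interaction — the root-mean-square distance of
the total correlation function h(r).  In the dilute regime
S(0) = 1 − 2 n B22 and ξ ≈ −n B22, so the workflow is:

1. Guinier-fit each profile → (R_g,obs, I(0)) per concentration.
2. Fit I(0)/n vs n with a line y = b(1 − 2 B22 n); B22 = −a/(2b).
3. Fit R_g,obs² against x = −n B22 (or the exact ξ): the slope is R_i²,
   the intercept R_g,0².

B22 here is in mL per particle pair (the scattering convention); helpers
convert to mL/mol and mol·mL/g².
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .constants import N_A
from .exceptions import FitError, ValidationError
from .guinier import DEFAULT_Q_HI, DEFAULT_Q_LO, GuinierResult, guinier_fit
from .linfit import LineFit, fit_line
from .profiles import ScatteringProfile

log = logging.getLogger(__name__)


# ---------------------------------------------------------------- utilities

def number_density(c: float, mw: float) -> float:
    """Particles per mL from mass concentration c [mg/mL] and M_W [g/mol].

    n = (c/1000) / M_W × N_A.
    """
    if c <= 0:
        raise ValidationError("concentration must be positive")
    if mw <= 0:
        raise ValidationError("molecular weight must be positive")
    return (c / 1000.0) / mw * N_A


def volume_fraction(c: float, rho: float) -> float:
    """Dimensionless volume fraction ϕ = c/ρ (c in mg/mL, ρ in g/cm³)."""
    if c <= 0:
        raise ValidationError("concentration must be positive")
    if rho <= 0:
        raise ValidationError("mass density must be positive")
    return (c / 1000.0) / rho


def convert_b22(b22_mL: float, mw: float) -> tuple[float, float]:
    """Convert B22 from mL/pair to (mL/mol, mol·mL/g²)."""
    if mw <= 0:
        raise ValidationError("molecular weight must be positive")
    per_mol = b22_mL * N_A
    per_mass = per_mol / mw**2
    return per_mol, per_mass


def s_zero(n: float, b22_mL: float) -> float:
    """Forward structure factor S(0) = 1 − 2 n B22 (dilute expansion)."""
    s0 = 1.0 - 2.0 * n * b22_mL
    if s0 <= 0:
        raise ValidationError(
            "beyond dilute-expansion validity: 2·n·B22 ≥ 1 gives S(0) ≤ 0"
        )
    return s0


def xi(s0: float) -> float:
    """Structure-factor prefactor ξ = ½ (S(0) − 1)/S(0)."""
    if s0 <= 0:
        raise ValidationError("S(0) must be positive")
    return 0.5 * (s0 - 1.0) / s0


def xi_dilute(n: float, b22_mL: float, order: str = "exact") -> float:
    """Dilute-limit ξ: exact −nB22/(1−2nB22), or first-order −nB22."""
    if order == "first":
        return -n * b22_mL
    if order == "exact":
        return -n * b22_mL / (1.0 - 2.0 * n * b22_mL)
    raise ValidationError(f"order must be 'first' or 'exact', got {order!r}")


# -------------------------------------------------------------- virial stage

@dataclass(frozen=True)
class VirialResult:
    """Second virial coefficient from the forward-scattering series.

    The fitted line is I(0)/n = b + a·n with B22 = −a/(2b);
    ``covariance`` is the 2×2 covariance of (intercept b, slope a).
    Unit conversions use the molecular weight supplied to
    :func:`fit_virial` (0 when absent).
    """

    b22_mL: float
    b22_err_mL: float
    slope_a: float
    intercept_b: float
    covariance: np.ndarray
    b22_mL_per_mol: float
    b22_mol_mL_per_g2: float
    fit: LineFit
    weighted: bool

    def s_zero(self, n: float) -> float:
        return s_zero(n, self.b22_mL)


def fit_virial(
    points: Sequence[tuple[float, float, float]],
    mw: float | None = None,
    weighted: bool = True,
) -> VirialResult:
    """B22 from (n, I(0), σ_I(0)) triples.

    Fits y = I(0)/n against n (σ_y = σ_I(0)/n when weighting) and returns
    B22 = −a/(2b) with the 1σ delta-method error including the (a, b)
    covariance term.
    """
    pts = [(float(n), float(i0), float(e)) for n, i0, e in points]
    if len(pts) < 3:
        raise ValidationError(f"≥ 3 required: got {len(pts)} points")
    n = np.array([p[0] for p in pts])
    i0 = np.array([p[1] for p in pts])
    err = np.array([p[2] for p in pts])
    if np.any(n <= 0) or np.any(i0 <= 0):
        raise ValidationError("all n and I(0) must be positive")

    y = i0 / n
    use_w = weighted and np.all(err > 0)
    sigma = err / n if use_w else None
    fit = fit_line(n, y, sigma=sigma)

    a, b = fit.slope, fit.intercept
    if b <= 0:
        raise FitError(f"unphysical intercept b = {b:.3g} ≤ 0 in I(0)/n vs n")

    b22 = -a / (2.0 * b)
    # delta method: ∂B/∂a = −1/(2b), ∂B/∂b = a/(2b²)
    da = -1.0 / (2.0 * b)
    db = a / (2.0 * b**2)
    var = (
        db**2 * fit.cov[0, 0]
        + da**2 * fit.cov[1, 1]
        + 2.0 * da * db * fit.cov[0, 1]
    )
    b22_err = math.sqrt(max(var, 0.0))

    if mw is not None:
        per_mol, per_mass = convert_b22(b22, mw)
    else:
        per_mol = per_mass = 0.0

    return VirialResult(
        b22_mL=b22,
        b22_err_mL=b22_err,
        slope_a=a,
        intercept_b=b,
        covariance=fit.cov,
        b22_mL_per_mol=per_mol,
        b22_mol_mL_per_g2=per_mass,
        fit=fit,
        weighted=bool(use_w),
    )


# --------------------------------------------------------- interaction stage

@dataclass(frozen=True)
class InteractionResult:
    """R_i² (slope) and R_g,0² (intercept) from R_g,obs² vs x.

    ``ri`` is NaN (flagged undefined) when the fitted R_i² is negative —
    reported, not hidden, since that is a primary data-quality diagnostic.
    ``x_mode`` records which abscissa was used ('dilute' for −nB22,
    'xi_exact' for −nB22/(1−2nB22)).
    """

    ri2: float
    ri2_err: float
    rg0_2: float
    rg0_2_err: float
    fit: LineFit
    x_mode: str = "dilute"

    @property
    def ri(self) -> float:
        return math.sqrt(self.ri2) if self.ri2 > 0 else float("nan")

    @property
    def ri_err(self) -> float:
        if self.ri2 <= 0:
            return float("nan")
        return self.ri2_err / (2.0 * math.sqrt(self.ri2))

    @property
    def ri_defined(self) -> bool:
        return self.ri2 > 0

    @property
    def rg0(self) -> float:
        return math.sqrt(self.rg0_2)

    @property
    def rg0_err(self) -> float:
        return self.rg0_2_err / (2.0 * math.sqrt(self.rg0_2))

    @property
    def ratio(self) -> float:
        """R_i / R_g,0 (NaN when R_i is undefined)."""
        return self.ri / self.rg0

    def ci95_band(self, x):
        """95% confidence half-width of the fitted line at abscissa x."""
        return self.fit.confidence_band(x, z=1.96)


def fit_interaction(
    points: Sequence[tuple[float, float, float]],
    weighted: bool = True,
    x_mode: str = "dilute",
) -> InteractionResult:
    """Fit R_g,obs² = R_g,0² + R_i²·x over (x, R_g,obs², σ_{R_g,obs²}).

    x is −nB22 (dilute) or exact ξ; the caller computes it.  A negative
    fitted slope is returned with R_i flagged undefined and a warning;
    a non-positive intercept raises, since R_g,0² > 0 always.
    """
    pts = [(float(x), float(y), float(e)) for x, y, e in points]
    if len(pts) < 3:
        raise ValidationError(f"≥ 3 required: got {len(pts)} points")
    x = np.array([p[0] for p in pts])
    y = np.array([p[1] for p in pts])
    err = np.array([p[2] for p in pts])
    if np.ptp(x) == 0:
        raise FitError("x-values all equal: interaction fit is singular")

    use_w = weighted and np.all(err > 0)
    fit = fit_line(x, y, sigma=err if use_w else None)

    rg0_2, ri2 = fit.intercept, fit.slope
    if rg0_2 <= 0:
        raise FitError(f"unphysical intercept R_g,0² = {rg0_2:.3g} ≤ 0")
    if ri2 <= 0:
        warnings.warn(
            f"fitted R_i² = {ri2:.3g} Å² ≤ 0: R_i undefined — the series "
            "carries no resolvable interaction signal"
        )

    return InteractionResult(
        ri2=ri2,
        ri2_err=fit.slope_err,
        rg0_2=rg0_2,
        rg0_2_err=fit.intercept_err,
        fit=fit,
        x_mode=x_mode,
    )


# ------------------------------------------------------------- full pipeline

@dataclass(frozen=True)
class SeriesAnalysis:
    """Full provenance chain of the two-stage inversion."""

    guinier: list[GuinierResult]
    virial: VirialResult
    interaction: InteractionResult
    n_per_mL: np.ndarray
    x: np.ndarray


def analyze_series(
    series: Sequence[ScatteringProfile],
    mw: float,
    q_lo: float = DEFAULT_Q_LO,
    q_hi: float = DEFAULT_Q_HI,
    weighted: bool = True,
    x_mode: str = "dilute",
) -> SeriesAnalysis:
    """Run the full workflow on an ordered concentration series.

    Every profile must carry a concentration.  Stages: Guinier fit per
    profile; virial fit of (n, I(0)); abscissa x = −nB22 (``x_mode=
    'dilute'``, the default) or exact ξ (``'xi_exact'``); interaction fit
    of (x, R_g,obs²).  Any stage failure is re-raised with the stage name.
    """
    if x_mode not in ("dilute", "xi_exact"):
        raise ValidationError(f"unknown x_mode {x_mode!r}")
    if len(series) < 3:
        raise ValidationError("≥ 3 required: series too short")
    for p in series:
        if p.concentration is None:
            raise ValidationError(f"profile {p.label!r} has no concentration")

    n_arr = np.array([number_density(p.concentration, mw) for p in series])

    gs: list[GuinierResult] = []
    for p in series:
        try:
            gs.append(guinier_fit(p, q_lo, q_hi, weighted=weighted))
        except Exception as exc:
            raise FitError(f"guinier stage failed on {p.label!r}: {exc}") from exc

    try:
        vir = fit_virial(
            [(n, g.i0, g.i0_err) for n, g in zip(n_arr, gs)],
            mw=mw,
            weighted=weighted,
        )
    except Exception as exc:
        raise FitError(f"virial stage failed: {exc}") from exc

    if x_mode == "dilute":
        x = -n_arr * vir.b22_mL
    else:
        x = np.array(
            [xi_dilute(n, vir.b22_mL, order="exact") for n in n_arr]
        )

    try:
        inter = fit_interaction(
            [(xi_, g.rg_obs2, g.rg_obs2_err) for xi_, g in zip(x, gs)],
            weighted=weighted,
            x_mode=x_mode,
        )
    except Exception as exc:
        raise FitError(f"interaction stage failed: {exc}") from exc

    return SeriesAnalysis(
        guinier=gs, virial=vir, interaction=inter, n_per_mL=n_arr, x=x
    )
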