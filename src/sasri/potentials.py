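"""R_i and B22 from isotropic pair potentials, plus structure-factor tools.

For a dilute solution the total correlation function is the Mayer
function, h(r) = e^(−V(r)/k_BT) − 1, and the radius of interparticle
interaction is the root-mean-square distance of h:

    R_i² = ∫ h(r) r² d³r / ∫ h(r) d³r = ∫ h r⁴ dr / ∫ h r² dr.

For weak potentials (|V| ≪ k_BT) the Mayer function linearizes to −βV and
R_i² ≈ ∫ V r⁴ dr / ∫ V r² dr.  The same integrals give the second virial
coefficient B22 = −½ ∫ h(r) 4π r² dr, and the structure factor follows
from the radial Fourier transform S(Q) = 1 + 4πn ∫ h r² sinc(Qr) dr with
the low-Q exponential asymptote S(Q) ≈ S(0)·exp(−⅙·((S(0)−1)/S(0))·Q²R_i²).

Hard-sphere closed forms (R_i = √(3/5)·σ = 2·R_g,HS, B22 = (2π/3)σ³)
serve as exact references for the quadratures.

Energies are handled in k_BT units internally; tabulated potentials in
absolute units are converted on ingestion using the supplied temperature.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import quad
from scipy.interpolate import interp1d

from .constants import K_B, ML_PER_A3, N_A
from .exceptions import IllConditionedError, ValidationError

_QUAD_TOL = 1e-9        # absolute+relative quadrature tolerance
_TAIL_TOL = 1e-12       # |integrand| cutoff (relative to peak) defining r_max


@dataclass(frozen=True)
class PotentialSpec:
    """An isotropic pair potential V(r).

    Supported forms and their ``params`` (lengths in Å, energies in k_BT):

    - ``hard_sphere``: sigma (contact diameter; V = ∞ below, 0 above)
    - ``square_well``: sigma, depth (ε > 0 means attractive V = −ε),
      lam (outer range as a multiple of sigma), hard_core (default True)
    - ``gaussian_well``: depth, lam (V = −ε·exp(−(r/λ)²); no core)
    - ``yukawa``: sigma, depth, lam (hard core below σ, then
      V = −ε·σ·exp(−(r−σ)/λ)/r)
    - ``tabulated``: r (strictly increasing from 0 or σ), v (same length);
      ``energy_unit`` one of 'kT' (default), 'J', 'kJ/mol', 'kcal/mol' —
      absolute units are divided by k_B·temperature on ingestion.
      A first grid point r[0] > 0 implies a hard core below it.  A
      potential-of-mean-force table ω(r) goes through the same pathway:
      the mathematics is identical, the caller asserts the interpretation.
    """

    form: str
    params: dict = field(default_factory=dict)
    temperature: float = 298.15  # K

    def __post_init__(self):
        forms = {"hard_sphere", "square_well", "gaussian_well", "yukawa",
                 "tabulated"}
        if self.form not in forms:
            raise ValidationError(f"unknown potential form {self.form!r}")
        p = dict(self.params)
        if self.form in ("hard_sphere", "square_well", "yukawa"):
            if p.get("sigma", 0.0) <= 0:
                raise ValidationError("sigma must be positive")
        if self.form == "square_well":
            if p.get("lam", 0.0) <= 1.0:
                raise ValidationError("square-well range lam must exceed 1")
            p.setdefault("hard_core", True)
        if self.form in ("gaussian_well", "yukawa"):
            if p.get("lam", 0.0) <= 0:
                raise ValidationError("range parameter lam must be positive")
        if self.form == "tabulated":
            r = np.asarray(p.get("r", ()), dtype=float)
            v = np.asarray(p.get("v", ()), dtype=float)
            if r.size < 2 or r.shape != v.shape:
                raise ValidationError("tabulated form needs matching r, v arrays")
            if r[0] < 0 or np.any(np.diff(r) <= 0):
                raise ValidationError("tabulated r must be ≥ 0 and strictly increasing")
            unit = p.get("energy_unit", "kT")
            kT = K_B * self.temperature
            scale = {
                "kT": 1.0,
                "J": 1.0 / kT,
                "kJ/mol": 1e3 / (kT * N_A),
                "kcal/mol": 4184.0 / (kT * N_A),
            }
            if unit not in scale:
                raise ValidationError(f"unknown energy_unit {unit!r}")
            p["r"] = r
            p["v"] = v * scale[unit]
            p["energy_unit"] = "kT"
        object.__setattr__(self, "params", p)

    # -- evaluation ---------------------------------------------------------

    @property
    def hard_core_radius(self) -> float:
        """Radius below which V = +∞ (0 when the potential is finite)."""
        p = self.params
        if self.form == "hard_sphere":
            return p["sigma"]
        if self.form == "square_well":
            return p["sigma"] if p["hard_core"] else 0.0
        if self.form == "yukawa":
            return p["sigma"]
        if self.form == "tabulated":
            return p["r"][0] if p["r"][0] > 0 else 0.0
        return 0.0

    @property
    def knots(self) -> tuple[float, ...]:
        """Radii where V is discontinuous or non-smooth (quadrature splits)."""
        p = self.params
        if self.form == "hard_sphere":
            return (p["sigma"],)
        if self.form == "square_well":
            return (p["sigma"], p["sigma"] * p["lam"])
        if self.form == "yukawa":
            return (p["sigma"],)
        if self.form == "tabulated":
            return tuple(p["r"])
        return ()

    def beta_v(self, r):
        """V(r)/k_BT for r beyond the hard core (vectorized)."""
        r = np.asarray(r, dtype=float)
        p = self.params
        if self.form == "hard_sphere":
            return np.zeros_like(r)
        if self.form == "square_well":
            return np.where(
                (r >= p["sigma"]) & (r < p["sigma"] * p["lam"]),
                -p["depth"], 0.0,
            )
        if self.form == "gaussian_well":
            return -p["depth"] * np.exp(-((r / p["lam"]) ** 2))
        if self.form == "yukawa":
            out = np.zeros_like(r)
            m = r >= p["sigma"]
            rm = np.where(m, r, p["sigma"])
            out = np.where(
                m,
                -p["depth"] * p["sigma"] * np.exp(-(rm - p["sigma"]) / p["lam"]) / rm,
                0.0,
            )
            return out
        # tabulated: linear interpolation, 0 beyond the table
        f = interp1d(
            p["r"], p["v"], kind="linear", bounds_error=False, fill_value=0.0
        )
        return f(r)

    def mayer(self, r):
        """h(r) = e^(−βV) − 1 beyond the hard core; −1 inside it."""
        r = np.asarray(r, dtype=float)
        core = self.hard_core_radius
        out = np.expm1(-self.beta_v(r))
        return np.where(r < core, -1.0, out)

    def r_max(self) -> float:
        """Adaptive outer cutoff: where |βV| has decayed below tolerance."""
        p = self.params
        if self.form == "hard_sphere":
            return p["sigma"]
        if self.form == "square_well":
            return p["sigma"] * p["lam"]
        if self.form == "tabulated":
            return float(p["r"][-1])
        # smooth tails: start at a few ranges and double until decayed
        if self.form == "gaussian_well":
            r = 6.0 * p["lam"]
        else:  # yukawa
            r = p["sigma"] + 6.0 * p["lam"]
        peak = max(abs(p["depth"]), 1e-30)
        for _ in range(60):
            if abs(float(self.beta_v(r))) < _TAIL_TOL * peak:
                return r
            r *= 2.0
        raise ValidationError("potential tail does not decay: r_max not found")


@dataclass(frozen=True)
class CorrelationFunction:
    """A total correlation function h(r) = g(r) − 1 on r ≥ 0.

    Either closed-form via ``func`` or tabulated via (r, h); h must stay
    ≥ −1 and decay to 0 at large r.  ``r_max`` bounds the support used in
    quadratures.
    """

    func: object = None
    r: np.ndarray | None = None
    h: np.ndarray | None = None
    r_max: float = 0.0
    knots: tuple = ()

    def __post_init__(self):
        if self.func is None:
            r = np.asarray(self.r, dtype=float)
            h = np.asarray(self.h, dtype=float)
            if r.size < 2 or r.shape != h.shape:
                raise ValidationError("tabulated h needs matching r, h arrays")
            if np.any(h < -1.0 - 1e-12):
                raise ValidationError("h(r) must be ≥ −1")
            object.__setattr__(self, "r", r)
            object.__setattr__(self, "h", h)
            if self.r_max == 0.0:
                object.__setattr__(self, "r_max", float(r[-1]))
            object.__setattr__(self, "knots", tuple(r))
        elif self.r_max <= 0.0:
            raise ValidationError("closed-form h needs an explicit r_max")

    def __call__(self, r):
        if self.func is not None:
            return np.asarray(self.func(np.asarray(r, dtype=float)), dtype=float)
        f = interp1d(
            self.r, self.h, kind="linear", bounds_error=False, fill_value=0.0
        )
        return f(r)

    @classmethod
    def from_potential(cls, pot: PotentialSpec) -> "CorrelationFunction":
        """Dilute-limit h from a potential: the Mayer function."""
        return cls(func=pot.mayer, r_max=pot.r_max(), knots=pot.knots)


# ------------------------------------------------------------- quadratures

def _radial_integral(f, r_max: float, knots=()) -> float:
    """∫₀^r_max f(r) dr with mandatory subdivision at the knots."""
    pts = sorted({0.0, r_max, *(k for k in knots if 0.0 < k < r_max)})
    total = 0.0
    for lo, hi in zip(pts[:-1], pts[1:]):
        val, _ = quad(f, lo, hi, epsabs=_QUAD_TOL, epsrel=_QUAD_TOL, limit=200)
        total += val
    return total


@dataclass(frozen=True)
class RiResult:
    """R_i² (Å²) and R_i (NaN-flagged when R_i² ≤ 0)."""

    ri2: float
    mode: str

    @property
    def ri(self) -> float:
        return math.sqrt(self.ri2) if self.ri2 > 0 else float("nan")

    @property
    def defined(self) -> bool:
        return self.ri2 > 0


def ri_from_potential(pot: PotentialSpec, mode: str = "mayer") -> RiResult:
    """Radius of interparticle interaction from a pair potential.

    ``mode='mayer'`` uses the dilute-limit weight w = e^(−βV) − 1;
    ``mode='weak'`` uses the weak-potential linearization w = V (valid
    only for potentials finite everywhere).  R_i² is the ratio
    ∫ w r⁴ dr / ∫ w r² dr over [0, r_max].

    Raises :class:`IllConditionedError` when the denominator integral is
    indistinguishable from zero (ideal gas, or a sign-cancelling weak-mode
    potential) — the ratio is then undefined, not zero.
    """
    if mode not in ("mayer", "weak"):
        raise ValidationError(f"mode must be 'mayer' or 'weak', got {mode!r}")
    if mode == "weak" and pot.hard_core_radius > 0:
        raise ValidationError(
            "weak-potential mode is undefined for potentials with a hard "
            "core (V is not small there); use mode='mayer'"
        )
    r_max = pot.r_max()
    if mode == "mayer":
        w = pot.mayer
    else:
        w = pot.beta_v

    num = _radial_integral(lambda r: w(r) * r**4, r_max, pot.knots)
    den = _radial_integral(lambda r: w(r) * r**2, r_max, pot.knots)
    # conditioning: compare against the magnitude integral so that a weak
    # but single-signed potential is fine while sign cancellation is not
    abs_den = _radial_integral(lambda r: np.abs(w(r)) * r**2, r_max, pot.knots)
    if abs_den <= _QUAD_TOL * r_max**3 or abs(den) <= 1e-6 * abs_den:
        raise IllConditionedError(
            "ill-conditioned R_i: ∫w(r) r² dr is within tolerance of zero"
        )
    return RiResult(ri2=num / den, mode=mode)


def ri_from_correlation(h: CorrelationFunction) -> RiResult:
    """R_i from an arbitrary total correlation function h(r)."""
    num = _radial_integral(lambda r: h(r) * r**4, h.r_max, h.knots)
    den = _radial_integral(lambda r: h(r) * r**2, h.r_max, h.knots)
    abs_den = _radial_integral(lambda r: np.abs(h(r)) * r**2, h.r_max, h.knots)
    if abs_den <= _QUAD_TOL * h.r_max**3 or abs(den) <= 1e-6 * abs_den:
        raise IllConditionedError(
            "ill-conditioned R_i: ∫h(r) r² dr is within tolerance of zero"
        )
    return RiResult(ri2=num / den, mode="correlation")


def hard_sphere_refs(r_hs: float) -> tuple[float, float, float]:
    """Closed-form (R_g,HS, R_i,HS, ratio) for a hard sphere of radius R_HS.

    A uniform sphere has R_g = √(3/5)·R_HS; the hard-sphere Mayer function
    (−1 inside the contact diameter σ = 2R_HS) gives R_i = √(3/5)·σ, hence
    the exact ratio R_i/R_g = 2.
    """
    if r_hs <= 0:
        raise ValidationError("hard-sphere radius must be positive")
    rg = math.sqrt(3.0 / 5.0) * r_hs
    ri = math.sqrt(3.0 / 5.0) * 2.0 * r_hs
    return rg, ri, ri / rg


def b22_from_potential(pot: PotentialSpec) -> tuple[float, float]:
    """Second virial coefficient B22 = −½∫(e^(−βV)−1)·4πr² dr.

    Returns (Å³, mL).  Positive for net repulsion (hard sphere:
    (2π/3)σ³), negative for net attraction.
    """
    r_max = pot.r_max()
    tail = abs(float(np.max(np.abs(pot.beta_v([r_max * (1 + 1e-9)])))))
    if tail > 1e-6:
        raise ValidationError(
            f"potential tail |βV| = {tail:.2g} at r_max: divergent or "
            "truncated integral"
        )
    integral = _radial_integral(
        lambda r: pot.mayer(r) * 4.0 * math.pi * r**2, r_max, pot.knots
    )
    b22_a3 = -0.5 * integral
    return b22_a3, b22_a3 * ML_PER_A3


def b22_square_well_analytic(sigma: float, depth: float, lam: float) -> float:
    """Textbook square-well B22 in Å³ (oracle for the quadrature)."""
    return (
        2.0 * math.pi / 3.0 * sigma**3
        * (1.0 - (math.expm1(depth)) * (lam**3 - 1.0))
    )


def s_low_q(qgrid, s0: float, ri: float) -> np.ndarray:
    """Low-Q exponential asymptote S(Q) ≈ S(0)·exp(−⅙·((S0−1)/S0)·Q²R_i²)."""
    if s0 <= 0:
        raise ValidationError("S(0) must be positive")
    if ri < 0:
        raise ValidationError("R_i must be non-negative")
    q = np.asarray(qgrid, dtype=float)
    return s0 * np.exp(-(s0 - 1.0) / (6.0 * s0) * q**2 * ri**2)


def structure_factor_numeric(
    h: CorrelationFunction, n: float, qgrid
) -> np.ndarray:
    """S(Q) = 1 + 4πn ∫ h(r) r² sin(Qr)/(Qr) dr by radial quadrature.

    n is in 1/Å³ here (number density on the same length scale as r);
    Q = 0 is handled by the sinc limit.
    """
    if n < 0:
        raise ValidationError("number density must be non-negative")
    q = np.atleast_1d(np.asarray(qgrid, dtype=float))
    out = np.empty_like(q)
    for j, qj in enumerate(q):
        if qj == 0.0:
            f = lambda r: h(r) * r**2
        else:
            f = lambda r: h(r) * r**2 * np.sinc(qj * r / math.pi)
        out[j] = 1.0 + 4.0 * math.pi * n * _radial_integral(f, h.r_max, h.knots)
    return out
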