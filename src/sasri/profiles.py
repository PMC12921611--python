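"""Reduced 1D scattering profiles and the concentration-series manifest.

A :class:`ScatteringProfile` holds one background-subtracted (or raw)
reduced curve: momentum transfer Q in Å⁻¹, intensity I in arbitrary but
mutually consistent units, and the 1σ counting uncertainty dI.  The
accepted on-disk dialect is the common reduced-SAS ASCII family:
whitespace- or comma-delimited, 2–4 numeric columns in the order
Q, I, dI, (dQ), with ``#`` or ``;`` comment prefixes.  dQ is parsed and
ignored — no resolution smearing is in scope.

A :class:`SeriesManifest` maps profiles to mass concentrations and carries
the three global constants the series analysis needs: molecular weight,
protein mass density and temperature.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .exceptions import FormatError, ManifestError, ValidationError

log = logging.getLogger(__name__)

_COMMENT_PREFIXES = ("#", ";")


@dataclass(frozen=True)
class ScatteringProfile:
    """One reduced 1D scattering curve.

    Attributes
    ----------
    q : ndarray
        Momentum transfer magnitudes, Å⁻¹; strictly increasing, > 0.
    i : ndarray
        Scattered intensity.
    di : ndarray
        1σ intensity uncertainty; all zeros means "no uncertainties".
    label : str
        Free-text identifier.
    concentration : float or None
        Mass concentration in mg/mL, when known.
    meta : dict
        Provenance (background constant subtracted, dropped-row count, ...).
    """

    q: np.ndarray
    i: np.ndarray
    di: np.ndarray
    label: str = ""
    concentration: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        q = np.asarray(self.q, dtype=float)
        i = np.asarray(self.i, dtype=float)
        di = np.asarray(self.di, dtype=float)
        if not (q.shape == i.shape == di.shape) or q.ndim != 1:
            raise ValidationError("q, i, di must be 1D arrays of equal length")
        if q.size < 3:
            raise ValidationError("profile needs at least 3 points")
        if np.any(q <= 0):
            raise ValidationError("all Q must be positive")
        if np.any(np.diff(q) <= 0):
            raise ValidationError("Q must be strictly increasing")
        if np.any(di < 0):
            raise ValidationError("uncertainties must be non-negative")
        object.__setattr__(self, "q", q)
        object.__setattr__(self, "i", i)
        object.__setattr__(self, "di", di)

    def __len__(self) -> int:
        return self.q.size

    @property
    def has_uncertainties(self) -> bool:
        return bool(np.any(self.di > 0))

    def window(self, q_lo: float, q_hi: float) -> np.ndarray:
        """Boolean mask of points with q_lo <= Q <= q_hi."""
        return (self.q >= q_lo) & (self.q <= q_hi)


@dataclass(frozen=True)
class SeriesManifest:
    """Concentration-series manifest.

    ``entries`` maps a profile id (usually a file path or label) to a mass
    concentration in mg/mL; ≥ 3 distinct concentrations are required for
    the downstream two-stage linear fits.
    """

    entries: tuple[tuple[str, float], ...]
    molecular_weight: float   # g/mol
    mass_density: float = 1.46  # g/cm³ (lysozyme default)
    temperature: float = 298.15  # K

    def __post_init__(self):
        entries = tuple((str(k), float(c)) for k, c in self.entries)
        if len(entries) < 3:
            raise ManifestError(
                "≥ 3 required: a concentration series needs at least three "
                f"entries for the two-stage linear fits (got {len(entries)})"
            )
        concs = [c for _, c in entries]
        if any(c <= 0 for c in concs):
            raise ManifestError("all concentrations must be positive")
        if len(set(concs)) != len(concs):
            raise ManifestError("concentrations must be distinct")
        if self.molecular_weight <= 0:
            raise ManifestError("molecular weight must be positive")
        if self.mass_density <= 0:
            raise ManifestError("mass density must be positive")
        object.__setattr__(self, "entries", entries)

    @property
    def concentrations(self) -> np.ndarray:
        return np.array([c for _, c in self.entries])


def _parse_row(line: str) -> list[float]:
    fields = line.replace(",", " ").split()
    return [float(f) for f in fields]


def read_profile(
    path,
    label: str | None = None,
    q_unit: str = "1/angstrom",
    concentration: float | None = None,
) -> ScatteringProfile:
    """Read a reduced 1D profile from delimited ASCII.

    Accepts 2–4 numeric columns (Q, I[, dI[, dQ]]); ``#``/``;`` comment
    lines and blank lines are skipped.  Rows containing non-finite values
    are dropped (count logged).  A descending Q column is re-sorted with a
    warning.  ``q_unit="1/nm"`` rescales Q by 0.1 into Å⁻¹.
    """
    path = Path(path)
    if q_unit not in ("1/angstrom", "1/nm"):
        raise ValidationError(f"unknown q_unit {q_unit!r}")
    rows: list[list[float]] = []
    ncols = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(_COMMENT_PREFIXES):
                continue
            try:
                vals = _parse_row(line)
            except ValueError:
                raise FormatError(
                    f"{path}: line {lineno} is not numeric: {line!r}"
                ) from None
            if len(vals) < 2 or len(vals) > 4:
                raise FormatError(
                    f"{path}: line {lineno} has {len(vals)} columns "
                    "(expected 2–4)"
                )
            if ncols is None:
                ncols = len(vals)
            elif len(vals) != ncols:
                raise FormatError(
                    f"{path}: line {lineno} has {len(vals)} columns, "
                    f"earlier rows had {ncols}"
                )
            rows.append(vals)
    if not rows:
        raise FormatError(f"{path}: no numeric data rows")

    arr = np.array(rows, dtype=float)
    finite = np.isfinite(arr).all(axis=1)
    ndropped = int((~finite).sum())
    if ndropped:
        log.info("%s: dropped %d rows with non-finite values", path, ndropped)
        arr = arr[finite]

    q = arr[:, 0]
    i = arr[:, 1]
    di = arr[:, 2] if arr.shape[1] >= 3 else np.zeros_like(q)
    if q_unit == "1/nm":
        q = q * 0.1

    if np.any(np.diff(q) < 0):
        warnings.warn(f"{path}: Q column not ascending; re-sorting")
        order = np.argsort(q, kind="stable")
        q, i, di = q[order], i[order], di[order]

    meta = {"path": str(path), "dropped_rows": ndropped}
    if arr.shape[1] == 2:
        meta["no_uncertainties"] = True
    return ScatteringProfile(
        q=q, i=i, di=di,
        label=label if label is not None else path.name,
        concentration=concentration, meta=meta,
    )


def write_profile(profile: ScatteringProfile, path) -> None:
    """Write a profile as 3-column ASCII (``# Q I dI`` header)."""
    path = Path(path)
    header_bits = [f"label: {profile.label}"]
    if profile.concentration is not None:
        header_bits.append(f"c_mg_per_mL: {profile.concentration}")
    with open(path, "w") as fh:
        for bit in header_bits:
            fh.write(f"# {bit}\n")
        fh.write("# Q(1/A)  I  dI\n")
        for q, i, di in zip(profile.q, profile.i, profile.di):
            fh.write(f"{q:.8e} {i:.8e} {di:.8e}\n")


def subtract_background(
    profile: ScatteringProfile,
    window_lo: float = 0.35,
    window_hi: float = 0.45,
) -> ScatteringProfile:
    """Subtract a flat background: the mean intensity over a high-Q window.

    The default window 0.35–0.45 Å⁻¹ sits well past the particle signal for
    small proteins on a typical SANS range.  dI is unchanged; the constant
    is recorded in ``meta["background_subtracted"]``.
    """
    if not window_lo < window_hi:
        raise ValidationError("window_lo must be < window_hi")
    mask = profile.window(window_lo, window_hi)
    if mask.sum() < 3:
        raise ValidationError(
            f"background window [{window_lo}, {window_hi}] Å⁻¹ overlaps "
            f"only {int(mask.sum())} points (need ≥ 3); data span "
            f"[{profile.q[0]:.4g}, {profile.q[-1]:.4g}]"
        )
    const = float(np.mean(profile.i[mask]))
    meta = dict(profile.meta)
    meta["background_subtracted"] = meta.get("background_subtracted", 0.0) + const
    meta["background_window"] = (window_lo, window_hi)
    return replace(profile, i=profile.i - const, meta=meta)


def build_series(
    manifest: SeriesManifest,
    profiles: Sequence[ScatteringProfile],
) -> list[ScatteringProfile]:
    """Match profiles to manifest entries and order by ascending concentration.

    Each returned profile is annotated with its concentration and, in
    ``meta``, the number density n (1/mL) and volume fraction ϕ computed
    from the manifest's molecular weight and mass density.
    """
    from .interaction import number_density, volume_fraction

    by_label = {}
    for p in profiles:
        if p.label in by_label:
            raise ManifestError(f"duplicate profile label {p.label!r}")
        by_label[p.label] = p
    out = []
    for key, c in manifest.entries:
        if key not in by_label:
            raise ManifestError(f"manifest entry {key!r} has no matching profile")
        p = by_label[key]
        meta = dict(p.meta)
        meta["n_per_mL"] = number_density(c, manifest.molecular_weight)
        meta["phi"] = volume_fraction(c, manifest.mass_density)
        out.append(replace(p, concentration=c, meta=meta))
    out.sort(key=lambda p: p.concentration)
    return out


def read_manifest(path) -> SeriesManifest:
    """Read a plain-text manifest.

    Format: ``key = value`` lines for the globals ``molecular_weight_Da``,
    ``mass_density_g_per_cm3``, ``temperature_K``; every other non-comment
    line is ``<file> <c_mg_per_mL>`` (whitespace or comma separated).
    File paths are resolved relative to the manifest's directory.
    """
    path = Path(path)
    globals_: dict[str, float] = {}
    entries: list[tuple[str, float]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(_COMMENT_PREFIXES):
                continue
            if "=" in line:
                key, _, val = line.partition("=")
                try:
                    globals_[key.strip()] = float(val)
                except ValueError:
                    raise FormatError(
                        f"{path}: line {lineno}: bad global {line!r}"
                    ) from None
                continue
            fields = line.replace(",", " ").split()
            if len(fields) != 2:
                raise FormatError(
                    f"{path}: line {lineno}: expected '<file> <c>': {line!r}"
                )
            try:
                c = float(fields[1])
            except ValueError:
                raise FormatError(
                    f"{path}: line {lineno}: concentration not numeric"
                ) from None
            entries.append((str((path.parent / fields[0])), c))
    if "molecular_weight_Da" not in globals_:
        raise ManifestError(f"{path}: missing molecular_weight_Da")
    return SeriesManifest(
        entries=tuple(entries),
        molecular_weight=globals_["molecular_weight_Da"],
        mass_density=globals_.get("mass_density_g_per_cm3", 1.46),
        temperature=globals_.get("temperature_K", 298.15),
    )


def write_manifest(manifest: SeriesManifest, path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"molecular_weight_Da = {manifest.molecular_weight}\n")
        fh.write(f"mass_density_g_per_cm3 = {manifest.mass_density}\n")
        fh.write(f"temperature_K = {manifest.temperature}\n")
        for key, c in manifest.entries:
            rel = Path(key)
            try:
                rel = rel.relative_to(path.parent)
            except ValueError:
                pass
            fh.write(f"{rel} {c}\n")
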