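"""Weighted straight-line least squares with parameter covariance.

The two-stage inversion rests entirely on straight-line fits, so a single
well-conditioned implementation is shared by the Guinier, virial and
interaction stages.  The design matrix is centered about the weighted mean
of x before solving, which keeps the normal equations well conditioned even
when x spans ~1e17 (number densities in 1/mL).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import FitError


@dataclass(frozen=True)
class LineFit:
    """Result of a straight-line fit y = intercept + slope * x.

    ``cov`` is the 2x2 covariance of (intercept, slope).  When per-point
    sigmas were supplied the covariance is the unscaled inverse normal
    matrix (errors taken at face value); for unweighted fits it is scaled
    by the residual variance, the ordinary least-squares convention.
    """

    slope: float
    intercept: float
    slope_err: float
    intercept_err: float
    cov: np.ndarray
    chi2: float
    dof: int

    def predict(self, x):
        return self.intercept + self.slope * np.asarray(x, dtype=float)

    def confidence_band(self, x, z: float = 1.96):
        """Half-width of the z-sigma confidence band of the fitted line."""
        x = np.asarray(x, dtype=float)
        var = (
            self.cov[0, 0]
            + 2.0 * x * self.cov[0, 1]
            + x**2 * self.cov[1, 1]
        )
        return z * np.sqrt(np.maximum(var, 0.0))


def fit_line(x, y, sigma=None) -> LineFit:
    """Fit y = a + b*x by (weighted) linear least squares.

    Parameters
    ----------
    x, y : array-like
        Data; at least two distinct x values required.
    sigma : array-like, optional
        1σ uncertainties of y.  When given, points are weighted 1/σ² and
        the covariance is unscaled; zero/non-finite sigmas raise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise FitError("x and y must be 1D arrays of equal length")
    if x.size < 2:
        raise FitError("need at least 2 points for a line fit")
    if np.ptp(x) == 0.0:
        raise FitError("singular design: all x values equal")

    if sigma is not None:
        sigma = np.asarray(sigma, dtype=float)
        if np.any(~np.isfinite(sigma)) or np.any(sigma <= 0):
            raise FitError("sigmas must be finite and positive")
        w = 1.0 / sigma**2
    else:
        w = np.ones_like(x)

    sw = w.sum()
    xbar = (w * x).sum() / sw
    u = x - xbar                      # centered abscissa
    suu = (w * u * u).sum()
    # solve in centered coordinates: y = a' + b*u
    b = (w * u * y).sum() / suu
    a_c = (w * y).sum() / sw
    a = a_c - b * xbar

    resid = y - (a + b * x)
    chi2 = float((w * resid**2).sum())
    dof = x.size - 2

    # covariance in centered basis is diagonal; transform back
    var_ac = 1.0 / sw
    var_b = 1.0 / suu
    cov = np.array(
        [
            [var_ac + xbar**2 * var_b, -xbar * var_b],
            [-xbar * var_b, var_b],
        ]
    )
    if sigma is None:
        # unweighted: scale by residual variance (0 when dof == 0)
        s2 = chi2 / dof if dof > 0 else 0.0
        cov = cov * s2

    return LineFit(
        slope=float(b),
        intercept=float(a),
        slope_err=float(np.sqrt(cov[1, 1])),
        intercept_err=float(np.sqrt(cov[0, 0])),
        cov=cov,
        chi2=chi2,
        dof=dof,
    )
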