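"""Empirical sigma <-> diameter calibration for cluster size estimates.

A diffraction-limited point source images to a Gaussian of width sigma0; a
bead or cluster of finite diameter d broadens it.  The relation is described
empirically by

    d = ((sigma^beta - sigma0^beta) / alpha) ** (1/beta)

with sigma0 the point-source width (um), alpha (um) and beta (dimensionless)
fitted to z-stacks of beads of known diameter.  sigma0 acquired at one
numerical aperture is rescaled to another by the NA ratio.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass

import numpy as np
import yaml
from scipy import optimize

__all__ = [
    "CalibrationParams",
    "diameter_from_sigma",
    "sigma_from_diameter",
    "fit_calibration",
    "convert_na_offset",
    "diameter_range",
]


@dataclass
class CalibrationParams:
    """Parameters of the empirical sigma(d) relation, with 1-SD errors."""

    sigma0: float  # um
    alpha: float  # um
    beta: float  # dimensionless
    na: float | None = None
    sigma0_err: float = float("nan")
    alpha_err: float = float("nan")
    beta_err: float = float("nan")

    def __post_init__(self) -> None:
        if self.sigma0 <= 0 or self.alpha <= 0 or self.beta <= 0:
            raise ValueError("sigma0, alpha and beta must be positive")

    def to_yaml(self) -> str:
        return yaml.safe_dump(dataclasses.asdict(self))

    @classmethod
    def from_yaml(cls, text: str) -> "CalibrationParams":
        return cls(**yaml.safe_load(text))


def diameter_from_sigma(sigma, cal: CalibrationParams):
    """Diameter (um) for a fitted width sigma (um).

    Undefined for sigma < sigma0 (narrower than a point source): returns NaN
    with a warning.  Accepts scalars or arrays.
    """
    sigma = np.asarray(sigma, dtype=float)
    # tolerate float rounding exactly at the sigma0 boundary
    below = sigma < cal.sigma0 * (1 - 1e-12)
    if np.any(below):
        warnings.warn("sigma below sigma0: diameter undefined, returning NaN",
                      stacklevel=2)
    with np.errstate(invalid="ignore"):
        num = np.clip(sigma**cal.beta - cal.sigma0**cal.beta, 0.0, None)
        d = (num / cal.alpha) ** (1.0 / cal.beta)
    d = np.where(below, np.nan, d)
    return float(d) if d.ndim == 0 else d


def sigma_from_diameter(d, cal: CalibrationParams):
    """Exact inverse of :func:`diameter_from_sigma` for d >= 0."""
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("diameter must be nonnegative")
    s = (cal.alpha * d**cal.beta + cal.sigma0**cal.beta) ** (1.0 / cal.beta)
    return float(s) if s.ndim == 0 else s


def fit_calibration(bead_diameters, mean_sigmas, na: float | None = None,
                    p0=(0.1, 0.05, 3.0)) -> CalibrationParams:
    """Fit (sigma0, alpha, beta) to bead diameters and their mean widths.

    Unweighted nonlinear least squares of sigma as a function of d (residuals
    in sigma); 1-SD parameter uncertainties from the Jacobian.
    """
    d = np.asarray(bead_diameters, dtype=float)
    s = np.asarray(mean_sigmas, dtype=float)
    if d.size < 3 or d.size != s.size:
        raise ValueError("need at least 3 (diameter, sigma) pairs")

    def model(dd, sigma0, alpha, beta):
        return (alpha * dd**beta + sigma0**beta) ** (1.0 / beta)

    try:
        popt, pcov = optimize.curve_fit(
            model, d, s, p0=p0,
            bounds=([1e-6, 1e-6, 0.1], [np.inf, np.inf, 20.0]), maxfev=20000)
    except RuntimeError as exc:
        raise RuntimeError(f"calibration fit did not converge: {exc}") from exc
    perr = np.sqrt(np.diag(pcov))
    return CalibrationParams(sigma0=float(popt[0]), alpha=float(popt[1]),
                             beta=float(popt[2]), na=na,
                             sigma0_err=float(perr[0]),
                             alpha_err=float(perr[1]),
                             beta_err=float(perr[2]))


def convert_na_offset(sigma0: float, na_from: float, na_to: float) -> float:
    """Rescale sigma0 acquired at one numerical aperture to another.

    The diffraction-limited width scales inversely with NA, so
    sigma0' = sigma0 * na_from / na_to.
    """
    if na_from <= 0 or na_to <= 0:
        raise ValueError("numerical apertures must be positive")
    return sigma0 * na_from / na_to


def diameter_range(sigmas, cal: CalibrationParams) -> tuple[float, float]:
    """Diameter range of a sigma sample via the 1.5x-IQR whisker bounds.

    Computes Q1 - 1.5*IQR and Q3 + 1.5*IQR of the sigma sample (quartiles by
    linear interpolation), clips the lower bound to sigma0, and converts both
    through the calibration.
    """
    s = np.asarray(sigmas, dtype=float)
    if s.size < 4:
        raise ValueError("need at least 4 sigma values")
    q1, q3 = np.quantile(s, [0.25, 0.75])
    iqr = q3 - q1
    lo = max(q1 - 1.5 * iqr, cal.sigma0)
    hi = q3 + 1.5 * iqr
    if hi < cal.sigma0:
        raise ValueError("entire sigma sample below sigma0")
    d_min = 0.0 if lo <= cal.sigma0 else float(diameter_from_sigma(lo, cal))
    d_max = float(diameter_from_sigma(hi, cal))
    return d_min, d_max
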