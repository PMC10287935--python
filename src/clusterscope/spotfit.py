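"""3D spot detection, Gaussian fitting and quality filtering.

Detection band-passes the stack with a difference-of-Gaussians (DoG) filter
and takes strict 26-connected local maxima above an absolute threshold as
candidates.  Each candidate is then fit with the model

    G(x, y, z) = I / ((2*pi)^(3/2) * sigma_xy^2 * sigma_z)
                 * exp(-((x-x0)^2 + (y-y0)^2)/(2 sigma_xy^2)
                       - (z-z0)^2/(2 sigma_z^2))
                 + b + bx*x + by*y + bz*z

in two steps inside an 11 x 11 x 7 (x, y, z) region of interest:

(i)  iterative moment analysis — the background-subtracted ROI is multiplied
     by a Gaussian window approximating the point spread function centered on
     the current position estimate, the position is updated from intensity
     moments and the tilted background is re-fit from the ROI edge voxels,
     until the position converges, drifts more than 3 voxels from the
     candidate, or 20 iterations pass.  I and the widths then come from
     second moments with a truncated-domain correction.

(ii) bounded L-BFGS-B minimisation of the sum of weighted squared log
     residuals, weighted by a wide Gaussian centered on the moment-analysis
     position so the fit stays anchored to the candidate rather than a
     brighter neighbor.

The peak density I_p = I / ((2*pi)^(3/2) sigma_xy^2 sigma_z) is the height of
the fitted Gaussian above the background at its center.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage, optimize
from scipy.special import ndtr  # standard normal CDF

logger = logging.getLogger(__name__)

TWO_PI_32 = (2.0 * np.pi) ** 1.5

__all__ = [
    "DetectionConfig",
    "SpotModelParams",
    "SpotFit",
    "detect_candidates",
    "threshold_from_sd",
    "estimate_edge_background",
    "refine_spot",
    "peak_intensity",
    "goodness_of_fit",
    "filter_spots",
    "fit_spots",
    "spots_to_dataframe",
]


@dataclass
class DetectionConfig:
    """Detection and fitting settings (all lengths in voxels).

    The DoG sigma pairs are (narrow, wide); the narrow blur minus the wide
    blur gives the band-pass response.  ``psf_sigma_*`` approximate the
    microscope point spread function and drive the moment-analysis window;
    ``weight_sigma_*`` (2x the psf) drive the log-residual weights.
    """

    dog_sigma_xy: tuple[float, float] = (1.245, 2.075)
    dog_sigma_z: tuple[float, float] = (0.795, 1.325)
    abs_threshold: float = 0.0
    psf_sigma_xy: float = 1.66
    psf_sigma_z: float = 1.06
    weight_sigma_xy: float = 3.32
    weight_sigma_z: float = 2.12
    roi_xy: int = 11
    roi_z: int = 7
    max_iter: int = 20
    move_tol: float = 1e-3
    max_shift: float = 3.0
    sigma_bounds: tuple[float, float] = (0.3, 10.0)
    log_floor: float = 1.0  # counts; floor for log residuals

    def __post_init__(self) -> None:
        if not (self.dog_sigma_xy[0] < self.dog_sigma_xy[1]
                and self.dog_sigma_z[0] < self.dog_sigma_z[1]):
            raise ValueError("DoG sigma pairs must be (narrow, wide)")
        if self.roi_xy % 2 == 0 or self.roi_z % 2 == 0:
            raise ValueError("ROI sizes must be odd")
        if self.abs_threshold < 0:
            raise ValueError("abs_threshold must be nonnegative")


@dataclass
class SpotModelParams:
    """Fitted model parameters in stack voxel coordinates."""

    I: float
    x0: float
    y0: float
    z0: float
    sigma_xy: float
    sigma_z: float
    b: float = 0.0
    bx: float = 0.0
    by: float = 0.0
    bz: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma_xy <= 0 or self.sigma_z <= 0:
            raise ValueError("sigmas must be positive")

    def as_array(self) -> np.ndarray:
        return np.array([self.I, self.x0, self.y0, self.z0, self.sigma_xy,
                         self.sigma_z, self.b, self.bx, self.by, self.bz])


@dataclass
class SpotFit:
    """One fitted spot with quality scores and provenance."""

    params: SpotModelParams | None
    peak_intensity: float
    r2_total: float
    r2_peak: float
    r2_background: float
    candidate_xyz: tuple[int, int, int]
    n_iterations: int
    converged: bool
    failed: bool = False
    cell_label: int = 0
    channel: str = ""
    reject_reason: str = ""

    @property
    def position(self) -> np.ndarray:
        """(x0, y0, z0) in voxels."""
        p = self.params
        return np.array([p.x0, p.y0, p.z0])


def peak_intensity(params: SpotModelParams) -> float:
    """Height of the Gaussian above the background plane at its center."""
    if params.sigma_xy <= 0 or params.sigma_z <= 0:
        raise ValueError("sigmas must be positive")
    return params.I / (TWO_PI_32 * params.sigma_xy**2 * params.sigma_z)


# ---------------------------------------------------------------------------
# Detection


def detect_candidates(stack: np.ndarray, cfg: DetectionConfig) -> np.ndarray:
    """Strict local maxima of the DoG response above cfg.abs_threshold.

    Returns an (n, 3) integer array of (z, y, x) candidate voxels, ordered by
    descending response.
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3:
        raise ValueError("expected a 3D stack (z, y, x)")
    response = dog_response(stack, cfg)
    footprint = np.ones((3, 3, 3), bool)
    footprint[1, 1, 1] = False
    neighbor_max = ndimage.maximum_filter(response, footprint=footprint,
                                          mode="nearest")
    is_max = (response > neighbor_max) & (response > cfg.abs_threshold)
    coords = np.argwhere(is_max)
    if coords.size:
        order = np.argsort(-response[coords[:, 0], coords[:, 1], coords[:, 2]],
                           kind="stable")
        coords = coords[order]
    return coords


def dog_response(stack: np.ndarray, cfg: DetectionConfig) -> np.ndarray:
    narrow = ndimage.gaussian_filter(
        stack, (cfg.dog_sigma_z[0], cfg.dog_sigma_xy[0], cfg.dog_sigma_xy[0]))
    wide = ndimage.gaussian_filter(
        stack, (cfg.dog_sigma_z[1], cfg.dog_sigma_xy[1], cfg.dog_sigma_xy[1]))
    return narrow - wide


def threshold_from_sd(stack: np.ndarray, cfg: DetectionConfig,
                      k: float = 10.0) -> float:
    """k times the robust (MAD-based) SD of the DoG response.

    Helper for the "k x standard deviation" detection thresholds used for
    bead fields; no single absolute threshold is appropriate across channels.
    """
    r = dog_response(np.asarray(stack, dtype=float), cfg)
    mad = np.median(np.abs(r - np.median(r)))
    return float(k * 1.4826 * mad)


# ---------------------------------------------------------------------------
# Background from ROI edges


def _roi_grids(shape: tuple[int, int, int]):
    nz, ny, nx = shape
    return np.meshgrid(np.arange(nz), np.arange(ny), np.arange(nx),
                       indexing="ij")


def _edge_mask(shape: tuple[int, int, int]) -> np.ndarray:
    m = np.zeros(shape, bool)
    m[0, :, :] = m[-1, :, :] = True
    m[:, 0, :] = m[:, -1, :] = True
    m[:, :, 0] = m[:, :, -1] = True
    return m


def estimate_edge_background(roi: np.ndarray) -> tuple[float, float, float, float]:
    """Least-squares tilted plane b + bx*x + by*y + bz*z through the voxels
    on the six boundary faces of the ROI (local ROI coordinates)."""
    roi = np.asarray(roi, dtype=float)
    if roi.ndim != 3 or min(roi.shape) < 3:
        raise ValueError("ROI must be 3D with at least 3 voxels per axis")
    zz, yy, xx = _roi_grids(roi.shape)
    edge = _edge_mask(roi.shape)
    vals = roi[edge]
    if np.ptp(vals) == 0:
        return float(vals[0]), 0.0, 0.0, 0.0
    A = np.column_stack([np.ones(vals.size), xx[edge], yy[edge], zz[edge]])
    coef, *_ = np.linalg.lstsq(A, vals, rcond=None)
    b, bx, by, bz = coef
    return float(b), float(bx), float(by), float(bz)


def _plane(shape, coeffs):
    zz, yy, xx = _roi_grids(shape)
    b, bx, by, bz = coeffs
    return b + bx * xx + by * yy + bz * zz


# ---------------------------------------------------------------------------
# Moment analysis with truncated-domain correction


def _truncated_sigma(s2: float, half_width: float) -> float:
    """Invert the variance of a symmetrically truncated normal.

    A Gaussian of width sigma observed only on [-L, L] has second central
    moment  s^2 = sigma^2 * (1 - 2 c phi(c) / (2 Phi(c) - 1))  with
    c = L / sigma.  Solve for sigma given the measured s^2; the observable
    s^2 saturates at the uniform-limit L^2/3, so inputs at or above that are
    mapped to the upper sigma bracket.
    """
    if s2 <= 0:
        return 0.3
    L = float(half_width)

    def f(sigma):
        c = L / sigma
        phi = np.exp(-0.5 * c * c) / np.sqrt(2 * np.pi)
        mass = 2 * ndtr(c) - 1
        return sigma**2 * (1 - 2 * c * phi / mass) - s2

    lo, hi = 1e-3, 50.0
    if f(hi) < 0:  # s2 at/above the saturation plateau
        return hi
    if f(lo) > 0:
        return lo
    return float(optimize.brentq(f, lo, hi, xtol=1e-10))


def _axis_mass(half_width: float, sigma: float) -> float:
    return 2 * ndtr(half_width / sigma) - 1


def _moment_analysis(roi: np.ndarray, cfg: DetectionConfig,
                     candidate_local: np.ndarray):
    """Iterative center estimation + moment-based (I, sigma) with domain
    correction.  Returns (center_zyx, I, sigma_xy, sigma_z, bg, n_iter,
    converged, drifted)."""
    zz, yy, xx = _roi_grids(roi.shape)
    center = candidate_local.astype(float).copy()  # (z, y, x)
    bg = estimate_edge_background(roi)
    n_iter = 0
    converged = False
    drifted = False
    for n_iter in range(1, cfg.max_iter + 1):
        bg = estimate_edge_background(roi)
        sub = np.clip(roi - _plane(roi.shape, bg), 0, None)
        w = np.exp(
            -((xx - center[2]) ** 2 + (yy - center[1]) ** 2)
            / (2 * cfg.psf_sigma_xy**2)
            - (zz - center[0]) ** 2 / (2 * cfg.psf_sigma_z**2))
        m = sub * w
        tot = m.sum()
        if tot <= 0:
            break
        new = np.array([(m * zz).sum(), (m * yy).sum(), (m * xx).sum()]) / tot
        move = np.linalg.norm(new - center)
        if np.linalg.norm(new - candidate_local) > cfg.max_shift:
            drifted = True
            center = new
            break
        center = new
        if move < cfg.move_tol:
            converged = True
            break
    # unweighted second moments of the background-subtracted ROI about the
    # converged center, corrected for the finite ROI domain
    sub = np.clip(roi - _plane(roi.shape, bg), 0, None)
    tot = sub.sum()
    if tot <= 0:
        return center, 0.0, cfg.psf_sigma_xy, cfg.psf_sigma_z, bg, n_iter, converged, drifted
    s2x = (sub * (xx - center[2]) ** 2).sum() / tot
    s2y = (sub * (yy - center[1]) ** 2).sum() / tot
    s2z = (sub * (zz - center[0]) ** 2).sum() / tot
    Lx = (roi.shape[2] - 1) / 2.0
    Ly = (roi.shape[1] - 1) / 2.0
    Lz = (roi.shape[0] - 1) / 2.0
    sigma_xy = 0.5 * (_truncated_sigma(s2x, Lx) + _truncated_sigma(s2y, Ly))
    sigma_z = _truncated_sigma(s2z, Lz)
    lo, hi = cfg.sigma_bounds
    sigma_xy = float(np.clip(sigma_xy, lo, hi))
    sigma_z = float(np.clip(sigma_z, lo, hi))
    # integrated intensity, corrected for Gaussian mass outside the ROI
    mass = (_axis_mass(Lx, sigma_xy) * _axis_mass(Ly, sigma_xy)
            * _axis_mass(Lz, sigma_z))
    I = float(tot / max(mass, 1e-12))
    return center, I, sigma_xy, sigma_z, bg, n_iter, converged, drifted


# ---------------------------------------------------------------------------
# Weighted log-residual fit


def _model_and_parts(p: np.ndarray, grids):
    zz, yy, xx = grids
    I, x0, y0, z0, sxy, sz, b, bx, by, bz = p
    amp = I / (TWO_PI_32 * sxy**2 * sz)
    g = amp * np.exp(-((xx - x0) ** 2 + (yy - y0) ** 2) / (2 * sxy**2)
                     - (zz - z0) ** 2 / (2 * sz**2))
    plane = b + bx * xx + by * yy + bz * zz
    return g, plane


def _objective(p, grids, logdata, w, floor):
    zz, yy, xx = grids
    I, x0, y0, z0, sxy, sz, b, bx, by, bz = p
    amp = I / (TWO_PI_32 * sxy**2 * sz)
    ex = np.exp(-((xx - x0) ** 2 + (yy - y0) ** 2) / (2 * sxy**2)
                - (zz - z0) ** 2 / (2 * sz**2))
    g = amp * ex
    model = g + b + bx * xx + by * yy + bz * zz
    clamped = model < floor
    m = np.where(clamped, floor, model)
    r = np.log(m) - logdata
    val = float((w * r * r).sum())

    # gradient: dJ/dp = sum 2 w r / m * dm/dp, zero where clamped
    pref = np.where(clamped, 0.0, 2.0 * w * r / m)
    dg_dI = g / I if I > 0 else ex / (TWO_PI_32 * sxy**2 * sz)
    dg_dx0 = g * (xx - x0) / sxy**2
    dg_dy0 = g * (yy - y0) / sxy**2
    dg_dz0 = g * (zz - z0) / sz**2
    dg_dsxy = g * (((xx - x0) ** 2 + (yy - y0) ** 2) / sxy**3 - 2.0 / sxy)
    dg_dsz = g * ((zz - z0) ** 2 / sz**3 - 1.0 / sz)
    grad = np.array([
        (pref * dg_dI).sum(),
        (pref * dg_dx0).sum(),
        (pref * dg_dy0).sum(),
        (pref * dg_dz0).sum(),
        (pref * dg_dsxy).sum(),
        (pref * dg_dsz).sum(),
        pref.sum(),
        (pref * xx).sum(),
        (pref * yy).sum(),
        (pref * zz).sum(),
    ])
    return val, grad


def _adjusted_r2(data: np.ndarray, model: np.ndarray, n_params: int) -> float:
    data = np.asarray(data, dtype=float).ravel()
    model = np.asarray(model, dtype=float).ravel()
    n = data.size
    if n <= n_params + 1:
        return float("nan")
    ss_res = ((data - model) ** 2).sum()
    ss_tot = ((data - data.mean()) ** 2).sum()
    if ss_tot == 0:
        r2 = 1.0 if ss_res == 0 else -np.inf
    else:
        r2 = 1 - ss_res / ss_tot
    return float(1 - (1 - r2) * (n - 1) / (n - n_params - 1))


def goodness_of_fit(roi: np.ndarray, params: SpotModelParams,
                    origin_zyx: tuple[int, int, int] = (0, 0, 0)):
    """Adjusted R-squared for the whole fit, the peak and the background.

    * total: full model vs the ROI (10 parameters);
    * peak: the Gaussian term vs the background-subtracted ROI (6 parameters);
    * background: the plane vs ROI voxels farther than 2 sigma from the
      center (4 parameters).
    """
    roi = np.asarray(roi, dtype=float)
    oz, oy, ox = origin_zyx
    zz, yy, xx = _roi_grids(roi.shape)
    p = params
    local = np.array([p.I, p.x0 - ox, p.y0 - oy, p.z0 - oz, p.sigma_xy,
                      p.sigma_z,
                      p.b + p.bx * ox + p.by * oy + p.bz * oz,
                      p.bx, p.by, p.bz])
    g, plane = _model_and_parts(local, (zz, yy, xx))
    r2_total = _adjusted_r2(roi, g + plane, 10)
    r2_peak = _adjusted_r2(roi - plane, g, 6)
    outside = (((xx - local[1]) ** 2 + (yy - local[2]) ** 2)
               / (2 * p.sigma_xy) ** 2
               + (zz - local[3]) ** 2 / (2 * p.sigma_z) ** 2) > 1.0
    if outside.sum() > 5:
        r2_background = _adjusted_r2(roi[outside], plane[outside], 4)
    else:
        r2_background = float("nan")
    return r2_total, r2_peak, r2_background


def _extract_roi(stack: np.ndarray, candidate, cfg: DetectionConfig):
    """Clip an ROI around the candidate at stack borders."""
    nz, ny, nx = stack.shape
    cz, cy, cx = candidate
    hz, hxy = cfg.roi_z // 2, cfg.roi_xy // 2
    z0, z1 = max(cz - hz, 0), min(cz + hz + 1, nz)
    y0, y1 = max(cy - hxy, 0), min(cy + hxy + 1, ny)
    x0, x1 = max(cx - hxy, 0), min(cx + hxy + 1, nx)
    return stack[z0:z1, y0:y1, x0:x1], (z0, y0, x0)


def refine_spot(stack: np.ndarray, candidate, cfg: DetectionConfig,
                cell_label: int = 0, channel: str = "") -> SpotFit:
    """Fit the Gaussian-plus-tilted-background model around one candidate.

    ``candidate`` is a (z, y, x) voxel.  Returns a SpotFit; fits on
    all-nonpositive ROIs or with no recoverable signal are marked failed.
    """
    stack = np.asarray(stack, dtype=float)
    candidate = tuple(int(c) for c in candidate)
    if not (0 <= candidate[0] < stack.shape[0]
            and 0 <= candidate[1] < stack.shape[1]
            and 0 <= candidate[2] < stack.shape[2]):
        raise ValueError(f"candidate {candidate} outside stack")
    roi, origin = _extract_roi(stack, candidate, cfg)
    cand_xyz = (candidate[2], candidate[1], candidate[0])

    def failed_fit(reason):
        return SpotFit(params=None, peak_intensity=np.nan, r2_total=np.nan,
                       r2_peak=np.nan, r2_background=np.nan,
                       candidate_xyz=cand_xyz, n_iterations=0, converged=False,
                       failed=True, cell_label=cell_label, channel=channel,
                       reject_reason=reason)

    if not np.any(roi > 0):
        return failed_fit("nonpositive_roi")

    cand_local = np.array(candidate, dtype=float) - np.array(origin)
    center, I, sigma_xy, sigma_z, bg, n_iter, converged, drifted = \
        _moment_analysis(roi, cfg, cand_local)
    if I <= 0:
        return failed_fit("no_signal")

    grids = _roi_grids(roi.shape)
    floor = cfg.log_floor
    logdata = np.log(np.maximum(roi, floor))
    zz, yy, xx = grids
    w = np.exp(-((xx - center[2]) ** 2 + (yy - center[1]) ** 2)
               / (2 * cfg.weight_sigma_xy**2)
               - (zz - center[0]) ** 2 / (2 * cfg.weight_sigma_z**2))
    p0 = np.array([max(I, 1e-3), center[2], center[1], center[0],
                   sigma_xy, sigma_z, *bg])
    lo, hi = cfg.sigma_bounds
    nzr, nyr, nxr = roi.shape
    bounds = [(1e-12, None),
              (0.0, nxr - 1.0), (0.0, nyr - 1.0), (0.0, nzr - 1.0),
              (lo, hi), (lo, hi),
              (None, None), (None, None), (None, None), (None, None)]
    res = optimize.minimize(
        _objective, p0, args=(grids, logdata, w, floor), jac=True,
        method="L-BFGS-B", bounds=bounds,
        options=dict(maxiter=500, ftol=1e-14, gtol=1e-10))
    pf = res.x
    oz, oy, ox = origin
    params = SpotModelParams(
        I=float(pf[0]), x0=float(pf[1] + ox), y0=float(pf[2] + oy),
        z0=float(pf[3] + oz), sigma_xy=float(pf[4]), sigma_z=float(pf[5]),
        b=float(pf[6] - pf[7] * ox - pf[8] * oy - pf[9] * oz),
        bx=float(pf[7]), by=float(pf[8]), bz=float(pf[9]))
    r2_total, r2_peak, r2_background = goodness_of_fit(roi, params, origin)
    return SpotFit(params=params, peak_intensity=peak_intensity(params),
                   r2_total=r2_total, r2_peak=r2_peak,
                   r2_background=r2_background, candidate_xyz=cand_xyz,
                   n_iterations=n_iter, converged=converged and not drifted,
                   cell_label=cell_label, channel=channel)


# ---------------------------------------------------------------------------
# Filtering


def filter_spots(fits: list[SpotFit], cells=None,
                 cfg: DetectionConfig | None = None,
                 duplicate_tol: float = 0.1,
                 r2_peak_min: float = -1.0) -> list[SpotFit]:
    """Apply the quality filters, in order:

    1. drop failed fits and fits whose center moved more than ``max_shift``
       (3 voxels) from the detection candidate;
    2. deduplicate pairs closer than ``duplicate_tol`` x the psf size using
       the psf-normalised distance
       sqrt(dx^2/s_xy^2 + dy^2/s_xy^2 + dz^2/s_z^2), keeping the first in
       input order;
    3. keep only spots inside a cell mask (if ``cells`` given), recording the
       cell label;
    4. keep only fits with peak adjusted R^2 above ``r2_peak_min``.

    Rejected fits are returned too (callers that want only survivors filter
    on ``reject_reason == ""``); the operation is idempotent.
    """
    cfg = cfg or DetectionConfig()
    out: list[SpotFit] = []
    kept_positions: list[np.ndarray] = []
    psf = np.array([cfg.psf_sigma_xy, cfg.psf_sigma_xy, cfg.psf_sigma_z])
    for f in fits:
        f = replace(f)
        if f.failed or f.params is None:
            f.reject_reason = f.reject_reason or "failed"
            out.append(f)
            continue
        shift = np.linalg.norm(f.position - np.asarray(f.candidate_xyz, float))
        if shift > cfg.max_shift:
            f.reject_reason = "moved_from_candidate"
            out.append(f)
            continue
        dup = any(np.sqrt((((f.position - q) / psf) ** 2).sum()) < duplicate_tol
                  for q in kept_positions)
        if dup:
            f.reject_reason = "duplicate"
            out.append(f)
            continue
        if cells is not None:
            xi = int(round(f.params.x0))
            yi = int(round(f.params.y0))
            labels = cells.labels if hasattr(cells, "labels") else np.asarray(cells)
            inside = (0 <= yi < labels.shape[0] and 0 <= xi < labels.shape[1]
                      and labels[yi, xi] > 0)
            if not inside:
                f.reject_reason = "outside_cells"
                out.append(f)
                continue
            f.cell_label = int(labels[yi, xi])
        if not np.isnan(f.r2_peak) and f.r2_peak <= r2_peak_min:
            f.reject_reason = "poor_peak_fit"
            out.append(f)
            continue
        f.reject_reason = ""
        kept_positions.append(f.position)
        out.append(f)
    return out


def kept(fits: list[SpotFit]) -> list[SpotFit]:
    return [f for f in fits if not f.failed and f.reject_reason == ""]


def fit_spots(stack: np.ndarray, cfg: DetectionConfig, cells=None,
              channel: str = "") -> list[SpotFit]:
    """Detect, fit and filter all spots in a stack."""
    cands = detect_candidates(stack, cfg)
    fits = [refine_spot(stack, c, cfg, channel=channel) for c in cands]
    n_in = len(fits)
    fits = filter_spots(fits, cells=cells, cfg=cfg)
    logger.info("fit_spots: %d candidates, %d kept", n_in, len(kept(fits)))
    return fits


def spots_to_dataframe(fits: list[SpotFit],
                       voxel_size=(0.25, 0.1, 0.1)) -> pd.DataFrame:
    """Tabulate fits with positions/widths in voxels and micrometres.

    ``voxel_size`` is (dz, dy, dx) in um; sigma_xy is converted with the xy
    pixel size, sigma_z with the z step.
    """
    dz, dy, dx = voxel_size
    rows = []
    for f in fits:
        p = f.params
        row = dict(channel=f.channel, cell=f.cell_label,
                   n_iterations=f.n_iterations,
                   kept=(not f.failed and f.reject_reason == ""),
                   reject_reason=f.reject_reason,
                   r2_total=f.r2_total, r2_peak=f.r2_peak,
                   r2_background=f.r2_background)
        if p is None:
            row.update({k: np.nan for k in
                        ("x0", "y0", "z0", "x0_um", "y0_um", "z0_um",
                         "sigma_xy", "sigma_z", "sigma_xy_um", "sigma_z_um",
                         "I", "I_p", "b", "bx", "by", "bz")})
        else:
            row.update(x0=p.x0, y0=p.y0, z0=p.z0,
                       x0_um=p.x0 * dx, y0_um=p.y0 * dy, z0_um=p.z0 * dz,
                       sigma_xy=p.sigma_xy, sigma_z=p.sigma_z,
                       sigma_xy_um=p.sigma_xy * dx, sigma_z_um=p.sigma_z * dz,
                       I=p.I, I_p=f.peak_intensity,
                       b=p.b, bx=p.bx, by=p.by, bz=p.bz)
        rows.append(row)
    cols = ["channel", "cell", "x0", "y0", "z0", "x0_um", "y0_um", "z0_um",
            "sigma_xy", "sigma_z", "sigma_xy_um", "sigma_z_um", "I", "I_p",
            "b", "bx", "by", "bz", "r2_total", "r2_peak", "r2_background",
            "n_iterations", "kept", "reject_reason"]
    return pd.DataFrame(rows, columns=cols)
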