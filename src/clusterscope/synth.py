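"""Synthetic microscopy generators with known ground truth.

Every downstream stage of the pipeline (segmentation, spot fitting,
registration, burst analysis) is exercised against images and traces produced
here, so each generator returns both the rendered data and a table of the
exact parameters used to render it.

The forward model for a spot is an anisotropic 3D Gaussian on a tilted
background,

    G(x, y, z) = I / ((2*pi)^(3/2) * sigma_xy^2 * sigma_z)
                 * exp(-((x-x0)^2 + (y-y0)^2) / (2 sigma_xy^2)
                       - (z-z0)^2 / (2 sigma_z^2))
                 + b + bx*x + by*y + bz*z

with I the integrated intensity (counts), (x0, y0, z0) the center in voxels
and (b, bx, by, bz) the background plane.  Axis order of all stacks is
(z, y, x); movies are (t, z, y, x).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "GroundTruthSpot",
    "TelegraphParams",
    "SceneSpec",
    "gaussian_spot_value",
    "render_spot_stack",
    "render_cell_field",
    "render_bead_pair",
    "simulate_telegraph_states",
    "simulate_ts_movie",
]

TWO_PI_32 = (2.0 * np.pi) ** 1.5


@dataclass
class GroundTruthSpot:
    """True parameters of one rendered spot (all positions in voxels)."""

    x0: float
    y0: float
    z0: float
    sigma_xy: float
    sigma_z: float
    total_intensity: float
    background: tuple[float, float, float, float] = (0.0, 0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if self.sigma_xy <= 0 or self.sigma_z <= 0:
            raise ValueError("sigma_xy and sigma_z must be positive")
        if self.total_intensity < 0:
            raise ValueError("total_intensity must be nonnegative")


@dataclass
class TelegraphParams:
    """Two-state (telegraph) promoter model parameters.

    The promoter switches on with rate ``k_on`` and off with rate ``k_off``
    (exponential dwell times).  While on, transcripts initiate as a Poisson
    process with rate ``initiation_rate``; each transcript stays at the
    transcription site for a fixed ``dwell_time`` and contributes
    ``intensity_per_transcript`` counts while resident.
    """

    k_on: float = 1.0 / 120.0
    k_off: float = 1.0 / 120.0
    initiation_rate: float = 0.2
    dwell_time: float = 120.0
    intensity_per_transcript: float = 100.0
    frame_interval: float = 15.0
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        for name in ("k_on", "k_off", "initiation_rate", "dwell_time",
                     "intensity_per_transcript", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")


@dataclass
class SceneSpec:
    """Geometry, noise model and seed of a synthetic acquisition.

    Defaults mirror the cluster acquisitions: a 512 x 512 pixel field imaged
    as 21 z-planes at 250 nm steps.  The xy pixel size is configurable
    (default 100 nm); every physical-unit output downstream carries the
    configured voxel size.
    """

    shape: tuple[int, int, int] = (21, 512, 512)  # (nz, ny, nx)
    voxel_size: tuple[float, float, float] = (0.25, 0.1, 0.1)  # (dz, dy, dx) um
    n_cells: int = 10
    spots_per_cell: tuple[float, float] = (0, 4)  # uniform integer range
    noise_model: str = "none"  # "none" | "gaussian" | "poisson"
    noise_sd: float = 10.0
    gain: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.shape):
            raise ValueError("shape must be positive")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel_size must be positive")
        if self.noise_model not in ("none", "gaussian", "poisson"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")

    def to_yaml(self) -> str:
        return yaml.safe_dump(dataclasses.asdict(self))

    @classmethod
    def from_yaml(cls, text: str) -> "SceneSpec":
        d = yaml.safe_load(text)
        for key in ("shape", "voxel_size", "spots_per_cell"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)


def gaussian_spot_value(spot: GroundTruthSpot, x, y, z, include_background=True):
    """Scalar (or broadcast) evaluation of the spot model at voxel coordinates.

    Independent of the vectorised renderer; used as a cross-check oracle.
    """
    amp = spot.total_intensity / (TWO_PI_32 * spot.sigma_xy**2 * spot.sigma_z)
    val = amp * np.exp(
        -((np.asarray(x) - spot.x0) ** 2 + (np.asarray(y) - spot.y0) ** 2)
        / (2.0 * spot.sigma_xy**2)
        - (np.asarray(z) - spot.z0) ** 2 / (2.0 * spot.sigma_z**2)
    )
    if include_background:
        b, bx, by, bz = spot.background
        val = val + b + bx * np.asarray(x) + by * np.asarray(y) + bz * np.asarray(z)
    return val


def _apply_noise(stack: np.ndarray, scene: SceneSpec, rng: np.random.Generator) -> np.ndarray:
    if scene.noise_model == "none":
        return stack
    if scene.noise_model == "gaussian":
        return stack + rng.normal(0.0, scene.noise_sd, stack.shape)
    # EM-CCD-like: Poisson shot noise on the expected photon count, scaled by
    # the camera gain, plus Gaussian read noise.
    photons = np.clip(stack / scene.gain, 0, None)
    out = rng.poisson(photons).astype(float) * scene.gain
    if scene.noise_sd > 0:
        out = out + rng.normal(0.0, scene.noise_sd, stack.shape)
    return out


def _add_spot(stack: np.ndarray, spot: GroundTruthSpot, truncate: float = 5.0) -> None:
    """Add the Gaussian term of one spot in place, truncated at ``truncate`` sigma."""
    nz, ny, nx = stack.shape
    if np.isfinite(truncate):
        rz = truncate * spot.sigma_z
        rxy = truncate * spot.sigma_xy
        z0 = max(int(np.floor(spot.z0 - rz)), 0)
        z1 = min(int(np.ceil(spot.z0 + rz)) + 1, nz)
        y0 = max(int(np.floor(spot.y0 - rxy)), 0)
        y1 = min(int(np.ceil(spot.y0 + rxy)) + 1, ny)
        x0 = max(int(np.floor(spot.x0 - rxy)), 0)
        x1 = min(int(np.ceil(spot.x0 + rxy)) + 1, nx)
    else:
        z0, z1, y0, y1, x0, x1 = 0, nz, 0, ny, 0, nx
    if z0 >= z1 or y0 >= y1 or x0 >= x1:
        return
    z = np.arange(z0, z1)[:, None, None]
    y = np.arange(y0, y1)[None, :, None]
    x = np.arange(x0, x1)[None, None, :]
    amp = spot.total_intensity / (TWO_PI_32 * spot.sigma_xy**2 * spot.sigma_z)
    stack[z0:z1, y0:y1, x0:x1] += amp * np.exp(
        -((x - spot.x0) ** 2 + (y - spot.y0) ** 2) / (2.0 * spot.sigma_xy**2)
        - (z - spot.z0) ** 2 / (2.0 * spot.sigma_z**2)
    )


def _background_plane(shape: tuple[int, int, int],
                      coeffs: tuple[float, float, float, float]) -> np.ndarray:
    nz, ny, nx = shape
    b, bx, by, bz = coeffs
    z = np.arange(nz)[:, None, None]
    y = np.arange(ny)[None, :, None]
    x = np.arange(nx)[None, None, :]
    return b + bx * x + by * y + bz * z + np.zeros(shape)


def spots_to_table(spots: list[GroundTruthSpot]) -> pd.DataFrame:
    rows = []
    for s in spots:
        b, bx, by, bz = s.background
        rows.append(dict(x0=s.x0, y0=s.y0, z0=s.z0, sigma_xy=s.sigma_xy,
                         sigma_z=s.sigma_z, total_intensity=s.total_intensity,
                         b=b, bx=bx, by=by, bz=bz))
    return pd.DataFrame(rows, columns=["x0", "y0", "z0", "sigma_xy", "sigma_z",
                                       "total_intensity", "b", "bx", "by", "bz"])


def render_spot_stack(spots: list[GroundTruthSpot], scene: SceneSpec,
                      truncate: float = np.inf):
    """Render spots on a tilted background plus noise.

    The background plane of the *first* spot is used as the stack background
    (spots in one stack share one local background); with no spots the stack
    is zero before noise.  Returns ``(stack, ground_truth_table)``.

    Set ``truncate`` to a finite number of sigmas (e.g. 5) to speed up large
    renders; the default evaluates every spot over the full stack.
    """
    nz, ny, nx = scene.shape
    for s in spots:
        if not (0 <= s.x0 < nx and 0 <= s.y0 < ny and 0 <= s.z0 < nz):
            raise ValueError(
                f"spot at ({s.x0}, {s.y0}, {s.z0}) lies outside the "
                f"stack domain (nz,ny,nx)={scene.shape}")
    stack = np.zeros(scene.shape, dtype=float)
    if spots:
        stack += _background_plane(scene.shape, spots[0].background)
    for s in spots:
        _add_spot(stack, s, truncate=truncate)
    rng = np.random.default_rng(scene.seed)
    stack = _apply_noise(stack, scene, rng)
    return stack, spots_to_table(spots)


# ---------------------------------------------------------------------------
# Cell fields


def _place_cells(rng: np.random.Generator, scene: SceneSpec, radius: float,
                 min_separation: float, max_tries: int = 2000):
    nz, ny, nx = scene.shape
    centers: list[tuple[float, float]] = []
    tries = 0
    while len(centers) < scene.n_cells:
        if tries >= max_tries:
            raise RuntimeError(
                f"could not place {scene.n_cells} cells with separation "
                f">= {min_separation} px in {max_tries} tries")
        tries += 1
        cy = rng.uniform(radius + 2, ny - radius - 2)
        cx = rng.uniform(radius + 2, nx - radius - 2)
        if all((cy - y) ** 2 + (cx - x) ** 2 >= min_separation**2
               for y, x in centers):
            centers.append((cy, cx))
    return centers


def render_cell_field(scene: SceneSpec, cell_radius: float = 30.0,
                      nucleus_radius: float = 12.0, min_separation: float = 70.0,
                      cell_intensity: float = 300.0, nucleus_intensity: float = 500.0,
                      spot_intensity: float = 5000.0, spot_sigma_xy: float = 1.66,
                      spot_sigma_z: float = 1.06,
                      min_spot_separation: float = 6.0):
    """Render a field of cells: autofluorescent ellipsoidal bodies with
    brighter nuclei, plus diffraction-limited spots inside each nucleus.

    Returns ``(body_stack, spot_stack, cell_mask, nucleus_mask, spot_table)``
    where the masks are 2D ground-truth label images (one label per cell) and
    the spot table carries a ``cell`` column.
    """
    rng = np.random.default_rng(scene.seed)
    nz, ny, nx = scene.shape
    centers = _place_cells(rng, scene, cell_radius, min_separation)
    zc = (nz - 1) / 2.0

    y = np.arange(ny)[:, None]
    x = np.arange(nx)[None, :]
    body2d = np.zeros((ny, nx))
    cell_mask = np.zeros((ny, nx), dtype=np.int32)
    nucleus_mask = np.zeros((ny, nx), dtype=np.int32)
    spots: list[GroundTruthSpot] = []
    spot_cells: list[int] = []

    for label, (cy, cx) in enumerate(centers, start=1):
        r2 = ((y - cy) ** 2 + (x - cx) ** 2)
        inside = r2 <= cell_radius**2
        cell_mask[inside] = label
        # smooth profile: cosine-tapered body + brighter Gaussian nucleus
        prof = np.clip(1 - r2 / cell_radius**2, 0, None)
        body2d += cell_intensity * prof
        body2d += nucleus_intensity * np.exp(-r2 / (2 * (nucleus_radius / 1.5) ** 2))
        nucleus_mask[r2 <= nucleus_radius**2] = label

        lo, hi = scene.spots_per_cell
        n_spots = int(rng.integers(int(lo), int(hi) + 1))
        placed: list[tuple[float, float]] = []
        for _ in range(n_spots):
            # keep spots in one nucleus mutually resolvable
            for _try in range(200):
                rr = nucleus_radius * 0.8 * np.sqrt(rng.uniform())
                th = rng.uniform(0, 2 * np.pi)
                sx, sy = cx + rr * np.cos(th), cy + rr * np.sin(th)
                if all((sx - px) ** 2 + (sy - py) ** 2
                       >= min_spot_separation**2 for px, py in placed):
                    break
            else:
                continue
            placed.append((sx, sy))
            spots.append(GroundTruthSpot(
                x0=sx, y0=sy, z0=zc + rng.uniform(-2, 2),
                sigma_xy=spot_sigma_xy, sigma_z=spot_sigma_z,
                total_intensity=spot_intensity * rng.uniform(0.5, 2.0)))
            spot_cells.append(label)

    # axial body profile: cells are in-focus near the center plane
    zprof = np.exp(-((np.arange(nz) - zc) ** 2) / (2 * (nz / 3.0) ** 2))
    body = zprof[:, None, None] * body2d[None, :, :]

    spot_stack = np.zeros(scene.shape)
    for s in spots:
        _add_spot(spot_stack, s, truncate=5.0)
    spot_stack += 0.05 * body  # bleed-through autofluorescence background

    body = _apply_noise(body, scene, rng)
    spot_stack = _apply_noise(spot_stack, scene, rng)
    table = spots_to_table(spots)
    table["cell"] = spot_cells if spots else pd.Series(dtype=int)
    return body, spot_stack, cell_mask, nucleus_mask, table


# ---------------------------------------------------------------------------
# Bead fields for two-channel registration


def render_bead_pair(n_beads: int, transform: np.ndarray, z_offset: float,
                     scene: SceneSpec, bead_intensity: float = 20000.0,
                     sigma_xy: float = 1.66, sigma_z: float = 1.06,
                     background: float = 100.0):
    """Render the same bead field in two channels related by a 2D affine + z offset.

    ``transform`` is a 2x3 matrix mapping channel-1 ``(x, y)`` to channel-2
    coordinates: ``(x2, y2) = A @ (x1, y1, 1)``.  Channel-2 z positions are
    channel-1 z plus ``z_offset``.  Returns ``(tv1, tv2, correspondences)``
    where the correspondence table holds the true paired coordinates.
    """
    transform = np.asarray(transform, dtype=float)
    if transform.shape != (2, 3):
        raise ValueError("transform must be a 2x3 affine matrix")
    if abs(np.linalg.det(transform[:, :2])) < 1e-12:
        raise ValueError("transform is not invertible")
    rng = np.random.default_rng(scene.seed)
    nz, ny, nx = scene.shape
    margin = 15.0
    pts = []
    tries = 0
    while len(pts) < n_beads:
        if tries > 100 * max(n_beads, 1):
            raise RuntimeError("could not place beads inside both channel domains")
        tries += 1
        x1 = rng.uniform(margin, nx - margin)
        y1 = rng.uniform(margin, ny - margin)
        z1 = rng.uniform(2.5, nz - 3.5)
        x2, y2 = transform @ np.array([x1, y1, 1.0])
        z2 = z1 + z_offset
        if not (margin / 2 <= x2 < nx - margin / 2 and
                margin / 2 <= y2 < ny - margin / 2 and 1 <= z2 < nz - 1):
            continue
        if any((y1 - p[1]) ** 2 + (x1 - p[0]) ** 2 < 20.0**2 for p in pts):
            continue
        pts.append((x1, y1, z1, x2, y2, z2))

    bg = (background, 0.0, 0.0, 0.0)
    tv1 = np.full(scene.shape, background, dtype=float)
    tv2 = np.full(scene.shape, background, dtype=float)
    for x1, y1, z1, x2, y2, z2 in pts:
        _add_spot(tv1, GroundTruthSpot(x1, y1, z1, sigma_xy, sigma_z,
                                       bead_intensity, bg), truncate=5.0)
        _add_spot(tv2, GroundTruthSpot(x2, y2, z2, sigma_xy, sigma_z,
                                       bead_intensity, bg), truncate=5.0)
    tv1 = _apply_noise(tv1, scene, rng)
    tv2 = _apply_noise(tv2, scene, rng)
    table = pd.DataFrame(pts, columns=["x1", "y1", "z1", "x2", "y2", "z2"])
    return tv1, tv2, table


# ---------------------------------------------------------------------------
# Telegraph-model transcription traces


def simulate_telegraph_states(params: TelegraphParams, duration: float,
                              rng: np.random.Generator, initial_state=None):
    """Simulate the on/off switching process as a list of (t_start, t_end, state).

    Dwell times are exponential with rates ``k_off`` (leaving on) and ``k_on``
    (leaving off).  ``initial_state`` defaults to a draw from the stationary
    distribution (all-off if k_on == 0, all-on if k_off == 0).
    """
    k_on, k_off = params.k_on, params.k_off
    if initial_state is None:
        if k_on + k_off == 0:
            state = 0
        else:
            state = int(rng.uniform() < k_on / (k_on + k_off))
    else:
        state = int(initial_state)
    t = 0.0
    intervals = []
    while t < duration:
        rate = k_off if state == 1 else k_on
        dt = np.inf if rate == 0 else rng.exponential(1.0 / rate)
        t_end = min(t + dt, duration)
        intervals.append((t, t_end, state))
        t = t_end
        state = 1 - state
    return intervals


def _trace_from_intervals(intervals, params: TelegraphParams, duration: float,
                          rng: np.random.Generator):
    """Frame-sampled TS intensity from switching intervals.

    Transcripts initiate as a Poisson process during on intervals and stay at
    the TS for a fixed dwell time; frame intensity counts resident transcripts.
    """
    times = np.arange(0.0, duration, params.frame_interval)
    init_times = []
    for t0, t1, state in intervals:
        if state == 1 and params.initiation_rate > 0:
            n = rng.poisson(params.initiation_rate * (t1 - t0))
            if n:
                init_times.append(rng.uniform(t0, t1, n))
    init_times = np.sort(np.concatenate(init_times)) if init_times else np.empty(0)
    # resident at frame t: initiated in (t - dwell, t]
    n_resident = (np.searchsorted(init_times, times, side="right")
                  - np.searchsorted(init_times, times - params.dwell_time, side="right"))
    intensity = params.intensity_per_transcript * n_resident.astype(float)
    if params.noise_sd > 0:
        intensity = intensity + rng.normal(0.0, params.noise_sd, intensity.size)
    state = np.zeros(times.size, dtype=int)
    for t0, t1, s in intervals:
        if s == 1:
            state[(times >= t0) & (times < t1)] = 1
    return times, intensity, state


def simulate_ts_movie(params: TelegraphParams, n_cells: int, duration: float,
                      seed: int = 0, initial_state=None):
    """Simulate per-cell transcription-site traces from the telegraph model.

    Returns a dict with ``times`` (shared frame grid), ``intensity``
    (n_cells x n_frames), ``state`` (true promoter state per frame) and
    ``intervals`` (per cell, list of (t_start, t_end, state) switching
    intervals).
    """
    if duration < params.frame_interval:
        raise ValueError("duration must cover at least one frame interval")
    rng = np.random.default_rng(seed)
    all_int, all_i, all_s = [], [], []
    times = None
    for _ in range(n_cells):
        intervals = simulate_telegraph_states(params, duration, rng, initial_state)
        times, intensity, state = _trace_from_intervals(intervals, params, duration, rng)
        all_int.append(intervals)
        all_i.append(intensity)
        all_s.append(state)
    return dict(times=times, intensity=np.array(all_i), state=np.array(all_s),
                intervals=all_int)


def render_ts_movie(traces: dict, scene: SceneSpec, positions=None,
                    sigma_xy: float = 1.66, sigma_z: float = 1.06,
                    background: float = 100.0):
    """Render simulated traces as a (t, z, y, x) movie with one TS per cell.

    ``positions`` is an optional (n_cells, 2) array of (y, x) TS positions;
    defaults to a deterministic grid.  Used to exercise the tracking stage.
    """
    intensity = traces["intensity"]
    n_cells, n_frames = intensity.shape
    nz, ny, nx = scene.shape
    rng = np.random.default_rng(scene.seed)
    if positions is None:
        side = int(np.ceil(np.sqrt(n_cells)))
        step_y, step_x = ny / (side + 1), nx / (side + 1)
        positions = np.array([[(i // side + 1) * step_y, (i % side + 1) * step_x]
                              for i in range(n_cells)])
    zc = (nz - 1) / 2.0
    movie = np.empty((n_frames, nz, ny, nx))
    for t in range(n_frames):
        frame = np.full((nz, ny, nx), background)
        for c in range(n_cells):
            amp = intensity[c, t]
            if amp > 0:
                _add_spot(frame, GroundTruthSpot(
                    positions[c, 1], positions[c, 0], zc, sigma_xy, sigma_z,
                    amp * TWO_PI_32 * sigma_xy**2 * sigma_z), truncate=5.0)
        movie[t] = _apply_noise(frame, scene, rng)
    return movie, np.asarray(positions)
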