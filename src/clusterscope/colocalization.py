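"""Two-channel registration and cluster / reference-label colocalization.

The two camera channels (TV1: DNA-/RNA-reference label, TV2: clusters) are
related by chromatic and geometric aberrations.  A 2D affine transform is
estimated from a two-color bead field by pairing bead centroids between
channels; z is corrected by a single focus offset, the IQR-filtered mean of
the per-pair z differences.  After mapping cluster positions into the
reference frame, the per-cell nearest-neighbor distance (NND) from the
reference spot to any cluster quantifies colocalization; cells whose
reference has no cluster keep a missing NND but stay in the denominator of
the normalized NND histogram.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .spotfit import DetectionConfig, SpotFit, fit_spots, kept, threshold_from_sd

__all__ = [
    "ChannelRegistration",
    "NNDRecord",
    "estimate_channel_registration",
    "apply_registration",
    "select_reference_spot",
    "nnd_analysis",
    "overlap_test",
]


@dataclass
class ChannelRegistration:
    """2D affine (2x3, mapping TV2 (x, y) into TV1 pixels) plus a z offset
    in planes: z_tv1 = z_tv2 + z_offset."""

    affine_2d: np.ndarray
    z_offset: float
    n_bead_pairs: int = 0
    residual_xy: float = float("nan")

    def __post_init__(self) -> None:
        self.affine_2d = np.asarray(self.affine_2d, dtype=float)
        if self.affine_2d.shape != (2, 3):
            raise ValueError("affine_2d must be 2x3")
        if abs(np.linalg.det(self.affine_2d[:, :2])) < 1e-12:
            raise ValueError("affine_2d is not invertible")

    def map_xy(self, xy: np.ndarray) -> np.ndarray:
        xy = np.atleast_2d(np.asarray(xy, dtype=float))
        return xy @ self.affine_2d[:, :2].T + self.affine_2d[:, 2]

    def to_yaml(self) -> str:
        return yaml.safe_dump(dict(affine_2d=self.affine_2d.tolist(),
                                   z_offset=float(self.z_offset),
                                   n_bead_pairs=int(self.n_bead_pairs),
                                   residual_xy=float(self.residual_xy)))

    @classmethod
    def from_yaml(cls, text: str) -> "ChannelRegistration":
        d = yaml.safe_load(text)
        return cls(affine_2d=np.array(d["affine_2d"]), z_offset=d["z_offset"],
                   n_bead_pairs=d.get("n_bead_pairs", 0),
                   residual_xy=d.get("residual_xy", float("nan")))


@dataclass
class NNDRecord:
    """Nearest-neighbor distance from one cell's reference spot to its clusters."""

    cell_label: int
    reference: SpotFit | None
    nnd_3d: float = float("nan")
    nnd_2d: float = float("nan")
    n_clusters_in_cell: int = 0


def _bead_centroids(stack: np.ndarray, cfg: DetectionConfig,
                    threshold_k: float = 10.0) -> np.ndarray:
    """Detect and fit beads; returns (n, 3) array of (x, y, z) in voxels."""
    cfg = dataclasses.replace(cfg, abs_threshold=threshold_from_sd(stack, cfg,
                                                                   threshold_k))
    fits = fit_spots(stack, cfg)
    pos = [f.position for f in kept(fits)]
    return np.array(pos) if pos else np.empty((0, 3))


def _mutual_nn_pairs(p1: np.ndarray, p2: np.ndarray, gate: float):
    """Mutual nearest neighbors in xy within a distance gate."""
    pairs = []
    if len(p1) == 0 or len(p2) == 0:
        return pairs
    d = np.linalg.norm(p1[:, None, :2] - p2[None, :, :2], axis=-1)
    nn12 = d.argmin(axis=1)
    nn21 = d.argmin(axis=0)
    for i, j in enumerate(nn12):
        if nn21[j] == i and d[i, j] <= gate:
            pairs.append((i, j))
    return pairs


def _iqr_inlier(values: np.ndarray) -> np.ndarray:
    """Boolean mask of values within [Q1 - 1.5 IQR, Q3 + 1.5 IQR]."""
    q1, q3 = np.quantile(values, [0.25, 0.75])
    iqr = q3 - q1
    return (values >= q1 - 1.5 * iqr) & (values <= q3 + 1.5 * iqr)


def estimate_channel_registration(tv1_beads: np.ndarray, tv2_beads: np.ndarray,
                                  cfg: DetectionConfig | None = None,
                                  threshold_k: float = 10.0,
                                  pair_gate: float = 10.0) -> ChannelRegistration:
    """Estimate the TV2 -> TV1 registration from a two-color bead field.

    Beads are localized in both channels with the standard detection/fitting
    pipeline at a ``threshold_k`` x SD detection threshold, paired by mutual
    nearest neighbors in xy within ``pair_gate`` px, filtered by the IQR rule
    on the xy displacement components, then least squares gives the 2D
    affine; the z offset is the IQR-filtered mean of the per-pair z
    differences.
    """
    cfg = cfg or DetectionConfig()
    p1 = _bead_centroids(np.asarray(tv1_beads, float), cfg, threshold_k)
    p2 = _bead_centroids(np.asarray(tv2_beads, float), cfg, threshold_k)
    if len(p1) < 3 or len(p2) < 3:
        raise ValueError("need at least 3 detectable beads in each channel")
    pairs = _mutual_nn_pairs(p1, p2, pair_gate)
    if len(pairs) < 3:
        raise ValueError(f"only {len(pairs)} bead pairs found; need >= 3")
    i1 = np.array([i for i, _ in pairs])
    i2 = np.array([j for _, j in pairs])
    a, b = p1[i1], p2[i2]

    dxy = a[:, :2] - b[:, :2]
    good = _iqr_inlier(dxy[:, 0]) & _iqr_inlier(dxy[:, 1])
    if good.sum() < 3:
        good[:] = True
    a, b = a[good], b[good]

    # least squares: [x2 y2 1] @ M.T = [x1 y1]
    A = np.column_stack([b[:, 0], b[:, 1], np.ones(len(b))])
    M, res, *_ = np.linalg.lstsq(A, a[:, :2], rcond=None)
    affine = M.T
    fitted = A @ M
    residual = float(np.sqrt(np.mean(np.sum((fitted - a[:, :2]) ** 2, axis=1))))

    dz = a[:, 2] - b[:, 2]
    z_offset = float(np.mean(dz[_iqr_inlier(dz)])) if len(dz) >= 4 else float(np.mean(dz))
    return ChannelRegistration(affine_2d=affine, z_offset=z_offset,
                               n_bead_pairs=int(good.sum()),
                               residual_xy=residual)


def apply_registration(spots: list[SpotFit],
                       reg: ChannelRegistration) -> list[SpotFit]:
    """Map TV2 spot positions into the TV1 frame; other fields unchanged."""
    out = []
    for f in spots:
        if f.params is None:
            out.append(f)
            continue
        x, y = reg.map_xy([f.params.x0, f.params.y0])[0]
        out.append(replace(f, params=dataclasses.replace(
            f.params, x0=float(x), y0=float(y),
            z0=f.params.z0 + reg.z_offset)))
    return out


def select_reference_spot(spots: list[SpotFit], nucleus,
                          cell_label: int) -> SpotFit | None:
    """The in-nucleus reference-channel spot with the largest peak density.

    Ties on I_p are broken by input order (first wins).
    """
    labels = nucleus.labels if hasattr(nucleus, "labels") else np.asarray(nucleus)
    best = None
    for f in spots:
        if f.params is None:
            continue
        xi, yi = int(round(f.params.x0)), int(round(f.params.y0))
        if not (0 <= yi < labels.shape[0] and 0 <= xi < labels.shape[1]):
            continue
        if labels[yi, xi] != cell_label:
            continue
        if best is None or f.peak_intensity > best.peak_intensity:
            best = f
    return best


def _distance_um(a: SpotFit, b: SpotFit, voxel_size, mode: str) -> float:
    dz, dy, dx = voxel_size
    ddx = (a.params.x0 - b.params.x0) * dx
    ddy = (a.params.y0 - b.params.y0) * dy
    if mode == "2D":
        return float(np.hypot(ddx, ddy))
    ddz = (a.params.z0 - b.params.z0) * dz
    return float(np.sqrt(ddx**2 + ddy**2 + ddz**2))


def nnd_analysis(clusters: list[SpotFit], references: list[NNDRecord],
                 voxel_size=(0.25, 0.1, 0.1), mode: str = "3D",
                 bin_width: float = 0.1, n_boot: int = 1000,
                 seed: int = 0):
    """Per-cell nearest-neighbor distances and their normalized histogram.

    ``references`` seed the analysis: one record per reference-bearing cell.
    For each, the NND is the minimal distance (in um, via ``voxel_size``)
    from the reference spot to any cluster in the same cell — missing if the
    cell has no cluster, in which case the cell still counts in the histogram
    denominator.  Bar heights are n_in_bin / n_reference_cells, so the bars
    sum to the fraction of reference-bearing cells with at least one cluster.
    Per-bin SEM is the SD over ``n_boot`` bootstrap resamples of cells.

    Returns ``(records, histogram_dataframe)``.
    """
    if mode not in ("2D", "3D"):
        raise ValueError("mode must be '2D' or '3D'")
    if not references:
        raise ValueError("no reference-bearing cells")
    by_cell: dict[int, list[SpotFit]] = {}
    for c in clusters:
        if c.params is not None:
            by_cell.setdefault(c.cell_label, []).append(c)

    records = []
    for ref in references:
        cl = by_cell.get(ref.cell_label, [])
        rec = replace(ref, n_clusters_in_cell=len(cl))
        if cl and rec.reference is not None:
            d3 = [_distance_um(rec.reference, c, voxel_size, "3D") for c in cl]
            d2 = [_distance_um(rec.reference, c, voxel_size, "2D") for c in cl]
            rec.nnd_3d = min(d3)
            rec.nnd_2d = min(d2)
        else:
            rec.nnd_3d = float("nan")
            rec.nnd_2d = float("nan")
        records.append(rec)

    nnds = np.array([r.nnd_3d if mode == "3D" else r.nnd_2d for r in records])
    n_cells = len(records)
    finite = nnds[np.isfinite(nnds)]
    n_bins = max(int(np.ceil((finite.max() + 1e-9) / bin_width)), 1) if finite.size else 1
    edges = np.arange(n_bins + 1) * bin_width
    counts, _ = np.histogram(finite, bins=edges)
    frac = counts / n_cells

    rng = np.random.default_rng(seed)
    boot = np.empty((n_boot, n_bins))
    for i in range(n_boot):
        sample = nnds[rng.integers(0, n_cells, n_cells)]
        c, _ = np.histogram(sample[np.isfinite(sample)], bins=edges)
        boot[i] = c / n_cells
    sem = boot.std(axis=0, ddof=0)

    hist = pd.DataFrame(dict(bin_left=edges[:-1], bin_right=edges[1:],
                             fraction=frac, sem=sem, count=counts))
    return records, hist


def overlap_test(records_a: list[NNDRecord], records_b: list[NNDRecord],
                 threshold: float = 0.4, mode: str = "3D",
                 n_boot: int = 1000, seed: int = 0):
    """Fraction of reference-bearing cells with an overlapping cluster, per
    condition, with bootstrap SEM, plus a two-sided Fisher's exact test on
    the 2x2 overlap / no-overlap table.

    Returns ``(frac_a, sem_a, frac_b, sem_b, p_value)``.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if not records_a or not records_b:
        raise ValueError("both record lists must be nonempty")

    def nnd(r):
        return r.nnd_3d if mode == "3D" else r.nnd_2d

    def stats_for(records):
        vals = np.array([nnd(r) for r in records])
        hit = np.isfinite(vals) & (vals < threshold)
        frac = hit.mean()
        rng = np.random.default_rng(seed)
        boots = np.array([hit[rng.integers(0, len(hit), len(hit))].mean()
                          for _ in range(n_boot)])
        return frac, boots.std(ddof=0), int(hit.sum()), len(hit)

    frac_a, sem_a, ka, na = stats_for(records_a)
    frac_b, sem_b, kb, nb = stats_for(records_b)
    table = [[ka, na - ka], [kb, nb - kb]]
    _, p = stats.fisher_exact(table, alternative="two-sided")
    return frac_a, sem_a, frac_b, sem_b, float(p)


def records_to_dataframe(records: list[NNDRecord]) -> pd.DataFrame:
    rows = [dict(cell=r.cell_label, nnd_3d=r.nnd_3d, nnd_2d=r.nnd_2d,
                 n_clusters=r.n_clusters_in_cell,
                 ref_x0=(r.reference.params.x0 if r.reference else np.nan),
                 ref_y0=(r.reference.params.y0 if r.reference else np.nan),
                 ref_z0=(r.reference.params.z0 if r.reference else np.nan),
                 ref_Ip=(r.reference.peak_intensity if r.reference else np.nan))
            for r in records]
    return pd.DataFrame(rows)
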