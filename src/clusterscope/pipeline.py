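"""End-to-end pipelines: cluster quantification and burst kinetics.

Each run writes its tables (CSV), registration/calibration (YAML) and a JSON
manifest (inputs with hashes, configuration, seed, package version, per-stage
in/out counts) sufficient to reproduce it exactly.  All randomness flows from
one top-level seed, split deterministically per stage.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__, io
from .burstkinetics import (binarize_trace, burst_statistics,
                            correct_xy_drift, estimate_background_sd,
                            set_endpoint_from_binary,
                            track_transcription_sites)
from .cluster_stats import clusters_per_cell
from .colocalization import (ChannelRegistration, NNDRecord,
                             apply_registration, nnd_analysis,
                             records_to_dataframe, select_reference_spot)
from .segmentation import cell_table, segment_cells, segment_nuclei
from .spotfit import (DetectionConfig, filter_spots, fit_spots, kept,
                      spots_to_dataframe, threshold_from_sd)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Configuration shared by both pipelines."""

    voxel_size: tuple[float, float, float] = (0.25, 0.1, 0.1)
    detection: DetectionConfig = field(default_factory=DetectionConfig)
    threshold_k: float | None = 5.0  # k x robust SD if abs_threshold unset
    overlap_threshold: float = 0.4  # um
    binarize_k: float = 6.0
    frame_interval: float = 15.0
    n_boot: int = 1000
    seed: int = 0
    out_dir: str = "results"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        d = io.load_yaml(path) or {}
        det = d.pop("detection", None)
        cfg = cls(**{k: tuple(v) if k == "voxel_size" else v
                     for k, v in d.items()})
        if det:
            for k, v in det.items():
                setattr(cfg.detection, k, tuple(v) if isinstance(v, list) else v)
        return cfg


def _stage_seed(seed: int, stage: str) -> int:
    h = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "little") % (2**31)

def _file_hash(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def _manifest(out: Path, config: PipelineConfig, inputs: dict, stages: dict,
              failed_stage: str | None = None) -> None:
    man = dict(version=__version__, seed=config.seed,
               config={k: (dataclasses.asdict(v) if dataclasses.is_dataclass(v)
                           else list(v) if isinstance(v, tuple) else v)
                       for k, v in dataclasses.asdict(config).items()},
               inputs=inputs, stages=stages, failed_stage=failed_stage)
    (out / "manifest.json").write_text(json.dumps(man, indent=2, default=str))


def run_cluster_pipeline(cluster_stack_path, config: PipelineConfig,
                         reference_stack_path=None, bead_registration=None):
    """Segmentation -> detection -> fitting -> filtering -> (optional)
    registration + colocalization -> statistics.

    ``cluster_stack_path`` is the cluster-channel (TV2) z-stack; the optional
    ``reference_stack_path`` (TV1) enables reference selection and NND
    analysis, corrected by ``bead_registration`` (a ChannelRegistration or a
    YAML path) if given.  Returns a result dict; writes tables and a
    manifest under ``config.out_dir``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    inputs, stages = {}, {}
    failed = None
    result: dict = {}
    try:
        for name, p in (("cluster_stack", cluster_stack_path),
                        ("reference_stack", reference_stack_path)):
            if p is not None:
                if not Path(p).exists():
                    raise FileNotFoundError(f"input file not found: {p}")
                inputs[name] = dict(path=str(p), sha256=_file_hash(p))

        stack = io.read_stack(cluster_stack_path)

        cells = segment_cells(stack)
        nuclei = segment_nuclei(stack, cells)
        stages["segmentation"] = dict(n_cells=cells.n_labels,
                                      n_nuclei=nuclei.n_labels)
        io.write_label_mask(out / "cells.tif", cells.labels)
        io.write_label_mask(out / "nuclei.tif", nuclei.labels)
        cell_table(cells).to_csv(out / "cells.csv", index=False)

        det = config.detection
        if det.abs_threshold == 0 and config.threshold_k:
            det = dataclasses.replace(
                det, abs_threshold=threshold_from_sd(stack, det,
                                                     config.threshold_k))
        fits = fit_spots(stack, det, cells=cells, channel="TV2")
        survivors = kept(fits)
        stages["spots"] = dict(n_candidates=len(fits), n_kept=len(survivors))
        spots_to_dataframe(fits, config.voxel_size).to_csv(
            out / "spots_tv2.csv", index=False)
        result["spots"] = survivors

        counts, hist = clusters_per_cell(
            survivors, cells, n_boot=config.n_boot,
            seed=_stage_seed(config.seed, "counts"))
        hist.to_csv(out / "clusters_per_cell.csv", index=False)
        result["counts"] = counts

        if reference_stack_path is not None:
            ref_stack = io.read_stack(reference_stack_path)
            ref_det = dataclasses.replace(
                det, abs_threshold=threshold_from_sd(
                    ref_stack, det, config.threshold_k or 5.0))
            ref_fits = kept(fit_spots(ref_stack, ref_det, cells=cells,
                                      channel="TV1"))
            stages["reference_spots"] = dict(n_kept=len(ref_fits))
            spots = survivors
            if bead_registration is not None:
                reg = (bead_registration
                       if isinstance(bead_registration, ChannelRegistration)
                       else ChannelRegistration.from_yaml(
                           Path(bead_registration).read_text()))
                spots = apply_registration(survivors, reg)
                (out / "registration.yaml").write_text(reg.to_yaml())
            refs = []
            for lab in cells.label_ids():
                best = select_reference_spot(ref_fits, nuclei, int(lab))
                if best is not None:
                    refs.append(NNDRecord(cell_label=int(lab), reference=best))
            if refs:
                records, hist3d = nnd_analysis(
                    spots, refs, config.voxel_size, mode="3D",
                    n_boot=config.n_boot,
                    seed=_stage_seed(config.seed, "nnd"))
                records_to_dataframe(records).to_csv(out / "nnd.csv",
                                                     index=False)
                hist3d.to_csv(out / "nnd_hist_3d.csv", index=False)
                result["nnd_records"] = records
            stages["colocalization"] = dict(n_reference_cells=len(refs))
    except Exception as exc:
        failed = f"{type(exc).__name__}: {exc}"
        _manifest(out, config, inputs, stages, failed)
        raise
    _manifest(out, config, inputs, stages)
    result.update(cells=cells, nuclei=nuclei, stages=stages)
    return result


def run_burst_pipeline(movie_path, config: PipelineConfig, cells_mask=None):
    """Drift correction -> tracking -> background SD -> binarization ->
    burst statistics.

    ``cells_mask`` (a LabelMask, 2D label array or TIFF path) may be given;
    otherwise cells are segmented from the time-averaged projection.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    inputs, stages = {}, {}
    failed = None
    try:
        if not Path(movie_path).exists():
            raise FileNotFoundError(f"input file not found: {movie_path}")
        inputs["movie"] = dict(path=str(movie_path),
                               sha256=_file_hash(movie_path))
        movie = io.read_movie(movie_path)

        movie, shifts, flagged = correct_xy_drift(movie)
        stages["drift"] = dict(max_shift=float(np.abs(shifts).max()),
                               n_flagged=int(flagged.sum()))

        if cells_mask is None:
            proj = movie.max(axis=1).mean(axis=0) if movie.ndim == 4 \
                else movie.mean(axis=0)
            cells = segment_cells(proj)
        elif isinstance(cells_mask, (str, Path)):
            from .segmentation import LabelMask
            cells = LabelMask(io.read_label_mask(cells_mask))
        else:
            cells = cells_mask
        stages["segmentation"] = dict(n_cells=int(
            len(np.unique(cells.labels[cells.labels > 0]))
            if hasattr(cells, "labels") else len(np.unique(cells[cells > 0]))))

        traces = track_transcription_sites(
            movie, cells, frame_interval=config.frame_interval)
        for tr in traces:
            tr.bg_sd = estimate_background_sd(movie, tr)
        binaries = []
        for tr in traces:
            bt = binarize_trace(tr, k=config.binarize_k)
            set_endpoint_from_binary(tr, bt)
            binaries.append(bt)
        stages["tracking"] = dict(n_traces=len(traces),
                                  n_active=sum(b.states.any() for b in binaries))

        bs = burst_statistics(binaries, traces,
                              frame_interval=config.frame_interval,
                              n_boot=config.n_boot,
                              seed=_stage_seed(config.seed, "bursts"))
        import pandas as pd
        pd.DataFrame(dict(
            cell=[t.cell_label for t in traces],
            active=[bool(b.states.any()) for b in binaries],
            bg_sd=[t.bg_sd for t in traces],
        )).to_csv(out / "traces.csv", index=False)
        pd.DataFrame([dict(metric=k, mean=v, err=bs.errors.get(k))
                      for k, v in bs.means.items()
                      ] + [dict(metric="active_fraction",
                                mean=bs.active_fraction,
                                err=bs.active_fraction_err)]
                     ).to_csv(out / "burst_stats.csv", index=False)
    except Exception as exc:
        failed = f"{type(exc).__name__}: {exc}"
        _manifest(out, config, inputs, stages, failed)
        raise
    _manifest(out, config, inputs, stages)
    return dict(traces=traces, binaries=binaries, stats=bs, stages=stages)
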