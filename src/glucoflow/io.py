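"""Standard-format I/O, configuration and the end-to-end pipeline.

Image series are stored as 4-D NIfTI (ny, nx, 1, time) next to a JSON
sidecar carrying the acquisition plan and frame labels; cohort tables are
CSV; result summaries are JSON.  Conventions: voxel indices are 0-based;
CEST times are minutes (t=0 at injection onset), ASL times seconds —
both stored explicitly in the sidecars.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from . import asl as _asl
from . import cest as _cest
from . import cohort as _cohort
from . import simulate as _sim

__all__ = [
    "PipelineConfig",
    "write_cest_session",
    "read_cest_session",
    "write_asl_session",
    "read_asl_session",
    "write_cohort",
    "read_cohort",
    "write_map",
    "read_map",
    "run_pipeline",
]

log = logging.getLogger("glucoflow")


def _to_nifti(data: np.ndarray) -> nib.Nifti1Image:
    arr = np.asarray(data, dtype=np.float64)
    if arr.ndim == 3:  # (ny, nx, t) -> (ny, nx, 1, t)
        arr = arr[:, :, None, :]
    return nib.Nifti1Image(arr, affine=np.eye(4))


def _from_nifti(path: Path) -> np.ndarray:
    arr = np.asarray(nib.load(str(path)).dataobj, dtype=np.float64)
    if arr.ndim == 4 and arr.shape[2] == 1:
        arr = arr[:, :, 0, :]
    return arr


def _paths(prefix: str | Path) -> tuple[Path, Path]:
    prefix = Path(prefix)
    if prefix.name.endswith(".nii.gz") or prefix.name.endswith(".nii"):
        stem = prefix.name[: -7] if prefix.name.endswith(".nii.gz") else prefix.stem
        prefix = prefix.parent / stem
    return prefix.parent / (prefix.name + ".nii.gz"), prefix.parent / (prefix.name + ".json")


# ---------------------------------------------------------------------------
# CEST sessions


def write_cest_session(series: _cest.CESTSeries, prefix: str | Path) -> Path:
    """Write a CEST series as NIfTI + JSON sidecar; returns the image path."""
    nii, side = _paths(prefix)
    nii.parent.mkdir(parents=True, exist_ok=True)
    nib.save(_to_nifti(series.data), str(nii))
    sched = dataclasses.asdict(series.schedule)
    sidecar = {
        "kind": "cest",
        "time_unit": "min",
        "n_frames": int(series.data.shape[-1]),
        "frame_times_min": series.frame_times.tolist(),
        "frame_offsets_ppm": series.frame_offsets.tolist(),
        "frame_segments": series.frame_segments.tolist(),
        "schedule": sched,
    }
    side.write_text(json.dumps(sidecar, indent=1))
    return nii


def read_cest_session(prefix: str | Path) -> _cest.CESTSeries:
    """Read a CEST series written by :func:`write_cest_session`.

    Validates that the sidecar frame labels match the image frame count.
    """
    nii, side = _paths(prefix)
    if not side.exists():
        raise FileNotFoundError(f"missing JSON sidecar: expected {side}")
    if not nii.exists():
        raise FileNotFoundError(f"missing image file: expected {nii}")
    meta = json.loads(side.read_text())
    if meta.get("kind") != "cest":
        raise ValueError(f"sidecar {side} does not describe a CEST series")
    data = _from_nifti(nii)
    if data.shape[-1] != meta["n_frames"] or len(meta["frame_times_min"]) != data.shape[-1]:
        raise ValueError(
            f"sidecar frame count {meta['n_frames']} does not match image "
            f"frames {data.shape[-1]}"
        )
    sched = meta["schedule"]
    sched["offsets"] = tuple(sched["offsets"])
    schedule = _cest.SaturationSchedule(**sched)
    return _cest.CESTSeries(
        data=data,
        frame_times=np.asarray(meta["frame_times_min"], dtype=float),
        frame_offsets=np.asarray(meta["frame_offsets_ppm"], dtype=float),
        frame_segments=np.asarray(meta["frame_segments"], dtype=int),
        schedule=schedule,
    )


# ---------------------------------------------------------------------------
# ASL sessions


def write_asl_session(series: _asl.ASLSeries, prefix: str | Path) -> Path:
    nii, side = _paths(prefix)
    nii.parent.mkdir(parents=True, exist_ok=True)
    nib.save(_to_nifti(series.data), str(nii))
    d = series.design
    sidecar = {
        "kind": "asl",
        "time_unit": "s",
        "n_frames": int(series.data.shape[-1]),
        "n_pairs": d.n_pairs,
        "frame_order": "label_first",
        "pair_times_s": d.pair_times().tolist(),
        "design": {
            "baseline_duration": d.baseline_duration,
            "block_duration": d.block_duration,
            "n_blocks": d.n_blocks,
            "rest_duration": d.rest_duration,
            "tr": d.tr,
        },
    }
    side.write_text(json.dumps(sidecar, indent=1))
    return nii


def read_asl_session(prefix: str | Path) -> _asl.ASLSeries:
    nii, side = _paths(prefix)
    if not side.exists():
        raise FileNotFoundError(f"missing JSON sidecar: expected {side}")
    if not nii.exists():
        raise FileNotFoundError(f"missing image file: expected {nii}")
    meta = json.loads(side.read_text())
    if meta.get("kind") != "asl":
        raise ValueError(f"sidecar {side} does not describe an ASL series")
    data = _from_nifti(nii)
    if data.shape[-1] != meta["n_frames"]:
        raise ValueError(
            f"sidecar frame count {meta['n_frames']} does not match image "
            f"frames {data.shape[-1]}"
        )
    design = _asl.StimDesign(**meta["design"])
    return _asl.ASLSeries(data=data, design=design)


# ---------------------------------------------------------------------------
# tables and maps


def write_cohort(table: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False)
    return path


def read_cohort(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path)
    required = {"rat_id", "diet", "genotype", "sex", "metric", "value"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"cohort table missing columns: {sorted(missing)}")
    return table


def write_map(image: np.ndarray, path: str | Path) -> Path:
    """Write a 2-D map (e.g. CBF, AUC, mask) as NIfTI."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(nib.Nifti1Image(np.asarray(image, dtype=np.float64), np.eye(4)), str(path))
    return path


def read_map(path: str | Path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).dataobj, dtype=np.float64)


# ---------------------------------------------------------------------------
# configuration and pipeline


@dataclass
class PipelineConfig:
    """Validated configuration of the end-to-end synthetic pipeline."""

    out_dir: str = "glucoflow_out"
    seed: int = 0
    grid_shape: tuple[int, int] = (64, 64)
    # CEST
    cest_noise_sd: float = 0.002
    uptake_amplitude: float = 0.01
    headline_offset: float = 2.9
    # ASL
    asl_noise_sd: float = 0.01
    cbf_true: float = 150.0
    response_pct: float = 0.20
    q: float = 0.05
    min_cluster: int = 4
    fwhm_mm: float = 0.55
    voxel_size_mm: float = 0.32
    # cohort
    n_per_cell: int = 6
    diet_effect: float = -0.3
    genotype_effect: float = 0.1
    sex_effect: float = 0.0
    rat_sd: float = 0.1
    residual_sd: float = 0.2

    def validate(self) -> None:
        if not 0 < self.q < 1:
            raise ValueError(f"FDR level q must be in (0, 1), got {self.q}")
        if self.min_cluster < 1:
            raise ValueError("min_cluster must be at least 1")
        if self.fwhm_mm < 0 or self.voxel_size_mm <= 0:
            raise ValueError("invalid smoothing geometry")
        if min(self.cest_noise_sd, self.asl_noise_sd) < 0:
            raise ValueError("noise SDs must be non-negative")
        if self.n_per_cell < 1:
            raise ValueError("n_per_cell must be at least 1")
        if self.cbf_true < 0:
            raise ValueError("cbf_true must be non-negative")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        text = Path(path).read_text()
        raw = yaml.safe_load(text) or {}
        unknown = set(raw) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "grid_shape" in raw:
            raw["grid_shape"] = tuple(raw["grid_shape"])
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def content_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Simulate -> quantify CEST -> quantify ASL -> group stats.

    Writes all stage outputs plus a machine-readable provenance record
    (config hash, seeds, versions) under ``config.out_dir`` and returns
    the result bundle as a dict.  Any stage failure aborts with a
    stage-named error.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle: dict = {}

    def _stage(name):
        log.info("stage %s starting", name)

    try:
        _stage("simulate_cest")
        truth_c = _sim.CESTGroundTruth(
            uptake_amplitude=config.uptake_amplitude, noise_sd=config.cest_noise_sd
        )
        cest_series, _ = _sim.simulate_cest_session(
            truth=truth_c, seed=config.seed, grid_shape=config.grid_shape
        )
        write_cest_session(cest_series, out / "cest_session")
    except Exception as e:
        raise RuntimeError(f"stage simulate_cest failed: {e}") from e

    try:
        _stage("quantify_cest")
        norm = _cest.drift_correct(cest_series)
        mtr = _cest.compute_mtr(norm)
        curve = _cest.delta_mtr(mtr, offset=config.headline_offset)
        roi = np.ones(config.grid_shape, dtype=bool)
        mean_curve, sem = _cest.roi_timecourse(curve.values, roi, mtr.valid_mask)
        roi_curve = _cest.UptakeCurve(
            values=mean_curve, times=curve.times, offset=curve.offset,
            baseline_window=curve.baseline_window, sem=sem,
        )
        summary = _cest.phase_aucs(roi_curve)
        n_invalid = int((~mtr.valid_mask).sum())
        log.info("quantify_cest: %d invalid voxels", n_invalid)
        pd.DataFrame(
            {"time_min": roi_curve.times, "delta_mtr": mean_curve, "sem": sem}
        ).to_csv(out / "cest_roi_curve.csv", index=False)
        bundle["cest"] = {**summary.as_dict(), "offset_ppm": config.headline_offset,
                          "unit": summary.unit, "n_invalid_voxels": n_invalid}
    except Exception as e:
        raise RuntimeError(f"stage quantify_cest failed: {e}") from e

    try:
        _stage("simulate_asl")
        ny, nx = config.grid_shape
        active = np.zeros(config.grid_shape, dtype=bool)
        active[ny // 4 : ny // 2, nx // 4 : 3 * nx // 4] = True
        truth_a = _sim.ASLGroundTruth(
            cbf_true=config.cbf_true,
            response_pct=config.response_pct,
            active_mask=active,
            noise_sd=config.asl_noise_sd,
        )
        asl_series, _ = _sim.simulate_asl_session(
            truth=truth_a, seed=config.seed + 1, grid_shape=config.grid_shape
        )
        write_asl_session(asl_series, out / "asl_session")
    except Exception as e:
        raise RuntimeError(f"stage simulate_asl failed: {e}") from e

    try:
        _stage("quantify_asl")
        dm, m0 = _asl.perfusion_difference(asl_series)
        with np.errstate(divide="ignore", invalid="ignore"):
            frac = dm.mean(axis=-1) / m0
        cbf_map = _asl.resting_cbf(frac)
        write_map(cbf_map.cbf, out / "cbf_map.nii.gz")
        mask = np.ones(config.grid_shape, dtype=bool)
        act = _asl.activation_summary(
            asl_series, mask, q=config.q, min_cluster=config.min_cluster,
            fwhm_mm=config.fwhm_mm, voxel_size_mm=config.voxel_size_mm,
        )
        write_map(act.sig_mask.astype(float), out / "activation_mask.nii.gz")
        write_map(act.effect, out / "activation_effect.nii.gz")
        bundle["asl"] = {
            "resting_cbf_mean": float(cbf_map.cbf[cbf_map.valid_mask].mean()),
            "area_fraction": act.area_fraction,
            "response_pct": act.response_pct,
            "n_invalid_voxels": int((~cbf_map.valid_mask).sum()),
        }
    except Exception as e:
        raise RuntimeError(f"stage quantify_asl failed: {e}") from e

    try:
        _stage("group_stats")
        spec = _sim.EffectSpec(
            intercept=1.0,
            diet_effect=config.diet_effect,
            genotype_effect=config.genotype_effect,
            sex_effect=config.sex_effect,
            rat_sd=config.rat_sd,
            residual_sd=config.residual_sd,
        )
        table = _sim.simulate_cohort(spec, config.n_per_cell, seed=config.seed + 2)
        write_cohort(table, out / "cohort.csv")
        lmm = _cohort.fit_lmm(table)
        vals = table["value"].to_numpy()
        _, sw_p, is_normal = _cohort.normality_gate(vals)
        pairs = _cohort.tukey_pairwise(table)
        bundle["group_stats"] = {
            "lmm_formula": lmm.formula,
            "lmm_converged": lmm.converged,
            "coefficients": {
                term: {"estimate": lmm.coef(term), "se": lmm.se(term)}
                for term in lmm.coefficients.index
            },
            "shapiro_p": sw_p,
            "routed_test": "tukey_hsd" if is_normal else "mann_whitney_u",
            "tukey": [dataclasses.asdict(p) for p in pairs],
        }
    except Exception as e:
        raise RuntimeError(f"stage group_stats failed: {e}") from e

    import glucoflow

    bundle["provenance"] = {
        "config": dataclasses.asdict(config),
        "config_hash": config.content_hash(),
        "seed": config.seed,
        "versions": {
            "glucoflow": glucoflow.__version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    (out / "results.json").write_text(json.dumps(bundle, indent=1, default=float))
    return bundle
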