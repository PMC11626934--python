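"""Dynamic glucose-enhanced CEST quantification.

Quantifies 2-deoxy-D-glucose (2DG) uptake from a dynamic CEST series
acquired at a small set of saturation offsets, bracketed by far-off-resonance
reference scans.  The chain is:

1. :func:`drift_correct` — per-segment linear normalization by the two
   reference scans (scanner drift removal and S0 normalization),
2. :func:`compute_mtr` — magnetization transfer ratio MTR = 1 - S/S0,
3. :func:`delta_mtr` — subtraction of the pre-injection baseline MTR,
4. :func:`uptake_auc` / :func:`phase_aucs` — trapezoidal area under the
   ΔMTR curve over the post-injection hour and its three 20-min phases.

Times are in minutes throughout; t = 0 is the onset of the 2DG infusion.
ΔMTR is a dimensionless fraction, so AUC carries units of ΔMTR·min.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SaturationSchedule",
    "CESTSeries",
    "MTRSeries",
    "UptakeCurve",
    "UptakeSummary",
    "drift_correct",
    "compute_mtr",
    "delta_mtr",
    "uptake_auc",
    "phase_aucs",
    "roi_timecourse",
    "center_kspace_saturation",
]


@dataclass(frozen=True)
class SaturationSchedule:
    """Timed saturation-offset acquisition plan for one dynamic CEST session.

    The default reproduces a 20.7-min segment consisting of a reference scan
    at 667 ppm, 12 repetitions of a three-offset block (1.2, 2.0, 2.9 ppm),
    and a closing 667 ppm reference; the segment is acquired four times —
    once during baseline, three times over the post-injection hour.

    Parameters
    ----------
    baseline_duration : float
        Nominal pre-injection acquisition span, minutes.
    n_segments : int
        Number of repeated segments (first one is baseline).
    reps_per_offset_per_segment : int
        Offset-block repetitions inside one segment.
    offsets : tuple of float
        Saturation offsets probed, ppm from water.
    reference_offset : float
        Far off-resonance reference offset, ppm (effectively unsaturated).
    segment_duration : float
        Wall-clock duration of one segment, minutes.
    injection_time : float
        Infusion onset on the session clock, minutes; the time axis is
        shifted so this instant is t = 0.
    saturation_amplitude_ut, saturation_pulse_ms, matrix_size
        Acquisition metadata (1.5 μT, 490 ms per k-space line, 64 lines);
        not used by the quantification chain itself.
    """

    baseline_duration: float = 20.0
    n_segments: int = 4
    reps_per_offset_per_segment: int = 12
    offsets: tuple[float, ...] = (1.2, 2.0, 2.9)
    reference_offset: float = 667.0
    segment_duration: float = 20.7
    injection_time: float = 20.7
    saturation_amplitude_ut: float = 1.5
    saturation_pulse_ms: float = 490.0
    matrix_size: int = 64

    def __post_init__(self) -> None:
        if self.n_segments < 1:
            raise ValueError("schedule needs at least one segment")
        if self.reps_per_offset_per_segment < 1:
            raise ValueError("schedule needs at least one repetition per offset")
        if not self.offsets:
            raise ValueError("schedule needs at least one saturation offset")
        if self.segment_duration <= 0:
            raise ValueError("segment_duration must be positive")

    @property
    def frames_per_segment(self) -> int:
        """One leading + one trailing reference plus the offset blocks."""
        return 2 + len(self.offsets) * self.reps_per_offset_per_segment

    @property
    def n_frames(self) -> int:
        return self.frames_per_segment * self.n_segments

    def samples_per_offset(self) -> int:
        """Total number of acquisitions at each saturation offset."""
        return self.reps_per_offset_per_segment * self.n_segments

    def frame_table(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-frame (time_min, offset_ppm, segment_index).

        Frames sit at the centers of equal acquisition slots within each
        segment; segment k spans ``[k*segment_duration - injection_time,
        (k+1)*segment_duration - injection_time]`` so that the baseline
        segment ends at t = 0.  Reference frames occupy the first and last
        slot of every segment.
        """
        fps = self.frames_per_segment
        times = np.empty(self.n_frames)
        offs = np.empty(self.n_frames)
        segs = np.empty(self.n_frames, dtype=int)
        block = np.tile(self.offsets, self.reps_per_offset_per_segment)
        seg_offsets = np.concatenate(
            ([self.reference_offset], block, [self.reference_offset])
        )
        rel = (np.arange(fps) + 0.5) * (self.segment_duration / fps)
        for k in range(self.n_segments):
            sl = slice(k * fps, (k + 1) * fps)
            times[sl] = k * self.segment_duration - self.injection_time + rel
            offs[sl] = seg_offsets
            segs[sl] = k
        return times, offs, segs


@dataclass
class CESTSeries:
    """Voxel × time CEST image stack with per-frame acquisition labels."""

    data: np.ndarray  # (ny, nx, n_frames)
    frame_times: np.ndarray  # minutes, t=0 at injection onset
    frame_offsets: np.ndarray  # ppm
    frame_segments: np.ndarray  # segment index per frame
    schedule: SaturationSchedule
    valid_mask: np.ndarray | None = None  # voxels with usable references

    def __post_init__(self) -> None:
        n = self.data.shape[-1]
        if not (len(self.frame_times) == len(self.frame_offsets) == len(self.frame_segments) == n):
            raise ValueError("frame labels inconsistent with image frame count")
        if np.any(np.diff(self.frame_times) <= 0):
            raise ValueError("frame times must be strictly increasing")
        if self.valid_mask is None:
            self.valid_mask = np.ones(self.data.shape[:-1], dtype=bool)

    @property
    def grid_shape(self) -> tuple[int, ...]:
        return self.data.shape[:-1]

    def is_reference(self) -> np.ndarray:
        return np.isclose(self.frame_offsets, self.schedule.reference_offset)


@dataclass
class MTRSeries:
    """Per-voxel, per-offset magnetization transfer ratio time courses.

    ``data[offset]`` is (ny, nx, n_samples) aligned with ``times[offset]``.
    """

    data: dict[float, np.ndarray]
    times: dict[float, np.ndarray]
    valid_mask: np.ndarray
    schedule: SaturationSchedule


@dataclass
class UptakeCurve:
    """ΔMTR time course at one offset (voxelwise or ROI-averaged)."""

    values: np.ndarray  # (..., n_samples)
    times: np.ndarray  # minutes
    offset: float
    baseline_window: tuple[float, float]
    sem: np.ndarray | None = None  # set for ROI curves


@dataclass(frozen=True)
class UptakeSummary:
    """Total and per-phase areas under the ΔMTR curve, in ΔMTR·min."""

    auc_total: float
    auc_initial: float
    auc_peak: float
    auc_washout: float
    offset: float = 2.9
    unit: str = "dMTR*min"

    def as_dict(self) -> dict[str, float]:
        return {
            "auc_total": self.auc_total,
            "auc_initial": self.auc_initial,
            "auc_peak": self.auc_peak,
            "auc_washout": self.auc_washout,
        }


# ---------------------------------------------------------------------------
# drift correction and MTR


def drift_correct(series: CESTSeries) -> CESTSeries:
    """Normalize each segment by the line through its two reference scans.

    A straight line is fitted voxelwise through the initial and final
    reference frames of every segment, evaluated at each sample time, and
    every frame is divided by it.  This removes scanner drift (exactly, for
    any per-segment linear multiplicative drift) and expresses the signal
    as the dimensionless ratio S/S0.  Reference frames are dropped from the
    output.  Voxels whose interpolated reference is not strictly positive
    anywhere are flagged invalid rather than raising.
    """
    is_ref = series.is_reference()
    data = series.data
    out_frames = ~is_ref
    norm = np.empty_like(data[..., out_frames], dtype=float)
    valid = series.valid_mask.copy()

    col = 0
    for k in range(int(series.frame_segments.max()) + 1):
        in_seg = series.frame_segments == k
        ref_idx = np.flatnonzero(in_seg & is_ref)
        if len(ref_idx) != 2:
            raise ValueError(
                f"segment {k} must have exactly one leading and one trailing "
                f"reference frame, found {len(ref_idx)}"
            )
        i0, i1 = ref_idx
        if not (i0 == np.flatnonzero(in_seg)[0] and i1 == np.flatnonzero(in_seg)[-1]):
            raise ValueError(f"segment {k} references must bracket the segment")
        t0, t1 = series.frame_times[i0], series.frame_times[i1]
        r0, r1 = data[..., i0], data[..., i1]
        slope = (r1 - r0) / (t1 - t0)
        samp_idx = np.flatnonzero(in_seg & ~is_ref)
        t = series.frame_times[samp_idx]
        # (ny, nx, n_samples) interpolated reference
        ref_line = r0[..., None] + slope[..., None] * (t - t0)
        valid &= np.all(ref_line > 0, axis=-1)
        with np.errstate(divide="ignore", invalid="ignore"):
            norm[..., col : col + len(samp_idx)] = data[..., samp_idx] / ref_line
        col += len(samp_idx)

    return CESTSeries(
        data=norm,
        frame_times=series.frame_times[out_frames],
        frame_offsets=series.frame_offsets[out_frames],
        frame_segments=series.frame_segments[out_frames],
        schedule=series.schedule,
        valid_mask=valid,
    )


def compute_mtr(normalized: CESTSeries) -> MTRSeries:
    """MTR = 1 - S/S0 per voxel, offset and time.

    Expects a drift-corrected series (signal already divided by the
    interpolated reference), split into one time course per offset.
    """
    data: dict[float, np.ndarray] = {}
    times: dict[float, np.ndarray] = {}
    for off in normalized.schedule.offsets:
        sel = np.isclose(normalized.frame_offsets, off)
        data[off] = 1.0 - normalized.data[..., sel]
        times[off] = normalized.frame_times[sel]
    return MTRSeries(
        data=data,
        times=times,
        valid_mask=normalized.valid_mask.copy(),
        schedule=normalized.schedule,
    )


def delta_mtr(
    mtr: MTRSeries,
    offset: float = 2.9,
    baseline_window: tuple[float, float] | None = None,
) -> UptakeCurve:
    """ΔMTR = MTR - mean MTR over the pre-injection baseline window.

    The default window is the whole baseline segment (all samples with
    t < 0).  The baseline samples of the output average to zero by
    construction.
    """
    if offset not in mtr.data:
        raise KeyError(f"offset {offset} ppm not present in MTR series")
    t = mtr.times[offset]
    if baseline_window is None:
        baseline_window = (float(t[0]), 0.0)
    lo, hi = baseline_window
    in_base = (t >= lo) & (t < hi)
    if in_base.sum() < 2:
        raise ValueError("baseline window must contain at least 2 samples")
    vals = mtr.data[offset]
    base = vals[..., in_base].mean(axis=-1, keepdims=True)
    return UptakeCurve(
        values=vals - base,
        times=t,
        offset=offset,
        baseline_window=(lo, hi),
    )


# ---------------------------------------------------------------------------
# areas under the curve


def _snap(t: np.ndarray, edge: float) -> float:
    """Nearest sample time to a nominal window edge."""
    return float(t[np.argmin(np.abs(t - edge))])


def uptake_auc(
    curve: UptakeCurve,
    window: tuple[float, float] = (0.0, 60.0),
    snap_to_samples: bool = True,
) -> np.ndarray | float:
    """Trapezoidal integral of ΔMTR over a time window, in ΔMTR·min.

    Window edges are snapped to the nearest sample times (shared convention
    with :func:`phase_aucs`, which makes phase AUCs a partition of the
    total).
    """
    t = curve.times
    lo, hi = window
    if snap_to_samples:
        lo, hi = _snap(t, lo), _snap(t, hi)
    if lo < t[0] - 1e-9 or hi > t[-1] + 1e-9:
        raise ValueError(f"window [{lo}, {hi}] outside sampled range [{t[0]}, {t[-1]}]")
    sel = (t >= lo - 1e-9) & (t <= hi + 1e-9)
    if sel.sum() < 2:
        raise ValueError("window must contain at least 2 samples")
    auc = np.trapezoid(curve.values[..., sel], t[sel], axis=-1)
    return float(auc) if np.ndim(auc) == 0 else auc


def phase_aucs(
    curve: UptakeCurve,
    phase_duration: float = 20.0,
    n_phases: int = 3,
) -> UptakeSummary:
    """AUC over the post-injection hour and its three 20-min phases.

    Phases are fixed windows [0,20], [20,40], [40,60] min after injection
    onset (initial uptake, peak uptake, washout); boundaries are snapped to
    the nearest sample time, identically for the phase and total integrals,
    so the phases sum to the total.
    """
    t = curve.times
    span = n_phases * phase_duration
    dt = (t[-1] - t[0]) / (len(t) - 1)  # mean sample spacing
    if t[-1] < span - dt:
        raise ValueError(
            f"post-injection span {t[-1]:.1f} min is insufficient for "
            f"{n_phases} phases of {phase_duration} min"
        )
    if curve.values.ndim != 1:
        raise ValueError("phase_aucs expects a 1-D (ROI or single-voxel) curve")
    edges = [_snap(t, k * phase_duration) for k in range(n_phases + 1)]
    if len(set(edges)) != n_phases + 1:
        raise ValueError("sampling too sparse: phase edges collapse")
    phases = [
        uptake_auc(curve, (edges[k], edges[k + 1]), snap_to_samples=False)
        for k in range(n_phases)
    ]
    total = uptake_auc(curve, (edges[0], edges[-1]), snap_to_samples=False)
    return UptakeSummary(
        auc_total=float(total),
        auc_initial=float(phases[0]),
        auc_peak=float(phases[1]),
        auc_washout=float(phases[2]),
        offset=curve.offset,
    )


def roi_timecourse(
    curve_values: np.ndarray,
    mask: np.ndarray,
    valid_mask: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-time-point mean and SEM over in-mask valid voxels.

    ``curve_values`` is (ny, nx, n_samples); returns (mean, sem), each of
    length n_samples.  A single-voxel ROI has SEM 0 by convention.
    """
    mask = np.asarray(mask, dtype=bool)
    if valid_mask is not None:
        mask = mask & valid_mask
    n = int(mask.sum())
    if n == 0:
        raise ValueError("ROI mask is empty (or all voxels invalid)")
    vox = curve_values[mask]  # (n, n_samples)
    mean = vox.mean(axis=0)
    if n == 1:
        sem = np.zeros_like(mean)
    else:
        sem = vox.std(axis=0, ddof=1) / np.sqrt(n)
    return mean, sem


def center_kspace_saturation(schedule: SaturationSchedule) -> float:
    """Cumulative saturation time (s) at acquisition of the k-space center.

    With one saturation pulse per k-space line and linear encoding, the
    center line is reached after matrix_size/2 pulses.
    """
    return schedule.saturation_pulse_ms / 1000.0 * schedule.matrix_size / 2.0
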