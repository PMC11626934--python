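"""pCASL perfusion quantification and stimulation-evoked activation mapping.

Resting cerebral blood flow (CBF) is quantified from the baseline window of
an interleaved label/control pCASL series with the standard single-
compartment, single post-labeling-delay closed form::

    CBF = 6000 * lambda * (dM/M0) * R1a * exp(w * R1a)
          / (2 * alpha * (1 - exp(-tau * R1a)))      [ml/100g/min]

where dM = control - label, M0 is the mean control signal, lambda is the
blood-brain water partition coefficient, R1a the longitudinal relaxation
rate of arterial blood, alpha the labeling efficiency, tau the labeling
duration and w the post-labeling delay.  The factor 6000 converts
ml/g/s to ml/100g/min.

Functional hyperemia is mapped by ordinary least squares of the perfusion-
weighted (control - label) signal on [intercept, linear drift, stimulus
boxcar], thresholded by Benjamini-Hochberg FDR and a minimum cluster
extent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "PerfusionParams",
    "StimDesign",
    "ASLSeries",
    "CBFMap",
    "ActivationResult",
    "perfusion_difference",
    "resting_cbf",
    "cbf_to_fractional_difference",
    "gaussian_smooth",
    "glm_activation",
    "bh_fdr",
    "cluster_filter",
    "activation_summary",
]


@dataclass(frozen=True)
class PerfusionParams:
    """Constants of the single-compartment pCASL quantification model.

    lam : blood-brain water partition coefficient, mL/g.
    r1a : longitudinal relaxation rate of arterial blood, 1/s
          (0.45 1/s corresponds to blood T1 of about 2.2 s at 7 T).
    alpha : labeling efficiency (inversion fraction achieved).
    tau : labeling duration, s.
    w : post-labeling delay, s.
    """

    lam: float = 0.9
    r1a: float = 0.45
    alpha: float = 0.85
    tau: float = 2.0
    w: float = 0.35

    def __post_init__(self) -> None:
        if min(self.lam, self.r1a, self.alpha, self.tau, self.w) <= 0:
            raise ValueError("all perfusion parameters must be strictly positive")
        if self.alpha > 1:
            raise ValueError("labeling efficiency alpha cannot exceed 1")

    def scale(self) -> float:
        """ml/100g/min of CBF per unit of fractional difference dM/M0."""
        return (
            6000.0
            * self.lam
            * self.r1a
            * np.exp(self.w * self.r1a)
            / (2.0 * self.alpha * (1.0 - np.exp(-self.tau * self.r1a)))
        )


@dataclass(frozen=True)
class StimDesign:
    """Block paradigm: baseline, then stimulation blocks separated by rests.

    Default: 4 min baseline followed by three cycles of 2-min bilateral
    forepaw stimulation + 4-min rest — 22 min, i.e. 264 label/control
    pairs at 5 s per pair (TR 2.5 s per image).  The stimulation current/
    pulse parameters are metadata only.
    """

    baseline_duration: float = 4.0  # min
    block_duration: float = 2.0  # min
    n_blocks: int = 3
    rest_duration: float = 4.0  # min, after each block
    tr: float = 2.5  # s per image; one pair = 2*tr
    stim_metadata: tuple[str, ...] = ("10 mA", "0.3 ms", "3 Hz")

    def __post_init__(self) -> None:
        if self.n_blocks < 1 or self.block_duration <= 0 or self.tr <= 0:
            raise ValueError("invalid stimulation design")

    @property
    def total_duration(self) -> float:
        """Total paradigm duration in minutes."""
        return self.baseline_duration + self.n_blocks * (
            self.block_duration + self.rest_duration
        )

    @property
    def n_pairs(self) -> int:
        pair_min = 2.0 * self.tr / 60.0
        n = self.total_duration / pair_min
        if abs(n - round(n)) > 1e-9:
            raise ValueError("design duration is not a whole number of pairs")
        return int(round(n))

    def pair_times(self) -> np.ndarray:
        """Midpoint time of each label/control pair, seconds."""
        pair_s = 2.0 * self.tr
        return (np.arange(self.n_pairs) + 0.5) * pair_s

    def boxcar(self) -> np.ndarray:
        """Stimulus regressor (1 inside stimulation blocks) per pair."""
        t_min = self.pair_times() / 60.0
        box = np.zeros(self.n_pairs)
        start = self.baseline_duration
        for _ in range(self.n_blocks):
            box[(t_min >= start) & (t_min < start + self.block_duration)] = 1.0
            start += self.block_duration + self.rest_duration
        return box


@dataclass
class ASLSeries:
    """Interleaved label/control EPI pairs (label first within each pair)."""

    data: np.ndarray  # (ny, nx, 2*n_pairs)
    design: StimDesign

    def __post_init__(self) -> None:
        if self.data.shape[-1] != 2 * self.design.n_pairs:
            raise ValueError(
                f"series has {self.data.shape[-1]} frames; design requires "
                f"{2 * self.design.n_pairs} (label+control per pair)"
            )

    @property
    def n_pairs(self) -> int:
        return self.design.n_pairs

    @property
    def labels(self) -> np.ndarray:
        return self.data[..., 0::2]

    @property
    def controls(self) -> np.ndarray:
        return self.data[..., 1::2]


@dataclass
class CBFMap:
    """Per-voxel perfusion in ml/100g/min with a validity mask."""

    cbf: np.ndarray
    valid_mask: np.ndarray
    unit: str = "ml/100g/min"


@dataclass
class ActivationResult:
    """Voxelwise GLM output and the thresholded activation summary.

    effect is the fractional perfusion change during stimulation relative
    to baseline perfusion; response_pct its in-mask mean times 100.
    area_fraction is |significant| / |analysis mask|; response_pct is NaN
    when nothing survives thresholding.
    """

    effect: np.ndarray
    tstat: np.ndarray
    pvalue: np.ndarray
    sig_mask: np.ndarray
    analysis_mask: np.ndarray
    area_fraction: float
    response_pct: float
    q: float
    min_cluster: int


# ---------------------------------------------------------------------------
# perfusion quantification


def perfusion_difference(
    series: ASLSeries,
    window: tuple[float, float] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Pairwise control-label difference and mean control (M0) image.

    ``window`` is (start, end) in minutes over pair midpoints; the default
    is the pre-stimulation baseline.  Returns (dM, M0) with dM of shape
    (ny, nx, n_pairs_in_window).
    """
    t_min = series.design.pair_times() / 60.0
    if window is None:
        window = (0.0, series.design.baseline_duration)
    lo, hi = window
    sel = (t_min >= lo) & (t_min < hi)
    if not sel.any():
        raise ValueError(f"window [{lo}, {hi}] min contains no label/control pairs")
    dm = series.controls[..., sel] - series.labels[..., sel]
    m0 = series.controls[..., sel].mean(axis=-1)
    return dm, m0


def resting_cbf(
    dm_over_m0: np.ndarray,
    params: PerfusionParams = PerfusionParams(),
    warn_threshold: float = 0.2,
) -> CBFMap:
    """Closed-form single-compartment CBF from the fractional difference.

    ``dm_over_m0`` may be a mean fractional-difference image or any array;
    non-finite entries (e.g. from division by non-positive M0) are marked
    invalid.  Fractional differences beyond ``warn_threshold`` violate the
    small-signal assumption and are flagged invalid as well.
    """
    frac = np.asarray(dm_over_m0, dtype=float)
    valid = np.isfinite(frac) & (np.abs(frac) <= warn_threshold)
    cbf = np.where(np.isfinite(frac), frac, 0.0) * params.scale()
    return CBFMap(cbf=cbf, valid_mask=valid)


def cbf_to_fractional_difference(
    cbf: np.ndarray | float,
    params: PerfusionParams = PerfusionParams(),
) -> np.ndarray | float:
    """Inverse of :func:`resting_cbf`: dM/M0 producing a given CBF."""
    return np.asarray(cbf, dtype=float) / params.scale()


def gaussian_smooth(
    image: np.ndarray,
    fwhm_mm: float,
    voxel_size_mm: float,
) -> np.ndarray:
    """Per-frame in-plane Gaussian smoothing at a fixed FWHM.

    sigma = FWHM / (2*sqrt(2*ln 2)); FWHM 0 is the identity.  For stacks
    the last axis is treated as time and left unsmoothed.
    """
    if voxel_size_mm <= 0:
        raise ValueError("voxel size must be positive")
    if fwhm_mm < 0:
        raise ValueError("FWHM must be non-negative")
    if fwhm_mm == 0:
        return np.asarray(image, dtype=float).copy()
    sigma_vox = fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / voxel_size_mm
    img = np.asarray(image, dtype=float)
    sigma = (sigma_vox, sigma_vox) + (0.0,) * (img.ndim - 2)
    return ndimage.gaussian_filter(img, sigma=sigma)


# ---------------------------------------------------------------------------
# activation mapping


def glm_activation(
    series: ASLSeries,
    mask: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Voxelwise OLS of the perfusion-weighted signal on the block design.

    The running control-label difference, assigned to pair midpoints, is
    normalized by its voxelwise baseline mean so the stimulus coefficient
    is directly the fractional perfusion change.  Regressors: intercept,
    centered linear drift, and the unconvolved stimulus boxcar.  Returns
    (effect, t, p) images; out-of-mask or zero-baseline voxels carry
    effect 0, t 0, p 1.
    """
    design = series.design
    t_s = design.pair_times()
    box = design.boxcar()
    drift = (t_s - t_s.mean()) / t_s.std()
    X = np.column_stack([np.ones_like(t_s), drift, box])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient design matrix")

    dm = series.controls - series.labels  # (ny, nx, n_pairs)
    base_sel = box == 0
    base_sel &= t_s / 60.0 < design.baseline_duration
    base = dm[..., base_sel].mean(axis=-1)

    ny, nx = dm.shape[:2]
    if mask is None:
        mask = np.ones((ny, nx), dtype=bool)
    usable = mask & (np.abs(base) > np.finfo(float).tiny)

    effect = np.zeros((ny, nx))
    tstat = np.zeros((ny, nx))
    pval = np.ones((ny, nx))

    y = dm[usable] / base[usable][:, None]  # (n_vox, n_pairs)
    if y.shape[0]:
        pinv = np.linalg.pinv(X)
        beta = y @ pinv.T  # (n_vox, 3)
        resid = y - beta @ X.T
        dof = X.shape[0] - X.shape[1]
        s2 = (resid**2).sum(axis=1) / dof
        cov_box = np.linalg.inv(X.T @ X)[2, 2]
        se = np.sqrt(s2 * cov_box)
        with np.errstate(divide="ignore", invalid="ignore"):
            tv = np.where(se > 0, beta[:, 2] / se, 0.0)
        pv = 2.0 * stats.t.sf(np.abs(tv), dof)
        pv = np.where(se > 0, pv, np.where(np.abs(beta[:, 2]) > 0, 0.0, 1.0))
        effect[usable] = beta[:, 2]
        tstat[usable] = tv
        pval[usable] = pv
    return effect, tstat, pval


def bh_fdr(pvalues: np.ndarray, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection set at FDR level q."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value array")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if not 0 < q < 1:
        raise ValueError("q must lie in (0, 1)")
    reject, *_ = multipletests(p.ravel(), alpha=q, method="fdr_bh")
    return reject.reshape(p.shape)


def cluster_filter(
    mask: np.ndarray,
    min_size: int = 4,
    connectivity: int = 4,
) -> np.ndarray:
    """Remove connected components smaller than ``min_size`` voxels.

    ``connectivity`` is 4 (edge-sharing neighbours, default) or 8
    (edges + diagonals) in 2-D.  Idempotent.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim != 2:
        raise ValueError("cluster_filter expects a 2-D mask")
    if connectivity == 4:
        structure = ndimage.generate_binary_structure(2, 1)
    elif connectivity == 8:
        structure = ndimage.generate_binary_structure(2, 2)
    else:
        raise ValueError("connectivity must be 4 or 8")
    labels, n = ndimage.label(mask, structure=structure)
    if n == 0:
        return mask.copy()
    sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
    keep = np.flatnonzero(sizes >= min_size) + 1
    return np.isin(labels, keep)


def activation_summary(
    series: ASLSeries,
    mask: np.ndarray,
    q: float = 0.05,
    min_cluster: int = 4,
    connectivity: int = 4,
    fwhm_mm: float = 0.0,
    voxel_size_mm: float = 0.32,
) -> ActivationResult:
    """Full activation analysis: (smooth) -> GLM -> BH-FDR -> cluster filter.

    area_fraction = significant voxels / analysis-mask voxels;
    response_pct = 100 * mean fractional effect over significant voxels
    (NaN if none survive).
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty analysis mask")
    if fwhm_mm > 0:
        series = ASLSeries(
            data=gaussian_smooth(series.data, fwhm_mm, voxel_size_mm),
            design=series.design,
        )
    effect, tstat, pval = glm_activation(series, mask)
    reject = np.zeros_like(mask)
    reject[mask] = bh_fdr(pval[mask], q=q)
    sig = cluster_filter(reject, min_size=min_cluster, connectivity=connectivity)
    area_fraction = float(sig.sum() / mask.sum())
    response_pct = float(100.0 * effect[sig].mean()) if sig.any() else float("nan")
    return ActivationResult(
        effect=effect,
        tstat=tstat,
        pvalue=pval,
        sig_mask=sig,
        analysis_mask=mask,
        area_fraction=area_fraction,
        response_pct=response_pct,
        q=q,
        min_cluster=min_cluster,
    )
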