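"""Synthetic scanner: CEST sessions, pCASL sessions and cohort tables.

Generates inputs with the statistical structure the quantification chain
assumes, carrying the ground truth used by parameter-recovery tests:

* :func:`simulate_cest_session` — dynamic CEST series whose reference scans
  carry a linear scanner drift and whose offset images follow
  ``S0 * (1 + drift*t) * (1 - MTR(t))`` with a gamma-variate 2DG uptake
  curve added to the baseline MTR after injection;
* :func:`simulate_asl_session` — interleaved label/control pairs with the
  label decrement given by the inverse of the single-compartment CBF model,
  scaled up inside stimulation blocks for active voxels;
* :func:`simulate_cohort` — balanced diet x genotype x sex cohort tables
  with per-rat random intercepts, for the mixed-model and pairwise-test
  machinery.

Noise is additive i.i.d. Gaussian on image intensities (at the SNR regime
of magnitude MRI where the Rician distribution is effectively Gaussian).
Every operation takes an explicit integer seed; no global random state is
used or mutated.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .asl import ASLSeries, PerfusionParams, StimDesign, cbf_to_fractional_difference
from .cest import CESTSeries, SaturationSchedule

__all__ = [
    "CESTGroundTruth",
    "ASLGroundTruth",
    "EffectSpec",
    "gamma_variate",
    "simulate_cest_session",
    "simulate_asl_session",
    "simulate_cohort",
]

DIETS = ("CHOW", "HCHF")
GENOTYPES = ("nTg", "TgAD")
SEXES = ("M", "F")


@dataclass(frozen=True)
class CESTGroundTruth:
    """Generating parameters of a synthetic dynamic CEST session.

    The uptake curve is a gamma-variate in the time since injection:
    rise-then-washout, peaking near 25 min post-injection with the
    defaults, emulating hippocampal 2DG uptake dynamics.

    uptake_amplitude : peak ΔMTR (dimensionless fraction of S0).
    uptake_onset : minutes from injection to uptake start.
    rise_rate, decay_rate : 1/min; their ratio sets the gamma shape and
        ``onset + (rise/decay)/decay`` is the peak time.
    drift_slope : fractional signal change per minute (linear scanner drift).
    noise_sd : additive Gaussian noise SD as a fraction of S0.
    baseline_mtr : pre-injection MTR at the probed offsets.
    s0 : unsaturated signal amplitude (arbitrary units).
    """

    uptake_amplitude: float = 0.01
    uptake_onset: float = 1.0
    rise_rate: float = 0.06
    decay_rate: float = 0.05
    drift_slope: float = -0.0005
    noise_sd: float = 0.002
    baseline_mtr: float = 0.05
    s0: float = 1.0

    def __post_init__(self) -> None:
        if self.uptake_amplitude < 0:
            raise ValueError("uptake amplitude must be non-negative")
        if self.rise_rate <= 0 or self.decay_rate <= 0:
            raise ValueError("rise and decay rates must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise SD must be non-negative")

    def delta_mtr_true(self, t_min: np.ndarray) -> np.ndarray:
        """Generating ΔMTR curve at times ``t_min`` (minutes, 0=injection)."""
        return gamma_variate(
            np.asarray(t_min, dtype=float),
            amplitude=self.uptake_amplitude,
            onset=self.uptake_onset,
            rise_rate=self.rise_rate,
            decay_rate=self.decay_rate,
        )


def gamma_variate(
    t: np.ndarray,
    amplitude: float,
    onset: float,
    rise_rate: float,
    decay_rate: float,
) -> np.ndarray:
    """Gamma-variate bolus curve, peak value ``amplitude``.

    With shape a = rise_rate/decay_rate and rate b = decay_rate::

        y(t) = A * (b*(t-t0)/a)^a * exp(a - b*(t-t0)),   t > t0

    which peaks (value A) at t0 + a/b and is 0 for t <= t0.
    """
    t = np.asarray(t, dtype=float)
    a = rise_rate / decay_rate
    u = np.clip(t - onset, 0.0, None)
    with np.errstate(invalid="ignore"):
        y = amplitude * (decay_rate * u / a) ** a * np.exp(a - decay_rate * u)
    return np.where(u > 0, y, 0.0)


@dataclass
class ASLGroundTruth:
    """Generating parameters of a synthetic pCASL session.

    cbf_true : resting perfusion, ml/100g/min (scalar or (ny, nx) map).
    response_pct : fractional CBF increase during stimulation in active
        voxels (0.20 = +20%).
    active_mask : boolean (ny, nx) image of responding voxels (None: no
        voxel responds).
    noise_sd : additive Gaussian noise SD as a fraction of M0.
    m0 : equilibrium (control) signal amplitude.
    """

    cbf_true: float | np.ndarray = 150.0
    response_pct: float = 0.20
    active_mask: np.ndarray | None = None
    noise_sd: float = 0.01
    m0: float = 1.0

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.cbf_true) < 0):
            raise ValueError("cbf_true must be non-negative")
        if self.response_pct < -1:
            raise ValueError("response_pct below -1 would invert perfusion")
        if self.noise_sd < 0:
            raise ValueError("noise SD must be non-negative")


@dataclass(frozen=True)
class EffectSpec:
    """Fixed-effect and variance structure of a synthetic cohort metric.

    Coefficients are on indicator coding: diet_effect applies to HCHF,
    genotype_effect to TgAD, sex_effect to F, each relative to the
    reference cell (CHOW, nTg, M).  ``interactions`` maps tuples of factor
    levels, e.g. ("HCHF", "TgAD"), to an extra additive coefficient.
    """

    intercept: float = 0.0
    diet_effect: float = 0.0
    genotype_effect: float = 0.0
    sex_effect: float = 0.0
    interactions: tuple[tuple[tuple[str, ...], float], ...] = ()
    rat_sd: float = 0.0
    residual_sd: float = 1.0

    def __post_init__(self) -> None:
        if self.rat_sd < 0 or self.residual_sd < 0:
            raise ValueError("SDs must be non-negative")
        known = set(DIETS) | set(GENOTYPES) | set(SEXES)
        for levels, _ in self.interactions:
            for lev in levels:
                if lev not in known:
                    raise ValueError(f"unknown factor level {lev!r} in interaction")

    def cell_mean(self, diet: str, genotype: str, sex: str) -> float:
        mu = self.intercept
        mu += self.diet_effect if diet == "HCHF" else 0.0
        mu += self.genotype_effect if genotype == "TgAD" else 0.0
        mu += self.sex_effect if sex == "F" else 0.0
        cell = {diet, genotype, sex}
        for levels, coef in self.interactions:
            if set(levels) <= cell:
                mu += coef
        return mu


# ---------------------------------------------------------------------------
# generators


def simulate_cest_session(
    schedule: SaturationSchedule | None = None,
    truth: CESTGroundTruth | None = None,
    seed: int = 0,
    grid_shape: tuple[int, int] = (64, 64),
) -> tuple[CESTSeries, CESTGroundTruth]:
    """Dynamic CEST series with known uptake, drift and noise.

    Reference frames carry ``s0 * (1 + drift_slope * t)``; offset frames
    carry the same drifting S0 times ``1 - MTR(t)`` with
    ``MTR(t) = baseline_mtr + ΔMTR_true(t)`` (identical at every probed
    offset), plus additive Gaussian noise.  Identical seeds give bitwise-
    identical output.
    """
    schedule = schedule or SaturationSchedule()
    truth = truth or CESTGroundTruth()
    rng = np.random.default_rng(seed)
    times, offs, segs = schedule.frame_table()
    is_ref = np.isclose(offs, schedule.reference_offset)

    s0_t = truth.s0 * (1.0 + truth.drift_slope * times)
    mtr_t = truth.baseline_mtr + truth.delta_mtr_true(times)
    frame_vals = np.where(is_ref, s0_t, s0_t * (1.0 - mtr_t))

    data = np.broadcast_to(frame_vals, grid_shape + (len(times),)).astype(float).copy()
    if truth.noise_sd > 0:
        data += rng.normal(0.0, truth.noise_sd * truth.s0, size=data.shape)
    series = CESTSeries(
        data=data,
        frame_times=times,
        frame_offsets=offs,
        frame_segments=segs,
        schedule=schedule,
    )
    return series, truth


def simulate_asl_session(
    design: StimDesign | None = None,
    truth: ASLGroundTruth | None = None,
    params: PerfusionParams | None = None,
    seed: int = 0,
    grid_shape: tuple[int, int] = (64, 64),
) -> tuple[ASLSeries, ASLGroundTruth]:
    """Interleaved label/control pCASL series with known CBF and response.

    Control images are ``m0`` plus noise; label images are the control
    (noise-free part) minus ΔM, where ΔM inverts the closed-form CBF model
    at ``cbf_true`` and is scaled by ``1 + response_pct`` inside
    stimulation blocks for voxels in ``active_mask``.
    """
    design = design or StimDesign()
    truth = truth or ASLGroundTruth()
    params = params or PerfusionParams()
    rng = np.random.default_rng(seed)

    n_pairs = design.n_pairs
    cbf = np.broadcast_to(np.asarray(truth.cbf_true, dtype=float), grid_shape)
    dm_rest = truth.m0 * np.asarray(cbf_to_fractional_difference(cbf, params))

    box = design.boxcar()  # (n_pairs,)
    active = (
        np.zeros(grid_shape, dtype=bool)
        if truth.active_mask is None
        else np.asarray(truth.active_mask, dtype=bool)
    )
    if active.shape != tuple(grid_shape):
        raise ValueError("active_mask shape does not match the image grid")
    gain = 1.0 + truth.response_pct * (active[..., None] & (box > 0))
    dm = dm_rest[..., None] * gain  # (ny, nx, n_pairs)

    data = np.empty(grid_shape + (2 * n_pairs,))
    data[..., 0::2] = truth.m0 - dm  # label
    data[..., 1::2] = truth.m0  # control
    if truth.noise_sd > 0:
        data += rng.normal(0.0, truth.noise_sd * truth.m0, size=data.shape)
    return ASLSeries(data=data, design=design), truth


def simulate_cohort(
    spec: EffectSpec,
    n_per_cell: int,
    seed: int = 0,
    metric: str = "auc_2p9",
    ages: tuple[float, ...] = (12.0,),
    n_reps: int = 1,
) -> pd.DataFrame:
    """Balanced diet x genotype x sex cohort table with per-rat intercepts.

    Each of the 8 cells receives ``n_per_cell`` rats; each rat contributes
    ``n_reps`` records per age with value = cell mean + rat intercept +
    residual noise.  Returns the long-format table used by the group-stats
    module (columns rat_id, age, diet, genotype, sex, metric, value).
    """
    if n_per_cell < 1:
        raise ValueError("n_per_cell must be at least 1")
    rng = np.random.default_rng(seed)
    rows = []
    rat = 0
    for diet, geno, sex in itertools.product(DIETS, GENOTYPES, SEXES):
        mu = spec.cell_mean(diet, geno, sex)
        for _ in range(n_per_cell):
            rat += 1
            intercept = rng.normal(0.0, spec.rat_sd) if spec.rat_sd > 0 else 0.0
            for age in ages:
                for _ in range(n_reps):
                    eps = rng.normal(0.0, spec.residual_sd) if spec.residual_sd > 0 else 0.0
                    rows.append(
                        {
                            "rat_id": f"rat{rat:04d}",
                            "age": age,
                            "diet": diet,
                            "genotype": geno,
                            "sex": sex,
                            "metric": metric,
                            "value": mu + intercept + eps,
                        }
                    )
    return pd.DataFrame(rows)
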