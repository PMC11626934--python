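"""Cohort-level inference on per-animal summary metrics.

Per-animal metrics (glucose-uptake AUC, resting CBF, activation area and
amplitude) are compared across diet, genotype, sex and age with:

* a Shapiro-Wilk normality gate per contrast,
* a linear mixed-effects model (REML) with a per-rat random intercept,
* all-pairs Tukey HSD contrasts (normal branch) or Mann-Whitney U
  (non-normal branch),
* percent-change / fold-ratio reporting and the human-BMI-derived
  weight-gain classification.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = [
    "LMMResult",
    "PairwiseResult",
    "normality_gate",
    "fit_lmm",
    "tukey_pairwise",
    "mann_whitney",
    "percent_change",
    "fold_ratio",
    "classify_weight_gain",
    "WEIGHT_GAIN_BANDS",
]

#: Half-open [lo, hi) percent-weight-gain bands mapped from human BMI classes.
WEIGHT_GAIN_BANDS: tuple[tuple[str, float, float], ...] = (
    ("normal", -np.inf, 14.0),
    ("overweight", 14.0, 38.0),
    ("obese_1", 38.0, 62.0),
    ("obese_2", 62.0, 84.0),
    ("above_range", 84.0, np.inf),
)


@dataclass
class LMMResult:
    """Fixed effects, variance components and fit diagnostics of the LMM."""

    coefficients: pd.DataFrame  # index: term; columns: estimate, se, p
    random_intercept_var: float
    residual_var: float
    converged: bool
    formula: str
    n_obs: int
    n_groups: int

    def coef(self, term: str) -> float:
        return float(self.coefficients.loc[term, "estimate"])

    def se(self, term: str) -> float:
        return float(self.coefficients.loc[term, "se"])

    def term_for_level(self, level: str) -> str:
        """Design-matrix term name for a non-reference factor level."""
        hits = [t for t in self.coefficients.index if f"[T.{level}]" in t]
        if len(hits) != 1:
            raise KeyError(f"level {level!r} matches {len(hits)} terms")
        return hits[0]


@dataclass(frozen=True)
class PairwiseResult:
    """One pairwise group contrast with its multiplicity-adjusted p-value."""

    group_a: str
    group_b: str
    estimate: float  # mean difference (Tukey) or U statistic (Mann-Whitney)
    p_adjusted: float
    reject: bool
    method: str
    alpha: float = 0.05


def normality_gate(values: np.ndarray, alpha: float = 0.05) -> tuple[float, float, bool]:
    """Shapiro-Wilk test routing a contrast to Tukey HSD or Mann-Whitney.

    Returns (statistic, p, is_normal); ``is_normal`` (p >= alpha) selects
    the parametric branch downstream.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 3:
        raise ValueError("Shapiro-Wilk requires at least 3 observations")
    stat, p = stats.shapiro(values)
    return float(stat), float(p), bool(p >= alpha)


def fit_lmm(
    table: pd.DataFrame,
    fixed: tuple[str, ...] = ("diet", "genotype", "sex"),
    response: str = "value",
    interactions: tuple[tuple[str, str], ...] = (),
    metric: str | None = None,
) -> LMMResult:
    """REML linear mixed-effects fit with a per-rat random intercept.

    ``table`` is a long-format cohort table (one row per rat x metric x
    timepoint) with a ``rat_id`` grouping column.  Categorical factors are
    treatment-coded; ``age`` (if included) enters as a numeric covariate.
    Wald p-values are reported for the fixed effects.  Non-convergence is
    reported via the ``converged`` flag, never silently.
    """
    data = table if metric is None else table[table["metric"] == metric]
    if data.empty:
        raise ValueError("no rows to fit (wrong metric name?)")
    if data["rat_id"].nunique() < 2:
        raise ValueError("need at least 2 rats for a random-intercept model")
    references = {"diet": "CHOW", "genotype": "nTg", "sex": "M"}

    def _term(f: str) -> str:
        if f == "age":
            return "age"
        ref = references.get(f)
        if ref is not None and ref in set(data[f]):
            return f"C({f}, Treatment('{ref}'))"
        return f"C({f})"

    terms = []
    for f in fixed:
        if f != "age" and data[f].nunique() < 2:
            raise ValueError(f"factor {f!r} has a single level in the data")
        terms.append(_term(f))
    for a, b in interactions:
        terms.append(f"{_term(a)}:{_term(b)}")
    formula = f"{response} ~ " + " + ".join(terms)

    model = MixedLM.from_formula(formula, groups="rat_id", data=data)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = model.fit(reml=True)
    k = model.k_fe
    coefs = pd.DataFrame(
        {
            "estimate": fit.params.iloc[:k],
            "se": fit.bse.iloc[:k],
            "p": fit.pvalues.iloc[:k],
        }
    )
    return LMMResult(
        coefficients=coefs,
        random_intercept_var=float(np.squeeze(fit.cov_re)),
        residual_var=float(fit.scale),
        converged=bool(getattr(fit, "converged", True)),
        formula=formula,
        n_obs=int(len(data)),
        n_groups=int(data["rat_id"].nunique()),
    )


def tukey_pairwise(
    table: pd.DataFrame,
    group: str | tuple[str, ...] = ("diet", "genotype"),
    response: str = "value",
    alpha: float = 0.05,
) -> list[PairwiseResult]:
    """All-pairs Tukey HSD contrasts on raw cell means.

    ``group`` may be one column or a tuple of columns whose levels are
    combined (e.g. CHOW-nTg, HCHF-TgAD).  Family-wise error is controlled
    at ``alpha`` via the studentized-range distribution.
    """
    if isinstance(group, str):
        labels = table[group].astype(str)
    else:
        labels = table[list(group)].astype(str).agg("-".join, axis=1)
    uniq = labels.unique()
    if len(uniq) < 2:
        raise ValueError("Tukey HSD needs at least 2 groups")
    counts = labels.value_counts()
    if (counts < 2).any():
        raise ValueError("every group needs at least 2 observations")
    res = pairwise_tukeyhsd(
        endog=table[response].to_numpy(dtype=float),
        groups=labels.to_numpy(),
        alpha=alpha,
    )
    out = []
    frame = pd.DataFrame(
        res.summary().data[1:], columns=[c for c in res.summary().data[0]]
    )
    for row, padj, rej, diff in zip(
        frame.itertuples(index=False), res.pvalues, res.reject, res.meandiffs
    ):
        out.append(
            PairwiseResult(
                group_a=str(row[0]),
                group_b=str(row[1]),
                estimate=float(diff),
                p_adjusted=float(padj),
                reject=bool(rej),
                method="tukey_hsd",
                alpha=alpha,
            )
        )
    return out


def mann_whitney(
    a: np.ndarray,
    b: np.ndarray,
    alpha: float = 0.05,
) -> PairwiseResult:
    """Two-sided Mann-Whitney U test for a non-normal contrast.

    Uses the exact null distribution for small untied samples and the
    normal approximation with tie correction otherwise (scipy's 'auto'
    policy).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    return PairwiseResult(
        group_a="a",
        group_b="b",
        estimate=float(res.statistic),
        p_adjusted=float(res.pvalue),
        reject=bool(res.pvalue < alpha),
        method="mann_whitney_u",
        alpha=alpha,
    )


def percent_change(
    reference_mean: float,
    comparison_mean: float,
    rounded: bool = True,
) -> float:
    """Signed percent change of ``comparison`` relative to ``reference``.

    100 * (comparison - reference) / reference, rounded to the nearest
    integer percent by default (the reporting convention for group
    contrasts).
    """
    if reference_mean == 0:
        raise ZeroDivisionError("reference mean must be non-zero")
    pct = 100.0 * (comparison_mean - reference_mean) / reference_mean
    return float(np.rint(pct)) if rounded else float(pct)


def fold_ratio(reference_mean: float, comparison_mean: float) -> float:
    """Fold ratio comparison/|reference| (the 'x-times higher' convention)."""
    if reference_mean == 0:
        raise ZeroDivisionError("reference mean must be non-zero")
    return float(comparison_mean / abs(reference_mean))


def classify_weight_gain(pct_gain_vs_reference: float) -> str:
    """Weight-gain class from percent gain over the age/sex-matched
    CHOW-fed non-transgenic mean weight.

    Bands (half-open [lo, hi), percent): normal < 14, overweight [14, 38),
    obese class 1 [38, 62), obese class 2 [62, 84), above_range >= 84.
    """
    x = float(pct_gain_vs_reference)
    if not np.isfinite(x):
        raise ValueError("weight gain must be finite")
    for name, lo, hi in WEIGHT_GAIN_BANDS:
        if lo <= x < hi:
            return name
    raise AssertionError("unreachable: bands cover the real line")
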