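"""Cohort analysis: sampling variability, summaries, classification.

The central question for any biopsy-based biomarker is how much its value
depends on *where* the needle sampled the liver.  With several biopsies
per explanted liver, the intra-liver coefficient of variation
(CoV = 100·σ/μ) quantifies that sampling variability per patient, and its
cohort summary compares biomarkers: a phenotypic composite score is
expected to be markedly more stable than a single-measurement biomarker
such as CPA.

Conventions: population standard deviation (denominator n) throughout;
CoV classes low (<15%), moderate (15–30%, boundaries included) and high
(>30%); AUROC by the rank (Mann–Whitney) estimator with ties counted
0.5 and a class-stratified percentile bootstrap for its CI.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

__all__ = [
    "ClassifierEval",
    "cov",
    "classify_cov",
    "per_liver_cov",
    "summarize_cohort",
    "auroc",
    "group_compare",
]


@dataclass
class ClassifierEval:
    """AUROC point estimate with bootstrap confidence interval."""

    auroc: float
    ci_low: float
    ci_high: float
    n_pos: int
    n_neg: int
    bootstrap_reps: int
    seed: int


def _sigma(arr: np.ndarray, denominator: str) -> float:
    if denominator == "population":
        return float(arr.std(ddof=0))
    if denominator == "sample":
        return float(arr.std(ddof=1))
    raise ValueError("denominator must be 'population' or 'sample'")


def cov(values, denominator: str = "population") -> float:
    """Coefficient of variation, percent: 100·σ/μ.

    Requires at least two values and a non-zero mean.
    """
    arr = np.asarray(list(values), dtype=float)
    if arr.size < 2:
        raise ValueError("CoV needs at least 2 values")
    mu = arr.mean()
    if mu == 0:
        raise ValueError("CoV undefined for zero mean")
    return 100.0 * _sigma(arr, denominator) / mu


def classify_cov(cov_percent: float) -> str:
    """Variability class: low (<15), moderate (15–30), high (>30)."""
    if cov_percent < 0:
        raise ValueError("CoV cannot be negative")
    if cov_percent < 15.0:
        return "low"
    if cov_percent <= 30.0:
        return "moderate"
    return "high"


def per_liver_cov(
    records: pd.DataFrame,
    metric: str,
    patient_col: str = "patient_id",
    exclude_flagged: bool = False,
    adequacy_col: str = "adequate",
    denominator: str = "population",
) -> dict[str, float]:
    """Intra-liver CoV of ``metric`` across each patient's biopsies.

    ``records`` holds one row per biopsy.  With ``exclude_flagged``,
    biopsies whose ``adequacy_col`` is falsy are dropped first (the
    adequacy-filtered variant).  Livers with fewer than two usable
    biopsies are omitted with a warning.
    """
    out: dict[str, float] = {}
    for pid, grp in records.groupby(patient_col, sort=True):
        if exclude_flagged and adequacy_col in grp.columns:
            grp = grp[grp[adequacy_col].astype(bool)]
        vals = grp[metric].dropna()
        if len(vals) < 2:
            logger.warning("liver %s: <2 usable biopsies for %s; omitted", pid, metric)
            continue
        out[str(pid)] = cov(vals, denominator=denominator)
    return out


def summarize_cohort(values, round_spec: int | None = None) -> dict[str, float]:
    """Summary row: mean, median, min, max, SD (population), SE.

    ``round_spec`` rounds the reported values half-up to that many
    decimals, matching report-table formatting.
    """
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("summarize_cohort needs at least one value")
    sd = float(arr.std(ddof=0))
    out = {
        "n": int(arr.size),
        "mean": float(arr.mean()),
        "median": float(np.median(arr)),
        "min": float(arr.min()),
        "max": float(arr.max()),
        "sd": sd,
        "se": sd / float(np.sqrt(arr.size)),
    }
    if round_spec is not None:
        from decimal import ROUND_HALF_UP, Decimal

        q = Decimal(1).scaleb(-round_spec)
        out = {
            k: (float(Decimal(repr(v)).quantize(q, rounding=ROUND_HALF_UP)) if k != "n" else v)
            for k, v in out.items()
        }
    return out


def auroc(
    scores,
    labels,
    bootstrap_reps: int = 2000,
    seed: int = 0,
    ci: float = 0.95,
) -> ClassifierEval:
    """AUROC via the rank (Mann–Whitney U) estimator, ties counted 0.5.

    The confidence interval is a class-stratified percentile bootstrap:
    positives and negatives are resampled separately so both classes are
    always present.  Deterministic given ``seed``.
    """
    s = np.asarray(list(scores), dtype=float)
    y = np.asarray(list(labels)).astype(int)
    if s.shape != y.shape:
        raise ValueError("scores and labels must have equal length")
    pos, neg = s[y == 1], s[y == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be present")

    def _auc(p, n):
        ranks = sps.rankdata(np.concatenate([p, n]))
        u = ranks[: len(p)].sum() - len(p) * (len(p) + 1) / 2.0
        return u / (len(p) * len(n))

    point = float(_auc(pos, neg))
    rng = np.random.default_rng(seed)
    boots = np.empty(bootstrap_reps)
    for i in range(bootstrap_reps):
        bp = pos[rng.integers(0, len(pos), len(pos))]
        bn = neg[rng.integers(0, len(neg), len(neg))]
        boots[i] = _auc(bp, bn)
    lo_q = 100 * (1 - ci) / 2
    ci_low, ci_high = np.percentile(boots, [lo_q, 100 - lo_q])
    return ClassifierEval(
        auroc=point,
        ci_low=float(min(ci_low, point)),
        ci_high=float(max(ci_high, point)),
        n_pos=int(len(pos)),
        n_neg=int(len(neg)),
        bootstrap_reps=bootstrap_reps,
        seed=seed,
    )


def group_compare(group_a, group_b, test: str = "welch_t") -> float:
    """Two-sided p-value comparing two score groups.

    Welch's t-test by default; Mann–Whitney as the rank-based option.
    Two constant groups with equal means give p = 1.
    """
    a = np.asarray(list(group_a), dtype=float)
    b = np.asarray(list(group_b), dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    if a.std() == 0 and b.std() == 0:
        return 1.0 if a.mean() == b.mean() else 0.0
    if test == "welch_t":
        return float(sps.ttest_ind(a, b, equal_var=False).pvalue)
    if test == "mann_whitney":
        return float(sps.mannwhitneyu(a, b, alternative="two-sided").pvalue)
    raise ValueError("test must be 'welch_t' or 'mann_whitney'")
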