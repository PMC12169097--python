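"""Composite phenotypic fibrosis scores.

A composite score is a normalised, equi-weighted linear combination of
*principal* qFTs — the parameters that separate two clinical severity
phenotypes (e.g., early vs advanced fibrosis, Laennec 4A vs 4C, Beijing
regressive vs progressive).  Construction:

1. :func:`select_principal_qfts` — keep qFTs whose group means differ by
   at least ``change_threshold`` (relative, default 20%) *and* whose
   two-group test is significant at ``alpha``;
2. :func:`fit_composite` — per selected qFT, store the fitting cohort's
   2.5th/97.5th percentiles as normalisation bounds and the sign of the
   group shift as the severity direction;
3. :func:`apply_composite` — map each qFT to [0, 1] with a clipped
   affine transform (flipped by its direction), average with equal
   weights, and scale to the output range (default 0-10).

No multiple-testing correction is applied by default; per-test selection
is the convention the score family was built with.  A Benjamini–Hochberg
switch is available for sensitivity analyses.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats as sps

from .qft import QFTMatrix, QFTVector

logger = logging.getLogger(__name__)

__all__ = [
    "CompositeModel",
    "select_principal_qfts",
    "fit_composite",
    "apply_composite",
    "score_matrix",
]

#: guard for relative change against near-zero baselines
EPSILON = 1e-12


def _as_frame(rows) -> pd.DataFrame:
    if isinstance(rows, QFTMatrix):
        return rows.data
    return pd.DataFrame(rows)


@dataclass
class CompositeModel:
    """A fitted composite-score definition (fully serialisable)."""

    name: str
    selected_qfts: list[str]
    bounds: dict[str, tuple[float, float]]  # (low, high) per qFT
    directions: dict[str, int]  # +1 severity increases the qFT
    output_scale: tuple[float, float] = (0.0, 10.0)
    selection_params: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.selected_qfts:
            raise ValueError("a composite needs at least one selected qFT")
        for name in self.selected_qfts:
            lo, hi = self.bounds[name]
            if not lo < hi:
                raise ValueError(f"degenerate bounds for {name}: ({lo}, {hi})")

    @property
    def weight(self) -> float:
        return 1.0 / len(self.selected_qfts)

    def to_json(self, path=None) -> str:
        payload = asdict(self)
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "CompositeModel":
        if isinstance(source, bytes) or (
            isinstance(source, str) and source.lstrip().startswith("{")
        ):
            payload = json.loads(source)
        else:
            with open(source) as fh:
                payload = json.load(fh)
        payload["bounds"] = {k: tuple(v) for k, v in payload["bounds"].items()}
        payload["output_scale"] = tuple(payload["output_scale"])
        return cls(**payload)


def select_principal_qfts(
    group_a,
    group_b,
    change_threshold: float = 0.20,
    alpha: float = 0.05,
    test: str = "welch_t",
    min_group_n: int = 3,
    min_complete_fraction: float = 0.9,
    fdr: bool = False,
) -> pd.DataFrame:
    """Screen qFTs that separate phenotype group A (less severe) from B.

    A qFT is selected iff ``|mean_B - mean_A| / max(|mean_A|, eps) >=
    change_threshold`` *and* the two-sided test p-value is below
    ``alpha``.  Eligibility requires at least ``min_group_n`` non-missing
    biopsies per group and a non-missing fraction of at least
    ``min_complete_fraction`` in each group — a qFT that is undefined for
    many biopsies (e.g. assembled-fibre statistics where no assembled
    fibres exist) cannot anchor a score meant to apply cohort-wide.
    Returns a DataFrame (qft, mean_a, mean_b, relative_change, p_value,
    direction, selected, near_zero_baseline) sorted by descending
    relative change among the selected.
    """
    A, B = _as_frame(group_a), _as_frame(group_b)
    overlap = A.index.intersection(B.index)
    if len(overlap):
        raise ValueError(f"groups share biopsies: {list(overlap)[:5]}")
    if test not in ("welch_t", "mann_whitney"):
        raise ValueError("test must be 'welch_t' or 'mann_whitney'")

    rows = []
    for name in A.columns.intersection(B.columns):
        a = A[name].dropna().to_numpy(float)
        b = B[name].dropna().to_numpy(float)
        if len(a) < min_group_n or len(b) < min_group_n:
            continue
        if len(a) < min_complete_fraction * len(A) or len(b) < min_complete_fraction * len(B):
            continue
        mean_a, mean_b = a.mean(), b.mean()
        near_zero = abs(mean_a) < EPSILON
        rel = abs(mean_b - mean_a) / max(abs(mean_a), EPSILON)
        if a.std() == 0 and b.std() == 0:
            p = 1.0 if mean_a == mean_b else 0.0
        elif test == "welch_t":
            p = float(sps.ttest_ind(a, b, equal_var=False).pvalue)
        else:
            p = float(sps.mannwhitneyu(a, b, alternative="two-sided").pvalue)
        rows.append(
            {
                "qft": name,
                "mean_a": mean_a,
                "mean_b": mean_b,
                "relative_change": rel,
                "p_value": p,
                "direction": int(np.sign(mean_b - mean_a)) or 1,
                "near_zero_baseline": near_zero,
            }
        )
    table = pd.DataFrame(rows)
    if table.empty:
        table["selected"] = pd.Series(dtype=bool)
        return table
    pcol = table["p_value"]
    if fdr:
        order = np.argsort(pcol.values)
        m = len(pcol)
        adj = np.empty(m)
        adj[order] = np.minimum.accumulate(
            (pcol.values[order] * m / np.arange(1, m + 1))[::-1]
        )[::-1]
        pcol = pd.Series(np.minimum(adj, 1.0), index=table.index)
    table["selected"] = (table["relative_change"] >= change_threshold) & (pcol < alpha)
    return table.sort_values(
        ["selected", "relative_change"], ascending=[False, False]
    ).reset_index(drop=True)


def fit_composite(
    matrix,
    selected: pd.DataFrame,
    output_scale: tuple[float, float] = (0.0, 10.0),
    name: str = "Ph-FCS",
    percentiles: tuple[float, float] = (2.5, 97.5),
) -> CompositeModel:
    """Freeze normalisation bounds and directions into a composite model.

    Bounds are the fitting cohort's ``percentiles`` (default
    2.5/97.5) of each selected qFT — robust min–max normalisation.
    qFTs constant in the fitting cohort are dropped with a warning.
    """
    data = _as_frame(matrix)
    sel = selected[selected["selected"]] if "selected" in selected.columns else selected
    if sel.empty:
        raise ValueError("no selected qFTs to fit")
    bounds, directions, kept = {}, {}, []
    for _, row in sel.iterrows():
        qft = row["qft"]
        vals = data[qft].dropna().to_numpy(float)
        lo, hi = np.percentile(vals, percentiles)
        if not lo < hi:
            logger.warning("%s: qFT %s constant in fitting cohort; dropped", name, qft)
            continue
        bounds[qft] = (float(lo), float(hi))
        directions[qft] = int(row["direction"])
        kept.append(qft)
    if not kept:
        raise ValueError("all selected qFTs were constant in the fitting cohort")
    return CompositeModel(
        name=name,
        selected_qfts=kept,
        bounds=bounds,
        directions=directions,
        output_scale=tuple(output_scale),
        selection_params={
            "percentiles": list(percentiles),
            "n_candidates": int(len(selected)),
            "n_selected": len(kept),
        },
        provenance={"n_fitting_biopsies": int(len(data))},
    )


def _normalise_one(value: float, lo: float, hi: float, direction: int) -> float:
    z = (value - lo) / (hi - lo)
    z = min(max(z, 0.0), 1.0)
    return z if direction >= 0 else 1.0 - z


def apply_composite(
    model: CompositeModel,
    vector,
    max_missing_fraction: float = 0.20,
    return_contributions: bool = False,
):
    """Score one biopsy with a fitted composite model.

    ``vector`` may be a :class:`~fibroquant.qft.QFTVector`, a pandas
    Series or a plain mapping.  Missing selected qFTs up to
    ``max_missing_fraction`` are tolerated (weights renormalised, result
    flagged); beyond that a ``ValueError`` is raised.
    """
    if isinstance(vector, QFTVector):
        mapping = vector.values
    elif isinstance(vector, pd.Series):
        mapping = vector.to_dict()
    else:
        mapping = dict(vector)

    contribs = {}
    for qft in model.selected_qfts:
        val = mapping.get(qft)
        if val is None or (isinstance(val, float) and np.isnan(val)):
            continue
        lo, hi = model.bounds[qft]
        contribs[qft] = _normalise_one(float(val), lo, hi, model.directions[qft])
    missing = len(model.selected_qfts) - len(contribs)
    if len(contribs) == 0 or missing / len(model.selected_qfts) > max_missing_fraction:
        raise ValueError(
            f"{model.name}: {missing}/{len(model.selected_qfts)} selected qFTs missing"
        )
    if missing:
        logger.warning("%s: scored over %d/%d qFTs (weights renormalised)",
                       model.name, len(contribs), len(model.selected_qfts))
    lo_s, hi_s = model.output_scale
    score = lo_s + (hi_s - lo_s) * float(np.mean(list(contribs.values())))
    if return_contributions:
        return score, contribs
    return score


def score_matrix(model: CompositeModel, matrix, **kwargs) -> pd.Series:
    """Apply a composite model to every row of a qFT matrix."""
    data = _as_frame(matrix)
    return pd.Series(
        {idx: apply_composite(model, row, **kwargs) for idx, row in data.iterrows()},
        name=model.name,
    )
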