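"""Reidentify individuals by Pearson correlation of panel proteins.

Each non-reference ("query") sample is correlated against one designated
reference sample per individual; the predicted identity is the owner of
the best-correlating reference.  Correlations are computed on log10
intensities by default (plasma intensities span orders of magnitude),
with pairwise-complete deletion of missing values and a minimum-overlap
guard.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from proteoid.cohort_io import IntensityMatrix, SampleKey, round_percent
from proteoid.specificity import ProteinPanel

__all__ = [
    "CorrelationMatrix",
    "AssignmentResult",
    "QueryAssignment",
    "log_transform",
    "pearson_on_panel",
    "correlation_matrix",
    "assign_by_correlation",
    "evaluate_assignment",
]

DEFAULT_MIN_OVERLAP = 20


def log_transform(matrix: IntensityMatrix) -> pd.DataFrame:
    """Elementwise log10 of the intensity matrix; missing stays missing."""
    if (matrix.values <= 0).any().any():
        bad = matrix.values.index[(matrix.values <= 0).any(axis=1)]
        raise ValueError(f"non-positive intensity for protein(s): {list(bad)}")
    return np.log10(matrix.values)


def _panel_frame(
    matrix: IntensityMatrix, panel: ProteinPanel | list[str] | None, log_scale: bool
) -> pd.DataFrame:
    frame = log_transform(matrix) if log_scale else matrix.values
    if panel is None:
        return frame
    ids = panel.protein_ids if isinstance(panel, ProteinPanel) else list(panel)
    missing = [p for p in ids if p not in frame.index]
    if missing:
        raise KeyError(f"panel protein(s) not in matrix: {missing}")
    return frame.loc[ids]


def pearson_on_panel(
    matrix: IntensityMatrix,
    panel: ProteinPanel | list[str] | None,
    sample_a: SampleKey | str,
    sample_b: SampleKey | str,
    *,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    log_scale: bool = True,
) -> tuple[float, int]:
    """Pearson r between two samples on the panel proteins.

    Uses only proteins non-missing in both samples; returns ``(nan, n)``
    when fewer than ``min_overlap`` proteins overlap.
    """
    frame = _panel_frame(matrix, panel, log_scale)
    a = sample_a.label if isinstance(sample_a, SampleKey) else sample_a
    b = sample_b.label if isinstance(sample_b, SampleKey) else sample_b
    x = frame[a].to_numpy(dtype=float)
    y = frame[b].to_numpy(dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    n = int(ok.sum())
    if n < min_overlap:
        return float("nan"), n
    x, y = x[ok] - x[ok].mean(), y[ok] - y[ok].mean()
    denom = np.sqrt((x * x).sum() * (y * y).sum())
    if denom == 0:
        return float("nan"), n
    return float((x * y).sum() / denom), n


@dataclass
class CorrelationMatrix:
    """All-vs-all sample correlation on the panel proteins."""

    samples: list[SampleKey]
    r: pd.DataFrame          # symmetric, unit diagonal, NaN where undefined
    n_overlap: pd.DataFrame  # per-pair count of proteins used

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def n_unordered_pairs(self) -> int:
        """Number of informative off-diagonal unordered entries: n(n-1)/2."""
        n = self.n_samples
        return n * (n - 1) // 2

    def to_tsv(self, path) -> None:
        self.r.to_csv(path, sep="\t", na_rep="NA")


def correlation_matrix(
    matrix: IntensityMatrix,
    panel: ProteinPanel | list[str] | None = None,
    *,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    log_scale: bool = True,
) -> CorrelationMatrix:
    """Cross-correlate every pair of samples on the panel proteins."""
    if len(matrix.samples) < 2:
        raise ValueError("need at least 2 samples")
    frame = _panel_frame(matrix, panel, log_scale)
    r = frame.corr(method="pearson", min_periods=max(min_overlap, 2))
    notna = frame.notna().astype(float)
    n_overlap = notna.T @ notna
    np.fill_diagonal(r.values, 1.0)
    return CorrelationMatrix(samples=list(matrix.samples), r=r, n_overlap=n_overlap.astype(int))


@dataclass
class QueryAssignment:
    sample: SampleKey
    ranked: list[tuple[str, float]]  # (individual_id, r) descending
    true_individual: str
    predicted_individual: str | None
    correct: bool
    rank_of_truth: int | None
    ambiguous: bool = False


@dataclass
class AssignmentResult:
    """Ranked candidate individuals per query sample plus summary rates."""

    queries: list[QueryAssignment]
    reference_timepoint: int
    reference_individuals: list[str]
    score_table: pd.DataFrame  # query label x reference individual

    @property
    def n_queries(self) -> int:
        return len(self.queries)

    @property
    def n_correct(self) -> int:
        return sum(q.correct for q in self.queries)

    @property
    def error_rate_percent(self) -> float:
        if not self.queries:
            return 0.0
        return round_percent(100.0 * (1 - self.n_correct / self.n_queries))

    def to_report_dict(self) -> dict:
        return {
            "summary": {
                "n_queries": self.n_queries,
                "n_correct": self.n_correct,
                "error_rate_percent": self.error_rate_percent,
                "reference_timepoint": self.reference_timepoint,
            },
            "queries": [
                {
                    "sample": q.sample.label,
                    "true_individual": q.true_individual,
                    "predicted_individual": q.predicted_individual,
                    "correct": q.correct,
                    "rank_of_truth": q.rank_of_truth,
                    "ambiguous": q.ambiguous,
                    "top_score": q.ranked[0][1] if q.ranked else None,
                }
                for q in self.queries
            ],
        }


def _rank_queries(
    score_table: pd.DataFrame,
    query_samples: list[SampleKey],
    higher_is_better: bool = True,
) -> list[QueryAssignment]:
    out = []
    for sample in query_samples:
        row = score_table.loc[sample.label]
        scores = [
            (ind, float(row[ind]) if pd.notna(row[ind]) else float("-inf"))
            for ind in score_table.columns
        ]
        scores.sort(key=lambda t: (-t[1], t[0]))
        top_ind, top_score = scores[0]
        ambiguous = len(scores) > 1 and scores[1][1] == top_score
        truth = sample.individual_id
        rank = next((i + 1 for i, (ind, _) in enumerate(scores) if ind == truth), None)
        correct = (top_ind == truth) and not ambiguous
        out.append(
            QueryAssignment(
                sample=sample,
                ranked=scores,
                true_individual=truth,
                predicted_individual=top_ind,
                correct=correct,
                rank_of_truth=rank,
                ambiguous=ambiguous,
            )
        )
    return out


def assign_by_correlation(
    matrix: IntensityMatrix,
    panel: ProteinPanel | list[str] | None,
    reference_timepoint: int = 1,
    *,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    log_scale: bool = True,
) -> AssignmentResult:
    """Assign every non-reference sample to an individual by correlation.

    One sample per individual at ``reference_timepoint`` acts as that
    individual's reference; individuals lacking it are dropped from the
    reference set with a warning but their remaining samples are still
    evaluated as queries.  Ties are broken lexicographically and flagged
    ambiguous (counted incorrect).
    """
    refs: dict[str, SampleKey] = {}
    for s in matrix.samples:
        if s.timepoint == reference_timepoint:
            refs[s.individual_id] = s
    missing_ref = [i for i in matrix.individuals if i not in refs]
    if missing_ref:
        warnings.warn(
            f"individual(s) without reference TP{reference_timepoint}: {missing_ref}; "
            "excluded from references"
        )
    if not refs:
        raise ValueError(f"no sample at reference timepoint {reference_timepoint}")
    ref_samples = set(refs.values())
    queries = [s for s in matrix.samples if s not in ref_samples]

    frame = _panel_frame(matrix, panel, log_scale)
    corr = frame.corr(method="pearson", min_periods=max(min_overlap, 2))
    ref_inds = sorted(refs)
    score_table = pd.DataFrame(
        {ind: corr[refs[ind].label] for ind in ref_inds},
        index=corr.index,
    ).loc[[q.label for q in queries]]

    return AssignmentResult(
        queries=_rank_queries(score_table, queries),
        reference_timepoint=reference_timepoint,
        reference_individuals=ref_inds,
        score_table=score_table,
    )


def evaluate_assignment(
    result: AssignmentResult, corr: CorrelationMatrix | None = None
) -> dict:
    """Summary statistics: counts, error rate, rank-of-truth distribution,
    and (given the full correlation matrix) median intra- vs
    inter-individual r."""
    if result.n_queries < 1:
        raise ValueError("need at least one query")
    ranks: dict[int, int] = {}
    for q in result.queries:
        if q.rank_of_truth is not None:
            ranks[q.rank_of_truth] = ranks.get(q.rank_of_truth, 0) + 1
    summary = {
        "n_queries": result.n_queries,
        "n_correct": result.n_correct,
        "error_rate_percent": result.error_rate_percent,
        "rank_of_truth_distribution": dict(sorted(ranks.items())),
    }
    # intra/inter split of the query-vs-reference score table
    intra, inter = [], []
    for q in result.queries:
        for ind, score in q.ranked:
            if not np.isfinite(score):
                continue
            (intra if ind == q.true_individual else inter).append(score)
    summary["median_intra_r"] = float(np.median(intra)) if intra else float("nan")
    summary["median_inter_r"] = float(np.median(inter)) if inter else float("nan")
    if corr is not None:
        ind_of = {s.label: s.individual_id for s in corr.samples}
        labels = [s.label for s in corr.samples]
        intra_all, inter_all = [], []
        for i, a in enumerate(labels):
            for b in labels[i + 1 :]:
                v = corr.r.at[a, b]
                if pd.isna(v):
                    continue
                (intra_all if ind_of[a] == ind_of[b] else inter_all).append(float(v))
        summary["median_intra_r_all_pairs"] = (
            float(np.median(intra_all)) if intra_all else float("nan")
        )
        summary["median_inter_r_all_pairs"] = (
            float(np.median(inter_all)) if inter_all else float("nan")
        )
    return summary
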