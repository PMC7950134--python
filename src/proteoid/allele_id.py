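"""Reidentify individuals by matching present/absent variant-peptide calls.

Each query sample is compared with one reference sample per individual by
counting panel positions where the boolean calls agree (both present or
both absent); the predicted identity is the individual with the highest
match count.  The score equals panel size minus Hamming distance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from proteoid.cohort_io import EvidenceTable, SampleKey, round_percent
from proteoid.variant_panel import AllelePanel, group_presence

__all__ = [
    "PresenceVector",
    "MatchResult",
    "QueryMatch",
    "match_score",
    "presence_vectors",
    "assign_by_matches",
    "evaluate_allele_assignment",
]


@dataclass
class PresenceVector:
    sample: SampleKey
    calls: np.ndarray  # boolean, one per panel group, panel order

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=bool)


def match_score(vector_a, vector_b) -> int:
    """Count of positions where two call vectors agree; symmetric."""
    a = np.asarray(vector_a.calls if isinstance(vector_a, PresenceVector) else vector_a, dtype=bool)
    b = np.asarray(vector_b.calls if isinstance(vector_b, PresenceVector) else vector_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    return int((a == b).sum())


def presence_vectors(
    evidence: EvidenceTable, panel: AllelePanel
) -> pd.DataFrame:
    """Panel-group x sample boolean calls in panel order.

    Missing evidence for a (group, sample) is treated as absent — the
    present/absent framing admits no third state by default.
    """
    return group_presence(evidence, panel.groups)


@dataclass
class QueryMatch:
    sample: SampleKey
    ranked: list[tuple[str, int]]  # (individual_id, score) descending
    true_individual: str
    predicted_individual: str | None
    correct: bool
    rank_of_truth: int | None
    ambiguous: bool = False


@dataclass
class MatchResult:
    """Ranked candidates per query by present/absent match counts."""

    queries: list[QueryMatch]
    reference_timepoint: int
    reference_individuals: list[str]
    panel_size: int
    score_table: pd.DataFrame  # query label x reference individual

    @property
    def n_total(self) -> int:
        return len(self.queries)

    @property
    def n_correct(self) -> int:
        return sum(q.correct for q in self.queries)

    @property
    def percent_correct(self) -> float:
        if not self.queries:
            return 0.0
        return round_percent(100.0 * self.n_correct / self.n_total)

    def to_report_dict(self) -> dict:
        return {
            "summary": {
                "n_total": self.n_total,
                "n_correct": self.n_correct,
                "percent_correct": self.percent_correct,
                "panel_size": self.panel_size,
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


def assign_by_matches(
    evidence: EvidenceTable,
    panel: AllelePanel,
    reference_timepoint: int = 1,
    *,
    strict_missing: bool = False,
) -> MatchResult:
    """Score every non-reference sample against each individual's reference.

    Ties for the best score are flagged ambiguous and counted incorrect.
    With ``strict_missing``, panel calls never explicitly listed in the
    evidence file are skipped rather than treated as absent; queries whose
    calls are all missing are excluded with a warning.
    """
    calls = presence_vectors(evidence, panel)
    if strict_missing and evidence.observed is not None:
        observed = group_presence(
            EvidenceTable(
                meta=evidence.meta,
                presence=evidence.observed,
                samples=evidence.samples,
                observed=None,
            ),
            panel.groups,
        )
    else:
        observed = pd.DataFrame(True, index=calls.index, columns=calls.columns)

    refs: dict[str, SampleKey] = {}
    for s in evidence.samples:
        if s.timepoint == reference_timepoint:
            refs[s.individual_id] = s
    all_inds = list(dict.fromkeys(s.individual_id for s in evidence.samples))
    missing_ref = [i for i in all_inds if i not in refs]
    if missing_ref:
        warnings.warn(
            f"individual(s) without reference TP{reference_timepoint}: {missing_ref}; "
            "excluded from references"
        )
    if not refs:
        raise ValueError(f"no sample at reference timepoint {reference_timepoint}")
    ref_samples = set(refs.values())
    queries = [s for s in evidence.samples if s not in ref_samples]
    if strict_missing:
        kept = []
        for q in queries:
            if observed[q.label].any():
                kept.append(q)
            else:
                warnings.warn(f"query {q.label} has all-missing calls; excluded")
        queries = kept

    ref_inds = sorted(refs)
    score = pd.DataFrame(index=[q.label for q in queries], columns=ref_inds, dtype=float)
    for q in queries:
        qc = calls[q.label].to_numpy()
        qo = observed[q.label].to_numpy()
        for ind in ref_inds:
            rc = calls[refs[ind].label].to_numpy()
            ro = observed[refs[ind].label].to_numpy()
            use = qo & ro
            score.at[q.label, ind] = int((qc[use] == rc[use]).sum())

    results = []
    for q in queries:
        row = score.loc[q.label]
        ranked = sorted(
            ((ind, int(row[ind])) for ind in ref_inds), key=lambda t: (-t[1], t[0])
        )
        top_ind, top_score = ranked[0]
        ambiguous = len(ranked) > 1 and ranked[1][1] == top_score
        truth = q.individual_id
        rank = next((i + 1 for i, (ind, _) in enumerate(ranked) if ind == truth), None)
        results.append(
            QueryMatch(
                sample=q,
                ranked=ranked,
                true_individual=truth,
                predicted_individual=top_ind,
                correct=(top_ind == truth) and not ambiguous,
                rank_of_truth=rank,
                ambiguous=ambiguous,
            )
        )
    return MatchResult(
        queries=results,
        reference_timepoint=reference_timepoint,
        reference_individuals=ref_inds,
        panel_size=panel.size,
        score_table=score.astype(int),
    )


def evaluate_allele_assignment(result: MatchResult) -> dict:
    """Percent correct, per-individual accuracy, and median within- vs
    between-individual match scores."""
    if result.n_total < 1:
        raise ValueError("need at least one query")
    per_ind: dict[str, list[bool]] = {}
    within, between = [], []
    for q in result.queries:
        per_ind.setdefault(q.true_individual, []).append(q.correct)
        for ind, score in q.ranked:
            (within if ind == q.true_individual else between).append(score)
    return {
        "n_total": result.n_total,
        "n_correct": result.n_correct,
        "percent_correct": result.percent_correct,
        "per_individual_accuracy": {
            ind: round_percent(100.0 * sum(v) / len(v)) for ind, v in sorted(per_ind.items())
        },
        "median_within_score": float(np.median(within)) if within else float("nan"),
        "median_between_score": float(np.median(between)) if between else float("nan"),
    }
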