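"""Selection of individual-specific proteins and marker-spike screening.

A protein counts as individual-specific when (a) its per-participant level
deviates from the population median by more than a fold threshold in at
least a given fraction of participants and (b) it is stable within persons
over time (median within-participant coefficient of variation below a
threshold).  Levels are per-participant medians across time points; the
population median is the median of those levels.  CV is computed on
linear-scale intensities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from proteoid.cohort_io import IntensityMatrix, SampleKey

__all__ = [
    "SpecificityParams",
    "ProteinPanel",
    "MarkerFlag",
    "participant_levels",
    "within_cv",
    "select_individual_specific",
    "flag_marker_spikes",
]


@dataclass(frozen=True)
class SpecificityParams:
    fold_threshold: float = 1.5
    participant_fraction: float = 0.25
    cv_threshold: float = 0.20
    #: proteins quantified in fewer than this fraction of samples are
    #: excluded before evaluation (unstable medians otherwise)
    min_quantified_fraction: float = 0.5

    def __post_init__(self) -> None:
        if not self.fold_threshold > 1:
            raise ValueError("fold_threshold must be > 1")
        if not 0 < self.participant_fraction <= 1:
            raise ValueError("participant_fraction must be in (0, 1]")
        if not 0 < self.cv_threshold < 1:
            raise ValueError("cv_threshold must be in (0, 1)")


@dataclass
class ProteinPanel:
    """Ordered list of selected proteins plus the statistics behind each call."""

    protein_ids: list[str]
    stats: pd.DataFrame  # index: protein_id; columns: fraction_deviating, median_within_cv

    def __post_init__(self) -> None:
        missing = [p for p in self.protein_ids if p not in self.stats.index]
        if missing:
            raise ValueError(f"panel members without stats: {missing}")

    def to_report_dict(self) -> dict:
        return {
            "protein_ids": list(self.protein_ids),
            "summary": {"n_proteins": len(self.protein_ids)},
            "stats": {
                p: {
                    "fraction_deviating": float(self.stats.at[p, "fraction_deviating"]),
                    "median_within_cv": float(self.stats.at[p, "median_within_cv"]),
                }
                for p in self.protein_ids
            },
        }

    @classmethod
    def from_report_dict(cls, d: dict) -> "ProteinPanel":
        stats = pd.DataFrame.from_dict(d.get("stats", {}), orient="index")
        if stats.empty:
            stats = pd.DataFrame(
                index=d["protein_ids"],
                data={
                    "fraction_deviating": np.nan,
                    "median_within_cv": np.nan,
                },
            )
        return cls(protein_ids=list(d["protein_ids"]), stats=stats)


@dataclass(frozen=True)
class MarkerFlag:
    sample: SampleKey
    marker_protein: str
    fold_over_personal_median: float


def _individual_of_columns(matrix: IntensityMatrix) -> pd.Series:
    return pd.Series(
        [s.individual_id for s in matrix.samples], index=matrix.values.columns
    )


def participant_levels(matrix: IntensityMatrix, protein: str) -> pd.Series:
    """Per-individual level: median of non-missing intensities across TPs.

    Individuals with no observation for the protein yield NaN.  The result
    is indexed by individual id in cohort order.
    """
    if protein not in matrix.values.index:
        raise KeyError(f"protein {protein!r} not in matrix")
    row = matrix.values.loc[protein]
    by_ind = row.groupby(_individual_of_columns(matrix), sort=False)
    return by_ind.median().reindex(matrix.individuals)


def within_cv(matrix: IntensityMatrix, protein: str, individual: str) -> float:
    """Coefficient of variation (sd/mean, linear scale) across one
    individual's time points; NaN with fewer than two observations."""
    if protein not in matrix.values.index:
        raise KeyError(f"protein {protein!r} not in matrix")
    cols = matrix.columns_of(individual)
    if not cols:
        raise KeyError(f"individual {individual!r} not in matrix")
    vals = matrix.values.loc[protein, cols].dropna()
    if len(vals) < 2:
        return float("nan")
    return float(vals.std(ddof=1) / vals.mean())


def _levels_frame(matrix: IntensityMatrix) -> pd.DataFrame:
    """Proteins x individuals frame of per-participant median levels."""
    groups = _individual_of_columns(matrix)
    return (
        matrix.values.T.groupby(groups, sort=False).median().T.reindex(
            columns=matrix.individuals
        )
    )


def _cv_frame(matrix: IntensityMatrix) -> pd.DataFrame:
    """Proteins x individuals frame of within-participant CVs (NaN if <2 obs)."""
    groups = _individual_of_columns(matrix)
    t = matrix.values.T
    counts = t.notna().groupby(groups, sort=False).sum().T
    means = t.groupby(groups, sort=False).mean().T
    sds = t.groupby(groups, sort=False).std(ddof=1).T
    cv = sds / means
    return cv.where(counts >= 2).reindex(columns=matrix.individuals)


def select_individual_specific(
    matrix: IntensityMatrix, params: SpecificityParams = SpecificityParams()
) -> ProteinPanel:
    """Select individual-specific proteins from a longitudinal matrix.

    Both criteria must hold: the fraction of individuals whose level
    deviates from the population median by a symmetric ratio
    ``max(level/median, median/level) > fold_threshold`` is at least
    ``participant_fraction``, and the median within-participant CV is
    below ``cv_threshold``.  Proteins quantified in fewer than
    ``min_quantified_fraction`` of samples are excluded up front.
    """
    if matrix.values.empty:
        return ProteinPanel(
            protein_ids=[],
            stats=pd.DataFrame(columns=["fraction_deviating", "median_within_cv"]),
        )

    quant_frac = matrix.values.notna().mean(axis=1)
    eligible = quant_frac >= params.min_quantified_fraction

    levels = _levels_frame(matrix)
    n_levels = levels.notna().sum(axis=1)
    pop_median = levels.median(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = levels.div(pop_median, axis=0)
        ratio = np.maximum(r, 1.0 / r)
    deviating = (ratio > params.fold_threshold) & levels.notna()
    frac_dev = deviating.sum(axis=1) / n_levels.replace(0, np.nan)

    cvs = _cv_frame(matrix)
    med_cv = cvs.median(axis=1, skipna=True)

    selected = (
        eligible
        & (n_levels >= 2)
        & (frac_dev >= params.participant_fraction)
        & (med_cv < params.cv_threshold)
    )
    stats = pd.DataFrame(
        {"fraction_deviating": frac_dev, "median_within_cv": med_cv}
    )
    panel_ids = [p for p in matrix.protein_ids if bool(selected.get(p, False))]
    return ProteinPanel(protein_ids=panel_ids, stats=stats.loc[panel_ids].copy())


def flag_marker_spikes(
    matrix: IntensityMatrix,
    marker_proteins: list[str],
    fold_threshold: float,
) -> list[MarkerFlag]:
    """Flag samples where a marker exceeds ``fold_threshold`` times the
    individual's own median level of that marker."""
    if not fold_threshold > 1:
        raise ValueError("fold_threshold must be > 1")
    unknown = [m for m in marker_proteins if m not in matrix.values.index]
    if unknown:
        raise KeyError(f"unknown marker protein(s): {unknown}")
    flags: list[MarkerFlag] = []
    levels = _levels_frame(matrix)
    for marker in marker_proteins:
        for sample in matrix.samples:
            val = matrix.values.at[marker, sample.label]
            base = levels.at[marker, sample.individual_id]
            if pd.isna(val) or pd.isna(base) or base <= 0:
                continue
            fold = float(val / base)
            if fold > fold_threshold:
                flags.append(
                    MarkerFlag(
                        sample=sample, marker_protein=marker,
                        fold_over_personal_median=fold,
                    )
                )
    return flags
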