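"""Synthetic longitudinal plasma-proteome cohorts.

Generates (1) a protein intensity matrix whose log10 values follow a
log-additive variance-component model (baseline + between-individual +
within-individual noise) in which between-individual variance dominates
for "specific" proteins, (2) diploid variant-peptide identification
evidence with Hardy-Weinberg genotypes and per-sample detection dropout,
and (3) optional marker spikes.  One seed governs a fixed
stream-splitting order (intensities, genotypes, evidence, spikes), so
adding spikes never perturbs earlier draws.  Identical config + seed
gives bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import json
import numpy as np
import pandas as pd

from proteoid.cohort_io import (
    EvidenceTable,
    IntensityMatrix,
    SampleKey,
    VariantRecord,
    write_evidence_table,
    write_fasta,
    write_intensity_matrix,
    write_variant_table,
)

__all__ = [
    "CohortConfig",
    "MarkerSpike",
    "LocusTruth",
    "SyntheticCohort",
    "simulate_intensities",
    "simulate_allele_evidence",
    "inject_marker_spike",
    "simulate_cohort",
    "write_cohort",
]

# filler alphabet excludes K/R (cleavage) and P (protease edge cases)
_FILLER = "ACDEFGHILMNQSTVWY"


@dataclass(frozen=True)
class MarkerSpike:
    individual_id: str
    timepoint: int
    marker_protein: str
    fold: float


@dataclass(frozen=True)
class LocusTruth:
    gene_id: str
    protein_accession: str
    variant_site: int
    ref_aa: str
    alt_aa: str
    variant_id: str
    alt_allele_freq: float
    erratic: bool
    canonical_sequence: str


@dataclass
class CohortConfig:
    n_individuals: int = 42
    n_timepoints: int = 7
    n_proteins: int = 300
    fraction_specific: float = 0.7
    sigma_between: float = 0.3
    sigma_within: float = 0.05
    sigma_between_flat: float = 0.02
    sigma_within_flat: float = 0.05
    mu_log10_range: tuple[float, float] = (1.0, 6.0)
    missing_rate: float = 0.01
    n_loci: int = 60
    alt_allele_freq: float | None = None  # None: drawn uniform [0.1, 0.9] per locus
    peptide_detection_prob: float = 0.95
    erratic_gene_fraction: float = 0.05
    erratic_presence_rate: float = 0.35
    marker_spikes: list[MarkerSpike] = field(default_factory=list)
    seed: int = 0

    def validate(self) -> None:
        errors = []
        for name in ("n_individuals", "n_timepoints", "n_proteins"):
            if getattr(self, name) < 1:
                errors.append(f"{name} must be >= 1")
        if self.n_loci < 0:
            errors.append("n_loci must be >= 0")
        for name in (
            "fraction_specific",
            "missing_rate",
            "peptide_detection_prob",
            "erratic_gene_fraction",
            "erratic_presence_rate",
        ):
            if not 0 <= getattr(self, name) <= 1:
                errors.append(f"{name} must be in [0, 1]")
        for name in (
            "sigma_between",
            "sigma_within",
            "sigma_between_flat",
            "sigma_within_flat",
        ):
            if getattr(self, name) < 0:
                errors.append(f"{name} must be >= 0")
        if self.alt_allele_freq is not None and not 0 < self.alt_allele_freq < 1:
            errors.append("alt_allele_freq must be in (0, 1)")
        if not self.mu_log10_range[0] <= self.mu_log10_range[1]:
            errors.append("mu_log10_range must be a non-empty interval")
        if not isinstance(self.seed, (int, np.integer)):
            errors.append("seed must be an integer")
        if errors:
            raise ValueError("invalid config: " + "; ".join(errors))

    def samples(self) -> list[SampleKey]:
        width = max(2, len(str(self.n_individuals)))
        return [
            SampleKey(f"I{i + 1:0{width}d}", t + 1)
            for i in range(self.n_individuals)
            for t in range(self.n_timepoints)
        ]

    def individuals(self) -> list[str]:
        width = max(2, len(str(self.n_individuals)))
        return [f"I{i + 1:0{width}d}" for i in range(self.n_individuals)]


@dataclass
class SyntheticCohort:
    config: CohortConfig
    matrix: IntensityMatrix
    evidence: EvidenceTable
    genotypes: pd.DataFrame  # individuals x gene_id: alt-allele copies 0/1/2
    loci: list[LocusTruth]
    canonical_records: list[tuple[str, str]]
    variant_records: list[VariantRecord]
    specific_proteins: list[str]
    flat_proteins: list[str]

    @property
    def erratic_genes(self) -> list[str]:
        return [l.gene_id for l in self.loci if l.erratic]


def _streams(seed: int) -> list[np.random.Generator]:
    """Documented stream order: intensities, genotypes, evidence, spikes."""
    children = np.random.SeedSequence(seed).spawn(4)
    return [np.random.default_rng(c) for c in children]


def simulate_intensities(
    config: CohortConfig, rng: np.random.Generator | None = None
) -> tuple[IntensityMatrix, list[str], list[str]]:
    """Simulate the intensity matrix; returns (matrix, specific, flat) ids.

    log10 intensity = mu_p + b_{p,i} + eps_{p,i,t} with
    b ~ N(0, sigma_between^2) per (protein, individual) and
    eps ~ N(0, sigma_within^2) per observation; flat proteins use the flat
    sigmas.  Values are exponentiated to linear scale and masked missing
    uniformly at ``missing_rate``.
    """
    config.validate()
    if rng is None:
        rng = _streams(config.seed)[0]
    n_p, n_i, n_t = config.n_proteins, config.n_individuals, config.n_timepoints
    protein_ids = [f"P{k + 1:04d}" for k in range(n_p)]
    n_specific = int(round(config.fraction_specific * n_p))
    specific_idx = rng.choice(n_p, size=n_specific, replace=False)
    is_specific = np.zeros(n_p, dtype=bool)
    is_specific[specific_idx] = True

    mu = rng.uniform(*config.mu_log10_range, size=n_p)
    sb = np.where(is_specific, config.sigma_between, config.sigma_between_flat)
    sw = np.where(is_specific, config.sigma_within, config.sigma_within_flat)
    b = rng.normal(0.0, 1.0, size=(n_p, n_i)) * sb[:, None]
    eps = rng.normal(0.0, 1.0, size=(n_p, n_i, n_t)) * sw[:, None, None]
    log10 = mu[:, None, None] + b[:, :, None] + eps
    values = np.power(10.0, log10).reshape(n_p, n_i * n_t)
    if config.missing_rate > 0:
        mask = rng.random(size=values.shape) < config.missing_rate
        values = np.where(mask, np.nan, values)

    samples = config.samples()
    frame = pd.DataFrame(values, index=protein_ids, columns=[s.label for s in samples])
    matrix = IntensityMatrix(values=frame, samples=samples)
    specific = [p for p, s in zip(protein_ids, is_specific) if s]
    flat = [p for p, s in zip(protein_ids, is_specific) if not s]
    return matrix, specific, flat


def _random_peptide(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(_FILLER), size=length))


def _make_locus(
    rng: np.random.Generator, index: int, alt_freq: float, erratic: bool,
    used_peptides: set[str],
) -> LocusTruth:
    """Build a canonical sequence whose middle tryptic peptide (length 9,
    positions 11-19) carries the variant site at position 15."""
    while True:
        prefix = _random_peptide(rng, 9) + "K"
        left = _random_peptide(rng, 4)
        right = _random_peptide(rng, 3) + "K"
        suffix = _random_peptide(rng, 9)
        ref_aa, alt_aa = rng.choice(list(_FILLER), size=2, replace=False)
        mid_ref = left + ref_aa + right
        mid_alt = left + alt_aa + right
        candidates = {mid_ref, mid_alt, mid_ref + suffix, mid_alt + suffix}
        if candidates & used_peptides:
            continue
        used_peptides |= candidates
        return LocusTruth(
            gene_id=f"GENE{index + 1:03d}",
            protein_accession=f"PV{index + 1:04d}",
            variant_site=15,
            ref_aa=str(ref_aa),
            alt_aa=str(alt_aa),
            variant_id=f"VAR_{index + 1:06d}",
            alt_allele_freq=float(alt_freq),
            erratic=erratic,
            canonical_sequence=prefix + mid_ref + suffix,
        )


def simulate_allele_evidence(
    config: CohortConfig,
    rng_geno: np.random.Generator | None = None,
    rng_evid: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, EvidenceTable, list[LocusTruth]]:
    """Simulate genotypes and variant-peptide identification evidence.

    Genotypes follow Hardy-Weinberg proportions per locus; an allele's
    peptide group is detectable in a sample iff the individual carries at
    least one copy, and detection occurs with ``peptide_detection_prob``
    independently per sample.  Both the fully cleaved and the 1-missed-
    cleavage form of each group are emitted (the missed form only
    alongside group detection) to exercise collapsing.  Erratic genes
    instead receive presence scattered uniformly at random across all
    samples at ``erratic_presence_rate``, irrespective of genotype.
    """
    config.validate()
    if rng_geno is None or rng_evid is None:
        streams = _streams(config.seed)
        rng_geno = rng_geno or streams[1]
        rng_evid = rng_evid or streams[2]

    individuals = config.individuals()
    samples = config.samples()
    labels = [s.label for s in samples]
    n_i, n_t, n_l = config.n_individuals, config.n_timepoints, config.n_loci

    n_erratic = int(round(config.erratic_gene_fraction * n_l))
    erratic_idx = set(rng_geno.choice(n_l, size=n_erratic, replace=False).tolist()) if n_l else set()
    if config.alt_allele_freq is None:
        freqs = rng_geno.uniform(0.1, 0.9, size=n_l)
    else:
        freqs = np.full(n_l, config.alt_allele_freq)

    used: set[str] = set()
    loci = [
        _make_locus(rng_geno, k, freqs[k], k in erratic_idx, used) for k in range(n_l)
    ]
    geno = pd.DataFrame(
        rng_geno.binomial(2, freqs[None, :], size=(n_i, n_l)) if n_l else
        np.zeros((n_i, 0), dtype=int),
        index=individuals,
        columns=[l.gene_id for l in loci],
    )

    ind_index = np.repeat(np.arange(n_i), n_t)
    meta_rows = []
    presence_rows = []
    for k, locus in enumerate(loci):
        copies = geno.iloc[:, k].to_numpy()
        for allele_id, carrier in (
            ("ref", copies < 2),
            (locus.variant_id, copies > 0),
        ):
            if locus.erratic:
                group = rng_evid.random(n_i * n_t) < config.erratic_presence_rate
            else:
                detected = rng_evid.random(n_i * n_t) < config.peptide_detection_prob
                group = carrier[ind_index] & detected
            missed = group & (rng_evid.random(n_i * n_t) < 0.3)
            aa = locus.ref_aa if allele_id == "ref" else locus.alt_aa
            seq = locus.canonical_sequence
            mid = seq[10:14] + aa + seq[15:19]  # fully cleaved form, pos 11-19
            full_form = mid
            missed_form = mid + seq[19:28]  # retains the internal K at pos 19
            for pep, present in ((full_form, group), (missed_form, missed)):
                meta_rows.append(
                    (pep, locus.gene_id, locus.protein_accession, allele_id,
                     locus.variant_site)
                )
                presence_rows.append(present)

    meta = pd.DataFrame(
        meta_rows,
        columns=["peptide_sequence", "gene_id", "protein_accession", "allele_id", "variant_site"],
    )
    meta["variant_site"] = pd.array(meta["variant_site"], dtype="Int64")
    presence = pd.DataFrame(
        np.array(presence_rows, dtype=bool).reshape(len(meta_rows), len(labels))
        if meta_rows else np.zeros((0, len(labels)), dtype=bool),
        columns=labels,
    )
    evidence = EvidenceTable(meta=meta, presence=presence, samples=samples)
    return geno, evidence, loci


def inject_marker_spike(
    matrix: IntensityMatrix, spikes: list[MarkerSpike | tuple]
) -> IntensityMatrix:
    """Multiply designated (individual, timepoint, marker) cells by a fold."""
    values = matrix.values.copy()
    for sp in spikes:
        if not isinstance(sp, MarkerSpike):
            sp = MarkerSpike(*sp)
        if sp.marker_protein not in values.index:
            raise KeyError(f"unknown marker protein {sp.marker_protein!r}")
        label = SampleKey(sp.individual_id, sp.timepoint).label
        if label not in values.columns:
            raise KeyError(f"unknown sample {label!r}")
        if sp.fold <= 0:
            raise ValueError(f"fold must be > 0, got {sp.fold}")
        values.at[sp.marker_protein, label] *= sp.fold
    return IntensityMatrix(values=values, samples=list(matrix.samples))


def simulate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Compose intensity, genotype/evidence, and spike generation under one seed."""
    config.validate()
    rng_int, rng_geno, rng_evid, _rng_spk = _streams(config.seed)
    matrix, specific, flat = simulate_intensities(config, rng_int)
    geno, evidence, loci = simulate_allele_evidence(config, rng_geno, rng_evid)
    if config.marker_spikes:
        matrix = inject_marker_spike(matrix, config.marker_spikes)
    canonical_records = [
        (f"sp|{l.protein_accession}|{l.gene_id}", l.canonical_sequence) for l in loci
    ]
    variant_records = [
        VariantRecord(
            protein_accession=l.protein_accession,
            position=l.variant_site,
            ref_aa=l.ref_aa,
            alt_aa=l.alt_aa,
            variant_id=l.variant_id,
        )
        for l in loci
    ]
    return SyntheticCohort(
        config=config,
        matrix=matrix,
        evidence=evidence,
        genotypes=geno,
        loci=loci,
        canonical_records=canonical_records,
        variant_records=variant_records,
        specific_proteins=specific,
        flat_proteins=flat,
    )


def write_cohort(cohort: SyntheticCohort, out_dir: str | Path) -> dict[str, Path]:
    """Write all cohort artifacts in the pipeline's external formats."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": out / "intensity.tsv",
        "annotations": out / "annotations.tsv",
        "evidence": out / "evidence.tsv",
        "fasta": out / "canonical.fasta",
        "variants": out / "variants.tsv",
        "truth": out / "truth.json",
    }
    write_intensity_matrix(cohort.matrix, paths["matrix"], paths["annotations"])
    write_evidence_table(cohort.evidence, paths["evidence"])
    write_fasta(cohort.canonical_records, paths["fasta"])
    write_variant_table(cohort.variant_records, paths["variants"])
    truth = {
        "specific_proteins": cohort.specific_proteins,
        "flat_proteins": cohort.flat_proteins,
        "erratic_genes": cohort.erratic_genes,
        "genotypes": {
            ind: {g: int(cohort.genotypes.at[ind, g]) for g in cohort.genotypes.columns}
            for ind in cohort.genotypes.index
        },
        "loci": [
            {
                "gene_id": l.gene_id,
                "protein_accession": l.protein_accession,
                "variant_site": l.variant_site,
                "ref_aa": l.ref_aa,
                "alt_aa": l.alt_aa,
                "variant_id": l.variant_id,
                "alt_allele_freq": l.alt_allele_freq,
                "erratic": l.erratic,
            }
            for l in cohort.loci
        ],
    }
    with open(paths["truth"], "w") as fh:
        json.dump(truth, fh, indent=2)
        fh.write("\n")
    return paths
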