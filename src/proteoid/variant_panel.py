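"""Allele-discriminating variant-peptide panel construction.

Pipeline: apply single-residue substitutions to canonical sequences,
digest every allele sequence in silico (cleavage C-terminal to K/R, up to
two missed cleavages, minimum length seven), enumerate peptides that
cover a variant site and differ between alleles, collapse missed-cleavage
forms of the same allele site into one group, then run a five-stage
filter cascade over identification evidence to keep only reliably and
consistently observed allele groups.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from proteoid.cohort_io import EvidenceTable, SampleKey, VariantRecord

__all__ = [
    "DigestParams",
    "PanelFilterParams",
    "DigestFragment",
    "AllelePeptide",
    "PeptideGroup",
    "AllelePanel",
    "apply_substitutions",
    "tryptic_digest",
    "enumerate_allele_peptides",
    "group_missed_cleavage_forms",
    "groups_from_evidence",
    "group_presence",
    "filter_cascade",
]

CANONICAL_ALLELE_ID = "ref"


@dataclass(frozen=True)
class DigestParams:
    """In-silico protease settings (trypsin + LysC style)."""

    cleave_after: frozenset[str] = frozenset({"K", "R"})
    max_missed_cleavages: int = 2
    min_length: int = 7
    #: by default K/R-P bonds are cleaved too (LysC cleaves K-P); set True
    #: for strict trypsin behaviour
    no_cleave_before_proline: bool = False

    def __post_init__(self) -> None:
        if self.max_missed_cleavages < 0:
            raise ValueError("max_missed_cleavages must be >= 0")
        if self.min_length < 1:
            raise ValueError("min_length must be >= 1")


@dataclass(frozen=True)
class PanelFilterParams:
    min_presence: int = 6
    n_timepoints: int = 7
    variation_ratio: float = 10.0

    def __post_init__(self) -> None:
        if not 1 <= self.min_presence <= self.n_timepoints:
            raise ValueError("require 1 <= min_presence <= n_timepoints")
        if self.variation_ratio <= 0:
            raise ValueError("variation_ratio must be > 0")


@dataclass(frozen=True)
class DigestFragment:
    sequence: str
    start: int  # 1-based inclusive on the parent sequence
    end: int
    missed_cleavages: int

    def __post_init__(self) -> None:
        if self.end - self.start + 1 != len(self.sequence):
            raise ValueError("fragment coordinates inconsistent with sequence length")


@dataclass(frozen=True)
class AllelePeptide:
    """A digest fragment that covers a variant site and discriminates alleles."""

    sequence: str
    gene_id: str
    allele_id: str
    variant_site: int  # 1-based position on the canonical sequence
    start: int
    end: int
    missed_cleavages: int

    def __post_init__(self) -> None:
        if not self.start <= self.variant_site <= self.end:
            raise ValueError("variant_site outside peptide coordinates")
        if self.end - self.start + 1 != len(self.sequence):
            raise ValueError("peptide coordinates inconsistent with sequence length")

    @property
    def group_key(self) -> tuple[str, str, int]:
        return (self.gene_id, self.allele_id, self.variant_site)


@dataclass
class PeptideGroup:
    """Missed-cleavage forms of one allele site, collapsed.

    Presence of the group in a sample is the logical OR of its members'
    presences (a missed-cleavage form carries the same allele information
    as the fully cleaved one, so the allele is counted once).
    """

    gene_id: str
    allele_id: str
    variant_site: int
    peptide_sequences: list[str]

    @property
    def key(self) -> tuple[str, str, int]:
        return (self.gene_id, self.allele_id, self.variant_site)


@dataclass
class AllelePanel:
    """Surviving allele groups plus per-stage bookkeeping of the cascade."""

    groups: list[PeptideGroup]
    stage_counts: list[int]

    def __post_init__(self) -> None:
        keys = [g.key for g in self.groups]
        if len(set(keys)) != len(keys):
            raise ValueError("panel groups not disjoint by (gene, allele, site)")
        tail = self.stage_counts[1:]
        if any(b > a for a, b in zip(self.stage_counts, tail)):
            raise ValueError("stage_counts must be non-increasing after stage 1")

    @property
    def size(self) -> int:
        return len(self.groups)

    def to_report_dict(self) -> dict:
        return {
            "summary": {"panel_size": self.size, "stage_counts": list(self.stage_counts)},
            "stage_counts": list(self.stage_counts),
            "groups": [
                {
                    "gene_id": g.gene_id,
                    "allele_id": g.allele_id,
                    "variant_site": g.variant_site,
                    "peptide_sequences": list(g.peptide_sequences),
                }
                for g in self.groups
            ],
        }

    @classmethod
    def from_report_dict(cls, d: dict) -> "AllelePanel":
        return cls(
            groups=[
                PeptideGroup(
                    gene_id=g["gene_id"],
                    allele_id=g["allele_id"],
                    variant_site=int(g["variant_site"]),
                    peptide_sequences=list(g["peptide_sequences"]),
                )
                for g in d["groups"]
            ],
            stage_counts=[int(c) for c in d["stage_counts"]],
        )


# ---------------------------------------------------------------------------
# substitution + digestion
# ---------------------------------------------------------------------------

def apply_substitutions(
    canonical_sequence: str, variant_records: Sequence[VariantRecord]
) -> list[tuple[str, str]]:
    """Apply each substitution independently to the canonical sequence.

    Returns one ``(variant_id, variant_sequence)`` per record; sequence
    length is preserved.  The canonical residues at the substituted span
    must equal the record's ref_aa.
    """
    out = []
    for rec in variant_records:
        i0 = rec.position - 1
        span = canonical_sequence[i0 : i0 + len(rec.ref_aa)]
        if span != rec.ref_aa:
            raise ValueError(
                f"{rec.protein_accession} {rec.variant_id}: reference mismatch at "
                f"position {rec.position}: expected {rec.ref_aa!r}, found {span!r}"
            )
        variant = (
            canonical_sequence[:i0] + rec.alt_aa + canonical_sequence[i0 + len(rec.ref_aa):]
        )
        out.append((rec.variant_id, variant))
    return out


def cleavage_sites(sequence: str, params: DigestParams) -> list[int]:
    """0-based indices i such that the protease cuts between i and i+1."""
    sites = []
    for i in range(len(sequence) - 1):
        if sequence[i] in params.cleave_after:
            if params.no_cleave_before_proline and sequence[i + 1] == "P":
                continue
            sites.append(i)
    return sites


def tryptic_digest(
    sequence: str, params: DigestParams = DigestParams()
) -> list[DigestFragment]:
    """Enumerate digest fragments with up to ``max_missed_cleavages``
    retained internal sites and length >= ``min_length``.

    Fragments are emitted in (start, missed_cleavages) order with 1-based
    inclusive coordinates.
    """
    if not sequence:
        raise ValueError("empty sequence")
    sites = cleavage_sites(sequence, params)
    bounds = [0] + [i + 1 for i in sites] + [len(sequence)]
    base = [(bounds[k], bounds[k + 1]) for k in range(len(bounds) - 1)]
    frags = []
    for k in range(len(base)):
        for mc in range(params.max_missed_cleavages + 1):
            if k + mc >= len(base):
                break
            start, end = base[k][0], base[k + mc][1]
            if end - start < params.min_length:
                continue
            frags.append(
                DigestFragment(
                    sequence=sequence[start:end],
                    start=start + 1,
                    end=end,
                    missed_cleavages=mc,
                )
            )
    frags.sort(key=lambda f: (f.start, f.missed_cleavages))
    return frags


def enumerate_allele_peptides(
    canonical: str,
    variant_records: Sequence[VariantRecord],
    digest_params: DigestParams = DigestParams(),
    *,
    gene_id: str | None = None,
) -> list[AllelePeptide]:
    """Enumerate peptides that discriminate alleles at each variant locus.

    Records sharing a position form one locus whose alleles are the
    canonical sequence plus one variant sequence per record.  Each allele
    sequence is digested independently (a substitution may create or
    destroy a cleavage site); a fragment qualifies when it covers the
    substituted span and its sequence differs from the same-coordinate
    substring of every other allele at the locus.  Substitutions preserve
    length, so coordinates are comparable across alleles.
    """
    if not variant_records:
        return []
    accession = variant_records[0].protein_accession
    gene = gene_id if gene_id is not None else accession
    by_pos: dict[int, list[VariantRecord]] = {}
    for rec in variant_records:
        if rec.protein_accession != accession:
            raise ValueError("all records must target one protein")
        by_pos.setdefault(rec.position, []).append(rec)

    peptides: list[AllelePeptide] = []
    for pos in sorted(by_pos):
        recs = by_pos[pos]
        span_len = max(len(r.ref_aa) for r in recs)
        alleles: dict[str, str] = {CANONICAL_ALLELE_ID: canonical}
        for vid, vseq in apply_substitutions(canonical, recs):
            alleles[vid] = vseq
        for allele_id, seq in alleles.items():
            for frag in tryptic_digest(seq, digest_params):
                # overlap of [start, end] with the substituted span
                if frag.end < pos or frag.start > pos + span_len - 1:
                    continue
                others = [
                    other_seq[frag.start - 1 : frag.end]
                    for other_id, other_seq in alleles.items()
                    if other_id != allele_id
                ]
                if any(frag.sequence == o for o in others):
                    continue
                peptides.append(
                    AllelePeptide(
                        sequence=frag.sequence,
                        gene_id=gene,
                        allele_id=allele_id,
                        variant_site=pos,
                        start=frag.start,
                        end=frag.end,
                        missed_cleavages=frag.missed_cleavages,
                    )
                )
    return peptides


def group_missed_cleavage_forms(
    peptides: Sequence[AllelePeptide],
) -> list[PeptideGroup]:
    """Collapse missed-cleavage forms: one group per (gene, allele, site)."""
    groups: dict[tuple[str, str, int], PeptideGroup] = {}
    for p in peptides:
        g = groups.get(p.group_key)
        if g is None:
            groups[p.group_key] = PeptideGroup(
                gene_id=p.gene_id,
                allele_id=p.allele_id,
                variant_site=p.variant_site,
                peptide_sequences=[p.sequence],
            )
        elif p.sequence not in g.peptide_sequences:
            g.peptide_sequences.append(p.sequence)
    return list(groups.values())


# ---------------------------------------------------------------------------
# evidence-driven cascade
# ---------------------------------------------------------------------------

def groups_from_evidence(evidence: EvidenceTable) -> list[PeptideGroup]:
    """Derive peptide groups directly from evidence labels (rows lacking a
    variant_site are skipped — they cannot discriminate alleles)."""
    peptide_like = []
    for _, m in evidence.meta.iterrows():
        if pd.isna(m["variant_site"]):
            continue
        peptide_like.append(
            (m["gene_id"], m["allele_id"], int(m["variant_site"]), m["peptide_sequence"])
        )
    groups: dict[tuple[str, str, int], PeptideGroup] = {}
    for gene, allele, site, seq in peptide_like:
        key = (gene, allele, site)
        if key not in groups:
            groups[key] = PeptideGroup(gene, allele, site, [seq])
        elif seq not in groups[key].peptide_sequences:
            groups[key].peptide_sequences.append(seq)
    return list(groups.values())


def group_presence(
    evidence: EvidenceTable, groups: Sequence[PeptideGroup]
) -> pd.DataFrame:
    """Boolean groups x samples frame; group presence = OR over member rows.

    Evidence rows are matched to groups by (gene_id, allele_id,
    variant_site); groups with no matching evidence row are all-absent.
    """
    labels = evidence.sample_labels
    meta = evidence.meta
    row_keys = []
    for _, m in meta.iterrows():
        site = None if pd.isna(m["variant_site"]) else int(m["variant_site"])
        row_keys.append((m["gene_id"], m["allele_id"], site))
    pres = np.zeros((len(groups), len(labels)), dtype=bool)
    for gi, g in enumerate(groups):
        rows = [i for i, k in enumerate(row_keys) if k == g.key]
        if rows:
            pres[gi] = evidence.presence.iloc[rows].any(axis=0).to_numpy()
    return pd.DataFrame(pres, index=pd.RangeIndex(len(groups)), columns=labels)


def filter_cascade(
    evidence: EvidenceTable,
    groups: Sequence[PeptideGroup] | None = None,
    params: PanelFilterParams = PanelFilterParams(),
) -> AllelePanel:
    """Apply the five-stage filter cascade to allele groups.

    S1 keep groups present in >= min_presence of n_timepoints time points
       in at least one individual;
    S2 drop groups identified in every sample or in none;
    S3 keep groups with >= 1 surviving counterpart group from another
       allele of the same gene at the same variant site;
    S4 missed-cleavage collapsing (already reflected in the groups; the
       count is recorded for bookkeeping);
    S5 per gene, let total = sample-level identifications of its groups
       study-wide and consistent = identifications within individuals
       where the group was seen min_presence..n_timepoints times; if
       total > variation_ratio * consistent, drop every allele of the gene.
    """
    if groups is None:
        groups = groups_from_evidence(evidence)
    groups = list(groups)
    presence = group_presence(evidence, groups)
    tp_counts = _per_individual_tp_counts(presence, evidence.samples)

    stage_counts: list[int] = []

    # S1: reliably seen in at least one individual
    surviving = [
        i for i in range(len(groups)) if (tp_counts.iloc[i] >= params.min_presence).any()
    ]
    stage_counts.append(len(surviving))

    # S2: uninformative groups (always or never identified)
    n_samples = presence.shape[1]
    totals = presence.sum(axis=1)
    surviving = [i for i in surviving if 0 < totals.iloc[i] < n_samples]
    stage_counts.append(len(surviving))

    # S3: needs a counterpart allele at the same gene/site
    locus_alleles: dict[tuple[str, int], set[str]] = {}
    for i in surviving:
        g = groups[i]
        locus_alleles.setdefault((g.gene_id, g.variant_site), set()).add(g.allele_id)
    surviving = [
        i
        for i in surviving
        if len(locus_alleles[(groups[i].gene_id, groups[i].variant_site)]) >= 2
    ]
    stage_counts.append(len(surviving))

    # S4: collapsing is inherent to the group representation
    stage_counts.append(len(surviving))

    # S5: drop genes whose identifications are dominated by erratic appearances
    by_gene: dict[str, list[int]] = {}
    for i in surviving:
        by_gene.setdefault(groups[i].gene_id, []).append(i)
    dropped_genes = set()
    for gene, idxs in by_gene.items():
        total = int(totals.iloc[idxs].sum())
        consistent = 0
        for i in idxs:
            counts = tp_counts.iloc[i]
            ok = (counts >= params.min_presence) & (counts <= params.n_timepoints)
            consistent += int(counts[ok].sum())
        if total > params.variation_ratio * consistent:
            dropped_genes.add(gene)
    surviving = [i for i in surviving if groups[i].gene_id not in dropped_genes]
    stage_counts.append(len(surviving))

    return AllelePanel(groups=[groups[i] for i in surviving], stage_counts=stage_counts)


def _per_individual_tp_counts(
    presence: pd.DataFrame, samples: Sequence[SampleKey]
) -> pd.DataFrame:
    """Groups x individuals frame: number of time points with the group present."""
    ind_of = pd.Series([s.individual_id for s in samples], index=[s.label for s in samples])
    return presence.T.groupby(ind_of, sort=False).sum().T
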