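from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from proteoid.cohort_io import EvidenceTable, VariantRecord
from proteoid.variant_panel import (
    AllelePanel,
    DigestParams,
    PanelFilterParams,
    PeptideGroup,
    apply_substitutions,
    enumerate_allele_peptides,
    filter_cascade,
    group_missed_cleavage_forms,
    groups_from_evidence,
    tryptic_digest,
)

from conftest import cohort_samples

AA = "ACDEFGHIKLMNPQRSTVWY"


def brute_force_digest(sequence, params: DigestParams):
    """Oracle: all substrings with valid tryptic termini, <= max_missed
    internal cleavage sites, and length >= min_length."""
    cuts = set()
    for i in range(len(sequence) - 1):
        if sequence[i] in params.cleave_after:
            if params.no_cleave_before_proline and sequence[i + 1] == "P":
                continue
            cuts.add(i)
    out = set()
    n = len(sequence)
    for start in range(n):
        for end in range(start, n):  # inclusive 0-based
            valid_nterm = start == 0 or (start - 1) in cuts
            valid_cterm = end == n - 1 or end in cuts
            if not (valid_nterm and valid_cterm):
                continue
            internal = sum(1 for c in cuts if start <= c < end)
            if internal > params.max_missed_cleavages:
                continue
            if end - start + 1 < params.min_length:
                continue
            out.add((sequence[start : end + 1], start + 1, end + 1, internal))
    return out


class TestApplySubstitutions:
    def test_positional_replacement(self):
        rec = VariantRecord("P1", 5, "F", "L", "VAR_1")
        assert apply_substitutions("ACDEFGHIK", [rec]) == [("VAR_1", "ACDELGHIK")]

    def test_identity_substitution(self):
        rec = VariantRecord("P1", 5, "F", "F", "VAR_1")
        assert apply_substitutions("ACDEFGHIK", [rec])[0][1] == "ACDEFGHIK"

    def test_reference_mismatch_error_names_details(self):
        rec = VariantRecord("P1", 5, "W", "L", "VAR_1")
        with pytest.raises(ValueError, match="position 5") as exc:
            apply_substitutions("ACDEFGHIK", [rec])
        assert "'W'" in str(exc.value) and "'F'" in str(exc.value)

    def test_multi_residue_substitution(self):
        rec = VariantRecord("P1", 3, "DE", "NQ", "VAR_2")
        assert apply_substitutions("ACDEFGHIK", [rec])[0][1] == "ACNQFGHIK"

    def test_length_preserved(self):
        rec = VariantRecord("P1", 1, "A", "G", "VAR_3")
        (_, out) = apply_substitutions("ACDEFGHIK", [rec])[0]
        assert len(out) == 9


class TestTrypticDigest:
    def test_no_cleavage_site_single_peptide(self):
        frags = tryptic_digest("AAAAAAA")
        assert [(f.sequence, f.start, f.end, f.missed_cleavages) for f in frags] == [
            ("AAAAAAA", 1, 7, 0)
        ]

    def test_hand_enumerated_example(self):
        params = DigestParams(min_length=1, max_missed_cleavages=2)
        frags = {f.sequence for f in tryptic_digest("MKWVTFR", params)}
        assert frags == {"MK", "WVTFR", "MKWVTFR"}

    def test_minimum_length_seven(self):
        # any fragment of length 6 is excluded under defaults
        for f in tryptic_digest("AAAKCCCKDDDKEEEK"):
            assert len(f.sequence) >= 7

    def test_zero_mc_fragments_reconstruct_sequence(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            seq = "".join(rng.choice(list(AA), size=rng.integers(5, 60)))
            params = DigestParams(min_length=1)
            frags = [f for f in tryptic_digest(seq, params) if f.missed_cleavages == 0]
            frags.sort(key=lambda f: f.start)
            assert "".join(f.sequence for f in frags) == seq

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            tryptic_digest("")

    def test_no_cleave_before_proline_mode(self):
        params = DigestParams(min_length=1, no_cleave_before_proline=True)
        frags = {f.sequence for f in tryptic_digest("AAKPCCK", params) if f.missed_cleavages == 0}
        assert frags == {"AAKPCCK"}
        default = {f.sequence for f in tryptic_digest("AAKPCCK", DigestParams(min_length=1)) if f.missed_cleavages == 0}
        assert default == {"AAK", "PCCK"}

    @settings(max_examples=200, deadline=None)
    @given(
        seq=st.text(alphabet=AA, min_size=1, max_size=60),
        max_mc=st.integers(0, 3),
        min_len=st.integers(1, 10),
    )
    def test_oracle_equivalence(self, seq, max_mc, min_len):
        params = DigestParams(max_missed_cleavages=max_mc, min_length=min_len)
        got = {
            (f.sequence, f.start, f.end, f.missed_cleavages)
            for f in tryptic_digest(seq, params)
        }
        assert got == brute_force_digest(seq, params)


class TestEnumerateAllelePeptides:
    def test_simple_locus_both_alleles(self):
        # C->S inside the fully cleaved 8-mer "ACDECFGK"
        canonical = "AAAK" + "ACDECFGK" + "WWWWWWW"
        rec = VariantRecord("P1", 9, "C", "S", "VAR_1")
        peps = enumerate_allele_peptides(canonical, [rec])
        zero_mc = [p for p in peps if p.missed_cleavages == 0]
        assert {(p.allele_id, p.sequence) for p in zero_mc} == {
            ("ref", "ACDECFGK"),
            ("VAR_1", "ACDESFGK"),
        }
        for p in peps:
            assert p.start <= p.variant_site <= p.end

    def test_short_first_peptide_no_reportables(self):
        canonical = "ACK" + "DDDDDDDK"
        rec = VariantRecord("P1", 1, "A", "G", "VAR_1")
        peps = enumerate_allele_peptides(canonical, [rec])
        # only fragments of length >= 7 covering position 1 qualify: the
        # 1-missed form covers it, the fully cleaved 3-mer does not
        assert all(p.missed_cleavages >= 1 for p in peps)
        short = enumerate_allele_peptides(
            canonical, [rec], DigestParams(max_missed_cleavages=0)
        )
        assert short == []

    def test_cleavage_site_gain(self):
        # K->R at a cleavage site: allele peptides differ only at the C terminus
        canonical = "AAAAAAK" + "CCCCCCC"
        rec = VariantRecord("P1", 7, "K", "R", "VAR_1")
        peps = enumerate_allele_peptides(canonical, [rec])
        zero_mc = {(p.allele_id, p.sequence) for p in peps if p.missed_cleavages == 0}
        assert ("ref", "AAAAAAK") in zero_mc
        assert ("VAR_1", "AAAAAAR") in zero_mc

    def test_substitution_destroying_site_digests_independently(self):
        canonical = "AAAAAAK" + "CCCCCCC"
        rec = VariantRecord("P1", 7, "K", "S", "VAR_1")
        peps = enumerate_allele_peptides(canonical, [rec])
        var_seqs = {p.sequence for p in peps if p.allele_id == "VAR_1"}
        assert "AAAAAASCCCCCCC" in var_seqs  # no cleavage in the variant allele

    def test_no_records_no_peptides(self):
        assert enumerate_allele_peptides("AAAAAAA", []) == []


class TestGroupMissedCleavageForms:
    def _pep(self, seq, allele, site=9, gene="G1", start=5, mc=0):
        from proteoid.variant_panel import AllelePeptide

        return AllelePeptide(
            sequence=seq, gene_id=gene, allele_id=allele, variant_site=site,
            start=start, end=start + len(seq) - 1, missed_cleavages=mc,
        )

    def test_forms_collapse_to_one_group(self):
        peps = [
            self._pep("ACDECFGK", "ref"),
            self._pep("ACDECFGKWWWWWWW", "ref", mc=1),
        ]
        groups = group_missed_cleavage_forms(peps)
        assert len(groups) == 1
        assert groups[0].peptide_sequences == ["ACDECFGK", "ACDECFGKWWWWWWW"]

    def test_two_alleles_stay_separate(self):
        peps = [self._pep("ACDECFGK", "ref"), self._pep("ACDESFGK", "VAR_1")]
        assert len(group_missed_cleavage_forms(peps)) == 2

    def test_no_shared_sites_identity(self):
        peps = [self._pep("ACDECFGK", "ref", site=9), self._pep("WWDECFGK", "ref", site=20, start=16)]
        assert len(group_missed_cleavage_forms(peps)) == 2


def build_evidence(presence_by_row, samples):
    """presence_by_row: {(pep, gene, allele, site): iterable of present labels}."""
    labels = [s.label for s in samples]
    meta_rows, pres_rows = [], []
    for (pep, gene, allele, site), present in presence_by_row.items():
        meta_rows.append((pep, gene, f"ACC_{gene}", allele, site))
        pres_rows.append([lab in set(present) for lab in labels])
    meta = pd.DataFrame(
        meta_rows,
        columns=["peptide_sequence", "gene_id", "protein_accession", "allele_id", "variant_site"],
    )
    meta["variant_site"] = pd.array(meta["variant_site"], dtype="Int64")
    presence = pd.DataFrame(np.array(pres_rows, dtype=bool), columns=labels)
    return EvidenceTable(meta=meta, presence=presence, samples=list(samples))


class TestFilterCascade:
    SAMPLES = cohort_samples(3, 7)  # I01..I03, TP1..7

    def _labels(self, ind, tps):
        return [f"{ind}_TP{t}" for t in tps]

    def test_survives_s1_to_s3_with_counterpart(self):
        # present 6/7 TPs in I01, absent elsewhere, counterpart allele in I02
        ev = build_evidence(
            {
                ("AAAAAAA", "G1", "ref", 5): self._labels("I01", range(1, 7)),
                ("CAAAAAA", "G1", "VAR_1", 5): self._labels("I02", range(1, 8)),
            },
            self.SAMPLES,
        )
        panel = filter_cascade(ev)
        assert panel.stage_counts == [2, 2, 2, 2, 2]
        assert {g.allele_id for g in panel.groups} == {"ref", "VAR_1"}

    def test_always_identified_dropped_at_s2(self):
        all_labels = [s.label for s in self.SAMPLES]
        ev = build_evidence(
            {
                ("AAAAAAA", "G1", "ref", 5): all_labels,
                ("CAAAAAA", "G1", "VAR_1", 5): self._labels("I02", range(1, 8)),
            },
            self.SAMPLES,
        )
        panel = filter_cascade(ev)
        # the always-present group passes S1, dies at S2; its counterpart
        # then dies at S3 for lack of an overlapping allele
        assert panel.stage_counts[0] == 2
        assert panel.stage_counts[1] == 1
        assert panel.stage_counts[2] == 0

    def test_never_identified_dropped(self):
        ev = build_evidence(
            {
                ("AAAAAAA", "G1", "ref", 5): [],
                ("CAAAAAA", "G1", "VAR_1", 5): self._labels("I01", range(1, 8)),
            },
            self.SAMPLES,
        )
        panel = filter_cascade(ev)
        assert panel.stage_counts[-1] == 0

    def test_no_counterpart_dropped_at_s3(self):
        ev = build_evidence(
            {("AAAAAAA", "G1", "ref", 5): self._labels("I01", range(1, 8))},
            self.SAMPLES,
        )
        panel = filter_cascade(ev)
        assert panel.stage_counts == [1, 1, 0, 0, 0]

    def test_s5_constructed_counts(self):
        # gene G1 at min_presence 4: ref allele has one 4-of-7-consistent
        # individual (I01, 4 ids) plus 81 scattered ids (3 per individual,
        # below the consistency band); the counterpart allele has one
        # consistent individual (I02, 4 ids).  Gene totals: 89 identified,
        # 8 consistent.  89 > 10 * 8 -> both alleles dropped at S5.
        samples = cohort_samples(30, 7)
        ref_labels = [f"I01_TP{t}" for t in range(1, 5)]
        scattered = [f"I{i:02d}_TP{t}" for i in range(3, 30) for t in range(1, 4)]
        assert len(scattered) == 81
        ev = build_evidence(
            {
                ("AAAAAAA", "G1", "ref", 5): ref_labels + scattered,
                ("CAAAAAA", "G1", "VAR_1", 5): [f"I02_TP{t}" for t in range(1, 5)],
            },
            samples,
        )
        relaxed = filter_cascade(
            ev, params=PanelFilterParams(min_presence=4, variation_ratio=100)
        )
        assert relaxed.stage_counts == [2, 2, 2, 2, 2]  # reaches and survives S5
        dropped = filter_cascade(
            ev, params=PanelFilterParams(min_presence=4, variation_ratio=10)
        )
        assert dropped.stage_counts == [2, 2, 2, 2, 0]

    def test_pure_filter_and_non_increasing(self, default_cohort):
        panel = filter_cascade(default_cohort.evidence)
        counts = panel.stage_counts
        assert all(b <= a for a, b in zip(counts, counts[1:]))
        all_keys = {g.key for g in groups_from_evidence(default_cohort.evidence)}
        assert {g.key for g in panel.groups} <= all_keys

    def test_monotone_in_min_presence_and_ratio(self, default_cohort):
        ev = default_cohort.evidence
        base = {g.key for g in filter_cascade(ev, params=PanelFilterParams()).groups}
        stricter_presence = {
            g.key
            for g in filter_cascade(ev, params=PanelFilterParams(min_presence=7)).groups
        }
        lower_ratio = {
            g.key
            for g in filter_cascade(ev, params=PanelFilterParams(variation_ratio=2)).groups
        }
        assert stricter_presence <= base
        assert lower_ratio <= base

    def test_erratic_genes_removed(self, default_cohort):
        panel = filter_cascade(default_cohort.evidence)
        panel_genes = {g.gene_id for g in panel.groups}
        assert panel_genes.isdisjoint(set(default_cohort.erratic_genes))

    def test_retains_diploid_consistent_loci(self, default_cohort):
        panel = filter_cascade(default_cohort.evidence)
        panel_genes = {g.gene_id for g in panel.groups}
        # informative loci: both alleles carried somewhere, neither fixed
        geno = default_cohort.genotypes
        consistent = []
        for locus in default_cohort.loci:
            if locus.erratic:
                continue
            copies = geno[locus.gene_id]
            if (copies > 0).any() and (copies < 2).any():
                consistent.append(locus.gene_id)
        retained = sum(1 for g in consistent if g in panel_genes)
        assert retained / len(consistent) >= 0.90


class TestAllelePanelSerialization:
    def test_json_roundtrip(self, default_cohort):
        panel = filter_cascade(default_cohort.evidence)
        back = AllelePanel.from_report_dict(panel.to_report_dict())
        assert [g.key for g in back.groups] == [g.key for g in panel.groups]
        assert back.stage_counts == panel.stage_counts

    def test_stage_counts_must_be_non_increasing(self):
        with pytest.raises(ValueError):
            AllelePanel(groups=[], stage_counts=[1, 2])

    def test_duplicate_groups_rejected(self):
        g = PeptideGroup("G1", "ref", 5, ["AAAAAAA"])
        with pytest.raises(ValueError):
            AllelePanel(groups=[g, PeptideGroup("G1", "ref", 5, ["CAAAAAA"])], stage_counts=[2])
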