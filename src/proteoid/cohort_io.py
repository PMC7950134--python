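"""Readers and writers for every external format the pipeline touches.

All tabular formats are plain TSV; sequences are FASTA (via Biopython);
reports and panels are JSON.  Readers validate strictly and name the
offending row or column in error messages.  Every read/write pair is a
lossless roundtrip on valid inputs, and sample order is preserved
end-to-end.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

AA_RE = re.compile(r"^[ACDEFGHIKLMNPQRSTVWY]+$")

__all__ = [
    "SampleKey",
    "IntensityMatrix",
    "EvidenceTable",
    "VariantRecord",
    "read_intensity_matrix",
    "write_intensity_matrix",
    "read_evidence_table",
    "write_evidence_table",
    "read_variant_table",
    "write_variant_table",
    "read_fasta",
    "write_fasta",
    "write_report",
    "round_percent",
]


@dataclass(frozen=True, order=True)
class SampleKey:
    """A cohort sample: one individual at one time point (TP)."""

    individual_id: str
    timepoint: int

    def __post_init__(self) -> None:
        if self.timepoint < 1:
            raise ValueError(f"timepoint must be >= 1, got {self.timepoint}")

    @property
    def label(self) -> str:
        """Canonical display form ``<individual_id>_TP<timepoint>``."""
        return f"{self.individual_id}_TP{self.timepoint}"

    @classmethod
    def from_label(cls, label: str) -> "SampleKey":
        ind, sep, tp = label.rpartition("_TP")
        if not sep or not tp.isdigit():
            raise ValueError(f"cannot parse sample label {label!r}")
        return cls(ind, int(tp))


@dataclass
class IntensityMatrix:
    """Proteins x samples linear-scale intensities with missing values.

    ``values`` is indexed by protein accession with one column per sample
    label; missing cells are NaN.  ``samples`` fixes the column order and
    carries the (individual, time point) annotation of each column.
    """

    values: pd.DataFrame
    samples: list[SampleKey]

    def __post_init__(self) -> None:
        labels = [s.label for s in self.samples]
        if len(set(labels)) != len(labels):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise ValueError(f"duplicate samples: {dupes}")
        if list(self.values.columns) != labels:
            raise ValueError("matrix columns do not match sample order")
        if self.values.index.duplicated().any():
            dupes = sorted(self.values.index[self.values.index.duplicated()])
            raise ValueError(f"duplicate protein ids: {dupes}")
        bad = (self.values <= 0).any(axis=1)
        if bad.any():
            raise ValueError(
                f"non-positive intensity for protein(s): {list(self.values.index[bad])}"
            )

    @property
    def protein_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def individuals(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.samples:
            seen.setdefault(s.individual_id, None)
        return list(seen)

    def samples_of(self, individual_id: str) -> list[SampleKey]:
        return [s for s in self.samples if s.individual_id == individual_id]

    def columns_of(self, individual_id: str) -> list[str]:
        return [s.label for s in self.samples_of(individual_id)]


@dataclass
class EvidenceTable:
    """Binary peptide-by-sample identification calls with allele labels.

    ``meta`` holds one row per (peptide_sequence, allele_id) with columns
    peptide_sequence, gene_id, protein_accession, allele_id, variant_site
    (nullable integer).  ``presence`` is a boolean frame aligned row-for-row
    with ``meta``, one column per sample label.  ``observed`` marks which
    (row, sample) cells were explicitly listed in the source file; cells
    never listed default to not-identified but can be treated as missing by
    a strict consumer.
    """

    meta: pd.DataFrame
    presence: pd.DataFrame
    samples: list[SampleKey]
    observed: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        labels = [s.label for s in self.samples]
        if list(self.presence.columns) != labels:
            raise ValueError("presence columns do not match sample order")
        if len(self.meta) != len(self.presence):
            raise ValueError("meta/presence row mismatch")
        keys = list(zip(self.meta["peptide_sequence"], self.meta["allele_id"]))
        if len(set(keys)) != len(keys):
            dupes = sorted({k for k in keys if keys.count(k) > 1})
            raise ValueError(f"duplicate (peptide, allele) rows: {dupes}")
        for seq in self.meta["peptide_sequence"]:
            if not AA_RE.match(str(seq)):
                raise ValueError(f"illegal peptide sequence {seq!r}")

    @property
    def sample_labels(self) -> list[str]:
        return [s.label for s in self.samples]

    def sample_map(self) -> dict[str, SampleKey]:
        return {s.label: s for s in self.samples}


@dataclass(frozen=True)
class VariantRecord:
    """A single-locus amino-acid substitution on a canonical sequence."""

    protein_accession: str
    position: int  # 1-based residue index on the canonical sequence
    ref_aa: str
    alt_aa: str
    variant_id: str

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"{self.variant_id}: position must be >= 1")
        if len(self.ref_aa) != len(self.alt_aa) or len(self.ref_aa) < 1:
            raise ValueError(
                f"{self.variant_id}: ref/alt length mismatch "
                f"({self.ref_aa!r} vs {self.alt_aa!r}); indels are unsupported"
            )
        for aa in (self.ref_aa, self.alt_aa):
            if not AA_RE.match(aa):
                raise ValueError(f"{self.variant_id}: illegal residue string {aa!r}")


# ---------------------------------------------------------------------------
# annotations + intensity matrix
# ---------------------------------------------------------------------------

def read_annotations(path: str | Path) -> dict[str, SampleKey]:
    """Read a sample-annotation TSV (sample_id, individual_id, timepoint)."""
    ann = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "individual_id": str})
    for col in ("sample_id", "individual_id", "timepoint"):
        if col not in ann.columns:
            raise ValueError(f"annotations missing column {col!r}")
    if ann["sample_id"].duplicated().any():
        dupes = sorted(ann.loc[ann["sample_id"].duplicated(), "sample_id"])
        raise ValueError(f"duplicate sample_id in annotations: {dupes}")
    out: dict[str, SampleKey] = {}
    for row in ann.itertuples(index=False):
        out[row.sample_id] = SampleKey(row.individual_id, int(row.timepoint))
    keys = list(out.values())
    if len(set(keys)) != len(keys):
        raise ValueError("duplicate (individual_id, timepoint) in annotations")
    return out


def write_annotations(samples: Sequence[SampleKey], path: str | Path) -> None:
    pd.DataFrame(
        {
            "sample_id": [s.label for s in samples],
            "individual_id": [s.individual_id for s in samples],
            "timepoint": [s.timepoint for s in samples],
        }
    ).to_csv(path, sep="\t", index=False)


def read_intensity_matrix(
    path_matrix: str | Path, path_annotations: str | Path
) -> IntensityMatrix:
    """Read a proteins x samples TSV plus its sample-annotation TSV.

    The matrix has a header row of sample ids and the first column holds
    protein accessions; empty cells and "NA" are missing.  Every matrix
    column must resolve to an annotated sample.
    """
    ann = read_annotations(path_annotations)
    values = pd.read_csv(
        path_matrix, sep="\t", index_col=0, na_values=["NA", ""], keep_default_na=False
    )
    values.columns = [str(c) for c in values.columns]
    values.index.name = None
    unknown = [c for c in values.columns if c not in ann]
    if unknown:
        raise ValueError(f"matrix column(s) not in annotations: {unknown}")
    values = values.astype(float)
    samples = [ann[c] for c in values.columns]
    return IntensityMatrix(values=values, samples=samples)


def write_intensity_matrix(
    matrix: IntensityMatrix, path_matrix: str | Path, path_annotations: str | Path
) -> None:
    out = matrix.values.copy()
    out.index.name = "protein_id"
    out.to_csv(path_matrix, sep="\t", na_rep="NA")
    write_annotations(matrix.samples, path_annotations)


# ---------------------------------------------------------------------------
# evidence table
# ---------------------------------------------------------------------------

_EVIDENCE_COLS = [
    "peptide_sequence",
    "gene_id",
    "protein_accession",
    "allele_id",
    "variant_site",
    "sample_id",
    "identified",
]


def read_evidence_table(
    path: str | Path, samples: Sequence[SampleKey] | None = None
) -> EvidenceTable:
    """Read long-format peptide identification evidence.

    Columns: peptide_sequence, gene_id, protein_accession, allele_id,
    variant_site (may be empty), sample_id, identified (0/1).  Missing
    (peptide, sample) combinations default to not-identified.  When
    ``samples`` is omitted the cohort is inferred from the sample ids,
    which must follow the ``<individual>_TP<k>`` convention.
    """
    long = pd.read_csv(
        path,
        sep="\t",
        dtype={
            "peptide_sequence": str,
            "gene_id": str,
            "protein_accession": str,
            "allele_id": str,
            "sample_id": str,
        },
        na_values=["NA"],
        keep_default_na=False,
    )
    for col in _EVIDENCE_COLS:
        if col not in long.columns:
            raise ValueError(f"evidence missing column {col!r}")
    bad_ident = ~long["identified"].isin([0, 1, "0", "1"])
    if bad_ident.any():
        vals = sorted({str(v) for v in long.loc[bad_ident, "identified"]})
        raise ValueError(f"identified values outside {{0,1}}: {vals}")
    long["identified"] = long["identified"].astype(int)
    for seq in long["peptide_sequence"].unique():
        if not AA_RE.match(str(seq)):
            raise ValueError(f"illegal peptide sequence {seq!r}")

    if samples is None:
        seen: dict[str, SampleKey] = {}
        for sid in long["sample_id"]:
            if sid not in seen:
                seen[sid] = SampleKey.from_label(sid)
        samples = list(seen.values())
    smap = {s.label: s for s in samples}
    unknown = sorted(set(long["sample_id"]) - set(smap))
    if unknown:
        raise ValueError(f"evidence references unannotated sample(s): {unknown}")

    conflicts = (
        long.groupby(["peptide_sequence", "allele_id", "sample_id"])["identified"]
        .nunique()
    )
    if (conflicts > 1).any():
        bad = list(conflicts[conflicts > 1].index[:5])
        raise ValueError(f"conflicting duplicate evidence rows: {bad}")

    labels = [s.label for s in samples]
    meta = (
        long[["peptide_sequence", "gene_id", "protein_accession", "allele_id", "variant_site"]]
        .drop_duplicates(subset=["peptide_sequence", "allele_id"])
        .reset_index(drop=True)
    )
    meta["variant_site"] = pd.array(
        [int(v) if pd.notna(v) and str(v) != "" else pd.NA for v in meta["variant_site"]],
        dtype="Int64",
    )
    n = len(meta)
    row_of = {
        (p, a): i
        for i, (p, a) in enumerate(zip(meta["peptide_sequence"], meta["allele_id"]))
    }
    col_of = {lab: j for j, lab in enumerate(labels)}
    pres = np.zeros((n, len(labels)), dtype=bool)
    obs = np.zeros((n, len(labels)), dtype=bool)
    for row in long.itertuples(index=False):
        i = row_of[(row.peptide_sequence, row.allele_id)]
        j = col_of[row.sample_id]
        pres[i, j] = pres[i, j] or bool(row.identified)
        obs[i, j] = True
    presence = pd.DataFrame(pres, columns=labels)
    observed = pd.DataFrame(obs, columns=labels)
    return EvidenceTable(meta=meta, presence=presence, samples=list(samples), observed=observed)


def write_evidence_table(table: EvidenceTable, path: str | Path) -> None:
    """Write evidence in long format, one row per (peptide, sample)."""
    labels = table.sample_labels
    rows = []
    for i, m in table.meta.iterrows():
        site = "" if pd.isna(m["variant_site"]) else int(m["variant_site"])
        for j, lab in enumerate(labels):
            rows.append(
                (
                    m["peptide_sequence"],
                    m["gene_id"],
                    m["protein_accession"],
                    m["allele_id"],
                    site,
                    lab,
                    int(table.presence.iat[i, j]),
                )
            )
    pd.DataFrame(rows, columns=_EVIDENCE_COLS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# variant table
# ---------------------------------------------------------------------------

def read_variant_table(path: str | Path) -> list[VariantRecord]:
    """Read a substitution table (accession, position, ref, alt, variant_id)."""
    tab = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("accession", "position", "ref", "alt", "variant_id"):
        if col not in tab.columns:
            raise ValueError(f"variant table missing column {col!r}")
    records = []
    for row in tab.itertuples(index=False):
        records.append(
            VariantRecord(
                protein_accession=row.accession,
                position=int(row.position),
                ref_aa=row.ref,
                alt_aa=row.alt,
                variant_id=row.variant_id,
            )
        )
    return records


def write_variant_table(records: Iterable[VariantRecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            (r.protein_accession, r.position, r.ref_aa, r.alt_aa, r.variant_id)
            for r in records
        ],
        columns=["accession", "position", "ref", "alt", "variant_id"],
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read FASTA into (header, sequence) pairs; sequences uppercased."""
    records = []
    headers = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        header = rec.description
        seq = str(rec.seq).upper()
        if not seq:
            raise ValueError(f"empty sequence for header {header!r}")
        if header in headers:
            raise ValueError(f"header collision: {header!r}")
        headers.add(header)
        records.append((header, seq))
    return records


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    headers = set()
    out = []
    for header, seq in records:
        if not seq:
            raise ValueError(f"empty sequence for header {header!r}")
        if header in headers:
            raise ValueError(f"header collision: {header!r}")
        headers.add(header)
        name = header.split()[0] if header.split() else header
        rec = SeqRecord(Seq(seq.upper()), id=name, description=header)
        # SeqIO prepends id to description; keep the exact header instead
        rec.id = header
        rec.description = ""
        out.append(rec)
    SeqIO.write(out, str(path), "fasta")


def variant_fasta_header(canonical_header: str, accession: str, variant_id: str) -> str:
    """Header for a variant sequence: canonical header + ``<accession>|<variant_id>``."""
    return f"{canonical_header} {accession}|{variant_id}"


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------

def round_percent(x: float) -> float:
    """Round a percentage half-up to one decimal place."""
    return float(Decimal(repr(float(x))).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def _jsonable(obj):
    if hasattr(obj, "to_report_dict"):
        return _jsonable(obj.to_report_dict())
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, SampleKey):
        return obj.label
    if isinstance(obj, pd.DataFrame):
        return {str(i): _jsonable(row.to_dict()) for i, row in obj.iterrows()}
    if obj is None or isinstance(obj, (str, int, float, bool)):
        return obj
    return str(obj)


def write_report(results: dict, out_dir: str | Path) -> tuple[Path, Path]:
    """Write a machine-readable JSON report plus a human-readable TSV summary.

    ``results`` maps section names to result objects (assignment results,
    panels, marker flags, ...).  Objects exposing ``to_report_dict`` are
    serialized through it.  Percentages in the TSV are shown to one decimal.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    payload = _jsonable(results)
    json_path = out_dir / "report.json"
    with open(json_path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")

    lines = [("section", "key", "value")]
    for section, content in payload.items():
        if isinstance(content, dict):
            summary = content.get("summary", content)
            if isinstance(summary, dict):
                for k, v in summary.items():
                    if isinstance(v, float) and ("percent" in k or "rate" in k):
                        v = f"{round_percent(v):.1f}"
                    lines.append((section, k, v))
            else:
                lines.append((section, "value", summary))
        elif isinstance(content, list):
            lines.append((section, "n_rows", len(content)))
        else:
            lines.append((section, "value", content))
    tsv_path = out_dir / "summary.tsv"
    with open(tsv_path, "w") as fh:
        for row in lines:
            fh.write("\t".join(str(x) for x in row) + "\n")
    return json_path, tsv_path
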