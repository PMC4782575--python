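"""Readers and writers for the external formats the pipeline touches.

FASTQ is fixed to Sanger Phred+33 (platform exports in other encodings must
be converted upstream).  All report tables are TSV with a fixed column order
so reruns diff cleanly.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
from Bio import SeqIO
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from ._seq import is_acgt

MAX_PHRED = 93


class ParseError(ValueError):
    """Raised when an input file violates its format contract."""


class ValidationError(ValueError):
    """Raised when a parsed input violates a semantic invariant."""


@dataclass
class SequencedRead:
    """One raw read with per-base Phred qualities."""

    read_id: str
    bases: str
    quals: list[int]
    run_id: str = ""

    def __post_init__(self) -> None:
        if len(self.bases) != len(self.quals):
            raise ValidationError(
                f"read {self.read_id!r}: {len(self.bases)} bases but "
                f"{len(self.quals)} quality scores"
            )
        if any(q < 0 or q > MAX_PHRED for q in self.quals):
            raise ValidationError(f"read {self.read_id!r}: Phred score outside [0, {MAX_PHRED}]")

    def __len__(self) -> int:
        return len(self.bases)


@dataclass(frozen=True)
class SampleSheetEntry:
    forward_mid: str
    reverse_mid: str
    individual_id: str
    replicate_id: str
    run_id: str


@dataclass
class SampleSheet:
    """Barcode-combination -> (individual, replicate, run) mapping."""

    entries: list[SampleSheetEntry]

    def __post_init__(self) -> None:
        seen: dict[tuple[str, str, str], SampleSheetEntry] = {}
        for e in self.entries:
            for mid in (e.forward_mid, e.reverse_mid):
                if not mid or not is_acgt(mid):
                    raise ValidationError(
                        f"MID {mid!r} of {e.individual_id}/{e.replicate_id} is not a "
                        "plain ACGT string (ambiguity codes are not allowed in barcodes)"
                    )
            key = (e.forward_mid, e.reverse_mid, e.run_id)
            if key in seen:
                raise ValidationError(
                    f"duplicate barcode combination {key} used by both "
                    f"{seen[key].individual_id}/{seen[key].replicate_id} and "
                    f"{e.individual_id}/{e.replicate_id}"
                )
            seen[key] = e

    def lookup(self) -> dict[tuple[str, str, str], SampleSheetEntry]:
        return {(e.forward_mid, e.reverse_mid, e.run_id): e for e in self.entries}

    @property
    def individuals(self) -> list[str]:
        out: list[str] = []
        for e in self.entries:
            if e.individual_id not in out:
                out.append(e.individual_id)
        return out


@dataclass
class AlleleCatalog:
    """Ordered, named reference/called allele sequences for one locus."""

    alleles: dict[str, str] = field(default_factory=dict)
    locus_tag: str = "DRB"

    def __post_init__(self) -> None:
        seqs = list(self.alleles.values())
        if any(not s for s in seqs):
            raise ValidationError("allele catalog contains an empty sequence")
        if len(set(seqs)) != len(seqs):
            raise ValidationError("allele catalog contains duplicate sequences")

    def name_of(self, sequence: str) -> str | None:
        for name, seq in self.alleles.items():
            if seq == sequence:
                return name
        return None

    def next_number(self) -> int:
        """Next ordinal for a novel allele name, continuing any *NN suffixes."""
        best = len(self.alleles)
        for name in self.alleles:
            tail = name.rsplit("*", 1)[-1]
            if tail.isdigit():
                best = max(best, int(tail))
        return best + 1

    def add_novel(self, sequence: str) -> str:
        num = self.next_number()
        name = f"{self.locus_tag}*{num:02d}"
        self.alleles[name] = sequence
        return name


# ---------------------------------------------------------------------------
# FASTQ / FASTA
# ---------------------------------------------------------------------------

def parse_fastq(path: str | os.PathLike, run_id: str = "") -> Iterator[SequencedRead]:
    """Stream Sanger-encoded FASTQ records as :class:`SequencedRead`.

    Malformed records raise :class:`ParseError` naming the 0-based record
    index at which parsing failed.
    """
    index = 0
    try:
        with open(path) as handle:
            for title, seq, qual in FastqGeneralIterator(handle):
                if len(seq) != len(qual):
                    raise ParseError(
                        f"record {index} ({title.split()[0]}): sequence and "
                        "quality strings differ in length"
                    )
                quals = [ord(c) - 33 for c in qual]
                if any(q < 0 or q > MAX_PHRED for q in quals):
                    raise ParseError(
                        f"record {index} ({title.split()[0]}): quality character "
                        "outside the Sanger Phred+33 range"
                    )
                yield SequencedRead(title.split()[0], seq.upper(), quals, run_id)
                index += 1
    except ValueError as exc:
        if isinstance(exc, (ParseError, ValidationError)):
            raise
        raise ParseError(f"record {index}: {exc}") from exc


def write_fastq(reads: Iterable[SequencedRead], path: str | os.PathLike) -> None:
    with open(path, "w") as handle:
        for r in reads:
            qual = "".join(chr(q + 33) for q in r.quals)
            handle.write(f"@{r.read_id}\n{r.bases}\n+\n{qual}\n")


def parse_fasta(path: str | os.PathLike, locus_tag: str = "DRB") -> AlleleCatalog:
    alleles: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in alleles:
            raise ValidationError(f"duplicate FASTA record name {rec.id!r}")
        alleles[rec.id] = str(rec.seq).upper()
    return AlleleCatalog(alleles=alleles, locus_tag=locus_tag)


def write_fasta(catalog: AlleleCatalog, path: str | os.PathLike) -> None:
    with open(path, "w") as handle:
        for name, seq in catalog.alleles.items():
            handle.write(f">{name}\n{seq}\n")


# ---------------------------------------------------------------------------
# Sample sheet
# ---------------------------------------------------------------------------

SAMPLE_SHEET_COLUMNS = ["forward_mid", "reverse_mid", "individual_id", "replicate_id", "run_id"]


def parse_sample_sheet(path: str | os.PathLike) -> SampleSheet:
    """Read the tab-separated barcode/sample mapping (header row required)."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    missing = [c for c in SAMPLE_SHEET_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"sample sheet is missing columns: {', '.join(missing)}")
    entries = [
        SampleSheetEntry(
            r.forward_mid.upper(), r.reverse_mid.upper(),
            r.individual_id, r.replicate_id, r.run_id,
        )
        for r in df.itertuples()
    ]
    return SampleSheet(entries=entries)


def write_sample_sheet(sheet: SampleSheet, path: str | os.PathLike) -> None:
    df = pd.DataFrame(
        [[e.forward_mid, e.reverse_mid, e.individual_id, e.replicate_id, e.run_id]
         for e in sheet.entries],
        columns=SAMPLE_SHEET_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Report tables
# ---------------------------------------------------------------------------

GENOTYPE_COLUMNS = [
    "individual_id", "status", "n_alleles", "allele_names",
    "total_reads", "n_replicates_used",
]


def write_genotype_table(genotypes, path: str | os.PathLike) -> None:
    """TSV genotype report, one row per individual (incl. failed ones).

    Allele names are comma-joined in sorted order; individuals below the
    read threshold keep status ``insufficient_reads`` with empty counts.
    """
    rows = []
    for g in genotypes:
        if g.status == "genotyped":
            rows.append([
                g.individual_id, g.status, len(g.allele_names),
                ",".join(sorted(g.allele_names)),
                g.total_reads, g.n_replicates_used,
            ])
        else:
            rows.append([g.individual_id, g.status, "", "", g.total_reads, 0])
    pd.DataFrame(rows, columns=GENOTYPE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_genotype_table(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"individual_id": str, "allele_names": str})


def write_tsv(df: pd.DataFrame, path: str | os.PathLike) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)
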