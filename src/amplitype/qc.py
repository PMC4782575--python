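"""Step I: read filtering, primer/MID location, demultiplexing, locus screen.

Whole reads are accepted or rejected — there is no quality trimming.  The
filter order is fixed (length -> quality -> primer/MID -> reference screen)
and every stage keeps counters so attrition tables reconcile exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import edlib

from ._seq import iupac_mismatches, revcomp
from .io import AlleleCatalog, SampleSheet, SequencedRead

# degenerate site-specific DRB exon-2 primer sequences (5'->3')
DEFAULT_FORWARD_PRIMER = "GAGTGTCATTTCTWCAACGGGACG"
DEFAULT_REVERSE_PRIMER = "GATCCCGTAGTTGTGTCTGCA"

REJECT_TOO_SHORT = "too_short"
REJECT_TOO_LONG = "too_long"
REJECT_LOW_QUALITY = "low_quality"
REJECT_MISSING_TAG = "missing_tag"
REJECT_REFERENCE = "reference_mismatch"
UNASSIGNED = "unassigned"


@dataclass
class QcConfig:
    """Step-I thresholds.

    Defaults follow the published workflow: discard reads shorter than
    150 bp or longer than 400 bp, or with more than 5 % of bases below
    Phred 20; demand complete 10-bp MIDs plus site-specific primers at
    both ends; and require >= 80 % identity to a published reference.
    """

    min_len: int = 150
    max_len: int = 400
    max_low_qual_fraction: float = 0.05
    qual_floor: int = 20
    mid_len: int = 10
    max_primer_mismatches: int = 0
    min_reference_identity: float = 0.80

    def __post_init__(self) -> None:
        if not (0 < self.min_len <= self.max_len):
            raise ValueError("require 0 < min_len <= max_len")
        if not (0.0 <= self.max_low_qual_fraction <= 1.0):
            raise ValueError("max_low_qual_fraction must be a proportion")


@dataclass
class Amplicon:
    """All retained, trimmed inserts for one (individual, replicate, run)."""

    individual_id: str
    replicate_id: str
    run_id: str
    inserts: list[tuple[str, list[int]]] = field(default_factory=list)

    @property
    def depth(self) -> int:
        return len(self.inserts)

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.individual_id, self.replicate_id, self.run_id)


def filter_read(read: SequencedRead, config: QcConfig) -> tuple[bool, str | None]:
    """Length/quality accept-reject decision; returns (keep, reject_reason)."""
    n = len(read)
    if n < config.min_len:
        return False, REJECT_TOO_SHORT
    if n > config.max_len:
        return False, REJECT_TOO_LONG
    n_low = sum(q < config.qual_floor for q in read.quals)
    if n_low / n > config.max_low_qual_fraction:
        return False, REJECT_LOW_QUALITY
    return True, None


def _find_tags(bases: str, quals: list[int], fwd: str, rev: str, mid_len: int,
               max_mm: int) -> tuple[str, list[int], str, str] | None:
    """Try to locate MID+fwd_primer ... revcomp(rev_primer)+revcomp(MID)."""
    lf, lr = len(fwd), len(rev)
    if len(bases) < mid_len + lf + lr + mid_len + 1:
        return None
    head = bases[mid_len:mid_len + lf]
    rc_rev = revcomp(rev)
    tail = bases[-(mid_len + lr):-mid_len]
    if iupac_mismatches(fwd, head) > max_mm:
        return None
    if iupac_mismatches(rc_rev, tail) > max_mm:
        return None
    fmid = bases[:mid_len]
    rmid = revcomp(bases[-mid_len:])
    insert = bases[mid_len + lf:-(mid_len + lr)]
    iq = quals[mid_len + lf:len(quals) - (mid_len + lr)]
    if not insert:
        return None
    return insert, iq, fmid, rmid


def locate_and_trim(read: SequencedRead, forward_primer: str, reverse_primer: str,
                    config: QcConfig):
    """Recover the primer-enclosed insert and its MID pair, or reject.

    Tries the read as given and then its reverse complement, so output
    inserts are canonicalized to forward orientation.  Returns
    ``(insert, insert_quals, forward_mid, reverse_mid)`` or ``None``
    (reason: missing_tag).
    """
    fwd = forward_primer.upper()
    rev = reverse_primer.upper()
    hit = _find_tags(read.bases, read.quals, fwd, rev, config.mid_len,
                     config.max_primer_mismatches)
    if hit is None:
        hit = _find_tags(revcomp(read.bases), read.quals[::-1], fwd, rev,
                         config.mid_len, config.max_primer_mismatches)
    return hit


def demultiplex(tagged_reads, sheet: SampleSheet) -> tuple[dict, int]:
    """Assign trimmed reads to amplicons by exact barcode-combination match.

    ``tagged_reads`` yields (insert, quals, forward_mid, reverse_mid, run_id).
    Returns (amplicons keyed by (individual, replicate, run), n_unassigned).
    MID matching is exact: a read whose pair matches no sheet entry for its
    run is counted unassigned and discarded.
    """
    lookup = sheet.lookup()
    amplicons: dict[tuple[str, str, str], Amplicon] = {}
    unassigned = 0
    for insert, quals, fmid, rmid, run_id in tagged_reads:
        entry = lookup.get((fmid, rmid, run_id))
        if entry is None:
            unassigned += 1
            continue
        key = (entry.individual_id, entry.replicate_id, entry.run_id)
        amp = amplicons.get(key)
        if amp is None:
            amp = amplicons[key] = Amplicon(*key)
        amp.inserts.append((insert, quals))
    return amplicons, unassigned


def alignment_identity(a: str, b: str) -> float:
    """Identity of the unit-cost global (NW) alignment: matches / columns."""
    res = edlib.align(a, b, mode="NW", task="path")
    matches = columns = 0
    num = ""
    for ch in res["cigar"]:
        if ch.isdigit():
            num += ch
        else:
            n = int(num)
            num = ""
            columns += n
            if ch == "=":
                matches += n
    return matches / columns if columns else 0.0


def reference_screen(insert: str, catalog: AlleleCatalog, config: QcConfig) -> bool:
    """Keep iff best identity against any catalog sequence >= threshold."""
    refs = tuple(catalog.alleles.values())
    if not refs:
        raise ValueError("reference catalog is empty")
    return _best_identity(insert, refs) >= config.min_reference_identity


@lru_cache(maxsize=200_000)
def _best_identity(insert: str, refs: tuple[str, ...]) -> float:
    return max(alignment_identity(insert, ref) for ref in refs)


@dataclass
class QcCounters:
    """Per-run attrition accounting (reads in == kept + rejected + unassigned)."""

    reads_in: int = 0
    kept: int = 0
    rejected: dict[str, int] = field(default_factory=dict)
    unassigned: int = 0

    def reject(self, reason: str) -> None:
        self.rejected[reason] = self.rejected.get(reason, 0) + 1

    @property
    def total_rejected(self) -> int:
        return sum(self.rejected.values())

    def reconciles(self) -> bool:
        return self.reads_in == self.kept + self.total_rejected + self.unassigned


def run_qc(reads, sheet: SampleSheet, catalog: AlleleCatalog,
           forward_primer: str, reverse_primer: str,
           config: QcConfig | None = None) -> tuple[dict, dict[str, QcCounters]]:
    """Full Step I over a read stream; returns (amplicons, per-run counters).

    Stages run in the fixed order length -> quality -> primer/MID ->
    barcode assignment -> reference screen; a read is charged to the first
    stage that rejects it.
    """
    config = config or QcConfig()
    counters: dict[str, QcCounters] = {}
    tagged = []
    for read in reads:
        c = counters.setdefault(read.run_id, QcCounters())
        c.reads_in += 1
        keep, reason = filter_read(read, config)
        if not keep:
            c.reject(reason)
            continue
        hit = locate_and_trim(read, forward_primer, reverse_primer, config)
        if hit is None:
            c.reject(REJECT_MISSING_TAG)
            continue
        insert, iq, fmid, rmid = hit
        if not reference_screen(insert, catalog, config):
            c.reject(REJECT_REFERENCE)
            continue
        tagged.append((insert, iq, fmid, rmid, read.run_id))

    lookup = sheet.lookup()
    amplicons: dict[tuple[str, str, str], Amplicon] = {}
    for insert, iq, fmid, rmid, run_id in tagged:
        entry = lookup.get((fmid, rmid, run_id))
        c = counters.setdefault(run_id, QcCounters())
        if entry is None:
            c.unassigned += 1
            continue
        key = (entry.individual_id, entry.replicate_id, entry.run_id)
        amp = amplicons.get(key)
        if amp is None:
            amp = amplicons[key] = Amplicon(*key)
        amp.inserts.append((insert, iq))
        c.kept += 1
    return amplicons, counters
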