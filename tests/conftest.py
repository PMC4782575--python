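"""Shared fixtures and builders for synthetic reads and amplicons."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from amplitype.io import SampleSheet, SampleSheetEntry, SequencedRead
from amplitype.qc import Amplicon

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

# concrete primer pair used by hand-built reads (forward primer carries a W
# in its degenerate form; here we embed the T expansion)
FWD_DEGENERATE = "GAGTGTCATTTCTWCAACGGGACG"
FWD_CONCRETE = "GAGTGTCATTTCTTCAACGGGACG"
REV = "GATCCCGTAGTTGTGTCTGCA"

_COMP = str.maketrans("ACGT", "TGCA")


def rc(s: str) -> str:
    return s.translate(_COMP)[::-1]


def make_read(insert: str, fmid: str = "ACGTACGTAC", rmid: str = "TGCATGCATG",
              qual: int = 35, read_id: str = "r1", run_id: str = "run1",
              fwd: str = FWD_CONCRETE, rev: str = REV) -> SequencedRead:
    """Fuse MIDs + primers around an insert the way the platforms see it."""
    bases = fmid + fwd + insert + rc(rmid + rev)
    return SequencedRead(read_id, bases, [qual] * len(bases), run_id)


def make_amplicon(inserts: dict[str, int] | list[str],
                  individual_id: str = "ind1", replicate_id: str = "rep1",
                  run_id: str = "run1", qual: int = 35) -> Amplicon:
    """Amplicon from {sequence: count} (or a plain list of sequences)."""
    if isinstance(inserts, dict):
        seqs = [s for s, n in inserts.items() for _ in range(n)]
    else:
        seqs = list(inserts)
    return Amplicon(individual_id, replicate_id, run_id,
                    inserts=[(s, [qual] * len(s)) for s in seqs])


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_sheet():
    return SampleSheet(entries=[
        SampleSheetEntry("ACGTACGTAC", "TGCATGCATG", "ind1", "rep1", "run1"),
        SampleSheetEntry("GGGGTTTTCC", "TGCATGCATG", "ind1", "rep2", "run1"),
        SampleSheetEntry("AACCGGTTAA", "CCAATTGGCC", "ind2", "rep1", "run1"),
    ])
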