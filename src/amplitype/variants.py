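"""Step II: collapse reads into variants, distances, chimera flagging.

Chimera calling is a deterministic single-crossover, two-parent rule with an
abundance-skew gate, a simplification of de-novo chimera detectors suited to
a fixed-length locus: a candidate is chimeric when some prefix matches one
higher-count parent and the complementary suffix matches another.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import edlib

from ._seq import hamming
from .qc import Amplicon

INTRA_MOST_FREQUENT = "most_frequent"
INTRA_DIFF_1_2BP = "diff_1_2bp"
INTRA_DIFF_GT2BP = "diff_gt2bp"
INTRA_CHIMERA = "chimera_candidate"
INTRA_SINGLETON = "singleton_discarded"
INTRA_LOW_FREQ = "below_min_freq"


@dataclass
class Variant:
    """A unique insert sequence within one amplicon."""

    sequence: str
    count: int
    rel_freq: float
    amplicon_key: tuple[str, str, str]
    intra_class: str | None = None
    parent: str | None = None  # nearest higher-count variant (artifact parent)
    chimera: "ChimeraCall | None" = None


@dataclass
class ChimeraCall:
    candidate: str
    parent_a: str
    parent_b: str
    breakpoint: int  # 0-based first position taken from parent_b


def cluster_reads(amplicon: Amplicon) -> list[Variant]:
    """Collapse identical inserts into variants, most frequent first.

    Relative frequencies use the full pre-discard depth (singletons
    included in the denominator).  Count ties break lexicographically by
    sequence.  Singletons are returned marked ``singleton_discarded`` so
    attrition stays auditable, but take no further part in classification.
    """
    if amplicon.depth < 1:
        raise ValueError("cannot cluster an empty amplicon")
    counts = Counter(seq for seq, _ in amplicon.inserts)
    depth = amplicon.depth
    variants = [
        Variant(seq, n, n / depth, amplicon.key)
        for seq, n in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    ]
    for v in variants:
        if v.count == 1:
            v.intra_class = INTRA_SINGLETON
    return variants


def variant_distance(a: str, b: str) -> int:
    """bp differences: Hamming for equal lengths, else unit-cost edit distance."""
    if not a or not b:
        raise ValueError("variant_distance requires non-empty sequences")
    if len(a) == len(b):
        return hamming(a, b)
    return edlib.align(a, b, mode="NW", task="distance")["editDistance"]


def _common_prefix(a: str, b: str) -> int:
    n = 0
    for x, y in zip(a, b):
        if x != y:
            break
        n += 1
    return n


def flag_chimeras(variants: list[Variant], skew: float = 2.0,
                  min_diff_each_side: int = 1) -> list[ChimeraCall]:
    """Flag single-crossover two-parent chimeras among sorted variants.

    A candidate is flagged iff two distinct equal-length higher-count
    parents exist, each with count >= skew x candidate count, and a
    breakpoint k has candidate[:k] == parent_a[:k], candidate[k:] ==
    parent_b[k:], with >= ``min_diff_each_side`` differences from parent_a
    in the suffix and from parent_b in the prefix.  The smallest qualifying
    k is reported (parent pairs scanned in descending-count order).
    """
    active = [v for v in variants if v.intra_class != INTRA_SINGLETON]
    calls: list[ChimeraCall] = []
    for ci, cand in enumerate(active):
        L = len(cand.sequence)
        parents = [
            p for p in active[:ci]
            if len(p.sequence) == L
            and p.count >= skew * cand.count
            and p.sequence != cand.sequence
        ]
        best: ChimeraCall | None = None
        for pa in parents:
            lcp = _common_prefix(cand.sequence, pa.sequence)
            for pb in parents:
                if pb is pa:
                    continue
                lcs = _common_prefix(cand.sequence[::-1], pb.sequence[::-1])
                # valid k: candidate[:k]==pa[:k] (k<=lcp), candidate[k:]==pb[k:]
                # (k>=L-lcs); crossover needs 1<=k<=L-1
                lo, hi = max(1, L - lcs), min(lcp, L - 1)
                for k in range(lo, hi + 1):
                    if hamming(cand.sequence[k:], pa.sequence[k:]) < min_diff_each_side:
                        continue
                    if hamming(cand.sequence[:k], pb.sequence[:k]) < min_diff_each_side:
                        continue
                    if best is None or k < best.breakpoint:
                        best = ChimeraCall(cand.sequence, pa.sequence, pb.sequence, k)
                    break  # smallest k for this parent pair
        if best is not None:
            cand.chimera = best
            calls.append(best)
    return calls


@dataclass
class AmpliconVariants:
    """Clustered + chimera-annotated view of one amplicon."""

    amplicon: Amplicon
    variants: list[Variant] = field(default_factory=list)
    chimera_calls: list[ChimeraCall] = field(default_factory=list)

    @property
    def classifiable(self) -> list[Variant]:
        return [v for v in self.variants if v.intra_class != INTRA_SINGLETON]


def collapse_amplicon(amplicon: Amplicon, skew: float = 2.0,
                      min_diff_each_side: int = 1) -> AmpliconVariants:
    variants = cluster_reads(amplicon)
    calls = flag_chimeras(variants, skew=skew, min_diff_each_side=min_diff_each_side)
    return AmpliconVariants(amplicon, variants, calls)
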