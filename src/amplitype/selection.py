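"""Molecular-evolution statistics on a called allele set.

Implements variable-site counts, mean pairwise differences, Nei-Gojobori
(1986) pathway-counting dN/dS with codon-bootstrap standard errors, the
one-tailed codon-based Z-test of positive selection (dN > dS), and the
per-codon amino-acid frequency matrix behind sequence logos.

Conventions (documented, fixed):

* site counting — each codon contributes exactly three sites; a one-step
  change creating a stop codon counts as nonsynonymous;
* multi-substitution codons — synonymous/nonsynonymous differences are
  averaged over all minimal mutational pathways with equal weights
  (pathways through stop intermediates are not excluded);
* ambiguity codes / gaps — pairwise deletion: a codon column is skipped
  for a pair when either sequence carries a non-ACGT character there;
* distances — raw proportions pN = Nd/N, pS = Sd/S and Jukes-Cantor
  corrected d = -3/4 ln(1 - 4p/3); the corrected form is undefined for
  p >= 3/4 and flagged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from itertools import combinations, permutations

import numpy as np
from scipy.stats import norm

from ._seq import is_acgt
from .io import AlleleCatalog

_BASES = "ACGT"
_STANDARD_TABLE = {}  # codon -> amino acid, '*' for stop


def _build_codon_table() -> dict[str, str]:
    from Bio.Data.CodonTable import standard_dna_table

    table = dict(standard_dna_table.forward_table)
    for stop in standard_dna_table.stop_codons:
        table[stop] = "*"
    return table


_STANDARD_TABLE = _build_codon_table()


def translate_codon(codon: str) -> str:
    return _STANDARD_TABLE[codon]


class StopCodonError(ValueError):
    """An in-frame stop codon where a coding sequence was required."""


@dataclass
class CodonAlignment:
    """Equal-length coding sequences with an antigen-binding-site mask."""

    names: list[str]
    sequences: list[str]
    frame_offset: int = 0
    abs_mask: set[int] = field(default_factory=set)  # 1-based codon indices

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            raise ValueError("sequences must all have the same length")
        if self.frame_offset not in (0, 1, 2):
            raise ValueError("frame_offset must be 0, 1 or 2")
        bad = self.abs_mask - set(range(1, self.n_codons + 1))
        if bad:
            raise ValueError(f"ABS mask indices outside 1..{self.n_codons}: {sorted(bad)}")

    @property
    def seq_length(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0

    @property
    def n_codons(self) -> int:
        return (self.seq_length - self.frame_offset) // 3

    def codons(self, i: int) -> list[str]:
        """Codon list of sequence i over the analyzed in-frame window."""
        s = self.sequences[i]
        off = self.frame_offset
        return [s[off + 3 * k: off + 3 * k + 3] for k in range(self.n_codons)]

    def check_no_stops(self) -> None:
        for i, name in enumerate(self.names):
            for k, codon in enumerate(self.codons(i)):
                if is_acgt(codon) and translate_codon(codon) == "*":
                    raise StopCodonError(f"stop codon in {name} at codon {k + 1}")

    def region_codons(self, region: str) -> list[int]:
        """0-based codon indices of 'all' | 'ABS' | 'nonABS'."""
        allc = list(range(self.n_codons))
        if region == "all":
            return allc
        if not self.abs_mask:
            raise ValueError(f"region {region!r} requires an ABS mask")
        mask0 = {i - 1 for i in self.abs_mask}
        if region == "ABS":
            return [i for i in allc if i in mask0]
        if region == "nonABS":
            return [i for i in allc if i not in mask0]
        raise ValueError(f"unknown region {region!r}")

    @classmethod
    def from_catalog(cls, catalog: AlleleCatalog, frame_offset: int = 0,
                     abs_mask: set[int] | None = None) -> "CodonAlignment":
        return cls(names=list(catalog.alleles.keys()),
                   sequences=[s.upper() for s in catalog.alleles.values()],
                   frame_offset=frame_offset, abs_mask=abs_mask or set())


def load_abs_mask(path=None) -> set[int]:
    """Read 1-based ABS codon indices, one per line ('#' comments allowed).

    With no path, loads the shipped consensus-derived human-DRB mask
    (synthetic approximation; override with a locus-specific file).
    """
    if path is None:
        text = resources.files("amplitype.data").joinpath(
            "abs_mask_drb_consensus_synthetic.txt").read_text()
    else:
        text = open(path).read()
    mask: set[int] = set()
    for line in text.splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            mask.add(int(line))
    return mask


# ---------------------------------------------------------------------------
# Site-level summaries
# ---------------------------------------------------------------------------

def _aa_matrix(alignment: CodonAlignment) -> list[list[str]]:
    """Per-sequence amino acids; raises on in-frame stops."""
    out = []
    for i, name in enumerate(alignment.names):
        row = []
        for k, codon in enumerate(alignment.codons(i)):
            if not is_acgt(codon):
                row.append(None)
                continue
            aa = translate_codon(codon)
            if aa == "*":
                raise StopCodonError(f"stop codon in {name} at codon {k + 1}")
            row.append(aa)
        out.append(row)
    return out


def count_variable_sites(alignment: CodonAlignment,
                         level: str = "nucleotide") -> tuple[int, int, float]:
    """(n_sites, n_variable, percent); a site is variable with >= 2 states.

    Non-ACGT characters (gaps, ambiguity codes) do not count as states.
    """
    if level == "nucleotide":
        columns = zip(*alignment.sequences)
        states_per_col = [
            {c for c in col if c in _BASES} for col in columns
        ]
    elif level == "amino_acid":
        aa = _aa_matrix(alignment)
        states_per_col = [
            {row[k] for row in aa if row[k] is not None}
            for k in range(alignment.n_codons)
        ]
    else:
        raise ValueError("level must be 'nucleotide' or 'amino_acid'")
    n_sites = len(states_per_col)
    n_var = sum(len(s) >= 2 for s in states_per_col)
    return n_sites, n_var, 100.0 * n_var / n_sites if n_sites else 0.0


def mean_pairwise_diffs(alignment: CodonAlignment, level: str = "nucleotide",
                        codon_subset: list[int] | None = None):
    """(mean, SD, min, max) pairwise differing sites over all C(n,2) pairs."""
    if len(alignment.sequences) < 2:
        raise ValueError("need >= 2 sequences")
    if level == "nucleotide":
        rows = alignment.sequences
        n = len(rows)
        diffs = []
        for i, j in combinations(range(n), 2):
            diffs.append(sum(
                a != b
                for a, b in zip(rows[i], rows[j])
                if a in _BASES and b in _BASES
            ))
    elif level == "amino_acid":
        aa = _aa_matrix(alignment)
        cols = codon_subset if codon_subset is not None else range(alignment.n_codons)
        diffs = []
        for i, j in combinations(range(len(aa)), 2):
            diffs.append(sum(
                aa[i][k] != aa[j][k]
                for k in cols
                if aa[i][k] is not None and aa[j][k] is not None
            ))
    else:
        raise ValueError("level must be 'nucleotide' or 'amino_acid'")
    arr = np.array(diffs, dtype=float)
    return float(arr.mean()), float(arr.std(ddof=1)) if len(arr) > 1 else 0.0, \
        int(arr.min()), int(arr.max())


# ---------------------------------------------------------------------------
# Nei-Gojobori 1986
# ---------------------------------------------------------------------------

def _codon_site_counts(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site counts of one codon (sums to 3)."""
    syn = 0.0
    aa = translate_codon(codon)
    for pos in range(3):
        for b in _BASES:
            if b == codon[pos]:
                continue
            mutant = codon[:pos] + b + codon[pos + 1:]
            if translate_codon(mutant) == aa != "*":
                syn += 1.0
    syn /= 3.0
    return syn, 3.0 - syn


_SITE_CACHE = {c: _codon_site_counts(c)
               for c in (a + b + d for a in _BASES for b in _BASES for d in _BASES)
               if translate_codon(c) != "*"}


def _codon_diff_counts(c1: str, c2: str) -> tuple[float, float]:
    """(Sd, Nd) between two codons, averaged over all minimal pathways."""
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        return 0.0, 0.0
    paths = list(permutations(diff_pos))
    sd = nd = 0.0
    w = 1.0 / len(paths)
    for order in paths:
        cur = c1
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if translate_codon(cur) == translate_codon(nxt):
                sd += w
            else:
                nd += w
            cur = nxt
    return sd, nd


_DIFF_CACHE: dict[tuple[str, str], tuple[float, float]] = {}


def ng86_pair(codons_a: list[str] | str, codons_b: list[str] | str,
              site_subset: list[int] | None = None) -> dict[str, float]:
    """NG86 counts for one in-frame sequence pair.

    Accepts codon lists or plain nucleotide strings (length divisible by
    3).  Returns N, S (site counts averaged over the two sequences), Nd,
    Sd, the raw proportions pN, pS, and Jukes-Cantor distances dN, dS
    (NaN where the correction is undefined, i.e. p >= 3/4).  Codons with
    non-ACGT characters in either sequence are skipped (pairwise deletion),
    as are stop codons.
    """
    if isinstance(codons_a, str):
        if len(codons_a) % 3 or len(codons_b) % 3:
            raise ValueError("sequence length must be divisible by 3")
        codons_a = [codons_a[i:i + 3] for i in range(0, len(codons_a), 3)]
        codons_b = [codons_b[i:i + 3] for i in range(0, len(codons_b), 3)]
    if len(codons_a) != len(codons_b):
        raise ValueError("codon lists must have equal length")
    idx = site_subset if site_subset is not None else range(len(codons_a))
    N = S = Nd = Sd = 0.0
    for k in idx:
        ca, cb = codons_a[k], codons_b[k]
        if not (is_acgt(ca) and is_acgt(cb)):
            continue
        if translate_codon(ca) == "*" or translate_codon(cb) == "*":
            continue
        sa, na = _SITE_CACHE[ca]
        sb, nb = _SITE_CACHE[cb]
        S += (sa + sb) / 2.0
        N += (na + nb) / 2.0
        key = (ca, cb)
        if key not in _DIFF_CACHE:
            _DIFF_CACHE[key] = _codon_diff_counts(ca, cb)
        sd, nd = _DIFF_CACHE[key]
        Sd += sd
        Nd += nd
    pN = Nd / N if N > 0 else 0.0
    pS = Sd / S if S > 0 else 0.0
    return {
        "N": N, "S": S, "Nd": Nd, "Sd": Sd, "pN": pN, "pS": pS,
        "dN": jukes_cantor(pN), "dS": jukes_cantor(pS),
    }


def jukes_cantor(p: float) -> float:
    """JC69 multiple-hit correction; NaN for p >= 3/4 (undefined)."""
    if p >= 0.75:
        return float("nan")
    return -0.75 * math.log1p(-4.0 * p / 3.0)


@dataclass
class SelectionStats:
    region: str
    n_codons: int
    n_variable_aa: int
    mean_daa: float
    se_daa: float
    dN: float
    se_dN: float
    dS: float
    se_dS: float
    Z: float
    p: float
    n_bootstrap: int
    distance: str  # 'raw' or 'jc'


def _pair_codon_tables(alignment: CodonAlignment, codon_idx: list[int]):
    """Per-pair, per-codon N/S/Nd/Sd arrays over the region's codons."""
    seqs = [alignment.codons(i) for i in range(len(alignment.sequences))]
    pairs = list(combinations(range(len(seqs)), 2))
    ncod = len(codon_idx)
    N = np.zeros((len(pairs), ncod))
    S = np.zeros((len(pairs), ncod))
    Nd = np.zeros((len(pairs), ncod))
    Sd = np.zeros((len(pairs), ncod))
    for p, (i, j) in enumerate(pairs):
        for c, k in enumerate(codon_idx):
            ca, cb = seqs[i][k], seqs[j][k]
            if not (is_acgt(ca) and is_acgt(cb)):
                continue
            if translate_codon(ca) == "*" or translate_codon(cb) == "*":
                continue
            sa, na = _SITE_CACHE[ca]
            sb, nb = _SITE_CACHE[cb]
            S[p, c] = (sa + sb) / 2.0
            N[p, c] = (na + nb) / 2.0
            key = (ca, cb)
            if key not in _DIFF_CACHE:
                _DIFF_CACHE[key] = _codon_diff_counts(ca, cb)
            Sd[p, c], Nd[p, c] = _DIFF_CACHE[key]
    return N, S, Nd, Sd


def _mean_dnds(N, S, Nd, Sd, cols, distance: str) -> tuple[float, float]:
    """Mean-over-pairs dN and dS for the chosen codon columns."""
    n = N[:, cols].sum(axis=1)
    s = S[:, cols].sum(axis=1)
    nd = Nd[:, cols].sum(axis=1)
    sd = Sd[:, cols].sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        pn = np.where(n > 0, nd / np.where(n > 0, n, 1.0), 0.0)
        ps = np.where(s > 0, sd / np.where(s > 0, s, 1.0), 0.0)
        if distance == "jc":
            pn = np.where(pn < 0.75, -0.75 * np.log1p(-4.0 * pn / 3.0), np.nan)
            ps = np.where(ps < 0.75, -0.75 * np.log1p(-4.0 * ps / 3.0), np.nan)
    return float(np.nanmean(pn)), float(np.nanmean(ps))


def dnds_summary(alignment: CodonAlignment, region: str = "all",
                 n_bootstrap: int = 1000, seed: int = 0,
                 distance: str = "raw") -> SelectionStats:
    """Region-wide dN/dS with codon-bootstrap SEs and the one-tailed Z-test.

    dN and dS are means over all sequence pairs of the NG86 per-pair
    estimates restricted to the region's codons.  Standard errors come
    from resampling codon sites with replacement (``n_bootstrap``
    replicates, seeded).  Z = (dN - dS) / SE_boot(dN - dS); the one-tailed
    p-value is the standard-normal upper tail, so only dN > dS counts as
    evidence of positive selection.
    """
    codon_idx = alignment.region_codons(region)
    if len(codon_idx) < 2:
        raise ValueError(f"region {region!r} has fewer than 2 codons")
    N, S, Nd, Sd = _pair_codon_tables(alignment, codon_idx)
    ncod = len(codon_idx)
    all_cols = np.arange(ncod)
    dN, dS = _mean_dnds(N, S, Nd, Sd, all_cols, distance)

    rng = np.random.default_rng(seed)
    boot = np.empty((n_bootstrap, 2))
    for b in range(n_bootstrap):
        cols = rng.integers(0, ncod, size=ncod)
        boot[b] = _mean_dnds(N, S, Nd, Sd, cols, distance)
    se_dN = float(np.nanstd(boot[:, 0], ddof=1))
    se_dS = float(np.nanstd(boot[:, 1], ddof=1))
    se_diff = float(np.nanstd(boot[:, 0] - boot[:, 1], ddof=1))
    Z = (dN - dS) / se_diff if se_diff > 0 else 0.0
    p = float(norm.sf(Z))

    # region-restricted amino-acid summaries
    aa = _aa_matrix(alignment)
    states = [
        {row[k] for row in aa if row[k] is not None} for k in codon_idx
    ]
    n_var_aa = sum(len(s) >= 2 for s in states)
    mean_daa, sd_daa, _, _ = mean_pairwise_diffs(alignment, "amino_acid",
                                                 codon_subset=codon_idx)
    # bootstrap SE of the mean pairwise AA difference over codons
    aa_arr = np.array([[row[k] for k in codon_idx] for row in aa], dtype=object)
    pairs = list(combinations(range(len(aa)), 2))
    diff_mat = np.zeros((len(pairs), ncod))
    for pi, (i, j) in enumerate(pairs):
        for c in range(ncod):
            a, b2 = aa_arr[i, c], aa_arr[j, c]
            diff_mat[pi, c] = (a is not None and b2 is not None and a != b2)
    daa_boot = np.empty(n_bootstrap)
    rng2 = np.random.default_rng(seed + 1)
    for b in range(n_bootstrap):
        cols = rng2.integers(0, ncod, size=ncod)
        daa_boot[b] = diff_mat[:, cols].sum(axis=1).mean()
    se_daa = float(np.std(daa_boot, ddof=1))

    return SelectionStats(
        region=region, n_codons=ncod, n_variable_aa=n_var_aa,
        mean_daa=mean_daa, se_daa=se_daa,
        dN=dN, se_dN=se_dN, dS=dS, se_dS=se_dS,
        Z=Z, p=p, n_bootstrap=n_bootstrap, distance=distance,
    )


def aa_site_frequencies(alignment: CodonAlignment) -> list[dict[str, float]]:
    """Per-codon amino-acid relative frequencies (the logo matrix).

    Each column's frequencies are over the sequences with a translatable
    codon there and sum to 1.
    """
    aa = _aa_matrix(alignment)
    out: list[dict[str, float]] = []
    for k in range(alignment.n_codons):
        col = [row[k] for row in aa if row[k] is not None]
        freqs: dict[str, float] = {}
        for a in col:
            freqs[a] = freqs.get(a, 0.0) + 1.0
        total = sum(freqs.values())
        out.append({a: v / total for a, v in sorted(freqs.items())} if total else {})
    return out
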