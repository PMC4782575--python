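"""Selection statistics: NG86 against independent oracles, plus invariants."""

import itertools
import math

import numpy as np
import pytest

from amplitype.selection import (
    CodonAlignment,
    StopCodonError,
    _STANDARD_TABLE,
    aa_site_frequencies,
    count_variable_sites,
    dnds_summary,
    jukes_cantor,
    load_abs_mask,
    mean_pairwise_diffs,
    ng86_pair,
)

BASES = "ACGT"
SENSE = [c for c in map("".join, itertools.product(BASES, repeat=3))
         if _STANDARD_TABLE[c] != "*"]


# -- independent brute-force oracle ----------------------------------------

def oracle_site_counts(codon):
    """Synonymous fraction per position by enumerating all 9 one-step mutants."""
    aa = _STANDARD_TABLE[codon]
    syn = 0
    for pos in range(3):
        for b in BASES:
            if b == codon[pos]:
                continue
            mutant = codon[:pos] + b + codon[pos + 1:]
            if _STANDARD_TABLE[mutant] == aa and _STANDARD_TABLE[mutant] != "*":
                syn += 1
    return syn / 3.0, 3.0 - syn / 3.0


def oracle_diff_counts(c1, c2):
    """Average syn/nonsyn steps over every minimal substitution pathway."""
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0
    pathways = list(itertools.permutations(diff))
    syn = non = 0.0
    for order in pathways:
        cur = c1
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if _STANDARD_TABLE[cur] == _STANDARD_TABLE[nxt]:
                syn += 1
            else:
                non += 1
            cur = nxt
    return syn / len(pathways), non / len(pathways)


def _random_coding(rng, n_codons):
    return "".join(rng.choice(SENSE, n_codons))


def _aln(seqs, abs_mask=None):
    return CodonAlignment(names=[f"s{i}" for i in range(len(seqs))],
                          sequences=list(seqs), abs_mask=abs_mask or set())


@pytest.fixture(scope="module")
def coding_alignment():
    """Ten related coding sequences, 57 codons, no stops."""
    rng = np.random.default_rng(99)
    ancestor = _random_coding(rng, 57)
    seqs = []
    while len(seqs) < 10:
        chars = list(ancestor)
        for pos in np.nonzero(rng.random(len(chars)) < 0.03)[0]:
            chars[pos] = rng.choice([b for b in BASES if b != chars[pos]])
        cand = "".join(chars)
        if all(_STANDARD_TABLE[cand[i:i + 3]] != "*" for i in range(0, len(cand), 3)):
            seqs.append(cand)
    return _aln(seqs, abs_mask=load_abs_mask())


class TestNg86Pair:
    def test_sampled_codon_pairs_match_pathway_oracle(self, rng):
        idx = rng.choice(len(SENSE), size=(300, 2))
        for i, j in idx:
            c1, c2 = SENSE[i], SENSE[j]
            r = ng86_pair([c1], [c2])
            s1, n1 = oracle_site_counts(c1)
            s2, n2 = oracle_site_counts(c2)
            sd, nd = oracle_diff_counts(c1, c2)
            assert r["S"] == pytest.approx((s1 + s2) / 2)
            assert r["N"] == pytest.approx((n1 + n2) / 2)
            assert r["Sd"] == pytest.approx(sd)
            assert r["Nd"] == pytest.approx(nd)

    def test_identical_sequences_have_zero_distances(self):
        r = ng86_pair("TTTAAAGGG", "TTTAAAGGG")
        assert r["Nd"] == r["Sd"] == 0.0
        assert r["dN"] == r["dS"] == 0.0
        assert r["N"] + r["S"] == pytest.approx(9.0)

    def test_phe_synonymous_third_position(self):
        # TTT->TTC is Phe->Phe: one synonymous difference
        r = ng86_pair("TTT", "TTC")
        assert r["Sd"] == 1.0 and r["Nd"] == 0.0
        s, _ = oracle_site_counts("TTT")
        s2, _ = oracle_site_counts("TTC")
        assert r["S"] == pytest.approx((s + s2) / 2)

    def test_two_difference_codon_averages_both_pathways(self):
        sd, nd = oracle_diff_counts("TTT", "GTC")
        r = ng86_pair("TTT", "GTC")
        assert r["Sd"] == pytest.approx(sd)
        assert r["Nd"] == pytest.approx(nd)
        assert sd + nd == pytest.approx(2.0)

    def test_symmetry_and_site_additivity(self, rng):
        a = _random_coding(rng, 12)
        b = _random_coding(rng, 12)
        r_ab, r_ba = ng86_pair(a, b), ng86_pair(b, a)
        for key in ("N", "S", "Nd", "Sd"):
            assert r_ab[key] == pytest.approx(r_ba[key])
        left = ng86_pair(a, b, site_subset=list(range(6)))
        right = ng86_pair(a, b, site_subset=list(range(6, 12)))
        whole = ng86_pair(a, b)
        for key in ("N", "S", "Nd", "Sd"):
            assert left[key] + right[key] == pytest.approx(whole[key])

    def test_matches_biopython_ng86_jc_distances(self, rng):
        from Bio.codonalign.codonseq import CodonSeq, cal_dn_ds

        for _ in range(5):
            a = _random_coding(rng, 30)
            while True:
                chars = list(a)
                for pos in np.nonzero(rng.random(len(chars)) < 0.05)[0]:
                    chars[pos] = rng.choice([x for x in BASES if x != chars[pos]])
                b = "".join(chars)
                if all(_STANDARD_TABLE[b[i:i + 3]] != "*"
                       for i in range(0, len(b), 3)):
                    break
            dn_bp, ds_bp = cal_dn_ds(CodonSeq(a), CodonSeq(b), method="NG86")
            r = ng86_pair(a, b)
            assert r["dN"] == pytest.approx(dn_bp, abs=1e-9)
            assert r["dS"] == pytest.approx(ds_bp, abs=1e-9)

    def test_jc_correction_undefined_above_three_quarters(self):
        assert math.isnan(jukes_cantor(0.75))
        assert jukes_cantor(0.0) == 0.0


class TestSiteSummaries:
    def test_identical_sequences_have_no_variable_sites(self):
        aln = _aln(["TTTAAAGGG"] * 3)
        assert count_variable_sites(aln, "nucleotide") == (9, 0, 0.0)
        assert count_variable_sites(aln, "amino_acid") == (3, 0, 0.0)

    def test_constructed_variable_site_percentages(self):
        seqs = ["TTTAAAGGG", "TTCAAAGGG", "TTTAATGGG"]
        n, var, pct = count_variable_sites(_aln(seqs), "nucleotide")
        assert (n, var) == (9, 2)
        assert pct == pytest.approx(100 * 2 / 9)

    def test_stop_codon_reported_with_position(self):
        aln = _aln(["TTTTAAGGG"])
        with pytest.raises(StopCodonError, match="codon 2"):
            count_variable_sites(aln, "amino_acid")

    def test_pairwise_diffs_two_and_three_sequences(self):
        a, b = "AAAAAAAAA", "AAACCCAAC"  # 4 differences
        mean, sd, lo, hi = mean_pairwise_diffs(_aln([a, b]))
        assert (mean, sd, lo, hi) == (4.0, 0.0, 4, 4)
        c = "AAAAAACCC"
        mean, sd, lo, hi = mean_pairwise_diffs(_aln([a, b, c]))
        diffs = sorted([4, 3, 5])
        assert mean == pytest.approx(np.mean(diffs))
        assert sd == pytest.approx(np.std(diffs, ddof=1))
        assert (lo, hi) == (3, 5)

    def test_aa_site_frequencies_normalized(self, coding_alignment):
        logo = aa_site_frequencies(coding_alignment)
        assert len(logo) == 57
        for col in logo:
            assert sum(col.values()) == pytest.approx(1.0)

    def test_invariant_column_frequency_one(self):
        logo = aa_site_frequencies(_aln(["ATGTTT", "ATGTTC"]))
        assert logo[0] == {"M": 1.0}
        assert logo[1] == {"F": 1.0}


class TestDndsSummary:
    def test_purely_synonymous_variation_gives_nonpositive_z(self):
        # third-position Phe wobble only
        seqs = ["TTTTTTTTTTTT", "TTCTTTTTCTTT", "TTTTTCTTTTTC"]
        s = dnds_summary(_aln(seqs), "all", n_bootstrap=200, seed=0)
        assert s.dN == 0.0
        assert s.Z <= 0.0
        assert s.p >= 0.5

    def test_region_site_counts_are_additive(self, coding_alignment):
        pairs = list(itertools.combinations(range(10), 2))
        for region_pair in [("ABS", "nonABS")]:
            tot = {k: 0.0 for k in ("N", "S", "Nd", "Sd")}
            for region in region_pair:
                idx = coding_alignment.region_codons(region)
                for i, j in pairs[:5]:
                    r = ng86_pair(coding_alignment.codons(i),
                                  coding_alignment.codons(j), site_subset=idx)
                    for k in tot:
                        tot[k] += r[k]
            whole = {k: 0.0 for k in tot}
            for i, j in pairs[:5]:
                r = ng86_pair(coding_alignment.codons(i), coding_alignment.codons(j))
                for k in whole:
                    whole[k] += r[k]
            for k in tot:
                assert tot[k] == pytest.approx(whole[k])

    def test_bootstrap_is_seed_reproducible(self, coding_alignment):
        a = dnds_summary(coding_alignment, "all", n_bootstrap=150, seed=42)
        b = dnds_summary(coding_alignment, "all", n_bootstrap=150, seed=42)
        assert (a.dN, a.dS, a.se_dN, a.se_dS, a.Z, a.p) == \
            (b.dN, b.dS, b.se_dN, b.se_dS, b.Z, b.p)

    def test_bootstrap_se_stable_under_doubling(self, coding_alignment):
        a = dnds_summary(coding_alignment, "all", n_bootstrap=500, seed=1)
        b = dnds_summary(coding_alignment, "all", n_bootstrap=1000, seed=2)
        assert b.se_dN == pytest.approx(a.se_dN, rel=0.25)

    def test_region_requires_mask(self):
        aln = _aln(["TTTAAAGGG", "TTCAAAGGG"])
        with pytest.raises(ValueError):
            dnds_summary(aln, "ABS", n_bootstrap=10, seed=0)

    def test_shipped_mask_is_fifteen_codons_within_window(self):
        mask = load_abs_mask()
        assert len(mask) == 15
        assert mask <= set(range(1, 58))
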