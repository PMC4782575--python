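"""Unit tests of the replicate-aware classification steps on handcrafted cohorts."""

import numpy as np
import pytest

from amplitype.caller import (
    CLASS_ALLELE,
    CLASS_ARTIFACT,
    CLASS_LOW_EFF,
    CLASS_UNCLASSIFIED,
    CallerConfig,
    Genotype,
    STATUS_GENOTYPED,
    STATUS_INSUFFICIENT,
    SaturationWarning,
    TrioRecord,
    apply_depth_threshold,
    call_genotypes,
    depth_saturation_check,
    trio_concordance,
)
from amplitype.io import AlleleCatalog
from conftest import make_amplicon


def _seq(rng, n=171):
    return "".join(rng.choice(list("ACGT"), n))


def _mut(seq, positions):
    table = {"A": "C", "C": "G", "G": "T", "T": "A"}
    chars = list(seq)
    for p in positions:
        chars[p] = table[chars[p]]
    return "".join(chars)


def _call(amplicons, **cfg):
    amp_map = {a.key: a for a in amplicons}
    order = []
    for a in amplicons:
        if a.individual_id not in order:
            order.append(a.individual_id)
    return call_genotypes(amp_map, CallerConfig(**cfg), individual_order=order)


class TestDepthThreshold:
    def test_boundary_is_inclusive(self):
        amps = {("i", "r1", "x"): make_amplicon({"A" * 171: 119}, "i", "r1", "x"),
                ("i", "r2", "x"): make_amplicon({"A" * 171: 120}, "i", "r2", "x")}
        retained, discarded = apply_depth_threshold(amps, CallerConfig())
        assert list(retained) == [("i", "r2", "x")]
        assert discarded == [("i", "r1", "x")]

    def test_individual_with_no_surviving_amplicon_is_insufficient(self, rng):
        a = _seq(rng)
        amps = [make_amplicon({a: 50}, "i1", "rep1"),
                make_amplicon({a: 300}, "i2", "rep1"),
                make_amplicon({a: 300}, "i2", "rep2")]
        calls = _call(amps)
        by_id = {g.individual_id: g for g in calls.genotypes}
        assert by_id["i1"].status == STATUS_INSUFFICIENT
        assert by_id["i2"].status == STATUS_GENOTYPED


class TestFrequencyRule:
    def test_below_floor_in_every_replicate_is_artifact(self, rng):
        a = _seq(rng)
        low = _mut(a, range(0, 30, 3))  # far from a, but always <= 1%
        amps = [make_amplicon({a: 995, low: 5}, "i1", "rep1"),
                make_amplicon({a: 992, low: 8}, "i1", "rep2")]
        calls = _call(amps)
        assert calls.final_class[("i1", low)] == CLASS_ARTIFACT
        assert calls.final_class[("i1", a)] == CLASS_ALLELE

    def test_above_floor_in_any_one_replicate_retains_everywhere(self, rng):
        a = _seq(rng)
        b = _mut(a, range(0, 30, 3))
        amps = [make_amplicon({a: 992, b: 8}, "i1", "rep1"),      # 0.8%
                make_amplicon({a: 950, b: 50}, "i1", "rep2")]     # 5%
        calls = _call(amps)
        # retained in both replicates -> putative allele in both -> allele
        assert calls.final_class[("i1", b)] == CLASS_ALLELE


class TestReplicateResolution:
    def test_putative_allele_in_all_replicates_is_allele(self, rng):
        a, b = _seq(rng), None
        b = _mut(a, range(0, 21, 4))  # 6 bp away: independent allele
        amps = [make_amplicon({a: 300, b: 200}, "i1", f"rep{r}") for r in (1, 2, 3)]
        calls = _call(amps)
        assert calls.final_class[("i1", a)] == CLASS_ALLELE
        assert calls.final_class[("i1", b)] == CLASS_ALLELE

    def test_allele_in_one_of_three_replicates_is_low_efficiency(self, rng):
        a = _seq(rng)
        b = _mut(a, range(0, 21, 4))
        amps = [make_amplicon({a: 300, b: 90}, "i1", "rep1"),
                make_amplicon({a: 300}, "i1", "rep2"),
                make_amplicon({a: 300}, "i1", "rep3")]
        calls = _call(amps)
        # b is >2 bp from a but seen in a single replicate only: with a second
        # supporting individual it is a dropout-prone (low-efficiency) allele
        amps.append(make_amplicon({b: 200, a: 150}, "i2", "rep1"))
        amps.append(make_amplicon({b: 200, a: 150}, "i2", "rep2"))
        calls = _call(amps)
        assert calls.final_class[("i1", b)] == CLASS_LOW_EFF
        by_id = {g.individual_id: g for g in calls.genotypes}
        assert b in by_id["i1"].allele_sequences

    def test_near_parent_minority_variant_is_artifact_in_every_replicate(self, rng):
        a = _seq(rng)
        err = _mut(a, [10])  # 1 bp from its parent, always minority
        amps = [make_amplicon({a: 300, err: 30}, "i1", "rep1"),
                make_amplicon({a: 280, err: 25}, "i1", "rep2")]
        calls = _call(amps)
        assert calls.final_class[("i1", err)] == CLASS_ARTIFACT
        by_id = {g.individual_id: g for g in calls.genotypes}
        assert by_id["i1"].allele_sequences == {a}

    def test_two_bp_distance_is_still_artifact_class(self, rng):
        a = _seq(rng)
        err = _mut(a, [10, 50])
        amps = [make_amplicon({a: 300, err: 30}, "i1", "rep1"),
                make_amplicon({a: 280, err: 25}, "i1", "rep2")]
        calls = _call(amps)
        assert calls.final_class[("i1", err)] == CLASS_ARTIFACT

    def test_novel_gt2bp_variant_in_one_replicate_stays_unclassified(self, rng):
        a = _seq(rng)
        novel = _mut(a, range(0, 30, 3))
        amps = [make_amplicon({a: 300, novel: 40}, "i1", "rep1"),
                make_amplicon({a: 300}, "i1", "rep2")]
        calls = _call(amps)
        assert calls.final_class[("i1", novel)] == CLASS_UNCLASSIFIED
        by_id = {g.individual_id: g for g in calls.genotypes}
        assert novel not in by_id["i1"].allele_sequences  # collapsed to artifact


class TestSingleAmpliconProtocol:
    def test_cross_individual_evidence_makes_allele(self, rng):
        a = _seq(rng)
        b = _mut(a, range(0, 21, 4))
        shared_err = _mut(b, [7])  # 1 bp from i2's top variant
        amps = [
            make_amplicon({a: 300, b: 200}, "i1", "rep1"),
            make_amplicon({a: 300, b: 200}, "i1", "rep2"),
            # i2 has one amplicon; b is allele-classed in i1
            make_amplicon({b: 250, shared_err: 20}, "i2", "rep1"),
        ]
        calls = _call(amps)
        assert calls.final_class[("i2", b)] == CLASS_ALLELE
        # 1-bp neighbor of i2's top variant, seen nowhere else -> artifact
        assert calls.final_class[("i2", shared_err)] == CLASS_ARTIFACT

    def test_novel_gt2bp_variant_unsupported_elsewhere_is_unclassified(self, rng):
        a = _seq(rng)
        novel = _mut(a, range(0, 30, 3))
        amps = [
            make_amplicon({a: 300}, "i1", "rep1"),
            make_amplicon({a: 300}, "i1", "rep2"),
            make_amplicon({a: 250, novel: 50}, "i2", "rep1"),
        ]
        calls = _call(amps)
        assert calls.final_class[("i2", novel)] == CLASS_UNCLASSIFIED
        assert calls.final_class[("i2", a)] == CLASS_ALLELE


class TestDeepCoverageCorrection:
    def _rich_cohort(self, rng, n_private=9, n_shared=7):
        shared = [_seq(rng) for _ in range(n_shared)]
        private = [_seq(rng) for _ in range(n_private)]
        rich = {s: 500 for s in shared + private}
        amps = [make_amplicon(rich, "deep", "rep1"),
                make_amplicon(rich, "deep", "rep2")]
        for j, s in enumerate(shared):
            amps.append(make_amplicon({s: 300}, f"o{j}", "rep1"))
            amps.append(make_amplicon({s: 300}, f"o{j}", "rep2"))
        return amps, shared, private

    def test_private_alleles_of_artifact_free_rich_genotype_demoted(self, rng):
        amps, shared, private = self._rich_cohort(rng)
        calls = _call(amps)
        for s in private:
            assert calls.final_class[("deep", s)] == CLASS_ARTIFACT
        for s in shared:
            assert calls.final_class[("deep", s)] == CLASS_ALLELE
        by_id = {g.individual_id: g for g in calls.genotypes}
        assert by_id["deep"].allele_sequences == set(shared)

    def test_all_shared_alleles_retained_with_anomaly_not_truncation(self, rng):
        amps, shared, private = self._rich_cohort(rng, n_private=0, n_shared=16)
        calls = _call(amps)
        by_id = {g.individual_id: g for g in calls.genotypes}
        assert by_id["deep"].allele_sequences == set(shared)
        assert any(a.individual_id == "deep" for a in calls.anomalies)

    def test_individual_with_artifacts_is_untouched(self, rng):
        a = _seq(rng)
        b = _mut(a, range(0, 21, 4))
        err = _mut(a, [3])
        amps = [make_amplicon({a: 300, b: 200, err: 30}, "i1", "rep1"),
                make_amplicon({a: 300, b: 200, err: 25}, "i1", "rep2")]
        calls = _call(amps)
        by_id = {g.individual_id: g for g in calls.genotypes}
        assert by_id["i1"].allele_sequences == {a, b}


class TestAssembly:
    def test_collapsing_contract_no_artifact_in_genotypes(self, rng):
        a = _seq(rng)
        b = _mut(a, range(0, 21, 4))
        err = _mut(a, [3])
        amps = [make_amplicon({a: 300, b: 90, err: 20}, "i1", "rep1"),
                make_amplicon({a: 300, err: 18}, "i1", "rep2")]
        calls = _call(amps)
        by_id = {g.individual_id: g for g in calls.genotypes}
        for seq in by_id["i1"].allele_sequences:
            assert calls.final_class[("i1", seq)] in (CLASS_ALLELE, CLASS_LOW_EFF)

    def test_novel_names_continue_catalog_numbering(self, rng):
        seqs = [_seq(rng) for _ in range(3)]
        catalog = AlleleCatalog(
            alleles={f"DRB*{i:02d}": _seq(rng) for i in range(1, 13)},
            locus_tag="DRB")
        amps = {}
        for j, s in enumerate(seqs):
            for r in ("rep1", "rep2"):
                amp = make_amplicon({s: 300}, f"i{j}", r)
                amps[amp.key] = amp
        calls = call_genotypes(amps, CallerConfig(), catalog,
                               individual_order=[f"i{j}" for j in range(3)])
        new_names = sorted(n for g in calls.genotypes for n in g.allele_names)
        assert new_names == ["DRB*13", "DRB*14", "DRB*15"]

    def test_same_individual_on_two_runs_merges_into_one_genotype(self, rng):
        a = _seq(rng)
        amps = [make_amplicon({a: 300}, "i1", "rep1", run_id="run1"),
                make_amplicon({a: 300}, "i1", "rep1", run_id="run2")]
        calls = _call(amps)
        assert len(calls.genotypes) == 1
        g = calls.genotypes[0]
        assert g.n_replicates_used == 2 and g.allele_sequences == {a}

    def test_determinism_under_read_order_permutation(self, rng):
        a, b = _seq(rng), _seq(rng)
        inserts = [a] * 200 + [b] * 150
        amp1 = make_amplicon(list(inserts), "i1", "rep1")
        rng.shuffle(inserts)
        amp2 = make_amplicon(list(inserts), "i1", "rep1")
        for amp in (amp1, amp2):
            calls = _call([amp, make_amplicon({a: 180, b: 160}, "i1", "rep2")])
            assert {g.individual_id: g.allele_sequences for g in calls.genotypes} \
                == {"i1": {a, b}}


class TestTrioConcordance:
    def _geno(self, ind, names):
        return Genotype(ind, allele_names=set(names))

    def test_concordant_when_parents_cover_offspring(self):
        genos = [self._geno("o", {"a", "b"}), self._geno("d", {"a", "c"}),
                 self._geno("s", {"b", "d"})]
        rep, = trio_concordance(genos, [TrioRecord("o", "d", "s")])
        assert rep.status == "concordant"

    def test_orphan_allele_reported_with_suspect_parent(self):
        genos = [self._geno("o", {"a", "e"}), self._geno("d", {"a", "c"}),
                 self._geno("s", {"b", "d"})]
        rep, = trio_concordance(genos, [TrioRecord("o", "d", "s")])
        assert rep.status == "mismatch"
        assert rep.orphan_alleles == {"e"}
        assert rep.suspect_parent == "s"  # dam explains 'a', sire explains nothing

    def test_missing_member_skips_with_reason(self):
        genos = [self._geno("o", {"a"}), self._geno("d", {"a"}),
                 Genotype("s", status=STATUS_INSUFFICIENT)]
        rep, = trio_concordance(genos, [TrioRecord("o", "d", "s")])
        assert rep.status == "skipped" and "s" in rep.reason


class TestDepthSaturation:
    def test_constant_allele_count_has_zero_slope(self):
        genos = [Genotype(f"i{k}", allele_names={"a", "b"},
                          mean_depth=100.0 * (k + 1)) for k in range(5)]
        slope, r2 = depth_saturation_check(genos)
        assert slope == 0.0 and r2 == 0.0

    def test_proportional_allele_count_warns(self):
        genos = [Genotype(f"i{k}", allele_names={f"x{j}" for j in range(k + 1)},
                          mean_depth=100.0 * (k + 1)) for k in range(6)]
        with pytest.warns(SaturationWarning):
            slope, r2 = depth_saturation_check(genos)
        assert r2 == pytest.approx(1.0)
        assert slope == pytest.approx(0.01)

    def test_requires_three_points(self):
        genos = [Genotype("i1", allele_names={"a"}, mean_depth=100.0),
                 Genotype("i2", allele_names={"a"}, mean_depth=200.0)]
        with pytest.raises(ValueError):
            depth_saturation_check(genos)
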