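"""Steps III-VI: from per-amplicon variants to validated multi-allele genotypes.

The caller is seed-free and fully deterministic: identical inputs (up to read
order) produce identical genotypes and allele names.

Classification proceeds cohort-wide, one step completed for every amplicon
before the next begins:

1. depth threshold on amplicons;
2. the >1 %-in-some-replicate frequency rule per individual;
3. within-amplicon classes (most frequent / chimera / 1-2 bp / >2 bp);
4. chimera rescue: a flagged variant present above the frequency floor in
   two or more independent replicates is promoted back to candidate allele;
5. replicate resolution for multi-replicate individuals
   (allele / low-efficiency allele / artifact / unclassified);
6. cross-individual rescue of unclassified variants, then the modified
   single-amplicon protocol, then the deep-coverage correction;
7. genotype assembly, allele naming, and QC verifications (trios,
   depth-saturation regression).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .io import AlleleCatalog
from .qc import Amplicon
from .variants import (
    INTRA_CHIMERA,
    INTRA_DIFF_1_2BP,
    INTRA_DIFF_GT2BP,
    INTRA_LOW_FREQ,
    INTRA_MOST_FREQUENT,
    INTRA_SINGLETON,
    AmpliconVariants,
    Variant,
    collapse_amplicon,
    variant_distance,
)

CLASS_ALLELE = "allele"
CLASS_LOW_EFF = "low_efficiency_allele"
CLASS_ARTIFACT = "artifact"
CLASS_UNCLASSIFIED = "unclassified"

STATUS_GENOTYPED = "genotyped"
STATUS_INSUFFICIENT = "insufficient_reads"

# intra-amplicon classes that count as "putative allele" evidence
_PUTATIVE_ALLELE = {INTRA_MOST_FREQUENT, INTRA_DIFF_GT2BP}


@dataclass
class CallerConfig:
    """Caller thresholds.

    ``min_amplicon_depth`` defaults to the 120-read threshold the multi-copy
    reanalysis settled on (25 was the single-copy starting point; 60 and 200
    are the published sensitivity alternatives).  ``max_alleles`` caps a
    genotype at two variants per gene copy.  ``assumed_efficiency`` is the
    planning value for mean amplification efficiency and is reported in run
    manifests only.
    """

    min_amplicon_depth: int = 120
    min_rel_freq: float = 0.01
    copy_number: int = 4
    max_alleles: int | None = None
    assumed_efficiency: float = 0.70
    chimera_skew: float = 2.0
    chimera_min_diff: int = 1

    def __post_init__(self) -> None:
        if self.min_amplicon_depth < 1:
            raise ValueError("min_amplicon_depth must be >= 1")
        if not (0.0 < self.min_rel_freq < 1.0):
            raise ValueError("min_rel_freq must be in (0, 1)")
        if self.copy_number < 1:
            raise ValueError("copy_number must be >= 1")
        if self.max_alleles is None:
            self.max_alleles = 2 * self.copy_number


@dataclass
class Genotype:
    individual_id: str
    allele_names: set[str] = field(default_factory=set)
    allele_sequences: set[str] = field(default_factory=set)
    mean_depth: float = 0.0
    total_reads: int = 0
    n_replicates_used: int = 0
    status: str = STATUS_GENOTYPED


@dataclass(frozen=True)
class TrioRecord:
    offspring_id: str
    dam_id: str
    sire_id: str

    def __post_init__(self) -> None:
        if len({self.offspring_id, self.dam_id, self.sire_id}) != 3:
            raise ValueError("trio member ids must be distinct")


@dataclass
class TrioReport:
    trio: TrioRecord
    status: str  # concordant | mismatch | skipped
    orphan_alleles: set[str] = field(default_factory=set)
    suspect_parent: str | None = None
    reason: str | None = None


@dataclass
class Anomaly:
    individual_id: str
    description: str


@dataclass
class CohortCalls:
    """Everything the caller knows after classification."""

    amplicons: dict[tuple[str, str, str], AmpliconVariants]
    discarded_amplicons: list[tuple[str, str, str]]
    final_class: dict[tuple[str, str], str]  # (individual, sequence) -> class
    genotypes: list[Genotype]
    catalog: AlleleCatalog
    anomalies: list[Anomaly] = field(default_factory=list)

    def class_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for cls in self.final_class.values():
            counts[cls] = counts.get(cls, 0) + 1
        return counts


# ---------------------------------------------------------------------------
# Step gates
# ---------------------------------------------------------------------------

def apply_depth_threshold(amplicons: dict[tuple[str, str, str], Amplicon],
                          config: CallerConfig):
    """Split amplicons into retained (depth >= threshold) and discarded keys."""
    retained = {k: a for k, a in amplicons.items()
                if a.depth >= config.min_amplicon_depth}
    discarded = [k for k in amplicons if k not in retained]
    return retained, discarded


def apply_frequency_rule(by_individual: dict[str, list[AmpliconVariants]],
                         config: CallerConfig) -> None:
    """Discard variants never above min_rel_freq in any replicate amplicon.

    A variant is kept for an individual iff its relative frequency exceeds
    the floor in at least one of that individual's replicate amplicons;
    otherwise it is marked ``below_min_freq`` in all of them (a final
    artifact).  Singletons are already out of play.
    """
    for avs in by_individual.values():
        passing: set[str] = set()
        for av in avs:
            for v in av.classifiable:
                if v.rel_freq > config.min_rel_freq:
                    passing.add(v.sequence)
        for av in avs:
            for v in av.classifiable:
                if v.sequence not in passing:
                    v.intra_class = INTRA_LOW_FREQ


# ---------------------------------------------------------------------------
# Within-amplicon classification
# ---------------------------------------------------------------------------

def classify_within_amplicon(av: AmpliconVariants) -> None:
    """Assign intra-amplicon classes to the surviving variants.

    The most frequent surviving variant is a putative allele.  Every other
    variant is a chimera candidate if flagged; otherwise it is classed by
    the distance to its parent — the nearest (by bp distance, then higher
    count, then sequence) more-frequent variant: <= 2 bp means putative
    artifact, > 2 bp putative allele pending replicate evidence.
    """
    active = [v for v in av.variants
              if v.intra_class in (None,)]  # not singleton / low-freq
    if not active:
        return
    active[0].intra_class = INTRA_MOST_FREQUENT
    for i, v in enumerate(active[1:], start=1):
        if v.chimera is not None:
            v.intra_class = INTRA_CHIMERA
            continue
        higher = active[:i]
        scored = sorted(
            ((variant_distance(v.sequence, h.sequence), -h.count, h.sequence)
             for h in higher),
        )
        dist, _, parent_seq = scored[0]
        v.parent = parent_seq
        v.intra_class = INTRA_DIFF_1_2BP if dist <= 2 else INTRA_DIFF_GT2BP


def rescue_chimeras(by_individual: dict[str, list[AmpliconVariants]],
                    config: CallerConfig) -> None:
    """Step V: promote chimera flags that replicate independently.

    A truly chimeric molecule arises anew in each PCR, so the same hybrid
    sequence above the frequency floor in >= 2 independent replicates is
    better explained as a real allele; such variants are reclassed as
    putative alleles (>2 bp class) before replicate resolution.
    """
    for avs in by_individual.values():
        if len(avs) < 2:
            continue
        present: dict[str, int] = {}
        for av in avs:
            for v in av.classifiable:
                if v.intra_class == INTRA_CHIMERA and v.rel_freq > config.min_rel_freq:
                    present[v.sequence] = present.get(v.sequence, 0) + 1
        promote = {seq for seq, n in present.items() if n >= 2}
        for av in avs:
            for v in av.classifiable:
                if v.intra_class == INTRA_CHIMERA and v.sequence in promote:
                    v.intra_class = INTRA_DIFF_GT2BP


# ---------------------------------------------------------------------------
# Replicate resolution and cross-individual evidence
# ---------------------------------------------------------------------------

def resolve_across_replicates(avs: list[AmpliconVariants]) -> dict[str, str]:
    """Step VI for one multi-replicate individual.

    Per variant sequence: putative allele in every replicate where present
    and present in >= 2 replicates -> allele; putative allele somewhere but
    not everywhere -> low-efficiency allele; never a putative allele ->
    artifact; except that a >2 bp variant seen in a single replicate stays
    provisionally unclassified (cross-individual evidence may rescue it).
    """
    seen: dict[str, list[str]] = {}
    for av in avs:
        for v in av.classifiable:
            if v.intra_class in (INTRA_LOW_FREQ,):
                seen.setdefault(v.sequence, []).append(INTRA_LOW_FREQ)
            else:
                seen.setdefault(v.sequence, []).append(v.intra_class)
    out: dict[str, str] = {}
    for seq, classes in seen.items():
        if all(c == INTRA_LOW_FREQ for c in classes):
            out[seq] = CLASS_ARTIFACT
            continue
        allele_votes = sum(c in _PUTATIVE_ALLELE for c in classes)
        if allele_votes == len(classes) and len(classes) >= 2:
            out[seq] = CLASS_ALLELE
        elif allele_votes >= 1:
            if (len(classes) == 1 and classes[0] == INTRA_DIFF_GT2BP):
                out[seq] = CLASS_UNCLASSIFIED
            else:
                out[seq] = CLASS_LOW_EFF
        else:
            out[seq] = CLASS_ARTIFACT
    return out


def classify_single_amplicon(av: AmpliconVariants,
                             cross_index: dict[str, set[str]],
                             individual_id: str) -> dict[str, str]:
    """Modified protocol for individuals with exactly one retained amplicon.

    The dominant variant is accepted as an allele.  Other variants are
    alleles when allele-classed in >= 1 other individual; otherwise >2 bp
    variants stay unclassified and near-parent (or chimeric / sub-floor)
    variants are artifacts.
    """
    out: dict[str, str] = {}
    for v in av.classifiable:
        others = cross_index.get(v.sequence, set()) - {individual_id}
        if others:
            out[v.sequence] = CLASS_ALLELE
        elif v.intra_class == INTRA_MOST_FREQUENT:
            out[v.sequence] = CLASS_ALLELE
        elif v.intra_class == INTRA_DIFF_GT2BP:
            out[v.sequence] = CLASS_UNCLASSIFIED
        else:  # diff_1_2bp, chimera_candidate, below_min_freq
            out[v.sequence] = CLASS_ARTIFACT
    return out


def _allele_sequences(classes: dict[str, str]) -> set[str]:
    return {s for s, c in classes.items() if c in (CLASS_ALLELE, CLASS_LOW_EFF)}


def _build_cross_index(per_individual: dict[str, dict[str, str]]) -> dict[str, set[str]]:
    index: dict[str, set[str]] = {}
    for ind, classes in per_individual.items():
        for seq in _allele_sequences(classes):
            index.setdefault(seq, set()).add(ind)
    return index


def deep_coverage_correction(per_individual: dict[str, dict[str, str]],
                             config: CallerConfig) -> list[Anomaly]:
    """Demote private 'alleles' of artifact-free, over-rich genotypes.

    Very deep amplicons can leave no variant fulfilling any artifact
    criterion, so everything is called an allele.  For any individual with
    more called alleles than ``max_alleles`` and zero artifact-classed
    variants, every called allele not allele-classed in another individual
    is reclassified as an artifact.  Individuals still over the cap are
    reported as anomalies, never silently truncated.
    """
    anomalies: list[Anomaly] = []
    cross = _build_cross_index(per_individual)
    for ind in sorted(per_individual):
        classes = per_individual[ind]
        called = _allele_sequences(classes)
        n_artifacts = sum(c == CLASS_ARTIFACT for c in classes.values())
        if len(called) <= config.max_alleles or n_artifacts > 0:
            continue
        for seq in sorted(called):
            if not (cross.get(seq, set()) - {ind}):
                classes[seq] = CLASS_ARTIFACT
        remaining = _allele_sequences(classes)
        if len(remaining) > config.max_alleles:
            anomalies.append(Anomaly(
                ind,
                f"{len(remaining)} alleles remain after deep-coverage "
                f"correction (cap {config.max_alleles}); all are shared with "
                "other individuals, so none was demoted",
            ))
    return anomalies


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

def call_genotypes(amplicons: dict[tuple[str, str, str], Amplicon],
                   config: CallerConfig | None = None,
                   catalog: AlleleCatalog | None = None,
                   individual_order: list[str] | None = None) -> CohortCalls:
    """Run Steps II-VI cohort-wide and assemble named genotypes.

    ``catalog`` seeds allele naming (novel sequences are appended);
    ``individual_order`` (e.g. sample-sheet order) fixes the naming order
    of first appearance and the set of expected individuals.
    """
    config = config or CallerConfig()
    catalog = catalog if catalog is not None else AlleleCatalog(alleles={}, locus_tag="DRB")

    retained, discarded = apply_depth_threshold(amplicons, config)

    # deterministic amplicon order: sample-sheet individual order, then key
    if individual_order is None:
        individual_order = sorted({k[0] for k in amplicons})
    order_idx = {ind: i for i, ind in enumerate(individual_order)}
    keys = sorted(retained, key=lambda k: (order_idx.get(k[0], len(order_idx)), k))

    collapsed = {k: collapse_amplicon(retained[k], skew=config.chimera_skew,
                                      min_diff_each_side=config.chimera_min_diff)
                 for k in keys}

    by_individual: dict[str, list[AmpliconVariants]] = {}
    for k in keys:
        by_individual.setdefault(k[0], []).append(collapsed[k])

    # Step II gate + Step III intra classes + Step V chimera rescue
    apply_frequency_rule(by_individual, config)
    for av in collapsed.values():
        classify_within_amplicon(av)
    rescue_chimeras(by_individual, config)

    # Step VI: multi-replicate individuals first
    per_individual: dict[str, dict[str, str]] = {}
    single_amplicon: list[str] = []
    for ind, avs in by_individual.items():
        if len(avs) >= 2:
            per_individual[ind] = resolve_across_replicates(avs)
        else:
            single_amplicon.append(ind)

    # cross-individual rescue of provisional unclassified variants
    cross = _build_cross_index(per_individual)
    for ind, classes in per_individual.items():
        for seq, cls in classes.items():
            if cls == CLASS_UNCLASSIFIED and (cross.get(seq, set()) - {ind}):
                classes[seq] = CLASS_LOW_EFF
    cross = _build_cross_index(per_individual)

    # modified protocol for one-amplicon individuals
    for ind in single_amplicon:
        per_individual[ind] = classify_single_amplicon(by_individual[ind][0], cross, ind)

    anomalies = deep_coverage_correction(per_individual, config)

    # genotype assembly + naming
    final_class: dict[tuple[str, str], str] = {}
    for ind, classes in per_individual.items():
        for seq, cls in classes.items():
            final_class[(ind, seq)] = cls

    appearance: list[str] = []
    seen_seqs: set[str] = set()
    for k in keys:
        ind = k[0]
        for v in collapsed[k].classifiable:
            if per_individual[ind].get(v.sequence) in (CLASS_ALLELE, CLASS_LOW_EFF):
                if v.sequence not in seen_seqs:
                    seen_seqs.add(v.sequence)
                    appearance.append(v.sequence)

    names: dict[str, str] = {}
    for seq in appearance:
        existing = catalog.name_of(seq)
        names[seq] = existing if existing is not None else catalog.add_novel(seq)

    genotypes: list[Genotype] = []
    for ind in individual_order:
        avs = by_individual.get(ind)
        if not avs:
            genotypes.append(Genotype(ind, status=STATUS_INSUFFICIENT))
            continue
        alleles = _allele_sequences(per_individual[ind])
        depths = [av.amplicon.depth for av in avs]
        g = Genotype(
            ind,
            allele_names={names[s] for s in alleles},
            allele_sequences=set(alleles),
            mean_depth=float(np.mean(depths)),
            total_reads=int(np.sum(depths)),
            n_replicates_used=len(avs),
        )
        if not alleles:
            anomalies.append(Anomaly(ind, "no allele-classed variant in any retained amplicon"))
        if len(alleles) > config.max_alleles:
            anomalies.append(Anomaly(
                ind, f"genotype of {len(alleles)} alleles exceeds cap {config.max_alleles}"))
        genotypes.append(g)

    return CohortCalls(
        amplicons=collapsed,
        discarded_amplicons=sorted(discarded),
        final_class=final_class,
        genotypes=genotypes,
        catalog=catalog,
        anomalies=anomalies,
    )


# ---------------------------------------------------------------------------
# QC verifications
# ---------------------------------------------------------------------------

def trio_concordance(genotypes: list[Genotype],
                     trios: list[TrioRecord]) -> list[TrioReport]:
    """Mendelian check: every offspring allele must occur in a parent.

    A mismatch lists the orphan alleles; the suspect parent (dropout
    candidate) is the one sharing no allele with the offspring while the
    other parent shares some.
    """
    by_id = {g.individual_id: g for g in genotypes}
    reports: list[TrioReport] = []
    for trio in trios:
        members = [by_id.get(i) for i in (trio.offspring_id, trio.dam_id, trio.sire_id)]
        if any(m is None or m.status != STATUS_GENOTYPED for m in members):
            missing = [i for i, m in zip(
                (trio.offspring_id, trio.dam_id, trio.sire_id), members)
                if m is None or m.status != STATUS_GENOTYPED]
            reports.append(TrioReport(trio, "skipped",
                                      reason=f"ungenotyped member(s): {','.join(missing)}"))
            continue
        off, dam, sire = (m.allele_names for m in members)
        orphans = off - dam - sire
        if not orphans:
            reports.append(TrioReport(trio, "concordant"))
            continue
        dam_explains = bool(off & dam)
        sire_explains = bool(off & sire)
        suspect = None
        if dam_explains and not sire_explains:
            suspect = trio.sire_id
        elif sire_explains and not dam_explains:
            suspect = trio.dam_id
        reports.append(TrioReport(trio, "mismatch", orphan_alleles=orphans,
                                  suspect_parent=suspect))
    return reports


class SaturationWarning(UserWarning):
    """Allele count still rises with depth: sequencing may be unsaturated."""


def depth_saturation_check(genotypes: list[Genotype]) -> tuple[float, float]:
    """OLS of allele count on mean per-amplicon depth; returns (slope, R^2).

    Warns when the slope is significantly positive (one-sided p < 0.05),
    i.e. deeper-sequenced individuals still gain alleles.
    """
    pts = [(g.mean_depth, len(g.allele_names))
           for g in genotypes if g.status == STATUS_GENOTYPED]
    if len(pts) < 3:
        raise ValueError("depth_saturation_check needs >= 3 genotyped individuals")
    x = np.array([p[0] for p in pts], dtype=float)
    y = np.array([p[1] for p in pts], dtype=float)
    if np.allclose(y, y[0]) or np.allclose(x, x[0]):
        return 0.0, 0.0
    res = stats.linregress(x, y)
    slope, r2 = float(res.slope), float(res.rvalue ** 2)
    one_sided_p = res.pvalue / 2 if slope > 0 else 1.0 - res.pvalue / 2
    if slope > 0 and one_sided_p < 0.05:
        warnings.warn(
            f"allele count increases with read depth (slope={slope:.3g}, "
            f"one-sided p={one_sided_p:.3g}); coverage may be unsaturated",
            SaturationWarning,
            stacklevel=2,
        )
    return slope, r2
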