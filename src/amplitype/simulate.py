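"""Synthetic amplicon cohorts with known truth.

The generator reproduces the statistical structure the caller assumes:
multi-copy genotypes drawn from an allele pool, per-allele amplification
efficiencies (the source of allelic dropout), negative-binomial read depth,
substitution and homopolymer-indel read errors, single-crossover PCR
chimeras, MID/primer-fused reads in both orientations, and replicate PCRs.
Every emitted read carries provenance, so tests can attribute each
genotyping miss to its cause.

Platform profiles are coarse multipliers (pyrosequencing-style chemistry
doubles homopolymer indels; ion-semiconductor halves substitutions), not
flowgram simulations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from ._seq import revcomp
from .io import (
    AlleleCatalog,
    SampleSheet,
    SampleSheetEntry,
    SequencedRead,
    write_fasta,
    write_fastq,
    write_sample_sheet,
)

# concrete expansions of the degenerate site-specific DRB exon-2 primers
# (the W of the forward primer is emitted as T; QC matches it degenerately)
DEFAULT_FORWARD_PRIMER = "GAGTGTCATTTCTTCAACGGGACG"
DEFAULT_REVERSE_PRIMER = "GATCCCGTAGTTGTGTCTGCA"

_SENSE_CODONS = None


def _sense_codons() -> list[str]:
    global _SENSE_CODONS
    if _SENSE_CODONS is None:
        from .selection import _STANDARD_TABLE

        _SENSE_CODONS = sorted(c for c, aa in _STANDARD_TABLE.items() if aa != "*")
    return _SENSE_CODONS


@dataclass
class SimConfig:
    """Study-condition knobs for one simulated cohort.

    Defaults emulate the motivating system: a 171-bp exon-2 fragment, a
    pool of distinct alleles separated by >= 3 bp, four gene copies per
    individual, wide per-allele amplification-efficiency spread, deep
    overdispersed coverage, low per-base substitution noise, homopolymer
    indels, a small chimera fraction, and two replicate PCRs per
    individual.
    """

    n_alleles_pool: int = 20
    insert_length: int = 171
    min_pairwise_diff: int = 3
    pool_divergence: float | None = 0.035  # per-base divergence from a shared ancestor
    n_individuals: int = 50
    copy_number: int = 4
    efficiency_range: tuple[float, float] = (0.5, 1.0)
    depth_mean: float = 500.0
    depth_dispersion: float = 5.0  # NB shape; larger = tighter around the mean
    depth_min: int = 0
    sub_rate: float = 1e-3
    homopolymer_indel_rate: float = 5e-3
    chimera_rate: float = 0.02
    n_replicates: int = 2
    platform_profile: str = "profile-454"
    revcomp_fraction: float = 0.5
    mid_len: int = 10
    forward_primer: str = DEFAULT_FORWARD_PRIMER
    reverse_primer: str = DEFAULT_REVERSE_PRIMER
    locus_tag: str = "SimDRB"
    seed: int = 0

    def __post_init__(self) -> None:
        for rate in (self.sub_rate, self.homopolymer_indel_rate, self.chimera_rate):
            if not (0.0 <= rate <= 1.0):
                raise ValueError("rates must be proportions in [0, 1]")
        if self.depth_mean <= 0:
            raise ValueError("depth_mean must be positive")
        if self.min_pairwise_diff < 1:
            raise ValueError("min_pairwise_diff must be >= 1")
        if self.platform_profile not in ("profile-454", "profile-pgm"):
            raise ValueError("platform_profile must be 'profile-454' or 'profile-pgm'")

    @property
    def effective_sub_rate(self) -> float:
        return self.sub_rate * (0.5 if self.platform_profile == "profile-pgm" else 1.0)

    @property
    def effective_hp_rate(self) -> float:
        return self.homopolymer_indel_rate * (
            2.0 if self.platform_profile == "profile-454" else 1.0)


@dataclass
class ReadProvenance:
    read_id: str
    individual_id: str
    replicate_id: str
    source_allele: str | None  # None for chimeric reads
    chimera_parents: tuple[str, str] | None = None
    chimera_breakpoint: int | None = None
    n_substitutions: int = 0
    n_indels: int = 0
    reverse_oriented: bool = False


@dataclass
class SimTruth:
    pool: AlleleCatalog
    genotypes: dict[str, dict[str, int]]  # individual -> allele name -> copy dosage
    efficiencies: dict[tuple[str, str], float]  # (individual, allele) -> efficiency
    sheet: SampleSheet | None = None
    provenance: dict[str, ReadProvenance] = field(default_factory=dict)
    depth_overrides: dict[tuple[str, str], int] = field(default_factory=dict)

    def distinct_alleles(self, individual_id: str) -> set[str]:
        return set(self.genotypes[individual_id])


# ---------------------------------------------------------------------------
# Pool and cohort
# ---------------------------------------------------------------------------

def _random_coding(length: int, rng) -> str:
    codons = _sense_codons()
    n_codons, tail = divmod(length, 3)
    body = "".join(rng.choice(codons) for _ in range(n_codons))
    body += "".join(rng.choice(list("ACGT")) for _ in range(tail))
    return body


def _diverge_coding(ancestor: str, rate: float, rng) -> str:
    """Substitute each base with prob ``rate``, never creating in-frame stops."""
    from .selection import _STANDARD_TABLE

    chars = list(ancestor)
    n_codons = len(ancestor) // 3
    for pos in np.nonzero(rng.random(len(chars)) < rate)[0]:
        old = chars[pos]
        alts = [b for b in "ACGT" if b != old]
        rng.shuffle(alts)
        for b in alts:
            chars[pos] = b
            ci = pos // 3
            if ci >= n_codons:
                break  # trailing partial codon, anything goes
            codon = "".join(chars[3 * ci: 3 * ci + 3])
            if _STANDARD_TABLE[codon] != "*":
                break
            chars[pos] = old
    return "".join(chars)


def simulate_pool(config: SimConfig, max_attempts: int = 10_000) -> AlleleCatalog:
    """Allele pool: codon-structured, stop-free, pairwise >= min diff apart.

    With ``pool_divergence`` set (the default), alleles descend from one
    random coding ancestor with that per-base substitution probability, so
    pairwise differences land near 2 x divergence x length — the realistic
    regime for a hypervariable exon (tens of bp, not random-sequence
    distances).  With ``pool_divergence=None`` each allele is an
    independent random coding sequence.  Either way the pool is
    rejection-sampled so every pair differs by at least
    ``min_pairwise_diff`` substitutions (keeping true alleles out of each
    other's artifact neighborhoods).
    """
    if config.n_alleles_pool < 1:
        raise ValueError("n_alleles_pool must be >= 1")
    rng = np.random.default_rng(config.seed)
    ancestor = _random_coding(config.insert_length, rng)
    seqs: list[str] = []
    attempts = 0
    while len(seqs) < config.n_alleles_pool:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError(
                "could not sample a pool with the requested minimum pairwise "
                "difference; lower n_alleles_pool or min_pairwise_diff")
        if config.pool_divergence is None:
            body = _random_coding(config.insert_length, rng)
        else:
            body = _diverge_coding(ancestor, config.pool_divergence, rng)
        if all(_hamming(body, s) >= config.min_pairwise_diff for s in seqs):
            seqs.append(body)
    width = max(2, len(str(config.n_alleles_pool)))
    alleles = {f"{config.locus_tag}*{i + 1:0{width}d}": s for i, s in enumerate(seqs)}
    return AlleleCatalog(alleles=alleles, locus_tag=config.locus_tag)


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def simulate_cohort(pool: AlleleCatalog, config: SimConfig) -> SimTruth:
    """Draw genotypes and efficiencies: copy_number draws with replacement
    (uniform over the pool), so 1..copy_number distinct alleles per
    individual; efficiency ~ uniform(efficiency_range) per (individual,
    allele)."""
    rng = np.random.default_rng(config.seed + 1)
    names = list(pool.alleles)
    genotypes: dict[str, dict[str, int]] = {}
    efficiencies: dict[tuple[str, str], float] = {}
    width = len(str(config.n_individuals))
    lo, hi = config.efficiency_range
    for i in range(config.n_individuals):
        ind = f"ind{i + 1:0{width}d}"
        draws = rng.choice(names, size=config.copy_number, replace=True)
        dosage: dict[str, int] = {}
        for a in draws:
            dosage[a] = dosage.get(a, 0) + 1
        genotypes[ind] = dosage
        for a in dosage:
            efficiencies[(ind, a)] = float(rng.uniform(lo, hi))
    sheet = _make_sample_sheet(list(genotypes), config)
    return SimTruth(pool=pool, genotypes=genotypes, efficiencies=efficiencies,
                    sheet=sheet)


def _make_sample_sheet(individuals: list[str], config: SimConfig) -> SampleSheet:
    """Unique MID pairs per (individual, replicate), one synthetic run."""
    rng = np.random.default_rng(config.seed + 2)
    n_needed = len(individuals) * config.n_replicates
    n_tags = int(np.ceil(np.sqrt(n_needed))) + 1
    tags: list[str] = []
    while len(tags) < 2 * n_tags:
        t = "".join(rng.choice(list("ACGT")) for _ in range(config.mid_len))
        if all(_hamming(t, u) >= 3 for u in tags):
            tags.append(t)
    fwd, rev = tags[:n_tags], tags[n_tags:]
    entries = []
    i = 0
    for ind in individuals:
        for r in range(config.n_replicates):
            fi, ri = divmod(i, n_tags)
            entries.append(SampleSheetEntry(fwd[fi], rev[ri], ind, f"rep{r + 1}", "sim-run1"))
            i += 1
    return SampleSheet(entries=entries)


# ---------------------------------------------------------------------------
# Reads
# ---------------------------------------------------------------------------

def _apply_homopolymer_indels(seq: str, rate: float, rng) -> tuple[str, int]:
    """+-1 bp slips in homopolymer runs of length >= 3."""
    if rate <= 0:
        return seq, 0
    out = []
    n_indels = 0
    i = 0
    while i < len(seq):
        j = i
        while j < len(seq) and seq[j] == seq[i]:
            j += 1
        run = seq[i:j]
        if len(run) >= 3 and rng.random() < rate:
            n_indels += 1
            run = run + run[0] if rng.random() < 0.5 else run[:-1]
        out.append(run)
        i = j
    return "".join(out), n_indels


def _mutate(seq: str, rate: float, rng) -> tuple[str, int]:
    if rate <= 0:
        return seq, 0
    n = rng.binomial(len(seq), rate)
    if n == 0:
        return seq, 0
    pos = rng.choice(len(seq), size=n, replace=False)
    chars = list(seq)
    for p in pos:
        alts = [b for b in "ACGT" if b != chars[p]]
        chars[p] = alts[rng.integers(0, 3)]
    return "".join(chars), int(n)


def _draw_depth(config: SimConfig, rng) -> int:
    """Negative-binomial depth, optionally truncated below at depth_min."""
    shape = config.depth_dispersion
    p = shape / (shape + config.depth_mean)
    for _ in range(1000):
        d = int(rng.negative_binomial(shape, p))
        if d >= max(1, config.depth_min):
            return d
    return max(1, config.depth_min)


def simulate_amplicon(truth: SimTruth, individual_id: str, replicate_id: str,
                      config: SimConfig, rng) -> list[SequencedRead]:
    """Generate one replicate PCR's tagged reads for one individual."""
    entry = next(e for e in truth.sheet.entries
                 if e.individual_id == individual_id and e.replicate_id == replicate_id)
    dosage = truth.genotypes[individual_id]
    names = sorted(dosage)
    weights = np.array([
        dosage[a] * truth.efficiencies[(individual_id, a)] for a in names
    ], dtype=float)
    weights /= weights.sum()
    depth = truth.depth_overrides.get((individual_id, replicate_id))
    if depth is None:
        depth = _draw_depth(config, rng)

    reads: list[SequencedRead] = []
    for r in range(depth):
        read_id = f"{individual_id}:{replicate_id}:{r:06d}"
        chimera_parents = chimera_breakpoint = None
        source: str | None
        if len(names) >= 2 and rng.random() < config.chimera_rate:
            ia, ib = rng.choice(len(names), size=2, replace=False, p=weights)
            a, b = names[ia], names[ib]
            k = int(rng.integers(1, config.insert_length))
            insert = truth.pool.alleles[a][:k] + truth.pool.alleles[b][k:]
            source, chimera_parents, chimera_breakpoint = None, (a, b), k
        else:
            source = names[int(rng.choice(len(names), p=weights))]
            insert = truth.pool.alleles[source]

        insert, n_ind = _apply_homopolymer_indels(insert, config.effective_hp_rate, rng)
        insert, n_sub = _mutate(insert, config.effective_sub_rate, rng)

        bases = (entry.forward_mid + config.forward_primer + insert
                 + revcomp(entry.reverse_mid + config.reverse_primer))
        quals = [int(q) for q in rng.integers(30, 41, size=len(bases))]
        reverse = bool(rng.random() < config.revcomp_fraction)
        if reverse:
            bases = revcomp(bases)
            quals = quals[::-1]
        reads.append(SequencedRead(read_id, bases, quals, entry.run_id))
        truth.provenance[read_id] = ReadProvenance(
            read_id, individual_id, replicate_id, source,
            chimera_parents, chimera_breakpoint, n_sub, n_ind, reverse)
    return reads


def simulate_reads(truth: SimTruth, config: SimConfig) -> list[SequencedRead]:
    """All reads of the cohort, replicate by replicate, deterministically."""
    rng = np.random.default_rng(config.seed + 3)
    reads: list[SequencedRead] = []
    for e in truth.sheet.entries:
        reads.extend(simulate_amplicon(truth, e.individual_id, e.replicate_id, config, rng))
    return reads


def simulate_study(config: SimConfig,
                   depth_overrides: dict[tuple[str, str], int] | None = None):
    """Pool + cohort + reads in one call; returns (truth, reads)."""
    pool = simulate_pool(config)
    truth = simulate_cohort(pool, config)
    if depth_overrides:
        truth.depth_overrides.update(depth_overrides)
    reads = simulate_reads(truth, config)
    return truth, reads


def noiseless(config: SimConfig) -> SimConfig:
    """The same study with all error processes off and equal efficiencies."""
    return replace(config, sub_rate=0.0, homopolymer_indel_rate=0.0,
                   chimera_rate=0.0, efficiency_range=(1.0, 1.0))


# ---------------------------------------------------------------------------
# Truth emission
# ---------------------------------------------------------------------------

def emit_truth(truth: SimTruth, reads: list[SequencedRead],
               out_dir: str | Path) -> dict[str, Path]:
    """Write the self-contained cohort: inputs for the caller + truth files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "pool_fasta": out / "pool.fasta",
        "sample_sheet": out / "sample_sheet.tsv",
        "fastq": out / "reads.fastq",
        "truth_genotypes": out / "truth_genotypes.tsv",
        "truth_efficiencies": out / "truth_efficiencies.tsv",
        "truth_provenance": out / "truth_provenance.tsv",
    }
    write_fasta(truth.pool, paths["pool_fasta"])
    write_sample_sheet(truth.sheet, paths["sample_sheet"])
    write_fastq(reads, paths["fastq"])

    rows = [[ind, len(dos), ",".join(sorted(dos)),
             ",".join(str(dos[a]) for a in sorted(dos))]
            for ind, dos in truth.genotypes.items()]
    pd.DataFrame(rows, columns=["individual_id", "n_alleles", "allele_names",
                                "copy_dosage"]).to_csv(
        paths["truth_genotypes"], sep="\t", index=False)

    rows = [[ind, a, f"{eff:.6f}"] for (ind, a), eff in sorted(truth.efficiencies.items())]
    pd.DataFrame(rows, columns=["individual_id", "allele_name", "efficiency"]).to_csv(
        paths["truth_efficiencies"], sep="\t", index=False)

    rows = []
    for p in truth.provenance.values():
        rows.append([
            p.read_id, p.individual_id, p.replicate_id,
            p.source_allele or "",
            "|".join(p.chimera_parents) if p.chimera_parents else "",
            "" if p.chimera_breakpoint is None else p.chimera_breakpoint,
            p.n_substitutions, p.n_indels, int(p.reverse_oriented),
        ])
    pd.DataFrame(rows, columns=[
        "read_id", "individual_id", "replicate_id", "source_allele",
        "chimera_parents", "chimera_breakpoint", "n_substitutions",
        "n_indels", "reverse_oriented"]).to_csv(
        paths["truth_provenance"], sep="\t", index=False)
    return paths
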