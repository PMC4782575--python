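"""Stage orchestration: QC -> cluster -> call -> stats, with a run manifest.

Stages run strictly in order, each completed cohort-wide before the next
begins.  The manifest snapshots the configuration and the per-stage counts,
and those counts must reconcile (reads in == kept + rejected + unassigned;
variants == sum over final classes), so a run is fully auditable.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .caller import (
    CallerConfig,
    CohortCalls,
    TrioRecord,
    call_genotypes,
    depth_saturation_check,
    trio_concordance,
)
from .io import (
    AlleleCatalog,
    parse_fasta,
    parse_fastq,
    parse_sample_sheet,
    read_genotype_table,
    write_fasta,
    write_genotype_table,
    write_tsv,
)
from .qc import DEFAULT_FORWARD_PRIMER, DEFAULT_REVERSE_PRIMER, QcConfig, run_qc
from .variants import INTRA_SINGLETON

log = logging.getLogger("amplitype")


@dataclass
class PipelineConfig:
    fastq: list[str] = field(default_factory=list)  # path or path:run_id
    sample_sheet: str = ""
    references: str = ""
    out_dir: str = "amplitype_out"
    forward_primer: str = DEFAULT_FORWARD_PRIMER
    reverse_primer: str = DEFAULT_REVERSE_PRIMER
    locus_tag: str = "DRB"
    qc: QcConfig = field(default_factory=QcConfig)
    caller: CallerConfig = field(default_factory=CallerConfig)
    sensitivity_thresholds: list[int] = field(default_factory=list)
    trios: str = ""
    abs_mask: str = ""
    run_stats: bool = True
    stats_seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        qc = QcConfig(**raw.pop("qc", {}))
        caller = CallerConfig(**raw.pop("caller", {}))
        return cls(qc=qc, caller=caller, **raw)


@dataclass
class RunManifest:
    tool_version: str
    config: dict
    per_run_reads: dict = field(default_factory=dict)
    amplicons_retained: int = 0
    amplicons_discarded: int = 0
    variant_class_counts: dict = field(default_factory=dict)
    n_singletons: int = 0
    n_genotyped: int = 0
    n_insufficient: int = 0
    n_anomalies: int = 0
    saturation_slope: float | None = None
    saturation_r2: float | None = None
    seeds: dict = field(default_factory=dict)

    def reconciles(self) -> bool:
        for counts in self.per_run_reads.values():
            total = counts["kept"] + counts["unassigned"] + sum(
                counts["rejected"].values())
            if counts["reads_in"] != total:
                return False
        return True

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")


def _load_trios(path: str) -> list[TrioRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    need = ["offspring_id", "dam_id", "sire_id"]
    missing = [c for c in need if c not in df.columns]
    if missing:
        raise ValueError(f"trio table is missing columns: {', '.join(missing)}")
    return [TrioRecord(r.offspring_id, r.dam_id, r.sire_id) for r in df.itertuples()]


def _variant_report(calls: CohortCalls) -> pd.DataFrame:
    rows = []
    for key, av in calls.amplicons.items():
        ind = key[0]
        for v in av.variants:
            final = calls.final_class.get((ind, v.sequence), "")
            chim = v.chimera
            rows.append([
                ind, key[1], key[2], v.sequence, v.count,
                f"{v.rel_freq:.6f}", v.intra_class or "", final,
                v.parent or "",
                chim.parent_a if chim else "", chim.parent_b if chim else "",
                chim.breakpoint if chim else "",
            ])
    return pd.DataFrame(rows, columns=[
        "individual_id", "replicate_id", "run_id", "sequence", "count",
        "rel_freq", "intra_class", "final_class", "artifact_parent",
        "chimera_parent_a", "chimera_parent_b", "chimera_breakpoint"])


def run_pipeline(config: PipelineConfig) -> tuple[CohortCalls, RunManifest]:
    """Execute all stages; writes every report into ``config.out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    sheet = parse_sample_sheet(config.sample_sheet)
    catalog = parse_fasta(config.references, locus_tag=config.locus_tag)

    def read_stream():
        for spec in config.fastq:
            path, _, run_id = spec.partition("::")
            yield from parse_fastq(path, run_id=run_id or "")

    log.info("Step I: filtering, trimming and demultiplexing reads")
    amplicons, counters = run_qc(read_stream(), sheet, catalog,
                                 config.forward_primer, config.reverse_primer,
                                 config.qc)
    for run_id, c in sorted(counters.items()):
        log.info("run %s: %d reads in, %d kept, %d rejected, %d unassigned",
                 run_id or "<default>", c.reads_in, c.kept, c.total_rejected,
                 c.unassigned)

    log.info("Steps II-VI: variant classification and genotype assembly")
    calls = call_genotypes(amplicons, config.caller, catalog,
                           individual_order=sheet.individuals)

    write_genotype_table(calls.genotypes, out / "genotypes.tsv")
    write_tsv(_variant_report(calls), out / "variant_classification.tsv")
    write_fasta(calls.catalog, out / "allele_catalog.fasta")
    write_tsv(pd.DataFrame(
        [[a.individual_id, a.description] for a in calls.anomalies],
        columns=["individual_id", "description"]), out / "anomalies.tsv")

    attrition_rows = []
    for run_id, c in sorted(counters.items()):
        row = {"run_id": run_id, "reads_in": c.reads_in, "kept": c.kept,
               "unassigned": c.unassigned}
        row.update({f"rejected_{k}": v for k, v in sorted(c.rejected.items())})
        attrition_rows.append(row)
    write_tsv(pd.DataFrame(attrition_rows).fillna(0), out / "attrition.tsv")

    trio_reports = []
    if config.trios:
        trios = _load_trios(config.trios)
        trio_reports = trio_concordance(calls.genotypes, trios)
        write_tsv(pd.DataFrame(
            [[t.trio.offspring_id, t.trio.dam_id, t.trio.sire_id, t.status,
              ",".join(sorted(t.orphan_alleles)), t.suspect_parent or "",
              t.reason or ""] for t in trio_reports],
            columns=["offspring_id", "dam_id", "sire_id", "status",
                     "orphan_alleles", "suspect_parent", "reason"]),
            out / "trio_report.tsv")

    slope = r2 = None
    n_genotyped = sum(g.status == "genotyped" for g in calls.genotypes)
    if n_genotyped >= 3:
        slope, r2 = depth_saturation_check(calls.genotypes)

    n_singletons = sum(
        v.intra_class == INTRA_SINGLETON
        for av in calls.amplicons.values() for v in av.variants)

    manifest = RunManifest(
        tool_version=__version__,
        config={
            "qc": asdict(config.qc), "caller": asdict(config.caller),
            "forward_primer": config.forward_primer,
            "reverse_primer": config.reverse_primer,
            "locus_tag": config.locus_tag,
            "fastq": list(config.fastq), "sample_sheet": config.sample_sheet,
            "references": config.references,
        },
        per_run_reads={
            run_id: {"reads_in": c.reads_in, "kept": c.kept,
                     "rejected": dict(sorted(c.rejected.items())),
                     "unassigned": c.unassigned}
            for run_id, c in sorted(counters.items())},
        amplicons_retained=len(calls.amplicons),
        amplicons_discarded=len(calls.discarded_amplicons),
        variant_class_counts=calls.class_counts(),
        n_singletons=n_singletons,
        n_genotyped=n_genotyped,
        n_insufficient=sum(g.status != "genotyped" for g in calls.genotypes),
        n_anomalies=len(calls.anomalies),
        saturation_slope=slope,
        saturation_r2=r2,
        seeds={"stats_seed": config.stats_seed},
    )
    if not manifest.reconciles():
        raise RuntimeError("manifest counters do not reconcile; aborting")
    manifest.write(out / "manifest.json")

    if config.sensitivity_thresholds:
        _sensitivity_mode(amplicons, sheet, catalog, config, out)

    return calls, manifest


def _sensitivity_mode(amplicons, sheet, catalog: AlleleCatalog,
                      config: PipelineConfig, out: Path) -> None:
    """Re-genotype the same amplicons at alternative depth thresholds."""
    from dataclasses import replace as dc_replace

    # one shared catalog across thresholds keeps novel-allele names stable,
    # so genotype comparisons reflect sequence content, not naming order
    tables = {}
    for thr in sorted(config.sensitivity_thresholds):
        cfg = dc_replace(config.caller, min_amplicon_depth=thr)
        calls = call_genotypes(amplicons, cfg, catalog,
                               individual_order=sheet.individuals)
        path = out / f"genotypes_threshold_{thr}.tsv"
        write_genotype_table(calls.genotypes, path)
        tables[thr] = path
    thresholds = sorted(tables)
    rows = []
    for a, b in zip(thresholds, thresholds[1:]):
        cmp = compare_genotype_sets(read_genotype_table(tables[a]),
                                    read_genotype_table(tables[b]))
        pct = 100.0 * sum(v == "identical" for v in cmp.values()) / len(cmp)
        rows.append([a, b, f"{pct:.2f}",
                     ",".join(sorted(i for i, v in cmp.items() if v != "identical"))])
    write_tsv(pd.DataFrame(rows, columns=[
        "threshold_a", "threshold_b", "pct_identical", "differing_individuals"]),
        out / "sensitivity_summary.tsv")


def compare_genotype_sets(a: pd.DataFrame, b: pd.DataFrame) -> dict[str, str]:
    """Per-individual concordance between two genotype tables.

    Returns individual -> 'identical' or 'differing'.  Individuals are
    matched on id; an individual genotyped in one table but not the other
    is 'differing'.  Raises when the id sets are disjoint.
    """
    a_map = {r.individual_id: r for r in a.itertuples()}
    b_map = {r.individual_id: r for r in b.itertuples()}
    shared = set(a_map) & set(b_map)
    if not shared:
        raise ValueError("genotype tables share no individual ids")
    out: dict[str, str] = {}
    for ind in sorted(set(a_map) | set(b_map)):
        ra, rb = a_map.get(ind), b_map.get(ind)
        if ra is None or rb is None:
            out[ind] = "differing"
            continue
        sa = _allele_set(ra)
        sb = _allele_set(rb)
        status_a = ra.status
        status_b = rb.status
        same = status_a == status_b and sa == sb
        out[ind] = "identical" if same else "differing"
    return out


def _allele_set(row) -> frozenset[str]:
    names = getattr(row, "allele_names", "")
    if not isinstance(names, str) or not names:
        return frozenset()
    return frozenset(names.split(","))
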