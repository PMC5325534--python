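"""End-to-end orchestration: combine per-sample calls into breed
databases, remove multi-allele error positions, apply the depth-only,
ratio-only and combined stringent filters, build the replicate-concordant
Venn decomposition, breed comparisons, de-novo detection, QTL/candidate-
gene classification, mapping statistics and validation statistics.

Every stage is a pure function of (inputs, settings); when an output
directory is given, each file carries a provenance header (stage,
parameters, seed).  Any stage failure aborts with the stage name;
partial outputs already written are preserved.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

from . import build, compare, filters, io, mapping, popgen, qtl
from .model import (
    Breed,
    FlagstatProfile,
    GeneLocus,
    GenotypeTable,
    SampleMeta,
    SnpDb,
    VariantRecord,
)


@dataclass
class PipelineSettings:
    """Defaults reproduce the study's stated thresholds: combined filter
    at alternate depth >= 10 with a 100% SNP ratio, Venn concordance at
    depth >= 5 in both replicates, top-10 polymorphic ranking."""

    seed: int = 0
    min_depth: int = 10
    ratio: Optional[float] = 1.0
    venn_min_depth: int = 5
    evidence_mode: str = "any"
    top_k: int = 10
    mono_def: str = "fixed"
    mc_dememorization: int = 10_000
    mc_batches: int = 20
    mc_iterations: int = 5_000

    def mc(self) -> popgen.McSettings:
        return popgen.McSettings(
            seed=self.seed, dememorization=self.mc_dememorization,
            batches=self.mc_batches,
            iterations_per_batch=self.mc_iterations)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _result_to_json(res: popgen.ExactTestResult) -> dict:
    d = {"p_value": res.p_value, "method": res.method,
         "statistic": res.statistic, "mc_std_error": res.mc_std_error}
    if res.settings is not None:
        d["settings"] = asdict(res.settings)
    return d


def run_pipeline(per_sample: dict[SampleMeta, Sequence[VariantRecord]],
                 settings: PipelineSettings,
                 profiles: Optional[Sequence[FlagstatProfile]] = None,
                 loci: Optional[Sequence[GeneLocus]] = None,
                 genotype_tables: Optional[Sequence[GenotypeTable]] = None,
                 outdir: Optional[Path] = None) -> dict:
    """Run every stage; returns the aggregated run report (all counts)
    and, if ``outdir`` is given, writes per-stage TSV/JSON outputs."""
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"settings": asdict(settings), "stages": {}}

    def stage(name):
        def deco(fn):
            try:
                report["stages"][name] = fn()
            except Exception as exc:  # noqa: BLE001 - reported with stage name
                raise StageError(name, exc) from exc
        return deco

    all_records = [r for recs in per_sample.values() for r in recs]
    breeds_present = sorted({s.breed for s in per_sample},
                            key=lambda b: b.value)
    raw_dbs: dict[Breed, SnpDb] = {}
    clean_dbs: dict[Breed, SnpDb] = {}
    combined_dbs: dict[Breed, SnpDb] = {}

    @stage("build")
    def _build():
        counts = {}
        for breed in breeds_present:
            recs = [r for s, rs in per_sample.items()
                    if s.breed == breed for r in rs]
            raw_dbs[breed] = build.build_breed_snpdb(recs, breed)
            counts[breed.value] = len(raw_dbs[breed])
        summary = build.summarize_counts(
            {s: list(rs) for s, rs in per_sample.items()})
        return {"reliable_records": counts,
                "grand_totals": summary["grand_totals"],
                "breed_shares_pct": summary["breed_shares_pct"],
                "average_per_bull": summary["average_per_bull"]}

    @stage("error_removal")
    def _errors():
        out = {}
        for breed, db in raw_dbs.items():
            clean, removed = build.remove_error_records(db)
            clean_dbs[breed] = clean
            out[breed.value] = {"removed": removed, "remaining": len(clean)}
            if outdir is not None:
                io.write_snpdb_tsv(clean, outdir / f"{breed.value}_noerr.tsv")
        return out

    @stage("filters")
    def _filters():
        out = {}
        for breed, db in clean_dbs.items():
            depth_only = filters.filter_records(
                db, min_depth=settings.min_depth, exact_ratio=None,
                evidence_mode=settings.evidence_mode)
            ratio_only = filters.filter_records(
                db, min_depth=0, exact_ratio=settings.ratio,
                evidence_mode=settings.evidence_mode)
            combined = filters.filter_records(
                db, min_depth=settings.min_depth, exact_ratio=settings.ratio,
                evidence_mode=settings.evidence_mode)
            combined_dbs[breed] = combined
            out[breed.value] = {"depth_only": len(depth_only),
                                "ratio_only": len(ratio_only),
                                "combined": len(combined)}
            if outdir is not None:
                io.write_snpdb_tsv(combined,
                                   outdir / f"{breed.value}_combined.tsv")
        return out

    @stage("venn")
    def _venn():
        if len(breeds_present) != 3:
            return {"skipped": "needs exactly 3 breeds"}
        concordant = [
            filters.replicate_concordant_set(
                all_records, breed, min_depth=settings.venn_min_depth)
            for breed in breeds_present]
        regions = compare.venn_regions(concordant)
        counts = {label: r.count for label, r in regions.items()}
        if outdir is not None:
            io.write_outputs(counts, outdir / "venn.json", "json")
        return counts

    @stage("breed_comparison")
    def _compare():
        out = {}
        dbs = list(combined_dbs.values())
        for focus in dbs:
            others = [d for d in dbs if d.breed != focus.breed]
            for other in others:
                unique = compare.breed_unique_sets(focus, [other])
                out[f"{focus.breed}_not_in_{other.breed}"] = len(unique)
            if len(others) == 2:
                unique_both = compare.breed_unique_sets(focus, others)
                out[f"{focus.breed}_not_in_either"] = len(unique_both)
        return out

    @stage("de_novo")
    def _denovo():
        out = {}
        for breed in breeds_present:
            recs = [r for s, rs in per_sample.items()
                    if s.breed == breed for r in rs]
            dn = filters.detect_de_novo(recs, min_depth=settings.min_depth,
                                        exact_ratio=settings.ratio)
            out[breed.value] = len(dn)
        return out

    @stage("qtl_cg")
    def _qtl():
        if loci is None:
            return {"skipped": "no locus table supplied"}
        out = {}
        per_breed = {}
        for breed, db in combined_dbs.items():
            summaries = qtl.locus_hits(db, loci)
            classified = qtl.classify_locus_polymorphism(
                summaries, db, top_k=settings.top_k,
                mono_def=settings.mono_def)
            per_breed[breed.value] = classified
            out[breed.value] = {
                "no_hit": sum(s.status == "no_hit" for s in classified),
                "monomorphic": sum(s.status == "monomorphic"
                                   for s in classified),
                "polymorphic": sum(s.status == "polymorphic"
                                   for s in classified),
                "highly_polymorphic": sorted(
                    s.symbol for s in classified if s.highly_polymorphic),
            }
        out["concordance"] = qtl.cross_breed_concordance(per_breed)
        return out

    @stage("mapping_stats")
    def _mapstats():
        if not profiles:
            return {"skipped": "no flagstat profiles supplied"}
        per_breed = mapping.aggregate_and_percentages(profiles, "breed")
        overall = mapping.aggregate_and_percentages(profiles, "global")
        return {
            "per_breed": {name: {
                "properly_paired_pct": s.properly_paired_pct,
                "overall_alignment_pct": s.overall_alignment_pct}
                for name, s in per_breed.items()},
            "overall_alignment_pct": overall.overall_alignment_pct,
        }

    @stage("validation")
    def _validate():
        if not genotype_tables:
            return {"skipped": "no genotype tables supplied"}
        rep = popgen.validate_markers(genotype_tables, settings.mc())
        out = {"excluded_monomorphic": rep["excluded_monomorphic"],
               "markers": {}}
        for marker, entry in rep["markers"].items():
            m = {"hwe": {b: _result_to_json(r)
                         for b, r in entry["hwe"].items()}}
            if "genic_differentiation" in entry:
                m["chi_square"] = entry["chi_square"]
                m["genic_differentiation"] = _result_to_json(
                    entry["genic_differentiation"])
                m["genotypic_differentiation"] = _result_to_json(
                    entry["genotypic_differentiation"])
            out["markers"][marker] = m
        if "global" in rep:
            out["global"] = rep["global"]
        return out

    if outdir is not None:
        io.write_outputs(report, outdir / "report.json", "json")
    return report


# ---------------------------------------------------------------------------
# file-based entry (flat key=value config)
# ---------------------------------------------------------------------------

def load_manifest(path) -> list[dict]:
    """Panel manifest CSV: sample_id, breed, age_months, replicate, path,
    dialect."""
    import csv

    with open(path, newline="") as fh:
        return list(csv.DictReader(fh))


def run_from_config(config_path) -> dict:
    """Flat ``key = value`` config naming the inputs and thresholds."""
    cfg: dict[str, str] = {}
    base = Path(config_path).parent
    for line in Path(config_path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, _, value = line.partition("=")
        cfg[key.strip()] = value.strip()

    settings = PipelineSettings(
        seed=int(cfg.get("seed", 0)),
        min_depth=int(cfg.get("min_depth", 10)),
        ratio=None if cfg.get("ratio", "1.0").lower() == "none"
        else float(cfg.get("ratio", "1.0")),
        venn_min_depth=int(cfg.get("venn_min_depth", 5)),
        evidence_mode=cfg.get("evidence_mode", "any"),
        top_k=int(cfg.get("top_k", 10)),
        mono_def=cfg.get("mono_def", "fixed"),
    )

    def resolve(p: str) -> Path:
        path = Path(p)
        return path if path.is_absolute() else base / path

    per_sample: dict[SampleMeta, list[VariantRecord]] = {}
    for row in load_manifest(resolve(cfg["manifest"])):
        sample = SampleMeta(sample_id=row["sample_id"],
                            breed=Breed(row["breed"]),
                            age_months=int(row["age_months"]),
                            replicate=int(row["replicate"]))
        per_sample[sample] = io.read_variant_calls(
            resolve(row["path"]), row.get("dialect", "tsv"), sample)

    profiles = None
    if "flagstat" in cfg:
        profiles = io.read_flagstat_tsv(resolve(cfg["flagstat"]))
    loci = None
    if "loci" in cfg:
        loci = io.read_gene_loci(resolve(cfg["loci"]),
                                 cfg.get("loci_dialect", "tsv"))
    tables = None
    if "genotypes" in cfg:
        tables = io.read_genotype_csv(resolve(cfg["genotypes"]))

    outdir = resolve(cfg["outdir"]) if "outdir" in cfg else None
    return run_pipeline(per_sample, settings, profiles=profiles, loci=loci,
                        genotype_tables=tables, outdir=outdir)
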