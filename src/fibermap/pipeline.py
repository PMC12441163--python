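"""End-to-end "simulate → classify → scan → map → annotate → DEG" driver.

Every run writes its stage outputs plus a manifest (structured config
echo, seed, config hash, package version) into one directory; rerunning
with the same configuration and seed is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bsa import bin_counts, detect_peak, subtract_shared_variants
from .color import average_replicates, classify_colors, compare_groups
from .deg import fold_change, normalize, summarize_pathway, test_deg
from .io import write_bed, write_fasta, write_gff3, write_table
from .ltr import annotate_ltr, call_pav
from .markers import calls_matrix, find_interval, score_recombinants
from .segregation import chi_square_ratio
from .sim import (
    CrossConfig,
    GenomeModel,
    assign_phenotypes,
    default_marker_panel,
    make_bulks,
    simulate_bulk_variants,
    simulate_counts,
    simulate_f2,
    simulate_locus_sequences,
    simulate_marker_calls,
)

log = logging.getLogger("fibermap")

ALL_STAGES = ("simulate", "classify", "segregate", "scan", "map", "annotate-ltr", "deg")


@dataclass(frozen=True)
class RunConfig:
    """Parameters of one pipeline run.

    Defaults mirror the emulated study design: 508 F2 plants, 77-plant
    bulks, 5-Mb scan bins, FDR 0.05 with a two-fold DEG threshold.
    """

    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES
    n_f2: int = 508
    bulk_size: int = 77
    noise_sd: float = 1.0
    genotyping_error: float = 0.02
    dropout: float = 0.05
    cream_band: float = 5.0
    bin_width: int = 5_000_000
    extend_fraction: float = 0.5
    segregation_ratio: tuple[float, float] = (3.0, 1.0)
    fdr_alpha: float = 0.05
    fold_threshold: float = 2.0
    n_genes: int = 2_000
    planted_folds: tuple[float, ...] = (179.0, 756.0)
    deg_dispersion: float = 0.05
    min_ltr: int = 500
    ltr_min_identity: float = 0.85
    pav_min_coverage: float = 0.8

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        if "stages" in raw:
            raw = {**raw, "stages": tuple(raw["stages"])}
        if "segregation_ratio" in raw:
            raw = {**raw, "segregation_ratio": tuple(raw["segregation_ratio"])}
        if "planted_folds" in raw:
            raw = {**raw, "planted_folds": tuple(raw["planted_folds"])}
        cfg = cls(**raw)
        bad = set(cfg.stages) - set(ALL_STAGES)
        if bad:
            raise ValueError(f"unknown stages: {sorted(bad)}")
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stages"] = list(self.stages)
        d["segregation_ratio"] = list(self.segregation_ratio)
        d["planted_folds"] = list(self.planted_folds)
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    def cross_config(self) -> CrossConfig:
        return CrossConfig(
            n_f2=self.n_f2,
            bulk_size=self.bulk_size,
            noise_sd=self.noise_sd,
            genotyping_error=self.genotyping_error,
            dropout=self.dropout,
            cream_band=self.cream_band,
            seed=self.seed,
        )


def run_pipeline(
    config: RunConfig, outdir, genome: GenomeModel | None = None
) -> dict:
    """Execute the requested stages in dependency order.

    Returns a JSON-serializable summary of the headline results (peak
    region, segregation fit, marker interval, PAV calls, DEG counts) and
    writes all per-stage files under ``outdir``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome = genome or GenomeModel.default()
    stages = [s for s in ALL_STAGES if s in config.stages]
    summary: dict = {"config_hash": config.config_hash(), "seed": config.seed}
    t0 = time.monotonic()

    master = np.random.SeedSequence(config.seed)
    streams = {
        name: np.random.default_rng(s)
        for name, s in zip(
            ("cross", "phenotype", "bulks", "variants", "sequences", "counts"),
            master.spawn(6),
        )
    }
    cross = config.cross_config()

    population = simulate_f2(genome, cross, rng=streams["cross"])
    assign_phenotypes(population, cross, rng=streams["phenotype"])
    log.info("simulated %d F2 individuals", len(population))

    if "simulate" in stages or "classify" in stages:
        pheno = population.phenotype_frame()
        write_table(pheno, outdir / "phenotypes.csv", sep=",")

    if "classify" in stages:
        averaged = average_replicates(pheno)
        groups = pheno.drop_duplicates("id").set_index("id")["group"]
        assignments = averaged.assign(group=groups.loc[averaged["id"]].to_numpy())
        write_table(assignments, outdir / "groups.csv", sep=",")
        comparisons = [
            compare_groups(
                averaged[ch].to_numpy(), assignments["group"].to_numpy(), trait=ch
            ).to_frame()
            for ch in ("L", "a", "b")
        ]
        write_table(pd.concat(comparisons, ignore_index=True), outdir / "group_comparisons.tsv")
        summary["groups"] = {k: int(v) for k, v in assignments["group"].value_counts().items()}

    if "segregate" in stages:
        counts = population.genotype_counts()
        carriers = sum(
            1 for ind in population.individuals if ind.group in ("brown", "cream")
        )
        whites = len(population) - carriers
        seg = chi_square_ratio([carriers, whites], config.segregation_ratio)
        write_table(pd.DataFrame([seg.to_row()]), outdir / "segregation.tsv")
        summary["segregation"] = {
            "carriers": carriers,
            "white": whites,
            "chi2": round(seg.chi2, 4),
            "p_value": round(seg.p_value, 4),
        }
        summary["causal_genotype_counts"] = {str(k): v for k, v in counts.items()}

    if "scan" in stages or "map" in stages:
        brown_bulk, white_bulk = make_bulks(
            population, "brown", "white", config.bulk_size, rng=streams["bulks"]
        )

    if "scan" in stages:
        bulk_sets = simulate_bulk_variants(
            genome,
            population,
            {"brown": brown_bulk, "white": white_bulk},
            cross,
            rng=streams["variants"],
        )
        bulk_sets["brown"].to_vcf(outdir / "bulk_brown.vcf", sample="brown_bulk")
        bulk_sets["white"].to_vcf(outdir / "bulk_white.vcf", sample="white_bulk")
        residual = subtract_shared_variants(
            bulk_sets["brown"], bulk_sets["white"], labels=("brown", "white")
        )
        residual.to_vcf(outdir / "bulk_differential.vcf", sample="differential")
        bins = bin_counts(residual, config.bin_width, genome)
        write_bed(bins, outdir / "scan_bins.bed")
        peak = detect_peak(bins, config.extend_fraction)
        write_table(
            pd.DataFrame(
                [
                    {
                        "chrom": peak.chrom,
                        "start_1based": None if peak.start is None else peak.start + 1,
                        "end": peak.end,
                        "peak_count": peak.peak_count,
                        "found": peak.found,
                    }
                ]
            ),
            outdir / "scan_peak.tsv",
        )
        summary["scan"] = {
            "n_differential": len(residual),
            "peak_chrom": peak.chrom,
            "peak_count": peak.peak_count,
            "region_start": peak.start,
            "region_end": peak.end,
        }

    if "map" in stages:
        panel = default_marker_panel(genome)
        calls = simulate_marker_calls(population, panel)
        write_table(panel, outdir / "markers.csv", sep=",")
        write_table(calls, outdir / "marker_calls.csv", sep=",")
        groups = {ind.id: ind.group for ind in population.individuals}
        rec = score_recombinants(calls, groups)
        interval = find_interval(panel, rec)
        write_table(pd.DataFrame([interval.to_row()]), outdir / "interval.tsv")
        write_table(
            calls_matrix(calls, panel).reset_index(), outdir / "marker_matrix.tsv"
        )
        summary["interval"] = interval.to_row()

    if "annotate-ltr" in stages:
        seqs = simulate_locus_sequences(streams["sequences"])
        write_fasta(seqs, outdir / "locus_sequences.fasta")
        ann = annotate_ltr(
            seqs["element"], min_ltr=config.min_ltr, min_identity=config.ltr_min_identity
        )
        write_gff3({"element": ann}, outdir / "ltr_annotation.gff3")
        pav_rows = []
        for accession in ("insertion_region", "empty_region", "solo_ltr_region"):
            pav = call_pav(
                seqs[accession],
                seqs["element"],
                min_identity=config.ltr_min_identity,
                min_coverage=config.pav_min_coverage,
            )
            pav_rows.append(
                {
                    "accession": accession,
                    "status": pav.status,
                    "identity": round(pav.identity, 4),
                    "coverage": round(pav.coverage, 4),
                    "remnant": pav.remnant,
                }
            )
        write_table(pd.DataFrame(pav_rows), outdir / "pav_calls.tsv")
        summary["ltr"] = {
            "ltr5": None if ann is None else ann.ltr5_length,
            "ltr3": None if ann is None else ann.ltr3_length,
            "internal": None if ann is None else ann.internal_length,
            "pav": {r["accession"]: r["status"] for r in pav_rows},
        }

    if "deg" in stages:
        groups_map = {
            "mutant_1": "mutant", "mutant_2": "mutant",
            "control_1": "control", "control_2": "control",
        }
        planted = [
            (f"gene_{i + 1:04d}", "mutant", fc)
            for i, fc in enumerate(config.planted_folds)
        ]
        counts, design = simulate_counts(
            config.n_genes,
            groups_map,
            planted=planted,
            dispersion=config.deg_dispersion,
            seed=streams["counts"],
        )
        write_table(counts.reset_index(), outdir / "counts.tsv")
        write_table(design, outdir / "design.csv", sep=",")
        cpm = normalize(counts)
        results = test_deg(
            cpm, design, alpha=config.fdr_alpha, fold_threshold=config.fold_threshold
        )
        fc = fold_change(cpm, design, "mutant", "control")
        results["fold_change"] = fc
        write_table(results.reset_index(), outdir / "deg_results.tsv")
        pathways = {gene: "flavonoid" for gene, _, _ in planted}
        write_table(summarize_pathway(results, pathways), outdir / "pathway_summary.tsv")
        summary["deg"] = {
            "n_significant": int(results["significant"].sum()),
            "planted_fold_recovered": {
                gene: round(float(fc[gene]), 1) for gene, _, _ in planted
            },
        }

    manifest = {
        "package": "fibermap",
        "version": __version__,
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": stages,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    log.info("pipeline finished in %.1f s", time.monotonic() - t0)
    return summary
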