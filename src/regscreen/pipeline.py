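"""End-to-end orchestration: simulate, call consensus, quantify, screen,
validate by motif/ChIP, associate gene sets, and write a manifest + report."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from . import __version__
from .accessibility import normalize, quantify
from .enrichment import GeneSet, associate, read_gmt, score_gene_sets, write_gmt
from .intervals import (
    assign_promoters,
    consensus_regions,
    read_gene_models,
    read_peaks,
    write_peaks,
    write_regions_bed,
)
from .matrices import ExpressionMatrix
from .motif_chip import (
    chip_overlap_test,
    pwm_from_counts,
    read_jaspar_pfm,
    scan,
    write_hits,
    write_jaspar_pfm,
)
from .screen import ScreenConfig, TFPanel, build_inflammatory_panel, screen_tfs
from .synthetic import (
    Cohort,
    CohortConfig,
    SyntheticTruth,
    decoy_names,
    default_motif_counts,
    generate_annotation,
    generate_chip_peaks,
    generate_cohort,
    generate_sequences,
    plant_motif,
    write_cohort,
)

logger = logging.getLogger("regscreen")

__all__ = ["PipelineConfig", "simulate", "run_screen"]


@dataclass
class PipelineConfig:
    """Structured configuration for the full pipeline."""

    outdir: str = "regscreen_out"
    seed: int = 7
    target_gene: str = "CD274"
    promoter_upstream: int = 2000
    promoter_downstream: int = 500
    min_support: float = 0.9
    fixed_width: Optional[int] = 500
    normalization: str = "cpm_log2"
    screen: ScreenConfig = field(default_factory=ScreenConfig)
    motif_threshold_frac: float = 0.8
    n_perm: int = 1000
    # synthetic cohort knobs (used by `simulate` / default `run`)
    truth: SyntheticTruth = field(default_factory=SyntheticTruth)
    cohort: CohortConfig = field(default_factory=CohortConfig)
    n_chip_background: int = 20
    n_null_gene_sets: int = 5

    def __post_init__(self) -> None:
        if not self.target_gene:
            raise ValueError("target_gene is required")
        if self.n_perm < 100:
            raise ValueError("n_perm must be >= 100")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        kwargs = {}
        for f in dataclasses.fields(cls):
            if f.name not in raw:
                continue
            value = raw.pop(f.name)
            if f.name == "screen":
                value = ScreenConfig(**value)
            elif f.name == "truth":
                value = SyntheticTruth(**value)
            elif f.name == "cohort":
                value = CohortConfig(**value)
            kwargs[f.name] = value
        if raw:
            raise ValueError(f"unknown config keys: {sorted(raw)}")
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


class _Manifest:
    def __init__(self, outdir: Path, config: PipelineConfig):
        self.path = outdir / "manifest.json"
        self.data: dict = {
            "tool": "regscreen",
            "version": __version__,
            "config": config.to_dict(),
            "inputs": {},
            "outputs": {},
            "stages": [],
            "complete": False,
        }
        self.flush()

    def add_input(self, name: str, path) -> None:
        self.data["inputs"][name] = {"path": str(path), "sha256": _sha256(path)}

    def add_output(self, name: str, path) -> None:
        self.data["outputs"][name] = str(path)

    def stage_done(self, name: str, seconds: float) -> None:
        self.data["stages"].append({"stage": name, "seconds": round(seconds, 3)})
        self.flush()

    def finish(self) -> None:
        self.data["complete"] = True
        self.flush()

    def flush(self) -> None:
        with open(self.path, "w") as fh:
            json.dump(self.data, fh, indent=2, sort_keys=True)


def simulate(config: PipelineConfig) -> tuple[Cohort, dict]:
    """Generate and write the synthetic cohort plus ChIP peaks, FASTA and GMT."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth = dataclasses.replace(config.truth, seed=config.seed)
    cohort_cfg = config.cohort
    from .synthetic import responsive_names

    named = [
        truth.regulator_gene,
        truth.target_gene,
        *decoy_names(cohort_cfg),
        *responsive_names(cohort_cfg),
    ]
    annotation = generate_annotation(cohort_cfg, seed=config.seed, named_genes=named)
    cohort = generate_cohort(truth, cohort_cfg, annotation)
    paths = write_cohort(cohort, outdir / "cohort")

    # ChIP peaks for the validation stage
    chip = generate_chip_peaks(
        truth, cohort_cfg, annotation, jitter_sd=20.0,
        n_background=config.n_chip_background, seed=config.seed + 1,
    )
    chip_path = outdir / "cohort" / "chip.narrowPeak"
    write_peaks(chip, chip_path, dialect="narrowPeak")
    paths["chip"] = str(chip_path)

    # genome sequence with the regulator motif planted in the target promoter
    seqs = generate_sequences(cohort_cfg, seed=config.seed + 2)
    pwm = pwm_from_counts(default_motif_counts(), name=truth.regulator_gene)
    chrom = cohort.promoter_region.chrom
    plant_at = cohort.promoter_region.midpoint - pwm.length // 2
    seqs[chrom] = plant_motif(seqs[chrom], pwm, plant_at, strand="+")
    fasta_path = outdir / "cohort" / "genome.fa"
    with open(fasta_path, "w") as fh:
        for name, seq in sorted(seqs.items()):
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")
    paths["genome"] = str(fasta_path)
    pfm_path = outdir / "cohort" / "motif.pfm"
    write_jaspar_pfm(default_motif_counts(), truth.regulator_gene, pfm_path)
    paths["motif"] = str(pfm_path)

    # gene sets: one latent-responsive signature plus shuffled null sets
    rng = np.random.default_rng(config.seed + 3)
    gene_pool = [g.gene for g in annotation]
    sets = []
    if cohort.responsive_genes:
        sets.append(GeneSet("latent_responsive", frozenset(cohort.responsive_genes)))
    background_pool = [
        g for g in gene_pool
        if g not in set(cohort.responsive_genes)
        and g not in {truth.regulator_gene, truth.target_gene}
    ]
    set_size = max(5, len(cohort.responsive_genes))
    for i in range(1, config.n_null_gene_sets + 1):
        members = rng.choice(background_pool, size=min(set_size, len(background_pool)),
                             replace=False)
        sets.append(GeneSet(f"null_set_{i}", frozenset(str(m) for m in members)))
    gmt_path = outdir / "cohort" / "gene_sets.gmt"
    write_gmt(sets, gmt_path)
    paths["gene_sets"] = str(gmt_path)
    return cohort, paths


def run_screen(config: PipelineConfig) -> dict:
    """Execute all stages on the (simulated) cohort and write every artifact.

    Returns a result dictionary with the key tables. Reruns with identical
    config produce byte-identical outputs.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(outdir, config)
    results: dict = {}

    def stage(name):
        class _Timer:
            def __enter__(self_inner):
                logger.info("stage %s: start", name)
                self_inner.t0 = time.perf_counter()
                return self_inner

            def __exit__(self_inner, exc_type, exc, tb):
                dt = time.perf_counter() - self_inner.t0
                if exc_type is None:
                    manifest.stage_done(name, dt)
                    logger.info("stage %s: done in %.2fs", name, dt)
                else:
                    logger.error("stage %s: FAILED (%s)", name, exc)
                return False

        return _Timer()

    with stage("simulate"):
        cohort, paths = simulate(config)
        for key in ("expression", "annotation", "chip", "genome", "motif", "gene_sets"):
            manifest.add_input(key, paths[key])

    with stage("consensus"):
        peak_sets_list = [cohort.peak_sets[s] for s in cohort.samples]
        regions_support = consensus_regions(
            peak_sets_list,
            min_support=config.min_support,
            fixed_width=config.fixed_width,
            chrom_sizes=config.cohort.chrom_sizes,
        )
        bed = outdir / "consensus.bed"
        write_regions_bed(regions_support, bed, outdir / "consensus_support.tsv")
        manifest.add_output("consensus_bed", bed)

    with stage("promoters"):
        regions = [iv for iv, _ in regions_support]
        assignment = assign_promoters(
            regions, cohort.annotation,
            upstream=config.promoter_upstream, downstream=config.promoter_downstream,
        )
        target_regions = [
            r for r, hit in assignment.items()
            if hit is not None and hit[0] == config.target_gene
        ]
        target_regions.sort(key=lambda r: (r.chrom, r.start))
        if not target_regions:
            raise RuntimeError(
                f"no consensus region assigned to target gene {config.target_gene!r}"
            )
        results["target_regions"] = target_regions

    with stage("quantify"):
        acc_raw = quantify(regions, cohort.peak_sets)
        acc = normalize(acc_raw, method=config.normalization)
        acc_path = outdir / "accessibility.tsv"
        acc.to_tsv(acc_path)
        manifest.add_output("accessibility", acc_path)
        # restrict to the target's promoter regions for the screen
        rows = [acc.regions.index(r) for r in target_regions]
        target_acc = type(acc)(
            regions=target_regions,
            samples=list(acc.samples),
            values=acc.values[rows, :],
            normalization=acc.normalization,
        )

    with stage("screen"):
        panel_symbols = [config.truth.regulator_gene, *decoy_names(config.cohort)]
        panel = TFPanel.from_symbols(panel_symbols)
        screen_result = screen_tfs(
            cohort.expression, target_acc, panel, config.target_gene, config.screen
        )
        cand_path = outdir / "candidates.tsv"
        screen_result.summary.to_csv(cand_path, sep="\t", index=False, float_format="%.6g")
        screen_result.per_region.to_csv(
            outdir / "candidates_per_region.tsv", sep="\t", index=False, float_format="%.6g"
        )
        manifest.add_output("candidates", cand_path)
        results["screen"] = screen_result

    with stage("motif"):
        pwm = read_jaspar_pfm(paths["motif"])
        from Bio import SeqIO

        seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(paths["genome"], "fasta")}
        all_hits = []
        for region in target_regions:
            seq = seqs[region.chrom][region.start : region.end]
            all_hits.extend(
                scan(
                    seq, pwm,
                    threshold_bits=config.motif_threshold_frac * pwm.max_score(),
                    chrom=region.chrom, offset=region.start,
                )
            )
        hits_path = outdir / "motif_hits.bed"
        write_hits(all_hits, hits_path, outdir / "motif_hits.tsv")
        manifest.add_output("motif_hits", hits_path)
        results["motif_hits"] = all_hits

    with stage("chip"):
        chip_peaks = read_peaks(paths["chip"], dialect="narrowPeak")
        observed, p = chip_overlap_test(
            chip_peaks, target_regions, config.cohort.chrom_sizes,
            n_perm=config.n_perm, seed=config.seed,
        )
        chip_path = outdir / "chip_overlap.json"
        with open(chip_path, "w") as fh:
            json.dump({"observed": observed, "p": p, "n_perm": config.n_perm}, fh, indent=2)
        manifest.add_output("chip_overlap", chip_path)
        results["chip"] = {"observed": observed, "p": p}

    with stage("enrich"):
        gene_sets = read_gmt(paths["gene_sets"])
        scores = score_gene_sets(cohort.expression, gene_sets)
        scores.to_tsv(outdir / "enrichment_scores.tsv")
        assoc = associate(
            scores,
            cohort.expression.row(config.truth.regulator_gene),
            cohort.expression.row(config.target_gene),
            config.screen,
        )
        assoc_path = outdir / "enrichment_associations.tsv"
        assoc.to_csv(assoc_path, sep="\t", index=False, float_format="%.6g")
        manifest.add_output("enrichment", assoc_path)
        results["associations"] = assoc

    with stage("report"):
        report_path = outdir / "report.txt"
        top = screen_result.summary.iloc[0]
        lines = [
            f"Top candidate: {top['tf']} "
            f"(mean region r={top['r_region']:.3f}, r vs target={top['r_target']:.3f}, "
            f"min p={top['p_min']:.3g})",
            "",
            f"Target gene: {config.target_gene}",
            f"Consensus regions assigned to target promoter: "
            + ", ".join(r.display() for r in target_regions),
            f"Motif hits in target regions: {len(all_hits)}",
            f"ChIP overlap: observed={observed} regions, permutation p={p:.4g}",
            f"Gene sets passing dual filter: "
            + (", ".join(assoc[assoc["passes"]]["gene_set"]) if len(assoc) else "none"),
        ]
        report_path.write_text("\n".join(lines) + "\n")
        manifest.add_output("report", report_path)
        results["report"] = str(report_path)

    manifest.finish()
    results["manifest"] = str(manifest.path)
    results["outdir"] = str(outdir)
    return results
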