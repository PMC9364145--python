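"""Synthetic paired ATAC/RNA cohorts with a planted regulator.

A latent per-sample activity drives (i) the regulator's expression, (ii) the
target-promoter accessibility, and (iii) target expression through that
accessibility, alongside decoy TFs, background genes, shared background open
regions, sample depth factors, peak-boundary jitter, and peak dropout. This
gives every downstream stage a cohort with known ground truth.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np

from .intervals import (
    GeneModel,
    GenomicInterval,
    Peak,
    write_gene_models,
    write_peaks,
)
from .matrices import AccessibilityMatrix, ExpressionMatrix
from .motif_chip import PWM

__all__ = [
    "SyntheticTruth",
    "CohortConfig",
    "Cohort",
    "generate_annotation",
    "generate_cohort",
    "generate_sequences",
    "plant_motif",
    "generate_chip_peaks",
    "default_motif_counts",
    "write_cohort",
]


@dataclass
class SyntheticTruth:
    """Planted causal chain: latent activity -> regulator, accessibility, target."""

    regulator_gene: str = "STAT2"
    target_gene: str = "CD274"
    alpha: float = 1.5  # latent activity -> regulator expression
    beta: float = 1.5  # latent activity -> target-promoter accessibility
    gamma: float = 1.5  # accessibility deviation -> target expression
    noise_sd_expr: float = 0.5
    noise_sd_acc: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("alpha", "beta", "gamma"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if self.noise_sd_expr <= 0 or self.noise_sd_acc <= 0:
            raise ValueError("noise SDs must be > 0")
        if self.regulator_gene == self.target_gene:
            raise ValueError("regulator and target must be distinct genes")


@dataclass
class CohortConfig:
    n_samples: int = 41
    n_genes: int = 200
    n_decoy_tfs: int = 20
    chrom_sizes: dict[str, int] = field(default_factory=lambda: {"chr9": 1_000_000})
    promoter_peak_width: int = 500
    peak_jitter_sd: float = 10.0
    peak_dropout_rate: float = 0.0
    # extras beyond the minimal contract, with safe defaults
    min_tss_spacing: int = 2000
    n_background_regions: int = 50
    background_peak_width: int = 400
    depth_log2_sd: float = 0.25
    n_responsive_genes: int = 10

    def __post_init__(self) -> None:
        if self.n_samples < 3:
            raise ValueError("n_samples must be >= 3")
        if any(size <= 0 for size in self.chrom_sizes.values()):
            raise ValueError("chromosome sizes must be > 0")
        if self.promoter_peak_width <= 0 or self.background_peak_width <= 0:
            raise ValueError("peak widths must be > 0")
        if not 0 <= self.peak_dropout_rate < 1:
            raise ValueError("peak_dropout_rate must be in [0, 1)")
        if self.n_genes < 2:
            raise ValueError("n_genes must be >= 2")


def decoy_names(config: CohortConfig) -> list[str]:
    return [f"TF{i:03d}" for i in range(1, config.n_decoy_tfs + 1)]


def responsive_names(config: CohortConfig) -> list[str]:
    return [f"RESP{i:03d}" for i in range(1, config.n_responsive_genes + 1)]


def generate_annotation(
    config: CohortConfig,
    seed: int,
    named_genes: Sequence[str] = (),
) -> list[GeneModel]:
    """Place ``config.n_genes`` TSSs with minimum spacing, both strands present.

    ``named_genes`` (regulator, target, decoys, ...) take the first placed
    slots; remaining genes get generic symbols. Raises when the chromosomes
    cannot hold that many TSSs at ``min_tss_spacing``.
    """
    rng = np.random.default_rng(seed)
    n = config.n_genes
    if len(set(named_genes)) != len(named_genes):
        raise ValueError("named_genes contains duplicates")
    if len(named_genes) > n:
        raise ValueError("more named genes than n_genes")
    spacing = max(1, config.min_tss_spacing)
    capacity = {c: max(0, size // spacing) for c, size in config.chrom_sizes.items()}
    if sum(capacity.values()) < n:
        raise ValueError(
            f"cannot place {n} genes at {spacing} bp spacing on "
            f"{sum(config.chrom_sizes.values())} bp of sequence"
        )
    # apportion genes across chromosomes proportionally to capacity
    chroms = sorted(config.chrom_sizes)
    counts = {c: 0 for c in chroms}
    weights = np.array([capacity[c] for c in chroms], dtype=float)
    for c in rng.choice(chroms, size=n, p=weights / weights.sum()):
        counts[c] += 1
    # rebalance any chromosome over capacity
    for c in chroms:
        while counts[c] > capacity[c]:
            spare = [d for d in chroms if counts[d] < capacity[d]]
            counts[c] -= 1
            counts[rng.choice(spare)] += 1

    positions: list[tuple[str, int]] = []
    for c in chroms:
        k = counts[c]
        if k == 0:
            continue
        # sorted uniform draws stretched to enforce the spacing
        size = config.chrom_sizes[c]
        slack = size - k * spacing
        u = np.sort(rng.integers(0, slack + 1, size=k))
        tss = u + np.arange(k) * spacing
        positions.extend((c, int(t)) for t in tss)

    names = list(named_genes) + [
        f"G{i:04d}" for i in range(1, n - len(named_genes) + 1)
    ]
    strands = rng.choice(["+", "-"], size=n)
    if n >= 2 and len(set(strands)) == 1:  # guarantee both strands
        strands[0] = "+" if strands[0] == "-" else "-"
    order = rng.permutation(n)  # shuffle which gene gets which slot
    return [
        GeneModel(gene=names[i], chrom=positions[order[i]][0],
                  tss=positions[order[i]][1], strand=str(strands[i]))
        for i in range(n)
    ]


def _target_promoter_region(
    target: GeneModel, config: CohortConfig
) -> GenomicInterval:
    """Fixed-width open region centered on the target TSS."""
    w = config.promoter_peak_width
    size = config.chrom_sizes[target.chrom]
    start = max(0, min(target.tss - w // 2, size - w))
    return GenomicInterval(target.chrom, start, start + w)


@dataclass
class Cohort:
    """A generated cohort plus its ground truth."""

    truth: SyntheticTruth
    config: CohortConfig
    annotation: list[GeneModel]
    samples: list[str]
    peak_sets: dict[str, list[Peak]]
    expression: ExpressionMatrix
    promoter_region: GenomicInterval
    accessibility_log2: np.ndarray  # per-sample target-promoter log2 accessibility
    latent: np.ndarray
    background_regions: list[GenomicInterval]
    responsive_genes: list[str]

    def accessibility_matrix(self) -> AccessibilityMatrix:
        """Target-promoter accessibility as a 1 x n_samples matrix (log2 scale)."""
        return AccessibilityMatrix(
            regions=[self.promoter_region],
            samples=list(self.samples),
            values=self.accessibility_log2[None, :],
            normalization="log2",
        )


def _jittered(
    iv: GenomicInterval, rng: np.random.Generator, sd: float, size: int
) -> GenomicInterval:
    start = int(round(iv.start + rng.normal(0, sd)))
    end = int(round(iv.end + rng.normal(0, sd)))
    start = max(0, min(start, size - 1))
    end = max(start + 1, min(end, size))
    return GenomicInterval(iv.chrom, start, end)


def generate_cohort(
    truth: SyntheticTruth,
    config: CohortConfig,
    annotation: Sequence[GeneModel],
) -> Cohort:
    """Simulate the cohort; seeded by ``truth.seed`` (single RNG stream)."""
    genes = {g.gene: g for g in annotation}
    for required in (truth.regulator_gene, truth.target_gene):
        if required not in genes:
            raise ValueError(f"annotation lacks required gene {required!r}")
    rng = np.random.default_rng(truth.seed)
    n = config.n_samples
    samples = [f"S{i:03d}" for i in range(1, n + 1)]
    gene_names = [g.gene for g in annotation]

    latent = rng.standard_normal(n)
    base_expr = rng.uniform(3.0, 9.0, size=len(gene_names))
    expr = base_expr[:, None] + rng.normal(0, truth.noise_sd_expr, size=(len(gene_names), n))

    base_acc = 6.0
    acc_noise = rng.normal(0, truth.noise_sd_acc, size=n)
    acc = base_acc + truth.beta * latent + acc_noise
    acc_dev = acc - base_acc

    idx = {g: i for i, g in enumerate(gene_names)}
    expr[idx[truth.regulator_gene]] += truth.alpha * latent
    expr[idx[truth.target_gene]] += truth.gamma * acc_dev
    responsive = [g for g in responsive_names(config) if g in idx]
    for g in responsive:
        expr[idx[g]] += truth.gamma * latent

    target = genes[truth.target_gene]
    promoter_region = _target_promoter_region(target, config)
    size_of = config.chrom_sizes

    # shared background open regions, kept clear of the target promoter window
    # (guard covers a -2000/+500 promoter assignment window) and mutually
    # separated enough to survive fixed-width standardization without overlap
    background_regions: list[GenomicInterval] = []
    chroms = sorted(size_of)
    weights = np.array([size_of[c] for c in chroms], dtype=float)
    guard = 3000
    pad = 400
    attempts = 0
    while len(background_regions) < config.n_background_regions and attempts < 100_000:
        attempts += 1
        c = str(rng.choice(chroms, p=weights / weights.sum()))
        w = config.background_peak_width
        if size_of[c] <= w:
            continue
        start = int(rng.integers(0, size_of[c] - w + 1))
        cand = GenomicInterval(c, start, start + w)
        if cand.chrom == promoter_region.chrom and (
            cand.start < promoter_region.end + guard
            and promoter_region.start - guard < cand.end
        ):
            continue
        if any(
            cand.chrom == b.chrom and cand.start < b.end + pad and b.start - pad < cand.end
            for b in background_regions
        ):
            continue
        background_regions.append(cand)
    background_regions.sort(key=lambda r: (r.chrom, r.start))
    bg_base = rng.uniform(4.0, 8.0, size=len(background_regions))

    peak_sets: dict[str, list[Peak]] = {}
    for s_idx, sample in enumerate(samples):
        depth = 2.0 ** rng.normal(0, config.depth_log2_sd)
        peaks: list[Peak] = []
        if rng.random() >= config.peak_dropout_rate:
            iv = _jittered(
                promoter_region, rng, config.peak_jitter_sd, size_of[promoter_region.chrom]
            )
            peaks.append(
                Peak(
                    interval=iv,
                    signal=depth * 2.0 ** acc[s_idx],
                    summit_offset=iv.width // 2,
                    name=f"{sample}_promoter",
                )
            )
        for b_idx, region in enumerate(background_regions):
            if rng.random() < config.peak_dropout_rate:
                continue
            iv = _jittered(region, rng, config.peak_jitter_sd, size_of[region.chrom])
            signal = depth * 2.0 ** (bg_base[b_idx] + rng.normal(0, 1.0))
            peaks.append(
                Peak(
                    interval=iv,
                    signal=signal,
                    summit_offset=iv.width // 2,
                    name=f"{sample}_bg{b_idx + 1}",
                )
            )
        peaks.sort(key=lambda p: (p.interval.chrom, p.interval.start))
        peak_sets[sample] = peaks

    expression = ExpressionMatrix(genes=gene_names, samples=samples, values=expr)
    return Cohort(
        truth=truth,
        config=config,
        annotation=list(annotation),
        samples=samples,
        peak_sets=peak_sets,
        expression=expression,
        promoter_region=promoter_region,
        accessibility_log2=acc,
        latent=latent,
        background_regions=background_regions,
        responsive_genes=responsive,
    )


def generate_sequences(
    config: CohortConfig, seed: int
) -> dict[str, str]:
    """Uniform random DNA for every synthetic chromosome."""
    rng = np.random.default_rng(seed)
    return {
        chrom: "".join(rng.choice(list("ACGT"), size=size))
        for chrom, size in sorted(config.chrom_sizes.items())
    }


def plant_motif(sequence: str, pwm: PWM, position: int, strand: str = "+") -> str:
    """Overwrite a window with the PWM consensus (reverse-complemented on -)."""
    from .motif_chip import reverse_complement

    L = pwm.length
    if position < 0 or position + L > len(sequence):
        raise ValueError(
            f"motif of length {L} at position {position} exceeds sequence bounds"
        )
    word = pwm.consensus()
    if strand == "-":
        word = reverse_complement(word)
    elif strand != "+":
        raise ValueError(f"strand must be + or -, got {strand!r}")
    return sequence[:position] + word + sequence[position + L :]


def generate_chip_peaks(
    truth: SyntheticTruth,
    config: CohortConfig,
    annotation: Sequence[GeneModel],
    jitter_sd: float = 0.0,
    n_background: int = 0,
    seed: int = 0,
    peak_width: int = 200,
) -> list[Peak]:
    """ChIP peak set: one peak on the target promoter plus uniform background."""
    genes = {g.gene: g for g in annotation}
    if truth.target_gene not in genes:
        raise ValueError(f"annotation lacks target gene {truth.target_gene!r}")
    rng = np.random.default_rng(seed)
    promoter = _target_promoter_region(genes[truth.target_gene], config)
    size_of = config.chrom_sizes

    center = promoter.midpoint + int(round(rng.normal(0, jitter_sd))) if jitter_sd else promoter.midpoint
    size = size_of[promoter.chrom]
    start = max(0, min(center - peak_width // 2, size - peak_width))
    peaks = [
        Peak(
            interval=GenomicInterval(promoter.chrom, start, start + peak_width),
            signal=100.0,
            name="chip_promoter",
        )
    ]
    chroms = sorted(size_of)
    weights = np.array([size_of[c] for c in chroms], dtype=float)
    placed = 0
    attempts = 0
    while placed < n_background and attempts < 100_000:
        attempts += 1
        c = str(rng.choice(chroms, p=weights / weights.sum()))
        if size_of[c] <= peak_width:
            continue
        s = int(rng.integers(0, size_of[c] - peak_width + 1))
        cand = GenomicInterval(c, s, s + peak_width)
        if cand.overlaps(promoter):
            continue
        placed += 1
        peaks.append(Peak(interval=cand, signal=float(rng.uniform(10, 100)),
                          name=f"chip_bg{placed}"))
    peaks.sort(key=lambda p: (p.interval.chrom, p.interval.start))
    return peaks


# STAT-like palindromic GAS/ISRE-flavoured default motif (9 columns).
def default_motif_counts() -> np.ndarray:
    consensus = "TTCCGGGAA"
    counts = np.full((4, len(consensus)), 2, dtype=int)
    for j, b in enumerate(consensus):
        counts["ACGT".index(b), j] = 94
    return counts


def write_cohort(cohort: Cohort, outdir) -> dict[str, object]:
    """Write the cohort to disk; returns a path manifest.

    Emits per-sample narrowPeak files, the expression TSV, the annotation
    BED6 TSS table, chromosome sizes and the truth JSON.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    peak_dir = outdir / "peaks"
    peak_dir.mkdir(exist_ok=True)
    peak_files = {}
    for sample in cohort.samples:
        path = peak_dir / f"{sample}.narrowPeak"
        write_peaks(cohort.peak_sets[sample], path, dialect="narrowPeak")
        peak_files[sample] = str(path)
    expr_path = outdir / "expression.tsv"
    cohort.expression.to_tsv(expr_path)
    ann_path = outdir / "annotation.bed"
    write_gene_models(cohort.annotation, ann_path)
    sizes_path = outdir / "chrom.sizes"
    with open(sizes_path, "w") as fh:
        for chrom, size in sorted(cohort.config.chrom_sizes.items()):
            fh.write(f"{chrom}\t{size}\n")
    truth_path = outdir / "truth.json"
    with open(truth_path, "w") as fh:
        json.dump(asdict(cohort.truth), fh, indent=2, sort_keys=True)
    acc_path = outdir / "promoter_accessibility.tsv"
    with open(acc_path, "w") as fh:
        fh.write("sample\tlog2_accessibility\n")
        for sample, value in zip(cohort.samples, cohort.accessibility_log2):
            fh.write(f"{sample}\t{value:.6f}\n")
    return {
        "peaks": peak_files,
        "expression": str(expr_path),
        "annotation": str(ann_path),
        "chrom_sizes": str(sizes_path),
        "truth": str(truth_path),
        "promoter_accessibility": str(acc_path),
    }
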