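"""PWM motif scanning and permutation-based ChIP-peak overlap testing."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .intervals import GenomicInterval, Peak, merge_intervals

__all__ = [
    "PWM",
    "MotifHit",
    "pwm_from_counts",
    "read_jaspar_pfm",
    "write_jaspar_pfm",
    "scan",
    "reverse_complement",
    "chip_overlap_test",
    "write_hits",
]

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


@dataclass
class PWM:
    """Position weight matrix: 4 x L base probabilities (rows A, C, G, T)."""

    name: str
    matrix: np.ndarray
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    pseudocount: float = 0.0

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != 4 or self.matrix.shape[1] < 1:
            raise ValueError(f"matrix must be 4 x L, got {self.matrix.shape}")
        if np.any(np.abs(self.matrix.sum(axis=0) - 1.0) > 1e-9):
            raise ValueError("every PWM column must sum to 1")
        if abs(self.background.sum() - 1.0) > 1e-9 or np.any(self.background <= 0):
            raise ValueError("background must be positive and sum to 1")

    @property
    def length(self) -> int:
        return self.matrix.shape[1]

    def log_odds(self) -> np.ndarray:
        """4 x L log2-odds against the background; zero probabilities map to -inf."""
        with np.errstate(divide="ignore"):
            return np.log2(self.matrix / self.background[:, None])

    def max_score(self) -> float:
        return float(self.log_odds().max(axis=0).sum())

    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.matrix.argmax(axis=0))


@dataclass
class MotifHit:
    interval: GenomicInterval
    strand: str
    score: float
    matched: str

    def __post_init__(self) -> None:
        if not np.isfinite(self.score):
            raise ValueError("hit score must be finite")


def pwm_from_counts(
    counts: np.ndarray,
    pseudocount: float = 1.0,
    background: Optional[Sequence[float]] = None,
    name: str = "pwm",
) -> PWM:
    """Counts -> probabilities: ``(c + pc) / (column_total + 4 pc)``."""
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2 or counts.shape[0] != 4 or counts.shape[1] < 1:
        raise ValueError(f"counts must be 4 x L, got {counts.shape}")
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    totals = counts.sum(axis=0)
    if pseudocount == 0 and np.any(totals == 0):
        raise ValueError("all-zero column with pseudocount 0")
    matrix = (counts + pseudocount) / (totals + 4 * pseudocount)
    bg = np.full(4, 0.25) if background is None else np.asarray(background, dtype=float)
    return PWM(name=name, matrix=matrix, background=bg, pseudocount=pseudocount)


def read_jaspar_pfm(path, pseudocount: float = 1.0) -> PWM:
    """Read the first motif from a JASPAR-format PFM text file."""
    from Bio import motifs

    with open(path) as fh:
        motif = motifs.read(fh, "jaspar")
    counts = np.array([motif.counts[b] for b in BASES], dtype=float)
    return pwm_from_counts(counts, pseudocount=pseudocount, name=motif.name or motif.matrix_id)


def write_jaspar_pfm(counts: np.ndarray, name: str, path) -> None:
    counts = np.asarray(counts)
    with open(path, "w") as fh:
        fh.write(f">{name} {name}\n")
        for i, base in enumerate(BASES):
            row = " ".join(f"{int(c):6d}" for c in counts[i])
            fh.write(f"{base} [{row} ]\n")


def _score_forward(window: str, lo: np.ndarray) -> float:
    return float(sum(lo[_BASE_INDEX[b], j] for j, b in enumerate(window)))


def scan(
    sequence: str,
    pwm: PWM,
    threshold_bits: Optional[float] = None,
    strands: str = "both",
    chrom: str = "seq",
    offset: int = 0,
) -> list[MotifHit]:
    """Scan a sequence for PWM hits scoring >= ``threshold_bits`` (log2 odds).

    Default threshold is 80% of the PWM's maximal achievable score. Windows
    containing N are skipped. Minus-strand hits score the reverse complement
    with coordinates reported on the forward strand; results are sorted by
    position then strand (+ before -).
    """
    seq = sequence.upper()
    if any(c not in "ACGTN" for c in seq):
        raise ValueError("sequence must be over the alphabet {A, C, G, T, N}")
    L = pwm.length
    if threshold_bits is None:
        threshold_bits = 0.8 * pwm.max_score()
    if L > len(seq):
        return []
    lo = pwm.log_odds()
    strand_list = {"both": ("+", "-"), "+": ("+",), "-": ("-",)}[strands]
    hits: list[MotifHit] = []
    for i in range(len(seq) - L + 1):
        window = seq[i : i + L]
        if "N" in window:
            continue
        for strand in strand_list:
            probe = window if strand == "+" else reverse_complement(window)
            score = _score_forward(probe, lo)
            if score >= threshold_bits:
                hits.append(
                    MotifHit(
                        interval=GenomicInterval(chrom, offset + i, offset + i + L),
                        strand=strand,
                        score=score,
                        matched=window,
                    )
                )
    hits.sort(key=lambda h: (h.interval.start, h.strand))
    return hits


def write_hits(hits: Sequence[MotifHit], bed_path, tsv_path=None) -> None:
    """BED6 with bit score x100 in the score column; exact scores in a TSV."""
    with open(bed_path, "w") as fh:
        for i, h in enumerate(hits, start=1):
            iv = h.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\thit_{i}\t{int(round(h.score * 100))}"
                f"\t{h.strand}\n"
            )
    if tsv_path is not None:
        with open(tsv_path, "w") as fh:
            fh.write("hit\tchrom\tstart\tend\tstrand\tscore_bits\tmatched\n")
            for i, h in enumerate(hits, start=1):
                iv = h.interval
                fh.write(
                    f"hit_{i}\t{iv.chrom}\t{iv.start}\t{iv.end}\t{h.strand}"
                    f"\t{h.score:.6g}\t{h.matched}\n"
                )


def _overlaps_any(
    region_start: int, region_end: int, starts: np.ndarray, ends: np.ndarray
) -> bool:
    # merged, sorted chip intervals: find first interval ending after region start
    i = int(np.searchsorted(ends, region_start, side="right"))
    return i < len(starts) and starts[i] < region_end


def chip_overlap_test(
    chip_peaks: Sequence[Peak],
    regions: Sequence[GenomicInterval],
    chrom_sizes: Mapping[str, int],
    n_perm: int = 1000,
    seed: int = 0,
) -> tuple[int, float]:
    """Permutation test of region / ChIP-peak overlap.

    Observed statistic: number of regions overlapping >= 1 ChIP peak. Null:
    each region is independently re-placed uniformly (width-preserving) on its
    own chromosome, per permutation. Returns ``(observed, p)`` with
    ``p = (1 + #{null >= observed}) / (n_perm + 1)``.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    for r in regions:
        if r.chrom not in chrom_sizes:
            raise ValueError(f"no chromosome size for {r.chrom}")
        if r.width > chrom_sizes[r.chrom]:
            raise ValueError(f"region {r.display()} wider than its chromosome")

    merged = merge_intervals(p.interval for p in chip_peaks) if chip_peaks else []
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom in {iv.chrom for iv in merged}:
        ivs = [iv for iv in merged if iv.chrom == chrom]
        by_chrom[chrom] = (
            np.array([iv.start for iv in ivs]),
            np.array([iv.end for iv in ivs]),
        )

    def count(starts_by_region: Sequence[int]) -> int:
        c = 0
        for r, s in zip(regions, starts_by_region):
            if r.chrom in by_chrom and _overlaps_any(
                s, s + r.width, by_chrom[r.chrom][0], by_chrom[r.chrom][1]
            ):
                c += 1
        return c

    observed = count([r.start for r in regions])
    rng = np.random.default_rng(seed)
    exceed = 0
    widths = [r.width for r in regions]
    limits = [chrom_sizes[r.chrom] for r in regions]
    for _ in range(n_perm):
        starts = [
            int(rng.integers(0, limit - w + 1)) for w, limit in zip(widths, limits)
        ]
        if count(starts) >= observed:
            exceed += 1
    p = (1 + exceed) / (n_perm + 1)
    return observed, p
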