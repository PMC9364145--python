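"""Genomic interval data model, BED/narrowPeak I/O, consensus calling and annotation.

Coordinates are 0-based half-open internally (BED convention); user-facing
display strings are 1-based inclusive (``chrom:start+1-end``).
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

__all__ = [
    "GenomicInterval",
    "Peak",
    "GeneModel",
    "ParseError",
    "read_peaks",
    "write_peaks",
    "read_gene_models",
    "write_gene_models",
    "merge_intervals",
    "consensus_regions",
    "promoter_window",
    "assign_promoters",
    "annotate_features",
    "write_regions_bed",
]

_STRANDS = {"+", "-", "."}


class ParseError(ValueError):
    """Raised for malformed interval files; carries the 1-based line number."""

    def __init__(self, message: str, path: object = None, line: Optional[int] = None):
        loc = f"{path}:{line}: " if line is not None else ""
        super().__init__(f"{loc}{message}")
        self.path = path
        self.line = line


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open interval ``[start, end)`` on a chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(f"end ({self.end}) must be > start ({self.start})")
        if self.strand not in _STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def display(self) -> str:
        """1-based inclusive display string, e.g. ``chr9:5449463-5449962``."""
        return f"{self.chrom}:{self.start + 1}-{self.end}"

    def overlaps(self, other: "GenomicInterval") -> bool:
        return self.chrom == other.chrom and self.start < other.end and other.start < self.end

    def overlap_len(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass
class Peak:
    """A called peak: interval plus signal and optional summit."""

    interval: GenomicInterval
    signal: float = 0.0
    summit_offset: Optional[int] = None
    name: str = "."

    def __post_init__(self) -> None:
        if self.signal < 0:
            raise ValueError(f"signal must be non-negative, got {self.signal}")
        if self.summit_offset is not None and not (
            0 <= self.summit_offset < self.interval.width
        ):
            raise ValueError(
                f"summit_offset {self.summit_offset} outside [0, {self.interval.width})"
            )


@dataclass(frozen=True)
class GeneModel:
    """Minimal gene model: symbol, chromosome, TSS and strand."""

    gene: str
    chrom: str
    tss: int
    strand: str

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"gene strand must be + or -, got {self.strand!r}")
        if self.tss < 0:
            raise ValueError("tss must be >= 0")


# ---------------------------------------------------------------------------
# I/O

_DIALECT_MIN_COLS = {"bed3": 3, "bed6": 6, "narrowPeak": 10}


def _is_skippable(line: str) -> bool:
    s = line.strip()
    return not s or s.startswith(("#", "track", "browser"))


def read_peaks(path, dialect: str = "narrowPeak") -> list[Peak]:
    """Read peaks from a BED3/BED6/narrowPeak file.

    narrowPeak column 10 (0-based offset of the summit from start) of -1 maps
    to an absent summit. Track and comment lines are skipped.
    """
    if dialect not in _DIALECT_MIN_COLS:
        raise ValueError(f"unknown dialect {dialect!r}")
    ncols = _DIALECT_MIN_COLS[dialect]
    peaks: list[Peak] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if _is_skippable(line):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < ncols:
                raise ParseError(
                    f"expected >= {ncols} columns for {dialect}, got {len(fields)}",
                    path,
                    lineno,
                )
            try:
                chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"non-integer coordinate: {exc}", path, lineno) from exc
            if end <= start:
                raise ParseError(f"end ({end}) <= start ({start})", path, lineno)
            name = "."
            signal = 0.0
            strand = "."
            summit: Optional[int] = None
            if dialect in ("bed6", "narrowPeak"):
                name = fields[3]
                strand = fields[5] if fields[5] in _STRANDS else "."
            if dialect == "bed6":
                signal = float(fields[4])
            elif dialect == "narrowPeak":
                signal = float(fields[6])
                summit_raw = int(fields[9])
                summit = None if summit_raw == -1 else summit_raw
            try:
                peaks.append(
                    Peak(
                        interval=GenomicInterval(chrom, start, end, strand),
                        signal=signal,
                        summit_offset=summit,
                        name=name,
                    )
                )
            except ValueError as exc:
                raise ParseError(str(exc), path, lineno) from exc
    return peaks


def write_peaks(peaks: Iterable[Peak], path, dialect: str = "narrowPeak") -> None:
    """Write peaks in the given dialect (inverse of :func:`read_peaks`)."""
    if dialect not in _DIALECT_MIN_COLS:
        raise ValueError(f"unknown dialect {dialect!r}")
    with open(path, "w") as fh:
        for p in peaks:
            iv = p.interval
            if dialect == "bed3":
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
            elif dialect == "bed6":
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{p.name}\t{p.signal:g}\t{iv.strand}\n"
                )
            else:
                summit = -1 if p.summit_offset is None else p.summit_offset
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{p.name}\t0\t{iv.strand}"
                    f"\t{p.signal:g}\t-1\t-1\t{summit}\n"
                )


def read_gene_models(path) -> list[GeneModel]:
    """Read a gene TSS table stored as BED6 with 1 bp intervals (start == TSS)."""
    genes: list[GeneModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if _is_skippable(line):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 6:
                raise ParseError("expected 6 columns (BED6 TSS table)", path, lineno)
            try:
                genes.append(
                    GeneModel(
                        gene=fields[3],
                        chrom=fields[0],
                        tss=int(fields[1]),
                        strand=fields[5],
                    )
                )
            except ValueError as exc:
                raise ParseError(str(exc), path, lineno) from exc
    return genes


def write_gene_models(genes: Iterable[GeneModel], path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g.chrom}\t{g.tss}\t{g.tss + 1}\t{g.gene}\t0\t{g.strand}\n")


def write_regions_bed(
    regions_with_support: Sequence[tuple[GenomicInterval, int]], path, tsv_path=None
) -> None:
    """Write consensus regions as BED6; score = support capped at 1000.

    Exact support counts go to ``tsv_path`` when given.
    """
    with open(path, "w") as fh:
        for i, (iv, support) in enumerate(regions_with_support, start=1):
            score = min(int(support), 1000)
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\tregion_{i}\t{score}\t.\n")
    if tsv_path is not None:
        with open(tsv_path, "w") as fh:
            fh.write("region\tchrom\tstart\tend\tsupport\n")
            for i, (iv, support) in enumerate(regions_with_support, start=1):
                fh.write(f"region_{i}\t{iv.chrom}\t{iv.start}\t{iv.end}\t{support}\n")


# ---------------------------------------------------------------------------
# Interval algebra


def merge_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Union of intervals per chromosome, returned sorted and non-overlapping."""
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    merged: list[GenomicInterval] = []
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom], key=lambda x: (x.start, x.end))
        cur_s, cur_e = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start <= cur_e:
                cur_e = max(cur_e, iv.end)
            else:
                merged.append(GenomicInterval(chrom, cur_s, cur_e))
                cur_s, cur_e = iv.start, iv.end
        merged.append(GenomicInterval(chrom, cur_s, cur_e))
    return merged


def consensus_regions(
    peak_sets: Sequence[Sequence[Peak]],
    min_support: float,
    fixed_width: Optional[int] = None,
    chrom_sizes: Optional[Mapping[str, int]] = None,
) -> list[tuple[GenomicInterval, int]]:
    """Call cohort-consensus regions by per-base distinct-sample support.

    A base is supported when covered by peaks from at least
    ``ceil(min_support * n_samples)`` distinct samples (duplicate peaks within
    one sample cannot inflate support). Maximal supported runs are reported;
    with ``fixed_width``, each run becomes a window of that width centered on
    the run midpoint (floor), trimmed at chromosome edges. The reported
    support is the number of samples with >= 1 bp overlap of the final region.
    """
    if not (0 < min_support <= 1):
        raise ValueError(f"min_support must be in (0, 1], got {min_support}")
    if not peak_sets:
        raise ValueError("need at least one sample")
    n = len(peak_sets)
    k = math.ceil(min_support * n)

    # per-sample union so a sample contributes at most 1 to per-base support
    sample_merged: list[list[GenomicInterval]] = [
        merge_intervals(ps) if ps else [] for ps in ({p.interval for p in ps} for ps in peak_sets)
    ]

    events: dict[str, list[tuple[int, int]]] = {}
    for ivs in sample_merged:
        for iv in ivs:
            events.setdefault(iv.chrom, []).append((iv.start, 1))
            events[iv.chrom].append((iv.end, -1))

    runs: list[GenomicInterval] = []
    for chrom in sorted(events):
        evs = sorted(events[chrom])
        cov = 0
        run_start: Optional[int] = None
        i = 0
        while i < len(evs):
            pos = evs[i][0]
            while i < len(evs) and evs[i][0] == pos:
                cov += evs[i][1]
                i += 1
            if cov >= k and run_start is None:
                run_start = pos
            elif cov < k and run_start is not None:
                runs.append(GenomicInterval(chrom, run_start, pos))
                run_start = None

    out: list[tuple[GenomicInterval, int]] = []
    for run in runs:
        region = run
        if fixed_width is not None:
            mid = run.midpoint
            start = mid - fixed_width // 2
            end = start + fixed_width
            if start < 0:
                start, end = 0, min(end - start, fixed_width)
            if chrom_sizes is not None and run.chrom in chrom_sizes:
                size = chrom_sizes[run.chrom]
                if end > size:
                    end = size
                    start = max(0, end - fixed_width)
            region = GenomicInterval(run.chrom, start, end)
        support = sum(
            1
            for ivs in sample_merged
            if any(region.overlaps(iv) for iv in ivs)
        )
        out.append((region, support))
    out.sort(key=lambda t: (t[0].chrom, t[0].start, t[0].end))
    return out


# ---------------------------------------------------------------------------
# Promoter assignment & feature annotation


def promoter_window(gene: GeneModel, upstream: int, downstream: int) -> GenomicInterval:
    """Strand-aware promoter window around the TSS.

    Plus strand: ``[tss - upstream, tss + downstream)``. Minus strand is the
    mirror image around the TSS base: ``[tss - downstream + 1, tss + upstream + 1)``.
    """
    if upstream < 0 or downstream < 0:
        raise ValueError("upstream and downstream must be >= 0")
    if gene.strand == "+":
        start, end = gene.tss - upstream, gene.tss + downstream
    else:
        start, end = gene.tss - downstream + 1, gene.tss + upstream + 1
    return GenomicInterval(gene.chrom, max(0, start), max(1, end), gene.strand)


def assign_promoters(
    regions: Sequence[GenomicInterval],
    gene_models: Sequence[GeneModel],
    upstream: int = 2000,
    downstream: int = 500,
) -> dict[GenomicInterval, Optional[tuple[str, int]]]:
    """Map each region to the gene whose promoter window it overlaps.

    Ties between multiple overlapping promoters are resolved by the smaller
    ``|region midpoint - TSS|``, then the lexicographically smallest symbol.
    Unmapped regions map to ``None`` (flagged, not dropped).
    """
    windows = [(g, promoter_window(g, upstream, downstream)) for g in gene_models]
    result: dict[GenomicInterval, Optional[tuple[str, int]]] = {}
    for region in regions:
        hits = [
            (abs(region.midpoint - g.tss), g.gene)
            for g, win in windows
            if region.overlaps(win)
        ]
        result[region] = min(hits)[::-1] if hits else None
    return result


def annotate_features(
    regions: Sequence[GenomicInterval],
    gene_models: Sequence[GeneModel],
    exons: Sequence[GenomicInterval] = (),
    introns: Sequence[GenomicInterval] = (),
    upstream: int = 2000,
    downstream: int = 500,
) -> tuple[dict[GenomicInterval, str], Counter]:
    """Classify each region as promoter > exon > intron > intergenic."""
    windows = [promoter_window(g, upstream, downstream) for g in gene_models]
    classes: dict[GenomicInterval, str] = {}
    for region in regions:
        if any(region.overlaps(w) for w in windows):
            cls = "promoter"
        elif any(region.overlaps(e) for e in exons):
            cls = "exon"
        elif any(region.overlaps(i) for i in introns):
            cls = "intron"
        else:
            cls = "intergenic"
        classes[region] = cls
    return classes, Counter(classes.values())
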