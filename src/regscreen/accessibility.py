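"""Per-sample accessibility quantification over consensus regions."""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np

from .intervals import GenomicInterval, Peak
from .matrices import AccessibilityMatrix

__all__ = ["quantify", "normalize"]


def _check_non_overlapping(regions: Sequence[GenomicInterval]) -> None:
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for r in regions:
        by_chrom.setdefault(r.chrom, []).append(r)
    for chrom, ivs in by_chrom.items():
        ivs = sorted(ivs, key=lambda x: x.start)
        for a, b in zip(ivs, ivs[1:]):
            if b.start < a.end:
                raise ValueError(
                    f"regions overlap on {chrom}: {a.display()} and {b.display()}"
                )


def quantify(
    regions: Sequence[GenomicInterval],
    peak_sets: Mapping[str, Sequence[Peak]],
) -> AccessibilityMatrix:
    """Overlap-weighted signal sum per (region, sample).

    ``value(region, sample) = sum_peaks signal * overlap_bp / peak_width``.
    Samples with no overlapping peak get 0. Regions must be non-overlapping.
    """
    _check_non_overlapping(regions)
    samples = list(peak_sets)
    values = np.zeros((len(regions), len(samples)))
    for j, sample in enumerate(samples):
        for peak in peak_sets[sample]:
            iv = peak.interval
            for i, region in enumerate(regions):
                ov = region.overlap_len(iv)
                if ov:
                    values[i, j] += peak.signal * ov / iv.width
    return AccessibilityMatrix(list(regions), samples, values, normalization="raw")


def normalize(
    matrix: AccessibilityMatrix, method: str = "cpm_log2", pseudocount: float = 1.0
) -> AccessibilityMatrix:
    """Normalize a raw accessibility matrix.

    ``cpm_log2`` scales each sample column to a total of 1e6 and applies
    log2(x + pseudocount); all-zero columns are left at 0 with a warning.
    ``none`` is the identity.
    """
    if method == "none":
        return AccessibilityMatrix(
            list(matrix.regions), list(matrix.samples), matrix.values.copy(),
            normalization=matrix.normalization,
        )
    if method != "cpm_log2":
        raise ValueError(f"unknown normalization method {method!r}")
    if np.any(matrix.values < 0):
        raise ValueError("cpm_log2 requires non-negative raw values")
    values = matrix.values.astype(float).copy()
    totals = values.sum(axis=0)
    zero = totals == 0
    if zero.any():
        bad = [s for s, z in zip(matrix.samples, zero) if z]
        warnings.warn(f"all-zero sample columns left at 0: {bad}")
    scale = np.where(zero, 1.0, totals)
    values = values / scale * 1e6
    values[:, zero] = 0.0
    values = np.log2(values + pseudocount)
    values[:, zero] = 0.0
    return AccessibilityMatrix(
        list(matrix.regions), list(matrix.samples), values, normalization="cpm_log2"
    )
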