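"""Single-sample rank-based gene-set scoring and dual-correlation association.

The per-sample score contrasts the cumulative weight of in-set versus
out-of-set genes walking down a sample's expression ranking (an ssGSEA-style
statistic). The association step applies the dual filter: a set passes when
its score correlates with BOTH the candidate TF and the target gene at
r > r_threshold and p < p_threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .matrices import ExpressionMatrix
from .screen import CorrelationRecord, ScreenConfig, correlate

__all__ = [
    "GeneSet",
    "ScoreMatrix",
    "read_gmt",
    "write_gmt",
    "ss_enrichment",
    "score_gene_sets",
    "associate",
]


@dataclass
class GeneSet:
    name: str
    members: frozenset[str]
    category: str = "pathway"

    def __post_init__(self) -> None:
        self.members = frozenset(self.members)
        if not self.members:
            raise ValueError(f"gene set {self.name!r} is empty")
        if self.category not in {"pathway", "immune_signature"}:
            raise ValueError(f"unknown category {self.category!r}")


@dataclass
class ScoreMatrix:
    """Gene sets x samples enrichment scores; NaN rows mark undefined sets."""

    sets: list[str]
    samples: list[str]
    values: np.ndarray
    skipped: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sets, columns=self.samples)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="gene_set")


def read_gmt(path, category: str = "pathway") -> list[GeneSet]:
    """Read gene sets from a GMT file (name, description, members...)."""
    sets: list[GeneSet] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise ValueError(f"malformed GMT line: {line!r}")
            sets.append(GeneSet(fields[0], frozenset(g for g in fields[2:] if g), category))
    return sets


def write_gmt(gene_sets: Sequence[GeneSet], path) -> None:
    with open(path, "w") as fh:
        for gs in gene_sets:
            fh.write("\t".join([gs.name, gs.category, *sorted(gs.members)]) + "\n")


def ss_enrichment(
    expr: ExpressionMatrix, gene_set: GeneSet, weight_exponent: float = 0.25
) -> np.ndarray:
    """Per-sample enrichment score in [-1, 1] for one gene set.

    Within a sample, genes are ranked by expression (average ranks on ties).
    Walking down the descending ranking, in-set genes advance a weighted
    in-set step function P_in (weight = ascending-rank ** tau, normalized by
    the in-set total) while out-of-set genes advance P_out by 1/(n_genes -
    n_set); the score is ``sum_i (P_in_i - P_out_i) / n_genes``. tau = 0 uses
    ranks only, making the score invariant to monotone transformations.
    A set covering every gene scores 0 by convention.
    """
    if weight_exponent < 0:
        raise ValueError("weight_exponent must be >= 0")
    in_set = np.array([g in gene_set.members for g in expr.genes])
    m = int(in_set.sum())
    n_genes = len(expr.genes)
    if m == 0:
        raise ValueError(f"gene set {gene_set.name!r} has no members in the expression matrix")
    scores = np.empty(len(expr.samples))
    if m == n_genes:
        scores.fill(0.0)
        return scores
    for j in range(len(expr.samples)):
        v = expr.values[:, j]
        asc_ranks = stats.rankdata(v)  # 1 = lowest expression, average ties
        # deterministic descending walk: by value desc, then gene symbol
        order = sorted(range(n_genes), key=lambda i: (-v[i], expr.genes[i]))
        weights = np.where(in_set, asc_ranks**weight_exponent, 0.0)
        w_total = weights.sum()
        p_in = np.cumsum(weights[order]) / w_total
        p_out = np.cumsum((~in_set[order]).astype(float)) / (n_genes - m)
        scores[j] = float((p_in - p_out).sum() / n_genes)
    return scores


def score_gene_sets(
    expr: ExpressionMatrix,
    gene_sets: Sequence[GeneSet],
    weight_exponent: float = 0.25,
) -> ScoreMatrix:
    """Score every gene set; sets with no members in ``expr`` get NaN rows."""
    values = np.full((len(gene_sets), len(expr.samples)), np.nan)
    skipped: list[str] = []
    for i, gs in enumerate(gene_sets):
        try:
            values[i] = ss_enrichment(expr, gs, weight_exponent)
        except ValueError:
            skipped.append(gs.name)
    return ScoreMatrix(
        sets=[gs.name for gs in gene_sets],
        samples=list(expr.samples),
        values=values,
        skipped=skipped,
    )


def associate(
    scores: ScoreMatrix,
    tf_expr: Sequence[float],
    target_expr: Sequence[float],
    config: Optional[ScreenConfig] = None,
) -> pd.DataFrame:
    """Dual-correlation filter of set scores against TF and target expression.

    A set passes iff r > r_threshold AND p < p_threshold versus BOTH vectors.
    The table is sorted by min(r_tf, r_target) descending and includes every
    scorable set with a ``passes`` flag.
    """
    config = config or ScreenConfig()
    tf_expr = np.asarray(tf_expr, dtype=float)
    target_expr = np.asarray(target_expr, dtype=float)
    if len(tf_expr) != len(scores.samples) or len(target_expr) != len(scores.samples):
        raise ValueError("tf/target vectors must align with the score matrix samples")
    rows = []
    for name, row in zip(scores.sets, scores.values):
        if np.isnan(row).any():
            continue
        rec_tf = correlate(row, tf_expr, method=config.method, feature_a=name, feature_b="tf")
        rec_tg = correlate(
            row, target_expr, method=config.method, feature_a=name, feature_b="target"
        )
        if rec_tf.degenerate or rec_tg.degenerate:
            continue
        passes = (
            rec_tf.r > config.r_threshold
            and rec_tf.p < config.p_threshold
            and rec_tg.r > config.r_threshold
            and rec_tg.p < config.p_threshold
        )
        rows.append(
            {
                "gene_set": name,
                "r_tf": rec_tf.r,
                "p_tf": rec_tf.p,
                "r_target": rec_tg.r,
                "p_target": rec_tg.p,
                "r_min": min(rec_tf.r, rec_tg.r),
                "passes": passes,
            }
        )
    table = pd.DataFrame(
        rows,
        columns=["gene_set", "r_tf", "p_tf", "r_target", "p_target", "r_min", "passes"],
    )
    if len(table):
        table = table.sort_values(
            by=["r_min", "gene_set"], ascending=[False, True], kind="stable"
        ).reset_index(drop=True)
    return table
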