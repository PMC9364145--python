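"""TF-expression x promoter-accessibility correlation screen.

Builds the curated inflammation-related TF panel, correlates each panel
member's expression with per-region promoter accessibility and with the
target gene's expression, controls FDR (Benjamini-Hochberg), and ranks
candidates with a deterministic total order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .matrices import AccessibilityMatrix, ExpressionMatrix

__all__ = [
    "TFPanel",
    "CorrelationRecord",
    "ScreenConfig",
    "ScreenResult",
    "build_inflammatory_panel",
    "correlate",
    "bh_fdr",
    "screen_tfs",
    "NFKB_FAMILY",
    "IRF_FAMILY",
    "STAT_FAMILY",
]

# Curated inflammation-mediating TF families. The five-member NF-kB family
# (Rel homology domain: NFKB1, NFKB2, RELA, RELB, REL) plus nine IRFs and
# seven STATs give the 21-member panel.
NFKB_FAMILY = ("NFKB1", "NFKB2", "RELA", "RELB", "REL")
IRF_FAMILY = tuple(f"IRF{i}" for i in range(1, 10))
STAT_FAMILY = ("STAT1", "STAT2", "STAT3", "STAT4", "STAT5A", "STAT5B", "STAT6")


@dataclass
class TFPanel:
    """A set of TF symbols with optional family labels."""

    members: frozenset[str]
    family: dict[str, str] = field(default_factory=dict)
    source: str = "all_tfs"

    def __post_init__(self) -> None:
        self.members = frozenset(self.members)
        if self.source == "inflammatory_panel":
            missing = self.members - self.family.keys()
            if missing:
                raise ValueError(f"panel members without family labels: {sorted(missing)}")

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, symbol: str) -> bool:
        return symbol in self.members

    @classmethod
    def from_symbols(cls, symbols: Sequence[str]) -> "TFPanel":
        return cls(members=frozenset(symbols), source="all_tfs")


def build_inflammatory_panel() -> TFPanel:
    """The 21-member inflammatory TF panel: NF-kB + IRF + STAT families."""
    family = {s: "NF-kB" for s in NFKB_FAMILY}
    family.update({s: "IRF" for s in IRF_FAMILY})
    family.update({s: "STAT" for s in STAT_FAMILY})
    return TFPanel(
        members=frozenset(family), family=family, source="inflammatory_panel"
    )


@dataclass
class CorrelationRecord:
    """One pairwise correlation test."""

    feature_a: str
    feature_b: str
    r: float
    n: int
    p: float
    q: Optional[float] = None
    method: str = "pearson"
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not self.degenerate:
            if not -1.0 - 1e-12 <= self.r <= 1.0 + 1e-12:
                raise ValueError(f"|r| must be <= 1, got {self.r}")
            if not 0.0 <= self.p <= 1.0:
                raise ValueError(f"p must be in [0, 1], got {self.p}")
        if self.n < 3:
            raise ValueError(f"n must be >= 3, got {self.n}")


@dataclass
class ScreenConfig:
    method: str = "pearson"
    p_threshold: float = 0.05
    r_threshold: float = 0.4
    require_all_regions: bool = True
    top_k: int = 5

    def __post_init__(self) -> None:
        if self.method not in {"pearson", "spearman"}:
            raise ValueError(f"unknown method {self.method!r}")
        if not 0 < self.p_threshold <= 1:
            raise ValueError("p_threshold must be in (0, 1]")
        if not -1 <= self.r_threshold <= 1:
            raise ValueError("r_threshold must be in [-1, 1]")
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")


def correlate(
    x: Sequence[float],
    y: Sequence[float],
    method: str = "pearson",
    feature_a: str = "x",
    feature_b: str = "y",
) -> CorrelationRecord:
    """Pearson or Spearman correlation with a two-sided t-transform p-value.

    Spearman is Pearson on average ranks. Zero-variance input yields a
    degenerate record (r, p = NaN) which downstream stages exclude.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError(f"x and y must be equal-length vectors, got {x.shape} vs {y.shape}")
    n = len(x)
    if n < 3:
        raise ValueError(f"need n >= 3 paired samples, got {n}")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    if method == "spearman":
        x = stats.rankdata(x)
        y = stats.rankdata(y)
    elif method != "pearson":
        raise ValueError(f"unknown method {method!r}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationRecord(
            feature_a, feature_b, math.nan, n, math.nan, method=method, degenerate=True
        )
    xc = x - x.mean()
    yc = y - y.mean()
    r = float(np.dot(xc, yc) / np.sqrt(np.dot(xc, xc) * np.dot(yc, yc)))
    r = max(-1.0, min(1.0, r))
    # two-sided p via t = r * sqrt((n-2) / (1-r^2)) with n-2 df
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * math.sqrt((n - 2) / (1 - r * r))
        p = float(2 * stats.t.sf(abs(t), df=n - 2))
    return CorrelationRecord(feature_a, feature_b, r, n, p, method=method)


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values, in the input order.

    ``q(i) = min_{j >= i} p(j) * m / j`` over the ascending sort, capped at 1.
    NaN entries (degenerate tests) propagate as NaN and do not count toward m.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvalues must be a vector")
    finite = ~np.isnan(p)
    if np.any((p[finite] < 0) | (p[finite] > 1)):
        raise ValueError("p-values must be in [0, 1]")
    q = np.full(p.shape, np.nan)
    pf = p[finite]
    m = len(pf)
    if m == 0:
        return q
    order = np.argsort(pf, kind="stable")
    ranked = pf[order] * m / np.arange(1, m + 1)
    qf = np.minimum.accumulate(ranked[::-1])[::-1]
    qf = np.minimum(qf, 1.0)
    out = np.empty(m)
    out[order] = qf
    q[finite] = out
    return q


@dataclass
class ScreenResult:
    """Output of :func:`screen_tfs`.

    ``summary`` is the ranked per-TF table; ``per_region`` holds every
    (TF, region) correlation record; ``missing`` lists panel members absent
    from the expression matrix; ``degenerate`` lists TFs excluded for
    zero-variance expression.
    """

    summary: pd.DataFrame
    per_region: pd.DataFrame
    missing: list[str]
    degenerate: list[str]

    @property
    def top_tf(self) -> str:
        return str(self.summary.iloc[0]["tf"])


def screen_tfs(
    expr: ExpressionMatrix,
    acc: AccessibilityMatrix,
    panel: TFPanel,
    target_gene: str,
    config: Optional[ScreenConfig] = None,
) -> ScreenResult:
    """Rank panel TFs by correlation with target-promoter accessibility.

    For every (TF, region) pair a correlation record is computed; BH q-values
    are assigned across all (TF, region) tests. The per-TF ranking key is
    (mean per-region r desc, r vs target expression desc, min region p asc,
    symbol asc) -- a deterministic total order. ``passes`` applies the raw-p
    gate (all regions, or any, per ``config.require_all_regions``).
    """
    config = config or ScreenConfig()
    if list(expr.samples) != list(acc.samples):
        if set(expr.samples) != set(acc.samples):
            raise ValueError("expression and accessibility matrices share no aligned sample set")
        # same samples, different order: align accessibility to expression
        idx = [acc.samples.index(s) for s in expr.samples]
        acc = AccessibilityMatrix(
            list(acc.regions), list(expr.samples), acc.values[:, idx], acc.normalization
        )
    if len(expr.samples) < 3:
        raise ValueError("need >= 3 shared samples")
    if target_gene not in expr.genes:
        raise ValueError(f"target gene {target_gene!r} not in expression matrix")

    members = sorted(panel.members)
    missing = [tf for tf in members if tf not in expr.genes]
    present = [tf for tf in members if tf in expr.genes]
    target_vec = expr.row(target_gene)

    rows = []
    degenerate: list[str] = []
    for tf in present:
        tf_vec = expr.row(tf)
        if np.ptp(tf_vec) == 0:
            degenerate.append(tf)
        for region in acc.regions:
            rec = correlate(
                tf_vec, acc.row(region), method=config.method,
                feature_a=tf, feature_b=region.display(),
            )
            rows.append(
                {
                    "tf": tf,
                    "family": panel.family.get(tf, ""),
                    "region": region.display(),
                    "r": rec.r,
                    "n": rec.n,
                    "p": rec.p,
                    "degenerate": rec.degenerate,
                }
            )
    per_region = pd.DataFrame(
        rows, columns=["tf", "family", "region", "r", "n", "p", "degenerate"]
    )
    if len(per_region):
        per_region["q"] = bh_fdr(per_region["p"].to_numpy())
    else:
        per_region["q"] = []

    summaries = []
    for tf in present:
        if tf in degenerate:
            continue
        sub = per_region[per_region["tf"] == tf]
        r_target_rec = correlate(
            expr.row(tf), target_vec, method=config.method,
            feature_a=tf, feature_b=target_gene,
        )
        if config.require_all_regions:
            passes = bool((sub["p"] < config.p_threshold).all())
        else:
            passes = bool((sub["p"] < config.p_threshold).any())
        summaries.append(
            {
                "tf": tf,
                "family": panel.family.get(tf, ""),
                "r_region": float(sub["r"].mean()),
                "r_target": float("nan") if r_target_rec.degenerate else r_target_rec.r,
                "p_min": float(sub["p"].min()),
                "q_min": float(sub["q"].min()),
                "n": int(sub["n"].iloc[0]) if len(sub) else len(expr.samples),
                "passes": passes,
            }
        )
    summary = pd.DataFrame(
        summaries,
        columns=["tf", "family", "r_region", "r_target", "p_min", "q_min", "n", "passes"],
    )
    if len(summary):
        summary = summary.sort_values(
            by=["r_region", "r_target", "p_min", "tf"],
            ascending=[False, False, True, True],
            kind="stable",
        ).reset_index(drop=True)
        summary["rank"] = np.arange(1, len(summary) + 1)
    else:
        summary["rank"] = []
    return ScreenResult(
        summary=summary, per_region=per_region, missing=missing, degenerate=degenerate
    )
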