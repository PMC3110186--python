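"""Per-gene treatment-vs-control testing with FDR control.

Each contrast compares one treatment group to its matched vehicle
control at a single timepoint with a two-sample Student's t-test
(pooled variance, df = n1 + n2 - 2; Welch available behind a flag).
Testing is done separately per timepoint so kinetic differences do not
confound the comparison. P-values are converted to Q-values with the
Benjamini–Hochberg step-up procedure, per contrast (family = all genes
of that contrast). Significance filtering and cross-timepoint Venn
overlap counting complete the stage.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import ExpressionDataset

__all__ = [
    "ContrastSpec",
    "contrast_ttest",
    "bh_adjust",
    "add_qvalues",
    "significance_filter",
    "overlap_counts",
    "OverlapSummary",
    "common_upregulated",
]


@dataclass(frozen=True)
class ContrastSpec:
    """One treatment-vs-control comparison at one timepoint."""

    treatment: str
    control: str
    timepoint_h: float

    def __post_init__(self) -> None:
        if self.treatment == self.control:
            raise ValueError("treatment and control groups must differ")

    def label(self) -> str:
        return f"{self.treatment}_vs_{self.control}_{self.timepoint_h:g}h"


def contrast_ttest(
    data: ExpressionDataset, contrast: ContrastSpec, welch: bool = False
) -> pd.DataFrame:
    """Per-gene two-sample t-test for one contrast.

    Returns a DataFrame indexed by gene with columns ``t``, ``p``
    (two-sided), ``p_up`` (upper tail: treatment > control), ``p_down``,
    ``log2fc`` (mean treatment − mean control) and ``zero_variance``.
    Genes with zero pooled variance are flagged and given p = 1,
    p_up = p_down = 0.5 (their log2fc is still reported).
    """
    t_samples = data.samples_for(contrast.treatment, contrast.timepoint_h)
    c_samples = data.samples_for(contrast.control, contrast.timepoint_h)
    if len(t_samples) < 2 or len(c_samples) < 2:
        raise ValueError(
            f"contrast {contrast.label()}: need >=2 replicates per side, "
            f"got {len(t_samples)} vs {len(c_samples)}"
        )
    xt = data.values[t_samples].to_numpy(dtype=float)
    xc = data.values[c_samples].to_numpy(dtype=float)
    n1, n2 = xt.shape[1], xc.shape[1]
    m1, m2 = xt.mean(axis=1), xc.mean(axis=1)
    v1 = xt.var(axis=1, ddof=1)
    v2 = xc.var(axis=1, ddof=1)
    log2fc = m1 - m2

    if welch:
        se2 = v1 / n1 + v2 / n2
        with np.errstate(divide="ignore", invalid="ignore"):
            tstat = (m1 - m2) / np.sqrt(se2)
            df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
        degenerate = se2 == 0
        df = np.where(degenerate, 1.0, df)
    else:
        pooled = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
        with np.errstate(divide="ignore", invalid="ignore"):
            tstat = (m1 - m2) / np.sqrt(pooled * (1 / n1 + 1 / n2))
        degenerate = pooled == 0
        df = np.full_like(tstat, float(n1 + n2 - 2))

    tstat = np.where(degenerate, 0.0, tstat)
    p_up = stats.t.sf(tstat, df)
    p_down = stats.t.cdf(tstat, df)
    p_two = 2.0 * np.minimum(p_up, p_down)
    p_up = np.where(degenerate, 0.5, p_up)
    p_down = np.where(degenerate, 0.5, p_down)
    p_two = np.where(degenerate, 1.0, np.minimum(p_two, 1.0))

    return pd.DataFrame(
        {
            "t": tstat,
            "p": p_two,
            "p_up": p_up,
            "p_down": p_down,
            "log2fc": log2fc,
            "zero_variance": degenerate,
        },
        index=data.values.index.copy(),
    )


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (Q-values).

    On ascending order p_(1) <= ... <= p_(m):
    Q_(i) = min_{j >= i} (m * p_(j) / j), capped at 1, mapped back to the
    input order. Monotone in p.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvalues must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if not np.isfinite(p).all() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must be finite and lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def add_qvalues(table: pd.DataFrame) -> pd.DataFrame:
    """Append BH Q-values (column ``q``) computed over all genes of the
    contrast's two-sided p-values."""
    out = table.copy()
    out["q"] = bh_adjust(out["p"].to_numpy())
    return out


def significance_filter(
    table: pd.DataFrame, q_threshold: float = 0.001, direction: str = "any"
) -> list[str]:
    """Genes with Q <= threshold, optionally restricted by fold-change
    sign; ordered by ascending Q with ties broken by gene id."""
    if not 0.0 < q_threshold <= 1.0:
        raise ValueError("q_threshold must lie in (0, 1]")
    if direction not in {"up", "down", "any"}:
        raise ValueError(f"unknown direction {direction!r}")
    if "q" not in table.columns:
        raise ValueError("table lacks Q-values; call add_qvalues first")
    mask = table["q"] <= q_threshold
    if direction == "up":
        mask &= table["log2fc"] > 0
    elif direction == "down":
        mask &= table["log2fc"] < 0
    sub = table.loc[mask, ["q"]].copy()
    sub["gene"] = sub.index
    sub = sub.sort_values(["q", "gene"], kind="stable")
    return list(sub["gene"])


@dataclass
class OverlapSummary:
    """Venn-style overlap counts of significant genes across timepoints."""

    singles: dict[float, int]
    pairwise: dict[tuple[float, float], int]
    triple: int
    union: int

    def as_frame(self) -> pd.DataFrame:
        rows = [{"region": f"{tp:g}h", "count": c} for tp, c in self.singles.items()]
        rows += [
            {"region": f"{a:g}h&{b:g}h", "count": c}
            for (a, b), c in self.pairwise.items()
        ]
        rows.append({"region": "all", "count": self.triple})
        rows.append({"region": "union", "count": self.union})
        return pd.DataFrame(rows)


def overlap_counts(per_timepoint_sets: dict[float, set]) -> OverlapSummary:
    """Exact set-algebra counts: per-timepoint totals, every pairwise
    intersection, the full intersection, and the union."""
    if not per_timepoint_sets:
        raise ValueError("need at least one timepoint")
    tps = sorted(per_timepoint_sets)
    sets = {tp: set(per_timepoint_sets[tp]) for tp in tps}
    singles = {tp: len(sets[tp]) for tp in tps}
    pairwise = {
        (a, b): len(sets[a] & sets[b]) for a, b in combinations(tps, 2)
    }
    full = set.intersection(*sets.values()) if sets else set()
    union = set.union(*sets.values()) if sets else set()
    return OverlapSummary(singles, pairwise, len(full), len(union))


def common_upregulated(
    sets_a: dict[float, set], sets_b: dict[float, set]
) -> set:
    """Genes up-significant in at least one timepoint for *each* of two
    treatments (the cross-treatment "commonly up-regulated" rule)."""
    any_a = set.union(*sets_a.values()) if sets_a else set()
    any_b = set.union(*sets_b.values()) if sets_b else set()
    return any_a & any_b
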