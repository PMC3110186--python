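"""Reporter-algorithm gene-set enrichment with Monte-Carlo background.

The reporter algorithm maps gene-level significance onto gene sets
(GO terms, pathways): each gene's one-sided p-value becomes a normal
score Z_g = Phi^-1(1 - p), a set's raw score is the mean-normalized sum
Z_raw = sum(Z_g) / sqrt(k) over its k scored members, and the raw score
is calibrated against size-matched random sets drawn from the scored
gene universe: Z_corr = (Z_raw - mu_k) / sigma_k, p = 1 - Phi(Z_corr).
Up- and down-regulation are analyzed as separate runs using the
corresponding one-sided p-values.

The significance matrix collects -log10 reporter p across conditions
for sets significant anywhere, hierarchically clustered for display;
the directional fraction (the "arrow angle": proportion of a set's
scored members with positive fold change) accompanies each set.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .datatypes import GeneSetCollection

logger = logging.getLogger(__name__)

__all__ = [
    "gene_zscores",
    "reporter_raw_score",
    "ReporterNull",
    "background_correct",
    "direction_fraction",
    "reporter_analysis",
    "build_significance_matrix",
]

_EPS = 1e-15


def gene_zscores(table: pd.DataFrame, direction: str = "up") -> pd.Series:
    """Inverse-normal gene scores from one-sided p-values.

    Z_g = Phi^-1(1 - p_dir), with p clamped to [1e-15, 1 - 1e-15] so the
    score stays finite.
    """
    col = {"up": "p_up", "down": "p_down"}.get(direction)
    if col is None:
        raise ValueError(f"direction must be 'up' or 'down', got {direction!r}")
    p = np.clip(table[col].to_numpy(dtype=float), _EPS, 1 - _EPS)
    return pd.Series(stats.norm.isf(p), index=table.index, name=f"z_{direction}")


def reporter_raw_score(zscores: pd.Series, members) -> tuple[float, int]:
    """Raw reporter score of one set: (sum Z_i) / sqrt(k_eff) over the
    k_eff members present in the score mapping. Returns (nan, 0) when no
    member is scored."""
    present = [g for g in members if g in zscores.index]
    k = len(present)
    if k == 0:
        return float("nan"), 0
    return float(zscores.loc[present].sum() / np.sqrt(k)), k


class ReporterNull:
    """Size-matched Monte-Carlo null for reporter scores.

    For each set size k it draws ``n_samples`` random k-subsets (without
    replacement) of the scored-gene universe and records the mean and SD
    of their raw scores. Nulls are cached per k so all sets of equal
    size share one null, and the whole object is reusable across sets
    for one condition/direction.
    """

    def __init__(self, zscores: pd.Series, n_samples: int = 10_000, seed: int = 0):
        if n_samples < 1000:
            raise ValueError("n_samples must be >= 1000 for a stable null")
        self.z = np.asarray(zscores, dtype=float)
        self.n_samples = n_samples
        self._rng = np.random.default_rng(seed)
        self._cache: dict[int, tuple[float, float]] = {}

    def moments(self, k: int) -> tuple[float, float]:
        """(mu_k, sigma_k) of the size-k null, cached."""
        if k < 1:
            raise ValueError("k must be >= 1")
        if k not in self._cache:
            n = self.z.size
            draws = np.empty(self.n_samples)
            sqrt_k = np.sqrt(k)
            for i in range(self.n_samples):
                idx = self._rng.choice(n, size=k, replace=False)
                draws[i] = self.z[idx].sum() / sqrt_k
            mu = float(draws.mean())
            sigma = float(draws.std(ddof=1))
            if sigma <= 1e-12 * max(1.0, abs(mu)):
                raise ValueError(
                    "degenerate null: all gene scores equal, sigma_k = 0"
                )
            self._cache[k] = (mu, sigma)
        return self._cache[k]

    def correct(self, z_raw: float, k: int) -> tuple[float, float]:
        """Background-corrected score and reporter p-value."""
        mu, sigma = self.moments(k)
        z_corr = (z_raw - mu) / sigma
        p = float(np.clip(stats.norm.sf(z_corr), _EPS, 1 - _EPS))
        return float(z_corr), p


def background_correct(
    z_raw: float,
    k_eff: int,
    zscores: pd.Series,
    n_samples: int = 10_000,
    seed: int = 0,
) -> tuple[float, float]:
    """One-shot wrapper over :class:`ReporterNull` for a single set."""
    null = ReporterNull(zscores, n_samples=n_samples, seed=seed)
    return null.correct(z_raw, k_eff)


def direction_fraction(table: pd.DataFrame, members) -> float:
    """Proportion of a set's scored members with log2fc > 0 (the arrow
    angle of the heatmap display: 1.0 = all up, 0.5 = half up). Genes
    with log2fc exactly 0 are excluded from the denominator; NaN when no
    member is scored or all are ties."""
    present = [g for g in members if g in table.index]
    if not present:
        return float("nan")
    fc = table.loc[present, "log2fc"].to_numpy(dtype=float)
    nonzero = fc[fc != 0]
    if nonzero.size == 0:
        return float("nan")
    return float((nonzero > 0).sum() / nonzero.size)


def reporter_analysis(
    table: pd.DataFrame,
    sets: GeneSetCollection,
    direction: str = "up",
    n_samples: int = 10_000,
    seed: int = 0,
    condition: str = "",
) -> pd.DataFrame:
    """Score every gene set of a collection against one contrast.

    Returns a table with one row per set: ``set``, ``condition``,
    ``direction``, ``k_eff``, ``z_raw``, ``z_corrected``, ``p`` and
    ``fraction_up``. Sets with no scored member are skipped with a
    logged warning.
    """
    z = gene_zscores(table, direction)
    null = ReporterNull(z, n_samples=n_samples, seed=seed)
    rows = []
    for name, members in sets.items():
        z_raw, k = reporter_raw_score(z, members)
        if k == 0:
            logger.warning("set %s has no scored members; skipped", name)
            continue
        z_corr, p = null.correct(z_raw, k)
        rows.append(
            {
                "set": name,
                "condition": condition,
                "direction": direction,
                "k_eff": k,
                "z_raw": z_raw,
                "z_corrected": z_corr,
                "p": p,
                "fraction_up": direction_fraction(table, members),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "set", "condition", "direction", "k_eff",
            "z_raw", "z_corrected", "p", "fraction_up",
        ],
    )


def build_significance_matrix(
    tables: pd.DataFrame, p_select: float = 0.001
) -> pd.DataFrame:
    """Set × condition matrix of -log10 reporter p, clustered.

    *tables* is the concatenation of :func:`reporter_analysis` outputs
    across conditions (one direction). Sets reaching p <= ``p_select``
    in at least one condition are retained; rows and columns are ordered
    by average-linkage hierarchical clustering on Euclidean distance
    (deterministic: inputs are pre-sorted by label so ties resolve by
    label). Returns an empty frame, with a warning, when nothing passes.
    """
    wide = tables.pivot_table(index="set", columns="condition", values="p")
    wide = wide.sort_index().sort_index(axis=1)
    keep = (wide <= p_select).any(axis=1)
    wide = wide.loc[keep]
    if wide.empty:
        logger.warning("no set reaches reporter p <= %g in any condition", p_select)
        return pd.DataFrame()
    mat = -np.log10(wide.to_numpy(dtype=float))
    mat = np.nan_to_num(mat, nan=0.0)

    def _leaf_order(m: np.ndarray) -> np.ndarray:
        if m.shape[0] < 3:
            return np.arange(m.shape[0])
        link = hierarchy.linkage(pdist(m, metric="euclidean"), method="average")
        return np.asarray(hierarchy.leaves_list(link))

    row_order = _leaf_order(mat)
    col_order = _leaf_order(mat.T)
    out = pd.DataFrame(mat, index=wide.index, columns=wide.columns)
    return out.iloc[row_order, col_order]
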