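"""Weighted co-expression network construction and module detection.

For each treatment arm, genes significant at Q <= 0.01 in at least one
timepoint are selected and their expression across all of that arm's
arrays (treatment + matched control, all timepoints pooled) is turned
into an unsigned weighted network: a_ij = |cor(x_i, x_j)|^beta, with
beta chosen so the connectivity distribution approximates a scale-free
law. The topological overlap matrix (TOM) augments direct adjacency
with shared-neighbor weight; average-linkage clustering of 1 - TOM cut
at a fixed height yields co-expression modules, whose functional
content is assessed by hypergeometric enrichment against a gene-set
collection.

Also exposed as the scikit-learn clusterer :class:`CoexpressionModules`
(fit on samples × genes, module labels in ``labels_``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.utils.validation import check_array

from .datatypes import ExpressionDataset, GeneSetCollection
from .diffexpr import bh_adjust

logger = logging.getLogger(__name__)

__all__ = [
    "CoexprConfig",
    "select_coexpr_genes",
    "adjacency_matrix",
    "pick_soft_threshold",
    "topological_overlap",
    "detect_modules",
    "refine_modules",
    "module_eigengene",
    "ModulePartition",
    "module_enrichment",
    "CoexpressionModules",
]


@dataclass
class CoexprConfig:
    """Tunables of the co-expression stage."""

    q_select: float = 0.01
    beta: int | str = "auto"
    candidate_betas: tuple[int, ...] = (1, 2, 3, 4, 5, 6, 7, 8, 10, 12, 14, 16)
    r2_target: float = 0.8
    cut_height: float = 0.99
    min_module_size: int = 30
    signed: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.q_select <= 1.0:
            raise ValueError("q_select must lie in (0, 1]")
        if not 0.0 < self.r2_target < 1.0:
            raise ValueError("r2_target must lie in (0, 1)")
        if not 0.0 < self.cut_height <= 1.0:
            raise ValueError("cut_height must lie in (0, 1]")
        if self.beta != "auto" and (not isinstance(self.beta, int) or self.beta < 1):
            raise ValueError("beta must be a positive integer or 'auto'")


def select_coexpr_genes(
    tables: dict[float, pd.DataFrame], q_select: float = 0.01
) -> list[str]:
    """Union of genes with Q <= q_select in at least one timepoint of a
    treatment, sorted by gene id."""
    if not tables:
        raise ValueError("need at least one timepoint table")
    selected: set[str] = set()
    for table in tables.values():
        if "q" not in table.columns:
            raise ValueError("table lacks Q-values")
        selected |= set(table.index[table["q"] <= q_select])
    if not selected:
        raise ValueError(
            f"no gene reaches Q <= {q_select} at any timepoint; relax q_select"
        )
    return sorted(selected)


def _correlation(x: np.ndarray) -> np.ndarray:
    sd = x.std(axis=1, ddof=1)
    keep = sd > 0
    r = np.atleast_2d(np.corrcoef(x[keep]))
    return r, keep


def adjacency_matrix(
    data: ExpressionDataset, genes, beta: int = 6, signed: bool = False
) -> pd.DataFrame:
    """Unsigned weighted adjacency a_ij = |cor(x_i, x_j)|^beta (signed
    variant: ((1 + r)/2)^beta); unit diagonal. Zero-variance genes are
    dropped with a warning."""
    genes = [g for g in genes if g in data.values.index]
    x = data.values.loc[genes].to_numpy(dtype=float)
    if x.shape[1] < 4:
        raise ValueError("need >= 4 samples for a meaningful correlation network")
    r, keep = _correlation(x)
    if not keep.all():
        dropped = [g for g, k in zip(genes, keep) if not k]
        logger.warning("dropped %d zero-variance gene(s): %s...", len(dropped), dropped[:5])
        genes = [g for g, k in zip(genes, keep) if k]
    r = np.clip(r, -1.0, 1.0)
    a = ((1.0 + r) / 2.0) ** beta if signed else np.abs(r) ** beta
    np.fill_diagonal(a, 1.0)
    return pd.DataFrame(a, index=genes, columns=genes)


def _scale_free_r2(k: np.ndarray, n_bins: int = 10) -> float:
    """R^2 of log10(frequency) on log10(mean connectivity) over bins —
    the scale-free topology fit index."""
    k = k[k > 0]
    if k.size < n_bins:
        return 0.0
    edges = np.quantile(k, np.linspace(0, 1, n_bins + 1))
    edges = np.unique(edges)
    if edges.size < 3:
        return 0.0
    idx = np.clip(np.digitize(k, edges[1:-1]), 0, edges.size - 2)
    log_k, log_f = [], []
    for b in range(edges.size - 1):
        members = k[idx == b]
        if members.size == 0:
            continue
        log_k.append(np.log10(members.mean()))
        log_f.append(np.log10(members.size / k.size))
    if len(log_k) < 3:
        return 0.0
    res = stats.linregress(log_k, log_f)
    r2 = float(res.rvalue**2)
    return 0.0 if np.isnan(r2) else r2


def pick_soft_threshold(
    data: ExpressionDataset,
    genes,
    candidate_betas=(1, 2, 3, 4, 5, 6, 7, 8, 10, 12, 14, 16),
    r2_target: float = 0.8,
    signed: bool = False,
) -> int:
    """Smallest candidate power whose connectivity distribution fits a
    scale-free law at R^2 >= r2_target; falls back (with a warning) to
    the best-fitting candidate when none reaches the target."""
    candidates = list(candidate_betas)
    if len(candidates) < 1:
        raise ValueError("need at least one candidate beta")
    best_beta, best_r2 = None, -1.0
    for beta in candidates:
        a = adjacency_matrix(data, genes, beta=beta, signed=signed).to_numpy()
        k = a.sum(axis=1) - 1.0
        if np.allclose(k, k[0]):
            raise ValueError("degenerate network: all connectivities identical")
        r2 = _scale_free_r2(k)
        if r2 >= r2_target:
            return beta
        if r2 > best_r2:
            best_beta, best_r2 = beta, r2
    if best_beta is None:
        best_beta = candidates[0]
    logger.warning(
        "no candidate beta reached scale-free R^2 >= %.2f; using beta=%d (R^2=%.2f)",
        r2_target, best_beta, best_r2,
    )
    return best_beta


def topological_overlap(adjacency: pd.DataFrame | np.ndarray) -> pd.DataFrame | np.ndarray:
    """Topological overlap matrix.

    TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij) for i != j, with
    l_ij = sum_{u != i,j} a_iu a_uj and k_i = sum_{u != i} a_iu;
    TOM_ii = 1. Requires a symmetric input with unit diagonal and
    entries in [0, 1].
    """
    labels = None
    a = adjacency
    if isinstance(a, pd.DataFrame):
        labels = a.index
        a = a.to_numpy(dtype=float)
    if a.shape[0] != a.shape[1] or not np.allclose(a, a.T, atol=1e-10):
        raise ValueError("adjacency must be square and symmetric")
    if (a < -1e-12).any() or (a > 1 + 1e-12).any():
        raise ValueError("adjacency entries must lie in [0, 1]")
    a = np.clip(a, 0.0, 1.0)
    d = a.copy()
    np.fill_diagonal(d, 0.0)  # off-diagonal part
    k = d.sum(axis=1)
    l = d @ d  # (A^2)_ij over u != i,j requires removing nothing extra: diag already 0
    num = l + d
    kmin = np.minimum.outer(k, k)
    with np.errstate(divide="ignore", invalid="ignore"):
        tom = num / (kmin + 1.0 - d)
    tom = np.nan_to_num(tom, nan=0.0)
    np.fill_diagonal(tom, 1.0)
    tom = np.clip((tom + tom.T) / 2.0, 0.0, 1.0)
    if labels is not None:
        return pd.DataFrame(tom, index=labels, columns=labels)
    return tom


@dataclass
class ModulePartition:
    """Gene -> module labels (positive ints, 0 = unassigned) plus
    per-module summaries."""

    labels: pd.Series
    summaries: pd.DataFrame

    def genes_in(self, module: int) -> list[str]:
        return sorted(self.labels.index[self.labels == module])

    def n_modules(self) -> int:
        return int((self.summaries["module"] > 0).sum()) if len(self.summaries) else 0


def detect_modules(
    tom: pd.DataFrame, cut_height: float = 0.99, min_module_size: int = 30
) -> ModulePartition:
    """Cut the average-linkage dendrogram of 1 - TOM at ``cut_height``.

    Clusters below ``min_module_size`` become label 0 (unassigned);
    remaining clusters are labeled 1..M by decreasing size (ties broken
    by smallest member gene id). Mean intramodular connectivity
    (mean within-module TOM excluding self) is reported per module.
    """
    genes = sorted(tom.index)
    tom = tom.loc[genes, genes]
    m = tom.to_numpy(dtype=float)
    dissim = 1.0 - m
    np.fill_diagonal(dissim, 0.0)
    dissim = np.clip((dissim + dissim.T) / 2.0, 0.0, None)
    link = hierarchy.linkage(squareform(dissim, checks=False), method="average")
    raw = hierarchy.fcluster(link, t=cut_height, criterion="distance")

    sizes: dict[int, int] = {}
    first_gene: dict[int, str] = {}
    for g, c in zip(genes, raw):
        sizes[c] = sizes.get(c, 0) + 1
        first_gene.setdefault(c, g)
    big = [c for c in sizes if sizes[c] >= min_module_size]
    big.sort(key=lambda c: (-sizes[c], first_gene[c]))
    relabel = {c: i + 1 for i, c in enumerate(big)}
    labels = pd.Series(
        [relabel.get(c, 0) for c in raw], index=genes, name="module", dtype=int
    )
    if not big:
        logger.warning("no cluster reached min_module_size=%d; all genes unassigned",
                       min_module_size)

    rows = []
    for mod in sorted(set(labels)):
        idx = np.where(labels.to_numpy() == mod)[0]
        if mod == 0 or idx.size < 2:
            mean_conn = float("nan")
        else:
            block = m[np.ix_(idx, idx)]
            mean_conn = float((block.sum() - idx.size) / (idx.size * (idx.size - 1)))
        rows.append({"module": mod, "size": int(idx.size),
                     "mean_intramodular_tom": mean_conn})
    return ModulePartition(labels, pd.DataFrame(rows))


def module_eigengene(x: np.ndarray) -> np.ndarray:
    """First principal component of a module's standardized expression
    (genes × samples), oriented to correlate positively with the mean
    module profile."""
    sd = x.std(axis=1, ddof=1, keepdims=True)
    sd[sd == 0] = 1.0
    xs = (x - x.mean(axis=1, keepdims=True)) / sd
    _, _, vt = np.linalg.svd(xs, full_matrices=False)
    e = vt[0]
    if np.corrcoef(e, xs.mean(axis=0))[0, 1] < 0:
        e = -e
    return e


def refine_modules(
    data: ExpressionDataset,
    partition: ModulePartition,
    tom: pd.DataFrame | None = None,
    signed: bool = True,
    merge_r: float = 0.8,
    kme_min: float = 0.3,
    min_module_size: int = 30,
    n_iter: int = 5,
) -> ModulePartition:
    """Eigengene-based refinement of a tree-cut partition.

    Iteratively (a) merges modules whose eigengenes correlate above
    ``merge_r`` and (b) reassigns every gene to the module whose
    eigengene it correlates with best (its kME), leaving genes whose
    best kME falls below ``kme_min`` unassigned. With ``signed`` the
    raw correlation is used, so anti-correlated genes are not absorbed;
    unsigned uses |kME|. Run this on the seed modules from a fine
    dendrogram cut: chained or borderline genes move to the module
    they statistically belong to, and over-split factors re-merge.
    Modules below ``min_module_size`` after refinement are dropped and
    the rest relabeled 1..M by decreasing size.
    """
    genes = list(partition.labels.index)
    x = data.values.loc[genes].to_numpy(dtype=float)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    sd[sd == 0] = 1.0
    xs = (x - x.mean(axis=1, keepdims=True)) / sd
    n = x.shape[1]
    lab = partition.labels.copy()

    for _ in range(n_iter):
        mods = sorted(set(lab) - {0})
        if not mods:
            break
        eigs = {m: module_eigengene(x[lab.to_numpy() == m]) for m in mods}
        # merge close modules (transitively, toward the smaller label)
        merged: dict[int, int] = {}
        for i, m in enumerate(mods):
            for m2 in mods[:i]:
                if np.corrcoef(eigs[m], eigs[m2])[0, 1] > merge_r:
                    merged[m] = merged.get(m2, m2)
                    break
        if merged:
            lab = lab.map(lambda c: merged.get(c, c))
            mods = sorted(set(lab) - {0})
            eigs = {m: module_eigengene(x[lab.to_numpy() == m]) for m in mods}
        # vectorized kME: correlation of every gene with every eigengene
        emat = np.vstack([(eigs[m] - eigs[m].mean()) / eigs[m].std(ddof=1)
                          for m in mods])
        kme = xs @ emat.T / (n - 1)
        if not signed:
            kme = np.abs(kme)
        best_idx = np.argmax(kme, axis=1)
        best_val = kme[np.arange(len(genes)), best_idx]
        new_labels = np.where(best_val >= kme_min,
                              np.array(mods)[best_idx], 0)
        changed = int((new_labels != lab.to_numpy()).sum())
        lab = pd.Series(new_labels, index=genes, name="module", dtype=int)
        if changed == 0 and not merged:
            break

    # enforce final size floor, relabel by decreasing size
    sizes = lab[lab > 0].value_counts()
    keep = sorted(
        (c for c in sizes.index if sizes[c] >= min_module_size),
        key=lambda c: (-sizes[c], min(g for g in genes
                                      if lab.loc[g] == c)),
    )
    relabel = {c: i + 1 for i, c in enumerate(keep)}
    lab = lab.map(lambda c: relabel.get(c, 0)).astype(int)

    rows = []
    m_tom = tom.loc[genes, genes].to_numpy() if tom is not None else None
    for mod in sorted(set(lab)):
        idx = np.where(lab.to_numpy() == mod)[0]
        mean_conn = float("nan")
        if mod != 0 and idx.size >= 2 and m_tom is not None:
            block = m_tom[np.ix_(idx, idx)]
            mean_conn = float((block.sum() - idx.size)
                              / (idx.size * (idx.size - 1)))
        rows.append({"module": mod, "size": int(idx.size),
                     "mean_intramodular_tom": mean_conn})
    return ModulePartition(lab, pd.DataFrame(rows))


def module_enrichment(
    partition: ModulePartition,
    sets: GeneSetCollection,
    universe,
) -> pd.DataFrame:
    """Hypergeometric upper-tail enrichment of each module in each set.

    For a universe of N genes containing K set members, a module of n
    genes overlapping the set in x genes gets
    p = P[X >= x], X ~ Hypergeometric(N, K, n). BH adjustment is applied
    across all module × set tests; sets disjoint from the universe are
    skipped.
    """
    universe = set(universe)
    if not set(partition.labels.index) <= universe:
        raise ValueError("universe must contain every partitioned gene")
    N = len(universe)
    rows = []
    modules = sorted(set(partition.labels) - {0})
    for name, members in sets.items():
        inset = set(members) & universe
        if not inset:
            continue
        K = len(inset)
        for mod in modules:
            mod_genes = set(partition.genes_in(mod))
            n = len(mod_genes)
            overlap = sorted(mod_genes & inset)
            x = len(overlap)
            p = float(stats.hypergeom.sf(x - 1, N, K, n)) if x > 0 else 1.0
            rows.append({
                "module": mod, "set": name, "module_size": n, "set_size": K,
                "overlap": x, "p": min(p, 1.0), "overlap_genes": ",".join(overlap),
            })
    out = pd.DataFrame(
        rows, columns=["module", "set", "module_size", "set_size",
                       "overlap", "p", "overlap_genes"]
    )
    if len(out):
        out["q"] = bh_adjust(out["p"].to_numpy())
    else:
        out["q"] = pd.Series(dtype=float)
    return out


class CoexpressionModules(BaseEstimator, ClusterMixin):
    """Scikit-learn clusterer: weighted co-expression module detection.

    Fit on a samples × genes matrix; after fitting, ``labels_`` holds
    one module label per gene (0 = unassigned), ``tom_`` the topological
    overlap matrix and ``beta_`` the soft-threshold power used.

    Parameters mirror :class:`CoexprConfig`.
    """

    def __init__(self, beta: int | str = 6, cut_height: float = 0.99,
                 min_module_size: int = 30, signed: bool = False,
                 r2_target: float = 0.8):
        self.beta = beta
        self.cut_height = cut_height
        self.min_module_size = min_module_size
        self.signed = signed
        self.r2_target = r2_target

    def fit(self, X, y=None):
        X = check_array(X, dtype=float)
        genes = [f"g{i}" for i in range(X.shape[1])]
        values = pd.DataFrame(X.T, index=genes,
                              columns=[f"s{j}" for j in range(X.shape[0])])
        design = pd.DataFrame(
            {"group": "all", "timepoint_h": 1.0, "replicate": 1},
            index=values.columns,
        )
        data = ExpressionDataset(values, design)
        beta = self.beta
        if beta == "auto":
            beta = pick_soft_threshold(data, genes, r2_target=self.r2_target,
                                       signed=self.signed)
        adj = adjacency_matrix(data, genes, beta=beta, signed=self.signed)
        tom = topological_overlap(adj)
        part = detect_modules(tom, self.cut_height, self.min_module_size)
        self.beta_ = beta
        self.tom_ = tom
        self.partition_ = part
        self.labels_ = part.labels.loc[genes].to_numpy()
        self.n_features_in_ = X.shape[1]
        return self
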