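"""Synthetic expression studies with planted ground truth.

Emulates the design of a two-adjuvant mucosal stimulation study: two
treatment groups (a TLR9-agonist-like "rapid broad" responder and an
iNKT-agonist-like "delayed transient" responder), each with a matched
vehicle control, sampled at 4, 24 and 48 hours with four biological
replicates. The generator plants, and records as ground truth:

* differentially expressed genes per treatment × timepoint with signed
  log2 effects and treatment-specific kinetics,
* co-expression modules driven by a shared latent factor with an
  analytically controlled within-module correlation,
* gene sets enriched for perturbed genes of one direction,
* a hub gene wired into an interaction graph.

Every downstream stage of the pipeline is therefore testable without the
original microarray deposit.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
import pandas as pd

from .datatypes import ExpressionDataset, GeneSetCollection, InteractionGraph

logger = logging.getLogger(__name__)

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_dataset",
    "simulate_gene_sets",
    "simulate_graph",
    "study_config",
    "KINETIC_PRESETS",
]

# Kinetic presets expressed as de_fraction per timepoint (hours -> fraction
# of the genome perturbed). "rapid_broad" peaks early and stays high, decaying
# by 48 h; "delayed_transient" is an order of magnitude weaker and peaks at
# 24 h. The fractions correspond to roughly 2000/2700/1400 and 180/350/200
# perturbed genes on a 20k-gene genome.
KINETIC_PRESETS: dict[str, dict[float, float]] = {
    "rapid_broad": {4.0: 0.10, 24.0: 0.135, 48.0: 0.07},
    "delayed_transient": {4.0: 0.009, 24.0: 0.017, 48.0: 0.010},
}


@dataclass
class SimulationConfig:
    """Parameters of a planted-truth expression study.

    ``de_fraction`` maps (treatment, timepoint_h) -> fraction of genes
    perturbed in that cell; use :data:`KINETIC_PRESETS` for the two
    named kinetic shapes. ``module_r2`` is the expected pairwise Pearson
    correlation between genes of the same planted module.
    """

    n_genes: int = 2000
    groups: tuple[tuple[str, str], ...] = (("CpG", "PBS"), ("aGalCer", "PBSTween"))
    timepoints_h: tuple[float, ...] = (4.0, 24.0, 48.0)
    n_replicates: int = 4
    de_fraction: dict[tuple[str, float], float] = field(default_factory=dict)
    shared_fraction: float = 0.5
    effect_size_log2: float = 2.0
    effect_sd: float = 0.5
    up_fraction: float = 0.8
    noise_sd: float = 0.25
    baseline_mean: float = 8.0
    baseline_sd: float = 2.0
    n_modules: int = 3
    module_size: int = 30
    module_r2: float = 0.6
    n_sets: int = 20
    set_size: int = 25
    n_enriched_sets: int = 5
    enriched_purity: float = 0.8
    graph_hub_degree: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0 or self.n_replicates <= 0:
            raise ValueError("counts must be positive")
        if not 0.0 <= self.up_fraction <= 1.0:
            raise ValueError("up_fraction must lie in [0, 1]")
        if not 0.0 <= self.shared_fraction <= 1.0:
            raise ValueError("shared_fraction must lie in [0, 1]")
        if not 0.0 < self.module_r2 < 1.0:
            raise ValueError("module_r2 must lie in (0, 1)")
        if not 0.0 <= self.enriched_purity <= 1.0:
            raise ValueError("enriched_purity must lie in [0, 1]")
        for key, frac in self.de_fraction.items():
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"de_fraction{key} must lie in [0, 1]")
        if self.n_modules * self.module_size > self.n_genes:
            raise ValueError("planted modules exceed the gene universe")

    def treatments(self) -> list[str]:
        return [t for t, _ in self.groups]

    def control_of(self, treatment: str) -> str:
        for t, c in self.groups:
            if t == treatment:
                return c
        raise KeyError(treatment)


def study_config(n_genes: int = 2000, seed: int = 0, **overrides) -> SimulationConfig:
    """Config emulating the two-adjuvant study design: CpG-like
    rapid-broad kinetics vs aGalCer-like delayed-transient kinetics,
    3 timepoints, 4 replicates per group/timepoint."""
    de: dict[tuple[str, float], float] = {}
    for tp, frac in KINETIC_PRESETS["rapid_broad"].items():
        de[("CpG", tp)] = frac
    for tp, frac in KINETIC_PRESETS["delayed_transient"].items():
        de[("aGalCer", tp)] = frac
    # hub degree scales with genome size so the wiring stays feasible
    # within the up-perturbed pool on small simulated genomes
    hub_degree = int(min(30, max(5, n_genes // 40)))
    cfg = SimulationConfig(n_genes=n_genes, de_fraction=de, seed=seed,
                           graph_hub_degree=hub_degree)
    return replace(cfg, **overrides) if overrides else cfg


@dataclass
class GroundTruth:
    """Planted structure of a simulated study.

    ``effects`` maps (treatment, timepoint_h) -> {gene -> signed log2
    effect}. ``module_of`` maps each planted-module gene to its module
    label (1-based). ``enriched_sets`` maps set name -> direction
    ("up"/"down"); ``hub_gene`` is the designated interaction hub.
    """

    effects: dict[tuple[str, float], dict[str, float]]
    module_of: dict[str, int]
    enriched_sets: dict[str, str] = field(default_factory=dict)
    hub_gene: str | None = None

    def perturbed_genes(self, treatment: str, timepoint_h: float | None = None,
                        direction: str = "any") -> set[str]:
        keys = [k for k in self.effects
                if k[0] == treatment and (timepoint_h is None or k[1] == timepoint_h)]
        out: set[str] = set()
        for k in keys:
            for g, eff in self.effects[k].items():
                if direction == "up" and eff <= 0:
                    continue
                if direction == "down" and eff >= 0:
                    continue
                out.add(g)
        return out

    def all_perturbed(self, direction: str = "any") -> set[str]:
        out: set[str] = set()
        for (t, _tp) in self.effects:
            out |= self.perturbed_genes(t, direction=direction)
        return out


def _gene_ids(n: int) -> list[str]:
    width = max(5, len(str(n)))
    return [f"G{i:0{width}d}" for i in range(1, n + 1)]


def simulate_dataset(config: SimulationConfig) -> tuple[ExpressionDataset, GroundTruth]:
    """Draw one study from the generative model.

    Per gene g and sample s on the log2 scale:

        x_gs = mu_g + noise_sd * (sqrt(r2) * f_{m(g),s} + sqrt(1-r2) * eps_gs)
               + delta_{g,ts}                                  (treated cells)

    where mu_g ~ Normal(baseline_mean, baseline_sd) is the gene's basal
    level, f is the standard-normal latent factor of gene g's planted
    module (absent for unassigned genes, where the noise term is plain
    Normal(0, noise_sd)), and delta is the signed planted effect for the
    sample's (treatment, timepoint) cell. The latent-factor mixing gives
    an expected within-module pairwise correlation of exactly
    ``module_r2``. Identical seed -> identical output.
    """
    rng = np.random.default_rng(config.seed)
    genes = _gene_ids(config.n_genes)
    gene_index = {g: i for i, g in enumerate(genes)}

    # sample design: every group (treatments and controls) at every
    # timepoint, n_replicates each
    rows = []
    sample_ids = []
    all_groups = [g for pair in config.groups for g in pair]
    for grp in all_groups:
        for tp in config.timepoints_h:
            for rep in range(1, config.n_replicates + 1):
                sample_ids.append(f"{grp}_{tp:g}h_r{rep}")
                rows.append({"group": grp, "timepoint_h": tp, "replicate": rep})
    design = pd.DataFrame(rows, index=sample_ids)
    n_samples = len(sample_ids)

    mu = rng.normal(config.baseline_mean, config.baseline_sd, size=config.n_genes)

    # planted modules: disjoint blocks of genes sharing a latent factor
    module_of: dict[str, int] = {}
    module_gene_idx = rng.choice(
        config.n_genes, size=config.n_modules * config.module_size, replace=False
    )
    for m in range(config.n_modules):
        block = module_gene_idx[m * config.module_size:(m + 1) * config.module_size]
        for gi in block:
            module_of[genes[gi]] = m + 1

    eps = rng.standard_normal((config.n_genes, n_samples))
    noise = eps.copy()
    if config.n_modules > 0:
        factors = rng.standard_normal((config.n_modules, n_samples))
        r = math.sqrt(config.module_r2)
        s = math.sqrt(1.0 - config.module_r2)
        for g, m in module_of.items():
            gi = gene_index[g]
            noise[gi] = r * factors[m - 1] + s * eps[gi]
    x = mu[:, None] + config.noise_sd * noise

    # planted differential expression. Each treatment responds through a
    # pool of genes; timepoint sets are drawn from that pool so
    # consecutive timepoints overlap, as sustained in-vivo responses do.
    # A fraction of every pool comes from a cross-treatment core (with a
    # per-gene sign and magnitude fixed globally), emulating the shared
    # innate-response program both stimuli engage.
    effects: dict[tuple[str, float], dict[str, float]] = {}
    col_index = {sid: j for j, sid in enumerate(sample_ids)}
    pool_sizes = {}
    for treatment in config.treatments():
        counts = [int(round(config.de_fraction.get((treatment, tp), 0.0)
                            * config.n_genes))
                  for tp in config.timepoints_h]
        max_cnt = max(counts, default=0)
        pool_sizes[treatment] = (
            min(config.n_genes, int(math.ceil(1.5 * max_cnt))) if max_cnt else 0
        )
    core_size = int(math.ceil(config.shared_fraction
                              * max(pool_sizes.values(), default=0)))
    core_size = min(core_size, config.n_genes)
    core = rng.choice(config.n_genes, size=core_size, replace=False)
    core_signs = np.where(rng.random(core_size) < config.up_fraction, 1.0, -1.0)
    core_mags = np.abs(rng.normal(config.effect_size_log2, config.effect_sd,
                                  core_size))
    core_set = set(core.tolist())
    non_core = np.array([i for i in range(config.n_genes) if i not in core_set])

    for treatment in config.treatments():
        cells = [(tp, config.de_fraction.get((treatment, tp), 0.0))
                 for tp in config.timepoints_h]
        counts = {tp: int(round(frac * config.n_genes)) for tp, frac in cells}
        if any(0 < frac and cnt < 1 for (_, frac), cnt in zip(cells, counts.values())):
            logger.warning("%s: de_fraction too small for any perturbed gene", treatment)
        pool_size = pool_sizes[treatment]
        if pool_size == 0:
            for tp in config.timepoints_h:
                effects[(treatment, tp)] = {}
            continue
        n_shared = min(int(round(config.shared_fraction * pool_size)), core_size)
        shared_idx = rng.choice(core_size, size=n_shared, replace=False)
        n_private = min(pool_size - n_shared, len(non_core))
        private = rng.choice(len(non_core), size=n_private, replace=False)
        pool = np.concatenate([core[shared_idx], non_core[private]])
        signs = np.concatenate([
            core_signs[shared_idx],
            np.where(rng.random(n_private) < config.up_fraction, 1.0, -1.0),
        ])
        mags = np.concatenate([
            core_mags[shared_idx],
            np.abs(rng.normal(config.effect_size_log2, config.effect_sd,
                              n_private)),
        ])
        for tp in config.timepoints_h:
            cnt = counts[tp]
            chosen = rng.choice(pool_size, size=cnt, replace=False) if cnt else []
            cell: dict[str, float] = {}
            for idx in chosen:
                cell[genes[pool[idx]]] = float(signs[idx] * mags[idx])
            effects[(treatment, tp)] = cell
            # add the shift to every treated replicate in this cell
            cols = [col_index[s] for s in sample_ids
                    if design.loc[s, "group"] == treatment
                    and design.loc[s, "timepoint_h"] == tp]
            for g, eff in cell.items():
                x[gene_index[g], cols] += eff

    values = pd.DataFrame(x, index=genes, columns=sample_ids)
    truth = GroundTruth(effects=effects, module_of=module_of)
    return ExpressionDataset(values, design), truth


def simulate_gene_sets(config: SimulationConfig, truth: GroundTruth) -> GeneSetCollection:
    """Plant gene sets over the simulated universe.

    The first ``n_enriched_sets`` sets draw ``enriched_purity`` of their
    members from the first treatment's up-perturbed genes (the broad
    responder, so the enrichment is measurable in that treatment's
    contrasts); the rest sample uniformly from all genes. Enriched-set
    names and directions are recorded on the truth object.
    """
    if config.set_size > config.n_genes:
        raise ValueError("set_size exceeds the number of genes")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    genes = _gene_ids(config.n_genes)
    first = config.treatments()[0] if config.groups else None
    up = sorted(truth.perturbed_genes(first, direction="up")) if first else []
    if not up:
        up = sorted(truth.all_perturbed("up"))
    sets: dict[str, tuple[str, tuple[str, ...]]] = {}
    truth.enriched_sets = {}
    n_enriched = min(config.n_enriched_sets, config.n_sets) if up else 0
    for i in range(config.n_sets):
        name = f"SET{i + 1:03d}"
        if i < n_enriched:
            n_sig = min(int(round(config.enriched_purity * config.set_size)), len(up))
            chosen = list(rng.choice(up, size=n_sig, replace=False))
            rest_pool = [g for g in genes if g not in set(chosen)]
            chosen += list(rng.choice(rest_pool, size=config.set_size - n_sig,
                                      replace=False))
            truth.enriched_sets[name] = "up"
            desc = "planted enriched (up)"
        else:
            chosen = list(rng.choice(genes, size=config.set_size, replace=False))
            desc = "background"
        sets[name] = (desc, tuple(chosen))
    return GeneSetCollection(sets)


def simulate_graph(config: SimulationConfig, truth: GroundTruth) -> InteractionGraph:
    """Preferential-attachment interaction graph with a planted hub.

    A Barabási–Albert graph is grown over all genes, then a designated
    perturbed gene is wired to ``graph_hub_degree`` other perturbed
    genes so that it dominates connectivity within the
    significance-induced subgraph.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    genes = _gene_ids(config.n_genes)
    # hub and partners come from the first treatment's up-perturbed genes
    # (the broad responder) so the hub sits inside that treatment's
    # significance-induced subgraph; fall back to any perturbed gene
    first = config.treatments()[0] if config.groups else None
    perturbed = sorted(truth.perturbed_genes(first, direction="up")) if first else []
    if not perturbed:
        perturbed = sorted(truth.all_perturbed("up")) or sorted(truth.all_perturbed())
    if config.graph_hub_degree > max(len(perturbed) - 1, 0):
        raise ValueError(
            f"graph_hub_degree={config.graph_hub_degree} exceeds the "
            f"{len(perturbed)} perturbed genes available"
        )
    base = nx.barabasi_albert_graph(
        config.n_genes, m=2, seed=int(rng.integers(2**31))
    )
    g = nx.relabel_nodes(base, dict(enumerate(genes)))
    hub = perturbed[int(rng.integers(len(perturbed)))]
    partners = [p for p in perturbed if p != hub]
    chosen = rng.choice(len(partners), size=config.graph_hub_degree, replace=False)
    g.add_edges_from((hub, partners[i]) for i in chosen)
    truth.hub_gene = hub
    return InteractionGraph.from_networkx(g)
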