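"""Synthetic multi-farm microbiome studies with known assembly processes.

The generator emulates the structure of a multi-farm strawberry-microbiome
survey: 13 farms in a ~1-degree region around 50N/23E, four niches (bulk
soil, rhizosphere soil, root, shoot), each farm either healthy or unhealthy,
with farm-level soil chemistry tied to a latent environmental axis.

Communities are assembled from a shared metacommunity pool (lognormal
rank-abundance) under one of three ground-truth regimes:

* ``selection`` — a fraction ``1 - selection_baseline`` of each sample's
  reads comes from the pool filtered by a Gaussian kernel on a Brownian
  trait around the sample's environment, the rest from neutral immigration
  (mass effects).  The immigration background keeps the group's taxon pool
  broad, so the abundance-weighted clustering of the selected clade is
  visible to the tip-shuffle null (βNTI strongly negative within
  environmentally consistent groups);
* ``drift`` — neutral multinomial sampling proportional to pool abundance;
* ``dispersal_limitation`` — each farm first receives a restricted local
  species pool (a uniform-random fraction ``m`` of the metacommunity),
  shared by all of the farm's samples, then samples neutrally within it
  (high between-farm turnover at |βNTI| < 2).  Which taxa reach a farm is
  independent of their metacommunity abundance — that independence is what
  produces between-farm turnover.

``mixed`` assigns regimes per niche x health group: healthy groups assemble
under selection, unhealthy under drift, and the rhizosphere under dispersal
limitation, so one dataset exercises every classifier output.

Every sample realizes an exact target richness: taxa are drawn without
replacement proportional to the regime weights (Gumbel top-k), each drawn
taxon is guaranteed one read, and the remaining reads are multinomial.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import TreeNode

from .core_io import (
    CountTable,
    NICHES,
    Phylogeny,
    SampleMetadata,
    Taxonomy,
)

REGIMES = ("selection", "dispersal_limitation", "drift", "mixed")

PHYLUM_NAMES = (
    "Proteobacteria",
    "Actinobacteriota",
    "Acidobacteriota",
    "Bacteroidota",
    "Verrucomicrobiota",
    "Firmicutes",
    "Chloroflexi",
    "Planctomycetota",
    "Myxococcota",
    "Gemmatimonadota",
)


@dataclass
class SyntheticScenario:
    """Generative parameters of one synthetic study."""

    n_taxa: int = 600
    n_farms: int = 13
    niches: tuple[str, ...] = NICHES
    samples_per_group: int = 12
    regime: str | dict[str, str] = "mixed"
    trait_sigma: float = 1.0
    tree_depth_skew: float = 1.0
    trait_delta: float = 0.3
    selection_strength: float | None = None  # None -> 0.2 x realized trait sd
    migration: float = 0.2
    local_drift_sd: float = 2.0
    selection_baseline: float = 0.3
    richness_target: int = 110
    depth_mean: int = 5000
    depth_sigma: float = 0.3
    chem_noise_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_taxa < 2 or self.n_farms < 1 or self.samples_per_group < 1:
            raise ValueError("sizes must be >= 1 (n_taxa >= 2)")
        if not 0 < self.migration <= 1:
            raise ValueError("migration must be in (0, 1]")
        if self.richness_target < 1 or self.depth_mean < self.richness_target:
            raise ValueError("need depth_mean >= richness_target >= 1")
        regimes = (
            set(self.regime.values())
            if isinstance(self.regime, dict)
            else {self.regime}
        )
        unknown = regimes - set(REGIMES)
        if unknown:
            raise ValueError(f"unknown regime(s) {sorted(unknown)}")


@dataclass
class GroundTruth:
    regime_per_group: dict[str, str]
    traits: dict[str, float]
    env_per_sample: dict[str, float]
    env_per_farm: dict[str, float]
    local_pools: dict[str, list[str]]
    selection_strength: float
    pool_abundance: dict[str, float]


@dataclass
class SyntheticDataset:
    table: CountTable
    tree: Phylogeny
    metadata: SampleMetadata
    taxonomy: Taxonomy
    truth: GroundTruth


# ---------------------------------------------------------------------------
# tree and traits


def simulate_tree(n_taxa: int, seed: int, depth_skew: float = 1.0) -> Phylogeny:
    """Pure-birth (Yule) tree with exponential waiting times, depth rescaled
    to 1, leaves labelled T0001..Tnnnn.

    ``depth_skew`` < 1 applies a power transform to node depths
    (d -> d**depth_skew, still ultrametric with depth 1), concentrating
    branch length on deep internal edges — the "long stems, tight terminal
    fans" shape of real 16S gene trees.  1.0 leaves the Yule depths as
    simulated.
    """
    if n_taxa < 2:
        raise ValueError("n_taxa must be >= 2")
    if depth_skew <= 0:
        raise ValueError("depth_skew must be > 0")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x7EE]))
    root = TreeNode(name=None)
    t = 0.0
    tips: list[tuple[TreeNode, float]] = []  # (node, birth time)
    for _ in range(2):
        child = TreeNode(name=None)
        root.append(child)
        tips.append((child, 0.0))
    while len(tips) < n_taxa:
        t += rng.exponential(1.0 / len(tips))
        k = int(rng.integers(len(tips)))
        node, birth = tips.pop(k)
        node.length = t - birth
        for _ in range(2):
            child = TreeNode(name=None)
            node.append(child)
            tips.append((child, t))
    t_end = t + rng.exponential(1.0 / n_taxa)
    order = rng.permutation(len(tips))
    for label_i, tip_i in enumerate(order):
        node, birth = tips[tip_i]
        node.length = t_end - birth
        node.name = f"T{label_i + 1:04d}"
    root.length = None
    for node in root.traverse(include_self=False):
        node.length = node.length / t_end
    if depth_skew != 1.0:
        depths = {id(root): 0.0}
        for node in root.preorder(include_self=False):
            d0 = depths[id(node.parent)]
            d1 = d0 + node.length
            depths[id(node)] = d1
            node.length = d1**depth_skew - d0**depth_skew
    return Phylogeny(root)


def simulate_traits(
    tree: Phylogeny, sigma: float, seed: int, delta: float = 1.0
) -> dict[str, float]:
    """Brownian motion along branches: child = parent + N(0, sigma^2 * bl).

    ``delta`` applies a Pagel-delta depth transform before simulating:
    per-branch variance is proportional to depth_child**delta -
    depth_parent**delta.  delta < 1 concentrates trait change on deep
    branches, producing clade-level niche conservatism — the regime in which
    nearest-taxon phylogenetic metrics are informative about selection.
    delta = 1 is plain Brownian motion.
    """
    if sigma <= 0 or delta <= 0:
        raise ValueError("sigma and delta must be > 0")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x7A1]))
    values: dict[int, float] = {id(tree.tree): 0.0}
    depth: dict[int, float] = {id(tree.tree): 0.0}
    traits: dict[str, float] = {}
    for node in tree.tree.preorder(include_self=False):
        d0 = depth[id(node.parent)]
        d1 = d0 + max(node.length, 0.0)
        depth[id(node)] = d1
        var = max(d1**delta - d0**delta, 0.0)
        val = values[id(node.parent)] + rng.normal(0.0, sigma * np.sqrt(var))
        values[id(node)] = val
        if node.is_tip():
            traits[node.name] = float(val)
    return traits


# ---------------------------------------------------------------------------
# community assembly


def _weighted_subset(
    weights: np.ndarray, k: int, rng: np.random.Generator
) -> np.ndarray:
    """k indices drawn without replacement with probability proportional to
    weights (Gumbel top-k)."""
    with np.errstate(divide="ignore"):
        keys = np.log(weights) + rng.gumbel(size=weights.size)
    return np.argpartition(-keys, k - 1)[:k]


def assemble_community(
    regime: str,
    env: float,
    pool_abundance: np.ndarray,
    traits: np.ndarray,
    richness_target: int,
    depth: int,
    migration: float = 1.0,
    selection_strength: float = 1.0,
    local_pool: np.ndarray | None = None,
    local_weights: np.ndarray | None = None,
    selection_baseline: float = 0.3,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """One community (counts over the full taxon pool) under a regime.

    For ``dispersal_limitation`` a ``local_pool`` index array restricts the
    effective pool (drawn here if not supplied; in a full study it is drawn
    once per farm and shared by the farm's samples).
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    if depth < richness_target or richness_target < 1:
        raise ValueError("need depth >= richness_target >= 1")
    w = np.asarray(pool_abundance, dtype=float).copy()
    fill_w = None
    if regime == "selection":
        sel = np.exp(-((traits - env) ** 2) / (2.0 * selection_strength**2))
        if sel.sum() <= 0:
            raise ValueError("selection filter removed every taxon")
        # immigration controls who ARRIVES (draw weights); selection controls
        # who THRIVES (fill weights): maladapted immigrants occur but stay rare
        nu = selection_baseline
        neutral = w / w.sum()
        w = (1.0 - nu) * sel / sel.sum() + nu * neutral
        nu_fill = nu * nu
        fill_w = (1.0 - nu_fill) * sel / sel.sum() + nu_fill * neutral
    elif regime == "dispersal_limitation":
        if local_weights is not None:
            w = np.asarray(local_weights, dtype=float).copy()
        elif local_pool is not None or migration < 1.0:
            if local_pool is None:
                size = max(2, int(round(migration * w.size)))
                local_pool = rng.choice(w.size, size=size, replace=False)
            mask = np.zeros(w.size, dtype=bool)
            mask[local_pool] = True
            w[~mask] = 0.0
        # migration = 1 with no explicit pool: the whole metacommunity
        # disperses freely, identical to drift
    elif regime != "drift":
        raise ValueError(f"cannot assemble under regime {regime!r}")
    if w.sum() <= 0:
        raise ValueError("empty effective pool")
    n_avail = int((w > 0).sum())
    s = min(richness_target, n_avail, depth)
    idx = _weighted_subset(w, s, rng)
    if fill_w is None:
        fill_w = w
    p = fill_w[idx] / fill_w[idx].sum()
    counts = np.zeros(w.size, dtype=np.int64)
    counts[idx] = rng.multinomial(depth - s, p) + 1
    return counts


# ---------------------------------------------------------------------------
# full study

_MIXED_DEFAULT_RULES = (
    ("rhizosphere_soil", None, "dispersal_limitation"),
    (None, "healthy", "selection"),
    (None, "unhealthy", "drift"),
)


def _regime_for_group(scenario: SyntheticScenario, niche: str, health: str) -> str:
    group = f"{niche}/{health}"
    if isinstance(scenario.regime, dict):
        reg = scenario.regime.get(group, scenario.regime.get(niche, "drift"))
    else:
        reg = scenario.regime
    if reg != "mixed":
        return reg
    for n_rule, h_rule, out in _MIXED_DEFAULT_RULES:
        if (n_rule is None or n_rule == niche) and (h_rule is None or h_rule == health):
            return out
    return "drift"


def _phylum_assignment(tree: Phylogeny, max_clades: int = 8) -> dict[str, str]:
    """Assign phylum labels to the basal clades of the tree."""
    clades = [tree.tree]
    while len(clades) < max_clades:
        clades.sort(key=lambda c: -c.count(tips=True))
        big = clades.pop(0)
        kids = big.children
        if not kids:
            clades.append(big)
            break
        clades.extend(kids)
    out: dict[str, str] = {}
    for i, clade in enumerate(
        sorted(clades, key=lambda c: -c.count(tips=True))
    ):
        name = PHYLUM_NAMES[i % len(PHYLUM_NAMES)]
        for tip in clade.tips(include_self=True):
            out[tip.name] = name
    return out


def generate_dataset(scenario: SyntheticScenario) -> SyntheticDataset:
    """End-to-end synthetic study: tree, traits, farms, chemistry, communities."""
    sc = scenario
    tree = simulate_tree(sc.n_taxa, sc.seed, depth_skew=sc.tree_depth_skew)
    taxon_ids = sorted(tree.leaf_names())
    traits_map = simulate_traits(tree, sc.trait_sigma, sc.seed, delta=sc.trait_delta)
    traits = np.array([traits_map[t] for t in taxon_ids])
    trait_sd = float(traits.std(ddof=0))
    sel_sigma = (
        sc.selection_strength
        if sc.selection_strength is not None
        else 0.2 * trait_sd
    )

    rng = np.random.default_rng(np.random.SeedSequence([sc.seed, 0xDA7A]))
    pool_ab = np.sort(rng.lognormal(0.0, 1.0, sc.n_taxa))[::-1]
    pool_ab = pool_ab[rng.permutation(sc.n_taxa)]
    pool_ab /= pool_ab.sum()

    farms = [f"F{i + 1:02d}" for i in range(sc.n_farms)]
    farm_health = {
        f: ("healthy" if i % 2 == 0 else "unhealthy") for i, f in enumerate(farms)
    }
    # group-level environments sit at interior trait quantiles so that taxa
    # matching each environment exist in the pool
    env_health = {
        "healthy": float(np.quantile(traits, 0.35)),
        "unhealthy": float(np.quantile(traits, 0.65)),
    }
    farm_env = {
        f: env_health[farm_health[f]] + rng.normal(0.0, 0.05 * trait_sd)
        for f in farms
    }
    coords = {
        f: (50.0 + rng.uniform(-0.5, 0.5), 23.0 + rng.uniform(-0.5, 0.5))
        for f in farms
    }
    env_arr = np.array([farm_env[f] for f in farms])
    env_z = (env_arr - env_arr.mean()) / (env_arr.std(ddof=0) or 1.0)
    chem = {}
    for i, f in enumerate(farms):
        chem[f] = {
            "pH": round(6.5 + 0.5 * env_z[i] + rng.normal(0, sc.chem_noise_sd), 2),
            "Mg": round(12.0 + 3.0 * env_z[i] + rng.normal(0, 3 * sc.chem_noise_sd), 2),
            "P2O5": round(float(np.clip(rng.normal(15, 5), 1, None)), 2),
            "K2O": round(float(np.clip(rng.normal(18, 5), 1, None)), 2),
            "organic_carbon": round(float(np.clip(rng.normal(2.5, 0.7), 0.2, None)), 2),
        }
    local_size = max(2, int(round(sc.migration * sc.n_taxa)))
    local_pools = {
        f: rng.choice(sc.n_taxa, size=local_size, replace=False) for f in farms
    }
    # founder effects: within its local pool each farm re-draws relative
    # abundances around the metacommunity values (lognormal perturbation),
    # so farm dominants are farm-specific
    farm_weights = {}
    for f in farms:
        w = np.zeros(sc.n_taxa)
        idx = local_pools[f]
        w[idx] = pool_ab[idx] * rng.lognormal(0.0, sc.local_drift_sd, idx.size)
        farm_weights[f] = w / w.sum()

    regime_per_group: dict[str, str] = {}
    meta_rows = []
    columns = []
    sample_ids = []
    counter = 0
    for niche in sc.niches:
        for health in ("healthy", "unhealthy"):
            group = f"{niche}/{health}"
            regime = _regime_for_group(sc, niche, health)
            regime_per_group[group] = regime
            group_farms = [f for f in farms if farm_health[f] == health]
            if not group_farms:
                continue
            for k in range(sc.samples_per_group):
                farm = group_farms[k % len(group_farms)]
                counter += 1
                sid = f"S{counter:04d}"
                depth = max(
                    sc.richness_target + 1,
                    int(rng.lognormal(np.log(sc.depth_mean), sc.depth_sigma)),
                )
                counts = assemble_community(
                    regime,
                    farm_env[farm],
                    pool_ab,
                    traits,
                    sc.richness_target,
                    depth,
                    migration=sc.migration,
                    selection_strength=sel_sigma,
                    local_pool=local_pools[farm],
                    local_weights=(
                        farm_weights[farm]
                        if regime == "dispersal_limitation"
                        else None
                    ),
                    selection_baseline=sc.selection_baseline,
                    rng=rng,
                )
                sample_ids.append(sid)
                columns.append(counts)
                meta_rows.append(
                    {
                        "sample_id": sid,
                        "farm_id": farm,
                        "niche": niche,
                        "health": health,
                        "latitude": round(coords[farm][0], 5),
                        "longitude": round(coords[farm][1], 5),
                        **chem[farm],
                    }
                )
    table = CountTable(taxon_ids, sample_ids, np.column_stack(columns))
    metadata = SampleMetadata(pd.DataFrame(meta_rows))
    phyla = _phylum_assignment(tree)
    taxonomy: Taxonomy = {
        t: ["Bacteria", phyla[t], "unclassified", "unclassified",
            "unclassified", "unclassified", "unclassified"]
        for t in taxon_ids
    }
    env_per_sample = {
        r["sample_id"]: farm_env[r["farm_id"]] for r in meta_rows
    }
    truth = GroundTruth(
        regime_per_group=regime_per_group,
        traits={t: float(v) for t, v in zip(taxon_ids, traits)},
        env_per_sample=env_per_sample,
        env_per_farm=dict(farm_env),
        local_pools={f: [taxon_ids[i] for i in idx] for f, idx in local_pools.items()},
        selection_strength=float(sel_sigma),
        pool_abundance={t: float(a) for t, a in zip(taxon_ids, pool_ab)},
    )
    return SyntheticDataset(table, tree, metadata, taxonomy, truth)
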