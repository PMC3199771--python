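"""Seeded generator of complete synthetic datasets.

Emulates the statistical structure of a species-level island radiation so the
whole pipeline can run and be validated without external data: a birth-death
tree of ~250 tips rescaled to a crown age of 44 Ma, right-skewed body-size
(SVL) and range-size distributions with a positive log-log association,
range centroids diffusing over a ~1600 x 600 km rectangular domain (young
sister species therefore sit close together), localities sampled inside each
species' true range disc, and per-locality climate variables that vary
smoothly in space.  A companion phylogram with lognormal rate variation
stands in for the pre-ultrametric tree whose branch lengths feed the contrast
denominators.

A single seed expands into named substreams (tree / rates / traits / space /
climate / support) so one component's draw count never shifts another's.
Every generated quantity that a recovery test might score is written into the
``truth`` ledger.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .phylo_io import PhyloTree

__all__ = ["SynthConfig", "SynthDataset", "simulate_tree",
           "simulate_traits_and_ranges", "generate_dataset", "make_fixture",
           "simulate_cherries", "write_dataset"]

_STREAMS = ("tree", "rates", "traits", "space", "climate", "support")


@dataclass
class SynthConfig:
    """Generator settings; defaults are the study conditions the pipeline
    is validated under (sizes and magnitudes of the mantellid-like radiation).
    """

    seed: int = 0
    n_tips: int = 250
    birth: float = 1.0                  # per-lineage speciation rate (pre-rescale)
    death: float = 0.6                  # extinction rate; 0 <= death < birth
    gamma: float = 0.0                  # trait effect: lambda_i = birth*exp(-gamma*x_i)
    sigma2_tree_trait: float = 0.5      # BM rate of the in-simulation trait (gamma runs)
    root_height_ma: float | None = 44.0  # rescale crown age to this (None = raw)
    # body size: log10 SVL in mm
    root_log_svl: float = math.log10(30.0)
    sigma2_log_svl: float = 0.003       # per Ma, on log10 scale
    # range size: log10 area in km2
    beta: float = 2.0                   # slope of log-range on log-SVL
    intercept_log_range: float = -0.8
    sigma2_log_range: float = 0.02      # BM deviation rate, per Ma
    noise_log_range: float = 0.3        # iid lognormal noise, log10 SD
    # space
    diffusion_km2_per_ma: float = 100.0  # per-axis BM variance rate of centroids
    domain_km: tuple[float, float] = (1600.0, 600.0)
    mean_extra_localities: float = 4.0   # localities per species ~ 1 + Poisson(mu)
    # climate
    n_climate_vars: int = 21
    climate_noise_sd: float = 0.3
    # phylogram (pre-ultrametric branch lengths)
    subst_rate_per_ma: float = 0.005     # substitutions/site/Ma
    rate_lognorm_sd: float = 0.3
    # support degradation for testing the support filter
    support_degrade_frac: float = 0.0


@dataclass
class SynthDataset:
    tree_time: PhyloTree            # ultrametric timetree (Ma)
    tree_subst: PhyloTree           # same topology, substitutions/site lengths
    traits: pd.DataFrame            # species, svl_mm
    localities: pd.DataFrame        # species, x, y (meters)
    climate: pd.DataFrame           # species + climate columns, one row/locality
    truth: dict = field(default_factory=dict)


def _rngs(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(_STREAMS))
    return {name: np.random.default_rng(ss) for name, ss in zip(_STREAMS, children)}


# --------------------------------------------------------------------------
# tree simulation
# --------------------------------------------------------------------------


class _Lineage:
    __slots__ = ("start", "end", "fate", "node", "trait", "children")

    def __init__(self, start: float, trait: float):
        self.start = start
        self.end: float | None = None
        self.fate: str | None = None      # "tip" | "extinct" | "split"
        self.trait = trait
        self.children: list["_Lineage"] = []


def _simulate_crown(rng: np.random.Generator, cfg: SynthConfig):
    """One attempt at a crown birth-death simulation stopped at n_tips extant
    lineages.  Returns (root_children, present_time) or None on extinction."""
    left = _Lineage(0.0, 0.0)
    right = _Lineage(0.0, 0.0)
    active = [left, right]
    t = 0.0
    trait_on = cfg.gamma != 0.0
    sigma_tree = math.sqrt(cfg.sigma2_tree_trait)
    while active:
        n = len(active)
        if n == cfg.n_tips:
            break
        if trait_on:
            lam = cfg.birth * np.exp(-cfg.gamma * np.array([l.trait for l in active]))
        else:
            lam = np.full(n, cfg.birth)
        total = lam.sum() + cfg.death * n
        dt = rng.exponential(1.0 / total)
        t += dt
        if trait_on:
            steps = rng.normal(0.0, sigma_tree * math.sqrt(dt), size=n)
            for lin, s in zip(active, steps):
                lin.trait += s
        u = rng.uniform(0.0, total)
        if u < lam.sum():
            idx = int(np.searchsorted(np.cumsum(lam), u))
            lin = active.pop(idx)
            lin.end, lin.fate = t, "split"
            lin.children = [_Lineage(t, lin.trait), _Lineage(t, lin.trait)]
            active.extend(lin.children)
        else:
            idx = rng.integers(0, n)
            lin = active.pop(idx)
            lin.end, lin.fate = t, "extinct"
    else:
        return None
    # Extend the present uniformly into the waiting time during which exactly
    # n_tips lineages exist, so the final split does not sit at age zero.
    n = len(active)
    if trait_on:
        lam = cfg.birth * np.exp(-cfg.gamma * np.array([l.trait for l in active]))
    else:
        lam = np.full(n, cfg.birth)
    total = lam.sum() + cfg.death * n
    dt = rng.exponential(1.0 / total) * rng.uniform()
    t += dt
    if trait_on:
        steps = rng.normal(0.0, sigma_tree * math.sqrt(dt), size=n)
        for lin, s in zip(active, steps):
            lin.trait += s
    for lin in active:
        lin.end, lin.fate = t, "tip"
    return (left, right), t


def _prune(lin: _Lineage):
    """Reconstructed (extinct-pruned) subtree below a lineage.

    Returns ``None`` if nothing survives, else ``(length, payload)`` where
    payload is a tip marker or a (left, right) pair of pruned subtrees.
    """
    length = lin.end - lin.start
    if lin.fate == "tip":
        return length, ("tip", lin)
    if lin.fate == "extinct":
        return None
    kids = [p for p in (_prune(c) for c in lin.children) if p is not None]
    if not kids:
        return None
    if len(kids) == 1:  # suppress the unifurcation
        sub_len, payload = kids[0]
        return length + sub_len, payload
    return length, ("node", lin.end, kids)


def simulate_tree(config: SynthConfig, rng: np.random.Generator | None = None,
                  max_tries: int = 200):
    """Birth-death timetree conditioned on ``n_tips`` extant species.

    Crown simulation stopped at the moment the ``n_tips``-th lineage appears;
    whole-radiation extinction triggers a retry on the same stream (logged in
    the truth ledger as ``n_tries``).  With ``gamma != 0`` a Brownian trait
    evolves along lineages and modulates speciation as
    ``lambda_i = birth * exp(-gamma * x_i)``, so small-trait lineages speciate
    faster; the tip values are returned in the truth ledger.  Node times are
    rescaled so the crown age equals ``root_height_ma`` (unless ``None``).

    Returns ``(PhyloTree, truth_dict)``.
    """
    if not 0 <= config.death < config.birth:
        raise ValueError("need 0 <= death < birth")
    if config.n_tips < 2:
        raise ValueError("need n_tips >= 2")
    rng = rng or _rngs(config.seed)["tree"]
    for attempt in range(1, max_tries + 1):
        sim = _simulate_crown(rng, config)
        if sim is None:
            continue
        (left, right), present = sim
        pl, pr = _prune(left), _prune(right)
        if pl is None or pr is None:
            # one crown lineage died: the reconstructed crown is younger than
            # the simulated one; retry so the stated crown age is exact
            continue
        scale = 1.0
        if config.root_height_ma is not None:
            scale = config.root_height_ma / present
        counter = {"i": 0}
        tip_traits: dict[str, float] = {}
        node_ages: list[float] = []

        def render(sub) -> str:
            length, payload = sub
            bl = length * scale
            if payload[0] == "tip":
                counter["i"] += 1
                name = f"sp{counter['i']:04d}"
                tip_traits[name] = payload[1].trait
                return f"{name}:{bl:.17g}"
            _, end_time, kids = payload
            node_ages.append((present - end_time) * scale)
            inner = ",".join(render(k) for k in kids)
            return f"({inner})100:{bl:.17g}"

        newick = f"({render(pl)},{render(pr)})100;"
        node_ages.append(present * scale)  # crown node
        tree = PhyloTree.from_string(newick)
        truth = {
            "height": present * scale,
            "node_ages": sorted(node_ages),
            "n_tries": attempt,
            "gamma": config.gamma,
            "tip_traits_sim": tip_traits if config.gamma != 0.0 else {},
        }
        return tree, truth
    raise RuntimeError(f"radiation went extinct in {max_tries} attempts")


def degrade_supports(tree: PhyloTree, frac: float, rng: np.random.Generator) -> None:
    """Assign random supports in [50, 100] to a fraction of internal nodes."""
    internal = [n for n in tree.nodes() if not n.is_leaf()]
    n_pick = int(round(frac * len(internal)))
    idx = rng.choice(len(internal), size=n_pick, replace=False)
    for i in idx:
        internal[i].support = float(rng.uniform(50.0, 100.0))


# --------------------------------------------------------------------------
# traits, ranges, space, climate
# --------------------------------------------------------------------------


def _bm_on_tree(tree: PhyloTree, root_value, sigma2: float,
                rng: np.random.Generator, ndim: int = 1) -> dict:
    """Brownian values at every node, preorder from the root."""
    values = {}
    for node in tree.nodes():
        if node.parent_node is None:
            values[node] = np.array(root_value, float, ndmin=1)[:ndim].copy() \
                if ndim > 1 else float(root_value)
            continue
        bl = max(node.edge.length or 0.0, 0.0)
        sd = math.sqrt(sigma2 * bl)
        if ndim == 1:
            values[node] = values[node.parent_node] + rng.normal(0.0, sd)
        else:
            values[node] = values[node.parent_node] + rng.normal(0.0, sd, size=ndim)
    return values


def simulate_traits_and_ranges(tree: PhyloTree, config: SynthConfig,
                               rng_traits: np.random.Generator,
                               rng_space: np.random.Generator):
    """Simulate SVL, range areas, centroids and localities on a timetree.

    log10-SVL evolves by Brownian motion; log10 range area is
    ``intercept + beta * log10(SVL) + BM deviation + noise``; range centroids
    follow 2-D Brownian diffusion clipped to the rectangular domain; the true
    range is a disc of the drawn area around the centroid and localities are
    sampled uniformly inside it.

    Returns ``(traits, localities, truth)``; locality coordinates in meters.
    """
    tips = tree.tips()
    log_svl_nodes = _bm_on_tree(tree, config.root_log_svl, config.sigma2_log_svl,
                                rng_traits)
    dev_nodes = _bm_on_tree(tree, 0.0, config.sigma2_log_range, rng_traits)
    names = [t.taxon.label for t in tips]
    log_svl = np.array([log_svl_nodes[t] for t in tips])
    noise = rng_traits.normal(0.0, config.noise_log_range, size=len(tips))
    log_range = (config.intercept_log_range + config.beta * log_svl
                 + np.array([dev_nodes[t] for t in tips]) + noise)

    Lx, Ly = config.domain_km
    centre = np.array([Lx / 2.0, Ly / 2.0])
    cent_nodes = _bm_on_tree(tree, centre, config.diffusion_km2_per_ma,
                             rng_space, ndim=2)
    centroids = {}
    loc_rows = []
    for tip, name, lr in zip(tips, names, log_range):
        c = np.clip(cent_nodes[tip], [0.0, 0.0], [Lx, Ly])
        centroids[name] = c
        radius_km = math.sqrt(10.0 ** lr / math.pi)
        n_loc = 1 + rng_space.poisson(config.mean_extra_localities)
        r = radius_km * np.sqrt(rng_space.uniform(size=n_loc))
        theta = rng_space.uniform(0.0, 2.0 * math.pi, size=n_loc)
        xs = (c[0] + r * np.cos(theta)) * 1e3
        ys = (c[1] + r * np.sin(theta)) * 1e3
        for x, y in zip(xs, ys):
            loc_rows.append({"species": name, "x": x, "y": y})

    traits = pd.DataFrame({"species": names, "svl_mm": 10.0 ** log_svl})
    localities = pd.DataFrame(loc_rows)
    truth = {
        "sigma2_log_svl": config.sigma2_log_svl,
        "beta": config.beta,
        "log_svl": dict(zip(names, map(float, log_svl))),
        "log_range_km2": dict(zip(names, map(float, log_range))),
        "centroids_km": {k: [float(v[0]), float(v[1])] for k, v in centroids.items()},
    }
    return traits, localities, truth


def simulate_climate(localities: pd.DataFrame, config: SynthConfig,
                     rng: np.random.Generator) -> pd.DataFrame:
    """Fabricate per-locality climate columns as smooth random fields of (x, y)
    plus noise, so spatially proximate species get similar climates."""
    Lx, Ly = config.domain_km
    x = localities["x"].to_numpy(float) / 1e3 / Lx
    y = localities["y"].to_numpy(float) / 1e3 / Ly
    cols = {"species": localities["species"].to_numpy()}
    for j in range(config.n_climate_vars):
        a, b = rng.normal(0.0, 1.0, size=2)
        c = rng.normal(0.0, 0.8)
        freq = rng.uniform(0.5, 2.5)
        phase = rng.uniform(0.0, 2.0 * math.pi)
        scale = 10.0 ** rng.uniform(0.0, 2.0)
        offset = rng.normal(0.0, 5.0) * scale
        base = a * x + b * y + c * np.sin(2.0 * math.pi * freq * x + phase)
        eps = rng.normal(0.0, config.climate_noise_sd, size=x.size)
        cols[f"clim{j + 1:02d}"] = offset + scale * (base + eps)
    return pd.DataFrame(cols)


def _make_phylogram(tree_time: PhyloTree, config: SynthConfig,
                    rng: np.random.Generator) -> PhyloTree:
    """Same topology with branch lengths in substitutions/site: Ma length times
    a lognormally varying per-branch rate."""
    newick = tree_time.to_newick()
    tree = PhyloTree.from_string(newick)
    mu = math.log(config.subst_rate_per_ma)
    for node in tree.nodes():
        if node.parent_node is None:
            continue
        rate = rng.lognormal(mu, config.rate_lognorm_sd)
        node.edge.length = max((node.edge.length or 0.0) * rate, 1e-9)
    return PhyloTree(tree._tree)


def generate_dataset(config: SynthConfig | None = None) -> SynthDataset:
    """Full synthetic dataset under one seed: timetree, phylogram, traits,
    localities, climate, plus the ground-truth ledger."""
    config = config or SynthConfig()
    rngs = _rngs(config.seed)
    tree_time, tree_truth = simulate_tree(config, rngs["tree"])
    if config.support_degrade_frac > 0:
        degrade_supports(tree_time, config.support_degrade_frac, rngs["support"])
    tree_subst = _make_phylogram(tree_time, config, rngs["rates"])
    if config.support_degrade_frac > 0:
        # mirror the degraded supports onto the phylogram (same topology order)
        for a, b in zip(tree_time.nodes(), tree_subst.nodes()):
            if not a.is_leaf():
                b.support = a.support
    traits, localities, tr_truth = simulate_traits_and_ranges(
        tree_time, config, rngs["traits"], rngs["space"])
    climate = simulate_climate(localities, config, rngs["climate"])
    truth = {"config": asdict(config), **tree_truth, **tr_truth}
    return SynthDataset(tree_time=tree_time, tree_subst=tree_subst,
                        traits=traits, localities=localities,
                        climate=climate, truth=truth)


def simulate_cherries(n_pairs: int, sigma2: float,
                      rng: np.random.Generator) -> pd.DataFrame:
    """Independent sister pairs with Brownian traits, for contrast calibration.

    Branch lengths are drawn Uniform(0.2, 2.0) per tip; each tip trait is the
    shared ancestral value plus N(0, sigma2 * bl).  The standardized contrast
    of each pair then has variance exactly sigma2.
    """
    bl1 = rng.uniform(0.2, 2.0, size=n_pairs)
    bl2 = rng.uniform(0.2, 2.0, size=n_pairs)
    root = rng.normal(0.0, 1.0, size=n_pairs)
    x1 = root + rng.normal(0.0, np.sqrt(sigma2 * bl1))
    x2 = root + rng.normal(0.0, np.sqrt(sigma2 * bl2))
    return pd.DataFrame({"x1": x1, "x2": x2, "bl1": bl1, "bl2": bl2})


# --------------------------------------------------------------------------
# deterministic toy fixture
# --------------------------------------------------------------------------

_FIXTURE_TIME_NEWICK = (
    "(((sp1:1,sp2:1)100:15,(sp3:3,sp4:3)100:13)100:9,"
    "((sp5:7,sp6:7)100:13,(sp7:12,sp8:12)100:8)100:5)100;"
)
_FIXTURE_SUBST_NEWICK = (
    "(((sp1:0.5,sp2:0.5)100:0.1,(sp3:0.3,sp4:0.7)100:0.1)100:0.1,"
    "((sp5:1.0,sp6:1.0)100:0.1,(sp7:0.8,sp8:0.2)100:0.1)100:0.1)100;"
)
_FIXTURE_SVL = {"sp1": 12.0, "sp2": 14.0, "sp3": 25.0, "sp4": 28.0,
                "sp5": 40.0, "sp6": 45.0, "sp7": 90.0, "sp8": 100.0}
# Square ranges (km) as 4 corner localities each; constructed overlaps:
# (sp1,sp2) 0%, (sp3,sp4) 0%, (sp5,sp6) 30%, (sp7,sp8) 100%.
_FIXTURE_SQUARES = {
    "sp1": (0.0, 10.0, 0.0, 10.0),
    "sp2": (20.0, 30.0, 0.0, 10.0),
    "sp3": (0.0, 10.0, 20.0, 30.0),
    "sp4": (20.0, 30.0, 20.0, 30.0),
    "sp5": (40.0, 50.0, 0.0, 10.0),
    "sp6": (47.0, 57.0, 0.0, 10.0),
    "sp7": (40.0, 60.0, 20.0, 40.0),
    "sp8": (45.0, 55.0, 25.0, 35.0),
}


def make_fixture() -> SynthDataset:
    """Hand-built deterministic 8-species dataset with 4 sister pairs.

    Pair ages are (1, 3, 7, 12) Ma; square ranges give pairwise overlaps of
    exactly (0, 0, 30, 100) percent, so classification yields 2 allopatric and
    2 sympatric pairs.  Rebuilt bit-identically from these constants on every
    call — it is synthetic throughout, standing in for field data.
    """
    tree_time = PhyloTree.from_string(_FIXTURE_TIME_NEWICK)
    tree_subst = PhyloTree.from_string(_FIXTURE_SUBST_NEWICK)
    traits = pd.DataFrame(
        {"species": list(_FIXTURE_SVL), "svl_mm": list(_FIXTURE_SVL.values())}
    )
    rows = []
    for sp, (x0, x1, y0, y1) in _FIXTURE_SQUARES.items():
        for x, y in ((x0, y0), (x1, y0), (x1, y1), (x0, y1)):
            rows.append({"species": sp, "x": x * 1e3, "y": y * 1e3})
    localities = pd.DataFrame(rows)
    clim = {"species": localities["species"].to_numpy()}
    xs = localities["x"].to_numpy() / 1e3
    ys = localities["y"].to_numpy() / 1e3
    for j in range(1, 7):
        clim[f"clim{j:02d}"] = (j * xs / 60.0 + (7 - j) * ys / 40.0
                                + 3.0 * np.sin(j + xs / 10.0))
    truth = {
        "pair_ages": {"sp1|sp2": 1.0, "sp3|sp4": 3.0,
                      "sp5|sp6": 7.0, "sp7|sp8": 12.0},
        "pair_overlap_pct": {"sp1|sp2": 0.0, "sp3|sp4": 0.0,
                             "sp5|sp6": 30.0, "sp7|sp8": 100.0},
    }
    return SynthDataset(tree_time=tree_time, tree_subst=tree_subst,
                        traits=traits, localities=localities,
                        climate=pd.DataFrame(clim), truth=truth)


def write_dataset(ds: SynthDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write a dataset in the exact formats the pipeline reads."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "tree_time": out / "tree_time.nwk",
        "tree_subst": out / "tree_subst.nwk",
        "traits": out / "traits.csv",
        "localities": out / "localities.csv",
        "climate": out / "climate.csv",
        "truth": out / "truth.json",
    }
    ds.tree_time.write(paths["tree_time"])
    ds.tree_subst.write(paths["tree_subst"])
    ds.traits.to_csv(paths["traits"], index=False)
    ds.localities.to_csv(paths["localities"], index=False)
    ds.climate.to_csv(paths["climate"], index=False)
    paths["truth"].write_text(json.dumps(ds.truth, sort_keys=True, indent=1,
                                         default=float))
    return paths
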