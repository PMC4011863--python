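"""Synthetic trees, traits and locality tables.

The generator emulates the structure of the compiled study data so every
analysis stage runs end-to-end with no external download: a 16-tip
ultrametric tree of ~150 Myr depth, developmental traits evolving under
BM / OU / lambda models, a correlated trait pair with phylogenetically
structured residuals (hatching time regressed on larval period), genome
size present for only 8 of 16 species, and per-species locality tables
with 3-322 records and within-species climate dispersion.

Seed discipline: a single integer master seed is expanded through
``numpy.random.SeedSequence.spawn`` into one child stream per stage, in
the fixed order (tree, developmental traits, climate means, localities,
planted-vetting noise), so any stage can be regenerated independently and
every output is bit-reproducible for a fixed seed and version.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from .tree import PhyloCov, TimeTree, lambda_scale, ou_scale, phylo_covariance

__all__ = [
    "sim_yule_tree",
    "sim_trait",
    "sim_regression_pair",
    "make_study_fixture",
    "StudyFixture",
]


def sim_yule_tree(
    n_tips: int, depth: float, seed, birth_rate: float = 1.0
) -> TimeTree:
    """Pure-birth (Yule) tree rescaled to an exact root-to-tip depth.

    Waiting times between splits are exponential with rate ``k * birth_rate``
    for ``k`` extant lineages, starting from the crown (two lineages); after
    the last split a final exponential waiting time sets the present.  All
    node times are then rescaled so the depth equals ``depth`` exactly, so
    the tree is ultrametric by construction.  Deterministic given ``seed``.
    """
    if n_tips < 3:
        raise ValueError("n_tips must be >= 3")
    if depth <= 0:
        raise ValueError("depth must be > 0")
    rng = np.random.default_rng(seed)
    tns = dendropy.TaxonNamespace()
    dtree = dendropy.Tree(taxon_namespace=tns)
    dtree.is_rooted = True
    root = dtree.seed_node
    active: list[tuple[dendropy.Node, float]] = []
    for _ in range(2):
        child = dendropy.Node()
        root.add_child(child)
        active.append((child, 0.0))
    t = 0.0
    while len(active) < n_tips:
        k = len(active)
        t += rng.exponential(1.0 / (k * birth_rate))
        node, born = active.pop(int(rng.integers(k)))
        node.edge.length = t - born
        for _ in range(2):
            child = dendropy.Node()
            node.add_child(child)
            active.append((child, t))
    t_end = t + rng.exponential(1.0 / (n_tips * birth_rate))
    for node, born in active:
        node.edge.length = t_end - born
    scale = depth / t_end
    for node in dtree.preorder_node_iter():
        if node.parent_node is not None:
            node.edge.length *= scale
    width = max(2, len(str(n_tips)))
    for i, leaf in enumerate(dtree.leaf_node_iter()):
        leaf.taxon = tns.new_taxon(f"sp{i + 1:0{width}d}")
    return TimeTree(dtree)


def _model_cov(tree: TimeTree, model: str, shape: float | None) -> PhyloCov:
    model = model.upper()
    if model == "BM":
        return phylo_covariance(tree)
    if model == "LAMBDA":
        if shape is None:
            raise ValueError("LAMBDA model needs shape = lambda")
        return lambda_scale(phylo_covariance(tree), shape)
    if model == "OU":
        if shape is None:
            raise ValueError("OU model needs shape = alpha")
        return ou_scale(tree, shape)
    raise ValueError(f"unknown model {model!r}")


def sim_trait(
    tree: TimeTree,
    model: str = "BM",
    sigma2: float = 1.0,
    shape: float | None = None,
    mu: float = 0.0,
    seed=None,
) -> pd.Series:
    """One multivariate-normal trait draw on the tree.

    Covariance is ``sigma2`` times the model's tip covariance; the draw is
    ``mu + sqrt(sigma2) L z`` with ``L`` a Cholesky factor of the (jittered)
    covariance shape.  ``sigma2 = 0`` returns the constant ``mu``.
    """
    if sigma2 < 0:
        raise ValueError("sigma2 must be >= 0")
    cov = _model_cov(tree, model, shape)
    if sigma2 == 0.0:
        return pd.Series(np.full(cov.n, mu), index=cov.tip_order)
    rng = np.random.default_rng(seed)
    V = cov.V + 1e-12 * np.trace(cov.V) / cov.n * np.eye(cov.n)
    L = np.linalg.cholesky(V)
    vals = mu + np.sqrt(sigma2) * (L @ rng.standard_normal(cov.n))
    return pd.Series(vals, index=cov.tip_order)


def sim_regression_pair(
    tree: TimeTree,
    beta0: float,
    beta1: float,
    resid_lambda: float,
    sigma2: float,
    seed,
    x_sigma2: float = 1.0,
    x_mu: float = 0.0,
) -> tuple[pd.Series, pd.Series]:
    """A predictor/response pair with phylogenetically structured residuals.

    ``x`` is a BM trait; ``y = beta0 + beta1 x + e`` with ``e`` drawn under
    the lambda-scaled covariance at ``resid_lambda`` times ``sigma2``.
    ``beta1 = 0`` gives the phylogenetic null.
    """
    ss = np.random.SeedSequence(seed) if not isinstance(seed, np.random.SeedSequence) else seed
    s_x, s_e = ss.spawn(2)
    x = sim_trait(tree, "BM", x_sigma2, mu=x_mu, seed=s_x)
    eps = sim_trait(tree, "LAMBDA", sigma2, shape=resid_lambda, seed=s_e)
    y = beta0 + beta1 * x + eps
    return x, y


@dataclass
class StudyFixture:
    """A complete synthetic study data set (tree + traits + localities)."""

    tree: TimeTree
    traits: pd.DataFrame
    localities: pd.DataFrame
    manifest: dict = field(default_factory=dict)


# Species-level climate parameters: (BM root mean, BM rate per Myr).  The
# rates put cross-species spreads in realistic bioclim ranges on a 150-Myr
# tree (e.g. annual precipitation sd ~ 250 mm, monthly temperature extremes
# sd ~ 3-4 deg C).
_CLIMATE_BM = {
    "bio12": (600.0, 417.0),
    "bio15": (45.0, 2.5),
    "bio5": (32.0, 0.06),
    "bio6": (-2.0, 0.107),
}
#: Within-species locality dispersion (sd) per variable.
_CLIMATE_DISPERSION = {
    "bio5": 1.5,
    "bio6": 1.5,
    "bio10": 1.5,
    "bio11": 1.5,
    "bio12": 60.0,
    "bio15": 5.0,
    "bio16": 30.0,
}


def make_study_fixture(
    seed,
    out_dir: str | Path | None = None,
    n_tips: int = 16,
    depth: float = 150.0,
    plant_beta0: float = 2.0,
    plant_beta1: float = 1.0,
    plant_resid_lambda: float = 0.6,
    plant_resid_sigma2: float = 0.6,
    min_localities: int = 3,
    max_localities: int = 322,
) -> StudyFixture:
    """Generate the full synthetic study data set.

    The planted regression links minimum hatching time to minimum larval
    period (``plant_*`` parameters); genome size is generated as a linear
    function of midpoint larval period plus high-lambda residuals and masked
    to 8 of 16 species, mirroring the study's coverage.  If ``out_dir`` is
    given, writes ``tree.nwk``, ``traits.csv``, ``localities.csv`` and a
    ``manifest.json`` recording the generation parameters and seed.
    """
    from .tree import write_newick

    master = np.random.SeedSequence(seed)
    ss_tree, ss_traits, ss_clim, ss_loc, ss_vet = master.spawn(5)

    tree = sim_yule_tree(n_tips, depth, ss_tree)
    species = list(tree.tips)

    # --- developmental traits -------------------------------------------
    tr = np.random.default_rng(ss_traits)
    ss_pair, ss_genome = ss_traits.spawn(2)
    min_lp, min_ht = sim_regression_pair(
        tree,
        beta0=plant_beta0,
        beta1=plant_beta1,
        resid_lambda=plant_resid_lambda,
        sigma2=plant_resid_sigma2,
        seed=ss_pair,
        x_sigma2=1.0,
        x_mu=35.0,
    )
    min_lp = min_lp.clip(lower=5.0)
    min_ht = min_ht.clip(lower=0.5)
    mid_lp = min_lp + 12.0 + np.abs(tr.normal(0.0, 4.0, n_tips))
    mid_ht = min_ht + 4.0 + np.abs(tr.normal(0.0, 1.5, n_tips))
    genome_resid = sim_trait(
        tree, "LAMBDA", sigma2=0.004, shape=0.95, seed=ss_genome
    )
    genome = (2.5 + 0.08 * (mid_lp - float(mid_lp.mean())) + genome_resid).clip(lower=0.5)
    n_genome = min(8, n_tips)
    with_genome = set(tr.choice(species, size=n_genome, replace=False))
    genome = genome.where(genome.index.isin(with_genome))
    lp_matched = min_lp + tr.normal(0.0, 2.0, n_tips)

    # --- species-level climate means (BM on the tree) -------------------
    clim_children = ss_clim.spawn(len(_CLIMATE_BM) + 1)
    cr = np.random.default_rng(clim_children[-1])
    clim_mean = {}
    for (var, (mu0, rate)), child in zip(_CLIMATE_BM.items(), clim_children):
        clim_mean[var] = sim_trait(tree, "BM", rate, mu=mu0, seed=child)
    clim_mean["bio12"] = clim_mean["bio12"].clip(lower=50.0)
    clim_mean["bio15"] = clim_mean["bio15"].clip(lower=5.0, upper=120.0)
    clim_mean["bio16"] = (0.35 * clim_mean["bio12"] + cr.normal(0, 20, n_tips)).clip(
        lower=20.0
    )
    clim_mean["bio16"] = np.minimum(clim_mean["bio16"], clim_mean["bio12"])
    clim_mean["bio10"] = clim_mean["bio5"] - 7.0 + cr.normal(0, 1, n_tips)
    clim_mean["bio11"] = clim_mean["bio6"] + 6.0 + cr.normal(0, 1, n_tips)

    # --- locality tables ------------------------------------------------
    lr = np.random.default_rng(ss_loc)
    vr = np.random.default_rng(ss_vet)
    counts = lr.integers(min_localities, max_localities + 1, size=n_tips)
    loc_rows = []
    for sp, n_loc in zip(species, counts):
        lon0 = lr.uniform(-120, 120)
        lat0 = lr.uniform(30, 50)
        elev0 = lr.uniform(100, 1800)
        for _ in range(int(n_loc)):
            rec = {
                "species": sp,
                "lon": float(np.clip(lon0 + lr.normal(0, 1.5), -180, 180)),
                "lat": float(np.clip(lat0 + lr.normal(0, 1.5), -90, 90)),
                "elevation": float(max(0.0, elev0 + lr.normal(0, 200))),
                "in_range": True,
            }
            for var in ("bio5", "bio6", "bio10", "bio11", "bio12", "bio15", "bio16"):
                rec[var] = float(
                    clim_mean[var][sp] + lr.normal(0, _CLIMATE_DISPERSION[var])
                )
            rec["bio12"] = max(rec["bio12"], 0.0)
            rec["bio16"] = max(min(rec["bio16"], rec["bio12"]), 0.0)
            # keep temperatures physically ordered and Q well defined
            rec["bio6"] = min(rec["bio6"], rec["bio5"] - 1.0)
            rec["bio6"] = max(rec["bio6"], -rec["bio5"] + 2.5)
            rec["bio11"] = min(rec["bio11"], rec["bio10"] - 1.0)
            rec["bio11"] = max(rec["bio11"], -rec["bio10"] + 2.5)
            loc_rows.append(rec)
    localities = pd.DataFrame(loc_rows)

    # plant vetting work for species with enough records: a duplicated
    # coordinate, an out-of-range flag and an elevation outlier each
    for sp in species:
        idx = localities.index[localities["species"] == sp]
        if len(idx) < 10:
            continue
        dup = localities.loc[[idx[0]]].copy()
        localities = pd.concat([localities, dup], ignore_index=True)
        localities.loc[idx[1], "in_range"] = False
        localities.loc[idx[2], "elevation"] = 3500.0 + float(vr.uniform(0, 500))

    # matched-locality columns: climate from the single driest sampled
    # locality per species
    driest = localities.groupby("species")["bio12"].min()
    precip_matched = driest.reindex(species)

    traits = pd.DataFrame(
        {
            "species": species,
            "midpoint_larval_period": mid_lp.to_numpy(),
            "minimum_larval_period": min_lp.to_numpy(),
            "midpoint_hatching_time": mid_ht.to_numpy(),
            "minimum_hatching_time": min_ht.to_numpy(),
            "genome_size": genome.to_numpy(),
            "larval_period_matched": lp_matched.to_numpy(),
            "annual_precip_matched": precip_matched.to_numpy(),
        }
    ).set_index("species")

    manifest = {
        "seed": int(seed) if np.isscalar(seed) else repr(seed),
        "n_tips": n_tips,
        "depth": depth,
        "plant": {
            "beta0": plant_beta0,
            "beta1": plant_beta1,
            "resid_lambda": plant_resid_lambda,
            "resid_sigma2": plant_resid_sigma2,
        },
        "localities_per_species": {
            sp: int(c) for sp, c in zip(species, counts)
        },
        "genome_size_species": sorted(with_genome),
        "temperature_units": "celsius",
    }

    fixture = StudyFixture(tree, traits, localities, manifest)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "tree.nwk").write_text(write_newick(tree))
        traits.reset_index().to_csv(out / "traits.csv", index=False)
        localities.to_csv(out / "localities.csv", index=False)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return fixture
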