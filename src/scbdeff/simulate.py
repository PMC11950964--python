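"""Seeded synthetic dryland landscapes with known ground truth.

The generator emulates the study design the pipeline targets: a sparse
dryland plant community sampled over an aridity gradient (default 84
plots x 67 species), with a correlated soil-fertility composite, species
traits that shift peak abundance, and niche optima evolved on a
pure-birth phylogeny so phylogenetic signal is controllable.

Data-generating model
---------------------
* Sites get an aridity index uniform over ``aridity_range``; five soil
  variables share one latent fertility axis correlated with aridity at
  ``soil_aridity_correlation`` (equicorrelated loadings with noise sd
  0.6, putting ~79% of soil variance on the first PCA axis).
* A pure-birth tree over the species carries Brownian niche optima;
  the realized optimum mixes the Brownian value with i.i.d. noise with
  weight ``trait_effect_sizes["mpd_signal"]``.
* Expected abundance is a Gaussian niche:
  ``lambda_ij = exp(a_j) * exp(-(z_i - opt_j)^2 / (2 * niche_breadth^2))``
  on the standardized aridity axis, where the species' peak log-abundance
  ``a_j`` shifts with its standardized log-traits (height, SLA, leaf
  production) and C3 indicator according to ``trait_effect_sizes``.
* Counts are negative-binomial with dispersion ``abundance_dispersion``
  (size parameter; smaller = more overdispersed) and thinned to zero with
  probability ``zero_inflation``.  Species or sites left empty are redrawn
  (up to 100 attempts) so scenario dimensions stay fixed.
"""

from __future__ import annotations

import dataclasses
import json
import random
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

__all__ = ["ScenarioConfig", "SyntheticLandscape", "generate_landscape",
           "write_landscape", "read_landscape"]

REQUIRED_EFFECTS = ("height", "sla", "leaf_production", "mpd_signal", "c3_fraction")

SOIL_COLUMNS = ("soil_organic_carbon", "soil_ph", "soil_texture",
                "cation_exchange", "water_availability")


def _default_effects() -> dict:
    return {"height": 0.3, "sla": -0.3, "leaf_production": 0.2,
            "mpd_signal": 0.6, "c3_fraction": 0.25}


@dataclass
class ScenarioConfig:
    """Parameters of one synthetic landscape scenario.

    Defaults reproduce the target study dimensions: 84 plots, 67 species,
    an arid-to-semiarid aridity index range, moderate soil-aridity
    coupling and moderately overdispersed counts.
    """

    n_sites: int = 84
    n_species: int = 67
    seed: int = 0
    aridity_range: tuple[float, float] = (0.03, 0.3)
    soil_aridity_correlation: float = 0.5
    niche_breadth: float = 1.0
    trait_effect_sizes: dict = field(default_factory=_default_effects)
    abundance_dispersion: float = 1.5
    zero_inflation: float = 0.1

    def __post_init__(self):
        if self.n_sites < 3 or self.n_species < 3:
            raise ValueError("need at least 3 sites and 3 species")
        lo, hi = self.aridity_range
        if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
            raise ValueError("aridity_range must be a finite closed interval")
        if not -1 <= self.soil_aridity_correlation <= 1:
            raise ValueError("soil_aridity_correlation must lie in [-1, 1]")
        if self.niche_breadth <= 0:
            raise ValueError("niche_breadth must be positive")
        if self.abundance_dispersion <= 0:
            raise ValueError("abundance_dispersion must be positive")
        if not 0 <= self.zero_inflation <= 1:
            raise ValueError("zero_inflation must lie in [0, 1]")
        missing = set(REQUIRED_EFFECTS) - set(self.trait_effect_sizes)
        if missing:
            raise ValueError(f"missing trait effect sizes: {sorted(missing)}")
        for k, v in self.trait_effect_sizes.items():
            if not np.isfinite(v):
                raise ValueError(f"non-finite effect size for {k!r}")

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["aridity_range"] = list(self.aridity_range)
        return d


@dataclass
class SyntheticLandscape:
    """A generated landscape plus its generating truth."""

    community: pd.DataFrame          # sites x species counts
    site_env: pd.DataFrame           # aridity + soil variables per site
    traits: pd.DataFrame             # per-species traits incl. pathway
    tree: dendropy.Tree
    truth: dict

    @property
    def species(self):
        return list(self.community.columns)

    @property
    def sites(self):
        return list(self.community.index)


def _simulate_tree(n_species: int, seed: int) -> dendropy.Tree:
    from dendropy.model import birthdeath

    rng = random.Random(seed)
    tree = birthdeath.birth_death_tree(
        birth_rate=1.0, death_rate=0.0, num_extant_tips=n_species, rng=rng,
    )
    # normalize depth to 1 and relabel tips sp001..spN for stable joins
    depth = max(leaf.distance_from_root() for leaf in tree.leaf_node_iter())
    if depth > 0:
        for edge in tree.preorder_edge_iter():
            if edge.length is not None:
                edge.length /= depth
    for i, leaf in enumerate(tree.leaf_node_iter()):
        leaf.taxon.label = f"sp{i + 1:03d}"
    return tree


def _brownian_tip_values(tree: dendropy.Tree, rng: np.random.Generator) -> pd.Series:
    values = {tree.seed_node: 0.0}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        el = node.edge.length or 0.0
        values[node] = values[node.parent_node] + rng.normal(0.0, np.sqrt(max(el, 0.0)))
    out = {leaf.taxon.label: values[leaf] for leaf in tree.leaf_node_iter()}
    return pd.Series(out)


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)


def generate_landscape(config: ScenarioConfig) -> SyntheticLandscape:
    """Draw one landscape under the Gaussian-niche / negative-binomial model."""
    rng = np.random.default_rng(config.seed)
    tree = _simulate_tree(config.n_species, seed=int(rng.integers(2**31 - 1)))
    species = sorted(leaf.taxon.label for leaf in tree.leaf_node_iter())
    sites = [f"site{i + 1:03d}" for i in range(config.n_sites)]

    # --- environment -------------------------------------------------------
    lo, hi = config.aridity_range
    aridity = np.sort(rng.uniform(lo, hi, config.n_sites))
    arid_z = _zscore(aridity)
    rho = config.soil_aridity_correlation
    latent = rho * arid_z + np.sqrt(max(1 - rho**2, 0.0)) * rng.normal(size=config.n_sites)
    soil = {}
    for k, col in enumerate(SOIL_COLUMNS):
        soil[col] = latent + 0.6 * rng.normal(size=config.n_sites)
    site_env = pd.DataFrame({"aridity": aridity, **soil}, index=sites)

    # --- species traits and niche optima -----------------------------------
    eff = config.trait_effect_sizes
    height = rng.lognormal(np.log(30.0), 0.5, config.n_species)
    sla = rng.lognormal(np.log(80.0), 0.4, config.n_species)
    leaf_prod = np.maximum(rng.lognormal(np.log(40.0), 0.6, config.n_species), 1.0)
    is_c3 = rng.random(config.n_species) < 0.7
    traits = pd.DataFrame(
        {
            "height_cm": height,
            "sla_cm2_per_g": sla,
            "leaf_production": np.round(leaf_prod),
            "pathway": np.where(is_c3, "C3", "C4"),
        },
        index=species,
    )

    bm = _brownian_tip_values(tree, rng).reindex(species).to_numpy()
    w = float(np.clip(eff["mpd_signal"], 0.0, 1.0))
    opt = w * _zscore(bm) + np.sqrt(1 - w**2) * rng.normal(size=config.n_species)
    opt = 1.2 * opt  # optima slightly overflow the gradient: edge species stay rare

    log_amax = (
        np.log(8.0)
        + eff["height"] * _zscore(np.log(height))
        + eff["sla"] * _zscore(np.log(sla))
        + eff["leaf_production"] * _zscore(np.log(leaf_prod))
        + eff["c3_fraction"] * (is_c3.astype(float) - is_c3.mean())
    )

    lam = np.exp(log_amax)[None, :] * np.exp(
        -((arid_z[:, None] - opt[None, :]) ** 2) / (2 * config.niche_breadth**2)
    )

    # --- counts -------------------------------------------------------------
    k = config.abundance_dispersion

    def draw(lam_block, shape):
        counts = rng.negative_binomial(k, k / (k + np.maximum(lam_block, 1e-12)), size=shape)
        if config.zero_inflation > 0:
            counts = counts * (rng.random(shape) > config.zero_inflation)
        return counts

    counts = draw(lam, lam.shape)
    for _ in range(100):  # redraw empty species columns / site rows
        empty_sp = counts.sum(axis=0) == 0
        empty_site = counts.sum(axis=1) == 0
        if not empty_sp.any() and not empty_site.any():
            break
        if empty_sp.any():
            counts[:, empty_sp] = draw(lam[:, empty_sp], lam[:, empty_sp].shape)
        if empty_site.any():
            counts[empty_site, :] = draw(lam[empty_site, :], lam[empty_site, :].shape)
    else:
        raise RuntimeError(
            "could not populate every species and site in 100 redraws; "
            "the scenario is too sparse (raise abundance or lower zero_inflation)"
        )

    community = pd.DataFrame(counts.astype(int), index=sites, columns=species)
    community.index.name = "site"
    site_env.index.name = "site"
    traits.index.name = "species"
    truth = {
        "config": config.as_dict(),
        "niche_optima": dict(zip(species, map(float, opt))),
        "log_peak_abundance": dict(zip(species, map(float, log_amax))),
        "expected_abundance_colmax": float(lam.max()),
        "soil_latent": list(map(float, latent)),
    }
    return SyntheticLandscape(community=community, site_env=site_env,
                              traits=traits, tree=tree, truth=truth)


def expected_abundance(config: ScenarioConfig) -> pd.DataFrame:
    """The analytic mean matrix lambda of the scenario (no sampling noise).

    Re-derives the deterministic part of :func:`generate_landscape` under
    the same seed, for property checks against the generator's mean model.
    """
    land = generate_landscape(config)
    arid_z = _zscore(land.site_env["aridity"].to_numpy())
    opt = np.array([land.truth["niche_optima"][s] for s in land.species])
    amax = np.exp([land.truth["log_peak_abundance"][s] for s in land.species])
    lam = amax[None, :] * np.exp(
        -((arid_z[:, None] - opt[None, :]) ** 2) / (2 * config.niche_breadth**2)
    )
    return pd.DataFrame(lam, index=land.sites, columns=land.species)


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def write_landscape(landscape: SyntheticLandscape, directory) -> dict:
    """Write community.csv, site_env.csv, traits.csv, tree.nwk, truth.json."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    paths = {
        "community": d / "community.csv",
        "site_env": d / "site_env.csv",
        "traits": d / "traits.csv",
        "tree": d / "tree.nwk",
        "truth": d / "truth.json",
    }
    landscape.community.to_csv(paths["community"], index_label="site")
    landscape.site_env.to_csv(paths["site_env"], index_label="site")
    landscape.traits.to_csv(paths["traits"], index_label="species")
    paths["tree"].write_text(
        landscape.tree.as_string(schema="newick", suppress_rooting=True)
    )
    paths["truth"].write_text(json.dumps(landscape.truth, indent=2))
    return {k: str(v) for k, v in paths.items()}


def read_landscape(directory) -> SyntheticLandscape:
    """Read back a landscape written by :func:`write_landscape`."""
    d = Path(directory)
    community = pd.read_csv(d / "community.csv", index_col="site")
    site_env = pd.read_csv(d / "site_env.csv", index_col="site")
    traits = pd.read_csv(d / "traits.csv", index_col="species")
    tree = dendropy.Tree.get(path=str(d / "tree.nwk"), schema="newick",
                             preserve_underscores=True)
    truth = json.loads((d / "truth.json").read_text())
    tips = sorted(leaf.taxon.label for leaf in tree.leaf_node_iter())
    if tips != sorted(map(str, community.columns)):
        raise ValueError("tree tips do not match community species")
    return SyntheticLandscape(community=community, site_env=site_env,
                              traits=traits, tree=tree, truth=truth)
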