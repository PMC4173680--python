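"""Synthetic studies with known ground truth.

Every stage of the pipeline can be exercised end-to-end on generated data:
a pure-birth (Yule) chronogram is the true phylogeny; tip traits evolve
with a lambda-scaled Brownian covariance and a known linear dependence of
the response on ln colony size (plus optional environmental effects);
observation-level records are drawn around the species truths with
lognormal noise and heterogeneous, partially missing sample sizes; source
trees are taxon-subsampled (optionally SPR-perturbed) copies of the true
tree; climate layers are smooth analytic fields sampled on a regular grid.

Default study conditions mirror the target system: 40 species, 12 source
trees, ln colony size spanning ln 16 to ln 6e6, lambda 0.9 for the social
traits, a colony-size effect of 0.4 on square-root worker size variation,
unit residual tip variance, and a 37.7-Myr-old root.  Every generator is
deterministic given its seed, and ``make_study`` records all parameters in
a manifest.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from . import geoclim, traits
from .comparative import phylo_covariance
from .dating import Calibration, branch_lengths_from_ages
from .geoclim import ClimateGrid
from .supertree import (_add_child, _apply_spr, _from_dendropy, _Node,
                        _preorder, _spr_candidates, _to_dendropy)

__all__ = [
    "StudyConfig",
    "SyntheticStudy",
    "simulate_yule_tree",
    "simulate_lambda_traits",
    "make_observation_table",
    "make_source_trees",
    "make_climate_grid",
    "make_study",
]


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------

def simulate_yule_tree(n_tips: int, seed: int, root_age: float = 1.0) -> dendropy.Tree:
    """Pure-birth tree: with k lineages the wait to the next split is
    exponential with rate k; node ages are rescaled so the root age equals
    ``root_age``.  Tips are labelled t1..tn in order of appearance."""
    if n_tips < 2:
        raise ValueError("need at least 2 tips")
    rng = np.random.default_rng(seed)
    tree = dendropy.Tree()
    tree.is_rooted = True
    root = tree.seed_node
    root.split_time = 0.0
    active = [root.new_child(), root.new_child()]
    t = 0.0
    while len(active) < n_tips:
        k = len(active)
        t += rng.exponential(1.0 / k)
        nd = active.pop(int(rng.integers(k)))
        nd.split_time = t
        active.extend([nd.new_child(), nd.new_child()])
    t_end = t + rng.exponential(1.0 / n_tips)
    for i, lf in enumerate(tree.leaf_node_iter()):
        lf.taxon = tree.taxon_namespace.require_taxon(f"t{i + 1}")
    scale = root_age / t_end
    for nd in tree.preorder_node_iter():
        if nd.is_leaf():
            nd.age = 0.0
        else:
            nd.age = (t_end - nd.split_time) * scale
    return branch_lengths_from_ages(tree)


def make_source_trees(true_tree: dendropy.Tree, n_sources: int = 12,
                      keep_fraction: float = 0.75, spr_moves: int = 0,
                      seed: int = 0) -> list[dendropy.Tree]:
    """Partially overlapping source topologies derived from the true tree.

    Each source keeps a random ``keep_fraction`` of the taxa (at least 3)
    and is then perturbed by ``spr_moves`` random subtree transfers."""
    if not 0.0 < keep_fraction <= 1.0:
        raise ValueError("keep_fraction must be in (0, 1]")
    if spr_moves < 0:
        raise ValueError("spr_moves must be >= 0")
    rng = np.random.default_rng(seed)
    labels = sorted(lf.taxon.label for lf in true_tree.leaf_node_iter())
    index = {lab: i for i, lab in enumerate(labels)}
    root = _from_dendropy(true_tree, index)
    n = len(labels)
    n_keep = max(3, int(round(keep_fraction * n)))
    out = []
    for s in range(n_sources):
        keep = set(rng.choice(n, size=n_keep, replace=False).tolist())
        pruned = _prune_internal(root, keep)
        for _ in range(spr_moves):
            cands = _spr_candidates(pruned)
            if not cands:
                break
            i, j = cands[int(rng.integers(len(cands)))]
            pruned = _apply_spr(pruned, i, j)
        t = _to_dendropy(pruned, labels)
        t.label = f"source_{s + 1}"
        out.append(t)
    return out


def _prune_internal(root: _Node, keep: set) -> _Node:
    def rec(nd: _Node) -> _Node | None:
        if not nd.children:
            return _Node(nd.taxon) if nd.taxon in keep else None
        kids = [rec(c) for c in nd.children]
        kids = [k for k in kids if k is not None]
        if not kids:
            return None
        if len(kids) == 1:
            return kids[0]
        new = _Node()
        for k in kids:
            _add_child(new, k)
        return new

    pruned = rec(root)
    if pruned is None or len(_preorder(pruned)) < 5:
        raise ValueError("pruned source has fewer than 3 taxa")
    return pruned


# ---------------------------------------------------------------------------
# traits
# ---------------------------------------------------------------------------

def simulate_lambda_traits(tree: dendropy.Tree, lam: float, beta=(0.0, 0.0),
                           predictor: pd.Series | None = None,
                           sigma2: float = 1.0, seed: int = 0,
                           predictor_sigma2: float = 1.0):
    """Tip values ``beta0 + beta1 * predictor + eps`` with
    ``eps ~ MVN(0, sigma2 * C(lambda))``.

    ``sigma2`` is the Brownian rate per unit branch length, so the tip
    variance is ``sigma2 * root-to-tip depth``.  When no predictor is
    supplied one is simulated as plain Brownian motion (lambda = 1) with
    rate ``predictor_sigma2``.  Returns ``(response, predictor)`` Series.
    """
    if sigma2 < 0:
        raise ValueError("sigma2 must be non-negative")
    rng = np.random.default_rng(seed)
    C1, taxa = phylo_covariance(tree, 1.0)
    n = len(taxa)
    if predictor is None:
        L = np.linalg.cholesky(predictor_sigma2 * C1 + 1e-12 * np.eye(n))
        predictor = pd.Series(L @ rng.standard_normal(n), index=taxa)
    else:
        predictor = predictor.reindex(taxa)
        if predictor.isna().any():
            raise ValueError("predictor must cover every tip")
    beta0, beta1 = beta
    if sigma2 == 0:
        eps = np.zeros(n)
    else:
        off = C1 - np.diag(np.diag(C1))
        Clam = np.diag(np.diag(C1)) + lam * off
        L = np.linalg.cholesky(sigma2 * Clam + 1e-12 * np.eye(n))
        eps = L @ rng.standard_normal(n)
    response = pd.Series(beta0 + beta1 * predictor.to_numpy(), index=taxa) + eps
    return response, predictor


def make_observation_table(species_truth: pd.DataFrame,
                           obs_per_species=(1, 5), noise_cv: float = 0.0,
                           missing_n_fraction: float = 0.0,
                           n_range=(1, 30), seed: int = 0) -> list:
    """Observation records drawn around per-species truths.

    ``species_truth`` is indexed by species with trait columns
    (colony_size, worker_head_width, queen_head_width, mating_system — any
    subset).  Observation means are lognormal around the truth with
    relative sd ``noise_cv`` (exact at 0), sample sizes are integers from
    ``n_range`` and are blanked with probability ``missing_n_fraction``.
    Mating system is recorded once per species, exactly.
    """
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    rng = np.random.default_rng(seed)
    records = []
    lo, hi = obs_per_species
    for sp, row in species_truth.iterrows():
        for trait in ("colony_size", "worker_head_width", "queen_head_width"):
            if trait not in row or pd.isna(row[trait]):
                continue
            m = int(rng.integers(lo, hi + 1))
            for _ in range(m):
                mean = _lognormal_around(rng, float(row[trait]), noise_cv)
                if trait == "colony_size":
                    mean = max(1.0, round(mean))
                n = int(rng.integers(n_range[0], n_range[1] + 1))
                if rng.random() < missing_n_fraction:
                    n = None
                records.append(traits.ObservationRecord(
                    species=str(sp), trait=trait, mean=mean, n=n,
                    source="synthetic"))
        if "mating_system" in row and not pd.isna(row["mating_system"]):
            records.append(traits.ObservationRecord(
                species=str(sp), trait="mating_system",
                mean=float(row["mating_system"]), source="synthetic"))
    return records


def _lognormal_around(rng, mean: float, rel_sd: float) -> float:
    if rel_sd == 0 or mean == 0:
        return mean
    s2 = np.log1p(rel_sd ** 2)
    return float(rng.lognormal(np.log(mean) - s2 / 2.0, np.sqrt(s2)))


# ---------------------------------------------------------------------------
# climate
# ---------------------------------------------------------------------------

def make_climate_grid(variable: str, field: str = "gradient",
                      cellsize_arcmin: float = 10.0,
                      extent=(-70.0, -25.0, -40.0, 5.0), seed: int = 0,
                      base: float = 10.0, lat_slope: float = 0.0,
                      lon_slope: float = 0.0, amplitude: float = 5.0,
                      period_deg: float = 13.0) -> ClimateGrid:
    """Deterministic analytic climate field sampled at cell centres.

    ``extent`` is (lon_min, lat_min, lon_max, lat_max); fields are
    'constant', 'gradient' (base + slopes * coordinates) or 'seasonal-mix'
    (two incommensurate sinusoids with seed-drawn phases).
    """
    lon_min, lat_min, lon_max, lat_max = extent
    if lon_max <= lon_min or lat_max <= lat_min:
        raise ValueError("invalid extent")
    cs = cellsize_arcmin / 60.0
    ncols = int(round((lon_max - lon_min) / cs))
    nrows = int(round((lat_max - lat_min) / cs))
    lon_c = lon_min + (np.arange(ncols) + 0.5) * cs
    lat_c = lat_min + (nrows - 1 - np.arange(nrows) + 0.5) * cs  # row 0 north
    LON, LAT = np.meshgrid(lon_c, lat_c)
    if field == "constant":
        values = np.full((nrows, ncols), base)
    elif field == "gradient":
        values = base + lat_slope * LAT + lon_slope * LON
    elif field == "seasonal-mix":
        rng = np.random.default_rng(seed)
        ph1, ph2 = rng.uniform(0, 2 * np.pi, size=2)
        values = (base
                  + amplitude * np.sin(2 * np.pi * LAT / period_deg + ph1)
                  + amplitude * np.cos(2 * np.pi * LON / (1.7 * period_deg) + ph2))
    else:
        raise ValueError("field must be constant, gradient or seasonal-mix")
    return ClimateGrid(variable, values, cellsize_arcmin, lon_min, lat_min)


# ---------------------------------------------------------------------------
# whole studies
# ---------------------------------------------------------------------------

@dataclass
class StudyConfig:
    """Ground-truth parameters and sizes of a synthetic study."""

    n_species: int = 40
    n_sources: int = 12
    keep_fraction: float = 0.75
    spr_moves: int = 0
    root_age: float = 37.7          # Myr
    ln_colony_range: tuple = (np.log(16.0), np.log(6.0e6))
    lambda_wsv: float = 0.9
    beta0_wsv: float = 1.0          # intercept on the sqrt-WSV scale
    beta_colony_wsv: float = 0.4    # slope of sqrt WSV on ln colony size
    sigma2_wsv: float = 1.0         # residual tip variance of sqrt WSV
    lambda_qwd: float = 0.9
    beta0_qwd: float = 1.5          # intercept on the ln-QWD scale
    beta_colony_qwd: float = 0.16
    sigma2_qwd: float = 0.6
    env_effects: dict = dc_field(default_factory=dict)  # variable -> slope
    obs_per_species: tuple = (3, 6)
    hw_obs_per_species: tuple = (4, 8)
    noise_cv: float = 0.05
    missing_n_fraction: float = 0.2
    extent: tuple = (-70.0, -25.0, -40.0, 5.0)
    cellsize_arcmin: float = 10.0
    fine_cellsize_arcmin: float = 5.0
    localities_per_species: tuple = (2, 6)
    coarse_locality_fraction: float = 0.1  # precision > 20 km2, to be filtered


@dataclass
class SyntheticStudy:
    """A complete generated study plus its ground truth."""

    config: StudyConfig
    seed: int
    tree: dendropy.Tree
    species_truth: pd.DataFrame
    observations: pd.DataFrame
    localities: pd.DataFrame
    source_trees: list
    grids: list
    calibrations: list
    manifest: dict

    def write(self, out_dir) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.observations.to_csv(out / "observations.csv", index=False)
        self.localities.to_csv(out / "localities.csv", index=False)
        self.species_truth.to_csv(out / "species_truth.csv")
        self.tree.write(path=str(out / "true_tree.nwk"), schema="newick")
        with open(out / "source_trees.nwk", "w") as fh:
            for t in self.source_trees:
                fh.write(t.as_string(schema="newick"))
        pd.DataFrame(
            [{"node": "|".join(sorted(c.taxa)), "age_Ma": c.age}
             for c in self.calibrations]
        ).to_csv(out / "calibrations.csv", index=False)
        for g in self.grids:
            geoclim.write_grid(g, out / f"grid_{g.name}.txt")
        with open(out / "manifest.json", "w") as fh:
            json.dump(self.manifest, fh, indent=2, default=str)
        return out


_ENV_FIELDS = {
    "diurnal_temperature_range": dict(field="gradient", base=12.0,
                                      lat_slope=0.15, lon_slope=0.0),
    "isothermality": dict(field="gradient", base=60.0, lat_slope=0.0,
                          lon_slope=0.3),
    "temperature_seasonality": dict(field="seasonal-mix", base=30.0,
                                    amplitude=6.0, period_deg=17.0),
    "precipitation_seasonality": dict(field="seasonal-mix", base=45.0,
                                      amplitude=9.0, period_deg=11.0),
}


def make_study(config: StudyConfig | None = None, seed: int = 0,
               out_dir=None) -> SyntheticStudy:
    """Generate a full synthetic study (see module docstring).

    Bit-for-bit reproducible for a given (config, seed); ``out_dir`` writes
    every file the pipeline consumes plus a ground-truth manifest.
    """
    cfg = config or StudyConfig()
    rng = np.random.default_rng(seed)
    sub = [int(s) for s in rng.integers(0, 2**31 - 1, size=8)]

    tree = simulate_yule_tree(cfg.n_species, seed=sub[0], root_age=cfg.root_age)
    taxa = sorted(lf.taxon.label for lf in tree.leaf_node_iter())

    # ln colony size: Brownian, affinely rescaled to the target span
    _, lncs_raw = simulate_lambda_traits(tree, 1.0, beta=(0.0, 0.0),
                                         sigma2=0.0, seed=sub[1],
                                         predictor_sigma2=1.0 / cfg.root_age)
    lo, hi = cfg.ln_colony_range
    span = lncs_raw.max() - lncs_raw.min()
    lncs = lo + (lncs_raw - lncs_raw.min()) * (hi - lo) / span

    # localities and climate
    lon_min, lat_min, lon_max, lat_max = cfg.extent
    rloc = np.random.default_rng(sub[2])
    loc_rows = []
    for sp in taxa:
        c_lat = rloc.uniform(lat_min + 2, lat_max - 2)
        c_lon = rloc.uniform(lon_min + 2, lon_max - 2)
        k = int(rloc.integers(cfg.localities_per_species[0],
                              cfg.localities_per_species[1] + 1))
        for _ in range(k):
            lat = float(np.clip(c_lat + rloc.normal(0, 1.0),
                                lat_min + 0.1, lat_max - 0.3))
            lon = float(np.clip(c_lon + rloc.normal(0, 1.0),
                                lon_min + 0.1, lon_max - 0.3))
            if rloc.random() < cfg.coarse_locality_fraction:
                prec = float(rloc.uniform(25.0, 500.0))
            elif rloc.random() < 0.5:
                prec = float(rloc.uniform(0.1, 15.0))
            else:
                prec = np.nan
            loc_rows.append({"species": sp, "lat": lat, "lon": lon,
                             "locality_precision_km2": prec})
    localities = pd.DataFrame(loc_rows)

    grids = [make_climate_grid(var, cellsize_arcmin=cfg.fine_cellsize_arcmin,
                               extent=cfg.extent, seed=sub[3] + i, **kw)
             for i, (var, kw) in enumerate(_ENV_FIELDS.items())]
    coarse = [geoclim.resample_grid(g, cfg.cellsize_arcmin) for g in grids]
    kept, _ = geoclim.filter_localities(localities)
    env = geoclim.species_environment_means(kept, coarse)
    env = env.reindex(taxa)

    # responses on their analysis scales
    env_term = np.zeros(len(taxa))
    for var, slope in cfg.env_effects.items():
        env_term += slope * env[var].to_numpy(float)
    sqrt_wsv, _ = simulate_lambda_traits(
        tree, cfg.lambda_wsv, beta=(cfg.beta0_wsv, cfg.beta_colony_wsv),
        predictor=lncs, sigma2=cfg.sigma2_wsv / cfg.root_age, seed=sub[4])
    sqrt_wsv = sqrt_wsv + pd.Series(env_term, index=env.index).reindex(sqrt_wsv.index)
    sqrt_wsv = sqrt_wsv.clip(lower=0.3)
    wsv = sqrt_wsv ** 2
    ln_qwd, _ = simulate_lambda_traits(
        tree, cfg.lambda_qwd, beta=(cfg.beta0_qwd, cfg.beta_colony_qwd),
        predictor=lncs, sigma2=cfg.sigma2_qwd / cfg.root_age, seed=sub[5])
    qwd = np.exp(ln_qwd).clip(1.0, 92.0)

    rtrait = np.random.default_rng(sub[6])
    worker_hw = pd.Series(
        np.clip(rtrait.lognormal(np.log(0.9), 0.35, size=len(taxa)), 0.3, 3.5),
        index=taxa)
    queen_hw = worker_hw / (1.0 - qwd.reindex(taxa) / 100.0)
    colony = np.exp(lncs)
    polyandrous = (lncs > lncs.quantile(0.75)).astype(int)

    species_truth = pd.DataFrame({
        "colony_size": colony, "ln_colony_size": lncs,
        "worker_head_width": worker_hw, "queen_head_width": queen_hw,
        "worker_size_variation": wsv.reindex(taxa),
        "sqrt_worker_size_variation": sqrt_wsv.reindex(taxa),
        "queen_worker_dimorphism": qwd.reindex(taxa),
        "mating_system": polyandrous,
    }, index=pd.Index(taxa, name="species")).join(env)

    # observation records: colony size and queen head width with generic
    # noise; worker head width dispersed so the observation CV realises the
    # species' true worker size variation
    base_truth = species_truth[["colony_size", "queen_head_width",
                                "mating_system"]].copy()
    records = make_observation_table(
        base_truth, obs_per_species=cfg.obs_per_species,
        noise_cv=cfg.noise_cv, missing_n_fraction=cfg.missing_n_fraction,
        seed=sub[7])
    rhw = np.random.default_rng(sub[7] + 1)
    for sp in taxa:
        cv = float(species_truth.loc[sp, "worker_size_variation"]) / 100.0
        mu = float(species_truth.loc[sp, "worker_head_width"])
        m = int(rhw.integers(cfg.hw_obs_per_species[0],
                             cfg.hw_obs_per_species[1] + 1))
        for _ in range(m):
            n = int(rhw.integers(1, 31))
            records.append(traits.ObservationRecord(
                species=sp, trait="worker_head_width",
                mean=_lognormal_around(rhw, mu, max(cv, 1e-6)),
                n=None if rhw.random() < cfg.missing_n_fraction else n,
                source="synthetic"))

    obs_frame = pd.DataFrame([dataclasses.asdict(r) for r in records])

    source_trees = make_source_trees(tree, cfg.n_sources, cfg.keep_fraction,
                                     cfg.spr_moves, seed=sub[3] + 101)

    # calibrations: the root plus two random internal nodes, at true ages
    internals = [nd for nd in tree.preorder_internal_node_iter()
                 if nd.parent_node is not None
                 and sum(1 for _ in nd.leaf_iter()) >= 3]
    rcal = np.random.default_rng(sub[0] + 1)
    picks = rcal.choice(len(internals), size=min(2, len(internals)),
                        replace=False) if internals else []
    calibrations = [Calibration(age=cfg.root_age, taxa=frozenset(taxa))]
    for p in picks:
        nd = internals[int(p)]
        calibrations.append(Calibration(
            age=float(nd.age),
            taxa=frozenset(lf.taxon.label for lf in nd.leaf_iter())))

    manifest = {
        "seed": seed,
        "config": dataclasses.asdict(cfg),
        "true_parameters": {
            "lambda_wsv": cfg.lambda_wsv,
            "beta_colony_wsv": cfg.beta_colony_wsv,
            "beta0_wsv": cfg.beta0_wsv,
            "sigma2_wsv": cfg.sigma2_wsv,
            "lambda_qwd": cfg.lambda_qwd,
            "beta_colony_qwd": cfg.beta_colony_qwd,
            "env_effects": cfg.env_effects,
        },
        "n_species": cfg.n_species,
        "taxa": taxa,
    }

    study = SyntheticStudy(
        config=cfg, seed=seed, tree=tree, species_truth=species_truth,
        observations=obs_frame, localities=localities,
        source_trees=source_trees, grids=grids, calibrations=calibrations,
        manifest=manifest)
    if out_dir is not None:
        study.write(out_dir)
    return study
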