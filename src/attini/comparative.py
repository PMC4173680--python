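"""Phylogenetically controlled multimodel regression.

The statistical engine of the package: generalized least squares with a
residual covariance proportional to shared phylogenetic path lengths,
Pagel's lambda scaling of the off-diagonal covariance estimated by maximum
likelihood on [0, 1], candidate-model enumeration over covariate subsets,
small-sample AICc weighting, natural model averaging over the informative
set (Delta AICc <= 7 by default), and phylogenetic-uncertainty intervals
from refitting over a sample of trees.

Model likelihood for response ``y`` (n species) and design ``X``::

    y ~ N(X beta, sigma^2 * V(lambda)),   V = C with off-diagonals * lambda

with ``C[i, j]`` the root-to-MRCA path length between species i and j.
The profile log-likelihood concentrates beta (GLS) and sigma^2 (ML) out,
leaving a 1-D search over lambda.  AICc counts ``k = #beta + 1`` for
sigma^2, plus 1 when lambda is estimated.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from scipy import linalg, optimize

__all__ = [
    "ModelSpec",
    "PGLSFit",
    "AveragedModel",
    "TreeSampleSummary",
    "phylo_covariance",
    "pgls",
    "pgls_fit",
    "phylogenetic_signal",
    "vif_eliminate",
    "enumerate_models",
    "aicc_weights",
    "model_average",
    "tree_sample_intervals",
    "run_averaged_analysis",
]


# ---------------------------------------------------------------------------
# covariance
# ---------------------------------------------------------------------------

def phylo_covariance(tree: dendropy.Tree, lam: float = 1.0,
                     taxa=None) -> tuple[np.ndarray, list[str]]:
    """Species covariance implied by a dated tree under lambda scaling.

    ``C[i, j]`` is the shared root-to-MRCA path length; off-diagonals are
    multiplied by ``lam``, diagonals (root-to-tip depths) are untouched.
    Returns ``(C, taxa)`` with rows ordered by ``taxa`` (default: sorted
    leaf labels).
    """
    if not 0.0 <= lam <= 1.0:
        raise ValueError("lambda must be in [0, 1]")
    leaves = {lf.taxon.label: lf for lf in tree.leaf_node_iter()}
    if taxa is None:
        taxa = sorted(leaves)
    else:
        taxa = list(taxa)
        missing = [t for t in taxa if t not in leaves]
        if missing:
            raise ValueError(f"taxa not in tree: {missing}")
    index = {t: i for i, t in enumerate(taxa)}
    n = len(taxa)
    # node depths from root via edge lengths
    depth: dict[int, float] = {}
    for nd in tree.preorder_node_iter():
        if nd.parent_node is None:
            depth[id(nd)] = 0.0
        else:
            depth[id(nd)] = depth[id(nd.parent_node)] + (nd.edge.length or 0.0)
    C = np.zeros((n, n))
    # leaf sets per node, bottom-up; MRCA depth fills the off-diagonals
    below: dict[int, list[int]] = {}
    for nd in tree.postorder_node_iter():
        if nd.is_leaf():
            lab = nd.taxon.label
            below[id(nd)] = [index[lab]] if lab in index else []
            if lab in index:
                C[index[lab], index[lab]] = depth[id(nd)]
        else:
            groups = [below.pop(id(c)) for c in nd.child_nodes()]
            d = depth[id(nd)]
            for ga, gb in itertools.combinations(groups, 2):
                for i in ga:
                    for j in gb:
                        C[i, j] = C[j, i] = d
            merged = [i for g in groups for i in g]
            below[id(nd)] = merged
    if lam != 1.0:
        off = C - np.diag(np.diag(C))
        C = np.diag(np.diag(C)) + lam * off
    return C, taxa


# ---------------------------------------------------------------------------
# model containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelSpec:
    """A candidate PGLS model: response plus an ordered covariate tuple.

    Interaction terms are written ``"a:b"`` and may only appear alongside
    both main effects."""

    response: str
    covariates: tuple[str, ...] = ()

    def __post_init__(self):
        for cov in self.covariates:
            if ":" in cov:
                a, b = cov.split(":")
                if a not in self.covariates or b not in self.covariates:
                    raise ValueError(
                        f"interaction {cov!r} requires both main effects")

    def design(self, data: pd.DataFrame) -> np.ndarray:
        cols = [np.ones(len(data))]
        for cov in self.covariates:
            if ":" in cov:
                a, b = cov.split(":")
                cols.append(data[a].to_numpy(float) * data[b].to_numpy(float))
            else:
                cols.append(data[cov].to_numpy(float))
        return np.column_stack(cols)

    @property
    def names(self) -> tuple[str, ...]:
        return ("(intercept)",) + self.covariates


@dataclass
class PGLSFit:
    """A fitted PGLS model."""

    spec: ModelSpec
    beta: dict[str, float]
    se: dict[str, float]
    lam: float
    sigma2: float
    loglik: float
    k: int
    aicc: float
    r2: float
    r2_pred: float
    n: int
    species: frozenset = field(default_factory=frozenset)

    def ci(self, name: str, multiplier: float = 1.96) -> tuple[float, float]:
        b, s = self.beta[name], self.se[name]
        return b - multiplier * s, b + multiplier * s


@dataclass
class AveragedModel:
    """Multimodel summary: natural averages over the informative set and
    cumulative weights over the full candidate set."""

    beta: dict[str, float]
    se: dict[str, float]
    ci: dict[str, tuple[float, float]]
    cumulative_weight: dict[str, float]
    table: pd.DataFrame  # per model: covariates, aicc, delta, weight, informative


@dataclass
class TreeSampleSummary:
    """Mean slopes and 95% phylogenetic-uncertainty half-widths over a tree
    sample."""

    mean_beta: dict[str, float]
    half_width: dict[str, float]
    interval: dict[str, tuple[float, float]]
    n_trees: int


# ---------------------------------------------------------------------------
# core GLS machinery
# ---------------------------------------------------------------------------

def _gls_pieces(y, X, V):
    cf = linalg.cho_factor(V, lower=True)
    logdet = 2.0 * np.sum(np.log(np.diag(cf[0])))
    Vy = linalg.cho_solve(cf, y)
    VX = linalg.cho_solve(cf, X)
    XtViX = X.T @ VX
    XtViy = X.T @ Vy
    try:
        beta = linalg.solve(XtViX, XtViy, assume_a="pos")
    except linalg.LinAlgError as exc:
        raise ValueError("singular design matrix") from exc
    resid = y - X @ beta
    rss = float(resid @ linalg.cho_solve(cf, resid))
    return beta, rss, logdet, XtViX, cf


def _check_design(X, names):
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        _, R, piv = linalg.qr(X, pivoting=True, mode="economic")
        d = np.abs(np.diag(R))
        bad = [names[piv[i]] for i in range(len(d)) if d[i] < 1e-10 * d.max()]
        bad = bad or [names[p] for p in piv[rank:]]
        raise ValueError(f"singular design: collinear columns {bad}")


def _profile_loglik(lam, y, X, C):
    n = len(y)
    V = np.diag(np.diag(C)) + lam * (C - np.diag(np.diag(C)))
    beta, rss, logdet, XtViX, cf = _gls_pieces(y, X, V)
    sigma2 = rss / n
    if sigma2 <= 0:
        sigma2 = np.finfo(float).tiny
    ll = -0.5 * (n * np.log(2.0 * np.pi * sigma2) + logdet + n)
    return ll, beta, rss, sigma2, XtViX


def pgls(y: np.ndarray, X: np.ndarray, C: np.ndarray, names,
         spec: ModelSpec | None = None, lam_mode: str = "ML",
         lam: float | None = None, species=(), xatol: float = 1e-6,
         count_lambda: bool = True) -> PGLSFit:
    """Fit a PGLS model given response, design and base covariance.

    ``lam_mode="ML"`` maximizes the profile log-likelihood over lambda in
    [0, 1] (bounded scalar search, endpoints checked); ``"fixed"`` uses
    ``lam`` as given.  See the module docstring for the likelihood, AICc
    and r-squared conventions.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    names = list(names)
    _check_design(X, names)
    if lam_mode == "ML":
        res = optimize.minimize_scalar(
            lambda l: -_profile_loglik(l, y, X, C)[0],
            bounds=(0.0, 1.0), method="bounded", options={"xatol": xatol})
        cands = [(float(res.x), -res.fun)]
        for edge in (0.0, 1.0):
            cands.append((edge, _profile_loglik(edge, y, X, C)[0]))
        lam_hat = max(cands, key=lambda c: c[1])[0]
        k = p + 1 + (1 if count_lambda else 0)
    elif lam_mode == "fixed":
        if lam is None or not 0.0 <= lam <= 1.0:
            raise ValueError("fixed mode needs lambda in [0, 1]")
        lam_hat = float(lam)
        k = p + 1
    else:
        raise ValueError("lam_mode must be 'ML' or 'fixed'")
    ll, beta, rss, sigma2_ml, XtViX = _profile_loglik(lam_hat, y, X, C)
    if n - k - 1 <= 0:
        raise ValueError("AICc undefined: n - k - 1 <= 0")
    aicc = -2.0 * ll + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)
    # SEs use the unbiased residual variance
    sigma2_u = rss / max(n - p, 1)
    cov_beta = sigma2_u * linalg.inv(XtViX)
    se = np.sqrt(np.diag(cov_beta))
    # whitened-space r2 against a GLS intercept-only fit on the same V(lambda)
    ll0, _, tss, _, _ = _profile_loglik(lam_hat, y, np.ones((n, 1)), C)
    r2 = 1.0 - rss / tss if tss > 0 else np.nan
    r2_pred = 1.0 - np.exp((2.0 / n) * (ll0 - ll))
    return PGLSFit(
        spec=spec or ModelSpec("y", tuple(names[1:])),
        beta=dict(zip(names, map(float, beta))),
        se=dict(zip(names, map(float, se))),
        lam=lam_hat, sigma2=float(sigma2_ml), loglik=float(ll), k=k,
        aicc=float(aicc), r2=float(r2), r2_pred=float(r2_pred), n=n,
        species=frozenset(species),
    )


def _align(spec: ModelSpec, data: pd.DataFrame, tree: dendropy.Tree):
    cols = [spec.response] + [c for cov in spec.covariates
                              for c in (cov.split(":") if ":" in cov else [cov])]
    cols = list(dict.fromkeys(cols))
    leaves = {lf.taxon.label for lf in tree.leaf_node_iter()}
    sub = data.loc[[sp for sp in data.index if sp in leaves], cols].dropna()
    return sub


def pgls_fit(spec: ModelSpec, data: pd.DataFrame, tree: dendropy.Tree,
             lam_mode: str = "ML", lam: float | None = None,
             count_lambda: bool = True) -> PGLSFit:
    """Fit a model spec against a species trait table and a dated tree.

    Species missing any variable of the model are dropped here (complete
    cases per model); the remaining species must number at least the
    parameter count plus two.
    """
    sub = _align(spec, data, tree)
    p = 1 + len(spec.covariates)
    if len(sub) < p + 2:
        raise ValueError(
            f"only {len(sub)} complete species for {spec.response} ~ "
            f"{spec.covariates}; need >= {p + 2}")
    C, taxa = phylo_covariance(tree, 1.0, taxa=list(sub.index))
    y = sub[spec.response].to_numpy(float)
    X = spec.design(sub)
    return pgls(y, X, C, spec.names, spec=spec, lam_mode=lam_mode, lam=lam,
                species=sub.index, count_lambda=count_lambda)


def phylogenetic_signal(trait: pd.Series, tree: dendropy.Tree) -> float:
    """Pagel's lambda of one trait: ML lambda of the intercept-only PGLS."""
    vals = trait.dropna()
    if vals.nunique() <= 1:
        raise ValueError("constant trait: lambda undefined")
    if len(vals) < 3:
        raise ValueError("need at least 3 species")
    leaves = {lf.taxon.label for lf in tree.leaf_node_iter()}
    vals = vals[[sp in leaves for sp in vals.index]]
    C, taxa = phylo_covariance(tree, 1.0, taxa=list(vals.index))
    fit = pgls(vals.to_numpy(float), np.ones((len(vals), 1)), C,
               ["(intercept)"], species=vals.index)
    return fit.lam


# ---------------------------------------------------------------------------
# collinearity screen and model set
# ---------------------------------------------------------------------------

def vif_eliminate(design: pd.DataFrame, threshold: float = 3.0):
    """Sequential variance-inflation-factor elimination.

    VIF_j = 1 / (1 - R^2_j) from an ordinary (non-phylogenetic) regression
    of covariate j on the remaining covariates plus an intercept.  The
    largest VIF is dropped until all fall below ``threshold``.  Returns
    ``(retained, dropped_log, final_vifs)``; perfectly collinear columns
    report an infinite VIF.
    """
    cols = list(design.columns)
    if len(cols) < 2:
        raise ValueError("need at least 2 covariates to screen")
    data = design.dropna()
    dropped = []
    while len(cols) > 1:
        vifs = {}
        for c in cols:
            yv = data[c].to_numpy(float)
            Xv = np.column_stack([np.ones(len(data))] +
                                 [data[o].to_numpy(float) for o in cols if o != c])
            coef, _, _, _ = np.linalg.lstsq(Xv, yv, rcond=None)
            resid = yv - Xv @ coef
            tss = float(np.sum((yv - yv.mean()) ** 2))
            rss = float(np.sum(resid ** 2))
            if tss == 0:
                vifs[c] = np.inf
                continue
            r2 = 1.0 - rss / tss
            vifs[c] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
        worst = max(cols, key=lambda c: vifs[c])
        if vifs[worst] < threshold:
            return cols, dropped, vifs
        dropped.append((worst, vifs[worst]))
        cols = [c for c in cols if c != worst]
    return cols, dropped, {cols[0]: 1.0}


def enumerate_models(response: str, candidate_covariates,
                     interactions=()) -> list[ModelSpec]:
    """All covariate subsets (including intercept-only), interactions only
    alongside both their main effects."""
    candidates = list(candidate_covariates)
    specs = []
    for r in range(len(candidates) + 1):
        for subset in itertools.combinations(candidates, r):
            base = ModelSpec(response, subset)
            specs.append(base)
            present = set(subset)
            usable = [ia for ia in interactions
                      if set(ia.split(":")) <= present]
            for q in range(1, len(usable) + 1):
                for ias in itertools.combinations(usable, q):
                    specs.append(ModelSpec(response, subset + ias))
    return specs


# ---------------------------------------------------------------------------
# information-theoretic summary
# ---------------------------------------------------------------------------

def aicc_weights(fits, delta_max: float = 7.0) -> pd.DataFrame:
    """Delta AICc and Akaike weights over the full candidate set.

    Weights are normalized over *all* fits; the informative flag marks
    ``delta <= delta_max``.  All fits must share one species set.
    """
    fits = list(fits)
    if not fits:
        raise ValueError("no fits")
    if len({f.species for f in fits}) != 1:
        raise ValueError("fits are on different species sets")
    aicc = np.array([f.aicc for f in fits])
    delta = aicc - aicc.min()
    w = np.exp(-delta / 2.0)
    w /= w.sum()
    return pd.DataFrame({
        "covariates": [" + ".join(f.spec.covariates) or "(intercept only)"
                       for f in fits],
        "k": [f.k for f in fits],
        "loglik": [f.loglik for f in fits],
        "aicc": aicc,
        "delta": delta,
        "weight": w,
        "informative": delta <= delta_max,
        "r2": [f.r2 for f in fits],
        "lambda": [f.lam for f in fits],
    })


def model_average(fits, delta_max: float = 7.0,
                  ci_multiplier: float = 1.96) -> AveragedModel:
    """Natural model averaging over the informative set.

    Per covariate: the average of its slope over informative models that
    contain it, weighted by renormalized Akaike weights; the unconditional
    standard error combines within-model variance and between-model spread
    (``sum w_i * sqrt(se_i^2 + (b_i - bbar)^2)``).  The cumulative weight W
    sums full-set weights of every model containing the covariate.
    Covariates absent from all informative models are reported with W only.
    """
    fits = list(fits)
    table = aicc_weights(fits, delta_max=delta_max)
    weights = table["weight"].to_numpy()
    informative = table["informative"].to_numpy()
    if not informative.any():
        raise ValueError("informative set is empty")
    terms = sorted({t for f in fits for t in f.spec.names})
    beta, se, ci, W = {}, {}, {}, {}
    for term in terms:
        has = np.array([term in f.spec.names for f in fits])
        if term != "(intercept)":
            W[term] = float(weights[has].sum())
        use = has & informative
        if not use.any():
            continue
        wsub = weights[use]
        wsub = wsub / wsub.sum()
        bs = np.array([f.beta[term] for f, u in zip(fits, use) if u])
        ses = np.array([f.se[term] for f, u in zip(fits, use) if u])
        bbar = float(np.dot(wsub, bs))
        se_u = float(np.dot(wsub, np.sqrt(ses ** 2 + (bs - bbar) ** 2)))
        beta[term] = bbar
        se[term] = se_u
        ci[term] = (bbar - ci_multiplier * se_u, bbar + ci_multiplier * se_u)
    return AveragedModel(beta=beta, se=se, ci=ci, cumulative_weight=W,
                         table=table)


def tree_sample_intervals(spec: ModelSpec, data: pd.DataFrame, trees,
                          lam_mode: str = "ML") -> TreeSampleSummary:
    """Refit one model over a sample of dated trees.

    Per covariate, reports the mean slope over trees and a 95%
    phylogenetic-uncertainty interval from the 2.5th-97.5th percentiles,
    expressed as a half-width about the mean.  Trees missing required taxa
    are skipped with a warning.
    """
    trees = list(trees)
    if len(trees) < 2:
        raise ValueError("need at least 2 trees")
    needed = set(_align(spec, data, trees[0]).index) if trees else set()
    betas: dict[str, list[float]] = {nm: [] for nm in spec.names}
    used = 0
    for i, t in enumerate(trees):
        leaves = {lf.taxon.label for lf in t.leaf_node_iter()}
        sub = _align(spec, data, t)
        if needed and not needed <= leaves:
            warnings.warn(f"tree {i} misses taxa; skipped")
            continue
        try:
            fit = pgls_fit(spec, data, t, lam_mode=lam_mode)
        except ValueError as exc:
            warnings.warn(f"tree {i} skipped: {exc}")
            continue
        used += 1
        for nm in spec.names:
            betas[nm].append(fit.beta[nm])
        del sub
    if used < 2:
        raise ValueError("fewer than 2 usable trees")
    mean_beta, half, interval = {}, {}, {}
    for nm in spec.names:
        arr = np.array(betas[nm])
        m = float(arr.mean())
        lo, hi = np.percentile(arr, [2.5, 97.5])
        mean_beta[nm] = m
        half[nm] = float(max(hi - m, m - lo, 0.0))
        interval[nm] = (float(lo), float(hi))
    return TreeSampleSummary(mean_beta=mean_beta, half_width=half,
                             interval=interval, n_trees=used)


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def run_averaged_analysis(data: pd.DataFrame, tree: dendropy.Tree,
                          response: str, candidates, interactions=(),
                          vif_threshold: float = 3.0, delta_max: float = 7.0,
                          w_threshold: float = 0.4, trees=None,
                          lam_mode: str = "ML") -> dict:
    """One full regression analysis for one response.

    VIF-screens the candidate covariates, enumerates all models, fits each
    by PGLS with ML lambda on the consensus tree, averages the informative
    set, and (optionally) refits the covariates with cumulative weight
    above ``w_threshold`` over a tree sample for phylogenetic-uncertainty
    intervals.  Returns a dict with keys ``retained``, ``vif_dropped``,
    ``vifs``, ``specs``, ``fits``, ``table``, ``averaged`` and (when a tree
    sample is given) ``uncertainty``.
    """
    complete = data.dropna(subset=[response] + list(candidates))
    if len(candidates) >= 2:
        retained, vif_dropped, vifs = vif_eliminate(
            complete[list(candidates)], threshold=vif_threshold)
    else:
        retained, vif_dropped, vifs = list(candidates), [], {}
    interactions = [ia for ia in interactions
                    if set(ia.split(":")) <= set(retained)]
    specs = enumerate_models(response, retained, interactions)
    fits = [pgls_fit(s, complete, tree, lam_mode=lam_mode) for s in specs]
    averaged = model_average(fits, delta_max=delta_max)
    out = {
        "retained": retained, "vif_dropped": vif_dropped, "vifs": vifs,
        "specs": specs, "fits": fits, "table": averaged.table,
        "averaged": averaged,
    }
    if trees is not None:
        selected = tuple(c for c in retained + list(interactions)
                         if averaged.cumulative_weight.get(c, 0.0) > w_threshold)
        if selected:
            try:
                uspec = ModelSpec(response, selected)
            except ValueError:
                # an interaction passed the threshold without a main effect
                mains = {m for c in selected for m in c.split(":")}
                uspec = ModelSpec(response, tuple(sorted(mains | set(selected))))
            out["uncertainty"] = tree_sample_intervals(uspec, complete, trees,
                                                       lam_mode=lam_mode)
            out["uncertainty_spec"] = uspec
    return out
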