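"""Phylogenetic comparative methods.

Implements the statistics used to relate per-species range-shift responses to
the phylogeny and to traits:

* **Pagel's lambda** — ML estimate of the multiplier on off-diagonal entries
  of the Brownian-motion (BM) covariance, with a likelihood-ratio test
  against lambda = 0 (chi-square, 1 df).
* **Blomberg's K** — observed-vs-BM-expected ratio of mean squared error
  statistics, with a seeded tip-shuffling permutation test.
* **Ancestral character reconstruction** — ML (= GLS) estimates of internal
  node states under BM.
* **PGLS** — generalized least squares with residual covariance from a
  branch-length-transformed tree (lambda, kappa or delta family), the
  transformation parameter profiled by maximum likelihood.

All functions take a :class:`facetshift.trees.FacetTree`; the BM covariance
``C`` has ``C[i, j]`` = shared root-path length of tips i and j.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .trees import FacetTree

logger = logging.getLogger(__name__)

__all__ = [
    "SignalResult", "pagel_lambda", "blomberg_k",
    "AncestralStates", "ancestral_reconstruction",
    "PGLS", "pgls", "run_comparative_suite",
]


# --------------------------------------------------------------------------- core GLS

def _gls_mean_rate(x: np.ndarray, v: np.ndarray) -> tuple[float, float, float]:
    """Profiled BM root mean, ML rate and log-likelihood for covariance v.

    Returns (mu_hat, sigma2_ml, loglik).
    """
    n = x.size
    chol = np.linalg.cholesky(v)
    one = np.ones(n)
    wi_x = np.linalg.solve(chol, x)  # whitened data
    wi_1 = np.linalg.solve(chol, one)
    mu = float(wi_1 @ wi_x / (wi_1 @ wi_1))
    resid = wi_x - mu * wi_1
    sigma2 = float(resid @ resid) / n
    logdet = 2.0 * np.log(np.diag(chol)).sum()
    loglik = -0.5 * (n * np.log(2.0 * np.pi * sigma2) + logdet + n)
    return mu, sigma2, loglik


def lambda_transform(c: np.ndarray, lam: float) -> np.ndarray:
    """Scale off-diagonal covariances by lambda, keep the diagonal."""
    out = c * lam
    np.fill_diagonal(out, np.diag(c))
    return out


def lambda_upper_bound(c: np.ndarray) -> float:
    """Largest lambda keeping every off-diagonal entry below both involved
    diagonals (necessary for a valid covariance; equals max tip depth over
    max node depth for ultrametric trees, hence >= 1)."""
    d = np.diag(c)
    off = c.copy()
    np.fill_diagonal(off, 0.0)
    pair_min = np.minimum(d[:, None], d[None, :])
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = np.where(off > 0, pair_min / off, np.inf)
    bound = float(ratios.min())
    return min(bound, 10.0) if np.isfinite(bound) else 1.0


@dataclass
class SignalResult:
    """Result of a phylogenetic-signal test."""

    statistic: str  # "lambda" or "K"
    estimate: float
    p_value: float
    loglik: float | None = None
    loglik_null: float | None = None
    n_permutations: int | None = None
    flat_likelihood: bool = False
    details: dict = field(default_factory=dict)


def pagel_lambda(tree: FacetTree, trait) -> SignalResult:
    """ML estimate of Pagel's lambda with a likelihood-ratio test vs 0.

    The BM rate and root mean are profiled analytically at each lambda; the
    search runs over [0, lambda_max] where lambda_max is computed from the
    covariance so it stays valid (1 for an ultrametric tree with the deepest
    split at the root).
    """
    x = np.asarray(trait, dtype=float)
    if x.size != tree.n_tips:
        raise ValueError("trait length must equal the number of tips")
    if tree.n_tips < 4:
        raise ValueError("need at least 4 tips")
    if np.ptp(x) == 0:
        raise ValueError("trait is constant: signal undefined")
    c = tree.cov_matrix()

    def negloglik(lam: float) -> float:
        v = lambda_transform(c, lam)
        try:
            return -_gls_mean_rate(x, v)[2]
        except np.linalg.LinAlgError:
            return np.inf

    lam_max = lambda_upper_bound(c)
    ll0 = -negloglik(0.0)
    if not np.isfinite(ll0):
        raise ValueError("non-finite likelihood; check for zero-length duplicate tips")

    # star tree: off-diagonals are all zero, the likelihood is flat in lambda
    off = c.copy()
    np.fill_diagonal(off, 0.0)
    if np.all(off == 0):
        return SignalResult("lambda", 0.0, 1.0, loglik=ll0, loglik_null=ll0,
                            flat_likelihood=True)

    res = optimize.minimize_scalar(negloglik, bounds=(0.0, lam_max), method="bounded",
                                   options={"xatol": 1e-6})
    cands = [(0.0, ll0), (float(res.x), -res.fun)]
    if lam_max >= 1.0:
        cands.append((1.0, -negloglik(1.0)))
    cands.append((lam_max, -negloglik(lam_max)))
    lam_hat, ll_hat = max(cands, key=lambda t: t[1])
    lr = max(0.0, 2.0 * (ll_hat - ll0))
    p = float(stats.chi2.sf(lr, df=1))
    return SignalResult("lambda", float(lam_hat), p, loglik=ll_hat, loglik_null=ll0,
                        details={"lambda_max": lam_max})


def _k_statistic_many(x: np.ndarray, c_inv: np.ndarray, expected_ratio: float) -> np.ndarray:
    """Blomberg's K for each column of x (n x B)."""
    n = x.shape[0]
    one = np.ones(n)
    ci1 = c_inv @ one
    denom = float(one @ ci1)
    ahat = (ci1 @ x) / denom  # (B,)
    d = x - ahat[None, :]
    mse0 = (d * d).sum(axis=0) / (n - 1)
    mse = (d * (c_inv @ d)).sum(axis=0) / (n - 1)
    return (mse0 / mse) / expected_ratio


def blomberg_k(tree: FacetTree, trait, n_permutations: int = 1000,
               seed: int = 0) -> SignalResult:
    """Blomberg's K with a tip-shuffling permutation test.

    K is the ratio MSE0/MSE (deviation from the phylogenetic mean over the
    GLS rate) standardised by its BM expectation
    ``(tr C - n / (1' C^-1 1)) / (n - 1)``; K = 1 is the BM expectation,
    K << 1 means less signal than BM.  The p-value is the fraction of
    tip permutations with K at least as large as observed (add-one rule).
    """
    x = np.asarray(trait, dtype=float)
    if x.size != tree.n_tips:
        raise ValueError("trait length must equal the number of tips")
    if tree.n_tips < 4:
        raise ValueError("need at least 4 tips")
    if np.ptp(x) == 0:
        raise ValueError("trait is constant: K undefined")
    c = tree.cov_matrix()
    n = x.size
    c_inv = np.linalg.inv(c)
    one = np.ones(n)
    expected = (np.trace(c) - n / float(one @ c_inv @ one)) / (n - 1)
    k_obs = float(_k_statistic_many(x[:, None], c_inv, expected)[0])

    rng = np.random.default_rng(seed)
    perms = np.empty((n, n_permutations))
    for b in range(n_permutations):
        perms[:, b] = x[rng.permutation(n)]
    k_null = _k_statistic_many(perms, c_inv, expected)
    p = float((1 + (k_null >= k_obs).sum()) / (n_permutations + 1))
    return SignalResult("K", k_obs, p, n_permutations=n_permutations,
                        details={"expected_ratio": expected})


# ----------------------------------------------------------- ancestral states

@dataclass
class AncestralStates:
    """ML internal-node states under Brownian motion."""

    node_ids: np.ndarray        # internal node indices of the tree
    estimates: np.ndarray
    variances: np.ndarray
    root_estimate: float
    sigma2: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"node": self.node_ids, "estimate": self.estimates,
                             "variance": self.variances})


def ancestral_reconstruction(tree: FacetTree, trait) -> AncestralStates:
    """GLS/ML reconstruction of continuous ancestral states under BM.

    Internal node u gets ``mu + Cov(u, tips) V^-1 (x - mu)`` with mu the GLS
    root mean; the reported variance is the GLS prediction variance including
    the uncertainty of mu.  The root estimate equals mu exactly.
    """
    x = np.asarray(trait, dtype=float)
    if x.size != tree.n_tips:
        raise ValueError("trait length must equal the number of tips")
    c = tree.cov_matrix()
    mu, sigma2, _ = _gls_mean_rate(x, c)
    n = tree.n_tips

    anc = tree.ancestor_edges().astype(float)  # (M, M) node x edge
    wl = tree.lengths
    internal = np.arange(n, tree.n_nodes)
    # cov(node u, tip j) = sum of edge lengths shared by both root paths
    cov_nt = (anc[internal] * wl[None, :]) @ anc[:n].T  # (n_internal, n)
    depths = tree.node_depths()

    v_inv = np.linalg.inv(c)
    one = np.ones(n)
    resid = x - mu
    est = mu + cov_nt @ (v_inv @ resid)

    # prediction variance with estimated mean:
    # sigma2 * [ d_u - q' V^-1 q + (1 - 1'V^-1 q)^2 / (1'V^-1 1) ]
    vi1 = v_inv @ one
    s11 = float(one @ vi1)
    quad = np.einsum("ij,jk,ik->i", cov_nt, v_inv, cov_nt)
    lin = cov_nt @ vi1
    var = sigma2 * (depths[internal] - quad + (1.0 - lin) ** 2 / s11)
    if np.ptp(x) == 0:
        est = np.full(internal.size, x[0])
    return AncestralStates(internal, est, np.maximum(var, 0.0), mu, sigma2)


# ------------------------------------------------------------------------ PGLS

_TRANSFORM_BOUNDS = {"lambda": None, "kappa": (0.0, 3.0), "delta": (0.0, 3.0)}


def _transformed_cov(tree: FacetTree, c: np.ndarray, family: str, param: float) -> np.ndarray:
    if family == "lambda":
        return lambda_transform(c, param)
    if family == "kappa":
        b = tree.tip_sets().astype(float)
        lk = np.where(tree.lengths > 0, tree.lengths, 0.0) ** param
        lk[tree.lengths == 0] = 0.0  # 0^0 := 0 (zero branches carry no time)
        return b.T @ (lk[:, None] * b)
    if family == "delta":
        with np.errstate(invalid="ignore"):
            out = np.where(c > 0, c, 0.0) ** param
        out[c == 0] = 0.0
        return out
    raise ValueError(f"unknown transform family {family!r}")


class PGLS:
    """Phylogenetic generalized least squares, sklearn-style.

    Parameters
    ----------
    tree : FacetTree
        Phylogeny covering all rows of X/y (tip order = row order).
    transform : {"lambda", "kappa", "delta", "best", "none"}
        Branch-length transformation family; ``"best"`` profiles all three
        and keeps the ML winner, ``"none"`` uses the raw BM covariance.
    grid_points : int
        Coarse ML grid size for the transformation parameter before local
        (bounded scalar) refinement.

    Attributes (after ``fit``)
    --------------------------
    coef_, intercept_, params_ : coefficient estimates (params_ includes the
        intercept first), se_, tvalues_, pvalues_, loglik_, transform_family_,
        transform_param_, sigma2_, df_resid_.
    """

    def __init__(self, tree: FacetTree, transform: str = "lambda", grid_points: int = 51):
        self.tree = tree
        self.transform = transform
        self.grid_points = grid_points

    def get_params(self, deep: bool = True) -> dict:
        return {"tree": self.tree, "transform": self.transform,
                "grid_points": self.grid_points}

    def set_params(self, **params) -> "PGLS":
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"invalid parameter {k!r}")
            setattr(self, k, v)
        return self

    # ------------------------------------------------------------------ fitting
    @staticmethod
    def _gls_fit(xmat: np.ndarray, y: np.ndarray, v: np.ndarray):
        """GLS fit via whitening; returns (beta, loglik_ml, sigma2_unbiased, cov_beta)."""
        n, p = xmat.shape
        if n <= p:
            raise ValueError(f"saturated design: {n} observations for {p} parameters")
        chol = np.linalg.cholesky(v)
        xw = np.linalg.solve(chol, xmat)
        yw = np.linalg.solve(chol, y)
        beta, *_ = np.linalg.lstsq(xw, yw, rcond=None)
        resid = yw - xw @ beta
        rss = float(resid @ resid)
        sigma2_ml = rss / n
        logdet = 2.0 * np.log(np.diag(chol)).sum()
        loglik = -0.5 * (n * np.log(2.0 * np.pi * sigma2_ml) + logdet + n)
        sigma2 = rss / (n - p)
        xtx_inv = np.linalg.inv(xw.T @ xw)
        return beta, loglik, sigma2, sigma2 * xtx_inv

    def _check_design(self, xmat: np.ndarray, names: list[str]) -> None:
        rank = np.linalg.matrix_rank(xmat)
        if rank < xmat.shape[1]:
            # name the offending columns via the small QR diagonal entries
            _, rr = np.linalg.qr(xmat)
            diag = np.abs(np.diag(rr))
            tol = diag.max() * max(xmat.shape) * np.finfo(float).eps
            bad = [names[j] for j in range(xmat.shape[1]) if diag[j] < tol] or names
            raise ValueError(f"singular design matrix; collinear columns involve: {bad}")

    def fit(self, X, y) -> "PGLS":
        xraw = np.asarray(X, dtype=float)
        if xraw.ndim == 1:
            xraw = xraw[:, None]
        y = np.asarray(y, dtype=float)
        n = y.size
        if xraw.shape[0] != n or n != self.tree.n_tips:
            raise ValueError("X/y rows must match the number of tree tips")
        names = list(getattr(X, "columns", [f"x{j}" for j in range(xraw.shape[1])]))
        xmat = np.column_stack([np.ones(n), xraw])
        self._check_design(xmat, ["(Intercept)"] + names)

        c = self.tree.cov_matrix()
        families = ([self.transform] if self.transform in ("lambda", "kappa", "delta")
                    else ["lambda", "kappa", "delta"] if self.transform == "best"
                    else [])
        best = None
        if not families:  # "none": raw BM covariance
            beta, ll, s2, covb = self._gls_fit(xmat, y, c)
            best = ("none", 1.0, beta, ll, s2, covb)
        for family in families:
            # lambda capped at 1: past it the covariance approaches
            # singularity and the profile likelihood degenerates (the
            # regression can absorb the near-null direction)
            bounds = _TRANSFORM_BOUNDS[family] or (0.0, min(1.0, lambda_upper_bound(c)))

            def nll(theta: float, fam=family) -> float:
                v = _transformed_cov(self.tree, c, fam, theta)
                try:
                    return -self._gls_fit(xmat, y, v)[1]
                except np.linalg.LinAlgError:
                    return np.inf

            grid = np.linspace(bounds[0], bounds[1], self.grid_points)
            vals = np.array([nll(t) for t in grid])
            j = int(np.argmin(vals))
            lo = grid[max(j - 1, 0)]
            hi = grid[min(j + 1, grid.size - 1)]
            if hi > lo:
                res = optimize.minimize_scalar(nll, bounds=(lo, hi), method="bounded",
                                               options={"xatol": 1e-6})
                theta, ll = float(res.x), -float(res.fun)
                if vals[j] < res.fun:  # keep the grid point if refinement stalled
                    theta, ll = float(grid[j]), -float(vals[j])
            else:
                theta, ll = float(grid[j]), -float(vals[j])
            v = _transformed_cov(self.tree, c, family, theta)
            beta, ll, s2, covb = self._gls_fit(xmat, y, v)
            if best is None or ll > best[3]:
                best = (family, theta, beta, ll, s2, covb)

        family, theta, beta, ll, s2, covb = best
        self.transform_family_ = family
        self.transform_param_ = theta
        self.params_ = beta
        self.intercept_ = float(beta[0])
        self.coef_ = beta[1:]
        self.se_ = np.sqrt(np.diag(covb))
        self.sigma2_ = s2
        self.loglik_ = ll
        self.df_resid_ = n - xmat.shape[1]
        with np.errstate(divide="ignore", invalid="ignore"):
            self.tvalues_ = beta / self.se_
        self.pvalues_ = 2.0 * stats.t.sf(np.abs(self.tvalues_), self.df_resid_)
        self.feature_names_in_ = names
        return self

    def predict(self, X) -> np.ndarray:
        x = np.asarray(X, dtype=float)
        if x.ndim == 1:
            x = x[:, None]
        return self.intercept_ + x @ self.coef_

    def summary(self) -> pd.DataFrame:
        """Coefficient table (estimate, SE, t, p)."""
        return pd.DataFrame(
            {
                "Estimate": self.params_,
                "Std. Error": self.se_,
                "t value": self.tvalues_,
                "Pr(>|t|)": self.pvalues_,
            },
            index=["(Intercept)"] + self.feature_names_in_,
        )

    def conf_int(self, alpha: float = 0.05) -> np.ndarray:
        half = stats.t.ppf(1 - alpha / 2, self.df_resid_) * self.se_
        return np.column_stack([self.params_ - half, self.params_ + half])


def pgls(tree: FacetTree, response, predictors, transform: str = "best") -> PGLS:
    """Functional wrapper over :class:`PGLS`."""
    return PGLS(tree, transform=transform).fit(predictors, response)


# ------------------------------------------------------------------ full suite

PGLS_PREDICTORS = ["body_length_mm", "flight_months", "lentic", "lotic"]
RESPONSES = ["relative_area_change", "altitude_difference", "centroid_difference"]


def _prune_design(xdf: pd.DataFrame) -> pd.DataFrame:
    """Drop predictor columns that would make the design (with intercept)
    singular — constant columns first, then any column that fails to raise
    the design rank.  Mirrors excluding collinear traits from the models."""
    n = len(xdf)
    kept: list[str] = []
    design = np.ones((n, 1))
    for col in xdf.columns:
        v = xdf[col].to_numpy(dtype=float)
        cand = np.column_stack([design, v])
        if np.linalg.matrix_rank(cand) > design.shape[1]:
            design = cand
            kept.append(col)
        else:
            logger.info("pgls design: dropping collinear/constant column %r", col)
    return xdf[kept]


def run_comparative_suite(
    shift_table: pd.DataFrame,
    trait_table: pd.DataFrame,
    tree: FacetTree,
    subsets: dict[str, list[str]] | None = None,
    responses: list[str] | None = None,
    n_permutations: int = 1000,
    seed: int = 0,
    transform: str = "best",
) -> dict[str, pd.DataFrame]:
    """Signal statistics and PGLS for every response x scenario x period and
    clade subset.

    Parameters
    ----------
    shift_table : tidy DataFrame with columns species, scenario, period and
        the response columns.
    trait_table : indexed by species, providing the PGLS predictors
        (body length, flight months, lentic, lotic).
    subsets : name -> species list; default one stratum "all" with every
        species in the tree.  Subsets with < 4 species are skipped.

    Returns
    -------
    dict with DataFrames ``signal`` (lambda and K rows) and ``pgls``
    (coefficient rows mirroring the usual PGLS output table).
    """
    responses = responses or [r for r in RESPONSES if r in shift_table.columns]
    subsets = subsets or {"all": list(tree.tip_labels)}
    signal_rows = []
    pgls_rows = []
    skipped: list[str] = []
    for stratum, members in subsets.items():
        members = [m for m in members if m in tree.tip_labels]
        if len(members) < 4:
            logger.info("comparative: skipping stratum %r (<4 species)", stratum)
            skipped.append(stratum)
            continue
        sub_tree = tree.prune(members) if set(members) != set(tree.tip_labels) else tree
        order = sub_tree.tip_labels
        for (scenario, period), grp in shift_table.groupby(["scenario", "period"]):
            grp = grp.set_index("species")
            usable = [s for s in order if s in grp.index and s in trait_table.index]
            if len(usable) < 4:
                continue
            t = sub_tree.prune(usable) if set(usable) != set(order) else sub_tree
            xdf = trait_table.loc[t.tip_labels, PGLS_PREDICTORS].astype(float)
            for resp in responses:
                yv = grp.loc[t.tip_labels, resp].to_numpy(dtype=float)
                if np.isnan(yv).any() or np.ptp(yv) == 0:
                    continue
                x_use = _prune_design(xdf)
                lam = pagel_lambda(t, yv)
                kres = blomberg_k(t, yv, n_permutations=n_permutations, seed=seed)
                for r in (lam, kres):
                    signal_rows.append({
                        "stratum": stratum, "scenario": scenario, "period": period,
                        "response": resp, "statistic": r.statistic,
                        "estimate": r.estimate, "p_value": r.p_value,
                    })
                if x_use.shape[1] == 0 or len(yv) < x_use.shape[1] + 2:
                    logger.info("pgls: skipping %s/%s/%s/%s (too few species "
                                "for the design)", stratum, scenario, period, resp)
                    continue
                fit = PGLS(t, transform=transform).fit(x_use, yv)
                tab = fit.summary().reset_index(names="term")
                tab["Res. variable"] = resp
                tab["Scenario"] = scenario
                tab["Time period"] = period
                tab["stratum"] = stratum
                tab["transform"] = fit.transform_family_
                tab["transform_param"] = fit.transform_param_
                pgls_rows.append(tab)
    return {
        "signal": pd.DataFrame(signal_rows),
        "pgls": pd.concat(pgls_rows, ignore_index=True) if pgls_rows else pd.DataFrame(),
        "skipped_strata": skipped,
    }
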