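"""Maximum-likelihood fitting and model comparison for trait evolution.

``fit_bm`` is closed form (GLS root mean, ML rate with divisor n).
``fit_ou`` and ``fit_eb`` profile the analytic (root, rate) out of the
likelihood and optimize the single remaining shape parameter (``alpha``
or ``r``) on a log/linear grid refined by bounded scalar minimization.
``fit_jn`` optimizes (sigma2, jump_rate, jump_var, root) by Nelder-Mead
on log-transformed scale parameters with multiple moment-based restarts.

Model support is summarized by Akaike weights
``w_i = exp(-D_i/2) / sum_j exp(-D_j/2)`` with ``D_i = AIC_i - min AIC``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize, minimize_scalar

from venomdyn.core_io import Phylogeny
from venomdyn.errors import NotUltrametricError
from venomdyn.phylo.likelihoods import (
    bm_loglik,
    bm_prune,
    eb_covariance,
    mvn_loglik,
    ou_covariance,
)
from venomdyn.phylo.jumpnormal import jn_loglik

__all__ = [
    "ModelParams",
    "ModelFit",
    "fit_bm",
    "fit_ou",
    "fit_eb",
    "fit_jn",
    "fit_all",
    "aic_weights",
    "pagel_lambda",
]


@dataclass
class ModelParams:
    """Parameters of one trait-evolution model.

    Only the fields relevant to ``model`` are set: BM uses (sigma2,
    root); OU adds (alpha, theta) with the root fixed at theta; EB adds
    the rate-decay exponent r <= 0; JN adds the jump rate (jumps per unit
    time) and jump variance.
    """

    model: str  # BM | OU | EB | JN
    sigma2: float = np.nan
    alpha: float = np.nan
    theta: float = np.nan
    r: float = np.nan
    jump_rate: float = np.nan
    jump_var: float = np.nan
    root: float = np.nan

    def __post_init__(self) -> None:
        if self.model not in {"BM", "OU", "EB", "JN"}:
            raise ValueError(f"unknown model {self.model!r}")


@dataclass
class ModelFit:
    """A fitted model: parameters, log-likelihood, AIC and Akaike weight."""

    params: ModelParams
    loglik: float
    k: int
    degenerate: bool = False
    weight: float = field(default=np.nan)

    @property
    def aic(self) -> float:
        return 2.0 * self.k - 2.0 * self.loglik

    @property
    def model(self) -> str:
        return self.params.model


def _gls_mean_rate(x: np.ndarray, cov: np.ndarray) -> tuple[float, float, float]:
    """GLS mean, ML rate (divisor n), and profile loglik for V = rate * cov."""
    n = len(x)
    cf = cho_factor(cov, lower=True)
    one = np.ones(n)
    ci1 = cho_solve(cf, one)
    a = float(ci1 @ x) / float(ci1 @ one)
    d = x - a
    ss = float(d @ cho_solve(cf, d))
    rate = ss / n
    logdet = 2.0 * np.sum(np.log(np.diag(cf[0])))
    if rate <= 0:
        return a, 0.0, np.nan
    ll = -0.5 * (n * np.log(2 * np.pi) + n * np.log(rate) + logdet + n)
    return a, rate, ll


def fit_bm(trait: np.ndarray, tree: Phylogeny) -> ModelFit:
    """Closed-form ML Brownian fit: GLS root, rate with ML divisor n; k = 2."""
    x = np.asarray(trait, float)
    n = tree.n_tips
    if n < 3:
        raise ValueError("BM fit needs at least 3 tips")
    ss, logdet, a = bm_prune(x, tree)
    sigma2 = ss / n
    if sigma2 <= 0:
        warnings.warn("constant trait: BM fit degenerate (sigma2 = 0)")
        return ModelFit(ModelParams("BM", sigma2=0.0, root=a), np.nan, 2, degenerate=True)
    ll = bm_loglik(x, tree, sigma2, a)
    return ModelFit(ModelParams("BM", sigma2=sigma2, root=a), ll, 2)


def _profile_fit_1d(
    x: np.ndarray,
    cov_fn,
    grid: np.ndarray,
    bounds: tuple[float, float],
) -> tuple[float, float, float, float]:
    """Maximize the (root, rate)-profiled loglik over one shape parameter.

    Returns (shape, root, rate, loglik)."""

    def negprof(s: float) -> float:
        try:
            _, _, ll = _gls_mean_rate(x, cov_fn(s))
        except np.linalg.LinAlgError:
            return np.inf
        return np.inf if np.isnan(ll) else -ll

    grid = np.sort(np.asarray(grid, float))
    vals = np.array([negprof(s) for s in grid])
    i = int(np.argmin(vals))
    lo = grid[i - 1] if i > 0 else bounds[0]
    hi = grid[i + 1] if i + 1 < len(grid) else bounds[1]
    best = grid[i]
    res = minimize_scalar(negprof, bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-10})
    shape = float(res.x) if res.fun <= vals.min() else float(best)
    a, rate, ll = _gls_mean_rate(x, cov_fn(shape))
    return shape, a, rate, ll


def fit_ou(trait: np.ndarray, tree: Phylogeny) -> ModelFit:
    """ML Ornstein-Uhlenbeck fit with the root fixed at the optimum; k = 3.

    alpha is profiled on a log grid spanning [1e-4/T, 50/T] and refined by
    bounded minimization; theta and sigma2 are closed form given alpha.
    """
    if not tree.is_ultrametric():
        raise NotUltrametricError("OU fit requires an ultrametric tree")
    x = np.asarray(trait, float)
    T = tree.height
    grid = np.geomspace(1e-4 / T, 50.0 / T, 40)
    alpha, theta, sigma2, ll = _profile_fit_1d(
        x, lambda a: ou_covariance(tree, 1.0, a), grid, (1e-6 / T, 200.0 / T)
    )
    params = ModelParams("OU", sigma2=sigma2, alpha=alpha, theta=theta, root=theta)
    return ModelFit(params, ll, 3, degenerate=sigma2 <= 0)


def fit_eb(trait: np.ndarray, tree: Phylogeny) -> ModelFit:
    """ML early-burst fit (r <= 0); k = 3. The r = 0 limit is BM."""
    if not tree.is_ultrametric():
        raise NotUltrametricError("EB fit requires an ultrametric tree")
    x = np.asarray(trait, float)
    T = tree.height
    grid = -np.geomspace(1e-6 / T, 10.0 / T, 30)
    grid = np.append(grid, 0.0)
    r, a, sigma2, ll = _profile_fit_1d(
        x, lambda r_: eb_covariance(tree, 1.0, r_), grid, (-20.0 / T, 0.0)
    )
    # the profile is continuous at r = 0; prefer the BM limit when equal
    _, _, ll0 = _gls_mean_rate(x, eb_covariance(tree, 1.0, 0.0))
    if ll0 >= ll - 1e-12:
        r = 0.0
        a, sigma2, ll = _gls_mean_rate(x, eb_covariance(tree, 1.0, 0.0))
    params = ModelParams("EB", sigma2=sigma2, r=r, root=a)
    return ModelFit(params, ll, 3, degenerate=sigma2 <= 0)


def fit_jn(
    trait: np.ndarray,
    tree: Phylogeny,
    n_restarts: int = 3,
    maxfev: int = 150,
    seed: int | None = None,
) -> ModelFit:
    """ML jump-normal (pulsed) fit over (sigma2, jump_rate, jump_var, root); k = 4.

    A coarse scan over jump rates and drift/jump variance splits (at the
    BM root and total rate) seeds derivative-free Nelder-Mead on
    (log sigma2, log jump_rate, log jump_var, root). A tree with >= 8
    tips is recommended for identifiability.
    """
    if not tree.is_ultrametric():
        raise NotUltrametricError("JN fit requires an ultrametric tree")
    x = np.asarray(trait, float)
    T = tree.height
    bm = fit_bm(x, tree)
    if bm.degenerate:
        return ModelFit(
            ModelParams("JN", sigma2=0.0, jump_rate=0.0, jump_var=0.0, root=bm.params.root),
            np.nan, 4, degenerate=True,
        )
    s2_bm, a0 = bm.params.sigma2, bm.params.root

    # identifiability bound: beyond ~10 expected jumps per tree height the
    # pulsed process is statistically indistinguishable from BM
    lam_cap = 10.0 / T

    def negll(p: np.ndarray) -> float:
        s2, lam, dv = np.exp(p[0]), np.exp(p[1]), np.exp(p[2])
        if not np.isfinite(s2 + lam + dv) or lam > lam_cap:
            return np.inf
        return -jn_loglik(x, tree, s2, lam, dv, p[3])

    rng = np.random.default_rng(seed)
    # candidate scan: split the BM total rate between drift and jumps at
    # several jump rates, keeping (root, total variance) at their BM values
    candidates = []
    for lam0 in (0.5 / T, 2.0 / T, 6.0 / T):
        for frac in (0.2, 0.5, 0.8):
            dv0 = (1 - frac) * s2_bm / lam0
            candidates.append([np.log(frac * s2_bm), np.log(lam0), np.log(dv0), a0])
    for _ in range(max(0, n_restarts - 1)):
        candidates.append(
            [
                np.log(s2_bm * rng.uniform(0.05, 1.0)),
                np.log(rng.uniform(0.2, 8.0) / T),
                np.log(s2_bm * T * rng.uniform(0.5, 20.0)),
                a0 + rng.normal(0, np.sqrt(s2_bm * T) / 4),
            ]
        )
    scores = [negll(np.asarray(c)) for c in candidates]
    order = np.argsort(scores)
    # flat surfaces (no jump signal above the BM submodel) need only a short
    # polish in the identifiable low-rate region; clearly pulsed data gets
    # the full budget over the whole range
    flat = min(scores) >= -bm.loglik - 1.0
    if flat:
        lam_cap = 3.0 / T
    budget = max(40, maxfev // 3) if flat else maxfev
    best = None
    for idx in order[: max(1, n_restarts - 2)]:
        res = minimize(
            negll, np.asarray(candidates[idx]), method="Nelder-Mead",
            options={"maxfev": budget, "fatol": 1e-8, "xatol": 1e-6},
        )
        if best is None or res.fun < best.fun:
            best = res
    p = best.x
    ll = -best.fun
    # never report a JN likelihood below its own BM submodel (jump_rate -> 0)
    if ll < bm.loglik:
        p = np.array([np.log(s2_bm), -np.inf, np.log(s2_bm * T), a0])
        ll = bm.loglik
    params = ModelParams(
        "JN",
        sigma2=float(np.exp(p[0])),
        jump_rate=float(np.exp(p[1])),
        jump_var=float(np.exp(p[2])),
        root=float(p[3]),
    )
    return ModelFit(params, float(ll), 4)


def aic_weights(fits: list[ModelFit]) -> list[ModelFit]:
    """Fill in Akaike weights across a compared set of fits (in place)."""
    aics = np.array([f.aic for f in fits])
    delta = aics - np.nanmin(aics)
    w = np.exp(-delta / 2.0)
    w = w / np.nansum(w)
    for f, wi in zip(fits, w):
        f.weight = float(wi)
    return fits


def fit_all(
    trait: np.ndarray,
    tree: Phylogeny,
    models: tuple[str, ...] = ("BM", "OU", "EB", "JN"),
    seed: int | None = None,
) -> list[ModelFit]:
    """Fit the requested models to one trait and attach Akaike weights."""
    dispatch = {
        "BM": lambda: fit_bm(trait, tree),
        "OU": lambda: fit_ou(trait, tree),
        "EB": lambda: fit_eb(trait, tree),
        "JN": lambda: fit_jn(trait, tree, seed=seed),
    }
    fits = [dispatch[m]() for m in models]
    return aic_weights(fits)


def pagel_lambda(trait: np.ndarray, tree: Phylogeny) -> tuple[float, float]:
    """ML Pagel's lambda phylogenetic signal; returns (lambda_hat, loglik).

    C_lambda scales the off-diagonal shared paths by lambda, searched over
    [0, lambda_max] where lambda_max keeps C_lambda positive definite
    (lambda_max >= 1 on ultrametric trees). lambda = 0 is a star tree (no
    signal), lambda = 1 recovers BM.
    """
    x = np.asarray(trait, float)
    if tree.n_tips < 4:
        raise ValueError("Pagel's lambda needs at least 4 tips")
    C = tree.shared_path_matrix()
    diag = np.diag(C).copy()

    def c_lambda(lam: float) -> np.ndarray:
        M = lam * C
        np.fill_diagonal(M, diag)
        return M

    def is_pd(lam: float) -> bool:
        try:
            cho_factor(c_lambda(lam), lower=True)
            return True
        except np.linalg.LinAlgError:
            return False

    # find the PD boundary above 1 by bisection
    hi = 1.0
    off = C[~np.eye(len(C), dtype=bool)]
    cap = diag.max() / off.max() if off.max() > 0 else 1.0
    cap = max(cap, 1.0)
    if is_pd(cap):
        lam_max = cap
    else:
        lo = 1.0
        hi = cap
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            if is_pd(mid):
                lo = mid
            else:
                hi = mid
        lam_max = lo
    lam, _, _, ll = _profile_fit_1d(
        x, c_lambda, np.linspace(0.0, lam_max * 0.999, 25), (0.0, lam_max * 0.999)
    )
    return float(lam), float(ll)
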