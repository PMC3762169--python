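"""Weighted mixtures of von Mises-Fisher distributions on the unit sphere.

The von Mises-Fisher (vMF) density on S^2 is

    f(x | mu, kappa) = c3(kappa) * exp(kappa * mu^T x),
    c3(kappa) = kappa / (4 pi sinh kappa),

the canonical unimodal distribution for directional data: mu is the mean
direction and kappa >= 0 the concentration (kappa = 0 is the uniform
sphere).  Mixtures are fitted by weighted expectation-maximization with
spherical k-means++ seeding, and the number of components is selected by
the Bayesian Information Criterion

    BIC = -2 * loglik + p * log(n_eff),    p = 4k - 1,

where n_eff is the total data weight and p counts 2 angles per mean
direction, one concentration per component and k - 1 free mixing weights.

Numerical notes: log c3 is evaluated in the log domain so large kappa
never overflows; kappa estimates use the Banerjee et al. approximation
kappa = rbar (3 - rbar^2) / (1 - rbar^2) and are capped at KAPPA_MAX = 700.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "VMFComponent",
    "VMFMixtureFit",
    "vmf_logpdf",
    "log_c3",
    "fit_movMF",
    "select_k_bic",
    "sample_vmf",
    "KAPPA_MAX",
]

LOG_4PI = np.log(4.0 * np.pi)
KAPPA_MAX = 700.0


@dataclass(frozen=True)
class VMFComponent:
    """One mixture component: mean direction, concentration, mixing weight."""

    mu: np.ndarray
    kappa: float
    alpha: float

    def __post_init__(self) -> None:
        mu = np.asarray(self.mu, dtype=float)
        if abs(np.linalg.norm(mu) - 1.0) > 1e-9:
            raise ValueError("component mean direction must be unit norm")
        if self.kappa < 0:
            raise ValueError("concentration kappa must be non-negative")
        object.__setattr__(self, "mu", mu)


@dataclass
class VMFMixtureFit:
    """A fitted vMF mixture with its log-likelihood and BIC."""

    components: list
    loglik: float
    bic: float
    n_effective: float
    converged: bool
    seed: int | None
    n_iter: int = 0
    kappa_capped: bool = False
    #: per-iteration log-likelihood trace of the winning restart
    history: list = field(default_factory=list, repr=False)

    @property
    def k(self) -> int:
        return len(self.components)

    def to_json(self) -> str:
        d = {
            "components": [
                {"mu": c.mu.tolist(), "kappa": c.kappa, "alpha": c.alpha} for c in self.components
            ],
            "loglik": self.loglik,
            "bic": self.bic,
            "n_effective": self.n_effective,
            "converged": self.converged,
            "seed": self.seed,
            "n_iter": self.n_iter,
            "kappa_capped": self.kappa_capped,
        }
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, s: str) -> "VMFMixtureFit":
        d = json.loads(s)
        comps = [VMFComponent(np.array(c["mu"]), c["kappa"], c["alpha"]) for c in d.pop("components")]
        return cls(components=comps, **d)


def log_c3(kappa) -> np.ndarray:
    """log of the S^2 vMF normalizing constant, stable for any kappa >= 0.

    log c3 = log kappa - log(4 pi) - kappa - log((1 - e^{-2 kappa}) / 2);
    the kappa -> 0 limit is log(1 / 4 pi).
    """
    kappa = np.asarray(kappa, dtype=float)
    if np.any(kappa < 0):
        raise ValueError("kappa must be non-negative")
    out = np.full(kappa.shape, -LOG_4PI)
    small = kappa < 1e-8
    k = np.where(small, 1.0, kappa)  # placeholder to avoid log(0)
    val = np.log(k) - LOG_4PI - k - np.log1p(-np.exp(-2.0 * k)) + np.log(2.0)
    return np.where(small, out, val)


def vmf_logpdf(x, mu, kappa: float) -> np.ndarray:
    """Log-density of vMF(mu, kappa) at unit vector(s) x (shape (3,) or (n, 3))."""
    x = np.asarray(x, dtype=float)
    mu = np.asarray(mu, dtype=float)
    if kappa < 0:
        raise ValueError("kappa must be non-negative")
    dots = x @ mu
    return float(log_c3(kappa)) + kappa * dots


def _component_logpdfs(points: np.ndarray, mus: np.ndarray, kappas: np.ndarray) -> np.ndarray:
    """(n, k) matrix of per-component log densities."""
    return log_c3(kappas)[None, :] + (points @ mus.T) * kappas[None, :]


def _kappa_mle(rbar: float) -> float:
    """Concentration MLE from the mean resultant length (d = 3).

    Solves A(kappa) = coth(kappa) - 1/kappa = rbar by Newton iteration from
    the Banerjee et al. closed-form start kappa0 = rbar(3 - rbar^2)/(1 - rbar^2).
    The exact solve keeps the M-step a true maximizer, so the EM
    log-likelihood is monotone; the result is capped at KAPPA_MAX."""
    rbar = min(rbar, 1.0 - 1e-12)
    if rbar <= 0:
        return 0.0
    k = rbar * (3.0 - rbar * rbar) / (1.0 - rbar * rbar)
    if k >= KAPPA_MAX:
        return KAPPA_MAX
    if k < 1e-2:  # A(k) ~ k/3 here; the closed form is already exact enough
        return k
    for _ in range(8):
        ek = np.exp(-2.0 * k)
        coth = (1.0 + ek) / (1.0 - ek)
        a = coth - 1.0 / k
        da = 1.0 / (k * k) - (coth * coth - 1.0)  # A'(k) = 1/k^2 - csch^2 k
        if da <= 0:
            break
        step = (a - rbar) / da
        k_new = k - step
        if not np.isfinite(k_new) or k_new <= 0:
            k_new = k / 2.0
        if abs(k_new - k) < 1e-12 * max(1.0, k):
            k = k_new
            break
        k = k_new
    return float(min(max(k, 0.0), KAPPA_MAX))


def _kmeanspp_means(points: np.ndarray, weights: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """Weighted spherical k-means++ seeding: means drawn from the data with
    probability proportional to weight times chordal distance to the
    nearest already-chosen mean."""
    n = len(points)
    p = weights / weights.sum()
    idx = rng.choice(n, p=p)
    means = [points[idx]]
    for _ in range(1, k):
        d = np.min(1.0 - points @ np.array(means).T, axis=1)  # chordal-type distance
        d = np.clip(d, 1e-12, None) * weights
        means.append(points[rng.choice(n, p=d / d.sum())])
    return np.array(means)


def _em(points, weights, k, rng, max_iter, tol, hard):
    n = len(points)
    mus = _kmeanspp_means(points, weights, k, rng)
    kappas = np.full(k, 10.0)
    alphas = np.full(k, 1.0 / k)
    w = weights
    wsum = w.sum()
    prev = -np.inf
    history = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # E-step (manual logsumexp keeps this inner loop cheap)
        logp = _component_logpdfs(points, mus, kappas) + np.log(alphas)[None, :]
        mx = logp.max(axis=1)
        lse = mx + np.log(np.exp(logp - mx[:, None]).sum(axis=1))
        loglik = float(np.sum(w * lse))
        resp = np.exp(logp - lse[:, None])
        if hard:
            hard_resp = np.zeros_like(resp)
            hard_resp[np.arange(n), np.argmax(resp, axis=1)] = 1.0
            resp = hard_resp
        # M-step
        wr = resp * w[:, None]                       # (n, k)
        mass = wr.sum(axis=0)                        # per-component weight mass
        live = mass > 1e-12 * wsum
        if not np.all(live):
            warnings.warn("pruning degenerate vMF component with zero responsibility mass")
            keep = np.where(live)[0]
            mus, kappas, alphas = mus[keep], kappas[keep], alphas[keep]
            k = len(keep)
            if k == 0:
                break
            prev = -np.inf
            continue
        alphas = mass / wsum
        resultant = wr.T @ points                    # (k, 3)
        rlen = np.linalg.norm(resultant, axis=1)
        mus = resultant / np.clip(rlen, 1e-300, None)[:, None]
        kappas = np.array([_kappa_mle(r / m) for r, m in zip(rlen, mass)])
        history.append(loglik)
        if loglik - prev < tol * max(1.0, abs(loglik)) and it > 1:
            converged = True
            break
        prev = loglik

    # final log-likelihood with the last parameter set
    if k == 0:
        return None
    logp = _component_logpdfs(points, mus, kappas) + np.log(alphas)[None, :]
    mx = logp.max(axis=1)
    loglik = float(np.sum(w * (mx + np.log(np.exp(logp - mx[:, None]).sum(axis=1)))))
    return mus, kappas, alphas, loglik, converged, it, history


def fit_movMF(
    points,
    weights=None,
    k: int = 1,
    restarts: int = 5,
    seed=None,
    max_iter: int = 200,
    tol: float = 1e-8,
    hard: bool = False,
) -> VMFMixtureFit:
    """Fit a k-component vMF mixture to weighted unit vectors by EM.

    Parameters
    ----------
    points : (n, 3) array of unit vectors.
    weights : (n,) non-negative observation weights (default all-ones).
    k : number of components.
    restarts : independent k-means++ initializations; the best final
        log-likelihood wins.
    seed : int or numpy Generator driving initialization.
    hard : use hard (classification) EM instead of soft responsibilities.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if weights is None:
        weights = np.ones(len(points))
    weights = np.asarray(weights, dtype=float)
    if np.any(weights < 0):
        raise ValueError("weights must be non-negative")
    if k <= 0:
        raise ValueError("k must be a positive integer")
    pos = weights > 0
    points, weights = points[pos], weights[pos]
    if len(points) < k:
        raise ValueError(f"need at least k={k} points with positive weight, got {len(points)}")
    norms = np.linalg.norm(points, axis=1)
    if np.any(np.abs(norms - 1.0) > 1e-6):
        raise ValueError("all points must be unit vectors")

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    best = None
    for _ in range(max(1, restarts)):
        res = _em(points, weights, k, rng, max_iter, tol, hard)
        if res is None:
            continue
        if best is None or res[3] > best[3]:
            best = res
    if best is None:
        raise RuntimeError("all EM restarts degenerated to zero components")
    mus, kappas, alphas, loglik, converged, n_iter, history = best
    n_eff = float(weights.sum())
    kk = len(mus)
    p = 4 * kk - 1
    bic = -2.0 * loglik + p * np.log(n_eff)
    comps = [VMFComponent(mu=m, kappa=float(ka), alpha=float(a)) for m, ka, a in zip(mus, kappas, alphas)]
    return VMFMixtureFit(
        components=comps,
        loglik=loglik,
        bic=float(bic),
        n_effective=n_eff,
        converged=bool(converged),
        seed=None if isinstance(seed, np.random.Generator) else seed,
        n_iter=n_iter,
        kappa_capped=bool(np.any(kappas >= KAPPA_MAX)),
        history=history,
    )


def select_k_bic(points, weights, k_candidates, restarts: int = 5, seed=None, **kwargs) -> VMFMixtureFit:
    """Fit each candidate k and return the fit minimizing BIC (ties -> smaller k)."""
    k_candidates = sorted(set(int(k) for k in k_candidates))
    if not k_candidates:
        raise ValueError("k_candidates must be non-empty")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    best = None
    for k in k_candidates:
        fit = fit_movMF(points, weights, k=k, restarts=restarts, seed=rng, **kwargs)
        if best is None or fit.bic < best.bic - 1e-12:
            best = fit
    return best


def sample_vmf(mu, kappa: float, n: int, rng=None) -> np.ndarray:
    """Draw n samples from vMF(mu, kappa) on S^2 (Wood's rejection algorithm)."""
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    mu = np.asarray(mu, dtype=float)
    mu = mu / np.linalg.norm(mu)
    if kappa < 0:
        raise ValueError("kappa must be non-negative")
    if kappa == 0:
        v = rng.standard_normal((n, 3))
        return v / np.linalg.norm(v, axis=1, keepdims=True)

    d = 3
    b = (-2.0 * kappa + np.sqrt(4.0 * kappa**2 + (d - 1) ** 2)) / (d - 1)
    x0 = (1.0 - b) / (1.0 + b)
    c = kappa * x0 + (d - 1) * np.log(1.0 - x0 * x0)

    ws = np.empty(n)
    filled = 0
    while filled < n:
        m = n - filled
        z = rng.beta((d - 1) / 2.0, (d - 1) / 2.0, size=m)
        w = (1.0 - (1.0 + b) * z) / (1.0 - (1.0 - b) * z)
        u = rng.uniform(size=m)
        accept = kappa * w + (d - 1) * np.log1p(-x0 * w) - c >= np.log(u)
        n_acc = int(accept.sum())
        ws[filled : filled + n_acc] = w[accept]
        filled += n_acc

    # tangent directions orthogonal to mu
    v = rng.standard_normal((n, 3))
    v -= (v @ mu)[:, None] * mu
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    return ws[:, None] * mu + np.sqrt(1.0 - ws**2)[:, None] * v
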