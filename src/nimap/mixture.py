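"""Transformed-Poisson mixture models of match-length densities.

The per-position average match-length track is histogrammed on the
integer grid ``1..ceil(max)``, optionally smoothed with a normalized
Gaussian kernel (21 taps, sd 3 grid units by default, reflected
boundaries), and modelled as a mixture of linearly rescaled Poisson
components

    G(l) = sum_i alpha_i * beta_i * P(lambda_i, beta_i * l),

where ``P(lambda, x) = lambda**x * exp(-lambda) / Gamma(x + 1)`` is the
continuous (Gamma-function) extension of the Poisson pmf, the
``alpha_i`` sum to one and the ``beta_i`` rescale the length axis, so the
model has ``3k - 1`` free parameters.  Parameters are estimated by
minimizing the sum of squared deviations from the observed density with
multi-start Nelder–Mead over an unconstrained parameterization (softmax
for alpha, log for beta and lambda).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import convolve1d
from scipy.optimize import minimize
from scipy.special import gammaln
from sklearn.base import BaseEstimator


@dataclass(frozen=True)
class SmoothingConfig:
    """Gaussian kernel: ``mu`` taps (odd), standard deviation ``sigma``
    in grid units."""

    mu: int = 21
    sigma: float = 3.0

    def __post_init__(self):
        if self.mu < 1 or self.mu % 2 == 0:
            raise ValueError("kernel tap count mu must be odd and >= 1")
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")


@dataclass(frozen=True)
class MixtureModel:
    """Fitted mixture: proportions, rescaling coefficients, Poisson
    parameters (sorted by lambda ascending) and the achieved sum of
    squared deviations."""

    k: int
    alpha: tuple[float, ...]
    beta: tuple[float, ...]
    lam: tuple[float, ...]
    error: float

    def __post_init__(self):
        if abs(sum(self.alpha) - 1.0) > 1e-9:
            raise ValueError("mixture proportions must sum to 1")
        if min(self.alpha) <= 0 or min(self.beta) <= 0 or min(self.lam) <= 0:
            raise ValueError("alpha, beta, lambda must all be positive")

    @property
    def n_free_parameters(self) -> int:
        return 3 * self.k - 1


def gaussian_kernel(mu: int = 21, sigma: float = 3.0) -> np.ndarray:
    cfg = SmoothingConfig(mu, sigma)
    x = np.arange(cfg.mu) - cfg.mu // 2
    k = np.exp(-0.5 * (x / cfg.sigma) ** 2)
    return k / k.sum()


def smooth_density(F, mu: int = 21, sigma: float = 3.0) -> np.ndarray:
    """Convolve a density on a uniform unit grid with a normalized
    Gaussian kernel (reflected boundaries) and renormalize to unit mass."""
    F = np.asarray(F, dtype=float)
    out = convolve1d(F, gaussian_kernel(mu, sigma), mode="reflect")
    total = out.sum()
    if total <= 0:
        raise ValueError("density has no mass")
    return out / total


def density_from_track(track, smooth: bool = True, mu: int = 21,
                       sigma: float = 3.0):
    """Integer-grid probability density of a per-position length track.

    Values are rounded to the nearest integer and clipped to >= 1; the
    grid is ``1..ceil(max)``.  Returns ``(l, F)``.
    """
    track = np.asarray(track, dtype=float)
    if track.size == 0:
        raise ValueError("empty track")
    top = int(np.ceil(track.max()))
    if top < 1:
        raise ValueError("track has no positive values")
    values = np.clip(np.rint(track).astype(np.int64), 1, top)
    counts = np.bincount(values, minlength=top + 1)[1:]
    F = counts / counts.sum()
    if smooth:
        F = smooth_density(F, mu, sigma)
    return np.arange(1, top + 1, dtype=float), F


def poisson_pdf(lam, x):
    """Continuous extension of the Poisson pmf via the Gamma function."""
    lam = np.asarray(lam, dtype=float)
    x = np.asarray(x, dtype=float)
    return np.exp(x * np.log(lam) - lam - gammaln(x + 1.0))


def mixture_pdf(l, alpha, beta, lam, rounding: bool = False) -> np.ndarray:
    """Evaluate ``G(l) = sum_i alpha_i beta_i P(lambda_i, beta_i l)``.

    ``rounding=True`` rounds ``beta_i * l`` to the nearest integer
    instead of using the continuous extension.
    """
    l = np.atleast_1d(np.asarray(l, dtype=float))
    alpha = np.asarray(alpha, dtype=float)
    beta = np.asarray(beta, dtype=float)
    lam = np.asarray(lam, dtype=float)
    if not (alpha.shape == beta.shape == lam.shape):
        raise ValueError("alpha, beta, lambda must have equal length")
    if np.any(l < 0):
        raise ValueError("lengths must be >= 0")
    x = beta[:, None] * l[None, :]
    if rounding:
        x = np.rint(x)
    comp = poisson_pdf(lam[:, None], x)
    return np.einsum("i,i,ij->j", alpha, beta, comp)


def _unpack(theta: np.ndarray, k: int):
    logits = np.append(theta[: k - 1], 0.0)
    logits -= logits.max()
    e = np.exp(logits)
    alpha = e / e.sum()
    beta = np.exp(theta[k - 1 : 2 * k - 1])
    lam = np.exp(theta[2 * k - 1 :])
    return alpha, beta, lam


def _pack(alpha, beta, lam, k: int) -> np.ndarray:
    logits = np.log(np.asarray(alpha) / alpha[-1])[: k - 1]
    return np.concatenate([logits, np.log(beta), np.log(lam)])


class PoissonMixture(BaseEstimator):
    """Least-squares transformed-Poisson mixture density fit.

    Parameters
    ----------
    k : number of components (>= 1); the model has ``3k - 1`` free
        parameters.
    n_restarts : random Nelder–Mead restarts per fit (default 32).
    random_state : seed for the restart generator; fits are reproducible
        bit-for-bit for a fixed seed.
    rounding : evaluate the Poisson pmf at rounded ``beta*l`` instead of
        the continuous Gamma extension.
    nested_init : additionally seed the search from the fitted
        ``k - 1``-component model with its heaviest component duplicated,
        guaranteeing the achieved error never increases with ``k``.

    Attributes
    ----------
    alpha_, beta_, lambda_ : fitted parameter arrays, sorted by lambda
        ascending.
    error_ : achieved sum of squared deviations.
    """

    def __init__(self, k: int = 2, n_restarts: int = 32,
                 random_state: int | None = None, rounding: bool = False,
                 nested_init: bool = True, maxiter: int = 4000):
        self.k = k
        self.n_restarts = n_restarts
        self.random_state = random_state
        self.rounding = rounding
        self.nested_init = nested_init
        self.maxiter = maxiter

    def _objective(self, theta, l, F):
        alpha, beta, lam = _unpack(theta, self.k)
        if np.any(beta > 1e6) or np.any(lam > 1e8):
            return 1e9
        resid = F - mixture_pdf(l, alpha, beta, lam, rounding=self.rounding)
        return float(resid @ resid)

    def _initial_points(self, l, F, rng):
        k = self.k
        pts = []
        # moment-style deterministic anchor: component means at density
        # quantiles, beta spread over plausible rescalings
        cdf = np.cumsum(F) / F.sum()
        qs = (np.arange(k) + 0.5) / k
        anchors = l[np.searchsorted(cdf, qs, side="left").clip(0, l.size - 1)]
        beta0 = np.geomspace(0.05, 0.6, k)
        pts.append(_pack(np.full(k, 1.0 / k), beta0,
                         np.maximum(beta0 * anchors, 1e-3), k))
        for _ in range(self.n_restarts):
            idx = rng.choice(l.size, size=k, p=F / F.sum())
            beta = np.exp(rng.uniform(np.log(0.02), np.log(1.0), size=k))
            lam = np.maximum(beta * l[idx], 1e-3)
            alpha = rng.dirichlet(np.ones(k))
            pts.append(_pack(np.maximum(alpha, 1e-6) /
                             np.maximum(alpha, 1e-6).sum(), beta, lam, k))
        return pts

    def fit(self, l, F=None):
        """Fit the mixture to a density ``F`` on grid ``l``.

        ``l`` may also be a ``(l, F)`` tuple as returned by
        :func:`density_from_track`.
        """
        if F is None:
            l, F = l
        l = np.asarray(l, dtype=float)
        F = np.asarray(F, dtype=float)
        if l.shape != F.shape or l.ndim != 1:
            raise ValueError("l and F must be equal-length 1-D arrays")
        if self.k < 1:
            raise ValueError("k must be >= 1")
        rng = np.random.default_rng(self.random_state)
        pts = self._initial_points(l, F, rng)
        if self.nested_init and self.k > 1:
            sub = PoissonMixture(
                k=self.k - 1, n_restarts=self.n_restarts,
                random_state=self.random_state, rounding=self.rounding,
                nested_init=self.nested_init, maxiter=self.maxiter,
            ).fit(l, F)
            alpha = np.array(list(sub.alpha_))
            j = int(np.argmax(alpha))
            alpha = np.concatenate([alpha, [alpha[j] / 2.0]])
            alpha[j] /= 2.0
            beta = np.append(sub.beta_, sub.beta_[j])
            lam = np.append(sub.lambda_, sub.lambda_[j])
            pts.append(_pack(alpha / alpha.sum(), beta, lam, self.k))
        best_theta, best_val = None, np.inf
        for x0 in pts:
            v0 = self._objective(x0, l, F)
            if v0 < best_val:
                best_theta, best_val = x0, v0
            res = minimize(
                self._objective, x0, args=(l, F), method="Nelder-Mead",
                options={"maxiter": self.maxiter, "xatol": 1e-10,
                         "fatol": 1e-14, "adaptive": True},
            )
            if res.fun < best_val:
                best_theta, best_val = res.x, res.fun
        for _ in range(2):  # polish
            res = minimize(
                self._objective, best_theta, args=(l, F),
                method="Nelder-Mead",
                options={"maxiter": self.maxiter, "xatol": 1e-12,
                         "fatol": 1e-16, "adaptive": True},
            )
            if res.fun < best_val:
                best_theta, best_val = res.x, res.fun
        alpha, beta, lam = _unpack(best_theta, self.k)
        order = np.argsort(lam)
        self.alpha_ = alpha[order]
        self.beta_ = beta[order]
        self.lambda_ = lam[order]
        self.error_ = float(best_val)
        self.n_grid_ = l.size
        return self

    def pdf(self, l) -> np.ndarray:
        return mixture_pdf(l, self.alpha_, self.beta_, self.lambda_,
                           rounding=self.rounding)

    def model_(self) -> MixtureModel:
        return MixtureModel(
            k=self.k,
            alpha=tuple(float(a) for a in self.alpha_),
            beta=tuple(float(b) for b in self.beta_),
            lam=tuple(float(x) for x in self.lambda_),
            error=self.error_,
        )


def fit_mixture(l, F, k: int, seed: int | None = 0, **kwargs) -> MixtureModel:
    """Functional wrapper around :class:`PoissonMixture`."""
    est = PoissonMixture(k=k, random_state=seed, **kwargs).fit(l, F)
    return est.model_()
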