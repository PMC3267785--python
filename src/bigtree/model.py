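"""GTR substitution model and discrete-Gamma rate heterogeneity.

The general time-reversible (GTR) generator is parameterized by six
exchangeabilities (the G<->T rate is fixed to 1 for identifiability) and
stationary base frequencies pi.  The generator is normalized so the mean
substitution rate is 1, i.e. -sum_i pi_i Q_ii = 1, which makes branch
lengths expected substitutions per site.  Transition probabilities
P(b, r) = exp(Q * b * r) are computed through the symmetric
eigendecomposition of diag(sqrt pi) Q diag(1/sqrt pi), cached per
parameter set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import gamma as gamma_dist

__all__ = ["GTRParams", "GammaRates", "gamma_discretize", "jc_params"]

STATE_ORDER = "ACGT"
# order of the 6 exchangeabilities: AC, AG, AT, CG, CT, GT
RATE_PAIRS = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]


@dataclass(frozen=True)
class GTRParams:
    """GTR exchangeabilities and base frequencies.

    exchangeabilities: (AC, AG, AT, CG, CT, GT); GT conventionally 1.
    frequencies: stationary probabilities of A, C, G, T (sum to 1).
    """

    exchangeabilities: tuple[float, ...]
    frequencies: tuple[float, ...]

    def __post_init__(self) -> None:
        ex = tuple(float(x) for x in self.exchangeabilities)
        fr = tuple(float(x) for x in self.frequencies)
        if len(ex) != 6 or any(x < 0 for x in ex):
            raise ValueError("need 6 non-negative exchangeabilities")
        if len(fr) != 4 or any(f <= 0 for f in fr):
            raise ValueError("need 4 strictly positive frequencies")
        if abs(sum(fr) - 1.0) > 1e-12:
            raise ValueError("frequencies must sum to 1")
        object.__setattr__(self, "exchangeabilities", ex)
        object.__setattr__(self, "frequencies", fr)

    @property
    def pi(self) -> np.ndarray:
        return np.asarray(self.frequencies)

    def generator(self) -> np.ndarray:
        """Normalized GTR rate matrix Q (mean rate 1)."""
        pi = self.pi
        q = np.zeros((4, 4))
        for rate, (i, j) in zip(self.exchangeabilities, RATE_PAIRS):
            q[i, j] = rate * pi[j]
            q[j, i] = rate * pi[i]
        np.fill_diagonal(q, -q.sum(axis=1))
        mu = -(pi * np.diag(q)).sum()
        return q / mu

    def eigensystem(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(eigenvalues, right transform, left transform) such that
        P(t) = right @ diag(exp(lam t)) @ left."""
        return _eigensystem_cached(self.exchangeabilities, self.frequencies)

    def transition_matrix(self, b: float, rate: float = 1.0) -> np.ndarray:
        """P(b * rate) = exp(Q b rate); rows sum to 1."""
        if not np.isfinite(b) or b < 0:
            raise ValueError(f"branch length must be finite and >= 0, got {b}")
        lam, right, left = self.eigensystem()
        return (right * np.exp(lam * b * rate)) @ left

    def transition_matrices(self, b: float, rates: np.ndarray) -> np.ndarray:
        """(K, 4, 4) stack of P(b * r_k) for a vector of rates."""
        if not np.isfinite(b) or b < 0:
            raise ValueError(f"branch length must be finite and >= 0, got {b}")
        lam, right, left = self.eigensystem()
        expo = np.exp(np.outer(np.asarray(rates), lam) * b)  # (K, 4)
        return np.einsum("ab,kb,bc->kac", right, expo, left, optimize=False)


_EIG_CACHE: dict[tuple, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}


def _eigensystem_cached(ex: tuple, fr: tuple):
    key = (ex, fr)
    if key not in _EIG_CACHE:
        params = GTRParams(ex, fr)
        pi = params.pi
        q = params.generator()
        sq = np.sqrt(pi)
        sym = (sq[:, None] * q) / sq[None, :]
        lam, vec = np.linalg.eigh((sym + sym.T) / 2.0)
        right = vec / sq[:, None]
        left = vec.T * sq[None, :]
        if len(_EIG_CACHE) > 256:
            _EIG_CACHE.clear()
        _EIG_CACHE[key] = (lam, right, left)
    return _EIG_CACHE[key]


def jc_params() -> GTRParams:
    """Jukes-Cantor: equal exchangeabilities and frequencies."""
    return GTRParams((1.0,) * 6, (0.25,) * 4)


@dataclass(frozen=True)
class GammaRates:
    """Discretized Gamma(alpha, alpha) rate distribution.

    K equiprobable categories (probability 1/K each) with strictly
    increasing rates whose mean is exactly 1.
    """

    alpha: float
    rates: tuple[float, ...]
    method: str = "mean"

    @property
    def K(self) -> int:
        return len(self.rates)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.rates)


def gamma_discretize(alpha: float, K: int = 4, method: str = "mean") -> GammaRates:
    """Discretize Gamma(alpha, alpha) into K equiprobable rate categories.

    method='mean' (default): each category rate is the conditional mean of
    its quantile bin, which preserves a mean rate of exactly 1.
    method='median': bin medians, rescaled to mean 1.
    """
    if alpha <= 0:
        raise ValueError(f"alpha must be > 0, got {alpha}")
    if K < 1:
        raise ValueError(f"K must be >= 1, got {K}")
    if K == 1:
        return GammaRates(alpha, (1.0,), method)
    dist = gamma_dist(a=alpha, scale=1.0 / alpha)
    edges = dist.ppf(np.linspace(0.0, 1.0, K + 1))
    if method == "mean":
        # E[X | bin] = K * alpha/alpha * (F_{alpha+1}(hi) - F_{alpha+1}(lo))
        shifted = gamma_dist(a=alpha + 1.0, scale=1.0 / alpha)
        cdf = shifted.cdf(edges)
        cdf[-1] = 1.0
        rates = (cdf[1:] - cdf[:-1]) * K * (alpha / alpha)
    elif method == "median":
        mids = dist.ppf((np.arange(K) + 0.5) / K)
        rates = mids * K / mids.sum()
    else:
        raise ValueError(f"unknown discretization method {method!r}")
    rates = rates / rates.mean()
    return GammaRates(alpha, tuple(float(r) for r in rates), method)
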