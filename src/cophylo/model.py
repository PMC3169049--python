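"""Time-reversible nucleotide substitution models.

A :class:`SubstitutionModel` bundles GTR exchangeabilities (order AC, AG, AT,
CG, CT, GT with GT fixed at 1 as the reference), stationary base frequencies
pi, an optional discrete-gamma shape ``alpha`` for among-site rate variation,
and a proportion ``p_inv`` of invariable sites.  The rate matrix is scaled so
that one unit of branch length equals one expected substitution per site at
stationarity.

Rate heterogeneity follows the standard "+G+I" convention: the variable
fraction ``1 - p_inv`` of sites draws a multiplier from a k-category
equal-probability discretisation of Gamma(alpha, mean 1) (mean-of-category
rates); the gamma mean is not rescaled when ``p_inv > 0``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy.special import gammainc
from scipy.stats import gamma as gamma_dist

__all__ = [
    "SubstitutionModel",
    "ModelError",
    "build_rate_matrix",
    "rate_matrix_eigen",
    "transition_probabilities",
    "discrete_gamma_rates",
    "jc",
    "k80",
    "hky",
    "gtr",
]

# exchangeability order
EXCH_PAIRS = ((0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3))  # AC AG AT CG CT GT
BASES = "ACGT"


class ModelError(ValueError):
    pass


@dataclass(frozen=True)
class SubstitutionModel:
    exchangeabilities: Tuple[float, float, float, float, float, float] = (1, 1, 1, 1, 1, 1)
    base_frequencies: Tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    gamma_shape: Optional[float] = None  # None: rate variation off
    p_inv: float = 0.0
    n_rate_categories: int = 4
    name: str = "GTR"

    def __post_init__(self):
        ex = np.asarray(self.exchangeabilities, float)
        pi = np.asarray(self.base_frequencies, float)
        if ex.shape != (6,) or np.any(ex < 0):
            raise ModelError("need 6 non-negative exchangeabilities (AC,AG,AT,CG,CT,GT)")
        if pi.shape != (4,) or np.any(pi <= 0):
            raise ModelError("need 4 positive base frequencies")
        if abs(pi.sum() - 1.0) > 1e-12:
            object.__setattr__(
                self, "base_frequencies", tuple((pi / pi.sum()).tolist())
            )
        if self.gamma_shape is not None and self.gamma_shape <= 0:
            raise ModelError(f"gamma shape must be positive, got {self.gamma_shape}")
        if not 0 <= self.p_inv < 1:
            raise ModelError(f"p_inv must be in [0,1), got {self.p_inv}")
        if self.n_rate_categories < 1:
            raise ModelError("need at least one rate category")

    @property
    def pi(self) -> np.ndarray:
        return np.asarray(self.base_frequencies, float)

    def category_rates(self) -> np.ndarray:
        """Rate multipliers of the variable fraction (length k, mean 1)."""
        if self.gamma_shape is None:
            return np.ones(1)
        return discrete_gamma_rates(self.gamma_shape, self.n_rate_categories)

    def with_(self, **kwargs) -> "SubstitutionModel":
        return replace(self, **kwargs)

    def describe(self) -> str:
        ex = ", ".join(f"{v:.4g}" for v in self.exchangeabilities)
        pi = ", ".join(f"{v:.4g}" for v in self.base_frequencies)
        g = "off" if self.gamma_shape is None else f"{self.gamma_shape:.4g} (k={self.n_rate_categories})"
        return (
            f"{self.name}: exchangeabilities (AC,AG,AT,CG,CT,GT) = [{ex}]; "
            f"pi(A,C,G,T) = [{pi}]; gamma shape = {g}; p_inv = {self.p_inv:.4g}"
        )


# ---------------------------------------------------------------------------
# Rate matrix and transition probabilities
# ---------------------------------------------------------------------------

def build_rate_matrix(model: SubstitutionModel) -> np.ndarray:
    """The normalised GTR rate matrix Q.

    ``Q[i, j] = s_ij * pi_j`` off the diagonal, rows summing to zero, scaled
    so the expected substitution rate at stationarity is one — i.e.
    ``-sum_i pi_i Q_ii = 1`` — which fixes branch lengths in expected
    substitutions per site.
    """
    pi = model.pi
    S = np.zeros((4, 4))
    for s, (i, j) in zip(model.exchangeabilities, EXCH_PAIRS):
        S[i, j] = S[j, i] = s
    Q = S * pi[None, :]
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    mu = -np.dot(pi, np.diag(Q))
    if mu <= 0:
        raise ModelError("degenerate rate matrix (all exchangeabilities zero?)")
    return Q / mu


def rate_matrix_eigen(
    Q: np.ndarray, freqs: Optional[np.ndarray] = None
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Eigendecomposition of a reversible Q via its symmetrised form.

    Returns ``(eigenvalues, U, U_inv)`` with ``Q = U diag(w) U_inv``; the
    symmetrisation ``diag(sqrt(pi)) Q diag(1/sqrt(pi))`` keeps the problem
    Hermitian and the decomposition numerically exact.
    """
    if freqs is None:
        freqs = stationary_distribution(Q)
    sq = np.sqrt(freqs)
    B = (Q * sq[:, None]) / sq[None, :]
    B = (B + B.T) / 2.0
    w, V = np.linalg.eigh(B)
    U = V / sq[:, None]
    U_inv = V.T * sq[None, :]
    return w, U, U_inv


def stationary_distribution(Q: np.ndarray) -> np.ndarray:
    """Left null vector of Q, normalised to a probability vector."""
    w, v = np.linalg.eig(Q.T)
    k = int(np.argmin(np.abs(w)))
    pi = np.real(v[:, k])
    pi = np.abs(pi)
    return pi / pi.sum()


def transition_probabilities(
    Q: np.ndarray, t: float, r: float = 1.0, freqs: Optional[np.ndarray] = None
) -> np.ndarray:
    """P(t) = exp(Q t r) for a reversible rate matrix."""
    if t < 0:
        raise ModelError(f"branch length must be non-negative, got {t}")
    if r < 0:
        raise ModelError(f"rate multiplier must be non-negative, got {r}")
    w, U, U_inv = rate_matrix_eigen(Q, freqs)
    P = (U * np.exp(w * t * r)[None, :]) @ U_inv
    np.clip(P, 0.0, None, out=P)
    P /= P.sum(axis=1, keepdims=True)
    return P


# ---------------------------------------------------------------------------
# Discrete gamma rate variation
# ---------------------------------------------------------------------------

def discrete_gamma_rates(alpha: float, k: int = 4) -> np.ndarray:
    """Mean-of-category rates for the equal-probability Gamma discretisation.

    The Gamma(alpha, mean 1) density is cut at its ``i/k`` quantiles and each
    category's rate is the conditional mean within its bin, computed with the
    incomplete-gamma identity; the k rates have equal weight 1/k and mean 1.
    """
    if alpha <= 0:
        raise ModelError(f"gamma shape must be positive, got {alpha}")
    if k < 1:
        raise ModelError(f"need at least one category, got {k}")
    if k == 1:
        return np.ones(1)
    cuts = gamma_dist.ppf(np.arange(1, k) / k, a=alpha, scale=1.0 / alpha)
    upper = gammainc(alpha + 1.0, np.append(cuts * alpha, np.inf))
    lower = np.append(0.0, gammainc(alpha + 1.0, cuts * alpha))
    rates = k * (upper - lower)
    return rates / rates.mean()  # mean exactly 1


# ---------------------------------------------------------------------------
# Named model families
# ---------------------------------------------------------------------------

def jc(gamma_shape: Optional[float] = None, p_inv: float = 0.0, k: int = 4) -> SubstitutionModel:
    """Jukes-Cantor: equal rates, equal frequencies."""
    return SubstitutionModel(
        (1, 1, 1, 1, 1, 1), (0.25, 0.25, 0.25, 0.25), gamma_shape, p_inv, k, name="JC"
    )


def k80(kappa: float = 2.0, gamma_shape: Optional[float] = None, p_inv: float = 0.0, k: int = 4) -> SubstitutionModel:
    """Kimura 2-parameter: transition/transversion ratio kappa, equal frequencies."""
    return SubstitutionModel(
        (1, kappa, 1, 1, kappa, 1), (0.25, 0.25, 0.25, 0.25), gamma_shape, p_inv, k, name="K80"
    )


def hky(
    kappa: float = 2.0,
    base_frequencies: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
    gamma_shape: Optional[float] = None,
    p_inv: float = 0.0,
    k: int = 4,
) -> SubstitutionModel:
    """HKY85: kappa plus unequal base frequencies."""
    return SubstitutionModel(
        (1, kappa, 1, 1, kappa, 1), tuple(base_frequencies), gamma_shape, p_inv, k, name="HKY"
    )


def gtr(
    exchangeabilities: Sequence[float] = (1, 1, 1, 1, 1, 1),
    base_frequencies: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
    gamma_shape: Optional[float] = None,
    p_inv: float = 0.0,
    k: int = 4,
) -> SubstitutionModel:
    """General time-reversible model."""
    return SubstitutionModel(
        tuple(exchangeabilities), tuple(base_frequencies), gamma_shape, p_inv, k, name="GTR"
    )
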