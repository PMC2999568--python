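"""Amino-acid substitution models: LG with gamma rates and invariant sites.

The model is a general time-reversible 20-state Markov process built from
a symmetric exchangeability table S and stationary frequencies pi:
Q_ij = S_ij * pi_j (i != j), rows summing to zero, normalized so that
-sum_i pi_i Q_ii = 1 (one expected substitution per unit branch length at
relative rate 1). Rate heterogeneity across sites uses Yang's discrete
gamma approximation (k equal-probability categories, category rate = bin
mean, overall mean 1) plus an optional proportion of invariant sites.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import gammainc
from scipy.stats import gamma as gamma_dist

from ._lg_data import AA_ORDER as _LG_AA_ORDER
from ._lg_data import LG_EXCHANGEABILITIES_LOWER, LG_FREQUENCIES
from .sequences import AMINO_ACIDS


def discretize_gamma(alpha: float, k: int) -> np.ndarray:
    """Rates of ``k`` equal-probability discrete gamma categories.

    Each category rate is the mean of Gamma(alpha, scale=1/alpha) over the
    corresponding inter-quantile bin; the returned rates are normalized to
    mean exactly 1.
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    if k < 1:
        raise ValueError("need at least one category")
    if k == 1:
        return np.array([1.0])
    bounds = gamma_dist.ppf(np.arange(1, k) / k, a=alpha, scale=1.0 / alpha)
    upper = gammainc(alpha + 1.0, alpha * bounds)
    cum = np.concatenate([[0.0], upper, [1.0]])
    rates = k * np.diff(cum)
    return rates / rates.mean()


@dataclass
class RateModel:
    """A reversible amino-acid rate matrix with optional +G / +I components.

    ``exchangeabilities`` and ``frequencies`` are indexed by the package
    alphabet ``ACDEFGHIKLMNPQRSTVWY``.
    """

    exchangeabilities: np.ndarray
    frequencies: np.ndarray
    alpha: float | None = None
    n_categories: int = 4
    p_invariant: float | None = None
    name: str = "custom"
    #: state labels; amino acids by default, but any state space works
    #: (small toy alphabets keep brute-force cross-checks tractable)
    alphabet: str = AMINO_ACIDS

    Q: np.ndarray = field(init=False, repr=False)
    _eig_vals: np.ndarray = field(init=False, repr=False)
    _eig_left: np.ndarray = field(init=False, repr=False)
    _eig_right: np.ndarray = field(init=False, repr=False)
    _rates_cache: np.ndarray | None = field(init=False, repr=False, default=None)

    def __post_init__(self) -> None:
        S = np.asarray(self.exchangeabilities, dtype=float)
        pi = np.asarray(self.frequencies, dtype=float)
        n = len(self.alphabet)
        if S.shape != (n, n):
            raise ValueError(f"exchangeabilities must be {n}x{n} for this alphabet")
        if pi.shape != (n,):
            raise ValueError(f"frequencies must have length {n}")
        if not np.allclose(S, S.T):
            raise ValueError("exchangeabilities must be symmetric")
        if np.any(S < 0):
            raise ValueError("exchangeabilities must be nonnegative")
        if np.any(pi <= 0) or abs(pi.sum() - 1.0) > 1e-6:
            raise ValueError("frequencies must be positive and sum to 1")
        pi = pi / pi.sum()
        Q = S * pi[None, :]
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        mu = -np.sum(pi * np.diag(Q))
        Q /= mu
        self.exchangeabilities = S
        self.frequencies = pi
        self.Q = Q
        # reversible Q is similar to the symmetric matrix D^1/2 Q D^-1/2
        d = np.sqrt(pi)
        sym = Q * (d[:, None] / d[None, :])
        vals, vecs = np.linalg.eigh((sym + sym.T) / 2.0)
        self._eig_vals = vals
        self._eig_right = vecs / d[:, None]  # rows scaled: D^-1/2 V
        self._eig_left = vecs.T * d[None, :]  # V^T D^1/2

    @property
    def category_rates(self) -> np.ndarray:
        if self._rates_cache is None:
            if self.alpha is None:
                rates = np.array([1.0])
            else:
                rates = discretize_gamma(self.alpha, self.n_categories)
            object.__setattr__(self, "_rates_cache", rates)
        return self._rates_cache

    @property
    def n_free_parameters(self) -> int:
        """Free rate-heterogeneity parameters (alpha and/or p_inv)."""
        return int(self.alpha is not None) + int(self.p_invariant is not None)

    def transition_probabilities(self, t: float, rate: float = 1.0) -> np.ndarray:
        """P(t) = exp(Q * t * rate); one 20x20 row-stochastic table."""
        if t < 0:
            raise ValueError("branch length must be nonnegative")
        w = np.exp(self._eig_vals * (t * rate))
        P = (self._eig_right * w[None, :]) @ self._eig_left
        return np.clip(P, 0.0, None)

    def transition_probabilities_per_category(self, t: float) -> np.ndarray:
        """(k, 20, 20) stack of P(t * r_c) over the gamma categories."""
        rates = self.category_rates
        w = np.exp(self._eig_vals[None, :] * (t * rates[:, None]))
        P = np.einsum("ij,cj,jk->cik", self._eig_right, w, self._eig_left)
        return np.clip(P, 0.0, None)

    @property
    def n_states(self) -> int:
        return len(self.alphabet)

    def with_params(self, **kwargs) -> "RateModel":
        keep = dict(
            exchangeabilities=self.exchangeabilities,
            frequencies=self.frequencies,
            alpha=self.alpha,
            n_categories=self.n_categories,
            p_invariant=self.p_invariant,
            name=self.name,
            alphabet=self.alphabet,
        )
        keep.update(kwargs)
        return RateModel(**keep)


def build_rate_matrix(
    exchangeabilities: np.ndarray,
    frequencies: np.ndarray,
    alpha: float | None = None,
    n_categories: int = 4,
    p_invariant: float | None = None,
    name: str = "custom",
) -> RateModel:
    """Normalized reversible rate model from exchangeabilities and frequencies."""
    return RateModel(
        exchangeabilities=np.asarray(exchangeabilities, dtype=float),
        frequencies=np.asarray(frequencies, dtype=float),
        alpha=alpha,
        n_categories=n_categories,
        p_invariant=p_invariant,
        name=name,
    )


def _lg_tables() -> tuple[np.ndarray, np.ndarray]:
    """LG exchangeabilities/frequencies reordered to the package alphabet."""
    S = np.zeros((20, 20))
    idx = 0
    for j in range(20):
        for i in range(j + 1, 20):
            S[i, j] = S[j, i] = LG_EXCHANGEABILITIES_LOWER[idx]
            idx += 1
    pi = np.array(LG_FREQUENCIES)
    order = [_LG_AA_ORDER.index(a) for a in AMINO_ACIDS]
    return S[np.ix_(order, order)], pi[order]


def lg_model(
    alpha: float | None = None,
    n_categories: int = 4,
    p_invariant: float | None = None,
    frequencies: Sequence[float] | None = None,
) -> RateModel:
    """The LG model, optionally +G (``alpha``) and/or +I (``p_invariant``).

    ``frequencies`` overrides the published LG stationary frequencies
    (e.g. with frequencies observed in an alignment, the "+F" variant).
    """
    S, pi = _lg_tables()
    if frequencies is not None:
        pi = np.asarray(frequencies, dtype=float)
    if alpha is not None and p_invariant is not None:
        name = "LG+I+G"
    elif alpha is not None:
        name = "LG+G"
    elif p_invariant is not None:
        name = "LG+I"
    else:
        name = "LG"
    return RateModel(
        exchangeabilities=S,
        frequencies=pi,
        alpha=alpha,
        n_categories=n_categories,
        p_invariant=p_invariant,
        name=name,
    )


def jukes_cantor_like_model() -> RateModel:
    """The symmetric 20-state model (uniform frequencies, equal rates)."""
    S = np.ones((20, 20))
    np.fill_diagonal(S, 0.0)
    return RateModel(exchangeabilities=S, frequencies=np.full(20, 0.05), name="Poisson")


@dataclass
class ModelFit:
    """One candidate's maximized fit in AIC-based model selection."""

    name: str
    model: RateModel
    log_likelihood: float
    n_parameters: int
    aic: float
    error: str | None = None


def select_model(alignment, tree, candidates=("LG", "LG+G", "LG+I+G"), k: int = 4):
    """Rank candidate models by AIC after optimizing their free parameters.

    For each candidate the gamma shape and/or invariant proportion and the
    branch lengths are optimized; AIC = 2p - 2 lnL with p counting the
    rate-heterogeneity parameters plus one per branch length. Optimization
    failures are reported per candidate rather than raised.
    """
    from .ml_phylo import optimize_branch_lengths_and_model

    # multistart initializations: the alternating (alpha, branch-length)
    # optimization can stall on a ridge, and the near-uniform-rates start
    # guarantees each +G/+I model dominates the models it nests
    starts: dict[str, list[RateModel]] = {
        "LG": [lg_model()],
        "LG+G": [lg_model(alpha=1.0, n_categories=k), lg_model(alpha=1e5, n_categories=k)],
        "LG+I+G": [
            lg_model(alpha=1.0, n_categories=k, p_invariant=0.1),
            lg_model(alpha=1e5, n_categories=k, p_invariant=1e-6),
        ],
    }
    fits: list[ModelFit] = []
    for cand in candidates:
        if cand not in starts:
            raise ValueError(f"unknown candidate model {cand!r}")
        best: ModelFit | None = None
        error: str | None = None
        for init in starts[cand]:
            try:
                fitted_tree, fitted_model, lnl = optimize_branch_lengths_and_model(
                    tree, alignment, init
                )
                n_branches = sum(1 for _ in fitted_tree.edges())
                p = fitted_model.n_free_parameters + n_branches
                fit = ModelFit(cand, fitted_model, lnl, p, 2.0 * p - 2.0 * lnl)
                if best is None or fit.log_likelihood > best.log_likelihood:
                    best = fit
            except Exception as exc:  # noqa: BLE001 - per-candidate failure is data
                error = str(exc)
        if best is None:
            fits.append(ModelFit(cand, starts[cand][0], float("nan"), 0, float("inf"), error))
        else:
            fits.append(best)
    fits.sort(key=lambda f: f.aic)
    return fits
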