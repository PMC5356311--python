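"""Empirical amino-acid substitution models (WAG, LG, Dayhoff) with +Γ rates.

A model is a reversible continuous-time Markov chain on the 20 amino acids:
exchangeabilities S (symmetric), equilibrium frequencies π, rate matrix
Q = S·diag(π) with the diagonal fixed so rows sum to zero, normalized so one
unit of branch length equals one expected substitution per site
(−Σ πᵢQᵢᵢ = 1).  Among-site rate variation uses the discrete-gamma
approximation: K equiprobable categories, each with the mean rate of its
quantile bin, renormalized to mean 1.

The exchangeability/frequency encodings are bundled as plain-text files in
PAML's .dat layout (lower-triangle rows, then frequencies, amino acids in
PAML order) and verified against checksums at load.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
from scipy.stats import gamma as gamma_dist

from .alignment import AA_ORDER, ProteinAlignment

#: Amino-acid order used inside the bundled .dat files (PAML convention).
PAML_ORDER = "ARNDCQEGHILKMFPSTWYV"

MODEL_FILES = {
    "WAG": ("wag.dat", "2ee7e3f825dc2784187e615fad4b310e8c6ca8eafa7c0eed39f37ecf848ca8f3"),
    "LG": ("lg.dat", "ff1f2d39733325a5edd8bf2e9b3401075515d8a570a7b8b8483f89ffe2baf400"),
    "Dayhoff": ("dayhoff.dat", "e5dc5a38287d9865dfc08e067daa7ac42aa6bc7a43d2054c983c75a88e945ac0"),
}

SUPPORTED_MODELS = tuple(MODEL_FILES)


class ModelError(ValueError):
    """Raised for invalid model names or parameters."""


def _load_dat(name: str) -> tuple[np.ndarray, np.ndarray]:
    """Parse a PAML-layout .dat file; return (S, π) in canonical AA order."""
    fname, digest = MODEL_FILES[name]
    raw = resources.files("peroxevo.data").joinpath(fname).read_bytes()
    if hashlib.sha256(raw).hexdigest() != digest:
        raise ModelError(f"bundled model file {fname} failed its checksum")
    numbers = [float(x) for x in raw.decode().split()]
    if len(numbers) != 190 + 20:
        raise ModelError(f"{fname}: expected 210 numbers, found {len(numbers)}")
    S = np.zeros((20, 20))
    k = 0
    for i in range(1, 20):
        for j in range(i):
            S[i, j] = S[j, i] = numbers[k]
            k += 1
    pi = np.array(numbers[190:])
    # permute PAML order -> canonical alphabetical order
    perm = [PAML_ORDER.index(aa) for aa in AA_ORDER]
    S = S[np.ix_(perm, perm)]
    pi = pi[perm]
    pi = pi / pi.sum()
    return S, pi


def discrete_gamma_rates(alpha: float, K: int) -> np.ndarray:
    """Mean-of-bin discrete-gamma category rates (shape α, K categories).

    Bin boundaries are the j/K quantiles of Gamma(α, rate α); the category
    rate is the conditional mean within each bin, then the rates are
    renormalized so their mean is exactly 1.  Rates are non-decreasing.
    """
    if alpha <= 0:
        raise ModelError(f"gamma shape must be positive, got {alpha}")
    if K < 1:
        raise ModelError(f"need at least one rate category, got {K}")
    if K == 1:
        return np.ones(1)
    # quantile bin edges of Gamma(shape=alpha, scale=1/alpha), mean 1
    edges = gamma_dist.ppf(np.arange(1, K) / K, a=alpha, scale=1.0 / alpha)
    edges = np.concatenate(([0.0], edges, [np.inf]))
    # E[X · 1{X in bin}] for Gamma(a, rate a) = F_{a+1}(upper) − F_{a+1}(lower)
    cdf_up = gamma_dist.cdf(edges, a=alpha + 1.0, scale=1.0 / alpha)
    rates = K * np.diff(cdf_up)
    rates = np.maximum(rates, 1e-300)
    return rates / rates.mean()


@dataclass
class SubstitutionModel:
    """Reversible amino-acid CTMC with optional discrete-gamma rates."""

    name: str
    S: np.ndarray
    pi: np.ndarray
    alpha: float | None = None
    K: int = 1
    rates: np.ndarray = field(init=False)
    Q: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        if abs(self.pi.sum() - 1.0) > 1e-12:
            raise ModelError("equilibrium frequencies must sum to 1")
        if np.any(self.pi <= 0):
            raise ModelError("equilibrium frequencies must be positive")
        self.rates = (discrete_gamma_rates(self.alpha, self.K)
                      if self.alpha is not None else np.ones(self.K))
        if self.alpha is None and self.K != len(self.rates):
            raise ModelError("K > 1 requires a gamma shape")
        Q = self.S * self.pi[None, :]
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        scale = -np.sum(self.pi * np.diag(Q))
        self.Q = Q / scale
        # symmetric eigendecomposition for fast P(t)
        sq = np.sqrt(self.pi)
        B = (self.Q * sq[:, None]) / sq[None, :]
        B = 0.5 * (B + B.T)
        eigval, eigvec = np.linalg.eigh(B)
        self._eigval = eigval
        self._left = eigvec / sq[:, None]      # D^{-1/2} U
        self._right = eigvec.T * sq[None, :]   # U^T D^{1/2}

    def with_gamma(self, alpha: float | None, K: int) -> "SubstitutionModel":
        return SubstitutionModel(self.name, self.S, self.pi, alpha=alpha, K=K)

    def transition_matrix(self, t: float, category: int = 0) -> np.ndarray:
        """P(t·r) for branch length t under rate category ``category``.

        Row-stochastic; P(0) is the identity.  Tiny negative entries from the
        eigendecomposition are clipped and rows renormalized.
        """
        if t < 0:
            raise ModelError(f"branch length must be non-negative, got {t}")
        r = self.rates[category]
        P = (self._left * np.exp(self._eigval * t * r)) @ self._right
        np.clip(P, 0.0, None, out=P)
        P /= P.sum(axis=1, keepdims=True)
        return P

    def transition_matrices(self, t: float) -> np.ndarray:
        """Stack of P(t·r_k) over all K categories, shape (K, 20, 20)."""
        return np.stack([self.transition_matrix(t, k) for k in range(len(self.rates))])


def build_model(
    name: str,
    frequency_mode: str = "model",
    aln: ProteinAlignment | None = None,
    alpha: float | None = None,
    K: int = 4,
    pseudocount: float = 1.0,
) -> SubstitutionModel:
    """Assemble a substitution model.

    frequency_mode "model" uses the published equilibrium frequencies;
    "observed" (+F) recomputes them from the alignment's non-gap residues
    with a pseudocount.  ``alpha=None`` means rate-homogeneous (K forced
    to 1); otherwise a K-category discrete gamma.
    """
    if name not in MODEL_FILES:
        raise ModelError(
            f"unknown model '{name}'; supported: {', '.join(SUPPORTED_MODELS)}")
    S, pi = _load_dat(name)
    if frequency_mode == "observed":
        if aln is None:
            raise ModelError("observed frequencies require an alignment")
        pi = aln.observed_frequencies(pseudocount=pseudocount)
    elif frequency_mode != "model":
        raise ModelError(f"frequency_mode must be 'model' or 'observed', got {frequency_mode!r}")
    if alpha is None:
        K = 1
    return SubstitutionModel(name, S, pi, alpha=alpha, K=K)
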