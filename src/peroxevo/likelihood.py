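"""Alignment likelihood on a tree by Felsenstein pruning.

Implements the inside (pruning) pass shared with marginal ancestral
reconstruction, total/per-site log-likelihoods with per-node per-site
scaling (log space) to avoid underflow, coordinate-wise branch-length
optimization, 1-D gamma-shape estimation, and AIC model comparison.

Gaps and ambiguity codes are missing data: their leaf partials are all-ones,
so such sites contribute through marginalization (the PAML convention).
Identical alignment columns are collapsed to weighted site patterns; the
inner products use fixed-order einsum reductions so compressed and
uncompressed evaluation agree exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

from .alignment import MISSING, ProteinAlignment
from .models import SUPPORTED_MODELS, ModelError, SubstitutionModel, build_model
from .trees import PhyloTree, TreeError

BL_MIN, BL_MAX = 1e-8, 20.0


@dataclass
class LikelihoodResult:
    total: float
    per_site: np.ndarray
    model_name: str
    alpha: float | None
    history: list[float] = field(default_factory=list)


@dataclass
class GammaShapeEstimate:
    alpha: float
    log_likelihood: float
    #: True when the fit at the upper bound is within half a log-unit of the
    #: optimum (or the estimate sits at the bound): the data carry no usable
    #: rate-variation signal and are effectively rate-homogeneous.
    effectively_homogeneous: bool


@dataclass
class ModelComparison:
    name: str
    log_likelihood: float
    n_parameters: int
    aic: float


def _leaf_codes(tree: PhyloTree, aln: ProteinAlignment) -> dict[int, np.ndarray]:
    codes = aln.encode()
    by_id = {sid: codes[i] for i, sid in enumerate(aln.ids)}
    out = {}
    for i in tree.leaf_indices():
        name = tree.names[i]
        if name not in by_id:
            raise TreeError(f"leaf '{name}' has no sequence in the alignment")
        out[i] = by_id[name]
    return out


def _site_patterns(tree: PhyloTree, aln: ProteinAlignment):
    """Collapse identical columns; returns (leaf codes per pattern, weights, inverse)."""
    leaves = tree.leaf_indices()
    codes = _leaf_codes(tree, aln)
    mat = np.stack([codes[i] for i in leaves])          # (n_leaves, L)
    patterns, inverse, counts = np.unique(
        mat.T, axis=0, return_inverse=True, return_counts=True)
    per_leaf = {leaf: patterns[:, j] for j, leaf in enumerate(leaves)}
    return per_leaf, counts.astype(float), inverse.ravel()


def _inside_pass(tree: PhyloTree, leaf_codes: dict[int, np.ndarray],
                 n_patterns: int, model: SubstitutionModel):
    """Conditional likelihoods below each node, per rate category.

    Returns F of shape (K, n_nodes, n_patterns, 20) and accumulated log
    scaling factors logS of shape (K, n_nodes, n_patterns).
    """
    K = len(model.rates)
    n = tree.n_nodes
    F = np.empty((K, n, n_patterns, 20))
    logS = np.zeros((K, n, n_patterns))
    P = {v: model.transition_matrices(tree.blen[v])
         for v in range(n) if tree.parent[v] >= 0}
    post = tree.postorder()
    for v in post:
        if tree.is_leaf(v):
            vec = np.zeros((n_patterns, 20))
            code = leaf_codes[v]
            obs = code < MISSING
            vec[np.arange(n_patterns)[obs], code[obs]] = 1.0
            vec[~obs] = 1.0
            F[:, v] = vec[None, :, :]
        else:
            acc = np.ones((K, n_patterns, 20))
            sl = np.zeros((K, n_patterns))
            for c in tree.children[v]:
                # message from child c: sum_a P[b,a] F[c,a]
                msg = np.einsum("kpa,kba->kpb", F[:, c], P[c], optimize=False)
                acc = acc * msg
                sl = sl + logS[:, c]
            scale = acc.max(axis=2)
            scale[scale == 0.0] = 1.0
            F[:, v] = acc / scale[:, :, None]
            logS[:, v] = sl + np.log(scale)
    return F, logS


def _per_site_loglik(tree, F, logS, model, weights):
    """Per-pattern log-likelihood mixing over rate categories."""
    root = tree.root
    K = len(model.rates)
    site_k = np.einsum("kpa,a->kp", F[:, root], model.pi, optimize=False)
    with np.errstate(divide="ignore"):
        logs = np.log(site_k) + logS[:, root] - np.log(K)
    m = logs.max(axis=0)
    return m + np.log(np.exp(logs - m).sum(axis=0))


def log_likelihood(tree: PhyloTree, aln: ProteinAlignment,
                   model: SubstitutionModel,
                   compress: bool = True) -> LikelihoodResult:
    """Total and per-site log-likelihood of the alignment on the tree."""
    if compress:
        leaf_codes, weights, inverse = _site_patterns(tree, aln)
        n_patterns = len(weights)
    else:
        leaf_codes = _leaf_codes(tree, aln)
        n_patterns = aln.length
        inverse = np.arange(n_patterns)
        weights = np.ones(n_patterns)
    F, logS = _inside_pass(tree, leaf_codes, n_patterns, model)
    per_pattern = _per_site_loglik(tree, F, logS, model, weights)
    per_site = per_pattern[inverse]
    return LikelihoodResult(float(per_site.sum()), per_site,
                            model.name, model.alpha)


def optimize_branch_lengths(
    tree: PhyloTree, aln: ProteinAlignment, model: SubstitutionModel,
    tol: float = 1e-6, max_rounds: int = 20, min_rounds: int = 2,
) -> tuple[PhyloTree, LikelihoodResult]:
    """Coordinate-wise ML branch lengths, clamped to [1e-8, 20].

    One round optimizes every branch once (bounded Brent); rounds continue
    until the log-likelihood improves by less than ``tol`` (at least
    ``min_rounds`` rounds).  The log-likelihood is non-decreasing across
    the recorded history.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    leaf_codes, weights, inverse = _site_patterns(tree, aln)
    n_patterns = len(weights)
    blen = tree.blen.copy()
    edges = [v for v in range(tree.n_nodes) if tree.parent[v] >= 0]

    def total(bl: np.ndarray) -> float:
        F, logS = _inside_pass(tree.with_branch_lengths(bl), leaf_codes,
                               n_patterns, model)
        pp = _per_site_loglik(tree, F, logS, model, weights)
        return float((pp * weights).sum())

    history = [total(blen)]
    converged = False
    for rnd in range(max_rounds):
        for v in edges:
            def neg(t: float, v=v) -> float:
                trial = blen.copy()
                trial[v] = t
                return -total(trial)

            res = minimize_scalar(neg, bounds=(BL_MIN, BL_MAX), method="bounded",
                                  options={"xatol": 1e-8})
            if -res.fun >= history[-1]:
                blen[v] = float(np.clip(res.x, BL_MIN, BL_MAX))
        history.append(total(blen))
        if rnd + 1 >= min_rounds and history[-1] - history[-2] < tol:
            converged = True
            break
    if not converged:
        warnings.warn("branch-length optimization did not converge; "
                      "returning best-so-far", RuntimeWarning)
    new_tree = tree.with_branch_lengths(blen)
    result = log_likelihood(new_tree, aln, model)
    result.history = history
    return new_tree, result


def estimate_gamma_shape(
    tree: PhyloTree, aln: ProteinAlignment, model: SubstitutionModel,
    bounds: tuple[float, float] = (0.05, 100.0), K: int = 4,
) -> GammaShapeEstimate:
    """ML estimate of the discrete-gamma shape α by bounded 1-D search.

    When the likelihood at the upper bound is indistinguishable from the
    optimum the data look rate-homogeneous and the estimate is flagged.
    """
    lo, hi = bounds
    if not (0 < lo < hi):
        raise ValueError(f"invalid bounds {bounds}")
    leaf_codes, weights, inverse = _site_patterns(tree, aln)
    n_patterns = len(weights)

    def neg(log_alpha: float) -> float:
        m = model.with_gamma(float(np.exp(log_alpha)), K)
        F, logS = _inside_pass(tree, leaf_codes, n_patterns, m)
        return -float((_per_site_loglik(tree, F, logS, m, weights) * weights).sum())

    res = minimize_scalar(neg, bounds=(np.log(lo), np.log(hi)), method="bounded",
                          options={"xatol": 1e-6})
    alpha = float(np.exp(res.x))
    logl = -float(res.fun)
    homogeneous = alpha > hi * 0.99 or (-neg(np.log(hi))) > logl - 0.5
    return GammaShapeEstimate(alpha, logl, homogeneous)


def compare_models(
    tree: PhyloTree, aln: ProteinAlignment, model_names: list[str],
    estimate_alpha: bool = True, K: int = 4,
    optimize_lengths: bool = False,
) -> list[ModelComparison]:
    """Rank substitution models by AIC = 2k − 2·logL.

    k counts the free parameters actually estimated here: α when
    ``estimate_alpha``, plus the branch lengths when ``optimize_lengths``.
    Ties are broken by model name.
    """
    if len(model_names) < 2:
        raise ModelError("model comparison needs at least two model names")
    for nm in model_names:
        if nm not in SUPPORTED_MODELS:
            raise ModelError(f"unknown model '{nm}'; supported: "
                             f"{', '.join(SUPPORTED_MODELS)}")
    n_branches = int((tree.parent >= 0).sum())
    out = []
    for nm in model_names:
        base = build_model(nm)
        k = 0
        work_tree = tree
        if optimize_lengths:
            work_tree, _ = optimize_branch_lengths(tree, aln, base)
            k += n_branches
        if estimate_alpha:
            est = estimate_gamma_shape(work_tree, aln, base, K=K)
            logL = est.log_likelihood
            k += 1
        else:
            logL = log_likelihood(work_tree, aln, base).total
        out.append(ModelComparison(nm, logL, k, 2.0 * k - 2.0 * logL))
    out.sort(key=lambda m: (m.aic, m.name))
    return out
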