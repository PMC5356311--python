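"""Marginal (empirical-Bayes) ancestral sequence reconstruction.

For each internal node and site, the posterior probability of each amino
acid given all tip data, mixing over discrete-gamma rate categories.  The
default implementation is a single inside–outside sweep (O(nodes) total);
a re-rooting route (pull the queried node to the root, where the posterior
is just π · inside partials) is provided as an independent path — for a
reversible model the two must agree.

Ancestral presence/absence of a site (indels are not modelled in the CTMC)
is decided post hoc by a descendant-majority rule, standing in for the
manual, progeny-based indel curation used when ancestors are prepared for
resurrection: a site is ancestrally absent iff fewer than half of the
node's descendant leaves have a residue there.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .alignment import AA_ORDER, GAP, ProteinAlignment
from .likelihood import _inside_pass, _site_patterns
from .models import SubstitutionModel
from .trees import PhyloTree, TreeError


class ReconstructionError(ValueError):
    pass


@dataclass
class PosteriorMatrix:
    """Per-site amino-acid posteriors at one internal node.

    ``probs[s]`` sums to 1 at unmasked sites; masked (ancestrally absent)
    sites carry an all-zero row and are reported as gaps downstream.
    """

    node: str
    probs: np.ndarray          # (L, 20)
    gap_mask: np.ndarray       # (L,) bool, True = ancestrally absent

    @property
    def length(self) -> int:
        return self.probs.shape[0]

    def site_max(self) -> np.ndarray:
        return self.probs.max(axis=1)


@dataclass
class AncestralSequence:
    node: str
    sequence: str              # alignment coordinates, '-' at masked sites
    site_max: np.ndarray
    mean_confidence: float

    def ungapped(self) -> str:
        return self.sequence.replace(GAP, "")


def ancestral_gap_mask(tree: PhyloTree, aln: ProteinAlignment, node: str,
                       present_threshold: float = 0.5) -> np.ndarray:
    """Descendant-majority presence call per alignment column.

    Masked (absent) iff the fraction of the node's descendant leaves that
    are non-gap at the column is < ``present_threshold``; a fraction exactly
    at the threshold counts as present.
    """
    v = tree.index(node)
    leaves = [tree.names[i] for i in tree.descendant_leaves(v)]
    rows = np.array([[c != GAP for c in aln.row(name)] for name in leaves])
    frac = rows.mean(axis=0)
    return frac < present_threshold


def _outside_pass(tree: PhyloTree, model: SubstitutionModel, F, logS, P):
    """Outside conditional likelihoods G (root carries π), with scaling."""
    K, n, n_patterns, _ = F.shape
    G = np.empty_like(F)
    logSG = np.zeros((K, n, n_patterns))
    root = tree.root
    G[:, root] = model.pi[None, None, :]
    msgs = {}
    for v in range(n):
        if tree.parent[v] >= 0:
            msgs[v] = np.einsum("kpa,kba->kpb", F[:, v], P[v], optimize=False)
    for p_node in tree.preorder():
        kids = tree.children[p_node]
        for c in kids:
            H = G[:, p_node].copy()
            logH = logSG[:, p_node].copy()
            for u in kids:
                if u != c:
                    H = H * msgs[u]
                    logH = logH + logS[:, u]
            Gc = np.einsum("kpb,kba->kpa", H, P[c], optimize=False)
            scale = Gc.max(axis=2)
            scale[scale == 0.0] = 1.0
            G[:, c] = Gc / scale[:, :, None]
            logSG[:, c] = logH + np.log(scale)
    return G, logSG


def _mix_posterior(Fv, logSv, Gv, logSGv) -> np.ndarray:
    """Combine inside/outside partials over categories into one posterior."""
    joint = Fv * Gv                                   # (K, n_patterns, 20)
    logfac = logSv + logSGv                           # (K, n_patterns)
    m = logfac.max(axis=0)                            # (n_patterns,)
    w = np.exp(logfac - m[None, :])
    post = np.einsum("kp,kpa->pa", w, joint, optimize=False)
    total = post.sum(axis=1, keepdims=True)
    total[total == 0.0] = 1.0
    return post / total


def marginal_posteriors(
    tree: PhyloTree, aln: ProteinAlignment, model: SubstitutionModel,
    node: str, method: str = "two_pass",
    present_threshold: float = 0.5,
) -> PosteriorMatrix:
    """Posterior amino-acid distribution per site at one internal node."""
    v = tree.index(node)
    if tree.is_leaf(v):
        raise ReconstructionError(f"'{node}' is a leaf; ancestors are internal nodes")
    if method == "two_pass":
        post = all_marginal_posteriors(tree, aln, model,
                                       nodes=[node],
                                       present_threshold=present_threshold)[node]
        return post
    if method != "reroot":
        raise ReconstructionError(f"unknown method {method!r}")
    rerooted = tree.reroot_at(node)
    leaf_codes, weights, inverse = _site_patterns(rerooted, aln)
    F, logS = _inside_pass(rerooted, leaf_codes, len(weights), model)
    r = rerooted.root
    Fv = F[:, r] * model.pi[None, None, :]
    probs = _mix_posterior(Fv, logS[:, r], np.ones_like(Fv), np.zeros(logS[:, r].shape))
    probs = probs[inverse]
    mask = ancestral_gap_mask(tree, aln, node, present_threshold)
    probs[mask] = 0.0
    return PosteriorMatrix(node, probs, mask)


def all_marginal_posteriors(
    tree: PhyloTree, aln: ProteinAlignment, model: SubstitutionModel,
    nodes: list[str] | None = None,
    present_threshold: float = 0.5,
) -> dict[str, PosteriorMatrix]:
    """Posteriors for every requested internal node from one two-pass sweep."""
    if nodes is None:
        nodes = [tree.names[i] for i in tree.internal_indices()]
    for nm in nodes:
        if tree.is_leaf(tree.index(nm)):
            raise ReconstructionError(f"'{nm}' is a leaf; ancestors are internal nodes")
    leaf_codes, weights, inverse = _site_patterns(tree, aln)
    n_patterns = len(weights)
    F, logS = _inside_pass(tree, leaf_codes, n_patterns, model)
    P = {v: model.transition_matrices(tree.blen[v])
         for v in range(tree.n_nodes) if tree.parent[v] >= 0}
    G, logSG = _outside_pass(tree, model, F, logS, P)
    out = {}
    for nm in nodes:
        v = tree.index(nm)
        probs = _mix_posterior(F[:, v], logS[:, v], G[:, v], logSG[:, v])[inverse]
        mask = ancestral_gap_mask(tree, aln, nm, present_threshold)
        probs[mask] = 0.0
        out[nm] = PosteriorMatrix(nm, probs, mask)
    return out


def most_probable_sequence(post: PosteriorMatrix) -> AncestralSequence:
    """Per-site argmax sequence; ties broken by canonical amino-acid order."""
    idx = post.probs.argmax(axis=1)      # first max = alphabetical tie-break
    chars = np.array(list(AA_ORDER))[idx]
    chars[post.gap_mask] = GAP
    site_max = post.site_max()
    conf = (reconstruction_confidence(post)
            if not post.gap_mask.all() else float("nan"))
    return AncestralSequence(post.node, "".join(chars), site_max, conf)


def reconstruction_confidence(post: PosteriorMatrix) -> float:
    """Mean of per-site maximum posteriors over unmasked sites."""
    unmasked = ~post.gap_mask
    if not unmasked.any():
        raise ReconstructionError(
            f"node '{post.node}': every site is masked; no confidence defined")
    return float(post.site_max()[unmasked].mean())
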