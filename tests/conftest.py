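import numpy as np
import pytest

from peroxevo.alignment import AA_INDEX, MISSING, ProteinAlignment
from peroxevo.models import build_model
from peroxevo.trees import tree_from_string

AA = "ACDEFGHIKLMNPQRSTVWY"


@pytest.fixture(scope="session")
def wag():
    return build_model("WAG")


@pytest.fixture(scope="session")
def wag_gamma():
    return build_model("WAG", alpha=0.7, K=4)


@pytest.fixture()
def quartet():
    """A 4-leaf tree and random ungapped alignment, small enough to enumerate."""
    rng = np.random.default_rng(42)
    tree = tree_from_string("((A:0.12,B:0.31)N1:0.21,(C:0.4,D:0.09)N2:0.17)N3;")
    rows = ["".join(rng.choice(list(AA), 8)) for _ in range(4)]
    return tree, ProteinAlignment(["A", "B", "C", "D"], rows)


def _leaf_vector(aln, name, site):
    c = aln.row(name)[site]
    code = AA_INDEX.get(c, MISSING)
    v = np.zeros(20)
    if code == MISSING:
        v[:] = 1.0
    else:
        v[code] = 1.0
    return v


def quartet_oracle(tree, aln, model):
    """Brute-force likelihood/posteriors for a ((A,B)N1,(C,D)N2)N3 tree.

    Enumerates the full joint over the three internal states (x at N1,
    y at N2, z at the root) as an explicit 20x20x20 tensor per site and
    rate category — no pruning recursion involved — and marginalizes.
    Returns (per-site log-likelihoods, {internal node: (L, 20) posteriors}).
    """
    root = tree.root
    n1, n2 = tree.children[root]
    names = tree.names
    kids1 = [names[c] for c in tree.children[n1]]
    kids2 = [names[c] for c in tree.children[n2]]
    K = len(model.rates)
    L = aln.length
    site_lik = np.zeros(L)
    joint_sum = np.zeros((L, 20, 20, 20))   # (site, x, y, z)
    for k in range(K):
        P = {v: model.transition_matrix(tree.blen[v], k)
             for v in range(tree.n_nodes) if tree.parent[v] >= 0}
        for s in range(L):
            la = P[tree.index(kids1[0])] @ _leaf_vector(aln, kids1[0], s)
            lb = P[tree.index(kids1[1])] @ _leaf_vector(aln, kids1[1], s)
            lc = P[tree.index(kids2[0])] @ _leaf_vector(aln, kids2[0], s)
            ld = P[tree.index(kids2[1])] @ _leaf_vector(aln, kids2[1], s)
            # joint[x, y, z] = pi_z P(z->x) P(z->y) la_x lb_x lc_y ld_y
            t = (model.pi[None, None, :]
                 * P[n1].T[:, None, :]          # (x, 1, z)
                 * P[n2].T[None, :, :]          # (1, y, z)
                 * (la * lb)[:, None, None]
                 * (lc * ld)[None, :, None])
            joint_sum[s] += t / K
    site_lik = joint_sum.sum(axis=(1, 2, 3))
    posts = {
        names[n1]: joint_sum.sum(axis=(2, 3)) / site_lik[:, None],
        names[n2]: joint_sum.sum(axis=(1, 3)) / site_lik[:, None],
        names[root]: joint_sum.sum(axis=(1, 2)) / site_lik[:, None],
    }
    return np.log(site_lik), posts
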