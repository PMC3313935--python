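"""Brute-force oracles, independent of the pruning/outside recursions.

Likelihoods and joint flanking-state posteriors are computed by explicit
summation over every assignment of states to every node of the tree, which
is feasible for trees with a handful of leaves and is the reference the
dynamic programs are checked against.
"""

import numpy as np


def _assignment_weights(tree, site_ind, P, rootdist):
    """Weight of every full state assignment (K^n_nodes vector) for one site.

    ``site_ind`` maps taxon label -> indicator vector; ``P`` maps branch id
    -> transition matrix (bottom state row, top state column).
    """
    nodes = tree.nodes
    K = len(rootdist)
    n = len(nodes)
    grids = np.indices((K,) * n).reshape(n, -1)
    w = np.asarray(rootdist, dtype=float)[grids[0]]
    for nd in nodes:
        if nd.parent is not None:
            w = w * P[nd.branch_id][grids[nd.parent.node_id], grids[nd.node_id]]
        if nd.label in site_ind:
            w = w * site_ind[nd.label][grids[nd.node_id]]
    return grids, w


def enum_site_likelihood(tree, site_ind, P, rootdist):
    _, w = _assignment_weights(tree, site_ind, P, rootdist)
    return float(w.sum())


def enum_joint_posterior(tree, site_ind, P, rootdist, branch_id):
    """Joint posterior of (parent state, child state) across a branch."""
    grids, w = _assignment_weights(tree, site_ind, P, rootdist)
    node = tree.branch_node(branch_id)
    K = len(rootdist)
    J = np.zeros((K, K))
    np.add.at(J, (grids[node.parent.node_id], grids[node.node_id]), w)
    return J / J.sum()


def enum_marginal_posterior(tree, site_ind, P, rootdist, node_id):
    """Marginal posterior of the state at one node."""
    grids, w = _assignment_weights(tree, site_ind, P, rootdist)
    K = len(rootdist)
    m = np.zeros(K)
    np.add.at(m, grids[node_id], w)
    return m / m.sum()
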