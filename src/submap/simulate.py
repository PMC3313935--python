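"""Non-homogeneous sequence simulation with true-path logging.

Sites evolve independently.  Root states are drawn from the stationary
distribution of a designated root model; along each mapped branch, full
substitution paths are simulated by the Gillespie algorithm under that
branch's generator for the branch's duration, and every realized jump is
typed by a substitution register and tallied into a :class:`SimulationTruth`
record.  The same seed therefore reproduces both the alignment and the true
counts, and with per-branch substreams the homogeneous and an
all-branches-equal non-homogeneous configuration produce bitwise-identical
data.

Parameter samplers implement the study conditions of the simulation
experiments: branch-specific dN/dS drawn from a gamma distribution of mean
0.2 and shape 0.5, and branch-specific equilibrium GC drawn uniformly on
(0, 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ParameterError
from .mapping import simulate_paths
from .models import BranchModelMap, register_dnds, register_gc
from .phylio import Alignment, Node, Tree

__all__ = [
    "SimulationTruth",
    "draw_branch_omegas",
    "draw_branch_thetas",
    "simulate_alignment",
    "distort_branch_lengths",
    "random_tree",
]


@dataclass
class SimulationTruth:
    """True typed substitution counts and per-branch parameters of one run."""

    counts: pd.DataFrame          # index branch_id, one column per type
    branch_params: dict           # branch_id -> parameter dict
    types: tuple
    seed: object = None
    config: dict = field(default_factory=dict)

    def totals(self):
        return self.counts.sum(axis=1)

    @property
    def grand_total(self):
        return int(self.counts.values.sum())

    def to_tsv(self, path, param_name="param"):
        rows = []
        for bid in self.counts.index:
            for s in self.types:
                par = self.branch_params.get(bid, {})
                val = next(iter(par.values())) if par else ""
                rows.append((bid, s, int(self.counts.loc[bid, s]), val))
        with open(path, "w") as fh:
            fh.write(f"branch_id\ttype\ttrue_count\ttrue_{param_name}\n")
            for r in rows:
                fh.write("\t".join(str(v) for v in r) + "\n")


def _branch_seed_sequences(seed, n_branches):
    """One independent substream per branch (+1 for the root draw),
    derived from a single master seed by counter-based spawning."""
    master = np.random.SeedSequence(seed)
    return master.spawn(n_branches + 1)


def draw_branch_omegas(tree=None, mean=0.2, shape=0.5, seed=None, n=None):
    """Branch-specific dN/dS values from a gamma distribution.

    The distribution is parameterized by its mean and shape (scale =
    mean/shape; the defaults give mean 0.2, shape 0.5, variance 0.08).
    Returns a ``{branch_id: omega}`` map when given a tree, or a plain array
    of ``n`` draws.
    """
    if mean <= 0 or shape <= 0:
        raise ParameterError("gamma mean and shape must be > 0")
    if (tree is None) == (n is None):
        raise ParameterError("provide exactly one of tree or n")
    rng = np.random.default_rng(seed)
    count = tree.n_branches if tree is not None else int(n)
    draws = rng.gamma(shape, scale=mean / shape, size=count)
    draws = np.maximum(draws, 1e-9)  # strictly positive for model validity
    if tree is None:
        return draws
    return {bid: float(w) for bid, w in zip(range(1, count + 1), draws)}


def draw_branch_thetas(tree=None, seed=None, n=None):
    """Branch-specific equilibrium-GC values, Uniform(0, 1) clipped away
    from the boundaries by 1e-6 for model validity."""
    if (tree is None) == (n is None):
        raise ParameterError("provide exactly one of tree or n")
    rng = np.random.default_rng(seed)
    count = tree.n_branches if tree is not None else int(n)
    draws = np.clip(rng.random(count), 1e-6, 1 - 1e-6)
    if tree is None:
        return draws
    return {bid: float(th) for bid, th in zip(range(1, count + 1), draws)}


def _default_register(alphabet):
    return register_dnds(alphabet) if alphabet.kind == "codon" else register_gc(alphabet)


def simulate_alignment(tree, models, n_sites, seed=None, register=None):
    """Simulate an alignment under a (possibly branch-heterogeneous) model.

    Returns the leaf alignment and a :class:`SimulationTruth` with the
    per-branch typed substitution counts realized along the simulated paths.
    """
    if not isinstance(models, BranchModelMap):
        models = BranchModelMap.homogeneous(models)
    models.validate_branch_ids(tree)
    if n_sites < 1:
        raise ParameterError(f"n_sites must be >= 1, got {n_sites}")
    alphabet = models.alphabet
    if register is None:
        register = _default_register(alphabet)
    if register.alphabet != alphabet:
        raise ParameterError("register alphabet does not match model alphabet")

    m = tree.n_branches
    seqs = _branch_seed_sequences(seed, m)
    root_rng = np.random.default_rng(seqs[0])
    rootdist = models.root_distribution
    K = alphabet.size

    states = {tree.root.node_id: root_rng.choice(K, size=n_sites, p=rootdist)}
    counts = np.zeros((m, len(register.types)), dtype=int)
    for node in tree.nodes:  # preorder: parents visited before children
        if node.parent is None:
            continue
        bid = node.branch_id
        model = models.model_for_branch(bid)
        rng = np.random.default_rng(seqs[bid])
        start = states[node.parent.node_id]
        if node.length > 0:
            end, typed = simulate_paths(model, node.length, register, start, rng)
            counts[bid - 1] += typed.sum(axis=0)
        else:
            end = start.copy()
        states[node.node_id] = end

    taxa, rows = [], []
    for leaf in tree.leaves:
        taxa.append(leaf.label)
        rows.append([alphabet.states[k] for k in states[leaf.node_id]])
    aln = Alignment(alphabet, taxa, rows)

    params = {}
    for bid in range(1, m + 1):
        params[bid] = dict(models.overrides.get(bid, {}))
    truth = SimulationTruth(
        counts=pd.DataFrame(counts, index=pd.Index(range(1, m + 1), name="branch_id"),
                            columns=list(register.types)),
        branch_params=params,
        types=register.types,
        seed=seed,
        config={"family": models.family, "shared": dict(models.shared),
                "n_sites": n_sites},
    )
    return aln, truth


def distort_branch_lengths(tree, fraction=0.25, seed=None):
    """Multiply every branch length by an independent Uniform(1-f, 1+f) factor.

    Reproduces the branch-length distortion used to probe the robustness of
    substitution mapping; topology is unchanged and zero-length branches
    stay zero.
    """
    if not 0 <= fraction < 1:
        raise ParameterError(f"fraction must be in [0, 1), got {fraction}")
    rng = np.random.default_rng(seed)
    out = tree.copy()
    for bid, t in out.branch_lengths().items():
        factor = rng.uniform(1 - fraction, 1 + fraction)
        out.set_branch_length(bid, t * factor)
    return out


def random_tree(n_leaves, seed=None, length_low=0.02, length_high=0.3,
                label_prefix="T"):
    """Random unrooted binary tree with i.i.d. uniform branch lengths.

    Topology is built by random sequential joins; the display has a
    trifurcating root so the tree exposes ``2 n_leaves - 3`` mapped branches.
    """
    if n_leaves < 3:
        raise ParameterError("random_tree requires at least 3 leaves")
    rng = np.random.default_rng(seed)
    nodes = [Node(label=f"{label_prefix}{i + 1}") for i in range(n_leaves)]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = Node()
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes = [nd for k, nd in enumerate(nodes) if k not in (i, j)] + [parent]
    root = Node()
    for nd in nodes:
        root.add_child(nd)
    tree = Tree(root)
    for nd in tree.nodes:
        if nd.parent is not None:
            nd.length = float(rng.uniform(length_low, length_high))
    return Tree(tree.root)
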