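"""Endpoint-conditioned expected substitution counts and substitution maps.

The core quantity is ``E[N_s | x, y, t]``: the expected number of type-``s``
substitutions on a branch of length ``t`` given the states at its two ends.
It is computed exactly (to a documented series tolerance) by uniformization:
the chain is embedded in a Poisson process of rate ``mu >= max_i |Q_ii|``
with one-jump transition matrix ``R = I + Q/mu``; summing the
Poisson-weighted expected number of real (state-changing) jumps of each type
over the number of uniformized jumps and dividing by ``P_xy(t)`` gives the
conditional expectation.  The Poisson series is truncated when its remaining
tail mass falls below a tolerance (1e-10 by default), with the truncation
point taken from the Poisson inverse CDF.

``map_alignment`` combines these kernels with the joint endpoint posteriors
from the inference engine: the posterior expected count of type ``s`` on
branch ``b`` at site ``i`` averages ``E[N_s | x, y, t_b]`` over the joint
posterior of the flanking states, and per-branch totals sum over sites.
A per-branch kernel is computed once and reused across all sites.

``mc_conditional_counts`` is an independent Monte-Carlo oracle: forward
Gillespie simulation of full substitution paths, rejecting paths that do not
end in the required state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import poisson

from .exceptions import NumericalError, ParameterError, SubmapError
from .inference import LikelihoodEngine
from .models import BranchModelMap, SubstitutionModel, SubstitutionRegister

__all__ = [
    "ConditionalCountKernel",
    "conditional_counts",
    "CountsTable",
    "map_alignment",
    "mc_conditional_counts",
    "simulate_paths",
]

_TAIL = 1e-10
_MAX_TERMS = 10_000
_P_UNDERFLOW = 1e-300


@dataclass
class ConditionalCountKernel:
    """E[N_s | x, y, t] for every ordered state pair and register type.

    ``counts[x, y, s]`` is the conditional expectation; ``pxy`` holds the
    endpoint probabilities ``P_xy(t)`` from the same truncated series, and
    ``unreliable`` flags cells whose endpoint probability underflowed.
    """

    model: SubstitutionModel
    t: float
    register: SubstitutionRegister
    counts: np.ndarray        # (K, K, S)
    pxy: np.ndarray           # (K, K)
    unreliable: np.ndarray    # (K, K) bool
    n_terms: int = 0

    @property
    def total(self):
        """E[N_total | x, y, t] — sum over register types (partition)."""
        return self.counts.sum(axis=2)


def conditional_counts(model, t, register, mu_factor=1.05, tail=_TAIL,
                       max_terms=_MAX_TERMS):
    """Exact endpoint-conditioned typed substitution counts by uniformization.

    Parameters
    ----------
    model : SubstitutionModel
    t : float
        Branch length (> 0) in expected substitutions per site.
    register : SubstitutionRegister
        Typing of ordered state pairs; must share the model's alphabet.
    mu_factor : float
        Uniformization rate as a multiple of ``max_i |Q_ii|`` (>= 1); the
        default 1.05 keeps a positive self-loop probability in every row.
    tail : float
        Poisson tail mass at which the series is truncated.
    """
    if t <= 0:
        raise ParameterError(f"branch length must be > 0, got {t}")
    if register.alphabet != model.alphabet:
        raise ParameterError("register alphabet does not match model alphabet")
    if mu_factor < 1.0:
        raise ParameterError("mu_factor must be >= 1 for a valid uniformization")
    Q = model.Q
    K = model.size
    mu = mu_factor * float(np.max(-np.diag(Q)))
    R = np.eye(K) + Q / mu

    lam = mu * t
    n_max = int(poisson.ppf(1.0 - tail, lam)) + 1
    n_max = min(max(n_max, 2), max_terms)
    weights = poisson.pmf(np.arange(n_max + 1), lam)

    types = register.types
    S = len(types)
    # real jumps of type s under the uniformized chain
    L = np.stack([np.where(register.masks[s], R, 0.0) for s in types])  # (S, K, K)

    # A[s] accumulates sum_n w_n * sum_{k<n} R^k L_s R^{n-1-k}
    # via the recursion C_n = R C_{n-1} + L_s R^{n-1}
    A = np.zeros((S, K, K))
    C = np.zeros((S, K, K))
    R_pow = np.eye(K)                 # R^{n-1} entering iteration n
    P_t = weights[0] * np.eye(K)
    for n in range(1, n_max + 1):
        C = R @ C + L @ R_pow         # sum_{k<n} R^k L_s R^{n-1-k}
        A += weights[n] * C
        R_pow = R_pow @ R             # R^n
        P_t += weights[n] * R_pow

    unreliable = P_t < _P_UNDERFLOW
    denom = np.where(unreliable, 1.0, P_t)
    counts = np.transpose(A, (1, 2, 0)) / denom[:, :, None]
    counts[unreliable] = 0.0
    if np.any(counts < -1e-9):
        raise NumericalError("negative conditional count: series truncation too aggressive")
    counts = np.clip(counts, 0.0, None)
    return ConditionalCountKernel(model=model, t=float(t), register=register,
                                  counts=counts, pxy=P_t, unreliable=unreliable,
                                  n_terms=n_max)


# ---------------------------------------------------------------------------
# Counts tables
# ---------------------------------------------------------------------------

@dataclass
class CountsTable:
    """Posterior expected substitution counts per (branch, type).

    ``per_branch`` is a DataFrame indexed by branch id with one column per
    register type; ``per_site`` optionally holds the (m, n_sites, S) layer
    whose site sums reproduce the per-branch totals.
    """

    types: tuple
    per_branch: pd.DataFrame
    branch_lengths: dict
    branch_parents: dict = field(default_factory=dict)
    branch_children: dict = field(default_factory=dict)
    per_site: np.ndarray = None
    metadata: dict = field(default_factory=dict)

    @property
    def branch_ids(self):
        return list(self.per_branch.index)

    def totals(self):
        """Per-branch total counts over all types (Series)."""
        return self.per_branch.sum(axis=1)

    @property
    def grand_total(self):
        return float(self.per_branch.values.sum())

    def to_tsv(self, path, per_site_path=None):
        with open(path, "w") as fh:
            for k, v in self.metadata.items():
                fh.write(f"# {k}: {v}\n")
            fh.write("branch_id\tparent_label\tchild_label\tbranch_length\ttype\tcount\n")
            for bid in self.branch_ids:
                for s in self.types:
                    fh.write(
                        f"{bid}\t{self.branch_parents.get(bid, '')}\t"
                        f"{self.branch_children.get(bid, '')}\t"
                        f"{self.branch_lengths[bid]:.10g}\t{s}\t"
                        f"{self.per_branch.loc[bid, s]:.10g}\n")
        if per_site_path is not None and self.per_site is not None:
            with open(per_site_path, "w") as fh:
                fh.write("branch_id\tsite\ttype\tcount\n")
                for bi, bid in enumerate(self.branch_ids):
                    for i in range(self.per_site.shape[1]):
                        for si, s in enumerate(self.types):
                            fh.write(f"{bid}\t{i + 1}\t{s}\t{self.per_site[bi, i, si]:.10g}\n")

    @classmethod
    def from_tsv(cls, path):
        metadata = {}
        with open(path) as fh:
            pos = fh.tell()
            line = fh.readline()
            while line.startswith("#"):
                key, _, val = line[1:].partition(":")
                metadata[key.strip()] = val.strip()
                pos = fh.tell()
                line = fh.readline()
            fh.seek(pos)
            df = pd.read_csv(fh, sep="\t")
        types = tuple(dict.fromkeys(df["type"]))
        wide = df.pivot_table(index="branch_id", columns="type", values="count",
                              sort=False)[list(types)]
        lengths = dict(zip(df["branch_id"], df["branch_length"]))
        parents = dict(zip(df["branch_id"], df["parent_label"].fillna("")))
        children = dict(zip(df["branch_id"], df["child_label"].fillna("")))
        return cls(types=types, per_branch=wide, branch_lengths=lengths,
                   branch_parents=parents, branch_children=children, metadata=metadata)


def _node_name(node):
    if node.label:
        return node.label
    return f"node{node.node_id}"


def map_alignment(tree, aln, models, register, per_site=False, engine=None,
                  kernel_cache=None):
    """Posterior expected typed substitution counts for every branch (and site).

    For branch ``b`` with flanking-state joint posterior ``J_{b,i}`` and
    count kernel ``E[N_s | x, y, t_b]``, the per-site count is
    ``n_{b,i}(s) = sum_{x,y} J_{b,i}[x,y] E[N_s | x, y, t_b]`` and the
    per-branch count sums over sites.  One kernel per distinct
    (branch model, branch length) pair serves all sites.
    """
    if engine is None:
        engine = LikelihoodEngine(tree, aln, models)
    if register.alphabet != aln.alphabet:
        raise ParameterError("register alphabet does not match alignment alphabet")
    bad = np.where(~np.isfinite(engine.site_loglik))[0]
    if bad.size:
        raise SubmapError(f"zero likelihood at site {bad[0] + 1}; cannot map")
    mmap = engine.models
    m = tree.n_branches
    types = register.types
    S = len(types)
    n_sites = aln.n_sites
    site_layer = np.zeros((m, n_sites, S))
    cache = kernel_cache if kernel_cache is not None else {}

    for bid in range(1, m + 1):
        node = tree.branch_node(bid)
        t = node.length
        if t == 0:
            continue  # zero-length branches carry zero counts by convention
        model = mmap.model_for_branch(bid)
        key = (id(model), float(t), id(register))
        if key not in cache:
            cache[key] = conditional_counts(model, t, register)
        kernel = cache[key]
        D, P, U, denom = engine.branch_arrays(bid)
        for si in range(S):
            M = P * kernel.counts[:, :, si]
            site_layer[bid - 1, :, si] = np.einsum("ix,xy,iy->i", D, M, U) / denom

    per_branch = pd.DataFrame(site_layer.sum(axis=1),
                              index=pd.Index(range(1, m + 1), name="branch_id"),
                              columns=list(types))
    parents, children = {}, {}
    for bid in range(1, m + 1):
        node = tree.branch_node(bid)
        children[bid] = _node_name(node)
        parents[bid] = _node_name(node.parent)
    meta = {
        "model": mmap.family,
        "register": "|".join(types),
        "n_sites": n_sites,
        "n_taxa": aln.n_taxa,
    }
    return CountsTable(types=types, per_branch=per_branch,
                       branch_lengths=tree.branch_lengths(),
                       branch_parents=parents, branch_children=children,
                       per_site=site_layer if per_site else None, metadata=meta)


# ---------------------------------------------------------------------------
# Monte-Carlo path oracle
# ---------------------------------------------------------------------------

def simulate_paths(model, t, register, start_states, rng):
    """Forward Gillespie simulation of substitution paths (vectorized).

    Parameters
    ----------
    start_states : (n,) int array of initial states.

    Returns
    -------
    end_states : (n,) int array
    typed_counts : (n, S) int array of real jumps per register type
    """
    Q = model.Q
    K = model.size
    rates = -np.diag(Q)
    with np.errstate(invalid="ignore", divide="ignore"):
        jump_probs = np.where(rates[:, None] > 0, Q / rates[:, None], 0.0)
    np.fill_diagonal(jump_probs, 0.0)
    cum = np.cumsum(jump_probs, axis=1)
    cum[:, -1] = 1.0  # guard against rounding

    type_index = np.full((K, K), -1, dtype=int)
    for si, s in enumerate(register.types):
        type_index[register.masks[s]] = si

    n = len(start_states)
    S = len(register.types)
    state = np.asarray(start_states, dtype=int).copy()
    clock = np.zeros(n)
    counts = np.zeros((n, S), dtype=int)
    active = np.ones(n, dtype=bool)
    while active.any():
        idx = np.where(active)[0]
        cur = state[idx]
        r = rates[cur]
        dt = np.where(r > 0, rng.exponential(1.0, size=idx.size) / np.maximum(r, 1e-300),
                      np.inf)
        clock[idx] += dt
        done = clock[idx] > t
        active[idx[done]] = False
        jumping = idx[~done]
        if jumping.size == 0:
            continue
        u = rng.random(jumping.size)
        rows = cum[state[jumping]]
        nxt = (rows < u[:, None]).sum(axis=1)
        ti = type_index[state[jumping], nxt]
        np.add.at(counts, (jumping, ti), 1)
        state[jumping] = nxt
    return state, counts


def mc_conditional_counts(model, t, register, x, y, n_paths, seed):
    """Monte-Carlo estimate of E[N_s | x, y, t] by rejection sampling.

    Simulates ``n_paths`` forward paths from state ``x`` of duration ``t``
    and keeps those ending in ``y``.  Returns per-type means, standard
    errors, and the number of accepted paths.
    """
    if n_paths < 1:
        raise ParameterError("n_paths must be >= 1")
    rng = np.random.default_rng(seed)
    start = np.full(n_paths, int(x), dtype=int)
    ends, counts = simulate_paths(model, t, register, start, rng)
    accepted = counts[ends == int(y)]
    n_acc = accepted.shape[0]
    if n_acc < 100:
        raise NumericalError(
            f"only {n_acc} of {n_paths} paths ended in the required state; "
            "increase n_paths for this endpoint pair")
    means = accepted.mean(axis=0)
    ses = accepted.std(axis=0, ddof=1) / np.sqrt(n_acc)
    return {
        "types": register.types,
        "mean": means,
        "se": ses,
        "n_accepted": n_acc,
    }
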