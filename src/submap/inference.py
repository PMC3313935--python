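"""Pruning likelihoods, joint endpoint posteriors, and coarse ML fitting.

The engine runs the pruning (inside) recursion vectorized across sites with
per-node rescaling, plus an outside recursion that yields, for every mapped
branch, the joint posterior distribution of the two states flanking the
branch given the whole alignment column.  These joint posteriors are the
averaging weights of probabilistic substitution mapping.

``fit_homogeneous`` performs the deliberately rough maximum-likelihood fit
used before mapping: round-robin one-dimensional searches over the
substitution parameters and the branch lengths, stopping when a full round
improves the log-likelihood by less than ``tol_lnl`` (1.0 by default —
mapping is robust to rough fits, so precision beyond a log-likelihood point
buys nothing).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

from .exceptions import NumericalError, ParameterError, SubmapError
from .models import BranchModelMap, SubstitutionModel, f3x4_frequencies

__all__ = [
    "LikelihoodEngine",
    "site_likelihood",
    "joint_endpoint_posterior",
    "FitResult",
    "fit_homogeneous",
]

_BL_FLOOR = 1e-6
_BL_CEIL = 100.0


def _as_model_map(models):
    if isinstance(models, SubstitutionModel):
        return BranchModelMap.homogeneous(models)
    if isinstance(models, BranchModelMap):
        return models
    raise ParameterError(f"expected SubstitutionModel or BranchModelMap, got {type(models)}")


class LikelihoodEngine:
    """Inside/outside likelihood arrays for one (tree, alignment, model) triple.

    Attributes of interest after construction:

    site_loglik : (n_sites,) array
        Per-site log-likelihoods (``-inf`` for impossible sites).
    up[node_id] : (n_sites, K)
        Rescaled conditional likelihoods of the subtree below a node.
    down[node_id] : (n_sites, K)
        Rescaled outside array for the branch above a node: root prior times
        everything outside that branch's subtree, evaluated at the parent
        state.
    """

    def __init__(self, tree, aln, models, compute_outside=True):
        self.tree = tree
        self.aln = aln
        self.models = _as_model_map(models)
        self.models.validate_branch_ids(tree)
        if set(tree.leaf_labels) != set(aln.taxa):
            missing = set(tree.leaf_labels) ^ set(aln.taxa)
            raise SubmapError(f"tree/alignment taxa mismatch: {sorted(missing)}")
        if self.models.alphabet != aln.alphabet:
            raise ParameterError("model alphabet does not match alignment alphabet")
        self.K = aln.alphabet.size
        self.n_sites = aln.n_sites
        self._row = {t: r for r, t in enumerate(aln.taxa)}
        self.P = {}      # branch_id -> transition matrix
        self.up = {}     # node_id -> scaled inside partials
        self.uplog = {}  # node_id -> per-site log scaling accumulator
        self.msg = {}    # node_id -> up @ P.T message to the parent
        self._run_inside()
        if compute_outside:
            self._run_outside()
        else:
            self.down = None

    # -- inside (pruning) ---------------------------------------------------

    def _run_inside(self):
        ind = self.aln.indicators()
        for node in self.tree.postorder():
            # a taxon node contributes its observed-state indicator; in the
            # 2-leaf display the root itself is a taxon and works the same
            if node.label in self._row:
                part = ind[self._row[node.label]].copy()
            else:
                part = np.ones((self.n_sites, self.K))
            logscale = np.zeros(self.n_sites)
            for child in node.children:
                m = self._message(child)
                part = part * m
                logscale = logscale + self.uplog[child.node_id]
            # per-site rescaling
            mx = part.max(axis=1)
            safe = np.where(mx > 0, mx, 1.0)
            part = part / safe[:, None]
            logscale = logscale + np.where(mx > 0, np.log(safe), -np.inf)
            self.up[node.node_id] = part
            self.uplog[node.node_id] = logscale
        root = self.tree.root
        rootdist = self.models.root_distribution
        lik = self.up[root.node_id] @ rootdist
        with np.errstate(divide="ignore"):
            self.site_loglik = np.log(lik) + self.uplog[root.node_id]

    def _message(self, child):
        """up[child] propagated through the branch above child."""
        nid = child.node_id
        if nid not in self.msg:
            P = self._transition(child)
            self.msg[nid] = self.up[nid] @ P.T
        return self.msg[nid]

    def _transition(self, node):
        bid = node.branch_id
        if bid not in self.P:
            model = self.models.model_for_branch(bid)
            self.P[bid] = model.transition_matrix(node.length)
        return self.P[bid]

    # -- outside ------------------------------------------------------------

    def _run_outside(self):
        root = self.tree.root
        self.down = {}    # node_id -> D array (outside at parent state, scaled)
        G = {root.node_id: np.tile(self.models.root_distribution, (self.n_sites, 1))}
        if root.label in self._row:
            # a taxon at the root contributes its observed-state indicator
            ind = self.aln.indicators()
            G[root.node_id] = G[root.node_id] * ind[self._row[root.label]]
        for node in self.tree.nodes:  # preorder
            for child in node.children:
                D = G[node.node_id].copy()
                for sib in node.children:
                    if sib is not child:
                        D = D * self._message(sib)
                mx = D.max(axis=1)
                safe = np.where(mx > 0, mx, 1.0)
                D = D / safe[:, None]
                self.down[child.node_id] = D
                if not child.is_leaf:
                    Gc = D @ self._transition(child)
                    mxc = Gc.max(axis=1)
                    Gc = Gc / np.where(mxc > 0, mxc, 1.0)[:, None]
                    G[child.node_id] = Gc

    # -- queries ------------------------------------------------------------

    @property
    def total_loglik(self):
        return float(self.site_loglik.sum())

    def joint_posterior(self, branch_id, site):
        """Joint posterior P(bottom=x, top=y | column) for a branch and 1-based site.

        Rows index the ancestral-side (bottom) state, columns the
        descendant-side (top) state of the branch.
        """
        if self.down is None:
            raise ParameterError("engine was built with compute_outside=False")
        if not 1 <= site <= self.n_sites:
            raise ParameterError(f"site {site} out of range 1..{self.n_sites}")
        i = site - 1
        if not np.isfinite(self.site_loglik[i]):
            raise NumericalError(f"site {site} has zero likelihood; posterior undefined")
        node = self.tree.branch_node(branch_id)
        P = self._transition(node)
        J = self.down[node.node_id][i][:, None] * P * self.up[node.node_id][i][None, :]
        total = J.sum()
        if total <= 0:
            raise NumericalError(f"degenerate joint posterior on branch {branch_id}, site {site}")
        return J / total

    def branch_arrays(self, branch_id):
        """(D, P, U, denom): scaled outside array, transition matrix, scaled
        inside array and per-site joint normalizer for one branch.  The
        normalizer is the site likelihood expressed in the same scaling as
        ``D`` and ``U``, so ratios of bilinear forms in these arrays are
        exact posteriors."""
        node = self.tree.branch_node(branch_id)
        D = self.down[node.node_id]
        U = self.up[node.node_id]
        P = self._transition(node)
        denom = np.einsum("ix,xy,iy->i", D, P, U)
        return D, P, U, denom


def site_likelihood(tree, aln, models, site):
    """Log-likelihood of one 1-based alignment column."""
    engine = LikelihoodEngine(tree, aln, models, compute_outside=False)
    if not 1 <= site <= aln.n_sites:
        raise ParameterError(f"site {site} out of range 1..{aln.n_sites}")
    return float(engine.site_loglik[site - 1])


def joint_endpoint_posterior(tree, aln, models, branch, site):
    """Joint posterior of the two states flanking ``branch`` at ``site``."""
    return LikelihoodEngine(tree, aln, models).joint_posterior(branch, site)


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    family: str
    params: dict
    tree: object
    loglik: float
    trace: list = field(default_factory=list)
    converged: bool = True
    model: SubstitutionModel = None
    model_map: BranchModelMap = None


_PARAM_BOUNDS = {
    "kappa": (0.05, 50.0),
    "omega": (1e-4, 20.0),
    "theta": (1e-4, 1.0 - 1e-4),
}
_FREE_PARAMS = {"jc": (), "t92": ("kappa", "theta"), "yn98": ("kappa", "omega")}
_INIT = {"kappa": 2.0, "omega": 0.2, "theta": 0.5}


def _total_loglik(tree, aln, mmap):
    return LikelihoodEngine(tree, aln, mmap, compute_outside=False).total_loglik


def _branch_profile(engine, branch_id):
    """Closure t -> total log-likelihood as a function of one branch length,
    everything else held fixed (exact, up to t-independent scaling terms)."""
    node = engine.tree.branch_node(branch_id)
    D = engine.down[node.node_id]
    U = engine.up[node.node_id]
    model = engine.models.model_for_branch(branch_id)

    def f(t):
        P = model.transition_matrix(t)
        lik = np.einsum("ix,xy,iy->i", D, P, U)
        with np.errstate(divide="ignore"):
            return float(np.sum(np.log(np.maximum(lik, 1e-300))))

    return f


def fit_homogeneous(tree, aln, family, tol_lnl=1.0, max_rounds=100,
                    codon_freqs=None, init=None, fit_branch_lengths=True):
    """Rough ML fit of a homogeneous model plus branch lengths.

    Alternates one-dimensional bounded Brent searches over the free
    substitution parameters (on a log scale for rate ratios) with a
    branch-length round; stops when a full round gains < ``tol_lnl`` log
    units.  The log-likelihood trace is non-decreasing.
    """
    if tol_lnl <= 0:
        raise ParameterError("tol_lnl must be > 0")
    if family not in _FREE_PARAMS:
        raise ParameterError(f"unknown family {family!r}")
    if family == "yn98" and aln.alphabet.kind != "codon":
        raise ParameterError("yn98 requires a codon alignment")
    if family == "t92" and aln.alphabet.kind != "nucleotide":
        raise ParameterError("t92 requires a nucleotide alignment")

    work = tree.copy()
    for bid, t in work.branch_lengths().items():
        work.set_branch_length(bid, min(max(t, _BL_FLOOR), _BL_CEIL))

    if family == "yn98" and codon_freqs is None:
        codon_freqs = f3x4_frequencies(aln)
    params = dict(_INIT)
    if init:
        params.update(init)
    params = {k: params[k] for k in _FREE_PARAMS[family]}
    if family == "jc" and aln.alphabet.kind == "codon":
        params["codon_single_step"] = False

    def make_map(p):
        return BranchModelMap(family, p, alphabet=aln.alphabet, codon_freqs=codon_freqs)

    cur = _total_loglik(work, aln, make_map(params))
    if not np.isfinite(cur):
        raise NumericalError(
            "non-finite log-likelihood at the starting point; consider raising "
            "the branch-length floor or checking the alignment for impossible sites")
    trace = [cur]
    converged = False

    for _ in range(max_rounds):
        round_start = cur
        # substitution parameters, one Brent search each
        for name in _FREE_PARAMS[family]:
            lo, hi = _PARAM_BOUNDS[name]
            logscale = name != "theta"

            def neg(u, name=name, logscale=logscale):
                v = float(np.exp(u)) if logscale else float(u)
                trial = dict(params, **{name: v})
                return -_total_loglik(work, aln, make_map(trial))

            bounds = (np.log(lo), np.log(hi)) if logscale else (lo, hi)
            res = minimize_scalar(neg, bounds=bounds, method="bounded",
                                  options={"xatol": 1e-3, "maxiter": 25})
            cand = float(np.exp(res.x)) if logscale else float(res.x)
            if -res.fun > cur:
                params[name] = cand
                cur = -res.fun

        # branch lengths: Jacobi round against one frozen inside/outside pass
        if fit_branch_lengths:
            mmap = make_map(params)
            engine = LikelihoodEngine(work, aln, mmap)
            old_lengths = work.branch_lengths()
            for bid in range(1, work.n_branches + 1):
                prof = _branch_profile(engine, bid)
                t0 = old_lengths[bid]

                def neg_t(u, prof=prof):
                    return -prof(float(np.exp(u)))

                res = minimize_scalar(neg_t, bounds=(np.log(_BL_FLOOR), np.log(_BL_CEIL)),
                                      method="bounded", options={"xatol": 1e-3, "maxiter": 20})
                t_new = float(np.exp(res.x))
                if prof(t_new) > prof(t0):
                    work.set_branch_length(bid, t_new)
            new_ll = _total_loglik(work, aln, make_map(params))
            if new_ll < cur:
                # simultaneous updates overshot: fall back to sequential
                # (exact, monotone) updates for this round
                for bid, t in old_lengths.items():
                    work.set_branch_length(bid, t)
                for bid in range(1, work.n_branches + 1):
                    engine = LikelihoodEngine(work, aln, make_map(params))
                    prof = _branch_profile(engine, bid)
                    t0 = work.branch_lengths()[bid]

                    def neg_t(u, prof=prof):
                        return -prof(float(np.exp(u)))

                    res = minimize_scalar(neg_t,
                                          bounds=(np.log(_BL_FLOOR), np.log(_BL_CEIL)),
                                          method="bounded",
                                          options={"xatol": 1e-3, "maxiter": 20})
                    t_new = float(np.exp(res.x))
                    if prof(t_new) > prof(t0):
                        work.set_branch_length(bid, t_new)
                new_ll = _total_loglik(work, aln, make_map(params))
            cur = max(cur, new_ll)

        trace.append(cur)
        if cur - round_start < tol_lnl:
            converged = True
            break

    mmap = make_map(params)
    model = mmap.model_for_branch(1)
    return FitResult(family=family, params=dict(params), tree=work, loglik=cur,
                     trace=trace, converged=converged, model=model, model_map=mmap)
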