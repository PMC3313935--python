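"""Continuous-time substitution models and substitution-type registers.

Every model is a reversible continuous-time Markov generator ``Q`` over an
alphabet, normalized so that one unit of branch length equals one expected
substitution per site at stationarity (``-sum_i pi_i Q_ii = 1``).  Supported
families:

* ``jc`` — equal-rates model over any alphabet (the 61-state codon variant
  allows multi-nucleotide changes by default; a ``codon_single_step`` switch
  restricts rates to single-nucleotide neighbours);
* ``t92`` — Tamura (1992) nucleotide model with transition/transversion
  ratio ``kappa`` and equilibrium GC content ``theta``;
* ``yn98`` — Yang & Nielsen (1998) codon model with ``kappa``, selection
  parameter ``omega`` (dN/dS) and target codon frequencies.

A :class:`SubstitutionRegister` partitions ordered unequal state pairs into
labeled substitution types (synonymous/non-synonymous for codons,
AT→GC / GC→AT / other for nucleotides); typed counts always sum to the
untyped total.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import expm

from .exceptions import NumericalError, ParameterError
from .phylio import Alphabet, codon_alphabet, nucleotide_alphabet

__all__ = [
    "SubstitutionModel",
    "build_jc",
    "build_t92",
    "build_yn98",
    "transition_probabilities",
    "f3x4_frequencies",
    "SubstitutionRegister",
    "register_dnds",
    "register_gc",
    "register_total",
    "BranchModelMap",
]

_ATOL = 1e-10


class SubstitutionModel:
    """Normalized reversible generator with cached spectral decomposition."""

    def __init__(self, alphabet, Q, pi, params=None, family=None):
        Q = np.asarray(Q, dtype=float)
        pi = np.asarray(pi, dtype=float)
        K = alphabet.size
        if Q.shape != (K, K):
            raise ParameterError(f"generator shape {Q.shape} does not match alphabet size {K}")
        if not np.all(np.isfinite(Q)):
            raise NumericalError("generator has non-finite entries")
        off = Q[~np.eye(K, dtype=bool)]
        if np.any(off < -_ATOL):
            raise ParameterError("off-diagonal generator entries must be >= 0")
        if np.max(np.abs(Q.sum(axis=1))) > 1e-8:
            raise ParameterError("generator rows must sum to 0")
        if abs(pi.sum() - 1.0) > 1e-8 or np.any(pi < 0):
            raise ParameterError("stationary distribution must be a probability vector")
        if np.max(np.abs(pi @ Q)) > 1e-8:
            raise ParameterError("pi is not stationary for Q")
        self.alphabet = alphabet
        self.Q = Q
        self.pi = pi
        self.params = dict(params or {})
        self.family = family
        self._eig = None

    @property
    def size(self):
        return self.alphabet.size

    @property
    def rate(self):
        """Expected substitutions per site per unit time at stationarity."""
        return -float(self.pi @ np.diag(self.Q))

    def _eigendecompose(self):
        """Spectral decomposition through the symmetrizing similarity
        transform B = D^{1/2} Q D^{-1/2} (valid for reversible models)."""
        if self._eig is None:
            if np.any(self.pi <= 0):
                self._eig = "expm"
                return self._eig
            d = np.sqrt(self.pi)
            B = (d[:, None] * self.Q) / d[None, :]
            sym_err = np.max(np.abs(B - B.T))
            if sym_err > 1e-8:
                self._eig = "expm"  # not reversible: fall back to expm
                return self._eig
            w, U = np.linalg.eigh((B + B.T) / 2.0)
            # conditioning guard: eigh of a symmetric matrix is well behaved,
            # but keep the scaling-and-squaring fallback reachable
            left = U.T * d[None, :]
            right = (U.T / d[None, :]).T
            self._eig = (w, right, left)
        return self._eig

    def transition_matrix(self, t):
        """P(t) = exp(Qt); rows sum to 1, entries clipped to [0, 1]."""
        if t < 0:
            raise ParameterError(f"time must be >= 0, got {t}")
        eig = self._eigendecompose()
        if eig == "expm":
            P = expm(self.Q * t)
        else:
            w, right, left = eig
            P = (right * np.exp(w * t)[None, :]) @ left
        if not np.all(np.isfinite(P)):
            raise NumericalError(f"non-finite transition probabilities at t={t}")
        row_err = np.max(np.abs(P.sum(axis=1) - 1.0))
        if row_err > _ATOL * 100:
            raise NumericalError(f"transition matrix rows sum to 1 +/- {row_err:.2e} at t={t}")
        return np.clip(P, 0.0, 1.0)

    def __repr__(self):
        ps = ", ".join(f"{k}={v}" for k, v in self.params.items() if np.isscalar(v))
        return f"SubstitutionModel({self.family}, K={self.size}, {ps})"


def transition_probabilities(model, t):
    """Transition probability matrix ``P(t) = exp(Qt)`` of a model."""
    return model.transition_matrix(t)


def _normalize(Q, pi):
    rate = -float(pi @ np.diag(Q))
    if rate <= 0:
        raise ParameterError("degenerate generator: zero substitution rate")
    return Q / rate


def build_jc(alphabet=None, codon_single_step=False):
    """Equal-rates (Jukes–Cantor type) model over any alphabet.

    With ``codon_single_step=True`` on a codon alphabet, rates are equal
    between single-nucleotide neighbours and zero otherwise; the default
    places equal rates on all ordered pairs.
    """
    if alphabet is None:
        alphabet = nucleotide_alphabet()
    K = alphabet.size
    if K < 2:
        raise ParameterError("alphabet must have at least 2 states")
    if codon_single_step:
        if alphabet.kind != "codon":
            raise ParameterError("codon_single_step requires a codon alphabet")
        Q = np.zeros((K, K))
        for i, x in enumerate(alphabet.states):
            for j, y in enumerate(alphabet.states):
                if i != j and _nt_diff(x, y) == 1:
                    Q[i, j] = 1.0
    else:
        Q = np.ones((K, K))
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    pi = np.full(K, 1.0 / K)
    Q = _normalize(Q, pi)
    return SubstitutionModel(alphabet, Q, pi, params={"codon_single_step": codon_single_step},
                             family="jc")


_T92_ORDER = ("A", "C", "G", "T")
_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


def build_t92(kappa, theta):
    """Tamura (1992) model: equilibrium GC ``theta``, ts/tv ratio ``kappa``."""
    if not kappa > 0:
        raise ParameterError(f"kappa must be > 0, got {kappa}")
    if not 0 < theta < 1:
        raise ParameterError(f"theta must be in (0, 1), got {theta}")
    alphabet = nucleotide_alphabet()
    pi = np.array([(1 - theta) / 2, theta / 2, theta / 2, (1 - theta) / 2])
    K = 4
    Q = np.zeros((K, K))
    for i, x in enumerate(_T92_ORDER):
        for j, y in enumerate(_T92_ORDER):
            if i == j:
                continue
            Q[i, j] = pi[j] * (kappa if (x, y) in _TRANSITIONS else 1.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    Q = _normalize(Q, pi)
    return SubstitutionModel(alphabet, Q, pi, params={"kappa": kappa, "theta": theta},
                             family="t92")


def _nt_diff(x, y):
    return sum(a != b for a, b in zip(x, y))


def build_yn98(kappa, omega, codon_freqs=None, alphabet=None):
    """Yang & Nielsen (1998) codon model.

    Rates between codons differing at exactly one nucleotide position are
    proportional to the target codon frequency, multiplied by ``kappa`` for
    transitions and by ``omega`` for amino-acid-changing substitutions;
    multi-nucleotide changes are excluded.
    """
    if not kappa > 0:
        raise ParameterError(f"kappa must be > 0, got {kappa}")
    if omega < 0:
        raise ParameterError(f"omega must be >= 0, got {omega}")
    if alphabet is None:
        alphabet = codon_alphabet()
    if alphabet.kind != "codon":
        raise ParameterError("yn98 requires a codon alphabet")
    K = alphabet.size
    if codon_freqs is None:
        pi = np.full(K, 1.0 / K)
    else:
        pi = np.asarray(codon_freqs, dtype=float)
        if pi.shape != (K,):
            raise ParameterError(f"codon_freqs must have length {K}")
        if np.any(pi < 0) or abs(pi.sum() - 1.0) > 1e-8:
            raise ParameterError("codon_freqs must be a probability simplex")
    Q = np.zeros((K, K))
    for i, x in enumerate(alphabet.states):
        for j, y in enumerate(alphabet.states):
            if i == j or _nt_diff(x, y) != 1:
                continue
            pos = next(p for p in range(3) if x[p] != y[p])
            rate = pi[j]
            if (x[pos], y[pos]) in _TRANSITIONS:
                rate *= kappa
            if alphabet.amino_acid(x) != alphabet.amino_acid(y):
                rate *= omega
            Q[i, j] = rate
    np.fill_diagonal(Q, -Q.sum(axis=1))
    Q = _normalize(Q, pi)
    return SubstitutionModel(alphabet, Q, pi,
                             params={"kappa": kappa, "omega": omega}, family="yn98")


def f3x4_frequencies(aln):
    """F3X4 codon frequencies: product of positional nucleotide frequencies,
    renormalized over the sense codons of the alignment's alphabet."""
    if aln.alphabet.kind != "codon":
        raise ParameterError("f3x4_frequencies requires a codon alignment")
    counts = np.zeros((3, 4))
    idx = {nt: k for k, nt in enumerate("ACGT")}
    for row in aln.tokens:
        for tok in row:
            for p, c in enumerate(tok.upper()):
                if c in idx:
                    counts[p, idx[c]] += 1
    counts += 0.5  # pseudo-count keeps every codon reachable
    pos = counts / counts.sum(axis=1, keepdims=True)
    freqs = np.array([
        pos[0, idx[s[0]]] * pos[1, idx[s[1]]] * pos[2, idx[s[2]]]
        for s in aln.alphabet.states
    ])
    return freqs / freqs.sum()


# ---------------------------------------------------------------------------
# Registers
# ---------------------------------------------------------------------------

class SubstitutionRegister:
    """Partition of ordered unequal state pairs into substitution types."""

    def __init__(self, alphabet, types, classify):
        self.alphabet = alphabet
        self.types = tuple(types)
        self._classify = classify
        K = alphabet.size
        self.masks = {t: np.zeros((K, K), dtype=bool) for t in self.types}
        for i in range(K):
            for j in range(K):
                if i == j:
                    continue
                label = classify(i, j)
                if label not in self.masks:
                    raise ParameterError(f"classifier returned unknown type {label!r}")
                self.masks[label][i, j] = True

    @property
    def n_types(self):
        return len(self.types)

    def classify(self, x, y):
        """Type label of the ordered pair of state indices (x != y)."""
        if x == y:
            raise ParameterError("classify is defined on unequal state pairs")
        return self._classify(x, y)

    def classify_states(self, sx, sy):
        return self.classify(self.alphabet.index[sx], self.alphabet.index[sy])


def register_dnds(alphabet):
    """Synonymous vs non-synonymous register for a codon alphabet.

    Classification is by amino-acid identity of the two codons, regardless
    of how many nucleotide positions differ.
    """
    if alphabet.kind != "codon":
        raise ParameterError("register_dnds requires a codon alphabet")

    def classify(i, j):
        same = alphabet.amino_acid(alphabet.states[i]) == alphabet.amino_acid(alphabet.states[j])
        return "syn" if same else "nonsyn"

    return SubstitutionRegister(alphabet, ("syn", "nonsyn"), classify)


def register_gc(alphabet=None):
    """AT→GC / GC→AT / other register over nucleotides.

    Changes within the weak (A, T) or strong (G, C) class are ``other``.
    """
    if alphabet is None:
        alphabet = nucleotide_alphabet()
    if alphabet.kind != "nucleotide":
        raise ParameterError("register_gc requires a nucleotide alphabet")
    strong = {"G", "C"}

    def classify(i, j):
        x, y = alphabet.states[i], alphabet.states[j]
        if x not in strong and y in strong:
            return "AT->GC"
        if x in strong and y not in strong:
            return "GC->AT"
        return "other"

    return SubstitutionRegister(alphabet, ("AT->GC", "GC->AT", "other"), classify)


def register_total(alphabet):
    """Single-type register counting every substitution as ``all``."""
    return SubstitutionRegister(alphabet, ("all",), lambda i, j: "all")


# ---------------------------------------------------------------------------
# Branch model maps
# ---------------------------------------------------------------------------

_BUILDERS = {
    "jc": lambda params, alphabet, freqs: build_jc(
        alphabet, codon_single_step=params.get("codon_single_step", False)),
    "t92": lambda params, alphabet, freqs: build_t92(params["kappa"], params["theta"]),
    "yn98": lambda params, alphabet, freqs: build_yn98(
        params["kappa"], params["omega"], codon_freqs=freqs, alphabet=alphabet),
}


class BranchModelMap:
    """A model family with shared parameters plus per-branch overrides.

    The homogeneous case is an empty override map.  Non-homogeneous maps
    carry a root model (by default the shared parameters, optionally with
    root-specific overrides) whose stationary distribution closes the
    likelihood recursion at the root.
    """

    def __init__(self, family, shared, alphabet=None, overrides=None,
                 root_params=None, codon_freqs=None):
        if family not in _BUILDERS:
            raise ParameterError(f"unknown model family {family!r}")
        self.family = family
        self.shared = dict(shared)
        self.overrides = {int(b): dict(p) for b, p in (overrides or {}).items()}
        self.root_params = dict(root_params) if root_params else None
        if alphabet is None:
            alphabet = codon_alphabet() if family == "yn98" else nucleotide_alphabet()
        self.alphabet = alphabet
        self.codon_freqs = None if codon_freqs is None else np.asarray(codon_freqs, float)
        self._cache = {}

    @classmethod
    def homogeneous(cls, model):
        """Wrap a single built model as a homogeneous map."""
        m = cls.__new__(cls)
        m.family = model.family
        m.shared = dict(model.params)
        m.overrides = {}
        m.root_params = None
        m.alphabet = model.alphabet
        m.codon_freqs = model.pi if model.family == "yn98" else None
        m._cache = {"__fixed__": model}
        return m

    @property
    def is_homogeneous(self):
        return not self.overrides

    def _build(self, params):
        key = tuple(sorted(params.items()))
        if "__fixed__" in self._cache and not params_differ(params, self.shared):
            return self._cache["__fixed__"]
        if key not in self._cache:
            self._cache[key] = _BUILDERS[self.family](params, self.alphabet, self.codon_freqs)
        return self._cache[key]

    def model_for_branch(self, branch_id):
        params = dict(self.shared)
        params.update(self.overrides.get(int(branch_id), {}))
        return self._build(params)

    @property
    def root_model(self):
        params = dict(self.shared)
        if self.root_params:
            params.update(self.root_params)
        return self._build(params)

    @property
    def root_distribution(self):
        return self.root_model.pi

    def validate_branch_ids(self, tree):
        m = tree.n_branches
        bad = [b for b in self.overrides if not 1 <= b <= m]
        if bad:
            raise ParameterError(f"override keys {bad} are not valid branch ids (1..{m})")


def params_differ(a, b):
    if set(a) != set(b):
        return True
    return any(a[k] != b[k] for k in a)
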