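"""Trees, alphabets, alignments, genetic code, and their file I/O.

Trees are stored as the rooted display of an unrooted phylogeny.  When a
Newick string has a bifurcating root, the two root-adjacent edges are merged
into a single mapped branch whose length is their sum, so an unrooted binary
tree with ``n >= 3`` leaves always exposes ``m = 2n - 3`` mapped branches and
results under reversible homogeneous models do not depend on where the input
tree was rooted.  Branches are indexed 1..m in preorder (each branch is
anchored at its child node), sites are indexed 1-based in all reports.

Alphabets are either the four nucleotides (order A, C, G, T) or the sense
codons of a genetic code (stop codons excluded; 61 states for the standard
code, ordered alphabetically).  IUPAC ambiguity symbols and gaps are accepted
in alignments and resolved into partial indicator vectors downstream.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import dendropy
from Bio import AlignIO
from Bio.Data import CodonTable, IUPACData

from .exceptions import AlignmentError, NewickError, ParameterError

__all__ = [
    "Alphabet",
    "nucleotide_alphabet",
    "codon_alphabet",
    "Node",
    "Tree",
    "read_newick",
    "write_newick",
    "Alignment",
    "read_alignment",
    "write_alignment",
    "extract_codon_position",
]

NUCLEOTIDES = ("A", "C", "G", "T")
GAP_SYMBOLS = frozenset("-.?")

# IUPAC symbol -> compatible nucleotide set (uppercase; U folded into T)
_AMBIGUITY = {k.upper(): frozenset(v) for k, v in IUPACData.ambiguous_dna_values.items()}
_AMBIGUITY["U"] = frozenset("T")
for _g in GAP_SYMBOLS:
    _AMBIGUITY[_g] = frozenset(NUCLEOTIDES)


class Alphabet:
    """Ordered state space: nucleotides or the sense codons of a genetic code.

    State indices are positions in :attr:`states`; this ordering is the
    contract used by every matrix in the package (generators, transition
    probabilities, count kernels).
    """

    def __init__(self, kind, states, code_id=None, codon_to_aa=None, stop_codons=()):
        self.kind = kind
        self.states = tuple(states)
        self.index = {s: i for i, s in enumerate(self.states)}
        self.size = len(self.states)
        self.code_id = code_id
        self.codon_to_aa = dict(codon_to_aa) if codon_to_aa else None
        self.stop_codons = frozenset(stop_codons)

    def __repr__(self):
        return f"Alphabet(kind={self.kind!r}, size={self.size})"

    def __eq__(self, other):
        return (
            isinstance(other, Alphabet)
            and self.kind == other.kind
            and self.states == other.states
            and self.code_id == other.code_id
        )

    def __hash__(self):
        return hash((self.kind, self.states, self.code_id))

    @property
    def token_length(self):
        return 1 if self.kind == "nucleotide" else 3

    def amino_acid(self, state):
        """Translate a codon state to its one-letter amino acid."""
        if self.codon_to_aa is None:
            raise ParameterError("amino_acid() requires a codon alphabet")
        return self.codon_to_aa[state]

    def indicator(self, token):
        """Indicator vector over states compatible with an observed token.

        Unambiguous tokens give a one-hot vector; IUPAC ambiguities and gaps
        set 1 for each compatible state (the standard missing-data treatment).
        An all-zero vector signals a token with no compatible state (e.g. a
        stop codon in a codon alphabet); callers must reject it.
        """
        token = token.upper()
        vec = np.zeros(self.size)
        if self.kind == "nucleotide":
            try:
                compat = _AMBIGUITY[token]
            except KeyError:
                raise AlignmentError(f"unknown nucleotide symbol {token!r}") from None
            for nt in compat:
                if nt in self.index:
                    vec[self.index[nt]] = 1.0
        else:
            if len(token) != 3:
                raise AlignmentError(f"codon token {token!r} is not a triplet")
            try:
                compat = [_AMBIGUITY[c] for c in token]
            except KeyError as exc:
                raise AlignmentError(f"unknown symbol in codon {token!r}") from exc
            for i, state in enumerate(self.states):
                if all(state[p] in compat[p] for p in range(3)):
                    vec[i] = 1.0
        return vec


def nucleotide_alphabet():
    """The four-nucleotide alphabet in A, C, G, T order."""
    return Alphabet("nucleotide", NUCLEOTIDES)


def codon_alphabet(code_id=1, states=None):
    """Sense-codon alphabet of a genetic code (61 states for the standard code).

    Parameters
    ----------
    code_id : int
        NCBI translation table id.
    states : sequence of str, optional
        Restriction to a subset of sense codons (useful for small test
        alphabets); order is preserved as given.
    """
    table = CodonTable.unambiguous_dna_by_id[code_id]
    codon_to_aa = dict(table.forward_table)
    stops = tuple(table.stop_codons)
    if states is None:
        states = tuple(
            "".join(c)
            for c in itertools.product(NUCLEOTIDES, repeat=3)
            if "".join(c) not in table.stop_codons
        )
    else:
        states = tuple(states)
        for s in states:
            if s in table.stop_codons:
                raise ParameterError(f"{s} is a stop codon in table {code_id}")
            if s not in codon_to_aa:
                raise ParameterError(f"{s!r} is not a codon")
    return Alphabet("codon", states, code_id=code_id,
                    codon_to_aa=codon_to_aa, stop_codons=stops)


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------

class Node:
    """Tree node; every non-root node anchors the mapped branch above it."""

    __slots__ = ("label", "length", "parent", "children", "node_id", "branch_id", "annotations")

    def __init__(self, label=None, length=None):
        self.label = label
        self.length = length          # length of the branch to the parent
        self.parent = None
        self.children = []
        self.node_id = None           # preorder position, root = 0
        self.branch_id = None         # 1..m, None for the root
        self.annotations = {}

    @property
    def is_leaf(self):
        return not self.children

    def add_child(self, child):
        child.parent = self
        self.children.append(child)


class Tree:
    """Rooted display of an unrooted phylogeny with indexed branches.

    ``nodes`` lists nodes in preorder; ``branch_node(b)`` returns the child
    node anchoring mapped branch ``b`` (1-based).
    """

    def __init__(self, root):
        self.root = root
        self._reindex()

    def _reindex(self):
        self.nodes = []
        stack = [self.root]
        while stack:
            nd = stack.pop()
            nd.node_id = len(self.nodes)
            self.nodes.append(nd)
            stack.extend(reversed(nd.children))
        bid = 0
        self._branch_nodes = []
        for nd in self.nodes:
            if nd.parent is not None:
                bid += 1
                nd.branch_id = bid
                self._branch_nodes.append(nd)
            else:
                nd.branch_id = None

    @property
    def leaves(self):
        # a labeled root is a taxon too (the 2-leaf display roots the tree
        # at one of its leaves)
        return [nd for nd in self.nodes
                if nd.is_leaf or (nd.parent is None and nd.label)]

    @property
    def leaf_labels(self):
        return [nd.label for nd in self.leaves]

    @property
    def n_leaves(self):
        return len(self.leaves)

    @property
    def n_branches(self):
        return len(self._branch_nodes)

    def branch_node(self, branch_id):
        if not 1 <= branch_id <= self.n_branches:
            raise ParameterError(f"branch id {branch_id} out of range 1..{self.n_branches}")
        return self._branch_nodes[branch_id - 1]

    def branch_lengths(self):
        """Branch id -> length, 1-based."""
        return {nd.branch_id: nd.length for nd in self._branch_nodes}

    def set_branch_length(self, branch_id, length):
        if not (math.isfinite(length) and length >= 0):
            raise ParameterError(f"branch length must be finite and >= 0, got {length}")
        self.branch_node(branch_id).length = float(length)

    @property
    def total_length(self):
        return sum(nd.length for nd in self._branch_nodes)

    def postorder(self):
        order = []
        stack = [(self.root, False)]
        while stack:
            nd, expanded = stack.pop()
            if expanded or nd.is_leaf:
                order.append(nd)
            else:
                stack.append((nd, True))
                stack.extend((c, False) for c in reversed(nd.children))
        return order

    def copy(self):
        def clone(nd):
            new = Node(nd.label, nd.length)
            new.annotations = dict(nd.annotations)
            for c in nd.children:
                new.add_child(clone(c))
            return new
        return Tree(clone(self.root))

    def __repr__(self):
        return f"Tree(n_leaves={self.n_leaves}, n_branches={self.n_branches})"


def _from_dendropy(dnode):
    node = Node(label=None, length=dnode.edge.length)
    if dnode.taxon is not None:
        node.label = dnode.taxon.label
    elif dnode.label:
        node.label = dnode.label
    for a in dnode.annotations:
        try:
            node.annotations[a.name] = float(a.value)
        except (TypeError, ValueError):
            node.annotations[a.name] = a.value
    for child in dnode.child_nodes():
        node.add_child(_from_dendropy(child))
    return node


def read_newick(text):
    """Parse a Newick string into a :class:`Tree`.

    Branch lengths are mandatory on every edge except above the root.  A
    bifurcating root is collapsed: the root's two subtending edges become one
    mapped branch of summed length.  Branch annotations in the
    ``label[&stat=value]:length`` dialect are parsed into node annotations.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            extract_comment_metadata=True,
        )
    except Exception as exc:  # dendropy raises several error classes
        raise NewickError(f"malformed Newick: {exc}") from exc

    root = _from_dendropy(dtree.seed_node)
    root.length = None

    # validation
    def walk(nd):
        yield nd
        for c in nd.children:
            yield from walk(c)

    labels = [nd.label for nd in walk(root) if nd.is_leaf]
    if len(labels) < 2:
        raise NewickError("tree must have at least 2 leaves")
    if any(lab in (None, "") for lab in labels):
        raise NewickError("every leaf must carry a non-empty label")
    dupes = {lab for lab in labels if labels.count(lab) > 1}
    if dupes:
        raise NewickError(f"duplicate leaf labels: {sorted(dupes)}")
    for nd in walk(root):
        if nd.parent is None and nd is not root:
            continue
        if nd is root:
            continue
        if nd.length is None:
            name = nd.label or "internal node"
            raise NewickError(f"missing branch length on edge above {name}")
        if not (math.isfinite(nd.length) and nd.length >= 0):
            name = nd.label or "internal node"
            raise NewickError(f"invalid branch length {nd.length} above {name}")

    # collapse a bifurcating root: merge the two root-adjacent edges
    if len(root.children) == 2:
        c1, c2 = root.children
        new_root = c1 if not c1.is_leaf else c2
        other = c2 if new_root is c1 else c1
        if new_root.is_leaf and len(labels) > 2:
            raise NewickError("degenerate topology: bifurcating root with two leaf children")
        other.length = c1.length + c2.length
        new_root.parent = None
        new_root.length = None
        new_root.add_child(other)
        root = new_root
    return Tree(root)


def _fmt_length(x):
    return repr(float(x))


def write_newick(tree, branch_annotations=None, annotation_name="stat"):
    """Serialize a tree to Newick (unrooted display, trifurcating root).

    ``branch_annotations`` maps branch ids to numbers, emitted as
    ``label[&name=value]:length`` comments readable back by
    :func:`read_newick`.
    """
    ann = {}
    if branch_annotations:
        for bid, val in branch_annotations.items():
            tree.branch_node(bid)  # validates the id
            if not math.isfinite(val):
                raise ParameterError(f"annotation for branch {bid} is not finite: {val}")
            ann[bid] = float(val)

    def render(nd):
        if nd.is_leaf:
            core = nd.label
        else:
            core = "(" + ",".join(render(c) for c in nd.children) + ")"
            if nd.label:
                core += nd.label
        if nd.parent is not None:
            if nd.branch_id in ann:
                core += f"[&{annotation_name}={ann[nd.branch_id]:g}]"
            core += ":" + _fmt_length(nd.length)
        return core

    return render(tree.root) + ";"


# ---------------------------------------------------------------------------
# Alignments
# ---------------------------------------------------------------------------

def _is_unambiguous_stop(token, alphabet):
    return token.upper() in alphabet.stop_codons


@dataclass
class Alignment:
    """Taxa x sites character matrix over an alphabet's tokens.

    ``tokens[r][i]`` is the token of taxon ``r`` at site ``i`` (0-based in
    memory; all user-facing site indices are 1-based).
    """

    alphabet: Alphabet
    taxa: list
    tokens: list  # list of lists of str
    _indicators: np.ndarray = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        if len(self.taxa) != len(self.tokens):
            raise AlignmentError("one token row required per taxon")
        if len(set(self.taxa)) != len(self.taxa):
            raise AlignmentError("duplicate taxon labels in alignment")
        lengths = {len(row) for row in self.tokens}
        if len(lengths) > 1:
            raise AlignmentError(f"ragged alignment: row lengths {sorted(lengths)}")

    @property
    def n_taxa(self):
        return len(self.taxa)

    @property
    def n_sites(self):
        return len(self.tokens[0]) if self.tokens else 0

    @classmethod
    def from_sequences(cls, alphabet, named_seqs):
        """Build from ``(name, sequence-string)`` pairs, validating frame and
        stop codons for codon alphabets."""
        taxa, rows = [], []
        step = alphabet.token_length
        for name, seq in named_seqs:
            seq = str(seq).upper()
            if alphabet.kind == "codon":
                if len(seq) % 3 != 0:
                    raise AlignmentError(
                        f"sequence length {len(seq)} of {name!r} is not divisible by 3"
                    )
                row = [seq[i:i + 3] for i in range(0, len(seq), 3)]
                for i, tok in enumerate(row):
                    if _is_unambiguous_stop(tok, alphabet):
                        raise AlignmentError(
                            f"in-frame stop codon {tok} in taxon {name!r} at codon site {i + 1}"
                        )
            else:
                row = list(seq)
            taxa.append(name)
            rows.append(row)
        return cls(alphabet, taxa, rows)

    def sequence(self, taxon):
        row = self.tokens[self.taxa.index(taxon)]
        return "".join(row)

    def indicators(self):
        """(n_taxa, n_sites, K) array of per-site state indicator vectors."""
        if self._indicators is None:
            K = self.alphabet.size
            arr = np.zeros((self.n_taxa, self.n_sites, K))
            for r, row in enumerate(self.tokens):
                for i, tok in enumerate(row):
                    vec = self.alphabet.indicator(tok)
                    if not vec.any():
                        raise AlignmentError(
                            f"token {tok!r} (taxon {self.taxa[r]!r}, site {i + 1}) "
                            "matches no state of the alphabet"
                        )
                    arr[r, i] = vec
            self._indicators = arr
        return self._indicators


def read_alignment(path, format, alphabet):
    """Read a FASTA or sequential Phylip alignment and validate it.

    Codon alphabets trigger frame-3 grouping and an in-frame stop-codon
    check; errors name the offending taxon and codon site.
    """
    fmt = {"fasta": "fasta", "phylip": "phylip-relaxed"}.get(format)
    if fmt is None:
        raise ParameterError(f"unsupported alignment format {format!r}")
    try:
        msa = AlignIO.read(path, fmt)
    except ValueError as exc:
        raise AlignmentError(f"cannot read {path} as {format}: {exc}") from exc
    return Alignment.from_sequences(alphabet, [(rec.id, str(rec.seq)) for rec in msa])


def write_alignment(aln, path, format="fasta"):
    """Write an alignment as FASTA or sequential Phylip."""
    if format == "fasta":
        with open(path, "w") as fh:
            for name in aln.taxa:
                fh.write(f">{name}\n{aln.sequence(name)}\n")
    elif format == "phylip":
        with open(path, "w") as fh:
            ncols = aln.n_sites * aln.alphabet.token_length
            fh.write(f" {aln.n_taxa} {ncols}\n")
            for name in aln.taxa:
                fh.write(f"{name[:64]}  {aln.sequence(name)}\n")
    else:
        raise ParameterError(f"unsupported alignment format {format!r}")


def extract_codon_position(aln, position):
    """Extract one codon position (1, 2 or 3) from a coding nucleotide alignment."""
    if aln.alphabet.kind != "nucleotide":
        raise ParameterError("extract_codon_position requires a nucleotide alignment")
    if position not in (1, 2, 3):
        raise ParameterError(f"codon position must be 1, 2 or 3, got {position}")
    if aln.n_sites % 3 != 0:
        raise AlignmentError(f"alignment length {aln.n_sites} is not divisible by 3")
    rows = [row[position - 1::3] for row in aln.tokens]
    return Alignment(aln.alphabet, list(aln.taxa), rows)
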