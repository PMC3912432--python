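"""Distance-based phylogenetics: corrected distances, neighbor joining, bootstrap.

Implements the distance pipeline used for marker-gene clone libraries:
pairwise p-distances with pairwise deletion of gapped/ambiguous columns,
multiple-hit corrections (Jukes-Cantor for nucleotides; Poisson and the
Dayhoff PAM-matrix method for amino acids), Saitou-Nei neighbor joining,
and nonparametric bootstrap supports from column resampling.

The distance corrections and the NJ agglomeration are implemented here
directly -- they are the core of the module and are oracle-tested --
while standard file formats go through established readers (Biopython
for FASTA, dendropy for Newick parsing).

Conventions, all deterministic:

* pairwise deletion drops a column for a pair iff either sequence has a
  gap or an ambiguity character there;
* NJ ties on the Q-criterion are broken by the lexicographically
  smallest index pair;
* negative NJ branch lengths are clamped to zero, with the total
  clamped deficit recorded on the tree and logged;
* bootstrap supports are percentages of replicate trees containing the
  same leaf bipartition, computed with a seeded generator.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO

from . import _dayhoff
from .errors import DomainError, InvalidMatrixError, NoOverlapError, SaturationError

logger = logging.getLogger(__name__)

__all__ = [
    "Alignment",
    "DistanceMatrix",
    "TreeNode",
    "PhyloTree",
    "read_fasta",
    "p_distance",
    "jc_distance",
    "poisson_distance",
    "dayhoff_distance",
    "distance_matrix",
    "nj_tree",
    "bootstrap_support",
]

NT_ALPHABET = frozenset("ACGTU")
AA_ALPHABET = frozenset(_dayhoff.AMINO_ACIDS)

#: distance model name -> (sequence kind, correction function p -> d)
MODELS = {
    "p": None,  # kind-agnostic, identity correction
    "jc": "nt",
    "poisson": "aa",
    "dayhoff": "aa",
}


@dataclass(frozen=True)
class Alignment:
    """A multiple sequence alignment with unique ids and equal-length rows.

    ``kind`` is ``"nt"`` or ``"aa"``; rows may contain the gap character
    '-' and ambiguity codes, which pairwise deletion removes per pair.
    """

    ids: tuple[str, ...]
    rows: tuple[str, ...]
    kind: str

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise DomainError("ids and rows must have equal length")
        if len(set(self.ids)) != len(self.ids):
            raise DomainError("sequence ids must be unique")
        if self.kind not in ("nt", "aa"):
            raise DomainError(f"kind must be 'nt' or 'aa', got {self.kind!r}")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise DomainError(f"rows have unequal lengths: {sorted(lengths)}")
        object.__setattr__(self, "rows", tuple(r.upper() for r in self.rows))

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def n_sites(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    @property
    def alphabet(self) -> frozenset[str]:
        return NT_ALPHABET if self.kind == "nt" else AA_ALPHABET

    def resample_columns(self, rng: np.random.Generator) -> "Alignment":
        """Bootstrap replicate: sample columns with replacement."""
        cols = rng.integers(0, self.n_sites, size=self.n_sites)
        rows = tuple("".join(r[c] for c in cols) for r in self.rows)
        return Alignment(self.ids, rows, self.kind)


def read_fasta(path, kind: str | None = None) -> Alignment:
    """Read an aligned FASTA file (wrapping allowed, '-' gaps).

    ``kind`` is inferred when not given: sequences whose unambiguous
    characters are all in {A,C,G,T,U} are called nucleotide, otherwise
    amino acid.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise DomainError(f"no sequences in {path}")
    ids = tuple(r.id for r in records)
    rows = tuple(str(r.seq).upper() for r in records)
    if kind is None:
        residues = set("".join(rows)) - {"-", "N", "X", "."}
        kind = "nt" if residues <= NT_ALPHABET else "aa"
    return Alignment(ids, rows, kind)


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------

def p_distance(a: str, b: str, alphabet: frozenset[str] = NT_ALPHABET) -> float:
    """Proportion of differing sites among pairwise-comparable columns.

    A column is comparable iff both characters are unambiguous residues
    of ``alphabet``; gaps and ambiguity codes in either sequence drop
    the column for this pair only (pairwise deletion).
    """
    if len(a) != len(b):
        raise DomainError("sequences must have equal aligned length")
    comparable = 0
    diff = 0
    for x, y in zip(a.upper(), b.upper()):
        if x in alphabet and y in alphabet:
            comparable += 1
            if x != y:
                diff += 1
    if comparable == 0:
        raise NoOverlapError("no comparable sites after pairwise deletion")
    return diff / comparable


def jc_distance(p: float) -> float:
    """Jukes-Cantor correction d = -(3/4) ln(1 - 4p/3) for nucleotides."""
    if not 0.0 <= p < 0.75:
        raise SaturationError(f"p must be in [0, 0.75) for Jukes-Cantor, got {p}")
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def poisson_distance(p: float) -> float:
    """Poisson correction d = -ln(1 - p) for amino-acid sequences."""
    if not 0.0 <= p < 1.0:
        raise SaturationError(f"p must be in [0, 1) for Poisson correction, got {p}")
    return -math.log1p(-p)


def dayhoff_distance(p: float, tol: float = 1e-6) -> float:
    """Dayhoff PAM-matrix distance for amino-acid sequences.

    Numerically inverts the expected proportion of observed differences
    as a function of time under the Dayhoff rate model with Dayhoff
    equilibrium frequencies (monotone curve, asymptote
    ``1 - sum pi_i^2``), by bisection to ``tol``.
    """
    model = _dayhoff.default_model()
    if not 0.0 <= p < model.p_max:
        raise SaturationError(
            f"p must be in [0, {model.p_max:.4f}) for the Dayhoff model, got {p}"
        )
    return model.invert(p, tol=tol)


_CORRECTIONS = {
    "p": lambda p: p,
    "jc": jc_distance,
    "poisson": poisson_distance,
    "dayhoff": dayhoff_distance,
}


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise distance matrix with taxon ids and model tag."""

    ids: tuple[str, ...]
    values: np.ndarray
    model: str = "p"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        n = len(self.ids)
        if v.shape != (n, n):
            raise InvalidMatrixError(f"matrix shape {v.shape} does not match {n} ids")
        if not np.all(np.isfinite(v)):
            raise InvalidMatrixError("matrix contains non-finite entries")
        if not np.allclose(v, v.T, atol=1e-12):
            raise InvalidMatrixError("matrix is not symmetric")
        if np.any(np.abs(np.diag(v)) > 1e-12):
            raise InvalidMatrixError("matrix diagonal is not zero")
        if np.any(v < 0):
            raise InvalidMatrixError("matrix has negative entries")

    def __len__(self) -> int:
        return len(self.ids)


def distance_matrix(aln: Alignment, model: str = "jc") -> DistanceMatrix:
    """All pairwise corrected distances of an alignment.

    ``model`` is one of ``p``, ``jc`` (nucleotide), ``poisson`` or
    ``dayhoff`` (amino acid).  Saturated pairs raise
    :class:`SaturationError` naming the pair.
    """
    model = model.lower()
    if model not in _CORRECTIONS:
        raise DomainError(f"unknown distance model {model!r}")
    expected_kind = MODELS[model]
    if expected_kind is not None and aln.kind != expected_kind:
        raise DomainError(
            f"model {model!r} applies to {expected_kind} alignments, got {aln.kind}"
        )
    correct = _CORRECTIONS[model]
    n = len(aln)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            p = p_distance(aln.rows[i], aln.rows[j], aln.alphabet)
            try:
                d[i, j] = d[j, i] = correct(p)
            except SaturationError as exc:
                raise SaturationError(
                    f"pair ({aln.ids[i]}, {aln.ids[j]}): {exc}"
                ) from exc
    return DistanceMatrix(aln.ids, d, model=model)


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------

@dataclass
class TreeNode:
    """A node of an (un)rooted tree; leaves carry names, edges lengths."""

    name: str | None = None
    length: float = 0.0  # length of the edge to the parent
    support: float | None = None  # bootstrap % of the edge to the parent
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        out: list[TreeNode] = []
        for c in self.children:
            out.extend(c.leaves())
        return out


@dataclass
class PhyloTree:
    """An unrooted tree stored with an arbitrary internal root.

    For n >= 3 leaves the root is an internal node of degree 3 (the last
    NJ join), so the topology is the unrooted one; ``supports`` and
    branch lengths live on child edges.
    """

    root: TreeNode
    clamp_deficit: float = 0.0  # total negative branch length clamped to 0
    bootstrap_replicates: int | None = None
    bootstrap_dropped: int = 0

    @property
    def leaf_names(self) -> tuple[str, ...]:
        return tuple(leaf.name for leaf in self.root.leaves())

    # -- analysis ----------------------------------------------------------

    def path_lengths(self) -> DistanceMatrix:
        """Leaf-to-leaf path-length (patristic distance) matrix."""
        names = sorted(self.leaf_names)
        index = {n: i for i, n in enumerate(names)}
        n = len(names)
        d = np.zeros((n, n))

        def walk(node: TreeNode) -> dict[int, float]:
            """leaf index -> distance from *node*; fills d across children."""
            if node.is_leaf:
                return {index[node.name]: 0.0}
            seen: dict[int, float] = {}
            for child in node.children:
                sub = {k: v + child.length for k, v in walk(child).items()}
                for i, di in sub.items():
                    for j, dj in seen.items():
                        d[i, j] = d[j, i] = di + dj
                seen.update(sub)
            return seen

        walk(self.root)
        return DistanceMatrix(tuple(names), d, model="path")

    def bipartitions(self) -> dict[frozenset[str], TreeNode]:
        """Internal-edge bipartitions, keyed by the leaf set not
        containing the lexicographically smallest leaf name."""
        all_leaves = frozenset(self.leaf_names)
        ref = min(all_leaves)
        out: dict[frozenset[str], TreeNode] = {}

        def walk(node: TreeNode) -> frozenset[str]:
            if node.is_leaf:
                return frozenset([node.name])
            below = frozenset().union(*(walk(c) for c in node.children))
            if node is not self.root and len(below) >= 2 and len(all_leaves - below) >= 2:
                key = below if ref not in below else all_leaves - below
                out[key] = node
            return below

        walk(self.root)
        return out

    # -- Newick I/O --------------------------------------------------------

    def to_newick(self, decimals: int = 6, min_support: float | None = None) -> str:
        """Newick string; supports as integer internal-node labels.

        ``min_support`` hides supports below a threshold in the rendered
        string (the common >= 50% display convention); the data model
        always keeps the raw values.
        """

        def fmt(node: TreeNode, top: bool) -> str:
            if node.is_leaf:
                body = node.name
            else:
                inner = ",".join(fmt(c, False) for c in node.children)
                label = ""
                if node.support is not None and (
                    min_support is None or node.support >= min_support
                ):
                    label = str(int(round(node.support)))
                body = f"({inner}){label}"
            if top:
                return body
            return f"{body}:{node.length:.{decimals}f}"

        return fmt(self.root, True) + ";"

    def write(self, path, **kwargs) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick(**kwargs) + "\n")

    @classmethod
    def from_newick(cls, newick: str) -> "PhyloTree":
        """Parse a Newick string (internal labels read as supports)."""
        import dendropy

        dt = dendropy.Tree.get(
            data=newick,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )

        def convert(dnode) -> TreeNode:
            node = TreeNode(
                name=dnode.taxon.label if dnode.taxon is not None else None,
                length=float(dnode.edge.length) if dnode.edge.length is not None else 0.0,
            )
            label = getattr(dnode, "label", None)
            if label is not None and dnode.child_nodes():
                try:
                    node.support = float(label)
                except ValueError:
                    pass
            node.children = [convert(c) for c in dnode.child_nodes()]
            return node

        return cls(root=convert(dt.seed_node))

    @classmethod
    def read(cls, path) -> "PhyloTree":
        with open(path) as fh:
            return cls.from_newick(fh.read())


def nj_tree(dm: DistanceMatrix) -> PhyloTree:
    """Saitou-Nei neighbor joining on a distance matrix.

    Agglomerates on the Q-criterion
    ``Q_ij = (N - 2) d_ij - r_i - r_j`` (``r_i`` the row sums of the
    active matrix), with ties broken by the lexicographically smallest
    index pair; branch lengths from the standard two-point formulas,
    negative lengths clamped to zero with the deficit logged.  Exact on
    additive matrices: the tree's path lengths reproduce the input.
    """
    n = len(dm)
    if n < 3:
        raise DomainError(f"need >= 3 taxa for a tree, got {n}")
    d = dm.values.astype(float).copy()
    nodes: list[TreeNode] = [TreeNode(name=i) for i in dm.ids]
    active = list(range(n))
    deficit = 0.0

    def clamp(x: float) -> float:
        nonlocal deficit
        if x < 0:
            deficit += -x
            return 0.0
        return x

    while len(active) > 3:
        m = len(active)
        r = {i: sum(d[i, k] for k in active if k != i) for i in active}
        best = None
        best_q = math.inf
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * d[i, j] - r[i] - r[j]
                if q < best_q:  # strict <: first (lexicographically smallest) pair wins ties
                    best_q = q
                    best = (i, j)
        i, j = best
        li = 0.5 * d[i, j] + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = d[i, j] - li
        child_i, child_j = nodes[i], nodes[j]
        child_i.length = clamp(li)
        child_j.length = clamp(lj)
        new = TreeNode(children=[child_i, child_j])
        # distances from the new node to every remaining taxon
        new_row = np.zeros(d.shape[0] + 1)
        for k in active:
            if k not in (i, j):
                new_row[k] = 0.5 * (d[i, k] + d[j, k] - d[i, j])
        d = np.pad(d, ((0, 1), (0, 1)))
        d[-1, : len(new_row)] = new_row
        d[: len(new_row), -1] = new_row
        nodes.append(new)
        u = d.shape[0] - 1
        active = [k for k in active if k not in (i, j)] + [u]

    # final three-way join: closed-form star lengths
    a, b, c = active
    la = 0.5 * (d[a, b] + d[a, c] - d[b, c])
    lb = 0.5 * (d[a, b] + d[b, c] - d[a, c])
    lc = 0.5 * (d[a, c] + d[b, c] - d[a, b])
    for idx, ln in ((a, la), (b, lb), (c, lc)):
        nodes[idx].length = clamp(ln)
    root = TreeNode(children=[nodes[a], nodes[b], nodes[c]])

    if deficit > 0:
        logger.info("neighbor joining clamped %.6g of negative branch length", deficit)
    return PhyloTree(root=root, clamp_deficit=deficit)


def bootstrap_support(
    aln: Alignment,
    model: str = "jc",
    n_reps: int = 500,
    seed: int | None = None,
) -> PhyloTree:
    """NJ tree with bootstrap supports from column resampling.

    Builds the tree from the full alignment, then ``n_reps`` replicate
    trees from alignments whose columns are resampled with replacement;
    the support of an internal edge is the percentage of replicate
    trees containing the same leaf bipartition.  Replicates in which a
    pairwise distance saturates (or loses all overlap) are dropped and
    counted in ``tree.bootstrap_dropped``.  Deterministic for a fixed
    seed.
    """
    if n_reps < 1:
        raise DomainError("n_reps must be >= 1")
    tree = nj_tree(distance_matrix(aln, model))
    rng = np.random.default_rng(seed)
    counts: dict[frozenset[str], int] = {key: 0 for key in tree.bipartitions()}
    dropped = 0
    used = 0
    for _ in range(n_reps):
        rep = aln.resample_columns(rng)
        try:
            rep_tree = nj_tree(distance_matrix(rep, model))
        except (SaturationError, NoOverlapError):
            dropped += 1
            continue
        used += 1
        rep_bip = rep_tree.bipartitions()
        for key in counts:
            if key in rep_bip:
                counts[key] += 1
    if dropped:
        logger.warning("bootstrap: dropped %d of %d replicates (saturation)", dropped, n_reps)
    if used == 0:
        raise SaturationError("all bootstrap replicates saturated; no supports computed")
    for key, node in tree.bipartitions().items():
        node.support = 100.0 * counts[key] / used
    tree.bootstrap_replicates = n_reps
    tree.bootstrap_dropped = dropped
    return tree
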