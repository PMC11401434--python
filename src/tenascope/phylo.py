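"""FReD-based phylogenetics: pairwise global alignment, p-distances,
neighbor joining with Felsenstein bootstrap, and nearest-reference paralog
assignment.

Scope note: this module deliberately replaces a maximum-likelihood web
pipeline with distance methods.  The claim it supports is clade-level
classification of fibrinogen-related domains (FReDs), not ML branch lengths;
distance NJ is desk-scale, dependency-light and testable against closed
forms.  Users with an external multiple alignment can feed it straight into
:func:`p_distance_matrix` / :func:`bootstrap_support`.
"""
from __future__ import annotations

import functools
from dataclasses import dataclass
from typing import Mapping, Sequence

import dendropy
import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .records import Architecture, DomainKind

GAP_OPEN = 11    # gap existence cost
GAP_EXTEND = 1   # per-residue gap cost


@dataclass(frozen=True)
class AlignmentResult:
    a_id: str
    b_id: str
    aligned_a: str
    aligned_b: str
    score: float
    percent_identity: float


@dataclass
class DistanceMatrix:
    labels: list[str]
    d: np.ndarray

    def __post_init__(self):
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix is not symmetric")
        if (self.d < 0).any():
            raise ValueError("negative distances")

    def value(self, a: str, b: str) -> float:
        return float(self.d[self.labels.index(a), self.labels.index(b)])


# ------------------------------------------------------------ alignment

@functools.lru_cache(maxsize=8)
def _aligner(matrix_name: str, gap_open: int, gap_extend: int) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(matrix_name)
    # BLAST convention: a gap of length k costs gap_open + gap_extend * k
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


def global_align(a: str, b: str, substitution_matrix: str = "BLOSUM62",
                 gap_open: int = GAP_OPEN, gap_extend: int = GAP_EXTEND,
                 a_id: str = "a", b_id: str = "b") -> AlignmentResult:
    """Optimal global alignment with affine gaps (gap of length k costs
    gap_open + gap_extend*k, end gaps included).  Percent identity is
    identical columns over *all* alignment columns, the BLAST-style
    convention.  The result is symmetric in argument order: the pair is
    canonicalized before alignment so identity(a,b) == identity(b,a)."""
    if not a or not b:
        raise ValueError("cannot align empty sequences")
    swapped = b < a
    x, y = (b, a) if swapped else (a, b)
    aligner = _aligner(substitution_matrix, gap_open, gap_extend)
    aln = aligner.align(x, y)[0]
    ax, ay = str(aln[0]), str(aln[1])
    if swapped:
        ax, ay = ay, ax
    ncols = len(ax)
    ident = sum(1 for p, q in zip(ax, ay) if p == q and p != "-")
    return AlignmentResult(a_id=a_id, b_id=b_id, aligned_a=ax, aligned_b=ay,
                           score=float(aln.score),
                           percent_identity=100.0 * ident / ncols)


# ------------------------------------------------------------ FReD extraction

def extract_fred(arch: Architecture, seq: str) -> str:
    """Subsequence of the carboxy-terminal FReD interval."""
    if not arch.has_terminal_fred:
        raise ValueError(f"{arch.protein_id}: no carboxy-terminal FReD")
    freds = arch.of_kind(DomainKind.FRED)
    dom = max(freds, key=lambda d: d.end)
    return seq[dom.start - 1:dom.end]


# ------------------------------------------------------------ distances

def _as_pairs(aligned_seqs) -> list[tuple[str, str]]:
    if isinstance(aligned_seqs, Mapping):
        return list(aligned_seqs.items())
    return [tuple(p) for p in aligned_seqs]


def p_distance_matrix(aligned_seqs) -> DistanceMatrix:
    """p-distance with pairwise gap deletion: mismatched columns divided by
    columns where neither sequence is gapped.  Accepts a mapping or a list of
    (label, gapped sequence) pairs of equal length; needs >=3 sequences."""
    pairs = _as_pairs(aligned_seqs)
    if len(pairs) < 3:
        raise ValueError("need at least 3 sequences")
    labels = [l for l, _ in pairs]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate labels")
    seqs = [s for _, s in pairs]
    n_cols = len(seqs[0])
    if any(len(s) != n_cols for s in seqs):
        raise ValueError("aligned sequences differ in length")
    n = len(seqs)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            comparable = mismatch = 0
            for p, q in zip(seqs[i], seqs[j]):
                if p == "-" or q == "-":
                    continue
                comparable += 1
                if p != q:
                    mismatch += 1
            if comparable == 0:
                raise ValueError(
                    f"no comparable columns between {labels[i]} and {labels[j]}")
            d[i, j] = d[j, i] = mismatch / comparable
    return DistanceMatrix(labels=labels, d=d)


# ------------------------------------------------------------ trees

class PhyloTree:
    """Unrooted tree with branch lengths and optional support values,
    serialized as Newick (supports as internal-node labels)."""

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree

    @classmethod
    def from_newick(cls, text: str) -> "PhyloTree":
        try:
            tree = dendropy.Tree.get(data=text, schema="newick",
                                     preserve_underscores=True,
                                     suppress_internal_node_taxa=True)
        except Exception as exc:  # dendropy raises several parse error types
            offset = getattr(exc, "column", None) or getattr(exc, "col_num", None)
            raise ValueError(
                f"malformed Newick near character {offset}: {exc}") from exc
        return cls(tree)

    def to_newick(self) -> str:
        s = self._tree.as_string(schema="newick", suppress_rooting=True,
                                 real_value_format_specifier=".6f",
                                 unquoted_underscores=True)
        return s.strip()

    def leaf_labels(self) -> list[str]:
        return sorted(l.taxon.label for l in self._tree.leaf_node_iter())

    def _canonical_split(self, clade: frozenset, leaves: frozenset) -> frozenset:
        other = leaves - clade
        return min(clade, other, key=lambda s: (len(s), tuple(sorted(s))))

    def bipartitions(self) -> set[frozenset]:
        """Canonical internal-edge bipartitions (smaller side of each split)."""
        leaves = frozenset(self.leaf_labels())
        splits: set[frozenset] = set()
        for node in self._tree.preorder_node_iter():
            if node.parent_node is None or node.is_leaf():
                continue
            clade = frozenset(l.taxon.label for l in node.leaf_iter())
            if len(clade) < 2 or len(leaves - clade) < 2:
                continue
            splits.add(self._canonical_split(clade, leaves))
        return splits

    def set_supports(self, support: Mapping[frozenset, float]) -> None:
        leaves = frozenset(self.leaf_labels())
        for node in self._tree.preorder_node_iter():
            if node.parent_node is None or node.is_leaf():
                continue
            clade = frozenset(l.taxon.label for l in node.leaf_iter())
            if len(clade) < 2 or len(leaves - clade) < 2:
                continue
            key = self._canonical_split(clade, leaves)
            if key in support:
                node.label = f"{support[key]:g}"

    def supports(self) -> dict[frozenset, float]:
        leaves = frozenset(self.leaf_labels())
        out: dict[frozenset, float] = {}
        for node in self._tree.preorder_node_iter():
            if node.parent_node is None or node.is_leaf() or node.label is None:
                continue
            clade = frozenset(l.taxon.label for l in node.leaf_iter())
            if len(clade) < 2 or len(leaves - clade) < 2:
                continue
            out[self._canonical_split(clade, leaves)] = float(node.label)
        return out

    def edge_lengths(self) -> dict[frozenset, float]:
        """Branch length per split; pendant edges keyed by the singleton set."""
        leaves = frozenset(self.leaf_labels())
        out: dict[frozenset, float] = {}
        for node in self._tree.preorder_node_iter():
            if node.parent_node is None:
                continue
            if node.is_leaf():
                key = frozenset([node.taxon.label])
            else:
                clade = frozenset(l.taxon.label for l in node.leaf_iter())
                comp = leaves - clade
                if not comp:
                    continue
                key = self._canonical_split(clade, leaves)
            out[key] = out.get(key, 0.0) + (node.edge.length or 0.0)
        return out


def neighbor_joining(matrix: DistanceMatrix) -> PhyloTree:
    """Canonical Saitou-Nei neighbor joining.

    Ties in the Q-criterion break on the lexicographically smallest pair of
    node names (an internal node is named for its smallest descendant leaf),
    so the output is deterministic.  Negative limb lengths are clamped to
    zero with the deficit moved to the sibling edge.
    """
    n = len(matrix.labels)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 labels")
    # active node bookkeeping: name (tie-break key) and newick fragment
    names = {i: matrix.labels[i] for i in range(n)}
    frags = {i: matrix.labels[i] for i in range(n)}
    d: dict[tuple[int, int], float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            d[(i, j)] = float(matrix.d[i, j])
    active = list(range(n))
    next_id = n

    def dist(i, j):
        return d[(i, j) if i < j else (j, i)]

    while len(active) > 3:
        m = len(active)
        r = {i: sum(dist(i, k) for k in active if k != i) for i in active}
        best = None
        for ii in range(m):
            for jj in range(ii + 1, m):
                i, j = active[ii], active[jj]
                q = (m - 2) * dist(i, j) - r[i] - r[j]
                pair_key = tuple(sorted((names[i], names[j])))
                if best is None or (q, pair_key) < (best[0], best[1]):
                    best = (q, pair_key, i, j)
        _, _, i, j = best
        dij = dist(i, j)
        li = dij / 2 + (r[i] - r[j]) / (2 * (m - 2))
        lj = dij - li
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
            li = max(li, 0.0)
        new = next_id
        next_id += 1
        frags[new] = f"({frags[i]}:{li!r},{frags[j]}:{lj!r})"
        names[new] = min(names[i], names[j])
        for k in active:
            if k in (i, j):
                continue
            d[(min(k, new), max(k, new))] = (dist(i, k) + dist(j, k) - dij) / 2
        active = [k for k in active if k not in (i, j)] + [new]

    a, b, c = sorted(active, key=lambda k: names[k])
    dab, dac, dbc = dist(a, b), dist(a, c), dist(b, c)
    la = max((dab + dac - dbc) / 2, 0.0)
    lb = max((dab + dbc - dac) / 2, 0.0)
    lc = max((dac + dbc - dab) / 2, 0.0)
    newick = f"({frags[a]}:{la!r},{frags[b]}:{lb!r},{frags[c]}:{lc!r});"
    return PhyloTree.from_newick(newick)


def bootstrap_support(aligned_seqs, n_reps: int, seed: int) -> PhyloTree:
    """Felsenstein bootstrap: resample alignment columns with replacement,
    rebuild the NJ tree, and report for each internal bipartition of the
    full-data tree the percentage of replicates containing it.  The same
    seed gives bit-identical output."""
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    pairs = _as_pairs(aligned_seqs)
    labels = [l for l, _ in pairs]
    seqs = [s for _, s in pairs]
    n_cols = len(seqs[0])
    tree = neighbor_joining(p_distance_matrix(pairs))
    splits = tree.bipartitions()
    counts = {s: 0 for s in splits}
    rng = np.random.default_rng(seed)
    for _ in range(n_reps):
        cols = rng.integers(0, n_cols, size=n_cols)
        rep_pairs = [(lab, "".join(s[c] for c in cols))
                     for lab, s in zip(labels, seqs)]
        rep_tree = neighbor_joining(p_distance_matrix(rep_pairs))
        rep_splits = rep_tree.bipartitions()
        for s in splits:
            if s in rep_splits:
                counts[s] += 1
    tree.set_supports({s: 100.0 * c / n_reps for s, c in counts.items()})
    return tree


# ------------------------------------------------------------ assignment

def assign_paralog_by_fred(query_fred: str,
                           references: Sequence[tuple[str, str, str]],
                           min_identity: float = 40.0,
                           min_margin: float = 2.0) -> tuple[str, float]:
    """Nearest-reference classification of a FReD sequence.

    ``references`` are (label, name, sequence) triples with at least one
    sequence per label.  The winning label is the one holding the single
    highest percent identity; the margin is the gap to the best
    reference of any other label.  Queries below ``min_identity`` or with a
    margin under ``min_margin`` percentage points are UNCLASSIFIED.
    """
    if not references:
        raise ValueError("empty reference set")
    best_by_label: dict[str, float] = {}
    for label, _name, seq in references:
        ident = global_align(query_fred, seq).percent_identity
        if ident > best_by_label.get(label, -1.0):
            best_by_label[label] = ident
    ranked = sorted(best_by_label.items(), key=lambda kv: (-kv[1], kv[0]))
    best_label, best_ident = ranked[0]
    margin = best_ident - ranked[1][1] if len(ranked) > 1 else best_ident
    if best_ident < min_identity or margin < min_margin:
        return "UNCLASSIFIED", margin
    return best_label, margin
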