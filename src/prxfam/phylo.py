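"""Distance-based family phylogeny.

Complete-deletion p-distances, Saitou-Nei neighbor-joining (exact on
additive matrices), column-bootstrap split supports, exemplar-based
subgroup assignment on the tree, and global pairwise percent similarity.

Trees are :class:`Bio.Phylo.BaseTree.Tree` objects; the "root" of an
unrooted NJ tree is a degree-3 internal node, so every internal node of
the unrooted topology has degree 3.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass
from io import StringIO

import numpy as np
import pandas as pd
from Bio import Phylo
from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Phylo.BaseTree import Clade, Tree

GAP = "-"


@dataclass
class AlignedProteinSet:
    """Pre-aligned amino-acid sequences with unique taxon ids."""

    ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows differ in length")
        if len(self.ids) < 3:
            raise ValueError("need at least 3 taxa")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate taxon ids")
        lengths = {len(r) for r in self.rows}
        if len(lengths) != 1:
            raise ValueError("rows are not equal length (not aligned)")
        self.rows = [r.upper() for r in self.rows]

    @property
    def n_columns(self) -> int:
        return len(self.rows[0])

    def as_array(self) -> np.ndarray:
        return np.array([list(r) for r in self.rows], dtype="U1")

    @classmethod
    def from_fasta(cls, path) -> "AlignedProteinSet":
        from Bio import SeqIO

        ids, rows = [], []
        for rec in SeqIO.parse(str(path), "fasta"):
            ids.append(rec.id)
            rows.append(str(rec.seq))
        return cls(ids=ids, rows=rows)


def p_distance_matrix(a: AlignedProteinSet, deletion: str = "complete") -> pd.DataFrame:
    """Pairwise p-distances under complete deletion.

    Every column containing a gap in ANY row is removed first, so all
    pairs are compared on the same retained-column set; d(i,j) is then
    the fraction of retained columns that mismatch.
    """
    if deletion != "complete":
        raise ValueError(f"unsupported deletion mode {deletion!r}")
    arr = a.as_array()
    keep = ~(arr == GAP).any(axis=0)
    if not keep.any():
        raise ValueError("no columns remain after complete deletion")
    arr = arr[:, keep]
    n = len(a.ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = float(np.mean(arr[i] != arr[j]))
    return pd.DataFrame(d, index=a.ids, columns=a.ids)


def _check_distance_matrix(d: pd.DataFrame) -> None:
    vals = d.to_numpy(dtype=float)
    if vals.shape[0] != vals.shape[1] or list(d.index) != list(d.columns):
        raise ValueError("distance matrix must be square with matching labels")
    if not np.allclose(vals, vals.T):
        raise ValueError("distance matrix is not symmetric")
    if not np.allclose(np.diag(vals), 0.0):
        raise ValueError("distance matrix diagonal is not zero")
    if (vals < -1e-12).any():
        raise ValueError("negative distances")


def nj_tree(d: pd.DataFrame) -> Tree:
    """Neighbor-joining tree from a symmetric distance matrix.

    Saitou-Nei agglomeration on the Q-criterion. Q-ties break on the
    lexicographically smallest (sorted) taxon-id pair, where an internal
    node carries the smallest id among its leaves. Negative limb lengths
    are clamped to 0 with the deficit moved to the sibling limb. For an
    additive matrix the tree's path metric reproduces the input exactly.
    """
    _check_distance_matrix(d)
    n = len(d.index)
    if n < 3:
        raise ValueError("need at least 3 taxa")
    # active nodes: id -> (clade, representative label for tie-breaking)
    clades: dict[int, Clade] = {
        i: Clade(name=str(lbl)) for i, lbl in enumerate(d.index)
    }
    rep: dict[int, str] = {i: str(lbl) for i, lbl in enumerate(d.index)}
    dist: dict[tuple[int, int], float] = {}
    vals = d.to_numpy(dtype=float)
    for i in range(n):
        for j in range(i + 1, n):
            dist[(i, j)] = vals[i, j]

    def get(i: int, j: int) -> float:
        return dist[(i, j) if i < j else (j, i)]

    active = list(range(n))
    next_id = n
    while len(active) > 3:
        m = len(active)
        totals = {i: sum(get(i, j) for j in active if j != i) for i in active}
        best = None
        best_key = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * get(i, j) - totals[i] - totals[j]
                key = (q, tuple(sorted((rep[i], rep[j]))))
                if best_key is None or key < best_key:
                    best_key = key
                    best = (i, j)
        i, j = best  # type: ignore[misc]
        dij = get(i, j)
        li = 0.5 * dij + (totals[i] - totals[j]) / (2 * (m - 2))
        lj = dij - li
        # clamp negatives, transfer deficit to sibling limb
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        ci, cj = clades[i], clades[j]
        ci.branch_length = max(li, 0.0)
        cj.branch_length = max(lj, 0.0)
        new = Clade(clades=[ci, cj])
        clades[next_id] = new
        rep[next_id] = min(rep[i], rep[j])
        for k in active:
            if k in (i, j):
                continue
            dk = 0.5 * (get(i, k) + get(j, k) - dij)
            dist[(min(k, next_id), max(k, next_id))] = max(dk, 0.0)
        active = [k for k in active if k not in (i, j)] + [next_id]
        next_id += 1

    # join the last three nodes at a degree-3 internal node (closed form)
    x, y, z = sorted(active, key=lambda k: rep[k])
    dxy, dxz, dyz = get(x, y), get(x, z), get(y, z)
    lx = 0.5 * (dxy + dxz - dyz)
    ly = 0.5 * (dxy + dyz - dxz)
    lz = 0.5 * (dxz + dyz - dxy)
    for node, length in ((x, lx), (y, ly), (z, lz)):
        clades[node].branch_length = max(length, 0.0)
    root = Clade(clades=[clades[x], clades[y], clades[z]])
    return Tree(root=root, rooted=False)


def tree_splits(tree: Tree) -> set[frozenset[str]]:
    """Non-trivial bipartitions of an unrooted tree.

    Each split is canonicalised as the smaller side (ties by sorted leaf
    tuple) so the set is invariant to which side a clade object holds.
    """
    leaves = frozenset(t.name for t in tree.get_terminals())
    splits: set[frozenset[str]] = set()
    for clade in tree.get_nonterminals():
        if clade is tree.root:
            continue
        side = frozenset(t.name for t in clade.get_terminals())
        comp = leaves - side
        if len(side) < 2 or len(comp) < 2:
            continue  # trivial split
        canon = min(
            (side, comp), key=lambda s: (len(s), tuple(sorted(s)))
        )
        splits.add(canon)
    return splits


def bootstrap_support(
    a: AlignedProteinSet,
    replicates: int = 500,
    seed: int = 0,
    deletion: str = "complete",
) -> Tree:
    """NJ tree with per-split bootstrap supports in [0, 1].

    Alignment columns are resampled with replacement ``replicates``
    times; the support of a split in the full-data tree is the fraction
    of replicate trees containing that split. Replicate r draws from an
    independent seeded stream so results are reproducible and order-free.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    base = nj_tree(p_distance_matrix(a, deletion=deletion))
    counts: dict[frozenset[str], int] = {s: 0 for s in tree_splits(base)}
    arr = a.as_array()
    ncol = arr.shape[1]
    root_ss = np.random.SeedSequence(seed)
    children = root_ss.spawn(replicates)
    for r in range(replicates):
        rng = np.random.default_rng(children[r])
        cols = rng.integers(0, ncol, size=ncol)
        rep = AlignedProteinSet(
            ids=list(a.ids), rows=["".join(row) for row in arr[:, cols]]
        )
        try:
            rep_tree = nj_tree(p_distance_matrix(rep, deletion=deletion))
        except ValueError:
            continue  # e.g. all resampled columns gapped
        rep_splits = tree_splits(rep_tree)
        for s in counts:
            if s in rep_splits:
                counts[s] += 1
    support = {s: c / replicates for s, c in counts.items()}
    leaves = frozenset(t.name for t in base.get_terminals())
    for clade in base.get_nonterminals():
        if clade is base.root:
            continue
        side = frozenset(t.name for t in clade.get_terminals())
        comp = leaves - side
        if len(side) < 2 or len(comp) < 2:
            continue
        canon = min((side, comp), key=lambda s: (len(s), tuple(sorted(s))))
        clade.confidence = support.get(canon, 0.0)
    return base


def split_support(tree: Tree, taxa: set[str]) -> float | None:
    """Bootstrap support of the bipartition isolating ``taxa``.

    Returns None when the tree does not contain that split.
    """
    leaves = frozenset(t.name for t in tree.get_terminals())
    members = frozenset(taxa)
    canon = min(
        (members, leaves - members), key=lambda s: (len(s), tuple(sorted(s)))
    )
    for clade in tree.get_nonterminals():
        if clade is tree.root:
            continue
        side = frozenset(t.name for t in clade.get_terminals())
        c = min((side, leaves - side), key=lambda s: (len(s), tuple(sorted(s))))
        if c == canon:
            return clade.confidence if clade.confidence is not None else None
    return None


@dataclass
class SubgroupAssignment:
    """Taxon -> subgroup label plus per-label monophyly flags."""

    labels: dict[str, str]
    monophyletic: dict[str, bool]


def assign_subgroups(tree: Tree, exemplars: dict[str, str]) -> SubgroupAssignment:
    """Assign each taxon to the subgroup of its nearest exemplar.

    ``exemplars`` maps exemplar taxon id -> subgroup label. Each
    unlabeled taxon takes the label of the exemplar minimising tree path
    length (ties by exemplar id). Also reports, per label, whether the
    label's taxa form a connected subtree (appear as one side of a
    split, or are a single taxon / the whole tree minus one clade).
    """
    terminal_names = {t.name for t in tree.get_terminals()}
    for ex in exemplars:
        if ex not in terminal_names:
            raise KeyError(f"exemplar {ex!r} not in tree")
    labels: dict[str, str] = {}
    for taxon in sorted(terminal_names):
        if taxon in exemplars:
            labels[taxon] = exemplars[taxon]
            continue
        best = min(
            sorted(exemplars),
            key=lambda ex: (tree.distance(taxon, ex), ex),
        )
        labels[taxon] = exemplars[best]
    # monophyly: the label's taxa must be one side of some bipartition
    leaves = frozenset(terminal_names)
    splits = tree_splits(tree)
    mono: dict[str, bool] = {}
    for lab in sorted(set(labels.values())):
        members = frozenset(t for t, l in labels.items() if l == lab)
        if len(members) <= 1 or members == leaves:
            mono[lab] = True
            continue
        comp = leaves - members
        if len(comp) == 1:
            mono[lab] = True  # complement is a single leaf: connected
            continue
        canon = min((members, comp), key=lambda s: (len(s), tuple(sorted(s))))
        mono[lab] = canon in splits
    return SubgroupAssignment(labels=labels, monophyletic=mono)


def pairwise_similarity(
    seq_a: str,
    seq_b: str,
    matrix: str | object = "BLOSUM62",
    open_gap: float = -10.0,
    extend_gap: float = -0.5,
) -> float:
    """Percent similarity from a Needleman-Wunsch global alignment.

    Similarity counts alignment columns whose substitution score is
    positive; gap columns count in the denominator but can never be
    similar. Returns a percentage in [0, 100].
    """
    if not seq_a or not seq_b:
        raise ValueError("empty sequence")
    sub = (
        substitution_matrices.load(matrix) if isinstance(matrix, str) else matrix
    )
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = sub
    aligner.open_gap_score = open_gap
    aligner.extend_gap_score = extend_gap
    aln = aligner.align(seq_a.upper(), seq_b.upper())[0]
    row_a, row_b = str(aln[0]), str(aln[1])
    ncols = len(row_a)
    similar = 0
    for ca, cb in zip(row_a, row_b):
        if ca == GAP or cb == GAP:
            continue
        if float(sub[ca, cb]) > 0:
            similar += 1
    return 100.0 * similar / ncols


def write_newick(tree: Tree, path=None, support_as_int: bool = True) -> str:
    """Serialise to Newick; supports become integer percent labels."""
    out = copy.deepcopy(tree)
    if support_as_int:
        for clade in out.get_nonterminals():
            if clade.confidence is not None and clade.confidence <= 1.0:
                clade.confidence = int(round(clade.confidence * 100))
    buf = StringIO()
    Phylo.write(out, buf, "newick")
    text = buf.getvalue()
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def read_newick(source) -> Tree:
    if isinstance(source, str) and "(" in source:
        return Phylo.read(StringIO(source), "newick")
    return Phylo.read(str(source), "newick")
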