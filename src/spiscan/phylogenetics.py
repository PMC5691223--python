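"""Distance-based phylogenetics: p-distances, neighbor joining, bootstrap.

Trees are built from pre-aligned protein blocks with the Saitou-Nei
neighbor-joining (NJ) agglomeration on uncorrected p-distances
(pairwise gap deletion by default), the simplest closed-form protein
distance.  Bootstrap supports are percentages of column-resampled
replicates whose NJ tree contains each internal bipartition of the
full-data tree.  All stochastic steps are seeded; Q-criterion ties
break to the lowest index pair, and negative NJ branch-length
estimates are clamped to zero, so the whole procedure is deterministic.

Trees are :class:`dendropy.Tree` objects, so they interoperate with
standard newick tooling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import dendropy
import numpy as np

from .io_formats import AlignedBlock


class PhyloError(ValueError):
    pass


@dataclass(frozen=True)
class DistanceMatrix:
    """Labelled symmetric distance matrix with zero diagonal."""

    labels: tuple[str, ...]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        n = len(self.labels)
        if m.shape != (n, n):
            raise PhyloError(f"matrix shape {m.shape} does not match {n} labels")
        if not np.allclose(m, m.T, atol=1e-12):
            raise PhyloError("distance matrix is not symmetric")
        if np.any(np.diag(m) != 0):
            raise PhyloError("distance matrix diagonal must be zero")
        if np.any(m < 0):
            raise PhyloError("distances must be non-negative")
        object.__setattr__(self, "matrix", m)

    @property
    def n(self) -> int:
        return len(self.labels)


def p_distance(block: AlignedBlock, gap_mode: str = "pairwise_deletion") -> DistanceMatrix:
    """Uncorrected protein p-distance: mismatches / compared columns.

    ``pairwise_deletion`` compares, per pair, the columns where neither
    sequence has a gap; ``complete_deletion`` first drops every column
    containing any gap.  A pair with zero comparable columns is an
    error naming the pair.
    """
    if gap_mode not in ("pairwise_deletion", "complete_deletion"):
        raise PhyloError(f"unknown gap mode {gap_mode!r}")
    seqs = [r.sequence for r in block.records]
    labels = block.labels
    if gap_mode == "complete_deletion":
        keep = [c for c in range(block.n_columns) if all(s[c] != "-" for s in seqs)]
        seqs = ["".join(s[c] for c in keep) for s in seqs]
    n = len(seqs)
    arr = np.array([list(s) for s in seqs])
    gap = arr == "-"
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mask = ~(gap[i] | gap[j])
            compared = int(mask.sum())
            if compared == 0:
                raise PhyloError(
                    f"no comparable columns between {labels[i]!r} and {labels[j]!r}"
                )
            mismatches = int(((arr[i] != arr[j]) & mask).sum())
            d[i, j] = d[j, i] = mismatches / compared
    return DistanceMatrix(labels=labels, matrix=d)


def nj_tree(dm: DistanceMatrix) -> dendropy.Tree:
    """Saitou-Nei neighbor joining; deterministic and unrooted.

    Q ties break to the lowest (i, j) index pair; negative branch
    lengths are clamped to zero with the total clamped deficit recorded
    on ``tree.nj_clamped_deficit``.
    """
    if dm.n < 3:
        raise PhyloError("neighbor joining needs at least 3 taxa")
    tns = dendropy.TaxonNamespace(list(dm.labels))
    tree = dendropy.Tree(taxon_namespace=tns)
    nodes: list[dendropy.Node] = []
    for label in dm.labels:
        node = dendropy.Node()
        node.taxon = tns.get_taxon(label)
        nodes.append(node)

    d = dm.matrix.copy()
    active = list(range(dm.n))
    clamped = 0.0

    def clamp(x: float) -> float:
        nonlocal clamped
        if x < 0:
            clamped += -x
            return 0.0
        return x

    while len(active) > 3:
        n = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        best = None
        for a in range(n):
            for b in range(a + 1, n):
                q = (n - 2) * sub[a, b] - r[a] - r[b]
                if best is None or q < best[0] - 1e-15:
                    best = (q, a, b)
        _, a, b = best
        i, j = active[a], active[b]
        dij = d[i, j]
        vi = clamp(0.5 * dij + (r[a] - r[b]) / (2 * (n - 2)))
        vj = clamp(dij - (0.5 * dij + (r[a] - r[b]) / (2 * (n - 2))))
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes[i].edge.length = vi
        nodes[j].edge.length = vj
        # distances from the new node to every remaining node
        new_idx = d.shape[0]
        d = np.pad(d, ((0, 1), (0, 1)))
        for k in active:
            if k in (i, j):
                continue
            d[new_idx, k] = d[k, new_idx] = 0.5 * (d[i, k] + d[j, k] - dij)
        nodes.append(parent)
        active = [k for k in active if k not in (i, j)] + [new_idx]

    # final three-point join at the unrooted central node
    i, j, k = active
    center = dendropy.Node()
    li = clamp(0.5 * (d[i, j] + d[i, k] - d[j, k]))
    lj = clamp(0.5 * (d[i, j] + d[j, k] - d[i, k]))
    lk = clamp(0.5 * (d[i, k] + d[j, k] - d[i, j]))
    for idx, length in ((i, li), (j, lj), (k, lk)):
        center.add_child(nodes[idx])
        nodes[idx].edge.length = length
    tree.seed_node = center
    tree.is_rooted = False
    tree.nj_clamped_deficit = clamped
    return tree


def _leaf_sets(tree: dendropy.Tree) -> dict[dendropy.Node, frozenset[str]]:
    """Leaf-label descendant set of every node."""
    sets: dict[dendropy.Node, frozenset[str]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            sets[node] = frozenset([node.taxon.label])
        else:
            acc: set[str] = set()
            for child in node.child_nodes():
                acc |= sets[child]
            sets[node] = frozenset(acc)
    return sets


def bipartitions(tree: dendropy.Tree) -> dict[dendropy.Node, frozenset[str]]:
    """Non-trivial bipartitions, keyed by the internal node below each edge.

    Each bipartition is normalized to the side not containing the
    lexicographically first taxon, so sets compare across trees.
    """
    sets = _leaf_sets(tree)
    all_taxa = sets[tree.seed_node]
    anchor = min(all_taxa)
    result: dict[dendropy.Node, frozenset[str]] = {}
    for node, side in sets.items():
        if node is tree.seed_node or node.is_leaf():
            continue
        if len(side) < 2 or len(side) > len(all_taxa) - 2:
            continue
        norm = side if anchor not in side else all_taxa - side
        result[node] = norm
    return result


def tree_path_lengths(tree: dendropy.Tree) -> DistanceMatrix:
    """Leaf-to-leaf path-length matrix of a tree."""
    pdm = tree.phylogenetic_distance_matrix()
    labels = tuple(sorted(t.label for t in tree.taxon_namespace if t))
    n = len(labels)
    m = np.zeros((n, n))
    taxa = {t.label: t for t in tree.taxon_namespace}
    for a in range(n):
        for b in range(a + 1, n):
            m[a, b] = m[b, a] = pdm.distance(taxa[labels[a]], taxa[labels[b]])
    return DistanceMatrix(labels=labels, matrix=m)


def bootstrap_support(
    block: AlignedBlock,
    n_reps: int,
    seed: int,
    gap_mode: str = "pairwise_deletion",
) -> dendropy.Tree:
    """NJ tree of the full alignment with bootstrap supports.

    Columns are resampled with replacement ``n_reps`` times; the support
    of each internal bipartition of the full-data tree is the integer
    percentage of valid replicates containing it.  Replicates whose
    resampled columns leave some pair with nothing to compare are
    discarded with a warning; the count is on
    ``tree.bootstrap_discarded``.
    """
    if n_reps < 1:
        raise PhyloError("n_reps must be >= 1")
    base = nj_tree(p_distance(block, gap_mode))
    base_biparts = bipartitions(base)
    counts = {node: 0 for node in base_biparts}
    rng = np.random.default_rng(seed)
    n_cols = block.n_columns
    valid = 0
    discarded = 0
    for _ in range(n_reps):
        cols = rng.integers(0, n_cols, size=n_cols)
        resampled = AlignedBlock(
            records=tuple(
                type(r)(id=r.id, sequence="".join(r.sequence[c] for c in cols))
                for r in block.records
            )
        )
        try:
            rep_tree = nj_tree(p_distance(resampled, gap_mode))
        except PhyloError:
            discarded += 1
            continue
        valid += 1
        rep_sets = set(bipartitions(rep_tree).values())
        for node, bset in base_biparts.items():
            if bset in rep_sets:
                counts[node] += 1
    if discarded:
        warnings.warn(f"{discarded} bootstrap replicate(s) discarded")
    for node, count in counts.items():
        support = int(round(100.0 * count / valid)) if valid else 0
        node.label = str(support)
    base.bootstrap_discarded = discarded
    base.bootstrap_valid = valid
    return base


def is_monophyletic(tree: dendropy.Tree, taxa: set[str]) -> bool:
    """True iff some edge bipartition separates exactly ``taxa``."""
    sets = _leaf_sets(tree)
    all_taxa = sets[tree.seed_node]
    taxa = frozenset(taxa)
    if not taxa <= all_taxa:
        raise PhyloError(f"unknown taxa: {sorted(taxa - all_taxa)}")
    if taxa == all_taxa or len(taxa) == 1:
        return True
    for node, side in sets.items():
        if node is tree.seed_node:
            continue
        if taxa == side or taxa == all_taxa - side:
            return True
    return False
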