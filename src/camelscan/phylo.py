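"""Fst-based population phylogenies with window-resampling bootstrap.

Population distances are average windowed Weir–Cockerham Fst values (ratio of
sums within each window, mean over windows, negative averages floored at zero
for distance use).  Trees are built with the Saitou–Nei neighbor-joining
algorithm, which is exact on additive distance matrices; ties in the
Q-criterion are broken deterministically toward the lexicographically
smallest label pair.  Bipartition support comes from rebuilding the tree on
replicates of randomly sampled, mutually distant windows, and a strict
majority-rule consensus is also available.  Newick serialization goes
through dendropy.
"""

from __future__ import annotations

import warnings
from bisect import bisect_left, insort
from typing import Sequence

import dendropy
import numpy as np

from .popmap import PopulationMap
from .popstats import (
    DistanceMatrix,
    Window,
    pop_site_stats,
    sites_in_window,
    tile_windows,
    wc_pair_components,
)
from .variants import GenotypeMatrix


class PhyloTree:
    """A leaf-labelled tree with branch lengths and optional % supports.

    Thin wrapper around a :class:`dendropy.Tree`; bipartitions are exposed as
    canonical frozensets of leaf labels (the side not containing the
    lexicographically smallest leaf), which makes support transfer, consensus
    and Robinson–Foulds comparisons straightforward.
    """

    def __init__(self, tree: dendropy.Tree) -> None:
        self.tree = tree

    # -------------------------------------------------------- construction
    @classmethod
    def from_newick(cls, newick: str) -> "PhyloTree":
        tree = dendropy.Tree.get(
            data=newick, schema="newick", suppress_internal_node_taxa=True
        )
        return cls(tree)

    def newick(self) -> str:
        s = self.tree.as_string(
            schema="newick", suppress_rooting=True, real_value_format_specifier=".10g"
        )
        return s.strip()

    # ------------------------------------------------------------ queries
    @property
    def leaf_labels(self) -> list[str]:
        return sorted(lf.taxon.label for lf in self.tree.leaf_node_iter())

    def _canonical(self, side: frozenset) -> frozenset:
        labels = set(self.leaf_labels)
        ref = min(labels)
        return frozenset(labels - side) if ref in side else side

    def bipartitions(self) -> dict[frozenset, float | None]:
        """Non-trivial splits -> support (None when unset)."""
        labels = set(self.leaf_labels)
        out: dict[frozenset, float | None] = {}
        for node in self.tree.preorder_node_iter():
            if node.parent_node is None or node.is_leaf():
                continue
            side = frozenset(lf.taxon.label for lf in node.leaf_iter())
            if 2 <= len(side) <= len(labels) - 2:
                sup = None
                if node.label is not None:
                    try:
                        sup = float(node.label)
                    except ValueError:
                        sup = None
                out[self._canonical(side)] = sup
        return out

    def set_supports(self, supports: dict[frozenset, float]) -> None:
        labels = set(self.leaf_labels)
        for node in self.tree.preorder_node_iter():
            if node.parent_node is None or node.is_leaf():
                continue
            side = frozenset(lf.taxon.label for lf in node.leaf_iter())
            if 2 <= len(side) <= len(labels) - 2:
                key = self._canonical(side)
                if key in supports:
                    node.label = f"{supports[key]:g}"

    def contains_split(self, side) -> bool:
        """True if the tree contains the bipartition with ``side`` on one side."""
        return self._canonical(frozenset(side)) in self.bipartitions()

    def support_for(self, side) -> float | None:
        """Support of the bipartition given by either of its sides."""
        key = self._canonical(frozenset(side))
        bps = self.bipartitions()
        if key not in bps:
            raise KeyError(f"tree does not contain the split {sorted(side)}")
        return bps[key]

    def robinson_foulds(self, other: "PhyloTree") -> int:
        """Number of splits present in exactly one of the two trees."""
        if self.leaf_labels != other.leaf_labels:
            raise ValueError("trees are on different leaf sets")
        return len(set(self.bipartitions()) ^ set(other.bipartitions()))

    def __repr__(self) -> str:
        return f"PhyloTree({len(self.leaf_labels)} leaves)"


def write_newick(tree: PhyloTree, path) -> None:
    with open(path, "w") as fh:
        fh.write(tree.newick() + "\n")


def read_newick(path) -> PhyloTree:
    with open(path) as fh:
        return PhyloTree.from_newick(fh.read())


# ------------------------------------------------------------- Fst distances

def pairwise_window_fst(
    matrix: GenotypeMatrix,
    popmap: PopulationMap,
    windows: Sequence[Window],
    populations: Sequence[str] | None = None,
) -> tuple[list[str], list[tuple[int, int]], np.ndarray]:
    """Per-window W&C Fst for every population pair.

    Returns (populations, pair index list, windows x pairs array with nan for
    windows where a pair's denominator is zero).  Populations with fewer than
    two samples raise an error.
    """
    pops = list(populations) if populations is not None else popmap.populations
    if len(pops) < 2:
        raise ValueError("need at least two populations")
    stats = {}
    for p in pops:
        idx = popmap.sample_indices(p, matrix.samples)
        if idx.size < 2:
            raise ValueError(f"population {p!r} has fewer than 2 samples")
        stats[p] = pop_site_stats(matrix, idx)
    win_masks = [sites_in_window(matrix, w) for w in windows]
    pairs = [(i, j) for i in range(len(pops)) for j in range(i + 1, len(pops))]
    fst = np.full((len(windows), len(pairs)), np.nan)
    for k, (i, j) in enumerate(pairs):
        comp_a, comp_abc, usable = wc_pair_components(stats[pops[i]], stats[pops[j]])
        for wi, m in enumerate(win_masks):
            mm = m & usable
            den = comp_abc[mm].sum()
            if den != 0:
                fst[wi, k] = comp_a[mm].sum() / den
    return pops, pairs, fst


def _matrix_from_window_fst(
    pops: list[str], pairs: list[tuple[int, int]], fst: np.ndarray, which: np.ndarray | None = None
) -> DistanceMatrix:
    values = np.zeros((len(pops), len(pops)))
    sub = fst if which is None else fst[which]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-nan columns
        means = np.nanmean(sub, axis=0)
    for k, (i, j) in enumerate(pairs):
        d = max(float(means[k]), 0.0) if np.isfinite(means[k]) else 0.0
        values[i, j] = values[j, i] = d
    return DistanceMatrix(labels=pops, values=values)


def fst_distance_matrix(
    matrix: GenotypeMatrix,
    popmap: PopulationMap,
    windows: Sequence[Window] | None = None,
    window_size: int = 10_000,
    populations: Sequence[str] | None = None,
) -> DistanceMatrix:
    """Average windowed Fst between every population pair, floored at zero."""
    if windows is None:
        from .popstats import windows_from_matrix

        windows = windows_from_matrix(matrix, window_size)
    pops, pairs, fst = pairwise_window_fst(matrix, popmap, windows, populations)
    return _matrix_from_window_fst(pops, pairs, fst)


# --------------------------------------------------------------------- NJ

def neighbor_joining(dist: DistanceMatrix) -> PhyloTree:
    """Saitou–Nei neighbor joining; exact on additive matrices.

    Tie-break: among pairs minimizing the Q-criterion, the pair whose
    (lexicographically smallest member labels) sort first is joined, making
    the output deterministic.  Negative branch lengths are clamped to zero
    with a warning.  Returns an unrooted tree (trifurcating root).
    """
    labels = list(dist.labels)
    if len(labels) < 3:
        raise ValueError("neighbor joining needs at least 3 labels")
    d = dist.values.astype(float).copy()
    clamped = False

    def _edge(length: float) -> float:
        nonlocal clamped
        if length < 0:
            clamped = True
            return 0.0
        return length

    # each active node: (newick fragment, min leaf label for tie-breaking)
    nodes = [(lbl, lbl) for lbl in labels]
    active = list(range(len(labels)))

    while len(active) > 3:
        r = len(active)
        sub = d[np.ix_(active, active)]
        row_sums = sub.sum(axis=1)
        q = (r - 2) * sub - row_sums[:, None] - row_sums[None, :]
        np.fill_diagonal(q, np.inf)
        qmin = q.min()
        ties = np.argwhere(np.isclose(q, qmin, rtol=0, atol=1e-12))
        best = min(
            (tuple(sorted((nodes[active[i]][1], nodes[active[j]][1]))), i, j)
            for i, j in ties
            if i < j
        )
        _, ai, aj = best
        i, j = active[ai], active[aj]
        dij = d[i, j]
        li = dij / 2.0 + (row_sums[ai] - row_sums[aj]) / (2.0 * (r - 2))
        lj = dij - li
        li, lj = _edge(li), _edge(lj)
        newick = f"({nodes[i][0]}:{li:.12g},{nodes[j][0]}:{lj:.12g})"
        minlab = min(nodes[i][1], nodes[j][1])
        # distances from the new node u to every other active node
        du = 0.5 * (d[i] + d[j] - dij)
        u = d.shape[0]
        d = np.pad(d, ((0, 1), (0, 1)))
        d[u, : u] = du
        d[: u, u] = du
        d[u, u] = 0.0
        nodes.append((newick, minlab))
        active = [k for k in active if k not in (i, j)] + [u]

    a, b, c = active
    la = _edge((d[a, b] + d[a, c] - d[b, c]) / 2.0)
    lb = _edge((d[a, b] + d[b, c] - d[a, c]) / 2.0)
    lc = _edge((d[a, c] + d[b, c] - d[a, b]) / 2.0)
    newick = (
        f"({nodes[a][0]}:{la:.12g},{nodes[b][0]}:{lb:.12g},{nodes[c][0]}:{lc:.12g});"
    )
    if clamped:
        warnings.warn("negative NJ branch length(s) clamped to 0")
    return PhyloTree.from_newick(newick)


def _nj_or_pair(dist: DistanceMatrix) -> PhyloTree:
    """NJ for >=3 labels; a single edge for exactly two."""
    if len(dist.labels) == 2:
        a, b = dist.labels
        half = dist.values[0, 1] / 2.0
        return PhyloTree.from_newick(f"({a}:{half:.12g},{b}:{half:.12g});")
    return neighbor_joining(dist)


# ---------------------------------------------------------------- bootstrap

def _max_feasible(starts: list[int], period: int) -> int:
    count, prev = 0, None
    for s in starts:
        if prev is None or s - prev >= period:
            count += 1
            prev = s
    return count


def _sample_spaced(
    rng: np.random.Generator,
    windows: Sequence[Window],
    n_windows: int,
    min_spacing: int,
) -> np.ndarray:
    """Greedy spaced sampling: shuffle candidates, accept while every pair on
    a chromosome keeps start-to-start distance >= window size + min_spacing."""
    order = rng.permutation(len(windows))
    accepted: list[int] = []
    by_chrom: dict[str, list[int]] = {}
    for idx in order:
        w = windows[idx]
        period = w.size + min_spacing
        starts = by_chrom.setdefault(w.chrom, [])
        k = bisect_left(starts, w.start)
        if k > 0 and w.start - starts[k - 1] < period:
            continue
        if k < len(starts) and starts[k] - w.start < period:
            continue
        insort(starts, w.start)
        accepted.append(int(idx))
        if len(accepted) >= n_windows:
            break
    return np.asarray(accepted, dtype=np.intp)


def bootstrap_support(
    matrix: GenotypeMatrix,
    popmap: PopulationMap,
    n_windows: int = 5000,
    window: int = 10_000,
    min_spacing: int = 100_000,
    replicates: int = 100,
    seed: int = 0,
    chromosome_lengths: dict[str, int] | None = None,
    populations: Sequence[str] | None = None,
) -> tuple[PhyloTree, list[PhyloTree]]:
    """NJ tree from all windows, with bipartition support from window resampling.

    Each replicate samples ``n_windows`` windows of ``window`` bp whose
    intervals are at least ``min_spacing`` apart (without replacement),
    rebuilds the Fst distance matrix and the NJ tree; support of each
    bipartition of the full-data tree is the percentage of replicate trees
    containing it.
    """
    if chromosome_lengths is None:
        chromosome_lengths = {
            c: int(matrix.pos[matrix.chrom == c].max())
            for c in dict.fromkeys(matrix.chrom.tolist())
        }
    candidates = tile_windows(chromosome_lengths, window)
    period = window + min_spacing
    feasible = 0
    for c in chromosome_lengths:
        starts = sorted(w.start for w in candidates if w.chrom == c)
        feasible += _max_feasible(starts, period)
    if n_windows > feasible:
        raise ValueError(
            f"cannot place {n_windows} windows {min_spacing} bp apart; "
            f"maximum feasible is {feasible}"
        )
    pops, pairs, fst = pairwise_window_fst(matrix, popmap, candidates, populations)
    full_tree = _nj_or_pair(_matrix_from_window_fst(pops, pairs, fst))
    rng = np.random.default_rng(seed)
    counts: dict[frozenset, int] = {bp: 0 for bp in full_tree.bipartitions()}
    replicate_trees = []
    for _ in range(replicates):
        chosen = _sample_spaced(rng, candidates, n_windows, min_spacing)
        rep_tree = _nj_or_pair(_matrix_from_window_fst(pops, pairs, fst, chosen))
        replicate_trees.append(rep_tree)
        rep_bps = set(rep_tree.bipartitions())
        for bp in counts:
            if bp in rep_bps:
                counts[bp] += 1
    supports = {bp: 100.0 * c / replicates for bp, c in counts.items()}
    full_tree.set_supports(supports)
    return full_tree, replicate_trees


# ---------------------------------------------------------------- consensus

def majority_consensus(trees: Sequence[PhyloTree]) -> PhyloTree:
    """Strict majority-rule consensus.

    Splits present in more than half of the trees are retained (such splits
    are mutually compatible, so they assemble greedily into one tree without
    conflict); edge supports are occurrence percentages.  All trees must
    share a leaf set.
    """
    if not trees:
        raise ValueError("need at least one tree")
    leaf_sets = {tuple(t.leaf_labels) for t in trees}
    if len(leaf_sets) != 1:
        raise ValueError("trees are on different leaf sets")
    labels = trees[0].leaf_labels
    ref = min(labels)
    counts: dict[frozenset, int] = {}
    for t in trees:
        for bp in t.bipartitions():
            counts[bp] = counts.get(bp, 0) + 1
    n = len(trees)
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], sorted(kv[0])))
    accepted: list[tuple[frozenset, float]] = []

    def _compatible(c: frozenset) -> bool:
        return all(c <= o or o <= c or not (c & o) for o, _ in accepted)

    for clade, cnt in ranked:
        if 2 * cnt > n and _compatible(clade):
            accepted.append((clade, 100.0 * cnt / n))

    # build the rooted-at-ref tree from the laminar family
    tns = dendropy.TaxonNamespace(labels)
    tree = dendropy.Tree(taxon_namespace=tns)
    ordered = sorted(accepted, key=lambda kv: -len(kv[0]))

    def build(node, members: set, clades):
        placed: set = set()
        for i, (clade, sup) in enumerate(clades):
            if clade <= members and not (clade & placed):
                child = node.new_child()
                child.label = f"{sup:g}"
                inner = [kv for kv in clades[i + 1 :] if kv[0] < clade]
                build(child, set(clade), inner)
                placed |= clade
        for lbl in sorted(members - placed):
            leaf = node.new_child()
            leaf.taxon = tns.get_taxon(lbl)

    build(tree.seed_node, set(labels) - {ref}, ordered)
    leaf = tree.seed_node.new_child()
    leaf.taxon = tns.get_taxon(ref)
    return PhyloTree(tree)
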