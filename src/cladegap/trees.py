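"""Neighbor-joining trees, column bootstrap, rooting and parsimony scoring.

NJ follows Saitou & Nei with the Studier-Keppler Q-criterion.  Two
implementation choices make results reproducible across platforms:

* ties in the Q minimisation are broken lexicographically, by the smallest
  tip label contained in each candidate cluster;
* negative branch-length estimates are clamped to zero and the deficit is
  transferred to the sibling branch, so total path lengths are preserved.

Internal edges whose estimated length is exactly zero (after clamping) are
collapsed into polytomies — a zero distance matrix therefore yields a star
tree rather than an arbitrary caterpillar.

Bootstrap support is computed by resampling aligned columns with
replacement: a resample is a multiplicity-weight vector over columns, which
lets a whole batch of replicate distance matrices be computed with three
matrix products (see :class:`cladegap.distances.PairColumnCounts`).
Supports are attached to internal nodes as integer percents (also written
as Newick internal-node labels).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence, Set, Tuple

import dendropy
import numpy as np

from .containers import CODE_GAP, Alignment
from .distances import DistanceMatrix, PairColumnCounts

logger = logging.getLogger(__name__)

_ZERO_EDGE = 1e-12


# ---------------------------------------------------------------------------
# lightweight tree used internally by NJ (converted to dendropy on demand)
# ---------------------------------------------------------------------------
class _Node:
    __slots__ = ("label", "children", "mask", "key")

    def __init__(self, label: Optional[str], mask: int, key: int):
        self.label = label
        self.children: List[Tuple["_Node", float]] = []
        self.mask = mask  # bitmask of tip ranks below this node
        self.key = key  # smallest tip rank below (deterministic sort key)


def _nj_build(D: np.ndarray, labels: Sequence[str]) -> _Node:
    """Agglomerate by the Studier-Keppler criterion; returns the root.

    The returned root is a trifurcation (or the full star for n <= 3);
    zero-length internal edges are collapsed afterwards by ``_collapse``.
    """
    n = len(labels)
    order = {lab: r for r, lab in enumerate(sorted(labels))}
    nodes: List[_Node] = [_Node(lab, 1 << order[lab], order[lab]) for lab in labels]
    if n == 1:
        return nodes[0]
    D = np.array(D, dtype=float)
    if np.isnan(D).any():
        raise ValueError("distance matrix contains NA entries")
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        sub = D  # D is kept compacted to the active set
        R = sub.sum(axis=1)
        Q = (m - 2) * sub - R[:, None] - R[None, :]
        # scan the upper triangle only (floating rounding can make Q[i,j]
        # and Q[j,i] differ in the last bit)
        Q[np.tril_indices(m)] = np.inf
        qmin = Q.min()
        ti, tj = np.nonzero(Q == qmin)
        # deterministic tie-break: smallest (min tip rank, max tip rank)
        best = None
        for a, b in zip(ti.tolist(), tj.tolist()):
            ka, kb = nodes[active[a]].key, nodes[active[b]].key
            cand = (min(ka, kb), max(ka, kb), a, b)
            if best is None or cand[:2] < best[:2]:
                best = cand
        i, j = best[2], best[3]
        dij = sub[i, j]
        vi = 0.5 * dij + (R[i] - R[j]) / (2.0 * (m - 2))
        vj = dij - vi
        if vi < 0:
            vj += vi
            vi = 0.0
        if vj < 0:
            vi += vj
            vj = 0.0
        ni, nj_ = nodes[active[i]], nodes[active[j]]
        new = _Node(None, ni.mask | nj_.mask, min(ni.key, nj_.key))
        new.children.append((ni, max(vi, 0.0)))
        new.children.append((nj_, max(vj, 0.0)))
        nodes.append(new)
        # distances from the new node to the remaining ones
        rest = [k for k in range(m) if k not in (i, j)]
        dnew = 0.5 * (sub[i, rest] + sub[j, rest] - dij)
        dnew = np.maximum(dnew, 0.0)
        keep = rest
        newD = np.empty((m - 1, m - 1))
        newD[:-1, :-1] = sub[np.ix_(keep, keep)]
        newD[-1, :-1] = dnew
        newD[:-1, -1] = dnew
        newD[-1, -1] = 0.0
        D = newD
        active = [active[k] for k in keep] + [len(nodes) - 1]

    root = _Node(None, 0, 0)
    if len(active) == 3:
        sub = D
        d01, d02, d12 = sub[0, 1], sub[0, 2], sub[1, 2]
        v0 = max(0.0, 0.5 * (d01 + d02 - d12))
        v1 = max(0.0, 0.5 * (d01 + d12 - d02))
        v2 = max(0.0, 0.5 * (d02 + d12 - d01))
        for k, v in zip(active, (v0, v1, v2)):
            root.children.append((nodes[k], v))
    else:  # two taxa
        a, b = active
        root.children.append((nodes[a], D[0, 1] / 2.0))
        root.children.append((nodes[b], D[0, 1] / 2.0))
    root.mask = 0
    for c, _ in root.children:
        root.mask |= c.mask
    root.key = min(c.key for c, _ in root.children)
    return root


def _collapse(node: _Node) -> None:
    """Collapse zero-length internal child edges into polytomies."""
    new_children: List[Tuple[_Node, float]] = []
    for child, length in node.children:
        _collapse(child)
        if child.children and length <= _ZERO_EDGE:
            new_children.extend(child.children)
        else:
            new_children.append((child, length))
    node.children = new_children


def _internal_masks(root: _Node, full_mask: int) -> Set[int]:
    """Canonical split bitmasks for retained internal edges."""
    out: Set[int] = set()
    stack = [c for c, _ in root.children]
    while stack:
        nd = stack.pop()
        if nd.children:
            m = nd.mask
            comp = full_mask & ~m
            if m and comp:
                out.add(min(m, comp))
            stack.extend(c for c, _ in nd.children)
    return out


def _newick(node: _Node, length: Optional[float] = None) -> str:
    if node.children:
        inner = ",".join(_newick(c, l) for c, l in node.children)
        s = f"({inner})"
        if node.label is not None:
            s += str(node.label)
    else:
        s = node.label
    if length is not None:
        s += f":{length:.10f}"
    return s


def _nj_splits(D: np.ndarray, labels: Sequence[str]) -> Set[int]:
    root = _nj_build(D, labels)
    _collapse(root)
    full = 0
    for _ in labels:
        full = (full << 1) | 1
    return _internal_masks(root, full)


def nj(dm: DistanceMatrix) -> dendropy.Tree:
    """Neighbor-joining tree from a distance matrix (unrooted).

    Raises on NA entries, naming the offending pairs.
    """
    if len(dm) < 2:
        raise ValueError("NJ requires at least two taxa")
    if dm.has_missing:
        raise ValueError(
            "distance matrix has NA entries for pairs "
            f"{dm.missing_pairs()}; switch deletion policy or prune taxa"
        )
    root = _nj_build(dm.values, dm.ids)
    _collapse(root)
    newick = _newick(root) + ";"
    tree = dendropy.Tree.get(
        data=newick,
        schema="newick",
        suppress_internal_node_taxa=True,
        preserve_underscores=True,
    )
    tree.is_rooted = False
    return tree


# ---------------------------------------------------------------------------
# supports / splits on dendropy trees
# ---------------------------------------------------------------------------
def _leafset(node) -> FrozenSet[str]:
    return frozenset(lf.taxon.label for lf in node.leaf_iter())


def tree_tip_labels(tree: dendropy.Tree) -> Set[str]:
    return {lf.taxon.label for lf in tree.leaf_node_iter()}


def _split_key(side: FrozenSet[str], all_tips: FrozenSet[str]) -> FrozenSet[FrozenSet[str]]:
    return frozenset((side, all_tips - side))


def node_support(node) -> Optional[int]:
    """Bootstrap percent stored on an internal node label, if any."""
    lab = node.label
    if lab is None:
        return None
    try:
        return int(round(float(lab)))
    except (TypeError, ValueError):
        return None


def harvest_supports(tree: dendropy.Tree) -> Dict[FrozenSet[FrozenSet[str]], int]:
    all_tips = frozenset(tree_tip_labels(tree))
    out: Dict[FrozenSet[FrozenSet[str]], int] = {}
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        sup = node_support(node)
        if sup is not None:
            out[_split_key(_leafset(node), all_tips)] = sup
    return out


def apply_supports(
    tree: dendropy.Tree, supports: Dict[FrozenSet[FrozenSet[str]], int]
) -> None:
    all_tips = frozenset(tree_tip_labels(tree))
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        key = _split_key(_leafset(node), all_tips)
        node.label = str(supports[key]) if key in supports else None


def internal_splits(tree: dendropy.Tree) -> Set[FrozenSet[FrozenSet[str]]]:
    all_tips = frozenset(tree_tip_labels(tree))
    out = set()
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        side = _leafset(node)
        if 0 < len(side) < len(all_tips):
            out.add(_split_key(side, all_tips))
    return out


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------
@dataclass
class BootstrapInfo:
    n_replicates: int
    n_skipped: int
    seed: int


def bootstrap(
    aln: Alignment,
    n_reps: int = 500,
    seed: int = 1,
    model: str = "k2p",
    deletion: str = "pairwise",
    indel_matrix=None,
) -> dendropy.Tree:
    """NJ tree with column-bootstrap supports on internal branches.

    Builds the reference NJ tree from the full alignment, then for each
    replicate resamples aligned columns with replacement, recomputes the
    distance matrix and the NJ tree.  The support of each internal split
    of the reference tree is the percentage of (successful) replicates
    containing it, rounded to the nearest integer.  Replicates whose matrix
    has NA entries (saturated or unshared pairs) are skipped and counted; a
    warning is emitted if more than 10% are skipped.

    ``indel_matrix`` (an :class:`~cladegap.stats.IndelCharacterMatrix`) may
    be passed to append coded gap characters as extra binary columns that
    are resampled together with the nucleotide columns; binary states are
    embedded as a pyrimidine pair so a 0/1 mismatch counts as one
    substitution.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    work = aln
    if indel_matrix is not None and indel_matrix.n_characters:
        coded = indel_matrix.appended_columns()
        trans = str.maketrans({"0": "C", "1": "T"})
        rows = {ind: aln.sequence(ind) + coded[ind].translate(trans) for ind in aln.ids}
        work = Alignment(aln.locus_name, rows)
    enc = work.encoded()
    if deletion == "complete":
        keep = ~(enc >= CODE_GAP).any(axis=0)
        if not keep.any():
            raise ValueError("complete deletion removed all columns")
        enc = enc[:, keep]

    ref_dm = DistanceMatrix(
        work.ids,
        _pair_dm(enc, model),
        model=model,
        deletion=deletion,
    )
    ref_tree = nj(ref_dm)

    order = {lab: r for r, lab in enumerate(sorted(work.ids))}
    full_mask = (1 << len(work.ids)) - 1

    counts = PairColumnCounts(enc, work.ids)
    L = enc.shape[1]
    rng = np.random.default_rng(seed)
    split_counts: Dict[int, int] = {}
    ref_masks = _nj_splits(ref_dm.values, ref_dm.ids)
    for m in ref_masks:
        split_counts[m] = 0
    n_skipped = 0
    n_ok = 0
    batch = 50
    done = 0
    while done < n_reps:
        b = min(batch, n_reps - done)
        W = rng.multinomial(L, np.full(L, 1.0 / L), size=b).T
        dms = counts.distance_batch(W, model=model)
        for k in range(b):
            D = dms[k]
            off = ~np.eye(len(work.ids), dtype=bool)
            if np.isnan(D[off]).any():
                n_skipped += 1
                continue
            masks = _nj_splits(D, work.ids)
            n_ok += 1
            for m in masks & split_counts.keys():
                split_counts[m] += 1
        done += b
    if n_skipped > 0.1 * n_reps:
        warnings.warn(
            f"bootstrap: {n_skipped}/{n_reps} replicates skipped "
            "(saturated or unshared pairs)",
            RuntimeWarning,
        )

    # attach supports to the reference tree by matching splits
    all_tips = frozenset(work.ids)
    for node in ref_tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        side = _leafset(node)
        mask = 0
        for t in side:
            mask |= 1 << order[t]
        canon = min(mask, full_mask & ~mask)
        if canon in split_counts and n_ok > 0:
            node.label = str(int(round(100.0 * split_counts[canon] / n_ok)))
    ref_tree.bootstrap_info = BootstrapInfo(n_reps, n_skipped, seed)
    return ref_tree


def _pair_dm(enc: np.ndarray, model: str) -> np.ndarray:
    from .distances import _distances_from_counts, _onehot_matmuls

    S, TS, TV = _onehot_matmuls(enc)
    return _distances_from_counts(S, TS, TV, model)


# ---------------------------------------------------------------------------
# rooting and monophyly
# ---------------------------------------------------------------------------
def root_with_outgroup(tree: dendropy.Tree, outgroup_tips: Iterable[str]) -> dendropy.Tree:
    """Root a tree on the branch subtending the outgroup.

    The outgroup must be a single tip or form one side of a split of the
    unrooted tree; otherwise an "outgroup not separable" error is raised.
    Bootstrap supports are carried over by split identity.
    """
    og = set(outgroup_tips)
    tips = tree_tip_labels(tree)
    if not og:
        raise ValueError("empty outgroup")
    unknown = og - tips
    if unknown:
        raise ValueError(f"outgroup tips not in tree: {sorted(unknown)}")
    if og == tips:
        raise ValueError("outgroup cannot contain every tip")

    clone = tree.clone(depth=1)
    # already rooted on this outgroup: nothing to do (idempotent)
    if tree.is_rooted:
        kids = clone.seed_node.child_nodes()
        if len(kids) == 2 and any(_leafset(k) == og for k in kids):
            clone.is_rooted = True
            return clone
    supports = harvest_supports(clone)
    target_edge = None
    for node in clone.preorder_node_iter():
        if node.parent_node is None:
            continue
        below = _leafset(node)
        if below == og or (tips - below) == og:
            target_edge = node.edge
            break
    if target_edge is None:
        raise ValueError("outgroup not separable: it does not form a clan in the tree")
    length = target_edge.length or 0.0
    clone.reroot_at_edge(target_edge, update_bipartitions=False)
    # split the original edge length evenly across the two root children
    root = clone.seed_node
    children = root.child_nodes()
    if len(children) == 2:
        half = length / 2.0
        for child in children:
            child.edge.length = half
    clone.is_rooted = True
    apply_supports(clone, supports)
    return clone


def is_monophyletic(
    tree: dendropy.Tree, tips: Iterable[str]
) -> Tuple[bool, Optional[int]]:
    """Test whether ``tips`` form a clade in a rooted tree.

    Returns ``(True, support)`` when the smallest clade containing the tips
    is exactly the tip set (support is the bootstrap label on that clade's
    subtending branch; NA for singletons and the full tip set).
    """
    if not tree.is_rooted:
        raise ValueError("monophyly is defined on rooted trees; root with an outgroup first")
    want = frozenset(tips)
    if not want:
        raise ValueError("empty tip set")
    all_tips = frozenset(tree_tip_labels(tree))
    unknown = want - all_tips
    if unknown:
        raise ValueError(f"unknown tips: {sorted(unknown)}")
    if len(want) == 1:
        return True, None
    if want == all_tips:
        return True, None
    # smallest clade containing all wanted tips
    best = None
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            continue
        ls = _leafset(node)
        if want <= ls and (best is None or len(ls) < len(best[0])):
            best = (ls, node)
    if best is None:
        return False, None
    ls, node = best
    if ls == want:
        return True, node_support(node)
    return False, None


# ---------------------------------------------------------------------------
# parsimony scoring (Fitch / Hartigan, handles polytomies)
# ---------------------------------------------------------------------------
_STATE_BITS = {"A": 1, "C": 2, "G": 4, "T": 8, "0": 16, "1": 32}
_MISSING_CHARS = set("-?N")
_N_STATE_BITS = 6
_FULL_SET = (1 << _N_STATE_BITS) - 1


def fitch_score(tree: dendropy.Tree, aln: Alignment, indel_matrix=None) -> int:
    """Small-parsimony length of an alignment on a fixed topology.

    Gap and missing characters contribute no cost (they are treated as
    fully ambiguous).  Pass an
    :class:`~cladegap.stats.IndelCharacterMatrix` as ``indel_matrix`` to
    append the binary gap characters (states ``0``/``1``), whose changes
    then add to the score.  Polytomies are handled exactly (Hartigan's
    generalisation of the Fitch pass).
    """
    tip_labels = tree_tip_labels(tree)
    if tip_labels != set(aln.ids):
        raise ValueError("tree tips do not match alignment individuals")
    seqs = {ind: aln.sequence(ind) for ind in aln.ids}
    if indel_matrix is not None and indel_matrix.n_characters:
        coded = indel_matrix.appended_columns()
        seqs = {ind: seqs[ind] + coded[ind] for ind in seqs}
    L = len(next(iter(seqs.values())))

    def tip_masks(ind: str) -> np.ndarray:
        out = np.empty(L, dtype=np.uint8)
        for k, ch in enumerate(seqs[ind]):
            if ch in _MISSING_CHARS:
                out[k] = _FULL_SET
            else:
                out[k] = _STATE_BITS.get(ch, _FULL_SET)
        return out

    cost = 0
    node_sets: Dict[int, np.ndarray] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            node_sets[id(node)] = tip_masks(node.taxon.label)
            continue
        children = node.child_nodes()
        stack = np.stack([node_sets.pop(id(c)) for c in children])
        # votes per state across children
        counts = np.zeros((_N_STATE_BITS, L), dtype=np.int32)
        for b in range(_N_STATE_BITS):
            counts[b] = ((stack >> b) & 1).sum(axis=0)
        K = counts.max(axis=0)
        V = np.zeros(L, dtype=np.uint8)
        for b in range(_N_STATE_BITS):
            V |= ((counts[b] == K).astype(np.uint8)) << b
        cost += int((len(children) - K).sum())
        node_sets[id(node)] = V
    return cost
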