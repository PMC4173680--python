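"""Matrix-representation-with-parsimony (MRP) supertree construction.

Source phylogenies are combined by coding every non-root internal node of
every rooted source tree as a binary character (Baum/Ragan coding: members of
the clade score 1, other taxa present in that source tree score 0, taxa
absent from the tree score ``?``).  The resulting weighted character matrix
is analysed with maximum parsimony via a parsimony-ratchet heuristic, the
equally most-parsimonious trees are summarised by strict consensus, and node
support is quantified with rQS (reduced qualitative support): each supertree
node is compared against each source tree after pruning both to their shared
taxa, and scored in [-1, +1].

Trees cross the API boundary as :class:`dendropy.Tree` objects; taxa are
matched by leaf label.
"""

from __future__ import annotations

import io
import itertools
from collections import deque
from dataclasses import dataclass, field

import dendropy
import numpy as np

MISSING = -1
_BIG = 1.0e9
_EPS = 1.0e-9

__all__ = [
    "MRPMatrix",
    "NodeSupport",
    "Removal",
    "mrp_encode",
    "safe_taxonomic_reduction",
    "regraft_taxa",
    "fitch_length",
    "ratchet_search",
    "exhaustive_search",
    "enumerate_topologies",
    "strict_consensus",
    "rqs_support",
    "bootstrap_rqs",
    "clade_sets",
    "tree_from_clades",
    "write_mrp_nexus",
]


# ---------------------------------------------------------------------------
# matrix container
# ---------------------------------------------------------------------------

@dataclass
class MRPMatrix:
    """Taxa x binary characters, entries in {0, 1, ?}.

    ``X`` holds the matrix with ``?`` stored as ``MISSING`` (-1); ``weights``
    is one positive real per character; ``provenance`` records the source
    tree each character was coded from.
    """

    taxa: list[str]
    X: np.ndarray
    weights: np.ndarray
    provenance: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.int8)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.X.ndim != 2 or self.X.shape[0] != len(self.taxa):
            raise ValueError("matrix shape does not match taxon list")
        if self.X.shape[1] != self.weights.size:
            raise ValueError("one weight per character required")
        if np.any(self.weights <= 0):
            raise ValueError("character weights must be positive")
        for j in range(self.X.shape[1]):
            col = self.X[:, j]
            if not ((col == 1).any() and (col == 0).any()):
                raise ValueError(f"character {j} is uninformative (needs a 0 and a 1)")

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_characters(self) -> int:
        return self.X.shape[1]


@dataclass
class Removal:
    """One taxon removed by safe taxonomic reduction."""

    taxon: str
    attachment: str
    reason: str  # "subsumed" or "uninformative"


@dataclass
class NodeSupport:
    """rQS scores per supertree clade.

    ``scores`` maps each nontrivial clade (frozenset of leaf labels) to its
    rQS value; ``counts`` maps it to (supporting, conflicting, uninformative)
    source-tree tallies.  The three tallies always sum to ``n_sources``.
    """

    scores: dict[frozenset, float]
    counts: dict[frozenset, tuple[int, int, int]]
    n_sources: int

    def tree_wide_mean(self) -> float:
        if not self.scores:
            return 0.0
        return float(np.mean(list(self.scores.values())))


# ---------------------------------------------------------------------------
# internal light-weight rooted tree used by the search
# ---------------------------------------------------------------------------

class _Node:
    __slots__ = ("children", "parent", "taxon")

    def __init__(self, taxon=None):
        self.children: list[_Node] = []
        self.parent: _Node | None = None
        self.taxon = taxon  # int leaf index or None


def _add_child(parent: _Node, child: _Node) -> None:
    parent.children.append(child)
    child.parent = parent


def _preorder(root: _Node) -> list[_Node]:
    out, stack = [], [root]
    while stack:
        nd = stack.pop()
        out.append(nd)
        stack.extend(reversed(nd.children))
    return out


def _postorder(root: _Node) -> list[_Node]:
    out, stack = [], [root]
    while stack:
        nd = stack.pop()
        out.append(nd)
        stack.extend(nd.children)
    out.reverse()
    return out


def _copy_tree(root: _Node) -> _Node:
    mapping = {}
    for nd in _preorder(root):
        cp = _Node(nd.taxon)
        mapping[id(nd)] = cp
        if nd.parent is not None:
            _add_child(mapping[id(nd.parent)], cp)
    return mapping[id(root)]


def _leaf_set(root: _Node) -> frozenset:
    return frozenset(nd.taxon for nd in _preorder(root) if not nd.children)


def _clades_int(root: _Node) -> frozenset:
    """Nontrivial proper clades as frozensets of leaf indices."""
    leaves: dict[int, set] = {}
    clades = []
    for nd in _postorder(root):
        if not nd.children:
            leaves[id(nd)] = {nd.taxon}
        else:
            s = set()
            for c in nd.children:
                s |= leaves[id(c)]
            leaves[id(nd)] = s
            if nd.parent is not None and len(s) >= 2:
                clades.append(frozenset(s))
    return frozenset(clades)


def _random_tree(n: int, rng: np.random.Generator) -> _Node:
    """Random rooted binary topology by random sequential joining."""
    nodes = [_Node(i) for i in range(n)]
    while len(nodes) > 1:
        i, j = rng.choice(len(nodes), size=2, replace=False)
        a, b = nodes[int(i)], nodes[int(j)]
        parent = _Node()
        _add_child(parent, a)
        _add_child(parent, b)
        nodes = [nd for nd in nodes if nd is not a and nd is not b]
        nodes.append(parent)
    return nodes[0]


# -- conversions ------------------------------------------------------------

def _quote(label: str) -> str:
    if any(ch in label for ch in " ,():;[]'"):
        return "'" + label.replace("'", "''") + "'"
    return label


def _to_newick(root: _Node, labels: list[str]) -> str:
    def rec(nd: _Node) -> str:
        if not nd.children:
            return _quote(labels[nd.taxon])
        return "(" + ",".join(rec(c) for c in nd.children) + ")"

    return rec(root) + ";"


def _to_dendropy(root: _Node, labels: list[str],
                 taxon_namespace: dendropy.TaxonNamespace | None = None) -> dendropy.Tree:
    return dendropy.Tree.get(
        data=_to_newick(root, labels),
        schema="newick",
        rooting="force-rooted",
        taxon_namespace=taxon_namespace,
    )


def _from_dendropy(tree: dendropy.Tree, index: dict[str, int]) -> _Node:
    def rec(dnode) -> _Node:
        if dnode.is_leaf():
            return _Node(index[dnode.taxon.label])
        nd = _Node()
        for c in dnode.child_nodes():
            _add_child(nd, rec(c))
        return nd

    return rec(tree.seed_node)


def clade_sets(tree: dendropy.Tree) -> set[frozenset]:
    """Nontrivial proper clades of a rooted tree as frozensets of leaf labels."""
    n_total = sum(1 for _ in tree.leaf_node_iter())
    out = set()
    for nd in tree.postorder_node_iter():
        if nd.is_leaf() or nd.parent_node is None:
            continue
        s = frozenset(lf.taxon.label for lf in nd.leaf_iter())
        if 2 <= len(s) < n_total:
            out.add(s)
    return out


def tree_from_clades(leaf_labels, clades) -> dendropy.Tree:
    """Build the rooted tree whose nontrivial clades are exactly ``clades``.

    The clades must be pairwise compatible (nested or disjoint); conflicts
    raise ``ValueError``.
    """
    leaf_labels = sorted(leaf_labels)
    clades = sorted({frozenset(c) for c in clades}, key=len, reverse=True)
    for a, b in itertools.combinations(clades, 2):
        if (a & b) and not (a <= b or b <= a):
            raise ValueError("incompatible clades cannot form a tree")
    index = {lab: i for i, lab in enumerate(leaf_labels)}
    root = _Node()
    nodes = [(frozenset(index.keys()), root)]
    for c in clades:
        # parent = smallest already-placed set strictly containing c
        best = None
        for s, nd in nodes:
            if c < s and (best is None or len(s) < len(best[0])):
                best = (s, nd)
        nd = _Node()
        _add_child(best[1], nd)
        nodes.append((c, nd))
    for lab in leaf_labels:
        best = None
        for s, nd in nodes:
            if lab in s and (best is None or len(s) < len(best[0])):
                best = (s, nd)
        _add_child(best[1], _Node(index[lab]))
    return _to_dendropy(root, leaf_labels)


# ---------------------------------------------------------------------------
# MRP coding
# ---------------------------------------------------------------------------

def mrp_encode(source_trees, taxon_universe=None, tree_weights=None) -> MRPMatrix:
    """Baum/Ragan-code rooted source trees into a binary character matrix.

    One character per non-root internal node of each source tree: clade
    members 1, other taxa in that tree 0, taxa absent from the tree ``?``.
    Star trees contribute no characters.  ``tree_weights`` optionally gives
    one weight per source tree (default 1.0), applied to all its characters.
    """
    source_trees = list(source_trees)
    if tree_weights is None:
        tree_weights = [1.0] * len(source_trees)
    if len(tree_weights) != len(source_trees):
        raise ValueError("one weight per source tree required")
    for k, t in enumerate(source_trees):
        if not t.is_rooted:
            raise ValueError(
                f"source tree {k} is unrooted; root it (e.g. with an outgroup or "
                "[&R] in the Newick string) before MRP coding"
            )
    if taxon_universe is None:
        universe: list[str] = []
        seen = set()
        for t in source_trees:
            for lf in t.leaf_node_iter():
                if lf.taxon.label not in seen:
                    seen.add(lf.taxon.label)
                    universe.append(lf.taxon.label)
    else:
        universe = list(taxon_universe)
    index = {lab: i for i, lab in enumerate(universe)}
    cols, weights, provenance = [], [], []
    for k, t in enumerate(source_trees):
        tree_taxa = [lf.taxon.label for lf in t.leaf_node_iter()]
        if not set(tree_taxa) <= set(universe):
            extra = sorted(set(tree_taxa) - set(universe))
            raise ValueError(f"source tree {k} has taxa outside the universe: {extra}")
        n_tree = len(tree_taxa)
        for nd in t.postorder_internal_node_iter():
            if nd.parent_node is None:
                continue
            clade = [lf.taxon.label for lf in nd.leaf_iter()]
            if len(clade) < 2 or len(clade) >= n_tree:
                continue
            col = np.full(len(universe), MISSING, dtype=np.int8)
            for lab in tree_taxa:
                col[index[lab]] = 0
            for lab in clade:
                col[index[lab]] = 1
            cols.append(col)
            weights.append(float(tree_weights[k]))
            provenance.append(t.label if t.label else k)
    if not cols:
        raise ValueError("no informative characters: all source trees are stars")
    return MRPMatrix(universe, np.column_stack(cols), np.array(weights), provenance)


def write_mrp_nexus(matrix: MRPMatrix, path) -> None:
    """Write the matrix as a NEXUS data block (symbols 01, missing ?)."""
    buf = io.StringIO()
    buf.write("#NEXUS\nBEGIN DATA;\n")
    buf.write(f"  DIMENSIONS NTAX={matrix.n_taxa} NCHAR={matrix.n_characters};\n")
    buf.write('  FORMAT SYMBOLS="01" MISSING=?;\n  MATRIX\n')
    width = max(len(t) for t in matrix.taxa) + 2
    for i, tx in enumerate(matrix.taxa):
        row = "".join("?" if v == MISSING else str(int(v)) for v in matrix.X[i])
        buf.write(f"    {tx.replace(' ', '_'):<{width}}{row}\n")
    buf.write("  ;\nEND;\n")
    buf.write("[weights: " + " ".join(f"{w:g}" for w in matrix.weights) + "]\n")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


# ---------------------------------------------------------------------------
# safe taxonomic reduction
# ---------------------------------------------------------------------------

def safe_taxonomic_reduction(matrix: MRPMatrix) -> tuple[MRPMatrix, list[Removal]]:
    """Remove taxa whose codings are subsumed by another taxon's.

    Taxon A is removed when some retained taxon B agrees with A at every
    character where A is scored: A then carries no signal B does not already
    carry, and can be re-grafted next to B after the search
    (:func:`regraft_taxa`).  Characters left uninformative by the removals
    are dropped.
    """
    X = matrix.X
    n = matrix.n_taxa
    removed: set[int] = set()
    log: list[Removal] = []
    for i in range(n):
        scored = X[i] != MISSING
        for j in range(n):
            if j == i or j in removed:
                continue
            if not scored.any():
                log.append(Removal(matrix.taxa[i], matrix.taxa[j], "uninformative"))
                removed.add(i)
                break
            if np.array_equal(X[i][scored], X[j][scored]):
                log.append(Removal(matrix.taxa[i], matrix.taxa[j], "subsumed"))
                removed.add(i)
                break
    keep = [i for i in range(n) if i not in removed]
    Xr = X[keep]
    # drop characters that lost their 0s or 1s
    good = [(Xr[:, j] == 1).any() and (Xr[:, j] == 0).any() for j in range(Xr.shape[1])]
    good = np.asarray(good)
    reduced = MRPMatrix(
        [matrix.taxa[i] for i in keep],
        Xr[:, good],
        matrix.weights[good],
        [p for p, g in zip(matrix.provenance, good) if g],
    )
    return reduced, log


def regraft_taxa(tree: dendropy.Tree, log: list[Removal]) -> dendropy.Tree:
    """Re-attach safely-reduced taxa as sisters of their attachment taxa.

    Removals are undone in reverse order, so chained removals resolve
    correctly.
    """
    labels = sorted(lf.taxon.label for lf in tree.leaf_node_iter())
    labels_all = list(labels)
    index = {lab: i for i, lab in enumerate(labels_all)}
    root = _from_dendropy(tree, index)
    for rem in reversed(log):
        if rem.taxon in index:
            continue
        index[rem.taxon] = len(labels_all)
        labels_all.append(rem.taxon)
        target_idx = index[rem.attachment]
        target = next(nd for nd in _preorder(root) if nd.taxon == target_idx)
        new_leaf = _Node(index[rem.taxon])
        joint = _Node()
        parent = target.parent
        if parent is None:
            _add_child(joint, target)
            _add_child(joint, new_leaf)
            root = joint
        else:
            parent.children[parent.children.index(target)] = joint
            joint.parent = parent
            _add_child(joint, target)
            _add_child(joint, new_leaf)
    return _to_dendropy(root, labels_all)


# ---------------------------------------------------------------------------
# parsimony length (two-state Sankoff; exact on polytomies, ? = {0,1})
# ---------------------------------------------------------------------------

def _tree_length_internal(root: _Node, X: np.ndarray, weights: np.ndarray,
                          rooted: bool = False) -> float:
    """Weighted parsimony length; with ``rooted=True`` an implicit all-zero
    outgroup sits at the root (the standard MRP rooting), so a state-1 root
    costs one extra step per character."""
    costs: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    for nd in _postorder(root):
        if not nd.children:
            row = X[nd.taxon]
            c0 = np.where(row == 1, _BIG, 0.0)
            c1 = np.where(row == 0, _BIG, 0.0)
        else:
            c0 = 0.0
            c1 = 0.0
            for ch in nd.children:
                k0, k1 = costs.pop(id(ch))
                c0 = c0 + np.minimum(k0, k1 + 1.0)
                c1 = c1 + np.minimum(k1, k0 + 1.0)
        costs[id(nd)] = (c0, c1)
    r0, r1 = costs[id(root)]
    per_char = np.minimum(r0, r1 + 1.0) if rooted else np.minimum(r0, r1)
    return float(np.dot(weights, per_char))


def fitch_length(tree: dendropy.Tree, matrix: MRPMatrix,
                 weights: np.ndarray | None = None) -> float:
    """Total weighted parsimony length of ``tree`` on ``matrix``.

    Minimum number of 0<->1 changes per character (``?`` free to take either
    state), summed with character weights.  Computed by a two-state
    dynamic programme, which equals Fitch counting on binary trees and stays
    exact on polytomies.
    """
    labels = {lf.taxon.label for lf in tree.leaf_node_iter()}
    if labels != set(matrix.taxa):
        raise ValueError("tree leaf set does not match matrix taxa")
    index = {lab: i for i, lab in enumerate(matrix.taxa)}
    root = _from_dendropy(tree, index)
    w = matrix.weights if weights is None else np.asarray(weights, dtype=float)
    return _tree_length_internal(root, matrix.X, w)


# ---------------------------------------------------------------------------
# SPR moves and hill climbing
# ---------------------------------------------------------------------------

def _spr_candidates(root: _Node) -> list[tuple[int, int]]:
    nodes = _preorder(root)
    pos = {id(nd): i for i, nd in enumerate(nodes)}
    # descendant index sets via preorder intervals
    sub: dict[int, set[int]] = {}
    for nd in reversed(nodes):
        s = {pos[id(nd)]}
        for c in nd.children:
            s |= sub[id(c)]
        sub[id(nd)] = s
    cands = []
    for i, p in enumerate(nodes):
        if p.parent is None:
            continue
        forbidden = sub[id(p)] | {pos[id(p.parent)]}
        for j in range(len(nodes)):
            if j not in forbidden:
                cands.append((i, j))
    return cands


def _apply_spr(root: _Node, prune_i: int, attach_j: int) -> _Node:
    nodes_src = _preorder(root)
    new_root = _copy_tree(root)
    nodes = _preorder(new_root)
    p = nodes[prune_i]
    a = nodes[attach_j]
    par = p.parent
    par.children.remove(p)
    p.parent = None
    if len(par.children) == 1:
        only = par.children[0]
        gp = par.parent
        if gp is None:
            only.parent = None
            new_root = only
        else:
            gp.children[gp.children.index(par)] = only
            only.parent = gp
        if a is par:
            a = only
    joint = _Node()
    if a.parent is None:
        _add_child(joint, a)
        _add_child(joint, p)
        new_root = joint
    else:
        ap = a.parent
        ap.children[ap.children.index(a)] = joint
        joint.parent = ap
        _add_child(joint, a)
        _add_child(joint, p)
    del nodes_src
    return new_root


def _hill_climb(root: _Node, X: np.ndarray, w: np.ndarray,
                rng: np.random.Generator) -> tuple[_Node, float]:
    cur = root
    cur_len = _tree_length_internal(cur, X, w, rooted=True)
    improved = True
    while improved:
        improved = False
        cands = _spr_candidates(cur)
        order = rng.permutation(len(cands))
        for k in order:
            i, j = cands[int(k)]
            nb = _apply_spr(cur, i, j)
            L = _tree_length_internal(nb, X, w, rooted=True)
            if L < cur_len - _EPS:
                cur, cur_len = nb, L
                improved = True
                break
    return cur, cur_len


def ratchet_search(matrix: MRPMatrix, iterations: int = 200,
                   reweight_fraction: float = 0.25, seed: int = 0,
                   max_trees: int = 10000, weight_multiplier: float = 2.0,
                   explore_plateau: bool = True):
    """Parsimony-ratchet heuristic search.

    Each cycle doubles the weight of a random ``reweight_fraction`` of the
    characters, hill-climbs under the perturbed weights with SPR moves,
    restores the original weights and hill-climbs again; trees no longer
    than the best found are kept (up to ``max_trees`` distinct topologies).
    After the cycles, the set of best trees is closed under equal-length SPR
    neighbours so ties are represented in the strict consensus.

    Returns ``(trees, best_length)`` with ``trees`` a list of
    :class:`dendropy.Tree` sharing one taxon namespace.  Deterministic for a
    given ``seed``.
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    if matrix.n_taxa < 3:
        raise ValueError("need at least 3 taxa to search")
    rng = np.random.default_rng(seed)
    X, w = matrix.X, matrix.weights.astype(float)
    nchar = matrix.n_characters

    cur, cur_len = _hill_climb(_random_tree(matrix.n_taxa, rng), X, w, rng)
    best_len = cur_len
    best: dict[frozenset, _Node] = {_clades_int(cur): cur}

    for _ in range(iterations):
        w2 = w.copy()
        nsel = max(1, int(round(reweight_fraction * nchar)))
        idx = rng.choice(nchar, size=nsel, replace=False)
        w2[idx] *= weight_multiplier
        t, _L = _hill_climb(_copy_tree(cur), X, w2, rng)
        t, L = _hill_climb(t, X, w, rng)
        if L < best_len - _EPS:
            best_len = L
            best = {}
        if L <= best_len + _EPS and len(best) < max_trees:
            best.setdefault(_clades_int(t), t)
            cur = t

    if explore_plateau:
        queue = deque(best.values())
        while queue and len(best) < max_trees:
            t = queue.popleft()
            for i, j in _spr_candidates(t):
                nb = _apply_spr(t, i, j)
                L = _tree_length_internal(nb, X, w, rooted=True)
                if L < best_len - _EPS:
                    best_len = L
                    best = {_clades_int(nb): nb}
                    queue = deque([nb])
                    break
                if L <= best_len + _EPS:
                    key = _clades_int(nb)
                    if key not in best and len(best) < max_trees:
                        best[key] = nb
                        queue.append(nb)

    ns = dendropy.TaxonNamespace()
    trees = [_to_dendropy(t, matrix.taxa, ns) for t in best.values()]
    return trees, best_len


def enumerate_topologies(n: int):
    """Yield every rooted binary topology over leaf indices 0..n-1."""
    if n < 2:
        raise ValueError("need >= 2 taxa")

    def grow(root: _Node, k: int):
        if k == n:
            yield root
            return
        edges = [nd for nd in _preorder(root)]
        for nd in edges:
            t = _copy_tree(root)
            target = _preorder(t)[_preorder(root).index(nd)]
            leaf = _Node(k)
            joint = _Node()
            parent = target.parent
            if parent is None:
                _add_child(joint, target)
                _add_child(joint, leaf)
                yield from grow(joint, k + 1)
            else:
                parent.children[parent.children.index(target)] = joint
                joint.parent = parent
                _add_child(joint, target)
                _add_child(joint, leaf)
                yield from grow(t, k + 1)

    base = _Node()
    _add_child(base, _Node(0))
    _add_child(base, _Node(1))
    yield from grow(base, 2)


def exhaustive_search(matrix: MRPMatrix, max_taxa: int = 8):
    """Exact maximum parsimony by enumeration of all rooted binary topologies.

    Only for small problems (guarded at ``max_taxa``); used as the oracle
    against which the heuristic search can be validated.
    """
    n = matrix.n_taxa
    if n > max_taxa:
        raise ValueError(f"exhaustive search limited to {max_taxa} taxa")
    best_len = np.inf
    best: dict[frozenset, _Node] = {}
    for t in enumerate_topologies(n):
        L = _tree_length_internal(t, matrix.X, matrix.weights, rooted=True)
        if L < best_len - _EPS:
            best_len = L
            best = {_clades_int(t): t}
        elif L <= best_len + _EPS:
            best.setdefault(_clades_int(t), t)
    ns = dendropy.TaxonNamespace()
    return [_to_dendropy(t, matrix.taxa, ns) for t in best.values()], float(best_len)


# ---------------------------------------------------------------------------
# consensus and support
# ---------------------------------------------------------------------------

def strict_consensus(trees) -> dendropy.Tree:
    """Tree containing exactly the clades shared by every input tree."""
    trees = list(trees)
    if not trees:
        raise ValueError("no trees to summarise")
    leafsets = [frozenset(lf.taxon.label for lf in t.leaf_node_iter()) for t in trees]
    if len(set(leafsets)) != 1:
        raise ValueError("strict consensus requires identical leaf sets")
    shared = clade_sets(trees[0])
    for t in trees[1:]:
        shared &= clade_sets(t)
    return tree_from_clades(leafsets[0], shared)


def _compatible(a: frozenset, b: frozenset) -> bool:
    return not (a & b) or a <= b or b <= a


def rqs_support(supertree: dendropy.Tree, source_trees,
                normalization: str = "all") -> NodeSupport:
    """Reduced qualitative support for every nontrivial supertree clade.

    For each source tree, both trees are pruned to their shared taxa.  A
    source votes +1 for a node when the node's restricted clade appears in
    the pruned source, -1 when the pruned source holds an incompatible
    clade, and 0 when uninformative (fewer than two shared members, the
    restricted clade is the whole shared set, or the source resolves
    nothing either way).  ``normalization="all"`` divides (support -
    conflict) by the number of source trees; ``"informative"`` divides by
    the informative votes only.
    """
    source_trees = list(source_trees)
    if not source_trees:
        raise ValueError("need at least one source tree")
    if normalization not in ("all", "informative"):
        raise ValueError("normalization must be 'all' or 'informative'")
    st_leaves = frozenset(lf.taxon.label for lf in supertree.leaf_node_iter())
    sources = []
    for t in source_trees:
        leafs = frozenset(lf.taxon.label for lf in t.leaf_node_iter())
        sources.append((leafs & st_leaves, clade_sets(t)))
    scores: dict[frozenset, float] = {}
    counts: dict[frozenset, tuple[int, int, int]] = {}
    for clade in clade_sets(supertree):
        sup = con = uninf = 0
        for shared, src_clades in sources:
            k = clade & shared
            if len(k) < 2 or k == shared:
                uninf += 1
                continue
            restricted = {c & shared for c in src_clades}
            restricted = {c for c in restricted if 2 <= len(c) < len(shared)}
            if k in restricted:
                sup += 1
            elif any(not _compatible(k, c) for c in restricted):
                con += 1
            else:
                uninf += 1
        denom = len(sources) if normalization == "all" else max(1, sup + con)
        scores[clade] = (sup - con) / denom
        counts[clade] = (sup, con, uninf)
    return NodeSupport(scores, counts, len(sources))


def bootstrap_rqs(matrix: MRPMatrix, source_trees, replicates: int,
                  seed: int = 0, iterations: int = 20,
                  reweight_fraction: float = 0.25, max_trees: int = 200,
                  normalization: str = "all"):
    """Character-bootstrap rQS.

    Each replicate resamples characters with replacement, re-runs the
    ratchet at the reduced settings given here, takes the strict consensus
    and scores it against the source trees.  Returns ``(per_clade_mean,
    tree_wide_mean)``: the first averages each clade's score over the
    replicates whose consensus contains it, the second averages the
    per-replicate mean node score.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    rng = np.random.default_rng(seed)
    totals: dict[frozenset, list[float]] = {}
    rep_means = []
    for _ in range(replicates):
        idx = rng.integers(0, matrix.n_characters, size=matrix.n_characters)
        Xb = matrix.X[:, idx]
        # resampling can leave a character uninformative within the sample;
        # such columns carry no signal and are dropped
        good = [(Xb[:, j] == 1).any() and (Xb[:, j] == 0).any() for j in range(Xb.shape[1])]
        good = np.asarray(good)
        boot = MRPMatrix(list(matrix.taxa), Xb[:, good], matrix.weights[idx][good],
                         [matrix.provenance[i] for i, g in zip(idx, good) if g])
        sub_seed = int(rng.integers(0, 2**31 - 1))
        trees, _ = ratchet_search(boot, iterations=iterations,
                                  reweight_fraction=reweight_fraction,
                                  seed=sub_seed, max_trees=max_trees)
        cons = strict_consensus(trees)
        support = rqs_support(cons, source_trees, normalization=normalization)
        rep_means.append(support.tree_wide_mean())
        for clade, sc in support.scores.items():
            totals.setdefault(clade, []).append(sc)
    per_clade = {c: float(np.mean(v)) for c, v in totals.items()}
    return per_clade, float(np.mean(rep_means))
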