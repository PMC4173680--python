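"""Node dating: fossil calibrations plus deterministic age imputation.

A supertree topology becomes an ultrametric chronogram in three steps:
fixed point ages (in Myr) are pinned to calibrated nodes (tips are age 0),
the remaining internal nodes are interpolated between their nearest dated
ancestor and dated descendants, and branch lengths are set to parent age
minus child age.

Two interpolation modes are offered.  ``even`` spaces the m undated nodes
of a bracketed path uniformly: node i gets ``t_a - i * (t_a - t_d) /
(m + 1)``.  ``yule`` divides the bracket in proportion to pure-birth
expected waiting times: sub-interval i below the dated ancestor is crossed
by ``k = 2 + i`` lineages of that ancestor's subtree, so receives a share
proportional to ``1 / k``.  Both modes preserve calibrated ages exactly and
always produce strictly decreasing ages root-to-tip.

Ages live on ``node.age`` attributes of :class:`dendropy.Tree` nodes.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import pandas as pd

__all__ = [
    "Calibration",
    "apply_calibrations",
    "impute_node_ages",
    "branch_lengths_from_ages",
    "read_calibrations",
    "node_ages_table",
    "is_ultrametric",
]


@dataclass
class Calibration:
    """A fixed node age: the MRCA of ``taxa`` (or the node labelled
    ``node_label``) is ``age`` Myr old."""

    age: float
    taxa: frozenset | None = None
    node_label: str | None = None

    def __post_init__(self) -> None:
        if self.age <= 0:
            raise ValueError("calibration ages must be positive")
        if self.taxa is None and self.node_label is None:
            raise ValueError("calibration needs a taxon set or a node label")
        if self.taxa is not None:
            self.taxa = frozenset(self.taxa)


def _resolve(tree: dendropy.Tree, cal: Calibration):
    if cal.node_label is not None:
        for nd in tree.preorder_node_iter():
            if nd.label == cal.node_label:
                return nd
        raise ValueError(f"no node labelled {cal.node_label!r}")
    node = tree.mrca(taxon_labels=list(cal.taxa))
    if node is None:
        raise ValueError(f"MRCA of {sorted(cal.taxa)} not found")
    return node


def apply_calibrations(tree: dendropy.Tree, calibrations) -> dendropy.Tree:
    """Pin calibrated node ages on a copy of ``tree``; tips get age 0.

    Raises when a calibrated descendant is at least as old as a calibrated
    ancestor (naming both nodes)."""
    tree = tree.clone(depth=1)
    for nd in tree.preorder_node_iter():
        nd.age = 0.0 if nd.is_leaf() else None
    for cal in calibrations:
        nd = _resolve(tree, cal)
        if nd.is_leaf():
            raise ValueError("cannot calibrate a tip to a positive age")
        nd.age = float(cal.age)
    # consistency: along every root-to-tip path, dated ages must decrease
    for nd in tree.preorder_node_iter():
        if nd.age is None:
            continue
        anc = nd.parent_node
        while anc is not None and anc.age is None:
            anc = anc.parent_node
        if anc is not None and anc.age <= nd.age:
            raise ValueError(
                f"calibration conflict: descendant node ({_describe(nd)}, "
                f"{nd.age} Myr) is not younger than ancestor ({_describe(anc)}, "
                f"{anc.age} Myr)")
    return tree


def _describe(nd) -> str:
    if nd.label:
        return nd.label
    tips = [lf.taxon.label for lf in nd.leaf_iter()]
    return "MRCA(" + ",".join(sorted(tips)[:3]) + ("..." if len(tips) > 3 else "") + ")"


def impute_node_ages(tree: dendropy.Tree, mode: str = "even") -> dendropy.Tree:
    """Fill undated internal nodes of a calibrated tree (in place).

    Requires a dated root.  Nodes are processed in preorder: an undated
    node with (already dated) parent age ``t_a`` is placed within
    ``(t_d, t_a)`` where ``t_d`` is the largest age among its dated
    descendants, according to the chosen mode (see module docstring).
    """
    if mode not in ("even", "yule"):
        raise ValueError("mode must be 'even' or 'yule'")
    root = tree.seed_node
    if getattr(root, "age", None) is None:
        raise ValueError("root must be dated (directly or via a calibration)")

    originally_dated = {id(nd) for nd in tree.preorder_node_iter()
                        if getattr(nd, "age", None) is not None}

    # bottom-up: for each node, the binding dated descendant age and the
    # number of undated nodes on the deepest path to it (inclusive)
    info: dict[int, tuple[float, int]] = {}
    for nd in tree.postorder_node_iter():
        if getattr(nd, "age", None) is not None:
            info[id(nd)] = (nd.age, 0)
        else:
            cands = [info[id(c)] for c in nd.child_nodes()]
            a = max(c[0] for c in cands)
            m = 1 + max(c[1] for c in cands if c[0] == a)
            info[id(nd)] = (a, m)

    for nd in tree.preorder_node_iter():
        if getattr(nd, "age", None) is not None:
            continue
        t_a = nd.parent_node.age
        t_d, m = info[id(nd)]
        span = t_a - t_d
        if span <= 0:
            raise ValueError("dated ancestor not older than dated descendant")
        if mode == "even":
            nd.age = t_a - span / (m + 1)
        else:
            # lineage count crossing the first sub-interval of this node's
            # bracket: the originally-dated ancestor's split contributes 2
            # lineages, and each undated split already placed on the path
            # above adds one
            k0 = 2
            anc = nd.parent_node
            while anc is not None and id(anc) not in originally_dated:
                k0 += 1
                anc = anc.parent_node
            weights = [1.0 / (k0 + i) for i in range(m + 1)]
            nd.age = t_a - span * weights[0] / sum(weights)
        info[id(nd)] = (nd.age, 0)
    return tree


def branch_lengths_from_ages(tree: dendropy.Tree) -> dendropy.Tree:
    """Set each edge length to parent age minus child age (in place)."""
    for nd in tree.preorder_node_iter():
        if getattr(nd, "age", None) is None:
            raise ValueError("all nodes must be dated first")
        if nd.parent_node is not None:
            length = nd.parent_node.age - nd.age
            if length < 0:
                raise ValueError(f"negative branch above {_describe(nd)}")
            nd.edge.length = length
    return tree


def is_ultrametric(tree: dendropy.Tree, tol: float = 1e-9) -> bool:
    depths = []
    for lf in tree.leaf_node_iter():
        d, nd = 0.0, lf
        while nd.parent_node is not None:
            d += nd.edge.length or 0.0
            nd = nd.parent_node
        depths.append(d)
    return max(depths) - min(depths) <= tol * max(1.0, max(depths))


def node_ages_table(tree: dendropy.Tree) -> pd.DataFrame:
    rows = []
    for i, nd in enumerate(tree.preorder_node_iter()):
        rows.append({
            "node": nd.label or (nd.taxon.label if nd.taxon else f"node_{i}"),
            "age_Ma": getattr(nd, "age", None),
            "is_leaf": nd.is_leaf(),
        })
    return pd.DataFrame(rows)


def read_calibrations(path) -> list[Calibration]:
    """Read a calibration CSV with columns ``node`` and ``age_Ma``.

    ``node`` is either a node label or a ``|``-separated taxon list whose
    MRCA is calibrated."""
    df = pd.read_csv(path)
    cals = []
    for _, row in df.iterrows():
        node = str(row["node"])
        age = float(row["age_Ma"])
        if "|" in node:
            cals.append(Calibration(age=age, taxa=frozenset(node.split("|"))))
        else:
            cals.append(Calibration(age=age, node_label=node))
    return cals
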