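"""Rooted-tree container and the tree algebra the pipeline is built on.

The :class:`Phylogeny` wraps a simple node structure (children lists, parent
links, branch lengths, optional support values) and provides the operations
every downstream stage needs: Newick round-tripping (parsing is delegated to
dendropy), pruning to a taxon subset, collapsing poorly supported branches
into polytomies, sister-pair extraction and the enumeration of speciation
events that can be assessed for geographic/ecological transitions.

Branch support may be encoded either on a 0-100 ("percent") or 0-1 ("unit")
scale; the dialect is recorded on the tree so thresholds are interpreted
consistently.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import dendropy

__all__ = [
    "Node",
    "Phylogeny",
    "SisterPair",
    "EventNodeSet",
    "read_tree",
    "write_tree",
    "prune_to_taxa",
    "collapse_low_support",
    "sister_pairs",
    "survey_nodes",
    "TreeError",
]


class TreeError(ValueError):
    """Raised on malformed trees or invalid tree operations."""


def normalize_label(label: str) -> str:
    """Canonical tip label: surrounding whitespace trimmed, spaces unified to
    underscores (Newick writers disagree on the separator)."""
    return label.strip().replace(" ", "_")


class Node:
    __slots__ = ("children", "parent", "length", "label", "support", "id")

    def __init__(self, label: str | None = None, length: float | None = None,
                 support: float | None = None):
        self.children: list[Node] = []
        self.parent: Node | None = None
        self.length = length
        self.support = support
        self.label = label
        self.id: str | None = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    def __repr__(self) -> str:  # pragma: no cover
        return f"<Node {self.id or self.label}>"


class Phylogeny:
    """A rooted tree with named tips and addressable internal nodes.

    Internal node ids are assigned in preorder (``n0`` is the root); tip ids
    equal their labels. Ids are stable for a given topology and are
    re-assigned whenever a derived tree is built.
    """

    def __init__(self, root: Node, support_dialect: str = "percent"):
        if support_dialect not in ("percent", "unit"):
            raise ValueError(f"unknown support dialect: {support_dialect!r}")
        self.root = root
        self.support_dialect = support_dialect
        self._assign_ids()
        self._index = {n.id: n for n in self.preorder()}
        labels = [n.label for n in self.leaves()]
        dup = {x for x in labels if labels.count(x) > 1}
        if dup:
            raise TreeError(f"duplicate tip labels: {sorted(dup)}")

    # -- traversal ---------------------------------------------------------
    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            n = stack.pop()
            yield n
            stack.extend(reversed(n.children))

    def postorder(self) -> Iterator[Node]:
        out: list[Node] = []
        stack = [self.root]
        while stack:
            n = stack.pop()
            out.append(n)
            stack.extend(n.children)
        return iter(reversed(out))

    def leaves(self, node: Node | None = None) -> Iterator[Node]:
        start = node or self.root
        for n in self._subtree(start):
            if n.is_leaf:
                yield n

    @staticmethod
    def _subtree(node: Node) -> Iterator[Node]:
        stack = [node]
        while stack:
            n = stack.pop()
            yield n
            stack.extend(n.children)

    def internal_nodes(self, node: Node | None = None) -> list[Node]:
        return [n for n in self._subtree(node or self.root) if not n.is_leaf]

    @property
    def tip_labels(self) -> list[str]:
        return [n.label for n in self.leaves()]

    def node(self, node_id: str) -> Node:
        try:
            return self._index[node_id]
        except KeyError:
            raise TreeError(f"no node with id {node_id!r}") from None

    def _assign_ids(self) -> None:
        i = 0
        for n in self.preorder():
            if n.is_leaf:
                n.id = n.label
            else:
                n.id = f"n{i}"
                i += 1

    # -- queries -----------------------------------------------------------
    def mrca(self, labels: Iterable[str]) -> Node:
        want = {normalize_label(l) for l in labels}
        missing = want - set(self.tip_labels)
        if missing:
            raise TreeError(f"unknown tip labels: {sorted(missing)}")
        node_sets = {}
        best = None
        for n in self.postorder():
            if n.is_leaf:
                node_sets[id(n)] = {n.label} & want
            else:
                s = set()
                for c in n.children:
                    s |= node_sets[id(c)]
                node_sets[id(n)] = s
            if node_sets[id(n)] == want and best is None:
                best = n
        assert best is not None
        return best

    def leaf_set(self, node: Node) -> frozenset[str]:
        return frozenset(n.label for n in self.leaves(node))

    def depths(self) -> dict[str, float]:
        """Root-to-node path lengths; missing branch lengths raise."""
        out: dict[str, float] = {}
        for n in self.preorder():
            if n is self.root:
                out[n.id] = 0.0
            else:
                if n.length is None:
                    raise TreeError(f"missing branch length above node {n.id}")
                out[n.id] = out[n.parent.id] + n.length
        return out

    def patristic_matrix(self) -> tuple[list[str], "list[list[float]]"]:
        """All pairwise tip-to-tip path-length distances (oracle helper)."""
        tips = list(self.leaves())
        labels = [t.label for t in tips]
        depth = self.depths()
        # ancestors of each tip
        anc = {}
        for t in tips:
            path = []
            n: Node | None = t
            while n is not None:
                path.append(n.id)
                n = n.parent
            anc[t.label] = path
        dist = [[0.0] * len(tips) for _ in tips]
        for i, a in enumerate(tips):
            seta = set(anc[a.label])
            for k, b in enumerate(tips):
                if k <= i:
                    continue
                for nid in anc[b.label]:
                    if nid in seta:
                        d = depth[a.label] + depth[b.label] - 2 * depth[nid]
                        dist[i][k] = dist[k][i] = d
                        break
        return labels, dist

    def copy(self) -> "Phylogeny":
        return Phylogeny(_copy_subtree(self.root), self.support_dialect)

    def __len__(self) -> int:
        return sum(1 for _ in self.leaves())

    def __repr__(self) -> str:  # pragma: no cover
        return f"<Phylogeny with {len(self)} tips>"


def _copy_subtree(node: Node) -> Node:
    new = Node(node.label, node.length, node.support)
    for c in node.children:
        new.add_child(_copy_subtree(c))
    return new


# ---------------------------------------------------------------------------
# Newick I/O (parsing via dendropy, writing direct)
# ---------------------------------------------------------------------------

def read_tree(newick_text: str, support_dialect: str = "percent") -> Phylogeny:
    """Parse a Newick string into a :class:`Phylogeny`.

    Support values are taken from internal-node labels when those labels are
    numeric; ``support_dialect`` records whether they live on a 0-100
    (``"percent"``) or 0-1 (``"unit"``) scale.
    """
    try:
        dtree = dendropy.Tree.get(
            data=newick_text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises schema-specific errors
        raise TreeError(f"Newick parse error: {exc}") from exc

    def convert(dnode) -> Node:
        if dnode.is_leaf():
            label = dnode.taxon.label if dnode.taxon else (dnode.label or "")
            n = Node(normalize_label(label), dnode.edge.length)
        else:
            support = None
            raw = dnode.label
            if raw is not None:
                try:
                    support = float(raw)
                except ValueError:
                    support = None
            n = Node(None, dnode.edge.length, support)
        for c in dnode.child_nodes():
            n.add_child(convert(c))
        return n

    root = convert(dtree.seed_node)
    if root.is_leaf:
        raise TreeError("tree has a single tip")
    return Phylogeny(root, support_dialect)


def write_tree(tree: Phylogeny, with_supports: bool = True) -> str:
    """Serialize to Newick; internal supports written as node labels."""

    def fmt(node: Node) -> str:
        if node.is_leaf:
            s = node.label
        else:
            s = "(" + ",".join(fmt(c) for c in node.children) + ")"
            if with_supports and node.support is not None:
                sup = node.support
                s += f"{sup:g}"
        if node.length is not None:
            s += f":{node.length:.12g}"
        return s

    return fmt(tree.root) + ";"


# ---------------------------------------------------------------------------
# Pruning and collapsing
# ---------------------------------------------------------------------------

def _sum_lengths(a: float | None, b: float | None) -> float | None:
    if a is None and b is None:
        return None
    return (a or 0.0) + (b or 0.0)


def prune_to_taxa(tree: Phylogeny, keep: Iterable[str]) -> Phylogeny:
    """Restrict the tree to ``keep``, suppressing unary nodes so that
    patristic distances among the kept tips are unchanged."""
    want = {normalize_label(l) for l in keep}
    have = set(tree.tip_labels)
    unknown = want - have
    if unknown:
        raise TreeError(f"unknown tip labels: {sorted(unknown)}")
    if len(want) < 2:
        raise TreeError("need at least two tips to keep")

    def build(node: Node) -> Node | None:
        if node.is_leaf:
            if node.label in want:
                return Node(node.label, node.length)
            return None
        kids = [k for k in (build(c) for c in node.children) if k is not None]
        if not kids:
            return None
        if len(kids) == 1:
            child = kids[0]
            child.length = _sum_lengths(child.length, node.length)
            return child
        new = Node(None, node.length, node.support)
        for k in kids:
            new.add_child(k)
        return new

    root = build(tree.root)
    assert root is not None
    root.length = None  # root edge carries no information after pruning
    return Phylogeny(root, tree.support_dialect)


def collapse_low_support(tree: Phylogeny, threshold: float) -> Phylogeny:
    """Collapse internal branches with support strictly below ``threshold``
    (interpreted on the tree's support dialect) into polytomies.

    Branches without a support value are never collapsed: absence of evidence
    is not low support. Tips and the root are untouched.
    """
    import warnings

    out = tree.copy()
    internals = [n for n in out.internal_nodes() if n is not out.root]
    if not any(n.support is not None for n in internals):
        warnings.warn("no support values present; nothing collapsed",
                      stacklevel=2)
    # contract bottom-up so child lists stay consistent
    for n in reversed(list(out.preorder())):
        if n.is_leaf or n is out.root:
            continue
        if n.support is not None and n.support < threshold:
            parent = n.parent
            i = parent.children.index(n)
            for c in n.children:
                c.parent = parent
                # collapsed branch length is absorbed into the polytomy
                if c.length is not None and n.length is not None:
                    c.length = c.length + n.length
            parent.children[i:i + 1] = n.children
    return Phylogeny(out.root, out.support_dialect)


# ---------------------------------------------------------------------------
# Sister pairs and speciation-event enumeration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SisterPair:
    """A cherry of two focal tips plus a descriptor of its closest relative.

    ``relative_is_single`` is True when the pair's sister lineage is a single
    tip, in which case the pair-plus-relative node is itself eligible for a
    second-iteration comparison.
    """
    tip_a: str
    tip_b: str
    node_id: str
    relative_is_single: bool
    relative_tips: tuple[str, ...]
    relative_node_id: str | None

    @property
    def tips(self) -> frozenset[str]:
        return frozenset((self.tip_a, self.tip_b))


def sister_pairs(tree: Phylogeny,
                 focal_tips: Iterable[str] | None = None) -> list[SisterPair]:
    """Every cherry (strictly bifurcating 2-tip clade) whose tips are focal.

    Polytomies of three or more tips yield no pair: there is no unambiguous
    cherry to compare. Returned in preorder of the cherry node.
    """
    if focal_tips is None:
        focal = set(tree.tip_labels)
    else:
        focal = {normalize_label(l) for l in focal_tips}
        unknown = focal - set(tree.tip_labels)
        if unknown:
            raise TreeError(f"unknown focal tips: {sorted(unknown)}")
    pairs: list[SisterPair] = []
    for n in tree.preorder():
        if len(n.children) != 2:
            continue
        a, b = n.children
        if not (a.is_leaf and b.is_leaf):
            continue
        if a.label not in focal or b.label not in focal:
            continue
        rel_single = False
        rel_tips: tuple[str, ...] = ()
        rel_node = None
        parent = n.parent
        if parent is not None and len(parent.children) == 2:
            sib = parent.children[0] if parent.children[1] is n else parent.children[1]
            rel_tips = tuple(sorted(tree.leaf_set(sib)))
            rel_node = sib.id
            rel_single = sib.is_leaf
        elif parent is not None:
            others = [c for c in parent.children if c is not n]
            rel_tips = tuple(sorted(set().union(*(tree.leaf_set(c) for c in others))))
        pairs.append(SisterPair(a.label, b.label, n.id, rel_single,
                                rel_tips, rel_node))
    return pairs


@dataclass
class EventNodeSet:
    """Partition of the focal clades' internal nodes into nodes assessable
    for range/precipitation/elevation/substrate transitions (sister-pair
    MRCAs and pair-plus-single-closest-relative MRCAs) and deeper nodes that
    can be evaluated for substrate only."""
    assessable: set[str] = field(default_factory=set)
    substrate_only: set[str] = field(default_factory=set)
    defining_tips: dict[str, frozenset[str]] = field(default_factory=dict)

    def to_frame(self):
        import pandas as pd
        rows = []
        for nid in sorted(self.assessable):
            rows.append((nid, "assessable", "|".join(sorted(self.defining_tips[nid]))))
        for nid in sorted(self.substrate_only):
            rows.append((nid, "substrate_only", "|".join(sorted(self.defining_tips[nid]))))
        return pd.DataFrame(rows, columns=["node", "type", "tips"])


def survey_nodes(tree: Phylogeny,
                 focal_clades: Sequence[Iterable[str]]) -> EventNodeSet:
    """Enumerate speciation-event nodes inside monophyletic focal clades.

    Assessable nodes are the MRCAs of focal sister pairs plus, when a pair's
    closest relative is a single tip, the MRCA of pair and relative. All
    remaining internal nodes of the focal clades can be surveyed for
    substrate transitions only (deeper events). The two sets partition the
    focal internal nodes.
    """
    result = EventNodeSet()
    for clade in focal_clades:
        tips = {normalize_label(l) for l in clade}
        if len(tips) < 2:
            continue  # single-tip lineage: no internal nodes to survey
        m = tree.mrca(tips)
        if tree.leaf_set(m) != frozenset(tips):
            extra = sorted(tree.leaf_set(m) - tips)
            raise TreeError(
                f"focal clade {sorted(tips)[:3]}... is not monophyletic; "
                f"MRCA also contains {extra[:5]}")
        clade_nodes = {n.id for n in tree.internal_nodes(m)}
        assessable: set[str] = set()
        for pair in sister_pairs(tree, tips):
            if pair.node_id in clade_nodes:
                assessable.add(pair.node_id)
            if pair.relative_is_single:
                parent = tree.node(pair.node_id).parent
                if parent is not None and parent.id in clade_nodes:
                    assessable.add(parent.id)
        result.assessable |= assessable
        result.substrate_only |= clade_nodes - assessable
        for nid in clade_nodes:
            result.defining_tips[nid] = tree.leaf_set(tree.node(nid))
    return result
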