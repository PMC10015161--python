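"""Unrooted tree topologies: Newick I/O, canonical forms, enumeration, OTU constraints.

Trees are unrooted at the mathematical level but stored rooted at an
arbitrary trifurcating "display root", matching the conventional printed
style ``(X,Y,OG);``.  Canonical forms make topology identity decidable:
two Newick strings denote the same unrooted topology iff their canonical
forms are equal, regardless of rooting or child order.

Exhaustive enumeration over a label set proceeds by stepwise leaf
addition onto every edge, which generates each unrooted binary topology
exactly once; the count is the double factorial (2k-5)!!.

An :class:`OTUConstraint` partitions the leaf set of a full alignment
into supertaxa (OTUs) with fixed internal subtrees, so that candidate
topologies need only be enumerated over the (few) OTU labels and then
expanded back to full leaf-level trees for likelihood evaluation.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field

import dendropy

__all__ = [
    "TreeError",
    "Node",
    "Tree",
    "parse_newick",
    "canonical_form",
    "enumerate_topologies",
    "expand_constrained",
    "collapse_to_otus",
    "OTUConstraint",
]


class TreeError(ValueError):
    """Raised for malformed Newick input or inconsistent tree operations."""


class Node:
    """A node of a (display-)rooted tree.  Leaves carry a label."""

    __slots__ = ("label", "length", "children")

    def __init__(self, label=None, length=None, children=None):
        self.label = label
        self.length = length
        self.children = children if children is not None else []

    @property
    def is_leaf(self):
        return not self.children

    def copy(self):
        return Node(self.label, self.length,
                    [c.copy() for c in self.children])


class Tree:
    """An unrooted tree held at a display root (trifurcation for binary trees)."""

    def __init__(self, root: Node):
        self.root = root

    # -- basic queries -------------------------------------------------

    def postorder(self):
        out = []
        stack = [self.root]
        while stack:
            v = stack.pop()
            out.append(v)
            stack.extend(v.children)
        out.reverse()
        return out

    def leaves(self):
        return [v for v in self.postorder() if v.is_leaf]

    def leaf_labels(self):
        return [v.label for v in self.leaves()]

    def n_leaves(self):
        return len(self.leaves())

    def copy(self):
        return Tree(self.root.copy())

    def has_lengths(self):
        return all(v.length is not None for v in self.postorder()
                   if v is not self.root)

    # -- serialization -------------------------------------------------

    def to_newick(self, lengths: bool = True) -> str:
        def render(v: Node) -> str:
            if v.is_leaf:
                s = v.label
            else:
                s = "(" + ",".join(render(c) for c in v.children) + ")"
                if v.label:
                    s += v.label
            if lengths and v.length is not None:
                s += f":{v.length:.10g}"
            return s

        return render(self.root) + ";"

    def canonical_form(self) -> str:
        return canonical_form(self)

    def __repr__(self):
        return f"Tree({self.to_newick(lengths=False)!r})"

    # -- rerooting -----------------------------------------------------

    def _adjacency(self):
        """Undirected adjacency: node -> list of (neighbor, edge_length)."""
        adj: dict[int, list] = {}
        nodes: dict[int, Node] = {}

        def add(a, b, ln):
            adj.setdefault(id(a), []).append((id(b), ln))
            adj.setdefault(id(b), []).append((id(a), ln))

        def walk(v):
            nodes[id(v)] = v
            adj.setdefault(id(v), [])
            for c in v.children:
                walk(c)
                add(v, c, c.length)

        walk(self.root)
        return adj, nodes

    def rerooted_adjacent_to_leaf(self, label: str) -> "Tree":
        """Return a copy rerooted at the internal node adjacent to *label*.

        The named leaf becomes a child of the new display root.  On a
        binary unrooted tree the new root is a trifurcation (or the
        original degree-3 node).
        """
        adj, nodes = self._adjacency()
        target = None
        for nid, node in nodes.items():
            if node.is_leaf and node.label == label:
                target = nid
        if target is None:
            raise TreeError(f"no leaf labelled {label!r}")
        nbrs = adj[target]
        if not nbrs:
            raise TreeError("cannot reroot a single-node tree")
        root_id = nbrs[0][0]
        return Tree(_build_rooted(adj, nodes, root_id, None))


def _build_rooted(adj, nodes, nid, parent_id, length=None) -> Node:
    old = nodes[nid]
    node = Node(old.label if old.is_leaf else None, length)
    for cid, ln in adj[nid]:
        if cid != parent_id:
            node.children.append(_build_rooted(adj, nodes, cid, nid, ln))
    return node


# ---------------------------------------------------------------------
# Newick I/O
# ---------------------------------------------------------------------

def parse_newick(text: str, *, rooted: bool = False) -> Tree:
    """Parse a Newick string into a :class:`Tree`.

    With ``rooted=False`` (the default, unrooted semantics) a bifurcating
    top level is collapsed into a trifurcation by merging the root's two
    edges, so that ``((A,B),(C,D));`` and ``((A,B),C,D);`` denote the
    same unrooted topology.  ``rooted=True`` keeps the string's shape
    verbatim (used for fixed within-OTU subtrees).
    """
    if not isinstance(text, str) or not text.strip():
        raise TreeError("empty Newick string")
    try:
        dtree = dendropy.Tree.get(
            data=text, schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy errors carry line/column info
        raise TreeError(f"Newick parse error: {exc}") from None

    def convert(dnode) -> Node:
        if dnode.is_leaf():
            label = dnode.taxon.label if dnode.taxon else dnode.label
            if label is None:
                raise TreeError("unlabelled leaf in Newick string")
            return Node(str(label), dnode.edge.length)
        return Node(None, dnode.edge.length,
                    [convert(c) for c in dnode.child_nodes()])

    root = convert(dtree.seed_node)
    labels = [v.label for v in Tree(root).leaves()]
    if len(set(labels)) != len(labels):
        dup = sorted({x for x in labels if labels.count(x) > 1})
        raise TreeError(f"duplicate leaf labels: {dup}")

    if not rooted and len(root.children) == 2 and len(labels) > 2:
        a, b = root.children
        # merge the two root edges; keep the non-leaf side as the new root
        if a.is_leaf and not b.is_leaf:
            a, b = b, a
        if not a.is_leaf:
            if a.length is not None or b.length is not None:
                b.length = (a.length or 0.0) + (b.length or 0.0)
            a.children.append(b)
            a.length = None
            root = a
    return Tree(root)


def write_newick_list(trees, path, lengths=False):
    with open(path, "w") as fh:
        for t in trees:
            fh.write(t.to_newick(lengths=lengths) + "\n")


def read_newick_list(path) -> list[Tree]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line:
                out.append(parse_newick(line))
    return out


# ---------------------------------------------------------------------
# Canonical form
# ---------------------------------------------------------------------

def canonical_form(tree: Tree) -> str:
    """Rooting- and rotation-invariant topology string.

    The unrooted tree is rerooted at the internal node adjacent to the
    globally smallest leaf label; children are then sorted recursively
    by the smallest leaf label in each subtree.  Branch lengths are
    ignored: canonical forms compare topology identity only.
    """
    labels = tree.leaf_labels()
    if not labels:
        raise TreeError("tree has no leaves")
    if len(labels) <= 2:
        return "(" + ",".join(sorted(labels)) + ");"
    adj, nodes = tree._adjacency()
    smallest = min(labels)
    leaf_id = next(nid for nid, nd in nodes.items()
                   if nd.is_leaf and nd.label == smallest)
    root_id = adj[leaf_id][0][0]

    def canon(nid, parent_id):
        nd = nodes[nid]
        if nd.is_leaf:
            return nd.label, nd.label
        parts = sorted(canon(cid, nid) for cid, _ in adj[nid]
                       if cid != parent_id)
        return parts[0][0], "(" + ",".join(p[1] for p in parts) + ")"

    return canon(root_id, None)[1] + ";"


# ---------------------------------------------------------------------
# Enumeration
# ---------------------------------------------------------------------

def enumerate_topologies(labels) -> list[Tree]:
    """All distinct unrooted binary topologies over *labels*.

    Stepwise addition: the (i+1)-th leaf is attached to every edge of
    every i-leaf topology.  Yields (2k-5)!! trees for k labels, each
    exactly once.  Output order is deterministic (labels sorted, edges
    in insertion order).
    """
    labels = sorted(labels)
    k = len(labels)
    if k != len(set(labels)):
        raise TreeError("duplicate labels")
    if k < 3:
        raise TreeError("need at least 3 labels to enumerate unrooted topologies")

    # integer nodes: 0..k-1 leaves, k.. internal
    first_internal = k
    results = []

    def grow(edges, next_leaf, next_internal):
        if next_leaf == k:
            results.append(edges)
            return
        for i in range(len(edges)):
            u, v = edges[i]
            w = next_internal
            new_edges = edges[:i] + edges[i + 1:] + [(u, w), (w, v), (w, next_leaf)]
            grow(new_edges, next_leaf + 1, next_internal + 1)

    grow([(first_internal, 0), (first_internal, 1), (first_internal, 2)],
         3, first_internal + 1)

    out = []
    for edges in results:
        adj: dict[int, list[int]] = {}
        for u, v in edges:
            adj.setdefault(u, []).append(v)
            adj.setdefault(v, []).append(u)
        root = adj[0][0]  # internal node adjacent to the first label

        def build(nid, parent):
            if nid < k:
                return Node(labels[nid])
            return Node(None, None,
                        [build(c, nid) for c in adj[nid] if c != parent])

        out.append(Tree(build(root, None)))
    return out


# ---------------------------------------------------------------------
# OTU constraints
# ---------------------------------------------------------------------

@dataclass
class OTUConstraint:
    """Partition of leaf labels into OTUs with fixed within-OTU subtrees.

    ``otu_of`` maps every leaf label to its OTU name; ``subtrees`` maps
    every OTU name to a Newick string over exactly that OTU's leaves
    (a bare label for singleton OTUs).
    """

    otu_of: dict[str, str]
    subtrees: dict[str, str]

    def __post_init__(self):
        self.validate()

    def validate(self):
        otus = set(self.otu_of.values())
        if otus != set(self.subtrees):
            raise TreeError(
                f"OTU names mismatch: membership has {sorted(otus)}, "
                f"subtrees have {sorted(self.subtrees)}")
        for otu, nwk in self.subtrees.items():
            members = {l for l, o in self.otu_of.items() if o == otu}
            if not members:
                raise TreeError(f"OTU {otu!r} has no members")
            sub = parse_newick(nwk, rooted=True)
            if set(sub.leaf_labels()) != members:
                raise TreeError(
                    f"subtree of OTU {otu!r} covers {sorted(sub.leaf_labels())}, "
                    f"membership is {sorted(members)}")

    @property
    def otu_names(self) -> list[str]:
        return sorted(set(self.otu_of.values()))

    def to_json(self) -> str:
        return json.dumps({"otu_of": self.otu_of, "subtrees": self.subtrees},
                          indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "OTUConstraint":
        d = json.loads(text)
        return cls(otu_of=dict(d["otu_of"]), subtrees=dict(d["subtrees"]))

    @classmethod
    def read(cls, path) -> "OTUConstraint":
        with open(path) as fh:
            return cls.from_json(fh.read())

    def write(self, path):
        with open(path, "w") as fh:
            fh.write(self.to_json() + "\n")


def expand_constrained(supertree: Tree, constraint: OTUConstraint) -> Tree:
    """Replace each OTU leaf of *supertree* by its fixed within-OTU subtree."""
    sup_labels = set(supertree.leaf_labels())
    otus = set(constraint.subtrees)
    if sup_labels != otus:
        raise TreeError(
            f"supertree leaves {sorted(sup_labels)} != OTU names {sorted(otus)}")

    def graft(v: Node) -> Node:
        if v.is_leaf:
            sub = parse_newick(constraint.subtrees[v.label], rooted=True)
            r = sub.root
            r.length = v.length
            return r
        return Node(None, v.length, [graft(c) for c in v.children])

    return Tree(graft(supertree.root))


def collapse_to_otus(tree: Tree, otu_of: dict[str, str]) -> Tree:
    """Collapse each OTU's (necessarily monophyletic) leaves to one OTU leaf.

    Each OTU is collapsed after rerooting next to a leaf outside it, so
    the result does not depend on where the input tree's display root
    sits relative to the OTU.  Raises if any OTU is not a clade of the
    unrooted tree.
    """
    labels = set(tree.leaf_labels())
    if labels != set(otu_of):
        raise TreeError("leaf set does not match the OTU mapping")
    current = tree.copy()
    otus = sorted(set(otu_of.values()))
    if len(otus) < 2:
        raise TreeError("need at least two OTUs")
    for otu in otus:
        members = {l for l, o in otu_of.items() if o == otu}
        outside = next(l for l in sorted(current.leaf_labels())
                       if l not in members)
        current = current.rerooted_adjacent_to_leaf(outside)
        current = _collapse_one(current, otu, members)
    return current


def _collapse_one(tree: Tree, otu: str, members: set) -> Tree:
    found = []

    def walk(v: Node):
        leafset = set()
        for c in list(v.children):
            leafset |= walk(c)
        if v.is_leaf:
            leafset = {v.label}
        if leafset == members:
            found.append(v)
        return leafset

    walk(tree.root)
    # the smallest node whose leafset equals the OTU is its MRCA
    if not found:
        raise TreeError(f"OTU {otu!r} is not monophyletic in the tree")
    mrca = found[0]
    mrca.children = []
    mrca.label = otu
    return tree


def extract_clade_subtree(tree: Tree, members: set) -> Node:
    """Deep copy of the subtree spanned by *members* (which must be a clade).

    The tree is rerooted next to a leaf outside the clade first, so the
    display root's position does not matter.  The returned node keeps
    its fitted branch lengths; its own ``length`` is the clade's stem.
    """
    members = set(members)
    labels = set(tree.leaf_labels())
    if not members < labels:
        raise TreeError("members must be a proper subset of the leaf set")
    outside = next(l for l in sorted(labels) if l not in members)
    rt = tree.rerooted_adjacent_to_leaf(outside)
    found = []

    def walk(v: Node):
        s = {v.label} if v.is_leaf else set()
        for c in v.children:
            s |= walk(c)
        if s == members:
            found.append(v)
        return s

    walk(rt.root)
    if not found:
        raise TreeError(f"{sorted(members)} is not a clade of the tree")
    return found[0].copy()


def clades_when_rooted_on(tree: Tree, outgroup_leaf: str) -> set[frozenset]:
    """All subtree leaf sets when rooted next to *outgroup_leaf* (outgroup excluded)."""
    rt = tree.rerooted_adjacent_to_leaf(outgroup_leaf)
    clades = set()

    def walk(v: Node) -> frozenset:
        if v.is_leaf:
            s = frozenset([v.label])
        else:
            s = frozenset().union(*(walk(c) for c in v.children))
        if outgroup_leaf not in s:
            clades.add(s)
        return s

    walk(rt.root)
    return clades
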