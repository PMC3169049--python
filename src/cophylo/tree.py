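"""Phylogenetic tree data model and topology operations.

The :class:`PhyloTree` here is the object every other stage exchanges: it is a
node-linked tree with unique leaf labels and optional branch lengths in
expected substitutions per site.  Trees may be rooted (degree-2 root) or
unrooted (stored with a trifurcating root node); all topology comparisons in
this package are *unrooted* — they operate on the set of non-trivial
bipartitions (splits) of the leaf set, so the placement of the root never
affects a Robinson–Foulds distance or a topology-equality check.

Conventions
-----------
* A bipartition is canonicalised as the side of the split that does *not*
  contain the lexicographically smallest leaf label, represented as a
  ``frozenset`` of labels.  Trivial splits (one leaf versus the rest) are
  excluded.
* ``rf_distance`` is the raw symmetric-difference count of bipartition sets
  (the Robinson–Foulds definition); ``rf_distance_normalized`` divides by the
  maximum ``2*(n-3)`` attainable for binary trees.
* ``random_topology`` draws uniformly from the ``(2n-5)!!`` labelled unrooted
  binary topologies by sequential attachment to a uniformly chosen edge.
"""

from __future__ import annotations

import math
from typing import Callable, Dict, FrozenSet, Iterable, Iterator, List, Optional, Sequence, Set, Tuple

import numpy as np

__all__ = [
    "Node",
    "PhyloTree",
    "NewickError",
    "TreeError",
    "HostAssociation",
    "parse_newick",
    "write_newick",
    "bipartition_set",
    "rf_distance",
    "rf_distance_normalized",
    "max_rf_distance",
    "topologies_equal",
    "random_topology",
    "map_and_prune",
    "nni_neighbors",
    "internal_edges",
    "spr_move",
]


class TreeError(ValueError):
    """Raised for structurally invalid tree operations."""


class NewickError(ValueError):
    """Raised when Newick text cannot be parsed."""


class Node:
    """A tree node with parent/child links, a label and a branch length."""

    __slots__ = ("name", "length", "children", "parent")

    def __init__(self, name: Optional[str] = None, length: Optional[float] = None):
        self.name = name
        self.length = length
        self.children: List["Node"] = []
        self.parent: Optional["Node"] = None

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    def remove_child(self, child: "Node") -> None:
        self.children.remove(child)
        child.parent = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def postorder(self) -> Iterator["Node"]:
        stack: List[Tuple[Node, bool]] = [(self, False)]
        while stack:
            node, expanded = stack.pop()
            if expanded:
                yield node
            else:
                stack.append((node, True))
                for ch in reversed(node.children):
                    stack.append((ch, False))

    def leaves(self) -> List["Node"]:
        return [n for n in self.postorder() if n.is_leaf]

    def copy(self) -> "Node":
        new = Node(self.name, self.length)
        for ch in self.children:
            new.add_child(ch.copy())
        return new


class PhyloTree:
    """A rooted or unrooted phylogenetic tree with uniquely labelled leaves.

    Unrooted trees are stored with a trifurcating root; the ``rooted`` flag
    reports whether the root node has exactly two children.
    """

    def __init__(self, root: Node):
        self.root = root
        self._check_labels()

    def _check_labels(self) -> None:
        seen: Set[str] = set()
        for leaf in self.root.leaves():
            if leaf.name is None:
                raise TreeError("unlabelled leaf")
            if leaf.name in seen:
                raise TreeError(f"duplicate leaf label: {leaf.name!r}")
            seen.add(leaf.name)

    # -- basic accessors -------------------------------------------------
    @property
    def rooted(self) -> bool:
        return len(self.root.children) == 2

    def leaves(self) -> List[Node]:
        return self.root.leaves()

    def leaf_names(self) -> FrozenSet[str]:
        return frozenset(leaf.name for leaf in self.leaves())

    @property
    def n_leaves(self) -> int:
        return len(self.leaves())

    def postorder(self) -> Iterator[Node]:
        return self.root.postorder()

    def find_leaf(self, name: str) -> Node:
        for leaf in self.leaves():
            if leaf.name == name:
                return leaf
        raise TreeError(f"leaf not found: {name!r}")

    def copy(self) -> "PhyloTree":
        return PhyloTree(self.root.copy())

    def edges(self) -> List[Node]:
        """Every edge, identified by its child node (root excluded)."""
        return [n for n in self.postorder() if n.parent is not None]

    def has_branch_lengths(self) -> bool:
        return all(n.length is not None for n in self.edges())

    def total_length(self) -> float:
        return sum(n.length or 0.0 for n in self.edges())

    def set_default_lengths(self, default: float = 0.1, only_missing: bool = True) -> None:
        for n in self.edges():
            if n.length is None or not only_missing:
                n.length = default

    def drop_lengths(self) -> None:
        for n in self.postorder():
            n.length = None

    # -- rooting ---------------------------------------------------------
    def is_binary_unrooted(self) -> bool:
        """True if, viewed unrooted, every internal vertex has degree 3."""
        for node in self.postorder():
            degree = len(node.children) + (0 if node.parent is None else 1)
            if node.is_leaf:
                continue
            if node.parent is None:
                if degree not in (2, 3):
                    return False
            elif degree != 3:
                return False
        if self.rooted:
            return True
        return len(self.root.children) == 3 or self.n_leaves <= 3

    def unroot(self) -> "PhyloTree":
        """Return a copy with any degree-2 root collapsed into a trifurcation.

        The two root edges merge into one: the surviving sibling's branch
        absorbs the folded child's length.
        """
        t = self.copy()
        root = t.root
        if len(root.children) == 2:
            a, b = root.children
            fold = a if not a.is_leaf else b
            if fold.is_leaf:  # 2-leaf tree: nothing to collapse
                return t
            other = b if fold is a else a
            root.remove_child(fold)
            for ch in list(fold.children):
                ch.parent = root
                root.children.append(ch)
            fold.children = []
            if fold.length is not None:
                other.length = (other.length or 0.0) + fold.length
        return t

    def rerooted_at(self, leaf_name: str) -> "PhyloTree":
        """Reroot (copy) so the named leaf's parent becomes the root."""
        t = self.copy()
        leaf = t.find_leaf(leaf_name)
        if leaf.parent is None:
            return t
        _reroot_at_node(t, leaf.parent)
        return t

    def __str__(self) -> str:
        return write_newick(self)

    def __repr__(self) -> str:
        return f"<PhyloTree n_leaves={self.n_leaves} rooted={self.rooted}>"


def _reroot_at_node(tree: PhyloTree, new_root: Node) -> None:
    """Reverse parent links so ``new_root`` becomes the root (in place).

    Branch lengths travel with the edge: after rerooting, the length on a
    child records the same physical edge as before.
    """
    if new_root is tree.root:
        return
    path: List[Node] = []
    node: Optional[Node] = new_root
    while node is not None:
        path.append(node)
        node = node.parent
    # path = [new_root, ..., old_root]; flip each edge along it
    orig_length = [n.length for n in path]
    for child, parent in zip(path[:-1], path[1:]):
        parent.children.remove(child)
    for i, (child, parent) in enumerate(zip(path[:-1], path[1:])):
        child.children.append(parent)
        parent.parent = child
        parent.length = orig_length[i]
    new_root.parent = None
    new_root.length = None
    old_root = path[-1]
    # suppress an old degree-2 root left behind
    if len(old_root.children) == 1 and old_root.parent is not None:
        only = old_root.children[0]
        grand = old_root.parent
        grand.children[grand.children.index(old_root)] = only
        only.parent = grand
        if old_root.length is not None and only.length is not None:
            only.length += old_root.length
        elif old_root.length is not None:
            only.length = old_root.length
        old_root.children = []
        old_root.parent = None
    tree.root = new_root


# ---------------------------------------------------------------------------
# Newick I/O
# ---------------------------------------------------------------------------

def _tokenize_newick(text: str) -> Iterator[str]:
    i, n = 0, len(text)
    while i < n:
        c = text[i]
        if c.isspace():
            i += 1
        elif c == "[":  # bracket comment (e.g. MrBayes [&U]); skipped
            j = text.find("]", i)
            if j < 0:
                raise NewickError("unterminated [comment]")
            i = j + 1
        elif c in "(),:;":
            yield c
            i += 1
        elif c == "'":
            j = i + 1
            chunks: List[str] = []
            while True:
                if j >= n:
                    raise NewickError("unterminated quoted label")
                if text[j] == "'":
                    if j + 1 < n and text[j + 1] == "'":
                        chunks.append("'")
                        j += 2
                        continue
                    break
                chunks.append(text[j])
                j += 1
            yield "Q" + "".join(chunks)  # marker: quoted token
            i = j + 1
        else:
            j = i
            while j < n and text[j] not in "(),:;'" and not text[j].isspace():
                j += 1
            yield "T" + text[i:j]  # marker: bare token
            i = j


def parse_newick(text: str) -> PhyloTree:
    """Parse a Newick string into a :class:`PhyloTree`.

    Supports branch lengths after ``:``, internal-node labels (kept verbatim,
    conventionally support values), and single-quoted labels with ``''``
    escapes.  Raises :class:`NewickError` on unbalanced parentheses or
    duplicate leaf labels, naming the offending token.
    """
    tokens = list(_tokenize_newick(text))
    if not tokens:
        raise NewickError("empty Newick string")
    pos = 0

    def peek() -> Optional[str]:
        return tokens[pos] if pos < len(tokens) else None

    def take() -> str:
        nonlocal pos
        tok = tokens[pos]
        pos += 1
        return tok

    def parse_clade() -> Node:
        nonlocal pos
        node = Node()
        tok = peek()
        if tok == "(":
            take()
            node.add_child(parse_clade())
            while peek() == ",":
                take()
                node.add_child(parse_clade())
            if peek() != ")":
                raise NewickError("unbalanced parentheses: expected ')'")
            take()
            tok = peek()
            if tok is not None and tok[0] in "QT":
                node.name = take()[1:]
        elif tok is not None and tok[0] in "QT":
            node.name = take()[1:]
        else:
            raise NewickError(f"unexpected token {tok!r}")
        if peek() == ":":
            take()
            tok = peek()
            if tok is None or tok[0] != "T":
                raise NewickError("expected branch length after ':'")
            raw = take()[1:]
            try:
                node.length = float(raw)
            except ValueError as exc:
                raise NewickError(f"invalid branch length {raw!r}") from exc
            if node.length < 0:
                raise NewickError(f"negative branch length {raw!r}")
        return node

    root = parse_clade()
    if peek() == ";":
        take()
    if pos != len(tokens):
        raise NewickError(f"trailing content after tree: {tokens[pos]!r}")
    return PhyloTree(root)


def _needs_quoting(name: str) -> bool:
    return any(c in "(),:;'[] \t\n" for c in name)


def _format_label(name: str) -> str:
    if _needs_quoting(name):
        return "'" + name.replace("'", "''") + "'"
    return name


def write_newick(tree: PhyloTree, precision: int = 10) -> str:
    """Serialise a tree to Newick; lengths kept to ``precision`` sig. digits."""

    def fmt(node: Node) -> str:
        if node.is_leaf:
            s = _format_label(node.name or "")
        else:
            s = "(" + ",".join(fmt(ch) for ch in node.children) + ")"
            if node.name:
                s += _format_label(node.name)
        if node.length is not None:
            s += f":{node.length:.{precision}g}"
        return s

    return fmt(tree.root) + ";"


# ---------------------------------------------------------------------------
# Bipartitions and Robinson–Foulds distance
# ---------------------------------------------------------------------------

def bipartition_set(tree: PhyloTree) -> FrozenSet[FrozenSet[str]]:
    """Canonical non-trivial bipartitions induced by the tree's internal edges.

    Each split is represented by the side *not* containing the smallest leaf
    label; trivial (singleton/complement) splits are excluded, so a binary
    unrooted ``n``-leaf tree yields exactly ``n - 3`` bipartitions.  The result
    does not depend on where the tree is rooted.
    """
    all_leaves = tree.leaf_names()
    n = len(all_leaves)
    if n < 4:
        return frozenset()
    ref = min(all_leaves)
    below: Dict[int, FrozenSet[str]] = {}
    splits: Set[FrozenSet[str]] = set()
    for node in tree.postorder():
        if node.is_leaf:
            below[id(node)] = frozenset((node.name,))
        else:
            side = frozenset().union(*(below[id(ch)] for ch in node.children))
            below[id(node)] = side
            if node.parent is None:
                continue
            if len(side) < 2 or len(side) > n - 2:
                continue
            splits.add(side if ref not in side else all_leaves - side)
    return frozenset(splits)


def _require_same_leaves(t1: PhyloTree, t2: PhyloTree) -> None:
    l1, l2 = t1.leaf_names(), t2.leaf_names()
    if l1 != l2:
        only1 = sorted(l1 - l2)
        only2 = sorted(l2 - l1)
        raise TreeError(
            f"leaf sets differ: only in first = {only1}, only in second = {only2}"
        )


def rf_distance(t1: PhyloTree, t2: PhyloTree) -> int:
    """Robinson–Foulds distance: |S1 symmetric-difference S2| over bipartitions."""
    _require_same_leaves(t1, t2)
    return len(bipartition_set(t1) ^ bipartition_set(t2))


def max_rf_distance(n_leaves: int) -> int:
    """Maximum RF distance between two binary unrooted trees on n leaves."""
    return max(0, 2 * (n_leaves - 3))


def rf_distance_normalized(t1: PhyloTree, t2: PhyloTree) -> float:
    """RF distance divided by the binary-tree maximum 2(n-3)."""
    denom = max_rf_distance(t1.n_leaves)
    if denom == 0:
        return 0.0
    return rf_distance(t1, t2) / denom


def topologies_equal(t1: PhyloTree, t2: PhyloTree) -> bool:
    """True iff the unrooted topologies agree (branch lengths ignored)."""
    _require_same_leaves(t1, t2)
    return bipartition_set(t1) == bipartition_set(t2)


# ---------------------------------------------------------------------------
# Random topologies
# ---------------------------------------------------------------------------

def n_unrooted_topologies(n: int) -> int:
    """(2n-5)!! — the number of labelled unrooted binary topologies."""
    out = 1
    for k in range(3, 2 * n - 4, 2):
        out *= k
    return out


def random_topology(taxa: Iterable[str], rng: np.random.Generator) -> PhyloTree:
    """Uniform draw from the labelled unrooted binary topologies on ``taxa``.

    Sequential construction: start from the 3-taxon star and attach each
    further taxon to an edge chosen uniformly at random, which yields the
    uniform distribution over the ``(2n-5)!!`` topologies.  No branch lengths
    are assigned.
    """
    labels_list = list(taxa)
    labels = sorted(set(labels_list))
    if len(labels) != len(labels_list):
        raise TreeError("duplicate taxon labels")
    if len(labels) < 3:
        raise TreeError(f"need at least 3 taxa, got {len(labels)}")
    root = Node()
    for name in labels[:3]:
        root.add_child(Node(name))
    edges: List[Node] = list(root.children)
    for name in labels[3:]:
        target = edges[int(rng.integers(len(edges)))]
        parent = target.parent
        mid = Node()
        parent.children[parent.children.index(target)] = mid
        mid.parent = parent
        mid.add_child(target)
        leaf = mid.add_child(Node(name))
        edges.append(mid)
        edges.append(leaf)
    return PhyloTree(root)


def enumerate_topologies(taxa: Sequence[str]) -> List[PhyloTree]:
    """All labelled unrooted binary topologies on ``taxa`` (small n only)."""
    labels = sorted(set(taxa))
    if len(labels) < 3:
        raise TreeError("need at least 3 taxa")

    def build(tree_root: Node, remaining: Sequence[str]) -> List[Node]:
        if not remaining:
            return [tree_root.copy()]
        name, rest = remaining[0], remaining[1:]
        out: List[Node] = []
        edges = [n for n in tree_root.postorder() if n.parent is not None]
        for k in range(len(edges)):
            work = tree_root.copy()
            wedges = [n for n in work.postorder() if n.parent is not None]
            target = wedges[k]
            parent = target.parent
            mid = Node()
            parent.children[parent.children.index(target)] = mid
            mid.parent = parent
            mid.add_child(target)
            mid.add_child(Node(name))
            out.extend(build(work, rest))
        return out

    base = Node()
    for name in labels[:3]:
        base.add_child(Node(name))
    return [PhyloTree(r) for r in build(base, labels[3:])]


# ---------------------------------------------------------------------------
# Host association, pruning and relabelling
# ---------------------------------------------------------------------------

class HostAssociation:
    """An injective mapping from virus taxon names to host taxon names."""

    def __init__(self, mapping: Dict[str, str]):
        hosts = list(mapping.values())
        if len(set(hosts)) != len(hosts):
            dupes = sorted({h for h in hosts if hosts.count(h) > 1})
            raise TreeError(f"association not injective; repeated hosts: {dupes}")
        self.mapping = dict(mapping)

    def __len__(self) -> int:
        return len(self.mapping)

    def __contains__(self, virus_taxon: str) -> bool:
        return virus_taxon in self.mapping

    def host_of(self, virus_taxon: str) -> str:
        return self.mapping[virus_taxon]

    @property
    def virus_taxa(self) -> FrozenSet[str]:
        return frozenset(self.mapping)

    @property
    def host_taxa(self) -> FrozenSet[str]:
        return frozenset(self.mapping.values())

    def items(self):
        return self.mapping.items()


def _prune_leaves(tree: PhyloTree, drop: Set[str]) -> None:
    """Remove named leaves in place, suppressing unifurcations."""
    for name in sorted(drop):
        leaf = tree.find_leaf(name)
        parent = leaf.parent
        if parent is None:
            raise TreeError("cannot prune the only node")
        parent.remove_child(leaf)
        # walk up suppressing degree-1 internal nodes
        node = parent
        while node is not None and not node.is_leaf and len(node.children) == 1:
            only = node.children[0]
            if node.parent is None:
                only.parent = None
                only.length = None
                tree.root = only
                node = None
            else:
                grand = node.parent
                grand.children[grand.children.index(node)] = only
                only.parent = grand
                if node.length is not None and only.length is not None:
                    only.length += node.length
                elif node.length is not None:
                    only.length = node.length
                node = grand if len(grand.children) == 1 else None


def map_and_prune(virus_tree: PhyloTree, assoc: HostAssociation) -> PhyloTree:
    """Restrict a virus tree to the mapped taxa and relabel them with hosts.

    Leaves absent from the association (outgroups) are pruned with degree-2
    suppression; the remaining leaves are renamed to their host taxa and
    branch lengths dropped, leaving a topology directly comparable to the
    host tree.
    """
    tree = virus_tree.copy()
    names = tree.leaf_names()
    missing = sorted(assoc.virus_taxa - names)
    if missing:
        raise TreeError(f"mapped virus taxa absent from tree: {missing}")
    _prune_leaves(tree, set(names - assoc.virus_taxa))
    for leaf in tree.leaves():
        leaf.name = assoc.host_of(leaf.name)
    tree.drop_lengths()
    # refresh label-uniqueness check after relabelling
    return PhyloTree(tree.root)


# ---------------------------------------------------------------------------
# Topology rearrangements: NNI and SPR
# ---------------------------------------------------------------------------

def internal_edges(tree: PhyloTree) -> List[Tuple[str, ...]]:
    """Internal edges of the unrooted topology, each identified by the leaf
    set on its child side (a stable identifier across rerooting/copying)."""
    out: List[Tuple[str, ...]] = []
    all_leaves = tree.leaf_names()
    n = len(all_leaves)
    below: Dict[int, Set[str]] = {}
    for node in tree.postorder():
        if node.is_leaf:
            below[id(node)] = {node.name}
        else:
            side = set().union(*(below[id(ch)] for ch in node.children))
            below[id(node)] = side
            if node.parent is not None and 2 <= len(side) <= n - 2:
                out.append(tuple(sorted(side)))
    # dedupe complements (a rooted tree's two root edges are one unrooted edge)
    seen: Set[FrozenSet[str]] = set()
    ref = min(all_leaves)
    uniq: List[Tuple[str, ...]] = []
    for side in out:
        canon = frozenset(side) if ref not in side else frozenset(all_leaves - set(side))
        if canon not in seen:
            seen.add(canon)
            uniq.append(side)
    return uniq


def _find_edge_node(tree: PhyloTree, edge: Tuple[str, ...]) -> Node:
    """Locate the node whose below-leafset equals ``edge`` (or its complement)."""
    want = frozenset(edge)
    comp = tree.leaf_names() - want
    below: Dict[int, FrozenSet[str]] = {}
    for node in tree.postorder():
        if node.is_leaf:
            below[id(node)] = frozenset((node.name,))
        else:
            below[id(node)] = frozenset().union(*(below[id(ch)] for ch in node.children))
        if node.parent is not None and below[id(node)] in (want, comp):
            return node
    raise TreeError(f"edge not found in tree: {edge}")


def nni_neighbors(tree: PhyloTree, edge: Tuple[str, ...]) -> List[PhyloTree]:
    """The two nearest-neighbour-interchange topologies across an internal edge.

    ``edge`` identifies the internal edge by the leaf set on one side.  Each
    neighbour differs from the input by RF distance 2.  Terminal edges raise
    :class:`TreeError`.
    """
    work = tree.unroot() if tree.rooted else tree.copy()
    child = _find_edge_node(work, edge)
    if child.is_leaf or child.parent is None:
        raise TreeError(f"not an internal edge: {edge}")
    _reroot_at_node(work, child.parent)
    u = work.root
    v = None
    want = frozenset(edge)
    comp = work.leaf_names() - want
    for ch in u.children:
        side = frozenset(l.name for l in ch.leaves())
        if side in (want, comp) and not ch.is_leaf:
            v = ch
            break
    if v is None or v.is_leaf:
        raise TreeError(f"not an internal edge: {edge}")
    others = [c for c in u.children if c is not v]
    a = others[0]
    out: List[PhyloTree] = []
    for c in list(v.children):
        t2 = work.copy()
        # relocate a and c in the copy by position
        u2 = t2.root
        v2 = u2.children[u.children.index(v)]
        a2 = u2.children[u.children.index(a)]
        c2 = v2.children[v.children.index(c)]
        u2.children[u2.children.index(a2)] = c2
        v2.children[v2.children.index(c2)] = a2
        a2.parent, c2.parent = v2, u2
        out.append(PhyloTree(t2.root))
    return out


def spr_move(
    tree: PhyloTree,
    rng: np.random.Generator,
    require_change: bool = True,
    max_tries: int = 200,
) -> PhyloTree:
    """One random subtree-prune-and-regraft move (used to emulate a host switch).

    A non-root subtree is pruned (its former sibling edge absorbs the freed
    length) and regrafted onto an edge chosen uniformly among the edges
    outside the pruned clade; the insertion point bisects that edge.  With
    ``require_change`` the draw is repeated until the unrooted topology
    actually changes.
    """
    if tree.n_leaves < 4:
        raise TreeError("SPR needs at least 4 leaves")
    for _ in range(max_tries):
        work = tree.copy()
        edges = work.edges()
        # candidate prune points: any edge whose removal leaves >= 3 leaves outside
        cands = [e for e in edges if work.n_leaves - len(e.leaves()) >= 3]
        sub = cands[int(rng.integers(len(cands)))]
        parent = sub.parent
        parent.remove_child(sub)
        # suppress the degree-2 node left at the attachment
        if len(parent.children) == 1:
            only = parent.children[0]
            if parent.parent is None:
                only.parent = None
                work.root = only
                only.length = None
            else:
                grand = parent.parent
                grand.children[grand.children.index(parent)] = only
                only.parent = grand
                if parent.length is not None and only.length is not None:
                    only.length += parent.length
                elif parent.length is not None:
                    only.length = parent.length
        rest = PhyloTree(work.root)
        regraft_edges = rest.edges()
        target = regraft_edges[int(rng.integers(len(regraft_edges)))]
        tparent = target.parent
        mid = Node()
        if target.length is not None:
            mid.length = target.length / 2.0
            target.length = target.length / 2.0
        tparent.children[tparent.children.index(target)] = mid
        mid.parent = tparent
        mid.add_child(target)
        mid.add_child(sub)
        result = PhyloTree(work.root)
        if not require_change or not topologies_equal(
            _topology_only(result), _topology_only(tree)
        ):
            return result
    raise TreeError("could not find a topology-changing SPR move")


def _topology_only(tree: PhyloTree) -> PhyloTree:
    t = tree.copy()
    t.drop_lengths()
    return t
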