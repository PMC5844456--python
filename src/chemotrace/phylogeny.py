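"""Rooted trees with polytomies, Newick I/O, and character binding.

Newick parsing is delegated to dendropy; the parsed topology is converted
into a minimal node structure that the parsimony engine traverses.  Branch
lengths are read but discarded: all downstream inference is parsimony.
Polytomies are kept as hard multifurcations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterator, Mapping

import dendropy
import yaml

from .chemo_matrix import MISSING, CharacterMatrix
from .errors import BindingError, TreeFormatError

__all__ = [
    "Node",
    "PhyloTree",
    "read_tree",
    "write_tree",
    "load_composite_tree",
    "load_manifest",
    "bind",
    "BoundCharacters",
]

_DATA = resources.files("chemotrace.data")


class Node:
    """One tree node; ``index`` is the stable preorder index."""

    __slots__ = ("label", "children", "parent", "index")

    def __init__(self, label: str | None = None):
        self.label = label
        self.children: list[Node] = []
        self.parent: Node | None = None
        self.index: int = -1

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def add(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    def __repr__(self) -> str:  # pragma: no cover
        kind = "leaf" if self.is_leaf else f"{len(self.children)}-furcation"
        return f"<Node {self.label or '(unnamed)'} {kind}>"


class PhyloTree:
    """A rooted, normalized tree: one root, unique leaf labels, no unary nodes."""

    def __init__(self, root: Node):
        self.root = root
        self.normalize()

    # -- construction -------------------------------------------------------

    @classmethod
    def from_dendropy(cls, tree: dendropy.Tree) -> "PhyloTree":
        def convert(dnode: dendropy.Node) -> Node:
            label = None
            if dnode.taxon is not None:
                label = dnode.taxon.label
            elif dnode.label:
                label = dnode.label
            node = Node(label)
            for child in dnode.child_nodes():
                node.add(convert(child))
            return node

        return cls(convert(tree.seed_node))

    def normalize(self) -> None:
        """Suppress unary nodes, reindex in preorder, validate labels."""

        def suppress(node: Node) -> Node:
            while len(node.children) == 1:
                child = node.children[0]
                child.label = node.label or child.label
                node = child
            node.children = [suppress(c) for c in node.children]
            for c in node.children:
                c.parent = node
            return node

        self.root = suppress(self.root)
        self.root.parent = None
        self._nodes: list[Node] = []
        for i, node in enumerate(self._preorder(self.root)):
            node.index = i
            self._nodes.append(node)
        labels = [n.label for n in self.leaves()]
        if any(lbl is None or lbl == "" for lbl in labels):
            raise TreeFormatError("every leaf must be labelled")
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        if dupes:
            raise TreeFormatError(f"duplicate leaf labels: {dupes}")

    # -- traversal ----------------------------------------------------------

    @staticmethod
    def _preorder(node: Node) -> Iterator[Node]:
        stack = [node]
        while stack:
            n = stack.pop()
            yield n
            stack.extend(reversed(n.children))

    def preorder(self) -> Iterator[Node]:
        return iter(self._nodes)

    def postorder(self) -> Iterator[Node]:
        out: list[Node] = []

        def walk(n: Node) -> None:
            for c in n.children:
                walk(c)
            out.append(n)

        walk(self.root)
        return iter(out)

    def leaves(self) -> list[Node]:
        return [n for n in self._nodes if n.is_leaf]

    @property
    def n_leaves(self) -> int:
        return len(self.leaves())

    @property
    def nodes(self) -> list[Node]:
        return list(self._nodes)

    def find(self, label: str) -> Node:
        """Locate a node (internal clade label or leaf) by its label."""
        for n in self._nodes:
            if n.label == label:
                return n
        raise KeyError(f"no node labelled {label!r}")

    def leaf_set(self, label: str) -> frozenset[str]:
        node = self.find(label)
        return frozenset(
            n.label for n in self._preorder(node) if n.is_leaf  # type: ignore[misc]
        )

    def polytomies(self) -> dict[int, int]:
        """Map node index -> out-degree for every multifurcating node."""
        return {n.index: len(n.children) for n in self._nodes if len(n.children) > 2}

    # -- output -------------------------------------------------------------

    def newick(self, annotations: Mapping[int, str] | None = None) -> str:
        """Serialize to Newick; *annotations* adds ``[&state=...]`` comments."""

        def fmt(node: Node) -> str:
            note = ""
            if annotations and node.index in annotations:
                note = f"[&state={annotations[node.index]}]"
            if node.is_leaf:
                return f"{node.label}{note}"
            inner = ",".join(fmt(c) for c in node.children)
            return f"({inner}){node.label or ''}{note}"

        return fmt(self.root) + ";"

    def __repr__(self) -> str:  # pragma: no cover
        return f"<PhyloTree {self.n_leaves} leaves, root={self.root.label!r}>"


def read_tree(source: str | Path) -> PhyloTree:
    """Read a rooted Newick tree from a path or a literal Newick string."""
    source = str(source)
    if source.lstrip().startswith("("):
        kwargs = {"data": source}
    else:
        path = Path(source)
        if not path.exists():
            raise TreeFormatError(f"no such tree file: {source}")
        kwargs = {"path": str(path)}
    try:
        tree = dendropy.Tree.get(
            schema="newick",
            preserve_underscores=True,
            rooting="force-rooted",
            **kwargs,
        )
    except Exception as exc:  # dendropy raises schema-specific subclasses
        raise TreeFormatError(f"newick parse error: {exc}") from exc
    return PhyloTree.from_dendropy(tree)


def write_tree(tree: PhyloTree, path: str | Path) -> None:
    Path(path).write_text(tree.newick() + "\n")


def load_composite_tree() -> PhyloTree:
    """The packaged composite harvestman phylogeny."""
    return read_tree((_DATA / "composite_tree.nwk").read_text())


def load_manifest() -> dict:
    """The checked-in manifest describing the composite tree fixture."""
    return yaml.safe_load((_DATA / "composite_manifest.yaml").read_text())


# ---------------------------------------------------------------------------
# binding characters to trees


@dataclass
class BoundCharacters:
    """A tree plus, per character, a complete leaf -> state assignment."""

    tree: PhyloTree
    characters: dict[str, dict[str, str]]
    unmatched_taxa: list[str] = field(default_factory=list)
    dataless_leaves: list[str] = field(default_factory=list)

    def states(self, character: str) -> dict[str, str]:
        from .errors import CharacterLookupError

        if character not in self.characters:
            raise CharacterLookupError(character)
        return self.characters[character]

    @property
    def character_names(self) -> list[str]:
        return list(self.characters)


def bind(
    tree: PhyloTree,
    chars: CharacterMatrix,
    on_unmatched: str = "code_missing",
) -> BoundCharacters:
    """Attach a character matrix to a tree's leaves.

    ``on_unmatched`` controls reconciliation: ``error`` rejects any
    mismatch in either direction, ``prune_tree`` drops dataless leaves,
    ``code_missing`` (default) codes dataless leaves as missing.  Matrix
    taxa absent from the tree are always reported in ``unmatched_taxa``.
    """
    if on_unmatched not in ("error", "prune_tree", "code_missing"):
        raise BindingError(f"unknown policy {on_unmatched!r}")
    leaf_labels = {n.label for n in tree.leaves()}
    taxa = set(chars.taxa)
    if not leaf_labels & taxa:
        raise BindingError("tree leaves and matrix taxa do not intersect")
    extra_taxa = sorted(taxa - leaf_labels)
    dataless = sorted(leaf_labels - taxa)
    if on_unmatched == "error":
        if extra_taxa:
            raise BindingError(f"matrix taxa not in tree: {extra_taxa}")
        if dataless:
            raise BindingError(f"tree leaves without data: {dataless}")
    if on_unmatched == "prune_tree" and dataless:
        tree = _prune(tree, keep=leaf_labels & taxa)
        dataless = []
    characters: dict[str, dict[str, str]] = {}
    for char in chars.characters:
        col = chars.column(char)
        characters[char] = {
            leaf.label: col.get(leaf.label, MISSING) for leaf in tree.leaves()
        }
    return BoundCharacters(tree, characters, extra_taxa, dataless)


def _prune(tree: PhyloTree, keep: set[str]) -> PhyloTree:
    def rebuild(node: Node) -> Node | None:
        if node.is_leaf:
            return Node(node.label) if node.label in keep else None
        kept = [rebuild(c) for c in node.children]
        kept = [c for c in kept if c is not None]
        if not kept:
            return None
        new = Node(node.label)
        for c in kept:
            new.add(c)
        return new

    root = rebuild(tree.root)
    if root is None:
        raise BindingError("pruning removed every leaf")
    return PhyloTree(root)
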