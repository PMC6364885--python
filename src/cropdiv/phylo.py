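"""Crop phylogeny handling: parsing, pruning, node-age dating, distances.

The tree is rooted, tips are species, and ages are in millions of years
(My) with tips at age 0. Branch lengths are derived from ages:
``length(child) = age(parent) - age(child)``. Undated internal nodes get
ages by even interpolation between the nearest dated ancestor and a dated
descendant (the branch-length-adjustment scheme used by the standard
community-phylogenetics toolchain, "ages file" dialect included).

Pruning keeps degree-2 pass-through nodes so age calibrations attached to
internal labels survive; branch lengths through them sum identically, so
diversity metrics are unaffected.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import dendropy
import numpy as np

from cropdiv.errors import (
    CalibrationError,
    UndatedTreeError,
    UnknownTaxaError,
    ValidationError,
)

__all__ = ["AgeTable", "DatedTree", "TreeIndex", "read_ages"]


class AgeTable(dict):
    """Internal-node label -> age (My). Root label must be present for dating."""

    def __init__(self, entries: Mapping[str, float]):
        super().__init__()
        for label, age in entries.items():
            age = float(age)
            if age <= 0:
                raise ValidationError(f"age for {label!r} must be > 0 (got {age})")
            self[str(label).strip()] = age

    @classmethod
    def read(cls, path) -> "AgeTable":
        return cls(read_ages(path))


def read_ages(path) -> dict[str, float]:
    """Read whitespace-delimited 'node-label age' lines (ages-file dialect)."""
    entries: dict[str, float] = {}
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ValidationError(f"malformed ages line: {line!r}")
            label, age = parts
            if label in entries:
                raise ValidationError(f"duplicate age entry for {label!r}")
            entries[label] = float(age)
    return entries


def _node_label(node: dendropy.Node) -> str | None:
    if node.taxon is not None and node.taxon.label:
        return node.taxon.label
    return node.label


class DatedTree:
    """Rooted phylogeny, optionally with node ages (My, tips at 0).

    Thin wrapper around a :class:`dendropy.Tree`; node ages live on
    ``node.age`` once :meth:`bladj_date` (or a fully-specified age table)
    has run, and branch lengths are then derivable as age differences.
    """

    def __init__(self, tree: dendropy.Tree, dated: bool = False):
        self._tree = tree
        self._dated = dated
        labels = [t.taxon.label for t in tree.leaf_node_iter()]
        if len(set(labels)) != len(labels):
            raise ValidationError("duplicate tip labels")

    # -- construction --------------------------------------------------

    @classmethod
    def read_newick(cls, source) -> "DatedTree":
        """Read newick from a path or a literal newick string (undated)."""
        text = str(source)
        if text.lstrip().startswith("("):
            tree = dendropy.Tree.get(
                data=text, schema="newick", suppress_internal_node_taxa=True
            )
        else:
            tree = dendropy.Tree.get(
                path=text, schema="newick", suppress_internal_node_taxa=True
            )
        return cls(tree, dated=False)

    def write_newick(self, path=None) -> str | None:
        """Write newick (with branch lengths when dated); return string if no path."""
        tree = self._tree
        if self._dated:
            for node in tree.preorder_node_iter():
                if node.parent_node is not None:
                    node.edge.length = node.parent_node.age - node.age
        text = tree.as_string(
            schema="newick", suppress_rooting=True,
            suppress_edge_lengths=not self._dated,
        )
        if path is None:
            return text
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(text)
        return None

    def clone(self) -> "DatedTree":
        out = DatedTree(self._tree.clone(depth=1), dated=self._dated)
        if self._dated:
            for src, dst in zip(
                self._tree.preorder_node_iter(), out._tree.preorder_node_iter()
            ):
                dst.age = src.age
        return out

    # -- introspection -------------------------------------------------

    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._tree

    @property
    def is_dated(self) -> bool:
        return self._dated

    @property
    def tip_labels(self) -> tuple[str, ...]:
        return tuple(sorted(t.taxon.label for t in self._tree.leaf_node_iter()))

    @property
    def n_tips(self) -> int:
        return sum(1 for _ in self._tree.leaf_node_iter())

    @property
    def internal_labels(self) -> tuple[str, ...]:
        out = []
        for node in self._tree.preorder_internal_node_iter():
            label = _node_label(node)
            if label:
                out.append(label)
        return tuple(out)

    def ages(self) -> dict[str, float]:
        """Label -> age for every labeled node (tips at 0); requires dating."""
        self._require_dated()
        out = {}
        for node in self._tree.preorder_node_iter():
            label = _node_label(node)
            if label:
                out[label] = node.age
        return out

    def _require_dated(self) -> None:
        if not self._dated:
            raise UndatedTreeError("tree must be dated first")

    def _tip_map(self) -> dict[str, dendropy.Node]:
        return {t.taxon.label: t for t in self._tree.leaf_node_iter()}

    # -- operations ----------------------------------------------------

    def prune_to_taxa(self, taxa: Iterable[str]) -> "DatedTree":
        """Minimal subtree spanning *taxa* and the original root.

        Degree-2 pass-through nodes are retained (with labels and ages) so
        that calibration entries attached to them survive pruning.
        """
        taxa = set(taxa)
        if not taxa:
            raise ValidationError("cannot prune to an empty taxon set")
        tips = self._tip_map()
        unknown = taxa - set(tips)
        if unknown:
            raise UnknownTaxaError(unknown)
        keep: set[int] = set()
        for label in taxa:
            node = tips[label]
            while node is not None and id(node) not in keep:
                keep.add(id(node))
                node = node.parent_node
        clone = self._tree.clone(depth=1)
        if self._dated:
            for src, dst in zip(
                self._tree.preorder_node_iter(), clone.preorder_node_iter()
            ):
                dst.age = src.age
        # parallel preorder gives matching ids via position
        src_nodes = list(self._tree.preorder_node_iter())
        dst_nodes = list(clone.preorder_node_iter())
        keep_dst = {
            id(d) for s, d in zip(src_nodes, dst_nodes) if id(s) in keep
        }
        for node in list(clone.postorder_node_iter()):
            if id(node) in keep_dst or node.parent_node is None:
                continue
            node.parent_node.remove_child(node)
        out = DatedTree(clone, dated=self._dated)
        return out

    def bladj_date(self, ages: Mapping[str, float]) -> "DatedTree":
        """Return a dated copy: fixed ages from *ages*, the rest interpolated.

        Each undated internal node is placed evenly along the path from its
        nearest dated ancestor A to the dated descendant D (dated internal
        node or tip, age 0) reachable through undated nodes only whose path
        holds the most undated nodes (ties: lexicographically smallest
        endpoint label). The k-th of m undated nodes on A->D gets
        ``age = t_A - k*(t_A - t_D)/(m+1)``.
        """
        ages = {str(k).strip(): float(v) for k, v in ages.items()}
        clone = self._tree.clone(depth=1)
        root = clone.seed_node
        root_label = _node_label(root)
        if root_label not in ages:
            raise CalibrationError("root must have a calibration age")

        fixed: dict[int, float] = {}
        for node in clone.preorder_node_iter():
            if node.is_leaf():
                fixed[id(node)] = 0.0
            else:
                label = _node_label(node)
                if label is not None and label in ages:
                    fixed[id(node)] = ages[label]
        # calibration consistency: aged node older than every aged descendant
        for node in clone.preorder_node_iter():
            if id(node) not in fixed or node.is_leaf():
                continue
            for desc in node.preorder_iter():
                if desc is node or desc.is_leaf():
                    continue
                if id(desc) in fixed and fixed[id(desc)] >= fixed[id(node)]:
                    raise CalibrationError(
                        f"node {_node_label(node)!r} (age {fixed[id(node)]}) is not "
                        f"older than descendant {_node_label(desc)!r} "
                        f"(age {fixed[id(desc)]})"
                    )

        def dated_endpoints(start: dendropy.Node):
            """Dated endpoints below *start* reachable through undated nodes.

            Yields (extra, t_D): undated nodes strictly between *start* and
            the endpoint, and the endpoint's fixed age.
            """
            stack = [(start, 0)]
            while stack:
                node, extra = stack.pop()
                for child in node.child_nodes():
                    if id(child) in fixed:
                        yield extra, fixed[id(child)]
                    else:
                        stack.append((child, extra + 1))

        # Sequential top-down even interpolation: each undated node is placed
        # between its parent's (already final) age and every dated endpoint
        # below it, splitting each path evenly; the oldest candidate wins, so
        # ages strictly decrease and every fixed descendant stays younger.
        # On a chain between two dated nodes this reduces to plain even
        # spacing of the intervening nodes.
        for node in clone.preorder_node_iter():
            if id(node) in fixed:
                node.age = fixed[id(node)]
                continue
            t_p = node.parent_node.age
            node.age = max(
                t_p - (t_p - t_d) / (extra + 2)
                for extra, t_d in dated_endpoints(node)
            )

        # admissibility: strictly decreasing root-to-tip (interior edges)
        for node in clone.preorder_node_iter():
            if node.parent_node is None:
                continue
            if node.parent_node.age <= node.age and not (
                node.is_leaf() and node.age == 0 and node.parent_node.age > 0
            ):
                raise CalibrationError(
                    f"interpolated ages not strictly decreasing at "
                    f"{_node_label(node) or '<unlabeled>'}"
                )
        return DatedTree(clone, dated=True)

    def total_branch_length(self, taxa: Iterable[str] | None = None) -> float:
        """Branch-length sum (My) of the minimal root-spanning subtree of *taxa*.

        With ``taxa=None``, the whole-tree branch sum.
        """
        self._require_dated()
        tips = self._tip_map()
        if taxa is None:
            taxa_set = set(tips)
        else:
            taxa_set = set(taxa)
            unknown = taxa_set - set(tips)
            if unknown:
                raise UnknownTaxaError(unknown)
            if not taxa_set:
                raise ValidationError("taxon set must be non-empty")
        visited: set[int] = set()
        total = 0.0
        for label in taxa_set:
            node = tips[label]
            while node.parent_node is not None and id(node) not in visited:
                visited.add(id(node))
                total += node.parent_node.age - node.age
                node = node.parent_node
        return total

    def patristic_distance(self, a: str, b: str) -> float:
        """Branch-length path distance between tips (2 x MRCA age for aged tips)."""
        self._require_dated()
        tips = self._tip_map()
        unknown = {t for t in (a, b) if t not in tips}
        if unknown:
            raise UnknownTaxaError(unknown)
        if a == b:
            return 0.0
        anc_a = []
        node = tips[a]
        while node is not None:
            anc_a.append(id(node))
            node = node.parent_node
        anc_a_set = set(anc_a)
        node = tips[b]
        while id(node) not in anc_a_set:
            node = node.parent_node
        mrca_age = node.age
        return 2.0 * mrca_age - tips[a].age - tips[b].age


@dataclass(frozen=True)
class TreeIndex:
    """Vectorized view of a dated tree for fast PD / distance queries.

    ``path[i, e]`` is True when edge ``e`` lies on tip i's root path;
    PD of a tip subset is the length-sum of the union of their paths.
    """

    labels: tuple[str, ...]
    edge_lengths: np.ndarray  # (n_edges,)
    path: np.ndarray  # bool (n_tips, n_edges)
    distances: np.ndarray  # (n_tips, n_tips) patristic

    @classmethod
    def from_tree(cls, tree: DatedTree) -> "TreeIndex":
        tree._require_dated()
        dtree = tree.dendropy_tree
        edges = []
        edge_index: dict[int, int] = {}
        for node in dtree.preorder_node_iter():
            if node.parent_node is not None:
                edge_index[id(node)] = len(edges)
                edges.append(node.parent_node.age - node.age)
        tips = sorted(dtree.leaf_node_iter(), key=lambda t: t.taxon.label)
        labels = tuple(t.taxon.label for t in tips)
        path = np.zeros((len(tips), len(edges)), dtype=bool)
        for i, tip in enumerate(tips):
            node = tip
            while node.parent_node is not None:
                path[i, edge_index[id(node)]] = True
                node = node.parent_node
        lengths = np.asarray(edges, dtype=float)
        depth = path @ lengths  # root-to-tip path length per tip
        shared = (path.astype(float) * lengths) @ path.T.astype(float)
        dist = depth[:, None] + depth[None, :] - 2.0 * shared
        np.fill_diagonal(dist, 0.0)
        return cls(labels, lengths, path, dist)

    @property
    def index_of(self) -> dict[str, int]:
        return {label: i for i, label in enumerate(self.labels)}

    def pd(self, tip_indices: np.ndarray) -> float:
        """Faith's PD (root path included) of the given tip rows."""
        mask = self.path[tip_indices].any(axis=0)
        return float(self.edge_lengths[mask].sum())
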