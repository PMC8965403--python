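"""Constrained data-free tree pseudo-posteriors.

A classification taxonomy (Glottolog-style, Newick with polytomies) fixes
which groupings are certain; everything unresolved inside it is uncertain.
``sample_trees`` turns the taxonomy into a sample of fully resolved binary
ultrametric trees in which

* every taxonomy grouping is monophyletic in every tree (frequency 1), and
* each polytomy is resolved independently per tree, uniformly over labeled
  histories (coalescent-style sequential pair joining), so e.g. each of the
  three resolutions of a trichotomy appears with probability 1/3.

This reproduces the two topological properties a data-free MCMC posterior
has — constraints at posterior probability 1, uniform uncertainty elsewhere —
directly and exactly.  Branch lengths come from a simple pure-birth-style
height model and are rescaled so the root height is 1; rates estimated
downstream are therefore expressed per total tree depth.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
import numpy as np

__all__ = [
    "Taxonomy",
    "TreePosterior",
    "read_taxonomy",
    "taxonomy_from_table",
    "sample_trees",
    "clade_frequency",
    "clade_frequencies",
    "write_trees",
    "read_trees",
]

_ULTRAMETRIC_TOL = 1e-9


@dataclass(frozen=True)
class Taxonomy:
    """Rooted classification with polytomies; every internal node is a
    monophyly constraint."""

    tree: dendropy.Tree

    def __post_init__(self) -> None:
        labels = self.tip_labels
        if len(labels) != len(set(labels)):
            dups = sorted({l for l in labels if labels.count(l) > 1})
            raise ValueError(f"duplicate taxa in taxonomy: {dups}")
        if len(labels) < 2:
            raise ValueError("taxonomy must contain at least 2 tips")

    @property
    def tip_labels(self) -> list[str]:
        return [lf.taxon.label for lf in self.tree.leaf_node_iter()]

    def constraints(self) -> list[frozenset[str]]:
        """Tip sets of all internal nodes (each is enforced monophyletic)."""
        out = []
        for nd in self.tree.preorder_node_iter():
            if not nd.is_leaf():
                out.append(frozenset(lf.taxon.label for lf in nd.leaf_iter()))
        return out


@dataclass
class TreePosterior:
    """An ordered sample of fully resolved binary ultrametric trees."""

    trees: list[dendropy.Tree]
    seed: int | None = None

    def __post_init__(self) -> None:
        tipsets = {frozenset(lf.taxon.label for lf in t.leaf_node_iter()) for t in self.trees}
        if len(tipsets) > 1:
            raise ValueError("trees in a posterior must share an identical tip set")

    def __len__(self) -> int:
        return len(self.trees)

    def __iter__(self):
        return iter(self.trees)

    def __getitem__(self, i):
        return self.trees[i]


def read_taxonomy(source: str | Path) -> Taxonomy:
    """Read a taxonomy from a Newick file (polytomies allowed)."""
    try:
        tree = dendropy.Tree.get(path=str(source), schema="newick", preserve_underscores=True)
    except dendropy.utility.error.DataParseError as e:
        raise ValueError(f"invalid taxonomy in {source}: {e}") from e
    return Taxonomy(tree)


def taxonomy_from_string(newick: str) -> Taxonomy:
    try:
        tree = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
    except dendropy.utility.error.DataParseError as e:
        raise ValueError(f"invalid taxonomy: {e}") from e
    return Taxonomy(tree)


def taxonomy_from_table(pairs: Iterable[tuple[str, str]]) -> Taxonomy:
    """Build a taxonomy from (parent, child) classification rows.

    Children with no row of their own are tips; exactly one name must never
    appear as a child (the root).
    """
    pairs = list(pairs)
    children: dict[str, list[str]] = {}
    child_names = set()
    for parent, child in pairs:
        children.setdefault(parent, []).append(child)
        if child in child_names:
            raise ValueError(f"node {child!r} has two parents")
        child_names.add(child)
    roots = set(children) - child_names
    if len(roots) != 1:
        raise ValueError(f"classification must have exactly one root, got {sorted(roots)}")
    (root_name,) = roots

    def newick(name: str) -> str:
        if name not in children:
            return name
        return "(" + ",".join(newick(c) for c in children[name]) + ")" + name

    return taxonomy_from_string(newick(root_name) + ";")


def _resolve_node(
    nd: dendropy.Node, rng: np.random.Generator, branch_model: str
) -> tuple[str, float]:
    """Recursively resolve a taxonomy node; returns (newick fragment, height).

    Polytomies are resolved by sequential uniform pair joining: while more
    than one lineage remains, a uniformly random pair is merged.  On k free
    lineages this draws uniformly from the labeled histories, giving each
    pairing of a trichotomy probability 1/3.  Join heights increase with an
    exponential (yule) or uniform (uniform-order) increment above the highest
    lineage merged so far.
    """
    if nd.is_leaf():
        return nd.taxon.label, 0.0
    lineages = [_resolve_node(c, rng, branch_model) for c in nd.child_nodes()]
    while len(lineages) > 1:
        i, j = rng.choice(len(lineages), size=2, replace=False)
        (s_i, h_i), (s_j, h_j) = lineages[i], lineages[j]
        base = max(h_i, h_j)
        if branch_model == "yule":
            h = base + rng.exponential(1.0)
        elif branch_model == "uniform-order":
            h = base + rng.uniform(0.0, 1.0)
        else:
            raise ValueError(f"unknown branch model {branch_model!r}")
        frag = f"({s_i}:{h - h_i!r},{s_j}:{h - h_j!r})"
        keep = [lineages[k] for k in range(len(lineages)) if k not in (i, j)]
        keep.append((frag, h))
        lineages = keep
    return lineages[0]


def sample_trees(
    taxonomy: Taxonomy,
    n: int,
    seed: int = 0,
    branch_model: str = "yule",
) -> TreePosterior:
    """Sample ``n`` resolved binary ultrametric trees honouring the taxonomy.

    Each tree uses an independent generator derived from ``seed`` (master
    seed + tree index), so any prefix of the sample is reproducible.  Node
    heights are rescaled tree by tree so the root height is exactly 1.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    trees: list[dendropy.Tree] = []
    namespace = dendropy.TaxonNamespace()
    for k in range(n):
        rng = np.random.default_rng(seed + k)
        frag, height = _resolve_node(taxonomy.tree.seed_node, rng, branch_model)
        tree = dendropy.Tree.get(
            data=frag + ";", schema="newick", taxon_namespace=namespace,
            preserve_underscores=True,
        )
        if height <= 0:
            raise ValueError("degenerate taxonomy: root height is zero")
        for edge in tree.preorder_edge_iter():
            if edge.length is not None:
                edge.length = edge.length / height
        trees.append(tree)
    return TreePosterior(trees, seed=seed)


def _clades(tree: dendropy.Tree) -> set[frozenset[str]]:
    out: set[frozenset[str]] = set()
    below: dict[int, frozenset[str]] = {}
    for nd in tree.postorder_node_iter():
        if nd.is_leaf():
            below[id(nd)] = frozenset((nd.taxon.label,))
        else:
            s = frozenset().union(*(below[id(c)] for c in nd.child_nodes()))
            below[id(nd)] = s
            out.add(s)
    return out


def clade_frequency(posterior: TreePosterior, tipset: Iterable[str]) -> float:
    """Fraction of trees in which ``tipset`` is exactly the tip set of a clade."""
    want = frozenset(tipset)
    if len(want) < 2:
        raise ValueError("tipset must contain at least 2 taxa")
    all_tips = {lf.taxon.label for lf in posterior[0].leaf_node_iter()}
    unknown = sorted(want - all_tips)
    if unknown:
        raise ValueError(f"unknown taxa in tipset: {unknown}")
    hits = sum(1 for t in posterior if want in _clades(t))
    return hits / len(posterior)


def clade_frequencies(
    posterior: TreePosterior, tipsets: Sequence[Iterable[str]]
) -> list[float]:
    """Clade frequencies for many tip sets in one pass over the sample."""
    wants = [frozenset(ts) for ts in tipsets]
    hits = np.zeros(len(wants))
    for t in posterior:
        clades = _clades(t)
        for i, w in enumerate(wants):
            if w in clades:
                hits[i] += 1
    return list(hits / len(posterior))


def check_ultrametric(tree: dendropy.Tree, tol: float = _ULTRAMETRIC_TOL) -> bool:
    depths = []
    depth: dict[int, float] = {id(tree.seed_node): 0.0}
    for nd in tree.preorder_node_iter():
        if nd.parent_node is not None:
            depth[id(nd)] = depth[id(nd.parent_node)] + (nd.edge.length or 0.0)
        if nd.is_leaf():
            depths.append(depth[id(nd)])
    return max(depths) - min(depths) <= tol


def write_trees(posterior: TreePosterior, path: str | Path, schema: str = "nexus") -> None:
    """Write the sample as a NEXUS tree block or one Newick per line."""
    if schema not in ("nexus", "newick"):
        raise ValueError(f"unknown schema {schema!r}")
    tl = dendropy.TreeList(posterior.trees, taxon_namespace=posterior[0].taxon_namespace)
    tl.write(path=str(path), schema=schema, suppress_rooting=True)


def read_trees(path: str | Path, schema: str | None = None) -> TreePosterior:
    """Read a tree sample back; schema inferred from the extension if omitted."""
    if schema is None:
        schema = "nexus" if str(path).lower().endswith((".nex", ".nexus", ".trees")) else "newick"
    tl = dendropy.TreeList.get(path=str(path), schema=schema, preserve_underscores=True)
    if not len(tl):
        raise ValueError(f"no trees found in {path}")
    return TreePosterior(list(tl))
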