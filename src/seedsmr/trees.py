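"""Phylogeny container and Newick I/O.

Trees are rooted, branch-length-bearing phylogenies over the study species.
Branch lengths are interpreted as divergence times in Myr throughout; no unit
conversion is attempted.  Ultrametricity (equal root-to-tip distances) is
checkable but not required, since empirical time trees are often only
approximately ultrametric after rounding.
"""

from __future__ import annotations

import dendropy

__all__ = [
    "Phylogeny",
    "NewickError",
    "TreeValidationError",
    "read_newick",
    "resolve_polytomies",
]


class NewickError(ValueError):
    """Raised when a Newick source cannot be parsed."""


class TreeValidationError(ValueError):
    """Raised when a parsed tree violates the Phylogeny invariants."""


class Phylogeny:
    """A rooted tree with branch lengths, validated for downstream analysis.

    Wraps a :class:`dendropy.Tree`.  Invariants enforced at construction:

    * every tip carries a unique label;
    * every non-root edge has a branch length, and all lengths are >= 0.

    ``taxa`` fixes the tip order used by every matrix-valued quantity derived
    from the tree (leaf order of the underlying tree).
    """

    def __init__(self, tree: dendropy.Tree):
        self.tree = tree
        errors: list[str] = []
        labels: list[str] = []
        for leaf in tree.leaf_node_iter():
            if leaf.taxon is None or not leaf.taxon.label:
                errors.append("unlabelled tip encountered")
            else:
                labels.append(leaf.taxon.label)
        dupes = {l for l in labels if labels.count(l) > 1}
        if dupes:
            errors.append(f"duplicate tip labels: {sorted(dupes)}")
        for node in tree.preorder_node_iter():
            if node.parent_node is None:
                continue  # root edge length is optional, treated as 0
            if node.edge.length is None:
                child = _describe_node(node)
                errors.append(f"missing branch length on edge above {child}")
            elif node.edge.length < 0:
                child = _describe_node(node)
                errors.append(f"negative branch length ({node.edge.length}) above {child}")
        if errors:
            raise TreeValidationError("; ".join(errors))
        self.taxa: list[str] = labels

    # -- construction ------------------------------------------------------

    @classmethod
    def from_newick(cls, source: str, *, is_path: bool = False) -> "Phylogeny":
        """Parse a Newick string (or file when ``is_path``) into a Phylogeny."""
        try:
            if is_path:
                tree = dendropy.Tree.get(
                    path=source, schema="newick", preserve_underscores=True
                )
            else:
                tree = dendropy.Tree.get(
                    data=source, schema="newick", preserve_underscores=True
                )
        except Exception as exc:  # dendropy raises several parse error types
            if "Duplicate" in type(exc).__name__:
                raise TreeValidationError(f"duplicate tip labels: {exc}") from exc
            raise NewickError(f"could not parse Newick input: {exc}") from exc
        return cls(tree)

    # -- serialization -----------------------------------------------------

    def to_newick(self) -> str:
        return self.tree.as_string(
            schema="newick",
            suppress_rooting=True,
            unquoted_underscores=True,
        ).strip() + "\n"

    def write_newick(self, path: str) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(self.to_newick())

    # -- geometry ----------------------------------------------------------

    @property
    def n_tips(self) -> int:
        return len(self.taxa)

    def tip_depths(self) -> dict[str, float]:
        """Root-to-tip path length for every tip, in branch-length units."""
        depths: dict[str, float] = {}
        for node in self.tree.preorder_node_iter():
            parent = node.parent_node
            d = 0.0 if parent is None else parent._ssmr_depth + (node.edge.length or 0.0)
            node._ssmr_depth = d
            if node.is_leaf():
                depths[node.taxon.label] = d
        return depths

    def height(self) -> float:
        """Maximum root-to-tip distance (tree height, Myr)."""
        return max(self.tip_depths().values())

    def is_ultrametric(self, tol: float = 1e-6) -> bool:
        depths = list(self.tip_depths().values())
        return max(depths) - min(depths) <= tol * max(max(depths), 1.0)

    def is_binary(self) -> bool:
        return all(
            len(n.child_nodes()) == 2
            for n in self.tree.preorder_internal_node_iter()
        )

    def copy(self) -> "Phylogeny":
        return Phylogeny(self.tree.clone(depth=1))

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"Phylogeny(n_tips={self.n_tips}, height={self.height():.3f})"


def _describe_node(node: dendropy.Node) -> str:
    if node.is_leaf() and node.taxon is not None:
        return f"tip '{node.taxon.label}'"
    tips = [l.taxon.label for l in node.leaf_iter() if l.taxon is not None][:3]
    return f"clade ({', '.join(tips)}{', ...' if len(tips) == 3 else ''})"


def read_newick(path: str) -> Phylogeny:
    """Read a Newick tree file into a validated :class:`Phylogeny`."""
    return Phylogeny.from_newick(path, is_path=True)


def resolve_polytomies(phylogeny: Phylogeny, offset_myr: float = 1.0) -> Phylogeny:
    """Resolve multifurcations into bifurcations with small time offsets.

    Each polytomy with k children is replaced by a left-to-right ladder
    (((c1,c2),c3),...,ck): children are grouped in their input order and the
    successive new divergence times are offset by ``offset_myr`` each, the
    deepest new node lying (k-2)*offset below the original node.  Child branch
    lengths are shortened accordingly so that tip depths are preserved (exactly
    when the shortened branches remain non-negative; they are floored at 0
    otherwise).  Binary trees are returned unchanged (as a copy).
    """
    if offset_myr <= 0:
        raise ValueError("offset_myr must be > 0")
    phy = phylogeny.copy()
    tree = phy.tree
    for node in list(tree.preorder_node_iter()):
        children = node.child_nodes()
        k = len(children)
        if k <= 2:
            continue
        for c in children:
            node.remove_child(c)
        # innermost pair sits deepest: (k-2) offsets below the original node
        cur = dendropy.Node()
        cur.edge.length = offset_myr
        for c in children[:2]:
            c.edge.length = max((c.edge.length or 0.0) - (k - 2) * offset_myr, 0.0)
            cur.add_child(c)
        for m, c in enumerate(children[2:-1], start=2):
            reduction = (k - 1 - m) * offset_myr
            c.edge.length = max((c.edge.length or 0.0) - reduction, 0.0)
            nxt = dendropy.Node()
            nxt.edge.length = offset_myr
            nxt.add_child(cur)
            nxt.add_child(c)
            cur = nxt
        node.add_child(cur)
        node.add_child(children[-1])
    return Phylogeny(tree)
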