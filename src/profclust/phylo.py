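"""Tree handling: newick parsing, midpoint rooting, candidate clade
enumeration.

Trees are scikit-bio :class:`~skbio.TreeNode` objects; this module adds the
validation and the deterministic clade ordering the training walk needs. A
*candidate clade* is an internal node together with all its descendant
leaves; candidates are consumed in descending size order with ties broken by
post-order position, so runs are reproducible regardless of how the input
newick happens to order children.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import FrozenSet, List, Sequence

import numpy as np
from skbio import TreeNode


class NewickParseError(ValueError):
    pass


def _check_parens(text: str) -> None:
    depth = 0
    for offset, ch in enumerate(text):
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise NewickParseError(
                    f"unbalanced ')' at character offset {offset}"
                )
    if depth != 0:
        raise NewickParseError(
            f"unclosed '(' — {depth} still open at end of input "
            f"(offset {len(text)})"
        )


def parse_newick(text: str) -> TreeNode:
    """Parse a newick string into a rooted tree.

    Absent branch lengths default to 0. Duplicate or empty leaf labels are
    a validation error; malformed newick raises
    :class:`NewickParseError` with a character offset where determinable.
    """
    _check_parens(text)
    try:
        tree = TreeNode.read(
            io.StringIO(text), format="newick", convert_underscores=False
        )
    except Exception as exc:
        raise NewickParseError(f"malformed newick: {exc}") from exc
    seen = set()
    for tip in tree.tips():
        if tip.name is None or not str(tip.name).strip():
            raise NewickParseError("tree contains an unnamed leaf")
        tip.name = str(tip.name).strip()
        if tip.name in seen:
            raise NewickParseError(f"duplicate leaf label {tip.name!r}")
        seen.add(tip.name)
    for node in tree.traverse(include_self=False):
        if node.length is None:
            node.length = 0.0
        elif node.length < 0:
            raise NewickParseError(
                f"negative branch length {node.length} above "
                f"{'leaf ' + node.name if node.is_tip() else 'an internal node'}"
            )
    if tree.length is None:
        tree.length = 0.0
    return tree


def to_newick(tree: TreeNode) -> str:
    buf = io.StringIO()
    tree.write(buf, format="newick")
    return buf.getvalue()


def midpoint_root(tree: TreeNode) -> TreeNode:
    """Re-root at the midpoint of the longest leaf-to-leaf path.

    Total path lengths are preserved. All-zero branch lengths leave the
    midpoint undefined and raise ``ValueError`` (supply a rooted tree
    instead).
    """
    tips = list(tree.tips())
    if len(tips) < 2:
        raise ValueError("midpoint rooting needs >= 2 leaves")
    total = sum(n.length or 0.0 for n in tree.traverse(include_self=False))
    if total <= 0:
        raise ValueError(
            "midpoint undefined: all branch lengths are zero; "
            "provide a rooted tree"
        )
    if len(tips) == 2:
        # place the root on the single path between the two leaves
        a, b = tips
        total = a.distance(b)
        half = total / 2.0
        return parse_newick(f"({a.name}:{half},{b.name}:{total - half});")
    rooted = tree.root_at_midpoint()
    for node in rooted.traverse(include_self=True):
        if node.length is None:
            node.length = 0.0
    return rooted


@dataclass(frozen=True)
class Clade:
    """A monophyletic candidate: an internal node plus its descendant
    leaves."""

    leaf_ids: FrozenSet[str]
    postorder_index: int

    @property
    def size(self) -> int:
        return len(self.leaf_ids)

    def __repr__(self) -> str:  # compact, deterministic
        ids = ",".join(sorted(self.leaf_ids)[:4])
        more = "..." if self.size > 4 else ""
        return f"Clade(size={self.size}, leaves=[{ids}{more}])"


def enumerate_candidate_clades(tree: TreeNode, min_size: int = 2) -> List[Clade]:
    """List candidate clades, largest first.

    One clade per internal node (multifurcations allowed) with at least
    ``min_size`` descendant leaves; ties in size break by post-order
    position, making the walk order a pure function of topology.
    """
    if min_size < 2:
        raise ValueError("min_size must be >= 2")
    clades = []
    for idx, node in enumerate(tree.postorder(include_self=True)):
        if node.is_tip():
            continue
        leaves = frozenset(t.name for t in node.tips())
        if len(leaves) >= min_size:
            clades.append(Clade(leaf_ids=leaves, postorder_index=idx))
    clades.sort(key=lambda c: (-c.size, c.postorder_index))
    return clades


def clade_membership_mask(clade: Clade, universe: Sequence[str]) -> np.ndarray:
    """Boolean mask over ``universe`` marking clade members."""
    index = {u: k for k, u in enumerate(universe)}
    mask = np.zeros(len(universe), dtype=bool)
    for leaf in clade.leaf_ids:
        if leaf not in index:
            raise ValueError(f"clade member {leaf!r} not in universe")
        mask[index[leaf]] = True
    return mask


def check_leaf_labels(tree: TreeNode, ids: Sequence[str]) -> None:
    """Hard check: tree leaf labels must equal the sequence id set."""
    leaves = {t.name for t in tree.tips()}
    ids = set(ids)
    missing = sorted(leaves - ids)
    extra = sorted(ids - leaves)
    if missing or extra:
        raise ValueError(
            "tree leaves and sequence ids differ; "
            f"in tree only: {missing[:10]}; in sequences only: {extra[:10]}"
        )
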