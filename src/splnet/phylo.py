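"""Neighbor-joining phylogeny with bootstrap supports.

Distances are protein p-distances with pairwise gap deletion (a Poisson
correction is available); trees are built with the Saitou-Nei
neighbor-joining algorithm (scikit-bio's implementation behind this
module's surface) and negative branch lengths are clamped to zero with a
warning.  Bootstrap supports are percentages of column-resampled replicate
trees containing the same leaf bipartition, written as internal node labels
in Newick output.
"""

from __future__ import annotations

import io
import math
import warnings
from typing import Dict, FrozenSet, Optional, Sequence, Tuple

import numpy as np
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj

from .errors import ValidationError

GAP_CHARS = frozenset("-.")


def _alignment_arrays(alignment: Sequence[Tuple[str, str]]):
    ids = [name for name, _ in alignment]
    rows = [row.upper() for _, row in alignment]
    if len(rows) < 3:
        raise ValidationError("alignment needs at least 3 rows")
    lengths = {len(r) for r in rows}
    if len(lengths) != 1:
        raise ValidationError("ragged alignment: unequal row lengths")
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate taxon ids in alignment")
    matrix = np.array([list(r) for r in rows])
    return ids, matrix


def p_distance_matrix(
    alignment: Sequence[Tuple[str, str]],
    poisson_correction: bool = False,
) -> DistanceMatrix:
    """Pairwise p-distances with pairwise deletion of gap columns.

    ``alignment`` is a list of (taxon id, aligned row).  d[i][j] is the
    fraction of differing columns among columns where neither row has a gap;
    with ``poisson_correction`` it becomes -ln(1 - p).
    """
    ids, matrix = _alignment_arrays(alignment)
    n = len(ids)
    gaps = np.isin(matrix, list(GAP_CHARS))
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            usable = ~(gaps[i] | gaps[j])
            total = int(usable.sum())
            if total == 0:
                raise ValidationError(
                    f"no comparable columns between {ids[i]!r} and {ids[j]!r}"
                )
            p = float((matrix[i, usable] != matrix[j, usable]).sum()) / total
            if poisson_correction:
                if p >= 1.0:
                    raise ValidationError(
                        f"p-distance 1.0 between {ids[i]!r} and {ids[j]!r}: "
                        "Poisson correction undefined"
                    )
                p = -math.log(1.0 - p)
            d[i, j] = d[j, i] = p
    return DistanceMatrix(d, ids)


def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Saitou-Nei NJ tree; negative branch lengths are clamped to zero."""
    if len(dm.ids) < 3:
        raise ValidationError("neighbor joining needs at least 3 taxa")
    tree = nj(dm)
    clamped = 0
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            if node.length < -1e-12:
                clamped += 1
            node.length = 0.0
    if clamped:
        warnings.warn(
            f"clamped {clamped} negative NJ branch lengths to 0",
            stacklevel=2,
        )
    return tree


def leaf_distances(tree: TreeNode) -> Dict[Tuple[str, str], float]:
    """Path-length distances between all leaf pairs."""
    leaves = [t.name for t in tree.tips()]
    out = {}
    for i, a in enumerate(leaves):
        for b in leaves[i + 1:]:
            d = tree.find(a).distance(tree.find(b))
            out[(a, b)] = out[(b, a)] = float(d)
    return out


def _canonical_bipartition(side: FrozenSet[str],
                           taxa: FrozenSet[str]) -> FrozenSet[str]:
    other = taxa - side
    a, b = sorted((side, other), key=lambda s: (len(s), tuple(sorted(s))))
    return a


def bipartitions(tree: TreeNode) -> set:
    """Canonical non-trivial leaf bipartitions of an (unrooted) tree."""
    taxa = frozenset(t.name for t in tree.tips())
    out = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if 2 <= len(side) <= len(taxa) - 2:
            out.add(_canonical_bipartition(side, taxa))
    return out


def bootstrap_supports(
    alignment: Sequence[Tuple[str, str]],
    n_reps: int = 1000,
    seed: Optional[int] = None,
    poisson_correction: bool = False,
) -> TreeNode:
    """NJ tree with bootstrap supports on internal edges.

    Columns are resampled with replacement ``n_reps`` times; an internal
    edge's support is the percentage of replicate trees containing the same
    leaf bipartition.  Supports are stored as ``node.support`` (float in
    [0, 100]) and as internal node names so Newick output carries them.
    """
    if n_reps < 1:
        raise ValidationError("n_reps must be >= 1")
    ids, matrix = _alignment_arrays(alignment)
    taxa = frozenset(ids)
    tree = neighbor_joining(p_distance_matrix(alignment, poisson_correction))
    rng = np.random.default_rng(seed)
    n_cols = matrix.shape[1]
    counts: Dict[FrozenSet[str], int] = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for _ in range(n_reps):
            cols = rng.integers(0, n_cols, size=n_cols)
            rep_alignment = [
                (name, "".join(row)) for name, row in
                zip(ids, matrix[:, cols])
            ]
            try:
                rep_tree = neighbor_joining(
                    p_distance_matrix(rep_alignment, poisson_correction))
            except ValidationError:
                continue  # replicate with no comparable columns for a pair
            for bp in bipartitions(rep_tree):
                counts[bp] = counts.get(bp, 0) + 1
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if 2 <= len(side) <= len(taxa) - 2:
            key = _canonical_bipartition(side, taxa)
            support = 100.0 * counts.get(key, 0) / n_reps
            node.support = support
            node.name = f"{support:.0f}"
    return tree


def annotate_mre_class(tree: TreeNode, flags: Dict[str, bool]) -> TreeNode:
    """Attach the miR156-MRE presence flag to each leaf (``mre_class``)."""
    for tip in tree.tips():
        tip.mre_class = bool(flags.get(tip.name, False))
    return tree


def write_newick(tree: TreeNode, path_or_handle) -> None:
    tree.write(path_or_handle, format="newick")


def read_newick(source) -> TreeNode:
    """Parse Newick text (path, handle, or string); internal labels become
    ``support`` attributes when numeric."""
    if isinstance(source, str) and source.lstrip().startswith("("):
        source = io.StringIO(source)
    try:
        tree = TreeNode.read(source, format="newick")
    except Exception as exc:  # skbio raises NewickFormatError with position
        raise ValidationError(f"malformed Newick: {exc}") from exc
    for node in tree.non_tips(include_self=True):
        if node.name is not None:
            try:
                node.support = float(node.name)
            except ValueError:
                pass
    return tree


def supports_table(tree: TreeNode):
    """TSV-ready DataFrame of internal-edge bipartitions and supports."""
    import pandas as pd

    rows = []
    for node in tree.non_tips(include_self=False):
        side = sorted(t.name for t in node.tips())
        rows.append({
            "clade": ",".join(side),
            "support": getattr(node, "support", math.nan),
            "branch_length": node.length,
        })
    return pd.DataFrame(rows, columns=["clade", "support", "branch_length"])
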