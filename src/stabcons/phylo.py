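"""Kimura-corrected protein distances, neighbor joining and node profiles.

The pairwise distance between two aligned protein sequences is the observed
mismatch fraction p (over columns ungapped in both) corrected for multiple
substitutions, d = -ln(1 - p - p^2/5).  Neighbor joining over these
distances yields an unrooted tree whose internal nodes define clades; the
per-node conservation profile of an alignment position is the amino-acid
frequency vector over a node's leaf descendants.  Positions whose disjoint
clades strongly prefer different amino acids are *tree-determinant*: their
conservation tracks phylogeny rather than a single global optimum.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import skbio
from skbio.tree import nj as _skbio_nj

from .msa import GAP_CHARS, WeightedMSA

__all__ = [
    "DistanceMatrix",
    "NodeProfile",
    "kimura_distance",
    "kimura_distance_matrix",
    "neighbor_joining",
    "node_conservation_profile",
    "is_tree_determinant",
    "write_phylip",
    "read_phylip",
]


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distances (substitutions/site) over sequence ids."""

    ids: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.ids), len(self.ids)):
            raise ValueError("matrix shape does not match id count")
        if not np.allclose(m, m.T):
            raise ValueError("distance matrix is not symmetric")
        if not np.isfinite(m).all():
            raise ValueError("non-finite distances")
        if (np.diag(m) != 0).any():
            raise ValueError("nonzero diagonal")
        self.matrix = m

    def get(self, a: str, b: str) -> float:
        return float(self.matrix[self.ids.index(a), self.ids.index(b)])

    def submatrix(self, ids: list[str]) -> "DistanceMatrix":
        pos = [self.ids.index(i) for i in ids]
        return DistanceMatrix(list(ids), self.matrix[np.ix_(pos, pos)])


@dataclass
class NodeProfile:
    """Amino-acid composition of one alignment column over a clade."""

    node_id: str
    position: int
    frequencies: dict[str, float]
    preferred_aa: str
    n_leaves: int
    leaf_ids: frozenset = field(default_factory=frozenset, repr=False)


#: distance assigned to saturated pairs in "cap" mode (ClustalW convention)
SATURATION_CAP = 10.0


def kimura_distance(seq_a: str, seq_b: str, on_saturation: str = "error") -> float:
    """Kimura-corrected distance between two aligned protein sequences.

    The correction d = -ln(1 - p - p^2/5) diverges as p approaches ~0.8541;
    beyond that the distance is undefined.  ``on_saturation`` selects between
    raising (default) and capping at ``SATURATION_CAP`` substitutions/site,
    the pragmatic guide-tree convention for extremely diverged pairs.
    """
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences must be aligned to equal length")
    if on_saturation not in ("error", "cap"):
        raise ValueError("on_saturation must be 'error' or 'cap'")
    n = mismatches = 0
    for x, y in zip(seq_a, seq_b):
        if x in GAP_CHARS or y in GAP_CHARS:
            continue
        n += 1
        mismatches += x != y
    if n == 0:
        raise ValueError("no ungapped overlap between sequences")
    p = mismatches / n
    arg = 1.0 - p - p * p / 5.0
    if arg <= 0:
        if on_saturation == "cap":
            return SATURATION_CAP
        raise ValueError(f"distance saturated at p = {p:.3f} (1 - p - p^2/5 <= 0)")
    return min(-math.log(arg), SATURATION_CAP) if on_saturation == "cap" else -math.log(arg)


def kimura_distance_matrix(
    msa: WeightedMSA, on_saturation: str = "error"
) -> DistanceMatrix:
    """All-pairs Kimura-corrected distances for an alignment (vectorised)."""
    if on_saturation not in ("error", "cap"):
        raise ValueError("on_saturation must be 'error' or 'cap'")
    n = msa.n_sequences
    chars = np.array([list(r) for r in msa.rows])
    gap = np.isin(chars, list(GAP_CHARS))
    m = np.zeros((n, n))
    for a in range(n):
        both = ~gap[a][None, :] & ~gap[a + 1 :]
        overlap = both.sum(axis=1)
        mism = ((chars[a][None, :] != chars[a + 1 :]) & both).sum(axis=1)
        if (overlap == 0).any():
            b = a + 1 + int(np.argmax(overlap == 0))
            raise ValueError(
                f"pair ({msa.ids[a]!r}, {msa.ids[b]!r}): no ungapped overlap"
            )
        p = mism / overlap
        arg = 1.0 - p - p * p / 5.0
        if (arg <= 0).any():
            if on_saturation == "error":
                b = a + 1 + int(np.argmax(arg <= 0))
                raise ValueError(
                    f"pair ({msa.ids[a]!r}, {msa.ids[b]!r}): distance saturated "
                    f"at p = {p[b - a - 1]:.3f} (1 - p - p^2/5 <= 0)"
                )
            d = np.full_like(arg, SATURATION_CAP)
            ok = arg > 0
            d[ok] = np.minimum(-np.log(arg[ok]), SATURATION_CAP)
        else:
            d = -np.log(arg)
            if on_saturation == "cap":
                d = np.minimum(d, SATURATION_CAP)
        m[a, a + 1 :] = d
    m = m + m.T
    return DistanceMatrix(list(msa.ids), m)


def neighbor_joining(dist: DistanceMatrix) -> skbio.TreeNode:
    """Neighbor-joining tree from a distance matrix.

    Ids are fed in sorted order so agglomeration tie-breaks are
    reproducible; negative branch lengths are clamped to zero.
    """
    if len(dist.ids) < 3:
        raise ValueError("neighbor joining needs at least 3 sequences")
    order = sorted(dist.ids)
    sub = dist.submatrix(order)
    dm = skbio.DistanceMatrix(sub.matrix, ids=order)
    tree = _skbio_nj(dm, neg_as_zero=True)
    return tree


def node_conservation_profile(
    tree: skbio.TreeNode, msa: WeightedMSA, column: int
) -> list[NodeProfile]:
    """Per-internal-node amino-acid frequency vectors for one column.

    Frequencies are unweighted leaf counts with gaps excluded; the preferred
    amino acid is the argmax with alphabetical tie-breaking.  A parent's
    vector is the leaf-count-weighted mixture of its children's.
    """
    if not (0 <= column < msa.n_columns):
        raise IndexError(f"column {column} out of range 0..{msa.n_columns - 1}")
    row_of = {sid: k for k, sid in enumerate(msa.ids)}
    missing = [t.name for t in tree.tips() if t.name not in row_of]
    if missing:
        raise KeyError(f"tree leaves absent from alignment: {missing[:5]}")

    profiles: list[NodeProfile] = []
    n_internal = 0
    for node in tree.postorder():
        if node.is_tip():
            continue
        n_internal += 1
        leaves = [t.name for t in node.tips()]
        counts: dict[str, int] = {}
        for sid in leaves:
            ch = msa.rows[row_of[sid]][column]
            if ch in GAP_CHARS:
                continue
            counts[ch] = counts.get(ch, 0) + 1
        total = sum(counts.values())
        freqs = {k: v / total for k, v in counts.items()} if total else {}
        preferred = min(
            freqs, key=lambda a: (-freqs[a], a)
        ) if freqs else "-"
        name = node.name if node.name else f"node{n_internal}"
        profiles.append(
            NodeProfile(
                node_id=name,
                position=column,
                frequencies=freqs,
                preferred_aa=preferred,
                n_leaves=len(leaves),
                leaf_ids=frozenset(leaves),
            )
        )
    return profiles


def is_tree_determinant(
    profiles: list[NodeProfile],
    min_leaf_fraction: float = 0.10,
    min_within_freq: float = 0.80,
) -> bool:
    """Whether disjoint clades prefer different amino acids at this position.

    True when at least two internal nodes with disjoint leaf sets, each
    covering at least ``min_leaf_fraction`` of all leaves, prefer different
    amino acids with within-clade frequency >= ``min_within_freq``.
    """
    if not profiles:
        return False
    n_total = max(p.n_leaves for p in profiles)
    eligible = [
        p
        for p in profiles
        if p.n_leaves >= min_leaf_fraction * n_total
        and p.frequencies.get(p.preferred_aa, 0.0) >= min_within_freq
    ]
    for a, b in combinations(eligible, 2):
        if a.preferred_aa != b.preferred_aa and a.leaf_ids.isdisjoint(b.leaf_ids):
            return True
    return False


def write_phylip(dist: DistanceMatrix) -> str:
    """Serialise to PHYLIP square distance-matrix format."""
    lines = [f"    {len(dist.ids)}"]
    for sid, row in zip(dist.ids, dist.matrix):
        name = f"{sid[:10]:<10}"
        lines.append(name + "  " + "  ".join(f"{v:.6f}" for v in row))
    return "\n".join(lines) + "\n"


def read_phylip(text: str) -> DistanceMatrix:
    """Parse a PHYLIP square distance matrix."""
    lines = [ln for ln in text.splitlines() if ln.strip()]
    n = int(lines[0].split()[0])
    ids: list[str] = []
    rows: list[list[float]] = []
    for ln in lines[1 : n + 1]:
        parts = ln.split()
        ids.append(parts[0])
        rows.append([float(v) for v in parts[1:]])
    return DistanceMatrix(ids, np.array(rows))
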