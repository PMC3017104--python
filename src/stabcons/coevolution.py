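"""Coevolution of alignment columns via normalized mutual information.

For columns i and j of a weighted alignment, MI(i,j) = H(i) + H(j) - H(i,j)
with all entropies computed from Henikoff-weighted symbol frequencies, and
the normalised MI is MI(i,j)/H(i,j), which bounds the statistic to [0,1] and
decouples it from per-column variability.  Pair significance is assessed two
ways: a Z-score of the normalised MI against the distribution over all
analysed pairs (Z > 4 flags candidate coevolution), and an empirical P-value
from a tree-based shuffling null that swaps column-j symbols preferentially
between phylogenetically close sequences — destroying the i-j coupling while
preserving the shared-ancestry signal that inflates naive MI.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .msa import GAP_CHARS, WeightedMSA
from .phylo import DistanceMatrix

__all__ = [
    "CoevolPair",
    "ShuffleNullSpec",
    "joint_entropy",
    "normalized_mi",
    "zscores_all_pairs",
    "tree_shuffle_null",
    "significant_pairs",
    "annotate_spatial_class",
]

_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_CODE = {a: k for k, a in enumerate(_ALPHABET)}
_K = len(_ALPHABET)


@dataclass
class CoevolPair:
    i: int
    j: int
    mi: float
    joint_entropy: float
    mi_norm: float
    z: float = float("nan")
    p_shuffle: float | None = None
    spatial_class: str = "unknown"


@dataclass
class ShuffleNullSpec:
    """Parameters of the tree-based shuffling null."""

    n_iterations: int = 100
    n_shuffles_per_iteration: int = 2000
    decay_lambda: float | None = None  # None -> 1 / mean pairwise distance
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_iterations < 20:
            raise ValueError("need >= 20 iterations for p-value reporting")
        if self.decay_lambda is not None and self.decay_lambda < 0:
            raise ValueError("decay_lambda must be >= 0")


def _encode_column(msa: WeightedMSA, j: int) -> np.ndarray:
    """Column as integer codes; gaps/unknown letters become -1."""
    return np.array(
        [_CODE.get(row[j], -1) if row[j] not in GAP_CHARS else -1 for row in msa.rows],
        dtype=np.int64,
    )


def _weights(msa: WeightedMSA) -> np.ndarray:
    if msa.weights is None:
        raise ValueError("weights unset; call henikoff_weights() first")
    return np.asarray(msa.weights, dtype=float)


def _entropy_from_weights(codes: np.ndarray, w: np.ndarray, n_states: int) -> float:
    f = np.bincount(codes, weights=w, minlength=n_states)
    total = f.sum()
    if total <= 0:
        return float("nan")
    f = f / total
    f = f[f > 0]
    return float(-(f * np.log(f)).sum())


def _pair_arrays(
    ci: np.ndarray, cj: np.ndarray, w: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Drop rows gapped at either column; renormalise weights."""
    valid = (ci >= 0) & (cj >= 0)
    wv = w[valid]
    total = wv.sum()
    if total > 0:
        wv = wv / total
    return ci[valid], cj[valid], wv


def _mi_from_codes(
    ci: np.ndarray, cj: np.ndarray, w: np.ndarray
) -> tuple[float, float, float]:
    """(mi, joint_entropy, mi_norm) from encoded pair columns; NaN-free."""
    if ci.size == 0:
        return 0.0, 0.0, 0.0
    h_i = _entropy_from_weights(ci, w, _K)
    h_j = _entropy_from_weights(cj, w, _K)
    h_ij = _entropy_from_weights(ci * _K + cj, w, _K * _K)
    mi = h_i + h_j - h_ij
    mi = max(mi, 0.0)  # clip tiny negative rounding
    mi_norm = mi / h_ij if h_ij > 0 else 0.0
    return mi, h_ij, min(mi_norm, 1.0)


def joint_entropy(msa: WeightedMSA, i: int, j: int) -> float:
    """Weighted joint Shannon entropy H(i,j) in nats (gapped rows dropped)."""
    i, j = min(i, j), max(i, j)  # exact symmetry
    ci, cj, w = _pair_arrays(_encode_column(msa, i), _encode_column(msa, j), _weights(msa))
    if ci.size == 0:
        return float("nan")
    return _entropy_from_weights(ci * _K + cj, w, _K * _K)


def normalized_mi(msa: WeightedMSA, i: int, j: int) -> tuple[float, float]:
    """(MI, MI/H(i,j)) for one column pair; a zero-entropy pair gives (0, 0).

    Computed on the ordered pair (min, max) so symmetry holds exactly.
    """
    i, j = min(i, j), max(i, j)
    ci, cj, w = _pair_arrays(_encode_column(msa, i), _encode_column(msa, j), _weights(msa))
    mi, _, mi_norm = _mi_from_codes(ci, cj, w)
    return mi, mi_norm


def zscores_all_pairs(
    msa: WeightedMSA, columns: list[int] | None = None
) -> list[CoevolPair]:
    """Normalised MI for every column pair, standardised across the pair set.

    z(i,j) = (mi_norm(i,j) - mean) / sd with mean and sd over all analysed
    pairs; by construction the returned z values have mean 0 and sd 1.
    Pairs come back sorted by z descending.
    """
    w = _weights(msa)
    if columns is None:
        columns = list(range(msa.n_columns))
    encoded = {c: _encode_column(msa, c) for c in columns}
    pairs: list[CoevolPair] = []
    for i, j in combinations(columns, 2):
        ci, cj, wv = _pair_arrays(encoded[i], encoded[j], w)
        mi, h_ij, mi_norm = _mi_from_codes(ci, cj, wv)
        pairs.append(CoevolPair(i=i, j=j, mi=mi, joint_entropy=h_ij, mi_norm=mi_norm))
    if len(pairs) < 10:
        import warnings

        warnings.warn(f"only {len(pairs)} pairs; Z-scores will be noisy")
    vals = np.array([p.mi_norm for p in pairs])
    sd = vals.std()
    if sd == 0:
        raise ValueError("degenerate alignment: all pairs have identical mi_norm")
    mean = vals.mean()
    for p in pairs:
        p.z = float((p.mi_norm - mean) / sd)
    pairs.sort(key=lambda p: (-p.z, p.i, p.j))
    return pairs


def tree_shuffle_null(
    msa: WeightedMSA,
    distances: DistanceMatrix,
    i: int,
    j: int,
    spec: ShuffleNullSpec | None = None,
    collect_columns: bool = False,
) -> tuple[float, np.ndarray] | tuple[float, np.ndarray, list[np.ndarray]]:
    """Empirical P-value of mi_norm(i,j) under tree-based shuffling of column j.

    Each iteration applies ``n_shuffles_per_iteration`` pairwise swaps of the
    column-j symbols, sampling sequence pairs (a,b) with probability
    proportional to exp(-lambda * d(a,b)): phylogenetically close sequences
    are swapped preferentially, so null alignments keep the tree signal.
    lambda defaults to 1/mean(d); lambda = 0 reduces to uniform permutation.
    The symbol multiset of the column is invariant under shuffling.

    Returns (p, null_mi_norms): p is the fraction of iterations whose null
    mi_norm is at least the observed one, floored at 1/(n_iterations + 1).
    """
    spec = spec or ShuffleNullSpec()
    w = _weights(msa)
    ci_full = _encode_column(msa, i)
    cj_full = _encode_column(msa, j)
    valid = (ci_full >= 0) & (cj_full >= 0)
    idx = np.nonzero(valid)[0]
    if idx.size < 3:
        raise ValueError("fewer than 3 ungapped sequences for this pair")
    ci = ci_full[idx]
    cj = cj_full[idx]
    wv = w[idx]
    total = wv.sum()
    if total > 0:
        wv = wv / total

    _, _, observed = _mi_from_codes(ci, cj, wv)

    order = [msa.ids[k] for k in idx]
    d = distances.submatrix(order).matrix
    iu, ju = np.triu_indices(len(order), k=1)
    dvals = d[iu, ju]
    lam = spec.decay_lambda
    if lam is None:
        mean_d = float(dvals.mean())
        lam = 1.0 / mean_d if mean_d > 0 else 0.0
    logits = -lam * dvals
    logits -= logits.max()
    probs = np.exp(logits)
    probs /= probs.sum()

    rng = np.random.default_rng(spec.seed)
    n_pairs = dvals.size
    null_vals = np.empty(spec.n_iterations)
    columns: list[np.ndarray] = []
    for it in range(spec.n_iterations):
        col = cj.copy()
        picks = rng.choice(n_pairs, size=spec.n_shuffles_per_iteration, p=probs)
        for k in picks:
            a, b = iu[k], ju[k]
            col[a], col[b] = col[b], col[a]
        _, _, null_vals[it] = _mi_from_codes(ci, col, wv)
        if collect_columns:
            columns.append(col)

    p = float(np.mean(null_vals >= observed))
    if p == 0.0:
        p = 1.0 / (spec.n_iterations + 1)
    if collect_columns:
        return p, null_vals, columns
    return p, null_vals


def significant_pairs(
    pairs: list[CoevolPair],
    z_min: float = 4.0,
    p_max: float = 0.05,
) -> list[CoevolPair]:
    """Pairs with z >= z_min and computed p_shuffle < p_max."""
    return [
        p
        for p in pairs
        if p.z >= z_min and p.p_shuffle is not None and p.p_shuffle < p_max
    ]


def annotate_spatial_class(
    pairs: list[CoevolPair],
    atoms,
    chain: str,
    proximal_cutoff: float = 8.0,
    position_of: dict[int, int] | None = None,
) -> None:
    """Label pairs proximal/distant by C-beta distance (C-alpha for glycine).

    ``position_of`` maps the pair indices (e.g. alignment-derived reference
    positions) to residue numbers in the structure; identity when omitted.
    """
    anchors: dict[int, np.ndarray] = {}
    fallback: dict[int, np.ndarray] = {}
    for a in atoms:
        if a.chain_id != chain:
            continue
        if a.atom_name == "CB":
            anchors[a.residue_number] = np.asarray(a.coord)
        elif a.atom_name == "CA":
            fallback.setdefault(a.residue_number, np.asarray(a.coord))
    for resnum, xyz in fallback.items():
        anchors.setdefault(resnum, xyz)

    for p in pairs:
        ri = position_of.get(p.i, p.i) if position_of else p.i
        rj = position_of.get(p.j, p.j) if position_of else p.j
        if ri in anchors and rj in anchors:
            dist = float(np.linalg.norm(anchors[ri] - anchors[rj]))
            p.spatial_class = "proximal" if dist <= proximal_cutoff else "distant"
        else:
            p.spatial_class = "unknown"
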