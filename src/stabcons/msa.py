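"""Evolutionary entropy from multiple sequence alignments with Henikoff weights.

Implements position-based sequence weighting (each sequence collects
1/(r*s) per column, r = distinct symbols in the column, s = multiplicity of
that sequence's symbol), weighted per-column amino-acid frequencies and their
Shannon entropy normalised by ln 20, the correlation between
stability-derived and evolutionary entropies, and the three-way partition of
positions into entropy outliers, stability-correlated positions, and
over-conserved positions.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import AlignIO
from scipy import stats

from .stability import AMINO_ACIDS

__all__ = [
    "WeightedMSA",
    "EntropyTable",
    "read_alignment",
    "henikoff_weights",
    "evolutionary_entropy",
    "column_frequencies",
    "pearson_with_p",
    "pearson_pvalue",
    "partition_positions",
    "read_entropy_tsv",
]

GAP_CHARS = {"-", ".", "X"}


@dataclass
class WeightedMSA:
    """Aligned sequences with optional Henikoff sequence weights.

    ``ref_positions`` maps alignment columns to the ungapped numbering of a
    designated reference row (None for columns gapped in the reference).
    """

    ids: list[str]
    rows: list[str]
    weights: np.ndarray | None = None
    species: list[str] | None = None
    reference_id: str | None = None
    ref_positions: list[int | None] = field(default_factory=list)

    def __post_init__(self) -> None:
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise ValueError(f"ragged alignment: row lengths {sorted(lengths)}")
        if len(set(self.ids)) != len(self.ids):
            dupes = {i for i in self.ids if self.ids.count(i) > 1}
            raise ValueError(f"duplicate sequence ids: {sorted(dupes)}")

    @property
    def n_sequences(self) -> int:
        return len(self.rows)

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def column(self, j: int) -> list[str]:
        return [row[j] for row in self.rows]

    def set_reference(self, reference_id: str) -> None:
        """Map alignment columns to the reference sequence's residue numbering."""
        if reference_id not in self.ids:
            raise KeyError(f"reference {reference_id!r} not in alignment")
        self.reference_id = reference_id
        ref_row = self.rows[self.ids.index(reference_id)]
        positions: list[int | None] = []
        n = 0
        for ch in ref_row:
            if ch in GAP_CHARS:
                positions.append(None)
            else:
                n += 1
                positions.append(n)
        self.ref_positions = positions

    def column_for_position(self, position: int) -> int:
        """Alignment column index of a reference residue number."""
        if not self.ref_positions:
            raise ValueError("reference not set; call set_reference() first")
        try:
            return self.ref_positions.index(position)
        except ValueError:
            raise KeyError(f"reference position {position} not found") from None


def read_alignment(text: str, fmt: str = "fasta") -> WeightedMSA:
    """Read a FASTA or Clustal alignment into a WeightedMSA (weights unset)."""
    if fmt not in ("fasta", "clustal"):
        raise ValueError(f"format must be fasta or clustal, got {fmt!r}")
    try:
        aln = AlignIO.read(io.StringIO(text), fmt)
    except ValueError as exc:
        # Biopython rejects ragged FASTA "alignments"; surface the offender
        if fmt == "fasta":
            from Bio import SeqIO

            recs = list(SeqIO.parse(io.StringIO(text), "fasta"))
            if len(recs) >= 2:
                ref_len = len(recs[0].seq)
                for r in recs:
                    if len(r.seq) != ref_len:
                        raise ValueError(
                            f"ragged alignment: sequence {r.id!r} has length "
                            f"{len(r.seq)} != {ref_len}"
                        ) from exc
        raise
    if len(aln) < 2:
        raise ValueError("alignment needs at least 2 sequences")
    ids = [rec.id for rec in aln]
    rows = [str(rec.seq).upper() for rec in aln]
    return WeightedMSA(ids=ids, rows=rows)


def henikoff_weights(msa: WeightedMSA, normalize: bool = True) -> np.ndarray:
    """Position-based sequence weights down-weighting redundant sequences.

    Per column each sequence earns 1/(r*s); the per-sequence sums are
    normalised to total 1 (identical sequences share weight equally).  Gap
    characters count as an ordinary symbol type for weighting purposes.
    """
    n, m = msa.n_sequences, msa.n_columns
    raw = np.zeros(n)
    for j in range(m):
        col = msa.column(j)
        counts: dict[str, int] = {}
        for ch in col:
            counts[ch] = counts.get(ch, 0) + 1
        r = len(counts)
        for i, ch in enumerate(col):
            raw[i] += 1.0 / (r * counts[ch])
    if normalize:
        total = raw.sum()
        if total > 0:
            raw = raw / total
    msa.weights = raw
    return raw


def column_frequencies(
    msa: WeightedMSA, column: int, exclude_gaps: bool = True
) -> dict[str, float]:
    """Weighted amino-acid frequencies at one alignment column.

    Gaps are excluded and the remaining mass renormalised (HSSP-style); an
    all-gap column yields an empty dict.
    """
    if msa.weights is None:
        raise ValueError("weights unset; call henikoff_weights() first")
    freqs: dict[str, float] = {}
    for w, row in zip(msa.weights, msa.rows):
        ch = row[column]
        if exclude_gaps and ch in GAP_CHARS:
            continue
        freqs[ch] = freqs.get(ch, 0.0) + float(w)
    total = sum(freqs.values())
    if total > 0:
        freqs = {k: v / total for k, v in freqs.items()}
    return freqs


def evolutionary_entropy(
    msa: WeightedMSA, column: int, exclude_gaps: bool = True
) -> float:
    """Weighted column entropy normalised by ln 20; NaN for all-gap columns."""
    freqs = column_frequencies(msa, column, exclude_gaps=exclude_gaps)
    if not freqs:
        return float("nan")
    p = np.array(list(freqs.values()))
    p = p[p > 0]
    return float(-(p * np.log(p)).sum() / math.log(20.0))


def pearson_with_p(x, y) -> tuple[float, float]:
    """Pearson r with the two-sided t-transform p-value.

    p comes from t = r*sqrt(n-2)/sqrt(1-r^2) against Student's t with n-2
    degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need n >= 3 paired finite values")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance in input")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def pearson_pvalue(r: float, n: int, two_sided: bool = True) -> float:
    """p-value for a given correlation coefficient and sample size.

    Used to check printed (r, n, p) triples without the underlying data.
    """
    if n < 3:
        raise ValueError("need n >= 3")
    if abs(r) >= 1:
        return 0.0
    if r == 0:
        return 1.0 if two_sided else 0.5
    t = r * math.sqrt(n - 2) / math.sqrt(1.0 - r * r)
    sf = stats.t.sf(abs(t), df=n - 2)
    return float(2 * sf if two_sided else sf)


@dataclass
class EntropyTable:
    """Per-position evolutionary vs stability-derived entropies with set labels."""

    table: pd.DataFrame  # columns: position, evo_entropy, calc_entropy, set_label
    outlier_evo_min: float | None = None
    band_tolerance: float | None = None
    correlated_slope: float | None = None
    correlated_r: float | None = None
    correlated_p: float | None = None


def partition_positions(
    positions,
    evo_entropy,
    calc_entropy,
    outlier_evo_min: float = 0.2,
    band_tolerance: float | None = None,
) -> EntropyTable:
    """Split positions into entropy outliers / correlated / over-conserved sets.

    Positions whose evolutionary entropy reaches ``outlier_evo_min`` are
    outliers.  A line is fitted (evolutionary on stability-derived entropy)
    through the remainder; points within the tolerance band (default 2x the
    RMS residual) are labelled correlated and the line is refitted on them to
    report slope, r and p; the rest are over-conserved (evolution holds them
    tighter than stability alone would).
    """
    evo = np.asarray(evo_entropy, dtype=float)
    calc = np.asarray(calc_entropy, dtype=float)
    positions = list(positions)
    labels = np.array(["unassigned"] * len(positions), dtype=object)

    outlier_mask = evo >= outlier_evo_min
    labels[outlier_mask] = "outlier"
    rest = ~outlier_mask

    slope = r = p = None
    tol = band_tolerance
    if rest.sum() >= 3 and np.std(calc[rest]) > 0:
        fit = stats.linregress(calc[rest], evo[rest])
        resid = evo[rest] - (fit.intercept + fit.slope * calc[rest])
        if tol is None:
            rms = float(np.sqrt(np.mean(resid**2)))
            tol = 2.0 * rms
        within = np.abs(resid) <= tol
        rest_idx = np.nonzero(rest)[0]
        labels[rest_idx[within]] = "correlated"
        labels[rest_idx[~within]] = "over-conserved"
        corr_idx = rest_idx[within]
        if corr_idx.size >= 3 and np.std(calc[corr_idx]) > 0:
            fit2 = stats.linregress(calc[corr_idx], evo[corr_idx])
            slope = float(fit2.slope)
            if np.std(evo[corr_idx]) > 0:
                r, p = pearson_with_p(calc[corr_idx], evo[corr_idx])
    else:
        labels[rest] = "over-conserved"

    df = pd.DataFrame(
        {
            "position": positions,
            "evo_entropy": evo,
            "calc_entropy": calc,
            "set_label": labels,
        }
    )
    return EntropyTable(
        table=df,
        outlier_evo_min=outlier_evo_min,
        band_tolerance=tol,
        correlated_slope=slope,
        correlated_r=r,
        correlated_p=p,
    )


def read_entropy_tsv(text: str) -> pd.DataFrame:
    """Read a per-position entropy TSV (position, entropy) such as an HSSP extract."""
    df = pd.read_csv(io.StringIO(text), sep="\t")
    if not {"position", "entropy"} <= set(df.columns):
        raise ValueError("entropy TSV needs columns: position, entropy")
    return df
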