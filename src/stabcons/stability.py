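"""Boltzmann sequence entropy from ddG mutational scans, and phenotype calls.

A per-position mutational scan gives the folding (or binding) free-energy
change ddG = dG_mut - dG_wt for mutating the native residue to each of 17
alternatives (all natural amino acids except cysteine and proline).  Assuming
amino-acid occupancy at a position follows a Boltzmann distribution at
physiological temperature, the propensity of residue i is

    p_i  ∝  exp(-ddG_i / (k_B T)),      ddG_native = 0,

normalised over the 18-letter alphabet (native included).  The positional
sequence entropy is H(k) = -sum_i p_i ln p_i, reported both in nats and
normalised by ln 20, the maximum attainable over the full amino-acid
alphabet.  Destabilising mutations (ddG at or above a cutoff, default
+3 kcal/mol) are predicted lethal; observed lethal/viable ddG samples are
compared with a one-tailed two-sample t-test.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "KB_KCAL",
    "AMINO_ACIDS",
    "SCAN_MUTANT_ALPHABET",
    "DdgRecord",
    "DdgScan",
    "PropensityProfile",
    "MutantPhenotype",
    "ConfusionSummary",
    "read_ddg_table",
    "read_phenotype_table",
    "boltzmann_weights",
    "boltzmann_propensities",
    "positional_entropy",
    "propensity_profile",
    "native_recapitulation",
    "classify_mutations",
    "lethal_viable_ttest",
    "position_weight_matrix",
]

#: Boltzmann constant in kcal/(mol*K).
KB_KCAL = 0.0019872

AMINO_ACIDS = tuple("ACDEFGHIKLMNPQRSTVWY")
#: Mutant alphabet of a scan: every natural amino acid except C and P.
SCAN_MUTANT_ALPHABET = tuple(a for a in AMINO_ACIDS if a not in ("C", "P"))

DEFAULT_TEMPERATURE_K = 300.0


@dataclass(frozen=True)
class DdgRecord:
    chain: str
    position: int
    wt_aa: str
    mut_aa: str
    ddg: float
    sem: float = 0.0
    ddg_type: str = "stability"

    def __post_init__(self) -> None:
        if self.sem < 0:
            raise ValueError("sem must be >= 0")
        if self.ddg_type not in ("stability", "binding"):
            raise ValueError(f"unknown ddg_type {self.ddg_type!r}")
        if self.mut_aa == self.wt_aa and self.ddg != 0.0:
            raise ValueError(
                f"self-record {self.wt_aa}{self.position} must have ddg = 0"
            )


@dataclass
class DdgScan:
    """Records grouped per (chain, position), with the native entry at ddg=0."""

    records: dict[tuple[str, int], list[DdgRecord]]
    temperature_K: float = DEFAULT_TEMPERATURE_K
    warnings: list[str] = field(default_factory=list)

    @property
    def positions(self) -> list[tuple[str, int]]:
        return sorted(self.records)

    def native_aa(self, key: tuple[str, int]) -> str:
        return self.records[key][0].wt_aa


@dataclass
class PositionPropensity:
    probabilities: dict[str, float]
    entropy_nats: float
    entropy_normalized: float
    temperature_K: float
    native_aa: str


@dataclass
class PropensityProfile:
    """Boltzmann propensities and entropies for every scanned position."""

    entries: dict[tuple[str, int], PositionPropensity]
    temperature_K: float


@dataclass(frozen=True)
class MutantPhenotype:
    mutation: str
    ddg: float
    phenotype: str

    def __post_init__(self) -> None:
        if self.phenotype not in ("lethal", "viable"):
            raise ValueError(f"phenotype must be lethal/viable, got {self.phenotype!r}")


@dataclass
class ConfusionSummary:
    """2x2 counts for the ddG-cutoff lethality classifier."""

    true_lethal: int
    false_viable: int  # lethal observed, predicted viable
    false_lethal: int  # viable observed, predicted lethal
    true_viable: int
    cutoff: float

    @property
    def lethal_sensitivity(self) -> float:
        n = self.true_lethal + self.false_viable
        return self.true_lethal / n if n else float("nan")

    @property
    def viable_specificity(self) -> float:
        n = self.true_viable + self.false_lethal
        return self.true_viable / n if n else float("nan")


def read_ddg_table(csv_text: str, temperature_K: float = DEFAULT_TEMPERATURE_K) -> DdgScan:
    """Parse a ddG scan CSV (chain, position, wt_aa, mut_aa, ddg, sem, ddg_type).

    Validates: no duplicate (position, mut_aa), no C/P mutants, numeric ddG,
    a native ddg=0 row per position.  Positions missing some of the 17
    mutants are accepted with a warning recorded on the scan.
    """
    df = pd.read_csv(io.StringIO(csv_text))
    required = {"chain", "position", "wt_aa", "mut_aa", "ddg"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"ddG table missing columns: {sorted(missing)}")
    if "sem" not in df.columns:
        df["sem"] = 0.0
    if "ddg_type" not in df.columns:
        df["ddg_type"] = "stability"

    records: dict[tuple[str, int], list[DdgRecord]] = {}
    seen: set[tuple[str, int, str]] = set()
    for idx, row in df.iterrows():
        try:
            ddg = float(row["ddg"])
        except (TypeError, ValueError) as exc:
            raise ValueError(f"row {idx + 2}: non-numeric ddg {row['ddg']!r}") from exc
        chain = str(row["chain"])
        position = int(row["position"])
        wt = str(row["wt_aa"]).upper()
        mut = str(row["mut_aa"]).upper()
        if mut != wt and mut in ("C", "P"):
            raise ValueError(
                f"row {idx + 2}: mutant {mut} not allowed (scans exclude C and P)"
            )
        key3 = (chain, position, mut)
        if key3 in seen:
            raise ValueError(f"row {idx + 2}: duplicate record for {key3}")
        seen.add(key3)
        rec = DdgRecord(chain, position, wt, mut, ddg, float(row["sem"]), str(row["ddg_type"]))
        records.setdefault((chain, position), []).append(rec)

    warnings: list[str] = []
    for key, recs in records.items():
        natives = [r for r in recs if r.mut_aa == r.wt_aa]
        if not natives:
            raise ValueError(f"position {key} lacks a native ddg=0 row")
        # native entry first for convenient access
        recs.sort(key=lambda r: (r.mut_aa != r.wt_aa, r.mut_aa))
        n_mut = len(recs) - len(natives)
        # full scan = every non-C/P letter except the native itself
        if n_mut < len(SCAN_MUTANT_ALPHABET) - 1:
            warnings.append(f"position {key}: only {n_mut}/17 mutants present")
    return DdgScan(records=records, temperature_K=temperature_K, warnings=warnings)


def read_phenotype_table(csv_text: str) -> list[MutantPhenotype]:
    """Parse a phenotype CSV with columns mutation, ddg, phenotype."""
    df = pd.read_csv(io.StringIO(csv_text))
    return [
        MutantPhenotype(str(r["mutation"]), float(r["ddg"]), str(r["phenotype"]).lower())
        for _, r in df.iterrows()
    ]


def boltzmann_weights(ddg, temperature_K: float = DEFAULT_TEMPERATURE_K) -> np.ndarray:
    """Normalised Boltzmann probabilities exp(-ddG/kT) / Z for a ddG vector.

    Shift-invariant: adding a constant to every ddG leaves the result
    unchanged (the max is subtracted before exponentiation).
    """
    if temperature_K <= 0:
        raise ValueError("temperature must be positive")
    w = -np.asarray(ddg, dtype=float) / (KB_KCAL * temperature_K)
    w -= w.max()
    p = np.exp(w)
    return p / p.sum()


def boltzmann_propensities(
    scan: DdgScan,
    position: tuple[str, int],
    temperature_K: float | None = None,
) -> PositionPropensity:
    """Boltzmann amino-acid propensities at one position.

    p_i ∝ exp(-ddG_i / kT) over the letters present in the scan (native at
    ddG=0).  Computed with a max-shift for numerical stability; invariant
    under adding a constant to all ddG values at the position.
    """
    if position not in scan.records:
        raise KeyError(f"position {position} not in scan")
    T = scan.temperature_K if temperature_K is None else temperature_K
    if T <= 0:
        raise ValueError("temperature must be positive")
    recs = scan.records[position]
    natives = [r for r in recs if r.mut_aa == r.wt_aa]
    if not natives:
        raise ValueError(f"position {position} lacks a native row")
    letters = [r.mut_aa for r in recs]
    p = boltzmann_weights([r.ddg for r in recs], T)
    probs = dict(zip(letters, p.tolist()))
    h, h_norm = positional_entropy(probs)
    return PositionPropensity(
        probabilities=probs,
        entropy_nats=h,
        entropy_normalized=h_norm,
        temperature_K=T,
        native_aa=natives[0].wt_aa,
    )


def positional_entropy(probabilities: dict[str, float]) -> tuple[float, float]:
    """Shannon entropy of a propensity vector, in nats and as H/ln(20)."""
    p = np.array(list(probabilities.values()), dtype=float)
    if not math.isclose(p.sum(), 1.0, abs_tol=1e-9):
        raise ValueError(f"probabilities sum to {p.sum()}, expected 1")
    p = p[p > 0]
    h = float(-(p * np.log(p)).sum())
    return h, h / math.log(20.0)


def propensity_profile(
    scan: DdgScan, temperature_K: float | None = None
) -> PropensityProfile:
    """Propensities and entropies for all positions of a scan."""
    T = scan.temperature_K if temperature_K is None else temperature_K
    entries = {
        key: boltzmann_propensities(scan, key, T) for key in scan.positions
    }
    return PropensityProfile(entries=entries, temperature_K=T)


def native_recapitulation(scan: DdgScan) -> float:
    """Fraction of positions whose lowest-ddG amino acid is the native one.

    Ties at the minimum count as recapitulated when the native is among the
    minima (the native always has ddG = 0).
    """
    if not scan.records:
        raise ValueError("empty scan")
    hits = 0
    for key, recs in scan.records.items():
        min_ddg = min(r.ddg for r in recs)
        native = scan.native_aa(key)
        winners = {r.mut_aa for r in recs if r.ddg == min_ddg}
        if native in winners:
            hits += 1
    return hits / len(scan.records)


def classify_mutations(
    phenotypes: list[MutantPhenotype], cutoff: float = 3.0
) -> ConfusionSummary:
    """Predict lethality as ddG >= cutoff and tabulate against observations.

    The comparison is inclusive so that a mutation printed exactly at the
    cutoff is called destabilising.
    """
    if not phenotypes:
        raise ValueError("no phenotype records")
    tl = fv = fl = tv = 0
    for m in phenotypes:
        predicted_lethal = m.ddg >= cutoff
        if m.phenotype == "lethal":
            tl += predicted_lethal
            fv += not predicted_lethal
        else:
            fl += predicted_lethal
            tv += not predicted_lethal
    return ConfusionSummary(tl, fv, fl, tv, cutoff)


def lethal_viable_ttest(
    lethal_ddg: list[float],
    viable_ddg: list[float],
    equal_var: bool = True,
) -> tuple[float, float]:
    """One-tailed two-sample t-test for mean(lethal ddG) > mean(viable ddG).

    Pooled-variance Student's t by default; Welch via ``equal_var=False``.
    Degenerate case (zero pooled variance, equal means) returns p = 0.5.
    """
    a = np.asarray(lethal_ddg, dtype=float)
    b = np.asarray(viable_ddg, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("both samples need at least 2 observations")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 0.5
        return (math.inf if a.mean() > b.mean() else -math.inf,
                0.0 if a.mean() > b.mean() else 1.0)
    res = stats.ttest_ind(a, b, equal_var=equal_var, alternative="greater")
    return float(res.statistic), float(res.pvalue)


def position_weight_matrix(profile: PropensityProfile) -> pd.DataFrame:
    """PWM over the 20 amino acids (rows = positions, zero for unscanned letters)."""
    rows = {}
    for (chain, pos), entry in sorted(profile.entries.items()):
        rows[f"{chain}:{pos}"] = [
            entry.probabilities.get(a, 0.0) for a in AMINO_ACIDS
        ]
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(AMINO_ACIDS))
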