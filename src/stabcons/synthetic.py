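"""Synthetic inputs with known ground truth for every pipeline stage.

Four generators emulate the pipeline's input classes:

* a toy atom cluster written as PDB text, with a central residue fully
  enclosed by a shell (known buried set);
* a ddG mutational scan whose per-position Boltzmann entropies are planted
  by inverse design (a target entropy is drawn, then the ddG gap solved);
* a tree-simulated alignment with per-site conservation and planted
  coevolving column pairs driven by a latent binary state inherited down
  the tree (so the coevolution signal is phylogeny-aware and the tree-based
  null is meaningfully exercised);
* lethal/viable ddG phenotype samples with a shifted-mean effect.

All generators are deterministic given the spec's seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.optimize import brentq

from .stability import KB_KCAL, SCAN_MUTANT_ALPHABET, DEFAULT_TEMPERATURE_K
from .msa import WeightedMSA

__all__ = [
    "SyntheticSpec",
    "gen_toy_structure",
    "gen_ddg_scan_csv",
    "gen_msa",
    "gen_iid_alignment",
    "gen_phenotype_table_csv",
    "write_bundle",
]

_AA20 = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class SyntheticSpec:
    """Knobs of the synthetic study conditions.

    ``conservation_q`` is the stationary probability mass of each site's
    dominant amino acid; give a (lo, hi) pair to vary it across sites.
    ``planted_pairs`` lists ((i, j), epsilon) couplings with epsilon in
    [0, 1): the probability that a leaf emits the latent-state letter pair
    instead of background letters.  ``ddg_spread`` (kcal/mol) sets the scale
    of planted ddG gaps, hence how frozen the planted entropies are.
    ``phenotype_effect`` (kcal/mol) is the lethal-minus-viable mean ddG shift.
    """

    seed: int = 0
    n_positions: int = 30
    n_sequences: int = 64
    tree_depth: float = 1.0
    conservation_q: float | tuple[float, float] = (0.4, 1.0)
    planted_pairs: list[tuple[tuple[int, int], float]] = field(default_factory=list)
    ddg_spread: float = 2.0
    phenotype_effect: float = 1.4
    phenotype_sigma: float = 1.5
    n_lethal: int = 27
    n_viable: int = 35
    substitution_rate: float = 3.0
    switch_rate: float = 1.0
    gap_rate: float = 0.0

    def __post_init__(self) -> None:
        used: set[int] = set()
        for (i, j), eps in self.planted_pairs:
            if not (0 <= eps < 1):
                raise ValueError(f"coupling must be in [0,1), got {eps}")
            for k in (i, j):
                if not (0 <= k < self.n_positions):
                    raise ValueError(f"planted index {k} >= n_positions")
                if k in used:
                    raise ValueError(f"planted pairs must be disjoint; {k} reused")
                used.add(k)

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, stream])


# 26 lattice directions (faces, edges, corners of a cube), normalised.
def _shell_directions() -> np.ndarray:
    dirs = []
    for x in (-1, 0, 1):
        for y in (-1, 0, 1):
            for z in (-1, 0, 1):
                if (x, y, z) != (0, 0, 0):
                    v = np.array([x, y, z], dtype=float)
                    dirs.append(v / np.linalg.norm(v))
    return np.array(dirs)


def _pdb_atom_line(serial: int, resnum: int, xyz: np.ndarray) -> str:
    x, y, z = xyz
    return (
        f"ATOM  {serial:>5}  CA  GLY A{resnum:>4}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C"
    )


def gen_toy_structure(
    spec: SyntheticSpec,
    n_residues: int = 27,
    shell_radius: float = 2.0,
) -> tuple[str, set[tuple[str, int]]]:
    """PDB text for a toy cluster plus the ground-truth buried residue set.

    With 27+ residues, residue 1 sits at the origin enclosed by a 26-atom
    shell at ``shell_radius``; every surface dot of the central inflated
    sphere then falls inside a shell atom's inflated sphere (the angular
    covering radius of the 26 directions is far below the occlusion
    half-angle arccos(shell_radius / (2 (r_vdw + probe)))), so its SASA is
    exactly zero.  Extra residues beyond 27 go on a distant outer ring.
    With fewer than 27 residues, atoms are laid out on a line 8 A apart and
    nothing is buried.
    """
    lines = []
    buried: set[tuple[str, int]] = set()
    if n_residues >= 27:
        coords = [np.zeros(3)]
        coords.extend(shell_radius * d for d in _shell_directions())
        for k in range(n_residues - 27):
            ang = 2 * math.pi * k / max(1, n_residues - 27)
            coords.append(np.array([12.0 * math.cos(ang), 12.0 * math.sin(ang), 0.0]))
        buried.add(("A", 1))
    else:
        coords = [np.array([8.0 * k, 0.0, 0.0]) for k in range(n_residues)]
    for k, xyz in enumerate(coords):
        lines.append(_pdb_atom_line(k + 1, k + 1, xyz))
    lines.append("END")
    return "\n".join(lines) + "\n", buried


def _gap_entropy(g: float, beta: float, n_equal: int, opposed: bool) -> float:
    """Entropy (nats) of a Boltzmann distribution with planted ddG gaps.

    ``opposed=False``: native at 0 and ``n_equal`` mutants at +g.
    ``opposed=True``: one preferred mutant at -g, native at 0, and
    ``n_equal`` mutants at +g.
    """
    if opposed:
        w = np.concatenate(([math.exp(beta * g), 1.0], np.full(n_equal, math.exp(-beta * g))))
    else:
        w = np.concatenate(([1.0], np.full(n_equal, math.exp(-beta * g))))
    p = w / w.sum()
    return float(-(p * np.log(p)).sum())


def gen_ddg_scan_csv(
    spec: SyntheticSpec,
    chain: str = "A",
    recap_miss_rate: float = 0.25,
    temperature_K: float = DEFAULT_TEMPERATURE_K,
    target_entropies: dict[int, float] | None = None,
) -> tuple[str, dict[int, float]]:
    """A ddG scan CSV with planted per-position Boltzmann entropies.

    Per position: a target entropy is drawn inside the range reachable with
    gaps in [0.5, 1.5] x ``ddg_spread`` (or taken from ``target_entropies``,
    nats, position -> H), and the gap solved by root finding so the
    Boltzmann entropy at ``temperature_K`` equals the target.  With
    probability ``recap_miss_rate`` the preferred (lowest-ddG) letter is a
    mutant rather than the native, planting imperfect native recapitulation.

    Returns (csv_text, {position: target_entropy_nats}).
    """
    rng = spec.rng(1)
    beta = 1.0 / (KB_KCAL * temperature_K)
    rows = ["chain,position,wt_aa,mut_aa,ddg,sem,ddg_type"]
    targets: dict[int, float] = {}
    g_lo, g_hi = 0.5 * spec.ddg_spread, 1.5 * spec.ddg_spread
    for pos in range(1, spec.n_positions + 1):
        native = SCAN_MUTANT_ALPHABET[rng.integers(len(SCAN_MUTANT_ALPHABET))]
        mutants = [a for a in SCAN_MUTANT_ALPHABET if a != native]
        opposed = bool(rng.random() < recap_miss_rate) and spec.ddg_spread > 0
        n_equal = len(mutants) - 1 if opposed else len(mutants)
        if target_entropies is not None:
            target = float(target_entropies[pos])
            h_max = math.log(len(mutants) + 1)
            if not (0 < target < h_max):
                raise ValueError(f"target entropy {target} outside (0, ln 18)")
            g = brentq(
                lambda x: _gap_entropy(x, beta, n_equal, opposed) - target,
                0.0, 100.0, xtol=1e-13, rtol=1e-15,
            )
            target = _gap_entropy(g, beta, n_equal, opposed)
        elif spec.ddg_spread <= 0:
            g = 0.0
            target = math.log(len(mutants) + 1)
        else:
            h_hi = _gap_entropy(g_lo, beta, n_equal, opposed)
            h_lo = _gap_entropy(g_hi, beta, n_equal, opposed)
            target = h_lo + (h_hi - h_lo) * rng.random()
            g = brentq(
                lambda x: _gap_entropy(x, beta, n_equal, opposed) - target,
                g_lo, g_hi, xtol=1e-13, rtol=1e-15,
            )
            target = _gap_entropy(g, beta, n_equal, opposed)
        targets[pos] = target
        sem = round(0.1 + 0.4 * rng.random(), 3)
        rows.append(f"{chain},{pos},{native},{native},0.0,0.0,stability")
        if opposed:
            preferred = mutants[rng.integers(len(mutants))]
            for m in mutants:
                ddg = -g if m == preferred else g
                rows.append(f"{chain},{pos},{native},{m},{ddg!r},{sem},stability")
        else:
            for m in mutants:
                rows.append(f"{chain},{pos},{native},{m},{g!r},{sem},stability")
    return "\n".join(rows) + "\n", targets


class _Node:
    __slots__ = ("children", "length", "name")

    def __init__(self, name: str | None = None, length: float = 0.0):
        self.children: list[_Node] = []
        self.length = length
        self.name = name

    def newick(self) -> str:
        if not self.children:
            return f"{self.name}:{self.length:.6f}"
        inner = ",".join(c.newick() for c in self.children)
        return f"({inner}):{self.length:.6f}"


def _balanced_tree(ids: list[str], depth: float) -> _Node:
    """Balanced ultrametric tree: equal edge lengths per bifurcation level."""
    levels = max(1, math.ceil(math.log2(len(ids)))) if len(ids) > 1 else 1
    unit = depth / levels

    def build(part: list[str], units: int) -> _Node:
        # `units` = edge-plus-subtree span from the parent down to the leaves
        if len(part) == 1:
            return _Node(name=part[0], length=unit * units)
        node = _Node(length=unit)
        half = len(part) // 2
        node.children = [build(part[:half], units - 1),
                         build(part[half:], units - 1)]
        return node

    root = _Node(length=0.0)
    half = len(ids) // 2
    root.children = [build(ids[:half], levels), build(ids[half:], levels)]
    return root


def gen_msa(spec: SyntheticSpec) -> tuple[WeightedMSA, str, dict]:
    """Tree-simulated alignment with planted conservation and coevolution.

    Characters evolve down a balanced ultrametric tree: along a branch of
    length t each site is redrawn from its stationary distribution with
    probability 1 - exp(-rate * t).  Site s has a dominant letter with
    stationary mass q_s and the remaining mass uniform over the other 19
    letters.  Each planted pair carries a latent binary state inherited down
    the tree (redrawn with probability 1 - exp(-switch_rate * t)); at each
    leaf, with probability epsilon both columns emit the state's letter pair.

    Returns (msa, newick, ground_truth) where ground_truth holds the
    expected per-column leaf-marginal entropies (normalised by ln 20), the
    per-site dominant letters and q values, and the planted pair list.
    """
    if spec.n_sequences < 4:
        raise ValueError("need at least 4 sequences")
    rng = spec.rng(2)
    n_pos = spec.n_positions
    if isinstance(spec.conservation_q, tuple):
        lo, hi = spec.conservation_q
        q = lo + (hi - lo) * rng.random(n_pos)
    else:
        q = np.full(n_pos, float(spec.conservation_q))
    dominant = rng.integers(0, 20, size=n_pos)
    # stationary distributions, one per site
    pi = np.full((n_pos, 20), 0.0)
    for s in range(n_pos):
        pi[s, :] = (1.0 - q[s]) / 19.0
        pi[s, dominant[s]] = q[s]

    ids = [f"s{k:04d}" for k in range(spec.n_sequences)]
    root = _balanced_tree(ids, spec.tree_depth)

    state_letters = []
    for (i, j), eps in spec.planted_pairs:
        # two distinct letter pairs, one per latent state
        picks = rng.choice(20, size=4, replace=False)
        state_letters.append(((picks[0], picks[1]), (picks[2], picks[3])))

    def draw_site(s: int, size=None):
        return rng.choice(20, size=size, p=pi[s])

    rows_out: dict[str, np.ndarray] = {}

    def descend(node: _Node, chars: np.ndarray, latents: list[int]) -> None:
        t = node.length
        p_sub = 1.0 - math.exp(-spec.substitution_rate * t)
        chars = chars.copy()
        redraw = rng.random(n_pos) < p_sub
        for s in np.nonzero(redraw)[0]:
            chars[s] = draw_site(int(s))
        latents = list(latents)
        p_switch = 1.0 - math.exp(-spec.switch_rate * t)
        for k in range(len(latents)):
            if rng.random() < p_switch:
                latents[k] = int(rng.integers(2))
        if not node.children:
            emitted = chars.copy()
            for k, ((i, j), eps) in enumerate(spec.planted_pairs):
                if rng.random() < eps:
                    li, lj = state_letters[k][latents[k]]
                    emitted[i] = li
                    emitted[j] = lj
            rows_out[node.name] = emitted
        else:
            for child in node.children:
                descend(child, chars, latents)

    root_chars = np.array([draw_site(s) for s in range(n_pos)])
    root_latents = [int(rng.integers(2)) for _ in spec.planted_pairs]
    for child in root.children:
        descend(child, root_chars, root_latents)

    rows = []
    for sid in ids:
        chars = rows_out[sid]
        row = "".join(_AA20[c] for c in chars)
        if spec.gap_rate > 0:
            mask = rng.random(n_pos) < spec.gap_rate
            row = "".join("-" if m else ch for ch, m in zip(row, mask))
        rows.append(row)
    msa = WeightedMSA(ids=list(ids), rows=rows)

    # expected leaf-marginal entropy per column, normalised by ln 20
    marginals = pi.copy()
    for k, ((i, j), eps) in enumerate(spec.planted_pairs):
        for col, letter_idx in (
            (i, (state_letters[k][0][0], state_letters[k][1][0])),
            (j, (state_letters[k][0][1], state_letters[k][1][1])),
        ):
            m = (1.0 - eps) * pi[col]
            m[letter_idx[0]] += 0.5 * eps
            m[letter_idx[1]] += 0.5 * eps
            marginals[col] = m
    with np.errstate(divide="ignore", invalid="ignore"):
        logm = np.where(marginals > 0, np.log(marginals), 0.0)
    expected_entropy = -(marginals * logm).sum(axis=1) / math.log(20.0)

    truth = {
        "expected_entropy_norm": expected_entropy,
        "dominant_letters": [_AA20[d] for d in dominant],
        "q": q,
        "planted_pairs": [(tuple(p), eps) for p, eps in spec.planted_pairs],
        "newick": root.newick().rsplit(":", 1)[0] + ";",
    }
    return msa, truth["newick"], truth


def gen_iid_alignment(
    n_sequences: int, n_positions: int, seed: int, q: float = 0.05
) -> WeightedMSA:
    """Alignment with all cells i.i.d. (uniform over 20 letters at q=0.05).

    Used for null calibration: columns carry no phylogenetic or pair signal.
    """
    rng = np.random.default_rng(seed)
    p = np.full(20, (1.0 - q) / 19.0)
    p[0] = q
    if abs(q - 0.05) < 1e-12:
        p[:] = 0.05
    chars = rng.choice(20, size=(n_sequences, n_positions), p=p)
    rows = ["".join(_AA20[c] for c in row) for row in chars]
    ids = [f"s{k:04d}" for k in range(n_sequences)]
    return WeightedMSA(ids=ids, rows=rows)


def gen_phenotype_table_csv(
    spec: SyntheticSpec, mu: float = 2.3
) -> tuple[str, dict[str, list[float]]]:
    """Phenotype CSV: lethal ddG ~ N(mu + effect, sigma), viable ~ N(mu, sigma).

    The default effect (1.4 kcal/mol at sigma = 1.5, n = 27/35) reproduces
    the magnitude of the published lethal-vs-viable separation: an expected
    t of ~3.6 (one-tailed p of a few 1e-4) and roughly 70% of each class on
    the correct side of the +3 kcal/mol cutoff.
    """
    if spec.phenotype_effect < 0:
        raise ValueError("phenotype effect must be >= 0")
    rng = spec.rng(3)
    lethal = rng.normal(mu + spec.phenotype_effect, spec.phenotype_sigma, spec.n_lethal)
    viable = rng.normal(mu, spec.phenotype_sigma, spec.n_viable)
    rows = ["mutation,ddg,phenotype"]
    truth = {"lethal": lethal.tolist(), "viable": viable.tolist()}
    for k, v in enumerate(lethal):
        rows.append(f"L{k + 1}A,{float(v)!r},lethal")
    for k, v in enumerate(viable):
        rows.append(f"V{k + 1}A,{float(v)!r},viable")
    return "\n".join(rows) + "\n", truth


def write_bundle(spec: SyntheticSpec, outdir: str | Path) -> dict[str, str]:
    """Write a full synthetic input bundle (PDB, CSVs, FASTA, Newick, manifest).

    Returns the mapping of artefact name to file path.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}

    pdb_text, buried = gen_toy_structure(spec)
    (outdir / "structure.pdb").write_text(pdb_text)
    paths["structure"] = str(outdir / "structure.pdb")

    ddg_csv, targets = gen_ddg_scan_csv(spec)
    (outdir / "ddg_scan.csv").write_text(ddg_csv)
    paths["ddg"] = str(outdir / "ddg_scan.csv")

    msa, newick, truth = gen_msa(spec)
    fasta = "".join(f">{sid}\n{row}\n" for sid, row in zip(msa.ids, msa.rows))
    (outdir / "alignment.fasta").write_text(fasta)
    (outdir / "tree.nwk").write_text(newick + "\n")
    paths["alignment"] = str(outdir / "alignment.fasta")
    paths["tree"] = str(outdir / "tree.nwk")

    pheno_csv, _ = gen_phenotype_table_csv(spec)
    (outdir / "phenotypes.csv").write_text(pheno_csv)
    paths["phenotypes"] = str(outdir / "phenotypes.csv")

    manifest = {
        "spec": {k: (list(v) if isinstance(v, tuple) else v)
                 for k, v in asdict(spec).items()},
        "ground_truth": {
            "buried": sorted(list(buried)),
            "entropy_targets_nats": targets,
            "planted_pairs": [(list(p), eps) for p, eps in spec.planted_pairs],
            "expected_entropy_norm": [float(x) for x in truth["expected_entropy_norm"]],
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    paths["manifest"] = str(outdir / "manifest.json")
    return paths
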