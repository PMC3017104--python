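# Methods

## Model and procedure

The package operationalises a stability-versus-conservation analysis in
seven stages. The scientific premise: if thermodynamic stability were the
only force conserving a buried residue, the amino-acid variability observed
across species at that position should match the variability tolerated by
the folding free energy. Stages:

1. **Burial/interface calls** from a structure, via dot-surface SASA.
2. **Stability entropies** from a ΔΔG mutational scan, via Boltzmann
   propensities.
3. **Evolutionary entropies** from a weighted alignment.
4. **Correlation and partition** of the two entropy profiles.
5. **Coevolution scan** (normalised MI, Z-scores, tree-based shuffle null).
6. **Per-node conservation profiles** on a neighbor-joining tree.
7. **Phenotype comparison** (ΔΔG-cutoff classifier, one-tailed t-test).

### Dot-surface SASA

Each atom's van der Waals sphere (Bondi radii, C = 1.70 Å convention) is
inflated by the probe radius and covered with an `n_dots` Fibonacci lattice.
A dot is exposed iff it lies outside every neighbour's inflated sphere;
per-atom SASA is the exposed fraction times 4π(r+probe)². The lattice is
deterministic (seedless) and body-fixed, so results are exactly reproducible
but individual atoms can shift by up to ~1–2% of their area under rigid
rotations (the discretization scale at 1024 dots); totals are stable to
<0.5%. Agreement with closed-form one- and two-sphere areas is within 2% at
1024 dots. Burial uses a strict `SASA < threshold` comparison
(default 1.0 Å², configurable) on whole-residue SASA of the full complex;
the side-chain-only alternative is not implemented. Interfaces use a
heavy-atom contact cutoff (default 4.5 Å) as a geometric surrogate for
contact persistence in simulation, plus verbatim override lists for curated
interface sets.

### Boltzmann entropies from ΔΔG

Propensities are `p_i ∝ exp(−ΔΔG_i / k_B T)` with k_B = 0.0019872
kcal/(mol·K) and T = 300 K by default. The alphabet is the native plus the
17 scanned mutants (18 letters; C and P are never scanned), while the
entropy normaliser stays ln 20 so values are comparable with
full-alphabet evolutionary entropies; a maximally flat scan therefore tops
out at ln 18 / ln 20 ≈ 0.965, not 1. Computation subtracts the max before
exponentiating, making the result exactly shift-invariant. Binding-type
ΔΔG rows (interface residues) are treated identically downstream and
distinguished only by a tag. The lethality cutoff comparison is inclusive
(ΔΔG ≥ +3 kcal/mol → predicted lethal) so a mutation printed exactly at the
cutoff is called destabilising. The t-test is the classical pooled-variance
two-sample test, one-tailed for mean(lethal) > mean(viable); Welch is
available behind a flag.

### Alignment entropies and weighting

Henikoff position-based weights: per column each sequence earns 1/(r·s)
(r = distinct symbols, s = multiplicity of its symbol; gaps count as a
symbol type), summed over columns and normalised to 1. Column entropies use
weighted frequencies with gaps excluded and renormalised (HSSP-style);
all-gap columns are flagged NaN. Correlation p-values use the t-transform
t = r√(n−2)/√(1−r²), two-sided (this reproduces published (r, n, p)
triples). The three-set partition: evolutionary entropy ≥ `outlier_evo_min`
(default 0.2 normalised) → outlier; remaining positions within 2× the RMS
residual of a line fitted through them → correlated (the slope refitted on
that set is reported); rest → over-conserved. The thresholds are reported
with the labels since no canonical values exist.

### Coevolution

MI and all entropies use the same Henikoff weights. Sequences gapped at
either column of a pair are dropped and weights renormalised (a gap-as-21st
symbol mode is configurable at the encoding level). mi_norm = MI/H(i,j)
with the convention 0 when H(i,j) = 0; pairs are computed on the ordered
(min, max) index pair so symmetry is exact. Z-scores standardise mi_norm
against all analysed pairs (mean 0, sd 1 by construction); Z ≥ 4 flags
candidates. The shuffle null swaps the column-j symbols of sequence pairs
sampled with probability ∝ exp(−λ·d(a,b)); λ defaults to 1/mean(d), and
λ = 0 reduces to a uniform permutation (verified against an independent
uniform-permutation oracle). Defaults are 100 iterations of 2000 swaps;
the empirical P is floored at 1/(iterations+1), so the resolution at
defaults is ~0.01. Spatial annotation uses Cβ–Cβ distance (Cα for glycine)
with an 8 Å proximal cutoff.

### Phylogeny

Kimura-corrected protein distance d = −ln(1 − p − p²/5) over columns
ungapped in both sequences. The correction saturates at p ≈ 0.854; by
contract this raises an error naming the pair, and a "cap" mode (clamp at
10 substitutions/site, the common guide-tree convention) is available and
used by the pipeline for robustness on highly diverged alignments.
Neighbor joining is delegated to scikit-bio with ids fed in sorted order
(deterministic tie-breaks) and negative branch lengths clamped to zero; on
additive matrices the tree reproduces pairwise distances exactly. Node
profiles are unweighted leaf-count frequencies with gaps excluded,
preferred residue = argmax with alphabetical tie-break. A position is
tree-determinant when ≥ 2 disjoint internal nodes, each covering ≥ 10% of
leaves, prefer different residues at within-clade frequency ≥ 0.8
(thresholds configurable; no published values exist).

## Synthetic data: what it emulates, what it does not

The generators are deterministic given the spec seed (streams are derived
per generator, so each artefact is independently reproducible).

* **Toy structure**: a central atom enclosed by a 26-direction shell at
  2 Å gives a provably zero-SASA core (the shell directions' angular
  covering radius is far below the occlusion half-angle), with exposed
  shell residues; extra residues go on a distant ring. It exercises the
  burial logic, not protein geometry: no side chains, no packing realism.
* **ΔΔG scans**: per position a target entropy is drawn (or supplied) and
  the ΔΔG gap solved by root finding, so planted entropies round-trip
  through the CSV to 1e-9. With probability 0.25 the preferred letter is a
  mutant, planting imperfect native recapitulation (~75%, the level seen in
  optimised cores). Gaps are uniform across mutants — no chemistry-aware
  substitution structure.
* **Alignments**: characters evolve down a balanced ultrametric tree
  (equal edge lengths per level), each site redrawn from its stationary
  distribution (dominant letter mass q, rest uniform) with probability
  1−exp(−rate·t) per branch. The default rate of 3 events per unit depth
  makes a depth-1 tree span eukaryote-wide divergence at variable sites.
  Planted pairs inherit a latent binary state down the tree and emit
  state-specific letter pairs with probability ε — so planted coevolution
  is phylogeny-aware and the tree-based null is meaningfully exercised.
  No indels by default (optional gap injection), no rate heterogeneity, no
  empirical substitution matrix: passing tests show the statistics behave
  correctly under the model, not that real alignments are this clean.
* **Phenotypes**: lethal ΔΔG ~ N(μ+effect, σ), viable ~ N(μ, σ) with
  n = 27/35. Defaults (μ = 2.3, effect = 1.4, σ = 1.5 kcal/mol) reproduce
  the magnitude of the published lethal/viable separation: expected t ≈ 3.6
  (one-tailed p of a few 1e-4) and roughly 70% of each class on the correct
  side of the +3 kcal/mol cutoff.

## Numerical choices

* Boltzmann weights: max-subtraction before exponentiation; probabilities
  validated to sum to 1 within 1e-9.
* Entropy: 0·ln 0 terms dropped; tiny negative MI from rounding clipped at
  0 and mi_norm clipped at 1.
* Root finding for planted entropies: Brent's method at xtol 1e-13.
* NJ tie-breaks: lexicographic id order into the solver.
* Degenerate inputs: zero-variance correlation → error; all-identical
  mi_norm across pairs → error (no Z-scale); zero pooled variance with
  equal means → t-test p = 0.5; all-gap columns → NaN, flagged.
* P-value floors: empirical shuffle p of 0 reported as 1/(n_iterations+1).

## Design choices that were genuinely open

* Propensity alphabet: native included (18 letters) — the native is a
  legitimate, indeed the reference, state of the Boltzmann ensemble; the
  17-letter alternative would make the native probability implicit.
* Z-score population: all analysed pairs, not only pairs involving
  buried/interface residues (a restricted mode can be had by passing a
  column subset).
* Shuffle-probability decay: exponential in genetic distance with
  λ = 1/mean(d); the normalisation and λ are recorded in output metadata.
* Evolutionary entropy source: recomputed from the alignment with Henikoff
  weights; a reader for external per-position entropy tables (e.g. an HSSP
  extract) is provided for users who prefer database profiles.
* Pipeline reports are timestamp-free so identical config+seed runs are
  byte-identical; timestamps live in the log.

## Problem sizes

The test suite and acceptance script run everything at desk scale, chosen
to make the statistical checks sharp while staying light: null calibration
at 500 sequences × 50 columns across 10–20 seeds (≥ 12,000 pairs),
planted-pair recovery at 200 sequences with three planted pairs, phenotype
null uniformity across 200 seeds, 10⁴ fuzz cases for the MI identities and
10³ for the Boltzmann properties.

## Known limitations

* SASA is dot-based, not analytic; hydrogens are ignored and nucleic-acid
  chains are excluded by design.
* The interface definition is geometric; it will not reproduce
  contact-persistence calls from molecular dynamics in borderline cases.
* Kimura distances saturate for extremely diverged pairs; the cap mode
  trades accuracy for robustness there.
* The coevolution null's swap-probability form (exponential decay) is one
  reasonable choice among several used in tree-aware shuffling; results
  near the significance boundary can depend on λ.
* No APC or other MI background corrections are applied.
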