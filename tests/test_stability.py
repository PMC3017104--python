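"""Boltzmann propensities, positional entropy and phenotype comparisons."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from stabcons.stability import (
    KB_KCAL,
    SCAN_MUTANT_ALPHABET,
    MutantPhenotype,
    boltzmann_propensities,
    classify_mutations,
    lethal_viable_ttest,
    native_recapitulation,
    position_weight_matrix,
    positional_entropy,
    propensity_profile,
    read_ddg_table,
)
from stabcons.synthetic import SyntheticSpec, gen_ddg_scan_csv

from conftest import make_scan

KT300 = KB_KCAL * 300.0  # 0.59616 kcal/mol


def full_scan_csv(ddg: float = 1.0) -> str:
    rows = ["chain,position,wt_aa,mut_aa,ddg,sem,ddg_type",
            "A,1,A,A,0.0,0.0,stability"]
    rows += [f"A,1,A,{m},{ddg},0.1,stability" for m in SCAN_MUTANT_ALPHABET if m != "A"]
    return "\n".join(rows) + "\n"


class TestReadDdgTable:
    def test_full_position_has_18_letter_alphabet(self):
        scan = read_ddg_table(full_scan_csv())
        assert len(scan.records[("A", 1)]) == 18
        assert not scan.warnings

    def test_cysteine_mutant_rejected(self):
        bad = full_scan_csv().replace("A,1,A,D,", "A,1,A,C,")
        with pytest.raises(ValueError, match="C"):
            read_ddg_table(bad)

    def test_duplicate_record_rejected(self):
        csv = full_scan_csv() + "A,1,A,D,2.0,0.1,stability\n"
        with pytest.raises(ValueError, match="duplicate"):
            read_ddg_table(csv)

    def test_non_numeric_ddg_names_row(self):
        csv = full_scan_csv().replace("A,1,A,D,1.0", "A,1,A,D,oops")
        with pytest.raises(ValueError, match="row"):
            read_ddg_table(csv)

    def test_generator_bookkeeping(self):
        csv, _ = gen_ddg_scan_csv(SyntheticSpec(seed=5, n_positions=30))
        scan = read_ddg_table(csv)
        assert len(scan.records) == 30


class TestBoltzmannPropensities:
    def test_all_equal_ddg_is_uniform(self):
        scan = read_ddg_table(full_scan_csv(ddg=0.0))
        entry = boltzmann_propensities(scan, ("A", 1))
        assert all(p == pytest.approx(1 / 18) for p in entry.probabilities.values())

    def test_three_letter_toy_matches_hand_weights(self):
        """ddG of exactly kT gives weights (1, e^-1, e^-1)."""
        scan = make_scan({"V": KT300, "L": KT300})
        entry = boltzmann_propensities(scan, ("A", 1))
        z = 1 + 2 * math.exp(-1)
        assert entry.probabilities["A"] == pytest.approx(1 / z, abs=1e-12)
        assert entry.probabilities["V"] == pytest.approx(math.exp(-1) / z, abs=1e-12)
        # the values the hand computation rounds to
        assert entry.probabilities["A"] == pytest.approx(0.576, abs=5e-4)
        assert entry.probabilities["V"] == pytest.approx(0.212, abs=5e-4)

    def test_dominated_limit(self):
        scan = make_scan({"V": 50.0})
        entry = boltzmann_propensities(scan, ("A", 1))
        assert entry.probabilities["A"] == pytest.approx(1.0, abs=1e-10)
        assert entry.entropy_nats == pytest.approx(0.0, abs=1e-8)

    @settings(deadline=None, derandomize=True)
    @given(st.lists(st.floats(-5, 5), min_size=2, max_size=18),
           st.floats(-20, 20))
    def test_shift_invariance(self, gaps, const):
        """Adding a constant to every ddG leaves propensities unchanged."""
        from stabcons.stability import boltzmann_weights

        p0 = boltzmann_weights(gaps)
        p1 = boltzmann_weights([g + const for g in gaps])
        assert np.allclose(p0, p1, atol=1e-12)

    def test_entropy_nondecreasing_in_temperature(self):
        scan = make_scan({"V": 1.0, "L": 2.5, "I": 0.3})
        temps = [200.0, 300.0, 400.0, 600.0, 1000.0]
        ents = [boltzmann_propensities(scan, ("A", 1), T).entropy_nats for T in temps]
        assert all(a <= b + 1e-12 for a, b in zip(ents, ents[1:]))

    def test_missing_native_row_rejected(self):
        from stabcons.stability import DdgRecord, DdgScan

        scan = DdgScan(records={("A", 1): [DdgRecord("A", 1, "A", "V", 1.0)]})
        with pytest.raises(ValueError, match="native"):
            boltzmann_propensities(scan, ("A", 1))


class TestPositionalEntropy:
    def test_uniform_18_letters(self):
        probs = {a: 1 / 18 for a in SCAN_MUTANT_ALPHABET}
        h, h_norm = positional_entropy(probs)
        assert h == pytest.approx(math.log(18), rel=1e-12)
        assert h_norm == pytest.approx(math.log(18) / math.log(20), rel=1e-12)

    def test_certainty_is_zero(self):
        assert positional_entropy({"A": 1.0}) == (0.0, 0.0)

    def test_direct_summation_oracle(self):
        p = {"A": 0.576, "V": 0.212, "L": 0.212}
        oracle = -sum(v * math.log(v) for v in p.values())
        h, _ = positional_entropy(p)
        assert h == pytest.approx(oracle, rel=1e-12)
        assert h == pytest.approx(0.975, abs=2e-3)


class TestNativeRecapitulation:
    def test_all_native_lowest(self):
        scan = read_ddg_table(full_scan_csv(ddg=1.0))
        assert native_recapitulation(scan) == 1.0

    def test_three_of_four_positions(self):
        rows = ["chain,position,wt_aa,mut_aa,ddg,sem,ddg_type"]
        for pos in range(1, 5):
            rows.append(f"A,{pos},A,A,0.0,0.0,stability")
            ddg = -1.0 if pos == 4 else 1.0  # position 4 prefers the mutant
            rows.append(f"A,{pos},A,V,{ddg},0.1,stability")
        scan = read_ddg_table("\n".join(rows) + "\n")
        assert native_recapitulation(scan) == 0.75

    def test_tie_counts_as_recapitulated(self):
        scan = make_scan({"V": 0.0, "L": 1.0})
        from stabcons.stability import DdgScan

        assert native_recapitulation(scan) == 1.0


class TestClassifyMutations:
    def test_table1_style_calls(self):
        phen = [
            MutantPhenotype("H113A", 8.1, "lethal"),
            MutantPhenotype("A114Y", 3.0, "lethal"),
            MutantPhenotype("X1Y", 0.0, "viable"),
        ]
        conf = classify_mutations(phen, cutoff=3.0)
        assert conf.true_lethal == 2  # 3.0 is inclusive
        assert conf.true_viable == 1

    def test_confusion_monotone_in_cutoff(self):
        rng = np.random.default_rng(0)
        phen = [MutantPhenotype(f"m{k}", float(d), "lethal" if k % 2 else "viable")
                for k, d in enumerate(rng.normal(2, 3, 40))]
        sens, spec = [], []
        for cut in [0.0, 1.0, 2.0, 4.0, 8.0]:
            c = classify_mutations(phen, cutoff=cut)
            sens.append(c.lethal_sensitivity)
            spec.append(c.viable_specificity)
        assert all(a >= b for a, b in zip(sens, sens[1:]))
        assert all(a <= b for a, b in zip(spec, spec[1:]))


class TestLethalViableTtest:
    def test_identical_samples_centre_the_null(self):
        t, p = lethal_viable_ttest([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(0.5)

    def test_permutation_oracle(self):
        """Label-permutation p using the t statistic matches the analytic p."""
        rng = np.random.default_rng(3)
        a = rng.normal(1.5, 1.0, 8)
        b = rng.normal(0.0, 1.0, 8)
        t_obs, p_analytic = lethal_viable_ttest(list(a), list(b))
        pooled = np.concatenate([a, b])
        n_rep = 100_000
        count = 0
        for _ in range(n_rep):
            perm = rng.permutation(pooled)
            x, y = perm[:8], perm[8:]
            sp = math.sqrt(((x.var(ddof=1) + y.var(ddof=1)) / 2) * (2 / 8))
            count += (x.mean() - y.mean()) / sp >= t_obs
        p_perm = count / n_rep
        mc = 3 * math.sqrt(max(p_perm, p_analytic) / n_rep) + 0.01
        assert abs(p_perm - p_analytic) <= mc

    def test_large_effect_bound(self):
        rng = np.random.default_rng(1)
        lethal = rng.normal(5.0, 1.0, 27)
        viable = rng.normal(0.0, 1.0, 35)
        _, p = lethal_viable_ttest(list(lethal), list(viable))
        assert p < 1e-6

    def test_degenerate_sizes_rejected(self):
        with pytest.raises(ValueError):
            lethal_viable_ttest([1.0], [1.0, 2.0])


def test_position_weight_matrix_rows_sum_to_one():
    csv, _ = gen_ddg_scan_csv(SyntheticSpec(seed=2, n_positions=5))
    profile = propensity_profile(read_ddg_table(csv))
    pwm = position_weight_matrix(profile)
    assert pwm.shape == (5, 20)
    assert np.allclose(pwm.sum(axis=1), 1.0)
    assert (pwm[["C", "P"]].to_numpy() == 0).all()
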