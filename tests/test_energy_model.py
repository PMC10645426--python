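"""Energy estimation, ePWM regression, logo normalization, comparisons."""

import math

import numpy as np
import pytest

from specseq import (
    FractionCounts,
    SimulationConfig,
    compare_energy_tables,
    fit_epwm,
    hamming_neighborhood,
    logo_matrix,
    predict_energy,
    relative_energies,
    simulate_counts,
)
from specseq.energy_model import AnchorError, InsufficientOverlapError
from specseq.library_design import BASES


def counts_for(lib, overrides, default=(100.0, 100.0)):
    return FractionCounts(
        library=lib, counts={v: overrides.get(v, default) for v in lib.variants}
    )


class TestRelativeEnergies:
    def test_reference_is_exactly_zero(self, hd_library):
        fc = counts_for(hd_library, {"TAAGGG": (37.0, 91.0)})
        et = relative_energies(fc, "TAATCC", pseudocount=1.0, min_reads=1)
        assert et.energies["TAATCC"] == 0.0

    def test_ln4_odds_ratio(self, hd_library):
        """Counts 50/200 against a 100/100 reference give ddG = ln 4."""
        fc = counts_for(hd_library, {"TAAGGG": (50.0, 200.0)})
        et = relative_energies(fc, "TAATCC", pseudocount=0.0, min_reads=1)
        assert et.energies["TAAGGG"] == pytest.approx(math.log(4.0), abs=1e-12)

    def test_counts_equal_to_reference_give_zero(self, hd_library):
        fc = counts_for(hd_library, {})
        et = relative_energies(fc, "TAATCC", pseudocount=0.0, min_reads=1)
        assert all(e == pytest.approx(0.0) for e in et.energies.values())

    def test_low_count_variants_are_missing_not_zero(self, hd_library):
        fc = counts_for(hd_library, {"TAAGGG": (3.0, 3.0)})
        et = relative_energies(fc, "TAATCC", min_reads=10)
        assert math.isnan(et.energies["TAAGGG"])
        assert et.n_used == 63

    def test_reference_below_floor_is_an_error(self, hd_library):
        fc = counts_for(hd_library, {"TAATCC": (2.0, 2.0)})
        with pytest.raises(AnchorError):
            relative_energies(fc, "TAATCC", min_reads=10)

    def test_reference_change_shifts_by_constant(self, hd_library, truth_pwm):
        """Re-anchoring shifts all energies by one constant; differences persist."""
        cfg = SimulationConfig(
            library=hd_library, truth_pwm=truth_pwm,
            reads_per_fraction=(100_000, 100_000), seed=9,
        )
        fc, _ = simulate_counts(cfg)
        et_a = relative_energies(fc, "TAATCC", min_reads=1)
        et_b = relative_energies(fc, "TAAGGG", min_reads=1)
        diffs = [
            et_a.energies[v] - et_b.energies[v]
            for v in hd_library.variants
            if math.isfinite(et_a.energies[v]) and math.isfinite(et_b.energies[v])
            and v != "TAATCC"
        ]
        assert np.ptp(diffs) < 1e-9


class TestEpwmFit:
    def test_recovers_exact_additive_truth(self, hd_library, truth_pwm):
        """Noiseless additive energies: fit equals truth, residual 0."""
        energies = {v: predict_energy(truth_pwm, v) for v in hd_library.variants}
        from specseq.energy_model import EnergyTable

        et = EnergyTable(
            library=hd_library, reference_variant="TAATCC",
            energies=energies, pseudocount=0.0, min_reads=0,
        )
        pwm = fit_epwm(et, max_mismatch=2)
        for key, value in pwm.beta.items():
            assert value == pytest.approx(truth_pwm.beta[key], abs=1e-9)
        assert pwm.fit.residual_sd == pytest.approx(0.0, abs=1e-9)
        assert predict_energy(pwm, "TAATCC") == 0.0

    def test_matches_normal_equations_oracle(self, hd_library, truth_pwm):
        """lstsq fit equals a brute-force normal-equations solve."""
        cfg = SimulationConfig(
            library=hd_library, truth_pwm=truth_pwm,
            reads_per_fraction=(200_000, 200_000), seed=13,
        )
        fc, _ = simulate_counts(cfg)
        et = relative_energies(fc, "TAATCC")
        pwm = fit_epwm(et, max_mismatch=2)

        ref = "TAATCC"
        hood = sorted(
            set(et.measured()) & hamming_neighborhood(ref, hd_library, 2).members
        )
        cols = [
            (p, b)
            for p in hd_library.variable_positions
            for b in BASES
            if b != ref[p]
        ]
        X = np.array(
            [[1.0 if v[p] == b else 0.0 for (p, b) in cols] for v in hood]
        )
        y = np.array([et.energies[v] for v in hood])
        beta_oracle = np.linalg.solve(X.T @ X, X.T @ y)
        for (p, b), expected in zip(cols, beta_oracle):
            assert pwm.beta[(p, b)] == pytest.approx(expected, abs=1e-9)

    def test_double_mutant_prediction_is_additive(self, hd_library, truth_pwm):
        singles = ("TAAGCC", "TAATGC")
        double = "TAAGGC"
        pred = {v: predict_energy(truth_pwm, v) for v in (*singles, double)}
        assert pred[double] == pytest.approx(
            pred["TAAGCC"] + pred["TAATGC"], abs=1e-12
        )

    def test_unobserved_base_reported_missing(self, hd_library):
        """A base absent from the fit neighborhood gets a NaN coefficient."""
        from specseq.energy_model import EnergyTable

        ref = "TAATCC"
        # only single mutants at the last position, and only two of them
        energies = {v: float("nan") for v in hd_library.variants}
        energies.update({ref: 0.0, "TAATCA": 0.5, "TAATCG": 0.9})
        et = EnergyTable(
            library=hd_library, reference_variant=ref,
            energies=energies, pseudocount=0.0, min_reads=0,
        )
        pwm = fit_epwm(et, max_mismatch=2)
        assert math.isnan(pwm.beta[(5, "T")])
        assert pwm.beta[(5, "A")] == pytest.approx(0.5)
        assert math.isnan(predict_energy(pwm, "TAATCT"))

    def test_pattern_violation_raises(self, truth_pwm):
        from specseq.library_design import MembershipError

        with pytest.raises(MembershipError):
            predict_energy(truth_pwm, "GGGTCC")


class TestLogoMatrix:
    def test_columns_are_mean_centered(self, hd_library, truth_pwm):
        lm = logo_matrix(truth_pwm)
        frame = lm.to_frame()
        assert np.all(np.abs(frame[list(BASES)].sum(axis=1)) < 1e-9)
        # display is the negation
        assert np.allclose(
            lm.display[list(BASES)].to_numpy(), -frame[list(BASES)].to_numpy()
        )

    def test_known_column_centering(self, hd_library):
        from specseq.energy_model import EnergyPWM, FitStats

        beta = {(p, b): 0.0 for p in hd_library.variable_positions for b in BASES}
        for i, b in enumerate(BASES):
            beta[(3, b)] = float(i)  # column (0, 1, 2, 3)
        pwm = EnergyPWM(
            library=hd_library, reference_variant="TAAACC", beta=beta,
            fit=FitStats(1.0, 0.0, 0),
        )
        lm = logo_matrix(pwm)
        assert [lm.columns[3][b] for b in BASES] == [-1.5, -0.5, 0.5, 1.5]
        # all-equal columns center to zero
        assert all(lm.columns[4][b] == 0.0 for b in BASES)

    def test_centering_is_idempotent(self, truth_pwm):
        lm = logo_matrix(truth_pwm)
        again = {
            p: {b: v - np.mean(list(col.values())) for b, v in col.items()}
            for p, col in lm.columns.items()
        }
        for p, col in lm.columns.items():
            for b in BASES:
                assert col[b] == pytest.approx(again[p][b], abs=1e-12)

    def test_fixed_positions_flagged(self, hd_library, truth_pwm):
        lm = logo_matrix(truth_pwm)
        assert lm.fixed_positions == {0: "T", 1: "A", 2: "A"}


class TestComparison:
    def test_identical_tables(self, hd_library, truth_pwm):
        cfg = SimulationConfig(
            library=hd_library, truth_pwm=truth_pwm,
            reads_per_fraction=(50_000, 50_000), seed=21,
        )
        fc, _ = simulate_counts(cfg)
        et = relative_energies(fc, "TAATCC")
        rep = compare_energy_tables(et, et)
        assert rep.pearson_r == pytest.approx(1.0)
        assert rep.rms_difference == 0.0
        assert rep.noise_level == 0.0
        assert rep.fit_slope == pytest.approx(1.0)

    def test_scaled_table_recovers_slope(self, hd_library, truth_pwm):
        from specseq.energy_model import EnergyTable

        energies = {v: predict_energy(truth_pwm, v) for v in hd_library.variants}
        a = EnergyTable(hd_library, "TAATCC", energies, 0.0, 0)
        b = EnergyTable(
            hd_library, "TAATCC", {v: 0.5 * e for v, e in energies.items()}, 0.0, 0
        )
        rep = compare_energy_tables(a, b)
        assert rep.fit_slope == pytest.approx(0.5, abs=1e-9)
        assert rep.fit_intercept == pytest.approx(0.0, abs=1e-9)
        assert rep.pearson_r == pytest.approx(1.0)

    def test_insufficient_overlap(self, hd_library):
        from specseq.energy_model import EnergyTable

        nan = float("nan")
        sparse = {v: nan for v in hd_library.variants}
        sparse["TAATCC"] = 0.0
        sparse["TAAGGG"] = 1.0
        a = EnergyTable(hd_library, "TAATCC", sparse, 0.0, 0)
        with pytest.raises(InsufficientOverlapError):
            compare_energy_tables(a, a)


def test_estimator_rmse_decreases_with_depth(hd_library, truth_pwm):
    """Consistency: deeper sequencing shrinks the median absolute error."""
    med = {}
    for depth in (1_000, 100_000):
        cfg = SimulationConfig(
            library=hd_library, truth_pwm=truth_pwm,
            reads_per_fraction=(depth, depth), seed=31,
        )
        fc, truth = simulate_counts(cfg)
        et = relative_energies(fc, "TAATCC", min_reads=1)
        errs = [
            abs(et.energies[v] - truth.energies[v])
            for v in hd_library.variants
            if math.isfinite(et.energies[v])
        ]
        med[depth] = np.median(errs)
    assert med[100_000] < med[1_000]
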