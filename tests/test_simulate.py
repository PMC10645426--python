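"""Equilibrium simulator and targetome table generator."""

import math

import numpy as np
import pytest

from specseq import (
    SimulationConfig,
    emit_reads,
    make_truth_pwm,
    occupancy,
    predict_energy,
    relative_energies,
    simulate_counts,
    simulate_targetome_tables,
)


class TestOccupancy:
    @pytest.mark.parametrize(
        "energy, activity, expected",
        [
            (0.0, 1.0, 0.5),
            (math.log(4.0), 1.0, 0.2),  # 0.25 / 1.25
            (50.0, 1.0, 0.0),
            (0.0, 3.0, 0.75),
        ],
    )
    def test_values(self, energy, activity, expected):
        assert occupancy(energy, activity) == pytest.approx(expected, abs=1e-12)

    def test_strictly_decreasing_in_energy(self):
        es = np.linspace(-2, 5, 50)
        thetas = [occupancy(e, 1.7) for e in es]
        assert all(a > b for a, b in zip(thetas, thetas[1:]))


class TestSimulateCounts:
    @pytest.mark.parametrize("activity", [0.1, 1.0, 10.0])
    def test_expected_mode_recovers_truth_exactly(self, hd_library, truth_pwm,
                                                  activity):
        """Activity cancels: expected-count estimates equal truth to 1e-12 kT."""
        cfg = SimulationConfig(
            library=hd_library, truth_pwm=truth_pwm, activity=activity, seed=1
        )
        fc, truth = simulate_counts(cfg, mode="expected")
        et = relative_energies(fc, "TAATCC", pseudocount=0.0, min_reads=0)
        for v in hd_library.variants:
            assert abs(et.energies[v] - truth.energies[v]) < 1e-12

    def test_same_seed_is_deterministic(self, hd_library, truth_pwm):
        cfg = SimulationConfig(
            library=hd_library, truth_pwm=truth_pwm,
            reads_per_fraction=(10_000, 10_000), seed=42,
        )
        fc1, _ = simulate_counts(cfg)
        fc2, _ = simulate_counts(cfg)
        assert fc1.counts == fc2.counts

    def test_doubling_activity_doubles_odds_not_energies(self, hd_library,
                                                         truth_pwm):
        ets = {}
        for a in (1.0, 2.0):
            cfg = SimulationConfig(
                library=hd_library, truth_pwm=truth_pwm, activity=a, seed=1
            )
            fc, _ = simulate_counts(cfg, mode="expected")
            nb, nu = zip(*(fc.counts[v] for v in hd_library.variants))
            odds = np.array(nb) / np.array(nu)
            ets[a] = (
                odds,
                relative_energies(fc, "TAATCC", pseudocount=0.0, min_reads=0),
            )
        # raw odds scale with activity (up to pool renormalization) ...
        ratio = ets[2.0][0] / ets[1.0][0]
        assert np.allclose(ratio, ratio[0])
        # ... but the estimated energies are unchanged
        for v in hd_library.variants:
            assert ets[1.0][1].energies[v] == pytest.approx(
                ets[2.0][1].energies[v], abs=1e-12
            )

    def test_degenerate_pool_raises(self, hd_library):
        flat = make_truth_pwm(hd_library, "TAATCC", energy_scale=0.0)
        cfg = SimulationConfig(
            library=hd_library, truth_pwm=flat, activity=1e12, seed=0
        )
        # occupancies all ~1: unbound pool weight underflows to 0 is not
        # guaranteed at 1e12, so push further
        cfg.activity = 1e300
        with pytest.raises(ValueError, match="unbound"):
            simulate_counts(cfg)


class TestEmitReads:
    def test_seed_determinism(self, hd_library, truth_pwm):
        cfg = SimulationConfig(
            library=hd_library, truth_pwm=truth_pwm,
            reads_per_fraction=(2_000, 2_000), seed=3,
        )
        fc, _ = simulate_counts(cfg)
        a = emit_reads(fc, hd_library, error_rate=0.02, seed=3)
        b = emit_reads(fc, hd_library, error_rate=0.02, seed=3)
        assert a == b

    def test_error_rate_zero_is_lossless(self, hd_library, truth_pwm):
        from specseq import count_fractions

        cfg = SimulationConfig(
            library=hd_library, truth_pwm=truth_pwm,
            reads_per_fraction=(3_000, 3_000), seed=8,
        )
        fc, _ = simulate_counts(cfg)
        bound, unbound = emit_reads(fc, hd_library, error_rate=0.0, seed=8)
        fc2 = count_fractions(
            (s for _, s in bound), (s for _, s in unbound), hd_library
        )
        assert fc2.counts == fc.counts

    def test_flank_reject_rate_matches_binomial(self, hd_library, truth_pwm):
        """Reject fraction ~ 1-(1-e)^L within a 99% binomial interval."""
        from scipy import stats as sps

        from specseq import count_fractions

        e = 0.01
        n = 20_000
        cfg = SimulationConfig(
            library=hd_library, truth_pwm=truth_pwm,
            reads_per_fraction=(n, n), seed=6,
        )
        fc, _ = simulate_counts(cfg)
        bound, unbound = emit_reads(fc, hd_library, error_rate=e, seed=6)
        fc2 = count_fractions(
            (s for _, s in bound), (s for _, s in unbound), hd_library
        )
        flank_len = len(hd_library.flank5) + len(hd_library.flank3)
        p0 = 1.0 - (1.0 - e) ** flank_len
        for fraction in ("bound", "unbound"):
            k = fc2.discarded[fraction]["flank_mismatch"]
            lo, hi = sps.binom.interval(0.99, n, p0)
            assert lo <= k <= hi


class TestParameterRecovery:
    def test_sampled_mode_recovers_truth(self, hd_library):
        """1e6 reads/fraction: median |ddG error| < 0.05 kT, ePWM within 0.1 kT."""
        from specseq import fit_epwm

        truth_pwm = make_truth_pwm(hd_library, "TAATCC", energy_scale=1.0, seed=2)
        cfg = SimulationConfig(
            library=hd_library, truth_pwm=truth_pwm,
            reads_per_fraction=(1_000_000, 1_000_000), seed=7,
        )
        fc, truth = simulate_counts(cfg)
        et = relative_energies(fc, "TAATCC")
        errs = [
            abs(et.energies[v] - truth.energies[v])
            for v in hd_library.variants
            if math.isfinite(et.energies[v])
        ]
        assert np.median(errs) < 0.05
        pwm = fit_epwm(et, max_mismatch=2)
        for key, value in pwm.beta.items():
            assert abs(value - truth_pwm.beta[key]) < 0.1


class TestTargetomeTables:
    def test_planted_classes_and_peaks(self):
        tt = simulate_targetome_tables(n_genes=200, seed=3)
        counts = tt.truth_labels.value_counts()
        assert counts["dependent_activated"] == 60
        assert counts["dependent_suppressed"] == 20
        assert counts["independent"] == 120
        # every classed gene's peak is planted lost, with strict threshold margins
        chip_lost = tt.chip.loc[sorted(tt.truth_lost_peaks)]
        assert (chip_lost["log2FC"] < -1.0).all()
        assert (chip_lost["fdr"] < 5e-2).all()

    def test_zero_class_proportion(self):
        tt = simulate_targetome_tables(
            n_genes=100,
            class_proportions={
                "dependent_activated": 0.5,
                "dependent_suppressed": 0.0,
                "independent": 0.5,
            },
            seed=1,
        )
        assert (tt.truth_labels == "dependent_suppressed").sum() == 0

    def test_decoy_peaks_are_far_from_every_tss(self):
        tt = simulate_targetome_tables(n_genes=100, seed=9)
        decoys = tt.peaks[tt.peaks["name"].str.startswith("peak_decoy")]
        tss = tt.tss["start"].to_numpy()
        for _, row in decoys.iterrows():
            mid = (row["start"] + row["end"]) / 2
            assert np.abs(tss - mid).min() > 100_000

    def test_activated_genes_rise_monotonically(self):
        tt = simulate_targetome_tables(n_genes=100, seed=12)
        act = tt.dev_expr.loc[tt.truth_labels == "dependent_activated"]
        diffs = act.to_numpy()[:, 1:] - act.to_numpy()[:, :-1]
        assert (diffs > 0).all()

    def test_determinism(self):
        a = simulate_targetome_tables(n_genes=50, seed=5)
        b = simulate_targetome_tables(n_genes=50, seed=5)
        assert a.chip.equals(b.chip)
        assert a.rna_p21.equals(b.rna_p21)
        assert a.dev_expr.equals(b.dev_expr)
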