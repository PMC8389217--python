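"""Experiment drivers: scan, noise grid, best design, perturbation, comparison."""

import numpy as np
import pandas as pd
import pytest

from phobr import ScalingFactors, apply_scaling, steady_state
from phobr.crn import COPIES_PER_UM
from phobr.experiments import (
    NoiseGridResult,
    best_design,
    compare_models,
    noise_grid,
    perturbation_experiment,
    promoter_scan,
    state_to_counts,
)
from phobr.models import build_full_model
from phobr.noise import NoiseSummary


class TestStateToCounts:
    def test_rounding_preserves_promoter_totals(self, full_model):
        x = steady_state(
            apply_scaling(full_model, ScalingFactors(0.1, 1, 1)), tol=np.inf
        )
        counts = state_to_counts(full_model, x)
        for law in full_model.conservation_laws:
            idx = [full_model.index(n) for n in law.species]
            assert counts[idx].sum() == law.total_copies
        assert counts.min() >= 0


@pytest.fixture(scope="module")
def small_scan(full_model):
    return promoter_scan(
        full_model,
        fc=1.0,
        bf_values=[0.5, 1.0, 1.5],
        uf_values=[0.5, 1.0, 1.5],
    )


class TestPromoterScan:
    def test_control_cell_equals_control_steady_state(self, small_scan, full_model):
        control = steady_state(
            apply_scaling(full_model, ScalingFactors(1, 1, 1)), tol=np.inf
        )
        expected = control[full_model.index("pPhoAa")] * COPIES_PER_UM
        got = small_scan.steady_pPhoAa[1, 1]  # (bf=1, uf=1)
        assert got == pytest.approx(expected, rel=1e-6)

    def test_monotone_in_binding_and_unbinding(self, small_scan):
        mat = small_scan.steady_pPhoAa
        assert np.all(np.diff(mat, axis=0) >= -1e-9)  # non-decreasing in bf
        assert np.all(np.diff(mat, axis=1) <= 1e-9)  # non-increasing in uf

    def test_entries_within_promoter_total(self, small_scan):
        assert np.all(small_scan.steady_pPhoAa >= 0)
        assert np.all(small_scan.steady_pPhoAa <= 10 + 1e-9)

    def test_default_grid_has_100_designs(self, full_model):
        res = promoter_scan(full_model, fc=0.3)
        assert res.steady_pPhoAa.shape == (10, 10)
        assert len(res.to_frame()) == 100
        assert res.bf_values[0] == 0.25 and res.bf_values[-1] == 2.5

    def test_empty_grid_rejected(self, full_model):
        with pytest.raises(ValueError):
            promoter_scan(full_model, bf_values=[], uf_values=[1.0])


@pytest.fixture(scope="module")
def tiny_grid(reduced_model):
    # structural checks only: 8 conditions, 2 replicates, short windows
    return noise_grid(
        reduced_model,
        fc_set=(1.0, 0.3),
        bf_set=(0.5, 1.5),
        uf_set=(0.5, 1.5),
        n_reps=2,
        t_run=200.0,
        base_seed=5,
    )


class TestNoiseGrid:
    def test_row_count_and_species(self, tiny_grid):
        df = tiny_grid.to_frame()
        assert len(df) == 8  # pPhoAa only: reduced model has no mRNA
        assert set(df.species) == {"pPhoAa"}
        assert df.n_replicates.eq(2).all()

    def test_seeds_distinct_and_logged(self, tiny_grid):
        all_seeds = [s for seeds in tiny_grid.seeds.values() for s in seeds]
        assert len(all_seeds) == len(set(all_seeds)) == 16

    def test_grid_rerun_is_deterministic(self, reduced_model, tiny_grid):
        again = noise_grid(
            reduced_model,
            fc_set=(1.0, 0.3),
            bf_set=(0.5, 1.5),
            uf_set=(0.5, 1.5),
            n_reps=2,
            t_run=200.0,
            base_seed=5,
        )
        pd.testing.assert_frame_equal(tiny_grid.to_frame(), again.to_frame())


class TestBestDesign:
    def _summary(self, fc, bf, uf, cv):
        mean = 5.0
        sd = cv * mean
        return NoiseSummary(
            species="pPhoAa",
            condition=ScalingFactors(fc, bf, uf),
            mean=mean,
            sd=sd,
            cv=cv,
            ff=cv * cv * mean,
            n_samples=100,
            n_replicates=5,
        )

    def test_known_minimum_is_found(self):
        rows = [
            self._summary(1.0, bf, uf, cv)
            for (bf, uf), cv in {
                (0.5, 0.5): 0.3,
                (0.5, 1.5): 0.5,
                (1.5, 0.5): 0.1,
                (1.5, 1.5): 0.4,
            }.items()
        ]
        grid = NoiseGridResult(rows, 5, 1000.0, 0)
        assert best_design(grid) == {1.0: (1.5, 0.5)}

    def test_single_condition_grid(self):
        grid = NoiseGridResult([self._summary(0.3, 1.0, 1.0, 0.2)], 5, 1000.0, 0)
        assert best_design(grid) == {0.3: (1.0, 1.0)}

    def test_tie_breaks_toward_low_uf_then_high_bf(self):
        rows = [
            self._summary(1.0, bf, uf, 0.2)
            for bf in (0.5, 1.5)
            for uf in (0.5, 1.5)
        ]
        grid = NoiseGridResult(rows, 5, 1000.0, 0)
        assert best_design(grid) == {1.0: (1.5, 0.5)}

    def test_missing_species_errors(self):
        grid = NoiseGridResult([self._summary(1.0, 1.0, 1.0, 0.2)], 5, 1000.0, 0)
        with pytest.raises(ValueError):
            best_design(grid, species="mRNAa")


class TestPerturbationExperiment:
    def test_null_pair_recovers_by_construction(self):
        m = build_full_model(promoter_copies=1, volume=0.1)
        _, report = perturbation_experiment(
            m,
            fc_pairs=[(1.0, 1.0)],
            t_switch=500.0,
            t_end=4000.0,
            n_reps=3,
            base_seed=3,
        )
        # no condition change: post-switch stationary mean stays at the
        # (pre == post) deterministic level up to sampling noise
        assert report.relative_gap.max() < 0.10

    def test_upward_switch_raises_promoter_activity(self):
        m = build_full_model(promoter_copies=1, volume=0.1)
        trajs, report = perturbation_experiment(
            m,
            fc_pairs=[(0.3, 1.0)],
            t_switch=2000.0,
            t_end=10000.0,
            n_reps=3,
            base_seed=11,
        )
        reps = trajs[(0.3, 1.0)]
        pre = np.mean([t.get("pPhoAa")[t.times < 2000].mean() for t in reps])
        post = np.mean([t.get("pPhoAa")[t.times > 8000].mean() for t in reps])
        assert post > pre  # fewer gaps in the active state after starvation


class TestCompareModels:
    def test_full_vs_itself_is_zero(self, full_model):
        df = compare_models(full_model, full_model, fc_set=(1.0,))
        for sp in ("PhoBp", "DiPhoBpp", "pPhoAa", "PhoA"):
            assert df[f"rel_diff_{sp}"].abs().max() < 1e-9

    def test_calibrated_reduction_beats_uncalibrated(self, full_model, reduced_model):
        from phobr.models import build_reduced_model

        uncal = build_reduced_model(k3_multiplier=1.0)
        cal = compare_models(full_model, reduced_model, fc_set=(1.0, 0.1))
        raw = compare_models(full_model, uncal, fc_set=(1.0, 0.1))
        assert (
            raw.rel_diff_DiPhoBpp.abs() > cal.rel_diff_DiPhoBpp.abs()
        ).all()

    def test_peak_flags(self, full_model, reduced_model):
        df = compare_models(full_model, reduced_model, fc_set=(1.0,))
        assert bool(df.full_has_peak.iloc[0]) is True
        assert bool(df.reduced_has_peak.iloc[0]) is False
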