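import numpy as np
import pytest

from evsecretome import (Component, ConditionSpec, ExperimentDesign,
                         PopulationSpec, default_grid, fold_change,
                         profiles_to_rates, read_profile, simulate_experiment,
                         simulate_profile)

TARGETS = {"exomere": 6.69e6, "exosome": 1.72e7,
           "microvesicle": 9.11e6, "apoptotic_body": 2.67e6}


def make_condition(div=3, targets=TARGETS):
    return ConditionSpec(region="cortex", platform="petri", compartment="dish",
                         div=div, condition="pre", timepoint_h=0.0,
                         target_class_medians=dict(targets),
                         cell_seed_density=5e5, collection_interval_days=3.0)


class TestSimulateProfile:
    def test_zero_abundance_gives_zero_profile(self):
        spec = PopulationSpec((Component("exosome", np.log(40), 0.2, 0.0),))
        prof = simulate_profile(spec, default_grid())
        assert prof.total == 0.0

    def test_mode_near_component_median(self):
        spec = PopulationSpec((Component("exosome", np.log(40), 0.15, 1.0),))
        grid = default_grid()
        prof = simulate_profile(spec, grid)
        peak = grid[np.argmax(prof.count_rate)]
        step = np.exp(np.log(5000 / 15) / 199)
        assert 40 / step <= peak <= 40 * step

    def test_seed_determinism(self):
        spec = PopulationSpec((Component("exosome", np.log(40), 0.2, 1.0),),
                              noise_cv=0.3, seed=42)
        grid = default_grid()
        p1 = simulate_profile(spec, grid)
        p2 = simulate_profile(spec, grid)
        np.testing.assert_array_equal(p1.count_rate, p2.count_rate)
        p3 = simulate_profile(PopulationSpec(spec.components, 0.3, seed=43), grid)
        assert not np.array_equal(p1.count_rate, p3.count_rate)

    def test_component_median_must_lie_in_class(self):
        with pytest.raises(ValueError, match="outside its class"):
            PopulationSpec((Component("exosome", np.log(200), 0.2, 1.0),))

    def test_empty_grid_rejected(self):
        spec = PopulationSpec((Component("exosome", np.log(40), 0.2, 1.0),))
        with pytest.raises(ValueError):
            simulate_profile(spec, np.array([]))


class TestSimulateExperiment:
    def test_noiseless_recovery_is_exact(self):
        design = ExperimentDesign(conditions=(make_condition(),), n_bio=3,
                                  noise_cv=0.0)
        table = profiles_to_rates(simulate_experiment(design, seed=0))
        for name, target in TARGETS.items():
            assert table[name].median() == pytest.approx(target, rel=1e-9)

    def test_replicate_structure(self):
        design = ExperimentDesign(conditions=(make_condition(),), n_bio=4)
        profiles = simulate_experiment(design, seed=0)
        assert len(profiles) == 4 * 7
        ids = {p.metadata.sample_id for p in profiles}
        assert len(ids) == 28

    def test_noisy_parameter_recovery_within_5_percent(self):
        # median over seeds of the recovered class medians vs design values
        design = ExperimentDesign(conditions=(make_condition(),), n_bio=10,
                                  noise_cv=0.3)
        est = {name: [] for name in TARGETS}
        for seed in range(50):
            table = profiles_to_rates(simulate_experiment(design, seed=seed))
            for name in TARGETS:
                est[name].append(table[name].median())
        for name, target in TARGETS.items():
            assert np.median(est[name]) == pytest.approx(target, rel=0.05)

    def test_designed_contrast_detected(self):
        # designed fold >= 3 at noise_cv 0.5 is found significant in most seeds
        from evsecretome import TestPolicy, compare
        lo = dict(TARGETS)
        hi = {k: (3.2 * v if k == "exosome" else v) for k, v in TARGETS.items()}
        detected = 0
        n_seeds = 10
        for seed in range(n_seeds):
            design = ExperimentDesign(
                conditions=(make_condition(3, lo), make_condition(9, hi)),
                n_bio=3, noise_cv=0.5)
            table = profiles_to_rates(simulate_experiment(design, seed=100 + seed))
            a = table.loc[table["div"] == 3, "exosome"]
            b = table.loc[table["div"] == 9, "exosome"]
            detected += compare(a, b, TestPolicy(alpha=0.05)).significant
        assert detected >= 0.8 * n_seeds

    def test_unrealizable_target_rejected(self):
        # positive target for a class with no grid support
        bad = make_condition(targets={**TARGETS, "apoptotic_body": 1e6})
        grid = default_grid()[default_grid() < 500]  # drop apoptotic-body radii
        design = ExperimentDesign(conditions=(bad,), n_bio=3)
        with pytest.raises(ValueError, match="no support"):
            simulate_experiment(design, seed=0, grid=grid)

    def test_emitted_files_roundtrip(self, tmp_path):
        design = ExperimentDesign(conditions=(make_condition(),), n_bio=3,
                                  noise_cv=0.2)
        profiles = simulate_experiment(design, seed=5, out_dir=tmp_path)
        files = sorted(tmp_path.glob("*.csv"))
        assert len(files) == len(profiles)
        by_id = {p.metadata.sample_id: p for p in profiles}
        back = read_profile(files[0])
        orig = by_id[back.metadata.sample_id]
        np.testing.assert_array_equal(back.grid, orig.grid)
        np.testing.assert_array_equal(back.count_rate, orig.count_rate)

    def test_design_structure_constraints(self):
        with pytest.raises(ValueError):
            ExperimentDesign(conditions=(make_condition(),), n_bio=2)
        with pytest.raises(ValueError):
            ExperimentDesign(conditions=(make_condition(),), n_meas=5)
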