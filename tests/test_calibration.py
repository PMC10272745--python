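"""Synthetic data generation and parameter recovery."""

import numpy as np
import pandas as pd
import pytest

import itpk
from itpk import (
    FitSpec,
    FreeParameter,
    PKDataset,
    fit,
    fit_partition,
    generate_synthetic,
    get_parameter,
    objective,
    set_parameter,
    simulate,
)
from itpk.calibration import lognormal_noise_factors
from itpk.model_core import ConfigurationError

from conftest import single_dose_schedule

TIMES = np.linspace(60.0, 1440.0, 8)


@pytest.fixture()
def small_problem(small_fast_params):
    schedule = single_dose_schedule()
    design = {"spinal_csf:lumbar": TIMES, "blood": TIMES}
    ds = generate_synthetic(small_fast_params, schedule, design, noise_cv=0.0,
                            seed=0, truth={"transport.dispersion_D":
                                           small_fast_params.transport.dispersion_D})
    return small_fast_params, schedule, ds


class TestParameterPaths:
    @pytest.mark.parametrize("path", [
        "transport.dispersion_D",
        "transport.clearance_k.5",
        "exchange.exchange_U.1-2",
        "exchange.stickiness_beta.4-5",
    ])
    def test_get_set_round_trip(self, ref_params, path):
        updated = set_parameter(ref_params, path, 0.123)
        assert get_parameter(updated, path) == pytest.approx(0.123)
        # the original is untouched (immutably updated)
        assert get_parameter(ref_params, path) != pytest.approx(0.123)

    def test_unknown_path_rejected(self, ref_params):
        with pytest.raises(ConfigurationError):
            get_parameter(ref_params, "geometry.colour")


class TestSyntheticData:
    def test_noise_free_equals_simulator_output(self, small_problem):
        params, schedule, ds = small_problem
        res = simulate(params, schedule, TIMES[-1], output_times=TIMES)
        from itpk.observables import extract_observable
        lumbar = extract_observable(res, "spinal_csf:lumbar")
        got = ds.data[ds.data.observable == "spinal_csf:lumbar"] \
            .sort_values("time_min").concentration_ug_ml.to_numpy()
        assert got == pytest.approx(lumbar, rel=1e-12)

    def test_same_seed_identical_dataset(self, small_fast_params):
        schedule = single_dose_schedule()
        design = {"blood": TIMES}
        d1 = generate_synthetic(small_fast_params, schedule, design,
                                noise_cv=0.3, seed=42)
        d2 = generate_synthetic(small_fast_params, schedule, design,
                                noise_cv=0.3, seed=42)
        pd.testing.assert_frame_equal(d1.data, d2.data)

    def test_lognormal_noise_moments(self):
        """1000 replicate draws at CV=0.2: sample CV in [0.17, 0.23], unit mean."""
        rng = np.random.default_rng(7)
        f = lognormal_noise_factors(rng, 0.2, 1000)
        assert 0.17 <= f.std(ddof=1) / f.mean() <= 0.23
        assert f.mean() == pytest.approx(1.0, abs=0.03)

    def test_unknown_observable_rejected(self, small_fast_params):
        with pytest.raises(ConfigurationError):
            generate_synthetic(small_fast_params, single_dose_schedule(),
                               {"cerebellar_cortex": TIMES})

    def test_csv_round_trip(self, small_problem, tmp_path):
        _, _, ds = small_problem
        path = tmp_path / "ds.csv"
        ds.to_csv(path)
        back = PKDataset.from_csv(path)
        pd.testing.assert_frame_equal(back.data, ds.data)
        assert back.provenance["truth"] == ds.provenance["truth"]


class TestObjective:
    def test_truth_gives_negligible_loss(self, small_problem):
        params, schedule, ds = small_problem
        spec = FitSpec(free=[FreeParameter("transport.dispersion_D", 1e-3, 10.0)])
        loss = objective(spec, [params.transport.dispersion_D],
                         [(ds, schedule)], params)
        assert loss < 1e-10

    def test_perturbing_dispersion_increases_loss(self, small_problem):
        params, schedule, ds = small_problem
        spec = FitSpec(free=[FreeParameter("transport.dispersion_D", 1e-3, 10.0)])
        at_truth = objective(spec, [0.1], [(ds, schedule)], params)
        doubled = objective(spec, [0.2], [(ds, schedule)], params)
        assert doubled > at_truth

    def test_additive_across_datasets(self, small_problem):
        params, schedule, ds = small_problem
        half_a = PKDataset(ds.data[ds.data.observable == "spinal_csf:lumbar"]
                           .reset_index(drop=True))
        half_b = PKDataset(ds.data[ds.data.observable == "blood"]
                           .reset_index(drop=True))
        spec = FitSpec(free=[FreeParameter("transport.dispersion_D", 1e-3, 10.0)])
        la = objective(spec, [0.25], [(half_a, schedule)], params)
        lb = objective(spec, [0.25], [(half_b, schedule)], params)
        lab = objective(spec, [0.25], [(half_a, schedule), (half_b, schedule)],
                        params)
        assert lab == pytest.approx(la + lb, rel=1e-10)


class TestFit:
    def test_dispersion_recovery_noise_free(self, small_problem):
        params, schedule, ds = small_problem
        spec = FitSpec(free=[FreeParameter("transport.dispersion_D", 1e-3, 10.0)])
        result = fit(spec, [(ds, schedule)], params,
                     initial_guess={"transport.dispersion_D": 0.5})
        assert result.success
        assert result.values["transport.dispersion_D"] == pytest.approx(
            0.1, rel=1e-3)
        assert result.recovery["transport.dispersion_D"] < 1e-3

    def test_fit_is_deterministic(self, small_problem):
        params, schedule, ds = small_problem
        spec = FitSpec(free=[FreeParameter("transport.dispersion_D", 1e-3, 10.0)],
                       seed=5)
        r1 = fit(spec, [(ds, schedule)], params, n_multistart=2)
        r2 = fit(spec, [(ds, schedule)], params, n_multistart=2)
        assert r1.values == r2.values
        assert r1.cost == r2.cost

    def test_noisy_recovery_monte_carlo(self, small_fast_params):
        """Median |relative error| on D over 5 noise seeds stays below 15%."""
        schedule = single_dose_schedule()
        spec = FitSpec(free=[FreeParameter("transport.dispersion_D", 1e-3, 10.0)])
        sample_times = np.linspace(240.0, 2880.0, 12)  # scaled 2-day design
        errors = []
        for seed in range(5):
            ds = generate_synthetic(
                small_fast_params, schedule,
                {"spinal_csf:lumbar": sample_times}, noise_cv=0.2, seed=seed,
                truth={"transport.dispersion_D": 0.1})
            result = fit(spec, [(ds, schedule)], small_fast_params,
                         initial_guess={"transport.dispersion_D": 0.3})
            errors.append(result.recovery["transport.dispersion_D"])
        assert np.median(errors) < 0.15

    def test_underdetermined_problem_rejected(self, small_problem):
        params, schedule, ds = small_problem
        tiny = PKDataset(ds.data.iloc[:1].reset_index(drop=True))
        spec = FitSpec(free=[FreeParameter("transport.dispersion_D", 1e-3, 10.0),
                             FreeParameter("exchange.exchange_U.1-2", 1e-4, 1.0)])
        with pytest.raises(ConfigurationError):
            fit(spec, [(tiny, schedule)], params)


class TestFitPartition:
    def _region_data(self, phi, spec, c4):
        t = np.linspace(0.0, 10.0, 6)
        v4 = float(np.sum(spec.region_volume_Vi))
        out = {}
        for name, vi, p in zip(spec.region_names, spec.region_volume_Vi, phi):
            out[name] = (t, p * v4 * c4 / vi)
        return t, out

    @pytest.mark.parametrize("phi", [
        (0.25, 0.25, 0.25, 0.25),
        (0.1, 0.2, 0.3, 0.4),
    ])
    def test_exact_recovery_noise_free(self, ref_params, phi):
        spec = ref_params.partition
        c4 = np.linspace(1.0, 0.1, 6)
        t, data = self._region_data(np.asarray(phi), spec, c4)
        est = fit_partition(data, t, c4, spec)
        assert [est[r] for r in spec.region_names] == pytest.approx(
            list(phi), abs=1e-9)

    def test_estimates_live_on_the_simplex(self, ref_params):
        spec = ref_params.partition
        c4 = np.linspace(1.0, 0.1, 6)
        rng = np.random.default_rng(0)
        t, data = self._region_data(rng.uniform(0.1, 1.0, 4), spec, c4)
        est = fit_partition(data, t, c4, spec)
        vals = np.array([est[r] for r in spec.region_names])
        assert np.all(vals >= 0.0)
        assert vals.sum() == pytest.approx(1.0, abs=1e-12)

    def test_degenerate_data_rejected(self, ref_params):
        spec = ref_params.partition
        t = np.linspace(0.0, 10.0, 6)
        data = {r: (t, np.zeros(6)) for r in spec.region_names}
        with pytest.raises(ConfigurationError):
            fit_partition(data, t, np.zeros(6), spec)
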