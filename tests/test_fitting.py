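"""Cost function, optimizers and the staged estimation pipeline."""

import numpy as np
import pytest

import haloresp as hr
from haloresp.fitting import (
    FitConfig,
    atp_datum_to_model_units,
    cost_terms,
    staged_fit,
)
from haloresp.synthetic_data import SyntheticSpec, generate


class TestDataset:
    def test_iondata_fixture_shape(self, iondata):
        assert iondata.N_K == 6
        assert iondata.N_Na == 5          # missing 40-min Na value dropped
        assert 2400.0 not in iondata.Na_times
        assert iondata.K_times[0] == 0.0 and iondata.K_times[-1] == 3600.0
        assert iondata.K_values[0] == pytest.approx(2.3047)
        assert iondata.ss_pmf == pytest.approx(0.280)
        assert iondata.t_final == 3600.0

    def test_atp_datum_unit_harmonization(self, iondata):
        """3.7 mmol/kg cell water maps onto the model's cell-volume scale
        through the water/volume ratio 0.80/1.36."""
        assert iondata.ss_ATP == pytest.approx(3.7e-3 * 0.80 / 1.36, rel=1e-12)
        assert atp_datum_to_model_units(1.0) == pytest.approx(
            1e-3 * 0.80 / 1.36)

    def test_csv_roundtrip(self, iondata, tmp_path):
        path = tmp_path / "ds.csv"
        iondata.to_csv(path)
        back = hr.FitDataset.from_csv(path)
        assert np.allclose(back.K_values, iondata.K_values)
        assert np.allclose(back.Na_times, iondata.Na_times)
        assert back.ss_ATP == pytest.approx(iondata.ss_ATP, rel=1e-9)
        assert back.t_final == iondata.t_final

    def test_invalid_dataset_rejected(self):
        with pytest.raises(ValueError):
            hr.FitDataset(K_times=[0, 0], K_values=[1, 1], Na_times=[0],
                          Na_values=[1], ss_ATP=1e-3, ss_pmf=0.2)


class TestCost:
    def test_normalization_oracle_single_point(self, iondata):
        """A lone K observation at twice the model value contributes
        (2m−m)²/(2m)² = 1/4 regardless of the magnitude m."""
        m = 0.37
        ds = hr.FitDataset(K_times=[60.0], K_values=[2 * m],
                           Na_times=[60.0], Na_values=[1.0],
                           ss_ATP=1e-3, ss_pmf=0.2)
        cfg = FitConfig()
        terms = cost_terms(np.array([m]), np.array([1.0]), 1e-3, 0.2, ds, cfg)
        assert terms["K"] == pytest.approx(0.25)
        assert terms["Na"] == 0.0
        assert terms["ATP"] == 0.0 and terms["pmf"] == 0.0
        assert terms["total"] == pytest.approx(0.25)

    def test_weighted_scalar_terms(self, iondata):
        ds = hr.FitDataset(K_times=[60.0], K_values=[1.0], Na_times=[60.0],
                           Na_values=[1.0], ss_ATP=2e-3, ss_pmf=0.28)
        cfg = FitConfig(w_ATP=10.0, w_pmf=0.5)
        terms = cost_terms(np.array([1.0]), np.array([1.0]),
                           1.8e-3, 0.21, ds, cfg)
        assert terms["ATP"] == pytest.approx(10.0 * 0.1)
        assert terms["pmf"] == pytest.approx(0.5 * 0.25)

    def test_pair_order_invariance(self):
        """The time-series terms do not depend on the ordering of the
        (time, value) pairs."""
        rng = np.random.default_rng(0)
        data = rng.uniform(1, 3, 6)
        model = rng.uniform(1, 3, 6)
        ds_kwargs = dict(Na_times=[1.0], Na_values=[1.0],
                         ss_ATP=1e-3, ss_pmf=0.2)
        cfg = FitConfig()
        ds = hr.FitDataset(K_times=np.arange(6.0), K_values=data, **ds_kwargs)
        ref = cost_terms(model, np.array([1.0]), 1e-3, 0.2, ds, cfg)["K"]
        perm = rng.permutation(6)
        ds2 = hr.FitDataset(K_times=np.arange(6.0), K_values=data[perm],
                            **ds_kwargs)
        val = cost_terms(model[perm], np.array([1.0]), 1e-3, 0.2, ds2,
                         cfg)["K"]
        assert val == pytest.approx(ref, rel=1e-14)

    def test_zero_at_truth_on_noise_free_data(self, en5):
        spec = SyntheticSpec(true_params=en5, noise_cv=0.0, ss_noise_cv=0.0,
                             seed=0)
        ds = generate(spec)
        assert hr.cost(en5.to_vector(), ds, FitConfig(variant="EN")) < 1e-8

    def test_nonnegative_and_penalty_for_nonfinite(self, iondata):
        cfg = FitConfig(variant="EN")
        p = np.full(8, np.nan)
        assert hr.cost(p, iondata, cfg) == cfg.penalty
        p = hr.load_parameter_set("EN5").to_vector()
        assert hr.cost(p, iondata, cfg) >= 0.0

    def test_wrong_parameter_count_raises(self, iondata):
        with pytest.raises(ValueError, match="expects 8"):
            hr.cost(np.ones(9), iondata, FitConfig(variant="EN"))


class TestOptimize:
    PSTAR = np.array([1.3, 0.7])

    @staticmethod
    def quadratic(p):
        return float(np.sum((p - TestOptimize.PSTAR) ** 2))

    @pytest.mark.parametrize("optimizer", ["nelder_mead",
                                           "simulated_annealing"])
    def test_quadratic_recovery(self, optimizer):
        cfg = FitConfig(optimizer=optimizer, seed=3)
        res = hr.optimize(self.quadratic, cfg, p0=np.ones(2))
        assert np.abs(res.p - self.PSTAR).max() < 1e-4
        assert res.cost < 1e-8

    @pytest.mark.parametrize("seed", [0, 7, 123])
    def test_annealing_trace_nonincreasing(self, seed):
        cfg = FitConfig(optimizer="simulated_annealing", seed=seed,
                        max_iter=2000)
        res = hr.optimize(self.quadratic, cfg, p0=np.ones(2))
        assert np.all(np.diff(res.trace) <= 0)

    def test_annealing_requires_seed(self):
        cfg = FitConfig(optimizer="simulated_annealing", seed=None)
        with pytest.raises(ValueError, match="seed"):
            hr.optimize(self.quadratic, cfg, p0=np.ones(2))

    def test_seeded_annealing_is_deterministic(self):
        cfg = FitConfig(optimizer="simulated_annealing", seed=11,
                        max_iter=1500)
        a = hr.optimize(self.quadratic, cfg, p0=np.ones(2))
        b = hr.optimize(self.quadratic, cfg, p0=np.ones(2))
        assert np.array_equal(a.p, b.p)
        assert np.array_equal(a.trace, b.trace)

    def test_noise_free_refit_improves_and_pins_stiff_parameters(self, en5):
        """Refitting noise-free data from a 1.2× start drives the cost far
        below its initial value and recovers the two stiffest (most
        Fisher-informative) parameters; the sloppy β's stay less
        determined, which is the model's identifiability structure."""
        ds = generate(SyntheticSpec(true_params=en5, noise_cv=0.0,
                                    ss_noise_cv=0.0, seed=0))
        cfg = FitConfig(variant="EN", optimizer="nelder_mead", max_iter=2000)
        p0 = en5.to_vector() * 1.2
        J0 = hr.cost(p0, ds, cfg)
        res = hr.fit(ds, cfg, p0=p0)
        assert res.cost < J0 / 100.0
        rel = np.abs(res.p - en5.to_vector()) / en5.to_vector()
        names = list(en5.free_names)
        assert rel[names.index("gamma_ETCP_pmf")] < 0.10
        assert rel[names.index("gamma_ATPS_ADP")] < 0.10


class TestStagedFit:
    def test_pipeline_topology_and_monotone_simplex(self, iondata):
        """The staged pipeline emits all five stages; the simplex
        refinement cannot end above the manual guess it started from."""
        cfg = FitConfig(variant="EN", seed=5, max_iter=60, sa_stop_T=0.5)
        out = staged_fit("EN", iondata, cfg)
        assert set(out["stages"]) == {
            "stage1_anneal_from_ones", "stage2_manual_guess",
            "stage3_simplex_refinement", "stage4_anneal_refinement",
            "stage5_final_anneal"}
        s2 = out["stages"]["stage2_manual_guess"]
        s3 = out["stages"]["stage3_simplex_refinement"]
        assert s3.cost <= s2.cost
        best = out["selected_result"].cost
        assert best == min(r.cost for r in out["stages"].values())

    def test_electrogenic_stage_estimates_nine_parameters(self, iondata):
        cfg = FitConfig(variant="EG", seed=5, max_iter=25, sa_stop_T=0.8)
        out = staged_fit("EG", iondata, cfg)
        for result in out["stages"].values():
            assert len(result.p) == 9
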