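"""Inverse fitting: estimator consistency, invariances, residual diagnostics."""

import numpy as np
import pandas as pd
import pytest

from slabdiff import (
    DAY_S,
    DiffusionScenario,
    DomainError,
    FitResult,
    Geometry1D,
    IdentifiabilityError,
    LangmuirCoupling,
    MeasurementSet,
    NoiseSpec,
    apply_adsorption_coupling,
    fit_diffusion_coefficient,
    generate_dataset,
    r_squared,
    residual_table,
    subset_fit,
)


@pytest.fixture
def reference_inward():
    """Noiseless inward dataset from known ground truth."""
    geom = Geometry1D.from_mm(20.0)
    scenario = DiffusionScenario(geom, "inward", 3.0e-10, n0=10.0)
    return generate_dataset(scenario), scenario


def template_like(scenario, **overrides):
    kwargs = dict(geometry=scenario.geometry, kind=scenario.kind, D=1e-10)
    if scenario.kind == "inward":
        kwargs["n0"] = scenario.n0
    elif scenario.kind == "outward":
        kwargs["C0"] = scenario.C0
    kwargs.update(overrides)
    return DiffusionScenario(**kwargs)


class TestRSquared:
    def test_perfect_fit_and_mean_baseline(self):
        m = np.array([1.0, 2.0, 5.0])
        assert r_squared(m, m) == pytest.approx(1.0)
        assert r_squared(m, np.full(3, m.mean())) == pytest.approx(0.0)

    def test_hand_computed_value(self):
        assert r_squared([1.0, 2.0, 3.0], [1.0, 2.0, 4.0]) == pytest.approx(0.5)

    def test_undefined_for_constant_measurements(self):
        with pytest.raises(DomainError):
            r_squared([2.0, 2.0], [1.0, 3.0])


class TestSelfConsistency:
    def test_noiseless_inward_recovers_generating_d(self, reference_inward):
        data, scenario = reference_inward
        fit = fit_diffusion_coefficient(data, template_like(scenario))
        assert fit.D_hat == pytest.approx(3.0e-10, rel=1e-3)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-9)
        assert fit.converged

    def test_noiseless_outward_recovers_generating_d(self):
        geom = Geometry1D.from_mm(20.0)
        scenario = DiffusionScenario(geom, "outward", 4.25e-10, C0=3.56)
        data = generate_dataset(scenario)
        fit = fit_diffusion_coefficient(data, template_like(scenario))
        assert fit.D_hat == pytest.approx(4.25e-10, rel=1e-3)

    def test_noisy_recovery_within_monte_carlo_band(self):
        # sd = 0.1 mg/L on a 10 mg/L scale: single-seed estimate within 10%
        geom = Geometry1D.from_mm(20.0)
        scenario = DiffusionScenario(geom, "inward", 3.0e-10, n0=10.0)
        data = generate_dataset(scenario, noise=NoiseSpec(sd=0.1, seed=7))
        fit = fit_diffusion_coefficient(data, template_like(scenario))
        assert fit.D_hat == pytest.approx(3.0e-10, rel=0.10)
        assert fit.r_squared > 0.95

    def test_joint_fit_recovers_depressed_boundary_concentration(self):
        # interface-effect diagnostic: generate with lower true n0, free it
        geom = Geometry1D.from_mm(34.0)
        true = DiffusionScenario(geom, "inward", 3.46e-10, n0=8.61)
        data = generate_dataset(true)
        template = template_like(true, n0=9.50)
        fit = fit_diffusion_coefficient(data, template, free=("D", "n0"))
        assert fit.D_hat == pytest.approx(3.46e-10, rel=1e-3)
        assert fit.free_params["n0"] == pytest.approx(8.61, rel=1e-3)


class TestInvariances:
    def test_scale_invariance_of_d(self, reference_inward):
        data, scenario = reference_inward
        k = 7.3
        scaled_records = data.records.assign(concentration=data.records["concentration"] * k)
        scaled = MeasurementSet(kind="inward", records=scaled_records,
                                geometry=scenario.geometry)
        f1 = fit_diffusion_coefficient(data, template_like(scenario))
        f2 = fit_diffusion_coefficient(scaled, template_like(scenario, n0=scenario.n0 * k))
        assert f2.D_hat == pytest.approx(f1.D_hat, rel=1e-6)

    def test_subset_of_all_labels_is_identity(self, reference_inward):
        data, scenario = reference_inward
        full = fit_diffusion_coefficient(data, template_like(scenario))
        sub = subset_fit(data, ["A", "B", "C", "D", "E"], template_like(scenario))
        assert sub.D_hat == pytest.approx(full.D_hat, rel=1e-9)

    def test_pure_diffusion_subsets_agree(self, reference_inward):
        # a correct model has no concentration-range dependence
        data, scenario = reference_inward
        hi = subset_fit(data, ["A", "B"], template_like(scenario))
        lo = subset_fit(data, ["D", "E"], template_like(scenario))
        assert hi.D_hat == pytest.approx(3.0e-10, rel=5e-3)
        assert lo.D_hat == pytest.approx(3.0e-10, rel=5e-3)


class TestAdsorptionCouplingDiagnostics:
    @pytest.fixture
    def coupled_fit_inputs(self):
        """Langmuir-coupled inward data fitted against the apparent boundary value."""
        geom = Geometry1D.from_mm(34.0)
        scenario = DiffusionScenario(geom, "inward", 2.93e-10, n0=9.50)
        coupling = LangmuirCoupling(q_max=2.0, K=1.0, phi=1.0)
        data = generate_dataset(scenario, coupling=coupling)
        n0_apparent = apply_adsorption_coupling(9.50, coupling)
        template = DiffusionScenario(geom, "inward", 1e-10, n0=n0_apparent)
        return data, template

    def test_low_concentration_subset_inflates_apparent_d(self, coupled_fit_inputs):
        data, template = coupled_fit_inputs
        hi = subset_fit(data, ["A", "B"], template)
        lo = subset_fit(data, ["D", "E"], template)
        assert lo.D_hat > hi.D_hat

    def test_residuals_positive_at_far_low_concentration_positions(self, coupled_fit_inputs):
        data, template = coupled_fit_inputs
        fit = fit_diffusion_coefficient(data, template)
        table = residual_table(data, fit, at_time=3 * DAY_S).table
        ordered = table.sort_values("position_m")
        # measured sits above the fitted surface at the far (lowest-C) position
        assert ordered["residual"].iloc[-1] > 0
        # and the far-end excess dominates the near-end one
        assert ordered["residual"].iloc[-1] > ordered["residual"].iloc[0]


class TestResidualTable:
    @staticmethod
    def _result_from_rows(positions_mm, measured, fitted, t=3 * DAY_S):
        rec = pd.DataFrame({
            "time_s": t,
            "position_m": np.asarray(positions_mm) * 1e-3,
            "concentration": measured,
            "fitted": fitted,
            "residual": np.asarray(measured) - np.asarray(fitted),
        })
        return FitResult(D_hat=1e-10, free_params={"D": 1e-10}, r_squared=0.98,
                         residuals=rec["residual"].to_numpy(), fitted=np.asarray(fitted),
                         n_obs=len(rec), converged=True, diagnostics={"records": rec})

    def test_third_day_percentages_from_printed_inputs(self):
        # near-face row: measured 7.04, fitted 7.21 -> -0.17 mg/L, -2.4%
        # far row: measured 1.91, fitted 1.64 -> +0.27 mg/L, +14.1%
        fit = self._result_from_rows([3.5, 17.5], [7.04, 1.91], [7.21, 1.64])
        data = MeasurementSet(kind="inward", records=fit.diagnostics["records"])
        table = residual_table(data, fit, at_time=3 * DAY_S).table
        assert table["residual"].iloc[0] == pytest.approx(-0.17)
        assert table["percentage_1dp"].iloc[0] == pytest.approx(-2.4)
        assert table["residual"].iloc[1] == pytest.approx(0.27)
        assert table["percentage_1dp"].iloc[1] == pytest.approx(14.1)

    def test_exact_fit_gives_zero_percentage_and_zero_guard(self):
        fit = self._result_from_rows([3.5, 7.0], [5.0, 0.0], [5.0, 0.1])
        data = MeasurementSet(kind="inward", records=fit.diagnostics["records"])
        table = residual_table(data, fit, at_time=3 * DAY_S).table
        assert table["percentage"].iloc[0] == 0.0
        assert np.isnan(table["percentage"].iloc[1])  # measured = 0: undefined


class TestIdentifiability:
    def test_single_time_or_position_rejected(self, reference_inward):
        data, scenario = reference_inward
        one_time = data.records[data.records["time_s"] == DAY_S]
        with pytest.raises(IdentifiabilityError):
            fit_diffusion_coefficient(
                MeasurementSet(kind="inward", records=one_time.reset_index(drop=True)),
                template_like(scenario),
            )

    def test_single_point_subset_rejected(self, reference_inward):
        data, scenario = reference_inward
        single = data.records[(data.records["label"] == "A")
                              & (data.records["time_s"] == DAY_S)]
        sub = MeasurementSet(kind="inward", records=single.reset_index(drop=True))
        with pytest.raises(IdentifiabilityError):
            subset_fit(sub, ["A"], template_like(scenario))
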