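"""Curves, derivative bands, color scale, clustering, and summaries."""

import numpy as np
import pytest

from conftest import random_model
from corthick import fdiff
from corthick.neuralnet import MLPModel
from corthick.preprocess import ScalingTransform, fit_scaler
from corthick.synthetic_cohort import trajectory_template
from corthick.trajectory import (
    AgeGrid,
    DerivativeBand,
    analytic_curve_derivative,
    band_colors,
    cluster_regions,
    derivative_band,
    predict_curve,
    summarize,
    TrajectoryCurve,
    _COLOR_NEUTRAL,
)


def make_model(rng, n_hidden=2, scale=0.8):
    m = random_model(rng, n_hidden, scale)
    m.input_scaler = ScalingTransform(5.0, 96.0)
    m.output_scaler = ScalingTransform(1.3, 4.1)
    m.region, m.hemisphere = "insula", "left"
    return m


class TestAgeGrid:
    def test_validation(self):
        with pytest.raises(ValueError):
            AgeGrid(10, 5)
        with pytest.raises(ValueError):
            AgeGrid(0, 4, 1.0)  # fewer than 7 nodes

    def test_node_count(self):
        assert len(AgeGrid(5, 96, 1.0)) == 92


class TestPredictCurve:
    def test_reproduces_its_own_training_points(self, rng):
        """A model with zero residual at some ages reproduces those values
        when the same ages appear as grid nodes."""
        m = make_model(rng)
        grid = AgeGrid(10, 90, 10.0)
        curve = predict_curve(m, grid)
        direct = m.output_scaler.invert(m.forward(m.input_scaler.apply(grid.ages)))
        assert np.allclose(curve.thickness, direct, atol=1e-15)

    def test_monotone_h0_model_gives_monotone_curve(self):
        m = MLPModel.zeros(0).with_params(np.array([0.8, 0.1]))
        m.input_scaler = ScalingTransform(5.0, 96.0)
        m.output_scaler = ScalingTransform(1.3, 4.1)
        curve = predict_curve(m, AgeGrid(5, 96, 1.0))
        assert np.all(np.diff(curve.thickness) > 0)

    def test_extrapolation_flagged(self, rng):
        m = make_model(rng)
        m.input_scaler = ScalingTransform(20.0, 80.0)
        curve = predict_curve(m, AgeGrid(5, 96, 1.0))
        assert curve.extrapolated[0] and curve.extrapolated[-1]
        assert not curve.extrapolated[len(curve.thickness) // 2]

    def test_missing_scalers_rejected(self, rng):
        with pytest.raises(ValueError):
            predict_curve(random_model(rng, 1), AgeGrid(5, 96))


def test_finite_difference_matches_chain_rule(rng):
    """The 7-point band derivative of a smooth model curve agrees with the
    closed-form tanh chain-rule derivative at interior nodes."""
    for _ in range(5):
        m = make_model(rng, n_hidden=2, scale=1.2)
        grid = AgeGrid(5, 96, 1.0)
        band = derivative_band(predict_curve(m, grid))
        exact = analytic_curve_derivative(m, grid)
        assert np.max(np.abs(band.derivative[3:-3] - exact[3:-3])) < 1e-6


class TestColors:
    def test_zero_derivative_maps_to_neutral_green(self):
        c = band_colors(np.array([0.0]), vmax=0.05)
        assert np.array_equal(c[0], _COLOR_NEUTRAL)

    def test_sign_convention(self):
        c = band_colors(np.array([-0.04, 0.04]), vmax=0.05)
        assert c[0][0] > c[0][2]  # loss: red dominates
        assert c[1][2] > c[1][0]  # gain: blue dominates

    def test_scale_symmetric_about_zero(self):
        """Equal-magnitude derivatives sit at equal distance from neutral."""
        d = 0.03
        cpos = band_colors(np.array([d]), 0.05)[0]
        cneg = band_colors(np.array([-d]), 0.05)[0]
        assert np.linalg.norm(cpos - _COLOR_NEUTRAL) == pytest.approx(
            np.linalg.norm(cneg - _COLOR_NEUTRAL) * np.linalg.norm(
                (np.array([0.129, 0.400, 0.675]) - _COLOR_NEUTRAL)
            ) / np.linalg.norm((np.array([0.698, 0.094, 0.169]) - _COLOR_NEUTRAL))
        )

    def test_saturation_clipped(self):
        c = band_colors(np.array([10.0, -10.0]), 0.05)
        assert np.all((c >= 0) & (c <= 1))


class TestBands:
    def test_constant_archetype_band_is_quiet(self):
        grid = AgeGrid(5, 96, 1.0)
        vals = trajectory_template("constant", grid.ages, 2.5, 0.25)
        curve = TrajectoryCurve("precuneus", "left", grid, vals)
        band = derivative_band(curve, vmax=0.05)
        assert np.max(np.abs(band.derivative)) < 0.015

    def test_change70_band_most_negative_near_70(self):
        grid = AgeGrid(5, 96, 1.0)
        vals = trajectory_template("change70", grid.ages, 2.5, 0.25)
        band = derivative_band(TrajectoryCurve("x", "left", grid, vals))
        age_at_min = grid.ages[np.argmin(band.derivative)]
        assert abs(age_at_min - 70.0) <= 5.0


def template_band(arch, grid, baseline=2.5, amplitude=0.25, name="r", hemi="left"):
    vals = trajectory_template(arch, grid.ages, baseline, amplitude)
    d = fdiff.differentiate(vals, step=grid.step)
    return DerivativeBand(name, hemi, grid, d, band_colors(d, 0.05), 0.05)


class TestClustering:
    def test_identical_bands_share_a_cluster(self):
        grid = AgeGrid(5, 96, 1.0)
        bands = [template_band("change25", grid, name=f"r{i}") for i in range(3)]
        bands += [template_band("change70", grid, name="other")]
        res = cluster_regions(bands, k=2)
        assert len(set(res.labels[:3])) == 1
        assert res.labels[3] != res.labels[0]

    def test_k1_single_cluster(self):
        grid = AgeGrid(5, 96, 1.0)
        bands = [template_band(a, grid, name=a) for a in ("change25", "change70")]
        res = cluster_regions(bands, k=1)
        assert set(res.labels) == {1}

    def test_k_exceeding_band_count_rejected(self):
        grid = AgeGrid(5, 96, 1.0)
        with pytest.raises(ValueError):
            cluster_regions([template_band("multi", grid)], k=3)

    def test_ordering_keeps_clusters_contiguous(self):
        grid = AgeGrid(5, 96, 1.0)
        archs = ["change25", "change70", "change25", "change70", "multi", "multi"]
        bands = [template_band(a, grid, name=f"r{i}") for i, a in enumerate(archs)]
        res = cluster_regions(bands, k=3)
        seq = [res.labels[i] for i in res.order]
        # once a cluster id ends it never reappears
        seen = []
        for lab in seq:
            if lab not in seen:
                seen.append(lab)
        assert seq == sorted(seq, key=seen.index)


class TestSummaries:
    def _models_from_templates(self, archs):
        """Cheap stand-in model set: H=0 nets whose curves are the scaled
        template trends (used only to exercise the summary bookkeeping)."""
        models = {}
        for i, arch in enumerate(archs):
            m = MLPModel.zeros(0).with_params(np.array([-0.3 - 0.1 * i, 0.0]))
            m.input_scaler = ScalingTransform(5.0, 96.0)
            m.output_scaler = ScalingTransform(1.3 + 0.2 * i, 2.9 + 0.2 * i)
            m.region, m.hemisphere = arch, "left"
            models[f"{arch}_{i}"] = m
        return models

    def test_window_extremes_and_linearity(self):
        models = self._models_from_templates(["a", "b", "c"])
        grid = AgeGrid(5, 96, 1.0)
        tables = summarize(models, grid)
        assert set(tables.extremes["window"]) == {"all", "ge40", "ge60"}
        # thickest model is the one with the highest output scaler
        assert tables.extremes.iloc[0]["highest_thickness"] == "c_2"
        assert (tables.linearity["metric"] == "line_r2").all()

    def test_near_linear_curve_has_unit_r2(self):
        m = MLPModel.zeros(0).with_params(np.array([0.05, 0.0]))
        m.input_scaler = ScalingTransform(5.0, 96.0)
        m.output_scaler = ScalingTransform(1.3, 4.1)
        m.region, m.hemisphere = "flat", "left"
        tables = summarize({"flat_left": m}, AgeGrid(5, 96, 1.0))
        from corthick.trajectory import _line_r2

        curve = predict_curve(m, AgeGrid(5, 96, 1.0))
        assert _line_r2(AgeGrid(5, 96, 1.0).ages, curve.thickness) > 0.9999

    def test_empty_window_rejected(self):
        models = self._models_from_templates(["a"])
        with pytest.raises(ValueError):
            summarize(models, AgeGrid(5, 96, 1.0), windows={"late": 200.0})

    def test_per_region_fit_comparison(self, rng):
        """On data with curvature, the network MSE beats the straight-line
        MSE when the network actually fits that curvature."""
        from corthick.cli import fit_region_model
        from corthick.synthetic_cohort import CohortConfig, RegionSpec, generate_cohort
        from corthick.training import LMConfig, SAConfig

        spec = RegionSpec("insula", "left", "change25", 2.9, 0.3, 0.02)
        cohort = generate_cohort(CohortConfig(n_subjects=250, regions=[spec], seed=2))
        res = fit_region_model(
            cohort, "insula_left", 2,
            SAConfig(n_temperatures=30, iters_per_temperature=30),
            LMConfig(), np.random.default_rng(3),
        )
        tables = summarize({"insula_left": res.model}, AgeGrid(5, 96, 1.0), cohort)
        row = tables.per_region.iloc[0]
        assert row["linear_mse"] > row["ann_mse"]
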