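import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from scgnorm import (
    AbundanceTable,
    BiasModel,
    GenePropertyTable,
    MarkerSet,
    Stage,
    apply_bias_correction,
    fit_bias_model,
    fit_shared_bias_model,
    load_bias_model,
    load_default_markers,
    marker_response,
    save_bias_model,
    synth_property_table,
)


class TestMarkerResponse:
    def test_constant(self):
        m = MarkerSet(("M1", "M2", "M3", "M4"))
        r = marker_response(pd.Series(1.0, index=list(m)), m)
        assert np.allclose(r, 1.0)

    def test_hand_example(self):
        m = MarkerSet(("M1", "M2"))
        r = marker_response(pd.Series({"M1": 1.0, "M2": 3.0}), m)
        assert list(r) == [0.5, 1.5]

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 2**32 - 1))
    def test_mean_is_one(self, seed):
        rng = np.random.default_rng(seed)
        m = MarkerSet(tuple(f"M{i}" for i in range(12)))
        abund = pd.Series(rng.gamma(2, 1, 12) + 1e-9, index=list(m))
        assert marker_response(abund, m).mean() == pytest.approx(1.0, rel=1e-12)

    def test_zero_mean_rejected(self):
        m = MarkerSet(("M1", "M2"))
        with pytest.raises(ValueError, match="zero"):
            marker_response(pd.Series({"M1": 0.0, "M2": 0.0}), m)


def _noise_free_fit(seed=3, weight=0.5):
    markers = load_default_markers()
    props, _ = synth_property_table(markers, n_properties=10, seed=seed)
    z = props.values["prop01"]
    z = (z - z.mean()) / z.std(ddof=0)
    responses = 1.0 + weight * z
    model = fit_bias_model(responses, props, folds=5, seed=seed)
    return model


class TestFitBiasModel:
    def test_noise_free_recovery(self):
        model = _noise_free_fit()
        assert model.weights["prop01"] == pytest.approx(0.5, abs=0.05)
        assert model.heldout_r2 > 0.95
        off = model.weights.drop("prop01").abs().max()
        assert off < 0.05

    def test_degenerate_constant_response(self):
        markers = load_default_markers()
        props, _ = synth_property_table(markers, n_properties=5, seed=0)
        responses = pd.Series(1.0, index=list(markers))
        model = fit_bias_model(responses, props, seed=0)
        assert np.allclose(model.weights, 0.0)
        assert model.heldout_r2 == 0.0

    def test_too_few_markers_rejected(self):
        props = GenePropertyTable(
            pd.DataFrame(np.zeros((4, 3)), index=list("abcd"),
                         columns=["p1", "p2", "p3"])
        )
        with pytest.raises(ValueError, match="at least"):
            fit_bias_model(pd.Series(1.0, index=list("abcd")), props, folds=5)

    def test_save_load_round_trip(self, tmp_path):
        model = _noise_free_fit()
        p = tmp_path / "model.tsv"
        save_bias_model(model, p)
        back = load_bias_model(p)
        assert back.intercept == pytest.approx(model.intercept, rel=1e-12)
        assert np.allclose(back.weights, model.weights)
        assert np.allclose(back.prop_means, model.prop_means)
        assert back.heldout_r2 == pytest.approx(model.heldout_r2, rel=1e-12)
        assert back.scope == model.scope


def _table_from_responses(responses: pd.Series, sample="S0", scale=1.0):
    return AbundanceTable(
        pd.DataFrame({sample: responses * scale}), Stage.marker_normalized
    )


class TestSharedModel:
    def test_pooling_identical_samples_matches_per_sample(self):
        markers = load_default_markers()
        props, fold = synth_property_table(
            markers, n_properties=8, true_weights={"prop02": 0.3}, noise_sd=0.05, seed=9
        )
        responses = fold / fold.mean()
        single = fit_bias_model(responses, props, seed=9)
        table = AbundanceTable(
            pd.DataFrame({"S1": responses, "S2": responses}), Stage.marker_normalized
        )
        pooled = fit_shared_bias_model(table, markers, props, seed=9)
        assert pooled.scope == "generic"
        assert np.allclose(pooled.weights, single.weights, atol=0.02)

    def test_shared_linear_bias_recovered(self):
        markers = load_default_markers()
        rng = np.random.default_rng(5)
        props, _ = synth_property_table(markers, n_properties=10, seed=5)
        z = props.values["prop04"]
        z = (z - z.mean()) / z.std(ddof=0)
        cols = {}
        for i in range(6):
            noise = rng.normal(0, 0.05, len(z))
            cols[f"S{i}"] = np.maximum(1.0 + 0.4 * z + noise, 0.05)
        table = AbundanceTable(
            pd.DataFrame(cols, index=list(markers)), Stage.marker_normalized
        )
        model = fit_shared_bias_model(table, markers, props, seed=5)
        assert model.weights["prop04"] == pytest.approx(0.4, abs=0.05)
        assert model.heldout_r2 > 0.5


class TestApplyCorrection:
    def _identity_model(self, props):
        zeros = pd.Series(0.0, index=props.values.columns)
        return BiasModel(
            intercept=1.0, weights=zeros,
            prop_means=pd.Series(0.0, index=zeros.index),
            prop_sds=pd.Series(1.0, index=zeros.index),
            prop_medians=pd.Series(0.0, index=zeros.index),
            alpha=0.0, l1_ratio=0.5, heldout_r2=0.0,
        )

    def test_identity_model(self):
        markers = load_default_markers()
        props, fold = synth_property_table(markers, n_properties=4, seed=1)
        table = _table_from_responses(fold / fold.mean())
        out = apply_bias_correction(table, self._identity_model(props), props)
        assert np.allclose(out.values, table.values)
        assert out.stage is Stage.bias_corrected

    def test_division_by_prediction(self):
        props = GenePropertyTable(pd.DataFrame({"p": [1.0]}, index=["K1"]))
        model = BiasModel(
            intercept=1.0, weights=pd.Series({"p": 1.0}),
            prop_means=pd.Series({"p": 0.0}), prop_sds=pd.Series({"p": 1.0}),
            prop_medians=pd.Series({"p": 0.0}),
            alpha=0.0, l1_ratio=0.5, heldout_r2=0.0,
        )
        table = AbundanceTable(pd.DataFrame({"S": [4.0]}, index=["K1"]),
                               Stage.marker_normalized)
        out = apply_bias_correction(table, model, props)
        # predicted fold-change = 1 + 1*1 = 2; 4 / 2 = 2
        assert out.data.loc["K1", "S"] == pytest.approx(2.0)

    def test_prediction_floor(self):
        props = GenePropertyTable(pd.DataFrame({"p": [-10.0]}, index=["K1"]))
        model = BiasModel(
            intercept=1.0, weights=pd.Series({"p": 1.0}),
            prop_means=pd.Series({"p": 0.0}), prop_sds=pd.Series({"p": 1.0}),
            prop_medians=pd.Series({"p": 0.0}),
            alpha=0.0, l1_ratio=0.5, heldout_r2=0.0,
        )
        table = AbundanceTable(pd.DataFrame({"S": [1.0]}, index=["K1"]),
                               Stage.marker_normalized)
        out = apply_bias_correction(table, model, props)
        assert out.data.loc["K1", "S"] == pytest.approx(1.0 / 0.01)

    def test_kos_without_properties_pass_through(self):
        props = GenePropertyTable(pd.DataFrame({"p": [1.0]}, index=["K1"]))
        model = BiasModel(
            intercept=2.0, weights=pd.Series({"p": 0.0}),
            prop_means=pd.Series({"p": 0.0}), prop_sds=pd.Series({"p": 1.0}),
            prop_medians=pd.Series({"p": 0.0}),
            alpha=0.0, l1_ratio=0.5, heldout_r2=0.0,
        )
        table = AbundanceTable(pd.DataFrame({"S": [4.0, 4.0]}, index=["K1", "K2"]),
                               Stage.marker_normalized)
        out = apply_bias_correction(table, model, props)
        assert out.data.loc["K1", "S"] == pytest.approx(2.0)
        assert out.data.loc["K2", "S"] == pytest.approx(4.0)

    def test_zeros_stay_zero_and_scale_free(self):
        markers = load_default_markers()
        props, fold = synth_property_table(
            markers, n_properties=6, true_weights={"prop00": 0.3}, noise_sd=0.02, seed=7
        )
        responses = fold / fold.mean()
        model = fit_bias_model(responses, props, seed=7)
        t1 = _table_from_responses(responses)
        t2 = _table_from_responses(responses, scale=10.0)
        o1 = apply_bias_correction(t1, model, props)
        o2 = apply_bias_correction(t2, model, props)
        assert np.allclose(o2.values, 10.0 * o1.values, rtol=1e-12)

    def test_training_variance_reduced(self):
        markers = load_default_markers()
        props, fold = synth_property_table(
            markers, n_properties=10, true_weights={"prop01": 0.4}, noise_sd=0.05, seed=2
        )
        responses = fold / fold.mean()
        model = fit_bias_model(responses, props, seed=2)
        table = _table_from_responses(responses)
        out = apply_bias_correction(table, model, props)
        corrected = marker_response(out.data["S0"], markers)
        before = float(((responses - 1.0) ** 2).sum())
        after = float(((corrected - 1.0) ** 2).sum())
        assert after < before
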