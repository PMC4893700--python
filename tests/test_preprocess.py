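"""Preprocessing tests: QC, blank filter, normalization, fusion, scaling."""

import numpy as np
import pandas as pd
import pytest

from dilimet.preprocess import (
    average_replicates,
    blank_filter,
    fuse_blocks,
    log_matrix,
    match_mass,
    normalize,
    preprocess_pipeline,
    qc_monitor,
    transform_scale,
)
from dilimet.tables import FeatureTable, SAMPLE_META_COLS


def _mini_table(intens, roles, is_response=None, protein=None, blocks=None):
    n = len(roles)
    idx = [f"s{i}" for i in range(n)]
    feats = list(intens.columns)
    samples = pd.DataFrame({
        "entity_id": [f"e{i}" for i in range(n)],
        "compound": "x", "concentration_uM": 1.0, "class": "control",
        "replicate": 1, "role": roles,
        "injection_order": np.arange(1, n + 1),
        "protein_mg": protein if protein is not None else np.ones(n),
        "is_response": is_response if is_response is not None else np.ones(n),
    }, index=idx)[SAMPLE_META_COLS]
    fmeta = pd.DataFrame({"block": blocks or "B1", "metabolite": feats,
                          "monoisotopic_mass": 100.0}, index=feats)
    intens = intens.set_axis(idx, axis=0)
    return FeatureTable(intens, samples, fmeta)


class TestQcMonitor:
    def test_constant_is_gives_zero_cv(self):
        t = _mini_table(pd.DataFrame({"f1": [5.0, 5.0, 5.0]}),
                        ["qc", "qc", "study"], is_response=[100.0, 100.0, 1.0])
        rep = qc_monitor(t)
        assert rep.loc["__IS__", "cv"] == 0.0
        assert rep.loc["__IS__", "passed"]

    def test_cv_matches_hand_computation(self):
        # sd(100,110)/mean = 7.0711/105 = 6.73%
        t = _mini_table(pd.DataFrame({"f1": [1.0, 1.0, 1.0]}),
                        ["qc", "qc", "study"], is_response=[100.0, 110.0, 1.0])
        rep = qc_monitor(t)
        assert rep.loc["__IS__", "cv"] == pytest.approx(7.0710678 / 105, rel=1e-6)

    def test_requires_two_qcs(self):
        t = _mini_table(pd.DataFrame({"f1": [1.0, 1.0]}), ["qc", "study"])
        with pytest.raises(ValueError, match="QC"):
            qc_monitor(t)

    def test_benchmark_qc_cvs_are_tight(self, benchmark):
        tables, _ = benchmark
        rep = qc_monitor(tables["B1"], cv_threshold=0.3)
        assert rep["passed"].mean() > 0.95

    def test_mass_accuracy_flags_drifted_channel(self, benchmark):
        tables, _ = benchmark
        t = tables["B1"]
        ref = t.features["monoisotopic_mass"]
        observed = ref * (1 + 2e-6)          # 2 ppm everywhere
        observed.iloc[0] = ref.iloc[0] * (1 + 25e-6)  # one drifted channel
        rep = qc_monitor(t, observed_masses=observed, mass_tol_ppm=10)
        drifted = ref.index[0]
        assert not rep.loc[drifted, "passed"]
        assert rep.loc[ref.index[1], "mass_ppm"] == pytest.approx(2.0, abs=0.01)


class TestBlankFilter:
    def test_all_zero_blanks_retain_everything(self):
        t = _mini_table(pd.DataFrame({"f1": [0.0, 50.0], "f2": [0.0, 3.0]}),
                        ["blank", "study"])
        out = blank_filter(t, min_ratio=1000)
        assert list(out.intensities.columns) == ["f1", "f2"]
        assert out.state == "blank_filtered"

    def test_ratio_rule_arithmetic(self):
        # study mean 30, blank mean 20 -> ratio 1.5 < 3 -> removed
        t = _mini_table(pd.DataFrame({"f1": [20.0, 30.0], "f2": [1.0, 30.0]}),
                        ["blank", "study"])
        out = blank_filter(t, min_ratio=3.0)
        assert list(out.intensities.columns) == ["f2"]

    def test_no_blanks_pass_through_with_warning(self):
        t = _mini_table(pd.DataFrame({"f1": [1.0, 2.0]}), ["study", "study"])
        with pytest.warns(UserWarning, match="no blank"):
            out = blank_filter(t)
        assert out.intensities.shape == t.intensities.shape

    def test_synthetic_backgrounds_all_removed(self, benchmark):
        tables, truth = benchmark
        for b, t in tables.items():
            out = blank_filter(t, min_ratio=3.0)
            removed = set(t.intensities.columns) - set(out.intensities.columns)
            bg = set(truth.index[truth["is_background"]]) & set(t.intensities.columns)
            assert removed == bg


class TestNormalize:
    def test_unit_is_and_protein_unchanged(self):
        t = _mini_table(pd.DataFrame({"f1": [100.0, 7.0]}), ["study", "study"])
        out = normalize(t)
        assert np.allclose(out.intensities, t.intensities)
        assert out.state == "normalized"

    def test_division_arithmetic(self):
        t = _mini_table(pd.DataFrame({"f1": [100.0]}), ["study"],
                        is_response=[2.0], protein=[0.5])
        assert normalize(t).intensities.iloc[0, 0] == pytest.approx(100.0)

    def test_double_normalization_forbidden(self):
        t = _mini_table(pd.DataFrame({"f1": [1.0]}), ["study"])
        with pytest.raises(ValueError, match="already normalized"):
            normalize(normalize(t))

    def test_nonpositive_is_names_sample(self):
        t = _mini_table(pd.DataFrame({"f1": [1.0, 1.0]}), ["qc", "qc"],
                        is_response=[1.0, -1.0])
        with pytest.raises(ValueError, match="s1"):
            normalize(t)


class TestMatchMass:
    REF = pd.DataFrame({"monoisotopic_mass": [308.0911, 150.0]},
                       index=["gsh_adduct", "other"])

    def test_exact_match_zero_ppm(self):
        hits = match_mass(308.0911, self.REF)
        assert hits.index[0] == "gsh_adduct"
        assert hits["ppm_error"].iloc[0] == 0.0

    def test_within_tolerance(self):
        hits = match_mass(308.0916, self.REF, tol_ppm=10)
        # |308.0916-308.0911|/308.0911*1e6 = 1.62 ppm
        assert hits["ppm_error"].iloc[0] == pytest.approx(1.623, abs=0.01)

    def test_outside_tolerance(self):
        m = 308.0911 * (1 + 11e-6)
        assert len(match_mass(m, self.REF, tol_ppm=10)) == 0

    def test_empty_reference_errors(self):
        with pytest.raises(ValueError, match="empty"):
            match_mass(100.0, self.REF.iloc[:0])


class TestFuseAverage:
    def test_single_block_identity(self, benchmark):
        tables, _ = benchmark
        t = normalize(blank_filter(tables["B1"]))
        fused = fuse_blocks([t])
        pd.testing.assert_frame_equal(fused.intensities, t.intensities)

    def test_fused_width_272(self, benchmark):
        tables, _ = benchmark
        norm = [normalize(blank_filter(tables[b])) for b in sorted(tables)]
        fused = fuse_blocks(norm)
        assert fused.intensities.shape[1] == 272

    def test_fusion_is_order_invariant(self, benchmark):
        tables, _ = benchmark
        norm = [normalize(blank_filter(tables[b])) for b in sorted(tables)]
        shuffled = [t.copy() for t in norm]
        rng = np.random.default_rng(0)
        for t in shuffled[1:]:
            order = rng.permutation(t.intensities.index)
            t.intensities = t.intensities.loc[order]
            t.samples = t.samples.loc[order]
        pd.testing.assert_frame_equal(fuse_blocks(norm).intensities,
                                      fuse_blocks(shuffled).intensities)

    def test_fuse_split_roundtrip(self, benchmark):
        tables, _ = benchmark
        norm = [normalize(blank_filter(tables[b])) for b in sorted(tables)]
        fused = fuse_blocks(norm)
        parts = []
        for t in norm:  # split by column partition, then re-fuse
            part = fused.copy()
            part.intensities = fused.intensities[t.intensities.columns]
            part.features = fused.features.loc[t.intensities.columns]
            parts.append(part)
        pd.testing.assert_frame_equal(fuse_blocks(parts).intensities,
                                      fused.intensities)

    def test_missing_sample_in_one_block_errors(self, benchmark):
        tables, _ = benchmark
        norm = [normalize(blank_filter(tables[b])) for b in sorted(tables)]
        broken = norm[1].copy()
        broken.intensities = broken.intensities.iloc[1:]
        broken.samples = broken.samples.iloc[1:]
        with pytest.raises(ValueError, match="differ across blocks"):
            fuse_blocks([norm[0], broken])

    def test_unnormalized_block_rejected(self, benchmark):
        tables, _ = benchmark
        with pytest.raises(ValueError, match="normalized"):
            fuse_blocks([tables["B1"]])

    def test_replicate_mean(self, benchmark):
        tables, _ = benchmark
        fused = fuse_blocks([normalize(blank_filter(tables[b]))
                             for b in sorted(tables)])
        mat = average_replicates(fused)
        assert mat.values.shape[0] == 30
        eid = mat.values.index[0]
        reps = fused.samples.index[(fused.samples["entity_id"] == eid)
                                   & (fused.samples["role"] == "study")]
        expected = fused.intensities.loc[reps].mean(axis=0)
        assert np.allclose(mat.values.loc[eid], expected)

    def test_replicate_mean_arithmetic(self):
        t = _mini_table(pd.DataFrame({"f1": [10.0, 20.0, 30.0]}),
                        ["study"] * 3)
        t.samples["entity_id"] = "e"
        t.state = "normalized"
        mat = average_replicates(t)
        assert mat.values.loc["e", "f1"] == 20.0


class TestTransformScale:
    def test_scaled_columns_mean0_sd1(self, entity_matrix):
        scaled = transform_scale(entity_matrix)
        x = scaled.values.to_numpy()
        assert np.abs(x.mean(axis=0)).max() < 1e-12
        assert np.abs(x.std(axis=0, ddof=1) - 1).max() < 1e-12

    def test_log10_before_centering(self):
        vals = pd.DataFrame({"f1": [100.0, 1.0], "f2": [10.0, 10000.0]},
                            index=["a", "b"])
        ents = pd.DataFrame({"compound": "x", "concentration_uM": 1.0,
                             "class": "control"}, index=["a", "b"])
        from dilimet.tables import EntityMatrix
        m = EntityMatrix(vals, ents)
        lg = log_matrix(m)
        assert lg.values.loc["a", "f1"] == pytest.approx(2.0)

    def test_projection_through_stored_params_is_identity(self, entity_matrix):
        scaled = transform_scale(entity_matrix)
        again = transform_scale(entity_matrix, params=scaled.scaling)
        pd.testing.assert_frame_equal(scaled.values, again.values)

    def test_unscale_roundtrip(self, entity_matrix):
        scaled = transform_scale(entity_matrix)
        back = scaled.scaling.inverse(scaled.values)
        orig = entity_matrix.values[scaled.scaling.columns]
        assert np.abs((back - orig) / orig).to_numpy().max() < 1e-10

    def test_zero_variance_column_dropped_with_warning(self):
        vals = pd.DataFrame({"f1": [5.0, 5.0, 5.0], "f2": [1.0, 2.0, 4.0]},
                            index=list("abc"))
        ents = pd.DataFrame({"compound": "x", "concentration_uM": 1.0,
                             "class": "control"}, index=list("abc"))
        from dilimet.tables import EntityMatrix
        with pytest.warns(UserWarning, match="zero-variance"):
            scaled = transform_scale(EntityMatrix(vals, ents))
        assert list(scaled.values.columns) == ["f2"]


def test_pipeline_produces_30x272_matrix(entity_matrix):
    assert entity_matrix.values.shape == (30, 272)
    assert entity_matrix.transform == "linear"
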