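import numpy as np
import pytest

import leapd
from leapd.io import SubjectRecord
from leapd.preprocess import Band
from leapd.training import (
    IMPAIRED,
    NORMAL,
    ChannelConfig,
    ChannelModel,
    LEAPDModel,
    TrainingSettings,
    assign_groups,
    fit_leapd,
    grid_search_channel,
    select_electrodes,
)


def _subjects(scores):
    return [
        SubjectRecord(f"s{i}", "PD", 60.0 + i, {"moca": float(v)})
        for i, v in enumerate(scores)
    ]


class TestAssignGroups:
    def test_moca_cutoff_convention(self):
        groups = assign_groups(_subjects([25, 26, 30, 20]), "moca")
        assert groups["s0"] == IMPAIRED  # 25 < 26
        assert groups["s1"] == NORMAL  # 26 is normal
        assert groups["s3"] == IMPAIRED

    def test_median_cut(self):
        groups = assign_groups(
            _subjects([10, 20, 30, 30]), "moca", rule="median_cut"
        )
        assert groups["s0"] == IMPAIRED and groups["s1"] == IMPAIRED
        assert groups["s2"] == NORMAL and groups["s3"] == NORMAL

    def test_constant_scores_rejected(self):
        with pytest.raises(ValueError):
            assign_groups(_subjects([26, 26, 26]), "moca", rule="median_cut")

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            assign_groups(_subjects([28, 29, 30]), "moca")  # nobody impaired


class TestGridSearch:
    def test_informative_band_wins(self, small_ds):
        """The band containing the cognition-driven peak must beat a band
        that excludes it."""
        groups = assign_groups(small_ds.subjects, "moca")
        peak_band, dead_band = Band(4, 14), Band(35, 45)
        grid = [(peak_band, 8, 3, 3), (dead_band, 8, 3, 3)]
        cm = grid_search_channel(small_ds, groups, "moca", "P8", grid)
        assert cm.config.band == peak_band

    def test_single_config_grid(self, small_ds):
        groups = assign_groups(small_ds.subjects, "moca")
        grid = [(Band(4, 14), 6, 2, 2)]
        cm = grid_search_channel(small_ds, groups, "moca", "O2", grid)
        assert cm.config.order == 6 and cm.config.band == Band(4, 14)
        assert -1.0 <= cm.train_correlation <= 1.0

    def test_empty_grid_rejected(self, small_ds):
        groups = assign_groups(small_ds.subjects, "moca")
        with pytest.raises(ValueError):
            grid_search_channel(small_ds, groups, "moca", "P8", [])


class TestSelectElectrodes:
    def _model(self, label, rho):
        cfg = ChannelConfig(label, Band(4, 14), 2, 0, 0)
        sub = leapd.fit_affine_subspace(np.eye(2), 0)
        return ChannelModel(cfg, sub, sub, rho)

    def test_ranking(self):
        models = [self._model(l, r) for l, r in
                  [("A", 0.9), ("B", 0.5), ("C", 0.7)]]
        assert select_electrodes(models, 2) == ["A", "C"]

    def test_tie_breaks_lexicographic(self):
        models = [self._model(l, 0.5) for l in ["B", "A", "C"]]
        assert select_electrodes(models, 2) == ["A", "B"]

    def test_bad_n_rejected(self):
        models = [self._model("A", 0.5)]
        with pytest.raises(ValueError):
            select_electrodes(models, 0)
        with pytest.raises(ValueError):
            select_electrodes(models, 2)


@pytest.fixture(scope="module")
def fitted(small_ds):
    groups = assign_groups(small_ds.subjects, "moca")
    model = fit_leapd(small_ds, groups, settings=TrainingSettings())
    return model, groups


class TestFitAndScore:

    def test_model_structure(self, fitted, small_ds):
        model, _ = fitted
        assert len(model.channel_models) == 8
        grid_bands = {g[0] for g in TrainingSettings().grid}
        assert all(m.config.band in grid_bands for m in model.channel_models)
        assert len(set(model.channels)) == 8

    def test_training_set_separation(self, fitted, small_ds):
        model, groups = fitted
        idx = {
            s.id: leapd.score_subject(model, small_ds.recordings[s.id])
            for s in small_ds.subjects
        }
        mean_imp = np.mean([idx[i] for i, g in groups.items() if g == IMPAIRED])
        mean_norm = np.mean([idx[i] for i, g in groups.items() if g == NORMAL])
        assert mean_imp < mean_norm

    def test_scoring_deterministic_and_bounded(self, fitted, small_ds):
        model, _ = fitted
        rec = small_ds.recordings[small_ds.ids[0]]
        a = leapd.score_subject(model, rec)
        b = leapd.score_subject(model, rec)
        assert a == b and 0.0 <= a <= 1.0

    def test_missing_channel_named_in_error(self, fitted, small_ds):
        model, _ = fitted
        rec = small_ds.recordings[small_ds.ids[0]]
        crippled = leapd.EEGRecording(
            rec.subject_id, ["only"], rec.sample_rate, rec.samples[:1]
        )
        ch = model.channels[0]
        with pytest.raises(KeyError, match=model.channels[0]):
            leapd.score_subject(model, crippled)

    def test_classification_threshold_convention(self, fitted, small_ds):
        model, _ = fitted
        rec = small_ds.recordings[small_ds.ids[0]]
        label = leapd.classify_subject(model, rec)
        idx = leapd.score_subject(model, rec)
        assert label == (NORMAL if idx > 0.5 else IMPAIRED)

    def test_empty_group_rejected(self, small_ds):
        groups = {i: NORMAL for i in small_ds.ids}
        with pytest.raises(ValueError):
            fit_leapd(small_ds, groups)

    def test_refit_is_identical(self, small_ds):
        groups = assign_groups(small_ds.subjects, "moca")
        settings = TrainingSettings(grid=[(Band(4, 14), 6, 2, 2)], n_electrodes=2)
        m1 = fit_leapd(small_ds, groups, settings=settings)
        m2 = fit_leapd(small_ds, groups, settings=settings)
        assert m1.channels == m2.channels
        for a, b in zip(m1.channel_models, m2.channel_models):
            np.testing.assert_array_equal(
                a.subspace_normal.centroid, b.subspace_normal.centroid
            )

    def test_json_roundtrip(self, fitted, small_ds, tmp_path):
        model, _ = fitted
        path = tmp_path / "model.json"
        model.save(path)
        back = LEAPDModel.load(path)
        rec = small_ds.recordings[small_ds.ids[3]]
        assert leapd.score_subject(back, rec) == pytest.approx(
            leapd.score_subject(model, rec), abs=1e-12
        )
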