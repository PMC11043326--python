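"""Statistical contracts of the synthetic screening-campaign generator."""

import numpy as np
import pytest
from scipy.stats import norm

from phenoscreen import synthetic as syn
from phenoscreen.evaluate import roc_auc


class TestConfigValidation:
    def test_too_many_clusters_rejected(self):
        with pytest.raises(syn.InvalidConfigError, match="n_clusters"):
            syn.GeneratorConfig(n_compounds=5, n_clusters=10)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"fill_rate": 0.0},
            {"hit_rate": 1.0},
            {"label_flip_rate": 1.0},
            {"n_assays": 0},
            {"phenotype_snr": -1.0},
            {"modality_linkage": "smell"},
        ],
    )
    def test_out_of_range_fields_rejected(self, kwargs):
        with pytest.raises(syn.InvalidConfigError):
            syn.GeneratorConfig(**kwargs)


class TestLibrary:
    def test_counts_and_cluster_coverage(self):
        cfg = syn.GeneratorConfig(n_compounds=10, n_assays=2, n_clusters=2, fp_bits=64,
                                  n_plates=1, n_features=4, seed=1)
        lib = syn.generate_library(cfg)
        assert lib.n_compounds == 10
        assert len(set(lib.compound_ids)) == 10
        assert set(lib.cluster_ids) == {0, 1}
        assert lib.fingerprints.shape == (10, 64)

    def test_same_seed_bit_identical(self, small_config):
        a = syn.generate_library(small_config)
        b = syn.generate_library(small_config)
        assert np.array_equal(a.fingerprints, b.fingerprints)
        assert np.array_equal(a.mechanisms, b.mechanisms)
        assert np.array_equal(a.cluster_ids, b.cluster_ids)

    def test_within_cluster_tanimoto_exceeds_between(self):
        from phenoscreen.chem import tanimoto_matrix

        cfg = syn.GeneratorConfig(n_compounds=500, n_assays=2, n_clusters=20, fp_bits=512,
                                  n_plates=4, n_features=4, seed=3)
        lib = syn.generate_library(cfg)
        sim = tanimoto_matrix(lib.fingerprints)
        iu = np.triu_indices(500, 1)
        same = (lib.cluster_ids[:, None] == lib.cluster_ids[None, :])[iu]
        assert sim[iu][same].mean() > sim[iu][~same].mean()


class TestLabels:
    def test_full_fill_no_noise_equals_truth(self, small_library, small_panel, small_config):
        cfg = small_config.with_(fill_rate=1.0, label_flip_rate=0.0)
        lm = syn.generate_labels(small_library, small_panel, cfg)
        assert not np.isnan(lm.labels).any()
        assert np.array_equal(lm.labels, lm.truth.astype(float))

    def test_fill_rate_concentrates_at_default(self):
        # full-scale matrix: 8300 x 140 cells observed at 47.8%
        cfg = syn.GeneratorConfig(n_compounds=8300, n_assays=140, n_clusters=600,
                                  fp_bits=64, n_plates=48, n_features=4, seed=5)
        lm = syn.generate_labels(syn.generate_library(cfg), syn.generate_panel(cfg), cfg)
        n_cells = 8300 * 140
        se = np.sqrt(0.478 * (1 - 0.478) / n_cells)
        assert abs(lm.fill_rate() - 0.478) < 3 * se

    def test_hit_rate_concentrates_at_configured_value(self):
        cfg = syn.GeneratorConfig(n_compounds=4000, n_assays=50, n_clusters=100,
                                  fp_bits=64, n_plates=24, n_features=4,
                                  hit_rate=0.03, seed=6)
        lm = syn.generate_labels(syn.generate_library(cfg), syn.generate_panel(cfg), cfg)
        n_obs = lm.observed_mask().sum()
        se = np.sqrt(0.03 * 0.97 / n_obs)
        assert abs(lm.hit_rate() - 0.03) < 3 * se

    def test_flip_noise_moves_observed_hit_rate(self, small_library, small_panel, small_config):
        cfg = small_config.with_(fill_rate=1.0, label_flip_rate=0.3)
        lm = syn.generate_labels(small_library, small_panel, cfg)
        flipped = (lm.labels != lm.truth).mean()
        assert flipped == pytest.approx(0.3, abs=0.02)


class TestProfiles:
    def test_snr_zero_actives_match_inactives(self, small_library, small_panel, small_config):
        cfg = small_config.with_(phenotype_snr=0.0)
        prof = syn.generate_profiles(small_library, small_panel, cfg)
        truth = syn.latent_activity(small_library, small_panel, cfg)
        active = truth.any(axis=1)
        frame = prof.frame[~prof.frame["is_control"]]
        comp_active = frame["compound_id"].map(
            dict(zip(small_library.compound_ids, active)))
        vals = prof.features[: len(frame)]
        a = vals[comp_active.to_numpy(bool)].mean()
        b = vals[~comp_active.to_numpy(bool)].mean()
        assert abs(a - b) < 0.05  # equal means up to sampling noise

    def test_no_plate_effect_aligns_control_medians(self, small_library, small_panel, small_config):
        cfg = small_config.with_(plate_effect_sd=0.0)
        prof = syn.generate_profiles(small_library, small_panel, cfg)
        ctrl = prof.frame[prof.frame["is_control"]]
        medians = ctrl.groupby("plate_id")[prof.feature_columns[0]].median()
        assert medians.max() - medians.min() < 1.5  # sampling noise only

    def test_every_plate_has_controls_and_replicates_present(self, small_profiles, small_config):
        frame = small_profiles.frame
        per_plate = frame.groupby("plate_id")["is_control"].sum()
        assert (per_plate >= 8).all()
        reps = frame[~frame["is_control"]].groupby("compound_id").size()
        assert (reps == small_config.replicates_per_compound).all()

    def test_high_snr_single_feature_separates_actives(self):
        link = ("phenotype", "phenotype")
        cfg = syn.GeneratorConfig(n_compounds=800, n_assays=2, n_clusters=40, fp_bits=64,
                                  n_plates=6, n_features=24, phenotype_snr=5.0,
                                  plate_effect_sd=0.0, modality_linkage=link, seed=9)
        lib = syn.generate_library(cfg)
        panel = syn.generate_panel(cfg)
        prof = syn.generate_profiles(lib, panel, cfg)
        truth = syn.latent_activity(lib, panel, cfg)
        active_of = dict(zip(lib.compound_ids, truth.any(axis=1)))
        frame = prof.frame[~prof.frame["is_control"]]
        y = frame["compound_id"].map(active_of).to_numpy(float)
        aucs = [roc_auc(frame[c].to_numpy(), y) for c in prof.feature_columns]
        assert max(aucs) > 0.9

    def test_capacity_overflow_raises(self, small_library, small_panel, small_config):
        cfg = small_config.with_(n_plates=1, replicates_per_compound=4)
        with pytest.raises(syn.InvalidConfigError, match="plates"):
            syn.generate_profiles(small_library, small_panel, cfg)

    def test_none_linked_assay_labels_independent_of_features(self):
        cfg = syn.GeneratorConfig(n_compounds=1500, n_assays=4, n_clusters=60, fp_bits=64,
                                  n_plates=10, n_features=48, phenotype_snr=4.0,
                                  fill_rate=1.0, hit_rate=0.1,
                                  modality_linkage=("phenotype", "phenotype", "none", "none"),
                                  seed=13)
        lib = syn.generate_library(cfg)
        panel = syn.generate_panel(cfg)
        lm = syn.generate_labels(lib, panel, cfg)
        prof = syn.generate_profiles(lib, panel, cfg)
        frame = prof.frame[~prof.frame["is_control"]]
        comp_idx = frame["compound_id"].map(
            {c: i for i, c in enumerate(lib.compound_ids)}).to_numpy()
        X = prof.features[: len(frame)]
        n = len(frame)
        # Bonferroni-style null band on |corr| over all features
        band = norm.ppf(1 - 0.001 / (2 * cfg.n_features)) / np.sqrt(n)
        for j, link in enumerate(panel.linkage):
            if link != "none":
                continue
            y = lm.labels[comp_idx, j]
            yc = y - y.mean()
            xc = X - X.mean(axis=0)
            corr = (xc * yc[:, None]).mean(axis=0) / (X.std(axis=0) * y.std() + 1e-12)
            assert np.abs(corr).max() < band


class TestImages:
    def _tiny(self, **kw):
        base = dict(n_compounds=6, n_assays=2, n_clusters=2, fp_bits=32, n_plates=1,
                    n_features=4, replicates_per_compound=1, image_size=24,
                    image_channels=5, modality_linkage="phenotype", hit_rate=0.34, seed=21)
        base.update(kw)
        return syn.GeneratorConfig(**base)

    def test_channel_count_and_dtype_range(self):
        cfg = self._tiny()
        lib = syn.generate_library(cfg)
        panel = syn.generate_panel(cfg)
        imgs = syn.generate_images(lib, panel, cfg, n_controls=2)
        assert imgs.images.shape[1:] == (5, 24, 24)
        assert imgs.images.dtype == np.uint16

    def test_unsupported_channel_count_raises(self):
        cfg = self._tiny(image_channels=4)
        lib = syn.generate_library(cfg)
        panel = syn.generate_panel(cfg)
        with pytest.raises(ValueError, match="channel"):
            syn.generate_images(lib, panel, cfg)

    def test_high_snr_separates_active_intensity(self):
        cfg = self._tiny(n_compounds=40, n_clusters=8, replicates_per_compound=2,
                         phenotype_snr=6.0)
        lib = syn.generate_library(cfg)
        panel = syn.generate_panel(cfg)
        truth = syn.latent_activity(lib, panel, cfg)
        imgs = syn.generate_images(lib, panel, cfg, n_controls=30)
        means = imgs.images.mean(axis=(1, 2, 3))
        active_of = dict(zip(lib.compound_ids, truth.any(axis=1)))
        is_ctrl = np.array([c == "" for c in imgs.compound_ids])
        is_active = np.array([bool(active_of.get(c, False)) for c in imgs.compound_ids])
        act, ctl = means[is_active], means[is_ctrl]
        pooled_sd = np.sqrt((act.var() + ctl.var()) / 2)
        assert (act.mean() - ctl.mean()) > 3 * pooled_sd
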