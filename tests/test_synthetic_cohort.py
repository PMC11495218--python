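"""Synthetic cohort generator: geometry, signals, covariates, determinism."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sp_stats

from ieeg_focality.focality_model import mann_whitney_auc, yates_chi2
from ieeg_focality.normative_atlas import zscore_power
from ieeg_focality.signal_processing import (
    BAND_NAMES,
    apply_bipolar,
    compute_clip_features,
    make_bipolar_montage,
    preprocess_clip,
)
from ieeg_focality.spatial_dispersion import standard_distance
from ieeg_focality.synthetic_cohort import (
    CohortConfig,
    generate_atlas_population,
    generate_cohort,
    generate_electrode_geometry,
    patient_rng,
    synthesize_clip_batch,
)

DELTA = BAND_NAMES.index("delta")


class TestConfigValidation:
    def test_rejects_low_sampling_rate(self):
        with pytest.raises(ValueError, match="fs_raw"):
            CohortConfig(fs_raw=256.0)

    def test_rejects_impossible_geometry(self):
        with pytest.raises(ValueError, match="geometry"):
            CohortConfig(contacts_per_shank=60, contact_spacing_mm=5.0)

    def test_rejects_bad_fraction_and_counts(self):
        with pytest.raises(ValueError):
            CohortConfig(focal_fraction=1.2)
        with pytest.raises(ValueError):
            CohortConfig(n_patients=0)
        with pytest.raises(ValueError):
            CohortConfig(n_shanks_range=(3, 2))


class TestGeometry:
    def test_single_shank_exact_spacing(self):
        cfg = CohortConfig.scaled_down(n_shanks_range=(1, 1), contacts_per_shank=8)
        es, truth = generate_electrode_geometry(cfg, "focal", patient_rng(0, 0))
        xyz = es.positions()
        assert len(xyz) == 8
        gaps = np.linalg.norm(np.diff(xyz, axis=0), axis=1)
        assert np.allclose(gaps, 3.5, atol=1e-9)
        # collinear: all gap vectors parallel
        d = np.diff(xyz, axis=0)
        d = d / np.linalg.norm(d, axis=1, keepdims=True)
        assert np.allclose(np.abs(d @ d[0]), 1.0, atol=1e-9)

    def test_focal_patients_have_one_epileptic_cluster(self):
        cfg = CohortConfig.scaled_down()
        for i in range(5):
            es, truth = generate_electrode_geometry(cfg, "focal", patient_rng(1, i))
            assert truth.epileptic_contacts
            pts = es.table[es.table["contact"].isin(truth.epileptic_contacts)]
            spread = standard_distance(pts[["x_mm", "y_mm", "z_mm"]].to_numpy())
            assert spread < cfg.nonfocal_spread_mm / 2

    def test_class_separation_of_implant_sd(self):
        cfg = CohortConfig.scaled_down(focal_cluster_radius_mm=15.0, nonfocal_spread_mm=70.0)
        sds = {}
        for label in ("focal", "broad"):
            vals = []
            for i in range(100):
                es, _ = generate_electrode_geometry(cfg, label, patient_rng(2, i))
                vals.append(standard_distance(es.positions()))
            sds[label] = np.mean(vals)
        assert sds["broad"] > sds["focal"]

    def test_separation_vanishes_when_spreads_equal(self):
        cfg = CohortConfig.scaled_down(focal_cluster_radius_mm=20.0, nonfocal_spread_mm=40.0)
        vals = {}
        for label in ("focal", "broad"):
            vals[label] = [
                standard_distance(generate_electrode_geometry(cfg, label, patient_rng(3, i))[0].positions())
                for i in range(100)
            ]
        assert abs(np.mean(vals["focal"]) - np.mean(vals["broad"])) < 0.1 * np.mean(vals["focal"])

    def test_white_matter_rate_in_declared_range(self):
        cfg = CohortConfig.scaled_down()
        tables = [
            generate_electrode_geometry(cfg, "focal", patient_rng(4, i))[0].table for i in range(30)
        ]
        rate = pd.concat(tables)["tissue"].eq("white").mean()
        assert 0.10 < rate < 0.20

    def test_unknown_label_rejected(self):
        cfg = CohortConfig.scaled_down()
        with pytest.raises(ValueError):
            generate_electrode_geometry(cfg, "weird", patient_rng(5, 0))


class TestDeterminism:
    def test_cohorts_identical_under_fixed_seed(self):
        cfg = CohortConfig.scaled_down(seed=9, n_patients=6, n_clips=2)
        a = generate_cohort(cfg)
        b = generate_cohort(cfg)
        for pa, pb in zip(a.patients, b.patients):
            pd.testing.assert_frame_equal(pa.electrodes.table, pb.electrodes.table)
            assert pa.five_sense == pb.five_sense
            assert pa.truth == pb.truth
        ca = a.clip_batch(a.patients[0])
        cb = b.clip_batch(b.patients[0])
        assert ca.tobytes() == cb.tobytes()

    def test_different_seed_differs(self):
        a = generate_cohort(CohortConfig.scaled_down(seed=1, n_patients=3, n_clips=1))
        b = generate_cohort(CohortConfig.scaled_down(seed=2, n_patients=3, n_clips=1))
        assert not np.array_equal(a.clip_batch(a.patients[0]), b.clip_batch(b.patients[0]))

    def test_patient_substreams_stable_under_cohort_size(self):
        small = generate_cohort(CohortConfig.scaled_down(seed=3, n_patients=3, n_clips=1))
        large = generate_cohort(CohortConfig.scaled_down(seed=3, n_patients=6, n_clips=1))
        pd.testing.assert_frame_equal(
            small.patients[1].electrodes.table, large.patients[1].electrodes.table
        )


class TestSignalInjection:
    def _score_patients(self, cfg, atlas, labels, n=3):
        """Per-channel delta-power Z and epileptic mask, pooled over patients."""
        z_all, ep_all = [], []
        for i in range(n):
            es, truth = generate_electrode_geometry(cfg, labels, patient_rng(cfg.seed, i))
            raw = synthesize_clip_batch(es, truth, cfg, patient_rng(cfg.seed, i, 2), cfg.n_clips)
            montage = make_bipolar_montage(es.table)
            clips = preprocess_clip(apply_bipolar(raw, es.contacts, montage), cfg.fs_raw)
            feats = compute_clip_features(clips, montage["channel"], montage["roi"])
            z = zscore_power(feats, atlas)
            ep = np.array(
                [
                    a in truth.epileptic_contacts and c in truth.epileptic_contacts
                    for a, c in zip(montage["anode"], montage["cathode"])
                ]
            )
            z_all.append(z)
            ep_all.append(ep)
        return z_all, ep_all

    def test_null_config_indistinguishable(self, null_atlas):
        cfg = CohortConfig.scaled_down(seed=21, power_effect=0.0, coherence_effect=0.0, n_clips=5)
        z_all, ep_all = self._score_patients(cfg, null_atlas, "focal", n=6)
        ep_vals = np.concatenate(
            [np.abs(z[:, ep, DELTA]).ravel() for z, ep in zip(z_all, ep_all)]
        )
        norm_vals = np.concatenate(
            [np.abs(z[:, ~ep, DELTA]).ravel() for z, ep in zip(z_all, ep_all)]
        )
        ep_vals = ep_vals[np.isfinite(ep_vals)][:200]
        norm_vals = norm_vals[np.isfinite(norm_vals)][:200]
        assert ep_vals.size >= 50
        p = sp_stats.mannwhitneyu(ep_vals, norm_vals, alternative="two-sided").pvalue
        assert p > 0.01

    def test_delta_effect_recovered(self, null_atlas):
        cfg = CohortConfig.scaled_down(seed=22, power_effect={"delta": 3.0}, coherence_effect=0.0, n_clips=5)
        z_all, ep_all = self._score_patients(cfg, null_atlas, "focal", n=4)
        vals = np.concatenate([z[:, ep, DELTA].ravel() for z, ep in zip(z_all, ep_all)])
        assert np.nanmedian(vals) >= 2.0

    def test_monotone_in_power_effect(self, null_atlas):
        medians = []
        for eff in (0.0, 1.5, 3.0):
            cfg = CohortConfig.scaled_down(
                seed=23, power_effect={"delta": eff}, coherence_effect=0.0, n_clips=4
            )
            z_all, ep_all = self._score_patients(cfg, null_atlas, "focal", n=3)
            vals = np.concatenate([np.abs(z[:, ep, DELTA]).ravel() for z, ep in zip(z_all, ep_all)])
            medians.append(np.nanmedian(vals))
        assert medians[0] < medians[1] < medians[2]


class TestAtlasPopulation:
    def test_every_roi_covered(self, scaled_cfg, null_population):
        from ieeg_focality.normative_atlas import build_atlas

        atlas = build_atlas(null_population)
        for r in range(scaled_cfg.n_rois):
            entry = atlas.power_entry(f"roi{r:02d}", "delta")
            assert entry is not None and entry[2] >= 5

    def test_under_covered_population_raises_naming_rois(self):
        cfg = CohortConfig.scaled_down(n_rois=10)
        with pytest.raises(ValueError, match="roi"):
            generate_atlas_population(cfg, 1, np.random.default_rng(0), min_channels_per_roi=50)


class TestClinicalCovariates:
    def test_null_score_auc_near_half(self):
        aucs = []
        for seed in range(20):
            cfg = CohortConfig.scaled_down(
                seed=seed,
                n_patients=60,
                five_sense_params={"focal": (0.55, 0.15), "nonfocal": (0.55, 0.15)},
                implant_score_corr=0.0,
            )
            cohort = generate_cohort(cfg)
            t = cohort.cohort_table()
            y = t["focality_label"] == "focal"
            _, _, auc = mann_whitney_auc(t.loc[y, "five_sense"], t.loc[~y, "five_sense"])
            aucs.append(auc)
        assert abs(np.mean(aucs) - 0.5) < 0.05

    def test_score_anticorrelated_with_implant_sd(self):
        rs = []
        for seed in range(20):
            cfg = CohortConfig.scaled_down(seed=seed)
            cohort = generate_cohort(cfg)
            sds = [
                standard_distance(
                    p.electrodes.table.query("tissue == 'gray'")[["x_mm", "y_mm", "z_mm"]].to_numpy()
                )
                for p in cohort.patients
            ]
            scores = [p.five_sense for p in cohort.patients]
            rs.append(sp_stats.pearsonr(scores, sds).statistic)
        assert -0.4 < np.mean(rs) < 0.0
        assert all(r < 0.05 for r in rs)

    def test_therapy_rates_reject_chi2(self):
        rejections = 0
        for seed in range(40):
            cohort = generate_cohort(CohortConfig.scaled_down(seed=seed))
            t = cohort.cohort_table()
            surg = t["therapy"].isin(["resection", "ablation"])
            focal = t["focality_label"] == "focal"
            table = [
                [int((surg & ~focal).sum()), int((~surg & ~focal).sum())],
                [int((surg & focal).sum()), int((~surg & focal).sum())],
            ]
            _, p = yates_chi2(table)
            rejections += p < 0.05
        assert rejections >= 36  # ≥ 90% of seeds

    def test_outcomes_only_for_surgical_patients(self):
        t = generate_cohort(CohortConfig.scaled_down(seed=2)).cohort_table()
        surgical = t["therapy"].isin(["resection", "ablation"])
        assert (t.loc[surgical, "outcome"] != "none").all()
        assert (t.loc[~surgical, "outcome"] == "none").all()

    def test_class_counts_match_fraction(self):
        t = generate_cohort(CohortConfig.scaled_down(seed=1)).cohort_table()
        assert (t["focality_label"] == "focal").sum() == 65
        assert len(t) == 101
        assert set(t.loc[t["focality_label"] == "nonfocal", "subtype"]) <= {
            "bifocal",
            "multifocal",
            "broad",
            "nonlocalized",
        }
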