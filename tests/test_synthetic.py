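import warnings
from dataclasses import replace

import numpy as np
import pytest
from scipy.stats import pearsonr

from calfish.calcium import compute_auc, compute_baseline, default_schedule
from calfish.classify import classify_cells, fit_nonresponder_threshold, select_union
from calfish.rnascope import fit_negative_control
from calfish.stats import fisher_interval, pearson
from calfish.synthetic import (ChannelParams, SynthConfig,
                               correlation_recovery_config,
                               discordance_from_counts, generate_dataset,
                               render_trace, sample_ground_truth,
                               sample_measurements, within_correlation)


class TestConfigValidation:
    @pytest.mark.parametrize("field,value,msg", [
        ("n_cells", 0, "n_cells"),
        ("fraction_neurons", 1.2, "fraction_neurons"),
        ("frame_rate", 0.0, "frame_rate"),
        ("noise_sd", -0.1, "noise_sd"),
        ("n_planes", 0, "n_planes"),
        ("cell_radius", -1.0, "cell_radius"),
        ("photon_noise", "cauchy", "photon_noise"),
        ("widefield_shape", (0, 64), "widefield_shape"),
    ])
    def test_invalid_values_name_the_field(self, field, value, msg):
        cfg = replace(SynthConfig(), **{field: value})
        with pytest.raises(ValueError, match=msg):
            cfg.validate()

    def test_channel_fraction_out_of_range(self):
        ch = ChannelParams(name="trpa1", agonist="aitc", fraction_expressing=1.5)
        with pytest.raises(ValueError, match="fraction_expressing"):
            ch.validate()

    def test_channel_agonist_must_be_scheduled(self):
        cfg = replace(SynthConfig(), channels=(
            ChannelParams(name="trpa1", agonist="menthol"),))
        with pytest.raises(ValueError, match="menthol"):
            cfg.validate()


class TestGroundTruth:
    def test_structural_invariants(self):
        cfg = replace(SynthConfig(), n_cells=300, seed=5)
        gt = sample_ground_truth(cfg)
        assert gt["cell_id"].is_unique
        assert not gt.loc[~gt["is_neuron"], "kcl_responsive"].any()
        for col in ("expression_trpa1", "expression_trpv1",
                    "true_auc_aitc", "true_auc_capsaicin"):
            assert (gt[col] >= 0).all()

    @pytest.mark.filterwarnings("ignore:channel .*no co-positive")
    def test_no_expression_when_fraction_zero(self):
        ch = (ChannelParams(name="trpa1", agonist="aitc", fraction_expressing=0.0),)
        gt = sample_ground_truth(replace(SynthConfig(), channels=ch, seed=1))
        assert (gt["expression_trpa1"] == 0).all()

    def test_perfect_coupling_at_unit_correlation(self):
        """true_correlation=1 with no noise: expression and AUC are an exact
        monotone map of one another on the co-positive population."""
        ch = (ChannelParams(name="trpa1", agonist="aitc", true_correlation=1.0),)
        cfg = replace(SynthConfig(), channels=ch, noise_sd=0.0,
                      intensity_noise_sd=0.0, seed=3)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # clip warning at the bound
            gt = sample_ground_truth(cfg)
        both = gt[gt["expressing_trpa1"] & gt["responder_trpa1"]]
        r_loglog = pearsonr(np.log(both["expression_trpa1"]),
                            np.log(both["true_auc_aitc"])).statistic
        assert r_loglog == pytest.approx(1.0, abs=1e-9)

    def test_gated_population_size_is_deterministic(self):
        cfg = replace(SynthConfig(), n_cells=200, fraction_neurons=0.85)
        gt = sample_ground_truth(cfg)
        assert int(gt["is_neuron"].sum()) == 170


class TestRenderTrace:
    schedule = default_schedule()

    def test_noiseless_auc_round_trip(self):
        cell = {"cell_id": 1, "kcl_responsive": True,
                "true_auc_aitc": 30.0, "true_auc_capsaicin": 12.0}
        tr = render_trace(cell, self.schedule, noise_sd=0.0)
        aitc = self.schedule[0]
        assert compute_auc(tr, aitc) == pytest.approx(30.0, abs=0.5)

    def test_zero_auc_distributed_around_zero(self):
        """A non-responder's measured AUC is pure integration + baseline
        noise: centered on zero with the predicted sd (~0.56 at ratio
        noise 0.02), so ~95% of draws fall within 2 sd."""
        from calfish.synthetic import auc_noise_sd
        cell = {"cell_id": 1, "kcl_responsive": True,
                "true_auc_aitc": 0.0, "true_auc_capsaicin": 0.0}
        sd_pred = auc_noise_sd(0.02)
        aucs = []
        for seed in range(50):
            tr = render_trace(cell, self.schedule, noise_sd=0.02, seed=seed)
            aucs.append(compute_auc(tr, self.schedule[0]))
        aucs = np.asarray(aucs)
        assert abs(aucs.mean()) < 3 * sd_pred / np.sqrt(50)
        assert np.mean(np.abs(aucs) < 2 * sd_pred) >= 0.9
        assert np.std(aucs) == pytest.approx(sd_pred, rel=0.35)

    def test_unresponsive_cell_has_no_kcl_transient(self):
        """Without a depolarization response the KCl window holds pure
        noise: the peak-above-baseline is an extreme order statistic of
        ~26 samples (median ~2.2 noise sd) and never approaches the 0.1
        gate delta."""
        from calfish.calcium import kcl_gate
        cell = {"cell_id": 1, "kcl_responsive": False,
                "true_auc_aitc": 0.0, "true_auc_capsaicin": 0.0}
        kcl = self.schedule[2]
        peaks = []
        for seed in range(100):
            tr = render_trace(cell, self.schedule, noise_sd=0.01, seed=seed)
            base = compute_baseline(tr, kcl)
            sel = (tr.times >= kcl.start) & (tr.times <= kcl.end + 10)
            peaks.append(float(np.max(tr.ratio[sel] - base)))
            assert not kcl_gate(tr, kcl, min_delta=0.1)
        assert np.median(peaks) <= 3 * 0.01
        assert max(peaks) <= 5 * 0.01

    def test_overlapping_schedule_rejected(self):
        from calfish.calcium import ApplicationWindow
        bad = [ApplicationWindow("aitc", 1e-4, 10.0, 60.0),
               ApplicationWindow("kcl", 60e-3, 30.0, 15.0)]
        cell = {"cell_id": 1, "kcl_responsive": True, "true_auc_aitc": 5.0}
        with pytest.raises(ValueError, match="overlap"):
            render_trace(cell, bad, noise_sd=0.0)

    def test_auc_calibration_over_replicates(self):
        """Noiseless rendered traces integrate back to their true AUC:
        mean recovered/true within 1% over 200 cells per agonist."""
        rng = np.random.default_rng(11)
        for agonist, window in (("aitc", self.schedule[0]),
                                ("capsaicin", self.schedule[1])):
            ratios = []
            for i in range(200):
                true = float(rng.uniform(5.0, 60.0))
                cell = {"cell_id": i, "kcl_responsive": True,
                        f"true_auc_{agonist}": true}
                tr = render_trace(cell, self.schedule, noise_sd=0.0)
                ratios.append(compute_auc(tr, window) / true)
            assert np.mean(ratios) == pytest.approx(1.0, abs=0.01)


class TestCalibration:
    def test_within_correlation_identity_when_population_is_pure(self):
        ch = ChannelParams(name="c", agonist="aitc", fraction_expressing=1.0,
                           family="normal", expression_median=150.0,
                           expression_sigma=25.0, auc_median=25.0, auc_sigma=5.0)
        rho_l = within_correlation(ch)
        assert rho_l == pytest.approx(0.43, abs=1e-9)

    def test_unattainable_target_warns_and_clips(self):
        rates = discordance_from_counts(98, 309, 95, 388)
        ch = ChannelParams(name="trpa1", agonist="aitc",
                           true_correlation=0.43, **rates)
        with pytest.warns(UserWarning, match="unattainable"):
            rho_l = within_correlation(ch)
        assert abs(rho_l) <= 1.0

    @pytest.mark.parametrize("rho", [0.0, 0.43, 0.9])
    def test_union_correlation_recovery_over_replicates(self, rho):
        """Measured-table recovery: the union-set Pearson R lands inside the
        Fisher-z 95% CI of the configured correlation in >= 90% of 50
        seeded replicates."""
        inside = 0
        for seed in range(50):
            cfg = correlation_recovery_config(rho, n_cells=500, seed=seed)
            cells, controls = sample_measurements(cfg)
            ncm = fit_negative_control(controls)
            gated = cells[cells["kcl_pass"]]
            fm = fit_nonresponder_threshold(gated["auc_aitc"])
            df = gated.rename(columns={"auc_aitc": "auc",
                                       "intensity_trpa1": "rnascope_intensity"})
            classified, _ = classify_cells(df, fm, ncm)
            union = select_union(classified)
            r = pearson(union["rnascope_intensity"], union["auc"]).r
            lo, hi = fisher_interval(rho, len(union))
            inside += (lo <= r <= hi)
        assert inside >= 45

    @pytest.mark.filterwarnings("ignore:channel .*no co-positive")
    def test_zero_expression_false_positive_rate_bounded(self):
        """With no expression anywhere, at most 5% of cells may be called
        RNAscope-positive at the negative-control threshold."""
        ch = (ChannelParams(name="trpa1", agonist="aitc", fraction_expressing=0.0),)
        rates = []
        for seed in range(10):
            cfg = replace(SynthConfig(), channels=ch, seed=seed)
            cells, controls = sample_measurements(cfg)
            thr = fit_negative_control(controls).threshold
            rates.append(float(np.mean(cells["intensity_trpa1"] > thr)))
        assert np.mean(rates) <= 0.05


class TestImageGeneration:
    def test_same_seed_bitwise_identical(self, small_config):
        a = generate_dataset(small_config)
        b = generate_dataset(small_config)
        assert np.array_equal(a.movie, b.movie)
        assert np.array_equal(a.roi_labels, b.roi_labels)
        for k in a.confocal:
            assert np.array_equal(a.confocal[k], b.confocal[k])
        assert np.array_equal(a.negative_controls, b.negative_controls)

    def test_different_seed_differs(self, small_config, small_dataset):
        other = generate_dataset(replace(small_config, seed=12))
        assert not np.array_equal(other.movie, small_dataset.movie)

    def test_expressors_brighter_than_blanks_in_confocal(self, small_dataset):
        """Projected soma intensity separates expressing from blank cells."""
        from calfish.registration import map_rois
        from calfish.rnascope import measure_cells, project_stack
        ds = small_dataset
        labels_conf, _ = map_rois(ds.roi_labels, ds.transform,
                                  ds.confocal_trans.shape)
        proj = project_stack(ds.confocal["trpa1"], "average")
        meas = measure_cells(proj, labels_conf, "trpa1").set_index("cell_id")
        gt = ds.ground_truth.set_index("cell_id")
        expr = meas.loc[gt.index[gt["expressing_trpa1"]], "mean_intensity"]
        blank = meas.loc[gt.index[~gt["expressing_trpa1"]], "mean_intensity"]
        assert expr.min() > blank.max()

    def test_confocal_frame_is_displaced_by_the_configured_transform(
            self, small_dataset):
        ds = small_dataset
        assert ds.transform.rotation_deg == pytest.approx(3.0)
        # cell centers in the confocal frame match the inverse mapping
        conf = ds.transform.inverse().apply_points(ds.centroids_widefield)
        ys, xs = np.nonzero(ds.roi_labels == 1)
        assert ds.roi_labels.max() == ds.config.n_cells

    def test_movie_rises_during_application_for_responders(self, small_dataset):
        ds = small_dataset
        gt = ds.ground_truth
        responders = gt[gt["responder_trpa1"]]
        assert len(responders) > 0
        cid = int(responders["cell_id"].iloc[0])
        mask = ds.roi_labels == cid
        aitc = ds.config.schedule[0]
        pre = ds.movie[int(aitc.start) - 5, 0][mask].mean()
        during = ds.movie[int(aitc.start + aitc.duration) - 5, 0][mask].mean()
        assert during > pre * 1.05
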