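import numpy as np
import pandas as pd
import pytest

from calfish.classify import (category_percentages, classify_cells,
                              fit_nonresponder_threshold, records_from_counts,
                              select_union, ThresholdModel)
from calfish.rnascope import NegativeControlModel
from calfish.synthetic import (discordance_from_counts, sample_measurements,
                               study_emulation_config)
from calfish.rnascope import fit_negative_control


def make_records(aucs, intensities, kcl=None):
    n = len(aucs)
    return pd.DataFrame({
        "cell_id": np.arange(1, n + 1),
        "auc": aucs,
        "rnascope_intensity": intensities,
        "kcl_pass": kcl if kcl is not None else [True] * n,
    })


class TestNonResponderThreshold:
    def test_all_identical_values(self):
        m = fit_nonresponder_threshold(np.full(20, 5.0))
        assert (m.mean, m.sd, m.threshold) == (5.0, 0.0, 5.0)
        assert m.converged

    def test_pure_gaussian_recovers_mean_plus_2sd(self):
        rng = np.random.default_rng(42)
        m = fit_nonresponder_threshold(rng.normal(0.0, 1.0, 10000))
        assert m.threshold == pytest.approx(2.0, abs=0.1)

    def test_planted_responders_are_trimmed_out(self):
        rng = np.random.default_rng(1)
        x = np.concatenate([rng.normal(0, 1, 9000), rng.normal(20, 1, 1000)])
        m = fit_nonresponder_threshold(x)
        assert m.threshold == pytest.approx(2.0, abs=0.3)

    def test_bimodal_realistic_mixture_converges_to_noise_core(self):
        # ~35% responders far above a tight noise core, as in gated data
        rng = np.random.default_rng(2)
        x = np.concatenate([rng.normal(0, 0.15, 276),
                            25 * np.exp(rng.normal(0, 0.7, 149))])
        m = fit_nonresponder_threshold(x)
        assert m.converged
        assert m.threshold < 1.0

    def test_too_few_cells(self):
        with pytest.raises(ValueError, match=">= 10"):
            fit_nonresponder_threshold(np.arange(5.0))


class TestClassification:
    fmodel = ThresholdModel("functional", 0.0, 0.5, 1.0, 100)
    rmodel = NegativeControlModel(1.0, 1.0, 3.0, 50)

    def test_value_at_threshold_is_negative(self):
        rec = make_records([1.0], [3.0])   # both exactly at thresholds
        out, counts = classify_cells(rec, self.fmodel, self.rmodel)
        assert not out["functional_positive"].iloc[0]
        assert not out["rnascope_positive"].iloc[0]
        assert counts["neither"] == 1

    def test_toy_table_spanning_all_quadrants(self):
        rec = make_records(
            aucs=[5.0, 0.0, 0.5, 2.0, 9.0, 0.2],
            intensities=[9.0, 8.0, 7.0, 1.0, 0.0, 0.5])
        out, counts = classify_cells(rec, self.fmodel, self.rmodel)
        assert counts == {"both": 1, "rnascope_only": 2,
                          "functional_only": 2, "neither": 1}
        assert sum(counts.values()) == len(out)

    def test_only_gated_cells_classified(self):
        rec = make_records([5.0, 5.0], [9.0, 9.0], kcl=[True, False])
        out, counts = classify_cells(rec, self.fmodel, self.rmodel)
        assert len(out) == 1 and sum(counts.values()) == 1

    def test_missing_measurement_rejected(self):
        rec = make_records([5.0, np.nan], [9.0, 1.0])
        with pytest.raises(ValueError, match="missing measurement"):
            classify_cells(rec, self.fmodel, self.rmodel)

    def test_category_counts_sum_to_gated(self):
        rng = np.random.default_rng(3)
        rec = make_records(rng.normal(1, 2, 200), rng.normal(3, 2, 200),
                           kcl=rng.random(200) < 0.8)
        out, counts = classify_cells(rec, self.fmodel, self.rmodel)
        assert sum(counts.values()) == int(rec["kcl_pass"].sum())


class TestUnion:
    def test_all_neither_gives_empty_union(self):
        df = records_from_counts(0, 0, 0, neither=10)
        assert len(select_union(df)) == 0

    def test_published_trpa1_breakdown(self):
        df = records_from_counts(both=98, rnascope_only=309, functional_only=95,
                                 neither=388)
        assert len(select_union(df)) == 502

    def test_published_trpv1_breakdown(self):
        df = records_from_counts(both=323, rnascope_only=488, functional_only=22)
        assert len(select_union(df)) == 833

    def test_raising_thresholds_never_grows_the_union(self):
        rng = np.random.default_rng(4)
        rec = make_records(rng.lognormal(1, 1, 300), rng.lognormal(2, 1, 300))
        fth = [0.5, 1.0, 2.0, 5.0, 20.0]
        rth = [1.0, 3.0, 8.0, 30.0]
        sizes_f = []
        for f in fth:
            out, _ = classify_cells(rec, ThresholdModel("f", 0, 0, f, 1),
                                    NegativeControlModel(0, 0, 3.0, 3))
            sizes_f.append(len(select_union(out)))
        assert sizes_f == sorted(sizes_f, reverse=True)
        sizes_r = []
        for r in rth:
            out, _ = classify_cells(rec, ThresholdModel("f", 0, 0, 1.0, 1),
                                    NegativeControlModel(0, 0, r, 3))
            sizes_r.append(len(select_union(out)))
        assert sizes_r == sorted(sizes_r, reverse=True)


class TestFalsePositiveRate:
    def test_pure_gaussian_fp_rate_near_one_sided_2sd_tail(self):
        rates = []
        for seed in range(5):
            rng = np.random.default_rng(100 + seed)
            x = rng.normal(3.0, 2.0, 10000)
            m = fit_nonresponder_threshold(x)
            rates.append(float(np.mean(x > m.threshold)))
        assert np.mean(rates) == pytest.approx(0.023, abs=0.01)


class TestPercentages:
    def test_printed_denominator(self):
        counts = {"both": 527, "functional_only": 197, "rnascope_only": 2,
                  "neither": 0}
        pct = category_percentages(counts, total=724)
        assert round(pct["both"]) == 73
        assert round(pct["functional_only"]) == 27

    def test_default_denominator_sums_counts(self):
        pct = category_percentages({"both": 1, "neither": 3})
        assert pct["both"] == pytest.approx(25.0)


class TestStudyEmulation:
    @pytest.mark.filterwarnings("ignore:channel .*unattainable")
    def test_category_fractions_match_published_proportions(self):
        """Generator configured from the printed 890-cell breakdowns must
        reproduce the observed category fractions within 3 percentage
        points on average over 20 seeds (both probes)."""
        published = {
            "trpa1": {"both": 98, "rnascope_only": 309, "functional_only": 95},
            "trpv1": {"both": 323, "rnascope_only": 488, "functional_only": 22},
        }
        sums = {ch: {} for ch in published}
        n_seeds = 20
        for seed in range(n_seeds):
            cfg = study_emulation_config(published, seed=seed)
            cells, controls = sample_measurements(cfg)
            ncm = fit_negative_control(controls)
            gated = cells[cells["kcl_pass"]]
            for ch, ag in (("trpa1", "aitc"), ("trpv1", "capsaicin")):
                fm = fit_nonresponder_threshold(gated[f"auc_{ag}"])
                df = gated.rename(columns={
                    f"auc_{ag}": "auc", f"intensity_{ch}": "rnascope_intensity"})
                _, counts = classify_cells(df, fm, ncm)
                tot = sum(counts.values())
                for k, v in counts.items():
                    sums[ch][k] = sums[ch].get(k, 0.0) + v / tot / n_seeds
        for ch, pub in published.items():
            pub = dict(pub)
            pub["neither"] = 890 - sum(pub.values())
            for k, target in pub.items():
                assert sums[ch][k] == pytest.approx(target / 890, abs=0.03), (
                    f"{ch}/{k}")

    def test_count_inversion_is_consistent(self):
        # forward-applying the false-positive model to the latent rates
        # returns the observed breakdown
        q = 0.02275013194817921
        rates = discordance_from_counts(98, 309, 95, 388, fp_rate=q)
        fe = rates["fraction_expressing"]
        sil = rates["p_silent_expressor"]
        rn = rates["p_responder_nonexpressor"]
        n = 890.0
        b = n * fe * (1 - sil)
        r = n * fe * sil
        f = n * (1 - fe) * rn
        nn = n * (1 - fe) * (1 - rn)
        assert b + q * r == pytest.approx(98.0)
        assert r * (1 - q) == pytest.approx(309.0)
        assert f + q * nn == pytest.approx(95.0)
        assert nn * (1 - q) == pytest.approx(388.0)
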