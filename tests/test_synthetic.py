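"""Synthetic sputum generator: population distributions, mixtures, controls,
beads and cohorts."""

import dataclasses
import math

import numpy as np
import pytest
from scipy import stats as sps

import sputumflow as sf
from sputumflow.fcs_io import TRUTH_CHANNEL
from sputumflow.synthetic import (
    COCKTAIL,
    TRUTH_CODES,
    TRUTH_DOUBLET,
    _draw_sample_params,
)


def _profile(config, name):
    return next(p for p in config.populations if p.name == name)


@pytest.fixture(scope="module")
def hr_config():
    return sf.build_sample_config(
        sf.default_sample_params("high_risk"), "S0",
        n_events=20_000, control_n_events=10_000, seed=7,
    )


class TestSamplePopulation:
    def test_zero_events(self, hr_config):
        t = sf.sample_population(
            _profile(hr_config, "granulocyte_lymphocyte"), 0, np.random.default_rng(0)
        )
        assert t.n_events == 0 and "CD45" in t.channel_names

    def test_lognormal_median_closed_form(self, hr_config):
        p = _profile(hr_config, "alveolar_macrophage")
        t = sf.sample_population(p, 10_000, np.random.default_rng(1))
        loc, scale = p.stained["CD206"]
        # median of a log-normal is exp(loc); MC-SE of the log-median is
        # ~ 1.2533 * scale / sqrt(n)
        se = 1.2533 * scale / math.sqrt(10_000)
        assert abs(math.log(np.median(t.channel("CD206"))) - loc) < 3 * se

    def test_sec_ssc_exceeds_granulocyte(self, hr_config):
        rng = np.random.default_rng(2)
        sec = sf.sample_population(_profile(hr_config, "sec"), 5000, rng)
        gran = sf.sample_population(
            _profile(hr_config, "granulocyte_lymphocyte"), 5000, rng
        )
        assert np.median(sec.channel("SSC-A")) > np.median(gran.channel("SSC-A"))

    def test_dead_population_exceeds_live_viability_support(self, hr_config):
        rng = np.random.default_rng(3)
        sec = sf.sample_population(_profile(hr_config, "sec"), 20_000, rng)
        gran = sf.sample_population(
            _profile(hr_config, "granulocyte_lymphocyte"), 20_000, rng
        )
        live_thr = np.quantile(gran.channel("FVS510"), 0.9995)
        assert (sec.channel("FVS510") > live_thr).mean() >= 0.99

    def test_invalid_profile_rejected(self):
        with pytest.raises(sf.ConfigurationError):
            sf.PopulationProfile(
                "sec", 1.5, (1000, 1000), (100, 100)
            )
        with pytest.raises(sf.ConfigurationError):
            sf.PopulationProfile(
                "sec", 0.5, (1000, 1000), (100, 100),
                stained={"TCPP": (5.0, -1.0)},
            )


class TestGenerateSample:
    def test_mixture_conservation(self, hr_config):
        tubes = sf.generate_sample(hr_config)
        truth = tubes.leukocyte.channel(TRUTH_CHANNEL)
        n_singlets = (truth != TRUTH_DOUBLET).sum()
        for p in hr_config.populations:
            observed = (truth == TRUTH_CODES[p.name]).sum()
            se = math.sqrt(n_singlets * p.fraction * (1 - p.fraction))
            assert abs(observed - n_singlets * p.fraction) < 4 * se + 1

    def test_no_doublets_means_tight_pulse_ratio(self):
        params = dataclasses.replace(sf.default_sample_params(), doublet_rate=0.0)
        cfg = sf.build_sample_config(params, "S", n_events=5000, seed=1)
        t = sf.generate_sample(cfg).leukocyte
        ratio = t.channel("FSC-H") / t.channel("FSC-A")
        assert np.quantile(ratio, 0.001) > 0.85 and np.quantile(ratio, 0.999) < 1.05

    def test_doublets_carry_summed_area_and_label(self):
        params = dataclasses.replace(sf.default_sample_params(), doublet_rate=0.2)
        cfg = sf.build_sample_config(params, "S", n_events=10_000, seed=2)
        t = sf.generate_sample(cfg).leukocyte
        truth = t.channel(TRUTH_CHANNEL)
        frac = (truth == TRUTH_DOUBLET).mean()
        assert frac == pytest.approx(0.2, abs=0.01)
        dbl = t.subset(truth == TRUTH_DOUBLET)
        sgl = t.subset(truth != TRUTH_DOUBLET)
        assert np.median(dbl.channel("FSC-A")) > 1.5 * np.median(sgl.channel("FSC-A"))
        ratio_dbl = np.median(dbl.channel("FSC-H") / dbl.channel("FSC-A"))
        assert ratio_dbl < 0.75  # height ~ max of the pair, area ~ sum

    def test_same_seed_identical_tubes(self, hr_config):
        a = sf.generate_sample(hr_config)
        b = sf.generate_sample(hr_config)
        np.testing.assert_array_equal(a.leukocyte.values, b.leukocyte.values)
        np.testing.assert_array_equal(a.epithelial.values, b.epithelial.values)

    def test_fractions_must_sum_to_one(self, hr_config):
        bad = [dataclasses.replace(p) for p in hr_config.populations]
        bad[0] = dataclasses.replace(bad[0], fraction=bad[0].fraction + 0.1)
        with pytest.raises(sf.ConfigurationError):
            sf.SampleConfig("S", bad, n_events=100)


@pytest.fixture(scope="module")
def stained_and_controls(hr_config):
    return sf.generate_sample(hr_config), sf.generate_controls(hr_config)


class TestControls:
    def test_fmo_changes_only_omitted_channel(self, stained_and_controls):
        tubes, controls = stained_and_controls
        for fmo, omitted in [
            (controls.fmo_cd206, "CD206"),
            (controls.fmo_cocktail, COCKTAIL),
        ]:
            for ch in tubes.leukocyte.channel_names:
                if ch == TRUTH_CHANNEL:
                    continue
                p = sps.ks_2samp(
                    tubes.leukocyte.channel(ch), fmo.channel(ch)
                ).pvalue
                if ch == omitted:
                    assert p < 1e-6, f"{ch} should revert to baseline"
                else:
                    assert p > 0.01, f"{ch} should keep its stained distribution"

    def test_fmo_retains_tcpp_staining(self, stained_and_controls):
        tubes, controls = stained_and_controls
        p = sps.ks_2samp(
            tubes.leukocyte.channel("TCPP"), controls.fmo_cocktail.channel("TCPP")
        ).pvalue
        assert p > 0.01

    def test_unstained_reverts_cd45_to_baseline(self, stained_and_controls):
        tubes, controls = stained_and_controls
        gran = TRUTH_CODES["granulocyte_lymphocyte"]
        stained_t = tubes.leukocyte
        unstained_t = controls.unstained_leukocyte
        stained_med = np.median(
            stained_t.channel("CD45")[stained_t.channel(TRUTH_CHANNEL) == gran]
        )
        unstained_med = np.median(
            unstained_t.channel("CD45")[unstained_t.channel(TRUTH_CHANNEL) == gran]
        )
        assert unstained_med < stained_med / 20
        # baseline is the shared autofluorescence distribution (median ~60)
        assert 30 < unstained_med < 120


class TestBeads:
    def test_three_clusters_monotone_medians(self):
        t = sf.generate_bead_run([5, 20, 30], np.random.default_rng(0))
        fsc = t.channel("FSC-A")
        groups = np.digitize(fsc, [60_000, 150_000])
        medians = [np.median(fsc[groups == i]) for i in range(3)]
        assert medians[0] < medians[1] < medians[2]

    def test_cluster_cv_bounded(self):
        cv = 0.03
        t = sf.generate_bead_run([20], np.random.default_rng(1), cv=cv)
        fsc = t.channel("FSC-A")
        assert fsc.std() / fsc.mean() < 1.5 * cv

    def test_unsorted_diameters_rejected(self):
        with pytest.raises(sf.ConfigurationError):
            sf.generate_bead_run([30, 5], np.random.default_rng(0))


class TestCohort:
    def test_zero_cancer_gives_pure_highrisk(self):
        cc = sf.default_cohort_config(0, 3, seed=1, n_events=200, control_n_events=100)
        samples = sf.generate_cohort(cc, with_controls=False)
        assert len(samples) == 3
        assert {s.group for s in samples} == {"high_risk"}

    def test_master_seed_determinism(self):
        cc = sf.default_cohort_config(2, 2, seed=9, n_events=500, control_n_events=300)
        a = sf.generate_cohort(cc)
        b = sf.generate_cohort(cc)
        for s, t in zip(a, b):
            assert s.sample_id == t.sample_id and s.smoking == t.smoking
            np.testing.assert_array_equal(
                s.tubes.leukocyte.values, t.tubes.leukocyte.values
            )
            np.testing.assert_array_equal(
                s.controls.fmo_epcam.values, t.controls.fmo_epcam.values
            )

    def test_cancer_group_mean_cd45_matches_configured(self):
        # parameter layer: the configured group mean must be recovered
        # within sampling error of the between-sample dispersion
        gp = sf.default_cohort_config().groups["cancer"]
        rng = np.random.default_rng(5)
        draws = np.array([_draw_sample_params(gp, rng)[0].cd45_frac for _ in range(200)])
        se = draws.std(ddof=1) / math.sqrt(len(draws))
        assert abs(draws.mean() - 0.4964) < 3 * se + 0.01

    def test_group_effect_directions_configured(self):
        cc = sf.default_cohort_config()
        ca, hr = cc.groups["cancer"].base, cc.groups["high_risk"].base
        assert ca.cd45_frac > hr.cd45_frac
        assert ca.gate1_frac > hr.gate1_frac and ca.gate3_frac > hr.gate3_frac
        assert ca.dp_frac > hr.dp_frac
        assert ca.epcam_loc > hr.epcam_loc
        assert ca.ssc_scale_bright < hr.ssc_scale_bright

    def test_cohort_dirs_roundtrip(self, tmp_path):
        cc = sf.default_cohort_config(1, 1, seed=3, n_events=400, control_n_events=300)
        samples = sf.generate_cohort(cc)
        sf.synthetic.write_cohort(samples, tmp_path)
        tubes, controls, sid = sf.synthetic.read_sample_dir(tmp_path / samples[0].sample_id)
        assert sid == samples[0].sample_id
        np.testing.assert_allclose(
            tubes.leukocyte.values, samples[0].tubes.leukocyte.values,
            rtol=1e-6, atol=1e-2,
        )
        meta = (tmp_path / "metadata.tsv").read_text().splitlines()
        assert meta[0].startswith("sample_id\tgroup") and len(meta) == 3
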