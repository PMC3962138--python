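import math

import numpy as np
import pytest

from nadquant.chromatography import detect_and_integrate, select_peak
from nadquant.simulate import (
    DEMO_TRUE_CONC_UM,
    SimConfig,
    default_response_factors,
    simulate_experiment,
    simulate_injection,
    simulate_standard_series,
)


@pytest.fixture(scope="module")
def quiet_config(panel):
    return SimConfig(seed=0, panel=panel).noise_free()


class TestSimulateInjection:
    def test_empty_contents_noise_free_gives_flat_traces(self, quiet_config):
        inj = simulate_injection(
            quiet_config, "i0", "alkaline", {}, {}, rng=quiet_config.rng()
        )
        for trace in inj.traces.values():
            assert np.all(trace.intensities == 0.0)

    def test_peak_area_matches_amount_times_response(self, quiet_config):
        rf = quiet_config.response_factor["NAD"]
        inj = simulate_injection(
            quiet_config, "i0", "alkaline", {"NAD": 10.0}, {}, rng=quiet_config.rng()
        )
        trace = inj.traces["NAD:light"]
        # fine-grid quadrature of the rendered trace
        assert np.trapezoid(trace.intensities, trace.times) == pytest.approx(
            10.0 * rf, rel=0.01
        )

    def test_fragmentation_moves_signal_at_source_rt(self, panel):
        config = SimConfig(
            seed=0, panel=panel, fragmentation_fraction={("NR", "Nam"): 0.2}
        ).noise_free()
        rf = config.response_factor["NR"]
        inj = simulate_injection(
            config, "i0", "acidic", {"NR": 10.0}, {}, rng=config.rng()
        )
        nam = inj.traces["Nam:light"]
        peaks = detect_and_integrate(nam, noise=1.0)
        assert len(peaks) == 1
        # crosstalk peak sits at NR's retention time, not Nam's
        assert peaks[0].apex_rt == pytest.approx(8.98, abs=0.02)
        assert peaks[0].area == pytest.approx(0.2 * 10.0 * rf, rel=0.01)
        # and the source channel conserves the remaining fraction
        nr_peaks = detect_and_integrate(inj.traces["NR:light"], noise=1.0)
        assert nr_peaks[0].area == pytest.approx(0.8 * 10.0 * rf, rel=0.01)

    def test_unknown_metabolite_rejected(self, quiet_config):
        with pytest.raises(KeyError):
            simulate_injection(
                quiet_config, "i0", "alkaline", {"Caffeine": 1.0}, {},
                rng=quiet_config.rng(),
            )

    def test_suppression_scales_light_and_heavy_identically(self, quiet_config):
        plain = simulate_injection(
            quiet_config, "a", "alkaline", {"NAD": 10.0}, {"NAD": 20.0},
            rng=quiet_config.rng(),
        )
        damped = simulate_injection(
            quiet_config, "b", "alkaline", {"NAD": 10.0}, {"NAD": 20.0},
            rng=quiet_config.rng(), suppression=0.4,
        )
        truth = {(r.metabolite, r.channel): r.pre_noise_area for r in plain.truth
                 if r.metabolite == "NAD"}
        damped_truth = {(r.metabolite, r.channel): r.pre_noise_area
                        for r in damped.truth if r.metabolite == "NAD"}
        ratio_light = damped_truth[("NAD", "light")] / truth[("NAD", "light")]
        ratio_heavy = damped_truth[("NAD", "heavy")] / truth[("NAD", "heavy")]
        assert ratio_light == pytest.approx(0.4, rel=1e-12)
        assert ratio_heavy == pytest.approx(ratio_light, rel=1e-12)


class TestStandardSeries:
    def test_nine_levels_per_separation(self, quiet_config):
        injections = simulate_standard_series(quiet_config)
        per_sep = {}
        for inj in injections:
            per_sep.setdefault(inj.separation, []).append(inj)
        assert len(per_sep["alkaline"]) == 9
        assert len(per_sep["acidic"]) == 9

    def test_zero_level_has_no_light_signal(self, quiet_config):
        injections = simulate_standard_series(quiet_config)
        level0 = [i for i in injections if i.level_um == 0.0]
        for inj in level0:
            for rec in inj.truth:
                if rec.channel == "light":
                    assert rec.true_pmol == 0.0 and rec.pre_noise_area == 0.0

    def test_top_level_puts_250_pmol_on_column(self, quiet_config):
        injections = simulate_standard_series(quiet_config)
        top = [i for i in injections if i.level_um == 200.0]
        for inj in top:
            for rec in inj.truth:
                if rec.channel == "light" and rec.true_pmol > 0:
                    assert rec.true_pmol == pytest.approx(250.0)


class TestExperiment:
    def test_replicates_emit_one_prep_each(self, quiet_config):
        injections, preps = simulate_experiment(quiet_config, replicates=3)
        assert len(preps) == 3
        assert len(injections) == 6  # alkaline + acidic per replicate
        assert len({p.sample_id for p in preps}) == 3

    def test_seed_changes_noise_but_not_design(self, panel):
        a = SimConfig(seed=1, panel=panel)
        b = SimConfig(seed=2, panel=panel)
        inj_a, _ = simulate_experiment(a, replicates=1)
        inj_b, _ = simulate_experiment(b, replicates=1)
        ta = inj_a[0].traces["NAD:light"].intensities
        tb = inj_b[0].traces["NAD:light"].intensities
        assert not np.array_equal(ta, tb)
        assert a.true_conc_um == b.true_conc_um

    def test_identical_seed_is_bit_identical(self, panel):
        runs = []
        for _ in range(2):
            config = SimConfig(seed=11, panel=panel)
            rng = config.rng()
            injections = simulate_standard_series(config, rng=rng)
            injections += simulate_experiment(config, replicates=1, rng=rng)[0]
            runs.append(injections)
        for inj_a, inj_b in zip(*runs):
            assert inj_a.injection_id == inj_b.injection_id
            for cid, trace in inj_a.traces.items():
                assert np.array_equal(trace.intensities, inj_b.traces[cid].intensities)


class TestDefaults:
    def test_response_factors_reproduce_loq_ordering(self):
        rf = default_response_factors()
        # least sensitive channels by design: NMN, ATP, NA, uridine
        least = sorted(rf, key=rf.get)[:4]
        assert set(least) == {"NMN", "ATP", "NA", "Uridine"}

    def test_demo_truth_covers_every_quantifiable_metabolite(self, panel):
        names = {m.name for m in panel.quantifiable()}
        assert names == set(DEMO_TRUE_CONC_UM)

    def test_selected_peaks_stay_within_window_of_generating_rt(self, panel):
        config = SimConfig(seed=3, panel=panel)
        rng = config.rng()
        injections, _ = simulate_experiment(config, replicates=1, rng=rng)
        for inj in injections:
            for cid, trace in inj.traces.items():
                met = cid.split(":")[0]
                peaks = detect_and_integrate(trace, noise=config.baseline_sigma)
                chosen = select_peak(peaks, panel[met].expected_rt, 0.3)
                if chosen is not None:
                    assert abs(chosen.apex_rt - panel[met].expected_rt) <= 0.3
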