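"""Synthetic slow-exchange HSQC series and rendered-grid round trips."""

import numpy as np
import pytest

from sidmap import (
    PerturbationScenario,
    WeightingScheme,
    fig4b_scenario,
    make_apo_peaklist,
    make_complex_series,
    match_peaks,
    minimal_shift_summary,
    pick_peaks,
    render_grid,
    weighted_distance,
)


class TestApoGenerator:
    def test_zero_peaks_gives_empty_list(self):
        assert len(make_apo_peaklist(n=0, seed=1)) == 0

    def test_deterministic_per_seed(self):
        a = make_apo_peaklist(n=90, seed=13)
        b = make_apo_peaklist(n=90, seed=13)
        assert [(p.id, p.h_ppm, p.n_ppm) for p in a] == [(p.id, p.h_ppm, p.n_ppm) for p in b]
        c = make_apo_peaklist(n=90, seed=14)
        assert [(p.h_ppm, p.n_ppm) for p in a] != [(p.h_ppm, p.n_ppm) for p in c]

    def test_box_and_min_separation(self):
        pl = make_apo_peaklist(n=90, seed=2)
        scheme = WeightingScheme()
        coords = [(p.h_ppm, p.n_ppm) for p in pl]
        assert all(6.5 <= h <= 10.5 and 103 <= n <= 133 for h, n in coords)
        dmin = min(
            weighted_distance(h1 - h2, n1 - n2, scheme)
            for i, (h1, n1) in enumerate(coords)
            for h2, n2 in coords[i + 1 :]
        )
        # positions are written at 1e-4 ppm precision, allow that rounding
        assert dmin >= 0.05 - 2e-4

    def test_nh2_pairs_flagged(self):
        pl = make_apo_peaklist(n=10, seed=3, n_nh2_pairs=2)
        flagged = [p for p in pl if p.kind == "sidechain_nh2"]
        assert len(flagged) == 4
        assert all(6.4 <= p.h_ppm <= 7.8 for p in flagged)

    def test_impossible_packing_raises(self):
        with pytest.raises(RuntimeError):
            make_apo_peaklist(n=500, seed=0, min_separation=1.0)


class TestComplexSeries:
    def test_zero_multiplier_zero_jitter_is_identity(self):
        apo = make_apo_peaklist(n=40, seed=5)
        scen = PerturbationScenario(mean_shift=0.1, effect_multipliers={"null": 0.0},
                                    jitter_sigma=0.0, seed=5)
        series = make_complex_series(apo, scen)
        s = minimal_shift_summary(series.lists["apo"], series.lists["null"])
        assert s.delta_min == 0.0

    def test_wt_exceeds_weak_mutant_and_matches_expectation(self):
        deltas_wt, deltas_mut = [], []
        for seed in range(20):
            apo = make_apo_peaklist(n=60, seed=seed)
            scen = PerturbationScenario(
                interface_fraction=0.3, mean_shift=0.1,
                effect_multipliers={"WT": 1.0, "mutA": 0.1}, jitter_sigma=0.0, seed=seed,
            )
            series = make_complex_series(apo, scen)
            deltas_wt.append(minimal_shift_summary(series.lists["apo"], series.lists["WT"]).delta_min)
            deltas_mut.append(minimal_shift_summary(series.lists["apo"], series.lists["mutA"]).delta_min)
        assert np.mean(deltas_wt) > np.mean(deltas_mut)
        # expectation by construction: interface_fraction x mean_shift
        assert np.mean(deltas_wt) == pytest.approx(0.03, rel=0.25)

    def test_true_correspondence_recovered_when_shifts_small(self):
        apo = make_apo_peaklist(n=50, seed=7, min_separation=0.08)
        scen = PerturbationScenario(mean_shift=0.02, effect_multipliers={"WT": 1.0},
                                    jitter_sigma=0.0, seed=7)
        series = make_complex_series(apo, scen)
        res = match_peaks(series.lists["apo"], series.lists["WT"])
        assert all(ida == idb for ida, idb, _ in res.pairs)

    def test_delta_min_monotone_in_mean_shift(self):
        means = []
        for mean_shift in (0.02, 0.05, 0.1, 0.2):
            vals = []
            for seed in range(5):
                apo = make_apo_peaklist(n=60, seed=seed)
                scen = PerturbationScenario(mean_shift=mean_shift,
                                            effect_multipliers={"WT": 1.0},
                                            jitter_sigma=0.0, seed=seed)
                series = make_complex_series(apo, scen)
                vals.append(minimal_shift_summary(series.lists["apo"], series.lists["WT"]).delta_min)
            means.append(np.mean(vals))
        assert means == sorted(means)

    def test_substoichiometric_flag_adds_apo_twins(self):
        apo = make_apo_peaklist(n=30, seed=9)
        scen = PerturbationScenario(mean_shift=0.2, effect_multipliers={"WT": 1.0},
                                    jitter_sigma=0.0, substoichiometric=1.0, seed=9)
        series = make_complex_series(apo, scen)
        twins = [p for p in series.lists["WT"] if p.id.endswith("_apo")]
        assert len(twins) == len(series.interface_ids)

    def test_exchangeable_labels_give_similar_delta_min(self):
        # two labels with identical multipliers: mean difference below
        # twice its standard error over 30 seeds
        diffs = []
        for seed in range(30):
            apo = make_apo_peaklist(n=60, seed=seed)
            scen = PerturbationScenario(mean_shift=0.1,
                                        effect_multipliers={"u": 0.5, "v": 0.5},
                                        jitter_sigma=0.004, seed=seed)
            series = make_complex_series(apo, scen)
            du = minimal_shift_summary(series.lists["apo"], series.lists["u"]).delta_min
            dv = minimal_shift_summary(series.lists["apo"], series.lists["v"]).delta_min
            diffs.append(du - dv)
        se = np.std(diffs, ddof=1) / np.sqrt(len(diffs))
        assert abs(np.mean(diffs)) < 2 * se + 1e-12

    def test_empty_apo_rejected(self):
        from sidmap import PeakList

        with pytest.raises(ValueError):
            make_complex_series(PeakList([]), PerturbationScenario())


class TestRenderGrid:
    def test_single_peak_apex_on_grid(self):
        pl = make_apo_peaklist(n=1, seed=1)
        grid = render_grid(pl, noise_sigma=0.0)
        r, c = np.unravel_index(np.argmax(grid.intensities), grid.shape)
        p = pl.peaks[0]
        assert abs(grid.h_axis[c] - p.h_ppm) <= grid.h_axis[1] - grid.h_axis[0]
        assert abs(grid.n_axis[r] - p.n_ppm) <= grid.n_axis[1] - grid.n_axis[0]

    def test_pick_recovers_twenty_separated_peaks(self):
        pl = make_apo_peaklist(n=20, seed=4, min_separation=0.3)
        grid = render_grid(pl, noise_sigma=0.05, seed=4)  # SNR ~ 20
        peaks = pick_peaks(grid, threshold_factor=5.0, merge_radius=(0.04, 0.5))
        assert len(peaks) == 20

    def test_noise_only_false_positive_rate_at_low_threshold(self):
        # picking pure i.i.d. noise at 1.4 sigma fires on ~6% of pixels
        # (local maximum above threshold): that factor assumes later manual
        # curation. Bound the rate so regressions are visible.
        pl = make_apo_peaklist(n=4, seed=8)
        quiet = [type(p)(id=p.id, h_ppm=p.h_ppm, n_ppm=p.n_ppm, intensity=0.0) for p in pl]
        from sidmap import PeakList

        grid = render_grid(PeakList(quiet), noise_sigma=1.0, seed=8, default_intensity=0.0,
                           grid_shape=(128, 128))
        n_false = len(pick_peaks(grid, threshold_factor=1.4))
        assert 0 < n_false < 0.10 * grid.intensities.size

    def test_empty_list_rejected(self):
        from sidmap import PeakList

        with pytest.raises(ValueError):
            render_grid(PeakList([]))


def test_fig4b_scenario_shape():
    apo, scen = fig4b_scenario(seed=0)
    assert len(apo) == 72
    assert set(scen.effect_multipliers) == {"WT", "L897A", "L900A", "I894A", "T898E", "T898A"}
    mult = scen.effect_multipliers
    assert mult["WT"] > mult["T898A"] > mult["T898E"] > mult["I894A"] > mult["L900A"] > mult["L897A"]
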