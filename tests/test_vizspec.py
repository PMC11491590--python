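import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from caratlas.graph import ValidationError
from caratlas.summaries import summarize_one
from caratlas.vizspec import (
    NEUTRAL_YELLOW,
    StyleSpec,
    apply_transparency,
    color_class_edges,
    estimate_color,
    overview_spec,
    render,
    v_plot_spec,
    wave_plot_spec,
)


def make_summary(draws, area_id="a"):
    return summarize_one(area_id, draws)


class TestWavePlot:
    def spec_for(self, draws):
        return wave_plot_spec(draws, make_summary(draws))

    def test_density_integrates_to_one(self, rng):
        spec = self.spec_for(rng.lognormal(0.3, 0.5, 2000))
        integral = np.trapezoid(spec.density, spec.log_grid)
        assert 0.98 <= integral <= 1.02

    def test_symmetric_draws_peak_near_zero(self, rng):
        z = rng.standard_normal(5000) * 0.3
        z = np.concatenate([z, -z])  # exactly symmetric in log space
        spec = self.spec_for(np.exp(z))
        step = spec.log_grid[1] - spec.log_grid[0]
        peak = spec.log_grid[np.argmax(spec.density)]
        assert abs(peak) <= step

    def test_lognormal_density_closed_form_at_mode(self, rng):
        x = rng.lognormal(0, 0.25, 10_000)
        spec = self.spec_for(x)
        k = np.argmin(np.abs(spec.log_grid))
        expected = 1.0 / (0.25 * np.sqrt(2 * np.pi))  # = 1.5958
        assert spec.density[k] == pytest.approx(expected, rel=0.10)

    def test_tick_labels_are_exponentiated_positions(self, rng):
        spec = self.spec_for(rng.lognormal(0, 0.4, 1000))
        assert len(spec.ticks) > 0
        for pos, label in spec.ticks:
            assert float(label) == pytest.approx(np.exp(pos), abs=0.005)

    def test_too_few_draws_rejected(self):
        with pytest.raises(ValidationError):
            self.spec_for(np.ones(10))


class TestVPlot:
    def test_folded_confidence_on_y(self, rng):
        draws = rng.lognormal(0.5, 0.2, (400, 2))
        summaries = [make_summary(draws[:, k], f"a{k}") for k in range(2)]
        pts = v_plot_spec(summaries)
        for p, s in zip(pts, summaries):
            assert p.y == max(s.ppd, 1 - s.ppd)
            assert p.x == s.point

    def test_reciprocal_draws_mirror_x_and_keep_y(self, rng):
        x = rng.lognormal(0.4, 0.3, 401)  # odd count: median is an order stat
        s1 = make_summary(x)
        s2 = make_summary(1.0 / x)
        p1, p2 = v_plot_spec([s1]), v_plot_spec([s2])
        assert np.log(p2[0].x) == pytest.approx(-np.log(p1[0].x), rel=1e-9)
        assert p2[0].y == pytest.approx(p1[0].y)

    def test_misaligned_styles_rejected(self, rng):
        s = [make_summary(rng.lognormal(0, 0.2, 100), "a")]
        styles = [StyleSpec(area_id="b", fill="#FFFFFF", alpha=1.0)]
        with pytest.raises(ValidationError):
            v_plot_spec(s, styles)

    def test_rank_correlation_against_brute_force(self, rng):
        from scipy.stats import spearmanr

        draws = rng.lognormal(0, 0.3, (500, 20)) * rng.lognormal(0, 0.2, 20)
        summaries = [make_summary(draws[:, k], f"a{k}") for k in range(20)]
        pts = v_plot_spec(summaries)
        r_pkg = spearmanr([abs(np.log(p.x)) for p in pts],
                          [p.y for p in pts]).statistic
        # brute-force recomputation from the raw draws
        xs, ys = [], []
        for k in range(20):
            col = draws[:, k]
            p = np.mean(col > 1)
            xs.append(abs(np.log(np.median(col))))
            ys.append(max(p, 1 - p))
        r_ref = spearmanr(xs, ys).statistic
        assert r_pkg == pytest.approx(r_ref)


class TestEstimateColor:
    def test_national_average_is_pale_yellow(self):
        assert estimate_color(1.0) == NEUTRAL_YELLOW
        assert estimate_color(1.0, breakpoints=(0.25, 4.0)) == NEUTRAL_YELLOW

    def test_clamps_beyond_breakpoints(self):
        assert estimate_color(0.25) == estimate_color(0.5)
        assert estimate_color(8.0) == estimate_color(2.0)

    def test_quarter_point_matches_anchor(self):
        # t = 0.25 at estimate 2**-0.5 for breakpoints (0.5, 2)
        assert estimate_color(2 ** -0.5) == "#ABD9E9"

    def test_interpolation_arithmetic(self):
        # t = 0.125: halfway between the blue anchor and the 0.25 anchor
        e = np.exp(np.log(0.5) + 0.125 * (np.log(2.0) - np.log(0.5)))
        a, b = (0x2C, 0x7B, 0xB6), (0xAB, 0xD9, 0xE9)
        got = estimate_color(e).lstrip("#")
        channels = [int(got[k:k + 2], 16) for k in (0, 2, 4)]
        for ch, x, y in zip(channels, a, b):
            assert abs(ch - (x + y) / 2) <= 0.51  # midpoint up to hex rounding

    def test_nonpositive_estimate_rejected(self):
        with pytest.raises(ValueError):
            estimate_color(0.0)


class TestTransparency:
    def test_maximal_fade_at_half(self):
        s = apply_transparency("#D7191C", 0.5)
        assert s.alpha == pytest.approx(0.1)

    def test_fully_opaque_when_certain(self):
        s = apply_transparency("#D7191C", 1.0)
        assert s.alpha == 1.0
        assert s.composited_fill() == "#D7191C"

    def test_piecewise_linear_value(self):
        # c = 0.3 -> alpha = 0.1 + 0.9 * (0.3 - 0.2) / 0.4 = 0.325
        s = apply_transparency("#D7191C", 0.65)
        assert s.alpha == pytest.approx(0.325)

    def test_disabled_forces_opaque(self):
        s = apply_transparency("#D7191C", 0.5, enabled=False)
        assert s.alpha == 1.0

    @settings(derandomize=True, max_examples=80)
    @given(st.floats(min_value=0.0, max_value=1.0),
           st.floats(min_value=0.0, max_value=1.0))
    def test_alpha_monotone_in_distance_from_half(self, p1, p2):
        a1 = apply_transparency("#D7191C", p1).alpha
        a2 = apply_transparency("#D7191C", p2).alpha
        if abs(p1 - 0.5) <= abs(p2 - 0.5):
            assert a1 <= a2 + 1e-12

    def test_invalid_mapping_rejected(self):
        with pytest.raises(ValueError):
            apply_transparency("#D7191C", 0.5, mapping=(0.6, 0.2, 0.1))


class TestOverview:
    def summaries(self, rng, n=12):
        draws = rng.lognormal(0, 0.4, (300, n)) * rng.lognormal(0, 0.3, n)
        return [make_summary(draws[:, k], f"a{k}") for k in range(n)]

    def test_single_bin_group_is_100_percent(self, rng):
        s = [make_summary(np.full(100, 1.01), f"a{k}") for k in range(4)]
        spec = overview_spec(s, {f"a{k}": "G" for k in range(4)})
        vals = spec.values["G"]
        assert vals.sum() == pytest.approx(100.0, abs=0.01)
        assert np.count_nonzero(vals) == 1

    def test_percentages_sum_to_100_per_group(self, rng):
        s = self.summaries(rng)
        groups = {x.area_id: ("north" if k < 5 else "south")
                  for k, x in enumerate(s)}
        spec = overview_spec(s, groups, mode="percentage")
        for g in spec.groups:
            assert spec.values[g].sum() == pytest.approx(100.0, abs=0.01)

    def test_counts_conserve_group_sizes(self, rng):
        s = self.summaries(rng)
        groups = {x.area_id: ("north" if k < 5 else "south")
                  for k, x in enumerate(s)}
        spec = overview_spec(s, groups, mode="count")
        assert spec.values["north"].sum() == 5
        assert spec.values["south"].sum() == 7

    def test_boxplot_quartiles_match_sorting_oracle(self, rng):
        s = self.summaries(rng)
        groups = {x.area_id: f"g{k % 3}" for k, x in enumerate(s)}
        spec = overview_spec(s, groups, mode="boxplot")
        for g in spec.groups:
            pts = sorted(x.point for x in s if groups[x.area_id] == g)
            mn, q1, med, q3, mx = spec.values[g]
            assert mn == pts[0] and mx == pts[-1]
            assert q1 == pytest.approx(np.quantile(pts, 0.25))
            assert med == pytest.approx(np.median(pts))

    def test_unassigned_area_rejected(self, rng):
        s = self.summaries(rng, n=3)
        with pytest.raises(ValidationError):
            overview_spec(s, {"a0": "G", "a1": "G"})

    def test_class_edges_cover_the_line(self):
        edges, colors = color_class_edges()
        assert edges[0] == 0.0 and edges[-1] == np.inf
        assert len(colors) == len(edges) - 1


class TestRender:
    def test_all_spec_kinds_produce_files(self, rng, tmp_path):
        from caratlas.synthetic import lattice_polygons

        draws = rng.lognormal(0.2, 0.3, (300, 4))
        ids = ["r0c0", "r0c1", "r1c0", "r1c1"]
        summaries = [make_summary(draws[:, k], ids[k]) for k in range(4)]
        wave = wave_plot_spec(draws[:, 0], summaries[0])
        from caratlas.vizspec import styles_for_summaries

        styles = styles_for_summaries(summaries)
        pts = v_plot_spec(summaries, styles)
        ov = overview_spec(summaries, {i: "all" for i in ids})
        polys = lattice_polygons(2, 2)
        for spec, name in [(wave, "w.png"), (pts, "v.png"), (ov, "o.svg")]:
            out = render(spec, tmp_path / name)
            assert (tmp_path / name).stat().st_size > 0
        render(styles, tmp_path / "map.png", polygons=polys)
        assert (tmp_path / "map.png").stat().st_size > 0

    def test_transparency_toggle_changes_only_uncertain_areas(self, rng):
        from caratlas.vizspec import styles_for_summaries

        draws = rng.lognormal(0, 0.3, (400, 9)) * rng.lognormal(0, 0.5, 9)
        summaries = [make_summary(draws[:, k], f"a{k}") for k in range(9)]
        on = styles_for_summaries(summaries, enabled=True)
        off = styles_for_summaries(summaries, enabled=False)
        c_lo, c_hi = 0.2, 0.6
        for s_on, s_off, summ in zip(on, off, summaries):
            c = 2 * abs(summ.ppd - 0.5)
            if c >= c_hi:
                assert s_on.alpha == s_off.alpha == 1.0
                assert s_on.composited_fill() == s_off.composited_fill()
            else:
                assert s_on.alpha < 1.0 == s_off.alpha

    def test_missing_polygon_rejected(self, rng):
        styles = [StyleSpec(area_id="zz", fill="#FFFFFF", alpha=1.0)]
        with pytest.raises(ValidationError):
            render(styles, "unused.png", polygons={})
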