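"""Path profiles, ROI summaries, the pair-ratio statistic, group comparisons."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from adductshift.spatial import (
    PixelPath,
    compare_groups,
    extract_path_profile,
    na_k_fractions,
    roi_summary,
    trace_crypt_path,
)


class TestNaKFractions:
    @pytest.mark.parametrize(
        "na, k, expect",
        [
            (50, 50, (0.5, 0.5)),  # healthy colon mucosa regime
            (30, 70, (0.3, 0.7)),  # adenomatous regime
            (0, 5, (0.0, 1.0)),
        ],
    )
    def test_pair_values(self, na, k, expect):
        assert na_k_fractions(na, k) == (pytest.approx(expect[0]), pytest.approx(expect[1]))

    def test_undefined_when_both_zero(self):
        f_na, f_k = na_k_fractions(0.0, 0.0)
        assert np.isnan(f_na) and np.isnan(f_k)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            na_k_fractions(-1.0, 2.0)

    @given(
        na=st.floats(min_value=0, max_value=1e6),
        k=st.floats(min_value=1e-9, max_value=1e6),
        scale=st.floats(min_value=1e-3, max_value=1e3),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_sums_to_one_and_scale_invariant(self, na, k, scale):
        f_na, f_k = na_k_fractions(na, k)
        assert f_na + f_k == pytest.approx(1.0)
        f_na2, _ = na_k_fractions(na * scale, k * scale)
        assert f_na2 == pytest.approx(f_na, rel=1e-9)

    def test_monotone_in_k(self):
        ks = np.linspace(0.1, 10, 50)
        _, f_k = na_k_fractions(np.full_like(ks, 2.0), ks)
        assert np.all(np.diff(f_k) > 0)


class TestPixelPath:
    def test_waypoint_densification_is_8_connected(self):
        path = PixelPath.from_waypoints([(0, 0), (5, 9), (12, 9)], "epithelium")
        assert path.pixels[0] == (0, 0)
        assert path.pixels[-1] == (12, 9)
        # validity of 8-connectivity is enforced by the constructor

    def test_arc_length_diagonal_steps(self):
        path = PixelPath.from_waypoints([(0, 0), (9, 9)], "epithelium", pixel_spacing=10.0)
        assert path.arc_length[-1] == pytest.approx(9 * 10.0 * np.sqrt(2))

    def test_short_or_revisiting_path_rejected(self):
        with pytest.raises(ValueError, match="at least 10"):
            PixelPath([(0, 0), (1, 0)], "epithelium")
        pixels = [(i, 0) for i in range(10)] + [(9, 0)]
        with pytest.raises(ValueError):
            PixelPath(pixels, "epithelium")

    def test_trace_crypt_runs_base_to_top(self, small_layout):
        path = trace_crypt_path(small_layout, crypt=0)
        axes = [small_layout.crypt_axis[y, x] for x, y in path.pixels]
        assert axes[0] == pytest.approx(0.0)
        assert axes[-1] == pytest.approx(1.0)
        assert np.all(np.diff(axes) >= 0)


class TestExtractPathProfile:
    def test_flat_species_constant_at_zero_noise(self, noiseless_table, small_layout):
        path = trace_crypt_path(small_layout, crypt=0)
        profile = extract_path_profile(noiseless_table, path, species=["PC 34:1"])
        track = profile.track("PC 34:1")
        # flat species, zero noise: pair fractions constant along the crypt
        assert track["f_K"].std() == pytest.approx(0.0, abs=1e-12)

    def test_gradient_species_slopes_but_ratio_flat(self, noiseless_table, small_layout):
        path = trace_crypt_path(small_layout, crypt=0)
        profile = extract_path_profile(noiseless_table, path, species=["PC 32:0"])
        track = profile.track("PC 32:0")
        total = track[["I_H", "I_Na", "I_K"]].sum(axis=1)
        axis = np.array([small_layout.crypt_axis[y, x] for x, y in path.pixels])
        slope = np.polyfit(axis, total, 1)[0]
        assert slope < 0  # configured negative crypt gradient
        assert track["f_K"].std() == pytest.approx(0.0, abs=1e-9)
        assert track["f_K"].iloc[0] == pytest.approx(0.5, abs=1e-9)

    def test_reversed_path_reverses_profile(self, noiseless_table, small_layout):
        path = trace_crypt_path(small_layout, crypt=0)
        fwd = extract_path_profile(noiseless_table, path, species=["PC 36:2"]).frame
        rev = extract_path_profile(
            noiseless_table, path.reversed(), species=["PC 36:2"]
        ).frame
        np.testing.assert_allclose(
            fwd["I_K"].to_numpy(), rev["I_K"].to_numpy()[::-1]
        )
        np.testing.assert_allclose(fwd["f_K"].to_numpy(), rev["f_K"].to_numpy()[::-1])

    def test_path_outside_raster_names_pixel(self, noiseless_table):
        path = PixelPath([(200 + i, 200) for i in range(12)], "epithelium")
        with pytest.raises(ValueError, match=r"\(200, 200\)"):
            extract_path_profile(noiseless_table, path)

    def test_smoothing_window_validation(self, noiseless_table, small_layout):
        path = trace_crypt_path(small_layout, crypt=0)
        with pytest.raises(ValueError):
            extract_path_profile(noiseless_table, path, smooth_window=4)
        prof = extract_path_profile(noiseless_table, path, smooth_window=5)
        assert prof.smoothed is not None
        assert len(prof.smoothed) == len(prof.frame)


class TestRoiSummary:
    def test_zero_noise_epithelium_fk_exact(self, noiseless_table, small_layout):
        summary = roi_summary(noiseless_table, "epithelium", small_layout)
        for _, row in summary.iterrows():
            assert row["mean_fK"] == pytest.approx(0.5, abs=1e-9)
            assert row["pooled_fK"] == pytest.approx(0.5, abs=1e-9)

    def test_compartment_independence_under_shared_partition(
        self, noiseless_table, small_layout
    ):
        epi = roi_summary(noiseless_table, "epithelium", small_layout).set_index("species")
        lam = roi_summary(noiseless_table, "lamina_propria", small_layout).set_index("species")
        for name in epi.index:
            assert epi.loc[name, "mean_fK"] == pytest.approx(
                lam.loc[name, "mean_fK"], abs=1e-9
            )

    def test_missing_compartment_raises(self, noiseless_table):
        with pytest.raises(ValueError):
            roi_summary(noiseless_table, "muscularis")


def _fake_summary(f_k: float, jitter: float, seed: int) -> pd.DataFrame:
    rng = np.random.default_rng(seed)
    rows = []
    for name in ("PC 34:1", "PC 36:3"):
        fk = np.clip(f_k + rng.normal(0, jitter), 0.01, 0.99)
        rows.append(
            {
                "species": name,
                "mean_H": 0.3 + rng.normal(0, jitter),
                "mean_Na": (1 - fk) * 0.7,
                "mean_K": fk * 0.7,
                "mean_fK": fk,
                "pooled_fK": fk,
                "n_pixels": 100,
            }
        )
    return pd.DataFrame(rows)


class TestCompareGroups:
    def test_identical_groups_no_effect(self):
        group = [_fake_summary(0.5, 0.02, s) for s in range(4)]
        comparison = compare_groups(group, group, paired=True)
        assert (comparison.fractions["t"] == 0).all()
        assert (comparison.fractions["p"] == 1).all()

    def test_direction_of_shift_detected(self):
        healthy = [_fake_summary(0.5, 0.01, s) for s in range(4)]
        adenoma = [_fake_summary(0.7, 0.01, 10 + s) for s in range(3)]
        comparison = compare_groups(healthy, adenoma, paired=False)
        assert (
            comparison.fractions["mean_fK_adenoma"]
            > comparison.fractions["mean_fK_healthy"]
        ).all()
        assert (comparison.fractions["p"] < 0.05).all()

    def test_proportions_sum_to_one_per_species_and_group(self):
        healthy = [_fake_summary(0.5, 0.02, s) for s in range(4)]
        adenoma = [_fake_summary(0.7, 0.02, 10 + s) for s in range(3)]
        comparison = compare_groups(healthy, adenoma)
        sums = comparison.proportions[["prop_H", "prop_Na", "prop_K"]].sum(axis=1)
        np.testing.assert_allclose(sums, 1.0, rtol=1e-9)

    def test_paired_requires_equal_counts(self):
        healthy = [_fake_summary(0.5, 0.02, s) for s in range(4)]
        adenoma = [_fake_summary(0.7, 0.02, s) for s in range(3)]
        with pytest.raises(ValueError, match="equal subject counts"):
            compare_groups(healthy, adenoma, paired=True)

    def test_bh_adjustment_available(self):
        healthy = [_fake_summary(0.5, 0.02, s) for s in range(4)]
        adenoma = [_fake_summary(0.7, 0.02, 10 + s) for s in range(3)]
        comparison = compare_groups(healthy, adenoma, adjust=True)
        assert "p_adj" in comparison.adducts.columns
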