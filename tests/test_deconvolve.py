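"""Annotation, per-spectrum class-ratio estimation, and isobaric apportionment."""

import numpy as np
import pandas as pd
import pytest

from adductshift.deconvolve import (
    AnnotationTable,
    annotate,
    apportion_overlaps,
    assignment_mass_errors,
    estimate_class_ratios,
    species_totals,
)
from adductshift.preprocess import (
    IMSDataset,
    Spectrum,
    align_to_axis,
    filter_dataset,
    normalize_dataset,
)
from adductshift.registry import ADDUCTS, IonChannel, colon_panel
from adductshift.synthetic import simulate_dataset


def chan(panel, name, adduct):
    return IonChannel(panel.get(name), ADDUCTS[adduct])


def make_annot(panel, channels, intensities, labels=None):
    """Hand-build an AnnotationTable: channels = list of candidate lists."""
    X = np.atleast_2d(np.asarray(intensities, dtype=float))
    n = X.shape[0]
    mz = np.array(
        [np.mean([c.theoretical_mz for c, _ in cands]) for cands in channels]
    )
    return AnnotationTable(
        channel_mz=mz,
        channel_index=np.arange(len(channels)),
        candidates=channels,
        intensities=X,
        pixels=np.stack([np.arange(n), np.zeros(n, dtype=int)], axis=1),
        labels=np.array(labels or ["epithelium"] * n, dtype=object),
        tolerance_ppm=9.0,
        n_unassigned=0,
    )


class TestAnnotate:
    def test_engineered_channel_is_ambiguous(self, panel):
        ds = IMSDataset([Spectrum(0, 0, np.array([782.568, 500.0]), np.array([1.0, 0.5]))], 1, 1)
        aligned, axis = align_to_axis(ds, 6.0)
        annot = annotate(aligned, axis, panel, 9.0)
        assert annot.n_channels == 1
        names = {(c.species.display_name, c.adduct.label) for c, _ in annot.candidates[0]}
        assert names == {("PC 34:1", "Na"), ("PC 36:4", "H")}
        assert annot.ambiguous[0]
        # the decoy at m/z 500 matched nothing and was excluded
        assert annot.n_unassigned == 1

    def test_all_candidates_within_tolerance(self, healthy_subject):
        annot = healthy_subject.annotations
        for cands in annot.candidates:
            for _, err in cands:
                assert err <= 9.0
        assert np.array_equal(annot.ambiguous, np.array([len(c) >= 2 for c in annot.candidates]))

    def test_demo_panel_species_recovered(self, healthy_subject):
        names = healthy_subject.annotations.species_names()
        assert sum(n.startswith("PC") for n in names) == 8
        assert sum(n.startswith("SM") for n in names) == 1


class TestEstimateClassRatios:
    def test_ratio_definition(self, panel):
        annot = make_annot(
            panel,
            [
                [(chan(panel, "PC 32:0", "H"), 0.0)],
                [(chan(panel, "PC 32:0", "Na"), 0.0)],
                [(chan(panel, "PC 32:0", "K"), 0.0)],
            ],
            [[40.0, 30.0, 30.0]],
        )
        ratios = estimate_class_ratios(annot)
        np.testing.assert_allclose(ratios.ratios["PC"][0], [0.4, 0.3, 0.3])
        assert ratios.support["PC"] == 3
        assert not ratios.fallback_used["PC"][0]

    def test_zero_noise_ratio_matches_generating_partition(
        self, small_layout, noiseless_config, panel
    ):
        dataset, truth = simulate_dataset(small_layout, noiseless_config)
        dataset = normalize_dataset(dataset)
        aligned, axis = align_to_axis(dataset, 6.0)
        filtered = filter_dataset(aligned, 0.005)
        annot = annotate(filtered, axis, panel, 9.0)
        ratios = estimate_class_ratios(annot)
        for i, comp in enumerate(annot.labels):
            for cls in ("PC", "SM"):
                np.testing.assert_allclose(
                    ratios.ratios[cls][i],
                    truth.partitions[comp][cls].fractions,
                    atol=1e-9,
                )

    def test_empty_class_spectrum_uses_stratum_fallback(self, panel):
        annot = make_annot(
            panel,
            [
                [(chan(panel, "PC 32:0", "H"), 0.0)],
                [(chan(panel, "PC 32:0", "Na"), 0.0)],
                [(chan(panel, "PC 32:0", "K"), 0.0)],
            ],
            [[40.0, 30.0, 30.0], [0.0, 0.0, 0.0]],
        )
        ratios = estimate_class_ratios(annot)
        assert ratios.fallback_used["PC"][1]
        np.testing.assert_allclose(ratios.ratios["PC"][1], [0.4, 0.3, 0.3])


class TestApportionOverlaps:
    def overlap_annot(self, panel, obs=100.0):
        # complete species PC 32:0 pins r = (1/3, 1/3, 1/3); PC 34:1 anchored
        # at H=K=60 (T=180), PC 36:4 at Na=K=40 (T=120); the shared channel
        # then splits 60:40
        channels = [
            [(chan(panel, "PC 32:0", "H"), 0.0)],
            [(chan(panel, "PC 32:0", "Na"), 0.0)],
            [(chan(panel, "PC 32:0", "K"), 0.0)],
            [(chan(panel, "PC 34:1", "H"), 0.0)],
            [(chan(panel, "PC 34:1", "K"), 0.0)],
            [(chan(panel, "PC 36:4", "Na"), 0.0)],
            [(chan(panel, "PC 36:4", "K"), 0.0)],
            [(chan(panel, "PC 34:1", "Na"), 1.5), (chan(panel, "PC 36:4", "H"), 1.5)],
        ]
        X = [10.0, 10.0, 10.0, 60.0, 60.0, 40.0, 40.0, obs]
        return make_annot(panel, channels, X)

    def test_proportional_split(self, panel):
        annot = self.overlap_annot(panel)
        table = apportion_overlaps(annot, estimate_class_ratios(annot))
        f = table.frame.set_index(["species", "adduct"])["intensity"]
        assert f.loc[("PC 34:1", "Na")] == pytest.approx(60.0)
        assert f.loc[("PC 36:4", "H")] == pytest.approx(40.0)

    def test_single_candidate_passes_through(self, panel):
        annot = self.overlap_annot(panel)
        table = apportion_overlaps(annot, estimate_class_ratios(annot))
        f = table.frame.set_index(["species", "adduct"])
        assert f.loc[("PC 32:0", "H"), "intensity"] == pytest.approx(10.0)
        assert not f.loc[("PC 32:0", "H"), "ambiguous"]

    def test_intensity_conservation(self, panel):
        annot = self.overlap_annot(panel, obs=123.456)
        table = apportion_overlaps(annot, estimate_class_ratios(annot))
        assert table.frame["intensity"].sum() == pytest.approx(
            annot.intensities.sum(), rel=1e-9
        )

    def test_candidate_order_irrelevant(self, panel):
        a = self.overlap_annot(panel)
        b = self.overlap_annot(panel)
        b.candidates[-1] = list(reversed(b.candidates[-1]))
        ta = apportion_overlaps(a, estimate_class_ratios(a)).frame
        tb = apportion_overlaps(b, estimate_class_ratios(b)).frame
        key = ["species", "adduct"]
        pd.testing.assert_frame_equal(
            ta.sort_values(key).reset_index(drop=True),
            tb.sort_values(key).reset_index(drop=True),
        )

    def test_unanchored_candidates_split_equally_and_flagged(self, panel):
        channels = [
            [(chan(panel, "PC 34:1", "Na"), 1.5), (chan(panel, "PC 36:4", "H"), 1.5)],
        ]
        annot = make_annot(panel, channels, [80.0])
        table = apportion_overlaps(annot, estimate_class_ratios(annot))
        f = table.frame.set_index(["species", "adduct"])
        assert f.loc[("PC 34:1", "Na"), "intensity"] == pytest.approx(40.0)
        assert f.loc[("PC 36:4", "H"), "intensity"] == pytest.approx(40.0)
        assert f["low_confidence"].all()

    def test_zero_noise_oracle_equivalence(self, small_layout, noiseless_config, panel):
        # at zero noise the apportionment must reproduce the exact linear
        # mixing that generated the merged channels, pixel by pixel
        dataset_raw, truth = simulate_dataset(small_layout, noiseless_config)
        tics = np.array([sp.intensity.sum() for sp in dataset_raw.spectra])
        dataset = normalize_dataset(dataset_raw)
        aligned, axis = align_to_axis(dataset, 6.0)
        filtered = filter_dataset(aligned, 0.005)
        annot = annotate(filtered, axis, panel, 9.0)
        table = apportion_overlaps(annot, estimate_class_ratios(annot))

        wide = table.frame.pivot_table(
            index=["pixel_x", "pixel_y"], columns=["species", "adduct"],
            values="intensity", aggfunc="sum",
        )
        adduct_idx = {"H": 0, "Na": 1, "K": 2}
        for i in range(truth.pixels.shape[0]):
            x, y = truth.pixels[i]
            rec = wide.loc[(x, y)]
            for s, name in enumerate(truth.species_names):
                for adduct, a in adduct_idx.items():
                    expect = truth.intensities[i, s, a] / tics[i]  # TIC-normalized truth
                    got = rec[(name, adduct)]
                    assert got == pytest.approx(expect, rel=1e-6), (x, y, name, adduct)


class TestSpeciesTotals:
    def test_totals_sum_adducts(self, panel):
        annot = TestApportionOverlaps().overlap_annot(panel)
        table = apportion_overlaps(annot, estimate_class_ratios(annot))
        totals = species_totals(table).set_index("species")["total"]
        assert totals.loc["PC 32:0"] == pytest.approx(30.0)
        assert totals.loc["PC 34:1"] == pytest.approx(180.0)  # 60 + 60 + 60
        assert totals.loc["PC 36:4"] == pytest.approx(120.0)
        # conservation across the whole table
        assert totals.sum() == pytest.approx(annot.intensities.sum(), rel=1e-9)

    def test_total_bounds_single_adduct(self, panel):
        annot = make_annot(panel, [[(chan(panel, "SM d34:1", "H"), 0.0)]], [[7.0]])
        table = apportion_overlaps(annot, estimate_class_ratios(annot))
        totals = species_totals(table)
        assert totals["total"].iloc[0] == pytest.approx(7.0)


class TestAssignmentMassErrors:
    def test_errors_within_tolerance_and_mostly_tight(self, healthy_subject):
        err = healthy_subject.mass_errors["ppm_error"]
        assert len(err) > 1000
        assert err.max() <= 9.0
        # 1.5 ppm jitter: the vast majority of accepted peaks sit within 3 ppm
        assert (err <= 3.0).mean() >= 0.9
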