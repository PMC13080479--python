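"""Segmentation, state classification, strip maps, and spatial binning."""

import numpy as np
import pytest

from sporesense import (
    ImageFrame,
    ImageLayout,
    OpticsSpec,
    SegmentationConfig,
    SporeRecord,
    ValidationError,
    classify_spore_states,
    fraction_vs_distance,
    gen_spore_image_pair,
    render_strip_map,
    segment_spores,
)

SYN_CFG = SegmentationConfig(min_area=5, max_area=300)


def _match(records, truth, tol=2.0):
    """Greedy nearest matching of detections to ground-truth centres."""
    cents = np.array([r.centroid for r in records])
    tp, errs = 0, []
    for _, row in truth.iterrows():
        if cents.size == 0:
            break
        d = np.hypot(cents[:, 0] - row.row, cents[:, 1] - row.col)
        if d.min() <= tol:
            tp += 1
            errs.append(d.min())
    return tp, len(records) - tp, errs


class TestSegmentation:
    def test_blank_image_yields_no_records(self):
        with pytest.warns(UserWarning):
            records = segment_spores(ImageFrame(np.zeros((64, 64))))
        assert records == []

    @pytest.mark.parametrize("snr", [5.0, 10.0])
    def test_detection_on_synthetic_field(self, snr):
        """>= 95% detection, <= 2% false positives, centroids within 1 px."""
        layout = ImageLayout(n_spores=200)
        optics = OpticsSpec(amplitude=snr * 5.0, noise_sd=5.0)
        f0, _, truth = gen_spore_image_pair(layout, lambda x: np.zeros_like(x),
                                            optics, seed=21)
        records = segment_spores(f0, SYN_CFG)
        tp, fp, errs = _match(records, truth)
        assert tp / layout.n_spores >= 0.95
        assert fp / max(len(records), 1) <= 0.02
        assert max(errs) <= 1.0

    def test_small_speck_filtered_by_area(self):
        layout = ImageLayout(n_spores=20, shape=(128, 256))
        optics = OpticsSpec(amplitude=50.0, noise_sd=5.0)
        f0, _, truth = gen_spore_image_pair(layout, lambda x: np.zeros_like(x),
                                            optics, seed=4)
        base = segment_spores(f0, SYN_CFG)
        spiked = f0.pixels.copy()
        spiked[5:7, 5] += 60.0  # 2-px speck, below min_area
        with_speck = segment_spores(ImageFrame(spiked, f0.pixel_size), SYN_CFG)
        assert len(with_speck) == len(base) == len(truth)

    def test_records_in_raster_order(self):
        layout = ImageLayout(n_spores=50, shape=(128, 512))
        f0, _, _ = gen_spore_image_pair(layout, lambda x: np.zeros_like(x), seed=2)
        records = segment_spores(f0, SYN_CFG)
        rows = [r.centroid[0] for r in records]
        assert rows == sorted(rows)


class TestClassification:
    @pytest.fixture()
    def pair(self):
        layout = ImageLayout(n_spores=150)
        f0, fF, truth = gen_spore_image_pair(
            layout, lambda x: np.full_like(x, 0.5), seed=8
        )
        return f0, fF, truth

    def test_identical_frames_all_dormant(self, pair):
        f0, _, _ = pair
        records = classify_spore_states(f0, f0, segment_spores(f0, SYN_CFG), SYN_CFG)
        assert all(r.state == "dormant" for r in records)

    def test_recovers_true_states(self, pair):
        f0, fF, truth = pair
        records = classify_spore_states(f0, fF, segment_spores(f0, SYN_CFG), SYN_CFG)
        true_by_pos = {
            (round(t.row), round(t.col)): t.germinated for t in truth.itertuples()
        }
        agree = total = 0
        for rec in records:
            key = min(
                true_by_pos,
                key=lambda k: (k[0] - rec.centroid[0]) ** 2 + (k[1] - rec.centroid[1]) ** 2,
            )
            total += 1
            agree += (rec.state == "germinated") == true_by_pos[key]
        assert agree / total >= 0.98

    def test_boundary_drop_is_dormant(self):
        """A drop of exactly drop_fraction stays dormant (strictly-below rule)."""
        img0 = np.zeros((64, 64))
        img0[30:34, 30:34] = 100.0
        imgF = img0 * 0.5
        mask = img0 > 0
        rec = SporeRecord(0, mask, (31.5, 31.5), 16, 100.0)
        out = classify_spore_states(
            ImageFrame(img0), ImageFrame(imgF), [rec], SegmentationConfig()
        )
        assert out[0].state == "dormant"

    def test_mismatched_shapes_rejected(self):
        with pytest.raises(ValidationError):
            classify_spore_states(
                ImageFrame(np.zeros((4, 4))), ImageFrame(np.zeros((5, 5))), []
            )


class TestStripMap:
    def _two_spores(self, states, cols=(40, 60)):
        records = []
        for i, (state, col) in enumerate(zip(states, cols)):
            mask = np.zeros((128, 128), dtype=bool)
            mask[62:66, col : col + 4] = True
            records.append(
                SporeRecord(i, mask, (63.5, col + 1.5), 16, 1.0, 1.0, state)
            )
        return records

    def test_single_dormant_disk(self):
        recs = self._two_spores(["dormant"], cols=(60,))
        smap = render_strip_map(recs, (128, 128), dilation_radius=10, seed=0)
        assert np.all(np.isin(smap.labels, [0, 1]))
        assert (smap.labels == 1).sum() > recs[0].mask.sum()

    def test_same_state_overlap_never_randomised(self):
        recs = self._two_spores(["germinated", "germinated"])
        a = render_strip_map(recs, (128, 128), 20, seed=1)
        b = render_strip_map(recs, (128, 128), 20, seed=2)
        assert np.array_equal(a.labels, b.labels)
        assert set(np.unique(a.labels)) == {0, 2}

    def test_conflicting_overlap_is_seed_deterministic(self):
        recs = self._two_spores(["dormant", "germinated"])
        a = render_strip_map(recs, (128, 128), 20, seed=7)
        b = render_strip_map(recs, (128, 128), 20, seed=7)
        c = render_strip_map(recs, (128, 128), 20, seed=8)
        assert np.array_equal(a.labels, b.labels)
        assert not np.array_equal(a.labels, c.labels)  # both states in the overlap
        assert {1, 2} <= set(np.unique(a.labels))

    def test_unassigned_state_rejected(self):
        recs = self._two_spores(["unassigned"], cols=(60,))
        with pytest.raises(ValidationError):
            render_strip_map(recs, (128, 128), 20, seed=0)


class TestFractionVsDistance:
    def _records_at(self, cols_states, pixel_size=10.0):
        records = []
        for i, (col, state) in enumerate(cols_states):
            mask = np.zeros((8, 1200), dtype=bool)
            mask[4, col] = True
            records.append(SporeRecord(i, mask, (4.0, float(col)), 1, 1.0, 1.0, state))
        return records

    def test_all_germinated_gives_unit_fractions(self):
        recs = self._records_at([(50, "germinated"), (250, "germinated")])
        prof = fraction_vs_distance(recs, pixel_size=10.0)
        assert np.nansum(prof.fraction_germinated == 1.0) == np.sum(prof.n_spores > 0)

    def test_step_profile_recovered(self):
        """States set by 'germinated iff distance < 3 mm' bin to a step at 3 mm."""
        cols_states = [
            (c, "germinated" if c * 10.0 / 1000.0 < 3.0 else "dormant")
            for c in range(25, 1200, 50)
        ]
        prof = fraction_vs_distance(self._records_at(cols_states), pixel_size=10.0)
        expected = (prof.bin_centers < 3.0).astype(float)
        occupied = prof.n_spores > 0
        np.testing.assert_allclose(prof.fraction_germinated[occupied], expected[occupied])

    def test_empty_bins_flagged_not_invented(self):
        recs = self._records_at([(25, "dormant"), (1125, "germinated")])
        prof = fraction_vs_distance(recs, pixel_size=10.0)
        assert prof.n_spores[5] == 0 and np.isnan(prof.fraction_germinated[5])
        assert prof.n_spores.sum() == 2

    def test_unclassified_records_rejected(self):
        recs = self._records_at([(25, "unassigned")])
        with pytest.raises(ValidationError):
            fraction_vs_distance(recs, pixel_size=10.0)
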