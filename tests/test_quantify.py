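"""Segmentation, focus detection and foci-factor behaviour."""

import numpy as np
import pytest

from mrtbio import (
    FociFactor,
    FocusRecord,
    ImagingConfig,
    SegmentationResult,
    detect_foci,
    dsber,
    foci_factor,
    generate_uniform,
    segment_nuclei,
)
from conftest import match_detections

PX = 0.65


def disk_image(centres_px, radius_px, shape=(200, 200), amplitude=3000.0, base=150.0):
    img = np.full(shape, base)
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    for cy, cx in centres_px:
        img[np.hypot(yy - cy, xx - cx) <= radius_px] += amplitude
    return img


def synthetic_segmentation(n_nuclei=2, radius_px=20, spacing_px=60, pixel_size=PX):
    """Labelled disks, equal areas, evenly spaced along x."""
    shape = (120, spacing_px * n_nuclei + 60)
    labels = np.zeros(shape, dtype=np.int32)
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    records = []
    from mrtbio.quantify import NucleusRecord

    for i in range(n_nuclei):
        cy, cx = 60, 40 + i * spacing_px
        mask = np.hypot(yy - cy, xx - cx) <= radius_px
        labels[mask] = i + 1
        records.append(
            NucleusRecord(
                label=i + 1,
                x_um=(cx + 0.5) * pixel_size,
                y_um=(cy + 0.5) * pixel_size,
                area_um2=float(mask.sum()) * pixel_size**2,
            )
        )
    return SegmentationResult(records, labels, pixel_size)


class TestSegmentNuclei:
    def test_recovers_well_separated_nuclei(self, small_config):
        cfg = ImagingConfig(**{**small_config.__dict__, "n_nuclei": 100, "seed": 70})
        bundle = generate_uniform(0.5, cfg)
        seg = segment_nuclei(bundle.nuclear_channel, cfg.pixel_size)
        assert abs(len(seg) - 100) <= 2
        det = np.array([[r.x_um, r.y_um] for r in seg.records])
        true = bundle.truth.nuclei[["x_um", "y_um"]].to_numpy()
        hits, n_true, _ = match_detections(det, true, radius_um=5.0)
        assert hits >= 0.98 * n_true

    def test_all_zero_image_yields_no_nuclei(self):
        seg = segment_nuclei(np.zeros((100, 100), dtype=np.uint16), PX)
        assert len(seg) == 0

    def test_touching_nuclei_split_by_watershed(self):
        # two disks overlapping by construction
        img = disk_image([(100, 80), (100, 117)], radius_px=22)
        seg = segment_nuclei(img, PX)
        assert len(seg) == 2

    def test_saturated_image_flagged(self):
        img = disk_image([(100, 100)], radius_px=30, amplitude=70000.0)
        img = np.clip(img, 0, 65535)
        with pytest.warns(UserWarning, match="saturated"):
            seg = segment_nuclei(img, PX)
        assert seg.saturated


class TestDetectFoci:
    def test_low_density_recall_and_precision(self):
        # reference-sized nuclei, ~2 foci/nucleus (well under 5)
        cfg = ImagingConfig(image_width=600, image_height=400, n_nuclei=40)
        hits = trues = dets = 0
        for seed in (80, 81, 82):
            b = generate_uniform(0.5, cfg.with_seed(seed))
            seg = segment_nuclei(b.nuclear_channel, PX)
            foci = detect_foci(b.foci_channel, seg, PX)
            h, t, d = match_detections(
                np.array([[f.x_um, f.y_um] for f in foci]),
                b.truth.foci[["x_um", "y_um"]].to_numpy(),
                radius_um=1.0,
            )
            hits, trues, dets = hits + h, trues + t, dets + d
        assert hits / trues >= 0.9
        assert hits / dets >= 0.9

    def test_noise_only_false_positive_rate(self, small_config):
        cfg = ImagingConfig(
            **{**small_config.__dict__, "background_foci_rate": 0.0, "seed": 83}
        )
        b = generate_uniform(0.0, cfg)
        seg = segment_nuclei(b.nuclear_channel, PX)
        foci = detect_foci(b.foci_channel, seg, PX)
        assert len(foci) / len(seg) <= 0.5

    def test_foci_outside_nuclei_excluded(self):
        seg = synthetic_segmentation(n_nuclei=1)
        img = np.full(seg.labels.shape, 150.0)
        yy, xx = np.mgrid[: img.shape[0], : img.shape[1]]
        inside = (60, 40)
        outside = (60, 100)  # beyond the single nucleus
        for cy, cx in (inside, outside):
            img += 6000.0 * np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * 1.0**2))
        foci = detect_foci(img, seg, PX)
        assert len(foci) == 1
        assert foci[0].parent_nucleus == 1
        assert abs(foci[0].x_um - (40 + 0.5) * PX) < 1.0


def make_focus(x_um, y_um, area_um2, parent=1, intensity=1000.0):
    return FocusRecord(
        x_um=x_um, y_um=y_um, area_um2=area_um2,
        integrated_intensity=intensity, parent_nucleus=parent,
    )


class TestFociFactor:
    def test_identical_isolated_foci_over_two_nuclei(self):
        seg = synthetic_segmentation(n_nuclei=2)
        foci = [make_focus(10.0 + i, 39.0, area_um2=1.5) for i in range(10)]
        ff = foci_factor(foci, seg, ref_area_um2=1.5)
        assert ff.ff == pytest.approx(5.0)

    def test_merged_blob_counts_by_area_multiplicity(self):
        seg = synthetic_segmentation(n_nuclei=1)
        foci = [make_focus(26.0, 39.0, area_um2=4.5)]
        ff = foci_factor(foci, seg, ref_area_um2=1.5)
        assert ff.ff == pytest.approx(3.0)

    @pytest.mark.parametrize("strategy", ["area", "intensity"])
    def test_whole_image_ff_close_to_true_mean(self, small_config, strategy, uniform_bundle):
        b = uniform_bundle
        seg = segment_nuclei(b.nuclear_channel, PX)
        foci = detect_foci(b.foci_channel, seg, PX)
        kw = {"foci_channel": b.foci_channel} if strategy == "intensity" else {}
        ff = foci_factor(foci, seg, strategy=strategy, **kw)
        true_mean = b.truth.nuclei.n_foci.mean()
        assert ff.ff == pytest.approx(true_mean, rel=0.15)

    @pytest.mark.parametrize("strategy", ["area", "intensity"])
    def test_invariant_under_intensity_scaling(self, uniform_bundle, strategy):
        b = uniform_bundle
        seg = segment_nuclei(b.nuclear_channel, PX)
        scaled = (b.foci_channel.astype(np.float64)) * 3.0
        kw1 = {"foci_channel": b.foci_channel} if strategy == "intensity" else {}
        kw2 = {"foci_channel": scaled} if strategy == "intensity" else {}
        ff1 = foci_factor(detect_foci(b.foci_channel, seg, PX), seg, strategy=strategy, **kw1)
        ff2 = foci_factor(detect_foci(scaled, seg, PX), seg, strategy=strategy, **kw2)
        assert ff2.ff == pytest.approx(ff1.ff, rel=1e-6)

    def test_area_additive_over_disjoint_regions(self, mrt_bundle):
        b = mrt_bundle
        seg = segment_nuclei(b.nuclear_channel, PX)
        foci = detect_foci(b.foci_channel, seg, PX)
        width = b.config.width_um
        cut = width / 3.0
        regions = [[(0.0, cut)], [(cut, width)]]
        whole = foci_factor(foci, seg)
        total_area = seg.nuclear_area_in(None)
        weighted = 0.0
        for iv in regions:
            ff = foci_factor(foci, seg, iv)
            weighted += ff.ff * seg.nuclear_area_in(iv)
        assert weighted / total_area == pytest.approx(whole.ff, rel=1e-9)

    def test_empty_region_is_undefined(self, uniform_bundle):
        seg = segment_nuclei(uniform_bundle.nuclear_channel, PX)
        with pytest.raises(ValueError, match="no nuclear area"):
            foci_factor([], seg, [(1e5, 1e5 + 1.0)])


class TestDsber:
    def test_identity_for_equal_factors(self):
        ff = FociFactor(region="whole-image", ff=2.5, n_nuclei=10)
        assert dsber(ff, ff) == pytest.approx(1.0)

    def test_zero_control_raises(self):
        ff = FociFactor(region="whole-image", ff=2.5, n_nuclei=10)
        zero = FociFactor(region="whole-image", ff=0.0, n_nuclei=10)
        with pytest.raises(ValueError):
            dsber(ff, zero)

    def test_uniform_dose_ratio_matches_generative_model(self, small_config):
        # DSBER -> (b + k d)/b for background rate b and yield k
        cfg = ImagingConfig(
            **{**small_config.__dict__, "background_foci_rate": 1.0,
               "n_nuclei": 200, "nucleus_radius_mean": 4.5}
        )
        ffs = {}
        for dose in (0.0, 2.0):
            vals = []
            for s in range(3):
                b = generate_uniform(dose, cfg.with_seed(90 + s + int(dose) * 10))
                seg = segment_nuclei(b.nuclear_channel, PX)
                foci = detect_foci(b.foci_channel, seg, PX)
                vals.append(
                    foci_factor(
                        foci, seg, strategy="intensity", foci_channel=b.foci_channel
                    ).ff
                )
            ffs[dose] = np.mean(vals)
        expected = (1.0 + 4.0 * 2.0) / 1.0
        assert ffs[2.0] / ffs[0.0] == pytest.approx(expected, rel=0.2)
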