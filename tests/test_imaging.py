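import numpy as np
import pytest
from skimage import measure

import myoscreen as ms
from myoscreen.imaging import CellMask


def strip_mask(shape, r0, r1, c0, c1):
    """Manually constructed rectangular CellMask (no thresholding involved)."""
    m = np.zeros(shape, dtype=bool)
    m[r0:r1, c0:c1] = True
    return CellMask.from_labeled(measure.label(m), 1)


def sinusoid_strip(period_um, cal=0.2, ncols=700, nrows=200, amps=None):
    """Horizontal strip whose axial intensity is a (sum of) cosine(s)."""
    x = np.arange(ncols) * cal
    if amps is None:
        amps = {period_um: 1.0}
    prof = sum(a * np.cos(2 * np.pi * x / p) for p, a in amps.items())
    img = np.full((nrows, ncols), 100.0)
    img[50:150, :] = 1000.0 + 400.0 * prof[None, :]
    return ms.FieldImage(pixels=img, calibration_um_per_px=cal)


class TestSarcomereFFT:
    def test_pure_sinusoid_exact(self):
        img = sinusoid_strip(2.0)
        mask = strip_mask(img.pixels.shape, 50, 150, 0, 700)
        assert ms.sarcomere_length_fft(img, mask) == pytest.approx(2.0, abs=0.005)

    def test_rat_cell_period(self, rat_cell_image, rat_cell_mask):
        """Rendered rat rod at 0.2 um/px: detected period within 0.01 um."""
        sl = ms.sarcomere_length_fft(rat_cell_image, rat_cell_mask)
        assert sl == pytest.approx(1.826, abs=0.01)

    def test_dominant_component_wins(self):
        img = sinusoid_strip(1.9, amps={1.9: 1.0, 2.2: 0.5})
        mask = strip_mask(img.pixels.shape, 50, 150, 0, 700)
        assert ms.sarcomere_length_fft(img, mask) == pytest.approx(1.9, abs=0.01)

    def test_no_striation_raises(self):
        img = ms.FieldImage(pixels=np.full((200, 700), 500.0),
                            calibration_um_per_px=0.2)
        mask = strip_mask(img.pixels.shape, 50, 150, 0, 700)
        with pytest.raises(ms.NoStriationError):
            ms.sarcomere_length_fft(img, mask)

    def test_unbiased_over_noisy_replicates(self):
        """Mean detection error < 0.005 um over 50 noisy renders."""
        errs = []
        for seed in range(50):
            spec = ms.FieldImageSpec(
                image_size_px=(1024, 1024), calibration_um_per_px=0.2,
                cells=[ms.CellSpec(center_um=(102.4, 102.4), orientation_rad=0.3)],
                noise_sd=40.0, seed=seed,
            )
            img = ms.gen_field_image(spec)
            masks = ms.find_cells(img)
            errs.append(ms.sarcomere_length_fft(img, masks[0]) - 1.826)
        assert abs(np.mean(errs)) < 0.005


class TestCellLengthEdges:
    def test_rendered_rod_length(self, rat_cell_image, rat_cell_mask):
        L = ms.cell_length_edges(rat_cell_image, rat_cell_mask)
        assert L == pytest.approx(133.3, abs=1.0)

    def test_rotation_invariance(self):
        lengths = {}
        for theta in (0.0, np.pi / 4):
            spec = ms.FieldImageSpec(
                image_size_px=(1024, 1024), calibration_um_per_px=0.2,
                cells=[ms.CellSpec(center_um=(102.4, 102.4), orientation_rad=theta)],
                seed=0,
            )
            img = ms.gen_field_image(spec)
            mask = ms.find_cells(img)[0]
            lengths[theta] = ms.cell_length_edges(img, mask)
        assert abs(lengths[0.0] - lengths[np.pi / 4]) <= 0.2  # 1 px at 0.2 um/px

    def test_uniform_background_raises(self):
        img = ms.FieldImage(pixels=np.full((256, 256), 100.0),
                            calibration_um_per_px=0.5)
        mask = strip_mask(img.pixels.shape, 100, 150, 30, 220)
        with pytest.raises(ms.NoCellEdgeError):
            ms.cell_length_edges(img, mask)


def _rod(center, area_target, aspect=0.3, period=1.826, contrast=0.5):
    """CellSpec with rectangle dimensions hitting a target mask area (um^2)."""
    # area = L*W - (4-pi)*(W/4)^2 with W = aspect*L
    L = np.sqrt(area_target / (aspect - (4 - np.pi) * aspect**2 / 16))
    return ms.CellSpec(center_um=center, length_um=L, width_um=aspect * L,
                       striation_period_um=period, striation_contrast=contrast)


class TestFindCells:
    def test_empty_field(self):
        img = ms.gen_field_image(ms.FieldImageSpec(image_size_px=(256, 256),
                                                   cells=[], noise_sd=1.0))
        assert ms.find_cells(img) == []

    def test_area_bounds_accept_exactly_table_rules(self):
        """Objects at 800/1200/3500/6200 um^2: only 1200 and 3500 pass."""
        spec = ms.FieldImageSpec(
            image_size_px=(1200, 1200), calibration_um_per_px=0.5,
            cells=[
                _rod((120, 120), 800), _rod((120, 420), 1200),
                _rod((400, 220), 3500), _rod((480, 480), 6200),
            ],
            seed=0,
        )
        img = ms.gen_field_image(spec)
        masks = ms.find_cells(img)
        areas = sorted(m.area_px * 0.25 for m in masks)
        assert len(areas) == 2
        assert areas[0] == pytest.approx(1200, rel=0.05)
        assert areas[1] == pytest.approx(3500, rel=0.05)

    def test_overlap_rule_rejects_both(self):
        """Two valid cells closer than 40 um clearance are both discarded."""
        rod = _rod((150, 150), 3500)
        width = rod.width_um
        near = _rod((150 + width + 30.0, 150), 3500)  # 30 um edge gap
        spec = ms.FieldImageSpec(
            image_size_px=(1200, 1200), calibration_um_per_px=0.5,
            cells=[rod, near], seed=0,
        )
        assert ms.find_cells(ms.gen_field_image(spec)) == []

    def test_aspect_ratio_window(self):
        # square-ish blob: aspect ~1 -> rejected despite valid area
        blob = ms.CellSpec(center_um=(150, 150), length_um=60, width_um=55,
                           striation_period_um=1.826, striation_contrast=0.0)
        spec = ms.FieldImageSpec(image_size_px=(600, 600),
                                 calibration_um_per_px=0.5, cells=[blob], seed=0)
        assert ms.find_cells(ms.gen_field_image(spec)) == []

    def test_intensity_rescaling_invariance(self, rat_cell_image):
        """Accepted masks are unchanged under affine gray transforms."""
        masks0 = ms.find_cells(rat_cell_image)
        rescaled = ms.FieldImage(pixels=rat_cell_image.pixels * 2.7 + 300.0,
                                 calibration_um_per_px=0.2)
        masks1 = ms.find_cells(rescaled)
        assert len(masks0) == len(masks1) == 1
        assert np.array_equal(masks0[0].mask, masks1[0].mask)

    def test_accepted_cells_satisfy_all_bounds(self):
        """Post-hoc: every accepted mask passes every criterion."""
        crit = ms.FinderCriteria()
        spec = ms.FieldImageSpec(
            image_size_px=(1200, 1200), calibration_um_per_px=0.5,
            cells=[_rod((150, 150), 2000), _rod((150, 450), 4500),
                   _rod((450, 300), 900)],
            seed=0,
        )
        img = ms.gen_field_image(spec)
        for m in ms.find_cells(img, crit):
            props = measure.regionprops(m.mask.astype(np.uint8))[0]
            area = props.area * 0.25
            aspect = props.axis_minor_length / props.axis_major_length
            assert crit.min_area_um2 <= area <= crit.max_area_um2
            assert crit.min_aspect <= aspect <= crit.max_aspect


class TestMorphology:
    def test_square_mask(self):
        img = ms.FieldImage(pixels=np.zeros((128, 128)), calibration_um_per_px=1.0)
        img.pixels[10:110, 10:110] = 1000.0
        mask = strip_mask((128, 128), 10, 110, 10, 110)
        p = ms.measure_morphology(img, mask)
        assert p.area_um2 == pytest.approx(10_000)
        assert p.solidity == pytest.approx(1.0, abs=0.01)
        assert p.eccentricity == pytest.approx(0.0, abs=0.05)

    def test_ellipse_eccentricity_analytic(self):
        """Discretised ellipse a=60, b=15 px: ecc ~ sqrt(1-(b/a)^2) = 0.968."""
        rr, cc = np.mgrid[0:200, 0:200]
        emask = ((cc - 100) / 60.0) ** 2 + ((rr - 100) / 15.0) ** 2 <= 1.0
        mask = CellMask.from_labeled(measure.label(emask), 1)
        img = ms.FieldImage(pixels=emask * 1000.0, calibration_um_per_px=1.0)
        p = ms.measure_morphology(img, mask)
        assert p.eccentricity == pytest.approx(np.sqrt(1 - (15 / 60) ** 2), abs=0.01)
        assert p.length_um == pytest.approx(120, rel=0.02)
        assert p.width_um == pytest.approx(30, rel=0.02)

    def test_rendered_rod_morphology(self, rat_cell_image, rat_cell_mask):
        p = ms.measure_morphology(rat_cell_image, rat_cell_mask)
        assert p.solidity > 0.85
        assert p.sarcomere_um == pytest.approx(1.826, abs=0.01)
        assert p.area_um2 == pytest.approx(133.3 * 37.39 - (4 - np.pi) * (37.39 / 4) ** 2,
                                           rel=0.02)

    def test_rotation_invariance_of_measures(self):
        results = []
        for theta in (0.0, 1.0, 2.0):
            spec = ms.FieldImageSpec(
                image_size_px=(1024, 1024), calibration_um_per_px=0.2,
                cells=[ms.CellSpec(center_um=(102.4, 102.4), orientation_rad=theta)],
                seed=0,
            )
            img = ms.gen_field_image(spec)
            results.append(ms.measure_morphology(img, ms.find_cells(img)[0]))
        for attr in ("area_um2", "length_um", "width_um"):
            vals = [getattr(r, attr) for r in results]
            assert np.ptp(vals) / np.mean(vals) < 0.02

    def test_degenerate_mask_raises(self):
        img = ms.FieldImage(pixels=np.zeros((32, 32)), calibration_um_per_px=1.0)
        tiny = np.zeros((32, 32), dtype=bool)
        tiny[5, 5] = True
        mask = CellMask(mask=tiny, centroid_px=(5, 5), bbox=(5, 5, 6, 6),
                        orientation_rad=0.0, area_px=1)
        with pytest.raises(ValueError, match="degenerate"):
            ms.measure_morphology(img, mask)


class TestSpectralProfile:
    def test_dominant_peak_at_striation_period(self):
        spec = ms.FieldImageSpec(
            image_size_px=(1024, 1024), calibration_um_per_px=0.2,
            cells=[ms.CellSpec(center_um=(102.4, 102.4), orientation_rad=0.3,
                               striation_period_um=1.8)],
            seed=0,
        )
        img = ms.gen_field_image(spec)
        mask = ms.find_cells(img)[0]
        _, _, peak, prom = ms.spectral_profile(img, mask)
        assert peak == pytest.approx(1.8, abs=0.05)
        assert prom >= 3.0

    def test_uniform_interior_no_peak(self):
        spec = ms.FieldImageSpec(
            image_size_px=(1024, 1024), calibration_um_per_px=0.2,
            cells=[ms.CellSpec(center_um=(102.4, 102.4), striation_contrast=0.0)],
            seed=0,
        )
        img = ms.gen_field_image(spec)
        mask = ms.find_cells(img)[0]
        _, _, peak, _ = ms.spectral_profile(img, mask)
        assert np.isnan(peak)

    def test_agrees_with_axial_fft(self, rat_cell_image, rat_cell_mask):
        """Cross-method consistency within 0.05 um on the same cell."""
        sl = ms.sarcomere_length_fft(rat_cell_image, rat_cell_mask)
        _, _, peak, _ = ms.spectral_profile(rat_cell_image, rat_cell_mask)
        assert peak == pytest.approx(sl, abs=0.05)
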