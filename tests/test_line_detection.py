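import numpy as np
import pytest

from lfiaquant import (
    ControlLineLostError,
    ControlLineNotFoundError,
    GrayImage,
    LineLists,
    LineRegion,
    StripGeometry,
    StripSpec,
    ThresholdParams,
    adaptive_binarize,
    add_noise,
    column_profile,
    control_threshold,
    finalize_lists,
    generate_strip,
    locate_control_line,
    median_denoise,
    refine_lists,
    symmetry_response,
    transition_lists,
)
from lfiaquant.pipeline import analyze_image
from lfiaquant.synthetic import default_geometry

from conftest import painted_strip


class TestControlThreshold:
    def test_direct_substitution(self, params):
        img = GrayImage(np.zeros((10, 40), dtype=np.uint8))
        prof = column_profile(img)
        assert control_threshold(prof, params, 10) == 300.0

    def test_default_offset_is_thirty(self, params):
        assert params.offset == 30.0

    def test_separates_control_from_background(self, params):
        img, truth = generate_strip(StripSpec(seed=4))
        prof = column_profile(img)
        thr = control_threshold(prof, params, img.height)
        control = truth["lines"][0]
        assert prof.sums[control["center"]] <= thr
        # background columns far from every line sit above the threshold
        bg_cols = [10, 150, 270]
        assert all(prof.sums[j] > thr for j in bg_cols)


class TestLocateControlLine:
    def test_painted_control_recovered_exactly(self, params):
        img = painted_strip(bands=[(50, 64, 100)])
        region = locate_control_line(img, params)
        assert abs(region.head - 50) <= 2 and abs(region.end - 64) <= 2

    def test_constant_image_has_no_control(self, params):
        img = GrayImage(np.full((50, 200), 180, dtype=np.uint8))
        with pytest.raises(ControlLineNotFoundError):
            locate_control_line(img, params)

    def test_minimum_width_gate(self, params):
        # run of 5 columns is rejected (width must exceed 5), 6 is accepted
        with pytest.raises(ControlLineNotFoundError):
            locate_control_line(painted_strip(bands=[(50, 54, 100)]), params)
        region = locate_control_line(painted_strip(bands=[(50, 55, 100)]), params)
        assert (region.head, region.end) == (50, 55)

    def test_darkest_run_wins(self, params):
        img = painted_strip(bands=[(40, 52, 105), (100, 112, 130)])
        region = locate_control_line(img, params)
        assert (region.head, region.end) == (100, 112)


class TestMedianDenoise:
    def test_constant_image_unchanged(self, params):
        img = GrayImage(np.full((12, 30), 77, dtype=np.uint8))
        assert (median_denoise(img, params).pixels == 77).all()

    def test_single_impulse_removed(self):
        px = np.zeros((5, 5), dtype=np.uint8)
        px[2, 2] = 255
        out = median_denoise(GrayImage(px), ThresholdParams(median_kernel=3))
        assert (out.pixels == 0).all()

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(21)
        px = rng.integers(0, 256, size=(9, 7), dtype=np.uint8)
        out = median_denoise(GrayImage(px), ThresholdParams(median_kernel=3))
        padded = np.pad(px, 1, mode="edge")
        for i in range(9):
            for j in range(7):
                window = padded[i : i + 3, j : j + 3]
                assert out.pixels[i, j] == int(np.median(window))

    def test_salt_pepper_residual_fraction(self, params):
        clean, _ = generate_strip(StripSpec(seed=6))
        noisy = add_noise(clean, "salt_pepper", 0.05, seed=17)
        restored = median_denoise(noisy, params)
        diff = np.abs(restored.pixels.astype(int) - clean.pixels.astype(int))
        assert (diff > 10).mean() < 0.005


class TestAdaptiveBinarize:
    def test_clean_two_line_strip_first_iteration(self, params):
        img = painted_strip(bands=[(60, 75, 120), (200, 215, 80)])
        mask = adaptive_binarize(img, params)
        fg_cols = np.flatnonzero(mask.any(axis=0))
        expected = np.r_[60:76, 200:216]
        assert set(fg_cols) == set(expected)

    def test_constant_image_yields_empty_mask(self, params):
        img = GrayImage(np.full((30, 90), 150, dtype=np.uint8))
        assert not adaptive_binarize(img, params).any()

    def test_speckle_triggers_morphological_opening(self, params):
        px = np.full((20, 300), 200, dtype=np.int64)
        px[:, 50:66] -= 150  # genuine wide line
        # heavy isolated speckle: dark pixels in isolated columns, so the
        # mask SNR stays low at every binarization factor
        for col in range(80, 300, 4):
            px[(2, 7, 12, 17), col] = 0
        mask = adaptive_binarize(GrayImage(np.clip(px, 0, 255)), params)
        assert mask[:, 50:66].all(axis=0).any()  # line retained
        assert mask[:, 80:].sum() < 20  # speckle removed by the opening


class TestSymmetryResponse:
    @pytest.mark.parametrize("shape", [(4, 4), (16, 16), (5, 8), (8, 5)])
    def test_matches_triple_loop_oracle(self, shape):
        rng = np.random.default_rng(sum(shape))
        px = rng.integers(0, 256, size=shape, dtype=np.uint8)
        resp = symmetry_response(GrayImage(px))
        inv = 255 - px.astype(np.int64)
        h, w = shape
        d = np.zeros((h, w), dtype=np.int64)
        for x in range(h):
            for y in range(w):
                left = inv[x, y] if y < w // 2 else 0
                d[x, y] = left * inv[x, w - 1 - y]
        sums = [sum(int(inv[i, j]) for i in range(h)) for j in range(w)]
        n = min(h, w)
        for k in range(w):
            expected = sum(d[x, k] * sums[x] for x in range(n))
            assert resp.c_vec[k] == expected
        assert (resp.d == d).all()

    def test_zero_inverted_image_gives_zero_response(self):
        img = GrayImage(np.full((6, 12), 255, dtype=np.uint8))
        resp = symmetry_response(img)
        assert not resp.d.any() and not resp.c_vec.any()

    def test_mirror_symmetric_image_squares_left_half(self):
        rng = np.random.default_rng(2)
        half = rng.integers(0, 256, size=(6, 5), dtype=np.uint8)
        px = np.hstack([half, half[:, ::-1]])
        resp = symmetry_response(GrayImage(px))
        inv = 255 - px.astype(np.int64)
        assert (resp.d[:, :5] == inv[:, :5] ** 2).all()
        assert not resp.d[:, 5:].any()


class TestTransitionLists:
    def test_single_run(self, params):
        px = np.full((5, 9), 255, dtype=np.int64)
        px[:, 3:6] = 200
        lists = transition_lists(GrayImage(px), params)
        assert lists.head == (3,) and lists.end == (5,)

    def test_multiple_runs_match_rle_oracle(self, params):
        rng = np.random.default_rng(13)
        col_mask = rng.random(80) < 0.25
        px = np.where(col_mask, 40, 255)[None, :].repeat(20, axis=0)
        lists = transition_lists(GrayImage(px), params)
        # independent run-length encoding of the column mask
        heads, ends, inside = [], [], False
        for j, v in enumerate(col_mask):
            if v and not inside:
                heads.append(j); inside = True
            if not v and inside:
                ends.append(j - 1); inside = False
        if inside:
            ends.append(len(col_mask) - 1)
        assert list(lists.head) == heads and list(lists.end) == ends

    def test_blank_image_gives_empty_lists(self, params):
        lists = transition_lists(GrayImage(np.full((8, 40), 230, dtype=np.uint8)), params)
        assert len(lists) == 0


GEOM = StripGeometry(expected_gap=20.0, nominal_line_width=9)  # merge tol 5


class TestRefineLists:
    control = LineRegion(0, 9)

    def test_distant_runs_unchanged(self):
        lists = LineLists((0, 30, 60), (9, 39, 69))
        assert refine_lists(lists, self.control, GEOM) == lists

    def test_close_fragments_fused(self):
        # 3-column gap, tolerance 5: fused into one run spanning both
        lists = LineLists((0, 13), (9, 22))
        out = refine_lists(lists, self.control, GEOM)
        assert out.head == (0,) and out.end == (22,)

    def test_width_outliers_dropped(self):
        lists = LineLists((0, 30, 60), (9, 30, 69))  # middle run 1 wide
        out = refine_lists(lists, self.control, GEOM)
        assert out.head == (0, 60) and out.end == (9, 69)

    def test_idempotent(self):
        for lists in [
            LineLists((0, 13), (9, 22)),
            LineLists((0, 30, 31, 60), (9, 30, 40, 69)),
        ]:
            once = refine_lists(lists, self.control, GEOM)
            assert refine_lists(once, self.control, GEOM) == once


class TestFinalizeLists:
    def test_blank_strip_imputes_nominal_positions(self, params, blank_strip):
        img, truth = blank_strip
        geom = default_geometry(StripSpec())
        den = median_denoise(img, params)
        control = locate_control_line(den, params)
        lists = transition_lists(den, params)
        final = finalize_lists(refine_lists(lists, control, geom), control, geom, img=den)
        regions = final.regions()
        assert len(regions) == 4
        for reg, line in zip(regions, truth["lines"]):
            assert abs(reg.head - line["head"]) <= 2
            assert abs(reg.end - line["end"]) <= 2

    def test_always_four_disjoint_ordered_regions(self, params, dark_strip):
        img, _ = dark_strip
        geom = default_geometry(StripSpec())
        den = median_denoise(img, params)
        control = locate_control_line(den, params)
        lists = refine_lists(transition_lists(den, params), control, geom)
        regions = finalize_lists(lists, control, geom, img=den).regions()
        assert len(regions) == 4
        for a, b in zip(regions, regions[1:]):
            assert a.end < b.head

    def test_excess_runs_keep_strongest_per_slot(self):
        geom = StripGeometry(expected_gap=100.0, nominal_line_width=11)
        # control at 50, two competing runs near slot 1 (145 weak, 155 strong)
        img = painted_strip(
            width=600,
            bands=[(45, 55, 120), (140, 150, 30), (150, 160, 90), (245, 255, 60)],
        )
        control = LineRegion(45, 55)
        lists = LineLists((45, 140, 150, 245), (55, 149, 160, 255))
        final = finalize_lists(lists, control, geom, img=img)
        t1 = final.regions()[1]
        assert abs(t1.center - 155) <= 2

    def test_control_absent_raises(self):
        geom = StripGeometry(expected_gap=100.0, nominal_line_width=11)
        control = LineRegion(40, 50)
        lists = LineLists((300,), (320,))
        with pytest.raises(ControlLineLostError):
            finalize_lists(lists, control, geom)


class TestNoiseRobustness:
    def test_detection_success_non_increasing_in_salt_pepper_density(self, config):
        rng = np.random.default_rng(31)
        specs = [
            StripSpec(concentration=float(c), seed=500 + i)
            for i, c in enumerate(rng.uniform(600, 1500, size=10))
        ]
        successes = []
        for density in (0.0, 0.02, 0.05, 0.1):
            n_ok = 0
            for spec in specs:
                img, truth = generate_strip(spec)
                if density > 0:
                    img = add_noise(img, "salt_pepper", density, seed=spec.seed + 1)
                rep = analyze_image(img, config)
                if rep.ok:
                    regions = [rep.control] + rep.test_lines
                    n_ok += all(
                        abs(r.head - l["head"]) <= 2 and abs(r.end - l["end"]) <= 2
                        for r, l in zip(regions, truth["lines"])
                    )
            successes.append(n_ok)
        assert all(a >= b for a, b in zip(successes, successes[1:])), successes
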