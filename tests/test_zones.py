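import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

import eitzones as ez
from eitzones.errors import NoPositiveSignalError, ValidationError


def masks_from_coords(shape, coords):
    m = np.zeros(shape, dtype=bool)
    for rc in coords:
        m[rc] = True
    return m


class TestStatusImages:
    def test_identical_frames_give_zero_tidal(self):
        frames = np.tile(np.arange(4.0).reshape(1, 2, 2), (6, 1, 1))
        seq = ez.FrameSequence(frames, 40.0, "s", 0.0)
        marks = ez.BreathMarks(np.array([1, 3]), np.array([2, 4]))
        st_img = ez.status_images(seq, marks)
        np.testing.assert_array_equal(st_img.tidal, np.zeros((2, 2)))

    def test_constant_offset_appears_in_tidal(self):
        exp = np.ones((2, 2))
        frames = np.stack([exp, exp + 3.0])
        seq = ez.FrameSequence(frames, 40.0, "s", 0.0)
        marks = ez.BreathMarks(np.array([1]), np.array([0]))
        st_img = ez.status_images(seq, marks)
        np.testing.assert_array_equal(st_img.tidal, np.full((2, 2), 3.0))

    def test_matches_per_pixel_loop_oracle(self, rng):
        frames = rng.normal(size=(10, 3, 3))
        seq = ez.FrameSequence(frames, 40.0, "s", 0.0)
        insp, exp = np.array([1, 3, 5, 7, 9]), np.array([0, 2, 4, 6, 8])
        st_img = ez.status_images(seq, ez.BreathMarks(insp, exp))
        for i in range(3):
            for j in range(3):
                mi = sum(frames[t][i, j] for t in insp) / 5
                me = sum(frames[t][i, j] for t in exp) / 5
                assert st_img.end_insp[i, j] == pytest.approx(mi)
                assert st_img.end_exp[i, j] == pytest.approx(me)
                assert st_img.tidal[i, j] == pytest.approx(mi - me)

    def test_tidal_plus_end_exp_equals_end_insp(self, rng):
        frames = rng.normal(size=(8, 4, 4))
        seq = ez.FrameSequence(frames, 40.0, "s", 0.0)
        st_img = ez.status_images(seq, ez.BreathMarks(np.array([1, 5]), np.array([0, 4])))
        np.testing.assert_allclose(st_img.tidal + st_img.end_exp, st_img.end_insp)

    def test_out_of_range_mark_rejected(self):
        seq = ez.FrameSequence(np.zeros((3, 2, 2)), 40.0, "s", 0.0)
        with pytest.raises(ValidationError, match="out of range"):
            ez.status_images(seq, ez.BreathMarks(np.array([5]), np.array([0])))


class TestLungMask:
    def test_strict_inequality_at_threshold(self):
        img = np.array([[100.0, 25.0], [25.0001, 0.0]])
        mask = ez.lung_mask(img, 0.25)
        assert mask[0, 0] and not mask[0, 1] and mask[1, 0] and not mask[1, 1]

    def test_uniform_positive_image_is_all_included(self):
        # every pixel equals the maximum, and frac·max < max for frac < 1
        assert ez.lung_mask(np.full((3, 3), 7.0), 0.25).all()

    def test_hand_enumerated_example(self):
        img = np.array([[0, 1, 2], [3, 4, 10], [0, 0, 5]], dtype=float)
        mask = ez.lung_mask(img, 0.25)  # threshold 2.5
        expected = img > 2.5  # selects {3, 4, 10, 5}
        np.testing.assert_array_equal(mask, expected)
        assert sorted(img[mask]) == [3, 4, 5, 10]

    def test_no_positive_signal_raises(self):
        with pytest.raises(NoPositiveSignalError, match="baseline"):
            ez.lung_mask(np.full((2, 2), -1.0), 0.25)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(
        img=arrays(float, (4, 4), elements=st.floats(-5, 10, width=32)),
        scale=st.floats(0.001, 1000),
        frac=st.floats(0.05, 0.95),
    )
    def test_scale_invariance(self, img, scale, frac):
        if img.max() <= 0:
            return
        np.testing.assert_array_equal(
            ez.lung_mask(img, frac), ez.lung_mask(scale * img, frac)
        )

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(img=arrays(float, (5, 5), elements=st.floats(0, 10, width=32)))
    def test_threshold_monotonicity(self, img):
        if img.max() <= 0:
            return
        sizes = [ez.lung_mask(img, f).sum() for f in (0.15, 0.25, 0.35)]
        assert sizes[0] >= sizes[1] >= sizes[2]


class TestClassifyStep:
    def test_identical_regions_give_empty_categories(self):
        img = np.array([[1.0, 0.0], [0.0, 1.0]])
        status = ez.StatusImages(end_insp=2 * img, end_exp=img, tidal=img)
        masks = ez.classify_step(status)
        assert not masks.overinflated.any() and not masks.cyclic.any()

    def test_degenerate_tidal_image_raises(self):
        pos = np.ones((2, 2))
        status = ez.StatusImages(end_insp=pos, end_exp=pos, tidal=np.zeros((2, 2)))
        with pytest.raises(NoPositiveSignalError):
            ez.classify_step(status)

    def test_toy_set_difference(self):
        # lung_ee = {A, B}, lung_tidal = {B, C} → overinflated {A}, cyclic {C}
        a, b, c = (0, 0), (0, 1), (1, 0)
        end_exp = np.zeros((2, 2))
        end_exp[a] = end_exp[b] = 1.0
        tidal = np.zeros((2, 2))
        tidal[b] = tidal[c] = 1.0
        end_exp[1, 1] = tidal[1, 1] = 0.01  # keep maxima positive elsewhere
        masks = ez.classify_step(ez.StatusImages(end_exp + tidal, end_exp, tidal))
        np.testing.assert_array_equal(masks.overinflated, masks_from_coords((2, 2), [a]))
        np.testing.assert_array_equal(masks.cyclic, masks_from_coords((2, 2), [c]))

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(
        end_exp=arrays(float, (4, 4), elements=st.floats(0, 10, width=32)),
        tidal=arrays(float, (4, 4), elements=st.floats(0, 10, width=32)),
    )
    def test_set_algebra_invariants(self, end_exp, tidal):
        if end_exp.max() <= 0 or tidal.max() <= 0:
            return
        masks = ez.classify_step(ez.StatusImages(end_exp + tidal, end_exp, tidal))
        assert not (masks.overinflated & masks.cyclic).any()
        assert (masks.overinflated <= masks.lung_ee).all()
        assert (masks.cyclic <= masks.lung_tidal).all()

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(
        end_exp=arrays(float, (4, 4), elements=st.floats(0, 10, width=32)),
        tidal=arrays(float, (4, 4), elements=st.floats(0, 10, width=32)),
        perm_seed=st.integers(0, 1000),
    )
    def test_commutes_with_pixel_permutation(self, end_exp, tidal, perm_seed):
        if end_exp.max() <= 0 or tidal.max() <= 0:
            return
        perm = np.random.default_rng(perm_seed).permutation(16)

        def apply(img):
            return img.ravel()[perm].reshape(4, 4)

        direct = ez.classify_step(
            ez.StatusImages(apply(end_exp + tidal), apply(end_exp), apply(tidal))
        )
        base = ez.classify_step(ez.StatusImages(end_exp + tidal, end_exp, tidal))
        for name in ("lung_ee", "lung_tidal", "overinflated", "cyclic"):
            np.testing.assert_array_equal(
                getattr(direct, name), apply(getattr(base, name))
            )


class TestRecruitedMask:
    def test_self_difference_is_empty(self):
        m = np.array([[True, False], [True, True]])
        assert not ez.recruited_mask(m, m).any()

    def test_empty_reference_returns_current(self):
        cur = np.array([[True, False], [False, True]])
        np.testing.assert_array_equal(
            ez.recruited_mask(cur, np.zeros((2, 2), bool)), cur
        )

    def test_hand_enumerated_difference(self):
        cur = masks_from_coords((2, 2), [(0, 0), (0, 1), (1, 0)])  # {A,B,C}
        ref = masks_from_coords((2, 2), [(0, 1)])  # {B}
        expected = masks_from_coords((2, 2), [(0, 0), (1, 0)])  # {A,C}
        np.testing.assert_array_equal(ez.recruited_mask(cur, ref), expected)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            ez.recruited_mask(np.zeros((2, 2), bool), np.zeros((3, 3), bool))


class TestBruteForceEquivalence:
    """classify_step and recruited_mask versus per-pixel set enumeration."""

    @staticmethod
    def brute_force(end_exp, tidal, ref_lung_ee, ee_frac=0.25, tidal_frac=0.20):
        h, w = end_exp.shape
        lung_ee = {(i, j) for i in range(h) for j in range(w)
                   if end_exp[i, j] > ee_frac * end_exp.max()}
        lung_tidal = {(i, j) for i in range(h) for j in range(w)
                      if tidal[i, j] > tidal_frac * tidal.max()}
        ref = {(i, j) for i in range(h) for j in range(w) if ref_lung_ee[i, j]}
        return {
            "overinflated": lung_ee - lung_tidal,
            "cyclic": lung_tidal - lung_ee,
            "recruited": lung_ee - ref,
        }

    def test_matches_on_1000_random_instances(self):
        rng = np.random.default_rng(2016)
        for _ in range(1000):
            end_exp = rng.uniform(0.01, 1, size=(8, 8))
            tidal = rng.uniform(0.01, 1, size=(8, 8))
            ref = rng.random((8, 8)) < 0.5
            masks = ez.classify_step(ez.StatusImages(end_exp + tidal, end_exp, tidal))
            rec = ez.recruited_mask(masks.lung_ee, ref)
            oracle = self.brute_force(end_exp, tidal, ref)
            for name, got in (("overinflated", masks.overinflated),
                              ("cyclic", masks.cyclic), ("recruited", rec)):
                assert {tuple(rc) for rc in np.argwhere(got)} == oracle[name]


class TestDice:
    def test_both_empty_is_one(self):
        assert ez.dice(np.zeros((2, 2), bool), np.zeros((2, 2), bool)) == 1.0

    def test_partial_overlap(self):
        a = masks_from_coords((2, 2), [(0, 0), (0, 1)])
        b = masks_from_coords((2, 2), [(0, 1), (1, 1)])
        assert ez.dice(a, b) == pytest.approx(0.5)
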