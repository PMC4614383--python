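"""Segmentation, phase flipping, classification, spectrum measurement."""

import numpy as np
import pandas as pd
import pytest

from barlattice.lattice import HelicalSymmetry, TubeGeometry, layer_lines
from barlattice.preprocess import (
    MeasurementError,
    align_and_classify,
    measure_diameter,
    measure_layer_lines,
    phase_flip,
    segment_tube,
)
from barlattice.reconstruct import project
from barlattice.segments import CTFParams, SegmentStack, ctf_2d
from barlattice.simulate import (
    default_tube_model,
    lattice_projection_image,
    render_segments,
)


class TestSegmentTube:
    @pytest.mark.parametrize(
        "length,box,overlap,expected",
        [
            (1200, 300, 0.9, 31),  # floor(900/30) + 1
            (300, 300, 0.5, 1),
            (299, 300, 0.0, 0),
            (1000, 100, 0.0, 10),
        ],
    )
    def test_center_counts_on_straight_traces(self, length, box, overlap, expected):
        trace = np.array([[0.0, 0.0], [0.0, float(length)]])
        centers = segment_tube(trace, box, overlap)
        assert len(centers) == expected

    def test_step_spacing(self):
        trace = np.array([[0.0, 0.0], [0.0, 1200.0]])
        centers = segment_tube(trace, 300, 0.9)
        ys = np.array([c[1] for c in centers])
        assert np.all(np.diff(ys) == 30)

    def test_degenerate_trace(self):
        assert segment_tube(np.array([[5.0, 5.0]]), 100, 0.5) == []

    def test_invalid_overlap(self):
        with pytest.raises(ValueError):
            segment_tube(np.array([[0, 0], [0, 500]]), 100, 1.0)


class TestPhaseFlip:
    def test_involution(self, ctf):
        rng = np.random.default_rng(0)
        img = rng.standard_normal((64, 64))
        twice = phase_flip(phase_flip(img, ctf), ctf)
        assert np.allclose(twice, img, atol=1e-10)

    def test_total_power_preserved(self, ctf):
        rng = np.random.default_rng(1)
        img = rng.standard_normal((64, 64))
        out = phase_flip(img, ctf)
        p_in = np.abs(np.fft.fft2(img)) ** 2
        p_out = np.abs(np.fft.fft2(out)) ** 2
        assert np.allclose(p_in.sum(), p_out.sum(), rtol=1e-12)

    def test_single_frequency_sign(self, ctf):
        """A sinusoid is inverted exactly where the CTF is negative."""
        h = ctf_2d((64, 64), ctf)
        x = np.arange(64)
        for ky in (3, 6, 9, 12):
            img = np.cos(2 * np.pi * ky * x / 64)[:, None] * np.ones((1, 64))
            out = phase_flip(img, ctf)
            expected = np.sign(h[ky, 0]) * img
            assert np.allclose(out, expected, atol=1e-8), f"ky={ky}"


@pytest.fixture(scope="module")
def two_class_stack():
    ctf = CTFParams(defocus=1.5, pixel_size=3.0)
    m_a = default_tube_model(
        geometry=TubeGeometry(182, 248, 280), symmetry=HelicalSymmetry(3.81, 55.92)
    )
    m_b = default_tube_model(
        geometry=TubeGeometry(214, 280, 312), symmetry=HelicalSymmetry(3.83, 55.96)
    )
    stacks = [
        render_segments(m, ctf, 15, snr=0.5, seed=40 + i, box=120)
        for i, m in enumerate((m_a, m_b))
    ]
    images = np.concatenate([s.images for s in stacks])
    meta = pd.concat([s.metadata for s in stacks], ignore_index=True)
    meta["id"] = np.arange(30)
    meta["tube_id"] = [0] * 15 + [1] * 15
    return SegmentStack(images, 3.0, meta, ctf)


class TestAlignAndClassify:
    def test_identical_segments_single_class(self, tube_volume):
        from barlattice.preprocess import _align_one

        img = project(tube_volume, 25.0)
        stack = SegmentStack(np.stack([img] * 4), 3.0)
        (avg,) = align_and_classify(stack, 1, rotation_range=0.0)
        assert len(avg.member_ids) == 4
        aligned, _, _ = _align_one(np.asarray(stack.images[0]), 0.0, 1.0)
        assert np.allclose(avg.image, aligned, atol=1e-5)

    def test_two_diameters_separate_at_snr_05(self, two_class_stack):
        """Label accuracy >= 95% on a 2-class mixture at SNR 0.5."""
        classes = align_and_classify(two_class_stack, 2, seed=0)
        meta = two_class_stack.metadata.set_index("id")
        correct = 0
        for c in classes:
            truth = meta.loc[c.member_ids, "tube_id"]
            correct += max((truth == 0).sum(), (truth == 1).sum())
        assert correct / len(two_class_stack) >= 0.95

    def test_order_invariant_given_seed(self, two_class_stack):
        classes = align_and_classify(two_class_stack, 2, seed=0)
        perm = np.random.default_rng(1).permutation(len(two_class_stack))
        shuffled = SegmentStack(
            two_class_stack.images[perm],
            two_class_stack.pixel_size,
            two_class_stack.metadata.iloc[perm].reset_index(drop=True),
        )
        classes2 = align_and_classify(shuffled, 2, seed=0)
        sets1 = sorted(tuple(sorted(c.member_ids)) for c in classes)
        sets2 = sorted(tuple(sorted(c.member_ids)) for c in classes2)
        assert sets1 == sets2

    def test_more_classes_than_segments(self, two_class_stack):
        with pytest.raises(ValueError):
            align_and_classify(two_class_stack, 31)


class TestMeasureLayerLines:
    def test_major_class_spacings(self, tube_model):
        img = lattice_projection_image(tube_model, 2.0, (256, 160))
        sm = measure_layer_lines(img, min_prominence=5.0, pixel_size=2.0)
        top2 = sorted(s for s, _ in sm.axial_peaks[:2])
        assert top2[0] == pytest.approx(43.6, abs=1.0)
        assert top2[1] == pytest.approx(56.0, abs=1.2)

    def test_pure_noise_gives_no_peaks(self):
        rng = np.random.default_rng(3)
        img = rng.standard_normal((128, 128))
        sm = measure_layer_lines(img, min_prominence=20.0, pixel_size=2.0)
        assert sm.axial_peaks == []

    def test_shift_invariance(self, tube_model):
        img = lattice_projection_image(tube_model, 2.0, (256, 160))
        rolled = np.roll(img, 17, axis=0)
        a = measure_layer_lines(img, 5.0, pixel_size=2.0)
        b = measure_layer_lines(rolled, 5.0, pixel_size=2.0)
        sa = [round(s, 3) for s, _ in a.axial_peaks]
        sb = [round(s, 3) for s, _ in b.axial_peaks]
        assert sa == sb

    @pytest.mark.parametrize("seed", range(5))
    def test_peaks_match_selection_rule(self, seed):
        """Measured peaks land on allowed layer lines (one Fourier pixel)."""
        rng = np.random.default_rng(seed)
        sym = HelicalSymmetry(
            rise=float(rng.uniform(3.0, 5.0)), twist=float(rng.uniform(40.0, 75.0))
        )
        model = default_tube_model(symmetry=sym)
        ny, px = 256, 2.0
        img = lattice_projection_image(model, px, (ny, 160))
        sm = measure_layer_lines(img, min_prominence=5.0, pixel_size=px)
        allowed = np.array(
            [abs(L.axial_frequency) for L in layer_lines(sym, 20, 3)]
        )
        df = 1.0 / (ny * px)
        for spacing, _ in sm.axial_peaks[:4]:
            z = 1.0 / spacing
            assert np.min(np.abs(allowed - z)) <= df, (sym, spacing)


class TestMeasureDiameter:
    def test_round_trip_outer_leaflet(self, membrane_volume):
        img = project(membrane_volume, 0.0)
        d = measure_diameter(img, pixel_size=2.0)
        assert d == pytest.approx(248.0, abs=2.0)  # one voxel

    def test_uniform_image_fails(self):
        with pytest.raises(MeasurementError):
            measure_diameter(np.ones((64, 64)), pixel_size=2.0)

    def test_pixel_size_scaling(self, membrane_volume):
        img = project(membrane_volume, 0.0)
        d1 = measure_diameter(img, pixel_size=2.0)
        d2 = measure_diameter(img, pixel_size=4.0)
        assert d2 == pytest.approx(2 * d1)
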