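"""Signal synthesis: closed-form attenuations, mixtures, FOD path, Rician noise."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dwiphantom import (
    DiffusivitySet,
    FiberKernel,
    GradientScheme,
    NoiseSpec,
    SignalError,
    add_rician_noise,
    fiber_attenuation,
    isotropic_attenuation,
    make_single_voxel,
    project_fod,
    signal_from_fod,
    simulate_volume,
    voxel_signal,
)
from dwiphantom.signal import project_fod_field

Z = np.array([0.0, 0.0, 1.0])
X = np.array([1.0, 0.0, 0.0])

unit_vectors = st.tuples(
    st.floats(-1, 1), st.floats(-1, 1), st.floats(-1, 1)
).map(np.array).filter(lambda v: np.linalg.norm(v) > 1e-3).map(
    lambda v: v / np.linalg.norm(v)
)


class TestAttenuations:
    @pytest.mark.parametrize(
        "g, expected",
        [(Z, math.exp(-2.2)), (X, math.exp(-0.2))],
        ids=["parallel", "perpendicular"],
    )
    def test_fiber_closed_form_at_default_kernel(self, g, expected):
        assert fiber_attenuation(FiberKernel(), Z, g, 1000.0) == pytest.approx(
            expected, rel=1e-12
        )

    def test_fiber_b0_is_one(self):
        assert fiber_attenuation(FiberKernel(), Z, X, 0.0) == 1.0

    def test_fiber_nonunit_rejected(self):
        with pytest.raises(SignalError, match="unit"):
            fiber_attenuation(FiberKernel(), 2 * Z, X, 1000.0)

    @settings(deadline=None, derandomize=True)
    @given(v=unit_vectors, g=unit_vectors, b=st.floats(0, 3000))
    def test_fiber_attenuation_bounded_and_antipodally_symmetric(self, v, g, b):
        k = FiberKernel()
        a = fiber_attenuation(k, v, g, b)
        assert 0.0 < a <= 1.0
        assert fiber_attenuation(k, -v, g, b) == pytest.approx(a, rel=1e-12)
        assert fiber_attenuation(k, v, -g, b) == pytest.approx(a, rel=1e-12)

    @pytest.mark.parametrize(
        "D, b, expected",
        [
            (3.0e-3, 1000.0, math.exp(-3.0)),
            (2.0e-4, 1000.0, math.exp(-0.2)),
            (9.0e-4, 0.0, 1.0),
        ],
        ids=["csf", "wm", "b0"],
    )
    def test_isotropic_closed_form(self, D, b, expected):
        assert isotropic_attenuation(D, b) == pytest.approx(expected, rel=1e-12)

    def test_isotropic_negative_b_rejected(self):
        with pytest.raises(SignalError):
            isotropic_attenuation(1e-3, -1.0)

    def test_invalid_kernel_rejected(self):
        with pytest.raises(SignalError):
            FiberKernel(lambda_par=1e-4, lambda_perp=2e-4)


def _single_dir_scheme(g, b=1000.0):
    return GradientScheme(bvals=[0.0, b], bvecs=[[0, 0, 0], g])


class TestVoxelSignal:
    def test_mixed_voxel_closed_form(self):
        sch = _single_dir_scheme(Z)
        s = voxel_signal({"WM": 0.2, "CSF": 0.1}, [0.7], [Z], sch, s0=1.0)
        expected = 0.7 * math.exp(-2.2) + 0.2 * math.exp(-0.2) + 0.1 * math.exp(-3.0)
        assert s[1] == pytest.approx(expected, rel=1e-12)
        assert s[0] == pytest.approx(1.0)  # b0 conservation

    def test_pure_csf_b2000(self):
        sch = _single_dir_scheme(X, b=2000.0)
        s = voxel_signal({"CSF": 1.0}, [], [], sch, s0=1.0)
        assert s[1] == pytest.approx(math.exp(-6.0), rel=1e-12)

    def test_all_zero_voxel_yields_zero(self, scheme30):
        s = voxel_signal({}, [], [], scheme30, s0=1.0)
        assert np.all(s == 0)

    def test_abnormal_without_diffusivity_rejected(self, scheme30):
        with pytest.raises(SignalError, match="abnormal"):
            voxel_signal({"abnormal": 1.0}, [], [], scheme30)

    def test_monotone_nonincreasing_in_b(self):
        bs = [0.0, 500.0, 1000.0, 2000.0, 3000.0]
        sch = GradientScheme(bvals=bs, bvecs=[[0, 0, 0]] + [list(Z)] * 4)
        s = voxel_signal({"WM": 0.3}, [0.7], [Z], sch, s0=1.0)
        assert np.all(np.diff(s) <= 0)


class TestSimulateVolume:
    def test_b0_equals_s0_in_brain(self, mini_brain, scheme30):
        vol = simulate_volume(mini_brain, scheme30, s0=1000.0)
        b0 = vol.data[..., scheme30.b0_mask][..., 0]
        inside = mini_brain.fraction_total() > 0
        np.testing.assert_allclose(b0[inside], 1000.0, atol=1e-6)
        assert np.all(b0[~inside] == 0)

    def test_single_voxel_csf_reduces_to_isotropic(self, scheme_two_shell):
        m = make_single_voxel({"CSF": 1.0})
        vol = simulate_volume(m, scheme_two_shell, s0=1.0)
        expected = np.exp(-scheme_two_shell.bvals * 3.0e-3)
        np.testing.assert_allclose(vol.data[0, 0, 0], expected, rtol=1e-12)

    def test_crossing_voxel_signal_between_single_fiber_extremes(self):
        # at 90 degrees with the default kernel the WM attenuation coincides
        # with the perpendicular fiber attenuation, so the crossing-voxel
        # mixture lies strictly between the two pure-fiber extremes
        from dwiphantom import FixtureSpec, make_crossing_slab

        m = make_crossing_slab(
            FixtureSpec(kind="crossing_slab", shape=(16, 16, 8), crossing_angle=90.0)
        )
        k = FiberKernel()
        g = m.fibers.V[0][8, 8, 4]
        sch = _single_dir_scheme(g)
        vol = simulate_volume(m, sch, s0=1.0)
        both = (m.fibers.F[0] > 0.1) & (m.fibers.F[1] > 0.1)
        assert both.any()
        lo = fiber_attenuation(k, g, g, 1000.0)  # parallel: strongest decay
        hi = fiber_attenuation(k, m.fibers.V[1][8, 8, 4], g, 1000.0)  # perpendicular
        assert np.all(vol.data[both, 1] > lo)
        assert np.all(vol.data[both, 1] < hi)

    def test_convexity_bounds(self, mixed_voxel, scheme30):
        # mixture bounded by min/max compartment attenuation per volume
        vol = simulate_volume(mixed_voxel, scheme30, s0=1.0)
        k = FiberKernel()
        d = DiffusivitySet()
        sig = vol.data[0, 0, 0]
        c = scheme30.bvecs @ Z
        atts = np.stack(
            [
                np.exp(-scheme30.bvals * (k.lambda_perp + k.delta * c**2)),
                np.exp(-scheme30.bvals * d.D_WM),
                np.exp(-scheme30.bvals * d.D_CSF),
            ]
        )
        assert np.all(sig >= atts.min(axis=0) - 1e-12)
        assert np.all(sig <= atts.max(axis=0) + 1e-12)

    def test_antipodal_scheme_invariance(self, mini_brain, scheme30):
        flipped = GradientScheme(bvals=scheme30.bvals, bvecs=-scheme30.bvecs)
        a = simulate_volume(mini_brain, scheme30)
        b = simulate_volume(mini_brain, flipped)
        np.testing.assert_array_equal(a.data, b.data)


class TestFodPath:
    def test_single_fiber_along_z_is_axially_symmetric(self):
        coeffs = project_fod([1.0], [Z], max_order=8)
        from dwiphantom.sh import sh_index_list

        for c, (l, m) in zip(coeffs, sh_index_list(8)):
            if m != 0:
                assert abs(c) < 1e-9

    def test_empty_voxel_zero_coefficients(self):
        assert np.all(project_fod([], [], max_order=8) == 0)

    def test_integral_equals_total_fraction(self):
        coeffs = project_fod([0.4, 0.3], [Z, X], max_order=8)
        assert coeffs[0] * math.sqrt(4 * math.pi) == pytest.approx(0.7, abs=1e-3)

    def test_equal_crossing_fibers_have_equal_maxima(self):
        from dwiphantom.sh import real_sh_basis

        coeffs = project_fod([0.5, 0.5], [Z, X], max_order=8)
        # dense spherical grid evaluation
        theta = np.linspace(0, np.pi, 181)
        phi = np.linspace(0, 2 * np.pi, 361)
        tt, pp = np.meshgrid(theta, phi, indexing="ij")
        dirs = np.stack(
            [np.sin(tt) * np.cos(pp), np.sin(tt) * np.sin(pp), np.cos(tt)], axis=-1
        ).reshape(-1, 3)
        vals = real_sh_basis(8, dirs) @ coeffs
        at_z = vals[np.argmax(dirs @ Z)]
        at_x = vals[np.argmax(dirs @ X)]
        assert at_z == pytest.approx(vals.max(), rel=1e-3)
        assert at_z == pytest.approx(at_x, abs=1e-6)

    def test_odd_order_rejected(self):
        with pytest.raises(SignalError, match="even"):
            project_fod([1.0], [Z], max_order=7)

    @pytest.mark.parametrize(
        "dirs",
        [
            [Z],
            [Z, X],
            [Z, np.array([math.sin(math.pi / 3), 0, math.cos(math.pi / 3)])],
            [Z, X, np.array([0.0, 1.0, 0.0])],
        ],
        ids=["single", "cross90", "cross60", "three"],
    )
    def test_matches_discrete_sum_within_2pct_rms(self, dirs, scheme30):
        k = FiberKernel()
        fracs = [1.0 / len(dirs)] * len(dirs)
        coeffs = project_fod(fracs, dirs, max_order=8)
        fod_sig = signal_from_fod(coeffs, k, scheme30, max_order=8)
        disc = np.zeros(len(scheme30))
        for f, v in zip(fracs, dirs):
            c = scheme30.bvecs @ v
            disc += f * np.exp(-scheme30.bvals * (k.lambda_perp + k.delta * c**2))
        disc[scheme30.b0_mask] = sum(fracs)
        rms = np.sqrt(np.mean((fod_sig - disc) ** 2)) / np.sqrt(np.mean(disc**2))
        assert rms < 0.02

    def test_zero_fod_gives_zero_signal(self, scheme30):
        coeffs = np.zeros(45)
        assert np.all(signal_from_fod(coeffs, FiberKernel(), scheme30, 8) == 0)

    def test_field_projection_matches_voxelwise(self, crossing_slab_60):
        field = project_fod_field(crossing_slab_60, max_order=8)
        ijk = (8, 8, 4)
        fracs = [f[ijk] for f in crossing_slab_60.fibers.F]
        dirs = [v[ijk] for v in crossing_slab_60.fibers.V]
        expected = project_fod(
            [f for f in fracs if f > 0], [d for f, d in zip(fracs, dirs) if f > 0], 8
        )
        np.testing.assert_allclose(field.coefficients[ijk], expected, atol=1e-12)


class TestRicianNoise:
    def test_infinite_snr_is_identity(self, mini_brain, scheme30):
        vol = simulate_volume(mini_brain, scheme30)
        out = add_rician_noise(vol, NoiseSpec(snr=math.inf, seed=0))
        np.testing.assert_array_equal(out.data, vol.data)

    def test_same_seed_reproduces(self, mini_brain, scheme30):
        vol = simulate_volume(mini_brain, scheme30)
        a = add_rician_noise(vol, NoiseSpec(snr=30.0, seed=42))
        b = add_rician_noise(vol, NoiseSpec(snr=30.0, seed=42))
        np.testing.assert_array_equal(a.data, b.data)

    def test_background_mean_is_rayleigh(self, mini_brain, scheme30):
        vol = simulate_volume(mini_brain, scheme30, s0=1000.0)
        noisy = add_rician_noise(vol, NoiseSpec(snr=30.0, seed=3))
        sigma = 1000.0 / 30.0
        bg = mini_brain.fraction_total() == 0
        samples = noisy.data[bg].ravel()
        assert samples.size > 1e5
        assert samples.mean() == pytest.approx(sigma * math.sqrt(math.pi / 2), rel=0.02)

    def test_no_brain_voxels_rejected(self, scheme30):
        m = make_single_voxel({"CSF": 1.0})
        vol = simulate_volume(m, scheme30)
        vol.data[...] = 0.0
        with pytest.raises(SignalError, match="in-brain"):
            add_rician_noise(vol, NoiseSpec(snr=30.0, seed=0))

    def test_output_nonnegative(self, mini_brain, scheme30):
        vol = simulate_volume(mini_brain, scheme30)
        noisy = add_rician_noise(vol, NoiseSpec(snr=5.0, seed=1))
        assert np.all(noisy.data >= 0)
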