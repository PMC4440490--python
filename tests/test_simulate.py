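"""Phantoms, projections and noise: the synthetic-data machinery."""

import numpy as np
import pytest
from scipy.ndimage import map_coordinates

from phantomnoise import (
    AtomList,
    NoiseSpec,
    Orientation,
    add_noise,
    blob_phantom,
    density_from_atoms,
    make_dataset,
    make_noise_stack,
    project,
    random_orientations,
)


class TestDensityFromAtoms:
    def test_single_carbon_projects_to_gaussian(self):
        atoms = AtomList(np.array([[0.0, 0.0, 0.0]]), ["C"], np.ones(1), np.zeros(1))
        v = density_from_atoms(atoms, pixel_size=1.0, box=32, sigma=2.0)
        proj = v.data.sum(axis=0)
        # peak at the rotation centre
        assert np.unravel_index(proj.argmax(), proj.shape) == (16, 16)
        # measured width of the projected Gaussian matches sigma
        y = np.arange(32) - 16.0
        marginal = proj.sum(axis=1)
        sigma_meas = np.sqrt((marginal * y**2).sum() / marginal.sum())
        assert sigma_meas == pytest.approx(2.0, rel=0.02)

    def test_total_mass_matches_atomic_numbers(self):
        rng = np.random.default_rng(2)
        pos = rng.uniform(-4, 4, (12, 3))
        elements = ["C", "N", "O", "S"] * 3
        atoms = AtomList(pos, elements, np.ones(12), np.zeros(12))
        v = density_from_atoms(atoms, pixel_size=1.0, box=40, sigma=1.5)
        expected = atoms.atomic_numbers.sum()
        assert v.data.sum() == pytest.approx(expected, rel=0.01)

    def test_empty_atoms_rejected(self):
        with pytest.raises(ValueError):
            AtomList(np.zeros((0, 3)), [], np.zeros(0), np.zeros(0))

    def test_atom_outside_box_reports_count(self):
        # three clustered atoms keep the centroid close to them; the one
        # outlier lands outside the box after centring
        pos = np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [-1.0, 0.0, 0.0],
                        [100.0, 0.0, 0.0]])
        atoms = AtomList(pos, ["C"] * 4, np.ones(4), np.zeros(4))
        with pytest.raises(ValueError, match=r"1 atom\(s\)"):
            density_from_atoms(atoms, pixel_size=1.0, box=64, sigma=1.0)


class TestBlobPhantom:
    def test_seeded_determinism(self):
        a = blob_phantom(10, 32, rng=np.random.default_rng(3))
        b = blob_phantom(10, 32, rng=np.random.default_rng(3))
        np.testing.assert_array_equal(a.data, b.data)

    def test_nonnegative(self, phantom32):
        assert phantom32.data.min() >= 0.0

    def test_support_inside_half_radius(self, phantom48):
        n = phantom48.box
        c = n // 2
        zz, yy, xx = np.meshgrid(*(np.arange(n) - c,) * 3, indexing="ij")
        r = np.sqrt(xx**2 + yy**2 + zz**2)
        assert np.all(phantom48.data[r >= n / 2 - 1] == 0.0)


class TestProject:
    def test_identity_projection_is_z_sum(self, phantom32):
        img = project(phantom32, Orientation.identity())
        np.testing.assert_allclose(img, phantom32.data.sum(axis=0), rtol=1e-4, atol=1e-4)

    def test_line_integral_conservation(self, phantom48):
        o = random_orientations(1, np.random.default_rng(1))[0]
        img = project(phantom48, o)
        assert img.sum() == pytest.approx(phantom48.data.sum(), rel=1e-3)

    def test_shift_moves_cross_correlation_peak(self, phantom32):
        o0 = Orientation.identity()
        o1 = Orientation(o0.rotation, (3.0, -2.0))
        a, b = project(phantom32, o0), project(phantom32, o1)
        cc = np.fft.ifft2(np.fft.fft2(b) * np.conj(np.fft.fft2(a))).real
        py, px = np.unravel_index(cc.argmax(), cc.shape)
        n = phantom32.box
        assert ((py + n // 2) % n - n // 2, (px + n // 2) % n - n // 2) == (-2, 3)

    def test_projection_theorem(self, phantom48):
        """FT of a projection matches the central section of the volume FT
        (shell correlation >= 0.99 up to 0.8 Nyquist).

        The oracle section is sampled from a 2x zero-padded spectrum so
        its own interpolation error stays well below the tested path's.
        """
        v = phantom48
        n = v.box
        m = 2 * n
        o = random_orientations(1, np.random.default_rng(21))[0]
        img = project(v, o)
        pad = np.zeros((m, m, m))
        lo = (m - n) // 2
        pad[lo : lo + n, lo : lo + n, lo : lo + n] = v.data
        F3 = np.fft.fftn(np.fft.ifftshift(pad))  # spectrum at half-shell spacing
        F2 = np.fft.fft2(np.fft.ifftshift(img.astype(float)))
        k = np.fft.fftfreq(n) * n
        ky, kx = np.meshgrid(k, k, indexing="ij")
        pts = np.stack([kx, ky, np.zeros_like(kx)], -1) @ o.rotation.as_matrix().T
        fine = 2.0 * pts  # fine-grid indices of the same frequencies
        coords = np.stack([fine[..., 2] % m, fine[..., 1] % m, fine[..., 0] % m])
        Fs = map_coordinates(F3.real, coords, order=1, mode="grid-wrap") + 1j * map_coordinates(
            F3.imag, coords, order=1, mode="grid-wrap"
        )
        shells = np.round(np.sqrt(kx**2 + ky**2)).astype(int)
        for sh in range(1, int(0.8 * (n // 2)) + 1):
            m = shells == sh
            num = np.abs(np.vdot(Fs[m], F2[m]))
            den = np.sqrt((np.abs(Fs[m]) ** 2).sum() * (np.abs(F2[m]) ** 2).sum())
            assert num / den >= 0.99, f"shell {sh}: {num / den:.4f}"


class TestAddNoise:
    def test_variance_definition(self, phantom48):
        img = project(phantom48, Orientation.identity())
        img = img / img.std() * np.sqrt(2.0)  # variance 2.0
        noisy = add_noise(img, NoiseSpec(0.1, seed=1))
        assert np.var(noisy - img) == pytest.approx(20.0, rel=0.05)

    def test_infinite_snr_is_identity(self, phantom32):
        img = project(phantom32, Orientation.identity())
        np.testing.assert_array_equal(add_noise(img, NoiseSpec(np.inf)), img)

    def test_output_variance(self, phantom48):
        img = project(phantom48, Orientation.identity())
        for snr in (0.5, 2.0):
            noisy = add_noise(img, NoiseSpec(snr, seed=3))
            assert np.var(noisy) == pytest.approx(np.var(img) * (1 + 1 / snr), rel=0.05)

    def test_noise_independent_of_signal(self, phantom48):
        img = project(phantom48, Orientation.identity())
        noisy = add_noise(img, NoiseSpec(1.0, seed=5))
        diff = (noisy - img).ravel()
        sig = (img - img.mean()).ravel()
        corr = np.dot(diff - diff.mean(), sig) / (
            np.linalg.norm(diff - diff.mean()) * np.linalg.norm(sig)
        )
        assert abs(corr) <= 3.0 / np.sqrt(img.size)

    def test_invalid_snr_rejected(self):
        with pytest.raises(ValueError):
            NoiseSpec(0.0)
        with pytest.raises(ValueError):
            NoiseSpec(-1.0)

    def test_matched_mode_preserves_variance(self, phantom48):
        img = project(phantom48, Orientation.identity())
        noisy = add_noise(img, NoiseSpec(0.5, model="matched", seed=7))
        assert np.var(noisy - img) == pytest.approx(np.var(img) / 0.5, rel=0.05)


class TestMakeNoiseStack:
    def test_white_mode_variance(self):
        stack = make_noise_stack(
            100, 64, reference_stats=(1.0, 4.0), rng=np.random.default_rng(2)
        )
        per_image = stack.data.var(axis=(1, 2))
        assert np.all(np.abs(per_image - 4.0) / 4.0 < 0.10)

    def test_seeded_determinism(self):
        a = make_noise_stack(5, 32, rng=np.random.default_rng(9))
        b = make_noise_stack(5, 32, rng=np.random.default_rng(9))
        np.testing.assert_array_equal(a.data, b.data)

    def test_white_spectrum_flat(self):
        """Rotationally averaged power is flat across shells (within 3 SE)."""
        n = 64
        stack = make_noise_stack(200, n, rng=np.random.default_rng(4))
        F = np.fft.fft2(stack.data)
        power = (np.abs(F) ** 2).mean(axis=0)
        k = np.fft.fftfreq(n) * n
        kr = np.round(np.sqrt(k[:, None] ** 2 + k[None, :] ** 2)).astype(int)
        shells = np.arange(2, n // 2)
        means = np.array([power[kr == s].mean() for s in shells])
        counts = np.array([(kr == s).sum() for s in shells])
        grand = means.mean()
        se = grand / np.sqrt(counts * 200 / 2.0)
        assert np.all(np.abs(means - grand) <= 3 * se + 3 * se.max())


class TestMakeDataset:
    def test_ground_truth_row_count(self, phantom32):
        stack, gt = make_dataset(phantom32, 17, NoiseSpec(1.0, seed=3))
        assert len(stack) == 17
        assert len(gt) == 17

    def test_noise_free_images_match_their_orientations(self, phantom32):
        stack, gt = make_dataset(phantom32, 5, NoiseSpec(np.inf, seed=8))
        for i in range(5):
            row = gt.df.iloc[i]
            o = Orientation.from_euler(row.phi, row.theta, row.psi, (row.dx, row.dy))
            re_img = project(phantom32, o)
            a = stack.data[i] - stack.data[i].mean()
            b = re_img - re_img.mean()
            corr = np.dot(a.ravel(), b.ravel()) / (
                np.linalg.norm(a) * np.linalg.norm(b)
            )
            assert corr == pytest.approx(1.0, abs=1e-6)

    def test_empirical_snr_matches_imposed(self, phantom48):
        clean, gt = make_dataset(phantom48, 30, NoiseSpec(np.inf, seed=12))
        rng = np.random.default_rng(12)  # same orientations via same seed
        noisy, _ = make_dataset(phantom48, 30, NoiseSpec(0.1, seed=12))
        noise = noisy.data - clean.data
        snr_emp = clean.data.var(axis=(1, 2)) / noise.var(axis=(1, 2))
        assert np.mean(snr_emp) == pytest.approx(0.1, rel=0.10)
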