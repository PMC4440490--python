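"""Fourier central-section reconstruction: identities, symmetry, linearity."""

import numpy as np
import pytest

from phantomnoise import (
    ImageStack,
    ParamTable,
    Volume,
    fsc_curve,
    halfset_reconstructions,
    reconstruct,
    symmetry_operators,
)
from phantomnoise.reconstruct import insert_images, merge_partials
from phantomnoise.simulate import NoiseSpec, make_dataset


def _identity_row(i=0, **kw):
    row = dict(id=i, phi=0.0, theta=0.0, psi=0.0, dx=0.0, dy=0.0, score=1.0, select=1)
    row.update(kw)
    return row


def _shell_corr_2d(a, b, n):
    k = np.fft.fftfreq(n) * n
    ky, kx = np.meshgrid(k, k, indexing="ij")
    kr = np.round(np.sqrt(kx**2 + ky**2)).astype(int)
    out = {}
    for sh in range(1, n // 2):
        m = kr == sh
        den = np.sqrt((np.abs(a[m]) ** 2).sum() * (np.abs(b[m]) ** 2).sum())
        out[sh] = np.abs(np.vdot(a[m], b[m])) / den if den > 0 else 0.0
    return out


class TestCentralSliceIdentity:
    def test_single_identity_image(self, phantom32):
        """The reconstruction's central Fourier section reproduces the
        image transform; the single section inverts to a slab whose
        z-projection is image / oversample."""
        img = phantom32.data.sum(axis=0)
        stack = ImageStack(img[None].astype(np.float32))
        table = ParamTable.from_rows([_identity_row()])
        rec = reconstruct(stack, table, "C1", oversample=2)
        n = phantom32.box
        np.testing.assert_allclose(
            rec.data.sum(axis=0), img / 2.0, rtol=1e-5, atol=1e-5 * np.abs(img).max()
        )
        F3 = np.fft.fftn(np.fft.ifftshift(rec.data.astype(float)))
        F2 = np.fft.fft2(np.fft.ifftshift(img.astype(float)))
        corr = _shell_corr_2d(F3[0], F2, n)
        assert min(corr[sh] for sh in range(1, int(0.8 * (n // 2)))) >= 0.99

    def test_shift_correction_round_trip(self, phantom32):
        """An image recorded with a shift reconstructs like the unshifted one."""
        img = phantom32.data.sum(axis=0)
        f = np.fft.fft2(img)
        from scipy.ndimage import fourier_shift

        shifted = np.fft.ifft2(fourier_shift(f, (-2.0, 3.0))).real  # (dy, dx)
        stack = ImageStack(shifted[None].astype(np.float32))
        table = ParamTable.from_rows([_identity_row(dx=3.0, dy=-2.0)])
        rec = reconstruct(stack, table, "C1", oversample=2)
        np.testing.assert_allclose(
            rec.data.sum(axis=0), img / 2.0, rtol=1e-3, atol=1e-3 * np.abs(img).max()
        )

    def test_parseval_within_band(self, phantom32):
        """The inserted central section carries the image's Fourier power
        (Parseval, on the oversampled accumulator, within 5%)."""
        img = phantom32.data.sum(axis=0)
        stack = ImageStack(img[None].astype(np.float32))
        table = ParamTable.from_rows([_identity_row()])
        acc, wacc = insert_images(stack, table, symmetry_operators("C1"), 2)
        eps = 1e-6 * wacc.max()
        F = acc / np.maximum(wacc, eps)
        p_grid = (np.abs(F[wacc > 0.5]) ** 2).sum()
        n = phantom32.box
        m = 2 * n
        padded = np.zeros((m, m))
        lo = (m - n) // 2
        padded[lo : lo + n, lo : lo + n] = img
        p_img = (np.abs(np.fft.fft2(padded)) ** 2).sum()
        assert p_grid == pytest.approx(p_img, rel=0.05)


class TestFidelity:
    def test_noise_free_fidelity(self, phantom32, noisefree500):
        """500 noise-free projections at known orientations rebuild the
        phantom to FSC >= 0.99 up to 0.8 Nyquist."""
        stack, gt = noisefree500
        rec = reconstruct(stack, gt, "C1", oversample=2)
        c = fsc_curve(rec, phantom32)
        hi = int(0.8 * (phantom32.box // 2))
        assert c.fsc[1 : hi + 1].min() >= 0.99


class TestSymmetry:
    def test_c4_equals_expanded_c1(self, phantom32):
        """Reconstructing with C4 symmetry equals reconstructing with C1
        from the 4x symmetry-expanded parameter table."""
        # make a C4-symmetric phantom by averaging over the group
        ops = symmetry_operators("C4")
        from phantomnoise.geometry import Orientation
        from scipy.ndimage import affine_transform

        data = np.zeros_like(phantom32.data, dtype=np.float64)
        for g in ops.operators:
            J = g.as_matrix()[::-1, ::-1]
            c = np.full(3, float(phantom32.origin))
            data += affine_transform(
                phantom32.data.astype(float), J, offset=c - J @ c, order=3
            )
        vsym = Volume((data / 4).astype(np.float32))
        stack, gt = make_dataset(vsym, 40, NoiseSpec(np.inf, seed=2))
        rec_sym = reconstruct(stack, gt, "C4", oversample=2)
        rows = []
        k = 0
        for _, row in gt.df.iterrows():
            base = Orientation.from_euler(row.phi, row.theta, row.psi)
            for g in ops.operators:
                phi, theta, psi = _zyz(g * base.rotation)
                rows.append(
                    dict(id=k, phi=phi, theta=theta, psi=psi, dx=row.dx, dy=row.dy,
                         score=1.0, select=1)
                )
                k += 1
        big = ImageStack(
            np.repeat(stack.data, 4, axis=0), stack.pixel_size, list(range(k))
        )
        rec_c1 = reconstruct(big, ParamTable.from_rows(rows), "C1", oversample=2)
        c = fsc_curve(rec_sym, rec_c1)
        hi = int(0.8 * (phantom32.box // 2))
        assert c.fsc[1 : hi + 1].min() >= 0.99


def _zyz(rot):
    ang = rot.as_euler("ZYZ", degrees=True)
    if ang[1] < 0:
        ang = np.array([ang[0] + 180.0, -ang[1], ang[2] + 180.0])
    return ang[0] % 360, ang[1], ang[2] % 360


class TestLinearity:
    def test_merge_of_partials_equals_joint(self, phantom32, noisefree500):
        stack, gt = noisefree500
        ids = gt.selected_ids()[:40]
        sym = symmetry_operators("C1")
        acc_a, w_a = insert_images(stack, gt, sym, 2, ids=ids[:15])
        acc_b, w_b = insert_images(stack, gt, sym, 2, ids=ids[15:])
        merged = merge_partials(acc_a + acc_b, w_a + w_b, 32, 1.0)
        joint = reconstruct(stack, gt, "C1", 2, ids=ids)
        scale = np.abs(joint.data).max()
        assert np.abs(merged.data - joint.data).max() <= 1e-5 * scale


class TestHalfsets:
    def test_split_sizes_and_exclusivity(self, phantom32):
        stack, gt = make_dataset(phantom32, 10, NoiseSpec(np.inf, seed=4))
        rng = np.random.default_rng(0)
        # inspect the split through the reconstruction seed determinism
        sel = gt.selected_ids()
        perm = np.random.default_rng(5).permutation(len(sel))
        h1, h2 = set(sel[perm[:5]]), set(sel[perm[5:]])
        assert len(h1) == len(h2) == 5
        assert h1 | h2 == set(sel) and not h1 & h2

    def test_seeded_split_reproducible(self, phantom32):
        stack, gt = make_dataset(phantom32, 12, NoiseSpec(np.inf, seed=4))
        a1, a2 = halfset_reconstructions(stack, gt, "C1", rng=np.random.default_rng(7))
        b1, b2 = halfset_reconstructions(stack, gt, "C1", rng=np.random.default_rng(7))
        np.testing.assert_array_equal(a1.data, b1.data)
        np.testing.assert_array_equal(a2.data, b2.data)

    def test_too_few_images_rejected(self, phantom32):
        stack, gt = make_dataset(phantom32, 2, NoiseSpec(np.inf, seed=4))
        one = ParamTable(gt.df.iloc[:1].copy())
        with pytest.raises(ValueError, match="at least 2"):
            halfset_reconstructions(stack, one, "C1")


class TestErrors:
    def test_missing_parameter_row(self, phantom32):
        stack, gt = make_dataset(phantom32, 3, NoiseSpec(np.inf, seed=4))
        with pytest.raises(KeyError):
            reconstruct(stack, gt, "C1", ids=[99])

    def test_zero_selected_rejected(self, phantom32):
        stack, gt = make_dataset(phantom32, 3, NoiseSpec(np.inf, seed=4))
        gt.df["select"] = 0
        with pytest.raises(ValueError, match="zero selected"):
            reconstruct(stack, gt, "C1")
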