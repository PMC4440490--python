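"""3D reconstruction by central-section insertion in Fourier space.

Each (shift-corrected, oversampled) image transform is inserted as a
central section at its orientation — and at every symmetry-equivalent
orientation — into an oversampled 3D transform by trilinear spreading
with weight accumulation; the accumulated transform is normalized by the
weights, inverse-transformed and cropped back to the original box.

The weight-normalized Fourier samples estimate the volume transform
directly, so reconstructions from projections of a volume converge to
that volume on its own amplitude scale (which keeps truth-based spectral
SNR meaningful). A single inserted section inverts to a slab through the
box whose z-projection is image / oversample.
"""

from __future__ import annotations

import numpy as np
from numba import njit
from scipy import fft as sfft

from .formats import ImageStack, ParamTable, Volume
from .geometry import Orientation, SymmetryGroup, symmetry_operators

__all__ = ["reconstruct", "insert_images", "merge_partials", "halfset_reconstructions"]


@njit(cache=False)
def _grid_insert(pos, vals, acc, wacc, m):  # pragma: no cover - exercised via reconstruct
    """Trilinear scatter of complex samples onto a periodic m^3 grid.

    pos is (L, 3) in xyz order, vals (L,) complex; acc/wacc are flat
    (m^3,) accumulators indexed as (z * m + y) * m + x.
    """
    for i in range(pos.shape[0]):
        px, py, pz = pos[i, 0], pos[i, 1], pos[i, 2]
        bx, by, bz = np.floor(px), np.floor(py), np.floor(pz)
        fx, fy, fz = px - bx, py - by, pz - bz
        ix0, iy0, iz0 = int(bx) % m, int(by) % m, int(bz) % m
        ix1, iy1, iz1 = (ix0 + 1) % m, (iy0 + 1) % m, (iz0 + 1) % m
        v = vals[i]
        gx0, gx1 = 1.0 - fx, fx
        gy0, gy1 = 1.0 - fy, fy
        gz0, gz1 = 1.0 - fz, fz
        w = gz0 * gy0 * gx0
        j = (iz0 * m + iy0) * m + ix0
        acc[j] += w * v
        wacc[j] += w
        w = gz0 * gy0 * gx1
        j = (iz0 * m + iy0) * m + ix1
        acc[j] += w * v
        wacc[j] += w
        w = gz0 * gy1 * gx0
        j = (iz0 * m + iy1) * m + ix0
        acc[j] += w * v
        wacc[j] += w
        w = gz0 * gy1 * gx1
        j = (iz0 * m + iy1) * m + ix1
        acc[j] += w * v
        wacc[j] += w
        w = gz1 * gy0 * gx0
        j = (iz1 * m + iy0) * m + ix0
        acc[j] += w * v
        wacc[j] += w
        w = gz1 * gy0 * gx1
        j = (iz1 * m + iy0) * m + ix1
        acc[j] += w * v
        wacc[j] += w
        w = gz1 * gy1 * gx0
        j = (iz1 * m + iy1) * m + ix0
        acc[j] += w * v
        wacc[j] += w
        w = gz1 * gy1 * gx1
        j = (iz1 * m + iy1) * m + ix1
        acc[j] += w * v
        wacc[j] += w


def _slice_coords(n_pad: int) -> np.ndarray:
    """Integer (kx, ky, 0) coordinates of a central section, fft order, (P, 3)."""
    k = (np.fft.fftfreq(n_pad) * n_pad).astype(np.float64)
    ky, kx = np.meshgrid(k, k, indexing="ij")
    return np.stack([kx.ravel(), ky.ravel(), np.zeros(kx.size)], axis=1)


def insert_images(
    stack: ImageStack,
    params: ParamTable,
    sym: SymmetryGroup,
    oversample: int = 2,
    ids=None,
):
    """Accumulate central-section insertions for the selected images.

    Returns (fourier_sum, weight_sum) on the oversampled grid; divide and
    invert with merge_partials(). Splitting a stack over several calls and
    summing the accumulators is exact (the gridding is linear).
    """
    if oversample < 1:
        raise ValueError("oversample must be >= 1")
    n = stack.box
    m = oversample * n
    sel = params.selected_ids() if ids is None else np.asarray(ids)
    if len(sel) == 0:
        raise ValueError("zero selected images")
    id_to_index = {img_id: i for i, img_id in enumerate(stack.ids)}
    lo = (m - n) // 2

    coords0 = _slice_coords(m)  # (P, 3)
    acc = np.zeros(m * m * m, dtype=np.complex128)
    wacc = np.zeros(m * m * m, dtype=np.float64)
    ops = sym.operators.as_matrix()  # (G, 3, 3)
    k = np.fft.fftfreq(m)
    for img_id in np.asarray(sel):
        if img_id not in id_to_index:
            raise KeyError(f"image id {img_id} not present in the stack")
        row = params.row_for(img_id)
        img = stack.data[id_to_index[img_id]].astype(np.float64)
        padded = np.zeros((m, m), dtype=np.float64)
        padded[lo : lo + n, lo : lo + n] = img
        F = sfft.fft2(np.fft.ifftshift(padded))
        # undo the recorded shift with a phase ramp
        if row.dx or row.dy:
            F = F * np.exp(2j * np.pi * (k[None, :] * row.dx + k[:, None] * row.dy))
        vals = F.ravel()
        R = Orientation.from_euler(row.phi, row.theta, row.psi).rotation.as_matrix()
        for g in ops:
            # symmetry-equivalent orientation g @ R; 3D position of each sample
            pos = coords0 @ (g @ R).T
            _grid_insert(pos, vals, acc, wacc, m)
    return acc.reshape(m, m, m), wacc.reshape(m, m, m)


def merge_partials(
    acc: np.ndarray, wacc: np.ndarray, box: int, pixel_size: float
) -> Volume:
    """Normalize accumulated insertions and return the real-space volume.

    Dividing by the weights makes each covered Fourier voxel an unbiased
    estimate of the volume transform, so no further scaling is applied:
    a well-covered reconstruction reproduces the source volume's
    amplitudes as-is.
    """
    m = acc.shape[0]
    eps = 1e-6 * max(wacc.max(), 1e-30)
    F = acc / np.maximum(wacc, eps)
    vol = np.fft.fftshift(sfft.ifftn(F).real)
    lo = (m - box) // 2
    vol = vol[lo : lo + box, lo : lo + box, lo : lo + box]
    return Volume(np.ascontiguousarray(vol).astype(np.float32), pixel_size=pixel_size)


def reconstruct(
    stack: ImageStack,
    params: ParamTable,
    sym: SymmetryGroup | str = "C1",
    oversample: int = 2,
    ids=None,
) -> Volume:
    """Fourier-gridding reconstruction from aligned images.

    Symmetry is applied by parameter expansion: each image is inserted at
    all |G| equivalent orientations. ids, when given, restricts the
    reconstruction to that subset of image ids (all must be selected rows).
    """
    if isinstance(sym, str):
        sym = symmetry_operators(sym)
    acc, wacc = insert_images(stack, params, sym, oversample, ids)
    return merge_partials(acc, wacc, stack.box, stack.pixel_size)


def halfset_reconstructions(
    stack: ImageStack,
    params: ParamTable,
    sym: SymmetryGroup | str = "C1",
    oversample: int = 2,
    rng: np.random.Generator | None = None,
    ids=None,
) -> tuple[Volume, Volume]:
    """Reconstructions from two mutually exclusive, exhaustive half-sets.

    The split is a random permutation halving under the given generator
    (pass numpy.random.default_rng(seed) for reproducibility); with
    rng=None the split is by even/odd position (parity rule).
    """
    sel = params.selected_ids() if ids is None else np.asarray(ids)
    if len(sel) < 2:
        raise ValueError("need at least 2 selected images to split")
    if rng is None:
        h1, h2 = sel[0::2], sel[1::2]
    else:
        perm = rng.permutation(len(sel))
        half = len(sel) // 2
        h1, h2 = sel[perm[:half]], sel[perm[half:]]
    v1 = reconstruct(stack, params, sym, oversample, ids=h1)
    v2 = reconstruct(stack, params, sym, oversample, ids=h2)
    return v1, v2
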