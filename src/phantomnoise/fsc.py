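"""Fourier shell correlation, resolution estimation, and the SSNR model.

The spectral signal-to-noise ratio of a reconstruction from N images is
modelled as SSNR(s, N) = N * C * s * SSNR_img(s) * exp(-B^2 s^2), with s
the spatial frequency (1/Å), C a proportionality constant and B (Å) a
decay parameter absorbing alignment error. fit_ssnr_model() recovers
(C, B) from measured shell-SSNR curves at several N by weighted linear
least squares in log space.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .formats import Volume

__all__ = [
    "FSCCurve",
    "SSNRModel",
    "fsc_curve",
    "resolution_at_cutoff",
    "ResolutionEstimate",
    "shell_ssnr",
    "ssnr_from_halves",
    "predict_ssnr",
    "fit_ssnr_model",
]


@dataclass
class FSCCurve:
    """Per-shell correlation between two volumes.

    s: shell-centre spatial frequencies (1/Å, strictly increasing up to
    Nyquist); fsc: correlation in [-1, 1]; n_terms: independent Fourier
    samples per shell.
    """

    s: np.ndarray
    fsc: np.ndarray
    n_terms: np.ndarray
    pixel_size: float = 1.0

    @property
    def nyquist(self) -> float:
        return 1.0 / (2.0 * self.pixel_size)


@dataclass
class ResolutionEstimate:
    """FSC resolution: value in Å plus a flag when the curve never crossed
    the cutoff (resolution limited by the sampling, not the data)."""

    resolution: float
    limit_reached: bool = False

    def __float__(self) -> float:
        return float(self.resolution)


def _shell_index(n: int) -> np.ndarray:
    k = np.fft.fftfreq(n) * n
    kz, ky, kx = np.meshgrid(k, k, k, indexing="ij")
    return np.round(np.sqrt(kx**2 + ky**2 + kz**2)).astype(np.int64)


_shell_cache: dict[int, tuple[np.ndarray, np.ndarray]] = {}


def _shells(n: int) -> tuple[np.ndarray, np.ndarray]:
    """Flattened shell index and per-shell counts for an n^3 grid (cached)."""
    if n not in _shell_cache:
        idx = _shell_index(n).ravel()
        n_shells = n // 2 + 1
        idx = np.minimum(idx, n_shells)  # lump the corner region past Nyquist
        counts = np.bincount(idx, minlength=n_shells + 1)[:n_shells]
        _shell_cache[n] = (idx, counts)
    return _shell_cache[n]


def fsc_curve(v1: Volume, v2: Volume) -> FSCCurve:
    """Fourier shell correlation between two equally sampled volumes.

    Per shell of one Fourier-voxel width (assignment by rounding the
    radial index): Re(sum F1 F2*) / sqrt(sum |F1|^2 * sum |F2|^2).
    """
    if v1.data.shape != v2.data.shape:
        raise ValueError(f"volume shapes differ: {v1.data.shape} vs {v2.data.shape}")
    if abs(v1.pixel_size - v2.pixel_size) > 1e-9:
        raise ValueError("volume pixel sizes differ")
    n = v1.box
    F1 = np.fft.fftn(v1.data.astype(np.float64))
    F2 = np.fft.fftn(v2.data.astype(np.float64))
    idx, counts = _shells(n)
    n_shells = n // 2 + 1
    cross = np.bincount(idx, weights=(F1 * np.conj(F2)).real.ravel(), minlength=n_shells + 1)[:n_shells]
    p1 = np.bincount(idx, weights=(np.abs(F1) ** 2).ravel(), minlength=n_shells + 1)[:n_shells]
    p2 = np.bincount(idx, weights=(np.abs(F2) ** 2).ravel(), minlength=n_shells + 1)[:n_shells]
    denom = np.sqrt(p1 * p2)
    fsc = np.where(denom > 0, cross / np.maximum(denom, 1e-300), 0.0)
    s = np.arange(n_shells) / (n * v1.pixel_size)
    return FSCCurve(s=s, fsc=fsc, n_terms=counts, pixel_size=v1.pixel_size)


def resolution_at_cutoff(curve: FSCCurve, cutoff: float = 0.5) -> ResolutionEstimate:
    """Resolution (Å) at the first downward crossing of the cutoff.

    Scanning from low frequency, the first shell pair bracketing the
    cutoff is linearly interpolated in s; if the curve never drops below
    the cutoff the Nyquist resolution is returned with limit_reached set.
    """
    if len(curve.s) == 0:
        raise ValueError("empty FSC curve")
    s, f = curve.s, curve.fsc
    for i in range(1, len(s)):
        if f[i] < cutoff <= f[i - 1]:
            frac = (f[i - 1] - cutoff) / (f[i - 1] - f[i])
            s_cross = s[i - 1] + frac * (s[i] - s[i - 1])
            return ResolutionEstimate(1.0 / s_cross, limit_reached=False)
    return ResolutionEstimate(2.0 * curve.pixel_size, limit_reached=True)


def shell_ssnr(recon: Volume, truth: Volume, clamp: float = 1e6) -> np.ndarray:
    """Truth-based spectral SNR per shell: sum|S|^2 / sum|R - S|^2."""
    if recon.data.shape != truth.data.shape:
        raise ValueError("volume shapes differ")
    n = recon.box
    S = np.fft.fftn(truth.data.astype(np.float64))
    R = np.fft.fftn(recon.data.astype(np.float64))
    idx, _ = _shells(n)
    n_shells = n // 2 + 1
    sig = np.bincount(idx, weights=(np.abs(S) ** 2).ravel(), minlength=n_shells + 1)[:n_shells]
    err = np.bincount(idx, weights=(np.abs(R - S) ** 2).ravel(), minlength=n_shells + 1)[:n_shells]
    return np.minimum(np.where(err > 0, sig / np.maximum(err, 1e-300), clamp), clamp)


def ssnr_from_halves(h1: Volume, h2: Volume, clamp_fsc: float = 0.999) -> np.ndarray:
    """Half-set spectral SNR per shell via the standard relation 2F/(1-F)."""
    f = np.clip(fsc_curve(h1, h2).fsc, -clamp_fsc, clamp_fsc)
    return 2.0 * f / (1.0 - f)


@dataclass
class SSNRModel:
    """Parameters of the reconstruction-SSNR relation.

    C: proportionality constant (unitless*Å); B: alignment-error decay (Å);
    s: frequency grid of the per-image SSNR curve; ssnr_img: image SSNR
    on that grid.
    """

    C: float
    B: float
    s: np.ndarray = field(default_factory=lambda: np.array([]))
    ssnr_img: np.ndarray = field(default_factory=lambda: np.array([]))

    def __post_init__(self):
        if self.C <= 0:
            raise ValueError("C must be > 0")
        if self.B < 0:
            raise ValueError("B must be >= 0")


def predict_ssnr(m: SSNRModel, s, N: float):
    """Evaluate SSNR(s, N) = N C s SSNR_img(s) exp(-B^2 s^2)."""
    s = np.asarray(s, dtype=float)
    if len(m.s):
        ssnr_img = np.interp(s, m.s, m.ssnr_img)
    else:
        ssnr_img = 1.0
    out = N * m.C * s * ssnr_img * np.exp(-(m.B**2) * s**2)
    return out if out.ndim else float(out)


def fit_ssnr_model(
    s: np.ndarray,
    curves: dict[int, np.ndarray],
    ssnr_img: np.ndarray,
    n_terms: np.ndarray | None = None,
) -> SSNRModel:
    """Fit (C, B) from measured shell-SSNR curves at several image counts.

    log(SSNR / (N s SSNR_img)) is regressed against s^2 (slope -B^2,
    intercept log C), weighted by the per-shell term counts when given.
    Shells with nonpositive measured SSNR (or zero s / image SSNR) are
    excluded from the log fit.
    """
    s = np.asarray(s, dtype=float)
    ssnr_img = np.asarray(ssnr_img, dtype=float)
    if len(curves) < 2:
        raise ValueError("need measurements at >= 2 distinct image counts")
    xs, ys, ws = [], [], []
    for N, curve in curves.items():
        curve = np.asarray(curve, dtype=float)
        ok = (curve > 0) & (s > 0) & (ssnr_img > 0)
        if ok.sum() < 5:
            continue
        xs.append(s[ok] ** 2)
        ys.append(np.log(curve[ok] / (N * s[ok] * ssnr_img[ok])))
        ws.append((n_terms[ok] if n_terms is not None else np.ones(ok.sum())).astype(float))
    if not xs:
        raise ValueError("no usable (positive) SSNR samples for the fit")
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    w = np.concatenate(ws)
    A = np.stack([np.ones_like(x), x], axis=1)
    sw = np.sqrt(w)
    coef, *_ = np.linalg.lstsq(A * sw[:, None], y * sw, rcond=None)
    C = float(np.exp(coef[0]))
    B = float(np.sqrt(max(-coef[1], 0.0)))
    return SSNRModel(C=C, B=B, s=s, ssnr_img=ssnr_img)
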