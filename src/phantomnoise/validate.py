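"""The noise-baseline validation test and supporting studies.

The central operation compares resolution-versus-N curves (FSC at 0.5
from half-set reconstructions, averaged over repeated random selections)
for particle images against pure-noise images aligned to the same
reference. A reconstruction is credible only while it beats the noise
baseline: any map is eventually recoverable from enough aligned noise
images, so the comparison at limited N is what carries information.

Also here: the resolution-limited cross-check (information beyond the
alignment band only appears for genuinely alignable images), the
alignment-error-versus-SNR study, and micrograph background-window
extraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .align import Aligner, AlignmentParams, align_stack
from .formats import ImageStack, ParamTable, Volume
from .fsc import FSCCurve, fsc_curve, resolution_at_cutoff
from .geometry import Orientation, orientation_errors, symmetry_operators
from .reconstruct import reconstruct
from .simulate import NoiseSpec, make_dataset, make_noise_stack

__all__ = [
    "ResolutionCurve",
    "ErrorSummary",
    "Verdict",
    "ResolutionLimitedResult",
    "resolution_vs_n",
    "noise_baseline",
    "compare_curves",
    "resolution_limited_check",
    "error_study",
    "snr_threshold",
    "extract_background_windows",
]


@dataclass
class ResolutionCurve:
    """FSC_0.5 resolution (Å, mean +/- SD over repeats) versus image count."""

    n_images: np.ndarray
    mean_res: np.ndarray
    sd_res: np.ndarray
    repeats: int
    arm_label: str = "particle"
    limit_fraction: np.ndarray = field(default_factory=lambda: np.array([]))

    def __post_init__(self):
        self.n_images = np.asarray(self.n_images)
        if np.any(np.diff(self.n_images) <= 0):
            raise ValueError("n_images must be strictly increasing")


@dataclass
class ErrorSummary:
    """Mean alignment errors against ground truth at one imposed SNR."""

    snr: float
    mean_view_error: float
    mean_inplane_error: float
    mean_shift_error: float
    n_images: int


@dataclass
class Verdict:
    """Outcome of the particle-versus-noise comparison.

    margins[i] = noise mean resolution - particle mean resolution at
    n_list[i] (Å; positive means the particle images did better).
    decision is "distinguishable" iff the margin exceeds k pooled SDs at
    a fraction >= q of the N points.
    """

    decision: str
    n_list: np.ndarray
    margins: np.ndarray
    pooled_sd: np.ndarray
    fraction_beating: float
    k: float
    q: float


@dataclass
class ResolutionLimitedResult:
    """Resolution curve from band-limited alignment plus the beyond-limit flag."""

    curve: ResolutionCurve
    beyond_limit: bool
    limit: float
    fsc_at_max_n: FSCCurve


# ---------------------------------------------------------------------------
# Resolution-vs-N protocol
# ---------------------------------------------------------------------------

def _halfset_resolution(
    stack: ImageStack,
    params: ParamTable,
    ids: np.ndarray,
    sym,
    oversample: int,
    rng: np.random.Generator,
) -> tuple[float, bool]:
    perm = rng.permutation(len(ids))
    half = len(ids) // 2
    v1 = reconstruct(stack, params, sym, oversample, ids=ids[perm[:half]])
    v2 = reconstruct(stack, params, sym, oversample, ids=ids[perm[half:]])
    est = resolution_at_cutoff(fsc_curve(v1, v2))
    return float(est.resolution), est.limit_reached


def _curve_from_alignment(
    stack: ImageStack,
    params: ParamTable,
    n_list,
    repeats: int,
    sym,
    oversample: int,
    rng: np.random.Generator,
    arm_label: str,
) -> ResolutionCurve:
    ids_all = params.selected_ids()
    means, sds, limfrac = [], [], []
    for n in n_list:
        vals, flags = [], []
        for _ in range(repeats):
            pick = rng.choice(len(ids_all), size=n, replace=False)
            res, flag = _halfset_resolution(
                stack, params, ids_all[pick], sym, oversample, rng
            )
            vals.append(res)
            flags.append(flag)
        means.append(np.mean(vals))
        sds.append(np.std(vals, ddof=1) if repeats > 1 else 0.0)
        limfrac.append(np.mean(flags))
    return ResolutionCurve(
        n_images=np.asarray(list(n_list)),
        mean_res=np.asarray(means),
        sd_res=np.asarray(sds),
        repeats=repeats,
        arm_label=arm_label,
        limit_fraction=np.asarray(limfrac),
    )


def resolution_vs_n(
    stack: ImageStack,
    ref: Volume,
    n_list,
    repeats: int,
    p: AlignmentParams,
    rng: np.random.Generator,
    oversample: int = 2,
    aligner: Aligner | None = None,
    params: ParamTable | None = None,
    realign: bool = False,
    arm_label: str = "particle",
) -> ResolutionCurve:
    """Mean +/- SD FSC_0.5 resolution versus number of images.

    Per N and repeat: draw N images without replacement, split into
    half-sets, reconstruct both halves and record the FSC_0.5 resolution.
    By default the whole stack is aligned once and the repeats resample
    the aligned images; realign=True re-runs the alignment on every draw
    (with a fixed reference both give identical rows image-by-image, so
    the flag only trades runtime).
    """
    n_list = list(n_list)
    if max(n_list) > len(stack):
        raise ValueError(f"max(n_list)={max(n_list)} exceeds stack size {len(stack)}")
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    if params is None:
        params = align_stack(stack, ref, p, aligner=aligner)
    if realign:
        # contractual mode: re-align each drawn subset from scratch
        ids_all = params.selected_ids()
        means, sds, limfrac = [], [], []
        for n in n_list:
            vals, flags = [], []
            for _ in range(repeats):
                pick = rng.choice(len(ids_all), size=n, replace=False)
                sub = ImageStack(
                    stack.data[pick], stack.pixel_size, [stack.ids[i] for i in pick]
                )
                sub_params = align_stack(sub, ref, p, aligner=aligner)
                res, flag = _halfset_resolution(
                    sub, sub_params, sub_params.selected_ids(), p.symmetry, oversample, rng
                )
                vals.append(res)
                flags.append(flag)
            means.append(np.mean(vals))
            sds.append(np.std(vals, ddof=1) if repeats > 1 else 0.0)
            limfrac.append(np.mean(flags))
        return ResolutionCurve(
            np.asarray(n_list), np.asarray(means), np.asarray(sds),
            repeats, arm_label, np.asarray(limfrac),
        )
    return _curve_from_alignment(
        stack, params, n_list, repeats, p.symmetry, oversample, rng, arm_label
    )


def noise_baseline(
    ref: Volume,
    n_list,
    repeats: int,
    image_stats,
    p: AlignmentParams,
    rng: np.random.Generator,
    oversample: int = 2,
    pool_size: int | None = None,
    model: str = "white",
    aligner: Aligner | None = None,
) -> ResolutionCurve:
    """Resolution-vs-N for freshly generated pure-noise images.

    image_stats is a (mean, variance) pair or a reference ImageStack
    (required for the spectrum-matched mode). The noise pool is aligned
    to the reference with exactly the same parameters as the particle arm.
    """
    n_list = list(n_list)
    pool = pool_size if pool_size is not None else max(n_list)
    spec = NoiseSpec(1.0, model=model)
    noise = make_noise_stack(
        pool, ref.box, ref.pixel_size, reference_stats=image_stats, spec=spec, rng=rng
    )
    params = align_stack(noise, ref, p, aligner=aligner)
    return _curve_from_alignment(
        noise, params, n_list, repeats, p.symmetry, oversample, rng, "noise"
    )


def compare_curves(
    particle: ResolutionCurve, noise: ResolutionCurve, k: float = 2.0, q: float = 0.5
) -> Verdict:
    """Margin-based verdict: is the particle arm distinguishable from noise?

    Per N the margin is noise mean minus particle mean (Å; positive =
    particle better) and the pooled SD is sqrt((sd_p^2 + sd_n^2) / 2).
    Distinguishable iff margin > k * pooled SD at a fraction >= q of the
    N points.
    """
    if not np.array_equal(particle.n_images, noise.n_images):
        raise ValueError("particle and noise curves must share the same n_list")
    margins = noise.mean_res - particle.mean_res
    pooled = np.sqrt((particle.sd_res**2 + noise.sd_res**2) / 2.0)
    beating = margins > k * pooled
    fraction = float(np.mean(beating))
    decision = "distinguishable" if fraction >= q else "indistinguishable"
    return Verdict(
        decision=decision,
        n_list=particle.n_images.copy(),
        margins=margins,
        pooled_sd=pooled,
        fraction_beating=fraction,
        k=k,
        q=q,
    )


def resolution_limited_check(
    stack: ImageStack,
    ref: Volume,
    limit: float,
    n_list,
    repeats: int,
    p: AlignmentParams,
    rng: np.random.Generator,
    oversample: int = 2,
) -> ResolutionLimitedResult:
    """Align with a high-resolution limit; look for information beyond it.

    The alignment scoring band is capped at `limit` (Å) while the
    reconstruction and FSC are unrestricted. Alignable images recover
    signal beyond the limit; aligned noise shows a sharp FSC drop at the
    limit instead. The flag is set when the FSC_0.5 frequency at the
    largest N exceeds the limit frequency.
    """
    if limit <= 2.0 * ref.pixel_size:
        raise ValueError("limit must be coarser than Nyquist")
    p_lim = AlignmentParams(
        angular_step=p.angular_step,
        inplane_step=p.inplane_step,
        max_shift=p.max_shift,
        lo_res=p.lo_res,
        hi_res=limit,
        symmetry=p.symmetry,
    )
    params = align_stack(stack, ref, p_lim)
    n_list = list(n_list)
    curve = _curve_from_alignment(
        stack, params, n_list, repeats, p.symmetry, oversample, rng, "limited"
    )
    # half-set FSC at the largest N for the drop-off diagnostics
    ids_all = params.selected_ids()
    pick = rng.choice(len(ids_all), size=max(n_list), replace=False)
    ids = ids_all[pick]
    perm = rng.permutation(len(ids))
    half = len(ids) // 2
    v1 = reconstruct(stack, params, p.symmetry, oversample, ids=ids[perm[:half]])
    v2 = reconstruct(stack, params, p.symmetry, oversample, ids=ids[perm[half:]])
    fsc_big = fsc_curve(v1, v2)
    mean_at_max = curve.mean_res[-1]
    beyond = bool(1.0 / mean_at_max > 1.0 / limit)
    return ResolutionLimitedResult(
        curve=curve, beyond_limit=beyond, limit=limit, fsc_at_max_n=fsc_big
    )


# ---------------------------------------------------------------------------
# SNR -> alignment-error study
# ---------------------------------------------------------------------------

def error_study(
    v: Volume,
    snr_list,
    n: int,
    p: AlignmentParams,
    rng: np.random.Generator,
    aligner: Aligner | None = None,
) -> list[ErrorSummary]:
    """Mean alignment errors against ground truth per imposed SNR."""
    if n < 10:
        raise ValueError("need at least 10 images per SNR point")
    aligner = Aligner(v, p) if aligner is None else aligner
    group = symmetry_operators(p.symmetry)
    out = []
    for snr in snr_list:
        stack, gt = make_dataset(v, n, NoiseSpec(snr), rng=rng)
        params = align_stack(stack, v, p, aligner=aligner)
        verrs, ierrs, serrs = [], [], []
        for img_id in stack.ids:
            t = gt.row_for(img_id)
            e = params.row_for(img_id)
            truth = Orientation.from_euler(t.phi, t.theta, t.psi, (t.dx, t.dy))
            est = Orientation.from_euler(e.phi, e.theta, e.psi, (e.dx, e.dy))
            ve, ie, se = orientation_errors(truth, est, group)
            verrs.append(ve)
            ierrs.append(ie)
            serrs.append(se)
        out.append(
            ErrorSummary(
                snr=float(snr),
                mean_view_error=float(np.mean(verrs)),
                mean_inplane_error=float(np.mean(ierrs)),
                mean_shift_error=float(np.mean(serrs)),
                n_images=n,
            )
        )
    return out


def snr_threshold(
    summaries: list[ErrorSummary],
    which: str = "view",
    threshold: float = 1.0,
) -> float:
    """SNR at which the mean error crosses a tolerance.

    Log-linear interpolation: the error is treated as linear in log(SNR)
    between the two adjacent measured SNRs bracketing the threshold.
    """
    attr = {
        "view": "mean_view_error",
        "inplane": "mean_inplane_error",
        "shift": "mean_shift_error",
    }
    if which not in attr:
        raise ValueError(f"which must be one of {sorted(attr)}")
    pts = sorted(summaries, key=lambda s: s.snr)
    if len(pts) < 2:
        raise ValueError("need at least 2 SNR points")
    errs = np.array([getattr(s, attr[which]) for s in pts])
    snrs = np.array([s.snr for s in pts])
    for i in range(1, len(pts)):
        e0, e1 = errs[i - 1], errs[i]
        if (e0 - threshold) * (e1 - threshold) <= 0 and e0 != e1:
            x0, x1 = np.log10(snrs[i - 1]), np.log10(snrs[i])
            t = (e0 - threshold) / (e0 - e1)
            return float(10 ** (x0 + t * (x1 - x0)))
    raise ValueError(
        f"threshold {threshold} not bracketed: errors span "
        f"[{errs.min():.4g}, {errs.max():.4g}] over SNR [{snrs.min():g}, {snrs.max():g}]"
    )


# ---------------------------------------------------------------------------
# Background windows
# ---------------------------------------------------------------------------

def extract_background_windows(
    micrograph: np.ndarray,
    particle_centers,
    box: int,
    n: int,
    rng: np.random.Generator,
    max_attempts: int = 10_000,
) -> ImageStack:
    """n background windows avoiding all particle boxes.

    A window is accepted when it lies fully inside the micrograph and its
    centre is at least `box` pixels (in both axes) from every particle
    centre, so the boxes cannot overlap. Rejection sampling with an
    attempt cap.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    h, w = micrograph.shape
    if h < box or w < box:
        raise ValueError("micrograph smaller than the window box")
    centers = np.atleast_2d(np.asarray(particle_centers, dtype=float)) if len(
        np.atleast_1d(particle_centers)
    ) else np.zeros((0, 2))
    half = box / 2.0
    out = np.empty((n, box, box), dtype=np.float32)
    got = 0
    for _ in range(max_attempts):
        if got == n:
            break
        cx = rng.uniform(half, w - half)
        cy = rng.uniform(half, h - half)
        if len(centers):
            dx = np.abs(centers[:, 0] - cx)
            dy = np.abs(centers[:, 1] - cy)
            if np.any((dx < box) & (dy < box)):
                continue
        x0 = int(round(cx - half))
        y0 = int(round(cy - half))
        x0 = min(max(x0, 0), w - box)
        y0 = min(max(y0, 0), h - box)
        out[got] = micrograph[y0 : y0 + box, x0 : x0 + box]
        got += 1
    if got < n:
        raise RuntimeError(
            f"could only place {got} of {n} background windows in {max_attempts} attempts"
        )
    return ImageStack(out, pixel_size=1.0)
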