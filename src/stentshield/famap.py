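"""Double-angle flip-angle mapping, T1 fitting and protocol adaptation.

The double-angle method (DAM) maps the transmit field through the local flip
angle: two spoiled gradient-echo (FLASH) magnitude images are acquired with
nominal flip angles ``alpha`` and ``2 alpha``, and their ratio

    I1/I2 = 1 / (2 cos(alpha)) * (1 - cos(2 alpha) E1) / (1 - cos(alpha) E1)

with ``E1 = exp(-TR/T1)`` is inverted per pixel by a monotone lookup table on
``alpha in (0, 90)`` degrees.  Comparing the apparent flip-angle map against
a background map acquired without the implant gives the shielding map:

    full (both components shielded):     beta = 1 - alpha / alpha_BG
    single-component (orthogonal loop):  beta = 1 - (2 alpha - alpha_BG) / alpha_BG

Known shielding feeds back into the protocol: scaling the prescribed flip
angle by ``1/(1 - beta)`` restores the intraluminal excitation, and scaling
the number of averages by ``1/(1 - beta)^2`` additionally restores the SNR
lost to the reciprocally shielded receive field.

A synthetic image-pair generator (Rician noise on FLASH steady-state
magnitudes) provides end-to-end recovery fixtures standing in for scanner
data.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.optimize import curve_fit

from .geometry import SpecError
from .inductance import NumericalError

#: saturation-recovery times used by the reference protocol (ms)
DEFAULT_TI_MS = (55, 70, 100, 125, 150, 175, 200, 250, 350, 500, 1000)


@dataclasses.dataclass
class ImagePairSet:
    """Two GRE magnitude images at nominal flip angles ``alpha`` and ``2 alpha``.

    ``alpha_bg_deg`` is the background flip-angle map acquired without the
    stent (same nominal angle as image 1).  ``mode`` selects the shielding
    map: ``"full"`` when both B1 components are shielded, ``"single"`` when
    only one component is (loop orthogonal to B0).
    """

    image1: np.ndarray
    image2: np.ndarray
    alpha1_deg: float
    alpha2_deg: float
    tr_ms: float
    t1_ms: float
    alpha_bg_deg: np.ndarray
    mode: str = "full"
    beta_truth: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.image1 = np.asarray(self.image1, dtype=float)
        self.image2 = np.asarray(self.image2, dtype=float)
        self.alpha_bg_deg = np.asarray(self.alpha_bg_deg, dtype=float)
        if self.image1.shape != self.image2.shape:
            raise SpecError("image pair must share one shape")
        if self.alpha_bg_deg.shape != self.image1.shape:
            raise SpecError("background flip-angle map must match the images")
        if not np.isclose(self.alpha2_deg, 2.0 * self.alpha1_deg):
            raise SpecError("double-angle pair requires alpha2 = 2 alpha1")
        if self.mode not in ("full", "single"):
            raise SpecError("mode must be 'full' or 'single'")
        if not 0.0 < self.e1 < 1.0:
            raise SpecError("TR and T1 must give 0 < E1 < 1")

    @property
    def e1(self) -> float:
        return float(np.exp(-self.tr_ms / self.t1_ms))


@dataclasses.dataclass
class SRSeries:
    """A saturation-recovery series ``A(t) = A0 (1 - exp(-t/T1))``."""

    times_ms: np.ndarray
    signal: np.ndarray
    t1_ms: float | None = None
    a0: float | None = None

    def __post_init__(self) -> None:
        self.times_ms = np.asarray(self.times_ms, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.times_ms.ndim != 1 or self.times_ms.shape != self.signal.shape:
            raise SpecError("times and signal must be matching 1-D arrays")
        if np.any(np.diff(self.times_ms) <= 0):
            raise SpecError("recovery times must be strictly increasing")


def flash_signal(alpha_deg, e1):
    """FLASH steady-state magnitude, ``sin(a) (1 - E1) / (1 - cos(a) E1)``."""
    a = np.deg2rad(np.asarray(alpha_deg, dtype=float))
    return np.sin(a) * (1.0 - e1) / (1.0 - np.cos(a) * e1)


def flash_ratio(alpha_deg, e1):
    """Signal ratio ``I1/I2`` of a double-angle FLASH pair.

    ``I1/I2 = 1/(2 cos a) * (1 - cos(2a) E1) / (1 - cos(a) E1)`` for nominal
    angle ``a`` (degrees).  Rejected at ``a >= 90`` where ``cos a`` vanishes.
    """
    a_arr = np.asarray(alpha_deg, dtype=float)
    if np.any(a_arr <= 0.0) or np.any(a_arr >= 90.0):
        raise SpecError("flash_ratio requires 0 < alpha < 90 degrees")
    a = np.deg2rad(a_arr)
    out = (
        (1.0 - np.cos(2.0 * a) * e1)
        / (1.0 - np.cos(a) * e1)
        / (2.0 * np.cos(a))
    )
    return float(out) if np.isscalar(alpha_deg) else out


class FlipAngleLUT:
    """Monotone lookup table inverting :func:`flash_ratio` for fixed ``E1``.

    The table spans ``alpha in (0, alpha_max)`` degrees at the given step;
    construction fails loudly if the ratio is not strictly monotone there
    (it is, for ``E1 in [0, 1)``).  Ratios outside the covered range --
    noise-dominated pixels -- are clamped to the nearest boundary and
    flagged in the returned quality mask; a ratio near 1/2 maps to
    ``alpha -> 0`` and hence a shielding near 1 downstream.
    """

    def __init__(
        self, e1: float, alpha_max_deg: float = 89.9, step_deg: float = 0.01
    ) -> None:
        if not 0.0 <= e1 < 1.0:
            raise SpecError("E1 must lie in [0, 1)")
        self.e1 = float(e1)
        self.alpha_deg = np.arange(step_deg, alpha_max_deg + step_deg / 2, step_deg)
        self.ratio = flash_ratio(self.alpha_deg, self.e1)
        if not np.all(np.diff(self.ratio) > 0):
            raise NumericalError(
                "flip-angle lookup relation is not injective for this E1"
            )
        self.step_deg = step_deg

    def invert(self, ratio) -> tuple[np.ndarray, np.ndarray]:
        """Map a ratio (map) to a flip-angle map and a validity mask."""
        r = np.asarray(ratio, dtype=float)
        valid = (r >= self.ratio[0]) & (r <= self.ratio[-1])
        alpha = np.interp(r, self.ratio, self.alpha_deg)
        alpha = np.where(r < self.ratio[0], self.alpha_deg[0], alpha)
        alpha = np.where(r > self.ratio[-1], self.alpha_deg[-1], alpha)
        return alpha, valid


def invert_ratio(ratio_map, e1: float) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel flip angles (degrees) from an ``I1/I2`` ratio map."""
    return FlipAngleLUT(e1).invert(ratio_map)


def fit_t1(series: SRSeries) -> SRSeries:
    """Mono-exponential saturation-recovery fit ``A(t) = A0 (1 - e^(-t/T1))``.

    Least squares over the series; needs at least four points spanning the
    recovery.  The fitted ``t1_ms`` and ``a0`` are stored on the series.
    """
    if len(series.times_ms) < 4:
        raise SpecError("T1 fit needs at least four recovery points")

    def model(t, a0, t1):
        return a0 * (1.0 - np.exp(-t / t1))

    a0_guess = float(series.signal.max())
    t1_guess = float(np.median(series.times_ms))
    try:
        popt, _ = curve_fit(
            model,
            series.times_ms,
            series.signal,
            p0=(a0_guess, t1_guess),
            maxfev=10000,
        )
    except RuntimeError as exc:  # pragma: no cover - pathological series
        raise NumericalError(f"T1 fit did not converge: {exc}") from exc
    a0, t1 = popt
    if t1 <= 0:
        raise NumericalError(f"T1 fit returned non-physical T1 = {t1:.3g} ms")
    series.a0 = float(a0)
    series.t1_ms = float(t1)
    return series


def beta_map_full(alpha_map, alpha_bg_map) -> np.ndarray:
    """Shielding map when both B1 components are shielded: ``1 - a/a_BG``.

    Pixels with non-positive background angle are set to NaN.
    """
    a = np.asarray(alpha_map, dtype=float)
    bg = np.asarray(alpha_bg_map, dtype=float)
    out = np.full(np.broadcast(a, bg).shape, np.nan)
    ok = bg > 0
    out[ok] = 1.0 - np.broadcast_to(a, out.shape)[ok] / np.broadcast_to(bg, out.shape)[ok]
    return out


def beta_map_single_component(alpha_map, alpha_bg_map) -> np.ndarray:
    """Shielding of one B1 component: ``1 - (2a - a_BG)/a_BG``.

    Applies when only one component is shielded (loop orthogonal to B0) and
    the background splits equally over both components,
    ``a_BG = 2 a_BG,x``.
    """
    a = np.asarray(alpha_map, dtype=float)
    bg = np.asarray(alpha_bg_map, dtype=float)
    out = np.full(np.broadcast(a, bg).shape, np.nan)
    ok = bg > 0
    aa = np.broadcast_to(a, out.shape)[ok]
    bb = np.broadcast_to(bg, out.shape)[ok]
    out[ok] = 1.0 - (2.0 * aa - bb) / bb
    return out


@dataclasses.dataclass(frozen=True)
class AdaptedProtocol:
    """Flip-angle and averaging adaptation restoring intraluminal signal."""

    beta: float
    fa_target_deg: float
    fa_adapted_deg: float
    fa_adapted_rounded_deg: int
    fa_factor: float
    averages_ref: int
    averages_factor: float
    averages_adapted: float
    snr_restoration_factor: float


def adapt_protocol(
    beta: float, fa_target_deg: float, averages_ref: int = 1
) -> AdaptedProtocol:
    """Compensate a known shielding ``beta`` in a GRE protocol.

    The prescribed flip angle is scaled by ``1/(1 - beta)`` so the
    intraluminal flip angle reaches the target, and the number of averages
    by ``1/(1 - beta)^2`` so the SNR (additionally reduced by the
    reciprocally shielded receive field) matches the stent-free reference.
    """
    if not 0.0 <= beta < 1.0:
        raise SpecError("adaptation requires 0 <= beta < 1")
    if fa_target_deg <= 0:
        raise SpecError("target flip angle must be positive")
    factor = 1.0 / (1.0 - beta)
    fa_adapted = factor * fa_target_deg
    return AdaptedProtocol(
        beta=beta,
        fa_target_deg=fa_target_deg,
        fa_adapted_deg=fa_adapted,
        fa_adapted_rounded_deg=int(round(fa_adapted)),
        fa_factor=factor,
        averages_ref=averages_ref,
        averages_factor=factor**2,
        averages_adapted=factor**2 * averages_ref,
        snr_restoration_factor=factor,
    )


def synthesize_image_pair(
    beta_truth,
    alpha_bg_deg,
    tr_ms: float = 200.0,
    t1_ms: float = 100.0,
    alpha1_deg: float = 40.6,
    noise_sigma: float = 0.0,
    signal_scale: float = 1000.0,
    shape: tuple[int, int] = (32, 32),
    seed: int | None = None,
    mode: str = "full",
    bg_shading: bool = False,
) -> ImagePairSet:
    """Simulate a double-angle GRE magnitude pair for a known shielding map.

    The per-pixel true flip angle is ``(1 - beta) * alpha_BG`` (and twice
    that for the second image); magnitudes follow the FLASH steady-state
    signal with Rician noise of absolute scale ``noise_sigma`` (Gaussian
    noise on both quadrature channels before magnitude).  ``beta_truth``
    and ``alpha_bg_deg`` may be scalars or maps; scalars are broadcast to
    ``shape``.  ``bg_shading`` superimposes a smooth quadratic dip on the
    background map, emulating coil shading.  Deterministic under a fixed
    seed.
    """
    beta_map = np.broadcast_to(
        np.asarray(beta_truth, dtype=float), shape
    ).copy() if np.ndim(beta_truth) == 0 else np.asarray(beta_truth, float)
    if np.ndim(alpha_bg_deg) == 0:
        bg = np.full(beta_map.shape, float(alpha_bg_deg))
    else:
        bg = np.asarray(alpha_bg_deg, dtype=float).copy()
    if bg.shape != beta_map.shape:
        raise SpecError("beta map and background map shapes differ")
    if bg_shading:
        ny, nx = bg.shape
        yy, xx = np.meshgrid(
            np.linspace(-1, 1, ny), np.linspace(-1, 1, nx), indexing="ij"
        )
        bg = bg * (1.0 - 0.1 * (xx**2 + yy**2))
    e1 = float(np.exp(-tr_ms / t1_ms))
    if mode == "single":
        # only one of the two equal background components is shielded
        alpha_true = (1.0 - beta_map / 2.0) * bg
    else:
        alpha_true = (1.0 - beta_map) * bg
    img1 = signal_scale * flash_signal(alpha_true, e1)
    img2 = signal_scale * flash_signal(2.0 * alpha_true, e1)
    if noise_sigma > 0.0:
        rng = np.random.default_rng(seed)
        img1 = np.hypot(
            img1 + rng.normal(0.0, noise_sigma, img1.shape),
            rng.normal(0.0, noise_sigma, img1.shape),
        )
        img2 = np.hypot(
            img2 + rng.normal(0.0, noise_sigma, img2.shape),
            rng.normal(0.0, noise_sigma, img2.shape),
        )
    return ImagePairSet(
        image1=img1,
        image2=img2,
        alpha1_deg=alpha1_deg,
        alpha2_deg=2.0 * alpha1_deg,
        tr_ms=tr_ms,
        t1_ms=t1_ms,
        alpha_bg_deg=bg,
        mode=mode,
        beta_truth=beta_map,
    )


def estimate_beta(pair: ImagePairSet) -> tuple[np.ndarray, np.ndarray]:
    """End-to-end DAM pipeline: ratio -> flip-angle map -> shielding map.

    Returns ``(beta_map, quality_mask)`` where the mask is True at pixels
    whose intensity ratio was invertible without clamping.
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = pair.image1 / pair.image2
    ratio[~np.isfinite(ratio)] = np.inf
    alpha, valid = invert_ratio(ratio, pair.e1)
    if pair.mode == "single":
        beta = beta_map_single_component(alpha, pair.alpha_bg_deg)
    else:
        beta = beta_map_full(alpha, pair.alpha_bg_deg)
    return beta, valid
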