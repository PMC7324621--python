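"""Contrast statistics of natural scenes: contrast energy (CE) and spatial coherence (SC).

The local-contrast distribution of a natural image is well described by a
two-parameter Weibull distribution.  Its scale parameter (beta) tracks the
average local contrast strength — contrast energy — while its shape parameter
(gamma) tracks how closely the distribution resembles a power law (sparse
scenes with a few salient edges, gamma < 1) or a Gaussian (cluttered textures,
gamma near 2) — spatial coherence.  Both indices are computed from a
multi-scale bank of non-oriented centre–surround contrast filters, emulating
the population response of LGN-like receptive fields.

Two routes to (CE, SC) are provided:

* ``route="weibull"`` (reference): pool local-contrast magnitudes across the
  scene and fit a Weibull by maximum likelihood; CE := beta-hat, SC :=
  gamma-hat.
* ``route="lgn"`` (approximation): CE := spatial mean of contrast magnitude;
  SC := shape proxy obtained by inverting the Weibull coefficient of
  variation, CV(gamma)^2 = Gamma(1 + 2/gamma) / Gamma(1 + 1/gamma)^2 - 1,
  at the empirical CV of the pooled magnitudes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, optimize, special

__all__ = [
    "ContrastMap",
    "WeibullParams",
    "SceneStats",
    "to_luminance",
    "compute_local_contrast",
    "fit_weibull",
    "weibull_shape_from_cv",
    "compute_scene_stats",
    "DEFAULT_SCALES",
]

#: Octave-spaced centre sigmas (px) of the default filter bank; the surround
#: sigma is always twice the centre sigma.
DEFAULT_SCALES: tuple[float, ...] = (1.0, 2.0, 4.0, 8.0, 16.0)

# Rec. 709 luma weights.
_LUMA_WEIGHTS = np.array([0.2126, 0.7152, 0.0722])


class FormatError(ValueError):
    """Raised for images with an unexpected layout."""


class ParameterError(ValueError):
    """Raised for invalid filter-bank or fit parameters."""


class DegenerateInputError(ValueError):
    """Raised when the input carries no usable contrast variation."""


@dataclass(frozen=True)
class WeibullParams:
    """Scale ``beta`` (contrast units) and shape ``gamma`` of a Weibull fit."""

    beta: float
    gamma: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.beta) and self.beta > 0):
            raise ParameterError(f"beta must be finite and > 0, got {self.beta}")
        if not (np.isfinite(self.gamma) and self.gamma > 0):
            raise ParameterError(f"gamma must be finite and > 0, got {self.gamma}")


@dataclass(frozen=True)
class SceneStats:
    """Per-image complexity indices: contrast energy and spatial coherence."""

    CE: float
    SC: float
    n_samples: int = 0
    n_zeros_dropped: int = 0
    route: str = "weibull"


@dataclass
class ContrastMap:
    """Per-scale planes of non-negative local-contrast magnitude.

    ``planes[i]`` has the spatial extent of the source image; ``border[i]``
    pixels on each side are excluded from pooling (one surround sigma, where
    filter support is incomplete).
    """

    planes: list[np.ndarray] = field(default_factory=list)
    scales: list[float] = field(default_factory=list)
    border: list[int] = field(default_factory=list)

    def pooled(self, policy: str = "finest") -> np.ndarray:
        """Pool magnitudes across space (and optionally scales) into a 1-D sample.

        ``policy="finest"`` pools the finest scale only; ``"max"`` takes the
        per-pixel maximum over scales (within the widest valid border).
        """
        if not self.planes:
            raise DegenerateInputError("empty contrast map")
        if policy == "finest":
            i = int(np.argmin(self.scales))
            b = self.border[i]
            return self.planes[i][b:-b or None, b:-b or None].ravel()
        if policy == "max":
            b = max(self.border)
            stack = np.stack([p[b:-b or None, b:-b or None] for p in self.planes])
            return stack.max(axis=0).ravel()
        raise ParameterError(f"unknown pooling policy {policy!r}")


def _validate_image(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise FormatError(f"expected a 2-D luminance image, got shape {image.shape}")
    if image.shape[0] < 32 or image.shape[1] < 32:
        raise FormatError(f"image too small: {image.shape}; need at least 32x32")
    if not np.all(np.isfinite(image)) or image.min() < 0 or image.max() > 1:
        raise FormatError("luminance values must be finite and in [0, 1]")
    return image


def to_luminance(rgb_image: np.ndarray) -> np.ndarray:
    """Convert an RGB image to a luminance plane in [0, 1].

    Accepts float images in [0, 1] or integer images in [0, 255]; grayscale
    input (2-D) is passed through after rescaling.
    """
    arr = np.asarray(rgb_image)
    if np.issubdtype(arr.dtype, np.integer):
        arr = arr.astype(float) / 255.0
    else:
        arr = arr.astype(float)
    if arr.ndim == 2:
        pass
    elif arr.ndim == 3 and arr.shape[2] == 3:
        arr = arr @ _LUMA_WEIGHTS
    elif arr.ndim == 3 and arr.shape[2] == 4:  # drop alpha
        arr = arr[..., :3] @ _LUMA_WEIGHTS
    else:
        raise FormatError(f"expected HxW or HxWx3 image, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)) or arr.min() < -1e-9 or arr.max() > 1 + 1e-9:
        raise FormatError("channel values must be in [0, 1] (float) or [0, 255] (int)")
    return np.clip(arr, 0.0, 1.0)


def compute_local_contrast(
    image: np.ndarray,
    scales: tuple[float, ...] = DEFAULT_SCALES,
    filter: str = "grad_dog",
    normalize: bool = False,
) -> ContrastMap:
    """Compute per-scale local contrast magnitude with centre–surround filters.

    Each scale applies a band-pass centre–surround operator with centre sigma
    ``s`` and surround sigma ``2 s``.  The default ``filter="grad_dog"``
    responds with the Euclidean modulus of the x/y pair of
    difference-of-Gaussian first-derivative filters; being the modulus of a
    zero-mean quadrature pair, it peaks at edges and yields Rayleigh-distributed
    magnitudes on white-noise input.  ``filter="dog"`` instead takes the
    absolute value of the isotropic (zeroth-order) difference of Gaussians.

    ``normalize=True`` divides each response by the local mean luminance
    (surround-scale Gaussian average, floored at 1 % of max luminance),
    giving a Weber-like contrast.
    """
    image = _validate_image(image)
    h, w = image.shape
    cmap = ContrastMap()
    for s in scales:
        s = float(s)
        if s <= 0 or s >= min(h, w) / 4:
            raise ParameterError(
                f"scale {s} invalid for image of shape {image.shape}: "
                f"must be in (0, {min(h, w) / 4})"
            )
        if filter == "grad_dog":
            gx = ndimage.gaussian_filter(image, s, order=(0, 1)) - ndimage.gaussian_filter(
                image, 2 * s, order=(0, 1)
            )
            gy = ndimage.gaussian_filter(image, s, order=(1, 0)) - ndimage.gaussian_filter(
                image, 2 * s, order=(1, 0)
            )
            resp = np.hypot(gx, gy)
        elif filter == "dog":
            resp = np.abs(
                ndimage.gaussian_filter(image, s) - ndimage.gaussian_filter(image, 2 * s)
            )
        else:
            raise ParameterError(f"unknown filter kind {filter!r}")
        if normalize:
            local_mean = ndimage.gaussian_filter(image, 2 * s)
            floor = max(0.01 * image.max(), 1e-6)
            resp = resp / np.maximum(local_mean, floor)
        cmap.planes.append(resp)
        cmap.scales.append(s)
        cmap.border.append(max(1, int(np.ceil(2 * s))))
    return cmap


def _profile_score(gamma: float, logx: np.ndarray, x: np.ndarray) -> float:
    # d/dgamma of the profile log-likelihood (beta profiled out in closed form)
    xg = np.exp(gamma * logx)
    return 1.0 / gamma + logx.mean() - float(np.sum(xg * logx) / np.sum(xg))


def fit_weibull(samples: np.ndarray, min_samples: int = 100) -> WeibullParams:
    """Maximum-likelihood two-parameter Weibull fit to non-negative samples.

    Exact zeros are dropped (the density lives on x > 0); the shape gamma is
    found by a bracketed root of the profile score with the scale beta given
    in closed form, ``beta = mean(x**gamma) ** (1/gamma)``.  Deterministic.
    """
    x = np.asarray(samples, dtype=float).ravel()
    if x.size and (not np.all(np.isfinite(x)) or x.min() < 0):
        raise ParameterError("samples must be finite and non-negative")
    x = x[x > 0]
    if x.size < min_samples:
        raise DegenerateInputError(
            f"need at least {min_samples} strictly positive samples, got {x.size}"
        )
    if np.ptp(x) == 0:
        raise DegenerateInputError("all samples identical; Weibull fit undefined")
    # work on x / geometric-mean scale for numerical stability of x**gamma
    logx = np.log(x)
    shift = logx.mean()
    logx = logx - shift
    lo, hi = 1e-2, 1.0
    while _profile_score(hi, logx, np.exp(logx)) > 0 and hi < 1e3:
        lo, hi = hi, hi * 2
    gamma = optimize.brentq(
        _profile_score, lo, hi, args=(logx, np.exp(logx)), xtol=1e-8, rtol=1e-12
    )
    beta = float(np.exp(shift) * np.mean(np.exp(gamma * logx)) ** (1.0 / gamma))
    return WeibullParams(beta=beta, gamma=float(gamma))


def weibull_shape_from_cv(cv: float) -> float:
    """Invert the Weibull coefficient of variation to a shape parameter.

    For Weibull(beta, gamma), CV depends on gamma only:
    ``CV^2 = Gamma(1 + 2/gamma) / Gamma(1 + 1/gamma)^2 - 1`` (monotone
    decreasing in gamma).  Used as the moment-based SC proxy of the
    approximation route.
    """
    if not np.isfinite(cv) or cv <= 0:
        raise DegenerateInputError(f"coefficient of variation must be > 0, got {cv}")

    def f(g: float) -> float:
        return special.gamma(1 + 2 / g) / special.gamma(1 + 1 / g) ** 2 - 1 - cv**2

    lo, hi = 0.05, 20.0
    if f(lo) < 0:  # CV larger than attainable at gamma=0.05
        return lo
    if f(hi) > 0:
        return hi
    return float(optimize.brentq(f, lo, hi, xtol=1e-10))


def compute_scene_stats(
    image: np.ndarray,
    scales: tuple[float, ...] = DEFAULT_SCALES,
    route: str = "weibull",
    scale_policy: str = "finest",
    filter: str = "grad_dog",
    normalize: bool = False,
) -> SceneStats:
    """Compute (CE, SC) for one luminance image.

    See the module docstring for the two routes.  The same pooled sample of
    contrast magnitudes feeds both; results are deterministic for a fixed
    image and configuration.
    """
    cmap = compute_local_contrast(image, scales=scales, filter=filter, normalize=normalize)
    pooled = cmap.pooled(scale_policy)
    n_total = pooled.size
    positive = pooled[pooled > 0]
    n_zeros = n_total - positive.size
    if route == "weibull":
        params = fit_weibull(positive)
        ce, sc = params.beta, params.gamma
    elif route == "lgn":
        if positive.size < 100:
            raise DegenerateInputError("not enough positive contrast samples")
        mean = float(positive.mean())
        std = float(positive.std(ddof=1))
        if std == 0:
            raise DegenerateInputError("zero contrast variance")
        ce = mean
        sc = weibull_shape_from_cv(std / mean)
    else:
        raise ParameterError(f"unknown route {route!r}")
    return SceneStats(CE=float(ce), SC=float(sc), n_samples=int(positive.size),
                      n_zeros_dropped=int(n_zeros), route=route)
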