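"""Camera calibration: linearisation, equalisation and ROI extraction.

Raw camera responses are nonlinear in light intensity. The workflow mirrors
standard reflectance photography practice: fit per-channel linearisation
curves from a set of grey reflectance standards of known nominal reflectance
(eight Spectralon standards spanning 2–99% in the emulated study design),
apply them to the raw planes, then equalise each photograph with a dark and a
light standard (8.5%/95% or 7%/93%) — a per-channel affine map that removes
lighting differences between shots. ROI means over equalised images are then
reflectance estimates through the camera's spectral bands.

Linearisation curves are polynomials in log–log space (log reflectance as a
polynomial in log pixel value), with the degree chosen by leave-one-out
cross-validation; a pure gamma response is exactly degree 1 in this space.
Saturated raw pixels (≥ 99% of bit depth) are flagged at linearisation time
and excluded from all ROI and standard-patch means.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import tifffile

logger = logging.getLogger(__name__)

__all__ = [
    "MultispectralImage",
    "StandardPatch",
    "LinearisationCurve",
    "fit_linearisation",
    "linearise",
    "equalise",
    "extract_roi",
    "write_multispectral_tiff",
    "read_multispectral_tiff",
]

SATURATION_FRACTION = 0.99


@dataclass(frozen=True)
class MultispectralImage:
    """Aligned per-channel pixel planes.

    ``data`` has shape (H, W, C); ``role`` is one of raw | linearised |
    equalised. ``saturated`` flags pixels at ≥ 99% of bit depth in the raw
    image; it is propagated through linearisation and equalisation.
    """

    data: np.ndarray
    channel_names: tuple[str, ...]
    bit_depth: int = 16
    role: str = "raw"
    pixel_scale_mm: float | None = None
    saturated: np.ndarray | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        arr = np.asarray(self.data, dtype=float)
        if arr.ndim != 3 or arr.shape[2] != len(self.channel_names):
            raise ValueError("data must be (H, W, C) with one name per channel")
        if np.any(arr < 0):
            raise ValueError("pixel values must be non-negative")
        if self.role not in ("raw", "linearised", "equalised"):
            raise ValueError(f"unknown role {self.role!r}")
        if self.role == "raw" and np.any(arr >= 2**self.bit_depth):
            raise ValueError("raw values exceed bit depth")
        object.__setattr__(self, "data", arr)
        object.__setattr__(self, "channel_names", tuple(self.channel_names))

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape[:2]

    def plane(self, name: str) -> np.ndarray:
        return self.data[..., self.channel_names.index(name)]


@dataclass(frozen=True)
class StandardPatch:
    """A grey reflectance standard: nominal reflectance fraction + ROI mask."""

    nominal_reflectance: float
    mask: np.ndarray

    def __post_init__(self) -> None:
        if not 0 < self.nominal_reflectance < 1:
            raise ValueError("nominal reflectance must be in (0, 1)")
        mask = np.asarray(self.mask, dtype=bool)
        if not mask.any():
            raise ValueError("standard patch mask is empty")
        object.__setattr__(self, "mask", mask)


@dataclass(frozen=True)
class LinearisationCurve:
    """Per-channel monotone pixel → reflectance mapping (log-space polynomial)."""

    coefficients: dict[str, np.ndarray]
    domains: dict[str, tuple[float, float]]
    degree: int

    def map_values(self, channel: str, pixels: np.ndarray) -> np.ndarray:
        lo, _ = self.domains[channel]
        x = np.log(np.maximum(np.asarray(pixels, dtype=float), lo * 1e-3))
        return np.exp(np.polyval(self.coefficients[channel], x))


def _loo_rmse(logx: np.ndarray, logy: np.ndarray, degree: int) -> float:
    errs = []
    idx = np.arange(logx.size)
    for i in idx:
        keep = idx != i
        coef = np.polyfit(logx[keep], logy[keep], degree)
        errs.append(np.polyval(coef, logx[i]) - logy[i])
    return float(np.sqrt(np.mean(np.square(errs))))


def fit_linearisation(
    samples: dict[str, list[tuple[float, float]]],
    max_degree: int = 3,
) -> LinearisationCurve:
    """Fit per-channel linearisation curves from standard measurements.

    ``samples`` maps channel name to (mean pixel value, nominal reflectance)
    pairs; at least 4 standards spanning the dynamic range are required.
    The degree (≤ ``max_degree``) minimising leave-one-out RMSE in log space
    is selected per fit; the fitted curve must reproduce each calibration
    sample within 2% absolute reflectance and be monotone over the sample
    hull.
    """
    coefficients: dict[str, np.ndarray] = {}
    domains: dict[str, tuple[float, float]] = {}
    chosen = 1
    for channel, pts in samples.items():
        if len(pts) < 4:
            raise ValueError(f"insufficient standards for channel {channel!r}: need ≥ 4, got {len(pts)}")
        pts = sorted(pts, key=lambda p: p[0])
        px = np.array([p[0] for p in pts], dtype=float)
        refl = np.array([p[1] for p in pts], dtype=float)
        if np.any(px <= 0) or np.any(refl <= 0):
            raise ValueError(f"channel {channel!r}: pixel values and nominals must be positive")
        drop = np.diff(refl) <= 0
        if drop.any():
            i = int(np.argmax(drop))
            raise ValueError(
                f"non-monotone standards in channel {channel!r}: "
                f"pixel {px[i]:g}→{px[i + 1]:g} but reflectance {refl[i]:g}→{refl[i + 1]:g}"
            )
        logx, logy = np.log(px), np.log(refl)
        best = min(
            range(1, min(max_degree, px.size - 2) + 1),
            key=lambda d: _loo_rmse(logx, logy, d),
        )
        coef = np.polyfit(logx, logy, best)
        fitted = np.exp(np.polyval(coef, logx))
        worst = float(np.max(np.abs(fitted - refl)))
        if worst > 0.02:
            raise ValueError(
                f"channel {channel!r}: linearisation residual {worst:.3f} exceeds 2% reflectance"
            )
        dense = np.linspace(logx[0], logx[-1], 256)
        if np.any(np.diff(np.polyval(coef, dense)) <= 0):
            raise ValueError(f"channel {channel!r}: fitted curve not monotone on sample hull")
        coefficients[channel] = coef
        domains[channel] = (float(px[0]), float(px[-1]))
        chosen = best
    return LinearisationCurve(coefficients=coefficients, domains=domains, degree=chosen)


def linearise(image: MultispectralImage, curve: LinearisationCurve) -> MultispectralImage:
    """Apply a linearisation curve to a raw image; flags saturated pixels."""
    if image.role != "raw":
        raise ValueError(f"expected a raw image, got role {image.role!r}")
    sat_level = SATURATION_FRACTION * (2**image.bit_depth - 1)
    saturated = np.any(image.data >= sat_level, axis=2)
    planes = [
        curve.map_values(name, image.data[..., i])
        for i, name in enumerate(image.channel_names)
    ]
    return replace(
        image,
        data=np.stack(planes, axis=2),
        role="linearised",
        saturated=saturated,
    )


def _patch_mean(image: MultispectralImage, mask: np.ndarray) -> np.ndarray:
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != image.shape:
        raise ValueError("mask shape does not match image")
    if image.saturated is not None:
        n_sat = int((mask & image.saturated).sum())
        if n_sat:
            logger.info("excluding %d saturated pixels from patch mean", n_sat)
        mask = mask & ~image.saturated
    if not mask.any():
        raise ValueError("empty mask (or fully saturated patch)")
    return image.data[mask].mean(axis=0)


def equalise(
    image: MultispectralImage,
    dark: StandardPatch,
    light: StandardPatch,
) -> MultispectralImage:
    """Affine-normalise a linearised image to its two grey standards.

    Per channel, the map sends the dark patch mean to its nominal reflectance
    and the light patch mean to its nominal; any linear relighting of the
    scene (gain and offset) therefore cancels exactly, and equalising an
    already-equalised image with its own standards is the identity.
    """
    if dark.nominal_reflectance >= light.nominal_reflectance:
        raise ValueError("dark standard must have lower nominal than light standard")
    mean_dark = _patch_mean(image, dark.mask)
    mean_light = _patch_mean(image, light.mask)
    span = mean_light - mean_dark
    if np.any(span <= 0):
        raise ValueError("degenerate standards: identical or inverted patch means")
    gain = (light.nominal_reflectance - dark.nominal_reflectance) / span
    out = (image.data - mean_dark) * gain + dark.nominal_reflectance
    return replace(image, data=np.clip(out, 0.0, None), role="equalised")


def extract_roi(image: MultispectralImage, mask: np.ndarray) -> tuple[dict[str, float], int]:
    """Per-channel mean reflectance over a ROI, plus the pixel count used.

    Saturated pixels are excluded; the count reflects the pixels actually
    averaged.
    """
    if image.role != "equalised":
        raise ValueError("extract_roi expects an equalised image")
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != image.shape:
        raise ValueError("mask shape does not match image (or lies outside it)")
    if not mask.any():
        raise ValueError("empty ROI mask")
    used = mask if image.saturated is None else (mask & ~image.saturated)
    if not used.any():
        raise ValueError("ROI fully saturated")
    means = image.data[used].mean(axis=0)
    return dict(zip(image.channel_names, means)), int(used.sum())


def write_multispectral_tiff(path, image: MultispectralImage) -> None:
    """Write planes as a 32-bit float TIFF stack with a JSON sidecar."""
    tifffile.imwrite(
        path,
        np.moveaxis(image.data, 2, 0).astype(np.float32),
        photometric="minisblack",
    )
    meta = {
        "channel_names": list(image.channel_names),
        "bit_depth": image.bit_depth,
        "role": image.role,
        "pixel_scale_mm": image.pixel_scale_mm,
    }
    with open(str(path) + ".json", "w") as fh:
        json.dump(meta, fh, indent=1)


def read_multispectral_tiff(path) -> MultispectralImage:
    data = np.moveaxis(tifffile.imread(path).astype(float), 0, 2)
    with open(str(path) + ".json") as fh:
        meta = json.load(fh)
    return MultispectralImage(
        data=data,
        channel_names=tuple(meta["channel_names"]),
        bit_depth=int(meta["bit_depth"]),
        role=meta["role"],
        pixel_scale_mm=meta.get("pixel_scale_mm"),
    )
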