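"""Fish visual systems and cone quantum catches.

The two shipped receivers are the dichromatic pollack (single cones at 436 nm,
double-cone members at 521 nm, abundance ratio 0.70:1) and the trichromatic
two-spotted goby (456/531/553 nm, ratios 0.72:1:0.60), each with a 50% ocular
transmission cutoff at 410 nm and a reference noise-to-signal ratio ν = 0.05
on the most abundant cone class. Each double-cone member is an independent
channel.

Receptor sensitivities are built from the Govardovskii A1 visual-pigment
nomogram (alpha plus beta band) parameterised only by the peak wavelength,
multiplied by a logistic ocular-media transmission curve. Quantum catches are
von Kries normalised — divided by the catch of the illuminant itself — so a
flat reflectance c yields a catch of c in every channel under any illuminant,
and discriminability depends on reflectance contrast rather than illuminant
scale.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import yaml

from .spectra import DEFAULT_GRID, Spectrum, resample, d65 as _d65

__all__ = [
    "ReceptorChannel",
    "VisualSystem",
    "ConeCatchRecord",
    "pigment_sensitivity",
    "ocular_transmission",
    "cone_catch",
    "weber_fractions",
    "pollack",
    "goby",
]


@dataclass(frozen=True)
class ReceptorChannel:
    """One cone class: label, peak wavelength, relative abundance η."""

    name: str
    lambda_max_nm: float
    relative_abundance: float

    def __post_init__(self) -> None:
        if self.relative_abundance <= 0:
            raise ValueError(f"channel {self.name}: abundance must be positive")


@dataclass(frozen=True)
class VisualSystem:
    """An ordered set of receptor channels plus ocular media and noise level.

    Channels are ordered shortest to longest peak wavelength. Abundances are
    normalised so the most abundant channel has η = 1; the reference channel's
    Weber fraction is then exactly ν and the others ν/√η.
    """

    name: str
    channels: tuple[ReceptorChannel, ...]
    ocular_cutoff_nm: float = 410.0
    nu: float = 0.05
    grid: np.ndarray = field(default_factory=lambda: DEFAULT_GRID.copy(), compare=False)

    def __post_init__(self) -> None:
        if not 2 <= len(self.channels) <= 3:
            raise ValueError("visual systems with 2 or 3 channels are supported")
        peaks = [c.lambda_max_nm for c in self.channels]
        if not all(a < b for a, b in zip(peaks, peaks[1:])):
            raise ValueError("channel peak wavelengths must be strictly increasing")
        if self.nu <= 0:
            raise ValueError("nu must be positive")
        top = max(c.relative_abundance for c in self.channels)
        normed = tuple(
            ReceptorChannel(c.name, c.lambda_max_nm, c.relative_abundance / top)
            for c in self.channels
        )
        object.__setattr__(self, "channels", normed)

    @property
    def channel_names(self) -> tuple[str, ...]:
        return tuple(c.name for c in self.channels)

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    def sensitivities(self) -> list[Spectrum]:
        """Per-channel spectral sensitivity including ocular transmission."""
        trans = ocular_transmission(self.ocular_cutoff_nm, self.grid)
        out = []
        for ch in self.channels:
            pig = pigment_sensitivity(ch.lambda_max_nm, self.grid)
            out.append(Spectrum(self.grid, pig.values * trans.values, name=ch.name))
        return out

    @classmethod
    def from_yaml(cls, path) -> "VisualSystem":
        with open(path) as fh:
            cfg = yaml.safe_load(fh)
        return cls.from_config(cfg)

    @classmethod
    def from_config(cls, cfg: Mapping) -> "VisualSystem":
        channels = tuple(
            ReceptorChannel(c["name"], float(c["lambda_max_nm"]), float(c["relative_abundance"]))
            for c in cfg["channels"]
        )
        return cls(
            name=str(cfg["name"]),
            channels=channels,
            ocular_cutoff_nm=float(cfg.get("ocular_cutoff_nm", 410.0)),
            nu=float(cfg.get("nu", 0.05)),
        )


def _packaged_system(fname: str) -> VisualSystem:
    ref = importlib.resources.files("prawnvision.data") / fname
    with importlib.resources.as_file(ref) as p:
        return VisualSystem.from_yaml(p)


def pollack() -> VisualSystem:
    """The dichromatic pollack system (436/521 nm, ratio 0.70:1)."""
    return _packaged_system("pollack.yaml")


def goby() -> VisualSystem:
    """The trichromatic two-spotted goby system (456/531/553 nm, 0.72:1:0.60)."""
    return _packaged_system("goby.yaml")


@dataclass(frozen=True)
class ConeCatchRecord:
    """Normalised quantum catches of one subject in one visual system.

    Catches must be strictly positive so log-ratio receptor contrasts are
    defined. ``metadata`` carries colour_type, day, substrate, size_mm, etc.
    """

    subject_id: str
    channels: tuple[str, ...]
    catches: np.ndarray
    system: str = ""
    metadata: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        q = np.asarray(self.catches, dtype=float)
        if q.ndim != 1 or q.size != len(self.channels):
            raise ValueError("one catch per channel required")
        if not np.all(np.isfinite(q)) or np.any(q <= 0):
            raise ValueError("catches must be finite and strictly positive")
        object.__setattr__(self, "catches", q)
        object.__setattr__(self, "channels", tuple(self.channels))


# Govardovskii A1 alpha-band constants.
_A, _B, _C, _D = 69.7, 28.0, -14.9, 0.674
_b, _c = 0.922, 1.104


def _govardovskii_a1(lambda_max: float, wl: np.ndarray) -> np.ndarray:
    """A1 visual-pigment absorbance template (alpha + beta band), peak 1."""
    x = lambda_max / wl
    a = 0.8795 + 0.0459 * np.exp(-((lambda_max - 300.0) ** 2) / 11940.0)
    alpha = 1.0 / (
        np.exp(_A * (a - x)) + np.exp(_B * (_b - x)) + np.exp(_C * (_c - x)) + _D
    )
    # beta band: small Gaussian absorbance bump in the near-UV
    lam_beta = 189.0 + 0.315 * lambda_max
    b_beta = -40.5 + 0.195 * lambda_max
    beta = 0.26 * np.exp(-(((wl - lam_beta) / b_beta) ** 2))
    s = alpha + beta
    return s / s.max()


def pigment_sensitivity(lambda_max_nm: float, grid: np.ndarray | None = None) -> Spectrum:
    """Visual-pigment sensitivity curve for a given peak wavelength.

    Uses the A1 nomogram; the curve is unimodal over the working grid with its
    maximum at ``lambda_max_nm`` (±1 nm) and peak value exactly 1.
    """
    grid = DEFAULT_GRID if grid is None else np.asarray(grid, dtype=float)
    if not grid[0] <= lambda_max_nm <= grid[-1]:
        raise ValueError(
            f"lambda_max {lambda_max_nm:g} nm outside grid [{grid[0]:g}, {grid[-1]:g}]"
        )
    return Spectrum(grid, _govardovskii_a1(float(lambda_max_nm), grid), name=f"pigment_{lambda_max_nm:g}")


def ocular_transmission(cutoff_nm: float, grid: np.ndarray | None = None,
                        width_10_90_nm: float = 30.0) -> Spectrum:
    """Ocular-media transmission: logistic with 50% point at ``cutoff_nm``.

    The slope is set by the 10–90% rise width (default 30 nm); transmission
    tends to 1 at long wavelengths.
    """
    grid = DEFAULT_GRID if grid is None else np.asarray(grid, dtype=float)
    if not grid[0] <= cutoff_nm <= grid[-1]:
        raise ValueError(f"cutoff {cutoff_nm:g} nm outside grid")
    scale = width_10_90_nm / (2.0 * np.log(9.0))
    vals = 1.0 / (1.0 + np.exp(-(grid - cutoff_nm) / scale))
    return Spectrum(grid, vals, name="ocular_transmission")


def cone_catch(
    reflectance: Spectrum,
    illuminant: Spectrum | None = None,
    system: VisualSystem | None = None,
    subject_id: str = "",
    metadata: dict | None = None,
) -> ConeCatchRecord:
    """Von Kries-normalised quantum catches of a reflectance spectrum.

    For each channel i,

        q_i = ∫ R(λ) I(λ) T(λ) S_i(λ) dλ / ∫ I(λ) T(λ) S_i(λ) dλ,

    with R the reflectance, I the illuminant (default D65), T the ocular
    transmission and S_i the pigment sensitivity; trapezoid-rule integrals on
    the system grid. Flat reflectance c therefore maps to q_i = c in every
    channel regardless of the illuminant.
    """
    if system is None:
        raise ValueError("a VisualSystem is required")
    grid = system.grid
    illuminant = _d65(grid) if illuminant is None else resample(illuminant, grid)
    refl = resample(reflectance, grid)
    trans = ocular_transmission(system.ocular_cutoff_nm, grid)
    catches = np.empty(system.n_channels)
    for i, ch in enumerate(system.channels):
        sens = _govardovskii_a1(ch.lambda_max_nm, grid)
        weight = illuminant.values * trans.values * sens
        denom = np.trapezoid(weight, grid)
        num = np.trapezoid(refl.values * weight, grid)
        if num <= 0:
            raise ValueError(f"degenerate catch in channel {ch.name}")
        catches[i] = num / denom
    return ConeCatchRecord(
        subject_id=subject_id,
        channels=system.channel_names,
        catches=catches,
        system=system.name,
        metadata=metadata or {},
    )


def weber_fractions(system: VisualSystem) -> np.ndarray:
    """Per-channel Weber fractions ω_i = ν / √η_i.

    Abundances are already normalised so the most abundant channel has η = 1
    and therefore ω = ν exactly.
    """
    eta = np.array([c.relative_abundance for c in system.channels])
    return system.nu / np.sqrt(eta)
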