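"""Hue channels and the principal colour axis.

Hue is a catch-ratio colour channel: SWS/LWS for a dichromat and
SWS/(MWS+LWS) for a trichromat — a short- versus medium/long-wave opponent
ratio. A PCA on z-scored cone catches (covariance of standardised data)
identifies the main axis of colour variation; for green↔red prawn variation
the leading axis loads the short-wave channel opposite the medium+long
channels, which motivates the opponent hue ratio.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .visual_systems import ConeCatchRecord

__all__ = ["HueValue", "hue_dichromat", "hue_trichromat", "hue", "PCAColourAxis", "pca_colour_axis"]


@dataclass(frozen=True)
class HueValue:
    value: float
    definition: str  # "dichromat" | "trichromat"

    def __post_init__(self) -> None:
        if not np.isfinite(self.value) or self.value <= 0:
            raise ValueError("hue must be finite and positive")


def hue_dichromat(rec: ConeCatchRecord) -> HueValue:
    """Short/long catch ratio q_S / q_L for a two-channel record."""
    if len(rec.channels) != 2:
        raise ValueError("dichromat hue needs exactly two channels")
    return HueValue(float(rec.catches[0] / rec.catches[1]), "dichromat")


def hue_trichromat(rec: ConeCatchRecord) -> HueValue:
    """Opponent ratio q_S / (q_M + q_L) for a three-channel record."""
    if len(rec.channels) != 3:
        raise ValueError("trichromat hue needs exactly three channels")
    return HueValue(float(rec.catches[0] / (rec.catches[1] + rec.catches[2])), "trichromat")


def hue(rec: ConeCatchRecord) -> HueValue:
    """Dispatch on channel count (channels are ordered short → long)."""
    return hue_dichromat(rec) if len(rec.channels) == 2 else hue_trichromat(rec)


@dataclass(frozen=True)
class PCAColourAxis:
    """Loadings (rows = components) and variance fractions of catch-space PCA."""

    loadings: np.ndarray
    variance_fractions: np.ndarray
    channels: tuple[str, ...]


def pca_colour_axis(records: list[ConeCatchRecord]) -> PCAColourAxis:
    """PCA of the covariance of z-scored cone catches.

    Components are unit-norm rows sorted by decreasing explained variance;
    each component's sign is fixed so its short-wave loading is ≥ 0.
    """
    if len(records) < 3:
        raise ValueError("need at least 3 records")
    channels = records[0].channels
    if any(r.channels != channels for r in records):
        raise ValueError("records have mismatched channel sets")
    X = np.vstack([r.catches for r in records])
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        zero = channels[int(np.argmax(sd == 0))]
        raise ValueError(f"zero-variance channel {zero!r}")
    Z = (X - X.mean(axis=0)) / sd
    cov = np.cov(Z, rowvar=False)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    loadings = evecs.T
    flip = loadings[:, 0] < 0
    loadings[flip] *= -1.0
    fractions = evals / evals.sum()
    return PCAColourAxis(loadings=loadings, variance_fractions=fractions, channels=channels)
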