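"""Camera → cone-catch polynomial mapping.

A camera sees the world through its own spectral bands, not a fish's. Given
the camera's band sensitivities and a library of training reflectance
spectra, each cone catch is regressed on polynomial terms (default degree 2
with interactions) of the camera band catches; the fitted mapping then
converts camera-space ROI measurements into predicted predator cone catches.
Mapping quality is reported as held-out R² per cone channel — in-sample fit
is not the diagnostic.

The shipped default camera has Gaussian band sensitivities peaking near
460/530/600 nm (σ 35 nm), a plausible stand-in for a visible-band converted
DSLR; real measured curves can be supplied via CSV.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.preprocessing import PolynomialFeatures

from .spectra import DEFAULT_GRID, Spectrum, resample, d65 as _d65
from .visual_systems import ConeCatchRecord, VisualSystem, cone_catch

logger = logging.getLogger(__name__)

__all__ = ["CameraModel", "PolyMapping", "default_camera", "camera_catches", "fit_mapping", "apply_mapping"]

#: Predictions at or below zero are clamped here so log-ratios stay defined.
CATCH_FLOOR = 1e-4


@dataclass(frozen=True)
class CameraModel:
    """Per-band camera spectral sensitivities on the working grid."""

    bands: tuple[Spectrum, ...]

    def __post_init__(self) -> None:
        if not self.bands:
            raise ValueError("camera needs at least one band")
        for b in self.bands:
            if b.values.max() <= 0:
                raise ValueError(f"band {b.name!r} is identically zero")

    @property
    def band_names(self) -> tuple[str, ...]:
        return tuple(b.name for b in self.bands)


def default_camera(grid: np.ndarray | None = None) -> CameraModel:
    """Gaussian visible bands at 460/530/600 nm, σ 35 nm (visR/visG/visB order short→long)."""
    grid = DEFAULT_GRID if grid is None else np.asarray(grid, dtype=float)
    bands = []
    for name, peak in (("visB", 460.0), ("visG", 530.0), ("visR", 600.0)):
        vals = np.exp(-((grid - peak) ** 2) / (2 * 35.0**2))
        bands.append(Spectrum(grid, vals, name=name))
    return CameraModel(bands=tuple(bands))


def camera_catches(
    reflectance: Spectrum,
    camera: CameraModel,
    illuminant: Spectrum | None = None,
) -> np.ndarray:
    """Illuminant-normalised band catches: ∫R·I·B / ∫I·B per band (trapezoid).

    Flat reflectance c yields c in every band, so equalised-image ROI means
    are directly comparable to these catches.
    """
    grid = camera.bands[0].wavelengths_nm
    illum = _d65(grid) if illuminant is None else resample(illuminant, grid)
    refl = resample(reflectance, grid)
    out = np.empty(len(camera.bands))
    for j, band in enumerate(camera.bands):
        weight = illum.values * band.values
        out[j] = np.trapezoid(refl.values * weight, grid) / np.trapezoid(weight, grid)
    return out


@dataclass(frozen=True)
class PolyMapping:
    """Fitted polynomial camera→cone transform plus training diagnostics."""

    coefficients: np.ndarray  # (n_terms, n_cones)
    degree: int
    band_names: tuple[str, ...]
    cone_names: tuple[str, ...]
    system: str
    r2_holdout: dict[str, float] = field(default_factory=dict)

    def _design(self, X: np.ndarray) -> np.ndarray:
        feats = PolynomialFeatures(degree=self.degree, include_bias=True)
        return feats.fit_transform(X)

    def predict(self, camera_catch_rows: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(camera_catch_rows, dtype=float))
        if X.shape[1] != len(self.band_names):
            raise ValueError(
                f"expected {len(self.band_names)} camera bands, got {X.shape[1]}"
            )
        if np.any(X <= 0):
            raise ValueError("camera catches must be positive")
        pred = self._design(X) @ self.coefficients
        n_clamped = int((pred <= 0).sum())
        if n_clamped:
            logger.warning("clamped %d non-positive predicted catches to %g", n_clamped, CATCH_FLOOR)
        return np.maximum(pred, CATCH_FLOOR)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "coefficients": self.coefficients.tolist(),
                    "degree": self.degree,
                    "band_names": list(self.band_names),
                    "cone_names": list(self.cone_names),
                    "system": self.system,
                    "r2_holdout": self.r2_holdout,
                },
                fh,
                indent=1,
            )

    @classmethod
    def from_json(cls, path) -> "PolyMapping":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            coefficients=np.asarray(d["coefficients"], dtype=float),
            degree=int(d["degree"]),
            band_names=tuple(d["band_names"]),
            cone_names=tuple(d["cone_names"]),
            system=d["system"],
            r2_holdout=d["r2_holdout"],
        )


def fit_mapping(
    camera: CameraModel,
    system: VisualSystem,
    training_reflectances: list[Spectrum],
    illuminant: Spectrum | None = None,
    degree: int = 2,
    holdout_fraction: float = 0.25,
    seed: int = 0,
) -> PolyMapping:
    """Least-squares fit of cone catches on polynomial camera-catch terms.

    Requires ≥ 50 training spectra spanning the gamut of interest. A random
    held-out fraction provides the reported per-channel R²; the final
    coefficients are refit on all spectra.
    """
    if len(training_reflectances) < 50:
        raise ValueError(f"need ≥ 50 training spectra, got {len(training_reflectances)}")
    X = np.vstack([camera_catches(r, camera, illuminant) for r in training_reflectances])
    Y = np.vstack(
        [cone_catch(r, illuminant, system).catches for r in training_reflectances]
    )
    feats = PolynomialFeatures(degree=degree, include_bias=True)
    D = feats.fit_transform(X)
    if np.linalg.matrix_rank(D) < D.shape[1]:
        if degree > 1:
            raise ValueError(
                f"rank-deficient design for degree {degree}; try a lower degree or richer training spectra"
            )
        # degree-1 deficiency (e.g. flat-grey-only training): the min-norm
        # least-squares solution is still exact on the training manifold
        logger.warning("rank-deficient degree-1 design; using minimum-norm solution")

    rng = np.random.default_rng(seed)
    n = len(training_reflectances)
    n_hold = max(1, int(round(holdout_fraction * n)))
    hold = np.zeros(n, dtype=bool)
    hold[rng.choice(n, size=n_hold, replace=False)] = True

    coef_train, *_ = np.linalg.lstsq(D[~hold], Y[~hold], rcond=None)
    pred = D[hold] @ coef_train
    resid = Y[hold] - pred
    ss_res = np.sum(resid**2, axis=0)
    ss_tot = np.sum((Y[hold] - Y[hold].mean(axis=0)) ** 2, axis=0)
    r2 = 1.0 - ss_res / ss_tot

    coef_full, *_ = np.linalg.lstsq(D, Y, rcond=None)
    return PolyMapping(
        coefficients=coef_full,
        degree=degree,
        band_names=camera.band_names,
        cone_names=system.channel_names,
        system=system.name,
        r2_holdout=dict(zip(system.channel_names, map(float, r2))),
    )


def apply_mapping(
    mapping: PolyMapping,
    camera_catch_rows: np.ndarray,
    subject_ids: list[str] | None = None,
    metadata: list[dict] | None = None,
) -> list[ConeCatchRecord]:
    """Convert camera catches to predicted cone-catch records.

    Non-positive predictions are clamped to a small positive floor (with a
    logged warning) so downstream log-ratios remain defined.
    """
    pred = mapping.predict(camera_catch_rows)
    records = []
    for i, row in enumerate(pred):
        records.append(
            ConeCatchRecord(
                subject_id=subject_ids[i] if subject_ids else f"subject_{i}",
                channels=mapping.cone_names,
                catches=row,
                system=mapping.system,
                metadata=metadata[i] if metadata else {},
            )
        )
    return records
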