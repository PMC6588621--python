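"""Synthetic study inputs with known ground truth.

Everything the analysis pipeline consumes can be generated here: reflectance
spectra for green and red prawns and their seaweed substrates (sea lettuce
and dulse), 7-timepoint colour-change trajectories over 30 days with
front-loaded change and size-dependent kinetics, rendered raw multispectral
fixtures standing in for the photography chamber, and Y-maze behavioural
choice trials. All generators are deterministic under a seed and always emit
their ground truth alongside the data.

Spectral families
-----------------
Green coloration is modelled as a Gaussian reflectance peak (default 550 nm,
σ 40 nm); red coloration as a long-pass sigmoid edge (default 590 nm, width
20 nm) over a slightly higher short-wave baseline. Mixing the two families in
reflectance space reproduces the qualitative short-wave crossover seen when
green and red animals converge on each other's coloration: red spectra carry
more short-wave baseline than green ones, so hue (short/long catch ratio)
rises as a green animal reddens and falls as a red one greens.

Colour-change kinetics
----------------------
An individual's reflectance on day d is the mixture
(1−m)·start + m·target with m(d) = m_max·(1 − exp(−k·d)); exponential
approach encodes change that is fastest in the first 10 days. The rate is
coupled multiplicatively to body size, k_i = k·exp(−β·(size_i − size_ref)),
so larger individuals change more slowly. Dropout hazards per 5-day interval
default to (0, 0, 0.05, 0.06, 0.15, 0.25): survival is complete through day
10 and falls to roughly 57% by day 30.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .calibration import MultispectralImage
from .cone_mapping import CameraModel, camera_catches, default_camera
from .spectra import DEFAULT_GRID, Spectrum, d65 as _d65

__all__ = [
    "SpectrumModel",
    "ColourChangeSchedule",
    "ColourChangeRun",
    "RenderedFixture",
    "green_prawn_model",
    "red_prawn_model",
    "sea_lettuce_model",
    "dulse_model",
    "sample_reflectance",
    "sample_spectrum_library",
    "simulate_colour_change",
    "render_fixture",
    "simulate_choice_trials",
]


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


@dataclass(frozen=True)
class SpectrumModel:
    """Parametric reflectance family: green peak, red long-pass edge, or flat.

    ``peak_jitter_nm``, ``amplitude_jitter_rel`` and ``baseline_jitter_rel``
    control between-individual variation when sampling; ``noise_sd`` is
    pointwise measurement noise added to each sampled spectrum.
    """

    kind: str  # green_peak | red_longpass | flat
    peak_nm: float = 550.0
    width_nm: float = 40.0
    amplitude: float = 0.35
    baseline: float = 0.05
    edge_nm: float = 590.0
    noise_sd: float = 0.005
    peak_jitter_nm: float = 6.0
    amplitude_jitter_rel: float = 0.10
    baseline_jitter_rel: float = 0.10

    def __post_init__(self) -> None:
        if self.kind not in ("green_peak", "red_longpass", "flat"):
            raise ValueError(f"unknown spectrum kind {self.kind!r}")
        if self.amplitude + self.baseline > 1.0:
            raise ValueError("amplitude + baseline exceeds 1 (reflectance bound)")
        if self.baseline < 0 or self.amplitude < 0:
            raise ValueError("amplitude and baseline must be non-negative")

    def evaluate(self, grid: np.ndarray) -> np.ndarray:
        """Noise-free mean reflectance of the family on ``grid``."""
        if self.kind == "flat":
            return np.full(grid.shape, self.baseline)
        if self.kind == "green_peak":
            bump = np.exp(-((grid - self.peak_nm) ** 2) / (2 * self.width_nm**2))
        else:  # red_longpass
            bump = 1.0 / (1.0 + np.exp(-(grid - self.edge_nm) / self.width_nm))
        return self.baseline + self.amplitude * bump


def green_prawn_model() -> SpectrumModel:
    """Green prawn: Gaussian peak near 545 nm over a low short-wave baseline."""
    return SpectrumModel(kind="green_peak", peak_nm=545.0, width_nm=36.0,
                         amplitude=0.32, baseline=0.04)


def red_prawn_model() -> SpectrumModel:
    """Red prawn: long-pass edge near 588 nm over a higher short-wave baseline.

    The higher baseline gives red coloration the larger short-wave reflectance
    of the two types, so green↔red convergence produces the short-wave
    crossover the mixture construction is built around.
    """
    return SpectrumModel(kind="red_longpass", edge_nm=588.0, width_nm=20.0,
                         amplitude=0.42, baseline=0.14)


def sea_lettuce_model() -> SpectrumModel:
    """Sea lettuce (Ulva lactuca): green peak near 555 nm."""
    return SpectrumModel(kind="green_peak", peak_nm=555.0, width_nm=34.0,
                         amplitude=0.28, baseline=0.035,
                         peak_jitter_nm=4.0, amplitude_jitter_rel=0.08,
                         baseline_jitter_rel=0.08)


def dulse_model() -> SpectrumModel:
    """Dulse (Palmaria palmata): long-pass edge near 600 nm."""
    return SpectrumModel(kind="red_longpass", edge_nm=600.0, width_nm=18.0,
                         amplitude=0.36, baseline=0.12,
                         peak_jitter_nm=4.0, amplitude_jitter_rel=0.08,
                         baseline_jitter_rel=0.08)


def _jittered(model: SpectrumModel, rng: np.random.Generator) -> SpectrumModel:
    amp = model.amplitude * (1.0 + rng.normal(0.0, model.amplitude_jitter_rel))
    base = model.baseline * (1.0 + rng.normal(0.0, model.baseline_jitter_rel))
    amp = float(np.clip(amp, 0.0, 1.0))
    base = float(np.clip(base, 1e-3, 1.0 - amp))
    shift = rng.normal(0.0, model.peak_jitter_nm)
    return replace(
        model,
        amplitude=amp,
        baseline=base,
        peak_nm=model.peak_nm + shift,
        edge_nm=model.edge_nm + shift,
    )


def sample_reflectance(
    model: SpectrumModel,
    rng_seed,
    grid: np.ndarray | None = None,
    jitter: bool = True,
    name: str = "",
) -> Spectrum:
    """Draw one reflectance spectrum from the family, clipped to [0, 1]."""
    rng = _rng(rng_seed)
    grid = DEFAULT_GRID if grid is None else np.asarray(grid, dtype=float)
    m = _jittered(model, rng) if jitter else model
    vals = m.evaluate(grid)
    if model.noise_sd > 0:
        vals = vals + rng.normal(0.0, model.noise_sd, size=grid.shape)
    return Spectrum(grid, np.clip(vals, 0.0, 1.0), name=name)


def sample_spectrum_library(n: int, rng_seed, grid: np.ndarray | None = None) -> list[Spectrum]:
    """A diverse natural-spectra library for fitting camera→cone mappings.

    Mixes Gaussian peaks with random position/width, long-pass edges, flat
    greys, and green↔red prawn mixtures, spanning the gamut the pipeline
    operates in.
    """
    rng = _rng(rng_seed)
    grid = DEFAULT_GRID if grid is None else np.asarray(grid, dtype=float)
    green, red = green_prawn_model(), red_prawn_model()
    out: list[Spectrum] = []
    for i in range(n):
        u = rng.uniform()
        if u < 0.30:
            base = rng.uniform(0.02, 0.25)
            m = SpectrumModel(kind="green_peak", peak_nm=rng.uniform(430, 650),
                              width_nm=rng.uniform(20, 80),
                              amplitude=rng.uniform(0.1, 1.0 - base),
                              baseline=base, noise_sd=0.0)
            vals = m.evaluate(grid)
        elif u < 0.60:
            base = rng.uniform(0.02, 0.2)
            m = SpectrumModel(kind="red_longpass", edge_nm=rng.uniform(480, 650),
                              width_nm=rng.uniform(8, 40),
                              amplitude=rng.uniform(0.15, 1.0 - base),
                              baseline=base, noise_sd=0.0)
            vals = m.evaluate(grid)
        elif u < 0.75:
            vals = np.full(grid.shape, rng.uniform(0.02, 0.9))
        else:
            w = rng.uniform()
            vals = (1 - w) * green.evaluate(grid) + w * red.evaluate(grid)
        out.append(Spectrum(grid, np.clip(vals, 0.0, 1.0), name=f"lib_{i}"))
    return out


@dataclass(frozen=True)
class ColourChangeSchedule:
    """Timing, kinetics and attrition of a 30-day colour-change experiment."""

    days: tuple[int, ...] = (0, 5, 10, 15, 20, 25, 30)
    k_per_day: float = 0.15
    m_max: float = 0.8
    beta_per_mm: float = 0.05
    size_mean_mm: float = 8.0
    size_sd_mm: float = 1.5
    dropout_hazard: tuple[float, ...] = (0.0, 0.0, 0.05, 0.06, 0.15, 0.25)

    def __post_init__(self) -> None:
        if list(self.days) != sorted(self.days) or self.days[0] != 0:
            raise ValueError("days must be sorted and start at 0")
        if self.k_per_day <= 0 or not 0 < self.m_max <= 1:
            raise ValueError("need k > 0 and 0 < m_max ≤ 1")
        if len(self.dropout_hazard) != len(self.days) - 1:
            raise ValueError("one dropout hazard per inter-day interval required")
        if any(not 0 <= h < 1 for h in self.dropout_hazard):
            raise ValueError("hazards must be in [0, 1)")

    def mixing(self, day: float, k: float | None = None) -> float:
        """Mixture weight m(day) = m_max·(1 − e^{−k·day})."""
        k = self.k_per_day if k is None else k
        return self.m_max * (1.0 - np.exp(-k * day))


@dataclass(frozen=True)
class ColourChangeRun:
    """Per-individual, per-day spectra plus full ground truth."""

    spectra: dict[tuple[str, int], Spectrum]
    truth: pd.DataFrame  # individual, day, m, size_mm, k, alive

    def individuals(self) -> list[str]:
        return sorted(self.truth["individual"].unique())


def simulate_colour_change(
    start: SpectrumModel,
    target: SpectrumModel,
    schedule: ColourChangeSchedule | None = None,
    n_individuals: int = 25,
    rng_seed=0,
    id_prefix: str = "prawn",
) -> ColourChangeRun:
    """Simulate individuals changing from one spectral family toward another.

    Each individual gets fixed jittered start and target spectra and a body
    size; its day-d reflectance is the mixture (1−m)·start + m·target with
    m following the schedule's exponential-approach kinetics at the
    size-adjusted rate, plus fresh measurement noise each day. Spectra are
    only emitted for days the individual survives to; the truth table flags
    survival explicitly.
    """
    if n_individuals < 1:
        raise ValueError("need at least one individual")
    schedule = schedule or ColourChangeSchedule()
    rng = _rng(rng_seed)
    grid = DEFAULT_GRID
    spectra: dict[tuple[str, int], Spectrum] = {}
    rows = []
    for i in range(n_individuals):
        ind = f"{id_prefix}_{i:03d}"
        size = float(rng.normal(schedule.size_mean_mm, schedule.size_sd_mm))
        k_i = schedule.k_per_day * float(
            np.exp(-schedule.beta_per_mm * (size - schedule.size_mean_mm))
        )
        start_vals = _jittered(start, rng).evaluate(grid)
        target_vals = _jittered(target, rng).evaluate(grid)
        alive = True
        for j, day in enumerate(schedule.days):
            if alive and j > 0 and rng.uniform() < schedule.dropout_hazard[j - 1]:
                alive = False
            m = float(schedule.mixing(day, k_i))
            rows.append(
                {"individual": ind, "day": day, "m": m, "size_mm": size,
                 "k": k_i, "alive": alive}
            )
            if alive:
                vals = (1.0 - m) * start_vals + m * target_vals
                if start.noise_sd > 0:
                    vals = vals + rng.normal(0.0, start.noise_sd, size=grid.shape)
                spectra[(ind, day)] = Spectrum(
                    grid, np.clip(vals, 0.0, 1.0), name=f"{ind}_d{day}"
                )
    return ColourChangeRun(spectra=spectra, truth=pd.DataFrame(rows))


@dataclass(frozen=True)
class RenderedFixture:
    """A raw rendered multispectral image plus everything needed to check it."""

    image: MultispectralImage
    masks: dict[str, np.ndarray]
    spectra: dict[str, Spectrum]
    linearisation_nominals: dict[str, float]
    dark_name: str
    light_name: str
    camera_truth: dict[str, np.ndarray]  # true reflectance band catches
    gamma: float


#: Eight grey linearisation standards spanning 2–99% reflectance.
LINEARISATION_NOMINALS = (0.02, 0.05, 0.10, 0.20, 0.40, 0.60, 0.80, 0.99)


def render_fixture(
    subjects: dict[str, Spectrum],
    camera: CameraModel | None = None,
    illuminant: Spectrum | None = None,
    dark_nominal: float = 0.085,
    light_nominal: float = 0.95,
    gamma: float = 2.2,
    noise_sd: float = 0.003,
    bit_depth: int = 14,
    gain: float = 0.9,
    patch_px: int = 24,
    rng_seed=0,
) -> RenderedFixture:
    """Render a photography-chamber fixture as a raw camera image.

    The scene is a tile grid: eight grey linearisation standards (2–99%), the
    dark and light equalisation standards (defaults 8.5%/95%), then the
    subject patches. Per-pixel values are the illuminant-normalised camera
    band catches of each patch spectrum, scaled by a lighting gain,
    gamma-encoded, perturbed with Gaussian sensor noise and quantised to the
    bit depth. Ground-truth spectra, masks and true band catches are
    returned; determinism under the seed is exact.
    """
    if not subjects:
        raise ValueError("no subject patches")
    if dark_nominal >= light_nominal:
        raise ValueError("standards' nominals must be distinct (dark < light)")
    camera = camera or default_camera()
    rng = _rng(rng_seed)
    grid = camera.bands[0].wavelengths_nm
    illuminant = _d65(grid) if illuminant is None else illuminant

    patches: list[tuple[str, np.ndarray]] = []
    lin_nominals: dict[str, float] = {}
    for nominal in LINEARISATION_NOMINALS:
        name = f"std_{nominal:.2f}"
        patches.append((name, np.full(len(camera.bands), nominal)))
        lin_nominals[name] = nominal
    dark_name, light_name = "std_dark", "std_light"
    patches.append((dark_name, np.full(len(camera.bands), dark_nominal)))
    patches.append((light_name, np.full(len(camera.bands), light_nominal)))

    camera_truth: dict[str, np.ndarray] = {}
    spectra: dict[str, Spectrum] = {}
    for name, spec in subjects.items():
        catch = camera_catches(spec, camera, illuminant)
        patches.append((name, catch))
        camera_truth[name] = catch
        spectra[name] = spec

    n_cols = 5
    n_rows = int(np.ceil(len(patches) / n_cols))
    H, W = n_rows * patch_px, n_cols * patch_px
    maxval = 2**bit_depth - 1
    data = np.zeros((H, W, len(camera.bands)))
    masks: dict[str, np.ndarray] = {}
    for idx, (name, catch) in enumerate(patches):
        r, c = divmod(idx, n_cols)
        sl = (slice(r * patch_px, (r + 1) * patch_px), slice(c * patch_px, (c + 1) * patch_px))
        mask = np.zeros((H, W), dtype=bool)
        mask[sl] = True
        masks[name] = mask
        encoded = np.power(gain * catch, 1.0 / gamma)
        tile = encoded[None, None, :] + rng.normal(0.0, noise_sd, size=(patch_px, patch_px, len(catch)))
        data[sl] = np.clip(tile, 0.0, 1.0)
    raw = np.round(data * maxval)
    image = MultispectralImage(
        data=raw, channel_names=camera.band_names, bit_depth=bit_depth, role="raw"
    )
    return RenderedFixture(
        image=image,
        masks=masks,
        spectra=spectra,
        linearisation_nominals=lin_nominals,
        dark_name=dark_name,
        light_name=light_name,
        camera_truth=camera_truth,
        gamma=gamma,
    )


def simulate_choice_trials(
    n_trials_per_type: int = 90,
    p_choice_made: float = 0.44,
    p_match_given_choice: float = 0.8,
    rng_seed=0,
) -> pd.DataFrame:
    """Y-maze substrate choice trials for both prawn colour types.

    Each trial either ends with no choice (probability 1 − p_choice_made) or
    a substrate choice that matches the prawn's own colour with probability
    ``p_match_given_choice``. Defaults emulate a 79-of-180 decision rate and
    a strong (0.8) matching preference. Columns: colour_type, outcome
    (sea_lettuce | dulse | no_choice), duration_s.
    """
    for p in (p_choice_made, p_match_given_choice):
        if not 0.0 <= p <= 1.0:
            raise ValueError("probabilities must be in [0, 1]")
    rng = _rng(rng_seed)
    rows = []
    matching = {"green": "sea_lettuce", "red": "dulse"}
    other = {"green": "dulse", "red": "sea_lettuce"}
    for colour in ("green", "red"):
        for _ in range(n_trials_per_type):
            if rng.uniform() >= p_choice_made:
                rows.append({"colour_type": colour, "outcome": "no_choice",
                             "duration_s": 600.0})
                continue
            chose_match = rng.uniform() < p_match_given_choice
            rows.append(
                {
                    "colour_type": colour,
                    "outcome": matching[colour] if chose_match else other[colour],
                    "duration_s": float(rng.uniform(10.0, 600.0)),
                }
            )
    return pd.DataFrame(rows)
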