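"""End-to-end orchestration of the three analyses.

Three entry points mirror the study structure:

``run_field_camouflage``
    Green and red prawns against sea-lettuce and dulse backgrounds: cone
    catches for both fish systems, random one-to-one prawn–background
    pairing, JNDs and mean ± SE per (colour type × substrate × system).

``run_colour_change``
    Each colour type switched to the mismatched seaweed for 30 days
    (photograph days 0, 5, …, 30): per-day hue (dichromat and trichromat
    definitions) and per-day JND against the new background pool, survivors
    only.

``run_choice_analysis``
    Y-maze substrate choices with per-type exact binomial tests.

Cone catches can be computed directly from spectra (``route="spectral"``) or
through the camera + fitted polynomial mapping (``route="camera"``), the
route the photographic workflow uses. Every output table carries the package
version and a hash of the configuration; reruns with the same config are
identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .colour_metrics import hue
from .cone_mapping import apply_mapping, camera_catches, default_camera, fit_mapping
from .discrimination import jnd, jnd_table
from .spectra import Spectrum
from .stats import group_summary, summarise_choices
from .synthetic import (
    ColourChangeSchedule,
    dulse_model,
    green_prawn_model,
    red_prawn_model,
    sample_reflectance,
    sample_spectrum_library,
    sea_lettuce_model,
    simulate_choice_trials,
    simulate_colour_change,
)
from .visual_systems import ConeCatchRecord, VisualSystem, cone_catch, goby, pollack

__all__ = ["RunConfig", "run_field_camouflage", "run_colour_change", "run_choice_analysis", "run_all"]


@dataclass(frozen=True)
class RunConfig:
    """Reproducible settings for the synthetic end-to-end analyses."""

    seed: int = 0
    n_prawns_field: int = 64
    n_backgrounds_field: int = 64
    n_individuals_change: int = 25
    n_backgrounds_change: int = 26
    n_trials_per_type: int = 90
    p_choice_made: float = 0.44
    p_match_given_choice: float = 0.8
    route: str = "spectral"  # spectral | camera
    mapping_degree: int = 2
    n_training_spectra: int = 200
    pairing_mode: str = "fixed"  # fixed | per_day (colour-change pairing)

    def __post_init__(self) -> None:
        if self.route not in ("spectral", "camera"):
            raise ValueError(f"unknown route {self.route!r}")
        if self.pairing_mode not in ("fixed", "per_day"):
            raise ValueError(f"unknown pairing mode {self.pairing_mode!r}")

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:10]


def _systems() -> list[VisualSystem]:
    return [pollack(), goby()]


def _stamp(df: pd.DataFrame, config: RunConfig) -> pd.DataFrame:
    df = df.copy()
    df["package_version"] = __version__
    df["config_hash"] = config.config_hash()
    return df


class _CatchComputer:
    """Spectrum → ConeCatchRecord via the configured route."""

    def __init__(self, config: RunConfig):
        self.route = config.route
        if self.route == "camera":
            self.camera = default_camera()
            library = sample_spectrum_library(
                config.n_training_spectra, np.random.default_rng(config.seed + 77)
            )
            self.mappings = {
                sys.name: fit_mapping(self.camera, sys, library,
                                      degree=config.mapping_degree, seed=config.seed)
                for sys in _systems()
            }

    def __call__(self, spec: Spectrum, system: VisualSystem,
                 subject_id: str, metadata: dict) -> ConeCatchRecord:
        if self.route == "spectral":
            return cone_catch(spec, None, system, subject_id=subject_id, metadata=metadata)
        row = camera_catches(spec, self.camera)
        return apply_mapping(self.mappings[system.name], row[None, :],
                             subject_ids=[subject_id], metadata=[metadata])[0]


def run_field_camouflage(config: RunConfig | None = None) -> dict[str, pd.DataFrame]:
    """Field camouflage: JNDs of both prawn types against both seaweeds.

    Each prawn is paired with one randomly drawn background from each
    seaweed pool, for each visual system, mirroring a 64-prawn /
    64-image-pool comparison design. Returns the tidy per-pairing ``jnd``
    table and a mean ± SE ``summary`` per (colour type × substrate × system).
    """
    config = config or RunConfig()
    rng = np.random.default_rng(config.seed)
    compute = _CatchComputer(config)

    prawn_specs = {
        "green": [sample_reflectance(green_prawn_model(), rng, name=f"green_{i:03d}")
                  for i in range(config.n_prawns_field)],
        "red": [sample_reflectance(red_prawn_model(), rng, name=f"red_{i:03d}")
                for i in range(config.n_prawns_field)],
    }
    background_specs = {
        "sea_lettuce": [sample_reflectance(sea_lettuce_model(), rng, name=f"sl_{i:03d}")
                        for i in range(config.n_backgrounds_field)],
        "dulse": [sample_reflectance(dulse_model(), rng, name=f"du_{i:03d}")
                  for i in range(config.n_backgrounds_field)],
    }

    tables = []
    for system in _systems():
        records = {
            colour: [compute(s, system, s.name, {"colour_type": colour})
                     for s in specs]
            for colour, specs in prawn_specs.items()
        }
        pools = {
            substrate: [compute(s, system, s.name, {"substrate": substrate})
                        for s in specs]
            for substrate, specs in background_specs.items()
        }
        for colour, subs in records.items():
            for substrate, pool in pools.items():
                t = jnd_table(subs, pool, system, pairing="random",
                              seed=int(rng.integers(2**31)))
                t["substrate"] = substrate
                tables.append(t)
    jnds = pd.concat(tables, ignore_index=True)
    summary = group_summary(jnds, "delta_s", ["colour_type", "substrate", "system"])
    return {"jnd": _stamp(jnds, config), "summary": _stamp(summary, config)}


def run_colour_change(config: RunConfig | None = None) -> dict[str, pd.DataFrame]:
    """Colour change on mismatched seaweed: hue and JND trajectories.

    Green prawns are moved onto dulse (changing toward red coloration), red
    prawns onto sea lettuce. Per day and visual system the pipeline reports
    hue (SWS/LWS or SWS/(MWS+LWS)) and the JND to the new background,
    survivors only. With ``pairing_mode="fixed"`` each individual keeps one
    randomly assigned background across days; ``"per_day"`` redraws daily.
    """
    config = config or RunConfig()
    rng = np.random.default_rng(config.seed)
    compute = _CatchComputer(config)
    schedule = ColourChangeSchedule()

    arms = {
        "green": (green_prawn_model(), red_prawn_model(), dulse_model()),
        "red": (red_prawn_model(), green_prawn_model(), sea_lettuce_model()),
    }

    hue_rows, jnd_rows = [], []
    for colour, (start, target, new_background) in arms.items():
        run = simulate_colour_change(
            start, target, schedule,
            n_individuals=config.n_individuals_change,
            rng_seed=np.random.default_rng(int(rng.integers(2**31))),
            id_prefix=colour,
        )
        pool_specs = [
            sample_reflectance(new_background, rng, name=f"{colour}_bg_{i:03d}")
            for i in range(config.n_backgrounds_change)
        ]
        for system in _systems():
            pool = [cc for cc in (compute(s, system, s.name, {}) for s in pool_specs)]
            fixed_partner = {
                ind: int(rng.integers(len(pool))) for ind in run.individuals()
            }
            for (ind, day), spec in run.spectra.items():
                meta = {"colour_type": colour, "day": day}
                rec = compute(spec, system, ind, meta)
                hue_rows.append(
                    {"individual": ind, "colour_type": colour, "day": day,
                     "system": system.name, "hue": hue(rec).value}
                )
                if config.pairing_mode == "fixed":
                    bg = pool[fixed_partner[ind]]
                else:
                    bg = pool[int(rng.integers(len(pool)))]
                jnd_rows.append(
                    {"individual": ind, "colour_type": colour, "day": day,
                     "system": system.name, "background_id": bg.subject_id,
                     "delta_s": jnd(rec, bg, system).delta_s}
                )

    hues = pd.DataFrame(hue_rows)
    jnds = pd.DataFrame(jnd_rows)
    return {
        "hue": _stamp(hues, config),
        "jnd": _stamp(jnds, config),
        "hue_summary": _stamp(
            group_summary(hues, "hue", ["colour_type", "day", "system"]), config
        ),
        "jnd_summary": _stamp(
            group_summary(jnds, "delta_s", ["colour_type", "day", "system"]), config
        ),
    }


def run_choice_analysis(config: RunConfig | None = None) -> dict[str, pd.DataFrame]:
    """Y-maze choice trials: per-type proportions and exact binomial tests."""
    config = config or RunConfig()
    trials = simulate_choice_trials(
        n_trials_per_type=config.n_trials_per_type,
        p_choice_made=config.p_choice_made,
        p_match_given_choice=config.p_match_given_choice,
        rng_seed=config.seed,
    )
    summary = summarise_choices(trials)
    overall = summary.attrs.copy()
    out = {"trials": _stamp(trials, config), "choice_summary": _stamp(summary, config)}
    out["choice_summary"].attrs.update(overall)
    return out


def run_all(config: RunConfig | None = None) -> dict[str, dict[str, pd.DataFrame]]:
    """All three analyses under one config."""
    config = config or RunConfig()
    return {
        "field": run_field_camouflage(config),
        "colour_change": run_colour_change(config),
        "choice": run_choice_analysis(config),
    }
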