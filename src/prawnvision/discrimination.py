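"""Receptor-noise-limited chromatic discrimination (JNDs).

Discriminability of two stimuli is the noise-weighted contrast of receptor
log signals (the Vorobyev–Osorio receptor-noise-limited model). With catches
q_i(a), q_i(b) and Weber fractions ω_i, the receptor contrasts are
Δf_i = ln(q_i(a)/q_i(b)) and

    dichromat:  ΔS = |Δf_1 − Δf_2| / sqrt(ω_1² + ω_2²)
    trichromat: ΔS = sqrt( [ω_1²(Δf_2−Δf_3)² + ω_2²(Δf_1−Δf_3)²
                            + ω_3²(Δf_1−Δf_2)²]
                           / [(ω_1ω_2)² + (ω_1ω_3)² + (ω_2ω_3)²] )

ΔS is in just-noticeable-difference (JND) units; values below 1 predict the
pair cannot be discriminated by the receiver.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd

from .visual_systems import ConeCatchRecord, VisualSystem, weber_fractions

__all__ = ["JNDResult", "jnd", "jnd_table", "DISCRIMINATION_THRESHOLD"]

#: JNDs above this threshold predict the receiver can discriminate the pair.
DISCRIMINATION_THRESHOLD = 1.0


@dataclass(frozen=True)
class JNDResult:
    delta_s: float
    system: str
    subject_id: str = ""
    background_id: str = ""

    @property
    def discriminable(self) -> bool:
        return self.delta_s > DISCRIMINATION_THRESHOLD


def _delta_s(df: np.ndarray, omega: np.ndarray) -> float:
    if df.size == 2:
        w1, w2 = omega
        return float(abs(df[0] - df[1]) / np.hypot(w1, w2))
    w1, w2, w3 = omega
    f1, f2, f3 = df
    num = (
        w1**2 * (f2 - f3) ** 2
        + w2**2 * (f1 - f3) ** 2
        + w3**2 * (f1 - f2) ** 2
    )
    den = (w1 * w2) ** 2 + (w1 * w3) ** 2 + (w2 * w3) ** 2
    return float(np.sqrt(num / den))


def jnd(a: ConeCatchRecord, b: ConeCatchRecord, system: VisualSystem) -> JNDResult:
    """Chromatic distance between two cone-catch records, in JND units.

    Symmetric in its arguments and invariant to a common scaling of both
    records (log-ratio receptor code).
    """
    if a.channels != b.channels:
        raise ValueError(f"channel sets differ: {a.channels} vs {b.channels}")
    if a.channels != system.channel_names:
        raise ValueError("records do not match the visual system's channels")
    df = np.log(a.catches / b.catches)
    omega = weber_fractions(system)
    return JNDResult(
        delta_s=_delta_s(df, omega),
        system=system.name,
        subject_id=a.subject_id,
        background_id=b.subject_id,
    )


def jnd_table(
    subjects: list[ConeCatchRecord],
    backgrounds: list[ConeCatchRecord],
    system: VisualSystem,
    pairing: str = "random",
    seed: int | None = None,
) -> pd.DataFrame:
    """JNDs between subjects and backgrounds, one row per pairing.

    ``pairing="random"`` draws one background per subject — without
    replacement when the pool is at least as large as the subject list, with
    replacement otherwise; a seed is required for reproducibility.
    ``pairing="all"`` computes the full cartesian product.
    """
    if not subjects:
        raise ValueError("empty subject list")
    if not backgrounds:
        raise ValueError("empty background pool")
    if pairing == "random":
        if seed is None:
            raise ValueError("random pairing requires a seed")
        rng = np.random.default_rng(seed)
        replace = len(backgrounds) < len(subjects)
        idx = rng.choice(len(backgrounds), size=len(subjects), replace=replace)
        pairs = [(s, backgrounds[i]) for s, i in zip(subjects, idx)]
    elif pairing == "all":
        pairs = list(product(subjects, backgrounds))
    else:
        raise ValueError(f"unknown pairing mode {pairing!r}")

    rows = []
    for subj, bg in pairs:
        res = jnd(subj, bg, system)
        rows.append(
            {
                "subject_id": subj.subject_id,
                "background_id": bg.subject_id,
                "system": system.name,
                "delta_s": res.delta_s,
                "discriminable": res.discriminable,
                **{k: v for k, v in subj.metadata.items()},
            }
        )
    return pd.DataFrame(rows)
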