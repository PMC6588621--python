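"""Self-contained statistics: exact binomial choice test and group summaries.

The behavioural choice analysis tests, separately per prawn colour type,
whether the proportion of choices for the colour-matching seaweed differs
from 0.5 using a two-sided exact binomial test. The two-sided p-value uses
the small-probability-mass convention (sum of all outcome probabilities no
larger than that of the observed count), matching R's ``binom.test``; exact
binomial two-sided definitions differ between packages, so the convention is
stated explicitly.

Group summaries report mean ± SE with SE = s/√n (sample standard deviation,
n−1 denominator), the form used for all trajectory figures.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

__all__ = ["BinomialTestResult", "exact_binomial_test", "summarise_choices", "group_summary"]

OUTCOMES = {"sea_lettuce", "dulse", "no_choice"}
MATCHING_SUBSTRATE = {"green": "sea_lettuce", "red": "dulse"}


@dataclass(frozen=True)
class BinomialTestResult:
    successes: int
    n: int
    proportion: float
    two_sided_p: float

    def __post_init__(self) -> None:
        if not 0 <= self.successes <= self.n:
            raise ValueError("successes must be between 0 and n")
        if not 0.0 <= self.two_sided_p <= 1.0:
            raise ValueError("p must be in [0, 1]")


def exact_binomial_test(successes: int, n: int, p0: float = 0.5) -> BinomialTestResult:
    """Two-sided exact binomial test of ``successes``/``n`` against ``p0``.

    p = Σ_k P(K = k) over all k with P(K = k) ≤ P(K = observed) under
    Binomial(n, p0) — the small-probability-mass two-sided convention.
    """
    if n < 1 or not 0 <= successes <= n:
        raise ValueError(f"invalid counts: successes={successes}, n={n}")
    p = sps.binomtest(successes, n, p0, alternative="two-sided").pvalue
    return BinomialTestResult(
        successes=int(successes), n=int(n),
        proportion=successes / n, two_sided_p=float(p),
    )


def summarise_choices(table: pd.DataFrame) -> pd.DataFrame:
    """Per-colour-type choice summary with exact binomial tests.

    A "matched" choice is the seaweed of the prawn's own coloration (green →
    sea lettuce, red → dulse). No-choice trials are excluded from each test's
    n but counted in the overall choice rate. Returns one row per colour type
    with columns n_trials, n_choices, matched, proportion, two_sided_p, plus
    the overall choice rate in ``attrs``.
    """
    if table.empty:
        raise ValueError("empty trial table")
    unknown = set(table["outcome"].unique()) - OUTCOMES
    if unknown:
        raise ValueError(f"unknown outcome labels: {sorted(unknown)}")
    decided = table[table["outcome"] != "no_choice"]
    if decided.empty:
        raise ValueError("no decisions to analyse (all trials were no-choice)")
    rows = []
    for colour, sub in table.groupby("colour_type"):
        choices = sub[sub["outcome"] != "no_choice"]
        if choices.empty:
            logger.warning("no decisions for colour type %s; skipped", colour)
            continue
        matched = int((choices["outcome"] == MATCHING_SUBSTRATE[colour]).sum())
        res = exact_binomial_test(matched, len(choices))
        rows.append(
            {
                "colour_type": colour,
                "n_trials": len(sub),
                "n_choices": len(choices),
                "matched": matched,
                "proportion": res.proportion,
                "two_sided_p": res.two_sided_p,
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["overall_choice_rate"] = len(decided) / len(table)
    out.attrs["n_decided"] = len(decided)
    out.attrs["n_trials"] = len(table)
    return out


def group_summary(
    df: pd.DataFrame,
    value: str,
    by: list[str] | str,
) -> pd.DataFrame:
    """Mean, SE and n of ``value`` per group. SE is NaN for single-value groups.

    Empty groups (all-NaN values) are dropped with a warning.
    """
    by = [by] if isinstance(by, str) else list(by)
    rows = []
    for keys, sub in df.groupby(by, dropna=False):
        vals = sub[value].dropna().to_numpy(dtype=float)
        if vals.size == 0:
            logger.warning("dropping empty group %s", keys)
            continue
        keys = keys if isinstance(keys, tuple) else (keys,)
        se = float(vals.std(ddof=1) / np.sqrt(vals.size)) if vals.size > 1 else np.nan
        rows.append(
            {**dict(zip(by, keys)), "mean": float(vals.mean()), "se": se, "n": int(vals.size)}
        )
    return pd.DataFrame(rows)
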