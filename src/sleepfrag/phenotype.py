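"""Social-interaction scoring and susceptible/resilient classification.

After chronic social defeat, mice are phenotyped in a two-trial social
interaction (SI) test: time spent in the interaction zone with a caged
social target versus without one. The SI score is the percent ratio
target/no-target; scores well below 100 indicate social avoidance
(susceptible), scores at or above 100 indicate approach (resilient).
A symmetric exclusion band of width ``threshold_pct`` around 100 removes
animals whose score is too close to 100 to call either way:

* ``score < 100 - threshold``      -> SUSCEPTIBLE
* ``score >= 100 + threshold``     -> RESILIENT
* otherwise                        -> EXCLUDED

The band boundaries are intentionally asymmetric (strict ``<`` below,
inclusive ``>=`` above), matching the convention in the chronic-social-
defeat literature; a score exactly at ``100 - threshold`` is EXCLUDED.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import pandas as pd

__all__ = ["SITrial", "PhenotypeLabel", "si_score", "classify_phenotype",
           "phenotype_table", "TRIAL_LENGTH_S", "DEFAULT_THRESHOLD_PCT"]

#: Length of each SI trial, seconds (2.5 min).
TRIAL_LENGTH_S = 150.0
#: Default half-width of the exclusion band around an SI score of 100.
DEFAULT_THRESHOLD_PCT = 1.0


class PhenotypeLabel(str, Enum):
    SUSCEPTIBLE = "SUSCEPTIBLE"
    RESILIENT = "RESILIENT"
    EXCLUDED = "EXCLUDED"


@dataclass(frozen=True)
class SITrial:
    """Interaction-zone occupancy for the two SI trials of one animal.

    Corner-zone time and travel distance are descriptive metadata only;
    no classification rule uses them.
    """

    time_target_s: float
    time_no_target_s: float
    corner_time_s: float | None = None
    distance: float | None = None

    def __post_init__(self) -> None:
        for name in ("time_target_s", "time_no_target_s"):
            t = getattr(self, name)
            if not (0.0 <= t <= TRIAL_LENGTH_S):
                raise ValueError(
                    f"{name}={t} outside [0, {TRIAL_LENGTH_S}] s trial"
                )


def si_score(trial: SITrial) -> float:
    """SI score: 100 x (interaction-zone time with target) /
    (interaction-zone time without target).

    Undefined when the no-target time is zero.
    """
    if trial.time_no_target_s <= 0:
        raise ValueError("SI score undefined: no-target time is zero")
    return 100.0 * trial.time_target_s / trial.time_no_target_s


def classify_phenotype(
    score: float, threshold_pct: float = DEFAULT_THRESHOLD_PCT
) -> PhenotypeLabel:
    """Map an SI score to SUSCEPTIBLE / RESILIENT / EXCLUDED."""
    if threshold_pct < 0:
        raise ValueError("threshold must be non-negative")
    if score < 0:
        raise ValueError("SI scores are non-negative")
    if score < 100.0 - threshold_pct:
        return PhenotypeLabel.SUSCEPTIBLE
    if score >= 100.0 + threshold_pct:
        return PhenotypeLabel.RESILIENT
    return PhenotypeLabel.EXCLUDED


def phenotype_table(
    si: pd.DataFrame, threshold_pct: float = DEFAULT_THRESHOLD_PCT
) -> pd.DataFrame:
    """Append ``si_score`` and ``phenotype`` columns to an SI table.

    Expects columns ``animal``, ``time_no_target_s``, ``time_target_s``.
    """
    required = {"animal", "time_no_target_s", "time_target_s"}
    missing = required - set(si.columns)
    if missing:
        raise ValueError(f"SI table missing columns: {sorted(missing)}")
    out = si.copy()
    scores = [
        si_score(SITrial(time_target_s=row.time_target_s,
                         time_no_target_s=row.time_no_target_s))
        for row in out.itertuples()
    ]
    out["si_score"] = scores
    out["phenotype"] = [classify_phenotype(s, threshold_pct).value for s in scores]
    return out
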