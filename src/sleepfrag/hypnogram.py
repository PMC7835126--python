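"""Core domain types: vigilance states, hypnograms, phase windows.

A hypnogram is a sequence of scored vigilance states (wake, NREM sleep,
REM sleep), one label per fixed-length epoch (5 s by default), anchored to
zeitgeber time (ZT): ZT 0 = lights on, ZT 12 = lights off, 12:12 cycle.
Artifact flags mark epochs whose EEG contains movement or electrical
artifacts; those epochs keep their scored state for all architecture
metrics and are excluded only from spectral averages.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

LIGHT_HOURS = 12.0
CYCLE_HOURS = 24.0


class VigilanceState(str, Enum):
    """The three scored vigilance states."""

    WAKE = "WAKE"
    NREM = "NREM"
    REM = "REM"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


STATES: tuple[VigilanceState, ...] = (
    VigilanceState.WAKE,
    VigilanceState.NREM,
    VigilanceState.REM,
)

#: Ordered state pairs reported as transition counts.
TRANSITION_PAIRS: tuple[tuple[VigilanceState, VigilanceState], ...] = (
    (VigilanceState.REM, VigilanceState.WAKE),
    (VigilanceState.WAKE, VigilanceState.NREM),
    (VigilanceState.NREM, VigilanceState.WAKE),
    (VigilanceState.NREM, VigilanceState.REM),
)


class Phase(str, Enum):
    LIGHT = "LIGHT"
    DARK = "DARK"


def _coerce_states(labels: Iterable) -> np.ndarray:
    arr = np.asarray(
        [VigilanceState(lab).value for lab in labels], dtype="U4"
    )
    return arr


@dataclass(frozen=True)
class Hypnogram:
    """Epoch-scored vigilance-state sequence anchored to zeitgeber time.

    Parameters
    ----------
    states : sequence of VigilanceState (or their string values)
        One label per epoch.
    artifact : boolean sequence, optional
        Per-epoch artifact flags (default: all clean). Artifact epochs
        retain their scored state for architecture metrics; spectral
        averages skip them.
    epoch_length_s : float
        Scoring window length in seconds (default 5).
    start_zt_h : float
        Zeitgeber time of the first epoch, in hours, in [0, 24).
    """

    states: np.ndarray
    artifact: np.ndarray = None  # type: ignore[assignment]
    epoch_length_s: float = 5.0
    start_zt_h: float = 0.0

    def __post_init__(self) -> None:
        states = _coerce_states(self.states)
        object.__setattr__(self, "states", states)
        if self.artifact is None:
            artifact = np.zeros(states.shape[0], dtype=bool)
        else:
            artifact = np.asarray(self.artifact, dtype=bool)
        object.__setattr__(self, "artifact", artifact)
        if artifact.shape[0] != states.shape[0]:
            raise ValueError(
                f"artifact mask length {artifact.shape[0]} != "
                f"number of epochs {states.shape[0]}"
            )
        if self.epoch_length_s <= 0:
            raise ValueError("epoch_length_s must be positive")
        if not (0.0 <= self.start_zt_h < CYCLE_HOURS):
            raise ValueError("start_zt_h must lie in [0, 24)")

    def __len__(self) -> int:
        return self.states.shape[0]

    @property
    def n_epochs(self) -> int:
        return self.states.shape[0]

    @property
    def epoch_length_h(self) -> float:
        return self.epoch_length_s / 3600.0

    @property
    def duration_h(self) -> float:
        """Total recorded time in hours."""
        return self.n_epochs * self.epoch_length_h

    @property
    def end_zt_h(self) -> float:
        """ZT hour just past the last epoch (non-wrapping axis)."""
        return self.start_zt_h + self.duration_h

    def epoch_zt_h(self) -> np.ndarray:
        """ZT hour of each epoch start, on a non-wrapping axis.

        For multi-day recordings values exceed 24; reduce modulo 24 to
        recover clock phase.
        """
        return self.start_zt_h + np.arange(self.n_epochs) * self.epoch_length_h

    def epoch_phase(self) -> np.ndarray:
        """LIGHT/DARK phase of each epoch (array of Phase values)."""
        clock = np.mod(self.epoch_zt_h(), CYCLE_HOURS)
        out = np.where(clock < LIGHT_HOURS, Phase.LIGHT.value, Phase.DARK.value)
        return out

    def state_mask(self, state: VigilanceState | str) -> np.ndarray:
        return self.states == VigilanceState(state).value


@dataclass(frozen=True)
class PhaseWindow:
    """Half-open window [start_zt_h, end_zt_h) on the non-wrapping ZT axis."""

    start_zt_h: float
    end_zt_h: float
    phase: Phase | None = None

    def __post_init__(self) -> None:
        if not self.start_zt_h < self.end_zt_h:
            raise ValueError("window start must precede end")

    @property
    def duration_h(self) -> float:
        return self.end_zt_h - self.start_zt_h

    def epoch_mask(self, hyp: Hypnogram) -> np.ndarray:
        zt = hyp.epoch_zt_h()
        return (zt >= self.start_zt_h) & (zt < self.end_zt_h)


def _clipped(window: PhaseWindow, hyp: Hypnogram) -> PhaseWindow:
    lo = max(window.start_zt_h, hyp.start_zt_h)
    hi = min(window.end_zt_h, hyp.end_zt_h)
    if (lo, hi) != (window.start_zt_h, window.end_zt_h):
        logger.warning(
            "window [%g, %g) clipped to recorded span [%g, %g)",
            window.start_zt_h, window.end_zt_h, lo, hi,
        )
    if not lo < hi:
        raise ValueError(
            f"window [{window.start_zt_h}, {window.end_zt_h}) does not "
            f"overlap the recording [{hyp.start_zt_h}, {hyp.end_zt_h})"
        )
    return PhaseWindow(lo, hi, window.phase)


def light_window(hyp: Hypnogram, day: int = 0) -> PhaseWindow:
    """The 12-h light-phase window [ZT 0, ZT 12) of the given day."""
    w = PhaseWindow(day * CYCLE_HOURS, day * CYCLE_HOURS + LIGHT_HOURS, Phase.LIGHT)
    return _clipped(w, hyp)


def dark_window(hyp: Hypnogram, day: int = 0) -> PhaseWindow:
    """The 12-h dark-phase window [ZT 12, ZT 24) of the given day."""
    w = PhaseWindow(day * CYCLE_HOURS + LIGHT_HOURS, (day + 1) * CYCLE_HOURS, Phase.DARK)
    return _clipped(w, hyp)


def full_window(hyp: Hypnogram) -> PhaseWindow:
    """Window covering the entire recording."""
    return PhaseWindow(hyp.start_zt_h, hyp.end_zt_h)


# ---------------------------------------------------------------------------
# File I/O: tab-delimited hypnogram exchange format
# ---------------------------------------------------------------------------

HYPNOGRAM_COLUMNS = ("epoch_index", "zt_start_s", "state", "artifact")


def read_hypnogram(path) -> Hypnogram:
    """Read a tab-delimited hypnogram file.

    Expected header: ``epoch_index  zt_start_s  state  artifact`` with one
    row per epoch, states in {WAKE, NREM, REM} and artifact in {0, 1}.
    Epoch length and start ZT are inferred from the ``zt_start_s`` column.
    """
    df = pd.read_csv(path, sep="\t")
    missing = set(HYPNOGRAM_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"hypnogram file missing columns: {sorted(missing)}")
    df = df.sort_values("epoch_index").reset_index(drop=True)
    zt = df["zt_start_s"].to_numpy(dtype=float)
    if len(zt) > 1:
        steps = np.diff(zt)
        if not np.allclose(steps, steps[0]):
            raise ValueError("non-uniform epoch spacing in zt_start_s")
        epoch_length_s = float(steps[0])
    else:
        epoch_length_s = 5.0
    return Hypnogram(
        states=df["state"].to_numpy(),
        artifact=df["artifact"].to_numpy(dtype=bool),
        epoch_length_s=epoch_length_s,
        start_zt_h=float(zt[0]) / 3600.0 % CYCLE_HOURS if len(zt) else 0.0,
    )


def write_hypnogram(hyp: Hypnogram, path) -> None:
    """Write a hypnogram in the tab-delimited exchange format."""
    zt0 = hyp.start_zt_h * 3600.0
    df = pd.DataFrame(
        {
            "epoch_index": np.arange(hyp.n_epochs),
            "zt_start_s": zt0 + np.arange(hyp.n_epochs) * hyp.epoch_length_s,
            "state": hyp.states,
            "artifact": hyp.artifact.astype(int),
        }
    )
    df.to_csv(path, sep="\t", index=False)
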