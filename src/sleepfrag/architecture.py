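"""Sleep-architecture metrics from epoch-scored hypnograms.

Segments a hypnogram into bouts (maximal runs of one vigilance state) and
derives the standard architecture read-outs: percent time in state, bout
counts and mean durations, state-transition counts, latency to first bout,
mean inter-bout interval, 2-h binned time series and cumulative state
duration curves.

Conventions (documented, applied uniformly):

* epoch indexing is 0-based; every window is half-open ``[start, end)``
  on the ZT axis, so bin edges are never double-counted;
* a bout belongs to the window containing its first epoch; a transition to
  the window containing its post-transition epoch;
* bouts truncated by the start or end of the recording are counted at
  their observed length;
* artifact epochs keep their scored state (artifacts matter only for
  spectral averages);
* undefined metrics (no bouts, no qualifying gaps, state absent) are
  returned as ``nan``, never as zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .hypnogram import (
    CYCLE_HOURS,
    LIGHT_HOURS,
    STATES,
    TRANSITION_PAIRS,
    Hypnogram,
    Phase,
    PhaseWindow,
    VigilanceState,
    dark_window,
    full_window,
    light_window,
)

logger = logging.getLogger(__name__)

__all__ = [
    "Bout",
    "segment_bouts",
    "percent_time",
    "bout_metrics",
    "count_transitions",
    "latency",
    "interbout_interval",
    "bin_series",
    "cumulative_duration",
    "architecture_table",
]


@dataclass(frozen=True)
class Bout:
    """Maximal run of consecutive epochs in one vigilance state."""

    state: VigilanceState
    start_epoch: int
    n_epochs: int
    duration_s: float

    @property
    def end_epoch(self) -> int:
        """Index one past the last epoch of the bout (half-open)."""
        return self.start_epoch + self.n_epochs


def segment_bouts(hyp: Hypnogram) -> list[Bout]:
    """Run-length encode a hypnogram into an ordered list of bouts.

    The concatenation of the returned bouts reproduces the label sequence
    exactly; consecutive bouts always differ in state. Artifact flags do
    not affect segmentation. An empty hypnogram yields an empty list.
    """
    n = hyp.n_epochs
    if n == 0:
        return []
    change = np.flatnonzero(hyp.states[1:] != hyp.states[:-1]) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [n]))
    return [
        Bout(
            state=VigilanceState(hyp.states[s]),
            start_epoch=int(s),
            n_epochs=int(e - s),
            duration_s=float(e - s) * hyp.epoch_length_s,
        )
        for s, e in zip(starts, ends)
    ]


def _window_or_full(hyp: Hypnogram, window: PhaseWindow | None) -> PhaseWindow:
    return full_window(hyp) if window is None else window


def _require_coverage(hyp: Hypnogram, window: PhaseWindow) -> np.ndarray:
    mask = window.epoch_mask(hyp)
    if not mask.any():
        raise ValueError(
            f"window [{window.start_zt_h}, {window.end_zt_h}) contains no "
            "epochs of the recording"
        )
    return mask


def percent_time(
    hyp: Hypnogram,
    state: VigilanceState | str,
    window: PhaseWindow | None = None,
) -> float:
    """Percent of a window's epochs scored as ``state``.

    Artifact epochs are counted under their scored state. Raises if the
    window is disjoint from the recording.
    """
    window = _window_or_full(hyp, window)
    mask = _require_coverage(hyp, window)
    in_state = hyp.state_mask(state) & mask
    return 100.0 * in_state.sum() / mask.sum()


def bout_metrics(
    hyp: Hypnogram,
    state: VigilanceState | str,
    window: PhaseWindow | None = None,
) -> tuple[int, float]:
    """Number of bouts of ``state`` starting in the window and their mean
    duration in seconds.

    A bout is attributed to the window containing its first epoch; bouts
    truncated by the recording boundaries contribute their observed
    length. With zero bouts the mean is ``nan``.
    """
    window = _window_or_full(hyp, window)
    _require_coverage(hyp, window)
    zt = hyp.epoch_zt_h()
    state = VigilanceState(state)
    durations = [
        b.duration_s
        for b in segment_bouts(hyp)
        if b.state is state
        and window.start_zt_h <= zt[b.start_epoch] < window.end_zt_h
    ]
    if not durations:
        return 0, float("nan")
    return len(durations), float(np.mean(durations))


def count_transitions(
    hyp: Hypnogram,
    from_state: VigilanceState | str,
    to_state: VigilanceState | str,
    window: PhaseWindow | None = None,
) -> int:
    """Count adjacent epoch pairs (i, i+1) labelled (from_state, to_state).

    The transition is attributed to the window containing epoch ``i+1``
    (the post-transition epoch). ``from_state`` must differ from
    ``to_state``.
    """
    from_state = VigilanceState(from_state)
    to_state = VigilanceState(to_state)
    if from_state is to_state:
        raise ValueError("a transition requires two distinct states")
    window = _window_or_full(hyp, window)
    if hyp.n_epochs < 2:
        return 0
    pair = (hyp.states[:-1] == from_state.value) & (hyp.states[1:] == to_state.value)
    zt_next = hyp.epoch_zt_h()[1:]
    in_window = (zt_next >= window.start_zt_h) & (zt_next < window.end_zt_h)
    return int((pair & in_window).sum())


def latency(
    hyp: Hypnogram,
    state: VigilanceState | str,
    from_zt_h: float | None = None,
) -> float:
    """Seconds from a reference instant to the onset of the first bout of
    ``state`` at or after it.

    No minimum bout duration is imposed: the first epoch scored as the
    state defines onset. Returns ``nan`` when the state never occurs at or
    after the reference.
    """
    if from_zt_h is None:
        from_zt_h = hyp.start_zt_h
    if not (hyp.start_zt_h <= from_zt_h < hyp.end_zt_h):
        raise ValueError("reference instant outside the recorded span")
    zt = hyp.epoch_zt_h()
    hits = np.flatnonzero(hyp.state_mask(state) & (zt >= from_zt_h))
    if hits.size == 0:
        return float("nan")
    return (zt[hits[0]] - from_zt_h) * 3600.0


def _phase_block(zt_h: float) -> int:
    """Index of the 12-h light/dark block containing ZT hour ``zt_h``."""
    return int(np.floor(zt_h / LIGHT_HOURS + 1e-12))


def interbout_interval(
    hyp: Hypnogram,
    state: VigilanceState | str,
    window: PhaseWindow | None = None,
) -> float:
    """Mean gap, in seconds, between successive bouts of ``state``.

    A gap runs from the end of one bout of the state to the start of the
    next. Only gaps lying entirely inside the window and not spanning a
    light/dark boundary qualify. With no qualifying gap the result is
    ``nan``.
    """
    window = _window_or_full(hyp, window)
    _require_coverage(hyp, window)
    state = VigilanceState(state)
    bouts = [b for b in segment_bouts(hyp) if b.state is state]
    if len(bouts) < 2:
        return float("nan")
    eph = hyp.epoch_length_h
    gaps: list[float] = []
    for prev, nxt in zip(bouts[:-1], bouts[1:]):
        gap_start_h = hyp.start_zt_h + prev.end_epoch * eph
        gap_end_h = hyp.start_zt_h + nxt.start_epoch * eph
        if gap_start_h < window.start_zt_h or gap_end_h > window.end_zt_h:
            continue
        # first and last epoch of the gap must share a light/dark block
        if _phase_block(gap_start_h) != _phase_block(gap_end_h - eph):
            continue
        gaps.append((gap_end_h - gap_start_h) * 3600.0)
    if not gaps:
        return float("nan")
    return float(np.mean(gaps))


def bin_series(
    hyp: Hypnogram,
    metric: Callable[[Hypnogram, PhaseWindow], float],
    bin_h: float = 2.0,
) -> pd.Series:
    """Evaluate a per-window metric over consecutive ``bin_h``-hour bins.

    Bins are half-open, aligned to the ZT grid from the recording start.
    A trailing partial bin is dropped with a log message. Raises if the
    bin exceeds the recorded span.
    """
    if bin_h <= 0:
        raise ValueError("bin_h must be positive")
    if bin_h > hyp.duration_h:
        raise ValueError(
            f"bin of {bin_h} h exceeds the recorded span of {hyp.duration_h} h"
        )
    n_bins = int(np.floor(hyp.duration_h / bin_h + 1e-9))
    if not np.isclose(n_bins * bin_h, hyp.duration_h):
        logger.info(
            "dropping trailing partial bin (%.3g h)",
            hyp.duration_h - n_bins * bin_h,
        )
    starts = hyp.start_zt_h + bin_h * np.arange(n_bins)
    values = [
        metric(hyp, PhaseWindow(s, s + bin_h)) for s in starts
    ]
    return pd.Series(values, index=pd.Index(starts, name="bin_start_zt_h"))


def cumulative_duration(
    hyp: Hypnogram,
    state: VigilanceState | str,
    from_zt_h: float | None = None,
) -> pd.Series:
    """Cumulative seconds spent in ``state`` from a reference instant.

    Returns a non-decreasing step curve sampled at epoch ends, indexed by
    seconds elapsed since the reference; its terminal value is the total
    state time at or after the reference.
    """
    if from_zt_h is None:
        from_zt_h = hyp.start_zt_h
    if not (hyp.start_zt_h <= from_zt_h < hyp.end_zt_h):
        raise ValueError("reference instant outside the recorded span")
    zt = hyp.epoch_zt_h()
    keep = zt >= from_zt_h
    contrib = (hyp.state_mask(state) & keep) * hyp.epoch_length_s
    cum = np.cumsum(contrib[keep])
    elapsed = (zt[keep] - from_zt_h) * 3600.0 + hyp.epoch_length_s
    return pd.Series(cum, index=pd.Index(elapsed, name="seconds_post_reference"))


# ---------------------------------------------------------------------------
# Tidy metrics table
# ---------------------------------------------------------------------------

def _phase_windows(hyp: Hypnogram) -> list[PhaseWindow]:
    wins = []
    for day in range(int(np.ceil(hyp.end_zt_h / CYCLE_HOURS))):
        for fn in (light_window, dark_window):
            try:
                wins.append(fn(hyp, day=day))
            except ValueError:
                continue
    return wins


def architecture_table(
    hyp: Hypnogram,
    animal: str = "animal",
    condition: str = "baseline",
    bin_h: float = 2.0,
) -> pd.DataFrame:
    """Long-format table of all architecture metrics for one recording.

    Columns: ``animal condition phase bin state metric value``. Phase-level
    rows carry the 12-h light/dark summaries (percent time, bout count and
    duration, latency from phase start, inter-bout interval, the four
    reported transition counts); bin-level rows carry the ``bin_h``-binned
    percent-time/bout series used for time-course plots.
    """
    rows: list[dict] = []

    def add(phase, bin_label, state, metric, value):
        rows.append(
            dict(
                animal=animal,
                condition=condition,
                phase=phase,
                bin=bin_label,
                state=state,
                metric=metric,
                value=value,
            )
        )

    for win in _phase_windows(hyp):
        phase = win.phase.value if win.phase else "ALL"
        for state in STATES:
            add(phase, "", state.value, "percent_time",
                percent_time(hyp, state, win))
            n, dur = bout_metrics(hyp, state, win)
            add(phase, "", state.value, "n_bouts", n)
            add(phase, "", state.value, "mean_bout_duration_s", dur)
            add(phase, "", state.value, "latency_s",
                latency(hyp, state, win.start_zt_h))
            add(phase, "", state.value, "mean_interbout_interval_s",
                interbout_interval(hyp, state, win))
        for a, b in TRANSITION_PAIRS:
            add(phase, "", f"{a.value}->{b.value}", "n_transitions",
                count_transitions(hyp, a, b, win))

    for state in STATES:
        series = bin_series(hyp, lambda h, w, s=state: percent_time(h, s, w), bin_h)
        for start, val in series.items():
            add("", f"{start:g}", state.value, "percent_time", val)
        series = bin_series(hyp, lambda h, w, s=state: bout_metrics(h, s, w)[0], bin_h)
        for start, val in series.items():
            add("", f"{start:g}", state.value, "n_bouts", val)

    return pd.DataFrame(rows)
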