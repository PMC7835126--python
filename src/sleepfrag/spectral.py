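"""Epoch power spectra, band powers and slow-wave-activity time courses.

Slow-wave activity (SWA, delta-band NREM power, 0.5-4.5 Hz) indexes
homeostatic sleep pressure: it is high after extended waking and decays
across sleep. The workflow here mirrors the standard sleep-deprivation
analysis: estimate a power spectral density per 5-s epoch, normalize each
animal's spectra to its own pre-stress baseline SWA over artifact-free
NREM epochs of the 12-h light phase, then average the normalized low-delta
band (0.5-3 Hz) over NREM epochs in 2-h bins after the deprivation ends.

Per-epoch PSDs use averaged periodograms with rectangular (boxcar)
sub-windows and 20% overlap; 2-s sub-windows give the 0.5-Hz grid, so a
5-s epoch contributes two full sub-windows. Power is scaled as a density:
the integral over the full one-sided grid approximates the signal
variance.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal as sps

from .hypnogram import Hypnogram, PhaseWindow, VigilanceState, light_window

__all__ = [
    "Band",
    "SWA",
    "LOW_SWA",
    "THETA",
    "BETA",
    "SLOW_GAMMA",
    "SpectrumSeries",
    "epoch_psd",
    "band_power",
    "normalize_to_baseline",
    "swa_timecourse",
    "read_psd_matrix",
    "write_psd_matrix",
]

#: Default sampling rate of the (already subsampled) EEG trace, Hz.
DEFAULT_FS = 250.0
#: Frequency resolution of the analysis grid, Hz.
GRID_DF = 0.5
#: Upper edge of the default analysis grid, Hz.
GRID_FMAX = 90.0


@dataclass(frozen=True)
class Band:
    """Closed frequency band; membership is by bin center, inclusive."""

    name: str
    lo_hz: float
    hi_hz: float

    def __post_init__(self) -> None:
        if not (0 < self.lo_hz < self.hi_hz):
            raise ValueError("band requires 0 < lo < hi")

    def bin_indices(self, freqs: np.ndarray) -> np.ndarray:
        idx = np.flatnonzero((freqs >= self.lo_hz - 1e-9) & (freqs <= self.hi_hz + 1e-9))
        if idx.size == 0:
            raise ValueError(f"band {self.name} [{self.lo_hz}, {self.hi_hz}] "
                             "contains no grid bins")
        return idx


SWA = Band("SWA", 0.5, 4.5)
LOW_SWA = Band("lowSWA", 0.5, 3.0)
# Theta/beta/slow-gamma edges are conventional defaults, adjust per lab.
THETA = Band("theta", 5.0, 9.0)
BETA = Band("beta", 15.0, 30.0)
SLOW_GAMMA = Band("slow_gamma", 30.0, 50.0)


@dataclass(frozen=True)
class SpectrumSeries:
    """Per-epoch power spectra on a uniform frequency grid, aligned
    one-to-one with a hypnogram."""

    freqs: np.ndarray
    power: np.ndarray  # (n_epochs, n_freqs), non-negative
    hypnogram: Hypnogram

    def __post_init__(self) -> None:
        freqs = np.asarray(self.freqs, dtype=float)
        power = np.asarray(self.power)
        object.__setattr__(self, "freqs", freqs)
        object.__setattr__(self, "power", power)
        if power.ndim != 2 or power.shape[1] != freqs.shape[0]:
            raise ValueError("power must be (n_epochs, n_freqs)")
        if power.shape[0] != self.hypnogram.n_epochs:
            raise ValueError("one spectrum per hypnogram epoch required")
        df = np.diff(freqs)
        if freqs.size > 1 and not (np.all(df > 0) and np.allclose(df, df[0])):
            raise ValueError("frequency grid must be strictly increasing "
                             "and uniformly spaced")
        if np.any(power < 0):
            raise ValueError("spectral power must be non-negative")

    @property
    def n_epochs(self) -> int:
        return self.power.shape[0]

    def scaled(self, factor: float) -> "SpectrumSeries":
        return replace(self, power=self.power * factor)


def epoch_psd(
    signal: np.ndarray,
    epoch_length_s: float = 5.0,
    fs: float = DEFAULT_FS,
    fmax: float = GRID_FMAX,
) -> tuple[np.ndarray, np.ndarray]:
    """Averaged-periodogram PSD of one epoch on the 0.5-Hz grid.

    Rectangular 2-s sub-windows with 20% overlap (a 5-s epoch yields two
    full sub-windows). Returns ``(freqs, power)`` with frequencies from
    0.5 Hz to ``fmax``; pass ``fmax = fs / 2`` for the full one-sided
    grid, over which ``sum(power) * 0.5`` approximates the signal
    variance.
    """
    x = np.asarray(signal, dtype=float)
    expected = int(round(epoch_length_s * fs))
    if x.shape != (expected,):
        raise ValueError(f"expected {expected} samples, got {x.shape}")
    if not np.all(np.isfinite(x)):
        raise ValueError("signal contains non-finite samples")
    nperseg = int(round(fs / GRID_DF))  # 2-s sub-window -> 0.5-Hz bins
    freqs, pxx = sps.welch(
        x,
        fs=fs,
        window="boxcar",
        nperseg=nperseg,
        noverlap=int(round(0.2 * nperseg)),
        detrend=False,
        scaling="density",
    )
    keep = (freqs >= GRID_DF - 1e-9) & (freqs <= fmax + 1e-9)
    return freqs[keep], pxx[keep]


def band_power(
    freqs: np.ndarray, power: np.ndarray, band: Band
) -> float | np.ndarray:
    """Mean power over the bins whose centers fall inside the band.

    The mean (not the sum) keeps the value invariant to extending the
    grid. ``power`` may be a single spectrum or an (epochs, freqs) matrix;
    a matrix returns one value per epoch.
    """
    idx = band.bin_indices(np.asarray(freqs, dtype=float))
    power = np.asarray(power)
    if power.ndim == 1:
        return float(power[idx].mean())
    return power[:, idx].mean(axis=1)


def _baseline_divisor(baseline: SpectrumSeries, band: Band = SWA) -> float:
    """Mean band power over artifact-free NREM epochs of the baseline
    light phase."""
    hyp = baseline.hypnogram
    mask = (
        hyp.state_mask(VigilanceState.NREM)
        & ~hyp.artifact
        & light_window(hyp).epoch_mask(hyp)
    )
    if not mask.any():
        raise ValueError(
            "baseline has no artifact-free NREM epoch in its light phase"
        )
    per_epoch = band_power(baseline.freqs, baseline.power[mask], band)
    return float(np.mean(per_epoch))


def normalize_to_baseline(
    series: SpectrumSeries,
    baseline: SpectrumSeries,
    band: Band = SWA,
) -> SpectrumSeries:
    """Divide every spectrum by the baseline's mean light-phase NREM band
    power (artifact-free epochs only).

    The divisor is a single per-animal scalar, so normalizing a baseline
    against itself leaves its light-phase NREM band mean at exactly 1.
    """
    divisor = _baseline_divisor(baseline, band)
    return replace(series, power=series.power / divisor)


def swa_timecourse(
    series: SpectrumSeries,
    from_zt_h: float,
    band: Band = LOW_SWA,
    bin_h: float = 2.0,
) -> pd.Series:
    """Mean normalized band power over artifact-free NREM epochs per
    ``bin_h``-hour bin after a reference instant.

    Indexed by hours since the reference (bin midpoints); bins with no
    qualifying NREM epoch are ``nan``.
    """
    hyp = series.hypnogram
    if not (hyp.start_zt_h <= from_zt_h < hyp.end_zt_h):
        raise ValueError("reference instant outside the recorded span")
    per_epoch = band_power(series.freqs, series.power, band)
    ok = hyp.state_mask(VigilanceState.NREM) & ~hyp.artifact
    zt = hyp.epoch_zt_h()
    n_bins = int(np.floor((hyp.end_zt_h - from_zt_h) / bin_h + 1e-9))
    mids, values = [], []
    for k in range(n_bins):
        lo = from_zt_h + k * bin_h
        sel = ok & (zt >= lo) & (zt < lo + bin_h)
        mids.append(k * bin_h + bin_h / 2.0)
        values.append(float(np.mean(per_epoch[sel])) if sel.any() else float("nan"))
    return pd.Series(values, index=pd.Index(mids, name="hours_post_reference"))


# ---------------------------------------------------------------------------
# PSD matrix file I/O
# ---------------------------------------------------------------------------

def write_psd_matrix(series: SpectrumSeries, path) -> None:
    """Delimited PSD matrix: header = epoch_index + frequency grid, one
    row of powers per epoch."""
    df = pd.DataFrame(series.power, columns=[f"{f:g}" for f in series.freqs])
    df.insert(0, "epoch_index", np.arange(series.n_epochs))
    df.to_csv(path, sep="\t", index=False)


def read_psd_matrix(path, hypnogram: Hypnogram) -> SpectrumSeries:
    """Read a PSD matrix written by :func:`write_psd_matrix`, aligning
    rows to the hypnogram by epoch index."""
    df = pd.read_csv(path, sep="\t")
    if "epoch_index" not in df.columns:
        raise ValueError("PSD matrix must carry an epoch_index column")
    df = df.sort_values("epoch_index").reset_index(drop=True)
    freqs = np.array([float(c) for c in df.columns if c != "epoch_index"])
    power = df.drop(columns="epoch_index").to_numpy(dtype=float)
    return SpectrumSeries(freqs=freqs, power=power, hypnogram=hypnogram)
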