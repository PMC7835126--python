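"""Synthetic vigilance-state cohorts: semi-Markov hypnograms, a
two-process sleep homeostat, state-conditioned epoch spectra and
social-interaction trials.

The generator stands in for undeposited chronic-social-defeat recordings.
Its components:

* **Semi-Markov hypnogram.** Each vigilance state has a geometric dwell
  time at 5-s epoch granularity (mean dwell per light/dark phase); on
  leaving a state, the successor is drawn from a kernel in which wake can
  only enter NREM, NREM splits between wake and REM, and REM splits
  between wake and NREM (REM is reachable only from NREM — the rodent
  convention; configurable). The continuation probability is re-drawn per
  epoch from the current phase's dwell mean, so a bout straddling the
  ZT 12 boundary adapts smoothly instead of being truncated.

* **Two-process homeostat.** Sleep pressure S rises exponentially toward
  an upper asymptote U during wake (time constant ``tau_rise_h``) and
  falls toward a lower asymptote L during sleep (``tau_fall_h``),
  continuous at state changes. After sleep deprivation, NREM dwell means
  are inflated by a factor proportional to the normalized pressure, so
  NREM rebound decays as S does.

* **Spectra.** Per epoch: a 1/f background plus a state bump — a delta
  bump at 1.5 Hz in NREM whose amplitude scales with ``swa_gain * S``, a
  theta bump at 7 Hz in REM, flat broadband in wake — times multiplicative
  log-normal noise.

* **Phenotype presets.** SUSCEPTIBLE shortens NREM dwell and raises
  NREM->wake switching in both phases (NREM fragmentation); RESILIENT
  lengthens dark-phase wake dwell. Magnitudes are calibration choices of
  this generator, not measured effect sizes.

One cohort seed fans out to per-animal, per-recording substreams through
``numpy.random.SeedSequence.spawn``, so cohorts regenerate identically
from their provenance manifest.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .hypnogram import (
    CYCLE_HOURS,
    LIGHT_HOURS,
    Hypnogram,
    Phase,
    VigilanceState,
)
from .phenotype import PhenotypeLabel, SITrial, classify_phenotype, si_score
from .spectral import GRID_DF, GRID_FMAX, SpectrumSeries

__all__ = [
    "HomeostatParams",
    "SpectrumParams",
    "SimParams",
    "PRESETS",
    "preset",
    "poststress_params",
    "simulate_hypnogram",
    "simulate_sd",
    "homeostat_trace",
    "simulate_epoch_spectra",
    "simulate_si_trial",
    "simulate_cohort",
    "Cohort",
    "AnimalRecord",
]

W, N, R = VigilanceState.WAKE, VigilanceState.NREM, VigilanceState.REM


@dataclass(frozen=True)
class HomeostatParams:
    """Two-process Process-S parameters (dimensionless pressure)."""

    lower: float = 0.1       # L, asymptote reached by consolidated sleep
    upper: float = 1.0       # U, asymptote approached during waking
    tau_rise_h: float = 8.0  # exponential rise constant in wake, hours
    tau_fall_h: float = 2.0  # exponential fall constant in sleep, hours
    s0: float = 0.5          # pressure at recording start

    def __post_init__(self) -> None:
        if not (0 <= self.lower < self.upper):
            raise ValueError("require 0 <= L < U")
        if self.tau_rise_h <= 0 or self.tau_fall_h <= 0:
            raise ValueError("time constants must be positive")

    def step(self, s: float, awake: bool, dt_h: float) -> float:
        """Advance S by ``dt_h`` hours in the given state (closed form)."""
        if awake:
            return self.upper - (self.upper - s) * np.exp(-dt_h / self.tau_rise_h)
        return self.lower + (s - self.lower) * np.exp(-dt_h / self.tau_fall_h)


@dataclass(frozen=True)
class SpectrumParams:
    """State-conditioned spectrum model parameters."""

    bg_amp: float = 1.0        # 1/f background amplitude
    bg_slope: float = 1.0      # 1/f exponent
    # swa_gain and wake_broadband chosen so the NREM delta-band increment
    # (gain * S * mean bump, >= gain * L * 0.42) exceeds the wake
    # broadband floor for every attainable pressure S >= L
    swa_gain: float = 2.0      # NREM delta-bump amplitude per unit S
    delta_center_hz: float = 1.5
    delta_width_hz: float = 0.8
    theta_amp: float = 0.5     # REM theta-bump amplitude
    theta_center_hz: float = 7.0
    theta_width_hz: float = 1.0
    wake_broadband: float = 0.05
    noise_sigma: float = 0.2   # log-normal sigma, multiplicative


@dataclass(frozen=True)
class SimParams:
    """Full parameter bundle for one synthetic phenotype.

    ``dwell_s`` maps (phase, state) to the mean dwell time in seconds
    (geometric at epoch granularity). ``p_nrem_to_wake`` and
    ``q_rem_to_wake`` give, per phase, the probability that an exit from
    NREM (resp. REM) lands in wake; the complement goes to REM (resp.
    NREM). Wake always exits to NREM.
    """

    dwell_s: Mapping[tuple[Phase, VigilanceState], float]
    p_nrem_to_wake: Mapping[Phase, float]
    q_rem_to_wake: Mapping[Phase, float]
    homeostat: HomeostatParams = HomeostatParams()
    spectrum: SpectrumParams = SpectrumParams()
    rebound_gain: float = 1.5      # NREM dwell inflation per unit (S-L)/(U-L)
    artifact_prob_wake: float = 0.02
    artifact_prob_sleep: float = 0.005

    def __post_init__(self) -> None:
        for (phase, state), mu in self.dwell_s.items():
            if mu < 5.0:
                raise ValueError(
                    f"dwell mean {mu}s for {phase}/{state} below epoch length"
                )
        for m in (self.p_nrem_to_wake, self.q_rem_to_wake):
            for phase, p in m.items():
                if not (0.0 <= p <= 1.0):
                    raise ValueError("kernel probabilities must lie in [0, 1]")

    def to_dict(self) -> dict:
        return {
            "dwell_s": {f"{ph.value}:{st.value}": mu
                        for (ph, st), mu in self.dwell_s.items()},
            "p_nrem_to_wake": {ph.value: p for ph, p in self.p_nrem_to_wake.items()},
            "q_rem_to_wake": {ph.value: q for ph, q in self.q_rem_to_wake.items()},
            "homeostat": dataclasses.asdict(self.homeostat),
            "spectrum": dataclasses.asdict(self.spectrum),
            "rebound_gain": self.rebound_gain,
            "artifact_prob_wake": self.artifact_prob_wake,
            "artifact_prob_sleep": self.artifact_prob_sleep,
        }


def _naive() -> SimParams:
    L, D = Phase.LIGHT, Phase.DARK
    return SimParams(
        dwell_s={
            (L, W): 100.0, (L, N): 140.0, (L, R): 70.0,
            (D, W): 400.0, (D, N): 90.0, (D, R): 55.0,
        },
        p_nrem_to_wake={L: 0.65, D: 0.80},
        q_rem_to_wake={L: 0.85, D: 0.85},
    )


def _resilient() -> SimParams:
    base = _naive()
    dwell = dict(base.dwell_s)
    dwell[(Phase.DARK, W)] = 600.0  # more dark-phase wake
    return replace(base, dwell_s=dwell)


def _susceptible() -> SimParams:
    base = _naive()
    dwell = dict(base.dwell_s)
    for ph in (Phase.LIGHT, Phase.DARK):
        dwell[(ph, N)] = base.dwell_s[(ph, N)] * 0.6   # shorter NREM bouts
    dwell[(Phase.LIGHT, W)] = base.dwell_s[(Phase.LIGHT, W)] * 0.8
    p = {ph: min(0.95, base.p_nrem_to_wake[ph] * 1.2)   # more NREM<->wake switching
         for ph in (Phase.LIGHT, Phase.DARK)}
    return replace(base, dwell_s=dwell, p_nrem_to_wake=p)


PRESETS: dict[str, SimParams] = {
    "naive": _naive(),
    "resilient": _resilient(),
    "susceptible": _susceptible(),
}


def preset(name: str) -> SimParams:
    try:
        return PRESETS[name]
    except KeyError:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")


def poststress_params(params: SimParams) -> SimParams:
    """Post-stress parameter shift: fragmentation deepens slightly in
    both phases (shorter NREM dwell, higher NREM->wake switching)."""
    dwell = dict(params.dwell_s)
    for ph in (Phase.LIGHT, Phase.DARK):
        dwell[(ph, N)] = params.dwell_s[(ph, N)] * 0.9
    p = {ph: min(0.95, params.p_nrem_to_wake[ph] * 1.1)
         for ph in (Phase.LIGHT, Phase.DARK)}
    return replace(params, dwell_s=dwell, p_nrem_to_wake=p)


# ---------------------------------------------------------------------------
# Hypnogram simulation
# ---------------------------------------------------------------------------

_EPOCH_S = 5.0


def _phase_of(zt_h: float) -> Phase:
    return Phase.LIGHT if (zt_h % CYCLE_HOURS) < LIGHT_HOURS else Phase.DARK


def _next_state(state: VigilanceState, phase: Phase, u: float,
                params: SimParams) -> VigilanceState:
    if state is W:
        return N
    if state is N:
        return W if u < params.p_nrem_to_wake[phase] else R
    return W if u < params.q_rem_to_wake[phase] else N


def _simulate_states(
    params: SimParams,
    n_epochs: int,
    start_zt_h: float,
    rng: np.random.Generator,
    forced_wake_epochs: int = 0,
    s_coupled_rebound: bool = False,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Core epoch loop. Returns (states, artifact, S trace at epoch starts)."""
    u_cont = rng.random(n_epochs)
    u_next = rng.random(n_epochs)
    u_art = rng.random(n_epochs)
    hp = params.homeostat
    dt_h = _EPOCH_S / 3600.0
    states = np.empty(n_epochs, dtype="U4")
    artifact = np.zeros(n_epochs, dtype=bool)
    s_trace = np.empty(n_epochs)

    state = W
    s = hp.s0
    for i in range(n_epochs):
        zt = start_zt_h + i * dt_h
        phase = _phase_of(zt)
        if i < forced_wake_epochs:
            state = W
        states[i] = state.value
        s_trace[i] = s
        p_art = (params.artifact_prob_wake if state is W
                 else params.artifact_prob_sleep)
        artifact[i] = u_art[i] < p_art
        # dwell continuation re-drawn per epoch from the current phase
        mu = params.dwell_s[(phase, state)]
        if s_coupled_rebound and state is N and i >= forced_wake_epochs:
            frac = (s - hp.lower) / (hp.upper - hp.lower)
            mu = mu * (1.0 + params.rebound_gain * frac)
        leave = u_cont[i] < _EPOCH_S / mu
        s = hp.step(s, awake=(state is W), dt_h=dt_h)
        if i + 1 < forced_wake_epochs:
            state = W
        elif leave:
            state = _next_state(state, phase, u_next[i], params)
    return states, artifact, s_trace


def simulate_hypnogram(
    params: SimParams,
    duration_h: float = 24.0,
    start_zt_h: float = 0.0,
    seed: int | np.random.SeedSequence = 0,
) -> Hypnogram:
    """Simulate a phase-modulated semi-Markov hypnogram."""
    rng = np.random.default_rng(seed)
    n = int(round(duration_h * 3600.0 / _EPOCH_S))
    states, artifact, _ = _simulate_states(params, n, start_zt_h, rng)
    return Hypnogram(states=states, artifact=artifact,
                     epoch_length_s=_EPOCH_S, start_zt_h=start_zt_h)


def simulate_sd(
    params: SimParams,
    sd_hours: float = 4.0,
    total_h: float = 24.0,
    start_zt_h: float = 0.0,
    seed: int | np.random.SeedSequence = 0,
) -> tuple[Hypnogram, np.ndarray]:
    """Sleep-deprivation day: forced wake for ``sd_hours`` from lights-on,
    then recovery with an S-coupled NREM rebound.

    Returns the hypnogram and the homeostat trace (S at each epoch start).
    """
    if not sd_hours < total_h:
        raise ValueError("sd_hours must be shorter than the recording")
    rng = np.random.default_rng(seed)
    n = int(round(total_h * 3600.0 / _EPOCH_S))
    forced = int(round(sd_hours * 3600.0 / _EPOCH_S))
    states, artifact, s_trace = _simulate_states(
        params, n, start_zt_h, rng,
        forced_wake_epochs=forced, s_coupled_rebound=True,
    )
    hyp = Hypnogram(states=states, artifact=artifact,
                    epoch_length_s=_EPOCH_S, start_zt_h=start_zt_h)
    return hyp, s_trace


def homeostat_trace(
    hyp: Hypnogram, homeostat: HomeostatParams | None = None
) -> np.ndarray:
    """Deterministic Process-S trace for a given hypnogram.

    S at each epoch start, advanced with the closed-form rise (wake) /
    fall (NREM, REM) over each epoch.
    """
    hp = homeostat or HomeostatParams()
    dt_h = hyp.epoch_length_s / 3600.0
    s = hp.s0
    out = np.empty(hyp.n_epochs)
    wake = hyp.state_mask(W)
    for i in range(hyp.n_epochs):
        out[i] = s
        s = hp.step(s, awake=bool(wake[i]), dt_h=dt_h)
    return out


# ---------------------------------------------------------------------------
# Spectra
# ---------------------------------------------------------------------------

def simulate_epoch_spectra(
    hyp: Hypnogram,
    s_trace: np.ndarray,
    params: SimParams,
    seed: int | np.random.SeedSequence = 0,
    dtype=np.float64,
) -> SpectrumSeries:
    """State-conditioned per-epoch spectra on the 0.5-Hz grid (0.5-90 Hz).

    power(f) = background 1/f^slope + state bump + multiplicative
    log-normal noise; the NREM delta bump amplitude is
    ``swa_gain * S(epoch)``.
    """
    s_trace = np.asarray(s_trace, dtype=float)
    if s_trace.shape[0] != hyp.n_epochs:
        raise ValueError("homeostat trace not aligned to hypnogram")
    sp = params.spectrum
    freqs = np.arange(GRID_DF, GRID_FMAX + GRID_DF / 2, GRID_DF)
    bg = sp.bg_amp * freqs ** (-sp.bg_slope)
    power = np.tile(bg, (hyp.n_epochs, 1)).astype(dtype)

    delta_bump = np.exp(-0.5 * ((freqs - sp.delta_center_hz) / sp.delta_width_hz) ** 2)
    theta_bump = np.exp(-0.5 * ((freqs - sp.theta_center_hz) / sp.theta_width_hz) ** 2)

    nrem = hyp.state_mask(N)
    rem = hyp.state_mask(R)
    wake = hyp.state_mask(W)
    power[nrem] += (sp.swa_gain * s_trace[nrem])[:, None] * delta_bump[None, :]
    power[rem] += sp.theta_amp * theta_bump[None, :]
    power[wake] += sp.wake_broadband

    if sp.noise_sigma > 0:
        rng = np.random.default_rng(seed)
        power *= rng.lognormal(0.0, sp.noise_sigma, size=power.shape).astype(dtype)
    return SpectrumSeries(freqs=freqs, power=power, hypnogram=hyp)


# ---------------------------------------------------------------------------
# Social-interaction trials
# ---------------------------------------------------------------------------

def simulate_si_trial(
    group: str,
    rng: np.random.Generator,
    overlap: float = 0.0,
) -> SITrial:
    """Draw SI-trial zone times so the score lands in the group's band.

    With ``overlap = 0`` susceptible scores fall in [40, 95] and resilient
    scores in [105, 170]; a positive overlap widens both bands toward (and
    past) the 100 +/- 1 exclusion zone.
    """
    if group == "susceptible":
        lo, hi = 40.0, 95.0 + overlap
    elif group == "resilient":
        lo, hi = 105.0 - overlap, 170.0
    elif group == "naive":
        lo, hi = 80.0, 140.0
    else:
        raise ValueError(f"unknown group {group!r}")
    score = rng.uniform(lo, hi)
    no_target = rng.uniform(40.0, 80.0)
    return SITrial(
        time_target_s=min(score / 100.0 * no_target, 150.0),
        time_no_target_s=no_target,
    )


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

@dataclass
class AnimalRecord:
    animal_id: str
    group: str
    si_trial: SITrial
    si_score: float
    label: PhenotypeLabel
    #: (period, day) -> Hypnogram, e.g. ("pre", "baseline"), ("post", "sd")
    hypnograms: dict[tuple[str, str], Hypnogram] = field(default_factory=dict)
    #: homeostat traces aligned to each hypnogram
    s_traces: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)
    spectra: dict[tuple[str, str], SpectrumSeries] = field(default_factory=dict)


@dataclass
class Cohort:
    animals: list[AnimalRecord]
    provenance: dict

    def baseline_hypnograms(self, period: str = "pre") -> dict[str, Hypnogram]:
        return {a.animal_id: a.hypnograms[(period, "baseline")]
                for a in self.animals}

    def labels(self) -> dict[str, PhenotypeLabel]:
        return {a.animal_id: a.label for a in self.animals}


def simulate_cohort(
    n_per_group: int = 8,
    presets: Mapping[str, SimParams] | None = None,
    seed: int = 0,
    days: Sequence[str] = ("baseline",),
    periods: Sequence[str] = ("pre",),
    include_spectra: bool = False,
    si_overlap: float = 0.0,
    sd_hours: float = 4.0,
) -> Cohort:
    """Generate a full synthetic cohort.

    Per animal and requested (period, day): a 24-h recording — plain
    baseline, or a sleep-deprivation day (``sd_hours`` forced wake from
    lights-on plus rebound) — with its homeostat trace and, optionally,
    state-conditioned spectra. Post-stress recordings use the
    phenotype-shifted parameters of :func:`poststress_params`. SI scores
    are drawn per group and labelled with the standard threshold rule.

    The provenance dict records everything needed to regenerate the
    cohort identically.
    """
    if n_per_group < 1:
        raise ValueError("n_per_group must be >= 1")
    if presets is None:
        presets = {"susceptible": PRESETS["susceptible"],
                   "resilient": PRESETS["resilient"]}
    groups = sorted(presets)
    root = np.random.SeedSequence(seed)
    animal_seeds = root.spawn(len(groups) * n_per_group)

    animals: list[AnimalRecord] = []
    idx = 0
    for group in groups:
        params_pre = presets[group]
        params_post = poststress_params(params_pre)
        for k in range(n_per_group):
            aid = f"{group}_{k:02d}"
            # fixed fan-out: one stream per recording slot + SI + spectra
            streams = animal_seeds[idx].spawn(2 * 2 * 2 + 1)
            idx += 1
            rng_si = np.random.default_rng(streams[-1])
            trial = simulate_si_trial(group, rng_si, overlap=si_overlap)
            score = si_score(trial)
            rec = AnimalRecord(
                animal_id=aid, group=group, si_trial=trial,
                si_score=score, label=classify_phenotype(score),
            )
            si = 0
            for period in periods:
                params = params_pre if period == "pre" else params_post
                for day in days:
                    hyp_seed, spec_seed = streams[2 * si], streams[2 * si + 1]
                    si += 1
                    if day == "baseline":
                        hyp = simulate_hypnogram(params, seed=hyp_seed)
                        s_tr = homeostat_trace(hyp, params.homeostat)
                    elif day == "sd":
                        hyp, s_tr = simulate_sd(params, sd_hours=sd_hours,
                                                seed=hyp_seed)
                    else:
                        raise ValueError(f"unknown day type {day!r}")
                    rec.hypnograms[(period, day)] = hyp
                    rec.s_traces[(period, day)] = s_tr
                    if include_spectra:
                        rec.spectra[(period, day)] = simulate_epoch_spectra(
                            hyp, s_tr, params, seed=spec_seed, dtype=np.float32
                        )
            animals.append(rec)

    provenance = {
        "seed": seed,
        "n_per_group": n_per_group,
        "groups": groups,
        "presets": {g: presets[g].to_dict() for g in groups},
        "days": list(days),
        "periods": list(periods),
        "include_spectra": include_spectra,
        "si_overlap": si_overlap,
        "sd_hours": sd_hours,
    }
    return Cohort(animals=animals, provenance=provenance)


def write_provenance(cohort: Cohort, path) -> None:
    with open(path, "w") as fh:
        json.dump(cohort.provenance, fh, indent=2, sort_keys=True)
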