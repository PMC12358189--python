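"""Ground-truth synthetic session generator.

Emulates multi-electrode dorsal-horn recordings collected around peripheral
DC neuromodulation of the sciatic nerve:

* modality-specific evoked responses (sustained noxious-thermal firing with
  ~1 s onset latency, noxious-press bursts at 50-100 ms, tactile single/double
  spikes within ~10 ms, proprioceptive bimodal bursts across 400 ms);
* pain-model alterations (elevated evoked counts; longer, non-unimodal
  tactile latency distributions);
* DC-conditioned suppression of windowed evoked counts with a mild elevation
  of spontaneous firing, and modality-dependent post-DC recovery kinetics.

Sessions can be produced at the spike level (the fast path used by most of
the analysis) or rendered to raw voltage for testing the detection and
sorting stages.  Every random draw is controlled by a single integer seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict, replace

import numpy as np

MODALITIES = ("noxious_thermal", "noxious_press", "tactile", "proprioceptive")
GROUPS = ("naive", "neuropathic", "inflammatory")
PAIN_GROUPS = ("neuropathic", "inflammatory")
POLARITIES = ("none", "cathodic_centre", "anodic_centre")

#: per-unit absolute refractory dead time enforced on every true spike train,
#: in seconds; keeps clean planted units below the ISI contamination rule.
REFRACTORY_S = 1.5e-3

#: trial segment span (s relative to trigger) per modality
TRIAL_SPAN_S = {
    "noxious_thermal": (-1.0, 4.5),
    "noxious_press": (-1.0, 1.0),
    "tactile": (-1.0, 1.0),
    "proprioceptive": (-1.0, 1.0),
}

#: true response windows (ms relative to trigger) used by the generator when
#: applying DC suppression; identical to the analysis windows.
TRUE_WINDOWS_MS = {
    "noxious_thermal": {"main": (800.0, 1500.0), "sustained": (1500.0, 4500.0)},
    "noxious_press": {"main": (0.0, 500.0)},
    "tactile": {"main": (0.0, 40.0)},
    "proprioceptive": {"main": (0.0, 400.0)},
}


class ConfigurationError(ValueError):
    """Raised for invalid generator configuration."""


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class StimulusParadigm:
    modality: str
    n_stimuli: int
    inter_stimulus_interval_s: float
    stimulus_duration_s: float

    def __post_init__(self):
        if self.n_stimuli < 1:
            raise ConfigurationError("n_stimuli must be >= 1")
        if self.inter_stimulus_interval_s <= self.stimulus_duration_s:
            raise ConfigurationError("inter-stimulus interval must exceed stimulus duration")


def default_paradigm(modality: str, n_stimuli: int | None = None) -> StimulusParadigm:
    """Stimulation paradigms: two long laser pulses for noxious thermal,
    sets of 50 stimulations at 1 Hz otherwise."""
    if modality == "noxious_thermal":
        return StimulusParadigm(modality, n_stimuli or 2, 20.0, 1.0)
    defaults = {"noxious_press": 0.3, "tactile": 0.00025, "proprioceptive": 0.2}
    return StimulusParadigm(modality, n_stimuli or 50, 1.0, defaults[modality])


@dataclass(frozen=True)
class DCSchedule:
    """DC condition of one recording set.

    The waveform itself (10 s on/offset ramps around a 100-110 s plateau) is
    metadata: recordings start after the onset ramp completes and end before
    the offset ramp, so within a set the condition is constant.
    """
    phase: str                       # pre | during | post
    amplitude_uA: float = 0.0        # 0, 500 or 1000
    polarity: str = "none"           # none | cathodic_centre | anodic_centre
    ramp_s: float = 10.0
    plateau_total_s: float = 105.0
    time_since_dc_end_s: float | None = None   # post phase only

    def __post_init__(self):
        if self.phase not in ("pre", "during", "post"):
            raise ConfigurationError(f"unknown phase {self.phase!r}")
        if (self.amplitude_uA == 0) != (self.phase != "during"):
            raise ConfigurationError("amplitude must be 0 iff phase is not 'during'")
        if (self.polarity == "none") != (self.amplitude_uA == 0):
            raise ConfigurationError("polarity must be 'none' iff amplitude is 0")
        if self.phase == "post" and self.time_since_dc_end_s is None:
            raise ConfigurationError("post phase requires time_since_dc_end_s")


@dataclass(frozen=True)
class EvokedProfile:
    """Evoked-response model of one modality: spike count per stimulus is
    Poisson(mean_count) with latencies from a (possibly two-mode) truncated
    normal mixture, plus an optional uniform sustained tail (noxious thermal).
    All latencies in ms relative to the trigger."""
    mean_count: float
    latency_ms: float
    latency_sd_ms: float
    support_ms: tuple[float, float]
    second_latency_ms: float | None = None
    second_sd_ms: float | None = None
    second_weight: float = 0.0
    sustained_mean_count: float = 0.0
    sustained_span_ms: tuple[float, float] = (1500.0, 4500.0)

    def __post_init__(self):
        if not 0.0 <= self.second_weight <= 1.0:
            raise ConfigurationError("mixture weight must be in [0, 1]")
        if self.mean_count < 0 or self.sustained_mean_count < 0:
            raise ConfigurationError("rates must be >= 0")

    @property
    def mean_latency_ms(self) -> float:
        w = self.second_weight
        second = self.second_latency_ms if self.second_latency_ms is not None else self.latency_ms
        return (1.0 - w) * self.latency_ms + w * second


def default_profile(modality: str, group: str = "naive") -> EvokedProfile:
    """Study-condition evoked profiles.

    Tactile latencies centre on 8.31 ms in naive animals; pain groups mix in a
    delayed second mode at 16 ms with the weight chosen so the mixture mean
    matches the group's reported mean latency (10.85 ms neuropathic, 10.41 ms
    inflammatory).  Pain groups also carry a 1.3x elevated evoked count
    (baseline hypersensitivity).
    """
    pain = group in PAIN_GROUPS
    gain = 1.3 if pain else 1.0
    if modality == "tactile":
        if group == "neuropathic":
            w = (10.85 - 8.31) / (16.0 - 8.31)
            return EvokedProfile(1.5 * gain, 8.31, 1.2, (0.0, 40.0), 16.0, 1.5, w)
        if group == "inflammatory":
            w = (10.41 - 8.31) / (16.0 - 8.31)
            return EvokedProfile(1.5 * gain, 8.31, 1.2, (0.0, 40.0), 16.0, 1.5, w)
        return EvokedProfile(1.5, 8.31, 1.2, (0.0, 40.0))
    if modality == "noxious_press":
        return EvokedProfile(8.0 * gain, 90.0, 80.0, (0.0, 500.0))
    if modality == "proprioceptive":
        return EvokedProfile(6.0 * gain, 50.0, 30.0, (0.0, 400.0), 250.0, 40.0, 0.5)
    if modality == "noxious_thermal":
        return EvokedProfile(35.0 * gain, 1150.0, 150.0, (800.0, 1500.0),
                             sustained_mean_count=25.0 * gain)
    raise ConfigurationError(f"unknown modality {modality!r}")


#: lower bounds of the reported percent reductions of windowed evoked counts
#: during DC, as generated-truth fractions r per (group, modality, window).
#: A value of 0 encodes "no significant reduction reported".
DEFAULT_REDUCTIONS: dict[str, dict[str, dict[str, float]]] = {
    "naive": {
        "noxious_thermal": {"main": 0.397, "sustained": 0.0},
        "noxious_press": {"main": 0.221},
        "tactile": {"main": 0.0},
        "proprioceptive": {"main": 0.290},
    },
    "neuropathic": {
        "noxious_thermal": {"main": 0.705, "sustained": 0.564},
        "noxious_press": {"main": 0.259},
        "tactile": {"main": 0.576},
        "proprioceptive": {"main": 0.0},
    },
    "inflammatory": {
        "noxious_thermal": {"main": 0.705, "sustained": 0.564},
        "noxious_press": {"main": 0.259},
        # tactile reduction in the inflammatory group was only seen at 1000 uA
        "tactile": {"main": {500.0: 0.0, 1000.0: 0.305}},
        "proprioceptive": {"main": 0.0},
    },
}

#: post-DC block-release half-lives (minutes) per modality; chosen to
#: reproduce the observed recovery ordering tactile < press < thermal.
DEFAULT_RECOVERY_HALFLIFE_MIN = {
    "noxious_thermal": 20.0,
    "noxious_press": 8.0,
    "tactile": 2.0,
    "proprioceptive": 1.0,
}


@dataclass
class GeneratorConfig:
    modality: str = "tactile"
    treatment_group: str = "naive"
    sex: str = "F"
    n_units_per_modality: int = 4
    sampling_rate: float = 30000.0
    noise_sd_uV: float = 5.0
    snr: float = 8.0
    spontaneous_rate: float = 5.0            # spikes/s per unit
    dc_spontaneous_gain: float = 1.1         # multiplicative, during DC only
    cathodic_spontaneous_offset: float = 0.0  # optional extra gain for cathodic centre
    evoked_profile: EvokedProfile | None = None
    dc_reduction: dict | None = None          # window -> r, or window -> {amplitude: r}
    recovery_halflife_min: float | None = None
    unit_gain_sd: float = 0.25               # log-scale between-unit evoked gain
    animal_gain_sd: float = 0.10             # log-scale between-animal gain
    n_pre_sets: int = 2
    n_post_sets: int = 9
    post_interval_min: float = 5.0
    n_stimuli: int | None = None
    #: if True all units share one 3-channel footprint (one channel group,
    #: the spike-sorting scenario); otherwise footprints tile distinct triples
    shared_footprint: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.modality not in MODALITIES:
            raise ConfigurationError(f"unknown modality {self.modality!r}")
        if self.treatment_group not in GROUPS:
            raise ConfigurationError(f"unknown group {self.treatment_group!r}")
        if self.snr <= 0:
            raise ConfigurationError("snr must be > 0")
        if self.spontaneous_rate < 0:
            raise ConfigurationError("rates must be >= 0")
        if self.dc_spontaneous_gain < 1.0:
            raise ConfigurationError("dc_spontaneous_gain must be >= 1")
        if self.evoked_profile is None:
            self.evoked_profile = default_profile(self.modality, self.treatment_group)
        if self.dc_reduction is None:
            self.dc_reduction = {
                k: (dict(v) if isinstance(v, dict) else v)
                for k, v in DEFAULT_REDUCTIONS[self.treatment_group][self.modality].items()
            }
        for r in self.dc_reduction.values():
            vals = r.values() if isinstance(r, dict) else [r]
            if any(not 0.0 <= v <= 1.0 for v in vals):
                raise ConfigurationError("reduction fraction r must be in [0, 1]")
        if self.recovery_halflife_min is None:
            self.recovery_halflife_min = DEFAULT_RECOVERY_HALFLIFE_MIN[self.modality]

    def reduction(self, window: str, amplitude_uA: float) -> float:
        r = self.dc_reduction.get(window, 0.0)
        if isinstance(r, dict):
            return r.get(float(amplitude_uA), r.get(int(amplitude_uA), 0.0))
        return float(r)


@dataclass
class UnitTruth:
    unit_id: int
    animal_id: str
    modality: str
    gain: float                     # multiplicative evoked-count gain
    channel_start: int              # first channel of the 3-channel footprint
    template_id: int
    tau_release_s: float            # post-DC block release time
    expected_window_counts: dict = field(default_factory=dict)
    # window -> {"pre": mu, amplitude: (1-r)*mu}


@dataclass
class GroundTruth:
    units: dict[int, UnitTruth]
    reductions: dict                # window -> {amplitude: r}

    def expected_pre(self, window: str = "main") -> float:
        return float(np.mean([u.expected_window_counts[window]["pre"]
                              for u in self.units.values()]))


@dataclass
class SpikeSet:
    """One recording set at spike level: per-unit true spike times (seconds
    from set start), triggers, and the DC condition."""
    set_id: str
    animal_id: str
    group: str
    sex: str
    paradigm: StimulusParadigm
    schedule: DCSchedule
    triggers_s: np.ndarray
    duration_s: float
    unit_times: dict[int, np.ndarray]
    sampling_rate: float = 30000.0

    @property
    def phase(self) -> str:
        return self.schedule.phase


@dataclass
class Session:
    config: GeneratorConfig
    truth: GroundTruth
    sets: list[SpikeSet]

    def sets_by_phase(self, phase: str) -> list[SpikeSet]:
        return [s for s in self.sets if s.phase == phase]


# --------------------------------------------------------------------------
# templates & geometry
# --------------------------------------------------------------------------

def poly2_geometry(n_channels: int = 32, spacing_um: float = 50.0) -> np.ndarray:
    """Two-column poly layout; returns (n, 2) x/y positions in um, ordered by
    depth so that consecutive indices are spatially adjacent."""
    pos = np.zeros((n_channels, 2))
    pos[:, 0] = (np.arange(n_channels) % 2) * spacing_um / 2.0
    pos[:, 1] = np.arange(n_channels) * spacing_um / 2.0
    return pos


def adjacent_triples(geometry: np.ndarray) -> list[tuple[int, int, int]]:
    n = len(geometry)
    if n < 3:
        raise ConfigurationError("geometry must have at least 3 channels")
    order = np.argsort(geometry[:, 1], kind="stable")
    return [tuple(order[i:i + 3]) for i in range(n - 2)]


TEMPLATE_PRE = 18      # samples before the negative peak at 30 kHz (0.6 ms)
TEMPLATE_POST = 30     # samples after (1.0 ms); total 48 samples (~1.6 ms)


def _spike_shape(rng, n=TEMPLATE_PRE + TEMPLATE_POST):
    """One normalised (trough = -1) extracellular waveform: asymmetric
    trough, optional pre-spike positivity, and a slower rebound."""
    t = np.arange(n, dtype=float) - TEMPLATE_PRE
    w_rise = rng.uniform(1.5, 4.0)
    w_fall = rng.uniform(2.0, 7.0)
    trough = -np.where(t < 0, np.exp(-0.5 * (t / w_rise) ** 2),
                       np.exp(-0.5 * (t / w_fall) ** 2))
    a_pre = rng.uniform(0.0, 0.35)
    d_pre = w_rise * rng.uniform(1.5, 3.0)
    pre = a_pre * np.exp(-0.5 * ((t + d_pre) / w_rise) ** 2)
    a_reb = rng.uniform(0.15, 0.6)
    d_reb = w_fall * rng.uniform(1.2, 3.0)
    w_reb = w_fall * rng.uniform(1.5, 3.0)
    reb = a_reb * np.exp(-0.5 * ((t - d_reb) / w_reb) ** 2)
    w = trough + pre + reb
    return w / np.abs(w.min())


def make_templates(n_units: int, geometry: np.ndarray, seed: int,
                   snr: float = 8.0, noise_sd_uV: float = 5.0,
                   max_similarity: float = 0.75) -> np.ndarray:
    """Draw ``n_units`` biphasic 3-channel waveform footprints.

    The dominant (centre) channel peaks at ``snr * noise_sd_uV``; flanking
    channels are attenuated by at least 40%.  Templates are redrawn until all
    pairwise normalised cross-correlations fall below ``max_similarity``.
    Returns an array of shape (n_units, 3, 48), in uV.
    """
    if n_units < 1:
        raise ConfigurationError("n_units must be >= 1")
    if len(geometry) < 3:
        raise ConfigurationError("geometry must have at least 3 channels")
    rng = np.random.default_rng(seed)
    peak = snr * noise_sd_uV
    templates: list[np.ndarray] = []
    for _ in range(n_units):
        for _attempt in range(500):
            shape = _spike_shape(rng)
            # units sit at different depths: the dominant channel varies
            # within the triple, flanks attenuated by >= 40%
            dom = int(rng.integers(3))
            atten = rng.uniform(0.0, 0.6, size=3)
            atten[dom] = 1.0
            tpl = np.stack([shape * a for a in atten]) * peak
            v = tpl.ravel()
            if all(abs(np.dot(v, o.ravel())) / (np.linalg.norm(v) * np.linalg.norm(o))
                   < max_similarity for o in templates):
                templates.append(tpl)
                break
        else:  # pragma: no cover - extremely unlikely
            raise RuntimeError("could not draw a sufficiently distinct template")
    return np.stack(templates)


# --------------------------------------------------------------------------
# spike-time samplers
# --------------------------------------------------------------------------

def _truncated_mixture(n, profile: EvokedProfile, rng) -> np.ndarray:
    lo, hi = profile.support_ms
    out = np.empty(n)
    use2 = rng.random(n) < profile.second_weight
    mu = np.where(use2, profile.second_latency_ms or profile.latency_ms, profile.latency_ms)
    sd = np.where(use2, profile.second_sd_ms or profile.latency_sd_ms, profile.latency_sd_ms)
    out = rng.normal(mu, sd)
    bad = (out < lo) | (out >= hi)
    for _ in range(100):
        if not bad.any():
            break
        out[bad] = rng.normal(mu[bad], sd[bad])
        bad = (out < lo) | (out >= hi)
    return np.clip(out, lo, np.nextafter(hi, lo))


def sample_evoked_times(paradigm: StimulusParadigm, profile: EvokedProfile,
                        seed=None, rng=None, gain: float = 1.0) -> list[np.ndarray]:
    """Per-trial evoked spike times (seconds relative to the trigger).

    Counts are Poisson; latencies follow the profile's truncated (mixture)
    normal; the thermal sustained tail is an independent homogeneous Poisson
    component on its own span.  A zero-rate profile yields empty trains.
    """
    rng = np.random.default_rng(seed) if rng is None else rng
    trials = []
    for _ in range(paradigm.n_stimuli):
        n = rng.poisson(profile.mean_count * gain)
        t = _truncated_mixture(n, profile, rng) if n else np.empty(0)
        if profile.sustained_mean_count > 0:
            m = rng.poisson(profile.sustained_mean_count * gain)
            lo, hi = profile.sustained_span_ms
            t = np.concatenate([t, rng.uniform(lo, hi, size=m)])
        trials.append(np.sort(t) / 1000.0)
    return trials


def _enforce_refractory(times: np.ndarray, dead_s: float = REFRACTORY_S) -> np.ndarray:
    if times.size < 2:
        return times
    times = np.sort(times)
    keep = [times[0]]
    for t in times[1:]:
        if t - keep[-1] >= dead_s:
            keep.append(t)
    return np.asarray(keep)


# --------------------------------------------------------------------------
# DC effect
# --------------------------------------------------------------------------

def apply_dc_effect(times: np.ndarray, triggers_s: np.ndarray, windows_ms: dict,
                    reduction, schedule: DCSchedule, seed=None, rng=None,
                    tau_release_s: float = math.inf,
                    spontaneous_rate: float = 0.0,
                    spontaneous_gain: float = 1.0,
                    duration_s: float | None = None) -> np.ndarray:
    """Apply the DC condition to one unit's spike train of one set.

    During DC, spikes falling inside a response window (trial-relative
    ``windows_ms``: name -> (lo, hi) ms) are independently thinned with the
    window's reduction probability r, so the expected windowed count is
    exactly (1-r) times its pre-DC value; spontaneous firing outside the
    windows is scaled by ``spontaneous_gain`` (extra superposed Poisson
    spikes).  Post DC, the unit is still fully thinned (probability r) until
    its block-release time ``tau_release_s`` and unaffected afterwards, so
    the population-average thinning decays as r * 2^(-t/halflife) when
    release times are exponential with median equal to the half-life.
    """
    if schedule.phase == "pre":
        return times
    rng = np.random.default_rng(seed) if rng is None else rng
    red = reduction if isinstance(reduction, dict) else {"main": reduction}
    for r in red.values():
        if not 0.0 <= r <= 1.0:
            raise ConfigurationError("reduction fraction r must be in [0, 1]")
    released = (schedule.phase == "post"
                and schedule.time_since_dc_end_s is not None
                and schedule.time_since_dc_end_s >= tau_release_s)
    out = np.asarray(times, dtype=float)
    if not released:
        keep = np.ones(out.size, dtype=bool)
        for name, (lo, hi) in windows_ms.items():
            r = red.get(name, 0.0)
            if r == 0.0 or out.size == 0:
                continue
            rel = (out[None, :] - triggers_s[:, None]) * 1000.0
            in_win = ((rel >= lo) & (rel < hi)).any(axis=0)
            keep[in_win] &= rng.random(out.size)[in_win] >= r
        out = out[keep]
    if schedule.phase == "during" and spontaneous_gain > 1.0 and spontaneous_rate > 0:
        dur = duration_s if duration_s is not None else (out.max() if out.size else 0.0)
        extra = rng.poisson((spontaneous_gain - 1.0) * spontaneous_rate * dur)
        t_extra = rng.uniform(0.0, dur, size=extra)
        rel = (t_extra[None, :] - triggers_s[:, None]) * 1000.0
        in_any = np.zeros(extra, dtype=bool)
        for lo, hi in windows_ms.values():
            in_any |= ((rel >= lo) & (rel < hi)).any(axis=0)
        t_extra = t_extra[~in_any]
        # added spikes must respect the unit's dead time; the base train
        # (already refractory-clean) has priority so thinning statistics
        # inside the response windows are untouched
        if out.size and t_extra.size:
            idx = np.searchsorted(out, t_extra)
            prev = np.where(idx > 0, t_extra - out[np.maximum(idx - 1, 0)], np.inf)
            nxt = np.where(idx < out.size, out[np.minimum(idx, out.size - 1)] - t_extra, np.inf)
            t_extra = t_extra[(prev >= REFRACTORY_S) & (nxt >= REFRACTORY_S)]
        out = np.sort(np.concatenate([out, _enforce_refractory(t_extra)]))
    return out


# --------------------------------------------------------------------------
# session generation
# --------------------------------------------------------------------------

def _dc_permutations(rng) -> list[tuple[float, str]]:
    perms = [(a, p) for a in (500.0, 1000.0) for p in ("cathodic_centre", "anodic_centre")]
    return [perms[i] for i in rng.permutation(4)]


def _set_layout(paradigm: StimulusParadigm, modality: str):
    pre_s, post_s = TRIAL_SPAN_S[modality]
    first = 2.0  # leaves a stimulus-free baseline for multi-unit rates
    triggers = first + np.arange(paradigm.n_stimuli) * paradigm.inter_stimulus_interval_s
    duration = float(triggers[-1] + post_s + 0.5)
    return triggers, duration


def generate_session(config: GeneratorConfig, animal_id: str = "A0",
                     unit_id_start: int = 0) -> Session:
    """Generate one animal's session for one modality response.

    Layout: ``n_pre_sets`` pre-DC sets, four during-DC sets covering the
    {500, 1000} uA x {cathodic, anodic} permutations in pseudorandom order,
    and ``n_post_sets`` post-DC sets at increasing time since DC end.
    """
    rng = np.random.default_rng(config.seed)
    modality = config.modality
    paradigm = default_paradigm(modality, config.n_stimuli)
    profile = config.evoked_profile
    triggers, duration = _set_layout(paradigm, modality)
    windows = TRUE_WINDOWS_MS[modality]

    halflife_s = config.recovery_halflife_min * 60.0
    animal_gain = float(np.exp(rng.normal(0.0, config.animal_gain_sd)))
    n_units = config.n_units_per_modality
    units: dict[int, UnitTruth] = {}
    for i in range(n_units):
        uid = unit_id_start + i
        gain = animal_gain * float(np.exp(rng.normal(0.0, config.unit_gain_sd)))
        tau = float(rng.exponential(halflife_s / math.log(2.0)))
        expected = {}
        for name, (lo, hi) in windows.items():
            mass = profile.sustained_mean_count if name == "sustained" else profile.mean_count
            mu = gain * mass + config.spontaneous_rate * (hi - lo) / 1000.0
            expected[name] = {"pre": mu}
            for amp in (500.0, 1000.0):
                expected[name][amp] = (1.0 - config.reduction(name, amp)) * mu
        c0 = 0 if config.shared_footprint else 3 * (i % 10)
        units[uid] = UnitTruth(uid, animal_id, modality, gain, c0, i, tau, expected)

    schedules: list[DCSchedule] = []
    for _ in range(config.n_pre_sets):
        schedules.append(DCSchedule("pre"))
    for amp, pol in _dc_permutations(rng):
        schedules.append(DCSchedule("during", amp, pol))
    for k in range(config.n_post_sets):
        t = (k + 1) * config.post_interval_min * 60.0
        schedules.append(DCSchedule("post", time_since_dc_end_s=t))

    sets = []
    for idx, sched in enumerate(schedules):
        unit_times = {}
        for uid, ut in units.items():
            evoked = sample_evoked_times(paradigm, profile, rng=rng, gain=ut.gain)
            t_evoked = np.concatenate(
                [trig + tr for trig, tr in zip(triggers, evoked)]) if evoked else np.empty(0)
            n_spont = rng.poisson(config.spontaneous_rate * duration)
            t_spont = rng.uniform(0.0, duration, size=n_spont)
            # dead time is enforced on the base train BEFORE any DC thinning,
            # so the (1-r) windowed-count relation holds exactly by construction
            t_all = _enforce_refractory(np.sort(np.concatenate([t_evoked, t_spont])))
            if sched.phase != "pre":
                red = {name: config.reduction(name, sched.amplitude_uA or 1000.0)
                       for name in windows}
                gain_sp = config.dc_spontaneous_gain
                if sched.polarity == "cathodic_centre":
                    gain_sp += config.cathodic_spontaneous_offset
                t_all = apply_dc_effect(
                    t_all, triggers, windows, red, sched, rng=rng,
                    tau_release_s=ut.tau_release_s,
                    spontaneous_rate=config.spontaneous_rate,
                    spontaneous_gain=gain_sp, duration_s=duration)
            unit_times[uid] = t_all
        sets.append(SpikeSet(
            set_id=f"{animal_id}-{modality}-{idx:02d}", animal_id=animal_id,
            group=config.treatment_group, sex=config.sex, paradigm=paradigm,
            schedule=sched, triggers_s=triggers.copy(), duration_s=duration,
            unit_times=unit_times, sampling_rate=config.sampling_rate))

    reductions = {name: {amp: config.reduction(name, amp) for amp in (500.0, 1000.0)}
                  for name in windows}
    return Session(config=config, truth=GroundTruth(units, reductions), sets=sets)


def generate_cohort(config: GeneratorConfig, n_animals: int,
                    units_per_animal: int) -> list[Session]:
    """Several single-animal sessions with distinct per-animal seeds and
    globally unique unit ids (units nested within animals)."""
    seeds = np.random.SeedSequence(config.seed).generate_state(n_animals)
    sessions = []
    for a in range(n_animals):
        cfg = replace(config, n_units_per_modality=units_per_animal,
                      seed=int(seeds[a] % (2 ** 31)))
        sessions.append(generate_session(cfg, animal_id=f"A{a}",
                                         unit_id_start=a * units_per_animal))
    return sessions


# --------------------------------------------------------------------------
# voltage rendering & container I/O
# --------------------------------------------------------------------------

def render_voltage(spike_set: SpikeSet, truth: GroundTruth, templates: np.ndarray,
                   n_channels: int = 32, noise_sd_uV: float = 5.0,
                   seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Render one set to a (channels x samples) voltage matrix in uV.

    Gaussian noise of sd ``noise_sd_uV`` plus linear superposition of each
    unit's 3-channel template at its spike samples.  Returns (voltage,
    trigger sample indices).
    """
    fs = spike_set.sampling_rate
    n_samp = int(round(spike_set.duration_s * fs))
    rng = np.random.default_rng(seed)
    v = rng.standard_normal((n_channels, n_samp)) * noise_sd_uV if noise_sd_uV > 0 \
        else np.zeros((n_channels, n_samp))
    for uid, times in spike_set.unit_times.items():
        ut = truth.units[uid]
        tpl = templates[ut.template_id]
        c0 = ut.channel_start
        if c0 + 3 > n_channels:
            raise ConfigurationError("unit footprint outside the channel count")
        samples = np.round(times * fs).astype(int)
        for s in samples:
            a, b = s - TEMPLATE_PRE, s + TEMPLATE_POST
            ta, tb = max(0, -a), tpl.shape[1] - max(0, b - n_samp)
            a, b = max(a, 0), min(b, n_samp)
            if a < b:
                v[c0:c0 + 3, a:b] += tpl[:, ta:tb]
    trig = np.round(spike_set.triggers_s * fs).astype(int)
    return v, trig


def save_set_hdf5(path, voltage_uV: np.ndarray, trigger_samples: np.ndarray,
                  spike_set: SpikeSet, geometry: np.ndarray,
                  scale_uV_per_bit: float = 0.05) -> None:
    """Write one rendered set to an HDF5 container (int16 voltage with a uV
    scale attribute) plus a JSON metadata sidecar."""
    import h5py

    path = str(path)
    with h5py.File(path, "w") as f:
        q = np.clip(np.round(voltage_uV / scale_uV_per_bit), -32768, 32767).astype(np.int16)
        d = f.create_dataset("voltage", data=q)
        d.attrs["scale_uV_per_bit"] = scale_uV_per_bit
        f.create_dataset("triggers", data=trigger_samples.astype(np.int64))
        f.attrs["sampling_rate"] = spike_set.sampling_rate
        f.create_dataset("geometry", data=geometry)
    meta = {
        "set_id": spike_set.set_id, "animal_id": spike_set.animal_id,
        "group": spike_set.group, "sex": spike_set.sex,
        "phase": spike_set.schedule.phase,
        "amplitude_uA": spike_set.schedule.amplitude_uA,
        "polarity": spike_set.schedule.polarity,
        "time_since_dc_end_s": spike_set.schedule.time_since_dc_end_s,
        "paradigm": asdict(spike_set.paradigm),
        "ground_truth_spike_samples": {
            str(uid): np.round(t * spike_set.sampling_rate).astype(int).tolist()
            for uid, t in spike_set.unit_times.items()},
    }
    with open(path + ".json", "w") as f:
        json.dump(meta, f)


def load_set_hdf5(path):
    """Read a container written by :func:`save_set_hdf5`.

    Returns (voltage uV, trigger samples, sampling_rate, geometry, metadata).
    """
    import h5py

    path = str(path)
    with h5py.File(path, "r") as f:
        scale = f["voltage"].attrs["scale_uV_per_bit"]
        v = f["voltage"][()].astype(float) * scale
        trig = f["triggers"][()]
        fs = float(f.attrs["sampling_rate"])
        geom = f["geometry"][()]
    with open(path + ".json") as f:
        meta = json.load(f)
    return v, trig, fs, geom, meta
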