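"""Synthetic continuous EEG for a stimulation schedule.

The simulator embeds the evoked-component structure the downstream analyses
are designed to detect: obligatory P1/N1/P2 deflections on every sound, a
frontocentral mismatch negativity (MMN) on within-pair deviants, a
frontocentral P3a on train deviants, and a centroparietal P3b on train
deviants in the active condition only.  Components are Gaussian-windowed
deflections with per-channel gains derived from two-pole (frontocentral /
centroparietal) synthetic topographies; ongoing activity is spatially
correlated 1/f noise plus a posterior alpha rhythm.  Signals are expressed
against the online reference CPz, and the mastoids carry noise only, so the
offline re-reference step behaves as it would on a real recording.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, replace

import numpy as np

from .montage import Montage, standard_montage
from .paradigm import EventSchedule, ParadigmConfig, StimulusEvent, generate_session
from ._utils import stage_rng

__all__ = [
    "ComponentSpec",
    "NoiseSpec",
    "RawRecording",
    "build_default_components",
    "component_topography",
    "simulate_recording",
    "simulate_participant",
    "simulate_cohort",
]

#: Gaussian full-width-at-half-maximum to sigma.
_FWHM = 2.0 * np.sqrt(2.0 * np.log(2.0))

#: Event-role predicates a component can attach to.
ROLES = ("any", "deviant_second", "st_second")


@dataclass(frozen=True)
class ComponentSpec:
    """One evoked component: a Gaussian deflection with a scalp gain map."""

    name: str
    peak_latency_ms: float
    half_width_ms: float               # FWHM of the Gaussian envelope
    amplitude_uv: float                # signed peak amplitude at the topography pole
    topography: str = "frontocentral"  # "frontocentral" | "centroparietal"
    applies_to: str = "any"            # role predicate, see ROLES
    active_only: bool = False
    latency_jitter_sd_ms: float = 10.0

    def __post_init__(self):
        if self.half_width_ms <= 0:
            raise ValueError("half_width_ms must be > 0")
        if self.applies_to not in ROLES:
            raise ValueError(f"unknown role {self.applies_to!r}")

    def applies(self, event: StimulusEvent, condition: str) -> bool:
        if self.active_only and condition != "active":
            return False
        if self.applies_to == "any":
            return True
        if event.position != "second":
            return False
        if self.applies_to == "deviant_second":
            return event.pair_type in ("SF", "ST")
        return event.pair_type == "ST"   # "st_second"


@dataclass(frozen=True)
class NoiseSpec:
    """Ongoing-activity model: spatially correlated 1/f noise plus alpha."""

    one_over_f_exponent: float = 1.0
    broadband_sd_uv: float = 8.0
    alpha_amplitude_uv: float = 3.0
    alpha_freq_hz: float = 10.0
    spatial_smoothing: float = 0.5     # neighbor-mixing weight in [0, 1)
    artifact_rate: float = 0.0         # fraction of pairs given +/-150 uV excursions

    def __post_init__(self):
        if self.broadband_sd_uv < 0 or self.one_over_f_exponent < 0:
            raise ValueError("noise sd and spectral exponent must be >= 0")
        if not 0 <= self.spatial_smoothing < 1:
            raise ValueError("spatial_smoothing must be in [0, 1)")
        if not 0 <= self.artifact_rate <= 1:
            raise ValueError("artifact_rate must be in [0, 1]")


@dataclass
class RawRecording:
    """Continuous multichannel signal in microvolts with embedded events."""

    data: np.ndarray                   # (channels, samples)
    srate: float
    montage: Montage
    events: EventSchedule
    reference: str = "CPz"
    participant_id: str = "sim"

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def event_sample(self, ev: StimulusEvent) -> int:
        return int(round(ev.onset_ms * self.srate / 1000.0))


# Default component parameters: latencies follow canonical auditory ERP
# timing (P1 76, N1 124, P2 184, MMN 148, P3a 248, P3b 330 ms).  Amplitudes
# are free parameters of the generator, set in the upper part of the
# canonical per-component ranges so that full-length sessions yield the
# near-ceiling individual detectability this paradigm is designed for
# (topographic gain, latency jitter, and filtering attenuate the effective
# evoked amplitude by roughly half at a single electrode).
_DEFAULTS = [
    ("P1", 76.0, 30.0, 2.5, "frontocentral", "any", False),
    ("N1", 124.0, 36.0, -4.0, "frontocentral", "any", False),
    ("P2", 184.0, 48.0, 3.0, "frontocentral", "any", False),
    ("MMN", 148.0, 44.0, -3.5, "frontocentral", "deviant_second", False),
    ("P3a", 248.0, 60.0, 5.0, "frontocentral", "st_second", False),
    ("P3b", 330.0, 80.0, 5.0, "centroparietal", "st_second", True),
]


def build_default_components(condition: str) -> list[ComponentSpec]:
    """Default component set for a condition; passive drops the P3b."""
    if condition not in ("active", "passive"):
        raise ValueError(f"unknown condition {condition!r}")
    specs = [ComponentSpec(*row) for row in _DEFAULTS]
    return [c for c in specs if not (c.active_only and condition != "active")]


def component_topography(kind: str, montage: Montage) -> np.ndarray:
    """Per-channel gain in [0, 1]: Gaussian fall-off from a scalp pole.

    Gains are expressed against the online reference (CPz subtracted), and
    the mastoids carry no component signal, mimicking signal-free reference
    sites; consequently gains of the recorded signal may be negative at
    channels far from the pole.
    """
    pos = montage.positions
    if kind == "frontocentral":
        pole = pos[montage.index("FCz")]
    elif kind == "centroparietal":
        a, b = montage.index("CPz"), montage.index("Pz")
        pole = pos[a] + pos[b]
        pole /= np.linalg.norm(pole)
    else:
        raise ValueError(f"unknown topography {kind!r}")
    d = np.linalg.norm(pos - pole, axis=1)
    gain = np.exp(-(d**2) / (2 * 0.45**2))
    gain /= gain.max()
    for ch in montage.offline_reference:
        gain[montage.index(ch)] = 0.0
    return gain


def _recorded_gains(comp: ComponentSpec, montage: Montage) -> np.ndarray:
    g = component_topography(comp.topography, montage)
    return g - g[montage.index("CPz")]


def _one_over_f_noise(rng, n_ch, n_samp, srate, exponent, sd):
    """FFT-shaped Gaussian noise with a 1/f^exponent amplitude spectrum."""
    if sd == 0:
        return np.zeros((n_ch, n_samp))
    freqs = np.fft.rfftfreq(n_samp, d=1.0 / srate)
    shape = np.zeros_like(freqs)
    shape[1:] = freqs[1:] ** (-exponent / 2.0)
    spec = (rng.standard_normal((n_ch, len(freqs)))
            + 1j * rng.standard_normal((n_ch, len(freqs)))) * shape
    x = np.fft.irfft(spec, n=n_samp, axis=1)
    x *= sd / x.std(axis=1, keepdims=True)
    return x


def _make_noise(rng, montage: Montage, n_samp: int, srate: float,
                noise: NoiseSpec) -> np.ndarray:
    n_ch = len(montage.labels)
    x = _one_over_f_noise(rng, n_ch, n_samp, srate,
                          noise.one_over_f_exponent, noise.broadband_sd_uv)
    if noise.alpha_amplitude_uv > 0:
        t = np.arange(n_samp) / srate
        # Posterior-dominant alpha: gain peaks over parieto-occipital sites.
        pole = montage.positions[montage.index("POz")]
        d = np.linalg.norm(montage.positions - pole, axis=1)
        gain = np.exp(-(d**2) / (2 * 0.6**2))
        phase = rng.uniform(0, 2 * np.pi, n_ch)
        x += (noise.alpha_amplitude_uv * gain)[:, None] * np.sin(
            2 * np.pi * noise.alpha_freq_hz * t[None, :] + phase[:, None])
    c = noise.spatial_smoothing
    if c > 0:
        # One neighbor-mixing pass; approximate neighbor correlation ~ c.
        deg = montage.adjacency.sum(axis=1, keepdims=True).astype(float)
        deg[deg == 0] = 1.0
        mixed = (1 - c) * x + c * (montage.adjacency @ x) / deg
        sd_x = x.std(axis=1, keepdims=True)
        sd_m = mixed.std(axis=1, keepdims=True)
        sd_m[sd_m == 0] = 1.0
        x = mixed * (sd_x / sd_m)
    return x


def _add_artifacts(rng, data, srate, schedule, rate, amplitude_uv=150.0):
    """Square-pulse excursions exceeding the rejection threshold."""
    pairs = schedule.events[1::2]
    n_art = int(round(rate * len(pairs)))
    if n_art == 0:
        return
    width = int(0.1 * srate)
    for k in rng.choice(len(pairs), size=n_art, replace=False):
        ev = pairs[k]
        start = int(round(ev.onset_ms * srate / 1000.0))
        ch = rng.integers(data.shape[0])
        sign = rng.choice([-1.0, 1.0])
        stop = min(start + width, data.shape[1])
        data[ch, start:stop] += sign * amplitude_uv


def simulate_recording(schedule: EventSchedule,
                       components: list[ComponentSpec] | None = None,
                       noise: NoiseSpec | None = None,
                       montage: Montage | None = None,
                       seed: int = 0,
                       srate: float = 1000.0,
                       post_ms: float = 1000.0,
                       participant_id: str = "sim") -> RawRecording:
    """Render a schedule into continuous EEG (microvolts).

    data = sum of component deflections at their event onsets (with
    per-event latency jitter) + correlated 1/f + alpha noise.  Deterministic
    under ``seed``; the component sum and the noise use separate child
    streams so that simulations differing only in component content share
    the noise realization bit-for-bit (additivity).
    """
    montage = montage or standard_montage()
    noise = noise or NoiseSpec()
    if components is None:
        components = build_default_components(schedule.condition)
    if any(e.onset_ms is None for e in schedule.events):
        raise ValueError("schedule has unset onsets")

    n_samp = int(np.ceil((schedule.events[-1].onset_ms + post_ms) * srate / 1000.0))
    rng_noise = np.random.default_rng(np.random.SeedSequence([seed, 0]))
    rng_art = np.random.default_rng(np.random.SeedSequence([seed, 2]))

    data = _make_noise(rng_noise, montage, n_samp, srate, noise)
    cond = schedule.condition
    for comp in components:
        # Per-component jitter stream keyed by name: the simulation is then
        # additive over the component set under a common seed.
        rng_comp = np.random.default_rng(
            np.random.SeedSequence([seed, 1, zlib.crc32(comp.name.encode())]))
        gains = _recorded_gains(comp, montage)
        sigma = comp.half_width_ms / _FWHM / 1000.0 * srate
        half = int(np.ceil(4 * sigma))
        kernel_t = np.arange(-half, half + 1)
        for ev in schedule.events:
            if not comp.applies(ev, cond):
                continue
            jitter = rng_comp.normal(0.0, comp.latency_jitter_sd_ms)
            center = (ev.onset_ms + comp.peak_latency_ms + jitter) * srate / 1000.0
            c0 = int(round(center))
            if c0 + half >= n_samp or c0 - half < 0:
                if c0 - half >= n_samp:
                    raise ValueError("event beyond allocated recording duration")
                continue
            wave = comp.amplitude_uv * np.exp(-((kernel_t - (center - c0)) ** 2)
                                              / (2 * sigma**2))
            data[:, c0 - half:c0 + half + 1] += gains[:, None] * wave[None, :]
    if noise.artifact_rate > 0:
        _add_artifacts(rng_art, data, srate, schedule, noise.artifact_rate)
    return RawRecording(data=data, srate=srate, montage=montage, events=schedule,
                        participant_id=participant_id)


def _perturbed(components, rng, amp_sd_frac, latency_shift_sd_ms=5.0):
    """Per-participant component perturbations, shared across sessions."""
    out = []
    for comp in components:
        scale = max(0.0, 1.0 + amp_sd_frac * rng.standard_normal())
        shift = latency_shift_sd_ms * rng.standard_normal() if amp_sd_frac > 0 else 0.0
        out.append(replace(comp,
                           amplitude_uv=comp.amplitude_uv * scale,
                           peak_latency_ms=comp.peak_latency_ms + shift))
    return out


def simulate_participant(p: int,
                         config: ParadigmConfig | None = None,
                         components: list[ComponentSpec] | None = None,
                         noise: NoiseSpec | None = None,
                         between_subject_sd: float = 0.2,
                         seed: int = 0,
                         montage: Montage | None = None,
                         srate: float = 1000.0,
                         ) -> tuple[RawRecording, RawRecording]:
    """Simulate one participant's paired (active, passive) sessions.

    The participant gets one schedule (identical auditory stimulation in
    both sessions) and one set of amplitude/latency perturbations shared by
    both sessions; noise realizations differ between sessions.
    """
    config = config or ParadigmConfig()
    montage = montage or standard_montage()
    base_active = components or build_default_components("active")
    pid = f"sub-{p + 1:02d}"
    sched_cfg = replace(config, seed=int(stage_rng(seed, "schedule", p).integers(2**31)))
    subj_rng = stage_rng(seed, "subject", p)
    comps_active = _perturbed(base_active, subj_rng, between_subject_sd)
    comps_passive = [c for c in comps_active if not c.active_only]
    recs = {}
    for cond, comps in (("active", comps_active), ("passive", comps_passive)):
        schedule = generate_session(sched_cfg, cond)
        recs[cond] = simulate_recording(
            schedule, comps, noise, montage,
            seed=int(stage_rng(seed, f"noise-{cond}", p).integers(2**31)),
            srate=srate, participant_id=pid)
    return recs["active"], recs["passive"]


def simulate_cohort(n_participants: int,
                    config: ParadigmConfig | None = None,
                    components: list[ComponentSpec] | None = None,
                    noise: NoiseSpec | None = None,
                    between_subject_sd: float = 0.2,
                    seed: int = 0,
                    montage: Montage | None = None,
                    srate: float = 1000.0) -> list[tuple[RawRecording, RawRecording]]:
    """Simulate paired (active, passive) sessions for a whole cohort."""
    if n_participants < 1:
        raise ValueError("n_participants must be >= 1")
    return [
        simulate_participant(p, config, components, noise, between_subject_sd,
                             seed, montage, srate)
        for p in range(n_participants)
    ]
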