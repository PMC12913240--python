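"""Signal chain and epoch/contrast extraction.

The continuous recording is sequentially notch-filtered at 50 Hz,
high-passed at 1 Hz and low-passed at 30 Hz (zero-phase FIR throughout, so
component latencies are preserved), re-referenced to the mastoid mean
(M1/M2), and down-sampled to 250 Hz.  Five condition contrasts are then cut
into baseline-corrected epochs:

======================  =======================================================
P1N1P2                  first standard S of each pair (-100..350 ms) vs the
                        resting-state interval immediately before S onset
                        (-450..0 ms, baseline -450..-350 ms)
Local_SF / Local_ST     second-stimulus deviant (F or T) vs the first S of the
                        same pair, both -100..350 ms
Global_SS_ST1           T of an S-T pair in an S-S context vs the second S of
Global_SF_ST2           the immediately preceding S-S pair (resp. F of the
                        preceding S-F pair), both -100..800 ms
======================  =======================================================

Amplitude artifact rejection (+/-100 uV on any non-reference channel) is
*matched*: the two members of a trial pair are rejected concurrently, so the
two conditions of a contrast always keep equal trial counts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from scipy.signal import resample_poly

from .simulate import RawRecording

__all__ = [
    "EpochSet", "ContrastSpec", "CONTRASTS", "ContrastError",
    "filter_chain", "extract_epochs", "reject_amplitude",
    "save_epochs", "load_epochs",
]


class ContrastError(ValueError):
    """Raised when a contrast cannot be built from a schedule."""


@dataclass(frozen=True)
class ContrastSpec:
    """Definition of one condition contrast."""

    name: str
    epoch_span_ms: tuple[float, float]      # half-open [start, stop) re lock event
    baseline_ms: tuple[float, float]
    decode_window_ms: tuple[float, float]
    lock_shift_b_ms: float = 0.0            # B lock offset re A lock event
    context: str | None = None              # global contrasts: required context


CONTRASTS: dict[str, ContrastSpec] = {
    # The resting-state (RS) epoch is the 450-ms interval immediately before
    # S onset (-450..0 ms, baseline -450..-350 ms).  It is cut as the same
    # -100..350 window around a virtual lock 350 ms before the true one, so
    # the RS set shares the S set's time axis and feature geometry.
    "P1N1P2": ContrastSpec("P1N1P2", (-100, 350), (-100, 0), (0, 300),
                           lock_shift_b_ms=-350.0),
    "Local_SF": ContrastSpec("Local_SF", (-100, 350), (-100, 0), (0, 300)),
    "Local_ST": ContrastSpec("Local_ST", (-100, 350), (-100, 0), (0, 300)),
    "Global_SS_ST1": ContrastSpec("Global_SS_ST1", (-100, 800), (-100, 0), (0, 400),
                                  context="SS"),
    "Global_SF_ST2": ContrastSpec("Global_SF_ST2", (-100, 800), (-100, 0), (0, 400),
                                  context="SF"),
}


@dataclass
class EpochSet:
    """trials x channels x samples, with a shared time axis in ms."""

    data: np.ndarray
    times: np.ndarray                      # ms relative to the lock event
    baseline_window: tuple[float, float]
    labels: np.ndarray                     # per-trial condition tag
    participant_id: str
    contrast_name: str
    channels: tuple[str, ...]

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    def mean(self) -> np.ndarray:
        return self.data.mean(axis=0)

    def channel_index(self, label: str) -> int:
        return self.channels.index(label)


def filter_chain(raw: RawRecording, notch_hz: float = 50.0, l_freq: float = 1.0,
                 h_freq: float = 30.0, resample_to: float = 250.0) -> RawRecording:
    """Notch -> high-pass -> low-pass (zero-phase FIR), mastoid re-reference,
    down-sample.  Reference channels are retained in the output."""
    from mne.filter import filter_data, notch_filter

    for ch in raw.montage.offline_reference:
        if ch not in raw.montage.labels:
            raise ValueError(f"reference channel {ch} missing from montage")
    data = np.ascontiguousarray(raw.data, dtype=np.float64)
    data = notch_filter(data, raw.srate, freqs=notch_hz, method="fir",
                        phase="zero", verbose=False)
    data = filter_data(data, raw.srate, l_freq=l_freq, h_freq=None,
                       phase="zero", verbose=False)
    data = filter_data(data, raw.srate, l_freq=None, h_freq=h_freq,
                       phase="zero", verbose=False)
    ref_idx = raw.montage.indices(raw.montage.offline_reference)
    data = data - data[ref_idx].mean(axis=0, keepdims=True)
    down = raw.srate / resample_to
    if abs(down - round(down)) > 1e-9:
        raise ValueError("resampling requires an integer decimation factor")
    data = resample_poly(data, up=1, down=int(round(down)), axis=1)
    return RawRecording(data=data, srate=resample_to, montage=raw.montage,
                        events=raw.events, reference="M1M2",
                        participant_id=raw.participant_id)


def _window_offsets(span_ms, srate):
    step = 1000.0 / srate
    start = int(np.ceil(span_ms[0] / step - 1e-9))
    stop = int(np.ceil(span_ms[1] / step - 1e-9))
    offsets = np.arange(start, stop)
    return offsets, offsets * step


def _cut(raw: RawRecording, lock_events, span_ms, baseline_ms, lock_shift_ms=0.0):
    offsets, times = _window_offsets(span_ms, raw.srate)
    shift = int(round(lock_shift_ms * raw.srate / 1000.0))
    kept_idx, rows = [], []
    for i, ev in enumerate(lock_events):
        s = raw.event_sample(ev) + shift
        if s + offsets[0] < 0 or s + offsets[-1] >= raw.n_samples:
            continue
        rows.append(raw.data[:, s + offsets])
        kept_idx.append(i)
    if not rows:
        return np.empty((0, raw.data.shape[0], len(offsets))), times, []
    data = np.stack(rows)
    bmask = (times >= baseline_ms[0]) & (times < baseline_ms[1])
    data -= data[:, :, bmask].mean(axis=2, keepdims=True)
    return data, times, kept_idx


def extract_epochs(raw: RawRecording, contrast: str | ContrastSpec,
                   ) -> tuple[EpochSet, EpochSet]:
    """Cut the two baseline-corrected epoch sets of a contrast.

    Returned trial pairs are aligned: trial i of A and trial i of B belong
    to the same stimulus pair (local contrasts), the same deviant/context
    pair (global contrasts), or the same first-standard event (P1N1P2).
    Epochs whose window falls outside the recording are dropped pairwise.
    """
    spec = CONTRASTS[contrast] if isinstance(contrast, str) else contrast
    sched = raw.events
    pairs = {}  # pair_index -> (first_ev, second_ev)
    for first, second in zip(sched.events[::2], sched.events[1::2]):
        pairs[first.pair_index] = (first, second)

    if spec.name == "P1N1P2":
        locks_a = [f for f, _ in pairs.values() if f.analyzed]
        locks_b = locks_a
    elif spec.name.startswith("Local"):
        ptype = "SF" if spec.name == "Local_SF" else "ST"
        sel = [(f, s) for f, s in pairs.values() if f.analyzed and f.pair_type == ptype]
        locks_a = [s for _, s in sel]
        locks_b = [f for f, _ in sel]
    else:  # global contrasts
        locks_a, locks_b = [], []
        for f, s in pairs.values():
            if f.analyzed and f.pair_type == "ST" and s.global_context == spec.context:
                prev = pairs.get(f.pair_index - 1)
                if prev is None:
                    continue
                locks_a.append(s)
                locks_b.append(prev[1])
    if not locks_a:
        raise ContrastError(f"contrast {spec.name}: no qualifying trials in schedule")

    data_a, times_a, kept_a = _cut(raw, locks_a, spec.epoch_span_ms, spec.baseline_ms)
    data_b, times_b, kept_b = _cut(raw, locks_b, spec.epoch_span_ms, spec.baseline_ms,
                                   lock_shift_ms=spec.lock_shift_b_ms)
    common = sorted(set(kept_a) & set(kept_b))
    if not common:
        raise ContrastError(f"contrast {spec.name}: no trials inside the recording")
    sel_a = [kept_a.index(i) for i in common]
    sel_b = [kept_b.index(i) for i in common]
    la, lb = _condition_labels(spec)
    mk = lambda d, t, lab: EpochSet(  # noqa: E731
        data=d, times=t, baseline_window=spec.baseline_ms, labels=np.array(lab),
        participant_id=raw.participant_id, contrast_name=spec.name,
        channels=tuple(raw.montage.labels))
    A = mk(data_a[sel_a], times_a, [la] * len(common))
    B = mk(data_b[sel_b], times_b, [lb] * len(common))
    return A, B


def _condition_labels(spec: ContrastSpec) -> tuple[str, str]:
    return {
        "P1N1P2": ("S", "RS"),
        "Local_SF": ("F", "S"),
        "Local_ST": ("T", "S"),
        "Global_SS_ST1": ("T1", "S"),
        "Global_SF_ST2": ("T2", "F"),
    }[spec.name]


def reject_amplitude(A: EpochSet, B: EpochSet, threshold_uv: float = 100.0,
                     matched: bool = True,
                     exclude_channels: tuple[str, ...] = ("M1", "M2"),
                     ) -> tuple[EpochSet, EpochSet]:
    """Drop trials whose absolute amplitude exceeds the threshold anywhere.

    With ``matched=True`` (trial i of A paired with trial i of B) a
    rejection in either member drops both, keeping counts equal.
    """
    def bad(es: EpochSet) -> np.ndarray:
        keep_ch = [i for i, c in enumerate(es.channels) if c not in exclude_channels]
        return (np.abs(es.data[:, keep_ch, :]) > threshold_uv).any(axis=(1, 2))

    if matched:
        if A.n_trials != B.n_trials:
            raise ValueError("matched rejection requires aligned trial pairs")
        drop = bad(A) | bad(B)
        keep_a = keep_b = ~drop
    else:
        keep_a, keep_b = ~bad(A), ~bad(B)
    if not keep_a.any() or not keep_b.any():
        raise ValueError(f"all trials rejected at +/-{threshold_uv} uV")
    out_a = replace(A, data=A.data[keep_a], labels=A.labels[keep_a])
    out_b = replace(B, data=B.data[keep_b], labels=B.labels[keep_b])
    return out_a, out_b


def save_epochs(es: EpochSet, path: str | Path) -> None:
    """Write an epoch set as .npz plus a JSON sidecar of its metadata."""
    path = Path(path)
    np.savez_compressed(path.with_suffix(".npz"), data=es.data, times=es.times)
    meta = dict(baseline_window=list(es.baseline_window), labels=es.labels.tolist(),
                participant_id=es.participant_id, contrast_name=es.contrast_name,
                channels=list(es.channels), n_trials=int(es.n_trials))
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def load_epochs(path: str | Path) -> EpochSet:
    path = Path(path)
    arrays = np.load(path.with_suffix(".npz"))
    meta = json.loads(path.with_suffix(".json").read_text())
    return EpochSet(data=arrays["data"], times=arrays["times"],
                    baseline_window=tuple(meta["baseline_window"]),
                    labels=np.array(meta["labels"]),
                    participant_id=meta["participant_id"],
                    contrast_name=meta["contrast_name"],
                    channels=tuple(meta["channels"]))
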