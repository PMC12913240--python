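"""Paired-stimulus local-global event schedules.

Every trial is a pair of 200-ms sounds separated by a fixed 350-ms SOA.  The
first sound of a pair is always the 1000-Hz standard tone S; the second is
either S again (S-S pair), a 1500-Hz frequency deviant F (S-F pair), or a
spoken-numeral train deviant T (S-T pair).  Local deviance lives inside a
pair (S-F, S-T); global deviance is carried by the second stimulus of an S-T
pair that interrupts a run of same-type pairs (an established regularity of
either S-S or S-F pairs).  Sessions open with a block of regularity-
establishing S-S pairs that is flagged as excluded from analysis.

The generator enforces the composition by exact counts rather than by
Bernoulli draws, so every session reproduces the configured trial numbers
deterministically, and it guarantees a homogeneous run of at least
``min_intervening_pairs`` same-type pairs immediately before every S-T pair,
which makes the "disrupted regularity" of each global deviant well defined.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "NUMERALS",
    "ParadigmConfig",
    "StimulusEvent",
    "EventSchedule",
    "ScheduleError",
    "generate_session",
    "assign_onsets",
    "validate_schedule",
    "write_events_tsv",
    "read_events_tsv",
]

#: Identifiers of the nine spoken-numeral train-deviant tokens.
NUMERALS: tuple[str, ...] = (
    "one", "two", "three", "four", "five", "six", "seven", "eight", "nine",
)


class ScheduleError(ValueError):
    """Raised for infeasible or inconsistent paradigm configurations."""


@dataclass(frozen=True)
class ParadigmConfig:
    """Composition and timing of one stimulation session.

    Defaults reproduce the full-scale session: 1380 pairs of which the first
    30 S-S pairs only establish the regularity, leaving 1350 analyzed pairs
    split 555 S-S / 540 S-F / 255 S-T (an 18.89% S-T rate), with the S-T
    pairs' immediate contexts split 121 S-S vs 134 S-F.
    """

    n_total_pairs: int = 1380
    n_regularity_pairs: int = 30
    n_ss: int = 555
    n_sf: int = 540
    n_st: int = 255
    n_st_context_ss: int = 121
    n_st_context_sf: int = 134
    min_intervening_pairs: int = 3
    soa_within_pair_ms: float = 350.0
    iti_min_ms: float = 1000.0
    iti_max_ms: float = 1300.0
    iti_step_ms: float = 50.0
    stimulus_duration_ms: float = 200.0
    numeral_set: tuple[str, ...] = NUMERALS
    seed: int = 0

    @property
    def n_analyzed(self) -> int:
        return self.n_total_pairs - self.n_regularity_pairs

    def validate(self) -> None:
        c = self
        counts = dict(
            n_total_pairs=c.n_total_pairs, n_regularity_pairs=c.n_regularity_pairs,
            n_ss=c.n_ss, n_sf=c.n_sf, n_st=c.n_st,
            n_st_context_ss=c.n_st_context_ss, n_st_context_sf=c.n_st_context_sf,
            min_intervening_pairs=c.min_intervening_pairs,
        )
        for name, v in counts.items():
            if v < 0:
                raise ScheduleError(f"{name} must be >= 0, got {v}")
        if c.n_ss + c.n_sf + c.n_st != c.n_analyzed:
            raise ScheduleError(
                "n_ss + n_sf + n_st must equal n_total_pairs - n_regularity_pairs "
                f"({c.n_ss}+{c.n_sf}+{c.n_st} != {c.n_analyzed})"
            )
        if c.n_st_context_ss + c.n_st_context_sf != c.n_st:
            raise ScheduleError(
                f"context counts {c.n_st_context_ss}+{c.n_st_context_sf} != n_st={c.n_st}"
            )
        if c.iti_step_ms <= 0 or c.iti_max_ms < c.iti_min_ms:
            raise ScheduleError("invalid inter-pair jitter range")
        n_steps = (c.iti_max_ms - c.iti_min_ms) / c.iti_step_ms
        if abs(n_steps - round(n_steps)) > 1e-9:
            raise ScheduleError("jitter range must be divisible by the step")
        if not c.numeral_set:
            raise ScheduleError("numeral_set must be non-empty")
        # Feasibility of the homogeneous-run construction: every S-T pair
        # needs min_intervening_pairs same-type pairs immediately before it.
        need_ss = c.min_intervening_pairs * c.n_st_context_ss
        need_sf = c.min_intervening_pairs * c.n_st_context_sf
        if c.n_ss < need_ss or c.n_sf < need_sf:
            raise ScheduleError(
                "infeasible separation constraint: need at least "
                f"{need_ss} S-S and {need_sf} S-F pairs for the configured contexts, "
                f"have {c.n_ss} and {c.n_sf}"
            )
        if c.n_analyzed <= 0:
            raise ScheduleError("no analyzed pairs configured")

    def iti_values_ms(self) -> np.ndarray:
        n = int(round((self.iti_max_ms - self.iti_min_ms) / self.iti_step_ms)) + 1
        return self.iti_min_ms + self.iti_step_ms * np.arange(n)


@dataclass
class StimulusEvent:
    """One sound within one pair."""

    onset_ms: float | None
    stimulus_code: str          # "S", "F", or "T1".."T9"
    pair_index: int
    position: str               # "first" | "second"
    pair_type: str              # "SS" | "SF" | "ST"
    global_context: str | None  # "SS"/"SF" on second stimuli of S-T pairs, else None
    analyzed: bool


@dataclass
class EventSchedule:
    """Ordered, timed stimulus events of one session."""

    events: list[StimulusEvent]
    condition: str              # "active" | "passive"
    config: ParadigmConfig

    @property
    def n_pairs(self) -> int:
        return len(self.events) // 2

    def pair_types(self, analyzed_only: bool = False) -> list[str]:
        out = []
        for ev in self.events:
            if ev.position == "first" and (ev.analyzed or not analyzed_only):
                out.append(ev.pair_type)
        return out

    def duration_ms(self) -> float:
        last = self.events[-1]
        return float(last.onset_ms) + self.config.stimulus_duration_ms

    def to_frame(self) -> pd.DataFrame:
        rows = [
            dict(
                onset=(None if ev.onset_ms is None else ev.onset_ms / 1000.0),
                duration=self.config.stimulus_duration_ms / 1000.0,
                trial_type=ev.stimulus_code,
                pair_index=ev.pair_index,
                position=ev.position,
                pair_type=ev.pair_type,
                global_context=ev.global_context if ev.global_context else "n/a",
                analyzed=int(ev.analyzed),
            )
            for ev in self.events
        ]
        return pd.DataFrame(rows)


def _random_composition(rng: np.random.Generator, total: int, parts: int) -> np.ndarray:
    """Split `total` indistinguishable extras over `parts` slots at random."""
    if parts == 0:
        if total:
            raise ScheduleError("extras with no slot to place them")
        return np.zeros(0, dtype=int)
    if total == 0:
        return np.zeros(parts, dtype=int)
    return rng.multinomial(total, np.full(parts, 1.0 / parts))


def generate_session(config: ParadigmConfig, condition: str = "passive") -> EventSchedule:
    """Build a full session satisfying the composition and separation rules.

    The sequence is assembled constructively: the regularity block of S-S
    pairs, then for each S-T pair (context order shuffled) a homogeneous run
    of its context type of length >= ``min_intervening_pairs`` followed by
    the S-T pair itself, and finally a shuffled tail absorbing leftover
    pairs.  Extra same-type pairs beyond the minimum runs are scattered over
    the runs and the tail at random, so S-T placement is pseudo-random while
    every count is exact.  The random stream depends only on ``config.seed``,
    hence the active and passive variants built from one seed are identical.
    """
    if condition not in ("active", "passive"):
        raise ScheduleError(f"unknown condition {condition!r}")
    config.validate()
    rng = np.random.default_rng(config.seed)

    m = config.min_intervening_pairs
    contexts = ["SS"] * config.n_st_context_ss + ["SF"] * config.n_st_context_sf
    rng.shuffle(contexts)

    # Distribute surplus pairs of each type over that type's runs plus one
    # shared tail slot (the stretch after the last S-T pair).
    extra_ss = config.n_ss - m * config.n_st_context_ss
    extra_sf = config.n_sf - m * config.n_st_context_sf
    ss_slots = _random_composition(rng, extra_ss, config.n_st_context_ss + 1)
    sf_slots = _random_composition(rng, extra_sf, config.n_st_context_sf + 1)

    pair_seq: list[str] = ["SS"] * config.n_regularity_pairs
    i_ss = i_sf = 0
    for ctx in contexts:
        if ctx == "SS":
            run = m + int(ss_slots[i_ss]); i_ss += 1
        else:
            run = m + int(sf_slots[i_sf]); i_sf += 1
        pair_seq.extend([ctx] * run)
        pair_seq.append("ST")
    tail = ["SS"] * int(ss_slots[-1]) + ["SF"] * int(sf_slots[-1])
    if config.n_st == 0:
        # Degenerate composition: nothing constrains the order.
        tail = ["SS"] * config.n_ss + ["SF"] * config.n_sf
    rng.shuffle(tail)
    pair_seq.extend(tail)
    assert len(pair_seq) == config.n_total_pairs

    events: list[StimulusEvent] = []
    for k, ptype in enumerate(pair_seq):
        analyzed = k >= config.n_regularity_pairs
        if ptype == "SS":
            second = "S"
        elif ptype == "SF":
            second = "F"
        else:
            second = f"T{rng.integers(len(config.numeral_set)) + 1}"
        ctx = pair_seq[k - 1] if (ptype == "ST" and k > 0) else None
        events.append(StimulusEvent(None, "S", k, "first", ptype, None, analyzed))
        events.append(StimulusEvent(None, second, k, "second", ptype, ctx, analyzed))

    schedule = EventSchedule(events=events, condition=condition, config=config)
    assign_onsets(schedule, config, rng)
    report = validate_schedule(schedule)
    if report:  # pragma: no cover - generator/validator consistency guard
        raise ScheduleError("generator produced an invalid schedule: " + "; ".join(report))
    return schedule


def assign_onsets(schedule: EventSchedule, config: ParadigmConfig,
                  rng: np.random.Generator) -> EventSchedule:
    """Assign onsets in place: fixed within-pair SOA, jittered silent gaps.

    The jittered inter-pair interval is the silent gap between the offset of
    the second sound of pair k and the onset of the first sound of pair k+1,
    drawn uniformly from {iti_min, iti_min+step, ..., iti_max}.  With the
    default timing the expected pair period is 350 + 200 + 1150 = 1700 ms,
    so a 1380-pair session lasts about 39 minutes.
    """
    itis = config.iti_values_ms()
    t = 0.0
    for ev_first, ev_second in zip(schedule.events[::2], schedule.events[1::2]):
        ev_first.onset_ms = t
        ev_second.onset_ms = t + config.soa_within_pair_ms
        gap = float(rng.choice(itis))
        t = ev_second.onset_ms + config.stimulus_duration_ms + gap
    return schedule


def validate_schedule(schedule: EventSchedule) -> list[str]:
    """Check every schedule invariant; return one message per violation."""
    cfg = schedule.config
    ev = schedule.events
    report: list[str] = []

    if len(ev) != 2 * cfg.n_total_pairs:
        report.append(f"expected {2 * cfg.n_total_pairs} events, got {len(ev)}")
        return report

    onsets = [e.onset_ms for e in ev]
    if any(o is None for o in onsets):
        report.append("unset onsets present")
    elif any(b <= a for a, b in zip(onsets, onsets[1:])):
        bad = [i for i, (a, b) in enumerate(zip(onsets, onsets[1:])) if b <= a]
        report.append(f"onsets not strictly increasing at events {bad[:5]}")

    for e1, e2 in zip(ev[::2], ev[1::2]):
        if e1.stimulus_code != "S":
            report.append(f"pair {e1.pair_index}: first stimulus is {e1.stimulus_code}, not S")
        if e1.onset_ms is not None and e2.onset_ms is not None:
            if abs((e2.onset_ms - e1.onset_ms) - cfg.soa_within_pair_ms) > 1e-6:
                report.append(f"pair {e1.pair_index}: within-pair SOA violated")
        if (e2.global_context is not None) != (e2.pair_type == "ST"):
            report.append(f"pair {e2.pair_index}: global_context defined iff pair is S-T")

    ptypes = schedule.pair_types()
    analyzed = [e.analyzed for e in ev[::2]]
    if any(analyzed[: cfg.n_regularity_pairs]):
        report.append("regularity block flagged as analyzed")
    if not all(analyzed[cfg.n_regularity_pairs:]):
        report.append("analyzed pairs flagged as excluded")
    if any(t != "SS" for t in ptypes[: cfg.n_regularity_pairs]):
        report.append("regularity block contains non-S-S pairs")

    a_types = ptypes[cfg.n_regularity_pairs:]
    counts = {t: a_types.count(t) for t in ("SS", "SF", "ST")}
    want = {"SS": cfg.n_ss, "SF": cfg.n_sf, "ST": cfg.n_st}
    if counts != want:
        report.append(f"analyzed composition {counts} != configured {want}")

    st_idx = [k for k, t in enumerate(ptypes) if t == "ST"]
    for a, b in zip(st_idx, st_idx[1:]):
        if b - a - 1 < cfg.min_intervening_pairs:
            report.append(f"S-T pairs {a} and {b} separated by only {b - a - 1} pairs")
    ctx_counts = {"SS": 0, "SF": 0}
    for k in st_idx:
        if k == 0:
            report.append("S-T pair at session start has no context")
            continue
        ctx = ev[2 * k + 1].global_context
        if ptypes[k - 1] == "ST":
            report.append(f"S-T pair {k} immediately preceded by another S-T pair")
        elif ctx != ptypes[k - 1]:
            report.append(f"S-T pair {k}: context label {ctx} != preceding type {ptypes[k - 1]}")
        run = ptypes[max(0, k - cfg.min_intervening_pairs): k]
        if len(set(run)) > 1 or len(run) < cfg.min_intervening_pairs:
            report.append(f"S-T pair {k}: preceding run of {cfg.min_intervening_pairs} "
                          "pairs is not homogeneous")
        if ctx in ctx_counts:
            ctx_counts[ctx] += 1
    if st_idx and ctx_counts != {"SS": cfg.n_st_context_ss, "SF": cfg.n_st_context_sf}:
        report.append(f"context counts {ctx_counts} != configured "
                      f"{{'SS': {cfg.n_st_context_ss}, 'SF': {cfg.n_st_context_sf}}}")
    return report


def write_events_tsv(schedule: EventSchedule, path: str | Path) -> None:
    """Write a BIDS-style events table (onset/duration in seconds)."""
    schedule.to_frame().to_csv(path, sep="\t", index=False, na_rep="n/a")


def read_events_tsv(path: str | Path, config: ParadigmConfig | None = None,
                    condition: str = "passive") -> EventSchedule:
    """Read a BIDS-style events table written by :func:`write_events_tsv`."""
    df = pd.read_csv(path, sep="\t", na_values=["n/a"], keep_default_na=False)
    events = [
        StimulusEvent(
            onset_ms=float(r.onset) * 1000.0,
            stimulus_code=str(r.trial_type),
            pair_index=int(r.pair_index),
            position=str(r.position),
            pair_type=str(r.pair_type),
            global_context=None if (pd.isna(r.global_context) or r.global_context == "")
            else str(r.global_context),
            analyzed=bool(int(r.analyzed)),
        )
        for r in df.itertuples()
    ]
    return EventSchedule(events=events, condition=condition,
                         config=config or ParadigmConfig())
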