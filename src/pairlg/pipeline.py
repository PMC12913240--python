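"""End-to-end orchestration of the synthetic study.

``run_study`` drives the full pipeline from one configuration: schedule
generation -> continuous EEG simulation -> filtering/epoching with matched
rejection -> group-level TFCE cluster statistics -> individual-level
classification sensitivity (including the active-vs-passive comparison on
global deviants) -> the sensor x epoch degradation sweep.  Every random
stream is derived from one master seed by hash-based fan-out, so re-running
with the same configuration reproduces all numbers exactly; a manifest
records the configuration, its hash, and the derived seeds.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from ._utils import stage_seed
from .cluster import Cluster, ClusterResult, GroupData, permutation_test
from .decoding import (active_passive_contrast, participant_sensitivity,
                       prepare_samples)
from .montage import Montage, standard_montage
from .paradigm import ParadigmConfig
from .preprocess import CONTRASTS, EpochSet, extract_epochs, filter_chain, \
    reject_amplitude
from .simulate import ComponentSpec, NoiseSpec, build_default_components, \
    simulate_participant
from .sweep import correlate_performance, run_sweep

__all__ = ["StudyConfig", "AnalysisConfig", "run_study", "make_fixtures"]

log = logging.getLogger("pairlg")

GLOBAL_CONTRASTS = ("Global_SS_ST1", "Global_SF_ST2")


@dataclass(frozen=True)
class AnalysisConfig:
    alpha: float = 0.05
    n_perm: int = 1000
    n_blocks: int = 50
    n_iter: int = 1000
    k_folds: int = 5
    reject_uv: float = 100.0
    sweep_repeats: int = 500
    sweep_boot: int = 1000
    sensor_counts: tuple[int, ...] = (8, 16, 32, 64)
    fractions: tuple[float, ...] = (0.25, 0.5, 0.75, 1.0)


@dataclass(frozen=True)
class StudyConfig:
    paradigm: ParadigmConfig = field(default_factory=ParadigmConfig)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    component_overrides: dict = field(default_factory=dict)
    n_participants: int = 30
    between_subject_sd: float = 0.2
    master_seed: int = 0
    contrasts: tuple[str, ...] = tuple(CONTRASTS)
    include_sweep: bool = True

    def components(self, condition: str) -> list[ComponentSpec]:
        comps = build_default_components("active")
        out = []
        for c in comps:
            over = self.component_overrides.get(c.name, {})
            out.append(replace(c, **over))
        return out

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        d = dict(d)
        if "paradigm" in d:
            p = dict(d["paradigm"])
            if "numeral_set" in p:
                p["numeral_set"] = tuple(p["numeral_set"])
            d["paradigm"] = ParadigmConfig(**p)
        if "analysis" in d:
            a = dict(d["analysis"])
            for key in ("sensor_counts", "fractions"):
                if key in a:
                    a[key] = tuple(a[key])
            d["analysis"] = AnalysisConfig(**a)
        if "noise" in d:
            d["noise"] = NoiseSpec(**d["noise"])
        if "contrasts" in d:
            d["contrasts"] = tuple(d["contrasts"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))


def make_fixtures(scale: str) -> StudyConfig:
    """Miniature study configurations for fast end-to-end runs.

    ``unit``: 2 participants, 60 pairs, 100-permutation/100-iteration
    settings, runnable in well under a minute.  ``smoke``: 6 participants,
    300 pairs, 200 permutations -- large enough for nonempty clusters at the
    default SNR while staying desk-scale.
    """
    if scale == "unit":
        # Just enough S-T pairs that the 25%-epoch sweep cell keeps >= 3
        # samples per class for the reduced 3-fold CV.
        paradigm = ParadigmConfig(n_total_pairs=106, n_regularity_pairs=4,
                                  n_ss=40, n_sf=38, n_st=24,
                                  n_st_context_ss=12, n_st_context_sf=12)
        analysis = AnalysisConfig(n_perm=100, n_iter=100, n_blocks=10,
                                  k_folds=3, sweep_repeats=10, sweep_boot=50)
        return StudyConfig(paradigm=paradigm, analysis=analysis, n_participants=2)
    if scale == "smoke":
        paradigm = ParadigmConfig(n_total_pairs=300, n_regularity_pairs=10,
                                  n_ss=119, n_sf=116, n_st=55,
                                  n_st_context_ss=26, n_st_context_sf=29)
        analysis = AnalysisConfig(n_perm=200, n_iter=100, n_blocks=50,
                                  sweep_repeats=25, sweep_boot=200)
        return StudyConfig(paradigm=paradigm, analysis=analysis, n_participants=6)
    raise ValueError(f"unknown fixture scale {scale!r}")


def _participant_epochs(config: StudyConfig, p: int, montage: Montage,
                        ) -> dict[tuple[str, str], tuple[EpochSet, EpochSet]]:
    """Simulate, filter, epoch, and reject for one participant."""
    active, passive = simulate_participant(
        p, config.paradigm, config.components("active"), config.noise,
        config.between_subject_sd, config.master_seed, montage)
    out = {}
    for cond, raw in (("active", active), ("passive", passive)):
        filtered = filter_chain(raw)
        for name in config.contrasts:
            A, B = extract_epochs(filtered, name)
            A, B = reject_amplitude(A, B, threshold_uv=config.analysis.reject_uv)
            out[(name, cond)] = (A, B)
        log.info("participant %d %s: %s", p, cond,
                 {n: out[(n, cond)][0].n_trials for n in config.contrasts})
    return out


def _group_data(per_part, contrast: str, cond: str, montage: Montage) -> GroupData:
    keep = [i for i, c in enumerate(montage.labels)
            if c not in montage.offline_reference]
    labels = tuple(montage.labels[i] for i in keep)
    a_stack, b_stack = [], []
    for epochs in per_part:
        A, B = epochs[(contrast, cond)]
        a_stack.append(A.mean()[keep])
        b_stack.append(B.mean()[keep])
    times = per_part[0][(contrast, cond)][0].times
    return GroupData(cond_a=np.stack(a_stack), cond_b=np.stack(b_stack),
                     times=times, channels=labels,
                     adjacency=montage.adjacency[np.ix_(keep, keep)])


def _active_passive_group(per_part, contrast: str, montage: Montage) -> GroupData:
    """Active vs passive difference-waveform contrast (deviant minus standard)."""
    keep = [i for i, c in enumerate(montage.labels)
            if c not in montage.offline_reference]
    labels = tuple(montage.labels[i] for i in keep)
    act, pas = [], []
    for epochs in per_part:
        Aa, Ba = epochs[(contrast, "active")]
        Ap, Bp = epochs[(contrast, "passive")]
        act.append((Aa.mean() - Ba.mean())[keep])
        pas.append((Ap.mean() - Bp.mean())[keep])
    times = per_part[0][(contrast, "active")][0].times
    return GroupData(cond_a=np.stack(act), cond_b=np.stack(pas), times=times,
                     channels=labels, adjacency=montage.adjacency[np.ix_(keep, keep)])


def _cluster_row(contrast, cond, result: ClusterResult) -> list[dict]:
    return [
        dict(contrast=contrast, condition=cond, onset_ms=c.onset_ms,
             offset_ms=c.offset_ms, polarity=c.polarity, peak_stat=c.peak_stat,
             peak_latency_ms=c.peak_latency_ms, p_value=c.p_value,
             n_channels=len(c.channels))
        for c in result.clusters
    ]


def run_study(config: StudyConfig, output_dir: str | Path | None = None) -> dict:
    """Run the full synthetic study; return (and optionally write) a report."""
    montage = standard_montage()
    ana = config.analysis

    per_part = []
    for p in range(config.n_participants):
        try:
            per_part.append(_participant_epochs(config, p, montage))
        except Exception as err:  # noqa: BLE001
            raise RuntimeError(f"stage=preprocess participant={p}: {err}") from err

    # Group-level cluster statistics.
    cluster_rows, cluster_results = [], {}
    for name in config.contrasts:
        for cond in ("passive", "active"):
            gd = _group_data(per_part, name, cond, montage)
            res = permutation_test(gd, n_perm=ana.n_perm, alpha=ana.alpha,
                                   seed=stage_seed(config.master_seed,
                                                   f"cluster-{name}-{cond}"))
            cluster_results[(name, cond)] = res
            cluster_rows += _cluster_row(name, cond, res)
        gd = _active_passive_group(per_part, name, montage)
        res = permutation_test(gd, n_perm=ana.n_perm, alpha=ana.alpha,
                               seed=stage_seed(config.master_seed,
                                               f"cluster-{name}-avp"))
        cluster_results[(name, "active_vs_passive")] = res
        cluster_rows += _cluster_row(name, "active_vs_passive", res)

    # Individual-level sensitivity.
    detect_rows = []
    for name in config.contrasts:
        window = CONTRASTS[name].decode_window_ms
        for cond in ("passive", "active"):
            for p, epochs in enumerate(per_part):
                A, B = epochs[(name, cond)]
                r = participant_sensitivity(
                    A, B, window, n_blocks=ana.n_blocks, n_iter=ana.n_iter,
                    k=ana.k_folds,
                    seed=stage_seed(config.master_seed, f"decode-{name}-{cond}", p))
                detect_rows.append(dict(
                    contrast=name, condition=cond, participant=r.participant_id,
                    mean_accuracy=r.mean_accuracy, accuracy_sd=r.accuracy_sd,
                    threshold=r.threshold, p_value=r.p_value,
                    detected=int(r.detected)))
    for name in GLOBAL_CONTRASTS:
        if name not in config.contrasts:
            continue
        window = CONTRASTS[name].decode_window_ms
        for p, epochs in enumerate(per_part):
            sa = prepare_samples(epochs[(name, "active")][0], window, ana.n_blocks)
            sp = prepare_samples(epochs[(name, "passive")][0], window, ana.n_blocks)
            n = min(len(sa), len(sp))
            r = active_passive_contrast(
                sa[:n], sp[:n], n_iter=ana.n_iter, k=ana.k_folds,
                seed=stage_seed(config.master_seed, f"decode-{name}-avp", p),
                participant_id=epochs[(name, "active")][0].participant_id,
                contrast_name=name)
            detect_rows.append(dict(
                contrast=name, condition="active_vs_passive",
                participant=r.participant_id, mean_accuracy=r.mean_accuracy,
                accuracy_sd=r.accuracy_sd, threshold=r.threshold,
                p_value=r.p_value, detected=int(r.detected)))
    detect_df = pd.DataFrame(detect_rows)
    table = (detect_df.groupby(["contrast", "condition"])
             .agg(n_detected=("detected", "sum"), n=("detected", "size"),
                  mean_accuracy=("mean_accuracy", "mean"))
             .reset_index())

    # Sensor x epoch sweep on the global contrasts (active vs passive).
    sweep_results = {}
    if config.include_sweep:
        for name in GLOBAL_CONTRASTS:
            if name not in config.contrasts:
                continue
            cohort = [(epochs[(name, "active")][0], epochs[(name, "passive")][0])
                      for epochs in per_part]
            sw = run_sweep(cohort, montage, sensor_counts=ana.sensor_counts,
                           fractions=ana.fractions, n_repeats=ana.sweep_repeats,
                           n_blocks=ana.n_blocks, k=ana.k_folds,
                           window_ms=CONTRASTS[name].decode_window_ms,
                           seed=stage_seed(config.master_seed, f"sweep-{name}"),
                           contrast_name=name)
            sw = correlate_performance(sw, n_boot=ana.sweep_boot,
                                       seed=stage_seed(config.master_seed,
                                                       f"sweep-boot-{name}"))
            sweep_results[name] = sw

    report = dict(
        manifest=dict(config=config.to_dict(), config_hash=config.config_hash(),
                      master_seed=config.master_seed, version=__version__),
        clusters=cluster_rows,
        detection=detect_rows,
        detection_table=table.to_dict(orient="records"),
        sweep={
            name: dict(grid_mean=sw.grid_mean.tolist(),
                       grid_se=sw.grid_se.tolist(),
                       sensor_counts=list(sw.sensor_counts),
                       fractions=list(sw.fractions),
                       rho_epochs=sw.rho_epochs, rho_epochs_ci=list(sw.rho_epochs_ci),
                       rho_sensors=sw.rho_sensors,
                       rho_sensors_ci=list(sw.rho_sensors_ci))
            for name, sw in sweep_results.items()
        },
    )
    report["_cluster_results"] = cluster_results   # in-memory only

    if output_dir is not None:
        out = Path(output_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "manifest.json").write_text(json.dumps(report["manifest"], indent=1,
                                                      default=str))
        (out / "clusters.json").write_text(json.dumps(cluster_rows, indent=1))
        detect_df.to_csv(out / "detection.tsv", sep="\t", index=False)
        table.to_csv(out / "detection_table.tsv", sep="\t", index=False)
        (out / "sweep.json").write_text(json.dumps(report["sweep"], indent=1))
    return report
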