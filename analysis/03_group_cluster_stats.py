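"""Group-level TFCE cluster statistics on a synthetic cohort.

Runs the paired sign-flip permutation test with threshold-free cluster
enhancement for every contrast in both conditions plus the active-vs-
passive difference contrasts, and writes the significant cluster windows
(onset/offset/peak, Fz- and Pz-restricted summaries) to results/.
"""

import json
import sys
from dataclasses import replace
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

import pandas as pd

from pairlg.cluster import permutation_test, report_representative
from pairlg.montage import standard_montage
from pairlg.pipeline import (_active_passive_group, _group_data,
                             _participant_epochs, make_fixtures)
from pairlg.preprocess import CONTRASTS
from pairlg._utils import stage_seed

OUT = Path(__file__).resolve().parents[1] / "results"


def main(seed: int = 0, scale: str = "smoke") -> None:
    OUT.mkdir(exist_ok=True)
    cfg = replace(make_fixtures(scale), master_seed=seed)
    montage = standard_montage()
    per = [_participant_epochs(cfg, p, montage)
           for p in range(cfg.n_participants)]
    rows = []
    for name in CONTRASTS:
        rep_ch = "Pz" if name.startswith("Global") else "Fz"
        groups = {
            "passive": _group_data(per, name, "passive", montage),
            "active": _group_data(per, name, "active", montage),
            "active_vs_passive": _active_passive_group(per, name, montage),
        }
        for cond, gd in groups.items():
            res = permutation_test(gd, n_perm=cfg.analysis.n_perm,
                                   seed=stage_seed(seed, f"cluster-{name}-{cond}"))
            reps = report_representative(res, rep_ch)
            for c, rep in zip(res.clusters, reps):
                rows.append(dict(
                    contrast=name, condition=cond, polarity=c.polarity,
                    onset_ms=c.onset_ms, offset_ms=c.offset_ms,
                    peak_stat=round(c.peak_stat, 1),
                    peak_latency_ms=c.peak_latency_ms, p=c.p_value,
                    rep_channel=rep_ch,
                    rep_onset_ms=rep.onset_ms if rep.present else None,
                    rep_offset_ms=rep.offset_ms if rep.present else None))
            print(f"{name:>14} {cond:>17}: {len(res.clusters)} cluster(s)")
    df = pd.DataFrame(rows)
    df.to_csv(OUT / "cluster_windows.tsv", sep="\t", index=False)
    print(df.to_string(index=False) if len(df) else "no significant clusters")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 0,
         sys.argv[2] if len(sys.argv) > 2 else "smoke")
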