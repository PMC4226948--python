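#!/usr/bin/env python
"""Border strength on the simulated Hi-C map and its planted-truth recovery.

Scores every restriction cut site by local contrast (median-centred to 1),
checks that the centred score at true TAD borders tracks the planted border
leakage, and delineates TAD borders by the occupancy class of planted APBSs.

Run:  python analysis/03_border_strength.py [--seed 1]
Writes results/border_scores.tsv, results/border_recovery.tsv,
results/delineation_percentages.tsv.
"""

import argparse
from pathlib import Path

import pandas as pd

from apbskit import SynthConfig, gen_contact_map, local_contrast
from apbskit.borders import scores_to_frame
from apbskit.experiments import border_strength_recovery, delineation_on_planted_borders


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    cfg = SynthConfig(seed=args.seed)
    matrices, fragmap, tads, truth = gen_contact_map(cfg)
    scores = local_contrast(matrices, fragmap, window_w=10)
    scores_to_frame(scores).to_csv(args.out / "border_scores.tsv", sep="\t", index=False)
    print(f"scored {len(scores)} cut sites across {len(tads.domains)} TADs; "
          f"median centred contrast = 1 by construction")

    rows = []
    for w in (5, 10, 20):
        rec = border_strength_recovery(seed=args.seed, window_w=w)
        rows.append({
            "window_fragments": w,
            "spearman_neg_lambda_vs_L": rec["spearman"],
            "mean_L_low_leakage": rec["tercile_means"][0],
            "mean_L_mid_leakage": rec["tercile_means"][1],
            "mean_L_high_leakage": rec["tercile_means"][2],
        })
    rec_frame = pd.DataFrame(rows)
    rec_frame.to_csv(args.out / "border_recovery.tsv", sep="\t", index=False)
    print("\nplanted-leakage recovery (stronger leakage -> weaker border):")
    print(rec_frame.round(3).to_string(index=False))

    planted = delineation_on_planted_borders(seed=args.seed, plant=True)
    empty = delineation_on_planted_borders(seed=args.seed, plant=False)
    delin = pd.DataFrame([
        {"scenario": "high-k APBS at every border", **planted["percentages"]},
        {"scenario": "no APBS anywhere", **empty["percentages"]},
    ])
    delin.to_csv(args.out / "delineation_percentages.tsv", sep="\t", index=False)
    print("\ndelineation within one cut site:")
    print(delin.to_string(index=False))


if __name__ == "__main__":
    main()
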