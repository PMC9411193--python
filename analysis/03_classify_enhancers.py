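"""Classify NFRs into active-enhancer classes and compare SNP-bearing classes.

NFRs (ATAC fragments < 100 bp) become overlapped / flanked / negative by
H3K27ac peak proximity; summit-centred ATAC signal profiles are aggregated
per class, and the candidate-SNP epigenome partition is KS-compared between
classes.
"""

import argparse
from collections import Counter
from pathlib import Path

import numpy as np
import pandas as pd

from episcreen.enhancers import aggregate_signal, ks_two_sample, write_ae_calls
from episcreen.pipeline import run_pipeline

from common import DATASET_DIR, config_for


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--data", type=Path, default=DATASET_DIR)
    ap.add_argument("--out", type=Path, default=Path("results/03_enhancers"))
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)
    cfg = config_for(args.data, args.out, args.seed)
    ctx = run_pipeline(cfg, ["load", "annotate", "enhancers"])
    calls = ctx["ae_calls"]
    write_ae_calls(calls, args.out / "ae_calls.bed")
    counts = Counter(c.label for c in calls)
    n_ae = counts["overlapped"] + counts["flanked"]
    print(f"{len(calls)} NFRs: {dict(counts)}  (AEs: {n_ae}, "
          f"{n_ae / len(calls):.0%} of NFRs)")

    profiles = {}
    for label in ("overlapped", "flanked", "negative"):
        sel = [c for c in calls if c.label == label]
        matrix, profile = aggregate_signal(sel, ctx["coverage"])
        profiles[label] = profile
        print(f"  {label:10s}: n={len(sel):5d}  peak signal {profile.max():.2f}")
    pd.DataFrame(profiles).to_csv(args.out / "signal_profiles.tsv", sep="\t",
                                  index=False)

    # per-SNP ATAC signal by epigenome class (AE vs negative-NFR vs outside)
    cov = ctx["coverage"]
    by_class = {}
    for a in ctx["candidates"]:
        v = cov.integral(a.snp.chrom, a.snp.pos - 250, a.snp.pos + 250) / 500
        by_class.setdefault(a.epigenome_class or "outside", []).append(v)
    print("  candidate-SNP epigenome partition:",
          {k: len(v) for k, v in by_class.items()})
    keys = [k for k in ("AE", "nfr_only", "outside") if len(by_class.get(k, [])) >= 2]
    for i, a in enumerate(keys):
        for b in keys[i + 1:]:
            d, p = ks_two_sample(by_class[a], by_class[b])
            print(f"  ATAC signal {a} vs {b}: KS D={d:.2f} p={p:.2e}")


if __name__ == "__main__":
    main()
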