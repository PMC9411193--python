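"""Select sub-threshold candidate SNPs and annotate their genomic context.

Keeps variants with P < 1e-3, assigns significance strata, promoter / exon /
intron / intergenic context and TSS distance, and runs the expression-matched
random-gene control: TPMs of genes hosting exonic candidates are compared by
KS test against random same-size gene sets.
"""

import argparse
from collections import Counter
from pathlib import Path

import numpy as np

from episcreen.annotate import annotation_table, expression_matched_control
from episcreen.pipeline import run_pipeline

from common import DATASET_DIR, config_for


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--data", type=Path, default=DATASET_DIR)
    ap.add_argument("--out", type=Path, default=Path("results/02_annotation"))
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)
    cfg = config_for(args.data, args.out, args.seed)
    ctx = run_pipeline(cfg, ["load", "annotate"])
    cands = ctx["candidates"]
    table = annotation_table(cands)
    table.to_csv(args.out / "candidates.tsv", sep="\t", index=False)
    print(f"{len(cands)} candidate SNPs of {len(ctx['snps'])} "
          f"(P < {cfg.p_max:g})")
    print("  strata  :", dict(Counter(a.stratum for a in cands)))
    print("  context :", dict(Counter(a.context for a in cands)))
    noncoding = sum(1 for a in cands if a.context not in ("exon", "promoter"))
    print(f"  noncoding share: {noncoding / len(cands):.1%}")
    dists = [a.tss_distance for a in cands if a.tss_distance]
    print(f"  median TSS distance: {np.median(dists):,.0f} bp")

    # expression-matched control for genes hosting exonic candidates
    host = {a.host_gene for a in cands if a.context == "exon" and a.host_gene}
    expr = ctx["expression"]
    pool = [t for _, t in expr.items() if t > 0]
    target = [expr.get(g) for g in host]
    if target:
        res = expression_matched_control(pool, target, n_draws=1000, seed=args.seed)
        res.to_csv(args.out / "expression_control.tsv", sep="\t", index=False)
        print(f"  expression-matched control over {len(target)} host genes: "
              f"median KS p = {res['pvalue'].median():.3f} "
              f"({(res['pvalue'] < 0.05).mean():.1%} of draws significant)")
    else:
        print("  no exonic candidate SNPs in expressed genes; control skipped")


if __name__ == "__main__":
    main()
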