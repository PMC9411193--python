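"""PWM gain/loss at linked variants (relative profile score threshold 80%).

For each linked variant, both allele windows are scanned with every supplied
JASPAR PFM over both strands; a motif counts as present for an allele when a
placement covering the SNP reaches 80% relative score.  Motifs present for
the non-risk but not the risk allele are lost, the reverse are gained.
"""

import argparse
from pathlib import Path

from episcreen.motifs import write_motif_delta_table
from episcreen.pipeline import run_pipeline
from episcreen.synthetic import TruthManifest

from common import DATASET_DIR, config_for


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--data", type=Path, default=DATASET_DIR)
    ap.add_argument("--out", type=Path, default=Path("results/07_motifs"))
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)
    cfg = config_for(args.data, args.out, args.seed)
    ctx = run_pipeline(
        cfg, ["load", "annotate", "enhancers", "contacts", "link", "motifs"]
    )
    deltas = ctx["motif_deltas"]
    write_motif_delta_table(deltas, ctx["pwms"], args.out / "motif_delta.tsv")
    manifest = TruthManifest.from_json(args.data / "manifest.json")
    functional = set(manifest.functional_rsids)
    n_lost = sum(len(d.lost) for d in deltas)
    n_gained = sum(len(d.gained) for d in deltas)
    func_lost = sum(1 for d in deltas if d.rsid in functional and d.lost)
    n_func = sum(1 for d in deltas if d.rsid in functional)
    print(f"{len(deltas)} linked variants scanned against "
          f"{len(ctx['pwms'])} PWMs at threshold {cfg.motif_threshold:.0%}")
    print(f"  motifs lost: {n_lost}, gained: {n_gained}")
    print(f"  planted functional variants losing their motif: "
          f"{func_lost}/{n_func}")


if __name__ == "__main__":
    main()
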