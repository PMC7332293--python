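#!/usr/bin/env python
"""Four-criterion interaction filter, merge with the exclusivity calls, and
scoring against the generating truth.

A (bait, protein) record becomes a high-confidence candidate interacting
protein (HCIP) iff p < 0.05, log2 fold change > 0, >= 2 unique peptides in
the bait's samples, and the protein is not a common contaminant. Exclusivity
calls are merged in afterwards (enrichment provenance wins on overlap).
Because the experiment is simulated, the calls can be scored against the
known truth: sensitivity over spiked pairs, empirical FDR, and the
exclusivity path's recovery.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from apmspipe import hcip, quant_io, sinq
from apmspipe.simulate import SyntheticTruth, truth_report

ROOT = Path(__file__).resolve().parent.parent


def load_truth(path: Path) -> SyntheticTruth:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    roles, interactors, exclusives, effects = {}, {}, {}, {}
    for row in df.itertuples(index=False):
        roles[row.protein_acc] = row.role
        baits = row.cognate_baits.split(";") if row.cognate_baits else []
        for b in baits:
            target = interactors if row.role == "interactor" else exclusives
            target.setdefault(b, set()).add(row.protein_acc)
        if row.effects:
            for item in row.effects.split(";"):
                b, v = item.split(":")
                effects[(row.protein_acc, b)] = float(v)
    return SyntheticTruth(roles, interactors, exclusives, effects)


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.parse_args()

    sim = ROOT / "scratch" / "sim"
    qm = quant_io.read_quant_table(sim / "quant.tsv", sim / "samples.tsv")
    contams = quant_io.read_contaminant_list(sim / "contaminants.txt")
    results = pd.read_csv(ROOT / "scratch" / "bscg_results.tsv", sep="\t")
    excl_df = pd.read_csv(ROOT / "results" / "03_exclusives.tsv", sep="\t")
    exclusives = [
        sinq.ExclusiveCall(r.bait, r.protein, r.max_sinq, int(r.total_sc))
        for r in excl_df.itertuples(index=False)
    ]

    calls = hcip.call_hcips(results, qm, contams)
    merged = hcip.merge_hcips([r for r in calls if r.passed_filters], exclusives)
    print(
        f"{sum(r.passed_filters for r in calls)} enrichment calls + "
        f"{len(exclusives)} exclusives -> {len(merged)} merged interactions"
    )

    truth = load_truth(sim / "truth.tsv")
    rep = truth_report(merged, truth, qm=qm, min_effect=2.0)
    print(
        f"sensitivity {rep['sensitivity']:.3f}, FDR {rep['fdr']:.3f}, "
        f"exclusive-path sensitivity {rep['exclusive_sensitivity']:.3f}"
    )

    out = ROOT / "results"
    quant_io.write_outputs(
        merged,
        {
            "n_interactions": len(merged),
            "recovery": {k: v for k, v in rep.items() if k != "recovery_curve"},
        },
        out / "04_hcips",
    )
    with open(out / "04_recovery.json", "w") as fh:
        json.dump(rep, fh, indent=2)


if __name__ == "__main__":
    main()
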