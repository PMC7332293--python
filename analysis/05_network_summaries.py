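#!/usr/bin/env python
"""Network-level summaries of the merged interactome.

Reproduces the descriptive views a multi-bait AP-MS study reports: the
unique/shared prey-degree distribution, the correlation between each bait's
raw abundance (its own summed self-pulldown intensity) and its interactor
count, a hierarchically clustered bait x prey -log10(p) heat-map matrix, and
the per-bait spectral-count profile of a ubiquitously co-purifying protein
(the most-detected contaminant stands in for an abundant cofactor such as
the AAA-ATPase VCP/p97).
"""

import argparse
import json
import math
from pathlib import Path

import pandas as pd

from apmspipe import hcip, quant_io, sinq

ROOT = Path(__file__).resolve().parent.parent


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.parse_args()

    sim = ROOT / "scratch" / "sim"
    qm = quant_io.read_quant_table(sim / "quant.tsv", sim / "samples.tsv")
    merged = quant_io.read_hcips(ROOT / "results" / "04_hcips" / "hcips.tsv")
    out = ROOT / "results"

    net = hcip.build_network(merged, qm)
    hist = hcip.sharing_distribution(net)
    n_preys = sum(hist.values())
    print(
        f"{len(net.edges)} interactions over {n_preys} distinct preys; "
        f"{hist['1']} ({hist['1'] / n_preys:.0%}) unique to one bait, "
        f"shared by 2: {hist['2']}, 3: {hist['3']}, >=4: {hist['>=4']}"
    )
    pd.DataFrame([hist]).to_csv(
        out / "05_sharing_histogram.tsv", sep="\t", index=False
    )

    try:
        r = hcip.abundance_hcip_correlation(net)
        print(f"bait raw abundance vs interactor count: Pearson r = {r:.3f}")
    except ValueError:
        r = math.nan

    bait_order, prey_order, mat = hcip.cluster_pvalue_heatmap(merged)
    mat.to_csv(out / "05_heatmap_matrix.tsv", sep="\t", float_format="%.6g")
    with open(out / "05_heatmap_leaf_orders.json", "w") as fh:
        json.dump({"baits": bait_order, "preys": prey_order}, fh, indent=2)

    # the most-detected contaminant as the panel's ubiquitous co-purifier
    truth = pd.read_csv(sim / "truth.tsv", sep="\t", keep_default_na=False)
    contams = truth.loc[truth.role == "contaminant", "protein_acc"]
    present = [c for c in contams if c in qm.spectral_count.index]
    ubiq = max(present, key=lambda c: int(qm.spectral_count.loc[c].sum()))
    prof = sinq.spectral_count_profile(qm, ubiq)
    prof.to_csv(out / "05_ubiquitous_profile.tsv", sep="\t", index=False)
    med = prof["median_across_baits"].iloc[0]
    top = prof[prof.upper_quartile]["bait_id"].tolist()
    print(
        f"spectral-count profile of {ubiq}: median {med:g} per bait; "
        f"upper quartile: {', '.join(top)}"
    )

    with open(out / "05_network_summary.json", "w") as fh:
        json.dump(
            {
                "n_interactions": len(net.edges),
                "n_distinct_preys": n_preys,
                "sharing_histogram": hist,
                "abundance_hcip_pearson_r": None if math.isnan(r) else round(r, 4),
                "ubiquitous_protein": ubiq,
                "ubiquitous_median_sc": med,
            },
            fh,
            indent=2,
        )


if __name__ == "__main__":
    main()
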