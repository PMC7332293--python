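"""End-to-end driver: read -> background -> normalize -> enrichment ->
spectral index -> call -> merge -> summaries -> write.

Every stage logs its input/output record counts to the module logger, all
randomness (control-side imputation) flows from the single configured seed,
and reruns with identical inputs, config and seed produce identical outputs.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import bscg, hcip, quant_io, sinq

logger = logging.getLogger("apmspipe")


@dataclass
class PipelineConfig:
    quant_table: str = ""
    sample_sheet: str = ""
    fasta: str = ""
    contaminants: str = ""
    annotations: str | None = None
    prior_edges: str | None = None
    out_dir: str = "out"
    alpha: float = hcip.DEFAULT_ALPHA
    min_unique_peptides: int = hcip.DEFAULT_MIN_UNIQUE_PEPTIDES
    min_sinq: float = sinq.DEFAULT_MIN_SINQ
    min_sc: int = sinq.DEFAULT_MIN_SC
    background_threshold: float = bscg.DEFAULT_BACKGROUND_THRESHOLD
    test_method: str = "pooled"  # or "welch"
    cluster_method: str = "average"
    cluster_metric: str = "euclidean"
    seed: int = 0

    def validate(self) -> None:
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        if not (0 < self.background_threshold <= 1):
            raise ValueError("background_threshold must be in (0, 1]")
        if self.min_sinq < 0 or self.min_sc < 0 or self.min_unique_peptides < 0:
            raise ValueError("thresholds must be non-negative")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full scoring pipeline and write all outputs.

    Returns the summary dictionary that is also written to summary.json.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    logger.info("stage read: %s", config.quant_table)
    qm = quant_io.read_quant_table(config.quant_table, config.sample_sheet)
    logger.info(
        "stage read: %d proteins x %d samples (%d baits)",
        len(qm.proteins), len(qm.sample_ids), len(qm.baits),
    )
    lengths = quant_io.read_fasta_lengths(config.fasta)
    contaminants = quant_io.read_contaminant_list(config.contaminants)
    annotations = (
        quant_io.read_annotations(config.annotations) if config.annotations else None
    )
    prior = (
        quant_io.read_prior_edges(config.prior_edges) if config.prior_edges else None
    )

    bg = bscg.define_background(qm, contaminants, config.background_threshold)
    logger.info("stage background: %d members", len(bg.members))
    nm = bscg.normalize_to_background(qm, bg)
    logger.info("stage normalize: scale factors in [%.3g, %.3g]",
                nm.scale_factors.min(), nm.scale_factors.max())

    results = bscg.score_all_baits(nm, seed=config.seed, method=config.test_method)
    logger.info("stage enrichment: %d (bait, protein) records", len(results))
    results.to_csv(out / "bscg_results.tsv", sep="\t", index=False,
                   float_format="%.8g")

    st = sinq.sinq_table(qm, lengths)
    st.to_csv(out / "sinq_scores.tsv", sep="\t", index=False, float_format="%.8g")
    exclusives = sinq.find_exclusives(
        st, qm.samples, contaminants, config.min_sinq, config.min_sc
    )
    logger.info("stage sinq: %d exclusivity calls", len(exclusives))
    pd.DataFrame(
        [
            {"bait": e.bait_id, "protein": e.protein_acc,
             "max_sinq": e.max_sinq, "total_sc": e.total_spectral_count}
            for e in exclusives
        ],
        columns=["bait", "protein", "max_sinq", "total_sc"],
    ).to_csv(out / "exclusives.tsv", sep="\t", index=False, float_format="%.8g")

    calls = hcip.call_hcips(
        results, qm, contaminants, config.alpha, config.min_unique_peptides
    )
    n_pass = sum(r.passed_filters for r in calls)
    logger.info("stage call: %d of %d records pass the filter", n_pass, len(calls))
    merged = hcip.merge_hcips([r for r in calls if r.passed_filters], exclusives)
    logger.info("stage merge: %d interactions", len(merged))

    net = hcip.build_network(merged, qm)
    hist = hcip.sharing_distribution(net)
    try:
        r = hcip.abundance_hcip_correlation(net)
    except ValueError:
        r = math.nan

    summary: dict = {
        "thresholds": {
            "alpha": config.alpha,
            "min_unique_peptides": config.min_unique_peptides,
            "min_sinq": config.min_sinq,
            "min_sc": config.min_sc,
            "background_threshold": config.background_threshold,
        },
        "seed": config.seed,
        "n_proteins": len(qm.proteins),
        "n_samples": len(qm.sample_ids),
        "n_baits": len(qm.baits),
        "n_background_members": len(bg.members),
        "n_interactions": len(merged),
        "n_bscg_interactions": sum(1 for x in merged if x.provenance == "bscg"),
        "n_exclusive_interactions": sum(
            1 for x in merged if x.provenance == "sinq_exclusive"
        ),
        "n_distinct_preys": len({x.protein_acc for x in merged}),
        "per_bait_counts": {
            b: int(n) for b, n in sorted(net.per_bait_count.items())
        },
        "sharing_histogram": hist,
        "abundance_hcip_pearson_r": None if math.isnan(r) else r,
    }

    pd.DataFrame(
        sorted(net.edges), columns=["bait", "prey"]
    ).to_csv(out / "network.tsv", sep="\t", index=False)
    pd.DataFrame([hist]).to_csv(out / "sharing_histogram.tsv", sep="\t", index=False)

    bait_order, prey_order, mat = hcip.cluster_pvalue_heatmap(
        merged, config.cluster_method, config.cluster_metric
    )
    mat.to_csv(out / "heatmap_matrix.tsv", sep="\t", float_format="%.8g")
    with open(out / "heatmap_leaf_orders.json", "w") as fh:
        json.dump({"baits": bait_order, "preys": prey_order}, fh, indent=2)

    if annotations is not None:
        classes = hcip.classify_secretory(merged, annotations)
        classes.to_csv(out / "secretory_classes.tsv", sep="\t", index=False)
        summary["er_membrane_fraction"] = hcip.secretory_fraction(classes)
    if prior is not None:
        frac, flags = hcip.known_overlap(merged, prior)
        flags.to_csv(out / "overlap.tsv", sep="\t", index=False)
        summary["known_overlap_fraction"] = frac

    quant_io.write_outputs(merged, summary, out)
    logger.info("pipeline complete: outputs in %s", out)
    return summary
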