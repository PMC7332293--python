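"""High-confidence candidate interacting protein (HCIP) calling and
network-level summaries.

A prey scored by the comparative enrichment analysis is admitted as an HCIP
iff it clears four criteria simultaneously: (1) p-value < alpha (default
0.05); (2) strictly positive log2 fold change; (3) at least
``min_unique_peptides`` (default 2) distinct peptide sequences supporting the
identification within the bait's samples; and (4) absence from the common-
contaminant list. Bait self-detection is excluded from the edge list but its
summed intensity is retained as the bait's raw abundance. Exclusivity calls
from the spectral-index path are merged in afterwards; where a (bait, prey)
pair is called by both routes the enrichment-based record takes precedence.

Summaries over the merged network mirror the standard descriptive analyses of
a multi-bait interactome: the unique/shared prey-degree distribution, the
correlation of bait raw abundance with HCIP count, the secretory-pathway
classification of preys from sequence features, overlap with prior
interaction resources, and a hierarchically clustered bait x prey -log10(p)
matrix.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist

from .quant_io import QuantMatrix
from .sinq import ExclusiveCall

DEFAULT_ALPHA = 0.05
DEFAULT_MIN_UNIQUE_PEPTIDES = 2


@dataclass
class HcipRecord:
    """One evaluated bait-prey pair with the filter values that judged it."""

    bait_id: str
    protein_acc: str
    provenance: str  # "bscg" or "sinq_exclusive"
    p_value: float = math.nan
    q_value: float = math.nan
    log2fc: float = math.nan
    unique_peptides: int = 0
    sinq_score: float = math.nan
    passed_filters: bool = False

    def __eq__(self, other) -> bool:  # NaN-tolerant field equality
        if not isinstance(other, HcipRecord):
            return NotImplemented

        def same(a, b):
            if isinstance(a, float) and isinstance(b, float):
                return (math.isnan(a) and math.isnan(b)) or a == b
            return a == b

        return all(
            same(getattr(self, f), getattr(other, f))
            for f in (
                "bait_id",
                "protein_acc",
                "provenance",
                "p_value",
                "q_value",
                "log2fc",
                "unique_peptides",
                "sinq_score",
                "passed_filters",
            )
        )


@dataclass
class InteractionNetwork:
    edges: set[tuple[str, str]]
    raw_abundance: dict[str, float] = field(default_factory=dict)

    @property
    def prey_degree(self) -> dict[str, int]:
        deg: dict[str, int] = {}
        for _, prey in self.edges:
            deg[prey] = deg.get(prey, 0) + 1
        return deg

    @property
    def per_bait_count(self) -> dict[str, int]:
        cnt: dict[str, int] = {}
        for bait, _ in self.edges:
            cnt[bait] = cnt.get(bait, 0) + 1
        return cnt


def call_hcips(
    bscg: pd.DataFrame,
    qm: QuantMatrix,
    contaminants: set[str],
    alpha: float = DEFAULT_ALPHA,
    min_unique_peptides: int = DEFAULT_MIN_UNIQUE_PEPTIDES,
    bait_accessions: dict[str, str] | None = None,
) -> list[HcipRecord]:
    """Evaluate every enrichment record against the four HCIP criteria.

    Returns one record per (bait, protein) row of the enrichment table with
    ``passed_filters`` set accordingly; bait self-rows never pass.
    """
    if not (0 < alpha < 1):
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    acc_of = bait_accessions or {}
    up = qm.unique_peptides
    records: list[HcipRecord] = []
    for row in bscg.itertuples(index=False):
        bait, prot = row.bait_id, row.protein_acc
        n_up = int(up.at[prot, bait]) if prot in up.index and bait in up.columns else 0
        p = float(row.p_value) if pd.notna(row.p_value) else math.nan
        fc = float(row.log2fc) if pd.notna(row.log2fc) else math.nan
        passed = (
            (not math.isnan(p))
            and p < alpha
            and (not math.isnan(fc))
            and fc > 0
            and n_up >= min_unique_peptides
            and prot not in contaminants
            and prot != acc_of.get(bait, bait)
        )
        records.append(
            HcipRecord(
                bait_id=bait,
                protein_acc=prot,
                provenance="bscg",
                p_value=p,
                q_value=float(row.q_value) if hasattr(row, "q_value") and pd.notna(row.q_value) else math.nan,
                log2fc=fc,
                unique_peptides=n_up,
                passed_filters=bool(passed),
            )
        )
    return records


def merge_hcips(
    bscg_calls: list[HcipRecord], exclusives: list[ExclusiveCall]
) -> list[HcipRecord]:
    """Union of enrichment-based calls and exclusivity calls, keyed on
    (bait, prey); the enrichment record wins when both routes fire."""
    merged: dict[tuple[str, str], HcipRecord] = {
        (r.bait_id, r.protein_acc): r for r in bscg_calls
    }
    for ex in exclusives:
        key = (ex.bait_id, ex.protein_acc)
        if key in merged:
            if math.isnan(merged[key].sinq_score):
                merged[key].sinq_score = ex.max_sinq
            continue
        merged[key] = HcipRecord(
            bait_id=ex.bait_id,
            protein_acc=ex.protein_acc,
            provenance="sinq_exclusive",
            sinq_score=ex.max_sinq,
            unique_peptides=0,
            passed_filters=True,
        )
    return sorted(merged.values(), key=lambda r: (r.bait_id, r.protein_acc))


def build_network(
    records: list[HcipRecord], qm: QuantMatrix | None = None,
    bait_accessions: dict[str, str] | None = None,
) -> InteractionNetwork:
    """Edge set over passing records; bait raw abundance = the bait protein's
    summed intensity across its own samples (self-pulldown signal)."""
    edges = {(r.bait_id, r.protein_acc) for r in records if r.passed_filters}
    ra: dict[str, float] = {}
    if qm is not None:
        acc_of = bait_accessions or {}
        for b in qm.baits:
            acc = acc_of.get(b, b)
            if acc in qm.intensity.index:
                ra[b] = float(qm.intensity.loc[acc, qm.samples_of_bait(b)].sum(skipna=True))
            else:
                ra[b] = 0.0
    return InteractionNetwork(edges, ra)


def sharing_distribution(net: InteractionNetwork) -> dict[str, int]:
    """Histogram of prey degree over the bins 1, 2, 3 and >=4."""
    hist = {"1": 0, "2": 0, "3": 0, ">=4": 0}
    for deg in net.prey_degree.values():
        hist[str(deg) if deg <= 3 else ">=4"] += 1
    return hist


def abundance_hcip_correlation(net: InteractionNetwork) -> float:
    """Pearson r between bait raw abundance and bait HCIP count.

    Returns NaN with a warning when either variable has zero variance.
    """
    baits = sorted(net.raw_abundance)
    if len(baits) < 3:
        raise ValueError("correlation requires >= 3 baits")
    counts = net.per_bait_count
    x = np.array([net.raw_abundance[b] for b in baits])
    y = np.array([counts.get(b, 0) for b in baits], dtype=float)
    if np.std(x) == 0 or np.std(y) == 0:
        warnings.warn("zero variance: Pearson r undefined", stacklevel=2)
        return math.nan
    return float(stats.pearsonr(x, y).statistic)


def classify_secretory(
    records: list[HcipRecord], annotations: pd.DataFrame
) -> pd.DataFrame:
    """Classify each distinct passing prey as ER/membrane vs soluble.

    ER/membrane iff any of the four secretory-pathway features (TMD, signal
    peptide, N-glycosylation, disulphide bond) is annotated; preys absent from
    the annotation table are labelled ``unknown`` and excluded from the
    reported fraction.
    """
    preys = sorted({r.protein_acc for r in records if r.passed_filters})
    flag_cols = ["has_tmd", "has_signal_peptide", "has_nglyc", "has_disulphide"]
    rows = []
    for p in preys:
        if p in annotations.index:
            cls = (
                "ER/membrane"
                if bool(annotations.loc[p, flag_cols].any())
                else "soluble"
            )
        else:
            cls = "unknown"
        rows.append({"protein_acc": p, "secretory_class": cls})
    return pd.DataFrame(rows, columns=["protein_acc", "secretory_class"])


def secretory_fraction(classes: pd.DataFrame) -> float:
    """Fraction of annotated preys classified ER/membrane (unknowns excluded)."""
    known = classes[classes["secretory_class"] != "unknown"]
    if known.empty:
        return math.nan
    return float((known["secretory_class"] == "ER/membrane").mean())


def known_overlap(
    records: list[HcipRecord], prior_edges: set[frozenset[str]],
    bait_accessions: dict[str, str] | None = None,
) -> tuple[float, pd.DataFrame]:
    """Fraction of called edges whose unordered accession pair appears in the
    prior-interaction resource, plus per-edge novelty flags."""
    acc_of = bait_accessions or {}
    rows = []
    for r in sorted(
        (r for r in records if r.passed_filters),
        key=lambda r: (r.bait_id, r.protein_acc),
    ):
        pair = frozenset((acc_of.get(r.bait_id, r.bait_id), r.protein_acc))
        rows.append(
            {"bait_id": r.bait_id, "protein_acc": r.protein_acc,
             "known": pair in prior_edges}
        )
    flags = pd.DataFrame(rows, columns=["bait_id", "protein_acc", "known"])
    frac = float(flags["known"].mean()) if len(flags) else 0.0
    return frac, flags


def cluster_pvalue_heatmap(
    records: list[HcipRecord],
    method: str = "average",
    metric: str = "euclidean",
) -> tuple[list[str], list[str], pd.DataFrame]:
    """Bait x prey matrix of -log10 p over passing calls, with both axes
    ordered by hierarchical clustering (average linkage, Euclidean, by
    default). Missing (bait, prey) combinations contribute 0; exclusivity
    calls, which carry no p-value, also enter as 0.

    Deterministic for fixed input. With fewer than two baits or preys the
    input order is returned with a warning.
    """
    passing = [r for r in records if r.passed_filters]
    baits = sorted({r.bait_id for r in passing})
    preys = sorted({r.protein_acc for r in passing})
    mat = pd.DataFrame(0.0, index=baits, columns=preys)
    for r in passing:
        if not math.isnan(r.p_value) and r.p_value > 0:
            mat.at[r.bait_id, r.protein_acc] = -math.log10(r.p_value)
    if len(baits) < 2 or len(preys) < 2:
        warnings.warn("too few baits or preys to cluster; input order kept",
                      stacklevel=2)
        return baits, preys, mat

    def order(frame: pd.DataFrame) -> list[str]:
        Z = linkage(pdist(frame.to_numpy(), metric=metric), method=method)
        return [frame.index[i] for i in leaves_list(Z)]

    bait_order = order(mat)
    prey_order = order(mat.T)
    return bait_order, prey_order, mat.loc[bait_order, prey_order]
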