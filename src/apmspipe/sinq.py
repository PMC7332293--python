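"""Normalized spectral-index (SINQ) quantitation and exclusivity rescue.

A fold-change-based comparison cannot score a prey detected with only one
bait: there is nothing to divide by. The spectral-index path rescues these
candidates. For every sample, each detected protein receives a spectral index
(its summed peptide intensity, or optionally its spectral count when
intensities are unavailable), which is normalized by the sample's total index
and by protein length:

    sinq_score[p] = (index[p] / sum_k index[k]) / length_aa[p]

so that sum over detected proteins of sinq_score * length == 1 per sample.
A protein detected with exactly one bait, with a per-sample maximum score of
at least ``min_sinq`` (default 1e-7) and more than ``min_sc`` (default 1)
spectral counts summed over that bait's replicates, and not on the
contaminant list, is called a bait-exclusive interactor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .quant_io import QuantMatrix, SampleMeta

DEFAULT_MIN_SINQ = 1e-7
DEFAULT_MIN_SC = 1  # criterion is "> min_sc", i.e. at least 2 spectra


class SinqError(Exception):
    pass


@dataclass(frozen=True)
class ExclusiveCall:
    bait_id: str
    protein_acc: str
    max_sinq: float
    total_spectral_count: int


def spectral_index(
    qm: QuantMatrix,
    lengths: dict[str, int],
    sample: str,
    use_spectral_counts: bool = False,
) -> pd.DataFrame:
    """SINQ rows for one sample: spectral_index, sinq_score, detection flags.

    ``use_spectral_counts`` substitutes spectral counts for intensities as the
    raw index, for tables without intensity values.
    """
    if sample not in qm.sample_ids:
        raise SinqError(f"unknown sample {sample!r}")
    sc = qm.spectral_count[sample]
    detected = sc > 0
    if use_spectral_counts:
        idx_raw = sc.astype(float).where(detected, 0.0)
    else:
        idx_raw = qm.intensity[sample].fillna(0.0)

    missing_len = [p for p in qm.proteins if detected[p] and p not in lengths]
    if missing_len:
        raise SinqError(f"detected proteins lacking a length entry: {missing_len[:5]}")

    total = float(idx_raw.sum())
    if total <= 0:
        warnings.warn(f"sample {sample!r} has no detected signal", stacklevel=2)
        score = pd.Series(0.0, index=qm.intensity.index)
    else:
        L = pd.Series({p: lengths.get(p, np.nan) for p in qm.proteins})
        score = (idx_raw / total) / L
        score = score.where(detected, 0.0)
    return pd.DataFrame(
        {
            "sample_id": sample,
            "protein_acc": qm.intensity.index,
            "spectral_index": idx_raw.to_numpy(),
            "sinq_score": score.fillna(0.0).to_numpy(),
            "spectral_count": sc.to_numpy(),
            "detected": detected.to_numpy(),
        }
    ).reset_index(drop=True)


def sinq_table(
    qm: QuantMatrix, lengths: dict[str, int], use_spectral_counts: bool = False
) -> pd.DataFrame:
    """Concatenated SINQ rows for every sample of the experiment."""
    frames = [
        spectral_index(qm, lengths, s, use_spectral_counts) for s in qm.sample_ids
    ]
    return pd.concat(frames, ignore_index=True)


def find_exclusives(
    sinq: pd.DataFrame,
    samples: list[SampleMeta],
    contaminants: set[str],
    min_sinq: float = DEFAULT_MIN_SINQ,
    min_sc: int = DEFAULT_MIN_SC,
    bait_accessions: dict[str, str] | None = None,
) -> list[ExclusiveCall]:
    """Proteins detected with exactly one bait that clear the SINQ criteria.

    ``bait_accessions`` maps bait_id to the bait's own protein accession; the
    bait itself is never its own exclusive. Defaults to the identity map.
    """
    if min_sinq < 0 or min_sc < 0:
        raise ValueError("thresholds must be non-negative")
    bait_of = {s.sample_id: s.bait_id for s in samples}
    acc_of = bait_accessions or {}
    det = sinq[sinq["detected"]].copy()
    det["bait_id"] = det["sample_id"].map(bait_of)

    calls: list[ExclusiveCall] = []
    for prot, grp in det.groupby("protein_acc", sort=True):
        baits = grp["bait_id"].unique()
        if len(baits) != 1:
            continue
        bait = baits[0]
        if prot in contaminants:
            continue
        if prot == acc_of.get(bait, bait):
            continue
        max_sinq = float(grp["sinq_score"].max())
        total_sc = int(grp["spectral_count"].sum())
        if max_sinq >= min_sinq and total_sc > min_sc:
            calls.append(ExclusiveCall(bait, str(prot), max_sinq, total_sc))
    return calls


def spectral_count_profile(qm: QuantMatrix, protein: str) -> pd.DataFrame:
    """Per-bait total spectral counts for one protein, with the across-bait
    median and an upper-quartile membership flag.

    Mirrors the panel-wide profiling of a ubiquitously co-purifying protein
    (e.g. the AAA-ATPase VCP/p97) to distinguish enrichment from abundance.
    """
    if protein not in qm.spectral_count.index:
        raise KeyError(f"protein {protein!r} not in matrix")
    row = qm.spectral_count.loc[protein]
    counts = {}
    for b in qm.baits:
        counts[b] = int(row[qm.samples_of_bait(b)].sum())
    vals = np.array(list(counts.values()), dtype=float)
    median = float(np.median(vals))
    q3 = float(np.percentile(vals, 75))
    return pd.DataFrame(
        {
            "bait_id": list(counts),
            "total_spectral_count": list(counts.values()),
            "median_across_baits": median,
            "upper_quartile": [v >= q3 for v in counts.values()],
        }
    )
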