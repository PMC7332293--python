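"""Bait-specific control group (BSCG) enrichment analysis.

In a multi-bait AP-MS panel every purification shares a large set of commonly
co-purifying proteins — the *background proteome*. The BSCG design exploits
this: each sample is normalized to the background proteome (median-of-ratios,
as in bulk-count size-factor estimation), and each bait's replicates are then
tested for per-protein enrichment against the pooled samples of all *other*
baits, which act as that bait's control group. The result is a log2 fold
change and a p-value for every protein detected with a bait.

Statistical choices (all exposed as parameters):

* test statistic — a two-sample t-test on log2(intensity + eps), with a
  pooled-variance default that remains calibrated at two technical
  duplicates per bait and a Welch variant behind the same interface;
* pseudocount eps = 1 intensity unit, avoiding -inf on near-zero cells
  without distorting high-intensity ratios;
* control-side missing cells are imputed by seeded draws around the
  protein's own observed control mean (spread set by the median
  within-protein sd), which keeps the null distribution of the test
  calibrated; a global low-abundance policy (per-sample 1st percentile of
  log2 intensity, the Perseus-style left-shifted imputation) is available as
  an option but inserts low outliers into mid-abundance control groups and
  makes the test conservative. Bait-side missing cells are dropped —
  detection with a bait coupled to absence in controls is the signal of
  interest and must not be erased;
* proteins never detected in any control sample cannot form a fold change:
  they are emitted with n_ctrl_obs = 0 and a missing p-value and are picked
  up by the spectral-index exclusivity path instead;
* no multiple-testing correction is applied to the filter; Benjamini-
  Hochberg q-values are reported as an extra column.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .quant_io import QuantMatrix

DEFAULT_BACKGROUND_THRESHOLD = 0.9
DEFAULT_PSEUDOCOUNT = 1.0
MIN_BACKGROUND_MEMBERS = 10


class BscgError(Exception):
    pass


class DegenerateBackgroundError(BscgError):
    pass


class NormalizationError(BscgError):
    pass


class StatisticsError(BscgError):
    pass


@dataclass(frozen=True)
class BackgroundProteome:
    members: frozenset[str]
    detection_fraction_threshold: float


@dataclass
class NormalizedMatrix:
    values: pd.DataFrame  # proteins x samples, NaN = missing
    scale_factors: pd.Series  # per sample, positive
    samples: list  # SampleMeta, aligned with columns


def define_background(
    qm: QuantMatrix,
    contaminants: set[str],
    threshold: float = DEFAULT_BACKGROUND_THRESHOLD,
) -> BackgroundProteome:
    """Proteins detected in at least ``threshold`` of all samples, minus contaminants."""
    if not (0 < threshold <= 1):
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    if len(qm.baits) < 2:
        raise BscgError("background definition requires >= 2 baits")
    frac = qm.intensity.notna().mean(axis=1)
    members = frozenset(frac.index[frac >= threshold]) - frozenset(contaminants)
    if len(members) < MIN_BACKGROUND_MEMBERS:
        raise DegenerateBackgroundError(
            f"only {len(members)} background members at threshold {threshold}; "
            "normalization would be unreliable — lower the threshold"
        )
    return BackgroundProteome(members, threshold)


def normalize_to_background(qm: QuantMatrix, bg: BackgroundProteome) -> NormalizedMatrix:
    """Median-of-ratios normalization of every sample to the background proteome.

    For each background member p, rowref[p] is the median of its raw intensity
    over samples where it is detected; a sample's scale factor is the median,
    over background members detected in it, of raw/rowref. All cells are then
    divided by the sample's scale factor; missing stays missing.
    """
    missing = set(bg.members) - set(qm.proteins)
    if missing:
        raise BscgError(f"background members absent from matrix: {sorted(missing)[:5]}")
    raw = qm.intensity
    bg_rows = raw.loc[sorted(bg.members)]
    rowref = bg_rows.median(axis=1, skipna=True)
    ratios = bg_rows.div(rowref, axis=0)
    n_obs = ratios.notna().sum(axis=0)
    bad = n_obs.index[n_obs < 3]
    if len(bad):
        raise NormalizationError(
            f"samples with <3 background observations: {list(bad)}"
        )
    scale = ratios.median(axis=0, skipna=True)
    return NormalizedMatrix(raw.div(scale, axis=1), scale, list(qm.samples))


def _imputation_sd(log_values: pd.DataFrame) -> float:
    """Median across proteins of the within-protein sd of log2 intensity."""
    sds = log_values.std(axis=1, skipna=True, ddof=1)
    med = float(sds.median(skipna=True))
    if not np.isfinite(med) or med <= 0:
        med = 0.3  # fallback for degenerate (noise-free) fixtures
    return med


def bscg_statistics(
    nm: NormalizedMatrix,
    bait: str,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    seed: int = 0,
    method: str = "pooled",
    imputation: str = "protein_mean",
) -> pd.DataFrame:
    """Per-protein two-sample test of one bait's replicates against all other
    baits.

    ``imputation`` selects how control-side missing cells are filled:
    ``"protein_mean"`` (default) draws around the protein's observed control
    mean; ``"low_abundance"`` draws around the per-sample 1st percentile of
    log2 intensity. Proteins with no detected control cell are never imputed.

    ``method`` selects the variance strategy: ``"pooled"`` (default) is the
    classical equal-variance t-test, which borrows the control group's
    degrees of freedom and stays calibrated with as few as two bait
    replicates; ``"welch"`` drops the homoscedasticity assumption but is
    anticonservative at two replicates, where its 1-df bait variance
    estimate occasionally collapses while the Satterthwaite df stays large.

    Returns a DataFrame with columns bait_id, protein_acc, log2fc, p_value,
    n_bait_obs, n_ctrl_obs — one row per protein detected in at least one of
    the bait's replicates.
    """
    if method not in ("pooled", "welch"):
        raise ValueError(f"unknown test method {method!r}")
    if imputation not in ("protein_mean", "low_abundance"):
        raise ValueError(f"unknown imputation policy {imputation!r}")
    bait_cols = [s.sample_id for s in nm.samples if s.bait_id == bait]
    ctrl_cols = [s.sample_id for s in nm.samples if s.bait_id != bait]
    if len(bait_cols) < 2:
        raise StatisticsError(
            f"bait {bait!r} has {len(bait_cols)} replicate(s); >= 2 required "
            "for a variance estimate"
        )
    ctrl_baits = {s.bait_id for s in nm.samples if s.bait_id != bait}
    if len(ctrl_baits) < 2:
        raise StatisticsError("control group requires >= 2 other baits")

    log_all = np.log2(nm.values + pseudocount)
    bait_log = log_all[bait_cols]
    ctrl_log = log_all[ctrl_cols]

    detected_in_bait = bait_log.notna().any(axis=1)
    idx = bait_log.index[detected_in_bait]
    bait_arr = bait_log.loc[idx].to_numpy()
    ctrl_arr = ctrl_log.loc[idx].to_numpy()
    n_bait_obs = np.sum(~np.isnan(bait_arr), axis=1)
    n_ctrl_obs = np.sum(~np.isnan(ctrl_arr), axis=1)

    # impute control-side missing cells, but only for proteins seen in >= 1
    # control sample — never-seen proteins go to the exclusivity path instead
    rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, _stable_hash(bait)]))
    sd = _imputation_sd(log_all)
    ctrl_filled = ctrl_arr.copy()
    has_ctrl = n_ctrl_obs > 0
    miss = np.isnan(ctrl_arr) & has_ctrl[:, None]
    if miss.any():
        if imputation == "protein_mean":
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                mu = np.broadcast_to(
                    np.nanmean(ctrl_arr, axis=1)[:, None], ctrl_arr.shape
                )
        else:  # low_abundance: per-sample 1st percentile of log2 intensity
            q01 = ctrl_log.quantile(0.01, axis=0).to_numpy()
            mu = np.broadcast_to(q01, ctrl_arr.shape)
        ctrl_filled[miss] = rng.normal(mu[miss], sd)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        bait_mean = np.nanmean(bait_arr, axis=1)
        ctrl_mean = np.nanmean(ctrl_filled, axis=1)
        res = stats.ttest_ind(
            bait_arr,
            ctrl_filled,
            axis=1,
            equal_var=(method == "pooled"),
            nan_policy="omit",
        )
    log2fc = bait_mean - np.where(has_ctrl, ctrl_mean, np.nan)
    p = np.asarray(res.pvalue, dtype=float)
    # zero variance in both groups makes the Welch statistic 0/0; resolve by
    # the limit: identical means -> no evidence (p=1), distinct means -> p=0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        se2 = np.nanvar(bait_arr, axis=1, ddof=1) + np.nanvar(
            ctrl_filled, axis=1, ddof=1
        )
    degenerate = np.isnan(p) & (n_bait_obs >= 2) & has_ctrl & (se2 == 0)
    p[degenerate] = np.where(np.isclose(bait_mean[degenerate], ctrl_mean[degenerate]), 1.0, 0.0)
    p = np.where(has_ctrl & (n_bait_obs >= 2), p, np.nan)

    return pd.DataFrame(
        {
            "bait_id": bait,
            "protein_acc": idx,
            "log2fc": log2fc,
            "p_value": p,
            "n_bait_obs": n_bait_obs,
            "n_ctrl_obs": n_ctrl_obs,
        }
    ).reset_index(drop=True)


def _stable_hash(text: str) -> int:
    h = 2166136261
    for ch in text.encode():
        h = ((h ^ ch) * 16777619) & 0x7FFFFFFF
    return h


def score_all_baits(
    nm: NormalizedMatrix,
    baits: list[str] | None = None,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    seed: int = 0,
    method: str = "pooled",
    imputation: str = "protein_mean",
) -> pd.DataFrame:
    """Run ``bscg_statistics`` for every bait; add Benjamini-Hochberg q-values.

    q-values are computed per bait over that bait's testable records; they are
    reported but never used by the interaction filter.
    """
    if baits is None:
        seen: dict[str, None] = {}
        for s in nm.samples:
            seen.setdefault(s.bait_id, None)
        baits = list(seen)
    frames = [
        bscg_statistics(
            nm, b, pseudocount=pseudocount, seed=seed, method=method,
            imputation=imputation,
        )
        for b in baits
    ]
    df = pd.concat(frames, ignore_index=True)
    df["q_value"] = np.nan
    for b in baits:
        mask = (df["bait_id"] == b) & df["p_value"].notna()
        if mask.any():
            df.loc[mask, "q_value"] = multipletests(
                df.loc[mask, "p_value"].to_numpy(), method="fdr_bh"
            )[1]
    return df.sort_values(["bait_id", "protein_acc"], kind="stable").reset_index(
        drop=True
    )
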