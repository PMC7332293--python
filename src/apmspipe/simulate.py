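"""Synthetic multi-bait AP-MS experiment generator with known ground truth.

The generator emulates the statistical structure of a comparative AP-MS panel
in which every purification shares a common background proteome:

* *background* proteins appear in every sample around a protein-specific base
  log2 intensity drawn from N(mu, sigma);
* each bait's *interactors* are background proteins spiked in that bait's
  samples by a log2 effect drawn uniformly from an effect range;
* *exclusive* preys have signal only in their cognate bait's samples and are
  therefore invisible to any fold-change comparison;
* *contaminants* are present everywhere at high intensity and are listed in
  the generated exclusion list;
* each bait's own protein is abundant in its own samples (the self-pulldown
  signal used as raw abundance).

Cells are observed through an intensity-dependent logistic detection model
(undetected cells are missing with spectral count 0 — missingness is monotone
in intensity, the dominant missingness mode of label-free MS). Spectral
counts for detected cells are 1 + Poisson(intensity / kappa). Peptide rows
are synthesized from a per-protein peptide pool so that unique-peptide counts
correlate with intensity, and the generated files use exactly the dialect the
readers consume, so the pipeline is exercised through its public I/O surface.

Everything derives from a single integer seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .quant_io import QuantMatrix, SampleMeta, build_quant_matrix

_AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


@dataclass(frozen=True)
class SimulationConfig:
    """Generating conditions for one synthetic experiment.

    Defaults mirror the study design this pipeline targets: 21 baits analysed
    as technical duplicates over a ~400-protein shared background, with 8
    enriched and 2 exclusive preys per bait and 30 common contaminants.
    """

    n_baits: int = 21
    n_replicates: int = 2
    n_background: int = 400
    n_interactors_per_bait: int = 8
    n_exclusive_per_bait: int = 2
    n_contaminants: int = 30
    log2_effect_range: tuple[float, float] = (2.0, 6.0)
    background_log2_mean_sd: tuple[float, float] = (20.0, 2.0)
    noise_cv: float = 0.25
    detection_midpoint: float = 16.0
    detection_slope: float = 1.0
    contaminant_log2_mean_sd: tuple[float, float] = (24.0, 1.0)
    exclusive_log2_mean_sd: tuple[float, float] = (21.0, 1.0)
    bait_log2_mean_sd: tuple[float, float] = (22.5, 1.0)
    count_scale: float = 2.0**19  # kappa: background median spectral count ~ 3
    peptide_count_scale: float = 2.0**25  # background IDs mostly rest on 1 peptide
    peptide_pool_size: int = 6
    min_two_peptides_prob: float = 0.95
    length_range: tuple[int, int] = (100, 1500)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "n_baits",
            "n_replicates",
            "n_background",
            "n_interactors_per_bait",
            "n_exclusive_per_bait",
            "n_contaminants",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.noise_cv <= 0:
            raise ValueError("noise_cv must be > 0")
        lo, hi = self.log2_effect_range
        if lo > hi:
            raise ValueError("log2_effect_range must satisfy low <= high")


@dataclass
class SyntheticTruth:
    """Ground-truth labels: role per protein and true effect per (protein, bait)."""

    roles: dict[str, str]  # background | interactor | exclusive | contaminant | bait
    interactors: dict[str, set[str]]  # bait -> spiked background preys
    exclusives: dict[str, set[str]]  # bait -> exclusive preys
    effects: dict[tuple[str, str], float] = field(default_factory=dict)

    def true_pairs(self, min_effect: float | None = None) -> set[tuple[str, str]]:
        pairs = set()
        for b, prots in self.interactors.items():
            for p in prots:
                if min_effect is None or self.effects[(p, b)] >= min_effect:
                    pairs.add((b, p))
        return pairs

    def exclusive_pairs(self) -> set[tuple[str, str]]:
        return {(b, p) for b, prots in self.exclusives.items() for p in prots}


def simulate(
    config: SimulationConfig, out_dir: str | Path | None = None
) -> tuple[QuantMatrix, dict[str, int], set[str], SyntheticTruth]:
    """Generate one experiment; optionally write the file dialects to out_dir.

    Returns (QuantMatrix, accession->length map, contaminant set, truth). The
    QuantMatrix is produced by aggregating the synthesized peptide table with
    the same roll-up the readers use.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)

    baits = [f"E3_{i + 1:02d}" for i in range(cfg.n_baits)]
    bg = [f"BG{i + 1:04d}" for i in range(cfg.n_background)]
    contams = [f"CON{i + 1:03d}" for i in range(cfg.n_contaminants)]
    exclusives: dict[str, set[str]] = {b: set() for b in baits}
    excl_all: list[str] = []
    for bi, b in enumerate(baits):
        for j in range(cfg.n_exclusive_per_bait):
            acc = f"EXC_{b}_{j + 1}"
            exclusives[b].add(acc)
            excl_all.append(acc)

    proteins = baits + bg + excl_all + contams
    roles = {p: "bait" for p in baits}
    roles.update({p: "background" for p in bg})
    roles.update({p: "exclusive" for p in excl_all})
    roles.update({p: "contaminant" for p in contams})

    interactors: dict[str, set[str]] = {}
    effects: dict[tuple[str, str], float] = {}
    lo, hi = cfg.log2_effect_range
    for b in baits:
        k = min(cfg.n_interactors_per_bait, len(bg))
        chosen = rng.choice(len(bg), size=k, replace=False)
        interactors[b] = {bg[i] for i in chosen}
        for i in chosen:
            roles[bg[i]] = "interactor"
            effects[(bg[i], b)] = float(rng.uniform(lo, hi))

    samples = [
        SampleMeta(f"{b}_r{r + 1}", b, r + 1)
        for b in baits
        for r in range(cfg.n_replicates)
    ]
    sample_ids = [s.sample_id for s in samples]
    bait_of_sample = np.array([s.bait_id for s in samples])
    n_p, n_s = len(proteins), len(samples)

    mu_bg, sd_bg = cfg.background_log2_mean_sd
    mu_con, sd_con = cfg.contaminant_log2_mean_sd
    mu_exc, sd_exc = cfg.exclusive_log2_mean_sd
    mu_bait, sd_bait = cfg.bait_log2_mean_sd

    base = np.full(n_p, -np.inf)
    idx = {p: i for i, p in enumerate(proteins)}
    for p in proteins:
        role = roles[p]
        if role in ("background", "interactor"):
            base[idx[p]] = rng.normal(mu_bg, sd_bg)
        elif role == "contaminant":
            base[idx[p]] = rng.normal(mu_con, sd_con)
        elif role == "exclusive":
            base[idx[p]] = rng.normal(mu_exc, sd_exc)
        elif role == "bait":
            base[idx[p]] = rng.normal(mu_bait, sd_bait)

    # per-cell mean log2 intensity; -inf marks structurally absent
    mean_log2 = np.tile(base[:, None], (1, n_s))
    for b in baits:
        cols = np.flatnonzero(bait_of_sample == b)
        other = np.flatnonzero(bait_of_sample != b)
        for p in interactors[b]:
            mean_log2[idx[p], cols] += effects[(p, b)]
        for p in exclusives[b]:
            mean_log2[idx[p], other] = -np.inf
        mean_log2[idx[b], other] = -np.inf  # bait protein only in own samples

    noise_sd = math.log2(1.0 + cfg.noise_cv)
    log2_int = mean_log2 + rng.normal(0.0, noise_sd, size=(n_p, n_s))
    present = np.isfinite(log2_int)

    # logistic intensity-dependent detection
    with np.errstate(over="ignore", invalid="ignore"):
        p_det = 1.0 / (
            1.0 + np.exp(-(log2_int - cfg.detection_midpoint) / cfg.detection_slope)
        )
    p_det = np.where(present, p_det, 0.0)
    detected = rng.random((n_p, n_s)) < p_det

    intensity = np.where(detected, np.exp2(np.where(present, log2_int, 0.0)), 0.0)
    lam = intensity / cfg.count_scale
    sc = np.where(detected, 1 + rng.poisson(np.where(detected, lam, 0.0)), 0)

    # peptide pools: globally distinct sequences per protein, ordered by
    # detectability — a cell supported by k peptides always carries the top k,
    # so the same "flyer" peptides recur across replicates
    pool = cfg.peptide_pool_size
    pep_len = 10
    pep_seqs = {
        p: [
            "".join(rng.choice(_AA, size=pep_len)) + "K"
            for _ in range(pool)
        ]
        for p in proteins
    }

    # distinct peptides supporting each detected cell: background
    # identifications mostly rest on a single best-flying peptide, while
    # preys intended to clear the >=2-unique-peptides criterion usually do
    n_pep = np.zeros((n_p, n_s), dtype=int)
    lam_pep = intensity / cfg.peptide_count_scale
    n_pep[detected] = 1 + rng.poisson(lam_pep[detected])
    n_pep = np.minimum(n_pep, pool)
    force2 = rng.random((n_p, len(baits))) < cfg.min_two_peptides_prob
    for bi, b in enumerate(baits):
        cols = np.flatnonzero(bait_of_sample == b)
        for p in interactors[b] | exclusives[b]:
            i = idx[p]
            if force2[i, bi]:
                n_pep[i, cols] = np.where(
                    detected[i, cols], np.maximum(n_pep[i, cols], 2), 0
                )
    sc = np.maximum(sc, n_pep)  # every reported peptide carries >= 1 spectrum

    # split each cell's intensity and counts over its top-n_pep peptides
    pep_int = np.zeros((n_p, pool, n_s))
    pep_sc = np.zeros((n_p, pool, n_s), dtype=int)
    for i in range(n_p):
        for j in np.flatnonzero(detected[i]):
            k = n_pep[i, j]
            w = rng.dirichlet(np.ones(k) * 5.0)
            pep_int[i, :k, j] = intensity[i, j] * w
            extra = rng.multinomial(sc[i, j] - k, w)
            pep_sc[i, :k, j] = 1 + extra

    rows = []
    for i, p in enumerate(proteins):
        used = np.flatnonzero(pep_sc[i].sum(axis=1) > 0)
        for u in used:
            row = {"protein": p, "peptide": pep_seqs[p][u]}
            for j, sid in enumerate(sample_ids):
                row[f"{sid}.intensity"] = pep_int[i, u, j]
                row[f"{sid}.sc"] = pep_sc[i, u, j]
            rows.append(row)
    columns = ["protein", "peptide"]
    for sid in sample_ids:
        columns += [f"{sid}.intensity", f"{sid}.sc"]
    pep_df = pd.DataFrame(rows, columns=columns)

    qm = build_quant_matrix(pep_df, samples)

    lo_L, hi_L = cfg.length_range
    lengths = {p: int(rng.integers(lo_L, hi_L + 1)) for p in proteins}
    truth = SyntheticTruth(roles, interactors, exclusives, effects)
    contam_set = set(contams)

    if out_dir is not None:
        _write_simulation(Path(out_dir), pep_df, samples, lengths, contam_set, truth)
    return qm, lengths, contam_set, truth


def _write_simulation(out, pep_df, samples, lengths, contaminants, truth) -> None:
    out.mkdir(parents=True, exist_ok=True)
    pep_df.to_csv(out / "quant.tsv", sep="\t", index=False)
    pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in samples],
            "bait_id": [s.bait_id for s in samples],
            "replicate": [s.replicate_index for s in samples],
        }
    ).to_csv(out / "samples.tsv", sep="\t", index=False)
    rng = np.random.default_rng(0)  # sequence content is irrelevant; length matters
    with open(out / "proteins.fasta", "w") as fh:
        for acc in sorted(lengths):
            seq = "".join(rng.choice(_AA, size=lengths[acc]))
            fh.write(f">{acc}\n")
            for k in range(0, len(seq), 60):
                fh.write(seq[k : k + 60] + "\n")
    with open(out / "contaminants.txt", "w") as fh:
        fh.write("# synthetic common contaminants\n")
        for acc in sorted(contaminants):
            fh.write(acc + "\n")
    rows = []
    for p, role in sorted(truth.roles.items()):
        cognates = sorted(
            {b for b, s in truth.interactors.items() if p in s}
            | {b for b, s in truth.exclusives.items() if p in s}
        )
        rows.append(
            {
                "protein_acc": p,
                "role": role,
                "cognate_baits": ";".join(cognates),
                "effects": ";".join(
                    f"{b}:{truth.effects[(p, b)]:.4f}"
                    for b in cognates
                    if (p, b) in truth.effects
                ),
            }
        )
    pd.DataFrame(rows).to_csv(out / "truth.tsv", sep="\t", index=False)


def truth_report(
    calls,
    truth: SyntheticTruth,
    qm: QuantMatrix | None = None,
    min_effect: float | None = None,
    n_curve_bins: int = 4,
) -> dict:
    """Score called interactions against the generating truth.

    Returns sensitivity over true spiked (bait, interactor) pairs (optionally
    restricted to effects >= min_effect), empirical FDR over all passing
    calls, a per-effect-size recovery curve, and the exclusivity path scored
    separately (sensitivity over exclusive pairs; when a QuantMatrix is
    given, restricted to exclusives with >1 total spectral count in their
    cognate bait, the generated analogue of the spectral-count criterion).
    """
    called = {(r.bait_id, r.protein_acc) for r in calls if r.passed_filters}
    true_pairs = truth.true_pairs(min_effect)
    all_true = truth.true_pairs() | truth.exclusive_pairs()

    sensitivity = (
        len(called & true_pairs) / len(true_pairs) if true_pairs else math.nan
    )
    fdr = len(called - all_true) / len(called) if called else math.nan

    excl = truth.exclusive_pairs()
    if qm is not None:
        eligible = set()
        for b, p in excl:
            if p in qm.spectral_count.index:
                tot = int(qm.spectral_count.loc[p, qm.samples_of_bait(b)].sum())
                if tot > 1:
                    eligible.add((b, p))
        excl = eligible
    excl_called = {
        (r.bait_id, r.protein_acc)
        for r in calls
        if r.passed_filters and r.provenance == "sinq_exclusive"
    }
    exclusive_sensitivity = len(excl_called & excl) / len(excl) if excl else math.nan

    curve = []
    effects = sorted(truth.effects.items(), key=lambda kv: kv[1])
    if effects:
        vals = np.array([v for _, v in effects])
        edges = np.quantile(vals, np.linspace(0, 1, n_curve_bins + 1))
        for k in range(n_curve_bins):
            lo, hi = edges[k], edges[k + 1]
            sel = [
                (b, p)
                for (p, b), v in truth.effects.items()
                if (v >= lo and (v < hi or k == n_curve_bins - 1))
            ]
            if sel:
                rec = sum((pair in called) for pair in sel) / len(sel)
                curve.append(
                    {"effect_lo": float(lo), "effect_hi": float(hi),
                     "n": len(sel), "recovery": rec}
                )
    return {
        "sensitivity": sensitivity,
        "fdr": fdr,
        "exclusive_sensitivity": exclusive_sensitivity,
        "recovery_curve": curve,
        "n_called": len(called),
        "n_true_pairs": len(true_pairs),
    }
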