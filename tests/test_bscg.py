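import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import t as tdist

from apmspipe import bscg
from apmspipe.bscg import (
    DegenerateBackgroundError,
    NormalizationError,
    NormalizedMatrix,
    StatisticsError,
    bscg_statistics,
    define_background,
    normalize_to_background,
    score_all_baits,
)
from apmspipe.quant_io import QuantMatrix, SampleMeta


def welch_oracle(a, b):
    """Closed-form Welch t-test (Satterthwaite df), independent of scipy's
    ttest_ind code path."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(a), len(b)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    se2 = va / na + vb / nb
    t = (a.mean() - b.mean()) / math.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    return t, 2 * tdist.sf(abs(t), df)


def make_matrix(values, samples):
    """NormalizedMatrix from a proteins x samples DataFrame (scale factors 1)."""
    return NormalizedMatrix(
        values, pd.Series(1.0, index=values.columns), list(samples)
    )


def panel_samples(n_baits, n_reps=2):
    return [
        SampleMeta(f"B{b}_r{r + 1}", f"B{b}", r + 1)
        for b in range(n_baits)
        for r in range(n_reps)
    ]


def full_quant_matrix(values, samples):
    sc = values.notna().astype(int)
    baits = []
    for s in samples:
        if s.bait_id not in baits:
            baits.append(s.bait_id)
    up = pd.DataFrame(2, index=values.index, columns=baits)
    return QuantMatrix(values, sc, up, list(samples))


class TestBackground:
    def test_membership_and_contaminant_exclusion(self):
        samples = panel_samples(2)
        rng = np.random.default_rng(0)
        vals = pd.DataFrame(
            rng.uniform(10, 20, (12, 4)),
            index=[f"P{i}" for i in range(12)],
            columns=[s.sample_id for s in samples],
        )
        qm = full_quant_matrix(vals, samples)
        bg = define_background(qm, contaminants={"P3"}, threshold=0.9)
        assert "P0" in bg.members
        assert "P3" not in bg.members

    def test_threshold_matches_brute_force_tally(self):
        # 20 proteins x 10 samples; protein P0 missing in 2 of 10 samples
        samples = panel_samples(5)
        rng = np.random.default_rng(1)
        vals = pd.DataFrame(
            rng.uniform(10, 20, (20, 10)),
            index=[f"P{i}" for i in range(20)],
            columns=[s.sample_id for s in samples],
        )
        vals.iloc[0, [2, 7]] = np.nan
        vals.iloc[5, [1]] = np.nan
        qm = full_quant_matrix(vals, samples)
        bg = define_background(qm, contaminants=set(), threshold=0.9)
        expected = {
            p
            for p in vals.index
            if vals.loc[p].notna().sum() / 10 >= 0.9
        }
        assert set(bg.members) == expected
        assert "P0" not in bg.members and "P5" in bg.members

    def test_degenerate_background_raises(self):
        samples = panel_samples(2)
        vals = pd.DataFrame(
            np.full((5, 4), 10.0),
            index=[f"P{i}" for i in range(5)],
            columns=[s.sample_id for s in samples],
        )
        with pytest.raises(DegenerateBackgroundError, match="threshold"):
            define_background(full_quant_matrix(vals, samples), set(), 0.9)


class TestNormalization:
    def _fixture(self, n_prot=12, n_baits=2, seed=0):
        samples = panel_samples(n_baits)
        rng = np.random.default_rng(seed)
        vals = pd.DataFrame(
            rng.uniform(5, 50, (n_prot, len(samples))),
            index=[f"P{i}" for i in range(n_prot)],
            columns=[s.sample_id for s in samples],
        )
        return full_quant_matrix(vals, samples)

    def test_doubled_sample_gets_scale_factor_two(self):
        # five identical samples plus one at exactly 2x every row reference
        samples = panel_samples(3)
        col = np.linspace(10, 40, 15)
        vals = pd.DataFrame(
            np.tile(col[:, None], (1, 6)),
            index=[f"P{i}" for i in range(15)],
            columns=[s.sample_id for s in samples],
        )
        vals.iloc[:, 0] *= 2.0
        qm = full_quant_matrix(vals, samples)
        bg = define_background(qm, set(), 1.0)
        nm = normalize_to_background(qm, bg)
        assert np.isclose(nm.scale_factors.iloc[0], 2.0)
        assert np.allclose(nm.scale_factors.iloc[1:], 1.0)
        assert np.allclose(nm.values.iloc[:, 0], col)
        # per-sample normalized background medians sit on the row reference
        rowref = qm.intensity.loc[sorted(bg.members)].median(axis=1)
        ratios = nm.values.loc[sorted(bg.members)].div(rowref, axis=0)
        assert np.allclose(ratios.median(axis=0), 1.0, atol=1e-9)

    def test_identical_samples_are_left_unchanged(self):
        samples = panel_samples(2)
        col = np.linspace(10, 40, 15)
        vals = pd.DataFrame(
            np.tile(col[:, None], (1, 4)),
            index=[f"P{i}" for i in range(15)],
            columns=[s.sample_id for s in samples],
        )
        qm = full_quant_matrix(vals, samples)
        nm = normalize_to_background(qm, define_background(qm, set(), 1.0))
        assert np.allclose(nm.scale_factors, 1.0)
        assert np.allclose(nm.values, vals)

    def test_scale_factors_match_brute_force_median_of_ratios(self):
        qm = self._fixture(n_prot=10, seed=3)
        bg = define_background(qm, set(), 0.9)
        nm = normalize_to_background(qm, bg)
        raw = qm.intensity
        for s in raw.columns:
            ratios = sorted(
                raw.at[p, s] / np.median(raw.loc[p].dropna())
                for p in sorted(bg.members)
                if not np.isnan(raw.at[p, s])
            )
            k = len(ratios)
            exp = (
                ratios[k // 2]
                if k % 2
                else 0.5 * (ratios[k // 2 - 1] + ratios[k // 2])
            )
            assert abs(nm.scale_factors[s] - exp) < 1e-9

    def test_sample_with_too_few_background_observations(self):
        qm = self._fixture()
        qm.intensity.iloc[:-2, 0] = np.nan  # leave 2 background obs in sample 0
        qm.spectral_count.iloc[:-2, 0] = 0
        bg = define_background(qm, set(), threshold=0.5)
        with pytest.raises(NormalizationError, match="B0_r1"):
            normalize_to_background(qm, bg)


class TestStatistics:
    def test_bait_equal_to_controls_gives_null_result(self):
        samples = panel_samples(3)
        vals = pd.DataFrame(
            np.full((12, 6), 100.0),
            index=[f"P{i}" for i in range(12)],
            columns=[s.sample_id for s in samples],
        )
        res = bscg_statistics(make_matrix(vals, samples), "B0")
        assert np.allclose(res["log2fc"], 0.0)
        assert np.allclose(res["p_value"], 1.0)

    def test_spec_example_fold_change_and_welch_oracle(self):
        # bait at log2 = 10, controls at log2 = 6 with 1e-3-scale jitter
        samples = panel_samples(3)
        jit = np.array([1e-3, -1e-3, 2e-3, -2e-3])
        log2_vals = np.array([[10.0, 10.0 + 1e-3, *(6 + jit)]])
        vals = pd.DataFrame(
            2.0 ** log2_vals - 1.0,
            index=["PX"],
            columns=[s.sample_id for s in samples],
        )
        block = pd.DataFrame(
            np.full((11, 6), 2.0**8 - 1),
            index=[f"P{i}" for i in range(11)],
            columns=vals.columns,
        )
        nm = make_matrix(pd.concat([vals, block]), samples)
        res = bscg_statistics(nm, "B0", method="welch")
        row = res[res.protein_acc == "PX"].iloc[0]
        assert abs(row.log2fc - 4.0) < 1e-2
        _, p_exp = welch_oracle(log2_vals[0, :2], log2_vals[0, 2:])
        assert abs(row.p_value - p_exp) < 1e-9

    def test_welch_matches_oracle_on_random_inputs(self):
        rng = np.random.default_rng(42)
        samples = panel_samples(4)
        log2_vals = rng.normal(10, 1, (8, 8))
        vals = pd.DataFrame(
            2.0**log2_vals - 1.0,
            index=[f"P{i}" for i in range(8)],
            columns=[s.sample_id for s in samples],
        )
        res = bscg_statistics(make_matrix(vals, samples), "B0", method="welch")
        for i, row in res.iterrows():
            j = list(vals.index).index(row.protein_acc)
            _, p_exp = welch_oracle(log2_vals[j, :2], log2_vals[j, 2:])
            assert abs(row.p_value - p_exp) < 1e-9

    def test_welch_within_band_of_exhaustive_permutation_p(self):
        # 6-sample toy: permutation p over all C(6,2) bait-label assignments
        obs = np.array([12.1, 11.8, 9.9, 10.2, 10.0, 9.7])
        samples = panel_samples(3)
        vals = pd.DataFrame(
            2.0 ** obs[None, :] - 1.0,
            index=["PX"],
            columns=[s.sample_id for s in samples],
        )
        res = bscg_statistics(make_matrix(vals, samples), "B0", method="welch")
        p_welch = float(res[res.protein_acc == "PX"].p_value.iloc[0])
        t_obs, _ = welch_oracle(obs[:2], obs[2:])
        stats = []
        for pair in itertools.combinations(range(6), 2):
            a = obs[list(pair)]
            b = obs[[i for i in range(6) if i not in pair]]
            stats.append(abs(welch_oracle(a, b)[0]))
        p_perm = float(np.mean(np.array(stats) >= abs(t_obs) - 1e-12))
        assert abs(p_welch - p_perm) <= 0.15

    def test_single_replicate_bait_rejected(self):
        samples = [
            SampleMeta("B0_r1", "B0", 1),
            SampleMeta("B1_r1", "B1", 1),
            SampleMeta("B1_r2", "B1", 2),
            SampleMeta("B2_r1", "B2", 1),
            SampleMeta("B2_r2", "B2", 2),
        ]
        vals = pd.DataFrame(
            np.full((3, 5), 10.0),
            index=["P0", "P1", "P2"],
            columns=[s.sample_id for s in samples],
        )
        with pytest.raises(StatisticsError, match="B0"):
            bscg_statistics(make_matrix(vals, samples), "B0")

    def test_protein_never_in_controls_flagged_for_exclusive_path(self):
        samples = panel_samples(3)
        vals = pd.DataFrame(
            np.full((12, 6), 50.0),
            index=[f"P{i}" for i in range(12)],
            columns=[s.sample_id for s in samples],
        )
        vals.loc["P0", ["B1_r1", "B1_r2", "B2_r1", "B2_r2"]] = np.nan
        res = bscg_statistics(make_matrix(vals, samples), "B0")
        row = res[res.protein_acc == "P0"].iloc[0]
        assert row.n_ctrl_obs == 0
        assert math.isnan(row.p_value)

    def test_records_only_for_proteins_detected_in_bait(self):
        samples = panel_samples(3)
        vals = pd.DataFrame(
            np.full((4, 6), 50.0),
            index=["P0", "P1", "P2", "P3"],
            columns=[s.sample_id for s in samples],
        )
        vals.loc["P3", ["B0_r1", "B0_r2"]] = np.nan
        res = bscg_statistics(make_matrix(vals, samples), "B0")
        assert "P3" not in set(res.protein_acc)

    def test_bait_label_equivariance(self):
        samples = panel_samples(3)
        rng = np.random.default_rng(5)
        vals = pd.DataFrame(
            rng.uniform(20, 80, (10, 6)),
            index=[f"P{i}" for i in range(10)],
            columns=[s.sample_id for s in samples],
        )
        nm = make_matrix(vals, samples)
        res = score_all_baits(nm)
        # swap the bait identities of the first and last sample pairs
        swapped = [
            SampleMeta(s.sample_id, {"B0": "B2", "B2": "B0"}.get(s.bait_id, s.bait_id),
                       s.replicate_index)
            for s in samples
        ]
        res_sw = score_all_baits(make_matrix(vals, swapped))
        for bait, twin in (("B0", "B2"), ("B2", "B0"), ("B1", "B1")):
            a = res[res.bait_id == bait].set_index("protein_acc")
            b = res_sw[res_sw.bait_id == twin].set_index("protein_acc")
            assert np.allclose(a["p_value"], b["p_value"])
            assert np.allclose(a["log2fc"], b["log2fc"])

    def test_effect_monotonicity_in_p_value(self):
        samples = panel_samples(4)
        rng = np.random.default_rng(9)
        base = pd.DataFrame(
            rng.uniform(40, 60, (10, 8)),
            index=[f"P{i}" for i in range(10)],
            columns=[s.sample_id for s in samples],
        )
        prev = None
        for delta in (0.0, 1.0, 2.0, 4.0):
            vals = base.copy()
            vals.loc["P0", ["B0_r1", "B0_r2"]] *= 2.0**delta
            res = bscg_statistics(make_matrix(vals, samples), "B0")
            p = float(res[res.protein_acc == "P0"].p_value.iloc[0])
            if prev is not None:
                assert p <= prev + 1e-12
            prev = p

    def test_q_values_reported_not_below_p(self):
        samples = panel_samples(3)
        rng = np.random.default_rng(11)
        vals = pd.DataFrame(
            rng.uniform(20, 80, (15, 6)),
            index=[f"P{i}" for i in range(15)],
            columns=[s.sample_id for s in samples],
        )
        res = score_all_baits(make_matrix(vals, samples))
        ok = res.dropna(subset=["p_value"])
        assert (ok["q_value"] >= ok["p_value"] - 1e-12).all()


class TestScaleInvariance:
    def test_exact_absorption_when_row_references_are_stable(self):
        # sample B0_r1 is uniformly the largest for every protein, so scaling
        # it cannot move any row-reference median: absorption must be exact
        samples = panel_samples(3)
        rng = np.random.default_rng(2)
        vals = pd.DataFrame(
            rng.uniform(20, 40, (15, 6)),
            index=[f"P{i}" for i in range(15)],
            columns=[s.sample_id for s in samples],
        )
        vals.iloc[:, 0] = vals.iloc[:, 1:].max(axis=1) * 2
        qm = full_quant_matrix(vals, samples)

        def run(q):
            nm = normalize_to_background(q, define_background(q, set(), 1.0))
            return score_all_baits(nm)

        res_a = run(qm)
        scaled = full_quant_matrix(vals.copy(), samples)
        scaled.intensity.iloc[:, 0] *= 7.0
        res_b = run(scaled)
        assert np.allclose(res_a["p_value"], res_b["p_value"], atol=1e-12)
        assert np.allclose(res_a["log2fc"], res_b["log2fc"], atol=1e-12)

    def test_near_invariance_on_simulated_panel(self, default_sim):
        qm, _, contams, _ = default_sim
        def run(q):
            nm = normalize_to_background(q, define_background(q, contams))
            return score_all_baits(nm, seed=1)

        res_a = run(qm)
        scaled = QuantMatrix(
            qm.intensity.copy(), qm.spectral_count, qm.unique_peptides, qm.samples
        )
        scaled.intensity.iloc[:, 0] *= 3.0
        res_b = run(scaled)
        d_fc = (res_a["log2fc"] - res_b["log2fc"]).abs().dropna()
        assert float(d_fc.quantile(0.99)) < 0.1
        same_call = (res_a["p_value"] < 0.05) == (res_b["p_value"] < 0.05)
        assert same_call.mean() > 0.99
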