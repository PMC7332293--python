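import numpy as np
import pandas as pd
import pytest

from apmspipe import bscg, hcip, sinq
from apmspipe.quant_io import SampleMeta, build_quant_matrix
from apmspipe.simulate import SimulationConfig, simulate

CANONICAL_SEED = 1


def make_peptide_table(samples, rows):
    """Build a dialect-conformant peptide table from sparse row specs.

    ``rows`` is a list of (protein, peptide, {sample_id: (intensity, sc)}).
    """
    recs = []
    for prot, pep, cells in rows:
        rec = {"protein": prot, "peptide": pep}
        for s in samples:
            inten, sc = cells.get(s.sample_id, (0.0, 0))
            rec[f"{s.sample_id}.intensity"] = inten
            rec[f"{s.sample_id}.sc"] = sc
        recs.append(rec)
    cols = ["protein", "peptide"]
    for s in samples:
        cols += [f"{s.sample_id}.intensity", f"{s.sample_id}.sc"]
    return pd.DataFrame(recs, columns=cols)


@pytest.fixture(scope="session")
def default_sim():
    """The default-condition experiment: 21 baits x 2 replicates, 400
    background proteins, 8 interactors + 2 exclusives per bait."""
    return simulate(SimulationConfig(seed=CANONICAL_SEED))


@pytest.fixture(scope="session")
def default_scored(default_sim):
    """BSCG results + SINQ exclusives + merged calls on the default run."""
    qm, lengths, contams, truth = default_sim
    bg = bscg.define_background(qm, contams)
    nm = bscg.normalize_to_background(qm, bg)
    results = bscg.score_all_baits(nm, seed=CANONICAL_SEED)
    table = sinq.sinq_table(qm, lengths)
    exclusives = sinq.find_exclusives(table, qm.samples, contams)
    calls = hcip.call_hcips(results, qm, contams)
    merged = hcip.merge_hcips([r for r in calls if r.passed_filters], exclusives)
    return {
        "qm": qm,
        "lengths": lengths,
        "contaminants": contams,
        "truth": truth,
        "background": bg,
        "normalized": nm,
        "results": results,
        "sinq_table": table,
        "exclusives": exclusives,
        "calls": calls,
        "merged": merged,
    }


@pytest.fixture(scope="session")
def small_sim_files(tmp_path_factory):
    """A compact written experiment for pipeline/CLI tests (6 baits)."""
    out = tmp_path_factory.mktemp("smallsim")
    cfg = SimulationConfig(
        n_baits=6,
        n_background=80,
        n_interactors_per_bait=4,
        n_exclusive_per_bait=1,
        n_contaminants=8,
        seed=7,
    )
    simulate(cfg, out_dir=out)
    return out


@pytest.fixture
def toy_samples():
    return [
        SampleMeta("A_r1", "A", 1),
        SampleMeta("A_r2", "A", 2),
        SampleMeta("B_r1", "B", 1),
        SampleMeta("B_r2", "B", 2),
    ]


@pytest.fixture
def toy_qm(toy_samples):
    rows = [
        ("P1", "AAAK", {"A_r1": (5.0, 2), "A_r2": (6.0, 1),
                        "B_r1": (5.5, 2), "B_r2": (5.0, 1)}),
        ("P1", "CCCK", {"A_r1": (5.0, 1), "B_r1": (4.0, 1), "B_r2": (3.0, 2)}),
        ("P2", "DDDK", {"A_r1": (9.0, 3), "A_r2": (8.0, 2),
                        "B_r1": (7.0, 2), "B_r2": (9.0, 3)}),
        ("P3", "EEEK", {"A_r1": (2.0, 1), "A_r2": (2.5, 1), "B_r1": (2.2, 1)}),
    ]
    return build_quant_matrix(make_peptide_table(toy_samples, rows), toy_samples)
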