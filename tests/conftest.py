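"""Shared fixtures: tiny hand-written inputs and one cached recovery run."""

from __future__ import annotations

import numpy as np
import pytest

import eqtlrank as er


EQTL_TSV = """snp\teffect_allele\tgene\ttissue\tnes\tfdr
rsA\tA\tGENE1\tHeart_Atrial_Appendage\t0.40\t0.01
rsA\tA\tGENE2\tBrain_Cerebellum\t-0.25\t0.02
rsB\tC\tGENE1\tHeart_Atrial_Appendage\t-0.50\t0.01
"""


@pytest.fixture
def eqtl_tsv(tmp_path):
    p = tmp_path / "eqtl.tsv"
    p.write_text(EQTL_TSV)
    return p


@pytest.fixture
def small_table(eqtl_tsv):
    return er.load_eqtl_table(eqtl_tsv, study_snps={"rsA", "rsB", "rsX"})


@pytest.fixture
def small_gm():
    """4 samples x 3 SNPs, counted alleles already the effect alleles."""
    dosages = np.array([
        [0, 1, 2],
        [1, 2, 0],
        [2, 0, 1],
        [0, 0, 0],
    ], dtype=float)
    return er.GenotypeMatrix(
        sample_ids=["s1", "s2", "s3", "s4"],
        snp_ids=["rsA", "rsB", "rsX"],
        dosages=dosages,
        counted_allele={"rsA": "A", "rsB": "C", "rsX": "G"},
        other_allele={"rsA": "G", "rsB": "T", "rsX": "A"},
        labels=np.array([1, 1, 0, 0]),
    )


@pytest.fixture(scope="session")
def recovery_run():
    """One full recovery-config run shared by the slower tests.

    Simulated cohort with 12 causal features in one tissue (population AUC
    0.70), filtered, with a 50-model ensemble and final fit.
    """
    cfg = er.recovery_config(seed=11)
    table = er.simulate_reference(cfg)
    gm, truth = er.simulate_cohort(cfg, table)
    fm, _ = er.build_feature_matrix(gm, table)
    fms = er.standardize(fm)
    fmk, results = er.filter_features(fms)
    hp = er.HyperParams("elastic_net", 0.1, 0.5)
    ens = er.cv_ensemble(fmk, hp, repeats=5, folds=10, seed=11)
    model = er.fit_final_model(fmk, hp, seed=11)
    return {
        "cfg": cfg, "table": table, "gm": gm, "truth": truth, "fm": fms,
        "fm_kept": fmk, "filter_results": results, "hp": hp,
        "ensemble": ens, "model": model,
    }
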