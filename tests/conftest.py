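"""Shared fixtures: small synthetic cohorts and on-disk fixture files."""

import numpy as np
import pandas as pd
import pytest

import carrierprs as cp


@pytest.fixture(scope="session")
def small_spec():
    """A modest clinic-ascertained BRCA1 breast-cancer-like study."""
    return cp.make_study_spec("brca1_bc", n_target=1500, seed=42)


@pytest.fixture(scope="session")
def small_cohort(small_spec):
    cohort, gmat, truth = cp.gen_cohort(small_spec)
    return cohort, gmat, truth


@pytest.fixture(scope="session")
def scored_cohort(small_spec, small_cohort):
    cohort, gmat, _ = small_cohort
    result = cp.score_cohort(
        cp.weight_table_for_spec(small_spec), gmat, scheme=cp.PercentileScheme()
    )
    return cohort, result


@pytest.fixture()
def weight_table_file(tmp_path):
    def make(n=3, tag="custom", weight_override=None):
        rng = np.random.default_rng(7)
        df = pd.DataFrame(
            {
                "variant_id": [f"rs{i}" for i in range(n)],
                "chrom": ["1"] * n,
                "pos": np.arange(1, n + 1) * 100,
                "effect_allele": ["A"] * n,
                "other_allele": ["G"] * n,
                "effect_allele_freq": rng.uniform(0.05, 0.95, n).round(4),
                "weight": rng.normal(0, 0.1, n).round(5),
                "phenotype_tag": [tag] * n,
            }
        )
        if weight_override is not None:
            df.loc[weight_override[0], "weight"] = weight_override[1]
        path = tmp_path / "weights.tsv"
        df.to_csv(path, sep="\t", index=False)
        return path, df

    return make


@pytest.fixture()
def cohort_file(tmp_path):
    def make(rows):
        df = pd.DataFrame(
            rows,
            columns=[
                "individual_id",
                "family_id",
                "study",
                "gene",
                "affected",
                "age_end",
                "age_entry",
            ],
        )
        path = tmp_path / "cohort.tsv"
        df.to_csv(path, sep="\t", index=False)
        return path

    return make
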