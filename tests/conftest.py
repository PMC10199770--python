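"""Shared fixtures: small synthetic cohorts and signatures, generated in-process."""

import numpy as np
import pandas as pd
import pytest

import exopurity as xp


@pytest.fixture(scope="session")
def cohort():
    """Default synthetic two-group cohort (500 miRNAs, 30 planted DE, 20+20)."""
    spec = xp.SyntheticCohortSpec(seed=11)
    counts, meta, truth = xp.synthetic_cohort(spec)
    return {"spec": spec, "counts": counts, "meta": meta, "truth": truth}


@pytest.fixture(scope="session")
def cohort_signature(cohort):
    return xp.build_signature(cohort["counts"], cohort["meta"])


@pytest.fixture(scope="session")
def cohort_sources(cohort):
    """Per-group CPM source matrices of the default cohort."""
    cpm = xp.cpm_normalize(cohort["counts"])
    meta = cohort["meta"]
    by_group = {
        g: cpm.subset_samples(meta.loc[meta["group"] == g, "sample_id"])
        for g in ("cancer", "healthy")
    }
    return by_group


@pytest.fixture()
def tiny_signature():
    """Hand-built, well-separated two-column profile for exact checks."""
    E = np.array(
        [
            [100.0, 10.0],
            [5.0, 80.0],
            [300.0, 50.0],
            [20.0, 200.0],
        ]
    )
    return xp.SignatureProfile(
        mirna_ids=["mir-a", "mir-b", "mir-c", "mir-d"], E=E
    )


@pytest.fixture()
def tiny_counts():
    values = pd.DataFrame(
        {
            "s1": [10.0, 0.0, 5.0],
            "s2": [5.0, 7.0, 3.0],
            "s3": [1.0, 3.0, 0.0],
            "s4": [2.0, 2.0, 2.0],
        },
        index=pd.Index(["mir-a", "mir-b", "mir-c"], name="mirna_id"),
    )
    return xp.CountMatrix(values, scale="raw_counts")


@pytest.fixture()
def tiny_meta():
    return pd.DataFrame(
        {
            "sample_id": ["s1", "s2", "s3", "s4"],
            "group": ["cancer", "cancer", "healthy", "healthy"],
            "cancer_type": ["lung", "lung", None, None],
        }
    )
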