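"""Differential testing, stability filtering and signature assembly."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import exopurity as xp
from exopurity.signature import bh_adjust, nb_de_test, size_factors


def bh_oracle(p):
    """Brute-force Benjamini-Hochberg: sort, p*n/rank, cumulative min, monotone."""
    p = np.asarray(p, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(n)
    running = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * n / rank)
        adj[i] = running
    return adj


@settings(max_examples=40, deadline=None, derandomize=True)
@given(
    p=st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=1000)
)
def test_bh_matches_brute_force_oracle(p):
    np.testing.assert_allclose(bh_adjust(p), bh_oracle(p), rtol=1e-12, atol=1e-12)


def test_bh_at_least_pvalue():
    rng = np.random.default_rng(0)
    p = rng.uniform(size=200)
    assert (bh_adjust(p) >= p - 1e-15).all()


def test_size_factors_recover_depth_ratio():
    # sample 2 sequenced exactly twice as deep as sample 1
    rng = np.random.default_rng(1)
    base = rng.integers(50, 500, size=100).astype(float)
    values = np.column_stack([base, 2 * base])
    sf = size_factors(values)
    np.testing.assert_allclose(sf[1] / sf[0], 2.0, rtol=1e-12)


class TestNbDeTest:
    def test_null_type_one_error(self):
        """Two identical NB groups: ~5% of miRNAs significant at p<0.05."""
        spec = xp.SyntheticCohortSpec(
            n_mirna=2000, n_de=0, nb_dispersion=0.1, seed=101
        )
        counts, meta, _ = xp.synthetic_cohort(spec)
        res = nb_de_test(counts, meta)
        rate = (res["pvalue"] < 0.05).mean()
        assert 0.03 <= rate <= 0.07

    def test_planted_log2fc_recovered(self):
        """Planted 4-fold changes estimated within +-0.3 for >=90% of miRNAs."""
        spec = xp.SyntheticCohortSpec(
            n_mirna=400,
            n_de=80,
            log2fc_range=(2.0, 2.0),
            nb_dispersion=0.05,
            seed=7,
        )
        counts, meta, truth = xp.synthetic_cohort(spec)
        res = nb_de_test(counts, meta).set_index("mirna_id")
        planted = truth[truth.is_de]
        est = res.loc[planted.mirna_id, "log2fc"].to_numpy()
        ok = np.abs(est - planted.true_log2fc.to_numpy()) <= 0.3
        assert ok.mean() >= 0.9

    def test_identical_counts_give_zero_lfc(self, tiny_meta):
        df = pd.DataFrame(
            {s: [40.0, 10.0] for s in tiny_meta.sample_id},
            index=pd.Index(["m1", "m2"], name="mirna_id"),
        )
        res = nb_de_test(xp.CountMatrix(df), tiny_meta)
        np.testing.assert_allclose(res["log2fc"], 0.0, atol=1e-8)

    def test_small_group_rejected(self, tiny_counts, tiny_meta):
        meta = tiny_meta.copy()
        meta.loc[1, "group"] = "healthy"
        with pytest.raises(ValueError, match="2 samples per group"):
            nb_de_test(tiny_counts, meta)


class TestVarianceFilter:
    def _cpm(self, rows, meta):
        df = pd.DataFrame(
            rows, index=pd.Index([f"m{i}" for i in range(len(rows))], name="mirna_id"),
            columns=list(meta.sample_id),
        )
        # declare as CPM directly: the filter operates on the given matrix
        return xp.CountMatrix(df, scale="cpm")

    def test_constant_within_groups_retained(self, tiny_meta):
        cpm = self._cpm([[100.0, 100.0, 7.0, 7.0]], tiny_meta)
        assert xp.variance_filter(cpm, tiny_meta) == {"m0"}

    def test_high_variance_excluded(self, tiny_meta):
        # within-group log2 values {0, 4}: variance 8 with ddof=1, > 2
        cpm = self._cpm([[0.0, 15.0, 0.0, 15.0]], tiny_meta)
        assert xp.variance_filter(cpm, tiny_meta) == set()

    def test_infinite_threshold_keeps_all(self, tiny_meta):
        cpm = self._cpm([[0.0, 15.0, 0.0, 15.0], [1.0, 2.0, 3.0, 4.0]], tiny_meta)
        got = xp.variance_filter(cpm, tiny_meta, var_threshold=np.inf)
        assert got == {"m0", "m1"}


class TestBuildSignature:
    def test_recovers_planted_de(self, cohort, cohort_signature):
        planted = set(cohort["truth"].loc[cohort["truth"].is_de, "mirna_id"])
        chosen = set(cohort_signature.mirna_ids)
        assert len(chosen & planted) >= 27
        assert len(chosen - planted) <= 5

    def test_no_de_cohort_raises(self):
        spec = xp.SyntheticCohortSpec(n_mirna=150, n_de=0, seed=3)
        counts, meta, _ = xp.synthetic_cohort(spec)
        with pytest.raises(ValueError, match="relax"):
            xp.build_signature(counts, meta)

    def test_sample_and_mirna_order_invariance(self, cohort):
        counts, meta = cohort["counts"], cohort["meta"]
        rng = np.random.default_rng(9)
        s_perm = list(rng.permutation(counts.sample_ids))
        m_perm = list(rng.permutation(counts.mirna_ids))
        shuffled = xp.CountMatrix(
            counts.values.loc[m_perm, s_perm], scale="raw_counts"
        )
        sig1 = xp.build_signature(counts, meta)
        sig2 = xp.build_signature(shuffled, meta)
        assert set(sig1.mirna_ids) == set(sig2.mirna_ids)
        f1 = sig1.to_frame().set_index("mirna_id").sort_index()
        f2 = sig2.to_frame().set_index("mirna_id").sort_index()
        np.testing.assert_allclose(f1.to_numpy(), f2.to_numpy(), rtol=1e-12)

    def test_external_de_table_bypasses_internal_test(self, cohort):
        counts, meta, truth = cohort["counts"], cohort["meta"], cohort["truth"]
        de = pd.DataFrame(
            {
                "mirna_id": truth.mirna_id,
                "log2fc": truth.true_log2fc,
                "pvalue": np.where(truth.is_de, 1e-12, 0.9),
                "fdr": np.where(truth.is_de, 1e-10, 0.95),
            }
        )
        sig = xp.build_signature(counts, meta, de_table=de)
        assert set(sig.mirna_ids) == set(truth.loc[truth.is_de, "mirna_id"])


class TestPanCancerSignature:
    def _sig(self, ids, offset=0.0):
        E = np.column_stack(
            [100.0 + offset + np.arange(len(ids)), 10.0 + np.arange(len(ids))]
        )
        return xp.SignatureProfile(mirna_ids=ids, E=E)

    def test_strictly_more_than_threshold(self):
        # mir-x in 6 of 11 signatures (included), mir-y in 5 (excluded)
        sigs = {}
        for k in range(11):
            ids = ["mir-a", "mir-b"]
            if k < 6:
                ids.append("mir-x")
            if k < 5:
                ids.append("mir-y")
            sigs[f"c{k}"] = self._sig(ids)
        pan = xp.pan_cancer_signature(sigs, min_cancer_count=5)
        assert "mir-x" in pan.mirna_ids
        assert "mir-y" not in pan.mirna_ids
        assert {"mir-a", "mir-b"} <= set(pan.mirna_ids)

    def test_identical_inputs_give_identity(self):
        sigs = {f"c{k}": self._sig(["mir-a", "mir-b", "mir-c"]) for k in range(3)}
        pan = xp.pan_cancer_signature(sigs, min_cancer_count=2)
        ref = sigs["c0"]
        assert pan.mirna_ids == ref.mirna_ids
        np.testing.assert_allclose(pan.E, ref.E)

    def test_e_is_unweighted_mean_over_carriers(self):
        sigs = {
            "c0": self._sig(["mir-a", "mir-b", "mir-c"], offset=0.0),
            "c1": self._sig(["mir-a", "mir-b", "mir-c"], offset=10.0),
            "c2": self._sig(["mir-a", "mir-b"], offset=40.0),
        }
        pan = xp.pan_cancer_signature(sigs, min_cancer_count=1)
        row = dict(zip(pan.mirna_ids, pan.E))
        np.testing.assert_allclose(row["mir-a"][0], (100 + 110 + 140) / 3)
        np.testing.assert_allclose(row["mir-c"][0], (102 + 112) / 2)

    def test_too_few_inputs_raise(self):
        sigs = {f"c{k}": self._sig(["mir-a", "mir-b"]) for k in range(4)}
        with pytest.raises(ValueError, match="more than 5"):
            xp.pan_cancer_signature(sigs, min_cancer_count=5)
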