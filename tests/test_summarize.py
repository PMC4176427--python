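import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from methylqc import io as mio
from methylqc import summarize as msum
from methylqc import synthetic_data as msim
from .conftest import oracle_quantiles

finite_intensity = st.floats(min_value=0.0, max_value=1e7, allow_nan=False)


class TestTransforms:
    def test_cn_is_elementwise_sum(self):
        assert msum.compute_cn(500.0, 300.0) == 800.0
        assert msum.compute_cn(0.0, 0.0) == 0.0
        rng = np.random.default_rng(0)
        m, u = rng.uniform(0, 1e4, (10, 4)), rng.uniform(0, 1e4, (10, 4))
        expected = np.array([[m[i, j] + u[i, j] for j in range(4)] for i in range(10)])
        np.testing.assert_array_equal(msum.compute_cn(m, u), expected)

    def test_cn_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            msum.compute_cn(np.ones((2, 2)), np.ones((3, 2)))

    @pytest.mark.parametrize(
        "m, u, offset, expected",
        [
            (1000.0, 1000.0, 100.0, 1000.0 / 2100.0),
            (0.0, 123.0, 100.0, 0.0),
            (900.0, 0.0, 100.0, 0.9),
            (0.0, 0.0, 0.0, 0.0),  # defined as 0 in the degenerate case
        ],
    )
    def test_beta_direct_evaluation(self, m, u, offset, expected):
        assert msum.compute_beta(m, u, offset) == pytest.approx(expected, abs=1e-12)

    def test_beta_negative_offset_rejected(self):
        with pytest.raises(ValueError):
            msum.compute_beta(1.0, 1.0, -0.1)

    def test_mvalue_direct_evaluation(self):
        assert msum.compute_mvalue(100.0, 400.0, 1.0) == pytest.approx(
            np.log2(101.0 / 401.0), abs=1e-12
        )
        assert msum.compute_mvalue(100.0, 400.0, 1.0) == pytest.approx(-1.98925, abs=1e-5)

    def test_mvalue_epsilon_must_be_positive(self):
        with pytest.raises(ValueError):
            msum.compute_mvalue(1.0, 1.0, 0.0)

    @settings(derandomize=True, max_examples=50)
    @given(m=finite_intensity, u=finite_intensity)
    def test_mvalue_antisymmetry_and_beta_range(self, m, u):
        assert msum.compute_mvalue(m, u) == pytest.approx(-msum.compute_mvalue(u, m), abs=1e-9)
        b = msum.compute_beta(m, u)
        assert 0.0 <= b < 1.0
        if m == u:
            assert msum.compute_mvalue(m, u) == 0.0


class TestQuantileSummary:
    def test_exact_order_statistics(self):
        np.testing.assert_array_equal(
            msum.quantile_summary([1, 2, 3, 4, 5], [0.0, 0.5, 1.0]), [1.0, 3.0, 5.0]
        )

    def test_constant_vector(self):
        np.testing.assert_array_equal(
            msum.quantile_summary([7.0] * 10, [0.0, 0.3, 1.0]), [7.0, 7.0, 7.0]
        )

    def test_matches_independent_oracle(self):
        rng = np.random.default_rng(42)
        values = rng.uniform(size=100)
        probs = np.linspace(0, 1, 500)
        np.testing.assert_allclose(
            msum.quantile_summary(values, probs), oracle_quantiles(values, probs), atol=1e-12
        )

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            msum.quantile_summary([], [0.0, 1.0])


class TestSummarizeRaw:
    def test_stratum_quantiles_match_filtered_oracle(self, clean_small_dataset, clean_small_summary):
        d, s = clean_small_dataset, clean_small_summary
        ids = d.manifest.stratum_probes("IGrn")
        meth = d.signals.meth.loc[ids]
        for sample in s.sample_ids[:3]:
            expected = oracle_quantiles(meth[sample], s.quantile_probs)
            np.testing.assert_allclose(
                s.quantiles["IGrn"]["M"][sample].to_numpy(), expected, atol=1e-12
            )

    def test_stratification_is_a_partition(self, clean_small_dataset):
        man = clean_small_dataset.manifest
        counts = sum(len(man.stratum_probes(s)) for s in ("IGrn", "IRed", "II", "chrX", "chrY"))
        assert counts == len(man.table)

    def test_empty_chry_stratum_recorded_empty(self, clean_small_dataset):
        d = clean_small_dataset
        keep = d.manifest.table["chromosome"] != "chrY"
        man = mio.ProbeManifest(table=d.manifest.table[keep])
        sig = mio.SignalSet(meth=d.signals.meth[keep.to_numpy()], unmeth=d.signals.unmeth[keep.to_numpy()])
        s = msum.summarize_raw(sig, man, d.controls, d.phenotypes)
        assert s.is_empty_stratum("chrY")
        from methylqc import sex_prediction as msex

        with pytest.raises(ValueError, match="chrY"):
            msex.sex_difference(s)

    def test_probe_absent_from_manifest_rejected(self, clean_small_dataset):
        d = clean_small_dataset
        man = mio.ProbeManifest(table=d.manifest.table.iloc[5:])
        with pytest.raises(ValueError, match="absent from manifest"):
            msum.summarize_raw(d.signals, man, d.controls, d.phenotypes)

    def test_identical_sample_columns_give_identical_quantiles(self, clean_small_dataset):
        d = clean_small_dataset
        meth = d.signals.meth.copy()
        unmeth = d.signals.unmeth.copy()
        for c in meth.columns:
            meth[c] = meth.iloc[:, 0]
            unmeth[c] = unmeth.iloc[:, 0]
        s = msum.summarize_raw(
            mio.SignalSet(meth=meth, unmeth=unmeth), d.manifest, d.controls, d.phenotypes
        )
        tab = s.quantiles["II"]["Beta"].to_numpy()
        assert np.all(tab == tab[:, [0]])

    def test_scale_equivariance(self, clean_small_dataset):
        d = clean_small_dataset
        c = 3.0
        base = msum.TransformParams()
        scaled = msum.TransformParams(beta_offset=base.beta_offset * c, mvalue_epsilon=base.mvalue_epsilon * c)
        s1 = msum.summarize_raw(d.signals, d.manifest, d.controls, d.phenotypes, base)
        sig_c = mio.SignalSet(meth=d.signals.meth * c, unmeth=d.signals.unmeth * c)
        s2 = msum.summarize_raw(sig_c, d.manifest, d.controls, d.phenotypes, scaled)
        for measure in ("M", "U", "CN"):
            np.testing.assert_allclose(
                s2.quantiles["II"][measure].to_numpy(),
                c * s1.quantiles["II"][measure].to_numpy(),
                rtol=1e-10,
            )
        np.testing.assert_allclose(
            s2.quantiles["II"]["Beta"].to_numpy(), s1.quantiles["II"]["Beta"].to_numpy(), rtol=1e-10
        )
        np.testing.assert_allclose(
            s2.quantiles["II"]["MValue"].to_numpy(),
            s1.quantiles["II"]["MValue"].to_numpy(),
            rtol=1e-9,
            atol=1e-10,
        )

    def test_sample_order_invariance(self, clean_small_dataset):
        d = clean_small_dataset
        perm = list(reversed(d.signals.sample_ids))
        sig = mio.SignalSet(meth=d.signals.meth[perm], unmeth=d.signals.unmeth[perm])
        s = msum.summarize_raw(sig, d.manifest, d.controls, d.phenotypes)
        ref = msum.summarize_raw(d.signals, d.manifest, d.controls, d.phenotypes)
        for sample in perm:
            np.testing.assert_array_equal(
                s.quantiles["autosomal"]["Beta"][sample].to_numpy(),
                ref.quantiles["autosomal"]["Beta"][sample].to_numpy(),
            )


@pytest.fixture(scope="module")
def beta_norm(clean_small_dataset):
    d = clean_small_dataset
    return pd.DataFrame(
        msum.compute_beta(d.signals.meth, d.signals.unmeth),
        index=d.signals.meth.index,
        columns=d.signals.meth.columns,
    )


class TestSummarizeNormalized:
    def test_half_beta_gives_zero_mvalue(self, clean_small_dataset):
        d = clean_small_dataset
        beta = pd.DataFrame(0.5, index=d.signals.meth.index, columns=d.signals.meth.columns)
        s = msum.summarize_normalized(beta, d.manifest, d.phenotypes)
        assert np.all(s.quantiles["II"]["MValue"].to_numpy() == 0.0)

    def test_structure_and_shared_grid(self, beta_norm, clean_small_dataset, clean_small_summary):
        d = clean_small_dataset
        s = msum.summarize_normalized(beta_norm, d.manifest, d.phenotypes)
        assert s.label == "normalized"
        assert s.controls is None
        assert s.measures("II") == ["Beta", "MValue"]
        np.testing.assert_array_equal(s.quantile_probs, clean_small_summary.quantile_probs)

    def test_beta_quantiles_match_oracle(self, beta_norm, clean_small_dataset):
        d = clean_small_dataset
        s = msum.summarize_normalized(beta_norm, d.manifest, d.phenotypes)
        ids = d.manifest.stratum_probes("II").intersection(beta_norm.index)
        sample = s.sample_ids[0]
        np.testing.assert_allclose(
            s.quantiles["II"]["Beta"][sample].to_numpy(),
            oracle_quantiles(beta_norm.loc[ids, sample], s.quantile_probs),
            atol=1e-12,
        )

    def test_out_of_range_rejected(self, clean_small_dataset):
        d = clean_small_dataset
        beta = pd.DataFrame(0.5, index=d.signals.meth.index, columns=d.signals.meth.columns)
        beta.iloc[0, 0] = 1.5
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            msum.summarize_normalized(beta, d.manifest, d.phenotypes)


class TestSummarizeControls:
    def test_single_element_and_group_means(self):
        t = pd.DataFrame(
            {
                "control_id": ["c1", "c2"],
                "control_type": ["NEGATIVE", "NEGATIVE"],
                "sample_id": ["S1", "S1"],
                "green": [100.0, 300.0],
                "red": [200.0, 400.0],
            }
        )
        out = msum.summarize_controls(mio.ControlTable(table=t))
        row = out.iloc[0]
        assert (row["mean_green"], row["mean_red"], row["mean_combined"]) == (200.0, 300.0, 250.0)

    def test_matches_grouped_loop_oracle(self, clean_small_dataset):
        ct = clean_small_dataset.controls
        out = msum.summarize_controls(ct).set_index(["sample_id", "control_type"])
        t = ct.table
        for (sample, ctype), grp in t.groupby(["sample_id", "control_type"]):
            g = sum(grp["green"]) / len(grp)
            r = sum(grp["red"]) / len(grp)
            assert out.loc[(sample, ctype), "mean_green"] == pytest.approx(g, rel=1e-12)
            assert out.loc[(sample, ctype), "mean_red"] == pytest.approx(r, rel=1e-12)
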