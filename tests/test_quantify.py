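import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cytobalance.quantify import (
    CountTable,
    ExpressionTable,
    SampleMeta,
    check_meta,
    compute_tpm,
    cytotype_means,
    mean_expression,
    read_meta_tsv,
    tpm_ratio,
    write_meta_tsv,
)


def make_counts(data: dict[str, list[int]], genes: list[str]) -> CountTable:
    return CountTable(counts=pd.DataFrame(data, index=genes, dtype=np.int64))


class TestComputeTpm:
    def test_single_gene_is_million(self):
        ct = make_counts({"s1": [7]}, ["AT1G00010"])
        expr = compute_tpm(ct, {"AT1G00010": 1.0})
        assert expr.values.loc["AT1G00010", "s1"] == pytest.approx(1_000_000.0)

    def test_equal_rpk_split_evenly(self):
        ct = make_counts({"s1": [10, 30]}, ["AT1G00010", "AT1G00020"])
        expr = compute_tpm(ct, {"AT1G00010": 1.0, "AT1G00020": 3.0})
        assert expr.values["s1"].tolist() == pytest.approx([500_000.0, 500_000.0])

    def test_hand_arithmetic(self):
        # counts {100 @ 2kb, 50 @ 0.5kb} -> RPK {50, 100} -> TPM {1/3, 2/3} of 1e6
        ct = make_counts({"s1": [100, 50]}, ["AT1G00010", "AT1G00020"])
        expr = compute_tpm(ct, {"AT1G00010": 2.0, "AT1G00020": 0.5})
        assert expr.values.loc["AT1G00010", "s1"] == pytest.approx(333_333.33, abs=0.01)
        assert expr.values.loc["AT1G00020", "s1"] == pytest.approx(666_666.67, abs=0.01)

    def test_oracle_literal_transcription(self):
        """Vectorized implementation matches a literal loop transcription of
        the normalization rule on a 5-gene, 2-sample toy table."""
        genes = ["AT1G00010", "AT1G00020", "AT2G00010", "AT3G00010", "AT5G00010"]
        lengths = {g: l for g, l in zip(genes, [0.5, 1.0, 2.0, 0.25, 3.3])}
        ct = make_counts({"s1": [3, 0, 44, 17, 251], "s2": [90, 12, 1, 0, 5]}, genes)
        expr = compute_tpm(ct, lengths)
        for sample in ("s1", "s2"):
            rpk = {g: ct.counts.loc[g, sample] / lengths[g] for g in genes}
            total = sum(rpk.values())
            for g in genes:
                expected = rpk[g] / (total / 1_000_000.0)
                assert expr.values.loc[g, sample] == pytest.approx(expected, rel=1e-12)

    def test_tpm_sums_to_million(self, toy_counts, toy_annotation):
        expr = compute_tpm(toy_counts, toy_annotation.lengths_kb())
        plant = expr.values.loc[~expr.spike_flags]
        assert np.allclose(plant.sum(axis=0), 1e6, rtol=1e-9)

    def test_spikes_excluded_from_denominator(self, toy_counts, toy_annotation):
        expr = compute_tpm(toy_counts, toy_annotation.lengths_kb())
        spikes = expr.values.loc[expr.spike_flags.astype(bool)]
        assert (spikes > 0).all().all()  # spikes still quantified
        # doubling spike counts leaves plant TPM unchanged
        doubled = toy_counts.counts.copy()
        doubled.loc[toy_counts.spike_flags.astype(bool)] *= 2
        expr2 = compute_tpm(CountTable(counts=doubled), toy_annotation.lengths_kb())
        plant = ~expr.spike_flags
        pd.testing.assert_frame_equal(expr.values.loc[plant], expr2.values.loc[plant])

    def test_scale_invariance(self, toy_counts, toy_annotation):
        expr = compute_tpm(toy_counts, toy_annotation.lengths_kb())
        scaled = toy_counts.counts.copy()
        scaled["s2a"] *= 17
        expr2 = compute_tpm(CountTable(counts=scaled), toy_annotation.lengths_kb())
        pd.testing.assert_series_equal(expr.values["s2a"], expr2.values["s2a"])

    def test_all_zero_sample_raises(self):
        ct = make_counts({"s1": [1], "s2": [0]}, ["AT1G00010"])
        with pytest.raises(ValueError, match="s2"):
            compute_tpm(ct, {"AT1G00010": 1.0})

    def test_missing_length_raises(self):
        ct = make_counts({"s1": [1, 2]}, ["AT1G00010", "AT1G00020"])
        with pytest.raises(ValueError, match="AT1G00020"):
            compute_tpm(ct, {"AT1G00010": 1.0})


class TestCountTable:
    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            CountTable(counts=pd.DataFrame({"s1": [-1]}, index=["AT1G00010"]))

    def test_duplicate_genes_rejected(self):
        df = pd.DataFrame({"s1": [1, 2]}, index=["AT1G00010", "AT1G00010"])
        with pytest.raises(ValueError):
            CountTable(counts=df)

    def test_htseq_special_counters_dropped(self, tmp_path):
        path = tmp_path / "m.tsv"
        path.write_text(
            "gene_id\ts1\nAT1G00010\t5\n__no_feature\t100\n__ambiguous\t7\n"
        )
        ct = CountTable.from_matrix_tsv(path)
        assert ct.genes == ["AT1G00010"]

    def test_htseq_two_column_merge(self, tmp_path):
        for name, vals in (("a", [3, 1]), ("b", [0, 9])):
            (tmp_path / f"{name}.txt").write_text(
                f"AT1G00010\t{vals[0]}\nAT1G00020\t{vals[1]}\n__no_feature\t4\n"
            )
        ct = CountTable.from_htseq_files(
            {"a": tmp_path / "a.txt", "b": tmp_path / "b.txt"}
        )
        assert ct.counts.loc["AT1G00020", "b"] == 9
        assert ct.counts.shape == (2, 2)

    def test_matrix_round_trip(self, toy_counts, tmp_path):
        path = tmp_path / "counts.tsv"
        toy_counts.write_tsv(path)
        reloaded = CountTable.from_matrix_tsv(path)
        pd.testing.assert_frame_equal(reloaded.counts, toy_counts.counts)


class TestMeanExpression:
    def test_mean_of_replicates(self, toy_annotation):
        genes = ["AT1G00010"]
        ct = make_counts({"a": [1], "b": [1], "c": [1]}, genes)
        expr = compute_tpm(ct, {"AT1G00010": 1.0})
        expr.values.loc["AT1G00010"] = [10.0, 20.0, 30.0]
        meta = [
            SampleMeta("a", "leaf", "2C", 1),
            SampleMeta("b", "leaf", "2C", 2),
            SampleMeta("c", "leaf", "2C", 3),
        ]
        assert mean_expression(expr, meta, "leaf", "2C").iloc[0] == pytest.approx(20.0)

    def test_missing_cytotype_raises(self, toy_counts, toy_annotation, toy_meta):
        expr = compute_tpm(toy_counts, toy_annotation.lengths_kb())
        with pytest.raises(ValueError, match="8C"):
            mean_expression(expr, toy_meta, "leaf", "8C")

    def test_permutation_invariance(self, toy_counts, toy_annotation, toy_meta):
        expr = compute_tpm(toy_counts, toy_annotation.lengths_kb())
        fwd = mean_expression(expr, toy_meta, "leaf", "2C")
        rev = mean_expression(expr, list(reversed(toy_meta)), "leaf", "2C")
        pd.testing.assert_series_equal(fwd, rev)

    def test_cytotype_means_columns(self, toy_counts, toy_annotation, toy_meta):
        expr = compute_tpm(toy_counts, toy_annotation.lengths_kb())
        means = cytotype_means(expr, toy_meta)
        assert set(means.columns) == {("leaf", "2C"), ("leaf", "4C")}


class TestTpmRatio:
    def test_identical_means_all_one(self):
        m = pd.Series({"AT1G00010": 5.0, "AT1G00020": 7.0})
        df = tpm_ratio(m, m.copy())
        assert (df["ratio"] == 1.0).all()

    def test_zero_mean_excluded(self):
        a = pd.Series({"AT1G00010": 4.0, "AT1G00020": 3.0})
        b = pd.Series({"AT1G00010": 2.0, "AT1G00020": 0.0})
        df = tpm_ratio(a, b)
        assert list(df.index) == ["AT1G00010"]
        assert df.loc["AT1G00010", "ratio"] == pytest.approx(2.0)

    def test_antisymmetry(self, toy_counts, toy_annotation, toy_meta):
        expr = compute_tpm(toy_counts, toy_annotation.lengths_kb())
        a = mean_expression(expr, toy_meta, "leaf", "4C")
        b = mean_expression(expr, toy_meta, "leaf", "2C")
        fwd = tpm_ratio(a, b, toy_annotation)
        rev = tpm_ratio(b, a, toy_annotation)
        shared = fwd.index.intersection(rev.index)
        assert np.allclose(
            fwd.loc[shared, "ratio"], 1.0 / rev.loc[shared, "ratio"], rtol=1e-12
        )

    def test_classes_attached(self, toy_counts, toy_annotation, toy_meta):
        expr = compute_tpm(toy_counts, toy_annotation.lengths_kb())
        a = mean_expression(expr, toy_meta, "leaf", "4C")
        b = mean_expression(expr, toy_meta, "leaf", "2C")
        df = tpm_ratio(a, b, toy_annotation)
        assert df.loc["AT1G00010", "targeting"] == "plastid"
        assert df.loc["AT1G00010", "tier"] == "direct"
        assert df.loc["ATCG00010", "genome"] == "plastid"


@settings(max_examples=30, deadline=None)
@given(
    counts=st.lists(st.integers(min_value=0, max_value=10_000), min_size=2, max_size=8),
    lengths=st.lists(
        st.floats(min_value=0.05, max_value=50.0, allow_nan=False), min_size=8, max_size=8
    ),
)
def test_tpm_sum_property(counts, lengths):
    genes = [f"AT1G{i:05d}" for i in range(10, 10 + len(counts))]
    if sum(counts) == 0:
        counts = counts[:-1] + [1]
    ct = CountTable(counts=pd.DataFrame({"s1": counts}, index=genes, dtype=np.int64))
    expr = compute_tpm(ct, dict(zip(genes, lengths)))
    assert expr.values["s1"].sum() == pytest.approx(1e6, rel=1e-9)


class TestMetaIO:
    def test_round_trip(self, toy_meta, tmp_path):
        path = tmp_path / "meta.tsv"
        write_meta_tsv(toy_meta, path)
        reloaded = read_meta_tsv(path)
        assert reloaded == toy_meta

    def test_duplicate_replicate_rejected(self):
        with pytest.raises(ValueError):
            check_meta(
                [
                    SampleMeta("a", "leaf", "2C", 1),
                    SampleMeta("b", "leaf", "2C", 1),
                ]
            )

    def test_bad_ploidy_rejected(self):
        with pytest.raises(ValueError):
            SampleMeta("a", "leaf", "3C", 1)


class TestExpressionTableIO:
    def test_tsv_round_trip_with_basis(self, toy_counts, toy_annotation, tmp_path):
        expr = compute_tpm(toy_counts, toy_annotation.lengths_kb())
        path = tmp_path / "expr.tsv"
        expr.write_tsv(path)
        assert path.read_text().startswith("# basis=tpm\n")
        reloaded = ExpressionTable.read_tsv(path)
        assert reloaded.basis == "tpm"
        pd.testing.assert_frame_equal(reloaded.values, expr.values)
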