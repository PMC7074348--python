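import numpy as np
import pandas as pd
import pytest

from cytobalance.quantify import compute_tpm, mean_expression, tpm_ratio
from cytobalance.stoichiometry import (
    balance_ratio,
    bulk_ratio_table,
    complex_correlation,
    cv_by_tier,
    genome_tpm_ratios,
    organelle_nuclear_ratio,
    targeted_fraction,
    tier_of_ratios,
)

CLASSES = ("plastid", "mitochondrion", "dual", "other", "unknown")


class TestTargetedFraction:
    def test_spreadsheet_oracle(self, toy_counts, toy_annotation):
        """Every fraction matches an independent dict-based recomputation."""
        for sample in toy_counts.samples:
            col = toy_counts.counts[sample]
            by_class: dict[str, int] = {}
            nuclear_total = 0
            for gid in toy_counts.genes:
                rec = toy_annotation[gid]
                if rec.genome != "nuclear":
                    continue
                nuclear_total += int(col[gid])
                by_class[rec.targeting] = by_class.get(rec.targeting, 0) + int(col[gid])
            for cls in CLASSES:
                expected = by_class.get(cls, 0) / nuclear_total
                assert targeted_fraction(toy_counts, toy_annotation, cls, sample) == pytest.approx(
                    expected, rel=1e-12
                )

    def test_partition_sums_to_one(self, toy_counts, toy_annotation):
        for sample in toy_counts.samples:
            total = sum(
                targeted_fraction(toy_counts, toy_annotation, cls, sample) for cls in CLASSES
            )
            assert total == pytest.approx(1.0, rel=1e-12)

    def test_hand_sum(self, toy_annotation):
        from cytobalance.quantify import CountTable

        # plastid-targeted 250 of 1000 nuclear reads
        genes = ["AT1G00030", "AT3G00020", "ATCG00010", "ERCC-00001"]
        df = pd.DataFrame({"s": [250, 750, 999, 42]}, index=genes, dtype=np.int64)
        ct = CountTable(counts=df)
        assert targeted_fraction(ct, toy_annotation, "plastid", "s") == pytest.approx(0.25)

    def test_zero_nuclear_reads_raises(self, toy_annotation):
        from cytobalance.quantify import CountTable

        df = pd.DataFrame({"s": [0, 5]}, index=["AT1G00030", "ATCG00010"], dtype=np.int64)
        ct = CountTable(counts=df)
        with pytest.raises(ValueError, match="s"):
            targeted_fraction(ct, toy_annotation, "plastid", "s")


class TestBulkRatios:
    def test_spreadsheet_oracle(self, toy_counts, toy_annotation):
        for sample in toy_counts.samples:
            col = toy_counts.counts[sample]
            sums: dict[str, int] = {"nuclear": 0, "plastid": 0, "mitochondrion": 0}
            targeted: dict[str, int] = {"plastid": 0, "mitochondrion": 0, "dual": 0}
            for gid in toy_counts.genes:
                rec = toy_annotation[gid]
                if rec.genome in sums:
                    sums[rec.genome] += int(col[gid])
                if rec.genome == "nuclear" and rec.targeting in targeted:
                    targeted[rec.targeting] += int(col[gid])
            for org in ("plastid", "mitochondrion"):
                assert organelle_nuclear_ratio(
                    toy_counts, toy_annotation, org, sample
                ).value == pytest.approx(sums[org] / sums["nuclear"], rel=1e-12)
                assert balance_ratio(
                    toy_counts, toy_annotation, org, sample
                ).value == pytest.approx(sums[org] / targeted[org], rel=1e-12)
                assert balance_ratio(
                    toy_counts, toy_annotation, org, sample, include_dual=True
                ).value == pytest.approx(
                    sums[org] / (targeted[org] + targeted["dual"]), rel=1e-12
                )

    def test_hand_sum(self, toy_annotation):
        from cytobalance.quantify import CountTable

        genes = ["AT1G00030", "AT3G00020", "ATCG00010"]
        df = pd.DataFrame({"s": [4000, 6000, 500]}, index=genes, dtype=np.int64)
        ct = CountTable(counts=df)
        assert organelle_nuclear_ratio(ct, toy_annotation, "plastid", "s").value == pytest.approx(
            0.05
        )

    def test_algebraic_identity(self, toy_counts, toy_annotation):
        """balance = organelle/nuclear divided by the targeted fraction."""
        for sample in toy_counts.samples:
            for org in ("plastid", "mitochondrion"):
                lhs = balance_ratio(toy_counts, toy_annotation, org, sample).value
                rhs = organelle_nuclear_ratio(
                    toy_counts, toy_annotation, org, sample
                ).value / targeted_fraction(toy_counts, toy_annotation, org, sample)
                assert lhs == pytest.approx(rhs, rel=1e-12)

    def test_exclusion_list(self, toy_counts, toy_annotation):
        full = balance_ratio(toy_counts, toy_annotation, "mitochondrion", "s2a")
        partial = balance_ratio(
            toy_counts, toy_annotation, "mitochondrion", "s2a", exclude=["ATMG00020"]
        )
        dropped = int(toy_counts.counts.loc["ATMG00020", "s2a"])
        assert partial.value < full.value or dropped == 0

    def test_tidy_table(self, toy_counts, toy_annotation, toy_meta):
        df = bulk_ratio_table(toy_counts, toy_annotation, toy_meta)
        assert set(df["ratio_kind"]) == {"organelle_nuclear", "balance", "balance_plus_dual"}
        assert len(df) == len(toy_counts.samples) * 2 * 3


class TestGenomeRatios:
    def test_identical_expression_all_one(self, toy_counts, toy_annotation, toy_meta):
        expr = compute_tpm(toy_counts, toy_annotation.lengths_kb())
        m = mean_expression(expr, toy_meta, "leaf", "2C")
        df = genome_tpm_ratios(m, m.copy(), toy_annotation)
        for genome in ("nuclear", "plastid", "mitochondrion"):
            sub = df[df["genome"] == genome]
            assert np.allclose(sub["ratio"], 1.0)

    def test_exclusion_removes_one_entry(self, toy_counts, toy_annotation, toy_meta):
        expr = compute_tpm(toy_counts, toy_annotation.lengths_kb())
        a = mean_expression(expr, toy_meta, "leaf", "4C")
        b = mean_expression(expr, toy_meta, "leaf", "2C")
        full = genome_tpm_ratios(a, b, toy_annotation)
        reduced = genome_tpm_ratios(a, b, toy_annotation, exclude=["ATMG00020"])
        assert len(full) - len(reduced) == 1
        assert "ATMG00020" not in reduced.index

    def test_spikes_never_included(self, toy_counts, toy_annotation, toy_meta):
        expr = compute_tpm(toy_counts, toy_annotation.lengths_kb())
        a = mean_expression(expr, toy_meta, "leaf", "4C")
        b = mean_expression(expr, toy_meta, "leaf", "2C")
        df = genome_tpm_ratios(a, b, toy_annotation)
        assert not df.index.str.startswith("ERCC-").any()


class TestCvByTier:
    def _ratio_frame(self, values_by_tier):
        rows = []
        for tier, values in values_by_tier.items():
            for i, v in enumerate(values):
                targeting = "other" if tier == "other" else "plastid"
                row_tier = {"other": "none", "targeted": "none"}.get(tier, tier)
                rows.append(
                    {
                        "ratio": v,
                        "genome": "nuclear",
                        "targeting": targeting,
                        "tier": row_tier,
                    }
                )
        return pd.DataFrame(rows, index=[f"AT1G{i:05d}" for i in range(len(rows))])

    def test_all_equal_cv_zero(self):
        df = self._ratio_frame({"other": [2.0, 2.0, 2.0]})
        reports = cv_by_tier(df, tiers=("other",))
        assert reports[0].cv == pytest.approx(0.0)

    def test_hand_computation(self):
        # {1,2,3}: mean 2, sd 1 (n-1), cv 0.5
        df = self._ratio_frame({"other": [1.0, 2.0, 3.0]})
        reports = cv_by_tier(df, tiers=("other",))
        assert reports[0].cv == pytest.approx(0.5)
        assert reports[0].n_genes == 3

    def test_scale_invariance(self):
        df1 = self._ratio_frame({"other": [1.0, 2.0, 5.0]})
        df2 = self._ratio_frame({"other": [3.0, 6.0, 15.0]})
        cv1 = cv_by_tier(df1, tiers=("other",))[0].cv
        cv2 = cv_by_tier(df2, tiers=("other",))[0].cv
        assert cv1 == pytest.approx(cv2)

    def test_small_tier_omitted_with_warning(self, caplog):
        df = self._ratio_frame({"other": [1.0, 2.0], "direct": [1.0]})
        with caplog.at_level("WARNING", logger="cytobalance.stoichiometry"):
            reports = cv_by_tier(df, tiers=("other", "direct"))
        assert [r.tier for r in reports] == ["other"]

    def test_nesting_selection(self, toy_counts, toy_annotation, toy_meta):
        expr = compute_tpm(toy_counts, toy_annotation.lengths_kb())
        a = mean_expression(expr, toy_meta, "leaf", "4C")
        b = mean_expression(expr, toy_meta, "leaf", "2C")
        ratios = tpm_ratio(a, b, toy_annotation)
        n_direct = len(tier_of_ratios(ratios, "direct"))
        n_complexed = len(tier_of_ratios(ratios, "complexed"))
        n_targeted = len(tier_of_ratios(ratios, "targeted"))
        assert n_direct <= n_complexed <= n_targeted


class TestComplexCorrelation:
    def test_perfect_linearity(self):
        m2 = pd.Series({"AT1G00010": 10.0, "AT1G00020": 100.0, "ATCG00010": 1000.0})
        m4 = 0.8 * m2
        cc = complex_correlation(m4, m2, list(m2.index), complex_id="X")
        assert cc.r_all == pytest.approx(1.0)

    def test_degenerate_raises(self):
        m2 = pd.Series({"AT1G00010": 5.0, "AT1G00020": 5.0, "ATCG00010": 5.0})
        with pytest.raises(ValueError):
            complex_correlation(m2, m2.copy(), list(m2.index))

    def test_too_few_members_raises(self):
        m = pd.Series({"AT1G00010": 1.0, "AT1G00020": 2.0})
        with pytest.raises(ValueError, match=">= 3"):
            complex_correlation(m, m.copy(), list(m.index))

    def test_subgroup_split(self, toy_counts, toy_annotation, toy_meta):
        expr = compute_tpm(toy_counts, toy_annotation.lengths_kb())
        a = mean_expression(expr, toy_meta, "leaf", "4C")
        b = mean_expression(expr, toy_meta, "leaf", "2C")
        members = toy_annotation.complex_members("CPX1")
        cc = complex_correlation(a, b, members, toy_annotation, "CPX1")
        assert cc.n_all == len(members)
        assert cc.n_nuclear == 3
        assert cc.n_organellar == 1
        assert cc.r_organellar is None  # fewer than 3 organellar members
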