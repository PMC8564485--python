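import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from h2sguilds import (
    call_expressed,
    co_expression_fraction,
    methanogenesis_call,
    sample_tier_expression,
    tpm_from_counts,
)
from h2sguilds.errors import ConsistencyError
from h2sguilds.expression import (
    ExpressionMatrix,
    SampleCall,
    matrix_from_quant_files,
    read_quant_sf,
)
from h2sguilds.simulate import quant_sf_text


def _df(values, genes, samples):
    return pd.DataFrame(values, index=genes, columns=samples)


class TestTpmFromCounts:
    def test_equal_counts_equal_lengths_split_evenly(self):
        counts = _df([[10], [10], [10], [10]], list("abcd"), ["s1"])
        tpm = tpm_from_counts(counts, {g: 500.0 for g in "abcd"})
        assert (tpm["s1"] == 250_000.0).all()

    def test_single_expressed_gene_takes_the_million(self):
        counts = _df([[42], [0]], ["a", "b"], ["s1"])
        tpm = tpm_from_counts(counts, {"a": 100.0, "b": 900.0})
        assert tpm.loc["a", "s1"] == 1e6
        assert tpm.loc["b", "s1"] == 0.0

    def test_matches_direct_formula_and_sums_to_a_million(self, rng):
        counts = _df(rng.integers(0, 500, size=(10, 5)).astype(float),
                     [f"g{i}" for i in range(10)], [f"s{j}" for j in range(5)])
        lengths = {f"g{i}": float(rng.integers(200, 3000))
                   for i in range(10)}
        tpm = tpm_from_counts(counts, lengths)
        assert np.allclose(tpm.sum(axis=0), 1e6, atol=1e-6)
        rates = counts.div(pd.Series(lengths), axis=0)
        expected = rates / rates.sum(axis=0) * 1e6
        assert np.allclose(tpm, expected)

    def test_all_zero_sample_stays_zero_with_warning(self, caplog):
        counts = _df([[0], [0]], ["a", "b"], ["s1"])
        with caplog.at_level("WARNING"):
            tpm = tpm_from_counts(counts, {"a": 100.0, "b": 100.0})
        assert (tpm["s1"] == 0).all()
        assert "all-zero" in caplog.text

    def test_nonpositive_length_rejected(self):
        counts = _df([[1]], ["a"], ["s1"])
        with pytest.raises(ValueError, match="positive"):
            tpm_from_counts(counts, {"a": 0.0})

    def test_negative_counts_rejected(self):
        counts = _df([[-1.0]], ["a"], ["s1"])
        with pytest.raises(ValueError, match="non-negative"):
            tpm_from_counts(counts, {"a": 100.0})

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(scale=hst.floats(min_value=1e-3, max_value=1e3))
    def test_scale_invariance_in_counts(self, scale):
        counts = _df([[3.0, 1.0], [7.0, 0.0], [2.0, 9.0]],
                     ["a", "b", "c"], ["s1", "s2"])
        lengths = {"a": 150.0, "b": 900.0, "c": 420.0}
        base = tpm_from_counts(counts, lengths)
        scaled = tpm_from_counts(counts * scale, lengths)
        assert np.allclose(base, scaled, rtol=1e-9)


class TestCallExpressed:
    def test_threshold_boundary_is_non_strict(self):
        tpm = _df([[10.0], [9.999]], ["a", "b"], ["s1"])
        flags = call_expressed(tpm)
        assert bool(flags.loc["a", "s1"]) is True
        assert bool(flags.loc["b", "s1"]) is False

    def test_all_zero_column_is_all_false(self):
        flags = call_expressed(_df([[0.0], [0.0]], ["a", "b"], ["s1"]))
        assert not flags["s1"].any()

    def test_raising_threshold_never_adds_flags(self, rng):
        tpm = _df(rng.random((6, 4)) * 50, [f"g{i}" for i in range(6)],
                  [f"s{j}" for j in range(4)])
        low = call_expressed(tpm, 5.0)
        high = call_expressed(tpm, 20.0)
        assert not (high & ~low).any().any()


class TestSampleTierExpression:
    def _flags(self, expressed, catalog, samples=("s1",)):
        genes = list(catalog.symbols())
        df = pd.DataFrame(False, index=genes, columns=list(samples))
        for sample, gene_list in expressed.items():
            for g in gene_list:
                df.loc[g, sample] = True
        return df

    def test_single_primary_gene_flags_primary_only(self, catalog):
        calls = sample_tier_expression(
            self._flags({"s1": ["yhaM"]}, catalog), catalog
        )
        (c,) = calls
        assert c.expresses_primary
        assert not (c.expresses_secondary or c.expresses_erroneous
                    or c.expresses_dsr)

    def test_dsr_requires_both_subunits_by_default(self, catalog):
        only_a = sample_tier_expression(
            self._flags({"s1": ["dsrA"]}, catalog), catalog
        )[0]
        both = sample_tier_expression(
            self._flags({"s1": ["dsrA", "dsrB"]}, catalog), catalog
        )[0]
        assert not only_a.expresses_dsr
        assert both.expresses_dsr

    def test_dsr_either_rule(self, catalog):
        call = sample_tier_expression(
            self._flags({"s1": ["dsrB"]}, catalog), catalog, dsr_rule="either"
        )[0]
        assert call.expresses_dsr

    def test_no_expression_all_false(self, catalog):
        (c,) = sample_tier_expression(self._flags({}, catalog), catalog)
        assert not any([c.expresses_primary, c.expresses_secondary,
                        c.expresses_erroneous, c.expresses_dsr,
                        c.is_methanogenic])

    def test_cohort_scale_prevalence_arithmetic(self, catalog):
        # 637 of 736 samples with a primary gene expressed -> 86.5%
        samples = [f"s{i}" for i in range(736)]
        expressed = {s: ["mgl"] for s in samples[:637]}
        calls = sample_tier_expression(
            self._flags(expressed, catalog, samples), catalog
        )
        frac = sum(c.expresses_primary for c in calls) / len(calls)
        assert round(100 * frac, 1) == 86.5


class TestMethanogenesisCall:
    PANEL = [f"mg{i}" for i in range(16)]

    def _counts(self, n_with_reads):
        return {g: (1.0 if i < n_with_reads else 0.0)
                for i, g in enumerate(self.PANEL)}

    @pytest.mark.parametrize("n,expected", [(13, True), (12, False),
                                            (16, True), (0, False)])
    def test_eighty_percent_of_sixteen_rule(self, n, expected):
        assert methanogenesis_call(self._counts(n), self.PANEL) is expected

    def test_rule_uses_raw_reads_not_tpm(self):
        # one read on 13 genes is enough even though TPM would be tiny
        counts = self._counts(13)
        counts["mg0"] = 1.0
        assert methanogenesis_call(counts, self.PANEL)

    def test_empty_panel_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            methanogenesis_call({}, [])


class TestCoExpression:
    def _calls(self, dsr_flags, meth_flags):
        return [
            SampleCall(sample_id=f"s{i}", expresses_dsr=d, is_methanogenic=m)
            for i, (d, m) in enumerate(zip(dsr_flags, meth_flags))
        ]

    def test_seven_of_fiftynine_prints_11_9_percent(self):
        both = [True] * 7 + [False] * 52
        calls = self._calls(both, both)
        frac = co_expression_fraction(
            calls, lambda c: c.expresses_dsr, lambda c: c.is_methanogenic
        )
        assert round(100 * frac, 1) == 11.9

    def test_always_true_predicates_give_one(self):
        calls = self._calls([True] * 5, [True] * 5)
        assert co_expression_fraction(calls, lambda c: True,
                                      lambda c: True) == 1.0

    def test_bounded_by_marginals_and_matches_counting(self, rng):
        d = rng.random(300) < 0.6
        m = rng.random(300) < 0.3
        calls = self._calls(d.tolist(), m.tolist())
        pa = lambda c: c.expresses_dsr
        pb = lambda c: c.is_methanogenic
        joint = co_expression_fraction(calls, pa, pb)
        assert joint == np.mean(d & m)
        assert joint <= min(np.mean(d), np.mean(m))

    def test_empty_calls_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            co_expression_fraction([], lambda c: True, lambda c: True)


class TestQuantIngestion:
    def test_consistent_file_parses_and_recomputes_tpm(self, tmp_path):
        text = quant_sf_text({"mgl": 120.0, "cysK": 30.0},
                             {"mgl": 900.0, "cysK": 1500.0})
        path = tmp_path / "quant.sf"
        path.write_text(text)
        df = read_quant_sf(path, strict=True)
        assert np.allclose(df["tpm_recomputed"], df["TPM"], rtol=1e-6)

    def test_inconsistent_tpm_raises_in_strict_mode(self, tmp_path):
        path = tmp_path / "quant.sf"
        path.write_text(
            "Name\tLength\tEffectiveLength\tTPM\tNumReads\n"
            "mgl\t900\t900.0\t999999.0\t10\n"
            "cysK\t1500\t1500.0\t1.0\t10\n"
        )
        with pytest.raises(ConsistencyError, match="deviates"):
            read_quant_sf(path, strict=True)

    def test_matrix_assembly_from_two_samples(self, tmp_path):
        lengths = {"mgl": 900.0, "cysK": 1500.0}
        for name, counts in (("a", {"mgl": 120.0, "cysK": 30.0}),
                             ("b", {"mgl": 0.0, "cysK": 70.0})):
            (tmp_path / f"{name}.sf").write_text(
                quant_sf_text(counts, lengths)
            )
        em = matrix_from_quant_files(
            {"a": tmp_path / "a.sf", "b": tmp_path / "b.sf"}
        )
        assert em.counts.loc["mgl", "a"] == 120.0
        assert em.counts.loc["mgl", "b"] == 0.0
        assert em.tpm.loc["cysK", "b"] == 1e6


def test_expression_matrix_requires_lengths_for_every_gene():
    counts = pd.DataFrame([[1.0]], index=["a"], columns=["s1"])
    with pytest.raises(ValueError, match="lengths"):
        ExpressionMatrix(counts=counts, lengths={})
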