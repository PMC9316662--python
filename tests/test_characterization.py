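"""Mutational load, Fisher tests, top-list overlaps, consequence tables."""

from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from pansubtypes.characterization import (
    Contingency2x2,
    build_gene_motif_presence,
    consequence_frequencies,
    fisher_exact,
    mutational_load,
    pairwise_overlap,
    subtype_feature_tests,
)
from pansubtypes.io_profiles import CohortMatrix


def enumeration_oracle_greater(a, b, c, d):
    """Exact one-sided Fisher p by hypergeometric enumeration (rationals)."""
    n = a + b + c + d
    r1, c1 = a + b, a + c
    total = comb(n, c1)
    p = Fraction(0)
    for x in range(a, min(r1, c1) + 1):
        p += Fraction(comb(r1, x) * comb(n - r1, c1 - x), total)
    return float(p)


def cohort(counts, ctypes=None):
    arr = np.asarray(counts)
    df = pd.DataFrame(arr, index=[f"S{i}" for i in range(arr.shape[0])],
                      columns=[f"G{j}" for j in range(arr.shape[1])])
    return CohortMatrix(df, pd.Series(ctypes or ["CT1"] * len(df), index=df.index))


def labels_for(matrix, mapping):
    return pd.Series(mapping).reindex(matrix.sample_ids)


class TestMutationalLoad:
    def test_fractions(self):
        m = cohort([[1], [2], [1], [0]])
        lab = labels_for(m, {s: "C1" for s in m.sample_ids})
        load = mutational_load(m, lab)
        assert load.loc["G0", "C1"] == pytest.approx(0.75)

    def test_saturated_gene(self):
        m = cohort([[1], [3]])
        lab = labels_for(m, {s: "C1" for s in m.sample_ids})
        assert mutational_load(m, lab).loc["G0", "C1"] == 1.0

    def test_min_mutations_threshold(self):
        m = cohort([[2], [3]])
        lab = labels_for(m, {s: "C1" for s in m.sample_ids})
        load3 = mutational_load(m, lab, min_mutations=3)
        assert load3.loc["G0", "C1"] == pytest.approx(0.5)

    def test_monotone_nonincreasing_in_threshold(self):
        rng = np.random.default_rng(0)
        m = cohort(rng.poisson(1.2, size=(30, 8)))
        lab = labels_for(m, {s: ("C1" if i < 15 else "C2")
                             for i, s in enumerate(m.sample_ids)})
        prev = mutational_load(m, lab, 1)
        for mm in (2, 3, 4):
            cur = mutational_load(m, lab, mm)
            assert (cur.to_numpy() <= prev.to_numpy() + 1e-12).all()
            prev = cur

    def test_incomplete_labels_are_error(self):
        m = cohort([[1], [1]])
        with pytest.raises(ValueError):
            mutational_load(m, pd.Series({"S0": "C1"}))


class TestFisherExact:
    def test_printed_margin_examples(self):
        p, odds = fisher_exact(Contingency2x2(3, 0, 0, 3), "greater")
        assert p == pytest.approx(0.05, abs=1e-12)  # 1 / C(6,3)
        p, _ = fisher_exact(Contingency2x2(1, 1, 1, 1), "greater")
        assert p == pytest.approx(5 / 6, abs=1e-12)

    def test_empty_table_convention(self):
        p, odds = fisher_exact(Contingency2x2(0, 0, 0, 0))
        assert p == 1.0 and np.isnan(odds)

    def test_negative_cell_is_error(self):
        with pytest.raises(ValueError):
            Contingency2x2(-1, 0, 0, 0)

    @settings(derandomize=True, max_examples=60)
    @given(st.integers(0, 12), st.integers(0, 12),
           st.integers(0, 12), st.integers(0, 12))
    def test_matches_enumeration_oracle(self, a, b, c, d):
        p, _ = fisher_exact(Contingency2x2(a, b, c, d), "greater")
        assert p == pytest.approx(enumeration_oracle_greater(a, b, c, d),
                                  abs=1e-12)

    def test_undefined_and_infinite_odds(self):
        _, odds = fisher_exact(Contingency2x2(3, 0, 0, 3))
        assert np.isinf(odds)
        _, odds = fisher_exact(Contingency2x2(0, 3, 0, 3))
        assert np.isnan(odds)


class TestSubtypeFeatureTests:
    def _toy(self):
        # 4 subtype samples, 4 rest; F0 dominant in subtype, F1 equal rates
        pres = pd.DataFrame(
            {"F0": [1, 1, 1, 1, 0, 0, 0, 0],
             "F1": [1, 1, 0, 0, 1, 1, 0, 0]},
            index=[f"S{i}" for i in range(8)])
        lab = pd.Series(["A"] * 4 + ["B"] * 4, index=pres.index)
        return pres, lab

    def test_dominant_feature_ranks_first(self):
        pres, lab = self._toy()
        tops = subtype_feature_tests(pres, lab)
        assert tops["A"].iloc[0]["feature"] == "F0"
        assert tops["A"].iloc[0]["p_value"] == pytest.approx(1 / 70, abs=1e-12)

    def test_equal_rates_are_not_enriched(self):
        pres, lab = self._toy()
        tops = subtype_feature_tests(pres, lab)
        p_f1 = tops["A"].set_index("feature").loc["F1", "p_value"]
        assert p_f1 >= 0.5

    def test_short_feature_list_is_not_padded(self):
        pres, lab = self._toy()
        tops = subtype_feature_tests(pres, lab, top=100)
        assert len(tops["A"]) == 2

    def test_single_subtype_is_error(self):
        pres, _ = self._toy()
        with pytest.raises(ValueError):
            subtype_feature_tests(pres, pd.Series("A", index=pres.index))

    def test_rank_ties_break_deterministically(self):
        pres = pd.DataFrame(np.ones((6, 3), dtype=int),
                            index=[f"S{i}" for i in range(6)],
                            columns=["FZ", "FA", "FM"])
        lab = pd.Series(["A"] * 3 + ["B"] * 3, index=pres.index)
        tops = subtype_feature_tests(pres, lab)
        assert list(tops["A"]["feature"]) == ["FA", "FM", "FZ"]


class TestPairwiseOverlap:
    def test_examples(self):
        t = lambda feats: pd.DataFrame({"feature": feats})
        mats = {"A": t(["x", "y", "z"]), "B": t(["y", "z", "w"]),
                "C": t(["p", "q", "r"])}
        m = pairwise_overlap(mats)
        assert m.loc["A", "B"] == 2
        assert m.loc["A", "C"] == 0
        assert m.loc["A", "A"] == 3

    def test_symmetry_and_diagonal(self):
        rng = np.random.default_rng(0)
        mats = {f"C{i}": pd.DataFrame(
            {"feature": rng.choice(50, size=20, replace=False).astype(str)})
            for i in range(4)}
        m = pairwise_overlap(mats)
        assert (m.to_numpy() == m.to_numpy().T).all()
        assert (np.diag(m.to_numpy()) == 20).all()

    def test_needs_two_lists(self):
        with pytest.raises(ValueError):
            pairwise_overlap({"A": pd.DataFrame({"feature": ["x"]})})


class TestConsequences:
    def test_single_type_is_unit_fraction(self, record_factory):
        recs = [record_factory(sample=f"S{i}") for i in range(3)]
        lab = pd.Series({f"S{i}": "C1" for i in range(3)})
        tab = consequence_frequencies(recs, lab,
                                      {"missense_variant": "MODERATE"})
        assert tab.loc["C1", "missense_variant"] == 1.0

    def test_unmapped_and_empty_become_unavailable(self, record_factory):
        recs = [record_factory(cons="weird_consequence"),
                record_factory(pos=7, ref="G", alt="A", cons="")]
        lab = pd.Series({"S1": "C1"})
        tab = consequence_frequencies(recs, lab, {"missense_variant": "x"})
        assert tab.loc["C1", "Unavailable"] == 1.0

    def test_rows_sum_to_one(self, record_factory):
        recs = [record_factory(sample=f"S{i}", cons=c)
                for i, c in enumerate(["missense_variant", "stop_gained",
                                       "odd", ""])]
        lab = pd.Series({f"S{i}": ("C1" if i < 2 else "C2") for i in range(4)})
        tab = consequence_frequencies(
            recs, lab, {"missense_variant": "m", "stop_gained": "h"})
        assert np.allclose(tab.sum(axis=1), 1.0, atol=1e-9)


def test_gene_motif_presence(toy_fasta, record_factory):
    recs = [
        record_factory(sample="S1", pos=3, ref="C", alt="T", gene="G1"),
        record_factory(sample="S1", pos=3, ref="C", alt="T", gene="G1"),
        record_factory(sample="S2", pos=7, ref="G", alt="A", gene="G2"),
    ]
    pres = build_gene_motif_presence(recs, toy_fasta)
    assert pres.loc["S1", "G1|A[C>T]G"] == 1  # presence, not multiplicity
    assert pres.loc["S2", "G2|G[C>T]A"] == 1
    assert pres.to_numpy().sum() == 2
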