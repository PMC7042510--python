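import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from cernanet import (ExpressionMatrix, InteractionSet,
                      directional_candidates, shared_mirna_test,
                      coexpression, sensitivity_correlation,
                      infer_cerna_pairs)
from .conftest import enumerate_hypergeom_tail, make_interactions_for_counts


def _de(rows):
    return pd.DataFrame(rows, columns=["gene_id", "direction"])


class TestDirectionalCandidates:
    def test_sponge_direction_triple_accepted(self, toy_interactions):
        # lncRNA Down, miRNA Up, mRNA Down: the stretch-typical case
        out = directional_candidates(
            _de([("ASCC3", "Down")]), _de([("miR-4728-5p", "Up")]),
            _de([("NOTCH2", "Down")]), toy_interactions)
        assert out[["lncrna", "mirna", "mrna"]].values.tolist() == \
            [["ASCC3", "miR-4728-5p", "NOTCH2"]]

    def test_all_up_rejected(self, toy_interactions):
        out = directional_candidates(
            _de([("ASCC3", "Up")]), _de([("miR-4728-5p", "Up")]),
            _de([("NOTCH2", "Up")]), toy_interactions)
        assert out.empty

    def test_down_up_down_orientation_excludes_mirror(self, toy_interactions):
        up_mirror = dict(de_lnc=_de([("ASCC3", "Up")]),
                         de_mir=_de([("miR-4728-5p", "Down")]),
                         de_mrna=_de([("NOTCH2", "Up")]))
        both = directional_candidates(interactions=toy_interactions,
                                      orientation="both", **up_mirror)
        strict = directional_candidates(interactions=toy_interactions,
                                        orientation="down_up_down",
                                        **up_mirror)
        assert len(both) == 1 and strict.empty

    def test_matches_brute_force_enumeration_on_full_grid(self):
        # 2 lnc x 2 mir x 2 mrna, all edges present, mixed directions
        lncs = [("l1", "Up"), ("l2", "Down")]
        mirs = [("u1", "Down"), ("u2", "Up")]
        mrnas = [("m1", "Up"), ("m2", "Down")]
        rows = [(u, l, "lncRNA", "") for u, _ in mirs for l, _ in lncs]
        rows += [(u, m, "mRNA", "") for u, _ in mirs for m, _ in mrnas]
        interactions = InteractionSet.from_tuples(rows)
        out = directional_candidates(_de(lncs), _de(mirs), _de(mrnas),
                                     interactions)
        got = set(map(tuple, out[["lncrna", "mirna", "mrna"]].values))
        expected = set()
        for (l, dl), (u, du), (m, dm) in itertools.product(lncs, mirs,
                                                           mrnas):
            if dl == dm and dl != du:
                expected.add((l, u, m))
        assert got == expected


class TestSharedMirnaTest:
    def test_enumeration_example_n10(self):
        iset, bg = make_interactions_for_counts(N=10, K=5, n=4, k=4)
        res = shared_mirna_test("L", "M", iset, bg)
        assert (res.N, res.K, res.n, res.k) == (10, 5, 4, 4)
        assert res.p_value == pytest.approx(5 / 210, abs=1e-12)

    def test_zero_overlap_gives_p_one(self):
        iset, bg = make_interactions_for_counts(N=8, K=3, n=2, k=0)
        assert shared_mirna_test("L", "M", iset, bg).p_value == 1.0

    def test_enumeration_example_n4(self):
        iset, bg = make_interactions_for_counts(N=4, K=2, n=2, k=2)
        assert shared_mirna_test("L", "M", iset, bg).p_value == \
            pytest.approx(1 / 6, abs=1e-12)

    def test_empty_background_rejected(self, toy_interactions):
        with pytest.raises(ValueError, match="background"):
            shared_mirna_test("ASCC3", "NOTCH2", toy_interactions, set())

    @pytest.mark.parametrize("N", [5, 8])
    def test_agrees_with_enumeration_small_sweep(self, N):
        for K in range(N + 1):
            for n in range(N + 1):
                for k in range(max(0, K + n - N), min(K, n) + 1):
                    if K == 0 or n == 0:
                        continue
                    iset, bg = make_interactions_for_counts(N, K, n, k)
                    res = shared_mirna_test("L", "M", iset, bg)
                    assert res.p_value == pytest.approx(
                        enumerate_hypergeom_tail(N, K, n, k), abs=1e-12)

    def test_p_non_increasing_in_k(self):
        N, K, n = 12, 6, 5
        ps = []
        for k in range(0, min(K, n) + 1):
            iset, bg = make_interactions_for_counts(N, K, n, k)
            ps.append(shared_mirna_test("L", "M", iset, bg).p_value)
        assert all(a >= b - 1e-15 for a, b in zip(ps, ps[1:]))


class TestCoexpression:
    def test_identical_profiles(self, toy_matrix):
        r, p = coexpression("ASCC3", "ASCC3", toy_matrix)
        assert r == pytest.approx(1.0)

    def test_negated_profile(self):
        values = pd.DataFrame([[1, 2, 3, 4, 5, 6.0],
                               [-1, -2, -3, -4, -5, -6.0]],
                              index=["a", "b"],
                              columns=["c1", "c2", "c3", "s1", "s2", "s3"])
        m = ExpressionMatrix(
            values, pd.Series({"a": "lncRNA", "b": "mRNA"}),
            pd.Series({"c1": "control", "c2": "control", "c3": "control",
                       "s1": "stretch", "s2": "stretch", "s3": "stretch"}))
        r, _ = coexpression("a", "b", m)
        assert r == pytest.approx(-1.0)

    def test_matches_direct_covariance_formula(self):
        x = np.array([1, 2, 3, 4, 5, 6.0])
        y = np.array([2, 4, 5, 4, 5, 7.0])
        values = pd.DataFrame([x, y], index=["a", "b"],
                              columns=["c1", "c2", "c3", "s1", "s2", "s3"])
        m = ExpressionMatrix(
            values, pd.Series({"a": "lncRNA", "b": "mRNA"}),
            pd.Series({"c1": "control", "c2": "control", "c3": "control",
                       "s1": "stretch", "s2": "stretch", "s3": "stretch"}))
        r, p = coexpression("a", "b", m)
        xc, yc = x - x.mean(), y - y.mean()
        expected = (xc @ yc) / np.sqrt((xc @ xc) * (yc @ yc))
        assert r == pytest.approx(expected, abs=1e-12)
        assert 0 < p < 1

    def test_zero_variance_reports_r_zero_with_warning(self):
        values = pd.DataFrame([[5, 5, 5, 5, 5, 5.0],
                               [1, 2, 3, 4, 5, 6.0]],
                              index=["flat", "b"],
                              columns=["c1", "c2", "c3", "s1", "s2", "s3"])
        m = ExpressionMatrix(
            values, pd.Series({"flat": "lncRNA", "b": "mRNA"}),
            pd.Series({"c1": "control", "c2": "control", "c3": "control",
                       "s1": "stretch", "s2": "stretch", "s3": "stretch"}))
        with pytest.warns(UserWarning, match="zero variance"):
            r, p = coexpression("flat", "b", m)
        assert (r, p) == (0.0, 1.0)


def _matrix_from(rows: dict) -> ExpressionMatrix:
    values = pd.DataFrame(rows).T
    values.columns = ["c1", "c2", "c3", "s1", "s2", "s3"]
    biotype = pd.Series({g: ("miRNA" if g.startswith("u") else
                             "lncRNA" if g.startswith("l") else "mRNA")
                         for g in rows})
    group = pd.Series({"c1": "control", "c2": "control", "c3": "control",
                       "s1": "stretch", "s2": "stretch", "s3": "stretch"})
    return ExpressionMatrix(values, biotype, group)


class TestSensitivityCorrelation:
    def test_uncorrelated_mirna_gives_zero(self):
        # orthogonal miRNA: partial equals marginal, sensitivity 0
        l = np.array([1, -1, 1, -1, 1, -1.0])
        m = np.array([1, -1, 1, -1, -1, 1.0])
        u = np.array([1, 1, -1, -1, 0, 0.0])
        mat = _matrix_from({"l1": l, "m1": m, "u1": u})
        # r(l,u) = r(m,u) = 0 by construction
        assert np.isclose(np.corrcoef(l, u)[0, 1], 0)
        assert np.isclose(np.corrcoef(m, u)[0, 1], 0)
        assert sensitivity_correlation("l1", "m1", {"u1"}, mat) == \
            pytest.approx(0.0, abs=1e-12)

    def test_hand_evaluated_single_mirna(self):
        # r(l,m)=0.8, r(l,u)=r(m,u)=-0.6 -> 0.8 - (0.8-0.36)/0.64 = 0.1125
        r_lm, r_lu, r_mu = 0.8, -0.6, -0.6
        partial = (r_lm - r_lu * r_mu) / np.sqrt(
            (1 - r_lu ** 2) * (1 - r_mu ** 2))
        assert r_lm - partial == pytest.approx(0.1125, abs=1e-12)

    def test_matches_precision_matrix_partial_correlation(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            data = rng.normal(0, 1, (3, 6))
            mat = _matrix_from({"l1": data[0], "m1": data[1],
                                "u1": data[2]})
            got = sensitivity_correlation("l1", "m1", {"u1"}, mat)
            prec = np.linalg.inv(np.corrcoef(data))
            partial = -prec[0, 1] / np.sqrt(prec[0, 0] * prec[1, 1])
            r_lm = np.corrcoef(data[0], data[1])[0, 1]
            assert got == pytest.approx(r_lm - partial, abs=1e-9)

    def test_perfectly_correlated_mirna_skipped_then_error(self):
        l = np.array([1, 2, 3, 4, 5, 6.0])
        mat = _matrix_from({"l1": l, "m1": l[::-1] + 0.5,
                            "u1": 2 * l + 1})
        with pytest.warns(UserWarning, match="perfectly correlated"):
            with pytest.raises(ValueError, match="undefined"):
                sensitivity_correlation("l1", "m1", {"u1"}, mat)

    def test_empty_shared_set_rejected(self, toy_matrix):
        with pytest.raises(ValueError, match="empty"):
            sensitivity_correlation("ASCC3", "NOTCH2", set(), toy_matrix)


class TestInferCernaPairs:
    def _candidates(self, triples):
        rows = [(l, u, m, "Down", "Up", "Down") for l, u, m in triples]
        return pd.DataFrame(rows, columns=["lncrna", "mirna", "mrna",
                                           "lnc_direction", "mir_direction",
                                           "mrna_direction"])

    def test_planted_pair_beats_single_shared_decoys(self):
        # planted pair shares 3 miRNAs; decoy pairs share one each
        rows = [(f"u{i}", "L1", "lncRNA", "") for i in range(3)]
        rows += [(f"u{i}", "M1", "mRNA", "") for i in range(3)]
        rows += [("u3", "L2", "lncRNA", ""), ("u3", "M2", "mRNA", ""),
                 ("u4", "L3", "lncRNA", ""), ("u4", "M3", "mRNA", "")]
        interactions = InteractionSet.from_tuples(rows)
        cand = self._candidates(
            [("L1", f"u{i}", "M1") for i in range(3)] +
            [("L2", "u3", "M2"), ("L3", "u4", "M3")])
        out = infer_cerna_pairs(cand, interactions, min_shared=2,
                                hypergeom_p=1.0)
        assert out[["lncrna", "mrna"]].values.tolist() == [["L1", "M1"]]
        assert out.iloc[0]["k"] == 3

    def test_permissive_thresholds_return_all_candidate_pairs(self,
                                                              toy_interactions):
        cand = self._candidates([("ASCC3", "miR-4728-5p", "NOTCH2")])
        out = infer_cerna_pairs(cand, toy_interactions, hypergeom_p=1.0,
                                min_shared=1)
        assert len(out) == 1

    def test_single_shared_mirna_pair(self, toy_interactions):
        cand = self._candidates([("ASCC3", "miR-4728-5p", "NOTCH2")])
        out = infer_cerna_pairs(cand, toy_interactions, hypergeom_p=1.0)
        row = out.iloc[0]
        assert row["k"] == 1
        assert row["shared_mirnas"] == "miR-4728-5p"

    def test_empty_candidates_yield_empty_table(self, toy_interactions):
        out = infer_cerna_pairs(self._candidates([]), toy_interactions)
        assert out.empty

    def test_invalid_thresholds_rejected(self, toy_interactions):
        cand = self._candidates([("ASCC3", "miR-4728-5p", "NOTCH2")])
        with pytest.raises(ValueError):
            infer_cerna_pairs(cand, toy_interactions, hypergeom_p=0.0)
        with pytest.raises(ValueError):
            infer_cerna_pairs(cand, toy_interactions, min_shared=0)

    def test_correlation_filter_requires_matrix(self, toy_interactions):
        cand = self._candidates([("ASCC3", "miR-4728-5p", "NOTCH2")])
        with pytest.raises(ValueError, match="matrix"):
            infer_cerna_pairs(cand, toy_interactions,
                              require_positive_corr=True)

    def test_positive_correlation_filter(self, toy_interactions, toy_matrix):
        # ASCC3 and NOTCH2 both fall under stretch -> positive correlation
        cand = self._candidates([("ASCC3", "miR-4728-5p", "NOTCH2")])
        out = infer_cerna_pairs(cand, toy_interactions, matrix=toy_matrix,
                                hypergeom_p=1.0, require_positive_corr=True)
        assert len(out) == 1 and out.iloc[0]["pearson_r"] > 0

    @given(st.floats(0.01, 1.0), st.floats(0.01, 1.0))
    def test_tightening_hypergeom_threshold_never_adds_pairs(
            self, p1, p2, ):
        rows = [(f"u{i}", "L1", "lncRNA", "") for i in range(3)]
        rows += [(f"u{i}", "M1", "mRNA", "") for i in range(3)]
        rows += [("u3", "L2", "lncRNA", ""), ("u3", "M2", "mRNA", "")]
        rows += [(f"u{i}", "PAD", "mRNA", "") for i in range(8)]
        interactions = InteractionSet.from_tuples(rows)
        cand = self._candidates(
            [("L1", f"u{i}", "M1") for i in range(3)] +
            [("L2", "u3", "M2")])
        loose = infer_cerna_pairs(cand, interactions,
                                  hypergeom_p=max(p1, p2))
        tight = infer_cerna_pairs(cand, interactions,
                                  hypergeom_p=min(p1, p2))
        assert set(map(tuple, tight[["lncrna", "mrna"]].values)) <= \
            set(map(tuple, loose[["lncrna", "mrna"]].values))
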