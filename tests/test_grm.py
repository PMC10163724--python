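import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gsel.genotypes import genotype_frequencies
from gsel.grm import (
    GRM_METHODS,
    Pedigree,
    build_grm,
    build_numerator_A,
    marker_variance,
    read_gcta_grm,
    read_grm_tsv,
    regularize,
    write_gcta_grm,
    write_grm_tsv,
)

from conftest import make_geno


def hwe_column(p_count_alt_hom, p_count_het, p_count_ref, reps=1):
    """A dosage column at exact genotype counts."""
    col = [2] * p_count_alt_hom + [1] * p_count_het + [0] * p_count_ref
    return np.array(col * reps).reshape(-1, 1)


class TestMarkerVariance:
    def test_true_equals_hwe_at_hwe_proportions(self):
        fr = genotype_frequencies(make_geno(hwe_column(1, 2, 1)))
        assert marker_variance(fr, "TRUE")[0] == pytest.approx(0.5)
        assert marker_variance(fr, "HWE")[0] == pytest.approx(0.5)

    def test_fully_inbred_column(self):
        # [0,0,2,2]: empirical variance 1.0, HWE formula halves it
        fr = genotype_frequencies(make_geno(hwe_column(2, 0, 2)))
        assert marker_variance(fr, "TRUE")[0] == pytest.approx(1.0)
        assert marker_variance(fr, "HWE")[0] == pytest.approx(0.5)

    def test_monomorphic_is_zero_under_both(self):
        fr = genotype_frequencies(make_geno(hwe_column(0, 0, 4)))
        assert marker_variance(fr, "TRUE")[0] == 0.0
        assert marker_variance(fr, "HWE")[0] == 0.0

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=200, deadline=None)
    def test_true_variance_is_population_variance(self, seed):
        """Var* must equal the divide-by-n variance of the dosage column."""
        rng = np.random.default_rng(seed)
        col = rng.integers(0, 3, size=rng.integers(2, 25)).reshape(-1, 1)
        fr = genotype_frequencies(make_geno(col.astype(np.int8)))
        assert marker_variance(fr, "TRUE")[0] == pytest.approx(
            np.var(col.astype(float)), abs=1e-12
        )


class TestBuildGrm:
    def test_two_animal_iv_hand_computation(self):
        # M=[[0],[2]]: Z* = [-1, 1], Var* = 1, m = 1 -> [[1,-1],[-1,1]]
        geno = make_geno([[0], [2]])
        g = build_grm(geno, "IV")
        assert g.values == pytest.approx(np.array([[1.0, -1.0], [-1.0, 1.0]]))

    def test_hwe_limit_sp_equals_sv_and_ip_equals_iv(self):
        rng = np.random.default_rng(3)
        cols = [hwe_column(k * k, 2 * k * (4 - k), (4 - k) ** 2)
                for k in (1, 2, 3)]  # exact HWE counts with n=16
        d = np.hstack([np.repeat(c, 1, axis=1) for c in cols])
        perm = rng.permutation(d.shape[0])
        geno = make_geno(d[perm])
        assert build_grm(geno, "SP").values == pytest.approx(
            build_grm(geno, "SV").values, abs=1e-10
        )
        assert build_grm(geno, "IP").values == pytest.approx(
            build_grm(geno, "IV").values, abs=1e-10
        )

    def test_iv_trace_identity(self):
        rng = np.random.default_rng(7)
        for _ in range(5):
            d = rng.integers(0, 3, size=(rng.integers(5, 30), rng.integers(4, 40)))
            d[0] = 0
            d[1] = 2  # keep polymorphic columns likely; drop failures
            geno = make_geno(d.astype(np.int8))
            fr = genotype_frequencies(geno)
            if (marker_variance(fr, "TRUE") <= 0).any():
                continue
            g = build_grm(geno, "IV")
            assert np.trace(g.values) / geno.n_animals == pytest.approx(1.0, abs=1e-8)

    def test_marker_order_invariance(self):
        rng = np.random.default_rng(1)
        d = rng.integers(0, 3, size=(15, 20)).astype(np.int8)
        geno = make_geno(d)
        perm = rng.permutation(20)
        shuffled = geno.subset(markers=perm)
        for method in GRM_METHODS:
            try:
                a = build_grm(geno, method).values
            except ValueError:
                continue
            assert a == pytest.approx(build_grm(shuffled, method).values, abs=1e-12)

    def test_zero_variance_marker_rejected(self):
        geno = make_geno([[0, 1], [0, 2], [0, 1]])
        with pytest.raises(ValueError, match="qc_filter"):
            build_grm(geno, "IV")

    def test_unknown_method_rejected(self):
        geno = make_geno([[0], [2]])
        with pytest.raises(ValueError, match="method"):
            build_grm(geno, "XX")


class TestRegularize:
    def test_epsilon_bounds(self):
        g = build_grm(make_geno([[0], [2]]), "IV")
        for eps in (0.0, 1.0, -0.1):
            with pytest.raises(ValueError):
                regularize(g, eps)

    def test_identity_fixed_point(self):
        from gsel.grm import RelationshipMatrix

        rel = RelationshipMatrix(np.eye(4), np.array(list("abcd"), dtype=object), "SP")
        assert regularize(rel, 0.01).values == pytest.approx(np.eye(4))

    def test_rank_deficient_becomes_positive_definite(self):
        rng = np.random.default_rng(2)
        d = rng.integers(0, 3, size=(30, 5)).astype(np.int8)  # m << n
        g = build_grm(make_geno(d), "SP")
        assert np.linalg.eigvalsh(g.values).min() < 1e-10
        reg = regularize(g, 0.01)
        assert np.linalg.eigvalsh(reg.values).min() > 0


# ---------------------------------------------------------------------------
# Pedigree A


def path_coefficient_a(records):
    """Independent brute-force numerator relationship via recursive kinship.

    f(i, j) is the kinship; a(i, j) = 2 f(i, j).  Classic recursion over
    parents, memoized, valid for any acyclic pedigree.
    """
    parents = {r[0]: (r[1], r[2]) for r in records}
    order = {r[0]: k for k, r in enumerate(records)}
    from functools import lru_cache

    @lru_cache(maxsize=None)
    def kinship(i, j):
        if i is None or j is None:
            return 0.0
        if i == j:
            s, d = parents[i]
            return 0.5 * (1.0 + kinship(s, d))
        # recurse on the younger animal
        if order[i] < order[j]:
            i, j = j, i
        s, d = parents[i]
        return 0.5 * (kinship(s, j) + kinship(d, j))

    ids = [r[0] for r in records]
    n = len(ids)
    a = np.empty((n, n))
    for x in range(n):
        for y in range(n):
            a[x, y] = 2.0 * kinship(ids[x], ids[y])
    return ids, a


class TestNumeratorA:
    def test_parent_offspring_half(self):
        ped = Pedigree(pd.DataFrame({"id": ["s", "o"], "sire": [None, "s"], "dam": [None, None]}))
        a = build_numerator_A(ped)
        i, j = a.index_of(["s", "o"])
        assert a.values[i, j] == pytest.approx(0.5)

    def test_unrelated_founders_identity(self):
        ped = Pedigree(pd.DataFrame({"id": list("abc"), "sire": [None] * 3, "dam": [None] * 3}))
        assert build_numerator_A(ped).values == pytest.approx(np.eye(3))

    def test_full_sibs_half(self):
        ped = Pedigree(
            pd.DataFrame(
                {"id": ["s", "d", "o1", "o2"], "sire": [None, None, "s", "s"],
                 "dam": [None, None, "d", "d"]}
            )
        )
        a = build_numerator_A(ped)
        i, j = a.index_of(["o1", "o2"])
        assert a.values[i, j] == pytest.approx(0.5)

    def test_matches_path_coefficient_oracle_on_deep_pedigree(self):
        records = [
            ("f1", None, None), ("f2", None, None),
            ("c1", "f1", "f2"), ("c2", "f1", "f2"),
            ("g1", "c1", "f2"),            # inbred: parent-with-own-parent chain
            ("g2", "c1", "c2"),            # full-sib mating
        ]
        ped = Pedigree(pd.DataFrame(records, columns=["id", "sire", "dam"]))
        built = build_numerator_A(ped)
        ids, oracle = path_coefficient_a(records)
        idx = built.index_of(ids)
        assert built.values[np.ix_(idx, idx)] == pytest.approx(oracle, abs=1e-12)
        assert (oracle >= 0).all() and (oracle <= 2).all()

    def test_random_pedigrees_match_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(20):
            records = [("p0", None, None), ("p1", None, None)]
            for k in range(2, 8):
                s = f"p{rng.integers(k)}"
                d = f"p{rng.integers(k)}"
                if s == d:
                    d = None
                records.append((f"p{k}", s, d))
            ped = Pedigree(pd.DataFrame(records, columns=["id", "sire", "dam"]))
            built = build_numerator_A(ped)
            ids, oracle = path_coefficient_a(records)
            idx = built.index_of(ids)
            assert built.values[np.ix_(idx, idx)] == pytest.approx(oracle, abs=1e-12)

    def test_self_parenting_rejected(self):
        with pytest.raises(ValueError, match="own parent"):
            Pedigree(pd.DataFrame({"id": ["x"], "sire": ["x"], "dam": [None]}))

    def test_cycle_rejected(self):
        df = pd.DataFrame(
            {"id": ["a", "b"], "sire": ["b", "a"], "dam": [None, None]}
        )
        with pytest.raises(ValueError, match="cycle"):
            Pedigree(df)


class TestGrmIO:
    def test_gcta_binary_roundtrip(self, tmp_path):
        rng = np.random.default_rng(4)
        d = rng.integers(0, 3, size=(10, 30)).astype(np.int8)
        g = build_grm(make_geno(d), "SP")
        write_gcta_grm(g, tmp_path / "t", n_markers=30)
        back = read_gcta_grm(tmp_path / "t", "SP")
        assert back.values == pytest.approx(g.values, abs=1e-6)  # float32 storage
        assert list(back.ids) == list(g.ids)

    def test_tsv_roundtrip(self, tmp_path):
        g = build_grm(make_geno([[0, 1], [2, 1], [1, 0]]), "SV")
        write_grm_tsv(g, tmp_path / "g.tsv")
        back = read_grm_tsv(tmp_path / "g.tsv", "SV")
        assert back.values == pytest.approx(g.values)
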