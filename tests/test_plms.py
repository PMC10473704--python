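import itertools
import math

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from lck.io_core import ValidationError
from lck.plms import (
    EnrichParams,
    LFQTable,
    candidate_filter,
    impute_missing,
    moderated_t,
    normalize_to_bait,
    permutation_fdr,
    read_lfq,
    write_lfq,
)
from lck.synthetic import LFQTruth, gen_lfq


def _table(values, groups, msms=None):
    values = pd.DataFrame(values)
    design = pd.DataFrame({"group": groups}, index=values.columns)
    return LFQTable(values=values, design=design,
                    ms_ms_identified=msms if msms is not None else set(values.index))


def _six_samples(rng, n_proteins=200, missing=0.0):
    vals = rng.normal(25, 2, size=(n_proteins, 6))
    if missing:
        vals[rng.random(vals.shape) < missing] = np.nan
    df = pd.DataFrame(vals, index=[f"p{i}" for i in range(n_proteins)],
                      columns=[f"s{i}" for i in range(6)])
    return _table(df, ["a"] * 3 + ["b"] * 3)


class TestImputeMissing:
    def test_no_missing_unchanged(self, rng):
        t = _six_samples(rng)
        out = impute_missing(t, EnrichParams(), seed=0)
        assert out.values.equals(t.values)

    def test_imputed_moments_match_downshifted_normal(self, rng):
        t = _six_samples(rng, n_proteins=3000, missing=0.2)
        mask = t.values.isna().to_numpy()
        observed = t.values.to_numpy()[~mask]
        mu, sigma = observed.mean(), observed.std()
        out = impute_missing(t, EnrichParams(), seed=1)
        imputed = out.values.to_numpy()[mask]
        n = len(imputed)
        se_mean = 0.3 * sigma / math.sqrt(n)
        assert abs(imputed.mean() - (mu - 1.8 * sigma)) <= 4 * se_mean
        assert imputed.std() == pytest.approx(0.3 * sigma, rel=0.1)
        # observed entries untouched
        np.testing.assert_array_equal(out.values.to_numpy()[~mask], observed)

    def test_fixed_seed_identical(self, rng):
        t = _six_samples(rng, missing=0.3)
        a = impute_missing(t, EnrichParams(), seed=7)
        b = impute_missing(t, EnrichParams(), seed=7)
        assert a.values.equals(b.values)

    def test_all_missing_rejected(self):
        t = _table(pd.DataFrame(np.full((4, 4), np.nan),
                                columns=list("wxyz")), ["a", "a", "b", "b"])
        with pytest.raises(ValidationError):
            impute_missing(t, EnrichParams(), seed=0)


class TestNormalizeToBait:
    def test_bait_row_becomes_zero(self, rng):
        t = _six_samples(rng)
        out = normalize_to_bait(t, "p0")
        np.testing.assert_allclose(out.values.loc["p0"], 0.0)

    def test_column_shift_invariance(self, rng):
        t = _six_samples(rng)
        shifted = _table(t.values.copy(), list(t.design["group"]))
        shifted.values["s0"] += 5.0
        a = normalize_to_bait(t, "p0").values
        b = normalize_to_bait(shifted, "p0").values
        pd.testing.assert_frame_equal(a, b)

    def test_two_by_two_entrywise(self):
        t = _table(pd.DataFrame({"s1": [10.0, 12.0], "s2": [11.0, 15.0]},
                                index=["bait", "x"]), ["a", "a"])
        out = normalize_to_bait(t, "bait").values
        assert out.loc["x", "s1"] == 2.0 and out.loc["x", "s2"] == 4.0

    def test_missing_bait_names_sample(self, rng):
        t = _six_samples(rng)
        t.values.loc["p0", "s3"] = np.nan
        with pytest.raises(ValidationError, match="s3"):
            normalize_to_bait(t, "p0")


class TestModeratedT:
    def test_identical_groups_zero(self):
        assert moderated_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], s0=0.5) == (0.0, 0.0)

    def test_s0_zero_recovers_student_t(self, rng):
        for _ in range(1000):
            a = rng.normal(size=rng.integers(2, 6))
            b = rng.normal(size=rng.integers(2, 6))
            _, t_mod = moderated_t(a, b, s0=0.0)
            t_ref = scipy.stats.ttest_ind(a, b, equal_var=True).statistic
            assert t_mod == pytest.approx(t_ref, abs=1e-9)

    def test_textbook_example(self):
        diff, t_mod = moderated_t([3, 4, 5], [1, 2, 3], s0=0.0)
        assert diff == 2.0
        assert t_mod == pytest.approx(scipy.stats.ttest_ind(
            [3, 4, 5], [1, 2, 3], equal_var=True).statistic)

    def test_positive_s0_shrinks_t(self):
        _, t0 = moderated_t([3, 4, 5], [1, 2, 3], s0=0.0)
        _, t5 = moderated_t([3, 4, 5], [1, 2, 3], s0=0.5)
        assert abs(t5) < abs(t0)

    def test_zero_variance_s0_zero_rejected(self):
        with pytest.raises(ValidationError):
            moderated_t([1.0, 1.0], [2.0, 2.0], s0=0.0)


def _brute_force_fdr(values, na, s0, fdr):
    """Independent oracle: enumerate all label assignments explicitly."""
    n = values.shape[1]

    def tstat(vals, ia):
        ib = [j for j in range(n) if j not in ia]
        a, b = vals[:, list(ia)], vals[:, ib]
        sp2 = (a.var(axis=1, ddof=1) * (a.shape[1] - 1)
               + b.var(axis=1, ddof=1) * (b.shape[1] - 1)) / (n - 2)
        se = np.sqrt(sp2 * (1 / a.shape[1] + 1 / b.shape[1]))
        return (a.mean(axis=1) - b.mean(axis=1)) / (se + s0)

    identity = tuple(range(na))
    complement = tuple(range(na, n))
    obs = np.abs(tstat(values, identity))
    nulls = [np.abs(tstat(values, c))
             for c in itertools.combinations(range(n), na)
             if c not in (identity, complement)]
    significant = set()
    for thr in sorted(obs, reverse=True):
        total_null = sum((nv >= thr).sum() for nv in nulls)
        est = ((total_null + 1) / (len(nulls) + 1)) / (obs >= thr).sum()
        if est <= fdr:
            significant = {i for i in range(len(obs)) if obs[i] >= thr}
    return significant


class TestPermutationFdr:
    def test_matches_exhaustive_brute_force_oracle(self, rng):
        base = rng.normal(25, 2, size=(120, 1))  # protein abundance
        vals = base + rng.normal(0, 0.5, size=(120, 6))  # replicate noise
        vals[:10, :3] += 4.0  # planted
        t = _table(pd.DataFrame(vals, index=[f"p{i}" for i in range(120)],
                                columns=[f"s{i}" for i in range(6)]),
                   ["a"] * 3 + ["b"] * 3)
        params = EnrichParams(s0=0.5, fdr=0.05)
        res = permutation_fdr(t, ("a", "b"), params, seed=0)
        got = {i for i, p in enumerate(res["passed"]) if p}
        expected = _brute_force_fdr(vals, 3, 0.5, 0.05)
        assert got == expected
        assert got  # the planted block is detectable

    def test_exhaustive_permutations_seed_free(self, rng):
        t = _six_samples(rng)
        t.values.iloc[:5, :3] += 4.0
        params = EnrichParams()
        r1 = permutation_fdr(t, ("a", "b"), params, seed=1)
        r2 = permutation_fdr(t, ("a", "b"), params, seed=99)
        pd.testing.assert_frame_equal(r1, r2)

    def test_significant_set_grows_with_fdr_and_is_threshold_set(self, rng):
        vals = rng.normal(25, 0.5, size=(300, 6))
        vals[:40, :3] += rng.uniform(0.5, 3.0, size=(40, 1))
        t = _table(pd.DataFrame(vals, index=[f"p{i}" for i in range(300)],
                                columns=[f"s{i}" for i in range(6)]),
                   ["a"] * 3 + ["b"] * 3)

        def res_at(fdr):
            return permutation_fdr(t, ("a", "b"), EnrichParams(s0=0.5, fdr=fdr), seed=0)

        sets = {}
        for fdr in (0.01, 0.05, 0.10):
            res = res_at(fdr)
            sets[fdr] = set(res.loc[res.passed, "protein"])
            if sets[fdr]:  # significant set is a |t| threshold set
                min_t = res.loc[res.passed, "t_mod"].abs().min()
                assert (res["t_mod"].abs() >= min_t).equals(res["passed"])
        assert sets[0.01] <= sets[0.05] <= sets[0.10]

    def test_missing_values_rejected(self, rng):
        t = _six_samples(rng, missing=0.2)
        with pytest.raises(ValidationError, match="impute"):
            permutation_fdr(t, ("a", "b"), EnrichParams(), seed=0)


class TestCandidateFilter:
    def test_gates(self, rng):
        proteins = [f"p{i}" for i in range(4)]
        vals = pd.DataFrame(rng.normal(25, 1, size=(4, 4)), index=proteins,
                            columns=["b1", "b2", "w1", "w2"])
        vals.loc["p2", ["b1", "b2"]] = np.nan  # fails detection gate
        t = _table(vals, ["bait", "bait", "wt", "wt"],
                   msms={"p0", "p2", "p3"})  # p1 fails MS/MS gate
        res = {
            "vs_wt": pd.DataFrame({"protein": proteins, "diff": [1, 1, 1, 1.0],
                                   "t_mod": [3.0] * 4, "fdr_est": [0.01] * 4,
                                   "passed": [True, True, True, True]}),
            "vs_mock": pd.DataFrame({"protein": proteins, "diff": [1, 1, 1, -1.0],
                                     "t_mod": [3.0] * 4, "fdr_est": [0.01] * 4,
                                     "passed": [True, True, True, False]}),
        }
        out = candidate_filter(res, t, EnrichParams(), bait_biotin_group="bait")
        # p0: all gates pass; p1: no MS/MS; p2: <2 bait reps; p3: fails vs_mock
        assert out == {"p0"}

    def test_no_contrasts_rejected(self, rng):
        with pytest.raises(ValidationError):
            candidate_filter({}, _six_samples(rng), EnrichParams(),
                             bait_biotin_group="a")


class TestLfqIO:
    def test_round_trip(self, tmp_path, rng):
        t = gen_lfq(50, {f"g_r{r}": "g" for r in (1, 2)} | {f"h_r{r}": "h" for r in (1, 2)},
                    LFQTruth(frozenset(["prot_0001"]), effect=2.0, missing_rate=0.1),
                    seed=3, bait_group="g")
        write_lfq(t, tmp_path / "v.tsv", tmp_path / "d.tsv", tmp_path / "m.txt")
        back = read_lfq(tmp_path / "v.tsv", tmp_path / "d.tsv", tmp_path / "m.txt")
        pd.testing.assert_frame_equal(back.values, t.values, check_names=False)
        assert list(back.design["group"]) == list(t.design["group"])
        assert back.ms_ms_identified == t.ms_ms_identified
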