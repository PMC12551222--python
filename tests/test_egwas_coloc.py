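"""Expression cis scans, TSS profiles, LD, colocalization, and SMR."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import hapintro as hi


class TestExpressionFilter:
    def test_gene_with_too_many_low_samples_removed(self):
        expr = pd.DataFrame(
            [[0.05] * 25 + [1.0] * 75, [1.0] * 100],
            index=["low", "ok"],
            columns=[f"s{i}" for i in range(100)],
        )
        kept = hi.filter_expressed_genes(expr)
        assert list(kept.index) == ["ok"]

    def test_all_expressed_kept(self):
        expr = pd.DataFrame(
            np.full((3, 10), 0.5), index=list("abc"),
            columns=[f"s{i}" for i in range(10)],
        )
        assert len(hi.filter_expressed_genes(expr)) == 3

    def test_matches_row_wise_oracle(self):
        rng = np.random.default_rng(3)
        expr = pd.DataFrame(
            rng.exponential(0.3, (50, 40)),
            index=[f"g{i}" for i in range(50)],
            columns=[f"s{i}" for i in range(40)],
        )
        kept = set(hi.filter_expressed_genes(expr).index)
        expected = {
            g for g in expr.index
            if (expr.loc[g] < 0.1).mean() <= 0.2
        }
        assert kept == expected


def test_bonferroni_threshold_is_alpha_over_gene_count():
    thr = hi.bonferroni_threshold(12_143)
    assert thr == 0.05 / 12_143
    assert thr == pytest.approx(4.12e-6, rel=1e-2)


def make_cis_data(seed, n=100, n_blocks=60, causal=30, var_frac=0.1):
    rng = np.random.default_rng(seed)
    # Markov-correlated haplotype carriers: neighbouring cis blocks share
    # ancestry tracts, as the recoded blocks do
    hap = np.empty((2 * n, n_blocks), dtype=float)
    hap[:, 0] = rng.random(2 * n) < 0.3
    for j in range(1, n_blocks):
        fresh = rng.random(2 * n) < 0.1
        hap[:, j] = np.where(fresh, rng.random(2 * n) < 0.3, hap[:, j - 1])
    D = hap.reshape(n, 2, n_blocks).sum(1)
    d = D[:, causal]
    beta = np.sqrt(var_frac / d.var())
    month = rng.integers(0, 6, n).astype(float)
    y = d * beta + 0.05 * month + rng.normal(0, np.sqrt(1 - var_frac), n)
    expr = pd.DataFrame([y], index=["gene1"], columns=[f"s{i}" for i in range(n)])
    meta = pd.DataFrame(
        {
            "marker": np.arange(n_blocks),
            "chrom": "1",
            "start": np.arange(n_blocks) * 50_000,
            "end": np.arange(n_blocks) * 50_000 + 50_000,
        }
    )
    tss = pd.DataFrame(
        {"gene_id": ["gene1"], "chrom": ["1"], "tss": [causal * 50_000], "strand": ["+"]}
    )
    cov = pd.DataFrame({"month_age": month})
    return expr, tss, D, meta, cov


class TestCisScan:
    def test_adjusted_p_exceeds_nominal_and_floor(self):
        expr, tss, D, meta, cov = make_cis_data(1)
        out = hi.cis_scan(expr, tss, D, meta, cov, seed=5)
        row = out.iloc[0]
        assert row["p_perm"] >= row["p_nominal"]
        assert row["p_perm"] >= 1 / (row["n_perm"] + 1)

    def test_beta_approximation_tracks_direct_permutation(self):
        agree = 0
        checked = 0
        for s in range(6):
            expr, tss, D, meta, cov = make_cis_data(40 + s, var_frac=0.04)
            out = hi.cis_scan(expr, tss, D, meta, cov, seed=6).iloc[0]
            if 0.001 <= out["p_perm"] <= 0.5:
                checked += 1
                ratio = out["p_beta"] / out["p_perm"]
                agree += 0.5 <= ratio <= 2.0
        assert checked == 0 or agree == checked

    def test_permuted_expression_yields_no_bonferroni_hits(self):
        rng = np.random.default_rng(9)
        expr, tss, D, meta, cov = make_cis_data(2, var_frac=0.0)
        expr.iloc[0] = rng.permutation(expr.iloc[0].to_numpy())
        out = hi.cis_scan(expr, tss, D, meta, cov, seed=7)
        thr = hi.bonferroni_threshold(1000)
        assert (out["p_beta"].dropna() > thr).all()

    def test_simulated_cis_effect_detected(self):
        hits = 0
        reps = 12
        for s in range(reps):
            expr, tss, D, meta, cov = make_cis_data(100 + s, var_frac=0.1)
            out = hi.cis_scan(expr, tss, D, meta, cov, seed=8).iloc[0]
            hits += bool(out["p_beta"] < 0.05)
        assert hits >= 0.7 * reps

    def test_gene_without_cis_marker_flagged(self):
        expr, tss, D, meta, cov = make_cis_data(3)
        tss_far = tss.copy()
        tss_far["tss"] = 50_000_000
        out = hi.cis_scan(expr, tss_far, D, meta, cov, seed=9)
        assert out.iloc[0]["n_cis_markers"] == 0
        assert np.isnan(out.iloc[0]["p_nominal"])


class TestTssDistance:
    def test_marker_at_tss_gives_zero(self):
        assoc = pd.DataFrame(
            {"gene_id": ["g"], "marker_start": [990], "marker_end": [1010]}
        )
        tss = pd.DataFrame(
            {"gene_id": ["g"], "chrom": ["1"], "tss": [1000], "strand": ["+"]}
        )
        out = hi.tss_distance_profile(assoc, tss)
        assert out["tss_distance"].iloc[0] == 0.0

    def test_minus_strand_flips_sign(self):
        assoc = pd.DataFrame(
            {"gene_id": ["g"], "marker_start": [1500], "marker_end": [2500]}
        )
        tss = pd.DataFrame(
            {"gene_id": ["g"], "chrom": ["1"], "tss": [1000], "strand": ["-"]}
        )
        out = hi.tss_distance_profile(assoc, tss)
        assert out["tss_distance"].iloc[0] == -1000.0

    def test_detected_signals_lie_near_tss(self):
        """Cis architecture within +-100 kb: detected signals' median
        |distance| stays well under 500 kb."""
        rng = np.random.default_rng(12)
        rows = []
        for g in range(30):
            tss_pos = int(rng.integers(1_000_000, 9_000_000))
            offset = int(rng.integers(-100_000, 100_000))
            rows.append(("g%d" % g, tss_pos, offset))
        assoc = pd.DataFrame(
            {
                "gene_id": [r[0] for r in rows],
                "marker_start": [r[1] + r[2] - 25_000 for r in rows],
                "marker_end": [r[1] + r[2] + 25_000 for r in rows],
            }
        )
        tss = pd.DataFrame(
            {
                "gene_id": [r[0] for r in rows],
                "chrom": "1",
                "tss": [r[1] for r in rows],
                "strand": rng.choice(["+", "-"], 30),
            }
        )
        out = hi.tss_distance_profile(assoc, tss)
        assert out["tss_distance"].abs().median() < 500_000


class TestLd:
    def test_self_correlation_is_one(self):
        a = np.array([0.0, 1, 2, 1, 0, 2])
        assert hi.ld_r2(a, a) == pytest.approx(1.0)

    def test_orthogonal_vectors_give_zero(self):
        a = np.array([1.0, 1, -1, -1])
        b = np.array([1.0, -1, 1, -1])
        assert hi.ld_r2(a, b) == pytest.approx(0.0, abs=1e-12)

    def test_matches_textbook_formula(self):
        rng = np.random.default_rng(4)
        a, b = rng.integers(0, 3, (2, 50)).astype(float)
        num = ((a - a.mean()) * (b - b.mean())).sum()
        den = np.sqrt(((a - a.mean()) ** 2).sum() * ((b - b.mean()) ** 2).sum())
        assert hi.ld_r2(a, b) == pytest.approx((num / den) ** 2, abs=1e-12)

    def test_constant_vector_flagged(self):
        assert np.isnan(hi.ld_r2(np.ones(5), np.arange(5.0)))


def coloc_sim(seed, shared=True, n=200, m=80):
    """Summary stats for two traits with a shared or distinct causal variant."""
    rng = np.random.default_rng(seed)
    D = rng.binomial(2, 0.4, (n, m)).astype(float)
    c1 = m // 2
    c2 = c1 if shared else m // 4
    if not shared and hi.ld_r2(D[:, c1], D[:, c2]) > 0.2:
        D[:, c2] = rng.binomial(2, 0.4, n)
    def scan(causal, frac):
        d = D[:, causal]
        beta = np.sqrt(frac / d.var())
        y = d * beta + rng.normal(0, np.sqrt(1 - frac), n)
        betas, ses = np.empty(m), np.empty(m)
        for j in range(m):
            x = D[:, j] - D[:, j].mean()
            yc = y - y.mean()
            b = (x @ yc) / (x @ x)
            r = yc - b * x
            ses[j] = np.sqrt(r @ r / (n - 2) / (x @ x))
            betas[j] = b
        return {"beta": betas, "se": ses}
    return scan(c1, 0.25), scan(c2, 0.25)


class TestColoc:
    def test_posteriors_sum_to_one_on_random_inputs(self):
        rng = np.random.default_rng(5)
        for _ in range(1000):
            m = int(rng.integers(2, 30))
            t = {"z": rng.normal(0, 2, m), "se": rng.uniform(0.05, 0.5, m)}
            e = {"z": rng.normal(0, 2, m), "se": rng.uniform(0.05, 0.5, m)}
            res = hi.coloc_abf(t, e)
            assert sum(res.pp.values()) == pytest.approx(1.0, abs=1e-10)

    def test_shared_causal_variant_gives_high_h4(self):
        hits = 0
        reps = 15
        for s in range(reps):
            t, e = coloc_sim(600 + s, shared=True)
            hits += bool(hi.coloc_abf(t, e).pp_h4 > 0.75)
        assert hits >= 0.8 * reps

    def test_distinct_causal_variants_favor_h3(self):
        hits = 0
        reps = 15
        for s in range(reps):
            t, e = coloc_sim(700 + s, shared=False)
            pp = hi.coloc_abf(t, e).pp
            hits += bool(pp["PP.H3"] > pp["PP.H4"])
        assert hits >= 0.8 * reps

    def test_h4_monotone_in_shared_prior(self):
        t, e = coloc_sim(8, shared=True)
        h4s = [
            hi.coloc_abf(t, e, p12=p12).pp_h4 for p12 in (1e-6, 1e-5, 1e-4)
        ]
        assert h4s[0] <= h4s[1] <= h4s[2]

    def test_zero_standard_errors_rejected(self):
        with pytest.raises(ValueError):
            hi.coloc_abf({"z": np.ones(3), "se": np.zeros(3)},
                         {"z": np.ones(3), "se": np.ones(3)})


class TestIterativeColoc:
    def test_enumeration_oracle_with_two_companions(self):
        rng = np.random.default_rng(13)
        n, m = 150, 12
        D = rng.binomial(2, 0.5, (n, m)).astype(float)
        lead = 3
        D[:, 4] = D[:, lead]  # r2 = 1 companions
        D[:, 5] = D[:, lead]
        t, e = (
            {"z": rng.normal(0, 2, m), "se": rng.uniform(0.1, 0.3, m)},
            {"z": rng.normal(0, 2, m), "se": rng.uniform(0.1, 0.3, m)},
        )
        best = hi.iterative_coloc(t, e, D, lead_index=lead, r2_threshold=0.9)
        # independent enumeration of the runs
        H = [j for j in range(m) if hi.ld_r2(D[:, j], D[:, lead]) > 0.9]
        R = [j for j in range(m) if j not in H]
        assert len(H) == 3  # lead + 2 planted companions

        def run_pp(idx):
            sub_t = {k: np.asarray(v)[idx] for k, v in t.items()}
            sub_e = {k: np.asarray(v)[idx] for k, v in e.items()}
            return hi.coloc_abf(sub_t, sub_e).pp_h4

        expected = np.full(m, -np.inf)
        pp_base = run_pp(R)
        for j in R:
            expected[j] = max(expected[j], pp_base)
        for h in H:
            idx = sorted(R + [h])
            pp = run_pp(idx)
            for j in idx:
                expected[j] = max(expected[j], pp)
        np.testing.assert_allclose(best, expected, atol=1e-12)

    def test_result_invariant_to_companion_order(self):
        rng = np.random.default_rng(14)
        n, m = 100, 8
        D = rng.binomial(2, 0.5, (n, m)).astype(float)
        D[:, 1] = D[:, 0]
        t = {"z": rng.normal(0, 2, m), "se": rng.uniform(0.1, 0.3, m)}
        e = {"z": rng.normal(0, 2, m), "se": rng.uniform(0.1, 0.3, m)}
        a = hi.iterative_coloc(t, e, D, lead_index=0)
        b = hi.iterative_coloc(t, e, D, lead_index=1)
        cols = [j for j in range(m) if j not in (0, 1)]
        np.testing.assert_allclose(a[cols], b[cols], atol=1e-12)


class TestSmr:
    def test_smr_bound_holds_for_arbitrary_z(self):
        from hypothesis import given, settings, strategies as st

        finite = st.floats(-50, 50, allow_nan=False)

        @given(zg=finite, ze=finite)
        @settings(max_examples=200, derandomize=True)
        def check(zg, ze):
            T, p = hi.smr_test(zg, ze)
            if zg * zg + ze * ze == 0:  # includes underflow of both z^2
                assert np.isnan(T)
            else:
                assert T <= min(zg**2, ze**2) + 1e-9
                assert 0.0 <= p <= 1.0

        check()

    def test_equal_z_of_two(self):
        T, p = hi.smr_test(2.0, 2.0)
        assert T == pytest.approx(2.0)
        assert p == pytest.approx(stats.chi2.sf(2.0, 1))

    def test_limit_large_instrument(self):
        T, _ = hi.smr_test(3.0, 1e9)
        assert T == pytest.approx(9.0, rel=1e-6)

    def test_p_matches_survival_function_on_random_inputs(self):
        rng = np.random.default_rng(6)
        for _ in range(100):
            zg, ze = rng.normal(0, 3, 2)
            if ze == 0:
                continue
            T, p = hi.smr_test(zg, ze)
            assert p == pytest.approx(float(stats.chi2.sf(T, 1)), rel=1e-12)
            assert T <= min(zg**2, ze**2) + 1e-12

    def test_double_zero_is_undefined(self):
        T, p = hi.smr_test(0.0, 0.0)
        assert np.isnan(T) and np.isnan(p)
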