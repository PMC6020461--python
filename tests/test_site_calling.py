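"""Site calling: mRatio, background pooling, Fisher calling, BH, replicates."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from m5ctopo.formats_io import ValidationError
from m5ctopo.site_calling import (
    Background,
    CallResult,
    bh_adjust,
    call_site,
    call_sites,
    combine_replicates,
    estimate_background,
    mratio,
)

from conftest import fisher_one_sided_oracle, make_site


class TestMratio:
    @pytest.mark.parametrize(
        "n_meth,n_unmeth,expected",
        [(5, 5, 0.5), (10, 0, 1.0), (1, 9, 0.1), (0, 7, 0.0)],
    )
    def test_hand_values(self, n_meth, n_unmeth, expected):
        assert mratio(n_meth, n_unmeth) == pytest.approx(expected)

    def test_equals_one_minus_conversion_rate(self):
        # conversion rate 0.9 (9 of 10 reads converted) -> mRatio 0.1
        assert mratio(1, 9) == pytest.approx(1 - 0.9)

    def test_zero_coverage_undefined(self):
        with pytest.raises(ValidationError):
            mratio(0, 0)


class TestBackground:
    def test_pooled_rate_arithmetic(self):
        sites = [make_site(n_meth=1, n_unmeth=99), make_site(pos=2, n_meth=2, n_unmeth=98)]
        bg = estimate_background(sites)
        assert bg.b_meth == 3 and bg.b_unmeth == 197
        assert bg.rate == pytest.approx(0.015)

    def test_all_converted_gives_zero_rate(self):
        bg = estimate_background([make_site(n_meth=0, n_unmeth=50)])
        assert bg.rate == 0.0

    def test_empty_input_rejected(self):
        with pytest.raises(ValidationError):
            estimate_background([])

    def test_null_simulation_recovers_p0(self):
        # pooled estimate over >=1e5 reads lands within 3 SE of the truth
        rng = np.random.default_rng(42)
        p0 = 0.0275
        cov = rng.integers(20, 40, size=5000)
        sites = [
            make_site(pos=i + 1, n_meth=int(m), n_unmeth=int(c - m))
            for i, (c, m) in enumerate(zip(cov, rng.binomial(cov, p0)))
        ]
        bg = estimate_background(sites)
        total = bg.total
        assert total >= 1e5
        se = np.sqrt(p0 * (1 - p0) / total)
        assert abs(bg.rate - p0) <= 3 * se


class TestCallSite:
    def test_no_excess_gives_p_one(self):
        assert call_site(make_site(n_meth=0, n_unmeth=10), Background(100, 9900)) == 1.0

    def test_matches_brute_force_hypergeometric(self):
        bg = Background(5, 95)
        p = call_site(make_site(n_meth=3, n_unmeth=7), bg, exclude_self=False)
        assert p == pytest.approx(fisher_one_sided_oracle(3, 7, 5, 95), abs=1e-12)

    def test_matches_scipy_fisher_one_sided(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            a, b, c, d = rng.integers(0, 30, size=4)
            if a + b == 0 or c + d == 0:
                continue
            ours = call_site(
                make_site(n_meth=int(a), n_unmeth=int(b) + 1),
                Background(int(c), int(d)),
                exclude_self=False,
            )
            ref = stats.fisher_exact(
                [[int(a), int(b) + 1], [int(c), int(d)]], alternative="greater"
            )[1]
            assert ours == pytest.approx(ref, rel=1e-9)

    def test_converges_to_binomial_tail_for_huge_background(self):
        # with the background pool -> infinity at fixed rate, Fisher's exact
        # tends to the one-sided binomial tail
        p0 = 0.0275
        big = 10_000_000
        bg = Background(int(big * p0), big - int(big * p0))
        site = make_site(n_meth=4, n_unmeth=26)
        fisher_p = call_site(site, bg, exclude_self=False)
        binom_p = stats.binom.sf(3, 30, bg.rate)
        assert fisher_p == pytest.approx(binom_p, rel=5e-3)

    def test_monotone_in_n_meth_at_fixed_coverage(self):
        bg = Background(300, 9700)
        pvals = [
            call_site(make_site(n_meth=k, n_unmeth=20 - k), bg, exclude_self=False)
            for k in range(21)
        ]
        assert all(p1 >= p2 for p1, p2 in zip(pvals, pvals[1:]))

    def test_self_exclusion_removes_site_counts_from_pool(self):
        site = make_site(n_meth=10, n_unmeth=10)
        pool = Background(10 + 5, 10 + 995)  # pool that includes the site
        p_excl = call_site(site, pool, exclude_self=True)
        p_manual = call_site(site, Background(5, 995), exclude_self=False)
        assert p_excl == pytest.approx(p_manual, abs=1e-15)


class TestBHAdjust:
    def test_step_up_arithmetic(self):
        assert bh_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_single_value_unchanged(self):
        assert bh_adjust([0.2]) == pytest.approx([0.2])

    def test_matches_definitional_oracle_on_random_vectors(self):
        def oracle(p):
            # textbook step-up: q_(i) = min_{j>=i} min(1, p_(j) * n / j)
            n = len(p)
            order = np.argsort(p)
            q = np.empty(n)
            running = 1.0
            for rank in range(n - 1, -1, -1):
                running = min(running, p[order[rank]] * n / (rank + 1))
                q[order[rank]] = min(1.0, running)
            return q

        rng = np.random.default_rng(7)
        for _ in range(200):
            p = rng.uniform(1e-8, 1, size=rng.integers(1, 40))
            assert bh_adjust(p) == pytest.approx(oracle(p), abs=1e-12)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(1e-9, 1.0), min_size=1, max_size=30), st.randoms())
    def test_invariant_under_permutation(self, pvals, rnd):
        perm = list(range(len(pvals)))
        rnd.shuffle(perm)
        base = bh_adjust(pvals)
        shuffled = bh_adjust([pvals[i] for i in perm])
        assert np.allclose([shuffled[perm.index(i)] for i in range(len(pvals))], base)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValidationError):
            bh_adjust([0.0, 0.5])
        with pytest.raises(ValidationError):
            bh_adjust([1.5])


class TestCombineReplicates:
    def _res(self, fdr, called=None, n_meth=3, n_unmeth=17, pos=100):
        site = make_site(pos=pos, n_meth=n_meth, n_unmeth=n_unmeth)
        return CallResult(
            site=site,
            mratio=mratio(n_meth, n_unmeth),
            pvalue=fdr / 2,
            fdr=fdr,
            called=(fdr < 0.05) if called is None else called,
        )

    def test_called_requires_significance_in_every_replicate(self):
        reps = [[self._res(0.01)], [self._res(0.01)], [self._res(0.2)]]
        (combined,) = combine_replicates(reps)
        assert not combined.called

    def test_site_absent_from_one_replicate_dropped(self):
        reps = [[self._res(0.5)], [self._res(0.5)], []]
        assert combine_replicates(reps) == []

    def test_counts_summed_and_mratio_recomputed(self):
        reps = [
            [self._res(0.9, n_meth=3, n_unmeth=7)],
            [self._res(0.9, n_meth=2, n_unmeth=8)],
            [self._res(0.9, n_meth=5, n_unmeth=5)],
        ]
        (combined,) = combine_replicates(reps, min_coverage=9)
        assert (combined.site.n_meth, combined.site.n_unmeth) == (10, 20)
        assert combined.mratio == pytest.approx(1 / 3)

    def test_uncalled_site_needs_coverage_everywhere(self):
        low = self._res(0.5, n_meth=1, n_unmeth=5)  # coverage 6 <= 10
        ok = self._res(0.5)
        assert combine_replicates([[ok], [ok], [low]], min_coverage=10) == []

    def test_single_replicate_is_identity(self):
        rep = [self._res(0.01), self._res(0.5, pos=200)]
        assert combine_replicates([rep]) == rep


class TestCallSitesPipeline:
    def test_type_one_error_controlled_on_null_data(self):
        rng = np.random.default_rng(11)
        p0 = 0.0275
        cov = rng.negative_binomial(5, 5 / 35, size=4000)
        sites = [
            make_site(pos=i + 1, n_meth=int(m), n_unmeth=int(c - m))
            for i, (c, m) in enumerate(zip(cov, rng.binomial(cov, p0)))
            if c > 0
        ]
        results = call_sites(sites)
        frac = np.mean([r.called for r in results]) if results else 0.0
        mc_se = np.sqrt(0.05 * 0.95 / max(1, len(results)))
        assert frac <= 0.05 + 3 * mc_se

    def test_coverage_filter_applied(self):
        sites = [make_site(pos=1, n_meth=1, n_unmeth=5), make_site(pos=2, n_meth=1, n_unmeth=20)]
        results = call_sites(sites, min_coverage=10)
        assert [r.site.pos for r in results] == [2]

    def test_truly_methylated_sites_recovered(self):
        rng = np.random.default_rng(3)
        null = [
            make_site(pos=i + 1, n_meth=int(m), n_unmeth=int(30 - m))
            for i, m in enumerate(rng.binomial(30, 0.0275, size=2000))
        ]
        hot = [
            make_site(pos=10_000 + i, n_meth=int(m), n_unmeth=int(30 - m))
            for i, m in enumerate(rng.binomial(30, 0.8, size=50))
        ]
        results = call_sites(null + hot)
        called_hot = sum(r.called for r in results if r.site.pos >= 10_000)
        called_null = sum(r.called for r in results if r.site.pos < 10_000)
        assert called_hot >= 45
        assert called_null <= 20
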