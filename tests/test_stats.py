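import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import kruskal as scipy_kruskal
from scipy.stats import norm, spearmanr

from torsobaro.errors import UndefinedIndexError, ValidationError
from torsobaro.indices import IndexSet
from torsobaro.stats import (
    SubjectRecord,
    cluster_by_cobb,
    dunn_posthoc,
    effect_size,
    holm_adjust,
    kruskal_wallis,
    spearman,
    validity_analysis,
)


def random_groups(rng, with_ties=True):
    k = int(rng.integers(2, 5))
    sizes = rng.integers(2, 12, size=k)
    pool = np.arange(8) if with_ties else None
    groups = []
    for n in sizes:
        if with_ties and rng.random() < 0.7:
            groups.append(rng.choice(pool, size=n).astype(float))
        else:
            groups.append(rng.normal(0, 1, size=n))
    return groups


class TestClusterByCobb:
    @pytest.mark.parametrize(
        "cobb,severity",
        [
            (7.1, "none"),
            (9.99, "none"),
            (10.0, "mild"),
            (14.0, "mild"),
            (19.99, "mild"),
            (20.0, "moderate"),
            (26.2, "moderate"),
            (39.99, "moderate"),
        ],
    )
    def test_boundaries(self, cobb, severity):
        assert cluster_by_cobb(cobb) == severity

    @pytest.mark.parametrize("cobb", [40.0, 45.0, -1.0])
    def test_out_of_range_rejected(self, cobb):
        with pytest.raises(ValidationError):
            cluster_by_cobb(cobb)


class TestKruskalWallis:
    def test_identical_groups_have_zero_h(self):
        h, p = kruskal_wallis([[1, 2, 3], [1, 2, 3], [1, 2, 3]])
        assert h == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_hand_evaluated_instance(self):
        # mean ranks 1.5 / 3.5 / 5.5 of N=6 -> H = 4.571...
        h, p = kruskal_wallis([[1, 2], [3, 4], [5, 6]])
        assert h == pytest.approx(12 / 42 * (2 * 4 + 0 + 2 * 4), abs=1e-12)
        assert h == pytest.approx(4.571428571, abs=1e-6)
        assert p == pytest.approx(0.1017, abs=1e-3)

    def test_all_tied_values(self):
        h, p = kruskal_wallis([[5, 5], [5, 5, 5]])
        assert (h, p) == (0.0, 1.0)

    def test_matches_scipy_on_random_data(self, rng):
        for _ in range(300):
            groups = random_groups(rng)
            try:
                h_ref, p_ref = scipy_kruskal(*groups)
            except ValueError:  # scipy rejects all-identical data
                continue
            h, p = kruskal_wallis(groups)
            assert abs(h - h_ref) < 1e-10
            assert abs(p - p_ref) < 1e-10


def dunn_reference(groups):
    """Independent Dunn implementation: explicit sort-based midranks."""
    labeled = [(v, g) for g, vals in enumerate(groups) for v in vals]
    labeled.sort(key=lambda t: t[0])
    values = [t[0] for t in labeled]
    ranks = [0.0] * len(values)
    k = 0
    while k < len(values):
        m = k
        while m + 1 < len(values) and values[m + 1] == values[k]:
            m += 1
        midrank = (k + m) / 2.0 + 1.0
        for q in range(k, m + 1):
            ranks[q] = midrank
        k = m + 1
    n = len(values)
    from collections import Counter

    tie = sum(c**3 - c for c in Counter(values).values())
    mean_rank = [0.0] * len(groups)
    counts = [0] * len(groups)
    for (v, g), r in zip(labeled, ranks):
        mean_rank[g] += r
        counts[g] += 1
    mean_rank = [s / c for s, c in zip(mean_rank, counts)]
    out = []
    for a in range(len(groups)):
        for b in range(a + 1, len(groups)):
            var = (n * (n + 1) / 12 - tie / (12 * (n - 1))) * (
                1 / counts[a] + 1 / counts[b]
            )
            z = (mean_rank[a] - mean_rank[b]) / math.sqrt(var) if var > 0 else 0.0
            out.append(((a, b), z, 2 * norm.sf(abs(z))))
    return out


class TestDunn:
    def test_identical_groups_give_zero_z(self):
        for (_, z, p) in dunn_posthoc([[1, 2, 3], [1, 2, 3]]):
            assert z == pytest.approx(0.0, abs=1e-12)
            assert p == pytest.approx(1.0)

    def test_hand_evaluated_pair(self):
        [( _, z, p)] = dunn_posthoc([[1, 2], [3, 4]])
        assert z == pytest.approx(-2 / math.sqrt(20 / 12), abs=1e-9)
        assert z == pytest.approx(-1.549, abs=1e-3)
        assert p == pytest.approx(0.121, abs=1e-3)

    def test_matches_independent_implementation(self, rng):
        for _ in range(300):
            groups = random_groups(rng)
            ref = dunn_reference(groups)
            got = dunn_posthoc(groups)
            for (pair_r, z_r, p_r), (pair_g, z_g, p_g) in zip(ref, got):
                assert pair_r == pair_g
                assert abs(z_r - z_g) < 1e-10
                assert abs(p_r - p_g) < 1e-10

    def test_empty_group_rejected(self):
        with pytest.raises(ValidationError):
            dunn_posthoc([[1, 2], []])


class TestHolm:
    def test_single_p_unchanged(self):
        assert holm_adjust([0.042]) == pytest.approx([0.042])

    def test_step_down_by_hand(self):
        np.testing.assert_allclose(
            holm_adjust([0.01, 0.02, 0.03]), [0.03, 0.04, 0.04], atol=1e-12
        )

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        for _ in range(300):
            p = rng.uniform(0, 1, size=int(rng.integers(1, 10)))
            ref = multipletests(p, method="holm")[1]
            np.testing.assert_allclose(holm_adjust(p), ref, atol=1e-10)

    @given(
        st.lists(st.floats(min_value=0, max_value=1, allow_nan=False), min_size=1, max_size=12)
    )
    def test_dominance_and_cap(self, pvals):
        adj = holm_adjust(pvals)
        assert (adj >= np.asarray(pvals) - 1e-15).all()
        assert (adj <= 1.0).all()

    @given(
        st.lists(st.floats(min_value=0, max_value=1, allow_nan=False), min_size=2, max_size=8),
        st.randoms(use_true_random=False),
    )
    def test_permutation_equivariance(self, pvals, rnd):
        perm = list(range(len(pvals)))
        rnd.shuffle(perm)
        direct = holm_adjust([pvals[k] for k in perm])
        via = holm_adjust(pvals)
        np.testing.assert_allclose(direct, [via[k] for k in perm], atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            holm_adjust([0.5, 1.2])


class TestEffectSize:
    def test_zero_z(self):
        es, cat = effect_size(0.0, 87)
        assert es == 0.0 and cat == "negligible"

    def test_band_edges(self):
        es, cat = effect_size(3.0, 36)
        assert es == pytest.approx(0.5) and cat == "large"
        es, cat = effect_size(2.2, 87)
        assert es == pytest.approx(0.2359, abs=1e-4) and cat == "small"

    def test_halves_when_n_quadruples(self):
        es1, _ = effect_size(2.0, 25)
        es2, _ = effect_size(2.0, 100)
        assert es2 == pytest.approx(es1 / 2)

    def test_negative_z_categorized_by_magnitude(self):
        es, cat = effect_size(-4.0, 64)
        assert es == -0.5 and cat == "large"


class TestSpearman:
    def test_perfect_monotone(self):
        rho, p, cat = spearman([1, 2, 3, 4, 5], [10, 20, 40, 80, 160])
        assert rho == pytest.approx(1.0, abs=1e-9)
        assert p == pytest.approx(0.0, abs=1e-10)
        assert cat == "strong"

    def test_hand_evaluated_rank_formula(self):
        rho, _, cat = spearman([1, 2, 3, 4], [2, 1, 4, 3])
        assert rho == pytest.approx(0.6, abs=1e-12)
        assert cat == "good"

    def test_matches_scipy_with_ties(self, rng):
        for _ in range(300):
            n = int(rng.integers(4, 25))
            x = rng.choice(np.arange(6), size=n).astype(float)
            y = rng.choice(np.arange(6), size=n).astype(float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            ref = spearmanr(x, y)
            rho, p, _ = spearman(x, y)
            assert abs(rho - ref.statistic) < 1e-10
            if abs(rho) < 1.0:
                assert abs(p - ref.pvalue) < 1e-10

    def test_constant_vector_undefined(self):
        with pytest.raises(UndefinedIndexError):
            spearman([1, 1, 1, 1], [1, 2, 3, 4])


def make_records(rng, shift_by_group=(0.0, 0.0, 0.0), n=(13, 49, 25)):
    """Synthetic SubjectRecords with controllable group separation in WAA."""
    cobb_by_group = {"none": 7.0, "mild": 14.0, "moderate": 26.0}
    records = []
    for g, (sev, size) in enumerate(zip(("none", "mild", "moderate"), n)):
        for k in range(size):
            idx = IndexSet(
                tba=float(rng.normal(5, 1)),
                sii=float(rng.normal(100, 10)),
                tai=float(rng.normal(20, 3)),
                saa=float(abs(rng.normal(0, 2))),
                waa=float(abs(rng.normal(0, 1)) + shift_by_group[g]),
                paa=float(abs(rng.normal(0, 1))),
            )
            records.append(
                SubjectRecord(
                    id=f"{sev}-{k}",
                    index_set=idx,
                    cobb_angle_deg=cobb_by_group[sev] + float(rng.uniform(-1, 1)),
                )
            )
    return records


class TestValidityAnalysis:
    def test_gatekeeping_and_pairwise_family(self, rng):
        records = make_records(rng, shift_by_group=(0.0, 0.0, 8.0))
        comps, corrs = validity_analysis(records)
        by_name = {c.index: c for c in comps}
        assert by_name["waa"].p_adjusted < 0.05
        assert len(by_name["waa"].pairwise) == 3
        for c in comps:
            if c.p_adjusted >= 0.05:
                assert c.pairwise == []
            assert c.p_adjusted >= c.p_raw - 1e-15
        assert len(corrs) == 6

    def test_invariant_to_subject_order(self, rng):
        records = make_records(rng, shift_by_group=(0.0, 2.0, 8.0))
        comps1, corrs1 = validity_analysis(records)
        rng.shuffle(records)
        comps2, corrs2 = validity_analysis(records)
        for a, b in zip(comps1, comps2):
            assert a.h_statistic == pytest.approx(b.h_statistic, abs=1e-12)
            assert a.p_adjusted == pytest.approx(b.p_adjusted, abs=1e-12)
            assert a.pairwise == b.pairwise
        for a, b in zip(corrs1, corrs2):
            assert a.rho == pytest.approx(b.rho, abs=1e-12)

    def test_single_group_rejected(self, rng):
        records = [r for r in make_records(rng) if r.severity == "mild"]
        with pytest.raises(ValidationError):
            validity_analysis(records)

    def test_inconsistent_severity_rejected(self):
        with pytest.raises(ValidationError, match="inconsistent"):
            SubjectRecord(id="x", index_set=IndexSet(), cobb_angle_deg=25.0, severity="mild")
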