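"""MIC statistic: analytic anchors, oracle equivalence of the dynamic
program, monotone invariance, permutation p-values and edge building."""

import numpy as np
import pandas as pd
import pytest

from oracles import exhaustive_best_x_partition, reference_mic
from protistnet import (
    MicParams,
    MicResult,
    OtuTable,
    build_edge_set,
    compute_mic,
    edge_sign,
    mic_statistic,
    permutation_pvalue,
)
from protistnet.mic import _equipartition, _mic_one_orientation


class TestAnchors:
    def test_noiseless_line_is_one(self):
        x = np.arange(1, 51, dtype=float)
        assert mic_statistic(x, x) == pytest.approx(1.0, abs=1e-12)
        assert mic_statistic(x, -3 * x + 7) == pytest.approx(1.0, abs=1e-12)

    def test_constant_vector_is_zero(self):
        x = np.arange(20, dtype=float)
        assert mic_statistic(x, np.full(20, 3.0)) == 0.0

    def test_bounds(self, rng):
        for _ in range(20):
            m = mic_statistic(rng.normal(size=20), rng.normal(size=20))
            assert 0.0 <= m <= 1.0

    def test_short_input_rejected(self):
        with pytest.raises(ValueError, match="n >= 8"):
            mic_statistic(np.arange(7), np.arange(7))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            mic_statistic(np.arange(10), np.arange(11))


class TestInvariance:
    def test_symmetry(self, rng):
        for _ in range(25):
            x, y = rng.normal(size=24), rng.normal(size=24)
            assert mic_statistic(x, y) == pytest.approx(
                mic_statistic(y, x), abs=1e-12)

    def test_monotone_transform_invariance(self, rng):
        """MIC depends on the data only through ranks and ties."""
        for _ in range(100):
            x, y = rng.normal(size=28), rng.normal(size=28)
            base = mic_statistic(x, y)
            assert mic_statistic(np.exp(x), y) == pytest.approx(base, abs=1e-12)
            assert mic_statistic(x, y ** 3) == pytest.approx(base, abs=1e-12)
            assert mic_statistic(2 * x + 1, -y) == pytest.approx(
                mic_statistic(x, -y), abs=1e-12)


class TestDynamicProgramOracle:
    def test_dp_equals_exhaustive_partition_search(self, rng):
        """Per shape/orientation the clump DP attains the exhaustive optimum
        over all free-axis partitions (small n, budget <= 6)."""
        worst = 0.0
        for trial in range(120):
            n = int(rng.integers(8, 13))
            x, y = rng.normal(size=n), rng.normal(size=n)
            if trial % 3 == 0:
                y = x + rng.normal(scale=0.5, size=n)
            if trial % 5 == 0:
                x = np.round(x)  # tie-heavy
            budget = int(rng.integers(4, 7))
            dp = max(float(_mic_one_orientation(x, y, budget, 15)), 0.0)
            # same y-equipartition, brute force over x cuts, all shapes
            best_ref = 0.0
            oy = np.argsort(y, kind="mergesort")
            for ky in range(2, budget // 2 + 1):
                max_kx = budget // ky
                if max_kx < 2:
                    break
                rows_sorted = np.asarray(_equipartition(y[oy], ky))
                rows = np.empty(n, dtype=int)
                rows[oy] = rows_sorted
                mi = exhaustive_best_x_partition(x, rows, ky, max_kx)
                best_ref = max(best_ref, mi / np.log2(min(max_kx, ky)))
            # the DP maximizes per (kx, ky); compare at the orientation level
            worst = max(worst, abs(dp - best_ref))
        assert worst < 1e-9


class TestReferenceImplementation:
    def test_agreement_at_study_sample_count(self, rng):
        """Implementation vs an independently-coded brute-force reference
        (exhaustive free-axis search instead of clumps + DP) at n = 28."""
        params = MicParams()
        budget = params.budget(28)
        for trial in range(60):
            x, y = rng.normal(size=28), rng.normal(size=28)
            if trial % 4 == 1:
                y = x + rng.normal(scale=0.5, size=28)
            if trial % 4 == 2:
                y = np.sin(3 * x) + rng.normal(scale=0.3, size=28)
            if trial % 4 == 3:
                x = np.round(x * 2)
            assert mic_statistic(x, y, params) == pytest.approx(
                reference_mic(x, y, budget), abs=0.02)


class TestPermutationPvalue:
    def test_perfect_dependence_gives_minimal_p(self):
        x = np.arange(1, 51, dtype=float)
        p = permutation_pvalue(x, x)
        assert p == pytest.approx(1 / 1001)

    def test_p_in_unit_interval(self, rng):
        x, y = rng.normal(size=20), rng.normal(size=20)
        p = permutation_pvalue(x, y, MicParams(n_permutations=99))
        assert 0 < p <= 1

    def test_zero_permutations_rejected(self, rng):
        with pytest.raises(ValueError):
            permutation_pvalue(rng.normal(size=10), rng.normal(size=10),
                               MicParams(n_permutations=0))

    def test_reproducible_for_fixed_seed(self, rng):
        x, y = rng.normal(size=20), rng.normal(size=20)
        params = MicParams(n_permutations=200, seed=7)
        assert permutation_pvalue(x, y, params) == permutation_pvalue(x, y, params)


class TestEdgeSign:
    @pytest.mark.parametrize(
        "mic,r,expected",
        [
            (0.9, 0.95, "positive"),   # nonlinearity ~ -0.0025
            (0.9, 0.1, "negative"),    # nonlinearity 0.89
            (0.75, 0.5, "positive"),   # exactly 0.5 -> positive (strict >)
        ],
    )
    def test_rule(self, mic, r, expected):
        res = MicResult("a", "b", mic=mic, pearson_r=r,
                        nonlinearity=mic - r ** 2)
        assert edge_sign(res) == expected

    def test_compute_mic_carries_nonlinearity(self, rng):
        x = np.arange(28, dtype=float)
        res = compute_mic(x, x)
        assert res.nonlinearity == pytest.approx(res.mic - res.pearson_r ** 2)
        assert res.sign == "positive"


@pytest.fixture(scope="module")
def block_table():
    """5 co-varying OTUs (shared latent factor) + 20 independent ones."""
    rng = np.random.default_rng(99)
    n_samples = 28
    latent = rng.lognormal(0, 1.0, size=n_samples)
    rows = {}
    for i in range(5):
        lam = 200 * latent * rng.lognormal(0, 0.15, size=n_samples)
        rows[f"block{i}"] = rng.poisson(lam)
    for i in range(20):
        rows[f"indep{i}"] = rng.poisson(
            rng.lognormal(np.log(100), 0.8), size=n_samples)
    counts = pd.DataFrame(rows, index=[f"s{j}" for j in range(n_samples)]).T
    return OtuTable(counts=counts)


class TestBuildEdgeSet:
    def test_planted_block_recovered(self, block_table):
        params = MicParams(n_permutations=500, seed=11)
        edges = build_edge_set(block_table, params)
        within = [e for e in edges if e.otu_a.startswith("block")
                  and e.otu_b.startswith("block")]
        assert len(within) >= 8  # of the 10 within-block pairs
        # independent OTUs: median significant-edge count is 0
        indep_deg = {f"indep{i}": 0 for i in range(20)}
        for e in edges:
            for node in (e.otu_a, e.otu_b):
                if node in indep_deg:
                    indep_deg[node] += 1
        assert np.median(list(indep_deg.values())) == 0

    def test_threshold_one_returns_all_pairs(self, block_table):
        sub = OtuTable(counts=block_table.counts.iloc[:6])
        edges = build_edge_set(sub, MicParams(n_permutations=30, p_threshold=1.0,
                                              seed=0))
        assert len(edges) == 15  # all 6*5/2 pairs, significant or not

    def test_identical_rows_have_mic_one_minimal_p(self):
        rng = np.random.default_rng(3)
        base = rng.poisson(80, size=28)
        counts = pd.DataFrame(
            {"s%d" % j: [base[j], base[j], rng.poisson(50)] for j in range(28)},
            index=["twin1", "twin2", "other"])
        params = MicParams(n_permutations=200, seed=5)
        edges = build_edge_set(OtuTable(counts=counts), params)
        twin = [e for e in edges if {e.otu_a, e.otu_b} == {"twin1", "twin2"}]
        assert len(twin) == 1
        assert twin[0].mic == pytest.approx(1.0, abs=1e-12)
        assert twin[0].p_value == pytest.approx(1 / 201)

    def test_single_otu_rejected(self):
        counts = pd.DataFrame({"s%d" % j: [j] for j in range(10)}, index=["only"])
        with pytest.raises(ValueError):
            build_edge_set(OtuTable(counts=counts))

    def test_deterministic_under_seed(self, block_table):
        sub = OtuTable(counts=block_table.counts.iloc[:8])
        params = MicParams(n_permutations=100, seed=21)
        e1 = build_edge_set(sub, params)
        e2 = build_edge_set(sub, params)
        assert [(e.otu_a, e.otu_b, e.p_value) for e in e1] == \
               [(e.otu_a, e.otu_b, e.p_value) for e in e2]
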