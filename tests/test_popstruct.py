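"""AMOVA Phi-statistics, diversity, Tajima's D and Fu's F_s."""

from __future__ import annotations

import math
from fractions import Fraction
from itertools import combinations

import numpy as np
import pytest
from scipy.stats import kstest

from phylogeokit.gendist import DistanceMatrix, distance_matrix
from phylogeokit.popstruct import (
    PopulationPartition,
    Undefined,
    amova3,
    diversity,
    ewens_k_pmf,
    fus_fs,
    neutrality,
    pairwise_phist,
    tajimas_d,
)
from phylogeokit.seqdata import Alignment


def make_partition(assignments: dict[str, tuple[str, str]]) -> PopulationPartition:
    """assignments: sample -> (site, basin)."""
    return PopulationPartition(
        site_of={s: v[0] for s, v in assignments.items()},
        basin_of={s: v[1] for s, v in assignments.items()},
    )


# ---------------------------------------------------------------------------
# brute-force AMOVA oracle (independent SSD arithmetic)
# ---------------------------------------------------------------------------


def brute_amova3(sq: np.ndarray, basins: list[list[list[int]]]):
    """Nested variance components from first principles (explicit loops)."""

    def ssd(idx: list[int]) -> float:
        total = 0.0
        for i in idx:
            for j in idx:
                total += sq[i, j]
        return total / (2 * len(idx))

    pops = [site for basin in basins for site in basin]
    basin_flat = [[i for site in basin for i in site] for basin in basins]
    everyone = [i for b in basin_flat for i in b]
    N, P, G = len(everyone), len(pops), len(basins)

    ssd_total = ssd(everyone)
    ssd_wp = sum(ssd(site) for site in pops if len(site) > 1)
    ssd_wg = sum(ssd(b) for b in basin_flat if len(b) > 1)
    ssd_ap, ssd_ag = ssd_wg - ssd_wp, ssd_total - ssd_wg

    sigma_c = ssd_wp / (N - P)
    # size coefficients, written out longhand
    sum_sq_over_g = 0.0
    for basin, flat in zip(basins, basin_flat):
        for site in basin:
            sum_sq_over_g += len(site) ** 2 / len(flat)
    sum_sq_over_n = sum(len(s) ** 2 for s in pops) / N
    sum_g_sq_over_n = sum(len(b) ** 2 for b in basin_flat) / N
    n1 = (N - sum_sq_over_g) / (P - G)
    n2 = (sum_sq_over_g - sum_sq_over_n) / (G - 1)
    n3 = (N - sum_g_sq_over_n) / (G - 1)
    sigma_b = (ssd_ap / (P - G) - sigma_c) / n1
    sigma_a = (ssd_ag / (G - 1) - sigma_c - n2 * sigma_b) / n3
    return sigma_a, sigma_b, sigma_c


class TestPairwisePhist:
    def _matrix(self, vals, labels=None):
        labels = labels or [f"s{i}" for i in range(len(vals))]
        return DistanceMatrix(labels, np.asarray(vals, dtype=float))

    def test_complete_differentiation(self):
        # within-basin distances 0, between 1 -> Phi_ST = 1
        vals = np.ones((4, 4))
        vals[np.ix_([0, 1], [0, 1])] = 0.0
        vals[np.ix_([2, 3], [2, 3])] = 0.0
        dm = self._matrix(vals)
        part = make_partition(
            {"s0": ("x", "A"), "s1": ("x", "A"), "s2": ("y", "B"), "s3": ("y", "B")}
        )
        phi, p = pairwise_phist(dm, part, "A", "B", nperm=99, seed=0)
        assert phi == pytest.approx(1.0)
        # only the original 2|2 split (prob 1/3 under permutation) ties Phi=1
        assert p == pytest.approx(1 / 3, abs=0.15)

    def test_identical_groups_phi_zero(self):
        # all pairwise distances equal: no between-group excess
        vals = np.full((6, 6), 2.0)
        np.fill_diagonal(vals, 0.0)
        dm = self._matrix(vals)
        part = make_partition(
            {f"s{i}": ("x" if i < 3 else "y", "A" if i < 3 else "B") for i in range(6)}
        )
        phi, _ = pairwise_phist(dm, part, "A", "B", nperm=19, seed=0)
        assert phi == pytest.approx(0.0, abs=1e-12)

    def test_small_basin_undefined(self):
        vals = np.full((3, 3), 1.0)
        np.fill_diagonal(vals, 0.0)
        dm = self._matrix(vals)
        part = make_partition(
            {"s0": ("x", "A"), "s1": ("y", "B"), "s2": ("y", "B")}
        )
        phi, p = pairwise_phist(dm, part, "A", "B", nperm=9, seed=0)
        assert isinstance(phi, Undefined) and "<2" in phi.reason

    def test_six_sequence_hand_example(self):
        """Two basins of three; components recomputed longhand in the test."""
        rng = np.random.default_rng(5)
        vals = rng.random((6, 6))
        vals = (vals + vals.T) / 2
        np.fill_diagonal(vals, 0.0)
        dm = self._matrix(vals)
        part = make_partition(
            {f"s{i}": ("x" if i < 3 else "y", "A" if i < 3 else "B") for i in range(6)}
        )
        phi, _ = pairwise_phist(dm, part, "A", "B", nperm=9, seed=0)
        # longhand: SSD(T), SSD within each basin, equal sizes n=3
        sq = vals
        idx_a, idx_b = [0, 1, 2], [3, 4, 5]
        ssd_t = sq.sum() / (2 * 6)
        ssd_w = sum(sq[np.ix_(g, g)].sum() / (2 * 3) for g in (idx_a, idx_b))
        sigma_w = ssd_w / (6 - 2)
        n_c = (6 - (9 + 9) / 6) / 1
        sigma_a = ((ssd_t - ssd_w) / 1 - sigma_w) / n_c
        assert phi == pytest.approx(sigma_a / (sigma_a + sigma_w), abs=1e-12)

    def test_null_p_values_roughly_uniform(self):
        """Random labels on a panmictic pool: p should be ~ Uniform(0,1]."""
        rng = np.random.default_rng(21)
        pvals = []
        for rep in range(200):
            vals = rng.random((10, 10))
            vals = (vals + vals.T) / 2
            np.fill_diagonal(vals, 0.0)
            dm = self._matrix(vals)
            part = make_partition(
                {f"s{i}": ("x" if i < 5 else "y", "A" if i < 5 else "B") for i in range(10)}
            )
            _, p = pairwise_phist(dm, part, "A", "B", nperm=99, seed=rep)
            pvals.append(p)
        stat = kstest(pvals, "uniform").statistic
        assert stat < 0.12  # 1% KS critical value for n=200 is ~0.115


class TestAmova3:
    def test_identical_sequences_undefined(self):
        aln = Alignment([f"s{i}" for i in range(6)], ["ACGT"] * 6)
        dm = distance_matrix(aln)
        part = make_partition(
            {f"s{i}": (f"site{i % 2}", "A" if i < 3 else "B") for i in range(6)}
        )
        res = amova3(dm, part, nperm=9, seed=0)
        assert isinstance(res.phi_st, Undefined)

    def test_structure_concentrates_among_basins(self):
        """Deep split, shallow within-basin coalescence: between >> within."""
        from phylogeokit import synthgen

        scen = synthgen.two_basin_scenario(split_myr=4.0, n_per_basin=6, with_ridge=False)
        config = synthgen.SimulationConfig(seed=2, within_basin_Ne_scaled=0.02)
        rng = np.random.default_rng(2)
        tree = synthgen.simulate_genealogy(scen, config, rng)
        aln = synthgen.simulate_sequences(tree, config, rng)
        dm = distance_matrix(aln)
        part = PopulationPartition.from_table(scen.sample_table())
        res = amova3(dm, part, nperm=99, seed=1)
        assert res.pct_a > 90.0
        # one site per basin: the site-level Phi_CT permutation has no power
        # (every reassignment reproduces the same grouping), so test Phi_ST
        assert res.p_st <= 0.05
        assert res.pct_a + res.pct_b + res.pct_c == pytest.approx(100.0, abs=1e-6)
        # Phi_ST = 1 - within/total
        total = res.sigma_a + res.sigma_b + res.sigma_c
        assert res.phi_st == pytest.approx(1.0 - res.sigma_c / total, abs=1e-12)

    def test_matches_brute_force_components(self):
        rng = np.random.default_rng(9)
        n = 13
        vals = rng.random((n, n))
        vals = (vals + vals.T) / 2
        np.fill_diagonal(vals, 0.0)
        labels = [f"s{i}" for i in range(n)]
        dm = DistanceMatrix(labels, vals)
        layout = {  # 3 basins, uneven sites
            "s0": ("p1", "A"), "s1": ("p1", "A"), "s2": ("p2", "A"),
            "s3": ("p2", "A"), "s4": ("p3", "B"), "s5": ("p3", "B"),
            "s6": ("p3", "B"), "s7": ("p4", "B"), "s8": ("p5", "C"),
            "s9": ("p5", "C"), "s10": ("p6", "C"), "s11": ("p6", "C"),
            "s12": ("p6", "C"),
        }
        res = amova3(dm, make_partition(layout), nperm=9, seed=0)
        basins = [
            [[0, 1], [2, 3]],
            [[4, 5, 6], [7]],
            [[8, 9], [10, 11, 12]],
        ]
        a, b, c = brute_amova3(vals, basins)
        assert res.sigma_a == pytest.approx(a, abs=1e-12)
        assert res.sigma_b == pytest.approx(b, abs=1e-12)
        assert res.sigma_c == pytest.approx(c, abs=1e-12)


class TestDiversity:
    def test_identical_pair(self):
        stats = diversity(Alignment(["a", "b"], ["ACGT", "ACGT"]))
        assert stats.pi == 0.0 and stats.S == 0

    def test_hand_counts(self):
        # 2 transitions (A<->G, C<->T) and 1 transversion (A<->C)
        stats = diversity(Alignment(["a", "b"], ["AAACAA", "GAATAC"]))
        assert stats.pi == 3.0
        assert (stats.n_s, stats.n_v, stats.n_d) == (2, 1, 3)

    def test_pi_equals_brute_force_pair_loop(self, rng):
        seqs = ["".join(rng.choice(list("ACGT"), size=40)) for _ in range(6)]
        aln = Alignment([f"s{i}" for i in range(6)], seqs)
        stats = diversity(aln)
        diffs = [
            sum(1 for x, y in zip(a, b) if x != y)
            for a, b in combinations(seqs, 2)
        ]
        assert stats.pi == pytest.approx(float(np.mean(diffs)))

    def test_single_sequence_undefined(self):
        assert isinstance(diversity(Alignment(["a"], ["ACGT"])), Undefined)

    def test_nd_decomposition(self, rng):
        seqs = ["".join(rng.choice(list("ACGT"), size=50)) for _ in range(8)]
        stats = diversity(Alignment([f"s{i}" for i in range(8)], seqs))
        assert stats.n_d == stats.n_s + stats.n_v


class TestTajimasD:
    def test_zero_numerator(self):
        n, S = 10, 5
        a1 = sum(1 / i for i in range(1, n))
        assert tajimas_d(n, S, S / a1) == pytest.approx(0.0, abs=1e-12)

    def test_formula_oracle(self):
        """n=4, S=3, pi=1.5 against an in-test evaluation of the constants."""
        n, S, pi = 4, 3, 1.5
        a1 = 1 + 1 / 2 + 1 / 3
        a2 = 1 + 1 / 4 + 1 / 9
        b1 = (n + 1) / (3 * (n - 1))
        b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
        c1 = b1 - 1 / a1
        c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
        e1, e2 = c1 / a1, c2 / (a1**2 + a2)
        expect = (pi - S / a1) / math.sqrt(e1 * S + e2 * S * (S - 1))
        assert tajimas_d(n, S, pi) == pytest.approx(expect, abs=1e-9)

    def test_no_segregating_sites_undefined(self):
        assert isinstance(tajimas_d(10, 0, 0.0), Undefined)

    def test_small_sample_undefined(self):
        assert isinstance(tajimas_d(3, 2, 1.0), Undefined)


# ---------------------------------------------------------------------------
# Ewens / Fu's F_s, with an exact-partition oracle
# ---------------------------------------------------------------------------


def integer_partitions(n: int, max_part: int | None = None):
    if n == 0:
        yield ()
        return
    if max_part is None:
        max_part = n
    for first in range(min(n, max_part), 0, -1):
        for rest in integer_partitions(n - first, first):
            yield (first,) + rest


def ewens_k_exact(n: int, theta: Fraction) -> dict[int, Fraction]:
    """P(K = k) by exact summation of the Ewens sampling formula over
    partition types: P(a) = n! / prod(j^a_j a_j!) * theta^k / theta^(n)."""
    rising = Fraction(1)
    for i in range(n):
        rising *= theta + i
    out: dict[int, Fraction] = {}
    for part in integer_partitions(n):
        k = len(part)
        mult: dict[int, int] = {}
        for block in part:
            mult[block] = mult.get(block, 0) + 1
        weight = Fraction(math.factorial(n))
        for j, a_j in mult.items():
            weight /= Fraction(j) ** a_j * math.factorial(a_j)
        out[k] = out.get(k, Fraction(0)) + weight * theta**k / rising
    return out


class TestEwensAndFs:
    @pytest.mark.parametrize("n", [2, 5, 8, 15, 30])
    def test_pmf_sums_to_one(self, n):
        pmf = ewens_k_pmf(n, theta=2.37)
        assert pmf.sum() == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("n,theta", [(5, Fraction(1)), (6, Fraction(3, 2)), (8, Fraction(5))])
    def test_pmf_matches_exact_partition_enumeration(self, n, theta):
        exact = ewens_k_exact(n, theta)
        pmf = ewens_k_pmf(n, float(theta))
        for k in range(1, n + 1):
            assert pmf[k - 1] == pytest.approx(float(exact.get(k, Fraction(0))), abs=1e-12)

    def test_fs_zero_at_half(self):
        # n=2, k=2: S' = theta/(1+theta); theta=1 -> S' = 1/2 -> F_s = 0
        assert fus_fs(2, 2, 1.0) == pytest.approx(0.0, abs=1e-12)

    def test_fs_against_exact_enumeration(self):
        n, k_obs, theta = 5, 3, Fraction(1)
        exact = ewens_k_exact(n, theta)
        s_prime = sum(exact.get(k, Fraction(0)) for k in range(k_obs, n + 1))
        expect = math.log(float(s_prime) / float(1 - s_prime))
        assert fus_fs(n, k_obs, float(theta)) == pytest.approx(expect, abs=1e-10)

    def test_undefined_inputs(self):
        assert isinstance(fus_fs(1, 1, 1.0), Undefined)
        assert isinstance(fus_fs(5, 6, 1.0), Undefined)
        assert isinstance(fus_fs(5, 3, 0.0), Undefined)

    def test_neutrality_wrapper(self, rng):
        seqs = ["".join(rng.choice(list("ACGT"), size=60)) for _ in range(6)]
        stats = neutrality(Alignment([f"s{i}" for i in range(6)], seqs))
        assert stats.k_obs == 6
        assert isinstance(stats.tajima_D, float)
        assert isinstance(stats.fu_Fs, float)
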