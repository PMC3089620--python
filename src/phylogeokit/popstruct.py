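"""Population structure and diversity from molecular distances.

Implements the distance-based analysis of molecular variance (AMOVA) of
Excoffier, Smouse & Quattro (1992): sums of squared deviations computed
directly from a pairwise distance matrix, variance components from the
expected mean squares with unequal sample sizes, Phi-statistics
(Phi_CT among groups, Phi_SC among populations within groups, Phi_ST
overall), and permutation p-values.  Also: nucleotide diversity (mean
pairwise differences), transition/transversion substitution counts,
Tajima's D and Fu's F_s.

By the Arlequin convention for user-supplied molecular distances, matrix
entries are used directly as squared deviations; pass ``square_entries=True``
to square raw distances instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .gendist import DistanceMatrix, encode
from .seqdata import Alignment

__all__ = [
    "Undefined",
    "PopulationPartition",
    "AmovaResult",
    "DiversityStats",
    "NeutralityStats",
    "pairwise_phist",
    "amova3",
    "diversity",
    "tajimas_d",
    "fus_fs",
    "ewens_k_pmf",
]


@dataclass(frozen=True)
class Undefined:
    """Explicit not-a-value for statistics that cannot be computed."""

    reason: str

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"Undefined({self.reason!r})"


Stat = float | Undefined


@dataclass
class PopulationPartition:
    """Three-level sample assignment: samples within sites within basins."""

    site_of: dict[str, str]
    basin_of: dict[str, str]

    @classmethod
    def from_table(cls, table: pd.DataFrame) -> "PopulationPartition":
        return cls(
            site_of=dict(zip(table["sample_id"], table["site"])),
            basin_of=dict(zip(table["sample_id"], table["basin"])),
        )

    def basins(self) -> list[str]:
        seen: list[str] = []
        for b in self.basin_of.values():
            if b not in seen:
                seen.append(b)
        return seen

    def samples_in_basin(self, basin: str) -> list[str]:
        return [s for s, b in self.basin_of.items() if b == basin]

    def sites_in_basin(self, basin: str) -> list[str]:
        seen: list[str] = []
        for s, b in self.basin_of.items():
            if b == basin and self.site_of[s] not in seen:
                seen.append(self.site_of[s])
        return seen


# ---------------------------------------------------------------------------
# AMOVA machinery
# ---------------------------------------------------------------------------


def _squared(matrix: DistanceMatrix, square_entries: bool) -> np.ndarray:
    return matrix.values**2 if square_entries else matrix.values


def _ssd_within(sq: np.ndarray, groups: Sequence[np.ndarray]) -> float:
    """Sum over groups of (sum of squared deviations within) / group size."""
    total = 0.0
    for idx in groups:
        if len(idx) < 2:
            continue
        sub = sq[np.ix_(idx, idx)]
        total += sub.sum() / (2.0 * len(idx))
    return total


def _two_level_components(
    sq: np.ndarray, pops: Sequence[np.ndarray]
) -> tuple[float, float, float]:
    """One-level AMOVA (populations vs total): returns (sigma_a, sigma_w, phi_st)."""
    n_tot = sum(len(p) for p in pops)
    all_idx = np.concatenate(pops)
    ssd_total = sq[np.ix_(all_idx, all_idx)].sum() / (2.0 * n_tot)
    ssd_within = _ssd_within(sq, pops)
    ssd_among = ssd_total - ssd_within
    df_among = len(pops) - 1
    df_within = n_tot - len(pops)
    sigma_w = ssd_within / df_within if df_within > 0 else float("nan")
    n_c = (n_tot - sum(len(p) ** 2 for p in pops) / n_tot) / df_among
    ms_among = ssd_among / df_among
    sigma_a = (ms_among - sigma_w) / n_c
    total = sigma_a + sigma_w
    phi = sigma_a / total if total != 0 else float("nan")
    return sigma_a, sigma_w, phi


def pairwise_phist(
    matrix: DistanceMatrix,
    partition: PopulationPartition,
    basin_a: str,
    basin_b: str,
    nperm: int = 10_000,
    seed: int = 0,
    square_entries: bool = False,
) -> tuple[Stat, Stat]:
    """Pairwise Phi_ST between two basins with a permutation p-value.

    A two-group AMOVA on the distance submatrix of the two basins.  The
    p-value is the fraction of permutations (sample labels shuffled between
    the two basins, observed arrangement included) with Phi_ST at least as
    large as observed.
    """
    ids_a = partition.samples_in_basin(basin_a)
    ids_b = partition.samples_in_basin(basin_b)
    if len(ids_a) < 2 or len(ids_b) < 2:
        reason = f"basin with <2 samples ({basin_a}: {len(ids_a)}, {basin_b}: {len(ids_b)})"
        return Undefined(reason), Undefined(reason)
    if nperm < 1:
        raise ValueError("nperm must be >= 1")
    sub = matrix.submatrix(ids_a + ids_b)
    sq = _squared(sub, square_entries)
    n_a = len(ids_a)
    n = sub.n
    idx = np.arange(n)
    _, _, phi_obs = _two_level_components(sq, [idx[:n_a], idx[n_a:]])
    if math.isnan(phi_obs):
        reason = "zero total variance"
        return Undefined(reason), Undefined(reason)
    rng = np.random.default_rng(seed)
    hits = 1  # observed arrangement counts
    for _ in range(nperm):
        perm = rng.permutation(n)
        _, _, phi = _two_level_components(sq, [perm[:n_a], perm[n_a:]])
        if not math.isnan(phi) and phi >= phi_obs - 1e-12:
            hits += 1
    return float(phi_obs), hits / (nperm + 1)


@dataclass
class AmovaResult:
    """Three-level AMOVA: variance components, Phi-statistics, p-values."""

    sigma_a: Stat  # among basins
    sigma_b: Stat  # among sites within basins
    sigma_c: Stat  # within sites
    pct_a: Stat
    pct_b: Stat
    pct_c: Stat
    phi_ct: Stat
    phi_sc: Stat
    phi_st: Stat
    p_ct: Stat
    p_sc: Stat
    p_st: Stat
    nperm: int
    seed: int
    df: dict[str, int] = field(default_factory=dict)
    ssd: dict[str, float] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        def v(x: Stat):
            return x if isinstance(x, float) else float("nan")

        return pd.DataFrame(
            {
                "source": [
                    "among_basins",
                    "among_sites_within_basins",
                    "within_sites",
                ],
                "df": [
                    self.df.get("among", float("nan")),
                    self.df.get("among_within", float("nan")),
                    self.df.get("within", float("nan")),
                ],
                "ssd": [
                    self.ssd.get("among", float("nan")),
                    self.ssd.get("among_within", float("nan")),
                    self.ssd.get("within", float("nan")),
                ],
                "variance": [v(self.sigma_a), v(self.sigma_b), v(self.sigma_c)],
                "pct": [v(self.pct_a), v(self.pct_b), v(self.pct_c)],
                "phi": [v(self.phi_ct), v(self.phi_sc), v(self.phi_st)],
                "p": [v(self.p_ct), v(self.p_sc), v(self.p_st)],
            }
        )


def _amova3_components(
    sq: np.ndarray,
    basin_groups: Sequence[Sequence[np.ndarray]],
) -> tuple[float, float, float, dict[str, float], dict[str, int]]:
    """Variance components for a nested design given index groups per basin.

    ``basin_groups[g]`` is the list of per-site index arrays of basin g.
    Returns (sigma_a, sigma_b, sigma_c, ssd, df).
    """
    pops = [idx for basin in basin_groups for idx in basin]
    basin_idx = [np.concatenate(basin) for basin in basin_groups]
    all_idx = np.concatenate(basin_idx)
    n_tot = len(all_idx)
    n_pops = len(pops)
    n_groups = len(basin_groups)

    ssd_total = sq[np.ix_(all_idx, all_idx)].sum() / (2.0 * n_tot)
    ssd_wp = _ssd_within(sq, pops)  # within populations (sites)
    ssd_wg = _ssd_within(sq, basin_idx)  # within groups (basins)
    ssd_ap = ssd_wg - ssd_wp  # among sites within basins
    ssd_ag = ssd_total - ssd_wg  # among basins

    df_ag = n_groups - 1
    df_ap = n_pops - n_groups
    df_wp = n_tot - n_pops

    ssd = {"among": ssd_ag, "among_within": ssd_ap, "within": ssd_wp}
    df = {"among": df_ag, "among_within": df_ap, "within": df_wp}

    sigma_c = ssd_wp / df_wp if df_wp > 0 else float("nan")

    # size coefficients (Excoffier et al. 1992, unequal sample sizes)
    sum_np2_over_ng = sum(
        sum(len(p) ** 2 for p in basin) / len(g_idx)
        for basin, g_idx in zip(basin_groups, basin_idx)
    )
    sum_np2_over_n = sum(len(p) ** 2 for p in pops) / n_tot
    sum_ng2_over_n = sum(len(g) ** 2 for g in basin_idx) / n_tot

    if df_ap > 0:
        n1 = (n_tot - sum_np2_over_ng) / df_ap
        sigma_b = (ssd_ap / df_ap - sigma_c) / n1
    else:
        sigma_b = 0.0  # structurally zero: no replicate sites anywhere
    if df_ag > 0:
        n2 = (sum_np2_over_ng - sum_np2_over_n) / df_ag
        n3 = (n_tot - sum_ng2_over_n) / df_ag
        sigma_a = (ssd_ag / df_ag - sigma_c - n2 * sigma_b) / n3
    else:
        sigma_a = float("nan")
    return sigma_a, sigma_b, sigma_c, ssd, df


def _partition_indices(
    labels: Sequence[str], partition: PopulationPartition
) -> list[list[np.ndarray]]:
    pos = {l: i for i, l in enumerate(labels)}
    groups: list[list[np.ndarray]] = []
    for basin in partition.basins():
        basin_sites = []
        for site in partition.sites_in_basin(basin):
            idx = [
                pos[s]
                for s in labels
                if partition.basin_of[s] == basin and partition.site_of[s] == site
            ]
            basin_sites.append(np.array(idx, dtype=int))
        groups.append(basin_sites)
    return groups


def amova3(
    matrix: DistanceMatrix,
    partition: PopulationPartition,
    nperm: int = 10_000,
    seed: int = 0,
    square_entries: bool = False,
) -> AmovaResult:
    """Three-level AMOVA (basins / sites within basins / samples within sites).

    Permutation schemes follow the standard nested design: whole sites are
    permuted among basins for Phi_CT; samples among sites within their basin
    for Phi_SC; samples among sites without regard to basin for Phi_ST.
    Negative variance components are reported as-is, not truncated.
    """
    labels = matrix.labels
    missing = [s for s in labels if s not in partition.basin_of]
    if missing:
        raise KeyError(f"samples missing from partition: {missing[:5]}")
    groups = _partition_indices(labels, partition)
    if len(groups) < 2:
        raise ValueError("need >= 2 basins for AMOVA")
    sq = _squared(matrix, square_entries)

    sigma_a, sigma_b, sigma_c, ssd, df = _amova3_components(sq, groups)
    total = sigma_a + sigma_b + sigma_c

    def undef_if_nan(x: float, reason: str) -> Stat:
        return Undefined(reason) if math.isnan(x) else float(x)

    if total == 0 or math.isnan(total):
        reason = "zero or undefined total variance"
        und = Undefined(reason)
        return AmovaResult(
            undef_if_nan(sigma_a, reason), sigma_b, sigma_c,
            und, und, und, und, und, und, und, und, und,
            nperm=nperm, seed=seed, df=df, ssd=ssd,
        )

    phi_ct = sigma_a / total
    phi_st = (sigma_a + sigma_b) / total
    phi_sc = sigma_b / (sigma_b + sigma_c) if (sigma_b + sigma_c) != 0 else float("nan")

    rng = np.random.default_rng(seed)

    def recompute(perm_groups: Sequence[Sequence[np.ndarray]]):
        a, b, c, _, _ = _amova3_components(sq, perm_groups)
        tot = a + b + c
        if tot == 0 or math.isnan(tot):
            return float("nan"), float("nan"), float("nan")
        ct = a / tot
        st = (a + b) / tot
        sc = b / (b + c) if (b + c) != 0 else float("nan")
        return ct, sc, st

    # Phi_CT: permute whole sites among basins (basin site-counts preserved)
    sites_flat = [idx for basin in groups for idx in basin]
    counts = [len(basin) for basin in groups]
    hits_ct = 1
    for _ in range(nperm):
        order = rng.permutation(len(sites_flat))
        it = iter(order)
        perm_groups = [[sites_flat[next(it)] for _ in range(c)] for c in counts]
        ct, _, _ = recompute(perm_groups)
        if not math.isnan(ct) and ct >= phi_ct - 1e-12:
            hits_ct += 1

    # Phi_SC: permute samples among sites within each basin
    hits_sc = 1
    phi_sc_defined = not math.isnan(phi_sc)
    if phi_sc_defined:
        for _ in range(nperm):
            perm_groups = []
            for basin in groups:
                pool = np.concatenate(basin)
                pool = rng.permutation(pool)
                sizes = [len(s) for s in basin]
                out, start = [], 0
                for size in sizes:
                    out.append(pool[start : start + size])
                    start += size
                perm_groups.append(out)
            _, sc, _ = recompute(perm_groups)
            if not math.isnan(sc) and sc >= phi_sc - 1e-12:
                hits_sc += 1

    # Phi_ST: permute samples among sites across the whole design
    hits_st = 1
    pool_all = np.concatenate([idx for basin in groups for idx in basin])
    shape = [[len(s) for s in basin] for basin in groups]
    for _ in range(nperm):
        pool = rng.permutation(pool_all)
        perm_groups, start = [], 0
        for sizes in shape:
            out = []
            for size in sizes:
                out.append(pool[start : start + size])
                start += size
            perm_groups.append(out)
        _, _, st = recompute(perm_groups)
        if not math.isnan(st) and st >= phi_st - 1e-12:
            hits_st += 1

    denom = nperm + 1
    return AmovaResult(
        sigma_a=float(sigma_a),
        sigma_b=float(sigma_b),
        sigma_c=float(sigma_c),
        pct_a=100.0 * sigma_a / total,
        pct_b=100.0 * sigma_b / total,
        pct_c=100.0 * sigma_c / total,
        phi_ct=float(phi_ct),
        phi_sc=float(phi_sc) if phi_sc_defined else Undefined("sigma_b + sigma_c = 0"),
        phi_st=float(phi_st),
        p_ct=hits_ct / denom,
        p_sc=hits_sc / denom if phi_sc_defined else Undefined("sigma_b + sigma_c = 0"),
        p_st=hits_st / denom,
        nperm=nperm,
        seed=seed,
        df=df,
        ssd=ssd,
    )


# ---------------------------------------------------------------------------
# Diversity and neutrality
# ---------------------------------------------------------------------------


@dataclass
class DiversityStats:
    """Nucleotide diversity and substitution counts for one group."""

    n: int
    pi: float  # mean pairwise differences (count per sequence pair)
    pi_sd: float  # Tajima's (1983) sampling SD of pi
    S: int  # segregating sites
    n_s: int  # transitions (parsimony-minimum over segregating sites)
    n_v: int  # transversions
    n_d: int  # substitutions = n_s + n_v


def _pairwise_diff_counts(codes: list[np.ndarray]) -> list[int]:
    out = []
    for i in range(len(codes)):
        for j in range(i + 1, len(codes)):
            valid = (codes[i] >= 0) & (codes[j] >= 0)
            out.append(int(((codes[i] != codes[j]) & valid).sum()))
    return out


def diversity(alignment: Alignment) -> DiversityStats | Undefined:
    """Mean pairwise differences, segregating sites, ts/tv substitution counts.

    pi is the mean count of differing sites over unordered sequence pairs
    (pairwise deletion of gaps/ambiguities); its SD uses Tajima's variance
    estimator, V(pi) = (3n(n+1) pi + 2(n^2+n+3) pi^2) / (11(n^2 - 7n + 6)).
    Per segregating site the minimum substitution count is the number of
    observed unambiguous states minus one; transitions are counted when both
    members of a purine or pyrimidine pair are present.
    """
    n = alignment.n
    if n < 2:
        return Undefined("need >= 2 sequences")
    codes = [encode(s) for s in alignment.seqs]
    diffs = _pairwise_diff_counts(codes)
    pi = float(np.mean(diffs))
    if n > 6:
        var = (3 * n * (n + 1) * pi + 2 * (n**2 + n + 3) * pi**2) / (
            11 * (n**2 - 7 * n + 6)
        )
    else:
        # Tajima's small-sample variance of the mean pairwise difference
        var = ((n + 1) / (3 * (n - 1))) * pi + (
            2 * (n**2 + n + 3) / (9 * n * (n - 1))
        ) * pi**2
    S = n_s = n_v = 0
    stacked = np.stack(codes)
    for col in stacked.T:
        states = set(int(c) for c in col if c >= 0)
        if len(states) < 2:
            continue
        S += 1
        ts = int({0, 2} <= states) + int({1, 3} <= states)
        subs = len(states) - 1
        n_s += ts
        n_v += subs - ts
    return DiversityStats(
        n=n, pi=pi, pi_sd=math.sqrt(max(var, 0.0)), S=S, n_s=n_s, n_v=n_v,
        n_d=n_s + n_v,
    )


def tajimas_d(n: int, S: int, pi: float) -> Stat:
    """Tajima's (1989) D from sample size, segregating sites and pi.

    D = (pi - S/a1) / sqrt(e1 S + e2 S (S-1)) with Tajima's constants.
    """
    if n < 4:
        return Undefined(f"n = {n} < 4")
    if S < 1:
        return Undefined("no segregating sites")
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    denom = math.sqrt(e1 * S + e2 * S * (S - 1))
    if denom == 0:
        return Undefined("zero variance denominator")
    return (pi - S / a1) / denom


@dataclass
class NeutralityStats:
    """Neutrality-test summary for one group."""

    tajima_D: Stat
    fu_Fs: Stat
    theta_pi: float
    k_obs: int


@lru_cache(maxsize=None)
def _stirling_first_row(n: int) -> tuple[int, ...]:
    """Unsigned Stirling numbers of the first kind |S(n, k)|, k = 0..n (exact)."""
    row = [1]  # n = 0
    for m in range(1, n + 1):
        prev = row
        row = [0] * (m + 1)
        for k in range(1, m + 1):
            row[k] = prev[k - 1] + (m - 1) * (prev[k] if k <= m - 1 else 0)
    return tuple(row)


def ewens_k_pmf(n: int, theta: float) -> np.ndarray:
    """P(K = k) for k = 1..n under the Ewens sampling distribution.

    P(K = k) = |S(n,k)| theta^k / (theta (theta+1) ... (theta+n-1)),
    with exact Stirling numbers combined in log space.
    """
    if n < 1 or theta <= 0:
        raise ValueError("need n >= 1 and theta > 0")
    stirling = _stirling_first_row(n)
    log_rising = sum(math.log(theta + i) for i in range(n))
    logs = np.array(
        [math.log(stirling[k]) + k * math.log(theta) - log_rising for k in range(1, n + 1)]
    )
    return np.exp(logs)


def fus_fs(n: int, k_obs: int, theta_pi: float) -> Stat:
    """Fu's (1997) F_s statistic.

    S' = P(K >= k_obs | theta = theta_pi) under the Ewens distribution of the
    number of distinct alleles K; F_s = ln(S' / (1 - S')).  A numerically
    degenerate S' (0 or 1) yields a signed-infinity result.
    """
    if n < 2:
        return Undefined(f"n = {n} < 2")
    if not 1 <= k_obs <= n:
        return Undefined(f"k_obs = {k_obs} outside 1..{n}")
    if theta_pi <= 0:
        return Undefined("theta_pi <= 0 (no diversity)")
    stirling = _stirling_first_row(n)
    log_rising = sum(math.log(theta_pi + i) for i in range(n))
    log_terms = [
        math.log(stirling[k]) + k * math.log(theta_pi) - log_rising
        for k in range(1, n + 1)
    ]
    log_ge = logsumexp(log_terms[k_obs - 1 :])
    if k_obs == 1:
        # S' = P(K >= 1) = 1 exactly
        return float("inf")
    log_lt = logsumexp(log_terms[: k_obs - 1])
    # F_s = log(S') - log(1 - S') computed from the two complementary sums
    if not math.isfinite(log_ge):
        return float("-inf")
    if not math.isfinite(log_lt):
        return float("inf")
    return float(log_ge - log_lt)


def neutrality(alignment: Alignment) -> NeutralityStats | Undefined:
    """Tajima's D and Fu's F_s for one group of sequences.

    theta for F_s is estimated by pi (the mean pairwise difference count);
    k_obs is the number of distinct sequences observed.
    """
    stats = diversity(alignment)
    if isinstance(stats, Undefined):
        return stats
    k_obs = len(set(alignment.seqs))
    d = tajimas_d(stats.n, stats.S, stats.pi)
    if stats.pi > 0:
        fs = fus_fs(stats.n, k_obs, stats.pi)
    else:
        fs = Undefined("pi = 0")
    return NeutralityStats(tajima_D=d, fu_Fs=fs, theta_pi=stats.pi, k_obs=k_obs)
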