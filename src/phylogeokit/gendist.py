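"""Pairwise genetic distances: K2P, gamma-corrected K2P, and net divergence.

The Kimura two-parameter (K2P) distance separates transitions (A<->G, C<->T)
from transversions and corrects both for multiple hits.  Among-site rate
heterogeneity is handled with the Jin & Nei (1990) gamma variant, using a
shape parameter estimated elsewhere (default alpha = 0.68).  Between-group
divergence is corrected for within-group polymorphism with Nei's net
divergence d_A = d_xy - (d_x + d_y)/2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .seqdata import Alignment

__all__ = [
    "PairwiseCounts",
    "DistanceModel",
    "DistanceMatrix",
    "NetDivergence",
    "SaturationError",
    "count_site_patterns",
    "k2p_distance",
    "distance_matrix",
    "group_mean_distance",
    "net_divergence",
    "net_divergence_table",
]

# integer encoding: A=0, C=1, G=2, T=3; anything ambiguous/gapped = -1.
_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i

# A(0) and G(2) are purines (even codes); C(1) and T(3) pyrimidines (odd):
# a difference within one parity class is a transition.


def encode(seq: str) -> np.ndarray:
    """Encode a sequence as int8 codes; gaps/ambiguities become -1."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


class SaturationError(ValueError):
    """K2P log/power argument non-positive: the pair is too divergent."""


@dataclass(frozen=True)
class PairwiseCounts:
    """Compared-site count with transition/transversion proportions.

    L counts only positions where both sequences carry an unambiguous base
    (pairwise deletion); P and Q are the transition and transversion
    proportions of those L sites.
    """

    L: int
    P: float
    Q: float

    def __post_init__(self) -> None:
        if self.L < 1:
            raise ValueError("no comparable sites (L = 0)")
        if not 0.0 <= self.P + self.Q <= 1.0:
            raise ValueError("P + Q outside [0, 1]")


@dataclass(frozen=True)
class DistanceModel:
    """Distance flavour: plain K2P or its gamma-rate correction."""

    kind: Literal["k2p", "gamma_k2p"] = "gamma_k2p"
    alpha: float = 0.68

    def __post_init__(self) -> None:
        if self.kind not in ("k2p", "gamma_k2p"):
            raise ValueError(f"unknown distance kind {self.kind!r}")
        if self.kind == "gamma_k2p" and not self.alpha > 0:
            raise ValueError("gamma shape alpha must be > 0")


def count_site_patterns(seq_a: str, seq_b: str) -> PairwiseCounts:
    """Count transitions/transversions between two aligned sequences.

    Positions where either sequence has a gap, N, or IUPAC ambiguity are
    excluded entirely (pairwise deletion).
    """
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences differ in length")
    a, b = encode(seq_a), encode(seq_b)
    valid = (a >= 0) & (b >= 0)
    L = int(valid.sum())
    if L == 0:
        raise SaturationError("no comparable sites after pairwise deletion")
    diff = valid & (a != b)
    transitions = diff & ((a % 2) == (b % 2))
    n_ts = int(transitions.sum())
    n_tv = int(diff.sum()) - n_ts
    return PairwiseCounts(L=L, P=n_ts / L, Q=n_tv / L)


def k2p_distance(counts: PairwiseCounts, model: DistanceModel = DistanceModel()) -> float:
    """K2P distance from transition/transversion proportions.

    Plain form:   d = -1/2 ln(1-2P-Q) - 1/4 ln(1-2Q)
    Gamma form (Jin & Nei 1990):
                  d = a/2 [(1-2P-Q)^(-1/a) - 1] + a/4 [(1-2Q)^(-1/a) - 1]
    """
    w1 = 1.0 - 2.0 * counts.P - counts.Q
    w2 = 1.0 - 2.0 * counts.Q
    if w1 <= 0.0 or w2 <= 0.0:
        raise SaturationError(
            f"saturated pair: 1-2P-Q={w1:.4g}, 1-2Q={w2:.4g} (P={counts.P}, Q={counts.Q})"
        )
    if model.kind == "k2p":
        return -0.5 * math.log(w1) - 0.25 * math.log(w2)
    a = model.alpha
    return (a / 2.0) * (w1 ** (-1.0 / a) - 1.0) + (a / 4.0) * (w2 ** (-1.0 / a) - 1.0)


@dataclass
class DistanceMatrix:
    """A labelled symmetric distance matrix with zero diagonal."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(self.values, self.values.T, equal_nan=True):
            raise ValueError("matrix is not symmetric")
        if not np.allclose(np.diag(self.values), 0.0):
            raise ValueError("diagonal is not zero")

    @property
    def n(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(label) from None

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.index(a), self.index(b)])

    def submatrix(self, labels: Sequence[str]) -> "DistanceMatrix":
        idx = [self.index(l) for l in labels]
        return DistanceMatrix(list(labels), self.values[np.ix_(idx, idx)])

    def condensed(self) -> np.ndarray:
        """Upper-triangle entries (i < j), row-major."""
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index_label="")

    @classmethod
    def from_csv(cls, path: str | Path) -> "DistanceMatrix":
        frame = pd.read_csv(path, index_col=0)
        return cls([str(c) for c in frame.columns], frame.to_numpy(dtype=float))

    def to_phylip(self, path: str | Path) -> None:
        """Square PHYLIP distance-matrix export."""
        with open(path, "w") as fh:
            fh.write(f"{self.n}\n")
            for label, row in zip(self.labels, self.values):
                name = label[:10].ljust(10)
                fh.write(name + " " + " ".join(f"{v:.6f}" for v in row) + "\n")


def distance_matrix(
    alignment: Alignment, model: DistanceModel = DistanceModel()
) -> DistanceMatrix:
    """All-pairs K2P distance matrix for an alignment (pairwise deletion)."""
    codes = [encode(s) for s in alignment.seqs]
    n = alignment.n
    out = np.zeros((n, n))
    for i in range(n):
        a = codes[i]
        for j in range(i + 1, n):
            b = codes[j]
            valid = (a >= 0) & (b >= 0)
            L = int(valid.sum())
            if L == 0:
                raise SaturationError(
                    f"no comparable sites between {alignment.ids[i]} and {alignment.ids[j]}"
                )
            diff = valid & (a != b)
            n_ts = int((diff & ((a % 2) == (b % 2))).sum())
            n_tv = int(diff.sum()) - n_ts
            try:
                d = k2p_distance(PairwiseCounts(L, n_ts / L, n_tv / L), model)
            except SaturationError as err:
                raise SaturationError(
                    f"{alignment.ids[i]} vs {alignment.ids[j]}: {err}"
                ) from None
            out[i, j] = out[j, i] = d
    return DistanceMatrix(list(alignment.ids), out)


def group_mean_distance(
    matrix: DistanceMatrix,
    group_x: Sequence[str],
    group_y: Sequence[str] | None = None,
) -> float:
    """Mean pairwise distance between two groups (or within one).

    For distinct groups the mean runs over all cross pairs; for a group
    against itself it runs over unordered within-group pairs, excluding the
    self-pair, with a single-member group returning 0 by convention.
    """
    if group_y is None:
        group_y = group_x
    if not group_x or not group_y:
        raise ValueError("groups must be nonempty")
    ix = [matrix.index(l) for l in group_x]
    iy = [matrix.index(l) for l in group_y]
    if set(ix) == set(iy):
        if len(ix) < 2:
            return 0.0
        sub = matrix.values[np.ix_(ix, ix)]
        iu = np.triu_indices(len(ix), k=1)
        return float(sub[iu].mean())
    return float(matrix.values[np.ix_(ix, iy)].mean())


def net_divergence(d_xy: float, d_x: float, d_y: float) -> float:
    """Nei's net divergence d_A = d_xy - (d_x + d_y)/2.

    Negative values (possible when within-group diversity exceeds the
    between-group mean) are reported as-is; dating flags them downstream.
    """
    for v in (d_xy, d_x, d_y):
        if not math.isfinite(v):
            raise ValueError("non-finite distance input")
    return d_xy - (d_x + d_y) / 2.0


@dataclass
class NetDivergence:
    """Between-group mean, within-group means, and the corrected divergence."""

    d_xy: float
    d_x: float
    d_y: float

    @property
    def d_A(self) -> float:
        return net_divergence(self.d_xy, self.d_x, self.d_y)


def net_divergence_table(
    matrix: DistanceMatrix, groups: Mapping[str, Sequence[str]]
) -> tuple[DistanceMatrix, dict[str, float]]:
    """Net divergence d_A for every pair of groups, plus within-group means.

    ``groups`` maps a group label to its member sequence labels.  Returns a
    labelled matrix of d_A (zero diagonal) and the within-group mean
    distances keyed by group label.
    """
    names = list(groups)
    within = {g: group_mean_distance(matrix, list(groups[g])) for g in names}
    n = len(names)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d_xy = group_mean_distance(
                matrix, list(groups[names[i]]), list(groups[names[j]])
            )
            d_a = net_divergence(d_xy, within[names[i]], within[names[j]])
            out[i, j] = out[j, i] = d_a
    return DistanceMatrix(names, out), within
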