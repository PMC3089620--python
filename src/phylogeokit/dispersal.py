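"""Phylogeographic Brownian-diffusion dispersal inference.

A substitution-length tree is smoothed into an ultrametric chronogram with
nonparametric rate smoothing (Sanderson 1997), rooted at a fixed age.  Tip
coordinates (projected to planar km) are then modelled as the outcome of
independent 2-D Brownian motion along the chronogram, with the per-branch
variance sigma^2_class x branch duration; branches are grouped into
dispersal classes, each with its own diffusion rate.  Likelihoods come from
Felsenstein's pruning algorithm on independent contrasts (REML, root
location profiled out); nested class models are compared by chi-squared
likelihood-ratio tests, and per-class per-generation dispersal distances are
correlated with basin range size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, logit
from scipy.stats import chi2, pearsonr

from .landscape import project_coordinates  # re-exported: coordinate plumbing

__all__ = [
    "Chronogram",
    "DiffusionFit",
    "LrtResult",
    "RangeCorrelation",
    "nprs_chronogram",
    "project_coordinates",
    "bm_loglik",
    "fit_dispersal",
    "lrt_classes",
    "range_correlation",
    "branch_key",
    "single_class_map",
    "clade_class_map",
    "simulate_bm_tips",
]

_DUR_FLOOR = 1e-9


def branch_key(node: dendropy.Node) -> tuple[str, ...]:
    """Stable identifier of the branch above ``node``: its sorted tip labels."""
    return tuple(sorted(l.taxon.label for l in node.leaf_iter()))


# ---------------------------------------------------------------------------
# Chronogram
# ---------------------------------------------------------------------------


@dataclass
class Chronogram:
    """A rooted binary ultrametric tree with node ages in Myr."""

    tree: dendropy.Tree
    root_age: float

    def __post_init__(self) -> None:
        self._check_ultrametric()

    def _check_ultrametric(self, tol: float = 1e-6) -> None:
        for node in self.tree.preorder_node_iter():
            if node.parent_node is None:
                node._depth = 0.0
            else:
                node._depth = node.parent_node._depth + (node.edge.length or 0.0)
        depths = [l._depth for l in self.tree.leaf_node_iter()]
        if max(depths) - min(depths) > tol * max(1.0, max(depths)):
            raise ValueError(
                f"tree is not ultrametric: tip depths span {min(depths)}..{max(depths)}"
            )

    def ages(self) -> dict[tuple[str, ...], float]:
        out = {}
        for node in self.tree.preorder_node_iter():
            depth = 0.0
            p = node
            while p.parent_node is not None:
                depth += p.edge.length or 0.0
                p = p.parent_node
            out[branch_key(node)] = self.root_age - depth
        return out

    def n_tips(self) -> int:
        return sum(1 for _ in self.tree.leaf_node_iter())


def _clocklike_init(node: dendropy.Node) -> float:
    """Mean substitution path length from ``node`` down to its tips."""
    if node.is_leaf():
        return 0.0
    return float(
        np.mean(
            [
                _clocklike_init(c) + (c.edge.length or 0.0)
                for c in node.child_nodes()
            ]
        )
    )


def nprs_chronogram(
    tree: dendropy.Tree,
    root_age: float = 5.0,
    n_starts: int = 5,
    seed: int = 0,
    tol: float = 1e-9,
) -> Chronogram:
    """Nonparametric rate smoothing: substitution lengths -> time tree.

    Node ages minimize the sum over internal nodes of squared local rate
    differences between a branch and its descendant branches; at the root,
    where no ancestral branch exists, the term is the squared deviation of
    each child rate from their mean.  Tips sit at age 0 and the root is fixed
    at ``root_age``.  Ages are optimized on logit-transformed fractions of
    the parent age (guaranteeing parent > child), quasi-Newton with
    ``n_starts`` multi-starts.
    """
    work = tree.clone(depth=1)
    for node in work.preorder_node_iter():
        if node.parent_node is not None and len(node.child_nodes()) == 1:
            raise ValueError("tree must be strictly binary (no unifurcations)")
    nodes = list(work.preorder_node_iter())
    root = work.seed_node
    free = [n for n in nodes if n.parent_node is not None and not n.is_leaf()]

    # substitution lengths, floored so rates stay identifiable
    sub_len = {
        id(n): max(n.edge.length or 0.0, 0.0) for n in nodes if n.parent_node is not None
    }
    if any(
        v == 0.0
        for n, v in ((n, sub_len[id(n)]) for n in nodes if n.parent_node is not None)
    ):
        # zero-length branches make local rates degenerate; nudge them
        for k in sub_len:
            sub_len[k] = max(sub_len[k], 1e-8)

    ages: dict[int, float] = {}

    def set_ages(z: np.ndarray) -> None:
        ages[id(root)] = root_age
        for leaf in work.leaf_node_iter():
            ages[id(leaf)] = 0.0
        for zi, node in zip(z, free):
            ages[id(node)] = ages[id(node.parent_node)] * float(expit(zi))

    def objective(z: np.ndarray) -> float:
        set_ages(z)
        rate: dict[int, float] = {}
        for n in nodes:
            if n.parent_node is None:
                continue
            dur = max(ages[id(n.parent_node)] - ages[id(n)], _DUR_FLOOR)
            rate[id(n)] = sub_len[id(n)] / dur
        total = 0.0
        for n in nodes:
            if n.is_leaf():
                continue
            child_rates = [rate[id(c)] for c in n.child_nodes()]
            if n.parent_node is None:
                rbar = float(np.mean(child_rates))
                total += sum((rc - rbar) ** 2 for rc in child_rates)
            else:
                rp = rate[id(n)]
                total += sum((rp - rc) ** 2 for rc in child_rates)
        return total

    if free:
        # clock-like proportional depths as the primary start
        clock_age = {id(n): _clocklike_init(n) for n in nodes}
        z0 = []
        for n in free:
            parent_age = clock_age[id(n.parent_node)]
            frac = clock_age[id(n)] / parent_age if parent_age > 0 else 0.5
            z0.append(float(logit(np.clip(frac, 1e-6, 1 - 1e-6))))
        z0 = np.array(z0)
        rng = np.random.default_rng(seed)
        starts = [z0] + [z0 + rng.normal(0.0, 1.0, size=len(free)) for _ in range(n_starts - 1)]
        best = None
        for start in starts:
            res = minimize(objective, start, method="L-BFGS-B", tol=tol)
            if best is None or res.fun < best.fun:
                best = res
        set_ages(best.x)
    else:
        set_ages(np.empty(0))

    for n in nodes:
        if n.parent_node is not None:
            n.edge.length = ages[id(n.parent_node)] - ages[id(n)]
    return Chronogram(tree=work, root_age=root_age)


# ---------------------------------------------------------------------------
# Branch classes
# ---------------------------------------------------------------------------


def single_class_map(chronogram: Chronogram) -> dict[tuple[str, ...], int]:
    """Every branch in class 1."""
    return {
        branch_key(n): 1
        for n in chronogram.tree.preorder_node_iter()
        if n.parent_node is not None
    }


def clade_class_map(
    chronogram: Chronogram,
    clades: Mapping[str, Sequence[str]],
    background: str = "other",
) -> tuple[dict[tuple[str, ...], int], dict[str, int]]:
    """Assign branches to classes by clade membership.

    A branch joins the class of clade ``c`` when all its descendant tips are
    in ``clades[c]``; remaining branches form the background class.  Returns
    (branch -> class id, class name -> class id).
    """
    names = list(clades) + [background]
    class_id = {name: i + 1 for i, name in enumerate(names)}
    out: dict[tuple[str, ...], int] = {}
    for node in chronogram.tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        tips = set(branch_key(node))
        assigned = class_id[background]
        for name, members in clades.items():
            if tips <= set(members):
                assigned = class_id[name]
                break
        out[branch_key(node)] = assigned
    return out, class_id


# ---------------------------------------------------------------------------
# Brownian-motion likelihood (pruning / REML contrasts)
# ---------------------------------------------------------------------------


def _contrast_terms(
    chronogram: Chronogram,
    tip_xy: Mapping[str, tuple[float, float]],
    class_map: Mapping[tuple[str, ...], int],
    sigma2: Mapping[int, float],
) -> tuple[float, tuple[float, float]]:
    """(REML log-likelihood, inferred root location) by pruning.

    Branch variance = sigma2[class] x duration.  Each internal node yields
    one contrast per axis: difference of child values, variance = sum of the
    children's accumulated variances; the node passes upward the
    variance-weighted mean value with the usual v1 v2/(v1+v2) inflation.
    """
    tree = chronogram.tree
    lnl = 0.0
    value: dict[int, np.ndarray] = {}
    extra: dict[int, float] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            label = node.taxon.label
            if label not in tip_xy:
                raise KeyError(f"no coordinates for tip {label!r}")
            value[id(node)] = np.asarray(tip_xy[label], dtype=float)
            extra[id(node)] = 0.0
            continue
        children = node.child_nodes()
        if len(children) != 2:
            raise ValueError("tree must be binary for contrasts")
        vs, xs = [], []
        for child in children:
            key = branch_key(child)
            if key not in class_map:
                raise KeyError(f"branch {key} missing from class map")
            s2 = sigma2[class_map[key]]
            if not s2 > 0:
                raise ValueError("sigma^2 must be > 0")
            vs.append(s2 * max(child.edge.length or 0.0, 0.0) + extra[id(child)])
            xs.append(value[id(child)])
        v = vs[0] + vs[1]
        if v <= 0:
            raise ValueError("degenerate zero-variance contrast (zero tree depth?)")
        diff = xs[0] - xs[1]
        for axis in range(2):
            lnl += -0.5 * (math.log(2.0 * math.pi * v) + diff[axis] ** 2 / v)
        value[id(node)] = (xs[0] * vs[1] + xs[1] * vs[0]) / v
        extra[id(node)] = vs[0] * vs[1] / v
    root_xy = value[id(tree.seed_node)]
    return lnl, (float(root_xy[0]), float(root_xy[1]))


def bm_loglik(
    chronogram: Chronogram,
    tip_xy: Mapping[str, tuple[float, float]],
    class_map: Mapping[tuple[str, ...], int],
    sigma2: Mapping[int, float],
) -> float:
    """REML log-likelihood of tip coordinates under per-class 2-D diffusion."""
    lnl, _ = _contrast_terms(chronogram, tip_xy, class_map, sigma2)
    return lnl


@dataclass
class DiffusionFit:
    """Maximum-likelihood diffusion rates per dispersal class."""

    sigma2: dict[int, float]  # km^2 / Myr per axis
    loglik: float
    root_xy: tuple[float, float]
    psi: dict[int, float]  # per-generation dispersal distance, km
    generation_myr: float
    converged: bool
    message: str = ""
    n_classes: int = 0
    class_map: dict[tuple[str, ...], int] = field(default_factory=dict, repr=False)
    boundary: bool = False  # true when a rate collapsed to the lower bound


def _class_durations(
    chronogram: Chronogram, class_map: Mapping[tuple[str, ...], int]
) -> dict[int, float]:
    totals: dict[int, float] = {}
    for node in chronogram.tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        cls = class_map[branch_key(node)]
        totals[cls] = totals.get(cls, 0.0) + (node.edge.length or 0.0)
    return totals


def fit_dispersal(
    chronogram: Chronogram,
    tip_xy: Mapping[str, tuple[float, float]],
    class_map: Mapping[tuple[str, ...], int],
    generation_myr: float = 1e-6,
    n_starts: int = 3,
    seed: int = 0,
) -> DiffusionFit:
    """Maximize the diffusion likelihood over per-class rates sigma^2_c.

    Optimization is quasi-Newton on log sigma^2 with multi-starts around a
    single-rate moment estimate.  The per-class per-generation dispersal
    distance is psi_c = sqrt(sigma^2_c x g) with generation time g in Myr
    (default 1 year): the per-axis SD of one generation's displacement.
    """
    classes = sorted(set(class_map.values()))
    durations = _class_durations(chronogram, class_map)
    for cls in classes:
        if durations.get(cls, 0.0) <= 0.0:
            raise ValueError(f"class {cls} has zero total branch duration: unidentifiable")
    n_tips = chronogram.n_tips()
    if n_tips < 2:
        raise ValueError("need >= 2 located tips")

    # moment start: single-rate REML estimate
    base = {cls: 1.0 for cls in classes}
    lnl0, _ = _contrast_terms(chronogram, tip_xy, class_map, base)
    # with all sigma2 = 1, contrasts c_i have variance v_i; the closed-form
    # single-rate scale is mean(c^2 / v) over both axes
    scale = _single_rate_scale(chronogram, tip_xy, class_map)
    if scale <= 0.0:
        # all tips coincident: boundary fit
        eps = 1e-12
        sig = {cls: eps for cls in classes}
        lnl = bm_loglik(chronogram, tip_xy, class_map, sig)
        return DiffusionFit(
            sigma2=sig, loglik=lnl, root_xy=next(iter(tip_xy.values())),
            psi={cls: math.sqrt(eps * generation_myr) for cls in classes},
            generation_myr=generation_myr, converged=True,
            message="zero dispersal signal: rates at boundary",
            n_classes=len(classes), class_map=dict(class_map), boundary=True,
        )

    rng = np.random.default_rng(seed)
    x0 = np.full(len(classes), math.log(scale))
    starts = [x0] + [x0 + rng.normal(0.0, 1.5, size=len(classes)) for _ in range(n_starts - 1)]

    def neg_loglik(logs: np.ndarray) -> float:
        sig = {cls: math.exp(v) for cls, v in zip(classes, logs)}
        try:
            return -bm_loglik(chronogram, tip_xy, class_map, sig)
        except (ValueError, OverflowError):
            return 1e12

    best = None
    for start in starts:
        res = minimize(neg_loglik, start, method="L-BFGS-B", bounds=[(-46, 46)] * len(classes))
        if best is None or res.fun < best.fun:
            best = res
    sigma2 = {cls: math.exp(v) for cls, v in zip(classes, best.x)}
    lnl, root_xy = _contrast_terms(chronogram, tip_xy, class_map, sigma2)
    boundary = bool(np.any(best.x <= -45.0))
    return DiffusionFit(
        sigma2=sigma2,
        loglik=lnl,
        root_xy=root_xy,
        psi={cls: math.sqrt(s * generation_myr) for cls, s in sigma2.items()},
        generation_myr=generation_myr,
        converged=bool(best.success),
        message=str(best.message),
        n_classes=len(classes),
        class_map=dict(class_map),
        boundary=boundary,
    )


def _single_rate_scale(
    chronogram: Chronogram,
    tip_xy: Mapping[str, tuple[float, float]],
    class_map: Mapping[tuple[str, ...], int],
) -> float:
    """Closed-form REML rate if all classes shared one sigma^2."""
    unit = {cls: 1.0 for cls in set(class_map.values())}
    tree = chronogram.tree
    value: dict[int, np.ndarray] = {}
    extra: dict[int, float] = {}
    num, count = 0.0, 0
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            value[id(node)] = np.asarray(tip_xy[node.taxon.label], dtype=float)
            extra[id(node)] = 0.0
            continue
        c1, c2 = node.child_nodes()
        v1 = max(c1.edge.length or 0.0, 0.0) + extra[id(c1)]
        v2 = max(c2.edge.length or 0.0, 0.0) + extra[id(c2)]
        v = v1 + v2
        diff = value[id(c1)] - value[id(c2)]
        num += float(diff @ diff) / v
        count += 2
        value[id(node)] = (value[id(c1)] * v2 + value[id(c2)] * v1) / v
        extra[id(node)] = v1 * v2 / v
    del unit
    return num / count if count else 0.0


@dataclass(frozen=True)
class LrtResult:
    """Chi-squared likelihood-ratio test between nested class models."""

    statistic: float
    df: int
    p: float


def lrt_classes(fit_simple: DiffusionFit, fit_complex: DiffusionFit) -> LrtResult:
    """LRT of a simple class model against a nested, richer one.

    The simple map must be a coarsening of the complex map (each complex
    class maps into exactly one simple class); statistic = 2 (lnL_complex -
    lnL_simple), df = difference in class counts, p from the upper chi^2 tail.
    """
    refine: dict[int, int] = {}
    for key, complex_cls in fit_complex.class_map.items():
        simple_cls = fit_simple.class_map.get(key)
        if simple_cls is None:
            raise ValueError(f"branch {key} absent from the simple model")
        if refine.setdefault(complex_cls, simple_cls) != simple_cls:
            raise ValueError("class maps are not nested")
    stat = 2.0 * (fit_complex.loglik - fit_simple.loglik)
    if stat < -1e-6:
        raise ValueError(
            f"negative LRT statistic {stat:.3g}: complex-model optimization failed"
        )
    stat = max(stat, 0.0)
    df = fit_complex.n_classes - fit_simple.n_classes
    if df < 0:
        raise ValueError("complex model has fewer classes than the simple one")
    if df == 0:
        return LrtResult(statistic=stat, df=0, p=1.0)
    return LrtResult(statistic=stat, df=df, p=float(chi2.sf(stat, df)))


@dataclass(frozen=True)
class RangeCorrelation:
    """Correlation of per-class dispersal distance with basin range size."""

    r: float
    p: float
    n: int


def range_correlation(
    psi_per_class: Mapping[str, float], area_km2: Mapping[str, float]
) -> RangeCorrelation:
    """Pearson correlation of dispersal distance psi with sqrt(range area).

    Two-sided p from t = r sqrt(n-2)/sqrt(1-r^2) with n-2 degrees of
    freedom.  Classes present in both mappings are used, in sorted order.
    """
    keys = sorted(set(psi_per_class) & set(area_km2))
    if len(keys) < 3:
        raise ValueError("need >= 3 paired classes")
    psi = np.array([psi_per_class[k] for k in keys], dtype=float)
    root_area = np.sqrt(np.array([area_km2[k] for k in keys], dtype=float))
    if np.std(psi) == 0 or np.std(root_area) == 0:
        raise ValueError("zero variance: correlation undefined")
    r, p = pearsonr(psi, root_area)
    return RangeCorrelation(r=float(r), p=float(p), n=len(keys))


# ---------------------------------------------------------------------------
# Simulation (for calibration and recovery studies)
# ---------------------------------------------------------------------------


def simulate_bm_tips(
    chronogram: Chronogram,
    class_map: Mapping[tuple[str, ...], int],
    sigma2: Mapping[int, float],
    root_xy: tuple[float, float] = (0.0, 0.0),
    seed: int = 0,
) -> dict[str, tuple[float, float]]:
    """Simulate tip coordinates under the per-class diffusion model."""
    rng = np.random.default_rng(seed)
    pos: dict[int, np.ndarray] = {}
    out: dict[str, tuple[float, float]] = {}
    for node in chronogram.tree.preorder_node_iter():
        if node.parent_node is None:
            pos[id(node)] = np.asarray(root_xy, dtype=float)
        else:
            s2 = sigma2[class_map[branch_key(node)]]
            var = s2 * max(node.edge.length or 0.0, 0.0)
            step = rng.normal(0.0, math.sqrt(var), size=2) if var > 0 else np.zeros(2)
            pos[id(node)] = pos[id(node.parent_node)] + step
        if node.is_leaf():
            out[node.taxon.label] = (float(pos[id(node)][0]), float(pos[id(node)][1]))
    return out


def psi_table(fit: DiffusionFit, class_names: Mapping[str, int] | None = None) -> pd.DataFrame:
    """Per-class diffusion rates and dispersal distances as a tidy table."""
    rows = []
    name_of = {}
    if class_names:
        name_of = {v: k for k, v in class_names.items()}
    for cls in sorted(fit.sigma2):
        rows.append(
            {
                "class": cls,
                "name": name_of.get(cls, str(cls)),
                "sigma2_km2_per_myr": fit.sigma2[cls],
                "psi_km_per_generation": fit.psi[cls],
            }
        )
    frame = pd.DataFrame(rows)
    frame.attrs["loglik"] = fit.loglik
    return frame
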