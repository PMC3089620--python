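"""Orchestration: run the full analysis chain on one dataset.

Stages: sequence input -> genetic distances -> population structure ->
haplotype network -> divergence dating -> landscape/IBD -> dispersal.  Each
stage persists its tables under the output directory; the run report records
per-stage status, every output file with a checksum, and a fingerprint of
the configuration actually used.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
import yaml

from . import clockdate, dispersal, gendist, hapnet, landscape, popstruct, seqdata
from .popstruct import Undefined

__all__ = ["RunConfig", "RunReport", "Finding", "validate_config", "run_all"]

log = logging.getLogger("phylogeokit")


@dataclass
class RunConfig:
    """Inputs and model settings for a full pipeline run.

    All seeds, permutation counts and thresholds are explicit so the
    persisted copy fully determines the run.
    """

    alignment: str = ""
    samples: str = ""
    dem: str = ""  # optional: enables the landscape/IBD stage
    tree: str = ""  # optional: enables the dispersal stage
    out_dir: str = "results"

    gamma_alpha: float = 0.68
    clock_rate: float = 0.021
    clock_rate_sd: float = 0.001
    friction_a: float = 1.4142
    friction_b: float = 0.0035
    friction_cap_m: float = 2300.0
    friction_mode: str = "exponential"
    mjn_epsilon: int = 0
    nperm: int = 10_000
    seed: int = 0
    generation_myr: float = 1e-6
    root_age_myr: float = 5.0
    min_class_size: int = 10
    reference_lat: float | None = None
    basin_areas_km2: dict[str, float] = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    def fingerprint(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass(frozen=True)
class Finding:
    level: str  # "error" | "warning"
    message: str


def validate_config(config: RunConfig) -> list[Finding]:
    """Structural and range checks; returns findings instead of raising."""
    findings: list[Finding] = []

    def err(msg: str) -> None:
        findings.append(Finding("error", msg))

    def warn(msg: str) -> None:
        findings.append(Finding("warning", msg))

    if config.clock_rate <= 0:
        err(f"clock rate must be > 0 (got {config.clock_rate})")
    if config.clock_rate_sd < 0:
        err("clock rate sd must be >= 0")
    if config.gamma_alpha <= 0:
        err("gamma alpha must be > 0")
    if config.mjn_epsilon < 0:
        err("median-joining epsilon must be >= 0")
    if config.nperm < 1:
        err("permutation count must be >= 1")
    if config.friction_mode not in ("exponential", "linear", "calibrated"):
        err(f"unknown friction mode {config.friction_mode!r}")
    elif config.friction_mode != "exponential":
        warn(f"friction mode {config.friction_mode!r} departs from the printed model")
    if config.alignment and not Path(config.alignment).exists():
        err(f"alignment file not found: {config.alignment}")
    if config.samples and not Path(config.samples).exists():
        err(f"sample table not found: {config.samples}")
    if config.dem and not Path(config.dem).exists():
        err(f"DEM not found: {config.dem}")
    if config.tree and not Path(config.tree).exists():
        err(f"tree not found: {config.tree}")
    return findings


@dataclass
class RunReport:
    """Per-stage status and the output-file inventory of one run."""

    fingerprint: str
    stages: dict[str, str] = field(default_factory=dict)  # name -> ok|failed|skipped
    timings_s: dict[str, float] = field(default_factory=dict)
    files: dict[str, str] = field(default_factory=dict)  # path -> sha256
    errors: dict[str, str] = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return all(v != "failed" for v in self.stages.values())

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _fmt(stat) -> object:
    return "NA" if isinstance(stat, Undefined) else stat


def run_all(config: RunConfig) -> RunReport:
    """Execute every applicable stage; failures skip dependent stages."""
    findings = validate_config(config)
    errors = [f for f in findings if f.level == "error"]
    if errors:
        raise ValueError(
            "invalid configuration: " + "; ".join(f.message for f in errors)
        )
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config_used.yaml")
    report = RunReport(fingerprint=config.fingerprint())
    outputs: list[Path] = [out / "config_used.yaml"]
    state: dict[str, object] = {}

    def stage(name: str, fn, requires: tuple[str, ...] = ()) -> None:
        for dep in requires:
            if report.stages.get(dep) != "ok":
                report.stages[name] = "skipped"
                log.info("stage %-12s skipped (needs %s)", name, dep)
                return
        t0 = time.perf_counter()
        try:
            produced = fn()
            outputs.extend(produced or [])
            report.stages[name] = "ok"
        except Exception as exc:  # noqa: BLE001 - report, do not crash the run
            report.stages[name] = "failed"
            report.errors[name] = f"{type(exc).__name__}: {exc}"
            log.warning("stage %-12s failed: %s", name, exc)
        report.timings_s[name] = round(time.perf_counter() - t0, 3)
        log.info("stage %-12s %s (%.2fs)", name, report.stages[name], report.timings_s[name])

    # --- seqdata -----------------------------------------------------------
    def s_seqdata():
        alignment = seqdata.read_alignment(config.alignment)
        table = seqdata.read_sample_table(config.samples)
        missing = set(alignment.ids) - set(table["sample_id"])
        if missing:
            raise ValueError(f"samples missing from table: {sorted(missing)[:5]}")
        table = table[table["sample_id"].isin(alignment.ids)].reset_index(drop=True)
        haps = seqdata.collapse_haplotypes(alignment)
        haps.write_map(out / "haplotype_map.csv")
        state["alignment"] = alignment
        state["table"] = table
        state["haps"] = haps
        return [out / "haplotype_map.csv"]

    stage("seqdata", s_seqdata)

    # --- gendist -----------------------------------------------------------
    def s_gendist():
        alignment = state["alignment"]
        table = state["table"]
        model = gendist.DistanceModel(kind="gamma_k2p", alpha=config.gamma_alpha)
        dm = gendist.distance_matrix(alignment, model)
        dm.to_csv(out / "distances_k2p_gamma.csv")
        groups = {
            b: table.loc[table["basin"] == b, "sample_id"].tolist()
            for b in table["basin"].unique()
        }
        net, within = gendist.net_divergence_table(dm, groups)
        net.to_csv(out / "net_divergence.csv")
        state["dm"] = dm
        state["net"] = net
        state["within"] = within
        state["groups"] = groups
        return [out / "distances_k2p_gamma.csv", out / "net_divergence.csv"]

    stage("gendist", s_gendist, requires=("seqdata",))

    # --- popstruct ---------------------------------------------------------
    def s_popstruct():
        dm = state["dm"]
        table = state["table"]
        partition = popstruct.PopulationPartition.from_table(table)
        amova = popstruct.amova3(dm, partition, nperm=config.nperm, seed=config.seed)
        amova.to_frame().to_csv(out / "amova.csv", index=False)
        basins = partition.basins()
        rows = []
        for i, a in enumerate(basins):
            for b in basins[i + 1 :]:
                phi, p = popstruct.pairwise_phist(
                    dm, partition, a, b, nperm=config.nperm, seed=config.seed
                )
                rows.append(
                    {"basin_a": a, "basin_b": b, "phi_st": _fmt(phi), "p": _fmt(p)}
                )
        pd.DataFrame(rows).to_csv(out / "pairwise_phist.csv", index=False)
        div_rows = []
        alignment = state["alignment"]
        for basin in basins:
            ids = table.loc[table["basin"] == basin, "sample_id"].tolist()
            sub = alignment.subset(ids)
            div = popstruct.diversity(sub)
            neut = popstruct.neutrality(sub)
            row: dict[str, object] = {"basin": basin, "n": len(ids)}
            if isinstance(div, Undefined):
                row["note"] = div.reason
            else:
                row.update(
                    pi=div.pi, pi_sd=div.pi_sd, S=div.S,
                    n_s=div.n_s, n_v=div.n_v, n_d=div.n_d,
                )
            if not isinstance(neut, Undefined):
                row["tajima_D"] = _fmt(neut.tajima_D)
                row["fu_Fs"] = _fmt(neut.fu_Fs)
                row["k_obs"] = neut.k_obs
            div_rows.append(row)
        pd.DataFrame(div_rows).to_csv(out / "diversity.csv", index=False)
        state["partition"] = partition
        return [out / "amova.csv", out / "pairwise_phist.csv", out / "diversity.csv"]

    stage("popstruct", s_popstruct, requires=("gendist",))

    # --- hapnet ------------------------------------------------------------
    def s_hapnet():
        graph = hapnet.median_joining(
            state["haps"], hapnet.MjnParams(epsilon=config.mjn_epsilon)
        )
        hapnet.write_edge_list(graph, out / "network_edges.csv")
        hapnet.write_gml(graph, out / "network.gml")
        return [out / "network_edges.csv", out / "network.gml"]

    stage("hapnet", s_hapnet, requires=("seqdata",))

    # --- clockdate ---------------------------------------------------------
    def s_clockdate():
        model = clockdate.ClockModel(rate=config.clock_rate, rate_sd=config.clock_rate_sd)
        clockdate.write_date_report(
            state["net"], model, out / "divergence_dates.csv", within=state["within"]
        )
        return [out / "divergence_dates.csv"]

    stage("clockdate", s_clockdate, requires=("gendist",))

    # --- landscape ---------------------------------------------------------
    def s_landscape():
        if not config.dem:
            raise ValueError("no DEM configured")
        dem = landscape.read_ascii_grid(config.dem)
        if config.friction_mode == "calibrated":
            fmodel = landscape.FrictionModel.calibrated(cap_elevation=config.friction_cap_m)
        else:
            fmodel = landscape.FrictionModel(
                a=config.friction_a, b=config.friction_b,
                cap_elevation=config.friction_cap_m, mode=config.friction_mode,
            )
        table = state["table"]
        sites = (
            table.groupby("site", sort=True)
            .agg(lat=("lat", "mean"), lon=("lon", "mean"), basin=("basin", "first"))
            .reset_index()
        )
        eff = landscape.effective_distance_matrix(
            sites, dem, fmodel, reference_lat=config.reference_lat
        )
        eff.to_csv(out / "effective_distances.csv")
        # site-level genetic distances: mean K2P between samples of two sites
        dm = state["dm"]
        ids_of = {
            s: table.loc[table["site"] == s, "sample_id"].tolist()
            for s in sites["site"]
        }
        labels = list(sites["site"])
        vals = np.zeros((len(labels), len(labels)))
        for i, a in enumerate(labels):
            for j in range(i + 1, len(labels)):
                vals[i, j] = vals[j, i] = gendist.group_mean_distance(
                    dm, ids_of[a], ids_of[labels[j]]
                )
        gsite = gendist.DistanceMatrix(labels, vals)
        gsite.to_csv(out / "site_genetic_distances.csv")
        reachable = np.isfinite(eff.condensed()).all()
        if reachable:
            mres = landscape.mantel(gsite, eff, nperm=config.nperm, seed=config.seed)
            state["mantel"] = mres
        else:
            state["mantel"] = None
        basin_of_site = dict(zip(sites["site"], sites["basin"]))
        finite = eff.values.copy()
        ibd = landscape.ibd_partition(gsite, eff, basin_of_site) if reachable else None
        with open(out / "ibd.csv", "w") as fh:
            fh.write("statistic,value\n")
            if state["mantel"] is not None:
                fh.write(f"mantel_r,{state['mantel'].r}\n")
                fh.write(f"mantel_p,{state['mantel'].p}\n")
            if ibd is not None:
                for basin, slope in ibd.within_slopes.items():
                    fh.write(f"within_slope_{basin},{'' if slope is None else slope}\n")
                fh.write(
                    f"between_slope,{'' if ibd.between_slope is None else ibd.between_slope}\n"
                )
                ibd.scatter.to_csv(out / "ibd_scatter.csv", index=False)
        del finite
        produced = [
            out / "effective_distances.csv",
            out / "site_genetic_distances.csv",
            out / "ibd.csv",
        ]
        if ibd is not None:
            produced.append(out / "ibd_scatter.csv")
        return produced

    if config.dem:
        stage("landscape", s_landscape, requires=("gendist",))
    else:
        report.stages["landscape"] = "skipped"

    # --- dispersal ---------------------------------------------------------
    def s_dispersal():
        if not config.tree:
            raise ValueError("no tree configured")
        tree = dendropy.Tree.get(path=config.tree, schema="newick")
        chrono = dispersal.nprs_chronogram(tree, root_age=config.root_age_myr, seed=config.seed)
        chrono.tree.write(path=str(out / "chronogram.nwk"), schema="newick")
        table = state["table"]
        ref_lat = (
            config.reference_lat
            if config.reference_lat is not None
            else float(table["lat"].mean())
        )
        tip_xy = {}
        for _, row in table.iterrows():
            x, y = dispersal.project_coordinates(row["lat"], row["lon"], ref_lat)
            tip_xy[row["sample_id"]] = (float(x), float(y))
        one_map = dispersal.single_class_map(chrono)
        fit1 = dispersal.fit_dispersal(
            chrono, tip_xy, one_map, generation_myr=config.generation_myr, seed=config.seed
        )
        counts = table["basin"].value_counts()
        clades = {
            b: table.loc[table["basin"] == b, "sample_id"].tolist()
            for b in counts.index
            if counts[b] > config.min_class_size
        }
        produced = [out / "chronogram.nwk"]
        if clades:
            class_map, class_id = dispersal.clade_class_map(chrono, clades)
            fitk = dispersal.fit_dispersal(
                chrono, tip_xy, class_map,
                generation_myr=config.generation_myr, seed=config.seed,
            )
            lrt = dispersal.lrt_classes(fit1, fitk)
            tab = dispersal.psi_table(fitk, class_id)
            tab.to_csv(out / "dispersal_classes.csv", index=False)
            with open(out / "dispersal_lrt.csv", "w") as fh:
                fh.write("statistic,df,p,lnL_single,lnL_classes\n")
                fh.write(
                    f"{lrt.statistic},{lrt.df},{lrt.p},{fit1.loglik},{fitk.loglik}\n"
                )
            produced += [out / "dispersal_classes.csv", out / "dispersal_lrt.csv"]
            if config.basin_areas_km2:
                psi_named = {
                    name: fitk.psi[cid]
                    for name, cid in class_id.items()
                    if name in config.basin_areas_km2
                }
                if len(psi_named) >= 3:
                    corr = dispersal.range_correlation(psi_named, config.basin_areas_km2)
                    with open(out / "dispersal_range_correlation.csv", "w") as fh:
                        fh.write("r,p,n\n")
                        fh.write(f"{corr.r},{corr.p},{corr.n}\n")
                    produced.append(out / "dispersal_range_correlation.csv")
        return produced

    if config.tree:
        stage("dispersal", s_dispersal, requires=("seqdata",))
    else:
        report.stages["dispersal"] = "skipped"

    for path in outputs:
        if Path(path).exists():
            report.files[str(path)] = _sha256(Path(path))
    report.to_json(out / "run_report.json")
    return report
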