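"""End-to-end pipeline: simulate -> DTM -> heights -> stats -> genetics.

Each stage writes its outputs to the run directory in standard formats
(float32 GeoTIFF with explicit nodata for rasters, GeoJSON for polygons,
headed CSV for tables) before the next stage starts, and a manifest records
every artifact with a SHA-256 content hash.  Re-running with the same
configuration reproduces identical manifests.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import heights as he
from . import quantgen as qg
from . import terrain as te
from . import validation as vs
from .synthetic_field import PARENT_IDS, SimulationConfig, simulate_field

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]

logger = logging.getLogger(__name__)


@dataclass
class AnalysisParams:
    lod_threshold: float = 2.5
    scan_step_cm: float = 1.0
    cofactor_p_in: float = 0.001
    cofactor_p_out: float = 0.002
    cv_k: int = 5
    cv_repeats: int = 20
    exclusion_flank_cm: float = 10.0
    ge_divisor: str = "reps"


@dataclass
class PipelineConfig:
    seed: int = 0
    out_dir: str = "uavheight_run"
    log_level: str = "INFO"
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    extraction: he.ExtractionParams = field(default_factory=he.ExtractionParams)
    analysis: AnalysisParams = field(default_factory=AnalysisParams)

    def __post_init__(self) -> None:
        # one explicit seed drives every stage; no silent entropy
        self.simulation = dataclasses.replace(self.simulation, seed=self.seed)
        self.extraction = dataclasses.replace(self.extraction, seed=self.seed + 1)


def load_config(path: str | Path | None, seed: int | None = None) -> PipelineConfig:
    """Build a PipelineConfig from a YAML file; CLI seed overrides the file."""
    raw: dict = {}
    if path is not None:
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ValueError("config file must contain a mapping")
    sim = SimulationConfig(**raw.get("simulation", {}))
    ext = he.ExtractionParams(**raw.get("extraction", {}))
    ana = AnalysisParams(**raw.get("analysis", {}))
    top = {k: v for k, v in raw.items() if k in ("seed", "out_dir", "log_level")}
    if seed is not None:
        top["seed"] = seed
    return PipelineConfig(simulation=sim, extraction=ext, analysis=ana, **top)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class _Manifest:
    def __init__(self, root: Path):
        self.root = root
        self.entries: list[dict] = []

    def add(self, path: Path) -> None:
        self.entries.append(
            {
                "path": str(path.relative_to(self.root)),
                "sha256": _sha256(path),
                "bytes": path.stat().st_size,
            }
        )

    def write(self) -> Path:
        out = self.root / "manifest.json"
        out.write_text(json.dumps({"artifacts": self.entries}, indent=2))
        return out


def write_simulation(sim, out: Path) -> list[str]:
    """Write every simulated artifact to ``out``; returns the file names."""
    out.mkdir(parents=True, exist_ok=True)
    sim.linkage_map.to_csv(out / "linkage_map.csv")
    sim.genotypes.to_csv(out / "genotypes.csv")
    sim.phenotypes.to_csv(out / "phenotypes_ground.csv", index=False)
    sim.ground_truth.plot_heights.to_csv(out / "true_plot_heights.csv", index=False)
    sim.ground_truth.genetic_values.to_csv(out / "true_genetic_values.csv", index=False)
    names = [
        "linkage_map.csv", "genotypes.csv", "phenotypes_ground.csv",
        "true_plot_heights.csv", "true_genetic_values.csv",
    ]
    for site, layout in sim.layouts.items():
        layout.plots_to_geojson(out / f"plots_{site}.geojson")
        layout.bare_ground_to_geojson(out / f"bare_ground_{site}.geojson")
        sim.dsm[site].to_geotiff(out / f"dsm_{site}.tif")
        sim.ground_truth.true_dtm[site].to_geotiff(out / f"true_dtm_{site}.tif")
        names += [
            f"plots_{site}.geojson", f"bare_ground_{site}.geojson",
            f"dsm_{site}.tif", f"true_dtm_{site}.tif",
        ]
    return names


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage in order; returns a summary dict with key results."""
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(out)
    logger.info("pipeline config: %s", dataclasses.asdict(config))

    # ---- stage 1: simulate the field -----------------------------------
    sim = simulate_field(config.simulation)
    for name in sorted(write_simulation(sim, out)):
        manifest.add(out / name)

    # ---- stage 2-3: DTM, PHM and height extraction per site -------------
    uav_tables = []
    dtm_stats = {}
    for site, layout in sim.layouts.items():
        dsm = sim.dsm[site]
        points = te.sample_ground_elevations(dsm, layout.bare_ground)
        dtm, quality = te.interpolate_dtm(points, dsm)
        te.control_points_frame(points).to_csv(
            out / f"control_points_{site}.csv", index=False
        )
        dtm.to_geotiff(out / f"dtm_{site}.tif")
        quality.to_geotiff(out / f"dtm_quality_{site}.tif")
        dtm_stats[site] = te.dtm_error(dtm, sim.ground_truth.true_dtm[site])
        phm = he.compute_phm(dsm, dtm)
        phm.to_geotiff(out / f"phm_{site}.tif")
        table, _ = he.extract_all(
            dsm, dtm, layout, config.extraction, stage=config.simulation.stage
        )
        uav_tables.append(table)
        for name in (
            f"control_points_{site}.csv", f"dtm_{site}.tif",
            f"dtm_quality_{site}.tif", f"phm_{site}.tif",
        ):
            manifest.add(out / name)
    uav = pd.concat(uav_tables, ignore_index=True)
    uav.to_csv(out / "heights_uav.csv", index=False)
    manifest.add(out / "heights_uav.csv")

    # ---- stage 4: validation against ground truth -----------------------
    merged = uav.merge(
        sim.phenotypes.rename(columns={"value_cm": "ground_cm"})[
            ["genotype_id", "site", "rep", "ground_cm"]
        ],
        on=["genotype_id", "site", "rep"],
    )
    report = vs.regress_validate(
        merged["value_cm"].to_numpy(), merged["ground_cm"].to_numpy()
    )
    elev = vs.bias_by_elevation(
        merged["value_cm"].to_numpy(), merged["ground_cm"].to_numpy()
    )
    pd.DataFrame([{**dataclasses.asdict(report), **elev, **{
        f"dtm_rmse_{s}_m": v["rmse_m"] for s, v in dtm_stats.items()
    }}]).to_csv(out / "validation_report.csv", index=False)
    manifest.add(out / "validation_report.csv")

    # ---- stage 5: variance components / heritability --------------------
    vc_rows = []
    for label, tab in (("uav", uav), ("ground", sim.phenotypes)):
        vc = vs.anova_variance_components(tab)
        vc_rows.append(
            {
                "source": label,
                **{k: v for k, v in dataclasses.asdict(vc).items() if k != "truncated"},
                "h2": vc.heritability(config.analysis.ge_divisor),
            }
        )
    vc_df = pd.DataFrame(vc_rows)
    vc_df.to_csv(out / "variance_components.csv", index=False)
    manifest.add(out / "variance_components.csv")

    # ---- stage 6: QTL scan (on DH line means, parents excluded) ---------
    dh = sim.phenotypes[~sim.phenotypes["genotype_id"].isin(PARENT_IDS)]
    dh_uav = uav[~uav["genotype_id"].isin(PARENT_IDS)]
    results = {}
    for label, tab in (("uav", dh_uav), ("ground", dh)):
        means = qg.line_means(tab)
        cof = qg.select_cofactors(
            sim.genotypes, means,
            config.analysis.cofactor_p_in, config.analysis.cofactor_p_out,
        )
        scan = qg.icim_scan(
            sim.genotypes, sim.linkage_map, means, cof,
            step_cm=config.analysis.scan_step_cm,
        )
        peaks = qg.qtl_peaks(scan, threshold=config.analysis.lod_threshold)
        scan.table.to_csv(out / f"qtl_scan_{label}.csv", index=False)
        pd.DataFrame([dataclasses.asdict(p) for p in peaks]).to_csv(
            out / f"qtl_peaks_{label}.csv", index=False
        )
        _plot_scan(scan, out / f"qtl_scan_{label}.png", config.analysis.lod_threshold)
        manifest.add(out / f"qtl_scan_{label}.csv")
        manifest.add(out / f"qtl_peaks_{label}.csv")
        results[label] = {"scan": scan, "peaks": peaks, "means": means}

    # ---- stage 7: genomic prediction ------------------------------------
    cv_rows = []
    for label in ("uav", "ground"):
        cv = qg.cross_validate(
            sim.genotypes, results[label]["means"],
            k=config.analysis.cv_k, repeats=config.analysis.cv_repeats,
            seed=config.seed + 10,
        )
        regions = [
            (p.chromosome, p.support_lo_cm, p.support_hi_cm)
            for p in results[label]["peaks"]
        ]
        excl = None
        if regions:
            excl = qg.marker_exclusion_experiment(
                sim.genotypes, sim.linkage_map, results[label]["means"],
                excluded_regions=regions,
                flank_cm=config.analysis.exclusion_flank_cm,
                k=config.analysis.cv_k, repeats=config.analysis.cv_repeats,
                seed=config.seed + 10,
            )
        cv_rows.append(
            {
                "source": label,
                "r_mean": cv.r_mean,
                "r_se": cv.r_se,
                "k": cv.k,
                "repeats": cv.repeats,
                "r_full": excl["r_full"] if excl else cv.r_mean,
                "r_excluded": excl["r_excluded"] if excl else float("nan"),
                "frac_repeats_reduced": (
                    excl["frac_repeats_reduced"] if excl else float("nan")
                ),
            }
        )
        results[label]["cv"] = cv
        results[label]["exclusion"] = excl
    pd.DataFrame(cv_rows).to_csv(out / "genomic_prediction.csv", index=False)
    manifest.add(out / "genomic_prediction.csv")

    manifest_path = manifest.write()
    logger.info("pipeline complete; manifest at %s", manifest_path)
    return {
        "manifest": str(manifest_path),
        "validation": report,
        "dtm_stats": dtm_stats,
        "variance_components": vc_df,
        "results": results,
        "out_dir": str(out),
    }


def _plot_scan(scan: qg.QtlScanResult, path: Path, threshold: float) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(9, 3))
    offset = 0.0
    ticks, labels = [], []
    for chrom, sub in scan.table.groupby("chromosome", sort=False):
        x = sub["position_cm"].to_numpy() + offset
        ax.plot(x, sub["lod"], lw=1)
        ticks.append(offset + sub["position_cm"].max() / 2)
        labels.append(chrom)
        offset = x.max() + 10
    ax.axhline(threshold, color="gray", ls="--", lw=0.8)
    ax.set_xticks(ticks, labels)
    ax.set_ylabel("LOD")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
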