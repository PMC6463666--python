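"""Synthetic wheat field generator with known ground truth.

Everything the phenotyping pipeline consumes is generated here: a linkage
map, a doubled-haploid (DH) population, a genetic architecture with two
major dwarfing loci plus polygenic background, balanced multi-site plot
phenotypes, a field layout, and rendered DSM/DTM raster pairs.  Because the
generator knows the true terrain, the true per-plot canopy heights and the
true genetic values, every downstream stage (terrain model, height
extraction, variance components, QTL scan, genomic prediction) can be tested
for recovery of known quantities.

Study design emulated by the defaults: 198 DH lines plus the two parents,
randomized complete blocks with 3 replicates at each of 2 sites, plots of
1.3 m x 3 m, rasters at 2.5 cm ground sampling distance.

Meiosis uses the Haldane map function (no crossover interference): the
recombination fraction between loci d centimorgans apart is
``r = (1 - exp(-2d/100)) / 2``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import box

from .layout import BareGroundFeature, FieldLayout, PlotFeature
from .raster import ElevationRaster

__all__ = [
    "LinkageMap",
    "GenotypeMatrix",
    "QtlLocus",
    "QtlSpec",
    "SimulationConfig",
    "GroundTruth",
    "SimulatedField",
    "haldane_r",
    "default_linkage_map",
    "make_linkage_map",
    "simulate_dh_population",
    "simulate_phenotypes",
    "make_field_layout",
    "render_field_dsm",
    "simulate_field",
]

PARENT_IDS = ("P1", "P2")


def haldane_r(d_cm: np.ndarray | float) -> np.ndarray | float:
    """Haldane recombination fraction for a map distance in centimorgans."""
    return (1.0 - np.exp(-2.0 * np.asarray(d_cm, dtype=float) / 100.0)) / 2.0


# --------------------------------------------------------------------- types
@dataclass(frozen=True)
class LinkageMap:
    """Ordered biallelic markers with centimorgan positions per chromosome."""

    marker_ids: tuple[str, ...]
    chromosomes: tuple[str, ...]
    positions_cm: np.ndarray  # float, parallel to marker_ids

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "positions_cm", np.asarray(self.positions_cm, dtype=float)
        )
        n = len(self.marker_ids)
        if n == 0:
            raise ValueError("linkage map must contain at least one marker")
        if len(self.chromosomes) != n or len(self.positions_cm) != n:
            raise ValueError("map fields must be parallel")
        if len(set(self.marker_ids)) != n:
            raise ValueError("marker ids must be unique")
        if np.any(self.positions_cm < 0):
            raise ValueError("map positions must be nonnegative")
        for chrom in self.chromosome_names:
            pos = self.positions_on(chrom)
            if np.any(np.diff(pos) < 0):
                raise ValueError(f"positions on {chrom} must be nondecreasing")

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    @property
    def chromosome_names(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.chromosomes:
            seen.setdefault(c)
        return list(seen)

    def indices_on(self, chrom: str) -> np.ndarray:
        return np.flatnonzero(np.asarray(self.chromosomes) == chrom)

    def positions_on(self, chrom: str) -> np.ndarray:
        return self.positions_cm[self.indices_on(chrom)]

    def nearest_marker(self, chrom: str, pos_cm: float) -> int:
        """Global index of the marker on ``chrom`` nearest to ``pos_cm``."""
        idx = self.indices_on(chrom)
        if idx.size == 0:
            raise ValueError(f"chromosome {chrom!r} absent from map")
        return int(idx[np.argmin(np.abs(self.positions_cm[idx] - pos_cm))])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "marker_id": self.marker_ids,
                "chromosome": self.chromosomes,
                "position_cm": self.positions_cm,
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "LinkageMap":
        df = pd.read_csv(path)
        return cls(
            marker_ids=tuple(df["marker_id"].astype(str)),
            chromosomes=tuple(df["chromosome"].astype(str)),
            positions_cm=df["position_cm"].to_numpy(float),
        )


@dataclass(frozen=True)
class GenotypeMatrix:
    """DH lines x biallelic markers; entries in {0, 1} (no heterozygotes)."""

    line_ids: tuple[str, ...]
    marker_ids: tuple[str, ...]
    values: np.ndarray  # (n_lines, n_markers) in {0, 1}

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=np.int8))
        if self.values.shape != (len(self.line_ids), len(self.marker_ids)):
            raise ValueError("genotype matrix shape must be lines x markers")
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("DH genotypes must be 0 or 1")

    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    def signed(self) -> np.ndarray:
        """{0,1} coding mapped to {-1,+1} (parental contrast)."""
        return self.values.astype(float) * 2.0 - 1.0

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            self.values, index=list(self.line_ids), columns=list(self.marker_ids)
        ).to_csv(path, index_label="line_id")

    @classmethod
    def from_csv(cls, path: str | Path) -> "GenotypeMatrix":
        df = pd.read_csv(path, index_col="line_id")
        return cls(
            line_ids=tuple(df.index.astype(str)),
            marker_ids=tuple(df.columns.astype(str)),
            values=df.to_numpy(),
        )


@dataclass(frozen=True)
class QtlLocus:
    chromosome: str
    position_cm: float
    effect_cm: float  # additive effect on the {-1,+1} allele contrast


@dataclass(frozen=True)
class QtlSpec:
    """Planted genetic architecture: major loci plus polygenic variance.

    The default mirrors a wheat DH population segregating for the two
    Green-Revolution dwarfing loci (Rht-B1 on 4B, Rht-D1 on 4D) and a minor
    growth locus on 6D, on top of a polygenic background.
    """

    loci: tuple[QtlLocus, ...] = (
        QtlLocus("4B", 60.0, -10.0),
        QtlLocus("4D", 75.0, -9.0),
        QtlLocus("6D", 40.0, 4.0),
    )
    polygenic_variance: float = 60.0  # cm^2

    def __post_init__(self) -> None:
        for q in self.loci:
            if not math.isfinite(q.effect_cm):
                raise ValueError("QTL effects must be finite")
        if self.polygenic_variance < 0:
            raise ValueError("polygenic variance must be >= 0")


@dataclass
class SimulationConfig:
    """All knobs of the synthetic study, with study-design defaults."""

    seed: int = 0
    # map grid
    n_chromosomes: int = 6
    chromosome_length_cm: float = 150.0
    marker_spacing_cm: float = 5.0
    # population / trial design
    n_lines: int = 198
    n_sites: int = 2
    n_reps: int = 3
    include_parents: bool = True
    # phenotype model (cm, cm^2)
    mean_height_cm: float = 85.0
    sigma_ge2: float = 24.0
    sigma_e2: float = 120.0
    sigma_site2: float = 25.0
    stage: str = "mid_grain_fill"
    # field geometry (m)
    plot_width_m: float = 1.3
    plot_length_m: float = 3.0
    alley_x_m: float = 0.4
    alley_y_m: float = 0.8
    n_plot_columns: int = 25
    # raster rendering
    gsd_m: float = 0.025
    sensor_noise_sd_m: float = 0.02
    terrain_amplitude_m: float = 0.5
    spike_fraction: float = 0.35
    spike_height_sd_m: float = 0.03
    canopy_deficit_frac: float = 0.10

    def __post_init__(self) -> None:
        for name in ("sigma_ge2", "sigma_e2", "sigma_site2"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not self.gsd_m > 0:
            raise ValueError("ground sampling distance must be positive")
        if not 0 < self.spike_fraction <= 1:
            raise ValueError("spike fraction must lie in (0, 1]")
        if not 0 <= self.canopy_deficit_frac < 1:
            raise ValueError("canopy deficit fraction must lie in [0, 1)")
        if self.sensor_noise_sd_m < 0 or self.spike_height_sd_m < 0:
            raise ValueError("noise standard deviations must be >= 0")

    @property
    def site_names(self) -> list[str]:
        return [f"site{i + 1}" for i in range(self.n_sites)]


@dataclass
class GroundTruth:
    """Oracle values for recovery tests: what the pipeline should find."""

    plot_heights: pd.DataFrame  # plot_id, genotype_id, site, rep, height_cm
    genetic_values: pd.DataFrame  # genotype_id, genetic_value_cm
    true_dtm: dict[str, ElevationRaster] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.plot_heights["height_cm"] <= 0).any():
            raise ValueError("true plot heights must be positive")


@dataclass
class SimulatedField:
    """Complete synthetic study: genetics, phenotypes, layouts and rasters."""

    config: SimulationConfig
    linkage_map: LinkageMap
    genotypes: GenotypeMatrix
    qtl: QtlSpec
    phenotypes: pd.DataFrame
    ground_truth: GroundTruth
    layouts: dict[str, FieldLayout]
    dsm: dict[str, ElevationRaster]


# ----------------------------------------------------------------- map & pop
_WHEAT_CHROMOSOMES = ("1A", "2B", "3A", "4B", "4D", "6D")


def make_linkage_map(
    n_chromosomes: int = 6,
    chromosome_length_cm: float = 150.0,
    marker_spacing_cm: float = 5.0,
    chromosome_names: tuple[str, ...] | None = None,
) -> LinkageMap:
    """Regular marker grid: equally spaced markers on each chromosome."""
    if chromosome_names is None:
        if n_chromosomes <= len(_WHEAT_CHROMOSOMES):
            chromosome_names = _WHEAT_CHROMOSOMES[:n_chromosomes]
        else:
            chromosome_names = tuple(f"chr{i + 1}" for i in range(n_chromosomes))
    positions = np.arange(0.0, chromosome_length_cm + 1e-9, marker_spacing_cm)
    ids, chroms, pos = [], [], []
    for c in chromosome_names:
        for p in positions:
            ids.append(f"{c}_{p:g}")
            chroms.append(c)
            pos.append(p)
    return LinkageMap(tuple(ids), tuple(chroms), np.array(pos))


def default_linkage_map(config: SimulationConfig | None = None) -> LinkageMap:
    cfg = config or SimulationConfig()
    return make_linkage_map(
        cfg.n_chromosomes, cfg.chromosome_length_cm, cfg.marker_spacing_cm
    )


def simulate_dh_population(
    linkage_map: LinkageMap, n_lines: int, seed: int | np.random.Generator = 0
) -> GenotypeMatrix:
    """Simulate DH genotypes: one recombinant gamete per line, then doubled.

    Gametes are generated chromosome by chromosome as a Markov chain along
    the marker order: the first allele is Bernoulli(1/2) and each subsequent
    allele switches parental phase with the Haldane recombination fraction
    for the adjacent-marker distance.
    """
    if linkage_map.n_markers == 0:
        raise ValueError("linkage map is empty")
    if n_lines < 2:
        raise ValueError("need at least 2 lines")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    geno = np.empty((n_lines, linkage_map.n_markers), dtype=np.int8)
    for chrom in linkage_map.chromosome_names:
        idx = linkage_map.indices_on(chrom)
        pos = linkage_map.positions_cm[idx]
        r = haldane_r(np.diff(pos))
        alleles = np.empty((n_lines, idx.size), dtype=np.int8)
        alleles[:, 0] = rng.random(n_lines) < 0.5
        if idx.size > 1:
            switches = rng.random((n_lines, idx.size - 1)) < r[None, :]
            # cumulative XOR of switch events propagates phase along the chromosome
            alleles[:, 1:] = alleles[:, [0]] ^ np.cumsum(switches, axis=1) % 2
        geno[:, idx] = alleles
    line_ids = tuple(f"DH{i + 1:03d}" for i in range(n_lines))
    return GenotypeMatrix(line_ids, linkage_map.marker_ids, geno)


# -------------------------------------------------------------- phenotypes
def genetic_values(
    genotypes: GenotypeMatrix,
    linkage_map: LinkageMap,
    qtl: QtlSpec,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """True genetic value per line: major-QTL contrasts + polygenic background.

    The polygenic background is marker-borne: every marker carries a small
    i.i.d. N(0, sigma_g^2 / p) effect on the signed coding, so that the
    background is in principle capturable by genome-wide marker regression
    (as it is for a real genotyped population).  The expected across-line
    variance of the background equals ``polygenic_variance``.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    s = genotypes.signed()
    g = np.zeros(genotypes.n_lines)
    for locus in qtl.loci:
        j = linkage_map.nearest_marker(locus.chromosome, locus.position_cm)
        g += locus.effect_cm * s[:, j]
    p = genotypes.values.shape[1]
    poly_effects = rng.normal(0.0, math.sqrt(qtl.polygenic_variance / p), size=p)
    g += s @ poly_effects
    return pd.DataFrame(
        {"genotype_id": list(genotypes.line_ids), "genetic_value_cm": g}
    )


def simulate_phenotypes(
    genotypes: GenotypeMatrix,
    linkage_map: LinkageMap,
    qtl: QtlSpec,
    config: SimulationConfig,
    seed: int | np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Balanced plot-level phenotypes for every genotype x site x rep cell.

    Plot value (cm) = mean + genetic value + site effect + GxE deviate +
    residual.  Parents (if included) enter as the two homozygous extremes of
    the marker panel.  Returns ``(phenotypes, genetic_values)``; the
    phenotype table carries ``source='ground'`` since these are the true
    plot heights the ground crew would measure.
    """
    for locus in qtl.loci:
        if locus.chromosome not in linkage_map.chromosome_names:
            raise ValueError(f"QTL chromosome {locus.chromosome!r} absent from map")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(config.seed if seed is None else seed)
    )
    gmat = genotypes
    if config.include_parents:
        p = len(genotypes.marker_ids)
        parent_rows = np.vstack([np.zeros(p, np.int8), np.ones(p, np.int8)])
        gmat = GenotypeMatrix(
            genotypes.line_ids + PARENT_IDS,
            genotypes.marker_ids,
            np.vstack([genotypes.values, parent_rows]),
        )
    gv = genetic_values(gmat, linkage_map, qtl, rng)
    sites = config.site_names
    site_effects = rng.normal(0.0, math.sqrt(config.sigma_site2), size=len(sites))
    n_g = len(gmat.line_ids)
    ge = rng.normal(0.0, math.sqrt(config.sigma_ge2), size=(n_g, len(sites)))
    rows = []
    g_arr = gv["genetic_value_cm"].to_numpy()
    for si, site in enumerate(sites):
        for rep in range(1, config.n_reps + 1):
            eps = rng.normal(0.0, math.sqrt(config.sigma_e2), size=n_g)
            values = (
                config.mean_height_cm + g_arr + site_effects[si] + ge[:, si] + eps
            )
            for gi, gid in enumerate(gmat.line_ids):
                rows.append((gid, site, rep, config.stage, "ground", values[gi]))
    table = pd.DataFrame(
        rows, columns=["genotype_id", "site", "rep", "stage", "source", "value_cm"]
    )
    if (table["value_cm"] <= 0).any():
        raise ValueError(
            "simulated plot heights include nonpositive values; "
            "raise mean_height_cm or lower the variances"
        )
    return table, gv


# ------------------------------------------------------------------- layout
def make_field_layout(
    genotype_ids: list[str],
    config: SimulationConfig,
    site: str,
    seed: int | np.random.Generator = 0,
) -> FieldLayout:
    """Randomized complete block layout for one site.

    Replicate blocks are stacked south of each other; within a block the
    genotypes are shuffled onto a regular grid of ``n_plot_columns`` plots
    per row.  Bare-ground polygons are sketched in the alleys between plot
    rows, every third plot column, plus the field border — the spaces a
    ground operator would digitize for terrain estimation.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    w, h = config.plot_width_m, config.plot_length_m
    ax, ay = config.alley_x_m, config.alley_y_m
    ncol = config.n_plot_columns
    x0, y0 = 500000.0, 4000000.0  # arbitrary projected origin (m)
    plots: list[PlotFeature] = []
    n_g = len(genotype_ids)
    rows_per_block = int(np.ceil(n_g / ncol))
    row_offset = 0
    for rep in range(1, config.n_reps + 1):
        order = list(rng.permutation(genotype_ids))
        for k, gid in enumerate(order):
            i = row_offset + k // ncol
            j = k % ncol
            west = x0 + j * (w + ax)
            north = y0 - i * (h + ay)
            poly = box(west, north - h, west + w, north)
            plots.append(
                PlotFeature(
                    plot_id=f"{site}_r{rep}_{k + 1:03d}",
                    genotype_id=str(gid),
                    rep=rep,
                    site=site,
                    polygon=poly,
                )
            )
        row_offset += rows_per_block
    n_rows = row_offset
    # bare-ground polygons centered in the horizontal alleys (incl. margins)
    bare: list[BareGroundFeature] = []
    bw, bh = 0.6, 0.5
    k = 0
    for i in range(n_rows + 1):
        # alley above plot row i (i = n_rows is the bottom margin)
        yc = y0 - i * (h + ay) + ay / 2.0
        for j in sorted(set(range(0, ncol, 3)) | {ncol - 1}):
            xc = x0 + j * (w + ax) + w / 2.0
            bare.append(
                BareGroundFeature(
                    polygon_id=f"{site}_bg{k:04d}",
                    polygon=box(xc - bw / 2, yc - bh / 2, xc + bw / 2, yc + bh / 2),
                )
            )
            k += 1
    return FieldLayout(plots=plots, bare_ground=bare)


# ---------------------------------------------------------------- rendering
def _terrain_surface(
    xx: np.ndarray,
    yy: np.ndarray,
    bounds: tuple[float, float, float, float],
    amplitude: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Gentle farmland relief: tilted plane plus three low-frequency waves."""
    minx, miny, maxx, maxy = bounds
    lx = max(maxx - minx, 1e-9)
    ly = max(maxy - miny, 1e-9)
    xn = (xx - minx) / lx
    yn = (yy - miny) / ly
    sx, sy = rng.uniform(-0.2, 0.2, size=2) * amplitude
    z = 100.0 + sx * xn + sy * yn
    for a_frac in (0.25, 0.15, 0.10):
        fx, fy = rng.uniform(0.5, 1.5, size=2)
        phase = rng.uniform(0.0, 2.0 * np.pi)
        z += amplitude * a_frac * np.sin(2 * np.pi * (fx * xn + fy * yn) + phase)
    return z


def render_field_dsm(
    layout: FieldLayout,
    plot_heights: pd.DataFrame,
    config: SimulationConfig,
    seed: int | np.random.Generator = 0,
) -> tuple[ElevationRaster, ElevationRaster]:
    """Render one site's DSM together with its true DTM.

    The true DTM is a smooth terrain surface sampled on the pixel grid.  The
    DSM equals the terrain everywhere except inside plot polygons, where a
    canopy texture is drawn.  The canopy-top level is the true (ruler)
    height scaled down by ``canopy_deficit_frac`` — photogrammetric surface
    reconstruction undersamples thin spike tips, so the DSM systematically
    underestimates ruler height, more for taller plots.  A fraction
    ``spike_fraction`` of pixels are spike tops sitting at the canopy-top
    level minus a half-normal(spike sd) offset; the remaining pixels image
    lower leaves and canopy gaps, uniformly between 35% and 90% of the top
    level.  I.i.d. sensor noise is added to every DSM pixel; the true DTM
    stays noise-free.
    """
    if config.gsd_m > min(config.plot_width_m, config.plot_length_m):
        raise ValueError("ground sampling distance exceeds the plot size")
    heights = plot_heights.set_index("plot_id")["height_cm"]
    missing = [p.plot_id for p in layout.plots if p.plot_id not in heights.index]
    if missing:
        raise ValueError(f"plots without a true height: {missing[:5]} ...")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    margin = 1.5
    minx, miny, maxx, maxy = layout.bounds()
    minx, miny, maxx, maxy = minx - margin, miny - margin, maxx + margin, maxy + margin
    px = config.gsd_m
    nx = int(np.ceil((maxx - minx) / px))
    ny = int(np.ceil((maxy - miny) / px))
    template = ElevationRaster(
        data=np.zeros((ny, nx)), x_origin=minx, y_origin=maxy, pixel_size=px,
        crs=layout.crs,
    )
    xx, yy = np.meshgrid(template.x_centers(), template.y_centers())
    terrain = _terrain_surface(
        xx, yy, (minx, miny, maxx, maxy), config.terrain_amplitude_m, rng
    )
    dsm = terrain.copy()
    for plot in layout.plots:
        rows, cols = template.polygon_mask(plot.polygon)
        npix = rows.size
        if npix == 0:
            raise ValueError(f"plot {plot.plot_id} covers no pixels")
        h = float(heights.loc[plot.plot_id]) / 100.0  # cm -> m
        # the DSM's canopy-top level sits below the ruler height: thin spike
        # tips are undersampled by photogrammetry
        top = h * (1.0 - config.canopy_deficit_frac)
        is_spike = rng.random(npix) < config.spike_fraction
        canopy = np.empty(npix)
        canopy[is_spike] = top - np.abs(
            rng.normal(0.0, config.spike_height_sd_m, is_spike.sum())
        )
        n_low = npix - is_spike.sum()
        canopy[~is_spike] = top * rng.uniform(0.35, 0.90, n_low)
        dsm[rows, cols] = terrain[rows, cols] + canopy
    if config.sensor_noise_sd_m > 0:
        dsm = dsm + rng.normal(0.0, config.sensor_noise_sd_m, size=dsm.shape)
    return template.like(dsm), template.like(terrain)


# ------------------------------------------------------------- orchestration
def simulate_field(config: SimulationConfig) -> SimulatedField:
    """Generate the full synthetic study from one seed.

    Child seeds for the independent stochastic stages (meiosis, phenotypes,
    layout randomization, per-site rendering) are derived deterministically
    from ``config.seed`` so the whole object is reproducible bit for bit.
    """
    ss = np.random.SeedSequence(config.seed)
    seeds = ss.spawn(4 + config.n_sites)
    lmap = default_linkage_map(config)
    genotypes = simulate_dh_population(
        lmap, config.n_lines, np.random.default_rng(seeds[0])
    )
    qtl = QtlSpec()
    phenotypes, gv = simulate_phenotypes(
        genotypes, lmap, qtl, config, np.random.default_rng(seeds[1])
    )
    genotype_ids = list(genotypes.line_ids) + (
        list(PARENT_IDS) if config.include_parents else []
    )
    layouts: dict[str, FieldLayout] = {}
    dsms: dict[str, ElevationRaster] = {}
    true_dtms: dict[str, ElevationRaster] = {}
    layout_rng = np.random.default_rng(seeds[2])
    cell_height = phenotypes.set_index(["genotype_id", "site", "rep"])["value_cm"]
    height_frames = []
    for si, site in enumerate(config.site_names):
        layout = make_field_layout(genotype_ids, config, site, layout_rng)
        layouts[site] = layout
        site_heights = pd.DataFrame(
            {
                "plot_id": [p.plot_id for p in layout.plots],
                "genotype_id": [p.genotype_id for p in layout.plots],
                "site": site,
                "rep": [p.rep for p in layout.plots],
                "height_cm": [
                    cell_height.loc[(p.genotype_id, site, p.rep)]
                    for p in layout.plots
                ],
            }
        )
        height_frames.append(site_heights)
        dsm, true_dtm = render_field_dsm(
            layout, site_heights, config, np.random.default_rng(seeds[4 + si])
        )
        dsms[site] = dsm
        true_dtms[site] = true_dtm
    truth = GroundTruth(
        plot_heights=pd.concat(height_frames, ignore_index=True),
        genetic_values=gv,
        true_dtm=true_dtms,
    )
    return SimulatedField(
        config=config,
        linkage_map=lmap,
        genotypes=genotypes,
        qtl=qtl,
        phenotypes=phenotypes,
        ground_truth=truth,
        layouts=layouts,
        dsm=dsms,
    )
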