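"""QTL interval mapping and genomic prediction for DH-line means.

Interval mapping follows the two-stage inclusive composite interval mapping
(ICIM) scheme in regression form: a forward-backward stepwise scan first
selects background cofactor markers; the phenotype, adjusted for cofactors
outside the interval being tested, is then regressed on the expected QTL
genotype at each grid position.  For a doubled-haploid population the
expected genotype at a position between flanking markers follows from
Haldane recombination probabilities (no interference), matching the meiosis
model of the simulator.  LOD = (n/2) log10(RSS0 / RSS1).

Genomic prediction is ridge-regression BLUP: marker effects are shrunk by
``lambda = sigma_eps^2 / sigma_u^2`` with the variance ratio estimated by
restricted maximum likelihood on the spectral decomposition of the marker
covariance (a 1-D problem).  :class:`RidgeBLUP` is a scikit-learn style
estimator so it composes with sklearn model selection; the module-level
functions are thin wrappers.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.model_selection import KFold
from sklearn.utils.validation import check_is_fitted

from .synthetic_field import GenotypeMatrix, LinkageMap, haldane_r

__all__ = [
    "QtlScanResult",
    "QtlPeak",
    "PredictionResult",
    "line_means",
    "select_cofactors",
    "icim_scan",
    "qtl_peaks",
    "RidgeBLUP",
    "fit_gblup",
    "cross_validate",
    "marker_exclusion_experiment",
]

logger = logging.getLogger(__name__)

LOD_THRESHOLD = 2.5


# -------------------------------------------------------------- line means
def line_means(table: pd.DataFrame) -> pd.Series:
    """Arithmetic entry mean over sites x reps per genotype (cm)."""
    if table.empty:
        raise ValueError("empty phenotype table")
    return table.groupby("genotype_id")["value_cm"].mean()


def _aligned_phenotype(genotypes: GenotypeMatrix, y: pd.Series | np.ndarray) -> np.ndarray:
    if isinstance(y, pd.Series):
        missing = [l for l in genotypes.line_ids if l not in y.index]
        if missing:
            raise ValueError(f"phenotype missing for lines {missing[:5]} ...")
        return y.loc[list(genotypes.line_ids)].to_numpy(float)
    y = np.asarray(y, dtype=float)
    if y.shape != (genotypes.n_lines,):
        raise ValueError("phenotype length must equal the number of lines")
    return y


# ------------------------------------------------------- cofactor selection
def select_cofactors(
    genotypes: GenotypeMatrix,
    y: pd.Series | np.ndarray,
    p_in: float = 0.001,
    p_out: float = 0.002,
) -> list[int]:
    """Forward-backward stepwise marker selection (ICIM background control).

    Returns indices of the selected cofactor markers.  Entry requires a
    partial-F p-value <= ``p_in``; after each entry, selected markers whose
    partial p-value exceeds ``p_out`` are dropped.  Deterministic given the
    data; an empty result reduces the scan to plain interval mapping.
    """
    yv = _aligned_phenotype(genotypes, y)
    s = genotypes.signed()
    n, p = s.shape
    selected: list[int] = []

    def rss_of(cols: list[int]) -> float:
        X = np.column_stack([np.ones(n)] + [s[:, j] for j in cols])
        resid = yv - X @ np.linalg.lstsq(X, yv, rcond=None)[0]
        return float(resid @ resid)

    rss_current = rss_of([])
    while len(selected) < min(n - 2, p):
        best_j, best_rss = -1, np.inf
        for j in range(p):
            if j in selected:
                continue
            r = rss_of(selected + [j])
            if r < best_rss:
                best_rss, best_j = r, j
        df2 = n - len(selected) - 2
        if df2 <= 0 or best_rss <= 0:
            break
        f = (rss_current - best_rss) / (best_rss / df2)
        p_val = stats.f.sf(f, 1, df2)
        if p_val > p_in:
            break
        selected.append(best_j)
        rss_current = best_rss
        # backward elimination
        changed = True
        while changed and len(selected) > 1:
            changed = False
            worst_j, worst_p = -1, -1.0
            for j in selected:
                others = [k for k in selected if k != j]
                r_without = rss_of(others)
                df2b = n - len(selected) - 1
                fb = (r_without - rss_current) / (rss_current / df2b)
                pb = stats.f.sf(max(fb, 0.0), 1, df2b)
                if pb > worst_p:
                    worst_p, worst_j = pb, j
            if worst_p > p_out:
                selected.remove(worst_j)
                rss_current = rss_of(selected)
                changed = True
    return selected


# ------------------------------------------------------------ interval scan
def _expected_signed_genotype(
    s: np.ndarray, pos: np.ndarray, query_cm: float
) -> np.ndarray:
    """E[signed genotype] at ``query_cm`` for DH lines, from flanking markers.

    ``s`` is the (n_lines, n_markers_on_chromosome) signed genotype block and
    ``pos`` the marker positions on the chromosome.  At a marker the
    expectation collapses to the observed genotype.
    """
    j_right = int(np.searchsorted(pos, query_cm))
    if j_right == 0:
        r = haldane_r(pos[0] - query_cm)
        return s[:, 0] * (1.0 - 2.0 * r)
    if j_right >= pos.size:
        r = haldane_r(query_cm - pos[-1])
        return s[:, -1] * (1.0 - 2.0 * r)
    j_left = j_right - 1
    if np.isclose(pos[j_left], query_cm):
        return s[:, j_left].copy()
    r_l = float(haldane_r(query_cm - pos[j_left]))
    r_r = float(haldane_r(pos[j_right] - query_cm))
    r_t = r_l + r_r - 2.0 * r_l * r_r
    s1, s2 = s[:, j_left], s[:, j_right]
    same = s1 == s2
    z = np.empty(s1.shape, dtype=float)
    c_same = ((1 - r_l) * (1 - r_r) - r_l * r_r) / (1 - r_t)
    c_diff = ((1 - r_l) * r_r - r_l * (1 - r_r)) / r_t
    z[same] = s1[same] * c_same
    z[~same] = s1[~same] * c_diff
    return z


@dataclass
class QtlScanResult:
    """Genome scan profile plus the data needed for joint peak summaries."""

    table: pd.DataFrame  # chromosome, position_cm, lod, effect_cm, pve_pct
    cofactors: list[int]
    step_cm: float
    _signed: np.ndarray = field(repr=False, default=None)
    _y: np.ndarray = field(repr=False, default=None)
    _map: LinkageMap = field(repr=False, default=None)

    def max_lod(self) -> float:
        return float(self.table["lod"].max())


def icim_scan(
    genotypes: GenotypeMatrix,
    linkage_map: LinkageMap,
    y: pd.Series | np.ndarray,
    cofactors: list[int] | None = None,
    step_cm: float = 1.0,
    cofactor_window_cm: float = 10.0,
) -> QtlScanResult:
    """Adjusted-phenotype interval scan over the whole map.

    At each grid position the phenotype is adjusted by the selected cofactors
    except those within ``cofactor_window_cm`` of the position on the same
    chromosome (so a cofactor cannot absorb the signal of the locus being
    tested), then regressed on the expected signed QTL genotype.  PVE is
    expressed against the total phenotypic variance of the unadjusted line
    means.
    """
    if tuple(genotypes.marker_ids) != tuple(linkage_map.marker_ids):
        raise ValueError("genotype columns and map markers are not aligned")
    yv = _aligned_phenotype(genotypes, y)
    s = genotypes.signed()
    n = s.shape[0]
    cof = list(cofactors) if cofactors is not None else []
    ss_tot = float(np.sum((yv - yv.mean()) ** 2))
    # full-model cofactor coefficients, reused for every adjustment
    if cof:
        Xc = np.column_stack([np.ones(n)] + [s[:, j] for j in cof])
        beta = np.linalg.lstsq(Xc, yv, rcond=None)[0]
    rows = []
    chroms = np.asarray(linkage_map.chromosomes)
    for chrom in linkage_map.chromosome_names:
        idx = linkage_map.indices_on(chrom)
        pos = linkage_map.positions_cm[idx]
        s_chr = s[:, idx]
        length = pos[-1] - pos[0]
        if step_cm > length > 0:
            warnings.warn(
                f"scan step {step_cm} cM exceeds chromosome {chrom} length; "
                "evaluating at the midpoint only",
                stacklevel=2,
            )
            grid = np.array([pos[0] + length / 2.0])
        else:
            grid = np.arange(pos[0], pos[-1] + step_cm / 2.0, step_cm)
        for q in grid:
            y_adj = yv
            if cof:
                keep = np.ones(len(cof), dtype=bool)
                for kk, j in enumerate(cof):
                    if chroms[j] == chrom and abs(
                        linkage_map.positions_cm[j] - q
                    ) <= cofactor_window_cm:
                        keep[kk] = False
                adj = np.zeros(n)
                for kk, j in enumerate(cof):
                    if keep[kk]:
                        adj = adj + beta[kk + 1] * s[:, j]
                y_adj = yv - adj  # intercept is refit by centering below
            z = _expected_signed_genotype(s_chr, pos, float(q))
            yc = y_adj - y_adj.mean()
            rss0 = float(yc @ yc)
            zc = z - z.mean()
            denom = float(zc @ zc)
            if denom < 1e-12:
                lod, effect, pve = 0.0, 0.0, 0.0
            else:
                b = float(zc @ yc) / denom
                resid = yc - b * zc
                rss1 = float(resid @ resid)
                lod = max(0.0, (n / 2.0) * np.log10(rss0 / rss1)) if rss1 > 0 else np.inf
                effect = b
                pve = 100.0 * max(rss0 - rss1, 0.0) / ss_tot if ss_tot > 0 else 0.0
            rows.append((chrom, float(q), lod, effect, min(pve, 100.0)))
    table = pd.DataFrame(
        rows, columns=["chromosome", "position_cm", "lod", "effect_cm", "pve_pct"]
    )
    return QtlScanResult(
        table=table, cofactors=cof, step_cm=step_cm, _signed=s, _y=yv,
        _map=linkage_map,
    )


@dataclass(frozen=True)
class QtlPeak:
    chromosome: str
    position_cm: float
    lod: float
    effect_cm: float
    pve_pct: float
    support_lo_cm: float
    support_hi_cm: float
    nearest_marker: str


def qtl_peaks(
    scan: QtlScanResult,
    threshold: float = LOD_THRESHOLD,
    min_separation_cm: float = 20.0,
) -> list[QtlPeak]:
    """Declare QTL: local scan maxima above threshold with 1-LOD supports.

    Peaks on the same chromosome whose 1-LOD support intervals overlap, or
    whose positions are closer than ``min_separation_cm``, are treated as one
    QTL (the higher peak is kept).  Ties on LOD break to the leftmost
    position.  Per-peak PVE is recomputed from the joint regression of the
    phenotype on all peak-nearest markers.
    """
    peaks: list[QtlPeak] = []
    for chrom, sub in scan.table.groupby("chromosome", sort=False):
        lod = sub["lod"].to_numpy()
        pos = sub["position_cm"].to_numpy()
        eff = sub["effect_cm"].to_numpy()
        order = np.argsort(-lod, kind="stable")  # stable: leftmost wins ties
        claimed = np.zeros(lod.size, dtype=bool)
        chrom_peaks: list[tuple[int, tuple[float, float]]] = []
        for i in order:
            if lod[i] < threshold or claimed[i]:
                continue
            is_local_max = (i == 0 or lod[i] >= lod[i - 1]) and (
                i == lod.size - 1 or lod[i] >= lod[i + 1]
            )
            if not is_local_max:
                continue
            # 1-LOD support: contiguous run around i with lod >= lod[i] - 1
            lo = i
            while lo > 0 and lod[lo - 1] >= lod[i] - 1.0:
                lo -= 1
            hi = i
            while hi < lod.size - 1 and lod[hi + 1] >= lod[i] - 1.0:
                hi += 1
            support = (pos[lo], pos[hi])
            merged = False
            for k, (pi, (slo, shi)) in enumerate(chrom_peaks):
                if (
                    support[0] <= shi
                    and support[1] >= slo
                ) or abs(pos[i] - pos[pi]) < min_separation_cm:
                    merged = True  # same QTL as an already-declared higher peak
                    break
            if merged:
                continue
            chrom_peaks.append((i, support))
            claimed[lo : hi + 1] = True
        for i, (slo, shi) in chrom_peaks:
            j = scan._map.nearest_marker(str(chrom), pos[i])
            peaks.append(
                QtlPeak(
                    chromosome=str(chrom),
                    position_cm=float(pos[i]),
                    lod=float(lod[i]),
                    effect_cm=float(eff[i]),
                    pve_pct=float(sub["pve_pct"].to_numpy()[i]),
                    support_lo_cm=float(slo),
                    support_hi_cm=float(shi),
                    nearest_marker=scan._map.marker_ids[j],
                )
            )
    peaks.sort(key=lambda p: (p.chromosome, p.position_cm))
    if len(peaks) >= 1 and scan._signed is not None:
        peaks = _joint_pve(peaks, scan)
    return peaks


def _joint_pve(peaks: list[QtlPeak], scan: QtlScanResult) -> list[QtlPeak]:
    """Per-peak PVE from the joint regression on peak-nearest markers."""
    y = scan._y
    n = y.size
    cols = [scan._map.marker_ids.index(p.nearest_marker) for p in peaks]
    X_full = np.column_stack([np.ones(n)] + [scan._signed[:, j] for j in cols])
    rss_full = _rss(X_full, y)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    out = []
    for k, p in enumerate(peaks):
        keep = [c for i, c in enumerate(cols) if i != k]
        X_red = np.column_stack([np.ones(n)] + [scan._signed[:, j] for j in keep])
        pve = 100.0 * max(_rss(X_red, y) - rss_full, 0.0) / ss_tot
        out.append(
            QtlPeak(
                chromosome=p.chromosome,
                position_cm=p.position_cm,
                lod=p.lod,
                effect_cm=p.effect_cm,
                pve_pct=float(min(pve, 100.0)),
                support_lo_cm=p.support_lo_cm,
                support_hi_cm=p.support_hi_cm,
                nearest_marker=p.nearest_marker,
            )
        )
    return out


def _rss(X: np.ndarray, y: np.ndarray) -> float:
    resid = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
    return float(resid @ resid)


# ------------------------------------------------------------------- GBLUP
class RidgeBLUP(BaseEstimator, RegressorMixin):
    """Ridge-regression BLUP of marker effects (rrBLUP / GBLUP).

    Model: ``y = mu + Z u + eps`` with ``u ~ N(0, sigma_u^2 I)`` on the
    centered signed marker coding, equivalent to ridge regression with
    ``lambda = sigma_eps^2 / sigma_u^2``.

    Parameters
    ----------
    shrinkage
        ``"reml"`` (default) estimates lambda by restricted maximum
        likelihood on a 1-D log-lambda grid with golden-section refinement;
        a float fixes lambda directly (0 gives OLS when it is well posed).

    Attributes (after fit)
    ----------------------
    mu_ : float — fixed intercept (the training mean; exact GLS solution).
    coef_ : ndarray (p,) — BLUP marker effects on the centered signed coding.
    lambda_ : float — shrinkage actually used.
    sigma_u2_, sigma_e2_ : float — REML variance components (REML mode only).
    """

    def __init__(self, shrinkage: str | float = "reml"):
        self.shrinkage = shrinkage

    # ------------------------------------------------------------- fitting
    def fit(self, X: np.ndarray, y: np.ndarray) -> "RidgeBLUP":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2 or y.shape != (X.shape[0],):
            raise ValueError("X must be (n, p) and y (n,)")
        if X.shape[0] < 2:
            raise ValueError("need at least 2 lines")
        Z = self._signed(X)
        self.col_means_ = Z.mean(axis=0)
        Zc = Z - self.col_means_
        self.mu_ = float(y.mean())
        yc = y - self.mu_
        n, p = Zc.shape
        if self.shrinkage == "reml":
            lam, su2, se2 = _reml_lambda(Zc, yc)
            self.lambda_ = lam
            self.sigma_u2_ = su2
            self.sigma_e2_ = se2
        else:
            self.lambda_ = float(self.shrinkage)
            if self.lambda_ < 0:
                raise ValueError("fixed lambda must be >= 0")
        lam = self.lambda_
        if lam == 0.0:
            if n <= p or np.linalg.matrix_rank(Zc) < p:
                raise ValueError("lambda = 0 requires full-rank Zc with n > p")
            self.coef_ = np.linalg.lstsq(Zc, yc, rcond=None)[0]
        elif p <= n:
            self.coef_ = np.linalg.solve(
                Zc.T @ Zc + lam * np.eye(p), Zc.T @ yc
            )
        else:
            alpha = np.linalg.solve(Zc @ Zc.T + lam * np.eye(n), yc)
            self.coef_ = Zc.T @ alpha
        self.n_features_in_ = p
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        check_is_fitted(self, "coef_")
        Z = self._signed(np.asarray(X, dtype=float)) - self.col_means_
        return self.mu_ + Z @ self.coef_

    @staticmethod
    def _signed(X: np.ndarray) -> np.ndarray:
        """Map {0,1} coding to the signed parental contrast; pass through
        data that is already signed."""
        vals = np.unique(X)
        if np.all(np.isin(vals, (0.0, 1.0))):
            return X * 2.0 - 1.0
        return X


def _reml_lambda(Zc: np.ndarray, yc: np.ndarray) -> tuple[float, float, float]:
    """REML estimate of lambda = sigma_e^2 / sigma_u^2 via the spectrum of
    Zc Zc'.  Falls back to lambda = p (loudly) if no interior optimum exists.
    """
    n, p = Zc.shape
    A = Zc @ Zc.T
    d, U = np.linalg.eigh(A)
    d = np.clip(d, 0.0, None)
    # the all-ones direction is in the null space (columns are centered);
    # REML removes it together with the intercept
    ones = np.ones(n) / np.sqrt(n)
    k_drop = int(np.argmax(np.abs(U.T @ ones)))
    keep = np.arange(n) != k_drop
    eta = (U.T @ yc)[keep]
    dk = d[keep]
    m = n - 1  # residual degrees of freedom after the intercept

    def neg_restricted_ll(log_lam: float) -> float:
        lam = 10.0**log_lam
        w = dk + lam
        quad = float(np.sum(eta**2 / w))
        return 0.5 * (m * np.log(quad) + float(np.sum(np.log(w))))

    grid = np.linspace(-6.0, 9.0, 61)
    vals = np.array([neg_restricted_ll(g) for g in grid])
    i = int(np.argmin(vals))
    if i == 0 or i == len(grid) - 1:
        logger.warning(
            "REML failed to bracket an interior optimum; falling back to "
            "lambda = p = %d", p,
        )
        lam = float(p)
    else:
        res = optimize.minimize_scalar(
            neg_restricted_ll,
            bracket=(grid[i - 1], grid[i], grid[i + 1]),
            method="brent",
        )
        lam = float(10.0**res.x)
    su2 = float(np.sum(eta**2 / (dk + lam)) / m)
    se2 = lam * su2
    return lam, su2, se2


def fit_gblup(
    genotypes: GenotypeMatrix,
    y: pd.Series | np.ndarray,
    shrinkage: str | float = "reml",
) -> RidgeBLUP:
    """Fit ridge BLUP on a genotype matrix; thin wrapper over RidgeBLUP."""
    yv = _aligned_phenotype(genotypes, y)
    return RidgeBLUP(shrinkage=shrinkage).fit(genotypes.values.astype(float), yv)


# --------------------------------------------------------- cross-validation
@dataclass
class PredictionResult:
    accuracies: np.ndarray  # per-repeat pooled correlations
    k: int
    repeats: int
    seed: int
    predictions: pd.DataFrame  # first repeat: line_id, observed, predicted

    @property
    def r_mean(self) -> float:
        return float(np.mean(self.accuracies))

    @property
    def r_se(self) -> float:
        if len(self.accuracies) < 2:
            return float("nan")
        return float(np.std(self.accuracies, ddof=1) / np.sqrt(len(self.accuracies)))


def _cv_accuracy(
    X: np.ndarray, yv: np.ndarray, folds: list[tuple[np.ndarray, np.ndarray]],
    shrinkage: str | float,
) -> tuple[float, np.ndarray]:
    """One repeat: refit per fold (REML included), pool, correlate.

    Observed and predicted values are centered within each test fold before
    pooling: the per-fold prediction intercept is the training mean, which is
    anti-correlated with the held-out fold's mean, and pooling without
    centering would bias the null accuracy below zero.  Folds too small to
    center (leave-one-out) are pooled as-is.
    """
    pred = np.empty_like(yv)
    yc_parts, pc_parts = [], []
    for train, test in folds:
        model = RidgeBLUP(shrinkage=shrinkage).fit(X[train], yv[train])
        pred[test] = model.predict(X[test])
        if test.size >= 3:
            yc_parts.append(yv[test] - yv[test].mean())
            pc_parts.append(pred[test] - pred[test].mean())
    if yc_parts:
        yc = np.concatenate(yc_parts)
        pc = np.concatenate(pc_parts)
    else:  # leave-one-out style folds
        yc, pc = yv - yv.mean(), pred - pred.mean()
    r = float(np.corrcoef(yc, pc)[0, 1]) if np.ptp(pc) > 0 else 0.0
    return r, pred


def cross_validate(
    genotypes: GenotypeMatrix,
    y: pd.Series | np.ndarray,
    k: int = 5,
    repeats: int = 20,
    seed: int = 0,
    shrinkage: str | float = "reml",
) -> PredictionResult:
    """Repeated k-fold cross-validated prediction accuracy.

    Every line is predicted exactly once per repeat from models fitted on the
    other folds; accuracy is the pooled observed-predicted correlation within
    a repeat, averaged over repeats.  Deterministic given the seed.
    """
    yv = _aligned_phenotype(genotypes, y)
    n = yv.size
    if k > n:
        raise ValueError("k cannot exceed the number of lines")
    X = genotypes.values.astype(float)
    rs = np.random.SeedSequence(seed).generate_state(repeats)
    accuracies = []
    first_pred: np.ndarray | None = None
    for rep in range(repeats):
        kf = KFold(n_splits=k, shuffle=True, random_state=int(rs[rep] % 2**31))
        folds = list(kf.split(X))
        r, pred = _cv_accuracy(X, yv, folds, shrinkage)
        accuracies.append(r)
        if first_pred is None:
            first_pred = pred
    predictions = pd.DataFrame(
        {
            "line_id": list(genotypes.line_ids),
            "observed": yv,
            "predicted": first_pred,
        }
    )
    return PredictionResult(
        accuracies=np.asarray(accuracies), k=k, repeats=repeats, seed=seed,
        predictions=predictions,
    )


def marker_exclusion_experiment(
    genotypes: GenotypeMatrix,
    linkage_map: LinkageMap,
    y: pd.Series | np.ndarray,
    excluded_regions: list[tuple[str, float, float]] | None = None,
    excluded_chromosomes: list[str] | None = None,
    flank_cm: float = 10.0,
    k: int = 5,
    repeats: int = 20,
    seed: int = 0,
    shrinkage: str | float = "reml",
) -> dict:
    """Paired comparison: CV accuracy with all markers vs QTL-region markers removed.

    Regions are (chromosome, low cM, high cM) support intervals, widened by
    ``flank_cm`` on both sides; whole chromosomes can be excluded instead.
    Both arms run on identical fold partitions so the difference is paired.
    """
    yv = _aligned_phenotype(genotypes, y)
    chroms = np.asarray(linkage_map.chromosomes)
    pos = linkage_map.positions_cm
    excluded = np.zeros(linkage_map.n_markers, dtype=bool)
    for region in excluded_regions or []:
        c, lo, hi = region
        excluded |= (chroms == c) & (pos >= lo - flank_cm) & (pos <= hi + flank_cm)
    for c in excluded_chromosomes or []:
        excluded |= chroms == c
    if (~excluded).sum() < 10:
        raise ValueError("exclusion must leave at least 10 markers")
    X_full = genotypes.values.astype(float)
    X_excl = X_full[:, ~excluded]
    rs = np.random.SeedSequence(seed).generate_state(repeats)
    r_full, r_excl = [], []
    for rep in range(repeats):
        kf = KFold(n_splits=k, shuffle=True, random_state=int(rs[rep] % 2**31))
        folds = list(kf.split(X_full))
        r_full.append(_cv_accuracy(X_full, yv, folds, shrinkage)[0])
        r_excl.append(_cv_accuracy(X_excl, yv, folds, shrinkage)[0])
    r_full = np.asarray(r_full)
    r_excl = np.asarray(r_excl)
    diff = r_full - r_excl
    return {
        "r_full": float(r_full.mean()),
        "r_excluded": float(r_excl.mean()),
        "paired_diff_mean": float(diff.mean()),
        "paired_diffs": diff,
        "n_excluded_markers": int(excluded.sum()),
        "frac_repeats_reduced": float(np.mean(diff > 0)),
    }
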