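"""Validation statistics and quantitative-genetic variance components.

Two jobs live here:

* agreement between UAV-extracted and ground-measured plot heights
  (ordinary least squares fit, RMSE, mean bias, and an error split by canopy
  elevation);
* variance-component estimation for the balanced genotype x environment
  trial by expected-mean-squares (EMS) equating on the two-way ANOVA, with
  F-tests and broad-sense heritability on an entry-mean basis.

For a balanced design with ``g`` genotypes, ``e`` environments and ``r``
replicates, the EMS solutions are::

    sigma_eps^2 = MSE
    sigma_ge^2  = (MS_GE - MSE) / r
    sigma_g^2   = (MS_G - MS_GE) / (r * e)

with F-ratios F_G = MS_G / MS_GE, F_E = MS_E / MS_GE, F_GE = MS_GE / MSE
(genotype and environment tested against their interaction, the interaction
against the residual).  Negative EMS solutions are truncated to zero and
flagged.  Heritability follows the entry-mean formula

    h^2 = sigma_g^2 / (sigma_g^2 + sigma_ge^2 / r + sigma_eps^2 / (r e))

with the genotype x environment term divided by the replicate count; the
more common convention (divide by the number of environments ``e``) is
available behind ``ge_divisor="environments"``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ValidationReport",
    "VarianceComponents",
    "regress_validate",
    "bias_by_elevation",
    "anova_variance_components",
    "heritability",
]


@dataclass(frozen=True)
class ValidationReport:
    slope: float
    intercept: float
    r_squared: float
    rmse_cm: float
    bias_cm: float  # mean(ground - uav)
    n: int

    def __post_init__(self) -> None:
        if self.n < 3:
            raise ValueError("need at least 3 pairs")
        if not 0 <= self.r_squared <= 1 + 1e-12:
            raise ValueError("R^2 must lie in [0, 1]")
        if self.rmse_cm < 0:
            raise ValueError("RMSE must be >= 0")


@dataclass
class VarianceComponents:
    sigma_g2: float
    sigma_ge2: float
    sigma_e2: float  # residual
    n_reps: int
    n_envs: int
    n_genotypes: int
    f_genotype: float
    f_environment: float
    f_ge: float
    p_genotype: float
    p_environment: float
    p_ge: float
    truncated: tuple[str, ...] = ()

    def heritability(self, ge_divisor: str = "reps") -> float:
        return heritability(self, ge_divisor=ge_divisor)


def regress_validate(uav: np.ndarray, ground: np.ndarray) -> ValidationReport:
    """OLS fit of ground heights on UAV heights, with RMSE and mean bias.

    Values are paired per plot (same genotype, site and replicate).  RMSE and
    bias are computed on the raw differences ``ground - uav``, so a constant
    UAV underestimate shows up as a positive bias and contributes fully to
    the RMSE.
    """
    uav = np.asarray(uav, dtype=float)
    ground = np.asarray(ground, dtype=float)
    if uav.shape != ground.shape or uav.ndim != 1:
        raise ValueError("uav and ground must be paired 1-D arrays")
    if uav.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.ptp(uav) == 0:
        raise ValueError("UAV values have zero variance; regression undefined")
    fit = stats.linregress(uav, ground)
    diff = ground - uav
    return ValidationReport(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        rmse_cm=float(np.sqrt(np.mean(diff**2))),
        bias_cm=float(np.mean(diff)),
        n=int(uav.size),
    )


def bias_by_elevation(
    uav: np.ndarray, ground: np.ndarray
) -> dict[str, float]:
    """Mean absolute UAV error for short vs tall plots.

    Plots are split at the median ground-measured height; ties go to the
    short group.  Quantifies whether taller canopies are measured worse.
    """
    uav = np.asarray(uav, dtype=float)
    ground = np.asarray(ground, dtype=float)
    cut = float(np.median(ground))
    short = ground <= cut
    tall = ~short
    if short.sum() < 2 or tall.sum() < 2:
        raise ValueError("need at least 2 plots in each elevation group")
    abs_err = np.abs(uav - ground)
    return {
        "mae_short_cm": float(abs_err[short].mean()),
        "mae_tall_cm": float(abs_err[tall].mean()),
        "split_cm": cut,
        "n_short": int(short.sum()),
        "n_tall": int(tall.sum()),
    }


def anova_variance_components(table: pd.DataFrame) -> VarianceComponents:
    """Two-way genotype x environment ANOVA with EMS variance components.

    Expects a balanced long table with columns ``genotype_id``, ``site``,
    ``rep`` and ``value_cm``, one stage and one source at a time.  Sites play
    the role of environments.
    """
    required = {"genotype_id", "site", "rep", "value_cm"}
    if not required.issubset(table.columns):
        raise ValueError(f"table must have columns {sorted(required)}")
    for col in ("stage", "source"):
        if col in table.columns and table[col].nunique() > 1:
            raise ValueError(f"analyse one {col} at a time")
    envs = sorted(table["site"].unique())
    e = len(envs)
    if e < 2:
        raise ValueError(
            "genotype x environment variance is inestimable with a single "
            "environment; provide data from >= 2 sites"
        )
    counts = table.groupby(["genotype_id", "site"])["value_cm"].count()
    r = int(counts.iloc[0])
    if counts.nunique() != 1 or r < 2:
        raise ValueError(
            "unbalanced table: every genotype x site cell needs the same "
            "replicate count (>= 2); subset to a balanced design first"
        )
    g = table["genotype_id"].nunique()
    y = table["value_cm"].to_numpy(float)
    grand = y.mean()
    cell_means = table.groupby(["genotype_id", "site"])["value_cm"].mean()
    g_means = table.groupby("genotype_id")["value_cm"].mean()
    e_means = table.groupby("site")["value_cm"].mean()

    ss_g = e * r * ((g_means - grand) ** 2).sum()
    ss_e = g * r * ((e_means - grand) ** 2).sum()
    cell_dev = (
        cell_means
        - g_means.reindex(cell_means.index.get_level_values(0)).to_numpy()
        - e_means.reindex(cell_means.index.get_level_values(1)).to_numpy()
        + grand
    )
    ss_ge = r * (cell_dev**2).sum()
    keyed = table.set_index(["genotype_id", "site"])
    ss_err = (
        (keyed["value_cm"] - cell_means.reindex(keyed.index)) ** 2
    ).sum()

    df_g, df_e = g - 1, e - 1
    df_ge = df_g * df_e
    df_err = g * e * (r - 1)
    ms_g, ms_e, ms_ge, mse = ss_g / df_g, ss_e / df_e, ss_ge / df_ge, ss_err / df_err

    def _ratio(num: float, den: float) -> float:
        return float(num / den) if den > 0 else float("nan")

    f_g = _ratio(ms_g, ms_ge)
    f_e = _ratio(ms_e, ms_ge)
    f_ge = _ratio(ms_ge, mse)
    p_g = float(stats.f.sf(f_g, df_g, df_ge)) if np.isfinite(f_g) else float("nan")
    p_e = float(stats.f.sf(f_e, df_e, df_ge)) if np.isfinite(f_e) else float("nan")
    p_ge = float(stats.f.sf(f_ge, df_ge, df_err)) if np.isfinite(f_ge) else float("nan")

    truncated: list[str] = []
    sigma_eps = mse
    sigma_ge = (ms_ge - mse) / r
    if sigma_ge < 0:
        sigma_ge = 0.0
        truncated.append("sigma_ge2")
    sigma_g = (ms_g - ms_ge) / (r * e)
    if sigma_g < 0:
        sigma_g = 0.0
        truncated.append("sigma_g2")
    return VarianceComponents(
        sigma_g2=float(sigma_g),
        sigma_ge2=float(sigma_ge),
        sigma_e2=float(sigma_eps),
        n_reps=r,
        n_envs=e,
        n_genotypes=g,
        f_genotype=float(f_g),
        f_environment=float(f_e),
        f_ge=float(f_ge),
        p_genotype=p_g,
        p_environment=p_e,
        p_ge=p_ge,
        truncated=tuple(truncated),
    )


def heritability(vc: VarianceComponents, ge_divisor: str = "reps") -> float:
    """Broad-sense heritability on an entry-mean basis, clipped to [0, 1].

    ``ge_divisor='reps'`` divides the interaction variance by the replicate
    count (the printed formula this package follows by default);
    ``'environments'`` selects the common alternative convention.
    """
    if vc.n_reps < 1 or vc.n_envs < 1:
        raise ValueError("need r >= 1 and e >= 1")
    if min(vc.sigma_g2, vc.sigma_ge2, vc.sigma_e2) < 0:
        raise ValueError("variance components must be >= 0")
    if vc.sigma_g2 == vc.sigma_ge2 == vc.sigma_e2 == 0:
        raise ValueError("all variance components are zero; h^2 undefined")
    if ge_divisor == "reps":
        d = vc.n_reps
    elif ge_divisor == "environments":
        d = vc.n_envs
    else:
        raise ValueError("ge_divisor must be 'reps' or 'environments'")
    h2 = vc.sigma_g2 / (
        vc.sigma_g2 + vc.sigma_ge2 / d + vc.sigma_e2 / (vc.n_reps * vc.n_envs)
    )
    return float(min(max(h2, 0.0), 1.0))
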