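"""Funnel plot of region means against region size, with normal control limits.

Each region contributes a point (n, mean days to initiation), optionally
age/sex-adjusted by indirect standardization. Under the hypothesis that all
regions share a common patient-level outcome distribution with mean mu and
SD sigma, a region mean based on n patients lies within mu +/- z * sigma /
sqrt(n) with the nominal coverage of z; the 95% and 99.8% two-sided limits
(z = 1.95996, 3.09023) draw the funnel. sigma is the pooled within-region
patient-level SD (common-variance assumption, no overdispersion inflation).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

DEFAULT_LEVELS: tuple[float, ...] = (95.0, 99.8)


def z_for_level(level_pct: float) -> float:
    """Two-sided normal quantile for a coverage level given in percent."""
    if not 0 < level_pct < 100:
        raise ValueError("level must be in (0, 100)")
    return float(norm.ppf(0.5 + level_pct / 200))


def adjust_means(
    region_summary: pd.DataFrame, strata: pd.DataFrame
) -> pd.DataFrame:
    """Indirectly standardized region means for age-band x sex case mix.

    For region r with stratum weights w_rs (its own case mix) and pooled
    stratum means mu_s (each stratum's n-weighted mean across all regions):

        expected_r = sum_s w_rs * mu_s
        adjusted_r = observed_r - expected_r + mu   (mu = overall mean)

    A region whose case mix matches the pooled mix keeps its observed mean.
    Strata empty in a region are simply absent from its expectation (weights
    renormalize automatically since w_rs sum to 1 over populated cells).
    """
    if strata.empty:
        raise ValueError("no stratum means available for adjustment")
    pooled = (
        strata.assign(w=strata["n"] * strata["mean_days"])
        .groupby(["age_band", "sex"], observed=True)
        .agg(n=("n", "sum"), wsum=("w", "sum"))
    )
    pooled["mu_s"] = pooled["wsum"] / pooled["n"]
    mu = float(pooled["wsum"].sum() / pooled["n"].sum())

    s = strata.merge(
        pooled["mu_s"].reset_index(), on=["age_band", "sex"], how="left"
    )
    per_region = s.groupby("region_id").apply(
        lambda g: pd.Series(
            {
                "observed_mean": (g["n"] * g["mean_days"]).sum() / g["n"].sum(),
                "expected_mean": (g["n"] * g["mu_s"]).sum() / g["n"].sum(),
            }
        ),
        include_groups=False,
    )
    per_region["adjusted_mean"] = (
        per_region["observed_mean"] - per_region["expected_mean"] + mu
    )
    out = region_summary.merge(per_region.reset_index(), on="region_id", how="left")
    return out[
        ["region_id", "province", "n_eol", "observed_mean", "expected_mean",
         "adjusted_mean"]
    ]


@dataclass(frozen=True)
class FunnelSeries:
    """Everything needed to draw (or test) a funnel display."""

    overall_mean: float
    pooled_sd: float
    points: pd.DataFrame  # region_id, province, n_eol, mean_days (plotted value)
    levels: tuple[float, ...] = DEFAULT_LEVELS
    benchmark_line: float | None = None

    def limits(self, n, level_pct: float) -> tuple[np.ndarray, np.ndarray]:
        """Lower and upper control limits at a region size (vectorized)."""
        n = np.asarray(n, dtype=float)
        half = z_for_level(level_pct) * self.pooled_sd / np.sqrt(n)
        return self.overall_mean - half, self.overall_mean + half

    def outside(self, level_pct: float) -> pd.Series:
        """Boolean per region: plotted mean falls outside the level's limits."""
        lo, hi = self.limits(self.points["n_eol"].values, level_pct)
        m = self.points["mean_days"].values
        return pd.Series((m < lo) | (m > hi), index=self.points.index)

    def to_frame(self, n_grid: np.ndarray | None = None) -> pd.DataFrame:
        """Tabulated limit curves on a size grid (for CSV export)."""
        if n_grid is None:
            n_max = int(self.points["n_eol"].max()) if len(self.points) else 1000
            n_grid = np.unique(np.linspace(1, max(n_max, 2), 200).astype(int))
        out = pd.DataFrame({"n": n_grid})
        for lv in self.levels:
            lo, hi = self.limits(n_grid, lv)
            out[f"lower_{lv:g}"] = lo
            out[f"upper_{lv:g}"] = hi
        out["overall_mean"] = self.overall_mean
        if self.benchmark_line is not None:
            out["benchmark"] = self.benchmark_line
        return out


def pooled_within_region_sd(region_summary: pd.DataFrame) -> float:
    """Common-variance estimate: sqrt of the df-weighted mean of region variances."""
    df = region_summary.loc[region_summary["n_eol"] >= 2].dropna(subset=["sd_days"])
    if df.empty:
        return 0.0
    dof = df["n_eol"] - 1
    return float(np.sqrt((dof * df["sd_days"] ** 2).sum() / dof.sum()))


def funnel_series(
    region_summary: pd.DataFrame,
    adjusted: pd.DataFrame | None = None,
    benchmark=None,
    levels: tuple[float, ...] = DEFAULT_LEVELS,
) -> FunnelSeries:
    """Assemble the funnel display series.

    Parameters
    ----------
    region_summary : DataFrame
        Region table with n_eol, mean_days, sd_days.
    adjusted : DataFrame, optional
        Output of :func:`adjust_means`; when given, adjusted means are
        plotted instead of observed means.
    benchmark : BenchmarkResult or float, optional
        Benchmark level to overlay.
    """
    df = region_summary.loc[region_summary["n_eol"] > 0].copy()
    if df.empty:
        raise ValueError("no plottable regions (all n_eol = 0)")
    if adjusted is not None:
        df = df.drop(columns=["mean_days"]).merge(
            adjusted[["region_id", "adjusted_mean"]].rename(
                columns={"adjusted_mean": "mean_days"}
            ),
            on="region_id",
        )
    mu = float((df["n_eol"] * df["mean_days"]).sum() / df["n_eol"].sum())
    sigma = pooled_within_region_sd(region_summary)
    if sigma == 0:
        warnings.warn("pooled SD is zero; control limits degenerate to the mean")
    bench = getattr(benchmark, "benchmark_mean", benchmark)
    return FunnelSeries(
        overall_mean=mu,
        pooled_sd=sigma,
        points=df[["region_id", "province", "n_eol", "mean_days"]].reset_index(
            drop=True
        ),
        levels=tuple(levels),
        benchmark_line=None if bench is None else float(bench),
    )


def render_funnel(series: FunnelSeries, out_path) -> None:
    """Render the funnel plot to a PNG/SVG file (deterministic for fixed input)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if series.points.empty:
        raise ValueError("empty funnel series; nothing to render")
    pts = series.points
    n_max = int(pts["n_eol"].max())
    grid = np.linspace(max(1, pts["n_eol"].min() * 0.8), n_max * 1.05, 400)

    fig, ax = plt.subplots(figsize=(8, 5))
    colors = {"BC": "#1b9e77", "NS": "#7570b3", "ON": "#d95f02"}
    for prov, g in pts.groupby("province"):
        ax.scatter(
            g["n_eol"], g["mean_days"], s=28, zorder=3,
            color=colors.get(prov, "grey"), label=prov,
        )
    styles = ["-", "--"]
    for style, lv in zip(styles, series.levels):
        lo, hi = series.limits(grid, lv)
        ax.plot(grid, lo, style, color="black", lw=0.9, label=f"{lv:g}% limits")
        ax.plot(grid, hi, style, color="black", lw=0.9)
    ax.axhline(series.overall_mean, color="black", lw=2.2, label="overall mean")
    if series.benchmark_line is not None:
        ax.axhline(series.benchmark_line, color="red", lw=1.8, label="benchmark")
    ax.set_xlabel("Region EOL sub-cohort size (n)")
    ax.set_ylabel("Mean days to first EOL nursing visit")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
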