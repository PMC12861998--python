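"""Per-cycle evaluation metrics and across-replicate comparison statistics.

Metrics follow the standard long-term selection bookkeeping:

  * ρ — prediction accuracy, Pearson correlation of true vs predicted
    genetic values on the population where predictions act (the shelf).
  * R_t = Ḡ_t(parents) − Ḡ_0(population) — cumulative response to selection
    relative to the base population, in founder genetic-SD units.
  * R_t^(%/yr) = (100 / t) · (Ḡ_t − Ḡ_0) / |Ḡ_0| — annualized relative
    response over the t-year horizon (50 years at the end of 10 cycles).
  * True variance components Va and Vaa, computed from the architecture-based
    additive and epistatic components (not REML estimates).
  * Relativized trajectories: each series expressed as a proportion of its
    cycle-0 value, so scenarios started from different base populations are
    comparable.

Scenario comparisons across progeny sizes use Welch's heteroscedastic one-way
ANOVA with an omega-squared effect size and Games–Howell pairwise tests
(Bonferroni-adjusted), computed through pingouin.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
import pingouin as pg

__all__ = [
    "CycleRecord",
    "ComparisonResult",
    "accuracy",
    "response",
    "annualized_response",
    "variance_components_true",
    "relativize",
    "omega_squared",
    "compare_sizes",
    "records_to_frame",
    "add_response_columns",
    "summarize_records",
]

RECORD_COLUMNS = [
    "replicate",
    "cycle",
    "year",
    "context",
    "progeny_size",
    "epistasis_ratio",
    "mean_G",
    "best_line_G",
    "Va",
    "Vaa",
    "accuracy",
    "parents_mean_G",
    "sigma_a2_hat",
    "sigma_aa2_hat",
    "sigma_e2_hat",
    "seed",
]


@dataclasses.dataclass
class CycleRecord:
    """One breeding cycle's metrics; the unit of all downstream statistics."""

    replicate: int
    cycle: int
    year: int
    context: str
    progeny_size: int
    epistasis_ratio: float
    mean_G: float
    best_line_G: float
    Va: float
    Vaa: float
    accuracy: float
    parents_mean_G: float
    sigma_a2_hat: float = np.nan
    sigma_aa2_hat: float = np.nan
    sigma_e2_hat: float = np.nan
    seed: int = -1

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclasses.dataclass
class ComparisonResult:
    welch: pd.DataFrame  # pingouin Welch ANOVA table
    omega_squared: float
    pairwise: pd.DataFrame  # Games–Howell with Bonferroni-adjusted p
    group_means: pd.Series


def accuracy(true_G: np.ndarray, predicted: np.ndarray) -> float:
    """Pearson correlation ρ between true and predicted genetic values."""
    true_G = np.asarray(true_G, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if len(true_G) != len(predicted) or len(true_G) < 3:
        raise ValueError("need equal-length vectors with at least 3 entries")
    if true_G.std() == 0 or predicted.std() == 0:
        warnings.warn("zero variance: accuracy undefined, returning NaN")
        return float("nan")
    return float(np.corrcoef(true_G, predicted)[0, 1])


def response(parents_mean_t: float, pop_mean_0: float) -> float:
    """Cumulative response R_t = Ḡ_t(parents) − Ḡ_0(population)."""
    return float(parents_mean_t - pop_mean_0)


def annualized_response(
    g_t: float, g_0: float, t_years: float, tol: float = 1e-9
) -> float:
    """Annualized relative response in %/yr; NaN when the baseline is ~0."""
    if abs(g_0) < tol:
        warnings.warn("baseline mean near zero: annualized response unstable")
        return float("nan")
    return float(100.0 / t_years * (g_t - g_0) / abs(g_0))


def variance_components_true(pop, arch) -> tuple[float, float]:
    """True Va and Vaa: variances of the architecture-based components."""
    from .trait_model import genetic_value

    real = genetic_value(pop, arch)
    return float(real.additive_component.var()), float(real.epistatic_component.var())


def relativize(
    series: np.ndarray, baseline: float | None = None, mode: str = "ratio"
) -> np.ndarray:
    """Express a per-cycle series relative to its cycle-0 value.

    ``mode="ratio"`` divides by the baseline (cycle 0 maps to 1);
    ``mode="difference"`` subtracts it (cycle 0 maps to 0).
    """
    series = np.asarray(series, dtype=float)
    b = float(series[0]) if baseline is None else float(baseline)
    if mode == "difference":
        return series - b
    if not np.isfinite(b) or b == 0:
        warnings.warn("zero/non-finite baseline: relativized series undefined")
        return np.full_like(series, np.nan)
    return series / b


def omega_squared(groups: list[np.ndarray]) -> float:
    """Omega-squared effect size ω² = (SSb − dfb·MSw) / (SSt + MSw).

    Negative estimates (possible under the null) are truncated at 0.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    k = len(groups)
    ns = np.array([len(g) for g in groups])
    grand = np.concatenate(groups)
    ssb = float(sum(n * (g.mean() - grand.mean()) ** 2 for n, g in zip(ns, groups)))
    ssw = float(sum(((g - g.mean()) ** 2).sum() for g in groups))
    msw = ssw / (ns.sum() - k)
    sst = ssb + ssw
    om = (ssb - (k - 1) * msw) / (sst + msw)
    return float(max(om, 0.0))


def compare_sizes(responses_by_size: dict[int, np.ndarray]) -> ComparisonResult:
    """Welch ANOVA + ω² + Games–Howell (Bonferroni) across progeny sizes."""
    if len(responses_by_size) < 2:
        raise ValueError("need at least two progeny-size groups")
    for size, vals in responses_by_size.items():
        if len(vals) < 3:
            raise ValueError(f"group {size} has fewer than 3 replicates")
    df = pd.DataFrame(
        {
            "size": np.concatenate(
                [[s] * len(v) for s, v in responses_by_size.items()]
            ),
            "value": np.concatenate(list(responses_by_size.values())),
        }
    )
    welch = pg.welch_anova(data=df, dv="value", between="size")
    gh = pg.pairwise_gameshowell(data=df, dv="value", between="size")
    m = len(gh)
    gh = gh.assign(pval_bonf=np.minimum(gh["pval"].to_numpy() * m, 1.0))
    om = omega_squared(list(responses_by_size.values()))
    means = df.groupby("size")["value"].mean()
    return ComparisonResult(welch=welch, omega_squared=om, pairwise=gh, group_means=means)


def records_to_frame(records: list[CycleRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.to_dict() for r in records], columns=RECORD_COLUMNS)


def add_response_columns(df: pd.DataFrame) -> pd.DataFrame:
    """Attach R_t, annualized %/yr and relativized trajectories per run.

    The baseline Ḡ_0 is the cycle-0 population mean of each
    (context, size, epistasis, replicate) run; the Ḡ_t series in both response
    formulas is the parents' mean, so cumulative and annualized responses
    describe the same trajectory.
    """
    df = df.sort_values(["context", "progeny_size", "epistasis_ratio", "replicate", "cycle"])
    keys = ["context", "progeny_size", "epistasis_ratio", "replicate"]

    def _per_run(run: pd.DataFrame) -> pd.DataFrame:
        base = run.loc[run["cycle"] == 0].iloc[0]
        g0 = base["mean_G"]
        run = run.copy()
        run["response"] = run["parents_mean_G"] - g0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            run["response_pct_yr"] = [
                annualized_response(g, g0, y) if y > 0 else 0.0
                for g, y in zip(run["parents_mean_G"], run["year"])
            ]
        for col in ("mean_G", "best_line_G", "Va", "Vaa"):
            b = base[col]
            run[f"{col}_rel"] = run[col] / b if b != 0 else np.nan
        return run

    out = df.groupby(keys, group_keys=False)[df.columns].apply(_per_run)
    return out.reset_index(drop=True)


def summarize_records(df: pd.DataFrame) -> pd.DataFrame:
    """Per-scenario, per-cycle mean ± sd of the headline metrics."""
    df = add_response_columns(df)
    keys = ["context", "progeny_size", "epistasis_ratio", "cycle", "year"]
    agg = df.groupby(keys).agg(
        n_replicates=("replicate", "nunique"),
        mean_G=("mean_G", "mean"),
        response_mean=("response", "mean"),
        response_sd=("response", "std"),
        response_pct_yr_mean=("response_pct_yr", "mean"),
        response_pct_yr_sd=("response_pct_yr", "std"),
        accuracy_mean=("accuracy", "mean"),
        accuracy_sd=("accuracy", "std"),
        Va_mean=("Va", "mean"),
        Vaa_mean=("Vaa", "mean"),
    )
    return agg.reset_index()
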