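"""Protein-family richness: analytic and Monte-Carlo rarefaction, and the
regression of richness on the fluid-mixing proxy log10(SO4/Cl).

Rarefaction subsamples proteins *without replacement* and counts the distinct
families hit, the convention of standard ecological software.  The analytic
companion is the hypergeometric expectation

    E[S_d] = sum_f [ 1 - C(N - N_f, d) / C(N, d) ]

with N the metagenome's total protein count, N_f family f's count, and d the
subsampling depth; binomial coefficients are evaluated in log space.

High SO4(2-)/Cl(-) spring waters reflect vapor-phase input (sulfide-derived
sulfate) mixing with meteoric water; low ratios reflect the deep chloride-rich
hydrothermal reservoir.  The regression quantifies how protein-family richness
tracks this mixing axis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import gammaln

from .exceptions import (
    DegenerateDesignError,
    InsufficientDataError,
    InvalidInputError,
    InvalidParameterError,
)

logger = logging.getLogger(__name__)

DEFAULT_N_REPS = 100
#: Geometric depth ladder (half-decade steps) used when no depths are given.
DEFAULT_DEPTH_LADDER = (1000, 3162, 10000, 31623, 100000)


@dataclass(frozen=True)
class RarefactionResult:
    metagenome_id: str
    depth: int
    mean_richness: float
    sd_richness: float
    n_reps: int
    seed: int


@dataclass(frozen=True)
class RegressionFit:
    """OLS fit of richness on log10(SO4/Cl).

    ``adj_r2`` follows the single-predictor formula
    1 - (1 - R^2)(n - 1)/(n - 2); ``p_value`` is the model F-test probability.
    ``slope_ci`` is the 95% confidence interval for the slope; ``n_dropped``
    counts springs excluded listwise for missing richness or geochemistry.
    """

    slope: float
    intercept: float
    r2: float
    adj_r2: float
    p_value: float
    n: int
    slope_se: float
    slope_ci: tuple[float, float]
    n_dropped: int = 0


def _log_choose(n: np.ndarray | float, k: float) -> np.ndarray | float:
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def expected_richness(counts: Iterable[int], depth: int) -> float:
    """Hypergeometric expectation of distinct families in a depth-d subsample."""
    counts = np.asarray(list(counts), dtype=np.int64)
    if np.any(counts < 0):
        raise InvalidInputError("family counts must be non-negative")
    counts = counts[counts > 0]
    n_total = int(counts.sum())
    if not 0 <= depth <= n_total:
        raise InvalidParameterError(
            f"depth must be in [0, {n_total}], got {depth}"
        )
    if depth == 0:
        return 0.0
    remaining = n_total - counts  # proteins outside each family
    p_absent = np.zeros(len(counts))
    feasible = remaining >= depth  # else family cannot be missed
    p_absent[feasible] = np.exp(
        _log_choose(remaining[feasible].astype(float), float(depth))
        - _log_choose(float(n_total), float(depth))
    )
    return float(np.sum(1.0 - p_absent))


def default_depths(max_total: int, ladder: Sequence[int] = DEFAULT_DEPTH_LADDER) -> list[int]:
    """The depth ladder truncated at a metagenome's total protein count."""
    return [d for d in ladder if d <= max_total]


def rarefied_richness(
    table: pd.DataFrame,
    depths: Sequence[int],
    n_reps: int = DEFAULT_N_REPS,
    seed: int = 0,
) -> list[RarefactionResult]:
    """Monte-Carlo rarefaction of a metagenome x family count table.

    For each metagenome and each depth not exceeding its protein total, draws
    ``n_reps`` subsamples without replacement and reports the mean and standard
    deviation of the number of distinct families hit.  Metagenomes shallower
    than a requested depth are skipped (and logged).  Deterministic for a fixed
    seed.
    """
    if n_reps <= 0:
        raise InvalidParameterError(f"n_reps must be positive, got {n_reps}")
    if any(d < 0 for d in depths):
        raise InvalidParameterError("depths must be non-negative")
    rng = np.random.default_rng(seed)
    results: list[RarefactionResult] = []
    skipped: list[tuple[str, int]] = []
    for mg_id, row in table.iterrows():
        counts = row.to_numpy(dtype=np.int64)
        n_total = int(counts.sum())
        labels = np.repeat(np.arange(len(counts)), counts)
        for depth in depths:
            if depth > n_total:
                skipped.append((str(mg_id), depth))
                continue
            richness = np.empty(n_reps)
            for r in range(n_reps):
                picked = rng.choice(n_total, size=depth, replace=False)
                richness[r] = np.unique(labels[picked]).size
            results.append(
                RarefactionResult(
                    metagenome_id=str(mg_id),
                    depth=int(depth),
                    mean_richness=float(richness.mean()),
                    sd_richness=float(richness.std(ddof=1)) if n_reps > 1 else 0.0,
                    n_reps=n_reps,
                    seed=seed,
                )
            )
    if skipped:
        logger.warning(
            "rarefied_richness: skipped %d (metagenome, depth) pairs below depth: %s",
            len(skipped),
            skipped[:10],
        )
    return results


def subsampled_richness(
    table: pd.DataFrame, depth: int = 10000, n_reps: int = DEFAULT_N_REPS, seed: int = 0
) -> pd.Series:
    """Fixed-depth comparison richness, one value per metagenome deep enough.

    The mean over ``n_reps`` subsamples at a single common depth (default
    10,000 proteins) — the quantity compared across springs on the fluid-mixing
    axis.  Metagenomes with fewer proteins than ``depth`` are omitted.
    """
    results = rarefied_richness(table, [depth], n_reps=n_reps, seed=seed)
    return pd.Series(
        {r.metagenome_id: r.mean_richness for r in results}, name=f"richness_at_{depth}"
    )


def fluid_mixing_ratio(geochem: pd.DataFrame) -> pd.Series:
    """log10(sulfate/chloride) per spring; NaN where either is missing/nonpositive."""
    sulfate = pd.to_numeric(geochem["sulfate"], errors="coerce")
    chloride = pd.to_numeric(geochem["chloride"], errors="coerce")
    ratio = sulfate / chloride
    ratio[(sulfate <= 0) | (chloride <= 0)] = np.nan
    return np.log10(ratio).rename("log_ratio")


def fit_diversity_model(
    richness: Mapping[str, float] | pd.Series,
    geochem: pd.DataFrame,
) -> RegressionFit:
    """OLS of per-spring richness on log10(SO4/Cl).

    ``geochem`` must carry a ``spring_id`` column (or index) and either a
    ``log_ratio`` column or ``sulfate``/``chloride`` columns from which the
    ratio is computed.  Springs lacking either variable are dropped listwise
    and counted in ``n_dropped``.
    """
    richness = pd.Series(richness, dtype=float)
    geo = geochem.copy()
    if "spring_id" in geo.columns:
        geo = geo.set_index("spring_id")
    if "log_ratio" not in geo.columns:
        geo["log_ratio"] = fluid_mixing_ratio(geo)
    merged = pd.DataFrame({"richness": richness}).join(geo["log_ratio"], how="outer")
    n_before = len(merged)
    merged = merged.dropna()
    n_dropped = n_before - len(merged)
    if n_dropped:
        logger.info("fit_diversity_model: dropped %d springs with missing data", n_dropped)
    n = len(merged)
    if n < 3:
        raise InsufficientDataError(f"regression needs >= 3 complete springs, got {n}")
    x = merged["log_ratio"].to_numpy()
    if np.ptp(x) == 0:
        raise DegenerateDesignError("log10(SO4/Cl) has zero variance across springs")
    X = sm.add_constant(x)
    fit = sm.OLS(merged["richness"].to_numpy(), X).fit()
    ci = fit.conf_int(alpha=0.05)
    return RegressionFit(
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        r2=float(fit.rsquared),
        adj_r2=float(fit.rsquared_adj),
        p_value=float(fit.f_pvalue),
        n=n,
        slope_se=float(fit.bse[1]),
        slope_ci=(float(ci[1, 0]), float(ci[1, 1])),
        n_dropped=n_dropped,
    )


def results_to_frame(results: Sequence[RarefactionResult]) -> pd.DataFrame:
    """Rarefaction results as a tidy DataFrame (one row per metagenome x depth)."""
    return pd.DataFrame([r.__dict__ for r in results])


def plot_rarefaction(results: Sequence[RarefactionResult], path) -> None:
    """Write rarefaction curves (mean +/- sd per metagenome) to an SVG/PNG file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = results_to_frame(results)
    fig, ax = plt.subplots(figsize=(6, 4))
    for mg_id, sub in df.groupby("metagenome_id"):
        sub = sub.sort_values("depth")
        ax.errorbar(sub["depth"], sub["mean_richness"], yerr=sub["sd_richness"], label=mg_id)
    ax.set_xlabel("proteins subsampled")
    ax.set_ylabel("distinct protein families")
    ax.set_xscale("log")
    if df["metagenome_id"].nunique() <= 12:
        ax.legend(fontsize=6)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
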