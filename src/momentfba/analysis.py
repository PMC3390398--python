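"""Statistical analyses relating kinetic parameters to fluxes and growth.

The central empirical observation behind enzyme-constrained modeling is
that reactions carrying high flux tend to be catalyzed by enzymes with
high turnover numbers.  This module provides the statistics used to
establish and exploit that relation: log-scale correlations between
keyed quantities (kcat, molecular weight, expression, flux), a simple
multiple linear regression of flux on kinetic predictors, the
closed-form fit of the total enzyme capacity C against measured growth
rates (valid because predicted growth scales linearly in C), a
shuffled-kcat permutation null, the growth-versus-sqrt(yield) relation,
and paired Wilcoxon comparisons of correlation sets (e.g. aerobic versus
anaerobic media).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError

#: values with magnitude below this are treated as zero under log10
LOG_FLOOR = 1e-9


@dataclass
class CorrelationReport:
    """Paired-correlation summary on shared keys."""

    n: int
    pearson_r: float
    pearson_p: float
    spearman_r: float
    spearman_p: float
    transform: str = "log10"
    dropped: int = 0

    def as_dict(self) -> dict:
        return {
            "n": self.n,
            "pearson_r": self.pearson_r,
            "pearson_p": self.pearson_p,
            "spearman_r": self.spearman_r,
            "spearman_p": self.spearman_p,
            "transform": self.transform,
            "dropped": self.dropped,
        }


def _pair(
    x: dict[str, float], y: dict[str, float], transform: str
) -> tuple[np.ndarray, np.ndarray, int]:
    keys = sorted(set(x) & set(y))
    xs, ys, dropped = [], [], 0
    for k in keys:
        a, b = float(x[k]), float(y[k])
        if transform == "log10":
            a, b = abs(a), abs(b)
            if a < LOG_FLOOR or b < LOG_FLOOR:
                dropped += 1
                continue
            a, b = math.log10(a), math.log10(b)
        xs.append(a)
        ys.append(b)
    return np.array(xs), np.array(ys), dropped


def correlate(
    x: dict[str, float],
    y: dict[str, float],
    transform: str = "log10",
    min_n: int = 3,
) -> CorrelationReport:
    """Pearson and Spearman correlation over shared keys.

    Under the ``log10`` transform both sides are taken in absolute value
    and pairs with a near-zero member (< 1e-9) are dropped and counted in
    ``dropped``.  Requires at least ``min_n`` usable pairs.
    """
    if transform not in ("log10", "none"):
        raise ValidationError(f"unknown transform {transform!r}")
    xs, ys, dropped = _pair(x, y, transform)
    if len(xs) < min_n:
        raise ValidationError(
            f"need >= {min_n} shared pairs after exclusions, got {len(xs)}"
        )
    pr = stats.pearsonr(xs, ys)
    sr = stats.spearmanr(xs, ys)
    return CorrelationReport(
        n=len(xs),
        pearson_r=float(pr.statistic),
        pearson_p=float(pr.pvalue),
        spearman_r=float(sr.statistic),
        spearman_p=float(sr.pvalue),
        transform=transform,
        dropped=dropped,
    )


@dataclass
class RegressionReport:
    n: int
    R: float                      # multiple correlation coefficient
    coefficients: dict[str, float]
    intercept: float
    predictors: list[str]


def regress_flux(
    flux: dict[str, float],
    kcat: dict[str, float],
    mw: dict[str, float] | None = None,
    expression: dict[str, float] | None = None,
    log_mw: bool = True,
) -> RegressionReport:
    """OLS of log10 |flux| on log10 predictors (kcat, MW, expression).

    Reports the multiple correlation R = sqrt(R^2) between fitted and
    observed log-fluxes.  ``log_mw=False`` keeps molecular weight on the
    raw scale.
    """
    predictors: dict[str, dict[str, float]] = {"kcat": kcat}
    if mw is not None:
        predictors["mw"] = mw
    if expression is not None:
        predictors["expression"] = expression
    keys = set(flux)
    for p in predictors.values():
        keys &= set(p)
    rows = []
    for k in sorted(keys):
        f = abs(float(flux[k]))
        vals = [abs(float(p[k])) for p in predictors.values()]
        if f < LOG_FLOOR or any(v < LOG_FLOOR for v in vals):
            continue
        rows.append((math.log10(f), vals))
    n = len(rows)
    if n < len(predictors) + 2:
        raise ValidationError(
            f"need >= {len(predictors) + 2} usable observations, got {n}"
        )
    y = np.array([r[0] for r in rows])
    X = np.ones((n, len(predictors) + 1))
    for j, name in enumerate(predictors):
        col = np.array([r[1][j] for r in rows])
        if name == "mw" and not log_mw:
            X[:, j + 1] = col
        else:
            X[:, j + 1] = np.log10(col)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ beta
    ss_res = float(np.sum((y - fitted) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot <= 0:
        raise ValidationError("response has zero variance")
    r2 = max(0.0, 1.0 - ss_res / ss_tot)
    return RegressionReport(
        n=n,
        R=math.sqrt(r2),
        coefficients={name: float(beta[j + 1]) for j, name in enumerate(predictors)},
        intercept=float(beta[0]),
        predictors=list(predictors),
    )


@dataclass
class CapacityFit:
    C_star: float
    sse: float
    n: int
    scale: float                  # C_star / C0


def fit_capacity(
    predicted_at_C0: dict[str, float],
    measured: dict[str, float],
    C0: float,
) -> CapacityFit:
    """Capacity C* minimizing squared growth-rate deviation.

    Because predicted growth is linear in the capacity C, predictions at
    any C are (C/C0) * p_i, and the least-squares C* has the closed form
    C* = C0 * sum(p_i m_i) / sum(p_i^2) (regression through the origin).
    """
    keys = sorted(set(predicted_at_C0) & set(measured))
    if len(keys) < 2:
        raise ValidationError(f"need >= 2 shared media, got {len(keys)}")
    p = np.array([float(predicted_at_C0[k]) for k in keys])
    m = np.array([float(measured[k]) for k in keys])
    denom = float(p @ p)
    if denom <= 0:
        raise ValidationError("all predictions are zero; cannot fit capacity")
    scale = float(p @ m) / denom
    sse = float(np.sum((scale * p - m) ** 2))
    return CapacityFit(C_star=C0 * scale, sse=sse, n=len(keys), scale=scale)


@dataclass
class ShuffleNullResult:
    observed: float
    p_strict: float               # fraction of shuffles strictly greater
    p_geq: float                  # fraction greater-or-equal
    n_shuffles: int
    null_mean: float
    null_sd: float
    null_values: np.ndarray


def shuffle_null(
    kcats: dict[str, float],
    reference: dict[str, float],
    n_shuffles: int = 1000,
    seed: int = 0,
    statistic=None,
    observed: float | None = None,
    exhaustive: bool = False,
    transform: str = "log10",
) -> ShuffleNullResult:
    """Permutation null: shuffle kcat values over their keys.

    The default statistic is the Pearson correlation (log10 transform)
    against ``reference``; pass ``statistic`` (a callable mapping a kcat
    dict to a number, e.g. a full growth-prediction pipeline followed by
    a correlation) to randomize any downstream quantity.  ``p_strict``
    counts shuffles with a strictly greater statistic than the observed
    value; ``p_geq`` uses greater-or-equal.  With ``exhaustive=True`` all
    permutations are enumerated (small key sets only).
    """
    keys = sorted(kcats)
    values = [kcats[k] for k in keys]
    if statistic is None:
        def statistic(kc):
            return correlate(kc, reference, transform=transform).pearson_r

    if observed is None:
        observed = float(statistic(dict(kcats)))

    null = []
    if exhaustive:
        if len(keys) > 8:
            raise ValidationError("exhaustive enumeration limited to <= 8 keys")
        for perm in permutations(values):
            null.append(float(statistic(dict(zip(keys, perm)))))
    else:
        if n_shuffles < 100:
            raise ValidationError(f"need >= 100 shuffles, got {n_shuffles}")
        rng = np.random.default_rng(seed)
        arr = np.array(values, dtype=float)
        for _ in range(n_shuffles):
            shuffled = arr[rng.permutation(len(arr))]
            null.append(float(statistic(dict(zip(keys, shuffled)))))
    null = np.array(null)
    eps = 1e-12
    return ShuffleNullResult(
        observed=observed,
        p_strict=float(np.mean(null > observed + eps)),
        p_geq=float(np.mean(null >= observed - eps)),
        n_shuffles=len(null),
        null_mean=float(null.mean()),
        null_sd=float(null.std(ddof=0)),
        null_values=null,
    )


def growth_vs_sqrt_yield(solutions: dict[str, "object"]) -> CorrelationReport:
    """Correlation between growth rate and sqrt(biomass yield) across media.

    Yield is growth / total carbon uptake in model units, taken from each
    solution's recorded uptake.  Raises on zero uptake or degenerate
    (zero-variance) inputs.
    """
    growth: dict[str, float] = {}
    sqrt_yield: dict[str, float] = {}
    for name, sol in sorted(solutions.items()):
        if not getattr(sol, "optimal", False):
            continue
        if sol.uptake is None or sol.uptake <= 0:
            raise ValidationError(f"medium {name!r}: carbon uptake is zero")
        growth[name] = sol.growth
        sqrt_yield[name] = math.sqrt(sol.growth / sol.uptake)
    if len(growth) < 3:
        raise ValidationError(f"need >= 3 optimal media, got {len(growth)}")
    g = np.array(list(growth.values()))
    s = np.array(list(sqrt_yield.values()))
    if np.ptp(g) < 1e-12 or np.ptp(s) < 1e-12:
        raise ValidationError("degenerate input: zero variance across media")
    return correlate(growth, sqrt_yield, transform="none")


def compare_condition_sets(
    corr_a: list[float], corr_b: list[float], paired: bool = True
) -> float:
    """Two-sided Wilcoxon p-value comparing two sets of correlations.

    Paired (signed-rank) by default, e.g. the same media under aerobic
    versus anaerobic conditions; requires >= 6 pairs.
    """
    a = np.asarray(corr_a, dtype=float)
    b = np.asarray(corr_b, dtype=float)
    if paired:
        if len(a) != len(b):
            raise ValidationError("paired comparison needs equal-length lists")
        if len(a) < 6:
            raise ValidationError(f"need >= 6 pairs, got {len(a)}")
        if np.allclose(a, b):
            return 1.0
        res = stats.wilcoxon(a, b, alternative="two-sided")
    else:
        if min(len(a), len(b)) < 6:
            raise ValidationError("need >= 6 observations per set")
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
    return float(res.pvalue)


def mean_flux_across_media(
    flux_by_medium: dict[str, dict[str, float]]
) -> dict[str, float]:
    """Arithmetic mean of |flux| per reaction over media (pre-log)."""
    sums: dict[str, float] = {}
    counts: dict[str, int] = {}
    for fluxes in flux_by_medium.values():
        for rid, v in fluxes.items():
            sums[rid] = sums.get(rid, 0.0) + abs(float(v))
            counts[rid] = counts.get(rid, 0) + 1
    return {rid: sums[rid] / counts[rid] for rid in sums}


def report_to_frame(report: CorrelationReport) -> pd.DataFrame:
    return pd.DataFrame([report.as_dict()])
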