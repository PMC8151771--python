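"""Model-comparison statistics for paired prediction-error series.

Covers the three comparison routes used when several acquisition systems
predict the same reference chemistry:

* SEL — standard error of laboratory, a precision estimate from duplicate
  measurements (reference assays or duplicate NIR predictions);
* the SEP < 2*SEL_ref rule of thumb for judging a model's prediction error
  against the reference method's own repeatability;
* a paired t confidence interval for the difference between two models'
  biases;
* the Fearn K/L confidence interval for the ratio of two correlated error
  standard deviations (SEPs), which accounts for the correlation r between
  the two error series:

      K = 1 + 2 (1 - r^2) t^2_{n-2, 0.025} / (n - 2)
      L = sqrt(K + sqrt(K^2 - 1))

  the 95% interval for sd_a/sd_b is (ratio/L, ratio*L); the standard
  deviations differ significantly (p <= 0.05) iff the interval excludes 1.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import DataValidationError


@dataclass
class SELResult:
    """Standard error of laboratory estimated from duplicate pairs."""

    value: float
    m: int
    source: str = ""
    denominator: str = "2m"


@dataclass
class BiasComparison:
    """Paired t comparison of two models' biases (95% CI for the mean
    difference of their error series)."""

    mean_diff: float
    ci_low: float
    ci_high: float
    p_value: float
    significant: bool
    n: int


@dataclass
class ComparisonResult:
    """Pairwise comparison of two models sharing a prediction set."""

    model_a: str
    model_b: str
    n: int
    bias_a: float
    bias_b: float
    sd_a: float
    sd_b: float
    r: float
    K: float
    L: float
    ratio: float
    interval_low: float
    interval_high: float
    significant_sd: bool
    bias_test: BiasComparison | None = None


def sel(duplicates: np.ndarray, denominator: str = "2m", source: str = "") -> SELResult:
    """Standard error of laboratory from an (m, 2) array of duplicate pairs.

    The default form SEL = sqrt(sum d^2 / (2m)) estimates the standard
    deviation of a single measurement from paired differences d = x1 - x2
    (the standard duplicate-precision estimator); ``denominator="m"``
    selects the sqrt(sum d^2 / m) variant, which estimates the sd of the
    difference instead.
    """
    pairs = np.asarray(duplicates, dtype=float)
    if pairs.ndim != 2 or pairs.shape[1] != 2:
        raise DataValidationError("duplicates must be an (m, 2) array")
    if not np.all(np.isfinite(pairs)):
        bad = np.flatnonzero(~np.isfinite(pairs).all(axis=1))
        raise DataValidationError(f"incomplete duplicate pairs at rows {bad[:5].tolist()}")
    m = pairs.shape[0]
    if m < 2:
        raise DataValidationError("need at least 2 duplicate pairs")
    if denominator not in ("2m", "m"):
        raise DataValidationError(f"unknown SEL denominator {denominator!r}")
    d2 = np.sum((pairs[:, 0] - pairs[:, 1]) ** 2)
    denom = 2 * m if denominator == "2m" else m
    return SELResult(
        value=float(np.sqrt(d2 / denom)), m=m, source=source, denominator=denominator
    )


@dataclass
class SepVsSelVerdict:
    sep: float
    sel_ref: float
    ratio: float
    good: bool


def sep_vs_sel(sep: float, sel_ref: float) -> SepVsSelVerdict:
    """Rule of thumb: prediction is 'good' iff SEP < 2 * SEL_ref (strict)."""
    if sep < 0 or sel_ref < 0:
        raise DataValidationError("SEP and SEL must be non-negative")
    if sel_ref == 0:
        ratio = 0.0 if sep == 0 else np.inf
    else:
        ratio = sep / sel_ref
    return SepVsSelVerdict(sep=sep, sel_ref=sel_ref, ratio=float(ratio), good=ratio < 2.0)


def compare_biases(
    errors_a: np.ndarray, errors_b: np.ndarray, alpha: float = 0.05
) -> BiasComparison:
    """95% paired-t confidence interval for the difference of two models'
    biases; the biases are declared 'not different' iff the CI contains 0.
    """
    a = np.asarray(errors_a, dtype=float).ravel()
    b = np.asarray(errors_b, dtype=float).ravel()
    if a.size != b.size:
        raise DataValidationError("paired error vectors must have equal length")
    n = a.size
    if n < 3:
        raise DataValidationError("need >= 3 paired errors")
    d = a - b
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    if sd == 0:
        # degenerate: constant shift between the models
        significant = mean != 0.0
        return BiasComparison(
            mean_diff=mean,
            ci_low=mean,
            ci_high=mean,
            p_value=0.0 if significant else 1.0,
            significant=significant,
            n=n,
        )
    se = sd / np.sqrt(n)
    tcrit = stats.t.ppf(1 - alpha / 2, n - 1)
    tstat = mean / se
    p = 2 * stats.t.sf(abs(tstat), n - 1)
    lo, hi = mean - tcrit * se, mean + tcrit * se
    return BiasComparison(
        mean_diff=mean,
        ci_low=float(lo),
        ci_high=float(hi),
        p_value=float(p),
        significant=not (lo <= 0.0 <= hi),
        n=n,
    )


def fearn_sd_interval(
    errors_a: np.ndarray,
    errors_b: np.ndarray,
    model_a: str = "a",
    model_b: str = "b",
    alpha: float = 0.05,
    with_bias_test: bool = True,
) -> ComparisonResult:
    """95% confidence interval for the ratio of two correlated error SDs.

    The error series are bias-corrected before the SD computation (the SDs
    are SEPs); r is the Pearson correlation between the raw error vectors.
    """
    a = np.asarray(errors_a, dtype=float).ravel()
    b = np.asarray(errors_b, dtype=float).ravel()
    if a.size != b.size:
        raise DataValidationError("paired error vectors must have equal length")
    n = a.size
    if n < 4:
        raise DataValidationError("need >= 4 paired errors for the sd-ratio interval")
    sd_a = float(a.std(ddof=1))
    sd_b = float(b.std(ddof=1))
    if sd_b == 0:
        raise DataValidationError("second error series has zero standard deviation")
    if sd_a == 0:
        raise DataValidationError("first error series has zero standard deviation")
    if np.allclose(a - a.mean(), b - b.mean()):
        r = 1.0
    else:
        r = float(np.corrcoef(a, b)[0, 1])
    tcrit = float(stats.t.ppf(1 - alpha / 2, n - 2))
    K = 1.0 + 2.0 * (1.0 - r**2) * tcrit**2 / (n - 2)
    L = float(np.sqrt(K + np.sqrt(K**2 - 1.0)))
    ratio = sd_a / sd_b
    lo, hi = ratio / L, ratio * L
    return ComparisonResult(
        model_a=model_a,
        model_b=model_b,
        n=n,
        bias_a=float(a.mean()),
        bias_b=float(b.mean()),
        sd_a=sd_a,
        sd_b=sd_b,
        r=r,
        K=float(K),
        L=L,
        ratio=float(ratio),
        interval_low=float(lo),
        interval_high=float(hi),
        significant_sd=not (lo <= 1.0 <= hi),
        bias_test=compare_biases(a, b, alpha=alpha) if with_bias_test else None,
    )


def pairwise_sd_comparisons(
    errors_by_system: dict[str, np.ndarray], alpha: float = 0.05
) -> list[ComparisonResult]:
    """All unordered pairwise comparisons among >= 2 error series."""
    systems = list(errors_by_system)
    if len(systems) < 2:
        raise DataValidationError("need at least two systems to compare")
    sizes = {s: np.asarray(e).size for s, e in errors_by_system.items()}
    if len(set(sizes.values())) != 1:
        raise DataValidationError(f"prediction-set sizes differ: {sizes}")
    return [
        fearn_sd_interval(
            errors_by_system[a], errors_by_system[b], model_a=a, model_b=b, alpha=alpha
        )
        for a, b in itertools.combinations(systems, 2)
    ]


def comparison_report(
    errors: dict[str, dict[str, np.ndarray]],
    sel_ref: dict[str, float] | None = None,
    sel_nir: dict[str, dict[str, float]] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Pairwise comparison table across responses and systems.

    ``errors`` maps response -> {system -> prediction-error vector}; the
    optional SEL maps add the laboratory-precision columns.  One row per
    response x unordered system pair, flag columns mirroring the usual
    'n.s.' / '*' presentation.
    """
    rows = []
    for response, by_system in errors.items():
        for res in pairwise_sd_comparisons(by_system, alpha=alpha):
            row = {
                "response": response,
                "system_a": res.model_a,
                "system_b": res.model_b,
                "n": res.n,
                "sep_a": res.sd_a,
                "sep_b": res.sd_b,
                "r": res.r,
                "K": res.K,
                "L": res.L,
                "sd_ratio": res.ratio,
                "interval_low": res.interval_low,
                "interval_high": res.interval_high,
                "sd_flag": "*" if res.significant_sd else "n.s.",
                "bias_diff": res.bias_test.mean_diff,
                "bias_ci_low": res.bias_test.ci_low,
                "bias_ci_high": res.bias_test.ci_high,
                "bias_p": res.bias_test.p_value,
                "bias_flag": "*" if res.bias_test.significant else "n.s.",
            }
            if sel_ref is not None:
                row["sel_ref"] = sel_ref.get(response, np.nan)
            if sel_nir is not None:
                row["sel_nir_a"] = sel_nir.get(response, {}).get(res.model_a, np.nan)
                row["sel_nir_b"] = sel_nir.get(response, {}).get(res.model_b, np.nan)
            rows.append(row)
    return pd.DataFrame(rows)
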