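"""Multi-run statistical validation of classification metrics.

Given per-run metric values (e.g. composite scores from 10 independent
train/test runs), this module computes summary moments, a one-sample
t-test against a reference value, Cohen's d and its small-sample
correction Hedges' g, and the Shapiro–Wilk, Jarque–Bera, and
Kolmogorov–Smirnov normality tests.

The reference value of the t-test must be chosen by the analyst. A
common but circular choice is the sample mean itself, which by
construction yields t = 0, p = 1, d = g = 0; :func:`summarize` supports
``ref="mean"`` to reproduce that convention but notes it in the output.

Conventions: sample (n−1) standard deviation throughout this module;
the KS test uses Normal(mean, sd) with parameters estimated from the
data (no Lilliefors correction), matching common practice.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)


@dataclass
class MetricSeries:
    """One metric's per-run values for one block."""

    values: np.ndarray
    metric: str = ""
    block: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("metric values must be finite")

    @property
    def n(self) -> int:
        return self.values.size


@dataclass
class StatReport:
    """All per-series statistics in one record."""

    mean: float
    sd: float
    t: float
    p: float
    cohens_d: float
    hedges_g: float
    shapiro_p: float
    jarque_bera_p: float
    ks_p: float
    n: int
    ref: float
    flags: list[str] = field(default_factory=list)


def hedges_correction(n: int) -> float:
    """Small-sample bias correction: g = d·(1 − 3/(4n − 5))."""
    return 1.0 - 3.0 / (4.0 * n - 5.0)


def one_sample_t(series: MetricSeries | Sequence[float],
                 ref: float) -> tuple[float, float, float, float]:
    """One-sample t-test plus effect sizes against reference ``ref``.

    t = (mean − ref)/(sd/√n), two-sided p from Student t with n−1 df,
    d = (mean − ref)/sd, g = d·(1 − 3/(4n−5)). A zero-sd series yields
    d = g = 0 when mean equals ref, and signed infinity otherwise.
    """
    s = series if isinstance(series, MetricSeries) else MetricSeries(np.asarray(series))
    if s.n < 3:
        raise ValueError("one_sample_t requires n >= 3")
    mean = float(s.values.mean())
    sd = float(s.values.std(ddof=1))
    if sd == 0.0:
        if mean == ref:
            return 0.0, 1.0, 0.0, 0.0
        sign = np.sign(mean - ref)
        logger.warning("zero-sd series with mean != ref: effect sizes infinite")
        return float(sign * np.inf), 0.0, float(sign * np.inf), float(sign * np.inf)
    t = (mean - ref) / (sd / np.sqrt(s.n))
    p = float(2.0 * sps.t.sf(abs(t), df=s.n - 1))
    d = (mean - ref) / sd
    g = d * hedges_correction(s.n)
    return float(t), p, float(d), float(g)


def normality_suite(series: MetricSeries | Sequence[float]
                    ) -> tuple[float, float, float]:
    """(Shapiro–Wilk p, Jarque–Bera p, Kolmogorov–Smirnov p).

    KS is one-sample against Normal(mean, sd) with estimated parameters
    (uncorrected, so its p values are conservative against normality). A
    constant series is degenerate for all three; by convention all p
    values are returned as 0 and a warning logged.
    """
    s = series if isinstance(series, MetricSeries) else MetricSeries(np.asarray(series))
    if s.n < 3:
        raise ValueError("normality_suite requires n >= 3")
    sd = float(s.values.std(ddof=1))
    if sd == 0.0:
        logger.warning("constant series: normality tests degenerate (p := 0)")
        return 0.0, 0.0, 0.0
    shapiro_p = float(sps.shapiro(s.values).pvalue)
    jb_p = float(sps.jarque_bera(s.values).pvalue)
    ks_p = float(sps.kstest(s.values, "norm",
                            args=(float(s.values.mean()), sd)).pvalue)
    return shapiro_p, jb_p, ks_p


def analyze_series(series: MetricSeries, ref: float | str = "mean") -> StatReport:
    """Full report for one series; ``ref="mean"`` tests against the sample
    mean (circular by construction — flagged in the report)."""
    flags = []
    if ref == "mean":
        ref_val = float(series.values.mean())
        flags.append("ref=sample-mean (t/d/g are 0 by construction)")
    else:
        ref_val = float(ref)
    t, p, d, g = one_sample_t(series, ref_val)
    sw, jb, ks = normality_suite(series)
    if series.values.std(ddof=1) == 0:
        flags.append("degenerate: zero variance")
    return StatReport(mean=float(series.values.mean()),
                      sd=float(series.values.std(ddof=1)),
                      t=t, p=p, cohens_d=d, hedges_g=g,
                      shapiro_p=sw, jarque_bera_p=jb, ks_p=ks,
                      n=series.n, ref=ref_val, flags=flags)


def summarize(series_table: Mapping[tuple[str, str], Sequence[float]] | pd.DataFrame,
              ref: float | str = "mean") -> pd.DataFrame:
    """Tidy report over (block, metric) series.

    Accepts either a mapping ``{(block, metric): values}`` or the tidy
    metrics table from the classifier stack (columns run, block, metric,
    value). One row per series with mean, sd, and all test outputs.
    """
    if isinstance(series_table, pd.DataFrame):
        grouped = {
            (b, m): g["value"].to_numpy()
            for (b, m), g in series_table.groupby(["block", "metric"], sort=True)
        }
    else:
        grouped = {k: np.asarray(v, dtype=np.float64)
                   for k, v in series_table.items()}
    rows = []
    for (block, metric), values in grouped.items():
        s = MetricSeries(values, metric=metric, block=block)
        if s.n >= 3:
            rep = analyze_series(s, ref=ref)
            rows.append({"block": block, "metric": metric, "n": rep.n,
                         "mean": rep.mean, "sd": rep.sd, "ref": rep.ref,
                         "t": rep.t, "p": rep.p,
                         "cohens_d": rep.cohens_d, "hedges_g": rep.hedges_g,
                         "shapiro_p": rep.shapiro_p,
                         "jarque_bera_p": rep.jarque_bera_p,
                         "ks_p": rep.ks_p,
                         "flags": "; ".join(rep.flags)})
        else:
            rows.append({"block": block, "metric": metric, "n": s.n,
                         "mean": float(s.values.mean()),
                         "sd": float(s.values.std(ddof=1)) if s.n > 1 else 0.0,
                         "flags": "n < 3: tests skipped"})
    return pd.DataFrame(rows)


def render_report(table: pd.DataFrame) -> str:
    """Human-readable rendering of a summary table."""
    lines = []
    for _, r in table.iterrows():
        lines.append(f"{r['block']}/{r['metric']}: mean={r['mean']:.4f} "
                     f"sd={r.get('sd', float('nan')):.4f} n={int(r['n'])}")
        if "t" in r and pd.notna(r.get("t")):
            lines.append(f"  t={r['t']:.4g} p={r['p']:.4g} "
                         f"d={r['cohens_d']:.4g} g={r['hedges_g']:.4g}")
            lines.append(f"  normality p: shapiro={r['shapiro_p']:.3g} "
                         f"jarque-bera={r['jarque_bera_p']:.3g} "
                         f"ks={r['ks_p']:.3g}")
        if r.get("flags"):
            lines.append(f"  note: {r['flags']}")
    return "\n".join(lines)
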