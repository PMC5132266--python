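"""Rank statistics on t_max distributions: merging, testing, outliers.

The pipeline treats each monomer trajectory as an independent data-set of
per-residue maximum occupancy times.  Data-sets are pooled into
"macro-samples" only when a Kruskal-Wallis test (alpha = 0.01, compared
against the tabulated chi-square critical value) cannot distinguish their
medians; if the full set fails, the test is repeated leaving one data-set
out at a time and the passing subset with the smallest H is merged.
Outliers of the merged distribution are residues whose t_max exceeds the
upper box-plot (Tukey) fence T = Q3 + 1.5*(Q3 - Q1); the fence is the
operational boundary between diffusive, nanosecond contacts and specific,
microsecond-scale interactions.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)


def tukey_upper_fence(q1: float, q3: float) -> float:
    """Upper box-plot fence Q3 + 1.5*IQR."""
    return q3 + 1.5 * (q3 - q1)


@dataclass(frozen=True)
class DistributionSummary:
    """Spread descriptors of one t_max distribution (contacting residues)."""

    label: str
    n_contacting: int
    median: float
    q1: float
    q3: float
    outlier_threshold_T: float


@dataclass(frozen=True)
class TestResult:
    name: str
    statistic: float
    df: int
    alpha: float
    critical: float
    pvalue: float
    reject: bool
    note: str = ""


@dataclass
class MacroSample:
    """A merged set of data-sets that passed the homogeneity test.

    ``values`` concatenates the member samples (used when the macro-sample
    itself enters a rank test); ``residue_tmax`` optionally carries the
    per-residue aggregate (max over members), which is the distribution the
    spread descriptors and the outlier fence are computed on.
    """

    members: list[str]
    excluded: dict[str, str]
    values: np.ndarray
    residue_tmax: pd.Series | None = None
    h_history: list[tuple[tuple[str, ...], float]] = field(default_factory=list)

    @property
    def n(self) -> int:
        return len(self.values)


def summarize(values, label: str = "", method: str = "linear") -> DistributionSummary:
    """Median/quartiles (linear interpolation between order statistics by
    default) and the Tukey fence of a t_max sample.  Values are expected to
    be the t_max of contacting residues only (strictly positive)."""
    values = np.asarray(values, dtype=float)
    if values.size < 4:
        raise ValueError("need at least 4 values for quartiles")
    q1, med, q3 = np.percentile(values, [25, 50, 75], method=method)
    return DistributionSummary(label, int(values.size), float(med), float(q1),
                               float(q3), tukey_upper_fence(float(q1), float(q3)))


def chi2_critical(alpha: float, df: int) -> float:
    """(1-alpha) quantile of the chi-square distribution."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if df < 1:
        raise ValueError("df must be >= 1")
    return float(sps.chi2.ppf(1.0 - alpha, df))


def dagostino_pearson(values, alpha: float = 0.01) -> TestResult:
    """D'Agostino-Pearson K² omnibus normality test (skewness + kurtosis
    z-scores, chi-square reference with df=2)."""
    values = np.asarray(values, dtype=float)
    if values.size and np.ptp(values) == 0:
        raise ValueError("constant input: moments undefined")
    note = ""
    if values.size < 20:
        note = "small sample (n < 20): normality test unreliable"
        logger.warning(note)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        k2, p = sps.normaltest(values)
    crit = chi2_critical(alpha, 2)
    return TestResult("dagostino-pearson", float(k2), 2, alpha, crit, float(p),
                      bool(k2 > crit), note)


def kruskal_wallis(samples, alpha: float = 0.01) -> TestResult:
    """Kruskal-Wallis H (tie corrected) for k samples, decided against the
    tabulated chi-square critical value with df = k-1."""
    samples = [np.asarray(s, dtype=float) for s in samples]
    if len(samples) < 2:
        raise ValueError("need at least two samples")
    if any(s.size == 0 for s in samples):
        raise ValueError("empty sample")
    h, p = sps.kruskal(*samples)
    df = len(samples) - 1
    crit = chi2_critical(alpha, df)
    return TestResult("kruskal-wallis", float(h), df, alpha, crit, float(p),
                      bool(h > crit))


def wilcoxon_rank_sum(a, b, alpha: float = 0.01) -> TestResult:
    """Two-sided rank-sum test, normal approximation with tie correction."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty sample")
    n1, n2 = a.size, b.size
    ranks = sps.rankdata(np.concatenate([a, b]))
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    tie = sps.tiecorrect(ranks)
    sigma = np.sqrt(tie * n1 * n2 * (n1 + n2 + 1) / 12.0)
    z = 0.0 if sigma == 0 else (u1 - mu) / sigma
    p = 2.0 * sps.norm.sf(abs(z))
    crit = float(sps.norm.ppf(1.0 - alpha / 2.0))
    return TestResult("wilcoxon-rank-sum", float(z), 1, alpha, crit,
                      float(min(p, 1.0)), bool(abs(z) > crit))


def _passes(samples: list[np.ndarray], alpha: float) -> tuple[bool, float]:
    res = kruskal_wallis(samples, alpha)
    return (not res.reject), res.statistic


def leave_one_out_merge(datasets: dict, alpha: float = 0.01) -> MacroSample:
    """Merge data-sets whose medians a Kruskal-Wallis test cannot tell apart.

    If the full set passes at ``alpha`` everything is merged; otherwise every
    leave-one-out subset is tested and, among the passing ones, the subset
    with the smallest H is merged (the excluded data-set is recorded).  If no
    subset of size k-1 passes, smaller subsets are tried down to size 2
    (pairs are decided by the same rank test with k=2).  With no passing
    subset at all the result is an empty, "irreconcilable" macro-sample.
    """
    labels = list(datasets)
    arrays = {k: np.asarray(v, dtype=float) for k, v in datasets.items()}
    if len(labels) < 2:
        raise ValueError("need at least 2 data-sets")
    history: list[tuple[tuple[str, ...], float]] = []

    ok, h = _passes([arrays[k] for k in labels], alpha)
    history.append((tuple(labels), h))
    if ok:
        return MacroSample(labels, {}, np.concatenate([arrays[k] for k in labels]),
                           h_history=history)

    for size in range(len(labels) - 1, 1, -1):
        candidates: list[tuple[float, tuple[str, ...]]] = []
        for combo in itertools.combinations(labels, size):
            okc, hc = _passes([arrays[k] for k in combo], alpha)
            history.append((combo, hc))
            if okc:
                candidates.append((hc, combo))
        if candidates:
            hbest, best = min(candidates, key=lambda t: t[0])
            if len(candidates) > 1:
                logger.info("%d subsets of size %d pass; selected %s by "
                            "minimal H=%.3f", len(candidates), size, best, hbest)
            excluded = {k: "kruskal-wallis reject" for k in labels if k not in best}
            return MacroSample(list(best), excluded,
                               np.concatenate([arrays[k] for k in best]),
                               h_history=history)
    return MacroSample([], {k: "irreconcilable" for k in labels},
                       np.empty(0), h_history=history)


def find_outliers(macro: MacroSample,
                  summary: DistributionSummary | None = None) -> pd.DataFrame:
    """Residues whose aggregated t_max strictly exceeds the Tukey fence of
    the macro-sample, sorted by decreasing t_max."""
    if macro.residue_tmax is None:
        raise ValueError("macro-sample carries no per-residue aggregate")
    vals = macro.residue_tmax[macro.residue_tmax > 0]
    if summary is None:
        summary = summarize(vals.to_numpy(), label="macro")
    out = vals[vals > summary.outlier_threshold_T].sort_values(ascending=False)
    return out.rename("tmax_ns").reset_index()
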