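"""Paired pre/post cohort statistics.

Endpoints are summarized as ``median [range]``, compared with the Wilcoxon
signed-rank test (exact null distribution up to n = 25 nonzero differences,
continuity-corrected normal approximation above), accompanied by Cliff's
delta as the effect size, and corrected across the endpoint family with the
Benjamini-Hochberg false-discovery-rate step-up.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as spstats
from statsmodels.stats.multitest import multipletests

from .errors import ParameterError

EXACT_WILCOXON_MAX_N = 25


def ks_normality(sample: np.ndarray) -> float:
    """One-sample Kolmogorov-Smirnov p against a fitted normal."""
    x = np.asarray(sample, dtype=float)
    if x.size < 3:
        raise ParameterError("need at least 3 observations")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ParameterError("degenerate (constant) sample")
    return float(spstats.kstest(x, "norm", args=(x.mean(), sd)).pvalue)


def wilcoxon_signed_rank(pre: np.ndarray, post: np.ndarray,
                         zero_method: str = "wilcox",
                         alternative: str = "two-sided"
                         ) -> tuple[float, float]:
    """Paired Wilcoxon signed-rank test.

    Zero differences are dropped by default (Wilcoxon's original policy;
    ``zero_method="pratt"`` is available).  Uses the exact null
    distribution for up to 25 nonzero differences and the normal
    approximation with continuity correction beyond that.  All-zero
    differences yield ``(0.0, 1.0)``.
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape:
        raise ParameterError("pre and post must have equal length")
    d = post - pre
    nz = int(np.count_nonzero(d))
    if nz == 0:
        return 0.0, 1.0
    method = "exact" if nz <= EXACT_WILCOXON_MAX_N else "approx"
    res = spstats.wilcoxon(pre, post, zero_method=zero_method,
                           correction=(method == "approx"),
                           alternative=alternative, method=method)
    return float(res.statistic), float(res.pvalue)


def cliffs_delta(x: np.ndarray, y: np.ndarray) -> float:
    """Cliff's delta over all cross pairs: P(x > y) - P(x < y)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ParameterError("both samples must be nonempty")
    diff = x[:, None] - y[None, :]
    return float((np.sign(diff)).sum() / (x.size * y.size))


def fdr_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (monotone step-up)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ParameterError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def median_range(x: np.ndarray) -> str:
    """Summary in ``median [min-max]`` style."""
    x = np.asarray(x, dtype=float)
    return f"{np.median(x):.1f} [{x.min():.1f}-{x.max():.1f}]"


@dataclass
class EndpointResult:
    endpoint: str
    n: int
    n_excluded: int
    median_pre: float
    median_post: float
    summary_pre: str
    summary_post: str
    statistic: float
    p_value: float
    effect_size: float
    fdr_adjusted_p: float | None = None


def compare_endpoint(name: str, pre: np.ndarray, post: np.ndarray
                     ) -> EndpointResult:
    """Complete-case paired comparison of one endpoint.

    Subjects with a missing value in either arm are excluded (and counted);
    Cliff's delta is computed between the two arms over cross pairs, so a
    decrease from pre to post yields a negative delta.
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    ok = np.isfinite(pre) & np.isfinite(post)
    n_excl = int((~ok).sum())
    pre, post = pre[ok], post[ok]
    if pre.size < 2:
        raise ParameterError(f"endpoint {name!r}: fewer than 2 complete pairs")
    stat, p = wilcoxon_signed_rank(pre, post)
    delta = cliffs_delta(post, pre)
    return EndpointResult(name, int(pre.size), n_excl,
                          float(np.median(pre)), float(np.median(post)),
                          median_range(pre), median_range(post),
                          stat, p, delta)


def compare_cohort(metrics: dict[str, tuple[np.ndarray, np.ndarray]]
                   ) -> pd.DataFrame:
    """Compare a family of endpoints and FDR-adjust across the family.

    ``metrics`` maps endpoint name -> (pre values, post values), aligned by
    subject with NaN for missing measurements.
    """
    results = [compare_endpoint(name, pre, post)
               for name, (pre, post) in metrics.items()]
    adj = fdr_adjust([r.p_value for r in results])
    for r, a in zip(results, adj):
        r.fdr_adjusted_p = float(a)
    return pd.DataFrame([vars(r) for r in results])


def compare_subgroups(values_a: np.ndarray, values_b: np.ndarray
                      ) -> tuple[float, float, float]:
    """Unpaired two-group contrast (Mann-Whitney U + Cliff's delta).

    Used for contrasts like burden change in clinically improved versus
    non-improved subjects.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if a.size == 0 or b.size == 0:
        raise ParameterError("both subgroups must be nonempty")
    res = spstats.mannwhitneyu(a, b, alternative="two-sided")
    return float(res.statistic), float(res.pvalue), cliffs_delta(a, b)
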