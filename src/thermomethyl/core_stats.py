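"""Shared statistical engine for count-based differential analysis.

All differential calling in this package (methylation sites, gene-level
methylation sums, RNA-seq counts) runs through one negative-binomial (NB)
engine: median-of-ratios normalization, a method-of-moments common
dispersion, and a two-sided exact test on group sums conditional on their
total. Multiple-testing adjustment is Benjamini-Hochberg step-up.

The NB parameterization throughout is mean/dispersion with
``Var = mu + phi * mu**2``; ``phi = 0`` degenerates to Poisson, in which
case the conditional test is the exact binomial split of the total.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats

CONTROL = "control"
TREATMENT = "treatment"

#: features with all-positive counts required before median-of-ratios is
#: trusted; below this the upper-quartile fallback is used.
MIN_POSITIVE_FEATURES = 50

#: pseudocount added to group mean normalized counts for log2 fold change
#: only -- never enters the test statistic.
DEFAULT_PSEUDOCOUNT = 0.5


class DegenerateDataError(ValueError):
    """Raised when the input admits no meaningful estimate."""


@dataclass
class CountMatrix:
    """Feature x sample matrix of non-negative integer counts.

    Parameters
    ----------
    counts
        DataFrame indexed by feature id with one column per sample.
    group_of
        Mapping sample id -> ``"control"`` | ``"treatment"``. Every column
        of `counts` must be assigned, and both groups must be non-empty.
    """

    counts: pd.DataFrame
    group_of: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (np.asarray(self.counts) < 0).any():
            raise ValueError("counts must be non-negative")
        missing = [s for s in self.counts.columns if s not in self.group_of]
        if missing:
            raise ValueError(f"samples without group assignment: {missing}")
        bad = {g for g in self.group_of.values() if g not in (CONTROL, TREATMENT)}
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)}")
        for g in (CONTROL, TREATMENT):
            if not self.samples(g):
                raise ValueError(f"group '{g}' has no samples")

    def samples(self, group: str) -> list[str]:
        return [s for s in self.counts.columns if self.group_of.get(s) == group]


@dataclass
class NormalizationResult:
    size_factors: pd.Series        # positive, one per sample
    normalized: pd.DataFrame       # counts / size_factor, columnwise

    def __post_init__(self) -> None:
        if (self.size_factors <= 0).any():
            raise ValueError("size factors must be positive")


@dataclass
class DifferentialResult:
    feature_id: str
    log2fc: float
    p_value: float
    q_value: float
    significant: bool
    direction: str  # up | down | none


def estimate_size_factors(
    counts: pd.DataFrame, min_positive_features: int = MIN_POSITIVE_FEATURES
) -> NormalizationResult:
    """Median-of-ratios size factors against the geometric-mean reference.

    For each feature with all-positive counts the per-sample ratio to the
    feature's geometric mean is formed; a sample's factor is the median of
    its ratios. When fewer than `min_positive_features` features qualify,
    falls back to upper-quartile scaling (quartiles rescaled so that their
    geometric mean is 1), which tolerates sparse matrices.
    """
    arr = np.asarray(counts, dtype=float)
    if arr.size == 0 or not np.any(arr > 0):
        raise DegenerateDataError("no usable features: all counts are zero")
    all_pos = np.all(arr > 0, axis=1)
    if all_pos.sum() >= min_positive_features or (
        all_pos.any() and arr.shape[0] < min_positive_features
    ):
        sub = arr[all_pos]
        log_geo = np.mean(np.log(sub), axis=1, keepdims=True)
        factors = np.exp(np.median(np.log(sub) - log_geo, axis=0))
    else:
        col_uq = np.array([
            np.percentile(col[col > 0], 75) if np.any(col > 0) else np.nan
            for col in arr.T
        ])
        if np.isnan(col_uq).any():
            raise DegenerateDataError("no usable features: a sample is all zero")
        factors = col_uq / np.exp(np.mean(np.log(col_uq)))
    if not np.all(factors > 0):
        raise DegenerateDataError("no usable features for size-factor estimation")
    sf = pd.Series(factors, index=counts.columns, name="size_factor")
    return NormalizationResult(size_factors=sf, normalized=counts / sf)


def estimate_common_dispersion(
    m: CountMatrix, size_factors: pd.Series
) -> float:
    """Method-of-moments common NB dispersion from within-group moments.

    For normalized counts ``z = k/s`` of a feature with mean mu,
    ``Var(z_j) = mu/s_j + phi*mu^2``; pooling the within-group sample
    variance v and mean m over features gives the ratio estimator
    ``phi = sum(v - m*mean(1/s)) / sum(m^2)``, clamped at 0.
    Requires at least one group with >= 2 samples.
    """
    groups = [m.samples(CONTROL), m.samples(TREATMENT)]
    if max(len(g) for g in groups) < 2:
        raise DegenerateDataError("dispersion not estimable: no replicated group")
    num = 0.0
    den = 0.0
    for samples in groups:
        if len(samples) < 2:
            continue
        z = np.asarray(m.counts[samples], dtype=float) / np.asarray(
            size_factors[samples], dtype=float
        )
        mu = z.mean(axis=1)
        v = z.var(axis=1, ddof=1)
        inv_s = float(np.mean(1.0 / np.asarray(size_factors[samples])))
        keep = mu > 0
        num += float(np.sum(v[keep] - mu[keep] * inv_s))
        den += float(np.sum(mu[keep] ** 2))
    if den == 0.0:
        return 0.0
    return max(0.0, num / den)


def _group_sum_logpmf(a: np.ndarray, mean: float, phi_group: float) -> np.ndarray:
    """log pmf of a group's count sum: NB matched in mean/variance, Poisson at phi=0."""
    if phi_group <= 0:
        return stats.poisson.logpmf(a, mean)
    r = 1.0 / phi_group
    p = r / (r + mean)
    return stats.nbinom.logpmf(a, r, p)


def nb_exact_test(
    counts: pd.Series | np.ndarray,
    group_of: dict[str, str],
    size_factors: pd.Series,
    dispersion: float,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> tuple[float, float]:
    """Two-sided exact NB test of treatment vs control for one feature.

    The fold change is ``log2((mean normalized treatment + pc) /
    (mean normalized control + pc))``. The p-value conditions on the
    integer total of the two group sums: under the null the split follows
    the ratio of effective sizes (summed size factors); each group sum is
    modelled as NB with matched mean and variance (for per-sample
    dispersion phi the group-sum dispersion is
    ``phi * sum(s_j^2) / sum(s_j)^2``). The smaller of the two tails is
    doubled and capped at 1. ``phi = 0`` reduces to the exact
    binomial/Poisson conditional split.
    """
    counts = pd.Series(counts) if not isinstance(counts, pd.Series) else counts
    if (counts < 0).any():
        raise ValueError("negative counts")
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    ctrl = [s for s in counts.index if group_of.get(s) == CONTROL]
    trt = [s for s in counts.index if group_of.get(s) == TREATMENT]
    if not ctrl or not trt:
        raise ValueError("both groups must be non-empty")

    sf = size_factors
    norm_c = float(np.mean(counts[ctrl] / sf[ctrl]))
    norm_t = float(np.mean(counts[trt] / sf[trt]))
    log2fc = float(np.log2((norm_t + pseudocount) / (norm_c + pseudocount)))

    k_c = int(round(float(counts[ctrl].sum())))
    k_t = int(round(float(counts[trt].sum())))
    total = k_c + k_t
    if total == 0:
        return 0.0 if norm_c == norm_t else log2fc, 1.0

    s_c = np.asarray(sf[ctrl], dtype=float)
    s_t = np.asarray(sf[trt], dtype=float)
    S_c, S_t = s_c.sum(), s_t.sum()
    q0 = total / (S_c + S_t)
    mu_c, mu_t = q0 * S_c, q0 * S_t
    phi_c = dispersion * float(np.sum(s_c**2)) / S_c**2
    phi_t = dispersion * float(np.sum(s_t**2)) / S_t**2

    # enumeration window: +/-12 sd of the conditional mean (mass outside
    # is numerically zero); always covers the observed split.
    var_c = mu_c + phi_c * mu_c**2
    frac = S_c / (S_c + S_t)
    sd = max(1.0, np.sqrt(var_c))
    lo = int(max(0, min(k_c, np.floor(total * frac - 12 * sd))))
    hi = int(min(total, max(k_c, np.ceil(total * frac + 12 * sd))))
    a = np.arange(lo, hi + 1)
    logp = _group_sum_logpmf(a, mu_c, phi_c) + _group_sum_logpmf(
        total - a, mu_t, phi_t
    )
    logp -= special.logsumexp(logp)
    prob = np.exp(logp)
    obs = k_c - lo
    tail_low = float(prob[: obs + 1].sum())   # control sum <= observed
    tail_high = float(prob[obs:].sum())
    p = min(1.0, 2.0 * min(tail_low, tail_high))
    return log2fc, p


def bh_adjust(p: np.ndarray | list[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    ``q_(i) = min_{j >= i} p_(j) * m / j`` over the ascending order
    statistics, mapped back to the input order. Raises on p outside [0, 1].
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def hypergeometric_tail(N: int, K: int, n: int, k: int) -> float:
    """Upper-tail P(X >= k) for X ~ Hypergeometric(N, K, n).

    N genes in the universe, K of them annotated to the term, n selected,
    k in the overlap.
    """
    if not (0 <= K <= N and 0 <= n <= N and 0 <= k <= min(K, n)):
        raise ValueError(
            f"inconsistent counts: N={N}, K={K}, n={n}, k={k}"
        )
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def pearson_correlation(x, y) -> tuple[float, float]:
    """Pearson r and its two-sided p from the t transform with n-2 df."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length vectors with n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise DegenerateDataError("undefined correlation: zero variance")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def run_differential(
    m: CountMatrix,
    dispersion: float | None = None,
    alpha: float = 0.05,
    lfc_threshold: float = 1.0,
    use_fdr: bool = False,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> pd.DataFrame:
    """Full two-group differential run over a count matrix.

    Normalizes, estimates common dispersion unless given, tests every
    feature, BH-adjusts, and applies the significance rule
    ``(q if use_fdr else p) < alpha AND |log2fc| > lfc_threshold``.

    Returns a DataFrame indexed by feature with columns
    log2fc, p_value, q_value, significant, direction.
    """
    norm = estimate_size_factors(m.counts)
    if dispersion is None:
        dispersion = estimate_common_dispersion(m, norm.size_factors)
    rows = []
    for fid in m.counts.index:
        lfc, p = nb_exact_test(
            m.counts.loc[fid], m.group_of, norm.size_factors, dispersion,
            pseudocount=pseudocount,
        )
        rows.append((fid, lfc, p))
    out = pd.DataFrame(rows, columns=["feature_id", "log2fc", "p_value"])
    out = out.set_index("feature_id")
    out["q_value"] = bh_adjust(out["p_value"].to_numpy())
    crit = out["q_value"] if use_fdr else out["p_value"]
    out["significant"] = (crit < alpha) & (out["log2fc"].abs() > lfc_threshold)
    out["direction"] = np.where(
        ~out["significant"], "none", np.where(out["log2fc"] > 0, "up", "down")
    )
    return out
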