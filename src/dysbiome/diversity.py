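"""Alpha-diversity panel, Good's coverage, rarefaction and evenness analyses.

Richness is summarised by the bias-corrected Chao-1 estimator and Fisher's
log-series alpha, diversity by the Shannon index (natural log) and evenness
by Simpson's 1-D.  Good's coverage (1 - singletons/reads) gauges sequencing
depth adequacy, and rarefaction curves track expected richness under random
subsampling without replacement.

The evenness of a community is additionally profiled by the successive
relative-contribution difference curve: genera contributing at least 1% are
sorted descending and adjacent differences are plotted; a steep (log-trend)
slope marks dominance by a few genera, a flat one an even community.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import wilcoxon as _scipy_wilcoxon

from .tables import (
    CLASSES,
    AbundanceTable,
    ValidationError,
    to_relative,
)


def _as_composition(p) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if (p < 0).any():
        raise ValidationError("composition entries must be non-negative")
    s = p.sum()
    if s <= 0:
        raise ValidationError("composition sums to zero")
    if abs(s - 1.0) > 1e-8:
        p = p / s
    return p[p > 0]


def shannon(p) -> float:
    """Shannon diversity H = -sum p_i ln p_i (natural log, zeros skipped)."""
    p = _as_composition(p)
    return float(-(p * np.log(p)).sum())


def simpson_1_minus_D(p) -> float:
    """Simpson evenness 1 - D = 1 - sum p_i^2."""
    p = _as_composition(p)
    return float(1.0 - (p * p).sum())


def _as_counts(counts) -> np.ndarray:
    c = np.asarray(counts)
    if c.size == 0:
        raise ValidationError("empty count vector")
    if np.any(c < 0):
        raise ValidationError("counts must be non-negative")
    if not np.allclose(c, np.round(c)):
        raise ValidationError("counts must be integers")
    return np.round(c).astype(np.int64)


def chao1(counts) -> float:
    """Bias-corrected Chao-1 richness: S_obs + F1(F1-1) / (2(F2+1))."""
    c = _as_counts(counts)
    s_obs = int((c > 0).sum())
    f1 = int((c == 1).sum())
    f2 = int((c == 2).sum())
    return s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))


def fisher_alpha(S: int, N: int, tol: float = 1e-9) -> float:
    """Fisher's log-series alpha: the root of S = alpha * ln(1 + N/alpha).

    Undefined when S == N (every individual a distinct taxon).
    """
    if not (1 <= S <= N):
        raise ValidationError(f"need 1 <= S <= N, got S={S}, N={N}")
    if S == N:
        raise ValidationError("Fisher's alpha undefined when S == N (all singletons)")

    def f(a):
        return a * math.log1p(N / a) - S

    lo = 1e-12
    hi = 1.0
    while f(hi) < 0:
        hi *= 2.0
        if hi > 1e12:
            raise ValidationError("Fisher's alpha failed to bracket")
    return float(brentq(f, lo, hi, xtol=tol))


def goods_coverage(counts) -> float:
    """Good's coverage 1 - F1/N (F1 singletons, N total reads)."""
    c = _as_counts(counts)
    n = int(c.sum())
    if n == 0:
        raise ValidationError("empty sample (zero total count)")
    f1 = int((c == 1).sum())
    return 1.0 - f1 / n


def rarefaction_curve(counts, depths, reps: int = 10, seed: int = 0):
    """Mean observed richness over *reps* random subsamples (without
    replacement) at each depth.  Returns a list of (depth, mean_richness)."""
    c = _as_counts(counts)
    pos = c[c > 0]
    n = int(pos.sum())
    rng = np.random.default_rng(seed)
    out = []
    for d in depths:
        d = int(d)
        if d < 1 or d > n:
            raise ValidationError(f"rarefaction depth {d} outside [1, {n}]")
        if d == n:
            out.append((d, float((c > 0).sum())))
            continue
        rich = [
            int((rng.multivariate_hypergeometric(pos, d) > 0).sum())
            for _ in range(reps)
        ]
        out.append((d, float(np.mean(rich))))
    return out


def expected_rarefaction(counts, depth: int) -> float:
    """Exact hypergeometric expectation of rarefied richness,
    E[S_d] = sum_i (1 - C(N-n_i, d) / C(N, d))."""
    c = _as_counts(counts)
    pos = c[c > 0].astype(float)
    n = pos.sum()
    if not (1 <= depth <= n):
        raise ValidationError(f"depth {depth} outside [1, {int(n)}]")
    # log-gamma evaluation of C(N-n_i, d)/C(N, d)
    from scipy.special import gammaln

    def logC(a, b):
        return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)

    terms = np.where(
        n - pos >= depth,
        np.exp(logC(n - pos, depth) - logC(n, depth)),
        0.0,
    )
    return float((1.0 - terms).sum())


@dataclass
class EvennessCurve:
    """Descending contributions >= min_pct, their successive differences and
    the slope of a log-trend fit (difference vs ln(position))."""

    contributions: np.ndarray
    differences: np.ndarray
    slope: float
    min_pct: float


def successive_contribution_differences(contrib, min_pct: float = 1.0) -> EvennessCurve:
    """Evenness curve from a taxon -> percent mapping (retain >= *min_pct*,
    sort descending, difference adjacent values, fit slope vs ln(rank))."""
    if min_pct < 0:
        raise ValidationError("min_pct must be >= 0")
    vals = pd.Series(contrib, dtype=float)
    kept = np.sort(vals[vals >= min_pct].to_numpy())[::-1]
    if kept.size < 2:
        raise ValidationError(
            f"need >= 2 taxa with contribution >= {min_pct}%, got {kept.size}"
        )
    diffs = -np.diff(kept)
    x = np.log(np.arange(1, diffs.size + 1, dtype=float))
    if diffs.size == 1 or np.allclose(x, x[0]):
        slope = 0.0
    else:
        slope = float(np.polyfit(x, diffs, 1)[0])
    return EvennessCurve(kept, diffs, slope, min_pct)


def taxa_at_thresholds(contrib, thresholds=(0.01, 0.1, 1.0)) -> dict[float, int]:
    """Number of taxa whose contribution is at least each threshold percent."""
    vals = pd.Series(contrib, dtype=float)
    out = {}
    for t in thresholds:
        if t <= 0:
            raise ValidationError("thresholds must be positive")
        out[float(t)] = int((vals >= t).sum())
    return out


def diversity_report(table: AbundanceTable, meta) -> pd.DataFrame:
    """Per-sample alpha-diversity panel from a counts table.

    Columns: observed_richness, chao1, fisher_alpha, shannon,
    simpson_1_minus_D, goods_coverage, class.  Fisher's alpha is NaN where
    undefined (all reads singletons).
    """
    if table.unit != "counts":
        raise ValidationError("diversity_report expects a counts table")
    klass_of = {m.sample_id: m.klass for m in meta}
    rel = to_relative(table)
    rows = []
    for s in table.samples:
        c = table.data[s].to_numpy()
        p = rel.data[s].to_numpy() / 100.0
        s_obs = int((c > 0).sum())
        n = int(c.sum())
        try:
            fa = fisher_alpha(s_obs, n)
        except ValidationError:
            fa = float("nan")
        rows.append(
            {
                "sample_id": s,
                "class": klass_of.get(s, ""),
                "observed_richness": s_obs,
                "chao1": chao1(c),
                "fisher_alpha": fa,
                "shannon": shannon(p),
                "simpson_1_minus_D": simpson_1_minus_D(p),
                "goods_coverage": goods_coverage(c),
            }
        )
    return pd.DataFrame(rows).set_index("sample_id")


def compare_indices_by_class(report: pd.DataFrame, meta) -> pd.Series:
    """Paired (within-subject) two-sided Wilcoxon signed-rank p-values for
    each diversity index between the two sample classes."""
    subj = {m.sample_id: m.subject_id for m in meta}
    klass = {m.sample_id: m.klass for m in meta}
    cols = ["observed_richness", "chao1", "fisher_alpha", "shannon",
            "simpson_1_minus_D", "goods_coverage"]
    pairs: dict[str, dict[str, str]] = {}
    for s in report.index:
        pairs.setdefault(subj[s], {})[klass[s]] = s
    ps = {}
    for col in cols:
        diffs = [
            report.loc[p[CLASSES[0]], col] - report.loc[p[CLASSES[1]], col]
            for p in pairs.values()
            if len(p) == 2
        ]
        diffs = np.asarray(diffs, dtype=float)
        diffs = diffs[np.isfinite(diffs)]
        nz = diffs[diffs != 0]
        if nz.size == 0:
            ps[col] = float("nan")
            continue
        ps[col] = float(_scipy_wilcoxon(diffs, zero_method="wilcox").pvalue)
    return pd.Series(ps, name="wilcoxon_signed_rank_p")
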