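"""Bootstrapped nonparametric differential-abundance procedure.

The procedure decides, per taxon, whether its relative abundance differs
between lesional and non-lesional samples, using subsampled class medians as
the unit of comparison:

Step 1: draw 50% of the samples from each class at random (without
replacement).
Step 2: record the median abundance of every taxon within each class's
subset.

Steps 1-2 are repeated 40 times, giving two 40-vectors of medians per taxon.
A two-sided Wilcoxon rank-sum test compares the vectors, and Benjamini-
Hochberg correction across taxa at FDR 1e-4 marks significant taxa.  The
whole block is bootstrapped 1000 times; taxa marked in at least 99.5% of the
outer iterations are retained.  Direction of change is read off the overall
class medians of per-sample abundance.

The plain paired Wilcoxon signed-rank screen used alongside it, and the BH
step-up correction, are exposed as standalone functions.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .tables import (
    LESIONAL,
    NON_LESIONAL,
    AbundanceTable,
    ValidationError,
    relative_contribution,
)

DIRECTION_LESIONAL = "higher_in_lesional"
DIRECTION_NON_LESIONAL = "higher_in_non_lesional"
DIRECTION_UNDETERMINED = "undetermined"


# ---------------------------------------------------------------------------
# elementary tests


def wilcoxon_rank_sum(x, y) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    Exact-enumeration null for combined n <= 20 without ties; otherwise the
    normal approximation with tie and continuity corrections.  Returns NaN
    when every value is identical (zero-variance; p undefined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("rank-sum test needs non-empty samples")
    combined = np.concatenate([x, y])
    if np.all(combined == combined[0]):
        return float("nan")
    has_ties = np.unique(combined).size < combined.size
    if combined.size <= 20 and not has_ties:
        return float(stats.mannwhitneyu(x, y, method="exact").pvalue)
    return float(_ranksum_asymptotic(x[:, None], y[:, None])[0])


def _ranksum_asymptotic(xm: np.ndarray, ym: np.ndarray) -> np.ndarray:
    """Vectorised two-sided normal-approximation rank-sum p-values.

    *xm* (n1, T) and *ym* (n2, T) hold T independent columns.  Tie correction
    is recovered from the variance of the midranks (Var(r) = (n^2-1)/12 -
    sum(t^3-t)/(12 n)); a 0.5 continuity correction is applied.  Columns with
    zero rank variance give NaN.
    """
    n1, n2 = xm.shape[0], ym.shape[0]
    n = n1 + n2
    allv = np.concatenate([xm, ym], axis=0)
    r = stats.rankdata(allv, axis=0)
    u1 = r[:n1].sum(axis=0) - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    tie_sum = np.clip(n * (n * n - 1) - 12.0 * n * r.var(axis=0), 0.0, None)
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_sum / (n * (n - 1.0)))
    sigma = np.sqrt(np.clip(sigma2, 0.0, None))
    num = np.maximum(np.abs(u1 - mu) - 0.5, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sigma > 0, num / np.where(sigma > 0, sigma, 1.0), np.nan)
    return np.where(np.isnan(z), np.nan, np.minimum(2.0 * stats.norm.sf(z), 1.0))


def wilcoxon_signed_rank(paired_diffs) -> float:
    """Two-sided Wilcoxon signed-rank p-value on paired differences.

    Zero differences are dropped.  Exact null for <= 25 nonzero untied
    absolute differences, else normal approximation with continuity
    correction.
    """
    d = np.asarray(paired_diffs, dtype=float)
    d = d[d != 0]
    if d.size == 0:
        raise ValidationError("signed-rank test needs at least one nonzero difference")
    tied = np.unique(np.abs(d)).size < d.size
    if d.size <= 25 and not tied:
        return float(stats.wilcoxon(d, zero_method="wilcox", method="exact").pvalue)
    return float(
        stats.wilcoxon(d, zero_method="wilcox", method="approx", correction=True).pvalue
    )


def bh_correct(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# the bootstrapped procedure


@dataclass
class BootDiffParams:
    """Parameters of the bootstrapped differential-abundance procedure."""

    subsample_fraction: float = 0.5
    n_median_reps: int = 40
    n_bootstraps: int = 1000
    fdr: float = 1e-4
    retention_fraction: float = 0.995
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.subsample_fraction <= 1):
            raise ValidationError("subsample_fraction must be in (0, 1]")
        if self.n_median_reps < 1 or self.n_bootstraps < 1:
            raise ValidationError("n_median_reps and n_bootstraps must be >= 1")
        if not (0 < self.fdr < 1):
            raise ValidationError("fdr must be in (0, 1)")
        if not (0 < self.retention_fraction <= 1):
            raise ValidationError("retention_fraction must be in (0, 1]")


@dataclass
class DiffAbundanceResult:
    """Per-taxon verdicts in a Table-like layout.

    ``frame`` columns: retention (fraction of outer iterations marked),
    significant, direction, rel_contrib / median / min / max per class.
    """

    frame: pd.DataFrame
    params: BootDiffParams

    @property
    def significant_taxa(self) -> list[str]:
        return list(self.frame.index[self.frame["significant"]])


def _group_rng_key(sample_ids) -> int:
    """Stable 32-bit key for a class group derived from its member ids, so a
    group keeps its own random draws regardless of which label it carries."""
    return zlib.crc32("|".join(sorted(sample_ids)).encode())


def bootstrapped_diff(
    table: AbundanceTable, meta, params: BootDiffParams
) -> DiffAbundanceResult:
    """Run the full subsampled-median / rank-sum / BH / retention procedure.

    *table* must be a percent table; *meta* supplies the class labels.
    Taxa with zero abundance in every sample of both classes are excluded
    from testing (constant-zero medians, p undefined) and reported with
    retention 0.
    """
    if table.unit != "percent":
        raise ValidationError("bootstrapped_diff expects a percent table")
    groups = {}
    for klass in (LESIONAL, NON_LESIONAL):
        ids = [m.sample_id for m in meta
               if m.klass == klass and m.sample_id in table.data.columns]
        if len(ids) < 2:
            raise ValidationError(f"class {klass!r} needs >= 2 samples, got {len(ids)}")
        groups[klass] = sorted(ids)

    k = {kl: int(params.subsample_fraction * len(ids)) for kl, ids in groups.items()}
    for kl, kk in k.items():
        if kk < 1:
            raise ValidationError(
                f"subsample of class {kl!r} is empty "
                f"({params.subsample_fraction} of {len(groups[kl])} samples)"
            )

    vals = {kl: table.data[ids].to_numpy(dtype=float) for kl, ids in groups.items()}
    taxa = np.asarray(table.taxa)
    nonzero = (vals[LESIONAL].sum(axis=1) + vals[NON_LESIONAL].sum(axis=1)) > 0
    tested = {kl: v[nonzero] for kl, v in vals.items()}
    n_tested = int(nonzero.sum())

    marked = np.zeros(n_tested, dtype=np.int64)
    if n_tested:
        keys = {kl: _group_rng_key(ids) for kl, ids in groups.items()}
        for b in range(params.n_bootstraps):
            meds = {}
            for kl in (LESIONAL, NON_LESIONAL):
                rng = np.random.default_rng(
                    np.random.SeedSequence([params.seed, keys[kl], b])
                )
                n_cls = len(groups[kl])
                # one subset draw per inner repetition, shared by all taxa
                idx = np.argsort(
                    rng.random((params.n_median_reps, n_cls)), axis=1
                )[:, : k[kl]]
                meds[kl] = np.median(tested[kl][:, idx], axis=2)  # (T, reps)
            p = _ranksum_asymptotic(meds[LESIONAL].T, meds[NON_LESIONAL].T)
            # degenerate case (e.g. subsample_fraction=1): both median
            # vectors constant -> test undefined -> taxon not marked
            degenerate = (np.ptp(meds[LESIONAL], axis=1) == 0) & (
                np.ptp(meds[NON_LESIONAL], axis=1) == 0
            )
            p[degenerate] = np.nan
            ok = np.isfinite(p)
            if ok.any():
                adj = bh_correct(p[ok])
                hits = np.zeros(n_tested, dtype=bool)
                hits[np.flatnonzero(ok)[adj <= params.fdr]] = True
                marked += hits

    retention = np.zeros(len(taxa))
    retention[nonzero] = marked / params.n_bootstraps
    significant = retention >= params.retention_fraction - 1e-12

    med = {kl: np.median(v, axis=1) for kl, v in vals.items()}
    direction = np.where(
        med[LESIONAL] > med[NON_LESIONAL],
        DIRECTION_LESIONAL,
        np.where(
            med[LESIONAL] < med[NON_LESIONAL],
            DIRECTION_NON_LESIONAL,
            DIRECTION_UNDETERMINED,
        ),
    )
    contrib = {
        kl: relative_contribution(table, meta, kl).to_numpy()
        for kl in (NON_LESIONAL, LESIONAL)
    }
    frame = pd.DataFrame(
        {
            "retention": retention,
            "significant": significant,
            "direction": direction,
            "rel_contrib_non_lesional": contrib[NON_LESIONAL],
            "rel_contrib_lesional": contrib[LESIONAL],
            "median_non_lesional": med[NON_LESIONAL],
            "median_lesional": med[LESIONAL],
            "min_non_lesional": vals[NON_LESIONAL].min(axis=1),
            "max_non_lesional": vals[NON_LESIONAL].max(axis=1),
            "min_lesional": vals[LESIONAL].min(axis=1),
            "max_lesional": vals[LESIONAL].max(axis=1),
        },
        index=pd.Index(taxa, name="taxon_id"),
    )
    return DiffAbundanceResult(frame, params)
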