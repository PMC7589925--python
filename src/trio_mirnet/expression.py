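"""Normalization, differential expression and expression-profile summaries.

Small-RNA counts are normalized to reads per million (RPM); mRNA counts to
FPKM (fragments per kilobase of transcript per million mapped fragments).

Differential expression is tested per feature on log2(x + pseudocount)
transformed normalized abundances. For two-group contrasts the default is a
moderated pooled t-test: the per-feature pooled variance is shrunk toward a
prior estimated across all features by empirical Bayes (scaled inverse
chi-square prior fitted by moments on log sample variances), which restores
power and calibration at the small replicate counts typical of sequencing
designs; a plain Welch (unequal-variance) t and a plain Student t are
selectable, and contrasts with more than two groups use a one-way ANOVA.
Benjamini-Hochberg q-values are reported alongside the raw p-values; the
pipeline's significance filter is raw p < alpha (default 0.05), q kept for
transparency.

Also here: presence/Venn membership of features across condition groups,
the six-way temporal classification of developmental profiles over the five
grain time-points, and the 2^-ddCt fold-change convention used for qPCR
comparisons.
"""

from __future__ import annotations

from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .types import AbundanceMatrix

DE_COLUMNS = ["feature_id", "contrast", "log2fc", "p_value", "q_value", "test"]

DE_METHODS = ("moderated_t", "welch_t", "student_t", "anova")


def _fit_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moments fit of a scaled inverse chi-square prior for sample variances.

    Given per-feature pooled variances ``s2`` with ``df`` residual degrees of
    freedom each, returns (d0, s0_squared): the prior degrees of freedom and
    prior variance such that s2 ~ s0^2 * F(df, d0). Follows the log-variance
    moment equations (digamma/trigamma); d0 = inf when the observed spread of
    log variances is no larger than the chi-square sampling spread alone.
    """
    from scipy.special import digamma, polygamma

    s2 = np.asarray(s2, dtype=float)
    positive = s2[s2 > 0]
    if len(positive) < 2:
        return np.inf, float(positive[0]) if len(positive) else 1.0
    z = np.log(positive)
    e = z - digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = float(e.mean())
    excess = float(e.var(ddof=1)) - float(polygamma(1, df / 2.0))
    if excess <= 0:
        return np.inf, float(np.exp(e_mean))
    # invert trigamma(d0/2) = excess by Newton iteration
    y = 0.5 + 1.0 / excess  # starting value from trigamma(x) ~ 1/x
    for _ in range(50):
        tri = float(polygamma(1, y))
        step = tri * (1.0 - tri / excess) / float(polygamma(2, y))
        y = max(y + step, 1e-8)
        if abs(step) < 1e-10 * y:
            break
    d0 = 2.0 * y
    s0_sq = float(np.exp(e_mean + digamma(y) - np.log(y)))
    return d0, s0_sq


def _moderated_t(
    a: np.ndarray, b: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Two-sided moderated pooled t across features (rows of a and b)."""
    n1, n2 = a.shape[1], b.shape[1]
    df = n1 + n2 - 2
    v1 = a.var(axis=1, ddof=1)
    v2 = b.var(axis=1, ddof=1)
    s2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
    d0, s0_sq = _fit_variance_prior(s2, df)
    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_sq)
        df_post = 1e6
    else:
        s2_post = (d0 * s0_sq + df * s2) / (d0 + df)
        df_post = d0 + df
    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (a.mean(axis=1) - b.mean(axis=1)) / se
    p = 2.0 * stats.t.sf(np.abs(t), df_post)
    return t, p


def normalize_rpm(matrix: AbundanceMatrix) -> AbundanceMatrix:
    """Scale raw counts to reads per million; column sums become 10^6."""
    if matrix.unit != "raw_count":
        raise ValueError(f"RPM normalization expects raw counts, got {matrix.unit}")
    totals = matrix.values.sum(axis=0)
    zero = totals.index[totals <= 0]
    if len(zero):
        raise ValueError(f"library with zero total counts: {list(zero)}")
    return AbundanceMatrix(
        values=matrix.values / totals * 1e6,
        meta=matrix.meta,
        unit="RPM",
        feature_lengths=matrix.feature_lengths,
    )


def compute_fpkm(
    matrix: AbundanceMatrix, lengths: Optional[pd.Series] = None
) -> AbundanceMatrix:
    """FPKM = count * 10^9 / (length_nt * library_total)."""
    if matrix.unit != "raw_count":
        raise ValueError(f"FPKM normalization expects raw counts, got {matrix.unit}")
    if lengths is None:
        lengths = matrix.feature_lengths
    if lengths is None:
        raise ValueError("FPKM requires feature lengths (nt)")
    missing = matrix.values.index.difference(lengths.index)
    if len(missing):
        raise ValueError(f"missing lengths for features: {list(missing)[:5]}")
    lengths = lengths.loc[matrix.values.index].astype(float)
    if (lengths <= 0).any():
        raise ValueError("feature lengths must be positive")
    totals = matrix.values.sum(axis=0)
    zero = totals.index[totals <= 0]
    if len(zero):
        raise ValueError(f"library with zero total counts: {list(zero)}")
    fpkm = matrix.values.mul(1e9).div(lengths, axis=0).div(totals, axis=1)
    return AbundanceMatrix(
        values=fpkm, meta=matrix.meta, unit="FPKM", feature_lengths=lengths
    )


def five_number_summary(values: Sequence[float]) -> dict[str, float]:
    """Min, lower quartile, median, upper quartile, max of one library."""
    v = np.asarray(values, dtype=float)
    q = np.percentile(v, [0, 25, 50, 75, 100])
    return dict(zip(["min", "q1", "median", "q3", "max"], map(float, q)))


def test_differential(
    matrix: AbundanceMatrix,
    groups: Mapping[str, Sequence[str]],
    method: str = "auto",
    pseudocount: float = 1.0,
    contrast: Optional[str] = None,
    log_transform: bool = True,
) -> pd.DataFrame:
    """Per-feature differential test between library groups.

    ``groups`` maps group label -> library ids. With two groups the test is
    two-sided on log2(x + pseudocount) values (``log_transform=False`` tests
    the raw values): ``moderated_t`` (default) shrinks the pooled variance
    across features by empirical Bayes, ``student_t`` and ``welch_t`` are
    the plain pooled and unequal-variance t-tests. log2fc is
    log2((mean1 + pc) / (mean2 + pc)) of the untransformed group means, in
    the given group order. With more groups a one-way ANOVA is used and
    log2fc is 0.0 (an omnibus test carries no direction). Features that are
    all-zero across the tested libraries get p = 1 and log2fc = 0 by
    convention. q-values are Benjamini-Hochberg over the tested features.
    """
    labels = list(groups)
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    for lab in labels:
        if len(groups[lab]) < 2:
            raise ValueError(f"group {lab!r} has <2 replicates")
    if method == "auto":
        method = "moderated_t" if len(labels) == 2 else "anova"
    if method not in DE_METHODS:
        raise ValueError(f"unknown method {method!r}")
    if method != "anova" and len(labels) != 2:
        raise ValueError(f"{method} requires exactly two groups")

    arrays = [matrix.values[list(groups[lab])].to_numpy(dtype=float) for lab in labels]
    stacked = np.concatenate(arrays, axis=1)
    all_zero = ~(stacked > 0).any(axis=1)
    tested = (
        [np.log2(a + pseudocount) for a in arrays] if log_transform else arrays
    )

    if method == "anova":
        with np.errstate(divide="ignore", invalid="ignore"):
            _, p = stats.f_oneway(*tested, axis=1)
        log2fc = np.zeros(len(matrix.values))
        default_contrast = "_vs_".join(labels)
    else:
        if method == "moderated_t":
            _, p = _moderated_t(tested[0], tested[1])
        else:
            with np.errstate(divide="ignore", invalid="ignore"):
                _, p = stats.ttest_ind(
                    tested[0], tested[1], axis=1, equal_var=(method == "student_t")
                )
        m1 = arrays[0].mean(axis=1)
        m2 = arrays[1].mean(axis=1)
        log2fc = np.log2((m1 + pseudocount) / (m2 + pseudocount))
        default_contrast = f"{labels[0]}_vs_{labels[1]}"

    p = np.asarray(p, dtype=float)
    p[~np.isfinite(p)] = 1.0  # degenerate variance (e.g. identical groups)
    p[all_zero] = 1.0
    log2fc = np.where(all_zero, 0.0, log2fc)
    q = multipletests(p, method="fdr_bh")[1]

    return pd.DataFrame(
        {
            "feature_id": matrix.values.index,
            "contrast": contrast or default_contrast,
            "log2fc": log2fc,
            "p_value": p,
            "q_value": q,
            "test": method,
        },
        columns=DE_COLUMNS,
    ).reset_index(drop=True)


TEMPORAL_CLASSES = (
    "descending",
    "ascending",
    "peak_15",
    "peak_25",
    "peak_35",
    "other",
)


def classify_temporal_pattern(
    profile: Sequence[float],
    fold_threshold: float = 2.0,
    timepoints: Sequence[int] = (5, 15, 25, 35, 45),
) -> str:
    """Classify a five-point developmental profile into six categories.

    Descending: non-increasing across the five time-points with at least a
    ``fold_threshold``-fold end-to-end drop (5 DPA vs 45 DPA); ascending is
    the mirror image. peak_15/25/35: the unique maximum sits at that interior
    time-point. Everything else is "other". The rule is scale-invariant.
    """
    v = np.asarray(profile, dtype=float)
    if v.shape != (len(timepoints),):
        raise ValueError(f"expected {len(timepoints)} values, got {v.shape}")
    if not np.all(np.isfinite(v)) or (v < 0).any():
        raise ValueError("profile values must be finite and non-negative")

    rtol = 1e-9
    non_increasing = np.all(v[1:] <= v[:-1] * (1 + rtol))
    non_decreasing = np.all(v[1:] >= v[:-1] * (1 - rtol))
    if non_increasing and v[0] >= fold_threshold * v[-1] and v[0] > 0:
        return "descending"
    if non_decreasing and v[-1] >= fold_threshold * v[0] and v[-1] > 0:
        return "ascending"
    peak = int(np.argmax(v))
    if peak in (1, 2, 3) and np.sum(v == v[peak]) == 1:
        return f"peak_{timepoints[peak]}"
    return "other"


def expression_membership(
    matrix: AbundanceMatrix,
    by: str = "treatment",
    presence_threshold: float = 0.0,
    where: Optional[Mapping[str, object]] = None,
) -> dict[str, frozenset]:
    """Which condition groups each feature is expressed in.

    A feature is present in a group iff its maximum abundance over that
    group's libraries exceeds ``presence_threshold``. ``where`` optionally
    restricts the libraries first (e.g. one genotype at one time-point), the
    layout behind per-time-point treatment Venn diagrams.
    """
    if where:
        matrix = matrix.subset(matrix.libraries_where(**where))
    groups = matrix.meta.groupby(by, sort=True).groups
    membership: dict[str, set] = {f: set() for f in matrix.values.index}
    for group_label, lib_ids in groups.items():
        gmax = matrix.values[list(lib_ids)].max(axis=1)
        for feat in gmax.index[gmax > presence_threshold]:
            membership[feat].add(group_label)
    return {f: frozenset(s) for f, s in membership.items()}


def venn_region_counts(membership: Mapping[str, frozenset]) -> dict[tuple, int]:
    """Count features per exact Venn region (keyed by the sorted group tuple).

    Features expressed nowhere are excluded, matching how expression Venn
    diagrams are drawn.
    """
    out: dict[tuple, int] = {}
    for groups in membership.values():
        if not groups:
            continue
        key = tuple(sorted(groups))
        out[key] = out.get(key, 0) + 1
    return out


def log2fc_ddct(
    ct_target_stress: float,
    ct_housekeeping_stress: float,
    ct_target_control: float,
    ct_housekeeping_control: float,
) -> float:
    """log2 fold-change from the 2^-ddCt relative-quantification convention.

    ddCt = (Ct_target,stress - Ct_hk,stress) - (Ct_target,control -
    Ct_hk,control); the returned value is log2(2^-ddCt) = -ddCt.
    """
    cts = (
        ct_target_stress,
        ct_housekeeping_stress,
        ct_target_control,
        ct_housekeeping_control,
    )
    if not all(np.isfinite(c) for c in cts):
        raise ValueError("Ct values must be finite")
    ddct = (ct_target_stress - ct_housekeeping_stress) - (
        ct_target_control - ct_housekeeping_control
    )
    return -ddct
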