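"""Copy-number / expression integration statistics.

For each candidate region the cohort is partitioned into a gain group G
(region copy number > 3) and a neutral group N (1.5-2.5 copies); samples with
loss or intermediate copy number are excluded.  Per gene a linear model

    expression ~ group + histotype

is fitted by least squares and the group coefficient (logFC, log2 units) is
tested with an empirical-Bayes moderated t statistic: the per-gene residual
variances s_g^2 (d_g df) are shrunk toward a common prior s_0^2 with d_0
prior degrees of freedom, the hyperparameters being estimated by matching the
first two moments of log s_g^2 through digamma/trigamma identities.  The
moderated statistic t = logFC / (s~_g * sqrt(v_g)) has d_0 + d_g degrees of
freedom.  P values are adjusted with the Benjamini-Hochberg step-up rule.

Gene-level copy number is the length-weighted mean of segment means over the
gene interval extended by a 10 kb flank on each side, and is correlated with
expression by Pearson's r.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats as sps

__all__ = [
    "GroupAssignment",
    "ModerationPrior",
    "gene_copy_number",
    "gene_cn_matrix",
    "interval_copy_number",
    "assign_groups",
    "estimate_moderation_prior",
    "moderated_t_test",
    "bh_adjust",
    "cn_expr_correlation",
    "welch_t_test",
]

DEFAULT_FLANK = 10_000
GAIN_GROUP_CUTOFF = 3.0
NEUTRAL_RANGE = (1.5, 2.5)


@dataclass(frozen=True)
class GroupAssignment:
    """Per-region partition of the cohort into gain (G) and neutral (N)."""

    region_id: str
    G: tuple[str, ...]
    N: tuple[str, ...]
    excluded: dict[str, str]  # sample -> reason (loss | intermediate | missing)

    @property
    def testable(self) -> bool:
        return len(self.G) >= 2 and len(self.N) >= 2


@dataclass(frozen=True)
class ModerationPrior:
    """Empirical-Bayes variance prior: d0 prior df and s0^2 prior variance."""

    d0: float
    s0_sq: float

    def __post_init__(self) -> None:
        if not (self.d0 > 0 or math.isinf(self.d0)):
            raise ValueError("d0 must be positive (inf allowed)")
        if not self.s0_sq > 0:
            raise ValueError("s0_sq must be positive")


# ---------------------------------------------------------------------------
# gene-level copy number


def interval_copy_number(segments: pd.DataFrame, chrom: str, start: int,
                         end: int) -> float:
    """Length-weighted mean segment CN over [start, end); NaN if no overlap.

    ``segments`` holds one sample's segments (columns chrom, start, end,
    mean_cn).  Only the overlapping portion of each segment contributes.
    """
    sub = segments[(segments["chrom"] == chrom) & (segments["end"] > start)
                   & (segments["start"] < end)]
    if sub.empty:
        return float("nan")
    ov = (np.minimum(sub["end"].to_numpy(), end)
          - np.maximum(sub["start"].to_numpy(), start))
    return float(np.average(sub["mean_cn"].to_numpy(), weights=ov))


def gene_copy_number(segments: pd.DataFrame, gene: tuple[str, int, int],
                     flank: int = DEFAULT_FLANK) -> float:
    """Copy number of one gene in one sample, with +-``flank`` bp added."""
    chrom, start, end = gene
    return interval_copy_number(segments, chrom, max(0, start - flank), end + flank)


def gene_cn_matrix(segments: pd.DataFrame, genes: pd.DataFrame,
                   flank: int = DEFAULT_FLANK) -> pd.DataFrame:
    """Genes x samples matrix of flanked gene-level copy number.

    ``segments`` is a cohort segment table (sample column required); ``genes``
    needs columns gene, chrom, start, end.  Missing coverage yields NaN.
    """
    samples = sorted(segments["sample"].unique())
    out = np.full((len(genes), len(samples)), np.nan)
    for j, sample in enumerate(samples):
        segs = segments[segments["sample"] == sample]
        for chrom, cgrp in segs.groupby("chrom"):
            gsel = genes.index[genes["chrom"] == chrom]
            if len(gsel) == 0:
                continue
            starts = cgrp["start"].to_numpy()
            ends = cgrp["end"].to_numpy()
            means = cgrp["mean_cn"].to_numpy()
            for gi in gsel:
                g = genes.loc[gi]
                a = max(0, int(g["start"]) - flank)
                b = int(g["end"]) + flank
                ov = np.minimum(ends, b) - np.maximum(starts, a)
                mask = ov > 0
                if mask.any():
                    out[genes.index.get_loc(gi), j] = np.average(
                        means[mask], weights=ov[mask])
    return pd.DataFrame(out, index=genes["gene"].to_numpy(), columns=samples)


# ---------------------------------------------------------------------------
# group assignment


def assign_groups(region_id: str, region_cn: pd.Series,
                  gain_group_cutoff: float = GAIN_GROUP_CUTOFF,
                  neutral_range: tuple[float, float] = NEUTRAL_RANGE
                  ) -> GroupAssignment:
    """Partition samples by their copy number at one region.

    G: CN strictly above ``gain_group_cutoff`` (default 3).  N: CN inside the
    closed ``neutral_range`` (default [1.5, 2.5]).  Everything else is
    excluded with a reason: below the neutral range is a loss, between the
    neutral range and the gain cutoff is intermediate, NaN is missing.
    """
    lo, hi = neutral_range
    if not lo < hi <= gain_group_cutoff:
        raise ValueError("need neutral lo < hi <= gain cutoff")
    G, N, excluded = [], [], {}
    for sample, cn in region_cn.items():
        if pd.isna(cn):
            excluded[sample] = "missing"
        elif cn > gain_group_cutoff:
            G.append(sample)
        elif lo <= cn <= hi:
            N.append(sample)
        elif cn < lo:
            excluded[sample] = "loss"
        else:
            excluded[sample] = "intermediate"
    return GroupAssignment(region_id=region_id, G=tuple(G), N=tuple(N),
                           excluded=excluded)


# ---------------------------------------------------------------------------
# moderated t


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration."""
    if x <= 0:
        raise ValueError("trigamma inverse needs x > 0")
    if x > 1e7:
        return 1.0 / math.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = float(special.polygamma(1, y))
        dif = tri * (1.0 - tri / x) / float(special.polygamma(2, y))
        y += dif
        if -dif / y < 1e-8:
            break
    return y


def estimate_moderation_prior(s2: np.ndarray, df: np.ndarray) -> ModerationPrior:
    """Fit the scaled inverse-chi-square variance prior (d0, s0^2).

    Matches the mean and variance of log s_g^2 using the digamma/trigamma
    moments of the log chi-square distribution.  Genes with non-positive
    variance or zero df are ignored.  When the observed spread of log s_g^2
    does not exceed what the residual chi-square alone explains, d0 is
    infinite (all variances shrink fully to s0^2).
    """
    s2 = np.asarray(s2, dtype=float)
    df = np.asarray(df, dtype=float)
    keep = (s2 > 0) & (df > 0) & np.isfinite(s2)
    s2, df = s2[keep], df[keep]
    if s2.size < 2:
        raise ValueError("need at least two positive variances to fit the prior")
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = float(e.mean())
    n = e.size
    e_var = float(((e - e_mean) ** 2).sum() / (n - 1))
    excess = e_var - float(np.mean(special.polygamma(1, df / 2.0)))
    if excess > 0:
        d0 = 2.0 * _trigamma_inverse(excess)
        s0_sq = math.exp(e_mean + float(special.digamma(d0 / 2.0)) - math.log(d0 / 2.0))
    else:
        d0 = math.inf
        s0_sq = math.exp(e_mean)
    return ModerationPrior(d0=d0, s0_sq=s0_sq)


def _design_matrix(groups: GroupAssignment,
                   histotypes: pd.Series | None) -> tuple[np.ndarray, list[str]]:
    """Intercept + G indicator + histotype dummies over the G∪N samples.

    Histotype levels with fewer than two samples among G∪N are collapsed into
    an "other" level; dummies that end up constant are dropped.
    """
    samples = list(groups.G) + list(groups.N)
    cols = [np.ones(len(samples)),
            np.array([1.0] * len(groups.G) + [0.0] * len(groups.N))]
    names = ["intercept", "group"]
    if histotypes is not None:
        h = histotypes.reindex(samples).astype(str)
        counts = h.value_counts()
        rare = counts[counts < 2].index
        h = h.where(~h.isin(rare), "other")
        levels = sorted(h.unique())
        for lev in levels[1:]:  # first level is the reference
            v = (h == lev).to_numpy(dtype=float)
            if 0 < v.sum() < len(samples):
                cols.append(v)
                names.append(f"histotype[{lev}]")
    X = np.column_stack(cols)
    # drop collinear columns (keep group)
    q, r = np.linalg.qr(X)
    keep = np.abs(np.diag(r)) > 1e-10
    if not keep[1]:
        raise ValueError("group indicator is collinear with other covariates")
    return X[:, keep], [n for n, k in zip(names, keep) if k]


def fit_group_lm(expr: pd.DataFrame, groups: GroupAssignment,
                 histotypes: pd.Series | None = None) -> pd.DataFrame:
    """Per-gene least-squares fit of expression ~ group + histotype.

    Returns a frame indexed by probeset with columns logFC (the group
    coefficient), s2 (residual variance), df_residual and v_group (the
    group-coefficient entry of (X'X)^-1, shared by all genes).
    """
    if not groups.testable:
        raise ValueError(f"region {groups.region_id}: need >=2 samples in G and N")
    samples = list(groups.G) + list(groups.N)
    missing = [s for s in samples if s not in expr.columns]
    if missing:
        raise ValueError(f"expression matrix lacks samples: {missing[:5]}")
    X, _ = _design_matrix(groups, histotypes)
    Y = expr[samples].to_numpy(dtype=float)
    n, p = X.shape
    df_resid = n - p
    if df_resid < 1:
        raise ValueError("no residual degrees of freedom")
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = Y @ (X @ xtx_inv.T)  # genes x p
    resid = Y - beta @ X.T
    s2 = (resid ** 2).sum(axis=1) / df_resid
    return pd.DataFrame(
        {
            "logFC": beta[:, 1],
            "s2": s2,
            "df_residual": float(df_resid),
            "v_group": xtx_inv[1, 1],
        },
        index=expr.index,
    )


def moderate_fit(fit: pd.DataFrame, d0: float, s0_sq: float,
                 n_G: int, n_N: int) -> pd.DataFrame:
    """Apply empirical-Bayes shrinkage to a fitted table and compute p-values.

    ``d0 = 0`` gives the ordinary per-gene (unmoderated) t-test; ``d0 = inf``
    shrinks every variance fully to ``s0_sq``.
    """
    s2 = fit["s2"].to_numpy(dtype=float)
    logfc = fit["logFC"].to_numpy(dtype=float)
    df_resid = fit["df_residual"].to_numpy(dtype=float)
    v_group = fit["v_group"].to_numpy(dtype=float)

    if d0 == 0:
        s2_post = s2.copy()
        df_total = df_resid.copy()
    elif math.isinf(d0):
        s2_post = np.full(s2.size, s0_sq)
        df_total = np.full(s2.size, math.inf)
    else:
        s2_post = (d0 * s0_sq + df_resid * s2) / (d0 + df_resid)
        df_total = d0 + df_resid

    se = np.sqrt(s2_post * v_group)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, logfc / se, np.where(np.abs(logfc) > 0, np.inf, 0.0))
    p_raw = np.empty_like(t)
    finite_df = np.isfinite(df_total)
    p_raw[finite_df] = 2.0 * sps.t.sf(np.abs(t[finite_df]), df_total[finite_df])
    p_raw[~finite_df] = 2.0 * sps.norm.sf(np.abs(t[~finite_df]))
    # genes that are constant everywhere: logFC 0, t undefined -> p 1
    flat = (s2 <= 1e-24) & (np.abs(logfc) <= 1e-12)
    p_raw[flat] = 1.0
    t = np.where(flat, 0.0, t)

    return pd.DataFrame(
        {
            "logFC": logfc,
            "t_moderated": t,
            "p_raw": p_raw,
            "p_adj": bh_adjust(p_raw),
            "n_G": n_G,
            "n_N": n_N,
            "s2": s2,
            "df_residual": df_resid,
            "df_total": df_total,
        },
        index=fit.index,
    )


def moderated_t_test(expr: pd.DataFrame, groups: GroupAssignment,
                     histotypes: pd.Series | None = None,
                     prior: ModerationPrior | None = None,
                     d0_override: float | None = None) -> tuple[pd.DataFrame, ModerationPrior]:
    """Empirical-Bayes moderated differential-expression test, G vs N.

    Parameters
    ----------
    expr
        Probesets/genes x samples log2 expression matrix; only the G and N
        samples are used.
    groups
        Output of :func:`assign_groups`; needs >= 2 samples per group.
    histotypes
        Optional per-sample histological subtype, included as a factor.
    prior
        A pre-estimated ModerationPrior (e.g. a genome-wide fit when the
        region holds too few genes to fit its own); estimated from these
        genes when omitted.
    d0_override
        Force the prior df (0 recovers the ordinary per-gene t-test; inf
        gives full shrinkage to s0^2).  Mainly for validation.

    Returns the per-gene result table (logFC, t_moderated, p_raw, p_adj,
    n_G, n_N, s2, df_residual, df_total) and the prior that was used.
    """
    fit = fit_group_lm(expr, groups, histotypes)
    if prior is None:
        s2 = fit["s2"].to_numpy()
        try:
            prior = estimate_moderation_prior(s2, fit["df_residual"].to_numpy())
        except ValueError:
            prior = ModerationPrior(d0=math.inf, s0_sq=max(float(np.mean(s2)), 1e-12))
    d0 = prior.d0 if d0_override is None else d0_override
    result = moderate_fit(fit, d0, prior.s0_sq, len(groups.G), len(groups.N))
    return result, prior


# ---------------------------------------------------------------------------
# BH adjustment, correlation, Welch


def bh_adjust(p_raw) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (original order kept).

    p_adj for the i-th ranked p-value is min over j >= i of m * p_(j) / j,
    capped at 1.  NaN inputs propagate as NaN and do not count toward m.
    """
    p = np.asarray(p_raw, dtype=float)
    if p.ndim != 1:
        raise ValueError("expected a 1-D p-value vector")
    ok = ~np.isnan(p)
    if np.any((p[ok] < 0) | (p[ok] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    out = np.full(p.shape, np.nan)
    m = int(ok.sum())
    if m == 0:
        return out
    vals = p[ok]
    order = np.argsort(vals, kind="mergesort")
    ranked = vals[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    tmp = np.empty(m)
    tmp[order] = adj
    out[ok] = tmp
    return out


def cn_expr_correlation(expr: np.ndarray, cn: np.ndarray) -> tuple[float, float, int]:
    """Pearson correlation of expression with gene copy number.

    Pairs with a missing value on either side are dropped.  Returns
    (r, p_two_sided, n).  With fewer than 3 complete pairs or zero variance
    in either vector, r and p are NaN.
    """
    expr = np.asarray(expr, dtype=float)
    cn = np.asarray(cn, dtype=float)
    keep = ~(np.isnan(expr) | np.isnan(cn))
    x, y = expr[keep], cn[keep]
    n = int(keep.sum())
    if n < 3 or np.std(x) == 0 or np.std(y) == 0:
        return float("nan"), float("nan"), n
    r, p = sps.pearsonr(x, y)
    return float(r), float(p), n


def welch_t_test(group_a, group_b) -> tuple[float, float]:
    """Welch's unequal-variance two-sample t-test (two-sided).

    Degenerate case: both groups constant with equal means gives t = 0,
    p = 1.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least two observations")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return math.copysign(math.inf, a.mean() - b.mean()), 0.0
    t, p = sps.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)
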