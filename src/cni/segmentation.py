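"""Circular binary segmentation (CBS) of marker-level copy-number series.

A copy-number profile is an ordered series of marker estimates on the
absolute-copy scale (diploid = 2).  CBS recursively searches each current
segment for the arc ``x[i:j]`` whose mean differs most from the mean of the
complementary markers, measured by the two-sample t statistic with pooled
variance.  A candidate split is accepted iff its permutation p-value is below
``alpha``; accepted arcs contribute their endpoints as breakpoints and the
resulting pieces are searched again.

Marker-index breakpoints are converted to base-pair segment bounds using the
midpoint between flanking markers, so the segments of one series tile the
marker span exactly (0-based half-open coordinates throughout).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit

__all__ = [
    "MarkerSeries",
    "Segment",
    "CbsParams",
    "cbs_segment",
    "segment_cohort",
    "summarise_profile",
]

# t value standing in for an infinite statistic (zero pooled variance with a
# non-zero mean difference, i.e. a noiseless change point).
_T_INF = 1e30


@dataclass(frozen=True)
class MarkerSeries:
    """Ordered copy-number markers on one chromosome of one sample."""

    chrom: str
    positions: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=np.int64)
        val = np.asarray(self.values, dtype=np.float64)
        if pos.ndim != 1 or val.ndim != 1 or pos.size != val.size:
            raise ValueError("positions and values must be 1-D and equal length")
        if pos.size < 1:
            raise ValueError("a marker series needs at least one marker")
        if np.any(np.diff(pos) <= 0):
            raise ValueError("marker positions must be strictly increasing")
        if not np.all(np.isfinite(val)):
            raise ValueError("marker values must be finite (no NaN/inf)")
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "values", val)

    def __len__(self) -> int:
        return int(self.positions.size)


@dataclass(frozen=True)
class Segment:
    """A piecewise-constant copy-number segment (0-based half-open)."""

    chrom: str
    start: int
    end: int
    n_markers: int
    mean_cn: float
    sample: str = ""

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"segment start {self.start} >= end {self.end}")
        if self.n_markers < 1:
            raise ValueError("segment must contain at least one marker")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class CbsParams:
    """Tuning parameters for the CBS change-point search.

    alpha
        Significance level a permutation p-value must beat for a split to be
        accepted.
    n_perm
        Nominal permutation count.  The effective count is capped at
        ``ceil(perm_cap_factor / alpha)`` so the test retains resolution below
        ``alpha`` without wasting permutations, and the permutation loop stops
        early as soon as the p-value can no longer fall below ``alpha``.
    min_width
        Minimum marker count for the arc and for its complement.
    undo_sd
        If set, adjacent segments whose means differ by less than
        ``undo_sd`` residual standard deviations are merged after the search.
    """

    alpha: float = 0.01
    n_perm: int = 10_000
    min_width: int = 2
    perm_cap_factor: float = 5.0
    undo_sd: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.n_perm < 100:
            raise ValueError("n_perm must be >= 100")
        if self.min_width < 1:
            raise ValueError("min_width must be >= 1")
        if self.perm_cap_factor <= 1.0:
            raise ValueError("perm_cap_factor must exceed 1")

    @property
    def n_perm_effective(self) -> int:
        return int(min(self.n_perm, math.ceil(self.perm_cap_factor / self.alpha)))


@njit(cache=True)
def _arc_weights(n: int, min_width: int) -> np.ndarray:  # pragma: no cover
    """w[m] = n / (m * (n - m)) for admissible arc lengths, else 0."""
    w = np.zeros(n + 1)
    for m in range(min_width, n - min_width + 1):
        w[m] = n / (m * (n - m))
    return w


@njit(cache=True)
def _max_between_ss(x: np.ndarray, min_width: int):  # pragma: no cover - numba
    """Exhaustive scan for the arc (i, j) maximising the between-group sum of
    squares B = D^2 * n / (m * (n - m)), D being the centred partial-sum
    difference Z_j - Z_i.

    B is a strictly increasing function of the arc-vs-complement t statistic
    (t^2 = (n-2) B / (SS_tot - B)), and SS_tot is permutation invariant, so
    all comparisons the segmentation needs can be done in B-space.  Ties are
    broken toward the leftmost i, then the smallest j (shortest arc), which
    the ascending scan order guarantees with a strict comparison.

    Returns (b_max, i, j, ss_tot); b_max < 0 means no admissible arc.
    """
    n = x.shape[0]
    if n < 3 or n < 2 * min_width:
        return -1.0, 0, n, 0.0
    mean = 0.0
    for k in range(n):
        mean += x[k]
    mean /= n
    Z = np.empty(n + 1)
    Z[0] = 0.0
    ss_tot = 0.0
    for k in range(n):
        d = x[k] - mean
        Z[k + 1] = Z[k] + d
        ss_tot += d * d
    w = _arc_weights(n, min_width)
    best = -1.0
    bi = 0
    bj = n
    for i in range(0, n - 2 * min_width + 1):
        zi = Z[i]
        j_hi = i + (n - min_width)
        if j_hi > n:
            j_hi = n
        for j in range(i + min_width, j_hi + 1):
            d = Z[j] - zi
            b = d * d * w[j - i]
            if b > best:
                best = b
                bi = i
                bj = j
    return best, bi, bj, ss_tot


@njit(cache=True)
def _perm_exceeds(x: np.ndarray, min_width: int,
                  b_obs: float) -> bool:  # pragma: no cover - numba
    """Does any admissible arc of (permuted) x reach between-SS b_obs?

    Exits on the first exceedance; prescreens with the O(n) bound
    (Zmax - Zmin)^2 * max(w) before the quadratic scan.
    """
    n = x.shape[0]
    mean = 0.0
    for k in range(n):
        mean += x[k]
    mean /= n
    Z = np.empty(n + 1)
    Z[0] = 0.0
    zmin = 0.0
    zmax = 0.0
    for k in range(n):
        Z[k + 1] = Z[k] + x[k] - mean
        if Z[k + 1] < zmin:
            zmin = Z[k + 1]
        if Z[k + 1] > zmax:
            zmax = Z[k + 1]
    w = _arc_weights(n, min_width)
    w_max = w[min_width]
    span = zmax - zmin
    if span * span * w_max < b_obs:
        return False
    for i in range(0, n - 2 * min_width + 1):
        zi = Z[i]
        # per-row bound: the largest |D| this row can reach
        dmax = zmax - zi
        dmin = zi - zmin
        dbig = dmax if dmax > dmin else dmin
        if dbig * dbig * w_max < b_obs:
            continue
        j_hi = i + (n - min_width)
        if j_hi > n:
            j_hi = n
        for j in range(i + min_width, j_hi + 1):
            d = Z[j] - zi
            if d * d * w[j - i] >= b_obs:
                return True
    return False


@njit(cache=True)
def _count_exceedances(perms: np.ndarray, min_width: int, b_obs: float,
                       stop_at: int):  # pragma: no cover - numba
    """Count permuted series reaching b_obs, stopping early at stop_at."""
    count = 0
    for r in range(perms.shape[0]):
        if _perm_exceeds(perms[r], min_width, b_obs):
            count += 1
            if count >= stop_at:
                return count, r + 1
    return count, perms.shape[0]


def _max_abs_t(x: np.ndarray, min_width: int):
    """Arc (i, j) with the maximal |t| and its value (reporting helper)."""
    b, i, j, ss_tot = _max_between_ss(np.ascontiguousarray(x, dtype=np.float64),
                                      min_width)
    n = x.shape[0]
    if b < 0:
        return -1.0, i, j
    resid = ss_tot - b
    if resid <= 1e-300 * max(ss_tot, 1.0):
        t = _T_INF if b > 0 else 0.0
    else:
        t = math.sqrt((n - 2) * b / resid)
    return t, i, j


def _test_split(x: np.ndarray, params: CbsParams, rng: np.random.Generator):
    """Permutation test of the best arc in x.

    Returns (i, j) of an accepted split or None.  The permutation loop stops
    as soon as enough exceedances accumulate that the final p-value could not
    be below alpha, which makes null (no change point) tests cheap.
    """
    n = x.size
    if n < 2 * params.min_width or n < 4:
        return None
    x = np.ascontiguousarray(x, dtype=np.float64)
    b_obs, bi, bj, ss_tot = _max_between_ss(x, params.min_width)
    if b_obs <= 0.0:
        return None
    n_perm = params.n_perm_effective
    # Reject once (1 + count) >= alpha * (1 + n_perm): p can no longer beat alpha.
    reject_at = math.ceil(params.alpha * (1 + n_perm) - 1.0 + 1e-12)
    reject_at = max(reject_at, 1)
    count = 0
    done = 0
    chunk = 16  # grows geometrically: most null tests reject within a few dozen
    while done < n_perm:
        b = min(chunk, n_perm - done)
        perms = rng.permuted(np.broadcast_to(x, (b, n)).copy(), axis=1)
        c, used = _count_exceedances(perms, params.min_width, b_obs,
                                     reject_at - count)
        count += c
        done += used
        chunk = min(chunk * 2, 256)
        if count >= reject_at:
            return None
    p = (1 + count) / (1 + n_perm)
    if p < params.alpha:
        return bi, bj
    return None


def _marker_edges(positions: np.ndarray) -> np.ndarray:
    """Base-pair edges so that marker k occupies [edges[k], edges[k+1])."""
    edges = np.empty(positions.size + 1, dtype=np.int64)
    edges[0] = positions[0]
    edges[-1] = positions[-1] + 1
    if positions.size > 1:
        edges[1:-1] = (positions[:-1] + positions[1:]) // 2 + 1
    return edges


def _undo_splits(x: np.ndarray, bounds: list[int], undo_sd: float) -> list[int]:
    """Merge adjacent segments whose mean gap is below undo_sd residual sds."""
    while len(bounds) > 2:
        means = [x[bounds[k]:bounds[k + 1]].mean() for k in range(len(bounds) - 1)]
        resid = np.concatenate(
            [x[bounds[k]:bounds[k + 1]] - means[k] for k in range(len(bounds) - 1)]
        )
        sd = resid.std(ddof=1) if resid.size > 1 else 0.0
        gaps = np.abs(np.diff(means))
        worst = int(np.argmin(gaps))
        if sd > 0 and gaps[worst] < undo_sd * sd:
            del bounds[worst + 1]
        else:
            break
    return bounds


def cbs_segment(series: MarkerSeries, params: CbsParams | None = None,
                seed: int | np.random.Generator = 0) -> list[Segment]:
    """Segment one marker series into piecewise-constant segments.

    Parameters
    ----------
    series
        Markers of a single chromosome, positions strictly increasing.
    params
        CBS tuning parameters (defaults mirror the common reference settings:
        alpha 0.01, min_width 2).
    seed
        Integer seed or a ``numpy.random.Generator`` driving the permutations;
        the same series, params and seed always give the same segments.
    """
    params = params or CbsParams()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    x = series.values
    n = x.size

    breakpoints: set[int] = set()
    stack: list[tuple[int, int]] = [(0, n)]
    while stack:
        lo, hi = stack.pop()
        hit = _test_split(x[lo:hi], params, rng)
        if hit is None:
            continue
        i, j = hit
        cuts = []
        if lo + i > lo:
            cuts.append(lo + i)
        if lo + j < hi:
            cuts.append(lo + j)
        breakpoints.update(cuts)
        pieces = sorted({lo, hi, *cuts})
        # push right-to-left so the left piece is processed first (determinism)
        for a, b in reversed(list(zip(pieces[:-1], pieces[1:]))):
            if b - a >= 2 * params.min_width:
                stack.append((a, b))

    bounds = [0, *sorted(breakpoints), n]
    if params.undo_sd is not None and len(bounds) > 2:
        bounds = _undo_splits(x, bounds, params.undo_sd)

    edges = _marker_edges(series.positions)
    segments = []
    for a, b in zip(bounds[:-1], bounds[1:]):
        segments.append(
            Segment(
                chrom=series.chrom,
                start=int(edges[a]),
                end=int(edges[b]),
                n_markers=b - a,
                mean_cn=float(x[a:b].mean()),
            )
        )
    return segments


def segment_cohort(markers: pd.DataFrame, params: CbsParams | None = None,
                   seed: int = 0) -> pd.DataFrame:
    """Segment every (sample, chromosome) series of a marker table.

    ``markers`` needs columns sample, chrom, pos, cn.  Each series gets its
    own deterministic RNG derived from ``seed`` and the series identity, so
    results do not depend on processing order.  Returns a SEG-like frame with
    columns sample, chrom, start, end, n_markers, mean_cn (0-based half-open).
    """
    params = params or CbsParams()
    rows = []
    for (sample, chrom), grp in markers.groupby(["sample", "chrom"], sort=True):
        grp = grp.sort_values("pos")
        series = MarkerSeries(chrom=chrom,
                              positions=grp["pos"].to_numpy(),
                              values=grp["cn"].to_numpy())
        sub_seed = np.random.SeedSequence(entropy=seed,
                                          spawn_key=(_stable_key(sample), _stable_key(chrom)))
        segs = cbs_segment(series, params, np.random.default_rng(sub_seed))
        for s in segs:
            rows.append((sample, chrom, s.start, s.end, s.n_markers, s.mean_cn))
    return pd.DataFrame(rows, columns=["sample", "chrom", "start", "end",
                                       "n_markers", "mean_cn"])


def _stable_key(text: str) -> int:
    """Deterministic small integer from a label (hash() is salted per run)."""
    h = 0
    for ch in str(text):
        h = (h * 131 + ord(ch)) % (2**31 - 1)
    return h


def summarise_profile(segments: pd.DataFrame, gain_cutoff: float = 2.5,
                      loss_cutoff: float = 1.5) -> pd.DataFrame:
    """Per-sample counts and genome fractions of gained / lost bases.

    Fractions are summed gained (lost) bp over the total profiled bp of that
    sample, i.e. the span covered by its segments.
    """
    df = segments.copy()
    df["length"] = df["end"] - df["start"]
    out = []
    for sample, grp in df.groupby("sample", sort=True):
        total = int(grp["length"].sum())
        gained = grp[grp["mean_cn"] > gain_cutoff]
        lost = grp[grp["mean_cn"] < loss_cutoff]
        out.append(
            {
                "sample": sample,
                "n_segments": len(grp),
                "n_gain": len(gained),
                "n_loss": len(lost),
                "gain_fraction": gained["length"].sum() / total if total else 0.0,
                "loss_fraction": lost["length"].sum() / total if total else 0.0,
            }
        )
    return pd.DataFrame(out)
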