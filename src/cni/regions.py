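"""Recurrent copy-number region discovery.

Segments from all tumours are state-called (gain / loss / neutral), folded
into a per-base frequency track by a breakpoint sweep, thresholded to extract
regions gained in at least ``min_freq`` of the cohort, and finally collapsed
by cytoband: qualifying intervals falling wholly inside one band are grouped
and re-bounded by the lowest member start and highest member stop, while an
interval spanning a band boundary becomes its own region tagged with every
band it touches.

All coordinates are 0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "StateThresholds",
    "CollapsedRegion",
    "call_state",
    "call_states",
    "build_frequency_track",
    "frequent_gain_regions",
    "collapse_by_cytoband",
]

GAIN, LOSS, NEUTRAL = "gain", "loss", "neutral"


@dataclass(frozen=True)
class StateThresholds:
    """Copy-number cutoffs on the absolute scale (diploid = 2).

    A segment is a gain when its mean exceeds ``gain_cutoff`` (default 2.5)
    and a loss when below ``loss_cutoff`` (default 1.5); both comparisons are
    strict.
    """

    gain_cutoff: float = 2.5
    loss_cutoff: float = 1.5

    def __post_init__(self) -> None:
        if not self.loss_cutoff < 2.0 < self.gain_cutoff:
            raise ValueError("need loss_cutoff < 2 < gain_cutoff")


@dataclass
class CollapsedRegion:
    """A cytoband-collapsed recurrent-gain region.

    ``start``/``end`` are the min member start and max member end; ``bands``
    lists the cytoband tag(s); ``members`` the qualifying intervals that were
    grouped.
    """

    region_id: str
    chrom: str
    start: int
    end: int
    bands: tuple[str, ...]
    gain_frequency: float
    members: list[tuple[int, int]] = field(default_factory=list)

    @property
    def band_tag(self) -> str:
        return "-".join(self.bands)


def call_state(mean_cn: float, thresholds: StateThresholds | None = None) -> str:
    """Classify one segment mean as gain, loss or neutral."""
    thresholds = thresholds or StateThresholds()
    if not np.isfinite(mean_cn):
        raise ValueError("mean_cn must be finite")
    if mean_cn > thresholds.gain_cutoff:
        return GAIN
    if mean_cn < thresholds.loss_cutoff:
        return LOSS
    return NEUTRAL


def call_states(segments: pd.DataFrame,
                thresholds: StateThresholds | None = None) -> pd.DataFrame:
    """Vectorised state call; adds a 'state' column to a segment table."""
    thresholds = thresholds or StateThresholds()
    cn = segments["mean_cn"].to_numpy()
    if not np.all(np.isfinite(cn)):
        raise ValueError("segment means must be finite")
    state = np.where(cn > thresholds.gain_cutoff, GAIN,
                     np.where(cn < thresholds.loss_cutoff, LOSS, NEUTRAL))
    out = segments.copy()
    out["state"] = state
    return out


def build_frequency_track(segments: pd.DataFrame, n_samples: int | None = None,
                          thresholds: StateThresholds | None = None) -> pd.DataFrame:
    """Per-base gain/loss recurrence counts across samples.

    Parameters
    ----------
    segments
        State-called segment table (columns sample, chrom, start, end,
        mean_cn and optionally state; states are computed if absent).
    n_samples
        Cohort denominator for frequencies.  Defaults to the number of
        distinct samples present in ``segments``; pass the full cohort size
        explicitly when some samples contributed no segments.

    Returns a frame with columns chrom, start, end, gain_count, loss_count,
    n_samples, gain_freq, loss_freq whose intervals tile the analysed span of
    each chromosome.
    """
    if segments.empty:
        return pd.DataFrame(columns=["chrom", "start", "end", "gain_count",
                                     "loss_count", "n_samples", "gain_freq",
                                     "loss_freq"])
    if "state" not in segments.columns:
        segments = call_states(segments, thresholds)
    if n_samples is None:
        n_samples = segments["sample"].nunique()
    if n_samples < 1:
        raise ValueError("need at least one sample")
    tracks = []
    for chrom, grp in segments.groupby("chrom", sort=True):
        points = np.unique(np.concatenate([grp["start"].to_numpy(),
                                           grp["end"].to_numpy()]))
        base = pd.DataFrame({"chrom": chrom, "start": points[:-1], "end": points[1:]})
        for state, col in ((GAIN, "gain_count"), (LOSS, "loss_count")):
            sub = grp[grp["state"] == state]
            counts = np.zeros(points.size, dtype=np.int64)
            if not sub.empty:
                delta = np.zeros(points.size, dtype=np.int64)
                np.add.at(delta, np.searchsorted(points, sub["start"].to_numpy()), 1)
                np.add.at(delta, np.searchsorted(points, sub["end"].to_numpy()), -1)
                counts = np.cumsum(delta)
            base[col] = counts[:-1]
        tracks.append(base)
    track = pd.concat(tracks, ignore_index=True)
    bad_g = track["gain_count"] > n_samples
    bad_l = track["loss_count"] > n_samples
    if bad_g.any() or bad_l.any():
        raise ValueError("recurrence count exceeds n_samples; check denominator")
    track["n_samples"] = n_samples
    track["gain_freq"] = track["gain_count"] / n_samples
    track["loss_freq"] = track["loss_count"] / n_samples
    return track


def frequent_gain_regions(track: pd.DataFrame, min_freq: float = 0.40) -> pd.DataFrame:
    """Maximal intervals whose gain frequency is >= min_freq (inclusive).

    Adjacent or touching qualifying intervals are merged per chromosome.
    Returns columns chrom, start, end, gain_freq where gain_freq is the
    length-weighted mean frequency over the merged interval.
    """
    if not 0.0 < min_freq <= 1.0:
        raise ValueError("min_freq must be in (0, 1]")
    cols = ["chrom", "start", "end", "gain_freq"]
    if track.empty:
        return pd.DataFrame(columns=cols)
    hits = track[track["gain_freq"] >= min_freq]
    rows = []
    for chrom, grp in hits.groupby("chrom", sort=True):
        grp = grp.sort_values("start")
        cur_s = cur_e = None
        freqs: list[tuple[int, float]] = []
        for s, e, f in zip(grp["start"], grp["end"], grp["gain_freq"]):
            if cur_e is not None and s <= cur_e:
                cur_e = max(cur_e, e)
                freqs.append((e - s, f))
            else:
                if cur_e is not None:
                    rows.append((chrom, cur_s, cur_e, _wmean(freqs)))
                cur_s, cur_e = s, e
                freqs = [(e - s, f)]
        if cur_e is not None:
            rows.append((chrom, cur_s, cur_e, _wmean(freqs)))
    return pd.DataFrame(rows, columns=cols)


def _wmean(pairs: list[tuple[int, float]]) -> float:
    w = sum(p[0] for p in pairs)
    return sum(p[0] * p[1] for p in pairs) / w if w else 0.0


def _chrom_ordinal(chrom: str) -> str:
    return chrom[3:] if chrom.lower().startswith("chr") else chrom


def collapse_by_cytoband(intervals: pd.DataFrame,
                         cytobands: pd.DataFrame) -> list[CollapsedRegion]:
    """Group frequent-gain intervals by cytoband (min-start / max-stop rule).

    Intervals wholly inside one band are pooled per band; the collapsed
    region spans the lowest member start to the highest member stop and keeps
    that band's tag.  An interval overlapping more than one band forms its
    own region tagged with all touched bands and is never merged into a
    single-band group.  Region ids are ``<chrom>_<ordinal>`` in genomic order
    per chromosome (chrom printed without a 'chr' prefix).

    ``intervals`` needs columns chrom, start, end and optionally gain_freq;
    ``cytobands`` needs chrom, start, end, band.
    """
    groups: dict[tuple, dict] = {}
    for row in intervals.itertuples(index=False):
        bands = cytobands[(cytobands["chrom"] == row.chrom)
                          & (cytobands["end"] > row.start)
                          & (cytobands["start"] < row.end)]
        if bands.empty:
            raise ValueError(
                f"interval {row.chrom}:{row.start}-{row.end} overlaps no cytoband")
        names = tuple(bands.sort_values("start")["band"])
        freq = getattr(row, "gain_freq", np.nan)
        if len(names) == 1:
            key = ("band", row.chrom, names[0])
        else:
            key = ("span", row.chrom, row.start, row.end, names)
        g = groups.setdefault(key, {"chrom": row.chrom, "bands": names,
                                    "members": [], "freqs": []})
        g["members"].append((int(row.start), int(row.end)))
        g["freqs"].append((int(row.end) - int(row.start), float(freq)))

    regions = []
    for g in groups.values():
        start = min(m[0] for m in g["members"])
        end = max(m[1] for m in g["members"])
        regions.append(
            CollapsedRegion(
                region_id="",
                chrom=g["chrom"],
                start=start,
                end=end,
                bands=g["bands"],
                gain_frequency=_wmean(g["freqs"]),
                members=sorted(g["members"]),
            )
        )
    regions.sort(key=lambda r: (_sort_chrom(r.chrom), r.start, r.end))
    counters: dict[str, int] = {}
    for r in regions:
        n = counters.get(r.chrom, 0) + 1
        counters[r.chrom] = n
        r.region_id = f"{_chrom_ordinal(r.chrom)}_{n}"
    return regions


def _sort_chrom(chrom: str) -> tuple:
    name = _chrom_ordinal(chrom)
    return (0, int(name)) if name.isdigit() else (1, name)


def regions_to_frame(regions: list[CollapsedRegion]) -> pd.DataFrame:
    """Tabular view of collapsed regions (one row per region)."""
    return pd.DataFrame(
        [
            {
                "region_id": r.region_id,
                "chrom": r.chrom,
                "start": r.start,
                "end": r.end,
                "bands": r.band_tag,
                "gain_freq": r.gain_frequency,
                "n_members": len(r.members),
            }
            for r in regions
        ]
    )
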