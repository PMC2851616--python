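"""Germline copy-number polymorphism (CNP) detection and subtraction.

Recurrent alteration in the matched-normal profiles marks a locus as a
germline polymorphism rather than a somatic event: any interval where more
than ``cnp_freq`` (default 5%, strict) of normals show gain or loss is called
a CNP.  CNPs are then subtracted from candidate somatic regions with simple
interval algebra: a CNP strictly interior to a region splits it in two, a CNP
overlapping one edge trims that edge, and a CNP covering the whole region
removes it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .regions import GAIN, LOSS, StateThresholds, build_frequency_track, call_states

__all__ = ["CnpCall", "detect_cnps", "subtract_cnp", "subtract_cnps"]


@dataclass(frozen=True)
class CnpCall:
    """A germline CNP locus: altered in > cnp_freq of normal samples."""

    chrom: str
    start: int
    end: int
    n_normals_altered: int
    n_normals: int
    type: str  # "gain" | "loss" | "both"

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("CNP start must be < end")
        if not 0 < self.n_normals_altered <= self.n_normals:
            raise ValueError("invalid carrier count")


def detect_cnps(normal_segments: pd.DataFrame, n_normals: int | None = None,
                cnp_freq: float = 0.05,
                thresholds: StateThresholds | None = None,
                pool_gain_loss: bool = True) -> list[CnpCall]:
    """Call CNPs from segmented normal-sample profiles.

    States are called with the same cutoffs used for tumours (gain > 2.5,
    loss < 1.5).  By default gain and loss evidence is pooled per sample when
    counting carriers, since germline polymorphisms commonly show both states
    at one locus across individuals; ``pool_gain_loss=False`` counts the two
    states separately and emits separate calls.  The frequency comparison is
    strict: a locus altered in exactly 5% of normals is not a CNP.
    """
    if normal_segments.empty or normal_segments["sample"].nunique() == 0:
        raise ValueError("no normal samples provided")
    if n_normals is None:
        n_normals = normal_segments["sample"].nunique()
    if n_normals < 10:
        warnings.warn(f"only {n_normals} normals; CNP frequencies are unstable",
                      stacklevel=2)
    if not 0.0 < cnp_freq < 1.0:
        raise ValueError("cnp_freq must be in (0, 1)")
    segs = call_states(normal_segments, thresholds)

    def _emit(sub: pd.DataFrame, label: str) -> list[CnpCall]:
        if sub.empty:
            return []
        track = build_frequency_track(sub, n_samples=n_normals)
        track["alt_count"] = track["gain_count"] + track["loss_count"]
        hits = track[track["alt_count"] / n_normals > cnp_freq]
        calls = []
        for chrom, grp in hits.groupby("chrom", sort=True):
            grp = grp.sort_values("start")
            cur = None
            for r in grp.itertuples(index=False):
                if cur is not None and r.start <= cur["end"]:
                    cur["end"] = max(cur["end"], r.end)
                    cur["n"] = max(cur["n"], int(r.alt_count))
                    cur["states"].update(_states_of(r))
                else:
                    if cur is not None:
                        calls.append(_to_call(cur, chrom, n_normals, label))
                    cur = {"start": r.start, "end": r.end,
                           "n": int(r.alt_count), "states": _states_of(r)}
            if cur is not None:
                calls.append(_to_call(cur, chrom, n_normals, label))
        return calls

    if pool_gain_loss:
        return _emit(segs, "pooled")
    out = _emit(segs[segs["state"] == GAIN], GAIN)
    out += _emit(segs[segs["state"] == LOSS], LOSS)
    return sorted(out, key=lambda c: (c.chrom, c.start))


def _states_of(row) -> set[str]:
    states = set()
    if row.gain_count > 0:
        states.add(GAIN)
    if row.loss_count > 0:
        states.add(LOSS)
    return states


def _to_call(cur: dict, chrom: str, n_normals: int, label: str) -> CnpCall:
    if label == "pooled":
        kind = "both" if cur["states"] == {GAIN, LOSS} else next(iter(cur["states"]))
    else:
        kind = label
    return CnpCall(chrom=chrom, start=int(cur["start"]), end=int(cur["end"]),
                   n_normals_altered=cur["n"], n_normals=n_normals, type=kind)


def subtract_cnp(region: tuple[str, int, int],
                 cnp: CnpCall) -> list[tuple[str, int, int]]:
    """Subtract one CNP interval from one region; returns 0, 1 or 2 pieces.

    A strictly interior CNP splits the region; a CNP overlapping one edge
    trims it; full containment drops the region; no overlap returns the
    region unchanged.  Zero-length pieces are discarded.
    """
    chrom, start, end = region
    if chrom != cnp.chrom or cnp.end <= start or cnp.start >= end:
        return [region]
    pieces = []
    if cnp.start > start:
        pieces.append((chrom, start, cnp.start))
    if cnp.end < end:
        pieces.append((chrom, cnp.end, end))
    return pieces


def subtract_cnps(region: tuple[str, int, int],
                  cnps: list[CnpCall]) -> list[tuple[str, int, int]]:
    """Iteratively subtract every CNP from a region (order-independent)."""
    pieces = [region]
    for cnp in cnps:
        nxt: list[tuple[str, int, int]] = []
        for p in pieces:
            nxt.extend(subtract_cnp(p, cnp))
        pieces = nxt
    return sorted(pieces, key=lambda p: p[1])
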