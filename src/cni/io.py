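"""Readers and writers for the on-disk formats.

Conventions: internal coordinates are 0-based half-open everywhere.  SEG
files are written 1-based inclusive (start = internal start + 1, end =
internal end), the common dialect; BED and UCSC cytoBand files are natively
0-based half-open and pass through unchanged.  Chromosome names are
normalised to a "chrN" prefix on read.  Expression matrices are TSV with the
probeset/gene id in the first column and one column per sample; missing
values are "NA".  All floats are written with repr-stable formatting so
identical inputs give byte-identical files.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "normalise_chrom",
    "read_markers", "write_markers",
    "read_seg", "write_seg",
    "read_cytoband", "write_cytoband",
    "read_bed", "write_bed",
    "read_expression", "write_expression",
    "read_sample_sheet", "write_sample_sheet",
    "read_yaml_config", "write_json", "file_sha256",
]

SEG_COLUMNS = ["Sample", "Chromosome", "Start", "End", "Num_Probes", "Segment_Mean"]
FLOAT_FMT = "%.10g"


def normalise_chrom(chrom: str) -> str:
    c = str(chrom).strip()
    return c if c.lower().startswith("chr") else f"chr{c}"


def _read_tsv(path, **kw) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", **kw)
    except (pd.errors.ParserError, ValueError) as exc:
        raise ValueError(f"{path}: malformed TSV ({exc})") from exc


# --- marker tables ---------------------------------------------------------

def read_markers(path) -> pd.DataFrame:
    """Marker TSV with columns sample, chrom, pos, cn (pos in bp)."""
    df = _read_tsv(path)
    required = {"sample", "chrom", "pos", "cn"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: marker table needs columns {sorted(required)}")
    df["chrom"] = df["chrom"].map(normalise_chrom)
    df["pos"] = df["pos"].astype(np.int64)
    df["cn"] = df["cn"].astype(float)
    if df["cn"].isna().any():
        raise ValueError(f"{path}: marker table contains missing CN values")
    return df


def write_markers(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


# --- SEG -------------------------------------------------------------------

def read_seg(path) -> pd.DataFrame:
    """Read a SEG file (1-based inclusive on disk -> 0-based half-open).

    Returns columns sample, chrom, start, end, n_markers, mean_cn.  Malformed
    rows raise with the offending line number; unsorted rows are sorted with
    a warning.
    """
    df = _read_tsv(path)
    if list(df.columns) != SEG_COLUMNS:
        raise ValueError(f"{path}: expected SEG header {SEG_COLUMNS}, "
                         f"got {list(df.columns)}")
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            s, e = int(row.Start), int(row.End)
            float(row.Segment_Mean)
            n = int(row.Num_Probes)
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}: malformed row at line {i}: {exc}") from exc
        if e < s:
            raise ValueError(f"{path}: line {i}: End {e} < Start {s}")
        if n < 1:
            raise ValueError(f"{path}: line {i}: Num_Probes must be >= 1")
    out = pd.DataFrame({
        "sample": df["Sample"].astype(str),
        "chrom": df["Chromosome"].map(normalise_chrom),
        "start": df["Start"].astype(np.int64) - 1,
        "end": df["End"].astype(np.int64),
        "n_markers": df["Num_Probes"].astype(np.int64),
        "mean_cn": df["Segment_Mean"].astype(float),
    })
    sorted_out = out.sort_values(["sample", "chrom", "start"], kind="mergesort")
    if not sorted_out.index.equals(out.index):
        warnings.warn(f"{path}: rows were not sorted; sorting", stacklevel=2)
        out = sorted_out.reset_index(drop=True)
    return out


def write_seg(df: pd.DataFrame, path) -> None:
    """Write an internal segment table as SEG (1-based inclusive on disk)."""
    disk = pd.DataFrame({
        "Sample": df["sample"],
        "Chromosome": df["chrom"],
        "Start": df["start"].astype(np.int64) + 1,
        "End": df["end"].astype(np.int64),
        "Num_Probes": df["n_markers"].astype(np.int64),
        "Segment_Mean": df["mean_cn"],
    })
    disk.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


# --- cytoband --------------------------------------------------------------

def read_cytoband(path) -> pd.DataFrame:
    """UCSC cytoBand file: chrom, start, end, band, gieStain (0-based
    half-open).  Overlapping bands on one chromosome are an error; gaps are
    retained with a warning."""
    df = _read_tsv(path, header=None,
                   names=["chrom", "start", "end", "band", "gie_stain"])
    df["chrom"] = df["chrom"].map(normalise_chrom)
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    if (df["start"] >= df["end"]).any():
        raise ValueError(f"{path}: cytoband with start >= end")
    for chrom, grp in df.groupby("chrom"):
        grp = grp.sort_values("start")
        ends = grp["end"].to_numpy()[:-1]
        starts = grp["start"].to_numpy()[1:]
        if np.any(starts < ends):
            raise ValueError(f"{path}: overlapping cytobands on {chrom}")
        if np.any(starts > ends):
            warnings.warn(f"{path}: gap between cytobands on {chrom}; retained",
                          stacklevel=2)
    return df.sort_values(["chrom", "start"]).reset_index(drop=True)


def write_cytoband(df: pd.DataFrame, path) -> None:
    df[["chrom", "start", "end", "band", "gie_stain"]].to_csv(
        path, sep="\t", index=False, header=False)


def band_at(cytobands: pd.DataFrame, chrom: str, pos: int) -> str:
    """Band containing pos (half-open: a boundary belongs to the right band)."""
    hit = cytobands[(cytobands["chrom"] == chrom) & (cytobands["start"] <= pos)
                    & (cytobands["end"] > pos)]
    if hit.empty:
        raise ValueError(f"no cytoband at {chrom}:{pos}")
    return str(hit.iloc[0]["band"])


# --- BED (gene annotation) -------------------------------------------------

def read_bed(path) -> pd.DataFrame:
    """BED with at least 4 columns -> columns gene, chrom, start, end."""
    df = _read_tsv(path, header=None)
    if df.shape[1] < 4:
        raise ValueError(f"{path}: BED needs at least 4 columns")
    out = pd.DataFrame({
        "gene": df.iloc[:, 3].astype(str),
        "chrom": df.iloc[:, 0].map(normalise_chrom),
        "start": df.iloc[:, 1].astype(np.int64),
        "end": df.iloc[:, 2].astype(np.int64),
    })
    if (out["start"] >= out["end"]).any():
        raise ValueError(f"{path}: BED interval with start >= end")
    return out


def write_bed(genes: pd.DataFrame, path) -> None:
    bed = pd.DataFrame({
        "chrom": genes["chrom"],
        "start": genes["start"].astype(np.int64),
        "end": genes["end"].astype(np.int64),
        "name": genes["gene"],
        "score": 0,
        "strand": "+",
    })
    bed.to_csv(path, sep="\t", index=False, header=False)


# --- expression ------------------------------------------------------------

def read_expression(path) -> pd.DataFrame:
    """Probesets x samples log2 expression TSV; 'NA' marks missing values."""
    df = _read_tsv(path, index_col=0, na_values=["NA"], keep_default_na=False)
    if df.shape[1] < 1:
        raise ValueError(f"{path}: expression matrix has no sample columns")
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric expression value ({exc})") from exc
    return df


def write_expression(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=True, index_label="probeset",
              na_rep="NA", float_format=FLOAT_FMT)


# --- sample sheet ----------------------------------------------------------

def read_sample_sheet(path) -> pd.DataFrame:
    """TSV with columns sample, histotype, status (tumour|normal) and an
    optional matched_normal column."""
    df = _read_tsv(path)
    required = {"sample", "histotype", "status"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: sample sheet needs columns {sorted(required)}")
    bad = set(df["status"]) - {"tumour", "normal"}
    if bad:
        raise ValueError(f"{path}: unknown status values {sorted(bad)}")
    return df


def write_sample_sheet(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


# --- config / manifest -----------------------------------------------------

def read_yaml_config(path) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return data


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True,
                                     default=_json_default) + "\n")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.ndarray, tuple, set)):
        return list(obj)
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()
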