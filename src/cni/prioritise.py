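"""High-amplitude amplicon detection and candidate driver-gene prioritisation.

Two complementary routes feed the final candidate list:

Branch A ("high frequency"): genes inside recurrent-gain regions that are
differentially expressed (BH-adjusted p < 0.05) between gain and neutral
samples, pass a log2 fold-change (> 0.7) or copy-number/expression
correlation (> 0.7) cut, and clear a per-chromosome gain-frequency cut
(defaults chr8 >= 60%, chr3 >= 50%, chr20 >= 42%; other chromosomes fall back
to the global 40% floor).

Branch B ("high amplitude"): genes within +-10 kb of a region where at least
``amp_support`` samples carry a segment of mean copy number >= ``amp_cn``
(defaults 5 and 5), kept when their correlation exceeds 0.6 or their logFC
exceeds 0.6.

The final list is the union, deduplicated by gene symbol, and every candidate
carries per-criterion flags so the cascade can be replayed and audited.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "BranchAConfig",
    "BranchBConfig",
    "PriorityConfig",
    "high_amplitude_regions",
    "genes_in_high_amp",
    "prioritise",
    "audit_candidates",
]


@dataclass(frozen=True)
class BranchAConfig:
    freq_min: float = 0.40
    logfc_min: float = 0.7
    r_min: float = 0.7
    p_adj_max: float = 0.05
    per_chrom_freq: dict[str, float] = field(
        default_factory=lambda: {"chr8": 0.60, "chr3": 0.50, "chr20": 0.42})


@dataclass(frozen=True)
class BranchBConfig:
    amp_cn: float = 5.0
    amp_support: int = 5
    r_min: float = 0.6
    logfc_min: float = 0.6


@dataclass(frozen=True)
class PriorityConfig:
    branch_a: BranchAConfig = field(default_factory=BranchAConfig)
    branch_b: BranchBConfig = field(default_factory=BranchBConfig)
    gene_flank: int = 10_000

    def __post_init__(self) -> None:
        a, b = self.branch_a, self.branch_b
        for frac in (a.freq_min, *a.per_chrom_freq.values()):
            if not 0.0 < frac <= 1.0:
                raise ValueError("frequency cutoffs must be in (0, 1]")
        if b.amp_support < 1 or b.amp_cn <= 2.0:
            raise ValueError("invalid high-amplitude thresholds")
        if self.gene_flank < 0:
            raise ValueError("gene_flank must be >= 0")


def high_amplitude_regions(segments: pd.DataFrame, amp_cn: float = 5.0,
                           amp_support: int = 5) -> pd.DataFrame:
    """Maximal intervals where >= amp_support samples have a covering segment
    of mean CN >= amp_cn.

    Returns columns chrom, start, end, n_samples_supporting, samples (the
    sorted supporting sample ids over the interval).
    """
    amps = segments[segments["mean_cn"] >= amp_cn]
    rows = []
    for chrom, grp in amps.groupby("chrom", sort=True):
        points = np.unique(np.concatenate([grp["start"].to_numpy(),
                                           grp["end"].to_numpy()]))
        delta = np.zeros(points.size, dtype=np.int64)
        np.add.at(delta, np.searchsorted(points, grp["start"].to_numpy()), 1)
        np.add.at(delta, np.searchsorted(points, grp["end"].to_numpy()), -1)
        count = np.cumsum(delta)[:-1]
        qual = count >= amp_support
        # merge consecutive qualifying elementary intervals
        k = 0
        while k < qual.size:
            if not qual[k]:
                k += 1
                continue
            j = k
            while j + 1 < qual.size and qual[j + 1]:
                j += 1
            start, end = int(points[k]), int(points[j + 1])
            sup = grp[(grp["end"] > start) & (grp["start"] < end)]["sample"]
            rows.append((chrom, start, end, int(count[k:j + 1].max()),
                         tuple(sorted(sup.unique()))))
            k = j + 1
    return pd.DataFrame(rows, columns=["chrom", "start", "end",
                                       "n_samples_supporting", "samples"])


def genes_in_high_amp(regions: pd.DataFrame, genes: pd.DataFrame,
                      flank: int = 10_000) -> set[str]:
    """Genes whose +-flank interval overlaps any high-amplitude region."""
    hits: set[str] = set()
    for row in regions.itertuples(index=False):
        sel = genes[(genes["chrom"] == row.chrom)
                    & (genes["end"] + flank > row.start)
                    & (genes["start"] - flank < row.end)]
        hits.update(sel["gene"])
    return hits


def prioritise(gene_table: pd.DataFrame,
               high_amp_genes: set[str],
               config: PriorityConfig | None = None) -> pd.DataFrame:
    """Apply the two-branch candidate cascade.

    ``gene_table`` carries one row per gene symbol with columns: gene, chrom,
    p_adj (best over the gene's probesets), logfc, r (copy-number/expression
    correlation), gain_freq (fraction of the cohort with flanked gene CN
    above the gain cutoff).  Genes without a symbol must be dropped by the
    caller.  Returns the table with per-criterion boolean flags, branch
    membership and the final-list flag.
    """
    config = config or PriorityConfig()
    a, b = config.branch_a, config.branch_b
    t = gene_table.copy()
    if t["gene"].duplicated().any():
        raise ValueError("gene_table must hold one row per gene symbol")

    p_adj = t["p_adj"].to_numpy(dtype=float)
    logfc = t["logfc"].to_numpy(dtype=float)
    r = t["r"].to_numpy(dtype=float)
    freq = t["gain_freq"].to_numpy(dtype=float)

    with np.errstate(invalid="ignore"):
        t["flag_de"] = ~np.isnan(p_adj) & (p_adj < a.p_adj_max)
        t["flag_logfc_a"] = ~np.isnan(logfc) & (logfc > a.logfc_min)
        t["flag_r_a"] = ~np.isnan(r) & (r > a.r_min)

        chrom_cut = np.empty(len(t))
        for i, chrom in enumerate(t["chrom"]):
            if chrom in a.per_chrom_freq:
                chrom_cut[i] = a.per_chrom_freq[chrom]
            else:
                chrom_cut[i] = a.freq_min
        missing = sorted(set(t["chrom"]) - set(a.per_chrom_freq))
        if missing:
            logger.warning("no per-chromosome frequency cut for %s; "
                           "falling back to freq_min=%.2f", missing, a.freq_min)
        t["flag_chrom_freq"] = ~np.isnan(freq) & (freq >= chrom_cut)

        t["flag_high_amp"] = t["gene"].isin(high_amp_genes).to_numpy()
        t["flag_r_b"] = ~np.isnan(r) & (r > b.r_min)
        t["flag_logfc_b"] = ~np.isnan(logfc) & (logfc > b.logfc_min)

    t["branch_a"] = (t["flag_de"] & (t["flag_logfc_a"] | t["flag_r_a"])
                     & t["flag_chrom_freq"])
    t["branch_b"] = t["flag_high_amp"] & (t["flag_r_b"] | t["flag_logfc_b"])
    t["final"] = t["branch_a"] | t["branch_b"]
    return t


def audit_candidates(result: pd.DataFrame, config: PriorityConfig | None = None) -> bool:
    """Replay the cascade rules over a prioritisation result.

    Verifies that every final-list gene is justified by its own flags and
    that no flagged-out gene slipped in.  Returns True when consistent,
    raises AssertionError otherwise.
    """
    config = config or PriorityConfig()
    br_a = result["flag_de"] & (result["flag_logfc_a"] | result["flag_r_a"]) \
        & result["flag_chrom_freq"]
    br_b = result["flag_high_amp"] & (result["flag_r_b"] | result["flag_logfc_b"])
    if not (result["branch_a"] == br_a).all():
        raise AssertionError("branch A membership does not replay from flags")
    if not (result["branch_b"] == br_b).all():
        raise AssertionError("branch B membership does not replay from flags")
    if not (result["final"] == (br_a | br_b)).all():
        raise AssertionError("final list is not the union of the branches")
    return True
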