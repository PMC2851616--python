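"""Synthetic tumour/normal cohort generator with known planted structure.

The generator emulates the statistical shape of a SNP-array ovarian-carcinoma
cohort: ~70 tumours of four or five histological subtypes with complex
segmental gains and losses, recurrent driver amplicons carried by 40-60% of
tumours at low amplitude (3-4 copies), occasional high-amplitude amplicons
(copy number >= 5), germline copy-number polymorphisms shared by a tumour and
its matched normal, and log2 expression in which dosage-sensitive genes track
their DNA copy number with a per-gene slope beta while passengers do not.

Marker-level copy number is simulated on the absolute scale (diploid = 2):

    cn(marker) = 2 + gain effects (max rule) + loss effects + N(0, noise_sd)

and expression per gene g in sample s as

    expr[g, s] = mu_g + beta_g * (CN[g, s] - 2) + histotype offset + N(0, sigma_e)

where CN[g, s] is the noiseless event copy number averaged over the gene
interval.  Every planted quantity is recorded in a SyntheticTruth object so
downstream stages can be scored against ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PlantedAmplicon",
    "PlantedCNP",
    "CohortConfig",
    "SyntheticTruth",
    "make_gene_grid",
    "make_cytobands",
    "simulate_cohort",
    "simulate_expression",
    "default_config",
]


@dataclass(frozen=True)
class PlantedAmplicon:
    """A recurrent driver amplicon planted into a fraction of tumours.

    ``cn_low``/``cn_high`` bound the uniform draw of the attained copy number
    per carrier (use e.g. (3, 4) for a low-gain driver, (5, 7) for a
    high-amplitude one).  ``dosage_genes`` maps gene ids to their expression
    slope beta in log2 units per copy; genes not listed have beta 0.
    """

    chrom: str
    start: int
    end: int
    frequency: float
    cn_low: float = 3.0
    cn_high: float = 4.0
    dosage_genes: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 < self.frequency <= 1.0:
            raise ValueError("amplicon frequency must be in (0, 1]")
        if self.start >= self.end:
            raise ValueError("amplicon start must be < end")
        if not 2.0 < self.cn_low <= self.cn_high:
            raise ValueError("need 2 < cn_low <= cn_high")
        if any(not math.isfinite(b) for b in self.dosage_genes.values()):
            raise ValueError("dosage slopes must be finite")


@dataclass(frozen=True)
class PlantedCNP:
    """A germline copy-number polymorphism.

    A carrier individual shows the CNP in both the tumour and its matched
    normal.  ``effect`` is the copy-number offset in carriers (+1 gain,
    -1 loss, or "both" to randomise the sign per carrier, mimicking loci that
    show gain in some individuals and loss in others).
    """

    chrom: str
    start: int
    end: int
    population_frequency: float
    effect: str = "both"  # "gain" | "loss" | "both"

    def __post_init__(self) -> None:
        if not 0.0 < self.population_frequency <= 1.0:
            raise ValueError("population_frequency must be in (0, 1]")
        if self.start >= self.end:
            raise ValueError("CNP start must be < end")
        if self.effect not in ("gain", "loss", "both"):
            raise ValueError("effect must be gain, loss or both")


@dataclass(frozen=True)
class CohortConfig:
    """Everything needed to simulate one cohort.

    ``histotypes`` maps subtype label to cohort proportion (must sum to 1);
    ``histotype_rate_multipliers`` optionally scales the passenger event rate
    per subtype (all 1 by default).  ``passenger_rate`` is the expected
    number of random background CNA segments per tumour; their lengths are
    log-uniform on [50 kb, 10 Mb] and their copy-number offset is +-1.

    ``exact_frequencies`` switches carrier assignment for planted amplicons
    and CNPs from independent Bernoulli draws (the default, emulating a real
    cohort) to exactly ``round(frequency * n)`` carriers chosen uniformly —
    useful for ground-truth benchmarks where the nominal frequency must be
    realised in every replicate.
    """

    n_tumours: int
    n_normals: int
    histotypes: dict[str, float]
    chrom_lengths: dict[str, int]
    marker_spacing: int
    driver_amplicons: tuple[PlantedAmplicon, ...] = ()
    passenger_rate: float = 6.0
    cnp_spec: tuple[PlantedCNP, ...] = ()
    noise_sd_cn: float = 0.25
    seed: int = 0
    histotype_rate_multipliers: dict[str, float] = field(default_factory=dict)
    passenger_length_range: tuple[int, int] = (50_000, 10_000_000)
    exact_frequencies: bool = False

    def __post_init__(self) -> None:
        if self.n_tumours < 4:
            raise ValueError("need at least 4 tumours")
        if self.n_normals < 0:
            raise ValueError("n_normals must be >= 0")
        if self.n_normals > self.n_tumours:
            raise ValueError("matched normals cannot outnumber tumours")
        if abs(sum(self.histotypes.values()) - 1.0) > 1e-9:
            raise ValueError("histotype proportions must sum to 1")
        if self.marker_spacing <= 0:
            raise ValueError("marker_spacing must be positive")
        if self.noise_sd_cn < 0:
            raise ValueError("noise_sd_cn must be >= 0")
        if self.passenger_rate < 0:
            raise ValueError("passenger_rate must be >= 0")
        for amp in self.driver_amplicons:
            if amp.chrom not in self.chrom_lengths:
                raise ValueError(f"amplicon chromosome {amp.chrom} not in chrom_lengths")
            if amp.end > self.chrom_lengths[amp.chrom]:
                raise ValueError(f"amplicon {amp.chrom}:{amp.start}-{amp.end} "
                                 "exceeds its chromosome length")
        for cnp in self.cnp_spec:
            if cnp.chrom not in self.chrom_lengths:
                raise ValueError(f"CNP chromosome {cnp.chrom} not in chrom_lengths")
            if cnp.end > self.chrom_lengths[cnp.chrom]:
                raise ValueError("CNP interval exceeds its chromosome length")


@dataclass
class SyntheticTruth:
    """Ground truth of one simulated cohort.

    events
        Per sample: list of (chrom, start, end, cn, kind) with kind one of
        driver / passenger / cnp.  Matched-normal CNP events are under the
        normal's sample id.
    amplicon_carriers
        Per planted amplicon index: tumour sample ids carrying it.
    cnp_carriers
        Per planted CNP index: individual indices (tumour i and, when
        matched, normal i both express the event).
    beta
        Per-gene dosage slope (0 for passengers).
    histotype_offsets
        gene id -> {histotype: offset} for the genes given subtype effects.
    """

    events: dict[str, list[tuple[str, int, int, float, str]]]
    amplicon_carriers: dict[int, list[str]]
    cnp_carriers: dict[int, list[int]]
    histotype: dict[str, str]
    beta: dict[str, float]
    histotype_offsets: dict[str, dict[str, float]]
    sigma_e: float = float("nan")

    def to_dict(self) -> dict:
        return {
            "events": {s: [list(e) for e in ev] for s, ev in self.events.items()},
            "amplicon_carriers": {str(k): v for k, v in self.amplicon_carriers.items()},
            "cnp_carriers": {str(k): v for k, v in self.cnp_carriers.items()},
            "histotype": self.histotype,
            "beta": self.beta,
            "histotype_offsets": self.histotype_offsets,
            "sigma_e": None if math.isnan(self.sigma_e) else self.sigma_e,
        }


def make_cytobands(chrom_lengths: dict[str, int],
                   bands_per_arm: int = 4) -> pd.DataFrame:
    """Synthetic cytoband table tiling each chromosome.

    Each chromosome is split into a p and a q arm of equal size, each holding
    ``bands_per_arm`` equal bands named p11.., q11.. (UCSC-like columns:
    chrom, start, end, band, gie_stain)."""
    rows = []
    stains = ["gneg", "gpos50"]
    for chrom, length in chrom_lengths.items():
        half = length // 2
        for arm, (lo, hi) in (("p", (0, half)), ("q", (half, length))):
            step = (hi - lo) // bands_per_arm
            for k in range(bands_per_arm):
                start = lo + k * step
                end = hi if k == bands_per_arm - 1 else lo + (k + 1) * step
                rows.append((chrom, start, end, f"{arm}1{k + 1}",
                             stains[k % len(stains)]))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "band",
                                       "gie_stain"])


def make_gene_grid(chrom_lengths: dict[str, int], genes_per_chrom: int,
                   gene_length: int = 20_000) -> pd.DataFrame:
    """Evenly spaced gene annotation (columns gene, chrom, start, end)."""
    rows = []
    for chrom, length in chrom_lengths.items():
        step = length // (genes_per_chrom + 1)
        for k in range(genes_per_chrom):
            start = (k + 1) * step
            rows.append((f"{chrom}_g{k:04d}", chrom, start, start + gene_length))
    return pd.DataFrame(rows, columns=["gene", "chrom", "start", "end"])


def _marker_positions(length: int, spacing: int) -> np.ndarray:
    return np.arange(spacing // 2, length, spacing, dtype=np.int64)


def _apply_events(positions: np.ndarray, events) -> np.ndarray:
    """Noiseless marker CN from an event list (one chromosome).

    Overlapping gains resolve to the maximum event CN; losses to the minimum;
    a locus under both a gain and a loss gets 2 + (gain-2) + (loss-2).
    """
    gain = np.full(positions.size, 2.0)
    loss = np.full(positions.size, 2.0)
    for start, end, cn in events:
        mask = (positions >= start) & (positions < end)
        if cn >= 2.0:
            np.maximum.at(gain, np.nonzero(mask)[0], cn)
        else:
            np.minimum.at(loss, np.nonzero(mask)[0], cn)
    return 2.0 + (gain - 2.0) + (loss - 2.0)


def simulate_cohort(config: CohortConfig
                    ) -> tuple[pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Simulate matched tumour/normal marker-level copy-number profiles.

    Returns (tumour_markers, normal_markers, truth).  Marker tables have
    columns sample, chrom, pos, cn.  Tumour ids are T01.., normal ids N01..;
    normal k is the matched normal of tumour k and shares its germline CNPs.
    Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    tumours = [f"T{k + 1:03d}" for k in range(config.n_tumours)]
    normals = [f"N{k + 1:03d}" for k in range(config.n_normals)]

    labels = list(config.histotypes)
    probs = np.array([config.histotypes[h] for h in labels])
    histotype = {s: labels[i] for s, i in
                 zip(tumours, rng.choice(len(labels), size=len(tumours), p=probs))}

    events: dict[str, list] = {s: [] for s in tumours + normals}
    amplicon_carriers: dict[int, list[str]] = {}
    cnp_carriers: dict[int, list[int]] = {}

    def _draw_carriers(freq: float) -> np.ndarray:
        if config.exact_frequencies:
            k = int(round(freq * config.n_tumours))
            mask = np.zeros(config.n_tumours, dtype=bool)
            mask[rng.choice(config.n_tumours, size=k, replace=False)] = True
            return mask
        return rng.random(config.n_tumours) < freq

    # driver amplicons: carrier draws per tumour
    for ai, amp in enumerate(config.driver_amplicons):
        carrier_mask = _draw_carriers(amp.frequency)
        amplicon_carriers[ai] = [t for t, c in zip(tumours, carrier_mask) if c]
        for t, c in zip(tumours, carrier_mask):
            if c:
                cn = float(rng.uniform(amp.cn_low, amp.cn_high))
                events[t].append((amp.chrom, amp.start, amp.end, cn, "driver"))

    # germline CNPs: carrier individuals show the event in tumour AND normal
    for ci, cnp in enumerate(config.cnp_spec):
        carrier_mask = _draw_carriers(cnp.population_frequency)
        cnp_carriers[ci] = [k for k in range(config.n_tumours) if carrier_mask[k]]
        for k in cnp_carriers[ci]:
            if cnp.effect == "both":
                offset = 1.0 if rng.random() < 0.5 else -1.0
            else:
                offset = 1.0 if cnp.effect == "gain" else -1.0
            cn = 2.0 + offset
            ev = (cnp.chrom, cnp.start, cnp.end, cn, "cnp")
            events[tumours[k]].append(ev)
            if k < config.n_normals:
                events[normals[k]].append(ev)

    # passenger background segments, rate scaled per histotype
    chroms = list(config.chrom_lengths)
    chrom_len = np.array([config.chrom_lengths[c] for c in chroms], dtype=float)
    chrom_p = chrom_len / chrom_len.sum()
    lo_len, hi_len = config.passenger_length_range
    for t in tumours:
        mult = config.histotype_rate_multipliers.get(histotype[t], 1.0)
        n_ev = rng.poisson(config.passenger_rate * mult)
        for _ in range(n_ev):
            ci = int(rng.choice(len(chroms), p=chrom_p))
            chrom = chroms[ci]
            length = int(math.exp(rng.uniform(math.log(lo_len), math.log(hi_len))))
            length = min(length, config.chrom_lengths[chrom] - 1)
            start = int(rng.integers(0, config.chrom_lengths[chrom] - length))
            offset = 1.0 if rng.random() < 0.5 else -1.0
            events[t].append((chrom, start, start + length, 2.0 + offset, "passenger"))

    # marker-level tables
    def _profile(sample_ids: list[str]) -> pd.DataFrame:
        frames = []
        for s in sample_ids:
            for chrom in chroms:
                pos = _marker_positions(config.chrom_lengths[chrom],
                                        config.marker_spacing)
                ev = [(a, b, cn) for (c, a, b, cn, _) in events[s] if c == chrom]
                cn = _apply_events(pos, ev)
                if config.noise_sd_cn > 0:
                    cn = cn + rng.normal(0.0, config.noise_sd_cn, size=pos.size)
                frames.append(pd.DataFrame({"sample": s, "chrom": chrom,
                                            "pos": pos, "cn": cn}))
        if not frames:
            return pd.DataFrame(columns=["sample", "chrom", "pos", "cn"])
        return pd.concat(frames, ignore_index=True)

    tumour_markers = _profile(tumours)
    normal_markers = _profile(normals)

    truth = SyntheticTruth(events=events, amplicon_carriers=amplicon_carriers,
                           cnp_carriers=cnp_carriers, histotype=histotype,
                           beta={}, histotype_offsets={})
    return tumour_markers, normal_markers, truth


def true_gene_cn(config: CohortConfig, truth: SyntheticTruth,
                 genes: pd.DataFrame, sample: str) -> pd.Series:
    """Noiseless event copy number averaged over each gene interval."""
    out = {}
    ev_by_chrom: dict[str, list] = {}
    for (c, a, b, cn, _) in truth.events.get(sample, []):
        ev_by_chrom.setdefault(c, []).append((a, b, cn))
    for row in genes.itertuples(index=False):
        evs = ev_by_chrom.get(row.chrom, [])
        length = row.end - row.start
        # partition gene interval at event boundaries and apply the same
        # max-gain / min-loss combination rule used for markers
        cuts = sorted({row.start, row.end,
                       *[max(row.start, min(row.end, x)) for a, b, _ in evs
                         for x in (a, b)]})
        acc = 0.0
        for a, b in zip(cuts[:-1], cuts[1:]):
            gain, loss = 2.0, 2.0
            for (s, e, cn) in evs:
                if s < b and e > a:
                    if cn >= 2.0:
                        gain = max(gain, cn)
                    else:
                        loss = min(loss, cn)
            acc += (2.0 + (gain - 2.0) + (loss - 2.0)) * (b - a)
        out[row.gene] = acc / length
    return pd.Series(out)


def simulate_expression(config: CohortConfig, truth: SyntheticTruth,
                        genes: pd.DataFrame, sigma_e: float, seed: int,
                        beta: dict[str, float] | None = None,
                        histotype_offsets: dict[str, dict[str, float]] | None = None,
                        histotype_offset_fraction: float = 0.10,
                        histotype_offset_sd: float = 0.5,
                        baseline_mean: float = 7.0,
                        baseline_sd: float = 1.0) -> pd.DataFrame:
    """Simulate a genes x tumours log2 expression matrix.

    ``beta`` overrides/extends the dosage slopes declared on the planted
    amplicons; genes not mentioned anywhere have beta 0.  A random
    ``histotype_offset_fraction`` of genes receive per-subtype offsets drawn
    N(0, histotype_offset_sd), motivating the histotype covariate in the
    differential-expression model; pass ``histotype_offsets`` (gene ->
    {histotype: offset}) to plant specific offsets instead.  Updates
    ``truth`` in place with beta, offsets and sigma_e.  Deterministic given
    ``seed``.
    """
    if sigma_e < 0:
        raise ValueError("sigma_e must be >= 0")
    rng = np.random.default_rng(seed)
    tumours = [s for s in truth.events if s.startswith("T")]
    gene_ids = genes["gene"].tolist()

    slopes = {g: 0.0 for g in gene_ids}
    for amp in config.driver_amplicons:
        slopes.update(amp.dosage_genes)
    if beta:
        slopes.update(beta)
    unknown = set(slopes) - set(gene_ids)
    if unknown:
        raise ValueError(f"dosage genes missing from annotation: {sorted(unknown)[:5]}")

    mu = rng.normal(baseline_mean, baseline_sd, size=len(gene_ids))

    if histotype_offsets is not None:
        offsets = {g: dict(v) for g, v in histotype_offsets.items()}
    else:
        # random offsets go to genes WITHOUT a dosage slope, so the two
        # planted effect types stay separable in the truth object; pass
        # histotype_offsets explicitly to put both on one gene
        offsets = {}
        eligible = [g for g in gene_ids if slopes[g] == 0.0]
        n_off = min(int(round(histotype_offset_fraction * len(gene_ids))),
                    len(eligible))
        if n_off > 0 and config.histotypes:
            chosen = rng.choice(len(eligible), size=n_off, replace=False)
            for gi in chosen:
                offsets[eligible[gi]] = {
                    h: float(rng.normal(0.0, histotype_offset_sd))
                    for h in config.histotypes
                }

    cn_true = pd.DataFrame(
        {t: true_gene_cn(config, truth, genes, t) for t in tumours})

    expr = np.empty((len(gene_ids), len(tumours)))
    for i, g in enumerate(gene_ids):
        base = mu[i] + slopes[g] * (cn_true.loc[g].to_numpy() - 2.0)
        if g in offsets:
            base = base + np.array([offsets[g].get(truth.histotype[t], 0.0)
                                    for t in tumours])
        noise = rng.normal(0.0, sigma_e, size=len(tumours)) if sigma_e > 0 else 0.0
        expr[i] = base + noise

    truth.beta = slopes
    truth.histotype_offsets = offsets
    truth.sigma_e = float(sigma_e)
    return pd.DataFrame(expr, index=gene_ids, columns=tumours)


def default_config(seed: int = 0) -> CohortConfig:
    """A study-scale default cohort: 68 tumours, 57 matched normals, four
    main histotypes plus one rare, recurrent low-gain drivers at 40-60%
    frequency, one high-amplitude amplicon and two common CNPs on two
    chromosomes."""
    chrom_lengths = {"chr1": 60_000_000, "chr2": 60_000_000}
    return CohortConfig(
        n_tumours=68,
        n_normals=57,
        histotypes={"serous": 0.54, "endometrioid": 0.21, "clearcell": 0.13,
                    "mucinous": 0.10, "undifferentiated": 0.02},
        chrom_lengths=chrom_lengths,
        marker_spacing=100_000,
        driver_amplicons=(
            PlantedAmplicon("chr1", 10_000_000, 13_000_000, frequency=0.55,
                            cn_low=3.0, cn_high=4.0),
            PlantedAmplicon("chr1", 40_000_000, 43_000_000, frequency=0.45,
                            cn_low=3.0, cn_high=4.0),
            PlantedAmplicon("chr2", 20_000_000, 23_000_000, frequency=0.60,
                            cn_low=3.0, cn_high=4.0),
            PlantedAmplicon("chr2", 48_000_000, 49_000_000, frequency=0.10,
                            cn_low=5.0, cn_high=7.0),
        ),
        passenger_rate=6.0,
        cnp_spec=(
            PlantedCNP("chr1", 11_400_000, 11_600_000, population_frequency=0.25),
            PlantedCNP("chr2", 35_000_000, 35_300_000, population_frequency=0.15),
        ),
        noise_sd_cn=0.25,
        seed=seed,
    )
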