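"""End-to-end pipeline driver.

Stage order: segment the tumour (and normal) marker profiles -> call gain /
loss states -> build the cohort gain-frequency track -> extract frequent-gain
regions and collapse them by cytoband -> detect germline CNPs in the normals
and subtract them (re-checking each surviving fragment's frequency) ->
per-region differential expression (moderated t, histotype factor, BH) and
gene-level copy-number/expression correlation -> high-amplitude amplicon
detection -> two-branch candidate-gene prioritisation.

Configured by a single PipelineConfig (YAML/JSON serialisable, unknown keys
rejected).  Every run writes its outputs plus a RunManifest recording the
config hash, input checksums and per-stage record counts, which form the
audit trail of the analysis.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as cio
from . import __version__
from .cnp import CnpCall, detect_cnps, subtract_cnps
from .prioritise import (BranchAConfig, BranchBConfig, PriorityConfig,
                         audit_candidates, genes_in_high_amp,
                         high_amplitude_regions, prioritise)
from .regions import (StateThresholds, build_frequency_track, call_states,
                      collapse_by_cytoband, frequent_gain_regions,
                      regions_to_frame)
from .segmentation import CbsParams, segment_cohort, summarise_profile
from .stats import (DEFAULT_FLANK, ModerationPrior, assign_groups,
                    cn_expr_correlation, estimate_moderation_prior,
                    fit_group_lm, gene_cn_matrix, interval_copy_number,
                    moderate_fit)
from .synthetic import (CohortConfig, PlantedAmplicon, PlantedCNP,
                        make_cytobands, make_gene_grid, simulate_cohort,
                        simulate_expression)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline", "config_from_dict",
           "validation_config"]

MIN_GENES_FOR_REGION_PRIOR = 10


@dataclass(frozen=True)
class SimulateBlock:
    """Inline synthetic-cohort settings (used when no input files are given)."""

    cohort: CohortConfig
    genes_per_chrom: int = 250
    gene_length: int = 20_000
    sigma_e: float = 0.3
    dosage_beta: dict[str, float] = field(default_factory=dict)


@dataclass(frozen=True)
class InputBlock:
    """Paths to pre-computed inputs (alternative to simulation)."""

    tumour_markers: str | None = None
    normal_markers: str | None = None
    tumour_seg: str | None = None
    normal_seg: str | None = None
    expression: str | None = None
    genes_bed: str | None = None
    cytoband: str | None = None
    sample_sheet: str | None = None


@dataclass(frozen=True)
class PipelineConfig:
    seed: int = 0
    simulate: SimulateBlock | None = None
    inputs: InputBlock | None = None
    cbs: CbsParams = field(default_factory=CbsParams)
    thresholds: StateThresholds = field(default_factory=StateThresholds)
    min_freq: float = 0.40
    cohort_n: int | None = None  # frequency denominator; default = CN cohort size
    cnp_freq: float = 0.05
    gain_group_cutoff: float = 3.0
    neutral_range: tuple[float, float] = (1.5, 2.5)
    gene_flank: int = DEFAULT_FLANK
    priority: PriorityConfig = field(default_factory=PriorityConfig)

    def __post_init__(self) -> None:
        if not 0.0 < self.min_freq <= 1.0:
            raise ValueError("min_freq must be in (0, 1]")
        if not 0.0 < self.cnp_freq < 1.0:
            raise ValueError("cnp_freq must be in (0, 1)")
        if (self.simulate is None) == (self.inputs is None):
            raise ValueError("exactly one of simulate/inputs must be set")
        if self.gene_flank < 0:
            raise ValueError("gene_flank must be >= 0")


@dataclass
class RunManifest:
    config_hash: str
    version: str
    seed: int
    input_checksums: dict[str, str]
    stage_counts: dict[str, int]
    warnings: list[str]
    timestamp: str

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _build_nested(cls, data: dict):
    """Construct a (frozen) dataclass from a dict, rejecting unknown keys."""
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"{cls.__name__}: unknown config keys {sorted(unknown)}")
    return cls(**data)


def config_from_dict(data: dict) -> PipelineConfig:
    """Build a PipelineConfig from a plain (YAML/JSON) mapping.

    Nested blocks mirror the dataclass structure; unknown keys anywhere are
    rejected rather than silently ignored.
    """
    data = dict(data)
    if "simulate" in data and data["simulate"] is not None:
        sim = dict(data["simulate"])
        cohort = dict(sim.pop("cohort"))
        cohort["driver_amplicons"] = tuple(
            _build_nested(PlantedAmplicon, dict(a))
            for a in cohort.get("driver_amplicons", ()))
        cohort["cnp_spec"] = tuple(
            _build_nested(PlantedCNP, dict(c)) for c in cohort.get("cnp_spec", ()))
        sim["cohort"] = _build_nested(CohortConfig, cohort)
        data["simulate"] = _build_nested(SimulateBlock, sim)
    if "inputs" in data and data["inputs"] is not None:
        data["inputs"] = _build_nested(InputBlock, dict(data["inputs"]))
    if "cbs" in data:
        data["cbs"] = _build_nested(CbsParams, dict(data["cbs"]))
    if "thresholds" in data:
        data["thresholds"] = _build_nested(StateThresholds, dict(data["thresholds"]))
    if "priority" in data:
        pri = dict(data["priority"])
        if "branch_a" in pri:
            pri["branch_a"] = _build_nested(BranchAConfig, dict(pri["branch_a"]))
        if "branch_b" in pri:
            pri["branch_b"] = _build_nested(BranchBConfig, dict(pri["branch_b"]))
        data["priority"] = _build_nested(PriorityConfig, pri)
    if "neutral_range" in data:
        data["neutral_range"] = tuple(data["neutral_range"])
    return _build_nested(PipelineConfig, data)


def _config_hash(config: PipelineConfig) -> str:
    def enc(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {f.name: enc(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
        if isinstance(obj, dict):
            return {str(k): enc(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [enc(v) for v in obj]
        if isinstance(obj, float) and obj != obj:  # NaN
            return None
        return obj

    blob = json.dumps(enc(config), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()


def validation_config(seed: int = 0, n_tumours: int = 60, n_normals: int = 20,
                      genes_per_chrom: int = 250, sigma_e: float = 0.3,
                      dosage_beta: float = 0.5) -> PipelineConfig:
    """A fully specified synthetic study for end-to-end validation.

    Two 60 Mb chromosomes profiled at 100 kb marker spacing; three recurrent
    low-gain (CN 3-4) driver amplicons carried by 50-60% of tumours, each
    with five dosage-sensitive genes of slope ``dosage_beta``; one
    high-amplitude amplicon (CN ~6) at 10% frequency with three dosage genes;
    two germline CNPs (one inside a driver amplicon, one outside any);
    passenger CNAs at rate 6 per tumour and expression noise ``sigma_e``.
    All downstream ground-truth scoring (driver recall, passenger
    false-positive rate, CNP exclusion) runs against this cohort.

    Carrier counts use ``exact_frequencies`` so the nominal planted
    frequencies are realised in every replicate: with Bernoulli carrier
    draws a 10% x 60-tumour amplicon misses its own >=5-sample support
    condition in about a quarter of replicates, which would benchmark the
    sampler rather than the detectors.
    """
    chrom_lengths = {"chr1": 60_000_000, "chr2": 60_000_000}
    genes = make_gene_grid(chrom_lengths, genes_per_chrom)

    def dosage(chrom: str, start: int, end: int, k: int) -> dict[str, float]:
        sel = genes[(genes["chrom"] == chrom) & (genes["start"] >= start)
                    & (genes["end"] <= end)]
        return {g: dosage_beta for g in sel["gene"].head(k)}

    amps = (
        PlantedAmplicon("chr1", 10_000_000, 13_000_000, frequency=0.55,
                        cn_low=3.0, cn_high=4.0,
                        dosage_genes=dosage("chr1", 10_000_000, 13_000_000, 5)),
        PlantedAmplicon("chr1", 40_000_000, 43_000_000, frequency=0.50,
                        cn_low=3.0, cn_high=4.0,
                        dosage_genes=dosage("chr1", 40_000_000, 43_000_000, 5)),
        PlantedAmplicon("chr2", 20_000_000, 23_000_000, frequency=0.60,
                        cn_low=3.0, cn_high=4.0,
                        dosage_genes=dosage("chr2", 20_000_000, 23_000_000, 5)),
        PlantedAmplicon("chr2", 48_000_000, 49_500_000, frequency=0.10,
                        cn_low=5.5, cn_high=6.5,
                        dosage_genes=dosage("chr2", 48_000_000, 49_500_000, 3)),
    )
    cohort = CohortConfig(
        n_tumours=n_tumours,
        n_normals=n_normals,
        histotypes={"serous": 0.55, "endometrioid": 0.20,
                    "clearcell": 0.15, "mucinous": 0.10},
        chrom_lengths=chrom_lengths,
        marker_spacing=100_000,
        driver_amplicons=amps,
        passenger_rate=6.0,
        cnp_spec=(
            PlantedCNP("chr1", 11_200_000, 11_800_000, population_frequency=0.25),
            PlantedCNP("chr2", 35_000_000, 35_600_000, population_frequency=0.15),
        ),
        noise_sd_cn=0.25,
        seed=seed,
        exact_frequencies=True,
    )
    return PipelineConfig(
        seed=seed,
        simulate=SimulateBlock(cohort=cohort, genes_per_chrom=genes_per_chrom,
                               sigma_e=sigma_e),
    )


def write_simulation(sim: SimulateBlock, outdir: str | Path):
    """Simulate a cohort and write its input files under ``outdir``.

    Writes tumour/normal marker TSVs, the gene BED, a synthetic cytoband
    table, the expression matrix, the sample sheet and the ground-truth JSON.
    Returns (genes, cytobands, tumour_markers, normal_markers, expression,
    samples, truth).
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    cohort = sim.cohort
    genes = make_gene_grid(cohort.chrom_lengths, sim.genes_per_chrom,
                           sim.gene_length)
    cytobands = make_cytobands(cohort.chrom_lengths)
    tum_markers, nrm_markers, truth = simulate_cohort(cohort)
    expr = simulate_expression(cohort, truth, genes, sim.sigma_e,
                               seed=cohort.seed + 1, beta=sim.dosage_beta)
    samples = pd.DataFrame(
        [{"sample": s, "histotype": truth.histotype[s], "status": "tumour"}
         for s in sorted(truth.histotype)]
        + [{"sample": s, "histotype": "NA", "status": "normal"}
           for s in sorted(set(nrm_markers["sample"]))])
    cio.write_markers(tum_markers, out / "tumour_markers.tsv")
    cio.write_markers(nrm_markers, out / "normal_markers.tsv")
    cio.write_bed(genes, out / "genes.bed")
    cio.write_cytoband(cytobands, out / "cytoband.txt")
    cio.write_expression(expr, out / "expression.tsv")
    cio.write_sample_sheet(samples, out / "samples.tsv")
    cio.write_json(truth.to_dict(), out / "truth.json")
    return genes, cytobands, tum_markers, nrm_markers, expr, samples, truth


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> RunManifest:
    """Execute every stage and write all artifacts under ``outdir``.

    Deterministic given the config (including its seed): running twice with
    the same config and inputs produces byte-identical result tables.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int] = {}
    warns: list[str] = []
    checksums: dict[str, str] = {}

    # ------------------------------------------------------------------ inputs
    try:
        if config.simulate is not None:
            (genes, cytobands, tum_markers, nrm_markers, expr, samples,
             truth) = write_simulation(config.simulate, out)
            tum_seg = nrm_seg = None
        else:
            inp = config.inputs
            for name in ("expression", "genes_bed", "cytoband", "sample_sheet"):
                if getattr(inp, name) is None:
                    raise ValueError(f"inputs.{name} is required")
            if inp.tumour_markers is None and inp.tumour_seg is None:
                raise ValueError("need tumour markers or a tumour SEG file")
            for name in dataclasses.fields(inp):
                path = getattr(inp, name.name)
                if path is not None:
                    checksums[name.name] = cio.file_sha256(path)
            genes = cio.read_bed(inp.genes_bed)
            cytobands = cio.read_cytoband(inp.cytoband)
            expr = cio.read_expression(inp.expression)
            samples = cio.read_sample_sheet(inp.sample_sheet)
            tum_markers = (cio.read_markers(inp.tumour_markers)
                           if inp.tumour_markers else None)
            nrm_markers = (cio.read_markers(inp.normal_markers)
                           if inp.normal_markers else None)
            tum_seg = cio.read_seg(inp.tumour_seg) if inp.tumour_seg else None
            nrm_seg = cio.read_seg(inp.normal_seg) if inp.normal_seg else None
            truth = None
    except Exception as exc:
        raise RuntimeError(f"stage 'inputs' failed: {exc}") from exc

    histotypes = samples[samples["status"] == "tumour"].set_index("sample")["histotype"]

    # ------------------------------------------------------------- segmentation
    try:
        if tum_seg is None:
            tum_seg = segment_cohort(tum_markers, config.cbs, seed=config.seed)
        if nrm_seg is None and nrm_markers is not None and not nrm_markers.empty:
            nrm_seg = segment_cohort(nrm_markers, config.cbs, seed=config.seed + 1)
        cio.write_seg(tum_seg, out / "tumour.seg")
        if nrm_seg is not None:
            cio.write_seg(nrm_seg, out / "normal.seg")
        counts["tumour_segments"] = len(tum_seg)
        counts["normal_segments"] = 0 if nrm_seg is None else len(nrm_seg)
    except Exception as exc:
        raise RuntimeError(f"stage 'segmentation' failed: {exc}") from exc

    # ------------------------------------------------- states & frequency track
    try:
        tum_called = call_states(tum_seg, config.thresholds)
        n_cn_cohort = config.cohort_n or tum_called["sample"].nunique()
        profile_summary = summarise_profile(tum_seg,
                                            config.thresholds.gain_cutoff,
                                            config.thresholds.loss_cutoff)
        profile_summary.to_csv(out / "profile_summary.tsv", sep="\t", index=False,
                               float_format=cio.FLOAT_FMT)
        track = build_frequency_track(tum_called, n_samples=n_cn_cohort)
        track.to_csv(out / "frequency_track.tsv", sep="\t", index=False,
                     float_format=cio.FLOAT_FMT)
        counts["gain_segments"] = int((tum_called["state"] == "gain").sum())
        counts["loss_segments"] = int((tum_called["state"] == "loss").sum())
    except Exception as exc:
        raise RuntimeError(f"stage 'frequency' failed: {exc}") from exc

    # ------------------------------------------------------- frequent regions
    try:
        frequent = frequent_gain_regions(track, config.min_freq)
        regions = collapse_by_cytoband(frequent, cytobands)
        regions_pre = regions_to_frame(regions)
        regions_pre.to_csv(out / "regions_pre_cnp.tsv", sep="\t", index=False,
                           float_format=cio.FLOAT_FMT)
        counts["frequent_intervals"] = len(frequent)
        counts["regions_pre_cnp"] = len(regions)
    except Exception as exc:
        raise RuntimeError(f"stage 'regions' failed: {exc}") from exc

    # ------------------------------------------------------------- CNP filter
    try:
        cnps: list[CnpCall] = []
        if nrm_seg is not None and not nrm_seg.empty:
            import warnings as _warnings
            with _warnings.catch_warnings(record=True) as wlist:
                _warnings.simplefilter("always")
                cnps = detect_cnps(nrm_seg, cnp_freq=config.cnp_freq,
                                   thresholds=config.thresholds)
            warns.extend(str(w.message) for w in wlist)
        cnp_frame = pd.DataFrame(
            [{"chrom": c.chrom, "start": c.start, "end": c.end,
              "n_normals_altered": c.n_normals_altered,
              "n_normals": c.n_normals, "type": c.type} for c in cnps])
        cnp_frame.to_csv(out / "cnps.tsv", sep="\t", index=False)
        counts["cnps"] = len(cnps)

        frag_rows = []
        for reg in regions:
            pieces = subtract_cnps((reg.chrom, reg.start, reg.end), cnps)
            for (chrom, s, e) in pieces:
                # re-check the gain frequency of each surviving fragment
                sub = track[(track["chrom"] == chrom) & (track["end"] > s)
                            & (track["start"] < e)]
                if sub.empty:
                    freq = 0.0
                else:
                    w = (np.minimum(sub["end"], e) - np.maximum(sub["start"], s))
                    freq = float(np.average(sub["gain_freq"], weights=w))
                frag_rows.append({"chrom": chrom, "start": int(s), "end": int(e),
                                  "bands": reg.band_tag, "parent_id": reg.region_id,
                                  "gain_freq": freq, "split": len(pieces) > 1,
                                  "below_freq": freq < config.min_freq})
        frags = pd.DataFrame(frag_rows, columns=["chrom", "start", "end", "bands",
                                                 "parent_id", "gain_freq", "split",
                                                 "below_freq"])
        if not frags.empty:
            frags = frags.sort_values(["chrom", "start", "end"]).reset_index(drop=True)
            ords = frags.groupby("chrom").cumcount() + 1
            stripped = frags["chrom"].str.replace("^chr", "", regex=True)
            frags["region_id"] = stripped + "_" + ords.astype(str)
        else:
            frags["region_id"] = pd.Series(dtype=str)
        frags.to_csv(out / "regions.tsv", sep="\t", index=False,
                     float_format=cio.FLOAT_FMT)
        counts["regions_post_cnp"] = len(frags)
        counts["regions_below_freq_after_split"] = int(frags["below_freq"].sum()) \
            if not frags.empty else 0
    except Exception as exc:
        raise RuntimeError(f"stage 'cnp_filter' failed: {exc}") from exc

    # -------------------------------------------------------------- integration
    try:
        analysis_regions = frags[~frags["below_freq"]] if not frags.empty else frags
        expr_samples = [c for c in expr.columns]
        cn_samples = sorted(tum_seg["sample"].unique())
        common = [s for s in cn_samples if s in expr_samples]

        # gene-level copy number for every annotated gene (flanked)
        full_cn = gene_cn_matrix(tum_seg, genes, flank=config.gene_flank)
        gene_cn = full_cn[[s for s in full_cn.columns if s in common]]

        # gene-level gain frequency over the CN cohort
        gain_freq = ((full_cn > config.thresholds.gain_cutoff).sum(axis=1)
                     / n_cn_cohort)

        # first pass: per-region linear fits
        fits = {}
        assignments = {}
        skipped = []
        for reg in analysis_regions.itertuples(index=False):
            region_cn = pd.Series(
                {s: interval_copy_number(tum_seg[tum_seg["sample"] == s],
                                         reg.chrom, reg.start, reg.end)
                 for s in common})
            grp = assign_groups(reg.region_id, region_cn,
                                config.gain_group_cutoff, config.neutral_range)
            gsel = genes[(genes["chrom"] == reg.chrom) & (genes["end"] > reg.start)
                         & (genes["start"] < reg.end)]
            if gsel.empty:
                skipped.append((reg.region_id, "no probesets"))
                continue
            if not grp.testable:
                skipped.append((reg.region_id, "empty G or N"))
                warns.append(f"region {reg.region_id} untestable "
                             f"(G={len(grp.G)}, N={len(grp.N)})")
                continue
            sub_expr = expr.loc[expr.index.isin(gsel["gene"])]
            fits[reg.region_id] = fit_group_lm(sub_expr, grp, histotypes)
            assignments[reg.region_id] = grp

        # genome-wide moderation prior from all per-region fits
        global_prior = None
        if fits:
            all_s2 = np.concatenate([f["s2"].to_numpy() for f in fits.values()])
            all_df = np.concatenate([f["df_residual"].to_numpy() for f in fits.values()])
            try:
                global_prior = estimate_moderation_prior(all_s2, all_df)
            except ValueError:
                global_prior = ModerationPrior(d0=np.inf,
                                               s0_sq=max(float(all_s2.mean()), 1e-12))

        de_rows = []
        for region_id, fit in fits.items():
            grp = assignments[region_id]
            if len(fit) >= MIN_GENES_FOR_REGION_PRIOR:
                try:
                    prior = estimate_moderation_prior(fit["s2"].to_numpy(),
                                                      fit["df_residual"].to_numpy())
                except ValueError:
                    prior = global_prior
            else:
                prior = global_prior
            res = moderate_fit(fit, prior.d0, prior.s0_sq, len(grp.G), len(grp.N))
            for probeset, row in res.iterrows():
                e = expr.loc[probeset, gene_cn.columns].to_numpy(dtype=float)
                c = gene_cn.loc[probeset].to_numpy(dtype=float) \
                    if probeset in gene_cn.index else np.full(len(gene_cn.columns), np.nan)
                r, p_r, n_r = cn_expr_correlation(e, c)
                de_rows.append({
                    "region_id": region_id, "probeset": probeset, "gene": probeset,
                    "r": r, "r_p": p_r, "r_n": n_r,
                    "logFC": row["logFC"], "t": row["t_moderated"],
                    "p_raw": row["p_raw"], "p_adj": row["p_adj"],
                    "n_G": int(row["n_G"]), "n_N": int(row["n_N"]),
                })
        de = pd.DataFrame(de_rows, columns=["region_id", "probeset", "gene", "r",
                                            "r_p", "r_n", "logFC", "t", "p_raw",
                                            "p_adj", "n_G", "n_N"])
        de.to_csv(out / "integration.tsv", sep="\t", index=False,
                  float_format=cio.FLOAT_FMT)
        counts["regions_tested"] = len(fits)
        counts["regions_skipped"] = len(skipped)
        counts["de_probesets"] = int((de["p_adj"] < 0.05).sum()) if not de.empty else 0
        counts["probesets_tested"] = len(de)
    except Exception as exc:
        raise RuntimeError(f"stage 'integration' failed: {exc}") from exc

    # ---------------------------------------------------------------- high-amp
    try:
        hi = high_amplitude_regions(tum_seg, config.priority.branch_b.amp_cn,
                                    config.priority.branch_b.amp_support)
        hi_out = hi.copy()
        hi_out["length"] = hi_out["end"] - hi_out["start"]
        hi_out["samples"] = hi_out["samples"].map(lambda s: ",".join(s))
        hi_genes = genes_in_high_amp(hi, genes, flank=config.priority.gene_flank)
        hi_out["genes"] = [
            ",".join(sorted(genes_in_high_amp(pd.DataFrame([row._asdict()]), genes,
                                              config.priority.gene_flank)))
            for row in hi.itertuples(index=False)]
        hi_out.to_csv(out / "high_amplitude_regions.tsv", sep="\t", index=False)
        counts["high_amp_regions"] = len(hi)
        counts["high_amp_genes"] = len(hi_genes)
    except Exception as exc:
        raise RuntimeError(f"stage 'high_amplitude' failed: {exc}") from exc

    # ------------------------------------------------------------ prioritisation
    try:
        # gene-level rollup: best adjusted p across regions, logFC at that
        # probeset, correlation from the gene-level analysis
        if not de.empty:
            best = (de.sort_values(["gene", "p_adj"])
                    .drop_duplicates("gene").set_index("gene"))
        else:
            best = pd.DataFrame(columns=["p_adj", "logFC", "r"])
        rows = []
        for gene in genes["gene"]:
            in_de = gene in best.index
            e = expr.loc[gene, gene_cn.columns].to_numpy(dtype=float) \
                if gene in expr.index else None
            if in_de:
                r_val = best.loc[gene, "r"]
            elif gene in hi_genes and e is not None and gene in gene_cn.index:
                r_val, _, _ = cn_expr_correlation(e, gene_cn.loc[gene].to_numpy())
            else:
                r_val = np.nan
            rows.append({
                "gene": gene,
                "chrom": genes.set_index("gene").loc[gene, "chrom"],
                "p_adj": best.loc[gene, "p_adj"] if in_de else np.nan,
                "logfc": best.loc[gene, "logFC"] if in_de else np.nan,
                "r": r_val,
                "gain_freq": float(gain_freq.get(gene, np.nan)),
            })
        gene_table = pd.DataFrame(rows)
        candidates = prioritise(gene_table, hi_genes, config.priority)
        audit_candidates(candidates, config.priority)
        candidates.to_csv(out / "candidates.tsv", sep="\t", index=False,
                          float_format=cio.FLOAT_FMT)
        final = candidates[candidates["final"]]
        final.to_csv(out / "final_candidates.tsv", sep="\t", index=False,
                     float_format=cio.FLOAT_FMT)
        counts["branch_a_genes"] = int(candidates["branch_a"].sum())
        counts["branch_b_genes"] = int(candidates["branch_b"].sum())
        counts["final_genes"] = int(candidates["final"].sum())
    except Exception as exc:
        raise RuntimeError(f"stage 'prioritisation' failed: {exc}") from exc

    manifest = RunManifest(
        config_hash=_config_hash(config),
        version=__version__,
        seed=config.seed,
        input_checksums=checksums,
        stage_counts=counts,
        warnings=warns,
        timestamp=time.strftime("%Y-%m-%dT%H:%M:%S", time.gmtime()),
    )
    cio.write_json(manifest.to_dict(), out / "manifest.json")
    logger.info("pipeline complete: %s", counts)
    return manifest
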