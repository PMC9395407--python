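"""End-to-end orchestration: simulate -> signal -> QC -> HMM -> CNVR ->
F_ST -> annotation, under a single configuration.

Every threshold of the analysis appears as an explicit configuration key
with its conventional default: sample call rate 0.90, SNP missingness 0.05,
MAF 0.02, HWE exact p 1e-6, LRR SD 0.3, BAF drift 0.01, waviness 0.05,
F_ST window 5, outlier quantile 0.01. A run writes all stage outputs under
one directory and returns a manifest of record counts, so filter effects
are auditable stage by stage; the same config and seed reproduce identical
outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import annotate as _annotate
from . import cnvr as _cnvr
from . import fst as _fst
from . import hmm as _hmm
from . import io as _io
from . import qc as _qc
from . import signal as _signal
from . import simulate as _simulate

__all__ = ["PipelineConfig", "RunManifest", "run_all", "load_config", "desk_scale_config"]

__version__ = "0.1.0"


@dataclass(frozen=True)
class PipelineConfig:
    """One configuration for the whole run (simulation + all thresholds)."""

    sim: _simulate.SimConfig = field(default_factory=_simulate.SimConfig)
    sample_qc: _qc.SampleQcThresholds = field(default_factory=_qc.SampleQcThresholds)
    snp_qc: _qc.SnpQcThresholds = field(default_factory=_qc.SnpQcThresholds)
    hmm: _hmm.HmmParams = field(default_factory=_hmm.HmmParams)
    fst_window: int = 5
    outlier_quantile: float = 0.01
    proximity_kb: float = 1000.0
    cnvr_scope: str = "per-breed"  # default scope for the headline region count
    merge_call_gaps: bool = False

    def digest(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class RunManifest:
    """Auditable record of one pipeline run."""

    config_digest: str
    seed: int
    version: str
    counts: dict
    paths: dict


def desk_scale_config(seed: int = 7, **overrides) -> PipelineConfig:
    """The reduced 2-breed, 2-chromosome configuration used by the tests.

    30 samples x 5,000 SNPs with 2 implanted events per sample on average —
    small enough for a laptop run, large enough for recovery statistics.
    """
    sim = _simulate.SimConfig(
        n_breeds=2,
        n_per_breed=15,
        n_chromosomes=2,
        snps_per_chromosome=2500,
        chrom_length_bp=125_000_000,
        cnvs_per_individual_mean=2.0,
        lrr_noise_sd=0.2,
        seed=seed,
        **overrides,
    )
    return PipelineConfig(sim=sim)


def load_config(path) -> PipelineConfig:
    """Build a PipelineConfig from a YAML file with per-stage sections."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    sim_kwargs = dict(raw.get("sim", {}))
    if "cnv_length_range_bp" in sim_kwargs:
        sim_kwargs["cnv_length_range_bp"] = tuple(sim_kwargs["cnv_length_range_bp"])
    hmm_kwargs = {k: tuple(v) if isinstance(v, list) else v for k, v in raw.get("hmm", {}).items()}
    return PipelineConfig(
        sim=_simulate.SimConfig(**sim_kwargs),
        sample_qc=_qc.SampleQcThresholds(**raw.get("sample_qc", {})),
        snp_qc=_qc.SnpQcThresholds(**raw.get("snp_qc", {})),
        hmm=_hmm.HmmParams(**hmm_kwargs),
        fst_window=raw.get("fst_window", 5),
        outlier_quantile=raw.get("outlier_quantile", 0.01),
        proximity_kb=raw.get("proximity_kb", 1000.0),
        cnvr_scope=raw.get("cnvr_scope", "per-breed"),
        merge_call_gaps=raw.get("merge_call_gaps", False),
    )


def run_all(config: PipelineConfig, out_dir, qtl_intervals=None, external_cnvrs=None) -> RunManifest:
    """Execute every stage and write outputs plus a JSON manifest.

    Optional ``qtl_intervals`` / ``external_cnvrs`` (lists of
    ``GenomeInterval``) switch on the QTL-overlap and cross-dataset
    comparison stages.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts: dict = {}
    paths: dict = {}

    # --- simulate ---------------------------------------------------------
    cohort = _simulate.simulate_cohort(config.sim)
    paths.update(_simulate.write_cohort(cohort, out / "cohort"))
    counts["samples"] = cohort.n_samples
    counts["snps"] = cohort.n_snps
    counts["truth_events"] = len(cohort.truth)

    # --- signal: clusters + PFB from the cohort as its own reference ------
    theta = _signal.compute_theta(cohort.x, cohort.y)
    r = cohort.x + cohort.y
    clusters = _signal.estimate_clusters(theta, r, cohort.dosage)
    signals = [
        _signal.transform_sample(row.sample_id, row.breed, cohort.x[i], cohort.y[i], clusters)
        for i, row in cohort.samples.iterrows()
    ]
    baf_matrix = np.vstack([s.baf for s in signals])
    pfb, _pfb_flagged = _signal.compile_pfb(baf_matrix)
    counts["usable_cluster_snps"] = int(clusters.usable.sum())

    # --- QC ---------------------------------------------------------------
    chrom_arr = cohort.marker_map["chrom"].to_numpy()
    pos_arr = cohort.marker_map["pos"].to_numpy()
    call_rates = 1.0 - (cohort.dosage < 0).mean(axis=1)
    sample_reports = [
        _qc.sample_metrics(s.sample_id, s.lrr, s.baf, chrom_arr, pos_arr, call_rates[i], config.sample_qc)
        for i, s in enumerate(signals)
    ]
    passing = set(_qc.filter_samples(sample_reports))
    counts["samples_pass_qc"] = len(passing)
    pd.DataFrame([vars(rep) for rep in sample_reports]).to_csv(out / "sample_qc.tsv", sep="\t", index=False)
    paths["sample_qc"] = out / "sample_qc.tsv"

    retained, snp_reports = _qc.filter_snps(
        cohort.dosage, cohort.marker_map, cohort.samples["breed"].to_numpy(), config.snp_qc
    )
    counts["snps_retained"] = int(retained.sum())
    pd.DataFrame([vars(rep) for rep in snp_reports]).to_csv(out / "snp_qc.tsv", sep="\t", index=False)
    paths["snp_qc"] = out / "snp_qc.tsv"

    # --- HMM calling (QC-passing samples, all signal-usable markers) ------
    usable = clusters.usable
    calls: list[_hmm.CnvCall] = []
    loh_runs: list[_hmm.CnvCall] = []
    for i, s in enumerate(signals):
        if s.sample_id not in passing:
            continue
        for chrom in pd.unique(chrom_arr):
            sel = (chrom_arr == chrom) & usable
            c_calls, c_loh = _hmm.call_chromosome(
                pos_arr[sel], s.lrr[sel], s.baf[sel], pfb[sel], config.hmm, s.sample_id, str(chrom)
            )
            calls.extend(c_calls)
            loh_runs.extend(c_loh)
    if config.merge_call_gaps:
        calls = _hmm.merge_adjacent_calls(calls)
    counts["cnv_calls"] = len(calls)
    counts["loh_runs"] = len(loh_runs)
    _io.write_calls(out / "calls.tsv", calls)
    paths["calls"] = out / "calls.tsv"

    # --- CNVRs ------------------------------------------------------------
    breed_of = dict(zip(cohort.samples["sample_id"], cohort.samples["breed"]))
    per_breed = _cnvr.merge_calls(calls, breed_of, scope="per-breed")
    cohort_regions = _cnvr.merge_calls(calls, breed_of, scope="cohort")
    headline = (
        [r for regions in per_breed.values() for r in regions]
        if config.cnvr_scope == "per-breed"
        else cohort_regions
    )
    counts["cnvrs"] = len(headline)
    counts["cnvrs_by_status"] = {
        status: sum(1 for r in headline if r.status == status) for status in ("Loss", "Gain", "Both")
    }
    counts["cnvrs_per_breed"] = {b: len(v) for b, v in per_breed.items()} if isinstance(per_breed, dict) else {}
    _io.write_cnvrs(out / "cnvrs.tsv", headline)
    paths["cnvrs"] = out / "cnvrs.tsv"
    summary = _cnvr.summarize(events=calls, n_samples=len(passing))
    counts["cnv_mean_length_kb"] = summary.mean_length_kb
    if cohort.n_samples >= 2 and len(per_breed) >= 2:
        venn = _cnvr.venn_counts(per_breed)
        counts["venn"] = {"+".join(sorted(k)): v for k, v in venn.items()}

    # --- F_ST scans -------------------------------------------------------
    scans = _fst.pairwise_scans(
        cohort.dosage[:, retained],
        cohort.samples["breed"].to_numpy(),
        cohort.marker_map.loc[retained].reset_index(drop=True),
        window_size=config.fst_window,
        q=config.outlier_quantile,
    )
    flagged_intervals: list[_annotate.GenomeInterval] = []
    counts["fst"] = {}
    for pair, scan in scans.items():
        tag = f"{pair[0]}_vs_{pair[1]}"
        scan["records"].to_csv(out / f"fst_{tag}.tsv", sep="\t", index=False, float_format="%.6f")
        win = scan["windows"].copy()
        win["flagged"] = scan["flagged"]
        win.to_csv(out / f"fst_windows_{tag}.tsv", sep="\t", index=False, float_format="%.6f")
        _fst.manhattan_plot(win, out / f"fst_{tag}.png", title=f"Windowed F_ST {tag}")
        counts["fst"][tag] = {
            "windows": int(len(win)),
            "flagged": int(scan["flagged"].sum()),
            "multilocus_theta": scan["multilocus_theta"],
        }
        for k, row in win[win["flagged"]].iterrows():
            flagged_intervals.append(
                _annotate.GenomeInterval(str(row["chrom"]), int(row["start"]), int(row["end"]), f"{tag}_w{k}", "window")
            )

    # --- annotation -------------------------------------------------------
    cnvr_intervals = [
        _annotate.GenomeInterval(r.chromosome, r.start_bp, r.end_bp, f"cnvr_{k}", "CNVR")
        for k, r in enumerate(headline)
    ]
    sel = _annotate.selection_overlap(cnvr_intervals, flagged_intervals)
    counts["cnvrs_under_selection"] = len(sel)
    if qtl_intervals is not None:
        qtl_hits = _annotate.intersect(cnvr_intervals, qtl_intervals)
        counts["cnvrs_overlapping_qtl"] = len({h.query_id for h in qtl_hits})
        counts["qtls_overlapped"] = len({h.subject_id for h in qtl_hits})
    if external_cnvrs is not None:
        _, xsummary = _annotate.cross_dataset_compare(cnvr_intervals, external_cnvrs, config.proximity_kb)
        counts["external_comparison"] = xsummary

    manifest = RunManifest(
        config_digest=config.digest(),
        seed=config.sim.seed,
        version=__version__,
        counts=counts,
        paths={k: str(v) for k, v in paths.items()},
    )
    with open(out / "manifest.json", "w") as fh:
        json.dump(vars(manifest), fh, indent=2, default=str)
    return manifest
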