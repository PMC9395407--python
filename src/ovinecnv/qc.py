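"""Marker- and sample-level quality control before calling and scanning.

Sample-level gates follow the standard SNP-array CNV exclusions: LRR
standard deviation < 0.3, BAF drift < 0.01, waviness factor < 0.05 and a
genotype call rate >= 0.90. Marker-level gates drop SNPs with > 5% missing
genotypes, minor allele frequency < 0.02, an exact Hardy–Weinberg test
p-value below 1e-6, or without an autosomal position.

Two of the sample statistics are named in the array-QC literature without a
closed definition, so they are operationalised (and config-overridable)
here: *BAF drift* is the fraction of markers whose BAF falls in the drifted
bands (0.15, 0.35) or (0.65, 0.85) — i.e. away from the three canonical
clusters — and *waviness* is the SD of per-1-Mb-bin median LRR.

The Hardy–Weinberg test is the exact conditional test: given the observed
allele counts, the p-value sums the probabilities of all heterozygote
counts whose probability does not exceed the observed one. In multi-breed
cohorts it is applied within each breed and the minimum p is compared to
the threshold (pooling breeds would confound differentiation with
disequilibrium).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

__all__ = [
    "SampleQcReport",
    "SnpQcReport",
    "SampleQcThresholds",
    "SnpQcThresholds",
    "sample_metrics",
    "exact_hwe_p",
    "filter_snps",
    "filter_samples",
]

DRIFT_BANDS = ((0.15, 0.35), (0.65, 0.85))
NON_AUTOSOMES = {"X", "Y", "XY", "MT", "M", "0", ""}


@dataclass(frozen=True)
class SampleQcThresholds:
    max_lrr_sd: float = 0.3
    max_baf_drift: float = 0.01
    max_waviness: float = 0.05
    min_call_rate: float = 0.90


@dataclass(frozen=True)
class SnpQcThresholds:
    max_missing: float = 0.05
    min_maf: float = 0.02
    min_hwe_p: float = 1e-6


@dataclass
class SampleQcReport:
    sample_id: str
    lrr_sd: float
    baf_drift: float
    waviness: float
    call_rate: float
    passed: bool
    low_confidence: bool = False


@dataclass
class SnpQcReport:
    name: str
    missing_rate: float
    maf: float
    hwe_p: float
    on_autosome: bool
    has_position: bool
    passed: bool


def sample_metrics(
    sample_id: str,
    lrr: np.ndarray,
    baf: np.ndarray,
    chrom: np.ndarray,
    pos: np.ndarray,
    call_rate: float = 1.0,
    thresholds: SampleQcThresholds = SampleQcThresholds(),
    waviness_bin_bp: int = 1_000_000,
    drift_bands=DRIFT_BANDS,
) -> SampleQcReport:
    """Per-sample signal-quality statistics and pass/fail decision.

    ``lrr_sd`` is the SD (ddof=1) of finite autosomal LRR; ``baf_drift`` the
    fraction of finite BAF values inside the drifted bands; ``waviness`` the
    SD of per-bin median LRR (bins of ``waviness_bin_bp`` within each
    chromosome). Fewer than 100 usable markers flags the report
    low-confidence rather than failing it.
    """
    lrr = np.asarray(lrr, dtype=float)
    baf = np.asarray(baf, dtype=float)
    chrom = np.asarray(chrom)
    pos = np.asarray(pos)

    finite_lrr = np.isfinite(lrr)
    n_usable = int(finite_lrr.sum())
    lrr_sd = float(np.std(lrr[finite_lrr], ddof=1)) if n_usable > 1 else 0.0

    finite_baf = np.isfinite(baf)
    if finite_baf.any():
        b = baf[finite_baf]
        drifted = np.zeros(b.shape, dtype=bool)
        for lo, hi in drift_bands:
            drifted |= (b > lo) & (b < hi)
        baf_drift = float(drifted.mean())
    else:
        baf_drift = 0.0

    bin_medians = []
    for c in pd.unique(chrom):
        on_c = (chrom == c) & finite_lrr
        if not on_c.any():
            continue
        bins = pos[on_c] // waviness_bin_bp
        med = pd.Series(lrr[on_c]).groupby(bins).median()
        bin_medians.append(med.to_numpy())
    if bin_medians:
        med_all = np.concatenate(bin_medians)
        waviness = float(np.std(med_all)) if med_all.size > 1 else 0.0
    else:
        waviness = 0.0

    passed = (
        lrr_sd < thresholds.max_lrr_sd
        and baf_drift < thresholds.max_baf_drift
        and waviness < thresholds.max_waviness
        and call_rate >= thresholds.min_call_rate
    )
    return SampleQcReport(
        sample_id=sample_id,
        lrr_sd=lrr_sd,
        baf_drift=baf_drift,
        waviness=waviness,
        call_rate=float(call_rate),
        passed=passed,
        low_confidence=n_usable < 100,
    )


def exact_hwe_p(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Exact conditional Hardy–Weinberg test p-value.

    Conditions on the observed allele counts and sums, over every
    heterozygote count with the right parity, the probability of outcomes no
    more probable than the observed one. A monomorphic locus returns 1.
    """
    n_aa, n_ab, n_bb = int(n_aa), int(n_ab), int(n_bb)
    if min(n_aa, n_ab, n_bb) < 0 or n_aa + n_ab + n_bb < 1:
        raise ValueError("genotype counts must be non-negative with at least one sample")
    n = n_aa + n_ab + n_bb
    n_b = n_ab + 2 * n_bb  # B-allele count
    if n_b == 0 or n_b == 2 * n:
        return 1.0

    het = np.arange(n_b % 2, min(n_b, 2 * n - n_b) + 1, 2)
    hom_b = (n_b - het) // 2
    hom_a = n - het - hom_b
    # log P(het | allele counts) up to a shared constant
    logp = het * np.log(2.0) - gammaln(hom_a + 1) - gammaln(het + 1) - gammaln(hom_b + 1)
    logp -= logp.max()
    prob = np.exp(logp)
    prob /= prob.sum()
    observed = prob[np.flatnonzero(het == n_ab)[0]]
    # tolerance absorbs float round-off in "no more probable than observed"
    return float(min(1.0, prob[prob <= observed * (1.0 + 1e-12)].sum()))


def _snp_counts(dosage_col: np.ndarray) -> tuple[int, int, int]:
    return (
        int((dosage_col == 0).sum()),
        int((dosage_col == 1).sum()),
        int((dosage_col == 2).sum()),
    )


def filter_snps(
    dosage: np.ndarray,
    marker_map: pd.DataFrame,
    breeds: np.ndarray | None = None,
    thresholds: SnpQcThresholds = SnpQcThresholds(),
) -> tuple[np.ndarray, list[SnpQcReport]]:
    """Apply the marker-level filters; order is preserved.

    ``dosage`` is (n_samples, n_snps) B-allele dosage with negative values
    meaning missing. With ``breeds`` given, the HWE exact test runs within
    each breed and the minimum p is used. Returns a boolean retained mask and
    per-SNP reports. Raises if nothing survives.
    """
    dosage = np.asarray(dosage)
    n_samples, n_snps = dosage.shape
    if len(marker_map) != n_snps:
        raise ValueError("marker map and dosage matrix are misaligned")
    chroms = marker_map["chrom"].astype(str).str.strip().to_numpy()
    pos = marker_map["pos"].to_numpy()
    breed_groups: list[np.ndarray]
    if breeds is None:
        breed_groups = [np.arange(n_samples)]
    else:
        breeds = np.asarray(breeds)
        breed_groups = [np.flatnonzero(breeds == b) for b in pd.unique(breeds)]

    missing = dosage < 0
    n_obs = (~missing).sum(axis=0)
    missing_rate = missing.sum(axis=0) / n_samples
    with np.errstate(invalid="ignore", divide="ignore"):
        freq_b = np.where(n_obs > 0, np.where(missing, 0, dosage).sum(axis=0) / (2 * np.maximum(n_obs, 1)), np.nan)
    maf = np.minimum(freq_b, 1.0 - freq_b)

    reports: list[SnpQcReport] = []
    retained = np.zeros(n_snps, dtype=bool)
    for j in range(n_snps):
        on_autosome = chroms[j].upper().removeprefix("CHR") not in NON_AUTOSOMES and not chroms[j].upper().removeprefix("CHR").startswith(("X", "Y"))
        has_position = bool(pos[j] > 0)
        hwe_p = 1.0
        for rows in breed_groups:
            col = dosage[rows, j]
            col = col[col >= 0]
            if col.size:
                hwe_p = min(hwe_p, exact_hwe_p(*_snp_counts(col)))
        ok = (
            missing_rate[j] <= thresholds.max_missing
            and np.isfinite(maf[j])
            and maf[j] >= thresholds.min_maf
            and hwe_p >= thresholds.min_hwe_p
            and on_autosome
            and has_position
        )
        retained[j] = ok
        reports.append(
            SnpQcReport(
                name=str(marker_map["name"].iloc[j]),
                missing_rate=float(missing_rate[j]),
                maf=float(maf[j]) if np.isfinite(maf[j]) else 0.0,
                hwe_p=float(hwe_p),
                on_autosome=on_autosome,
                has_position=has_position,
                passed=bool(ok),
            )
        )
    if not retained.any():
        raise ValueError("no SNPs survive quality control")
    return retained, reports


def filter_samples(reports: list[SampleQcReport]) -> list[str]:
    """IDs of samples passing all sample-level gates."""
    return [r.sample_id for r in reports if r.passed]
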