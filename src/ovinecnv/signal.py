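"""Allele-intensity signal transforms for Illumina-style SNP arrays.

Raw per-SNP intensities (X for the A allele, Y for the B allele) are turned
into the two tracks a copy-number HMM consumes:

* **theta** — the arctan-normalised allelic angle, ``arctan(Y/X) / (pi/2)``,
  in [0, 1]; 0 is pure A signal, 1 pure B.
* **BAF** (B-allele frequency) — theta rescaled piecewise-linearly against the
  three canonical genotype cluster angles (AA, AB, BB) so that the clusters
  land at 0, 0.5 and 1.
* **LRR** (log R ratio) — ``log2(R_observed / R_expected)`` where
  R = X + Y and R_expected comes from linear interpolation of the canonical
  cluster (theta, R) nodes. LRR shifts negative under deletion and positive
  under duplication.

Canonical clusters are estimated from reference samples (by default the
cohort itself) as per-genotype medians of theta and R; the per-SNP population
B-allele frequency (PFB) is the mean reference BAF.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CanonicalClusters",
    "SampleSignal",
    "compute_theta",
    "compute_baf",
    "inverse_baf",
    "expected_r",
    "compute_lrr",
    "estimate_clusters",
    "compile_pfb",
    "transform_sample",
]

#: LRR assigned when the observed intensity is exactly zero (log of zero).
DEFAULT_LRR_FLOOR = -5.0


@dataclass
class CanonicalClusters:
    """Per-SNP canonical genotype cluster parameters.

    Each field is an array over SNPs. ``usable`` is False where the theta
    ordering is violated or a segment has zero width, in which case BAF and
    expected R are undefined (returned as NaN).
    """

    theta_aa: np.ndarray
    theta_ab: np.ndarray
    theta_bb: np.ndarray
    r_aa: np.ndarray
    r_ab: np.ndarray
    r_bb: np.ndarray
    usable: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        for name in ("theta_aa", "theta_ab", "theta_bb", "r_aa", "r_ab", "r_bb"):
            setattr(self, name, np.atleast_1d(np.asarray(getattr(self, name), dtype=float)))
        if self.usable is None:
            self.usable = (
                (self.theta_aa < self.theta_ab)
                & (self.theta_ab < self.theta_bb)
                & np.isfinite(self.theta_aa)
                & np.isfinite(self.theta_ab)
                & np.isfinite(self.theta_bb)
            )
        else:
            self.usable = np.atleast_1d(np.asarray(self.usable, dtype=bool))

    def __len__(self) -> int:
        return self.theta_aa.shape[0]


@dataclass
class SampleSignal:
    """Aligned per-sample signal vectors over the marker map."""

    sample_id: str
    breed: str
    x: np.ndarray
    y: np.ndarray
    r: np.ndarray
    theta: np.ndarray
    baf: np.ndarray
    lrr: np.ndarray


def compute_theta(x, y):
    """Allelic angle theta = arctan(Y/X)/(pi/2) in [0, 1].

    X = 0 maps to 1 (pure B). Markers with X = Y = 0 carry no signal and are
    returned as NaN rather than raising.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.any(x < 0) or np.any(y < 0):
        raise ValueError("intensities must be non-negative")
    with np.errstate(invalid="ignore"):
        theta = np.arctan2(y, x) / (np.pi / 2.0)
    theta = np.where((x == 0) & (y == 0), np.nan, theta)
    return theta if theta.ndim else float(theta)


def compute_baf(theta, clusters: CanonicalClusters):
    """Piecewise-linear BAF from theta against canonical cluster angles.

    0 below theta_AA; linear to 0.5 at theta_AB; linear to 1 at theta_BB;
    1 above. Unusable SNPs (non-monotone or zero-width segments) give NaN.
    """
    theta = np.asarray(theta, dtype=float)
    t_aa, t_ab, t_bb = clusters.theta_aa, clusters.theta_ab, clusters.theta_bb
    with np.errstate(invalid="ignore", divide="ignore"):
        lower = 0.5 * (theta - t_aa) / (t_ab - t_aa)
        upper = 0.5 + 0.5 * (theta - t_ab) / (t_bb - t_ab)
        baf = np.where(theta < t_aa, 0.0, np.where(theta <= t_ab, lower, np.where(theta < t_bb, upper, 1.0)))
    baf = np.where(clusters.usable & np.isfinite(theta), baf, np.nan)
    baf = np.clip(baf, 0.0, 1.0)
    return baf if baf.ndim else float(baf)


def inverse_baf(baf, clusters: CanonicalClusters):
    """Theta whose compute_baf image is ``baf`` (used by the simulator).

    The inverse of the piecewise-linear map on its interior; BAF 0 and 1 map
    to the outer cluster angles.
    """
    baf = np.asarray(baf, dtype=float)
    t_aa, t_ab, t_bb = clusters.theta_aa, clusters.theta_ab, clusters.theta_bb
    lower = t_aa + (baf / 0.5) * (t_ab - t_aa)
    upper = t_ab + ((baf - 0.5) / 0.5) * (t_bb - t_ab)
    theta = np.where(baf <= 0.5, lower, upper)
    theta = np.where(clusters.usable, theta, np.nan)
    return theta if theta.ndim else float(theta)


def expected_r(theta, clusters: CanonicalClusters):
    """Expected total intensity by linear interpolation of cluster (theta, R).

    Constant (clamped) extrapolation outside [theta_AA, theta_BB].
    """
    theta = np.asarray(theta, dtype=float)
    t_aa, t_ab, t_bb = clusters.theta_aa, clusters.theta_ab, clusters.theta_bb
    r_aa, r_ab, r_bb = clusters.r_aa, clusters.r_ab, clusters.r_bb
    with np.errstate(invalid="ignore", divide="ignore"):
        lower = r_aa + (theta - t_aa) / (t_ab - t_aa) * (r_ab - r_aa)
        upper = r_ab + (theta - t_ab) / (t_bb - t_ab) * (r_bb - r_ab)
        r = np.where(theta <= t_aa, r_aa, np.where(theta <= t_ab, lower, np.where(theta < t_bb, upper, r_bb)))
    r = np.where(clusters.usable & np.isfinite(theta), r, np.nan)
    return r if r.ndim else float(r)


def compute_lrr(r_observed, r_expected, floor: float = DEFAULT_LRR_FLOOR):
    """LRR = log2(R_observed / R_expected).

    Zero observed intensity maps to ``floor``; non-positive expected
    intensity masks the marker (NaN).
    """
    r_obs = np.asarray(r_observed, dtype=float)
    r_exp = np.asarray(r_expected, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        lrr = np.log2(r_obs / r_exp)
    lrr = np.where(r_obs == 0, floor, lrr)
    lrr = np.where((r_exp > 0) & np.isfinite(r_exp) & np.isfinite(r_obs), lrr, np.nan)
    return lrr if lrr.ndim else float(lrr)


def estimate_clusters(
    theta: np.ndarray,
    r: np.ndarray,
    dosage: np.ndarray,
    fallback: str = "mirror",
) -> CanonicalClusters:
    """Canonical clusters as per-genotype medians over reference samples.

    Parameters
    ----------
    theta, r
        (n_samples, n_snps) matrices of allelic angle and total intensity.
    dosage
        (n_samples, n_snps) B-allele dosage in {0, 1, 2}; negative = missing.
    fallback
        "mirror": impute an empty outer class by reflecting around theta_AB
        (theta_BB = 2*theta_AB - theta_AA clamped to <= 1, and symmetrically),
        with the opposite class's R. "drop": flag the SNP unusable instead.

    Medians are robust to the occasional CNV-carrying reference sample.
    """
    if fallback not in ("mirror", "drop"):
        raise ValueError("fallback must be 'mirror' or 'drop'")
    theta = np.asarray(theta, dtype=float)
    r = np.asarray(r, dtype=float)
    dosage = np.asarray(dosage)
    n_snps = theta.shape[1]
    t = np.full((3, n_snps), np.nan)
    rr = np.full((3, n_snps), np.nan)
    for g in (0, 1, 2):
        mask = dosage == g
        tg = np.where(mask, theta, np.nan)
        rg = np.where(mask, r, np.nan)
        any_obs = np.any(mask & np.isfinite(theta), axis=0)
        with np.errstate(all="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            t[g] = np.where(any_obs, np.nanmedian(tg, axis=0), np.nan)
            rr[g] = np.where(any_obs, np.nanmedian(rg, axis=0), np.nan)

    if fallback == "mirror":
        # outer classes from reflection; AB from the midpoint of the outers
        have = np.isfinite(t)
        miss_bb = ~have[2] & have[0] & have[1]
        t[2, miss_bb] = np.minimum(2 * t[1, miss_bb] - t[0, miss_bb], 1.0)
        rr[2, miss_bb] = rr[0, miss_bb]
        miss_aa = ~have[0] & have[2] & have[1]
        t[0, miss_aa] = np.maximum(2 * t[1, miss_aa] - t[2, miss_aa], 0.0)
        rr[0, miss_aa] = rr[2, miss_aa]
        miss_ab = ~have[1] & have[0] & have[2]
        t[1, miss_ab] = 0.5 * (t[0, miss_ab] + t[2, miss_ab])
        rr[1, miss_ab] = 0.5 * (rr[0, miss_ab] + rr[2, miss_ab])

    usable = np.isfinite(t).all(axis=0) & (t[0] < t[1]) & (t[1] < t[2])
    return CanonicalClusters(t[0], t[1], t[2], rr[0], rr[1], rr[2], usable)


def compile_pfb(baf_matrix: np.ndarray, clip: tuple[float, float] = (0.01, 0.99)):
    """Population B-allele frequency per SNP: mean reference BAF, clipped.

    Clipping to [0.01, 0.99] keeps the HMM's binomial BAF-mixture weights
    away from degenerate point masses. SNPs with no non-missing BAF get 0.5
    and are flagged in the returned mask.
    """
    baf = np.asarray(baf_matrix, dtype=float)
    n_obs = np.isfinite(baf).sum(axis=0)
    with np.errstate(all="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        pfb = np.nanmean(baf, axis=0)
    flagged = n_obs == 0
    pfb = np.where(flagged, 0.5, pfb)
    pfb = np.clip(pfb, clip[0], clip[1])
    return pfb, flagged


def transform_sample(
    sample_id: str,
    breed: str,
    x: np.ndarray,
    y: np.ndarray,
    clusters: CanonicalClusters,
    lrr_floor: float = DEFAULT_LRR_FLOOR,
) -> SampleSignal:
    """Full X/Y -> (R, theta, BAF, LRR) transform for one sample."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    r = x + y
    theta = compute_theta(x, y)
    baf = compute_baf(theta, clusters)
    r_exp = expected_r(theta, clusters)
    lrr = compute_lrr(r, r_exp, floor=lrr_floor)
    return SampleSignal(sample_id, breed, x, y, r, theta, baf, lrr)


def signal_frame(sig: SampleSignal, marker_map: pd.DataFrame) -> pd.DataFrame:
    """Tabular (Name, Chr, Position, BAF, LRR) view of one sample's signal."""
    return pd.DataFrame(
        {
            "Name": marker_map["name"].to_numpy(),
            "Chr": marker_map["chrom"].to_numpy(),
            "Position": marker_map["pos"].to_numpy(),
            "B Allele Freq": sig.baf,
            "Log R Ratio": sig.lrr,
        }
    )
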