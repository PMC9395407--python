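"""Synthetic multi-breed SNP-array cohort generator.

Real ovine genotype-intensity cohorts are rarely shareable, so every
downstream stage here (signal transforms, QC, HMM calling, CNV-region
construction, F_ST scans) is exercised on a fully specified synthetic cohort:

* a marker map of autosomal SNPs with strictly increasing positions,
* per-breed allele frequencies drawn from the Balding–Nichols model —
  Beta with mean p and variance F·p·(1−p) — so population differentiation
  has a known F_ST truth,
* Hardy–Weinberg genotypes within each breed (independent loci),
* an implanted truth set of deletion/duplication segments (Poisson event
  counts per individual, log-uniform lengths, no within-sample overlap),
* X/Y allele intensities whose noise-free expectations invert the signal
  model: BAF = k/c for B-dosage k under copy number c, and LRR equal to the
  calling HMM's state mean for c.

Defaults mirror the study design this generator stands in for: 3 breeds x
15 animals genotyped on a ~50k ovine array (26 autosomes), F_ST ≈ 0.10,
about 9 CNV events per animal with lengths between 20 kb and 2 Mb. Tests
run a reduced 2-chromosome configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import hmm as _hmm
from . import signal as _signal

__all__ = [
    "SimConfig",
    "TruthCnv",
    "Cohort",
    "draw_allele_frequencies",
    "implant_cnvs",
    "synthesize_intensities",
    "simulate_cohort",
    "write_cohort",
]

DEFAULT_BREED_NAMES = ("Arab", "Baluchi", "Gadik")

#: True canonical cluster geometry used when synthesizing intensities.
TRUE_THETA = (0.05, 0.50, 0.95)
TRUE_R = (2.0, 2.1, 2.0)


@dataclass(frozen=True)
class SimConfig:
    """Stated-world parameters of the synthetic cohort.

    ``cnvs_per_individual_mean`` defaults to the observed per-animal event
    burden (9.13); ``p_deletion`` to the observed loss fraction among CNV
    regions (~0.33). Noise SDs default to values that pass the per-sample
    signal QC gates (LRR SD < 0.3).
    """

    n_breeds: int = 3
    n_per_breed: int = 15
    n_chromosomes: int = 26
    snps_per_chromosome: int = 2000
    chrom_length_bp: int = 96_000_000
    fst_target: float = 0.10
    cnvs_per_individual_mean: float = 9.13
    cnv_length_range_bp: tuple[int, int] = (20_000, 2_000_000)
    p_deletion: float = 0.33
    lrr_noise_sd: float = 0.2
    baf_noise_sd: float = 0.04
    seed: int = 7

    def __post_init__(self) -> None:
        for name in ("n_breeds", "n_per_breed", "n_chromosomes", "snps_per_chromosome"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0.0 <= self.fst_target < 1.0:
            raise ValueError("fst_target must be in [0, 1)")
        if not 0.0 < self.p_deletion < 1.0:
            raise ValueError("p_deletion must be in (0, 1)")
        lo, hi = self.cnv_length_range_bp
        if not 0 < lo < hi:
            raise ValueError("cnv_length_range_bp must satisfy 0 < min < max")
        if hi > self.chrom_length_bp:
            raise ValueError("maximum CNV length exceeds chromosome length")
        if self.cnvs_per_individual_mean < 0:
            raise ValueError("cnvs_per_individual_mean must be >= 0")
        if self.lrr_noise_sd < 0 or self.baf_noise_sd < 0:
            raise ValueError("noise SDs must be >= 0")


@dataclass(frozen=True)
class TruthCnv:
    """One implanted copy-number event (1-based inclusive)."""

    sample_id: str
    chromosome: str
    start_bp: int
    end_bp: int
    copy_number: int

    def __post_init__(self) -> None:
        if self.start_bp > self.end_bp:
            raise ValueError("start_bp must be <= end_bp")
        if self.copy_number not in (0, 1, 3, 4):
            raise ValueError("truth events carry copy number in {0, 1, 3, 4}")

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp + 1


@dataclass
class Cohort:
    """In-memory synthetic cohort: map, labels, truth and signal matrices."""

    config: SimConfig
    marker_map: pd.DataFrame  # name, chrom, pos (sorted)
    samples: pd.DataFrame  # sample_id, breed
    ancestral_freq: np.ndarray  # (n_snps,)
    breed_freqs: np.ndarray  # (n_breeds, n_snps)
    dosage: np.ndarray  # (n_samples, n_snps) diploid B-allele dosage
    truth: list[TruthCnv] = field(default_factory=list)
    x: np.ndarray | None = None  # (n_samples, n_snps)
    y: np.ndarray | None = None
    clusters: _signal.CanonicalClusters | None = None

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_snps(self) -> int:
        return len(self.marker_map)


def draw_allele_frequencies(ancestral_freq, fst_target: float, n_breeds: int, rng) -> np.ndarray:
    """Per-breed frequencies under the Balding–Nichols model.

    Draws from Beta(p(1-F)/F, (1-p)(1-F)/F), whose mean is the ancestral
    frequency p and whose variance is F·p·(1-p). F = 0 returns p unchanged
    for every breed. ``ancestral_freq`` may be scalar or a vector of loci;
    the result has shape (n_breeds,) + p.shape.
    """
    p = np.asarray(ancestral_freq, dtype=float)
    if np.any(p <= 0.0) or np.any(p >= 1.0):
        raise ValueError("ancestral frequency must lie strictly in (0, 1)")
    if not 0.0 <= fst_target < 1.0:
        raise ValueError("fst_target must be in [0, 1)")
    if n_breeds < 1:
        raise ValueError("n_breeds must be >= 1")
    shape = (n_breeds,) + p.shape
    if fst_target == 0.0:
        return np.broadcast_to(p, shape).copy()
    scale = (1.0 - fst_target) / fst_target
    a = p * scale
    b = (1.0 - p) * scale
    return rng.beta(np.broadcast_to(a, shape), np.broadcast_to(b, shape))


def _make_marker_map(config: SimConfig, rng) -> pd.DataFrame:
    frames = []
    for c in range(1, config.n_chromosomes + 1):
        n = config.snps_per_chromosome
        pos = np.array([], dtype=np.int64)
        while pos.size < n:  # top up until n distinct positions
            extra = rng.integers(1, config.chrom_length_bp + 1, size=n - pos.size + 16)
            pos = np.unique(np.concatenate([pos, extra]))
        pos = np.sort(rng.choice(pos, size=n, replace=False))
        frames.append(
            pd.DataFrame(
                {
                    "name": [f"snp_{c}_{i + 1}" for i in range(n)],
                    "chrom": str(c),
                    "pos": pos,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def implant_cnvs(config: SimConfig, marker_map: pd.DataFrame, rng, sample_ids=None) -> list[TruthCnv]:
    """Draw the implanted truth set of deletion/duplication segments.

    Per sample the event count is Poisson(cnvs_per_individual_mean); lengths
    are log-uniform over the configured range; events are clipped to
    chromosome bounds, must span at least one marker, and never overlap
    within one sample (colliding draws are resampled).
    """
    if sample_ids is None:
        sample_ids = _sample_ids(config)
    chroms = sorted(marker_map["chrom"].unique(), key=lambda s: (len(s), s))
    pos_by_chrom = {c: marker_map.loc[marker_map["chrom"] == c, "pos"].to_numpy() for c in chroms}
    lo, hi = config.cnv_length_range_bp
    truth: list[TruthCnv] = []
    for sid in sample_ids:
        n_events = rng.poisson(config.cnvs_per_individual_mean)
        placed: dict[str, list[tuple[int, int]]] = {}
        for _ in range(n_events):
            for _attempt in range(1000):
                chrom = chroms[rng.integers(len(chroms))]
                length = int(np.exp(rng.uniform(np.log(lo), np.log(hi))))
                length = min(length, config.chrom_length_bp)
                start = int(rng.integers(1, config.chrom_length_bp - length + 2))
                end = start + length - 1
                pos = pos_by_chrom[chrom]
                n_markers = int(np.searchsorted(pos, end, side="right") - np.searchsorted(pos, start, side="left"))
                if n_markers < 1:
                    continue
                if any(s <= end and start <= e for s, e in placed.get(chrom, [])):
                    continue
                if rng.random() < config.p_deletion:
                    cn = 1 if rng.random() < 0.85 else 0
                else:
                    cn = 3 if rng.random() < 0.85 else 4
                placed.setdefault(chrom, []).append((start, end))
                truth.append(TruthCnv(sid, chrom, start, end, cn))
                break
            else:
                raise RuntimeError("could not place a CNV without overlap; config too dense")
    return truth


def _sample_ids(config: SimConfig) -> list[str]:
    breeds = _breed_names(config)
    return [f"{b}_{i + 1:02d}" for b in breeds for i in range(config.n_per_breed)]


def _breed_names(config: SimConfig) -> list[str]:
    if config.n_breeds <= len(DEFAULT_BREED_NAMES):
        return list(DEFAULT_BREED_NAMES[: config.n_breeds])
    return [f"breed{i + 1}" for i in range(config.n_breeds)]


def _true_clusters(n_snps: int) -> _signal.CanonicalClusters:
    ones = np.ones(n_snps)
    return _signal.CanonicalClusters(
        theta_aa=TRUE_THETA[0] * ones,
        theta_ab=TRUE_THETA[1] * ones,
        theta_bb=TRUE_THETA[2] * ones,
        r_aa=TRUE_R[0] * ones,
        r_ab=TRUE_R[1] * ones,
        r_bb=TRUE_R[2] * ones,
    )


def synthesize_intensities(
    dosage: np.ndarray,
    truth: list[TruthCnv],
    marker_map: pd.DataFrame,
    config: SimConfig,
    rng,
    sample_ids=None,
    breed_freq_per_sample: np.ndarray | None = None,
    hmm_params: _hmm.HmmParams = _hmm.DEFAULT_PARAMS,
) -> tuple[np.ndarray, np.ndarray]:
    """X/Y intensity matrices consistent with genotypes and implanted CNVs.

    For copy number c >= 1 with B-allele dosage k the noise-free BAF is k/c
    and the noise-free LRR is the calling HMM's state mean for c (0 for
    c = 2); homozygous deletions emit uniform BAF (no alleles, no genotype
    signal). Gaussian noise with the configured SDs is added in BAF/LRR
    space, then inverted through the canonical-cluster geometry to X, Y >= 0.
    Inside a CNV the B-dosage among the c copies is redrawn as
    Binomial(c, breed frequency).
    """
    dosage = np.asarray(dosage)
    n_samples, n_snps = dosage.shape
    if sample_ids is None:
        sample_ids = _sample_ids(config)
    sid_index = {s: i for i, s in enumerate(sample_ids)}
    chrom = marker_map["chrom"].to_numpy()
    pos = marker_map["pos"].to_numpy()

    cn = np.full((n_samples, n_snps), 2, dtype=np.int8)
    for ev in truth:
        rows = np.flatnonzero((chrom == ev.chromosome) & (pos >= ev.start_bp) & (pos <= ev.end_bp))
        cn[sid_index[ev.sample_id], rows] = ev.copy_number

    if breed_freq_per_sample is None:
        with np.errstate(invalid="ignore"):
            freq = np.clip(dosage.mean(axis=0) / 2.0, 0.01, 0.99)
        breed_freq_per_sample = np.broadcast_to(freq, (n_samples, n_snps))

    k = dosage.astype(np.int16).copy()
    off_diploid = cn != 2
    if off_diploid.any():
        k[off_diploid] = rng.binomial(cn[off_diploid].astype(np.int64), breed_freq_per_sample[off_diploid])

    lrr_mean_by_cn = {c: hmm_params.lrr_mean[_hmm.STATE_COPY_NUMBER.index(c)] for c in (0, 1, 2, 3, 4)}
    mean_lrr = np.vectorize(lrr_mean_by_cn.get)(cn).astype(float)
    lrr = mean_lrr + rng.normal(0.0, config.lrr_noise_sd, size=cn.shape)

    with np.errstate(invalid="ignore", divide="ignore"):
        baf_clean = np.where(cn > 0, k / np.maximum(cn, 1), 0.0)
    baf = baf_clean + rng.normal(0.0, config.baf_noise_sd, size=cn.shape)
    baf[cn == 0] = rng.uniform(0.0, 1.0, size=int((cn == 0).sum()))
    baf = np.clip(baf, 0.0, 1.0)

    clusters = _true_clusters(n_snps)
    theta = _signal.inverse_baf(baf, clusters)
    r = _signal.expected_r(theta, clusters) * np.exp2(lrr)
    t = np.tan(theta * np.pi / 2.0)
    x = r / (1.0 + t)
    y = r - x
    return np.maximum(x, 0.0), np.maximum(y, 0.0)


def simulate_cohort(config: SimConfig) -> Cohort:
    """Generate the full cohort: map, frequencies, genotypes, truth, signals.

    Deterministic given ``config.seed``: the same config reproduces every
    array and file byte-for-byte.
    """
    rng = np.random.default_rng(config.seed)
    marker_map = _make_marker_map(config, rng)
    n_snps = len(marker_map)
    ancestral = rng.uniform(0.05, 0.95, size=n_snps)
    breed_freqs = draw_allele_frequencies(ancestral, config.fst_target, config.n_breeds, rng)

    breeds = _breed_names(config)
    sample_ids = _sample_ids(config)
    samples = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "breed": [b for b in breeds for _ in range(config.n_per_breed)],
        }
    )
    breed_idx = np.repeat(np.arange(config.n_breeds), config.n_per_breed)
    dosage = rng.binomial(2, breed_freqs[breed_idx]).astype(np.int8)

    truth = implant_cnvs(config, marker_map, rng, sample_ids)
    x, y = synthesize_intensities(
        dosage,
        truth,
        marker_map,
        config,
        rng,
        sample_ids=sample_ids,
        breed_freq_per_sample=breed_freqs[breed_idx],
    )
    return Cohort(
        config=config,
        marker_map=marker_map,
        samples=samples,
        ancestral_freq=ancestral,
        breed_freqs=breed_freqs,
        dosage=dosage,
        truth=truth,
        x=x,
        y=y,
        clusters=_true_clusters(n_snps),
    )


def write_cohort(cohort: Cohort, out_dir) -> dict[str, object]:
    """Write the cohort in interoperable text formats.

    Per-sample PennCNV-style signal files (Name, Chr, Position, X, Y,
    B Allele Freq, Log R Ratio), a PFB file, PLINK PED/MAP with the breed as
    family ID, and the truth-set TSV. All positions 1-based inclusive.
    Returns a manifest of written paths.
    """
    from . import io as _io

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    clusters = cohort.clusters or _true_clusters(cohort.n_snps)

    signal_dir = out / "signals"
    signal_dir.mkdir(exist_ok=True)
    signal_paths = []
    for i, row in cohort.samples.iterrows():
        sig = _signal.transform_sample(row.sample_id, row.breed, cohort.x[i], cohort.y[i], clusters)
        p = signal_dir / f"{row.sample_id}.signal.tsv"
        _io.write_signal_file(p, cohort.marker_map, cohort.x[i], cohort.y[i], sig.baf, sig.lrr)
        signal_paths.append(p)

    pfb = np.clip(cohort.breed_freqs.mean(axis=0), 0.01, 0.99)
    pfb_path = out / "cohort.pfb"
    _io.write_pfb(pfb_path, cohort.marker_map, pfb)

    ped_path, map_path = out / "cohort.ped", out / "cohort.map"
    _io.write_plink(ped_path, map_path, cohort.marker_map, cohort.samples, cohort.dosage)

    truth_path = out / "truth_cnvs.tsv"
    pd.DataFrame(
        [
            {
                "sample_id": t.sample_id,
                "chrom": t.chromosome,
                "start": t.start_bp,
                "end": t.end_bp,
                "copy_number": t.copy_number,
            }
            for t in cohort.truth
        ],
        columns=["sample_id", "chrom", "start", "end", "copy_number"],
    ).to_csv(truth_path, sep="\t", index=False)

    return {
        "signals": signal_paths,
        "pfb": pfb_path,
        "ped": ped_path,
        "map": map_path,
        "truth": truth_path,
    }
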