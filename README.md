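# ovinecnv

Genome-wide copy-number-variation (CNV) analysis for multi-breed sheep
SNP-array cohorts, as a tested, reusable Python library.

Livestock CNV studies on ~50k genotyping arrays follow a common workflow:
transform raw allele intensities into B-allele frequency (BAF) and log R
ratio (LRR) tracks, call per-animal CNVs with a hidden Markov model, merge
calls across animals into CNV regions (CNVRs), summarise them, scan the
same genotypes for selection signatures with windowed Weir–Cockerham
F<sub>ST</sub>, and intersect the CNVRs with genes, QTLs, selection peaks and
external CNVR sets. `ovinecnv` implements every step of that workflow plus a
fully specified synthetic-cohort generator, so the whole analysis is testable
end to end without access to any proprietary genotype data.

## The model in brief

**Signal transforms.** For allele intensities X (A allele) and Y (B allele),
R = X + Y and

- θ = arctan(Y/X) / (π/2) ∈ [0, 1],
- BAF is θ rescaled piecewise-linearly against the canonical genotype
  cluster angles θ_AA ≤ θ_AB ≤ θ_BB so the clusters land at 0, 0.5, 1,
- LRR = log₂(R_observed / R_expected), with R_expected linearly
  interpolated from the cluster (θ, R) nodes.

**CNV calling.** A six-state HMM over {CN0, CN1, CN2, CN2-LOH, CN3, CN4}
with distance-dependent transitions
A_ij(d) = e^(−d/D)·[i=j] + (1 − e^(−d/D))·π_j and emissions combining a
Gaussian on LRR with a Binomial(c, PFB)-weighted mixture of BAF clusters at
k/c. Exact Viterbi decoding; runs of ≥ 3 markers in a non-diploid state
become calls (copy-neutral LOH is recorded but never counted as a CNV).

**CNVRs.** Transitive merging of calls that share ≥ 1 base, classified
Loss / Gain / Both, with descriptive statistics (mean/median length,
size classes, per-breed Venn sharing).

**Selection scan.** Per-SNP Weir–Cockerham θ̂ = a/(a+b+c) from the 1984
variance components, averaged over consecutive 5-SNP windows; windows in
the top 1% empirical tail are selection-signature candidates and are
intersected with the CNVRs.

**Synthetic cohorts.** Balding–Nichols per-breed allele frequencies
(Beta with mean p, variance F·p(1−p)) give a known F<sub>ST</sub> truth;
implanted deletion/duplication segments perturb LRR and BAF exactly as the
calling model expects, so recovery is measurable against a truth set.

## Worked example

```python
import ovinecnv as oc

manifest = oc.run_all(oc.pipeline.desk_scale_config(seed=7), "scratch/run")
print(manifest.counts)
```

prints (abridged):

```
samples=30 snps=5000 truth_events=59
samples_pass_qc=19 snps_retained=4779
cnv_calls=21 cnvrs=21 by_status={'Loss': 4, 'Gain': 17, 'Both': 0}
fst Arab_vs_Baluchi: windows=957 flagged=10 theta=0.1015
cnvrs_under_selection=2
```

Reading the numbers: 30 simulated animals from two breeds were genotyped at
5,000 SNPs and 59 CNV events were implanted; 19 animals pass the signal QC
gates (LRR SD < 0.3, BAF drift < 0.01, waviness < 0.05, call rate ≥ 0.90)
and 4,779 SNPs pass the marker filters (missingness ≤ 5%, MAF ≥ 0.02,
exact-HWE p ≥ 10⁻⁶, autosomal position). The HMM makes 21 calls on the
passing animals, which merge into 21 regions, mostly duplications. The
F<sub>ST</sub> scan's ratio-of-sums θ (0.1015) recovers the simulated
differentiation target F = 0.10, ten 5-SNP windows fall in the top-1% tail,
and two CNV regions sit under those selection peaks.

The `examples/` directory contains one short narrative script per
capability (simulation, signal transforms, calling, region construction,
the F<sub>ST</sub> scan, interval annotation, and the full pipeline); each
builds a small input, runs the method and explains what it prints.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the full analysis from scratch at the reduced desk scale —
simulating the cohort for the given seed, running signal transforms, QC,
HMM calling, CNVR construction, the F<sub>ST</sub> scan and the
selection-overlap annotation — prints the stage-by-stage record counts, and
writes the target report to `--out`.

## Layout

- `src/ovinecnv/simulate.py` — synthetic cohort generator (stated defaults
  mirror a 3-breed × 15-animal, 26-autosome, ~50k-SNP design)
- `src/ovinecnv/signal.py` — θ/BAF/LRR transforms, cluster estimation, PFB
- `src/ovinecnv/qc.py` — sample/marker filters, exact Hardy–Weinberg test
- `src/ovinecnv/hmm.py` — six-state HMM, Viterbi, call segmentation
- `src/ovinecnv/cnvr.py` — region merging, classification, summaries, Venn
- `src/ovinecnv/fst.py` — Weir–Cockerham components, windowed scan, outliers
- `src/ovinecnv/annotate.py` — interval intersection, gap distances,
  cross-dataset comparison
- `src/ovinecnv/pipeline.py` — one-config orchestration with a run manifest
- `docs/methods.md` — the methods note (model details, defaults, limits)
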