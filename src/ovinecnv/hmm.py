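"""Six-state copy-number HMM over BAF/LRR tracks.

States are CN0 (homozygous deletion), CN1 (hemizygous deletion), CN2
(normal diploid), CN2-LOH (copy-neutral loss of heterozygosity), CN3
(single-copy duplication) and CN4 (double duplication). Emissions combine a
Gaussian on LRR (state-specific mean/SD) with a binomial mixture of BAF
clusters at k/c for B-allele dosage k under copy number c, weighted by the
per-SNP population B-allele frequency (PFB). Transitions decay toward the
stationary distribution with inter-marker distance:

    A_ij(d) = exp(-d/D) * [i == j] + (1 - exp(-d/D)) * pi_j

Decoding is exact Viterbi in log space; maximal runs of a single non-normal
state with at least ``min_snps_per_call`` supporting markers become CNV
calls. CN2-LOH runs are copy-neutral and are reported separately, never as
CNVs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from ._util import normalize_chrom

__all__ = [
    "STATES",
    "STATE_COPY_NUMBER",
    "HmmParams",
    "CnvCall",
    "transition_matrix",
    "emission_loglik",
    "viterbi",
    "path_to_calls",
    "call_chromosome",
    "merge_adjacent_calls",
]

STATES: tuple[str, ...] = ("CN0", "CN1", "CN2", "CN2-LOH", "CN3", "CN4")
STATE_COPY_NUMBER: tuple[int, ...] = (0, 1, 2, 2, 3, 4)
_CN2 = STATES.index("CN2")
_LOH = STATES.index("CN2-LOH")
_TINY = 1e-300


@dataclass(frozen=True)
class HmmParams:
    """Fixed HMM parameters (no re-estimation is performed).

    Defaults follow the published SNP-array CNV HMM family: LRR means of
    roughly -3.5 / -0.66 / 0 / +0.40 / +0.68 for copy numbers 0/1/2/3/4, a
    tight diploid LRR SD, BAF cluster SD 0.04, a heavily diploid-weighted
    stationary vector, and a 100 kb transition decay distance.
    """

    lrr_mean: tuple[float, ...] = (-3.5, -0.66, 0.0, 0.0, 0.40, 0.68)
    lrr_sd: tuple[float, ...] = (1.3, 0.28, 0.16, 0.16, 0.21, 0.24)
    baf_sd: float = 0.04
    pi: tuple[float, ...] = (1e-4, 5e-4, 0.9983, 5e-4, 5e-4, 1e-4)
    decay_bp: float = 100_000.0
    min_snps_per_call: int = 3

    def __post_init__(self) -> None:
        if len(self.lrr_mean) != 6 or len(self.lrr_sd) != 6 or len(self.pi) != 6:
            raise ValueError("HmmParams vectors must have one entry per state")
        if not np.isclose(sum(self.pi), 1.0):
            raise ValueError("stationary distribution must sum to 1")
        if any(p <= 0 for p in self.pi) or any(s <= 0 for s in self.lrr_sd):
            raise ValueError("pi and lrr_sd entries must be positive")
        if self.decay_bp <= 0:
            raise ValueError("decay distance must be positive")
        cn_order = [self.lrr_mean[STATES.index(s)] for s in ("CN0", "CN1", "CN2", "CN3", "CN4")]
        if not all(a < b for a, b in zip(cn_order, cn_order[1:])):
            raise ValueError("lrr_mean must be increasing in copy number")


DEFAULT_PARAMS = HmmParams()


@dataclass
class CnvCall:
    """One called copy-number event (1-based inclusive SNP-span coordinates)."""

    sample_id: str
    chromosome: str
    start_bp: int
    end_bp: int
    state: str
    copy_number: int
    n_snps: int
    confidence: float

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp + 1


def transition_matrix(d: float, params: HmmParams = DEFAULT_PARAMS) -> np.ndarray:
    """Distance-dependent transition matrix; rows sum to one."""
    if d < 0:
        raise ValueError("inter-marker distance must be non-negative")
    e = np.exp(-d / params.decay_bp)
    pi = np.asarray(params.pi, dtype=float)
    return e * np.eye(len(STATES)) + (1.0 - e) * pi[None, :]


def _baf_mixture_loglik(baf: np.ndarray, pfb: np.ndarray, params: HmmParams) -> np.ndarray:
    """Log-density of BAF per state, (n_states, n_markers).

    Each copy-number-c state mixes truncated-Gaussian clusters at k/c
    (k = 0..c) with Binomial(c, pfb) weights; probability mass that falls
    outside [0, 1] is assigned to the clipped boundary values, so BAF exactly
    0 or 1 is scored with the boundary point mass. CN0 has no alleles and
    emits Uniform(0, 1); CN2-LOH keeps only the homozygous k in {0, 2}
    components, renormalised.
    """
    n = baf.shape[0]
    sd = params.baf_sd
    out = np.zeros((len(STATES), n))
    valid = np.isfinite(baf)
    b = np.where(valid, baf, 0.5)
    at0 = valid & (b <= 0.0)
    at1 = valid & (b >= 1.0)
    interior = valid & ~at0 & ~at1

    for s, state in enumerate(STATES):
        c = STATE_COPY_NUMBER[s]
        if state == "CN0":
            # no genotype signal: uniform density 1 -> log 0
            continue
        ks = np.arange(c + 1)
        w = stats.binom.pmf(ks[:, None], c, pfb[None, :])  # (c+1, n)
        if state == "CN2-LOH":
            keep = np.array([True, False, True])
            w = np.where(keep[:, None], w, 0.0)
            w = w / w.sum(axis=0, keepdims=True)
        means = ks[:, None] / c  # (c+1, 1)
        pdf = stats.norm.pdf(b[None, :], loc=means, scale=sd)
        mass0 = stats.norm.cdf(0.0, loc=means, scale=sd)
        mass1 = stats.norm.sf(1.0, loc=means, scale=sd)
        comp = np.where(at0[None, :], mass0, np.where(at1[None, :], mass1, pdf))
        dens = (w * comp).sum(axis=0)
        out[s] = np.where(valid, np.log(np.maximum(dens, _TINY)), 0.0)
    return out


def emission_loglik(
    lrr: np.ndarray,
    baf: np.ndarray,
    pfb: np.ndarray,
    params: HmmParams = DEFAULT_PARAMS,
) -> np.ndarray:
    """Per-marker emission log-likelihood, shape (n_states, n_markers).

    Missing (NaN) LRR or BAF contributes zero from that term, so a marker
    with both missing is uninformative rather than fatal.
    """
    lrr = np.atleast_1d(np.asarray(lrr, dtype=float))
    baf = np.atleast_1d(np.asarray(baf, dtype=float))
    pfb = np.atleast_1d(np.asarray(pfb, dtype=float))
    mean = np.asarray(params.lrr_mean)[:, None]
    sd = np.asarray(params.lrr_sd)[:, None]
    valid_lrr = np.isfinite(lrr)
    l = np.where(valid_lrr, lrr, 0.0)
    lrr_term = stats.norm.logpdf(l[None, :], loc=mean, scale=sd)
    lrr_term = np.where(valid_lrr[None, :], lrr_term, 0.0)
    return lrr_term + _baf_mixture_loglik(baf, pfb, params)


def viterbi(
    positions: np.ndarray,
    lrr: np.ndarray,
    baf: np.ndarray,
    pfb: np.ndarray,
    params: HmmParams = DEFAULT_PARAMS,
    emissions: np.ndarray | None = None,
) -> np.ndarray:
    """Maximum-likelihood state path over one chromosome's markers.

    Markers must be position-sorted. Ties are broken toward the lower state
    index, deterministically. Returns an int array of state indices.
    """
    positions = np.asarray(positions, dtype=float)
    n = positions.shape[0]
    if n == 0:
        return np.zeros(0, dtype=int)
    if np.any(np.diff(positions) < 0):
        raise ValueError("markers must be sorted by position")
    em = emission_loglik(lrr, baf, pfb, params) if emissions is None else emissions
    log_pi = np.log(np.asarray(params.pi))
    d = np.diff(positions)
    decay = np.exp(-d / params.decay_bp)  # (n-1,)
    pi = np.asarray(params.pi)
    eye = np.eye(len(STATES))
    # all transition matrices at once: (n-1, 6, 6)
    trans = decay[:, None, None] * eye[None, :, :] + (1 - decay)[:, None, None] * pi[None, None, :]
    log_trans = np.log(trans)

    delta = log_pi + em[:, 0]
    psi = np.zeros((n, len(STATES)), dtype=int)
    for t in range(1, n):
        scores = delta[:, None] + log_trans[t - 1]  # (from, to)
        psi[t] = np.argmax(scores, axis=0)  # first max -> lowest index on ties
        delta = scores[psi[t], np.arange(len(STATES))] + em[:, t]
    path = np.zeros(n, dtype=int)
    path[-1] = int(np.argmax(delta))
    for t in range(n - 1, 0, -1):
        path[t - 1] = psi[t, path[t]]
    return path


def path_to_calls(
    path: np.ndarray,
    positions: np.ndarray,
    params: HmmParams = DEFAULT_PARAMS,
    sample_id: str = "",
    chromosome: str = "",
    emissions: np.ndarray | None = None,
) -> tuple[list[CnvCall], list[CnvCall]]:
    """Segment a decoded path into CNV calls and copy-neutral LOH runs.

    Maximal runs of one non-CN2, non-LOH state with at least
    ``min_snps_per_call`` markers become calls spanning the first to last
    supporting SNP. Confidence is the summed per-marker emission
    log-likelihood advantage of the called state over CN2 (NaN when
    emissions are not supplied). Returns ``(cnv_calls, loh_runs)``.
    """
    path = np.asarray(path, dtype=int)
    positions = np.asarray(positions)
    chromosome = normalize_chrom(chromosome)
    calls: list[CnvCall] = []
    loh: list[CnvCall] = []
    n = path.shape[0]
    i = 0
    while i < n:
        j = i
        while j + 1 < n and path[j + 1] == path[i]:
            j += 1
        s = int(path[i])
        run_len = j - i + 1
        if s != _CN2 and run_len >= params.min_snps_per_call:
            conf = float(np.sum(emissions[s, i : j + 1] - emissions[_CN2, i : j + 1])) if emissions is not None else float("nan")
            call = CnvCall(
                sample_id=sample_id,
                chromosome=chromosome,
                start_bp=int(positions[i]),
                end_bp=int(positions[j]),
                state=STATES[s],
                copy_number=STATE_COPY_NUMBER[s],
                n_snps=run_len,
                confidence=conf,
            )
            (loh if s == _LOH else calls).append(call)
        i = j + 1
    return calls, loh


def call_chromosome(
    positions: np.ndarray,
    lrr: np.ndarray,
    baf: np.ndarray,
    pfb: np.ndarray,
    params: HmmParams = DEFAULT_PARAMS,
    sample_id: str = "",
    chromosome: str = "",
) -> tuple[list[CnvCall], list[CnvCall]]:
    """Viterbi-decode one chromosome and segment the path into calls."""
    em = emission_loglik(lrr, baf, pfb, params)
    path = viterbi(positions, lrr, baf, pfb, params, emissions=em)
    return path_to_calls(path, positions, params, sample_id, chromosome, emissions=em)


def merge_adjacent_calls(calls: list[CnvCall], max_gap_fraction: float = 0.2) -> list[CnvCall]:
    """Optionally bridge same-state calls separated by a small gap.

    Two consecutive calls of the same sample/chromosome/state are merged when
    the gap between them is smaller than ``max_gap_fraction`` of their
    combined span. OFF by default in the pipeline: the conservative
    un-merged calls are what the per-call statistics describe.
    """
    out: list[CnvCall] = []
    key = lambda c: (c.sample_id, c.chromosome, c.state, c.start_bp)
    for call in sorted(calls, key=key):
        if out:
            prev = out[-1]
            same = (
                prev.sample_id == call.sample_id
                and prev.chromosome == call.chromosome
                and prev.state == call.state
            )
            gap = call.start_bp - prev.end_bp - 1
            combined = prev.length_bp + call.length_bp
            if same and 0 <= gap < max_gap_fraction * combined:
                out[-1] = replace_call(prev, call)
                continue
        out.append(call)
    return sorted(out, key=lambda c: (c.sample_id, c.chromosome, c.start_bp))


def replace_call(prev: CnvCall, nxt: CnvCall) -> CnvCall:
    return CnvCall(
        sample_id=prev.sample_id,
        chromosome=prev.chromosome,
        start_bp=prev.start_bp,
        end_bp=nxt.end_bp,
        state=prev.state,
        copy_number=prev.copy_number,
        n_snps=prev.n_snps + nxt.n_snps,
        confidence=prev.confidence + nxt.confidence,
    )
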