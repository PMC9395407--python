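"""Weir–Cockerham F_ST estimation and windowed selection scans.

Per SNP, the unbiased 1984 variance-component estimator theta-hat is
computed from per-population sample sizes n_i, B-allele frequencies p_i and
observed heterozygote frequencies h_i:

    n_bar = mean n_i                 n_c = (r*n_bar - sum n_i^2/(r*n_bar)) / (r-1)
    p_bar = sum n_i p_i / (r n_bar)  s^2  = sum n_i (p_i - p_bar)^2 / ((r-1) n_bar)
    h_bar = sum n_i h_i / (r n_bar)

    a = n_bar/n_c * [ s^2 - (p_bar(1-p_bar) - (r-1)/r s^2 - h_bar/4) / (n_bar-1) ]
    b = n_bar/(n_bar-1) * [ p_bar(1-p_bar) - (r-1)/r s^2 - (2 n_bar - 1)/(4 n_bar) h_bar ]
    c = h_bar / 2
    theta_hat = a / (a + b + c)

theta-hat is 1 when populations are fixed for different alleles, can be
slightly negative (the estimator is unbiased, not truncated), and is
undefined (NaN) at globally monomorphic loci.

Scans average theta-hat over consecutive non-overlapping blocks of 5
adjacent SNPs per chromosome ("windowed F_ST"); a terminal block shorter
than the window is kept and flagged. Windows at or above the empirical
(1-q) quantile of the scan are flagged as selection-signature candidates.
The multi-locus (ratio-of-sums) estimate sum(a)/sum(a+b+c) is the standard
genome-wide differentiation summary and is what the simulator's
Balding–Nichols F target is recovered against.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "wc_theta",
    "per_snp_fst",
    "windowed_fst",
    "flag_outlier_windows",
    "multilocus_theta",
    "pairwise_scans",
    "manhattan_plot",
]


def wc_theta(n, p, h):
    """Weir–Cockerham variance components and theta-hat.

    Parameters are arrays over populations, optionally with a trailing locus
    axis: ``n`` sample sizes (individuals), ``p`` B-allele frequencies,
    ``h`` observed heterozygote frequencies. Returns ``(a, b, c,
    theta_hat)`` with the population axis reduced.
    """
    n = np.asarray(n, dtype=float)
    p = np.asarray(p, dtype=float)
    h = np.asarray(h, dtype=float)
    if n.shape[0] < 2:
        raise ValueError("at least two populations are required")
    if np.any(n < 1):
        raise ValueError("population sample sizes must be >= 1")
    r = n.shape[0]
    n_bar = n.mean(axis=0)
    n_c = (r * n_bar - (n**2).sum(axis=0) / (r * n_bar)) / (r - 1)
    p_bar = (n * p).sum(axis=0) / (r * n_bar)
    s2 = (n * (p - p_bar) ** 2).sum(axis=0) / ((r - 1) * n_bar)
    h_bar = (n * h).sum(axis=0) / (r * n_bar)

    with np.errstate(invalid="ignore", divide="ignore"):
        a = (n_bar / n_c) * (s2 - (p_bar * (1 - p_bar) - (r - 1) / r * s2 - h_bar / 4) / (n_bar - 1))
        b = (n_bar / (n_bar - 1)) * (p_bar * (1 - p_bar) - (r - 1) / r * s2 - (2 * n_bar - 1) / (4 * n_bar) * h_bar)
        c = h_bar / 2
        denom = a + b + c
        theta = np.where(denom != 0, a / np.where(denom != 0, denom, 1.0), np.nan)
    return a, b, c, theta


def per_snp_fst(
    dosage: np.ndarray,
    breeds: np.ndarray,
    pair: tuple[str, str],
    marker_map: pd.DataFrame,
) -> pd.DataFrame:
    """Per-SNP Weir–Cockerham components for one breed pair.

    ``dosage`` is (n_samples, n_snps) with negative = missing. Returns a
    DataFrame (name, chrom, pos, n1, n2, p1, p2, a, b, c, theta) aligned to
    the marker map; monomorphic or all-missing SNPs carry NaN theta.
    """
    breeds = np.asarray(breeds)
    stats = []
    for breed in pair:
        rows = np.flatnonzero(breeds == breed)
        if rows.size == 0:
            raise ValueError(f"no samples for breed {breed!r}")
        sub = np.asarray(dosage)[rows]
        obs = sub >= 0
        n_i = obs.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p_i = np.where(obs, sub, 0).sum(axis=0) / (2.0 * np.maximum(n_i, 1))
            h_i = ((sub == 1) & obs).sum(axis=0) / np.maximum(n_i, 1)
        stats.append((n_i, p_i, h_i))
    n = np.stack([s[0] for s in stats]).astype(float)
    p = np.stack([s[1] for s in stats])
    h = np.stack([s[2] for s in stats])
    usable = (n >= 1).all(axis=0)
    a = np.full(n.shape[1], np.nan)
    b = np.full(n.shape[1], np.nan)
    c = np.full(n.shape[1], np.nan)
    theta = np.full(n.shape[1], np.nan)
    if usable.any():
        a_u, b_u, c_u, t_u = wc_theta(n[:, usable], p[:, usable], h[:, usable])
        a[usable], b[usable], c[usable], theta[usable] = a_u, b_u, c_u, t_u
    return pd.DataFrame(
        {
            "name": marker_map["name"].to_numpy(),
            "chrom": marker_map["chrom"].astype(str).to_numpy(),
            "pos": marker_map["pos"].to_numpy(),
            "n1": n[0],
            "n2": n[1],
            "p1": p[0],
            "p2": p[1],
            "a": a,
            "b": b,
            "c": c,
            "theta": theta,
        }
    )


def windowed_fst(records: pd.DataFrame, window_size: int = 5, mode: str = "block") -> pd.DataFrame:
    """Average per-SNP theta-hat over sets of adjacent SNPs.

    Records must be sorted by (chromosome, position); rows with undefined
    theta are dropped before windowing. ``mode="block"`` (default) uses
    consecutive non-overlapping sets of ``window_size`` SNPs per chromosome,
    keeping and flagging a shorter terminal set; ``mode="sliding"`` emits a
    window at every SNP whose full set fits. Returns (chrom, start, end,
    mid, fst, n_snps, short, members).
    """
    if mode not in ("block", "sliding"):
        raise ValueError("mode must be 'block' or 'sliding'")
    recs = records.dropna(subset=["theta"])
    rows = []
    for chrom, grp in recs.groupby("chrom", sort=False):
        theta = grp["theta"].to_numpy()
        pos = grp["pos"].to_numpy()
        names = grp["name"].to_numpy()
        m = theta.shape[0]
        if m == 0:
            continue
        if mode == "block":
            starts = range(0, m, window_size)
        else:
            starts = range(0, max(m - window_size + 1, 1))
        for i in starts:
            j = min(i + window_size, m)
            rows.append(
                {
                    "chrom": chrom,
                    "start": int(pos[i]),
                    "end": int(pos[j - 1]),
                    "mid": float(0.5 * (pos[i] + pos[j - 1])),
                    "fst": float(theta[i:j].mean()),
                    "n_snps": j - i,
                    "short": j - i < window_size,
                    "members": ",".join(map(str, names[i:j])),
                }
            )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "mid", "fst", "n_snps", "short", "members"])


def flag_outlier_windows(windows: pd.DataFrame, q: float = 0.01) -> np.ndarray:
    """Boolean mask of windows in the top q tail of the empirical scan.

    The threshold is the (1-q) empirical quantile (method "higher"); ties at
    the threshold are all flagged. q = 1 flags everything.
    """
    if not 0.0 < q <= 1.0:
        raise ValueError("q must be in (0, 1]")
    if len(windows) == 0:
        raise ValueError("at least one window is required")
    values = windows["fst"].to_numpy(dtype=float)
    if q == 1.0:
        return np.ones(values.shape, dtype=bool)
    threshold = np.quantile(values, 1.0 - q, method="higher")
    return values >= threshold


def multilocus_theta(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Ratio-of-sums multi-locus theta: sum(a) / sum(a+b+c) over defined loci."""
    a = np.asarray(a, dtype=float)
    total = a + np.asarray(b, dtype=float) + np.asarray(c, dtype=float)
    ok = np.isfinite(total)
    denom = total[ok].sum()
    if denom == 0:
        return float("nan")
    return float(a[ok].sum() / denom)


def pairwise_scans(
    dosage: np.ndarray,
    breeds: np.ndarray,
    marker_map: pd.DataFrame,
    window_size: int = 5,
    q: float = 0.01,
) -> dict[tuple[str, str], dict]:
    """Full scan for every breed pair: per-SNP records, windows, outliers."""
    uniq = list(pd.unique(np.asarray(breeds)))
    out = {}
    for i in range(len(uniq)):
        for j in range(i + 1, len(uniq)):
            pair = (uniq[i], uniq[j])
            records = per_snp_fst(dosage, breeds, pair, marker_map)
            windows = windowed_fst(records, window_size=window_size)
            flagged = flag_outlier_windows(windows, q=q) if len(windows) else np.zeros(0, dtype=bool)
            out[pair] = {
                "records": records,
                "windows": windows,
                "flagged": flagged,
                "multilocus_theta": multilocus_theta(records["a"], records["b"], records["c"]),
            }
    return out


def manhattan_plot(windows: pd.DataFrame, path, title: str = "Windowed F_ST") -> None:
    """Manhattan-style scan plot, windows coloured by chromosome."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(10, 3))
    offset = 0.0
    ticks, labels = [], []
    for k, (chrom, grp) in enumerate(windows.groupby("chrom", sort=False)):
        x = grp["mid"].to_numpy() + offset
        ax.scatter(x, grp["fst"], s=4, color=f"C{k % 10}")
        ticks.append(offset + grp["mid"].mean())
        labels.append(str(chrom))
        offset += grp["end"].max()
    ax.set_xticks(ticks, labels)
    ax.set_xlabel("chromosome")
    ax.set_ylabel("windowed F_ST")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
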