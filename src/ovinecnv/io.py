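"""Readers and writers for the plain-text interchange formats.

Formats handled (all tab-delimited text, positions 1-based inclusive):

* per-sample signal files — Name, Chr, Position, X, Y, B Allele Freq,
  Log R Ratio (the Genome-Studio-like export a CNV caller consumes); files
  with precomputed BAF/LRR but no X/Y are accepted and bypass the raw
  transforms,
* PFB files — Name, Chr, Position, PFB,
* PLINK PED/MAP text genotypes with the breed carried as family ID and
  "0 0" meaning missing,
* CNV call tables (chr, start, end, state, cn, sample, n_snps, conf) and
  CNVR tables, plus BED flavours of both (BED is 0-based half-open: start
  is the 1-based start minus one).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from ._util import normalize_chrom
from .cnvr import Cnvr
from .hmm import CnvCall

__all__ = [
    "write_signal_file",
    "read_signal_file",
    "write_pfb",
    "read_pfb",
    "write_plink",
    "read_plink",
    "write_calls",
    "read_calls",
    "write_cnvrs",
    "write_bed",
    "read_intervals",
]


def write_signal_file(path, marker_map: pd.DataFrame, x, y, baf, lrr) -> None:
    df = pd.DataFrame(
        {
            "Name": marker_map["name"].to_numpy(),
            "Chr": marker_map["chrom"].to_numpy(),
            "Position": marker_map["pos"].to_numpy(),
            "X": np.asarray(x),
            "Y": np.asarray(y),
            "B Allele Freq": np.asarray(baf),
            "Log R Ratio": np.asarray(lrr),
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_signal_file(path) -> pd.DataFrame:
    """Read a signal file; requires Name/Chr/Position plus either X/Y or
    precomputed BAF+LRR columns."""
    df = pd.read_csv(path, sep="\t")
    required = {"Name", "Chr", "Position"}
    if not required.issubset(df.columns):
        raise ValueError(f"signal file {path} lacks {required - set(df.columns)}")
    has_xy = {"X", "Y"}.issubset(df.columns)
    has_tracks = {"B Allele Freq", "Log R Ratio"}.issubset(df.columns)
    if not (has_xy or has_tracks):
        raise ValueError(f"signal file {path} needs X/Y or BAF/LRR columns")
    df["Chr"] = df["Chr"].map(normalize_chrom)
    return df


def write_pfb(path, marker_map: pd.DataFrame, pfb) -> None:
    pd.DataFrame(
        {
            "Name": marker_map["name"].to_numpy(),
            "Chr": marker_map["chrom"].to_numpy(),
            "Position": marker_map["pos"].to_numpy(),
            "PFB": np.asarray(pfb),
        }
    ).to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_pfb(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    df["Chr"] = df["Chr"].map(normalize_chrom)
    return df


def write_plink(ped_path, map_path, marker_map: pd.DataFrame, samples: pd.DataFrame, dosage) -> None:
    """PED/MAP text genotypes; family ID = breed, alleles A/B, missing '0 0'."""
    dosage = np.asarray(dosage)
    map_df = pd.DataFrame(
        {
            "chrom": marker_map["chrom"].to_numpy(),
            "name": marker_map["name"].to_numpy(),
            "cm": 0,
            "pos": marker_map["pos"].to_numpy(),
        }
    )
    map_df.to_csv(map_path, sep="\t", index=False, header=False)
    allele_strings = {-1: "0 0", 0: "A A", 1: "A B", 2: "B B"}
    with open(ped_path, "w") as fh:
        for i, row in samples.iterrows():
            lead = [str(row.breed), str(row.sample_id), "0", "0", "0", "-9"]
            genos = [allele_strings[int(g) if g >= 0 else -1] for g in dosage[i]]
            fh.write(" ".join(lead + genos) + "\n")


def read_plink(ped_path, map_path) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray]:
    """Read PED/MAP into (marker_map, samples, dosage).

    Dosage counts B alleles (-1 = missing); the PED's first allele seen per
    SNP is taken as A when files were not written by this package.
    """
    map_df = pd.read_csv(map_path, sep=r"\s+", header=None, names=["chrom", "name", "cm", "pos"], dtype={"chrom": str})
    marker_map = pd.DataFrame(
        {"name": map_df["name"], "chrom": map_df["chrom"].map(normalize_chrom), "pos": map_df["pos"].astype(np.int64)}
    )
    n_snps = len(marker_map)
    sample_rows = []
    dosages = []
    with open(ped_path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            fid, iid = parts[0], parts[1]
            alleles = parts[6:]
            if len(alleles) != 2 * n_snps:
                raise ValueError(f"PED row {iid} has {len(alleles) // 2} genotypes, map has {n_snps}")
            a1 = np.array(alleles[0::2])
            a2 = np.array(alleles[1::2])
            missing = (a1 == "0") | (a2 == "0")
            dos = (a1 == "B").astype(np.int8) + (a2 == "B").astype(np.int8)
            dos[missing] = -1
            sample_rows.append({"sample_id": iid, "breed": fid})
            dosages.append(dos)
    samples = pd.DataFrame(sample_rows)
    return marker_map, samples, np.vstack(dosages)


_CALL_COLS = ["chr", "start", "end", "state", "cn", "sample", "n_snps", "conf"]


def write_calls(path, calls: list[CnvCall]) -> None:
    pd.DataFrame(
        [
            {
                "chr": c.chromosome,
                "start": c.start_bp,
                "end": c.end_bp,
                "state": c.state,
                "cn": c.copy_number,
                "sample": c.sample_id,
                "n_snps": c.n_snps,
                "conf": c.confidence,
            }
            for c in calls
        ],
        columns=_CALL_COLS,
    ).to_csv(path, sep="\t", index=False, float_format="%.4f")


def read_calls(path) -> list[CnvCall]:
    df = pd.read_csv(path, sep="\t", dtype={"chr": str})
    return [
        CnvCall(
            sample_id=str(r["sample"]),
            chromosome=normalize_chrom(r["chr"]),
            start_bp=int(r["start"]),
            end_bp=int(r["end"]),
            state=str(r["state"]),
            copy_number=int(r["cn"]),
            n_snps=int(r["n_snps"]),
            confidence=float(r["conf"]),
        )
        for _, r in df.iterrows()
    ]


def write_cnvrs(path, regions: list[Cnvr]) -> None:
    pd.DataFrame(
        [
            {
                "chrom": r.chromosome,
                "start": r.start_bp,
                "end": r.end_bp,
                "status": r.status,
                "n_samples": len(r.samples),
                "breeds": ",".join(r.breeds),
            }
            for r in regions
        ],
        columns=["chrom", "start", "end", "status", "n_samples", "breeds"],
    ).to_csv(path, sep="\t", index=False)


def write_bed(path, intervals) -> None:
    """BED (0-based half-open): chromStart = 1-based start - 1."""
    with open(path, "w") as fh:
        for iv in intervals:
            chrom = getattr(iv, "chromosome")
            start = getattr(iv, "start_bp") - 1
            end = getattr(iv, "end_bp")
            name = getattr(iv, "feature_id", None) or getattr(iv, "status", ".")
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\n")


def read_intervals(path, feature_class: str = "") -> list:
    """Read a BED-like TSV (chrom, start, end[, name]) as 1-based intervals.

    Columns may be headed or headless; a fourth column is the feature id.
    Starts are treated as 1-based inclusive (use ``bed=True`` semantics by
    adding one beforehand if the source is true BED).
    """
    from .annotate import GenomeInterval

    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
    if isinstance(df.iloc[0, 1], str):  # header row present
        df = df.iloc[1:].reset_index(drop=True)
    out = []
    for i, row in df.iterrows():
        name = str(row[3]) if df.shape[1] > 3 else f"{feature_class or 'iv'}_{i}"
        out.append(
            GenomeInterval(
                chromosome=str(row[0]),
                start_bp=int(row[1]),
                end_bp=int(row[2]),
                feature_id=name,
                feature_class=feature_class,
            )
        )
    return out
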