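"""Readers and writers for the package's on-disk formats.

- IBD segments: tab-separated, header ``iid1 iid2 ch start_cM end_cM
  length_cM``, one row per shared segment, pair order normalised
  lexicographically (the dialect of imputation-based IBD callers).
- Metadata: CSV ``id,date_lo,date_hi,group,lat,lon,sex`` (lat/lon/sex may be
  empty).
- Genotypes: the EIGENSTRAT trio (geno/snp/ind); genetic positions are
  stored in Morgans in the .snp file, 9 is missing in .geno.
- Allele frequencies: CSV ``snp_id,chrom,cm,block,<pop1>,<pop2>,...``.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import pandas as pd

from .metadata import IndividualRecord
from .pedigree import IBDSegment
from .popsim import AlleleFreqTable, GenotypeMatrix

IBD_COLUMNS = ["iid1", "iid2", "ch", "start_cM", "end_cM", "length_cM"]


def write_ibd_tsv(segments: list[IBDSegment], path: str | Path) -> None:
    rows = []
    for s in segments:
        a, b = sorted((s.iid1, s.iid2))
        rows.append((a, b, s.ch, s.start_cm, s.end_cm, s.length_cm))
    df = pd.DataFrame(rows, columns=IBD_COLUMNS)
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_ibd_tsv(path: str | Path) -> list[IBDSegment]:
    df = pd.read_csv(path, sep="\t", dtype={"ch": str})
    missing = set(IBD_COLUMNS[:5]) - set(df.columns)
    if missing:
        raise ValueError(f"IBD table {path} lacks columns: {sorted(missing)}")
    out = []
    for row in df.itertuples(index=False):
        a, b = sorted((str(row.iid1), str(row.iid2)))
        out.append(IBDSegment(a, b, str(row.ch), float(row.start_cM), float(row.end_cM)))
    return out


def write_metadata_csv(records: list[IndividualRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "id": [r.id for r in records],
            "date_lo": [r.date_lo for r in records],
            "date_hi": [r.date_hi for r in records],
            "group": [r.group for r in records],
            "lat": [r.latitude for r in records],
            "lon": [r.longitude for r in records],
            "sex": [r.sex for r in records],
        }
    )
    df.to_csv(path, index=False)


def _opt_float(x) -> float | None:
    return None if x is None or (isinstance(x, float) and math.isnan(x)) else float(x)


def read_metadata_csv(path: str | Path) -> list[IndividualRecord]:
    df = pd.read_csv(path, dtype={"id": str, "group": str, "sex": str})
    required = {"id", "date_lo", "date_hi", "group"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"metadata {path} lacks columns: {sorted(missing)}")
    out = []
    for row in df.itertuples(index=False):
        sex = getattr(row, "sex", None)
        out.append(
            IndividualRecord(
                id=str(row.id),
                date_lo=int(row.date_lo),
                date_hi=int(row.date_hi),
                group=str(row.group),
                latitude=_opt_float(getattr(row, "lat", None)),
                longitude=_opt_float(getattr(row, "lon", None)),
                sex=None if sex is None or (isinstance(sex, float) and math.isnan(sex)) else str(sex),
            )
        )
    return out


# ---------------------------------------------------------------------------
# EIGENSTRAT


def write_eigenstrat(gm: GenotypeMatrix, prefix: str | Path) -> None:
    """Write geno/snp/ind files under ``prefix`` (.geno, .snp, .ind)."""
    prefix = Path(prefix)
    with open(f"{prefix}.geno", "w") as fh:
        for row in gm.calls:
            fh.write("".join(str(int(v)) for v in row) + "\n")
    with open(f"{prefix}.snp", "w") as fh:
        for i, row in enumerate(gm.snps.itertuples(index=False)):
            morgans = row.cm / 100.0
            physpos = int(round(row.cm * 1_000_000))  # synthetic physical coordinate
            fh.write(
                f"{row.snp_id}\t{row.chrom}\t{morgans:.8f}\t{physpos}\tA\tG\n"
            )
    with open(f"{prefix}.ind", "w") as fh:
        for ind, pop in zip(gm.individuals, gm.populations):
            fh.write(f"{ind}\tU\t{pop}\n")


def read_eigenstrat(prefix: str | Path, ploidy: str = "pseudohaploid") -> GenotypeMatrix:
    prefix = Path(prefix)
    snp = pd.read_csv(
        f"{prefix}.snp",
        sep=r"\s+",
        header=None,
        names=["snp_id", "chrom", "morgans", "physpos", "ref", "alt"],
        dtype={"snp_id": str, "chrom": str},
    )
    snps = pd.DataFrame(
        {
            "snp_id": snp["snp_id"],
            "chrom": snp["chrom"],
            "cm": snp["morgans"] * 100.0,
        }
    )
    ind = pd.read_csv(
        f"{prefix}.ind",
        sep=r"\s+",
        header=None,
        names=["id", "sex", "pop"],
        dtype=str,
    )
    with open(f"{prefix}.geno") as fh:
        rows = [np.frombuffer(line.strip().encode(), dtype=np.uint8) - ord("0")
                for line in fh if line.strip()]
    calls = np.asarray(rows, dtype=np.int8)
    if calls.shape != (len(snps), len(ind)):
        raise ValueError(
            f"geno matrix {calls.shape} does not match "
            f"{len(snps)} SNPs x {len(ind)} individuals"
        )
    if ploidy == "pseudohaploid" and np.any(calls == 1):
        ploidy = "diploid"
    return GenotypeMatrix(
        calls=calls,
        individuals=ind["id"].tolist(),
        populations=ind["pop"].tolist(),
        snps=snps,
        ploidy=ploidy,
    )


# ---------------------------------------------------------------------------
# allele-frequency tables


def write_freq_csv(table: AlleleFreqTable, path: str | Path) -> None:
    df = pd.concat([table.snps.reset_index(drop=True),
                    table.freqs.reset_index(drop=True)], axis=1)
    df.to_csv(path, index=False, float_format="%.8f")


def read_freq_csv(path: str | Path) -> AlleleFreqTable:
    df = pd.read_csv(path, dtype={"snp_id": str, "chrom": str})
    meta_cols = [c for c in ("snp_id", "chrom", "cm", "block") if c in df.columns]
    if "cm" not in meta_cols:
        raise ValueError(f"frequency table {path} lacks a 'cm' column")
    pops = [c for c in df.columns if c not in meta_cols]
    snps = df[meta_cols].copy()
    if "block" not in snps.columns:
        snps["block"] = 0
    if "snp_id" not in snps.columns:
        snps["snp_id"] = [f"rs{i}" for i in range(len(snps))]
    return AlleleFreqTable(snps=snps, freqs=df[pops].astype(float))
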