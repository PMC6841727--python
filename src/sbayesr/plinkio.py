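"""PLINK 1 bed/bim/fam reading and writing, and the in-memory genotype panel.

The .bed file is the standard SNP-major 2-bit encoding: magic bytes
``0x6c 0x1b`` followed by ``0x01`` (SNP-major), then ceil(n/4) bytes per
variant.  Two-bit codes (low bits first within a byte):

====  ==========================  =================
code  meaning                     A1 allele count
====  ==========================  =================
00    homozygous first allele     2
01    missing                     NaN
10    heterozygous                1
11    homozygous second allele    0
====  ==========================  =================
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import FormatError

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])


def _ext(prefix, ext: str) -> Path:
    return Path(str(prefix) + ext)

# code -> A1 dosage lookup, missing encoded as NaN
_DECODE = np.array([2.0, np.nan, 1.0, 0.0])


@dataclass
class GenotypeMatrix:
    """An n x p panel of 0/1/2 A1-allele counts (NaN = missing) with
    per-SNP allele metadata and map positions.

    ``freq`` is the A1 allele frequency implied by the column means after
    mean imputation of missing calls.
    """

    genotypes: np.ndarray  # (n, p) float64, values {0,1,2,NaN}
    snp_id: np.ndarray
    chrom: np.ndarray
    bp: np.ndarray
    A1: np.ndarray
    A2: np.ndarray
    cm: np.ndarray | None = None
    sample_id: np.ndarray | None = None
    scaled_convention: bool = False  # downstream effects on per-SD scale if True

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.float64)
        if self.genotypes.ndim != 2:
            raise ValueError("genotypes must be 2-D (individuals x SNPs)")
        if self.genotypes.shape[1] != len(self.snp_id):
            raise ValueError("SNP metadata length mismatch")
        if self.sample_id is None:
            self.sample_id = np.array([f"id{i + 1}" for i in range(self.n)])

    @property
    def n(self) -> int:
        return self.genotypes.shape[0]

    @property
    def p(self) -> int:
        return self.genotypes.shape[1]

    @property
    def freq(self) -> np.ndarray:
        return np.nanmean(self.genotypes, axis=0) / 2.0

    def imputed(self) -> np.ndarray:
        """Genotypes with missing calls replaced by the per-SNP mean."""
        G = self.genotypes
        if not np.isnan(G).any():
            return G.copy()
        means = np.nanmean(G, axis=0)
        out = G.copy()
        idx = np.where(np.isnan(out))
        out[idx] = means[idx[1]]
        return out

    def standardized(self, scale: bool = True, ddof: int = 0) -> np.ndarray:
        """Mean-imputed, centred (and optionally variance-scaled) copy."""
        X = self.imputed()
        X -= X.mean(axis=0)
        if scale:
            sd = X.std(axis=0, ddof=ddof)
            if np.any(sd == 0):
                j = int(np.argmax(sd == 0))
                raise ValueError(f"monomorphic SNP {self.snp_id[j]} cannot be scaled")
            X /= sd
        return X

    def subset(self, rows=None, cols=None) -> "GenotypeMatrix":
        rows = slice(None) if rows is None else rows
        cols = slice(None) if cols is None else np.asarray(cols)
        return GenotypeMatrix(
            genotypes=self.genotypes[rows][:, cols],
            snp_id=np.asarray(self.snp_id)[cols],
            chrom=np.asarray(self.chrom)[cols],
            bp=np.asarray(self.bp)[cols],
            A1=np.asarray(self.A1)[cols],
            A2=np.asarray(self.A2)[cols],
            cm=None if self.cm is None else np.asarray(self.cm)[cols],
            sample_id=np.asarray(self.sample_id)[rows],
            scaled_convention=self.scaled_convention,
        )

    def snp_table(self) -> pd.DataFrame:
        tbl = pd.DataFrame(
            {
                "snp_id": self.snp_id,
                "chrom": self.chrom,
                "bp": self.bp,
                "A1": self.A1,
                "A2": self.A2,
                "freq": self.freq,
            }
        )
        if self.cm is not None:
            tbl["cm"] = self.cm
        return tbl


def read_bed(prefix) -> GenotypeMatrix:
    """Read a PLINK bed/bim/fam fileset given its path prefix."""
    prefix = Path(prefix)
    bim = pd.read_csv(
        _ext(prefix, ".bim"),
        sep=r"\s+",
        header=None,
        names=["chrom", "snp_id", "cm", "bp", "A1", "A2"],
        dtype={"chrom": str, "snp_id": str, "A1": str, "A2": str},
    )
    fam = pd.read_csv(
        _ext(prefix, ".fam"),
        sep=r"\s+",
        header=None,
        names=["fid", "iid", "pid", "mid", "sex", "pheno"],
        dtype=str,
    )
    n, p = len(fam), len(bim)
    raw = _ext(prefix, ".bed").read_bytes()
    if raw[:3] != _BED_MAGIC:
        raise FormatError(f"{prefix}.bed: bad magic bytes (not SNP-major PLINK bed)")
    bytes_per_snp = (n + 3) // 4
    body = np.frombuffer(raw[3:], dtype=np.uint8)
    if body.size != bytes_per_snp * p:
        raise FormatError(
            f"{prefix}.bed: expected {bytes_per_snp * p} data bytes, found {body.size}"
        )
    mat = body.reshape(p, bytes_per_snp)
    # expand each byte into its four 2-bit codes, low bits first
    codes = np.empty((p, bytes_per_snp * 4), dtype=np.uint8)
    for k in range(4):
        codes[:, k::4] = (mat >> (2 * k)) & 0x3
    G = _DECODE[codes[:, :n]].T  # (n, p)
    return GenotypeMatrix(
        genotypes=G,
        snp_id=bim["snp_id"].to_numpy(),
        chrom=bim["chrom"].to_numpy(),
        bp=bim["bp"].to_numpy(dtype=np.int64),
        A1=bim["A1"].to_numpy(),
        A2=bim["A2"].to_numpy(),
        cm=bim["cm"].to_numpy(dtype=np.float64),
        sample_id=fam["iid"].to_numpy(),
    )


def write_bed(prefix, G: GenotypeMatrix) -> None:
    """Write a GenotypeMatrix as a PLINK bed/bim/fam fileset."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    n, p = G.n, G.p
    dose = G.genotypes
    codes = np.full((p, n), 0x1, dtype=np.uint8)  # missing
    dT = dose.T
    codes[dT == 2.0] = 0x0
    codes[dT == 1.0] = 0x2
    codes[dT == 0.0] = 0x3
    bytes_per_snp = (n + 3) // 4
    padded = np.zeros((p, bytes_per_snp * 4), dtype=np.uint8)
    padded[:, :n] = codes
    packed = np.zeros((p, bytes_per_snp), dtype=np.uint8)
    for k in range(4):
        packed |= padded[:, k::4] << (2 * k)
    with open(_ext(prefix, ".bed"), "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(packed.tobytes())
    cm = G.cm if G.cm is not None else np.zeros(p)
    bim = pd.DataFrame(
        {
            "chrom": G.chrom,
            "snp_id": G.snp_id,
            "cm": cm,
            "bp": G.bp,
            "A1": G.A1,
            "A2": G.A2,
        }
    )
    bim.to_csv(_ext(prefix, ".bim"), sep="\t", header=False, index=False)
    fam = pd.DataFrame(
        {
            "fid": G.sample_id,
            "iid": G.sample_id,
            "pid": 0,
            "mid": 0,
            "sex": 0,
            "pheno": -9,
        }
    )
    fam.to_csv(_ext(prefix, ".fam"), sep="\t", header=False, index=False)


def read_pheno(path) -> pd.DataFrame:
    """Read a phenotype table (FID IID value, whitespace-delimited, no header)."""
    df = pd.read_csv(path, sep=r"\s+", header=None)
    if df.shape[1] < 3:
        raise FormatError(f"{path}: phenotype files need >= 3 columns (FID IID value)")
    df = df.iloc[:, :3]
    df.columns = ["fid", "iid", "value"]
    df["iid"] = df["iid"].astype(str)
    return df
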