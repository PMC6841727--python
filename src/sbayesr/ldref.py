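"""Shrunk sparse LD reference matrices.

The reference LD correlation matrix B is estimated chromosome-wise from a
genotype panel.  Each off-diagonal sample correlation is multiplied by the
shrinkage factor

    exp(-rho_ij / (2 m)),   rho_ij = 4 Ne c_ij,

where ``Ne`` is the effective population size, ``m`` the sample size of the
panel used to build the genetic map, and ``c_ij`` the genetic distance
between sites i and j in Morgans.  Entries whose factor falls below a hard
cutoff are set to zero and omitted from storage, which makes each SNP's
column support a contiguous window of neighbours (positions are sorted, so
the factor is monotone in the index distance).

Note on units: the population-scaled recombination rate rho = 4 Ne c takes c
in Morgans (the Li-Stephens / Wen-Stephens convention).  With centimorgans
and Ne around 10^4 the factor would vanish for all but immediately adjacent
sites; the Morgan convention reproduces the ~10 Mb windows a default
configuration is expected to give.
"""

from __future__ import annotations

import struct
import zlib
from dataclasses import dataclass
from io import StringIO
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import CorruptLDError, FormatError, SBayesRError
from .plinkio import GenotypeMatrix

_LD_MAGIC = b"SPLD"
_LD_VERSION = 1


@dataclass
class GeneticMap:
    """A per-chromosome table of interpolated map positions.

    Columns: ``bp`` (strictly increasing physical position), ``cm``
    (non-decreasing genetic position, centimorgans) and ``rate`` (cM/Mb).
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        for col in ("bp", "cm"):
            if col not in self.df.columns:
                raise FormatError(f"genetic map missing column '{col}'")
        bp = self.df["bp"].to_numpy()
        cm = self.df["cm"].to_numpy()
        if len(bp) == 0:
            raise FormatError("empty genetic map")
        if np.any(np.diff(bp) <= 0):
            raise FormatError("genetic map bp positions must be strictly increasing")
        if np.any(np.diff(cm) < 0):
            raise FormatError("genetic map cm positions must be non-decreasing")

    @classmethod
    def read(cls, path) -> "GeneticMap":
        """Read a per-chromosome map file (columns: position, rate cM/Mb, map cM).

        A header line is detected by a non-numeric first token.
        """
        with open(path) as fh:
            first = fh.readline().split()
        try:
            float(first[0])
            header = None
        except (ValueError, IndexError):
            header = 0
        df = pd.read_csv(path, sep=r"\s+", header=header)
        if df.shape[1] < 3:
            raise FormatError(f"{path}: genetic map needs 3 columns (bp, rate, cm)")
        df = df.iloc[:, :3]
        df.columns = ["bp", "rate", "cm"]
        return cls(df=df[["bp", "cm", "rate"]].astype(float))

    @classmethod
    def uniform(cls, bp_max: int, rate_cm_per_mb: float = 1.0) -> "GeneticMap":
        """A constant-rate map spanning [1, bp_max] (useful for simulation)."""
        bp = np.array([1.0, float(bp_max)])
        cm = (bp - 1.0) * rate_cm_per_mb / 1e6
        return cls(df=pd.DataFrame({"bp": bp, "cm": cm, "rate": rate_cm_per_mb}))


def interpolate_cm(bp_positions, gmap: GeneticMap) -> np.ndarray:
    """Piecewise-linear interpolation of genetic position (cM) at ``bp_positions``.

    Positions outside the map range are extrapolated with the nearest
    interval's rate (or held constant for a single-row map).
    """
    bp = np.asarray(bp_positions, dtype=float)
    mbp = gmap.df["bp"].to_numpy(dtype=float)
    mcm = gmap.df["cm"].to_numpy(dtype=float)
    out = np.interp(bp, mbp, mcm)
    if len(mbp) >= 2:
        lo_rate = (mcm[1] - mcm[0]) / (mbp[1] - mbp[0])
        hi_rate = (mcm[-1] - mcm[-2]) / (mbp[-1] - mbp[-2])
        below = bp < mbp[0]
        above = bp > mbp[-1]
        out[below] = mcm[0] + (bp[below] - mbp[0]) * lo_rate
        out[above] = mcm[-1] + (bp[above] - mbp[-1]) * hi_rate
    return out


@dataclass
class ShrinkConfig:
    """Parameters of the shrinkage estimator of the LD matrix.

    Defaults: Ne = 11,400 (European effective population size), m_map = 183
    (CEU individuals behind the 1000G genetic map), cutoff = 1e-3.
    """

    Ne: float = 11400.0
    m_map: float = 183.0
    cutoff: float = 1e-3

    def __post_init__(self) -> None:
        if self.Ne <= 0 or self.m_map <= 0:
            raise ValueError("Ne and m_map must be positive")
        if not (0.0 < self.cutoff < 1.0):
            raise ValueError("cutoff must lie in (0, 1)")

    @property
    def max_distance_morgans(self) -> float:
        """Genetic distance at which the factor reaches the cutoff."""
        return -np.log(self.cutoff) * 2.0 * self.m_map / (4.0 * self.Ne)


def shrink_factor(c_ij, cfg: ShrinkConfig) -> np.ndarray | float:
    """Shrinkage factor exp(-4 Ne c / (2 m)) for genetic distance c (Morgans).

    Values below ``cfg.cutoff`` are hard-thresholded to 0.
    """
    c = np.asarray(c_ij, dtype=float)
    if np.any(c < 0):
        raise ValueError("genetic distances must be non-negative")
    f = np.exp(-4.0 * cfg.Ne * c / (2.0 * cfg.m_map))
    f = np.where(f < cfg.cutoff, 0.0, f)
    return float(f) if np.isscalar(c_ij) else f


class SparseLDMatrix:
    """Chromosome-wise shrunk LD correlation matrix in windowed sparse form.

    Each SNP j stores the contiguous index window ``[window_start[j],
    window_start[j] + nnz[j])`` of its nonzero column entries together with
    the values themselves (concatenated; ``indptr`` delimits columns as in
    CSC).  The matrix is symmetric with unit diagonal.  ``info`` carries the
    per-SNP metadata (snp_id, chrom, bp, cm, A1, A2, freq).
    """

    def __init__(self, info: pd.DataFrame, window_start: np.ndarray, values_per_snp):
        required = ["snp_id", "chrom", "bp", "cm", "A1", "A2", "freq"]
        missing = [c for c in required if c not in info.columns]
        if missing:
            raise ValueError(f"SparseLDMatrix info missing columns: {missing}")
        self.info = info.reset_index(drop=True)
        self.window_start = np.asarray(window_start, dtype=np.int64)
        if isinstance(values_per_snp, tuple):
            self.indptr, self.values = values_per_snp
            self.indptr = np.asarray(self.indptr, dtype=np.int64)
            self.values = np.asarray(self.values, dtype=np.float64)
        else:
            self.indptr = np.zeros(len(values_per_snp) + 1, dtype=np.int64)
            np.cumsum([len(v) for v in values_per_snp], out=self.indptr[1:])
            self.values = (
                np.concatenate(values_per_snp)
                if values_per_snp
                else np.empty(0, dtype=np.float64)
            )
        if len(self.window_start) != len(self.info):
            raise ValueError("window_start length mismatch")
        if len(self.indptr) != len(self.info) + 1:
            raise ValueError("indptr length mismatch")

    @property
    def n_snps(self) -> int:
        return len(self.info)

    @property
    def nnz(self) -> np.ndarray:
        return np.diff(self.indptr)

    def column(self, j: int) -> tuple[int, np.ndarray]:
        """(window start index, column values) for SNP j."""
        return int(self.window_start[j]), self.values[self.indptr[j] : self.indptr[j + 1]]

    def to_dense(self) -> np.ndarray:
        B = np.zeros((self.n_snps, self.n_snps))
        for j in range(self.n_snps):
            s, v = self.column(j)
            B[s : s + len(v), j] = v
        return B

    def subset_order(self, snp_ids) -> np.ndarray:
        """Indices of ``snp_ids`` within this matrix (error if any absent)."""
        lookup = {s: i for i, s in enumerate(self.info["snp_id"])}
        try:
            return np.array([lookup[s] for s in snp_ids], dtype=np.int64)
        except KeyError as exc:
            raise SBayesRError(f"SNP {exc.args[0]} absent from LD reference") from exc


def build_sparse_ld(
    G: GenotypeMatrix,
    cm: np.ndarray | None = None,
    cfg: ShrinkConfig | None = ShrinkConfig(),
) -> SparseLDMatrix:
    """Build the shrunk sparse LD matrix for a single chromosome.

    Pearson correlations are computed on mean-imputed, centred genotype
    columns; each off-diagonal is multiplied by the shrinkage factor for the
    pair's genetic distance ``|cm_i - cm_j| / 100`` Morgans and omitted when
    the factor is below the cutoff.  ``cfg=None`` disables shrinkage and
    thresholding entirely (dense, raw sample correlation) — used when an
    exact in-sample LD matrix is wanted.
    """
    chroms = np.unique(np.asarray(G.chrom, dtype=str))
    if len(chroms) > 1:
        raise ValueError("build_sparse_ld expects a single chromosome; "
                         "use build_genome_ld for multi-chromosome panels")
    if cm is None:
        if G.cm is None:
            raise ValueError("cm positions required (pass cm= or set G.cm)")
        cm = np.asarray(G.cm, dtype=float)
    cm = np.asarray(cm, dtype=float)
    p = G.p
    if p == 0:
        raise ValueError("empty genotype panel")
    X = G.imputed()
    X = X - X.mean(axis=0)
    sd = X.std(axis=0)
    if np.any(sd == 0):
        j = int(np.argmax(sd == 0))
        raise SBayesRError(
            f"monomorphic SNP {G.snp_id[j]}: filter monomorphic variants "
            "before building the LD reference"
        )
    Xs = X / sd
    R = (Xs.T @ Xs) / G.n
    np.clip(R, -1.0, 1.0, out=R)
    np.fill_diagonal(R, 1.0)

    if cfg is not None:
        dist = np.abs(cm[:, None] - cm[None, :]) / 100.0  # cM -> Morgans
        F = np.exp(-4.0 * cfg.Ne * dist / (2.0 * cfg.m_map))
        keep = F >= cfg.cutoff
        B = R * np.where(keep, F, 0.0)
        np.fill_diagonal(B, 1.0)
        np.fill_diagonal(keep, True)
    else:
        B = R
        keep = np.ones_like(B, dtype=bool)

    window_start = np.empty(p, dtype=np.int64)
    cols = []
    for j in range(p):
        idx = np.flatnonzero(keep[:, j])
        s, e = idx[0], idx[-1] + 1  # contiguous window (monotone distance)
        window_start[j] = s
        cols.append(B[s:e, j].copy())

    info = G.snp_table()
    info["cm"] = cm
    return SparseLDMatrix(info=info, window_start=window_start, values_per_snp=cols)


def build_genome_ld(
    G: GenotypeMatrix,
    cm: np.ndarray | None = None,
    cfg: ShrinkConfig | None = ShrinkConfig(),
) -> SparseLDMatrix:
    """Chromosome-wise LD build: block-diagonal concatenation over chromosomes.

    Inter-chromosomal LD is ignored by construction.  SNP order is the
    panel's order (assumed sorted by chromosome then position).
    """
    chrom = np.asarray(G.chrom, dtype=str)
    if cm is None and G.cm is None:
        raise ValueError("cm positions required")
    cm = np.asarray(G.cm if cm is None else cm, dtype=float)
    parts = []
    offset = 0
    infos = []
    window_start = []
    for c in pd.unique(chrom):
        idx = np.flatnonzero(chrom == c)
        sub = G.subset(cols=idx)
        m = build_sparse_ld(sub, cm=cm[idx], cfg=cfg)
        infos.append(m.info)
        window_start.append(m.window_start + offset)
        parts.append((m.indptr, m.values))
        offset += m.n_snps
    indptr = np.zeros(offset + 1, dtype=np.int64)
    pos = 0
    k = 0
    values = []
    for ip, v in parts:
        nn = np.diff(ip)
        for x in nn:
            indptr[k + 1] = indptr[k] + x
            k += 1
        values.append(v)
    all_values = np.concatenate(values) if values else np.empty(0)
    info = pd.concat(infos, ignore_index=True)
    return SparseLDMatrix(
        info=info,
        window_start=np.concatenate(window_start),
        values_per_snp=(indptr, all_values),
    )


def build_full_ld(G: GenotypeMatrix) -> SparseLDMatrix:
    """Exact dense in-sample LD: the full sample correlation matrix across
    all SNPs (including between-chromosome entries), no shrinkage.

    With the GWAS panel itself this reproduces the individual-level model
    exactly and is the configuration used to validate the summary-level
    sampler against its individual-level counterpart.
    """
    p = G.p
    if p == 0:
        raise ValueError("empty genotype panel")
    X = G.imputed()
    X = X - X.mean(axis=0)
    sd = X.std(axis=0)
    if np.any(sd == 0):
        j = int(np.argmax(sd == 0))
        raise SBayesRError(f"monomorphic SNP {G.snp_id[j]} in panel")
    Xs = X / sd
    R = (Xs.T @ Xs) / G.n
    np.clip(R, -1.0, 1.0, out=R)
    np.fill_diagonal(R, 1.0)
    info = G.snp_table()
    if "cm" not in info.columns:
        info["cm"] = 0.0
    indptr = np.arange(p + 1, dtype=np.int64) * p
    return SparseLDMatrix(
        info=info,
        window_start=np.zeros(p, dtype=np.int64),
        values_per_snp=(indptr, np.ascontiguousarray(R.T).ravel()),
    )


def write_ld(matrix: SparseLDMatrix, path) -> None:
    """Write a SparseLDMatrix to the package binary format.

    Layout: magic ``SPLD`` | uint32 version | int64 p | int64 nnz_total |
    int64 info-TSV byte length | window_start int64[p] | indptr int64[p+1] |
    values float64[nnz] | info TSV (utf-8) | uint32 CRC32 of everything
    before it.
    """
    if matrix.n_snps == 0:
        raise ValueError("refusing to write an empty LD matrix")
    p = matrix.n_snps
    buf = StringIO()
    matrix.info.to_csv(buf, sep="\t", index=False)
    info_bytes = buf.getvalue().encode()
    payload = b"".join(
        [
            _LD_MAGIC,
            struct.pack("<IqqQ", _LD_VERSION, p, int(matrix.indptr[-1]), len(info_bytes)),
            matrix.window_start.astype("<i8").tobytes(),
            matrix.indptr.astype("<i8").tobytes(),
            matrix.values.astype("<f8").tobytes(),
            info_bytes,
        ]
    )
    crc = zlib.crc32(payload) & 0xFFFFFFFF
    Path(path).write_bytes(payload + struct.pack("<I", crc))


def read_ld(path) -> SparseLDMatrix:
    """Read a SparseLDMatrix written by :func:`write_ld` (CRC-verified)."""
    raw = Path(path).read_bytes()
    if len(raw) < 4 + 28 + 4 or raw[:4] != _LD_MAGIC:
        raise CorruptLDError(f"{path}: not an LD store (bad magic or truncated)")
    crc_stored = struct.unpack("<I", raw[-4:])[0]
    payload = raw[:-4]
    if zlib.crc32(payload) & 0xFFFFFFFF != crc_stored:
        raise CorruptLDError(f"{path}: checksum mismatch (corrupt or truncated file)")
    version, p, nnz_total, info_len = struct.unpack("<IqqQ", payload[4:32])
    if version != _LD_VERSION:
        raise CorruptLDError(f"{path}: unsupported LD store version {version}")
    off = 32
    need = off + 8 * p + 8 * (p + 1) + 8 * nnz_total + info_len
    if len(payload) != need:
        raise CorruptLDError(f"{path}: size mismatch (expected {need}, got {len(payload)})")
    window_start = np.frombuffer(payload, dtype="<i8", count=p, offset=off).copy()
    off += 8 * p
    indptr = np.frombuffer(payload, dtype="<i8", count=p + 1, offset=off).copy()
    off += 8 * (p + 1)
    values = np.frombuffer(payload, dtype="<f8", count=nnz_total, offset=off).copy()
    off += 8 * nnz_total
    info = pd.read_csv(
        StringIO(payload[off:].decode()), sep="\t", dtype={"chrom": str, "snp_id": str}
    )
    return SparseLDMatrix(info=info, window_start=window_start, values_per_snp=(indptr, values))


def export_text(matrix: SparseLDMatrix, path) -> None:
    """Text export of the nonzero entries (i, j, value) for inspection."""
    with open(path, "w") as fh:
        fh.write("i\tj\tvalue\n")
        for j in range(matrix.n_snps):
            s, v = matrix.column(j)
            for k, val in enumerate(v):
                fh.write(f"{s + k}\t{j}\t{val:.8g}\n")
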