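"""GWAS summary-statistic ingestion, QC, allele alignment and reconstruction
of the sufficient statistics consumed by the summary-level Gibbs sampler.

The marginal (single-SNP) least-squares results ``b_j``, ``se(b_j)``, ``n_j``
are sufficient — together with an LD reference — to reconstruct the pieces of
the multiple-regression normal equations the sampler needs:

* ``D_jj``, the genotype sum of squares ``x_j'x_j``.  With centred genotypes
  it is recovered as ``1 / (se_j^2 + b_j^2 / n_j)``; with variance-scaled
  genotypes it is simply ``n_j``.
* ``X'y = D b``, the right-hand side of the normal equations.
* ``y'y``, taken as the median per-SNP sample size under the convention that
  the phenotype was centred and variance-standardised before the GWAS.

Input dialect is the 8-column COJO-style table (``SNP A1 A2 freq b se p N``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import DuplicateSNPError, EmptyResultError, FormatError, NumericError

logger = logging.getLogger(__name__)

MA_COLUMNS = ["SNP", "A1", "A2", "freq", "b", "se", "p", "N"]

#: complementary-base pairs whose strand cannot be resolved from alleles alone
AMBIGUOUS_PAIRS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass
class SummaryDataset:
    """Per-SNP GWAS summary records.

    Wraps a :class:`pandas.DataFrame` with columns ``snp_id, A1, A2, freq,
    b, se, p, n`` and optionally ``chrom, bp`` when positional information
    is available (it is attached on alignment to an LD reference, or present
    when the summaries were produced by :func:`sbayesr.simulate.run_gwas`).
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        required = ["snp_id", "A1", "A2", "freq", "b", "se", "p", "n"]
        missing = [c for c in required if c not in self.df.columns]
        if missing:
            raise FormatError(f"SummaryDataset missing columns: {missing}")
        dup = self.df["snp_id"][self.df["snp_id"].duplicated()]
        if len(dup):
            raise DuplicateSNPError(dup.unique())
        self.df = self.df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def snp_id(self) -> np.ndarray:
        return self.df["snp_id"].to_numpy()

    def __getattr__(self, name):
        if name in ("freq", "b", "se", "p", "n", "A1", "A2", "chrom", "bp"):
            return self.df[name].to_numpy()
        raise AttributeError(name)


@dataclass
class QCConfig:
    """Summary-statistic quality-control thresholds.

    ``n_lower_pct``/``n_upper_pct`` bound the per-SNP sample-size
    distribution (linear-interpolation percentiles); SNPs strictly outside
    the band are removed.  ``exclude_regions`` are ``(chrom, start, end)``
    half-open intervals (1-based inclusive start).
    """

    maf_min: float = 0.01
    drop_ambiguous: bool = True
    n_lower_pct: float = 0.0
    n_upper_pct: float = 100.0
    exclude_regions: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (0.0 <= self.n_lower_pct < self.n_upper_pct <= 100.0):
            raise ValueError("require 0 <= n_lower_pct < n_upper_pct <= 100")


@dataclass
class SufficientStats:
    """Reconstructed normal-equation pieces for the summary-level sampler."""

    D_diag: np.ndarray
    Xty: np.ndarray
    yty: float
    n_bar: float
    scaled: bool = False

    def __post_init__(self) -> None:
        self.D_diag = np.asarray(self.D_diag, dtype=np.float64)
        self.Xty = np.asarray(self.Xty, dtype=np.float64)
        if self.D_diag.shape != self.Xty.shape:
            raise ValueError("D_diag and Xty must have equal length")
        if np.any(self.D_diag <= 0):
            raise NumericError("all D_jj must be positive")

    @property
    def n_snps(self) -> int:
        return self.D_diag.shape[0]


def read_ma(path) -> SummaryDataset:
    """Read a whitespace-delimited COJO-style summary-statistics table.

    Header must contain ``SNP A1 A2 freq b se p N`` (extra columns are
    ignored).  Rows with non-numeric or invalid ``b``/``se``/``n`` (se <= 0,
    n < 1, freq outside (0,1)) are rejected with the count logged.
    """
    try:
        raw = pd.read_csv(path, sep=r"\s+", dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty summary-statistics file") from exc
    for col in MA_COLUMNS:
        if col not in raw.columns:
            raise FormatError(f"{path}: missing required column '{col}'")
    df = pd.DataFrame(
        {
            "snp_id": raw["SNP"].astype(str),
            "A1": raw["A1"].str.upper(),
            "A2": raw["A2"].str.upper(),
        }
    )
    for src, dst in [("freq", "freq"), ("b", "b"), ("se", "se"), ("p", "p"), ("N", "n")]:
        df[dst] = pd.to_numeric(raw[src], errors="coerce")
    ok = (
        df[["freq", "b", "se", "p", "n"]].notna().all(axis=1)
        & (df["se"] > 0)
        & (df["n"] >= 1)
        & (df["freq"] > 0)
        & (df["freq"] < 1)
        & (df["p"] > 0)
        & (df["p"] <= 1)
    )
    n_bad = int((~ok).sum())
    if n_bad:
        logger.warning("%s: rejected %d row(s) with invalid numeric fields", path, n_bad)
    df = df[ok].reset_index(drop=True)
    return SummaryDataset(df)


def is_ambiguous(a1: Sequence[str], a2: Sequence[str]) -> np.ndarray:
    """Boolean mask of strand-ambiguous (A/T, C/G) allele pairs."""
    return np.fromiter(
        ((x, y) in AMBIGUOUS_PAIRS for x, y in zip(a1, a2)), dtype=bool, count=len(a1)
    )


def qc_filter(ds: SummaryDataset, cfg: QCConfig) -> tuple[SummaryDataset, dict]:
    """Apply MAF, strand-ambiguity, per-SNP sample-size percentile and
    region-exclusion filters; return the filtered dataset and per-rule
    removal counts.

    The sample-size filter removes SNPs whose ``n`` lies strictly below the
    ``n_lower_pct`` percentile or strictly above the ``n_upper_pct``
    percentile of the dataset's ``n`` distribution.  Rules are applied
    jointly on the input dataset (a SNP failing several rules is counted
    under each).
    """
    if len(ds) == 0:
        raise EmptyResultError("qc_filter: input dataset is empty")
    df = ds.df
    maf = np.minimum(df["freq"].to_numpy(), 1.0 - df["freq"].to_numpy())
    fail_maf = maf <= cfg.maf_min

    if cfg.drop_ambiguous:
        fail_amb = is_ambiguous(df["A1"].to_numpy(), df["A2"].to_numpy())
    else:
        fail_amb = np.zeros(len(df), dtype=bool)

    n = df["n"].to_numpy(dtype=float)
    lo = np.percentile(n, cfg.n_lower_pct)
    hi = np.percentile(n, cfg.n_upper_pct)
    fail_n = (n < lo) | (n > hi)

    fail_region = np.zeros(len(df), dtype=bool)
    if cfg.exclude_regions and "chrom" in df.columns and "bp" in df.columns:
        chrom = df["chrom"].astype(str).to_numpy()
        bp = df["bp"].to_numpy(dtype=float)
        for c, start, end in cfg.exclude_regions:
            fail_region |= (chrom == str(c)) & (bp >= start) & (bp < end)

    keep = ~(fail_maf | fail_amb | fail_n | fail_region)
    counts = {
        "maf": int(fail_maf.sum()),
        "ambiguous": int(fail_amb.sum()),
        "sample_size": int(fail_n.sum()),
        "region": int(fail_region.sum()),
        "retained": int(keep.sum()),
    }
    logger.info("qc_filter removal counts: %s", counts)
    if not keep.any():
        raise EmptyResultError("qc_filter removed every SNP")
    return SummaryDataset(df[keep].reset_index(drop=True)), counts


def align_to_reference(
    ds: SummaryDataset,
    ref: pd.DataFrame,
    freq_diff_max: float = 0.2,
    drop_freq_mismatch: bool = False,
) -> tuple[SummaryDataset, dict]:
    """Align summary statistics to a reference panel's allele coding.

    ``ref`` must carry columns ``snp_id, A1, A2`` and optionally ``freq``
    (frequency of the reference's counted allele A1) plus ``chrom, bp``.
    Matching is on ``snp_id``.  When the dataset's (A1, A2) equal the
    reference's (A2, A1) the record is flipped: ``b -> -b``,
    ``freq -> 1 - freq``.  Pairs matching neither orientation are dropped.
    A post-flip allele-frequency discrepancy above ``freq_diff_max``
    triggers a warning (and a drop when ``drop_freq_mismatch``).
    """
    ref = ref.reset_index(drop=True)
    merged = ds.df.merge(
        ref.add_prefix("ref_"), left_on="snp_id", right_on="ref_snp_id", how="inner"
    )
    if len(merged) == 0:
        raise EmptyResultError("align_to_reference: zero SNP overlap with reference")

    same = (merged["A1"] == merged["ref_A1"]) & (merged["A2"] == merged["ref_A2"])
    flipped = (merged["A1"] == merged["ref_A2"]) & (merged["A2"] == merged["ref_A1"])
    mismatch = ~(same | flipped)

    out = merged[~mismatch].copy()
    flip = flipped[~mismatch].to_numpy()
    out.loc[flip, "b"] = -out.loc[flip, "b"]
    out.loc[flip, "freq"] = 1.0 - out.loc[flip, "freq"]
    out["A1"] = out["ref_A1"]
    out["A2"] = out["ref_A2"]

    n_freq = 0
    if "ref_freq" in out.columns and out["ref_freq"].notna().all():
        diff = (out["freq"] - out["ref_freq"]).abs().to_numpy()
        bad = diff > freq_diff_max
        n_freq = int(bad.sum())
        if n_freq:
            logger.warning(
                "align_to_reference: %d SNP(s) with |freq - ref freq| > %.2f",
                n_freq,
                freq_diff_max,
            )
            if drop_freq_mismatch:
                out = out[~bad]

    for col in ("chrom", "bp"):
        rc = f"ref_{col}"
        if rc in out.columns:
            out[col] = out[rc]
    out = out[[c for c in out.columns if not c.startswith("ref_")]]
    counts = {
        "matched": int(same.sum()),
        "flipped": int(flipped.sum()),
        "allele_mismatch": int(mismatch.sum()),
        "freq_mismatch": n_freq,
        "missing_from_reference": len(ds) - len(merged),
    }
    logger.info("align_to_reference counts: %s", counts)
    if len(out) == 0:
        raise EmptyResultError("align_to_reference: no SNPs left after alignment")
    return SummaryDataset(out.reset_index(drop=True)), counts


def reconstruct_D(ds: SummaryDataset, scaled: bool = False) -> np.ndarray:
    """Reconstruct the diagonal of X'X from summary statistics.

    ``scaled=False`` (centred genotypes): ``D_jj = 1 / (se_j^2 + b_j^2/n_j)``.
    ``scaled=True`` (variance-standardised genotypes): ``D_jj = n_j``.
    """
    se = ds.se.astype(float)
    b = ds.b.astype(float)
    n = ds.n.astype(float)
    if np.any(se <= 0) or np.any(n <= 0):
        raise NumericError("reconstruct_D requires se > 0 and n > 0 for all SNPs")
    if scaled:
        D = n.copy()
    else:
        D = 1.0 / (se**2 + b**2 / n)
    bad = ~np.isfinite(D) | (D <= 0)
    if bad.any():
        offender = ds.snp_id[bad][0]
        raise NumericError(f"non-finite D reconstruction at SNP {offender}")
    return D


def reconstruct_sufficient(ds: SummaryDataset, scaled: bool = False) -> SufficientStats:
    """Assemble :class:`SufficientStats` (D diag, X'y = D b, y'y, median n).

    y'y is set to the median per-SNP sample size, the exact value for a
    phenotype centred and scaled to unit (population) variance.
    """
    D = reconstruct_D(ds, scaled=scaled)
    b = ds.b.astype(float)
    n_bar = float(np.median(ds.n.astype(float)))
    return SufficientStats(D_diag=D, Xty=D * b, yty=n_bar, n_bar=n_bar, scaled=scaled)


def read_regions(path) -> list:
    """Read a 3-column (chrom, start, end) exclusion-region file.

    1-based inclusive start, half-open end; '#' comments allowed.
    """
    regions = []
    with open(path) as fh:
        for line in fh:
            line = line.split("#")[0].strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) < 3:
                raise FormatError(f"{path}: region lines need 3 columns, got {line!r}")
            regions.append((parts[0], int(parts[1]), int(parts[2])))
    return regions
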