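"""Synthetic genotype / phenotype generation and per-SNP least-squares GWAS.

The generator emulates the statistical structure of a genome-wide cohort at
desk scale:

* genotypes with blockwise LD — within blocks of ``block_size`` SNPs a
  latent Gaussian AR(1) process with parameter ``rho`` is thresholded per
  haplotype to Bernoulli(MAF) alleles and the two haplotypes summed, giving
  hard-call 0/1/2 genotypes whose neighbouring-SNP correlation rises with
  ``rho``; blocks are independent and are laid out as separate
  "chromosomes" so a chromosome-wise LD build captures all simulated LD;
* causal architectures drawn from a mixture of normals (counts per variance
  component, the classic 1:2:1 layout at full scale being 2500 / 5000 /
  2500 draws from N(0, 0.01), N(0, 0.1) and N(0, 1)) or a single normal
  (50,000 standard-normal effects at full scale);
* quantitative phenotypes built on centred-and-scaled genotypes with the
  residual variance set so the realised heritability matches the target;
* case-control status from the liability threshold model at a chosen
  prevalence K: an individual is a case when its standardised liability
  exceeds the threshold t = Phi^{-1}(1 - K).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .plinkio import GenotypeMatrix
from .sumstats import SummaryDataset

#: physical spacing between simulated SNPs (bp); with the default 1 cM/Mb
#: map this sets the genetic distance between neighbours to 1e-5 Morgans
DEFAULT_BP_SPACING = 10_000
DEFAULT_CM_PER_MB = 1.0


@dataclass
class ArchitectureSpec:
    """Causal-effect architecture.

    ``mode='bayesr-mixture'``: ``counts[k]`` causal variants drawn from
    N(0, weights[k] * sigma2_beta_base) for each non-null component.
    ``mode='single-normal'``: ``counts[0]`` draws from
    N(0, sigma2_beta_base).
    """

    mode: str = "bayesr-mixture"
    counts: tuple = (2500, 5000, 2500)
    weights: tuple = (0.01, 0.1, 1.0)
    sigma2_beta_base: float = 1.0

    def __post_init__(self) -> None:
        if self.mode not in ("bayesr-mixture", "single-normal"):
            raise ValueError(f"unknown architecture mode {self.mode!r}")
        if any(c < 0 for c in self.counts):
            raise ValueError("causal counts must be non-negative")
        if self.mode == "bayesr-mixture" and len(self.counts) != len(self.weights):
            raise ValueError("counts and weights must have equal length")

    @property
    def total_causal(self) -> int:
        return int(sum(self.counts))

    @classmethod
    def genome_wide_mixture(cls) -> "ArchitectureSpec":
        """The full-scale mixture architecture (10,000 causal variants)."""
        return cls(mode="bayesr-mixture", counts=(2500, 5000, 2500),
                   weights=(0.01, 0.1, 1.0), sigma2_beta_base=1.0)

    @classmethod
    def genome_wide_normal(cls) -> "ArchitectureSpec":
        """The full-scale single-normal architecture (50,000 causal variants)."""
        return cls(mode="single-normal", counts=(50000,), weights=(1.0,),
                   sigma2_beta_base=1.0)

    @classmethod
    def scaled_mixture(cls, total_causal: int) -> "ArchitectureSpec":
        """Mixture architecture scaled down, preserving the 1:2:1 component ratio."""
        c1 = max(1, round(total_causal / 4))
        c2 = max(1, total_causal - 2 * c1)
        return cls(mode="bayesr-mixture", counts=(c1, c2, c1),
                   weights=(0.01, 0.1, 1.0), sigma2_beta_base=1.0)


@dataclass
class LiabilityConfig:
    """Liability-threshold disease model at prevalence K.

    ``threshold`` t = Phi^{-1}(1-K) and ``z`` = phi(t) feed the
    observed-to-liability heritability transformation.
    """

    K: float
    P: float | None = None  # sample case proportion; defaults to K

    def __post_init__(self) -> None:
        if not (0.0 < self.K < 1.0):
            raise ValueError("prevalence K must lie in (0, 1)")

    @property
    def threshold(self) -> float:
        return float(sps.norm.ppf(1.0 - self.K))

    @property
    def z(self) -> float:
        return float(sps.norm.pdf(self.threshold))


def simulate_genotypes(
    n: int,
    p: int,
    block_size: int = 100,
    rho: float = 0.9,
    maf_range: tuple = (0.05, 0.5),
    seed: int = 0,
    bp_spacing: int = DEFAULT_BP_SPACING,
) -> GenotypeMatrix:
    """Blockwise-LD hard-call genotypes via a Gaussian-copula AR(1) model.

    Each block of ``block_size`` SNPs is an independent "chromosome": per
    haplotype, a latent AR(1, rho) Gaussian is thresholded at
    Phi^{-1}(MAF_j) to give the allele indicator, and the individual's two
    haplotypes are summed.  MAFs are Uniform(maf_range); the counted allele
    (A1) is the minor-ish allele with frequency MAF_j.
    """
    if not (0.0 <= rho < 1.0):
        raise ValueError("rho must lie in [0, 1)")
    lo, hi = maf_range
    if not (0.0 < lo <= hi <= 0.5):
        raise ValueError("maf_range must be within (0, 0.5]")
    rng = np.random.default_rng(seed)
    maf = rng.uniform(lo, hi, size=p)
    thresh = sps.norm.ppf(maf)

    G = np.empty((n, p), dtype=np.float64)
    scale = np.sqrt(1.0 - rho * rho)
    for start in range(0, p, block_size):
        end = min(start + block_size, p)
        width = end - start
        acc = np.zeros((n, width))
        for _hap in range(2):
            z = np.empty((n, width))
            z[:, 0] = rng.standard_normal(n)
            for k in range(1, width):
                z[:, k] = rho * z[:, k - 1] + scale * rng.standard_normal(n)
            acc += z < thresh[start:end]
        G[:, start:end] = acc

    n_blocks = (p + block_size - 1) // block_size
    block_idx = np.repeat(np.arange(n_blocks), block_size)[:p]
    within = np.arange(p) - block_idx * block_size
    return GenotypeMatrix(
        genotypes=G,
        snp_id=np.array([f"rs{j + 1}" for j in range(p)]),
        chrom=(block_idx + 1).astype(str),
        bp=(within + 1) * bp_spacing,
        A1=np.full(p, "A"),
        A2=np.full(p, "G"),
        cm=(within + 1) * bp_spacing * DEFAULT_CM_PER_MB / 1e6,
    )


def simulate_effects(
    p: int, arch: ArchitectureSpec, seed: int = 0
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw causal effects under an architecture.

    Returns ``(beta, causal_idx, labels)`` where ``labels[k]`` is the
    1-based non-null component of the k-th causal variant (matching
    ``causal_idx`` order) and ``beta`` is dense over all p SNPs.
    """
    if arch.total_causal > p:
        raise ValueError("total causal count exceeds number of SNPs")
    rng = np.random.default_rng(seed)
    causal = rng.choice(p, size=arch.total_causal, replace=False)
    beta = np.zeros(p)
    labels = np.empty(arch.total_causal, dtype=np.int64)
    offset = 0
    if arch.mode == "bayesr-mixture":
        comps = zip(arch.counts, arch.weights)
    else:
        comps = [(arch.counts[0], 1.0)]
    for k, (count, w) in enumerate(comps):
        idx = causal[offset : offset + count]
        beta[idx] = rng.normal(0.0, np.sqrt(w * arch.sigma2_beta_base), size=count)
        labels[offset : offset + count] = k + 1
        offset += count
    return beta, causal, labels


def simulate_phenotype(
    X: GenotypeMatrix | np.ndarray, beta: np.ndarray, h2: float, seed: int = 0
) -> np.ndarray:
    """Quantitative phenotype at heritability ``h2``.

    Genetic values g = X_cs beta use centred-and-scaled genotypes; the
    residual variance is var(g) (1 - h2) / h2, so the expected heritability
    equals ``h2`` (the realised value fluctuates with the noise draw).
    The returned phenotype is centred.
    """
    if not (0.0 < h2 < 1.0):
        raise ValueError("h2 must lie in (0, 1)")
    beta = np.asarray(beta, dtype=float)
    if not np.any(beta != 0):
        raise ValueError("all effects are zero: phenotype scaling undefined")
    Xcs = X.standardized(scale=True) if isinstance(X, GenotypeMatrix) else np.asarray(X)
    g = Xcs @ beta
    var_g = g.var()
    rng = np.random.default_rng(seed)
    eps = rng.normal(0.0, np.sqrt(var_g * (1.0 - h2) / h2), size=g.shape[0])
    y = g + eps
    return y - y.mean()


def simulate_case_control(
    liability: np.ndarray, K: float, seed: int | None = None
) -> np.ndarray:
    """Binary status under the liability-threshold model.

    ``liability`` must be on the standard-normal scale; an individual is a
    case iff liability > Phi^{-1}(1-K).  Deterministic given the liability
    vector (``seed`` is accepted for interface symmetry and unused).
    """
    cfg = LiabilityConfig(K=K)
    return (np.asarray(liability, dtype=float) > cfg.threshold).astype(np.int64)


def run_gwas(X: GenotypeMatrix, y: np.ndarray) -> SummaryDataset:
    """Per-SNP simple linear regression of ``y`` on allele counts.

    Returns COJO-style summary records: least-squares slope per A1-allele
    copy, its standard error (residual df = n - 2), two-sided Wald p value
    and the per-SNP non-missing sample size.
    """
    y = np.asarray(y, dtype=float)
    G = X.genotypes
    n_ind = G.shape[0]
    if y.shape[0] != n_ind:
        raise ValueError("phenotype length does not match panel")
    missing = np.isnan(G)
    n_j = (~missing).sum(axis=0).astype(float)
    Gz = np.where(missing, 0.0, G)
    sum_x = Gz.sum(axis=0)
    mean_x = sum_x / n_j
    # per-SNP phenotype moments over non-missing individuals
    sum_y = (~missing).T @ y
    mean_y = sum_y / n_j
    sxx = (Gz**2).sum(axis=0) - n_j * mean_x**2
    sxy = Gz.T @ y - n_j * mean_x * mean_y
    syy = (~missing).T @ (y**2) - n_j * mean_y**2
    if np.any(sxx <= 0):
        j = int(np.argmax(sxx <= 0))
        raise ValueError(f"monomorphic SNP {X.snp_id[j]} in GWAS panel")
    b = sxy / sxx
    df = n_j - 2
    rss = np.maximum(syy - b * sxy, 0.0)
    sigma2 = rss / df
    se = np.sqrt(sigma2 / sxx)
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = np.where(se > 0, b / se, np.inf)
    pval = 2.0 * sps.t.sf(np.abs(tstat), df)
    pval = np.clip(pval, np.finfo(float).tiny, 1.0)
    df_out = pd.DataFrame(
        {
            "snp_id": X.snp_id,
            "chrom": X.chrom,
            "bp": X.bp,
            "A1": X.A1,
            "A2": X.A2,
            "freq": mean_x / 2.0,
            "b": b,
            "se": se,
            "p": pval,
            "n": n_j,
        }
    )
    return SummaryDataset(df_out)


def write_ma(ds: SummaryDataset, path) -> None:
    """Write a SummaryDataset in the 8-column COJO dialect."""
    out = pd.DataFrame(
        {
            "SNP": ds.snp_id,
            "A1": ds.A1,
            "A2": ds.A2,
            "freq": ds.freq,
            "b": ds.b,
            "se": ds.se,
            "p": ds.p,
            "N": ds.n,
        }
    )
    out.to_csv(path, sep="\t", index=False)
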