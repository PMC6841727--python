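"""End-to-end study workflows: desk-scale twins of the genome-wide
simulation designs (simulate -> GWAS -> LD reference -> SBayesR -> evaluate).

These wire the package's pieces together the way the full-scale analyses
are run: a training cohort provides the per-SNP least-squares summary
statistics, a disjoint reference subsample provides the shrunk sparse LD
matrix, and prediction is assessed in held-out individuals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .evaluate import prediction_r2
from .gibbs import SBayesR
from .ldref import ShrinkConfig, build_full_ld, build_genome_ld
from .simulate import (
    ArchitectureSpec,
    simulate_effects,
    simulate_genotypes,
    simulate_phenotype,
)
from .simulate import run_gwas
from .sumstats import reconstruct_sufficient

logger = logging.getLogger(__name__)


@dataclass
class H2BiasResult:
    h2_true: list = field(default_factory=list)
    h2_mean: list = field(default_factory=list)  # per scenario, averaged over reps
    rel_bias_pct: list = field(default_factory=list)

    @property
    def max_upward_rel_bias_pct(self) -> float:
        return float(max(self.rel_bias_pct))


def h2_bias_study(
    seed: int,
    h2_values=(0.1, 0.2, 0.5),
    n_train: int = 3000,
    n_ref: int = 1000,
    p: int = 2000,
    n_causal: int = 20,
    block_size: int = 100,
    rho: float = 0.9,
    n_reps: int = 5,
    n_iter: int = 5000,
    burn_in: int = 2000,
    shrink: ShrinkConfig | None = ShrinkConfig(),
) -> H2BiasResult:
    """Heritability-estimation twin of the quantitative simulation scenarios.

    For each heritability scenario: simulate a blockwise-LD cohort, fit the
    per-SNP GWAS on the training subsample, build the shrunk sparse LD
    matrix from the disjoint reference subsample, run the summary-level
    sampler and average the posterior-mean h2 over ``n_reps`` seeded
    replicates.  Reports the per-scenario relative deviation (%) of the
    mean estimate from the generating value.
    """
    arch = ArchitectureSpec.scaled_mixture(n_causal)
    out = H2BiasResult()
    for s_idx, h2 in enumerate(h2_values):
        estimates = []
        for rep in range(n_reps):
            rep_seed = (seed + 7919 * s_idx + 104729 * rep) % (2**31 - 1)
            G = simulate_genotypes(n_train + n_ref, p, block_size=block_size,
                                   rho=rho, seed=rep_seed)
            beta, *_ = simulate_effects(p, arch, seed=rep_seed + 1)
            y = simulate_phenotype(G, beta, h2, seed=rep_seed + 2)
            train = G.subset(rows=slice(0, n_train))
            ref = G.subset(rows=slice(n_train, n_train + n_ref))
            y_tr = y[:n_train]
            y_tr = (y_tr - y_tr.mean()) / y_tr.std()
            stats = reconstruct_sufficient(run_gwas(train, y_tr), scaled=False)
            ld = build_genome_ld(ref, cfg=shrink)
            est = SBayesR(n_iter=n_iter, burn_in=burn_in, seed=rep_seed)
            est.fit(stats, ld)
            estimates.append(est.h2_mean_)
            logger.info("h2 twin: scenario h2=%.2f rep %d -> %.4f", h2, rep,
                        est.h2_mean_)
        mean_h2 = float(np.mean(estimates))
        out.h2_true.append(float(h2))
        out.h2_mean.append(mean_h2)
        out.rel_bias_pct.append(100.0 * (mean_h2 - h2) / h2)
    return out


@dataclass
class RecoveryResult:
    h2_true: float
    h2_means: np.ndarray  # per seed
    prs_r2: np.ndarray
    slopes: np.ndarray

    @property
    def h2_grand_mean(self) -> float:
        return float(self.h2_means.mean())

    @property
    def h2_mc_sd(self) -> float:
        """Monte-Carlo standard error of the grand mean across seeds."""
        return float(self.h2_means.std(ddof=1) / np.sqrt(len(self.h2_means)))


def recovery_study(
    seed: int,
    n_train: int = 5000,
    n_val: int = 1000,
    p: int = 2000,
    n_causal: int = 200,
    h2: float = 0.5,
    block_size: int = 100,
    rho: float = 0.9,
    n_seeds: int = 5,
    n_iter: int = 3000,
    burn_in: int = 1000,
) -> RecoveryResult:
    """Parameter-recovery and calibration study with exact in-sample LD.

    Uses the full LD correlation matrix of the GWAS cohort itself (the
    configuration in which the summary-level model is equivalent to the
    individual-level one), then scores held-out individuals with the
    posterior-mean effects and reports prediction R^2 and the calibration
    slope of the (standardised) true phenotype on the PRS.
    """
    arch = ArchitectureSpec.scaled_mixture(n_causal)
    h2_means, r2s, slopes = [], [], []
    for rep in range(n_seeds):
        rep_seed = (seed + 15485863 * rep) % (2**31 - 1)
        G = simulate_genotypes(n_train + n_val, p, block_size=block_size,
                               rho=rho, seed=rep_seed)
        beta, *_ = simulate_effects(p, arch, seed=rep_seed + 1)
        y = simulate_phenotype(G, beta, h2, seed=rep_seed + 2)
        train = G.subset(rows=slice(0, n_train))
        val = G.subset(rows=slice(n_train, n_train + n_val))
        y_tr = y[:n_train]
        y_tr = (y_tr - y_tr.mean()) / y_tr.std()
        stats = reconstruct_sufficient(run_gwas(train, y_tr), scaled=False)
        ld = build_full_ld(train)
        est = SBayesR(n_iter=n_iter, burn_in=burn_in, seed=rep_seed)
        est.fit(stats, ld)
        h2_means.append(est.h2_mean_)
        prs = est.predict(val)
        y_val = y[n_train:]
        y_val = (y_val - y_val.mean()) / y_val.std()
        acc = prediction_r2(y_val, prs)
        r2s.append(acc.r2)
        slopes.append(acc.slope)
        logger.info("recovery: rep %d h2=%.4f R2=%.4f slope=%.3f",
                    rep, est.h2_mean_, acc.r2, acc.slope)
    return RecoveryResult(
        h2_true=float(h2),
        h2_means=np.array(h2_means),
        prs_r2=np.array(r2s),
        slopes=np.array(slopes),
    )


def liability_prevalence_study(seed: int, n: int = 100_000, K: float = 0.05) -> float:
    """Observed case fraction of the liability-threshold generator."""
    from .simulate import simulate_case_control

    rng = np.random.default_rng(seed)
    liability = rng.standard_normal(n)
    return float(simulate_case_control(liability, K=K).mean())
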