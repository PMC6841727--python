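"""Summary-level Bayesian multiple regression with a mixture-of-normals prior.

The model relates the vector of marginal GWAS effects b to the multiple
regression coefficients beta through

    b = D^{-1/2} B D^{1/2} beta + D^{-1} X' eps,

where D = diag(x_j'x_j) and B is the LD correlation matrix, and places the
BayesR prior on each beta_j: a point mass at zero with probability pi_1 and
C-1 normal components N(0, gamma_c sigma_beta^2) with probabilities pi_c.
sigma_beta^2 and sigma_eps^2 carry scaled inverse-chi^2 priors and pi a
Dirichlet prior.  Posterior inference is by Gibbs sampling with a
right-hand-side updating scheme: the vector

    r* = X'y - X'X beta

is maintained incrementally, so each coordinate update touches only the
sparse LD window of the SNP being updated.

SNP-based heritability is computed each iteration as
h2 = sigma_g^2 / (sigma_g^2 + sigma_eps^2) with
sigma_g^2 = beta'(X'y - r*) / n = beta' X'X beta / n, the (population)
sample variance of X beta for centred genotypes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields as dc_fields

import numpy as np
from numba import njit
from sklearn.base import BaseEstimator

from .exceptions import DivergenceError
from .ldref import SparseLDMatrix
from .sumstats import SufficientStats

logger = logging.getLogger(__name__)

STATUS_OK = 0
STATUS_DIVERGED = 1


@dataclass
class MixtureSpec:
    """Finite mixture prior on SNP effects.

    ``gamma`` are the variance weights relative to sigma_beta^2 (first
    component 0 = the null spike); ``pi_init`` the starting mixing
    proportions; ``dirichlet_alpha`` the Dirichlet prior pseudo-counts.
    """

    gamma: tuple = (0.0, 0.01, 0.1, 1.0)
    pi_init: tuple = (0.95, 0.02, 0.02, 0.01)
    dirichlet_alpha: float | tuple = 1.0

    def __post_init__(self) -> None:
        g = np.asarray(self.gamma, dtype=float)
        pi = np.asarray(self.pi_init, dtype=float)
        if g[0] != 0.0:
            raise ValueError("gamma[0] must be 0 (null component)")
        if np.any(np.diff(g) < 0) or g[-1] <= 0:
            raise ValueError("gamma must be non-decreasing with gamma[-1] > 0")
        if len(pi) != len(g):
            raise ValueError("pi_init and gamma must have equal length")
        if abs(pi.sum() - 1.0) > 1e-8 or np.any(pi <= 0):
            raise ValueError("pi_init must be positive and sum to 1")

    @property
    def C(self) -> int:
        return len(self.gamma)

    def gamma_array(self) -> np.ndarray:
        return np.asarray(self.gamma, dtype=np.float64)

    def pi_array(self) -> np.ndarray:
        return np.asarray(self.pi_init, dtype=np.float64)

    def alpha_array(self) -> np.ndarray:
        a = self.dirichlet_alpha
        if np.isscalar(a):
            return np.full(self.C, float(a))
        return np.asarray(a, dtype=np.float64)


@dataclass
class ChainConfig:
    """MCMC chain settings and scaled inverse-chi^2 hyperparameters.

    Defaults mirror the reference analysis protocol: 10,000 iterations,
    4,000 burn-in, thinning 1 in 10, nu_beta = nu_eps = 4.  ``S2_beta_init``
    and ``S2_eps_init`` default to data-driven values (see the sampler).
    ``rhs_check_every > 0`` enables the from-scratch r* consistency
    recomputation every that many iterations (test mode).
    """

    n_iter: int = 10000
    burn_in: int = 4000
    thin: int = 10
    seed: int = 0
    nu_beta: float = 4.0
    S2_beta_init: float | None = None
    nu_eps: float = 4.0
    S2_eps_init: float | None = None
    update_order: str = "fixed"
    rhs_check_every: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.burn_in < self.n_iter):
            raise ValueError("require 0 <= burn_in < n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.update_order not in ("fixed", "permuted"):
            raise ValueError("update_order must be 'fixed' or 'permuted'")


@dataclass
class PosteriorSummary:
    """Thinned posterior draws and summaries from one chain."""

    beta_mean: np.ndarray  # posterior-mean effects, per-allele scale
    beta_mean_model_scale: np.ndarray  # on the scale the sampler worked in
    pip: np.ndarray
    comp_prob: np.ndarray  # (p, C) per-component posterior frequencies
    h2_samples: np.ndarray
    pi_samples: np.ndarray  # (n_kept, C)
    sigma2_beta_samples: np.ndarray
    sigma2_eps_samples: np.ndarray
    h2_trace: np.ndarray  # per-iteration h2 (all iterations)
    nnz_trace: np.ndarray  # per-iteration count of nonzero effects
    beta_samples: np.ndarray | None = None  # (n_kept, p) when recorded
    rhs_max_rel_dev: float = 0.0

    @property
    def h2_mean(self) -> float:
        return float(self.h2_samples.mean())

    def h2_credible_interval(self, level: float = 0.95) -> tuple[float, float]:
        lo = (1.0 - level) / 2.0
        return tuple(np.quantile(self.h2_samples, [lo, 1.0 - lo]))


@dataclass
class GibbsState:
    """Current sampler state (single-step API; the production chain runs in
    a compiled kernel that maintains the same quantities).

    ``r_star`` is the right-hand side X'y corrected for the current beta:
    r* = X'y - X'X beta, maintained incrementally.
    """

    beta: np.ndarray
    comp: np.ndarray  # component labels in 0..C-1 (0 = null spike)
    pi: np.ndarray
    sigma2_beta: float
    sigma2_eps: float
    r_star: np.ndarray

    @classmethod
    def initial(cls, stats: SufficientStats, mix: MixtureSpec,
                sigma2_beta: float, sigma2_eps: float) -> "GibbsState":
        p = stats.n_snps
        return cls(
            beta=np.zeros(p),
            comp=np.zeros(p, dtype=np.int64),
            pi=mix.pi_array().copy(),
            sigma2_beta=float(sigma2_beta),
            sigma2_eps=float(sigma2_eps),
            r_star=stats.Xty.copy(),
        )


def conditional_beta_moments(r_j, djj, gamma_c, sigma2_beta, sigma2_eps):
    """Mean and variance of beta_j given its (non-null) component:
    N(r_j / l, sigma2_eps / l) with l = djj + sigma2_eps/(gamma_c sigma2_beta)."""
    l_jc = djj + sigma2_eps / (gamma_c * sigma2_beta)
    return r_j / l_jc, sigma2_eps / l_jc


def component_log_likelihoods(r_j, djj, state: GibbsState, mix: MixtureSpec) -> np.ndarray:
    """Unnormalised log posterior weights of the mixture components for one
    SNP, with beta_j integrated out of the non-null components."""
    gamma = mix.gamma_array()
    logL = np.empty(mix.C)
    logL[0] = np.log(state.pi[0])
    for c in range(1, mix.C):
        gs = gamma[c] * state.sigma2_beta
        denom = state.sigma2_eps + gs * djj
        logL[c] = np.log(state.pi[c]) + 0.5 * (
            np.log(state.sigma2_eps / denom)
            + r_j * r_j * gs / (state.sigma2_eps * denom)
        )
    return logL


def sweep_snp(
    j: int,
    state: GibbsState,
    stats: SufficientStats,
    ld: SparseLDMatrix,
    mix: MixtureSpec,
    rng: np.random.Generator,
) -> GibbsState:
    """One coordinate update of beta_j (in place; returns the state).

    Samples the component label from the integrated conditional, then
    beta_j from its normal conditional when non-null, and applies the
    right-hand-side update r* <- r* - (X'x_j)(beta_new - beta_old) over the
    SNP's LD window only.
    """
    djj = stats.D_diag[j]
    r_j = state.r_star[j] + djj * state.beta[j]
    logL = component_log_likelihoods(r_j, djj, state, mix)
    w = np.exp(logL - logL.max())
    w /= w.sum()
    c_new = int(np.searchsorted(np.cumsum(w), rng.random(), side="left"))
    c_new = min(c_new, mix.C - 1)
    if c_new == 0:
        b_new = 0.0
    else:
        mean, var = conditional_beta_moments(
            r_j, djj, mix.gamma_array()[c_new], state.sigma2_beta, state.sigma2_eps
        )
        b_new = mean + rng.standard_normal() * np.sqrt(var)
    delta = b_new - state.beta[j]
    state.comp[j] = c_new
    if delta != 0.0:
        sqrtD = np.sqrt(stats.D_diag)
        start, vals = ld.column(j)
        sl = slice(start, start + len(vals))
        state.r_star[sl] -= sqrtD[sl] * vals * (sqrtD[j] * delta)
        state.beta[j] = b_new
    return state


def sample_sigma2_beta(state: GibbsState, mix: MixtureSpec, cfg: ChainConfig,
                       rng: np.random.Generator) -> float:
    """Draw sigma_beta^2 from its scaled inverse-chi^2 full conditional."""
    nz = state.comp > 0
    q = int(nz.sum())
    gamma = mix.gamma_array()
    ssq = float(np.sum(state.beta[nz] ** 2 / gamma[state.comp[nz]]))
    S2 = cfg.S2_beta_init if cfg.S2_beta_init is not None else 1.0
    return (ssq + cfg.nu_beta * S2) / rng.chisquare(cfg.nu_beta + q)


def sample_sigma2_eps(state: GibbsState, stats: SufficientStats, cfg: ChainConfig,
                      rng: np.random.Generator) -> float:
    """Draw sigma_eps^2: SSE = y'y - beta'(X'y + r*), floored at a small
    positive value, then scaled inverse-chi^2 with df nu_eps + n_bar."""
    sse = stats.yty - float(state.beta @ (stats.Xty + state.r_star))
    if not np.isfinite(sse):
        raise DivergenceError("non-finite SSE in sigma_eps^2 update")
    sse = max(sse, 1e-12 * stats.yty)
    S2 = cfg.S2_eps_init if cfg.S2_eps_init is not None else 1.0
    return (sse + cfg.nu_eps * S2) / rng.chisquare(cfg.nu_eps + stats.n_bar)


def sample_pi(state: GibbsState, mix: MixtureSpec,
              rng: np.random.Generator) -> np.ndarray:
    """Draw mixing proportions from Dirichlet(alpha + component counts)."""
    counts = np.bincount(state.comp, minlength=mix.C)
    return rng.dirichlet(mix.alpha_array() + counts)


def compute_h2(state: GibbsState, stats: SufficientStats) -> float:
    """SNP heritability at the current state: sigma_g^2/(sigma_g^2+sigma_eps^2)
    with sigma_g^2 = beta'(X'y - r*)/n_bar (the population variance of
    X beta for centred genotypes), floored at 0."""
    sig2g = float(state.beta @ (stats.Xty - state.r_star)) / stats.n_bar
    sig2g = max(sig2g, 0.0)
    return sig2g / (sig2g + state.sigma2_eps)


@njit(cache=True)
def _categorical_from_logs(logL, u):
    """Sample an index from unnormalised log weights with one uniform draw."""
    C = logL.shape[0]
    m = logL[0]
    for c in range(1, C):
        if logL[c] > m:
            m = logL[c]
    tot = 0.0
    probs = np.empty(C)
    for c in range(C):
        probs[c] = np.exp(logL[c] - m)
        tot += probs[c]
    acc = 0.0
    for c in range(C):
        acc += probs[c] / tot
        if u <= acc:
            return c
    return C - 1


@njit(cache=True)
def _sbayesr_kernel(
    seed,
    n_iter,
    burn_in,
    thin,
    D,
    win_start,
    indptr,
    vals,
    Xty,
    yty,
    n_bar,
    gamma,
    pi0,
    alpha,
    nu_b,
    s2_b,
    nu_e,
    s2_e,
    sig2b0,
    sig2e0,
    permuted,
    rhs_check_every,
    record_beta,
):
    p = D.shape[0]
    C = gamma.shape[0]
    np.random.seed(seed)

    beta = np.zeros(p)
    comp = np.zeros(p, dtype=np.int64)
    pi = pi0.copy()
    sig2b = sig2b0
    sig2e = sig2e0
    sqrtD = np.sqrt(D)
    r_star = Xty.copy()

    n_kept = 0
    for it in range(burn_in, n_iter):
        if (it - burn_in) % thin == 0:
            n_kept += 1

    beta_sum = np.zeros(p)
    comp_counts = np.zeros((p, C))
    h2_samples = np.empty(n_kept)
    pi_samples = np.empty((n_kept, C))
    s2b_samples = np.empty(n_kept)
    s2e_samples = np.empty(n_kept)
    h2_trace = np.empty(n_iter)
    nnz_trace = np.zeros(n_iter, dtype=np.int64)
    if record_beta:
        beta_samples = np.empty((n_kept, p))
    else:
        beta_samples = np.empty((0, p))

    order = np.arange(p)
    logL = np.empty(C)
    counts = np.empty(C, dtype=np.int64)
    rhs_dev = 0.0
    kept = 0

    for it in range(n_iter):
        if permuted:
            # Fisher-Yates with the shared RNG stream
            for i in range(p - 1, 0, -1):
                j = np.random.randint(0, i + 1)
                tmp = order[i]
                order[i] = order[j]
                order[j] = tmp

        for idx in range(p):
            j = order[idx]
            djj = D[j]
            rj = r_star[j] + djj * beta[j]
            logL[0] = np.log(pi[0])
            for c in range(1, C):
                gs = gamma[c] * sig2b
                denom = sig2e + gs * djj
                logL[c] = np.log(pi[c]) + 0.5 * (
                    np.log(sig2e / denom) + rj * rj * gs / (sig2e * denom)
                )
            u = np.random.random()
            c_new = _categorical_from_logs(logL, u)
            if c_new == 0:
                b_new = 0.0
            else:
                l_jc = djj + sig2e / (gamma[c_new] * sig2b)
                b_new = rj / l_jc + np.random.standard_normal() * np.sqrt(sig2e / l_jc)
            comp[j] = c_new
            delta = b_new - beta[j]
            if delta != 0.0:
                s = indptr[j]
                w0 = win_start[j]
                nv = indptr[j + 1] - s
                sdj = sqrtD[j] * delta
                for k in range(nv):
                    r_star[w0 + k] -= sqrtD[w0 + k] * vals[s + k] * sdj
                beta[j] = b_new

        # sigma_beta^2 | .
        q = 0
        ssq = 0.0
        for j in range(p):
            if comp[j] > 0:
                q += 1
                ssq += beta[j] * beta[j] / gamma[comp[j]]
        df_b = nu_b + q
        sig2b = (ssq + nu_b * s2_b) / np.random.chisquare(df_b)

        # pi | .
        for c in range(C):
            counts[c] = 0
        for j in range(p):
            counts[comp[j]] += 1
        tot = 0.0
        for c in range(C):
            g = np.random.gamma(alpha[c] + counts[c], 1.0)
            pi[c] = g
            tot += g
        for c in range(C):
            pi[c] /= tot

        # sigma_eps^2 | .
        bdot = 0.0
        for j in range(p):
            bdot += beta[j] * (Xty[j] + r_star[j])
        sse = yty - bdot
        floor = 1e-12 * yty
        if sse < floor:
            sse = floor
        if not np.isfinite(sse):
            return (STATUS_DIVERGED, it, beta_sum, comp_counts, h2_samples,
                    pi_samples, s2b_samples, s2e_samples, h2_trace, nnz_trace,
                    beta_samples, rhs_dev)
        df_e = nu_e + n_bar
        sig2e = (sse + nu_e * s2_e) / np.random.chisquare(df_e)

        # h2
        sg = 0.0
        for j in range(p):
            sg += beta[j] * (Xty[j] - r_star[j])
        sig2g = sg / n_bar
        if sig2g < 0.0:
            sig2g = 0.0
        h2 = sig2g / (sig2g + sig2e)
        if (not np.isfinite(h2)) or h2 > 1.0:
            return (STATUS_DIVERGED, it, beta_sum, comp_counts, h2_samples,
                    pi_samples, s2b_samples, s2e_samples, h2_trace, nnz_trace,
                    beta_samples, rhs_dev)
        h2_trace[it] = h2
        nnz_trace[it] = q

        if rhs_check_every > 0 and (it + 1) % rhs_check_every == 0:
            # from-scratch r* = X'y - D^{1/2} B D^{1/2} beta via sparse columns
            r_fresh = Xty.copy()
            for j in range(p):
                if beta[j] != 0.0:
                    s = indptr[j]
                    w0 = win_start[j]
                    nv = indptr[j + 1] - s
                    sdj = sqrtD[j] * beta[j]
                    for k in range(nv):
                        r_fresh[w0 + k] -= sqrtD[w0 + k] * vals[s + k] * sdj
            scale = 0.0
            for j in range(p):
                a = abs(Xty[j])
                if a > scale:
                    scale = a
            if scale < 1.0:
                scale = 1.0
            for j in range(p):
                d = abs(r_fresh[j] - r_star[j]) / scale
                if d > rhs_dev:
                    rhs_dev = d

        if it >= burn_in and (it - burn_in) % thin == 0:
            beta_sum += beta
            for j in range(p):
                comp_counts[j, comp[j]] += 1.0
            h2_samples[kept] = h2
            for c in range(C):
                pi_samples[kept, c] = pi[c]
            s2b_samples[kept] = sig2b
            s2e_samples[kept] = sig2e
            if record_beta:
                for j in range(p):
                    beta_samples[kept, j] = beta[j]
            kept += 1

    return (STATUS_OK, n_iter, beta_sum, comp_counts, h2_samples, pi_samples,
            s2b_samples, s2e_samples, h2_trace, nnz_trace, beta_samples, rhs_dev)


def _default_s2_beta(stats: SufficientStats, mix: MixtureSpec) -> float:
    """Prior scale chosen so the implied genetic variance is half the
    phenotypic variance under the initial mixing proportions."""
    var_y = stats.yty / stats.n_bar
    pi = mix.pi_array()
    gamma = mix.gamma_array()
    mean_d = float(np.mean(stats.D_diag)) / stats.n_bar
    per_snp = float(np.sum(pi * gamma))
    denom = mean_d * stats.n_snps * per_snp
    if denom <= 0:
        return var_y
    return 0.5 * var_y / denom


class SBayesR(BaseEstimator):
    """Summary-statistics Bayesian multiple regression (mixture prior).

    A scikit-learn style estimator: hyperparameters are constructor
    arguments, :meth:`fit` consumes the reconstructed sufficient statistics
    and a sparse LD reference, and the fitted state (posterior means,
    inclusion probabilities, heritability draws) is exposed through
    trailing-underscore attributes.  :meth:`predict` scores genotype panels
    with the posterior-mean effects.

    Parameters
    ----------
    gamma, pi_init, dirichlet_alpha : mixture prior (see MixtureSpec)
    n_iter, burn_in, thin, seed : chain control
    nu_beta, S2_beta_init, nu_eps, S2_eps_init : scaled-inv-chi^2 priors
    update_order : 'fixed' genomic order or seeded 'permuted' sweeps
    rhs_check_every : if > 0, recompute r* from scratch at this period and
        track the maximum relative deviation (``rhs_max_rel_dev_``)
    record_beta_samples : keep the thinned beta draws (memory: n_kept x p)
    """

    def __init__(
        self,
        gamma=(0.0, 0.01, 0.1, 1.0),
        pi_init=(0.95, 0.02, 0.02, 0.01),
        dirichlet_alpha=1.0,
        n_iter=10000,
        burn_in=4000,
        thin=10,
        seed=0,
        nu_beta=4.0,
        S2_beta_init=None,
        nu_eps=4.0,
        S2_eps_init=None,
        update_order="fixed",
        rhs_check_every=0,
        record_beta_samples=False,
    ):
        self.gamma = gamma
        self.pi_init = pi_init
        self.dirichlet_alpha = dirichlet_alpha
        self.n_iter = n_iter
        self.burn_in = burn_in
        self.thin = thin
        self.seed = seed
        self.nu_beta = nu_beta
        self.S2_beta_init = S2_beta_init
        self.nu_eps = nu_eps
        self.S2_eps_init = S2_eps_init
        self.update_order = update_order
        self.rhs_check_every = rhs_check_every
        self.record_beta_samples = record_beta_samples

    def _mix(self) -> MixtureSpec:
        return MixtureSpec(
            gamma=tuple(self.gamma),
            pi_init=tuple(self.pi_init),
            dirichlet_alpha=self.dirichlet_alpha,
        )

    def _chain(self) -> ChainConfig:
        return ChainConfig(
            n_iter=self.n_iter,
            burn_in=self.burn_in,
            thin=self.thin,
            seed=self.seed,
            nu_beta=self.nu_beta,
            S2_beta_init=self.S2_beta_init,
            nu_eps=self.nu_eps,
            S2_eps_init=self.S2_eps_init,
            update_order=self.update_order,
            rhs_check_every=self.rhs_check_every,
        )

    def fit(self, stats: SufficientStats, ld: SparseLDMatrix):
        """Run the Gibbs sampler.

        ``stats`` and ``ld`` must cover the same SNPs in the same order
        (align the summary dataset to the LD reference first).
        """
        mix = self._mix()
        cfg = self._chain()
        if stats.n_snps != ld.n_snps:
            raise ValueError(
                f"stats ({stats.n_snps} SNPs) and LD matrix ({ld.n_snps}) disagree"
            )
        var_y = stats.yty / stats.n_bar
        s2_b = cfg.S2_beta_init if cfg.S2_beta_init is not None else _default_s2_beta(stats, mix)
        s2_e = cfg.S2_eps_init if cfg.S2_eps_init is not None else var_y

        out = _sbayesr_kernel(
            cfg.seed,
            cfg.n_iter,
            cfg.burn_in,
            cfg.thin,
            stats.D_diag,
            ld.window_start,
            ld.indptr,
            ld.values,
            stats.Xty,
            float(stats.yty),
            float(stats.n_bar),
            mix.gamma_array(),
            mix.pi_array(),
            mix.alpha_array(),
            float(cfg.nu_beta),
            float(s2_b),
            float(cfg.nu_eps),
            float(s2_e),
            float(s2_b),
            float(s2_e),
            cfg.update_order == "permuted",
            cfg.rhs_check_every,
            self.record_beta_samples,
        )
        (status, it, beta_sum, comp_counts, h2_s, pi_s, s2b_s, s2e_s,
         h2_trace, nnz_trace, beta_samples, rhs_dev) = out
        if status == STATUS_DIVERGED:
            raise DivergenceError(
                f"sampler diverged at iteration {it}: h2 sample > 1 or "
                "non-finite state; check summary-statistic QC (sample-size "
                "filter, allele frequency consistency with the LD reference)"
            )
        n_kept = h2_s.shape[0]
        beta_mean_model = beta_sum / n_kept
        freq = ld.info["freq"].to_numpy(dtype=float)
        if stats.scaled:
            per_allele = beta_mean_model / np.sqrt(2.0 * freq * (1.0 - freq))
        else:
            per_allele = beta_mean_model.copy()
        comp_prob = comp_counts / n_kept
        summary = PosteriorSummary(
            beta_mean=per_allele,
            beta_mean_model_scale=beta_mean_model,
            pip=1.0 - comp_prob[:, 0],
            comp_prob=comp_prob,
            h2_samples=h2_s,
            pi_samples=pi_s,
            sigma2_beta_samples=s2b_s,
            sigma2_eps_samples=s2e_s,
            h2_trace=h2_trace,
            nnz_trace=nnz_trace,
            beta_samples=beta_samples if self.record_beta_samples else None,
            rhs_max_rel_dev=float(rhs_dev),
        )
        self.summary_ = summary
        self.beta_mean_ = summary.beta_mean
        self.pip_ = summary.pip
        self.comp_prob_ = summary.comp_prob
        self.h2_samples_ = summary.h2_samples
        self.h2_mean_ = summary.h2_mean
        self.pi_mean_ = summary.pi_samples.mean(axis=0)
        self.snp_info_ = ld.info.copy()
        self.rhs_max_rel_dev_ = summary.rhs_max_rel_dev
        logger.info(
            "SBayesR fit: %d SNPs, h2_mean=%.4f (95%% CI %.4f-%.4f), "
            "mean nonzero=%.0f",
            stats.n_snps,
            summary.h2_mean,
            *summary.h2_credible_interval(),
            float(nnz_trace[cfg.burn_in :].mean()),
        )
        return self

    def predict(self, G) -> np.ndarray:
        """Polygenic score for a genotype panel using posterior-mean effects."""
        from .evaluate import compute_prs
        import pandas as pd

        effects = pd.DataFrame(
            {
                "snp_id": self.snp_info_["snp_id"],
                "A1": self.snp_info_["A1"],
                "beta": self.beta_mean_,
            }
        )
        return compute_prs(G, effects)


def run_sbayesr(
    stats: SufficientStats,
    ld: SparseLDMatrix,
    mix: MixtureSpec | None = None,
    cfg: ChainConfig | None = None,
    record_beta_samples: bool = False,
) -> PosteriorSummary:
    """Functional wrapper over :class:`SBayesR` returning the posterior summary."""
    mix = mix or MixtureSpec()
    cfg = cfg or ChainConfig()
    est = SBayesR(
        gamma=mix.gamma,
        pi_init=mix.pi_init,
        dirichlet_alpha=mix.dirichlet_alpha,
        record_beta_samples=record_beta_samples,
        **{f.name: getattr(cfg, f.name) for f in dc_fields(ChainConfig)},
    )
    est.fit(stats, ld)
    return est.summary_
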