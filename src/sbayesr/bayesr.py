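"""Individual-level BayesR: the same hierarchical model as the
summary-level sampler, fitted directly to (genotypes, phenotypes).

The Gibbs sweep maintains the residual vector w = y - X beta on
individuals, so r_j = x_j'w + x_j'x_j beta_j uses exact inner products
rather than an LD reference.  With the LD matrix and X'X diagonal computed
exactly from the GWAS panel, the summary-level sampler and this one are the
same Markov chain; that equivalence is exercised in the test suite, which
is why this module deliberately shares no sampling code with
:mod:`sbayesr.gibbs` (only the configuration dataclasses).
"""

from __future__ import annotations

import logging

import numpy as np
from numba import njit
from sklearn.base import BaseEstimator, RegressorMixin

from .exceptions import DivergenceError
from .gibbs import (
    STATUS_DIVERGED,
    STATUS_OK,
    ChainConfig,
    MixtureSpec,
    PosteriorSummary,
)
from .plinkio import GenotypeMatrix

logger = logging.getLogger(__name__)


@njit(cache=True)
def _pick_component(logL, u):
    C = logL.shape[0]
    m = logL[0]
    for c in range(1, C):
        if logL[c] > m:
            m = logL[c]
    tot = 0.0
    w = np.empty(C)
    for c in range(C):
        w[c] = np.exp(logL[c] - m)
        tot += w[c]
    acc = 0.0
    for c in range(C):
        acc += w[c] / tot
        if u <= acc:
            return c
    return C - 1


@njit(cache=True)
def _bayesr_kernel(
    seed,
    n_iter,
    burn_in,
    thin,
    X,  # (n, p) centred (and optionally scaled), Fortran order
    y,  # centred phenotype
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
    resid_check_every,
    record_beta,
):
    n, p = X.shape
    C = gamma.shape[0]
    np.random.seed(seed)

    xx = np.empty(p)
    for j in range(p):
        s = 0.0
        for i in range(n):
            s += X[i, j] * X[i, j]
        xx[j] = s

    beta = np.zeros(p)
    comp = np.zeros(p, dtype=np.int64)
    pi = pi0.copy()
    sig2b = sig2b0
    sig2e = sig2e0
    resid = y.copy()

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
    resid_dev = 0.0
    kept = 0

    for it in range(n_iter):
        if permuted:
            for i in range(p - 1, 0, -1):
                j = np.random.randint(0, i + 1)
                tmp = order[i]
                order[i] = order[j]
                order[j] = tmp

        for idx in range(p):
            j = order[idx]
            djj = xx[j]
            dot = 0.0
            for i in range(n):
                dot += X[i, j] * resid[i]
            rj = dot + djj * beta[j]
            logL[0] = np.log(pi[0])
            for c in range(1, C):
                gs = gamma[c] * sig2b
                denom = sig2e + gs * djj
                logL[c] = np.log(pi[c]) + 0.5 * (
                    np.log(sig2e / denom) + rj * rj * gs / (sig2e * denom)
                )
            u = np.random.random()
            c_new = _pick_component(logL, u)
            if c_new == 0:
                b_new = 0.0
            else:
                l_jc = djj + sig2e / (gamma[c_new] * sig2b)
                b_new = rj / l_jc + np.random.standard_normal() * np.sqrt(sig2e / l_jc)
            comp[j] = c_new
            delta = b_new - beta[j]
            if delta != 0.0:
                for i in range(n):
                    resid[i] -= X[i, j] * delta
                beta[j] = b_new

        q = 0
        ssq = 0.0
        for j in range(p):
            if comp[j] > 0:
                q += 1
                ssq += beta[j] * beta[j] / gamma[comp[j]]
        sig2b = (ssq + nu_b * s2_b) / np.random.chisquare(nu_b + q)

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

        sse = 0.0
        for i in range(n):
            sse += resid[i] * resid[i]
        if not np.isfinite(sse):
            return (STATUS_DIVERGED, it, beta_sum, comp_counts, h2_samples,
                    pi_samples, s2b_samples, s2e_samples, h2_trace, nnz_trace,
                    beta_samples, resid_dev)
        sig2e = (sse + nu_e * s2_e) / np.random.chisquare(nu_e + float(n))

        # genetic variance: population variance of X beta = y - resid
        sg = 0.0
        for i in range(n):
            gv = y[i] - resid[i]
            sg += gv * gv
        sig2g = sg / n
        h2 = sig2g / (sig2g + sig2e)
        if (not np.isfinite(h2)) or h2 > 1.0:
            return (STATUS_DIVERGED, it, beta_sum, comp_counts, h2_samples,
                    pi_samples, s2b_samples, s2e_samples, h2_trace, nnz_trace,
                    beta_samples, resid_dev)
        h2_trace[it] = h2
        nnz_trace[it] = q

        if resid_check_every > 0 and (it + 1) % resid_check_every == 0:
            scale = 0.0
            for i in range(n):
                a = abs(y[i])
                if a > scale:
                    scale = a
            if scale < 1.0:
                scale = 1.0
            for i in range(n):
                fitted = 0.0
                for j in range(p):
                    if beta[j] != 0.0:
                        fitted += X[i, j] * beta[j]
                d = abs((y[i] - fitted) - resid[i]) / scale
                if d > resid_dev:
                    resid_dev = d

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
            s2b_samples, s2e_samples, h2_trace, nnz_trace, beta_samples, resid_dev)


class BayesR(RegressorMixin, BaseEstimator):
    """Individual-level BayesR estimator (mixture-of-normals prior).

    ``fit(X, y)`` accepts a :class:`GenotypeMatrix` (centred internally,
    scaled when ``scale_genotypes``) or a plain ndarray assumed already
    centred.  ``y`` is centred internally.  Fitted attributes mirror
    :class:`sbayesr.gibbs.SBayesR`.
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
        resid_check_every=0,
        record_beta_samples=False,
        scale_genotypes=False,
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
        self.resid_check_every = resid_check_every
        self.record_beta_samples = record_beta_samples
        self.scale_genotypes = scale_genotypes

    def fit(self, X, y):
        mix = MixtureSpec(
            gamma=tuple(self.gamma),
            pi_init=tuple(self.pi_init),
            dirichlet_alpha=self.dirichlet_alpha,
        )
        cfg = ChainConfig(
            n_iter=self.n_iter,
            burn_in=self.burn_in,
            thin=self.thin,
            seed=self.seed,
            nu_beta=self.nu_beta,
            S2_beta_init=self.S2_beta_init,
            nu_eps=self.nu_eps,
            S2_eps_init=self.S2_eps_init,
            update_order=self.update_order,
        )
        freq = None
        if isinstance(X, GenotypeMatrix):
            self._panel_info = X.snp_table()
            freq = X.freq
            Xmat = X.standardized(scale=self.scale_genotypes)
        else:
            self._panel_info = None
            Xmat = np.asarray(X, dtype=np.float64)
        if Xmat.ndim != 2 or Xmat.shape[0] == 0 or Xmat.shape[1] == 0:
            raise ValueError("X must be a non-empty n x p matrix")
        y = np.asarray(y, dtype=np.float64)
        y = y - y.mean()
        if y.shape[0] != Xmat.shape[0]:
            raise ValueError("X and y disagree on the number of individuals")
        n, p = Xmat.shape
        var_y = float(y @ y) / n
        if var_y == 0:
            var_y = 1.0
        pi = mix.pi_array()
        g = mix.gamma_array()
        xx_mean = float(np.mean(np.sum(Xmat**2, axis=0))) / n
        denom = xx_mean * p * float(np.sum(pi * g))
        s2_b = (
            cfg.S2_beta_init
            if cfg.S2_beta_init is not None
            else (0.5 * var_y / denom if denom > 0 else var_y)
        )
        s2_e = cfg.S2_eps_init if cfg.S2_eps_init is not None else var_y

        out = _bayesr_kernel(
            cfg.seed,
            cfg.n_iter,
            cfg.burn_in,
            cfg.thin,
            np.asfortranarray(Xmat),
            y,
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
            self.resid_check_every,
            self.record_beta_samples,
        )
        (status, it, beta_sum, comp_counts, h2_s, pi_s, s2b_s, s2e_s,
         h2_trace, nnz_trace, beta_samples, resid_dev) = out
        if status == STATUS_DIVERGED:
            raise DivergenceError(f"BayesR sampler diverged at iteration {it}")
        n_kept = h2_s.shape[0]
        beta_mean_model = beta_sum / n_kept
        if self.scale_genotypes and freq is not None:
            per_allele = beta_mean_model / np.sqrt(2.0 * freq * (1.0 - freq))
        else:
            per_allele = beta_mean_model.copy()
        comp_prob = comp_counts / n_kept
        self.summary_ = PosteriorSummary(
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
            rhs_max_rel_dev=float(resid_dev),
        )
        self.beta_mean_ = self.summary_.beta_mean
        self.pip_ = self.summary_.pip
        self.h2_samples_ = h2_s
        self.h2_mean_ = self.summary_.h2_mean
        self.resid_max_rel_dev_ = float(resid_dev)
        logger.info(
            "BayesR fit: n=%d, p=%d, h2_mean=%.4f", n, p, self.h2_mean_
        )
        return self

    def predict(self, X) -> np.ndarray:
        """Genetic value prediction for centred genotypes or a panel."""
        if isinstance(X, GenotypeMatrix):
            from .evaluate import compute_prs
            import pandas as pd

            effects = pd.DataFrame(
                {
                    "snp_id": self._panel_info["snp_id"],
                    "A1": self._panel_info["A1"],
                    "beta": self.beta_mean_,
                }
            )
            return compute_prs(X, effects)
        return np.asarray(X, dtype=float) @ self.summary_.beta_mean_model_scale


def run_bayesr(
    X,
    y,
    mix: MixtureSpec | None = None,
    cfg: ChainConfig | None = None,
    record_beta_samples: bool = False,
    scale_genotypes: bool = False,
) -> PosteriorSummary:
    """Functional wrapper over :class:`BayesR` returning the posterior summary."""
    mix = mix or MixtureSpec()
    cfg = cfg or ChainConfig()
    est = BayesR(
        gamma=mix.gamma,
        pi_init=mix.pi_init,
        dirichlet_alpha=mix.dirichlet_alpha,
        n_iter=cfg.n_iter,
        burn_in=cfg.burn_in,
        thin=cfg.thin,
        seed=cfg.seed,
        nu_beta=cfg.nu_beta,
        S2_beta_init=cfg.S2_beta_init,
        nu_eps=cfg.nu_eps,
        S2_eps_init=cfg.S2_eps_init,
        update_order=cfg.update_order,
        resid_check_every=cfg.rhs_check_every,
        record_beta_samples=record_beta_samples,
        scale_genotypes=scale_genotypes,
    )
    est.fit(X, y)
    return est.summary_
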