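"""Polygenic-score computation and prediction-accuracy statistics.

Covers PRS scoring on allele counts, prediction R^2 with the calibration
slope, AUC for binary traits (Mann-Whitney formulation), the
observed-to-liability-scale heritability transformation and nested-model
ANOVA comparison of two predictors.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .plinkio import GenotypeMatrix
from .simulate import LiabilityConfig


class PRSResult(NamedTuple):
    score: np.ndarray
    phenotype: np.ndarray
    scale: str  # 'quantitative' | 'binary'


class PredictionAccuracy(NamedTuple):
    r2: float
    slope: float


def compute_prs(G: GenotypeMatrix, effects: pd.DataFrame) -> np.ndarray:
    """Score individuals: score_i = sum_j count_ij(A1_j) * beta_j.

    ``effects`` needs columns ``snp_id, A1, beta``.  Effects whose A1
    matches the panel's A2 are counted on the flipped allele
    (count -> 2 - count); other allele mismatches and SNPs absent from the
    panel are ignored.  Missing genotypes contribute the expected dosage
    2 * freq_j * beta_j.
    """
    panel = pd.DataFrame(
        {
            "snp_id": G.snp_id,
            "col": np.arange(G.p),
            "panel_A1": G.A1,
            "panel_A2": G.A2,
        }
    )
    m = effects.merge(panel, on="snp_id", how="inner")
    same = (m["A1"] == m["panel_A1"]).to_numpy()
    flip = (m["A1"] == m["panel_A2"]).to_numpy() & ~same
    m = m[same | flip].reset_index(drop=True)
    flip = (m["A1"] == m["panel_A2"]).to_numpy() & (m["A1"] != m["panel_A1"]).to_numpy()
    cols = m["col"].to_numpy()
    beta = m["beta"].to_numpy(dtype=float)

    dose = G.genotypes[:, cols]
    freq = np.nanmean(dose, axis=0) / 2.0
    miss = np.isnan(dose)
    if miss.any():
        dose = np.where(miss, 2.0 * freq, dose)
    dose = np.where(flip, 2.0 - dose, dose)
    return dose @ beta


def prediction_r2(y: np.ndarray, prs: np.ndarray) -> PredictionAccuracy:
    """Squared Pearson correlation of phenotype and PRS, plus the
    calibration slope of the regression of y on the PRS."""
    y = np.asarray(y, dtype=float)
    prs = np.asarray(prs, dtype=float)
    if y.shape != prs.shape:
        raise ValueError("y and prs must have equal length")
    vy = y.var()
    vp = prs.var()
    if vp == 0 or vy == 0:
        return PredictionAccuracy(r2=0.0, slope=0.0)
    cov = np.mean((y - y.mean()) * (prs - prs.mean()))
    return PredictionAccuracy(r2=float(cov**2 / (vy * vp)), slope=float(cov / vp))


def auc(y_binary: np.ndarray, prs: np.ndarray) -> float:
    """Area under the ROC curve via the Mann-Whitney U statistic.

    Ties between case and control scores count one half.
    """
    y = np.asarray(y_binary)
    prs = np.asarray(prs, dtype=float)
    cases = y == 1
    n1 = int(cases.sum())
    n0 = int((~cases).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC needs at least one case and one control")
    ranks = sps.rankdata(prs)
    u = ranks[cases].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def liability_h2(h2_obs: float, K: float, P: float | None = None) -> float:
    """Transform an observed-scale h2 to the liability scale.

    h2_liab = h2_obs * K^2 (1-K)^2 / (z^2 P (1-P)) with z the standard
    normal density at the threshold Phi^{-1}(1-K); ``P`` (sample case
    proportion) defaults to K for population samples.
    """
    cfg = LiabilityConfig(K=K, P=P)
    P = K if P is None else P
    if not (0.0 < P < 1.0):
        raise ValueError("P must lie in (0, 1)")
    z = cfg.z
    return float(h2_obs * K**2 * (1.0 - K) ** 2 / (z**2 * P * (1.0 - P)))


class ModelComparison(NamedTuple):
    f_stat: float
    p_value: float
    partial_r2: float


def compare_models(y: np.ndarray, prs_low: np.ndarray, prs_high: np.ndarray) -> ModelComparison:
    """Nested-model ANOVA: y ~ prs_low (null) vs y ~ prs_low + prs_high.

    Returns the F statistic, its p value (1 numerator df) and the partial
    R^2 = (RSS0 - RSS1) / RSS0.
    """
    y = np.asarray(y, dtype=float)
    n = y.shape[0]
    X0 = np.column_stack([np.ones(n), prs_low])
    X1 = np.column_stack([np.ones(n), prs_low, prs_high])
    rss0 = _rss(X0, y)
    rss1 = _rss(X1, y)
    df_resid = n - X1.shape[1]
    if df_resid <= 0:
        raise ValueError("too few observations for the nested-model F test")
    num = max(rss0 - rss1, 0.0)
    if rss1 <= 0:
        f = np.inf if num > 0 else 0.0
    else:
        f = (num / 1.0) / (rss1 / df_resid)
    p = float(sps.f.sf(f, 1, df_resid)) if np.isfinite(f) else 0.0
    partial = num / rss0 if rss0 > 0 else 0.0
    return ModelComparison(f_stat=float(f), p_value=p, partial_r2=float(partial))


def _rss(X: np.ndarray, y: np.ndarray) -> float:
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    return float(resid @ resid)
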