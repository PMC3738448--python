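"""Winner's-curse selection-bias estimation at a selected SNP.

``truncated_normal_excess`` is the closed-form selection bias of a normal
statistic selected by a one-sided threshold; it serves as the analytic
oracle for the bootstrap estimator.  ``bootstrap_delta`` estimates the bias
from individual-level data by resampling: in each bootstrap resample the
selection rule is re-applied (detection copy) and the same SNP's statistic
is recomputed in the out-of-resample individuals (estimation copy), whose
expectation is free of selection.  The average detection-minus-estimation
difference over resamples in which the rule fires estimates the bias.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import special

logger = logging.getLogger(__name__)

__all__ = [
    "truncated_normal_excess", "conditional_mean_shift",
    "ThresholdSelection", "RankSelection", "bootstrap_delta",
]


def truncated_normal_excess(mu: float, z_crit: float) -> float:
    """E[Z | Z > z_crit] - mu for Z ~ N(mu, 1).

    Equals the inverse Mills ratio phi(a)/(1-Phi(a)) at a = z_crit - mu,
    evaluated through the scaled complementary error function so the
    far-tail ratio stays finite.
    """
    if math.isinf(z_crit) and z_crit < 0:
        return 0.0
    a = z_crit - mu
    # phi(a) / (1 - Phi(a)) = sqrt(2/pi) / erfcx(a / sqrt(2))
    return math.sqrt(2.0 / math.pi) / special.erfcx(a / math.sqrt(2.0))


def conditional_mean_shift(delta: float, stat_corr: float) -> float:
    """Expected inflation of a correlated statistic given selection.

    The tag's selection bias ``delta`` propagates to SNP i in proportion to
    the correlation between the two test statistics.
    """
    if abs(stat_corr) > 1:
        raise ValueError(f"stat_corr={stat_corr} outside [-1, 1]")
    return stat_corr * delta


@dataclass(frozen=True)
class ThresholdSelection:
    """Selection by a |Z| (or signed Z) threshold.

    ``snp_index`` restricts the rule to one SNP (the GWAS tag); ``None``
    applies it to the region-wide maximum, in which case the selected SNP
    is the one attaining the maximum.
    """
    z_crit: float
    snp_index: int | None = None
    two_sided: bool = True


@dataclass(frozen=True)
class RankSelection:
    """Selection of the top-ranked SNP (always fires)."""
    k: int = 1


def _trend_stats_weighted(g: np.ndarray, y: np.ndarray,
                          w: np.ndarray) -> np.ndarray:
    """Score/trend Z per SNP under resampling weights.

    ``g`` is n x m dosages with NaN for missing, ``y`` binary phenotype,
    ``w`` a B x n matrix of non-negative resample weights (multinomial
    counts, or an out-of-bag indicator).  Complete cases per SNP.  Returns
    B x m statistics; cells the weights leave empty or monomorphic give 0.
    """
    n, m = g.shape
    obs = ~np.isnan(g)
    g0 = np.where(obs, g, 0.0)
    z = np.empty((w.shape[0], m))
    for j in range(m):
        o = obs[:, j]
        wj = w[:, o]
        xj = g0[o, j]
        yj = y[o]
        sw = wj.sum(axis=1)
        sy = wj @ yj
        sx = wj @ xj
        sxy = wj @ (xj * yj)
        sxx = wj @ (xj * xj)
        with np.errstate(divide="ignore", invalid="ignore"):
            ybar = sy / sw
            u = sxy - ybar * sx
            v = ybar * (1 - ybar) * (sxx - sx * sx / sw)
            z[:, j] = np.where(v > 0, u / np.sqrt(np.maximum(v, 1e-300)), 0.0)
    return z


def trend_scan(g: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Score/trend Z per SNP on complete cases (single dataset)."""
    return _trend_stats_weighted(g, y, np.ones((1, g.shape[0])))[0]


def bootstrap_delta(genotypes: np.ndarray, phenotype: np.ndarray,
                    selection: ThresholdSelection | RankSelection,
                    b: int = 400, seed: int | np.random.Generator | None = None,
                    ) -> tuple[float, float, int]:
    """Bootstrap estimate of the selection bias Delta at the selected SNP.

    For each of ``b`` resamples of individuals (with replacement): all SNP
    statistics are recomputed in the resample, the selection rule is
    re-applied to identify the selected SNP and whether the rule fires; the
    detection statistic is that SNP's resample |Z|, the estimation
    statistic the same SNP's Z among out-of-resample individuals, rescaled
    to the full-sample Z scale by sqrt(n_obs/n_oob).  Resamples where the
    rule does not fire are dropped.

    Returns
    -------
    (delta_hat, se, b_effective)
        Bias estimate (floored at 0), its Monte-Carlo standard error and
        the number of resamples in which the rule fired.
    """
    g = np.asarray(genotypes, dtype=float)
    y = np.asarray(phenotype, dtype=float)
    if g.ndim == 1:
        g = g[:, None]
    n, m = g.shape
    if y.shape[0] != n:
        raise ValueError("genotypes and phenotype lengths differ")
    if b < 100:
        raise ValueError(f"b={b} bootstrap replicates is below 100")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)

    w = rng.multinomial(n, np.full(n, 1.0 / n), size=b).astype(float)
    z_in = _trend_stats_weighted(g, y, w)
    oob = (w == 0).astype(float)
    z_oob = _trend_stats_weighted(g, y, oob)

    n_obs_full = (~np.isnan(g)).sum(axis=0)          # per SNP
    n_oob_snp = oob @ (~np.isnan(g)).astype(float)   # B x m

    if isinstance(selection, ThresholdSelection):
        key = np.abs(z_in) if selection.two_sided else z_in
        if selection.snp_index is not None:
            sel = np.full(b, selection.snp_index)
            fires = key[np.arange(b), sel] > selection.z_crit
        else:
            sel = key.argmax(axis=1)
            fires = key[np.arange(b), sel] > selection.z_crit
    else:
        key = np.abs(z_in)
        sel = key.argmax(axis=1)
        fires = np.ones(b, dtype=bool)

    if not fires.any():
        raise RuntimeError(
            "selection unreplicable: the rule fired in no bootstrap "
            "resample; supply delta manually")
    dropped = int(b - fires.sum())
    if dropped:
        logger.info("bootstrap_delta: dropped %d/%d resamples where the "
                    "selection rule did not fire", dropped, b)

    idx = np.flatnonzero(fires)
    s = sel[idx]
    det = np.abs(z_in[idx, s])
    sign = np.sign(z_in[idx, s])
    scale = np.sqrt(n_obs_full[s] / np.maximum(n_oob_snp[idx, s], 1.0))
    est = sign * z_oob[idx, s] * scale
    diffs = det - est
    b_eff = len(idx)
    delta = float(max(diffs.mean(), 0.0))
    se = float(diffs.std(ddof=1) / math.sqrt(b_eff)) if b_eff > 1 else math.inf
    return delta, se, b_eff
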