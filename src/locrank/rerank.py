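"""The re-ranking statistic and region-wide re-ranking.

The corrected statistic for a sequenced/imputed SNP ``S_i`` is

    T~_Si = (T_Si - kappa_i * Delta_G) / (rho_Si * sqrt(c_Si))

where ``Delta_G`` is the winner's-curse selection bias at the GWAS tag,
``kappa_i = r_GSi * c_GSi / sqrt(c_G * c_Si)`` is the correlation between
the tag's and the SNP's test statistics (genotype correlation scaled by the
individual and joint call rates), ``rho_Si`` the genotyping accuracy and
``c_Si`` the call rate.  The numerator removes the part of the tag's
selection bias that propagates to SNP i through LD; the denominator undoes
the attenuation ``E[T_Si] proportional to rho_Si * sqrt(c_Si)`` caused by
the SNP's own genotyping error and missingness.  At perfect data the
statistic reduces to the naive one.

The meta-analysis variant divides the fixed-effect combined Z by the
weight-squared-averaged imputation accuracy across studies.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np

from .records import RankedSnp, RegionSnp, StudyStat, TagSnp

__all__ = [
    "stat_correlation_factor", "rerank_statistic", "rerank_region",
    "meta_z", "meta_rho", "rerank_meta", "leave_one_out_scan",
]


def stat_correlation_factor(tag_corr_obs: float, joint_call_rate: float,
                            call_rate_tag: float, call_rate_snp: float) -> float:
    """Correlation between the tag's and the SNP's test statistics.

    Equals the observed-genotype correlation scaled by
    ``c_GSi / sqrt(c_G * c_Si)``: with partially overlapping complete-case
    samples only the jointly observed fraction contributes covariance.
    """
    if joint_call_rate > min(call_rate_tag, call_rate_snp) + 1e-12:
        raise ValueError("joint call rate exceeds a marginal call rate")
    return tag_corr_obs * joint_call_rate / math.sqrt(
        call_rate_tag * call_rate_snp)


def rerank_statistic(snp: RegionSnp, tag: TagSnp) -> float:
    """Corrected (re-ranking) statistic for one SNP given the tag.

    Raises
    ------
    ValueError
        If the SNP's accuracy or call rate is zero (no information about
        the true genotype survives, the statistic cannot be de-attenuated).
    """
    if snp.rho_hat == 0 or snp.call_rate == 0:
        raise ValueError(
            f"{snp.snp_id}: statistic not re-rankable, accuracy/call-rate "
            "degenerate (rho_hat or call_rate is 0)")
    kappa = stat_correlation_factor(
        snp.tag_corr_obs, snp.joint_call_rate, tag.call_rate_g, snp.call_rate)
    return (snp.t_obs - kappa * tag.delta_hat) / (
        snp.rho_hat * math.sqrt(snp.call_rate))


def _tag_rerank_statistic(tag: TagSnp) -> float:
    # The tag competes with itself fully exposed to its selection bias
    # (kappa = 1); its own array genotyping accuracy rho_g is ~1 for GWAS
    # arrays but is honoured if supplied.
    if tag.rho_g == 0 or tag.call_rate_g == 0:
        raise ValueError(
            f"{tag.snp_id}: statistic not re-rankable, accuracy/call-rate "
            "degenerate")
    return (tag.t_gobs - tag.delta_hat) / (
        tag.rho_g * math.sqrt(tag.call_rate_g))


def _ranks(keys: list[tuple]) -> list[int]:
    # Deterministic dense ranking, 1-based; keys sort best-first.
    order = sorted(range(len(keys)), key=lambda i: keys[i])
    ranks = [0] * len(keys)
    for r, i in enumerate(order, start=1):
        ranks[i] = r
    return ranks


def rerank_region(snps: Sequence[RegionSnp], tag: TagSnp | None = None,
                  include_tag: bool = False) -> list[RankedSnp]:
    """Rank a region by |T| (naive) and by |T~| (re-ranked).

    Ties are broken deterministically by (larger accuracy, smaller
    position, lexicographic id) so the emitted ranks are a permutation of
    1..M.  When ``include_tag`` is set, the tag joins the competition with
    ``(T_Gobs - Delta_G) / (rho_G * sqrt(c_G))``.
    """
    if len(snps) == 0:
        raise ValueError("rerank_region needs at least one SNP")
    ids = [s.snp_id for s in snps] + ([tag.snp_id] if include_tag else [])
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate snp_ids in region")
    if tag is None:
        if include_tag:
            raise ValueError("include_tag requires a tag")
        tag = TagSnp(snp_id="__tag__", t_gobs=0.0)

    t_obs = [s.t_obs for s in snps]
    t_rr = [rerank_statistic(s, tag) for s in snps]
    tie = [(-s.rho_hat,
            s.position if s.position is not None else math.inf,
            s.snp_id) for s in snps]
    if include_tag:
        t_obs.append(tag.t_gobs)
        t_rr.append(_tag_rerank_statistic(tag))
        tie.append((-tag.rho_g, math.inf, tag.snp_id))
        ids = ids  # tag id already appended above

    naive = _ranks([(-abs(t),) + tb for t, tb in zip(t_obs, tie)])
    rer = _ranks([(-abs(t),) + tb for t, tb in zip(t_rr, tie)])
    return [RankedSnp(snp_id=i, t_obs=t, t_rerank=tr,
                      naive_rank=nr, rerank_rank=rr)
            for i, t, tr, nr, rr in zip(ids, t_obs, t_rr, naive, rer)]


# ---------------------------------------------------------------------------
# meta-analysis

def meta_z(studies: Sequence[StudyStat]) -> float:
    """Fixed-effect combined statistic ``sum(w_j Z_j) / sqrt(sum(w_j^2))``."""
    if len(studies) == 0:
        raise ValueError("meta_z needs at least one study")
    w = np.array([s.weight for s in studies])
    z = np.array([s.z for s in studies])
    return float(w @ z / math.sqrt(float(w @ w)))


def meta_rho(studies: Sequence[StudyStat], weighting: str = "w2") -> float:
    """Correlation between the error-free and the observed meta statistic.

    With independent per-study genotyping errors the covariance between the
    two combined statistics accumulates ``w_j^2 rho_j``, hence the
    weight-squared average ``sum(w_j^2 rho_j) / sum(w_j^2)``.  ``weighting=
    'w'`` switches to the plain weighted average for sensitivity analysis.
    """
    if len(studies) == 0:
        raise ValueError("meta_rho needs at least one study")
    w = np.array([s.weight for s in studies])
    r = np.array([s.rho for s in studies])
    if weighting == "w2":
        w = w * w
    elif weighting != "w":
        raise ValueError(f"weighting={weighting!r} must be 'w' or 'w2'")
    return float(w @ r / w.sum())


def rerank_meta(z_meta: float, rho_meta: float) -> float:
    """Meta-analysis re-ranking statistic: observed Z divided by accuracy."""
    if rho_meta == 0:
        raise ValueError("rho_meta is 0: statistic not re-rankable")
    if not 0 < rho_meta <= 1:
        raise ValueError(f"rho_meta={rho_meta} outside (0, 1]")
    return z_meta / rho_meta


def leave_one_out_scan(per_snp_studies: dict[str, Sequence[StudyStat]],
                       weighting: str = "w2"):
    """Leave-one-study-out heterogeneity diagnostic for meta re-ranking.

    For every study, recompute each SNP's combined Z, accuracy and
    re-ranking statistic without that study, and report the SNPs' naive and
    re-ranked ranks (1 = most significant, by |statistic|).

    Returns a :class:`pandas.DataFrame` with columns ``study_dropped``
    (``None`` row carries the all-study ranks), ``snp_id``, ``meta_z``,
    ``meta_rho``, ``t_rerank``, ``naive_rank`` and ``rerank_rank``.
    """
    import pandas as pd

    study_ids = sorted({s.study_id for ss in per_snp_studies.values()
                        for s in ss})
    if len(study_ids) < 2:
        raise ValueError("leave_one_out_scan needs at least two studies")

    def one_pass(drop: str | None):
        rows = []
        for snp_id, studies in per_snp_studies.items():
            kept = [s for s in studies if s.study_id != drop]
            if not kept:
                continue
            z = meta_z(kept)
            r = meta_rho(kept, weighting=weighting)
            rows.append((snp_id, z, r, rerank_meta(z, r)))
        df = pd.DataFrame(rows, columns=["snp_id", "meta_z", "meta_rho",
                                         "t_rerank"])
        df["naive_rank"] = (-df["meta_z"].abs()).rank(method="first").astype(int)
        df["rerank_rank"] = (-df["t_rerank"].abs()).rank(method="first").astype(int)
        df.insert(0, "study_dropped", drop)
        return df

    frames = [one_pass(None)] + [one_pass(s) for s in study_ids]
    return pd.concat(frames, ignore_index=True)
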