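"""Domain records for post-GWAS re-ranking.

All association statistics are carried on the signed Z scale.  Records are
sign-aligned at load time so that the coded allele of every SNP is positively
correlated with the risk allele of the GWAS tag (see :mod:`locrank.io`).
Construction validates every field and raises :class:`ValueError` naming the
offending field; no computation happens here.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

logger = logging.getLogger(__name__)

#: Two-sided 5e-7 genome-wide threshold on the |Z| scale.
Z_GENOMEWIDE = 5.026


def _check_range(name: str, value: float, lo: float, hi: float,
                 lo_open: bool = False, hi_open: bool = False) -> None:
    if not math.isfinite(value):
        raise ValueError(f"{name} must be finite, got {value!r}")
    below = value <= lo if lo_open else value < lo
    above = value >= hi if hi_open else value > hi
    if below or above:
        lob = "(" if lo_open else "["
        hib = ")" if hi_open else "]"
        raise ValueError(f"{name}={value!r} outside {lob}{lo}, {hi}{hib}")


@dataclass
class RegionSnp:
    """One sequenced/imputed SNP's summary record within an associated region.

    Parameters
    ----------
    snp_id : str
        Unique SNP identifier.
    t_obs : float
        Observed association statistic ``T_Si`` on the Z scale.
    maf : float
        Minor allele frequency, in (0, 0.5].
    rho_hat : float
        Estimated correlation between the true and the called/imputed
        genotype (square root of the allelic r-squared), in [0, 1].
    call_rate : float
        Proportion of samples with a non-missing genotype, in (0, 1].
    tag_corr_obs : float
        Sample correlation between the observed genotypes of the GWAS tag
        and this SNP, in [-1, 1].
    joint_call_rate : float
        Proportion of samples non-missing at both this SNP and the tag.
    position : int, optional
        1-based base-pair position; used only for deterministic tie-breaks.
    """

    snp_id: str
    t_obs: float
    maf: float = 0.5
    rho_hat: float = 1.0
    call_rate: float = 1.0
    tag_corr_obs: float = 0.0
    joint_call_rate: float = 1.0
    position: int | None = None

    def __post_init__(self) -> None:
        if not math.isfinite(self.t_obs):
            raise ValueError(f"t_obs must be finite, got {self.t_obs!r}")
        _check_range("maf", self.maf, 0.0, 0.5, lo_open=True)
        _check_range("rho_hat", self.rho_hat, 0.0, 1.0)
        _check_range("call_rate", self.call_rate, 0.0, 1.0, lo_open=True)
        _check_range("tag_corr_obs", self.tag_corr_obs, -1.0, 1.0)
        _check_range("joint_call_rate", self.joint_call_rate, 0.0, 1.0,
                     lo_open=True)
        if self.joint_call_rate > self.call_rate + 1e-12:
            raise ValueError(
                f"joint_call_rate={self.joint_call_rate} exceeds "
                f"call_rate={self.call_rate}")


@dataclass
class TagSnp:
    """The GWAS tag SNP: observed statistic, call rate and selection bias.

    ``selection_rule`` is one of ``"none"``, ``"threshold"`` (p-value/Z
    threshold selection) or ``"rank"`` (top-rank selection).  ``delta_hat``
    is the estimated winner's-curse selection bias of the tag statistic on
    the Z scale; it must be 0 when no selection was applied.  ``rho_g`` is
    the tag's own genotyping accuracy; GWAS array genotyping is essentially
    exact so it defaults to 1.
    """

    snp_id: str
    t_gobs: float
    call_rate_g: float = 1.0
    selection_rule: str = "none"
    z_crit: float | None = None
    delta_hat: float = 0.0
    rho_g: float = 1.0

    def __post_init__(self) -> None:
        if not math.isfinite(self.t_gobs):
            raise ValueError(f"t_gobs must be finite, got {self.t_gobs!r}")
        _check_range("call_rate_g", self.call_rate_g, 0.0, 1.0, lo_open=True)
        _check_range("rho_g", self.rho_g, 0.0, 1.0)
        if self.selection_rule not in ("none", "threshold", "rank"):
            raise ValueError(
                f"selection_rule={self.selection_rule!r} not one of "
                "'none', 'threshold', 'rank'")
        if self.delta_hat < 0:
            raise ValueError(f"delta_hat={self.delta_hat} must be >= 0")
        if self.selection_rule == "none" and self.delta_hat != 0:
            raise ValueError(
                "delta_hat must be 0 when selection_rule='none'")
        if self.selection_rule == "threshold":
            if self.z_crit is None or self.z_crit <= 0:
                raise ValueError(
                    f"z_crit={self.z_crit!r} must be > 0 for threshold "
                    "selection")


@dataclass
class RankedSnp:
    """Output record of region-wide re-ranking: one SNP, both ranks."""

    snp_id: str
    t_obs: float
    t_rerank: float
    naive_rank: int
    rerank_rank: int

    def __post_init__(self) -> None:
        for name in ("naive_rank", "rerank_rank"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 1:
                raise ValueError(f"{name}={v!r} must be an integer >= 1")


@dataclass
class StudyStat:
    """Per-study (Z, weight, accuracy) triple for meta-analysis re-ranking."""

    study_id: str
    z: float
    weight: float
    rho: float = 1.0

    def __post_init__(self) -> None:
        if not math.isfinite(self.z):
            raise ValueError(f"z must be finite, got {self.z!r}")
        if not (self.weight > 0) or not math.isfinite(self.weight):
            raise ValueError(f"weight={self.weight!r} must be > 0")
        _check_range("rho", self.rho, 0.0, 1.0)


@dataclass
class AnalyticRegion:
    """Gaussian model of a region's statistics for success-rate integration.

    The vector of statistics is modelled as multivariate normal with unit
    variances, means ``e_t`` (each ``r_CSi * rho_Si * sqrt(c_Si) * mu_c``)
    and correlation matrix ``stat_corr``.  ``mu_c`` is the noncentrality of
    the causal SNP at full accuracy and call rate, so every expected
    statistic is bounded by it.
    """

    mu_c: float
    e_t: np.ndarray
    stat_corr: np.ndarray
    causal_index: int = 0
    snp_labels: Sequence[str] | None = None
    selection_index: int | None = None
    selection_z_crit: float | None = None

    def __post_init__(self) -> None:
        self.e_t = np.asarray(self.e_t, dtype=float)
        self.stat_corr = np.asarray(self.stat_corr, dtype=float)
        if self.mu_c < 0:
            raise ValueError(f"mu_c={self.mu_c} must be >= 0")
        m = self.e_t.shape[0]
        if self.stat_corr.shape != (m, m):
            raise ValueError(
                f"stat_corr shape {self.stat_corr.shape} does not match "
                f"e_t length {m}")
        if not np.allclose(self.stat_corr, self.stat_corr.T, atol=1e-10):
            raise ValueError("stat_corr must be symmetric")
        if not np.allclose(np.diag(self.stat_corr), 1.0, atol=1e-10):
            raise ValueError("stat_corr must have unit diagonal")
        if np.linalg.eigvalsh(self.stat_corr).min() < -1e-8:
            raise ValueError("stat_corr is not positive semi-definite")
        if np.any(self.e_t < -1e-12) or np.any(self.e_t > self.mu_c + 1e-9):
            raise ValueError("e_t entries must lie in [0, mu_c]")
        if not 0 <= self.causal_index < m:
            raise ValueError(f"causal_index={self.causal_index} out of range")
        if self.selection_index is not None:
            if not 0 <= self.selection_index < m:
                raise ValueError(
                    f"selection_index={self.selection_index} out of range")
            if self.selection_z_crit is None:
                raise ValueError(
                    "selection_z_crit required when selection_index is set")

    @property
    def n_snps(self) -> int:
        return self.e_t.shape[0]


# Table of the simulation study designs.  `selection`:
#   "tag"  - phenotype accepted only if the tag statistic exceeds z_crit
#   "any"  - accepted if any SNP in the region exceeds z_crit
#   "none" - independent-sample fine-mapping, no conditioning
_SCENARIO_SELECTION = {1: "tag", 2: "any", 3: "none", 4: "none", 5: "none"}


@dataclass
class ScenarioConfig:
    """Full parameterization of one simulation scenario.

    Defaults reproduce the main study conditions: MAF 5%, causal odds ratio
    2, a chain of post-GWAS SNPs with adjacent dosage correlation 0.975, a
    tag correlated 0.95 with the causal SNP, and a balanced-cohort logistic
    phenotype model (intercept 0).  ``mean_accuracy`` / ``mean_call_rate``
    parameterize the per-SNP heterogeneity laws (see
    :func:`locrank.simulate.error_rate_for_mean_accuracy`).
    """

    scenario: int = 3
    n_cases: int = 1250
    n_controls: int = 1250
    m_postgwas: int = 10
    causal_indices: tuple[int, ...] = (0,)
    or_causal: tuple[float, ...] = (2.0,)
    maf: float = 0.05
    r_tag_causal: float = 0.95
    r_adjacent: float = 0.975
    r_causal_causal: float = 0.73
    mean_accuracy: float = 1.0
    mean_call_rate: float = 1.0
    heterogeneous: bool = True
    selection: str | None = None
    z_crit: float = Z_GENOMEWIDE
    n_reps: int = 800
    seed: int = 0
    success_top_k: int = 1
    bootstrap_b: int = 200
    prevalence: float | None = None

    def __post_init__(self) -> None:
        if self.scenario not in (1, 2, 3, 4, 5):
            raise ValueError(f"scenario={self.scenario} must be in 1..5")
        if self.selection is None:
            self.selection = _SCENARIO_SELECTION[self.scenario]
        if self.selection not in ("none", "tag", "any"):
            raise ValueError(f"selection={self.selection!r} invalid")
        for name in ("n_cases", "n_controls", "m_postgwas", "n_reps"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 1:
                raise ValueError(f"{name}={v!r} must be a positive integer")
        if isinstance(self.or_causal, (int, float)):
            self.or_causal = (float(self.or_causal),)
        if isinstance(self.causal_indices, (int, np.integer)):
            self.causal_indices = (int(self.causal_indices),)
        self.causal_indices = tuple(self.causal_indices)
        self.or_causal = tuple(float(b) for b in self.or_causal)
        if len(self.or_causal) != len(self.causal_indices):
            raise ValueError("or_causal length must match causal_indices")
        if any(not 0 <= i < self.m_postgwas for i in self.causal_indices):
            raise ValueError(
                f"causal_indices={self.causal_indices} out of range for "
                f"m_postgwas={self.m_postgwas}")
        if any(b <= 0 for b in self.or_causal):
            raise ValueError(f"or_causal={self.or_causal} must be > 0")
        _check_range("maf", self.maf, 0.0, 0.5, lo_open=True)
        for name in ("r_tag_causal", "r_adjacent", "r_causal_causal"):
            _check_range(name, getattr(self, name), 0.0, 1.0)
        _check_range("mean_accuracy", self.mean_accuracy, 0.0, 1.0,
                     lo_open=True)
        _check_range("mean_call_rate", self.mean_call_rate, 0.5, 1.0)
        if self.prevalence is not None:
            _check_range("prevalence", self.prevalence, 0.0, 1.0,
                         lo_open=True, hi_open=True)
        if self.z_crit <= 0:
            raise ValueError(f"z_crit={self.z_crit} must be > 0")
        if self.success_top_k < 1:
            raise ValueError("success_top_k must be >= 1")
        # Feasibility of the LD targets is checked at model construction
        # (tetrachoric inversion fails loudly on impossible pairs); here we
        # only reject error rates that the flip model cannot represent.
        from .simulate import error_rate_for_mean_accuracy
        e = error_rate_for_mean_accuracy(
            self.mean_accuracy, self.maf, heterogeneous=self.heterogeneous)
        if not 0 <= e < 0.5:
            raise ValueError(
                f"mean_accuracy={self.mean_accuracy} implies per-allele "
                f"error rate {e:.3f} outside [0, 0.5)")

    @property
    def n_total(self) -> int:
        return self.n_cases + self.n_controls


def scenario_config(scenario: int, n_total: int | None = None,
                    **kwargs) -> ScenarioConfig:
    """Build a :class:`ScenarioConfig` for one of the five study designs.

    ``n_total`` is split into equal cases and controls (scenario 1 defaults
    to the 1963/2938 split of its source design).  Remaining keyword
    arguments override defaults.
    """
    base: dict = {"scenario": scenario}
    if scenario == 1:
        base.update(n_cases=1963, n_controls=2938, maf=0.048,
                    or_causal=(1.5,), n_reps=300)
    if scenario == 4:
        base.update(m_postgwas=11, causal_indices=(0, 10),
                    or_causal=(2.0, 2.0))
    if n_total is not None:
        base["n_cases"] = n_total // 2
        base["n_controls"] = n_total - n_total // 2
    base.update(kwargs)
    return ScenarioConfig(**base)
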