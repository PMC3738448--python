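"""Latent-Gaussian (dichotomized) LD models for regional genotype simulation.

Haplotypes are generated by thresholding a multivariate normal vector at
``Phi^{-1}(1 - maf)`` per SNP; an individual's dosage is the sum of two
independent haplotype draws.  Because the two haplotypes are i.i.d., the
dosage-scale Pearson correlation between two SNPs equals the allele-scale
one, and the *latent* correlation needed to achieve a target dosage
correlation is found by inverting the tetrachoric relationship per pair.
This inversion matters: at MAF 5% a latent correlation of 0.975 yields a
dosage correlation of only about 0.81.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import optimize, stats

__all__ = [
    "dosage_corr_from_latent", "latent_from_dosage_corr",
    "LdModel", "chain_ld_model", "two_causal_ld_model",
]


def dosage_corr_from_latent(latent: float, maf1: float,
                            maf2: float | None = None) -> float:
    """Dosage-scale Pearson correlation implied by a latent correlation."""
    if maf2 is None:
        maf2 = maf1
    t1 = stats.norm.ppf(1 - maf1)
    t2 = stats.norm.ppf(1 - maf2)
    if latent >= 1.0:
        # comonotone alleles: P11 = min(p1, p2)
        p11 = min(maf1, maf2)
    else:
        cov = np.array([[1.0, latent], [latent, 1.0]])
        p11 = float(stats.multivariate_normal(
            mean=[0, 0], cov=cov, allow_singular=True).cdf([-t1, -t2]))
    num = p11 - maf1 * maf2
    den = math.sqrt(maf1 * (1 - maf1) * maf2 * (1 - maf2))
    return num / den


@lru_cache(maxsize=4096)
def _invert_cached(target: float, maf1: float, maf2: float) -> float:
    rmax = dosage_corr_from_latent(1.0, maf1, maf2)
    if target > rmax + 1e-9:
        raise ValueError(
            f"target dosage correlation {target:.4f} infeasible for MAFs "
            f"({maf1}, {maf2}); maximum attainable is {rmax:.4f}")
    if target >= rmax - 1e-12:
        return 1.0
    return optimize.brentq(
        lambda s: dosage_corr_from_latent(s, maf1, maf2) - target,
        -0.999, 1.0 - 1e-12, xtol=1e-6)


def latent_from_dosage_corr(target: float, maf1: float,
                            maf2: float | None = None) -> float:
    """Latent correlation achieving a target dosage correlation (to 1e-6)."""
    if maf2 is None:
        maf2 = maf1
    if target == 0.0:
        return 0.0
    return _invert_cached(round(float(target), 10), float(maf1), float(maf2))


@dataclass
class LdModel:
    """A region's LD model: target dosage correlations and latent Cholesky.

    Column order is the ``m`` post-GWAS SNPs followed by the tag (index
    ``m``).  ``causal_indices`` refer to post-GWAS columns.
    """

    target_corr: np.ndarray
    latent_corr: np.ndarray
    maf: float
    causal_indices: tuple[int, ...]
    tag_index: int

    def __post_init__(self) -> None:
        self.chol = np.linalg.cholesky(
            self.latent_corr + 1e-10 * np.eye(self.latent_corr.shape[0]))

    @property
    def n_snps(self) -> int:
        return self.target_corr.shape[0]


def _to_latent(target: np.ndarray, maf: float) -> np.ndarray:
    m = target.shape[0]
    latent = np.eye(m)
    for i in range(m):
        for j in range(i + 1, m):
            latent[i, j] = latent[j, i] = latent_from_dosage_corr(
                target[i, j], maf)
    ev = np.linalg.eigvalsh(latent).min()
    if ev < -1e-8:
        raise ValueError(
            f"latent correlation matrix not PSD (min eigenvalue {ev:.2e}); "
            "the requested dosage correlations are jointly infeasible")
    return latent


def chain_ld_model(m_snps: int, r_adjacent: float, r_tag_causal: float,
                   maf: float, causal_index: int = 0) -> LdModel:
    """Markov chain of post-GWAS SNPs with the causal SNP at one end.

    SNP at chain distance ``d`` from the causal has dosage correlation
    ``r_adjacent ** d`` with it (0.975**9 ~ 0.80 for a 10-SNP chain,
    spanning the realistic tagging range); the tag sits beyond the causal
    end at correlation ``r_tag_causal``, hence ``r_tag_causal *
    r_adjacent**d`` with the rest of the chain.
    """
    if causal_index != 0:
        raise ValueError("the chain model places the causal SNP at index 0")
    m = m_snps
    target = np.eye(m + 1)
    for i in range(m):
        for j in range(m):
            if i != j:
                target[i, j] = r_adjacent ** abs(i - j)
    for j in range(m):
        target[m, j] = target[j, m] = r_tag_causal * r_adjacent ** j
    return LdModel(target_corr=target, latent_corr=_to_latent(target, maf),
                   maf=maf, causal_indices=(0,), tag_index=m)


def two_causal_ld_model(m_snps: int, r_adjacent: float, r_tag_causal_b: float,
                        r_causal_causal: float, maf: float) -> LdModel:
    """Markov-tree model for a region with two causal SNPs.

    Causal A anchors a chain of non-causal SNPs (adjacent correlation
    ``r_adjacent``); causal B and the tag hang on a branch beyond the far
    chain end, placed so that corr(A, B) = ``r_causal_causal`` and
    corr(tag, B) = ``r_tag_causal_b`` hold exactly (Markov path products
    then imply corr(tag, A) = r_causal_causal / r_tag_causal_b).  The tree
    structure guarantees a valid correlation matrix; demanding all three
    stated pairwise targets exactly does not.
    """
    m = m_snps                       # post-GWAS SNPs: A, n1..n_{m-2}, B
    if m < 3:
        raise ValueError("two_causal_ld_model needs at least 3 post-GWAS SNPs")
    n_chain = m - 1                  # nodes A..n_{m-2} on the main chain
    r_end = r_adjacent ** (n_chain - 1)   # corr(A, last non-causal)
    r_tag_a = r_causal_causal / r_tag_causal_b
    if r_tag_a >= r_end:
        raise ValueError(
            "branch placement infeasible: corr(tag, A) implied by the tree "
            f"({r_tag_a:.3f}) exceeds corr(A, chain end) ({r_end:.3f})")
    target = np.eye(m + 1)
    ib, itag = m - 1, m              # causal B is the last post-GWAS column
    for i in range(n_chain):
        for j in range(n_chain):
            if i != j:
                target[i, j] = r_adjacent ** abs(i - j)
        back = r_adjacent ** (n_chain - 1 - i)      # corr(node i, chain end)
        target[i, itag] = target[itag, i] = back * r_tag_a / r_end
        target[i, ib] = target[ib, i] = back * r_causal_causal / r_end
    target[itag, ib] = target[ib, itag] = r_tag_causal_b
    return LdModel(target_corr=target, latent_corr=_to_latent(target, maf),
                   maf=maf, causal_indices=(0, ib), tag_index=itag)
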