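# locrank

Re-ranking of post-GWAS sequencing and imputation variants for accurate
causal-SNP localization.

## The problem

After a GWAS flags a region through a tag SNP, fine-mapping ranks the
sequenced or imputed SNPs in that region by the magnitude of their
association statistics and nominates the top SNP as the candidate causal
variant. Three forces systematically push the wrong SNP to the top:

1. **Selection (winner's curse).** If the same sample that produced the
   GWAS hit is re-used, the tag's statistic is inflated by the selection
   event, and that inflation propagates to every SNP in proportion to its
   correlation with the tag.
2. **Tagging.** A perfectly genotyped tag in high LD with the causal SNP
   captures most of the causal signal and often out-ranks it.
3. **Differential genotyping accuracy and call rates.** The expected
   statistic of a SNP with accuracy ρ (the correlation between true and
   called genotype, √ of the allelic r²) and call rate c is attenuated by
   ρ·√c, so better-genotyped proxies beat a noisily sequenced causal SNP —
   and the problem *worsens* as the sample grows.

`locrank` implements the corrected (re-ranking) statistic

    T̃ᵢ = (Tᵢ − κᵢ·Δ̂_G) / (ρ̂ᵢ·√cᵢ),     κᵢ = r̂_{Gi} · c_{Gi} / √(c_G·cᵢ)

where Δ̂_G is the tag's estimated selection bias (bootstrap
detection/out-of-bag estimator), κᵢ the correlation between the tag's and
SNP i's statistics, and the denominator undoes the SNP's own attenuation.
Ranking by |T̃| in place of |T| substantially raises the probability that
the causal SNP is top-ranked. The package also provides:

- the analytic bivariate/multivariate-normal model of the **localization
  success rate** P(|T_C| > |T_G|), with or without conditioning on tag
  selection;
- the meta-analysis variant (fixed-effect Z divided by the w²-weighted
  imputation accuracy), with a leave-one-study-out heterogeneity scan;
- a simulation framework (latent-Gaussian haplotype LD models with
  tetrachoric-inverted dosage correlations, per-allele genotyping-error and
  missingness models, retrospective case/control sampling) reproducing the
  five evaluation scenarios.

## Worked example

Re-rank a small region in which a noisily imputed SNP (ρ̂ = 0.8) trails a
better-genotyped neighbour:

```python
import locrank as lr

snps = [
    lr.RegionSnp("rs_causal", t_obs=4.6, rho_hat=0.80, tag_corr_obs=0.9),
    lr.RegionSnp("rs_proxy",  t_obs=5.0, rho_hat=1.00, tag_corr_obs=0.95),
]
tag = lr.TagSnp("rs_tag", t_gobs=5.5, selection_rule="threshold",
                z_crit=5.026, delta_hat=1.2)
for r in lr.rerank_region(snps, tag, include_tag=True):
    print(f"{r.snp_id:10s} T={r.t_obs:5.2f} T~={r.t_rerank:5.2f} "
          f"naive={r.naive_rank} reranked={r.rerank_rank}")
```

prints

```
rs_causal  T= 4.60 T~= 4.40 naive=3 reranked=1
rs_proxy   T= 5.00 T~= 3.86 naive=2 reranked=3
rs_tag     T= 5.50 T~= 4.30 naive=1 reranked=2
```

The proxy's and the tag's leads came from their genotyping advantage and
the selected tag's inflated statistic; after correction the causal SNP is
top-ranked.

The analytic model shows why larger samples can *hurt* localization when
the causal SNP is well-tagged (r = 0.98) but imperfectly sequenced
(ρ_C = 0.95):

```python
from locrank.analytic import locrate_2snp, noncentrality
for n in (50, 5000):
    mu = noncentrality(0.12, 1.25, n, n, scale="sqrt-total")
    print(n * 2, round(locrate_2snp(mu, 0.98, 0.95, 1.0), 3))
# 100   0.487
# 10000 0.273
```

A command-line interface exposes the same functionality:
`locrank rerank`, `locrank rerank-meta`, `locrank estimate-delta`,
`locrank locrate`, and `locrank simulate` (see `locrank --help`).

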