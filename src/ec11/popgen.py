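"""Basic population-genetic QC: allele frequencies, HWE exact test, LD r2."""

from __future__ import annotations

import numpy as np

from .cohort import Cohort, parse_call
from .panels import VariantDef

__all__ = ["allele_frequency", "genotype_counts", "hwe_test", "ld_r2"]


def genotype_counts(cohort: Cohort, variant: VariantDef) -> "tuple[int, int, int]":
    """(hom ref, het, hom variant) counts for one variant, missing excluded."""
    n_rr = n_rv = n_vv = 0
    for call in cohort.genotypes[variant.rsid]:
        pair = parse_call(call, variant)
        if pair is None:
            continue
        k = sum(1 for a in pair if a == variant.var_allele)
        if k == 0:
            n_rr += 1
        elif k == 1:
            n_rv += 1
        else:
            n_vv += 1
    return n_rr, n_rv, n_vv


def allele_frequency(cohort: Cohort, variant: VariantDef) -> float:
    """Variant-allele fraction: (variant alleles) / (2 x non-missing samples)."""
    n_rr, n_rv, n_vv = genotype_counts(cohort, variant)
    n = n_rr + n_rv + n_vv
    if n == 0:
        raise ValueError(f"{variant.rsid}: no non-missing calls")
    return (n_rv + 2 * n_vv) / (2 * n)


def hwe_test(counts: "tuple[int, int, int]") -> float:
    """Exact Hardy-Weinberg test p-value from (hom ref, het, hom var) counts.

    Conditional on the observed allele counts, the probability of each
    possible heterozygote count is computed exactly (the Levene-Haldane
    distribution) and the p-value sums the probabilities of all
    configurations no more likely than the observed one — the standard
    exact HWE test of Wigginton, Cutler & Abecasis (2005).
    """
    n_rr, n_het, n_vv = (int(c) for c in counts)
    if min(n_rr, n_het, n_vv) < 0:
        raise ValueError("negative genotype count")
    n = n_rr + n_het + n_vv
    if n == 0:
        raise ValueError("empty genotype table")
    n_rare = n_het + 2 * min(n_rr, n_vv)  # copies of the rarer allele

    # P(het = k | allele counts) up to a constant, via the recurrence
    # P(k+2)/P(k) = 4 * n_hom_rare(k) * n_hom_common(k) / ((k+2)(k+1));
    # heterozygote count has the same parity as the rare-allele count.
    # The recurrence runs in log space (the unnormalised weights overflow
    # double precision for n in the thousands).
    hets = np.arange(n_rare % 2, n_rare + 1, 2)
    log_probs = np.empty(len(hets))
    log_probs[0] = 0.0
    for i in range(len(hets) - 1):
        k = hets[i]
        hom_r = (n_rare - k) // 2
        hom_c = n - k - hom_r
        log_probs[i + 1] = log_probs[i] + np.log(
            4.0 * hom_r * hom_c / ((k + 2.0) * (k + 1.0))
        )
    probs = np.exp(log_probs - log_probs.max())
    probs /= probs.sum()
    observed = probs[hets == n_het][0]
    # sum over configurations no more probable than the observed one
    return float(min(1.0, probs[probs <= observed * (1 + 1e-12)].sum()))


def ld_r2(cohort: Cohort, variant_a: VariantDef, variant_b: VariantDef) -> float:
    """Squared Pearson correlation of genotype dosages (composite LD).

    Computed on samples with both variants called.  Unlike haplotype-based
    r2 (HaploView's EM estimate) this needs no phasing; for variants in HWE
    the two agree closely.
    """
    dos = []
    for v in (variant_a, variant_b):
        col = np.full(cohort.n_samples, np.nan)
        for i, call in enumerate(cohort.genotypes[v.rsid]):
            pair = parse_call(call, v)
            if pair is not None:
                col[i] = sum(1 for a in pair if a == v.var_allele)
        dos.append(col)
    a, b = dos
    keep = ~(np.isnan(a) | np.isnan(b))
    a, b = a[keep], b[keep]
    if len(a) == 0:
        raise ValueError("no samples with both variants called")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("LD r2 undefined for a fixed variant")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)
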