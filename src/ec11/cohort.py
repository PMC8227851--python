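"""Cohorts: genotype calls + PIE phenotypes, their encoding and I/O.

A :class:`Cohort` carries raw genotype calls (unordered allele pairs, e.g.
``"AG"``; indel alleles are full strings so a call may read ``"TCT-"``) and
a PIE-score per sample.  :func:`encode_cohort` applies a panel's coding
schemes and yields a :class:`CodedMatrix`, the numeric design matrix used by
every downstream stage.  Minor alleles are determined from the supplied
cohort itself and recorded in ``minor_allele_map`` so an encoding is
reproducible on other data sets.

On-disk formats are plain TSV: a genotype table with header
``sample_id<TAB>rs...`` and calls as concatenated allele pairs (missing
``./.``), and a phenotype table with columns ``sample_id`` and
``pie_score``.  A minimal VCF 4.x reader (GT field only, ID column keyed by
rsid) is available when :mod:`cyvcf2` is installed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .panels import PanelDef, VariantDef
from .transforms import transform_pie

__all__ = [
    "Cohort",
    "CodedMatrix",
    "parse_call",
    "encode_cohort",
    "read_cohort",
    "write_cohort",
    "read_vcf_genotypes",
]

MISSING = "./."


def parse_call(call: str, variant: VariantDef) -> "tuple[str, str] | None":
    """Split a concatenated allele-pair call against a variant's alleles.

    Returns the unordered pair as a sorted tuple, or None for missing.
    Raises ValueError when the call cannot be read as two declared alleles
    (no strand flipping or complementing is attempted).
    """
    if call is None or call == MISSING or (isinstance(call, float) and np.isnan(call)):
        return None
    alleles = variant.alleles
    for a in alleles:
        if call.startswith(a):
            rest = call[len(a):]
            if rest in alleles:
                return tuple(sorted((a, rest)))
    raise ValueError(
        f"{variant.rsid}: call {call!r} does not decompose into alleles {alleles}"
    )


@dataclass
class Cohort:
    """Raw genotype calls and PIE phenotypes for n samples.

    ``genotypes``: DataFrame indexed by sample_id, one column per rsid,
    values are call strings (``"AG"``) or the missing marker.  ``pie``:
    float Series of PIE-scores aligned to the same index.
    """

    genotypes: pd.DataFrame
    pie: pd.Series

    def __post_init__(self):
        self.genotypes = self.genotypes.copy()
        self.pie = pd.Series(self.pie, dtype=float).reindex(self.genotypes.index)
        if self.genotypes.index.has_duplicates:
            dup = self.genotypes.index[self.genotypes.index.duplicated()][0]
            raise ValueError(f"duplicate sample id {dup!r}")
        ok = self.pie.dropna()
        if ((ok < -1) | (ok > 1)).any():
            bad = ok[(ok < -1) | (ok > 1)].index[0]
            raise ValueError(f"sample {bad!r}: PIE-score outside [-1, 1]")

    @property
    def sample_ids(self) -> list:
        return list(self.genotypes.index)

    @property
    def rsids(self) -> list:
        return list(self.genotypes.columns)

    @property
    def n_samples(self) -> int:
        return len(self.genotypes)

    @property
    def y(self) -> pd.Series:
        """Phenotypes on the transformed (unbounded) scale."""
        return pd.Series(transform_pie(self.pie.to_numpy()), index=self.pie.index)

    def subset(self, sample_ids) -> "Cohort":
        return Cohort(self.genotypes.loc[list(sample_ids)], self.pie.loc[list(sample_ids)])


@dataclass
class CodedMatrix:
    """Numeric design matrix from applying a panel's codings to a cohort."""

    values: pd.DataFrame  # samples x variables, coded levels
    panel: PanelDef
    minor_allele_map: dict  # rsid -> allele used as "minor"

    @property
    def samples(self) -> list:
        return list(self.values.index)

    @property
    def variables(self) -> list:
        return list(self.values.columns)

    def to_numpy(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)


def minor_allele(cohort: Cohort, variant: VariantDef) -> str:
    """The less frequent of a variant's two alleles in this cohort.

    Ties at frequency 0.5 are broken lexicographically (smaller allele
    string wins) so encodings are deterministic.
    """
    counts = {variant.ref_allele: 0, variant.var_allele: 0}
    for call in cohort.genotypes[variant.rsid]:
        pair = parse_call(call, variant)
        if pair is None:
            continue
        counts[pair[0]] += 1
        counts[pair[1]] += 1
    if counts[variant.ref_allele] == counts[variant.var_allele]:
        return min(variant.alleles)
    return min(counts, key=lambda a: (counts[a], a))


def _minor_count(call, variant: VariantDef, minor: str) -> "int | None":
    pair = parse_call(call, variant)
    if pair is None:
        return None
    return sum(1 for a in pair if a == minor)


def encode_cohort(
    cohort: Cohort, panel: PanelDef, on_missing: str = "drop"
) -> CodedMatrix:
    """Apply a panel's coding schemes to a cohort.

    additive: minor-allele count 0/1/2; dominant: 1 iff homozygous for the
    panel's variant allele (rs12913832: AA/AG -> 0, GG -> 1); carrier: 1 iff
    at least one minor allele; combined: sum of constituent minor-allele
    counts capped at 2.

    ``on_missing``: ``"drop"`` removes samples with any missing panel call
    (the default — prediction modelling uses complete profiles only);
    ``"impute"`` fills each variable's missing codes with the variable mean;
    ``"error"`` raises.
    """
    if on_missing not in ("drop", "impute", "error"):
        raise ValueError("on_missing must be 'drop', 'impute' or 'error'")
    for rsid in panel.rsids:
        if rsid not in cohort.genotypes.columns:
            raise KeyError(f"cohort has no genotype column for {rsid}")

    minor_map = {}
    counts = {}  # rsid -> float array of minor-allele counts (nan = missing)
    for rsid in panel.rsids:
        variant = panel.variant(rsid)
        minor = minor_allele(cohort, variant)
        minor_map[rsid] = minor
        col = np.full(cohort.n_samples, np.nan)
        for i, call in enumerate(cohort.genotypes[rsid]):
            c = _minor_count(call, variant, minor)
            if c is not None:
                col[i] = c
        if np.all(np.isnan(col)):
            raise ValueError(f"{rsid}: no non-missing calls")
        counts[rsid] = col

    cols = {}
    for name, scheme in panel.variables:
        if scheme.kind == "additive":
            cols[name] = counts[scheme.constituent_rsids[0]]
        elif scheme.kind == "carrier":
            c = counts[scheme.constituent_rsids[0]]
            cols[name] = np.where(np.isnan(c), np.nan, (c >= 1).astype(float))
        elif scheme.kind == "combined":
            stack = np.vstack([counts[r] for r in scheme.constituent_rsids])
            s = stack.sum(axis=0)  # nan-propagating: any missing constituent
            cols[name] = np.minimum(s, 2.0)
        else:  # dominant: homozygous variant allele -> 1
            rsid = scheme.constituent_rsids[0]
            variant = panel.variant(rsid)
            col = np.full(cohort.n_samples, np.nan)
            for i, call in enumerate(cohort.genotypes[rsid]):
                pair = parse_call(call, variant)
                if pair is not None:
                    col[i] = 1.0 if pair == (variant.var_allele, variant.var_allele) else 0.0
            cols[name] = col

    values = pd.DataFrame(cols, index=cohort.genotypes.index)[list(panel.variable_names)]
    if values.isna().any().any():
        if on_missing == "error":
            raise ValueError("missing genotype calls in panel variants")
        if on_missing == "drop":
            values = values.dropna()
        else:
            values = values.fillna(values.mean())
    return CodedMatrix(values=values, panel=panel, minor_allele_map=minor_map)


# ---------------------------------------------------------------------------
# I/O


def read_cohort(genotype_path, phenotype_path) -> Cohort:
    """Read a cohort from a genotype TSV and a phenotype TSV.

    Samples must match one-to-one between the two files (order-insensitive);
    a sample present in only one file is an error.
    """
    geno = pd.read_csv(genotype_path, sep="\t", dtype=str).set_index("sample_id")
    pheno = pd.read_csv(phenotype_path, sep="\t", dtype={"sample_id": str})
    if pheno["sample_id"].duplicated().any():
        raise ValueError("duplicate sample id in phenotype file")
    pie = pheno.set_index("sample_id")["pie_score"].astype(float)
    only_geno = set(geno.index) - set(pie.index)
    only_pheno = set(pie.index) - set(geno.index)
    if only_geno or only_pheno:
        raise ValueError(
            f"sample sets differ between files (genotypes only: {sorted(only_geno)[:3]}, "
            f"phenotypes only: {sorted(only_pheno)[:3]})"
        )
    return Cohort(genotypes=geno, pie=pie.reindex(geno.index))


def write_cohort(cohort: Cohort, genotype_path, phenotype_path) -> None:
    gp = Path(genotype_path)
    gp.parent.mkdir(parents=True, exist_ok=True)
    geno = cohort.genotypes.fillna(MISSING)
    geno.index.name = "sample_id"
    geno.to_csv(gp, sep="\t")
    pp = Path(phenotype_path)
    pp.parent.mkdir(parents=True, exist_ok=True)
    pheno = pd.DataFrame(
        {"sample_id": cohort.pie.index, "pie_score": cohort.pie.to_numpy()}
    )
    pheno.to_csv(pp, sep="\t", index=False)


def read_vcf_genotypes(vcf_path, variants: "dict[str, VariantDef]") -> pd.DataFrame:
    """Genotype calls from a VCF (GT only), keyed by the ID column = rsid.

    REF/ALT alleles must match the :class:`VariantDef`; GT indices are
    mapped through them, so ``0/1`` at rs12913832 (ref A, alt G) becomes
    the call ``"AG"``.  Requires cyvcf2.
    """
    from cyvcf2 import VCF  # optional dependency

    vcf = VCF(str(vcf_path))
    samples = list(vcf.samples)
    data = {}
    for rec in vcf:
        rsid = rec.ID
        if rsid not in variants:
            continue
        v = variants[rsid]
        site_alleles = [rec.REF] + list(rec.ALT)
        for a in site_alleles:
            if a not in v.alleles:
                raise ValueError(f"{rsid}: VCF allele {a!r} not declared in VariantDef")
        calls = []
        for gt in rec.genotypes:
            i, j = gt[0], gt[1]
            if i < 0 or j < 0:
                calls.append(MISSING)
            else:
                pair = sorted((site_alleles[i], site_alleles[j]))
                calls.append("".join(pair))
        data[rsid] = calls
    out = pd.DataFrame(data, index=pd.Index(samples, name="sample_id"))
    return out
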