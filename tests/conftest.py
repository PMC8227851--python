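"""Shared fixtures: small panels and cohorts built programmatically."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from ec11.cohort import Cohort
from ec11.panels import CodingScheme, PanelDef, VariantDef


def make_variant(rsid="rs1", gene="GENE", ref="A", var="G", freq=0.3) -> VariantDef:
    return VariantDef(rsid=rsid, gene=gene, ref_allele=ref, var_allele=var, var_freq=freq)


@pytest.fixture
def snp_panel() -> PanelDef:
    """Three additive SNPs with distinct alleles and frequencies."""
    variants = [
        make_variant("rs1", "G1", "A", "G", 0.3),
        make_variant("rs2", "G2", "C", "T", 0.2),
        make_variant("rs3", "G3", "G", "C", 0.45),
    ]
    variables = [(v.rsid, CodingScheme("additive", (v.rsid,))) for v in variants]
    return PanelDef("snp3", tuple(variables), tuple(variants))


@pytest.fixture
def hub_panel() -> PanelDef:
    """A dominant hub variant plus two additive modifiers (rs12913832-style)."""
    variants = [
        make_variant("rs12913832", "HERC2", "A", "G", 0.74),
        make_variant("rs2", "G2", "C", "T", 0.2),
        make_variant("rs3", "G3", "G", "C", 0.45),
    ]
    variables = [
        ("rs12913832", CodingScheme("dominant", ("rs12913832",))),
        ("rs2", CodingScheme("additive", ("rs2",))),
        ("rs3", CodingScheme("additive", ("rs3",))),
    ]
    return PanelDef("hub3", tuple(variables), tuple(variants))


def cohort_from_calls(calls: dict, pie) -> Cohort:
    """Build a cohort from {rsid: [call, ...]} and a PIE-score list."""
    n = len(next(iter(calls.values())))
    idx = pd.Index([f"S{i:03d}" for i in range(n)], name="sample_id")
    geno = pd.DataFrame(calls, index=idx)
    return Cohort(genotypes=geno, pie=pd.Series(list(pie), index=idx, dtype=float))


@pytest.fixture
def rng():
    return np.random.default_rng(20210527)
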