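"""Variant and SNP-panel definitions.

A :class:`VariantDef` records a biallelic variant (rsid, gene, the two
alleles and the population variant-allele frequency).  A :class:`PanelDef`
is an ordered list of model variables, each tied to one or more variants
through a :class:`CodingScheme`:

additive
    number of minor alleles, 0/1/2 (the default for modifiers);
dominant
    rs12913832-style collapse, AA/AG -> 0 and GG -> 1;
carrier
    1 if at least one minor allele is present (used for rare variants);
combined
    capped sum of minor-allele counts over several rare variants, 0/1/2.

Built-in panels (packaged JSON): ``discovery44`` (the 44-variant ranking
panel), ``ec11``, ``irisplex6`` and ``rs12913832``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

__all__ = [
    "VariantDef",
    "CodingScheme",
    "PanelDef",
    "builtin_variants",
    "builtin_panel",
    "load_panel",
    "BUILTIN_PANELS",
]

CODING_KINDS = ("additive", "dominant", "carrier", "combined")

#: number of distinct coded levels per coding kind
CODING_LEVELS = {"additive": 3, "dominant": 2, "carrier": 2, "combined": 3}


@dataclass(frozen=True)
class VariantDef:
    rsid: str
    gene: str
    ref_allele: str
    var_allele: str
    var_freq: float

    def __post_init__(self):
        if self.ref_allele == self.var_allele:
            raise ValueError(f"{self.rsid}: identical ref and variant alleles")
        if not 0.0 <= self.var_freq <= 1.0:
            raise ValueError(f"{self.rsid}: variant frequency outside [0, 1]")

    @property
    def alleles(self) -> tuple:
        return (self.ref_allele, self.var_allele)


@dataclass(frozen=True)
class CodingScheme:
    kind: str
    constituent_rsids: tuple

    def __post_init__(self):
        if self.kind not in CODING_KINDS:
            raise ValueError(f"unknown coding kind {self.kind!r}")
        rsids = tuple(self.constituent_rsids)
        object.__setattr__(self, "constituent_rsids", rsids)
        if self.kind != "combined" and len(rsids) != 1:
            raise ValueError(f"{self.kind} coding takes exactly one rsid")
        if self.kind == "combined" and len(rsids) < 2:
            raise ValueError("combined coding needs at least two rsids")

    @property
    def n_levels(self) -> int:
        return CODING_LEVELS[self.kind]


@dataclass(frozen=True)
class PanelDef:
    """A named SNP set: ordered (variable name, coding) pairs plus variants."""

    name: str
    variables: tuple  # of (variable_name, CodingScheme)
    variants: tuple  # of VariantDef

    def __post_init__(self):
        object.__setattr__(self, "variables", tuple(self.variables))
        object.__setattr__(self, "variants", tuple(self.variants))
        names = [v for v, _ in self.variables]
        if len(set(names)) != len(names):
            raise ValueError("duplicate variable names in panel")
        by_rsid = {}
        for v in self.variants:
            if v.rsid in by_rsid:
                raise ValueError(f"duplicate variant {v.rsid}")
            by_rsid[v.rsid] = v
        for _, scheme in self.variables:
            for rsid in scheme.constituent_rsids:
                if rsid not in by_rsid:
                    raise ValueError(f"variable rsid {rsid} has no VariantDef")
        object.__setattr__(self, "_by_rsid", by_rsid)

    @property
    def variable_names(self) -> tuple:
        return tuple(v for v, _ in self.variables)

    @property
    def rsids(self) -> tuple:
        """All rsids used by the panel's variables, in variable order."""
        seen = []
        for _, scheme in self.variables:
            for rsid in scheme.constituent_rsids:
                if rsid not in seen:
                    seen.append(rsid)
        return tuple(seen)

    def variant(self, rsid: str) -> VariantDef:
        return self._by_rsid[rsid]

    def scheme(self, variable_name: str) -> CodingScheme:
        for name, scheme in self.variables:
            if name == variable_name:
                return scheme
        raise KeyError(variable_name)

    def n_combinations(self) -> int:
        """Size of the coded genotype space (product of level counts)."""
        n = 1
        for _, scheme in self.variables:
            n *= scheme.n_levels
        return n


def _read_builtin() -> dict:
    with resources.files("ec11.data").joinpath("variants.json").open() as fh:
        return json.load(fh)


def builtin_variants(freq_set: str = "discovery") -> "dict[str, VariantDef]":
    """All packaged variant definitions keyed by rsid.

    ``freq_set`` selects which printed frequency column populates
    ``var_freq``: ``"discovery"`` (757 Danes/Swedes/Italians) or ``"model"``
    (523 Norwegians; falls back to discovery where the variant was not typed
    in the model set).
    """
    if freq_set not in ("discovery", "model"):
        raise ValueError("freq_set must be 'discovery' or 'model'")
    raw = _read_builtin()
    out = {}
    for rec in raw["variants"]:
        freq = rec["discovery_freq"]
        if freq_set == "model" and rec["model_freq"] is not None:
            freq = rec["model_freq"]
        out[rec["rsid"]] = VariantDef(
            rsid=rec["rsid"],
            gene=rec["gene"],
            ref_allele=rec["ref_allele"],
            var_allele=rec["var_allele"],
            var_freq=freq,
        )
    return out


def _panel_from_config(name: str, cfg: dict, variants: "dict[str, VariantDef]") -> PanelDef:
    variables = []
    covered = set()
    for var in cfg.get("variables", []):
        scheme = CodingScheme(var["kind"], tuple(var["rsids"]))
        variables.append((var["name"], scheme))
        covered.update(scheme.constituent_rsids)
    if cfg.get("rsids") == "all":
        # remaining variants get the panel's default coding, in table order
        default = cfg.get("default_kind", "additive")
        for rsid in variants:
            if rsid not in covered:
                variables.append((rsid, CodingScheme(default, (rsid,))))
                covered.add(rsid)
    used = [v for rsid, v in variants.items() if rsid in covered]
    return PanelDef(name=name, variables=tuple(variables), variants=tuple(used))


BUILTIN_PANELS = ("discovery44", "ec11", "irisplex6", "rs12913832")


def builtin_panel(name: str, freq_set: str = "discovery") -> PanelDef:
    """Load a packaged panel by name (see :data:`BUILTIN_PANELS`)."""
    raw = _read_builtin()
    if name not in raw["panels"]:
        raise ValueError(f"unknown panel {name!r}; available: {sorted(raw['panels'])}")
    variants = builtin_variants(freq_set)
    return _panel_from_config(name, raw["panels"][name], variants)


def load_panel(path: "str | Path", name: "str | None" = None) -> PanelDef:
    """Load a panel from a user JSON file with the packaged file's layout."""
    raw = json.loads(Path(path).read_text())
    variants = {}
    for rec in raw["variants"]:
        variants[rec["rsid"]] = VariantDef(
            rec["rsid"],
            rec.get("gene", ""),
            rec["ref_allele"],
            rec["var_allele"],
            rec.get("var_freq", rec.get("discovery_freq", 0.0)),
        )
    panels = raw["panels"]
    if name is None:
        if len(panels) != 1:
            raise ValueError("panel file has several panels; give a name")
        name = next(iter(panels))
    return _panel_from_config(name, panels[name], variants)
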