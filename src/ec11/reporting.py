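"""Forensic reporting: threshold calls, outcome tables, genotype-space
enumeration and two-category likelihood ratios.

A categorical prediction is *called* as the most probable category
(``pmax``) or, under a probability threshold t, only when the maximum
probability reaches t — otherwise the prediction is inconclusive.  Outcome
tables summarise calls as percent correct / incorrect / inconclusive and
one-vs-rest sensitivity and specificity.  The genotype space of a panel is
the Cartesian product of its coded levels; enumerating it under a fitted
model shows which fractions of conceivable profiles map to each predicted
category.  The two-category weight of evidence for a genotype g is the
likelihood ratio LR = P(g | brown-eyed) / P(g | blue-eyed).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import Cohort
from .panels import PanelDef
from .prediction import LOOCVResult, FittedModel
from .transforms import TWO_CATEGORY

__all__ = [
    "CallPolicy",
    "ReportTable",
    "GenotypeSpace",
    "LikelihoodRatio",
    "call_category",
    "report",
    "enumerate_genotype_space",
    "likelihood_ratio",
]

INCONCLUSIVE = "inconclusive"


@dataclass(frozen=True)
class CallPolicy:
    """``threshold`` is a probability in (0, 1), or None for pmax (always
    call the most probable category).  Exact ties at the maximum are
    inconclusive under every policy."""

    threshold: "float | None" = None

    def __post_init__(self):
        if self.threshold is not None and not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must lie in (0, 1) or be None for pmax")

    @classmethod
    def parse(cls, text) -> "CallPolicy":
        if text is None or str(text).lower() in ("pmax", "none"):
            return cls(None)
        return cls(float(text))

    @property
    def label(self) -> str:
        return "pmax" if self.threshold is None else f"{self.threshold:g}"


def call_category(p, classes, policy: CallPolicy = CallPolicy()) -> str:
    """Call one category from a probability vector, or 'inconclusive'."""
    p = np.asarray(p, float)
    if p.ndim != 1 or len(p) != len(classes) or not np.isclose(p.sum(), 1.0, atol=1e-6):
        raise ValueError("malformed probability vector")
    if np.any(p < 0):
        raise ValueError("malformed probability vector")
    pmax = p.max()
    if np.sum(p == pmax) > 1:
        return INCONCLUSIVE
    if policy.threshold is not None and pmax < policy.threshold:
        return INCONCLUSIVE
    return list(classes)[int(np.argmax(p))]


@dataclass
class ReportTable:
    """Outcome summary of categorical LOOCV predictions under one policy."""

    policy: CallPolicy
    classes: tuple
    confusion: pd.DataFrame  # truth x (called classes + inconclusive), counts
    sensitivity: dict  # class -> TP/(TP+FN) over conclusive calls (NA-able)
    specificity: dict  # class -> TN/(TN+FP) over conclusive calls
    percent_correct: float
    percent_incorrect: float
    percent_inconclusive: float
    n: int

    def to_dict(self) -> dict:
        return {
            "policy": self.policy.label,
            "n": self.n,
            "percent_correct": self.percent_correct,
            "percent_incorrect": self.percent_incorrect,
            "percent_inconclusive": self.percent_inconclusive,
            "sensitivity": {k: _nan_to_none(v) for k, v in self.sensitivity.items()},
            "specificity": {k: _nan_to_none(v) for k, v in self.specificity.items()},
            "confusion": {
                str(t): {str(c): int(v) for c, v in row.items()}
                for t, row in self.confusion.iterrows()
            },
        }


def _nan_to_none(v):
    return None if v is None or (isinstance(v, float) and np.isnan(v)) else v


def report(loocv: LOOCVResult, policy: CallPolicy = CallPolicy()) -> ReportTable:
    """Summarise categorical LOOCV predictions under a call policy.

    Sensitivity (TP/(TP+FN)) and specificity (TN/(TN+FP)) are one-vs-rest
    per class and computed over conclusive calls only; a class never called
    conclusively on a positive truth gets sensitivity NA (None).  Percent
    correct / incorrect / inconclusive are over all samples and sum to 100.
    """
    if loocv.system == "quantitative":
        raise ValueError("outcome tables need a categorical reporting system")
    probs = loocv.prob_matrix()
    classes = tuple(probs.columns)
    truth = loocv.per_sample["truth"]
    calls = pd.Series(
        [call_category(probs.loc[i].to_numpy(), classes, policy) for i in probs.index],
        index=probs.index,
    )
    cols = list(classes) + [INCONCLUSIVE]
    confusion = pd.DataFrame(0, index=list(classes), columns=cols)
    for t, c in zip(truth, calls):
        confusion.loc[t, c] += 1
    n = len(truth)
    conclusive = calls != INCONCLUSIVE
    n_correct = int((calls[conclusive] == truth[conclusive]).sum())
    n_inconclusive = int((~conclusive).sum())
    n_incorrect = n - n_correct - n_inconclusive
    sens, spec = {}, {}
    for c in classes:
        pos = conclusive & (truth == c)
        neg = conclusive & (truth != c)
        tp = int((calls[pos] == c).sum())
        fn = int(pos.sum()) - tp
        fp = int((calls[neg] == c).sum())
        tn = int(neg.sum()) - fp
        sens[c] = tp / (tp + fn) if tp + fn > 0 else None
        spec[c] = tn / (tn + fp) if tn + fp > 0 else None
    return ReportTable(
        policy=policy,
        classes=classes,
        confusion=confusion,
        sensitivity=sens,
        specificity=spec,
        percent_correct=100.0 * n_correct / n,
        percent_incorrect=100.0 * n_incorrect / n,
        percent_inconclusive=100.0 * n_inconclusive / n,
        n=n,
    )


@dataclass
class GenotypeSpace:
    """All coded genotype combinations of a panel (+ model predictions)."""

    panel_name: str
    variables: tuple
    combinations: pd.DataFrame  # one row per coded combination
    n_combinations: int
    predicted: "pd.DataFrame | None" = None  # probabilities + argmax category
    category_counts: "dict | None" = None
    category_fractions: "dict | None" = None
    max_probability: "dict | None" = None  # per category, over the space
    coding_note: str = ""  # e.g. "rs12913832:2, ..., rs1800401:3" level counts


def enumerate_genotype_space(
    panel: PanelDef, model: "FittedModel | None" = None, cap: int = 10_000_000
) -> GenotypeSpace:
    """Enumerate the Cartesian product of a panel's coded genotype levels.

    Additive and combined variables contribute 3 levels (0/1/2), dominant
    and carrier variables 2 (0/1).  With a fitted model, each combination
    is scored: class probabilities, the pmax category, per-category counts
    and fractions of the space, and the maximum probability each category
    attains anywhere in the space.
    """
    n_comb = panel.n_combinations()
    if n_comb > cap:
        raise ValueError(f"genotype space has {n_comb} combinations (cap {cap})")
    level_ranges = [range(s.n_levels) for _, s in panel.variables]
    grid = pd.DataFrame(
        itertools.product(*level_ranges), columns=list(panel.variable_names)
    )
    space = GenotypeSpace(
        panel_name=panel.name,
        variables=tuple(panel.variable_names),
        combinations=grid,
        n_combinations=n_comb,
        coding_note=", ".join(f"{v}:{s.n_levels}" for v, s in panel.variables),
    )
    if model is None:
        return space
    probs = model.predict(grid)
    if isinstance(probs, pd.Series):
        raise ValueError("genotype-space scoring needs a categorical model")
    classes = list(probs.columns)
    argmax = probs.to_numpy().argmax(axis=1)
    ties = (probs.to_numpy() == probs.to_numpy().max(axis=1, keepdims=True)).sum(axis=1) > 1
    called = np.where(ties, INCONCLUSIVE, np.array(classes, dtype=object)[argmax])
    pred = probs.copy()
    pred["predicted"] = called
    space.predicted = pred
    counts = {c: int((called == c).sum()) for c in classes}
    space.category_counts = counts
    space.category_fractions = {c: counts[c] / n_comb for c in classes}
    space.max_probability = {c: float(probs[c].max()) for c in classes}
    return space


@dataclass
class LikelihoodRatio:
    """P(genotype | brown-eyed) / P(genotype | blue-eyed) from a cohort."""

    rsid: str
    genotype: str
    lr: float
    count_brown: int
    count_blue: int
    n_brown: int
    n_blue: int
    smoothed: bool


def likelihood_ratio(
    cohort: Cohort, rsid: str, genotype: str, smoothing: bool = False
) -> LikelihoodRatio:
    """Two-category weight of evidence for one genotype call at one variant.

    The cohort's PIE-scores define blue/brown under the two-category
    system; the LR is the genotype's relative frequency among brown-eyed
    over blue-eyed individuals.  ``smoothing`` adds 0.5 to both genotype
    counts (avoids zero numerators/denominators for rare genotypes);
    without it, a genotype absent among blue-eyed samples is an error.
    """
    labels = TWO_CATEGORY.categorise(cohort.pie.to_numpy())
    calls = cohort.genotypes[rsid]
    want = "".join(sorted(genotype)) if len(genotype) == 2 else genotype
    norm = calls.map(lambda c: None if c is None else "".join(sorted(str(c))) if len(str(c)) == 2 else str(c))
    is_g = (norm == want).to_numpy()
    known = calls.notna().to_numpy() & (calls != "./.").to_numpy()
    blue = (labels == "blue") & known
    brown = (labels == "brown") & known
    n_blue, n_brown = int(blue.sum()), int(brown.sum())
    if n_blue == 0 or n_brown == 0:
        raise ValueError("both eye-colour categories must be represented")
    c_blue = int((is_g & blue).sum())
    c_brown = int((is_g & brown).sum())
    if smoothing:
        f_brown = (c_brown + 0.5) / (n_brown + 1.0)
        f_blue = (c_blue + 0.5) / (n_blue + 1.0)
    else:
        if c_blue == 0:
            raise ValueError(
                f"genotype {genotype!r} absent among blue-eyed samples; "
                "LR undefined without smoothing"
            )
        f_brown = c_brown / n_brown
        f_blue = c_blue / n_blue
    return LikelihoodRatio(
        rsid=rsid,
        genotype=want,
        lr=f_brown / f_blue,
        count_brown=c_brown,
        count_blue=c_blue,
        n_brown=n_brown,
        n_blue=n_blue,
        smoothed=smoothing,
    )
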