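"""The resampled multi-model variable-importance ranking.

The selection procedure: the cohort is split 100 times into a 2/3 training
and 1/3 test part (splits with a fixed coded variant in the training part
are redrawn).  Per split, seven models are fitted on the training part:

=================  ==========================================
reporting system   models
=================  ==========================================
quantitative       lasso (main), lasso (+rs12913832 interactions), regression tree
two-category       lasso (main), lasso (+rs12913832 interactions), classification tree
three-category     classification tree
=================  ==========================================

Raw importances are |standardised coefficient| for the lasso fits (an
interaction term's coefficient accrues to both partner variables) and total
impurity decrease for the trees.  Within each (split, model) the
importances are standardised to sum one; the mean over all cells ranks the
variables, and variables at or above a mean-importance cutoff (default
0.3%) form the selected set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeClassifier, DecisionTreeRegressor

from .cohort import Cohort, CodedMatrix, encode_cohort
from .lasso import LassoFit, cv_lasso_1se
from .panels import PanelDef
from .transforms import THREE_CATEGORY, TWO_CATEGORY, transform_pie

__all__ = [
    "SplitSpec",
    "ModelSpec",
    "SEVEN_MODELS",
    "ImportanceTable",
    "make_splits",
    "fit_lasso",
    "fit_tree",
    "variable_importance",
    "rank_variants",
    "select_top",
    "DEFAULT_CUTOFF",
]

log = logging.getLogger(__name__)

DEFAULT_CUTOFF = 0.003
HUB = "rs12913832"
MAX_REDRAWS = 10_000


@dataclass(frozen=True)
class SplitSpec:
    train_ids: tuple
    test_ids: tuple
    redraw_count: int = 0


@dataclass(frozen=True)
class ModelSpec:
    system: str  # quantitative | two_category | three_category
    family: str  # lasso_main | lasso_interactions | tree

    @property
    def label(self) -> str:
        return f"{self.system}/{self.family}"


SEVEN_MODELS = (
    ModelSpec("quantitative", "lasso_main"),
    ModelSpec("quantitative", "lasso_interactions"),
    ModelSpec("quantitative", "tree"),
    ModelSpec("two_category", "lasso_main"),
    ModelSpec("two_category", "lasso_interactions"),
    ModelSpec("two_category", "tree"),
    ModelSpec("three_category", "tree"),
)


def _fixed_columns(values: pd.DataFrame, rows) -> list:
    sub = values.loc[list(rows)]
    return [c for c in sub.columns if sub[c].nunique() <= 1]


def make_splits(coded: CodedMatrix, n_reps: int, seed=0) -> "list[SplitSpec]":
    """Draw ``n_reps`` random 2/3-1/3 splits with no fixed coded variant in
    the training part; offending draws are discarded and redrawn (cap
    10,000 redraws, then an error naming a culprit variant).

    Samples are put in a canonical sorted order before shuffling so the
    result depends only on the sample-id set and the seed, not on row
    order.
    """
    ids = sorted(coded.samples)
    n = len(ids)
    if n < 6:
        raise ValueError("need at least 6 samples to split")
    n_train = round(2 * n / 3)
    globally_fixed = _fixed_columns(coded.values, ids)
    if globally_fixed:
        raise ValueError(
            f"variant fixed in the whole cohort: {globally_fixed[0]} "
            "(no valid training split exists)"
        )
    rng = np.random.default_rng(seed)
    splits = []
    redraws = 0
    last_fixed = None
    for _ in range(n_reps):
        while True:
            if redraws > MAX_REDRAWS:
                raise RuntimeError(
                    f"exceeded {MAX_REDRAWS} split redraws; near-fixed variant "
                    f"{last_fixed!r} cannot be kept variable in training sets"
                )
            perm = rng.permutation(n)
            train = [ids[i] for i in perm[:n_train]]
            fixed = _fixed_columns(coded.values, train)
            if not fixed:
                break
            last_fixed = fixed[0]
            redraws += 1
        test = [ids[i] for i in perm[n_train:]]
        splits.append(
            SplitSpec(train_ids=tuple(train), test_ids=tuple(test), redraw_count=redraws)
        )
    return splits


# ---------------------------------------------------------------------------
# model fits


def _design(values: pd.DataFrame, interactions: bool) -> "tuple[np.ndarray, list]":
    """Design matrix and column names; interaction columns are hub*other
    products named 'hub:other' (main effects always retained: the
    hierarchical principle holds by construction)."""
    names = list(values.columns)
    X = values.to_numpy(dtype=float)
    if interactions:
        if HUB not in names:
            raise ValueError(f"interaction design needs the {HUB!r} variable")
        hub = values[HUB].to_numpy(dtype=float)
        extra, extra_names = [], []
        for name in names:
            if name == HUB:
                continue
            extra.append(hub * values[name].to_numpy(dtype=float))
            extra_names.append(f"{HUB}:{name}")
        X = np.column_stack([X] + extra)
        names = names + extra_names
    return X, names


def fit_lasso(
    values: pd.DataFrame,
    response: np.ndarray,
    family: str,
    interactions: bool = False,
    rng=None,
) -> "tuple[LassoFit, list]":
    """L1-penalised fit (glmnet-style path + 10-fold 1-SE rule) on the
    coded training data; returns the fit and the design column names."""
    fixed = _fixed_columns(values, values.index)
    if fixed:
        raise ValueError(f"fixed variant in training data: {fixed[0]}")
    X, names = _design(values, interactions)
    fit = cv_lasso_1se(X, np.asarray(response, float), family=family, rng=rng)
    return fit, names


def fit_tree(values: pd.DataFrame, response, response_kind: str):
    """CART fit with rpart-flavoured defaults.

    minsplit 20 and maxdepth 30 map directly; rpart's complexity parameter
    cp=0.01 (minimum relative improvement of a split) is emulated with
    ``min_impurity_decrease = 0.01 x root impurity``.  Splits use variance
    reduction for a continuous response and Gini impurity otherwise;
    importances are summed impurity decreases over each variable's primary
    splits (no surrogate-split contributions).
    """
    X = values.to_numpy(dtype=float)
    y = np.asarray(response)
    if response_kind == "continuous":
        root_impurity = float(np.var(y.astype(float)))
        cls = DecisionTreeRegressor
    elif response_kind in ("binary", "three_class"):
        _, counts = np.unique(y, return_counts=True)
        pr = counts / counts.sum()
        root_impurity = float(1.0 - np.sum(pr**2))
        cls = DecisionTreeClassifier
    else:
        raise ValueError(f"unknown response kind {response_kind!r}")
    tree = cls(
        min_samples_split=20,
        max_depth=30,
        min_impurity_decrease=0.01 * root_impurity,
        random_state=0,
    )
    tree.fit(X, y)
    return tree


def variable_importance(fit, names, variables) -> pd.Series:
    """Raw (unstandardised) per-variable importance of a fitted model.

    Lasso: |standardised coefficient|; an interaction term 'a:b' adds its
    |coefficient| to both a and b.  Tree: total impurity decrease per
    feature.
    """
    imp = pd.Series(0.0, index=list(variables))
    if isinstance(fit, LassoFit):
        for name, coef in zip(names, fit.coef_std):
            if coef == 0.0:
                continue
            for part in name.split(":"):
                imp[part] += abs(coef)
    else:  # fitted sklearn tree
        # unnormalised impurity decrease: feature_importances_ is
        # normalised, so rescale by the total decrease it divides by
        t = fit.tree_
        total = 0.0
        raw = np.zeros(len(names))
        for node in range(t.node_count):
            if t.children_left[node] < 0:
                continue
            dec = (
                t.weighted_n_node_samples[node] * t.impurity[node]
                - t.weighted_n_node_samples[t.children_left[node]]
                * t.impurity[t.children_left[node]]
                - t.weighted_n_node_samples[t.children_right[node]]
                * t.impurity[t.children_right[node]]
            )
            raw[t.feature[node]] += dec
            total += dec
        for name, v in zip(names, raw):
            imp[name] += v
    return imp


def _standardise_importance(raw: pd.Series) -> pd.Series:
    s = raw.sum()
    return raw / s if s > 0 else raw * 0.0


def _responses(cohort: Cohort, samples) -> dict:
    pie = cohort.pie.loc[list(samples)].to_numpy()
    return {
        "quantitative": transform_pie(pie),
        "two_category": (TWO_CATEGORY.categorise(pie) == "blue").astype(float),
        "three_category": THREE_CATEGORY.categorise(pie),
    }


@dataclass
class ImportanceTable:
    """Standardised importances per (replicate, model), their mean and ranks."""

    per_model: pd.DataFrame  # MultiIndex (replicate, model) x variables
    mean_importance: pd.Series  # variable -> fraction of total importance
    rank: pd.Series  # variable -> 1-based rank by descending mean
    test_errors: pd.DataFrame  # (replicate, model) -> test error
    n_replicates: int
    gene_map: dict = None  # variable -> gene label(s), for display

    def per_model_mean(self) -> pd.DataFrame:
        """Mean importance per model (for inspection)."""
        return self.per_model.groupby(level="model").mean().T

    def to_frame(self) -> pd.DataFrame:
        """Rank table: rank, gene, mean importance (+ per-model means)."""
        out = pd.DataFrame(
            {
                "rank": self.rank,
                "gene": pd.Series(self.gene_map or {}, dtype=object).reindex(
                    self.rank.index, fill_value=""
                ),
                "mean_importance": self.mean_importance,
            }
        ).sort_values("rank")
        out.index.name = "variable"
        return out.join(self.per_model_mean())


def rank_variants(
    cohort: Cohort,
    panel: PanelDef,
    n_reps: int = 100,
    seed=0,
    attribute_interactions: str = "both",
) -> ImportanceTable:
    """Run the full resampled multi-model importance ranking.

    ``attribute_interactions``: "both" credits an interaction coefficient
    to both partner variables, "partner" only to the non-rs12913832 one.
    Replicates whose model fits fail are dropped with a logged reason; more
    than 10% dropped replicates aborts the run.
    """
    if attribute_interactions not in ("both", "partner"):
        raise ValueError("attribute_interactions must be 'both' or 'partner'")
    coded = encode_cohort(cohort, panel, on_missing="drop")
    splits = make_splits(coded, n_reps, seed)
    # independent, individually reproducible CV substreams per replicate
    cv_seeds = np.random.SeedSequence([seed, 1]).spawn(n_reps)

    variables = list(coded.variables)
    rows, row_index, err_rows = [], [], []
    n_failed = 0
    for rep, split in enumerate(splits):
        train = coded.values.loc[list(split.train_ids)]
        test = coded.values.loc[list(split.test_ids)]
        resp_train = _responses(cohort, split.train_ids)
        resp_test = _responses(cohort, split.test_ids)
        cv_rng = np.random.default_rng(cv_seeds[rep])
        try:
            fits = _fit_seven(train, resp_train, cv_rng)
        except Exception as exc:  # noqa: BLE001 - replicate-level abort
            n_failed += 1
            log.warning("replicate %d aborted: %s", rep, exc)
            continue
        for spec, (fit, names) in fits.items():
            raw = variable_importance(fit, names, variables)
            if attribute_interactions == "partner" and isinstance(fit, LassoFit):
                raw = _importance_partner_only(fit, names, variables)
            rows.append(_standardise_importance(raw))
            row_index.append((rep, spec.label))
            err_rows.append(
                {
                    "replicate": rep,
                    "model": spec.label,
                    "test_error": _model_test_error(spec, fit, names, train, test, resp_test),
                }
            )
    if n_failed > 0.1 * n_reps:
        raise RuntimeError(f"{n_failed}/{n_reps} replicates aborted")
    per_model = pd.DataFrame(
        rows, index=pd.MultiIndex.from_tuples(row_index, names=["replicate", "model"])
    )
    mean_imp = per_model.mean(axis=0)
    order = mean_imp.sort_values(ascending=False, kind="stable")
    rank = pd.Series(np.arange(1, len(order) + 1), index=order.index).reindex(
        mean_imp.index
    )
    errors = pd.DataFrame(err_rows).set_index(["replicate", "model"])
    gene_map = {}
    for name, scheme in panel.variables:
        genes = {panel.variant(r).gene for r in scheme.constituent_rsids}
        gene_map[name] = "+".join(sorted(genes))
    return ImportanceTable(
        per_model=per_model,
        mean_importance=mean_imp,
        rank=rank,
        test_errors=errors,
        n_replicates=n_reps - n_failed,
        gene_map=gene_map,
    )


def _importance_partner_only(fit: LassoFit, names, variables) -> pd.Series:
    imp = pd.Series(0.0, index=list(variables))
    for name, coef in zip(names, fit.coef_std):
        if coef == 0.0:
            continue
        if ":" in name:
            imp[name.split(":", 1)[1]] += abs(coef)
        else:
            imp[name] += abs(coef)
    return imp


def _fit_seven(train: pd.DataFrame, resp: dict, cv_rng) -> dict:
    fits = {}
    for spec in SEVEN_MODELS:
        if spec.family == "tree":
            kind = {
                "quantitative": "continuous",
                "two_category": "binary",
                "three_category": "three_class",
            }[spec.system]
            tree = fit_tree(train, resp[spec.system], kind)
            fits[spec] = (tree, list(train.columns))
        else:
            family = "gaussian" if spec.system == "quantitative" else "binomial"
            interactions = spec.family == "lasso_interactions"
            fit, names = fit_lasso(
                train, resp[spec.system], family, interactions=interactions, rng=cv_rng
            )
            fits[spec] = (fit, names)
    return fits


def _model_test_error(spec, fit, names, train, test, resp_test) -> float:
    """Held-out error: MSE (quantitative), mean -log p(truth) otherwise."""
    truth = resp_test[spec.system]
    Xte, _ = _design(test, interactions=(spec.family == "lasso_interactions"))
    if isinstance(fit, LassoFit):
        Xtr, _ = _design(train, interactions=(spec.family == "lasso_interactions"))
        mean = Xtr.mean(axis=0)
        sd = Xtr.std(axis=0)
        sd[sd == 0] = 1.0
        eta = ((Xte - mean) / sd) @ fit.coef_std + fit.intercept
        if spec.system == "quantitative":
            return float(np.mean((truth - eta) ** 2))
        p = np.clip(1.0 / (1.0 + np.exp(-eta)), 1e-12, 1 - 1e-12)
        return float(-np.mean(truth * np.log(p) + (1 - truth) * np.log(1 - p)))
    # tree
    if spec.system == "quantitative":
        pred = fit.predict(Xte)
        return float(np.mean((truth - pred) ** 2))
    proba = np.clip(fit.predict_proba(Xte), 1e-12, None)
    cols = {c: i for i, c in enumerate(fit.classes_)}
    idx = [cols[t] for t in truth]
    return float(-np.mean(np.log(proba[np.arange(len(idx)), idx])))


def select_top(table: ImportanceTable, cutoff: float = DEFAULT_CUTOFF) -> list:
    """Variables with mean importance >= cutoff, in rank order."""
    keep = table.mean_importance[table.mean_importance >= cutoff]
    return list(keep.sort_values(ascending=False, kind="stable").index)
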