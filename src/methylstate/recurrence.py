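"""Recurrence prediction from inferred cell-state proportions.

Exhaustive cell-state combination search under Monte Carlo cross-validation
(stratified 70/30 splits repeated 100 times, shared across combinations and
reference modes so comparisons are paired), tree-ensemble classifiers, AUC
by the rank (Mann-Whitney) formulation and Cohen's kappa at a 0.5
probability threshold, rank-sum comparison between approaches,
response-permutation feature importance, and cross-cohort transfer.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import (
    ExtraTreesClassifier,
    GradientBoostingClassifier,
    RandomForestClassifier,
)

from ._fast_trees import FastExtraTrees
from .deconvolution import CellProportionTable

log = logging.getLogger(__name__)

DEFAULT_TRAIN_FRACTION = 0.7
DEFAULT_N_REPEATS = 100
DEFAULT_N_ESTIMATORS = 100
# exhaustive screening refits thousands of models; a lighter ensemble ranks
# combinations while final evaluations use DEFAULT_N_ESTIMATORS
DEFAULT_SCREEN_N_ESTIMATORS = 50
DEFAULT_KAPPA_THRESHOLD = 0.5
CLINICAL_FIELDS = ("tnm_stage", "metastasis", "msi")
MODEL_KINDS = ("extra_trees", "extra_trees_sklearn", "random_forest", "gradient_boosting")


@dataclass
class ClinicalTable:
    """Per-patient clinical covariates and the binary recurrence label."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        if "recurrence" not in t.columns:
            raise ValueError("clinical table requires a 'recurrence' column")
        if not set(np.unique(t["recurrence"])) <= {0, 1}:
            raise ValueError("recurrence labels must be in {0, 1}")
        if "tnm_stage" in t.columns and not set(np.unique(t["tnm_stage"])) <= {1, 2, 3, 4}:
            raise ValueError("tnm_stage must be ordinal in {1,2,3,4}")

    @property
    def sample_ids(self) -> pd.Index:
        return self.table.index

    @property
    def recurrence(self) -> np.ndarray:
        return self.table["recurrence"].to_numpy(dtype=int)

    def encoded(self, fields: tuple[str, ...]) -> pd.DataFrame:
        """Numeric encoding of the requested clinical fields.

        TNM stays ordinal 1-4; binaries are 0/1; the optional location
        fields map left/colon to 0 and right/rectum to 1.
        """
        cols = {}
        for f in fields:
            if f not in self.table.columns:
                raise ValueError(f"clinical field {f!r} not present")
            col = self.table[f]
            if col.dtype == object:
                col = col.map({"left": 0, "right": 1, "colon": 0, "rectum": 1})
                if col.isna().any():
                    raise ValueError(f"cannot encode clinical field {f!r}")
            cols[f] = col.astype(float)
        return pd.DataFrame(cols, index=self.table.index)


@dataclass
class RecurrenceModelReport:
    """Combination-search output: per-combination CV performance and ranking."""

    ranking: pd.DataFrame  # combination, n_features, mean_auc, sd_auc, mean_kappa, sd_kappa
    auc_per_split: dict[tuple[str, ...], np.ndarray]
    kappa_per_split: dict[tuple[str, ...], np.ndarray]
    n_repeats: int
    seed: int
    model_kind: str
    top_k: pd.DataFrame = field(default=None)

    def best_combination(self) -> tuple[str, ...]:
        return tuple(self.ranking.iloc[0]["combination"])


def enumerate_combinations(class_labels: list[str], sizes: list[int] | None = None):
    """All nonempty subsets, ordered by size then lexicographically.

    ``sizes`` optionally restricts to given subset sizes (e.g. [3]).
    """
    k = len(class_labels)
    if not 1 <= k <= 16:
        raise ValueError("combination search supports 1..16 classes; restrict the label list")
    sizes = sizes or list(range(1, k + 1))
    out = []
    for s in sizes:
        out.extend(itertools.combinations(sorted(class_labels), s))
    return out


def monte_carlo_splits(
    n_samples: int,
    labels: np.ndarray,
    train_fraction: float = DEFAULT_TRAIN_FRACTION,
    n_repeats: int = DEFAULT_N_REPEATS,
    seed: int = 0,
    stratify: bool = True,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Repeated random train/test splits, stratified by label.

    Train size is round(train_fraction * n); per-class allocations keep at
    least one member of each class on both sides whenever the class has
    two or more members.
    """
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2 or counts.min() < 2:
        raise ValueError("both classes must be present with >=2 members")
    n_train = int(round(train_fraction * n_samples))
    if not 0 < n_train < n_samples:
        raise ValueError("degenerate train fraction")

    splits = []
    for rep in range(n_repeats):
        rng = np.random.default_rng([seed, rep])
        if not stratify:
            perm = rng.permutation(n_samples)
            tr, te = perm[:n_train], perm[n_train:]
            for attempt in range(100):
                if len(set(labels[tr])) == 2 and len(set(labels[te])) == 2:
                    break
                perm = rng.permutation(n_samples)
                tr, te = perm[:n_train], perm[n_train:]
            else:
                raise ValueError("could not obtain a split with both classes on both sides")
        else:
            raw = train_fraction * counts
            alloc = np.floor(raw).astype(int)
            # keep each class represented on both sides
            alloc = np.clip(alloc, 1, counts - 1)
            rem = n_train - alloc.sum()
            frac_order = np.argsort(-(raw - np.floor(raw)), kind="stable")
            i = 0
            guard = 0
            while rem != 0 and guard < 10 * len(classes):
                c = frac_order[i % len(classes)]
                if rem > 0 and alloc[c] < counts[c] - 1:
                    alloc[c] += 1
                    rem -= 1
                elif rem < 0 and alloc[c] > 1:
                    alloc[c] -= 1
                    rem += 1
                i += 1
                guard += 1
            if rem != 0:
                raise ValueError("cannot allocate stratified split of requested size")
            tr_parts, te_parts = [], []
            for c, cls in enumerate(classes):
                members = np.flatnonzero(labels == cls)
                perm = rng.permutation(members)
                tr_parts.append(perm[: alloc[c]])
                te_parts.append(perm[alloc[c] :])
            tr = np.concatenate(tr_parts)
            te = np.concatenate(te_parts)
        splits.append((np.sort(tr), np.sort(te)))
    return splits


def auc_rank(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC via the rank (Mann-Whitney) formulation with tie correction."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    n1 = int(labels.sum())
    n0 = len(labels) - n1
    if n1 == 0 or n0 == 0:
        return np.nan
    ranks = stats.rankdata(scores)
    return (ranks[labels == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0)


def cohen_kappa(pred: np.ndarray, truth: np.ndarray) -> float:
    """Chance-corrected agreement between binary predictions and truth."""
    pred = np.asarray(pred, dtype=int)
    truth = np.asarray(truth, dtype=int)
    po = float(np.mean(pred == truth))
    p1, t1 = pred.mean(), truth.mean()
    pe = p1 * t1 + (1 - p1) * (1 - t1)
    if pe == 1.0:
        return 0.0
    return (po - pe) / (1 - pe)


def _sklearn_model(model_kind: str, seed: int, n_estimators: int):
    if model_kind == "extra_trees_sklearn":
        return ExtraTreesClassifier(n_estimators=n_estimators, random_state=seed)
    if model_kind == "random_forest":
        return RandomForestClassifier(n_estimators=n_estimators, random_state=seed)
    if model_kind == "gradient_boosting":
        return GradientBoostingClassifier(n_estimators=n_estimators, random_state=seed)
    raise ValueError(f"unknown model_kind {model_kind!r}; expected one of {MODEL_KINDS}")


def _score_split(X, y, tr, te, model_kind, seed, n_estimators):
    if model_kind == "extra_trees":
        clf = FastExtraTrees(n_estimators=n_estimators, random_state=seed)
        return clf.fit_predict_proba(X[tr], y[tr], X[te])
    model = _sklearn_model(model_kind, seed, n_estimators)
    model.fit(X[tr], y[tr])
    return model.predict_proba(X[te])[:, 1]


def build_features(
    proportions: CellProportionTable | pd.DataFrame,
    clinical: ClinicalTable,
    combination: tuple[str, ...],
    clinical_fields: tuple[str, ...] = (),
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Feature matrix = selected proportion columns + encoded clinical fields."""
    props = proportions.proportions if isinstance(proportions, CellProportionTable) else proportions
    missing = [c for c in combination if c not in props.columns]
    if missing:
        raise ValueError(f"combination classes absent from proportions: {missing}")
    X = props[list(combination)]
    if clinical_fields:
        enc = clinical.encoded(tuple(clinical_fields)).reindex(X.index)
        X = pd.concat([X, enc], axis=1)
    if X.isna().to_numpy().any():
        raise ValueError("missing values in feature matrix")
    y = clinical.table["recurrence"].reindex(X.index)
    if y.isna().any():
        missing = list(y.index[y.isna()])[:5]
        raise ValueError(f"clinical labels missing for samples: {missing}")
    return X.to_numpy(dtype=float), y.to_numpy(dtype=int), list(X.columns)


def train_eval_combination(
    proportions: CellProportionTable | pd.DataFrame,
    clinical: ClinicalTable,
    combination: tuple[str, ...],
    splits: list[tuple[np.ndarray, np.ndarray]],
    clinical_fields: tuple[str, ...] = (),
    model_kind: str = "extra_trees",
    seed: int = 0,
    n_estimators: int = DEFAULT_N_ESTIMATORS,
    kappa_threshold: float = DEFAULT_KAPPA_THRESHOLD,
) -> dict[str, np.ndarray]:
    """Per-split AUC and kappa for one feature combination.

    A test split with a single class leaves that split's AUC undefined
    (NaN, excluded from means downstream, logged).
    """
    X, y, _ = build_features(proportions, clinical, combination, clinical_fields)
    aucs = np.empty(len(splits))
    kappas = np.empty(len(splits))
    for i, (tr, te) in enumerate(splits):
        split_seed = (seed * 1_000_003 + i * 7919 + 1) % (2**31 - 1)
        scores = _score_split(X, y, tr, te, model_kind, split_seed, n_estimators)
        a = auc_rank(scores, y[te])
        if np.isnan(a):
            log.warning("split %d has a single-class test set; AUC undefined", i)
        aucs[i] = a
        kappas[i] = cohen_kappa((scores >= kappa_threshold).astype(int), y[te])
    return {"auc": aucs, "kappa": kappas}


def run_combination_search(
    proportions: CellProportionTable | pd.DataFrame,
    clinical: ClinicalTable,
    combinations: list[tuple[str, ...]] | None = None,
    splits: list[tuple[np.ndarray, np.ndarray]] | None = None,
    clinical_fields: tuple[str, ...] = (),
    model_kind: str = "extra_trees",
    n_repeats: int = DEFAULT_N_REPEATS,
    seed: int = 0,
    n_estimators: int = DEFAULT_SCREEN_N_ESTIMATORS,
    top_k: int = 10,
) -> RecurrenceModelReport:
    """Evaluate every combination on one shared split list and rank them."""
    props = proportions.proportions if isinstance(proportions, CellProportionTable) else proportions
    if combinations is None:
        combinations = enumerate_combinations(list(props.columns))
    y = clinical.table["recurrence"].reindex(props.index).to_numpy(dtype=int)
    if splits is None:
        splits = monte_carlo_splits(len(props), y, n_repeats=n_repeats, seed=seed)
    auc_d: dict[tuple[str, ...], np.ndarray] = {}
    kappa_d: dict[tuple[str, ...], np.ndarray] = {}
    for combo in combinations:
        res = train_eval_combination(
            proportions, clinical, combo, splits,
            clinical_fields=clinical_fields, model_kind=model_kind,
            seed=seed, n_estimators=n_estimators,
        )
        auc_d[tuple(combo)] = res["auc"]
        kappa_d[tuple(combo)] = res["kappa"]
    report = rank_combinations(auc_d, kappa_d, n_repeats=len(splits), seed=seed,
                               model_kind=model_kind, top_k=top_k)
    return report


def rank_combinations(
    auc_per_split: dict[tuple[str, ...], np.ndarray],
    kappa_per_split: dict[tuple[str, ...], np.ndarray],
    n_repeats: int,
    seed: int = 0,
    model_kind: str = "extra_trees",
    top_k: int = 10,
) -> RecurrenceModelReport:
    """Rank by mean AUC descending; ties broken by fewer features, then
    lexicographically."""
    rows = []
    for combo, aucs in auc_per_split.items():
        kappas = kappa_per_split[combo]
        rows.append(
            {
                "combination": combo,
                "n_features": len(combo),
                "mean_auc": float(np.nanmean(aucs)),
                "sd_auc": float(np.nanstd(aucs)),
                "mean_kappa": float(np.nanmean(kappas)),
                "sd_kappa": float(np.nanstd(kappas)),
            }
        )
    ranking = pd.DataFrame(rows)
    ranking = ranking.sort_values(
        by=["mean_auc", "n_features", "combination"],
        ascending=[False, True, True],
        kind="stable",
    ).reset_index(drop=True)
    return RecurrenceModelReport(
        ranking=ranking,
        auc_per_split=auc_per_split,
        kappa_per_split=kappa_per_split,
        n_repeats=n_repeats,
        seed=seed,
        model_kind=model_kind,
        top_k=ranking.head(top_k).copy(),
    )


def clinical_combination_search(
    proportions: CellProportionTable | pd.DataFrame,
    clinical: ClinicalTable,
    base_combination: tuple[str, ...],
    splits: list[tuple[np.ndarray, np.ndarray]],
    clinical_fields: tuple[str, ...] = CLINICAL_FIELDS,
    model_kind: str = "extra_trees",
    seed: int = 0,
    n_estimators: int = DEFAULT_N_ESTIMATORS,
) -> pd.DataFrame:
    """Evaluate every subset of the clinical fields on top of one cell
    combination (the clinical-integration sweep), on shared splits.

    Returns one row per clinical subset (including the empty one) with the
    mean/sd AUC and kappa, sorted by mean AUC descending.
    """
    rows = []
    for r in range(len(clinical_fields) + 1):
        for fields in itertools.combinations(clinical_fields, r):
            res = train_eval_combination(
                proportions, clinical, base_combination, splits,
                clinical_fields=fields, model_kind=model_kind, seed=seed,
                n_estimators=n_estimators,
            )
            rows.append({
                "clinical_fields": fields,
                "mean_auc": float(np.nanmean(res["auc"])),
                "sd_auc": float(np.nanstd(res["auc"])),
                "mean_kappa": float(np.nanmean(res["kappa"])),
            })
    return (pd.DataFrame(rows)
            .sort_values("mean_auc", ascending=False, kind="stable")
            .reset_index(drop=True))


def compare_approaches(auc_samples_a, auc_samples_b) -> float:
    """Two-sided Mann-Whitney U p-value between two AUC distributions."""
    a = np.asarray(auc_samples_a, dtype=float)
    b = np.asarray(auc_samples_b, dtype=float)
    if len(a) < 10 or len(b) < 10:
        raise ValueError("need at least 10 AUC samples per approach")
    return float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)


def permutation_feature_importance(
    features: pd.DataFrame,
    labels: np.ndarray,
    n_perms: int = 100,
    max_features: int = 10,
    n_estimators: int = DEFAULT_N_ESTIMATORS,
    seed: int = 0,
) -> pd.DataFrame:
    """Response-permutation significance of ensemble feature importances.

    Fits the ensemble on the true labels, then on ``n_perms`` label
    permutations; per feature, p = (1 + #{null >= observed}) / (1 + n_perms),
    so a feature dominating every null draw floors at 1/(n_perms + 1).
    """
    if n_perms < 1:
        raise ValueError("n_perms must be >= 1")
    X = features.to_numpy(dtype=float)
    y = np.asarray(labels, dtype=int)
    if X.shape[1] < 2:
        raise ValueError("need at least 2 features")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    mf = min(max_features, X.shape[1])
    rng = np.random.default_rng(seed)

    def _importances(y_fit, s):
        clf = ExtraTreesClassifier(
            n_estimators=n_estimators, max_features=mf, random_state=s
        )
        clf.fit(X, y_fit)
        return clf.feature_importances_

    observed = _importances(y, int(rng.integers(2**31 - 1)))
    null = np.empty((n_perms, X.shape[1]))
    for i in range(n_perms):
        null[i] = _importances(rng.permutation(y), int(rng.integers(2**31 - 1)))
    pvals = (1.0 + (null >= observed[None, :]).sum(axis=0)) / (1.0 + n_perms)
    return pd.DataFrame(
        {"importance": observed, "p_value": pvals}, index=features.columns
    )


def cross_cohort_predict(
    train_proportions: CellProportionTable | pd.DataFrame,
    train_clinical: ClinicalTable,
    test_proportions: CellProportionTable | pd.DataFrame,
    test_clinical: ClinicalTable,
    combination: tuple[str, ...],
    clinical_fields: tuple[str, ...] = (),
    n_repeats: int = DEFAULT_N_REPEATS,
    model_kind: str = "extra_trees",
    seed: int = 0,
    n_estimators: int = DEFAULT_N_ESTIMATORS,
    kappa_threshold: float = DEFAULT_KAPPA_THRESHOLD,
) -> dict[str, np.ndarray]:
    """Train on one full cohort, score another; repeat over model seeds."""
    Xtr, ytr, cols_tr = build_features(train_proportions, train_clinical, combination, clinical_fields)
    Xte, yte, cols_te = build_features(test_proportions, test_clinical, combination, clinical_fields)
    if cols_tr != cols_te:
        raise ValueError(f"feature mismatch between cohorts: {set(cols_tr) ^ set(cols_te)}")
    aucs = np.empty(n_repeats)
    kappas = np.empty(n_repeats)
    for i in range(n_repeats):
        s = (seed * 1_000_003 + i * 104_729 + 3) % (2**31 - 1)
        scores = _score_split(
            np.vstack([Xtr, Xte]), np.concatenate([ytr, yte]),
            np.arange(len(ytr)), np.arange(len(ytr), len(ytr) + len(yte)),
            model_kind, s, n_estimators,
        )
        aucs[i] = auc_rank(scores, yte)
        kappas[i] = cohen_kappa((scores >= kappa_threshold).astype(int), yte)
    return {"auc": aucs, "kappa": kappas}
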