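"""Feature selection, class rebalancing and the RFE-RF response classifier.

The classification chain mirrors the standard delta-radiomics recipe:

1. stratified 80/20 train/test split;
2. z-score standardization (training statistics only);
3. maximum-relevance-minimum-redundancy (MRMR) ranking, keeping the top
   80% of features;
4. elastic-net-penalized logistic regression with 3-fold cross-validation,
   keeping features with importance (absolute standardized coefficient)
   above 0.1;
5. SMOTE oversampling of the training rows (K = 5 neighbors, synthetic
   draws favouring the minority class 3:1) until the classes balance;
6. a recursive-feature-elimination random forest (1000 trees) with
   repeated, nested five-fold cross-validation choosing the feature-subset
   size; the final forest is refit on the full training set.

Model variants: 1 = radiomics only; 2 = radiomics plus one-hot molecular
subtype (the subtype bypasses the radiomics pre-selection); 3 = radiomics
without the 12 MRI mean-intensity features.

All selection, scaling and resampling steps are functions of training rows
only; inside the nested cross-validation the whole chain is refit per
outer fold so out-of-fold scores are leakage-free.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegressionCV
from sklearn.model_selection import RepeatedStratifiedKFold, StratifiedKFold
from sklearn.neighbors import NearestNeighbors

from .core import LABEL_NO_PCR, LABEL_PCR, SUBTYPES
from .features import all_feature_names, intensity_feature_names

LABEL_COLUMN = "label"
SUBTYPE_COLUMN = "subtype"
SPLIT_COLUMN = "split"

#: Default candidate subset sizes for recursive feature elimination.
DEFAULT_RFE_GRID: tuple[int, ...] = (2, 4, 8, 16, 32, 64)


@dataclass
class ModelingConfig:
    """Hyper-parameters of the selection + classification chain."""

    keep_fraction: float = 0.8          #: MRMR top fraction
    importance_threshold: float = 0.1   #: elastic-net coefficient cut
    enet_cv_folds: int = 3
    enet_l1_ratios: tuple[float, ...] = (0.1, 0.5, 0.9)
    enet_n_cs: int = 5
    smote_k: int = 5
    minority_weight: float = 3.0
    n_trees: int = 1000
    #: forests used inside the cross-validated subset-size search; the
    #: final classifier always uses ``n_trees``
    n_trees_cv: int = 150
    cv_folds: int = 5
    cv_repeats: int = 3
    rfe_grid: tuple[int, ...] = DEFAULT_RFE_GRID
    seed: int = 0


@dataclass
class SelectionState:
    """Record of the feature pre-selection fitted on training rows."""

    mrmr_ranking: list[str]
    mrmr_kept: list[str]
    elasticnet_kept: list[str]
    scaling_mean: pd.Series
    scaling_sd: pd.Series
    dropped_constant: list[str]


@dataclass
class TrainedModel:
    """Fitted RFE-RF classifier with its selection state and CV record."""

    variant: int
    features: list[str]
    forest: RandomForestClassifier
    importances: pd.Series
    selection: SelectionState
    cv_predictions: pd.DataFrame    #: columns: row, repeat, score, y
    cv_auc: float
    cv_auc_per_repeat: list[float]
    size_profile: pd.DataFrame      #: mean CV AUC per candidate size
    best_size: int
    threshold: float                #: Youden-optimal on pooled CV scores
    config: ModelingConfig

    def predict_scores(self, table: pd.DataFrame) -> np.ndarray:
        """Classifier score P(pCR) for each row of ``table``."""
        X = encode_design(table, self.variant)
        Xs = (X[list(self.scaled_columns())] - self.selection.scaling_mean[
            self.scaled_columns()]) / self.selection.scaling_sd[self.scaled_columns()]
        X = X.copy()
        X[self.scaled_columns()] = Xs
        pcr_idx = list(self.forest.classes_).index(1)
        return self.forest.predict_proba(X[self.features].to_numpy())[:, pcr_idx]

    def scaled_columns(self) -> list[str]:
        return list(self.selection.scaling_mean.index)


def labels_to_binary(labels: pd.Series) -> np.ndarray:
    """Encode the response label: 1 = pCR, 0 = no-pCR."""
    bad = set(labels.unique()) - {LABEL_PCR, LABEL_NO_PCR}
    if bad:
        raise ValueError(f"unknown labels: {sorted(bad)}")
    return (labels == LABEL_PCR).to_numpy().astype(int)


def radiomics_columns(table: pd.DataFrame, variant: int = 1) -> list[str]:
    """The radiomics feature columns entering a given model variant."""
    cols = [c for c in all_feature_names() if c in table.columns]
    if variant == 3:
        drop = set(intensity_feature_names())
        cols = [c for c in cols if c not in drop]
    return cols


def encode_design(table: pd.DataFrame, variant: int) -> pd.DataFrame:
    """Feature matrix for a variant; one-hot subtype appended for variant 2."""
    X = table[radiomics_columns(table, variant)].copy()
    if variant == 2:
        if SUBTYPE_COLUMN not in table.columns:
            raise ValueError("variant 2 requires a subtype column")
        for s in SUBTYPES:
            X[f"subtype_{s}"] = (table[SUBTYPE_COLUMN] == s).astype(float)
    return X


def subtype_columns() -> list[str]:
    return [f"subtype_{s}" for s in SUBTYPES]


# ---------------------------------------------------------------------------
# split and scaling
# ---------------------------------------------------------------------------

def split_cohort(
    table: pd.DataFrame, train_fraction: float = 0.8, seed: int = 0
) -> pd.DataFrame:
    """Stratified train/test split; training count = floor(n * fraction).

    Per-class training counts are allocated by largest remainder so the
    total is exact while class proportions stay within rounding of the
    cohort proportions.  Returns a copy with a ``split`` column.
    """
    y = table[LABEL_COLUMN]
    counts = y.value_counts()
    if len(counts) < 2:
        raise ValueError("both response classes must be present")
    if counts.min() < 5:
        raise ValueError("need at least 5 lesions per class to split")
    n_train = int(np.floor(len(table) * train_fraction))
    quotas = counts * train_fraction
    base = np.floor(quotas).astype(int)
    remainder = n_train - int(base.sum())
    order = (quotas - base).sort_values(ascending=False).index
    for cls in order[:remainder]:
        base[cls] += 1

    rng = np.random.default_rng(seed)
    out = table.copy()
    out[SPLIT_COLUMN] = "test"
    for cls, k in base.items():
        idx = np.flatnonzero((y == cls).to_numpy())
        chosen = rng.choice(idx, size=int(k), replace=False)
        out.iloc[chosen, out.columns.get_loc(SPLIT_COLUMN)] = "train"
    return out


def zscore_fit_apply(
    train: pd.DataFrame, full: pd.DataFrame, columns: list[str]
) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    """Center/scale ``columns`` by training mean and sd.

    Training columns transform to mean 0, sd 1; every other row is
    transformed with the training statistics.  Zero-variance training
    columns are dropped with a warning.  Returns the transformed copy of
    ``full`` plus the scaling series.
    """
    mean = train[columns].mean()
    sd = train[columns].std(ddof=1)
    keep = sd > 0
    if not keep.all():
        dropped = list(sd.index[~keep])
        warnings.warn(f"dropping zero-variance features: {dropped}", stacklevel=2)
    cols = list(sd.index[keep])
    out = full.copy()
    out[cols] = (full[cols] - mean[cols]) / sd[cols]
    out = out.drop(columns=[c for c in columns if c not in cols])
    return out, mean[cols], sd[cols]


# ---------------------------------------------------------------------------
# MRMR
# ---------------------------------------------------------------------------

def _discretize_tertiles(X: np.ndarray) -> np.ndarray:
    """Tertile-bin each column into {0, 1, 2}."""
    q = np.quantile(X, [1 / 3, 2 / 3], axis=0)
    return (X > q[0]).astype(np.int64) + (X > q[1]).astype(np.int64)


def _mutual_info(a: np.ndarray, b: np.ndarray, na: int, nb: int) -> float:
    joint = np.bincount(a * nb + b, minlength=na * nb).astype(float)
    joint = joint.reshape(na, nb) / len(a)
    pa = joint.sum(axis=1)
    pb = joint.sum(axis=0)
    nz = joint > 0
    return float((joint[nz] * np.log(joint[nz] / np.outer(pa, pb)[nz])).sum())


def _mutual_info_columns(D: np.ndarray, b: np.ndarray, nb: int) -> np.ndarray:
    """MI of every tertile-coded column of ``D`` with the coded vector ``b``."""
    n, m = D.shape
    code = D * nb + b[:, None] + (np.arange(m) * (3 * nb))[None, :]
    joint = np.bincount(code.ravel(), minlength=m * 3 * nb).astype(float)
    joint = joint.reshape(m, 3, nb) / n
    pa = joint.sum(axis=2)
    pb = joint.sum(axis=1)
    denom = pa[:, :, None] * pb[:, None, :]
    nz = joint > 0
    terms = np.where(
        nz, joint * np.log(np.where(nz, joint, 1.0) / np.where(nz, denom, 1.0)), 0.0
    )
    return terms.sum(axis=(1, 2))


def mrmr_rank(X: pd.DataFrame, y: np.ndarray) -> list[str]:
    """Greedy MRMR ranking (mutual-information difference criterion).

    Features are tertile-discretized; the first pick maximizes relevance
    I(f; y) and each subsequent pick maximizes relevance minus the mean
    redundancy I(f; g) with the already selected features.
    """
    cols = list(X.columns)
    if len(cols) < 2:
        raise ValueError("MRMR needs at least 2 features")
    D = _discretize_tertiles(X.to_numpy(dtype=float))
    yb = np.asarray(y, dtype=np.int64)
    n_y = int(yb.max()) + 1
    m = len(cols)
    relevance = _mutual_info_columns(D, yb, n_y)

    selected: list[int] = []
    mask = np.ones(m, dtype=bool)
    redundancy_sum = np.zeros(m)
    first = int(np.argmax(relevance))
    selected.append(first)
    mask[first] = False
    while mask.any():
        redundancy_sum += _mutual_info_columns(D, D[:, selected[-1]], 3)
        scores = np.where(
            mask, relevance - redundancy_sum / len(selected), -np.inf
        )
        nxt = int(np.argmax(scores))
        selected.append(nxt)
        mask[nxt] = False
    return [cols[j] for j in selected]


def mrmr_select(
    X: pd.DataFrame, y: np.ndarray, keep_fraction: float = 0.8
) -> tuple[list[str], list[str]]:
    """MRMR ranking plus the top-``keep_fraction`` subset (round to nearest)."""
    ranking = mrmr_rank(X, y)
    n_keep = int(round(keep_fraction * len(ranking)))
    n_keep = max(1, min(n_keep, len(ranking)))
    return ranking, ranking[:n_keep]


# ---------------------------------------------------------------------------
# elastic net
# ---------------------------------------------------------------------------

def elasticnet_select(
    X: pd.DataFrame,
    y: np.ndarray,
    importance_threshold: float = 0.1,
    cv_folds: int = 3,
    l1_ratios=(0.1, 0.5, 0.9),
    n_cs: int = 5,
    seed: int = 0,
) -> tuple[list[str], pd.Series]:
    """Features whose elastic-net logistic coefficients exceed the threshold.

    A binomial model with elastic-net penalty is fitted on the (already
    standardized) features; the penalty strength and mixing parameter are
    chosen by ``cv_folds``-fold cross-validated log-loss.  Importance is
    the absolute coefficient; features with importance > threshold are
    kept.  An empty selection is returned with a warning (the caller is
    expected to fall back to the MRMR subset).
    """
    cv = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    model = LogisticRegressionCV(
        penalty="elasticnet",
        solver="saga",
        l1_ratios=list(l1_ratios),
        Cs=n_cs,
        cv=cv,
        scoring="neg_log_loss",
        max_iter=500,
        tol=1e-2,
        random_state=seed,
        n_jobs=None,
    )
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*ConvergenceWarning.*")
        from sklearn.exceptions import ConvergenceWarning

        warnings.simplefilter("ignore", ConvergenceWarning)
        model.fit(X.to_numpy(dtype=float), y)
    importance = pd.Series(np.abs(model.coef_[0]), index=X.columns)
    kept = list(importance.index[importance > importance_threshold])
    if not kept:
        warnings.warn(
            "elastic net selected no features; falling back to the MRMR set",
            stacklevel=2,
        )
    return kept, importance


# ---------------------------------------------------------------------------
# SMOTE
# ---------------------------------------------------------------------------

def smote_augment(
    X: np.ndarray,
    y: np.ndarray,
    k: int = 5,
    minority_weight: float = 3.0,
    rng: np.random.Generator | None = None,
    max_draws: int | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Synthetic-minority oversampling with class-weighted draws.

    Each draw picks a class with probability proportional to
    ``minority_weight`` for the minority class (3:1 by default) and 1 for
    the majority, then a random member of that class, and synthesizes a
    point uniformly on the segment between the member and one of its ``k``
    nearest same-class neighbors (among the original rows).  Draws stop
    when the class counts balance.

    Returns the augmented ``X``, ``y`` and a boolean mask flagging the
    synthetic rows.
    """
    rng = rng or np.random.default_rng()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError("SMOTE requires exactly two classes")
    minority = classes[np.argmin(counts)]
    majority = classes[np.argmax(counts)]
    if counts.min() == counts.max():
        return X, y, np.zeros(len(y), dtype=bool)

    members = {c: np.flatnonzero(y == c) for c in classes}
    k_eff = {}
    nbrs = {}
    for c in classes:
        kc = min(k, len(members[c]) - 1)
        if kc < 1:
            raise ValueError("each class needs at least 2 members for SMOTE")
        if kc < k:
            warnings.warn(
                f"class {c!r} has fewer than k+1 members; reduced k to {kc}",
                stacklevel=2,
            )
        k_eff[c] = kc
        nn = NearestNeighbors(n_neighbors=kc + 1).fit(X[members[c]])
        # drop self (first neighbor)
        nbrs[c] = members[c][nn.kneighbors(X[members[c]])[1][:, 1:]]

    p_min = minority_weight / (minority_weight + 1.0)
    tally = {c: int(n) for c, n in zip(classes, counts)}
    gap0 = abs(tally[majority] - tally[minority])
    cap = max_draws if max_draws is not None else 50 * gap0 + 100
    new_X, new_y = [], []
    draws = 0
    while tally[minority] != tally[majority] and draws < cap:
        draws += 1
        cls = minority if rng.uniform() < p_min else majority
        i = rng.integers(len(members[cls]))
        base = X[members[cls][i]]
        neighbor = X[nbrs[cls][i][rng.integers(k_eff[cls])]]
        t = rng.uniform()
        new_X.append(base + t * (neighbor - base))
        new_y.append(cls)
        tally[cls] += 1

    if not new_X:
        return X, y, np.zeros(len(y), dtype=bool)
    Xa = np.vstack([X, np.array(new_X)])
    ya = np.concatenate([y, np.array(new_y, dtype=y.dtype)])
    synthetic = np.zeros(len(ya), dtype=bool)
    synthetic[len(y):] = True
    return Xa, ya, synthetic


# ---------------------------------------------------------------------------
# RFE-RF with repeated nested cross-validation
# ---------------------------------------------------------------------------

def _auc(scores: np.ndarray, y: np.ndarray) -> float:
    """Mann-Whitney AUC with tie correction (midranks)."""
    from scipy.stats import rankdata

    pos = np.asarray(y) == 1
    n1 = int(pos.sum())
    n0 = len(y) - n1
    if n1 == 0 or n0 == 0:
        return np.nan
    ranks = rankdata(scores)
    return (ranks[pos].sum() - n1 * (n1 + 1) / 2) / (n1 * n0)


def _fit_chain(
    table: pd.DataFrame,
    variant: int,
    config: ModelingConfig,
    seed: int,
) -> tuple[SelectionState, pd.DataFrame, np.ndarray, np.ndarray, list[str]]:
    """Pre-selection + SMOTE on one set of training rows.

    Returns the selection state, the z-scored training design, the
    augmented training arrays, and the feature list entering the RFE-RF.
    """
    X = encode_design(table, variant)
    y = labels_to_binary(table[LABEL_COLUMN])
    radio_cols = [c for c in X.columns if not c.startswith("subtype_")]

    Xs, mean, sd = zscore_fit_apply(X, X, radio_cols)
    dropped = [c for c in radio_cols if c not in mean.index]
    radio_cols = list(mean.index)

    ranking, mrmr_kept = mrmr_select(Xs[radio_cols], y, config.keep_fraction)
    enet_kept, _importance = elasticnet_select(
        Xs[mrmr_kept],
        y,
        importance_threshold=config.importance_threshold,
        cv_folds=config.enet_cv_folds,
        l1_ratios=config.enet_l1_ratios,
        n_cs=config.enet_n_cs,
        seed=seed,
    )
    selected = enet_kept if enet_kept else list(mrmr_kept)
    model_cols = selected + (subtype_columns() if variant == 2 else [])

    rng = np.random.default_rng(seed)
    Xa, ya, _synth = smote_augment(
        Xs[model_cols].to_numpy(dtype=float),
        y,
        k=config.smote_k,
        minority_weight=config.minority_weight,
        rng=rng,
    )
    state = SelectionState(
        mrmr_ranking=ranking,
        mrmr_kept=mrmr_kept,
        elasticnet_kept=enet_kept,
        scaling_mean=mean,
        scaling_sd=sd,
        dropped_constant=dropped,
    )
    return state, Xs, Xa, ya, model_cols


def _apply_scaling(
    table: pd.DataFrame, variant: int, state: SelectionState, cols: list[str]
) -> np.ndarray:
    X = encode_design(table, variant)
    scaled = X.copy()
    sc = list(state.scaling_mean.index)
    scaled[sc] = (X[sc] - state.scaling_mean) / state.scaling_sd
    return scaled[cols].to_numpy(dtype=float)


#: sentinel size label meaning "all pre-selected features"
ALL_FEATURES = 1_000_000


def _candidate_sizes(n_features: int, grid) -> dict[int, int]:
    """Nominal grid label -> actual subset size for one fold.

    The pre-selected feature count varies between folds, so out-of-fold
    scores are pooled by the nominal label; labels above the fold's
    feature count are capped at it.
    """
    sizes = {s: min(s, n_features) for s in sorted(grid)}
    sizes[ALL_FEATURES] = n_features
    return sizes


def _forest(n_trees: int, seed: int, oob: bool = False) -> RandomForestClassifier:
    return RandomForestClassifier(
        n_estimators=n_trees, random_state=seed, n_jobs=None, oob_score=oob
    )


def train_rfe_rf(
    table: pd.DataFrame,
    variant: int = 1,
    config: ModelingConfig | None = None,
) -> TrainedModel:
    """Train the RFE-RF classifier with repeated nested five-fold CV.

    ``table`` holds one lesion per row with the 255 canonical feature
    columns, a ``label`` column, a ``subtype`` column (variant 2) and
    optionally a ``split`` column (only ``train`` rows are used, so test
    rows can never influence the fit).

    Per outer fold the full chain (scaling, MRMR, elastic net, SMOTE) is
    refit on the fold-training rows; a ranking forest orders features by
    Gini importance and each candidate subset size is scored on the
    held-out fold.  The reported out-of-fold predictions use, for every
    fold, the subset size that maximizes the *other* folds' held-out AUC
    (nested read-out, free of selection optimism); the final forest is
    refit on the whole training set at the size with the best overall
    mean out-of-fold AUC.  The operating threshold is the Youden point of
    the pooled out-of-fold scores.
    """
    config = config or ModelingConfig()
    if variant not in (1, 2, 3):
        raise ValueError("variant must be 1, 2 or 3")
    if SPLIT_COLUMN in table.columns:
        table = table[table[SPLIT_COLUMN] == "train"]
    table = table.reset_index(drop=True)
    y_all = labels_to_binary(table[LABEL_COLUMN])
    if min((y_all == 1).sum(), (y_all == 0).sum()) < config.cv_folds:
        raise ValueError("too few lesions per class for the outer CV")

    ss = np.random.SeedSequence(config.seed)
    fold_seeds = ss.generate_state(1 + config.cv_folds * config.cv_repeats + 1)
    outer = RepeatedStratifiedKFold(
        n_splits=config.cv_folds,
        n_repeats=config.cv_repeats,
        random_state=int(fold_seeds[0] % (2**31)),
    )

    records = []  # (size, fold, repeat, row, score, y)
    nested_fold_aucs: list[float] = []  # held-out AUC at each fold's own size
    for f, (tr_idx, te_idx) in enumerate(outer.split(table, y_all)):
        repeat = f // config.cv_folds
        seed_f = int(fold_seeds[1 + f] % (2**31))
        tr = table.iloc[tr_idx]
        state, _Xs, Xa, ya, cols = _fit_chain(tr, variant, config, seed_f)
        X_te = _apply_scaling(table.iloc[te_idx], variant, state, cols)

        ranker = _forest(config.n_trees_cv, seed_f, oob=True).fit(Xa, ya)
        order = np.argsort(ranker.feature_importances_)[::-1]
        pcr_idx = list(ranker.classes_).index(1)
        score_cache: dict[int, np.ndarray] = {}
        oob_cache: dict[int, float] = {}
        for nominal, actual in _candidate_sizes(len(cols), config.rfe_grid).items():
            if actual not in score_cache:
                top = order[:actual]
                if actual == len(cols):
                    rf = ranker
                else:
                    rf = _forest(config.n_trees_cv, seed_f, oob=True).fit(
                        Xa[:, top], ya
                    )
                score_cache[actual] = rf.predict_proba(X_te[:, top])[:, pcr_idx]
                # inner selection criterion: out-of-bag AUC on fold-train
                oob_cache[actual] = _auc(
                    rf.oob_decision_function_[:, pcr_idx], ya
                )
            sc = score_cache[actual]
            for row, s, yy in zip(te_idx, sc, y_all[te_idx]):
                records.append(
                    (nominal, f, repeat, int(row), float(s), int(yy))
                )
        # the fold's own subset size: best out-of-bag AUC (ties -> smaller)
        inner_best = min(
            oob_cache, key=lambda a: (-round(oob_cache[a], 12), a)
        )
        nested_fold_aucs.append(
            _auc(score_cache[inner_best], y_all[te_idx])
        )

    rec = pd.DataFrame(
        records, columns=["size", "fold", "repeat", "row", "score", "y"]
    )
    profile = (
        rec.groupby(["size", "repeat"])
        .apply(
            lambda g: _auc(g["score"].to_numpy(), g["y"].to_numpy()),
            include_groups=False,
        )
        .groupby("size")
        .mean()
        .rename("cv_auc")
        .reset_index()
    )
    best_size = int(
        profile.loc[profile["cv_auc"].idxmax(), "size"]
    )
    # nested read-out: each fold's subset size was chosen by the forests'
    # out-of-bag AUC on that fold's training rows, so the held-out AUC at
    # the chosen size is free of selection optimism.  Fold AUCs are
    # averaged rather than pooled because folds evaluated at different
    # sizes have incomparable score calibrations.
    auc_per_repeat = [
        float(np.mean(nested_fold_aucs[r * config.cv_folds : (r + 1) * config.cv_folds]))
        for r in range(config.cv_repeats)
    ]
    cv_auc = float(np.mean(auc_per_repeat))

    # pooled fixed-size out-of-fold scores (consistent calibration) for the
    # operating threshold and the CV ROC report
    best = (
        rec[rec["size"] == best_size]
        .drop(columns=["size", "fold"])
        .sort_values(["repeat", "row"], kind="stable")
        .reset_index(drop=True)
    )

    # final refit on the full training set
    final_seed = int(fold_seeds[-1] % (2**31))
    state, _Xs, Xa, ya, cols = _fit_chain(table, variant, config, final_seed)
    ranker = _forest(config.n_trees, final_seed).fit(Xa, ya)
    order = np.argsort(ranker.feature_importances_)[::-1]
    size = min(best_size, len(cols))
    top = order[:size]
    best_size = size
    final_cols = [cols[i] for i in top]
    forest = _forest(config.n_trees, final_seed).fit(Xa[:, top], ya)
    importances = pd.Series(
        forest.feature_importances_, index=final_cols
    ).sort_values(ascending=False)

    threshold = youden_threshold(best["score"].to_numpy(), best["y"].to_numpy())

    model = TrainedModel(
        variant=variant,
        features=final_cols,
        forest=forest,
        importances=importances,
        selection=state,
        cv_predictions=best.reset_index(drop=True),
        cv_auc=cv_auc,
        cv_auc_per_repeat=auc_per_repeat,
        size_profile=profile,
        best_size=best_size,
        threshold=threshold,
        config=config,
    )
    return model


def youden_threshold(scores: np.ndarray, y: np.ndarray) -> float:
    """Threshold maximizing sensitivity + specificity - 1 (Youden's J)."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y)
    order = np.argsort(scores)
    s = scores[order]
    cand = np.concatenate([[s[0] - 1e-9], (s[1:] + s[:-1]) / 2, [s[-1] + 1e-9]])
    n1 = (y == 1).sum()
    n0 = (y == 0).sum()
    best_t, best_j = cand[0], -np.inf
    for t in cand:
        pred = scores >= t
        tpr = (pred & (y == 1)).sum() / n1
        fpr = (pred & (y == 0)).sum() / n0
        j = tpr - fpr
        if j > best_j:
            best_j, best_t = j, t
    return float(best_t)
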