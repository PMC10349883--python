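"""Feature assembly, missing-stage imputation, and index models.

A cognitive index here is a linear score: held-out Elastic-Net predictions
of a cognitive target from the sleep-feature vector, trained with nested
ten-fold cross-validation (inner folds choose the penalty strength and
L1/L2 mixing on a glmnet-style path, outer folds give each subject exactly
one held-out prediction).  The brain-age comparator uses the same protocol
restricted to the waveform + frequency feature domains, predicting
chronological age; the index is predicted minus chronological age.

Features are z-scored and missing stages KNN-imputed strictly inside each
training fold, so the held-out fold never leaks into fitting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sstats
from sklearn.linear_model import ElasticNet, ElasticNetCV
from sklearn.model_selection import KFold

from .config import ModelConfig, PipelineConfig, log_stage
from .features import BAI_PREFIXES, feature_manifest
from .io import FeatureTable, Hypnogram, Recording
from .macrostructure import compute_macrostructure
from .preprocess import preprocess_recording
from .spectral import extract_region_spectral


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------

def assemble_features(macro: dict, event_feats: dict,
                      spectral_by_region: dict,
                      electrode_set: str = "central") -> pd.Series:
    """Concatenate feature blocks into the fixed manifest order."""
    merged = {}
    merged.update(macro)
    merged.update(event_feats)
    for region_feats in spectral_by_region.values():
        merged.update(region_feats)
    names = feature_manifest(electrode_set)
    unknown = set(merged) - set(names)
    if unknown:
        raise ValueError(f"unknown feature names: {sorted(unknown)[:5]}")
    missing = set(names) - set(merged)
    if missing:
        raise ValueError(f"feature blocks incomplete; missing "
                         f"{sorted(missing)[:5]}")
    return pd.Series([merged[n] for n in names], index=names, dtype=float)


def extract_features(recording: Recording, hypnogram: Hypnogram,
                     electrode_set: str = "central",
                     cfg: PipelineConfig | None = None) -> pd.Series:
    """Full single-night extraction: preprocess then all feature blocks."""
    from .events import extract_event_features
    from .features import ELECTRODE_SETS
    cfg = cfg or PipelineConfig()
    clean, grid = preprocess_recording(recording, hypnogram, cfg.preprocess)
    macro = compute_macrostructure(
        hypnogram, rem_latency_from_onset=cfg.macro.rem_latency_from_onset)
    ev = extract_event_features(clean, hypnogram, grid,
                                cfg.spindle, cfg.slow_osc)
    spec = {r: extract_region_spectral(clean, hypnogram, grid, r,
                                       cfg.spectral)
            for r in ELECTRODE_SETS[electrode_set]}
    row = assemble_features(macro, ev, spec, electrode_set)
    log_stage("extract_features", electrode_set=electrode_set,
              n_features=len(row),
              n_missing=int(row.isna().sum()))
    return row


# ---------------------------------------------------------------------------
# KNN imputation
# ---------------------------------------------------------------------------

class KNNFeatureImputer:
    """Impute missing features from the K nearest training subjects.

    Distances are root-mean-square differences over mutually observed,
    z-scored features (z statistics from the training table).  A missing
    value becomes the mean of the feature over the K nearest training
    subjects that observed it.
    """

    def __init__(self, k: int = 10):
        self.k = k

    def fit(self, table: pd.DataFrame) -> "KNNFeatureImputer":
        if self.k < 1:
            raise ValueError("K must be >= 1")
        all_missing = table.columns[table.isna().all()]
        if len(all_missing):
            raise ValueError(
                f"features missing for all subjects: {list(all_missing)}")
        self.columns_ = list(table.columns)
        self.means_ = table.mean().to_numpy()
        sds = table.std(ddof=0).to_numpy()
        sds[~(sds > 0)] = 1.0
        self.sds_ = sds
        self.train_z_ = (table.to_numpy(float) - self.means_) / self.sds_
        return self

    def _impute_row(self, z_row: np.ndarray, train_z: np.ndarray,
                    skip_self: int | None = None) -> np.ndarray:
        obs = ~np.isnan(z_row)
        out = z_row.copy()
        missing_j = np.flatnonzero(~obs)
        if missing_j.size == 0:
            return out
        diffs = train_z - z_row[None, :]
        shared = obs[None, :] & ~np.isnan(train_z)
        with np.errstate(invalid="ignore"):
            sq = np.where(shared, diffs ** 2, 0.0)
        counts = shared.sum(axis=1)
        dist = np.sqrt(sq.sum(axis=1) / np.maximum(counts, 1))
        dist[counts == 0] = np.inf
        if skip_self is not None:
            dist[skip_self] = np.inf
        order = np.argsort(dist, kind="stable")
        for j in missing_j:
            donors = [i for i in order
                      if np.isfinite(dist[i])
                      and not np.isnan(train_z[i, j])][:self.k]
            if not donors:
                raise ValueError(
                    f"no donor subjects for feature {self.columns_[j]!r}")
            out[j] = train_z[donors, j].mean()
        return out

    def transform(self, table: pd.DataFrame,
                  is_train: bool = False) -> pd.DataFrame:
        X = table[self.columns_].to_numpy(float)
        z = (X - self.means_) / self.sds_
        out = X.copy()
        for i in range(z.shape[0]):
            miss = np.isnan(z[i])
            if not miss.any():
                continue
            skip = i if is_train else None
            zf = self._impute_row(z[i], self.train_z_, skip_self=skip)
            out[i, miss] = zf[miss] * self.sds_[miss] + self.means_[miss]
        return pd.DataFrame(out, index=table.index, columns=self.columns_)


def knn_impute(table: FeatureTable, k: int = 10) -> FeatureTable:
    """Complete a feature table in place of its missing-stage NaNs."""
    imputer = KNNFeatureImputer(k).fit(table.df)
    out = imputer.transform(table.df, is_train=True)
    return FeatureTable(out, table.electrode_set)


# ---------------------------------------------------------------------------
# nested cross-validated Elastic Net
# ---------------------------------------------------------------------------

@dataclass
class FoldModel:
    feature_names: list
    coef: np.ndarray            # in z-scored feature space
    intercept: float
    mean: np.ndarray
    sd: np.ndarray
    alpha: float
    l1_ratio: float
    test_subjects: list = field(default_factory=list)


@dataclass
class IndexModelResult:
    target: str
    subject_ids: list
    y_true: np.ndarray
    y_pred: np.ndarray          # held-out prediction, one per subject
    fold_assignment: np.ndarray
    fold_models: list
    r_heldout: float
    mae: float

    def predictions_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "subject_id": self.subject_ids,
            "target": self.target,
            "fold": self.fold_assignment,
            "y_true": self.y_true,
            "y_pred": self.y_pred,
        })


def sci_score(feature_row, fold_model: FoldModel):
    """intercept + coef . z(features); accepts one row or a matrix."""
    x = np.asarray(feature_row, float)
    one_d = x.ndim == 1
    x = np.atleast_2d(x)
    if x.shape[1] != len(fold_model.feature_names):
        raise ValueError(
            f"feature dimension {x.shape[1]} does not match model "
            f"({len(fold_model.feature_names)})")
    z = (x - fold_model.mean) / fold_model.sd
    s = fold_model.intercept + z @ fold_model.coef
    return float(s[0]) if one_d else s


def nested_cv_elastic_net(table: FeatureTable, target_scores, seed: int = 0,
                          cfg: ModelConfig | None = None,
                          target_name: str = "score") -> IndexModelResult:
    """Nested ten-fold CV Elastic Net with strict train/test separation.

    Outer folds are a seeded random partition of subjects.  Within each
    outer training set an inner ten-fold CV picks (alpha, l1_ratio) by mean
    squared error over the configured grid; imputation and standardization
    statistics come from the outer training set only; the refit model then
    predicts the held-out fold.
    """
    cfg = cfg or ModelConfig()
    y = np.asarray(target_scores, float)
    n = len(y)
    if n != len(table.subject_ids):
        raise ValueError("target length does not match table")
    if n < 20:
        raise ValueError("need at least 20 subjects")
    if np.ptp(y) == 0:
        raise ValueError("constant target; nothing to fit")

    df = table.df
    outer = KFold(cfg.n_outer_folds, shuffle=True, random_state=seed)
    y_pred = np.full(n, np.nan)
    fold_assignment = np.full(n, -1, dtype=int)
    fold_models = []
    for fold_id, (tr, te) in enumerate(outer.split(df)):
        df_tr, df_te = df.iloc[tr], df.iloc[te]
        if df_tr.isna().any().any() or df_te.isna().any().any():
            imputer = KNNFeatureImputer(cfg.knn_k).fit(df_tr)
            df_tr = imputer.transform(df_tr, is_train=True)
            df_te = imputer.transform(df_te)
        Xtr, Xte = df_tr.to_numpy(float), df_te.to_numpy(float)
        mean, sd = Xtr.mean(axis=0), Xtr.std(axis=0)
        sd[~(sd > 0)] = 1.0
        Ztr, Zte = (Xtr - mean) / sd, (Xte - mean) / sd

        inner = KFold(cfg.n_inner_folds, shuffle=True,
                      random_state=seed + 1000 + fold_id)
        search = ElasticNetCV(l1_ratio=list(cfg.l1_ratios),
                              alphas=cfg.n_alphas, eps=cfg.alpha_eps,
                              cv=inner, max_iter=cfg.max_iter)
        search.fit(Ztr, y[tr])
        model = ElasticNet(alpha=search.alpha_, l1_ratio=search.l1_ratio_,
                           max_iter=cfg.max_iter)
        model.fit(Ztr, y[tr])
        y_pred[te] = model.predict(Zte)
        fold_assignment[te] = fold_id
        fold_models.append(FoldModel(
            feature_names=list(df.columns), coef=model.coef_.copy(),
            intercept=float(model.intercept_), mean=mean, sd=sd,
            alpha=float(search.alpha_), l1_ratio=float(search.l1_ratio_),
            test_subjects=[table.subject_ids[i] for i in te]))

    assert not np.isnan(y_pred).any(), "every subject predicted exactly once"
    r = float(sstats.pearsonr(y, y_pred)[0]) if np.ptp(y_pred) > 0 else 0.0
    mae = float(np.mean(np.abs(y - y_pred)))
    log_stage("nested_cv_elastic_net", target=target_name, n=n,
              r_heldout=round(r, 4), mae=round(mae, 4), seed=seed)
    return IndexModelResult(target_name, list(table.subject_ids), y.copy(),
                            y_pred, fold_assignment, fold_models, r, mae)


def fit_final_model(table: FeatureTable, target_scores,
                    result: IndexModelResult,
                    cfg: ModelConfig | None = None) -> FoldModel:
    """One deployable model: hyperparameters by majority vote over folds,
    refit on all subjects."""
    cfg = cfg or ModelConfig()
    pairs = [(m.alpha, m.l1_ratio) for m in result.fold_models]
    vals, counts = np.unique([f"{a}|{l}" for a, l in pairs],
                             return_counts=True)
    a, l = vals[int(np.argmax(counts))].split("|")
    alpha, l1_ratio = float(a), float(l)
    df = table.df
    if df.isna().any().any():
        df = KNNFeatureImputer(cfg.knn_k).fit(df).transform(df, is_train=True)
    X = df.to_numpy(float)
    mean, sd = X.mean(axis=0), X.std(axis=0)
    sd[~(sd > 0)] = 1.0
    model = ElasticNet(alpha=alpha, l1_ratio=l1_ratio, max_iter=cfg.max_iter)
    model.fit((X - mean) / sd, np.asarray(target_scores, float))
    return FoldModel(list(df.columns), model.coef_.copy(),
                     float(model.intercept_), mean, sd, alpha, l1_ratio)


# ---------------------------------------------------------------------------
# brain-age comparator
# ---------------------------------------------------------------------------

def bai_feature_subset(table: FeatureTable) -> FeatureTable:
    """Restrict to the waveform + frequency domains (the brain-age inputs)."""
    cols = [c for c in table.df.columns if c.startswith(BAI_PREFIXES)]
    return FeatureTable(table.df[cols], electrode_set=None)


def train_bai(table: FeatureTable, ages, seed: int = 0,
              cfg: ModelConfig | None = None):
    """Brain-age index: held-out predicted age minus chronological age.

    Returns (bai array, IndexModelResult of the age model).
    """
    sub = bai_feature_subset(table)
    result = nested_cv_elastic_net(sub, ages, seed=seed, cfg=cfg,
                                   target_name="age")
    bai = result.y_pred - np.asarray(ages, float)
    return bai, result


def electrode_subset(table_all: FeatureTable,
                     electrode_set: str) -> FeatureTable:
    """Project an all-electrode table onto one electrode set's manifest."""
    names = feature_manifest(electrode_set)
    missing = set(names) - set(table_all.df.columns)
    if missing:
        raise ValueError(f"table lacks columns for {electrode_set!r}: "
                         f"{sorted(missing)[:5]}")
    return FeatureTable(table_all.df[names], electrode_set)


def run_electrode_ablation(table_all: FeatureTable, target_scores,
                           seed: int = 0, cfg: ModelConfig | None = None,
                           sets=("central", "frontal", "occipital", "all"),
                           target_name: str = "score") -> pd.DataFrame:
    """One nested-CV result per electrode set (central / frontal /
    occipital / all), reported as held-out r and MAE per set."""
    rows = []
    for es in sets:
        res = nested_cv_elastic_net(electrode_subset(table_all, es),
                                    target_scores, seed=seed, cfg=cfg,
                                    target_name=f"{target_name}[{es}]")
        rows.append({"electrode_set": es, "n_features":
                     len(feature_manifest(es)), "r_heldout": res.r_heldout,
                     "mae": res.mae})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# model persistence
# ---------------------------------------------------------------------------

def fold_model_to_dict(m: FoldModel) -> dict:
    return {
        "feature_names": list(m.feature_names),
        "coef": [float(c) for c in m.coef],
        "intercept": m.intercept,
        "mean": [float(v) for v in m.mean],
        "sd": [float(v) for v in m.sd],
        "alpha": m.alpha,
        "l1_ratio": m.l1_ratio,
    }


def fold_model_from_dict(d: dict) -> FoldModel:
    return FoldModel(list(d["feature_names"]), np.asarray(d["coef"], float),
                     float(d["intercept"]), np.asarray(d["mean"], float),
                     np.asarray(d["sd"], float), float(d["alpha"]),
                     float(d["l1_ratio"]))
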