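"""Gradient-boosted classification with nested, cluster-grouped tuning.

The hybrid model concatenates GNN embeddings (per-fold encoders, used only
for embedding extraction), scaled physicochemical descriptors and binary
target annotations, selects features per fold, tunes the booster on inner
cluster-grouped folds scored by average precision, and reports ROC-AUC, MCC,
F1, precision and balanced accuracy on the outer validation folds and the
held-out test set.  A label-shuffle control reruns the entire pipeline with
permuted training labels to demonstrate chance-level behaviour.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import average_precision_score, roc_auc_score
from xgboost import XGBClassifier

from . import dmpnn
from .chemio import CompoundRecord
from .featurize import (FeatureMatrix, ScalerState, assemble,
                        build_target_vocabulary, descriptor_matrix,
                        encode_targets, fingerprint_matrix)
from .select import SelectionMask, default_budget, select_features
from .split import SplitPlan, murcko_scaffold_split, stratified_group_kfold

# ---------------------------------------------------------------------------
# configuration

@dataclass
class BoosterConfig:
    """Tree-ensemble hyperparameters; search ranges follow the published protocol."""

    n_trees: int = 300
    learning_rate: float = 0.1
    max_depth: int = 6
    colsample: float = 0.8
    seed: int = 0
    kind: str = "xgb"  # "xgb" (default) or "rf" (alternative comparator)


def sample_booster_config(rng: np.random.Generator) -> BoosterConfig:
    """One draw from the search space: trees 100-400, lr log-uniform 0.01-0.2,
    depth 3-10, column subsample 0.1-0.9."""
    return BoosterConfig(
        n_trees=int(rng.integers(100, 401)),
        learning_rate=float(np.exp(rng.uniform(np.log(0.01), np.log(0.2)))),
        max_depth=int(rng.integers(3, 11)),
        colsample=float(rng.uniform(0.1, 0.9)),
    )


def paper_booster_config() -> BoosterConfig:
    """The configuration reported for the final published model."""
    return BoosterConfig(n_trees=300, learning_rate=0.016, max_depth=6, colsample=0.4)


@dataclass
class PipelineOptions:
    """Knobs shared by nested CV, final fit, shuffle control and screening."""

    families: tuple[str, ...] = ("GNN", "DESCRIPTOR", "TARGET")
    budget: int | None = None          # None -> 400/300/200 by family count
    min_count: int = 2
    corr_threshold: float = 0.8
    rfe_step: float | int = 0.05
    n_iter: int = 15                   # booster random-search iterations
    inner_k: int = 3
    threshold: float = 0.5
    ecfp_radius: int = 2
    nbits: int = 2048
    mpnn: dmpnn.MPNNConfig = field(default_factory=dmpnn.MPNNConfig)
    scale_pos_weight: float | None = None  # booster reweighting escape hatch
    seed: int = 0


# ---------------------------------------------------------------------------
# metrics

@dataclass
class EvalReport:
    roc_auc: float
    mcc: float
    f1: float
    precision: float
    balanced_accuracy: float
    tp: int
    fp: int
    fn: int
    tn: int
    threshold: float = 0.5
    probabilities: dict[str, float] = field(default_factory=dict)
    labels: dict[str, int] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps({k: getattr(self, k) for k in
                           ("roc_auc", "mcc", "f1", "precision", "balanced_accuracy",
                            "tp", "fp", "fn", "tn", "threshold", "probabilities", "labels")})

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())


def metrics_from_confusion(tp: int, fp: int, fn: int, tn: int) -> dict[str, float]:
    """Precision, F1, balanced accuracy and MCC from confusion counts.

    Zero-denominator convention: precision and F1 are 0 when no positives are
    predicted; MCC is 0 when any marginal is empty.
    """
    precision = tp / (tp + fp) if (tp + fp) > 0 else 0.0
    f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) > 0 else 0.0
    sens = tp / (tp + fn) if (tp + fn) > 0 else 0.0
    spec = tn / (tn + fp) if (tn + fp) > 0 else 0.0
    balanced = 0.5 * (sens + spec)
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = ((tp * tn - fp * fn) / np.sqrt(denom)) if denom > 0 else 0.0
    return {"precision": precision, "f1": f1, "balanced_accuracy": balanced,
            "mcc": float(mcc)}


def evaluate(probabilities: Sequence[float], labels: Sequence[int],
             threshold: float = 0.5, ids: Sequence[str] | None = None) -> EvalReport:
    """Full evaluation report at the given decision threshold (default 0.5)."""
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels, dtype=int)
    if len(p) == 0:
        raise ValueError("empty input")
    if p.min() < 0 or p.max() > 1:
        raise ValueError("probabilities must lie in [0, 1]")
    pred = (p > threshold).astype(int)
    tp = int(((pred == 1) & (y == 1)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    m = metrics_from_confusion(tp, fp, fn, tn)
    roc = float(roc_auc_score(y, p)) if len(set(y.tolist())) == 2 else float("nan")
    ids = list(ids) if ids is not None else [str(i) for i in range(len(p))]
    return EvalReport(roc_auc=roc, mcc=m["mcc"], f1=m["f1"], precision=m["precision"],
                      balanced_accuracy=m["balanced_accuracy"], tp=tp, fp=fp, fn=fn,
                      tn=tn, threshold=threshold,
                      probabilities=dict(zip(ids, p.tolist())),
                      labels=dict(zip(ids, y.tolist())))


# ---------------------------------------------------------------------------
# featurization pipeline (fit on train rows only)

@dataclass
class FeaturePipeline:
    """Train-fitted featurizer: encoder embeddings, scaled descriptors, targets.

    The scaler and target vocabulary are fitted on training rows only; query
    rows are clipped into the training descriptor ranges and annotations
    outside the vocabulary are ignored.
    """

    families: tuple[str, ...]
    encoder: dmpnn.MPNNModel | None
    scaler: ScalerState | None
    vocabulary: list[str]
    ecfp_radius: int = 2
    nbits: int = 2048

    @classmethod
    def fit(cls, train_records: Sequence[CompoundRecord], families: Sequence[str],
            encoder: dmpnn.MPNNModel | None = None, ecfp_radius: int = 2,
            nbits: int = 2048) -> "FeaturePipeline":
        families = tuple(families)
        scaler = None
        if "DESCRIPTOR" in families:
            desc = descriptor_matrix(train_records)
            scaler = ScalerState.fit(desc)
        vocab = build_target_vocabulary(train_records) if "TARGET" in families else []
        if "GNN" in families and encoder is None:
            raise ValueError("GNN family requested but no trained encoder supplied")
        return cls(families, encoder, scaler, vocab, ecfp_radius, nbits)

    def transform(self, records: Sequence[CompoundRecord]) -> FeatureMatrix:
        parts = []
        smiles = [r.smiles_std for r in records]
        ids = [r.id for r in records]
        if "GNN" in self.families:
            parts.append(dmpnn.extract_embeddings(self.encoder, smiles, ids))
        if "DESCRIPTOR" in self.families:
            parts.append(self.scaler.transform(descriptor_matrix(records)))
        if "TARGET" in self.families:
            parts.append(encode_targets(records, self.vocabulary))
        if "FINGERPRINT" in self.families:
            parts.append(fingerprint_matrix(records, self.ecfp_radius, self.nbits))
        return assemble(parts)


def train_fold_encoder(records: Sequence[CompoundRecord], config: dmpnn.MPNNConfig,
                       seed: int) -> dmpnn.MPNNModel:
    """Train a fold-local encoder on a scaffold-balanced 80/10/10 split.

    The 10% scaffold-test part is held out entirely (the encoder is used for
    embeddings, not prediction, so it is never evaluated on it).
    """
    smiles = [r.smiles_std for r in records]
    ids = [r.id for r in records]
    tr, va, _te = murcko_scaffold_split(smiles, ids, seed=seed)
    by_id = {r.id: r for r in records}
    tr_rec = [by_id[i] for i in tr]
    va_rec = [by_id[i] for i in va]
    model, _ = dmpnn.train([r.smiles_std for r in tr_rec], [r.label for r in tr_rec],
                           replace(config, seed=seed),
                           val_smiles=[r.smiles_std for r in va_rec],
                           val_labels=[r.label for r in va_rec])
    return model


# ---------------------------------------------------------------------------
# booster

def _make_estimator(config: BoosterConfig, scale_pos_weight: float | None = None):
    if config.kind == "rf":
        return RandomForestClassifier(
            n_estimators=config.n_trees, max_depth=config.max_depth or None,
            max_features="sqrt", random_state=config.seed, n_jobs=1)
    est = XGBClassifier(
        n_estimators=config.n_trees, learning_rate=config.learning_rate,
        max_depth=config.max_depth, colsample_bytree=config.colsample,
        objective="binary:logistic", eval_metric="auc", random_state=config.seed,
        scale_pos_weight=scale_pos_weight if scale_pos_weight is not None else 1.0,
        n_jobs=1, verbosity=0, base_score=0.5)
    # xgboost's sklearn wrapper still reads the _estimator_type attribute that
    # recent scikit-learn mixins no longer define; save_model needs it
    est._estimator_type = "classifier"
    return est


@dataclass
class FittedModel:
    estimator: object
    feature_names: list[str]
    config: BoosterConfig

    def predict_proba(self, matrix: FeatureMatrix) -> np.ndarray:
        if matrix.names != self.feature_names:
            raise ValueError("feature columns do not match the fitted model")
        return self.estimator.predict_proba(matrix.values)[:, 1]


def fit(matrix: FeatureMatrix, labels: Sequence[int], config: BoosterConfig,
        scale_pos_weight: float | None = None) -> FittedModel:
    """Fit the tree ensemble on already-selected feature columns."""
    y = np.asarray(labels)
    if len(set(y.tolist())) < 2:
        raise ValueError("labels are constant; nothing to fit")
    est = _make_estimator(config, scale_pos_weight)
    est.fit(matrix.values, y)
    return FittedModel(est, list(matrix.names), config)


def tune_booster(matrix: FeatureMatrix, labels: Sequence[int], groups: Sequence[int],
                 n_iter: int = 15, inner_k: int = 3, seed: int = 0,
                 scale_pos_weight: float | None = None) -> BoosterConfig:
    """Seeded random search scored by mean average precision over inner grouped folds."""
    rng = np.random.default_rng(seed)
    y = np.asarray(labels)
    ids = [str(i) for i in range(len(y))]
    folds = stratified_group_kfold(ids, y, groups, k=inner_k, seed=seed)
    best_cfg, best_score = None, -np.inf
    for it in range(n_iter):
        cfg = sample_booster_config(rng)
        cfg = replace(cfg, seed=seed)
        scores = []
        for tr_ids, va_ids in folds:
            tr = [int(i) for i in tr_ids]
            va = [int(i) for i in va_ids]
            if len(set(y[tr].tolist())) < 2 or len(set(y[va].tolist())) < 2:
                warnings.warn("single-class inner fold skipped during tuning")
                continue
            est = _make_estimator(cfg, scale_pos_weight)
            est.fit(matrix.values[tr], y[tr])
            p = est.predict_proba(matrix.values[va])[:, 1]
            scores.append(average_precision_score(y[va], p))
        score = float(np.mean(scores)) if scores else -np.inf
        if best_cfg is None or score > best_score:
            best_cfg, best_score = cfg, score
    return best_cfg


def median_config(configs: Sequence[BoosterConfig]) -> BoosterConfig:
    """Componentwise median (lower median for integers, mode for categoricals)."""
    def lower_median(vals):
        s = sorted(vals)
        return s[(len(s) - 1) // 2]

    kinds = [c.kind for c in configs]
    return BoosterConfig(
        n_trees=int(lower_median([c.n_trees for c in configs])),
        learning_rate=float(np.median([c.learning_rate for c in configs])),
        max_depth=int(lower_median([c.max_depth for c in configs])),
        colsample=float(np.median([c.colsample for c in configs])),
        seed=configs[0].seed,
        kind=min(set(kinds), key=lambda k: (-kinds.count(k), k)),
    )


# ---------------------------------------------------------------------------
# bundle

@dataclass
class ModelBundle:
    """Everything needed to score new compounds."""

    pipeline: FeaturePipeline
    mask: SelectionMask
    model: FittedModel
    options: PipelineOptions

    def predict_proba(self, records: Sequence[CompoundRecord]) -> np.ndarray:
        feats = self.pipeline.transform(records)
        return self.model.predict_proba(self.mask.apply(feats))

    def save(self, directory: str | Path) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        if self.pipeline.encoder is not None:
            dmpnn.save_model(self.pipeline.encoder, d)
        meta = {
            "families": list(self.pipeline.families),
            "vocabulary": self.pipeline.vocabulary,
            "ecfp_radius": self.pipeline.ecfp_radius,
            "nbits": self.pipeline.nbits,
            "scaler": self.pipeline.scaler.to_dict() if self.pipeline.scaler else None,
            "booster_config": vars(self.model.config),
            "feature_names": self.model.feature_names,
            "options": {k: (vars(v) if k == "mpnn" else v)
                        for k, v in vars(self.options).items()},
        }
        (d / "bundle.json").write_text(json.dumps(meta))
        (d / "mask.json").write_text(self.mask.to_json())
        self.model.estimator.save_model(d / "booster.json")

    @classmethod
    def load(cls, directory: str | Path) -> "ModelBundle":
        d = Path(directory)
        meta = json.loads((d / "bundle.json").read_text())
        encoder = dmpnn.load_model(d) if (d / "encoder.npz").exists() else None
        scaler = ScalerState.from_dict(meta["scaler"]) if meta["scaler"] else None
        pipe = FeaturePipeline(tuple(meta["families"]), encoder, scaler,
                               list(meta["vocabulary"]), meta["ecfp_radius"], meta["nbits"])
        mask = SelectionMask.from_json((d / "mask.json").read_text())
        cfg = BoosterConfig(**meta["booster_config"])
        est = _make_estimator(cfg)
        est.load_model(d / "booster.json")
        opts_d = dict(meta["options"])
        opts_d["mpnn"] = dmpnn.MPNNConfig(**opts_d["mpnn"])
        opts_d["families"] = tuple(opts_d["families"])
        options = PipelineOptions(**opts_d)
        fitted = FittedModel(est, list(meta["feature_names"]), cfg)
        return cls(pipeline=pipe, mask=mask, model=fitted, options=options)


# ---------------------------------------------------------------------------
# nested CV / final fit / shuffle control

def _cluster_groups(ids: Sequence[str], cluster_of_id: dict[str, int]) -> list[int]:
    return [cluster_of_id[i] for i in ids]


def nested_cv(records: Sequence[CompoundRecord], plan: SplitPlan,
              cluster_of_id: dict[str, int], options: PipelineOptions,
              ) -> tuple[list[EvalReport], list[BoosterConfig]]:
    """Outer-fold training and evaluation with fold-local encoders and selection.

    Per outer fold: train a fold-specific encoder (when the GNN family is
    requested) on the fold's training part only, featurize, run staged feature
    selection, tune the booster on inner cluster-grouped folds, fit and
    evaluate on the outer validation part.  Outer-validation rows never enter
    any fit.
    """
    by_id = {r.id: r for r in records}
    reports, configs = [], []
    for f, (tr_ids, va_ids) in enumerate(plan.outer_folds):
        tr = [by_id[i] for i in tr_ids]
        va = [by_id[i] for i in va_ids]
        y_tr = np.array([r.label for r in tr])
        y_va = np.array([r.label for r in va])
        seed = options.seed + 101 * f
        encoder = None
        if "GNN" in options.families:
            encoder = train_fold_encoder(tr, options.mpnn, seed=seed)
        pipe = FeaturePipeline.fit(tr, options.families, encoder,
                                   options.ecfp_radius, options.nbits)
        X_tr = pipe.transform(tr)
        X_va = pipe.transform(va)
        budget = options.budget if options.budget is not None else default_budget(X_tr)
        mask = select_features(X_tr, y_tr, budget=budget, min_count=options.min_count,
                               threshold=options.corr_threshold, step=options.rfe_step,
                               seed=seed, fold_id=f"outer-{f}")
        cfg = tune_booster(mask.apply(X_tr), y_tr, _cluster_groups(tr_ids, cluster_of_id),
                           n_iter=options.n_iter, inner_k=options.inner_k, seed=seed,
                           scale_pos_weight=options.scale_pos_weight)
        fitted = fit(mask.apply(X_tr), y_tr, cfg, options.scale_pos_weight)
        probs = fitted.predict_proba(mask.apply(X_va))
        reports.append(evaluate(probs, y_va, options.threshold, ids=va_ids))
        configs.append(cfg)
    return reports, configs


def fit_final(records: Sequence[CompoundRecord], plan: SplitPlan,
              fold_configs: Sequence[BoosterConfig], options: PipelineOptions,
              labels_override: dict[str, int] | None = None,
              ) -> tuple[ModelBundle, EvalReport]:
    """Retrain on the full training set with median fold hyperparameters.

    The encoder is retrained, feature selection redone, and the booster refit;
    the held-out test set is touched exactly once, for the final evaluation.
    ``labels_override`` replaces training labels only (used by the shuffle
    control); test labels always come from the records themselves.
    """
    by_id = {r.id: r for r in records}
    train = [by_id[i] for i in plan.train_ids]
    test = [by_id[i] for i in plan.test_ids]
    if labels_override is not None:
        train = [replace(r, label=labels_override[r.id]) for r in train]
    y_tr = np.array([r.label for r in train])
    y_te = np.array([r.label for r in test])
    cfg = median_config(list(fold_configs))
    seed = options.seed
    encoder = None
    if "GNN" in options.families:
        encoder = train_fold_encoder(train, options.mpnn, seed=seed)
    pipe = FeaturePipeline.fit(train, options.families, encoder,
                               options.ecfp_radius, options.nbits)
    X_tr = pipe.transform(train)
    budget = options.budget if options.budget is not None else default_budget(X_tr)
    mask = select_features(X_tr, y_tr, budget=budget, min_count=options.min_count,
                           threshold=options.corr_threshold, step=options.rfe_step,
                           seed=seed, fold_id="final")
    fitted = fit(mask.apply(X_tr), y_tr, replace(cfg, seed=seed), options.scale_pos_weight)
    X_te = pipe.transform(test)
    probs = fitted.predict_proba(mask.apply(X_te))
    report = evaluate(probs, y_te, options.threshold, ids=plan.test_ids)
    bundle = ModelBundle(pipeline=pipe, mask=mask, model=fitted, options=options)
    return bundle, report


def shuffle_control(records: Sequence[CompoundRecord], plan: SplitPlan,
                    options: PipelineOptions, seed: int,
                    booster_config: BoosterConfig | None = None) -> EvalReport:
    """Rerun the whole pipeline with permuted training labels.

    Training labels are shuffled (seeded) before encoder training, feature
    selection and booster fitting; test labels are untouched.  Tuning is
    skipped in favour of a fixed booster configuration: under shuffled labels
    hyperparameter search has no signal to exploit, and a fixed configuration
    keeps the control focused on leakage rather than search noise.
    """
    rng = np.random.default_rng(seed)
    y_train = np.array([ {r.id: r for r in records}[i].label for i in plan.train_ids ])
    shuffled = rng.permutation(y_train)
    override = dict(zip(plan.train_ids, (int(v) for v in shuffled)))
    cfg = booster_config or paper_booster_config()
    opts = replace(options, seed=seed)
    _bundle, report = fit_final(records, plan, [cfg], opts, labels_override=override)
    return report
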