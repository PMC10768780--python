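"""Training, cross-validation, tuning and evaluation of the hybrid model.

The optimizer is adaptive-moment SGD (Adam) on the binary cross-entropy
loss, with early stopping on a seeded stratified validation split.  Model
selection in hyperparameter tuning uses mean validation MCC, with ties
broken by AUC and then by parameter count.
"""

from __future__ import annotations

import copy
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.model_selection import KFold, StratifiedKFold

from .config import RunConfig
from .metrics import MetricSet, evaluate_scores
from .network import HybridModel, bce_loss_t
from .pipeline import FeatureExtractor, NmPredictor
from .samples import SiteDataset

logger = logging.getLogger("nmsite")


# ---------------------------------------------------------------------------
# folds


@dataclass(frozen=True)
class FoldPlan:
    n_folds: int
    folds: tuple[tuple[tuple[int, ...], tuple[int, ...]], ...]  # (train, val)
    stratified: bool
    seed: int


def make_folds(dataset: SiteDataset, n_folds: int, stratified: bool = True,
               seed: int = 0) -> FoldPlan:
    """Seeded, shuffled k-fold plan; stratified by label by default."""
    n = len(dataset)
    if not 2 <= n_folds <= n:
        raise ValueError(f"n_folds={n_folds} must be in [2, {n}]")
    y = np.array(dataset.labels)
    if stratified:
        if len(np.unique(y)) < 2:
            raise ValueError("stratified folds require both classes present")
        splitter = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    else:
        splitter = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    folds = tuple(
        (tuple(int(i) for i in tr), tuple(int(i) for i in va))
        for tr, va in splitter.split(np.zeros(n), y)
    )
    return FoldPlan(n_folds=n_folds, folds=folds, stratified=stratified, seed=seed)


# ---------------------------------------------------------------------------
# optimizer


class Adam:
    def __init__(self, params: dict[str, np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for k, g in grads.items():
            p = self.params[k]
            m = self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            v = self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


# ---------------------------------------------------------------------------
# training


@dataclass
class TrainReport:
    epoch_train_loss: list[float] = field(default_factory=list)
    epoch_val_loss: list[float] = field(default_factory=list)
    best_epoch: int = -1
    best_val_loss: float = float("inf")
    seed: int = 0
    wall_time_s: float = 0.0
    config_echo: dict = field(default_factory=dict)
    val_metrics: MetricSet | None = None


def _stratified_holdout(y: np.ndarray, fraction: float, seed: int):
    rng = np.random.default_rng(seed)
    val_idx: list[int] = []
    for cls in (0, 1):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        n_val = max(1, int(round(fraction * idx.size)))
        val_idx.extend(idx[:n_val])
    val = np.sort(np.array(val_idx))
    train = np.setdiff1d(np.arange(y.size), val)
    return train, val


def train_network(
    model: HybridModel,
    descriptors: dict[str, np.ndarray],
    embeddings: dict[str, np.ndarray],
    labels: np.ndarray,
    config: RunConfig,
    seed: int,
) -> TrainReport:
    """Fit a HybridModel in place on featurized data.

    Adam on mean BCE; early stopping on a seeded stratified holdout
    (restores the best-epoch weights).  Single-threaded and reproducible for
    a fixed seed.
    """
    tc = config.training
    y = np.asarray(labels, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("training requires both classes")
    tr_idx, va_idx = _stratified_holdout(y, tc.validation_fraction, seed)
    d_tr = {k: v[tr_idx] for k, v in descriptors.items()}
    e_tr = {k: v[tr_idx] for k, v in embeddings.items()}
    d_va = {k: v[va_idx] for k, v in descriptors.items()}
    e_va = {k: v[va_idx] for k, v in embeddings.items()}
    y_tr, y_va = y[tr_idx], y[va_idx]

    flat = model.params.flat()
    opt = Adam(flat, lr=tc.learning_rate)
    rng = np.random.default_rng(seed + 1)
    report = TrainReport(seed=seed, config_echo=config.to_dict())
    best_params = None
    bad_epochs = 0
    t0 = time.time()
    n = y_tr.size
    for epoch in range(tc.max_epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, tc.batch_size):
            idx = order[start: start + tc.batch_size]
            d_b = {k: v[idx] for k, v in d_tr.items()}
            e_b = {k: v[idx] for k, v in e_tr.items()}
            prob, leaves, _ = model.forward_t(d_b, e_b, train=True, rng=rng)
            loss = bce_loss_t(y_tr[idx], prob)
            loss.backward()
            grads = {k: t.grad for k, t in leaves.items() if t.grad is not None}
            opt.step(grads)
            epoch_loss += float(loss.data) * idx.size
        report.epoch_train_loss.append(epoch_loss / n)

        val_probs = model.predict_proba(d_va, e_va)
        val_loss = float(
            -np.mean(
                y_va * np.log(np.clip(val_probs, 1e-7, 1 - 1e-7))
                + (1 - y_va) * np.log(np.clip(1 - val_probs, 1e-7, 1 - 1e-7))
            )
        )
        report.epoch_val_loss.append(val_loss)
        if val_loss < report.best_val_loss:
            report.best_val_loss = val_loss
            report.best_epoch = epoch
            best_params = {k: v.copy() for k, v in flat.items()}
            bad_epochs = 0
        else:
            bad_epochs += 1
            if bad_epochs > tc.patience:
                break
    if best_params is not None:
        for k, v in flat.items():
            v[...] = best_params[k]
    val_probs = model.predict_proba(d_va, e_va)
    report.val_metrics = evaluate_scores(y_va, val_probs, tc.threshold)
    report.wall_time_s = time.time() - t0
    return report


def train_model(
    train_set: SiteDataset,
    config: RunConfig | None = None,
    seed: int = 0,
    extractor: FeatureExtractor | None = None,
    features: tuple[dict, dict] | None = None,
) -> tuple[NmPredictor, TrainReport]:
    """End-to-end: fit embedding channels, featurize, train the network.

    ``extractor``/``features`` may be supplied to reuse featurization across
    folds or configurations.
    """
    cfg = (config or RunConfig()).validate()
    if len(train_set) == 0:
        raise ValueError("empty training set")
    if extractor is None:
        extractor = FeatureExtractor(config=cfg).fit(train_set, seed)
    if features is None:
        features = extractor.transform(train_set)
    descriptors, embeddings = features
    L = len(train_set[0].seq)
    d_dims, e_dims = extractor.dims(L=L)
    model = HybridModel(d_dims, e_dims, config=cfg.network, seed=seed,
                        site_type=train_set.site_type)
    report = train_network(
        model, descriptors, embeddings, np.array(train_set.labels), cfg, seed
    )
    predictor = NmPredictor(extractor=extractor, model=model, config=cfg, seed=seed)
    return predictor, report


# ---------------------------------------------------------------------------
# evaluation


def evaluate(predictor: NmPredictor, dataset: SiteDataset,
             threshold: float | None = None) -> MetricSet:
    """Forward pass + confusion metrics + AUC on a labelled dataset."""
    if len(dataset) == 0:
        raise ValueError("empty evaluation dataset")
    if predictor.site_type not in ("N", dataset.site_type):
        logger.warning(
            "cross-evaluation: %s model on %s dataset",
            predictor.site_type, dataset.site_type,
        )
    thr = threshold if threshold is not None else predictor.config.training.threshold
    probs = predictor.predict_proba(dataset)
    return evaluate_scores(np.array(dataset.labels), probs, thr)


def cross_evaluate(
    models: dict[str, NmPredictor],
    datasets: dict[str, SiteDataset],
    out_csv: str | Path | None = None,
) -> dict[tuple[str, str], MetricSet]:
    """Every model against every dataset (transferability matrix)."""
    if len(models) < 2 or len(datasets) < 2:
        raise ValueError("cross-evaluation requires >= 2 models and datasets")
    results: dict[tuple[str, str], MetricSet] = {}
    for m_type, predictor in models.items():
        for d_type, dataset in datasets.items():
            results[(m_type, d_type)] = evaluate(predictor, dataset)
    if out_csv is not None:
        with open(out_csv, "w") as fh:
            fh.write("model,dataset,ACC,MCC,Sn,Sp,PRE,F1,AUC\n")
            for (m_type, d_type), ms in results.items():
                fh.write(
                    f"{m_type},{d_type},{ms.ACC:.6f},{ms.MCC:.6f},{ms.Sn:.6f},"
                    f"{ms.Sp:.6f},{ms.PRE:.6f},{ms.F1:.6f},{ms.AUC:.6f}\n"
                )
    return results


# ---------------------------------------------------------------------------
# hyperparameter tuning


@dataclass
class TuneResult:
    best_config: RunConfig
    table: list[dict]  # one row per (config, fold)


def _param_count(predictor: NmPredictor) -> int:
    return sum(v.size for v in predictor.model.params.flat().values())


def tune_hyperparameters(
    dataset: SiteDataset,
    grid: list[RunConfig],
    n_folds: int = 5,
    seed: int = 0,
) -> TuneResult:
    """Exhaustive grid search by k-fold cross-validation.

    Selection: highest mean validation MCC; ties broken by mean AUC, then by
    smaller parameter count.
    """
    if not grid:
        raise ValueError("empty hyperparameter grid")
    plan = make_folds(dataset, n_folds=n_folds, stratified=True, seed=seed)
    table: list[dict] = []
    summaries: list[tuple[float, float, int, int]] = []
    for ci, cfg in enumerate(grid):
        mccs, aucs = [], []
        params = 0
        for fi, (tr, va) in enumerate(plan.folds):
            train_split = dataset.subset(tr, name=f"fold{fi}-train")
            val_split = dataset.subset(va, name=f"fold{fi}-val")
            predictor, _ = train_model(train_split, cfg, seed=seed + fi)
            ms = evaluate(predictor, val_split)
            params = _param_count(predictor)
            table.append({
                "config_index": ci, "fold": fi,
                "MCC": ms.MCC, "AUC": ms.AUC, "ACC": ms.ACC,
            })
            mccs.append(ms.MCC)
            aucs.append(ms.AUC)
        summaries.append((float(np.mean(mccs)), float(np.mean(aucs)), -params, ci))
    best = max(summaries)
    return TuneResult(best_config=grid[best[3]], table=table)
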