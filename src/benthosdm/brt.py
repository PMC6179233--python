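"""Boosted regression trees for presence/absence occurrence data.

The model is a stagewise additive ensemble of small regression trees fit
by gradient boosting on Bernoulli (binomial) deviance, the workhorse of
species distribution modelling.  Three hyperparameters matter:

* ``lr`` (learning rate): shrinkage applied to every tree's contribution;
* ``tc`` (tree complexity): the number of splits per tree, which bounds
  the order of predictor interactions a tree can represent;
* ``bf`` (bag fraction): the fraction of training rows randomly
  subsampled, without replacement, before fitting each tree.

Tree fitting is delegated to scikit-learn's ``GradientBoostingClassifier``
(``tc`` splits are enforced with ``max_leaf_nodes = tc + 1``); the
cross-validated selection of the ensemble size — grow up to ``max_trees``
in ``step_size`` increments, monitor the mean held-out deviance across
stratified k folds, and keep the tree count that minimises it — is
implemented here.  The hyperparameter grid is tuned by mean cross-validated
percent deviance explained (PDE), and the winning combination is refit on
all training rows.

A fitted model is exportable to JSON as explicit tree rules (split
feature, threshold, child indices, scaled leaf increments) plus the
log-odds intercept; prediction from the exported rules reproduces the
backend's probabilities exactly.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from sklearn.ensemble import GradientBoostingClassifier
from sklearn.model_selection import StratifiedKFold

from .grids import SITE_BASE_COLUMNS, GridSurface
from .predictors import PredictorStack

logger = logging.getLogger(__name__)

__all__ = [
    "BRTParams",
    "BRTModel",
    "TuningResult",
    "bernoulli_deviance",
    "percent_deviance_explained",
    "fit_brt_step",
    "tune_grid",
    "predict_surface",
    "DEFAULT_LR_VALUES",
    "DEFAULT_TC_VALUES",
    "DEFAULT_BF_VALUES",
]

EPS = 1e-9

# default tuning grid: 3 learning rates x 6 tree complexities x 2 bag
# fractions = 36 combinations
DEFAULT_LR_VALUES = (0.01, 0.001, 0.005)
DEFAULT_TC_VALUES = (2, 3, 4, 5, 10, 20)
DEFAULT_BF_VALUES = (0.5, 0.75)


@dataclass(frozen=True)
class BRTParams:
    """Hyperparameters of one boosted-tree fit."""

    lr: float = 0.005
    tc: int = 3
    bf: float = 0.75
    step_size: int = 50
    max_trees: int = 10_000
    fold_count: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lr <= 0:
            raise ValueError("lr must be > 0")
        if int(self.tc) != self.tc or self.tc < 1:
            raise ValueError("tc must be an integer >= 1")
        if not 0 < self.bf <= 1:
            raise ValueError("bf must lie in (0, 1]")
        if self.step_size < 1:
            raise ValueError("step_size must be >= 1")
        if self.max_trees < self.step_size:
            raise ValueError("max_trees must be >= step_size")
        if self.fold_count < 2:
            raise ValueError("fold_count must be >= 2")


# ---------------------------------------------------------------------------
# Deviance metrics
# ---------------------------------------------------------------------------

def _clip(p: np.ndarray) -> np.ndarray:
    return np.clip(p, EPS, 1 - EPS)


def bernoulli_deviance(obs, pred) -> float:
    """Total Bernoulli deviance  -2 sum[y ln p + (1-y) ln(1-p)]."""
    obs = np.asarray(obs, dtype=float)
    pred = _clip(np.asarray(pred, dtype=float))
    if obs.size == 0:
        raise ValueError("empty observation vector")
    if obs.shape != pred.shape:
        raise ValueError("obs and pred must have equal length")
    return float(-2.0 * np.sum(obs * np.log(pred) + (1 - obs) * np.log(1 - pred)))


def percent_deviance_explained(obs, pred) -> float:
    """PDE = 1 - residual deviance / null deviance, as a fraction.

    The null model predicts the observed mean everywhere.  PDE can be
    negative for a model worse than the null; that is allowed and logged.
    """
    obs = np.asarray(obs, dtype=float)
    if np.all(obs == obs.flat[0]):
        raise ValueError("PDE undefined: all observations identical (null deviance 0)")
    null_pred = np.full_like(obs, obs.mean())
    null_dev = bernoulli_deviance(obs, null_pred)
    pde = 1.0 - bernoulli_deviance(obs, pred) / null_dev
    if pde < 0:
        logger.info("model is worse than the null (PDE = %.4f)", pde)
    return float(pde)


# ---------------------------------------------------------------------------
# Model container
# ---------------------------------------------------------------------------

@dataclass
class BRTModel:
    """A fitted ensemble as explicit tree rules.

    ``trees`` holds exactly ``n_trees_selected`` trees; each tree is a dict
    of parallel arrays (``feature``, ``threshold``, ``children_left``,
    ``children_right``, ``value``) in scikit-learn node order, with
    ``value`` already scaled by the learning rate so that

        raw(x) = intercept + sum over trees of value[leaf(x)]

    and probability = logistic(raw).
    """

    intercept: float
    trees: list[dict]
    params: BRTParams
    n_trees_selected: int
    predictor_names: list[str]
    train_summary: dict = field(default_factory=dict)
    _backend: GradientBoostingClassifier | None = field(default=None, repr=False, compare=False)

    # -- construction -----------------------------------------------------
    @classmethod
    def from_sklearn(
        cls,
        est: GradientBoostingClassifier,
        params: BRTParams,
        predictor_names: list[str],
        train_summary: dict | None = None,
        n_trees: int | None = None,
    ) -> "BRTModel":
        n_trees = est.n_estimators_ if n_trees is None else n_trees
        trees = []
        for i in range(n_trees):
            t = est.estimators_[i, 0].tree_
            trees.append(
                {
                    "feature": t.feature.copy(),
                    "threshold": t.threshold.copy(),
                    "children_left": t.children_left.copy(),
                    "children_right": t.children_right.copy(),
                    "value": (est.learning_rate * t.value[:, 0, 0]).copy(),
                }
            )
        x0 = np.zeros((1, len(predictor_names)))
        intercept = float(est._raw_predict_init(x0)[0, 0])
        return cls(
            intercept=intercept,
            trees=trees,
            params=params,
            n_trees_selected=n_trees,
            predictor_names=list(predictor_names),
            train_summary=train_summary or {},
            _backend=est,
        )

    @classmethod
    def constant(cls, probability: float, predictor_names: list[str] | None = None) -> "BRTModel":
        """A zero-tree model predicting one probability everywhere."""
        return cls(
            intercept=float(logit(probability)),
            trees=[],
            params=BRTParams(),
            n_trees_selected=0,
            predictor_names=list(predictor_names or []),
        )

    # -- prediction -------------------------------------------------------
    def predict_raw(self, X: np.ndarray) -> np.ndarray:
        """Log-odds scores by explicit traversal of the stored tree rules."""
        X = np.asarray(X, dtype=float)
        raw = np.full(X.shape[0], self.intercept)
        for tree in self.trees:
            node = np.zeros(X.shape[0], dtype=np.int64)
            left, right = tree["children_left"], tree["children_right"]
            feat, thr = tree["feature"], tree["threshold"]
            while True:
                at_leaf = left[node] == -1
                if at_leaf.all():
                    break
                go = ~at_leaf
                n_go = node[go]
                goes_left = X[go, feat[n_go]] <= thr[n_go]
                node[go] = np.where(goes_left, left[n_go], right[n_go])
            raw += tree["value"][node]
        return raw

    def predict(self, X) -> np.ndarray:
        """Probability of presence for each row of X."""
        if isinstance(X, pd.DataFrame):
            X = X[self.predictor_names].to_numpy(dtype=float)
        return expit(self.predict_raw(X))

    # -- serialization ----------------------------------------------------
    def to_json(self) -> str:
        doc = {
            "intercept": self.intercept,
            "n_trees_selected": self.n_trees_selected,
            "predictor_names": self.predictor_names,
            "params": {
                "lr": self.params.lr,
                "tc": self.params.tc,
                "bf": self.params.bf,
                "step_size": self.params.step_size,
                "max_trees": self.params.max_trees,
                "fold_count": self.params.fold_count,
                "seed": self.params.seed,
            },
            "train_summary": self.train_summary,
            "trees": [
                {k: np.asarray(v).tolist() for k, v in tree.items()} for tree in self.trees
            ],
        }
        return json.dumps(doc)

    @classmethod
    def from_json(cls, text: str) -> "BRTModel":
        doc = json.loads(text)
        trees = [
            {
                "feature": np.asarray(t["feature"], dtype=np.int64),
                "threshold": np.asarray(t["threshold"], dtype=float),
                "children_left": np.asarray(t["children_left"], dtype=np.int64),
                "children_right": np.asarray(t["children_right"], dtype=np.int64),
                "value": np.asarray(t["value"], dtype=float),
            }
            for t in doc["trees"]
        ]
        return cls(
            intercept=doc["intercept"],
            trees=trees,
            params=BRTParams(**doc["params"]),
            n_trees_selected=doc["n_trees_selected"],
            predictor_names=doc["predictor_names"],
            train_summary=doc.get("train_summary", {}),
        )


# ---------------------------------------------------------------------------
# Fitting machinery
# ---------------------------------------------------------------------------

def _design_matrix(train: pd.DataFrame, predictor_names: list[str] | None):
    if predictor_names is None:
        predictor_names = [c for c in train.columns if c not in SITE_BASE_COLUMNS]
    X = train[predictor_names].to_numpy(dtype=float)
    y = train["presence"].to_numpy(dtype=int)
    return X, y, predictor_names


def _sub_seed(seed: int, k: int) -> int:
    return (seed * 1_000_003 + k) % (2**31)


def _make_backend(params: BRTParams, n_trees: int, seed: int) -> GradientBoostingClassifier:
    return GradientBoostingClassifier(
        loss="log_loss",
        learning_rate=params.lr,
        n_estimators=n_trees,
        subsample=params.bf,
        max_leaf_nodes=params.tc + 1,
        max_depth=None,
        random_state=seed,
    )


@dataclass
class CVSelection:
    """Cross-validated ensemble-size choice for one parameter combination."""

    n_trees: int
    cv_pde: float
    sd_cv_pde: float
    candidates: np.ndarray
    mean_holdout_deviance: np.ndarray


def _cv_select_trees(X: np.ndarray, y: np.ndarray, params: BRTParams) -> CVSelection:
    """Pick the ensemble size minimising mean held-out deviance across folds.

    Folds are stratified by class so every fold holds presences even at
    rare-species prevalence.
    """
    n = len(y)
    if len(np.unique(y)) < 2:
        raise ValueError("training data contain a single class")
    if n < 2 * params.fold_count:
        raise ValueError("too few rows for the requested fold count")

    steps = np.arange(params.step_size, params.max_trees + 1, params.step_size)
    skf = StratifiedKFold(
        n_splits=params.fold_count, shuffle=True, random_state=_sub_seed(params.seed, 1)
    )
    dev = np.empty((params.fold_count, len(steps)))
    null_dev_rate = np.empty(params.fold_count)  # per-site null deviance
    n_val = np.empty(params.fold_count)
    for f, (tr_idx, va_idx) in enumerate(skf.split(X, y)):
        Xtr, ytr = X[tr_idx], y[tr_idx]
        Xva, yva = X[va_idx], y[va_idx]
        est = _make_backend(params, int(steps[-1]), _sub_seed(params.seed, 100 + f))
        est.fit(Xtr, ytr)
        for i, raw in enumerate(est.staged_decision_function(Xva)):
            stage = i + 1
            if stage % params.step_size == 0:
                dev[f, stage // params.step_size - 1] = bernoulli_deviance(
                    yva, expit(raw.ravel())
                )
        null_pred = np.full(len(yva), ytr.mean())
        null_dev_rate[f] = bernoulli_deviance(yva, null_pred) / len(yva)
        n_val[f] = len(yva)
        dev[f] /= len(yva)  # per-site, so folds of unequal size average fairly

    mean_dev = dev.mean(axis=0)
    j = int(np.argmin(mean_dev))
    if j == len(steps) - 1:
        logger.warning(
            "held-out deviance still decreasing at max_trees=%d (lr=%g, tc=%d, bf=%g)",
            params.max_trees, params.lr, params.tc, params.bf,
        )
    mean_null = null_dev_rate.mean()
    cv_pde = 1.0 - mean_dev[j] / mean_null
    fold_pde = 1.0 - dev[:, j] / null_dev_rate
    return CVSelection(
        n_trees=int(steps[j]),
        cv_pde=float(cv_pde),
        sd_cv_pde=float(fold_pde.std(ddof=1)),
        candidates=steps,
        mean_holdout_deviance=mean_dev,
    )


def fit_brt_step(
    train: pd.DataFrame,
    params: BRTParams,
    predictor_names: list[str] | None = None,
) -> tuple[BRTModel, float]:
    """Fit a BRT with cross-validated selection of the number of trees.

    Mirrors the stagewise `grow, monitor held-out deviance, keep the
    minimiser` procedure: the ensemble size is chosen by k-fold CV and the
    final model is refit on all rows with that many trees.  Returns the
    model and the cross-validated PDE.
    """
    X, y, predictor_names = _design_matrix(train, predictor_names)
    sel = _cv_select_trees(X, y, params)
    est = _make_backend(params, sel.n_trees, _sub_seed(params.seed, 7))
    est.fit(X, y)
    model = BRTModel.from_sklearn(
        est,
        params,
        predictor_names,
        train_summary={"prevalence": float(y.mean()), "n": int(len(y)),
                       "cv_pde": sel.cv_pde},
    )
    return model, sel.cv_pde


@dataclass
class TuningResult:
    """Grid search over (lr, tc, bf) scored by mean cross-validated PDE."""

    rows: pd.DataFrame
    best: tuple[float, int, float]

    @property
    def best_params(self) -> BRTParams:
        lr, tc, bf = self.best
        return BRTParams(lr=lr, tc=int(tc), bf=bf)


def tune_grid(
    train: pd.DataFrame,
    lr_values=DEFAULT_LR_VALUES,
    tc_values=DEFAULT_TC_VALUES,
    bf_values=DEFAULT_BF_VALUES,
    fold_count: int = 10,
    step_size: int = 50,
    max_trees: int = 10_000,
    seed: int = 0,
    predictor_names: list[str] | None = None,
) -> TuningResult:
    """Evaluate every (lr, tc, bf) combination by k-fold CV.

    All fold models are discarded; only the score table and the winning
    combination survive.  Ties break to the highest mean CV PDE, then the
    fewest selected trees, then grid order.
    """
    if not (len(tuple(lr_values)) and len(tuple(tc_values)) and len(tuple(bf_values))):
        raise ValueError("tuning value lists must be non-empty")
    X, y, predictor_names = _design_matrix(train, predictor_names)
    records = []
    for lr, tc, bf in itertools.product(lr_values, tc_values, bf_values):
        params = BRTParams(
            lr=lr, tc=tc, bf=bf, step_size=step_size, max_trees=max_trees,
            fold_count=fold_count, seed=seed,
        )
        try:
            sel = _cv_select_trees(X, y, params)
            records.append(
                dict(lr=lr, tc=tc, bf=bf, mean_cv_pde=sel.cv_pde,
                     sd_cv_pde=sel.sd_cv_pde, n_trees=sel.n_trees, failed=False)
            )
        except Exception as exc:  # noqa: BLE001 - failures are recorded, not raised
            logger.warning("tuning combination (lr=%g, tc=%d, bf=%g) failed: %s", lr, tc, bf, exc)
            records.append(
                dict(lr=lr, tc=tc, bf=bf, mean_cv_pde=np.nan,
                     sd_cv_pde=np.nan, n_trees=0, failed=True)
            )
    rows = pd.DataFrame.from_records(records)
    ok = rows[~rows.failed]
    if ok.empty:
        raise RuntimeError("every tuning combination failed to fit")
    ranked = ok.reset_index().sort_values(
        by=["mean_cv_pde", "n_trees", "index"], ascending=[False, True, True],
        kind="mergesort",
    )
    top = ranked.iloc[0]
    return TuningResult(rows=rows, best=(float(top.lr), int(top.tc), float(top.bf)))


# ---------------------------------------------------------------------------
# Spatial prediction
# ---------------------------------------------------------------------------

def predict_surface(model: BRTModel, stack: PredictorStack) -> GridSurface:
    """Per-cell probability of presence; nodata propagates."""
    missing = [n for n in model.predictor_names if n not in stack.grids]
    if missing:
        raise KeyError(f"predictor stack is missing model predictors: {missing}")
    template = stack.grids[stack.names[0]]
    mask = np.ones(template.shape, dtype=bool)
    for n in model.predictor_names:
        mask &= stack.grids[n].mask
    X = np.column_stack([stack.grids[n].values[mask] for n in model.predictor_names])
    out = np.full(template.shape, np.nan)
    if model._backend is not None and len(model.trees) == model._backend.n_estimators_:
        raw = model._backend.decision_function(X)
        out[mask] = expit(raw)
    else:
        out[mask] = model.predict(X)
    return template.like(out)
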