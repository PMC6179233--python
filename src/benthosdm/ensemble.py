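"""Bootstrap prediction ensembles and per-cell uncertainty surfaces.

Model variability is quantified by refitting the tuned BRT on bootstrap
resamples (with replacement) of the training sites, predicting each model
across the grid, and reducing the prediction stack per cell to its mean,
sample standard deviation, and coefficient of variation CoV = sd / mean.

CoV translates directly into a probability range: a cell with mean
probability 0.5 and CoV 0.1 could vary by 0.5 x 0.1 = +-0.05.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .brt import BRTModel, BRTParams, _design_matrix, _make_backend
from .grids import GridSurface, require_aligned

logger = logging.getLogger(__name__)

__all__ = [
    "EnsembleSurfaces",
    "bootstrap_indices",
    "bootstrap_ensemble",
    "ensemble_surfaces",
    "implied_half_interval",
]


@dataclass
class EnsembleSurfaces:
    """Per-cell mean, sd and CoV over bootstrap predictions."""

    mean: GridSurface
    sd: GridSurface
    cov: GridSurface
    n_boot: int


def bootstrap_indices(n: int, seed: int, replicate: int) -> np.ndarray:
    """The seeded resample-index stream for one bootstrap replicate.

    Exposed so resamples can be audited or regenerated independently of
    the fitting loop.
    """
    rng = np.random.default_rng([seed, 0xB007, replicate])
    return rng.integers(0, n, size=n)


def bootstrap_ensemble(
    train: pd.DataFrame,
    params: BRTParams,
    n_boot: int = 100,
    seed: int = 0,
    n_trees: int | None = None,
    predictor_names: list[str] | None = None,
    max_redraws: int = 100,
) -> list[BRTModel]:
    """Fit ``n_boot`` models on size-n resamples drawn with replacement.

    Each model uses the tuned (lr, tc, bf) and the ensemble size selected
    by the cross-validated tree-count rule on the full training table:
    pass that count as ``n_trees`` (it defaults to ``params.max_trees``,
    which is rarely what you want).  Resamples that lack one of the two
    classes are redrawn and logged — at 4.5% prevalence and n = 292 this
    is a ~1e-6 event.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2 (CoV undefined otherwise)")
    X, y, predictor_names = _design_matrix(train, predictor_names)
    if len(np.unique(y)) < 2:
        raise ValueError("training data contain a single class")
    if n_trees is None:
        n_trees = params.max_trees
    n = len(y)
    models: list[BRTModel] = []
    for b in range(n_boot):
        idx = bootstrap_indices(n, seed, b)
        redraw = 0
        while len(np.unique(y[idx])) < 2:
            redraw += 1
            if redraw > max_redraws:
                raise RuntimeError(f"replicate {b}: could not draw a two-class resample")
            logger.warning("replicate %d: single-class resample, redrawing (%d)", b, redraw)
            idx = bootstrap_indices(n, seed, n_boot + b * max_redraws + redraw)
        est = _make_backend(params, n_trees, (seed * 7919 + b) % (2**31))
        est.fit(X[idx], y[idx])
        models.append(
            BRTModel.from_sklearn(
                est, params, predictor_names,
                train_summary={"prevalence": float(y[idx].mean()), "n": n, "replicate": b},
            )
        )
    return models


def ensemble_surfaces(predictions: list[GridSurface]) -> EnsembleSurfaces:
    """Reduce aligned probability surfaces to mean / sd / CoV per cell.

    The standard deviation uses the n-1 (sample) denominator.  Cells whose
    mean is zero get nodata CoV rather than infinity; cells nodata in any
    input stay nodata throughout.
    """
    if len(predictions) < 2:
        raise ValueError("need at least two surfaces")
    require_aligned(*predictions)
    stack = np.stack([p.values for p in predictions])
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = np.where(mean > 0, sd / np.where(mean > 0, mean, 1.0), np.nan)
    template = predictions[0]
    return EnsembleSurfaces(
        mean=template.like(mean),
        sd=template.like(sd),
        cov=template.like(cov),
        n_boot=len(predictions),
    )


def implied_half_interval(mean_probability: float, cov: float) -> float:
    """Half-width of the probability range a CoV implies: mean x CoV.

    E.g. mean 0.5 with CoV 0.1 -> +-0.05.
    """
    return mean_probability * cov
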