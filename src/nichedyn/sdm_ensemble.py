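"""Ensemble species distribution modelling with TSS-weighted averaging.

Presence-only occurrences are complemented with two sets of random
pseudo-absences, seven algorithm families are trained per pseudo-absence
set on a random 70/30 presence/absence split, and each fitted model is
scored on the held-out fold with the true skill statistic (TSS, at the
sensitivity+specificity-maximizing threshold) and the rank-based AUC.
Models passing TSS > 0.6 or AUC > 0.8 are averaged with weights
proportional to their TSS; the ensemble suitability surface is binarized
at the MSS threshold recomputed on the ensemble's own evaluation scores,
and the resulting range is measured in km² on the sphere.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import train_test_split
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import SplineTransformer, StandardScaler
from sklearn.tree import DecisionTreeClassifier

from .occurrence_prep import OccurrenceSet
from .predictors import SampleMatrix
from .raster import PredictorStack, RasterGrid, cell_areas_km2

logger = logging.getLogger(__name__)

TSS_GATE = 0.6
AUC_GATE = 0.8
PA_FLOOR = 1000


def pa_count(n_presence: int) -> int:
    """Pseudo-absences per set: match the presences above 1,000, else 1,000."""
    return n_presence if n_presence > PA_FLOOR else PA_FLOOR


@dataclass
class PseudoAbsenceSet:
    """Background cells sampled as surrogate absences."""

    points: pd.DataFrame  # columns lon, lat
    set_id: int
    seed: int

    def __len__(self) -> int:
        return len(self.points)


def sample_pseudo_absences(
    n_presence: int,
    stack: PredictorStack,
    seed: int,
    presence: OccurrenceSet | None = None,
    n_sets: int = 2,
) -> list[PseudoAbsenceSet]:
    """Draw pseudo-absence sets uniformly over valid background cells.

    Sampling is without replacement over cells valid in every stack layer,
    excluding any cell holding a presence record.
    """
    n_pa = pa_count(n_presence)
    valid = stack.combined_valid()
    if presence is not None:
        for lon, lat in presence.coords:
            idx = stack.transform.index_of(lon, lat, stack.shape)
            if idx is not None:
                valid[idx] = False
    cells = np.argwhere(valid)
    if len(cells) < n_pa:
        raise ValueError(
            f"background has only {len(cells)} available cells; need {n_pa} per set"
        )
    rng = np.random.default_rng(seed)
    out = []
    for set_id in range(1, n_sets + 1):
        pick = cells[rng.choice(len(cells), size=n_pa, replace=False)]
        coords = [stack.transform.cell_center(r, c) for r, c in pick]
        df = pd.DataFrame(coords, columns=["lon", "lat"])
        out.append(PseudoAbsenceSet(df, set_id=set_id, seed=seed))
    return out


@dataclass
class ModelEvaluation:
    """Held-out discrimination metrics for one fitted model."""

    algorithm: str
    tss: float
    auc: float
    mss_threshold: float
    sensitivity: float
    specificity: float
    retained: bool


def auc_score(scores: np.ndarray, labels: np.ndarray) -> float:
    """Rank-statistic AUC (Mann–Whitney with ties counted half)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined: both classes must be present")
    ranks = rankdata(scores)
    u = ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def mss_threshold(scores: np.ndarray, labels: np.ndarray) -> tuple[float, float, float]:
    """Sensitivity-specificity-sum-maximizing threshold.

    Scans all distinct scores as candidate cutoffs (presence predicted when
    score >= cutoff); ties in the maximum are broken by the smallest
    cutoff, which favors larger predicted ranges. Returns
    (threshold, sensitivity, specificity) at the optimum.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("threshold undefined: both classes must be present")
    best = (-np.inf, np.inf, np.nan, np.nan)  # (sum, threshold, sens, spec)
    for t in np.unique(scores):
        sens = float(np.mean(pos >= t))
        spec = float(np.mean(neg < t))
        total = sens + spec
        if total > best[0] + 1e-12 or (abs(total - best[0]) <= 1e-12 and t < best[1]):
            best = (total, t, sens, spec)
    return best[1], best[2], best[3]


def evaluate_scores(scores: np.ndarray, labels: np.ndarray, algorithm: str = "") -> ModelEvaluation:
    """TSS (at the MSS threshold) and AUC for one score/label set."""
    auc = auc_score(scores, labels)
    thr, sens, spec = mss_threshold(scores, labels)
    tss = sens + spec - 1.0
    return ModelEvaluation(
        algorithm=algorithm,
        tss=tss,
        auc=auc,
        mss_threshold=thr,
        sensitivity=sens,
        specificity=spec,
        retained=(tss > TSS_GATE) or (auc > AUC_GATE),
    )


def _make_registry(seed: int) -> dict[str, Callable[[], object]]:
    return {
        "ann": lambda: Pipeline([
            ("scale", StandardScaler()),
            ("clf", MLPClassifier(hidden_layer_sizes=(16,), max_iter=800, random_state=seed)),
        ]),
        "maxent_like": lambda: Pipeline([
            ("scale", StandardScaler()),
            ("clf", LogisticRegression(C=1.0, max_iter=2000)),
        ]),
        "rf": lambda: RandomForestClassifier(n_estimators=200, random_state=seed),
        "gam_like": lambda: Pipeline([
            ("scale", StandardScaler()),
            ("spline", SplineTransformer(n_knots=4, degree=3)),
            ("clf", LogisticRegression(C=1.0, max_iter=2000)),
        ]),
        "fda": lambda: LinearDiscriminantAnalysis(),
        "cta": lambda: DecisionTreeClassifier(min_samples_leaf=5, random_state=seed),
        "gbm": lambda: GradientBoostingClassifier(random_state=seed),
    }


DEFAULT_ALGORITHMS = list(_make_registry(0))


@dataclass
class SdmFit:
    """One fitted algorithm replicate: model, held-out evaluation, prediction map."""

    algorithm: str
    pa_set: int
    model: object
    evaluation: ModelEvaluation
    prediction: RasterGrid
    feature_names: list[str] = field(default_factory=list)

    def predict_points(self, x: pd.DataFrame) -> np.ndarray:
        proba = self.model.predict_proba(x[self.feature_names].to_numpy())
        col = list(self.model.classes_).index(1)
        return proba[:, col]


def _predict_raster(model, stack: PredictorStack, names: list[str]) -> RasterGrid:
    valid = stack.combined_valid()
    cells = stack.subset(names).to_matrix(valid_only=True)
    proba = model.predict_proba(cells)
    col = list(model.classes_).index(1)
    out = np.full(stack.shape, np.nan)
    out[valid] = proba[:, col]
    return RasterGrid(out, stack.transform, mask=~valid)


def fit_and_predict(
    presence: SampleMatrix,
    pseudo_absences: list[SampleMatrix],
    stack: PredictorStack,
    algorithms: list[str] | None = None,
    test_size: float = 0.3,
    seed: int = 0,
) -> list[SdmFit]:
    """Train every registered algorithm on each pseudo-absence replicate.

    Each (algorithm, PA set) pair is fitted on a random ``1 - test_size``
    fraction of the pooled presence/absence points and evaluated on the
    rest; the fitted model is projected over all valid stack cells. A model
    that fails to fit is logged and skipped, and the pipeline continues.
    """
    registry = _make_registry(seed)
    names = algorithms if algorithms is not None else list(registry)
    unknown = [a for a in names if a not in registry]
    if unknown:
        raise KeyError(f"unknown algorithms: {unknown}")
    feat = presence.columns
    fits: list[SdmFit] = []
    for pa_id, pa in enumerate(pseudo_absences, start=1):
        if list(pa.columns) != feat:
            raise ValueError("pseudo-absence matrix columns do not match presences")
        x = np.vstack([presence.to_numpy(), pa.to_numpy()])
        y = np.concatenate([np.ones(len(presence), dtype=int), np.zeros(len(pa), dtype=int)])
        x_tr, x_te, y_tr, y_te = train_test_split(
            x, y, test_size=test_size, random_state=seed, stratify=y
        )
        for algo in names:
            try:
                model = registry[algo]()
                model.fit(x_tr, y_tr)
                col = list(model.classes_).index(1)
                scores = model.predict_proba(x_te)[:, col]
                ev = evaluate_scores(scores, y_te, algorithm=algo)
            except Exception as exc:  # noqa: BLE001 - any failure marks the member unusable
                logger.warning("algorithm %s (PA set %d) failed: %s", algo, pa_id, exc)
                continue
            pred = _predict_raster(model, stack, feat)
            fits.append(SdmFit(algo, pa_id, model, ev, pred, feat))
    return fits


@dataclass
class EnsemblePrediction:
    """TSS-weighted ensemble suitability, its MSS cut and the range area."""

    suitability: RasterGrid
    weights: dict[str, float]
    mss_threshold: float
    binary_range: RasterGrid
    area_km2: float
    mean_tss: float
    mean_auc: float


def ensemble_predict(
    fits: list[SdmFit],
    eval_x: pd.DataFrame,
    eval_y: np.ndarray,
) -> EnsemblePrediction:
    """Weighted-average retained models and binarize at the ensemble MSS threshold.

    Weights are proportional to each retained member's TSS (negative TSS
    clipped to zero). The ensemble MSS threshold is recomputed on the
    ensemble's scores at the supplied evaluation points (typically all
    presences plus the pooled pseudo-absences).
    """
    retained = [f for f in fits if f.evaluation.retained]
    if not retained:
        raise ValueError("no model passed the TSS/AUC retention gates; ensemble is empty")
    raw_w = np.array([max(f.evaluation.tss, 0.0) for f in retained])
    if raw_w.sum() <= 0:
        raw_w = np.ones(len(retained))
    w = raw_w / raw_w.sum()

    first = retained[0].prediction
    suit = np.zeros(first.shape)
    for wi, f in zip(w, retained):
        suit += wi * np.where(f.prediction.mask, 0.0, f.prediction.values)
    suit_grid = RasterGrid(
        np.where(first.mask, np.nan, suit), first.transform, mask=first.mask.copy()
    )

    point_scores = np.zeros(len(eval_x))
    for wi, f in zip(w, retained):
        point_scores += wi * f.predict_points(eval_x)
    thr, _, _ = mss_threshold(point_scores, eval_y)

    binary = (~suit_grid.mask) & (suit_grid.values >= thr)
    binary_grid = RasterGrid(
        np.where(suit_grid.mask, np.nan, binary.astype(float)),
        suit_grid.transform,
        mask=suit_grid.mask.copy(),
    )
    return EnsemblePrediction(
        suitability=suit_grid,
        weights={f"{f.algorithm}/pa{f.pa_set}": float(wi) for wi, f in zip(w, retained)},
        mss_threshold=float(thr),
        binary_range=binary_grid,
        area_km2=range_area_km2(binary_grid),
        mean_tss=float(np.mean([f.evaluation.tss for f in retained])),
        mean_auc=float(np.mean([f.evaluation.auc for f in retained])),
    )


def range_area_km2(binary: RasterGrid) -> float:
    """Spherical area (km²) of the presence cells of a binary range map."""
    if not binary.crs.upper().startswith("EPSG:4326"):
        raise ValueError(f"unsupported CRS {binary.crs}; expected geographic degrees")
    areas = cell_areas_km2(binary.transform, binary.shape)
    presence = (~binary.mask) & (binary.values > 0.5)
    return float(areas[presence].sum())
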