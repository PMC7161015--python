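"""Bootstrap model/validation evaluation and multiclass scoring.

The validation scheme: the per-subject feature table is z-scored, then 1000
times a *model* subsample and a *validation* subsample are drawn — each
stratified per group, about half the group size, with replacement — the
classifier is trained on the model subsample, its predictions on the
validation subsample form a 3×3 confusion matrix with fixed class order
(AG, MG, CG), and per-class sensitivity, specificity, precision and accuracy
are computed from the per-class one-vs-rest counts

    TPᵢ = cᵢᵢ,  FPᵢ = Σₗ cₗᵢ − TPᵢ,  FNᵢ = Σₗ cᵢₗ − TPᵢ,
    TNᵢ = ΣΣ cₗₖ − TPᵢ − FPᵢ − FNᵢ.

Each metric's 1000 values are summarised as mean ± SD.

The package's front door is statsmodels-style:
``TMDClassificationModel.from_feature_table(df).fit()`` returns a
``TMDClassificationResults`` with the per-class metric table, diagnostics
and a ``summary()`` report.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .classify import PRESETS, ClassifierConfig, predict, train
from .features import FEATURE_NAMES
from .power import zscore_apply, zscore_fit
from .trajectory import CLASS_ORDER

__all__ = [
    "METRICS",
    "ScoreSet",
    "confusion_matrix",
    "score",
    "resample_split",
    "evaluate",
    "compare_classifiers",
    "EvaluationReport",
    "TMDClassificationModel",
    "TMDClassificationResults",
]

METRICS = ("sensitivity", "specificity", "precision", "accuracy")


def confusion_matrix(
    y_true: Sequence, y_pred: Sequence, classes: Sequence[str] = CLASS_ORDER
) -> np.ndarray:
    """3×3 count matrix, rows = true class, columns = predicted class."""
    classes = list(classes)
    index = {c: i for i, c in enumerate(classes)}
    C = np.zeros((len(classes), len(classes)), dtype=int)
    for t, p in zip(y_true, y_pred, strict=True):
        C[index[t], index[p]] += 1
    return C


@dataclass
class ScoreSet:
    """Per-class counts and metrics derived from one confusion matrix."""

    counts: pd.DataFrame  # index classes, columns tp/fp/fn/tn
    metrics: pd.DataFrame  # index classes, columns METRICS
    degenerate: list[tuple[str, str]]  # (class, metric) cells with 0 denominator

    @property
    def frame(self) -> pd.DataFrame:
        return self.counts.join(self.metrics)


def score(C: np.ndarray, classes: Sequence[str] = CLASS_ORDER) -> ScoreSet:
    """Per-class sensitivity, specificity, precision and accuracy.

    Degenerate cells (zero denominator, e.g. precision of a class never
    predicted) are reported as 0 and listed in ``degenerate``.
    """
    C = np.asarray(C)
    if C.ndim != 2 or C.shape[0] != C.shape[1] or (C < 0).any():
        raise ValueError("confusion matrix must be square with counts >= 0")
    total = C.sum()
    tp = np.diag(C).astype(float)
    fp = C.sum(axis=0) - tp
    fn = C.sum(axis=1) - tp
    tn = total - tp - fp - fn

    degenerate: list[tuple[str, str]] = []

    def ratio(num, den, metric):
        out = np.zeros_like(num, dtype=float)
        for i, c in enumerate(classes):
            if den[i] == 0:
                degenerate.append((c, metric))
            else:
                out[i] = num[i] / den[i]
        return out

    metrics = pd.DataFrame(
        {
            "sensitivity": ratio(tp, tp + fn, "sensitivity"),
            "specificity": ratio(tn, tn + fp, "specificity"),
            "precision": ratio(tp, tp + fp, "precision"),
            "accuracy": ratio(tp + tn, tp + tn + fp + fn, "accuracy"),
        },
        index=list(classes),
    )
    counts = pd.DataFrame(
        {"tp": tp, "fp": fp, "fn": fn, "tn": tn}, index=list(classes), dtype=int
    )
    return ScoreSet(counts=counts, metrics=metrics, degenerate=degenerate)


def resample_split(
    labels: Sequence[str],
    fraction: float,
    rng: np.random.Generator,
    disjoint: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Index pair (model, validation) for one bootstrap resample.

    Per group, ``ceil(n_g * fraction)`` row indices are drawn with
    replacement, independently for the model and validation subsamples.
    With ``disjoint=True`` the validation draw is restricted to rows the
    model subsample left unused (falling back to the whole group if it used
    every row).
    """
    labels = np.asarray(labels)
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    model_idx: list[np.ndarray] = []
    valid_idx: list[np.ndarray] = []
    for group in CLASS_ORDER:
        rows = np.flatnonzero(labels == group)
        if rows.size == 0:
            raise ValueError(f"empty group: {group}")
        size = int(np.ceil(rows.size * fraction))
        m = rng.choice(rows, size=size, replace=True)
        if disjoint:
            pool = np.setdiff1d(rows, m)
            if pool.size == 0:
                pool = rows
            v = rng.choice(pool, size=size, replace=True)
        else:
            v = rng.choice(rows, size=size, replace=True)
        model_idx.append(m)
        valid_idx.append(v)
    return np.concatenate(model_idx), np.concatenate(valid_idx)


@dataclass
class EvaluationReport:
    """Per-class, per-metric mean ± SD over the bootstrap resamples."""

    metrics: pd.DataFrame  # MultiIndex (class, metric) -> columns mean, sd
    n_resamples: int
    fraction: float
    seed: int
    config: ClassifierConfig
    degenerate_cells: int
    redrawn: int
    scores: np.ndarray = field(repr=False)  # (n_resamples, n_classes, 4)

    def to_frame(self) -> pd.DataFrame:
        """Long-format report: class, metric, mean, sd, n_resamples, degenerate_cells."""
        out = self.metrics.reset_index()
        out["n_resamples"] = self.n_resamples
        out["degenerate_cells"] = self.degenerate_cells
        return out


def _check_feature_matrix(table: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    missing = [f for f in FEATURE_NAMES if f not in table.columns]
    if missing:
        raise ValueError(f"missing feature column: {', '.join(missing)}")
    if "group" not in table.columns:
        raise ValueError("missing 'group' column")
    X = table.loc[:, list(FEATURE_NAMES)].to_numpy(float)
    y = table["group"].to_numpy()
    for group in CLASS_ORDER:
        if (y == group).sum() < 2:
            raise ValueError(f"group {group} needs >= 2 subjects")
    return X, y


def evaluate(
    table: pd.DataFrame,
    config: ClassifierConfig,
    n_resamples: int = 1000,
    fraction: float = 0.5,
    seed: int = 0,
    normalization: str = "pooled",
    disjoint: bool = False,
) -> EvaluationReport:
    """Run the full bootstrap model/validation evaluation on a feature table.

    ``normalization``: ``"pooled"`` z-scores the whole table once before
    splitting (the default mirrors normalising the complete dataset prior to
    subsampling, which leaks validation rows into the scaling);
    ``"per_resample"`` refits the z-score on each model subsample only;
    ``"none"`` assumes the table is already scaled.

    One master seed spawns an independent child RNG per resample index, so
    changing ``n_resamples`` never reshuffles earlier resamples. A resample
    whose model subsample lacks a class is redrawn and counted (cannot occur
    with stratified draws, kept as a guard).
    """
    if normalization not in ("pooled", "per_resample", "none"):
        raise ValueError(f"unknown normalization: {normalization!r}")
    X, y = _check_feature_matrix(table)
    if normalization == "pooled":
        frame = pd.DataFrame(X, columns=FEATURE_NAMES)
        X = zscore_apply(frame, zscore_fit(frame)).to_numpy(float)

    n_classes = len(CLASS_ORDER)
    scores = np.empty((n_resamples, n_classes, len(METRICS)))
    degenerate_cells = 0
    redrawn = 0
    for i in range(n_resamples):
        ss = np.random.SeedSequence([int(seed), i])
        rng = np.random.default_rng(ss)
        train_seed = int(rng.integers(0, 2**31 - 1))
        for _attempt in range(100):
            m_idx, v_idx = resample_split(y, fraction, rng, disjoint=disjoint)
            if len(np.unique(y[m_idx])) == n_classes:
                break
            redrawn += 1
        Xm, ym = X[m_idx], y[m_idx]
        Xv, yv = X[v_idx], y[v_idx]
        if normalization == "per_resample":
            fm = pd.DataFrame(Xm, columns=FEATURE_NAMES)
            params = zscore_fit(fm)
            Xm = zscore_apply(fm, params).to_numpy(float)
            Xv = zscore_apply(pd.DataFrame(Xv, columns=FEATURE_NAMES), params).to_numpy(float)
        model = train(config, Xm, ym, seed=train_seed)
        pred = predict(model, Xv)
        ss_i = score(confusion_matrix(yv, pred))
        degenerate_cells += len(ss_i.degenerate)
        scores[i] = ss_i.metrics.to_numpy()

    index = pd.MultiIndex.from_product(
        [list(CLASS_ORDER), list(METRICS)], names=["class", "metric"]
    )
    mean = scores.mean(axis=0).ravel()
    sd = scores.std(axis=0, ddof=1).ravel() if n_resamples > 1 else np.zeros(mean.shape)
    report = pd.DataFrame({"mean": mean, "sd": sd}, index=index)
    return EvaluationReport(
        metrics=report,
        n_resamples=n_resamples,
        fraction=fraction,
        seed=seed,
        config=config,
        degenerate_cells=degenerate_cells,
        redrawn=redrawn,
        scores=scores,
    )


def compare_classifiers(
    table: pd.DataFrame,
    configs: Mapping[str, ClassifierConfig] = PRESETS,
    n_resamples: int = 1000,
    fraction: float = 0.5,
    seed: int = 0,
    normalization: str = "pooled",
    disjoint: bool = False,
) -> dict[str, EvaluationReport]:
    """Evaluate several classifier configurations on the same table and seed."""
    return {
        name: evaluate(
            table, cfg, n_resamples=n_resamples, fraction=fraction,
            seed=seed, normalization=normalization, disjoint=disjoint,
        )
        for name, cfg in configs.items()
    }


class TMDClassificationModel:
    """Bootstrap-validated TMD classifier over an 18-feature table.

    Parameters
    ----------
    features : DataFrame
        One row per subject with the 18 feature columns (mm).
    labels : Series or array
        Diagnostic group per subject (AG / MG / CG).
    config : ClassifierConfig, optional
        Classifier configuration; defaults to 1-nearest-neighbour.

    Examples
    --------
    >>> model = TMDClassificationModel.from_feature_table(table)
    >>> results = model.fit(n_resamples=1000, seed=7)
    >>> print(results.summary())
    """

    def __init__(
        self,
        features: pd.DataFrame,
        labels: Sequence[str],
        config: ClassifierConfig | None = None,
    ) -> None:
        table = features.loc[:, list(FEATURE_NAMES)].copy()
        table["group"] = np.asarray(labels)
        _check_feature_matrix(table)
        self.table = table
        self.config = config if config is not None else PRESETS["knn"]

    @classmethod
    def from_feature_table(
        cls,
        table: pd.DataFrame,
        label_col: str = "group",
        config: ClassifierConfig | None = None,
    ) -> "TMDClassificationModel":
        """Build from a table that carries its labels as a column."""
        return cls(table, table[label_col], config=config)

    # alias matching DataFrame-first conventions
    from_dataframe = from_feature_table

    def fit(
        self,
        n_resamples: int = 1000,
        fraction: float = 0.5,
        seed: int = 0,
        normalization: str = "pooled",
        disjoint: bool = False,
    ) -> "TMDClassificationResults":
        report = evaluate(
            self.table,
            self.config,
            n_resamples=n_resamples,
            fraction=fraction,
            seed=seed,
            normalization=normalization,
            disjoint=disjoint,
        )
        return TMDClassificationResults(self, report)


class TMDClassificationResults:
    """Results of the bootstrap evaluation: estimates, spread, diagnostics."""

    def __init__(self, model: TMDClassificationModel, report: EvaluationReport):
        self.model = model
        self.report = report
        self.metrics = report.metrics
        self.n_resamples = report.n_resamples
        self.degenerate_cells = report.degenerate_cells
        self.seed = report.seed

    def to_frame(self) -> pd.DataFrame:
        return self.report.to_frame()

    def summary(self) -> str:
        """Human-readable per-class metric table, mean (± SD) over resamples."""
        cfg = self.report.config
        width = 18
        lines = [
            "        Bootstrap classifier evaluation",
            "=" * (6 + 4 * width),
            f"Classifier:  {cfg.describe()}",
            f"Resamples:   {self.n_resamples}   Fraction: {self.report.fraction}"
            f"   Seed: {self.seed}",
            f"Subjects:    {len(self.model.table)}   "
            f"Degenerate metric cells: {self.degenerate_cells}",
            "-" * (6 + 4 * width),
            f"{'Class':<6}" + "".join(f"{m.capitalize():>{width}}" for m in METRICS),
        ]
        for cls_ in CLASS_ORDER:
            cells = []
            for m in METRICS:
                mean = self.metrics.loc[(cls_, m), "mean"]
                sd = self.metrics.loc[(cls_, m), "sd"]
                cells.append(f"{mean:.4f} ({sd:.4f})")
            lines.append(f"{cls_:<6}" + "".join(f"{c:>{width}}" for c in cells))
        lines.append("=" * (6 + 4 * width))
        return "\n".join(lines)
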