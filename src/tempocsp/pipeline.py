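"""End-to-end training, prediction, repeated CV, and method comparison.

The full decoding chain: decompose each trial into the five cue-locked
segments (band-passed 8-30 Hz), fit one CSP model per segment on the
training trials, concatenate log-variance features into the trials x 20
table, run the configured selector down to k = 4 features, and fit a
linear SVM on the standardized selected features.  ``selector="none"``
is the classical single-window comparator: one CSP on a fixed window,
2m = 4 features, no selection.

Evaluation uses repeated stratified k-fold cross-validation (10 x 10 by
default); within every fold the spatial filters, the selector and the
classifier are fitted on the training split only.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import stats
from sklearn.model_selection import RepeatedStratifiedKFold
from sklearn.svm import SVC

from .trials import TrialSet
from .preprocess import SegmentScheme, BandpassSpec, decompose_trialset, bandpass, slice_window
from .csp import CSPModel, FeatureTable, fit_csp, build_feature_table
from . import select as _select
from .select import SelectionResult

__all__ = [
    "PipelineConfig",
    "TrainedPipeline",
    "CVReport",
    "train_pipeline",
    "predict",
    "cross_validate",
    "compare_methods",
    "paired_ttest",
    "segment_usage",
]

SELECTORS = ("muin", "lasso", "pca", "swlda", "none")


@dataclass(frozen=True)
class PipelineConfig:
    """Everything needed to reproduce one decoding run."""

    scheme: SegmentScheme = SegmentScheme()
    band: BandpassSpec = BandpassSpec()
    m: int = 2
    k: int = 4
    selector: str = "lasso"
    svm_kernel: str = "linear"
    svm_c: float = 1.0
    n_repeats: int = 10
    n_folds: int = 10
    seed: int = 0
    filter_mode: str = "global"
    #: fixed window (s, relative to cue) used by the selector-free comparator
    fixed_window_s: tuple[float, float] = (0.0, 4.0)
    shrinkage: float = 0.0
    normalized_variance: bool = False

    def __post_init__(self):
        if self.selector not in SELECTORS:
            raise ValueError(f"selector must be one of {SELECTORS}; got {self.selector!r}")
        if self.k % 2 != 0:
            raise ValueError(f"k must be even; got {self.k}")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["scheme"] = asdict(self.scheme)
        d["band"] = asdict(self.band)
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class TrainedPipeline:
    """Per-segment CSP models, the selection, the scaler and the SVM."""

    models: list[CSPModel]
    selection: SelectionResult
    scaler_mean: np.ndarray
    scaler_sd: np.ndarray
    svm: SVC
    config: PipelineConfig
    n_channels: int
    fs: float


def _segments(ts: TrialSet, config: PipelineConfig) -> list[TrialSet]:
    """Cue-locked, band-passed segment sets (or the single fixed window)."""
    if config.selector == "none":
        filtered = TrialSet(
            signals=bandpass(ts.signals, config.band, ts.fs),
            labels=ts.labels.copy(),
            fs=ts.fs,
            cue_onset_s=ts.cue_onset_s,
            channel_names=list(ts.channel_names),
        )
        return [slice_window(filtered, config.fixed_window_s)]
    return decompose_trialset(ts, config.scheme, config.band, mode=config.filter_mode)


def _fit_models(segments: list[TrialSet], config: PipelineConfig) -> list[CSPModel]:
    models = []
    for s, seg in enumerate(segments, start=1):
        i1, i2 = seg.class_indices(1), seg.class_indices(2)
        if len(i1) < config.m + 1 or len(i2) < config.m + 1:
            raise ValueError(
                f"segment {s}: need at least m+1={config.m + 1} training trials per class"
            )
        try:
            models.append(
                fit_csp(seg.signals[i1], seg.signals[i2], m=config.m, shrinkage=config.shrinkage)
            )
        except Exception as err:
            raise RuntimeError(f"CSP fit failed for segment {s}: {err}") from err
    return models


def _fit_selector(table: FeatureTable, config: PipelineConfig) -> SelectionResult:
    if config.selector == "none":
        cols = list(range(table.n_columns))
        return SelectionResult(
            method="none",
            selected_columns=cols,
            transform=np.eye(table.n_columns),
            scores=np.zeros(table.n_columns),
            meta={},
        )
    if config.selector == "muin":
        return _select.select_muin(table, config.k)
    if config.selector == "lasso":
        return _select.lasso_select(table, config.k)
    if config.selector == "pca":
        return _select.pca_transform(table, config.k)
    result = _select.swlda_select(table, config.k)
    if result.meta.get("empty"):
        # no feature passed the entry threshold; fall back to the marginal
        # pair ranking so the classifier still gets k features
        fallback = _select.marginal_pair_selection(table, config.k)
        fallback.method = "swlda"
        fallback.meta.update(result.meta)
        return fallback
    return result


def _featurize(models: list[CSPModel], segments: list[TrialSet], config: PipelineConfig) -> FeatureTable:
    return build_feature_table(models, segments, normalized=config.normalized_variance)


def train_pipeline(train: TrialSet, config: PipelineConfig = PipelineConfig()) -> TrainedPipeline:
    """Fit the full chain on a training TrialSet.

    Stages: segment decomposition -> per-segment CSP -> feature table ->
    selector -> standardization -> SVM.  Stage failures propagate with the
    stage name.
    """
    segments = _segments(train, config)
    models = _fit_models(segments, config)
    try:
        table = _featurize(models, segments, config)
    except Exception as err:
        raise RuntimeError(f"feature extraction failed: {err}") from err
    try:
        selection = _fit_selector(table, config)
    except Exception as err:
        raise RuntimeError(f"selector {config.selector!r} failed: {err}") from err
    x = selection.apply(table.values)
    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=0)
    sd = np.where(sd > 0, sd, 1.0)
    svm = SVC(kernel=config.svm_kernel, C=config.svm_c)
    try:
        svm.fit((x - mean) / sd, table.labels)
    except Exception as err:
        raise RuntimeError(f"SVM training failed: {err}") from err
    return TrainedPipeline(
        models=models,
        selection=selection,
        scaler_mean=mean,
        scaler_sd=sd,
        svm=svm,
        config=config,
        n_channels=train.n_channels,
        fs=train.fs,
    )


def predict(model: TrainedPipeline, trials: TrialSet) -> np.ndarray:
    """Labels in {1, 2} for each trial; deterministic, no batch effects."""
    if trials.n_channels != model.n_channels or trials.fs != model.fs:
        raise ValueError(
            f"geometry mismatch: got {trials.n_channels} channels at {trials.fs} Hz, "
            f"model expects {model.n_channels} at {model.fs} Hz"
        )
    segments = _segments(trials, model.config)
    table = _featurize(model.models, segments, model.config)
    x = model.selection.apply(table.values)
    return model.svm.predict((x - model.scaler_mean) / model.scaler_sd)


@dataclass
class CVReport:
    """Result of one repeated cross-validation run of one method."""

    method: str
    accuracies: np.ndarray  # (n_repeats, n_folds), fractions in [0, 1]
    n_correct: int
    n_tested: int
    fold_test_indices: list[tuple[int, ...]]
    selections: list[SelectionResult]
    seed: int
    config: PipelineConfig

    @property
    def mean_accuracy(self) -> float:
        return float(self.accuracies.mean())

    @property
    def sd_accuracy(self) -> float:
        return float(self.accuracies.std(ddof=1))

    def partition_hash(self) -> str:
        return hashlib.sha256(repr(self.fold_test_indices).encode()).hexdigest()[:16]

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "partition_hash": self.partition_hash(),
            "mean_accuracy": self.mean_accuracy,
            "sd_accuracy": self.sd_accuracy,
            "n_correct": self.n_correct,
            "n_tested": self.n_tested,
            "fold_accuracies": self.accuracies.ravel().tolist(),
            "seed": self.seed,
            "config_hash": self.config.config_hash(),
        }


def cross_validate(ts: TrialSet, config: PipelineConfig = PipelineConfig()) -> CVReport:
    """Repeated stratified k-fold CV with per-fold refitting.

    Band-pass filtering and window slicing are label-free per-trial
    transforms, so they run once up front; CSP, the selector and the SVM
    are refitted inside every fold on the training split only.  Within
    each repeat every trial lands in exactly one test fold.
    """
    for cls in (1, 2):
        if len(ts.class_indices(cls)) < config.n_folds:
            raise ValueError(f"class {cls} has fewer trials than n_folds={config.n_folds}")
    segments = _segments(ts, config)
    splitter = RepeatedStratifiedKFold(
        n_splits=config.n_folds, n_repeats=config.n_repeats, random_state=config.seed
    )
    acc = np.zeros((config.n_repeats, config.n_folds))
    fold_test_indices: list[tuple[int, ...]] = []
    selections: list[SelectionResult] = []
    n_correct = 0
    n_tested = 0
    dummy = np.zeros(ts.n_trials)
    for f, (train_idx, test_idx) in enumerate(splitter.split(dummy, ts.labels)):
        rep, fold = divmod(f, config.n_folds)
        train_segs = [seg.subset(train_idx) for seg in segments]
        models = _fit_models(train_segs, config)
        table = _featurize(models, train_segs, config)
        selection = _fit_selector(table, config)
        x = selection.apply(table.values)
        mean = x.mean(axis=0)
        sd = x.std(axis=0, ddof=0)
        sd = np.where(sd > 0, sd, 1.0)
        svm = SVC(kernel=config.svm_kernel, C=config.svm_c)
        svm.fit((x - mean) / sd, table.labels)
        test_table = _featurize(models, [seg.subset(test_idx) for seg in segments], config)
        pred = svm.predict((selection.apply(test_table.values) - mean) / sd)
        correct = int(np.sum(pred == ts.labels[test_idx]))
        acc[rep, fold] = correct / len(test_idx)
        n_correct += correct
        n_tested += len(test_idx)
        fold_test_indices.append(tuple(int(i) for i in test_idx))
        selections.append(selection)
    return CVReport(
        method=config.selector,
        accuracies=acc,
        n_correct=n_correct,
        n_tested=n_tested,
        fold_test_indices=fold_test_indices,
        selections=selections,
        seed=config.seed,
        config=config,
    )


def paired_ttest(a: np.ndarray, b: np.ndarray) -> tuple[float, float, bool]:
    """Two-sided paired t-test; (t, p, degenerate).

    Zero-variance differences are degenerate: by convention p = 1 with
    the flag set (identical vectors carry no evidence either way).
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError(f"paired vectors differ in length: {a.shape} vs {b.shape}")
    d = a - b
    if np.allclose(d.std(ddof=1) if len(d) > 1 else 0.0, 0.0):
        return 0.0, 1.0, True
    t, p = stats.ttest_rel(a, b)
    return float(t), float(p), False


def compare_methods(reports: dict[str, CVReport], comparator: str) -> dict[str, dict]:
    """Paired t-tests of every method against a comparator, fold-wise.

    All reports must share the identical fold partition (same CV seed on
    the same data); pairing is per fold.
    """
    if comparator not in reports:
        raise KeyError(f"comparator {comparator!r} not among {list(reports)}")
    base = reports[comparator]
    out = {}
    for name, rep in reports.items():
        if name == comparator:
            continue
        if rep.fold_test_indices != base.fold_test_indices:
            raise ValueError(
                f"report {name!r} uses a different fold partition than {comparator!r}"
            )
        t, p, degenerate = paired_ttest(rep.accuracies.ravel(), base.accuracies.ravel())
        out[name] = {
            "t": t,
            "p": p,
            "degenerate": degenerate,
            "mean_diff": rep.mean_accuracy - base.mean_accuracy,
        }
    return out


def _selection_segments(selection: SelectionResult, two_m: int) -> list[int]:
    """1-based segment index of every selected column/component.

    PCA components are attributed to the segment of their
    largest-magnitude loading.
    """
    if selection.method == "pca":
        cols = [int(np.argmax(np.abs(row))) for row in selection.transform]
    else:
        cols = selection.selected_columns
    return [c // two_m + 1 for c in cols]


def segment_usage(
    reports_or_selections, n_segments: int = 5, two_m: int = 4
) -> tuple[dict[int, int], float]:
    """Tally which time windows the per-fold selections used.

    Returns ``(counts, ratio)``: ``counts[i]`` is the number of selected
    columns originating from window ``i`` over all folds, and ``ratio``
    is the fraction of folds whose selection spans at least two distinct
    windows (the cross-window combination ratio).
    """
    selections: list[SelectionResult] = []
    for item in reports_or_selections:
        if isinstance(item, CVReport):
            selections.extend(item.selections)
        else:
            selections.append(item)
    counts = {i: 0 for i in range(1, n_segments + 1)}
    multi = 0
    for sel in selections:
        segs = _selection_segments(sel, two_m)
        for s in segs:
            counts[s] += 1
        if len(set(segs)) >= 2:
            multi += 1
    ratio = multi / len(selections) if selections else 0.0
    return counts, ratio
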