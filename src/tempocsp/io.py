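"""Dataset loaders, run configuration, and experiment execution.

Two on-disk dialects are understood: the package's own HDF5 container
(written by :meth:`TrialSet.save`) and a MAT-style continuous recording
with cue markers, the generic structure of the public BCI-competition
archives (a samples x channels signal, marker positions, class codes and
a sampling rate), epoched here around each cue.  The competition archives
themselves are not bundled and are never downloaded; users who have them
can point the loader at the files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.io import loadmat

from .trials import TrialSet
from .synthdata import SynthConfig, ErdSpec, generate_mi_trialset, generate_null_trialset
from .preprocess import SegmentScheme, BandpassSpec
from .pipeline import PipelineConfig, cross_validate, compare_methods, segment_usage

__all__ = ["load_trialset", "RunConfig", "run_experiment"]

logger = logging.getLogger("tempocsp")


# ---------------------------------------------------------------------------
# loaders
# ---------------------------------------------------------------------------

def _squeeze_field(obj, name):
    """Field access tolerant of MATLAB struct nesting produced by savemat."""
    val = obj[name] if isinstance(obj, dict) else getattr(obj, name)
    return np.squeeze(np.asarray(val))


def _load_mat_continuous(
    path,
    epoch_window_s: tuple[float, float],
    class_codes: tuple | None,
) -> TrialSet:
    mat = loadmat(path, squeeze_me=False, struct_as_record=False)
    if "cnt" in mat:  # competition calibration layout
        cnt = np.asarray(mat["cnt"], dtype=np.float64)  # samples x channels
        mrk = mat["mrk"][0, 0]
        pos = np.atleast_1d(_squeeze_field(mrk, "pos")).astype(int)
        codes = np.atleast_1d(_squeeze_field(mrk, "y")).astype(int)
        nfo = mat["nfo"][0, 0]
        fs = float(_squeeze_field(nfo, "fs"))
        try:
            clab = [str(np.squeeze(c)) for c in np.ravel(_squeeze_field(nfo, "clab"))]
        except Exception:
            clab = []
    elif "signal" in mat:  # generic layout
        cnt = np.asarray(mat["signal"], dtype=np.float64)
        pos = np.atleast_1d(np.squeeze(mat["cue_pos"])).astype(int)
        codes = np.atleast_1d(np.squeeze(mat["cue_y"])).astype(int)
        fs = float(np.squeeze(mat["fs"]))
        clab = (
            [str(np.squeeze(c)) for c in np.ravel(mat["channel_names"])]
            if "channel_names" in mat
            else []
        )
    else:
        raise ValueError(
            f"{path}: unknown MAT layout (expected 'cnt'+'mrk'+'nfo' or "
            f"'signal'+'cue_pos'+'cue_y'+'fs')"
        )
    if len(pos) != len(codes):
        raise ValueError(f"{path}: {len(pos)} markers but {len(codes)} class codes")
    if class_codes is None:
        uniq = sorted(set(codes.tolist()))
        if set(uniq) == {-1, 1}:
            class_codes = (-1, 1)
        else:
            class_codes = tuple(uniq[:2])
    code_map = {class_codes[0]: 1, class_codes[1]: 2}
    pre = int(round(epoch_window_s[0] * fs))
    length = int(round((epoch_window_s[1] - epoch_window_s[0]) * fs))
    trials, labels = [], []
    n_excluded_code = 0
    n_excluded_bounds = 0
    for p, code in zip(pos, codes):
        if code not in code_map:
            n_excluded_code += 1
            continue
        start = p + pre
        if start < 0 or start + length > cnt.shape[0]:
            n_excluded_bounds += 1
            continue
        trials.append(cnt[start : start + length].T)
        labels.append(code_map[code])
    if n_excluded_code:
        logger.warning("%s: excluded %d trials with unselected class codes", path, n_excluded_code)
    if n_excluded_bounds:
        logger.warning("%s: excluded %d trials running past the recording", path, n_excluded_bounds)
    if len(set(labels)) != 2:
        raise ValueError(f"{path}: fewer than two classes remain after filtering")
    return TrialSet(
        signals=np.stack(trials),
        labels=np.array(labels),
        fs=fs,
        cue_onset_s=-epoch_window_s[0],
        channel_names=clab,
    )


def load_trialset(
    path,
    format_hint: str | None = None,
    epoch_window_s: tuple[float, float] = (-2.0, 6.0),
    class_codes: tuple | None = None,
) -> TrialSet:
    """Load a TrialSet from disk.

    ``.h5``/``.hdf5`` (or ``format_hint="container"``) reads the package
    container; ``.mat`` (or ``format_hint="mat"``) epochs a continuous
    recording around its cue markers using ``epoch_window_s`` seconds
    relative to each cue.  ``class_codes`` picks the two marker codes to
    keep (mapped to labels 1 and 2); others are excluded with the count
    reported.  Four-class sources therefore reduce to the requested two.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format_hint
    if fmt is None:
        fmt = {".h5": "container", ".hdf5": "container", ".mat": "mat"}.get(path.suffix.lower())
    if fmt == "container":
        return TrialSet.load(path)
    if fmt == "mat":
        return _load_mat_continuous(path, epoch_window_s, class_codes)
    raise ValueError(f"cannot infer format of {path}; pass format_hint='container' or 'mat'")


# ---------------------------------------------------------------------------
# run configuration and execution
# ---------------------------------------------------------------------------

def _build_synth_config(overrides: dict, seed: int) -> SynthConfig:
    kwargs = dict(overrides)
    specs = kwargs.pop("erd_specs", None)
    if specs is not None:
        kwargs["erd_specs"] = tuple(
            ErdSpec(
                class_label=s["class_label"],
                channels=tuple(s["channels"]),
                band_hz=tuple(s.get("band_hz", (8.0, 12.0))),
                windows_s=tuple(tuple(w) for w in s.get("windows_s", ((0.0, 4.0),))),
                depth=s.get("depth", 0.8),
            )
            for s in specs
        )
    kwargs.setdefault("seed", seed)
    return SynthConfig(**kwargs)


def _build_pipeline_config(overrides: dict, selector: str, seed: int) -> PipelineConfig:
    kwargs = dict(overrides)
    if "scheme" in kwargs:
        kwargs["scheme"] = SegmentScheme(**kwargs["scheme"])
    if "band" in kwargs:
        kwargs["band"] = BandpassSpec(**kwargs["band"])
    if "fixed_window_s" in kwargs:
        kwargs["fixed_window_s"] = tuple(kwargs["fixed_window_s"])
    kwargs["selector"] = selector
    kwargs.setdefault("seed", seed)
    return PipelineConfig(**kwargs)


@dataclass
class RunConfig:
    """Serializable description of one experiment run."""

    dataset: str = "synthetic"  # "synthetic" or a path
    synth: dict = field(default_factory=dict)
    pipeline: dict = field(default_factory=dict)
    selectors: list[str] = field(default_factory=lambda: ["muin", "lasso", "pca", "swlda", "none"])
    comparator: str = "none"
    null_labels: bool = False
    out_dir: str = "tempocsp_out"
    log_level: str = "INFO"
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        return hashlib.sha256(json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:16]

    def to_yaml(self, path) -> None:
        with open(path, "w") as f:
            yaml.safe_dump(self.to_dict(), f, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as f:
            data = yaml.safe_load(f) or {}
        return cls(**data)


def run_experiment(config: RunConfig) -> dict[str, str]:
    """Execute a run end to end and persist its artifacts.

    Generates (or loads) the data, cross-validates every configured
    selector on the identical fold partition, and writes ``report.json``
    (per-method accuracies, paired t-tests against the comparator, config
    hash and seed), ``accuracy.csv`` and ``segment_usage.csv`` into the
    output directory.  Returns the artifact paths.
    """
    logging.basicConfig(
        level=getattr(logging, config.log_level.upper(), logging.INFO),
        format="%(asctime)s %(levelname)s %(name)s: %(message)s",
    )
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    t0 = time.perf_counter()
    if config.dataset == "synthetic":
        synth_cfg = _build_synth_config(config.synth, config.seed)
        ts = (
            generate_null_trialset(synth_cfg)
            if config.null_labels
            else generate_mi_trialset(synth_cfg)
        )
        logger.info("generated synthetic trial set: %d trials", ts.n_trials)
    else:
        ts = load_trialset(config.dataset)
        logger.info("loaded %s: %d trials", config.dataset, ts.n_trials)

    reports = {}
    timings = {"data_s": time.perf_counter() - t0}
    for selector in config.selectors:
        t1 = time.perf_counter()
        pipe_cfg = _build_pipeline_config(config.pipeline, selector, config.seed)
        reports[selector] = cross_validate(ts, pipe_cfg)
        timings[f"{selector}_s"] = time.perf_counter() - t1
        logger.info(
            "selector %-6s mean accuracy %.1f%% (%.1fs)",
            selector,
            100 * reports[selector].mean_accuracy,
            timings[f"{selector}_s"],
        )

    comparisons = {}
    if config.comparator in reports and len(reports) > 1:
        comparisons = compare_methods(reports, config.comparator)

    usage_rows = []
    for selector, rep in reports.items():
        if selector == "none":
            continue
        counts, ratio = segment_usage([rep])
        usage_rows.append({"method": selector, "cross_window_ratio": ratio, **{
            f"window_{i}": counts[i] for i in sorted(counts)
        }})

    report = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "n_trials": ts.n_trials,
        "methods": {name: rep.to_dict() for name, rep in reports.items()},
        "comparisons": comparisons,
        "timings_s": timings,
    }
    report_path = out_dir / "report.json"
    with open(report_path, "w") as f:
        json.dump(report, f, indent=2)

    acc_path = out_dir / "accuracy.csv"
    pd.DataFrame(
        [
            {
                "method": name,
                "mean_accuracy_pct": 100 * rep.mean_accuracy,
                "sd_accuracy_pct": 100 * rep.sd_accuracy,
            }
            for name, rep in reports.items()
        ]
    ).to_csv(acc_path, index=False)

    usage_path = out_dir / "segment_usage.csv"
    pd.DataFrame(usage_rows).to_csv(usage_path, index=False)
    logger.info("artifacts written to %s", out_dir)
    return {
        "report": str(report_path),
        "accuracy": str(acc_path),
        "segment_usage": str(usage_path),
    }
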