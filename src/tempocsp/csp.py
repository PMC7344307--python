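"""Common spatial patterns (CSP) and the concatenated feature table.

CSP finds spatial filters ``w`` that maximize the ratio of one class's
band-power to the total, by jointly diagonalizing the two trace-normalized
class covariance matrices: whiten the composite covariance ``C1 + C2``,
eigendecompose the whitened class-1 covariance, and sort eigenvalues
descending.  Filters from the ``m`` largest and ``m`` smallest eigenvalues
(``m = 2`` here, so four filters) form the reduced filter bank ``W_2m``;
filter ``j`` pairs with filter ``2m+1-j``, the two extremes carrying the
complementary class contrasts.

Features are log-variances of the spatially filtered segment,
``f_j = log(var(w_j' E))``; one 2m-vector per segment, concatenated
segment-major over the five segments into a trials x 20 feature table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg

from .trials import TrialSet

__all__ = [
    "CSPModel",
    "FeatureTable",
    "class_covariance",
    "fit_csp",
    "extract_features",
    "build_feature_table",
    "pair_partner",
]


def pair_partner(col: int, two_m: int = 4) -> int:
    """Partner of flat feature column ``col`` under the CSP pairing.

    Within a segment's block of ``2m`` filters, filter ``j`` (0-based)
    pairs with filter ``2m-1-j``; segment blocks are independent.
    """
    seg, j = divmod(col, two_m)
    return seg * two_m + (two_m - 1 - j)


def class_covariance(trials) -> np.ndarray:
    """Average trace-normalized spatial covariance of a class.

    Each trial ``E`` (channels x samples) contributes ``E E' / tr(E E')``;
    the result is symmetric PSD with unit trace.  A zero-energy trial is
    rejected by index.
    """
    trials = np.asarray(trials, dtype=np.float64)
    if trials.ndim == 2:
        trials = trials[None]
    if trials.shape[0] < 1:
        raise ValueError("need at least one trial")
    cov = np.zeros((trials.shape[1], trials.shape[1]))
    for i, e in enumerate(trials):
        s = e @ e.T
        tr = np.trace(s)
        if not np.isfinite(tr) or tr <= 0:
            raise ValueError(f"trial {i} has zero or non-finite energy (trace={tr})")
        cov += s / tr
    return cov / trials.shape[0]


@dataclass
class CSPModel:
    """Fitted CSP filter bank for one time segment.

    ``W_full`` holds all ``c`` filters as columns, ordered by descending
    eigenvalue of the whitened class-1 covariance; ``W_2m`` keeps the
    first ``m`` and last ``m`` columns.  Every filter satisfies
    ``w' (C1 + C2) w = 1``.
    """

    W_full: np.ndarray
    W_2m: np.ndarray
    eigenvalues: np.ndarray
    m: int

    @property
    def n_channels(self) -> int:
        return self.W_full.shape[0]

    def pair_index(self, j: int) -> int:
        """Partner column of ``W_2m`` column ``j`` (0-based): j <-> 2m-1-j."""
        return 2 * self.m - 1 - j


def fit_csp(class1_trials, class2_trials, m: int = 2, shrinkage: float = 0.0) -> CSPModel:
    """Fit CSP filters from two classes of (trials x channels x samples).

    Whitening-based joint diagonalization.  Eigenvalues lie in [0, 1],
    sorted descending; eigenvalue ``lambda_j`` is the class-1 share of the
    composite variance along filter ``j``.  ``shrinkage`` in [0, 1] mixes
    each class covariance toward a scaled identity,
    ``C <- (1-g) C + g (tr C / c) I``, for rank-deficient montages.

    Filter signs are fixed so each filter's largest-magnitude coefficient
    is positive (eigenvector signs are otherwise arbitrary).
    """
    c1 = class_covariance(class1_trials)
    c2 = class_covariance(class2_trials)
    c = c1.shape[0]
    if c2.shape != c1.shape:
        raise ValueError(f"channel mismatch: {c1.shape} vs {c2.shape}")
    if not 0 <= shrinkage <= 1:
        raise ValueError(f"shrinkage must be in [0, 1]; got {shrinkage}")
    if 2 * m > c:
        raise ValueError(f"2m={2*m} filters requested but only {c} channels")
    if shrinkage > 0:
        c1 = (1 - shrinkage) * c1 + shrinkage * (np.trace(c1) / c) * np.eye(c)
        c2 = (1 - shrinkage) * c2 + shrinkage * (np.trace(c2) / c) * np.eye(c)
    comp = c1 + c2
    evals, evecs = linalg.eigh(comp)
    tol = c * np.finfo(float).eps * evals[-1]
    if evals[0] <= tol:
        raise np.linalg.LinAlgError(
            "composite covariance is rank deficient; re-fit with shrinkage > 0 "
            "or drop linearly dependent channels"
        )
    whiten = (evecs / np.sqrt(evals)).T  # rows: whitening transform P
    s1 = whiten @ c1 @ whiten.T
    lam, b = linalg.eigh(s1)  # ascending
    lam = np.clip(lam[::-1], 0.0, 1.0)
    b = b[:, ::-1]
    w_full = whiten.T @ b  # columns are filters
    # deterministic sign: largest-|coefficient| entry positive
    idx = np.argmax(np.abs(w_full), axis=0)
    signs = np.sign(w_full[idx, np.arange(c)])
    signs[signs == 0] = 1.0
    w_full = w_full * signs
    w_2m = np.hstack([w_full[:, :m], w_full[:, c - m :]])
    return CSPModel(W_full=w_full, W_2m=w_2m, eigenvalues=lam, m=m)


def extract_features(
    model: CSPModel, trial_segment: np.ndarray, normalized: bool = False
) -> np.ndarray:
    """Log-variance features of one segment through the 2m selected filters.

    ``f_j = log(var(w_j' E))``; with ``normalized=True`` the variances are
    divided by their sum first (the conventional normalized variant).
    Accepts a single trial (channels x samples) or a stack
    (trials x channels x samples); returns (2m,) or (trials, 2m).
    """
    e = np.asarray(trial_segment, dtype=np.float64)
    single = e.ndim == 2
    if single:
        e = e[None]
    if e.shape[1] != model.n_channels:
        raise ValueError(
            f"trial has {e.shape[1]} channels; model was fitted on {model.n_channels}"
        )
    proj = np.einsum("cj,ncs->njs", model.W_2m, e)
    v = proj.var(axis=2)
    if np.any(v <= 0) or not np.all(np.isfinite(v)):
        bad = int(np.argwhere((v <= 0) | ~np.isfinite(v))[0][1])
        raise ValueError(f"zero or non-finite variance under filter {bad}")
    if normalized:
        v = v / v.sum(axis=1, keepdims=True)
    f = np.log(v)
    return f[0] if single else f


@dataclass
class FeatureTable:
    """Trials x (Ns * 2m) concatenated log-variance features.

    Column order is segment-major: all of segment 1's filters, then
    segment 2's, etc.  ``column_provenance`` records the 1-based
    (segment, filter) origin of every column.
    """

    values: np.ndarray
    column_provenance: list[tuple[int, int]]
    labels: np.ndarray

    @property
    def n_trials(self) -> int:
        return self.values.shape[0]

    @property
    def n_columns(self) -> int:
        return self.values.shape[1]

    @property
    def two_m(self) -> int:
        return max(f for _, f in self.column_provenance)

    def column_names(self) -> list[str]:
        return [f"s{s}_f{f}" for s, f in self.column_provenance]

    def partner(self, col: int) -> int:
        """CSP pair partner of flat column ``col`` (0-based)."""
        return pair_partner(col, self.two_m)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.column_names())
        df.insert(0, "label", self.labels)
        return df

    def to_csv(self, path) -> None:
        """CSV export with a provenance header row (segment/filter)."""
        self.to_dataframe().to_csv(path, index=False)


def build_feature_table(
    per_segment_models: list[CSPModel], segmented_trialsets: list[TrialSet], normalized: bool = False
) -> FeatureTable:
    """Concatenate per-segment CSP features into one table.

    Row ``i`` is ``[f_{1,i}, ..., f_{Ns,i}]``; with five segments and
    ``m = 2`` this yields 20 columns.
    """
    if len(per_segment_models) != len(segmented_trialsets):
        raise ValueError(
            f"{len(per_segment_models)} models for {len(segmented_trialsets)} segments"
        )
    labels = segmented_trialsets[0].labels
    n = segmented_trialsets[0].n_trials
    blocks = []
    provenance = []
    for s, (model, seg) in enumerate(zip(per_segment_models, segmented_trialsets), start=1):
        if seg.n_trials != n or not np.array_equal(seg.labels, labels):
            raise ValueError(f"segment {s} trials/labels differ from segment 1")
        blocks.append(extract_features(model, seg.signals, normalized=normalized))
        provenance.extend((s, j + 1) for j in range(2 * model.m))
    return FeatureTable(
        values=np.hstack(blocks), column_provenance=provenance, labels=labels.copy()
    )
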