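"""Feature selection over the concatenated spatio-temporal CSP features.

Four selectors operate on the trials x 20 feature table, each reducing it
to ``k = 4`` features for the classifier:

* **MUIN** ranks columns by the mutual information between the feature and
  the class label, with class-conditional densities estimated by a
  Gaussian Parzen window (Silverman bandwidth per class).
* **LASSO** regresses the numeric label on the table with an l1 penalty,
  ``argmin ||y - F b||^2 + lambda ||b||_1``, and ranks columns by the
  contribution degree ``CD_j = |b_j|``; lambda moves down a geometric grid
  until enough nonzero coefficients exist.
* **PCA** is an unsupervised k-dimensional orthonormal projection onto the
  top principal axes of the column-centered table.
* **SWLDA** runs forward (p < 0.1 to enter) / backward (p > 0.15 to
  remove) stepwise regression with partial F-tests, capped at k features.

CSP filters carry class information in pairs (largest with smallest
eigenvalue), so the three column selectors always return pair-closed sets:
whenever a column is chosen its partner in the same segment is chosen too.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.linear_model import Lasso

from .csp import FeatureTable, pair_partner

__all__ = [
    "SelectionResult",
    "mi_score",
    "select_muin",
    "solve_lasso",
    "lasso_select",
    "pca_transform",
    "swlda_select",
    "marginal_pair_selection",
]


@dataclass
class SelectionResult:
    """Outcome of one selector.

    For the column selectors ``transform`` holds one-hot rows picking
    ``selected_columns``; for PCA it holds the k orthonormal principal
    axes and ``selected_columns`` is empty.  ``scores`` is the per-column
    diagnostic on the full table (MI bits, |beta|, marginal p-values) or
    the PCA eigenvalues.
    """

    method: str
    selected_columns: list[int]
    transform: np.ndarray
    scores: np.ndarray
    meta: dict = field(default_factory=dict)

    @property
    def k(self) -> int:
        return self.transform.shape[0]

    def apply(self, values: np.ndarray) -> np.ndarray:
        """Project a trials x n_columns feature matrix to k dimensions."""
        values = np.asarray(values, dtype=np.float64)
        if self.method == "pca":
            return (values - self.meta["center"]) @ self.transform.T
        return values[:, self.selected_columns]


def _onehot_transform(cols: list[int], n_columns: int) -> np.ndarray:
    t = np.zeros((len(cols), n_columns))
    t[np.arange(len(cols)), cols] = 1.0
    return t


def _rank_to_pairs(ranking, k: int, two_m: int, eligible=None) -> list[int]:
    """Walk a column ranking, adding pair-closed columns until |S| = k.

    Because additions always come as (column, partner) and the set stays
    pair-closed, the size grows by exactly 2 per accepted column; ties
    were already broken in ``ranking`` (lower index first).
    """
    selected: list[int] = []
    for col in ranking:
        col = int(col)
        if col in selected:
            continue
        if eligible is not None and col not in eligible:
            continue
        selected.append(col)
        partner = pair_partner(col, two_m)
        if partner not in selected:
            selected.append(partner)
        if len(selected) >= k:
            break
    return selected


# ---------------------------------------------------------------------------
# mutual information (MUIN)
# ---------------------------------------------------------------------------

def mi_score(column: np.ndarray, labels: np.ndarray) -> float:
    """Mutual information I(v; w) in bits between a feature and the label.

    ``I = H(w) - H(w|v)`` with the class prior ``p(w) = n_w / n``;
    ``p(v|w)`` is a Gaussian Parzen estimate over the class-w training
    values with Silverman bandwidth ``h = (4 / (3 n_w))**(1/5) * sigma_w``,
    posteriors follow from Bayes' rule, and the conditional entropy is the
    empirical average over training trials of
    ``-sum_w p(w|v_i) log2 p(w|v_i)``.  Clipped to ``[0, H(w)]``.
    """
    v = np.asarray(column, dtype=np.float64).ravel()
    y = np.asarray(labels).ravel()
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError(f"need exactly two classes; got {classes}")
    n = len(v)
    priors, cond = [], []
    for cls in classes:
        vals = v[y == cls]
        n_w = len(vals)
        sigma = vals.std(ddof=1)
        if not np.isfinite(sigma) or sigma == 0:
            raise ValueError(
                f"feature is constant within class {cls}; Parzen bandwidth is zero"
            )
        h = (4.0 / (3.0 * n_w)) ** 0.2 * sigma
        # p(v_i | w) for every training point, vectorized over the class kernel centers
        z = (v[:, None] - vals[None, :]) / h
        dens = np.exp(-0.5 * z**2).sum(axis=1) / (n_w * h * np.sqrt(2 * np.pi))
        priors.append(n_w / n)
        cond.append(dens)
    priors_arr = np.array(priors)
    joint = np.stack(cond, axis=1) * priors_arr  # (n, 2): p(v_i|w) p(w)
    total = joint.sum(axis=1)
    post = joint / np.where(total > 0, total, 1.0)[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(post > 0, post * np.log2(post), 0.0)
    h_cond = -plogp.sum(axis=1).mean()
    h_prior = -(priors_arr * np.log2(priors_arr)).sum()
    return float(np.clip(h_prior - h_cond, 0.0, h_prior))


def select_muin(table: FeatureTable, k: int = 4) -> SelectionResult:
    """Rank columns by mutual information, keep the top k/2 with partners.

    Descending MI ranking (ties broken toward the lower column index);
    top-ranked columns are taken one at a time together with their CSP
    pair partner until exactly ``k`` distinct columns are selected.
    """
    _check_k(k, table.n_columns)
    scores = np.array([mi_score(table.values[:, j], table.labels) for j in range(table.n_columns)])
    ranking = np.argsort(-scores, kind="stable")
    selected = _rank_to_pairs(ranking, k, table.two_m)
    return SelectionResult(
        method="muin",
        selected_columns=selected,
        transform=_onehot_transform(selected, table.n_columns),
        scores=scores,
        meta={"ranking": ranking.tolist()},
    )


# ---------------------------------------------------------------------------
# LASSO
# ---------------------------------------------------------------------------

def solve_lasso(F: np.ndarray, y: np.ndarray, lam: float) -> tuple[np.ndarray, float]:
    """Minimize ``||y - b0 - F b||^2 + lam * ||b||_1``; returns (b, b0).

    ``lam = 0`` falls back to ordinary least squares.  The intercept is
    unpenalized (labels are coded 1/2, so the fit is around their mean).
    """
    F = np.asarray(F, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64).ravel()
    if lam < 0:
        raise ValueError(f"lambda must be >= 0; got {lam}")
    if lam == 0:
        X = np.column_stack([np.ones(len(y)), F])
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        return coef[1:], float(coef[0])
    n = len(y)
    model = Lasso(alpha=lam / (2 * n), fit_intercept=True, tol=1e-12, max_iter=1_000_000)
    model.fit(F, y)
    return model.coef_.copy(), float(model.intercept_)


def lambda_max(F: np.ndarray, y: np.ndarray) -> float:
    """Smallest penalty at which the solution is entirely zero.

    For the intercept-included problem this is ``max_j |2 f_j'(y - mean(y))|``.
    """
    y = np.asarray(y, dtype=np.float64).ravel()
    return float(np.max(np.abs(2.0 * np.asarray(F).T @ (y - y.mean()))))


def default_lambda_grid(F: np.ndarray, y: np.ndarray, n_points: int = 50) -> np.ndarray:
    """Geometric grid from lambda_max down to 1e-4 * lambda_max."""
    lmax = lambda_max(F, y)
    if lmax <= 0:
        raise ValueError("labels are constant; lambda grid undefined")
    return np.geomspace(lmax, 1e-4 * lmax, n_points)


def lasso_select(
    table: FeatureTable, k: int = 4, lambda_grid: np.ndarray | None = None
) -> SelectionResult:
    """Select k columns by LASSO contribution degree ``CD_j = |beta_j|``.

    Walks the penalty grid from the largest lambda downward and stops at
    the first value whose nonzero coefficients span at least k/2 CSP
    pairs; nonzero columns are then ranked by CD (descending, ties to the
    lower index) and pair-completed to exactly k columns.  Exhausting the
    grid without k selectable columns is an error reporting the count.
    """
    _check_k(k, table.n_columns)
    F, y = table.values, table.labels.astype(float)
    grid = default_lambda_grid(F, y) if lambda_grid is None else np.sort(np.asarray(lambda_grid))[::-1]
    best_nonzero = 0
    for gi, lam in enumerate(grid):
        beta, intercept = solve_lasso(F, y, float(lam))
        cd = np.abs(beta)
        nonzero = np.flatnonzero(cd > 0)
        best_nonzero = max(best_nonzero, len(nonzero))
        n_pairs = len({min(int(j), pair_partner(int(j), table.two_m)) for j in nonzero})
        if len(nonzero) >= k and 2 * n_pairs >= k:
            ranking = np.lexsort((np.arange(len(cd)), -cd))
            selected = _rank_to_pairs(ranking, k, table.two_m, eligible=set(map(int, nonzero)))
            if len(selected) >= k:
                return SelectionResult(
                    method="lasso",
                    selected_columns=selected[:k],
                    transform=_onehot_transform(selected[:k], table.n_columns),
                    scores=cd,
                    meta={
                        "lambda": float(lam),
                        "grid_index": gi,
                        "n_nonzero": int(len(nonzero)),
                        "intercept": intercept,
                    },
                )
    raise RuntimeError(
        f"lambda grid exhausted with at most {best_nonzero} nonzero coefficients; "
        f"cannot select {k} pair-closed columns"
    )


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

def pca_transform(table: FeatureTable, k: int = 4) -> SelectionResult:
    """Top-k principal axes of the column-centered table (unsupervised).

    Rows of ``transform`` are the k leading right singular vectors,
    orthonormal; the captured variance equals the sum of the k largest
    covariance eigenvalues.  PCA returns a projection, not a column
    subset, so the CSP pairing constraint does not apply.
    """
    F = table.values
    center = F.mean(axis=0)
    Fc = F - center
    u, s, vt = np.linalg.svd(Fc, full_matrices=False)
    rank = int(np.sum(s > s[0] * max(Fc.shape) * np.finfo(float).eps)) if s.size else 0
    if k > rank:
        raise ValueError(f"k={k} exceeds the centered table's rank {rank}")
    eigenvalues = s**2 / (table.n_trials - 1)
    w = vt[:k].copy()
    # deterministic sign: largest-|loading| entry positive per axis
    idx = np.argmax(np.abs(w), axis=1)
    signs = np.sign(w[np.arange(k), idx])
    signs[signs == 0] = 1.0
    w = w * signs[:, None]
    return SelectionResult(
        method="pca",
        selected_columns=[],
        transform=w,
        scores=eigenvalues,
        meta={
            "center": center,
            "captured_variance": float(eigenvalues[:k].sum()),
            "total_variance": float(eigenvalues.sum()),
        },
    )


# ---------------------------------------------------------------------------
# SWLDA
# ---------------------------------------------------------------------------

def _rss(X: np.ndarray, y: np.ndarray) -> float:
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ coef
    return float(r @ r)


def _partial_f_p(rss_small: float, rss_big: float, n: int, p_big: int) -> float:
    """p-value of the partial F-test for one added predictor.

    df = (1, n - p_big) where ``p_big`` counts all parameters of the
    larger model including its intercept.
    """
    df2 = n - p_big
    if df2 <= 0:
        return 1.0
    if rss_big <= 0:
        return 0.0
    f = max(rss_small - rss_big, 0.0) / (rss_big / df2)
    return float(stats.f.sf(f, 1, df2))


def _design(F: np.ndarray, cols: list[int]) -> np.ndarray:
    return np.column_stack([np.ones(F.shape[0]), F[:, cols]]) if cols else np.ones((F.shape[0], 1))


def marginal_pvalues(F: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Single-predictor partial-F p-value of each column against the mean."""
    n = F.shape[0]
    rss0 = _rss(_design(F, []), y)
    return np.array(
        [_partial_f_p(rss0, _rss(_design(F, [j]), y), n, 2) for j in range(F.shape[1])]
    )


def swlda_select(
    table: FeatureTable,
    k: int = 4,
    p_enter: float = 0.1,
    p_remove: float = 0.15,
    max_steps: int = 200,
) -> SelectionResult:
    """Stepwise forward/backward selection by partial F-tests, capped at k.

    Forward step: add the candidate with the smallest partial-F p-value if
    it is below ``p_enter``.  Backward step: drop any included feature
    whose p-value (in the current model) exceeds ``p_remove``, worst
    first.  Iterates until k features are included or no move is legal;
    the stepwise trace and which termination fired are recorded in
    ``meta``.  The final set is pair-completed: partners are added, whole
    pairs ranked by their best member's significance, refilled from the
    marginal ranking if the stepwise loop stalled early, and truncated to
    exactly k.  If nothing ever enters, an empty selection is returned
    with ``meta['empty'] = True`` (the caller decides the fallback).
    """
    _check_k(k, table.n_columns)
    F, y = table.values, table.labels.astype(float)
    n = F.shape[0]
    if n <= k + 1:
        raise ValueError(f"need more than k+1={k + 1} trials; got {n}")
    included: list[int] = []
    entry_p: dict[int, float] = {}
    trace: list[tuple[str, int, float]] = []
    termination = "stalled"
    for _ in range(max_steps):
        if len(included) >= k:
            termination = "reached_k"
            break
        moved = False
        rss_cur = _rss(_design(F, included), y)
        # forward
        cand_p = {}
        for j in range(F.shape[1]):
            if j in included:
                continue
            rss_j = _rss(_design(F, included + [j]), y)
            cand_p[j] = _partial_f_p(rss_cur, rss_j, n, len(included) + 2)
        if cand_p:
            best = min(cand_p, key=lambda j: (cand_p[j], j))
            if cand_p[best] < p_enter:
                included.append(best)
                entry_p[best] = cand_p[best]
                trace.append(("add", best, cand_p[best]))
                moved = True
        # backward
        while len(included) > 1:
            rss_full = _rss(_design(F, included), y)
            drop_p = {}
            for j in included:
                rest = [c for c in included if c != j]
                drop_p[j] = _partial_f_p(_rss(_design(F, rest), y), rss_full, n, len(included) + 1)
            worst = max(drop_p, key=lambda j: (drop_p[j], -j))
            if drop_p[worst] > p_remove:
                included.remove(worst)
                trace.append(("remove", worst, drop_p[worst]))
                moved = True
            else:
                break
        if not moved:
            break
    else:
        termination = "max_steps"

    scores = marginal_pvalues(F, y)
    meta = {
        "trace": trace,
        "termination": termination,
        "p_enter": p_enter,
        "p_remove": p_remove,
        "entry_p": dict(entry_p),
    }
    if not included:
        meta["empty"] = True
        return SelectionResult(
            method="swlda",
            selected_columns=[],
            transform=np.zeros((0, table.n_columns)),
            scores=scores,
            meta=meta,
        )

    # pair completion: whole pairs ranked by best member significance,
    # refilled from the marginal ranking, truncated to exactly k
    pair_score: dict[int, float] = {}
    for col in included:
        key = min(col, pair_partner(col, table.two_m))
        p = entry_p.get(col, 1.0)
        pair_score[key] = min(pair_score.get(key, np.inf), p)
    pairs = sorted(pair_score, key=lambda c: (pair_score[c], c))
    if len(pairs) < k // 2:
        # refill from marginal significance, lowest p first, new pairs only
        for j in np.lexsort((np.arange(len(scores)), scores)):
            key = min(int(j), pair_partner(int(j), table.two_m))
            if key not in pair_score:
                pairs.append(key)
                pair_score[key] = np.inf
            if len(pairs) >= k // 2:
                break
    selected = []
    for key in pairs[: k // 2]:
        selected.extend([key, pair_partner(key, table.two_m)])
    meta["n_entered"] = len(included)
    return SelectionResult(
        method="swlda",
        selected_columns=selected,
        transform=_onehot_transform(selected, table.n_columns),
        scores=scores,
        meta=meta,
    )


def marginal_pair_selection(table: FeatureTable, k: int = 4) -> SelectionResult:
    """Fallback selector: k/2 pairs ranked by marginal partial-F p-value."""
    _check_k(k, table.n_columns)
    scores = marginal_pvalues(table.values, table.labels.astype(float))
    ranking = np.lexsort((np.arange(len(scores)), scores))
    selected = _rank_to_pairs(ranking, k, table.two_m)
    return SelectionResult(
        method="marginal",
        selected_columns=selected,
        transform=_onehot_transform(selected, table.n_columns),
        scores=scores,
        meta={"fallback": True},
    )


def _check_k(k: int, n_columns: int) -> None:
    if k % 2 != 0 or k < 2:
        raise ValueError(f"k must be a positive even number; got {k}")
    if k > n_columns:
        raise ValueError(f"k={k} exceeds {n_columns} columns")
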