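"""Independent oracles used by the selector and acceptance tests.

Each recomputes an expected quantity by a route disjoint from the package
implementation: quadrature on true densities, bound-constrained quadratic
programming, exhaustive subset enumeration.
"""

import numpy as np
from scipy import integrate, optimize, stats


def gaussian_mixture_mi_bits(mu1: float, mu2: float, sd: float = 1.0, p1: float = 0.5) -> float:
    """MI between the class label and v ~ equal-variance Gaussian mixture,
    by numerical integration of the true densities."""
    p2 = 1 - p1

    def integrand(v):
        f1 = p1 * stats.norm.pdf(v, mu1, sd)
        f2 = p2 * stats.norm.pdf(v, mu2, sd)
        tot = f1 + f2
        out = 0.0
        for f in (f1, f2):
            if f > 0:
                w = f / tot
                out += -w * np.log2(w) * tot
        return out

    lo = min(mu1, mu2) - 10 * sd
    hi = max(mu1, mu2) + 10 * sd
    h_cond, _ = integrate.quad(integrand, lo, hi, limit=400)
    h_prior = -(p1 * np.log2(p1) + p2 * np.log2(p2))
    return h_prior - h_cond


def qp_lasso(F: np.ndarray, y: np.ndarray, lam: float) -> np.ndarray:
    """Solve min ||y - b0 - F b||^2 + lam ||b||_1 by bound-constrained QP.

    Intercept profiled out by centering; beta split into positive and
    negative parts, giving a smooth quadratic over the nonnegative orthant
    solved with L-BFGS-B.
    """
    F = np.asarray(F, float)
    y = np.asarray(y, float).ravel()
    fc = F - F.mean(axis=0)
    yc = y - y.mean()
    p = F.shape[1]
    gram = fc.T @ fc
    fty = fc.T @ yc

    def objective(z):
        beta = z[:p] - z[p:]
        r = gram @ beta - fty
        obj = beta @ gram @ beta - 2 * fty @ beta + yc @ yc + lam * z.sum()
        grad = np.concatenate([2 * r + lam, -2 * r + lam])
        return obj, grad

    res = optimize.minimize(
        objective,
        np.zeros(2 * p),
        jac=True,
        method="L-BFGS-B",
        bounds=[(0, None)] * 2 * p,
        options={"maxiter": 50000, "ftol": 1e-18, "gtol": 1e-12},
    )
    return res.x[:p] - res.x[p:]


def stepwise_entry_order(F: np.ndarray, y: np.ndarray, p_enter: float, p_remove: float,
                         k: int) -> list[int]:
    """Brute-force forward/backward stepwise on a numeric response.

    At each forward step every candidate's partial F-test is evaluated
    from explicit RSS computations; backward steps re-test every included
    column.  Returns the order in which columns entered (net of removals).
    """

    def rss(cols):
        X = np.column_stack([np.ones(len(y))] + [F[:, c] for c in cols])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ beta
        return float(r @ r)

    def p_value(rss_small, rss_big, p_big):
        df2 = len(y) - p_big
        if rss_big <= 0:
            return 0.0
        fstat = max(rss_small - rss_big, 0.0) / (rss_big / df2)
        return float(stats.f.sf(fstat, 1, df2))

    included: list[int] = []
    while len(included) < k:
        moved = False
        base = rss(included)
        cands = {
            j: p_value(base, rss(included + [j]), len(included) + 2)
            for j in range(F.shape[1])
            if j not in included
        }
        if cands:
            best = min(cands, key=lambda j: (cands[j], j))
            if cands[best] < p_enter:
                included.append(best)
                moved = True
        while len(included) > 1:
            full = rss(included)
            drops = {
                j: p_value(rss([c for c in included if c != j]), full, len(included) + 1)
                for j in included
            }
            worst = max(drops, key=lambda j: (drops[j], -j))
            if drops[worst] > p_remove:
                included.remove(worst)
                moved = True
            else:
                break
        if not moved:
            break
    return included
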