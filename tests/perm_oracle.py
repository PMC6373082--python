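"""Fixed-margin permutation oracle for the trend test.

Independent of the analytic implementation: the trend statistic is
recomputed from raw per-item scores and the null is sampled by permuting
the row assignment of the N items while holding both margins fixed.
"""

import numpy as np


def permutation_T(row_ko, row_wt, scores, n_perm, seed):
    """Observed centered statistic and its permutation sample."""
    row_ko = np.asarray(row_ko, float)
    row_wt = np.asarray(row_wt, float)
    scores = np.asarray(scores, float)
    c = (row_ko + row_wt).astype(int)
    items = np.repeat(scores, c)
    r1 = int(row_ko.sum())
    n = len(items)
    centering = r1 * items.sum() / n
    t_obs = float((scores * row_ko).sum() - centering)
    rng = np.random.default_rng(seed)
    mat = rng.permuted(np.tile(items, (n_perm, 1)), axis=1)
    t_perm = mat[:, :r1].sum(axis=1) - centering
    return t_obs, t_perm


def permutation_p(row_ko, row_wt, scores, n_perm=100_000, seed=0):
    """Two-sided doubled-tail mid-p permutation p-value."""
    t_obs, t_perm = permutation_T(row_ko, row_wt, scores, n_perm, seed)
    tol = 1e-9 * max(1.0, abs(t_obs))
    eq = np.count_nonzero(np.abs(t_perm - t_obs) <= tol)
    upper = (np.count_nonzero(t_perm > t_obs + tol) + 0.5 * eq) / n_perm
    lower = (np.count_nonzero(t_perm < t_obs - tol) + 0.5 * eq) / n_perm
    return min(1.0, 2.0 * min(upper, lower))


def table_grid():
    """Deterministic grid of 2xk tables: k in {2,3,4}, N in {12,20,40},
    balanced / skewed / edge-loaded margins, integer scores 0..k-1."""
    tables = []
    for k in (2, 3, 4):
        for n_tot in (12, 20, 40):
            half = n_tot // 2
            ko = np.full(k, half // k)
            wt = np.full(k, half // k)
            tables.append((ko, wt))
            ko = np.arange(1, k + 1, dtype=float)
            wt = np.arange(k, 0, -1, dtype=float)
            ko = np.round(ko * half / ko.sum()).astype(int)
            wt = np.round(wt * half / wt.sum()).astype(int)
            tables.append((ko, wt))
            ko = np.zeros(k, int)
            ko[-1] = n_tot // 4
            wt = np.full(k, max(1, (n_tot - ko.sum()) // k))
            tables.append((ko, wt))
    return tables
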