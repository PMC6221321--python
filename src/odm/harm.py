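"""Association of opioid-induced DE genes with drug-harm scores.

For each opioid DEG and each harm effect, the gene's cross-drug response
vector G_j (smoothed log2 ratio per drug at time point j) is tested against
the effect's score vector S_i with both a Pearson correlation and a
quadratic polynomial regression (expression on score); the pair is
significant when either test's p-value is below 0.05 (nominal, no
multiplicity correction).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AssociationResult",
    "build_drug_vector",
    "pearson_test",
    "quadratic_regression_test",
    "associate",
    "read_harm_scores",
    "validate_harm_table",
]

_P_FLOOR = np.finfo(float).tiny


def read_harm_scores(path) -> pd.DataFrame:
    """Harm-score CSV: effects (rows) x drugs (columns)."""
    df = pd.read_csv(path, index_col=0, comment="#")
    return df.astype(float)


def validate_harm_table(harm: pd.DataFrame, drugs: list[str]) -> None:
    missing = [d for d in drugs if d not in harm.columns]
    if missing:
        raise ValueError(f"harm-score table is missing drugs: {missing}")


def build_drug_vector(fits: dict, gene: str, time_point: float) -> np.ndarray:
    """G_j: per-drug smoothed log2 ratio of ``gene`` at ``time_point``,
    ordered as the keys of ``fits`` (drug -> DrugFits)."""
    out = []
    for drug, fit in fits.items():
        if fit is None:
            raise KeyError(f"no fit available for drug {drug!r}")
        j = int(np.argmin(np.abs(fit.grid - time_point)))
        if abs(fit.grid[j] - time_point) > 1e-6:
            raise ValueError(f"time point {time_point} not on the evaluation grid")
        i = fit.index_of(gene)
        out.append(fit.log2_ratio[i, j])
    return np.asarray(out, float)


def pearson_test(x: np.ndarray, y: np.ndarray) -> tuple[float, float, bool]:
    """Sample Pearson r with the two-sided p from the exact t transform
    ``t = r sqrt((n-2)/(1-r^2))`` on n-2 df.

    Returns ``(r, p, degenerate)``; a zero-variance input gives
    ``(0, 1, True)``.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    sx = x - x.mean()
    sy = y - y.mean()
    vx = float(sx @ sx)
    vy = float(sy @ sy)
    if vx <= 0 or vy <= 0:
        return 0.0, 1.0, True
    r = float(np.clip(sx @ sy / np.sqrt(vx * vy), -1.0, 1.0))
    if abs(r) >= 1.0:
        return r, float(_P_FLOOR), False
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * stats.t.sf(abs(t), n - 2)
    return r, float(max(p, _P_FLOOR)), False


def quadratic_regression_test(x: np.ndarray, y: np.ndarray) -> tuple[float, bool]:
    """F-test of the quadratic regression y = b0 + b1 x + b2 x^2 against the
    intercept-only model (F on (2, n-3) df).

    Returns ``(p, degenerate)``; fewer than 3 distinct x values (collinear
    design) gives ``(1, True)``.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = x.size
    if n < 5:
        raise ValueError("need at least 5 observations for the quadratic F-test")
    if np.unique(x).size <= 2:
        return 1.0, True
    X = np.column_stack([np.ones(n), x, x * x])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    rss = float(resid @ resid)
    tss = float(((y - y.mean()) ** 2).sum())
    if tss <= 0:
        return 1.0, True
    df1, df2 = 2, n - 3
    if rss <= 1e-12 * tss:
        return float(_P_FLOOR), False
    f = ((tss - rss) / df1) / (rss / df2)
    p = float(stats.f.sf(f, df1, df2))
    return max(p, float(_P_FLOOR)), False


@dataclass
class AssociationResult:
    gene: str
    effect: str
    time_point: float
    pearson_r: float
    pearson_p: float
    quad_p: float
    significant: bool
    degenerate: bool = False


def associate(
    deg_calls: pd.DataFrame,
    fits: dict,
    harm_table: pd.DataFrame,
    alpha: float = 0.05,
    all_timepoints: bool = False,
    time_points: list[float] | None = None,
) -> pd.DataFrame:
    """Test every (opioid DEG, harm effect) pair.

    Each DEG is tested at its own peak-response time ``t_max`` (or at every
    observed post-exposure time with ``all_timepoints=True``).  The drug
    order of G_j follows the harm table's columns.  Significance is the
    either-test rule at the nominal ``alpha``.
    """
    drugs = [d for d in harm_table.columns]
    missing = [d for d in drugs if d not in fits]
    if missing:
        raise KeyError(f"no fits for drugs required by the harm table: {missing}")
    ordered_fits = {d: fits[d] for d in drugs}
    de = deg_calls.loc[deg_calls["is_de"]]
    rows = []
    for gene, rec in de.iterrows():
        if all_timepoints:
            tps = list(time_points or [1.0, 2.0, 4.0, 8.0])
        else:
            tps = [float(rec["t_max"])]
        for tp in tps:
            g_vec = build_drug_vector(ordered_fits, gene, tp)
            for effect in harm_table.index:
                s_vec = harm_table.loc[effect].to_numpy(float)
                r, p_r, degen_r = pearson_test(s_vec, g_vec)
                p_q, degen_q = quadratic_regression_test(s_vec, g_vec)
                degen = degen_r and degen_q
                sig = (not degen) and min(p_r, p_q) < alpha
                rows.append((gene, effect, tp, r, p_r, p_q, sig, degen))
    return pd.DataFrame(
        rows,
        columns=[
            "gene", "effect", "time_point", "pearson_r",
            "pearson_p", "quad_p", "significant", "degenerate",
        ],
    )
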