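"""Downstream statistics: scaling, PCA, Welch tests with BH-FDR, RT-logD.

The multivariate view min-max scales each metabolite to [0, 1] and runs a
prcomp-style PCA (column centering, no variance scaling, SVD).  The
univariate view runs per-metabolite two-sample Welch t-tests between a
control and a treatment group, corrects p-values with the
Benjamini-Hochberg step-up, and reports the top-k significant
metabolites.  A small helper regresses lipophilicity (logD) on HILIC
retention time for panel characterization.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as _sps

__all__ = [
    "minmax_scale",
    "PCAResult",
    "pca",
    "welch_t",
    "bh_adjust",
    "differential",
    "top_k",
    "rt_logd_fit",
]


def minmax_scale(df: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Scale each column to [0, 1] over its non-missing values.

    Constant columns map to all zeros and are returned in the flag list.
    Missing values stay missing.
    """
    out = df.copy().astype(float)
    constant: list[str] = []
    for col in out.columns:
        v = out[col]
        lo, hi = v.min(), v.max()
        if not np.isfinite(hi - lo) or hi == lo:
            out[col] = np.where(v.notna(), 0.0, np.nan)
            constant.append(col)
        else:
            out[col] = (v - lo) / (hi - lo)
    return out, constant


@dataclass
class PCAResult:
    """Scores, loadings and explained-variance fractions of a PCA."""

    scores: pd.DataFrame  # samples x components
    loadings: pd.DataFrame  # variables x components
    explained_variance: np.ndarray  # per-component variance
    explained_fraction: np.ndarray  # fractions summing to 1


def pca(df: pd.DataFrame, center: bool = True) -> PCAResult:
    """Principal component analysis via SVD, prcomp-style.

    Columns are centered (no variance scaling); columns with any missing
    value are dropped listwise before decomposition.  Components are
    ordered by decreasing variance; explained-variance fractions sum to 1.
    """
    if len(df) < 2:
        raise ValueError("PCA needs at least 2 samples")
    complete = df.dropna(axis=1)
    x = complete.to_numpy(float)
    if center:
        x = x - x.mean(axis=0)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    k = min(x.shape)
    scores = u[:, :k] * s[:k]
    var = (s[:k] ** 2) / (x.shape[0] - 1)
    frac = var / var.sum() if var.sum() > 0 else var
    comp = [f"PC{i + 1}" for i in range(k)]
    return PCAResult(
        scores=pd.DataFrame(scores, index=df.index, columns=comp),
        loadings=pd.DataFrame(vt[:k].T, index=complete.columns, columns=comp),
        explained_variance=var,
        explained_fraction=frac,
    )


def welch_t(a: Sequence[float], b: Sequence[float]) -> tuple[float, float, float]:
    """Two-sample unequal-variance (Welch) t-test, two-sided.

    Returns (t, Welch-Satterthwaite df, p).  With both groups constant
    and equal the statistic is 0 with p = 1; with zero within-group
    variance but different means, p underflows toward 0 (reported as 0.0,
    df as the pooled-constant limit n_a + n_b - 2).
    """
    x, y = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(x), len(y)
    if na < 2 or nb < 2:
        raise ValueError("each group needs at least 2 values")
    va, vb = x.var(ddof=1), y.var(ddof=1)
    se2 = va / na + vb / nb
    diff = x.mean() - y.mean()
    if se2 == 0:
        if diff == 0:
            return 0.0, float(na + nb - 2), 1.0
        return float(np.sign(diff) * np.inf), float(na + nb - 2), 0.0
    t = diff / np.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2.0 * _sps.t.sf(abs(t), df)
    return float(t), float(df), float(min(p, 1.0))


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    q(i) = min over j >= i (ascending order) of p(j) * m / j, clipped at 1.
    """
    p = np.asarray(pvalues, float)
    if p.size and (np.nanmin(p) < 0 or np.nanmax(p) > 1):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty_like(adjusted)
    out[order] = adjusted
    return out


def differential(
    matrix: pd.DataFrame,
    groups: pd.Series,
    control: str,
    treatment: str,
    min_n: int = 3,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-metabolite Welch tests between two groups with BH correction.

    ``matrix`` is samples x metabolites, ``groups`` the per-sample group
    label.  Metabolites with fewer than ``min_n`` non-missing values in
    either group are skipped (flagged in the ``skipped`` column and left
    out of the FDR family).  Returns one row per metabolite with group
    means/SDs, t, df, raw and adjusted p, and a significance flag.
    """
    a_idx = groups[groups == control].index
    b_idx = groups[groups == treatment].index
    rows = []
    for col in matrix.columns:
        a = matrix.loc[a_idx, col].dropna().to_numpy(float)
        b = matrix.loc[b_idx, col].dropna().to_numpy(float)
        base = {
            "metabolite": col,
            "mean_control": a.mean() if len(a) else np.nan,
            "sd_control": a.std(ddof=1) if len(a) > 1 else np.nan,
            "mean_treatment": b.mean() if len(b) else np.nan,
            "sd_treatment": b.std(ddof=1) if len(b) > 1 else np.nan,
            "n_control": len(a),
            "n_treatment": len(b),
        }
        if len(a) < min_n or len(b) < min_n:
            rows.append({**base, "t": np.nan, "df": np.nan, "p": np.nan,
                         "skipped": True})
            continue
        t, dof, p = welch_t(a, b)
        rows.append({**base, "t": t, "df": dof, "p": p, "skipped": False})
    res = pd.DataFrame(rows).set_index("metabolite")
    tested = res.index[~res["skipped"]]
    res["p_adj"] = np.nan
    if len(tested):
        res.loc[tested, "p_adj"] = bh_adjust(res.loc[tested, "p"].to_numpy())
    res["significant"] = res["p_adj"] < alpha
    return res


def top_k(results: pd.DataFrame, k: int = 10,
          include: Sequence[str] = ()) -> pd.DataFrame:
    """The k most significant metabolites (lowest adjusted p).

    Only metabolites with adjusted p below the significance threshold
    qualify; ties on adjusted p break by |t| descending, then name.
    ``include`` force-keeps named metabolites regardless of significance
    (for displaying a borderline compound alongside the hits).
    """
    res = results.copy()
    eligible = res[res["significant"] | res.index.isin(include)].copy()
    eligible["_abs_t"] = eligible["t"].abs()
    eligible = eligible.sort_values(
        by=["p_adj", "_abs_t", "metabolite"],
        ascending=[True, False, True],
        kind="mergesort",
    )
    return eligible.drop(columns="_abs_t").head(k)


def rt_logd_fit(
    rt: Sequence[float],
    logd: Sequence[float],
    names: Sequence[str] | None = None,
    exclude: Sequence[str] = (),
) -> tuple[float, float, float]:
    """OLS of logD on retention time; returns (slope, intercept, r^2).

    Named outliers in ``exclude`` are removed before the fit; at least 3
    points must remain.  r^2 is the squared Pearson correlation.
    """
    rt = np.asarray(rt, float)
    logd = np.asarray(logd, float)
    if names is not None and len(exclude):
        keep = ~np.isin(np.asarray(names, dtype=object), np.asarray(exclude, dtype=object))
        rt, logd = rt[keep], logd[keep]
    if len(rt) < 3:
        raise ValueError("need at least 3 points after exclusions")
    res = _sps.linregress(rt, logd)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)
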