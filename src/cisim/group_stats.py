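"""Rank-based group statistics and the study's standard contrasts.

Paired Wilcoxon signed-rank tests compare surgical conditions per stimulus
frequency, Mann-Whitney U compares the shallow (5Ch) and deep (6Ch)
insertion groups, and ordinary least squares relates insertion depth and
tonotopic position to hearing loss.  Small samples use exact permutation
null distributions (all sign flips for Wilcoxon, all group labelings for
Mann-Whitney, ties mid-ranked); larger samples use the normal
approximation with continuity and tie corrections.  Per-frequency tests
are reported at alpha = 0.05 without multiple-testing correction, matching
the study's analysis; Holm adjustment is available behind a flag.
"""

from __future__ import annotations

import warnings
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats as sps

ALPHA = 0.05
WILCOXON_EXACT_MAX_N = 15
MANNWHITNEY_EXACT_MAX_N = 12

#: the stimulus-lattice cell the study labels "5.6 kHz" (2 kHz * 2^(6/4))
LATTICE_5P6_KHZ = 2000.0 * 2.0 ** (6 / 4)


def _two_sided(p_le: float, p_ge: float) -> float:
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def wilcoxon_signed_rank(
    paired_diffs, zero_method: str = "wilcox", exact_max_n: int = WILCOXON_EXACT_MAX_N
) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired differences.

    Returns ``(W+, p)`` where ``W+`` is the sum of ranks of positive
    differences.  Zero differences are dropped before ranking
    (``zero_method='wilcox'``, the default) or kept and signed-ranked with
    the Pratt rule (``'pratt'``).  For ``n <= exact_max_n`` the p-value is
    computed from the exact sign-flip distribution of the observed rank
    magnitudes (ties therefore handled exactly); above that, a normal
    approximation with tie and continuity corrections is used.
    """
    d = np.asarray(paired_diffs, dtype=float)
    if d.size == 0:
        raise ValueError("need at least one paired difference")
    if zero_method == "wilcox":
        d = d[d != 0]
    elif zero_method != "pratt":
        raise ValueError("zero_method must be 'wilcox' or 'pratt'")
    if d.size == 0 or np.all(d == 0):
        warnings.warn("all paired differences are zero; p = 1", stacklevel=2)
        return 0.0, 1.0
    ranks = sps.rankdata(np.abs(d))
    if zero_method == "pratt":
        keep = d != 0
        ranks, d = ranks[keep], d[keep]
    w_plus = float(ranks[d > 0].sum())
    n = d.size

    if n <= exact_max_n:
        # exact distribution of W+ over all 2^n sign assignments, via the
        # generating polynomial in half-rank units (midranks end in .0/.5)
        r2 = np.rint(ranks * 2).astype(int)
        total = int(r2.sum())
        counts = np.zeros(total + 1)
        counts[0] = 1.0
        for r in r2:
            counts[r:] = counts[r:] + counts[: counts.size - r]
        counts /= 2.0**n
        w2 = int(round(w_plus * 2))
        p_le = float(counts[: w2 + 1].sum())
        p_ge = float(counts[w2:].sum())
        return w_plus, _two_sided(p_le, p_ge)

    mean = n * (n + 1) / 4.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    var = n * (n + 1) * (2 * n + 1) / 24.0 - np.sum(tie_counts**3 - tie_counts) / 48.0
    if var <= 0:
        return w_plus, 1.0
    z = (w_plus - mean - 0.5 * np.sign(w_plus - mean)) / np.sqrt(var)
    return w_plus, float(min(1.0, 2.0 * sps.norm.sf(abs(z))))


def mann_whitney_u(
    group_a, group_b, exact_max_total: int = MANNWHITNEY_EXACT_MAX_N
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test for two independent groups.

    Returns ``(U_a, p)`` with ``U_a`` the U statistic of ``group_a``.
    For ``n + m <= exact_max_total`` the exact permutation distribution is
    enumerated over all group labelings (ties mid-ranked); otherwise the
    normal approximation with tie and continuity corrections is used.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    n, m = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    u_a = float(ranks[:n].sum() - n * (n + 1) / 2.0)

    if n + m <= exact_max_total:
        sums = np.array(
            [sum(ranks[list(idx)]) for idx in combinations(range(n + m), n)]
        )
        us = sums - n * (n + 1) / 2.0
        n_tot = comb(n + m, n)
        p_le = float(np.sum(us <= u_a + 1e-9)) / n_tot
        p_ge = float(np.sum(us >= u_a - 1e-9)) / n_tot
        return u_a, _two_sided(p_le, p_ge)

    mean = n * m / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    nm = n + m
    tie_term = np.sum(tie_counts**3 - tie_counts) / (nm * (nm - 1))
    var = n * m / 12.0 * (nm + 1 - tie_term)
    if var <= 0:
        return u_a, 1.0
    z = (u_a - mean - 0.5 * np.sign(u_a - mean)) / np.sqrt(var)
    return u_a, float(min(1.0, 2.0 * sps.norm.sf(abs(z))))


def linear_regression_test(x, y) -> tuple[float, float, float, float]:
    """Ordinary least squares with a t-test on the slope.

    Returns ``(slope, intercept, r_squared, p_slope)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need at least 3 paired observations")
    if np.ptp(x) == 0:
        raise ValueError("x must not be constant")
    if np.ptp(y) == 0:
        # degenerate flat response: slope 0, no variance explained
        return 0.0, float(y[0]), 0.0, 1.0
    res = sps.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue**2), float(res.pvalue)


# ---------------------------------------------------------------------------
# study contrasts
# ---------------------------------------------------------------------------


def _holm(pvals: np.ndarray) -> np.ndarray:
    order = np.argsort(pvals)
    adj = np.empty_like(pvals)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (pvals.size - rank) * pvals[idx])
        adj[idx] = min(1.0, running)
    return adj


def _paired_by_frequency(
    thresholds: pd.DataFrame, cond_a: str, cond_b: str, drop_censored: bool
) -> list[dict]:
    rows = []
    for f, sub in thresholds.groupby("frequency_hz"):
        piv = sub.pivot_table(index="ear", columns="condition", values="threshold_db")
        cens = sub.pivot_table(index="ear", columns="condition", values="censored")
        if cond_a not in piv.columns or cond_b not in piv.columns:
            continue
        ok = piv[[cond_a, cond_b]].notna().all(axis=1)
        if drop_censored:
            ok &= ~cens[[cond_a, cond_b]].astype(bool).any(axis=1)
        diffs = (piv.loc[ok, cond_b] - piv.loc[ok, cond_a]).to_numpy()
        if diffs.size == 0:
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            stat, p = wilcoxon_signed_rank(diffs)
        rows.append(
            {
                "contrast": f"{cond_a}_vs_{cond_b}",
                "frequency_hz": float(f),
                "test": "wilcoxon",
                "statistic": stat,
                "p": p,
                "n": int(diffs.size),
            }
        )
    return rows


def run_study_contrasts(
    thresholds: pd.DataFrame,
    shifts: pd.DataFrame,
    metrics: pd.DataFrame | None = None,
    alpha: float = ALPHA,
    holm: bool = False,
    drop_censored: bool = True,
    ts_frequency_hz: float = LATTICE_5P6_KHZ,
) -> pd.DataFrame:
    """Run the study's statistical comparisons on analysed cohort tables.

    * per-frequency paired Wilcoxon: initial vs cochleostomy and initial vs
      inserted thresholds;
    * per-frequency Mann-Whitney: 5Ch vs 6Ch insertion threshold shifts;
    * OLS regressions (if ``metrics`` with columns ``ear, depth_ch1_um,
      cf_ch1_hz`` is given): Ch1 depth vs per-ear maximal TS, and Ch1
      characteristic frequency vs TS at the 5.6 kHz lattice cell.

    Returns a tidy table (contrast, frequency_hz, test, statistic, p, n,
    significant).  No multiple-testing correction by default.
    """
    if "group" not in shifts.columns:
        raise ValueError("shifts table must carry group labels")
    rows: list[dict] = []
    rows += _paired_by_frequency(thresholds, "initial", "cochleostomy", drop_censored)
    rows += _paired_by_frequency(thresholds, "initial", "inserted", drop_censored)

    for f, sub in shifts.groupby("frequency_hz"):
        sub = sub[~sub["censored"]] if drop_censored else sub
        a = sub.loc[sub["group"] == "5Ch", "ts_db"].to_numpy()
        b = sub.loc[sub["group"] == "6Ch", "ts_db"].to_numpy()
        if a.size == 0 or b.size == 0:
            continue
        stat, p = mann_whitney_u(a, b)
        rows.append(
            {
                "contrast": "ts_5ch_vs_6ch",
                "frequency_hz": float(f),
                "test": "mann_whitney",
                "statistic": stat,
                "p": p,
                "n": int(a.size + b.size),
            }
        )

    if metrics is not None:
        from .cap_pipeline import ear_max_ts

        summary = ear_max_ts(shifts).merge(metrics, on="ear", how="inner")
        if len(summary) >= 3 and summary["depth_ch1_um"].nunique() > 1:
            slope, _, r2, p = linear_regression_test(
                summary["depth_ch1_um"], summary["max_ts_db"]
            )
            rows.append(
                {
                    "contrast": "depth_vs_max_ts",
                    "frequency_hz": np.nan,
                    "test": "ols_slope",
                    "statistic": slope,
                    "p": p,
                    "n": len(summary),
                }
            )
        near = shifts.loc[
            np.isclose(shifts["frequency_hz"], ts_frequency_hz, rtol=1e-6)
        ]
        near = near[~near["censored"]] if drop_censored else near
        joined = near.merge(metrics, on="ear", how="inner")
        if len(joined) >= 3 and joined["cf_ch1_hz"].nunique() > 1:
            slope, _, r2, p = linear_regression_test(joined["cf_ch1_hz"], joined["ts_db"])
            rows.append(
                {
                    "contrast": "cf_ch1_vs_ts_5p6khz",
                    "frequency_hz": float(ts_frequency_hz),
                    "test": "ols_slope",
                    "statistic": slope,
                    "p": p,
                    "n": len(joined),
                }
            )

    table = pd.DataFrame(rows)
    if table.empty:
        return pd.DataFrame(
            columns=["contrast", "frequency_hz", "test", "statistic", "p", "n", "significant"]
        )
    if holm:
        for contrast, idx in table.groupby("contrast").groups.items():
            table.loc[idx, "p"] = _holm(table.loc[idx, "p"].to_numpy())
    table["significant"] = table["p"] < alpha
    return table
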