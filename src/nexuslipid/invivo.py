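"""Two-group differential expression with empirical-Bayes-moderated t,
DEG calling, and the multi-parametric Comprehensive_Score target ranking.

The variance prior (d0, s0^2) is fitted by moment-matching a scaled-F
distribution to the per-gene residual variances on the log scale; the
moderated variance is s~2_g = (d0*s0^2 + d_g*s2_g)/(d0 + d_g) and the
moderated t is referred to a t distribution on d0 + d_g df.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)

D0_CAP = 1e6  # "infinite" prior df fallback: all genes shrunk to s0^2


def _trigamma(x):
    return special.polygamma(1, x)


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton iteration on a monotone map)."""
    if y <= 0:
        return np.inf
    x = 0.5 + 1.0 / y  # standard starting value
    for _ in range(50):
        tri = _trigamma(x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def fit_variance_prior(s2: np.ndarray, df: int) -> tuple[float, float]:
    """Moment-match (d0, s0^2) to the observed residual variances.

    Uses the log-variance moments: with z = log(s2),
    e = z - digamma(df/2) + log(df/2) satisfies
    var(e) = trigamma(df/2) + trigamma(d0/2) and
    mean(e) = log(s0^2) + digamma(d0/2) - log(d0/2).
    When the moment system has no positive d0 solution (observed variance
    no larger than the sampling variance), d0 falls back to D0_CAP.
    """
    s2 = np.asarray(s2, dtype=float)
    positive = s2[s2 > 0]
    if len(positive) == 0:
        raise ValueError("fit_variance_prior: all residual variances are zero")
    z = np.log(positive)
    if np.ptp(z) < 1e-8:
        # degenerate case: identical variances shrink exactly to themselves
        return D0_CAP, float(np.mean(positive))
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(np.mean(e))
    evar = float(np.var(e, ddof=1))
    excess = evar - float(_trigamma(df / 2.0))
    if excess <= 0:
        d0 = D0_CAP
        log.info("variance prior: no positive-df solution; using d0 cap")
    else:
        d0 = 2.0 * _trigamma_inverse(excess)
        d0 = min(d0, D0_CAP)
    s0_sq = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0_sq


def differential_expression(matrix: pd.DataFrame, groups: pd.Series,
                            prior_df: float | None = None,
                            assume_log2: bool = True) -> pd.DataFrame:
    """Per-gene two-group linear model with moderated t statistics.

    ``matrix`` is genes x samples on the log2 scale (linear input is
    auto-log2'ed with a +1 offset when ``assume_log2`` is False);
    ``groups`` holds exactly two labels, with "model"/"case"/1 treated as
    the test group when present, else the lexicographically later label.
    ``prior_df=0`` disables moderation (ordinary pooled t); None fits the
    prior from the data.  Zero-variance genes get p = 1 (logged).
    """
    groups = groups.loc[matrix.columns]
    levels = sorted(groups.unique())
    if len(levels) != 2:
        raise ValueError(f"differential_expression: need exactly 2 groups, got {levels}")
    for preferred in ("model", "case", 1, "1"):
        if preferred in levels:
            test_level = preferred
            break
    else:
        test_level = levels[1]
    ctrl_level = [l for l in levels if l != test_level][0]

    test_cols = groups[groups == test_level].index
    ctrl_cols = groups[groups == ctrl_level].index
    n1, n0 = len(test_cols), len(ctrl_cols)
    if n1 < 2 or n0 < 2:
        raise ValueError("differential_expression: need >= 2 samples per group")

    data = matrix
    if not assume_log2:
        log.info("linear-scale input: applying log2(x + 1)")
        data = np.log2(matrix + 1.0)

    m1 = data[test_cols].mean(axis=1)
    m0 = data[ctrl_cols].mean(axis=1)
    log2fc = m1 - m0
    lin = 2.0 ** data
    fc_mvsc = lin[test_cols].mean(axis=1) / lin[ctrl_cols].mean(axis=1)

    v1 = data[test_cols].var(axis=1, ddof=1)
    v0 = data[ctrl_cols].var(axis=1, ddof=1)
    df_resid = n1 + n0 - 2
    s2 = ((n1 - 1) * v1 + (n0 - 1) * v0) / df_resid
    overall_var = data.var(axis=1, ddof=1)

    s2_arr = s2.to_numpy()
    zero_var = s2_arr <= 0
    if zero_var.any():
        log.info("%d zero-variance gene(s): p set to 1", int(zero_var.sum()))

    if prior_df == 0:
        d0, s0_sq = 0.0, np.nan
        s2_mod = s2_arr
        t_df = df_resid
    elif not (s2_arr > 0).any():
        # every gene is constant within groups: nothing to moderate
        d0, s0_sq = D0_CAP, 0.0
        s2_mod = s2_arr
        t_df = df_resid
    else:
        if prior_df is None:
            d0, s0_sq = fit_variance_prior(s2_arr, df_resid)
        else:
            d0 = float(prior_df)
            _, s0_sq = fit_variance_prior(s2_arr, df_resid)
        s2_mod = (d0 * s0_sq + df_resid * s2_arr) / (d0 + df_resid)
        t_df = min(d0 + df_resid, 1e7)

    denom = np.sqrt(s2_mod * (1.0 / n1 + 1.0 / n0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t_mod = log2fc.to_numpy() / denom
    pvals = 2.0 * stats.t.sf(np.abs(t_mod), df=t_df)
    t_mod = np.where(zero_var, 0.0, t_mod)
    pvals = np.where(zero_var, 1.0, pvals)
    pvals = np.clip(pvals, np.finfo(float).tiny, 1.0)

    out = pd.DataFrame({
        "gene": matrix.index,
        "log2fc": log2fc.to_numpy(),
        "fc_mvsc": fc_mvsc.to_numpy(),
        "t": t_mod,
        "p": pvals,
        "fdr": multipletests(pvals, method="fdr_bh")[1],
        "var": overall_var.to_numpy(),
        "s2": s2_arr,
    })
    out.attrs["d0"] = d0
    out.attrs["s0_sq"] = s0_sq
    out.attrs["df_resid"] = df_resid
    return out


def call_degs(table: pd.DataFrame, p_thresh: float = 0.05,
              lfc_thresh: float = 1.0) -> dict:
    """Strict-inequality DEG call: p < p_thresh AND |log2fc| > lfc_thresh."""
    mask = (table["p"] < p_thresh) & (table["log2fc"].abs() > lfc_thresh)
    degs = table.loc[mask]
    up = degs[degs["log2fc"] > 0]["gene"].tolist()
    down = degs[degs["log2fc"] < 0]["gene"].tolist()
    return {"degs": sorted(degs["gene"].tolist()),
            "n_up": len(up), "n_down": len(down),
            "up": sorted(up), "down": sorted(down)}


def comprehensive_score(deg_genes, connectivity: pd.Series,
                        de_table: pd.DataFrame) -> pd.DataFrame:
    """Sum-of-ranks target score over connectivity, |log2fc| and variance.

    Each metric is ranked descending (1 = largest, ties averaged); the
    Comprehensive_Score is the sum of the three ranks and the final order
    is ascending score (lower = better), ties broken by gene symbol.
    """
    genes = sorted(deg_genes)
    if not genes:
        return pd.DataFrame(columns=["gene", "connectivity", "log2fc", "fc_mvsc",
                                     "var", "rank_connectivity", "rank_foldchange",
                                     "rank_variance", "comprehensive_score"])
    de = de_table.set_index("gene").loc[genes]
    conn = connectivity.reindex(genes, fill_value=0).astype(float)

    def _rank_desc(values: np.ndarray) -> np.ndarray:
        return stats.rankdata(-values, method="average")

    rank_conn = _rank_desc(conn.to_numpy())
    rank_fc = _rank_desc(de["log2fc"].abs().to_numpy())
    rank_var = _rank_desc(de["var"].to_numpy())
    out = pd.DataFrame({
        "gene": genes,
        "connectivity": conn.to_numpy().astype(int),
        "log2fc": de["log2fc"].to_numpy(),
        "fc_mvsc": de["fc_mvsc"].to_numpy(),
        "var": de["var"].to_numpy(),
        "rank_connectivity": rank_conn,
        "rank_foldchange": rank_fc,
        "rank_variance": rank_var,
    })
    out["comprehensive_score"] = (out["rank_connectivity"]
                                  + out["rank_foldchange"] + out["rank_variance"])
    return out.sort_values(["comprehensive_score", "gene"],
                           kind="mergesort").reset_index(drop=True)
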