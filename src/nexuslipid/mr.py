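"""Two-sample Mendelian randomization estimation and sensitivity suite.

Estimators operate on harmonized per-SNP effect pairs.  The primary
estimator is multiplicative random-effects IVW (standard-error inflation by
sqrt(max(1, Q/df)), never deflating below the fixed-effect SE); sensitivity
checks cover MR-Egger regression, Cochran's Q, leave-one-out, radial
outlier flagging, and Steiger directionality filtering.  An association
"qualifies" iff IVW P < 0.05, Egger-intercept P > 0.05 and Q P > 0.05.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

_PALINDROMIC = {frozenset("AT"), frozenset("CG")}


class InsufficientInstrumentsError(ValueError):
    pass


@dataclass(frozen=True)
class HarmonizedPair:
    snp_id: str
    beta_exp: float
    se_exp: float
    beta_out: float
    se_out: float
    eaf_exp: float = np.nan
    eaf_out: float = np.nan
    palindromic: bool = False
    flipped: bool = False


@dataclass(frozen=True)
class MrEstimate:
    method: str
    beta_hat: float
    se_hat: float
    pval: float
    nsnp: int

    @property
    def or_(self) -> float:
        return float(np.exp(self.beta_hat))

    @property
    def ci_low(self) -> float:
        return float(np.exp(self.beta_hat - 1.96 * self.se_hat))

    @property
    def ci_high(self) -> float:
        return float(np.exp(self.beta_hat + 1.96 * self.se_hat))


@dataclass
class SensitivityReport:
    egger_intercept: float = np.nan
    egger_intercept_p: float = np.nan
    q_stat: float = np.nan
    q_df: int = 0
    q_p: float = np.nan
    loo_table: pd.DataFrame | None = None
    radial_outliers: frozenset = frozenset()
    steiger_removed: frozenset = frozenset()


@dataclass
class QualifiedAssociation:
    exposure: str
    outcome: str
    direction: str  # "forward" | "reverse"
    estimate: MrEstimate
    sensitivity: SensitivityReport
    qualified: bool
    instruments: tuple[str, ...] = ()
    source: str = ""

    def to_dict(self) -> dict:
        e, s = self.estimate, self.sensitivity
        return {
            "exposure": self.exposure, "outcome": self.outcome,
            "direction": self.direction, "qualified": bool(self.qualified),
            "beta": e.beta_hat, "se": e.se_hat, "pval": e.pval,
            "or": e.or_, "ci_low": e.ci_low, "ci_high": e.ci_high,
            "nsnp": e.nsnp, "egger_intercept": s.egger_intercept,
            "egger_intercept_p": s.egger_intercept_p,
            "q_stat": s.q_stat, "q_df": s.q_df, "q_p": s.q_p,
            "radial_outliers": sorted(s.radial_outliers),
            "steiger_removed": sorted(s.steiger_removed),
            "instruments": list(self.instruments), "source": self.source,
        }


# ---------------------------------------------------------------------------
# instrument selection and harmonization
# ---------------------------------------------------------------------------

def select_instruments(gwas: pd.DataFrame, ld: pd.DataFrame,
                       p_thresh: float = 5e-8, r2_thresh: float = 0.001,
                       window_kb: float = 1000.0) -> list[str]:
    """Greedy LD clumping of genome-wide-significant SNPs.

    Candidates are sorted by ascending P; a SNP is retained iff its r^2 with
    every already-retained SNP lying within ``window_kb`` of it is below
    ``r2_thresh``.  Returns the retained SNP ids (empty list = explicit
    "no instruments" status, never an exception).
    """
    cand = gwas[gwas["pval"] < p_thresh].sort_values(["pval", "snp"])
    if cand.empty:
        log.info("no instruments: no SNP passes P < %g", p_thresh)
        return []
    missing = set(cand["snp"]) - set(ld.index)
    if missing:
        raise ValueError(f"LD matrix does not cover candidate SNPs: {sorted(missing)}")

    window = window_kb * 1000.0
    pos = gwas.set_index("snp")["pos"]
    kept: list[str] = []
    for snp in cand["snp"]:
        ok = True
        for other in kept:
            if abs(pos[snp] - pos[other]) <= window and ld.loc[snp, other] >= r2_thresh:
                ok = False
                break
        if ok:
            kept.append(snp)
    return kept


def harmonize(exposure: pd.DataFrame, outcome: pd.DataFrame,
              eaf_ambiguity: tuple[float, float] = (0.42, 0.58)
              ) -> list[HarmonizedPair]:
    """Align outcome effect alleles to the exposure's coding.

    The outcome beta is sign-flipped (and its EAF complemented) when its
    effect allele equals the exposure's other allele.  Palindromic (A/T or
    C/G) SNPs are dropped when either study's EAF lies inside the ambiguity
    window.  SNPs with incompatible alleles are dropped with a logged
    reason; an empty shared-SNP set yields an empty list ("no overlap").
    """
    out_by_snp = outcome.set_index("snp")
    lo, hi = eaf_ambiguity
    pairs: list[HarmonizedPair] = []
    shared = [s for s in exposure["snp"] if s in out_by_snp.index]
    if not shared:
        log.warning("harmonize: no overlap between exposure and outcome SNPs")
        return []
    exp_by_snp = exposure.set_index("snp")
    for snp in shared:
        e = exp_by_snp.loc[snp]
        o = out_by_snp.loc[snp]
        palindromic = frozenset((e["ea"], e["oa"])) in _PALINDROMIC
        if palindromic and (lo < e["eaf"] < hi or lo < o["eaf"] < hi):
            log.info("harmonize: dropping palindromic SNP %s (ambiguous EAF)", snp)
            continue
        if (o["ea"], o["oa"]) == (e["ea"], e["oa"]):
            flipped = False
            beta_out, eaf_out = o["beta"], o["eaf"]
        elif (o["ea"], o["oa"]) == (e["oa"], e["ea"]):
            flipped = True
            beta_out, eaf_out = -o["beta"], 1.0 - o["eaf"]
        else:
            log.info("harmonize: dropping SNP %s (allele mismatch %s/%s vs %s/%s)",
                     snp, e["ea"], e["oa"], o["ea"], o["oa"])
            continue
        pairs.append(HarmonizedPair(
            snp_id=snp, beta_exp=float(e["beta"]), se_exp=float(e["se"]),
            beta_out=float(beta_out), se_out=float(o["se"]),
            eaf_exp=float(e["eaf"]), eaf_out=float(eaf_out),
            palindromic=palindromic, flipped=flipped))
    return pairs


# ---------------------------------------------------------------------------
# estimators
# ---------------------------------------------------------------------------

def _ratio_arrays(pairs: list[HarmonizedPair]) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Wald ratios and first-order weights, excluding beta_exp == 0 SNPs."""
    usable = []
    for p in pairs:
        if p.beta_exp == 0:
            warnings.warn(f"SNP {p.snp_id} excluded: exposure beta is 0")
        else:
            usable.append(p)
    b = np.array([p.beta_out / p.beta_exp for p in usable])
    w = np.array([(p.beta_exp / p.se_out) ** 2 for p in usable])
    return b, w, [p.snp_id for p in usable]


def ivw(pairs: list[HarmonizedPair]) -> MrEstimate:
    """Multiplicative random-effects inverse-variance-weighted estimate.

    Equivalent to weighted least squares of beta_out on beta_exp through the
    origin with weights 1/se_out^2; the fixed-effect SE (sum w)^-1/2 is
    inflated by sqrt(max(1, Q/(k-1))).
    """
    b, w, _ = _ratio_arrays(pairs)
    k = len(b)
    if k < 2:
        raise InsufficientInstrumentsError(f"IVW requires >= 2 usable instruments, got {k}")
    beta_hat = float(np.sum(w * b) / np.sum(w))
    se_fixed = float(1.0 / np.sqrt(np.sum(w)))
    q = float(np.sum(w * (b - beta_hat) ** 2))
    se_hat = se_fixed * float(np.sqrt(max(1.0, q / (k - 1))))
    pval = float(2.0 * stats.norm.sf(abs(beta_hat) / se_hat))
    return MrEstimate(method="IVW", beta_hat=beta_hat, se_hat=se_hat,
                      pval=pval, nsnp=k)


def egger(pairs: list[HarmonizedPair]) -> tuple[MrEstimate, float, float]:
    """MR-Egger weighted regression with a free intercept.

    Pairs are first oriented so beta_exp >= 0 (removes the sign
    indeterminacy); weights are 1/se_out^2.  The coefficient covariance uses
    a residual scale of max(1, RSS_w/(k-2)) so SEs never deflate below the
    fixed-effect ones.  Returns (slope estimate, intercept, intercept P).
    """
    k = len(pairs)
    if k < 3:
        raise InsufficientInstrumentsError("Egger requires >=3 instruments")
    sign = np.array([1.0 if p.beta_exp >= 0 else -1.0 for p in pairs])
    x = sign * np.array([p.beta_exp for p in pairs])
    y = sign * np.array([p.beta_out for p in pairs])
    w = np.array([1.0 / p.se_out ** 2 for p in pairs])

    X = np.column_stack([np.ones(k), x])
    xtwx = X.T @ (w[:, None] * X)
    xtwy = X.T @ (w * y)
    coef = np.linalg.solve(xtwx, xtwy)
    resid = y - X @ coef
    rss_w = float(np.sum(w * resid ** 2))
    scale = max(1.0, rss_w / (k - 2))
    cov = np.linalg.inv(xtwx) * scale
    se = np.sqrt(np.diag(cov))
    tdist = stats.t(df=k - 2)
    p_int = float(2.0 * tdist.sf(abs(coef[0] / se[0]))) if se[0] > 0 else 0.0
    p_slope = float(2.0 * tdist.sf(abs(coef[1] / se[1]))) if se[1] > 0 else 0.0
    estimate = MrEstimate(method="Egger", beta_hat=float(coef[1]),
                          se_hat=float(se[1]), pval=p_slope, nsnp=k)
    return estimate, float(coef[0]), p_int


def cochran_q(pairs: list[HarmonizedPair],
              ivw_beta: float | None = None) -> tuple[float, int, float]:
    """Cochran's Q heterogeneity statistic on the Wald ratios."""
    b, w, _ = _ratio_arrays(pairs)
    k = len(b)
    if k < 2:
        raise InsufficientInstrumentsError("Cochran's Q requires >= 2 instruments")
    if ivw_beta is None:
        ivw_beta = float(np.sum(w * b) / np.sum(w))
    q = float(np.sum(w * (b - ivw_beta) ** 2))
    df = k - 1
    return q, df, float(stats.chi2.sf(q, df))


def leave_one_out(pairs: list[HarmonizedPair]) -> pd.DataFrame:
    """Per-SNP IVW estimates with that SNP removed.

    Flags SNPs whose removal crosses the P = 0.05 boundary or moves the
    estimate by more than one full-set fixed-effect SE.
    """
    if len(pairs) < 3:
        raise InsufficientInstrumentsError("leave-one-out requires >= 3 instruments")
    full = ivw(pairs)
    _, w_full, _ = _ratio_arrays(pairs)
    se_fixed = float(1.0 / np.sqrt(np.sum(w_full)))
    rows = []
    for i, p in enumerate(pairs):
        sub = pairs[:i] + pairs[i + 1:]
        est = ivw(sub)
        crossed = (est.pval < 0.05) != (full.pval < 0.05)
        moved = abs(est.beta_hat - full.beta_hat) > se_fixed
        rows.append({"snp": p.snp_id, "beta": est.beta_hat, "se": est.se_hat,
                     "pval": est.pval, "delta_beta": est.beta_hat - full.beta_hat,
                     "influential": bool(crossed or moved)})
    return pd.DataFrame(rows)


def radial_outliers(pairs: list[HarmonizedPair], alpha: float = 0.05,
                    bonferroni: bool = True) -> frozenset[str]:
    """Flag SNPs whose per-SNP radial Q contribution is an outlier.

    Q_i = w_i (b_i - beta_hat)^2 is compared against the chi-square(1)
    upper-alpha (optionally alpha/k Bonferroni-adjusted) quantile.
    """
    if len(pairs) < 3:
        raise InsufficientInstrumentsError("radial MR requires >= 3 instruments")
    b, w, snps = _ratio_arrays(pairs)
    beta_hat = float(np.sum(w * b) / np.sum(w))
    q_i = w * (b - beta_hat) ** 2
    level = alpha / len(b) if bonferroni else alpha
    threshold = stats.chi2.isf(level, df=1)
    return frozenset(s for s, q in zip(snps, q_i) if q > threshold)


def steiger_filter(pairs: list[HarmonizedPair], n_exp: int | None,
                   n_out: int | None, use_eaf: bool = False
                   ) -> tuple[list[HarmonizedPair], frozenset[str]]:
    """Remove instruments explaining more outcome than exposure variance.

    Default r^2 estimator is t^2/(t^2 + n - 2) with t = beta/se; with
    ``use_eaf=True`` the 2p(1-p)beta^2 estimator is used instead (then
    sample sizes are not needed).
    """
    if not use_eaf:
        if n_exp is None:
            raise ValueError("Steiger filtering: sample size missing for the exposure dataset")
        if n_out is None:
            raise ValueError("Steiger filtering: sample size missing for the outcome dataset")
    retained, removed = [], []
    for p in pairs:
        if use_eaf:
            r2_exp = 2 * p.eaf_exp * (1 - p.eaf_exp) * p.beta_exp ** 2
            r2_out = 2 * p.eaf_out * (1 - p.eaf_out) * p.beta_out ** 2
        else:
            t_exp = p.beta_exp / p.se_exp
            t_out = p.beta_out / p.se_out
            r2_exp = t_exp ** 2 / (t_exp ** 2 + n_exp - 2)
            r2_out = t_out ** 2 / (t_out ** 2 + n_out - 2)
        (removed if r2_out > r2_exp else retained).append(p)
    return retained, frozenset(p.snp_id for p in removed)


def qualify(exposure: str, outcome: str, direction: str,
            estimate: MrEstimate, sensitivity: SensitivityReport,
            instruments: tuple[str, ...] = (), source: str = ""
            ) -> QualifiedAssociation:
    """Apply the three-criterion qualification rule."""
    ok = (estimate.pval < 0.05
          and sensitivity.egger_intercept_p > 0.05
          and sensitivity.q_p > 0.05)
    return QualifiedAssociation(
        exposure=exposure, outcome=outcome, direction=direction,
        estimate=estimate, sensitivity=sensitivity, qualified=bool(ok),
        instruments=tuple(instruments), source=source)


def run_mr(exposure: pd.DataFrame, outcome: pd.DataFrame, ld: pd.DataFrame,
           exposure_name: str = "exposure", outcome_name: str = "outcome",
           direction: str = "forward", source: str = "",
           p_thresh: float = 5e-8, r2_thresh: float = 0.001,
           window_kb: float = 1000.0, steiger: bool = True,
           min_instruments: int = 3) -> QualifiedAssociation | None:
    """Full single-pair MR analysis: clump, harmonize, estimate, qualify.

    Returns None when fewer than ``min_instruments`` usable instruments
    survive selection, harmonization and Steiger filtering.
    """
    snps = select_instruments(exposure, ld, p_thresh=p_thresh,
                              r2_thresh=r2_thresh, window_kb=window_kb)
    if len(snps) < min_instruments:
        return None
    pairs = harmonize(exposure[exposure["snp"].isin(snps)], outcome)
    steiger_removed: frozenset[str] = frozenset()
    if steiger and pairs:
        n_exp = int(exposure["n"].iloc[0])
        n_out = int(outcome["n"].iloc[0])
        pairs, steiger_removed = steiger_filter(pairs, n_exp, n_out)
    if len(pairs) < min_instruments:
        return None
    estimate = ivw(pairs)
    _, intercept, p_int = egger(pairs)
    q, q_df, q_p = cochran_q(pairs, estimate.beta_hat)
    sens = SensitivityReport(
        egger_intercept=intercept, egger_intercept_p=p_int,
        q_stat=q, q_df=q_df, q_p=q_p,
        loo_table=leave_one_out(pairs),
        radial_outliers=radial_outliers(pairs),
        steiger_removed=steiger_removed)
    return qualify(exposure_name, outcome_name, direction, estimate, sens,
                   instruments=tuple(p.snp_id for p in pairs), source=source)
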