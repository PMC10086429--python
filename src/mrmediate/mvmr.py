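"""Multivariable MR: joint direct effects of several exposures on an outcome.

``mvmr_ivw`` is weighted least squares of the outcome effects on the
matrix of exposure effects with no intercept; ``mvmr_egger`` adds an
intercept after orienting SNPs on the first exposure; ``qhet_mvmr``
minimizes a heterogeneity objective whose weights absorb the exposure
effect uncertainty.  With a single exposure each reduces to its
univariable counterpart.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from mrmediate.harmonize import HarmonizedSet, harmonize_multi
from mrmediate.instruments import InstrumentSet, find_proxy, ld_clump
from mrmediate.sumstats import LDInfo, SummaryStats
from mrmediate.uvmr import Z95, Heterogeneity


@dataclass
class MVMRResult:
    """Direct effects of each exposure, conditional on the others."""

    exposure_labels: list[str]
    estimates: np.ndarray
    ses: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    pvals: np.ndarray
    method: str
    n_snps: int
    heterogeneity: Heterogeneity | None = None
    mv_egger_intercept: tuple[float, float, float] | None = None
    notes: list[str] = field(default_factory=list)

    def for_exposure(self, label: str) -> dict:
        k = self.exposure_labels.index(label)
        return {
            "exposure": label,
            "estimate": float(self.estimates[k]),
            "se": float(self.ses[k]),
            "ci_low": float(self.ci_low[k]),
            "ci_high": float(self.ci_high[k]),
            "pval": float(self.pvals[k]),
        }

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.for_exposure(lb) for lb in self.exposure_labels])


def build_mv_set(
    exposures: list[SummaryStats],
    outcome: SummaryStats,
    instrument_union: InstrumentSet,
    ld: LDInfo | None = None,
    proxy_table: pd.DataFrame | None = None,
    r2_max: float = 0.001,
    window_kb: float = 10_000,
    proxy_r2_min: float = 0.8,
    af_ambiguous: tuple[float, float] = (0.4, 0.6),
) -> HarmonizedSet:
    """Union of per-exposure instruments, jointly re-clumped and harmonized.

    Ranking for the joint clump uses each SNP's lowest p-value across the
    contributing exposure tables.  SNPs missing from the outcome are
    resolved by proxy when a table is supplied, otherwise dropped.
    """
    best_p: dict[str, float] = {}
    for expo in exposures:
        t = expo.table
        for snp, p in zip(t["snp"], t["pval"]):
            if snp in instrument_union.snp_ids:
                best_p[snp] = min(best_p.get(snp, 1.0), float(p))
    clumped = ld_clump(instrument_union, ld, r2_max, window_kb, pvals=best_p)

    present = set(outcome.snp_ids)
    final_ids: list[str] = []
    for snp in clumped.snp_ids:
        if snp in present:
            final_ids.append(snp)
        elif proxy_table is not None:
            proxy = find_proxy(snp, proxy_table, outcome, proxy_r2_min)
            if proxy is not None and proxy not in final_ids:
                final_ids.append(proxy)
                clumped.provenance[proxy] = f"proxy-of:{snp}"
            else:
                clumped.provenance[snp] = "dropped:missing-in-outcome"
        else:
            clumped.provenance[snp] = "dropped:missing-in-outcome"
    if not final_ids:
        raise ValueError("no instruments remain after clumping and outcome lookup")
    return harmonize_multi(exposures, outcome, final_ids, af_ambiguous)


def _design(h: HarmonizedSet) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    X, SX = h.exposure_matrix()
    y = h.beta_y
    sy = h.se_y
    return X, SX, y, sy


def _check_rank(X: np.ndarray, labels: list[str]) -> None:
    if np.linalg.matrix_rank(X) < X.shape[1]:
        corr = np.corrcoef(X, rowvar=False)
        pairs = [
            f"{labels[i]}~{labels[j]}"
            for i in range(len(labels))
            for j in range(i + 1, len(labels))
            if abs(corr[i, j]) > 0.999999
        ]
        raise ValueError(
            "rank-deficient exposure design (collinear exposures: "
            + (", ".join(pairs) if pairs else "unidentified pair") + ")"
        )


def _wls(
    X: np.ndarray, y: np.ndarray, w: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    WX = X * w[:, None]
    xtwx = X.T @ WX
    coef = np.linalg.solve(xtwx, WX.T @ y)
    resid = y - X @ coef
    df = len(y) - X.shape[1]
    scale2 = max(1.0, float(np.sum(w * resid**2) / df)) if df > 0 else 1.0
    ses = np.sqrt(np.diag(np.linalg.inv(xtwx)) * scale2)
    return coef, ses, float(np.sum(w * resid**2))


def mvmr_ivw(h: HarmonizedSet) -> MVMRResult:
    """Multivariable IVW: no-intercept WLS with weights ``se_y**-2``.

    SEs carry a multiplicative residual scaling bounded below by 1; Q and
    I² are computed on the weighted residuals with ``J - K`` degrees of
    freedom.
    """
    X, SX, y, sy = _design(h)
    J, K = X.shape
    if J <= K:
        raise ValueError(f"need more SNPs ({J}) than exposures ({K})")
    _check_rank(X, h.exposure_labels)
    w = sy**-2.0
    coef, ses, Q = _wls(X, y, w)
    df = J - K
    het = Heterogeneity(
        Q, df, float(stats.chi2.sf(Q, df)), max(0.0, (Q - df) / Q) if Q > 0 else 0.0
    )
    z = coef / ses
    return MVMRResult(
        exposure_labels=list(h.exposure_labels),
        estimates=coef,
        ses=ses,
        ci_low=coef - Z95 * ses,
        ci_high=coef + Z95 * ses,
        pvals=2.0 * stats.norm.sf(np.abs(z)),
        method="mv-ivw",
        n_snps=J,
        heterogeneity=het,
    )


def mvmr_egger(h: HarmonizedSet) -> MVMRResult:
    """Multivariable Egger: adds an intercept after orienting on exposure 1."""
    X, SX, y, sy = _design(h)
    J, K = X.shape
    if J <= K + 1:
        raise ValueError(f"need more SNPs ({J}) than exposures + 1 ({K + 1})")
    _check_rank(X, h.exposure_labels)
    flip = np.where(X[:, 0] >= 0, 1.0, -1.0)
    Xo = X * flip[:, None]
    yo = y * flip
    D = np.column_stack([np.ones(J), Xo])
    w = sy**-2.0
    coef, ses, Q = _wls(D, yo, w)
    df = J - K - 1
    het = Heterogeneity(
        Q, df, float(stats.chi2.sf(Q, df)), max(0.0, (Q - df) / Q) if Q > 0 else 0.0
    )
    est, se = coef[1:], ses[1:]
    tstat = est / se
    p_int = float(2.0 * stats.t.sf(abs(coef[0] / ses[0]), df))
    return MVMRResult(
        exposure_labels=list(h.exposure_labels),
        estimates=est,
        ses=se,
        ci_low=est - Z95 * se,
        ci_high=est + Z95 * se,
        pvals=2.0 * stats.t.sf(np.abs(tstat), df) * 1.0,
        method="mv-egger",
        n_snps=J,
        heterogeneity=het,
        mv_egger_intercept=(float(coef[0]), float(ses[0]), p_int),
    )


def _qhet_objective(theta: np.ndarray, X, SX, y, sy) -> float:
    denom = sy**2 + (SX**2) @ (theta**2)
    resid = y - X @ theta
    return float(np.sum(resid**2 / denom))


def qhet_mvmr(
    h: HarmonizedSet, ci_boot: int = 1000, seed: int = 0
) -> MVMRResult:
    """Heterogeneity-minimizing MVMR.

    Minimizes ``sum (by - X theta)^2 / (sy^2 + sum_k theta_k^2 sx_k^2)``
    starting from the multivariable IVW solution; confidence intervals by
    seeded nonparametric bootstrap over SNPs.
    """
    X, SX, y, sy = _design(h)
    J, K = X.shape
    if J <= K:
        raise ValueError(f"need more SNPs ({J}) than exposures ({K})")
    start = mvmr_ivw(h).estimates

    def fit(Xf, SXf, yf, syf, x0) -> np.ndarray:
        res = optimize.minimize(
            _qhet_objective, x0=x0, args=(Xf, SXf, yf, syf), method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 20000},
        )
        if not res.success:
            raise RuntimeError(f"QHET optimizer failed: {res.message}")
        return res.x

    theta = fit(X, SX, y, sy, start)
    rng = np.random.default_rng(seed)
    boots = np.empty((ci_boot, K))
    for b in range(ci_boot):
        idx = rng.integers(0, J, size=J)
        try:
            boots[b] = fit(X[idx], SX[idx], y[idx], sy[idx], theta)
        except (RuntimeError, np.linalg.LinAlgError):
            boots[b] = np.nan
    ok = ~np.isnan(boots).any(axis=1)
    ses = np.std(boots[ok], axis=0, ddof=1)
    lo = np.percentile(boots[ok], 2.5, axis=0)
    hi = np.percentile(boots[ok], 97.5, axis=0)
    z = theta / ses
    return MVMRResult(
        exposure_labels=list(h.exposure_labels),
        estimates=theta,
        ses=ses,
        ci_low=lo,
        ci_high=hi,
        pvals=2.0 * stats.norm.sf(np.abs(z)),
        method="qhet",
        n_snps=J,
        notes=[
            f"bootstrap reps={int(ok.sum())}/{ci_boot}",
            "interval method: nonparametric bootstrap percentiles "
            "(source method's interval construction unspecified)",
        ],
    )


def choose_mvmr_method(
    egger_intercept_p: float, p_Q: float, alpha: float = 0.05
) -> str:
    """Decision rule: pleiotropy → mv-egger; heterogeneity → qhet; else mv-ivw."""
    if egger_intercept_p < alpha:
        return "mv-egger"
    if p_Q < alpha:
        return "qhet"
    return "mv-ivw"
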