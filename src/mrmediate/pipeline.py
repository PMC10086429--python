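"""Config-driven orchestration of the full MR mediation analysis.

Stages: instrument selection → harmonization → outlier screen → the
univariable estimator battery with the method decision rule → joint
multivariable fits → per-mediator and combined mediation → FDR evidence
labels.  Everything that affected an output (thresholds, seeds, package
version) lands in a machine-readable manifest.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

import mrmediate
from mrmediate.harmonize import harmonize_pair
from mrmediate.instruments import (
    apply_exclusions,
    instrument_strength,
    ld_clump,
    load_exclusion_list,
    select_by_pvalue,
)
from mrmediate.mediation import (
    MediationConfig,
    combined_mediation,
    mediation_table,
    two_step_mediation,
)
from mrmediate.sumstats import (
    load_ld_matrix,
    load_proxy_table,
    load_summary_stats,
)
from mrmediate import uvmr as _uvmr

log = logging.getLogger("mrmediate")


@dataclass
class AnalysisConfig:
    """Validated pipeline configuration (YAML-loadable)."""

    exposure: str
    outcome: str
    mediators: list[str] = field(default_factory=list)
    labels: dict[str, str] = field(default_factory=dict)
    ld_matrix: str | None = None
    loci: str | None = None
    proxy_table: str | None = None
    exclude_snps: str | None = None
    p_threshold: float = 5e-5
    clump_r2: float = 0.001
    clump_kb: float = 10_000.0
    proxy_r2_min: float = 0.8
    af_ambiguous: tuple[float, float] = (0.4, 0.6)
    presso_nb_sim: int = 1000
    fdr_q: float = 0.05
    methods: list[str] = field(
        default_factory=lambda: ["ivw", "egger", "wmedian", "pwmedian", "ml", "radial"]
    )
    seed: int | None = None
    out_dir: str = "mr_results"

    def __post_init__(self) -> None:
        if not 0.0 < self.p_threshold < 1.0:
            raise ValueError("p_threshold must be in (0,1)")
        if not 0.0 < self.clump_r2 <= 1.0:
            raise ValueError("clump_r2 must be in (0,1]")
        if not 0.0 < self.fdr_q < 1.0:
            raise ValueError("fdr_q must be in (0,1)")
        lo, hi = self.af_ambiguous
        if not 0.0 <= lo < hi <= 1.0:
            raise ValueError("af_ambiguous must satisfy 0 <= lo < hi <= 1")
        stochastic = {"presso", "wmedian", "pwmedian", "simex"}
        if self.seed is None and stochastic & set(self.methods):
            raise ValueError(
                "seed is mandatory when a stochastic method is requested"
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        doc = yaml.safe_load(Path(path).read_text())
        if "af_ambiguous" in doc:
            doc["af_ambiguous"] = tuple(doc["af_ambiguous"])
        return cls(**doc)

    def to_manifest(self) -> dict:
        d = dataclasses.asdict(self)
        d["af_ambiguous"] = list(self.af_ambiguous)
        return d


@dataclass
class EvidenceLabel:
    raw_p: float
    q_value: float
    label: str  # significant | suggestive | null


def label_evidence(
    raw_p: float, q_value: float, q_cutoff: float = 0.05, p_cutoff: float = 0.05
) -> EvidenceLabel:
    """``significant`` iff q < cutoff; ``suggestive`` iff only raw p < 0.05."""
    if q_value < q_cutoff:
        lab = "significant"
    elif raw_p < p_cutoff:
        lab = "suggestive"
    else:
        lab = "null"
    return EvidenceLabel(raw_p, q_value, lab)


def choose_uvmr_method(
    egger_intercept_p: float, p_Q: float, i2: float
) -> tuple[str, str]:
    """Univariable method decision rule.

    Pleiotropy (intercept p < 0.05) → MR-Egger; else heterogeneity
    (p_Q < 0.05 AND I² > 0.25, both required) → random-effect IVW; else
    fixed-effect IVW.  Returns (method, effects model).
    """
    for name, v in (("egger_intercept_p", egger_intercept_p), ("p_Q", p_Q), ("I2", i2)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must be in [0,1], got {v}")
    if egger_intercept_p < 0.05:
        return ("mr-egger", "n/a")
    if p_Q < 0.05 and i2 > 0.25:
        return ("ivw", "random")
    return ("ivw", "fixed")


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini–Hochberg q-values, input order preserved."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0,1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def beta_to_or(
    beta: float, ci_low: float, ci_high: float, decimals: int | None = 2
) -> tuple[float, float, float]:
    """Exponentiate a log-odds effect and its CI bounds."""
    out = (np.exp(beta), np.exp(ci_low), np.exp(ci_high))
    if decimals is not None:
        out = tuple(round(float(v), decimals) for v in out)
    return out


def _load_tables(cfg: AnalysisConfig):
    expo = load_summary_stats(cfg.exposure, cfg.labels.get("exposure"))
    outc = load_summary_stats(cfg.outcome, cfg.labels.get("outcome"))
    meds = [
        load_summary_stats(m, cfg.labels.get(f"mediator{i + 1}"))
        for i, m in enumerate(cfg.mediators)
    ]
    ld = (
        load_ld_matrix(cfg.ld_matrix, cfg.loci) if cfg.ld_matrix is not None else None
    )
    proxies = load_proxy_table(cfg.proxy_table) if cfg.proxy_table else None
    return expo, meds, outc, ld, proxies


def _uvmr_battery(h, cfg: AnalysisConfig) -> pd.DataFrame:
    """Run the requested estimators; chooses the headline method."""
    runners = {
        "ivw": lambda: _uvmr.ivw(h, "auto"),
        "egger": lambda: _uvmr.mr_egger(h),
        "wmedian": lambda: _uvmr.weighted_median(h, seed=cfg.seed or 0),
        "pwmedian": lambda: _uvmr.weighted_median(h, penalized=True, seed=cfg.seed or 0),
        "ml": lambda: _uvmr.max_likelihood(h),
        "radial": lambda: _uvmr.radial_ivw(h),
        "simex": lambda: _uvmr.egger_simex(h, seed=cfg.seed or 0),
    }
    rows = []
    for name in cfg.methods:
        if name in ("presso", "loo"):
            continue
        try:
            rows.append(runners[name]().as_dict())
        except (ValueError, RuntimeError) as err:
            log.warning("method %s skipped: %s", name, err)
    return pd.DataFrame(rows)


def run_pipeline(cfg: AnalysisConfig) -> dict:
    """Execute the whole analysis; returns and writes the report bundle.

    Deterministic for a fixed config: all stochastic stages derive their
    seeds from ``cfg.seed``.
    """
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    exposure, mediators, outcome, ld, proxies = _load_tables(cfg)
    manifest: dict = {
        "config": cfg.to_manifest(),
        "version": mrmediate.__version__,
        "stages": [],
    }
    report: dict = {}

    def stage(name):
        manifest["stages"].append(name)
        log.info("stage: %s", name)

    try:
        stage("instruments")
        iv = select_by_pvalue(exposure, cfg.p_threshold)
        if cfg.exclude_snps:
            iv = apply_exclusions(iv, load_exclusion_list(cfg.exclude_snps))
        iv = ld_clump(iv, ld, cfg.clump_r2, cfg.clump_kb)
        strength = instrument_strength(exposure, iv)
        report["instrument_strength"] = strength
        if len(iv) < 3:
            log.warning(
                "instrument count fell to %d at p < %g", len(iv), cfg.p_threshold
            )

        stage("harmonize")
        h = harmonize_pair(
            exposure.subset(iv.snp_ids), outcome, cfg.af_ambiguous
        )
        report["drop_log"] = h.drop_log

        stage("presso")
        presso = None
        if h.n_snps >= 4 and cfg.seed is not None:
            presso = _uvmr.mr_presso(h, cfg.presso_nb_sim, seed=cfg.seed)
            if presso.outlier_snp_ids:
                h = h.drop_snps(presso.outlier_snp_ids, "presso-outlier")
            report["presso"] = {
                "global_p": presso.global_rss_p,
                "outliers": presso.outlier_snp_ids,
                "distortion_p": presso.distortion_p,
                "estimate_before": presso.estimate_before.estimate,
                "estimate_after": (
                    presso.estimate_after.estimate if presso.estimate_after else None
                ),
            }

        stage("uvmr")
        battery = _uvmr_battery(h, cfg)
        report["uvmr"] = battery
        egger_p = 1.0
        if "intercept_p" in battery.columns:
            eg = battery.loc[battery["method"] == "mr-egger"]
            if len(eg):
                egger_p = float(eg["intercept_p"].iloc[0])
        ivw_rows = battery.loc[battery["method"].str.startswith("ivw")]
        if len(ivw_rows):
            p_q = float(ivw_rows["p_Q"].iloc[0])
            i2 = float(ivw_rows["I2"].iloc[0])
            method, model = choose_uvmr_method(egger_p, p_q, i2)
            report["chosen_method"] = {"method": method, "effects_model": model}

        med_cfg = MediationConfig(
            p_threshold=cfg.p_threshold,
            clump_r2=cfg.clump_r2,
            clump_kb=cfg.clump_kb,
            proxy_r2_min=cfg.proxy_r2_min,
            af_ambiguous=cfg.af_ambiguous,
        )
        if mediators:
            stage("mediation")
            results = {}
            for med in mediators:
                r = two_step_mediation(
                    exposure, med, outcome, ld, med_cfg, proxies
                )
                results[(exposure.trait_id, med.trait_id, outcome.trait_id)] = r
            report["mediation"] = mediation_table(results)
            stage("combined-mediation")
            comb = combined_mediation(
                exposure, mediators, outcome, ld, med_cfg, proxies
            )
            report["combined_mediation"] = {
                "mediators": comb.mediator_labels,
                "combined_indirect": comb.combined_indirect.value,
                "combined_indirect_se": comb.combined_indirect.se,
                "combined_proportion": (
                    comb.combined_proportion.value
                    if comb.combined_proportion
                    else None
                ),
            }

        stage("fdr")
        if len(battery):
            q = bh_fdr(battery["pval"].to_numpy())
            battery = battery.assign(
                q_value=q,
                evidence=[
                    label_evidence(p, qq, cfg.fdr_q).label
                    for p, qq in zip(battery["pval"], q)
                ],
            )
            report["uvmr"] = battery
    except Exception as err:  # preserve partial outputs, then re-raise
        _write_report(report, manifest, out_dir)
        raise RuntimeError(
            f"pipeline failed at stage {manifest['stages'][-1]}: {err}"
        ) from err

    _write_report(report, manifest, out_dir)
    return report


def _write_report(report: dict, manifest: dict, out_dir: Path) -> None:
    for key in ("uvmr", "mediation", "instrument_strength", "drop_log"):
        if key in report and report[key] is not None and len(report[key]):
            report[key].to_csv(
                out_dir / f"{key}.tsv", sep="\t", index=False, float_format="%.10g"
            )
    plain = {
        k: v
        for k, v in report.items()
        if not isinstance(v, pd.DataFrame)
    }
    (out_dir / "summary.json").write_text(json.dumps(plain, indent=2, default=str))
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
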