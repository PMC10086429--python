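"""Two-step MR mediation with delta-method uncertainty.

The total effect of an exposure on an outcome (``beta_c``, univariable
MR) is decomposed into an indirect path through a mediator
(``beta_a * beta_b``: exposure→mediator from univariable MR times
mediator→outcome adjusted for the exposure from multivariable MR) and
the direct remainder ``beta_c - beta_a * beta_b``.  The proportion
mediated divides the indirect effect by the total.

Variance conventions (documented approximations):

- product: first-order delta, ``a² σ_b² + b² σ_a²``; the second-order
  ``+ σ_a² σ_b²`` term is available behind ``second_order=True``
- proportion: delta ratio treating numerator and denominator as
  independent
- combined (parallel mediators): indirect effects summed, variances
  summed (cross-mediator covariance ignored)
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from mrmediate.harmonize import HarmonizedSet
from mrmediate.instruments import InstrumentSet, select_by_pvalue
from mrmediate.mvmr import MVMRResult, build_mv_set, mvmr_ivw
from mrmediate.sumstats import LDInfo, SummaryStats
from mrmediate.uvmr import Z95, MRResult, ivw
from mrmediate.harmonize import harmonize_pair


@dataclass
class Estimate:
    value: float
    se: float

    @property
    def ci(self) -> tuple[float, float]:
        return (self.value - Z95 * self.se, self.value + Z95 * self.se)


@dataclass
class MediationResult:
    """Decomposition of a total effect for one mediator."""

    beta_c: Estimate  # total: exposure -> outcome
    beta_a: Estimate  # exposure -> mediator
    beta_b: Estimate  # mediator -> outcome, adjusted for exposure
    indirect: Estimate
    direct: float
    proportion: Estimate | None  # on the 0-1 scale; None when beta_c == 0
    pval_indirect: float
    notes: list[str] = field(default_factory=list)
    stages: dict = field(default_factory=dict)

    @property
    def proportion_pct(self) -> float | None:
        return None if self.proportion is None else 100.0 * self.proportion.value

    def as_dict(self) -> dict:
        d = {
            "beta_c": self.beta_c.value,
            "se_c": self.beta_c.se,
            "beta_a": self.beta_a.value,
            "se_a": self.beta_a.se,
            "beta_b": self.beta_b.value,
            "se_b": self.beta_b.se,
            "indirect": self.indirect.value,
            "indirect_se": self.indirect.se,
            "indirect_ci_low": self.indirect.ci[0],
            "indirect_ci_high": self.indirect.ci[1],
            "direct": self.direct,
            "pval_indirect": self.pval_indirect,
        }
        if self.proportion is not None:
            d["proportion"] = self.proportion.value
            d["proportion_se"] = self.proportion.se
            d["proportion_ci_low"] = self.proportion.ci[0]
            d["proportion_ci_high"] = self.proportion.ci[1]
        return d


@dataclass
class CombinedMediationResult:
    """Joint decomposition across parallel mediators."""

    mediator_labels: list[str]
    per_mediator: list[MediationResult]
    combined_indirect: Estimate
    combined_proportion: Estimate | None
    beta_c: Estimate
    notes: list[str] = field(default_factory=list)


def mediate(
    beta_a: float,
    se_a: float,
    beta_b: float,
    se_b: float,
    beta_c: float,
    se_c: float,
    second_order: bool = False,
) -> MediationResult:
    """Product-method mediation from three effect estimates.

    ``indirect = beta_a * beta_b`` with the delta-method SE; the direct
    effect is the exact remainder so ``direct + indirect == beta_c``
    always holds.  ``proportion = indirect / beta_c`` with a ratio
    delta-method SE assuming independent numerator and denominator;
    undefined (None, with a note) when ``beta_c`` is zero.
    """
    for name, se in (("se_a", se_a), ("se_b", se_b), ("se_c", se_c)):
        if se <= 0:
            raise ValueError(f"{name} must be > 0, got {se}")
    indirect = beta_a * beta_b
    var_ind = beta_a**2 * se_b**2 + beta_b**2 * se_a**2
    if second_order:
        var_ind += se_a**2 * se_b**2
    se_ind = float(np.sqrt(var_ind))
    z = indirect / se_ind if se_ind > 0 else np.inf
    pval = float(2.0 * stats.norm.sf(abs(z)))
    direct = beta_c - indirect
    notes = []
    if beta_c == 0:
        proportion = None
        notes.append("beta_c = 0: proportion mediated undefined")
    else:
        prop = indirect / beta_c
        se_prop = float(
            np.sqrt(se_ind**2 / beta_c**2 + indirect**2 * se_c**2 / beta_c**4)
        )
        proportion = Estimate(prop, se_prop)
    return MediationResult(
        beta_c=Estimate(beta_c, se_c),
        beta_a=Estimate(beta_a, se_a),
        beta_b=Estimate(beta_b, se_b),
        indirect=Estimate(indirect, se_ind),
        direct=direct,
        proportion=proportion,
        pval_indirect=pval,
        notes=notes,
    )


@dataclass
class MediationConfig:
    """Knobs for the instrument/harmonization stages of two-step mediation."""

    p_threshold: float = 5e-5
    clump_r2: float = 0.001
    clump_kb: float = 10_000
    proxy_r2_min: float = 0.8
    af_ambiguous: tuple[float, float] = (0.4, 0.6)
    effects_model: str = "auto"


def _uvmr_effect(
    exposure: SummaryStats,
    outcome: SummaryStats,
    ld: LDInfo | None,
    cfg: MediationConfig,
    stage: str,
) -> tuple[MRResult, InstrumentSet]:
    from mrmediate.instruments import ld_clump

    try:
        iv = select_by_pvalue(exposure, cfg.p_threshold)
        iv = ld_clump(iv, ld, cfg.clump_r2, cfg.clump_kb)
        h = harmonize_pair(
            exposure.subset(iv.snp_ids), outcome, cfg.af_ambiguous
        )
        return ivw(h, cfg.effects_model), iv
    except (ValueError, KeyError) as err:
        raise RuntimeError(f"stage {stage}: {err}") from err


def two_step_mediation(
    exposure: SummaryStats,
    mediator: SummaryStats,
    outcome: SummaryStats,
    ld: LDInfo | None = None,
    config: MediationConfig | None = None,
    proxy_table: pd.DataFrame | None = None,
) -> MediationResult:
    """Full two-step mediation from summary statistics.

    Step 1 (univariable): ``beta_c`` exposure→outcome and ``beta_a``
    exposure→mediator.  Step 2 (multivariable): ``beta_b`` is the
    mediator's coefficient in the joint regression of the outcome on
    exposure and mediator instruments.  All intermediate fits are kept in
    ``stages``.
    """
    cfg = config or MediationConfig()
    total, iv_x = _uvmr_effect(exposure, outcome, ld, cfg, "total-effect")
    a_fit, _ = _uvmr_effect(exposure, mediator, ld, cfg, "exposure-mediator")
    mv = _mv_fit(exposure, [mediator], outcome, ld, cfg, proxy_table)
    b = mv.for_exposure(mediator.trait_id)
    result = mediate(
        a_fit.estimate, a_fit.se, b["estimate"], b["se"], total.estimate, total.se
    )
    result.stages = {"total": total, "exposure_mediator": a_fit, "mvmr": mv}
    return result


def _mv_fit(
    exposure: SummaryStats,
    mediators: Sequence[SummaryStats],
    outcome: SummaryStats,
    ld: LDInfo | None,
    cfg: MediationConfig,
    proxy_table: pd.DataFrame | None,
) -> MVMRResult:
    from mrmediate.instruments import ld_clump

    union_ids: list[str] = []
    prov: dict[str, str] = {}
    for tab in [exposure, *mediators]:
        iv = select_by_pvalue(tab, cfg.p_threshold)
        iv = ld_clump(iv, ld, cfg.clump_r2, cfg.clump_kb)
        for s in iv.snp_ids:
            if s not in prov:
                union_ids.append(s)
                prov[s] = f"direct:{tab.trait_id}"
    union = InstrumentSet(
        snp_ids=union_ids,
        source_trait="+".join([exposure.trait_id] + [m.trait_id for m in mediators]),
        threshold_used=cfg.p_threshold,
        provenance=prov,
    )
    h = build_mv_set(
        [exposure, *mediators],
        outcome,
        union,
        ld,
        proxy_table,
        cfg.clump_r2,
        cfg.clump_kb,
        cfg.proxy_r2_min,
        cfg.af_ambiguous,
    )
    try:
        return mvmr_ivw(h)
    except ValueError as err:
        raise RuntimeError(f"stage mvmr: {err}") from err


def combined_mediation(
    exposure: SummaryStats,
    mediators: Sequence[SummaryStats],
    outcome: SummaryStats,
    ld: LDInfo | None = None,
    config: MediationConfig | None = None,
    proxy_table: pd.DataFrame | None = None,
) -> CombinedMediationResult:
    """Parallel-mediator decomposition from one joint multivariable fit.

    Each mediator's ``beta_b`` comes from the same all-mediator MVMR;
    indirect effects are summed and their variances added (independence
    working assumption).
    """
    if not mediators:
        raise ValueError("need at least one mediator")
    cfg = config or MediationConfig()
    total, _ = _uvmr_effect(exposure, outcome, ld, cfg, "total-effect")
    mv = _mv_fit(exposure, mediators, outcome, ld, cfg, proxy_table)
    per: list[MediationResult] = []
    for med in mediators:
        a_fit, _ = _uvmr_effect(exposure, med, ld, cfg, f"exposure-{med.trait_id}")
        b = mv.for_exposure(med.trait_id)
        r = mediate(
            a_fit.estimate, a_fit.se, b["estimate"], b["se"], total.estimate, total.se
        )
        r.stages = {"total": total, "exposure_mediator": a_fit, "mvmr": mv}
        per.append(r)
    combined = float(sum(r.indirect.value for r in per))
    se_combined = float(np.sqrt(sum(r.indirect.se**2 for r in per)))
    if total.estimate == 0:
        prop = None
    else:
        p = combined / total.estimate
        se_p = float(
            np.sqrt(
                se_combined**2 / total.estimate**2
                + combined**2 * total.se**2 / total.estimate**4
            )
        )
        prop = Estimate(p, se_p)
    return CombinedMediationResult(
        mediator_labels=[m.trait_id for m in mediators],
        per_mediator=per,
        combined_indirect=Estimate(combined, se_combined),
        combined_proportion=prop,
        beta_c=Estimate(total.estimate, total.se),
        notes=["combined SE ignores cross-mediator covariance"],
    )


def mediation_table(results: dict[tuple[str, str, str], MediationResult]) -> pd.DataFrame:
    """Report table keyed by (exposure, mediator, outcome), Table-style columns."""
    rows = []
    for (exp, med, out), r in results.items():
        d = {"exposure": exp, "mediator": med, "outcome": out}
        d.update(r.as_dict())
        if r.proportion is not None:
            d["proportion_pct"] = round(100.0 * r.proportion.value, 2)
            d["proportion_pct_ci_low"] = round(100.0 * r.proportion.ci[0], 2)
            d["proportion_pct_ci_high"] = round(100.0 * r.proportion.ci[1], 2)
        rows.append(d)
    return pd.DataFrame(rows)
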