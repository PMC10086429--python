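"""Instrumental-variable selection from exposure summary statistics.

Selection proceeds p-value threshold → exclusion list → greedy LD clump,
then instrument strength (per-SNP F and R²) is reported.  SNPs absent
from the supplied LD information are treated as unlinked singletons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from mrmediate.sumstats import LDInfo, SummaryStats


@dataclass
class InstrumentSet:
    """Ordered set of retained instruments with per-SNP provenance."""

    snp_ids: list[str]
    source_trait: str
    threshold_used: float
    r2_total: float | None = None
    f_stats: dict[str, float] = field(default_factory=dict)
    provenance: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.snp_ids)

    def __iter__(self):
        return iter(self.snp_ids)

    def replace_with_proxy(self, target: str, proxy: str) -> None:
        i = self.snp_ids.index(target)
        self.snp_ids[i] = proxy
        self.provenance[proxy] = f"proxy-of:{target}"

    def drop(self, snp_id: str, reason: str) -> None:
        self.snp_ids.remove(snp_id)
        self.provenance[snp_id] = f"dropped:{reason}"


def select_by_pvalue(stats_: SummaryStats, threshold: float) -> InstrumentSet:
    """Retain records with ``pval < threshold``, ordered by ascending p.

    Ties on p break lexicographically on snp id for determinism.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must be in (0,1), got {threshold}")
    df = stats_.table
    hit = df.loc[df["pval"] < threshold].sort_values(
        ["pval", "snp"], kind="mergesort"
    )
    ids = hit["snp"].tolist()
    if not ids:
        warnings.warn(
            f"no SNP passes p < {threshold:g} for {stats_.trait_id}", stacklevel=2
        )
    return InstrumentSet(
        snp_ids=ids,
        source_trait=stats_.trait_id,
        threshold_used=threshold,
        provenance={s: "direct" for s in ids},
    )


def apply_exclusions(
    candidates: InstrumentSet, exclude: Iterable[str], reason: str = "excluded"
) -> InstrumentSet:
    """Remove listed snp ids (e.g. a pleiotropy screen surrogate)."""
    excl = set(exclude)
    for s in [s for s in candidates.snp_ids if s in excl]:
        candidates.drop(s, reason)
    return candidates


def load_exclusion_list(path: str | Path) -> list[str]:
    lines = Path(path).read_text().splitlines()
    return [ln.split("\t")[0].strip() for ln in lines if ln.strip() and not ln.startswith("#")]


def _clumps_with(
    ld: LDInfo, kept: str, other: str, r2_max: float, window_kb: float
) -> bool:
    """True iff ``other`` must be discarded given ``kept`` is retained."""
    if kept not in ld or other not in ld:
        return False
    c1, p1 = ld.locus(kept)
    c2, p2 = ld.locus(other)
    if c1 != c2 or abs(p1 - p2) > window_kb * 1000:
        return False
    return ld.pair_r2(kept, other) >= r2_max


def ld_clump(
    candidates: InstrumentSet,
    ld: LDInfo | None,
    r2_max: float = 0.001,
    window_kb: float = 10_000,
    pvals: dict[str, float] | None = None,
) -> InstrumentSet:
    """Greedy clumping: keep the best remaining SNP, discard its neighbours.

    Candidates must already be ordered by priority (ascending p); pass
    ``pvals`` to re-rank, e.g. after merging instrument sets.  The result
    order is retention order.  Idempotent.
    """
    order = list(candidates.snp_ids)
    if pvals is not None:
        order.sort(key=lambda s: (pvals.get(s, 1.0), s))
    retained: list[str] = []
    prov = dict(candidates.provenance)
    discarded: set[str] = set()
    for snp in order:
        if snp in discarded:
            continue
        retained.append(snp)
        if ld is None:
            continue
        for other in order:
            if other == snp or other in discarded or other in retained:
                continue
            if _clumps_with(ld, snp, other, r2_max, window_kb):
                discarded.add(other)
                prov[other] = f"dropped:clumped-with:{snp}"
    out = InstrumentSet(
        snp_ids=retained,
        source_trait=candidates.source_trait,
        threshold_used=candidates.threshold_used,
        provenance=prov,
    )
    _assert_valid_clump(out, ld, r2_max, window_kb)
    return out


def _assert_valid_clump(
    instruments: InstrumentSet, ld: LDInfo | None, r2_max: float, window_kb: float
) -> None:
    """Exhaustively check no retained pair violates the clump rule."""
    if ld is None:
        return
    ids = instruments.snp_ids
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            if _clumps_with(ld, a, b, r2_max, window_kb):
                raise AssertionError(f"clump violation between {a} and {b}")


def find_proxy(
    missing_snp: str,
    proxy_table: pd.DataFrame,
    outcome: SummaryStats,
    r2_min: float = 0.8,
) -> str | None:
    """Highest-r² proxy (r² ≥ r2_min) for a SNP absent from the outcome."""
    if not 0.0 < r2_min <= 1.0:
        raise ValueError(f"r2_min must be in (0,1], got {r2_min}")
    present = set(outcome.snp_ids)
    cand = proxy_table.loc[
        (proxy_table["target_snp"] == missing_snp)
        & (proxy_table["r2"] >= r2_min)
        & (proxy_table["proxy_snp"].isin(present))
    ]
    if cand.empty:
        return None
    best = cand.sort_values(["r2", "proxy_snp"], ascending=[False, True]).iloc[0]
    return str(best["proxy_snp"])


def instrument_strength(
    exposure: SummaryStats, instruments: InstrumentSet, f_min: float = 10.0
) -> pd.DataFrame:
    """Per-SNP F = (beta/se)² and explained variance R².

    R² uses ``2 eaf (1-eaf) beta²`` (SD-scaled trait) when eaf is known
    and falls back to ``F / (F + n - 2)`` otherwise; the formula used is
    labelled per SNP.  Weak instruments (F < ``f_min``) are flagged.
    """
    sub = exposure.subset(instruments.snp_ids).table
    f = (sub["beta"] / sub["se"]) ** 2
    r2 = pd.Series(np.nan, index=sub.index)
    formula = pd.Series("", index=sub.index)
    has_eaf = sub["eaf"].notna()
    r2[has_eaf] = 2.0 * sub["eaf"] * (1.0 - sub["eaf"]) * sub["beta"] ** 2
    formula[has_eaf] = "2pq-beta2"
    fb = ~has_eaf
    if fb.any():
        n = sub.loc[fb, "n"]
        if n.isna().any() or (n <= 2).any():
            raise ValueError(
                "R² fallback F/(F+n-2) needs n > 2 for SNPs without eaf"
            )
        r2[fb] = f[fb] / (f[fb] + n - 2.0)
        formula[fb] = "F/(F+n-2)"
    out = pd.DataFrame(
        {
            "snp": sub["snp"],
            "f_stat": f,
            "r2": r2,
            "r2_formula": formula,
            "weak": f < f_min,
        }
    )
    instruments.f_stats = dict(zip(out["snp"], out["f_stat"]))
    instruments.r2_total = float(out["r2"].sum())
    return out
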