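"""Effect-allele alignment between summary-statistics tables.

Rules, per SNP shared by the two tables:

- same alleles → keep as is
- swapped alleles → negate the outcome beta, complement its eaf
- strand-complement alleles (tried only when direct and swapped matching
  both fail) → relabel to the complement, then apply the swap rule
- palindromic (A/T or C/G): allele labels cannot resolve strand, so the
  effect-allele frequencies decide — both outside the ambiguity interval
  and on the same side of 0.5 → keep; opposite sides → negate; either
  frequency inside the interval or missing → removed as ambiguous
- incompatible allele sets → removed

Only signs and labels ever change; |beta| is preserved.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from mrmediate.sumstats import SummaryStats

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

DEFAULT_AF_AMBIGUOUS = (0.4, 0.6)


def is_palindromic(a1: str, a2: str) -> bool:
    """True iff the allele pair is A/T or C/G (strand-ambiguous)."""
    return {a1.upper(), a2.upper()} in ({"A", "T"}, {"C", "G"})


@dataclass
class HarmonizedSet:
    """Effect-aligned exposure/outcome rows ready for MR estimation.

    ``exposures`` holds one (beta, se) column pair per exposure for the
    multivariable case; univariable constructors fill a single exposure.
    """

    table: pd.DataFrame = field(repr=False)
    exposure_labels: list[str] = field(default_factory=lambda: ["exposure"])
    drop_log: pd.DataFrame | None = None

    # column convention: beta_x, se_x (first exposure; aliases beta_x1...),
    # beta_y, se_y, eaf_x, eaf_y

    @property
    def n_snps(self) -> int:
        return len(self.table)

    @property
    def snp_ids(self) -> list[str]:
        return self.table["snp"].tolist()

    @property
    def beta_x(self) -> np.ndarray:
        return self.table["beta_x"].to_numpy(float)

    @property
    def se_x(self) -> np.ndarray:
        return self.table["se_x"].to_numpy(float)

    @property
    def beta_y(self) -> np.ndarray:
        return self.table["beta_y"].to_numpy(float)

    @property
    def se_y(self) -> np.ndarray:
        return self.table["se_y"].to_numpy(float)

    def exposure_matrix(self) -> tuple[np.ndarray, np.ndarray]:
        """(J, K) matrices of exposure betas and SEs, column order = labels."""
        K = len(self.exposure_labels)
        cols_b = ["beta_x"] if K == 1 else [f"beta_x{k + 1}" for k in range(K)]
        cols_s = ["se_x"] if K == 1 else [f"se_x{k + 1}" for k in range(K)]
        return (
            self.table[cols_b].to_numpy(float),
            self.table[cols_s].to_numpy(float),
        )

    def subset(self, snp_ids) -> "HarmonizedSet":
        keep = self.table["snp"].isin(set(snp_ids))
        return HarmonizedSet(
            self.table.loc[keep].reset_index(drop=True),
            list(self.exposure_labels),
            self.drop_log,
        )

    def drop_snps(self, snp_ids, reason: str) -> "HarmonizedSet":
        gone = self.table["snp"].isin(set(snp_ids))
        log = pd.DataFrame(
            {"snp": self.table.loc[gone, "snp"], "disposition": f"removed:{reason}"}
        )
        drop_log = (
            pd.concat([self.drop_log, log], ignore_index=True)
            if self.drop_log is not None
            else log
        )
        return HarmonizedSet(
            self.table.loc[~gone].reset_index(drop=True),
            list(self.exposure_labels),
            drop_log,
        )


def _align_record(
    x: pd.Series, y: pd.Series, af_lo: float, af_hi: float
) -> tuple[str, float, float]:
    """Resolve one SNP.  Returns (disposition, sign for beta_y, eaf_y).

    disposition is ``kept`` / ``flipped`` / ``removed:<reason>``.
    """
    a1x, a2x = x["effect_allele"], x["other_allele"]
    a1y, a2y = y["effect_allele"], y["other_allele"]
    eaf_y = y["eaf"]

    if is_palindromic(a1x, a2x):
        if {a1y, a2y} != {a1x, a2x}:
            return "removed:incompatible-alleles", 1.0, eaf_y
        sign = 1.0
        if a1y != a1x:  # swapped labels
            sign, eaf_y = -sign, 1.0 - eaf_y
        eaf_x = x["eaf"]
        ambiguous = (
            pd.isna(eaf_x)
            or pd.isna(eaf_y)
            or af_lo < eaf_x < af_hi
            or af_lo < eaf_y < af_hi
        )
        if ambiguous:
            return "removed:ambiguous-palindrome", 1.0, y["eaf"]
        if (eaf_x < 0.5) != (eaf_y < 0.5):  # opposite sides → strand flip
            sign, eaf_y = -sign, 1.0 - eaf_y
        disp = "kept" if sign > 0 else "flipped"
        return disp, sign, eaf_y

    if (a1y, a2y) == (a1x, a2x):
        return "kept", 1.0, eaf_y
    if (a1y, a2y) == (a2x, a1x):
        return "flipped", -1.0, 1.0 - eaf_y if pd.notna(eaf_y) else eaf_y
    c1y, c2y = _COMPLEMENT[a1y], _COMPLEMENT[a2y]
    if (c1y, c2y) == (a1x, a2x):
        return "kept", 1.0, eaf_y
    if (c1y, c2y) == (a2x, a1x):
        return "flipped", -1.0, 1.0 - eaf_y if pd.notna(eaf_y) else eaf_y
    return "removed:incompatible-alleles", 1.0, eaf_y


def harmonize_pair(
    exposure: SummaryStats,
    outcome: SummaryStats,
    af_ambiguous: tuple[float, float] = DEFAULT_AF_AMBIGUOUS,
) -> HarmonizedSet:
    """Align ``outcome`` effects to the exposure's effect alleles.

    Raises ``ValueError`` on an empty SNP intersection.  The returned
    drop log records the disposition of every shared SNP.
    """
    af_lo, af_hi = af_ambiguous
    xt = exposure.table.set_index("snp")
    yt = outcome.table.set_index("snp")
    shared = [s for s in exposure.snp_ids if s in yt.index]
    if not shared:
        raise ValueError(
            f"no shared SNPs between {exposure.trait_id} and {outcome.trait_id}"
        )
    rows, log = [], []
    for snp in shared:
        x, y = xt.loc[snp], yt.loc[snp]
        disp, sign, eaf_y = _align_record(x, y, af_lo, af_hi)
        log.append({"snp": snp, "disposition": disp})
        if disp.startswith("removed"):
            continue
        rows.append(
            {
                "snp": snp,
                "effect_allele": x["effect_allele"],
                "other_allele": x["other_allele"],
                "beta_x": x["beta"],
                "se_x": x["se"],
                "pval_x": x["pval"],
                "eaf_x": x["eaf"],
                "beta_y": sign * y["beta"],
                "se_y": y["se"],
                "eaf_y": eaf_y,
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "snp", "effect_allele", "other_allele",
            "beta_x", "se_x", "pval_x", "eaf_x",
            "beta_y", "se_y", "eaf_y",
        ],
    )
    return HarmonizedSet(
        table, [exposure.trait_id], drop_log=pd.DataFrame(log)
    )


def harmonize_multi(
    exposures: list[SummaryStats],
    outcome: SummaryStats,
    snp_ids: list[str],
    af_ambiguous: tuple[float, float] = DEFAULT_AF_AMBIGUOUS,
) -> HarmonizedSet:
    """Multi-exposure harmonization onto the first exposure's orientation.

    A SNP is retained only if it harmonizes cleanly against every
    exposure table and the outcome.
    """
    if not exposures:
        raise ValueError("need at least one exposure")
    first = exposures[0]
    ref = first.subset(snp_ids)
    if ref.n_snps == 0:
        raise ValueError("no requested SNPs present in the first exposure table")
    # outcome aligned to the reference orientation
    base = harmonize_pair(ref, outcome, af_ambiguous)
    keep = set(base.snp_ids)
    tables = [base.table.set_index("snp")]
    logs = [base.drop_log]
    for k, expo in enumerate(exposures[1:], start=2):
        h = harmonize_pair(ref.subset(sorted(keep)), expo, af_ambiguous)
        logs.append(h.drop_log.assign(against=expo.trait_id))
        keep &= set(h.snp_ids)
        tables.append(
            h.table.set_index("snp")[["beta_y", "se_y"]].rename(
                columns={"beta_y": f"beta_x{k}", "se_y": f"se_x{k}"}
            )
        )
    order = [s for s in base.snp_ids if s in keep]
    merged = pd.concat([t.loc[order] for t in tables], axis=1).reset_index()
    merged = merged.rename(columns={"index": "snp"})
    if len(exposures) > 1:
        merged = merged.rename(columns={"beta_x": "beta_x1", "se_x": "se_x1"})
        # keep unsuffixed aliases pointing at the first exposure
        merged["beta_x"] = merged["beta_x1"]
        merged["se_x"] = merged["se_x1"]
    return HarmonizedSet(
        merged,
        [e.trait_id for e in exposures],
        drop_log=pd.concat(logs, ignore_index=True),
    )
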