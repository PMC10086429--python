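"""Data model and I/O for GWAS summary-statistics tables.

The on-disk dialect is tab-delimited UTF-8 with a mandatory header and
``NA`` for missing values.  Canonical columns::

    snp  effect_allele  other_allele  beta  se  pval  eaf  n

``eaf`` may be missing (recorded as NaN, never silently zero).  A missing
``pval`` is imputed from the two-sided normal tail of ``beta/se``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

VALID_ALLELES = frozenset("ACGT")

COLUMNS = ["snp", "effect_allele", "other_allele", "beta", "se", "pval", "eaf", "n"]
MANDATORY = ["snp", "effect_allele", "other_allele", "beta", "se"]


class SchemaError(ValueError):
    """A mandatory column is absent or the file dialect is wrong."""


class RecordError(ValueError):
    """One or more records violate a per-record invariant."""

    def __init__(self, message: str, snp_ids: Sequence[str] = ()):
        super().__init__(message)
        self.snp_ids = list(snp_ids)


class ValidationWarning(UserWarning):
    """Non-fatal inconsistency detected during validation."""


@dataclass
class SummaryStats:
    """Per-SNP association table for one trait.

    Parameters
    ----------
    trait_id:
        Label of the trait (e.g. ``"exposure"``).
    table:
        DataFrame with the canonical columns.  ``beta`` is the per-allele
        effect on the trait scale (log-odds for binary traits, SD units
        for quantitative traits); ``se`` its standard error.
    """

    trait_id: str
    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        self.table = _coerce(self.table)
        validate(self.table)

    @property
    def snp_ids(self) -> list[str]:
        return self.table["snp"].tolist()

    @property
    def n_snps(self) -> int:
        return len(self.table)

    def subset(self, snp_ids: Sequence[str]) -> "SummaryStats":
        """Rows for ``snp_ids``, in the given order; unknown ids ignored."""
        idx = self.table.set_index("snp")
        keep = [s for s in snp_ids if s in idx.index]
        return SummaryStats(self.trait_id, idx.loc[keep].reset_index())

    def record(self, snp_id: str) -> pd.Series:
        row = self.table.loc[self.table["snp"] == snp_id]
        if row.empty:
            raise KeyError(snp_id)
        return row.iloc[0]


def _coerce(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    for col in COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    df = df[COLUMNS]
    df["snp"] = df["snp"].astype(str)
    for col in ("effect_allele", "other_allele"):
        df[col] = df[col].astype(str).str.upper()
    for col in ("beta", "se", "pval", "eaf", "n"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    # impute missing p from the two-sided normal tail of beta/se
    missing_p = df["pval"].isna() & df["beta"].notna() & df["se"].notna()
    if missing_p.any():
        z = df.loc[missing_p, "beta"] / df.loc[missing_p, "se"]
        df.loc[missing_p, "pval"] = 2.0 * stats.norm.sf(np.abs(z))
    return df.reset_index(drop=True)


def validate(df: pd.DataFrame) -> None:
    """Raise on invariant violations; warn on beta/se vs p inconsistency.

    Flags exactly the offending records: every error carries the snp ids
    of the rows that violate the invariant it reports.
    """
    missing = [c for c in MANDATORY if c not in df.columns]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {', '.join(missing)}")

    dup = df.loc[df["snp"].duplicated(), "snp"].unique().tolist()
    if dup:
        raise RecordError(f"duplicated snp id(s): {', '.join(dup)}", dup)

    bad_allele = df.loc[
        ~df["effect_allele"].isin(VALID_ALLELES)
        | ~df["other_allele"].isin(VALID_ALLELES),
        "snp",
    ].tolist()
    if bad_allele:
        raise RecordError(
            f"non-ACGT allele in record(s): {', '.join(bad_allele)}", bad_allele
        )

    same = df.loc[df["effect_allele"] == df["other_allele"], "snp"].tolist()
    if same:
        raise RecordError(
            f"effect_allele equals other_allele for: {', '.join(same)}", same
        )

    bad_se = df.loc[df["se"].isna() | (df["se"] <= 0), "snp"].tolist()
    if bad_se:
        raise RecordError(f"se missing or <= 0 for: {', '.join(bad_se)}", bad_se)

    bad_p = df.loc[df["pval"].notna() & ((df["pval"] < 0) | (df["pval"] > 1)), "snp"]
    if len(bad_p):
        raise RecordError(
            f"pval outside [0,1] for: {', '.join(bad_p.tolist())}", bad_p.tolist()
        )

    bad_n = df.loc[df["n"].notna() & (df["n"] <= 0), "snp"].tolist()
    if bad_n:
        raise RecordError(f"non-positive n for: {', '.join(bad_n)}", bad_n)

    # p vs beta/se consistency: warn if they disagree by more than 2x
    have = df["pval"].notna() & df["beta"].notna() & df["se"].notna()
    if have.any():
        z = (df.loc[have, "beta"] / df.loc[have, "se"]).abs()
        expect = 2.0 * stats.norm.sf(z)
        p = df.loc[have, "pval"]
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(expect > 0, p / expect, np.where(p > 0, np.inf, 1.0))
        off = df.loc[have, "snp"][(ratio > 2.0) | (ratio < 0.5)].tolist()
        if off:
            warnings.warn(
                "pval inconsistent with two-sided normal p of beta/se "
                f"(>2x off) for: {', '.join(off[:20])}",
                ValidationWarning,
                stacklevel=3,
            )


def load_summary_stats(
    path: str | Path,
    trait_id: str | None = None,
    column_map: Mapping[str, str] | None = None,
) -> SummaryStats:
    """Read a tab-delimited summary-statistics file.

    ``column_map`` maps canonical names to names used in the file, e.g.
    ``{"snp": "rsid", "pval": "p"}``.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, na_values=["NA"], keep_default_na=True)
    if column_map:
        rename = {v: k for k, v in column_map.items()}
        df = df.rename(columns=rename)
    missing = [c for c in MANDATORY if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{path.name}: missing mandatory column(s): {', '.join(missing)}"
        )
    return SummaryStats(trait_id or path.stem, df)


def write_summary_stats(stats_: SummaryStats, path: str | Path) -> None:
    """Write in the canonical dialect (see module docstring)."""
    df = stats_.table.copy()
    df.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.10g")


def se_from_ci(lower: float, upper: float, level: float = 0.95) -> float:
    """Standard error implied by a symmetric normal confidence interval.

    ``(upper - lower) / (2 z)`` with ``z`` the standard-normal quantile at
    ``(1 + level) / 2``.  Used to reconstruct SEs from printed intervals.
    """
    if not 0.0 < level < 1.0:
        raise ValueError(f"level must be in (0,1), got {level}")
    if upper <= lower:
        raise ValueError(f"upper ({upper}) must exceed lower ({lower})")
    z = stats.norm.ppf((1.0 + level) / 2.0)
    return (upper - lower) / (2.0 * z)


@dataclass
class LDInfo:
    """Pairwise LD (r²) plus positions for a set of SNPs."""

    snp_ids: list[str]
    r2: np.ndarray
    positions: np.ndarray
    chrom: list[str]

    def __post_init__(self) -> None:
        self.r2 = np.asarray(self.r2, dtype=float)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        k = len(self.snp_ids)
        if self.r2.shape != (k, k):
            raise ValueError(f"r2 must be {k}x{k}, got {self.r2.shape}")
        if not np.allclose(self.r2, self.r2.T):
            raise ValueError("r2 matrix must be symmetric")
        if not np.allclose(np.diag(self.r2), 1.0):
            raise ValueError("r2 diagonal must be 1")
        if (self.r2 < 0).any() or (self.r2 > 1 + 1e-12).any():
            raise ValueError("r2 values must lie in [0,1]")
        if len(self.positions) != k or len(self.chrom) != k:
            raise ValueError("positions/chrom length mismatch")
        self._index = {s: i for i, s in enumerate(self.snp_ids)}

    def __contains__(self, snp_id: str) -> bool:
        return snp_id in self._index

    def pair_r2(self, a: str, b: str) -> float:
        return float(self.r2[self._index[a], self._index[b]])

    def locus(self, snp_id: str) -> tuple[str, int]:
        i = self._index[snp_id]
        return self.chrom[i], int(self.positions[i])


def load_ld_matrix(
    matrix_path: str | Path, loci_path: str | Path | None = None
) -> LDInfo:
    """Read an LD matrix TSV (snp list header + square matrix).

    Positions/chromosomes come from ``loci_path`` (TSV: snp, chrom, pos);
    without it all SNPs are placed at distinct far-apart positions so only
    the r² rule can bind.
    """
    df = pd.read_csv(matrix_path, sep="\t", index_col=0)
    snp_ids = df.columns.tolist()
    r2 = df.to_numpy(dtype=float)
    if loci_path is not None:
        loci = pd.read_csv(loci_path, sep="\t").set_index("snp")
        chrom = [str(loci.loc[s, "chrom"]) for s in snp_ids]
        pos = [int(loci.loc[s, "pos"]) for s in snp_ids]
    else:
        chrom = ["0"] * len(snp_ids)
        pos = [int(1e9) * (i + 1) for i in range(len(snp_ids))]
    return LDInfo(snp_ids, r2, np.array(pos), chrom)


def write_ld_matrix(
    ld: LDInfo, matrix_path: str | Path, loci_path: str | Path | None = None
) -> None:
    df = pd.DataFrame(ld.r2, index=ld.snp_ids, columns=ld.snp_ids)
    df.to_csv(matrix_path, sep="\t", float_format="%.6g")
    if loci_path is not None:
        pd.DataFrame(
            {"snp": ld.snp_ids, "chrom": ld.chrom, "pos": ld.positions}
        ).to_csv(loci_path, sep="\t", index=False)


def load_proxy_table(path: str | Path) -> pd.DataFrame:
    """Proxy lookup table: columns target_snp, proxy_snp, r2."""
    df = pd.read_csv(path, sep="\t")
    need = {"target_snp", "proxy_snp", "r2"}
    if not need.issubset(df.columns):
        raise SchemaError(
            f"proxy table missing column(s): {', '.join(sorted(need - set(df.columns)))}"
        )
    return df
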