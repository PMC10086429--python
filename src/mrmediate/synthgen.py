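"""Synthetic cohorts with a known exposure→mediator→outcome structure.

The generating model is linear with additive genetics and a shared
confounder::

    X = G γ + c U + ε_x
    M = α X + G κ + c U + ε_m
    Y = θ_d X + β_m M + G π + c U + ε_y

so the true total effect of X on Y is ``θ_d + α β_m`` and the true
proportion mediated is ``α β_m / (θ_d + α β_m)``.  Per-trait GWAS are run
on disjoint subsamples by default (two-sample design) and written in the
:mod:`mrmediate.sumstats` dialect, with optional allele-label flips and
palindromic allele assignments to exercise harmonization.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from mrmediate.sumstats import (
    LDInfo,
    SummaryStats,
    write_ld_matrix,
    write_summary_stats,
)

# non-palindromic allele pairs used for the "easy" SNPs
_PLAIN_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"), ("G", "A"), ("C", "A")]
_PALINDROMIC_PAIRS = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]


@dataclass
class SimTruth:
    """Generating parameters of one synthetic dataset.

    ``gamma``, ``kappa``, ``pi`` and ``maf`` may be scalars (recycled to
    all J SNPs) or length-J arrays.
    """

    J: int = 100
    n_per_trait: int = 20_000
    gamma: np.ndarray | float = 0.08
    kappa: np.ndarray | float = 0.0
    pi: np.ndarray | float = 0.0
    alpha: float = 0.0
    beta_m: float = 0.0
    theta_d: float = 0.0
    confounder_load: float = 0.0
    maf: np.ndarray | float = 0.3
    palindromic_frac: float = 0.0
    flip_frac: float = 0.0
    ld_blocks: tuple[int, float] = (1, 0.0)  # (block size, within-block r²)
    noise_sd: tuple[float, float, float] = (1.0, 1.0, 1.0)  # ε scales for X, M, Y
    overlap_frac: float = 0.0
    binary_outcome: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.J <= 0 or self.n_per_trait <= 0:
            raise ValueError("J and n_per_trait must be positive")
        for name in ("gamma", "kappa", "pi", "maf"):
            val = np.broadcast_to(
                np.asarray(getattr(self, name), dtype=float), (self.J,)
            ).copy()
            setattr(self, name, val)
        if not np.all((self.maf > 0) & (self.maf <= 0.5)):
            raise ValueError("maf must lie in (0, 0.5]")
        block, r2 = self.ld_blocks
        if block < 1 or not 0.0 <= r2 <= 1.0:
            raise ValueError("ld_blocks must be (size >= 1, r2 in [0,1])")
        self.noise_sd = tuple(float(s) for s in self.noise_sd)
        if len(self.noise_sd) != 3 or any(s <= 0 for s in self.noise_sd):
            raise ValueError("noise_sd must be three positive scales")

    @property
    def theta_total(self) -> float:
        """True total effect of X on Y."""
        return self.theta_d + self.alpha * self.beta_m

    @property
    def proportion_mediated(self) -> float:
        if self.theta_total == 0:
            return float("nan")
        return self.alpha * self.beta_m / self.theta_total

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, np.ndarray):
                d[k] = v.tolist()
        d["theta_total"] = self.theta_total
        d["proportion_mediated"] = self.proportion_mediated
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "SimTruth":
        d = json.loads(text)
        d.pop("theta_total", None)
        d.pop("proportion_mediated", None)
        d["ld_blocks"] = tuple(d.get("ld_blocks", (1, 0.0)))
        return cls(**d)


@dataclass
class Cohort:
    genotypes: np.ndarray  # (n_total, J) dosages in {0,1,2}
    X: np.ndarray
    M: np.ndarray
    Y: np.ndarray
    truth: SimTruth
    seed: int


def _block_genotypes(rng: np.random.Generator, n: int, truth: SimTruth) -> np.ndarray:
    """Dosages with block LD via a Gaussian copula on haplotypes.

    Within a block the latent haplotype normals share correlation
    ``sqrt(r2)`` so indicator (allele) correlation — and hence genotype
    r² — is approximately the requested value.
    """
    J = truth.J
    block, r2 = truth.ld_blocks
    if block == 1 or r2 == 0.0:
        return rng.binomial(2, truth.maf, size=(n, J)).astype(np.int8)
    rho = float(np.sqrt(r2))
    haps = np.empty((2, n, J))
    for h in range(2):
        shared = rng.standard_normal((n, (J + block - 1) // block))
        own = rng.standard_normal((n, J))
        block_of = np.arange(J) // block
        z = np.sqrt(rho) * shared[:, block_of] + np.sqrt(1 - rho) * own
        haps[h] = z
    thresh = stats.norm.ppf(truth.maf)  # allele carried iff z < thresh
    return (haps < thresh).sum(axis=0).astype(np.int8)


def simulate_cohort(truth: SimTruth) -> Cohort:
    """Draw one cohort of genotypes and the three phenotypes.

    The cohort holds enough individuals for three disjoint per-trait
    subsamples (plus overlap handling downstream).
    """
    rng = np.random.default_rng(truth.seed)
    n_total = 3 * truth.n_per_trait
    G = _block_genotypes(rng, n_total, truth)
    Gf = G.astype(float)
    U = rng.standard_normal(n_total)
    c = truth.confounder_load
    sd_x, sd_m, sd_y = truth.noise_sd
    X = Gf @ truth.gamma + c * U + sd_x * rng.standard_normal(n_total)
    M = truth.alpha * X + Gf @ truth.kappa + c * U + sd_m * rng.standard_normal(n_total)
    Y = (
        truth.theta_d * X
        + truth.beta_m * M
        + Gf @ truth.pi
        + c * U
        + sd_y * rng.standard_normal(n_total)
    )
    if truth.binary_outcome:
        Y = (Y > np.median(Y)).astype(float)
    return Cohort(G, X, M, Y, truth, truth.seed)


def trait_subsamples(truth: SimTruth) -> dict[str, np.ndarray]:
    """Index sets per trait: disjoint unless ``overlap_frac`` > 0."""
    n = truth.n_per_trait
    idx = {
        "X": np.arange(0, n),
        "M": np.arange(n, 2 * n),
        "Y": np.arange(2 * n, 3 * n),
    }
    if truth.overlap_frac > 0:
        k = int(round(truth.overlap_frac * n))
        # outcome sample re-uses the first k exposure individuals
        idx["Y"] = np.concatenate([idx["X"][:k], idx["Y"][k:]])
    return idx


def compute_gwas_summary(
    cohort: Cohort,
    trait: str,
    subsample: np.ndarray,
    trait_id: str | None = None,
) -> SummaryStats:
    """Per-SNP simple linear regression of a trait on genotype dosage.

    Monomorphic SNPs in the subsample have no defined SE and are dropped
    with a warning.
    """
    if len(subsample) == 0:
        raise ValueError("subsample must be non-empty")
    y = {"X": cohort.X, "M": cohort.M, "Y": cohort.Y}[trait][subsample]
    G = cohort.genotypes[subsample].astype(float)
    n, J = G.shape
    g_mean = G.mean(axis=0)
    g_var = G.var(axis=0)
    mono = g_var == 0.0
    if mono.any():
        warnings.warn(
            f"dropping {int(mono.sum())} monomorphic SNP(s) in {trait} subsample",
            stacklevel=2,
        )
    yc = y - y.mean()
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = (G - g_mean).T @ yc / (n * g_var)
        resid_var = (
            np.sum(yc**2) / n - beta**2 * g_var
        )  # per-SNP residual variance of the simple regression
        se = np.sqrt(resid_var / (g_var * (n - 2)))
    z = beta / se
    pval = 2.0 * stats.norm.sf(np.abs(z))
    df = pd.DataFrame(
        {
            "snp": [f"rs{j + 1}" for j in range(J)],
            "effect_allele": "A",
            "other_allele": "G",
            "beta": beta,
            "se": se,
            "pval": pval,
            "eaf": g_mean / 2.0,
            "n": n,
        }
    )
    df = df.loc[~mono].reset_index(drop=True)
    return SummaryStats(trait_id or trait, df)


def truth_ld_info(truth: SimTruth) -> LDInfo:
    """Block-diagonal LD matrix implied by ``truth.ld_blocks``.

    Blocks sit 20 Mb apart on one chromosome with 1 kb spacing inside a
    block, so the distance window never splits a block but always
    separates two blocks.
    """
    J = truth.J
    block, r2 = truth.ld_blocks
    snp_ids = [f"rs{j + 1}" for j in range(J)]
    block_of = np.arange(J) // block
    mat = np.where(block_of[:, None] == block_of[None, :], r2, 0.0)
    np.fill_diagonal(mat, 1.0)
    pos = block_of * 20_000_000 + (np.arange(J) % block) * 1_000 + 1
    return LDInfo(snp_ids, mat, pos, ["1"] * J)


def _assign_alleles(
    rng: np.random.Generator, J: int, palindromic_frac: float
) -> tuple[list[tuple[str, str]], np.ndarray]:
    n_pal = int(round(palindromic_frac * J))
    pal_idx = rng.choice(J, size=n_pal, replace=False) if n_pal else np.array([], int)
    is_pal = np.zeros(J, dtype=bool)
    is_pal[pal_idx] = True
    pairs = []
    for j in range(J):
        pool = _PALINDROMIC_PAIRS if is_pal[j] else _PLAIN_PAIRS
        pairs.append(pool[rng.integers(len(pool))])
    return pairs, is_pal


def make_dataset(truth: SimTruth, out_dir: str | Path) -> dict[str, Path]:
    """Simulate, summarize, decorate with alleles/flips, and write a bundle.

    Writes ``exposure.tsv``, ``mediator.tsv``, ``outcome.tsv``,
    ``ld_matrix.tsv``, ``loci.tsv``, ``proxies.tsv`` and ``truth.json``.
    The truth file records the flipped and palindromic SNP ids plus the
    pre-flip outcome effects so harmonization can be verified exactly.
    Deterministic: the same truth (including seed) yields a byte-identical
    bundle.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort = simulate_cohort(truth)
    subs = trait_subsamples(truth)
    tables = {
        "exposure": compute_gwas_summary(cohort, "X", subs["X"], "exposure"),
        "mediator": compute_gwas_summary(cohort, "M", subs["M"], "mediator"),
        "outcome": compute_gwas_summary(cohort, "Y", subs["Y"], "outcome"),
    }

    rng = np.random.default_rng(np.random.SeedSequence([truth.seed, 7]))
    pairs, is_pal = _assign_alleles(rng, truth.J, truth.palindromic_frac)
    allele_of = {f"rs{j + 1}": pairs[j] for j in range(truth.J)}
    pal_ids = [f"rs{j + 1}" for j in range(truth.J) if is_pal[j]]

    for tab in tables.values():
        ids = tab.table["snp"]
        tab.table["effect_allele"] = [allele_of[s][0] for s in ids]
        tab.table["other_allele"] = [allele_of[s][1] for s in ids]

    # flip allele labels (and sign/eaf) on a fraction of outcome rows
    y = tables["outcome"].table
    pre_flip = y[["snp", "beta", "eaf"]].copy()
    n_flip = int(round(truth.flip_frac * len(y)))
    flip_rows = (
        rng.choice(len(y), size=n_flip, replace=False) if n_flip else np.array([], int)
    )
    flipped_ids = y.loc[flip_rows, "snp"].tolist()
    ea = y.loc[flip_rows, "effect_allele"].copy()
    y.loc[flip_rows, "effect_allele"] = y.loc[flip_rows, "other_allele"].to_numpy()
    y.loc[flip_rows, "other_allele"] = ea.to_numpy()
    y.loc[flip_rows, "beta"] = -y.loc[flip_rows, "beta"]
    y.loc[flip_rows, "eaf"] = 1.0 - y.loc[flip_rows, "eaf"]

    paths: dict[str, Path] = {}
    for name, tab in tables.items():
        paths[name] = out / f"{name}.tsv"
        write_summary_stats(tab, paths[name])

    ld = truth_ld_info(truth)
    paths["ld_matrix"] = out / "ld_matrix.tsv"
    paths["loci"] = out / "loci.tsv"
    write_ld_matrix(ld, paths["ld_matrix"], paths["loci"])

    # proxies: within-block neighbours qualify when block r² is high
    block, r2 = truth.ld_blocks
    rows = []
    if block > 1:
        for j in range(truth.J):
            b = j // block
            for k in range(b * block, min((b + 1) * block, truth.J)):
                if k != j:
                    rows.append((f"rs{j + 1}", f"rs{k + 1}", r2))
    proxies = pd.DataFrame(rows, columns=["target_snp", "proxy_snp", "r2"])
    paths["proxies"] = out / "proxies.tsv"
    proxies.to_csv(paths["proxies"], sep="\t", index=False, float_format="%.6g")

    truth_doc = json.loads(truth.to_json())
    truth_doc["flipped_snps"] = flipped_ids
    truth_doc["palindromic_snps"] = pal_ids
    # store pre-flip values in the writer's float format so recovery
    # after read-back is exact
    truth_doc["outcome_pre_flip"] = {
        r.snp: {"beta": float(f"{r.beta:.10g}"), "eaf": float(f"{r.eaf:.10g}")}
        for r in pre_flip.itertuples()
    }
    paths["truth"] = out / "truth.json"
    paths["truth"].write_text(json.dumps(truth_doc, indent=2, sort_keys=True))
    return paths
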