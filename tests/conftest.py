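"""Shared fixtures and builders for the test suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from mrmediate.harmonize import HarmonizedSet
from mrmediate.sumstats import SummaryStats
from mrmediate.synthgen import SimTruth


def make_sumstats(trait_id: str, rows: list[dict]) -> SummaryStats:
    return SummaryStats(trait_id, pd.DataFrame(rows))


def make_hset(bx, sx, by, sy, snp_ids=None) -> HarmonizedSet:
    """HarmonizedSet straight from effect arrays (single exposure)."""
    bx = np.asarray(bx, float)
    J = len(bx)
    return HarmonizedSet(
        pd.DataFrame(
            {
                "snp": snp_ids or [f"rs{i + 1}" for i in range(J)],
                "beta_x": bx,
                "se_x": np.broadcast_to(np.asarray(sx, float), (J,)),
                "beta_y": np.asarray(by, float),
                "se_y": np.broadcast_to(np.asarray(sy, float), (J,)),
            }
        )
    )


def make_mv_hset(X, SX, y, sy, labels) -> HarmonizedSet:
    """Multi-exposure HarmonizedSet from design matrices."""
    X = np.asarray(X, float)
    J, K = X.shape
    cols = {"snp": [f"rs{i + 1}" for i in range(J)]}
    for k in range(K):
        cols[f"beta_x{k + 1}"] = X[:, k]
        cols[f"se_x{k + 1}"] = np.broadcast_to(np.asarray(SX, float), (J, K))[:, k]
    cols["beta_x"] = X[:, 0]
    cols["se_x"] = cols["se_x1"]
    cols["beta_y"] = np.asarray(y, float)
    cols["se_y"] = np.broadcast_to(np.asarray(sy, float), (J,))
    return HarmonizedSet(pd.DataFrame(cols), list(labels))


def recovery_truth(seed: int, n_per_trait: int = 20_000) -> SimTruth:
    """Canonical mediation recovery design used across recovery tests.

    25 SNPs instrument the exposure, a disjoint 25 the mediator, 50 are
    null; no pleiotropy, no confounding, disjoint per-trait samples.
    True total effect −0.4397, true proportion mediated ≈ 15.85%.
    """
    gamma = np.r_[np.full(25, 0.3), np.zeros(75)]
    kappa = np.r_[np.zeros(25), np.full(25, 0.3), np.zeros(50)]
    return SimTruth(
        J=100,
        n_per_trait=n_per_trait,
        gamma=gamma,
        kappa=kappa,
        maf=0.4,
        alpha=-0.17,
        beta_m=0.41,
        theta_d=-0.37,
        noise_sd=(1.0, 1.0, 2.0),
        seed=seed,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def three_snp_hset():
    """The hand-computed WLS oracle fixture: estimate 0.3, fixed se 0.1/sqrt(6)."""
    return make_hset(
        bx=[1.0, 1.0, 2.0], sx=0.0, by=[0.2, 0.4, 0.6], sy=[0.1, 0.1, 0.1]
    )


@pytest.fixture
def small_bundle(tmp_path):
    """A small written dataset bundle exercising flips and palindromes."""
    from mrmediate.synthgen import make_dataset

    rng = np.random.default_rng(5)
    truth = SimTruth(
        J=50,
        n_per_trait=3000,
        gamma=0.15,
        maf=rng.uniform(0.1, 0.5, 50),
        palindromic_frac=0.2,
        flip_frac=0.5,
        seed=11,
    )
    paths = make_dataset(truth, tmp_path / "bundle")
    return truth, paths
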