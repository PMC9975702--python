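"""Shared fixtures: synthetic cohorts, confounds, spin geometry, oracles."""

import numpy as np
import pytest
from scipy.linalg import eigh

from neuromodes.blocks import DataBlock
from neuromodes.decompose import DecompositionConfig, run_full_decomposition
from neuromodes.project import ParcelGeometry
from neuromodes.simulate import (generate_linked_blocks, make_confound_table,
                                 make_parcel_geometry_frame)


def center(block: DataBlock) -> DataBlock:
    """Column-center a block (stand-in for full de-confounding in tests)."""
    v = block.values - block.values.mean(axis=0)
    return DataBlock(v, list(block.participant_ids), list(block.variable_names))


def cca_oracle(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Brute-force canonical correlations via the generalized eigenproblem.

    Solves [[0, Sxy], [Syx, 0]] v = rho [[Sxx, 0], [0, Syy]] v directly;
    independent of the QR/SVD route used by the package. Each block is
    first reduced to its non-degenerate principal subspace so the
    right-hand matrix is positive definite even for rank-deficient input.
    """
    def _reduce(A):
        A = A - A.mean(axis=0)
        U, S, Vt = np.linalg.svd(A, full_matrices=False)
        keep = S > S[0] * max(A.shape) * np.finfo(float).eps
        return A @ Vt[keep].T

    X = _reduce(np.asarray(X, float))
    Y = _reduce(np.asarray(Y, float))
    n = X.shape[0]
    Sxx = X.T @ X / (n - 1)
    Syy = Y.T @ Y / (n - 1)
    Sxy = X.T @ Y / (n - 1)
    p, q = X.shape[1], Y.shape[1]
    A = np.block([[np.zeros((p, p)), Sxy], [Sxy.T, np.zeros((q, q))]])
    B = np.block([[Sxx, np.zeros((p, q))], [np.zeros((q, p)), Syy]])
    w = eigh(A, B, eigvals_only=True)
    return np.sort(w)[::-1][: min(p, q)]


class PlantedCohort:
    """n=2600 linked cohort with 2 planted modes; first 2000 fitted, 600 held out."""

    def __init__(self):
        brain, behav, truth = generate_linked_blocks(
            n=2600, p_brain=120, p_behav=200, k_true=2,
            cross_block_corr=[0.9, 0.7], noise_sd=1.0, seed=11)
        self.truth = truth
        train = np.arange(2000)
        held = np.arange(2000, 2600)
        self.brain_train = center(brain.take_rows(train))
        self.behav_train = center(behav.take_rows(train))
        self.brain_held = center(brain.take_rows(held))
        self.behav_held = center(behav.take_rows(held))
        self.train_idx = train
        self.held_idx = held
        self.config = DecompositionConfig(n_comp_brain=30, n_comp_behav=30,
                                          n_modes=2, seed=11)
        self.modes = run_full_decomposition(self.brain_train, self.behav_train,
                                            self.config)

    def match_to_truth(self, loadings: np.ndarray, factors: np.ndarray):
        """(mode -> planted factor index, |r|) by best absolute correlation."""
        K = loadings.shape[1]
        pairs = []
        for k in range(K):
            rs = [abs(np.corrcoef(loadings[:, k], factors[:, j])[0, 1])
                  for j in range(factors.shape[1])]
            pairs.append((int(np.argmax(rs)), float(max(rs))))
        return pairs


@pytest.fixture(scope="session")
def planted():
    return PlantedCohort()


@pytest.fixture(scope="session")
def small_linked():
    """n=240 linked dataset with confounds, cheap enough for repeated fits."""
    brain, behav, truth = generate_linked_blocks(
        n=240, p_brain=30, p_behav=40, k_true=2, cross_block_corr=[0.9, 0.7],
        noise_sd=1.0, seed=3)
    conf = make_confound_table(240, seed=4)
    return brain, behav, truth, conf


@pytest.fixture(scope="session")
def geometry():
    return ParcelGeometry(make_parcel_geometry_frame(n_per_hemi=34, seed=2))
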