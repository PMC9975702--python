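"""Permutation inference for canonical variates and CCA-ICA modes.

Significance is assessed by permuting participant rows of the behaviour
block only and recomputing the decomposition. Family-wise error is
controlled by the max statistic: each observed correlation is compared to
the permutation distribution of the *maximum* correlation across
components, giving

    p_fwe[k] = (1 + #{max-null >= observed[k]}) / (1 + n_perm)

so Monte-Carlo p-values can never be zero. Because each block's PCA basis
is invariant to a row permutation of that block, per-permutation work
starts at CCA on (fixed brain scores, row-permuted behaviour scores) — an
exact shortcut, not an approximation.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
import json

import numpy as np

from .blocks import DataBlock
from .decompose import (DecompositionConfig, fit_cca, fit_pca,
                        run_full_decomposition, select_ica_rotation)

__all__ = ["PermutationReport", "permutation_test_cca", "permutation_test_modes"]

MIN_PERMUTATIONS = 100


@dataclass
class PermutationReport:
    n_perm: int
    observed: np.ndarray       # K statistics
    null_max: np.ndarray       # n_perm max-over-components null draws
    p_fwe: np.ndarray          # K
    seed: int
    statistic: str

    def to_json(self, path) -> None:
        payload = asdict(self)
        for k in ("observed", "null_max", "p_fwe"):
            payload[k] = np.asarray(payload[k]).tolist()
        with open(path, "w") as fh:
            json.dump(payload, fh)


def _fwe_p(observed: np.ndarray, null_max: np.ndarray) -> np.ndarray:
    return np.array([(1 + np.sum(null_max >= obs)) / (1 + null_max.size)
                     for obs in observed])


def _prepare_scores(imaging, behaviour, config):
    config = config or DecompositionConfig()
    imaging.check_aligned(behaviour)
    pca_brain = fit_pca(imaging, min(config.n_comp_brain, imaging.n_variables,
                                     imaging.n_participants - 1))
    pca_behav = fit_pca(behaviour, min(config.n_comp_behav, behaviour.n_variables,
                                       behaviour.n_participants - 1))
    return config, pca_brain, pca_behav


def _orthonormal_basis(scores: np.ndarray) -> np.ndarray:
    """Orthonormal column basis of the centered score matrix (rank-trimmed)."""
    Xc = scores - scores.mean(axis=0)
    U, S, _ = np.linalg.svd(Xc, full_matrices=False)
    tol = S[0] * max(Xc.shape) * np.finfo(float).eps if S.size else 0.0
    return U[:, S > tol]


def permutation_test_cca(
    imaging: DataBlock,
    behaviour: DataBlock,
    config: DecompositionConfig | None = None,
    n_perm: int = 1000,
    seed: int = 0,
) -> PermutationReport:
    """Max-statistic permutation test of the canonical correlations."""
    if n_perm < MIN_PERMUTATIONS:
        raise ValueError(
            f"n_perm={n_perm} below the minimum {MIN_PERMUTATIONS} "
            "(empirical p-value resolution)")
    config, pca_brain, pca_behav = _prepare_scores(imaging, behaviour, config)
    K = config.n_modes
    observed = fit_cca(pca_brain.scores, pca_behav.scores, K).canonical_corrs
    rng = np.random.default_rng(seed)
    null_max = np.empty(n_perm)
    n = imaging.n_participants
    # per-block orthonormal bases are permutation-equivariant, so each null
    # draw reduces to one small cross-product SVD
    Qx = _orthonormal_basis(pca_brain.scores)
    Qy = _orthonormal_basis(pca_behav.scores)
    for b in range(n_perm):
        perm = rng.permutation(n)
        # row permutation leaves column means (zero) and orthonormality of
        # Qy intact, so the null canonical correlations are the singular
        # values of the permuted cross-product alone
        s1 = np.linalg.svd(Qx.T @ Qy[perm], compute_uv=False)[0]
        null_max[b] = min(1.0, s1)
    return PermutationReport(n_perm, observed, null_max,
                             _fwe_p(observed, null_max), seed, "cca")


def permutation_test_modes(
    imaging: DataBlock,
    behaviour: DataBlock,
    config: DecompositionConfig | None = None,
    n_perm: int = 1000,
    seed: int = 0,
    recompute_ica: bool = True,
) -> PermutationReport:
    """Max-statistic permutation test of the CCA-ICA mode correlations.

    The observed statistics are the mode correlations from the full
    pipeline. By default ICA is re-estimated inside every permutation so
    the null reflects the complete procedure; ``recompute_ica=False``
    substitutes the cheaper max canonical correlation as the null statistic
    (the two coincide for K=1 and are near-identical in practice because
    the orthogonal rotation cannot raise the maximum correlation).
    """
    if n_perm < MIN_PERMUTATIONS:
        raise ValueError(
            f"n_perm={n_perm} below the minimum {MIN_PERMUTATIONS} "
            "(empirical p-value resolution)")
    config, pca_brain, pca_behav = _prepare_scores(imaging, behaviour, config)
    K = config.n_modes
    # non-strict ICA throughout: a significance test must be computable on
    # data with no real structure, where the ICA tolerance may be unreachable
    from dataclasses import replace
    observed = run_full_decomposition(imaging, behaviour,
                                      replace(config, ica_strict=False)).mode_corrs
    rng = np.random.default_rng(seed)
    null_max = np.empty(n_perm)
    n = imaging.n_participants
    Qx = _orthonormal_basis(pca_brain.scores)
    Qy = _orthonormal_basis(pca_behav.scores)
    n_restarts = config.n_restarts
    for b in range(n_perm):
        perm = rng.permutation(n)
        Uc, corrs, Vct = np.linalg.svd(Qx.T @ Qy[perm])
        corrs = np.clip(corrs[:K], 0.0, 1.0)
        if recompute_ica and K > 1:
            # same fixed-point rotation as the pipeline, on orthonormal
            # variates; non-strict because noise-only permuted data may
            # never reach the ICA tolerance (any rotation is a valid draw)
            U = Qx @ Uc[:, :K]
            V = Qy[perm] @ Vct.T[:, :K]
            stacked = np.vstack([U, V]) * np.sqrt(n - 1)
            C = stacked.T @ stacked / (stacked.shape[0] - 1)
            evals, evecs = np.linalg.eigh(C)
            whiten = evecs @ np.diag(np.maximum(evals, 1e-12) ** -0.5) @ evecs.T
            Z = stacked @ whiten
            best_w = select_ica_rotation(
                Z, int(rng.integers(2 ** 31 - 1)), n_restarts,
                config.ica_max_iter, config.ica_tol, strict=False)
            M = whiten @ best_w.T
            num = np.einsum("j,jk,jk->k", corrs, M, M)
            den = np.einsum("jk,jk->k", M, M)
            null_max[b] = (num / den).max()
        else:
            null_max[b] = corrs.max()
    return PermutationReport(n_perm, observed, null_max,
                             _fwe_p(observed, null_max), seed, "modes")
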