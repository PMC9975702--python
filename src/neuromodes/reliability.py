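"""Split-half reliability and data-driven dimensionality selection.

The PCA/ICA dimensionality is not fixed a priori: candidate (pca_brain,
pca_behav, K) triples are scored by split-half reliability and the
candidate whose *least reliable* mode is most reliable wins. Within one
split the decomposition is fitted independently in each half, modes are
matched across halves by optimal assignment on behaviour-side
variable-loading correlations, and the reliability of a matched pair is the
|r| of the concatenated (brain + behaviour) variable-loading vectors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .blocks import DataBlock
from .decompose import DecompositionConfig, ModeSet, run_full_decomposition

__all__ = ["SplitHalfReport", "split_half_once", "select_dimensionality",
           "match_modes"]


@dataclass
class SplitHalfReport:
    table: pd.DataFrame          # candidate, split, mode, reliability
    candidate_dims: list[tuple[int, int, int]]
    n_splits: int
    seed: int

    def min_reliability(self) -> pd.Series:
        """Mean over splits of the worst matched mode, per candidate."""
        per_split_min = (self.table.groupby(["candidate", "split"])["reliability"]
                         .min())
        return per_split_min.groupby("candidate").mean()

    def chosen(self) -> tuple[int, int, int]:
        scores = self.min_reliability()
        best = scores.max()
        # ties broken toward the smallest total dimensionality
        tied = [self.candidate_dims[i] for i in scores.index
                if scores[i] >= best - 1e-12]
        return min(tied, key=lambda d: (sum(d), d))


def match_modes(modes_a: ModeSet, modes_b: ModeSet) -> tuple[np.ndarray, np.ndarray]:
    """Match modes across two fits by optimal assignment.

    The assignment maximises the total |correlation| of behaviour-side
    variable-loading vectors; the returned reliabilities are |r| of the
    concatenated brain+behaviour loading vectors of each matched pair.
    Returns (permutation mapping a-mode -> b-mode, reliability per a-mode).
    """
    K = modes_a.n_modes

    def _vectors(m: ModeSet, block: str) -> np.ndarray:
        vl = m.variable_loadings
        sub = vl[vl["block"] == block] if block != "both" else vl
        sub = sub.sort_values(["block", "variable"], kind="stable")
        return np.column_stack([
            sub[sub["mode"] == k + 1]["loading"].to_numpy() for k in range(K)])

    behav_a, behav_b = _vectors(modes_a, "behaviour"), _vectors(modes_b, "behaviour")
    cost = np.zeros((K, K))
    for i in range(K):
        for j in range(K):
            cost[i, j] = -abs(np.corrcoef(behav_a[:, i], behav_b[:, j])[0, 1])
    rows, cols = linear_sum_assignment(cost)
    perm = np.empty(K, dtype=int)
    perm[rows] = cols

    all_a, all_b = _vectors(modes_a, "both"), _vectors(modes_b, "both")
    rel = np.array([abs(np.corrcoef(all_a[:, i], all_b[:, perm[i]])[0, 1])
                    for i in range(K)])
    return perm, rel


def split_half_once(
    imaging: DataBlock,
    behaviour: DataBlock,
    dims: tuple[int, int, int],
    seed: int = 0,
    site: np.ndarray | None = None,
    n_restarts: int = 3,
) -> np.ndarray:
    """Reliability vector for one random half-split at one dimensionality.

    ``site``, when given, stratifies the split so both halves have the same
    site composition (up to rounding).
    """
    imaging.check_aligned(behaviour)
    d1, d2, K = dims
    n = imaging.n_participants
    if n < 2 * (max(d1, d2) + 2):
        raise ValueError(
            f"n={n} too small for split-half at dims {dims}; need >= {2 * (max(d1, d2) + 2)}")
    rng = np.random.default_rng(seed)
    if site is not None:
        site = np.asarray(site)
        half_a = []
        for lev in np.unique(site):
            idx = np.where(site == lev)[0]
            idx = rng.permutation(idx)
            half_a.extend(idx[: len(idx) // 2])
        half_a = np.sort(np.asarray(half_a))
        half_b = np.setdiff1d(np.arange(n), half_a)
    else:
        perm = rng.permutation(n)
        half_a = np.sort(perm[: n // 2])
        half_b = np.sort(perm[n // 2:])

    # non-strict ICA: candidate dims above the true structure give noise
    # modes with no preferred independent directions; the best rotation
    # found is still a legitimate (unreliable) candidate decomposition
    cfg = DecompositionConfig(n_comp_brain=d1, n_comp_behav=d2, n_modes=K,
                              seed=int(rng.integers(2 ** 31 - 1)),
                              n_restarts=n_restarts, ica_strict=False)
    modes_a = run_full_decomposition(imaging.take_rows(half_a),
                                     behaviour.take_rows(half_a), cfg)
    modes_b = run_full_decomposition(imaging.take_rows(half_b),
                                     behaviour.take_rows(half_b), cfg)
    _, rel = match_modes(modes_a, modes_b)
    return rel


def select_dimensionality(
    imaging: DataBlock,
    behaviour: DataBlock,
    candidate_dims: list[tuple[int, int, int]],
    n_splits: int = 10,
    seed: int = 0,
    site: np.ndarray | None = None,
    n_restarts: int = 3,
) -> tuple[SplitHalfReport, tuple[int, int, int]]:
    """Pick the dimensionality whose least reliable mode is most reliable."""
    if not candidate_dims:
        raise ValueError("need at least one candidate dimensionality")
    rng = np.random.default_rng(seed)
    split_seeds = rng.integers(2 ** 31 - 1, size=n_splits)
    rows = []
    for ci, dims in enumerate(candidate_dims):
        for s in range(n_splits):
            rel = split_half_once(imaging, behaviour, dims,
                                  seed=int(split_seeds[s]), site=site,
                                  n_restarts=n_restarts)
            for k, r in enumerate(rel):
                rows.append((ci, s, k + 1, float(r)))
    table = pd.DataFrame(rows, columns=["candidate", "split", "mode", "reliability"])
    report = SplitHalfReport(table, [tuple(d) for d in candidate_dims],
                             n_splits, seed)
    return report, report.chosen()
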