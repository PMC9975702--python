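"""Statsmodels-style model/results facade over the decomposition pipeline.

``BrainBehaviourCCAICA`` is built from two aligned, preprocessed data
blocks; ``fit()`` returns a :class:`CCAICAResults` carrying the fitted
modes, their between-side correlations, and methods for permutation
inference, split-half reliability, out-of-sample projection and bootstrap
validation.

Example
-------
>>> from neuromodes import simulate, model
>>> brain, behav, truth = simulate.generate_linked_blocks(n=500, seed=7)
>>> res = model.BrainBehaviourCCAICA(brain, behav, n_modes=2, seed=7).fit()
>>> res.mode_corrs          # doctest: +SKIP
array([0.91..., 0.72...])
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .blocks import ConfoundTable, DataBlock
from .decompose import DecompositionConfig, ModeSet, run_full_decomposition
from .inference import (PermutationReport, permutation_test_cca,
                        permutation_test_modes)
from .project import (BootstrapReport, bootstrap_phenotype_correlations,
                      project_out_of_sample)
from .reliability import SplitHalfReport, select_dimensionality

__all__ = ["BrainBehaviourCCAICA", "CCAICAResults"]


class BrainBehaviourCCAICA:
    """PCA -> CCA -> ICA model linking an imaging and a behaviour block.

    Parameters
    ----------
    imaging, behaviour
        Row-aligned, complete (preprocessed) data blocks.
    n_comp_brain, n_comp_behav
        PCA dimensionality per block (use :meth:`select_dimensionality`
        for the data-driven choice).
    n_modes
        Number of CCA-ICA modes to extract.
    seed
        Controls ICA restarts; the fit is deterministic given the seed.
    """

    def __init__(self, imaging: DataBlock, behaviour: DataBlock,
                 n_comp_brain: int = 30, n_comp_behav: int = 30,
                 n_modes: int = 2, seed: int = 0, n_restarts: int = 5):
        imaging.check_aligned(behaviour)
        self.imaging = imaging
        self.behaviour = behaviour
        self.config = DecompositionConfig(
            n_comp_brain=n_comp_brain, n_comp_behav=n_comp_behav,
            n_modes=n_modes, seed=seed, n_restarts=n_restarts)

    @classmethod
    def from_dataframes(cls, imaging: pd.DataFrame, behaviour: pd.DataFrame,
                        **kwargs) -> "BrainBehaviourCCAICA":
        return cls(DataBlock.from_frame(imaging), DataBlock.from_frame(behaviour),
                   **kwargs)

    def fit(self) -> "CCAICAResults":
        modes = run_full_decomposition(self.imaging, self.behaviour, self.config)
        return CCAICAResults(self, modes)

    def select_dimensionality(self, candidate_dims, n_splits: int = 10,
                              seed: int | None = None,
                              site: np.ndarray | None = None
                              ) -> tuple[SplitHalfReport, tuple[int, int, int]]:
        """Split-half reliability selection of (pca_brain, pca_behav, K)."""
        report, chosen = select_dimensionality(
            self.imaging, self.behaviour, candidate_dims, n_splits=n_splits,
            seed=self.config.seed if seed is None else seed, site=site)
        self.config.n_comp_brain, self.config.n_comp_behav, self.config.n_modes = chosen
        return report, chosen

    def permutation_test(self, statistic: str = "modes", n_perm: int = 1000,
                         seed: int | None = None,
                         recompute_ica: bool = True) -> PermutationReport:
        seed = self.config.seed if seed is None else seed
        if statistic == "modes":
            return permutation_test_modes(self.imaging, self.behaviour,
                                          self.config, n_perm, seed,
                                          recompute_ica=recompute_ica)
        if statistic == "cca":
            return permutation_test_cca(self.imaging, self.behaviour,
                                        self.config, n_perm, seed)
        raise ValueError(f"unknown statistic {statistic!r}")


class CCAICAResults:
    """Fitted CCA-ICA decomposition with inference and validation methods."""

    def __init__(self, model: BrainBehaviourCCAICA, modes: ModeSet):
        self.model = model
        self.modes = modes

    @property
    def mode_corrs(self) -> np.ndarray:
        return self.modes.mode_corrs

    @property
    def variable_loadings(self) -> pd.DataFrame:
        return self.modes.variable_loadings

    @property
    def brain_mode_loadings(self) -> np.ndarray:
        return self.modes.brain_mode_loadings

    @property
    def behav_mode_loadings(self) -> np.ndarray:
        return self.modes.behav_mode_loadings

    def project(self, new_imaging: DataBlock) -> np.ndarray:
        """Decompose a new cohort's brain block with the fitted weights."""
        return project_out_of_sample(new_imaging, self.modes)

    def bootstrap_phenotypes(self, new_imaging: DataBlock,
                             phenotypes: pd.DataFrame, n_boot: int = 1000,
                             seed: int | None = None,
                             partial_covariates: pd.DataFrame | None = None
                             ) -> BootstrapReport:
        return bootstrap_phenotype_correlations(
            new_imaging, self.modes, phenotypes, n_boot=n_boot,
            seed=self.model.config.seed if seed is None else seed,
            partial_covariates=partial_covariates)

    def save(self, out_dir) -> None:
        self.modes.save(out_dir)

    def summary(self) -> str:
        cfg = self.model.config
        lines = [
            "Brain-behaviour CCA-ICA decomposition",
            "=" * 46,
            f"participants: {self.model.imaging.n_participants}",
            f"imaging variables: {self.model.imaging.n_variables} "
            f"(PCA -> {cfg.n_comp_brain})",
            f"behaviour variables: {self.model.behaviour.n_variables} "
            f"(PCA -> {cfg.n_comp_behav})",
            f"modes: {cfg.n_modes}   seed: {cfg.seed}",
            "",
            "mode   corr(brain, behaviour)   top behaviour variable",
        ]
        vl = self.variable_loadings
        for k in range(self.modes.n_modes):
            sub = vl[(vl["mode"] == k + 1) & (vl["block"] == "behaviour")]
            top = sub.loc[sub["loading"].abs().idxmax()]
            lines.append(f"{k + 1:>4}   {self.mode_corrs[k]:>22.3f}   "
                         f"{top['variable']} (r={top['loading']:.2f})")
        return "\n".join(lines)
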