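"""Out-of-sample validation: projection, spin tests, bootstrap CIs.

A fitted :class:`~neuromodes.decompose.ModeSet` carries a pure imaging-side
projection matrix, so an independent cohort's (de-confounded) brain block
can be decomposed by a single matrix product. Spatial overlap of the
resulting brain-weight maps with the training maps is tested against a
spin-permutation null that preserves spatial autocorrelation: parcel
centroids on the unit sphere are randomly rotated (the right hemisphere
uses the left rotation mirrored through the midsagittal plane) and each
parcel takes the value of its nearest rotated neighbour. Correlations of
projected brain loadings with phenotypes get percentile bootstrap CIs.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
import json

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist
from scipy.stats import special_ortho_group

from .blocks import DataBlock
from .decompose import ModeSet

__all__ = [
    "ParcelGeometry",
    "SpinReport",
    "BootstrapReport",
    "project_out_of_sample",
    "spatial_map_correlation",
    "bootstrap_phenotype_correlations",
]


@dataclass
class ParcelGeometry:
    """Parcel names, hemispheres and unit-sphere centroids for spin tests."""

    frame: pd.DataFrame     # columns: parcel, hemi, x, y, z, is_surface

    def __post_init__(self) -> None:
        required = {"parcel", "hemi", "x", "y", "z", "is_surface"}
        missing = required - set(self.frame.columns)
        if missing:
            raise KeyError(f"geometry table lacks columns: {sorted(missing)}")
        if self.frame["parcel"].duplicated().any():
            raise ValueError("duplicate parcel names in geometry")
        surf = self.frame[self.frame["is_surface"].astype(bool)]
        norms = np.linalg.norm(surf[["x", "y", "z"]].to_numpy(float), axis=1)
        if not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError("surface parcel centroids must lie on the unit sphere")

    @property
    def parcels(self) -> list[str]:
        return self.frame["parcel"].tolist()

    def surface_indices(self, hemi: str) -> np.ndarray:
        f = self.frame
        return np.where((f["hemi"] == hemi) & f["is_surface"].astype(bool))[0]

    @property
    def nonsurface_indices(self) -> np.ndarray:
        return np.where(~self.frame["is_surface"].astype(bool))[0]

    def centroids(self, idx) -> np.ndarray:
        return self.frame.iloc[idx][["x", "y", "z"]].to_numpy(float)

    @classmethod
    def read_csv(cls, path) -> "ParcelGeometry":
        return cls(pd.read_csv(path))

    def write_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)


@dataclass
class SpinReport:
    observed_r: float
    null_r: np.ndarray
    p_spin: float
    n_spin: int
    seed: int
    duplicate_fraction: float    # mean fraction of parcels mapped non-uniquely

    def to_json(self, path) -> None:
        payload = asdict(self)
        payload["null_r"] = np.asarray(payload["null_r"]).tolist()
        with open(path, "w") as fh:
            json.dump(payload, fh)


@dataclass
class BootstrapReport:
    table: pd.DataFrame    # mode, phenotype, r, ci_low, ci_high, n_undefined
    n_boot: int
    seed: int

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"n_boot": self.n_boot, "seed": self.seed,
                       "table": self.table.to_dict(orient="records")}, fh)


# ---------------------------------------------------------------------------
# projection


def project_out_of_sample(new_imaging: DataBlock, modes: ModeSet) -> np.ndarray:
    """Brain mode loadings for a new cohort: centered data × projection.

    Variables are matched by name (order-independent); training variables
    absent from the new block raise, never silently zero-fill. The map is
    purely linear: the new block is expected to be de-confounded with its
    own confound design (residualised columns have zero mean), exactly as
    the training block was, so no further centering is applied.
    """
    missing = [v for v in modes.brain_variables
               if v not in set(new_imaging.variable_names)]
    if missing:
        raise KeyError(
            f"new block lacks {len(missing)} training variables, "
            f"e.g. {missing[:5]}")
    aligned = new_imaging.subset_variables(modes.brain_variables)
    if not aligned.is_complete:
        raise ValueError("new imaging block has missing values; preprocess first")
    return aligned.values @ modes.brain_projection


# ---------------------------------------------------------------------------
# spin permutations


def _mirror(R: np.ndarray) -> np.ndarray:
    """Mirror a rotation through the midsagittal (x = 0) plane."""
    F = np.diag([-1.0, 1.0, 1.0])
    return F @ R @ F


def _spin_assignment(centroids: np.ndarray, R: np.ndarray, method: str):
    """Indices j such that spun_value[i] = value[j] under rotation R."""
    rotated = centroids @ R.T
    D = cdist(rotated, centroids)
    if method == "nearest":
        return np.argmin(D, axis=1)
    if method == "assignment":       # one-to-one, preserves the value multiset
        rows, cols = linear_sum_assignment(D)
        out = np.empty(len(centroids), dtype=int)
        out[rows] = cols
        return out
    raise ValueError(f"unknown spin method {method!r}")


def spatial_map_correlation(
    map_a: pd.Series,
    map_b: pd.Series,
    geometry: ParcelGeometry,
    n_spin: int = 1000,
    seed: int = 0,
    method: str = "nearest",
) -> SpinReport:
    """Correlate two parcel maps against a spin-permutation spatial null.

    Maps are pandas Series indexed by parcel name. Each spin draws one
    uniform random rotation (applied to the left hemisphere, mirrored for
    the right), reassigns surface parcels of ``map_a`` by ``method``
    ("nearest": nearest rotated centroid, duplicates allowed and recorded;
    "assignment": one-to-one optimal assignment), freely permutes
    non-surface features among themselves, and recomputes the correlation
    with ``map_b``. p is two-sided on |r|.
    """
    parcels = geometry.parcels
    missing = [p for p in parcels if p not in map_a.index or p not in map_b.index]
    if missing:
        raise KeyError(f"maps lack parcels: {missing[:5]}")
    a = map_a.loc[parcels].to_numpy(float)
    b = map_b.loc[parcels].to_numpy(float)
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("constant map: correlation undefined")
    for hemi in ("left", "right"):
        if len(geometry.surface_indices(hemi)) < 10:
            raise ValueError(f"need >= 10 surface parcels in {hemi} hemisphere")

    observed = float(stats.pearsonr(a, b).statistic)
    left = geometry.surface_indices("left")
    right = geometry.surface_indices("right")
    other = geometry.nonsurface_indices
    cent_l = geometry.centroids(left)
    cent_r = geometry.centroids(right)

    rng = np.random.default_rng(seed)
    null = np.empty(n_spin)
    dup_frac = np.empty(n_spin)
    for s in range(n_spin):
        R = special_ortho_group.rvs(3, random_state=rng)
        spun = a.copy()
        idx_l = _spin_assignment(cent_l, R, method)
        idx_r = _spin_assignment(cent_r, _mirror(R), method)
        spun[left] = a[left][idx_l]
        spun[right] = a[right][idx_r]
        n_surface = len(left) + len(right)
        dup_frac[s] = 1.0 - (len(np.unique(idx_l)) + len(np.unique(idx_r))) / n_surface
        if other.size:
            spun[other] = a[other][rng.permutation(other.size)]
        null[s] = stats.pearsonr(spun, b).statistic
    p = (1 + np.sum(np.abs(null) >= abs(observed))) / (1 + n_spin)
    return SpinReport(observed, null, float(p), n_spin, seed,
                      float(dup_frac.mean()))


# ---------------------------------------------------------------------------
# bootstrap


def _partial(x: np.ndarray, Z: np.ndarray | None) -> np.ndarray:
    if Z is None:
        return x
    Z1 = np.column_stack([np.ones(len(x)), Z])
    beta, *_ = np.linalg.lstsq(Z1, x, rcond=None)
    return x - Z1 @ beta


def bootstrap_phenotype_correlations(
    new_imaging: DataBlock,
    modes: ModeSet,
    phenotypes: pd.DataFrame,
    n_boot: int = 1000,
    seed: int = 0,
    partial_covariates: pd.DataFrame | None = None,
) -> BootstrapReport:
    """Percentile bootstrap CIs for mode-loading vs phenotype correlations.

    Each resample draws participants with replacement, projects the
    resampled imaging block through the fitted weights and correlates each
    mode's brain loadings with each phenotype column (both sides
    residualised on ``partial_covariates`` when given). Resamples in which
    a phenotype is constant are recorded as undefined and excluded.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    pheno = phenotypes.loc[new_imaging.participant_ids]
    Z = (partial_covariates.loc[new_imaging.participant_ids].to_numpy(float)
         if partial_covariates is not None else None)
    aligned = new_imaging.subset_variables(modes.brain_variables)
    X = aligned.values
    n = X.shape[0]
    K = modes.n_modes
    rng = np.random.default_rng(seed)

    point = {}
    loadings = X @ modes.brain_projection
    for k in range(K):
        for col in pheno.columns:
            y = pheno[col].to_numpy(float)
            point[(k, col)] = float(stats.pearsonr(
                _partial(loadings[:, k], Z), _partial(y, Z)).statistic)

    draws = {key: [] for key in point}
    undefined = {key: 0 for key in point}
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        lb = loadings[idx]
        Zb = Z[idx] if Z is not None else None
        for k in range(K):
            lk = _partial(lb[:, k], Zb)
            for col in pheno.columns:
                y = pheno[col].to_numpy(float)[idx]
                if np.ptp(y) == 0 or np.ptp(lk) == 0:
                    undefined[(k, col)] += 1
                    continue
                draws[(k, col)].append(
                    stats.pearsonr(lk, _partial(y, Zb)).statistic)

    rows = []
    for (k, col), vals in draws.items():
        vals = np.asarray(vals)
        lo, hi = (np.percentile(vals, [2.5, 97.5]) if vals.size
                  else (np.nan, np.nan))
        rows.append((k + 1, col, point[(k, col)], float(lo), float(hi),
                     undefined[(k, col)]))
    table = pd.DataFrame(rows, columns=["mode", "phenotype", "r",
                                        "ci_low", "ci_high", "n_undefined"])
    return BootstrapReport(table, n_boot, seed)
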