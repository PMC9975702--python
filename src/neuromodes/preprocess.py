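"""Cleaning, imputation, confound residualisation and normalisation.

The preprocessing chain runs clean -> impute -> residualise -> normalise:

1. :func:`clean_block` sets extreme cells (|robust z| above a threshold,
   computed on median/MAD) to missing, then drops variables and then
   participants with too much missingness.
2. :func:`knn_impute` fills the remaining holes with a variables-as-rows
   k-nearest-neighbour scheme: for each missing entry, the k variables
   closest in Euclidean distance over mutually observed participants supply
   an unweighted mean.
3. :func:`residualise` replaces every variable by its OLS residual against
   intercept + dummy-coded categorical confounds, with a global-volume
   covariate added to the design for volumetric variables only.
4. :func:`rank_inverse_normal` maps each variable's ranks through the
   normal quantile function with Blom offsets, enforcing Gaussian marginals.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
import json

import numpy as np
from scipy import stats

from .blocks import DataBlock, ConfoundTable

__all__ = [
    "CleaningReport",
    "clean_block",
    "knn_impute",
    "residualise",
    "rank_inverse_normal",
    "preprocess_block",
]

# offsets for the rank-based inverse normal transform: z = Phi^-1((r-c)/(n-2c+1))
INT_OFFSETS = {"blom": 3.0 / 8.0, "tukey": 1.0 / 3.0, "waerden": 0.0}


@dataclass
class CleaningReport:
    dropped_variables: dict = field(default_factory=dict)    # name -> reason
    dropped_participants: dict = field(default_factory=dict)  # id -> reason
    cells_set_missing: int = 0
    cells_imputed: int = 0

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)


def robust_z(values: np.ndarray) -> np.ndarray:
    """Column-wise (x - median) / (1.4826 * MAD); zero-MAD columns give 0."""
    med = np.nanmedian(values, axis=0)
    mad = np.nanmedian(np.abs(values - med), axis=0)
    scale = 1.4826 * mad
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (values - med) / scale
    z[:, scale == 0] = 0.0
    return z


def clean_block(
    block: DataBlock,
    z_extreme: float = 4.0,
    max_var_missing: float = 0.5,
    max_participant_missing: float = 0.5,
) -> tuple[DataBlock, CleaningReport]:
    """Censor extreme scores, then drop over-missing variables, then participants.

    The step order is fixed: extreme cells first become missing, variable
    missing fractions are then recomputed for the variable drop, and
    participant fractions recomputed once more for the participant drop.
    """
    if z_extreme <= 0 or max_var_missing <= 0 or max_participant_missing <= 0:
        raise ValueError("thresholds must be positive")
    if block.n_participants == 0 or block.n_variables == 0:
        raise ValueError("empty block")

    report = CleaningReport()
    values = block.values.copy()

    z = robust_z(values)
    extreme = np.abs(z) > z_extreme
    report.cells_set_missing = int(np.count_nonzero(extreme & ~np.isnan(values)))
    values[extreme] = np.nan

    var_missing = np.isnan(values).mean(axis=0)
    keep_vars = var_missing <= max_var_missing
    for name, frac in zip(block.variable_names, var_missing):
        if frac > max_var_missing:
            report.dropped_variables[name] = f"missing fraction {frac:.3f} > {max_var_missing}"
    if not keep_vars.any():
        raise ValueError(
            f"all variables dropped at z_extreme={z_extreme}, "
            f"max_var_missing={max_var_missing}")
    values = values[:, keep_vars]
    var_names = [n for n, k in zip(block.variable_names, keep_vars) if k]

    part_missing = np.isnan(values).mean(axis=1)
    keep_parts = part_missing <= max_participant_missing
    for pid, frac in zip(block.participant_ids, part_missing):
        if frac > max_participant_missing:
            report.dropped_participants[pid] = (
                f"missing fraction {frac:.3f} > {max_participant_missing}")
    values = values[keep_parts]
    ids = [p for p, k in zip(block.participant_ids, keep_parts) if k]

    return DataBlock(values, ids, var_names), report


def knn_impute(block: DataBlock, k: int = 1) -> DataBlock:
    """Fill missing cells from the k nearest variables (variables as rows).

    For a variable with a missing entry at participant j, candidate
    neighbours are the variables observed at j; distance is Euclidean over
    the participants both variables observe; the fill is the unweighted mean
    of the k nearest neighbours' values at j.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    values = block.values.copy()
    if not np.isnan(values).any():
        return block.copy()
    obs = ~np.isnan(values)
    if (~obs).all(axis=0).any():
        bad = [n for n, c in zip(block.variable_names, (~obs).all(axis=0)) if c]
        raise ValueError(f"variables with no observed values: {bad}")

    X = values.T          # variables × participants
    M = obs.T
    p = X.shape[0]
    filled = X.copy()
    for v in range(p):
        miss_at = np.where(~M[v])[0]
        if miss_at.size == 0:
            continue
        # distance from v to every other variable over shared observed entries
        dists = np.full(p, np.inf)
        for w in range(p):
            if w == v:
                continue
            shared = M[v] & M[w]
            if not shared.any():
                continue
            diff = X[v, shared] - X[w, shared]
            dists[w] = float(np.sqrt(np.sum(diff * diff)))
        for j in miss_at:
            candidates = np.where(M[:, j] & np.isfinite(dists))[0]
            if candidates.size == 0:
                raise ValueError(
                    f"variable {block.variable_names[v]!r} has no observed "
                    f"neighbour overlap at participant {block.participant_ids[j]!r}")
            order = candidates[np.argsort(dists[candidates], kind="stable")]
            neighbours = order[:k]
            filled[v, j] = float(np.mean(X[neighbours, j]))
    return DataBlock(filled.T, list(block.participant_ids), list(block.variable_names))


def residualise(
    block: DataBlock,
    confounds: ConfoundTable,
    spec: list[str],
    volumetric_vars=(),
    global_covariate: str = "etiv",
) -> DataBlock:
    """OLS-residualise every variable against the confound design.

    Variables named in ``volumetric_vars`` additionally get the
    global-volume covariate (eTIV-like) in their design; the covariate
    itself may still be carried as an analysis variable. Residual columns
    have exactly zero mean (intercept always included). With an empty
    ``spec`` this reduces to column centering.
    """
    if not block.is_complete:
        raise ValueError("residualise expects a complete block (impute first)")
    conf = confounds.aligned_to(block)
    X_base, _ = conf.design_matrix(list(spec))
    vol = set(volumetric_vars)
    unknown = vol - set(block.variable_names)
    if unknown:
        raise KeyError(f"volumetric variables not in block: {sorted(unknown)[:5]}")

    Y = block.values
    out = np.empty_like(Y)

    def _resid(X, y_cols):
        beta, *_ = np.linalg.lstsq(X, y_cols, rcond=None)
        return y_cols - X @ beta

    is_vol = np.array([n in vol for n in block.variable_names])
    if (~is_vol).any():
        out[:, ~is_vol] = _resid(X_base, Y[:, ~is_vol])
    if is_vol.any():
        if global_covariate not in conf.continuous:
            raise KeyError(f"global covariate {global_covariate!r} not a continuous confound")
        X_vol = np.column_stack([X_base, conf.frame[global_covariate].to_numpy(float)])
        if np.linalg.matrix_rank(X_vol) < X_vol.shape[1]:
            raise ValueError(
                f"design with {global_covariate!r} is rank-deficient")
        out[:, is_vol] = _resid(X_vol, Y[:, is_vol])
    return DataBlock(out, list(block.participant_ids), list(block.variable_names))


def rank_inverse_normal(
    block: DataBlock,
    variant: str = "blom",
    constant_policy: str = "error",
) -> DataBlock:
    """Rank-based inverse normal transform, per variable.

    Ranks (ties get average rank) are mapped through
    ``Phi^-1((r - c) / (n - 2c + 1))`` with the Blom offset c = 3/8 by
    default. Constant columns are degenerate (every value ties); policy
    "error" raises, "zeros" passes them through as all-zero columns.
    """
    if not block.is_complete:
        raise ValueError("transform runs after imputation; block has missing cells")
    if variant not in INT_OFFSETS:
        raise ValueError(f"unknown variant {variant!r}; choose from {sorted(INT_OFFSETS)}")
    c = INT_OFFSETS[variant]
    n = block.n_participants
    out = np.empty_like(block.values)
    constant_cols = []
    for j, name in enumerate(block.variable_names):
        col = block.values[:, j]
        if np.ptp(col) == 0:
            constant_cols.append(name)
            out[:, j] = 0.0
            continue
        r = stats.rankdata(col, method="average")
        out[:, j] = stats.norm.ppf((r - c) / (n - 2 * c + 1))
    if constant_cols and constant_policy == "error":
        raise ValueError(f"constant columns cannot be rank-normalised: {constant_cols}")
    return DataBlock(out, list(block.participant_ids), list(block.variable_names))


def preprocess_block(
    block: DataBlock,
    confounds: ConfoundTable,
    residualise_on: list[str],
    volumetric_vars=(),
    z_extreme: float = 4.0,
    max_var_missing: float = 0.5,
    max_participant_missing: float = 0.5,
    k: int = 1,
    int_variant: str = "blom",
    constant_policy: str = "error",
) -> tuple[DataBlock, CleaningReport]:
    """Full chain: clean -> impute -> residualise -> rank-inverse-normal."""
    cleaned, report = clean_block(block, z_extreme, max_var_missing,
                                  max_participant_missing)
    report.cells_imputed = int((~cleaned.mask).sum())
    imputed = knn_impute(cleaned, k=k)
    resid = residualise(imputed, confounds, residualise_on, volumetric_vars)
    normed = rank_inverse_normal(resid, variant=int_variant,
                                 constant_policy=constant_policy)
    return normed, report
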