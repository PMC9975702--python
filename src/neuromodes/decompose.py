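"""PCA -> CCA -> ICA mode decomposition.

The core of the package. Both preprocessed blocks are reduced by PCA
(avoiding rank deficiency and noise fitting), canonical correlation
analysis links the two reduced blocks, and the canonical scores are rotated
by fastICA into statistically independent, more interpretable modes. One
K × K unmixing matrix is estimated from the vertically stacked canonical
variates [U; V] and applied to each side separately, so that a pure
imaging-side projection matrix exists for out-of-sample decomposition.

CCA is computed by the numerically stable QR/SVD route (orthonormal bases
per block, SVD of their cross-product); covariance matrices are never
explicitly inverted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import integrate, stats

from .blocks import DataBlock, ConfoundTable

__all__ = [
    "PCAResult",
    "CCAResult",
    "ModeSet",
    "DecompositionConfig",
    "fit_pca",
    "fit_cca",
    "fit_ica_rotation",
    "compute_variable_loadings",
    "run_full_decomposition",
]


@dataclass
class PCAResult:
    basis: np.ndarray               # variables × n_comp, orthonormal columns
    scores: np.ndarray              # participants × n_comp
    explained_variance: np.ndarray  # n_comp, non-increasing
    n_comp: int
    mean: np.ndarray                # column means removed before projection


@dataclass
class CCAResult:
    brain_weights: np.ndarray       # d1 × K, on PCA-score space
    behav_weights: np.ndarray       # d2 × K
    U: np.ndarray                   # participants × K canonical variates, brain side
    V: np.ndarray                   # participants × K, behaviour side
    canonical_corrs: np.ndarray     # K, non-increasing in [0, 1]


@dataclass
class ModeSet:
    """A fitted CCA-ICA decomposition.

    ``brain_projection`` maps the centered de-confounded brain block
    directly to brain-side mode loadings (and likewise for behaviour), which
    is what out-of-sample projection multiplies new data with.
    """

    unmixing: np.ndarray                 # K × K (whitening ∘ ICA rotation)
    brain_mode_loadings: np.ndarray      # participants × K
    behav_mode_loadings: np.ndarray      # participants × K
    mode_corrs: np.ndarray               # K, descending
    brain_projection: np.ndarray         # p_brain × K
    behav_projection: np.ndarray         # p_behav × K
    brain_mean: np.ndarray               # p_brain column means of training block
    behav_mean: np.ndarray               # p_behav
    brain_variables: list[str]
    behav_variables: list[str]
    participant_ids: list[str]
    variable_loadings: pd.DataFrame | None = None   # variable, block, mode, loading
    config: dict = field(default_factory=dict)

    @property
    def n_modes(self) -> int:
        return self.unmixing.shape[0]

    def loading_vector(self, mode: int, concat: bool = True) -> np.ndarray:
        """Variable-loading vector of one mode (brain+behaviour concatenated)."""
        vl = self.variable_loadings
        if vl is None:
            raise ValueError("variable loadings were not computed")
        sub = vl[vl["mode"] == mode]
        if concat:
            return sub["loading"].to_numpy()
        return sub

    # -- serialisation -----------------------------------------------------
    def save(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        if self.variable_loadings is not None:
            self.variable_loadings.to_csv(out / "variable_loadings.tsv",
                                          sep="\t", index=False)
        rows = []
        for side, load in (("brain", self.brain_mode_loadings),
                           ("behaviour", self.behav_mode_loadings)):
            for k in range(self.n_modes):
                for pid, x in zip(self.participant_ids, load[:, k]):
                    rows.append((pid, side, k + 1, x))
        pd.DataFrame(rows, columns=["participant_id", "side", "mode", "loading"]
                     ).to_csv(out / "participant_loadings.tsv", sep="\t", index=False)
        for name, proj, names, mean in (
                ("projection_brain.tsv", self.brain_projection,
                 self.brain_variables, self.brain_mean),
                ("projection_behav.tsv", self.behav_projection,
                 self.behav_variables, self.behav_mean)):
            frame = pd.DataFrame(proj, index=pd.Index(names, name="variable"),
                                 columns=[f"mode_{k + 1}" for k in range(self.n_modes)])
            frame.insert(0, "train_mean", mean)
            frame.to_csv(out / name, sep="\t")
        with open(out / "summary.json", "w") as fh:
            json.dump({"mode_corrs": self.mode_corrs.tolist(),
                       "n_modes": self.n_modes,
                       "unmixing": self.unmixing.tolist(),
                       "config": self.config}, fh, indent=2)

    @classmethod
    def load(cls, out_dir) -> "ModeSet":
        out = Path(out_dir)
        with open(out / "summary.json") as fh:
            summary = json.load(fh)
        pb = pd.read_csv(out / "projection_brain.tsv", sep="\t", index_col="variable")
        pv = pd.read_csv(out / "projection_behav.tsv", sep="\t", index_col="variable")
        part = pd.read_csv(out / "participant_loadings.tsv", sep="\t",
                           dtype={"participant_id": str})
        k = summary["n_modes"]
        ids = part["participant_id"].drop_duplicates().tolist()
        brain = part[part["side"] == "brain"].pivot(index="participant_id",
                                                    columns="mode", values="loading")
        behav = part[part["side"] == "behaviour"].pivot(index="participant_id",
                                                        columns="mode", values="loading")
        vl_path = out / "variable_loadings.tsv"
        vl = pd.read_csv(vl_path, sep="\t") if vl_path.exists() else None
        return cls(np.asarray(summary["unmixing"], float),
                   brain.loc[ids].to_numpy(), behav.loc[ids].to_numpy(),
                   np.asarray(summary["mode_corrs"], float),
                   pb.drop(columns="train_mean").to_numpy(),
                   pv.drop(columns="train_mean").to_numpy(),
                   pb["train_mean"].to_numpy(), pv["train_mean"].to_numpy(),
                   pb.index.tolist(), pv.index.tolist(), ids, vl,
                   summary.get("config", {}))


@dataclass
class DecompositionConfig:
    n_comp_brain: int = 30
    n_comp_behav: int = 30
    n_modes: int = 2
    seed: int = 0
    n_restarts: int = 5
    ica_max_iter: int = 500
    ica_tol: float = 1e-5
    ica_strict: bool = True

    def to_dict(self) -> dict:
        return dict(self.__dict__)


# ---------------------------------------------------------------------------
# PCA


def fit_pca(block, n_comp: int) -> PCAResult:
    """Leading principal components of the centered matrix (via SVD).

    ``block`` may be a DataBlock (complete) or a plain array. Basis signs
    are fixed deterministically: the basis entry of largest magnitude in
    each column is made positive.
    """
    X = block.values if isinstance(block, DataBlock) else np.asarray(block, float)
    if np.isnan(X).any():
        raise ValueError("PCA input contains missing values")
    n, p = X.shape
    if n_comp > min(n - 1, p):
        raise ValueError(f"n_comp={n_comp} exceeds min(n-1, p)={min(n - 1, p)}")
    mean = X.mean(axis=0)
    Xc = X - mean
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    rank = int(np.sum(S > S[0] * max(n, p) * np.finfo(float).eps)) if S.size else 0
    if n_comp > rank:
        raise ValueError(f"n_comp={n_comp} exceeds attainable rank {rank}")
    basis = Vt[:n_comp].T
    # deterministic sign: largest |entry| of each basis column positive
    flip = np.sign(basis[np.argmax(np.abs(basis), axis=0), np.arange(n_comp)])
    flip[flip == 0] = 1.0
    basis = basis * flip
    scores = Xc @ basis
    explained = (S[:n_comp] ** 2) / (n - 1)
    return PCAResult(basis, scores, explained, n_comp, mean)


# ---------------------------------------------------------------------------
# CCA


def fit_cca(scores_brain: np.ndarray, scores_behav: np.ndarray, K: int) -> CCAResult:
    """Canonical correlation analysis via orthonormal bases + SVD.

    Inputs are column-centered score matrices. Each block is reduced to an
    orthonormal basis by SVD; the singular values of the cross-product of
    the two bases are the canonical correlations, and the right/left
    singular vectors give the weights. Canonical variates are scaled to
    unit sample variance.
    """
    X = np.asarray(scores_brain, float)
    Y = np.asarray(scores_behav, float)
    if X.shape[0] != Y.shape[0]:
        raise ValueError("row mismatch between blocks")
    n = X.shape[0]
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    if (Xc.std(axis=0) == 0).any() or (Yc.std(axis=0) == 0).any():
        raise ValueError("zero-variance column in CCA input")

    def _orth(A):
        U, S, Vt = np.linalg.svd(A, full_matrices=False)
        tol = S[0] * max(A.shape) * np.finfo(float).eps if S.size else 0.0
        r = int(np.sum(S > tol))
        return U[:, :r], S[:r], Vt[:r]

    Qx, Sx, Vxt = _orth(Xc)
    Qy, Sy, Vyt = _orth(Yc)
    if K > min(Qx.shape[1], Qy.shape[1]):
        raise ValueError(
            f"K={K} exceeds attainable rank {min(Qx.shape[1], Qy.shape[1])}")
    Uc, corrs, Vct = np.linalg.svd(Qx.T @ Qy)
    corrs = np.clip(corrs[:K], 0.0, 1.0)
    # weights on the original (centered) score space, variates unit-variance
    wx = Vxt.T @ ((Uc[:, :K] * np.sqrt(n - 1)) / Sx[:, None])
    wy = Vyt.T @ ((Vct.T[:, :K] * np.sqrt(n - 1)) / Sy[:, None])
    U = Xc @ wx
    V = Yc @ wy
    return CCAResult(wx, wy, U, V, corrs)


# ---------------------------------------------------------------------------
# ICA rotation

def _sym_decorrelate(W: np.ndarray) -> np.ndarray:
    """W <- (W W^T)^(-1/2) W, the symmetric (parallel) decorrelation step."""
    evals, evecs = np.linalg.eigh(W @ W.T)
    return evecs @ np.diag(evals ** -0.5) @ evecs.T @ W


def symmetric_fastica(Z: np.ndarray, w_init: np.ndarray,
                      max_iter: int = 500, tol: float = 1e-5
                      ) -> tuple[np.ndarray, bool]:
    """Fixed-point ICA on whitened data: log-cosh contrast, symmetric update.

    Iterates W <- E[g(WX) X^T] - E[g'(WX)] W with g = tanh (the a=1
    log-cosh score), re-orthonormalising every step, until the largest
    change in any filter direction falls below ``tol``. Returns the K × K
    orthonormal unmixing matrix (rows = filters) and a convergence flag.
    """
    n, K = Z.shape
    W = _sym_decorrelate(np.asarray(w_init, float))
    for _ in range(max_iter):
        S = Z @ W.T
        G = np.tanh(S)
        W_new = (G.T @ Z) / n - np.diag((1.0 - G ** 2).mean(axis=0)) @ W
        W_new = _sym_decorrelate(W_new)
        lim = np.max(np.abs(np.abs(np.einsum("ij,ij->i", W_new, W)) - 1.0))
        W = W_new
        if lim < tol:
            return W, True
    return W, False


_EG_LOGCOSH = None


def _expected_logcosh_gaussian() -> float:
    """E[log cosh(Z)] for Z ~ N(0,1), the negentropy reference point."""
    global _EG_LOGCOSH
    if _EG_LOGCOSH is None:
        val, _ = integrate.quad(
            lambda x: np.log(np.cosh(x)) * stats.norm.pdf(x), -12, 12)
        _EG_LOGCOSH = float(val)
    return _EG_LOGCOSH


def _negentropy(sources: np.ndarray) -> float:
    """Sum over components of the squared log-cosh negentropy proxy."""
    eg = _expected_logcosh_gaussian()
    s = sources / sources.std(axis=0, ddof=0)
    return float(np.sum((np.mean(np.log(np.cosh(s)), axis=0) - eg) ** 2))


def select_ica_rotation(Z: np.ndarray, seed: int, n_restarts: int,
                        max_iter: int, tol: float, strict: bool) -> np.ndarray:
    """Best unmixing over restarts: converged runs preferred, then by the
    log-cosh negentropy sum. Shared by the pipeline fit and the permutation
    null so both apply the identical statistic function."""
    K = Z.shape[1]
    rng = np.random.default_rng(seed)
    best = None                  # best converged rotation
    best_score = -np.inf
    fallback = None              # best rotation regardless of convergence
    fallback_score = -np.inf
    for _ in range(max(1, n_restarts)):
        W, converged = symmetric_fastica(Z, rng.standard_normal((K, K)),
                                         max_iter=max_iter, tol=tol)
        score = _negentropy(Z @ W.T)
        if score > fallback_score:
            fallback_score = score
            fallback = W
        if converged and score > best_score:
            best_score = score
            best = W
    if best is None:
        if strict:
            raise RuntimeError(
                f"fastICA did not reach tol={tol} within {max_iter} "
                f"iterations in any of {n_restarts} restarts")
        best = fallback
    return best


def fit_ica_rotation(
    cca: CCAResult,
    K: int | None = None,
    seed: int = 0,
    n_restarts: int = 5,
    max_iter: int = 500,
    tol: float = 1e-5,
    pca_brain: PCAResult | None = None,
    pca_behav: PCAResult | None = None,
    strict: bool = True,
) -> ModeSet:
    """Rotate canonical scores into independent modes with fastICA.

    The stacked variates [U; V] (2n × K) are ZCA-whitened, a K × K
    orthogonal unmixing is estimated by fixed-point ICA (log-cosh contrast,
    symmetric decorrelation) with restarts keeping the best negentropy sum,
    and the composed map (whitening then rotation) is applied to U and V
    separately. Modes are ordered by descending between-side correlation;
    the sign convention is applied later once variable loadings exist.

    With ``strict`` (default) a fit in which no restart reaches ``tol``
    within ``max_iter`` iterations raises. Non-strict mode keeps the best
    non-converged rotation instead — used inside permutation and split-half
    loops, where noise-only inputs have no preferred independent directions
    and any orthogonal rotation is an acceptable draw.
    """
    K = cca.U.shape[1] if K is None else K
    if K > cca.U.shape[1]:
        raise ValueError("K exceeds the number of canonical variate pairs")
    U = cca.U[:, :K]
    V = cca.V[:, :K]
    stacked = np.vstack([U, V])
    stacked = stacked - stacked.mean(axis=0)

    if K == 1:
        M = np.array([[1.0]])
    else:
        C = stacked.T @ stacked / (stacked.shape[0] - 1)
        evals, evecs = np.linalg.eigh(C)
        if evals.min() <= 0:
            raise ValueError("degenerate canonical-score covariance")
        whiten = evecs @ np.diag(evals ** -0.5) @ evecs.T   # ZCA, symmetric
        Z = stacked @ whiten
        best = select_ica_rotation(Z, seed, n_restarts, max_iter, tol, strict)
        M = whiten @ best.T                # total unmixing applied to U and V

    brain_load = U @ M
    behav_load = V @ M
    corrs = np.array([
        stats.pearsonr(brain_load[:, k], behav_load[:, k]).statistic
        for k in range(K)])
    order = np.argsort(-corrs)
    M = M[:, order]
    brain_load = brain_load[:, order]
    behav_load = behav_load[:, order]
    corrs = corrs[order]

    if pca_brain is not None and pca_behav is not None:
        proj_brain = pca_brain.basis @ cca.brain_weights[:, :K] @ M
        proj_behav = pca_behav.basis @ cca.behav_weights[:, :K] @ M
        brain_mean = pca_brain.mean
        behav_mean = pca_behav.mean
        brain_vars = [f"pc_{i}" for i in range(pca_brain.basis.shape[0])]
        behav_vars = [f"pc_{i}" for i in range(pca_behav.basis.shape[0])]
    else:
        proj_brain = cca.brain_weights[:, :K] @ M
        proj_behav = cca.behav_weights[:, :K] @ M
        brain_mean = np.zeros(proj_brain.shape[0])
        behav_mean = np.zeros(proj_behav.shape[0])
        brain_vars = [f"score_{i}" for i in range(proj_brain.shape[0])]
        behav_vars = [f"score_{i}" for i in range(proj_behav.shape[0])]

    n = U.shape[0]
    return ModeSet(M, brain_load, behav_load, corrs, proj_brain, proj_behav,
                   brain_mean, behav_mean, brain_vars, behav_vars,
                   [str(i) for i in range(n)])


# ---------------------------------------------------------------------------
# Variable loadings


def _partial_residuals(x: np.ndarray, Z: np.ndarray) -> np.ndarray:
    Z1 = np.column_stack([np.ones(len(x)), Z])
    beta, *_ = np.linalg.lstsq(Z1, x, rcond=None)
    return x - Z1 @ beta


def compute_variable_loadings(
    modes: ModeSet,
    brain_block: DataBlock,
    behav_block: DataBlock,
    covariates_to_partial: list[str] | None = None,
    confounds: ConfoundTable | None = None,
) -> pd.DataFrame:
    """Correlate participant mode loadings with the de-confounded variables.

    Brain variables are correlated with brain-side loadings, behaviour
    variables with behaviour-side loadings. When ``covariates_to_partial``
    names confound columns, both sides are residualised on those covariates
    first (partial correlations). Constant variables give NaN loadings.
    """
    brain_block.check_aligned(behav_block)
    Zpart = None
    if covariates_to_partial:
        if confounds is None:
            raise ValueError("confounds required for partial correlations")
        conf = confounds.aligned_to(brain_block)
        X, _ = conf.design_matrix(list(covariates_to_partial))
        Zpart = X[:, 1:]                    # drop intercept; added back inside

    rows = []
    for block, side, loadings in (
            (brain_block, "brain", modes.brain_mode_loadings),
            (behav_block, "behaviour", modes.behav_mode_loadings)):
        vals = block.values
        for k in range(modes.n_modes):
            lk = loadings[:, k]
            lk_use = _partial_residuals(lk, Zpart) if Zpart is not None else lk
            for j, name in enumerate(block.variable_names):
                col = vals[:, j]
                if np.ptp(col) == 0:
                    r = np.nan
                else:
                    col_use = _partial_residuals(col, Zpart) if Zpart is not None else col
                    if np.ptp(col_use) == 0 or np.ptp(lk_use) == 0:
                        r = np.nan
                    else:
                        r = stats.pearsonr(lk_use, col_use).statistic
                rows.append((name, side, k + 1, r))
    return pd.DataFrame(rows, columns=["variable", "block", "mode", "loading"])


def _apply_sign_convention(modes: ModeSet) -> ModeSet:
    """Orient each mode so the behaviour variable of largest |loading| is positive."""
    vl = modes.variable_loadings
    for k in range(modes.n_modes):
        sub = vl[(vl["mode"] == k + 1) & (vl["block"] == "behaviour")]
        if sub["loading"].abs().max() == 0 or sub["loading"].isna().all():
            continue
        top = sub.loc[sub["loading"].abs().idxmax(), "loading"]
        if top < 0:
            modes.brain_mode_loadings[:, k] *= -1
            modes.behav_mode_loadings[:, k] *= -1
            modes.brain_projection[:, k] *= -1
            modes.behav_projection[:, k] *= -1
            modes.unmixing[:, k] *= -1
            vl.loc[vl["mode"] == k + 1, "loading"] *= -1
    return modes


def run_full_decomposition(
    imaging: DataBlock,
    behaviour: DataBlock,
    config: DecompositionConfig | None = None,
) -> ModeSet:
    """PCA per block -> CCA -> ICA rotation -> variable loadings.

    Deterministic given the config seed. The returned projections map the
    centered blocks directly to mode loadings.
    """
    config = config or DecompositionConfig()
    imaging.check_aligned(behaviour)
    stage = "pca"
    try:
        pca_brain = fit_pca(imaging, min(config.n_comp_brain,
                                         imaging.n_variables,
                                         imaging.n_participants - 1))
        pca_behav = fit_pca(behaviour, min(config.n_comp_behav,
                                           behaviour.n_variables,
                                           behaviour.n_participants - 1))
        stage = "cca"
        cca = fit_cca(pca_brain.scores, pca_behav.scores, config.n_modes)
        stage = "ica"
        modes = fit_ica_rotation(cca, config.n_modes, seed=config.seed,
                                 n_restarts=config.n_restarts,
                                 max_iter=config.ica_max_iter,
                                 tol=config.ica_tol,
                                 pca_brain=pca_brain, pca_behav=pca_behav,
                                 strict=config.ica_strict)
        modes.brain_variables = list(imaging.variable_names)
        modes.behav_variables = list(behaviour.variable_names)
        modes.participant_ids = list(imaging.participant_ids)
        modes.config = config.to_dict()
        stage = "variable-loadings"
        modes.variable_loadings = compute_variable_loadings(modes, imaging, behaviour)
        modes = _apply_sign_convention(modes)
    except (ValueError, RuntimeError) as exc:
        raise type(exc)(f"[{stage}] {exc}") from exc
    return modes
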