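"""Synthetic linked two-block data with known latent structure.

The generator emulates the data-generating process the pipeline assumes: a
small number of latent modes shared between an imaging block and a
behaviour block, with a controllable cross-block correlation per mode.
Each side's latent score is

    z_side = sqrt(rho) * z_shared + sqrt(1 - rho) * z_side_unique

so corr(z_brain, z_behav) = rho in expectation, giving analytic control
over the target canonical correlation. Observed variables are random linear
mixtures of the side latents plus isotropic Gaussian noise. Confound
structure (site offsets, age trends, global scaling), MCAR missingness,
extreme-value contamination and diagnosis labels are injected separately so
each downstream cleaning stage is testable in isolation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .blocks import DataBlock, ConfoundTable

__all__ = [
    "SyntheticTruth",
    "generate_linked_blocks",
    "inject_confounds_and_noise",
    "assign_diagnoses",
    "make_confound_table",
    "make_parcel_geometry_frame",
    "FULL_COHORT_SCALE",
]

# desk-scale defaults: a large clinical youth cohort's dimensions divided
# by roughly four; FULL_COHORT_SCALE is the full-size preset
DEFAULT_N = 500
DEFAULT_P_BRAIN = 120
DEFAULT_P_BEHAV = 200
FULL_COHORT_SCALE = {"n": 1732, "p_behav": 793, "p_brain": 447}


@dataclass
class SyntheticTruth:
    """Ground truth of one generated dataset, for recovery tests.

    ``latent_factors`` are the shared factors; ``brain_factors`` and
    ``behav_factors`` are the realised side-specific latents whose pairwise
    correlation targets ``cross_block_corr``.
    """

    latent_factors: np.ndarray        # n × K_true shared factors
    brain_factors: np.ndarray         # n × K_true brain-side latents
    behav_factors: np.ndarray         # n × K_true behaviour-side latents
    brain_loadings: np.ndarray        # p_brain × K_true
    behaviour_loadings: np.ndarray    # p_behav × K_true
    cross_block_corr: np.ndarray      # K_true, in [0, 1]
    noise_sd_brain: float
    noise_sd_behav: float
    confound_effects: dict
    seed: int

    def to_json(self, path) -> None:
        payload = {k: (v.tolist() if isinstance(v, np.ndarray) else v)
                   for k, v in asdict(self).items()}
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        with open(path) as fh:
            payload = json.load(fh)
        for k in ("latent_factors", "brain_factors", "behav_factors",
                  "brain_loadings", "behaviour_loadings", "cross_block_corr"):
            payload[k] = np.asarray(payload[k], dtype=float)
        return cls(**payload)


def _ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"sub-{i:0{width}d}" for i in range(1, n + 1)]


def generate_linked_blocks(
    n: int = DEFAULT_N,
    p_brain: int = DEFAULT_P_BRAIN,
    p_behav: int = DEFAULT_P_BEHAV,
    k_true: int = 2,
    cross_block_corr=(0.9, 0.7),
    noise_sd: float = 1.0,
    seed: int = 0,
) -> tuple[DataBlock, DataBlock, SyntheticTruth]:
    """Generate dense linked imaging/behaviour blocks with planted modes.

    Returns ``(brain_block, behaviour_block, truth)``. Blocks contain no
    missing values; nuisance structure is added by
    :func:`inject_confounds_and_noise`.
    """
    if n < 10:
        raise ValueError("need n >= 10 participants")
    if k_true < 1:
        raise ValueError("k_true must be >= 1")
    rho = np.atleast_1d(np.asarray(cross_block_corr, dtype=float))
    if rho.shape != (k_true,):
        raise ValueError(
            f"cross_block_corr has length {rho.size}, expected k_true={k_true}")
    if ((rho < 0) | (rho > 1)).any():
        raise ValueError("cross_block_corr entries must lie in [0, 1]")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")

    rng = np.random.default_rng(seed)
    # unit-variance Laplace latents: ICA can only identify non-Gaussian
    # sources, so Gaussian factors would leave the planted modes unrecoverable
    # by the full pipeline (any rotation of a Gaussian pair is equally
    # "independent"). Heavy-tailed factors mirror real behavioural modes.
    scale = 1.0 / np.sqrt(2.0)
    z_shared = rng.laplace(0.0, scale, (n, k_true))
    z_brain = np.sqrt(rho) * z_shared + np.sqrt(1 - rho) * rng.laplace(0.0, scale, (n, k_true))
    z_behav = np.sqrt(rho) * z_shared + np.sqrt(1 - rho) * rng.laplace(0.0, scale, (n, k_true))

    load_brain = rng.standard_normal((p_brain, k_true))
    load_behav = rng.standard_normal((p_behav, k_true))

    x_brain = z_brain @ load_brain.T + noise_sd * rng.standard_normal((n, p_brain))
    x_behav = z_behav @ load_behav.T + noise_sd * rng.standard_normal((n, p_behav))

    ids = _ids(n)
    brain = DataBlock(x_brain, ids, [f"brain_{j:03d}" for j in range(1, p_brain + 1)])
    behav = DataBlock(x_behav, ids, [f"behav_{j:03d}" for j in range(1, p_behav + 1)])
    truth = SyntheticTruth(z_shared, z_brain, z_behav, load_brain, load_behav,
                           rho, float(noise_sd), float(noise_sd), {}, int(seed))
    return brain, behav, truth


def make_confound_table(
    n: int,
    seed: int = 0,
    sites=("siteA", "siteB", "siteC"),
    sequences=("seq1", "seq2"),
    age_range=(5.0, 21.0),
) -> ConfoundTable:
    """Random site/sequence/sex/age/eTIV-like/income covariates for n participants."""
    rng = np.random.default_rng(seed)
    frame = pd.DataFrame(
        {
            "site": rng.choice(list(sites), size=n),
            "sequence": rng.choice(list(sequences), size=n),
            "sex": rng.choice(["F", "M"], size=n),
            "age": rng.uniform(*age_range, size=n),
            "etiv": rng.normal(1500.0, 120.0, size=n),
            "household_income": rng.lognormal(11.0, 0.6, size=n),
            "medication": rng.choice(["no", "yes"], size=n, p=[0.83, 0.17]),
        },
        index=pd.Index(_ids(n), name="participant_id"),
    )
    return ConfoundTable(frame,
                         categorical=["site", "sequence", "sex", "medication"],
                         continuous=["age", "etiv", "household_income"])


def inject_confounds_and_noise(
    block: DataBlock,
    confounds: ConfoundTable,
    effects: dict | None,
    missing_rate: float = 0.0,
    extreme_rate: float = 0.0,
    seed: int = 0,
) -> DataBlock:
    """Add confound structure, MCAR missingness and extreme contamination.

    ``effects`` maps a confound name to either a per-variable coefficient
    vector (continuous confounds: effect = coef * value, added per cell) or,
    for a categorical confound, a ``{level: offset}`` dict whose offset is a
    scalar or per-variable vector added to that level's rows. Extreme cells
    are placed at >= 8 population SD from the column mean, so any sensible
    robust-z cleaning threshold catches them. Missingness is completely at
    random at rate ``missing_rate`` per cell; extreme contamination hits an
    ``extreme_rate`` fraction of the cells still observed.
    """
    if not (0 <= missing_rate < 0.5) or not (0 <= extreme_rate < 0.5):
        raise ValueError("missing_rate and extreme_rate must lie in [0, 0.5)")
    conf = confounds.aligned_to(block)
    rng = np.random.default_rng(seed)
    values = block.values.copy()
    n, p = values.shape

    for name, eff in (effects or {}).items():
        if name in conf.categorical:
            col = conf.frame[name]
            for level, offset in eff.items():
                rows = (col == level).to_numpy()
                values[rows] += np.broadcast_to(np.asarray(offset, float), (int(rows.sum()), p))
        elif name in conf.continuous:
            coef = np.broadcast_to(np.asarray(eff, float), (p,))
            values += np.outer(conf.frame[name].to_numpy(float), coef)
        else:
            raise KeyError(f"effect names unknown confound {name!r}")

    missing = rng.random((n, p)) < missing_rate

    if extreme_rate > 0:
        col_mean = np.nanmean(np.where(missing, np.nan, values), axis=0)
        col_sd = np.nanstd(np.where(missing, np.nan, values), axis=0, ddof=1)
        col_sd = np.where(col_sd > 0, col_sd, 1.0)
        hit = (rng.random((n, p)) < extreme_rate) & ~missing
        sign = rng.choice([-1.0, 1.0], size=(n, p))
        magnitude = 8.0 + rng.exponential(1.0, size=(n, p))
        extremes = col_mean + sign * magnitude * col_sd
        values = np.where(hit, extremes, values)

    values[missing] = np.nan
    return DataBlock(values, list(block.participant_ids), list(block.variable_names))


def assign_diagnoses(
    truth: SyntheticTruth,
    base_rates: dict,
    mode_effect: float = 0.0,
    seed: int = 0,
    mode_index: int = 1,
) -> pd.DataFrame:
    """Diagnosis labels whose rates depend on one latent mode.

    Each category's per-participant probability is its base rate tilted by
    ``exp(-mode_effect * z)`` where z is the participant's score on the
    chosen latent factor (default: the second factor, mirroring a clinical
    mode on which diagnosed participants score lower). The expected number
    of diagnoses is monotone in the same tilt. Returns a frame with
    ``primary_diagnosis`` (first diagnosis by category order, or
    "no diagnosis") and ``n_diagnoses``.
    """
    if not np.isfinite(mode_effect):
        raise ValueError("mode_effect must be finite")
    rates = np.asarray(list(base_rates.values()), dtype=float)
    if (rates < 0).any():
        raise ValueError("base rates must be non-negative")
    if rates.sum() > 1:
        raise ValueError("base rates must sum to <= 1")
    categories = list(base_rates.keys())
    k = truth.latent_factors.shape[1]
    z = truth.latent_factors[:, min(mode_index, k - 1)]
    n = z.shape[0]

    rng = np.random.default_rng(seed)
    tilt = np.exp(-mode_effect * z)                       # n
    prob = rates[None, :] * tilt[:, None]                 # n × C
    total = prob.sum(axis=1)
    over = total > 0.999
    prob[over] *= (0.999 / total[over])[:, None]

    # primary category: one multinomial draw per participant
    cum = np.cumsum(prob, axis=1)
    u = rng.random(n)
    primary = np.full(n, "no diagnosis", dtype=object)
    for c in range(len(categories) - 1, -1, -1):
        primary[u < cum[:, c]] = categories[c]

    diagnosed = primary != "no diagnosis"
    comorbid_p = np.clip(0.15 * tilt, 0.0, 1.0)
    extra = rng.binomial(4, comorbid_p)
    n_diag = np.where(diagnosed, 1 + extra, 0)

    return pd.DataFrame(
        {"primary_diagnosis": primary, "n_diagnoses": n_diag.astype(int)},
        index=pd.Index(_ids(n), name="participant_id"),
    )


def make_parcel_geometry_frame(n_per_hemi: int = 34, seed: int = 0,
                               n_subcortical: int = 0) -> pd.DataFrame:
    """Unit-sphere parcel centroids for both hemispheres (spin-test geometry).

    Centroids are drawn uniformly on the sphere; the right hemisphere is the
    left mirrored through the midsagittal plane plus jitter, mimicking an
    atlas's rough bilateral symmetry. Optional subcortical rows have no
    coordinates (``is_surface`` False).
    """
    rng = np.random.default_rng(seed)
    left = rng.standard_normal((n_per_hemi, 3))
    left /= np.linalg.norm(left, axis=1, keepdims=True)
    right = left * np.array([-1.0, 1.0, 1.0]) + 0.05 * rng.standard_normal((n_per_hemi, 3))
    right /= np.linalg.norm(right, axis=1, keepdims=True)
    rows = []
    for i in range(n_per_hemi):
        rows.append((f"lh_parcel_{i:02d}", "left", *left[i], True))
    for i in range(n_per_hemi):
        rows.append((f"rh_parcel_{i:02d}", "right", *right[i], True))
    for i in range(n_subcortical):
        rows.append((f"subcort_{i:02d}", "none", np.nan, np.nan, np.nan, False))
    return pd.DataFrame(rows, columns=["parcel", "hemi", "x", "y", "z", "is_surface"])
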