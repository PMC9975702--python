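"""Run configuration: a single YAML-serialisable tree of stage parameters.

Every random operation's seed, every threshold and every variant flag is
carried here so a run directory can be reproduced from its echoed config.
CLI flags override config-file values.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import yaml

from .inference import MIN_PERMUTATIONS

__all__ = ["RunConfig"]


@dataclass
class PreprocessParams:
    z_extreme: float = 4.0
    max_var_missing: float = 0.5
    max_participant_missing: float = 0.5
    k_impute: int = 1
    int_variant: str = "blom"
    constant_policy: str = "error"
    residualise_on: list = field(default_factory=lambda: ["site", "sequence"])
    volumetric_vars: list = field(default_factory=list)
    global_covariate: str = "etiv"


@dataclass
class DecomposeParams:
    n_comp_brain: int = 30
    n_comp_behav: int = 30
    n_modes: int = 2
    n_restarts: int = 5


@dataclass
class InferenceParams:
    n_perm: int = 1000
    recompute_ica: bool = True


@dataclass
class SplitHalfParams:
    enabled: bool = False
    candidates: list = field(default_factory=lambda: [[30, 30, 2]])
    n_splits: int = 10


@dataclass
class ProjectParams:
    n_spin: int = 1000
    n_boot: int = 1000
    spin_method: str = "nearest"


@dataclass
class RunConfig:
    seed: int = 0
    imaging_path: str | None = None
    behaviour_path: str | None = None
    confounds_path: str | None = None
    categorical_confounds: list = field(
        default_factory=lambda: ["site", "sequence", "sex", "medication"])
    continuous_confounds: list = field(
        default_factory=lambda: ["age", "etiv", "household_income"])
    preprocess: PreprocessParams = field(default_factory=PreprocessParams)
    decompose: DecomposeParams = field(default_factory=DecomposeParams)
    inference: InferenceParams = field(default_factory=InferenceParams)
    splithalf: SplitHalfParams = field(default_factory=SplitHalfParams)
    project: ProjectParams = field(default_factory=ProjectParams)

    def validate(self) -> None:
        if self.inference.n_perm < MIN_PERMUTATIONS:
            raise ValueError(
                f"inference.n_perm={self.inference.n_perm} below the "
                f"minimum {MIN_PERMUTATIONS}")
        if self.decompose.n_modes < 1:
            raise ValueError("decompose.n_modes must be >= 1")
        pp = self.preprocess
        if not (0 < pp.max_var_missing <= 1 and 0 < pp.max_participant_missing <= 1):
            raise ValueError("missingness thresholds must lie in (0, 1]")
        if pp.int_variant not in ("blom", "tukey", "waerden"):
            raise ValueError(f"unknown inverse-normal variant {pp.int_variant!r}")

    # -- (de)serialisation -------------------------------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        for key, sub in (("preprocess", PreprocessParams),
                         ("decompose", DecomposeParams),
                         ("inference", InferenceParams),
                         ("splithalf", SplitHalfParams),
                         ("project", ProjectParams)):
            if key in data and isinstance(data[key], dict):
                data[key] = sub(**data[key])
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})
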