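"""Run configuration: defaults, YAML loading, validation.

Defaults equal the calibrated optimum for the ER-resident benchmark
(k=0.1, lambda=16, omega=0.55; c=1000, gamma=0.01, w=1.2).  A YAML config
file overrides the defaults and command-line flags override the file.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .ensemble import SVMParams
from .pseaac import FeatureParams, load_scales


@dataclass(frozen=True)
class RunConfig:
    feature_params: FeatureParams = field(default_factory=FeatureParams)
    svm_params: SVMParams = field(default_factory=SVMParams)
    partition_seed: int = 0
    reshuffle_per_fold: bool = True
    scales_path: str | None = None

    def scales(self):
        return load_scales(self.scales_path)


_FEATURE_KEYS = {"k", "lambda", "omega"}
_SVM_KEYS = {"c", "gamma", "w"}


def load_config(path: str | Path | None = None,
                overrides: dict | None = None) -> RunConfig:
    """Build a RunConfig from defaults <- YAML file <- explicit overrides.

    Recognized keys: k, lambda, omega, c, gamma, w, partition_seed,
    reshuffle_per_fold, scales_path.  Overrides with value None are ignored
    so that absent CLI flags fall through to the file/defaults.
    """
    merged: dict = {}
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(loaded, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        merged.update(loaded)
    for key, value in (overrides or {}).items():
        if value is not None:
            merged["lambda" if key == "lam" else key] = value

    known = _FEATURE_KEYS | _SVM_KEYS | {"partition_seed",
                                         "reshuffle_per_fold", "scales_path"}
    unknown = set(merged) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")

    fp_kwargs = {("lam" if k == "lambda" else k): merged[k]
                 for k in _FEATURE_KEYS if k in merged}
    svm_kwargs = {k: merged[k] for k in _SVM_KEYS if k in merged}
    return RunConfig(
        feature_params=FeatureParams(**fp_kwargs),
        svm_params=SVMParams(**svm_kwargs),
        partition_seed=int(merged.get("partition_seed", 0)),
        reshuffle_per_fold=bool(merged.get("reshuffle_per_fold", True)),
        scales_path=merged.get("scales_path"),
    )
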