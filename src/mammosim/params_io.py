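"""YAML serialization of rate and effect parameters.

One document with two mappings, ``rates`` and ``effects``, mirroring the
fields of :class:`~mammosim.tissue_dynamics.RateParameters` and
:class:`~mammosim.exposure_effects.EffectParameters`.  The packaged
``data/calibrated_params.yaml`` holds the values produced by running the
package's own staged calibration against its default synthetic population.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import asdict
from pathlib import Path

import numpy as np
import yaml

from .exposure_effects import BrcaVariant, EffectParameters
from .tissue_dynamics import RateParameters

__all__ = ["save_params", "load_params", "calibrated_defaults"]


def _clean(value):
    if isinstance(value, np.ndarray):
        return [float(x) for x in value]
    if isinstance(value, (np.floating, np.integer)):
        return value.item()
    if isinstance(value, BrcaVariant):
        return value.value
    return value


def save_params(
    params: RateParameters, effects: EffectParameters, path: str | Path
) -> None:
    doc = {
        "rates": {k: _clean(v) for k, v in asdict(params).items()},
        "effects": {k: _clean(v) for k, v in asdict(effects).items()},
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))


def load_params(path: str | Path) -> tuple[RateParameters, EffectParameters]:
    try:
        doc = yaml.safe_load(Path(path).read_text())
    except FileNotFoundError:
        raise FileNotFoundError(
            f"parameter file {path} not found; generate one with "
            "'mammosim calibrate' or use the packaged defaults"
        ) from None
    if not isinstance(doc, dict) or "rates" not in doc or "effects" not in doc:
        raise ValueError(
            f"{path}: expected a YAML mapping with 'rates' and 'effects'"
        )
    rates = RateParameters(**{
        k: (np.asarray(v) if k == "loss_fraction" else v)
        for k, v in doc["rates"].items()
    })
    eff = dict(doc["effects"])
    if "brca_variant" in eff:
        eff["brca_variant"] = BrcaVariant(eff["brca_variant"])
    effects = EffectParameters(**eff)
    effects.validate()
    return rates, effects


def calibrated_defaults() -> tuple[RateParameters, EffectParameters]:
    """The packaged calibrated parameter set."""
    path = importlib.resources.files("mammosim") / "data" / "calibrated_params.yaml"
    return load_params(str(path))
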