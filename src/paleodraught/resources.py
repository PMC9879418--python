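"""Access to the bundled editable data files (age scheme, reference herds,
default configuration)."""

from __future__ import annotations

from importlib import resources as _ilr
from pathlib import Path
from typing import Optional, Union

import yaml

from .mortality import AgeClassScheme
from .pathology import ReferencePopulation

__all__ = [
    "data_path",
    "default_age_class_scheme",
    "load_reference_populations",
    "load_default_config_dict",
]


def data_path(name: str) -> Path:
    return Path(str(_ilr.files("paleodraught").joinpath("data", name)))


def default_age_class_scheme() -> AgeClassScheme:
    return AgeClassScheme.from_yaml(data_path("age_classes.yaml"))


def load_reference_populations(
    path: Optional[Union[str, Path]] = None,
) -> list[ReferencePopulation]:
    """Load reference-population index means. The bundled file contains
    clearly labelled synthetic stand-ins, not digitised published values."""
    path = Path(path) if path else data_path("reference_populations_synthetic.yaml")
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    return [
        ReferencePopulation(
            name=p["name"],
            mean_mpi_anterior=p.get("mean_mpi_anterior"),
            mean_mpi_posterior=p.get("mean_mpi_posterior"),
            mean_pi_anterior=p.get("mean_pi_anterior"),
            mean_pi_posterior=p.get("mean_pi_posterior"),
            draught=bool(p.get("draught", False)),
            provenance=p.get("provenance", ""),
        )
        for p in raw["populations"]
    ]


def load_default_config_dict() -> dict:
    with open(data_path("default_config.yaml"), "r", encoding="utf-8") as fh:
        return yaml.safe_load(fh)
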