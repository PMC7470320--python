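"""Accessors for the shipped default configuration files.

Everything the engine consumes — attribute schema, clinical decision trees,
ordinal distance matrices, solution-consistent augmentation intervals — is a
plain YAML config so a site can override it; these helpers load the packaged
defaults.
"""

from __future__ import annotations

from importlib import resources
from typing import Any

import yaml

from .case_model import AttributeSchema, parse_schema_config
from .cdt import ClinicalDecisionTree
from .distance import OrdinalDistanceMatrix, load_matrices

__all__ = [
    "default_schema",
    "default_cdt",
    "default_matrices",
    "default_ifu_ranges",
    "config_path",
]

_CDT_FILES = {
    "vascular_access": "cdt_vascular_access.yaml",
    "prosthesis": "cdt_prosthesis.yaml",
}


def _load(name: str) -> Any:
    with resources.files("tavicbr.configs").joinpath(name).open() as fh:
        return yaml.safe_load(fh)


def config_path(name: str):
    """Filesystem path of a packaged config (for CLI defaults and docs)."""
    return resources.files("tavicbr.configs").joinpath(name)


def default_schema() -> tuple[list[AttributeSchema], dict[str, list[str]], list[str]]:
    """(attributes, decisions, results) of the default TAVI schema."""
    return parse_schema_config(_load("schema_default.yaml"))


def default_cdt(decision: str) -> ClinicalDecisionTree:
    """Packaged clinical decision tree for ``vascular_access`` or ``prosthesis``."""
    if decision not in _CDT_FILES:
        raise KeyError(f"no default CDT for decision {decision!r}")
    doc = _load(_CDT_FILES[decision])
    return ClinicalDecisionTree(decision=doc["decision"], levels=tuple(tuple(lv) for lv in doc["levels"]))


def default_matrices() -> dict[str, OrdinalDistanceMatrix]:
    """Packaged expert ordinal matrices (calcification, both sides)."""
    with resources.as_file(resources.files("tavicbr.configs").joinpath("matrices_default.yaml")) as p:
        return load_matrices(p)


def default_ifu_ranges() -> tuple[str, dict[str, dict[str, tuple[float, float]]]]:
    """(decision name, label -> attribute -> (lo, hi)) augmentation intervals."""
    doc = _load("ifu_ranges.yaml")
    ranges = {
        label: {attr: tuple(bounds) for attr, bounds in attrs.items()}
        for label, attrs in doc["ranges"].items()
    }
    return doc["decision"], ranges
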