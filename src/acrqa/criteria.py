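"""Loading and validation of acceptance-criteria configurations."""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import yaml

__all__ = ["default_criteria", "load_criteria"]

_COMPARATORS = {"ge", "le", "abs_le", "abs_dev_le"}


def _validate(cfg: dict) -> dict:
    for family, c in cfg.items():
        if not isinstance(c, dict) or "comparator" not in c or "bound" not in c:
            raise ValueError(f"criterion {family!r} needs 'comparator' and 'bound'")
        if c["comparator"] not in _COMPARATORS:
            raise ValueError(
                f"criterion {family!r}: unknown comparator {c['comparator']!r}"
            )
    return cfg


def default_criteria() -> dict:
    """The shipped ACR-conventional defaults (see data/criteria.yaml)."""
    text = resources.files("acrqa.data").joinpath("criteria.yaml").read_text()
    return _validate(yaml.safe_load(text))


def load_criteria(path: str | Path) -> dict:
    """Criteria from a user YAML file; same schema as the shipped defaults."""
    with open(path) as fh:
        return _validate(yaml.safe_load(fh))
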