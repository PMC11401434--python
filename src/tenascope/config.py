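"""Packaged default configuration (domain-name synonyms, synteny marker sets)
and helpers to load user overrides from YAML."""
from __future__ import annotations

import functools
from importlib import resources

import yaml

from .records import DomainKind


def _read_packaged(name: str) -> dict:
    with resources.files("tenascope.data").joinpath(name).open() as fh:
        return yaml.safe_load(fh)


@functools.lru_cache(maxsize=None)
def domain_synonyms(path: str | None = None) -> dict[str, DomainKind]:
    """Case-insensitive map from external domain-name strings to DomainKind."""
    raw = yaml.safe_load(open(path)) if path else _read_packaged("domain_synonyms.yaml")
    table: dict[str, DomainKind] = {}
    for kind, names in raw.items():
        for name in names:
            table[name.upper()] = DomainKind(kind)
    return table


@functools.lru_cache(maxsize=None)
def _marker_config(path: str | None = None) -> dict:
    return yaml.safe_load(open(path)) if path else _read_packaged("marker_sets.yaml")


def marker_sets(path: str | None = None) -> dict[str, dict[str, float]]:
    """Per-paralog weighted marker-gene sets."""
    return {
        label: dict(markers)
        for label, markers in _marker_config(path)["marker_sets"].items()
    }


def symbol_synonyms(path: str | None = None) -> dict[str, str]:
    """Uppercased synonym -> canonical symbol map."""
    table: dict[str, str] = {}
    for canonical, alts in _marker_config(path)["symbol_synonyms"].items():
        table[canonical.upper()] = canonical.upper()
        for alt in alts:
            table[alt.upper()] = canonical.upper()
    return table
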