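"""Loaders for the package's bundled configuration data.

The indicator catalog, the abstract code dictionary and the default
(published) calibration counts all live as YAML under ``lungqi/data`` so
that deployments on real data can swap them out without touching code.
"""

from __future__ import annotations

import functools
from importlib import resources as _ires
from pathlib import Path

import yaml

_DATA_PKG = "lungqi.data"


def _read_yaml(name: str, path: str | Path | None = None) -> dict:
    if path is not None:
        with open(path, "r") as fh:
            return yaml.safe_load(fh)
    with _ires.files(_DATA_PKG).joinpath(name).open("r") as fh:
        return yaml.safe_load(fh)


@functools.lru_cache(maxsize=None)
def load_codes(path: str | None = None) -> dict:
    """Code dictionary: token metadata, token groups and Charlson weights."""
    return _read_yaml("codes.yaml", path)


@functools.lru_cache(maxsize=None)
def _load_catalog_raw(path: str | None = None) -> dict:
    return _read_yaml("catalog.yaml", path)


def load_catalog(path: str | None = None):
    """Parsed indicator catalog (an :class:`~lungqi.indicators.IndicatorCatalog`)."""
    from lungqi.indicators import IndicatorCatalog

    return IndicatorCatalog.from_dict(_load_catalog_raw(path), load_codes())


@functools.lru_cache(maxsize=None)
def load_milan_defaults(path: str | None = None) -> dict:
    """Published Milan-cohort marginals and per-indicator calibration counts."""
    return _read_yaml("milan.yaml", path)


@functools.lru_cache(maxsize=None)
def load_delphi_defaults(path: str | None = None) -> dict:
    """Round-1 panel conditions for the synthetic consensus survey."""
    return _read_yaml("delphi_round1.yaml", path)
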