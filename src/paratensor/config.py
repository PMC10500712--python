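"""Editable configuration: isotope gyromagnetic ratios, default CSA tensors
and lanthanide ion templates.

The packaged defaults live in ``data/defaults.toml``.  Users can load a
modified copy with :func:`load_config` or pass an explicit :class:`Config`
to the functions that take one; module-level helpers fall back to the
packaged defaults.
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass
from importlib import resources

import numpy as np

__all__ = [
    "Config",
    "default_config",
    "load_config",
    "gyromagnetic_ratio",
    "lanthanide_template",
]


@dataclass(frozen=True)
class Config:
    isotopes: dict
    csa: dict
    lanthanides: dict

    def gamma(self, element: str) -> float | None:
        """Gyromagnetic ratio (rad s^-1 T^-1) for an element, or None."""
        entry = self.isotopes.get(element.upper().strip())
        return None if entry is None else float(entry["gamma"])


def _from_dict(raw: dict) -> Config:
    return Config(
        isotopes=raw.get("isotopes", {}),
        csa=raw.get("csa", {}),
        lanthanides=raw.get("lanthanides", {}),
    )


def load_config(path) -> Config:
    with open(path, "rb") as fh:
        return _from_dict(tomllib.load(fh))


def _load_default() -> Config:
    text = resources.files("paratensor").joinpath("data/defaults.toml").read_bytes()
    return _from_dict(tomllib.loads(text.decode()))


_DEFAULT: Config | None = None


def default_config() -> Config:
    global _DEFAULT
    if _DEFAULT is None:
        _DEFAULT = _load_default()
    return _DEFAULT


def gyromagnetic_ratio(element: str, config: Config | None = None) -> float | None:
    cfg = config or default_config()
    return cfg.gamma(element)


def lanthanide_template(ion: str, config: Config | None = None) -> dict:
    """Template parameters (g, J, placeholder anisotropies, T1e) for a
    trivalent lanthanide, keyed by element symbol (e.g. ``"Tb"``)."""
    cfg = config or default_config()
    key = ion.strip().rstrip("3+").capitalize()
    try:
        entry = dict(cfg.lanthanides[key])
    except KeyError:
        raise KeyError(f"no lanthanide template for {ion!r}") from None
    return entry


def csa_parameters(element: str, config: Config | None = None):
    """Default CSA principal components (ppm, traceless) and tilt angle
    (radians) for a backbone spin, or None if no default exists."""
    cfg = config or default_config()
    entry = cfg.csa.get(element.upper().strip())
    if entry is None:
        return None
    pas = np.asarray(entry["pas"], dtype=float)
    return pas, float(np.deg2rad(entry.get("beta_deg", 0.0)))
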