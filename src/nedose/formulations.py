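"""Norepinephrine formulation conversion and norepinephrine-equivalent scoring.

Norepinephrine (NE) is marketed both as the free base molecule and as salt
formulations (tartrate, bitartrate, hydrochloride) that contain proportionally
less active base per milligram.  A dose written on a chart therefore depends on
the local reporting convention: the same infusion is ``0.24 ug/kg/min`` of base
or ``0.48 ug/kg/min`` of tartrate.  This module holds the conversion registry
(``reported_salt_dose = base_dose * c_f``) and the weighted-sum
norepinephrine-equivalent (NEE) score used to collapse multi-vasopressor
regimens onto a single NE-rate scale.

Both the conversion factors and the NEE weights are loaded from a shipped
plain-text config (``data/conversion.yaml``) and can be overridden at runtime;
no numeric constant is baked into the computation path.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping, Union

import yaml

__all__ = [
    "FormulationSpec",
    "FormulationRegistry",
    "NeEquivalentWeights",
    "load_conversion_config",
    "default_formulations",
    "default_nee_weights",
    "to_salt",
    "to_base",
    "ne_equivalent",
]


@dataclass(frozen=True)
class FormulationSpec:
    """A dose-reporting convention: a name and a multiplicative factor.

    ``factor`` converts a base-molecule dose into the dose reported under this
    convention (``reported = base * factor``).  The base molecule itself has
    factor exactly 1; every shipped salt has factor >= 1 because a salt
    milligram contains less active base.
    """

    name: str
    factor: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.factor) and self.factor > 0):
            raise ValueError(f"conversion factor must be finite and positive, got {self.factor!r}")


class FormulationRegistry(Mapping[str, FormulationSpec]):
    """Immutable name -> FormulationSpec mapping with a mandatory base entry."""

    def __init__(self, specs: Mapping[str, float]):
        if "base" not in specs:
            raise ValueError("registry must contain the 'base' formulation")
        if specs["base"] != 1.0:
            raise ValueError(f"base formulation factor must be exactly 1.0, got {specs['base']!r}")
        self._specs = {name: FormulationSpec(name, float(c)) for name, c in specs.items()}

    def __getitem__(self, name: str) -> FormulationSpec:
        try:
            return self._specs[name]
        except KeyError:
            raise KeyError(
                f"unknown formulation {name!r}; known: {sorted(self._specs)}"
            ) from None

    def __iter__(self):
        return iter(self._specs)

    def __len__(self) -> int:
        return len(self._specs)

    @property
    def salts(self) -> list[FormulationSpec]:
        return [s for s in self._specs.values() if s.name != "base"]


class NeEquivalentWeights:
    """Drug -> (weight, native rate unit) table for the NEE score.

    The score is the weighted sum ``sum_d w_d * rate_d`` with every rate given
    in the drug's native unit (vasopressin in U/min, catecholamines in
    ug/kg/min).  Weights must be positive and norepinephrine's weight is pinned
    to 1 so the score reduces to the NE rate when NE is the only drug running.
    """

    def __init__(self, table: Mapping[str, Mapping[str, object]]):
        if "norepinephrine" not in table:
            raise ValueError("weight table must include norepinephrine")
        self._table: dict[str, tuple[float, str]] = {}
        for drug, entry in table.items():
            w = float(entry["weight"])
            unit = str(entry["unit"])
            if not (math.isfinite(w) and w > 0):
                raise ValueError(f"weight for {drug!r} must be positive, got {w!r}")
            self._table[drug] = (w, unit)
        if self._table["norepinephrine"][0] != 1.0:
            raise ValueError("norepinephrine weight must be exactly 1.0")

    def weight(self, drug: str) -> float:
        return self._lookup(drug)[0]

    def unit(self, drug: str) -> str:
        return self._lookup(drug)[1]

    def _lookup(self, drug: str) -> tuple[float, str]:
        try:
            return self._table[drug]
        except KeyError:
            raise KeyError(
                f"drug {drug!r} not in NE-equivalent registry; known: {sorted(self._table)}"
            ) from None

    @property
    def drugs(self) -> list[str]:
        return sorted(self._table)


def load_conversion_config(
    path: str | Path | None = None,
) -> tuple[FormulationRegistry, NeEquivalentWeights]:
    """Load formulation factors and NEE weights from YAML.

    With ``path=None`` the shipped default config is used.
    """
    if path is None:
        text = resources.files("nedose.data").joinpath("conversion.yaml").read_text()
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text)
    return (
        FormulationRegistry(raw["formulations"]),
        NeEquivalentWeights(raw["ne_equivalent_weights"]),
    )


_DEFAULTS: tuple[FormulationRegistry, NeEquivalentWeights] | None = None


def _defaults() -> tuple[FormulationRegistry, NeEquivalentWeights]:
    global _DEFAULTS
    if _DEFAULTS is None:
        _DEFAULTS = load_conversion_config()
    return _DEFAULTS


def default_formulations() -> FormulationRegistry:
    """The shipped four-entry registry (base, hydrochloride, bitartrate, tartrate)."""
    return _defaults()[0]


def default_nee_weights() -> NeEquivalentWeights:
    """The shipped NEE weight table."""
    return _defaults()[1]


def _check_dose(dose: float) -> float:
    dose = float(dose)
    if not math.isfinite(dose) or dose < 0:
        raise ValueError(f"dose must be finite and non-negative, got {dose!r}")
    return dose


def _resolve(f: Union[str, FormulationSpec], registry: FormulationRegistry | None) -> FormulationSpec:
    if isinstance(f, FormulationSpec):
        return f
    return (registry or default_formulations())[f]


def to_salt(
    dose_base: float,
    f: Union[str, FormulationSpec],
    registry: FormulationRegistry | None = None,
) -> float:
    """Convert a base-molecule dose (ug/kg/min) to the dose reported as salt ``f``."""
    return _check_dose(dose_base) * _resolve(f, registry).factor


def to_base(
    dose_reported: float,
    f: Union[str, FormulationSpec],
    registry: FormulationRegistry | None = None,
) -> float:
    """Convert a salt-reported dose (ug/kg/min) back to the base-molecule dose."""
    return _check_dose(dose_reported) / _resolve(f, registry).factor


RateInput = Union[float, tuple[float, str]]


def ne_equivalent(
    rates: Mapping[str, RateInput],
    weights: NeEquivalentWeights | None = None,
) -> float:
    """Norepinephrine-equivalent rate (ug/kg/min) of a multi-drug regimen.

    ``rates`` maps drug name to either a bare rate (assumed to be in the drug's
    native unit) or a ``(rate, unit)`` pair; a unit that disagrees with the
    registry's native unit for that drug is an error, not a conversion.
    """
    w = weights or default_nee_weights()
    total = 0.0
    for drug, entry in rates.items():
        if isinstance(entry, tuple):
            rate, unit = entry
            native = w.unit(drug)
            if unit != native:
                raise ValueError(
                    f"rate for {drug!r} given in {unit!r} but registry expects {native!r}"
                )
        else:
            rate = entry
        rate = float(rate)
        if not math.isfinite(rate) or rate < 0:
            raise ValueError(f"rate for {drug!r} must be finite and non-negative, got {rate!r}")
        total += w.weight(drug) * rate
    return total
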