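"""Model parameters for the sigma-factor competition network.

Concentrations of the protein/RNA pools are held in micromolar (the unit
used for input and output); dissociation constants and everything handed to
the solvers are in molar. Chromosomal nonspecific sites and cognate
promoters are specified as copies per cell and converted to molar through
the cell volume by a single helper, :func:`counts_to_molar`.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterator, Mapping

import yaml

AVOGADRO = 6.02214076e23

#: fields interpreted as total pool concentrations, in uM
CONCENTRATION_FIELDS = (
    "E_total",
    "sigma70_total",
    "sigma38_total",
    "Rsd_total",
    "RNA6S_total",
)

#: fields interpreted as dissociation constants, in M
DISSOCIATION_FIELDS = (
    "K_E_sigma70",
    "K_E_sigma38",
    "K_Rsd",
    "K_6S",
    "K_NS",
    "K_EsigmaP",
)


def counts_to_molar(n: float, cell_volume: float) -> float:
    """Convert a per-cell copy number to a molar concentration.

    Parameters
    ----------
    n : float
        Copies per cell.
    cell_volume : float
        Cell volume in liters.
    """
    if cell_volume <= 0:
        raise ValueError("cell_volume must be positive")
    return n / (AVOGADRO * cell_volume)


@dataclass(frozen=True)
class ModelParameters:
    """Total pools, binding constants and rates of the competition network.

    Defaults are the stationary-phase estimates for *E. coli* used
    throughout: 4.3 uM core polymerase, 12 uM sigma70, 2.7 uM sigma38,
    10.4 uM Rsd, 13 uM 6S RNA, 4.6e6 nonspecific chromosomal sites and
    200 cognate promoters per sigma class in a 1 fL cell.
    """

    # total pools, uM
    E_total: float = 4.3
    sigma70_total: float = 12.0
    sigma38_total: float = 2.7
    Rsd_total: float = 10.4
    RNA6S_total: float = 13.0
    # per-cell copy numbers
    DNA_total_sites: float = 4.6e6
    P70_count: float = 200.0
    P38_count: float = 200.0
    # liters
    cell_volume: float = 1e-15
    # dissociation constants, M
    K_E_sigma70: float = 3.3e-9
    K_E_sigma38: float = 15.2e-9
    K_Rsd: float = 32e-9
    K_6S: float = 131e-9
    K_NS: float = 1e-4
    K_EsigmaP: float = 1e-7
    # rates, 1/s
    clearance_rate_c: float = 0.005
    elongation_escape_rate_e: float = 0.021
    # provenance only; elongation escape is given directly as a rate
    operon_length: float = 1000.0

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if not math.isfinite(v):
                raise ValueError(f"{f.name} must be finite, got {v!r}")
            if v < 0:
                raise ValueError(f"{f.name} must be >= 0, got {v!r}")
        if self.cell_volume <= 0:
            raise ValueError("cell_volume must be positive")

    # -- unit views -------------------------------------------------------

    def totals_molar(self) -> dict[str, float]:
        """All conserved totals in molar, including DNA sites and promoters."""
        out = {name: getattr(self, name) * 1e-6 for name in CONCENTRATION_FIELDS}
        out["DNA_total"] = counts_to_molar(self.DNA_total_sites, self.cell_volume)
        out["P70_total"] = counts_to_molar(self.P70_count, self.cell_volume)
        out["P38_total"] = counts_to_molar(self.P38_count, self.cell_volume)
        return out

    # -- plumbing ---------------------------------------------------------

    def replace(self, **changes: float) -> "ModelParameters":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict[str, float]:
        return dataclasses.asdict(self)

    @classmethod
    def field_names(cls) -> tuple[str, ...]:
        return tuple(f.name for f in dataclasses.fields(cls))

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "ModelParameters":
        unknown = set(d) - set(cls.field_names())
        if unknown:
            raise KeyError(f"unknown parameter(s): {sorted(unknown)}")
        return cls(**{k: float(v) for k, v in d.items()})

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ModelParameters":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    def __iter__(self) -> Iterator[tuple[str, float]]:
        return iter(self.to_dict().items())


def default_parameters_path() -> Path:
    """Path of the packaged default parameter file (YAML)."""
    return Path(__file__).parent / "data" / "default_parameters.yaml"
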