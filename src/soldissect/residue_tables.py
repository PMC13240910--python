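"""Per-residue constants and residue-group definitions.

This module is the single source of truth for every residue-level scale used
by feature extraction: average residue masses, Kyte-Doolittle hydropathy,
Chou-Fasman secondary-structure propensities, a residue-level disorder
propensity scale with its threshold, side-chain/termini pKa values, and the
physicochemical residue groups. All scales are overridable from a YAML config
so alternative literature scales (e.g. a different disorder scale) can be
substituted without code changes; provenance strings travel with the tables
so reports can state which scales produced a run.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import yaml

CANONICAL_RESIDUES: str = "ACDEFGHIKLMNPQRSTVWY"
AMBIGUOUS_RESIDUES: frozenset[str] = frozenset("XBZUO")

STRUCTURE_CLASSES = ("helix", "sheet", "turn")
GROUP_NAMES = ("positive", "negative", "polar", "hydrophobic", "tiny", "sulfur")

# Expasy average residue masses (Da); peptide mass = sum + one water.
_AVERAGE_RESIDUE_MASS = {
    "A": 71.0788, "C": 103.1388, "D": 115.0886, "E": 129.1155, "F": 147.1766,
    "G": 57.0519, "H": 137.1411, "I": 113.1594, "K": 128.1741, "L": 113.1594,
    "M": 131.1926, "N": 114.1038, "P": 97.1167, "Q": 128.1307, "R": 156.1875,
    "S": 87.0782, "T": 101.1051, "V": 99.1326, "W": 186.2132, "Y": 163.1760,
}
_WATER_MASS = 18.01524

# Kyte & Doolittle (1982) hydropathy index.
_KYTE_DOOLITTLE = {
    "A": 1.8, "C": 2.5, "D": -3.5, "E": -3.5, "F": 2.8,
    "G": -0.4, "H": -3.2, "I": 4.5, "K": -3.9, "L": 3.8,
    "M": 1.9, "N": -3.5, "P": -1.6, "Q": -3.5, "R": -4.5,
    "S": -0.8, "T": -0.7, "V": 4.2, "W": -0.9, "Y": -1.3,
}

# Chou & Fasman (1978) conformational parameters.
_CHOU_FASMAN = {
    "helix": {
        "A": 1.42, "C": 0.70, "D": 1.01, "E": 1.51, "F": 1.13,
        "G": 0.57, "H": 1.00, "I": 1.08, "K": 1.16, "L": 1.21,
        "M": 1.45, "N": 0.67, "P": 0.57, "Q": 1.11, "R": 0.98,
        "S": 0.77, "T": 0.83, "V": 1.06, "W": 1.08, "Y": 0.69,
    },
    "sheet": {
        "A": 0.83, "C": 1.19, "D": 0.54, "E": 0.37, "F": 1.38,
        "G": 0.75, "H": 0.87, "I": 1.60, "K": 0.74, "L": 1.30,
        "M": 1.05, "N": 0.89, "P": 0.55, "Q": 1.10, "R": 0.93,
        "S": 0.75, "T": 1.19, "V": 1.70, "W": 1.37, "Y": 1.47,
    },
    "turn": {
        "A": 0.66, "C": 1.19, "D": 1.46, "E": 0.74, "F": 0.60,
        "G": 1.56, "H": 0.95, "I": 0.47, "K": 1.01, "L": 0.59,
        "M": 0.60, "N": 1.56, "P": 1.52, "Q": 0.98, "R": 0.95,
        "S": 1.43, "T": 0.96, "V": 0.50, "W": 0.96, "Y": 1.14,
    },
}

# TOP-IDP disorder propensity scale (Campen et al., 2008); residues with
# d(a) > tau count toward the disorder ratio. tau=0 splits the scale at its
# order/disorder crossover; both scale and tau are configurable.
_TOP_IDP = {
    "A": 0.060, "C": 0.020, "D": 0.192, "E": 0.736, "F": -0.697,
    "G": 0.166, "H": 0.303, "I": -0.486, "K": 0.586, "L": -0.326,
    "M": -0.397, "N": 0.007, "P": 0.987, "Q": 0.318, "R": 0.180,
    "S": 0.341, "T": 0.059, "V": -0.121, "W": -0.884, "Y": -0.510,
}
_DEFAULT_DISORDER_THRESHOLD = 0.0

# EMBOSS pKa set: seven ionizable side chains plus the two termini.
PKA_SIDE_CHAINS = ("D", "E", "C", "Y", "H", "K", "R")
_EMBOSS_PKA = {
    "D": 3.9, "E": 4.1, "C": 8.5, "Y": 10.1, "H": 6.5, "K": 10.8, "R": 12.5,
    "n_term": 8.6, "c_term": 3.6,
}

_GROUPS = {
    "positive": frozenset("KRH"),
    "negative": frozenset("DE"),
    "polar": frozenset("STNQ"),
    "hydrophobic": frozenset("AVILMFWY"),
    "tiny": frozenset("AGST"),
    "sulfur": frozenset("CM"),
}

_DEFAULT_PROVENANCE = {
    "masses": "Expasy average residue masses",
    "hydropathy": "Kyte & Doolittle (1982)",
    "propensities": "Chou & Fasman (1978)",
    "disorder": "TOP-IDP (Campen et al., 2008), tau=0.0",
    "pka": "EMBOSS side-chain and termini pKa set",
    "groups": "charge/polarity/hydrophobicity/size/sulfur residue groups",
}


class TableValidationError(ValueError):
    """A residue scale or group set violates the table invariants."""


def _check_residue_map(name: str, mapping: Mapping[str, float]) -> dict[str, float]:
    missing = [a for a in CANONICAL_RESIDUES if a not in mapping]
    if missing:
        raise TableValidationError(
            f"scale {name!r} is missing residue(s): {', '.join(missing)}"
        )
    extra = sorted(set(mapping) - set(CANONICAL_RESIDUES))
    if extra:
        raise TableValidationError(f"scale {name!r} has unknown residue(s): {extra}")
    out = {}
    for a in CANONICAL_RESIDUES:
        v = mapping[a]
        if not isinstance(v, (int, float)) or isinstance(v, bool):
            raise TableValidationError(f"scale {name!r}[{a}] is not numeric: {v!r}")
        out[a] = float(v)
    return out


@dataclass(frozen=True)
class ResiduePropertyTables:
    """All per-residue scales and group sets used by feature extraction."""

    masses: dict[str, float]
    water_mass: float
    hydropathy: dict[str, float]
    propensities: dict[str, dict[str, float]]
    disorder_scale: dict[str, float]
    disorder_threshold: float
    pka: dict[str, float]
    groups: dict[str, frozenset[str]]
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "masses", _check_residue_map("masses", self.masses))
        if any(v <= 0 for v in self.masses.values()):
            raise TableValidationError("all residue masses must be positive")
        if self.water_mass <= 0:
            raise TableValidationError("water_mass must be positive")
        object.__setattr__(
            self, "hydropathy", _check_residue_map("hydropathy", self.hydropathy)
        )
        props = dict(self.propensities)
        if set(props) != set(STRUCTURE_CLASSES):
            raise TableValidationError(
                f"propensities must cover exactly {STRUCTURE_CLASSES}, got {sorted(props)}"
            )
        for s in STRUCTURE_CLASSES:
            props[s] = _check_residue_map(f"propensities[{s}]", props[s])
        object.__setattr__(self, "propensities", props)
        object.__setattr__(
            self, "disorder_scale", _check_residue_map("disorder", self.disorder_scale)
        )
        expected_pka = set(PKA_SIDE_CHAINS) | {"n_term", "c_term"}
        if set(self.pka) != expected_pka:
            raise TableValidationError(
                f"pka must cover exactly {sorted(expected_pka)}, got {sorted(self.pka)}"
            )
        groups = {k: frozenset(v) for k, v in self.groups.items()}
        if set(groups) != set(GROUP_NAMES):
            raise TableValidationError(
                f"groups must cover exactly {GROUP_NAMES}, got {sorted(groups)}"
            )
        for gname, members in groups.items():
            bad = sorted(set(members) - set(CANONICAL_RESIDUES))
            if bad:
                raise TableValidationError(f"group {gname!r} has unknown residue(s): {bad}")
        object.__setattr__(self, "groups", groups)

    def to_config_dict(self) -> dict:
        """Serialize every scale to a plain (YAML-friendly) dictionary."""
        return {
            "masses": dict(self.masses),
            "water_mass": self.water_mass,
            "hydropathy": dict(self.hydropathy),
            "propensities": {s: dict(m) for s, m in self.propensities.items()},
            "disorder": {
                "scale": dict(self.disorder_scale),
                "threshold": self.disorder_threshold,
            },
            "pka": dict(self.pka),
            "groups": {g: sorted(m) for g, m in self.groups.items()},
            "provenance": dict(self.provenance),
        }


def load_default_tables() -> ResiduePropertyTables:
    """Return the documented default scale set (see module docstring)."""
    return ResiduePropertyTables(
        masses=dict(_AVERAGE_RESIDUE_MASS),
        water_mass=_WATER_MASS,
        hydropathy=dict(_KYTE_DOOLITTLE),
        propensities={s: dict(m) for s, m in _CHOU_FASMAN.items()},
        disorder_scale=dict(_TOP_IDP),
        disorder_threshold=_DEFAULT_DISORDER_THRESHOLD,
        pka=dict(_EMBOSS_PKA),
        groups=dict(_GROUPS),
        provenance=dict(_DEFAULT_PROVENANCE),
    )


def load_tables_from_config(path: str | Path) -> ResiduePropertyTables:
    """Load tables from a YAML config; unspecified entries fall back to defaults.

    The file may contain any subset of the sections written by
    :func:`write_tables_config`. A partially specified residue scale is a
    validation error naming the missing residue (silent fallback inside one
    scale would be ambiguous).
    """
    path = Path(path)
    with open(path) as fh:
        try:
            cfg = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            raise ValueError(f"could not parse tables config {path}: {exc}") from exc
    if cfg is None:
        cfg = {}
    if not isinstance(cfg, dict):
        raise ValueError(f"tables config {path} must be a mapping")

    base = load_default_tables()
    masses = dict(cfg.get("masses", base.masses))
    water = cfg.get("water_mass", base.water_mass)
    hydropathy = dict(cfg.get("hydropathy", base.hydropathy))
    props = {s: dict(m) for s, m in base.propensities.items()}
    for s, m in dict(cfg.get("propensities", {})).items():
        props[s] = dict(m)
    disorder_cfg = dict(cfg.get("disorder", {}))
    disorder_scale = dict(disorder_cfg.get("scale", base.disorder_scale))
    tau = disorder_cfg.get("threshold", base.disorder_threshold)
    pka = dict(base.pka)
    pka.update(dict(cfg.get("pka", {})))
    groups = dict(base.groups)
    for g, members in dict(cfg.get("groups", {})).items():
        groups[g] = frozenset(members)
    provenance = dict(base.provenance)
    provenance.update(dict(cfg.get("provenance", {})))
    return ResiduePropertyTables(
        masses=masses,
        water_mass=float(water),
        hydropathy=hydropathy,
        propensities=props,
        disorder_scale=disorder_scale,
        disorder_threshold=float(tau),
        pka=pka,
        groups=groups,
        provenance=provenance,
    )


def write_tables_config(tables: ResiduePropertyTables, path: str | Path) -> None:
    """Write a complete YAML config that round-trips through the loader."""
    with open(path, "w") as fh:
        yaml.safe_dump(tables.to_config_dict(), fh, sort_keys=True)


def default_config_path() -> Path:
    """Path of the documented default tables config shipped with the package."""
    return Path(__file__).parent / "data" / "default_tables.yaml"
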