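"""Protein panel definitions for cyclic immunofluorescence experiments.

A t-CyCIF experiment assays a fixed marker panel over multiple
stain-image-inactivate rounds. Markers fall into two roles: *lineage*
proteins identify cell types (CD45 for immune cells, cytokeratins for
epithelium, ...) while *functional* proteins report cell state
(proliferation, signalling, hormone receptors). The round a marker belongs
to matters for multi-protein imputation, where whole acquisition rounds are
withheld at once.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import yaml


class Role(str, enum.Enum):
    LINEAGE = "lineage"
    FUNCTIONAL = "functional"


@dataclass(frozen=True)
class Protein:
    name: str
    role: Role
    round: int

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("protein name must be non-empty")
        if self.round < 1:
            raise ValueError(f"staining round must be >= 1, got {self.round}")


# The 16-marker breast-cancer panel: 8 lineage + 8 functional markers,
# 4 markers per staining round.
_DEFAULT_ENTRIES: tuple[tuple[str, Role, int], ...] = (
    ("CD45", Role.LINEAGE, 1),
    ("aSMA", Role.LINEAGE, 1),
    ("eCadherin", Role.LINEAGE, 1),
    ("CK19", Role.LINEAGE, 1),
    ("CK14", Role.LINEAGE, 2),
    ("CK17", Role.LINEAGE, 2),
    ("CK7", Role.LINEAGE, 2),
    ("Vimentin", Role.LINEAGE, 2),
    ("Ki67", Role.FUNCTIONAL, 3),
    ("pERK", Role.FUNCTIONAL, 3),
    ("PR", Role.FUNCTIONAL, 3),
    ("EGFR", Role.FUNCTIONAL, 3),
    ("p21", Role.FUNCTIONAL, 4),
    ("pRB", Role.FUNCTIONAL, 4),
    ("AR", Role.FUNCTIONAL, 4),
    ("HER2", Role.FUNCTIONAL, 4),
)


@dataclass(frozen=True)
class ProteinPanel:
    """An ordered marker panel with lineage/functional roles and rounds."""

    proteins: tuple[Protein, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        names = [p.name for p in self.proteins]
        if len(set(names)) != len(names):
            raise ValueError("panel protein names must be unique")

    @classmethod
    def default(cls) -> "ProteinPanel":
        """The 16-protein breast-cancer t-CyCIF panel."""
        return cls(tuple(Protein(n, r, rd) for n, r, rd in _DEFAULT_ENTRIES))

    @classmethod
    def from_entries(
        cls, entries: Iterable[tuple[str, str | Role, int]]
    ) -> "ProteinPanel":
        return cls(tuple(Protein(n, Role(r), rd) for n, r, rd in entries))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ProteinPanel":
        """Load a panel from YAML mapping ``name -> {role, round}``."""
        with open(path) as fh:
            raw: Mapping[str, Mapping[str, object]] = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise ValueError(f"panel YAML must be a mapping, got {type(raw)}")
        return cls.from_entries(
            (name, str(spec["role"]), int(spec["round"]))  # type: ignore[index]
            for name, spec in raw.items()
        )

    def to_yaml(self, path: str | Path) -> None:
        data = {
            p.name: {"role": p.role.value, "round": p.round} for p in self.proteins
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    @property
    def names(self) -> list[str]:
        return [p.name for p in self.proteins]

    @property
    def lineage(self) -> list[str]:
        return [p.name for p in self.proteins if p.role is Role.LINEAGE]

    @property
    def functional(self) -> list[str]:
        return [p.name for p in self.proteins if p.role is Role.FUNCTIONAL]

    @property
    def rounds(self) -> dict[int, list[str]]:
        """Marker names grouped by staining round, round-sorted."""
        out: dict[int, list[str]] = {}
        for p in self.proteins:
            out.setdefault(p.round, []).append(p.name)
        return dict(sorted(out.items()))

    def role_of(self, name: str) -> Role:
        for p in self.proteins:
            if p.name == name:
                return p.role
        raise KeyError(f"protein {name!r} not in panel")

    def __len__(self) -> int:
        return len(self.proteins)

    def __contains__(self, name: object) -> bool:
        return name in set(self.names)
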