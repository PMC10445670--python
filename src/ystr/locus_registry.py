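"""Static registry of Y-STR loci and combined marker panels.

The registry describes the 41 loci of the 41-plex kit: copy number
(the four multi-copy markers DYF387S1a/b, DYF404S1a/b, DYS385a/b and
DYS527a/b are single registry entries with ``copy_number == 2``),
repeat-unit length, motif complexity class, mutation-rate band, and the
per-locus rules used to turn a parsed repeat structure into an allele
designation.  Panels are named subsets (minimal haplotype, SWGDAM,
Yfiler, ... full kit) used to project haplotype statistics.

Both tables ship as editable YAML under :mod:`ystr.data`; a custom
registry can be loaded from any file with the same layout.
"""

from __future__ import annotations

import difflib
import re
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import yaml

__all__ = [
    "LocusSpec",
    "PanelSpec",
    "Registry",
    "UnknownLocusError",
    "UnknownPanelError",
    "default_registry",
]

MOTIF_CLASSES = ("simple", "compound", "complex")
RM_STATUSES = ("RM", "fast", "moderate", "slow")


class UnknownLocusError(KeyError):
    """Raised when a locus name is not in the registry."""

    def __init__(self, name: str, suggestions: list[str]):
        self.name = name
        self.suggestions = suggestions
        hint = f"; did you mean {', '.join(suggestions)}?" if suggestions else ""
        super().__init__(f"unknown locus {name!r}{hint}")


class UnknownPanelError(KeyError):
    def __init__(self, name: str, known: Iterable[str]):
        super().__init__(f"unknown panel {name!r}; available: {', '.join(known)}")


@dataclass(frozen=True)
class LocusSpec:
    """Description of one Y-STR marker.

    ``copy_number`` is the number of amplified copies per male (2 for the
    a/b duplicated markers), ``unit_length_bp`` the length of the core
    repeat unit in base pairs, ``motif_class`` the simple/compound/complex
    complexity class and ``rm_status`` the mutation-rate band with ``RM``
    flagging the initially defined rapidly mutating panel.

    ``canonical_spacer_bp`` and ``designation_offset`` parameterize the
    allele-designation rule applied to parsed repeat structures: repeat
    blocks and full-length single units are summed, shifted by the offset,
    and any deviation of the spacer total from its canonical length is
    expressed as a .x microvariant suffix.
    """

    name: str
    copy_number: int
    unit_length_bp: int
    motif_class: str
    rm_status: str
    typical_allele: int = 0
    canonical_spacer_bp: int | None = None
    designation_offset: int = 0

    def __post_init__(self) -> None:
        if self.copy_number not in (1, 2):
            raise ValueError(f"{self.name}: copy_number must be 1 or 2")
        if self.unit_length_bp not in (3, 4, 5, 6):
            raise ValueError(f"{self.name}: unit_length_bp must be 3..6")
        if self.motif_class not in MOTIF_CLASSES:
            raise ValueError(f"{self.name}: bad motif_class {self.motif_class!r}")
        if self.rm_status not in RM_STATUSES:
            raise ValueError(f"{self.name}: bad rm_status {self.rm_status!r}")

    @property
    def is_multi_copy(self) -> bool:
        return self.copy_number == 2

    @property
    def is_rm(self) -> bool:
        return self.rm_status == "RM"


@dataclass(frozen=True)
class PanelSpec:
    """A named combined Y-STR system.

    ``n_l`` is the conventionally *reported* locus count for the system
    and is carried as metadata; ``expanded_size(registry)`` gives the
    copy-number-weighted size of the actual locus list (the two can
    disagree where the literature count does not match the kit contents).
    """

    name: str
    loci: tuple[str, ...]
    n_l: int

    def expanded_size(self, registry: "Registry") -> int:
        return sum(registry.get_locus(l).copy_number for l in self.loci)


def _normalize(name: str) -> str:
    # case/punctuation-insensitive key; "DYS385a/b" == "dys385 a/b" == "DYS385"
    key = re.sub(r"[\s\-_/]", "", name).upper()
    key = re.sub(r"AB$", "", key)
    return key


class Registry:
    """Lookup table of :class:`LocusSpec` and :class:`PanelSpec` entries."""

    def __init__(self, loci: Iterable[LocusSpec], panels: Iterable[PanelSpec] = ()):
        self._loci: dict[str, LocusSpec] = {}
        self._alias: dict[str, str] = {}
        for spec in loci:
            if spec.name in self._loci:
                raise ValueError(f"duplicate locus {spec.name}")
            self._loci[spec.name] = spec
            self._alias[_normalize(spec.name)] = spec.name
        self._panels: dict[str, PanelSpec] = {}
        self._panel_alias: dict[str, str] = {}
        for p in panels:
            unknown = [l for l in p.loci if not self.knows(l)]
            if unknown:
                raise ValueError(f"panel {p.name}: unknown loci {unknown}")
            self._panels[p.name] = p
            self._panel_alias[_normalize(p.name)] = p.name

    # -- loci ----------------------------------------------------------
    def knows(self, name: str) -> bool:
        return _normalize(name) in self._alias

    def get_locus(self, name: str) -> LocusSpec:
        key = _normalize(name)
        if key not in self._alias:
            near = difflib.get_close_matches(key, self._alias, n=3, cutoff=0.6)
            raise UnknownLocusError(name, [self._alias[m] for m in near])
        return self._loci[self._alias[key]]

    def canonical_name(self, name: str) -> str:
        return self.get_locus(name).name

    @property
    def locus_names(self) -> tuple[str, ...]:
        return tuple(self._loci)

    def __iter__(self):
        return iter(self._loci.values())

    def __len__(self) -> int:
        return len(self._loci)

    @property
    def n_loci(self) -> int:
        """Total locus count with dual-copy markers counted twice."""
        return sum(s.copy_number for s in self)

    def transfers_per_pair(self) -> int:
        """Allele transmissions per father-son meiosis over the whole kit."""
        return self.n_loci

    def loci_by(self, attribute: str) -> dict[object, list[str]]:
        """Group locus names by a LocusSpec attribute (e.g. unit_length_bp)."""
        groups: dict[object, list[str]] = {}
        for spec in self:
            groups.setdefault(getattr(spec, attribute), []).append(spec.name)
        return groups

    # -- panels --------------------------------------------------------
    def panel(self, name: str) -> PanelSpec:
        key = _normalize(name)
        if key not in self._panel_alias:
            raise UnknownPanelError(name, self._panels)
        return self._panels[self._panel_alias[key]]

    @property
    def panel_names(self) -> tuple[str, ...]:
        return tuple(self._panels)


def _load(source) -> Mapping:
    if isinstance(source, Path) or (isinstance(source, str) and "\n" not in source):
        with open(source, "r", encoding="utf-8") as fh:
            return yaml.safe_load(fh)
    return yaml.safe_load(source)


def registry_from_yaml(loci_source, panels_source=None) -> Registry:
    """Build a registry from YAML files/streams with ``loci:``/``panels:`` maps."""
    loci_doc = _load(loci_source)
    loci = [
        LocusSpec(name=name, **fields) for name, fields in loci_doc["loci"].items()
    ]
    panels: list[PanelSpec] = []
    if panels_source is not None:
        panel_doc = _load(panels_source)
        for name, fields in panel_doc["panels"].items():
            panels.append(
                PanelSpec(name=name, loci=tuple(fields["loci"]), n_l=int(fields["n_l"]))
            )
    return Registry(loci, panels)


@lru_cache(maxsize=1)
def default_registry() -> Registry:
    """The 41-locus kit registry and seven standard panels shipped as data."""
    data = resources.files("ystr.data")
    return registry_from_yaml(
        (data / "loci.yaml").read_text(encoding="utf-8"),
        (data / "panels.yaml").read_text(encoding="utf-8"),
    )
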