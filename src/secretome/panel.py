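"""The 32-plex adaptive immune cytokine panel and its five functional groups.

The IsoPlexis single-cell secretome assay measures 32 cytokines per cell,
conventionally partitioned into five functional categories (chemoattractive,
effector, inflammatory, stimulatory, regulatory). Everything downstream —
polyfunctional strength indices, group-restricted MFI sums, heatmap blocks —
is defined relative to this partition, so the panel is a first-class,
validated object rather than a list of column names.
"""

from __future__ import annotations

import json
import unicodedata
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml

__all__ = [
    "CytokinePanel",
    "PanelMatchReport",
    "default_panel",
    "validate_panel",
    "normalize_name",
]

GROUP_NAMES = ("chemoattractive", "effector", "inflammatory", "stimulatory", "regulatory")

# Default adaptive immune panel. "IP-20" is the canonical token as printed by
# the assay vendor's grouping we follow; "IP-10" (the usual chemokine name)
# is registered as an alias of the same analyte.
_DEFAULT_GROUPS: dict[str, tuple[str, ...]] = {
    "chemoattractive": ("CCL-11", "IP-20", "MIP-1β", "RANTES"),
    "effector": ("Granzyme B", "IFNγ", "MIP-1α", "Perforin", "TNFα", "TNFβ"),
    "inflammatory": ("IL1β", "IL6", "IL17A", "IL17F", "MCP-1", "MCP-4"),
    "stimulatory": ("GMCSF", "IL2", "IL5", "IL7", "IL8", "IL9", "IL12", "IL15", "IL21"),
    "regulatory": ("IL4", "IL10", "IL13", "IL22", "TGFβ1", "sCD137", "sCD40L"),
}

# Extra accepted spellings (after normalization) → canonical cytokine name.
_EXTRA_ALIASES = {
    "ip10": "IP-20",
    "ccl11": "CCL-11",
    "eotaxin": "CCL-11",
    "granzymeb": "Granzyme B",
    "grzb": "Granzyme B",
    "tgfb": "TGFβ1",
}

_GREEK = {"α": "a", "β": "b", "γ": "g", "δ": "d"}


def normalize_name(name: str) -> str:
    """Canonical key for a cytokine name: case-folded, Greek letters mapped to
    ASCII, hyphens/spaces/underscores stripped.

    The literature mixes spellings freely (TNFa / TNF-α / tnfa); this
    normalization makes them collide on purpose.
    """
    s = unicodedata.normalize("NFC", name.strip())
    for greek, ascii_ in _GREEK.items():
        s = s.replace(greek, ascii_)
    s = s.lower()
    for ch in (" ", "-", "_", "."):
        s = s.replace(ch, "")
    return s


@dataclass(frozen=True)
class CytokinePanel:
    """An ordered cytokine list partitioned into named functional groups.

    Invariants (checked at construction): names unique, every cytokine in
    exactly one group, and the union of groups equals the panel.
    """

    cytokines: tuple[str, ...]
    groups: Mapping[str, frozenset[str]]
    _alias_map: dict[str, str] = field(repr=False, compare=False, default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.cytokines)) != len(self.cytokines):
            raise ValueError("panel cytokine names must be unique")
        seen: dict[str, str] = {}
        for gname, members in self.groups.items():
            for c in members:
                if c not in self.cytokines:
                    raise ValueError(f"group {gname!r} contains unknown cytokine {c!r}")
                if c in seen:
                    raise ValueError(
                        f"cytokine {c!r} appears in both {seen[c]!r} and {gname!r}"
                    )
                seen[c] = gname
        missing = set(self.cytokines) - set(seen)
        if missing:
            raise ValueError(f"cytokines not assigned to any group: {sorted(missing)}")
        alias = dict(self._alias_map)
        for c in self.cytokines:
            alias.setdefault(normalize_name(c), c)
        object.__setattr__(self, "_alias_map", alias)

    def __len__(self) -> int:
        return len(self.cytokines)

    def group(self, name: str) -> frozenset[str]:
        return self.groups[name]

    def group_of(self, cytokine: str) -> str:
        canonical = self.resolve(cytokine)
        for gname, members in self.groups.items():
            if canonical in members:
                return gname
        raise KeyError(cytokine)

    def resolve(self, name: str) -> str:
        """Map any accepted spelling to the canonical panel name."""
        key = normalize_name(name)
        try:
            return self._alias_map[key]
        except KeyError:
            raise KeyError(f"{name!r} is not a cytokine of this panel") from None

    def is_member(self, name: str) -> bool:
        return normalize_name(name) in self._alias_map

    # -- serialization --------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "cytokines": list(self.cytokines),
            "groups": {g: sorted(m) for g, m in self.groups.items()},
        }

    @classmethod
    def from_dict(cls, d: Mapping, aliases: Mapping[str, str] | None = None) -> "CytokinePanel":
        extra = {normalize_name(k): v for k, v in (aliases or {}).items()}
        return cls(
            cytokines=tuple(d["cytokines"]),
            groups={g: frozenset(m) for g, m in d["groups"].items()},
            _alias_map=extra,
        )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), allow_unicode=True, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CytokinePanel":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), ensure_ascii=False, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "CytokinePanel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def default_panel() -> CytokinePanel:
    """The 32-plex human adaptive immune panel with its five-group partition."""
    cytokines = tuple(c for g in GROUP_NAMES for c in _DEFAULT_GROUPS[g])
    return CytokinePanel(
        cytokines=cytokines,
        groups={g: frozenset(m) for g, m in _DEFAULT_GROUPS.items()},
        _alias_map={k: v for k, v in _EXTRA_ALIASES.items()},
    )


@dataclass(frozen=True)
class PanelMatchReport:
    """Result of matching a table header against a panel."""

    matched: dict[str, str]  # column name -> canonical cytokine
    missing: tuple[str, ...]  # panel cytokines with no column
    extra: tuple[str, ...]  # columns that are not panel cytokines

    @property
    def complete(self) -> bool:
        return not self.missing


def validate_panel(panel: CytokinePanel, columns: Sequence[str] | Iterable[str]) -> PanelMatchReport:
    """Match table columns against panel cytokines under name normalization.

    Raises ``ValueError`` if two columns collide on the same cytokine after
    normalization (e.g. both "TNFa" and "TNF-α" present).
    """
    columns = list(columns)
    matched: dict[str, str] = {}
    claimed: dict[str, str] = {}
    extra: list[str] = []
    for col in columns:
        if panel.is_member(col):
            canonical = panel.resolve(col)
            if canonical in claimed:
                raise ValueError(
                    f"columns {claimed[canonical]!r} and {col!r} both normalize to "
                    f"panel cytokine {canonical!r}"
                )
            claimed[canonical] = col
            matched[col] = canonical
        else:
            extra.append(col)
    missing = tuple(c for c in panel.cytokines if c not in claimed)
    return PanelMatchReport(matched=matched, missing=missing, extra=tuple(extra))
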