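"""Preferred Term -> System Organ Class mapping from a user-supplied table.

The MedDRA dictionary is licensed and is not bundled: callers provide a TSV
with columns ``pt``, ``soc_code``, ``soc_name`` (each PT mapped to its single
primary SOC). Lookups are case-insensitive after whitespace normalization, and
unmapped PTs are tagged and counted, never silently dropped.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Tuple

from .cohort import normalize_name

UNMAPPED_SOC = "<unmapped>"


class MeddraFormatError(ValueError):
    """Raised for malformed or internally conflicting mapping tables."""


@dataclass
class PtSocMap:
    """PT -> (soc_code, soc_name) lookup, keyed on normalized PT strings."""

    entries: Dict[str, Tuple[Optional[int], str]] = field(default_factory=dict)
    version_label: str = ""

    def __len__(self) -> int:
        return len(self.entries)

    @classmethod
    def from_rows(
        cls, rows: Iterable[Tuple[str, Optional[int], str]], version_label: str = ""
    ) -> "PtSocMap":
        entries: Dict[str, Tuple[Optional[int], str]] = {}
        conflicts: List[str] = []
        for pt, soc_code, soc_name in rows:
            if not soc_name:
                raise MeddraFormatError(f"PT {pt!r} has an empty SOC name")
            key = normalize_name(pt)
            value = (soc_code, soc_name)
            if key in entries and entries[key] != value:
                conflicts.append(pt)
            else:
                entries[key] = value
        if conflicts:
            raise MeddraFormatError(
                "conflicting SOC assignments for PT(s): " + ", ".join(sorted(set(conflicts)))
            )
        return cls(entries=entries, version_label=version_label)


def load_map(path: str | Path, version_label: str = "") -> PtSocMap:
    """Load a PT->SOC mapping TSV (columns pt, soc_code, soc_name).

    Duplicate consistent rows deduplicate silently; duplicates that disagree
    on the SOC raise an error naming the offending PTs.
    """
    path = Path(path)
    rows: List[Tuple[str, Optional[int], str]] = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"pt", "soc_code", "soc_name"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise MeddraFormatError(
                f"{path}: mapping table must have columns pt, soc_code, soc_name"
            )
        for row in reader:
            code = row["soc_code"].strip()
            rows.append(
                (row["pt"].strip(), int(code) if code else None, row["soc_name"].strip())
            )
    return PtSocMap.from_rows(rows, version_label=version_label)


def assign_soc(pt: str, mapping: PtSocMap) -> Optional[Tuple[Optional[int], str]]:
    """Primary SOC for a PT, or None when the PT is not in the mapping."""
    return mapping.entries.get(normalize_name(pt))


def unmapped_report(pts: Iterable[str], mapping: PtSocMap) -> Dict[str, int]:
    """Count occurrences of PTs that the mapping does not cover.

    Together with the mapped terms this reconciles exactly with the input:
    every PT is either mapped or appears here.
    """
    counts: Dict[str, int] = {}
    for pt in pts:
        if assign_soc(pt, mapping) is None:
            counts[pt] = counts.get(pt, 0) + 1
    return counts


def write_unmapped_report(counts: Dict[str, int], path: str | Path) -> Path:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("pt\tcount\n")
        for pt in sorted(counts):
            fh.write(f"{pt}\t{counts[pt]}\n")
    return path
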