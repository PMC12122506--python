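"""Drug-name normalization and preferred-term (PT) -> system-organ-class (SOC) coding.

MedDRA itself is licensed and cannot be redistributed, so the coding table is
supplied by the user as a plain two-column TSV (or produced by the synthetic
generator). Each PT maps to exactly one SOC, mirroring MedDRA primary-SOC
semantics, so SOC-level counts partition the mapped PT occurrences.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

#: Sentinel returned for PTs absent from the coding table.
UNMAPPED = "<unmapped>"

_WS = re.compile(r"\s+")


def normalize_drugname(raw: str) -> str:
    """Trim, case-fold and collapse internal whitespace of a verbatim drug name."""
    return _WS.sub(" ", raw.strip()).casefold()


@dataclass
class CodingTable:
    """A total PT -> SOC map with case-insensitive lookup.

    Parameters
    ----------
    pt_to_soc
        Mapping from preferred term to its (single, primary) system organ class.
    version_label
        Free-text provenance label, e.g. ``"MedDRA 26.1"`` or ``"toy-v1"``.
    """

    pt_to_soc: dict[str, str]
    version_label: str = "unversioned"
    n_unmapped: int = field(default=0, init=False)
    _index: dict[str, str] = field(default_factory=dict, init=False, repr=False)

    def __post_init__(self) -> None:
        self._index = {pt.casefold(): soc for pt, soc in self.pt_to_soc.items()}

    @property
    def socs(self) -> set[str]:
        return set(self.pt_to_soc.values())

    def lookup(self, pt: str) -> str:
        soc = self._index.get(pt.strip().casefold())
        if soc is None:
            self.n_unmapped += 1
            return UNMAPPED
        return soc


def map_pt_to_soc(pt: str, table: CodingTable) -> str:
    """Return the SOC for ``pt`` or :data:`UNMAPPED`; lookup is case-insensitive.

    Unmapped terms are tallied on ``table.n_unmapped`` rather than raised:
    spontaneous-reporting extracts routinely contain terms from a newer
    dictionary version than the coding table.
    """
    return table.lookup(pt)


def read_coding_table(path: str | Path, version_label: str | None = None) -> CodingTable:
    """Load a two-column (pt, soc) TSV; a header line ``pt<TAB>soc`` is auto-detected."""
    path = Path(path)
    mapping: dict[str, str] = {}
    with path.open(encoding="utf-8") as fh:
        for i, line in enumerate(fh):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}: line {i + 1} does not have exactly 2 tab-separated fields")
            pt, soc = parts
            if i == 0 and pt.strip().casefold() == "pt" and soc.strip().casefold() == "soc":
                continue
            mapping[pt] = soc
    return CodingTable(mapping, version_label or path.stem)


def write_coding_table(table: CodingTable, path: str | Path) -> Path:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("pt\tsoc\n")
        for pt in sorted(table.pt_to_soc):
            fh.write(f"{pt}\t{table.pt_to_soc[pt]}\n")
    return path
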