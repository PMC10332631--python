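"""Profile-HMM catalog: which models map to which functional labels.

The catalog is deliberately an editable config (JSON or two/four-column
TSV): only the accessory-domain model PF10437 is pinned by the method
itself; every other accession depends on the HMM collection in use
(TIGRFAM/Pfam releases plus sulfur-metabolism extension models), so
defaults ship as data and users swap in their own list.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

from .model import Label

#: Accessory ligase domain (LplB); the one accession the method pins down.
LPLB_ACCESSION = "PF10437"


@dataclass(frozen=True)
class CatalogEntry:
    acc: str
    label: Label
    trusted_cutoff: float
    priority: int = 50


class HmmCatalog:
    """Mapping hmm_acc -> (label, trusted cutoff, tie-break priority).

    ``priority`` orders labels when two models hit one protein with equal
    bitscore: the entry with the *lower* priority number wins; remaining
    ties fall back to lexicographic accession.
    """

    def __init__(self, entries: list[CatalogEntry]):
        self._entries: dict[str, CatalogEntry] = {}
        for e in entries:
            if e.acc in self._entries:
                raise ValueError(f"duplicate catalog accession {e.acc}")
            self._entries[e.acc] = e
        lplb = [e for e in entries if e.label is Label.LPLB]
        if lplb and not any(e.acc == LPLB_ACCESSION for e in lplb):
            raise ValueError(f"LplB must be reachable from {LPLB_ACCESSION}")

    def __contains__(self, acc: str) -> bool:
        return acc in self._entries

    def __len__(self) -> int:
        return len(self._entries)

    def entry(self, acc: str) -> CatalogEntry:
        return self._entries[acc]

    def label_of(self, acc: str) -> Label:
        return self._entries[acc].label

    def priority_of(self, acc: str) -> int:
        return self._entries[acc].priority

    def cutoff_of(self, acc: str) -> float:
        return self._entries[acc].trusted_cutoff

    def accessions_for(self, label: Label) -> list[str]:
        return sorted(a for a, e in self._entries.items() if e.label is label)

    @property
    def entries(self) -> list[CatalogEntry]:
        return [self._entries[a] for a in sorted(self._entries)]

    # ---- serialization -------------------------------------------------

    @classmethod
    def from_json(cls, path: str | Path) -> "HmmCatalog":
        with open(path) as fh:
            doc = json.load(fh)
        return cls._from_doc(doc)

    @classmethod
    def _from_doc(cls, doc: dict) -> "HmmCatalog":
        entries = [
            CatalogEntry(
                acc=m["acc"],
                label=Label(m["label"]),
                trusted_cutoff=float(m["trusted_cutoff"]),
                priority=int(m.get("priority", 50)),
            )
            for m in doc["models"]
        ]
        return cls(entries)

    def to_json(self, path: str | Path) -> None:
        doc = {
            "models": [
                {
                    "acc": e.acc,
                    "label": e.label.value,
                    "trusted_cutoff": e.trusted_cutoff,
                    "priority": e.priority,
                }
                for e in self.entries
            ]
        }
        Path(path).write_text(json.dumps(doc, indent=2) + "\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "HmmCatalog":
        """Read ``acc<TAB>label<TAB>trusted_cutoff[<TAB>priority]`` lines."""
        entries = []
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            entries.append(
                CatalogEntry(
                    acc=parts[0],
                    label=Label(parts[1]),
                    trusted_cutoff=float(parts[2]),
                    priority=int(parts[3]) if len(parts) > 3 else 50,
                )
            )
        return cls(entries)

    @classmethod
    def default(cls) -> "HmmCatalog":
        text = resources.files("lipomap.data").joinpath("default_catalog.json").read_text()
        return cls._from_doc(json.loads(text))


def load_catalog(path: str | Path | None = None) -> HmmCatalog:
    """Load a catalog from JSON/TSV, or the packaged defaults when ``path`` is None."""
    if path is None:
        return HmmCatalog.default()
    path = Path(path)
    if path.suffix.lower() == ".json":
        return HmmCatalog.from_json(path)
    return HmmCatalog.from_tsv(path)
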