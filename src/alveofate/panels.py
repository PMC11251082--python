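"""Gene panels: signatures, transcription factors, and the receptor table.

Panels ship with the package as plain-text files (one symbol per line; the
receptor panel as a two-column receptor/ligand TSV of which only the receptor
column is used).  Symbol matching downstream is case-insensitive so mouse-case
(``Itga3``) and human-case (``ITGA3``) data use the same panels.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd


@dataclass(frozen=True)
class GenePanel:
    """A named, unique list of gene symbols."""

    name: str
    symbols: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.symbols:
            raise ValueError(f"panel {self.name!r} is empty")
        folded = [s.upper() for s in self.symbols]
        if len(set(folded)) != len(folded):
            raise ValueError(f"panel {self.name!r} has duplicate symbols")

    def __len__(self) -> int:
        return len(self.symbols)

    def __iter__(self):
        return iter(self.symbols)

    def harmonized(self) -> frozenset[str]:
        """Case-folded (uppercase) symbol set, for cross-species matching."""
        return frozenset(s.upper() for s in self.symbols)


def load_panel_file(path: str | Path, name: str | None = None) -> GenePanel:
    """Read a one-symbol-per-line panel file (blank lines and # comments skipped)."""
    path = Path(path)
    symbols = [
        line.strip()
        for line in path.read_text().splitlines()
        if line.strip() and not line.startswith("#")
    ]
    return GenePanel(name=name or path.stem, symbols=tuple(symbols))


def _bundled(fname: str) -> Path:
    return Path(str(resources.files("alveofate").joinpath("panels", fname)))


def bundled_panel(name: str) -> GenePanel:
    """Load one of the panels shipped with the package.

    Available: ``injury_plasticity``, ``at2``, ``at1``, ``datp``, ``ifng``,
    ``primed_at2``, ``tf``.
    """
    return load_panel_file(_bundled(f"{name}.txt"), name=name)


def receptor_table() -> pd.DataFrame:
    """The curated receptor/ligand two-column table bundled with the package."""
    return pd.read_csv(_bundled("receptor_ligand.tsv"), sep="\t")


def receptor_panel() -> GenePanel:
    """Receptor column of the bundled receptor/ligand table, as a panel."""
    return GenePanel(name="receptors", symbols=tuple(receptor_table()["receptor"]))


#: the eight receptors found conserved across organoid, in vivo and human data
CONSERVED_RECEPTOR_PANEL = GenePanel(
    name="conserved_receptors",
    symbols=("OCLN", "ITGA3", "ADIPOR1", "PLXNB2", "CLDN4", "ST14", "ITGB1", "LSR"),
)
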