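"""Bundled reference tables: amino-acid compositions and the known-element
library used for motif annotation."""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from importlib import resources

# Residues over-weighted in the disorder-biased linker composition.  These are
# the disorder-promoting residues that dominate dehydrin sequences outside the
# conserved segments.
DISORDER_PROMOTING = "GSEKPQTH"


@dataclass(frozen=True)
class KnownElement:
    """A named plant cis-regulatory element with its IUPAC consensus.

    A PLACE-style stand-in library entry, not a PLACE redistribution.
    """

    name: str
    consensus_iupac: str
    function_note: str
    source_table: str = ""

    def __post_init__(self) -> None:
        if len(self.consensus_iupac) < 4:
            raise ValueError("element consensus must be at least 4 symbols")


def _read_table(filename: str) -> list[list[str]]:
    text = resources.files("dhnscan").joinpath("data", filename).read_text()
    rows = [line.split("\t") for line in text.strip().split("\n")]
    return rows[1:]  # drop header


@lru_cache(maxsize=None)
def globular_composition() -> dict[str, float]:
    """Average residue composition of globular proteins (Swiss-Prot average),
    renormalised to sum to exactly 1."""
    comp = {aa: float(freq) for aa, freq in _read_table("globular_composition.tsv")}
    total = sum(comp.values())
    return {aa: f / total for aa, f in comp.items()}


@lru_cache(maxsize=None)
def disorder_biased_composition() -> dict[str, float]:
    """Linker composition for synthetic dehydrins: the globular average with
    disorder-promoting residues (G,S,E,K,P,Q,T,H) weighted 2x, renormalised."""
    comp = dict(globular_composition())
    for aa in DISORDER_PROMOTING:
        comp[aa] *= 2.0
    total = sum(comp.values())
    return {aa: f / total for aa, f in comp.items()}


@lru_cache(maxsize=None)
def load_element_library() -> tuple[KnownElement, ...]:
    """The shipped known-element library (every element the class motif
    tables refer to)."""
    return tuple(
        KnownElement(name, consensus, note, table)
        for name, consensus, note, table in _read_table("place_elements.tsv")
    )
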