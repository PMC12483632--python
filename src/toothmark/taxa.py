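"""The four carnivore taxa whose tooth marks the classifiers discriminate.

The alphabetical ordering is fixed and used for every vector/matrix axis in
the package (probability vectors, confusion matrices, report rows).
"""

from __future__ import annotations

from enum import Enum

__all__ = ["TaxonLabel", "TAXA", "TAXON_INDEX"]


class TaxonLabel(str, Enum):
    CROCODILE = "crocodile"
    HYENA = "hyena"
    LEOPARD = "leopard"
    LION = "lion"

    def __str__(self) -> str:
        return self.value

    @classmethod
    def from_name(cls, name: str) -> "TaxonLabel":
        try:
            return cls(name.strip().lower())
        except ValueError:
            valid = ", ".join(t.value for t in cls)
            raise ValueError(f"unknown taxon {name!r}; expected one of: {valid}") from None


#: Fixed axis order (alphabetical).
TAXA: tuple[TaxonLabel, ...] = (
    TaxonLabel.CROCODILE,
    TaxonLabel.HYENA,
    TaxonLabel.LEOPARD,
    TaxonLabel.LION,
)

TAXON_INDEX: dict[TaxonLabel, int] = {t: i for i, t in enumerate(TAXA)}
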