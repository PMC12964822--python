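"""Result containers shared by all inbreeding algorithms."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class Diagnostics:
    """Work counters mirroring the instrumentation used to compare solvers.

    ``elements_computed_forward`` counts every element of the work vector
    computed during forward substitution (the dominant cost of the indirect
    solvers); ``l_row_entries`` counts emitted nonzeros of sire rows of L;
    ``sire_groups`` counts evaluated (sire, LAP-block) groups.
    """

    elements_computed_forward: int = 0
    l_row_entries: int = 0
    sire_groups: int = 0

    def merge(self, other: "Diagnostics") -> None:
        self.elements_computed_forward += other.elements_computed_forward
        self.l_row_entries += other.l_row_entries
        self.sire_groups += other.sire_groups

    def as_dict(self) -> dict:
        return {
            "elements_computed_forward": int(self.elements_computed_forward),
            "l_row_entries": int(self.l_row_entries),
            "sire_groups": int(self.sire_groups),
        }


@dataclass
class FResult:
    """Per-animal inbreeding coefficients plus run metadata.

    ``f`` is indexed like the sorted :class:`~pedinbreed.pedio.Pedigree`
    (metafounders first); a metafounder's entry is its self-relationship
    minus one (``gamma - 1``).
    """

    f: np.ndarray
    algorithm: str
    diagnostics: Diagnostics = field(default_factory=Diagnostics)
    workers: int = 1
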