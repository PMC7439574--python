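"""Subject-level records shared by the clock and telomere modules."""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping


class Group(str, Enum):
    """Cohort label: healthy donors, aplastic anemia (AA), dyskeratosis
    congenita (DKC), or anything else."""

    HEALTHY = "healthy"
    AA = "AA"
    DKC = "DKC"
    OTHER = "other"


class CellFraction(str, Enum):
    GRANULOCYTES = "granulocytes"
    LYMPHOCYTES = "lymphocytes"


@dataclass
class SubjectRecord:
    """One donor or patient.

    ``betas`` may be partial or empty (not every subject was measured on every
    assay); ``telomere_kb`` and ``cell_fraction`` are optional for the same
    reason.
    """

    subject_id: str
    chronological_age: float
    group: Group
    betas: Mapping[str, float] = field(default_factory=dict)
    telomere_kb: float | None = None
    cell_fraction: CellFraction | None = None

    def __post_init__(self) -> None:
        import math

        if not math.isfinite(self.chronological_age):
            raise ValueError("chronological_age must be finite")
        if isinstance(self.group, str) and not isinstance(self.group, Group):
            self.group = Group(self.group)
        if isinstance(self.cell_fraction, str) and not isinstance(
            self.cell_fraction, CellFraction
        ):
            self.cell_fraction = CellFraction(self.cell_fraction)
        for marker, beta in self.betas.items():
            if not 0.0 <= float(beta) <= 1.0:
                raise ValueError(f"beta for {marker!r} outside [0, 1]: {beta}")
        if self.telomere_kb is not None and self.telomere_kb <= 0:
            raise ValueError("telomere_kb must be positive when present")
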