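"""The 7-treatment postharvest storage design.

Treatments: PreTreat (at-harvest baseline), A1/A10/A20 (air storage at
1/10/20 degC), MCP (air + 1-MCP ethylene-perception inhibitor), CA
(controlled atmosphere, 2% O2 / 1% CO2 at 1 degC) and MCPCA (1-MCP + CA).
CA and MCPCA are the hypoxic treatments; everything else is normoxic.
MCP, CA and MCPCA are the long-term treatments sampled over months of
storage.
"""

from __future__ import annotations

from dataclasses import dataclass

TREATMENTS: tuple[str, ...] = ("PreTreat", "A1", "A10", "A20", "MCP", "CA", "MCPCA")
HYPOXIC: tuple[str, ...] = ("CA", "MCPCA")
NORMOXIC: tuple[str, ...] = ("PreTreat", "A1", "A10", "A20", "MCP")
SHORT_TERM: tuple[str, ...] = ("A1", "A10", "A20")
LONG_TERM: tuple[str, ...] = ("MCP", "CA", "MCPCA")


@dataclass(frozen=True)
class TreatmentGroup:
    label: str

    def __post_init__(self) -> None:
        if self.label not in TREATMENTS:
            raise ValueError(f"unknown treatment {self.label!r}")

    @property
    def hypoxic(self) -> bool:
        return self.label in HYPOXIC
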