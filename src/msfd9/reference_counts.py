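"""Record-count bookkeeping of the Mediterranean initial assessment.

Per-class record counts reported for the three Italian MSFD subregions
(Adriatic Sea; Western Mediterranean Sea; Ionian Sea and Central
Mediterranean Sea). These are reference inputs for consistency checks:
within each subregion the class counts must sum to the subregion total,
and the subregion totals to the overall campaign size (approximately
15000 records). HOCs = halogenated organic compounds (dioxins and
dioxin-like PCB sums).
"""

from __future__ import annotations

__all__ = [
    "RECORDS_BY_CLASS",
    "TOTAL_CELLS",
    "subregion_total",
    "grand_total",
]

RECORDS_BY_CLASS: dict[str, dict[str, int]] = {
    "AS": {"metals": 5801, "pahs": 1086, "hocs": 232},
    "WMS": {"metals": 1344, "pahs": 513, "hocs": 43},
    "ISCMS": {"metals": 5865, "pahs": 92, "hocs": 26},
}

#: Fishnet cell totals of the three subregion grids.
TOTAL_CELLS: dict[str, int] = {"AS": 51, "WMS": 166, "ISCMS": 77}


def subregion_total(label: str) -> int:
    """Total records of one subregion (sum over contaminant classes)."""
    return sum(RECORDS_BY_CLASS[label].values())


def grand_total() -> int:
    """Total records across the three subregions."""
    return sum(subregion_total(label) for label in RECORDS_BY_CLASS)
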