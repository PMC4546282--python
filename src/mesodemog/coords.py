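"""Coordinate bookkeeping for the mtDNA control region.

The control region wraps around the origin of the circular mitochondrial
genome: positions 16024-16569 (containing hypervariable region I,
16024-16365) are followed by positions 1-576 (containing hypervariable
region II, 73-340).  Simulated alignments represent the two segments as one
concatenated block of 1122 sites; this module maps between the 1-based
concatenated coordinate and the 1-based reference (rCRS-style) coordinate,
and labels each reference position with its hypervariable region.
"""

from __future__ import annotations

from dataclasses import dataclass

# (ref_start, ref_end) inclusive, in concatenation order
CONTROL_REGION_SEGMENTS: tuple[tuple[int, int], ...] = ((16024, 16569), (1, 576))

HVRI_RANGE = (16024, 16365)
HVRII_RANGE = (73, 340)


@dataclass(frozen=True)
class ControlRegionMap:
    """Offset table between concatenated simulator coordinates and reference
    coordinates for the control region."""

    segments: tuple[tuple[int, int], ...] = CONTROL_REGION_SEGMENTS

    @property
    def length(self) -> int:
        return sum(end - start + 1 for start, end in self.segments)

    def sim_to_ref(self, sim_pos: int) -> int:
        """1-based concatenated position -> 1-based reference position."""
        if not 1 <= sim_pos <= self.length:
            raise ValueError(f"simulator position {sim_pos} outside 1..{self.length}")
        offset = sim_pos - 1
        for start, end in self.segments:
            seg_len = end - start + 1
            if offset < seg_len:
                return start + offset
            offset -= seg_len
        raise AssertionError("unreachable")

    def ref_to_sim(self, ref_pos: int) -> int:
        """1-based reference position -> 1-based concatenated position."""
        offset = 0
        for start, end in self.segments:
            if start <= ref_pos <= end:
                return offset + (ref_pos - start) + 1
            offset += end - start + 1
        raise ValueError(f"reference position {ref_pos} not in the control region")

    def contains_ref(self, ref_pos: int) -> bool:
        return any(start <= ref_pos <= end for start, end in self.segments)


def region_of(ref_pos: int) -> str:
    """Label a reference position: 'HVRI', 'HVRII' or 'other'."""
    if HVRI_RANGE[0] <= ref_pos <= HVRI_RANGE[1]:
        return "HVRI"
    if HVRII_RANGE[0] <= ref_pos <= HVRII_RANGE[1]:
        return "HVRII"
    return "other"


DEFAULT_MAP = ControlRegionMap()
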