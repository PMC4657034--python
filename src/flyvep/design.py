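"""The 8x8 spatiotemporal stimulus design grid.

Contrast-reversing gratings are shown at every combination of 8 reversal
(temporal) frequencies and 8 spatial frequencies, giving 64 conditions.
The temporal frequencies are chosen so that each reversal cycle fits a
whole number of 1-second analysis bins, which makes the second harmonic
(2F) land exactly on an integer-Hz spectral bin.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List

TEMPORAL_FREQS_HZ: tuple = (1, 2, 4, 6, 8, 12, 18, 36)
SPATIAL_FREQS_CPD: tuple = (0.014, 0.028, 0.056, 0.11, 0.22, 0.44, 0.88, 1.76)


@dataclass(frozen=True, order=True)
class StimulusCondition:
    """One (temporal frequency, spatial frequency) pair of the design grid."""

    temporal_freq_hz: float
    spatial_freq_cpd: float

    def __post_init__(self):
        if self.temporal_freq_hz not in TEMPORAL_FREQS_HZ:
            raise ValueError(
                f"temporal_freq_hz must be one of {TEMPORAL_FREQS_HZ}, "
                f"got {self.temporal_freq_hz}"
            )
        if self.spatial_freq_cpd not in SPATIAL_FREQS_CPD:
            raise ValueError(
                f"spatial_freq_cpd must be one of {SPATIAL_FREQS_CPD}, "
                f"got {self.spatial_freq_cpd}"
            )

    @property
    def second_harmonic_hz(self) -> float:
        """Analysis frequency: twice the reversal frequency."""
        return 2 * self.temporal_freq_hz

    def label(self) -> str:
        return f"sf{self.spatial_freq_cpd:g}_tf{self.temporal_freq_hz:g}"


def design_grid() -> List[StimulusCondition]:
    """Return the 64 conditions in canonical order.

    Canonical order is spatial frequency ascending (outer loop), temporal
    frequency ascending (inner loop); this fixes the feature-vector layout
    everywhere in the package.
    """
    return [
        StimulusCondition(temporal_freq_hz=tf, spatial_freq_cpd=sf)
        for sf in SPATIAL_FREQS_CPD
        for tf in TEMPORAL_FREQS_HZ
    ]


def canonical_columns() -> List[str]:
    """Column labels of the 64 amplitude features, in canonical order."""
    return [c.label() for c in design_grid()]
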