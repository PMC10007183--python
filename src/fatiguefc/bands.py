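"""Frequency-band definitions for the multi-band analysis.

The five canonical EEG rhythms used throughout the pipeline. Note the band
edges intentionally leave small gaps (7-8, 12-13, 30-32 Hz); the printed
clinical edges are preserved rather than tiled.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class BandDefinition:
    """A named frequency band [f_low, f_high) in Hz."""

    name: str
    f_low: float
    f_high: float

    def __post_init__(self) -> None:
        if not (0.0 < self.f_low < self.f_high):
            raise ValueError(
                f"band {self.name!r}: need 0 < f_low < f_high, "
                f"got [{self.f_low}, {self.f_high}]"
            )

    @property
    def center(self) -> float:
        """Central frequency (f_low + f_high) / 2, Hz."""
        return 0.5 * (self.f_low + self.f_high)

    def validate_for_fs(self, fs: float) -> None:
        if self.f_high >= fs / 2:
            raise ValueError(
                f"band {self.name!r} upper edge {self.f_high} Hz is not below "
                f"the Nyquist frequency {fs / 2} Hz"
            )


DELTA = BandDefinition("delta", 0.5, 4.0)
THETA = BandDefinition("theta", 4.0, 7.0)
ALPHA = BandDefinition("alpha", 8.0, 12.0)
BETA = BandDefinition("beta", 13.0, 30.0)
GAMMA = BandDefinition("gamma", 32.0, 45.0)

DEFAULT_BANDS: dict[str, BandDefinition] = {
    b.name: b for b in (DELTA, THETA, ALPHA, BETA, GAMMA)
}

#: Full analysis range used for relative band power normalization, Hz.
TOTAL_RANGE = (0.5, 45.0)


def get_band(band: "str | BandDefinition") -> BandDefinition:
    """Resolve a band given by name or pass a BandDefinition through."""
    if isinstance(band, BandDefinition):
        return band
    try:
        return DEFAULT_BANDS[band]
    except KeyError:
        raise KeyError(
            f"unknown band {band!r}; known bands: {sorted(DEFAULT_BANDS)}"
        ) from None
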