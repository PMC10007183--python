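"""The in-memory container for a multichannel EEG recording."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np


@dataclass
class Recording:
    """A channels x samples EEG segment.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Signal in microvolts (scale is conventional; the analysis is
        amplitude-invariant where it matters).
    fs : float
        Sampling frequency in Hz.
    channel_names : list of str
        One label per row of ``data``.
    subject_id : str
        Identifier of the participant.
    condition : str
        ``"alert"``, ``"fatigue"`` or ``"unknown"``.
    """

    data: np.ndarray
    fs: float
    channel_names: list[str] = field(default_factory=list)
    subject_id: str = "unknown"
    condition: str = "unknown"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError(f"data must be 2-D, got shape {self.data.shape}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("recording contains non-finite samples")
        if self.fs <= 0:
            raise ValueError(f"sampling frequency must be positive, got {self.fs}")
        if not self.channel_names:
            self.channel_names = [f"CH{i}" for i in range(self.data.shape[0])]
        if len(self.channel_names) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channel_names)} channel names for "
                f"{self.data.shape[0]} data rows"
            )
        if self.condition not in ("alert", "fatigue", "unknown"):
            raise ValueError(f"unknown condition label {self.condition!r}")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Length in seconds."""
        return self.n_samples / self.fs

    def with_data(self, data: np.ndarray, fs: "float | None" = None) -> "Recording":
        """Copy of this recording with new samples (and optionally new fs)."""
        return replace(self, data=data, fs=self.fs if fs is None else fs)
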