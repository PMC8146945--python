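"""Core EEG recording container."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np


@dataclass(eq=False)
class EEGRecording:
    """A channels x samples numeric matrix with montage labels.

    Attributes
    ----------
    data:
        Array of shape ``(n_channels, n_samples)``, in microvolts.
    rate:
        Sampling rate in Hz.
    labels:
        Channel labels, one per row of ``data``.
    condition:
        Optional condition tag (e.g. ``"Pre"``, ``"Sound1"``).
    """

    data: np.ndarray
    rate: float
    labels: tuple[str, ...]
    condition: Optional[str] = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.labels = tuple(self.labels)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if self.data.shape[0] != len(self.labels):
            raise ValueError(
                f"{self.data.shape[0]} data rows but {len(self.labels)} labels"
            )
        if self.rate <= 0:
            raise ValueError("rate must be positive")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Length in seconds."""
        return self.n_samples / self.rate

    def channel(self, label: str) -> np.ndarray:
        try:
            idx = self.labels.index(label)
        except ValueError:
            raise KeyError(f"unknown channel label: {label!r}") from None
        return self.data[idx]

    def copy(self, **updates) -> "EEGRecording":
        kwargs = dict(
            data=self.data.copy(),
            rate=self.rate,
            labels=self.labels,
            condition=self.condition,
        )
        kwargs.update(updates)
        return EEGRecording(**kwargs)
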