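"""Core containers shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["RoiTimeSeries"]


@dataclass
class RoiTimeSeries:
    """ROI-level source time series for one subject.

    Parameters
    ----------
    data
        Real-valued array of shape ``(n_rois, n_samples)``.
    fs
        Sampling rate in Hz.
    labels
        Ordered, unique ROI labels, one per row of ``data``.
    subject_id, group
        Optional subject metadata (``group`` is e.g. ``"HC"`` or ``"BD"``).
    meta
        Free-form metadata (e.g. realized coupling levels for synthetic
        subjects, or the transient margin attached by the band-pass stage).
    """

    data: np.ndarray
    fs: float
    labels: list[str]
    subject_id: str = ""
    group: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise ValueError(f"data must be 2-D (n_rois, n_samples), got shape {self.data.shape}")
        self.labels = [str(l) for l in self.labels]
        if len(self.labels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.labels)} labels for {self.data.shape[0]} rows of data"
            )
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("ROI labels must be unique")
        if not self.fs > 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")

    @property
    def n_rois(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs
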