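"""Core in-memory containers shared across pipeline stages.

The pipeline passes ROI-level signals around as :class:`RoiTimeSeriesSet`
(ROI x time matrix plus labels and the sampling interval) and confounds as
:class:`NuisanceSet`.  Both are plain dataclasses over numpy arrays: cheap to
construct in tests, trivially serialisable to delimited text.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

__all__ = ["RoiTimeSeriesSet", "NuisanceSet", "hemisphere_of_label"]


def hemisphere_of_label(label: str) -> str:
    """Infer the hemisphere tag from an ROI label suffix (``_L``/``_R``)."""
    if label.endswith("_L"):
        return "left"
    if label.endswith("_R"):
        return "right"
    return "midline"


@dataclass
class NuisanceSet:
    """Confound regressors: one row per confound, one column per time sample.

    Holds the six motion-like regressors plus ventricular and white-matter
    signals that are projected out of every ROI series before filtering.
    """

    regressors: np.ndarray  # (n_confounds, n_timepoints)
    names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.regressors = np.atleast_2d(np.asarray(self.regressors, dtype=float))
        if not self.names:
            self.names = [f"confound{i}" for i in range(self.regressors.shape[0])]
        if len(self.names) != self.regressors.shape[0]:
            raise ValueError("one name per confound row required")

    @property
    def n_timepoints(self) -> int:
        return self.regressors.shape[1]


@dataclass
class RoiTimeSeriesSet:
    """Per-ROI signal vectors with sampling interval and ROI/hemisphere labels.

    ``signals`` is ROI x time.  ``hemisphere`` defaults from the ``_L``/``_R``
    label suffix.  ``flags`` records ROIs whose series degenerated (e.g. zero
    variance after detrending) so downstream stages can propagate validity
    instead of NaNs.
    """

    signals: np.ndarray  # (n_rois, n_timepoints)
    roi_labels: list[str]
    dt: float
    hemisphere: list[str] = field(default_factory=list)
    flags: dict[str, list[str]] = field(default_factory=dict)
    confounds: Optional[NuisanceSet] = None

    def __post_init__(self) -> None:
        self.signals = np.atleast_2d(np.asarray(self.signals, dtype=float))
        if len(self.roi_labels) != self.signals.shape[0]:
            raise ValueError(
                f"{len(self.roi_labels)} labels for {self.signals.shape[0]} ROIs"
            )
        if len(set(self.roi_labels)) != len(self.roi_labels):
            raise ValueError("ROI labels must be unique")
        if self.dt <= 0:
            raise ValueError("sampling interval dt must be positive")
        if np.isnan(self.signals).any():
            raise ValueError("missing samples are not allowed")
        if not self.hemisphere:
            self.hemisphere = [hemisphere_of_label(l) for l in self.roi_labels]

    @property
    def n_rois(self) -> int:
        return self.signals.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.signals.shape[1]

    @property
    def duration_seconds(self) -> float:
        """Total acquisition span: volumes x sampling interval."""
        return self.n_timepoints * self.dt

    def with_signals(self, signals: np.ndarray) -> "RoiTimeSeriesSet":
        """Copy of this set with new signal values, labels preserved."""
        return replace(self, signals=np.asarray(signals, dtype=float))

    def index_of(self, label: str) -> int:
        try:
            return self.roi_labels.index(label)
        except ValueError as exc:
            raise KeyError(f"ROI label {label!r} not present") from exc
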