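"""Signal conditioning for resting-state ROI series.

The chain mirrors standard rodent rs-fMRI practice: ROI extraction from a
labelled 4D volume (optional), linear+quadratic detrending with unit-variance
normalization, nuisance regression (six motion-like regressors plus
ventricular and white-matter signals), and a zero-phase band-pass at
0.01-0.1 Hz.  The canonical order is detrend -> nuisance -> band-pass; see
:func:`preprocess_series`.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import signal as sps

from .types import NuisanceSet, RoiTimeSeriesSet

__all__ = [
    "extract_roi_series",
    "detrend_normalize",
    "regress_nuisance",
    "bandpass_filter",
    "preprocess_series",
    "load_nifti_roi_series",
]


class MissingRoiError(KeyError):
    """A requested atlas label has no voxels in the atlas volume."""


def extract_roi_series(
    volume4d: np.ndarray,
    atlas: np.ndarray,
    dt: float,
    roi_labels: dict[int, str] | None = None,
) -> RoiTimeSeriesSet:
    """Average voxel time courses within each atlas label.

    Parameters
    ----------
    volume4d : array, shape (x, y, z, t)
        Intensity data.
    atlas : integer array, shape (x, y, z)
        Label volume; 0 is background.
    dt : float
        Sampling interval in seconds.
    roi_labels : dict, optional
        Maps integer label -> ROI name.  When given, every requested label
        must be present in the atlas (``MissingRoiError`` otherwise);
        when omitted, all positive labels found in the atlas are extracted.
    """
    volume4d = np.asarray(volume4d, dtype=float)
    atlas = np.asarray(atlas)
    if volume4d.ndim != 4 or atlas.shape != volume4d.shape[:3]:
        raise ValueError("atlas and volume must share spatial dimensions")
    present = set(np.unique(atlas[atlas > 0]).tolist())
    if roi_labels is None:
        roi_labels = {int(v): f"roi{int(v)}" for v in sorted(present)}
    signals, names = [], []
    for value, name in sorted(roi_labels.items()):
        if value not in present:
            raise MissingRoiError(f"label {value} ({name}) absent from atlas")
        mask = atlas == value
        signals.append(volume4d[mask].mean(axis=0))
        names.append(name)
    return RoiTimeSeriesSet(signals=np.vstack(signals), roi_labels=names, dt=dt)


def load_nifti_roi_series(volume_path: str, atlas_path: str,
                          roi_labels: dict[int, str] | None = None) -> RoiTimeSeriesSet:
    """Optional volume path: read a 4D NIfTI and 3D integer label atlas."""
    import nibabel as nib  # optional dependency

    img = nib.load(volume_path)
    atlas = nib.load(atlas_path)
    dt = float(img.header.get_zooms()[3]) if len(img.header.get_zooms()) > 3 else 1.0
    return extract_roi_series(
        np.asarray(img.dataobj, dtype=float),
        np.asarray(atlas.dataobj).astype(int),
        dt=dt,
        roi_labels=roi_labels,
    )


def detrend_normalize(series: RoiTimeSeriesSet) -> RoiTimeSeriesSet:
    """Remove per-ROI intercept + linear + quadratic trends, rescale to unit
    variance.

    ROIs that are constant after detrending are set to zeros and recorded
    under ``flags['zero_variance']`` rather than propagating NaNs.
    """
    X = series.signals
    T = X.shape[1]
    if T < 4:
        raise ValueError("detrending needs at least 4 timepoints")
    t = np.arange(T, dtype=float)
    basis = np.vstack([np.ones(T), t, t**2]).T  # (T, 3)
    beta, *_ = np.linalg.lstsq(basis, X.T, rcond=None)
    resid = X - (basis @ beta).T
    sd = resid.std(axis=1, ddof=0)
    flagged = [series.roi_labels[i] for i in np.flatnonzero(sd < 1e-12)]
    safe_sd = np.where(sd < 1e-12, 1.0, sd)
    out = resid / safe_sd[:, None]
    out[sd < 1e-12] = 0.0
    result = series.with_signals(out)
    if flagged:
        result.flags = {**series.flags, "zero_variance": flagged}
    return result


def regress_nuisance(series: RoiTimeSeriesSet, confounds: NuisanceSet) -> RoiTimeSeriesSet:
    """OLS residual of each ROI series on intercept + all confound rows.

    A rank-deficient confound matrix is handled with the pseudoinverse and a
    warning (duplicated confounds change nothing)."""
    X = series.signals
    R = confounds.regressors
    if R.shape[1] != X.shape[1]:
        raise ValueError("confounds and series must share timepoints")
    if R.shape[0] > X.shape[1] - 2:
        raise ValueError("need confound rows <= timepoints - 2")
    design = np.vstack([np.ones(X.shape[1]), R]).T  # (T, 1 + c)
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        warnings.warn(
            f"confound matrix rank-deficient (rank {rank} < {design.shape[1]}); "
            "using pseudoinverse",
            RuntimeWarning,
            stacklevel=2,
        )
    beta = np.linalg.pinv(design) @ X.T
    return series.with_signals(X - (design @ beta).T)


def bandpass_filter(series: RoiTimeSeriesSet, low: float = 0.01, high: float = 0.1,
                    order: int = 4) -> RoiTimeSeriesSet:
    """Zero-phase forward-backward Butterworth band-pass.

    Contract: gain >= 0.9 mid-band, <= 0.1 at frequencies <= low/2 or
    >= 2*high; DC is removed.  ``high`` must be strictly below the Nyquist
    frequency 1/(2*dt).
    """
    nyq = 1.0 / (2 * series.dt)
    if not 0 < low < high:
        raise ValueError("need 0 < low < high")
    if high >= nyq:
        raise ValueError(f"high={high} Hz is not below Nyquist ({nyq} Hz)")
    b, a = sps.butter(order, [low / nyq, high / nyq], btype="band")
    filtered = sps.filtfilt(b, a, series.signals, axis=1)
    return series.with_signals(filtered)


def preprocess_series(series: RoiTimeSeriesSet,
                      confounds: NuisanceSet | None = None,
                      low: float = 0.01, high: float = 0.1) -> RoiTimeSeriesSet:
    """Full conditioning chain: detrend/normalize -> nuisance -> band-pass."""
    out = detrend_normalize(series)
    if confounds is None:
        confounds = series.confounds
    if confounds is not None:
        out = regress_nuisance(out, confounds)
    return bandpass_filter(out, low=low, high=high)
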