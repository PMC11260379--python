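"""Functional connectivity and eigenvector centrality from parcellated BOLD.

Pipeline per subject: zero-phase band-pass filter (default 0.01-0.15 Hz,
the typical resting-state fluctuation band) -> pairwise Pearson correlation
between regional time series (the FC matrix) -> first eigenvector of the FC
matrix, i.e. the eigenvector of its largest eigenvalue. That eigenvector
scores each region by its connectedness to other well-connected regions and
is the direction of the best rank-1 symmetric approximation of FC.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .errors import AlignmentError, ConfigurationError, ValidationError

logger = logging.getLogger(__name__)

DEFAULT_LOW_HZ = 0.01
DEFAULT_HIGH_HZ = 0.15
_FILTER_ORDER = 4  # Butterworth order, applied forward-backward


@dataclass
class RegionTimeSeries:
    """One subject's parcellated BOLD signals.

    ``data`` is regions x timepoints; ``tr`` is the sampling period in
    seconds; ``region_ids`` label the rows.
    """

    data: np.ndarray
    tr: float
    region_ids: list = field(default_factory=list)
    subject_id: str = ""

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValidationError("time-series data must be 2-D (regions x timepoints)")
        if self.data.shape[1] < 4:
            raise ValidationError("need at least 4 timepoints")
        if not np.all(np.isfinite(self.data)):
            raise ValidationError("time series contain missing or non-finite values")
        if self.tr <= 0:
            raise ValidationError("tr must be positive")
        if not self.region_ids:
            self.region_ids = [f"region_{i:03d}" for i in range(self.data.shape[0])]
        if len(self.region_ids) != self.data.shape[0]:
            raise ValidationError("region_ids length does not match region count")

    @property
    def n_regions(self) -> int:
        return self.data.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[1]

    @property
    def nyquist(self) -> float:
        """Nyquist frequency in Hz (0.167 Hz at TR = 3 s)."""
        return 0.5 / self.tr


@dataclass
class FCMatrix:
    """Symmetric region x region Pearson correlation matrix with unit diagonal."""

    values: np.ndarray
    region_ids: list = field(default_factory=list)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n, m = self.values.shape if self.values.ndim == 2 else (0, -1)
        if n != m or n < 2:
            raise ValidationError("FC matrix must be square with at least 2 regions")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("FC matrix contains non-finite entries")
        if np.abs(self.values - self.values.T).max() > 1e-10:
            raise ValidationError("FC matrix is not symmetric within 1e-10")
        if np.any(np.diag(self.values) != 1.0):
            raise ValidationError("FC diagonal must be exactly 1")
        if self.values.min() < -1.0 or self.values.max() > 1.0:
            raise ValidationError("FC entries must lie in [-1, 1]")
        if not self.region_ids:
            self.region_ids = [f"region_{i:03d}" for i in range(n)]
        if len(self.region_ids) != n:
            raise ValidationError("region_ids length does not match matrix size")

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]


@dataclass
class CentralityVector:
    """Leading eigenvector of an FC matrix with its eigenvalue.

    Unit l2 norm; sign fixed so the entry sum is nonnegative.
    """

    values: np.ndarray
    eigenvalue: float
    region_ids: list = field(default_factory=list)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if abs(np.linalg.norm(self.values) - 1.0) > 1e-10:
            raise ValidationError("centrality vector must have unit l2 norm")


def bandpass_filter(
    ts: RegionTimeSeries,
    low_hz: float = DEFAULT_LOW_HZ,
    high_hz: float = DEFAULT_HIGH_HZ,
) -> RegionTimeSeries:
    """Zero-phase Butterworth band-pass, applied identically to every region.

    A 4th-order Butterworth is run forward and backward (``sosfiltfilt``), so
    the output has no phase shift and correlation structure is preserved.
    The band must satisfy 0 < low < high < Nyquist; at TR = 3 s the Nyquist
    is ~0.1667 Hz, so the 0.15 Hz default is valid but near the edge.
    """
    if not (0.0 < low_hz < high_hz):
        raise ConfigurationError(
            f"need 0 < low_hz < high_hz, got ({low_hz}, {high_hz})"
        )
    if high_hz >= ts.nyquist:
        raise ConfigurationError(
            f"high_hz={high_hz} Hz is at or above Nyquist {ts.nyquist:.4f} Hz "
            f"for tr={ts.tr} s"
        )
    sos = signal.butter(
        _FILTER_ORDER, [low_hz, high_hz], btype="bandpass", fs=1.0 / ts.tr,
        output="sos",
    )
    filtered = signal.sosfiltfilt(sos, ts.data, axis=1)
    return RegionTimeSeries(
        data=filtered, tr=ts.tr, region_ids=list(ts.region_ids),
        subject_id=ts.subject_id,
    )


def compute_fc(ts: RegionTimeSeries) -> FCMatrix:
    """Pairwise Pearson correlation between regional time series.

    Constant (zero-variance) regions are rejected rather than imputed; the
    error names the offending region.
    """
    sd = ts.data.std(axis=1)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        names = [ts.region_ids[i] for i in bad[:5]]
        raise ValidationError(
            f"zero-variance region(s) {names}: Pearson correlation undefined"
        )
    r = np.corrcoef(ts.data)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return FCMatrix(values=r, region_ids=list(ts.region_ids))


def eigenvector_centrality(fc: FCMatrix) -> CentralityVector:
    """Eigenvector of the FC matrix's largest eigenvalue.

    The FC matrix is used as-is (signed entries, no thresholding). Being a
    correlation matrix it is positive semidefinite, so the leading eigenvalue
    is nonnegative and ``eigenvalue * v v^T`` is the best rank-1 symmetric
    approximation of FC in Frobenius norm (Eckart-Young).

    Sign convention: the vector is flipped so its entry sum is nonnegative;
    if the sum is exactly 0, the largest-|entry| element is made positive.
    A near-tie between the top two eigenvalues (within 1e-9) is logged and
    broken deterministically by choosing, among the tied eigenvectors, the
    one whose largest-magnitude loading sits at the lowest region index.
    """
    vals, vecs = np.linalg.eigh(fc.values)
    lam = vals[-1]
    tied = np.flatnonzero(vals > lam - 1e-9)
    if tied.size > 1:
        logger.warning(
            "top eigenvalues tied within 1e-9 (multiplicity %d); "
            "applying deterministic tie-break", tied.size,
        )
        peak_idx = [int(np.argmax(np.abs(vecs[:, j]))) for j in tied]
        choice = tied[int(np.argmin(peak_idx))]
    else:
        choice = tied[0]
    v = vecs[:, choice]
    total = v.sum()
    if total < 0:
        v = -v
    elif total == 0 and v[np.argmax(np.abs(v))] < 0:
        v = -v
    v = v / np.linalg.norm(v)
    return CentralityVector(values=v, eigenvalue=float(lam),
                            region_ids=list(fc.region_ids))


def build_feature_matrix(
    cohort_ts: list[RegionTimeSeries],
    low_hz: float = DEFAULT_LOW_HZ,
    high_hz: float = DEFAULT_HIGH_HZ,
) -> pd.DataFrame:
    """Run filter -> FC -> centrality for every subject and stack the results.

    Returns a subjects x regions DataFrame (the brain feature matrix X);
    row order follows the input list, columns follow the shared region_ids.
    All subjects must share the same region set and ordering.
    """
    if not cohort_ts:
        raise ValidationError("empty cohort")
    ref_ids = list(cohort_ts[0].region_ids)
    rows, index = [], []
    for i, ts in enumerate(cohort_ts):
        if list(ts.region_ids) != ref_ids:
            raise AlignmentError(
                f"subject {ts.subject_id or i} has region_ids inconsistent "
                "with the first subject"
            )
        cen = eigenvector_centrality(compute_fc(bandpass_filter(ts, low_hz, high_hz)))
        rows.append(cen.values)
        index.append(ts.subject_id or f"sub-{i:04d}")
    return pd.DataFrame(np.vstack(rows), index=index, columns=ref_ids)
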