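"""Quality control and hemisphere-wise Fisher-z connectivity.

Turns cleaned region-by-time BOLD series into the two within-hemisphere
Fisher-z correlation matrices the dysconnectivity index operates on. Quality
gates follow standard resting-state practice: temporal signal-to-noise ratio
(tSNR, temporal mean over temporal SD) and mean framewise displacement (FD,
backward differences of the six rigid-body motion parameters with rotations
converted to millimetres on a 50 mm sphere).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

logger = logging.getLogger(__name__)

#: rotation-to-translation conversion radius for FD, in mm
FD_ROTATION_RADIUS_MM = 50.0

#: correlations are clipped to +/- (1 - CLIP_EPS) before arctanh
CLIP_EPS = 1e-6


@dataclass
class BoldTimeSeries:
    """Cleaned BOLD series: timepoints x regions, with region identities."""

    subject_id: str
    session: str
    data: np.ndarray
    tr_seconds: float
    region_ids: list[str]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[1] != len(self.region_ids):
            raise ValueError("data must be timepoints x regions matching region_ids")
        if self.data.shape[1] < 2:
            raise ValueError("need at least 2 regions")
        if np.isnan(self.data).any():
            raise ValueError("time series contain missing values")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]


@dataclass
class QCReport:
    subject_id: str
    tsnr_per_region: pd.Series
    mean_tsnr: float
    mean_fd_mm: float | None
    passed: bool
    parameters: dict = field(default_factory=dict)


@dataclass
class ConnectivityMatrix:
    """Within-hemisphere Fisher-z connectivity (symmetric, zero diagonal)."""

    subject_id: str
    session: str
    hemisphere: str
    z: np.ndarray
    region_ids: list[str]

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        n = len(self.region_ids)
        if self.z.shape != (n, n):
            raise ValueError("matrix shape must match region_ids")
        if not np.allclose(self.z, self.z.T, equal_nan=True):
            raise ValueError("connectivity matrix must be symmetric")


def framewise_displacement(motion: np.ndarray) -> np.ndarray:
    """Power-style FD from a frames x 6 motion table (tx ty tz rx ry rz).

    Translations in mm, rotations in radians; rotations are scaled by the
    50 mm head-radius convention. Returns one value per frame transition.
    """
    motion = np.asarray(motion, dtype=float)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise ValueError("motion table must have 6 columns")
    d = np.abs(np.diff(motion, axis=0))
    d[:, 3:] *= FD_ROTATION_RADIUS_MM
    return d.sum(axis=1)


def compute_qc(
    ts: BoldTimeSeries,
    motion: np.ndarray | pd.DataFrame | None = None,
    tsnr_min: float = 100.0,
    fd_max_mm: float = 0.3,
) -> QCReport:
    """tSNR per region and mean FD, with the two pass/fail gates applied."""
    mean = ts.data.mean(axis=0)
    sd = ts.data.std(axis=0, ddof=1)
    with np.errstate(divide="ignore"):
        tsnr = np.where(sd > 0, mean / np.where(sd > 0, sd, 1.0), np.inf)
    if np.isinf(tsnr).any():
        logger.warning(
            "%d region(s) with zero temporal SD; tSNR reported as +inf",
            int(np.isinf(tsnr).sum()),
        )
    tsnr_series = pd.Series(tsnr, index=ts.region_ids, name="tsnr")
    finite = tsnr[np.isfinite(tsnr)]
    mean_tsnr = float(finite.mean()) if finite.size else float("inf")

    mean_fd: float | None = None
    if motion is not None:
        mean_fd = float(framewise_displacement(np.asarray(motion)).mean())

    passed = mean_tsnr > tsnr_min and (mean_fd is None or mean_fd < fd_max_mm)
    return QCReport(
        subject_id=ts.subject_id,
        tsnr_per_region=tsnr_series,
        mean_tsnr=mean_tsnr,
        mean_fd_mm=mean_fd,
        passed=passed,
        parameters={"tsnr_min": tsnr_min, "fd_max_mm": fd_max_mm,
                    "fd_rotation_radius_mm": FD_ROTATION_RADIUS_MM},
    )


def preprocess(
    ts: BoldTimeSeries,
    drop_first: int = 5,
    band: tuple[float, float] | None = (0.01, 0.08),
    detrend: bool = True,
) -> BoldTimeSeries:
    """Drop leading frames, detrend, zero-phase band-pass, then standardise.

    Cleaning order is drop -> linear detrend -> band-pass -> per-region
    z-scoring, so every output region has mean 0 and SD 1 exactly. The
    band-pass is a second-order Butterworth applied forward and backward
    (``filtfilt``), i.e. zero phase, leaving correlations undistorted.
    """
    if ts.n_timepoints <= drop_first + 50:
        raise ValueError(
            f"need more than {drop_first + 50} timepoints, got {ts.n_timepoints}"
        )
    x = ts.data[drop_first:].copy()
    if detrend:
        x = signal.detrend(x, axis=0, type="linear")
    if band is not None:
        lo, hi = band
        nyquist = 0.5 / ts.tr_seconds
        if not 0.0 < lo < hi < nyquist:
            raise ValueError(
                f"band edges ({lo}, {hi}) Hz must satisfy 0 < lo < hi < Nyquist "
                f"({nyquist:g} Hz at tr_seconds={ts.tr_seconds})"
            )
        b, a = signal.butter(2, [lo, hi], btype="bandpass", fs=1.0 / ts.tr_seconds)
        x = signal.filtfilt(b, a, x, axis=0)
    x = (x - x.mean(axis=0)) / x.std(axis=0)
    return BoldTimeSeries(
        subject_id=ts.subject_id,
        session=ts.session,
        data=x,
        tr_seconds=ts.tr_seconds,
        region_ids=list(ts.region_ids),
    )


def fisher_z_connectivity(
    ts: BoldTimeSeries, region_meta: pd.DataFrame
) -> tuple[ConnectivityMatrix, ConnectivityMatrix]:
    """Within-hemisphere Pearson correlations mapped through arctanh.

    Correlation matrices are computed separately for the left and right
    hemispheres; cross-hemisphere pairs are never formed. Correlations are
    clipped to +/-(1 - 1e-6) before the Fisher transform so every z is finite.
    """
    meta = region_meta.set_index("region_id")
    out = []
    for hemi in ("L", "R"):
        ids = [r for r in ts.region_ids if meta.loc[r, "hemisphere"] == hemi]
        if len(ids) < 2:
            raise ValueError(f"hemisphere {hemi} has fewer than 2 regions")
        cols = [ts.region_ids.index(r) for r in ids]
        r = np.corrcoef(ts.data[:, cols], rowvar=False)
        r = np.clip(r, -(1.0 - CLIP_EPS), 1.0 - CLIP_EPS)
        z = np.arctanh(r)
        np.fill_diagonal(z, 0.0)
        z = (z + z.T) / 2.0
        out.append(
            ConnectivityMatrix(
                subject_id=ts.subject_id,
                session=ts.session,
                hemisphere=hemi,
                z=z,
                region_ids=ids,
            )
        )
    return out[0], out[1]


def connectivity_from_dataframe(
    df: pd.DataFrame,
    region_meta: pd.DataFrame,
    subject_id: str = "",
    session: str = "baseline",
    tr_seconds: float = 2.0,
    preprocessed: bool = True,
    **preprocess_kwargs,
) -> tuple[ConnectivityMatrix, ConnectivityMatrix]:
    """Convenience: DataFrame (time x regions) -> hemisphere-wise matrices."""
    ts = BoldTimeSeries(
        subject_id=subject_id,
        session=session,
        data=df.to_numpy(),
        tr_seconds=tr_seconds,
        region_ids=list(df.columns),
    )
    if not preprocessed:
        ts = preprocess(ts, **preprocess_kwargs)
    return fisher_z_connectivity(ts, region_meta)
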