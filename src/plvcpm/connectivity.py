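"""Band-limited phase-locking connectomes from regional time series.

Epochs are segmented with an amplitude-rejection rule, band-pass
filtered with a zero-phase Butterworth filter, converted to
instantaneous phase through the analytic signal, and summarized as a
phase locking value (PLV) matrix per epoch; epoch matrices are averaged
into one representative connectome per subject and band.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, hilbert, sosfiltfilt

from plvcpm._edges import N_REGIONS_DEFAULT, vectorize

#: Canonical EEG frequency bands (Hz).
BANDS: dict[str, "Band"] = {}

#: Samples discarded at each epoch end after phase extraction, in seconds.
EDGE_MARGIN_S = 1.0

#: Butterworth order per pass (applied forward and backward).
FILTER_ORDER = 4


@dataclass(frozen=True)
class Band:
    """A frequency band with inclusive passband edges in Hz."""

    name: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not 0 < self.lo < self.hi:
            raise ValueError(f"invalid band edges ({self.lo}, {self.hi})")

    def validate_for_fs(self, fs: float) -> None:
        if self.hi >= fs / 2:
            raise ValueError(
                f"band {self.name} ({self.lo}-{self.hi} Hz) violates the "
                f"Nyquist limit for fs={fs} Hz"
            )


for _name, _lo, _hi in [
    ("delta", 1.0, 4.0),
    ("theta", 4.0, 8.0),
    ("alpha", 8.0, 13.0),
    ("beta", 13.0, 30.0),
    ("gamma", 30.0, 45.0),
]:
    BANDS[_name] = Band(_name, _lo, _hi)


def get_band(band: "Band | str") -> Band:
    if isinstance(band, Band):
        return band
    try:
        return BANDS[band]
    except KeyError:
        raise ValueError(f"unknown band {band!r}; known: {sorted(BANDS)}") from None


def _default_labels(n: int) -> list[str]:
    return [f"region_{i:02d}" for i in range(n)]


@dataclass
class RegionalTimeSeries:
    """Regions x samples array of regional signals (muV) with sampling rate."""

    data: np.ndarray
    fs: float
    region_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError(f"data must be 2-D (regions x samples), got {self.data.ndim}-D")
        if self.fs <= 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("time series contains non-finite values")
        if not self.region_labels:
            self.region_labels = _default_labels(self.data.shape[0])
        elif len(self.region_labels) != self.data.shape[0]:
            raise ValueError("region_labels length does not match number of regions")

    @property
    def n_regions(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs


@dataclass
class Connectome:
    """Symmetric zero-diagonal connectivity matrix with entries in [0, 1]."""

    matrix: np.ndarray
    band: str = "alpha"
    subject_id: str = ""

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError(f"connectome matrix must be square, got {m.shape}")
        if not np.allclose(m, m.T, atol=1e-8):
            raise ValueError("connectome matrix is not symmetric")
        m = (m + m.T) / 2.0
        np.fill_diagonal(m, 0.0)
        if m.min() < -1e-12 or m.max() > 1 + 1e-12:
            raise ValueError("connectome entries must lie in [0, 1]")
        self.matrix = np.clip(m, 0.0, 1.0)

    @property
    def n_regions(self) -> int:
        return self.matrix.shape[0]

    def edge_vector(self) -> np.ndarray:
        """Row-major upper-triangle edge vector (length 2278 for 68 regions)."""
        return vectorize(self.matrix)


class EpochRejectionError(ValueError):
    """Raised when too few artifact-free epochs survive rejection."""


def segment_epochs(
    ts: RegionalTimeSeries,
    epoch_len: float = 40.0,
    max_abs: float = 100.0,
    n_keep: int = 4,
) -> list[RegionalTimeSeries]:
    """Cut consecutive non-overlapping epochs and keep clean ones.

    An epoch is rejected if any sample in any region exceeds ``max_abs``
    in absolute value. The earliest ``n_keep`` surviving epochs are
    returned, in temporal order.
    """
    n_per_epoch = int(round(epoch_len * ts.fs))
    if n_per_epoch < 1:
        raise ValueError("epoch_len too short for the sampling rate")
    n_epochs_avail = ts.n_samples // n_per_epoch
    if n_epochs_avail < 1:
        raise EpochRejectionError(
            f"recording of {ts.duration:.1f} s is shorter than one "
            f"{epoch_len:.0f}-s epoch"
        )
    kept: list[RegionalTimeSeries] = []
    for k in range(n_epochs_avail):
        chunk = ts.data[:, k * n_per_epoch : (k + 1) * n_per_epoch]
        if np.max(np.abs(chunk)) <= max_abs:
            kept.append(RegionalTimeSeries(chunk.copy(), ts.fs, list(ts.region_labels)))
        if len(kept) == n_keep:
            break
    if len(kept) < n_keep:
        raise EpochRejectionError(
            f"only {len(kept)} artifact-free epochs survive rejection; "
            f"{n_keep} required"
        )
    return kept


def bandpass(ts: RegionalTimeSeries, band: "Band | str") -> RegionalTimeSeries:
    """Zero-phase Butterworth band-pass (order 4 per pass, forward-backward).

    Forward-backward filtering doubles the effective order and removes
    phase distortion, which would otherwise corrupt the PLV estimate.
    """
    band = get_band(band)
    band.validate_for_fs(ts.fs)
    sos = butter(FILTER_ORDER, [band.lo, band.hi], btype="bandpass", fs=ts.fs, output="sos")
    filtered = sosfiltfilt(sos, ts.data, axis=-1)
    return RegionalTimeSeries(filtered, ts.fs, list(ts.region_labels))


def instantaneous_phase(ts: RegionalTimeSeries) -> np.ndarray:
    """Instantaneous phase (radians) of the analytic signal, per region.

    The input is assumed band-limited. Callers should discard
    ``EDGE_MARGIN_S`` seconds at each end before averaging phase
    statistics; the analytic signal is unreliable near epoch boundaries.
    """
    rms = np.sqrt(np.mean(ts.data**2, axis=-1))
    if np.any(rms == 0):
        dead = np.flatnonzero(rms == 0)
        raise FloatingPointError(
            f"all-zero signal in region(s) {dead.tolist()}: phase undefined"
        )
    return np.angle(hilbert(ts.data, axis=-1))


def edge_margin_samples(fs: float) -> int:
    return int(round(EDGE_MARGIN_S * fs))


def plv(phase_x: np.ndarray, phase_y: np.ndarray) -> float:
    """Phase locking value |< exp(i(phi_x - phi_y)) >| in [0, 1]."""
    phase_x = np.asarray(phase_x, dtype=float)
    phase_y = np.asarray(phase_y, dtype=float)
    if phase_x.shape != phase_y.shape:
        raise ValueError(
            f"phase series length mismatch: {phase_x.shape} vs {phase_y.shape}"
        )
    if phase_x.size < 2:
        raise ValueError("need at least 2 samples to estimate PLV")
    return float(np.abs(np.mean(np.exp(1j * (phase_x - phase_y)))))


def _plv_matrix(phases: np.ndarray) -> np.ndarray:
    """All-pairs PLV from a regions x samples phase array (vectorized)."""
    phasors = np.exp(1j * phases)
    n = phases.shape[1]
    cross = phasors @ phasors.conj().T / n
    m = np.abs(cross)
    np.fill_diagonal(m, 0.0)
    return np.clip((m + m.T) / 2.0, 0.0, 1.0)


def build_connectome(
    epochs: list[RegionalTimeSeries],
    band: "Band | str",
    subject_id: str = "",
) -> Connectome:
    """PLV connectome averaged across epochs for one frequency band.

    Each epoch is band-passed, phase-extracted, trimmed of boundary
    transients, and reduced to a PLV matrix; the epoch matrices are
    averaged arithmetically into the representative connectome.
    """
    if not epochs:
        raise ValueError("need at least one epoch to build a connectome")
    band = get_band(band)
    mats = []
    for ep in epochs:
        filtered = bandpass(ep, band)
        phases = instantaneous_phase(filtered)
        margin = edge_margin_samples(ep.fs)
        if phases.shape[1] <= 2 * margin + 2:
            raise ValueError(
                f"epoch of {ep.n_samples} samples too short after trimming "
                f"{margin}-sample boundary margins"
            )
        phases = phases[:, margin : phases.shape[1] - margin]
        mats.append(_plv_matrix(phases))
    avg = np.mean(mats, axis=0)
    return Connectome(avg, band=band.name, subject_id=subject_id)
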