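"""Single-molecule burst search and proximity-ratio histograms.

A burst is a group of at least ``min_photons`` photons (donor and acceptor
channels merged) in which every consecutive inter-photon gap is strictly
less than ``max_gap_us``.  For each burst a proximity ratio

    P = N_A / (N_A + N_D)

is computed after subtracting the expected background counts (channel
background rate x burst duration) and the donor crosstalk contribution.
Per-burst P values are histogrammed over [-0.1, 1.1) in bins of 0.02 so
that correction-induced values outside [0, 1] remain visible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._errors import ValidationError
from .fret import CorrectionSet

__all__ = [
    "PhotonStream",
    "Burst",
    "PHistogram",
    "detect_bursts",
    "burst_proximity",
    "build_histogram",
    "read_photon_stream",
    "write_burst_table",
]

logger = logging.getLogger(__name__)

DONOR, ACCEPTOR = 0, 1
_CHANNEL_CODES = {"D": DONOR, "A": ACCEPTOR, "donor": DONOR, "acceptor": ACCEPTOR}


@dataclass
class PhotonStream:
    """Time-ordered photon arrivals with channel tags.

    Parameters
    ----------
    timestamps_us
        Arrival times in microseconds, monotone non-decreasing.
    channels
        0 (donor) or 1 (acceptor) per photon.
    bkg_rate_donor, bkg_rate_acceptor
        Background count rates in counts/s, used for per-burst background
        subtraction.
    duration_us
        Acquisition duration; defaults to the last timestamp.
    """

    timestamps_us: np.ndarray
    channels: np.ndarray
    bkg_rate_donor: float = 0.0
    bkg_rate_acceptor: float = 0.0
    duration_us: float | None = None

    def __post_init__(self):
        self.timestamps_us = np.asarray(self.timestamps_us, dtype=float)
        self.channels = np.asarray(self.channels, dtype=np.int8)
        if self.timestamps_us.shape != self.channels.shape:
            raise ValidationError("timestamps and channels differ in length")
        if self.timestamps_us.size and np.any(np.diff(self.timestamps_us) < 0):
            raise ValidationError("photon stream is not time-ordered")
        if self.timestamps_us.size and self.timestamps_us[0] < 0:
            raise ValidationError("timestamps must be >= 0")
        if self.duration_us is None:
            self.duration_us = float(self.timestamps_us[-1]) if \
                self.timestamps_us.size else 0.0
        elif self.timestamps_us.size and \
                self.duration_us < self.timestamps_us[-1]:
            raise ValidationError("duration shorter than last timestamp")

    def __len__(self) -> int:
        return int(self.timestamps_us.size)


@dataclass
class Burst:
    """A contiguous photon cluster and its (corrected) proximity ratio."""

    start_us: float
    end_us: float
    n_donor_raw: int
    n_acceptor_raw: int
    n_donor_corr: float = field(default=np.nan)
    n_acceptor_corr: float = field(default=np.nan)
    p: float = field(default=np.nan)

    @property
    def size(self) -> int:
        return self.n_donor_raw + self.n_acceptor_raw

    @property
    def duration_us(self) -> float:
        return self.end_us - self.start_us


@dataclass
class PHistogram:
    """Proximity-ratio histogram over [-0.1, 1.1), half-open 0.02 bins."""

    bin_edges: np.ndarray
    counts: np.ndarray

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def frequencies(self) -> np.ndarray:
        """Counts normalised to sum 1; NaN everywhere when empty (flagged)."""
        total = self.counts.sum()
        if total == 0:
            return np.full(self.counts.shape, np.nan)
        return self.counts / total

    @property
    def is_empty(self) -> bool:
        return self.total == 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "bin_lo": self.bin_edges[:-1],
            "bin_hi": self.bin_edges[1:],
            "count": self.counts,
            "frequency": self.frequencies,
        })


def detect_bursts(stream: PhotonStream, min_photons: int = 50,
                  max_gap_us: float = 120.0) -> list[Burst]:
    """Partition the merged photon sequence into bursts.

    Maximal clusters in which every consecutive inter-photon gap is
    < ``max_gap_us`` (strict: a gap of exactly ``max_gap_us`` splits) and
    that contain at least ``min_photons`` photons become bursts.  Bursts
    are disjoint and returned in time order; raw counts are per channel,
    uncorrected.
    """
    if min_photons < 1:
        raise ValidationError("min_photons must be >= 1")
    if max_gap_us <= 0:
        raise ValidationError("max_gap_us must be > 0")
    t = stream.timestamps_us
    if t.size == 0:
        return []
    # cluster boundaries wherever the inter-photon gap reaches max_gap_us
    gaps = np.diff(t)
    breaks = np.flatnonzero(gaps >= max_gap_us) + 1
    starts = np.concatenate(([0], breaks))
    ends = np.concatenate((breaks, [t.size]))  # exclusive
    bursts: list[Burst] = []
    acc = stream.channels == ACCEPTOR
    for lo, hi in zip(starts, ends):
        n = hi - lo
        if n < min_photons:
            continue
        n_a = int(acc[lo:hi].sum())
        bursts.append(Burst(start_us=float(t[lo]), end_us=float(t[hi - 1]),
                            n_donor_raw=n - n_a, n_acceptor_raw=n_a))
    return bursts


def burst_proximity(burst: Burst, corrections: CorrectionSet | None = None,
                    bkg_rate_donor: float = 0.0,
                    bkg_rate_acceptor: float = 0.0) -> float | None:
    """Corrected per-burst proximity ratio (Burst is updated in place).

    Expected background counts are the channel background rate (counts/s)
    times the burst duration; crosstalk alpha removes a fraction of the
    corrected donor counts from the acceptor channel.  A burst whose
    corrected total is zero is flagged (p = NaN), logged and should be
    excluded by the caller; ``None`` is returned for it.
    """
    c = corrections or CorrectionSet()
    dur_s = burst.duration_us * 1e-6
    n_d = burst.n_donor_raw - bkg_rate_donor * dur_s
    n_a = (burst.n_acceptor_raw - bkg_rate_acceptor * dur_s
           - c.crosstalk_alpha * n_d)
    burst.n_donor_corr = n_d
    burst.n_acceptor_corr = n_a
    total = n_a + n_d
    if total == 0:
        burst.p = np.nan
        logger.warning("burst at %.1f us excluded: corrected total is zero",
                       burst.start_us)
        return None
    burst.p = n_a / total
    return burst.p


def process_stream(stream: PhotonStream, corrections: CorrectionSet | None = None,
                   min_photons: int = 50, max_gap_us: float = 120.0,
                   ) -> tuple[list[Burst], np.ndarray]:
    """Burst search + per-burst P in one call.

    Background rates are taken from the stream metadata.  Returns the burst
    list (all detected bursts, including flagged ones) and the array of
    valid P values.
    """
    bursts = detect_bursts(stream, min_photons=min_photons,
                           max_gap_us=max_gap_us)
    ps = []
    for b in bursts:
        p = burst_proximity(b, corrections,
                            bkg_rate_donor=stream.bkg_rate_donor,
                            bkg_rate_acceptor=stream.bkg_rate_acceptor)
        if p is not None:
            ps.append(p)
    return bursts, np.asarray(ps, dtype=float)


def build_histogram(ps, bin_width: float = 0.02,
                    lo: float = -0.1, hi: float = 1.1) -> PHistogram:
    """Histogram P values over [lo, hi) with half-open, left-closed bins.

    Values outside the range accumulate in the nearest edge bin.  An empty
    input yields a zero histogram whose frequencies are NaN (flagged via
    :attr:`PHistogram.is_empty`).
    """
    if bin_width <= 0:
        raise ValidationError("bin_width must be > 0")
    n_bins = int(round((hi - lo) / bin_width))
    edges = lo + bin_width * np.arange(n_bins + 1)
    ps = np.asarray(ps, dtype=float)
    if ps.size:
        idx = np.floor((ps - lo) / bin_width).astype(int)
        idx = np.clip(idx, 0, n_bins - 1)
        counts = np.bincount(idx, minlength=n_bins)
    else:
        counts = np.zeros(n_bins, dtype=int)
    return PHistogram(bin_edges=edges, counts=counts)


def read_photon_stream(path, bkg_rate_donor: float = 0.0,
                       bkg_rate_acceptor: float = 0.0) -> PhotonStream:
    """Read a photon stream from CSV/TSV with columns timestamp_us, channel."""
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df = pd.read_csv(path, sep=sep)
    ch = df["channel"].map(_CHANNEL_CODES)
    if ch.isna().any():
        bad = df["channel"][ch.isna()].unique()
        raise ValidationError(f"unknown channel labels: {list(bad)}")
    return PhotonStream(df["timestamp_us"].to_numpy(float),
                        ch.to_numpy(np.int8),
                        bkg_rate_donor=bkg_rate_donor,
                        bkg_rate_acceptor=bkg_rate_acceptor)


def write_photon_stream(stream: PhotonStream, path) -> None:
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    labels = np.where(stream.channels == ACCEPTOR, "A", "D")
    pd.DataFrame({"timestamp_us": stream.timestamps_us,
                  "channel": labels}).to_csv(path, sep=sep, index=False)


def write_burst_table(bursts: list[Burst], path) -> None:
    """Burst table CSV: start, end, N_D, N_A, p."""
    pd.DataFrame({
        "start_us": [b.start_us for b in bursts],
        "end_us": [b.end_us for b in bursts],
        "n_donor": [b.n_donor_raw for b in bursts],
        "n_acceptor": [b.n_acceptor_raw for b in bursts],
        "p": [b.p for b in bursts],
    }).to_csv(path, index=False)
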