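"""Spectral band-power phenotyping.

Converts multichannel recordings into the phenotype matrix Y: for each
participant, channel and frequency band, the power of a Hamming-windowed
full-length periodogram integrated over the band.  Bands widen linearly
with frequency (narrow delta/theta bands, wide gamma bands) and the band
containing the 50 Hz power line is dropped.

Normalization is Parseval-consistent: for white noise, band powers over a
partition of [0, Nyquist) sum to the signal variance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as _signal

from .cohort import RawCohort, SpectralPhenotype

__all__ = ["BandScheme", "band_edges", "band_power", "spectra_matrix", "average_conditions"]

log = logging.getLogger(__name__)


@dataclass
class BandScheme:
    """Ordered, contiguous, half-open frequency bands [lo, hi)."""

    bands: list[tuple[float, float]]
    notch_hz: float = 50.0
    dropped: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for (lo, hi) in self.bands:
            if hi <= lo:
                raise ValueError(f"empty band ({lo}, {hi})")
        for (a, b), (c, _) in zip(self.bands, self.bands[1:]):
            if c < b:
                raise ValueError("bands must be non-overlapping and ordered")

    @property
    def n_retained(self) -> int:
        return len(self.bands)

    def labels(self) -> list[str]:
        return [f"{lo:g}-{hi:g}Hz" for lo, hi in self.bands]


def band_edges(
    n_bands_total: int = 22,
    f_start: float = 1.0,
    w_first: float = 2.0,
    w_last: float = 6.0,
    notch_hz: float = 50.0,
) -> BandScheme:
    """Linearly widening band scheme with the power-line band removed.

    ``n_bands_total`` contiguous bands start at ``f_start``; widths are
    linearly interpolated from ``w_first`` to ``w_last``.  The single band
    containing ``notch_hz`` is dropped (so the default yields 21 retained
    bands, the first being [1, 3) Hz).
    """
    if n_bands_total < 2:
        raise ValueError("need at least two bands")
    if w_first <= 0 or w_last <= 0:
        raise ValueError("band widths must be positive")
    widths = np.linspace(w_first, w_last, n_bands_total)
    edges = f_start + np.concatenate([[0.0], np.cumsum(widths)])
    bands = [(float(edges[i]), float(edges[i + 1])) for i in range(n_bands_total)]
    retained, dropped = [], []
    for lo, hi in bands:
        if lo <= notch_hz < hi:
            dropped.append((lo, hi))
        else:
            retained.append((lo, hi))
    if not dropped:
        log.warning("notch frequency %.1f Hz outside covered range; no band dropped", notch_hz)
    return BandScheme(bands=retained, notch_hz=notch_hz, dropped=dropped)


def band_power(x: np.ndarray, fs: float, band: tuple[float, float]) -> float:
    """Band power of one signal from a full-length Hamming periodogram.

    Returns the integral of the one-sided spectral density over frequency
    bins with center in [lo, hi).
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("signal must be 1-D with at least two samples")
    lo, hi = band
    if not lo < hi:
        raise ValueError("band must satisfy lo < hi")
    if hi > fs / 2:
        raise ValueError(f"band edge {hi} Hz above Nyquist {fs / 2} Hz")
    f, psd = _signal.periodogram(x, fs=fs, window="hamming", scaling="density", detrend=False)
    df = f[1] - f[0]
    mask = (f >= lo) & (f < hi)
    return float(np.sum(psd[mask]) * df)


def _channel_band_powers(sig: np.ndarray, fs: float, scheme: BandScheme) -> np.ndarray:
    """Band powers for one participant, all channels at once. (C, B)."""
    f, psd = _signal.periodogram(sig, fs=fs, window="hamming", scaling="density",
                                 detrend=False, axis=-1)
    df = f[1] - f[0]
    out = np.empty((sig.shape[0], scheme.n_retained))
    for b, (lo, hi) in enumerate(scheme.bands):
        mask = (f >= lo) & (f < hi)
        out[:, b] = psd[:, mask].sum(axis=1) * df
    return out


def feature_names(n_channels: int, scheme: BandScheme) -> list[str]:
    """Channel-major (channel, band) column labels; P = C x n_retained."""
    return [
        f"ch{c:03d}_{lab}"
        for c in range(n_channels)
        for lab in scheme.labels()
    ]


def spectra_matrix(
    recordings: RawCohort,
    scheme: BandScheme,
    t_start_s: float = 0.0,
    t_stop_s: float | None = None,
    transform: str | None = None,
) -> SpectralPhenotype:
    """Phenotype matrix Y from a cohort of recordings.

    One row per participant; columns channel-major then band.  An optional
    window [t_start_s, t_stop_s) restricts the segment used.  ``transform``
    may be 'log10' (band powers are left untransformed by default).
    """
    fs = recordings.fs
    i0 = int(round(t_start_s * fs))
    i1 = recordings.signals.shape[2] if t_stop_s is None else int(round(t_stop_s * fs))
    if i1 > recordings.signals.shape[2] or i0 >= i1:
        raise ValueError("requested segment exceeds recording length")
    n, c, _ = recordings.signals.shape
    rows = np.empty((n, c * scheme.n_retained))
    for i in range(n):
        sig = recordings.signals[i, :, i0:i1]
        if not np.all(np.isfinite(sig)):
            raise ValueError(f"non-finite samples for participant {recordings.participants[i]}")
        rows[i] = _channel_band_powers(sig, fs, scheme).ravel()
    if transform == "log10":
        rows = np.log10(rows)
    elif transform is not None:
        raise ValueError(f"unknown transform {transform!r}")
    return SpectralPhenotype(
        values=rows,
        participants=list(recordings.participants),
        feature_names=feature_names(c, scheme),
        condition=recordings.condition,
    )


def average_conditions(Ys: list[SpectralPhenotype]) -> SpectralPhenotype:
    """Element-wise mean phenotype across experimental conditions."""
    if not Ys:
        raise ValueError("need at least one phenotype")
    ref = Ys[0]
    for y in Ys[1:]:
        if y.values.shape != ref.values.shape:
            raise ValueError("condition matrices must share shape")
        if y.participants != ref.participants:
            raise ValueError("condition matrices must share row order")
    mean = np.mean([y.values for y in Ys], axis=0)
    return SpectralPhenotype(
        values=mean,
        participants=list(ref.participants),
        feature_names=list(ref.feature_names),
        condition="mean",
    )
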