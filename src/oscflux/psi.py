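"""Phase Slope Index (PSI) directed connectivity with jackknife standardisation.

The PSI between channels i and j over a frequency band F is

    psi_raw[i, j] = Im( sum_{f in F} conj(C_ij(f)) * C_ij(f + df) )

where C_ij(f) = S_ij(f) / sqrt(S_ii(f) S_jj(f)) is the complex coherency and
S the cross-spectral matrix; equivalently a |C|^2-weighted average of the
phase slope across the band.  A positive value means channel i leads
(drives) channel j.  Because only the imaginary part of the coherency
enters, zero-lag (volume-conduction) mixing contributes nothing.

The raw index is standardised by its jackknife standard deviation over
epochs (leave one epoch out of the cross-spectral average at a time):

    psi_std = psi_raw / sd_jackknife,   sd^2 = (n-1)/n * sum_k (psi_(k) - mean)^2

giving a pseudo-z value comparable across channel pairs and participants.

Cross-spectra are Welch estimates: Hann-tapered segments (1 s, 50% overlap
by default, hence 1 Hz resolution) averaged over all segments of all epochs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger("oscflux.psi")

DEFAULT_BAND = (8.0, 13.0)


@dataclass
class CrossSpectrum:
    S: np.ndarray          # complex (n_channels, n_channels, n_freqs), Hermitian per f
    freqs: np.ndarray      # Hz
    delta_f: float         # frequency resolution
    n_segments: int


@dataclass
class CoherencyMatrix:
    C: np.ndarray          # complex (n_channels, n_channels, n_freqs), |C|<=1
    freqs: np.ndarray
    delta_f: float


@dataclass
class PSIMatrix:
    psi_raw: np.ndarray       # real antisymmetric (n_channels, n_channels)
    psi_std: np.ndarray       # psi_raw / jackknife SD; nan where SD degenerate
    jackknife_sd: np.ndarray
    band: tuple[float, float]
    channels: list[str] | None = None


# ---------------------------------------------------------------------------
# Spectral estimation
# ---------------------------------------------------------------------------

def _epoch_segments(epoch: np.ndarray, nper: int, step: int) -> np.ndarray:
    """(n_segments, n_channels, nper) sliding view of one (n_ch, n_samp) epoch."""
    n = epoch.shape[-1]
    if n < nper:
        return np.empty((0, epoch.shape[0], nper))
    starts = np.arange(0, n - nper + 1, step)
    return np.stack([epoch[:, s:s + nper] for s in starts], axis=0)


def _per_epoch_csd(epochs, fs: float, segment_length: float, overlap: float,
                   taper: str = "hann"):
    """Per-epoch summed segment cross-spectra.

    Returns (csd_sums, seg_counts, freqs): csd_sums has shape
    (n_epochs, n_ch, n_ch, n_freqs) and holds the *sum* of the tapered-FFT
    outer products over that epoch's segments; dividing by counts gives the
    Welch average.  Epochs shorter than one segment are skipped with a log
    entry (their count is 0).
    """
    if not 0.0 <= overlap < 1.0:
        raise ValueError("overlap must lie in [0, 1)")
    nper = int(round(segment_length * fs))
    if nper < 2:
        raise ValueError("segment too short")
    step = max(1, int(round(nper * (1.0 - overlap))))
    if taper == "hann":
        win = np.hanning(nper)
    elif taper in ("boxcar", "none"):
        win = np.ones(nper)
    else:
        raise ValueError(f"unknown taper {taper!r}")
    scale = 1.0 / (fs * np.sum(win ** 2))  # PSD density scaling
    freqs = np.fft.rfftfreq(nper, d=1.0 / fs)

    epochs = [np.asarray(e, float) for e in epochs]
    n_ch = epochs[0].shape[0]
    sums = np.zeros((len(epochs), n_ch, n_ch, freqs.size), dtype=complex)
    counts = np.zeros(len(epochs), dtype=int)
    for k, ep in enumerate(epochs):
        if ep.shape[0] != n_ch:
            raise ValueError("all epochs must have the same channel count")
        segs = _epoch_segments(ep, nper, step)
        if segs.shape[0] == 0:
            logger.info("epoch %d shorter than one segment; skipped", k)
            continue
        X = np.fft.rfft(segs * win, axis=-1)            # (nseg, ch, nf)
        sums[k] = np.einsum("scf,sdf->cdf", X, X.conj()) * scale
        counts[k] = segs.shape[0]
    if counts.sum() == 0:
        raise ValueError("no epoch long enough for a single segment")
    return sums, counts, freqs


def cross_spectrum(epochs, fs: float, segment_length: float = 1.0,
                   overlap: float = 0.5, taper: str = "hann") -> CrossSpectrum:
    """Welch cross-spectral matrix over all segments of all epochs."""
    sums, counts, freqs = _per_epoch_csd(epochs, fs, segment_length, overlap, taper)
    S = sums.sum(axis=0) / counts.sum()
    return CrossSpectrum(S=S, freqs=freqs, delta_f=float(freqs[1] - freqs[0]),
                         n_segments=int(counts.sum()))


def coherency(cs: CrossSpectrum) -> CoherencyMatrix:
    """Complex coherency C_ij(f) = S_ij(f) / sqrt(S_ii(f) S_jj(f))."""
    S = cs.S
    diag = np.real(np.einsum("iif->if", S))
    band_ok = diag > 0
    if not band_ok.all():
        ch, f_idx = np.argwhere(~band_ok)[0]
        # zero power at f=0 after Hann detrending is harmless; only complain
        # if an analysis-relevant bin is dead
        if cs.freqs[f_idx] > 0:
            raise ValueError(
                f"zero auto-spectrum for channel {ch} at {cs.freqs[f_idx]:.2f} Hz")
    denom = np.sqrt(diag[:, np.newaxis, :] * diag[np.newaxis, :, :])
    with np.errstate(invalid="ignore", divide="ignore"):
        C = np.where(denom > 0, S / np.where(denom > 0, denom, 1.0), 0.0)
    return CoherencyMatrix(C=C, freqs=cs.freqs, delta_f=cs.delta_f)


# ---------------------------------------------------------------------------
# PSI
# ---------------------------------------------------------------------------

def _band_pair_indices(freqs: np.ndarray, band: tuple[float, float]) -> np.ndarray:
    """Indices k with freqs[k] and freqs[k+1] both inside the band."""
    inband = (freqs >= band[0]) & (freqs <= band[1])
    idx = np.flatnonzero(inband)
    return idx[np.isin(idx + 1, idx)]


def psi_raw(coh: CoherencyMatrix, band: tuple[float, float] = DEFAULT_BAND) -> np.ndarray:
    """Raw PSI matrix over the band; antisymmetric, zero diagonal.

    Bins at the band's upper edge whose successor falls outside the band are
    dropped.  Requires at least two in-band bins.
    """
    if np.count_nonzero((coh.freqs >= band[0]) & (coh.freqs <= band[1])) < 2:
        raise ValueError(f"band {band} spans fewer than 2 frequency bins")
    k = _band_pair_indices(coh.freqs, band)
    C = coh.C
    psi = np.imag(np.sum(np.conj(C[:, :, k]) * C[:, :, k + 1], axis=-1))
    np.fill_diagonal(psi, 0.0)
    return psi


def _psi_from_sums(csd_sum: np.ndarray, freqs: np.ndarray,
                   band: tuple[float, float]) -> np.ndarray:
    """psi_raw from a (possibly stacked) summed cross-spectrum array
    (..., ch, ch, nf); normalisation by segment counts cancels in coherency."""
    diag = np.real(np.einsum("...iif->...if", csd_sum))
    denom = np.sqrt(diag[..., :, np.newaxis, :] * diag[..., np.newaxis, :, :])
    with np.errstate(invalid="ignore", divide="ignore"):
        C = np.where(denom > 0, csd_sum / np.where(denom > 0, denom, 1.0), 0.0)
    k = _band_pair_indices(freqs, band)
    psi = np.imag(np.sum(np.conj(C[..., k]) * C[..., k + 1], axis=-1))
    eye = np.eye(psi.shape[-1], dtype=bool)
    psi[..., eye] = 0.0
    return psi


def psi_standardised(epochs, fs: float, band: tuple[float, float] = DEFAULT_BAND,
                     segment_length: float = 1.0, overlap: float = 0.5,
                     channels: list[str] | None = None) -> PSIMatrix:
    """Raw and jackknife-standardised PSI over a set of epochs.

    The jackknife leaves one epoch out of the cross-spectral average at a
    time; its SD estimate sqrt((n-1)/n * sum (psi_(k) - mean)^2) divides the
    full-sample raw PSI.  SDs below 1e-12 flag the standardised value as
    missing (nan, logged).  Requires at least 3 epochs.
    """
    epochs = list(epochs)
    if len(epochs) < 3:
        raise ValueError("jackknife standardisation needs >= 3 epochs")
    sums, counts, freqs = _per_epoch_csd(epochs, fs, segment_length, overlap)
    used = counts > 0
    sums, counts = sums[used], counts[used]
    n = counts.size
    if n < 3:
        raise ValueError("fewer than 3 epochs long enough for a segment")
    total = sums.sum(axis=0)
    raw = _psi_from_sums(total, freqs, band)
    loo = total[np.newaxis] - sums                     # (n, ch, ch, nf)
    psi_loo = _psi_from_sums(loo, freqs, band)         # (n, ch, ch)
    sd = np.sqrt((n - 1) / n * np.sum((psi_loo - psi_loo.mean(axis=0)) ** 2, axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        std = np.where(sd > 1e-12, raw / np.where(sd > 1e-12, sd, 1.0), np.nan)
    np.fill_diagonal(std, 0.0)
    degenerate = (sd <= 1e-12) & ~np.eye(sd.shape[0], dtype=bool)
    if degenerate.any():
        logger.warning("%d channel pairs have degenerate jackknife SD; "
                       "standardised PSI flagged missing", int(degenerate.sum()) // 2)
    return PSIMatrix(psi_raw=raw, psi_std=std, jackknife_sd=sd, band=tuple(band),
                     channels=list(channels) if channels is not None else None)
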