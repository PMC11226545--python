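"""Synthetic EEG and behaviour generators with known ground truth.

Every generator is a pure function of its arguments including the seed, so
each downstream stage (burst detection, directed connectivity, cluster
permutation, semantic-distance scoring) can be exercised against a planted
truth without any recorded data.

The background model is aperiodic 1/f activity with an optional knee,

    S(f) = 10**offset / (knee + f**exponent)    [power density]

synthesised by inverse-FFT spectral shaping with uniformly random phases:
the realised periodogram matches the target spectrum exactly, which makes
spectral-recovery checks sharp.  Oscillatory bursts are Hann-tapered
sinusoids whose amplitude is defined as the ratio of burst RMS to the
background RMS in a +/-2 Hz band around the burst frequency, so a burst of
amplitude 3 sits a factor ~9 in band-limited power above the background.
Directed coupling is a lag-delayed, band-passed copy of the driver mixed
into the receiver, which gives the receiver a known positive phase-slope
(driver leads) in the coupling band.

Bursts use a Tukey envelope (cosine ramps of one cycle, flat plateau): pure
Hann tapering would leave a nominally 8-cycle burst above any fixed power
threshold for barely half its duration, making the planted duration an
unusable ground truth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import butter, sosfiltfilt
from scipy.signal.windows import tukey

logger = logging.getLogger("oscflux.synthgen")

DEFAULT_CHANNELS = ["F3", "C3", "P3", "T7", "F4", "C4", "P4", "T8"]


# ---------------------------------------------------------------------------
# Specs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AperiodicSpec:
    """Aperiodic (1/f-with-knee) background: S(f) = 10**offset / (knee + f**exponent)."""

    offset: float = 2.0
    knee: float = 0.0
    exponent: float = 1.5
    fs: float = 250.0
    duration: float = 2.0

    def __post_init__(self) -> None:
        if self.fs <= 0 or self.duration <= 0:
            raise ValueError("fs and duration must be positive")
        if self.exponent < 0:
            raise ValueError("exponent must be >= 0")
        if self.knee < 0:
            raise ValueError("knee must be >= 0")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.fs))

    def psd(self, freqs: np.ndarray) -> np.ndarray:
        """Target power spectral density at ``freqs`` (f=0 maps to 0)."""
        freqs = np.asarray(freqs, dtype=float)
        out = np.zeros_like(freqs)
        pos = freqs > 0
        denom = self.knee + freqs[pos] ** self.exponent
        out[pos] = np.divide(10.0 ** self.offset, denom, out=np.zeros_like(denom),
                             where=denom > 0)
        return out


@dataclass(frozen=True)
class BurstSpec:
    """One transient oscillation: a tapered sinusoid of n_cycles at freq.

    ``amplitude`` is the burst-to-background RMS ratio at the scale of the
    3-cycle wavelet analysis (squared, it is the factor by which the burst
    raises wavelet power at its frequency above the background mean), so an
    amplitude-3 burst sits a factor ~9 above the aperiodic level that the
    chi-squared detection threshold is anchored to.  ``reference='band'``
    switches to a plain +/-2 Hz band-limited RMS ratio instead.
    """

    freq: float
    onset: float
    n_cycles: float
    amplitude: float = 3.0
    reference: str = "wavelet"

    def __post_init__(self) -> None:
        if self.freq <= 0:
            raise ValueError("freq must be positive")
        if self.onset < 0:
            raise ValueError("onset must be >= 0")
        if self.n_cycles <= 0:
            raise ValueError("n_cycles must be positive")

    @property
    def duration(self) -> float:
        return self.n_cycles / self.freq


@dataclass(frozen=True)
class CouplingSpec:
    """Directed lagged coupling: receiver += gain * delayed band component of driver."""

    driver: str
    receiver: str
    lag: float = 0.02
    band: tuple[float, float] = (8.0, 13.0)
    coupling_gain: float = 1.0

    def __post_init__(self) -> None:
        if self.driver == self.receiver:
            raise ValueError("driver and receiver must differ")
        if self.lag <= 0:
            raise ValueError("lag must be positive")
        if not self.band[0] < self.band[1]:
            raise ValueError("band must satisfy f_lo < f_hi")


# ---------------------------------------------------------------------------
# 1/f noise
# ---------------------------------------------------------------------------

def _shaped_noise(shape: tuple[int, ...], n: int, spec: AperiodicSpec,
                  rng: np.random.Generator) -> np.ndarray:
    """Random-phase inverse-FFT noise with the target spectrum, shape (*shape, n)."""
    freqs = np.fft.rfftfreq(n, d=1.0 / spec.fs)
    # one-sided periodogram convention: P(f) = 2 |X|^2 / (fs * n)
    amp = np.sqrt(spec.psd(freqs) * spec.fs * n / 2.0)
    amp[0] = 0.0
    phases = rng.uniform(0.0, 2.0 * np.pi, size=(*shape, freqs.size))
    spectrum = amp * np.exp(1j * phases)
    if n % 2 == 0:
        # Nyquist bin must be real; keep its power, randomise the sign
        spectrum[..., -1] = amp[-1] * np.sign(np.cos(phases[..., -1]))
    return np.fft.irfft(spectrum, n=n, axis=-1)


def gen_aperiodic_noise(spec: AperiodicSpec, seed) -> np.ndarray:
    """Generate one channel of aperiodic 1/f background activity.

    Parameters
    ----------
    spec
        Background spectrum parameters (offset, knee, exponent, fs, duration).
    seed
        Seed (int or sequence of ints) for :func:`numpy.random.default_rng`.

    Returns
    -------
    numpy.ndarray
        Real series of ``round(duration * fs)`` samples, in the amplitude
        units implied by ``offset`` (microvolts by package convention).
    """
    n = spec.n_samples
    if n < 2:
        raise ValueError("duration * fs must be at least 2 samples")
    rng = np.random.default_rng(seed)
    return _shaped_noise((), n, spec, rng)


def _bandpass_sos(band: tuple[float, float], fs: float, order: int = 4):
    lo = max(band[0], 1e-3)
    hi = min(band[1], 0.499 * fs)
    return butter(order, [lo, hi], btype="bandpass", fs=fs, output="sos")


# ---------------------------------------------------------------------------
# Burst injection
# ---------------------------------------------------------------------------

def _morlet_kernel(freq: float, fs: float, n_cycles: float = 3.0) -> np.ndarray:
    """Complex Morlet kernel matching the analysis wavelet (unit-free)."""
    sigma_t = n_cycles / (2.0 * np.pi * freq)
    t = np.arange(-5.0 * sigma_t, 5.0 * sigma_t, 1.0 / fs)
    return np.exp(2j * np.pi * freq * t) * np.exp(-t ** 2 / (2.0 * sigma_t ** 2))


def inject_bursts(series: np.ndarray, bursts: list[BurstSpec], fs: float):
    """Add tapered sinusoidal bursts to a series.

    With the default ``reference='wavelet'`` the burst is scaled so that its
    response through a 3-cycle Morlet wavelet at the burst frequency is
    ``amplitude`` times the RMS of the background's response — i.e. the
    burst raises wavelet power by the factor amplitude**2 over the
    background mean, which is the signal-to-noise the chi-squared detection
    threshold operates on.  ``reference='band'`` instead matches the burst
    RMS to ``amplitude`` times the background RMS in a +/-2 Hz band.
    Returns the modified series (copy) and a ground-truth event table
    (onset, offset, freq, n_cycles, amplitude).
    """
    series = np.asarray(series, dtype=float)
    out = series.copy()
    n = series.size
    events = []
    intervals_by_freq: dict[float, list[tuple[float, float]]] = {}
    for b in bursts:
        i0 = int(round(b.onset * fs))
        n_samp = int(round(b.duration * fs))
        if i0 + n_samp > n:
            raise ValueError(
                f"burst at {b.onset:.3f}s ({b.duration:.3f}s) extends past series end")
        for (lo, hi) in intervals_by_freq.get(b.freq, []):
            if b.onset < hi and b.onset + b.duration > lo:
                logger.warning(
                    "overlapping bursts at %.2f Hz around %.3f s", b.freq, b.onset)
        intervals_by_freq.setdefault(b.freq, []).append((b.onset, b.onset + b.duration))

        t = np.arange(n_samp) / fs
        # click-free taper with a flat plateau: cosine ramps of one cycle at
        # each end (a full-length Hann for bursts of <= 2 cycles), so the
        # burst holds its nominal amplitude over nearly its whole duration
        ramp_fraction = min(1.0, 2.0 / b.n_cycles)
        taper = tukey(n_samp, alpha=ramp_fraction)
        raw = taper * np.sin(2.0 * np.pi * b.freq * t)
        # reference the series-wide background level: a window-local estimate
        # has only a handful of independent envelope samples and would
        # randomise the realised SNR from burst to burst
        if b.reference == "wavelet":
            kernel = _morlet_kernel(b.freq, fs)
            bg_resp = np.convolve(series, kernel, mode="same")
            bg_rms = float(np.sqrt(np.mean(np.abs(bg_resp) ** 2)))
            # response amplitude of a unit sinusoid: |K(f)| / 2
            k_gain = float(np.abs(np.sum(kernel * np.exp(-2j * np.pi * b.freq *
                                                         np.arange(kernel.size) / fs)))) / 2.0
            scale = b.amplitude * bg_rms / k_gain if k_gain > 0 else 0.0
        elif b.reference == "band":
            sos = _bandpass_sos((b.freq - 2.0, b.freq + 2.0), fs)
            bg_band = sosfiltfilt(sos, series)
            bg_rms = float(np.sqrt(np.mean(bg_band ** 2)))
            raw_rms = float(np.sqrt(np.mean(raw ** 2)))
            scale = b.amplitude * bg_rms / raw_rms if raw_rms > 0 else 0.0
        else:
            raise ValueError(f"unknown amplitude reference {b.reference!r}")
        out[i0:i0 + n_samp] += scale * raw
        events.append({
            "onset": i0 / fs,
            "offset": (i0 + n_samp) / fs,
            "freq": b.freq,
            "n_cycles": b.n_cycles,
            "amplitude": b.amplitude,
        })
    return out, pd.DataFrame(events, columns=["onset", "offset", "freq", "n_cycles", "amplitude"])


# ---------------------------------------------------------------------------
# Coupled pairs and group datasets
# ---------------------------------------------------------------------------

def _lag_samples(lag: float, fs: float) -> int:
    k = int(round(lag * fs))
    if k < 1:
        raise ValueError(f"lag {lag}s is below one sample at fs={fs}")
    return k


def gen_coupled_pair(spec: CouplingSpec, background: AperiodicSpec, seed,
                     n_epochs: int = 50):
    """Generate a two-channel epoch set with known directed coupling.

    Channel 0 is the driver, channel 1 the receiver.  The receiver is its own
    independent background plus ``coupling_gain`` times the band-passed,
    lag-delayed copy of the driver's signal, so the true information flux is
    driver -> receiver with a positive phase slope in ``spec.band``.

    Returns ``(epochs, truth)`` where ``epochs`` has shape
    (n_epochs, 2, n_samples) and ``truth`` records the planted direction.
    """
    fs = background.fs
    L = _lag_samples(spec.lag, fs)
    ns = background.n_samples
    rng = np.random.default_rng(seed)
    # lead-in of L samples so the delayed copy aligns inside the epoch
    drv_full = _shaped_noise((n_epochs,), ns + L, background, rng)
    rcv_own = _shaped_noise((n_epochs,), ns, background, rng)
    if spec.coupling_gain != 0.0:
        sos = _bandpass_sos(spec.band, fs)
        band_drv = sosfiltfilt(sos, drv_full, axis=-1)
        coupled = rcv_own + spec.coupling_gain * band_drv[:, :ns]
    else:
        coupled = rcv_own
    epochs = np.stack([drv_full[:, L:], coupled], axis=1)
    truth = {"driver": spec.driver, "receiver": spec.receiver,
             "driver_index": 0, "receiver_index": 1,
             "lag": L / fs, "band": list(spec.band), "gain": spec.coupling_gain}
    return epochs, truth


def gen_instantaneous_mixture(background: AperiodicSpec, seed,
                              n_epochs: int = 30,
                              mixing: np.ndarray | None = None) -> np.ndarray:
    """Zero-lag mixture of two independent sources (volume-conduction control).

    Both output channels are instantaneous linear combinations of the same
    two independent backgrounds, so any coherency between them is purely
    real and the phase slope index should be null.
    """
    if mixing is None:
        mixing = np.array([[1.0, 0.5], [0.5, 1.0]])
    rng = np.random.default_rng(seed)
    sources = _shaped_noise((n_epochs, 2), background.n_samples, background, rng)
    return np.einsum("cs,esn->ecn", np.asarray(mixing, float), sources)


@dataclass
class GroupDataset:
    """Two-condition multi-participant epoched EEG with planted couplings in B."""

    data: dict  # participant id -> {"A": array (n_ep, n_ch, ns), "B": ...}
    channels: list[str]
    fs: float
    couplings: list[CouplingSpec] = field(default_factory=list)

    @property
    def participants(self) -> list:
        return list(self.data.keys())


def gen_group_dataset(n_participants: int, n_epochs_per_condition: int,
                      channels: list[str] | None = None,
                      planted_effect: list[CouplingSpec] | None = None,
                      seed: int = 0,
                      background: AperiodicSpec | None = None) -> GroupDataset:
    """Generate a paired two-condition group dataset.

    Condition A is independent background noise on every channel; condition B
    additionally carries the planted lagged couplings, giving a known
    direction-specific connectivity difference for the permutation test.
    Per-participant RNG streams are derived from ``(seed, participant_index)``
    so participants are reproducible independently of each other.
    """
    if n_participants < 1:
        raise ValueError("n_participants must be >= 1")
    if n_epochs_per_condition < 1:
        raise ValueError("n_epochs_per_condition must be >= 1")
    channels = list(channels) if channels is not None else list(DEFAULT_CHANNELS)
    planted_effect = list(planted_effect or [])
    background = background or AperiodicSpec()
    ch_index = {c: i for i, c in enumerate(channels)}
    for cpl in planted_effect:
        if cpl.driver not in ch_index or cpl.receiver not in ch_index:
            raise ValueError(f"coupling {cpl.driver}->{cpl.receiver} not in channel set")

    fs = background.fs
    ns = background.n_samples
    lmax = max((_lag_samples(c.lag, fs) for c in planted_effect), default=0)
    n_ch = len(channels)
    sos_cache = {c.band: _bandpass_sos(c.band, fs) for c in planted_effect}

    data = {}
    for p in range(n_participants):
        rng = np.random.default_rng([int(seed), p])
        a = _shaped_noise((n_epochs_per_condition, n_ch), ns, background, rng)
        base_b = _shaped_noise((n_epochs_per_condition, n_ch), ns + lmax, background, rng)
        b = base_b[:, :, lmax:].copy()
        for cpl in planted_effect:
            L = _lag_samples(cpl.lag, fs)
            drv = base_b[:, ch_index[cpl.driver], :]
            band_drv = sosfiltfilt(sos_cache[cpl.band], drv, axis=-1)
            seg = band_drv[:, lmax - L: lmax - L + ns]
            b[:, ch_index[cpl.receiver], :] += cpl.coupling_gain * seg
        data[f"sub-{p:02d}"] = {"A": a, "B": b}
    return GroupDataset(data=data, channels=channels, fs=fs, couplings=planted_effect)


# ---------------------------------------------------------------------------
# Association sequences and word vectors
# ---------------------------------------------------------------------------

def _random_unit(rng: np.random.Generator, dim: int) -> np.ndarray:
    v = rng.standard_normal(dim)
    return v / np.linalg.norm(v)


def _step_vector(prev: np.ndarray, distance: float, rng: np.random.Generator) -> np.ndarray:
    """Unit vector at cosine distance ``distance`` (in [0, 1]) from ``prev``."""
    cos = 1.0 - float(np.clip(distance, 0.0, 1.0))
    r = rng.standard_normal(prev.size)
    r -= r.dot(prev) * prev
    nrm = np.linalg.norm(r)
    if nrm < 1e-12:  # pathological draw; retry deterministically
        return _step_vector(prev, distance, rng)
    w = r / nrm
    return cos * prev + np.sqrt(max(0.0, 1.0 - cos * cos)) * w


def gen_association_dataset(n_participants: int, n_items: int, n_responses: int,
                            dim: int = 50,
                            distance_profile: tuple[float, float] = (0.7, 0.1),
                            seed: int = 0,
                            thinking_time_log_mean: float = np.log(5.0),
                            thinking_time_log_sd: float = 0.6):
    """Generate association sequences whose consecutive semantic distances
    follow a target (mean, SD) profile.

    Word vectors are built by chaining on the unit sphere: each response
    vector is placed at an exact cosine distance (drawn from a clipped normal
    with the profile's mean and SD) from its predecessor, so the realised
    consecutive-distance distribution matches the target by construction.
    Items alternate between the ``free`` and ``goal_directed`` conditions.
    Thinking times are log-normal (default median 5 s).

    Returns ``(responses, vectors)``: a table with columns participant, item,
    condition, order, word, thinking_time, and a dict word -> unit vector.
    """
    if n_responses < 1:
        raise ValueError("n_responses must be >= 1")
    if dim < 2:
        raise ValueError("dim must be >= 2")
    mean_d, sd_d = distance_profile
    rng = np.random.default_rng(seed)
    rows = []
    vectors: dict[str, np.ndarray] = {}
    for p in range(n_participants):
        pid = f"P{p:03d}"
        for it in range(n_items):
            cue = f"cue_{pid}_i{it}"
            cond = "free" if it % 2 == 0 else "goal_directed"
            prev = _random_unit(rng, dim)
            vectors[cue] = prev
            for k in range(1, n_responses + 1):
                if sd_d > 0:
                    d = float(np.clip(rng.normal(mean_d, sd_d), 0.0, 1.0))
                else:
                    d = float(np.clip(mean_d, 0.0, 1.0))
                vec = _step_vector(prev, d, rng)
                word = f"{pid}_i{it}_r{k:03d}"
                vectors[word] = vec
                tt = float(rng.lognormal(thinking_time_log_mean, thinking_time_log_sd))
                rows.append({"participant": pid, "item": cue, "condition": cond,
                             "order": k, "word": word, "thinking_time": tt})
                prev = vec
    responses = pd.DataFrame(rows, columns=["participant", "item", "condition",
                                            "order", "word", "thinking_time"])
    return responses, vectors
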