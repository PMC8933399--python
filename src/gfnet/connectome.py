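"""Per-subject connectome construction.

Structural networks: streamline counts are direction-averaged (tractography
estimates a->b and b->a independently) and each connection is divided by the
mean size of the two parcels it joins, so that large parcels do not look
densely connected merely because they are large:

    w(a, b) = ((counts[a, b] + counts[b, a]) / 2) / ((size_a + size_b) / 2)

Functional networks: the broadband source signal is band-pass filtered with a
zero-phase FIR filter, the amplitude envelope is taken as the magnitude of
the analytic (Hilbert) signal, and connectivity is the Pearson correlation of
the envelopes of every pair of regions over the whole recording.
"""

from __future__ import annotations

import numpy as np
from scipy import signal

from .types import (
    BandTimeSeries,
    FrequencyBand,
    TractographySample,
    WeightedNetwork,
    get_band,
)

__all__ = [
    "build_structural_connectivity",
    "design_bandpass_fir",
    "bandpass_and_envelope",
    "build_functional_connectivity",
]


def build_structural_connectivity(sample: TractographySample) -> WeightedNetwork:
    """Turn a raw tractography sample into an undirected weighted network.

    Averages the two estimated directions and normalizes every connection by
    the average voxel size of the two parcels. The diagonal is zeroed: a
    region's connectivity with itself is uninformative.
    """
    c = sample.counts
    sizes = sample.roi_sizes
    sym = (c + c.T) / 2.0
    pair_size = (sizes[:, None] + sizes[None, :]) / 2.0
    w = sym / pair_size
    np.fill_diagonal(w, 0.0)
    return WeightedNetwork(w, list(sample.roi_labels), modality="structural")


def design_bandpass_fir(
    band: FrequencyBand, fs: float, cycles: float = 3.0
) -> np.ndarray:
    """Windowed-sinc band-pass FIR taps, odd length, linear phase.

    The filter order is ~``cycles`` periods of the low band edge, the usual
    rule of thumb for resolving the slowest in-band oscillation. Applied
    centred (see :func:`bandpass_and_envelope`) the symmetric impulse
    response gives an exactly zero-phase filter, so envelopes are not
    time-shifted.
    """
    band = band.capped(fs)
    numtaps = int(round(cycles * fs / band.lo))
    numtaps += 1 - numtaps % 2  # force odd for a symmetric (type I) filter
    numtaps = max(numtaps, 31)
    return signal.firwin(
        numtaps, [band.lo, band.hi], pass_zero=False, fs=fs, window="hamming"
    )


def _zero_phase_filter(data: np.ndarray, taps: np.ndarray) -> np.ndarray:
    """Apply a symmetric FIR centred on each sample (zero phase, no delay)."""
    half = (len(taps) - 1) // 2
    padded = np.pad(data, [(0, 0), (half, half)], mode="reflect")
    out = signal.fftconvolve(padded, taps[None, :], mode="valid", axes=1)
    return out


def bandpass_and_envelope(
    raw: BandTimeSeries,
    band: FrequencyBand | str,
    cycles: float = 3.0,
    trim: str | int = "auto",
) -> BandTimeSeries:
    """Band-pass filter each region and return its amplitude envelope.

    Parameters
    ----------
    raw
        Broadband regions x samples input with its sampling rate.
    band
        Target band (name or FrequencyBand); the upper edge is capped just
        inside Nyquist.
    cycles
        Filter length in periods of the low band edge.
    trim
        Samples to discard at each end of the envelope before it is used,
        absorbing filter and Hilbert edge transients. ``"auto"`` trims half
        the filter length; pass an int (possibly 0) to override.

    Returns
    -------
    BandTimeSeries
        The nonnegative envelope, tagged with the (capped) band.
    """
    band = get_band(band).capped(raw.fs)
    taps = design_bandpass_fir(band, raw.fs, cycles=cycles)
    min_samples = 3 * len(taps)
    if raw.n_samples < min_samples:
        raise ValueError(
            f"signal too short for the {band.name} filter: need >= {min_samples} "
            f"samples ({min_samples / raw.fs:.1f} s at {raw.fs} Hz), "
            f"got {raw.n_samples}"
        )
    filtered = _zero_phase_filter(raw.data, taps)
    env = np.abs(signal.hilbert(filtered, axis=1))
    if trim == "auto":
        n_trim = (len(taps) - 1) // 2
    else:
        n_trim = int(trim)
    if n_trim > 0:
        if env.shape[1] - 2 * n_trim <= 2 * raw.fs:
            raise ValueError(
                "envelope shorter than 2 s after edge trimming; provide a "
                "longer recording or a smaller trim"
            )
        env = env[:, n_trim:-n_trim]
    return BandTimeSeries(env, raw.fs, band, list(raw.roi_labels))


def build_functional_connectivity(envelopes: BandTimeSeries) -> WeightedNetwork:
    """Pearson correlation of every pair of envelope series.

    Raises if any region's envelope has zero variance (its correlation is
    undefined), naming the offending region.
    """
    data = envelopes.data
    if data.shape[0] < 2:
        raise ValueError("need at least 2 regions for connectivity")
    if data.shape[1] < 3:
        raise ValueError("need at least 3 samples for a correlation")
    sd = data.std(axis=1)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        names = ", ".join(envelopes.roi_labels[i] for i in bad[:5])
        raise ValueError(f"zero-variance envelope in region(s): {names}")
    r = np.corrcoef(data)
    r = np.clip(r, -1.0, 1.0)
    np.fill_diagonal(r, 0.0)
    return WeightedNetwork(
        r, list(envelopes.roi_labels), modality="functional", band=envelopes.band
    )
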