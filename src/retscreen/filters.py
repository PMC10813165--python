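"""Zero-phase frequency-domain filters.

All filtering in this package is done by multiplying the real FFT of a
record with a real, non-negative transfer function and inverting — a
zero-phase operation that cannot shift component peak times.  Transfer
functions use a raised-cosine transition band, positioned so that the
gain at the nominal cutoff is exactly 1/sqrt(2) (the -3 dB convention
used by ERG acquisition hardware).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "lowpass_transfer",
    "highpass_transfer",
    "bandpass_transfer",
    "apply_transfer",
]

# Fractional position of the -3 dB point inside the transition band.
# Falling raised cosine: 0.5*(1+cos(pi*x)) = 1/sqrt(2)  =>  x ~ 0.36405
# Rising raised cosine:  0.5*(1-cos(pi*x)) = 1/sqrt(2)  =>  x ~ 0.63595
_LP_POS = float(np.arccos(np.sqrt(2.0) - 1.0) / np.pi)
_HP_POS = float(np.arccos(1.0 - np.sqrt(2.0)) / np.pi)


def lowpass_transfer(f, cutoff_hz: float, transition_hz: float = 50.0):
    """Raised-cosine low-pass magnitude response.

    Gain is 1 up to the start of the transition band, 1/sqrt(2) at
    ``cutoff_hz`` and 0 above the transition band; monotone
    non-increasing in ``|f|``.

    Parameters
    ----------
    f : array_like
        Frequencies (Hz) at which to evaluate the response.
    cutoff_hz : float
        -3 dB frequency.
    transition_hz : float
        Full width of the raised-cosine transition band (Hz).
    """
    if cutoff_hz <= 0:
        raise ValueError("cutoff_hz must be positive")
    if transition_hz <= 0:
        raise ValueError("transition_hz must be positive")
    f1 = cutoff_hz - _LP_POS * transition_hz
    if f1 < 0:
        raise ValueError(
            "transition band extends below 0 Hz; reduce transition_hz "
            f"(cutoff={cutoff_hz} Hz, transition={transition_hz} Hz)"
        )
    x = np.clip((np.abs(np.asarray(f, dtype=float)) - f1) / transition_hz, 0.0, 1.0)
    return 0.5 * (1.0 + np.cos(np.pi * x))


def highpass_transfer(f, cutoff_hz: float, transition_hz: float = 0.4):
    """Raised-cosine high-pass magnitude response (-3 dB at ``cutoff_hz``)."""
    if cutoff_hz <= 0:
        raise ValueError("cutoff_hz must be positive")
    if transition_hz <= 0:
        raise ValueError("transition_hz must be positive")
    f1 = cutoff_hz - _HP_POS * transition_hz
    if f1 < 0:
        raise ValueError(
            "transition band extends below 0 Hz; reduce transition_hz "
            f"(cutoff={cutoff_hz} Hz, transition={transition_hz} Hz)"
        )
    x = np.clip((np.abs(np.asarray(f, dtype=float)) - f1) / transition_hz, 0.0, 1.0)
    return 0.5 * (1.0 - np.cos(np.pi * x))


def bandpass_transfer(
    f,
    hp_cutoff_hz: float,
    lp_cutoff_hz: float,
    hp_transition_hz: float = 0.4,
    lp_transition_hz: float = 200.0,
):
    """Band-pass response: product of the high- and low-pass responses.

    The two cutoffs are each -3 dB points provided the bands do not
    overlap (they never do for the 0.3–1000 Hz acquisition band).
    """
    if hp_cutoff_hz >= lp_cutoff_hz:
        raise ValueError("hp_cutoff_hz must be below lp_cutoff_hz")
    return highpass_transfer(f, hp_cutoff_hz, hp_transition_hz) * lowpass_transfer(
        f, lp_cutoff_hz, lp_transition_hz
    )


def apply_transfer(x, fs_hz: float, transfer) -> np.ndarray:
    """Filter ``x`` with zero phase by pointwise multiplication in the DFT domain.

    ``transfer`` is a callable mapping a frequency vector (Hz) to real
    gains.  The output is real and has the same length as the input.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("apply_transfer expects a 1-D record")
    n = x.size
    if n < 2:
        raise ValueError("record too short to filter")
    freqs = np.fft.rfftfreq(n, d=1.0 / fs_hz)
    h = np.asarray(transfer(freqs), dtype=float)
    if h.shape != freqs.shape:
        raise ValueError("transfer must return one gain per frequency bin")
    return np.fft.irfft(np.fft.rfft(x) * h, n)
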