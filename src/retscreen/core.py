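"""Core containers: the flash ERG record and the acquisition settings."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Mapping

import numpy as np
from scipy import signal as spsig

__all__ = ["AcquisitionSpec", "ERGWaveform", "GENOTYPES", "TREATMENTS", "GROUPS"]

GENOTYPES = ("WT", "HOM")
TREATMENTS = ("VEH", "LDOPA")
GROUPS = ("WT_VEH", "WT_LDOPA", "HOM_VEH", "HOM_LDOPA")


@dataclass(frozen=True)
class AcquisitionSpec:
    """Digitisation and analogue band-pass settings of the ERG system.

    Defaults emulate a standard rodent flash-ERG acquisition: 640 ms
    records sampled at 4 kHz, band-passed 0.3–1000 Hz (-3 dB), with a
    20 ms pre-stimulus baseline segment before the flash at t = 0.
    """

    fs_hz: float = 4000.0
    duration_s: float = 0.640
    hp_cutoff_hz: float = 0.3
    lp_cutoff_hz: float = 1000.0
    pre_stimulus_s: float = 0.020
    hp_order: int = 1
    lp_order: int = 2

    def __post_init__(self) -> None:
        if self.fs_hz <= 0 or self.duration_s <= 0:
            raise ValueError("sampling rate and duration must be positive")
        if not (0.0 < self.hp_cutoff_hz < self.lp_cutoff_hz < self.fs_hz / 2.0):
            raise ValueError(
                "band-pass cutoffs must satisfy 0 < hp < lp < Nyquist "
                f"(got hp={self.hp_cutoff_hz}, lp={self.lp_cutoff_hz}, fs={self.fs_hz})"
            )
        if not (0.0 <= self.pre_stimulus_s < self.duration_s):
            raise ValueError("pre_stimulus_s must lie within the record")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.fs_hz))

    def time_grid(self) -> np.ndarray:
        """Sample times in seconds relative to the flash (t=0)."""
        return -self.pre_stimulus_s + np.arange(self.n_samples) / self.fs_hz

    def _band_sos(self) -> np.ndarray:
        # Causal Butterworth sections emulating the amplifier's analogue
        # band-pass: -3 dB at each corner regardless of order.
        hp = spsig.butter(self.hp_order, self.hp_cutoff_hz, "highpass", fs=self.fs_hz, output="sos")
        lp = spsig.butter(self.lp_order, self.lp_cutoff_hz, "lowpass", fs=self.fs_hz, output="sos")
        return np.vstack([hp, lp])

    def band_gain(self, f) -> np.ndarray:
        """Magnitude response of the acquisition band-pass at frequencies ``f`` (Hz)."""
        f = np.atleast_1d(np.asarray(f, dtype=float))
        _, h = spsig.sosfreqz(self._band_sos(), worN=2.0 * np.pi * f / self.fs_hz)
        return np.abs(h)

    def bandpass(self, x) -> np.ndarray:
        """Apply the causal acquisition band-pass to a record."""
        x = np.asarray(x, dtype=float)
        if x.ndim != 1:
            raise ValueError("bandpass expects a 1-D record")
        return spsig.sosfilt(self._band_sos(), x)

    def undo_highpass(self, x) -> np.ndarray:
        """Invert the AC-coupling high-pass (restores slow-wave amplitude).

        The inverse of the first-order coupling filter integrates the
        record; over a single 640 ms sweep the accumulated noise is well
        below 1 uV, so slow components (the b-wave) recover their true
        amplitude.  Only meaningful for records actually acquired
        through this band-pass.
        """
        b, a = spsig.butter(self.hp_order, self.hp_cutoff_hz, "highpass", fs=self.fs_hz)
        return spsig.lfilter(a, b, np.asarray(x, dtype=float))


@dataclass
class ERGWaveform:
    """A single dark-adapted flash ERG response.

    ``t0_s`` is the time of the first sample relative to the flash and
    is negative when a pre-stimulus baseline segment was recorded.
    """

    samples_uV: np.ndarray
    fs_hz: float = 4000.0
    t0_s: float = -0.020
    flash_energy_log: float = 2.07
    meta: Mapping[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples_uV = np.asarray(self.samples_uV, dtype=float)
        if self.samples_uV.ndim != 1 or self.samples_uV.size < 2:
            raise ValueError("samples_uV must be a 1-D vector with >= 2 samples")
        if not np.all(np.isfinite(self.samples_uV)):
            raise ValueError("samples_uV contains non-finite values")
        if self.fs_hz <= 0:
            raise ValueError("fs_hz must be positive")

    @property
    def time_s(self) -> np.ndarray:
        return self.t0_s + np.arange(self.samples_uV.size) / self.fs_hz

    @property
    def duration_s(self) -> float:
        return self.samples_uV.size / self.fs_hz

    def prestimulus_sd(self) -> float:
        """SD of the pre-stimulus (t < 0) segment; 0 if none exists."""
        pre = self.samples_uV[self.time_s < 0.0]
        return float(np.std(pre)) if pre.size else 0.0
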