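"""Sinusoidally amplitude-modulated (SAM) tone stimuli and level schedules.

A SAM tone is

    SAM(t) = A * sin(2*pi*f_c*t) * (1 + m*sin(2*pi*f_m*t)) / 2

with carrier frequency ``f_c``, modulation frequency ``f_m`` and modulation
index ``m`` in [0, 1].  The amplitude ``A`` is chosen so that the waveform RMS
matches a requested sound pressure level in dB SPL (re 20 uPa).  Waveforms are
represented in pascal.

The module also carries the two level/duration schedules used throughout the
package: the recording schedule (10 levels, minutes-long presentations chosen
to reach a significant EFR SNR) and the simulation schedule (10-100 dB SPL in
5-dB steps, 1.2-s stimuli).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SAMStimulus",
    "make_sam",
    "level_schedule",
    "to_wav",
    "envelope",
    "envelope_rms",
    "RECORDED_SCHEDULE_MIN",
]

#: reference pressure for dB SPL, Pa
P_REF = 20e-6

#: recording-session schedule: stimulus level (dB SPL) -> presentation time (min)
RECORDED_SCHEDULE_MIN = {
    34: 10.0,
    40: 8.5,
    46: 8.5,
    54: 7.0,
    60: 7.0,
    66: 6.5,
    71: 5.5,
    77: 5.5,
    81: 5.5,
    87: 5.5,
}

#: duration of every simulated stimulus, s
SIMULATED_DURATION_S = 1.2


@dataclass(frozen=True)
class SAMStimulus:
    """A calibrated SAM-tone stimulus.

    Attributes
    ----------
    carrier_freq, mod_freq : float
        Carrier and modulation frequency, Hz.
    mod_index : float
        Modulation depth ``m`` in [0, 1].
    level_db_spl : float
        Calibrated RMS level, dB SPL re 20 uPa.
    duration : float
        Stimulus duration, s.
    sample_rate : float
        Sampling rate, Hz.
    waveform : numpy.ndarray
        Pressure samples, Pa; ``len == round(duration * sample_rate)``.
    amplitude : float
        Realized carrier amplitude ``A`` of the formula, Pa.
    """

    carrier_freq: float
    mod_freq: float
    mod_index: float
    level_db_spl: float
    duration: float
    sample_rate: float
    waveform: np.ndarray
    amplitude: float = 0.0

    @property
    def times(self) -> np.ndarray:
        """Sample times, s."""
        n = len(self.waveform)
        return np.arange(n) / self.sample_rate


def envelope(mod_freq: float, mod_index: float, t: np.ndarray) -> np.ndarray:
    """Stimulus envelope ``(1 + m*sin(2*pi*f_m*t)) / 2`` (unit carrier)."""
    return 0.5 * (1.0 + mod_index * np.sin(2.0 * np.pi * mod_freq * t))


def envelope_rms(mod_index: float) -> float:
    """RMS of the envelope: ``0.5 * sqrt(1 + m**2 / 2)``."""
    return 0.5 * np.sqrt(1.0 + 0.5 * mod_index**2)


def make_sam(
    carrier_freq: float,
    mod_freq: float,
    mod_index: float,
    level_db_spl: float,
    duration: float,
    sample_rate: float,
    ramp: float | None = None,
) -> SAMStimulus:
    """Generate a calibrated SAM tone.

    Parameters
    ----------
    carrier_freq, mod_freq : float
        Carrier and modulation frequency, Hz.  ``sample_rate`` must exceed
        twice their sum.
    mod_index : float
        Modulation depth in [0, 1].
    level_db_spl : float
        Target RMS level in dB SPL; the amplitude ``A`` is scaled so the
        generated waveform RMS equals ``20 uPa * 10**(level/20)``.
    duration : float
        Duration in seconds (> 0).
    sample_rate : float
        Sampling rate, Hz.
    ramp : float, optional
        Raised-cosine onset/offset ramp duration in seconds, applied after
        calibration.  Intended for exported audio; simulation uses unramped
        stimuli and analyzes the steady state only.

    Returns
    -------
    SAMStimulus
    """
    if not 0.0 <= mod_index <= 1.0:
        raise ValueError(f"mod_index must be in [0, 1], got {mod_index}")
    if duration <= 0:
        raise ValueError(f"duration must be positive, got {duration}")
    if sample_rate <= 2.0 * (carrier_freq + mod_freq):
        raise ValueError(
            "sample_rate must exceed twice the highest stimulus component "
            f"({carrier_freq} + {mod_freq} Hz)"
        )

    n = int(round(duration * sample_rate))
    t = np.arange(n) / sample_rate
    unit = np.sin(2.0 * np.pi * carrier_freq * t) * envelope(mod_freq, mod_index, t)
    target_rms = P_REF * 10.0 ** (level_db_spl / 20.0)
    # calibrate against the realized digital RMS so the round-trip is exact
    # for any duration, not only integer numbers of beat periods
    unit_rms = float(np.sqrt(np.mean(unit**2)))
    scale = target_rms / unit_rms
    waveform = scale * unit

    if ramp is not None:
        if ramp < 0 or 2 * ramp > duration:
            raise ValueError("ramp must be >= 0 and fit twice into duration")
        n_ramp = int(round(ramp * sample_rate))
        if n_ramp > 0:
            win = 0.5 * (1.0 - np.cos(np.pi * np.arange(n_ramp) / n_ramp))
            waveform = waveform.copy()
            waveform[:n_ramp] *= win
            waveform[-n_ramp:] *= win[::-1]

    return SAMStimulus(
        carrier_freq=carrier_freq,
        mod_freq=mod_freq,
        mod_index=mod_index,
        level_db_spl=level_db_spl,
        duration=duration,
        sample_rate=sample_rate,
        waveform=waveform,
        amplitude=scale,
    )


def to_wav(stim: SAMStimulus, path, normalize: bool = True) -> None:
    """Export a stimulus as a float32 WAV file.

    With ``normalize`` the waveform is scaled to a 0.5 peak so playback
    chains do not clip; pressure calibration is then carried by the file
    name / metadata, not the samples.
    """
    from scipy.io import wavfile

    w = stim.waveform.astype(np.float32)
    if normalize and np.abs(w).max() > 0:
        w = 0.5 * w / np.abs(w).max()
    wavfile.write(path, int(stim.sample_rate), w)


def level_schedule(group: str) -> list[tuple[float, float]]:
    """Level/duration schedule for a named stimulus group.

    Parameters
    ----------
    group : {"recorded", "simulated"}
        ``"recorded"`` returns the ten recording-session pairs (levels
        34-87 dB SPL, presentation times 5.5-10 min expressed in seconds).
        ``"simulated"`` returns levels 10-100 dB SPL in 5-dB steps, each
        with a 1.2-s stimulus.

    Returns
    -------
    list of (level_db_spl, duration_s)
    """
    if group == "recorded":
        return [(float(lv), 60.0 * mins) for lv, mins in RECORDED_SCHEDULE_MIN.items()]
    if group == "simulated":
        levels = np.arange(10, 101, 5)
        return [(float(lv), SIMULATED_DURATION_S) for lv in levels]
    raise ValueError(f"unknown schedule group {group!r}; expected 'recorded' or 'simulated'")
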