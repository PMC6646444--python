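"""Simulated envelope-following-response (EFR) magnitudes and level functions.

The simulated EFR is the amplitude of the modulation-frequency component of
the summed population PSTH: the PSTH is summed over the selected CF channels
and SR classes, the mean is removed, and a rectangular-window FFT over an
analysis window holding an integer number of modulation cycles returns the
amplitude (2/N scaling) at the modulation-frequency bin.

Magnitude-level functions collect one EFR per stimulus level and modulation
depth; 1/3-octave CF bands decompose the response into on-frequency (at the
carrier) and off-frequency (more basal) contributions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .periphery import (
    DEFAULT_TUNING,
    FiberClassParams,
    HairCellProfile,
    PopulationResponse,
    TuningParams,
    simulate_population,
)
from .population import CFGrid, FiberPopulation
from .stimuli import make_sam

__all__ = [
    "EFRMeasurement",
    "MagnitudeLevelFunction",
    "compute_efr",
    "band_select",
    "level_sweep",
    "magnitude_level_function",
    "normalize_to_reference",
]


@dataclass(frozen=True)
class EFRMeasurement:
    """EFR amplitude (linear, arbitrary units) at the modulation-frequency bin."""

    magnitude: float
    freq_bin: float
    analysis_window: float

    @property
    def db(self) -> float:
        """Magnitude in dB re 1 a.u."""
        return 20.0 * np.log10(self.magnitude) if self.magnitude > 0 else -np.inf


@dataclass(frozen=True)
class MagnitudeLevelFunction:
    """EFR magnitude as a function of stimulus level, for one modulation depth."""

    levels: np.ndarray
    efr: np.ndarray
    mod_index: float
    label: str = ""
    offset_db: float = 0.0

    def __post_init__(self):
        lv = np.asarray(self.levels, float)
        mg = np.asarray(self.efr, float)
        if lv.shape != mg.shape or np.any(np.diff(lv) <= 0):
            raise ValueError("levels must be strictly increasing and match efr in length")
        object.__setattr__(self, "levels", lv)
        object.__setattr__(self, "efr", mg)

    @property
    def db(self) -> np.ndarray:
        """Magnitudes in dB (offset applied; see :func:`normalize_to_reference`)."""
        with np.errstate(divide="ignore"):
            return 20.0 * np.log10(self.efr) + self.offset_db

    def at(self, level: float) -> float:
        """Linear magnitude at one stimulus level (must be on the grid)."""
        idx = np.nonzero(np.isclose(self.levels, level))[0]
        if len(idx) == 0:
            raise ValueError(f"level {level} dB SPL not in this function's levels")
        return float(self.efr[idx[0]])


def compute_efr(
    resp: PopulationResponse,
    fm: float | None = None,
    window: float = 1.0,
    cf_indices=None,
    classes=None,
    start: float | None = None,
) -> EFRMeasurement:
    """EFR magnitude of a population response at the modulation frequency.

    Parameters
    ----------
    resp : PopulationResponse
    fm : float, optional
        Modulation frequency; defaults to the stimulus value stored on the
        response.  ``fm * window`` must be an integer (the component must
        fall exactly on an FFT bin).
    window : float
        Analysis-window length in seconds, starting after the settling
        transient (or at ``start``).
    cf_indices, classes : optional
        Restrict the sum to a CF index set (see :func:`band_select`) and/or
        SR classes.
    """
    if fm is None:
        fm = resp.mod_freq
    cycles = fm * window
    if abs(cycles - round(cycles)) > 1e-9:
        raise ValueError(
            f"fm * window = {cycles} is not an integer; adjust the analysis window "
            "so the modulation frequency falls exactly on an FFT bin"
        )
    n = int(round(window / resp.bin_width))
    if abs(window / resp.bin_width - n) > 1e-6:
        raise ValueError("bin width must divide the analysis window")
    i0 = resp.steady_start_index if start is None else int(round(start / resp.bin_width))
    x = resp.summed(cf_indices=cf_indices, classes=classes)[i0 : i0 + n]
    if len(x) < n:
        raise ValueError(
            f"response too short: need {n} steady-state bins, have {len(x)}"
        )
    x = x - x.mean()
    spec = np.fft.rfft(x)
    k = int(round(cycles))
    magnitude = 2.0 / n * np.abs(spec[k])
    return EFRMeasurement(magnitude=float(magnitude), freq_bin=float(fm), analysis_window=window)


def band_select(grid: CFGrid, center: float, width_octaves: float = 1.0 / 3.0):
    """Indices of the CF channels within a band around ``center`` (Hz).

    The band is ``[center * 2**(-w/2), center * 2**(+w/2))``, half-open at
    the upper edge.  ``width_octaves = 0`` selects the single nearest CF.
    """
    if not grid.cf[0] <= center <= grid.cf[-1]:
        raise ValueError(f"band center {center} Hz outside the grid range")
    if width_octaves == 0:
        return np.array([int(np.argmin(np.abs(np.log2(grid.cf / center))))])
    lo = center * 2.0 ** (-width_octaves / 2.0)
    hi = center * 2.0 ** (width_octaves / 2.0)
    idx = np.nonzero((grid.cf >= lo) & (grid.cf < hi))[0]
    if len(idx) == 0:
        raise ValueError(f"no CF channels in the {width_octaves}-octave band at {center} Hz")
    return idx


def level_sweep(
    pop: FiberPopulation,
    hair: HairCellProfile | None = None,
    levels=None,
    mod_index: float = 0.85,
    selections: dict[str, tuple] | None = None,
    carrier_freq: float = 2005.0,
    mod_freq: float = 93.0,
    duration: float = 1.2,
    sample_rate: float = 48000.0,
    class_params: dict[str, FiberClassParams] | None = None,
    window: float = 1.0,
    bin_width: float = 1e-3,
    tuning: TuningParams = DEFAULT_TUNING,
    label: str = "",
) -> dict[str, MagnitudeLevelFunction]:
    """Magnitude-level functions for several CF/class selections at once.

    ``selections`` maps a selection label to a ``(cf_indices, classes)``
    pair (either entry may be None for "all").  The population is simulated
    once per (level, depth) and every selection is extracted from the same
    response, which is what makes band x fiber-type decompositions cheap.
    """
    if levels is None:
        levels = np.arange(10, 101, 5, dtype=float)
    levels = np.asarray(levels, float)
    if selections is None:
        selections = {"all": (None, None)}
    mags = {key: np.empty(len(levels)) for key in selections}
    for i, lv in enumerate(levels):
        stim = make_sam(carrier_freq, mod_freq, mod_index, lv, duration, sample_rate)
        resp = simulate_population(
            stim, pop, hair=hair, class_params=class_params, mode="analytic",
            bin_width=bin_width, tuning=tuning,
        )
        for key, (cf_indices, classes) in selections.items():
            mags[key][i] = compute_efr(
                resp, fm=mod_freq, window=window, cf_indices=cf_indices, classes=classes
            ).magnitude
    return {
        key: MagnitudeLevelFunction(
            levels=levels, efr=m, mod_index=mod_index,
            label=f"{label}:{key}" if label else key,
        )
        for key, m in mags.items()
    }


def magnitude_level_function(
    pop: FiberPopulation,
    hair: HairCellProfile | None = None,
    levels=None,
    mod_index: float = 0.85,
    cf_indices=None,
    classes=None,
    label: str = "",
    **kwargs,
) -> MagnitudeLevelFunction:
    """Simulated EFR magnitude-level function (analytic mode, deterministic).

    One stimulus is generated per level; each is run through the surrogate
    periphery and the EFR is extracted from the selected CFs/classes.  Extra
    keyword arguments are forwarded to :func:`level_sweep`.
    """
    out = level_sweep(
        pop, hair=hair, levels=levels, mod_index=mod_index,
        selections={"sel": (cf_indices, classes)}, **kwargs,
    )["sel"]
    return MagnitudeLevelFunction(levels=out.levels, efr=out.efr,
                                  mod_index=mod_index, label=label)


def normalize_to_reference(
    functions: list[MagnitudeLevelFunction],
    anchor_level: float,
    reference_db: float,
    anchor_mod_index: float = 0.85,
) -> list[MagnitudeLevelFunction]:
    """Anchor a family of simulated curves to a recorded reference point.

    A single additive dB offset is computed so that the curve with
    ``anchor_mod_index`` equals ``reference_db`` (dB re 1 uV) at
    ``anchor_level``, and the same offset is applied to every curve, leaving
    all between-scenario differences unchanged.
    """
    anchor = next((f for f in functions if np.isclose(f.mod_index, anchor_mod_index)), None)
    if anchor is None:
        raise ValueError(f"no curve with mod_index {anchor_mod_index} to anchor")
    mag = anchor.at(anchor_level)
    offset = reference_db - 20.0 * np.log10(mag)
    return [
        MagnitudeLevelFunction(
            levels=f.levels, efr=f.efr, mod_index=f.mod_index, label=f.label,
            offset_db=f.offset_db + offset,
        )
        for f in functions
    ]
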