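"""Humanized auditory-nerve fiber population and cochlear synaptopathy.

The population lives on a grid of characteristic frequencies (CF) placed at
equally spaced positions along the basilar membrane and mapped to frequency
by the human Greenwood map

    F(x) = A * (10**(a*x) - k),   A = 165.4, a = 2.1, k = 0.88,

with normalized place x (0 = apex, 1 = base).  Synapse counts per CF follow a
density profile (uniform, or a piecewise-linear approximation of the human
innervation-density curve) and are split into the three spontaneous-rate (SR)
classes in the cat proportions 61 % high / 23 % medium / 16 % low.  All
integerization uses deterministic largest-remainder rounding so grand totals
are exact.

Cochlear synaptopathy is expressed as a percentage of synapses lost per CF.
A profile is specified by anchor frequencies (with optional flat extensions
below/above the anchored range) and interpolated over the grid with a
shape-preserving piecewise cubic Hermite polynomial (PCHIP) on a
log2-frequency axis, which cannot overshoot the [0, 100] range.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import PchipInterpolator

__all__ = [
    "CFGrid",
    "FiberPopulation",
    "SynaptopathyProfile",
    "build_cf_grid",
    "allocate_fibers",
    "interpolate_loss",
    "apply_synaptopathy",
    "largest_remainder",
    "save_population",
    "load_population",
    "greenwood",
    "greenwood_position",
    "SR_CLASSES",
    "SR_FRACTIONS",
    "CS_PRESETS",
    "density_weights",
]

# human Greenwood-map constants (normalized place)
GREENWOOD_A = 165.4
GREENWOOD_ALPHA = 2.1
GREENWOOD_K = 0.88

SR_CLASSES = ("high", "medium", "low")
SR_FRACTIONS = (0.61, 0.23, 0.16)


def greenwood(x):
    """Frequency (Hz) at normalized basilar-membrane place ``x`` in [0, 1]."""
    return GREENWOOD_A * (10.0 ** (GREENWOOD_ALPHA * np.asarray(x, float)) - GREENWOOD_K)


def greenwood_position(f):
    """Normalized place for frequency ``f`` (Hz); inverse of :func:`greenwood`."""
    f = np.asarray(f, float)
    return np.log10(f / GREENWOOD_A + GREENWOOD_K) / GREENWOOD_ALPHA


@dataclass(frozen=True)
class CFGrid:
    """Characteristic-frequency grid at equally spaced cochlear places."""

    cf: np.ndarray
    position: np.ndarray

    @property
    def n_cf(self) -> int:
        return len(self.cf)


@dataclass(frozen=True)
class FiberPopulation:
    """Synapse counts per (CF, SR class).

    ``counts`` has shape (n_cf, 3) with columns ordered high/medium/low.
    """

    grid: CFGrid
    counts: np.ndarray
    density: str = "uniform"

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def class_total(self, sr_class: str) -> int:
        return int(self.counts[:, SR_CLASSES.index(sr_class)].sum())


@dataclass(frozen=True)
class SynaptopathyProfile:
    """Percent synapse loss per CF, evaluated on a grid."""

    grid: CFGrid
    per_cf_loss: np.ndarray
    anchors: tuple = field(default_factory=tuple)

    @property
    def mean_loss(self) -> float:
        return float(np.mean(self.per_cf_loss))


def build_cf_grid(n_cf: int = 200, f_min: float = 200.0, f_max: float = 20000.0) -> CFGrid:
    """Grid of ``n_cf`` CFs from ``f_min`` to ``f_max`` Hz, equally spaced in place.

    End positions are solved from the Greenwood map so the first and last CF
    hit ``f_min`` and ``f_max`` exactly.
    """
    if not 0.0 < f_min < f_max:
        raise ValueError("need 0 < f_min < f_max")
    if n_cf < 2:
        raise ValueError("n_cf must be >= 2")
    if f_max > greenwood(1.0):
        raise ValueError(
            f"f_max={f_max} Hz is beyond the Greenwood map range "
            f"({greenwood(1.0):.0f} Hz at the base)"
        )
    x = np.linspace(greenwood_position(f_min), greenwood_position(f_max), n_cf)
    return CFGrid(cf=greenwood(x), position=x)


def largest_remainder(targets: np.ndarray, total: int) -> np.ndarray:
    """Integerize nonnegative ``targets`` (summing to ``total``) exactly.

    Floors every target, then hands the remaining units to the entries with
    the largest fractional parts; ties resolve by index order, so the result
    is deterministic.
    """
    targets = np.asarray(targets, float)
    if np.any(targets < 0):
        raise ValueError("targets must be nonnegative")
    base = np.floor(targets).astype(int)
    short = int(total) - int(base.sum())
    if short < 0:
        raise ValueError("floor already exceeds total; targets must sum to total")
    if short > 0:
        # round away float noise so genuine ties resolve by index, not ulps
        frac = np.round(targets - base, 9)
        order = np.lexsort((np.arange(len(targets)), -frac))
        base[order[:short]] += 1
    return base


#: piecewise-linear approximation of the human innervation-density curve
#: (relative synapses per IHC vs frequency; peaks in the 2-4 kHz region,
#: lower toward apex and base).  Editable; "uniform" bypasses it.
HUMAN_DENSITY_ANCHORS_KHZ = {
    0.2: 0.55,
    0.5: 0.75,
    1.0: 1.0,
    2.0: 1.3,
    4.0: 1.3,
    8.0: 0.95,
    20.0: 0.55,
}


def density_weights(grid: CFGrid, profile: str = "uniform") -> np.ndarray:
    """Relative fibers-per-CF weights for a named density profile."""
    if profile == "uniform":
        return np.ones(grid.n_cf)
    if profile == "human":
        f_khz = np.array(list(HUMAN_DENSITY_ANCHORS_KHZ))
        w = np.array(list(HUMAN_DENSITY_ANCHORS_KHZ.values()))
        return np.interp(np.log2(grid.cf / 1000.0), np.log2(f_khz), w)
    raise ValueError(f"unknown density profile {profile!r}; expected 'uniform' or 'human'")


def allocate_fibers(
    grid: CFGrid,
    total: int = 32000,
    sr_fractions: tuple[float, float, float] = SR_FRACTIONS,
    density: str | np.ndarray = "uniform",
) -> FiberPopulation:
    """Allocate ``total`` synapses over the grid and the three SR classes.

    Per-CF totals are proportional to the density weights and integerized by
    largest remainder so the grand total is exactly ``total``; within each CF
    the class counts are the SR fractions of the per-CF total, integerized
    the same way.
    """
    fr = np.asarray(sr_fractions, float)
    if abs(fr.sum() - 1.0) > 1e-9:
        raise ValueError("sr_fractions must sum to 1")
    if isinstance(density, str):
        w = density_weights(grid, density)
        density_name = density
    else:
        w = np.asarray(density, float)
        density_name = "custom"
    if np.any(w < 0) or not np.any(w > 0):
        raise ValueError("density weights must be nonnegative and not all zero")
    if total < grid.n_cf:
        warnings.warn(
            f"total={total} is below the number of CFs ({grid.n_cf}); "
            "many channels will have zero synapses",
            stacklevel=2,
        )
    per_cf = largest_remainder(total * w / w.sum(), total)
    counts = np.empty((grid.n_cf, 3), dtype=int)
    for i, n in enumerate(per_cf):
        counts[i] = largest_remainder(n * fr, int(n))
    return FiberPopulation(grid=grid, counts=counts, density=density_name)


# Named synaptopathy presets: inner anchors {kHz: % loss} plus flat
# extensions ("le": hold the value at and below this kHz, "ge": at and
# above).  The anchor tables approximate the synaptopathy patterns fitted to
# the representative normal-threshold (NH09) and mildly impaired (HI04)
# listeners: NH09 concentrates up to 85 % loss in the octave band around
# 4 kHz; HI04 has 85 % loss at all CFs above 2.5 kHz with a graded onset.
CS_PRESETS: dict[str, dict] = {
    "NH09": {
        "le": (2.0, 0.0),
        "anchors": {
            2.3: 0.0,
            2.4: 0.0,
            2.5: 0.0,
            2.7: 20.0,
            2.8: 50.0,
            2.9: 85.0,
            3.0: 85.0,
            4.0: 85.0,
            5.65: 85.0,
            5.7: 50.0,
            5.75: 20.0,
        },
        "ge": (6.0, 0.0),
    },
    "HI04": {
        "le": (2.0, 20.0),
        "anchors": {
            2.3: 30.0,
            2.4: 50.0,
            2.5: 85.0,
            2.7: 85.0,
            2.8: 85.0,
            2.9: 85.0,
            3.0: 85.0,
            4.0: 85.0,
            5.65: 85.0,
            5.7: 85.0,
            5.75: 85.0,
        },
        "ge": (6.0, 85.0),
    },
}


def interpolate_loss(
    anchors,
    grid: CFGrid,
    le: tuple[float, float] | None = None,
    ge: tuple[float, float] | None = None,
) -> SynaptopathyProfile:
    """Interpolate anchor (kHz, % loss) pairs over a CF grid.

    Parameters
    ----------
    anchors : str, dict or sequence of pairs
        A preset name from :data:`CS_PRESETS`, a ``{freq_khz: loss_pct}``
        mapping, or ``(freq_khz, loss_pct)`` pairs.  Frequencies must be
        strictly increasing after expanding the flat extensions.
    le, ge : (freq_khz, loss_pct), optional
        Flat extensions: hold ``loss_pct`` at all CFs at or below / at or
        above the given frequency.

    Notes
    -----
    Interpolation is shape-preserving monotone piecewise-cubic (PCHIP) on a
    log2-frequency axis, so the interpolant stays within the range spanned by
    neighboring anchors and never leaves [0, 100].
    """
    if isinstance(anchors, str):
        try:
            preset = CS_PRESETS[anchors]
        except KeyError:
            raise ValueError(
                f"unknown synaptopathy preset {anchors!r}; available: {sorted(CS_PRESETS)}"
            ) from None
        return interpolate_loss(preset["anchors"], grid, le=preset.get("le"), ge=preset.get("ge"))

    if isinstance(anchors, dict):
        pairs = sorted(anchors.items())
    else:
        pairs = sorted((float(f), float(p)) for f, p in anchors)

    f_min_khz = grid.cf[0] / 1000.0
    f_max_khz = grid.cf[-1] / 1000.0
    full: list[tuple[float, float]] = []
    if le is not None:
        if f_min_khz < le[0]:
            full.append((f_min_khz, le[1]))
        full.append(tuple(le))
    full.extend(pairs)
    if ge is not None:
        full.append(tuple(ge))
        if f_max_khz > ge[0]:
            full.append((f_max_khz, ge[1]))

    freqs = np.array([f for f, _ in full])
    loss = np.array([p for _, p in full])
    if np.any(np.diff(freqs) <= 0):
        raise ValueError("anchor frequencies must be strictly increasing (no duplicates)")
    if np.any((loss < 0) | (loss > 100)):
        raise ValueError("loss percentages must lie in [0, 100]")

    interp = PchipInterpolator(np.log2(freqs), loss, extrapolate=False)
    x = np.log2(grid.cf / 1000.0)
    per_cf = interp(x)
    # grid points outside the anchored range hold the edge values
    per_cf = np.where(x <= np.log2(freqs[0]), loss[0], per_cf)
    per_cf = np.where(x >= np.log2(freqs[-1]), loss[-1], per_cf)
    return SynaptopathyProfile(grid=grid, per_cf_loss=per_cf, anchors=tuple(full))


def save_population(pop: FiberPopulation, path) -> None:
    """Dump a population as CSV (columns: cf_hz, n_high, n_med, n_low)."""
    data = np.column_stack([pop.grid.cf, pop.counts])
    np.savetxt(path, data, delimiter=",", header="cf_hz,n_high,n_med,n_low",
               comments="", fmt=["%.6f", "%d", "%d", "%d"])


def load_population(path) -> FiberPopulation:
    """Load a population dumped by :func:`save_population`.

    Grid positions are recovered by inverting the Greenwood map.
    """
    data = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
    cf = data[:, 0]
    grid = CFGrid(cf=cf, position=greenwood_position(cf))
    return FiberPopulation(grid=grid, counts=data[:, 1:4].astype(int), density="custom")


def apply_synaptopathy(
    pop: FiberPopulation,
    profile: SynaptopathyProfile,
    classes: tuple[str, ...] = SR_CLASSES,
) -> tuple[FiberPopulation, float]:
    """Remove a per-CF percentage of synapses from the selected SR classes.

    Counts become ``round(counts * (1 - loss/100))`` for the selected
    classes; other classes are untouched.  Returns the new population and the
    realized total loss as a percentage of the original grand total.
    """
    if profile.grid.n_cf != pop.grid.n_cf or not np.allclose(profile.grid.cf, pop.grid.cf):
        raise ValueError("profile must be evaluated on the population's CF grid")
    keep = 1.0 - profile.per_cf_loss / 100.0
    counts = pop.counts.copy()
    for name in classes:
        j = SR_CLASSES.index(name)
        counts[:, j] = np.rint(pop.counts[:, j] * keep).astype(int)
    original = pop.counts.sum()
    removed = original - counts.sum()
    realized = 100.0 * removed / original if original else 0.0
    return FiberPopulation(grid=pop.grid, counts=counts, density=pop.density), realized
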