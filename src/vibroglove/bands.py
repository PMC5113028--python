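"""One-third octave band grids and the ISO 5349-1 hand-arm frequency weighting.

Hand-transmitted vibration is conventionally reported as RMS acceleration per
one-third octave band over 6.3-1,250 Hz.  This module provides the band grid
(base-10 midband frequencies, ``f_c = 10**(n/10)``), the hand-arm frequency
weighting Wh in three realizations (analog-filter magnitude, the standard's
tabulated per-band factors, and unity), and the root-sum-square summaries used
everywhere downstream: a frequency-weighted band-domain RMS and the tri-axial
vector total.

Band values are always interpreted as RMS accelerations per band (not spectral
densities), so every summary is a root sum of squares.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BandGrid",
    "WeightingVector",
    "make_band_grid",
    "wh_weights",
    "wh_filter_magnitude",
    "weighted_band_rms",
    "vector_total",
    "NOMINAL_THIRDS",
    "WH_TABLE",
]

# Renard-series nominal labels for one decade of one-third octave centers.
NOMINAL_THIRDS = (1.0, 1.25, 1.6, 2.0, 2.5, 3.15, 4.0, 5.0, 6.3, 8.0)

# Supported band-index range (10**(n/10)): 1 Hz .. 10 kHz.
_N_MIN, _N_MAX = 0, 40

# ISO 5349-1 tabulated Wh factors by band index n (exact center 10**(n/10)).
# Published to three significant figures for each one-third octave band.
WH_TABLE: dict[int, float] = {
    8: 0.727,   # 6.3 Hz
    9: 0.873,   # 8 Hz
    10: 0.951,  # 10 Hz
    11: 0.958,  # 12.5 Hz
    12: 0.896,  # 16 Hz
    13: 0.782,  # 20 Hz
    14: 0.647,  # 25 Hz
    15: 0.519,  # 31.5 Hz
    16: 0.411,  # 40 Hz
    17: 0.324,  # 50 Hz
    18: 0.256,  # 63 Hz
    19: 0.202,  # 80 Hz
    20: 0.160,  # 100 Hz
    21: 0.127,  # 125 Hz
    22: 0.101,  # 160 Hz
    23: 0.0799,  # 200 Hz
    24: 0.0634,  # 250 Hz
    25: 0.0503,  # 315 Hz
    26: 0.0398,  # 400 Hz
    27: 0.0314,  # 500 Hz
    28: 0.0245,  # 630 Hz
    29: 0.0186,  # 800 Hz
    30: 0.0135,  # 1000 Hz
    31: 0.00894,  # 1250 Hz
}

_WEIGHTING_MODES = ("iso_wh", "table", "unity")


def _nominal_label(n: int) -> float:
    """Nominal one-third octave center for band index ``n`` (e.g. 25 -> 315.0)."""
    decade, pos = divmod(n, 10)
    return round(NOMINAL_THIRDS[pos] * 10**decade, 10)


def _index_for_nominal(f_nominal: float) -> int:
    for n in range(_N_MIN, _N_MAX + 1):
        if np.isclose(_nominal_label(n), f_nominal, rtol=1e-6):
            return n
    # Name the two nearest valid centers in the rejection message.
    labels = np.array([_nominal_label(n) for n in range(_N_MIN, _N_MAX + 1)])
    order = np.argsort(np.abs(np.log10(labels) - np.log10(max(f_nominal, 1e-12))))
    near = ", ".join(f"{labels[i]:g} Hz" for i in sorted(order[:2]))
    raise ValueError(
        f"{f_nominal:g} Hz is not a standard nominal one-third octave center; "
        f"nearest valid centers: {near}"
    )


@dataclass(frozen=True)
class BandGrid:
    """Contiguous run of one-third octave bands.

    ``exact_centers`` are the base-10 midband frequencies ``10**(n/10)`` used
    for all computation; ``nominal_centers`` are the conventional labels used
    only for I/O.  Band edges are ``center * 10**(+-1/20)`` so consecutive
    bands tile the frequency axis exactly.
    """

    band_index: tuple[int, ...]
    nominal_centers: tuple[float, ...] = field(init=False)
    exact_centers: np.ndarray = field(init=False, repr=False)
    lower_edges: np.ndarray = field(init=False, repr=False)
    upper_edges: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        idx = tuple(int(n) for n in self.band_index)
        if not idx:
            raise ValueError("band grid must contain at least one band")
        if list(idx) != list(range(idx[0], idx[-1] + 1)):
            raise ValueError("band indices must be consecutive integers")
        object.__setattr__(self, "band_index", idx)
        n = np.array(idx, dtype=float)
        centers = 10.0 ** (n / 10.0)
        object.__setattr__(self, "nominal_centers", tuple(_nominal_label(i) for i in idx))
        object.__setattr__(self, "exact_centers", centers)
        object.__setattr__(self, "lower_edges", centers * 10.0 ** (-1.0 / 20.0))
        object.__setattr__(self, "upper_edges", centers * 10.0 ** (1.0 / 20.0))

    def __len__(self) -> int:
        return len(self.band_index)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, BandGrid) and self.band_index == other.band_index

    def __hash__(self) -> int:
        return hash(self.band_index)

    def index_of(self, f_nominal: float) -> int:
        """Position of a nominal center within this grid."""
        n = _index_for_nominal(f_nominal)
        if n not in self.band_index:
            raise KeyError(f"{f_nominal:g} Hz not in grid {self.nominal_centers}")
        return self.band_index.index(n)

    def subgrid(self, fmin_nominal: float, fmax_nominal: float) -> "BandGrid":
        n0, n1 = _index_for_nominal(fmin_nominal), _index_for_nominal(fmax_nominal)
        if n0 < self.band_index[0] or n1 > self.band_index[-1]:
            raise ValueError(
                f"requested range {fmin_nominal:g}-{fmax_nominal:g} Hz exceeds "
                f"grid {self.nominal_centers[0]:g}-{self.nominal_centers[-1]:g} Hz"
            )
        return BandGrid(tuple(range(n0, n1 + 1)))

    def restrict_mask(self, fmin_nominal: float, fmax_nominal: float) -> np.ndarray:
        sub = self.subgrid(fmin_nominal, fmax_nominal)
        return np.array([n in sub.band_index for n in self.band_index])


def make_band_grid(fmin_nominal: float = 6.3, fmax_nominal: float = 1250.0) -> BandGrid:
    """Build the one-third octave grid spanning two nominal centers inclusive.

    >>> len(make_band_grid(6.3, 1250))
    24
    >>> len(make_band_grid(6.3, 500))
    20
    """
    n0 = _index_for_nominal(fmin_nominal)
    n1 = _index_for_nominal(fmax_nominal)
    if n0 > n1:
        raise ValueError("fmin_nominal must not exceed fmax_nominal")
    return BandGrid(tuple(range(n0, n1 + 1)))


def wh_filter_magnitude(freq_hz) -> np.ndarray:
    """Hand-arm weighting |Wh(f)| from the standard analog-filter realization.

    Magnitude product of the band-limiting filter (2-pole Butterworth high-pass
    at f1 = 6.31 Hz and low-pass at f2 = 1258.9 Hz) and the a-v transition
    filter (zero at f3 = 15.915 Hz, 2-pole section at f4 = 15.915 Hz with
    Q4 = 0.64).  Agrees with the tabulated per-band factors to the printed
    three significant figures at exact midband frequencies.
    """
    f = np.asarray(freq_hz, dtype=float)
    s = 1j * 2.0 * np.pi * f
    w1, w2 = 2.0 * np.pi * 6.31, 2.0 * np.pi * 1258.9
    w3, w4, q4 = 2.0 * np.pi * 15.915, 2.0 * np.pi * 15.915, 0.64
    h_band = (s**2 / (s**2 + np.sqrt(2.0) * w1 * s + w1**2)) * (
        w2**2 / (s**2 + np.sqrt(2.0) * w2 * s + w2**2)
    )
    h_trans = (s + w3) * w4**2 / ((s**2 + w4 * s / q4 + w4**2) * w3)
    return np.abs(h_band * h_trans)


@dataclass(frozen=True)
class WeightingVector:
    """Per-band weighting factors tied to a grid.

    ``mode`` is one of ``iso_wh`` (analog-filter magnitude evaluated at exact
    band centers), ``table`` (the standard's published per-band factors) or
    ``unity`` (all 1.0, i.e. unweighted acceleration).
    """

    grid: BandGrid
    wh: np.ndarray
    mode: str

    def __post_init__(self) -> None:
        wh = np.asarray(self.wh, dtype=float)
        if wh.shape != (len(self.grid),):
            raise ValueError("weight vector length must match grid")
        if np.any(wh <= 0):
            raise ValueError("weighting factors must be strictly positive")
        object.__setattr__(self, "wh", wh)

    @property
    def band_centers(self) -> np.ndarray:
        return self.grid.exact_centers


def wh_weights(grid: BandGrid, mode: str = "iso_wh") -> WeightingVector:
    """Evaluate the hand-arm weighting on a band grid.

    ``unity`` returns all ones (the unweighted-acceleration convention);
    ``iso_wh`` evaluates the filter magnitude at exact band centers; ``table``
    looks up the standard's per-band factors.
    """
    if mode not in _WEIGHTING_MODES:
        raise ValueError(f"unknown weighting mode {mode!r}; expected one of {_WEIGHTING_MODES}")
    if mode == "unity":
        wh = np.ones(len(grid))
    elif mode == "iso_wh":
        wh = wh_filter_magnitude(grid.exact_centers)
    else:
        missing = [n for n in grid.band_index if n not in WH_TABLE]
        if missing:
            labels = ", ".join(f"{_nominal_label(n):g}" for n in missing)
            raise ValueError(f"no tabulated Wh factor for band(s) {labels} Hz")
        wh = np.array([WH_TABLE[n] for n in grid.band_index])
    return WeightingVector(grid=grid, wh=wh, mode=mode)


def weighted_band_rms(values, weights: WeightingVector) -> float:
    """Root-sum-square of weighted per-band RMS accelerations.

    ``sqrt(sum_i (w_i * a_i)**2)`` -- the band-domain realization of the
    frequency-weighted RMS acceleration.
    """
    a = np.asarray(values, dtype=float)
    if a.shape != (len(weights.grid),):
        raise ValueError(
            f"values ({a.shape}) and weighting grid ({len(weights.grid)} bands) mismatch"
        )
    if np.any(a < 0):
        raise ValueError("band accelerations must be non-negative")
    return float(np.sqrt(np.sum((weights.wh * a) ** 2)))


def vector_total(components) -> float:
    """Vector sum (root-sum-square) of orthogonal-axis RMS accelerations."""
    c = np.asarray(components, dtype=float)
    if np.any(c < 0):
        raise ValueError("axis components must be non-negative")
    return float(np.sqrt(np.sum(c**2)))
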