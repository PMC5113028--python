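"""Glove-finger transmissibility spectra: ratios, direction combining, averaging.

The laboratory measurement drives a handle with broadband vibration in three
orthogonal directions while a scanning laser vibrometer records the response
at points on the dorsal fingers -- with the bare hand and through each glove.
From those point spectra this module computes

* the finger transmissibility ``T = a_response / a_excitation`` per direction,
* the glove transmissibility ``T_glove = T_gloved / T_bare``,
* the combined compression transmissibility
  ``T_xz = sqrt((T_x**2 + T_z**2)/2)`` (the finger x/z orientation is not
  reproducible across handle geometries, the x-z vector sum is),
* the total transmissibility ``T_xyz = sqrt((T_x**2 + T_y**2 + T_z**2)/3)``,

and aggregates them point -> area (fingertip, proximal) -> full finger ->
subject mean.  Measured spectra cover 16-500 Hz; the 6.3-12.5 Hz bands are
filled by interpolating from unity at 6.3 Hz to the measured 16 Hz value,
since glove transmissibility at such low frequencies is essentially 1.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .bands import BandGrid, make_band_grid

__all__ = [
    "BARE_HAND",
    "PointMeasurement",
    "TransmissibilitySpectrum",
    "finger_transmissibility",
    "glove_transmissibility",
    "combine_xz",
    "combine_xyz",
    "average_spectra",
    "extend_low_frequency",
    "truncate_to",
    "select_force_condition",
    "read_point_measurements",
    "write_point_measurements",
    "read_spectra",
    "write_spectra",
]

#: Sentinel glove id for bare-hand records.
BARE_HAND = "bare"

_DIRECTIONS = ("x", "y", "z")
_COMBINED = ("xz", "xyz")
_LOCATIONS = ("fingertip", "proximal", "full")
_AREA_LOCATION = {1: "fingertip", 2: "proximal"}
_AREA_MAX_POINTS = {1: 4, 2: 6}


@dataclass(frozen=True)
class PointMeasurement:
    """One laser-vibrometer point spectrum with its handle excitation spectrum.

    ``area`` 1 is the distal fingertip region (up to 4 points per hand),
    area 2 the proximal region (up to 6 points).  ``glove_id`` may be the
    bare-hand sentinel.  Accelerations are RMS per band, m/s^2.
    """

    subject_id: str
    glove_id: str
    finger: str
    area: int
    point_id: str
    grip_n: float
    push_n: float
    direction: str
    grid: BandGrid
    response: np.ndarray
    excitation: np.ndarray

    def __post_init__(self) -> None:
        if self.direction not in _DIRECTIONS:
            raise ValueError(f"direction must be one of {_DIRECTIONS}, got {self.direction!r}")
        if self.area not in _AREA_LOCATION:
            raise ValueError(f"area must be 1 (fingertip) or 2 (proximal), got {self.area!r}")
        resp = np.asarray(self.response, dtype=float)
        exc = np.asarray(self.excitation, dtype=float)
        if resp.shape != (len(self.grid),) or exc.shape != (len(self.grid),):
            raise ValueError("response and excitation must match the band grid")
        if np.any(resp < 0):
            raise ValueError("response spectrum must be non-negative")
        object.__setattr__(self, "response", resp)
        object.__setattr__(self, "excitation", exc)

    @property
    def location(self) -> str:
        return _AREA_LOCATION[self.area]


@dataclass(frozen=True)
class TransmissibilitySpectrum:
    """Dimensionless per-band transmissibility tagged by glove/location/direction."""

    glove_id: str
    location: str
    direction: str
    grid: BandGrid
    values: np.ndarray
    provenance: str = "measured-synthesized"

    def __post_init__(self) -> None:
        if self.direction not in _DIRECTIONS + _COMBINED:
            raise ValueError(f"unknown direction tag {self.direction!r}")
        if self.location not in _LOCATIONS:
            raise ValueError(f"unknown location tag {self.location!r}")
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.grid),):
            raise ValueError("values must match the band grid")
        if np.any(v <= 0) or not np.all(np.isfinite(v)):
            raise ValueError("transmissibility values must be finite and > 0")
        object.__setattr__(self, "values", v)

    def value_at(self, f_nominal: float) -> float:
        return float(self.values[self.grid.index_of(f_nominal)])


def _check_same_grid(a, b, what: str) -> None:
    if a.grid != b.grid:
        raise ValueError(f"{what}: band grids differ")


def finger_transmissibility(m: PointMeasurement) -> TransmissibilitySpectrum:
    """Per-band ratio of finger response to handle excitation (one direction)."""
    if np.any(m.excitation <= 0):
        bad = np.asarray(m.grid.nominal_centers)[np.asarray(m.excitation) <= 0]
        raise ValueError(
            f"excitation is zero/negative in band(s) {', '.join(f'{f:g}' for f in bad)} Hz"
        )
    return TransmissibilitySpectrum(
        glove_id=m.glove_id,
        location=m.location,
        direction=m.direction,
        grid=m.grid,
        values=m.response / m.excitation,
    )


def glove_transmissibility(
    gloved: TransmissibilitySpectrum, bare: TransmissibilitySpectrum
) -> TransmissibilitySpectrum:
    """Glove transmissibility: gloved-finger over bare-finger ratio per band."""
    _check_same_grid(gloved, bare, "glove_transmissibility")
    if gloved.direction != bare.direction:
        raise ValueError(
            f"direction mismatch: gloved {gloved.direction!r} vs bare {bare.direction!r}"
        )
    if gloved.location != bare.location:
        raise ValueError(
            f"location mismatch: gloved {gloved.location!r} vs bare {bare.location!r}"
        )
    return replace(gloved, values=gloved.values / bare.values)


def combine_xz(
    tx: TransmissibilitySpectrum, tz: TransmissibilitySpectrum
) -> TransmissibilitySpectrum:
    """Combined compression transmissibility sqrt((Tx^2 + Tz^2)/2), tag ``xz``."""
    _check_same_grid(tx, tz, "combine_xz")
    if (tx.direction, tz.direction) != ("x", "z"):
        raise ValueError(f"expected directions (x, z), got ({tx.direction}, {tz.direction})")
    if tx.glove_id != tz.glove_id or tx.location != tz.location:
        raise ValueError("combine_xz: glove/location tags differ")
    return replace(tx, direction="xz", values=np.sqrt((tx.values**2 + tz.values**2) / 2.0))


def combine_xyz(
    tx: TransmissibilitySpectrum,
    ty: TransmissibilitySpectrum,
    tz: TransmissibilitySpectrum,
) -> TransmissibilitySpectrum:
    """Total transmissibility sqrt((Tx^2 + Ty^2 + Tz^2)/3), tag ``xyz``."""
    _check_same_grid(tx, ty, "combine_xyz")
    _check_same_grid(tx, tz, "combine_xyz")
    if (tx.direction, ty.direction, tz.direction) != ("x", "y", "z"):
        raise ValueError(
            f"expected directions (x, y, z), got "
            f"({tx.direction}, {ty.direction}, {tz.direction})"
        )
    if len({tx.glove_id, ty.glove_id, tz.glove_id}) != 1 or len(
        {tx.location, ty.location, tz.location}
    ) != 1:
        raise ValueError("combine_xyz: glove/location tags differ")
    vals = np.sqrt((tx.values**2 + ty.values**2 + tz.values**2) / 3.0)
    return replace(tx, direction="xyz", values=vals)


def average_spectra(
    spectra: list[TransmissibilitySpectrum], level: str = "points"
) -> TransmissibilitySpectrum:
    """Arithmetic per-band mean of transmissibility spectra.

    ``level='points'`` averages point spectra within one area, ``'subjects'``
    averages per-subject spectra; both require homogeneous tags.
    ``level='areas'`` takes exactly one fingertip and one proximal spectrum and
    tags the result ``full``.
    """
    if level not in ("points", "areas", "subjects"):
        raise ValueError(f"unknown averaging level {level!r}")
    if not spectra:
        raise ValueError("cannot average an empty list of spectra")
    first = spectra[0]
    for s in spectra[1:]:
        _check_same_grid(first, s, "average_spectra")
        if s.glove_id != first.glove_id or s.direction != first.direction:
            raise ValueError("average_spectra: glove/direction tags differ")
    if level == "areas":
        locs = sorted(s.location for s in spectra)
        if locs != ["fingertip", "proximal"]:
            raise ValueError(
                "level='areas' requires exactly one fingertip and one proximal spectrum"
            )
        location = "full"
    else:
        if len({s.location for s in spectra}) != 1:
            raise ValueError(f"level={level!r}: location tags differ")
        location = first.location
    mean = np.mean([s.values for s in spectra], axis=0)
    return replace(first, location=location, values=mean)


def extend_low_frequency(
    t: TransmissibilitySpectrum,
    target_grid: BandGrid | None = None,
    abscissa: str = "log",
) -> TransmissibilitySpectrum:
    """Fill 6.3-12.5 Hz bands by interpolating from unity at 6.3 Hz.

    The measurement covers only >=16 Hz; below that the glove moves with the
    finger and transmissibility is ~1.  Values on the extension bands run from
    exactly 1.0 at 6.3 Hz to the measured value at 16 Hz.  ``abscissa='log'``
    (default) interpolates linearly in log-frequency, i.e. equal increments per
    band index; ``'hz'`` interpolates linearly in frequency.
    """
    if abscissa not in ("log", "hz"):
        raise ValueError(f"unknown interpolation abscissa {abscissa!r}")
    if t.grid.band_index[0] < 12:  # 16 Hz is band index 12
        raise ValueError("spectrum already contains bands below 16 Hz")
    if t.grid.band_index[0] != 12:
        raise ValueError("low-frequency extension requires the spectrum to start at 16 Hz")
    if target_grid is None:
        target_grid = make_band_grid(6.3, t.grid.nominal_centers[-1])
    if target_grid.band_index[0] != 8 or target_grid.band_index[-1] != t.grid.band_index[-1]:
        raise ValueError("target grid must span 6.3 Hz to the spectrum's top band")
    ext = make_band_grid(6.3, 16.0)
    t16 = float(t.values[0])
    if abscissa == "log":
        x = np.arange(len(ext), dtype=float) / (len(ext) - 1)
    else:
        f = ext.exact_centers
        x = (f - f[0]) / (f[-1] - f[0])
    ext_vals = 1.0 + x * (t16 - 1.0)
    values = np.concatenate([ext_vals[:-1], t.values])
    return replace(t, grid=target_grid, values=values)


def truncate_to(
    t: TransmissibilitySpectrum, fmin_nominal: float = 6.3, fmax_nominal: float = 500.0
) -> TransmissibilitySpectrum:
    """Restrict a spectrum to a nominal band range (default 6.3-500 Hz)."""
    mask = t.grid.restrict_mask(fmin_nominal, fmax_nominal)
    return replace(t, grid=t.grid.subgrid(fmin_nominal, fmax_nominal), values=t.values[mask])


def select_force_condition(
    pool: list[PointMeasurement], grip_n: float = 30.0, push_n: float = 50.0
) -> list[PointMeasurement]:
    """Keep measurements at one hand-force condition (default 30 N grip + 50 N push).

    The moderate grip-plus-push condition is the one used for glove evaluation;
    spectra from other hand forces are similar except for the lightest grip.
    """
    conditions = sorted({(m.grip_n, m.push_n) for m in pool})
    if (grip_n, push_n) not in conditions:
        avail = ", ".join(f"(grip={g:g} N, push={p:g} N)" for g, p in conditions)
        raise ValueError(
            f"no measurements at grip={grip_n:g} N, push={push_n:g} N; available: {avail}"
        )
    return [m for m in pool if (m.grip_n, m.push_n) == (grip_n, push_n)]


# ---------------------------------------------------------------------------
# delimited-text I/O

_POINT_COLUMNS = [
    "subject", "glove", "finger", "area", "point", "grip_n", "push_n",
    "direction", "freq_hz", "response_ms2", "excitation_ms2",
]


def write_point_measurements(measurements: list[PointMeasurement], path) -> None:
    rows = []
    for m in measurements:
        for f, r, e in zip(m.grid.nominal_centers, m.response, m.excitation):
            rows.append(
                (m.subject_id, m.glove_id, m.finger, m.area, m.point_id,
                 m.grip_n, m.push_n, m.direction, f, r, e)
            )
    pd.DataFrame(rows, columns=_POINT_COLUMNS).to_csv(path, index=False)


def read_point_measurements(path) -> list[PointMeasurement]:
    df = pd.read_csv(path)
    missing = set(_POINT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"point-measurement file missing columns: {sorted(missing)}")
    out: list[PointMeasurement] = []
    keys = ["subject", "glove", "finger", "area", "point", "grip_n", "push_n", "direction"]
    for key, g in df.groupby(keys, sort=True):
        g = g.sort_values("freq_hz")
        grid = make_band_grid(g["freq_hz"].iloc[0], g["freq_hz"].iloc[-1])
        if len(grid) != len(g):
            raise ValueError(f"non-contiguous band set for record {key}")
        out.append(
            PointMeasurement(
                subject_id=str(key[0]), glove_id=str(key[1]), finger=str(key[2]),
                area=int(key[3]), point_id=str(key[4]), grip_n=float(key[5]),
                push_n=float(key[6]), direction=str(key[7]), grid=grid,
                response=g["response_ms2"].to_numpy(),
                excitation=g["excitation_ms2"].to_numpy(),
            )
        )
    return out


def write_spectra(spectra: list[TransmissibilitySpectrum], path) -> None:
    rows = [
        (s.glove_id, s.location, s.direction, f, v)
        for s in spectra
        for f, v in zip(s.grid.nominal_centers, s.values)
    ]
    pd.DataFrame(rows, columns=["glove", "location", "direction", "freq_hz", "value"]).to_csv(
        path, index=False
    )


def read_spectra(path) -> list[TransmissibilitySpectrum]:
    df = pd.read_csv(path)
    out = []
    for (glove, loc, direction), g in df.groupby(["glove", "location", "direction"], sort=True):
        g = g.sort_values("freq_hz")
        grid = make_band_grid(g["freq_hz"].iloc[0], g["freq_hz"].iloc[-1])
        if len(grid) != len(g):
            raise ValueError(f"non-contiguous band set for spectrum {(glove, loc, direction)}")
        out.append(
            TransmissibilitySpectrum(
                glove_id=str(glove), location=str(loc), direction=str(direction),
                grid=grid, values=g["value"].to_numpy(), provenance="fixture",
            )
        )
    return out
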