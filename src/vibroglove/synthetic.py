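"""Synthetic glove point-measurements and tool spectra.

No measured glove-finger spectra or tool spectra are deposited with the study
this package operationalizes, so the generator emulates their structure: glove
transmissibility follows a base-excitation single-resonance magnitude

    T(f) = sqrt( (1 + (2 zeta r)^2) / ((1 - r^2)^2 + (2 zeta r)^2) ),  r = f/f_n

per direction and finger region (optionally with a second mode), multiplied by
lognormal measurement noise across points and subjects.  Tool spectra are
triangular envelopes in log-frequency around a dominant band, with the energy
split between the shear axis and the two compression axes and the unweighted
total normalized exactly to a requested magnitude.

The presets in :func:`scenario_suite` are qualitative archetypes of the four
glove constructions (gel, air bladder, air bubble, neoprene) and of
low-frequency, impact, high-frequency and shear-dominant tools; their peak
magnitudes are illustrative, not calibrated to any measured curve.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .bands import BandGrid, make_band_grid
from .tools import ToolSpectrum, summarize
from .transmissibility import BARE_HAND, PointMeasurement

__all__ = [
    "ResonanceParams",
    "GlovePreset",
    "ToolPreset",
    "sdof_transmissibility",
    "glove_model_curve",
    "generate_glove_measurements",
    "generate_tool_spectrum",
    "scenario_suite",
]

_DIRECTIONS = ("x", "y", "z")
_AREAS = (1, 2)
_AREA_LOCATION = {1: "fingertip", 2: "proximal"}


def sdof_transmissibility(freq_hz, f_n: float, zeta: float) -> np.ndarray:
    """Base-excitation single-resonance transmissibility magnitude."""
    r = np.asarray(freq_hz, dtype=float) / f_n
    num = 1.0 + (2.0 * zeta * r) ** 2
    den = (1.0 - r**2) ** 2 + (2.0 * zeta * r) ** 2
    return np.sqrt(num / den)


@dataclass(frozen=True)
class ResonanceParams:
    """Modal parameters for one direction x location of a glove preset.

    ``secondary`` is an optional ``(f_n2, zeta2, amplitude)`` second mode added
    as an amplitude-scaled deviation from unity, so the low-frequency limit
    stays 1.  ``plateau`` floors the curve (high-frequency residual
    transmission); the default 0 leaves the pure single-resonance form.
    """

    f_n: float
    zeta: float
    plateau: float = 0.0
    secondary: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        if not 16.0 <= self.f_n <= 500.0:
            raise ValueError(f"resonance frequency {self.f_n} Hz outside 16-500 Hz")
        if not 0.0 < self.zeta <= 2.0:
            raise ValueError(f"damping ratio {self.zeta} outside (0, 2]")
        if self.plateau < 0:
            raise ValueError("plateau must be >= 0")
        if self.secondary is not None:
            f2, z2, amp = self.secondary
            if not 16.0 <= f2 <= 500.0 or not 0.0 < z2 <= 2.0 or amp < 0:
                raise ValueError("invalid secondary mode parameters")


def glove_model_curve(freq_hz, params: ResonanceParams) -> np.ndarray:
    """Noiseless glove transmissibility model curve at given frequencies."""
    t = sdof_transmissibility(freq_hz, params.f_n, params.zeta)
    if params.secondary is not None:
        f2, z2, amp = params.secondary
        t = t + amp * (sdof_transmissibility(freq_hz, f2, z2) - 1.0)
    return np.maximum(t, params.plateau)


@dataclass(frozen=True)
class GlovePreset:
    """Generator parameters for one glove's point measurements.

    ``modes`` maps ``(direction, location)`` with direction in x/y/z and
    location in fingertip/proximal to :class:`ResonanceParams`.
    ``noise_sigma`` is the log-scale standard deviation of the multiplicative
    measurement noise applied independently per point, subject and band.
    """

    glove_id: str
    modes: dict[tuple[str, str], ResonanceParams]
    noise_sigma: float = 0.05
    n_subjects: int = 6
    n_points: dict[int, int] = field(default_factory=lambda: {1: 4, 2: 6})

    def __post_init__(self) -> None:
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.n_subjects < 1:
            raise ValueError("need at least one subject")
        for area, npts in self.n_points.items():
            limit = {1: 4, 2: 6}[area]
            if not 1 <= npts <= limit:
                raise ValueError(f"area {area} supports 1-{limit} points, got {npts}")
        for (direction, location) in self.modes:
            if direction not in _DIRECTIONS or location not in ("fingertip", "proximal"):
                raise ValueError(f"bad mode key {(direction, location)!r}")
        for d in _DIRECTIONS:
            for loc in ("fingertip", "proximal"):
                if (d, loc) not in self.modes:
                    raise ValueError(f"preset missing modal parameters for {(d, loc)}")


#: Flat per-direction excitation: overall RMS of the broadband drive, m/s^2.
EXCITATION_RMS_TOTAL = 19.6


def generate_glove_measurements(
    preset: GlovePreset,
    seed: int,
    grid: BandGrid | None = None,
    include_bare: bool = True,
    force_conditions: tuple[tuple[float, float], ...] = ((30.0, 50.0),),
) -> list[PointMeasurement]:
    """Simulate the laboratory point measurements for one glove.

    For every subject x area x point x direction (x force condition) the
    excitation is flat across the measured 16-500 Hz bands at a total RMS of
    19.6 m/s^2, and the response equals excitation x model transmissibility x
    ``exp(N(0, noise_sigma))`` per band.  Bare-hand records (model curve 1)
    are emitted alongside so the full ratio pipeline can run.  Deterministic
    given ``seed``.
    """
    if grid is None:
        grid = make_band_grid(16.0, 500.0)
    rng = np.random.default_rng(seed)
    f = grid.exact_centers
    exc = np.full(len(grid), EXCITATION_RMS_TOTAL / np.sqrt(len(grid)))
    out: list[PointMeasurement] = []
    for subj in range(1, preset.n_subjects + 1):
        for area in _AREAS:
            for pt in range(1, preset.n_points.get(area, 0) + 1):
                finger = "index" if pt % 2 == 1 else "middle"
                for direction in _DIRECTIONS:
                    curve = glove_model_curve(f, preset.modes[(direction, _AREA_LOCATION[area])])
                    for grip_n, push_n in force_conditions:
                        common = dict(
                            subject_id=f"S{subj}", finger=finger, area=area,
                            point_id=f"P{pt}", grip_n=grip_n, push_n=push_n,
                            direction=direction, grid=grid, excitation=exc,
                        )
                        noise_g = np.exp(rng.normal(0.0, preset.noise_sigma, len(grid)))
                        out.append(
                            PointMeasurement(
                                glove_id=preset.glove_id,
                                response=exc * curve * noise_g, **common,
                            )
                        )
                        if include_bare:
                            noise_b = np.exp(rng.normal(0.0, preset.noise_sigma, len(grid)))
                            out.append(
                                PointMeasurement(
                                    glove_id=BARE_HAND, response=exc * noise_b, **common,
                                )
                            )
    return out


@dataclass(frozen=True)
class ToolPreset:
    """Generator parameters for one synthetic tool spectrum.

    ``shear_fraction`` is the fraction of total vibration energy on the shear
    (y) axis; the remainder splits equally over x and z.  ``bandwidth_bands``
    is the half-width of the triangular log-frequency envelope in band steps.
    ``harmonics`` adds scaled envelope copies at further bands.
    ``ripple_sigma`` (log-scale) perturbs the envelope shape; the normalized
    total is exact regardless.
    """

    tool_id: str
    dominant_band_hz: float
    bandwidth_bands: int = 2
    total_unweighted_magnitude: float = 10.0
    shear_fraction: float = 1.0 / 3.0
    harmonics: tuple[tuple[float, float], ...] = ()
    ripple_sigma: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.shear_fraction <= 1.0:
            raise ValueError("shear_fraction must lie in [0, 1]")
        if self.total_unweighted_magnitude < 0:
            raise ValueError("total magnitude must be >= 0")
        if self.bandwidth_bands < 0:
            raise ValueError("bandwidth must be >= 0 bands")
        if self.ripple_sigma < 0:
            raise ValueError("ripple_sigma must be >= 0")


def generate_tool_spectrum(
    preset: ToolPreset, seed: int = 0, grid: BandGrid | None = None
) -> ToolSpectrum:
    """Synthesize a tri-axial tool spectrum from a preset.

    The per-band amplitude envelope is triangular in band index around the
    dominant band; the spectrum is scaled so the unweighted total acceleration
    over 6.3-500 Hz equals ``total_unweighted_magnitude`` exactly.
    Deterministic given ``seed``.
    """
    if grid is None:
        grid = make_band_grid(6.3, 1250.0)
    try:
        n0 = grid.band_index[grid.index_of(preset.dominant_band_hz)]
    except KeyError as exc:
        raise ValueError(
            f"dominant band {preset.dominant_band_hz:g} Hz outside the tool grid"
        ) from exc
    rng = np.random.default_rng(seed)
    n = np.array(grid.band_index, dtype=float)

    def envelope(center_n: float, amp: float) -> np.ndarray:
        d = np.abs(n - center_n)
        return amp * np.maximum(0.0, 1.0 - d / (preset.bandwidth_bands + 1.0))

    env = envelope(float(n0), 1.0)
    for f_h, amp in preset.harmonics:
        env = env + envelope(float(grid.band_index[grid.index_of(f_h)]), amp)
    if preset.ripple_sigma > 0:
        env = env * np.exp(rng.normal(0.0, preset.ripple_sigma, len(grid)))
    fy = preset.shear_fraction
    ay = np.sqrt(fy) * env
    ax = az = np.sqrt((1.0 - fy) / 2.0) * env
    tool = ToolSpectrum(tool_id=preset.tool_id, grid=grid, ax=ax, ay=ay, az=az,
                        source_citation="synthetic preset")
    total = summarize(tool).at
    if total == 0.0:
        raise ValueError("preset produced a zero spectrum in the 6.3-500 Hz range")
    scale = preset.total_unweighted_magnitude / total
    return ToolSpectrum(
        tool_id=preset.tool_id, grid=grid,
        ax=ax * scale, ay=ay * scale, az=az * scale,
        source_citation="synthetic preset",
    )


def scenario_suite() -> dict[str, dict[str, object]]:
    """Named glove and tool presets spanning the qualitative archetypes.

    Glove archetypes: gel-like (broad compression amplification, twin shear
    peaks), bladder-like (strong 400 Hz fingertip shear resonance near twice
    the input), bubble-like (low-ish fingertip compression peak, declining
    above), neoprene-like (sharp 100 Hz compression resonance, attenuation
    above).  All preset resonances sit at or above 80 Hz so spectra stay near
    unity below 25 Hz.  Tool archetypes: low-frequency (<25 Hz dominant),
    impact (broad mid-band), high-frequency compression, and shear-dominant
    at 80 Hz.
    """
    R = ResonanceParams

    def glove(glove_id, tip_xz, tip_y, prox_xz, prox_y, **kw):
        modes = {}
        for d in ("x", "z"):
            modes[(d, "fingertip")] = tip_xz
            modes[(d, "proximal")] = prox_xz
        modes[("y", "fingertip")] = tip_y
        modes[("y", "proximal")] = prox_y
        return GlovePreset(glove_id=glove_id, modes=modes, **kw)

    gloves = {
        "gel-like": glove(
            "gel-like",
            tip_xz=R(315.0, 0.60),
            tip_y=R(100.0, 0.30, secondary=(400.0, 0.30, 0.5)),
            prox_xz=R(160.0, 0.50),
            prox_y=R(125.0, 0.50),
        ),
        "bladder-like": glove(
            "bladder-like",
            tip_xz=R(400.0, 0.70),
            tip_y=R(400.0, 0.26),  # peak ~2x input
            prox_xz=R(125.0, 0.50),
            prox_y=R(200.0, 0.70),
        ),
        "bubble-like": glove(
            "bubble-like",
            tip_xz=R(80.0, 0.50),
            tip_y=R(125.0, 0.40, secondary=(400.0, 0.35, 0.4)),
            prox_xz=R(160.0, 0.60),
            prox_y=R(200.0, 0.80),
        ),
        "neoprene-like": glove(
            "neoprene-like",
            tip_xz=R(100.0, 0.30),
            tip_y=R(100.0, 0.35),
            prox_xz=R(125.0, 0.45),
            prox_y=R(100.0, 0.50),
        ),
    }
    tools = {
        "lowfreq16": ToolPreset("lowfreq16", dominant_band_hz=16.0, bandwidth_bands=2,
                                total_unweighted_magnitude=25.0, shear_fraction=0.3),
        "impact63": ToolPreset("impact63", dominant_band_hz=63.0, bandwidth_bands=4,
                               total_unweighted_magnitude=80.0, shear_fraction=0.25,
                               harmonics=((250.0, 0.4),)),
        "highfreq400": ToolPreset("highfreq400", dominant_band_hz=400.0, bandwidth_bands=2,
                                  total_unweighted_magnitude=40.0, shear_fraction=0.1),
        "shear80": ToolPreset("shear80", dominant_band_hz=80.0, bandwidth_bands=2,
                              total_unweighted_magnitude=15.0, shear_fraction=0.8),
    }
    return {"gloves": gloves, "tools": tools}
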