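"""Tri-axial tool vibration spectra in one-third octave bands.

Tool spectra come from workplace or laboratory measurements reported in the
literature as per-band RMS accelerations in three orthogonal directions.  The
axis convention is fixed at ingest: ``y`` is the shear direction along the
handle/finger axis, ``x`` and ``z`` are the compression directions.  Spectra
that do not cover the full 6.3-1,250 Hz range are zero-filled on the missing
bands; all summaries are root-sum-square, optionally frequency weighted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .bands import BandGrid, WeightingVector, make_band_grid, weighted_band_rms, wh_weights

__all__ = [
    "ToolSpectrum",
    "ToolSummary",
    "read_tool_spectra",
    "write_tool_spectra",
    "zero_fill",
    "summarize",
]

TOOL_COLUMNS = ["tool", "freq_hz", "ax_ms2", "ay_ms2", "az_ms2"]


@dataclass(frozen=True)
class ToolSpectrum:
    """Tri-axial per-band RMS accelerations (m/s^2) for one tool or process."""

    tool_id: str
    grid: BandGrid
    ax: np.ndarray
    ay: np.ndarray
    az: np.ndarray
    display_name: str = ""
    shear_axis_note: str = "y = axial shear along the handle/finger axis"
    source_citation: str = ""

    def __post_init__(self) -> None:
        arrs = {}
        for name in ("ax", "ay", "az"):
            a = np.asarray(getattr(self, name), dtype=float)
            if a.shape != (len(self.grid),):
                raise ValueError(f"{name} must have one value per band")
            if np.any(a < 0) or not np.all(np.isfinite(a)):
                raise ValueError(f"{name} must be finite and non-negative")
            arrs[name] = a
        if not any(np.any(a > 0) for a in arrs.values()):
            raise ValueError(f"tool {self.tool_id!r}: all bands are zero on every axis")
        for name, a in arrs.items():
            object.__setattr__(self, name, a)

    @property
    def name(self) -> str:
        return self.display_name or self.tool_id


@dataclass(frozen=True)
class ToolSummary:
    """Scalar acceleration summary: shear (Ay), compression (Axz), total (At)."""

    mode: str  # "unweighted" or "weighted"
    ay: float
    axz: float
    at: float


def zero_fill(t: ToolSpectrum, grid: BandGrid) -> ToolSpectrum:
    """Embed a spectrum in a wider grid, taking missing bands as zero."""
    present = set(t.grid.band_index)
    target = set(grid.band_index)
    if not present <= target:
        extra = sorted(present - target)
        raise ValueError(f"tool {t.tool_id!r} has bands outside the target grid: {extra}")
    idx = [grid.band_index.index(n) for n in t.grid.band_index]
    out = {}
    for name in ("ax", "ay", "az"):
        a = np.zeros(len(grid))
        a[idx] = getattr(t, name)
        out[name] = a
    return replace(t, grid=grid, **out)


def summarize(
    t: ToolSpectrum,
    weights: WeightingVector | None = None,
    fmin_nominal: float = 6.3,
    fmax_nominal: float = 500.0,
) -> ToolSummary:
    """Band-range RMS summary of a tool spectrum.

    ``Ay`` is the (optionally weighted) RMS of the shear axis, ``Axz`` the
    vector sum of the two compression axes, ``At = sqrt(Ay^2 + Axz^2)`` the
    total.  The default band range 6.3-500 Hz matches the range over which
    glove transmissibility spectra are available.
    """
    mask = t.grid.restrict_mask(fmin_nominal, fmax_nominal)
    sub = t.grid.subgrid(fmin_nominal, fmax_nominal)
    if weights is None:
        weights = wh_weights(sub, "unity")
    if weights.grid != sub:
        raise ValueError("weighting vector must be defined on the restricted band range")
    a_y = weighted_band_rms(t.ay[mask], weights)
    a_x = weighted_band_rms(t.ax[mask], weights)
    a_z = weighted_band_rms(t.az[mask], weights)
    a_xz = float(np.hypot(a_x, a_z))
    mode = "unweighted" if weights.mode == "unity" else "weighted"
    return ToolSummary(mode=mode, ay=a_y, axz=a_xz, at=float(np.hypot(a_y, a_xz)))


def write_tool_spectra(tools: list[ToolSpectrum], path) -> None:
    rows = [
        (t.tool_id, f, x, y, z)
        for t in tools
        for f, x, y, z in zip(t.grid.nominal_centers, t.ax, t.ay, t.az)
    ]
    pd.DataFrame(rows, columns=TOOL_COLUMNS).to_csv(path, index=False)


def read_tool_spectra(path, policy: str = "strict") -> list[ToolSpectrum]:
    """Read tool spectra from delimited text.

    Expected header ``tool,freq_hz,ax_ms2,ay_ms2,az_ms2`` with nominal band
    labels in ``freq_hz``.  ``policy='strict'`` rejects tools with an all-zero
    axis; ``'lenient'`` warns instead (several literature spectra genuinely
    lack high-frequency content on one axis).
    """
    if policy not in ("strict", "lenient"):
        raise ValueError(f"unknown validation policy {policy!r}")
    df = pd.read_csv(path)
    missing = set(TOOL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"tool-spectra file missing columns: {sorted(missing)}")
    for col in ("ax_ms2", "ay_ms2", "az_ms2"):
        if df[col].isna().any():
            bad = df.loc[df[col].isna(), "tool"].unique()
            raise ValueError(f"missing {col} values for tool(s): {', '.join(map(str, bad))}")
        if (df[col] < 0).any():
            bad = df.loc[df[col] < 0, "tool"].unique()
            raise ValueError(f"negative {col} values for tool(s): {', '.join(map(str, bad))}")
    out = []
    for tool, g in df.groupby("tool", sort=True):
        g = g.sort_values("freq_hz")
        grid = make_band_grid(g["freq_hz"].iloc[0], g["freq_hz"].iloc[-1])
        if len(grid) != len(g):
            raise ValueError(f"tool {tool!r}: non-contiguous or duplicated bands")
        for axis, col in (("x", "ax_ms2"), ("y", "ay_ms2"), ("z", "az_ms2")):
            if not (g[col] > 0).any():
                msg = f"tool {tool!r}: axis {axis} is all zero"
                if policy == "strict":
                    raise ValueError(msg)
                warnings.warn(msg, stacklevel=2)
        out.append(
            ToolSpectrum(
                tool_id=str(tool), grid=grid,
                ax=g["ax_ms2"].to_numpy(), ay=g["ay_ms2"].to_numpy(),
                az=g["az_ms2"].to_numpy(),
            )
        )
    return out
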