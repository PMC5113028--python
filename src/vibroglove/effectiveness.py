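"""Tool-specific glove effectiveness: transmissibility values, percent reduction.

A glove's per-band transmissibility spectrum says nothing by itself about how
well the glove works on a particular tool -- that depends on where the tool's
vibration energy sits in frequency.  The transfer-function assessment collapses
the spectra into tool-specific scalars by energy-weighting the glove
transmissibility with the tool spectrum (and optionally the hand-arm frequency
weighting Wh):

    T_y   = sqrt( sum_i [T_y(w_i) a_y(w_i) Wh(w_i)]^2 / sum_i [a_y(w_i) Wh(w_i)]^2 )
    T_xz  = sqrt( sum_i T_xz(w_i)^2 [a_x^2 + a_z^2](w_i) Wh(w_i)^2
                  / sum_i [a_x^2 + a_z^2](w_i) Wh(w_i)^2 )
    T_xzy = sqrt( sum_i {T_xz^2 [a_x^2+a_z^2] + T_y^2 a_y^2}(w_i) Wh(w_i)^2
                  / sum_i [a_x^2 + a_y^2 + a_z^2](w_i) Wh(w_i)^2 )

with unity Wh for the unweighted variant.  The percent reduction is
``R = (1 - T_xzy) * 100``: positive means the glove attenuates the tool's
vibration at the fingers, negative means it amplifies it.  Glove-tool matches
are classified by comparing R to a threshold (10% by convention).
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bands import WeightingVector
from .tools import ToolSpectrum
from .transmissibility import TransmissibilitySpectrum, average_spectra

__all__ = [
    "EffectivenessResult",
    "MatchReport",
    "tool_specific_values",
    "percent_reduction",
    "reconstruct_total_value",
    "full_finger_result",
    "classify_matches",
    "render_report",
    "round_half_away",
]

RESULT_COLUMNS = ["tool", "glove", "location", "mode", "t_y", "t_xz", "t_xzy", "r_percent"]


@dataclass(frozen=True)
class EffectivenessResult:
    """Tool-specific transmissibility values and percent reduction.

    ``t_y``/``t_xz`` may be NaN when the tool has no energy in that direction
    within the band range; ``t_xzy`` is always defined (total energy > 0).
    """

    glove_id: str
    tool_id: str
    location: str
    mode: str
    t_y: float
    t_xz: float
    t_xzy: float

    @property
    def r_percent(self) -> float:
        return (1.0 - self.t_xzy) * 100.0


def reconstruct_total_value(t_y: float, t_xz: float, a_y: float, a_xz: float) -> float:
    """Total transmissibility value from directional values and magnitudes.

    Algebraic identity of the total-vibration formula:
    ``T_xzy = sqrt((T_y^2 A_y^2 + T_xz^2 A_xz^2) / (A_y^2 + A_xz^2))`` --
    lets published per-direction values be recombined without band spectra.
    """
    if a_y < 0 or a_xz < 0:
        raise ValueError("acceleration magnitudes must be non-negative")
    den = a_y**2 + a_xz**2
    if den == 0:
        raise ValueError("total acceleration is zero")
    return math.sqrt((t_y**2 * a_y**2 + t_xz**2 * a_xz**2) / den)


def round_half_away(x) -> np.ndarray:
    """Round to integer, halves away from zero (report-table convention)."""
    x = np.asarray(x, dtype=float)
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def tool_specific_values(
    t_y: TransmissibilitySpectrum,
    t_xz: TransmissibilitySpectrum,
    tool: ToolSpectrum,
    weights: WeightingVector,
) -> EffectivenessResult:
    """Energy-weighted transmissibility values for one glove-tool pair.

    All inputs must share one band grid (tool spectra are zero-filled and glove
    spectra low-frequency-extended to 6.3-500 Hz beforehand).  A direction with
    zero tool energy yields NaN for its directional value rather than a
    fabricated 1.0; the total value only needs nonzero total energy.
    """
    grid = weights.grid
    for s, what in ((t_y, "shear spectrum"), (t_xz, "compression spectrum")):
        if s.grid != grid:
            raise ValueError(f"{what} grid does not match the weighting grid")
    if tool.grid != grid:
        raise ValueError("tool spectrum grid does not match the weighting grid")
    if t_y.direction != "y" or t_xz.direction != "xz":
        raise ValueError(
            f"expected direction tags (y, xz), got ({t_y.direction}, {t_xz.direction})"
        )
    if t_y.glove_id != t_xz.glove_id or t_y.location != t_xz.location:
        raise ValueError("shear and compression spectra carry different glove/location tags")

    w2 = weights.wh**2
    ey = tool.ay**2 * w2
    exz = (tool.ax**2 + tool.az**2) * w2
    den_y = float(np.sum(ey))
    den_xz = float(np.sum(exz))
    den_t = den_y + den_xz
    if den_t == 0.0:
        raise ValueError(f"tool {tool.tool_id!r} has zero weighted energy in the band range")
    ty_val = math.sqrt(float(np.sum(t_y.values**2 * ey)) / den_y) if den_y > 0 else math.nan
    txz_val = math.sqrt(float(np.sum(t_xz.values**2 * exz)) / den_xz) if den_xz > 0 else math.nan
    num_t = float(np.sum(t_xz.values**2 * exz + t_y.values**2 * ey))
    txzy_val = math.sqrt(num_t / den_t)
    return EffectivenessResult(
        glove_id=t_y.glove_id,
        tool_id=tool.tool_id,
        location=t_y.location,
        mode="unweighted" if weights.mode == "unity" else "weighted",
        t_y=ty_val,
        t_xz=txz_val,
        t_xzy=txzy_val,
    )


def percent_reduction(result: EffectivenessResult) -> float:
    """R = (1 - T_xzy) * 100; positive = reduction, negative = amplification."""
    return result.r_percent


def full_finger_result(
    fingertip: tuple[TransmissibilitySpectrum, TransmissibilitySpectrum],
    proximal: tuple[TransmissibilitySpectrum, TransmissibilitySpectrum],
    tool: ToolSpectrum,
    weights: WeightingVector,
    strategy: str = "spectrum_mean",
) -> EffectivenessResult:
    """Full-finger effectiveness from the fingertip and proximal area inputs.

    ``strategy='spectrum_mean'`` (default) averages the two areas' spectra per
    band and then applies the tool-specific evaluation -- the same order used
    to synthesize the full-finger spectra.  ``'value_mean'`` instead averages
    the two locations' scalar T values.
    """
    if strategy not in ("spectrum_mean", "value_mean"):
        raise ValueError(f"unknown full-finger strategy {strategy!r}")
    tip_y, tip_xz = fingertip
    prox_y, prox_xz = proximal
    if strategy == "spectrum_mean":
        full_y = average_spectra([tip_y, prox_y], level="areas")
        full_xz = average_spectra([tip_xz, prox_xz], level="areas")
        return tool_specific_values(full_y, full_xz, tool, weights)
    r_tip = tool_specific_values(tip_y, tip_xz, tool, weights)
    r_prox = tool_specific_values(prox_y, prox_xz, tool, weights)
    mean = lambda a, b: (a + b) / 2.0  # noqa: E731 - NaN-propagating by design
    return EffectivenessResult(
        glove_id=r_tip.glove_id,
        tool_id=tool.tool_id,
        location="full",
        mode=r_tip.mode,
        t_y=mean(r_tip.t_y, r_prox.t_y),
        t_xz=mean(r_tip.t_xz, r_prox.t_xz),
        t_xzy=mean(r_tip.t_xzy, r_prox.t_xzy),
    )


@dataclass(frozen=True)
class MatchReport:
    """Glove-tool match classification at a percent-reduction threshold.

    Counts per glove of tools classified ``reduced`` (R at/above threshold),
    ``amplified`` (R at/below minus threshold) and ``neutral``; comparison is
    applied to R rounded to integer percent.  ``inclusive=False`` uses strict
    >/< comparison instead of >=/<=.
    """

    threshold: float
    inclusive: bool
    counts: pd.DataFrame = field(repr=False)  # index: glove; reduced/amplified/neutral
    r_table: pd.DataFrame = field(repr=False)  # columns: tool, glove, r_percent
    mean_r: pd.Series = field(repr=False)  # per glove, unrounded

    @property
    def n_tools(self) -> int:
        return self.r_table["tool"].size // max(self.r_table["glove"].nunique(), 1)


def classify_matches(
    results: pd.DataFrame, threshold: float = 10.0, inclusive: bool = True
) -> MatchReport:
    """Classify every glove-tool pair by its percent reduction.

    ``results`` needs columns ``tool``, ``glove``, ``r_percent`` (one mode at a
    time).  R values are rounded to integer percent before comparison, matching
    the precision at which reductions are reported.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    required = {"tool", "glove", "r_percent"}
    if not required <= set(results.columns):
        raise ValueError(f"results table must have columns {sorted(required)}")
    r = results.copy()
    r["r_rounded"] = round_half_away(r["r_percent"].to_numpy())
    if inclusive:
        reduced = r["r_rounded"] >= threshold
        amplified = r["r_rounded"] <= -threshold
    else:
        reduced = r["r_rounded"] > threshold
        amplified = r["r_rounded"] < -threshold
    r["classification"] = np.where(reduced, "reduced", np.where(amplified, "amplified", "neutral"))
    counts = (
        r.groupby("glove")["classification"]
        .value_counts()
        .unstack(fill_value=0)
        .reindex(columns=["reduced", "amplified", "neutral"], fill_value=0)
    )
    mean_r = r.groupby("glove")["r_percent"].mean()
    return MatchReport(
        threshold=float(threshold),
        inclusive=bool(inclusive),
        counts=counts,
        r_table=r[["tool", "glove", "r_percent", "r_rounded", "classification"]],
        mean_r=mean_r,
    )


def render_report(
    report: MatchReport, results: pd.DataFrame, fmt: str = "text"
) -> str:
    """Render a per-tool table plus per-glove summary (counts and mean R).

    Transmissibility values print to 2 decimals and R to integer percent,
    mirroring the precision of published assessment tables.  ``fmt`` is
    ``text``, ``markdown`` or ``csv``.
    """
    if fmt not in ("text", "markdown", "csv"):
        raise ValueError(f"unknown report format {fmt!r}")
    if results.empty or results["glove"].nunique() == 0:
        raise ValueError("no results to report")
    df = results.copy()
    for col in ("t_y", "t_xz", "t_xzy"):
        if col in df.columns:
            df[col] = df[col].map(lambda v: f"{v:.2f}" if np.isfinite(v) else "")
    df["r_percent"] = round_half_away(df["r_percent"].to_numpy()).astype(int)
    df = df.merge(
        report.r_table[["tool", "glove", "classification"]], on=["tool", "glove"], how="left"
    )
    summary = report.counts.copy()
    summary["mean_r_percent"] = report.mean_r.round(1)
    if fmt == "csv":
        buf = io.StringIO()
        df.to_csv(buf, index=False)
        buf.write("\n")
        summary.to_csv(buf)
        return buf.getvalue()
    if fmt == "markdown":
        return (
            df.to_markdown(index=False)
            + "\n\nPer-glove summary (threshold "
            + f"{report.threshold:g}%, {'inclusive' if report.inclusive else 'strict'}):\n\n"
            + summary.to_markdown()
        )
    return (
        df.to_string(index=False)
        + "\n\nPer-glove summary (threshold "
        + f"{report.threshold:g}%, {'inclusive' if report.inclusive else 'strict'}):\n\n"
        + summary.to_string()
    )
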