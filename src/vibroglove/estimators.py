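"""Scikit-learn-style estimators for the glove-assessment pipeline.

:class:`TransmissibilitySynthesizer` fits on laboratory point measurements and
exposes the representative glove transmissibility spectra (per glove, finger
location and direction, including the combined xz and total xyz tags).
:class:`GloveEffectivenessScorer` fits on those spectra and predicts, for a
list of tool spectra, the tool-specific transmissibility values and percent
reductions.  Both follow the sklearn conventions (``get_params``/
``set_params``, fitted attributes with trailing underscores) and compose with
``sklearn.base.clone``.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import replace

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .bands import make_band_grid, wh_weights
from .effectiveness import (
    RESULT_COLUMNS,
    EffectivenessResult,
    MatchReport,
    classify_matches,
    tool_specific_values,
)
from .tools import ToolSpectrum, zero_fill
from .transmissibility import (
    BARE_HAND,
    PointMeasurement,
    TransmissibilitySpectrum,
    average_spectra,
    combine_xyz,
    combine_xz,
    extend_low_frequency,
    finger_transmissibility,
    glove_transmissibility,
    select_force_condition,
    truncate_to,
)

__all__ = ["TransmissibilitySynthesizer", "GloveEffectivenessScorer"]


class TransmissibilitySynthesizer(BaseEstimator):
    """Synthesize representative glove-finger transmissibility spectra.

    The fit replays the study's aggregation order: select one hand-force
    condition, form per-point glove transmissibilities (gloved-finger over
    bare-finger ratio), average points within each area, combine directions
    per subject (x-z compression vector mean, and the three-direction total),
    average the two areas into a full-finger spectrum, then average subjects.
    Finally each spectrum is extended down to 6.3 Hz (unity anchor) and
    truncated at ``fmax_nominal``.

    Parameters
    ----------
    grip_n, push_n : float
        Hand-force condition to select (default 30 N grip + 50 N push).
    extend : bool
        Apply the low-frequency extension below 16 Hz (default True).
    abscissa : {"log", "hz"}
        Interpolation abscissa of the extension.
    fmax_nominal : float
        Upper nominal band for the synthesized spectra (default 500 Hz).

    Attributes
    ----------
    spectra_ : dict[(glove, location, direction), TransmissibilitySpectrum]
        location in {fingertip, proximal, full}; direction in
        {x, y, z, xz, xyz}.
    gloves_ : list of glove ids (bare-hand sentinel excluded).
    n_subjects_ : int
    """

    def __init__(
        self,
        grip_n: float = 30.0,
        push_n: float = 50.0,
        extend: bool = True,
        abscissa: str = "log",
        fmax_nominal: float = 500.0,
    ) -> None:
        self.grip_n = grip_n
        self.push_n = push_n
        self.extend = extend
        self.abscissa = abscissa
        self.fmax_nominal = fmax_nominal

    def fit(self, X: list[PointMeasurement], y=None) -> "TransmissibilitySynthesizer":
        if not X:
            raise ValueError("no point measurements provided")
        pool = select_force_condition(list(X), self.grip_n, self.push_n)
        bare: dict[tuple, PointMeasurement] = {}
        gloved: dict[tuple, PointMeasurement] = {}
        for m in pool:
            key = (m.subject_id, m.finger, m.area, m.point_id, m.direction)
            if m.glove_id == BARE_HAND:
                bare[key] = m
            else:
                gloved[(m.glove_id, *key)] = m
        if not gloved:
            raise ValueError("no gloved measurements in the selected force condition")

        # per (glove, subject, area, direction): point-level glove ratios
        point_ratios: dict[tuple, list[TransmissibilitySpectrum]] = defaultdict(list)
        for (glove, subj, finger, area, point, direction), m in gloved.items():
            bkey = (subj, finger, area, point, direction)
            if bkey not in bare:
                raise ValueError(
                    f"no bare-hand reference for subject {subj}, area {area}, "
                    f"point {point}, direction {direction}"
                )
            tg = finger_transmissibility(m)
            tb = finger_transmissibility(bare[bkey])
            point_ratios[(glove, subj, area, direction)].append(
                glove_transmissibility(tg, tb)
            )

        # area means, per-subject direction combining, area->full, subject means
        per_subject: dict[tuple, TransmissibilitySpectrum] = {}
        for (glove, subj, area, direction), spectra in point_ratios.items():
            per_subject[(glove, subj, area, direction)] = average_spectra(
                spectra, level="points"
            )
        subjects = sorted({k[1] for k in per_subject})
        gloves = sorted({k[0] for k in per_subject})
        collected: dict[tuple, list[TransmissibilitySpectrum]] = defaultdict(list)
        for glove in gloves:
            for subj in subjects:
                by_loc: dict[str, dict[str, TransmissibilitySpectrum]] = {}
                for area, loc in ((1, "fingertip"), (2, "proximal")):
                    dirs = {}
                    for d in ("x", "y", "z"):
                        s = per_subject.get((glove, subj, area, d))
                        if s is None:
                            raise ValueError(
                                f"glove {glove!r}, subject {subj!r}: missing "
                                f"direction {d} in the {loc} area"
                            )
                        dirs[d] = s
                    dirs["xz"] = combine_xz(dirs["x"], dirs["z"])
                    dirs["xyz"] = combine_xyz(dirs["x"], dirs["y"], dirs["z"])
                    by_loc[loc] = dirs
                for d in ("x", "y", "z", "xz", "xyz"):
                    full = average_spectra(
                        [by_loc["fingertip"][d], by_loc["proximal"][d]], level="areas"
                    )
                    for loc in ("fingertip", "proximal"):
                        collected[(glove, loc, d)].append(by_loc[loc][d])
                    collected[(glove, "full", d)].append(full)

        spectra: dict[tuple, TransmissibilitySpectrum] = {}
        for key, per_subj in collected.items():
            mean = average_spectra(per_subj, level="subjects")
            if self.extend:
                mean = extend_low_frequency(mean, abscissa=self.abscissa)
            spectra[key] = truncate_to(
                mean, mean.grid.nominal_centers[0], self.fmax_nominal
            )
        self.spectra_ = spectra
        self.gloves_ = gloves
        self.n_subjects_ = len(subjects)
        return self

    def get_spectrum(self, glove: str, location: str, direction: str) -> TransmissibilitySpectrum:
        check_is_fitted(self, "spectra_")
        try:
            return self.spectra_[(glove, location, direction)]
        except KeyError:
            raise KeyError(
                f"no synthesized spectrum for glove={glove!r}, "
                f"location={location!r}, direction={direction!r}"
            ) from None

    def spectra(self) -> list[TransmissibilitySpectrum]:
        check_is_fitted(self, "spectra_")
        return [self.spectra_[k] for k in sorted(self.spectra_)]


class GloveEffectivenessScorer(BaseEstimator):
    """Score glove-tool matches by tool-specific percent vibration reduction.

    Parameters
    ----------
    weighting : {"iso_wh", "table"}
        Realization of the hand-arm weighting used for the weighted mode.
    modes : tuple of {"unweighted", "weighted"}
        Which assessment modes to compute.
    location : {"fingertip", "proximal", "full"}
        Finger region assessed (default full finger).
    strategy : {"spectrum_mean", "value_mean"}
        How the full-finger value is formed: average the two area spectra then
        evaluate (default), or average the two locations' scalar values.
    threshold : float
        Percent-reduction threshold for match classification.
    inclusive : bool
        Inclusive (>=) or strict (>) threshold comparison.
    fmin_nominal, fmax_nominal : float
        Assessment band range (default 6.3-500 Hz).

    Attributes
    ----------
    spectra_ : the fitted glove spectra keyed (glove, location, direction)
    gloves_ : assessed glove ids
    results_ : DataFrame of the last ``predict`` call
    """

    def __init__(
        self,
        weighting: str = "iso_wh",
        modes: tuple[str, ...] = ("unweighted", "weighted"),
        location: str = "full",
        strategy: str = "spectrum_mean",
        threshold: float = 10.0,
        inclusive: bool = True,
        fmin_nominal: float = 6.3,
        fmax_nominal: float = 500.0,
    ) -> None:
        self.weighting = weighting
        self.modes = modes
        self.location = location
        self.strategy = strategy
        self.threshold = threshold
        self.inclusive = inclusive
        self.fmin_nominal = fmin_nominal
        self.fmax_nominal = fmax_nominal

    # -- fitting ----------------------------------------------------------
    def fit(self, X, y=None) -> "GloveEffectivenessScorer":
        """Fit on glove spectra.

        ``X`` is either a fitted :class:`TransmissibilitySynthesizer`, a dict
        keyed ``(glove, location, direction)``, or a flat list of tagged
        :class:`TransmissibilitySpectrum` objects.
        """
        if isinstance(X, TransmissibilitySynthesizer):
            check_is_fitted(X, "spectra_")
            spectra = dict(X.spectra_)
        elif isinstance(X, dict):
            spectra = dict(X)
        else:
            spectra = {(s.glove_id, s.location, s.direction): s for s in X}
        if not spectra:
            raise ValueError("no glove spectra provided")
        for mode in self.modes:
            if mode not in ("unweighted", "weighted"):
                raise ValueError(f"unknown assessment mode {mode!r}")
        if self.weighting not in ("iso_wh", "table"):
            raise ValueError(f"weighting must be 'iso_wh' or 'table', got {self.weighting!r}")
        self.spectra_ = spectra
        self.gloves_ = sorted({k[0] for k in spectra})
        grid = make_band_grid(self.fmin_nominal, self.fmax_nominal)
        self._grid = grid
        self._weights = {
            "unweighted": wh_weights(grid, "unity"),
            "weighted": wh_weights(grid, self.weighting),
        }
        return self

    def _glove_inputs(self, glove: str, location: str):
        y = self.spectra_.get((glove, location, "y"))
        xz = self.spectra_.get((glove, location, "xz"))
        if y is None or xz is None:
            raise KeyError(
                f"glove {glove!r} is missing the y or xz spectrum at location {location!r}"
            )
        return self._on_grid(y), self._on_grid(xz)

    def _on_grid(self, s: TransmissibilitySpectrum) -> TransmissibilitySpectrum:
        if s.grid == self._grid:
            return s
        mask = s.grid.restrict_mask(self.fmin_nominal, self.fmax_nominal)
        sub = s.grid.subgrid(self.fmin_nominal, self.fmax_nominal)
        if sub != self._grid:
            raise ValueError(
                f"spectrum for glove {s.glove_id!r} does not cover the assessment "
                f"range {self.fmin_nominal:g}-{self.fmax_nominal:g} Hz"
            )
        return replace(s, grid=sub, values=s.values[mask])

    def _restrict_tool(self, tool: ToolSpectrum) -> ToolSpectrum:
        filled = zero_fill(tool, make_band_grid(
            min(tool.grid.nominal_centers[0], self.fmin_nominal),
            max(tool.grid.nominal_centers[-1], self.fmax_nominal),
        ))
        mask = filled.grid.restrict_mask(self.fmin_nominal, self.fmax_nominal)
        return replace(
            filled,
            grid=self._grid,
            ax=filled.ax[mask],
            ay=filled.ay[mask],
            az=filled.az[mask],
        )

    # -- prediction -------------------------------------------------------
    def predict(self, tools: list[ToolSpectrum]) -> pd.DataFrame:
        """Tool-specific T values and percent reductions per glove x mode."""
        check_is_fitted(self, "spectra_")
        if not tools:
            raise ValueError("no tool spectra provided")
        rows = []
        for tool in tools:
            t = self._restrict_tool(tool)
            for glove in self.gloves_:
                for mode in self.modes:
                    res = self._score_one(glove, t, mode)
                    rows.append(
                        (res.tool_id, res.glove_id, res.location, res.mode,
                         res.t_y, res.t_xz, res.t_xzy, res.r_percent)
                    )
        self.results_ = pd.DataFrame(rows, columns=RESULT_COLUMNS)
        return self.results_

    def _score_one(self, glove: str, tool: ToolSpectrum, mode: str) -> EffectivenessResult:
        weights = self._weights[mode]
        if self.location == "full" and self.strategy == "value_mean":
            from .effectiveness import full_finger_result

            return full_finger_result(
                self._glove_inputs(glove, "fingertip"),
                self._glove_inputs(glove, "proximal"),
                tool,
                weights,
                strategy="value_mean",
            )
        t_y, t_xz = self._glove_inputs(glove, self.location)
        return tool_specific_values(t_y, t_xz, tool, weights)

    def classify(self, results: pd.DataFrame | None = None, mode: str = "unweighted") -> MatchReport:
        """Match classification for one assessment mode of a results table."""
        check_is_fitted(self, "spectra_")
        if results is None:
            results = getattr(self, "results_", None)
            if results is None:
                raise ValueError("call predict() first or pass a results table")
        sub = results[results["mode"] == mode] if "mode" in results.columns else results
        if sub.empty:
            raise ValueError(f"no results in mode {mode!r}")
        return classify_matches(sub, threshold=self.threshold, inclusive=self.inclusive)

    def score(self, tools: list[ToolSpectrum], y=None) -> float:
        """Mean percent reduction over gloves and tools (first mode)."""
        df = self.predict(tools)
        first = df[df["mode"] == self.modes[0]]
        return float(first["r_percent"].mean())
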