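"""End-to-end run configuration and pipeline orchestration.

``run_pipeline`` ties the stages together: read point measurements, synthesize
representative glove spectra, read tool spectra, score every glove-tool pair
in both weighting modes, classify matches, and write the spectra, results,
report and a run manifest (config echo, package version, fixture checksums)
to an output directory.  Runs with identical config are byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .effectiveness import render_report
from .estimators import GloveEffectivenessScorer, TransmissibilitySynthesizer
from .fixtures import fixture_checksums
from .tools import read_tool_spectra
from .transmissibility import read_point_measurements, write_spectra

__all__ = ["RunConfig", "run_pipeline"]

log = logging.getLogger("vibroglove")


@dataclass(frozen=True)
class RunConfig:
    """Validated configuration for one assessment run."""

    measurements_path: str
    tools_path: str
    out_dir: str
    fmin: float = 6.3
    fmax: float = 500.0
    weighting: str = "iso_wh"  # realization used for the weighted mode
    grip_n: float = 30.0
    push_n: float = 50.0
    location: str = "full"
    strategy: str = "spectrum_mean"
    threshold: float = 10.0
    inclusive: bool = True
    extension_abscissa: str = "log"
    validation_policy: str = "strict"
    seed: int = 0
    verbosity: str = "INFO"
    debug_pair: tuple[str, str] | None = None  # (glove, tool) per-band trace

    def __post_init__(self) -> None:
        if not 6.3 <= self.fmin < self.fmax <= 1250.0:
            raise ValueError("band range must satisfy 6.3 <= fmin < fmax <= 1250")
        if self.threshold < 0:
            raise ValueError("threshold must be >= 0")
        if self.location not in ("fingertip", "proximal", "full"):
            raise ValueError(f"unknown location {self.location!r}")
        if self.strategy not in ("spectrum_mean", "value_mean"):
            raise ValueError(f"unknown full-finger strategy {self.strategy!r}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise ValueError("config file must hold a key/value mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "debug_pair" in raw and raw["debug_pair"] is not None:
            raw["debug_pair"] = tuple(raw["debug_pair"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if d["debug_pair"] is not None:
            d["debug_pair"] = list(d["debug_pair"])
        return d


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Execute the full assessment; returns paths of the written artifacts."""
    logging.basicConfig(level=getattr(logging, config.verbosity.upper(), logging.INFO))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    log.info("stage 1/4: reading point measurements from %s", config.measurements_path)
    measurements = read_point_measurements(config.measurements_path)
    log.info("  %d point records", len(measurements))

    log.info("stage 2/4: synthesizing representative glove spectra")
    synth = TransmissibilitySynthesizer(
        grip_n=config.grip_n,
        push_n=config.push_n,
        abscissa=config.extension_abscissa,
        fmax_nominal=config.fmax,
    ).fit(measurements)
    spectra_path = out / "transmissibility_spectra.csv"
    write_spectra(synth.spectra(), spectra_path)
    log.info("  %d spectra for gloves: %s", len(synth.spectra_), ", ".join(synth.gloves_))

    log.info("stage 3/4: reading tool spectra from %s", config.tools_path)
    tools = read_tool_spectra(config.tools_path, policy=config.validation_policy)
    log.info("  %d tools", len(tools))

    log.info("stage 4/4: scoring glove-tool matches")
    scorer = GloveEffectivenessScorer(
        weighting=config.weighting,
        location=config.location,
        strategy=config.strategy,
        threshold=config.threshold,
        inclusive=config.inclusive,
        fmin_nominal=config.fmin,
        fmax_nominal=config.fmax,
    ).fit(synth)
    results = scorer.predict(tools)
    if config.debug_pair is not None:
        glove, tool = config.debug_pair
        sel = results[(results.glove == glove) & (results.tool == tool)]
        log.debug("debug pair %s x %s:\n%s", glove, tool, sel.to_string(index=False))
    results_path = out / "effectiveness.csv"
    results.to_csv(results_path, index=False, float_format="%.6f")

    report_path = out / "match_report.csv"
    reports = []
    for mode in ("unweighted", "weighted"):
        rep = scorer.classify(results, mode=mode)
        reports.append(f"# mode: {mode}\n" + render_report(
            rep, results[results["mode"] == mode], fmt="csv"
        ))
    report_path.write_text("\n".join(reports))

    manifest_path = out / "manifest.json"
    manifest = {
        "config": config.to_dict(),
        "package_version": __version__,
        "n_measurements": len(measurements),
        "n_tools": len(tools),
        "gloves": synth.gloves_,
        "fixture_checksums": fixture_checksums(),
    }
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    log.info("wrote %s", ", ".join(p.name for p in (spectra_path, results_path, report_path, manifest_path)))
    return {
        "spectra": spectra_path,
        "results": results_path,
        "report": report_path,
        "manifest": manifest_path,
    }
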