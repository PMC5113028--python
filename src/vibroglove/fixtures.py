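"""Packaged reference tables transcribed from the published assessment.

Four delimited-text fixtures ship with the package:

``table1_gloves``
    Glove construction metadata including grip-strength reductions.
``tool_accel_summaries``
    Shear/compression/total acceleration magnitudes (Ay, Axz, At) per tool
    and weighting mode.  ``identity_ok`` is False for rows whose printed At
    differs from ``sqrt(Ay^2 + Axz^2)`` by more than 0.01 (print
    inconsistencies in the source tables); consistency checks skip those rows
    explicitly rather than silently.
``glove_tool_transmissibilities``
    Tool-specific T_y, T_xz, T_xzy per glove, finger location and mode.
``table4_reductions``
    Percent reductions of the full-finger total vibration for 79 tool spectra
    x 4 gloves x {unweighted, weighted}, plus the weighted total
    acceleration Aw.

Each loader verifies a frozen sha256 checksum so silent fixture edits fail
loudly.
"""

from __future__ import annotations

import hashlib
from importlib import resources

import pandas as pd

__all__ = ["load_fixture", "list_fixtures", "fixture_checksums"]

_CHECKSUMS = {
    "glove_tool_transmissibilities.csv": "5b5f5d79957f854a4ef13183b1488cfba4a038781d47227520b3cfe31caa1ab4",
    "table1_gloves.csv": "1097f6656a24aa51db08d7338354256877d17187431979b8e7ddae7c0bf98f3e",
    "table4_reductions.csv": "3113ee3667e94a1e847cdeb409f54d6d0bd2364372e1724e0e0edb4cf0a5ad4c",
    "tool_accel_summaries.csv": "a8c9a4b8000b2eff64b1e14775ce953c53375737e66ab877eeaaa390ea0be0e3",
}

_FIXTURES = {
    "table1": "table1_gloves.csv",
    "tool_accel_summaries": "tool_accel_summaries.csv",
    "glove_tool_transmissibilities": "glove_tool_transmissibilities.csv",
    "table4": "table4_reductions.csv",
}


def list_fixtures() -> list[str]:
    return sorted(_FIXTURES)


def fixture_checksums() -> dict[str, str]:
    return dict(_CHECKSUMS)


def load_fixture(name: str) -> pd.DataFrame:
    """Load a packaged fixture by short name, verifying its checksum."""
    if name not in _FIXTURES:
        raise KeyError(f"unknown fixture {name!r}; available: {', '.join(list_fixtures())}")
    fname = _FIXTURES[name]
    ref = resources.files("vibroglove.data") / fname
    raw = ref.read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != _CHECKSUMS[fname]:
        raise ValueError(f"fixture {fname} checksum mismatch: {digest}")
    import io

    df = pd.read_csv(io.BytesIO(raw))
    df.attrs["fixture"] = name
    df.attrs["sha256"] = digest
    return df
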