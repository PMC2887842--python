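"""Structured configuration files and tabular export.

A single YAML document carries the anatomy parameters, nerve template
parameters and conductivity overrides, so a complete model specification is
one text file.  Fields, nerve paths and sweep tables export to plain CSV.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .anatomy import AnatomyParams
from .conductivity import ConductivityTable, build_conductivity_table
from .nerves import NerveParams, NervePath
from .solver import PotentialField


def _tuplify(value):
    if isinstance(value, list):
        return tuple(_tuplify(v) for v in value)
    return value


def load_config(path: str | Path) -> tuple[AnatomyParams, NerveParams, ConductivityTable]:
    """Read (anatomy, nerves, conductivity) from a YAML config file.

    Sections ``anatomy``, ``nerves`` and ``conductivity`` are each optional;
    omitted keys fall back to the package defaults.
    """
    doc = yaml.safe_load(Path(path).read_text()) or {}
    anatomy = AnatomyParams(
        **{k: _tuplify(v) for k, v in (doc.get("anatomy") or {}).items()}
    )
    nerves = NerveParams(
        **{k: _tuplify(v) for k, v in (doc.get("nerves") or {}).items()}
    )
    table = build_conductivity_table(doc.get("conductivity") or None)
    return anatomy, nerves, table


def save_config(
    path: str | Path,
    anatomy: AnatomyParams | None = None,
    nerves: NerveParams | None = None,
    overrides: Mapping[str, float] | None = None,
) -> None:
    """Write a config file with the given (or default) parameters."""
    doc = {
        "anatomy": dataclasses.asdict(anatomy or AnatomyParams()),
        "nerves": dataclasses.asdict(nerves or NerveParams()),
    }
    if overrides:
        doc["conductivity"] = dict(overrides)
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def field_to_csv(field: PotentialField, path: str | Path, stride: int = 1) -> None:
    """Flat (x, y, z, V) table of the potential at voxel centres."""
    g = field.grid
    X, Y, Z = np.meshgrid(g.xc, g.yc, g.zc, indexing="ij")
    sl = (slice(None, None, stride),) * 3
    pd.DataFrame(
        {
            "x_mm": X[sl].ravel(),
            "y_mm": Y[sl].ravel(),
            "z_mm": Z[sl].ravel(),
            "v_volts": field.values[sl].ravel(),
        }
    ).to_csv(path, index=False)


def paths_to_csv(paths: Mapping[str, NervePath], path: str | Path) -> None:
    """Polyline export: one row per point with the path name."""
    frames = [
        pd.DataFrame(
            {"name": p.name, "x_mm": p.points[:, 0], "y_mm": p.points[:, 1], "z_mm": p.points[:, 2]}
        )
        for p in paths.values()
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
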