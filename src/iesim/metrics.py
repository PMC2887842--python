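"""Activating function and selectivity metrics.

The activating function (AF) at a node of Ranvier is the second spatial
difference of the extracellular potential along the fiber at the internodal
spacing, AF_n = (V(s_n - l) - 2 V(s_n) + V(s_n + l)) / l^2 with
l = 0.5 mm for the 5 um myelinated afferents modeled here.  For cathodic
stimulation a positive AF depolarizes; "maximum AF" throughout means the
maximum of the depolarizing-signed AF over the node grid.

At the distal fiber terminal the drive is the first spatial difference
(V(s_1) - V(s_0)) / l.  When the terminal competes with interior nodes for
the maximum it enters as the sealed-end one-sided second difference
(V(s_1) - V(s_0)) / l^2, which has interior units and is the standard
discrete cable end-node drive; the raw signed maximum over interior nodes
only is available via ``terminal_mode="exclude"``.

Node placement is repeated for 5 possible positions of the most distal node
(offsets 0, 0.1, ..., 0.4 mm = l/5 steps, commensurate with the 0.1 mm
potential sampling), and maxima are pooled bilaterally: the ensemble for a
trunk pair has 10 members (5 offsets x 2 sides), a single branch has 5.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np

from .nerves import NervePath, PotentialProfile, sample_potential
from .solver import PotentialField

L_NODE_MM = 0.5  # internodal length l for 5 um fibers
N_OFFSETS = 5
_STRIDE = int(round(L_NODE_MM / 0.1))  # profile samples per internode


class MetricsError(ValueError):
    """Profile too short or degenerate statistics input."""


@dataclass(frozen=True)
class AFProfile:
    """Activating function on one node grid along one profile."""

    name: str
    offset_index: int
    node_s_mm: np.ndarray  # node arclengths (terminal first)
    interior_af: np.ndarray  # V/m^2 at nodes 1..n-2 (or 1..n-1, see below)
    terminal_af: float | None  # V/m at node 0; None when the profile has no terminal
    max_af: float  # depolarizing max over nodes (terminal folded in as /l)


def activating_function(
    profile: PotentialProfile,
    offset: int,
    terminal_mode: str = "sealed_end",
    l_mm: float = L_NODE_MM,
) -> AFProfile:
    """AF along a sampled potential profile for one terminal-node offset.

    ``offset`` in 0..4 shifts the whole node grid proximally by
    offset * 0.1 mm.  The far end of the profile (where the trunk is
    truncated at the edge of the model) gets no AF value.  ``l_mm``
    overrides the internodal length (it must be a multiple of the 0.1 mm
    sample spacing; the default matches 5 um fibers).
    """
    if not 0 <= offset < N_OFFSETS:
        raise MetricsError("offset index must be 0..4")
    if terminal_mode not in ("sealed_end", "exclude"):
        raise MetricsError(f"unknown terminal_mode {terminal_mode!r}")
    stride = int(round(l_mm / profile.spacing_mm))
    if stride < 1 or abs(stride * profile.spacing_mm - l_mm) > 1e-9:
        raise MetricsError("internodal length must be a multiple of the sampling step")
    v = profile.v
    idx = np.arange(offset, v.size, stride)
    if idx.size < 3:
        raise MetricsError(
            f"{profile.name}: profile shorter than two internodal lengths"
        )
    l_m = l_mm * 1e-3
    vn = v[idx]
    interior = (vn[:-2] - 2 * vn[1:-1] + vn[2:]) / l_m**2
    # distal terminal: first spatial difference toward the fiber
    term = float((vn[1] - vn[0]) / l_m)
    candidates = [interior]
    if terminal_mode == "sealed_end":
        candidates.append(np.array([term / l_m]))
    max_af = float(max(np.max(c) for c in candidates if c.size))
    return AFProfile(
        name=profile.name,
        offset_index=offset,
        node_s_mm=profile.s_mm[idx],
        interior_af=interior,
        terminal_af=term,
        max_af=max_af,
    )


@dataclass(frozen=True)
class AFStats:
    """Mean +- SD of the maximum AF over an ensemble of node placements."""

    nerve: str
    mean: float
    sd: float
    n: int
    values: tuple[float, ...]

    @classmethod
    def from_values(cls, nerve: str, values: Iterable[float]) -> "AFStats":
        vals = tuple(float(x) for x in values)
        if len(vals) == 0:
            raise MetricsError("empty AF ensemble")
        arr = np.asarray(vals)
        sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
        return cls(nerve, float(arr.mean()), sd, arr.size, vals)


def max_af_stats(
    field: PotentialField,
    paths: Iterable[NervePath],
    nerve: str | None = None,
    terminal_mode: str = "sealed_end",
) -> AFStats:
    """Max-AF ensemble statistics for a set of paths under one field.

    For a bilateral trunk pair pass both sides; the ensemble pools the five
    terminal offsets of every path (10 members for a pair, 5 for a branch).
    """
    paths = list(paths)
    if not paths:
        raise MetricsError("no nerve paths given")
    values = []
    for p in paths:
        prof = sample_potential(field, p)
        for off in range(N_OFFSETS):
            values.append(activating_function(prof, off, terminal_mode).max_af)
    return AFStats.from_values(nerve or paths[0].name.split("-")[0], values)


@dataclass(frozen=True)
class SelectivityResult:
    """Conservative selectivity of target a over target b."""

    selectivity: float  # S = (mu_a - sd_a) / (mu_b + sd_b)
    af_ratio: float  # AFR = mu_a / mu_b
    selective: bool  # S > 1 and AFR > 1.5
    defined: bool = True


def selectivity(a: AFStats, b: AFStats) -> SelectivityResult:
    """S and AFR for activating target ``a`` below target ``b``'s threshold.

    S compares a minimum estimate (mean - SD) of the target's maximum AF
    against a maximum estimate (mean + SD) of the off-target's; the
    conservative decision rule flags ``selective`` only when S > 1 and the
    plain ratio of means exceeds 1.5.
    """
    denom = b.mean + b.sd
    if denom == 0 or b.mean == 0:
        return SelectivityResult(float("nan"), float("nan"), False, defined=False)
    if denom < 0:
        # the off-target is nowhere depolarized: the target is activatable at
        # any finite margin provided it is depolarized at all
        ok = a.mean - a.sd > 0
        inf = float("inf")
        return SelectivityResult(inf if ok else 0.0, inf if ok else 0.0, ok)
    s = (a.mean - a.sd) / denom
    afr = a.mean / b.mean
    return SelectivityResult(float(s), float(afr), bool(s > 1 and afr > 1.5))


def relative_threshold(stats_by_condition: Mapping[str, AFStats | float]) -> dict[str, float]:
    """Relative activation thresholds, inverse to the maximum AF.

    threshold(c) is proportional to 1 / mean-max-AF(c), normalized so the
    lowest-threshold condition equals 1.
    """
    mu = {
        k: (v.mean if isinstance(v, AFStats) else float(v))
        for k, v in stats_by_condition.items()
    }
    if not mu:
        raise MetricsError("no conditions given")
    if any(m <= 0 for m in mu.values()):
        raise MetricsError("relative thresholds need strictly positive mean AFs")
    top = max(mu.values())
    return {k: top / m for k, m in mu.items()}
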