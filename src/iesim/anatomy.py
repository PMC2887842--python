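"""Parametric voxel anatomy of the male cat urethra and surrounding tissue.

The model spans the urethra from the external meatus (x = 0, axial
coordinate in mm increasing proximally) to just proximal of the prostate.
Nine tissue compartments surround a catheter-filled lumen:

* penile urethra (x ≲ 44 mm): inner and outer urethral muscle layers around
  the lumen, enclosed by corpus spongiosum, the paired corpus cavernosum,
  and (distally) the prepuce;
* penile bulb (x ≈ 30-48 mm): bulbospongiosus and ischiocavernosus muscle;
* membranous/prostatic urethra (x ≳ 44 mm): urethral muscle wall,
  bulbocavernosus glands, and the prostate.

Everything else is a low-conductivity bath ("connective tissue etc.")
enclosed in a grounded bounding box.  Dorsal is +z; the model is mirror
symmetric about the midsagittal plane y = 0.

Dimensions are not printed in the source anatomy literature for this model,
so every extent and radius below is an explicit, documented default of this
package (cat penile urethra ≈ 4 cm, whole span 8 cm, 2 mm lumen) and can be
overridden through :class:`AnatomyParams`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .conductivity import ConductivityTable, build_conductivity_table
from .electrodes import ElectrodeConfig, get_config
from .grid import RectilinearGrid, graded_axis


class AnatomyError(ValueError):
    """Inconsistent anatomy parameters or placement request."""


@dataclass(frozen=True)
class AnatomyParams:
    """Geometry of the tissue model, the catheter, and the grid (mm)."""

    # axial layout
    span_mm: float = 80.0  # meatus to 0.5 cm proximal of the prostate
    lumen_length_mm: float = 78.0

    # radial layout of the urethral wall (shared by all segments)
    lumen_radius_mm: float = 1.0
    inner_muscle_radius_mm: float = 1.6
    outer_muscle_radius_mm: float = 2.2

    # penile compartments: (x_lo, x_hi) extents and outer radii
    spongiosum_x: tuple[float, float] = (0.0, 46.0)
    spongiosum_radius_mm: float = 3.4
    cavernosum_x: tuple[float, float] = (0.0, 48.0)
    cavernosum_radius_mm: float = 5.2
    # the paired erectile bodies form a dorsal wedge; the lateral and ventral
    # fascial plane outside the spongiosum stays connective tissue
    cavernosum_half_angle_deg: float = 45.0
    # the bulb muscles sit ventral to the urethra; the dorsal periurethral
    # space carries the neurovascular (fascial) plane the nerves run in
    bulbospongiosus_x: tuple[float, float] = (30.0, 48.0)
    bulbospongiosus_radius_mm: float = 6.5
    bulbospongiosus_z_max_mm: float = -3.5
    prepuce_x: tuple[float, float] = (0.0, 15.0)
    prepuce_radii_mm: tuple[float, float] = (5.2, 7.0)
    ischiocavernosus_x: tuple[float, float] = (34.0, 48.0)
    ischiocavernosus_radii_mm: tuple[float, float] = (6.5, 7.5)
    ischiocavernosus_z_max_mm: float = -3.5
    # membranous urethra: the urethral wall muscle thickens into the striated
    # periurethral sphincter (rhabdosphincter) proximal of the penile bulb
    membranous_wall_x_mm: float = 46.0
    membranous_wall_radius_mm: float = 5.0
    bulbocavernosus_gland_x: tuple[float, float] = (46.0, 54.0)
    bulbocavernosus_gland_radii_mm: tuple[float, float] = (2.2, 4.0)
    prostate_x: tuple[float, float] = (62.0, 78.0)
    prostate_radius_mm: float = 5.0

    # catheter; default flush with the lumen (the baseline contact model
    # assumes the contacts sit on the urethral wall)
    catheter_diameter_mm: float = 2.0

    # discretization
    voxel_mm: float = 0.5
    fine_lateral_mm: float = 10.0  # half-width of the uniformly fine core
    fine_axial_pad_mm: float = 5.0
    lateral_extent_mm: float = 350.0  # half-width of the bounding box
    axial_margin_mm: float = 250.0  # proximal bath margin beyond the tissue
    coarsen_ratio: float = 1.6
    h_coarse_max_mm: float = 48.0
    box_scale: float = 1.0  # bounding-box margin multiplier (2 = doubled box)
    refine_boxes: tuple[tuple[float, float, float, float, float, float, float], ...] = ()
    # each refine box: (x_lo, x_hi, y_lo, y_hi, z_lo, z_hi, h_fine)

    def __post_init__(self):
        if self.catheter_diameter_mm > 2 * self.lumen_radius_mm + 1e-9:
            raise AnatomyError("catheter diameter exceeds the urethral lumen")
        if self.voxel_mm <= 0:
            raise AnatomyError("voxel edge length must be > 0")
        if self.voxel_mm > self.lumen_radius_mm / 2 + 1e-9:
            raise AnatomyError(
                "voxel spacing too coarse to resolve the catheter "
                f"(need <= {self.lumen_radius_mm / 2} mm)"
            )
        if self.span_mm < 75.0:
            raise AnatomyError("model span must cover stimulation sites 1-7 cm")
        if not (
            self.lumen_radius_mm
            < self.inner_muscle_radius_mm
            < self.outer_muscle_radius_mm
            < self.spongiosum_radius_mm
            < self.cavernosum_radius_mm
        ):
            raise AnatomyError("radial layers must be strictly nested")
        for name in (
            "spongiosum_x",
            "cavernosum_x",
            "bulbospongiosus_x",
            "prepuce_x",
            "ischiocavernosus_x",
            "bulbocavernosus_gland_x",
            "prostate_x",
        ):
            lo, hi = getattr(self, name)
            if not (0 <= lo < hi <= self.span_mm):
                raise AnatomyError(f"{name} extent outside the model span")

    @property
    def catheter_radius_mm(self) -> float:
        return self.catheter_diameter_mm / 2

    @classmethod
    def from_french(cls, french: float, **kwargs) -> "AnatomyParams":
        """Parameters with the catheter diameter given in French (3 Fr = 1 mm)."""
        return cls(catheter_diameter_mm=french / 3.0, **kwargs)

    @classmethod
    def desk_scale(cls, **kwargs) -> "AnatomyParams":
        """A faster variant with a closer grounded boundary.

        Maximum AFs shift by a few percent relative to the default
        far-ground model, but the ratios, orderings and selectivity results
        the experiments report are insensitive to the difference; the sweep
        and Monte-Carlo experiments use this scale by default.
        """
        kwargs.setdefault("lateral_extent_mm", 120.0)
        kwargs.setdefault("axial_margin_mm", 80.0)
        kwargs.setdefault("coarsen_ratio", 1.45)
        kwargs.setdefault("h_coarse_max_mm", 16.0)
        return cls(**kwargs)

    def build_grid(self) -> RectilinearGrid:
        s = self.box_scale
        fine_hi = self.span_mm + self.fine_axial_pad_mm
        rx = [b for b in self.refine_boxes]
        # axis-wise refinement windows (the grid is tensor-product, so each
        # box refines the union of its axis intervals)
        def refine_for(axis: int):
            if not rx:
                return None
            lo = min(b[2 * axis] for b in rx)
            hi = max(b[2 * axis + 1] for b in rx)
            hf = min(b[6] for b in rx)
            return (lo, hi, hf)

        xe = graded_axis(
            0.0,
            fine_hi,
            self.voxel_mm,
            margin_lo=0.0,
            margin_hi=self.axial_margin_mm * s,
            ratio=self.coarsen_ratio,
            h_max=self.h_coarse_max_mm,
            refine=refine_for(0),
        )
        lat_margin = (self.lateral_extent_mm - self.fine_lateral_mm) * s
        ye = graded_axis(
            -self.fine_lateral_mm,
            self.fine_lateral_mm,
            self.voxel_mm,
            margin_lo=lat_margin,
            margin_hi=lat_margin,
            ratio=self.coarsen_ratio,
            h_max=self.h_coarse_max_mm,
            refine=refine_for(1),
        )
        ze = graded_axis(
            -self.fine_lateral_mm,
            self.fine_lateral_mm,
            self.voxel_mm,
            margin_lo=lat_margin,
            margin_hi=lat_margin,
            ratio=self.coarsen_ratio,
            h_max=self.h_coarse_max_mm,
            refine=refine_for(2),
        )
        return RectilinearGrid(xe, ye, ze)


#: compartment paint order (later entries overwrite earlier ones)
LABELS: tuple[str, ...] = (
    "bath",
    "prepuce",
    "ischiocavernosus muscle",
    "prostate",
    "bulbocavernosus glands",
    "bulbospongiosus muscle",
    "corpus cavernosum",
    "corpus spongiosum",
    "outer urethral muscle",
    "inner urethral muscle",
    "urine",
    "catheter",
)
LABEL_INDEX = {name: i for i, name in enumerate(LABELS)}


@dataclass
class ContactMask:
    """Voxel source footprint of one electrode contact."""

    polarity: str
    indices: np.ndarray  # (n, 3) int voxel indices
    weights: np.ndarray  # exposed-area weights, sum over the contact = 1


@dataclass
class VoxelModel:
    """Labeled conduction domain with per-voxel conductivity."""

    grid: RectilinearGrid
    labels: np.ndarray  # int8 label codes, shape = grid.shape
    conductivity: np.ndarray  # S/m, shape = grid.shape
    table: ConductivityTable
    params: AnatomyParams
    insulated_faces: frozenset[str] = frozenset({"x_min"})
    contacts: list[ContactMask] = field(default_factory=list)
    electrode: ElectrodeConfig | None = None
    depth_cm: float | None = None
    orientation_deg: float | None = None

    def label_volumes(self) -> dict[str, float]:
        """Total volume (mm^3) of each compartment present."""
        vol = self.grid.cell_volumes()
        out = {}
        for name, code in LABEL_INDEX.items():
            v = float(vol[self.labels == code].sum())
            if v > 0:
                out[name] = v
        return out

    def present_labels(self) -> set[str]:
        return {LABELS[c] for c in np.unique(self.labels)}


def build_anatomy(
    params: AnatomyParams | None = None,
    table: ConductivityTable | None = None,
) -> VoxelModel:
    """Voxelize the parametric anatomy and assign conductivities."""
    params = params or AnatomyParams()
    table = table or build_conductivity_table()
    grid = params.build_grid()
    X, Y, Z = grid.centers()
    R = np.sqrt(Y**2 + Z**2)  # radial distance from the lumen axis

    labels = np.full(grid.shape, LABEL_INDEX["bath"], dtype=np.int8)

    def paint(name: str, mask: np.ndarray):
        labels[mask] = LABEL_INDEX[name]

    def ax(extent):
        lo, hi = extent
        return (X >= lo) & (X < hi)

    p = params
    paint("prepuce", ax(p.prepuce_x) & (R >= p.prepuce_radii_mm[0]) & (R < p.prepuce_radii_mm[1]))
    paint(
        "ischiocavernosus muscle",
        ax(p.ischiocavernosus_x)
        & (R >= p.ischiocavernosus_radii_mm[0])
        & (R < p.ischiocavernosus_radii_mm[1])
        & (Z < p.ischiocavernosus_z_max_mm),
    )
    paint(
        "bulbospongiosus muscle",
        ax(p.bulbospongiosus_x)
        & (R >= p.spongiosum_radius_mm)
        & (R < p.bulbospongiosus_radius_mm)
        & (Z < p.bulbospongiosus_z_max_mm),
    )
    phi_dorsal = np.degrees(np.arctan2(np.abs(Y), Z))  # angle from dorsal
    paint(
        "corpus cavernosum",
        ax(p.cavernosum_x)
        & (R >= p.spongiosum_radius_mm)
        & (R < p.cavernosum_radius_mm)
        & (np.broadcast_to(phi_dorsal, labels.shape) < p.cavernosum_half_angle_deg),
    )
    paint(
        "corpus spongiosum",
        ax(p.spongiosum_x) & (R >= p.outer_muscle_radius_mm) & (R < p.spongiosum_radius_mm),
    )
    urethra = (X >= 0) & (X < p.span_mm)
    # the outer muscle layer thickens into the periurethral sphincter sleeve
    # along the membranous/prostatic urethra
    outer_r = np.where(
        X >= p.membranous_wall_x_mm, p.membranous_wall_radius_mm, p.outer_muscle_radius_mm
    )
    paint("outer urethral muscle", urethra & (R >= p.inner_muscle_radius_mm) & (R < outer_r))
    paint(
        "bulbocavernosus glands",
        ax(p.bulbocavernosus_gland_x)
        & (R >= p.bulbocavernosus_gland_radii_mm[0])
        & (R < p.bulbocavernosus_gland_radii_mm[1]),
    )
    paint("prostate", ax(p.prostate_x) & (R >= p.outer_muscle_radius_mm) & (R < p.prostate_radius_mm))
    paint("inner urethral muscle", urethra & (R >= p.lumen_radius_mm) & (R < p.inner_muscle_radius_mm))
    lumen = (X >= 0) & (X < p.lumen_length_mm) & (R < p.lumen_radius_mm)
    if p.catheter_radius_mm < p.lumen_radius_mm - 1e-9:
        paint("urine", lumen)  # fluid-filled annulus around a thin catheter
    paint("catheter", lumen & (R < p.catheter_radius_mm))

    cond = np.empty(grid.shape, dtype=np.float64)
    for name, code in LABEL_INDEX.items():
        sel = labels == code
        if sel.any():
            cond[sel] = table.for_compartment(name)

    required = set(LABELS) - {"urine"}
    missing = required - {LABELS[c] for c in np.unique(labels)}
    if missing:
        raise AnatomyError(f"compartments missing from the voxelization: {sorted(missing)}")

    return VoxelModel(grid=grid, labels=labels, conductivity=cond, table=table, params=params)


def _catheter_shell(model: VoxelModel) -> np.ndarray:
    """Tissue/fluid voxels laterally adjacent to the catheter surface.

    The regulated current is injected here: a metal contact flush on the
    (insulating) catheter surface drives current directly into the adjacent
    conducting medium.
    """
    cath = model.labels == LABEL_INDEX["catheter"]
    shell = np.zeros_like(cath)
    shell[:, 1:, :] |= cath[:, :-1, :]
    shell[:, :-1, :] |= cath[:, 1:, :]
    shell[:, :, 1:] |= cath[:, :, :-1]
    shell[:, :, :-1] |= cath[:, :, 1:]
    return shell & ~cath


def place_catheter(
    model: VoxelModel,
    config: str | ElectrodeConfig,
    depth_cm: float,
    orientation_deg: float = 0.0,
) -> VoxelModel:
    """Attach electrode contact masks centred at ``depth_cm`` from the meatus.

    ``orientation_deg`` rotates sector contacts about the catheter axis;
    0° points the sector centre dorsally (+z, toward the nerve trunks),
    180° ventrally.  Returns a new model sharing the grid and label arrays.
    """
    config = get_config(config)
    if not 1.0 - 1e-9 <= depth_cm <= 7.0 + 1e-9:
        raise AnatomyError("stimulation depth must be 1-7 cm from the meatus")
    p = model.params
    centre = depth_cm * 10.0
    tip = p.lumen_length_mm
    for c in config.contacts:
        hi = centre + c.offset_mm + c.length_mm / 2
        lo = centre + c.offset_mm - c.length_mm / 2
        if hi > tip or lo < 0:
            raise AnatomyError("contact extends past the catheter tip")

    grid = model.grid
    X, Y, Z = grid.centers()
    shell = _catheter_shell(model)
    # exposed-area weight of a shell voxel: axial extent x transverse extent
    dperp = np.sqrt(
        grid.dy[None, :, None] * grid.dz[None, None, :]
    )  # ~ local transverse cell size
    area = grid.dx[:, None, None] * dperp
    # angle about the catheter axis, measured from dorsal (+z) toward +y
    phi = np.degrees(np.arctan2(Y, Z))

    masks: list[ContactMask] = []
    for c in config.contacts:
        if c.polarity == "off":
            continue
        sel = (
            shell
            & (X >= centre + c.offset_mm - c.length_mm / 2)
            & (X < centre + c.offset_mm + c.length_mm / 2)
        )
        if c.arc_deg < 360:
            dphi = (phi - orientation_deg + 180.0) % 360.0 - 180.0
            sel = sel & (np.abs(np.broadcast_to(dphi, grid.shape)) <= c.arc_deg / 2)
        idx = np.argwhere(sel)
        if idx.size == 0:
            raise AnatomyError(
                f"contact of {config.name!r} produced an empty voxel mask"
            )
        w = np.broadcast_to(area, grid.shape)[sel].astype(float)
        masks.append(ContactMask(c.polarity, idx, w / w.sum()))

    return VoxelModel(
        grid=model.grid,
        labels=model.labels,
        conductivity=model.conductivity,
        table=model.table,
        params=model.params,
        insulated_faces=model.insulated_faces,
        contacts=masks,
        electrode=config,
        depth_cm=depth_cm,
        orientation_deg=orientation_deg,
    )


def source_density(model: VoxelModel, current_a: float = 1e-3) -> np.ndarray:
    """Per-voxel injected current (A): cathodes carry -current, anodes +current.

    ``current_a`` is the magnitude of the regulated current (default 1 mA).
    Contacts of one polarity share the current equally; within a contact it
    is distributed over the surface voxels in proportion to exposed area.
    """
    if not model.contacts:
        raise AnatomyError("model has no electrode contacts; call place_catheter")
    s = np.zeros(model.grid.shape)
    for pol, sign in (("cathode", -1.0), ("anode", +1.0)):
        masks = [m for m in model.contacts if m.polarity == pol]
        if not masks:
            continue
        total = sum(m.weights.sum() for m in masks)  # = number of contacts
        for m in masks:
            i, j, k = m.indices.T
            s[i, j, k] += sign * current_a * m.weights / total
    return s
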