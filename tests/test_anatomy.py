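import dataclasses

import numpy as np
import pytest

import iesim
from iesim.anatomy import LABEL_INDEX, LABELS, AnatomyError, source_density


@pytest.fixture(scope="module")
def model():
    return iesim.build_anatomy(iesim.AnatomyParams.desk_scale())


def test_default_anatomy_has_eleven_compartments(model):
    """Nine tissues plus catheter and bath; urine appears only when the
    catheter is thinner than the lumen."""
    labels = model.present_labels()
    assert len(labels) == 11
    assert "urine" not in labels
    assert {"catheter", "bath", "prepuce", "prostate"} <= labels


def test_urine_annulus_appears_for_thin_catheter():
    p = iesim.AnatomyParams.desk_scale(catheter_diameter_mm=1.0)
    labels = iesim.build_anatomy(p).present_labels()
    assert "urine" in labels and len(labels) == 12


def test_conductivity_roundtrips_through_label_table(model):
    for name, code in LABEL_INDEX.items():
        sel = model.labels == code
        if sel.any():
            assert np.all(model.conductivity[sel] == model.table.for_compartment(name))


def test_rebuild_is_bit_identical(model):
    again = iesim.build_anatomy(iesim.AnatomyParams.desk_scale())
    assert np.array_equal(again.labels, model.labels)
    assert np.array_equal(again.conductivity, model.conductivity)


def test_volume_fractions_stable_under_refinement():
    """Halving the voxel size changes compartment volume fractions < 10%.

    The inner urethral muscle is a 0.6 mm shell -- nearly a single voxel at
    the default spacing -- and converges only linearly, so it gets a 20%
    band; every thicker compartment must hold 10%.
    """
    vols = {}
    for h in (0.5, 0.25):
        m = iesim.build_anatomy(iesim.AnatomyParams.desk_scale(voxel_mm=h))
        v = m.label_volumes()
        tot = sum(v.values())
        vols[h] = {k: x / tot for k, x in v.items()}
    for name in vols[0.5]:
        if name == "bath":
            continue
        rel = 0.20 if name == "inner urethral muscle" else 0.10
        assert vols[0.5][name] == pytest.approx(vols[0.25][name], rel=rel), name


def test_catheter_volume_scales_with_diameter_squared():
    vols = {}
    for d in (2.0, 1.0):
        m = iesim.build_anatomy(iesim.AnatomyParams.desk_scale(voxel_mm=0.25, catheter_diameter_mm=d))
        vols[d] = m.label_volumes()["catheter"]
    assert vols[2.0] / vols[1.0] == pytest.approx(4.0, rel=0.15)


@pytest.mark.parametrize(
    "bad",
    [
        dict(catheter_diameter_mm=3.0),  # exceeds the lumen
        dict(voxel_mm=0.9),  # cannot resolve the catheter
        dict(span_mm=60.0),  # stimulation sites no longer fit
        dict(prostate_x=(70.0, 95.0)),  # outside the span
    ],
)
def test_invalid_params_rejected(bad):
    with pytest.raises(AnatomyError):
        iesim.AnatomyParams.desk_scale(**bad)


class TestPlaceCatheter:
    def test_full_ring_mask_invariant_under_rotation(self, model):
        a = iesim.place_catheter(model, "ring-1mm", 2.0, orientation_deg=0.0)
        b = iesim.place_catheter(model, "ring-1mm", 2.0, orientation_deg=90.0)
        assert np.array_equal(a.contacts[0].indices, b.contacts[0].indices)

    def test_sector_masks_related_by_half_turn(self, model):
        """Dorsal and ventral short contacts map onto each other under a
        180 deg rotation about the catheter axis, i.e. (y, z) -> (-y, -z)."""
        a = iesim.place_catheter(model, "short", 2.0, orientation_deg=0.0)
        b = iesim.place_catheter(model, "short", 2.0, orientation_deg=180.0)
        g = model.grid
        ny, nz = g.shape[1], g.shape[2]
        flipped = a.contacts[0].indices.copy()
        flipped[:, 1] = ny - 1 - flipped[:, 1]
        flipped[:, 2] = nz - 1 - flipped[:, 2]
        key = lambda idx: set(map(tuple, idx))
        assert key(flipped) == key(b.contacts[0].indices)

    def test_three_ring_masks_disjoint_at_pitch(self, model):
        placed = iesim.place_catheter(model, "3-ring", 2.0)
        assert len(placed.contacts) == 3
        sets = [set(map(tuple, c.indices)) for c in placed.contacts]
        assert not (sets[0] & sets[1]) and not (sets[1] & sets[2])
        centres = sorted(
            float(np.mean(model.grid.xc[c.indices[:, 0]])) for c in placed.contacts
        )
        assert np.diff(centres) == pytest.approx([3.5, 3.5], abs=0.3)

    def test_masks_hug_the_catheter_surface(self, model):
        placed = iesim.place_catheter(model, "ring-1mm", 2.0)
        g = model.grid
        idx = placed.contacts[0].indices
        r = np.hypot(g.yc[idx[:, 1]], g.zc[idx[:, 2]])
        rc = model.params.catheter_radius_mm
        assert np.all((r > rc) & (r < rc + 1.1 * model.params.voxel_mm * 2))

    @pytest.mark.parametrize("depth", [0.5, 7.5])
    def test_depth_outside_range_rejected(self, model, depth):
        with pytest.raises(AnatomyError):
            iesim.place_catheter(model, "ring-1mm", depth)

    def test_contact_past_catheter_tip_rejected(self, model):
        p = dataclasses.replace(model.params, lumen_length_mm=71.0)
        m = iesim.build_anatomy(p)
        with pytest.raises(AnatomyError):
            iesim.place_catheter(m, "5-ring", 7.0)

    def test_source_density_is_current_balanced(self, model):
        mono = iesim.place_catheter(model, "3-ring", 2.0)
        s = source_density(mono, 1e-3)
        assert s.sum() == pytest.approx(-1e-3, rel=1e-12)
        bi = iesim.place_catheter(model, "bipolar-ring-1mm", 2.0)
        s = source_density(bi, 1e-3)
        assert s.sum() == pytest.approx(0.0, abs=1e-18)
        assert s[s < 0].sum() == pytest.approx(-1e-3, rel=1e-12)
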