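import math

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from nanosolv import (
    BoxSpec,
    assign_bnnt_charges,
    build_bnnt,
    build_ssz_fixture,
    place_complex,
    solvate,
)
from nanosolv.structgen import WATER_OH


@pytest.fixture(scope="module")
def tube():
    return build_bnnt(n=9, rows=22, bond_length=1.45, cap=True)


@pytest.fixture(scope="module")
def ssz_keto():
    return build_ssz_fixture("keto")


class TestBNNT:
    def test_atom_inventory(self, tube):
        """(9,0) tube with 22 rows: 99 B + 99 N wall atoms plus 18 cap hydrogens."""
        counts = {e: tube.elements.count(e) for e in ("B", "N", "H")}
        assert counts == {"B": 99, "N": 99, "H": 18}

    def test_radius_matches_rolled_lattice(self, tube):
        """Cylinder radius near the ideal sqrt(3)*a*n/(2 pi) value."""
        pos = tube.positions
        wall = [i for i, e in enumerate(tube.elements) if e != "H"]
        r = np.hypot(pos[wall, 0], pos[wall, 1])
        ideal = math.sqrt(3) * 1.45 * 9 / (2 * math.pi)
        assert np.allclose(r, ideal, atol=1e-9)
        assert 3.5 <= r.mean() <= 3.8

    def test_length(self, tube):
        wall = [i for i, e in enumerate(tube.elements) if e != "H"]
        z = tube.positions[wall, 2]
        assert 21.6 <= z.max() - z.min() <= 23.6

    def test_bond_lengths_exact(self, tube):
        """Every B-N nearest-neighbour distance equals the requested bond length."""
        pos = tube.positions
        b = [i for i, e in enumerate(tube.elements) if e == "B"]
        n = [i for i, e in enumerate(tube.elements) if e == "N"]
        d = cdist(pos[b], pos[n])
        bonds = d[d < 1.6]
        assert bonds.size > 0
        assert np.allclose(bonds, 1.45, atol=1e-6)

    def test_interior_boron_has_three_nitrogen_neighbours(self, tube):
        pos = tube.positions
        n_pos = pos[[i for i, e in enumerate(tube.elements) if e == "N"]]
        for i, a in enumerate(tube.atoms):
            if a.element == "B" and a.role == "wall":
                nn = (np.linalg.norm(n_pos - pos[i], axis=1) < 1.6).sum()
                assert nn == 3

    def test_each_rim_atom_capped_once(self, tube):
        pos = tube.positions
        h_pos = pos[[i for i, e in enumerate(tube.elements) if e == "H"]]
        rim = [i for i, a in enumerate(tube.atoms) if a.role == "rim"]
        assert len(rim) == 18
        for i in rim:
            nh = (np.linalg.norm(h_pos - pos[i], axis=1) < 1.3).sum()
            assert nh == 1

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError):
            build_bnnt(n=9, rows=1)

    @pytest.mark.parametrize("qB,qN", [(0.83, -0.83), (0.92, -0.92)])
    def test_symmetric_charges_leave_caps_neutral(self, tube, qB, qN):
        out = assign_bnnt_charges(tube, qB, qN)
        h_charges = [a.charge for a in out.atoms if a.element == "H"]
        assert np.allclose(h_charges, 0.0, atol=1e-12)
        assert abs(out.total_charge) < 1e-6

    def test_asymmetric_charges_balanced_by_caps(self, tube):
        """99 B at +0.83 and 99 N at -0.80 leave +2.97; each of 18 H takes -0.165."""
        out = assign_bnnt_charges(tube, 0.83, -0.80)
        h_charges = [a.charge for a in out.atoms if a.element == "H"]
        assert np.allclose(h_charges, -99 * 0.03 / 18, atol=1e-12)
        assert abs(out.total_charge) < 1e-6

    def test_non_bnnt_rejected(self, ssz_keto):
        with pytest.raises(ValueError):
            assign_bnnt_charges(ssz_keto, 0.83, -0.83)


class TestSSZFixture:
    @pytest.mark.parametrize("tautomer", ["keto", "enol"])
    def test_formula_and_neutrality(self, tautomer):
        s = build_ssz_fixture(tautomer)
        counts = {e: s.elements.count(e) for e in ("C", "O", "N", "S", "H")}
        assert counts == {"C": 18, "O": 5, "N": 4, "S": 1, "H": 14}
        assert abs(s.total_charge) < 1e-6

    def test_keto_published_site_charges(self, ssz_keto):
        by_role = {a.role: a.charge for a in ssz_keto.atoms}
        assert by_role["S"] == pytest.approx(0.90)
        assert by_role["O_S"] == pytest.approx(-0.47)
        assert by_role["C1"] == pytest.approx(0.24)
        assert by_role["N4"] == pytest.approx(-0.41)

    def test_unknown_tautomer_rejected(self):
        with pytest.raises(ValueError):
            build_ssz_fixture("imine")


class TestComplexPlacement:
    def test_carbonyl_v2_contact_is_carbonyl_oxygen_over_boron(self, tube, ssz_keto):
        c = place_complex(tube, ssz_keto, "carbonyl_v2", gap=2.55)
        drug = c.positions[tube.n_atoms :]
        roles = [a.role for a in c.atoms[tube.n_atoms :]]
        b_pos = tube.positions[[i for i, e in enumerate(tube.elements) if e == "B"]]
        d_ob = cdist(drug[[roles.index("O1")]], b_pos).min()
        assert d_ob == pytest.approx(2.55, abs=0.01)

    @pytest.mark.parametrize("site", ["carbonyl_v1", "carbonyl_v2", "sulfonamide", "pyridine"])
    def test_gap_is_closest_approach(self, tube, ssz_keto, site):
        c = place_complex(tube, ssz_keto, site, gap=3.5)
        d = cdist(tube.positions, c.positions[tube.n_atoms :])
        assert float(d.min()) == pytest.approx(3.5, abs=0.05)

    def test_placement_deterministic(self, tube, ssz_keto):
        a = place_complex(tube, ssz_keto, "sulfonamide", gap=3.0)
        b = place_complex(tube, ssz_keto, "sulfonamide", gap=3.0)
        assert np.array_equal(a.positions, b.positions)

    def test_bad_gap_rejected(self, tube, ssz_keto):
        with pytest.raises(ValueError):
            place_complex(tube, ssz_keto, "pyridine", gap=1.0)


class TestSolvate:
    def test_empty_box_counts_match_density(self):
        """0.993 g/cm^3 is 0.0332 molecules/A^3: ~4150 waters in a 50 A box,
        ~63 in a 12.4 A box."""
        st = solvate(None, BoxSpec(edge=50.0, density=0.993), seed=2)
        assert 4100 <= st.n_water <= 4200
        st2 = solvate(None, BoxSpec(edge=12.4, density=0.993), seed=2)
        assert 60 <= st2.n_water <= 66

    def test_solute_carves_out_waters(self, tube, ssz_keto):
        complex_ = place_complex(tube, ssz_keto, "carbonyl_v2", gap=2.55)
        st = solvate(complex_, BoxSpec(edge=50.0), seed=2)
        assert 3900 <= st.n_water <= 4100
        # carved waters keep a clear shell around the solute
        d = cdist(st.waters[:, 0, :], st.solute.positions)
        assert d.min() >= 2.6

    def test_achieved_density_within_two_percent(self):
        from nanosolv.structgen import WATER_NUMBER_DENSITY_FACTOR

        box = BoxSpec(edge=20.0, density=0.993)
        st = solvate(None, box, seed=7)
        achieved = st.n_water / box.volume / WATER_NUMBER_DENSITY_FACTOR
        assert abs(achieved - 0.993) / 0.993 < 0.02

    def test_water_geometry_rigid(self):
        st = solvate(None, BoxSpec(edge=12.4), seed=3)
        oh1 = np.linalg.norm(st.waters[:, 1] - st.waters[:, 0], axis=1)
        oh2 = np.linalg.norm(st.waters[:, 2] - st.waters[:, 0], axis=1)
        assert np.allclose(oh1, WATER_OH, atol=1e-9)
        assert np.allclose(oh2, WATER_OH, atol=1e-9)

    def test_seed_determinism(self, tube):
        a = solvate(tube, BoxSpec(edge=36.0), seed=9)
        b = solvate(tube, BoxSpec(edge=36.0), seed=9)
        assert np.array_equal(a.waters, b.waters)

    def test_box_too_small_for_solute(self, tube):
        with pytest.raises(ValueError):
            solvate(tube, BoxSpec(edge=20.0), seed=1)
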