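"""Molecule construction and system assembly."""

import numpy as np
import pytest

from memdpd import (LipidSpec, MembraneSpec, ProteinSpec, assemble_bilayer,
                    build_lipid, build_protein, hexagon_bead_count,
                    insert_protein)
from memdpd.forcefield import SPECIES_INDEX
from memdpd.state import MOL_LIPID, MOL_LIPID_LONG, MOL_PROTEIN, MOL_WATER
from memdpd.structure import recenter_z


class TestLipid:
    @pytest.mark.parametrize("n_tail,n_bonds,n_angles", [
        (1, 1, 0), (3, 3, 2), (5, 5, 4),
    ])
    def test_chain_topology_counts(self, n_tail, n_bonds, n_angles):
        mol = build_lipid(LipidSpec(n_tail=n_tail))
        assert mol.positions.shape[0] == n_tail + 1
        assert mol.topology.n_bonds == n_bonds
        assert mol.topology.n_angles == n_angles

    def test_head_then_tail_species(self):
        mol = build_lipid(LipidSpec(n_tail=3))
        assert mol.species[0] == SPECIES_INDEX["H"]
        assert all(s == SPECIES_INDEX["T"] for s in mol.species[1:])
        lng = build_lipid(LipidSpec(n_tail=5, species_tag="long"))
        assert lng.species[0] == SPECIES_INDEX["H2"]
        assert all(s == SPECIES_INDEX["T2"] for s in lng.species[1:])

    def test_invalid_specs(self):
        with pytest.raises(ValueError):
            LipidSpec(n_tail=0)
        with pytest.raises(ValueError):
            MembraneSpec(n_tail=3, n_tail_long=3)


class TestProtein:
    @pytest.mark.parametrize("side,expected", [(1, 1), (2, 7), (3, 19),
                                               (4, 37)])
    def test_hexagon_bead_count_formula(self, side, expected):
        assert hexagon_bead_count(side) == expected
        # the lattice enumeration agrees with the closed form
        mol = build_protein(ProteinSpec(side_beads=side,
                                        n_hydrophobic_layers=1))
        assert mol.positions.shape[0] == 2 * expected

    def test_stacked_layers_and_species(self):
        spec = ProteinSpec(side_beads=3, n_hydrophobic_layers=3)
        mol = build_protein(spec)
        assert mol.positions.shape[0] == 4 * 19 == 76
        n_cap = (mol.species == SPECIES_INDEX["PH"]).sum()
        assert n_cap == 19
        assert (mol.species == SPECIES_INDEX["PT"]).sum() == 57

    def test_spring_network_rest_lengths_match_geometry(self):
        mol = build_protein(ProteinSpec(side_beads=2, n_hydrophobic_layers=2))
        b = mol.topology.bonds
        d = mol.positions[b[:, 0]] - mol.positions[b[:, 1]]
        np.testing.assert_allclose(np.linalg.norm(d, axis=1),
                                   mol.topology.bond_params[:, 1], atol=1e-12)
        # every bead is tied into the network
        assert set(b.ravel()) == set(range(mol.positions.shape[0]))


class TestBilayerAssembly:
    def test_symmetric_single_species_membrane(self, small_bilayer):
        state, topo, ff = small_bilayer
        lipids = state.mol_kind == MOL_LIPID
        assert (state.mol_kind == MOL_LIPID_LONG).sum() == 0
        n_lipids = len(np.unique(state.molecule_id[lipids]))
        assert n_lipids == 2 * 36
        # global bead density = rho
        assert state.n_beads == pytest.approx(3.0 * np.prod(state.box), abs=1)

    def test_long_lipids_only_in_upper_leaflet(self):
        spec = MembraneSpec(nx=10, ny=10, fraction_long=0.1, box_height=9.0)
        state, topo, ff = assemble_bilayer(spec, seed=2)
        long_beads = state.mol_kind == MOL_LIPID_LONG
        n_long = len(np.unique(state.molecule_id[long_beads]))
        assert n_long == round(0.1 * 100)
        zmid = state.box[2] / 2
        assert (state.positions[long_beads, 2] > zmid).all()
        # amplified repulsion between the two lipid species only
        S = SPECIES_INDEX
        assert ff.a[S["T"], S["T2"]] == pytest.approx(25.0 * 1.2)
        assert ff.a[S["W"], S["T2"]] == 100.0

    def test_infeasible_density_raises(self):
        spec = MembraneSpec(nx=20, ny=20, box_height=4.5)
        with pytest.raises(ValueError, match="density"):
            assemble_bilayer(spec, rho=1.0, seed=1)

    def test_tails_face_the_midplane(self, small_bilayer):
        state, _, _ = small_bilayer
        zmid = state.box[2] / 2
        heads = np.isin(state.species, [SPECIES_INDEX["H"]])
        tails = np.isin(state.species, [SPECIES_INDEX["T"]])
        assert (np.abs(state.positions[heads, 2] - zmid).min()
                > np.abs(state.positions[tails, 2] - zmid).min())


class TestInsertProtein:
    def _bilayer(self):
        return assemble_bilayer(MembraneSpec(nx=8, ny=8, box_height=9.0),
                                seed=9)

    def test_bead_bookkeeping_is_conserved(self):
        state, topo, ff = self._bilayer()
        n0 = state.n_beads
        spec = ProteinSpec(side_beads=2, n_hydrophobic_layers=3)
        new, newtopo, mol = insert_protein(state, topo, spec,
                                           (state.box[0] / 2, state.box[1] / 2))
        n_protein = 4 * 7
        removed = n0 + n_protein - new.n_beads
        assert removed > 0
        assert (new.mol_kind == MOL_PROTEIN).sum() == n_protein
        newtopo.validate(new.n_beads)

    @pytest.mark.parametrize("leaflet", ["upper", "lower"])
    def test_cap_sits_at_head_plane_anchor_toward_midplane(self, leaflet):
        state, topo, ff = self._bilayer()
        spec = ProteinSpec(side_beads=2, n_hydrophobic_layers=3,
                           leaflet=leaflet)
        new, _, mol = insert_protein(state, topo, spec,
                                     (state.box[0] / 2, state.box[1] / 2))
        idx = new.molecule_indices(mol)
        cap = idx[new.species[idx] == SPECIES_INDEX["PH"]]
        anchor = idx[new.species[idx] == SPECIES_INDEX["PT"]]
        pos = recenter_z(new)
        zmid = new.box[2] / 2
        cap_z = pos[cap, 2].mean()
        anchor_z = pos[anchor, 2].mean()
        if leaflet == "upper":
            assert cap_z > zmid and anchor_z < cap_z
        else:
            assert cap_z < zmid and anchor_z > cap_z

    def test_position_outside_box_rejected(self):
        state, topo, ff = self._bilayer()
        with pytest.raises(ValueError, match="inside the box"):
            insert_protein(state, topo, ProteinSpec(), (-1.0, 2.0))

    def test_no_severe_overlap_after_insertion(self):
        state, topo, ff = self._bilayer()
        spec = ProteinSpec(side_beads=3, n_hydrophobic_layers=4)
        new, _, mol = insert_protein(state, topo, spec,
                                     (state.box[0] / 2, state.box[1] / 2))
        idx = new.molecule_indices(mol)
        others = np.setdiff1d(np.arange(new.n_beads), idx)
        d = new.positions[others, None, :] - new.positions[None, idx, :]
        d -= new.box * np.round(d / new.box)
        min_d = np.sqrt(np.einsum("ijk,ijk->ij", d, d).min())
        assert min_d >= 0.1
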