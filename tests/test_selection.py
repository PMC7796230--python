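"""SSCR solute selection: SASA, interface detection, the three criteria,
and the atom-count bookkeeping."""

import numpy as np
import pytest

from grestlite.errors import ParameterError, SelectionError, ValidationError
from grestlite.selection import (
    SoluteRegion,
    SscrParams,
    atom_sasa,
    compute_sasa,
    count_solute_atoms,
    identify_interface_residues,
    rbp_solute_region,
    select_sscr,
)
from grestlite.structure import Structure, make_domains
from grestlite.toy import build_two_domain_system


def bead_structure(coords, charges, radii=2.0):
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    q = np.asarray(charges, dtype=float)
    names = np.where(q > 0, "CGP", np.where(q < 0, "CGN", "CGU"))
    return Structure(
        atom_names=np.full(n, "CA"), elements=np.full(n, "C"),
        res_ids=np.arange(1, n + 1), res_names=names,
        coords=coords, masses=np.full(n, 110.0), formal_charges=q,
        atom_radii=np.full(n, float(radii)))


class TestSasa:
    def test_isolated_sphere_closed_form(self):
        # one carbon, radius 1.7 Å, probe 1.4 Å: SASA = 4π(3.1)²
        area = atom_sasa(np.zeros((1, 3)), np.array([1.7]), 1.4, 960)[0]
        assert area == pytest.approx(4 * np.pi * 3.1 ** 2, rel=1e-12)

    def test_fully_buried_atom_has_zero_area(self):
        # central atom caged by 14 neighbors on a tight shell
        shell = []
        for u in (-1, 1):
            for axis in range(3):
                v = np.zeros(3)
                v[axis] = u * 2.2
                shell.append(v)
        for sx in (-1, 1):
            for sy in (-1, 1):
                for sz in (-1, 1):
                    shell.append(2.2 / np.sqrt(3) * np.array([sx, sy, sz]))
        coords = np.vstack([np.zeros(3), shell])
        radii = np.full(len(coords), 1.7)
        area = atom_sasa(coords, radii, 1.4, 960)
        assert area[0] == 0.0

    def test_dimer_matches_dense_grid_oracle(self):
        # brute-force oracle: spherical-cap integral has a closed form for
        # two spheres, but integrate numerically on a dense lattice instead
        r1, r2, probe, d = 1.7, 1.52, 1.4, 2.4
        coords = np.array([[0.0, 0, 0], [d, 0, 0]])
        radii = np.array([r1, r2])
        areas = atom_sasa(coords, radii, probe, 960)

        def oracle(center, rad, other, orad, n=400_000):
            rng = np.random.default_rng(0)
            v = rng.normal(size=(n, 3))
            v /= np.linalg.norm(v, axis=1)[:, None]
            pts = center + rad * v
            free = np.linalg.norm(pts - other, axis=1) >= orad
            return free.mean() * 4 * np.pi * rad ** 2

        exp0 = oracle(coords[0], r1 + probe, coords[1], r2 + probe)
        exp1 = oracle(coords[1], r2 + probe, coords[0], r1 + probe)
        assert areas[0] == pytest.approx(exp0, rel=0.02)
        assert areas[1] == pytest.approx(exp1, rel=0.02)

    def test_unknown_element_radius_raises(self):
        s = bead_structure(np.zeros((1, 3)), [0.0])
        s.atom_radii = None
        s.elements = np.array(["XX"])
        with pytest.raises(ParameterError):
            compute_sasa(s)

    def test_negative_values_rejected_by_profile(self):
        from grestlite.selection import SasaProfile
        with pytest.raises(ValidationError):
            SasaProfile(residue_ids=np.array([1]), values=np.array([-1.0]),
                        probe_radius=1.4, n_points=960)


class TestInterfaceResidues:
    def test_far_separated_domains_give_empty_set(self):
        coords = np.vstack([np.zeros((4, 3)), np.full((4, 3), 100.0)]) \
            + np.arange(8)[:, None] * [0.0, 3.0, 0.0]
        s = bead_structure(coords, np.zeros(8))
        dom = make_domains(ntd=[(1, 3)], ctd=[(5, 8)], hinge=[(4, 4)])
        assert identify_interface_residues(s, dom, 5.0) == frozenset()

    def test_symmetric_in_domain_order(self, toy_system):
        s = toy_system.to_structure("closed")
        dom = toy_system.domains
        from dataclasses import replace
        swapped = make_domains(
            ntd=[(min(dom.ctd), max(dom.ctd))],
            ctd=[(min(dom.ntd), max(dom.ntd))],
            hinge=[(min(dom.hinge), max(dom.hinge))])
        a = identify_interface_residues(s, dom, 8.0)
        b = identify_interface_residues(s, swapped, 8.0)
        assert a == b

    def test_toy_interface_contains_planted_pairs(self, toy_system):
        s = toy_system.to_structure("closed")
        ifc = identify_interface_residues(
            s, toy_system.domains, toy_system.sscr_params.interface_cutoff)
        for i, j in toy_system.planted["interface_pairs"]:
            assert i + 1 in ifc and j + 1 in ifc

    def test_empty_domain_rejected(self, toy_system):
        s = toy_system.to_structure("closed")
        dom = toy_system.domains
        bad = Structure(
            atom_names=s.atom_names, elements=np.full(s.n_atoms, "H"),
            res_ids=s.res_ids, res_names=s.res_names, coords=s.coords,
            masses=s.masses, formal_charges=s.formal_charges)
        with pytest.raises(ValidationError):
            identify_interface_residues(bad, dom, 5.0)


class TestSelectSscr:
    @pytest.mark.parametrize("n,seed", [(10, 7), (20, 1)])
    def test_planted_interface_and_hinge_exactly_recovered(self, n, seed):
        system = build_two_domain_system(n_per_domain=n, seed=seed) \
            if (n, seed) != (10, 7) else None
        system = system or build_two_domain_system()
        region = select_sscr(
            [system.to_structure("closed"), system.to_structure("open")],
            system.domains, system.sscr_params)
        planted = {b + 1 for b in system.planted["interface_charged"]} \
            | {b + 1 for b in system.planted["hinge_charged"]}
        assert set(region.residues) == planted
        assert region.net_charge == 0
        for b in system.planted["distant_charged"]:
            assert b + 1 not in region.residues

    def test_hinge_charges_selected_via_criterion_ii(self, toy_system):
        region = select_sscr(
            [toy_system.to_structure("closed"),
             toy_system.to_structure("open")],
            toy_system.domains, toy_system.sscr_params)
        for b in toy_system.planted["hinge_charged"]:
            assert region.provenance[b + 1] == "hinge"

    def test_selection_is_deterministic(self, toy_system):
        args = ([toy_system.to_structure("closed"),
                 toy_system.to_structure("open")],
                toy_system.domains, toy_system.sscr_params)
        assert select_sscr(*args).residues == select_sscr(*args).residues

    def test_enlarging_cutoff_never_removes_interface_members(self,
                                                              toy_system):
        structures = [toy_system.to_structure("closed"),
                      toy_system.to_structure("open")]
        base = toy_system.sscr_params
        small = select_sscr(structures, toy_system.domains, base)
        from dataclasses import replace
        big = select_sscr(structures, toy_system.domains,
                          replace(base, ca_cutoff=base.ca_cutoff + 4.0))
        kept = {r for r, t in small.provenance.items() if t == "interface"}
        got = {r for r, t in big.provenance.items()
               if t in ("interface", "hinge")}
        assert kept <= got | set(big.residues)

    def test_neutrality_completion_orders_by_interface_distance(self):
        # two domains; one excess + at the interface; two eligible − at
        # different distances: the nearer one completes the region
        coords = np.array([
            [0, 0, 0], [4, 0, 0], [8, 0, 0], [12, 0, 0],        # NTD
            [16, 0, 0], [20, 0, 0],                             # hinge
            [24, 0, 0], [28, 0, 0], [32, 0, 0], [36, 0, 0],     # CTD
        ], dtype=float)
        charges = np.array([0, 0, 0, 1, 0, 0, 0, 0, -1, -1])
        s = bead_structure(coords, charges, radii=2.0)
        dom = make_domains(ntd=[(1, 4)], ctd=[(7, 10)], hinge=[(5, 6)])
        # cutoff 13 Å makes exactly residues 4 and 7 the interface; the
        # negative charges at residues 9 and 10 are outside the 6 Å Cα
        # criterion, so neutrality completion must pick the nearer one
        region = select_sscr([s], dom,
                             SscrParams(ca_cutoff=6.0, sasa_threshold=5.0,
                                        interface_cutoff=13.0))
        assert region.net_charge == 0
        assert region.provenance[9] == "neutrality"
        assert 10 not in region.residues

    def test_unreachable_neutrality_is_an_error(self):
        coords = np.array([[0, 0, 0], [4, 0, 0], [8, 0, 0], [12, 0, 0],
                           [16, 0, 0], [20, 0, 0]], dtype=float)
        charges = np.array([0, 1, 0, 0, 0, 0])
        s = bead_structure(coords, charges, radii=2.0)
        dom = make_domains(ntd=[(1, 2)], ctd=[(5, 6)], hinge=[(3, 4)])
        with pytest.raises(SelectionError):
            select_sscr([s], dom,
                        SscrParams(ca_cutoff=100.0, sasa_threshold=5.0,
                                   interface_cutoff=100.0))


class TestCountSoluteAtoms:
    def test_empty_region(self):
        region = SoluteRegion(residues=frozenset(), atoms=(), net_charge=0,
                              provenance={}, residue_names={})
        assert count_solute_atoms(region) == 0

    def test_single_aspartate(self):
        region = SoluteRegion(residues=frozenset([67]), atoms=(),
                              net_charge=-1, provenance={67: "interface"},
                              residue_names={67: "ASP"})
        assert count_solute_atoms(region) == 12

    def test_published_22_residue_region_has_393_atoms(self):
        region = rbp_solute_region()
        assert region.n_residues == 22
        counts = list(region.residue_names.values())
        assert counts.count("ARG") == 5 and counts.count("LYS") == 6
        assert counts.count("ASP") == 8 and counts.count("GLU") == 3
        assert count_solute_atoms(region) == 393

    def test_missing_residue_name_raises(self):
        region = SoluteRegion(residues=frozenset([1]), atoms=(),
                              net_charge=0, provenance={1: "hinge"},
                              residue_names={1: "CGU"})
        with pytest.raises(ParameterError):
            count_solute_atoms(region)

    def test_provenance_must_cover_members(self):
        with pytest.raises(ValidationError):
            SoluteRegion(residues=frozenset([1, 2]), atoms=(), net_charge=0,
                         provenance={1: "hinge"}, residue_names={})
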