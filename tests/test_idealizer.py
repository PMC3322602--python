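"""Embedding and restrained idealization."""

import numpy as np
import pytest

from linksmith import idealizer
from linksmith.errors import CoordinateError, EmbedError
from linksmith.idealizer import IdealizerConfig, _Compiled, _objective
from linksmith.molgraph import AtomSpec, BondSpec, MonomerDescription, chiral_volume


def ideal_coords(mon, seed=7):
    coords = idealizer.embed(mon, seed=seed)
    coords, report = idealizer.regularize(mon, coords)
    return coords, report


class TestEmbed:
    def test_single_atom_at_origin(self):
        desc = MonomerDescription(code="ONE")
        desc.add_atom(AtomSpec("C1", "C"))
        coords = idealizer.embed(desc, seed=0)
        assert np.allclose(coords["C1"], 0.0)

    def test_same_seed_is_deterministic(self, lys):
        c1 = idealizer.embed(lys, seed=9)
        c2 = idealizer.embed(lys, seed=9)
        for n in lys.atoms:
            assert np.allclose(c1[n], c2[n])

    def test_different_seeds_differ_but_both_regularize(self, ala):
        c1 = idealizer.embed(ala, seed=1)
        c2 = idealizer.embed(ala, seed=2)
        assert any(not np.allclose(c1[n], c2[n]) for n in ala.atoms)
        for coords in (c1, c2):
            _, report = idealizer.regularize(ala, coords)
            assert report.converged

    def test_minimum_spacing(self, plp):
        coords = idealizer.embed(plp, seed=3)
        names = list(coords)
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                assert np.linalg.norm(coords[a] - coords[b]) >= 0.7

    def test_disconnected_graph_is_rejected(self):
        desc = MonomerDescription(code="TWO")
        desc.add_atom(AtomSpec("C1", "C"))
        desc.add_atom(AtomSpec("C2", "C"))
        with pytest.raises(EmbedError, match="disconnected"):
            idealizer.embed(desc, seed=0)


class TestRegularize:
    def test_already_ideal_coordinates_are_fixed_point(self, gly):
        coords, report = ideal_coords(gly)
        assert report.converged
        again, report2 = idealizer.regularize(gly, coords)
        assert report2.iterations <= 1
        for n in gly.atoms:
            assert np.allclose(coords[n], again[n], atol=1e-6)

    def test_objective_never_increases(self, cys_start):
        mon, start = cys_start
        f0 = idealizer.residuals(mon, start).objective
        _, report = idealizer.regularize(mon, start)
        assert report.objective <= f0 + 1e-9

    def test_wrong_chirality_start_is_corrected(self, ala):
        coords, _ = ideal_coords(ala, seed=13)
        # mirror the whole molecule: CA volume flips to the wrong sign
        mirrored = {n: np.array([p[0], p[1], -p[2]]) for n, p in coords.items()}
        ch = ala.chirals[0]
        assert chiral_volume(mirrored[ch.centre], mirrored[ch.atom1],
                             mirrored[ch.atom2], mirrored[ch.atom3]) > 0
        out, report = idealizer.regularize(ala, mirrored)
        vol = chiral_volume(out[ch.centre], out[ch.atom1], out[ch.atom2],
                            out[ch.atom3])
        assert vol < -0.1  # declared negative

    def test_missing_coordinate_raises(self, gly):
        with pytest.raises(CoordinateError):
            idealizer.regularize(gly, {"N": np.zeros(3)})


@pytest.fixture()
def cys_start(library):
    mon = library.monomers["CYS"].copy()
    return mon, idealizer.embed(mon, seed=21)


class TestResiduals:
    def test_ideal_coordinates_have_zero_rows(self, gly):
        coords, _ = ideal_coords(gly)
        report = idealizer.residuals(gly, coords)
        for row in report.rows:
            assert abs(row.deviation) < 2e-3, row

    def test_stretched_bond_shows_up_once(self, gly):
        coords, _ = ideal_coords(gly)
        bond = gly.bonds[0]
        direction = coords[bond.atom2] - coords[bond.atom1]
        direction /= np.linalg.norm(direction)
        # stretch a terminal atom along its own bond only
        coords2 = dict(coords)
        coords2[bond.atom1] = coords[bond.atom1] - 0.1 * direction
        report = idealizer.residuals(gly, coords2)
        rows = [r for r in report.rows if r.kind == "bond"
                and set(r.atoms) == set((bond.atom1, bond.atom2))]
        assert rows[0].deviation == pytest.approx(0.1, abs=1e-6)

    def test_maxima_match_rows(self, lys):
        rng = np.random.default_rng(5)
        coords, _ = ideal_coords(lys)
        noisy = {n: p + rng.normal(scale=0.05, size=3)
                 for n, p in coords.items()}
        report = idealizer.residuals(lys, noisy)
        for kind in ("bond", "angle", "torsion", "plane", "chirality"):
            rows = [abs(r.deviation) for r in report.rows if r.kind == kind]
            if rows:
                assert report.maxima[kind] == pytest.approx(max(rows))


class TestObjective:
    def test_gradient_matches_finite_differences(self, gly):
        comp = _Compiled(gly, IdealizerConfig())
        rng = np.random.default_rng(0)
        x = rng.normal(scale=2.0, size=3 * len(gly.atoms))
        f, g = _objective(x, comp)
        eps = 1e-6
        for i in rng.choice(len(x), size=12, replace=False):
            xp, xm = x.copy(), x.copy()
            xp[i] += eps
            xm[i] -= eps
            num = (_objective(xp, comp)[0] - _objective(xm, comp)[0]) / (2 * eps)
            assert g[i] == pytest.approx(num, rel=1e-4, abs=1e-5)

    def test_rigid_motion_invariance(self, plp):
        comp = _Compiled(plp, IdealizerConfig())
        coords, _ = ideal_coords(plp, seed=2)
        x = np.array([coords[n] for n in plp.atoms])
        f0, _ = _objective(x.ravel(), comp)
        rng = np.random.default_rng(8)
        for _ in range(3):
            q = rng.normal(size=(3, 3))
            rot, _r = np.linalg.qr(q)
            if np.linalg.det(rot) < 0:
                rot[:, 0] *= -1
            moved = x @ rot.T + rng.normal(scale=5.0, size=3)
            f1, _ = _objective(moved.ravel(), comp)
            assert f1 == pytest.approx(f0, abs=1e-6)


class TestWritePdb:
    def test_hetatm_records_round_trip_coordinates(self, gly):
        coords, _ = ideal_coords(gly)
        text = idealizer.write_pdb(gly, coords)
        from linksmith.completion import read_pdb_atoms
        atoms = read_pdb_atoms(text)
        assert [a.name for a in atoms] == list(gly.atoms)
        for a in atoms:
            assert np.allclose(a.xyz, coords[a.name], atol=1e-3)
        assert all(" 1.00 20.00" in line for line in text.splitlines()
                   if line.startswith("HETATM"))
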