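import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hrpfsasa.sasa import (
    ensemble_mean_sasa,
    residue_sidechain_sasa,
    shrake_rupley,
    unit_sphere_points,
)
from hrpfsasa.structure import Ensemble, StructureModel
from tests.conftest import make_atom


def single_atom_model(radius=1.7):
    return StructureModel("one", [make_atom(radius=radius)])


def sphere_area(r):
    return 4.0 * np.pi * r * r


class TestShrakeRupley:
    def test_isolated_atom_matches_sphere_area(self):
        sasa = shrake_rupley(single_atom_model(1.7), 1.4, 960)
        assert sasa[0] == pytest.approx(sphere_area(3.1), rel=0.01)

    def test_distant_atoms_unoccluded(self):
        model = StructureModel(
            "two",
            [make_atom(1, coords=(0, 0, 0), radius=1.7),
             make_atom(2, resseq=2, coords=(10.0, 0, 0), radius=1.7)],
        )
        sasa = shrake_rupley(model, 1.4, 960)
        np.testing.assert_allclose(sasa, sphere_area(3.1), rtol=1e-12)

    @pytest.mark.parametrize("separation", [2.0, 3.5, 5.0])
    def test_partial_overlap_matches_cap_formula(self, separation):
        """Two equal inflated spheres: exposed area has a closed form via
        the spherical-cap construction."""
        r = 1.7 + 1.4
        model = StructureModel(
            "pair",
            [make_atom(1, coords=(0, 0, 0), radius=1.7),
             make_atom(2, resseq=2, coords=(separation, 0, 0), radius=1.7)],
        )
        sasa = shrake_rupley(model, 1.4, 960)
        # cap of height h removed from each sphere
        h = r - separation / 2.0
        expected = sphere_area(r) - 2.0 * np.pi * r * h
        assert sasa[0] == pytest.approx(expected, rel=0.02)
        assert sasa[1] == pytest.approx(expected, rel=0.02)

    def test_fully_buried_atom_is_zero(self):
        # central atom enclosed by a tight shell of 26 larger atoms
        shell = []
        serial = 2
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for dz in (-1, 0, 1):
                    if dx == dy == dz == 0:
                        continue
                    shell.append(
                        make_atom(serial, "CB", "C", "ALA", "B", serial,
                                  coords=(2.5 * dx, 2.5 * dy, 2.5 * dz), radius=2.0)
                    )
                    serial += 1
        model = StructureModel("buried", [make_atom(1, radius=1.5)] + shell)
        sasa = shrake_rupley(model, 1.4, 960)
        assert sasa[0] == 0.0

    def test_coincident_equal_atoms_well_defined(self):
        model = StructureModel(
            "coincident",
            [make_atom(1, coords=(0, 0, 0), radius=1.7),
             make_atom(2, resseq=2, coords=(0, 0, 0), radius=1.7)],
        )
        sasa = shrake_rupley(model, 1.4, 960)
        assert np.all(np.isfinite(sasa))
        assert sasa[0] == pytest.approx(sasa[1])

    def test_convergence_with_point_count(self):
        errors = []
        for n in (96, 960, 4800):
            sasa = shrake_rupley(single_atom_model(1.7), 1.4, n)
            errors.append(abs(sasa[0] - sphere_area(3.1)) / sphere_area(3.1))
        assert errors[1] < 0.01
        assert errors[2] <= errors[1] + 1e-12

    def test_deterministic_point_generation(self):
        a = unit_sphere_points(960)
        b = unit_sphere_points(960)
        assert a is b or np.array_equal(a, b)
        np.testing.assert_allclose(np.linalg.norm(a, axis=1), 1.0, atol=1e-12)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            shrake_rupley(single_atom_model(), 1.4, 16)
        with pytest.raises(ValueError):
            shrake_rupley(single_atom_model(), -0.1, 960)

    @settings(deadline=None, max_examples=15, derandomize=True)
    @given(
        st.lists(
            st.tuples(
                st.floats(-4, 4), st.floats(-4, 4), st.floats(-4, 4)
            ),
            min_size=1, max_size=5, unique=True,
        )
    )
    def test_monotone_occlusion(self, extra_coords):
        """Adding atoms can only reduce any existing atom's SASA."""
        base = single_atom_model(1.7)
        sasa_alone = shrake_rupley(base, 1.4, 240)[0]
        atoms = list(base.atoms) + [
            make_atom(i + 2, "CB", "C", "ALA", "B", i + 2, coords=c, radius=1.7)
            for i, c in enumerate(extra_coords)
        ]
        sasa_crowded = shrake_rupley(StructureModel("crowd", atoms), 1.4, 240)[0]
        assert sasa_crowded <= sasa_alone + 1e-9


class TestIndependentCrossCheck:
    @pytest.mark.parametrize("resname", ["TRP", "LEU", "ARG"])
    def test_agrees_with_biotite_on_tripeptide(self, resname):
        """An independent Shrake–Rupley implementation (biotite) reproduces
        our per-atom SASA on realistic tripeptide geometry."""
        import biotite.structure as struc

        from hrpfsasa.gxg import build_gxg_model

        model = build_gxg_model(resname, chi1=30.0)
        arr = struc.AtomArray(len(model.atoms))
        for i, a in enumerate(model.atoms):
            arr.coord[i] = a.coords
            arr.atom_name[i] = a.name
            arr.element[i] = a.element
            arr.res_id[i] = a.residue_seq
            arr.res_name[i] = a.residue_name
            arr.chain_id[i] = a.chain_id
        radii = np.array([a.vdw_radius for a in model.atoms])
        reference = struc.sasa(arr, probe_radius=1.4, point_number=960,
                               vdw_radii=radii)
        ours = shrake_rupley(model, 1.4, 960)
        np.testing.assert_allclose(ours, reference, atol=0.05)


class TestResidueSASA:
    def test_lone_ala_sidechain_is_cb_only(self, simple_model):
        atom_sasa = shrake_rupley(simple_model, 1.4, 960)
        residues = residue_sidechain_sasa(simple_model, 1.4, 960)
        cb_indices = [i for i, a in enumerate(simple_model.atoms) if a.name == "CB"]
        for res, cb_i in zip(residues, cb_indices):
            assert res.mean_sasa == pytest.approx(atom_sasa[cb_i])

    def test_partition_of_total_sasa(self, simple_model):
        """Whole-residue sums reproduce the summed per-atom SASA exactly."""
        atom_sasa = shrake_rupley(simple_model, 1.4, 960)
        whole = residue_sidechain_sasa(simple_model, 1.4, 960, mode="all")
        assert sum(r.mean_sasa for r in whole) == pytest.approx(atom_sasa.sum(), abs=1e-9)

    def test_glycine_flagged_zero(self):
        model = StructureModel(
            "gly",
            [make_atom(1, "N", "N", "GLY"), make_atom(2, "CA", "C", "GLY", coords=(1.5, 0, 0))],
        )
        (res,) = residue_sidechain_sasa(model, 1.4, 96)
        assert res.mean_sasa == 0.0
        assert res.no_sidechain

    def test_buried_trp_below_surface_trp(self):
        """Identical side-chain pairs, one surrounded by an occluding shell."""
        def trp_at(resseq, chain, center):
            return [
                make_atom(resseq * 10, "CA", "C", "TRP", chain, resseq, center),
                make_atom(resseq * 10 + 1, "CB", "C", "TRP", chain, resseq,
                          (center[0] + 1.8, center[1], center[2])),
            ]

        surface = trp_at(1, "A", (0.0, 0.0, 0.0))
        buried = trp_at(2, "B", (50.0, 0.0, 0.0))
        shell = [
            make_atom(100 + i, "CB", "C", "ALA", "C", 100 + i,
                      (50.0 + 1.8 + 3.0 * np.cos(t), 3.0 * np.sin(t), z), radius=2.0)
            for i, (t, z) in enumerate(
                (t, z) for t in np.linspace(0, 2 * np.pi, 8, endpoint=False)
                for z in (-2.0, 0.0, 2.0)
            )
        ]
        model = StructureModel("pair", surface + buried + shell)
        residues = {r.residue_key: r for r in residue_sidechain_sasa(model, 1.4, 240)}
        assert residues[("B", 2, "TRP")].mean_sasa < residues[("A", 1, "TRP")].mean_sasa


class TestEnsembleSASA:
    def test_identical_models_zero_sd(self, simple_model):
        ens = Ensemble([simple_model, simple_model, simple_model])
        residues = ensemble_mean_sasa(ens, 1.4, 240)
        singles = residue_sidechain_sasa(simple_model, 1.4, 240)
        for r, s in zip(residues, singles):
            assert r.sd_sasa == 0.0
            assert r.mean_sasa == pytest.approx(s.mean_sasa)
            assert r.n_models == 3

    def test_mean_and_population_sd(self, simple_model):
        from dataclasses import replace

        # residue 2 packs against residue 1 in the second model only
        moved = [
            replace(a, coords=a.coords - (15.0 if a.residue_seq == 2 else 0.0) * np.array([1.0, 0, 0]))
            for a in simple_model.atoms
        ]
        ens = Ensemble([simple_model, StructureModel("m2", moved)])
        residues = ensemble_mean_sasa(ens, 1.4, 240)
        per_model = [
            residue_sidechain_sasa(m, 1.4, 240) for m in ens.models
        ]
        for i, r in enumerate(residues):
            vals = np.array([pm[i].mean_sasa for pm in per_model])
            assert r.mean_sasa == pytest.approx(vals.mean())
            assert r.sd_sasa == pytest.approx(vals.std())  # population SD

    def test_degenerate_weights_select_one_model(self, simple_model):
        other = simple_model.translated((0.3, 0.0, 0.0))
        ens = Ensemble([simple_model, StructureModel("m2", other.atoms)],
                       weights=np.array([1.0, 0.0]))
        residues = ensemble_mean_sasa(ens, 1.4, 240)
        singles = residue_sidechain_sasa(simple_model, 1.4, 240)
        for r, s in zip(residues, singles):
            assert r.mean_sasa == pytest.approx(s.mean_sasa)
            assert r.sd_sasa == pytest.approx(0.0, abs=1e-9)
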