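import numpy as np
import pandas as pd
import pytest

from trpscope import synthetic as syn
from trpscope.descriptors import (
    burstein_class,
    compute_acc,
    compute_den2,
    compute_ep_delta,
    descriptor_change,
    descriptor_table,
    locate_indole,
)
from trpscope.potential import PotentialGrid
from trpscope.structures import (
    Atom,
    Structure,
    read_pdb,
    read_pqr,
    read_structure,
    write_pdb,
    write_pqr,
)


def rotated(structure: Structure, rot: np.ndarray, shift=np.zeros(3)) -> Structure:
    atoms = [
        Atom(a.name, a.element, a.residue_name, a.residue_number, a.chain,
             rot @ a.pos + shift, a.charge, a.radius)
        for a in structure.atoms
    ]
    return Structure(atoms, structure.source_format)


class TestStructureIO:
    def test_pqr_atom_count_matches_generator(self, tmp_path):
        s = syn.make_toy_structure(2, 25, seed=1)
        path = tmp_path / "t.pqr"
        write_pqr(s, path)
        assert len(read_pqr(path)) == len(s)

    def test_pdb_lacks_charges_flagged(self, tmp_path):
        s = syn.make_toy_structure(1, 5, seed=1)
        path = tmp_path / "t.pdb"
        write_pdb(s, path)
        back = read_pdb(path)
        assert not back.has_charges

    def test_incomplete_trp_flagged(self):
        s = syn.make_toy_structure(1, 0, seed=0)
        pruned = Structure([a for a in s.atoms if a.name != "CZ3"], "PQR")
        assert pruned.incomplete_tryptophans() == [("A", 1)]
        with pytest.raises(ValueError):
            locate_indole(pruned, ("A", 1))
        assert descriptor_table(pruned).empty

    def test_malformed_pqr_reports_line(self, tmp_path):
        path = tmp_path / "bad.pqr"
        path.write_text("ATOM 1 CA TRP A 1 0.0 0.0\n")
        with pytest.raises(ValueError, match="line 1"):
            read_pqr(path)

    def test_format_inference(self, tmp_path):
        s = syn.make_toy_structure(1, 0, seed=0)
        write_pqr(s, tmp_path / "a.pqr")
        assert read_structure(tmp_path / "a.pqr").source_format == "PQR"


class TestIndoleFrame:
    def test_axis_unit_and_separation(self):
        s = syn.make_toy_structure(1, 0, seed=3)
        f = locate_indole(s, ("A", 1))
        assert np.linalg.norm(f.axis) == pytest.approx(1.0)
        assert 1.8 <= f.centroid_separation <= 2.5

    def test_rotation_equivariance(self):
        from scipy.spatial.transform import Rotation

        s = syn.make_toy_structure(1, 0, seed=3)
        rot = Rotation.from_euler("xyz", [0.3, -1.1, 2.0]).as_matrix()
        f0 = locate_indole(s, ("A", 1))
        f1 = locate_indole(rotated(s, rot, np.array([5.0, -2.0, 1.0])), ("A", 1))
        assert np.allclose(f1.axis, rot @ f0.axis, atol=1e-12)
        assert f1.centroid_separation == pytest.approx(f0.centroid_separation)


class TestDen2:
    def test_isolated_trp_zero(self):
        s = syn.make_toy_structure(1, 0, seed=0)
        assert compute_den2(s, locate_indole(s, ("A", 1))) == 0

    def test_cutoff_boundary(self):
        s = syn.make_toy_structure(1, 0, seed=0)
        frame = locate_indole(s, ("A", 1))
        ring = np.array([a.pos for a in frame.ring_atoms])
        # decoy placed at a controlled distance from its nearest ring atom
        direction = np.array([0.0, 0.0, 1.0])  # ring lies in z=0 before rotation
        base = ring[0]
        for dist, expected in ((7.4, 1), (7.6, 0)):
            probe = Atom("C", "C", "DEC", 999, "X", base + dist * direction)
            s2 = Structure(s.atoms + [probe], "PQR")
            d_min = np.linalg.norm(ring - probe.pos, axis=1).min()
            assert d_min == pytest.approx(dist, abs=1e-9)
            assert compute_den2(s2, frame) == expected

    def test_matches_brute_force_on_random_structures(self):
        for seed in range(6):
            s = syn.make_toy_structure(2, 80, seed=seed)
            for trp_id in s.tryptophans():
                frame = locate_indole(s, trp_id)
                ring = np.array([a.pos for a in frame.ring_atoms])
                brute = 0
                for a in s.atoms:
                    if a.is_hydrogen:
                        continue
                    if (a.chain, a.residue_number) == trp_id:
                        continue
                    dmin = min(np.linalg.norm(ring - a.pos, axis=1))
                    brute += dmin < 7.5
                assert compute_den2(s, frame) == brute

    def test_hydrogens_and_own_residue_excluded(self):
        s = syn.make_toy_structure(1, 0, seed=0)
        frame = locate_indole(s, ("A", 1))
        h = Atom("H1", "H", "DEC", 999, "X", frame.benzene_centroid + 3.0)
        assert compute_den2(Structure(s.atoms + [h], "PQR"), frame) == 0


class TestAcc:
    def test_buried_trp_near_zero(self):
        s = syn.make_toy_structure(1, 0, seed=0)
        # enclose the indole in two dense Fibonacci-sphere shells of atoms
        center = s.coords.mean(axis=0)
        shell = []
        idx = 0
        golden = np.pi * (3.0 - np.sqrt(5.0))
        for radius, n in ((6.0, 350), (8.3, 550)):
            for i in range(n):
                z = 1.0 - 2.0 * (i + 0.5) / n
                r_xy = np.sqrt(1.0 - z * z)
                theta = golden * i
                v = radius * np.array(
                    [r_xy * np.cos(theta), r_xy * np.sin(theta), z]
                )
                shell.append(Atom("C", "C", "SHL", 2000 + idx, "X", center + v, 0.0, 1.9))
                idx += 1
        buried = Structure(s.atoms + shell, "PQR")
        assert compute_acc(buried, ("A", 1)) < 1.0

    def test_exposure_monotonicity(self):
        s = syn.make_toy_structure(1, 0, seed=0)
        crowd = [
            Atom("C", "C", "DEC", 1000 + i, "X", pos, 0.0, 1.8)
            for i, pos in enumerate(
                np.random.default_rng(1).uniform(-6, 6, (60, 3))
            )
        ]
        crowded = Structure(s.atoms + crowd, "PQR")
        assert compute_acc(crowded, ("A", 1)) < compute_acc(s, ("A", 1))

    def test_rotation_invariance(self):
        from scipy.spatial.transform import Rotation

        s = syn.make_toy_structure(1, 20, seed=4)
        rot = Rotation.from_euler("zyx", [1.0, 0.2, -0.7]).as_matrix()
        a0 = compute_acc(s, ("A", 1))
        a1 = compute_acc(rotated(s, rot), ("A", 1))
        assert a1 == pytest.approx(a0, rel=0.05)  # Shrake-Rupley mesh jitter


class TestBursteinClass:
    @pytest.mark.parametrize(
        "value, kind, expected",
        [
            (12.1, "acc", "II"),
            (0.9, "acc", "S"),
            (7.1, "acc", "I"),
            (7.9, "acc", "I/II"),
            (25.0, "acc", "III"),
            (110, "den2", "II"),
            (143, "den2", "S"),
            (126, "den2", "I"),
            (121, "den2", "I/II"),
        ],
    )
    def test_calibrated_labels(self, value, kind, expected):
        assert burstein_class(value, kind) == expected

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            burstein_class(-1.0, "acc")
        with pytest.raises(ValueError):
            burstein_class(float("nan"), "den2")
        with pytest.raises(ValueError):
            burstein_class(1.0, "bogus")


class TestEPDelta:
    def grid_linear(self, g=1.0):
        x = np.arange(-8.0, 9.0, 1.0)
        X, _, _ = np.meshgrid(x, x, x, indexing="ij")
        return PotentialGrid((-8, -8, -8), (1, 1, 1), g * X)

    def test_uniform_grid_zero_delta(self):
        x = np.arange(-8.0, 9.0, 1.0)
        grid = PotentialGrid((-8, -8, -8), (1, 1, 1), np.full((17, 17, 17), 4.2))
        s = syn.make_toy_structure(1, 0, seed=0)
        out = compute_ep_delta(grid, locate_indole(s, ("A", 1)))
        assert out["delta"] == pytest.approx(0.0, abs=1e-12)

    def test_linear_field_projects_on_axis(self):
        s = syn.make_toy_structure(1, 0, seed=2)
        frame = locate_indole(s, ("A", 1))
        g = 1.7
        out = compute_ep_delta(self.grid_linear(g), frame)
        expected = g * (frame.pyrrole_centroid[0] - frame.benzene_centroid[0])
        assert out["delta"] == pytest.approx(expected, rel=1e-9)
        assert out["delta"] == pytest.approx(
            g * frame.axis[0] * frame.centroid_separation, rel=1e-9
        )

    def test_antisymmetric_under_ring_exchange(self):
        s = syn.make_toy_structure(1, 0, seed=2)
        frame = locate_indole(s, ("A", 1))
        grid = self.grid_linear(2.0)
        out = compute_ep_delta(grid, frame)
        from trpscope.descriptors import IndoleFrame

        swapped = IndoleFrame(
            frame.trp_id, frame.pyrrole_centroid, frame.benzene_centroid,
            -frame.axis, frame.ring_atoms,
        )
        assert compute_ep_delta(grid, swapped)["delta"] == pytest.approx(
            -out["delta"], rel=1e-12
        )


class TestDescriptorChange:
    def make_table(self, acc_values):
        return pd.DataFrame(
            {
                "chain": ["A", "B"],
                "residue": [133, 133],
                "acc": acc_values,
                "den2": [143, 145],
                "delta": [0.8, 1.0],
            }
        )

    def test_identity(self):
        t = self.make_table([1.14, 1.2])
        out = descriptor_change(t, t)
        assert np.allclose(out["acc_ratio"], 1.0)
        assert np.allclose(out["acc_diff"], 0.0)

    def test_fold_change_mean(self):
        # apo -> inhibitor-bound accessibility jump for the reoriented Trp
        a = self.make_table([1.14, 1.2])
        b = self.make_table([2.8, 2.7])
        out = descriptor_change(a, b)
        assert round(out.attrs["mean_acc_ratio"][133], 2) == 2.35

    def test_mismatched_ids_rejected(self):
        a = self.make_table([1.0, 1.0])
        b = a.copy()
        b["residue"] = [75, 84]
        with pytest.raises(ValueError):
            descriptor_change(a, b)


class TestDescriptorTable:
    def test_full_table_on_toy_structure(self):
        s = syn.make_toy_structure(2, 40, seed=6)
        coords = s.coords
        lo = coords.min(axis=0) - 5.0
        hi = coords.max(axis=0) + 5.0
        from trpscope.potential import SolventModel, grid_from_structure

        dims = np.maximum(((hi - lo) / 2.0).astype(int) + 1, 2)
        grid = grid_from_structure(
            s, SolventModel(), lo, (hi - lo) / (dims - 1), dims
        )
        table = descriptor_table(s, grid)
        assert len(table) == 2
        assert np.allclose(
            table["delta"], table["ep_pyrrole"] - table["ep_benzene"], atol=1e-9
        )
        assert set(table["acc_class"]) <= {"S", "I", "I/II", "II", "III"}
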