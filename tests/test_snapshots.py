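"""Snapshot protocol: replication, extraction, shells, QM/MM, RDF."""

import numpy as np
import pytest

from ecrism.fixtures import FixtureSpec, make_water_box
from ecrism.snapshots import (
    FIRST_SHELL_RADIUS,
    TrajectoryFrame,
    assign_shells,
    compute_rdf,
    extract_spherical_cluster,
    infer_mol_ids,
    qmmm_partition,
    read_frames,
    vertical_desolvation,
    write_frames_extxyz,
    write_qm_deck,
)


@pytest.fixture(scope="module")
def box_frames():
    return make_water_box(FixtureSpec(seed=5, n_waters=60, box_length=13.0,
                                      n_frames=4))


@pytest.fixture(scope="module")
def cluster(box_frames):
    # atom 1 is the nitroxide oxygen of the fragment
    return extract_spherical_cluster(box_frames[0], pivot_atom=1)


class TestFrameIO:
    def test_extxyz_round_trip(self, box_frames, tmp_path):
        p = tmp_path / "frames.extxyz"
        write_frames_extxyz(p, box_frames)
        back = read_frames(p)
        assert len(back) == len(box_frames)
        for a, b in zip(back, box_frames):
            assert a.elements == b.elements
            assert np.allclose(a.coords, b.coords, atol=1e-7)
            assert np.array_equal(a.mol_ids, b.mol_ids)
            assert a.box_length == pytest.approx(b.box_length)

    def test_stride_selects_frames(self, box_frames, tmp_path):
        p = tmp_path / "frames.extxyz"
        write_frames_extxyz(p, box_frames)       # 0, 200, 400, 600 fs
        every = read_frames(p, stride_fs=200)
        assert len(every) == 4
        sparse = read_frames(p, stride_fs=400)
        assert [f.time_fs for f in sparse] == [0.0, 400.0]

    def test_missing_lattice_rejected(self, tmp_path):
        p = tmp_path / "bad.xyz"
        p.write_text("1\nno lattice here\nO 0 0 0 1\n")
        with pytest.raises(ValueError, match="Lattice"):
            read_frames(p)

    def test_malformed_lattice_rejected(self, tmp_path):
        p = tmp_path / "bad.xyz"
        p.write_text('1\nLattice="1 2 3" Properties=species:S:1:pos:R:3\n'
                     "O 0 0 0\n")
        with pytest.raises(ValueError, match="[Ll]attice"):
            read_frames(p, n_solute_atoms=1)

    def test_infer_mol_ids_from_triplets(self):
        els = ["N", "O", "O", "H", "H", "O", "H", "H"]
        ids = infer_mol_ids(els, 2)
        assert list(ids) == [0, 0, 1, 1, 1, 2, 2, 2]
        with pytest.raises(ValueError):
            infer_mol_ids(["N", "O", "H", "O"], 2)

    def test_pdb_with_cryst1(self, box_frames, tmp_path):
        import MDAnalysis as mda
        fr = box_frames[0]
        p = tmp_path / "frame.pdb"
        n = fr.n_atoms
        u = mda.Universe.empty(n, n_residues=len(np.unique(fr.mol_ids)),
                               atom_resindex=fr.mol_ids,
                               trajectory=True)
        u.add_TopologyAttr("names", fr.elements)
        u.add_TopologyAttr("resids",
                           np.arange(1, len(np.unique(fr.mol_ids)) + 1))
        u.atoms.positions = fr.coords
        u.dimensions = [fr.box_length] * 3 + [90, 90, 90]
        u.atoms.write(str(p))
        back = read_frames(p, fmt="pdb")
        assert len(back) == 1
        assert back[0].n_atoms == n
        assert np.allclose(back[0].coords, fr.coords, atol=1e-3)


class TestExtraction:
    def test_extraction_radius_is_box_minus_shell(self, box_frames, cluster):
        L = box_frames[0].box_length
        assert cluster.extraction_radius == pytest.approx(
            L - FIRST_SHELL_RADIUS
        )

    def test_no_split_waters(self, cluster):
        assert cluster.water_coords.shape[1:] == (3, 3)
        # every included water has an intact O-H-H geometry (~1 A bonds)
        for mol in cluster.water_coords:
            assert np.linalg.norm(mol[1] - mol[0]) < 1.2
            assert np.linalg.norm(mol[2] - mol[0]) < 1.2

    def test_all_water_oxygens_within_radius(self, cluster):
        assert np.all(cluster.water_distances <= cluster.extraction_radius)

    def test_clash_free_with_image_pivots(self, box_frames, cluster):
        """No included water O within r_shell of any image pivot."""
        L = box_frames[0].box_length
        pivot = cluster.pivot
        shifts = np.array([[i, j, k] for i in (-1, 0, 1) for j in (-1, 0, 1)
                           for k in (-1, 0, 1) if (i, j, k) != (0, 0, 0)])
        for mol in cluster.water_coords:
            d = np.linalg.norm(mol[0] - (pivot + shifts * L), axis=1)
            assert d.min() > FIRST_SHELL_RADIUS

    def test_water_count_matches_density(self):
        """Count within +-15% of (4/3) pi R^3 rho for a bulk-density box."""
        frames = make_water_box(FixtureSpec(seed=9, n_waters=128,
                                            box_length=15.7, n_frames=1))
        cl = extract_spherical_cluster(frames[0], pivot_atom=1)
        R = cl.extraction_radius
        rho = 128 / 15.7**3
        expected = 4 / 3 * np.pi * R**3 * rho
        assert abs(cl.n_waters - expected) / expected < 0.15

    def test_solute_only_frame(self):
        frame = TrajectoryFrame(
            coords=np.array([[5.0, 5, 5], [5, 5, 6.28]]),
            elements=["N", "O"], mol_ids=np.array([0, 0]), box_length=10.0,
        )
        cl = extract_spherical_cluster(frame, pivot_atom=1)
        assert cl.n_waters == 0
        assert len(cl.solute_elements) == 2

    def test_too_small_box_rejected(self):
        frame = TrajectoryFrame(
            coords=np.array([[1.0, 1, 1], [1, 1, 2.0]]),
            elements=["N", "O"], mol_ids=np.array([0, 0]), box_length=3.0,
        )
        with pytest.raises(ValueError, match="box too small"):
            extract_spherical_cluster(frame, pivot_atom=1)

    def test_non_solute_pivot_rejected(self, box_frames):
        with pytest.raises(ValueError, match="solute"):
            extract_spherical_cluster(box_frames[0], pivot_atom=10)

    def test_translation_invariance_mod_box(self, box_frames):
        """Rigid translation of the frame (mod box) shifts the cluster
        rigidly: same water count and same internal distances."""
        fr = box_frames[0]
        shift = np.array([2.7, -1.3, 0.9])
        fr2 = TrajectoryFrame(
            coords=np.mod(fr.coords + shift, fr.box_length),
            elements=fr.elements, mol_ids=fr.mol_ids,
            box_length=fr.box_length,
        )
        c1 = extract_spherical_cluster(fr, 1)
        c2 = extract_spherical_cluster(fr2, 1)
        assert c1.n_waters == c2.n_waters
        assert np.allclose(np.sort(c1.water_distances),
                           np.sort(c2.water_distances), atol=1e-9)


class TestShellsAndPartitions:
    def test_shell_boundaries(self, cluster):
        shells = assign_shells(cluster)
        d = cluster.water_distances
        assert all(shells.labels[d <= 3.4] == "first")
        assert all(shells.labels[(d > 3.4) & (d <= 5.5)] == "second")
        assert all(shells.labels[d > 5.5] == "outer")

    def test_example_distances(self, cluster):
        from dataclasses import replace
        cl = replace(cluster, water_distances=np.array([3.0, 4.0, 6.0]),
                     water_coords=cluster.water_coords[:3])
        labels = assign_shells(cl).labels
        assert list(labels) == ["first", "second", "outer"]

    def test_invalid_cutoffs_rejected(self, cluster):
        with pytest.raises(ValueError):
            assign_shells(cluster, r1=5.5, r2=3.4)

    def test_vertical_desolvation_preserves_geometry(self, cluster):
        des = vertical_desolvation(cluster)
        assert des.n_atoms == len(cluster.solute_elements)
        assert np.array_equal(des.coords, cluster.solute_coords)
        # idempotent on the geometry: a second strip changes nothing
        assert np.array_equal(vertical_desolvation(cluster).coords,
                              des.coords)

    def test_partition_nesting(self, cluster):
        shells = assign_shells(cluster)
        counts = {}
        for level in ("none", "first", "second", "full"):
            part = qmmm_partition(cluster, level, shells)
            counts[level] = part.qm_water_count
            # QM + MM cover the cluster exactly
            assert part.qm_water_count + part.mm_charges.count // 3 \
                == cluster.n_waters
        assert counts["none"] == 0
        assert counts["none"] <= counts["first"] <= counts["second"] \
            <= counts["full"]
        assert counts["full"] == cluster.n_waters

    def test_partition_counts_hand_constructed(self):
        """2 first-shell + 10 second-shell waters -> 12 QM at level second."""
        rng = np.random.default_rng(77)
        dists = np.concatenate([
            rng.uniform(2.6, 3.3, 2),
            rng.uniform(3.6, 5.4, 10),
            rng.uniform(5.6, 7.5, 5),
        ])
        waters = []
        for d in dists:
            o = np.array([d, 0, 0])
            waters.append([o, o + [0.96, 0, 0], o + [-0.24, 0.93, 0]])
        from ecrism.snapshots import SphericalCluster
        cl = SphericalCluster(
            solute_elements=["N", "O"],
            solute_coords=np.array([[0, 0, -1.28], [0, 0, 0.0]]),
            water_coords=np.array(waters),
            water_distances=dists,
            extraction_radius=10.0,
            pivot_index=1,
        )
        part = qmmm_partition(cl, "second")
        assert part.qm_water_count == 12
        assert part.mm_charges.count == 5 * 3

    def test_mm_charges_are_tip3p(self, cluster):
        part = qmmm_partition(cluster, "none")
        q = part.mm_charges.charges
        assert set(np.round(np.unique(q), 3)) == {-0.834, 0.417}
        assert part.mm_charges.total_charge == pytest.approx(0.0, abs=1e-10)

    def test_qm_deck_files(self, cluster, tmp_path):
        part = qmmm_partition(cluster, "first")
        prefix = tmp_path / "deck"
        write_qm_deck(prefix, part)
        xyz = (tmp_path / "deck.xyz").read_text().splitlines()
        assert int(xyz[0]) == len(part.qm_elements)
        mmq = np.loadtxt(tmp_path / "deck.mmq")
        assert len(mmq) == part.mm_charges.count


class TestRdf:
    def test_ideal_gas_is_flat(self):
        """Uncorrelated positions give g(r)=1 within 3 sigma everywhere."""
        rng = np.random.default_rng(88)
        frames = []
        for _ in range(30):
            n = 80
            frames.append(TrajectoryFrame(
                coords=rng.uniform(0, 10, (3 * n, 3)),
                elements=["O", "H", "H"] * n,
                mol_ids=np.repeat(np.arange(1, n + 1), 3),
                box_length=10.0,
            ))
        r, g, se = compute_rdf(frames, ("O", "water"), ("O", "water"),
                               n_bins=25)
        dev = np.abs(g - 1.0)
        assert np.all(dev <= 3 * se)

    def test_fixed_pair_occupies_single_bin(self):
        d = 3.2
        frame = TrajectoryFrame(
            coords=np.array([[1.0, 1, 1], [1 + d, 1, 1]]),
            elements=["N", "O"], mol_ids=np.array([0, 0]), box_length=12.0,
        )
        r, g, _ = compute_rdf([frame], ("N", "solute"), ("O", "solute"),
                              n_bins=24, r_max=6.0)
        occupied = np.nonzero(g)[0]
        assert len(occupied) == 1
        assert abs(r[occupied[0]] - d) < 0.25

    def test_doubling_frames_shrinks_error(self):
        rng = np.random.default_rng(89)

        def ideal(n_frames, seed):
            r = np.random.default_rng(seed)
            fs = []
            for _ in range(n_frames):
                n = 60
                fs.append(TrajectoryFrame(
                    coords=r.uniform(0, 10, (3 * n, 3)),
                    elements=["O", "H", "H"] * n,
                    mol_ids=np.repeat(np.arange(1, n + 1), 3),
                    box_length=10.0,
                ))
            return fs

        _, _, se1 = compute_rdf(ideal(20, 1), ("O", "water"), ("O", "water"),
                                n_bins=10)
        _, _, se2 = compute_rdf(ideal(80, 2), ("O", "water"), ("O", "water"),
                                n_bins=10)
        ratio = se1.mean() / se2.mean()
        assert 1.5 < ratio < 2.7           # ~2 expected for 4x frames

    def test_r_max_beyond_half_box_rejected(self):
        frame = TrajectoryFrame(
            coords=np.zeros((3, 3)), elements=["O", "H", "H"],
            mol_ids=np.array([1, 1, 1]), box_length=10.0,
        )
        with pytest.raises(ValueError, match="half"):
            compute_rdf([frame], ("O", "water"), ("O", "water"), r_max=6.0)
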