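"""Accessible-volume geometry: helix construction, grid search, metrics."""

import numpy as np
import pytest

from sifi.av import (
    Attachment,
    DuplexSpec,
    EmptyAVError,
    Gap,
    HelixModel,
    LinkerDyeParams,
    Overhang,
    axial_reach,
    build_duplex_model,
    compute_av,
    stacking_fraction,
    write_av_cloud,
)

BLUNT_SEQ = "GCATTGCAGCATTGCAGCATTGCAGCAT"  # 28 bp, T at position 14


@pytest.fixture(scope="module")
def blunt_model():
    spec = DuplexSpec(sequence=BLUNT_SEQ, attachment=Attachment("A", 14))
    return build_duplex_model(spec)


@pytest.fixture(scope="module")
def blunt_av(blunt_model):
    return compute_av(blunt_model)


def overhang_model(offset):
    """Dye strand terminates at a junction; the other strand runs on as
    ssDNA. The dye sits `offset` bases into the duplex (T0/T2/T4 series)."""
    seq = "TGTGT" + "TG" * 11 + "T"
    spec = DuplexSpec(
        sequence=seq,
        features=(Overhang(length=5, polarity="5p", strand="A"),),
        attachment=Attachment("A", 5 + offset),
    )
    return build_duplex_model(spec)


class TestDuplexModel:
    def test_axial_extent_of_10bp_duplex(self):
        model = build_duplex_model(DuplexSpec(sequence="GCATTGCAGC"))
        extent = model.bp_center(9)[2] - model.bp_center(0)[2]
        assert extent == pytest.approx(9 * 3.4, abs=1e-9)

    def test_gap_removes_two_nucleotides_of_atoms(self):
        plain = build_duplex_model(DuplexSpec(sequence=BLUNT_SEQ))
        gapped = build_duplex_model(
            DuplexSpec(sequence=BLUNT_SEQ, features=(Gap(positions=(10, 11), strand="B"),))
        )
        per_nt = 3  # backbone, sugar, base spheres
        assert plain.n_atoms - gapped.n_atoms == 2 * per_nt

    def test_full_turn_at_ten_bp(self):
        model = build_duplex_model(DuplexSpec(sequence=BLUNT_SEQ))
        assert model.azimuth(10) == pytest.approx(model.azimuth(0), abs=1e-9)
        assert model.azimuth(5) != pytest.approx(model.azimuth(0))

    def test_non_complementary_pair_rejected(self):
        with pytest.raises(ValueError, match="complementary"):
            DuplexSpec(sequence="GCATGCAT", sequence_b="GCATGCAT")

    def test_purine_attachment_rejected_for_c5(self):
        with pytest.raises(ValueError, match="pyrimidine"):
            DuplexSpec(sequence="GCATTGCA", attachment=Attachment("A", 0))

    def test_attachment_on_deleted_nucleotide_rejected(self):
        spec = DuplexSpec(
            sequence="TGTGTGTGTGTG",
            features=(Overhang(length=4, polarity="5p", strand="A"),),
            attachment=Attachment("A", 2),
        )
        with pytest.raises(ValueError, match="deleted"):
            build_duplex_model(spec)


class TestAccessibleVolume:
    def test_free_space_volume_matches_sphere(self):
        """With no obstacles the AV is a ball of the linker radius."""
        L = 20.0
        params = LinkerDyeParams(linker_length=L, grid_spacing=L / 25)
        vol = compute_av(HelixModel.free_space(), params)
        assert vol.volume == pytest.approx(4.0 / 3.0 * np.pi * L**3, rel=0.02)

    def test_half_space_obstacle_gives_hemisphere(self):
        """A wall through the attachment blocks exactly half the ball."""
        L, h, rho, probe = 12.0, 12.0 / 25, 2.0, 1.0
        params = LinkerDyeParams(
            linker_length=L, linker_width=2 * probe, dye_radii=(probe,), grid_spacing=h
        )
        z0 = -(rho + probe) - h / 4
        xy = np.arange(-2 * L, 2 * L + 1e-9, 1.0)
        gx, gy = np.meshgrid(xy, xy)
        centers = np.column_stack([gx.ravel(), gy.ravel(), np.full(gx.size, z0)])
        n = len(centers)
        wall = HelixModel(
            positions=centers,
            clash_radii=np.full(n, rho),
            base_index=np.zeros(n, dtype=int),
            strand=np.array(["A"] * n, dtype=object),
            kind=np.array(["wall"] * n, dtype=object),
            attachment_point=(0.0, 0.0, 0.0),
            attachment_base=0,
        )
        vol = compute_av(wall, params, exclude_attachment_base=False)
        ratio = vol.volume / (4.0 / 3.0 * np.pi * L**3)
        assert ratio == pytest.approx(0.5, abs=0.02)
        assert vol.points[:, 2].min() >= 0.0

    def test_geodesic_never_below_euclidean(self, blunt_av):
        eucl = np.linalg.norm(blunt_av.points - blunt_av.attachment_point, axis=1)
        assert np.all(blunt_av.geodesic >= eucl - 1e-9)
        assert np.all(blunt_av.geodesic <= blunt_av.params.linker_length + 1e-6)

    def test_no_point_clashes_with_dna(self, blunt_av, blunt_model):
        r_dye = blunt_av.params.dye_radii[0]
        keep = ~(
            (blunt_model.base_index == blunt_model.attachment_base)
            & (blunt_model.kind == "base")
        )
        for c, r in zip(blunt_model.positions[keep], blunt_model.clash_radii[keep]):
            d = np.linalg.norm(blunt_av.points - c, axis=1)
            assert np.all(d > r + r_dye)

    def test_longer_linker_never_shrinks_av(self, blunt_model):
        """Monotonicity: the short-linker AV is a subset of the long one."""
        short = compute_av(blunt_model, LinkerDyeParams(linker_length=14.0))
        long_ = compute_av(blunt_model, LinkerDyeParams(linker_length=20.0))
        long_set = {tuple(np.round(p, 6)) for p in long_.points}
        short_set = {tuple(np.round(p, 6)) for p in short.points}
        assert short_set <= long_set

    def test_removing_obstacles_never_shrinks_av(self):
        full = build_duplex_model(DuplexSpec(sequence=BLUNT_SEQ, attachment=Attachment("A", 14)))
        gapped = build_duplex_model(
            DuplexSpec(
                sequence=BLUNT_SEQ,
                features=(Gap(positions=(12, 13), strand="B"),),
                attachment=Attachment("A", 14),
            )
        )
        av_full = compute_av(full)
        av_gap = compute_av(gapped)
        full_set = {tuple(np.round(p, 6)) for p in av_full.points}
        gap_set = {tuple(np.round(p, 6)) for p in av_gap.points}
        assert full_set <= gap_set

    def test_grid_convergence(self, blunt_model):
        coarse = compute_av(blunt_model, LinkerDyeParams(grid_spacing=1.4))
        fine = compute_av(blunt_model, LinkerDyeParams(grid_spacing=0.7))
        assert fine.volume == pytest.approx(coarse.volume, rel=0.05)

    def test_buried_attachment_raises(self):
        # attachment completely enclosed in a shell of spheres
        phi = np.linspace(0, np.pi, 12)
        theta = np.linspace(0, 2 * np.pi, 24)
        pts = []
        for p in phi:
            for t in theta:
                pts.append([3 * np.sin(p) * np.cos(t), 3 * np.sin(p) * np.sin(t), 3 * np.cos(p)])
        pts = np.asarray(pts)
        shell = HelixModel(
            positions=pts,
            clash_radii=np.full(len(pts), 2.5),
            base_index=np.zeros(len(pts), dtype=int),
            strand=np.array(["A"] * len(pts), dtype=object),
            kind=np.array(["wall"] * len(pts), dtype=object),
            attachment_point=(0.0, 0.0, 0.0),
            attachment_base=0,
        )
        with pytest.raises(EmptyAVError):
            compute_av(shell, LinkerDyeParams(linker_length=10.0), exclude_attachment_base=False)


class TestReach:
    def test_blunt_duplex_reach_at_most_four_bases(self, blunt_av, blunt_model):
        """The sulfo-Cy3 long linker explores no more than four bases."""
        assert axial_reach(blunt_av, blunt_model) <= 4

    def test_short_linker_reach_at_most_one_base(self, blunt_model):
        params = LinkerDyeParams(linker_length=3.0, linker_width=2.0, dye_radii=(1.0,), grid_spacing=0.5)
        vol = compute_av(blunt_model, params)
        assert axial_reach(vol, blunt_model) <= 1

    def test_doubling_linker_never_decreases_reach(self, blunt_model):
        r1 = axial_reach(compute_av(blunt_model, LinkerDyeParams(linker_length=10.0)), blunt_model)
        r2 = axial_reach(compute_av(blunt_model, LinkerDyeParams(linker_length=20.0)), blunt_model)
        assert r2 >= r1


class TestStacking:
    def test_fraction_decreases_away_from_junction(self):
        """T0 > T2 > T4, mirroring the lifetime ordering of the dye series."""
        fracs = []
        for offset in (0, 2, 4):
            model = overhang_model(offset)
            vol = compute_av(model)
            fracs.append(stacking_fraction(vol, junction_base_index=5, strand="A"))
        assert fracs[0] > fracs[1] > fracs[2]

    def test_positive_at_junction(self):
        model = overhang_model(0)
        vol = compute_av(model)
        assert stacking_fraction(vol, junction_base_index=5, strand="A") > 0.0

    def test_zero_when_junction_out_of_reach(self):
        model = overhang_model(0)
        vol = compute_av(model)
        # base 20 is ~51 A away: beyond linker_length + shell
        assert stacking_fraction(vol, junction_base_index=20, strand="A") == 0.0

    def test_missing_junction_index_errors(self):
        model = overhang_model(0)
        vol = compute_av(model)
        with pytest.raises(ValueError, match="base pseudo-atom"):
            stacking_fraction(vol, junction_base_index=2, strand="A")


class TestPDBOutput:
    def test_cloud_roundtrip(self, blunt_av, tmp_path):
        from Bio.PDB import PDBParser

        path = tmp_path / "cloud.pdb"
        write_av_cloud(blunt_av, path)
        structure = PDBParser(QUIET=True).get_structure("AV", str(path))
        chains = {c.id: c for c in structure[0]}
        assert set(chains) == {"A", "B"}
        cloud = np.array([a.coord for a in chains["B"].get_atoms()])
        assert cloud.shape[0] <= 9999
        stride = int(np.ceil(blunt_av.n_points / 9999))
        expected = blunt_av.points[::stride]
        assert cloud.shape == expected.shape
        assert np.allclose(cloud, expected, atol=1.5e-3)
        helix = np.array([a.coord for a in chains["A"].get_atoms()])
        assert helix.shape[0] == blunt_av.model.n_atoms
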