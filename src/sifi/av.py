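"""Accessible-volume (AV) modelling of a linker-tethered dye on B-form DNA.

The dye is treated as a sphere on a flexible linker of fixed maximum length
attached to the C5 atom of a pyrimidine base. The accessible volume is the
set of grid positions the dye centre can reach: a position is allowed when a
clash-free path of geodesic length no greater than the linker length, and
wide enough for the linker, connects it to the attachment point, and when
the dye sphere itself fits there without clashing with the DNA.

The DNA is an idealised B-form helix (3.4 Angstrom rise, 36 degree twist)
coarse-grained to three pseudo-atom spheres per nucleotide (backbone,
sugar, base). That level of detail is sufficient for the geometric
conclusions the AV supports — how many bases along the duplex the dye can
explore, and whether it can reach a nick/gap/overhang junction — which are
robust to sub-Angstrom structural detail.

Geodesics are computed by Dijkstra search on the 26-connected clash-free
grid, seeded with exact straight-line distances for every grid point in
unobstructed view of the attachment (so free-space geodesics are exact, and
obstructed ones are tight upper bounds).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra

__all__ = [
    "Nick",
    "Gap",
    "Overhang",
    "Attachment",
    "DuplexSpec",
    "LinkerDyeParams",
    "SULFO_CY3_LONG_LINKER",
    "HelixModel",
    "AccessibleVolume",
    "EmptyAVError",
    "build_duplex_model",
    "compute_av",
    "axial_reach",
    "stacking_fraction",
    "write_av_cloud",
]

_COMPLEMENT = {"A": "T", "T": "A", "G": "C", "C": "G"}

#: (kind, radial distance from helix axis, azimuthal offset from the base-pair
#: reference angle, clash radius) — all Angstrom/degrees. Standard B-form
#: dimensions: phosphate backbone at ~9 Angstrom radius, paired bases
#: stacked about the axis, grooves set by the +/-77 degree backbone offsets.
_NUCLEOTIDE_SPHERES = (
    ("backbone", 8.9, 77.0, 3.2),
    ("sugar", 6.3, 55.0, 2.8),
    ("base", 2.4, 15.0, 3.3),
)

#: Radial position of the pyrimidine C5 attachment atom (major-groove face;
#: in ideal B-form coordinates the pyrimidine ring extends inward from C1'
#: at ~5.9 Angstrom, putting C5 near 4 Angstrom from the axis).
_C5_RADIUS = 4.0
_C5_ANGLE_OFFSET = 180.0


class EmptyAVError(RuntimeError):
    """Raised when no dye position is sterically accessible."""


# ---------------------------------------------------------------------------
# specs


@dataclass(frozen=True)
class Nick:
    """A missing phosphodiester bond after base ``after`` (0-based) on one
    strand. Sterically silent in the coarse model; recorded for bookkeeping."""

    after: int
    strand: str = "B"


@dataclass(frozen=True)
class Gap:
    """Nucleotides deleted from one strand (a 1- or 2-nt gap)."""

    positions: tuple
    strand: str = "B"


@dataclass(frozen=True)
class Overhang:
    """Single-stranded extension: over the first ("5p") or last ("3p")
    ``length`` positions, the nucleotides of ``strand`` are absent while the
    other strand continues as ssDNA whose pseudo-atoms stay in place."""

    length: int
    polarity: str = "5p"
    strand: str = "B"


@dataclass(frozen=True)
class Attachment:
    """Dye attachment site: strand, 0-based base position, connecting atom."""

    strand: str = "A"
    position: int = 0
    atom: str = "C5"


@dataclass(frozen=True)
class DuplexSpec:
    """A duplex (or duplex-with-feature) construct.

    ``sequence`` is strand A, 5'->3'. ``sequence_b`` defaults to the full
    complement; if given it must pair base-by-base with strand A. Features
    then delete nucleotides (gap, overhang) or mark nicks.
    """

    sequence: str
    sequence_b: Optional[str] = None
    rise: float = 3.4
    twist: float = 36.0
    features: tuple = ()
    attachment: Optional[Attachment] = None

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        if not seq or any(b not in _COMPLEMENT for b in seq):
            raise ValueError("sequence must be non-empty A/C/G/T")
        comp = "".join(_COMPLEMENT[b] for b in seq)
        if self.sequence_b is None:
            object.__setattr__(self, "sequence_b", comp)
        else:
            sb = self.sequence_b.upper()
            object.__setattr__(self, "sequence_b", sb)
            if len(sb) != len(seq):
                raise ValueError("sequence_b must match sequence length")
            mism = [i for i, (x, y) in enumerate(zip(comp, sb)) if x != y]
            if mism:
                raise ValueError(f"non-complementary paired region at positions {mism}")
        n = len(seq)
        for f in self.features:
            if isinstance(f, Gap) and any(not 0 <= p < n for p in f.positions):
                raise ValueError("gap positions outside sequence")
            if isinstance(f, Overhang) and not 0 < f.length < n:
                raise ValueError("overhang length outside sequence")
        if self.attachment is not None:
            a = self.attachment
            if not 0 <= a.position < n:
                raise ValueError("attachment position outside sequence")
            base = seq[a.position] if a.strand == "A" else self.sequence_b[a.position]
            if a.atom == "C5" and base not in "CT":
                raise ValueError(
                    f"C5 attachment requires a pyrimidine; found {base} at "
                    f"position {a.position} of strand {a.strand}"
                )

    @property
    def n_bp(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class LinkerDyeParams:
    """Linker/dye geometry for the AV search.

    Defaults approximate a sulfo-Cy3 NHS-ester dye on its long linker as
    used in FRET-positioning AV calculations (~20 Angstrom linker, 4.5
    Angstrom linker width, single 3.5 Angstrom dye radius). These are
    modelling assumptions, not measured values; supply three radii for an
    AV3-style calculation (the dye must fit with each radius).
    """

    linker_length: float = 20.0
    linker_width: float = 4.5
    dye_radii: tuple = (3.5,)
    grid_spacing: float = 0.9

    def __post_init__(self) -> None:
        object.__setattr__(self, "dye_radii", tuple(float(r) for r in self.dye_radii))
        if min(self.linker_length, self.linker_width, self.grid_spacing) <= 0:
            raise ValueError("linker/grid parameters must be positive")
        if any(r <= 0 for r in self.dye_radii) or len(self.dye_radii) not in (1, 3):
            raise ValueError("dye_radii must be 1 or 3 positive radii")
        if self.grid_spacing > self.linker_width:
            raise ValueError("grid_spacing must not exceed linker_width")


SULFO_CY3_LONG_LINKER = LinkerDyeParams()


# ---------------------------------------------------------------------------
# helix model


@dataclass
class HelixModel:
    """Coarse pseudo-atom model of a (possibly featured) duplex.

    The helix axis is the z axis; base pair ``i`` is centred at
    ``z = i * rise``. Arrays are parallel: one entry per pseudo-atom.
    """

    positions: np.ndarray  # (n, 3) Angstrom
    clash_radii: np.ndarray  # (n,)
    base_index: np.ndarray  # (n,) int
    strand: np.ndarray  # (n,) "A"/"B"
    kind: np.ndarray  # (n,) backbone/sugar/base
    rise: float = 3.4
    twist: float = 36.0
    attachment_point: Optional[np.ndarray] = None
    attachment_base: Optional[int] = None
    spec: Optional[DuplexSpec] = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        self.clash_radii = np.asarray(self.clash_radii, dtype=float)
        if self.attachment_point is not None:
            self.attachment_point = np.asarray(self.attachment_point, dtype=float)

    @property
    def n_atoms(self) -> int:
        return self.positions.shape[0]

    def bp_center(self, i: int) -> np.ndarray:
        return np.array([0.0, 0.0, i * self.rise])

    def azimuth(self, i: int) -> float:
        """Reference azimuth of base pair ``i`` in degrees, modulo 360."""
        return (i * self.twist) % 360.0

    def base_sphere(self, base_index: int, strand: Optional[str] = None):
        """(centre, clash radius) of a base pseudo-atom at ``base_index``."""
        mask = (self.base_index == base_index) & (self.kind == "base")
        if strand is not None:
            mask &= self.strand == strand
        idx = np.nonzero(mask)[0]
        if idx.size == 0:
            raise ValueError(f"no base pseudo-atom at index {base_index}")
        return self.positions[idx[0]], float(self.clash_radii[idx[0]])

    @classmethod
    def free_space(cls, attachment_point=(0.0, 0.0, 0.0)) -> "HelixModel":
        """An obstacle-free model (for analytic AV limits)."""
        return cls(
            positions=np.empty((0, 3)),
            clash_radii=np.empty(0),
            base_index=np.empty(0, dtype=int),
            strand=np.empty(0, dtype=object),
            kind=np.empty(0, dtype=object),
            attachment_point=np.asarray(attachment_point, dtype=float),
            attachment_base=0,
        )


def _strand_present(spec: DuplexSpec, strand: str) -> np.ndarray:
    present = np.ones(spec.n_bp, dtype=bool)
    for f in spec.features:
        if isinstance(f, Gap) and f.strand == strand:
            present[list(f.positions)] = False
        elif isinstance(f, Overhang) and f.strand == strand:
            if f.polarity == "5p":
                present[: f.length] = False
            else:
                present[spec.n_bp - f.length :] = False
    return present


def build_duplex_model(spec: DuplexSpec) -> HelixModel:
    """Construct the ideal B-form pseudo-atom model for a duplex spec.

    Strand A nucleotides sit at azimuth offsets +delta from each base
    pair's reference angle, strand B at -delta (putting the two backbones
    154 degrees apart across the minor groove). Gap features delete the
    named nucleotides' pseudo-atoms; an overhang removes the partner strand
    but leaves the single-stranded atoms in place.
    """
    n = spec.n_bp
    a_present = _strand_present(spec, "A")
    b_present = _strand_present(spec, "B")

    pos, clash, b_idx, strands, kinds = [], [], [], [], []
    for i in range(n):
        theta = np.deg2rad(i * spec.twist)
        for strand, sign, present in (("A", +1.0, a_present[i]), ("B", -1.0, b_present[i])):
            if not present:
                continue
            for kind, radius, offset, r_clash in _NUCLEOTIDE_SPHERES:
                ang = theta + sign * np.deg2rad(offset)
                pos.append([radius * np.cos(ang), radius * np.sin(ang), i * spec.rise])
                clash.append(r_clash)
                b_idx.append(i)
                strands.append(strand)
                kinds.append(kind)

    attachment_point = None
    attachment_base = None
    if spec.attachment is not None:
        a = spec.attachment
        present = a_present if a.strand == "A" else b_present
        if not present[a.position]:
            raise ValueError(
                f"attachment nucleotide at position {a.position} of strand "
                f"{a.strand} was deleted by a feature"
            )
        attachment_base = a.position
        sign = +1.0 if a.strand == "A" else -1.0
        theta = np.deg2rad(a.position * spec.twist) + sign * np.deg2rad(_C5_ANGLE_OFFSET)
        attachment_point = np.array(
            [_C5_RADIUS * np.cos(theta), _C5_RADIUS * np.sin(theta), a.position * spec.rise]
        )

    return HelixModel(
        positions=np.array(pos).reshape(-1, 3),
        clash_radii=np.array(clash),
        base_index=np.array(b_idx, dtype=int),
        strand=np.array(strands, dtype=object),
        kind=np.array(kinds, dtype=object),
        rise=spec.rise,
        twist=spec.twist,
        attachment_point=attachment_point,
        attachment_base=attachment_base,
        spec=spec,
    )


# ---------------------------------------------------------------------------
# accessible volume


@dataclass
class AccessibleVolume:
    """The sterically allowed dye-centre positions.

    ``points`` are absolute coordinates (Angstrom) of allowed grid points;
    ``geodesic`` the linker path length to each.
    """

    points: np.ndarray
    geodesic: np.ndarray
    attachment_point: np.ndarray
    grid_spacing: float
    params: LinkerDyeParams
    model: Optional[HelixModel] = None

    @property
    def n_points(self) -> int:
        return self.points.shape[0]

    @property
    def volume(self) -> float:
        """AV volume in cubic Angstrom (grid-cell count times cell volume)."""
        return self.n_points * self.grid_spacing**3

    @property
    def mean_position(self) -> np.ndarray:
        return self.points.mean(axis=0)


def _clearance(points: np.ndarray, centers: np.ndarray, radii: np.ndarray) -> np.ndarray:
    """min over atoms of (distance - clash radius); +inf with no atoms."""
    if centers.shape[0] == 0:
        return np.full(points.shape[0], np.inf)
    out = np.full(points.shape[0], np.inf)
    for c, r in zip(centers, radii):
        d = np.linalg.norm(points - c, axis=1) - r
        np.minimum(out, d, out=out)
    return out


def _segment_clearance(origin: np.ndarray, points: np.ndarray, centers, radii) -> np.ndarray:
    """min over atoms of (distance from segment origin->point to atom surface)."""
    if centers.shape[0] == 0:
        return np.full(points.shape[0], np.inf)
    d = points - origin  # (m,3)
    dd = np.einsum("ij,ij->i", d, d)
    dd = np.maximum(dd, 1e-12)
    out = np.full(points.shape[0], np.inf)
    for c, r in zip(centers, radii):
        w = c - origin
        t = np.clip((d @ w) / dd, 0.0, 1.0)
        closest = d * t[:, None]
        dist = np.linalg.norm(closest - w, axis=1) - r
        np.minimum(out, dist, out=out)
    return out


# 26-neighbourhood: 13 unique offset pairs
_OFFSETS = np.array(
    [
        (dx, dy, dz)
        for dx in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dz in (-1, 0, 1)
        if (dx, dy, dz) > (0, 0, 0)
    ],
    dtype=int,
)


def compute_av(
    model: HelixModel,
    params: LinkerDyeParams = SULFO_CY3_LONG_LINKER,
    exclude_attachment_base: bool = True,
) -> AccessibleVolume:
    """Grid search for the dye's accessible volume.

    A cube of half-width ``linker_length`` around the attachment point is
    discretised at ``grid_spacing``. A grid point belongs to the AV when

    1. a clash-free path of width ``linker_width`` and geodesic length at
       most ``linker_length`` connects it to the attachment point, and
    2. a dye sphere of each radius in ``dye_radii`` fits there without
       clashing with any pseudo-atom.

    The base pseudo-atom of the attachment nucleotide is excluded from the
    clash set by default — the linker is bonded to it, and in the coarse
    model its sphere would otherwise bury the attachment atom.
    """
    if model.attachment_point is None:
        raise ValueError("model has no attachment point")
    origin = model.attachment_point
    L = params.linker_length
    h = params.grid_spacing

    centers = model.positions
    radii = model.clash_radii
    if exclude_attachment_base and model.n_atoms and model.attachment_base is not None:
        keep = ~(
            (model.base_index == model.attachment_base)
            & (model.kind == "base")
        )
        centers = centers[keep]
        radii = radii[keep]

    half = int(np.ceil(L / h))
    axis = np.arange(-half, half + 1) * h
    shape = (axis.size,) * 3
    gx, gy, gz = np.meshgrid(axis, axis, axis, indexing="ij")
    points = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()]) + origin

    probe = params.linker_width / 2.0
    linker_free = _clearance(points, centers, radii) > probe
    in_ball = np.linalg.norm(points - origin, axis=1) <= L + 1e-9
    candidate = linker_free & in_ball

    free_idx = np.nonzero(linker_free)[0]
    if free_idx.size == 0:
        raise EmptyAVError("attachment is fully buried: no clash-free grid points")
    n_free = free_idx.size
    rank = -np.ones(np.prod(shape), dtype=np.int64)
    rank[free_idx] = np.arange(n_free)

    # exact straight-line seeding: grid points in unobstructed view of the
    # attachment get their true Euclidean geodesic
    seg_clear = _segment_clearance(origin, points[free_idx], centers, radii)
    visible = seg_clear > probe
    eucl = np.linalg.norm(points[free_idx] - origin, axis=1)

    # lattice edges between clash-free neighbours
    free_mask3 = linker_free.reshape(shape)
    idx3 = rank.reshape(shape)
    rows, cols, weights = [], [], []
    for off in _OFFSETS:
        w = np.linalg.norm(off) * h
        sl_a = tuple(slice(max(o, 0), axis.size + min(o, 0)) for o in off)
        sl_b = tuple(slice(max(-o, 0), axis.size + min(-o, 0)) for o in off)
        both = free_mask3[sl_a] & free_mask3[sl_b]
        a = idx3[sl_a][both]
        b = idx3[sl_b][both]
        rows.append(a)
        cols.append(b)
        weights.append(np.full(a.size, w))
    # virtual source (node n_free) -> all visible nodes, weighted by the
    # exact Euclidean distance
    vis_nodes = np.nonzero(visible)[0]
    if vis_nodes.size == 0:
        # attachment in a pocket: seed from the nearest free grid points
        near = eucl <= np.sqrt(3.0) * h + 1e-9
        vis_nodes = np.nonzero(near)[0]
        if vis_nodes.size == 0:
            raise EmptyAVError("attachment is fully buried: no reachable grid points")
    rows.append(np.full(vis_nodes.size, n_free))
    cols.append(vis_nodes)
    weights.append(eucl[vis_nodes])

    graph = coo_matrix(
        (np.concatenate(weights), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n_free + 1, n_free + 1),
    ).tocsr()
    dist = dijkstra(graph, directed=False, indices=n_free)[:n_free]

    reachable = dist <= L + 1e-9
    allowed = candidate[free_idx] & reachable
    pts = points[free_idx[allowed]]
    geo = dist[allowed]

    # dye-sphere fit for each radius
    for r_dye in params.dye_radii:
        fits = _clearance(pts, centers, radii) > r_dye
        pts = pts[fits]
        geo = geo[fits]

    if pts.shape[0] == 0:
        raise EmptyAVError("no grid point satisfies both linker and dye criteria")
    return AccessibleVolume(
        points=pts,
        geodesic=geo,
        attachment_point=origin,
        grid_spacing=h,
        params=params,
        model=model,
    )


# ---------------------------------------------------------------------------
# metrics


def axial_reach(av: AccessibleVolume, model: Optional[HelixModel] = None) -> int:
    """How many bases along the helix the dye centre can explore.

    The maximum |z| displacement of allowed points from the attachment
    nucleotide's base-pair centre is converted to the number of base-pair
    centres it spans: a reach of ``k`` means the dye centre can sit level
    with the base pair ``k`` steps away, but not with the one beyond it.
    """
    model = model or av.model
    if model is None:
        raise ValueError("a helix model is required for axial reach")
    z0 = model.bp_center(model.attachment_base)[2]
    dz = np.max(np.abs(av.points[:, 2] - z0))
    return int(np.floor(dz / model.rise + 1e-9))


def stacking_fraction(
    av: AccessibleVolume,
    model: Optional[HelixModel] = None,
    junction_base_index: int = 0,
    strand: Optional[str] = None,
    shell: float = 5.0,
    max_radius: float = 9.0,
) -> float:
    """Fraction of the AV within a stacking shell of the junction base.

    The shell is measured from the surface of the junction terminal base
    pseudo-atom; the default 5 Angstrom comfortably covers van der Waals
    stacking contact of the dye ring system. Points farther than
    ``max_radius`` from the helix axis are excluded: they lie on the outer
    helix surface, close to the junction in distance but not on the exposed
    stacking face.
    """
    model = model or av.model
    if model is None:
        raise ValueError("a helix model is required")
    center, r_clash = model.base_sphere(junction_base_index, strand)
    d = np.linalg.norm(av.points - center, axis=1) - r_clash
    radial = np.linalg.norm(av.points[:, :2], axis=1)
    return float(np.mean((d <= shell) & (radial <= max_radius)))


# ---------------------------------------------------------------------------
# output


def write_av_cloud(av: AccessibleVolume, path, max_points: int = 9999) -> None:
    """Write the helix pseudo-atoms (chain A) and AV cloud (chain B) as PDB.

    Grid points beyond ``max_points`` are evenly subsampled so the file
    stays within PDB serial-number limits; coordinates round-trip at the
    format's 0.001 Angstrom precision.
    """
    from Bio.PDB import PDBIO, StructureBuilder

    builder = StructureBuilder.StructureBuilder()
    builder.init_structure("AV")
    builder.init_model(0)
    builder.init_seg("    ")

    def add_chain(chain_id, coords, resname, element="C", bfactors=None):
        builder.init_chain(chain_id)
        for i, xyz in enumerate(coords):
            builder.init_residue(resname, "H_" + resname, i + 1, " ")
            builder.init_atom(
                element,
                np.asarray(xyz, dtype=float),
                0.0 if bfactors is None else float(bfactors[i]),
                1.0,
                " ",
                element.rjust(2),
                element=element,
            )

    model = av.model
    if model is not None and model.n_atoms:
        add_chain("A", model.positions, "DNA", element="P")
    pts = av.points
    geo = av.geodesic
    if pts.shape[0] > max_points:
        stride = int(np.ceil(pts.shape[0] / max_points))
        pts = pts[::stride]
        geo = geo[::stride]
    add_chain("B", pts, "AVC", element="C", bfactors=geo)

    io = PDBIO()
    io.set_structure(builder.get_structure())
    io.save(str(path))
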