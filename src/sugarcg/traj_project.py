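"""Project all-atom frames onto bead coordinates and measure bonded terms.

Beads sit at the unweighted center of geometry of their mapped atoms
(hydrogens count with weight 1); each virtual site sits at the center of
geometry of its ring's three beads.  Bonded terms are measured over the CG
connectivity: 3 ring constraints per residue (bond0-2 acceptor, bond4-6
donor), the single inter-monomer distance (bond3), four junction angles and
one dihedral.  Units are nm and degrees throughout; dihedrals are signed
(IUPAC convention, atan2) and wrapped to (-180, 180].

Molecules are made whole before intramolecular measurement by minimum-image
unwrapping relative to the first atom, which is exact while the molecular
radius stays below half the box edge (always true for a disaccharide in the
boxes used here).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .chem_model import AtomGraph
from .cg_mapping import CGMapping

__all__ = [
    "Trajectory",
    "CGConnectivity",
    "TermSamples",
    "TERM_ORDER",
    "project_frame",
    "project_trajectory",
    "build_connectivity",
    "measure_terms",
    "load_trajectory",
]

log = logging.getLogger(__name__)

TERM_ORDER = tuple(
    [f"bond{i}" for i in range(7)] + [f"angle{i}" for i in range(4)] + ["dihedral0"]
)


@dataclass
class Trajectory:
    """Coordinates in nm, orthorhombic box edges in nm, times in ps."""

    coords: np.ndarray  # (F, N, 3)
    box: np.ndarray     # (3,) or (F, 3)
    times: np.ndarray   # (F,)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.box = np.asarray(self.box, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.coords.ndim != 3:
            raise ValueError("coords must be (n_frames, n_atoms, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")
        if np.any(self.box_per_frame() <= 0):
            raise ValueError("box edges must be positive")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def box_per_frame(self) -> np.ndarray:
        if self.box.ndim == 1:
            return np.broadcast_to(self.box, (self.n_frames, 3))
        return self.box


@dataclass(frozen=True)
class CGConnectivity:
    """Bonded-term index lists over the bead order of a CGMapping."""

    ring_constraint_pairs: tuple[tuple[int, int], ...]  # 6 entries: acceptor then donor
    inter_bond_pair: tuple[int, int]
    angle_triples: tuple[tuple[int, int, int], ...]     # 4 entries
    dihedral_quad: tuple[int, int, int, int]
    vs_constructions: tuple[tuple[int, tuple[int, int, int]], ...]
    labels: tuple[str, ...] = TERM_ORDER

    def distance_pairs(self) -> tuple[tuple[int, int], ...]:
        """bond0..bond6 in topology order (ring constraints flank bond3)."""
        rc = self.ring_constraint_pairs
        return rc[:3] + (self.inter_bond_pair,) + rc[3:]


@dataclass
class TermSamples:
    """Per-term measurement arrays; bond terms nm, angle/dihedral degrees."""

    data: dict[str, np.ndarray]
    times: np.ndarray | None = None

    def __getitem__(self, label: str) -> np.ndarray:
        return self.data[label]

    def labels(self) -> tuple[str, ...]:
        return tuple(self.data)

    def restrict_last(self, last_ps: float) -> "TermSamples":
        if self.times is None:
            raise ValueError("samples carry no times; cannot window")
        keep = self.times >= self.times.max() - last_ps
        return TermSamples(
            data={k: v[keep] for k, v in self.data.items()}, times=self.times[keep]
        )


def _bead_atom_indices(mapping: CGMapping, atom_graph: AtomGraph) -> list[np.ndarray]:
    index = atom_graph.index()
    out = []
    for bead in mapping.real_beads:
        try:
            out.append(np.array([index[ref] for ref in bead.atoms], dtype=int))
        except KeyError as exc:
            raise ValueError(f"mapped atom {exc.args[0]} missing from structure") from None
    return out


def _unwrap(coords: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Make the molecule whole via minimum image about the first atom."""
    ref = coords[..., :1, :]
    delta = coords - ref
    b = box[:, None, :] if box.ndim == 2 else box
    return ref + delta - b * np.round(delta / b)


def project_frame(coords: np.ndarray, mapping: CGMapping, atom_graph: AtomGraph,
                  box: np.ndarray | None = None) -> np.ndarray:
    """Bead coordinates (real beads then virtual sites) for one frame."""
    coords = np.asarray(coords, dtype=float)
    single = coords.ndim == 2
    frames = coords[None] if single else coords
    if box is not None:
        frames = _unwrap(frames, np.asarray(box, dtype=float))
    groups = _bead_atom_indices(mapping, atom_graph)
    n_real = len(groups)
    out = np.empty((frames.shape[0], len(mapping.beads), 3))
    for i, idx in enumerate(groups):
        out[:, i] = frames[:, idx].mean(axis=1)
    name_to_pos = {b.bead_name: i for i, b in enumerate(mapping.beads)}
    for vs_i, (_, triple) in enumerate(mapping.virtual_sites):
        cols = [name_to_pos[n] for n in triple]
        out[:, n_real + vs_i] = out[:, cols].mean(axis=1)
    return out[0] if single else out


def project_trajectory(traj: Trajectory, mapping: CGMapping,
                       atom_graph: AtomGraph) -> np.ndarray:
    """Bead coordinates for every frame, shape (F, n_beads, 3)."""
    return project_frame(traj.coords, mapping, atom_graph, box=traj.box_per_frame())


def build_connectivity(mapping: CGMapping, atom_graph: AtomGraph) -> CGConnectivity:
    """Derive the 7+4+1 bonded-term index lists from a mapping.

    The inter-monomer bond joins the glycosidic bead to the unique bead of
    the other residue that shares a covalent atom-atom bond with it; the
    four angles extend that bond into each residue's two remaining beads,
    and the dihedral uses the lowest-index bead on either side.
    """
    g = atom_graph.graph
    beads = mapping.beads
    atom_to_bead = mapping.atom_to_bead()
    glyco = mapping.glycosidic_bead_index(atom_graph.glycosidic_oxygen)
    glyco_res = beads[glyco].residue_index
    partners = set()
    for ref in beads[glyco].atoms:
        for nb in g.neighbors(ref):
            j = atom_to_bead[nb]
            if j != glyco and beads[j].residue_index != glyco_res:
                partners.add(j)
    if len(partners) != 1:
        raise ValueError(
            f"expected one inter-monomer junction bead, found {sorted(partners)}"
        )
    a = partners.pop()
    b = glyco
    res_a = beads[a].residue_index

    def residue_beads(resid: int) -> list[int]:
        return [i for i, bd in enumerate(beads)
                if bd.residue_index == resid and not bd.is_virtual]

    acc = residue_beads(1)
    don = residue_beads(2)
    ring_pairs = (
        (acc[0], acc[1]), (acc[1], acc[2]), (acc[0], acc[2]),
        (don[0], don[1]), (don[1], don[2]), (don[0], don[2]),
    )
    xs = sorted(i for i in residue_beads(res_a) if i != a)
    ys = sorted(i for i in residue_beads(beads[b].residue_index) if i != b)
    angles = (
        (xs[0], a, b), (xs[1], a, b), (a, b, ys[0]), (a, b, ys[1]),
    )
    dihedral = (xs[0], a, b, ys[0])
    n_real = len(mapping.real_beads)
    name_to_pos = {bd.bead_name: i for i, bd in enumerate(beads)}
    vs = tuple(
        (n_real + i, tuple(name_to_pos[n] for n in triple))
        for i, (_, triple) in enumerate(mapping.virtual_sites)
    )
    return CGConnectivity(
        ring_constraint_pairs=ring_pairs,
        inter_bond_pair=(a, b),
        angle_triples=angles,
        dihedral_quad=dihedral,
        vs_constructions=vs,
    )


def _angles_deg(u: np.ndarray, v: np.ndarray, label: str) -> np.ndarray:
    nu = np.linalg.norm(u, axis=-1)
    nv = np.linalg.norm(v, axis=-1)
    bad = (nu == 0) | (nv == 0)
    if np.any(bad):
        log.warning("%s: excluding %d frames with degenerate geometry",
                    label, int(bad.sum()))
    with np.errstate(invalid="ignore", divide="ignore"):
        cosang = np.einsum("...i,...i->...", u, v) / (nu * nv)
    ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    return np.where(bad, np.nan, ang)


def _dihedrals_deg(p0, p1, p2, p3) -> np.ndarray:
    """Signed dihedral, positive clockwise looking from p1 to p2."""
    b1 = p1 - p0
    b2 = p2 - p1
    b3 = p3 - p2
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m1 = np.cross(n1, b2 / np.linalg.norm(b2, axis=-1, keepdims=True))
    x = np.einsum("...i,...i->...", n1, n2)
    y = np.einsum("...i,...i->...", m1, n2)
    phi = np.degrees(np.arctan2(y, x))
    # wrap to (-180, 180]
    return np.where(phi <= -180.0, phi + 360.0, phi)


def measure_terms(traj: Trajectory, mapping: CGMapping, connectivity: CGConnectivity,
                  atom_graph: AtomGraph) -> TermSamples:
    """Measure all bonded terms over a trajectory (vectorized across frames)."""
    if traj.n_frames < 1:
        raise ValueError("need at least one frame")
    bead_xyz = project_trajectory(traj, mapping, atom_graph)
    data: dict[str, np.ndarray] = {}
    for label, (i, j) in zip(TERM_ORDER[:7], connectivity.distance_pairs()):
        data[label] = np.linalg.norm(bead_xyz[:, j] - bead_xyz[:, i], axis=-1)
    for label, (i, j, k) in zip(TERM_ORDER[7:11], connectivity.angle_triples):
        u = bead_xyz[:, i] - bead_xyz[:, j]
        v = bead_xyz[:, k] - bead_xyz[:, j]
        ang = _angles_deg(u, v, label)
        data[label] = ang[~np.isnan(ang)] if np.any(np.isnan(ang)) else ang
    i, j, k, l = connectivity.dihedral_quad
    data["dihedral0"] = _dihedrals_deg(
        bead_xyz[:, i], bead_xyz[:, j], bead_xyz[:, k], bead_xyz[:, l]
    )
    return TermSamples(data=data, times=traj.times.copy())


def load_trajectory(topology_path, traj_path=None) -> Trajectory:
    """Read a trajectory into nm/ps arrays.

    Multi-frame GRO files are read natively; other formats (PDB coordinates,
    XTC/TRR with a topology) are handled through MDAnalysis, converting
    from its angstrom convention.
    """
    topology_path = Path(topology_path)
    if traj_path is None and topology_path.suffix.lower() == ".gro":
        from .topology_io import read_gro_frames

        frames = list(read_gro_frames(topology_path))
        coords = np.stack([f[0] for f in frames])
        box = np.stack([f[1] for f in frames])
        times = np.array([f[2] if f[2] is not None else i
                          for i, f in enumerate(frames)], dtype=float)
        return Trajectory(coords=coords, box=box, times=times)

    import MDAnalysis as mda

    u = (mda.Universe(str(topology_path)) if traj_path is None
         else mda.Universe(str(topology_path), str(traj_path)))
    coords, boxes, times = [], [], []
    for ts in u.trajectory:
        coords.append(ts.positions / 10.0)
        boxes.append(np.asarray(ts.dimensions[:3], dtype=float) / 10.0)
        times.append(ts.time)
    return Trajectory(coords=np.stack(coords), box=np.stack(boxes),
                      times=np.array(times, dtype=float))
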