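"""Synthetic pseudo-all-atom trajectories with prescribed bead distributions.

The generator builds, frame by frame, the six real bead positions of a
disaccharide from sampled internal coordinates — the two ring triangles at
their (optionally rigid) target edge lengths, the inter-monomer distance,
the four junction angles and the dihedral drawn from independent Gaussians
— via sequential internal-to-Cartesian construction (trilateration for
in-plane placements, the standard distance/angle/dihedral chain rule for
the out-of-plane bead).  Each bead is then decorated with its mapped atoms
at fixed offsets whose center of geometry is exactly zero, so projecting
the pseudo-atomistic frame back onto beads inverts the decoration to
machine precision.  A random rigid-body move per frame exercises the
projection's rotation/translation equivariance without changing any
internal coordinate.

Because the sampled terms are exactly the terms the fitting model assumes
independent and Gaussian, the generator's targets are recovered by the
measure -> fit pipeline in expectation, which is what the round-trip suite
checks.  A second generator plants aggregation structure: single-bead
molecules chained below the network cutoff inside clusters that are kept
farther than a prescribed gap from each other.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .chem_model import DisaccharideSpec, build_atom_graph, parse_glycam_name
from .cg_mapping import CGMapping, MappingRules, DEFAULT_RULES, assign_beads, write_mapping_file
from .traj_project import CGConnectivity, Trajectory, TERM_ORDER, build_connectivity
from .topology_io import write_gro_frames

__all__ = [
    "GeneratorError",
    "GeneratorSpec",
    "FixtureResult",
    "default_targets",
    "gen_pseudo_aa_traj",
    "write_fixture",
    "gen_clustered_config",
]

#: study-condition defaults: ring edges and inter-monomer bond follow the
#: trehalose coarse-grained values (nm); angles/dihedral are realistic
#: feasible magnitudes (degrees).  Ring edges are rigid by default.
DEFAULT_TARGETS: dict[str, tuple[float, float]] = {
    "bond0": (0.32, 0.0),
    "bond1": (0.36, 0.0),
    "bond2": (0.45, 0.0),
    "bond3": (0.48, 0.02),
    "bond4": (0.33, 0.0),
    "bond5": (0.36, 0.0),
    "bond6": (0.47, 0.0),
    "angle0": (120.0, 5.0),
    "angle1": (100.0, 5.0),
    "angle2": (110.0, 5.0),
    "angle3": (130.0, 5.0),
    "dihedral0": (60.0, 15.0),
}


class GeneratorError(ValueError):
    """Geometrically impossible targets (e.g. triangle inequality violated)."""


def default_targets() -> dict[str, tuple[float, float]]:
    return dict(DEFAULT_TARGETS)


@dataclass
class GeneratorSpec:
    spec: DisaccharideSpec
    targets: dict[str, tuple[float, float]] = field(default_factory=default_targets)
    n_frames: int = 5000
    seed: int = 0
    box: tuple[float, float, float] = (6.145, 6.145, 6.145)  # nm
    dt_ps: float = 100.0
    atom_jitter: float = 0.06  # nm scale of the decoration offsets
    rules: MappingRules = field(default_factory=lambda: DEFAULT_RULES)

    def __post_init__(self) -> None:
        if isinstance(self.spec, str):
            self.spec = parse_glycam_name(self.spec)
        missing = [l for l in TERM_ORDER if l not in self.targets]
        if missing:
            raise ValueError(f"targets missing for terms: {missing}")
        for label, (_, sd) in self.targets.items():
            if sd < 0:
                raise ValueError(f"{label}: negative sd")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")


@dataclass
class FixtureResult:
    traj: Trajectory
    bead_coords: np.ndarray  # (F, n_beads, 3) ground-truth bead positions
    mapping: CGMapping
    connectivity: CGConnectivity
    graph: object  # AtomGraph
    manifest: dict


def _check_triangle(a: float, b: float, c: float, label: str) -> None:
    if a + b <= c or a + c <= b or b + c <= a:
        raise GeneratorError(
            f"{label}: edge targets ({a}, {b}, {c}) violate the triangle inequality"
        )


def _trilaterate(p1, p2, p3, r1, r2, r3, label: str) -> np.ndarray:
    """Vectorized 3-sphere intersection; returns the +ez branch.

    All inputs are (F, 3) / (F,) arrays; the local frame is built from the
    three centers, so the branch choice is deterministic per frame.
    """
    ex = p2 - p1
    d = np.linalg.norm(ex, axis=-1, keepdims=True)
    ex = ex / d
    d = d[..., 0]
    v = p3 - p1
    i = np.einsum("...k,...k->...", v, ex)
    ey = v - i[..., None] * ex
    j = np.linalg.norm(ey, axis=-1, keepdims=True)
    ey = ey / j
    j = j[..., 0]
    ez = np.cross(ex, ey)
    x = (r1 ** 2 - r2 ** 2 + d ** 2) / (2 * d)
    y = (r1 ** 2 - r3 ** 2 + i ** 2 + j ** 2) / (2 * j) - (i / j) * x
    z2 = r1 ** 2 - x ** 2 - y ** 2
    bad = z2 < -1e-9 * np.maximum(r1 ** 2, 1e-12)
    # rare Gaussian-tail frames may overshoot the feasible cone; clamp them to
    # the boundary, but infeasible *targets* (many violating frames) are fatal
    if np.any(bad):
        if bad.mean() > 0.01:
            raise GeneratorError(
                f"{label}: sampled internal coordinates are geometrically "
                f"impossible in {int(bad.sum())}/{bad.size} frames; "
                "check the angle/edge targets"
            )
    z = np.sqrt(np.clip(z2, 0.0, None))
    return p1 + x[..., None] * ex + y[..., None] * ey + z[..., None] * ez


def _nerf(a, b, c, r, theta_deg, phi_deg) -> np.ndarray:
    """Place the next point from distance r, angle at c, dihedral a-b-c."""
    theta = np.radians(theta_deg)
    phi = np.radians(phi_deg)
    bc = c - b
    bc = bc / np.linalg.norm(bc, axis=-1, keepdims=True)
    ab = b - a
    n = np.cross(ab, bc)
    n = n / np.linalg.norm(n, axis=-1, keepdims=True)
    m = np.cross(n, bc)
    # out-of-plane sign chosen so phi matches the signed (IUPAC) dihedral
    # measured by traj_project on the constructed geometry
    d = np.stack(
        [
            -r * np.cos(theta),
            r * np.sin(theta) * np.cos(phi),
            -r * np.sin(theta) * np.sin(phi),
        ],
        axis=-1,
    )
    return c + d[..., :1] * bc + d[..., 1:2] * m + d[..., 2:] * n


def _law_of_cosines(d1, d2, angle_deg):
    return np.sqrt(d1 ** 2 + d2 ** 2 - 2 * d1 * d2 * np.cos(np.radians(angle_deg)))


def _random_rotations(rng: np.random.Generator, n: int) -> np.ndarray:
    """Uniform rotation matrices via random quaternions, shape (n, 3, 3)."""
    q = rng.normal(size=(n, 4))
    q /= np.linalg.norm(q, axis=1, keepdims=True)
    w, x, y, z = q.T
    return np.stack(
        [
            np.stack([1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)], -1),
            np.stack([2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)], -1),
            np.stack([2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)], -1),
        ],
        axis=-2,
    )


def _sample(rng, targets, label, n):
    mean, sd = targets[label]
    if sd == 0:
        return np.full(n, float(mean))
    return rng.normal(mean, sd, size=n)


def generate_bead_series(gspec: GeneratorSpec):
    """Sample internal coordinates and build real-bead positions per frame.

    Returns (bead_xyz (F, 6, 3) in local frame, mapping, connectivity, graph).
    Bead columns follow the mapping order A1..A3, B1..B3.
    """
    graph = build_atom_graph(gspec.spec)
    mapping = assign_beads(graph, gspec.rules)
    conn = build_connectivity(mapping, graph)
    t = gspec.targets
    for tri, labels in (("acceptor ring", ("bond0", "bond1", "bond2")),
                        ("donor ring", ("bond4", "bond5", "bond6"))):
        _check_triangle(*(t[l][0] for l in labels), label=tri)

    rng = np.random.default_rng(gspec.seed)
    F = gspec.n_frames
    s = {label: _sample(rng, t, label, F) for label in TERM_ORDER}

    a_i, b_i = conn.inter_bond_pair
    acc = [i for i, bd in enumerate(mapping.real_beads) if bd.residue_index == 1]
    don = [i for i, bd in enumerate(mapping.real_beads) if bd.residue_index == 2]
    x1, x2 = [i for i in acc if i != a_i]
    y1, y2 = [i for i in don if i != b_i]

    # acceptor triangle in the z=0 plane: pairs (A1,A2),(A2,A3),(A1,A3)
    d01, d12, d02 = s["bond0"], s["bond1"], s["bond2"]
    beads = np.zeros((F, 6, 3))
    beads[:, acc[1], 0] = d01
    px = (d01 ** 2 + d02 ** 2 - d12 ** 2) / (2 * d01)
    py2 = d02 ** 2 - px ** 2
    if np.any(py2 <= 0):
        raise GeneratorError("acceptor ring: degenerate (collinear) edge targets")
    beads[:, acc[2], 0] = px
    beads[:, acc[2], 1] = np.sqrt(py2)

    def dist(i, j):
        return np.linalg.norm(beads[:, i] - beads[:, j], axis=-1)

    # glycosidic bead b: distance bond3 from a, angles angle0/angle1 to x1/x2
    r_bx1 = _law_of_cosines(dist(a_i, x1), s["bond3"], s["angle0"])
    r_bx2 = _law_of_cosines(dist(a_i, x2), s["bond3"], s["angle1"])
    beads[:, b_i] = _trilaterate(
        beads[:, a_i], beads[:, x1], beads[:, x2],
        s["bond3"], r_bx1, r_bx2, "junction bead",
    )
    # donor triangle: edges (b,y1)=bond4, (y1,y2)=bond5, (b,y2)=bond6
    beads[:, y1] = _nerf(beads[:, x1], beads[:, a_i], beads[:, b_i],
                         s["bond4"], s["angle2"], s["dihedral0"])
    r_ay2 = _law_of_cosines(dist(a_i, b_i), s["bond6"], s["angle3"])
    beads[:, y2] = _trilaterate(
        beads[:, b_i], beads[:, y1], beads[:, a_i],
        s["bond6"], s["bond5"], r_ay2, "donor ring closure",
    )
    return beads, mapping, conn, graph


def gen_pseudo_aa_traj(gspec: GeneratorSpec) -> FixtureResult:
    """Full fixture: decorated pseudo-atomistic trajectory plus ground truth."""
    beads, mapping, conn, graph = generate_bead_series(gspec)
    F = gspec.n_frames
    rng = np.random.default_rng(np.random.SeedSequence([gspec.seed, 1]))

    # rigid-body move per frame, molecule kept whole near the box center
    R = _random_rotations(rng, F)
    center = beads.mean(axis=1, keepdims=True)
    beads = np.einsum("fij,fnj->fni", R, beads - center)
    shift = np.asarray(gspec.box) / 2 + rng.uniform(-0.5, 0.5, size=(F, 3))
    beads = beads + shift[:, None, :]

    # decoration: fixed zero-mean atom offsets per bead
    index = graph.index()
    n_atoms = graph.n_atoms
    coords = np.empty((F, n_atoms, 3))
    for bead_i, bead in enumerate(mapping.real_beads):
        k = len(bead.atoms)
        offsets = rng.normal(0.0, gspec.atom_jitter, size=(k, 3))
        offsets -= offsets.mean(axis=0, keepdims=True)
        cols = [index[ref] for ref in bead.atoms]
        coords[:, cols] = beads[:, bead_i, None, :] + offsets[None]

    times = np.arange(F, dtype=float) * gspec.dt_ps
    traj = Trajectory(coords=coords, box=np.asarray(gspec.box, float), times=times)
    manifest = {
        "name": gspec.spec.name,
        "targets": {k: list(v) for k, v in gspec.targets.items()},
        "n_frames": F,
        "seed": gspec.seed,
        "box_nm": list(gspec.box),
        "dt_ps": gspec.dt_ps,
        "term_order": list(TERM_ORDER),
    }
    # include the virtual-site positions in the ground-truth bead array
    full = np.empty((F, len(mapping.beads), 3))
    full[:, : beads.shape[1]] = beads
    name_to_pos = {b.bead_name: i for i, b in enumerate(mapping.beads)}
    for i, (_, triple) in enumerate(mapping.virtual_sites):
        cols = [name_to_pos[n] for n in triple]
        full[:, beads.shape[1] + i] = full[:, cols].mean(axis=1)
    return FixtureResult(traj=traj, bead_coords=full, mapping=mapping,
                         connectivity=conn, graph=graph, manifest=manifest)


def write_fixture(gspec: GeneratorSpec, outdir) -> dict:
    """Emit traj.gro (multi-frame), mapping.txt and manifest.json; returns paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fx = gen_pseudo_aa_traj(gspec)
    names = [name for _, name in fx.graph.atom_order]
    resids = [resid for resid, _ in fx.graph.atom_order]
    resnames_codes = fx.manifest["name"].split("_")
    resnames = [resnames_codes[r - 1] for r in resids]
    paths = {
        "traj": outdir / "traj.gro",
        "mapping": outdir / "mapping.txt",
        "manifest": outdir / "manifest.json",
    }
    write_gro_frames(fx.traj.coords, fx.traj.box, fx.traj.times, paths["traj"],
                     names, resnames, resids, title=fx.manifest["name"])
    write_mapping_file(fx.mapping, paths["mapping"])
    paths["manifest"].write_text(json.dumps(fx.manifest, indent=1), encoding="utf-8")
    return {k: str(v) for k, v in paths.items()}


def gen_clustered_config(n_mol: int, planted_sizes, gap: float, box,
                         seed: int = 0, link_distance: float = 0.42):
    """Single-bead molecules with a planted aggregation partition.

    Molecules inside a cluster are chained at ``link_distance`` (below the
    0.47 nm network cutoff) along a compact 3D snake; cluster bounding boxes
    are separated by more than ``gap`` in every direction, including across
    the periodic boundary.  Returns (list of (1,3) arrays, box).
    """
    planted_sizes = list(planted_sizes)
    if sum(planted_sizes) != n_mol:
        raise ValueError("planted sizes must sum to n_mol")
    if any(s < 1 for s in planted_sizes):
        raise ValueError("cluster sizes must be >= 1")
    box = np.asarray(box, dtype=float)
    if gap <= 0 or link_distance <= 0:
        raise ValueError("gap and link_distance must be positive")

    def snake(size):
        k = int(np.ceil(size ** (1 / 3)))
        pts = []
        count = 0
        for iz in range(k):
            for iy in range(k):
                rng_x = range(k) if iy % 2 == 0 else range(k - 1, -1, -1)
                for ix in rng_x:
                    if count >= size:
                        return np.array(pts) * link_distance
                    pts.append((ix, iy if iz % 2 == 0 else k - 1 - iy, iz))
                    count += 1
        return np.array(pts) * link_distance

    clusters = [snake(s) for s in planted_sizes]
    extents = [c.max(axis=0) - c.min(axis=0) if len(c) > 1 else np.zeros(3)
               for c in clusters]
    pitch = max(float(e.max()) for e in extents) + gap * 1.001
    per_dim = int(np.floor(box.min() / pitch))
    if per_dim < 1 or per_dim ** 3 < len(clusters):
        raise GeneratorError(
            f"box {box} too small to separate {len(clusters)} clusters by > {gap} nm"
        )
    rng = np.random.default_rng(seed)
    cells = [(i, j, k) for i in range(per_dim) for j in range(per_dim)
             for k in range(per_dim)]
    chosen = rng.choice(len(cells), size=len(clusters), replace=False)
    molecules = []
    for cluster, cell_i in zip(clusters, chosen):
        origin = (np.array(cells[cell_i], dtype=float) + 0.05) * pitch
        for p in cluster:
            molecules.append((origin + p)[None, :])
    return molecules, box
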