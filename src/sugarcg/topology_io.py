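"""GROMACS-dialect topology (.itp) and coordinate (.gro) emission, plus the
run-protocol (.mdp) writer.

The emitted molecule block follows Martini conventions: ``nrexcl 1``, small
(S-prefix) beads at 54 amu, massless virtual sites built with
``[virtual_sitesn]`` funct 2 (center of geometry) and explicitly excluded
from their three constructing ring beads.  Angles are written as harmonic
funct 1 by default (switchable to the cosine-based funct 2); the single
proper dihedral is funct 1 with multiplicity 1 and phase ``phi0 - 180`` so
its minimum sits at the fitted equilibrium angle.

Numeric fields are canonically rounded at construction time (lengths to
1e-5 nm, angles and force constants to 1e-3), so write -> read round-trips
to exact equality.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .cg_mapping import CGMapping
from .param_fit import ClassifiedTerms
from .traj_project import CGConnectivity

__all__ = [
    "CGTopology",
    "Bead",
    "make_topology",
    "write_itp",
    "read_itp",
    "write_gro",
    "read_gro",
    "read_gro_frames",
    "write_gro_frames",
    "write_run_protocol",
    "BEAD_MASS",
]

BEAD_MASS = 54.0  # amu, Martini small-bead convention
GRO_FMT = "{:>5d}{:<5s}{:>5s}{:>5d}{:8.3f}{:8.3f}{:8.3f}\n"


def _r5(x: float) -> float:
    return round(float(x), 5)


def _r3(x: float) -> float:
    return round(float(x), 3)


@dataclass(frozen=True)
class Bead:
    name: str
    type: str
    residue_index: int
    residue_name: str
    charge: float = 0.0
    mass: float = BEAD_MASS


@dataclass
class CGTopology:
    """One molecule block; all bead indices are 0-based in memory."""

    name: str
    beads: list[Bead]
    constraints: list[tuple[int, int, float]]
    bonds: list[tuple[int, int, float, float]]
    angles: list[tuple[int, int, int, float, float]]
    dihedrals: list[tuple[int, int, int, int, float, float, int]]
    virtual_sites: list[tuple[int, tuple[int, int, int]]]
    exclusions: list[tuple[int, tuple[int, ...]]]
    nrexcl: int = 1
    angle_funct: int = 1

    def __post_init__(self) -> None:
        self.constraints = [(i, j, _r5(l)) for i, j, l in self.constraints]
        self.bonds = [(i, j, _r5(b), _r3(k)) for i, j, b, k in self.bonds]
        self.angles = [(i, j, k, _r3(t), _r3(kt)) for i, j, k, t, kt in self.angles]
        self.dihedrals = [(i, j, k, l, _r3(p), _r3(kp), int(m))
                          for i, j, k, l, p, kp, m in self.dihedrals]

    def term_counts(self) -> tuple[int, int, int, int, int]:
        """(constraints, bonds, angles, dihedrals, virtual sites)."""
        return (len(self.constraints), len(self.bonds), len(self.angles),
                len(self.dihedrals), len(self.virtual_sites))


def make_topology(molname: str, mapping: CGMapping, connectivity: CGConnectivity,
                  classified: ClassifiedTerms, angle_funct: int = 1) -> CGTopology:
    """Assemble the 8-bead molecule block from a mapping and fitted terms."""
    resnames = molname.split("_")
    if len(resnames) != 2:
        resnames = (molname[:4] or "RES1", "RES2")
    beads = []
    for b in mapping.beads:
        beads.append(
            Bead(
                name=b.bead_name,
                type=b.bead_type,
                residue_index=b.residue_index,
                residue_name=resnames[b.residue_index - 1],
                mass=0.0 if b.is_virtual else BEAD_MASS,
            )
        )
    # dihedral phase: funct-1 potential k(1+cos(n*phi - phi_s)) is minimal at
    # (phi_s + 180)/n, so phi_s = phi0 - 180 puts the minimum at the fit value.
    dihedrals = []
    for i, j, k, l, phi0, kphi, mult in classified.dihedrals:
        phi_s = math.fmod(phi0 * mult - 180.0, 360.0)
        if phi_s <= -180.0:
            phi_s += 360.0
        dihedrals.append((i, j, k, l, phi_s, kphi, mult))
    exclusions = [(site, tuple(cons)) for site, cons in connectivity.vs_constructions]
    return CGTopology(
        name=molname,
        beads=beads,
        constraints=list(classified.constraints),
        bonds=list(classified.bonds),
        angles=[(i, j, k, t, kt) for i, j, k, t, kt in classified.angles],
        dihedrals=dihedrals,
        virtual_sites=list(connectivity.vs_constructions),
        exclusions=exclusions,
        angle_funct=angle_funct,
    )


def write_itp(top: CGTopology, path=None) -> str:
    lines = []
    w = lines.append
    w("; Martini 3 disaccharide topology generated by sugarcg")
    w("[ moleculetype ]")
    w("; name  nrexcl")
    w(f"{top.name}  {top.nrexcl}")
    w("")
    w("[ atoms ]")
    w(";  nr  type  resnr  residue  atom  cgnr  charge  mass")
    for i, b in enumerate(top.beads, start=1):
        w(f"{i:>5d}  {b.type:<6s}{b.residue_index:>5d}  {b.residue_name:<7s}"
          f"{b.name:<6s}{i:>5d}{b.charge:>8.3f}{b.mass:>8.3f}")
    w("")
    w("[ bonds ]")
    w(";   i    j  funct  b0(nm)  k(kJ/mol/nm2)")
    for i, j, b0, k in top.bonds:
        w(f"{i + 1:>5d}{j + 1:>5d}      1  {b0:.5f}  {k:.3f}")
    w("")
    w("[ constraints ]")
    w(";   i    j  funct  length(nm)")
    for i, j, l in top.constraints:
        w(f"{i + 1:>5d}{j + 1:>5d}      1  {l:.5f}")
    w("")
    w("[ angles ]")
    w(";   i    j    k  funct  theta0(deg)  k")
    for i, j, k, t, kt in top.angles:
        w(f"{i + 1:>5d}{j + 1:>5d}{k + 1:>5d}      {top.angle_funct}  {t:.3f}  {kt:.3f}")
    w("")
    w("[ dihedrals ]")
    w(";   i    j    k    l  funct  phi_s(deg)  k(kJ/mol)  mult")
    for i, j, k, l, p, kp, m in top.dihedrals:
        w(f"{i + 1:>5d}{j + 1:>5d}{k + 1:>5d}{l + 1:>5d}      1  {p:.3f}  {kp:.3f}  {m}")
    w("")
    w("[ virtual_sitesn ]")
    w("; site  funct  constructing atoms (center of geometry)")
    for site, cons in top.virtual_sites:
        w(f"{site + 1:>5d}   2  " + " ".join(f"{c + 1}" for c in cons))
    w("")
    w("[ exclusions ]")
    for i, js in top.exclusions:
        w(f"{i + 1:>5d}  " + " ".join(f"{j + 1}" for j in js))
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text, encoding="utf-8")
    return text


def read_itp(path) -> CGTopology:
    """Parse an itp written by :func:`write_itp` back into a CGTopology."""
    if hasattr(path, "read"):
        text = path.read()
        source = "<stream>"
    else:
        text = Path(path).read_text(encoding="utf-8")
        source = str(path)
    section = None
    name, nrexcl = None, 1
    beads: list[Bead] = []
    constraints, bonds, angles, dihedrals, vsites, excl = [], [], [], [], [], []
    angle_funct = 1
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split(";", 1)[0].strip()
        if not line:
            continue
        if line.startswith("["):
            section = line.strip("[] ").lower()
            continue
        tok = line.split()
        try:
            if section == "moleculetype":
                name, nrexcl = tok[0], int(tok[1])
            elif section == "atoms":
                beads.append(Bead(name=tok[4], type=tok[1], residue_index=int(tok[2]),
                                  residue_name=tok[3], charge=float(tok[6]),
                                  mass=float(tok[7])))
            elif section == "bonds":
                bonds.append((int(tok[0]) - 1, int(tok[1]) - 1,
                              float(tok[3]), float(tok[4])))
            elif section == "constraints":
                constraints.append((int(tok[0]) - 1, int(tok[1]) - 1, float(tok[3])))
            elif section == "angles":
                angle_funct = int(tok[3])
                angles.append((int(tok[0]) - 1, int(tok[1]) - 1, int(tok[2]) - 1,
                               float(tok[4]), float(tok[5])))
            elif section == "dihedrals":
                dihedrals.append((int(tok[0]) - 1, int(tok[1]) - 1, int(tok[2]) - 1,
                                  int(tok[3]) - 1, float(tok[5]), float(tok[6]),
                                  int(tok[7])))
            elif section == "virtual_sitesn":
                if int(tok[1]) != 2:
                    raise ValueError(f"unsupported virtual_sitesn funct {tok[1]}")
                vsites.append((int(tok[0]) - 1, tuple(int(t) - 1 for t in tok[2:])))
            elif section == "exclusions":
                excl.append((int(tok[0]) - 1, tuple(int(t) - 1 for t in tok[1:])))
            elif section is None:
                raise ValueError("content before first section")
        except (IndexError, ValueError) as exc:
            raise ValueError(f"{source}:{lineno}: malformed itp line: {exc}") from exc
    if name is None:
        raise ValueError(f"{source}: missing [moleculetype]")
    return CGTopology(name=name, beads=beads, constraints=constraints, bonds=bonds,
                      angles=angles, dihedrals=dihedrals, virtual_sites=vsites,
                      exclusions=excl, nrexcl=nrexcl, angle_funct=angle_funct)


# --------------------------------------------------------------------------
# GRO coordinates (nm, fixed columns, no velocities)
# --------------------------------------------------------------------------

def _gro_frame_text(coords, box, names, resnames, resids, title="sugarcg",
                    time_ps=None) -> str:
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    header = title if time_ps is None else f"{title} t= {time_ps:.3f}"
    out = [header, f"{n:>5d}"]
    for i in range(n):
        nm = names[i][:5]
        rn = resnames[i][:5]
        out.append(GRO_FMT.format(resids[i] % 100000, rn, nm, (i + 1) % 100000,
                                  coords[i, 0], coords[i, 1], coords[i, 2])[:-1])
    out.append(f"{box[0]:10.5f}{box[1]:10.5f}{box[2]:10.5f}")
    return "\n".join(out) + "\n"


def write_gro(coords, box, path, names, resnames, resids, title="sugarcg",
              time_ps=None) -> None:
    Path(path).write_text(
        _gro_frame_text(coords, box, names, resnames, resids, title, time_ps),
        encoding="utf-8",
    )


def write_gro_frames(traj_coords, box, times, path, names, resnames, resids,
                     title="sugarcg") -> None:
    """Write a multi-frame (concatenated) GRO trajectory."""
    box = np.asarray(box, dtype=float)
    with open(path, "w", encoding="utf-8") as fh:
        for f in range(len(traj_coords)):
            b = box[f] if box.ndim == 2 else box
            fh.write(_gro_frame_text(traj_coords[f], b, names, resnames, resids,
                                     title, time_ps=float(times[f])))


def _parse_gro_block(lines, start):
    import re

    title = lines[start]
    m = re.search(r"t=\s*([-0-9.eE+]+)", title)
    time_ps = float(m.group(1)) if m else None
    n = int(lines[start + 1])
    coords = np.empty((n, 3))
    names, resnames, resids = [], [], []
    for i in range(n):
        ln = lines[start + 2 + i]
        resids.append(int(ln[0:5]))
        resnames.append(ln[5:10].strip())
        names.append(ln[10:15].strip())
        coords[i] = [float(ln[20:28]), float(ln[28:36]), float(ln[36:44])]
    box = np.array([float(x) for x in lines[start + 2 + n].split()[:3]])
    meta = {"names": names, "resnames": resnames, "resids": resids, "title": title}
    return coords, box, time_ps, meta, start + 3 + n


def read_gro(path):
    """Read a single GRO frame -> (coords nm, box nm, meta dict)."""
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    coords, box, time_ps, meta, _ = _parse_gro_block(lines, 0)
    meta["time_ps"] = time_ps
    return coords, box, meta


def read_gro_frames(path):
    """Iterate (coords, box, time_ps, meta) over a multi-frame GRO file."""
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    pos = 0
    while pos < len(lines) and lines[pos].strip():
        coords, box, time_ps, meta, pos = _parse_gro_block(lines, pos)
        yield coords, box, time_ps, meta


# --------------------------------------------------------------------------
# run-protocol parameter files
# --------------------------------------------------------------------------

_COMMON_MD = {
    "integrator": "md",
    "cutoff-scheme": "Verlet",
    "coulombtype": "reaction-field",
    "rcoulomb": 1.1,
    "epsilon_r": 15,
    "vdw-type": "cutoff",
    "vdw-modifier": "Potential-shift-verlet",
    "rvdw": 1.1,
    "tcoupl": "v-rescale",
    "ref_t": 300,
    "tau_t": 1.0,
    "constraints": "none",  # ring constraints live in the topology
    "constraint-algorithm": "lincs",
}

_PROTOCOLS = {
    ("simple", "minimization"): {
        "integrator": "steep", "nsteps": 500, "emtol": 100,
    },
    ("simple", "equilibration"): {  # 100 ns NVT, dt 20 fs
        **_COMMON_MD, "dt": 0.02, "nsteps": 5_000_000, "pcoupl": "no",
    },
    ("simple", "production"): {  # 1 us NPT
        **_COMMON_MD, "dt": 0.02, "nsteps": 50_000_000,
        "pcoupl": "c-rescale", "ref_p": 1.0, "tau_p": 4.0,
        "compressibility": 3e-4,
    },
    ("soft", "minimization"): {  # flexible ring bonds during minimization
        "integrator": "steep", "nsteps": 500, "emtol": 100, "define": "-DFLEXIBLE",
    },
    ("soft", "stage1"): {  # 25 ns NVT, dt 10 fs, flexible ring bonds
        **_COMMON_MD, "dt": 0.01, "nsteps": 2_500_000, "pcoupl": "no",
        "define": "-DFLEXIBLE",
    },
    ("soft", "stage2"): {  # 50 ns NVT, dt 20 fs, flexible ring bonds
        **_COMMON_MD, "dt": 0.02, "nsteps": 2_500_000, "pcoupl": "no",
        "define": "-DFLEXIBLE",
    },
    ("soft", "stage3"): {  # 50 ns NVT, dt 20 fs, ring constraints on
        **_COMMON_MD, "dt": 0.02, "nsteps": 2_500_000, "pcoupl": "no",
    },
    ("soft", "production"): {
        **_COMMON_MD, "dt": 0.02, "nsteps": 50_000_000,
        "pcoupl": "c-rescale", "ref_p": 1.0, "tau_p": 4.0,
        "compressibility": 3e-4,
    },
}


def write_run_protocol(kind: str, stage: str, path=None) -> str:
    """Emit the mdp-style settings for one equilibration/production stage."""
    key = (kind, stage)
    if key not in _PROTOCOLS:
        valid = sorted({k for k in _PROTOCOLS})
        raise ValueError(f"unknown protocol {key}; valid: {valid}")
    lines = [f"; sugarcg run protocol: {kind}/{stage}"]
    for k, v in _PROTOCOLS[key].items():
        lines.append(f"{k:<22s} = {v}")
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text, encoding="utf-8")
    return text
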