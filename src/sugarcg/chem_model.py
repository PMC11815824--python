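"""Molecular graph model of pyranose monosaccharides and their disaccharides.

The two hexoses handled here, D-glucopyranose and D-mannopyranose, share an
identical covalent topology; they differ only in the orientation of the C2
hydroxyl, which is carried as a stereo-descriptor string on the template.
Coarse-grained mapping is purely graph based, so the 2D atom graph is the
object everything downstream consumes; stereochemistry enters only through
the all-atom trajectories that are projected onto beads.

A disaccharide is described by a donor residue (non-reducing end, contributes
its anomeric C1 to the glycosidic bond), an acceptor residue (reducing end)
and a linkage position in {1,2,3,4,6}.  Condensation removes the donor's
anomeric hydroxyl (O1 + HO1) and the acceptor's hydroxyl hydrogen at the
linkage position; the glycosidic oxygen is the acceptor's retained O_x.

Naming follows the GLYCAM residue-code convention: the reducing residue is
coded ``<pos><S><A>`` and the terminal donor ``0<S><A>`` where S is G/M and
A is A/B for the alpha/beta anomer, joined with an underscore — e.g.
``4GB_0GA`` is beta-maltose, ``1GA_0GA`` is trehalose.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from functools import lru_cache
from importlib import resources

import networkx as nx

__all__ = [
    "Sugar",
    "Anomer",
    "VALID_POSITIONS",
    "MonosaccharideTemplate",
    "LinkageSpec",
    "DisaccharideSpec",
    "AtomGraph",
    "load_template",
    "enumerate_disaccharides",
    "glycam_name",
    "parse_glycam_name",
    "build_atom_graph",
    "automation_rate",
]

VALID_POSITIONS = (1, 2, 3, 4, 6)


class Sugar(str, Enum):
    GLC = "GLC"
    MAN = "MAN"

    @property
    def letter(self) -> str:
        return "G" if self is Sugar.GLC else "M"


class Anomer(str, Enum):
    ALPHA = "A"
    BETA = "B"


@dataclass(frozen=True)
class MonosaccharideTemplate:
    """Atom-level template of one pyranose residue, loaded from a data file."""

    sugar_id: Sugar
    atoms: tuple[tuple[str, str, bool], ...]  # (name, element, heavy)
    bonds: tuple[tuple[str, str], ...]
    ring_atoms: tuple[str, ...]  # (C1, C2, C3, C4, C5, O5)
    hydroxyl_map: dict[int, str]
    stereo: dict[str, str] = field(default_factory=dict)

    def atom_names(self) -> tuple[str, ...]:
        return tuple(a[0] for a in self.atoms)

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        for name, element, heavy in self.atoms:
            g.add_node(name, element=element, heavy=heavy)
        g.add_edges_from(self.bonds)
        return g

    def _validate(self) -> None:
        names = self.atom_names()
        if len(set(names)) != len(names):
            raise ValueError(f"{self.sugar_id}: duplicate atom names in template")
        if len(self.ring_atoms) != 6:
            raise ValueError(f"{self.sugar_id}: ring must have 6 atoms")
        g = self.graph()
        ring = list(self.ring_atoms)
        for a, b in zip(ring, ring[1:] + ring[:1]):
            if not g.has_edge(a, b):
                raise ValueError(f"{self.sugar_id}: ring atoms {a}-{b} not bonded")
        if not nx.is_connected(g):
            raise ValueError(f"{self.sugar_id}: template graph is not connected")
        for pos, oxy in self.hydroxyl_map.items():
            if oxy not in names:
                raise ValueError(f"{self.sugar_id}: hydroxyl O for position {pos} missing")


def _parse_template(text: str, source: str) -> MonosaccharideTemplate:
    sugar = None
    atoms: list[tuple[str, str, bool]] = []
    bonds: list[tuple[str, str]] = []
    ring: tuple[str, ...] = ()
    hydroxyl: dict[int, str] = {}
    stereo: dict[str, str] = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        tok = line.split()
        kind = tok[0]
        try:
            if kind == "sugar":
                sugar = Sugar(tok[1])
            elif kind == "atom":
                atoms.append((tok[1], tok[2], tok[3] == "heavy"))
            elif kind == "bond":
                bonds.append((tok[1], tok[2]))
            elif kind == "ring":
                ring = tuple(tok[1:])
            elif kind == "hydroxyl":
                hydroxyl[int(tok[1])] = tok[2]
            elif kind == "stereo":
                stereo[tok[1]] = tok[2]
            else:
                raise ValueError(f"unknown record '{kind}'")
        except (IndexError, ValueError) as exc:
            raise ValueError(f"{source}:{lineno}: bad template line: {exc}") from exc
    if sugar is None:
        raise ValueError(f"{source}: missing 'sugar' record")
    tmpl = MonosaccharideTemplate(
        sugar_id=sugar,
        atoms=tuple(atoms),
        bonds=tuple(bonds),
        ring_atoms=ring,
        hydroxyl_map=hydroxyl,
        stereo=stereo,
    )
    tmpl._validate()
    return tmpl


@lru_cache(maxsize=None)
def load_template(sugar: Sugar | str) -> MonosaccharideTemplate:
    """Load the shipped template for ``sugar`` (GLC or MAN)."""
    sugar = Sugar(sugar)
    path = resources.files("sugarcg.data.templates").joinpath(f"{sugar.value}.dat")
    return _parse_template(path.read_text(encoding="utf-8"), str(path))


@dataclass(frozen=True)
class LinkageSpec:
    """Glycosidic linkage: position on the acceptor plus both anomeric states."""

    position: int
    glycosidic_anomer: Anomer  # configuration at the donor (non-reducing) C1
    reducing_anomer: Anomer    # configuration at the acceptor (reducing) C1

    def __post_init__(self) -> None:
        if self.position not in VALID_POSITIONS:
            raise ValueError(
                f"invalid linkage position {self.position}; allowed: {VALID_POSITIONS}"
            )


@dataclass(frozen=True)
class DisaccharideSpec:
    donor: MonosaccharideTemplate
    acceptor: MonosaccharideTemplate
    linkage: LinkageSpec

    @property
    def name(self) -> str:
        return glycam_name(self)

    def __repr__(self) -> str:  # keep test output readable
        return f"DisaccharideSpec({self.name})"


def glycam_name(spec: DisaccharideSpec) -> str:
    """GLYCAM-style code: reducing residue with its linkage digit, donor with 0."""
    l = spec.linkage
    reducing = f"{l.position}{spec.acceptor.sugar_id.letter}{l.reducing_anomer.value}"
    donor = f"0{spec.donor.sugar_id.letter}{l.glycosidic_anomer.value}"
    return f"{reducing}_{donor}"


_NAME_RE = re.compile(r"^([12346])([GM])([AB])_0([GM])([AB])$")


def parse_glycam_name(name: str) -> DisaccharideSpec:
    """Inverse of :func:`glycam_name` (e.g. ``4GB_0GA`` -> beta-maltose spec)."""
    m = _NAME_RE.match(name.strip())
    if m is None:
        raise ValueError(
            f"cannot parse disaccharide name {name!r}; expected <pos><S><A>_0<S><A> "
            "with pos in 1/2/3/4/6, S in G/M, A in A/B"
        )
    pos, acc_s, red_a, don_s, gly_a = m.groups()
    sugars = {"G": Sugar.GLC, "M": Sugar.MAN}
    return DisaccharideSpec(
        donor=load_template(sugars[don_s]),
        acceptor=load_template(sugars[acc_s]),
        linkage=LinkageSpec(int(pos), Anomer(gly_a), Anomer(red_a)),
    )


def enumerate_disaccharides(
    sugars,
    positions=VALID_POSITIONS,
    dedupe_symmetric: bool = False,
) -> list[DisaccharideSpec]:
    """Enumerate homodimer disaccharides for the given sugars and positions.

    Per sugar and position, the 2 x 2 anomer combinations (glycosidic x
    reducing) are produced, in deterministic order.  The 1,1 alpha-beta and
    beta-alpha entries describe the same molecule read from either end; they
    are counted separately by default (matching the conventional count of 20
    glucose disaccharides) and collapsed when ``dedupe_symmetric`` is set.
    """
    sugars = sorted({Sugar(s) for s in sugars}, key=lambda s: s.value)
    if not sugars:
        raise ValueError("sugars must be non-empty")
    positions = sorted(set(positions))
    bad = [p for p in positions if p not in VALID_POSITIONS]
    if bad:
        raise ValueError(f"invalid linkage position(s) {bad}; allowed: {VALID_POSITIONS}")
    specs: list[DisaccharideSpec] = []
    for sugar in sugars:
        tmpl = load_template(sugar)
        for pos in positions:
            for gly in (Anomer.ALPHA, Anomer.BETA):
                for red in (Anomer.ALPHA, Anomer.BETA):
                    if (
                        dedupe_symmetric
                        and pos == 1
                        and gly.value > red.value
                    ):
                        continue  # 1,1 beta-alpha duplicates 1,1 alpha-beta
                    specs.append(
                        DisaccharideSpec(tmpl, tmpl, LinkageSpec(pos, gly, red))
                    )
    return specs


#: node identifier in an AtomGraph: (residue_index, atom_name); residue 1 is
#: the reducing/acceptor residue, residue 2 the terminal donor.
AtomRef = tuple[int, str]


@dataclass(frozen=True)
class AtomGraph:
    """Condensed disaccharide graph with a canonical atom order."""

    spec: DisaccharideSpec
    graph: nx.Graph
    glycosidic_oxygen: AtomRef
    atom_order: tuple[AtomRef, ...]

    @property
    def n_atoms(self) -> int:
        return len(self.atom_order)

    def index(self) -> dict[AtomRef, int]:
        return {ref: i for i, ref in enumerate(self.atom_order)}

    def is_heavy(self, ref: AtomRef) -> bool:
        return self.graph.nodes[ref]["heavy"]


def build_atom_graph(spec: DisaccharideSpec) -> AtomGraph:
    """Join donor and acceptor templates through one glycosidic oxygen.

    The acceptor's hydroxyl at the linkage position loses its hydrogen and
    the donor loses its anomeric O1/HO1 pair, so the disaccharide has
    2 x 24 - 3 = 45 atoms.  A 1,1 linkage is the donor C1 - (acceptor O1) -
    acceptor C1 bridge.
    """
    pos = spec.linkage.position
    removed = {
        1: {(1, f"HO{pos}")},  # acceptor loses the hydroxyl H at the linkage
        2: {(2, "O1"), (2, "HO1")},  # donor loses the anomeric hydroxyl
    }
    g = nx.Graph()
    order: list[AtomRef] = []
    for resid, tmpl in ((1, spec.acceptor), (2, spec.donor)):
        skip = removed[resid]
        for name, element, heavy in tmpl.atoms:
            ref = (resid, name)
            if ref in skip:
                continue
            g.add_node(ref, element=element, heavy=heavy, resid=resid, name=name)
            order.append(ref)
        for a, b in tmpl.bonds:
            ra, rb = (resid, a), (resid, b)
            if ra in g and rb in g:
                g.add_edge(ra, rb)
    glyc_o = (1, f"O{pos}")
    g.add_edge((2, "C1"), glyc_o)
    if not nx.is_connected(g):
        raise ValueError(f"{spec.name}: condensed graph is not connected")
    return AtomGraph(spec=spec, graph=g, glycosidic_oxygen=glyc_o, atom_order=tuple(order))


def automation_rate(n_total: int, n_manual: int) -> float:
    """Percentage of systems handled without manual mapping intervention."""
    if n_total <= 0 or n_manual < 0 or n_manual > n_total:
        raise ValueError("need 0 <= n_manual <= n_total with n_total > 0")
    return 100.0 * (n_total - n_manual) / n_total
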