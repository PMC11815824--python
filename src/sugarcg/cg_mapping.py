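"""Atom-to-bead assignment for Martini 3 disaccharides.

Each monosaccharide is represented by three real beads plus one massless
virtual site constructed at the center of geometry of those three beads
(ring-stacking aid).  One of the donor's beads additionally carries the
glycosidic bond: for 1->1/2/3/4 linkages it is seeded with the glycosidic
oxygen plus the donor anomeric-carbon group, for 1->6 linkages with the
acceptor's exocyclic C6/O6 group plus the donor C1/O5 pair.  The exact
heavy-atom composition per linkage class lives in an editable rules table
(:class:`MappingRules`); hydrogens always travel with their heavy atom.

A valid mapping is a partition: every atom in exactly one real bead, each
real bead 3-5 heavy atoms and contiguous in the molecular graph, each
residue's pyranose ring spanned by its three beads.  Violations raise
:class:`MappingError` naming the offending atoms — the same failure modes
(unassigned atoms, "split" beads) that force a fall-back to a manually
written mapping file, whose dialect is implemented here as well.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

import networkx as nx

from .chem_model import AtomGraph, AtomRef, Sugar

__all__ = [
    "MappingError",
    "BeadDefinition",
    "CGMapping",
    "MappingRules",
    "DEFAULT_RULES",
    "assign_beads",
    "bead_type_of",
    "read_mapping_file",
    "write_mapping_file",
]

HEAVY_MIN, HEAVY_MAX = 3, 5


class MappingError(RuntimeError):
    """Automated mapping failed; fall back to a manual mapping file."""


@dataclass(frozen=True)
class BeadDefinition:
    bead_name: str
    bead_type: str
    atoms: tuple[AtomRef, ...]  # empty for virtual sites
    residue_index: int
    is_virtual: bool = False


@dataclass(frozen=True)
class CGMapping:
    """Ordered beads (A1..A3, B1..B3, VS1, VS2) plus VS construction triples."""

    beads: tuple[BeadDefinition, ...]
    virtual_sites: tuple[tuple[int, tuple[str, str, str]], ...]

    @property
    def real_beads(self) -> tuple[BeadDefinition, ...]:
        return tuple(b for b in self.beads if not b.is_virtual)

    def bead_index(self, name: str) -> int:
        for i, b in enumerate(self.beads):
            if b.bead_name == name:
                return i
        raise KeyError(name)

    def atom_to_bead(self) -> dict[AtomRef, int]:
        out: dict[AtomRef, int] = {}
        for i, b in enumerate(self.beads):
            for ref in b.atoms:
                out[ref] = i
        return out

    def glycosidic_bead_index(self, glyc_o: AtomRef) -> int:
        hits = [i for i, b in enumerate(self.beads) if glyc_o in b.atoms]
        if len(hits) != 1:
            raise MappingError(
                f"glycosidic oxygen {glyc_o} appears in {len(hits)} beads"
            )
        return hits[0]


@dataclass(frozen=True)
class MappingRules:
    """Editable defaults for bead composition and typing.

    ``glyco_donor_atoms``/``glyco_foreign_atoms`` and the slot tables are
    keyed by linkage class: every position but 6 uses the ``"124"`` entry,
    position 6 the ``"6"`` entry.  Heavy-atom names only; hydrogens follow.
    """

    acceptor_types: tuple[str, str, str] = ("SP4r", "SP1r", "SP4r")
    donor_types: tuple[str, str, str] = ("SN6", "SP1r", "SP4r")
    glyco_type_default: str = "SN6"
    glyco_type_overrides: dict = field(
        default_factory=lambda: {(6, Sugar.MAN): "SN6r"}
    )
    vs_type: str = "TC4"
    # per-class heavy-atom slots; acceptor slot entries may name the glycosidic
    # oxygen, which is stripped at assignment time for positions 1-4.
    donor_slots: dict = field(
        default_factory=lambda: {
            "124": (("C1", "C2", "O2"), ("C3", "O3", "C4", "O4"), ("C5", "O5", "C6", "O6")),
            "6": (("C1", "O5"), ("C2", "O2", "C3", "O3"), ("C4", "O4", "C5", "C6", "O6")),
        }
    )
    acceptor_slots: dict = field(
        default_factory=lambda: {
            "124": (("C1", "O1", "C2", "O2"), ("C3", "O3", "C4", "O4"), ("C5", "O5", "C6", "O6")),
            "6": (("C1", "O1", "O5"), ("C2", "O2", "C3", "O3"), ("C4", "O4", "C5")),
        }
    )
    # foreign (acceptor-residue) heavy atoms pulled into the donor glyco bead,
    # besides the glycosidic oxygen itself for positions 1-4.
    glyco_foreign_extra: dict = field(default_factory=lambda: {"124": (), "6": ("C6",)})

    @staticmethod
    def linkage_class(position: int) -> str:
        return "6" if position == 6 else "124"

    def glyco_type(self, position: int, donor_sugar: Sugar) -> str:
        return self.glyco_type_overrides.get(
            (position, donor_sugar), self.glyco_type_default
        )


DEFAULT_RULES = MappingRules()


def bead_type_of(rules: MappingRules, role: str, slot: int, position: int,
                 sugar: Sugar) -> str:
    """Bead-type lookup keyed by (residue role, bead slot, linkage, sugar)."""
    if role not in ("donor", "acceptor") or slot not in (0, 1, 2):
        raise KeyError(f"no bead type for role={role!r} slot={slot}")
    if position not in (1, 2, 3, 4, 6):
        raise KeyError(f"no bead type rule for linkage position {position}")
    if role == "donor" and slot == 0:
        return rules.glyco_type(position, sugar)
    table = rules.donor_types if role == "donor" else rules.acceptor_types
    return table[slot]


def _hydrogens_of(graph: nx.Graph, heavy: AtomRef) -> list[AtomRef]:
    return sorted(
        n for n in graph.neighbors(heavy) if not graph.nodes[n]["heavy"]
    )


def _expand_with_hydrogens(graph: nx.Graph, heavy_refs: list[AtomRef]) -> tuple[AtomRef, ...]:
    out: list[AtomRef] = []
    for ref in heavy_refs:
        out.append(ref)
        out.extend(_hydrogens_of(graph, ref))
    return tuple(out)


def assign_beads(atom_graph: AtomGraph, rules: MappingRules = DEFAULT_RULES) -> CGMapping:
    """Deterministically partition a disaccharide graph into 6 beads + 2 VS."""
    g = atom_graph.graph
    pos = atom_graph.spec.linkage.position
    cls = MappingRules.linkage_class(pos)
    glyc_o = atom_graph.glycosidic_oxygen

    beads: list[BeadDefinition] = []
    # acceptor (residue 1)
    for slot, names in enumerate(rules.acceptor_slots[cls]):
        heavy = [(1, n) for n in names if (1, n) != glyc_o and (1, n) in g]
        beads.append(
            BeadDefinition(
                bead_name=f"A{slot + 1}",
                bead_type=bead_type_of(rules, "acceptor", slot, pos,
                                       atom_graph.spec.acceptor.sugar_id),
                atoms=_expand_with_hydrogens(g, heavy),
                residue_index=1,
            )
        )
    # donor (residue 2); slot 0 is the glycosidic bead
    foreign = [(1, n) for n in rules.glyco_foreign_extra[cls]]
    if cls == "124":
        foreign = [glyc_o] + foreign
    else:
        foreign = foreign + [glyc_o]  # for 1->6 the glycosidic O is acceptor O6
    for slot, names in enumerate(rules.donor_slots[cls]):
        heavy = [(2, n) for n in names if (2, n) in g]
        if slot == 0:
            heavy = heavy + [f for f in foreign if f in g]
        beads.append(
            BeadDefinition(
                bead_name=f"B{slot + 1}",
                bead_type=bead_type_of(rules, "donor", slot, pos,
                                       atom_graph.spec.donor.sugar_id),
                atoms=_expand_with_hydrogens(g, heavy),
                residue_index=2,
            )
        )

    vs = (
        (1, ("A1", "A2", "A3")),
        (2, ("B1", "B2", "B3")),
    )
    for i, (resid, triple) in enumerate(vs, start=1):
        beads.append(
            BeadDefinition(
                bead_name=f"VS{i}",
                bead_type=rules.vs_type,
                atoms=(),
                residue_index=resid,
                is_virtual=True,
            )
        )
    mapping = CGMapping(beads=tuple(beads), virtual_sites=vs)
    validate_mapping(mapping, atom_graph)
    return mapping


def validate_mapping(mapping: CGMapping, atom_graph: AtomGraph) -> None:
    """Enforce the partition/contiguity/heavy-count invariants."""
    g = atom_graph.graph
    seen: dict[AtomRef, str] = {}
    for bead in mapping.real_beads:
        for ref in bead.atoms:
            if ref not in g:
                raise MappingError(
                    f"bead {bead.bead_name} references unknown atom {ref}"
                )
            if ref in seen:
                raise MappingError(
                    f"atom {ref} assigned to both {seen[ref]} and {bead.bead_name}"
                )
            seen[ref] = bead.bead_name
    missing = [ref for ref in atom_graph.atom_order if ref not in seen]
    if missing:
        raise MappingError(
            f"atoms not assigned to any bead: {missing}; "
            "write a manual mapping file for this linkage"
        )
    for bead in mapping.real_beads:
        heavy = [r for r in bead.atoms if g.nodes[r]["heavy"]]
        if not HEAVY_MIN <= len(heavy) <= HEAVY_MAX:
            raise MappingError(
                f"bead {bead.bead_name} maps {len(heavy)} heavy atoms "
                f"({heavy}); expected {HEAVY_MIN}-{HEAVY_MAX}"
            )
        sub = g.subgraph(bead.atoms)
        if not nx.is_connected(sub):
            raise MappingError(
                f"bead {bead.bead_name} is split (non-contiguous): {bead.atoms}; "
                "write a manual mapping file for this linkage"
            )
        for ref in bead.atoms:
            if not g.nodes[ref]["heavy"]:
                heavy_nb = [n for n in g.neighbors(ref) if g.nodes[n]["heavy"]]
                if heavy_nb and seen[heavy_nb[0]] != bead.bead_name:
                    raise MappingError(
                        f"hydrogen {ref} in {bead.bead_name} but its heavy atom "
                        f"{heavy_nb[0]} is in {seen[heavy_nb[0]]}"
                    )
    mapping.glycosidic_bead_index(atom_graph.glycosidic_oxygen)
    # each residue's ring must be spanned by its three real beads
    for resid, tmpl in ((1, atom_graph.spec.acceptor), (2, atom_graph.spec.donor)):
        ring_beads = {seen[(resid, name)] for name in tmpl.ring_atoms if (resid, name) in seen}
        res_beads = {b.bead_name for b in mapping.real_beads if b.residue_index == resid}
        if ring_beads != res_beads:
            raise MappingError(
                f"residue {resid} ring atoms span beads {sorted(ring_beads)}, "
                f"expected all of {sorted(res_beads)}"
            )


# ---------------------------------------------------------------------------
# manual mapping file dialect
#
#   # comment
#   <residue_index> <bead_name> <bead_type> <atom> [<atom> ...]
#   VS <residue_index> <bead1> <bead2> <bead3>
#
# Atom tokens are bare names for atoms of the bead's own residue and
# "<residue_index>:<name>" for foreign atoms (the glycosidic bead crosses the
# residue boundary).  UTF-8, whitespace separated.
# ---------------------------------------------------------------------------

_ATOM_TOKEN = re.compile(r"^(?:(\d+):)?([A-Z][A-Z0-9]{0,3})$")


def write_mapping_file(mapping: CGMapping, path=None) -> str:
    """Serialize a mapping to the manual-file dialect; returns the text."""
    lines = ["# sugarcg bead mapping file"]
    for bead in mapping.real_beads:
        toks = []
        for resid, name in bead.atoms:
            toks.append(name if resid == bead.residue_index else f"{resid}:{name}")
        lines.append(
            f"{bead.residue_index} {bead.bead_name} {bead.bead_type} " + " ".join(toks)
        )
    for resid, triple in mapping.virtual_sites:
        lines.append(f"VS {resid} " + " ".join(triple))
    text = "\n".join(lines) + "\n"
    if path is not None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(text)
    return text


def read_mapping_file(path, vs_type: str = DEFAULT_RULES.vs_type) -> CGMapping:
    """Parse the manual mapping dialect; errors carry the offending line number."""
    if hasattr(path, "read"):
        text = path.read()
        source = "<stream>"
    else:
        with open(path, "r", encoding="utf-8") as fh:
            text = fh.read()
        source = str(path)
    beads: list[BeadDefinition] = []
    vs: list[tuple[int, tuple[str, str, str]]] = []
    seen_atoms: dict[AtomRef, int] = {}
    seen_names: set[str] = set()
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        tok = line.split()
        if tok[0] == "VS":
            if len(tok) != 5:
                raise MappingError(f"{source}:{lineno}: VS line needs 4 fields")
            vs.append((int(tok[1]), (tok[2], tok[3], tok[4])))
            continue
        if len(tok) < 4:
            raise MappingError(f"{source}:{lineno}: bead line needs >= 4 fields")
        try:
            resid = int(tok[0])
        except ValueError:
            raise MappingError(f"{source}:{lineno}: bad residue index {tok[0]!r}") from None
        bead_name, bead_type = tok[1], tok[2]
        if bead_name in seen_names:
            raise MappingError(f"{source}:{lineno}: duplicate bead name {bead_name}")
        seen_names.add(bead_name)
        atoms: list[AtomRef] = []
        for t in tok[3:]:
            m = _ATOM_TOKEN.match(t)
            if m is None:
                raise MappingError(f"{source}:{lineno}: unknown atom token {t!r}")
            ref = (int(m.group(1)) if m.group(1) else resid, m.group(2))
            if ref in seen_atoms:
                raise MappingError(
                    f"{source}:{lineno}: atom {ref} already assigned at line "
                    f"{seen_atoms[ref]}"
                )
            seen_atoms[ref] = lineno
            atoms.append(ref)
        beads.append(
            BeadDefinition(bead_name, bead_type, tuple(atoms), resid)
        )
    residues = {b.residue_index for b in beads}
    for resid, triple in vs:
        if resid not in residues:
            raise MappingError(f"{source}: VS declared for missing residue {resid}")
        for name in triple:
            if name not in seen_names:
                raise MappingError(f"{source}: VS references unknown bead {name}")
    if len(residues) < 2:
        raise MappingError(f"{source}: mapping must cover two residues, got {sorted(residues)}")
    for i, (resid, triple) in enumerate(vs, start=1):
        beads.append(
            BeadDefinition(f"VS{i}", vs_type, (), resid, is_virtual=True)
        )
    return CGMapping(beads=tuple(beads), virtual_sites=tuple(vs))
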