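"""Solution composition and minimum-distance aggregation networks.

Composition: the disaccharide-to-water ratio for a target concentration is
computed from molecular weights alone, approximating the solution volume by
the water mass at 1.000 g/cm^3; with trehalose (342.30 g/mol) this makes
7609 all-atom waters + 20 disaccharides evaluate to 50 g/L at the printed
precision, and the standard 4:1 water mapping turns 7609 waters into 1902
CG water beads.

Aggregation: per frame, molecules are nodes of a graph whose edges carry
the minimum bead-bead distance between the two molecules under the
orthorhombic minimum-image convention; edges longer than the 0.47 nm
(4.7 angstrom) cutoff are discarded (the cutoff itself is inclusive) and
connected components give the aggregate-size multiset.  Size distributions
pool frames at a fixed stride over the final window of one or more
replicas; the time evolution tracks per-frame component statistics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "MW_WATER",
    "MW_TREHALOSE",
    "DEFAULT_CUTOFF_NM",
    "CompositionSpec",
    "AggregateRecord",
    "waters_for_concentration",
    "concentration_of",
    "cg_water_beads",
    "min_intermolecular_distance",
    "distance_network",
    "aggregate_sizes",
    "aggregate_records",
    "size_distribution",
    "time_evolution",
]

MW_WATER = 18.015       # g/mol
MW_TREHALOSE = 342.30   # g/mol
DEFAULT_CUTOFF_NM = 0.47  # 4.7 angstrom network filter


def _require_positive(**kwargs) -> None:
    for name, value in kwargs.items():
        if value <= 0:
            raise ValueError(f"{name} must be positive, got {value}")


def concentration_of(n_solute: int, mw_solute: float, aa_waters: int,
                     mw_water: float = MW_WATER) -> float:
    """Solute concentration in g/L, water mass standing in for volume."""
    _require_positive(n_solute=n_solute, mw_solute=mw_solute,
                      aa_waters=aa_waters, mw_water=mw_water)
    water_litres = aa_waters * mw_water / 1000.0 / 1000.0  # g -> kg -> L at 1 g/cm3
    return n_solute * mw_solute / 1000.0 / water_litres / 1000.0 * 1000.0


def waters_for_concentration(n_solute: int, mw_solute: float, conc_g_per_l: float,
                             mw_water: float = MW_WATER) -> int:
    """Water count needed so n_solute molecules sit at the target g/L."""
    _require_positive(n_solute=n_solute, mw_solute=mw_solute,
                      conc_g_per_l=conc_g_per_l, mw_water=mw_water)
    return round(n_solute * mw_solute * 1000.0 / (conc_g_per_l * mw_water))


def cg_water_beads(aa_waters: int) -> int:
    """Standard 4:1 all-atom-water to Martini-water-bead mapping."""
    if aa_waters < 0:
        raise ValueError("aa_waters must be non-negative")
    return aa_waters // 4


@dataclass(frozen=True)
class CompositionSpec:
    n_solute: int
    mw_solute: float = MW_TREHALOSE
    mw_water: float = MW_WATER
    concentration: float = 50.0  # g/L
    aa_waters: int = 0
    cg_beads: int = 0

    @classmethod
    def for_concentration(cls, n_solute: int, concentration: float = 50.0,
                          mw_solute: float = MW_TREHALOSE,
                          mw_water: float = MW_WATER) -> "CompositionSpec":
        waters = waters_for_concentration(n_solute, mw_solute, concentration, mw_water)
        return cls(n_solute=n_solute, mw_solute=mw_solute, mw_water=mw_water,
                   concentration=concentration, aa_waters=waters,
                   cg_beads=cg_water_beads(waters))


def _check_box(box) -> np.ndarray:
    box = np.asarray(box, dtype=float)
    if box.shape != (3,):
        raise ValueError(
            "only orthorhombic boxes (three edge lengths) are supported; "
            "triclinic boxes are rejected"
        )
    if np.any(box <= 0):
        raise ValueError("box edges must be positive")
    return box


def min_intermolecular_distance(mol_i: np.ndarray, mol_j: np.ndarray, box) -> float:
    """Minimum over all bead pairs of minimum-image distances (nm)."""
    a = np.asarray(mol_i, dtype=float)
    b = np.asarray(mol_j, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty molecule")
    box = _check_box(box)
    delta = a[:, None, :] - b[None, :, :]
    delta -= box * np.round(delta / box)
    return float(np.sqrt((delta ** 2).sum(axis=-1)).min())


def distance_network(molecules, box, cutoff: float = DEFAULT_CUTOFF_NM) -> nx.Graph:
    """Molecule graph keeping edges with minimum distance <= cutoff (inclusive)."""
    g = nx.Graph()
    g.add_nodes_from(range(len(molecules)))
    for i in range(len(molecules)):
        for j in range(i + 1, len(molecules)):
            d = min_intermolecular_distance(molecules[i], molecules[j], box)
            if d <= cutoff:
                g.add_edge(i, j, distance=d)
    return g


@dataclass(frozen=True)
class AggregateRecord:
    time: float
    sizes: tuple[int, ...]  # sorted descending; sums to the molecule count

    @property
    def n_molecules(self) -> int:
        return sum(self.sizes)

    @property
    def largest(self) -> int:
        return self.sizes[0]


def aggregate_sizes(molecules, box, cutoff: float = DEFAULT_CUTOFF_NM,
                    time: float = 0.0) -> AggregateRecord:
    """Connected-component sizes of the cutoff-filtered network, one frame."""
    if len(molecules) == 0:
        raise ValueError("need at least one molecule")
    g = distance_network(molecules, box, cutoff)
    sizes = sorted((len(c) for c in nx.connected_components(g)), reverse=True)
    return AggregateRecord(time=time, sizes=tuple(sizes))


def _frame_molecules(traj, groups):
    """Yield (time, [per-molecule coords], box) over a Trajectory."""
    boxes = traj.box_per_frame()
    for f in range(traj.n_frames):
        mols = [traj.coords[f, idx] for idx in groups]
        yield float(traj.times[f]), mols, boxes[f]


def aggregate_records(traj, groups, cutoff: float = DEFAULT_CUTOFF_NM) -> list[AggregateRecord]:
    return [
        aggregate_sizes(mols, box, cutoff, time=t)
        for t, mols, box in _frame_molecules(traj, groups)
    ]


def _select_window(records, window_ps: float | None, stride_ps: float | None):
    times = np.array([r.time for r in records])
    span = times.max() - times.min()
    if window_ps is not None:
        if window_ps > span and len(records) > 1:
            raise ValueError(
                f"window {window_ps} ps exceeds trajectory span {span} ps"
            )
        records = [r for r in records if r.time >= times.max() - window_ps]
    if stride_ps is not None and len(records) > 1:
        out, next_t = [], None
        for r in records:
            if next_t is None or r.time >= next_t - 1e-9:
                out.append(r)
                next_t = r.time + stride_ps
        records = out
    return records


def size_distribution(records_or_replicas, window_ps: float | None = None,
                      stride_ps: float | None = None) -> pd.Series:
    """Aggregate-size histogram pooled over frames (and replicas).

    Accepts one replica's record list or a list of replicas; counts are
    indexed by size 1..N where N is the molecule count.
    """
    if len(records_or_replicas) == 0:
        raise ValueError("no records supplied")
    replicas = (records_or_replicas
                if isinstance(records_or_replicas[0], (list, tuple))
                else [records_or_replicas])
    n_mol = replicas[0][0].n_molecules
    counts = np.zeros(n_mol, dtype=int)
    for records in replicas:
        for r in _select_window(list(records), window_ps, stride_ps):
            for s in r.sizes:
                counts[s - 1] += 1
    return pd.Series(counts, index=pd.RangeIndex(1, n_mol + 1, name="size"),
                     name="count")


def time_evolution(records) -> pd.DataFrame:
    """Per-frame aggregate statistics over the full trajectory."""
    if len(records) == 0:
        raise ValueError("no records supplied")
    return pd.DataFrame(
        {
            "time_ps": [r.time for r in records],
            "n_aggregates": [len(r.sizes) for r in records],
            "largest": [r.largest for r in records],
            "mean_size": [float(np.mean(r.sizes)) for r in records],
        }
    )
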