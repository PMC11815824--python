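"""Histogram-overlap statistics and Table-style mean/%delta reports.

Two distributions binned on shared edges are compared by summing the
minimum probability mass per bin: 0 means disjoint, 1 perfect overlap.
The "full" overlap bins over the union of both supports; the "reference"
overlap bins over the reference distribution's own support and reads off
the fraction of the reference that the new data sampled.  The percentage
difference between matched all-atom and coarse-grained means uses the CG
mean as the denominator, 100*(aa - cg)/cg, reported at 2 decimals — the
convention recovered by matching all printed worked examples.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .traj_project import TermSamples, TERM_ORDER

__all__ = [
    "Histogram",
    "histogram_pair",
    "overlap_full",
    "overlap_reference",
    "percent_delta",
    "summarize_terms",
    "report_tsv",
    "report_text",
    "read_series",
    "DEFAULT_BINS",
]

DEFAULT_BINS = 100


@dataclass(frozen=True)
class Histogram:
    """Shared-edge probability-mass histogram (masses sum to 1)."""

    edges: np.ndarray
    masses: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "edges", np.asarray(self.edges, dtype=float))
        object.__setattr__(self, "masses", np.asarray(self.masses, dtype=float))
        if self.edges.ndim != 1 or self.masses.shape != (self.edges.size - 1,):
            raise ValueError("edges/masses shapes inconsistent")
        if np.any(self.masses < 0):
            raise ValueError("negative histogram mass")
        if abs(self.masses.sum() - 1.0) > 1e-12:
            raise ValueError("histogram masses must sum to 1")

    @classmethod
    def from_samples(cls, samples, edges) -> "Histogram":
        counts, _ = np.histogram(np.asarray(samples, dtype=float), bins=edges)
        total = counts.sum()
        if total == 0:
            raise ValueError("no samples fall inside the histogram support")
        return cls(edges=edges, masses=counts / total)


def histogram_pair(a, b, bins: int = DEFAULT_BINS) -> tuple[Histogram, Histogram]:
    """Bin two sample sets on shared edges spanning the union of supports."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both sample sets must be non-empty")
    lo = min(a.min(), b.min())
    hi = max(a.max(), b.max())
    if lo == hi:
        lo, hi = lo - 0.5, hi + 0.5
    edges = np.linspace(lo, hi, bins + 1)
    return Histogram.from_samples(a, edges), Histogram.from_samples(b, edges)


def overlap_full(h1: Histogram, h2: Histogram) -> float:
    """Sum over bins of the minimum mass; symmetric, in [0, 1]."""
    if h1.edges.shape != h2.edges.shape or not np.allclose(h1.edges, h2.edges):
        raise ValueError("histograms must share identical bin edges")
    return float(np.minimum(h1.masses, h2.masses).sum())


def overlap_samples(a, b, bins: int = DEFAULT_BINS) -> float:
    h1, h2 = histogram_pair(a, b, bins=bins)
    return overlap_full(h1, h2)


def overlap_reference(ref_samples, new_samples, bins: int = DEFAULT_BINS) -> float:
    """Fraction of the reference distribution sampled by the new data.

    Bins span the reference's own support; the new data's mass is normalized
    by its total count, so new samples falling outside the reference support
    contribute nothing.
    """
    ref = np.asarray(ref_samples, dtype=float)
    new = np.asarray(new_samples, dtype=float)
    if ref.size == 0 or new.size == 0:
        raise ValueError("both sample sets must be non-empty")
    lo, hi = ref.min(), ref.max()
    if lo == hi:
        lo, hi = lo - 0.5, hi + 0.5
    edges = np.linspace(lo, hi, bins + 1)
    r_counts, _ = np.histogram(ref, bins=edges)
    n_counts, _ = np.histogram(new, bins=edges)
    r = r_counts / r_counts.sum()
    s = n_counts / new.size  # total-count normalization, support-restricted mass
    return float(np.minimum(r, s).sum())


def percent_delta(aa_mean: float, cg_mean: float) -> float:
    """100*(aa - cg)/cg, rounded to the printed 2-decimal precision."""
    if cg_mean == 0:
        raise ZeroDivisionError("CG mean is zero; percent difference undefined")
    return round(100.0 * (aa_mean - cg_mean) / cg_mean, 2)


def summarize_terms(aa: TermSamples, cg: TermSamples, *,
                    last_ps: float | None = None,
                    bins: int = DEFAULT_BINS) -> pd.DataFrame:
    """Per-term mean/sd for both resolutions plus %delta and overlaps.

    Columns follow the topology term order (bond0..bond6, angles, dihedral);
    ``last_ps`` restricts both sample sets to the final window, emulating
    statistics taken over the tail of a production run.
    """
    if set(aa.labels()) != set(cg.labels()):
        raise KeyError(
            f"term labels differ: {sorted(set(aa.labels()) ^ set(cg.labels()))}"
        )
    if last_ps is not None:
        aa = aa.restrict_last(last_ps)
        cg = cg.restrict_last(last_ps)
    cols = [l for l in TERM_ORDER if l in aa.labels()]
    cols += [l for l in aa.labels() if l not in cols]
    rows = {}
    for label in cols:
        x, y = aa[label], cg[label]
        rows[label] = {
            "aa_mean": float(np.mean(x)),
            "aa_sd": float(np.std(x)),
            "cg_mean": float(np.mean(y)),
            "cg_sd": float(np.std(y)),
            "pct_delta": percent_delta(float(np.mean(x)), float(np.mean(y))),
            "overlap_full": overlap_samples(x, y, bins=bins),
            "overlap_ref": overlap_reference(x, y, bins=bins),
        }
    return pd.DataFrame(rows)[cols]


def report_tsv(report: pd.DataFrame, path=None) -> str:
    text = report.to_csv(sep="\t", float_format="%.6g")
    if path is not None:
        Path(path).write_text(text, encoding="utf-8")
    return text


def report_text(report: pd.DataFrame) -> str:
    return report.round(4).to_string()


def read_series(path) -> np.ndarray:
    """One-column numeric file (e.g. an externally computed SASA series)."""
    values = np.loadtxt(path, ndmin=1)
    if values.ndim != 1:
        raise ValueError(f"{path}: expected a single numeric column")
    return values
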