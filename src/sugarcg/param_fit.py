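"""Boltzmann inversion of measured bead distributions into bonded parameters.

For a harmonic term sampled at temperature T, equipartition gives
``Var(x) = k_B T / k``, so the force constant is recovered as
``k = k_B T / Var`` with the equilibrium value at the sample mean.  Bonds
are fitted in nm (k in kJ mol^-1 nm^-2), angles in radians internally
(k in kJ mol^-1 rad^-2, reported eq in degrees), and the single proper
dihedral uses the circular mean as its phase with multiplicity 1
(k in kJ mol^-1).

The fit model is a single Gaussian: a histogram-overlap check against the
fitted Gaussian guards bond fits (reject below threshold) and flags — but
does not block — multimodal angle/dihedral distributions, where a small
secondary population is knowingly absorbed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .traj_project import CGConnectivity, TermSamples, TERM_ORDER

__all__ = [
    "K_BOLTZMANN",
    "ThermoContext",
    "FittedTerm",
    "FitRejectedError",
    "fit_bond",
    "fit_angle",
    "fit_dihedral",
    "fit_all_terms",
    "classify_terms",
    "ClassifiedTerms",
]

log = logging.getLogger(__name__)

K_BOLTZMANN = 0.0083145  # kJ mol^-1 K^-1

MIN_SAMPLES = 100
K_BOND_CAP = 50_000.0  # kJ mol^-1 nm^-2; stiffer terms become constraints
DEFAULT_NORMALITY_THRESHOLD = 0.8


class FitRejectedError(ValueError):
    """Distribution failed the single-Gaussian acceptance check."""


@dataclass
class ThermoContext:
    temperature: float = 300.0  # K

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")

    @property
    def kBT(self) -> float:
        return K_BOLTZMANN * self.temperature


@dataclass
class FittedTerm:
    kind: str  # constraint | bond | angle | dihedral
    eq_value: float  # nm (bond/constraint) or degrees (angle/dihedral)
    force_constant: float | None  # None for constraints
    multiplicity: int | None = None  # dihedrals only
    n_samples: int = 0
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind == "constraint" and self.force_constant is not None:
            raise ValueError("constraints carry no force constant")
        if self.kind != "constraint" and (
            self.force_constant is None or self.force_constant <= 0
        ):
            raise ValueError(f"{self.kind} needs a positive force constant")


def _check_samples(samples: np.ndarray, min_samples: int = MIN_SAMPLES) -> np.ndarray:
    samples = np.asarray(samples, dtype=float).ravel()
    if samples.size < min_samples:
        raise ValueError(f"need >= {min_samples} samples, got {samples.size}")
    return samples


def gaussian_overlap(samples: np.ndarray, mean: float, sd: float,
                     bins: int = 100) -> float:
    """Histogram overlap between samples and their fitted Gaussian.

    Both distributions are binned on the same edges spanning the union of
    the sample range and mean +/- 4 sd; the Gaussian mass per bin comes from
    its CDF.  1 = the data look exactly Gaussian at this bin resolution.
    """
    if sd == 0:
        return 1.0
    lo = min(samples.min(), mean - 4 * sd)
    hi = max(samples.max(), mean + 4 * sd)
    edges = np.linspace(lo, hi, bins + 1)
    emp, _ = np.histogram(samples, bins=edges)
    emp = emp / emp.sum()
    cdf = stats.norm.cdf(edges, loc=mean, scale=sd)
    gauss = np.diff(cdf)
    gauss = gauss / gauss.sum()
    return float(np.minimum(emp, gauss).sum())


def fit_bond(samples, ctx: ThermoContext, *,
             normality_threshold: float | None = DEFAULT_NORMALITY_THRESHOLD,
             k_cap: float = K_BOND_CAP) -> FittedTerm:
    """Fit a harmonic bond (nm); degenerate/ultra-stiff samples become constraints."""
    samples = _check_samples(samples)
    mean = float(samples.mean())
    var = float(samples.var())
    n = samples.size
    if var == 0.0:
        return FittedTerm("constraint", mean, None, n_samples=n,
                          diagnostics={"reason": "zero variance"})
    k = ctx.kBT / var
    if k > k_cap:
        log.info("bond k=%.0f exceeds cap %.0f; converting to constraint", k, k_cap)
        return FittedTerm("constraint", mean, None, n_samples=n,
                          diagnostics={"reason": f"k {k:.0f} above cap {k_cap:.0f}"})
    overlap = gaussian_overlap(samples, mean, np.sqrt(var))
    if normality_threshold is not None and overlap < normality_threshold:
        raise FitRejectedError(
            f"bond distribution is not well described by one Gaussian "
            f"(overlap {overlap:.3f} < {normality_threshold}); inspect for multimodality"
        )
    return FittedTerm("bond", mean, k, n_samples=n,
                      diagnostics={"gaussian_overlap": overlap, "sd": float(np.sqrt(var))})


def fit_angle(samples_deg, ctx: ThermoContext, *,
              jacobian_correction: bool = False,
              multimodal_threshold: float = DEFAULT_NORMALITY_THRESHOLD) -> FittedTerm:
    """Fit a harmonic angle; input degrees, force constant in kJ mol^-1 rad^-2.

    The inversion works in plain angle space by default; the optional
    Jacobian correction reweights samples by 1/sin(theta) before taking
    moments.  Multimodality is flagged in diagnostics, never blocking.
    """
    samples = _check_samples(samples_deg)
    rad = np.radians(samples)
    if jacobian_correction:
        w = 1.0 / np.clip(np.sin(rad), 1e-8, None)
        w = w / w.sum()
        mean_r = float(np.sum(w * rad))
        var_r = float(np.sum(w * (rad - mean_r) ** 2))
    else:
        mean_r = float(rad.mean())
        var_r = float(rad.var())
    if var_r == 0.0:
        raise ValueError("angle samples are constant; cannot invert")
    overlap = gaussian_overlap(samples, float(np.degrees(mean_r)),
                               float(np.degrees(np.sqrt(var_r))))
    diags = {"gaussian_overlap": overlap, "sd_deg": float(np.degrees(np.sqrt(var_r)))}
    if overlap < multimodal_threshold:
        diags["multimodal_suspect"] = True
        log.warning("angle distribution poorly Gaussian (overlap %.3f); "
                    "single-Gaussian fit returned anyway", overlap)
    return FittedTerm("angle", float(np.degrees(mean_r)), ctx.kBT / var_r,
                      n_samples=samples.size, diagnostics=diags)


def fit_dihedral(samples_deg, ctx: ThermoContext, *,
                 multimodal_threshold: float = DEFAULT_NORMALITY_THRESHOLD) -> FittedTerm:
    """Fit one proper dihedral (multiplicity 1) from circular statistics.

    The phase is the circular mean; the force constant comes from the
    variance of deviations wrapped to (-180, 180], so distributions
    straddling the +/-180 seam are handled without artifacts.
    """
    samples = _check_samples(samples_deg)
    rad = np.radians(samples)
    mean_r = float(np.arctan2(np.sin(rad).sum(), np.cos(rad).sum()))
    dev = np.angle(np.exp(1j * (rad - mean_r)))  # wrapped deviations, radians
    var_r = float(np.mean(dev ** 2))
    if var_r == 0.0:
        raise ValueError("dihedral samples are constant; cannot invert")
    dev_deg = np.degrees(dev)
    overlap = gaussian_overlap(dev_deg, float(dev_deg.mean()), float(dev_deg.std()))
    diags = {"gaussian_overlap": overlap, "sd_deg": float(np.degrees(np.sqrt(var_r)))}
    if overlap < multimodal_threshold:
        diags["multimodal_suspect"] = True
        log.warning("dihedral distribution poorly Gaussian (overlap %.3f); "
                    "single-term fit returned anyway", overlap)
    eq_deg = float(np.degrees(mean_r))
    if eq_deg <= -180.0:
        eq_deg += 360.0
    return FittedTerm("dihedral", eq_deg, ctx.kBT / var_r, multiplicity=1,
                      n_samples=samples.size, diagnostics=diags)


def fit_all_terms(samples: TermSamples, ctx: ThermoContext, *,
                  normality_threshold: float | None = DEFAULT_NORMALITY_THRESHOLD,
                  jacobian_correction: bool = False) -> dict[str, FittedTerm]:
    """Fit every measured term; ring distance terms skip the normality gate
    (they are classified as constraints downstream regardless)."""
    fitted: dict[str, FittedTerm] = {}
    for label in samples.labels():
        x = samples[label]
        if label.startswith("bond"):
            gate = normality_threshold if label == "bond3" else None
            fitted[label] = fit_bond(x, ctx, normality_threshold=gate)
        elif label.startswith("angle"):
            fitted[label] = fit_angle(x, ctx, jacobian_correction=jacobian_correction)
        elif label.startswith("dihedral"):
            fitted[label] = fit_dihedral(x, ctx)
        else:
            raise KeyError(f"unknown term label {label!r}")
    return fitted


@dataclass
class ClassifiedTerms:
    """Topology-ready term lists (bead index pairs/tuples + parameters)."""

    constraints: list  # (i, j, length_nm)
    bonds: list        # (i, j, b0_nm, k)
    angles: list       # (i, j, k, theta0_deg, k_theta)
    dihedrals: list    # (i, j, k, l, phi0_deg, k_phi, multiplicity)


def classify_terms(connectivity: CGConnectivity,
                   fitted: dict[str, FittedTerm]) -> ClassifiedTerms:
    """Six ring distance terms become constraints at their mean lengths; the
    inter-monomer term (bond3) stays a harmonic bond."""
    missing = [l for l in TERM_ORDER if l not in fitted]
    if missing:
        raise KeyError(f"fitted terms missing: {missing}")
    pairs = connectivity.distance_pairs()
    constraints = []
    for idx in (0, 1, 2, 4, 5, 6):
        i, j = pairs[idx]
        constraints.append((i, j, fitted[f"bond{idx}"].eq_value))
    inter = fitted["bond3"]
    if inter.kind == "constraint":
        raise ValueError(
            "inter-monomer term (bond3) collapsed to a constraint "
            f"({inter.diagnostics.get('reason')}); it must remain harmonic"
        )
    i, j = pairs[3]
    bonds = [(i, j, inter.eq_value, inter.force_constant)]
    angles = []
    for label, (i, j, k) in zip(TERM_ORDER[7:11], connectivity.angle_triples):
        t = fitted[label]
        angles.append((i, j, k, t.eq_value, t.force_constant))
    i, j, k, l = connectivity.dihedral_quad
    t = fitted["dihedral0"]
    dihedrals = [(i, j, k, l, t.eq_value, t.force_constant, t.multiplicity or 1)]
    return ClassifiedTerms(constraints, bonds, angles, dihedrals)
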