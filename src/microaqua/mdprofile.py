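"""Solvation-shell analysis of particle frames around a macromolecule.

Given coordinate frames holding one central atom per solvent/reactant
molecule plus the macromolecule's atoms in a periodic orthorhombic box, the
analysis bins each particle by its minimum-image distance to the nearest
macromolecule atom into 0.05 nm shells, frame-averages the per-shell species
counts, and forms the per-shell water mole fraction

    x_H2O(r) = <N_H2O(r)> / (<N_H2O(r)> + <N_CPME(r)> + <N_Na(r)>
                             + <N_FA(r)> + <N_4VG(r)>)

The bulk distance r_bulk is the first shell from which the relative change
of x_H2O(r) between consecutive shells stays below a threshold (default
0.1%) for a persistence window of shells; the bulk water fraction is the
count-weighted average beyond it.  A scan of bulk fractions over increasing
total water counts is segmented into lag / linear rise / plateau to locate
the saturation point of the system.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import DomainError, InputError, NoBulkError

__all__ = [
    "SPECIES_ORDER",
    "Frame",
    "RadialProfile",
    "BulkResult",
    "SaturationScan",
    "surface_distances",
    "radial_profile",
    "find_r_bulk",
    "bulk_fraction",
    "analyze_bulk",
    "saturation_scan",
]

#: Canonical particle species and their column order in profiles.
SPECIES_ORDER = ("H2O", "CPME", "Na", "FA", "4VG")


@dataclass(frozen=True)
class Frame:
    """One coordinate frame: box, macromolecule atoms, particle central atoms.

    All coordinates and box lengths in nm; the box is orthorhombic and
    periodic.  ``species`` labels each particle row.
    """

    box: np.ndarray                  # (3,) box lengths
    macromolecule: np.ndarray        # (M, 3) atom coordinates
    species: np.ndarray              # (N,) particle labels
    coordinates: np.ndarray          # (N, 3) particle central-atom coordinates

    def __post_init__(self):
        box = np.asarray(self.box, dtype=float).reshape(3)
        macro = np.asarray(self.macromolecule, dtype=float).reshape(-1, 3)
        coords = np.asarray(self.coordinates, dtype=float).reshape(-1, 3)
        labels = np.asarray(self.species)
        if not np.all(box > 0):
            raise InputError("box lengths must be positive")
        if not (np.isfinite(macro).all() and np.isfinite(coords).all()):
            raise InputError("coordinates must be finite")
        unknown = set(labels.tolist()) - set(SPECIES_ORDER)
        if unknown:
            raise InputError(f"unknown particle species: {sorted(unknown)}")
        if len(labels) != len(coords):
            raise InputError("species labels and coordinates disagree in length")
        object.__setattr__(self, "box", box)
        object.__setattr__(self, "macromolecule", macro)
        object.__setattr__(self, "species", labels)
        object.__setattr__(self, "coordinates", coords)

    def counts(self) -> dict[str, int]:
        return {s: int(np.sum(self.species == s)) for s in SPECIES_ORDER}


def surface_distances(frame: Frame) -> np.ndarray:
    """Minimum-image distance (nm) of every particle to the macromolecule.

    Coordinates outside [0, box) are wrapped; uses a periodic k-d tree, which
    is exact for the orthorhombic minimum-image metric.
    """
    if frame.macromolecule.size == 0:
        raise DomainError("empty macromolecule")
    box = frame.box
    macro = np.mod(frame.macromolecule, box)
    pts = np.mod(frame.coordinates, box)
    if pts.size == 0:
        return np.empty(0)
    tree = cKDTree(macro, boxsize=box)
    d, _ = tree.query(pts, k=1)
    return np.asarray(d, dtype=float)


@dataclass(frozen=True)
class RadialProfile:
    """Frame-averaged per-shell species counts and water mole fraction.

    ``x_h2o`` is nan for unpopulated shells (undefined-fraction flag).
    """

    shell_width: float
    edges: np.ndarray                       # (n_shells + 1,)
    counts: dict[str, np.ndarray]           # species -> (n_shells,) mean counts
    n_frames: int = 1

    def species_counts(self, s: str) -> np.ndarray:
        zeros = np.zeros(len(self.edges) - 1)
        return self.counts.get(s, zeros)

    @property
    def total_counts(self) -> np.ndarray:
        return np.sum([self.species_counts(s) for s in SPECIES_ORDER], axis=0)

    @property
    def x_h2o(self) -> np.ndarray:
        tot = self.total_counts
        with np.errstate(invalid="ignore", divide="ignore"):
            x = np.where(tot > 0, self.species_counts("H2O") / np.where(tot > 0, tot, 1.0), np.nan)
        return x

    @property
    def populated(self) -> np.ndarray:
        return self.total_counts > 0

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "r_lo": self.edges[:-1],
            "r_hi": self.edges[1:],
            "N_H2O": self.species_counts("H2O"),
            "N_CPME": self.species_counts("CPME"),
            "N_Na": self.species_counts("Na"),
            "N_FA": self.species_counts("FA"),
            "N_4VG": self.species_counts("4VG"),
            "x_H2O": self.x_h2o,
        })


@dataclass(frozen=True)
class BulkResult:
    r_bulk: float
    x_h2o_bulk: float
    n_shells: int


@dataclass(frozen=True)
class SaturationScan:
    """Segmented lag/rise/plateau fit of a bulk-water saturation series."""

    n_values: np.ndarray
    x_values: np.ndarray
    saturated: bool
    n_sat: float | None = None
    lag_end: float | None = None
    sse: float = float("nan")


def radial_profile(frames, shell_width: float = 0.05, r_max: float | None = None) -> RadialProfile:
    """Per-shell species counts averaged over frames, plus x_H2O(r).

    The mole-fraction denominator includes every registered species (sodium
    included).  All frames must share the same box.
    """
    frames = list(frames)
    if not frames:
        raise InputError("need at least one frame")
    if shell_width <= 0:
        raise InputError("shell width must be positive")
    box0 = frames[0].box
    for f in frames[1:]:
        if not np.allclose(f.box, box0, rtol=0, atol=1e-9):
            raise InputError("inconsistent box across frames")

    all_d = [surface_distances(f) for f in frames]
    if r_max is None:
        r_max = max(float(d.max()) for d in all_d if d.size)
    n_shells = max(1, int(np.ceil(r_max / shell_width - 1e-12)))
    edges = np.arange(n_shells + 1) * shell_width

    counts = {s: np.zeros(n_shells) for s in SPECIES_ORDER}
    for f, d in zip(frames, all_d):
        idx = np.minimum((d / shell_width).astype(int), n_shells - 1)
        for s in SPECIES_ORDER:
            sel = idx[f.species == s]
            if sel.size:
                counts[s] += np.bincount(sel, minlength=n_shells)
    for s in SPECIES_ORDER:
        counts[s] /= len(frames)
    return RadialProfile(shell_width=shell_width, edges=edges, counts=counts,
                         n_frames=len(frames))


def find_r_bulk(profile: RadialProfile, threshold: float = 0.001,
                persistence: int = 3) -> float:
    """Distance from which x_H2O(r) has converged to a constant value.

    Returns the inner edge of the first (populated) shell such that the
    relative change |x(r_{k+1}) − x(r_k)| / x(r_k) between consecutive
    populated shells stays below ``threshold`` for ``persistence``
    consecutive shells.  Unpopulated shells are excluded.
    """
    if persistence < 1:
        raise DomainError("persistence must be >= 1")
    pop = np.flatnonzero(profile.populated)
    if pop.size < persistence + 1:
        raise NoBulkError("too few populated shells for the persistence window")
    x = profile.x_h2o[pop]
    with np.errstate(invalid="ignore", divide="ignore"):
        rel = np.abs(np.diff(x)) / np.where(x[:-1] > 0, x[:-1], np.nan)
    rel = np.where(np.isnan(rel), np.inf, rel)
    ok = rel < threshold
    for t in range(len(ok) - persistence + 1):
        if ok[t:t + persistence].all():
            return float(profile.edges[pop[t + 1]])
    raise NoBulkError("profile never converges below the threshold")


def bulk_fraction(profile: RadialProfile, r_bulk: float) -> float:
    """Count-weighted average of x_H2O over all shells at r >= r_bulk."""
    lo = profile.edges[:-1]
    sel = (lo >= r_bulk - 1e-12) & profile.populated
    if not sel.any():
        raise DomainError("no populated shells beyond r_bulk")
    tot = profile.total_counts[sel]
    return float(np.sum(profile.x_h2o[sel] * tot) / np.sum(tot))


def analyze_bulk(profile: RadialProfile, threshold: float = 0.001,
                 persistence: int = 3) -> BulkResult:
    """Convenience pipeline: r_bulk detection plus bulk water fraction."""
    r_bulk = find_r_bulk(profile, threshold, persistence)
    sel = (profile.edges[:-1] >= r_bulk - 1e-12) & profile.populated
    return BulkResult(r_bulk=r_bulk, x_h2o_bulk=bulk_fraction(profile, r_bulk),
                      n_shells=int(sel.sum()))


def _ramp_sse(n, x, k1, k2=None):
    """SSE of a continuous flat–rise(–flat) fit: x = a + b·ramp(n).

    ``ramp`` is zero up to the lag end k1, linear in between, and (when k2
    is given) constant beyond the plateau start k2.
    """
    hi = k2 if k2 is not None else np.inf
    ramp = np.clip(n, k1, hi) - k1
    X = np.column_stack([np.ones_like(n), ramp])
    coef, _, _, _ = np.linalg.lstsq(X, x, rcond=None)
    return float(np.sum((x - X @ coef) ** 2))


def saturation_scan(series, min_improvement: float = 0.05) -> SaturationScan:
    """Locate the water-saturation point of a (N_H2O, x_H2O(bulk)) series.

    Fits a three-segment continuous piecewise-linear model (lag, linear
    rise, plateau) by least squares, the two knots searched on the observed
    N grid (no interpolation); the plateau-start knot is the saturation
    count N_sat, ties broken toward the smallest N_sat.  If the three-segment
    fit does not improve the best two-segment residual by at least
    ``min_improvement``, the series has no plateau and a no-saturation
    result is returned.
    """
    arr = np.asarray(list(series), dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise InputError("series must be (N, x) pairs")
    n_vals, x_vals = arr[:, 0], arr[:, 1]
    if len(n_vals) < 6:
        raise InputError("need at least 6 points")
    if np.any(np.diff(n_vals) <= 0):
        raise InputError("series must be sorted by N_H2O")

    scale = max(1.0, float(np.max(np.abs(x_vals))))
    if np.ptp(x_vals) <= 1e-12 * scale:
        # degenerate all-plateau series: saturated from the first point
        return SaturationScan(n_values=n_vals, x_values=x_vals, saturated=True,
                              n_sat=float(n_vals[0]), lag_end=float(n_vals[0]), sse=0.0)

    m = len(n_vals)
    # plateau-free alternative: flat lag + unbounded linear rise (k1 at the
    # first point degenerates to a plain straight line)
    sse2 = min(_ramp_sse(n_vals, x_vals, k1=n_vals[b]) for b in range(0, m - 1))

    best = None  # (sse3, b1, b2); scan b2 ascending so ties keep smallest N_sat
    for b2 in range(1, m - 1):
        for b1 in range(0, b2):
            s = _ramp_sse(n_vals, x_vals, k1=n_vals[b1], k2=n_vals[b2])
            if best is None or s < best[0] - 1e-18:
                best = (s, b1, b2)

    tiny = 1e-12 * scale ** 2
    if best is None or sse2 <= tiny or best[0] > (1.0 - min_improvement) * sse2:
        return SaturationScan(n_values=n_vals, x_values=x_vals, saturated=False,
                              sse=float(sse2 if np.isfinite(sse2) else np.nan))
    sse3, b1, b2 = best
    return SaturationScan(n_values=n_vals, x_values=x_vals, saturated=True,
                          n_sat=float(n_vals[b2]), lag_end=float(n_vals[b1]),
                          sse=float(sse3))
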