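"""Seeded generators for solvation frames, saturation series and scenarios.

These produce every input the analysis modules need, with known ground
truth: particle frames with a planted exponential water enrichment around a
spherical macromolecule proxy in a periodic box, piecewise lag/rise/plateau
saturation series, and the all-in intensification scenarios of the
experimental campaign.  The generators validate the analyzers; they make no
attempt to mimic force-field-accurate solvation structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import SpecError
from .fedbatch import FeedSchedule, ReservoirSpec
from .mdprofile import SPECIES_ORDER, Frame

__all__ = [
    "EnrichmentSpec",
    "gen_solvation_frames",
    "gen_saturation_series",
    "gen_table1_scenarios",
    "AllInScenario",
    "TABLE1_ROWS",
]

#: Default per-species particle counts, echoing a fully solvated enzyme box
#: (4000 CPME, 1400 water, 24 sodium ions).
DEFAULT_COUNTS = {"H2O": 1400, "CPME": 4000, "Na": 24}


@dataclass(frozen=True)
class EnrichmentSpec:
    """Planted radial water structure around a spherical macromolecule proxy.

    Water positions are drawn with radial weight w(d) = 1 + α·exp(−d/λ)
    relative to the proxy surface (α > 0 enriches the surface, α = 0 is
    uniform); all other species are uniform outside the proxy.
    """

    alpha: float = 0.0
    lam: float = 0.3                     # decay length, nm
    counts: dict = field(default_factory=lambda: dict(DEFAULT_COUNTS))
    box_length: float = 9.7              # nm, cubic periodic box
    proxy_radius: float = 1.5            # nm
    proxy_atoms: int = 350

    def __post_init__(self):
        if self.alpha < -1.0:
            raise SpecError("alpha must be >= -1 so weights stay non-negative")
        if self.lam <= 0:
            raise SpecError("decay length must be positive")
        if any(c < 0 for c in self.counts.values()):
            raise SpecError("species counts must be non-negative")
        unknown = set(self.counts) - set(SPECIES_ORDER)
        if unknown:
            raise SpecError(f"unknown species in counts: {sorted(unknown)}")
        if self.box_length <= 2.0 * self.proxy_radius:
            raise SpecError("box smaller than the proxy diameter")

    def free_volume(self) -> float:
        return self.box_length ** 3 - 4.0 / 3.0 * np.pi * self.proxy_radius ** 3

    def weight_integral(self) -> float:
        """∫ w(d) dV over the free volume, spherical-shell closed form.

        The exponential tail is integrated to infinity; its weight beyond the
        half-box is e^{-(L/2 - R)/λ}-small and neglected.
        """
        a, lam = self.proxy_radius, self.lam
        j = 4.0 * np.pi * (a ** 2 * lam + 2.0 * a * lam ** 2 + 2.0 * lam ** 3)
        return self.free_volume() + self.alpha * j

    def expected_bulk_fraction(self) -> float:
        """Analytic far-field water mole fraction implied by the weights."""
        n_w = self.counts.get("H2O", 0)
        n_other = sum(c for s, c in self.counts.items() if s != "H2O")
        dens_w = n_w / self.weight_integral()
        dens_o = n_other / self.free_volume()
        return dens_w / (dens_w + dens_o)


def _fibonacci_sphere(n: int, radius: float, center: np.ndarray) -> np.ndarray:
    """Near-uniform points on a sphere (deterministic proxy surface atoms)."""
    i = np.arange(n)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * (i + 0.5) / n
    rho = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    pts = np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])
    return center + radius * pts


def _sample_positions(rng, spec: EnrichmentSpec, n: int, enriched: bool) -> np.ndarray:
    """Rejection-sample ``n`` positions outside the proxy, weighted if water."""
    center = np.full(3, spec.box_length / 2.0)
    w_max = 1.0 + max(spec.alpha, 0.0)
    out = np.empty((n, 3))
    got = 0
    while got < n:
        m = max(4 * (n - got), 256)
        pts = rng.random((m, 3)) * spec.box_length
        d = np.linalg.norm(pts - center, axis=1) - spec.proxy_radius
        keep = d > 0.0
        if enriched and spec.alpha != 0.0:
            w = 1.0 + spec.alpha * np.exp(-np.maximum(d, 0.0) / spec.lam)
            keep &= rng.random(m) * w_max < w
        pts = pts[keep]
        take = min(len(pts), n - got)
        out[got:got + take] = pts[:take]
        got += take
    return out


def gen_solvation_frames(spec: EnrichmentSpec, n_frames: int, seed: int
                         ) -> tuple[list[Frame], float]:
    """Frames with planted radial water enrichment, plus ground truth.

    Returns the list of frames and the analytic expected bulk water mole
    fraction implied by the sampling weights.  Pure function of
    (spec, n_frames, seed): the same arguments yield identical frames.
    """
    rng = np.random.default_rng(seed)
    center = np.full(3, spec.box_length / 2.0)
    macro = _fibonacci_sphere(spec.proxy_atoms, spec.proxy_radius, center)
    box = np.full(3, spec.box_length)

    frames = []
    for _ in range(n_frames):
        labels, coords = [], []
        for s in SPECIES_ORDER:
            n = spec.counts.get(s, 0)
            if n == 0:
                continue
            pts = _sample_positions(rng, spec, n, enriched=(s == "H2O"))
            labels.append(np.full(n, s))
            coords.append(pts)
        frames.append(Frame(box=box, macromolecule=macro,
                            species=np.concatenate(labels),
                            coordinates=np.concatenate(coords)))
    return frames, spec.expected_bulk_fraction()


def gen_saturation_series(lag_end: float = 200.0, slope: float = 1e-5,
                          n_sat: float = 1400.0, noise_sd: float = 0.0,
                          grid=None, seed: int = 0, baseline: float = 0.002
                          ) -> np.ndarray:
    """Piecewise lag → linear rise → plateau series of (N_H2O, x_H2O(bulk)).

    Values are flat at ``baseline`` up to ``lag_end``, rise with ``slope``
    per molecule up to ``n_sat``, then stay at the plateau level with
    Gaussian noise of sd ``noise_sd`` added on the plateau only.
    """
    if grid is None:
        grid = np.arange(100.0, 2100.0, 100.0)
    grid = np.asarray(grid, dtype=float)
    if not lag_end < n_sat:
        raise SpecError("lag_end must precede n_sat")
    rng = np.random.default_rng(seed)
    x = np.where(grid <= lag_end, baseline,
                 baseline + slope * (np.minimum(grid, n_sat) - lag_end))
    plateau = grid > n_sat
    if noise_sd > 0:
        x = x + plateau * rng.normal(0.0, noise_sd, size=len(grid))
    return np.column_stack([grid, x])


#: All-in intensification campaign: (substrate M, biocatalyst beads g/L,
#: moist support beads g/L, free water mL/L, decarboxylation conversion,
#: reaction time h, printed specific productivity and its uncertainty).
TABLE1_ROWS = (
    (0.1, 5, 0, 0, 0.99, 0.7, 28.4, 1.5),
    (0.1, 5, 0, 4, 0.99, 2.0, 9.7, 0.3),
    (0.3, 10, 0, 4, 0.99, 1.5, 19.1, 1.0),
    (0.3, 10, 11, 4, 0.99, 1.1, 25.5, 1.8),
    (0.5, 11, 12, 4, 0.99, 1.8, 24.8, 0.1),
    (0.5, 11, 17, 4, 0.99, 1.8, 25.5, 0.1),
    (1.0, 10, 18, 4, 0.99, 4.1, 23.6, 0.5),
    (1.0, 21, 17, 8, 0.99, 1.7, 27.1, 0.8),
    (1.5, 31, 20, 10, 0.99, 2.0, 24.0, 0.3),
    (2.0, 40, 30, 14, 0.99, 2.0, 24.8, 0.3),
)


@dataclass(frozen=True)
class AllInScenario:
    """One all-in run: feed schedule, reservoirs, and campaign metadata.

    The reservoir bead mass pools biocatalyst and support beads — both are
    moist carriers of the same material; ``catalyst_g_per_l`` is kept
    separately for productivity accounting.
    """

    substrate_m: float
    catalyst_g_per_l: float
    support_bead_g_per_l: float
    free_water_ml_per_l: float
    conversion: float
    time_h: float
    productivity_printed: float
    productivity_sd: float
    schedule: FeedSchedule
    reservoirs: ReservoirSpec

    @property
    def total_bead_g_per_l(self) -> float:
        return self.catalyst_g_per_l + self.support_bead_g_per_l


def gen_table1_scenarios(grid: int = 10) -> list[AllInScenario]:
    """One all-in scenario per campaign row, with the printed loadings."""
    out = []
    for sub, cat, ecr, h2o, conv, t, prod, sd in TABLE1_ROWS:
        out.append(AllInScenario(
            substrate_m=sub, catalyst_g_per_l=cat, support_bead_g_per_l=ecr,
            free_water_ml_per_l=h2o, conversion=conv, time_h=t,
            productivity_printed=prod, productivity_sd=sd,
            schedule=FeedSchedule.all_in(sub, grid=grid),
            reservoirs=ReservoirSpec(free_water_ml=h2o, bead_g=cat + ecr)))
    return out
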