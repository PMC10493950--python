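"""Synthetic-data generators with known ground truth.

No raw data from the study system is deposited anywhere, so every pipeline
stage is validated by parameter recovery on simulations that emulate the
measurement processes:

* time-lapse image stacks of a dehydrating leaf in which bright connected
  patches (cavitation events) appear at water potentials following a
  logistic vulnerability curve with known P50, plus Gaussian sensor noise
  and single-pixel "shrinkage" flicker;
* branchlet drydown mass series with an exponential stomatal-closure
  transient decaying to a cuticular steady state whose conductance g_min(T)
  is piecewise linear in temperature with a known breakpoint T_P;
* pure-birth ultrametric phylogenies, Brownian-motion trait evolution with
  Pagel-lambda-scaled covariance, and multivariate-normal climate tables
  with a prescribed correlation structure.

Every generator is a pure function of its arguments including the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

from .comparative import climate_pca
from .conductance import (MOLAR_MASS_WATER, P_ATM_KPA, MassSeries,
                          vapor_pressure_deficit)
from .optical import ImageStack, PsiTrace
from .trees import phylo_covariance, root_bipartition, simulate_yule_tree, tip_labels

__all__ = [
    "GroundTruth",
    "simulate_phylogeny",
    "simulate_traits_bm",
    "DEFAULT_CLIMATE_CORR",
    "CLIMATE_RANGES",
    "simulate_climate",
    "simulate_trait_climate",
    "simulate_drydown_images",
    "piecewise_gmin",
    "simulate_mass_series",
]

FRAME_INTERVAL_S = 180.0   # camera fires every 3 minutes
PSI_INTERVAL_S = 600.0     # psychrometer logs every 10 minutes


@dataclass
class GroundTruth:
    """Truth parameters recorded by the generators for recovery tests."""
    true_p50: float | None = None                    # MPa, < 0
    true_slope_vc: float | None = None               # % per MPa at midpoint
    true_gmin_by_T: dict[float, float] = field(default_factory=dict)
    true_tp: float | None = None                     # deg C
    true_lambda: float | None = None                 # in [0, 1]
    true_beta: np.ndarray | None = None
    event_log: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self):
        if self.true_p50 is not None and self.true_p50 >= 0:
            raise ValueError("true_p50 must be negative (MPa)")
        if self.true_lambda is not None and not (0.0 <= self.true_lambda <= 1.0):
            raise ValueError("true_lambda must be in [0, 1]")
        if any(px < 1 for _, px in self.event_log):
            raise ValueError("event pixel counts must be >= 1")


def simulate_phylogeny(n_taxa: int, seed: int) -> dendropy.Tree:
    """Ultrametric pure-birth tree with total depth 1.0 and unique tip labels."""
    return simulate_yule_tree(n_taxa, seed, depth=1.0)


def simulate_traits_bm(tree: dendropy.Tree, sigma2: float, root_value: float,
                       lam: float, seed: int) -> dict[str, float]:
    """One Brownian-motion draw on the tree with Pagel-lambda covariance.

    Tip values are a single multivariate-normal sample with mean
    ``root_value`` and covariance sigma2 * V(lambda).
    """
    if sigma2 <= 0:
        raise ValueError("sigma2 must be positive")
    V, labels = phylo_covariance(tree, lam)
    rng = np.random.default_rng(seed)
    try:
        L = np.linalg.cholesky(V)
    except np.linalg.LinAlgError as exc:
        raise ArithmeticError(f"V(lambda={lam}) not positive definite") from exc
    y = root_value + np.sqrt(sigma2) * (L @ rng.standard_normal(len(labels)))
    return dict(zip(labels, y.tolist()))


# climate variables: mean annual T, mean annual precip, warmest-month max T,
# coldest-month min T, driest-quarter precip.  The default correlation couples
# the three temperatures strongly and opposes them to the two precipitation
# variables, reproducing a dominant warm-dry vs cool-wet axis.
DEFAULT_CLIMATE_CORR = pd.DataFrame(
    [
        [1.00, -0.85, 0.95, 0.95, -0.85],
        [-0.85, 1.00, -0.80, -0.80, 0.95],
        [0.95, -0.80, 1.00, 0.90, -0.80],
        [0.95, -0.80, 0.90, 1.00, -0.80],
        [-0.85, 0.95, -0.80, -0.80, 1.00],
    ],
    index=["MAT", "MAP", "maxT", "minT", "Pdq"],
    columns=["MAT", "MAP", "maxT", "minT", "Pdq"],
)

# realistic spans for a cool-temperate island gradient (sub-alpine to coastal)
CLIMATE_RANGES = {
    "MAT": (6.0, 12.0),     # deg C
    "MAP": (600.0, 1500.0),  # mm
    "maxT": (14.5, 22.2),   # deg C
    "minT": (-3.0, 4.0),    # deg C
    "Pdq": (120.0, 260.0),  # mm
}


def simulate_climate(n_sites: int, target_corr: pd.DataFrame | np.ndarray | None = None,
                     seed: int = 0) -> pd.DataFrame:
    """Multivariate-normal site climate with a prescribed correlation structure.

    Columns MAT, MAP, maxT, minT, Pdq, affinely rescaled so that the +/-3 sd
    span of each variable matches :data:`CLIMATE_RANGES` (correlations are
    unchanged by the affine map).
    """
    if target_corr is None:
        target_corr = DEFAULT_CLIMATE_CORR
    C = np.asarray(target_corr, dtype=float)
    if C.shape[0] != C.shape[1] or not np.allclose(C, C.T) \
            or not np.allclose(np.diag(C), 1.0):
        raise ValueError("target_corr must be symmetric with unit diagonal")
    try:
        L = np.linalg.cholesky(C)
    except np.linalg.LinAlgError as exc:
        raise ValueError("target_corr is not positive definite") from exc
    names = list(target_corr.columns) if isinstance(target_corr, pd.DataFrame) \
        else ["MAT", "MAP", "maxT", "minT", "Pdq"][: C.shape[0]]
    rng = np.random.default_rng(seed)
    Z = rng.standard_normal((n_sites, C.shape[0])) @ L.T
    out = {}
    for j, name in enumerate(names):
        lo, hi = CLIMATE_RANGES.get(name, (0.0, 1.0))
        mid, sd = (lo + hi) / 2.0, (hi - lo) / 6.0
        out[name] = mid + sd * Z[:, j]
    return pd.DataFrame(out, index=[f"site{i + 1:02d}" for i in range(n_sites)])


def simulate_trait_climate(tree: dendropy.Tree, climate: pd.DataFrame,
                           beta: Sequence[float], lam_resid: float,
                           sigma2: float, seed: int
                           ) -> tuple[pd.DataFrame, GroundTruth]:
    """Species trait = intercept + b1*PC1 + b2*subgenus + phylogenetic noise.

    The design couples the trait to the first principal component of the
    climate table and to a binary subgenus factor given by the root
    bipartition of the tree; residuals are Brownian with Pagel-lambda
    ``lam_resid``.  One climate row per tip, in tip order.
    """
    labels = tip_labels(tree)
    if len(climate) != len(labels):
        raise ValueError(
            f"climate has {len(climate)} rows but tree has {len(labels)} tips")
    if not (0.0 <= lam_resid <= 1.0):
        raise ValueError("lam_resid must be in [0, 1]")
    beta = np.asarray(beta, dtype=float)
    clim = climate.copy()
    clim.index = labels
    pca = climate_pca(clim)
    sub = root_bipartition(tree)
    X = np.column_stack([
        np.ones(len(labels)),
        pca.pc1.loc[labels].to_numpy(),
        np.array([sub[t] for t in labels], dtype=float),
    ])
    V, order = phylo_covariance(tree, lam_resid, order=labels)
    rng = np.random.default_rng(seed)
    if sigma2 > 0:
        eps = np.sqrt(sigma2) * (np.linalg.cholesky(V) @ rng.standard_normal(len(labels)))
    else:
        eps = np.zeros(len(labels))
    y = X @ beta + eps
    table = clim.assign(
        subgenus=["Symphyomyrtus" if sub[t] == 0 else "Eucalyptus" for t in labels],
        pc1=pca.pc1.loc[labels].to_numpy(), trait=y)
    truth = GroundTruth(true_lambda=lam_resid, true_beta=beta)
    return table, truth


# ---------------------------------------------------------------------------
# optical-method image stacks

def _grow_patch(rng: np.random.Generator, block: tuple[int, int, int, int],
                size: int) -> list[tuple[int, int]]:
    """Random connected (4-neighbour growth) patch of ``size`` pixels in a block."""
    r0, r1, c0, c1 = block
    start = (int(rng.integers(r0, r1)), int(rng.integers(c0, c1)))
    patch = {start}
    frontier = [start]
    while len(patch) < size and frontier:
        r, c = frontier[int(rng.integers(len(frontier)))]
        nbrs = [(r + dr, c + dc) for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1))
                if r0 <= r + dr < r1 and c0 <= c + dc < c1
                and (r + dr, c + dc) not in patch]
        if not nbrs:
            frontier.remove((r, c))
            continue
        new = nbrs[int(rng.integers(len(nbrs)))]
        patch.add(new)
        frontier.append(new)
    return sorted(patch)


def vulnerability_logistic(psi, p50: float, slope_vc: float):
    """Cumulative embolised fraction (%) vs water potential:
    F(psi) = 100 / (1 + exp(slope_vc/25 * (psi - p50)))."""
    psi = np.asarray(psi, dtype=float)
    return 100.0 / (1.0 + np.exp(np.clip(slope_vc / 25.0 * (psi - p50), -500, 500)))


def simulate_drydown_images(
    p50: float, slope_vc: float = 50.0, height: int = 128, width: int = 128,
    n_frames: int = 200, psi_start: float = -0.5, psi_end: float = -8.0,
    noise_sd: float = 0.0, shrink_events: int = 0, seed: int = 0,
    background: int = 8000, event_amplitude: int = 20000,
    block: int = 8, event_size_range: tuple[int, int] = (6, 40),
    block_fill: float = 0.75,
) -> tuple[ImageStack, PsiTrace, GroundTruth]:
    """Simulate a bench-dehydration image stack with a known P50.

    Water potential falls linearly in time from ``psi_start`` to ``psi_end``;
    frames fire every 3 simulated minutes and the psychrometer logs every
    10.  The embolisable pixel pool is partitioned into connected patches
    (events) placed in disjoint blocks; events switch on permanently at the
    frame where the logistic cumulative curve (midpoint ``p50``, midpoint
    slope ``slope_vc`` % per MPa) crosses their cumulative pixel count.
    ``shrink_events`` single-pixel one-frame flickers emulate leaf-shrinkage
    artifacts; Gaussian intensity noise of sd ``noise_sd`` is added to every
    pixel of every frame.  Output frames are 16-bit.
    """
    if not (psi_end < p50 < psi_start <= 0):
        raise ValueError("require psi_end < p50 < psi_start <= 0")
    if n_frames < 20:
        raise ValueError("n_frames must be >= 20")
    rng = np.random.default_rng(seed)

    frame_times = np.arange(n_frames) * FRAME_INTERVAL_S
    duration = frame_times[-1]
    psi_frames = psi_start + (psi_end - psi_start) * frame_times / duration
    trace_times = np.arange(0.0, duration + PSI_INTERVAL_S / 2, PSI_INTERVAL_S)
    if trace_times[-1] < duration:
        trace_times = np.append(trace_times, duration)
    trace_psi = psi_start + (psi_end - psi_start) * trace_times / duration

    # partition disjoint blocks among events
    nbr, nbc = height // block, width // block
    blocks = [(r * block, (r + 1) * block, c * block, (c + 1) * block)
              for r in range(nbr) for c in range(nbc)]
    rng.shuffle(blocks)
    n_events = max(3, int(len(blocks) * block_fill))
    lo, hi = event_size_range
    sizes = rng.integers(lo, min(hi, block * block) + 1, size=n_events)
    patches = [_grow_patch(rng, blocks[i], int(sizes[i])) for i in range(n_events)]
    sizes = np.array([len(p) for p in patches])
    pool = int(sizes.sum())

    # logistic target cumulative pixel counts, normalised to end at the pool
    F = vulnerability_logistic(psi_frames, p50, slope_vc)
    target = pool * F / F[-1]
    order = rng.permutation(n_events)
    cum = np.cumsum(sizes[order])
    onset = np.searchsorted(target, cum - 0.5 * sizes[order], side="left")
    onset = np.clip(onset, 1, n_frames - 1)  # never in frame 0

    frames = np.full((n_frames, height, width), background, dtype=np.float64)
    event_log: list[tuple[int, int]] = []
    for ev, k in zip(order, onset):
        rows, cols = zip(*patches[ev])
        frames[int(k):, rows, cols] += event_amplitude
        event_log.append((int(k), int(sizes[ev])))

    # single-pixel, single-frame shrinkage flicker outside the event blocks
    used = set()
    for p in patches:
        used.update(p)
    for _ in range(shrink_events):
        while True:
            r, c = int(rng.integers(height)), int(rng.integers(width))
            if (r, c) not in used:
                break
        k = int(rng.integers(1, n_frames))
        frames[k, r, c] += event_amplitude
        if k + 1 < n_frames:
            frames[k + 1:, r, c] = frames[0, r, c]

    if noise_sd > 0:
        frames += rng.normal(0.0, noise_sd, size=frames.shape)
    frames = np.clip(np.round(frames), 0, 65535).astype(np.uint16)

    stack = ImageStack(frames=frames, frame_times=frame_times)
    trace = PsiTrace(times=trace_times, psi=trace_psi)
    truth = GroundTruth(true_p50=p50, true_slope_vc=slope_vc,
                        event_log=sorted(event_log))
    return stack, trace, truth


# ---------------------------------------------------------------------------
# drydown mass series

def piecewise_gmin(T, g_base: float, tp: float, slope_above: float,
                   slope_below: float = 0.0):
    """Piecewise-linear minimum conductance g_min(T) with breakpoint ``tp``."""
    T = np.asarray(T, dtype=float)
    out = g_base + slope_below * (T - tp) + (slope_above - slope_below) * np.clip(
        T - tp, 0.0, None)
    return float(out) if out.ndim == 0 else out


def simulate_mass_series(
    gmin_by_T: Mapping[float, float] | None = None,
    temps: Sequence[float] = (25.0, 28.0, 32.0, 36.0, 40.0, 44.0, 48.0),
    rh: float = 40.0, leaf_area_m2: float = 0.02,
    initial_stomatal_g: float = 50.0, closure_tau: float = 600.0,
    duration: float = 10800.0, dt: float = 300.0,
    noise_sd_mass: float = 0.0, seed: int = 0,
    g_base: float = 5.0, tp: float = 36.0, slope_above: float = 0.5,
    sla_m2_per_kg: float = 8.0, initial_mass_factor: float = 6.0,
) -> tuple[list[MassSeries], GroundTruth]:
    """Simulate branchlet drydown mass series at a set of oven temperatures.

    The instantaneous conductance decays exponentially from
    ``initial_stomatal_g`` to g_min(T) with time constant ``closure_tau``
    (stomatal closure); mass falls by the integrated water flux
    g(t) * VPD(T, rh) / P_atm * A converted to grams via the molar mass of
    water.  g_min(T) is either given explicitly (``gmin_by_T``) or generated
    as a piecewise-linear curve with breakpoint ``tp``.  Balance noise of sd
    ``noise_sd_mass`` grams is added to every reading.  Metadata (leaf dry
    mass, SLA) is set so the double-sided area recovers ``leaf_area_m2``.
    """
    temps = list(temps)
    if any(not (0.0 < T < 60.0) for T in temps):
        raise ValueError("temperatures must lie in (0, 60) deg C")
    if not (0.0 <= rh < 100.0):
        raise ValueError("relative humidity must be < 100% (zero VPD has no flux)")
    if leaf_area_m2 <= 0:
        raise ValueError("leaf area must be positive")
    n_pts = int(np.floor(duration / dt)) + 1
    if n_pts < 30:
        raise ValueError("duration/dt must give at least 30 samples")
    if gmin_by_T is None:
        gmin_by_T = {T: piecewise_gmin(T, g_base, tp, slope_above) for T in temps}
        true_tp = tp
    else:
        gmin_by_T = {float(k): float(v) for k, v in gmin_by_T.items()}
        true_tp = None
    rng = np.random.default_rng(seed)
    leaf_dry_mass = leaf_area_m2 / 2.0 / sla_m2_per_kg * 1000.0  # g
    m0 = leaf_dry_mass * initial_mass_factor
    times = np.arange(n_pts) * dt
    series: list[MassSeries] = []
    for T in temps:
        gmin = gmin_by_T[T]
        vpd = vapor_pressure_deficit(T, rh)
        # closed-form integral of g(t) = gmin + (g0-gmin) exp(-t/tau)
        integ = gmin * times + (initial_stomatal_g - gmin) * closure_tau * (
            1.0 - np.exp(-times / closure_tau))
        # mmol m^-2 (integrated flux) -> grams: x VPD/P_atm x A x M/1000
        flux_scale = vpd / P_ATM_KPA * leaf_area_m2 * MOLAR_MASS_WATER / 1000.0
        masses = m0 - flux_scale * integ
        if noise_sd_mass > 0:
            masses = masses + rng.normal(0.0, noise_sd_mass, size=masses.shape)
        series.append(MassSeries(times=times, masses=masses, temperature=T,
                                 rh=rh, leaf_dry_mass=leaf_dry_mass,
                                 sla=sla_m2_per_kg))
    truth = GroundTruth(true_gmin_by_T=dict(gmin_by_T), true_tp=true_tp)
    return series, truth
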