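"""Remodeler-ruler model: sliding-direction bias near barriers.

The model pictures a remodeler-bound nucleosome on a 1D DNA lattice that can
slide 1 bp left or right. A remodeler-intrinsic "ruler" senses the gap d
(bp of free DNA) between the nucleosome's flank and the nearest barrier edge
on that side — a bound general regulatory factor, a DNA end, or a
neighboring nucleosome — and biases the sliding direction:

* region A (0 <= d < a): sliding toward the barrier is disfavored,
  r_toward = r0 (1 - beta), r_away = r0 (1 + beta);
* region B (a <= d < a + b): sliding toward is favored,
  r_toward = r0 (1 + beta), r_away = r0 (1 - beta);
* region C (d >= a + b): out of reach, unbiased random walk (r0, r0).

The A/B boundary d = a is a self-stabilizing dynamic equilibrium: biased
fluxes from both regions converge on it, so the steady-state gap
distribution peaks there. Because a neighboring nucleosome is itself a
barrier, one mechanism yields both phasing (nucleosome vs. GRF or DNA end)
and spacing (nucleosome vs. nucleosome), and predicts density-independent
spacing ("clamping") as long as nucleosomes can reach region B.

Modes: ``reciprocal`` modulates both directions so the total sliding rate is
constant (r_toward + r_away = 2 r0 at every d); ``asymmetric`` modulates
only the toward-rate; ``kinetic_release`` is reciprocal with both rates
additionally scaled down at d = a, making the equilibrium point a local
minimum of total sliding rate without moving it.

When barriers are in reach on both sides, each engagement contributes an
independent multiplicative factor to each direction's rate (moving left is
"toward" the left barrier and "away" from the right one); with a single
barrier in reach this reduces exactly to the (r_toward, r_away) pair above.

Exact references: for a single nucleosome the dyad performs a birth-death
chain whose stationary law follows from detailed balance; for a few
small-footprint nucleosomes the full master-equation generator is solved
directly. The Gillespie simulator accumulates time-weighted dyad occupancy
and is validated against both.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .features import PeakCallParams, call_composite_peaks, quantify_array_features

MODES = ("reciprocal", "asymmetric", "kinetic_release")


@dataclass(frozen=True)
class RulerSpec:
    """Ruler reach and bias parameters.

    ``reach_a`` / ``reach_b``: lengths of regions A and B in bp;
    ``base_rate``: sliding attempt rate r0 per direction in region C (events
    per unit time); ``bias``: beta in [0, 1); ``gamma``: extra depression of
    the total rate at d = a in kinetic_release mode.
    """

    reach_a: int = 40
    reach_b: int = 40
    base_rate: float = 1.0
    bias: float = 0.5
    mode: str = "reciprocal"
    gamma: float = 0.5

    def __post_init__(self) -> None:
        if self.reach_a < 0 or self.reach_b <= 0:
            raise ValueError("need reach_a >= 0 and reach_b > 0")
        if self.base_rate <= 0:
            raise ValueError("base_rate must be positive")
        if not 0.0 <= self.bias < 1.0:
            raise ValueError("bias must be in [0, 1)")
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        if not 0.0 <= self.gamma < 1.0:
            raise ValueError("gamma must be in [0, 1)")

    def multipliers(self, d: float) -> tuple[float, float]:
        """(toward, away) rate multipliers for gap d; (1, 1) in region C."""
        if d < 0:
            raise ValueError(f"gap must be non-negative, got {d}")
        a, b = self.reach_a, self.reach_b
        if d >= a + b:
            return 1.0, 1.0
        if d < a:
            toward, away = 1.0 - self.bias, 1.0 + self.bias
        else:
            toward, away = 1.0 + self.bias, 1.0 - self.bias
        if self.mode == "asymmetric":
            away = 1.0
        elif self.mode == "kinetic_release" and d == a:
            toward *= 1.0 - self.gamma
            away *= 1.0 - self.gamma
        return toward, away


def ruler_rates(ruler: RulerSpec, d: float) -> tuple[float, float]:
    """Sliding rates (r_toward, r_away) for a gap of d bp to one barrier."""
    toward, away = ruler.multipliers(d)
    return ruler.base_rate * toward, ruler.base_rate * away


@dataclass
class LatticeState:
    """A 1D DNA domain with hard-wall ends, barriers and nucleosomes.

    ``length``: domain size in bp (positions 0..length-1). ``barriers``:
    barrier center positions; a barrier blocks ``barrier_footprint`` bp
    centered on it. With footprint 0 (DSB-like DNA end) the barrier is an
    infinitely thin wall between positions c-1 and c that nucleosomes
    cannot cross. ``dyads``: ascending nucleosome dyad positions; each
    nucleosome occupies ``footprint`` bp (odd) centered on its dyad.
    Domain ends are reflecting walls without ruler interaction.
    """

    length: int
    dyads: list[int] = field(default_factory=list)
    barriers: list[int] = field(default_factory=list)
    footprint: int = 147
    barrier_footprint: int = 0

    def __post_init__(self) -> None:
        if self.footprint % 2 != 1 or self.footprint < 1:
            raise ValueError("nucleosome footprint must be odd and positive")
        self.dyads = sorted(int(p) for p in self.dyads)
        self.barriers = sorted(int(p) for p in self.barriers)
        h = self.half_footprint
        for pos in self.dyads:
            if pos - h < 0 or pos + h >= self.length:
                raise ValueError(f"nucleosome at {pos} leaves the domain")
        for p, q in zip(self.dyads, self.dyads[1:]):
            if q - p < self.footprint:
                raise ValueError(f"nucleosomes at {p} and {q} overlap")
        blocked = _blocked_dyad_positions(self)
        for pos in self.dyads:
            if blocked[pos]:
                raise ValueError(f"nucleosome at {pos} collides with a barrier")

    @property
    def half_footprint(self) -> int:
        return (self.footprint - 1) // 2


def _barrier_intervals(lattice: LatticeState) -> list[tuple[int, int]]:
    """Inclusive blocked interval per barrier; empty interval (c, c-1) for
    a zero-footprint barrier, which then acts as a wall between c-1 and c."""
    w = lattice.barrier_footprint
    out = []
    for c in lattice.barriers:
        if w <= 0:
            out.append((c, c - 1))
        else:
            out.append((c - w // 2, c - w // 2 + w - 1))
    return out


def _blocked_dyad_positions(lattice: LatticeState) -> np.ndarray:
    """Boolean mask of dyad positions a nucleosome can never occupy."""
    h = lattice.half_footprint
    blocked = np.zeros(lattice.length, dtype=bool)
    blocked[:h] = True
    if h > 0:
        blocked[lattice.length - h:] = True
    for bs, be in _barrier_intervals(lattice):
        # dyads whose footprint would intersect [bs, be], or straddle a
        # zero-width wall (be = bs - 1)
        lo, hi = bs - h, be + h
        blocked[max(lo, 0): min(hi + 1, lattice.length)] = True
    return blocked


def _gaps(lattice: LatticeState, dyads: list[int], i: int
          ) -> tuple[float, float, float, float]:
    """Gaps for nucleosome i: (wall_left, wall_right, ruler_left, ruler_right).

    Wall gaps limit movement (nearest obstruction of any type, including the
    domain ends); ruler gaps drive the bias (nearest barrier or neighbor
    nucleosome; +inf when none on that side).
    """
    h = lattice.half_footprint
    left_flank, right_flank = dyads[i] - h, dyads[i] + h

    # inclusive blocked coordinates bounding the free run on each side
    ruler_left_edges: list[int] = []
    ruler_right_edges: list[int] = []
    if i > 0:
        ruler_left_edges.append(dyads[i - 1] + h)
    if i < len(dyads) - 1:
        ruler_right_edges.append(dyads[i + 1] - h)
    for bs, be in _barrier_intervals(lattice):
        if be < left_flank:  # entirely left of the nucleosome (incl. walls)
            ruler_left_edges.append(be)
        elif bs > right_flank:
            ruler_right_edges.append(bs)

    wall_left_edge = max(ruler_left_edges, default=-1)
    wall_right_edge = min(ruler_right_edges, default=lattice.length)
    wall_left = left_flank - max(wall_left_edge, -1) - 1
    wall_right = min(wall_right_edge, lattice.length) - right_flank - 1
    ruler_left = (left_flank - max(ruler_left_edges) - 1
                  if ruler_left_edges else math.inf)
    ruler_right = (min(ruler_right_edges) - right_flank - 1
                   if ruler_right_edges else math.inf)
    return wall_left, wall_right, ruler_left, ruler_right


def _move_rates(lattice: LatticeState, dyads: list[int], i: int,
                ruler: RulerSpec) -> tuple[float, float]:
    """(left, right) move rates for nucleosome i in the given configuration."""
    wall_l, wall_r, bar_l, bar_r = _gaps(lattice, dyads, i)
    t_l, a_l = ruler.multipliers(bar_l) if math.isfinite(bar_l) else (1.0, 1.0)
    t_r, a_r = ruler.multipliers(bar_r) if math.isfinite(bar_r) else (1.0, 1.0)
    rate_left = 0.0 if wall_l < 1 else ruler.base_rate * t_l * a_r
    rate_right = 0.0 if wall_r < 1 else ruler.base_rate * t_r * a_l
    return rate_left, rate_right


@dataclass
class SimulationResult:
    """Time-weighted dyad occupancy and trajectory bookkeeping."""

    occupancy: np.ndarray  # accumulated holding time per dyad position
    total_time: float
    n_events: int
    snapshots: list[tuple[float, list[int]]] = field(default_factory=list)

    def density(self) -> np.ndarray:
        """Per-position dyad density normalized to sum 1."""
        total = self.occupancy.sum()
        return self.occupancy / total if total > 0 else self.occupancy.copy()


def simulate(
    lattice: LatticeState,
    ruler: RulerSpec,
    t_max: float,
    seed: int = 0,
    burn_in: float = 0.0,
    sample_every: float = 0.0,
    max_events: int | None = None,
) -> SimulationResult:
    """Gillespie simulation of the sliding dynamics.

    Events are 1 bp moves of single nucleosomes; waiting times are
    exponential in the total rate. Dyad occupancy is accumulated
    time-weighted (each configuration contributes its holding time) after
    ``burn_in``. Optional configuration snapshots every ``sample_every``
    time units summarize the trajectory.
    """
    if t_max <= burn_in:
        raise ValueError("t_max must exceed burn_in")
    if not lattice.dyads:
        raise ValueError("no nucleosomes to simulate")
    rng = np.random.default_rng(seed)
    dyads = list(lattice.dyads)
    n = len(dyads)
    rates = np.zeros(2 * n)
    for i in range(n):
        rates[2 * i], rates[2 * i + 1] = _move_rates(lattice, dyads, i, ruler)

    occupancy = np.zeros(lattice.length)
    t = 0.0
    n_events = 0
    snapshots: list[tuple[float, list[int]]] = []
    next_snap = burn_in if sample_every > 0 else math.inf

    while True:
        total = rates.sum()
        if total <= 0:
            break
        dt = rng.exponential(1.0 / total)
        t_end = min(t + dt, t_max)
        lo, hi = max(t, burn_in), t_end
        if hi > lo:
            for pos in dyads:
                occupancy[pos] += hi - lo
        while next_snap <= t_end:
            snapshots.append((next_snap, list(dyads)))
            next_snap += sample_every
        if t + dt >= t_max or (max_events is not None and n_events >= max_events):
            t = t_end
            break
        t = t_end
        k = int(np.searchsorted(np.cumsum(rates), rng.random() * total,
                                side="right"))
        k = min(k, 2 * n - 1)
        i, direction = divmod(k, 2)
        dyads[i] += -1 if direction == 0 else 1
        n_events += 1
        for j in (i - 1, i, i + 1):  # only local gaps changed
            if 0 <= j < n:
                rates[2 * j], rates[2 * j + 1] = _move_rates(lattice, dyads, j, ruler)
    return SimulationResult(occupancy, max(t - burn_in, 0.0), n_events, snapshots)


@dataclass
class StationaryDensity:
    """Per-position dyad probability at stationarity.

    ``probability`` sums to the number of nucleosomes (it is the dyad
    marginal); ``configuration_probability`` holds the full law for the
    multi-nucleosome master-equation solution.
    """

    positions: np.ndarray
    probability: np.ndarray
    configuration_probability: dict | None = None

    def density(self) -> np.ndarray:
        return self.probability / self.probability.sum()

    def mode_position(self) -> int:
        return int(self.positions[int(np.argmax(self.probability))])


def _reachable_block(lattice: LatticeState, start: int) -> np.ndarray:
    """Contiguous run of admissible dyad positions containing ``start``."""
    blocked = _blocked_dyad_positions(lattice)
    allowed = np.flatnonzero(~blocked)
    blocks = np.split(allowed, np.flatnonzero(np.diff(allowed) > 1) + 1)
    for block in blocks:
        if block.size and block[0] <= start <= block[-1]:
            return block
    raise ValueError(f"initial dyad {start} sits on a blocked position")


def stationary_exact(lattice: LatticeState, ruler: RulerSpec,
                     max_states: int = 200_000) -> StationaryDensity:
    """Exact stationary law of the sliding chain.

    Single nucleosome: closed-form birth-death stationary distribution via
    detailed balance along the dyad coordinate. Several nucleosomes: all
    admissible configurations are enumerated (feasible for reduced
    footprints) and the master equation's stationary vector solved as a
    linear system; the result is reported as the per-position dyad marginal.

    Raises ``ValueError`` when the configuration count exceeds
    ``max_states`` — use :func:`simulate` then.
    """
    n = len(lattice.dyads)
    if n == 0:
        raise ValueError("no nucleosomes")
    if n == 1:
        return _stationary_single(lattice, ruler)
    return _stationary_multi(lattice, ruler, max_states)


def _stationary_single(lattice: LatticeState, ruler: RulerSpec) -> StationaryDensity:
    block = _reachable_block(lattice, lattice.dyads[0])
    log_pi = np.zeros(block.size)
    for k in range(1, block.size):
        right_prev = _move_rates(lattice, [int(block[k - 1])], 0, ruler)[1]
        left_here = _move_rates(lattice, [int(block[k])], 0, ruler)[0]
        log_pi[k] = log_pi[k - 1] + math.log(right_prev) - math.log(left_here)
    pi = np.exp(log_pi - log_pi.max())
    pi /= pi.sum()
    prob = np.zeros(lattice.length)
    prob[block] = pi
    return StationaryDensity(np.arange(lattice.length), prob)


def _stationary_multi(lattice: LatticeState, ruler: RulerSpec,
                      max_states: int) -> StationaryDensity:
    from itertools import combinations

    from scipy.sparse import lil_matrix
    from scipy.sparse.linalg import spsolve

    n = len(lattice.dyads)
    allowed = np.flatnonzero(~_blocked_dyad_positions(lattice)).tolist()
    w = lattice.footprint
    states = [c for c in combinations(allowed, n)
              if all(c[j + 1] - c[j] >= w for j in range(n - 1))]
    if len(states) > max_states:
        raise ValueError(
            f"{len(states)} configurations exceed max_states={max_states}; "
            "use simulate() instead"
        )
    index = {s: k for k, s in enumerate(states)}
    m = len(states)
    gen = lil_matrix((m, m))
    for s, k in index.items():
        dyads = list(s)
        out = 0.0
        for i in range(n):
            left, right = _move_rates(lattice, dyads, i, ruler)
            for rate, step in ((left, -1), (right, +1)):
                if rate <= 0:
                    continue
                new = list(dyads)
                new[i] += step
                target = index.get(tuple(new))
                if target is None:
                    continue
                gen[target, k] += rate
                out += rate
        gen[k, k] -= out
    # replace one balance equation with the normalization constraint
    a = gen.tolil()
    a[0, :] = 1.0
    rhs = np.zeros(m)
    rhs[0] = 1.0
    pi = spsolve(a.tocsr(), rhs)
    pi = np.clip(pi, 0.0, None)
    pi /= pi.sum()
    prob = np.zeros(lattice.length)
    for s, k in index.items():
        for pos in s:
            prob[pos] += pi[k]
    config = {s: float(pi[k]) for s, k in index.items()}
    return StationaryDensity(np.arange(lattice.length), prob, config)


def occupancy_to_profile(occupancy: np.ndarray, barrier_position: int,
                         flank: int = 1000):
    """Embed a dyad-occupancy vector as a barrier-centered composite profile."""
    from .alignment import CompositeProfile

    values = np.zeros(2 * flank + 1)
    offsets = np.arange(-flank, flank + 1)
    lo = max(barrier_position - flank, 0)
    hi = min(barrier_position + flank + 1, len(occupancy))
    values[lo - barrier_position + flank: hi - barrier_position + flank] = \
        occupancy[lo:hi]
    return CompositeProfile(offsets=offsets, values=values, n_sites=1)


def steady_state_features(
    occupancy: np.ndarray,
    barrier_position: int,
    footprint: int = 147,
    peak_params: PeakCallParams | None = None,
):
    """Peak-call a steady-state occupancy and compute array features.

    The occupancy (from :func:`simulate` or :func:`stationary_exact`) is
    treated as a composite profile centered on the barrier and run through
    the same peak calling and feature quantification as experimental
    coverage. The peak search is started at the first achievable dyad offset
    (half a footprint from the barrier) so the exclusion zone next to the
    barrier is not mistaken for structure. Returns ``ArrayFeatures``, or
    ``None`` when the occupancy is featureless (e.g. an unbiased ruler).
    """
    h = (footprint - 1) // 2
    params = peak_params or PeakCallParams()
    if params.min_first_offset < h:
        from dataclasses import replace

        params = replace(params, min_first_offset=h)
    profile = occupancy_to_profile(occupancy, barrier_position)
    peaks = call_composite_peaks(profile, params)
    if peaks.is_empty:
        return None
    return quantify_array_features(
        peaks,
        barrier_kind="model",
        half_footprint=h,
        footprint=footprint,
    )
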