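"""Jackson queueing-network model of nuclear export through NPCs.

The nuclear pore complexes (NPCs) of a cell are treated as a Jackson network
of ``n`` parallel M/M/1 queues: cargoes (pre-ribosomal particles) arrive in
the cell as a Poisson stream with rate ``lambda``, are routed uniformly at
random to one of the ``n`` NPCs, and are serviced (translocated) with an
exponential service time of mean ``d`` — the dwell time.  At equilibrium each
queue has occupation rate ``psi = lambda * d / n`` and a geometric state law
``P(N = k) = psi**k * (1 - psi)``.

Because the occupancy ``psi`` is what an instantaneous snapshot experiment
(high-pressure freezing + tomography) measures, the relation can be inverted
to infer the mean dwell time from an observed fraction of occupied NPCs.
:class:`DwellTimeModel` / :class:`DwellTimeResults` package that inference in
the usual model/results idiom; the module-level functions expose the
individual pieces.  :func:`simulate_network` is an exact event-driven
simulator of the same network, used as a stochastic cross-check of the
analytic law.

All rates are per second and all times in seconds internally; constructors
accept per-minute fluxes because experimental flux estimates are usually
quoted per minute.
"""

from __future__ import annotations

import heapq
import math
from collections import deque
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "NonErgodicError",
    "JacksonModel",
    "StateDistribution",
    "SensitivityGrid",
    "SimulationResult",
    "occupancy_rate_analytic",
    "invert_dwell_time",
    "state_distribution",
    "queue_probability",
    "sensitivity_grid",
    "simulate_network",
    "snapshot_census",
    "DwellTimeModel",
    "DwellTimeResults",
    "per_minute",
]


class NonErgodicError(ValueError):
    """Raised when psi = lambda*d/n >= 1 so the network has no equilibrium."""


def per_minute(rate_per_min: float) -> float:
    """Convert a per-minute rate to the internal per-second convention."""
    return rate_per_min / 60.0


@dataclass(frozen=True)
class JacksonModel:
    """Parameterization of the NPC export network.

    Parameters
    ----------
    flux_lambda : float
        Cargo arrival rate in particles per second (use
        :func:`per_minute` or :meth:`from_flux_per_minute` for
        per-minute inputs).
    n_servers : int
        Number of NPCs (parallel servers).
    dwell_time : float
        Mean service time ``d`` in seconds.
    """

    flux_lambda: float
    n_servers: int
    dwell_time: float

    def __post_init__(self) -> None:
        if not self.flux_lambda > 0:
            raise ValueError(f"flux_lambda must be > 0, got {self.flux_lambda}")
        if not (isinstance(self.n_servers, (int, np.integer)) and self.n_servers >= 1):
            raise ValueError(f"n_servers must be a positive integer, got {self.n_servers}")
        if not self.dwell_time >= 0:
            raise ValueError(f"dwell_time must be >= 0, got {self.dwell_time}")
        if self.psi >= 1.0:
            raise NonErgodicError(
                f"psi = lambda*d/n = {self.psi:.4g} >= 1: no equilibrium exists"
            )

    @property
    def psi(self) -> float:
        """Per-server occupation rate psi = lambda * d / n."""
        return self.flux_lambda * self.dwell_time / self.n_servers

    @classmethod
    def from_flux_per_minute(
        cls, flux_per_min: float, n_servers: int, dwell_time: float
    ) -> "JacksonModel":
        return cls(per_minute(flux_per_min), n_servers, dwell_time)


def occupancy_rate_analytic(model: JacksonModel) -> float:
    """Equilibrium probability that a given NPC holds >= 1 particle.

    For an M/M/1 queue this equals the occupation rate
    ``psi = lambda * d / n`` (the server-busy probability).
    """
    psi = model.psi
    if psi >= 1.0:
        raise NonErgodicError(f"psi = {psi:.4g} >= 1")
    return psi


def invert_dwell_time(occupancy: float, n_servers: int, flux_lambda: float) -> float:
    """Mean dwell time (seconds) implied by an observed NPC occupancy.

    Inverts ``psi = lambda * d / n`` to ``d = psi * n / lambda``.  This is
    the model fit step: the dwell time is the unique value reproducing the
    measured fraction of occupied NPCs.
    """
    if not 0 <= occupancy:
        raise ValueError(f"occupancy must be >= 0, got {occupancy}")
    if occupancy >= 1:
        raise NonErgodicError(f"occupancy {occupancy} >= 1: no equilibrium")
    if n_servers < 1:
        raise ValueError(f"n_servers must be >= 1, got {n_servers}")
    if not flux_lambda > 0:
        raise ValueError(f"flux_lambda must be > 0, got {flux_lambda}")
    return occupancy * n_servers / flux_lambda


@dataclass(frozen=True)
class StateDistribution:
    """Geometric equilibrium law of the per-NPC particle count.

    ``pmf[k] = P(N = k) = psi**k * (1 - psi)`` for ``k = 0..k_max`` and
    ``tail = P(N > k_max) = psi**(k_max + 1)``.
    """

    psi: float
    pmf: np.ndarray
    tail: float

    @property
    def k_max(self) -> int:
        return len(self.pmf) - 1

    def prob_at_least(self, k: int) -> float:
        """P(N >= k) = psi**k."""
        return self.psi**k

    def total_mass(self) -> float:
        return float(self.pmf.sum() + self.tail)


def state_distribution(psi: float, k_max: int = 10) -> StateDistribution:
    """Equilibrium distribution P(N = k) = psi^k (1 - psi), k = 0..k_max."""
    if not 0 <= psi < 1:
        raise NonErgodicError(f"psi must be in [0, 1), got {psi}")
    if k_max < 0:
        raise ValueError("k_max must be >= 0")
    k = np.arange(k_max + 1)
    pmf = psi**k * (1.0 - psi)
    return StateDistribution(psi=psi, pmf=pmf, tail=psi ** (k_max + 1))


def queue_probability(psi: float) -> float:
    """P(N >= 2): probability that an NPC has a particle waiting behind
    the one in service. Equals psi**2 under the geometric law."""
    if not 0 <= psi < 1:
        raise NonErgodicError(f"psi must be in [0, 1), got {psi}")
    return psi**2


@dataclass(frozen=True)
class SensitivityGrid:
    """Grid of inferred dwell times (ms) over (n_servers, occupancy).

    ``dwell_ms[i, j]`` is the dwell time for ``n_values[i]`` and
    ``occupancy_values[j]`` at the fixed flux, in milliseconds.
    """

    n_values: np.ndarray
    occupancy_values: np.ndarray
    flux_lambda: float
    dwell_ms: np.ndarray
    domain_polygon: tuple[tuple[float, float], tuple[float, float]] | None = None

    def dwell_range(
        self,
        n_bounds: tuple[float, float] | None = None,
        occupancy_bounds: tuple[float, float] | None = None,
    ) -> tuple[float, float]:
        """(min, max) inferred dwell time in ms over a rectangular domain.

        d = psi*n/lambda is increasing in both arguments, so the extrema sit
        at opposite corners of the domain.
        """
        if n_bounds is None or occupancy_bounds is None:
            if self.domain_polygon is None:
                raise ValueError("no domain given and no domain_polygon stored")
            n_bounds, occupancy_bounds = self.domain_polygon
        lo = 1000.0 * invert_dwell_time(occupancy_bounds[0], 1, self.flux_lambda) * n_bounds[0]
        hi = 1000.0 * invert_dwell_time(occupancy_bounds[1], 1, self.flux_lambda) * n_bounds[1]
        return lo, hi


def sensitivity_grid(
    n_values,
    occupancy_values,
    flux_lambda: float,
    domain_polygon: tuple[tuple[float, float], tuple[float, float]] | None = None,
) -> SensitivityGrid:
    """Dwell times (ms) inferred over a grid of server counts x occupancies.

    Emulates the robustness analysis of the dwell-time estimate: how much
    the inferred d moves when the NPC count or the measured occupancy is
    perturbed.  ``domain_polygon = ((n_lo, n_hi), (psi_lo, psi_hi))``
    optionally records the plausible-error rectangle.
    """
    n_values = np.atleast_1d(np.asarray(n_values, dtype=float))
    occupancy_values = np.atleast_1d(np.asarray(occupancy_values, dtype=float))
    if n_values.size == 0 or occupancy_values.size == 0:
        raise ValueError("empty n_values or occupancy_values")
    if np.any(n_values < 1):
        raise ValueError("all n_values must be >= 1")
    if np.any((occupancy_values < 0) | (occupancy_values >= 1)):
        raise NonErgodicError("occupancies must be in [0, 1)")
    if not flux_lambda > 0:
        raise ValueError("flux_lambda must be > 0")
    dwell_ms = 1000.0 * np.outer(n_values, occupancy_values) / flux_lambda
    return SensitivityGrid(
        n_values=n_values,
        occupancy_values=occupancy_values,
        flux_lambda=flux_lambda,
        dwell_ms=dwell_ms,
        domain_polygon=domain_polygon,
    )


@dataclass(frozen=True)
class SimulationResult:
    """Time-averaged statistics from an event-driven network simulation."""

    seed: int
    horizon: float
    warmup: float
    occupied_fraction: float
    queue_fraction: float
    state_histogram: np.ndarray
    mean_in_system: float
    mean_sojourn: float
    n_arrivals: int
    n_departures: int
    occupied_fraction_se: float
    #: per-state server counts sampled at regular epochs (for GOF tests);
    #: None unless a sample_interval was requested
    sampled_state_counts: np.ndarray | None = None

    def state_probability(self, k: int) -> float:
        if k >= len(self.state_histogram):
            return 0.0
        return float(self.state_histogram[k])


def simulate_network(
    model: JacksonModel,
    horizon: float,
    warmup: float | None = None,
    seed: int = 0,
    n_batches: int = 20,
    sample_interval: float | None = None,
) -> SimulationResult:
    """Exact event-driven simulation of the n-server Jackson network.

    Global Poisson arrivals at ``model.flux_lambda`` are routed uniformly at
    random to one of ``n_servers`` FIFO M/M/1 queues with unbounded waiting
    room; service times are drawn i.i.d. exponential with mean
    ``model.dwell_time`` at service start.  Statistics are time averages
    accumulated after ``warmup`` (default: five relaxation times,
    ``5 * max(d, n / lambda)``).

    A single seeded generator drives interarrival, routing, and service
    draws in event order, so results are bit-reproducible for a given seed.
    The standard error of the occupied fraction is estimated by batch means
    over ``n_batches`` equal sub-windows.

    With ``sample_interval`` set, the per-server state is additionally
    censused at epochs ``warmup + i * sample_interval``; choosing the
    interval well above the relaxation time gives near-independent
    equilibrium samples suitable for goodness-of-fit testing.
    """
    if model.psi >= 1.0:
        raise NonErgodicError(f"psi = {model.psi:.4g} >= 1: statistics would not converge")
    if warmup is None:
        warmup = 5.0 * max(model.dwell_time, model.n_servers / model.flux_lambda)
    if warmup < 0:
        raise ValueError("warmup must be >= 0")
    if not horizon > warmup:
        raise ValueError(f"horizon ({horizon}) must exceed warmup ({warmup})")

    rng = np.random.default_rng(seed)
    lam = model.flux_lambda
    n = model.n_servers
    d = model.dwell_time

    counts = np.zeros(n, dtype=np.int64)  # particles at each server (in service + queued)
    queues: list[deque] = [deque() for _ in range(n)]  # arrival times, FIFO
    # cnt_k[k] = number of servers currently holding exactly k particles
    cnt_k = [n]
    hist_time: list[float] = [0.0]
    n_busy = 0
    n_queued = 0
    total_in = 0

    busy_int = 0.0
    queue_int = 0.0
    in_sys_int = 0.0
    sojourn_sum = 0.0
    n_departures = 0
    n_arrivals = 0

    batch_edges = np.linspace(warmup, horizon, n_batches + 1)
    batch_busy = np.zeros(n_batches)

    dep_heap: list[tuple[float, int]] = []  # (departure time, server)
    t = 0.0
    next_arrival = rng.exponential(1.0 / lam) if d >= 0 else math.inf

    sample_counts: list[float] = [0.0]
    next_sample = warmup + sample_interval if sample_interval else math.inf

    def take_samples(t1: float) -> None:
        # state is piecewise constant between events: census cnt_k at every
        # sampling epoch that falls before the next event
        nonlocal next_sample
        while next_sample <= t1 and next_sample <= horizon:
            for k in range(len(cnt_k)):
                if cnt_k[k]:
                    while k >= len(sample_counts):
                        sample_counts.append(0.0)
                    sample_counts[k] += cnt_k[k]
            next_sample += sample_interval

    def accumulate(t0: float, t1: float) -> None:
        nonlocal busy_int, queue_int, in_sys_int
        lo = max(t0, warmup)
        if t1 <= lo:
            return
        dt = t1 - lo
        busy_int += dt * n_busy
        queue_int += dt * n_queued
        in_sys_int += dt * total_in
        for k in range(len(cnt_k)):
            if cnt_k[k]:
                while k >= len(hist_time):
                    hist_time.append(0.0)
                hist_time[k] += dt * cnt_k[k]
        # batch-means accumulation for the busy fraction
        i0 = int(np.searchsorted(batch_edges, lo, side="right")) - 1
        i1 = int(np.searchsorted(batch_edges, t1, side="left")) - 1
        if i0 == i1:
            batch_busy[i0] += (t1 - lo) * n_busy
        else:
            batch_busy[i0] += (batch_edges[i0 + 1] - lo) * n_busy
            for i in range(i0 + 1, i1):
                batch_busy[i] += (batch_edges[i + 1] - batch_edges[i]) * n_busy
            batch_busy[i1] += (t1 - batch_edges[i1]) * n_busy

    def shift_count(server: int, delta: int) -> None:
        nonlocal n_busy, n_queued, total_in
        k_old = counts[server]
        k_new = k_old + delta
        cnt_k[k_old] -= 1
        while k_new >= len(cnt_k):
            cnt_k.append(0)
        cnt_k[k_new] += 1
        counts[server] = k_new
        total_in += delta
        if delta > 0:
            if k_old == 0:
                n_busy += 1
            if k_new == 2:
                n_queued += 1
        else:
            if k_new == 0:
                n_busy -= 1
            if k_old == 2:
                n_queued -= 1

    while True:
        t_dep = dep_heap[0][0] if dep_heap else math.inf
        t_next = min(next_arrival, t_dep)
        if t_next >= horizon:
            accumulate(t, horizon)
            take_samples(horizon)
            break
        accumulate(t, t_next)
        take_samples(t_next)
        t = t_next
        if next_arrival <= t_dep:
            server = int(rng.integers(n))
            queues[server].append(t)
            was_idle = counts[server] == 0
            shift_count(server, +1)
            n_arrivals += 1
            if was_idle:
                svc = rng.exponential(d) if d > 0 else 0.0
                heapq.heappush(dep_heap, (t + svc, server))
            next_arrival = t + rng.exponential(1.0 / lam)
        else:
            _, server = heapq.heappop(dep_heap)
            arrived = queues[server].popleft()
            shift_count(server, -1)
            if t >= warmup:
                sojourn_sum += t - arrived
                n_departures += 1
            if counts[server] > 0:
                svc = rng.exponential(d) if d > 0 else 0.0
                heapq.heappush(dep_heap, (t + svc, server))

    span = horizon - warmup
    hist = np.asarray(hist_time) / (span * n)
    batch_frac = batch_busy / (np.diff(batch_edges) * n)
    se = float(batch_frac.std(ddof=1) / math.sqrt(n_batches)) if n_batches > 1 else float("nan")
    return SimulationResult(
        seed=seed,
        horizon=horizon,
        warmup=warmup,
        occupied_fraction=busy_int / (span * n),
        queue_fraction=queue_int / (span * n),
        state_histogram=hist,
        mean_in_system=in_sys_int / (span * n),
        mean_sojourn=sojourn_sum / n_departures if n_departures else float("nan"),
        n_arrivals=n_arrivals,
        n_departures=n_departures,
        occupied_fraction_se=se,
        sampled_state_counts=np.asarray(sample_counts) if sample_interval else None,
    )


def snapshot_census(model: JacksonModel, n_snapshots: int, seed: int = 0):
    """Emulate the freezing experiment: draw per-NPC particle counts from
    the equilibrium geometric law and tally them as an occupancy table.

    Each snapshot is one NPC observed at an independent equilibrium instant
    (high-pressure freezing is fast enough that a tomogram is an unbiased
    sample of the equilibrium state).
    """
    from .npc_mapper import OccupancyTable

    if n_snapshots <= 0:
        raise ValueError("n_snapshots must be > 0")
    psi = model.psi
    rng = np.random.default_rng(seed)
    if psi == 0:
        counts = np.zeros(n_snapshots, dtype=np.int64)
    else:
        # numpy's geometric counts trials to first success (support 1..);
        # subtracting 1 gives P(X = k) = psi^k (1 - psi), k >= 0
        counts = rng.geometric(1.0 - psi, size=n_snapshots) - 1
    n1 = int(np.sum(counts == 1))
    n2 = int(np.sum(counts >= 2))
    return OccupancyTable(
        strain="simulated",
        total_npcs=n_snapshots,
        npcs_1_particle=n1,
        npcs_2_particles=n2,
        total_particles=int(counts.sum()),
    )


class DwellTimeModel:
    """Dwell-time inference from an observed NPC occupancy.

    The model ties the snapshot census (``occupied`` of ``total`` NPCs hold
    at least one particle) to the Jackson-network equilibrium: the observed
    occupancy estimates ``psi``, and fitting chooses the mean dwell time
    ``d = psi * n / lambda`` that reproduces it, given the cellular flux of
    cargoes and the number of NPCs per cell.

    Parameters
    ----------
    occupied, total : int
        Occupied and total NPC counts from the census.
    n_servers : int
        NPCs per cell (default 110, an average over the cell cycle).
    flux_per_min : float
        Cargo flux in particles per minute (default 4000: two subunits per
        ribosome at ~2000 ribosomes/min).

    Examples
    --------
    >>> res = DwellTimeModel(44, 818).fit()
    >>> round(res.dwell_ms)
    89
    """

    def __init__(
        self,
        occupied: int,
        total: int,
        n_servers: int = 110,
        flux_per_min: float = 4000.0,
    ) -> None:
        if not 0 <= occupied <= total or total <= 0:
            raise ValueError("need 0 <= occupied <= total and total > 0")
        self.occupied = int(occupied)
        self.total = int(total)
        self.n_servers = int(n_servers)
        self.flux_lambda = per_minute(flux_per_min)

    @classmethod
    def from_occupancy_table(
        cls, table, n_servers: int = 110, flux_per_min: float = 4000.0
    ) -> "DwellTimeModel":
        """Build from an :class:`~porequeue.npc_mapper.OccupancyTable`.

        Uses the table's occupancy at its reported (one-decimal) precision,
        matching the convention of published occupancy fractions.
        """
        m = cls(table.npcs_with_particles, table.total_npcs, n_servers, flux_per_min)
        m._psi_reported = table.fraction_occupied / 100.0
        return m

    def fit(self, alpha: float = 0.05) -> "DwellTimeResults":
        """Fit the dwell time; the occupancy CI (Clopper-Pearson at level
        1 - alpha) propagates linearly to a dwell-time CI."""
        from scipy import stats as sps

        psi_hat = getattr(self, "_psi_reported", None)
        if psi_hat is None:
            psi_hat = self.occupied / self.total
        ci = sps.binomtest(self.occupied, self.total).proportion_ci(
            confidence_level=1 - alpha, method="exact"
        )
        return DwellTimeResults(model=self, psi=psi_hat, psi_ci=(ci.low, ci.high), alpha=alpha)


@dataclass
class DwellTimeResults:
    """Fitted dwell time with uncertainty and equilibrium diagnostics."""

    model: DwellTimeModel
    psi: float
    psi_ci: tuple[float, float]
    alpha: float
    dwell_time: float = field(init=False)

    def __post_init__(self) -> None:
        self.dwell_time = invert_dwell_time(self.psi, self.model.n_servers, self.model.flux_lambda)

    @property
    def dwell_ms(self) -> float:
        return 1000.0 * self.dwell_time

    @property
    def dwell_ci_ms(self) -> tuple[float, float]:
        n, lam = self.model.n_servers, self.model.flux_lambda
        return tuple(1000.0 * invert_dwell_time(p, n, lam) for p in self.psi_ci)

    @property
    def queue_probability(self) -> float:
        return queue_probability(self.psi)

    def state_distribution(self, k_max: int = 10) -> StateDistribution:
        return state_distribution(self.psi, k_max)

    def as_jackson_model(self) -> JacksonModel:
        return JacksonModel(self.model.flux_lambda, self.model.n_servers, self.dwell_time)

    def sensitivity(
        self,
        n_values=None,
        occupancy_values=None,
        domain_polygon=None,
    ) -> SensitivityGrid:
        """Dwell-time sensitivity to the NPC count and measured occupancy.

        Defaults scan n in [90, 130] and psi in [0.039, 0.069] (NPC count
        +/- 20 and occupancy +/- 1.5 percentage points around the fit)."""
        if n_values is None:
            n_values = np.arange(90, 131, 5)
        if occupancy_values is None:
            occupancy_values = np.round(np.arange(0.039, 0.0695, 0.003), 4)
        if domain_polygon is None:
            domain_polygon = ((90.0, 130.0), (0.039, 0.069))
        return sensitivity_grid(
            n_values, occupancy_values, self.model.flux_lambda, domain_polygon
        )

    def simulate(
        self, horizon: float, warmup: float | None = None, seed: int = 0
    ) -> SimulationResult:
        return simulate_network(self.as_jackson_model(), horizon, warmup, seed)

    def plot_sensitivity(self, ax=None, levels=None):
        """Contour plot of inferred dwell time (ms) over (psi, n)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        grid = self.sensitivity()
        cs = ax.contour(
            grid.occupancy_values, grid.n_values, grid.dwell_ms, levels=levels, colors="0.3"
        )
        ax.clabel(cs, fmt="%.0f ms")
        ax.plot([self.psi], [self.model.n_servers], "ko")
        ax.set_xlabel("NPC occupancy $\\psi$")
        ax.set_ylabel("NPCs per cell $n$")
        return ax

    def summary(self) -> str:
        lo, hi = self.dwell_ci_ms
        glo, ghi = self.sensitivity().dwell_range()
        lines = [
            "Jackson-network dwell-time inference",
            "=" * 52,
            f"Occupied NPCs          {self.model.occupied} / {self.model.total}",
            f"Occupancy psi          {self.psi:.4f}",
            f"NPCs per cell (n)      {self.model.n_servers}",
            f"Flux lambda            {self.model.flux_lambda * 60:.0f} /min "
            f"({self.model.flux_lambda:.3f} /s)",
            "-" * 52,
            f"Dwell time d           {self.dwell_ms:.1f} ms  (nearest ms: {round(self.dwell_ms):d})",
            f"{100 * (1 - self.alpha):.0f}% CI (binomial)      [{lo:.1f}, {hi:.1f}] ms",
            f"Sensitivity domain     [{glo:.1f}, {ghi:.1f}] ms "
            "(n in [90, 130], psi in [0.039, 0.069])",
            f"P(queue) = psi^2       {self.queue_probability:.4f} "
            f"({100 * self.queue_probability:.1f}%)",
            "=" * 52,
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "psi": self.psi,
            "psi_ci": list(self.psi_ci),
            "n_servers": self.model.n_servers,
            "flux_per_min": self.model.flux_lambda * 60.0,
            "dwell_ms": self.dwell_ms,
            "dwell_ms_rounded": int(round(self.dwell_ms)),
            "dwell_ci_ms": list(self.dwell_ci_ms),
            "queue_prob": self.queue_probability,
        }
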