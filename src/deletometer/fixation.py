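"""Take-over dynamics of beneficial deletions under recurrent mutation.

Two models of how a recurrently arising beneficial deletion spreads through
an asexual population:

* **Deterministic**: the mutant frequency p obeys

      dp/dg = u (1 - p) + s p (1 - p)

  per generation g, combining recurrent mutation at rate u per cell per
  generation with logistic selection at advantage s. The take-over time is
  the generation at which p first reaches the target frequency (50% by
  default). With u = 0 this reduces to the textbook logistic sweep with the
  closed form t = ln[(p_t/(1-p_t)) / (p0/(1-p0))] / s.

* **Stochastic serial passage**: growth-mutation-bottleneck cycles matching
  a daily-transfer regime. Within a cycle both classes grow
  deterministically (mutants with per-generation factor 2(1+s)), new
  mutation events arise as Poisson draws with mean u x (wild-type cell
  divisions), and the daily bottleneck samples N0 cells binomially at the
  current mutant frequency. Mutations arise during growth only, since they
  require cell division, and each mutation event seeds both daughters of
  the mutated division (a 2-cell lineage) so that the model's mean-field
  frequency influx is exactly the u(1-p) per generation of the
  deterministic equation — the two models then describe the same u.

Both are reconstructions of supplementary-model behaviour from the stated
passaging regime; see docs/methods.md.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

__all__ = [
    "Passage",
    "FixationScenario",
    "TakeoverResult",
    "takeover_time_deterministic",
    "simulate_serial_passage",
    "takeover_surface",
    "logistic_sweep_time",
]


@dataclass(frozen=True)
class Passage:
    """Serial-passage regime: bottleneck size and generations of regrowth."""

    N0: float
    generations_per_cycle: float

    def __post_init__(self) -> None:
        if self.N0 < 1:
            raise ValueError("bottleneck N0 must be >= 1")
        if self.generations_per_cycle <= 0:
            raise ValueError("generations_per_cycle must be > 0")


@dataclass
class FixationScenario:
    """Population size, beneficial-deletion rate, advantage and passage regime.

    ``N`` is the population at the end of growth; ``u`` the rate at which
    the beneficial deletion arises per cell per generation; ``s`` its
    per-generation advantage; ``p0`` the initial mutant frequency (default a
    single pre-existing copy, 1/N; set 0 to start from none). If ``passage``
    is omitted, stochastic runs assume the experimental daily-transfer
    regime of ~10^6 cells (capped at N/10 for small populations) regrown to
    N; at N = 10^9 this is exactly the 1:1000 daily dilution (log2(1000)
    ~ 9.97 generations per cycle).
    """

    N: float
    u: float
    s: float
    target_frequency: float = 0.5
    p0: float | None = None
    passage: Passage | None = None

    def __post_init__(self) -> None:
        if self.N < 1:
            raise ValueError("N must be >= 1")
        if self.u < 0:
            raise ValueError("u must be >= 0")
        if not (0.0 < self.target_frequency < 1.0):
            raise ValueError("target_frequency must be in (0, 1)")
        if self.p0 is None:
            self.p0 = 1.0 / self.N
        if not (0.0 <= self.p0 <= 1.0):
            raise ValueError("p0 must be a frequency in [0, 1]")
        if self.passage is not None and self.passage.N0 >= self.N:
            raise ValueError("bottleneck N0 must be smaller than N")

    def default_passage(self) -> Passage:
        if self.passage is not None:
            return self.passage
        n0 = min(1e6, self.N / 10.0)
        return Passage(N0=n0, generations_per_cycle=math.log2(self.N / n0))


@dataclass
class TakeoverResult:
    """Time (generations) for the mutant subpopulation to reach the target."""

    t50: float
    reached: bool
    trajectory: pd.DataFrame | None = None
    n_replicates: int | None = None
    mean_t50: float | None = None
    sd_t50: float | None = None
    n_not_reached: int | None = None
    t50_replicates: list[float] = field(default_factory=list)


def logistic_sweep_time(p0: float, p_target: float, s: float) -> float:
    """Closed-form u=0 sweep time: ln[(p_t/(1-p_t)) / (p0/(1-p0))] / s."""
    if not (0 < p0 < 1) or not (0 < p_target < 1):
        raise ValueError("frequencies must be in (0, 1)")
    if s == 0:
        raise ValueError("neutral sweep never progresses")
    return math.log((p_target / (1 - p_target)) / (p0 / (1 - p0))) / s


def takeover_time_deterministic(
    sc: FixationScenario,
    horizon: float = 1e6,
    rtol: float = 1e-8,
    establishment_factor: bool = False,
    return_trajectory: bool = False,
) -> TakeoverResult:
    """Integrate dp/dg = u(1-p) + s p(1-p) until p reaches the target.

    Adaptive integration at relative tolerance ``rtol``; the crossing
    generation is located by the integrator's event root-finder. With
    ``establishment_factor=True`` the mutational influx is multiplied by
    2s, the classical establishment probability of a beneficial mutant
    (off by default). If the target is unreachable (s <= 0 and u = 0 below
    target) the result is flagged not-reached rather than raising.
    """
    u = sc.u * (2.0 * sc.s if establishment_factor else 1.0)
    s, p0, target = sc.s, float(sc.p0), sc.target_frequency
    if u == 0.0 and p0 == 0.0:
        raise ValueError("need u > 0 or a nonzero initial frequency")
    if p0 >= target:
        return TakeoverResult(t50=0.0, reached=True)
    if u == 0.0 and s <= 0.0:
        return TakeoverResult(t50=math.inf, reached=False)

    def rhs(_g: float, p: np.ndarray) -> list[float]:
        return [u * (1.0 - p[0]) + s * p[0] * (1.0 - p[0])]

    def crossing(_g: float, p: np.ndarray) -> float:
        return p[0] - target

    crossing.terminal = True
    crossing.direction = 1.0

    sol = solve_ivp(
        rhs,
        (0.0, horizon),
        [p0],
        events=crossing,
        rtol=rtol,
        atol=1e-18,
        dense_output=return_trajectory,
        method="RK45",
    )
    if sol.status == 1 and len(sol.t_events[0]):
        t50 = float(sol.t_events[0][0])
        traj = None
        if return_trajectory:
            g = np.linspace(0.0, t50, 200)
            traj = pd.DataFrame({"generation": g, "frequency": sol.sol(g)[0]})
        return TakeoverResult(t50=t50, reached=True, trajectory=traj)
    return TakeoverResult(t50=math.inf, reached=False)


def simulate_serial_passage(
    sc: FixationScenario,
    n_replicates: int = 100,
    seed: int = 0,
    horizon: float = 1e4,
) -> TakeoverResult:
    """Stochastic growth-mutation-bottleneck serial-passage simulation.

    Each replicate starts with round(p0*N) mutant cells in a population of N
    at the end of growth. Every cycle: the bottleneck samples N0 cells
    binomially at the current mutant frequency, then the population regrows
    for generations_per_cycle generations (deterministic growth; mutants at
    per-generation factor 2(1+s)) with mutation events arising per
    generation as Poisson(u x wild-type divisions), each seeding a 2-cell
    mutant lineage (both daughters of the mutated division). t50 is the
    first cumulative generation at which the mutant frequency reaches the
    target. Replicates not reaching the target within ``horizon``
    generations are counted separately and excluded from mean/sd, never
    silently averaged.
    """
    rng = np.random.default_rng(seed)
    passage = sc.default_passage()
    gpc = passage.generations_per_cycle
    n_full = int(math.floor(gpc))
    frac = gpc - n_full
    steps = [1.0] * n_full + ([frac] if frac > 1e-12 else [])

    t50s: list[float] = []
    n_not_reached = 0
    for _ in range(n_replicates):
        m = float(round(sc.p0 * sc.N))
        w = sc.N - m
        g_total = 0.0
        reached = m / (m + w) >= sc.target_frequency
        t50 = 0.0
        while not reached and g_total < horizon:
            # daily bottleneck: binomial sample of N0 cells at current frequency
            freq = m / (m + w)
            k = rng.binomial(int(passage.N0), freq)
            m, w = float(k), float(passage.N0) - float(k)
            if m == 0.0 and sc.u == 0.0:
                break  # mutant lineage lost and cannot recur
            # regrowth, one generation at a time
            for step in steps:
                w_new = w * 2.0**step
                births = w_new - w
                m = m * (2.0 * (1.0 + sc.s)) ** step + 2.0 * rng.poisson(
                    sc.u * births
                )
                w = w_new
                g_total += step
                if m / (m + w) >= sc.target_frequency:
                    reached = True
                    t50 = g_total
                    break
        if reached:
            t50s.append(t50)
        else:
            n_not_reached += 1

    mean = float(np.mean(t50s)) if t50s else math.nan
    sd = float(np.std(t50s, ddof=1)) if len(t50s) > 1 else math.nan
    return TakeoverResult(
        t50=mean,
        reached=bool(t50s),
        n_replicates=n_replicates,
        mean_t50=mean,
        sd_t50=sd,
        n_not_reached=n_not_reached,
        t50_replicates=t50s,
    )


def takeover_surface(
    u_grid: np.ndarray,
    s_values: np.ndarray,
    N_values: np.ndarray,
    target_frequency: float = 0.5,
    horizon: float = 1e6,
) -> pd.DataFrame:
    """Deterministic take-over time over a (u, s, N) grid, long format."""
    rows = []
    for N in np.asarray(N_values, dtype=float):
        for s in np.asarray(s_values, dtype=float):
            for u in np.asarray(u_grid, dtype=float):
                res = takeover_time_deterministic(
                    FixationScenario(
                        N=N, u=u, s=s, target_frequency=target_frequency
                    ),
                    horizon=horizon,
                )
                rows.append(
                    {
                        "u": u,
                        "s": s,
                        "N": N,
                        "t50": res.t50,
                        "reached": res.reached,
                    }
                )
    return pd.DataFrame(rows)
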