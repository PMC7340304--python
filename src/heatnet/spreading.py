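"""Modified susceptible–infected (SI) spreading simulator.

The simulator scores seed sets (e.g. the top-10 nodes of a centrality
ranking) by how fast infection spreads from them.  Dynamics differ from
the textbook SI model in one respect: at each time step every infected
node picks *one* susceptible neighbor uniformly at random and infects it
with probability beta, instead of exposing all of its neighbors.  This
throttles hub nodes — a hub cannot contact all its neighbors in a single
step — which is exactly the regime where hubs and super-spreaders
disagree.

Updates are synchronous: susceptibility is judged against the state at
the start of the step, nodes infected in a step start transmitting the
next step, and two infectors selecting the same target produce a single
infection.  The result is independent of node iteration order.

The cumulative number of infected nodes F(t) is averaged over
independent replicates (default 100); each replicate has its own RNG
stream seeded ``rng_seed + replicate``, so any replicate is reproducible
in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .centrality import CentralityVector
from .graph import Graph, sorted_labels
from .ranking import topk

__all__ = ["SIConfig", "SpreadCurve", "si_step", "run_si", "spreading_capability"]


@dataclass(frozen=True)
class SIConfig:
    """Parameters of one SI experiment.

    beta
        Per-contact infection probability in [0, 1]; 1 makes every
        selected contact succeed.
    seeds
        Initially infected nodes (non-empty, all present in the graph).
    t_max
        Hard step cap, reached only when beta < 1 stalls the spread
        (with beta = 1 on a connected graph the process saturates in at
        most N - |seeds| steps).
    replicates
        Number of independent runs averaged into the curve.
    rng_seed
        Base seed; replicate r uses ``rng_seed + r``.
    """

    seeds: tuple
    beta: float = 1.0
    t_max: int = 1000
    replicates: int = 100
    rng_seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "seeds", tuple(self.seeds))
        if not self.seeds:
            raise ValueError("seed set must be non-empty")
        if not 0.0 <= self.beta <= 1.0:
            raise ValueError(f"beta must be in [0, 1], got {self.beta}")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.t_max < 0:
            raise ValueError("t_max must be non-negative")


@dataclass(frozen=True)
class SpreadCurve:
    """Mean ± sd of cumulative infections F(t) per step over replicates.

    ``t_c`` is the first step at which every replicate had no
    susceptible nodes left, or ``t_max`` if some replicate never
    saturated within the cap.
    """

    t: np.ndarray
    mean_F: np.ndarray
    sd_F: np.ndarray
    t_c: int
    replicates: int

    @property
    def final_F(self) -> float:
        """Mean spreading capability F(t_c)."""
        return float(self.mean_F[-1])


def si_step(g: Graph, infected: set, beta: float, rng: np.random.Generator) -> set:
    """One synchronous step; returns the set of newly infected nodes.

    Each node infected at the start of the step selects one susceptible
    neighbor uniformly at random (if it has any) and infects it with
    probability ``beta``.  Selections collide silently: a node picked by
    several infectors is infected once.
    """
    newly: set = set()
    for u in sorted_labels(infected):
        susceptible = sorted_labels(g.neighbors(u) - infected)
        if not susceptible:
            continue
        target = susceptible[int(rng.integers(len(susceptible)))]
        if rng.random() < beta:
            newly.add(target)
    return newly - infected


def run_si(g: Graph, cfg: SIConfig) -> SpreadCurve:
    """Replicated SI run from a fixed seed set; deterministic given rng_seed."""
    missing = [s for s in cfg.seeds if s not in g]
    if missing:
        raise ValueError(f"seed nodes not in graph: {missing!r}")
    if len(set(cfg.seeds)) != len(cfg.seeds):
        raise ValueError("seed set contains duplicates")
    n = g.n_nodes
    curves: list[list[int]] = []
    completion: list[int] = []
    for r in range(cfg.replicates):
        rng = np.random.default_rng(cfg.rng_seed + r)
        infected = set(cfg.seeds)
        curve = [len(infected)]
        t = 0
        while len(infected) < n and t < cfg.t_max:
            infected |= si_step(g, infected, cfg.beta, rng)
            curve.append(len(infected))
            t += 1
        curves.append(curve)
        completion.append(t if len(infected) == n else cfg.t_max)
    # replicates that saturated early stay flat at their final value
    length = max(len(c) for c in curves)
    mat = np.array([c + [c[-1]] * (length - len(c)) for c in curves], dtype=float)
    mean = mat.mean(axis=0)
    sd = mat.std(axis=0, ddof=1) if cfg.replicates > 1 else np.zeros(length)
    return SpreadCurve(
        t=np.arange(length),
        mean_F=mean,
        sd_F=sd,
        t_c=max(completion),
        replicates=cfg.replicates,
    )


def spreading_capability(
    g: Graph,
    measures: Sequence[CentralityVector],
    k: int,
    cfg: SIConfig | None = None,
    *,
    beta: float = 1.0,
    t_max: int = 1000,
    replicates: int = 100,
    rng_seed: int = 0,
) -> dict[str, SpreadCurve]:
    """Spread curves for each measure's top-k seed set, on a shared time axis.

    All measures run under the same base seed, so two measures with
    identical top-k sets produce identical curves.  ``cfg`` (if given)
    supplies beta/t_max/replicates/rng_seed; its ``seeds`` field is
    ignored in favor of each measure's top-k list.
    """
    if cfg is not None:
        beta, t_max = cfg.beta, cfg.t_max
        replicates, rng_seed = cfg.replicates, cfg.rng_seed
    out: dict[str, SpreadCurve] = {}
    for cv in measures:
        seeds = topk(cv, k)
        run_cfg = SIConfig(
            seeds=seeds, beta=beta, t_max=t_max,
            replicates=replicates, rng_seed=rng_seed,
        )
        out[cv.measure] = run_si(g, run_cfg)
    # align curves on a common time axis for side-by-side comparison
    length = max(len(c.t) for c in out.values())
    aligned = {}
    for name, c in out.items():
        pad = length - len(c.t)
        if pad:
            c = SpreadCurve(
                t=np.arange(length),
                mean_F=np.concatenate([c.mean_F, np.full(pad, c.mean_F[-1])]),
                sd_F=np.concatenate([c.sd_F, np.full(pad, c.sd_F[-1])]),
                t_c=c.t_c,
                replicates=c.replicates,
            )
        aligned[name] = c
    return aligned
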