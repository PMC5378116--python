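"""Coalescent simulation of multilocus pairwise segregating-site data.

The generator mirrors the study design used throughout: each locus
contributes one pair of sequences; half of the loci have one sequence from
each population (state 3) and a quarter each have both from population 1
(state 1) or population 2 (state 2); relative mutation rates are drawn once
per data set from a Gamma(15, 15) distribution (mean 1, sd ~0.26); the
pairwise coalescence time is drawn exactly from the piecewise IIM law and
the segregating-site count is Poisson with mean ``r_j * theta * T``.

Randomness flows from a single integer seed through a counter-based Philox
bit generator, so data sets are reproducible and independent streams can be
split off per replicate without overlap.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .coalescent_core import CoalParams, ParameterError
from .inference import Dataset, PhiVector

__all__ = ["SimConfig", "Epoch", "simulate_T", "simulate_dataset", "simulate_multiepoch"]

#: the canonical study conditions: state proportions and locus-rate law
DEFAULT_STATE_PROPORTIONS = (0.25, 0.25, 0.5)
DEFAULT_RATE_GAMMA = (15.0, 15.0)


@dataclass(frozen=True)
class SimConfig:
    """Configuration of one simulated data set."""

    phi: PhiVector
    n_loci: int
    state_proportions: tuple[float, float, float] = DEFAULT_STATE_PROPORTIONS
    rate_gamma: tuple[float, float] = DEFAULT_RATE_GAMMA
    rate_vector: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_loci <= 0:
            raise ParameterError("n_loci must be > 0")
        p = np.asarray(self.state_proportions, dtype=float)
        if p.min() < 0 or abs(p.sum() - 1.0) > 1e-9:
            raise ParameterError("state proportions must be >= 0 and sum to 1")
        shape, rate = self.rate_gamma
        if shape <= 0 or rate <= 0:
            raise ParameterError("Gamma shape and rate must be > 0")


@dataclass(frozen=True)
class Epoch:
    """One piecewise-constant epoch of a generic two-deme history.

    ``size1``/``size2`` are relative population sizes (coalescence rates
    ``1/size``), ``M1``/``M2`` scaled migration rates (a lineage in deme i
    moves at ``Mi/2``), ``duration`` in units of 2N generations.
    """

    duration: float
    size1: float
    size2: float
    M1: float = 0.0
    M2: float = 0.0

    def __post_init__(self) -> None:
        if self.duration <= 0 or self.size1 <= 0 or self.size2 <= 0:
            raise ParameterError("epoch duration and sizes must be > 0")
        if self.M1 < 0 or self.M2 < 0:
            raise ParameterError("epoch migration rates must be >= 0")


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.Generator(np.random.Philox(seed))


# ---------------------------------------------------------------------------
# Exact sampling of the pairwise coalescence time
# ---------------------------------------------------------------------------

def _gillespie_epochs(
    states: np.ndarray,
    epochs: Sequence[Epoch],
    anc_size: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Vectorized two-deme CTMC trajectory sampling for many pairs at once.

    ``states`` holds sampling states (1, 2, 3); returns absolute
    coalescence times.  Within each epoch the chain is simulated by
    competing exponentials; pairs that outlive every epoch coalesce in the
    ancestral population at rate ``1/anc_size``.
    """
    n = len(states)
    state = states.astype(np.int64).copy()
    coal_time = np.full(n, np.nan)
    alive = np.ones(n, dtype=bool)
    epoch_start = 0.0
    for ep in epochs:
        epoch_end = epoch_start + ep.duration
        t_local = np.zeros(n)
        active = alive.copy()
        while np.any(active):
            idx = np.flatnonzero(active)
            st = state[idx]
            rate_coal = np.where(st == 1, 1.0 / ep.size1, np.where(st == 2, 1.0 / ep.size2, 0.0))
            rate_move = np.where(
                st == 1, ep.M1, np.where(st == 2, ep.M2, 0.5 * (ep.M1 + ep.M2))
            )
            total = rate_coal + rate_move
            # pairs with no possible event just wait out the epoch
            stuck = total == 0.0
            if np.any(stuck):
                active[idx[stuck]] = False
                idx = idx[~stuck]
                if len(idx) == 0:
                    break
                st = st[~stuck]
                rate_coal = rate_coal[~stuck]
                rate_move = rate_move[~stuck]
                total = total[~stuck]
            dt = rng.exponential(1.0 / total)
            t_new = t_local[idx] + dt
            over = epoch_start + t_new >= epoch_end
            # events past the epoch boundary are censored: state carries over
            surv = idx[over]
            active[surv] = False
            idx = idx[~over]
            if len(idx) == 0:
                continue
            t_local[idx] = t_new[~over]
            u = rng.random(len(idx)) * total[~over]
            coal = u < rate_coal[~over]
            ic = idx[coal]
            coal_time[ic] = epoch_start + t_local[ic]
            alive[ic] = False
            active[ic] = False
            im = idx[~coal]
            st_m = state[im]
            # migration: from state 1 or 2 one lineage moves -> state 3;
            # from state 3 the mover determines the destination
            if np.any(st_m == 3):
                movers = im[st_m == 3]
                p_to_1 = np.full(len(movers), 0.5)
                both = ep.M1 + ep.M2
                if both > 0:
                    # lineage in deme 2 moves at M2/2 (-> both in deme 1)
                    p_to_1 = np.full(len(movers), ep.M2 / both)
                to1 = rng.random(len(movers)) < p_to_1
                state[movers[to1]] = 1
                state[movers[~to1]] = 2
            keep = st_m != 3
            state[im[keep]] = 3
        epoch_start = epoch_end
    rest = np.flatnonzero(alive)
    coal_time[rest] = epoch_start + rng.exponential(anc_size, size=len(rest))
    return coal_time


def _epochs_from_params(params: CoalParams) -> list[Epoch]:
    eps = []
    if params.tau1 > 0:
        eps.append(Epoch(params.tau1, params.c1, params.c2, 0.0, 0.0))
    if params.tau0 > params.tau1:
        eps.append(Epoch(params.tau0 - params.tau1, 1.0, params.b, params.M1, params.M2))
    return eps


def simulate_T(state: int, params: CoalParams, rng) -> float:
    """Draw one pairwise coalescence time exactly from the IIM law."""
    if state not in (1, 2, 3):
        raise ParameterError("sampling state must be 1, 2 or 3")
    gen = _rng(rng)
    return float(
        _gillespie_epochs(np.array([state]), _epochs_from_params(params), params.a, gen)[0]
    )


def _draw_states(n: int, proportions: tuple[float, float, float]) -> np.ndarray:
    """Deterministic state allocation matching the target proportions."""
    n1 = int(round(proportions[0] * n))
    n2 = int(round(proportions[1] * n))
    n3 = n - n1 - n2
    return np.concatenate(
        [np.full(n1, 1, np.int64), np.full(n2, 2, np.int64), np.full(n3, 3, np.int64)]
    )


def simulate_dataset(cfg: SimConfig) -> Dataset:
    """Simulate a multilocus data set of pairwise segregating-site counts."""
    rng = _rng(cfg.seed)
    params, theta = cfg.phi.to_coalparams()
    states = _draw_states(cfg.n_loci, cfg.state_proportions)
    if cfg.rate_vector is not None:
        r = np.asarray(cfg.rate_vector, dtype=float)
        if len(r) != cfg.n_loci or (r <= 0).any():
            raise ParameterError("rate_vector must have n_loci positive entries")
    else:
        shape, rate = cfg.rate_gamma
        r = rng.gamma(shape, 1.0 / rate, size=cfg.n_loci)
    T = _gillespie_epochs(states, _epochs_from_params(params), params.a, rng)
    s = rng.poisson(r * theta * T)
    frame = pd.DataFrame(
        {
            "locus_id": [f"L{i:07d}" for i in range(cfg.n_loci)],
            "state": states,
            "s": s.astype(np.int64),
            "rel_rate": r,
        }
    )
    return Dataset(frame)


def simulate_multiepoch(
    epochs: Sequence[Epoch],
    anc_size: float,
    theta: float,
    n_loci: int,
    state_proportions: tuple[float, float, float] = DEFAULT_STATE_PROPORTIONS,
    rate_gamma: tuple[float, float] = DEFAULT_RATE_GAMMA,
    rate_vector: np.ndarray | None = None,
    seed: int = 0,
) -> Dataset:
    """Simulate data under a generic piecewise-constant two-deme history.

    Epochs run from the present backward; after the last epoch the two
    demes merge into an ancestral population of relative size ``anc_size``.
    The IIM model is the special case of an isolation epoch followed by a
    migration epoch.  Useful for model-misspecification experiments such as
    gradual divergence or secondary contact.
    """
    if anc_size <= 0 or theta <= 0:
        raise ParameterError("anc_size and theta must be > 0")
    rng = _rng(seed)
    states = _draw_states(n_loci, state_proportions)
    if rate_vector is not None:
        r = np.asarray(rate_vector, dtype=float)
    else:
        shape, rate = rate_gamma
        r = rng.gamma(shape, 1.0 / rate, size=n_loci)
    T = _gillespie_epochs(states, list(epochs), anc_size, rng)
    s = rng.poisson(r * theta * T)
    frame = pd.DataFrame(
        {
            "locus_id": [f"L{i:07d}" for i in range(n_loci)],
            "state": states,
            "s": s.astype(np.int64),
            "rel_rate": r,
        }
    )
    return Dataset(frame)


#: illustrative misspecification scenarios (gradual divergence; secondary
#: contact).  These are representative configurations, not reproductions of
#: any published experiment.
MISSPECIFICATION_SCENARIOS: dict[str, dict] = {
    "gradual_divergence": {
        "epochs": (
            Epoch(0.5, 1.5, 1.8, 0.0, 0.0),
            Epoch(0.5, 1.2, 1.4, 0.25, 0.4),
            Epoch(0.5, 1.0, 1.1, 0.5, 0.8),
            Epoch(0.5, 0.9, 1.0, 1.0, 1.5),
        ),
        "anc_size": 0.8,
        "theta": 2.0,
    },
    "secondary_contact": {
        "epochs": (
            Epoch(0.6, 1.2, 1.5, 0.0, 0.0),
            Epoch(0.6, 1.0, 1.2, 0.8, 1.2),
            Epoch(0.8, 1.0, 1.2, 0.0, 0.0),
        ),
        "anc_size": 1.0,
        "theta": 2.0,
    },
}
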