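"""Multilocus likelihood, maximum-likelihood fitting and confidence intervals.

The data are independent loci, each contributing one pair of sequences
summarized by a sampling state (1, 2 or 3), a segregating-site count ``s``
and a known relative mutation rate ``r``.  The model is fitted in the
mutation-scaled parameterization

    phi = (theta_a, theta, theta_b, theta_c1, theta_c2, T1, V, M1, M2)

with ``theta_x = theta * x`` for the relative sizes, ``T1 = theta * tau1``
and ``V = theta * (tau0 - tau1)``; this decouples the mutation rate from
the coalescent time scale and markedly improves optimizer behaviour.  The
coalescent-scale parameters are recovered as ``a = theta_a / theta`` and so
on.  The log-likelihood of a data set is the sum over loci of the
segregating-sites log-PMF evaluated at ``theta_j = r_j * theta``.

Model variants (ISO, IM1, IIM1, IIM2, IIM3) are masks over phi: fixed
entries (e.g. ``M1 = 0``) and ties (in models without a distinct isolation
stage the isolation-stage sizes equal the migration-stage sizes).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.stats import qmc

from .coalescent_core import CoalParams, NumericalError, ParameterError, migration_spectrum
from .segsites import logpmf_array

__all__ = [
    "PARAM_NAMES",
    "ModelSpec",
    "MODELS",
    "PhiVector",
    "LocusObservation",
    "Dataset",
    "FitResult",
    "ConvertedEstimates",
    "LikelihoodError",
    "loglikelihood",
    "loglik_by_locus",
    "fit",
    "hessian",
    "wald_ci",
    "fisher_se",
    "profile_ci",
    "convert",
    "delta_method_ci",
    "calibrate_mu",
]

logger = logging.getLogger(__name__)

PARAM_NAMES: tuple[str, ...] = (
    "theta_a",
    "theta",
    "theta_b",
    "theta_c1",
    "theta_c2",
    "T1",
    "V",
    "M1",
    "M2",
)

#: parameters optimized on a log scale; migration rates stay on the natural
#: scale with a hard lower bound at zero (they may legitimately sit there)
_LOG_SCALE = frozenset(PARAM_NAMES) - {"M1", "M2"}
_LOG_LB, _LOG_UB = -25.0, 12.0
_M_UB = 40.0
#: relative log-likelihood convergence tolerance
_REL_TOL = 1e-8
#: finite-difference step policy for Hessians and scores
_FD_STEP = 1e-4


class LikelihoodError(RuntimeError):
    """Raised when the likelihood is not finite at the requested parameters."""


# ---------------------------------------------------------------------------
# Model masks
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelSpec:
    """Which phi entries are free, fixed, or tied to another entry."""

    name: str
    free: tuple[str, ...]
    fixed: Mapping[str, float] = field(default_factory=dict)
    tied: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        covered = set(self.free) | set(self.fixed) | set(self.tied)
        if covered != set(PARAM_NAMES):
            raise ValueError(f"model {self.name} does not cover all phi entries")

    @property
    def df(self) -> int:
        return len(self.free)

    def build_phi(self, free_values: Mapping[str, float]) -> "PhiVector":
        vals = dict(self.fixed)
        vals.update({k: float(free_values[k]) for k in self.free})
        for k, src in self.tied.items():
            vals[k] = vals[src]
        return PhiVector(model=self, **vals)

    def free_array(self, phi: "PhiVector") -> np.ndarray:
        return np.array([getattr(phi, k) for k in self.free], dtype=float)

    def is_nested_in(self, other: "ModelSpec") -> bool:
        """True if every phi reachable under self is reachable under other."""
        if not set(self.free) <= set(other.free):
            return False
        for k, v in other.fixed.items():
            if self.fixed.get(k) != v:
                return False
        for k, src in other.tied.items():
            if self.tied.get(k) != src:
                return False
        return True


_TIED_C = {"theta_c1": "theta", "theta_c2": "theta_b"}

MODELS: dict[str, ModelSpec] = {
    "ISO": ModelSpec(
        "ISO",
        ("theta_a", "theta", "theta_b", "V"),
        fixed={"T1": 0.0, "M1": 0.0, "M2": 0.0},
        tied=_TIED_C,
    ),
    "IM1": ModelSpec(
        "IM1",
        ("theta_a", "theta", "theta_b", "V", "M1", "M2"),
        fixed={"T1": 0.0},
        tied=_TIED_C,
    ),
    "IIM1": ModelSpec(
        "IIM1",
        ("theta_a", "theta", "theta_b", "V", "M1", "M2", "T1"),
        tied=_TIED_C,
    ),
    "IIM2": ModelSpec("IIM2", PARAM_NAMES),
    "IIM3": ModelSpec(
        "IIM3",
        tuple(n for n in PARAM_NAMES if n != "M1"),
        fixed={"M1": 0.0},
    ),
}


@dataclass(frozen=True)
class PhiVector:
    """The mutation-scaled parameter vector, optionally carrying its model mask."""

    theta_a: float
    theta: float
    theta_b: float
    theta_c1: float
    theta_c2: float
    T1: float
    V: float
    M1: float
    M2: float
    model: ModelSpec | None = None

    def __post_init__(self) -> None:
        for k in ("theta_a", "theta", "theta_b", "theta_c1", "theta_c2"):
            if not getattr(self, k) > 0:
                raise ParameterError(f"{k} must be > 0")
        if self.T1 < 0 or self.V < 0:
            raise ParameterError("T1 and V must be >= 0")
        if self.M1 < 0 or self.M2 < 0:
            raise ParameterError("M1 and M2 must be >= 0")
        if self.model is not None:
            for k, v in self.model.fixed.items():
                if getattr(self, k) != v:
                    raise ParameterError(
                        f"phi entry {k} must equal {v} under model {self.model.name}"
                    )

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, k) for k in PARAM_NAMES], dtype=float)

    def to_coalparams(self) -> tuple[CoalParams, float]:
        """Recover coalescent-scale parameters and the mean mutation rate."""
        th = self.theta
        return (
            CoalParams(
                a=self.theta_a / th,
                b=self.theta_b / th,
                c1=self.theta_c1 / th,
                c2=self.theta_c2 / th,
                tau1=self.T1 / th,
                tau0=(self.T1 + self.V) / th,
                M1=self.M1,
                M2=self.M2,
            ),
            th,
        )


# ---------------------------------------------------------------------------
# Data containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LocusObservation:
    """One locus: sampling state, segregating-site count, relative rate."""

    locus_id: str
    state: int
    s: int
    rel_rate: float = 1.0
    block: str | None = None


class Dataset:
    """A table of independent loci with cached per-state numpy views."""

    COLUMNS = ("locus_id", "state", "s", "rel_rate", "block")

    def __init__(self, frame: pd.DataFrame):
        df = frame.copy()
        if "rel_rate" not in df:
            df["rel_rate"] = 1.0
        if "block" not in df:
            df["block"] = None
        missing = {"locus_id", "state", "s"} - set(df.columns)
        if missing:
            raise ValueError(f"missing dataset columns: {sorted(missing)}")
        df = df.reset_index(drop=True)
        states = df["state"].to_numpy()
        if not np.isin(states, (1, 2, 3)).all():
            raise ValueError("sampling states must be in {1, 2, 3}")
        s = df["s"].to_numpy()
        if (s < 0).any() or not np.issubdtype(s.dtype, np.integer):
            raise ValueError("segregating-site counts must be integers >= 0")
        if (df["rel_rate"].to_numpy() <= 0).any():
            raise ValueError("relative rates must be > 0")
        if df["locus_id"].duplicated().any():
            raise ValueError("locus_id values must be unique")
        self.frame = df
        self._groups: dict[int, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for state in (1, 2, 3):
            idx = np.flatnonzero(states == state)
            self._groups[state] = (
                s[idx].astype(np.int64),
                df["rel_rate"].to_numpy(dtype=float)[idx],
                idx,
            )

    @classmethod
    def from_observations(cls, obs: Iterable[LocusObservation]) -> "Dataset":
        rows = [(o.locus_id, o.state, o.s, o.rel_rate, o.block) for o in obs]
        return cls(pd.DataFrame(rows, columns=cls.COLUMNS))

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def states_present(self) -> set[int]:
        return {st for st in (1, 2, 3) if len(self._groups[st][0])}

    def group(self, state: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return self._groups[state]

    def block_labels(self) -> np.ndarray:
        return self.frame["block"].to_numpy()

    def to_dataframe(self) -> pd.DataFrame:
        return self.frame.copy()


# ---------------------------------------------------------------------------
# Likelihood
# ---------------------------------------------------------------------------

def loglik_by_locus(data: Dataset, phi: PhiVector) -> np.ndarray:
    """Per-locus log-likelihood contributions, aligned with ``data.frame`` rows."""
    params, theta = phi.to_coalparams()
    spectrum = migration_spectrum(params)
    out = np.empty(len(data))
    for state in (1, 2, 3):
        s, r, idx = data.group(state)
        if len(idx) == 0:
            continue
        out[idx] = logpmf_array(state, s, r * theta, params, spectrum)
    return out

def loglikelihood(data: Dataset, phi: PhiVector) -> float:
    """Log of the product over loci of the segregating-sites PMF."""
    ll = loglik_by_locus(data, phi)
    if not np.all(np.isfinite(ll)):
        bad = int(np.flatnonzero(~np.isfinite(ll))[0])
        locus = data.frame["locus_id"].iloc[bad]
        raise LikelihoodError(
            f"non-finite likelihood at locus {locus!r} (row {bad}) for phi={phi!r}"
        )
    return float(ll.sum())


# ---------------------------------------------------------------------------
# Optimizer plumbing
# ---------------------------------------------------------------------------

def _to_internal(model: ModelSpec, values: np.ndarray) -> np.ndarray:
    x = np.array(values, dtype=float)
    for i, name in enumerate(model.free):
        if name in _LOG_SCALE:
            x[i] = math.log(max(x[i], 1e-12))
    return x


def _from_internal(model: ModelSpec, x: np.ndarray) -> np.ndarray:
    v = np.array(x, dtype=float)
    for i, name in enumerate(model.free):
        if name in _LOG_SCALE:
            v[i] = math.exp(v[i])
    return v


def _internal_bounds(model: ModelSpec) -> list[tuple[float, float]]:
    return [
        (_LOG_LB, _LOG_UB) if name in _LOG_SCALE else (0.0, _M_UB)
        for name in model.free
    ]


def _neg_loglik_factory(data: Dataset, model: ModelSpec) -> Callable[[np.ndarray], float]:
    def nll(x: np.ndarray) -> float:
        try:
            phi = model.build_phi(dict(zip(model.free, _from_internal(model, x))))
            return -loglikelihood(data, phi)
        except (ParameterError, NumericalError, LikelihoodError, OverflowError):
            return 1e12

    return nll


def _moment_init(data: Dataset, model: ModelSpec) -> PhiVector:
    """Crude method-of-moments style starting point.

    Matches the per-state mean of ``s / r`` (an estimate of ``theta E[T(i)]``)
    against the leading behaviour of the model: within-population means are
    dominated by the isolation-stage sizes, the between-population mean by
    the total divergence ``T1 + V + theta_a``.
    """
    means = {}
    for state in (1, 2, 3):
        s, r, idx = data.group(state)
        if len(idx):
            means[state] = float(np.mean(s / r))
    overall = np.mean(list(means.values())) if means else 1.0
    a1 = means.get(1, overall)
    a2 = means.get(2, overall)
    a3 = means.get(3, 2.0 * overall)
    a1, a2, a3 = (max(v, 0.05) for v in (a1, a2, a3))
    full = {
        "theta_c1": a1,
        "theta_c2": a2,
        "theta": 0.7 * min(a1, a2),
        "theta_b": 0.7 * min(a1, a2) * a2 / a1,
        "theta_a": max(0.4 * a3, 0.05),
        "T1": 0.3 * a3,
        "V": 0.3 * a3,
        "M1": 0.3,
        "M2": 0.3,
    }
    if "T1" not in model.free:  # no isolation stage: within-pop means track theta
        full["theta"] = a1
        full["theta_b"] = a2
        full["theta_a"] = max(0.5 * (a1 + a2), 0.05)
        full["V"] = max(a3 - full["theta_a"], 0.2)
    return model.build_phi(full)


@dataclass
class FitResult:
    """Outcome of a maximum-likelihood fit."""

    phi_hat: PhiVector
    model: ModelSpec
    logL: float
    hessian: np.ndarray | None
    free_names: tuple[str, ...]
    n_starts: int
    seed: int
    converged: bool
    start_logLs: list[float]
    n_failed_starts: int = 0

    def free_values(self) -> np.ndarray:
        return self.model.free_array(self.phi_hat)


def _polish(nll, x0, bounds, maxiter_nm, maxfun_qn=700):
    """One local optimization: simplex polish then bounded quasi-Newton."""
    f0 = nll(np.asarray(x0, dtype=float))
    res_nm = optimize.minimize(
        nll,
        x0,
        method="Nelder-Mead",
        bounds=bounds,
        options={
            "maxfev": maxiter_nm,
            "fatol": _REL_TOL * (1.0 + abs(f0)),
            "xatol": 1e-6,
            "adaptive": True,
        },
    )
    res = optimize.minimize(
        nll,
        res_nm.x,
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxfun": maxfun_qn, "ftol": 1e-12, "gtol": 1e-7, "eps": 1e-7},
    )
    if res.fun > res_nm.fun:
        return res_nm, bool(res_nm.success)
    return res, bool(res.success or res_nm.success)


def promote_phi(
    phi: PhiVector, target: ModelSpec, eps_migration: float = 0.15
) -> PhiVector:
    """Map a simpler model's estimate to a starting point for a larger model.

    Parameters absent from the source estimate are seeded off the boundary:
    migration rates at ``eps_migration``, the isolation time as a fraction
    of the divergence span (keeping ``T1 + V`` unchanged), and the
    isolation-stage sizes at their migration-stage counterparts.
    """
    vals = {k: getattr(phi, k) for k in PARAM_NAMES}
    src_model = phi.model
    src_free = set(src_model.free) if src_model is not None else set(PARAM_NAMES)
    for name in set(target.free) - src_free:
        if name in ("M1", "M2"):
            vals[name] = eps_migration
        elif name == "T1":
            span = vals["T1"] + vals["V"]
            vals["T1"] = 0.35 * span
            vals["V"] = max(span - vals["T1"], 1e-3)
        elif name == "theta_c1":
            vals[name] = vals["theta"]
        elif name == "theta_c2":
            vals[name] = vals["theta_b"]
    return target.build_phi({k: vals[k] for k in target.free})


def fit(
    data: Dataset,
    model: ModelSpec | str,
    n_starts: int = 10,
    seed: int = 0,
    init: PhiVector | Sequence[PhiVector] | None = None,
    compute_hessian: bool = True,
    cascade: bool = True,
) -> FitResult:
    """Maximize the multilocus likelihood under a model mask.

    The best of ``n_starts`` local optimizations is returned, each a
    Nelder-Mead simplex search followed by a bounded quasi-Newton polish.
    Starting points are a method-of-moments initialization plus
    Latin-hypercube jitter around it; extra warm starts may be supplied via
    ``init``.  Deterministic given ``(data, model, n_starts, seed)``.
    """
    if isinstance(model, str):
        model = MODELS[model]
    if len(data) == 0:
        raise ValueError("empty dataset")
    missing = {1, 2, 3} - data.states_present
    if missing:
        logger.warning(
            "model %s fitted without observations from states %s; "
            "some parameters may be poorly identified",
            model.name,
            sorted(missing),
        )

    nll = _neg_loglik_factory(data, model)
    bounds = _internal_bounds(model)
    d = model.df

    starts: list[np.ndarray] = []
    if init is not None:
        inits = [init] if isinstance(init, PhiVector) else list(init)
        starts.extend(_to_internal(model, model.free_array(p)) for p in inits)
    elif model.name != "ISO" and cascade:
        # warm starts promoted from a cheap isolation-model fit: the ISO
        # surface is well behaved and lands the search in the right basin
        iso = MODELS["ISO"]
        nll_iso = _neg_loglik_factory(data, iso)
        x_iso = _to_internal(iso, iso.free_array(_moment_init(data, iso)))
        res_iso, _ = _polish(nll_iso, x_iso, _internal_bounds(iso), maxiter_nm=60 * iso.df)
        phi_iso = iso.build_phi(dict(zip(iso.free, _from_internal(iso, res_iso.x))))
        starts.append(_to_internal(model, model.free_array(promote_phi(phi_iso, model, 0.3))))
    x_mom = _to_internal(model, model.free_array(_moment_init(data, model)))
    starts.append(x_mom)
    n_jitter = max(0, n_starts - len(starts))
    if n_jitter:
        sampler = qmc.LatinHypercube(d=d, seed=seed)
        u = sampler.random(n_jitter)
        for row in u:
            x = x_mom.copy()
            for i, name in enumerate(model.free):
                if name in _LOG_SCALE:
                    x[i] = x_mom[i] + (row[i] - 0.5) * 2.0
                else:
                    x[i] = 0.02 + row[i] * 1.2
            starts.append(x)

    best = None
    best_ok = False
    start_logLs: list[float] = []
    n_failed = 0
    for x0 in starts:
        try:
            res, ok = _polish(nll, x0, bounds, maxiter_nm=60 * d)
        except Exception:  # pragma: no cover - defensive
            n_failed += 1
            continue
        if not np.isfinite(res.fun) or res.fun >= 1e12:
            n_failed += 1
            continue
        start_logLs.append(-float(res.fun))
        if best is None or res.fun < best.fun:
            best, best_ok = res, ok
    if best is None:
        raise LikelihoodError(
            f"all {len(starts)} starts failed to converge for model {model.name}"
        )
    # refine the winning start with another simplex + quasi-Newton pass
    res, ok = _polish(nll, best.x, bounds, maxiter_nm=60 * d)
    if res.fun <= best.fun:
        best, best_ok = res, ok or best_ok

    values = _from_internal(model, best.x)
    phi_hat = model.build_phi(dict(zip(model.free, values)))
    logL = -float(best.fun)
    hess = None
    if compute_hessian:
        hess = hessian(lambda v: _loglik_free(data, model, v), values,
                       lower=np.array([0.0 if n in ("M1", "M2", "T1", "V") else -np.inf
                                       for n in model.free]))
    return FitResult(
        phi_hat=phi_hat,
        model=model,
        logL=logL,
        hessian=hess,
        free_names=model.free,
        n_starts=len(starts),
        seed=seed,
        converged=best_ok,
        start_logLs=start_logLs,
        n_failed_starts=n_failed,
    )


def _loglik_free(data: Dataset, model: ModelSpec, values: np.ndarray) -> float:
    phi = model.build_phi(dict(zip(model.free, values)))
    return loglikelihood(data, phi)


# ---------------------------------------------------------------------------
# Derivatives
# ---------------------------------------------------------------------------

def hessian(
    f: Callable[[np.ndarray], float],
    x: np.ndarray,
    lower: np.ndarray | None = None,
) -> np.ndarray:
    """Central-finite-difference Hessian with step ``1e-4 * (1 + |x_k|)``.

    When an estimate sits within one step of its lower bound the stencil
    centre is shifted just inside the domain, so boundary estimates (for
    example a migration rate at zero) still yield a usable curvature matrix.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    h = _FD_STEP * (1.0 + np.abs(x))
    centre = x.copy()
    if lower is not None:
        centre = np.maximum(centre, np.asarray(lower) + h)
    H = np.empty((n, n))
    f0 = f(centre)
    for i in range(n):
        ei = np.zeros(n)
        ei[i] = h[i]
        fpp = f(centre + ei)
        fmm = f(centre - ei)
        H[i, i] = (fpp - 2.0 * f0 + fmm) / h[i] ** 2
        for j in range(i + 1, n):
            ej = np.zeros(n)
            ej[j] = h[j]
            fp_p = f(centre + ei + ej)
            fp_m = f(centre + ei - ej)
            fm_p = f(centre - ei + ej)
            fm_m = f(centre - ei - ej)
            H[i, j] = H[j, i] = (fp_p - fp_m - fm_p + fm_m) / (4.0 * h[i] * h[j])
    return H


def score_by_locus(data: Dataset, fit_result: FitResult) -> np.ndarray:
    """Per-locus score vectors (central differences), shape (n_loci, n_free)."""
    model = fit_result.model
    x = fit_result.free_values()
    h = _FD_STEP * (1.0 + np.abs(x))
    lower = np.array([0.0 if n in ("M1", "M2", "T1", "V") else -np.inf for n in model.free])
    centre = np.maximum(x, lower + h)
    scores = np.empty((len(data), model.df))
    for k in range(model.df):
        ek = np.zeros(model.df)
        ek[k] = h[k]
        lp = loglik_by_locus(data, model.build_phi(dict(zip(model.free, centre + ek))))
        lm = loglik_by_locus(data, model.build_phi(dict(zip(model.free, centre - ek))))
        scores[:, k] = (lp - lm) / (2.0 * h[k])
    return scores


# ---------------------------------------------------------------------------
# Confidence intervals
# ---------------------------------------------------------------------------

_BOUNDARY_TOL = 1e-3


def _covariance(fit_result: FitResult) -> np.ndarray:
    if fit_result.hessian is None:
        raise ValueError("fit was run without a Hessian")
    info = -fit_result.hessian
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError as exc:
        raise LikelihoodError(
            "singular Hessian: Wald intervals unavailable, use profile_ci"
        ) from exc
    if np.any(np.diag(cov) <= 0):
        raise LikelihoodError(
            "negative variance from inverted Hessian: use profile_ci"
        )
    return cov


def fisher_se(fit_result: FitResult) -> dict[str, float]:
    """Standard errors from the observed Fisher information (inverse Hessian)."""
    cov = _covariance(fit_result)
    return dict(zip(fit_result.free_names, np.sqrt(np.diag(cov))))


def wald_ci(fit_result: FitResult, level: float = 0.95) -> dict[str, tuple[float, float]]:
    """Wald intervals ``estimate +- z * se`` from the inverted Hessian."""
    for name in ("M1", "M2", "T1"):
        if name in fit_result.free_names:
            v = getattr(fit_result.phi_hat, name)
            if v < _BOUNDARY_TOL:
                logger.warning(
                    "estimate of %s (%.3g) is on or near the boundary; "
                    "Wald intervals may be unreliable, consider profile_ci",
                    name,
                    v,
                )
    z = stats.norm.ppf(0.5 * (1.0 + level))
    se = fisher_se(fit_result)
    x = fit_result.free_values()
    return {
        name: (x[i] - z * se[name], x[i] + z * se[name])
        for i, name in enumerate(fit_result.free_names)
    }


@dataclass(frozen=True)
class ProfileInterval:
    lo: float
    hi: float
    lo_at_bound: bool = False
    hi_at_bound: bool = False

    def __iter__(self):
        return iter((self.lo, self.hi))


def _constrained_max(
    data: Dataset,
    model: ModelSpec,
    drop: str,
    build: Callable[[Mapping[str, float], float], PhiVector],
    v: float,
    x_warm: np.ndarray,
    kept: tuple[str, ...],
) -> tuple[float, np.ndarray]:
    """Maximize logL with one degree of freedom substituted out."""

    def nll(x: np.ndarray) -> float:
        vals = {}
        for i, name in enumerate(kept):
            vals[name] = math.exp(x[i]) if name in _LOG_SCALE else x[i]
        try:
            return -loglikelihood(data, build(vals, v))
        except (ParameterError, NumericalError, LikelihoodError, OverflowError):
            return 1e12

    bounds = [
        (_LOG_LB, _LOG_UB) if name in _LOG_SCALE else (0.0, _M_UB) for name in kept
    ]
    res, _ = _polish(nll, x_warm, bounds, maxiter_nm=400 * max(len(kept), 1))
    return -float(res.fun), res.x


def _profile_interval(
    data: Dataset,
    model: ModelSpec,
    fit_result: FitResult,
    drop: str,
    build: Callable[[Mapping[str, float], float], PhiVector],
    vhat: float,
    level: float,
    lower_bound: float,
    se_guess: float,
) -> ProfileInterval:
    """Generic profile-likelihood interval by outward bracketing + bisection."""
    kept = tuple(n for n in model.free if n != drop)
    x_full = fit_result.free_values()
    x_warm0 = np.array(
        [
            math.log(max(x_full[model.free.index(n)], 1e-12))
            if n in _LOG_SCALE
            else x_full[model.free.index(n)]
            for n in kept
        ]
    )
    target = fit_result.logL - 0.5 * stats.chi2.ppf(level, 1)
    cache: dict[float, float] = {}
    warm = {None: x_warm0}

    def profile(v: float) -> float:
        if v in cache:
            return cache[v]
        ll, xw = _constrained_max(data, model, drop, build, v, warm.get(None, x_warm0), kept)
        warm[None] = xw
        cache[v] = ll
        return ll

    def solve_side(direction: int) -> tuple[float, bool]:
        step = max(se_guess, 0.05 * (1.0 + abs(vhat)))
        v_in = vhat
        for _ in range(60):
            v_out = v_in + direction * step
            if direction < 0 and v_out <= lower_bound:
                v_out = lower_bound
            g = profile(v_out) - target
            if g < 0:
                # bracket found between v_in and v_out
                lo, hi = (v_out, v_in) if direction < 0 else (v_in, v_out)
                root = optimize.brentq(
                    lambda v: profile(v) - target,
                    lo,
                    hi,
                    xtol=1e-4 * (1.0 + abs(vhat)),
                    rtol=1e-6,
                )
                return float(root), False
            if direction < 0 and v_out == lower_bound:
                return lower_bound, True
            v_in = v_out
            step *= 1.6
        logger.warning("profile search did not bracket the %s endpoint", "lower" if direction < 0 else "upper")
        return v_in, True

    lo, lo_bound = solve_side(-1)
    hi, hi_bound = solve_side(+1)
    return ProfileInterval(lo, hi, lo_bound, hi_bound)


def profile_ci(
    data: Dataset,
    model: ModelSpec | str,
    fit_result: FitResult,
    param: str,
    level: float = 0.95,
) -> ProfileInterval:
    """Profile-likelihood interval: endpoints where the re-maximized logL
    drops by half the chi-square(1) quantile (1.9207 at 95%)."""
    if isinstance(model, str):
        model = MODELS[model]
    if param not in model.free:
        raise ValueError(f"{param} is not free under model {model.name}")

    def build(vals: Mapping[str, float], v: float) -> PhiVector:
        d = dict(vals)
        d[param] = v
        return model.build_phi(d)

    vhat = float(getattr(fit_result.phi_hat, param))
    try:
        se = fisher_se(fit_result).get(param, 0.1 * (1 + abs(vhat)))
    except LikelihoodError:
        se = 0.1 * (1 + abs(vhat))
    lower = 0.0 if param in ("M1", "M2", "T1", "V") else 1e-10
    return _profile_interval(data, model, fit_result, param, build, vhat, level, lower, se)


# ---------------------------------------------------------------------------
# Conversion to natural units
# ---------------------------------------------------------------------------

def calibrate_mu(
    mean_outgroup_divergence: float,
    divergence_time_years: float,
    g: float,
) -> float:
    """Molecular-clock estimate of the mean per-locus per-generation mutation rate.

    With the in/outgroup split ``t`` years ago and ``g`` years per
    generation, the expected pairwise divergence is ``2 (t / g) mu``, so
    ``mu_hat = k_bar * g / (2 t)``.
    """
    if mean_outgroup_divergence <= 0 or divergence_time_years <= 0 or g <= 0:
        raise ParameterError("calibration inputs must be > 0")
    return mean_outgroup_divergence * g / (2.0 * divergence_time_years)


@dataclass(frozen=True)
class ConvertedEstimates:
    """Estimates in demographic units (diploid individuals, years)."""

    Na: float
    N: float
    Nb: float
    Nc1: float
    Nc2: float
    t0: float
    t1: float
    q1: float
    s1: float
    wald: dict[str, tuple[float, float]] | None = None
    profile: dict[str, tuple[float, float]] | None = None


def _converted_point(phi: PhiVector, g: float, mu_hat: float) -> dict[str, float]:
    b_hat = phi.theta_b / phi.theta
    return {
        "Na": phi.theta_a / (4.0 * mu_hat),
        "N": phi.theta / (4.0 * mu_hat),
        "Nb": phi.theta_b / (4.0 * mu_hat),
        "Nc1": phi.theta_c1 / (4.0 * mu_hat),
        "Nc2": phi.theta_c2 / (4.0 * mu_hat),
        "t0": (g / (2.0 * mu_hat)) * (phi.T1 + phi.V),
        "t1": (g / (2.0 * mu_hat)) * phi.T1,
        "q1": mu_hat * phi.M2 * b_hat / phi.theta,
        "s1": phi.M2 * b_hat / 2.0,
    }


def convert(fit_result: FitResult, g: float, mu_hat: float) -> ConvertedEstimates:
    """Convert mutation-scaled estimates to demographic units.

    ``N_x = theta_x / (4 mu)`` (diploid individuals), ``t = (g / 2 mu)``
    times the mutation-scaled age, ``q1 = mu M2 b / theta`` (forward
    migrant fraction of population 1) and ``s1 = M2 b / 2`` (migrant
    sequences per generation).
    """
    if g <= 0 or mu_hat <= 0:
        raise ParameterError("g and mu_hat must be > 0")
    pt = _converted_point(fit_result.phi_hat, g, mu_hat)
    return ConvertedEstimates(**pt)


# psi parameterizations used for converted-scale uncertainty: the model is
# refitted (Hessian recomputed) in each, never chain-ruled by hand.
def _psi_space(model: ModelSpec, s1_variant: bool) -> tuple[tuple[str, ...], Callable]:
    """Names and phi-builder for the conversion parameterization.

    psi = (theta_a, theta, theta_b, theta_c1, theta_c2, T1, T0, G) with
    ``T0 = T1 + V`` and ``G = M2 b / theta`` (or ``M2 b`` for the migrant
    count ``s1``); entries absent from the model mask are dropped.
    """
    names = []
    for n in ("theta_a", "theta", "theta_b", "theta_c1", "theta_c2"):
        if n in model.free:
            names.append(n)
    if "T1" in model.free:
        names.append("T1")
    if "V" in model.free:
        names.append("T0")
    if "M2" in model.free:
        names.append("G")

    def build(psi: Mapping[str, float]) -> PhiVector:
        vals = {n: psi[n] for n in names if n in PARAM_NAMES}
        if "T0" in names:
            t1 = psi.get("T1", model.fixed.get("T1", 0.0))
            vals["V"] = psi["T0"] - t1
        if "G" in names:
            theta = vals.get("theta", model.fixed.get("theta"))
            theta_b = vals.get("theta_b", model.fixed.get("theta_b"))
            if s1_variant:
                vals["M2"] = psi["G"] * theta / theta_b
            else:
                vals["M2"] = psi["G"] * theta**2 / theta_b
        return model.build_phi(vals)

    return tuple(names), build


def _psi_values(phi: PhiVector, names: tuple[str, ...], s1_variant: bool) -> np.ndarray:
    out = []
    for n in names:
        if n == "T0":
            out.append(phi.T1 + phi.V)
        elif n == "G":
            b_hat = phi.theta_b / phi.theta
            out.append(phi.M2 * b_hat if s1_variant else phi.M2 * b_hat / phi.theta)
        else:
            out.append(getattr(phi, n))
    return np.array(out, dtype=float)


_PSI_TO_CONVERTED = {
    "theta_a": "Na",
    "theta": "N",
    "theta_b": "Nb",
    "theta_c1": "Nc1",
    "theta_c2": "Nc2",
    "T1": "t1",
    "T0": "t0",
    "G": "q1",
}


def delta_method_ci(
    fit_result: FitResult,
    data: Dataset,
    g: float,
    mu_hat: float,
    level: float = 0.95,
    profile: bool = False,
) -> ConvertedEstimates:
    """Intervals for converted estimates via the linear map ``phi_c = W psi``.

    The Hessian is recomputed in the conversion parameterization ``psi``
    (and once more in the ``M2 b`` variant used for ``s1``); the converted
    covariance is ``W Sigma W^T`` with ``W`` diagonal.  With
    ``profile=True``, profile intervals for each psi entry are computed and
    mapped through the same monotone scaling (likelihood-ratio invariance).
    """
    model = fit_result.model
    z = stats.norm.ppf(0.5 * (1.0 + level))
    pt = _converted_point(fit_result.phi_hat, g, mu_hat)
    wald: dict[str, tuple[float, float]] = {}
    prof: dict[str, tuple[float, float]] = {}

    for s1_variant in (False, True):
        names, build = _psi_space(model, s1_variant)
        psi_hat = _psi_values(fit_result.phi_hat, names, s1_variant)

        def ll(vec: np.ndarray) -> float:
            try:
                return loglikelihood(data, build(dict(zip(names, vec))))
            except (ParameterError, NumericalError, LikelihoodError, OverflowError):
                return -1e12

        lower = np.array(
            [0.0 if n in ("T1", "T0", "G") else -np.inf for n in names]
        )
        H = hessian(ll, psi_hat, lower=lower)
        cov = np.linalg.inv(-H)
        se = np.sqrt(np.maximum(np.diag(cov), 0.0))
        for i, n in enumerate(names):
            if s1_variant and n != "G":
                continue
            key = "s1" if s1_variant else _PSI_TO_CONVERTED[n]
            w = _conversion_weight(key, g, mu_hat)
            wald[key] = (w * (psi_hat[i] - z * se[i]), w * (psi_hat[i] + z * se[i]))
            if profile:
                interval = _psi_profile(
                    data, fit_result, names, build, n, psi_hat, level, se[i]
                )
                prof[key] = (w * interval.lo, w * interval.hi)

    return ConvertedEstimates(**pt, wald=wald, profile=prof if profile else None)


def _conversion_weight(key: str, g: float, mu_hat: float) -> float:
    if key.startswith("N"):
        return 1.0 / (4.0 * mu_hat)
    if key in ("t0", "t1"):
        return g / (2.0 * mu_hat)
    if key == "q1":
        return mu_hat
    if key == "s1":
        return 0.5
    raise KeyError(key)


def _psi_profile(data, fit_result, names, build, name, psi_hat, level, se):
    """Profile interval for one entry of the conversion parameterization."""
    vhat = float(psi_hat[list(names).index(name)])

    def build_fixed(vals: Mapping[str, float], v: float) -> PhiVector:
        d = dict(vals)
        d[name] = v
        return build(d)

    kept = tuple(n for n in names if n != name)

    def constrained(v: float, x_warm: np.ndarray) -> tuple[float, np.ndarray]:
        def nll(x: np.ndarray) -> float:
            vals = {}
            for i, n in enumerate(kept):
                vals[n] = math.exp(x[i]) if n not in ("G",) else x[i]
            try:
                return -loglikelihood(data, build_fixed(vals, v))
            except (ParameterError, NumericalError, LikelihoodError, OverflowError):
                return 1e12

        bounds = [(0.0, _M_UB) if n == "G" else (_LOG_LB, _LOG_UB) for n in kept]
        res, _ = _polish(nll, x_warm, bounds, maxiter_nm=400 * max(len(kept), 1))
        return -float(res.fun), res.x

    psi_full = dict(zip(names, psi_hat))
    x0 = np.array(
        [psi_full[n] if n == "G" else math.log(max(psi_full[n], 1e-12)) for n in kept]
    )
    target = fit_result.logL - 0.5 * stats.chi2.ppf(level, 1)
    warm = {"x": x0}
    cache: dict[float, float] = {}

    def prof(v: float) -> float:
        if v not in cache:
            ll, xw = constrained(v, warm["x"])
            warm["x"] = xw
            cache[v] = ll
        return cache[v]

    lower = 0.0 if name in ("T1", "T0", "G") else 1e-10

    def side(direction: int) -> tuple[float, bool]:
        step = max(se, 0.05 * (1.0 + abs(vhat)))
        v_in = vhat
        for _ in range(60):
            v_out = v_in + direction * step
            if direction < 0 and v_out <= lower:
                v_out = lower
            if prof(v_out) - target < 0:
                lo, hi = (v_out, v_in) if direction < 0 else (v_in, v_out)
                root = optimize.brentq(lambda v: prof(v) - target, lo, hi,
                                       xtol=1e-4 * (1 + abs(vhat)), rtol=1e-6)
                return float(root), False
            if direction < 0 and v_out == lower:
                return lower, True
            v_in = v_out
            step *= 1.6
        return v_in, True

    lo, lo_b = side(-1)
    hi, hi_b = side(+1)
    return ProfileInterval(lo, hi, lo_b, hi_b)
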