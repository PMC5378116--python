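"""Coalescent machinery for the isolation-with-initial-migration (IIM) model.

The IIM model describes two extant populations that split from a common
ancestral population ``tau0`` coalescent time units ago, exchanged migrants
until ``tau1`` (the *migration stage*), and have been completely isolated
since (the *isolation stage*, from ``tau1`` to the present).  Time is
measured in units of ``2N`` generations, where ``N`` is the size of
subpopulation 1 during the migration stage; all population sizes are
relative to that reference.

For a pair of haploid sequences the genealogy is a succession of three
continuous-time Markov chains, one per stage.  This module builds their
generator matrices, computes the exponential-mixture representation of the
absorption (coalescence) time of the migration-stage chain, and assembles
the piecewise density / CDF / mean of the pairwise coalescence time
``T(i)`` for each sampling state ``i``:

* state 1 -- both sequences from subpopulation 1,
* state 2 -- both from subpopulation 2,
* state 3 -- one from each.

The internal CTMC state order is ``(1, 3, 2, coalesced)``: keeping the
"split" state between the two "together" states makes the generator as
symmetric as possible.  All public interfaces re-index to sampling states
``(1, 2, 3)``.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass
from typing import Literal

import numpy as np

__all__ = [
    "CoalParams",
    "RateMatrix",
    "Spectrum",
    "ParameterError",
    "NumericalError",
    "build_generator_mig",
    "build_generator_iso",
    "build_generator_anc",
    "migration_spectrum",
    "density_T",
    "cdf_T",
    "survival_T",
    "mean_T",
]

logger = logging.getLogger(__name__)

#: relative threshold below which two decay rates count as degenerate
DEGENERACY_RTOL = 1e-8
#: multiplicative nudge applied to (M1, M2, b) to lift a degenerate spectrum
PERTURB_EPS = 1e-9
#: relative size above which imaginary parts of eigenvalues are an error
IMAG_RTOL = 1e-9


class ParameterError(ValueError):
    """Raised when coalescent parameters are outside their domain."""


class NumericalError(RuntimeError):
    """Raised when the eigen-decomposition is numerically unusable."""


@dataclass(frozen=True)
class CoalParams:
    """Parameters of the IIM coalescent, in coalescent units.

    Attributes
    ----------
    a : relative size of the ancestral population (ancestral / 2N).
    b : relative size of subpopulation 2 during the migration stage.
    c1, c2 : relative sizes of subpopulations 1 and 2 during isolation.
    tau1, tau0 : end of gene flow and population split, in units of 2N
        generations (``0 <= tau1 <= tau0``).
    M1, M2 : scaled migration rates ``Mi = 4N mi``; a single lineage in
        subpopulation ``i`` migrates at rate ``Mi / 2`` in coalescent time.
    """

    a: float
    b: float
    c1: float = 1.0
    c2: float = 1.0
    tau1: float = 0.0
    tau0: float = 0.0
    M1: float = 0.0
    M2: float = 0.0

    def __post_init__(self) -> None:
        for name in ("a", "b", "c1", "c2"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise ParameterError(f"{name} must be finite and > 0, got {v!r}")
        if not (0 <= self.tau1 <= self.tau0):
            raise ParameterError(
                f"need 0 <= tau1 <= tau0, got tau1={self.tau1!r}, tau0={self.tau0!r}"
            )
        if self.M1 < 0 or self.M2 < 0:
            raise ParameterError("migration rates must be >= 0")


@dataclass(frozen=True)
class RateMatrix:
    """A CTMC generator together with its state labels."""

    entries: np.ndarray
    state_order: tuple[str, ...]

    def __post_init__(self) -> None:
        q = np.asarray(self.entries, dtype=float)
        object.__setattr__(self, "entries", q)
        if q.shape[0] != q.shape[1] or q.shape[0] != len(self.state_order):
            raise ValueError("generator must be square and match state_order")


Regime = Literal["bidirectional", "uni_M1_zero", "uni_M2_zero", "none"]


@dataclass(frozen=True)
class Spectrum:
    """Exponential-mixture representation of the migration-stage coalescence time.

    The density of the absorption time from sampling state ``i`` is

        f_mig(i)(t) = sum_j A[i-1, j] * lam[j] * exp(-lam[j] * t)

    and the survival function is ``defect[i-1] + sum_j A[i-1,j] exp(-lam[j] t)``
    where ``defect = 1 - A.sum(axis=1)`` is the probability of never being
    absorbed during the migration stage (nonzero only for state 3 when
    ``M1 = M2 = 0``).  Rows of ``A`` are indexed by sampling state (1, 2, 3).
    """

    regime: Regime
    lam: np.ndarray
    A: np.ndarray

    @property
    def defect(self) -> np.ndarray:
        return 1.0 - self.A.sum(axis=1)

    def survival(self, state: int, u: float) -> float:
        """P(no coalescence within the first ``u`` time units of the stage)."""
        return _spectrum_survival(self, state, u)


def _spectrum_survival(spec: Spectrum, i: int, u: float) -> float:
    row = spec.A[i - 1]
    return float(1.0 - row.sum() + (row * np.exp(-spec.lam * u)).sum())


# ---------------------------------------------------------------------------
# Generator matrices
# ---------------------------------------------------------------------------

def build_generator_mig(params: CoalParams) -> RateMatrix:
    """Generator of the migration-stage chain, state order (1, 3, 2, coalesced).

    From state 1 each of the two lineages migrates at rate ``M1/2`` (total
    ``M1`` to state 3) and the pair coalesces at rate 1; from state 3 the
    lineage in subpopulation 2 moves at ``M2/2`` (to state 1) and the one in
    subpopulation 1 at ``M1/2`` (to state 2); from state 2 migration occurs
    at total rate ``M2`` and coalescence at rate ``1/b``.
    """
    M1, M2, b = params.M1, params.M2, params.b
    q = np.array(
        [
            [-(M1 + 1.0), M1, 0.0, 1.0],
            [M2 / 2.0, -(M1 + M2) / 2.0, M1 / 2.0, 0.0],
            [0.0, M2, -(M2 + 1.0 / b), 1.0 / b],
            [0.0, 0.0, 0.0, 0.0],
        ]
    )
    return RateMatrix(q, ("1", "3", "2", "coalesced"))


def build_generator_iso(params: CoalParams, state: int) -> RateMatrix:
    """Generator of the isolation-stage chain for sampling state 1 or 2.

    This is Kingman's coalescent for two lineages in a population of relative
    size ``c_state``; state 3 admits no coalescence before ``tau1`` and is
    handled by the density assembly, not here.
    """
    if state not in (1, 2):
        raise ParameterError("isolation-stage generator exists only for states 1 and 2")
    rate = 1.0 / (params.c1 if state == 1 else params.c2)
    q = np.array([[-rate, rate], [0.0, 0.0]])
    return RateMatrix(q, (str(state), "coalesced"))


def build_generator_anc(params: CoalParams) -> RateMatrix:
    """Generator of the ancestral-stage chain (Kingman, relative size ``a``)."""
    rate = 1.0 / params.a
    q = np.array([[-rate, rate], [0.0, 0.0]])
    return RateMatrix(q, ("0", "coalesced"))


# ---------------------------------------------------------------------------
# Spectrum of the migration-stage absorption time
# ---------------------------------------------------------------------------

def _closed_form_uni_m1_zero(M2: float, b: float) -> tuple[np.ndarray, np.ndarray]:
    """Mixture for gene flow into subpopulation 2 only (M1 = 0, M2 > 0).

    Obtained by conditioning on the first transition and applying a partial
    fraction decomposition to the moment-generating functions; decay rates
    are ``(1, M2/2, 1/b + M2)``.
    """
    lam = np.array([1.0, M2 / 2.0, 1.0 / b + M2])
    a21 = b * M2**2 / ((M2 - 2.0) * (1.0 - b + b * M2))
    a22 = 4.0 * b * M2 / ((2.0 - M2) * (2.0 + b * M2))
    a23 = 1.0 / (1.0 + b * M2) + b**2 * M2**2 / (
        (2.0 + b * M2) * (1.0 - b + b * M2) * (1.0 / b + M2)
    )
    a31 = M2 / (M2 - 2.0)
    a32 = 2.0 / (2.0 - M2)
    A = np.array([[1.0, 0.0, 0.0], [a21, a22, a23], [a31, a32, 0.0]])
    return lam, A


def _closed_form_uni_m2_zero(M1: float, b: float) -> tuple[np.ndarray, np.ndarray]:
    """Mixture for gene flow into subpopulation 1 only (M1 > 0, M2 = 0).

    Mirror-image system solved by the same MGF / partial-fraction route;
    decay rates are ``(1 + M1, M1/2, 1/b)``.
    """
    r, p, q = 1.0 + M1, M1 / 2.0, 1.0 / b
    lam = np.array([r, p, q])
    a11 = 1.0 / r + M1 * p * q / (r * (p - r) * (q - r))
    a12 = M1 * q / ((r - p) * (q - p))
    a13 = M1 * p / ((r - q) * (p - q))
    a32 = q / (q - p)
    a33 = p / (p - q)
    A = np.array([[a11, a12, a13], [0.0, 0.0, 1.0], [0.0, a32, a33]])
    return lam, A


def _eigen_spectrum(params: CoalParams) -> tuple[np.ndarray, np.ndarray]:
    """Dense eigen-decomposition route for bidirectional gene flow."""
    import scipy.linalg

    q = build_generator_mig(params).entries
    mu, R = scipy.linalg.eig(q)
    scale = max(abs(mu).max(), 1.0)
    if np.abs(mu.imag).max() > IMAG_RTOL * scale:
        raise NumericalError(
            f"complex eigenvalues beyond tolerance for params {params!r}"
        )
    if np.abs(R.imag).max() > IMAG_RTOL * max(np.abs(R.real).max(), 1.0):
        raise NumericalError(
            f"complex eigenvectors beyond tolerance for params {params!r}"
        )
    mu = mu.real
    R = R.real
    Rinv = np.linalg.inv(R)
    # the zero eigenvalue belongs to the absorbing state
    izero = int(np.argmin(np.abs(mu)))
    neg = [k for k in range(4) if k != izero]
    lam = -mu[neg]
    if lam.min() <= 0:
        raise NumericalError("non-positive decay rate in migration spectrum")
    # coefficient of exp(-lam_k t) in the absorption CDF, internal rows (1,3,2)
    coef = np.array([[-R[i, k] * Rinv[k, 3] for k in neg] for i in range(3)])
    # deterministic order: decay rates descending, ties broken by coefficients
    keys = np.round(np.vstack([coef, lam[None, :]]), 10)
    order = np.lexsort(keys)[::-1]
    lam = lam[order]
    coef = coef[:, order]
    A = coef[[0, 2, 1], :]  # internal (1,3,2) -> sampling (1,2,3)
    return lam, A


def _is_degenerate(lam: np.ndarray) -> bool:
    lam = np.sort(np.asarray(lam, dtype=float))
    gaps = np.diff(lam)
    pair_scale = 0.5 * (lam[1:] + lam[:-1])
    return bool((gaps < DEGENERACY_RTOL * pair_scale).any())


def migration_spectrum(params: CoalParams) -> Spectrum:
    """Exponential-mixture spectrum of the migration-stage coalescence time.

    The migration regime is chosen by the signs of ``M1`` and ``M2``:
    closed forms for unidirectional or absent gene flow, a dense
    eigen-decomposition of the 4x4 generator otherwise.  Nearly repeated
    decay rates (a measure-zero set on which the closed forms have vanishing
    denominators) are lifted by a relative perturbation of ``(M1, M2, b)``
    of order 1e-9, under which the likelihood is continuous.
    """
    work = params
    for attempt in range(4):
        M1, M2, b = work.M1, work.M2, work.b
        if M1 == 0.0 and M2 == 0.0:
            # the two Kingman rates never mix (states are decoupled), so a
            # coincidence 1 == 1/b is harmless
            lam = np.array([1.0, 1.0 / b, 1.0 + 1.0 / b])
            A = np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0], [0.0, 0.0, 0.0]])
            return Spectrum("none", lam, A)
        regime: Regime
        if M1 == 0.0:
            lam_probe = np.array([1.0, M2 / 2.0, 1.0 / b + M2])
            regime = "uni_M1_zero"
        elif M2 == 0.0:
            lam_probe = np.array([1.0 + M1, M1 / 2.0, 1.0 / b])
            regime = "uni_M2_zero"
        else:
            lam_probe = None
            regime = "bidirectional"
        if lam_probe is not None and not _is_degenerate(lam_probe):
            lam, A = (
                _closed_form_uni_m1_zero(M2, b)
                if regime == "uni_M1_zero"
                else _closed_form_uni_m2_zero(M1, b)
            )
            return Spectrum(regime, lam, A)
        if lam_probe is None:
            lam, A = _eigen_spectrum(work)
            if not _is_degenerate(lam):
                return Spectrum(regime, lam, A)
        eps = PERTURB_EPS * 10.0**attempt
        logger.warning(
            "near-degenerate migration spectrum for %r; perturbing rates by %g",
            work,
            eps,
        )
        work = dataclasses.replace(
            work,
            M1=work.M1 * (1.0 + eps),
            M2=work.M2 * (1.0 + 2.0 * eps),
            b=work.b * (1.0 + 0.5 * eps),
        )
    raise NumericalError(f"could not lift degenerate spectrum for {params!r}")


# ---------------------------------------------------------------------------
# Piecewise distribution of the pairwise coalescence time T(i)
# ---------------------------------------------------------------------------

def _check_state(state: int) -> None:
    if state not in (1, 2, 3):
        raise ParameterError(f"sampling state must be 1, 2 or 3, got {state!r}")


def _iso_rate(params: CoalParams, state: int) -> float:
    return 1.0 / (params.c1 if state == 1 else params.c2)


def density_T(state: int, t: float, params: CoalParams, spectrum: Spectrum | None = None) -> float:
    """Density of the pairwise coalescence time ``T(state)`` at time ``t``.

    Piecewise: Kingman exponential during isolation (states 1 and 2; zero
    for state 3), the exponential mixture of :func:`migration_spectrum`
    re-based at ``tau1`` during the migration stage, and a rate ``1/a``
    exponential re-based at ``tau0`` in the ancestral population, each piece
    weighted by the probability of reaching it.
    """
    _check_state(state)
    if t < 0:
        raise ParameterError("time must be >= 0")
    spec = spectrum if spectrum is not None else migration_spectrum(params)
    tau1, tau0, a = params.tau1, params.tau0, params.a
    row, lam = spec.A[state - 1], spec.lam
    if state == 3:
        surv_iso = 1.0
    else:
        rate = _iso_rate(params, state)
        if t <= tau1:
            return rate * math.exp(-rate * t)
        surv_iso = math.exp(-rate * tau1)
    if t <= tau1:  # state 3 cannot coalesce during isolation
        return 0.0
    if t <= tau0:
        mix = float((row * lam * np.exp(-lam * (t - tau1))).sum())
        return surv_iso * mix
    surv_mig = _spectrum_survival(spec, state, tau0 - tau1)
    return surv_iso * surv_mig * math.exp(-(t - tau0) / a) / a


def survival_T(state: int, t: float, params: CoalParams, spectrum: Spectrum | None = None) -> float:
    """P(T(state) > t); nonincreasing, equal to 1 at ``t = 0``."""
    _check_state(state)
    if t < 0:
        raise ParameterError("time must be >= 0")
    spec = spectrum if spectrum is not None else migration_spectrum(params)
    tau1, tau0, a = params.tau1, params.tau0, params.a
    if state == 3:
        surv_iso_t = 1.0
        surv_iso = 1.0
    else:
        rate = _iso_rate(params, state)
        if t <= tau1:
            return math.exp(-rate * t)
        surv_iso = math.exp(-rate * tau1)
        surv_iso_t = surv_iso
    if t <= tau1:
        return 1.0
    if t <= tau0:
        return surv_iso_t * _spectrum_survival(spec, state, t - tau1)
    return (
        surv_iso
        * _spectrum_survival(spec, state, tau0 - tau1)
        * math.exp(-(t - tau0) / a)
    )


def cdf_T(state: int, t: float, params: CoalParams, spectrum: Spectrum | None = None) -> float:
    """CDF of the pairwise coalescence time, ``1 - survival_T``."""
    return 1.0 - survival_T(state, t, params, spectrum)


def mean_T(state: int, params: CoalParams, spectrum: Spectrum | None = None) -> float:
    """Expected pairwise coalescence time, by integrating the survival function.

    Always finite: even when no coalescence is possible before ``tau0``
    (state 3 without gene flow), the ancestral stage absorbs with rate
    ``1/a``.
    """
    _check_state(state)
    spec = spectrum if spectrum is not None else migration_spectrum(params)
    tau1, tau0, a = params.tau1, params.tau0, params.a
    delta = tau0 - tau1
    row, lam = spec.A[state - 1], spec.lam
    defect = 1.0 - row.sum()
    if state == 3:
        head = tau1
        surv_iso = 1.0
    else:
        rate = _iso_rate(params, state)
        c = 1.0 / rate
        surv_iso = math.exp(-rate * tau1)
        head = c * (1.0 - surv_iso)
    mig_integral = defect * delta + float((row * (1.0 - np.exp(-lam * delta)) / lam).sum())
    tail = _spectrum_survival(spec, state, delta) * a
    return head + surv_iso * (mig_integral + tail)
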