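"""Closed-form 25-state equilibrium gating model of GIRK2.

The GIRK2 channel is a homotetramer carrying four equivalent G-beta-gamma
(Gbg) binding sites and four intracellular Na+ sites.  Each macrostate is an
occupancy pair (i, j), i Na+ and j Gbg bound, giving 5 x 5 = 25 states.  The
statistical weight of state (i, j) relative to the ligand-free channel is

    w(i, j) = C(4,i) C(4,j) (na/Kdn)^i (m/Kdb)^j
              * n^{-i(i-1)/2} * b^{-j(j-1)/2} * eta^{-ij}

where ``na`` is the Na+ concentration (mM), ``m`` the membrane Gbg
concentration in Ni-NTA-lipid mole-fraction units, ``Kdn`` and ``Kdb`` the
dissociation constants of the first ligand of each kind, ``b`` the pairwise
Gbg-Gbg cooperativity factor, ``n`` the Na+-Na+ factor (fixed at 1 by
default) and ``eta`` the Na+/Gbg cross-cooperativity factor.  Factors below
1 mean positive cooperativity.  Channel activity is the population-weighted
sum of per-state activities theta(i, j), which are zero unless all four Gbg
sites are occupied and rise linearly with Na+ occupancy:

    theta(i, 4) = theta04 + i (theta44 - theta04) / 4.

Weights are evaluated in log space so that fits may explore extreme
parameter values without overflow.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from typing import Callable, NamedTuple, Sequence

import numpy as np

__all__ = [
    "GatingParams",
    "OccupancyState",
    "StateDistribution",
    "REFERENCE_FIT",
    "NONCOOPERATIVE_FIT",
    "enumerate_states",
    "state_weight",
    "log_state_weights",
    "state_distribution",
    "theta_table",
    "activity",
    "eq1_activity",
    "limiting_slope",
    "small_m_threshold",
    "fold_affinity_gbg",
    "fold_affinity_na",
]

N_SITES = 4

_LOG_BINOM = np.log([math.comb(N_SITES, k) for k in range(N_SITES + 1)])


@dataclass(frozen=True)
class GatingParams:
    """The six fitted constants of the 25-state model plus fixed conventions.

    Attributes
    ----------
    kdn : float
        Na+ dissociation constant of the ligand-free channel, mM.
    kdb : float
        Gbg dissociation constant of the ligand-free channel, in
        Ni-NTA-lipid mole-fraction units.
    b : float
        Gbg-Gbg cooperativity factor per occupied-site pair (b < 1 means
        positive cooperativity).
    eta : float
        Na+/Gbg cross-cooperativity factor per occupied Na+-site/Gbg-site
        pair.
    theta04, theta44 : float
        Activity of the (0 Na+, 4 Gbg) and (4 Na+, 4 Gbg) states, in
        normalized-current units.
    n_na : float
        Na+-Na+ cooperativity factor; fixed at 1 under the model's
        assumption that Na+ binding alone is non-cooperative, kept as a
        field so the assumption is explicit and relaxable.
    """

    kdn: float
    kdb: float
    b: float
    eta: float
    theta04: float
    theta44: float
    n_na: float = 1.0

    def __post_init__(self) -> None:
        for name in ("kdn", "kdb", "b", "eta", "n_na"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be strictly positive, got {v!r}")
        if not (self.theta44 >= self.theta04 >= 0):
            raise ValueError(
                "activities must satisfy theta44 >= theta04 >= 0, got "
                f"theta04={self.theta04!r}, theta44={self.theta44!r}"
            )

    def replace(self, **kwargs) -> "GatingParams":
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        return {
            "kdn_mM": self.kdn,
            "kdb_molefrac": self.kdb,
            "b": self.b,
            "eta": self.eta,
            "theta04": self.theta04,
            "theta44": self.theta44,
            "n_na": self.n_na,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GatingParams":
        return cls(
            kdn=float(d["kdn_mM"]),
            kdb=float(d["kdb_molefrac"]),
            b=float(d["b"]),
            eta=float(d["eta"]),
            theta04=float(d["theta04"]),
            theta44=float(d["theta44"]),
            n_na=float(d.get("n_na", 1.0)),
        )


#: Best-fit constants from the global fit of the bilayer titration surface.
REFERENCE_FIT = GatingParams(
    kdn=60.0, kdb=0.019, b=0.30, eta=0.63, theta04=0.49, theta44=1.19
)

#: Constants of the constrained fit with Gbg cooperativity disallowed (b = 1).
NONCOOPERATIVE_FIT = GatingParams(
    kdn=110.0, kdb=0.0016, b=1.0, eta=0.62, theta04=0.49, theta44=1.22
)


class OccupancyState(NamedTuple):
    """Occupancy pair: i Na+ sites and j Gbg sites bound (0-4 each)."""

    i: int
    j: int


def enumerate_states() -> list[OccupancyState]:
    """All 25 occupancy states in i-major, then j, order."""
    return [OccupancyState(i, j) for i in range(N_SITES + 1) for j in range(N_SITES + 1)]


def _check_concentrations(na, m) -> tuple[np.ndarray, np.ndarray]:
    na = np.asarray(na, dtype=float)
    m = np.asarray(m, dtype=float)
    if np.any(na < 0) or np.any(m < 0):
        raise ValueError("ligand concentrations must be non-negative")
    return na, m


def _log_weights_raw(
    kdn: float, kdb: float, b: float, eta: float, n_na: float, na, m
) -> np.ndarray:
    na, m = _check_concentrations(na, m)
    i = np.arange(N_SITES + 1)[:, None]
    j = np.arange(N_SITES + 1)[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        lx = np.log(na / kdn)[..., None, None]
        ly = np.log(m / kdb)[..., None, None]
        # i*log(x) with the 0*log(0) = 0 convention so na=0 / m=0 stay exact
        ti = np.where(i == 0, 0.0, i * lx)
        tj = np.where(j == 0, 0.0, j * ly)
    return (
        _LOG_BINOM[:, None]
        + _LOG_BINOM[None, :]
        + ti
        + tj
        - (i * (i - 1) / 2) * math.log(n_na)
        - (j * (j - 1) / 2) * math.log(b)
        - (i * j) * math.log(eta)
    )


def log_state_weights(params: GatingParams, na, m) -> np.ndarray:
    """Log statistical weights of all 25 states, shape ``(..., 5, 5)``.

    ``na`` and ``m`` broadcast; axis -2 indexes Na+ occupancy i and axis -1
    Gbg occupancy j.  The ligand-free state has log-weight 0.
    """
    return _log_weights_raw(
        params.kdn, params.kdb, params.b, params.eta, params.n_na, na, m
    )


def state_weight(params: GatingParams, na: float, m: float, state: OccupancyState) -> float:
    """Statistical weight of one occupancy state relative to the empty channel."""
    i, j = state
    if not (0 <= i <= N_SITES and 0 <= j <= N_SITES):
        raise ValueError(f"occupancy out of range: {state}")
    lw = log_state_weights(params, na, m)
    return float(np.exp(lw[..., i, j]))


@dataclass(frozen=True)
class StateDistribution:
    """Normalized populations of the 25 states at one condition."""

    populations: np.ndarray  # shape (5, 5), axis 0 = i (Na+), axis 1 = j (Gbg)
    na: float
    m: float

    def __getitem__(self, state: tuple[int, int]) -> float:
        return float(self.populations[state])

    def as_dict(self) -> dict[OccupancyState, float]:
        return {s: float(self.populations[s.i, s.j]) for s in enumerate_states()}


def state_distribution(params: GatingParams, na: float, m: float) -> StateDistribution:
    """Populations c(i, j) = w(i, j) / Z at the given condition."""
    lw = log_state_weights(params, na, m)
    lw = lw - lw.max(axis=(-2, -1), keepdims=True)
    w = np.exp(lw)
    pops = w / w.sum(axis=(-2, -1), keepdims=True)
    return StateDistribution(populations=pops, na=float(na), m=float(m))


def theta_table(params: GatingParams) -> np.ndarray:
    """Per-state activities theta(i, j), shape (5, 5).

    Zero unless all four Gbg sites are occupied; linear in Na+ occupancy
    between theta04 and theta44.
    """
    theta = np.zeros((N_SITES + 1, N_SITES + 1))
    i = np.arange(N_SITES + 1)
    theta[:, N_SITES] = params.theta04 + i * (params.theta44 - params.theta04) / N_SITES
    return theta


def _activity_raw(
    kdn: float, kdb: float, b: float, eta: float,
    theta04: float, theta44: float, na, m, n_na: float = 1.0,
) -> np.ndarray | float:
    """Activity from raw parameter values, without invariant checks.

    Used by fitting code so the optimizer can move smoothly through
    regions (e.g. theta04 > theta44) that :class:`GatingParams` rejects.
    """
    lw = _log_weights_raw(kdn, kdb, b, eta, n_na, na, m)
    lw = lw - lw.max(axis=(-2, -1), keepdims=True)
    w = np.exp(lw)
    pops = w / w.sum(axis=(-2, -1), keepdims=True)
    theta = np.zeros((N_SITES + 1, N_SITES + 1))
    theta[:, N_SITES] = theta04 + np.arange(N_SITES + 1) * (theta44 - theta04) / N_SITES
    a = np.einsum("...ij,ij->...", pops, theta)
    return float(a) if a.ndim == 0 else a


def activity(params: GatingParams, na, m) -> np.ndarray | float:
    """Normalized current predicted by the model; broadcasts over na and m."""
    return _activity_raw(
        params.kdn, params.kdb, params.b, params.eta,
        params.theta04, params.theta44, na, m, params.n_na,
    )


def eq1_activity(kdb: float, b: float, thetas: Sequence[float], m) -> np.ndarray | float:
    """One-ligand (Na+-free) activity polynomial for the 4-site Gbg reaction.

    Evaluates, term by term,

        A = (b^6 Kdb^4 t0 + 4 b^6 Kdb^3 m t1 + 6 b^5 Kdb^2 m^2 t2
             + 4 b^3 Kdb m^3 t3 + m^4 t4)
            / (b^6 Kdb^4 + 4 b^6 Kdb^3 m + 6 b^5 Kdb^2 m^2 + 4 b^3 Kdb m^3 + m^4)

    with ``thetas`` = (t0, ..., t4) the activity at each Gbg occupancy.
    """
    thetas = np.asarray(thetas, dtype=float)
    if thetas.shape != (N_SITES + 1,):
        raise ValueError("thetas must have length 5")
    m = np.asarray(m, dtype=float)
    if np.any(m < 0):
        raise ValueError("m must be non-negative")
    coeffs = np.array(
        [
            b**6 * kdb**4,
            4 * b**6 * kdb**3,
            6 * b**5 * kdb**2,
            4 * b**3 * kdb,
            1.0,
        ]
    )
    powers = m[..., None] ** np.arange(N_SITES + 1)
    terms = coeffs * powers
    a = (terms * thetas).sum(axis=-1) / terms.sum(axis=-1)
    return float(a) if a.ndim == 0 else a


class AsymptoticRegimeWarning(UserWarning):
    """The evaluation point is outside the small-m asymptotic regime."""


def limiting_slope(
    activity_fn: Callable[[float], float],
    m: float,
    rel_step: float = 1e-4,
    regime_limit: float | None = None,
) -> float:
    """Log-log slope d ln A / d ln m of a dose-response function at m.

    Central difference with a relative step in log space.  At vanishing m
    the slope counts the number of ligands required for opening: 4 for a
    channel that opens only with all four Gbg sites occupied.  If
    ``regime_limit`` is given (typically ``small_m_threshold(b) * kdb``)
    and ``m`` exceeds it, a warning signals that the asymptotic slope may
    not yet be reached.
    """
    if m <= 0:
        raise ValueError("m must be positive")
    if regime_limit is not None and m > regime_limit:
        warnings.warn(
            f"m = {m:g} exceeds the asymptotic-regime limit {regime_limit:g}; "
            "the limiting slope may be underestimated",
            AsymptoticRegimeWarning,
            stacklevel=2,
        )
    h = rel_step
    a_hi = activity_fn(m * math.exp(h))
    a_lo = activity_fn(m * math.exp(-h))
    if not (a_hi > 0 and a_lo > 0):
        raise ValueError("activity must be positive on both sides of m")
    return (math.log(a_hi) - math.log(a_lo)) / (2 * h)


def small_m_threshold(b: float) -> float:
    """Mole-fraction multiplier s bounding the limiting-slope regime.

    The slope-4 asymptote of the fully-liganded-only model holds when
    m << s * Kdb with s the smallest of 1/4, sqrt(b/6), 4^(-1/3) b and
    b^(3/2).
    """
    if b <= 0:
        raise ValueError("b must be positive")
    return min(0.25, math.sqrt(b / 6), b / 4 ** (1 / 3), b**1.5)


def fold_affinity_gbg(b: float) -> float:
    """Fold increase in stepwise Gbg affinity, fourth binding vs first (b^-3)."""
    if b <= 0:
        raise ValueError("b must be positive")
    return b**-3


def fold_affinity_na(eta: float) -> float:
    """Fold increase in Gbg affinity when all four Na+ sites are occupied (eta^-4)."""
    if eta <= 0:
        raise ValueError("eta must be positive")
    return eta**-4
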