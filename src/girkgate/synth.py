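"""Synthetic-data generators emulating the bilayer and patch-clamp
measurements, so every fitting stage can be exercised end to end.

Each generator draws replicate measurements around the noise-free model
prediction and reports per-point mean and SEM, the same summary the
experiments provide.  The default noise model is proportional (5% CV) plus
an additive floor of 0.01 normalized-current units, approximating the
visible replicate scatter of bilayer recordings; both pieces are
configurable because only graphical SEMs are available to calibrate them.
All generators are deterministic under their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .amplification import NeuronCurrentSet
from .calibration import DoseResponseCurve
from .model import GatingParams, REFERENCE_FIT, activity
from .surface import TitrationSurface

__all__ = [
    "NoiseModel",
    "SerialBindingSpec",
    "DEFAULT_FRACTIONS",
    "DEFAULT_NA_LEVELS",
    "GUV_DOSES_NM",
    "gen_surface",
    "serial_binding_mole_fraction",
    "gen_solution_titration",
    "gen_guv_intensities",
    "gen_neuron_currents",
]

#: NTA-lipid mole fractions used in the bilayer titrations
#: (3%, 1.5%, 0.75%, 0.38%, 0.19%, 0.1%, 0.01%).
DEFAULT_FRACTIONS = (0.0001, 0.001, 0.0019, 0.0038, 0.0075, 0.015, 0.03)

#: Na+ titration levels, mM.
DEFAULT_NA_LEVELS = (0.0, 4.0, 8.0, 16.0, 32.0)

#: Labeled-protein doses of the GUV binding assay, nM.
GUV_DOSES_NM = (63.0, 125.0, 250.0, 500.0, 1000.0, 2000.0)


@dataclass(frozen=True)
class NoiseModel:
    """Replicate noise: proportional (cv), additive (sigma) or both.

    A draw around a true value mu is
    ``mu * (1 + cv * e1) + floor * e2`` with independent standard normals
    e1, e2.  ``kind`` restricts which terms apply.
    """

    kind: str = "mixed"  # additive | proportional | mixed
    cv: float = 0.05
    floor: float = 0.01
    sigma: float = 0.0

    def __post_init__(self):
        if self.kind not in ("additive", "proportional", "mixed"):
            raise ValueError(f"unknown noise kind {self.kind!r}")
        if self.cv < 0 or self.floor < 0 or self.sigma < 0:
            raise ValueError("noise scales must be non-negative")

    @classmethod
    def none(cls) -> "NoiseModel":
        return cls(kind="additive", cv=0.0, floor=0.0, sigma=0.0)

    def sd(self, mu: np.ndarray) -> np.ndarray:
        """Analytic per-draw standard deviation around a true value."""
        mu = np.asarray(mu, dtype=float)
        prop = (self.cv * mu) ** 2 if self.kind in ("proportional", "mixed") else 0.0
        add = self.floor if self.kind == "mixed" else (self.sigma or self.floor)
        addv = add**2 if self.kind in ("additive", "mixed") else 0.0
        return np.sqrt(prop + addv)

    def draw(self, mu: np.ndarray, size: tuple, rng: np.random.Generator) -> np.ndarray:
        mu = np.broadcast_to(np.asarray(mu, dtype=float), size)
        out = mu.copy()
        if self.kind in ("proportional", "mixed") and self.cv > 0:
            out = out + mu * self.cv * rng.standard_normal(size)
        add = self.floor if self.kind == "mixed" else self.sigma or self.floor
        if self.kind in ("additive", "mixed") and add > 0:
            out = out + add * rng.standard_normal(size)
        return out


def _summarize(draws: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Mean and SEM over the replicate axis (axis 0)."""
    n = draws.shape[0]
    mean = draws.mean(axis=0)
    sem = (
        draws.std(axis=0, ddof=1) / np.sqrt(n)
        if n > 1
        else np.zeros_like(mean)
    )
    return mean, sem


def gen_surface(
    params: GatingParams = REFERENCE_FIT,
    fractions: tuple = DEFAULT_FRACTIONS,
    na_levels: tuple = DEFAULT_NA_LEVELS,
    n_membranes: int = 4,
    noise: NoiseModel | None = None,
    seed: int | None = None,
    analytic_sem: bool = False,
) -> TitrationSurface:
    """Simulated 2-D titration: per-point mean +/- SEM over n_membranes.

    With zero noise the surface equals the model exactly (and SEMs are 0).
    Negative replicate draws are truncated at 0, as measured normalized
    currents are reported non-negative.  ``analytic_sem=True`` reports the
    noise model's exact SEM of the mean instead of the sample estimate
    (used in estimator-calibration studies, where weights must be
    correctly specified).
    """
    noise = noise if noise is not None else NoiseModel()
    rng = np.random.default_rng(seed)
    mf, na, y, sem, nm = [], [], [], [], []
    for f in fractions:
        for level in na_levels:
            mu = activity(params, level, f)
            draws = noise.draw(mu, (n_membranes,), rng)
            draws = np.clip(draws, 0.0, None)
            mean, s = _summarize(draws)
            if analytic_sem:
                s = float(noise.sd(mu)) / np.sqrt(n_membranes)
            mf.append(f)
            na.append(level)
            y.append(float(mean))
            sem.append(float(s))
            nm.append(n_membranes)
    return TitrationSurface(
        nta_mole_fraction=np.array(mf),
        na_mM=np.array(na),
        norm_current=np.array(y),
        sem=np.array(sem),
        n_membranes=np.array(nm),
    )


@dataclass(frozen=True)
class SerialBindingSpec:
    """The two serial equilibria of the anchoring assay.

    A His-tagged soluble Gbg first binds the Ni-NTA lipid from solution
    (dissociation constant ``kd_solution_nM``), then the anchored protein
    gates the channel.  ``nta_per_gbg`` is 3 for the His10 construct and 1
    for His4; the model's mole-fraction axis is calibrated in His10 units
    (3 lipids per protein), so a construct occupying fewer lipids delivers
    proportionally more protein at the same lipid fraction.
    """

    kd_solution_nM: float = 150.0
    nta_per_gbg: int = 3
    nta_fraction: float = 0.0019
    gating: GatingParams = REFERENCE_FIT
    na_mM: float = 32.0

    def __post_init__(self):
        if self.kd_solution_nM <= 0 or self.nta_fraction <= 0 or self.nta_per_gbg <= 0:
            raise ValueError("spec values must be positive")


def serial_binding_mole_fraction(spec: SerialBindingSpec, dose_nM) -> np.ndarray:
    """Effective membrane Gbg level (His10-calibrated NTA mole-fraction
    units) at the given solution dose."""
    dose = np.asarray(dose_nM, dtype=float)
    occupancy = dose / (dose + spec.kd_solution_nM)
    gbg_density = spec.nta_fraction / spec.nta_per_gbg * occupancy
    return 3.0 * gbg_density


def gen_solution_titration(
    spec: SerialBindingSpec,
    doses_nM: tuple = (0.0, 130.0, 250.0, 500.0, 1000.0, 2000.0),
    n_membranes: int = 4,
    noise: NoiseModel | None = None,
    seed: int | None = None,
    analytic_sem: bool = False,
) -> DoseResponseCurve:
    """Simulated GIRK activity vs solution His-tagged Gbg concentration.

    Saturating doses occupy all NTA lipid, so the response plateaus at the
    activity the fixed lipid fraction can support (sub-maximal for low
    fractions), reproducing the shape of the solution titrations.
    """
    noise = noise if noise is not None else NoiseModel()
    rng = np.random.default_rng(seed)
    doses = np.asarray(doses_nM, dtype=float)
    m_eff = serial_binding_mole_fraction(spec, doses)
    mu = np.array([activity(spec.gating, spec.na_mM, m) for m in m_eff])
    draws = noise.draw(mu, (n_membranes, doses.size), rng)
    draws = np.clip(draws, 0.0, None)
    mean, sem = _summarize(draws)
    if analytic_sem:
        sem = noise.sd(mu) / np.sqrt(n_membranes)
    return DoseResponseCurve(
        dose=doses,
        response=mean,
        sem=sem,
        n=np.full(doses.size, n_membranes),
        dose_units="nM",
        response_units="norm_current",
        label=f"sGbg-His{10 if spec.nta_per_gbg == 3 else 4}",
    )


def gen_guv_intensities(
    kd_nM: float = 90.0,
    bmax: float = 1.0,
    doses_nM: tuple = GUV_DOSES_NM,
    n_guvs: int = 6,
    noise: NoiseModel | None = None,
    seed: int | None = None,
    analytic_sem: bool = False,
) -> DoseResponseCurve:
    """Simulated GUV fluorescence vs labeled-protein concentration.

    A 1:1 binding isotherm bmax * d / (kd + d) with per-dose replicate
    scatter over n_guvs vesicles.
    """
    if kd_nM <= 0 or bmax <= 0:
        raise ValueError("kd and bmax must be positive")
    noise = noise if noise is not None else NoiseModel(kind="proportional", cv=0.10)
    rng = np.random.default_rng(seed)
    doses = np.asarray(doses_nM, dtype=float)
    mu = bmax * doses / (kd_nM + doses)
    draws = noise.draw(mu, (n_guvs, doses.size), rng)
    draws = np.clip(draws, 0.0, None)
    mean, sem = _summarize(draws)
    if analytic_sem:
        sem = noise.sd(mu) / np.sqrt(n_guvs)
    return DoseResponseCurve(
        dose=doses,
        response=mean,
        sem=sem,
        n=np.full(doses.size, n_guvs),
        dose_units="nM",
        response_units="intensity",
        label="GUV",
    )


def gen_neuron_currents(
    params: GatingParams = REFERENCE_FIT,
    true_m: float = 0.0028,
    na_pair: tuple[float, float] = (0.0, 32.0),
    n_cells: tuple[int, int] = (10, 11),
    cell_cv: float = 0.2,
    current_scale_pA: float = 200.0,
    measurement_cv: float = 0.1,
    seed: int | None = None,
) -> tuple[NeuronCurrentSet, NeuronCurrentSet]:
    """Simulated per-cell agonist-evoked currents at two internal Na+ levels.

    Cell-to-cell variability is placed on the membrane Gbg level (log-
    normal around ``true_m`` with coefficient of variation ``cell_cv``),
    reflecting variable receptor-released Gbg rather than channel count;
    because the activation curve is steep near physiological ``true_m``,
    this spreads the high-Na+ group more than proportionally.  A common
    current scale and multiplicative measurement noise complete the draw.
    The 27 mM internal solution of the recordings is represented by the
    model's 32 mM curve.
    """
    if true_m <= 0 or current_scale_pA <= 0:
        raise ValueError("true_m and current scale must be positive")
    rng = np.random.default_rng(seed)
    na_low, na_high = na_pair
    sets = []
    for na, n in zip((na_low, na_high), n_cells):
        if cell_cv > 0:
            sigma = np.sqrt(np.log1p(cell_cv**2))
            m_cells = true_m * np.exp(
                rng.standard_normal(n) * sigma - sigma**2 / 2
            )
        else:
            m_cells = np.full(n, true_m)
        act = np.array([activity(params, na, m) for m in m_cells])
        currents = current_scale_pA * act
        if measurement_cv > 0:
            currents = currents * (1 + measurement_cv * rng.standard_normal(n))
        sets.append(NeuronCurrentSet(currents_pA=currents, na_internal_mM=na))
    return sets[0], sets[1]
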