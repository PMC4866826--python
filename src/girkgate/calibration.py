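"""One-dimensional dose-response fits and the two-curve activity-matching
calibration that links solution His-tagged Gbg concentration to membrane
Ni-NTA-lipid occupancy.

Three fit families are used throughout the analysis:

* the Hill equation  ``response = max * d^n / (kd^n + d^n)``;
* its n = 1 special case, the rectangular hyperbola (1:1 binding isotherm);
* the Na+-dependence of the apparent Gbg dissociation constant,
  ``Kd(na) = Kdmax + (Kdmin - Kdmax) * na / (Kd_na + na)``.

All fits are weighted least squares (1/sem^2 when SEMs are present,
uniform otherwise) via lmfit, with standard errors from the Jacobian-based
covariance at the optimum and a small multistart over initializations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import lmfit
import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.optimize import brentq

from .model import GatingParams, REFERENCE_FIT, activity

__all__ = [
    "DoseResponseCurve",
    "HillFit",
    "HyperbolaFit",
    "HillFamilyFit",
    "KdVsNaFit",
    "IsothermMapping",
    "FitError",
    "fit_hill",
    "fit_hill_family",
    "fit_rect_hyperbola",
    "map_activity_to_mole_fraction",
    "estimate_stoichiometry",
    "fit_kd_vs_na",
]


class FitError(RuntimeError):
    """A fit failed to converge or the input is degenerate."""


@dataclass(frozen=True)
class DoseResponseCurve:
    """A 1-D titration: dose, mean response, optional SEM and replicate count.

    ``dose_units`` and ``response_units`` tag the axes (e.g. ``"uM"`` vs
    ``"norm_current"``, or ``"mole_fraction"`` vs ``"intensity"``).
    """

    dose: np.ndarray
    response: np.ndarray
    sem: np.ndarray | None = None
    n: np.ndarray | None = None
    dose_units: str = ""
    response_units: str = ""
    label: str = ""

    def __post_init__(self):
        object.__setattr__(self, "dose", np.asarray(self.dose, dtype=float))
        object.__setattr__(self, "response", np.asarray(self.response, dtype=float))
        if self.sem is not None:
            object.__setattr__(self, "sem", np.asarray(self.sem, dtype=float))
        if self.n is not None:
            object.__setattr__(self, "n", np.asarray(self.n))
        if self.dose.ndim != 1 or self.dose.shape != self.response.shape:
            raise ValueError("dose and response must be 1-D arrays of equal length")
        if np.any(self.dose < 0):
            raise ValueError("doses must be non-negative")
        if np.any(np.diff(self.dose) <= 0):
            raise ValueError("doses must be strictly increasing")
        if self.sem is not None and (
            self.sem.shape != self.dose.shape or np.any(self.sem < 0)
        ):
            raise ValueError("sem must be non-negative and match dose")

    def __len__(self) -> int:
        return self.dose.size

    def weights(self) -> np.ndarray | None:
        """lmfit residual weights: 1/sem when all SEMs are positive, else None."""
        if self.sem is None or np.any(self.sem <= 0):
            return None
        return 1.0 / self.sem


def _se(result: lmfit.minimizer.MinimizerResult | lmfit.model.ModelResult, name: str):
    p = result.params[name]
    return float(p.stderr) if p.stderr is not None else float("nan")


@dataclass(frozen=True)
class HillFit:
    max: float
    kd: float
    n_hill: float
    se_max: float
    se_kd: float
    se_n: float
    residual_norm: float
    fixed_n: bool = False


@dataclass(frozen=True)
class HyperbolaFit:
    max: float
    kd: float
    se_max: float
    se_kd: float
    residual_norm: float


@dataclass(frozen=True)
class HillFamilyFit:
    n_hill: float
    se_n: float
    kd: np.ndarray
    max: np.ndarray
    se_kd: np.ndarray
    se_max: np.ndarray
    residual_norm: float
    #: True when the shared-n fit is substantially worse than independent
    #: per-curve fits, suggesting the curves do not share a Hill coefficient.
    discordant: bool = False


@dataclass(frozen=True)
class KdVsNaFit:
    kdmax: float
    kdmin: float
    kd_na: float
    se_kdmax: float
    se_kdmin: float
    se_kd_na: float
    residual_norm: float
    identifiable: bool = True


def _hill(d, max_, kd, n):
    d = np.asarray(d, dtype=float)
    with np.errstate(invalid="ignore"):
        out = max_ * d**n / (kd**n + d**n)
    return np.where(d == 0, 0.0, out)


def _check_curve(curve: DoseResponseCurve, min_points: int) -> None:
    if len(curve) < min_points:
        raise FitError(f"need at least {min_points} points, got {len(curve)}")
    span = curve.response.max() - curve.response.min()
    scale = max(abs(curve.response).max(), 1e-300)
    if span <= 1e-9 * scale:
        raise FitError("degenerate curve: response is flat")


def fit_hill(curve: DoseResponseCurve, fix_n: float | None = None) -> HillFit:
    """Weighted Hill-equation fit with multistart initializations.

    ``fix_n`` pins the Hill coefficient (fix_n=1 reproduces the rectangular
    hyperbola).  Requires at least 4 points and a non-flat response.
    """
    _check_curve(curve, 4)
    model = lmfit.Model(_hill)
    weights = curve.weights()
    pos_doses = curve.dose[curve.dose > 0]
    kd_inits = np.quantile(pos_doses, [0.25, 0.5, 0.75])
    n_inits = [1.0, 2.0, 4.0]
    best = None
    for kd0, n0 in zip(kd_inits, n_inits):
        params = model.make_params(
            max_=dict(value=float(curve.response.max()), min=1e-12),
            kd=dict(value=float(kd0), min=1e-12),
            n=dict(value=float(fix_n) if fix_n is not None else n0, min=0.05, max=20,
                   vary=fix_n is None),
        )
        try:
            res = model.fit(
                curve.response, params, d=curve.dose, weights=weights,
                scale_covar=weights is None,
            )
        except Exception:
            continue
        if best is None or res.chisqr < best.chisqr:
            best = res
    if best is None or not best.success:
        raise FitError("Hill fit did not converge from any initialization")
    return HillFit(
        max=float(best.params["max_"].value),
        kd=float(best.params["kd"].value),
        n_hill=float(best.params["n"].value),
        se_max=_se(best, "max_"),
        se_kd=_se(best, "kd"),
        se_n=_se(best, "n") if fix_n is None else 0.0,
        residual_norm=float(np.sqrt(best.chisqr)),
        fixed_n=fix_n is not None,
    )


def fit_rect_hyperbola(curve: DoseResponseCurve) -> HyperbolaFit:
    """Fit the 1:1 binding isotherm response = max * d / (kd + d)."""
    _check_curve(curve, 3)
    if np.allclose(curve.response, 0):
        raise FitError("degenerate curve: all responses are zero")
    model = lmfit.Model(lambda d, max_, kd: max_ * d / (kd + d))
    weights = curve.weights()
    best = None
    for kd0 in np.quantile(curve.dose[curve.dose > 0], [0.25, 0.5, 0.75]):
        params = model.make_params(
            max_=dict(value=float(curve.response.max()), min=1e-12),
            kd=dict(value=float(kd0), min=1e-12),
        )
        try:
            res = model.fit(
                curve.response, params, d=curve.dose, weights=weights,
                scale_covar=weights is None,
            )
        except Exception:
            continue
        if best is None or res.chisqr < best.chisqr:
            best = res
    if best is None or not best.success:
        raise FitError("hyperbola fit did not converge")
    return HyperbolaFit(
        max=float(best.params["max_"].value),
        kd=float(best.params["kd"].value),
        se_max=_se(best, "max_"),
        se_kd=_se(best, "kd"),
        residual_norm=float(np.sqrt(best.chisqr)),
    )


def fit_hill_family(
    curves: list[DoseResponseCurve], discordance_factor: float = 2.0
) -> HillFamilyFit:
    """Joint Hill fit of several titrations sharing one Hill coefficient.

    Each curve keeps its own ``kd`` and ``max``; ``n`` is global.  When the
    shared-n residual exceeds ``discordance_factor`` times the summed
    residual of independent per-curve fits, the result is flagged
    ``discordant`` (the curves likely have different true coefficients).
    A single curve reduces to :func:`fit_hill`.
    """
    if len(curves) == 0:
        raise FitError("no curves given")
    if len(curves) == 1:
        f = fit_hill(curves[0])
        return HillFamilyFit(
            n_hill=f.n_hill, se_n=f.se_n,
            kd=np.array([f.kd]), max=np.array([f.max]),
            se_kd=np.array([f.se_kd]), se_max=np.array([f.se_max]),
            residual_norm=f.residual_norm,
        )
    for c in curves:
        _check_curve(c, 4)

    def residuals(params):
        out = []
        n = params["n"].value
        for k, c in enumerate(curves):
            pred = _hill(c.dose, params[f"max_{k}"].value, params[f"kd_{k}"].value, n)
            w = c.weights()
            r = c.response - pred
            out.append(r if w is None else r * w)
        return np.concatenate(out)

    params = lmfit.Parameters()
    params.add("n", value=2.0, min=0.05, max=20)
    for k, c in enumerate(curves):
        params.add(f"max_{k}", value=float(c.response.max()), min=1e-12)
        params.add(f"kd_{k}", value=float(np.median(c.dose[c.dose > 0])), min=1e-12)
    all_weighted = all(c.weights() is not None for c in curves)
    res = lmfit.minimize(residuals, params, scale_covar=not all_weighted)
    if not res.success:
        raise FitError("joint Hill fit did not converge")
    indep_chisqr = 0.0
    for c in curves:
        indep_chisqr += fit_hill(c).residual_norm ** 2
    return HillFamilyFit(
        n_hill=float(res.params["n"].value),
        se_n=_se(res, "n"),
        kd=np.array([res.params[f"kd_{k}"].value for k in range(len(curves))]),
        max=np.array([res.params[f"max_{k}"].value for k in range(len(curves))]),
        se_kd=np.array([_se(res, f"kd_{k}") for k in range(len(curves))]),
        se_max=np.array([_se(res, f"max_{k}") for k in range(len(curves))]),
        residual_norm=float(np.sqrt(res.chisqr)),
        discordant=bool(res.chisqr > discordance_factor * max(indep_chisqr, 1e-300)),
    )


@dataclass(frozen=True)
class IsothermMapping:
    """Solution-concentration to apparent-mole-fraction pairs.

    Produced by matching GIRK activity between a solution titration and a
    membrane (NTA mole-fraction) titration; isolates the binding reaction
    of the His-tagged protein to the Ni-NTA lipid.
    """

    solution_dose: np.ndarray
    apparent_mole_fraction: np.ndarray
    clipped: np.ndarray  # bool: matched activity was above the membrane plateau
    #: response SEMs propagated through the inversion (delta method,
    #: sem / f'(m)); large near the plateau where the inversion is steep
    sem: np.ndarray | None = None
    source: str = ""
    dose_units: str = ""

    def to_curve(self) -> DoseResponseCurve:
        return DoseResponseCurve(
            dose=self.solution_dose,
            response=self.apparent_mole_fraction,
            sem=self.sem,
            dose_units=self.dose_units,
            response_units="mole_fraction",
            label=self.source,
        )


def map_activity_to_mole_fraction(
    solution_curve: DoseResponseCurve,
    nta_curve: DoseResponseCurve,
    method: str = "model",
    params: GatingParams = REFERENCE_FIT,
    na: float = 32.0,
    source: str = "",
) -> IsothermMapping:
    """Map each solution dose to the membrane mole fraction of equal activity.

    The membrane titration (activity vs NTA mole fraction) defines a
    monotone forward curve f(m).  Each solution-titration activity r is
    inverted through f to the apparent mole fraction m with f(m) = r.
    ``method="model"`` uses the 25-state model curve at the given Na+
    concentration (the default, matching how the membrane titration is
    summarized); ``method="pchip"`` uses a monotone interpolant through the
    membrane data instead.  Activities above the membrane plateau are
    clipped to the plateau and flagged rather than extrapolated.
    """
    m_max = float(nta_curve.dose.max())
    if method == "model":
        def f(m):
            return float(activity(params, na, m))
    elif method == "pchip":
        if np.any(np.diff(nta_curve.response) <= 0):
            raise FitError("membrane titration is not monotone; cannot invert")
        dose = nta_curve.dose
        resp = nta_curve.response
        if dose[0] > 0:
            dose = np.concatenate([[0.0], dose])
            resp = np.concatenate([[0.0], resp])
        interp = PchipInterpolator(dose, resp)
        def f(m):
            return float(interp(m))
    else:
        raise ValueError(f"unknown inversion method {method!r}")
    if f(m_max) <= f(m_max * 0.5):
        raise FitError("forward curve is not increasing on the inversion bracket")

    plateau = f(m_max)
    mf = np.empty(len(solution_curve))
    clipped = np.zeros(len(solution_curve), dtype=bool)
    for k, r in enumerate(solution_curve.response):
        if r <= 0:
            mf[k] = 0.0
        elif r >= plateau:
            mf[k] = m_max
            clipped[k] = True
        else:
            mf[k] = brentq(lambda m: f(m) - r, 0.0, m_max, xtol=1e-15, rtol=1e-12)

    sem = None
    if solution_curve.sem is not None and np.any(solution_curve.sem > 0):
        # delta method: sem(m) = sem(response) / f'(m); the forward slope
        # vanishes toward the plateau, correctly deflating confidence in
        # near-saturated points
        sem = np.empty(len(solution_curve))
        for k in range(len(solution_curve)):
            m = max(mf[k], 1e-6 * m_max)
            h = 1e-4 * m
            slope = (f(min(m + h, m_max)) - f(max(m - h, 0.0))) / (
                min(m + h, m_max) - max(m - h, 0.0)
            )
            sem[k] = solution_curve.sem[k] / max(slope, 1e-300)
        # points reported with zero SEM get the tightest propagated SEM so
        # they stay maximally (but finitely) weighted
        pos = sem > 0
        sem[~pos] = sem[pos].min() if np.any(pos) else 1.0
    return IsothermMapping(
        solution_dose=solution_curve.dose.copy(),
        apparent_mole_fraction=mf,
        clipped=clipped,
        sem=sem,
        source=source or solution_curve.label,
        dose_units=solution_curve.dose_units,
    )


@dataclass(frozen=True)
class StoichiometryEstimate:
    ratio: float
    nta_per_gbg: int
    fit_his10: HyperbolaFit
    fit_his4: HyperbolaFit


def estimate_stoichiometry(
    mapping_his10: IsothermMapping, mapping_his4: IsothermMapping
) -> StoichiometryEstimate:
    """Infer how many Ni-NTA lipids anchor one His10-tagged Gbg.

    Both mappings are fit by rectangular hyperbolas; the ratio of their
    apparent-mole-fraction plateaus gives the lipids-per-protein ratio,
    assuming the His4 construct engages a single lipid.
    """
    f10 = fit_rect_hyperbola(mapping_his10.to_curve())
    f4 = fit_rect_hyperbola(mapping_his4.to_curve())
    ratio = f4.max / f10.max
    return StoichiometryEstimate(
        ratio=float(ratio),
        nta_per_gbg=int(round(ratio)),
        fit_his10=f10,
        fit_his4=f4,
    )


def fit_kd_vs_na(kds: list[tuple[float, float, float]]) -> KdVsNaFit:
    """Fit the Na+ dependence of the apparent Gbg dissociation constant.

    ``kds`` is a list of (na_mM, kd, se) triples including na = 0.  The
    model is the rectangular hyperbola
    Kd(na) = Kdmax + (Kdmin - Kdmax) * na / (Kd_na + na).  A flat Kd
    profile makes Kd_na structurally unidentifiable; the result is then
    flagged ``identifiable=False``.
    """
    arr = np.asarray(kds, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 3:
        raise ValueError("kds must be (na, kd, se) triples")
    if arr.shape[0] < 4:
        raise FitError("need at least 4 Na+ levels")
    if not np.any(arr[:, 0] == 0):
        raise FitError("a 0 mM Na+ level is required to anchor Kdmax")
    na, kd, se = arr.T
    span = kd.max() - kd.min()
    if span <= 1e-9 * max(kd.max(), 1e-300):
        return KdVsNaFit(
            kdmax=float(kd.mean()), kdmin=float(kd.mean()), kd_na=float("nan"),
            se_kdmax=float("nan"), se_kdmin=float("nan"), se_kd_na=float("nan"),
            residual_norm=0.0, identifiable=False,
        )

    def model(na, kdmax, kdmin, kd_na):
        return kdmax + (kdmin - kdmax) * na / (kd_na + na)

    lm = lmfit.Model(model)
    weights = 1.0 / se if np.all(se > 0) else None
    params = lm.make_params(
        kdmax=dict(value=float(kd.max()), min=1e-12),
        kdmin=dict(value=float(kd.min()), min=1e-12),
        kd_na=dict(value=float(np.median(na[na > 0])), min=1e-9),
    )
    res = lm.fit(kd, params, na=na, weights=weights, scale_covar=weights is None)
    if not res.success:
        raise FitError("Kd-vs-Na fit did not converge")
    return KdVsNaFit(
        kdmax=float(res.params["kdmax"].value),
        kdmin=float(res.params["kdmin"].value),
        kd_na=float(res.params["kd_na"].value),
        se_kdmax=_se(res, "kdmax"),
        se_kdmin=_se(res, "kdmin"),
        se_kd_na=_se(res, "kd_na"),
        residual_norm=float(np.sqrt(res.chisqr)),
    )
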