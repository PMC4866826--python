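#!/usr/bin/env python
"""Calibrate the His-tag anchoring of soluble Gbg to Ni-NTA lipid.

Fits the His10 and His4 solution titrations (Hill equation), maps each
through channel activity onto the membrane mole-fraction axis, fits the
resulting binding isotherms, and infers the anchoring stoichiometry from
the ratio of their plateaus.  The GUV fluorescence isotherm provides an
independent direct-binding estimate of the His10 affinity.
"""

from pathlib import Path

import numpy as np

from girkgate import io as gio
from girkgate.calibration import (
    estimate_stoichiometry,
    fit_hill,
    fit_rect_hyperbola,
    map_activity_to_mole_fraction,
)
from girkgate.model import REFERENCE_FIT

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    c10 = gio.read_curve(ROOT / "data" / "solution_titration_his10.csv")
    c4 = gio.read_curve(ROOT / "data" / "solution_titration_his4.csv")
    guv = gio.read_curve(ROOT / "data" / "guv_intensities.csv")

    hill10 = fit_hill(c10)
    hill4 = fit_hill(c4)
    print("solution titrations (composite Hill fits):")
    print(f"  His10: Kd = {hill10.kd:.0f} +/- {hill10.se_kd:.0f} nM, "
          f"n = {hill10.n_hill:.2f}, plateau = {hill10.max:.2f}")
    print(f"  His4:  Kd = {hill4.kd:.0f} +/- {hill4.se_kd:.0f} nM, "
          f"n = {hill4.n_hill:.2f}, plateau = {hill4.max:.2f}")

    m10 = map_activity_to_mole_fraction(c10, membrane_reference_curve(), source="His10")
    m4 = map_activity_to_mole_fraction(c4, membrane_reference_curve(), source="His4")
    st = estimate_stoichiometry(m10, m4)
    print("activity-matched binding isotherms (solution conc -> mole fraction):")
    print(f"  His10: Kd = {st.fit_his10.kd/1e3:.2f} uM, "
          f"plateau = {st.fit_his10.max:.4f} mole fraction")
    print(f"  His4:  Kd = {st.fit_his4.kd/1e3:.2f} uM, "
          f"plateau = {st.fit_his4.max:.4f} mole fraction")
    print(f"  plateau ratio = {st.ratio:.2f} -> {st.nta_per_gbg} NTA lipids "
          "per His10-anchored Gbg (His4 binds one)")

    guv_fit = fit_rect_hyperbola(guv)
    print(f"GUV direct-binding isotherm: Kd = {guv_fit.kd:.0f} "
          f"+/- {guv_fit.se_kd:.0f} nM")

    gio.write_report(
        {
            "stage": "calibrate-anchoring",
            "his10_hill": {"kd_nM": hill10.kd, "n": hill10.n_hill, "max": hill10.max},
            "his4_hill": {"kd_nM": hill4.kd, "n": hill4.n_hill, "max": hill4.max},
            "his10_isotherm": {"kd_nM": st.fit_his10.kd, "max_mf": st.fit_his10.max},
            "his4_isotherm": {"kd_nM": st.fit_his4.kd, "max_mf": st.fit_his4.max},
            "plateau_ratio": st.ratio,
            "nta_per_gbg_his10": st.nta_per_gbg,
            "guv_kd_nM": guv_fit.kd,
        },
        ROOT / "calibration.yaml",
    )
    print(f"report -> {ROOT / 'calibration.yaml'}")


def membrane_reference_curve():
    """Membrane titration (activity vs mole fraction) from the reference
    model at 32 mM Na+, the condition of the solution titrations."""
    from girkgate.calibration import DoseResponseCurve
    from girkgate.model import activity
    from girkgate.synth import DEFAULT_FRACTIONS

    fr = np.asarray(DEFAULT_FRACTIONS)
    return DoseResponseCurve(
        dose=fr,
        response=np.array([activity(REFERENCE_FIT, 32.0, f) for f in fr]),
        dose_units="mole_fraction",
        response_units="norm_current",
    )


if __name__ == "__main__":
    main()
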