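#!/usr/bin/env python
"""Estimate the membrane Gbg concentration in stimulated dopamine neurons.

Takes the paired baclofen-evoked current sets recorded at 0 and 27 mM
internal Na+, forms the Na+ amplification as the ratio of group means with
a bootstrap CI, inverts it through the fitted model's amplification curve,
and converts the resulting mole fraction into areal density and
slab-equivalent molarity.  Finishes with the lifetime arithmetic implied
by the weak fourth-subunit affinity.
"""

from pathlib import Path

from girkgate import io as gio
from girkgate.amplification import (
    active_channel_lifetime,
    complex_lifetime,
    estimate_gbg,
    kd_fourth_subunit,
)
from girkgate.model import REFERENCE_FIT

ROOT = Path(__file__).resolve().parent.parent / "results"
SEED = 99


def main() -> None:
    sets = gio.read_neuron_currents(ROOT / "data" / "neuron_currents.csv")
    na_lo, na_hi = sorted(sets)
    low, high = sets[na_lo], sets[na_hi]
    print(f"neuron currents: {low.n_cells} cells at {na_lo:g} mM, "
          f"{high.n_cells} cells at {na_hi:g} mM internal Na+")
    print(f"  group means: {low.mean():.1f} +/- {low.sem():.1f} pA vs "
          f"{high.mean():.1f} +/- {high.sem():.1f} pA")

    est = estimate_gbg(REFERENCE_FIT, low, high, seed=SEED)
    print(f"Na+ amplification = {est.fold:.2f}-fold "
          f"[{est.ci_fold[0]:.2f}, {est.ci_fold[1]:.2f}] (bootstrap 95% CI)")
    print(f"inverted membrane Gbg level = {est.mole_fraction:.4g} mole fraction "
          f"[{est.ci_mole_fraction[0]:.3g}, {est.ci_mole_fraction[1]:.3g}]")
    print(f"  = {est.areal_density_per_um2:.0f} Gbg per um^2 (single leaflet, "
          f"{est.assumptions['area_per_lipid_nm2']} nm^2 per lipid, "
          f"{est.assumptions['nta_per_gbg']} NTA lipids per Gbg)")
    print(f"  = {est.slab_concentration_uM:.0f} uM in a "
          f"{est.assumptions['slab_thickness_A']:.0f} A membrane-adjacent slab")

    kd_mf, kd_uM = kd_fourth_subunit(REFERENCE_FIT)
    kon = 1e7  # /M/s, diffusion-limited
    tau = complex_lifetime(kon, kd_uM * 1e-6)
    tau4 = active_channel_lifetime(kon, kd_uM * 1e-6)
    print(f"fourth-subunit Kd = {kd_mf:.3g} mole fraction = {kd_uM:.0f} uM")
    print(f"  at kon = 1e7 /M/s: single-complex lifetime {tau*1e3:.1f} ms; "
          f"fully liganded channel {tau4*1e3:.2f} ms -> Gbg exchanges many "
          "times during a ~1 s receptor response")

    gio.write_report(
        {
            "stage": "infer-neuronal-gbg",
            "seed": SEED,
            **est.report_dict(),
            "kd_fourth_mole_fraction": kd_mf,
            "kd_fourth_uM": kd_uM,
            "complex_lifetime_ms": tau * 1e3,
            "active_channel_lifetime_ms": tau4 * 1e3,
        },
        ROOT / "gbg_estimate.yaml",
    )
    print(f"report -> {ROOT / 'gbg_estimate.yaml'}")


if __name__ == "__main__":
    main()
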