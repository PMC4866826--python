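#!/usr/bin/env python
"""Generate the synthetic datasets every later stage consumes.

Emulates the study's four measurement types with the reference gating
parameters: the 2-D bilayer titration surface (7 NTA-lipid mole fractions
x 5 Na+ levels, n = 4 membranes per point), the His10/His4 solution
titrations at a fixed 0.0019 lipid fraction, the GUV fluorescence binding
isotherm, and paired neuronal current sets at 0 vs 27 mM internal Na+
(27 mM is represented by the model's 32 mM curve).  A manifest records
every seed and noise setting.
"""

from pathlib import Path

from girkgate import io as gio
from girkgate.amplification import invert_amplification
from girkgate.model import REFERENCE_FIT
from girkgate.synth import (
    NoiseModel,
    SerialBindingSpec,
    gen_guv_intensities,
    gen_neuron_currents,
    gen_solution_titration,
    gen_surface,
)

SEED = 20160413
OUT = Path(__file__).resolve().parent.parent / "results" / "data"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    noise = NoiseModel()  # 5% proportional + 0.01 floor

    surface = gen_surface(REFERENCE_FIT, noise=noise, seed=SEED)
    gio.write_surface(surface, OUT / "titration_surface.csv")

    surface_clean = gen_surface(REFERENCE_FIT, noise=NoiseModel.none(), seed=SEED)
    gio.write_surface(surface_clean, OUT / "titration_surface_noise_free.csv")

    his10 = gen_solution_titration(
        SerialBindingSpec(), noise=noise, seed=SEED + 1
    )
    gio.write_curve(his10, OUT / "solution_titration_his10.csv")

    his4 = gen_solution_titration(
        SerialBindingSpec(kd_solution_nM=5000.0, nta_per_gbg=1),
        doses_nM=(0.0, 250, 1000, 2000, 4000, 8000, 16000),
        noise=noise,
        seed=SEED + 2,
    )
    gio.write_curve(his4, OUT / "solution_titration_his4.csv")

    guv = gen_guv_intensities(kd_nM=90.0, seed=SEED + 3)
    gio.write_curve(guv, OUT / "guv_intensities.csv")

    m8 = invert_amplification(REFERENCE_FIT, 8.0)
    low, high = gen_neuron_currents(
        REFERENCE_FIT, true_m=m8, cell_cv=0.2, measurement_cv=0.1, seed=SEED + 4
    )
    gio.write_neuron_currents([low, high], OUT / "neuron_currents.csv")

    gio.write_report(
        {
            "stage": "simulate",
            "seed": SEED,
            "gating_params": REFERENCE_FIT.to_dict(),
            "noise": {"kind": noise.kind, "cv": noise.cv, "floor": noise.floor},
            "neuron_true_mole_fraction": m8,
            "files": sorted(p.name for p in OUT.glob("*.csv")),
        },
        OUT / "manifest.yaml",
    )
    print(f"wrote {len(list(OUT.glob('*.csv')))} datasets to {OUT}")
    print(f"  surface: {len(surface)} points; neuron true m = {m8:.4g}")


if __name__ == "__main__":
    main()
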