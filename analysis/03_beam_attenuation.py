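"""Absorption efficiency and water-slab primary transmission.

Computes the analytic AE of the 2-cm block under the default 6-MV model,
the monoenergetic AE(E) curve, and the detector-weighted primary
transmission R0 versus water thickness (the antiscatter comparator).
"""
import json
from pathlib import Path

import numpy as np
import pandas as pd

from fiberscint.beam_attenuation import (absorption_efficiency,
                                         absorption_efficiency_curve,
                                         primary_transmission_r0)
from fiberscint.config import default_spectrum, reference_detector

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)


def main():
    det = reference_detector()
    sp = default_spectrum()

    ae = absorption_efficiency(sp, det)
    energies = np.linspace(0.3, 6.0, 58)
    curve = absorption_efficiency_curve(det, energies)
    pd.DataFrame({"energy_mev": energies, "ae": curve}).to_csv(
        OUT / "ae_curve.csv", index=False)

    thick = [0.0, 10.0, 20.0, 30.0]
    r0w = {t: primary_transmission_r0(sp, t, det, True) for t in thick}
    r0p = {t: primary_transmission_r0(sp, t, det, False) for t in thick}

    rep = {"spectrum_mean_mev": sp.mean_energy,
           "absorption_efficiency": ae,
           "r0_weighted_by_water_cm": r0w,
           "r0_fluence_by_water_cm": r0p}
    (OUT / "attenuation.json").write_text(json.dumps(rep, indent=2) + "\n")

    print(f"spectrum mean energy     {sp.mean_energy:.2f} MeV")
    print(f"analytic AE (2 cm block) {100*ae:.1f}%")
    print(f"R0 (30 cm water, detector-weighted) {r0w[30.0]:.3f}")
    print("R0 falls short of the measured ~0.30; see docs/methods.md for "
          "why no 6-MV spectrum with mean <= 2 MeV can reach it.")


if __name__ == "__main__":
    main()
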