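"""Slit-method spatial resolution of the simulated detector.

Simulates the 80-um slit scan along the layer-stacking axis, processes it
through background subtraction, symmetrisation, tail extension and the
Fourier transform, and reports the LSF FWHM and the 50%-modulation
frequency.
"""
import json
from pathlib import Path

import pandas as pd

from fiberscint.config import reference_detector
from fiberscint.mtf import process_scan, simulate_slit_scan

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

HISTORIES_PER_POS = 3000     # quick-look; the acceptance script uses 8000
SEED = 77


def main():
    det = reference_detector()
    slit, noslit = simulate_slit_scan(
        det, n_histories_per_pos=HISTORIES_PER_POS, axis="y", seed=SEED)
    res, sym = process_scan(slit, noslit)

    pd.DataFrame({"position_mm": slit.positions,
                  "slit_reading": slit.slit,
                  "noslit_reading": noslit.noslit}
                 ).to_csv(OUT / "slit_scan_y.csv", index=False)
    pd.DataFrame({"freq_mm^-1": res.frequency, "mtf": res.mtf}
                 ).to_csv(OUT / "mtf_y.csv", index=False)

    rep = {"axis": "y", "histories_per_pos": HISTORIES_PER_POS,
           "seed": SEED, "fwhm_mm": res.fwhm, "f50_mm^-1": res.f50}
    (OUT / "mtf_y.json").write_text(json.dumps(rep, indent=2) + "\n")

    print(f"LSF FWHM  {res.fwhm:.2f} mm   (measured reference ~1.4 mm)")
    print(f"f50       {res.f50:.3f} mm^-1 (measured reference 0.2 mm^-1; "
          "the simulated LSF has thinner tails - see docs/methods.md)")


if __name__ == "__main__":
    main()
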