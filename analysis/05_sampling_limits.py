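"""Cone vs midget-RGC sampling limits across the central visual field.

Tabulates N_c (analytic normal mosaic) and N_mRGC (Drasdo-model density,
ON subfield) from the PRLF to 2.5 degrees, locates the transition
eccentricity where the mRGC limit overtakes the cone limit, and computes
the eccentricity shift implied by a carrier-like acuity of 1.41 arcmin
observed at 0.86 degrees.  Writes results/sampling_limits.csv and .json.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from foveal_limits import limits, mosaic
from foveal_limits.synthgen import MosaicSpec


def main() -> None:
    spec = MosaicSpec(peak_icd=0.58, icd_slope=0.35)
    nc_fn = lambda e: float(mosaic.icd_to_nc(spec.spacing(e)))
    eccs = np.linspace(0.0, 2.5, 26)
    df = pd.DataFrame({
        "ecc_deg": eccs,
        "nc_arcmin": [nc_fn(e) for e in eccs],
        "nmrgc_arcmin": [limits.nmrgc(e) for e in eccs],
    })
    df["predicted_mar"] = df[["nc_arcmin", "nmrgc_arcmin"]].max(axis=1)
    Path("results").mkdir(exist_ok=True)
    df.to_csv("results/sampling_limits.csv", index=False)

    e_cross = limits.transition_eccentricity(nc_fn)
    e_star = limits.eccentricity_shift(1.41, observed_ecc=0.0)
    shift = limits.eccentricity_shift(1.41, observed_ecc=0.86)
    print(df.iloc[::5].to_string(index=False))
    print(f"\ncone-limited zone ends at {e_cross:.2f} deg (private-line edge)")
    print(f"a 1.41-arcmin neural limit sits at {e_star:.2f} deg in a normal "
          f"retina; observed at 0.86 deg it implies a {shift:.2f} deg "
          "eccentricity shift of the carrier retina")

    Path("results/sampling_limits.json").write_text(json.dumps({
        "transition_ecc_deg": e_cross,
        "ecc_of_1p41_arcmin_deg": e_star,
        "shift_vs_0p86_deg": shift,
    }, indent=1))


if __name__ == "__main__":
    main()
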