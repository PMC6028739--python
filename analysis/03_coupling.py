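"""Gap-junction coupling: length-constant recovery from dye-spread records.

Coupled-soma intensity vs 3D distance decays exponentially; the length
constant C_lambda comes from the slope of the semilog linear fit.  Both the
control-like (33 um) and epileptic-like (26 um) settings are generated
noiselessly (exact recovery) and with 10 % lognormal intensity noise.
"""

import argparse
from pathlib import Path

import pandas as pd

from astroquant import coupling, synthetic


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", default="results")
    args = ap.parse_args()

    rows = []
    for lam in (33.0, 26.0):
        for noise in (0.0, 0.1):
            cs = synthetic.gen_coupling_set(lam, 50, noise, seed=args.seed)
            fit = coupling.fit_coupling(cs.records)
            rows.append({"planted_c_lambda_um": lam, "noise_sd": noise,
                         "fitted_c_lambda_um": fit.c_lambda, "I0": fit.I0,
                         "r2": fit.r2, "n_cells": fit.n_cells})
            print(f"planted {lam:.0f} um, noise {noise:.0%} -> "
                  f"C_lambda {fit.c_lambda:.2f} um (r2 {fit.r2:.3f})")
    out = Path(args.out)
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows).to_csv(out / "coupling_fits.csv", index=False)


if __name__ == "__main__":
    main()
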