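"""Calibrate the entropy-complexity plane on generated textures.

Ordered stripes, a branching silhouette and white noise are mapped through
the shearlet feature density; their mean normalized entropy H_s and
statistical complexity C verify the expected ordering — entropy grows
monotonically from ordered to random, while complexity peaks for the
structured-but-random branching texture.
"""

import argparse
from pathlib import Path

import pandas as pd

from astroquant import shearlet, synthetic
from astroquant.entropy_complexity import map_entropy_complexity


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--n-seeds", type=int, default=10)
    ap.add_argument("--out", default="results")
    args = ap.parse_args()

    system = shearlet.build_system((256, 256), 3)
    rows = []
    for s in range(args.seed, args.seed + args.n_seeds):
        for kind in ("periodic", "branching", "noise"):
            ec = map_entropy_complexity(synthetic.gen_pattern(kind, 256, s), system)
            rows.append({"seed": s, "texture": kind, "mean_Hs": ec.mean_entropy,
                         "mean_C": ec.mean_complexity})
    df = pd.DataFrame(rows)
    out = Path(args.out)
    out.mkdir(parents=True, exist_ok=True)
    df.to_csv(out / "texture_entropy_complexity.csv", index=False)

    means = df.groupby("texture")[["mean_Hs", "mean_C"]].mean()
    print(means.round(3))
    ordered = (
        means.loc["periodic", "mean_Hs"]
        < means.loc["branching", "mean_Hs"]
        < means.loc["noise", "mean_Hs"]
    )
    peak = means.loc["branching", "mean_C"] == means["mean_C"].max()
    print(f"\nentropy ordering periodic < branching < noise: {ordered}")
    print(f"complexity peaks at the branching texture: {peak}")


if __name__ == "__main__":
    main()
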