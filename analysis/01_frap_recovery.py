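#!/usr/bin/env python
"""Simulate pole-bleach FRAP acquisitions and recover the planted D.

Generates seeded synthetic line-profile stacks across the full range of
diffusion coefficients seen for cytoplasmic proteins (0.05-15 um^2/s),
adds 2% read noise, fits each stack with the 1D reflecting-boundary
diffusion model, and tabulates the recovery error.

Writes results/frap_recovery.csv and prints the median relative error.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from cytodiff.frap import fit_frap
from cytodiff.synth import (
    FrapSynthesisConfig,
    acquisition_for,
    generate_frap_stack,
)


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--n", type=int, default=20,
                        help="number of stacks across the D range")
    parser.add_argument("--out", type=Path,
                        default=Path("results/frap_recovery.csv"))
    args = parser.parse_args()

    seeds = np.random.SeedSequence(args.seed).generate_state(args.n)
    rows = []
    for d, s in zip(np.geomspace(0.05, 15.0, args.n), seeds):
        acq = acquisition_for(float(d))
        cfg = FrapSynthesisConfig(d_true=float(d), noise_sd=0.02,
                                  seed=int(s) % (2**31), **acq)
        res = fit_frap(generate_frap_stack(cfg))
        rows.append({
            "d_true": d, "d_fit": res.D,
            "rel_err": res.D / d - 1.0,
            "identifiable": res.identifiable,
            "frame_interval_s": acq["frame_interval"],
            "n_frames": acq["n_frames"],
            "n_pixels": acq["n_pixels"],
        })
    df = pd.DataFrame(rows)
    args.out.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(args.out, index=False)

    med = np.median(np.abs(df["rel_err"]))
    print(f"{args.n} synthetic stacks, D in [0.05, 15] um^2/s, 2% noise")
    print(f"median |relative error| of fitted D: {100 * med:.2f}%")
    print(f"worst case: {100 * np.abs(df['rel_err']).max():.2f}%")
    print(f"table written to {args.out}")


if __name__ == "__main__":
    main()
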