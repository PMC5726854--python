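#!/usr/bin/env python
"""Bound fractions and dissociation constants of the +25 probe.

Starting from the measured effective diffusion coefficients of the most
positive probe in three organisms of increasing cytoplasmic ionic
strength (0.2, 0.8, 2.1 M), inverts the two-state fast-exchange relation
for the bound fraction and converts it to a dissociation constant against
the geometric ribosome binding-site pool.

Writes results/bound_fractions.csv and results/site_census.csv.
"""

import argparse
from pathlib import Path

import pandas as pd

from cytodiff.binding import (
    estimate_sites,
    free_fraction,
    kd_from_bound_fraction,
)

# (organism label, ionic strength M, D_eff of +25 probe, D_free, D_bound),
# all diffusion coefficients in um^2/s; D_free is the fastest variant
# measured in that organism, D_bound the ribosome value
MEASUREMENTS = [
    ("low_salt_0.2M", 0.2, 0.14, 10.0, 0.04),
    ("mid_salt_0.8M", 0.8, 0.61, 6.2, 0.04),
    ("high_salt_2.1M", 2.1, 1.9, 10.0, 0.04),
]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--outdir", type=Path, default=Path("results"))
    args = parser.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    geo = estimate_sites(20.0, 0.5, 3.5, 10.0)
    pd.DataFrame([geo.__dict__]).to_csv(args.outdir / "site_census.csv",
                                        index=False)
    print(f"ribosome surface {geo.sphere_area:g} nm^2, RNA fraction "
          f"{geo.rna_surface_fraction:g} -> {geo.n_sites} sites/ribosome, "
          f"site pool {geo.site_conc:g} uM")

    rows = []
    for name, ionic, deff, dfree, dbound in MEASUREMENTS:
        f_free = free_fraction(deff, dfree, dbound)
        f_bound = 1.0 - f_free
        kd = kd_from_bound_fraction(f_bound, geo.site_conc)
        rows.append({
            "organism": name, "ionic_strength_M": ionic,
            "deff_um2_s": deff, "d_free_um2_s": dfree,
            "f_bound": f_bound, "kd_uM": kd,
        })
        print(f"{name}: D_eff {deff} -> bound fraction {f_bound:.2f}, "
              f"Kd {kd:.1f} uM")
    df = pd.DataFrame(rows)
    df.to_csv(args.outdir / "bound_fractions.csv", index=False)
    print(f"tables written to {args.outdir}/")
    print("even at 2.1 M ionic strength the +25 probe stays "
          f"{rows[-1]['f_bound']:.0%} ribosome-bound")


if __name__ == "__main__":
    main()
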