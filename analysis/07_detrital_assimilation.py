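"""Cumulative detrital carbon assimilation on the way to the sink.

Couples each species' shrinking detrital pool with its fitted gross
production trend and the light field along a sinking trajectory; the
warm species' failing photosynthesis caps its assimilation while the
cold-temperate species keep fixing carbon throughout the 50-day
journey.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from kelpcsp.assimilation import (
    DetritalTrajectory,
    LightEnvironment,
    cumulative_assimilation,
)
from kelpcsp.pipeline import build_budgets

parser = argparse.ArgumentParser()
parser.add_argument("--data", type=Path, default=Path("results/data"))
parser.add_argument("--out", type=Path, default=Path("results"))
parser.add_argument("--sink-depth", type=float, default=30.0)
parser.add_argument("--sink-distance", type=float, default=4000.0)
args = parser.parse_args()

budgets = build_budgets(
    pd.read_csv(args.data / "density.csv"),
    pd.read_csv(args.out / "export_estimates.csv"),
    pd.read_csv(args.out / "decomposition.csv"),
)
trends = pd.read_csv(args.out / "gpp_trends.csv").set_index("species")

env = LightEnvironment()
traj = DetritalTrajectory(args.sink_depth, args.sink_distance)
rows = []
for sp, b in budgets.items():
    tr = trends.loc[sp.value]
    ca = cumulative_assimilation(
        b, env, traj, tr["gpp_intercept"], tr["gpp_slope"], t=int(traj.travel_time)
    )
    rows.append(
        pd.DataFrame(
            {"species": sp.value, "age_d": np.arange(1, len(ca) + 1), "CA_cum_gC_m2": ca}
        )
    )
    extra = 100 * ca[-1] / (b.n_density * b.ce)
    print(
        f"{sp.value}: {ca[-1]:.0f} g C m^-2 assimilated over 50 days "
        f"(+{extra:.0f}% of annual areal export)"
    )
pd.concat(rows, ignore_index=True).to_csv(args.out / "assimilation.csv", index=False)
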