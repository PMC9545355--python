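"""Litterbag decomposition rates, grazing scars and biochemistry trends.

Pools both litterbag experiments into species mean decomposition rates,
summarises grazing-scar proportions, and fits detrital-age trends
(linear phenolic increase in L. hyperborea, common exponential C:N
decline) plus the decomposition~phenolics slope.
"""

import argparse
from pathlib import Path

import pandas as pd

from kelpcsp import decomposition as dec
from kelpcsp.pipeline import stage_biochem, stage_decompose

parser = argparse.ArgumentParser()
parser.add_argument("--data", type=Path, default=Path("results/data"))
parser.add_argument("--out", type=Path, default=Path("results"))
args = parser.parse_args()

bags = pd.read_csv(args.data / "litterbags.csv")
decomp = stage_decompose(bags)
decomp.to_csv(args.out / "decomposition.csv", index=False)
d = decomp.set_index("species")["mean_D_day"]
print((d * 100).round(2).rename("D % per day"))
print(
    f"decomposition is {100 * (d['ochroleuca'] / d['digitata'] - 1):.0f}% and "
    f"{100 * (d['ochroleuca'] / d['hyperborea'] - 1):.0f}% faster in the warm "
    "species than in L. digitata and L. hyperborea"
)

scars = pd.read_csv(args.data / "scars.csv")
ep = scars.apply(
    lambda r: dec.grazing_proportions(r.A_E_cm2, r.A_P_cm2, r.A_T_cm2), axis=1
)
scars[["E", "P"]] = pd.DataFrame(ep.tolist(), index=scars.index)
scars.groupby("species")[["E", "P"]].mean().to_csv(args.out / "grazing.csv")

bio = pd.read_csv(args.data / "biochem.csv")
trends = stage_biochem(bio)
trends.to_csv(args.out / "biochem_trends.csv", index=False)
print(trends.round(4).to_string(index=False))

# does biochemistry predict decomposition across species?
merged = decomp.merge(bio.groupby("species", as_index=False).mean(numeric_only=True))
fit = dec.decomposition_vs_biochem(merged["mean_D_day"] * 100, merged["phenolic_pct"])
print(f"decomposition ~ phenolics slope: {fit.slope:.2f} % day^-1 per %")
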