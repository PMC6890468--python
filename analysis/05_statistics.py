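"""Treatment comparisons and uncertainty screening on the derived rates.

Runs the nonparametric battery (Shapiro-Wilk per group, Kruskal-Wallis
omnibus, pairwise rank-sum with FDR correction and letter display) on the
cell-specific demands and POP rates, and checks that instrument-propagated
uncertainty is small next to between-replicate spread.  Writes
results/stats/.
"""

import argparse
from pathlib import Path

import pandas as pd

from reefbudget import stats as st
from reefbudget.uncertainty import INSTRUMENT_SD, Measured, propagate


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--rates", type=Path, default=Path("results/rates"))
    ap.add_argument("--out", type=Path, default=Path("results/stats"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    demands = pd.read_csv(args.rates / "demands.csv")
    pop_rates = pd.read_csv(args.rates / "pop_rates.csv")

    blocks = []
    for title, df, col in [
        ("cell-specific DOC demand", demands, "DOC_demand"),
        ("cell-specific O2 demand", demands, "O2_demand"),
        ("net dissolved O2 production", pop_rates, "net_dissolved_rate"),
        ("gas fraction", pop_rates, "gas_frac"),
    ]:
        rep = st.compare_treatments(df, col)
        blocks.append(f"== {title} ==\n{rep.to_text()}")
        print(f"{title}: p={rep.p_value:.3g}, letters "
              + " ".join(f"{g}:{l}" for g, l in rep.letters.items()))
        rep.pairwise.to_csv(args.out / f"pairwise_{col}.csv", index=False)
    (args.out / "test_reports.txt").write_text("\n\n".join(blocks) + "\n")

    # instrument-vs-replicate screening for the macroalgae net rate
    macro = pop_rates[pop_rates["treatment"] == "macroalgae"]
    rate = macro["net_dissolved_rate"]
    instr = propagate(
        lambda o2s, o2e, v, a, d: (o2e - o2s) * v / (a * d),
        [
            Measured(macro["O2_diss_start"].mean(), INSTRUMENT_SD["o2_umol_per_l"]),
            Measured(macro["O2_diss_end"].mean(), INSTRUMENT_SD["o2_umol_per_l"]),
            Measured(macro["chamber_volume"].iloc[0], INSTRUMENT_SD["volume_l"]),
            Measured(macro["surface_area"].mean(),
                     INSTRUMENT_SD["area_rel"] * macro["surface_area"].mean()),
            Measured(macro["duration_days"].iloc[0], INSTRUMENT_SD["time_days"]),
        ],
    )
    print(f"\nmacroalgae net rate: replicate SD {rate.std(ddof=1):.2f} vs "
          f"instrument-propagated SD {instr.sd:.2f} µmol/cm²/d "
          f"(ratio {rate.std(ddof=1) / instr.sd:.1f}x) - measurement error is "
          "negligible next to biological spread, so statistics use replicate "
          "variation only")


if __name__ == "__main__":
    main()
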