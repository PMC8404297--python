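"""Posterior summaries for the selected model.

Reads nothing from disk: re-runs the pipeline deterministically for the
given seed, then prints the smoothed SIR range per disease (with the
percent-deviation presentation), the between-disease correlation summary
and the spatial dependence parameter.  Maps and CSV outputs are written by
the pipeline under results/run/.
"""

import sys

from comap.pipeline import RunConfig, run
from comap.results import percent_deviation


def main(seed: int = 0) -> None:
    manifest = run(RunConfig(seed=seed, outdir="results/run"))
    surface = manifest["_surface"]
    corr = manifest["_correlations"]

    print(f"selected model: {manifest['selected_model']}\n")
    print("smoothed SIR range per disease:")
    for disease, sub in surface.table.groupby("disease"):
        lo, hi = sub["sir_median"].min(), sub["sir_median"].max()
        print(f"  {disease}: {lo:.2f} to {hi:.2f} "
              f"({percent_deviation(lo):+d}% to {percent_deviation(hi):+d}% "
              "versus the national level)")
    print("\nbetween-disease correlations (posterior median [95% CI]):")
    for row in corr.table.itertuples(index=False):
        print(f"  {row.pair}: {row.median:.2f} [{row.ci_low:.2f}, {row.ci_high:.2f}]")
    print("\nspatial dependence:")
    for row in corr.rho.itertuples(index=False):
        print(f"  {row.parameter}: {row.median:.2f} "
              f"[{row.ci_low:.2f}, {row.ci_high:.2f}]")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 0)
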