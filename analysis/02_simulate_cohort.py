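"""Simulate the synthetic individual-level cohort and write it to CSV.

Generates persons (demographics, vital dates, diagnosis dates) and yearly
area/income assignments for the default configuration, under
results/cohort/.  Pass a different seed as the first argument to vary the
replicate.
"""

import sys
from pathlib import Path

from comap.synthetic import CohortConfig, lattice_map, simulate_cohort

OUT = Path("results/cohort")


def main(seed: int = 0) -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    graph = lattice_map()
    cohort = simulate_cohort(
        CohortConfig(n_persons=10_000, n_areas=graph.n_areas),
        seed=seed,
        area_ids=graph.area_ids,
    )
    cohort.write_csv(OUT / "persons.csv", OUT / "person_years.csv")
    print(f"persons: {len(cohort.persons)}")
    for disease in ("AMI", "stroke", "AF"):
        n = cohort.persons[f"dx_{disease}"].notna().sum()
        print(f"diagnoses ({disease}): {n}")
    print(f"wrote {OUT / 'persons.csv'} and {OUT / 'person_years.csv'}")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 0)
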