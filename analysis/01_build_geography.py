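"""Build the 98-area study geography and write its adjacency structure.

Constructs the synthetic 7x14 rook lattice with detached island areas linked
to the mainland by their ferry connections, then writes the edge list plus
sidecar metadata under results/geography/.
"""

from pathlib import Path

import pandas as pd

from comap.geography import neighbour_counts, write_adjacency
from comap.synthetic import lattice_map

OUT = Path("results/geography")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    graph = lattice_map()
    write_adjacency(graph, OUT / "edges.csv", OUT / "adjacency.json")
    counts = pd.DataFrame(
        {"area": graph.area_ids, "n_neighbours": neighbour_counts(graph)}
    )
    counts.to_csv(OUT / "neighbour_counts.csv", index=False)
    print(f"areas: {graph.n_areas}")
    print(f"edges: {int(graph.W.sum()) // 2}")
    print(f"island links: {len(graph.island_links)}")
    print("neighbour count distribution:")
    print(counts["n_neighbours"].value_counts().sort_index().to_string())


if __name__ == "__main__":
    main()
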