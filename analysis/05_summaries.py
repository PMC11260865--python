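#!/usr/bin/env python
"""Build the figure-backing summary structures from the pipeline run.

Reads the stage outputs under results/pipeline/ and reports the
indication co-occurrence matrix, the action-type dendrogram leaf counts
for high-priority drugs (including the inhibitor share), and the
drugged-target trait partition.
"""

import json
from pathlib import Path

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    outdir = RESULTS / "pipeline"
    if not outdir.exists():
        raise SystemExit("run analysis/03_run_pipeline.py first")

    adjacency = json.loads((outdir / "indication_adjacency.json").read_text())
    n = len(adjacency["categories"])
    print(f"indication adjacency: {n}x{n} over specialties {adjacency['categories']}")

    leaf_counts = json.loads((outdir / "action_leaf_counts.json").read_text())
    total = sum(leaf_counts.values())
    if total:
        inhibitors = leaf_counts.get("inhibitor", 0)
        print(f"high-priority drug-action leaves: {total}; "
              f"inhibitors {inhibitors} ({100 * inhibitors / total:.0f}%)")
    else:
        print("no high-priority drug-action leaves in this world")

    partition = json.loads((outdir / "trait_partition.json").read_text())
    print(f"drugged-target trait partition: {partition} "
          f"(sum {sum(partition.values())})")


if __name__ == "__main__":
    main()
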