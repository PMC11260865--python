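#!/usr/bin/env python
"""Generate the synthetic study world used by the downstream drivers.

Writes a seeded bundle — registry, tractability, variant-to-gene table,
per-study gene reports, drugs with planted salt duplicates, mechanisms,
indications, evidence items — plus its ground-truth ledger to
results/bundle/.
"""

import json
from pathlib import Path

from afdrugprior.synth import GeneratorConfig, generate_world

RESULTS = Path(__file__).resolve().parent.parent / "results"
SEED = 1


def main() -> None:
    config = GeneratorConfig(seed=SEED)
    bundle = generate_world(config)
    outdir = RESULTS / "bundle"
    bundle.write(outdir)
    print(f"seed {SEED}: {len(bundle.registry)} genes, {len(bundle.reports)} study reports, "
          f"{len(bundle.drugs)} drug forms over {len(bundle.truth.parent_partition)} parents, "
          f"{len(bundle.truth.priority_genes)} planted priority genes")
    print(f"bundle written to {outdir} (ground truth in ledger.json)")


if __name__ == "__main__":
    main()
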