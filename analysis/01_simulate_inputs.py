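#!/usr/bin/env python
"""Generate every input of the downstream analyses with known truth.

Writes, under results/inputs/: the reference cross-species ortholog
collection (18 element sets, 45-mammal panel) as one multi-FASTA, a
two-genome interval pair with three planted conserved blocks, and the
planted truth as JSON.
"""

import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from ecrfoot.io import write_fasta, write_ortholog_fasta
from ecrfoot.synthetic import (SimulationConfig, generate_genome_pair,
                               reference_ortholog_collection)

SEED = 2016
OUT = Path(__file__).resolve().parents[1] / "results" / "inputs"


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    collection, truth_col = reference_ortholog_collection(seed=SEED)
    write_ortholog_fasta(collection, OUT / "ecr_orthologs.fa",
                         header_comment=f"reference collection seed={SEED}")
    n_seq = sum(len(v) for v in collection.values())
    print(f"wrote {len(collection)} element ortholog sets, {n_seq} sequences "
          f"-> {OUT / 'ecr_orthologs.fa'}")

    cfg = SimulationConfig(seed=SEED, n_elements=3, element_identity=0.85)
    genomeA, genomeB, truth = generate_genome_pair(cfg)
    write_fasta({"genomeA": genomeA, "genomeB": genomeB}, OUT / "genome_pair.fa")
    (OUT / "genome_pair_truth.json").write_text(
        json.dumps(truth.to_json_dict(), indent=2))
    print(f"wrote genome pair ({len(genomeA)} bp each) with "
          f"{len(truth.elements_ref)} planted 0.85-identity blocks")


if __name__ == "__main__":
    main()
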