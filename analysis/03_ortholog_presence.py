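#!/usr/bin/env python
"""Cross-species presence survey of the element probes.

Uses each element's mouse sequence as the probe in a seed-and-extend
search against every species' ortholog and summarises the results as
the species x element presence matrix of best hit scores.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from ecrfoot.conservation import build_presence_matrix, ortholog_search
from ecrfoot.io import read_ortholog_fasta
from ecrfoot.synthetic import MAMMAL_PANEL

ROOT = Path(__file__).resolve().parents[1] / "results"


def main():
    collection = read_ortholog_fasta(ROOT / "inputs" / "ecr_orthologs.fa")
    hits = []
    for element, seqs in collection.items():
        probe = seqs["mouse"]
        for species, target in seqs.items():
            hits.extend(ortholog_search(probe, target, probe_id=element,
                                        species=species))
    matrix = build_presence_matrix(
        hits, species=list(MAMMAL_PANEL),
        probes=[f"ECR{i}" for i in range(1, 19)])
    matrix.to_csv(ROOT / "presence_matrix.tsv", sep="\t")
    counts = matrix.attrs["species_count"]
    print(f"presence matrix: {matrix.shape[0]} species x {matrix.shape[1]} probes")
    print(f"mean species per element: {matrix.attrs['mean_species_count']:.1f}")
    best = sorted(counts, key=counts.get, reverse=True)[:5]
    print("most widely detected elements:", ", ".join(f"{e} ({counts[e]})" for e in best))


if __name__ == "__main__":
    main()
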