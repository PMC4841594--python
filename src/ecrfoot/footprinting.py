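"""Phylogenetic footprinting and cis-regulatory motif enrichment.

Given the set of orthologous sequences of one conserved element from
many species, the workflow is:

1. ``align_ortholog_set`` — align every ortholog pairwise to a chosen
   reference species and merge the pairwise alignments on reference
   coordinates into one block (reference-anchored, not progressive).
2. ``find_invariant_regions`` — report maximal runs of alignment
   columns in which every species carries the same non-gap base
   (phylogenetic footprints, candidate factor-binding sites).
3. ``scan_motifs`` / ``motif_frequency_matrix`` — count occurrences of
   an IUPAC motif library in each species' sequence and summarise, per
   (element, motif), the total count, the number of species with at
   least one copy, and the per-species ratio; a motif is flagged
   enriched when total hits / species-with-sequence strictly exceeds
   0.5.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .conservation import ConservationParams, pairwise_align
from .seqs import iter_iupac_matches, reverse_complement, validate_iupac, validate_sequence

ENRICHMENT_RATIO_THRESHOLD = 0.5  # strict: ratio must exceed this


@dataclass(frozen=True)
class Motif:
    """A named IUPAC motif, optionally with an explicit reverse-
    complement spelling (e.g. PITX2 GGGATTA/TAATCCC)."""

    name: str
    pattern: str
    revcomp_pattern: str = ""
    scan_both_strands: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "pattern", validate_iupac(self.pattern, name=f"{self.name} pattern"))
        rc = reverse_complement(self.pattern)
        if self.revcomp_pattern:
            given = validate_iupac(self.revcomp_pattern, name=f"{self.name} revcomp")
            if given != rc:
                raise ValueError(
                    f"{self.name}: revcomp spelling {given} inconsistent with {self.pattern} (expected {rc})")
        object.__setattr__(self, "revcomp_pattern", rc)

    @property
    def is_palindromic(self) -> bool:
        return self.pattern == self.revcomp_pattern


#: The four motifs recurrently found in the conserved elements of the
#: Peg3 imprinted domain: the E box (bHLH factors such as MYOD/E47/AP4),
#: PITX2, NF-kB and RFX1.
DEFAULT_MOTIF_LIBRARY: tuple[Motif, ...] = (
    Motif("E_box", "CAGCTG"),
    Motif("PITX2", "GGGATTA", "TAATCCC"),
    Motif("NF-kB", "GGAATTTT", "AAAATTCC"),
    Motif("RFX1", "CCATGG"),
)


@dataclass(frozen=True)
class MotifHit:
    motif: str
    offset: int  # forward-strand coordinate of the occurrence start
    strand: str


@dataclass
class MultipleAlignment:
    """A reference-anchored multiple alignment.

    All rows have equal length; ungapping a row reproduces the input
    sequence of that species.  ``ref_gap_columns[i]`` flags columns
    where the reference is gapped (insertions in some other species).
    """

    species: list[str]
    rows: list[str]
    reference: str
    ref_gap_columns: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise ValueError(f"rows have unequal lengths: {sorted(lengths)}")
        if self.reference not in self.species:
            raise ValueError(f"reference {self.reference!r} not among species")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def row(self, species: str) -> str:
        return self.rows[self.species.index(species)]

    def column_matrix(self) -> np.ndarray:
        return np.array([np.frombuffer(r.encode(), dtype="S1") for r in self.rows])

    def reference_coordinates(self) -> np.ndarray:
        """For each column, the reference coordinate of its base (or of
        the next reference base for reference-gap columns)."""
        ref_row = np.frombuffer(self.row(self.reference).encode(), dtype="S1")
        inc = ref_row != b"-"
        return np.concatenate(([0], np.cumsum(inc)[:-1]))


@dataclass(frozen=True)
class FootprintRegion:
    """A maximal run of invariant columns (identical non-gap base in
    every species)."""

    col_start: int
    col_end: int
    ref_start: int
    ref_end: int

    @property
    def length(self) -> int:
        return self.col_end - self.col_start


def _parse_pairwise(aln) -> tuple[list[str], dict[int, str]]:
    """Decompose a global reference/other alignment into the residue
    aligned to each reference position and the insertions preceding
    each reference position (keyed by that position; key == ref length
    for a trailing insertion)."""
    per_ref: list[str] = []
    insertions: dict[int, str] = {}
    ref_pos = 0
    pending = ""
    for r, q in zip(aln.aligned_ref, aln.aligned_query):
        if r == "-":
            pending += q
        else:
            if pending:
                insertions[ref_pos] = pending
                pending = ""
            per_ref.append(q)
            ref_pos += 1
    if pending:
        insertions[ref_pos] = pending
    return per_ref, insertions


def align_ortholog_set(sequences: dict[str, str], reference: str,
                       params: ConservationParams | None = None) -> MultipleAlignment:
    """Reference-anchored multiple alignment of one ortholog set.

    Each non-reference sequence is globally aligned to the reference
    (affine gaps); the pairwise alignments are merged on reference
    coordinates.  Insertions relative to the reference open
    reference-gap columns sized to the longest insertion at that point,
    with shorter insertions left-aligned and padded.
    """
    params = params or ConservationParams()
    if len(sequences) < 2:
        raise ValueError("need at least 2 sequences")
    if reference not in sequences:
        raise ValueError(f"reference label {reference!r} missing from input")
    seqs = {sp: validate_sequence(s, name=f"sequence of {sp}") for sp, s in sequences.items()}
    ref_seq = seqs[reference]
    species = list(seqs)
    per_ref_rows: dict[str, list[str]] = {}
    insert_rows: dict[str, dict[int, str]] = {}
    for sp in species:
        if sp == reference:
            per_ref_rows[sp] = list(ref_seq)
            insert_rows[sp] = {}
            continue
        aln = pairwise_align(ref_seq, seqs[sp], params, mode="global")
        per_ref, ins = _parse_pairwise(aln)
        per_ref_rows[sp], insert_rows[sp] = per_ref, ins
    max_ins = [0] * (len(ref_seq) + 1)
    for ins in insert_rows.values():
        for pos, s in ins.items():
            max_ins[pos] = max(max_ins[pos], len(s))
    rows, ref_gap_flags = [], []
    for sp in species:
        out = []
        for pos in range(len(ref_seq) + 1):
            if max_ins[pos]:
                s = insert_rows[sp].get(pos, "")
                out.append(s.ljust(max_ins[pos], "-"))
            if pos < len(ref_seq):
                out.append(per_ref_rows[sp][pos])
        rows.append("".join(out))
    for pos in range(len(ref_seq) + 1):
        ref_gap_flags.extend([True] * max_ins[pos])
        if pos < len(ref_seq):
            ref_gap_flags.append(False)
    return MultipleAlignment(species=species, rows=rows, reference=reference,
                             ref_gap_columns=np.array(ref_gap_flags, dtype=bool))


def invariant_columns(msa: MultipleAlignment) -> np.ndarray:
    """Boolean per column: all rows non-gap, non-N and identical."""
    mat = msa.column_matrix()
    same = np.all(mat == mat[0], axis=0)
    return same & (mat[0] != b"-") & (mat[0] != b"N")


def find_invariant_regions(msa: MultipleAlignment,
                           min_footprint_length: int = 6) -> list[FootprintRegion]:
    """Maximal runs of invariant columns of length >= the minimum
    (default 6 bp, the shortest library motif), with reference
    coordinates attached."""
    if min_footprint_length < 1:
        raise ValueError("min_footprint_length must be >= 1")
    inv = invariant_columns(msa)
    ref_coords = msa.reference_coordinates()
    regions = []
    n = len(inv)
    i = 0
    while i < n:
        if not inv[i]:
            i += 1
            continue
        j = i
        while j < n and inv[j]:
            j += 1
        if j - i >= min_footprint_length:
            regions.append(FootprintRegion(
                col_start=i, col_end=j,
                ref_start=int(ref_coords[i]),
                ref_end=int(ref_coords[j - 1]) + 1,
            ))
        i = j
    return regions


def scan_motifs(sequence: str, motif_library=DEFAULT_MOTIF_LIBRARY) -> list[MotifHit]:
    """All occurrences of every library motif in ``sequence``.

    Forward-strand matches use the forward spelling; minus-strand
    matches are found by scanning the reverse-complement spelling
    against the forward sequence, with offsets reported in forward
    coordinates.  A palindromic motif yields one hit per position, not
    two.  Overlapping occurrences are all counted; ``N`` in the
    sequence never matches.
    """
    sequence = validate_sequence(sequence)
    if not motif_library:
        raise ValueError("motif library is empty")
    hits: list[MotifHit] = []
    for motif in motif_library:
        for off in iter_iupac_matches(sequence, motif.pattern):
            hits.append(MotifHit(motif.name, off, "+"))
        if motif.scan_both_strands and not motif.is_palindromic:
            for off in iter_iupac_matches(sequence, motif.revcomp_pattern):
                hits.append(MotifHit(motif.name, off, "-"))
    hits.sort(key=lambda h: (h.motif, h.offset, h.strand))
    return hits


def motif_frequency_matrix(hits_by_element: dict[str, dict[str, list[MotifHit]]],
                           motif_library=DEFAULT_MOTIF_LIBRARY) -> pd.DataFrame:
    """Per (element, motif) summary of motif occurrence across species.

    ``hits_by_element`` maps element id -> species -> hit list, and must
    include every species that was scanned, including those with zero
    hits (their presence defines ``n_species_with_sequence``).  The
    ratio is total hits / species with sequence (it may exceed 1 when
    species carry multiple copies); ``enriched`` is True iff the ratio
    strictly exceeds 0.5.
    """
    records = []
    for element, by_species in hits_by_element.items():
        n_species = len(by_species)
        if n_species == 0:
            raise ValueError(f"element {element!r} has no scanned species")
        for motif in motif_library:
            total = sum(1 for hl in by_species.values() for h in hl if h.motif == motif.name)
            with_hit = sum(1 for hl in by_species.values()
                           if any(h.motif == motif.name for h in hl))
            ratio = total / n_species
            records.append({
                "element": element, "motif": motif.name,
                "total_hits": total,
                "n_species_with_sequence": n_species,
                "n_species_with_hit": with_hit,
                "ratio": ratio,
                "enriched": ratio > ENRICHMENT_RATIO_THRESHOLD,
            })
    return pd.DataFrame.from_records(records)
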