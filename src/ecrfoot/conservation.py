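"""Conserved-element calling and cross-species ortholog search.

The module mirrors the two comparative steps used to characterise
candidate regulatory elements in a syntenic locus:

1. ``pairwise_align`` + ``call_conserved_elements`` — align two genomic
   intervals (affine-gap scoring) and report every maximal block longer
   than ``min_length`` bp with identity above ``min_identity``
   (defaults: strictly >50 bp and strictly >75% identity, the classic
   human/mouse conserved-region criterion).
2. ``ortholog_search`` + ``build_presence_matrix`` — a seed-and-extend
   nucleotide search (exact seed words hashed over the target, hits
   extended by local alignment) used to ask, for each element probe and
   each species, whether an orthologous copy exists, summarised as a
   species x probe presence matrix of best hit scores.

Identity is defined as matches / aligned columns; gap columns count
against identity, and ``N`` never counts as a match.  All coordinates
are 0-based half-open.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align.substitution_matrices import Array as SubstitutionArray

from .intervals import GenomicInterval
from .seqs import reverse_complement, validate_sequence


@dataclass
class ConservationParams:
    """Thresholds and scores for element calling and ortholog search.

    ``min_length``/``min_identity`` are strict lower bounds: a block
    qualifies only if its length *exceeds* ``min_length`` and its
    identity *exceeds* ``min_identity``.
    """

    min_length: int = 50
    min_identity: float = 0.75
    match: int = 1
    mismatch: int = -1
    gap_open: int = -2
    gap_extend: int = -1
    seed_word_length: int = 11
    min_hit_score: int = 30

    def __post_init__(self) -> None:
        if not 0 < self.min_identity <= 1:
            raise ValueError("min_identity must be in (0, 1]")
        if self.min_length < 1:
            raise ValueError("min_length must be >= 1")
        if self.seed_word_length < 4:
            raise ValueError("seed_word_length must be >= 4")
        if self.match <= 0 or self.mismatch >= 0:
            raise ValueError("match must be positive and mismatch negative")


@dataclass
class PairwiseAlignment:
    """One pairwise alignment with per-column bookkeeping.

    ``aligned_ref``/``aligned_query`` are equal-length gapped strings
    covering the aligned region only (for local mode); ``ref_start`` etc.
    locate that region on the input sequences.  ``match_flags[i]`` is
    True iff column ``i`` pairs two identical non-``N`` bases.
    """

    ref: str
    query: str
    aligned_ref: str
    aligned_query: str
    score: float
    ref_start: int
    ref_end: int
    query_start: int
    query_end: int
    mode: str
    match_flags: np.ndarray = field(repr=False)

    @property
    def n_columns(self) -> int:
        return len(self.aligned_ref)

    @property
    def identity(self) -> float:
        if self.n_columns == 0:
            return 0.0
        return float(self.match_flags.sum()) / self.n_columns

    def ref_coordinates(self) -> np.ndarray:
        """Reference coordinate of each column (position of the ref base,
        or of the next ref base for columns where the reference is
        gapped)."""
        inc = np.frombuffer(self.aligned_ref.encode(), dtype="S1") != b"-"
        return self.ref_start + np.concatenate(([0], np.cumsum(inc)[:-1]))


@dataclass(frozen=True)
class ConservedElement:
    """A called conserved block with paired intervals and identity."""

    id: str
    interval_ref: GenomicInterval
    interval_query: GenomicInterval
    identity: float
    length: int


@dataclass(frozen=True)
class OrthologHit:
    """One seed-and-extend hit of a probe in a species' sequence."""

    probe_id: str
    species: str
    interval: GenomicInterval
    strand: str
    score: float
    identity: float


def _substitution_matrix(match: int, mismatch: int) -> SubstitutionArray:
    mat = SubstitutionArray("ACGTN", dims=2)
    for a in "ACGTN":
        for b in "ACGTN":
            mat[a, b] = match if (a == b and a != "N") else mismatch
    return mat


def _make_aligner(params: ConservationParams, mode: str) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    aligner.substitution_matrix = _substitution_matrix(params.match, params.mismatch)
    # Affine convention: a gap of length k costs gap_open + (k-1)*gap_extend.
    aligner.open_gap_score = params.gap_open
    aligner.extend_gap_score = params.gap_extend
    return aligner


def _gapped_strings(alignment: Align.Alignment, ref: str, query: str):
    """Rebuild gapped strings and input coordinates from aligned blocks."""
    blocks_ref, blocks_query = alignment.aligned
    if len(blocks_ref) == 0:
        return "", "", 0, 0, 0, 0
    ref_start, query_start = int(blocks_ref[0][0]), int(blocks_query[0][0])
    ref_end, query_end = int(blocks_ref[-1][1]), int(blocks_query[-1][1])
    out_ref, out_query = [], []
    prev_r, prev_q = ref_start, query_start
    for (r0, r1), (q0, q1) in zip(blocks_ref, blocks_query):
        r0, r1, q0, q1 = int(r0), int(r1), int(q0), int(q1)
        if r0 > prev_r:  # deletion in query
            out_ref.append(ref[prev_r:r0])
            out_query.append("-" * (r0 - prev_r))
        if q0 > prev_q:  # insertion in query
            out_ref.append("-" * (q0 - prev_q))
            out_query.append(query[prev_q:q0])
        out_ref.append(ref[r0:r1])
        out_query.append(query[q0:q1])
        prev_r, prev_q = r1, q1
    return "".join(out_ref), "".join(out_query), ref_start, ref_end, query_start, query_end


def _match_flags(aligned_ref: str, aligned_query: str) -> np.ndarray:
    a = np.frombuffer(aligned_ref.encode(), dtype="S1")
    b = np.frombuffer(aligned_query.encode(), dtype="S1")
    return (a == b) & (a != b"-") & (a != b"N")


def pairwise_align(seq_ref: str, seq_query: str,
                   params: ConservationParams | None = None,
                   mode: str = "local") -> PairwiseAlignment:
    """Optimal affine-gap alignment of two sequences.

    ``mode='local'`` (Smith-Waterman-Gotoh) is used for hit extension;
    ``mode='global'`` for aligning syntenic intervals prior to element
    calling.  ``N`` bases are accepted but always score as mismatches.
    """
    params = params or ConservationParams()
    seq_ref = validate_sequence(seq_ref, name="reference sequence")
    seq_query = validate_sequence(seq_query, name="query sequence")
    if mode not in {"local", "global"}:
        raise ValueError("mode must be 'local' or 'global'")
    aligner = _make_aligner(params, mode)
    results = aligner.align(seq_ref, seq_query)
    try:
        best = results[0]
    except IndexError:
        # local mode with no positive-scoring path: empty alignment
        return PairwiseAlignment(
            ref=seq_ref, query=seq_query, aligned_ref="", aligned_query="",
            score=0.0, ref_start=0, ref_end=0, query_start=0, query_end=0,
            mode=mode, match_flags=np.zeros(0, dtype=bool))
    ar, aq, r0, r1, q0, q1 = _gapped_strings(best, seq_ref, seq_query)
    return PairwiseAlignment(
        ref=seq_ref, query=seq_query, aligned_ref=ar, aligned_query=aq,
        score=float(best.score), ref_start=r0, ref_end=r1,
        query_start=q0, query_end=q1, mode=mode,
        match_flags=_match_flags(ar, aq),
    )


_EPS = 1e-9


def _max_subarray(prefix: np.ndarray, lo: int, hi: int) -> tuple[float, int, int]:
    """Best-scoring segment within [lo, hi) of the weight array whose
    prefix sums are given; ties broken leftmost-then-longest."""
    best_score, best_i, best_j = 0.0, lo, lo
    min_pos, min_val = lo, prefix[lo]
    for j in range(lo + 1, hi + 1):
        s = prefix[j] - min_val
        if s > best_score + _EPS or (s > best_score - _EPS and min_pos == best_i and j > best_j):
            best_score, best_i, best_j = s, min_pos, j
        if prefix[j] < min_val - _EPS:
            min_val, min_pos = prefix[j], j
    return best_score, best_i, best_j


def _maximal_scoring_segments(weights: np.ndarray) -> list[tuple[int, int]]:
    """Disjoint positive-scoring segments by repeated best-segment
    extraction (max-subarray, then recurse on both flanks).

    Extracting the globally best segment first keeps a long
    above-threshold block in one piece even when a sub-block scores
    higher per column.  Deterministic: ties go leftmost-then-longest.
    """
    prefix = np.concatenate(([0.0], np.cumsum(weights, dtype=float)))
    out: list[tuple[int, int]] = []
    stack = [(0, len(weights))]
    while stack:
        lo, hi = stack.pop()
        if hi - lo < 1:
            continue
        score, i, j = _max_subarray(prefix, lo, hi)
        if score <= _EPS:
            continue
        out.append((i, j))
        stack.append((lo, i))
        stack.append((j, hi))
    return sorted(out)


def call_conserved_elements(alignment: PairwiseAlignment,
                            params: ConservationParams | None = None,
                            ref_name: str = "ref",
                            query_name: str = "query") -> list[ConservedElement]:
    """Maximal qualifying blocks of an alignment.

    A block qualifies when its column count strictly exceeds
    ``min_length`` and its identity (matches / columns, gaps counting
    against) strictly exceeds ``min_identity``.  Candidate boundaries
    come from the *alignment score* signal, which separates conserved
    blocks from aligned background far more sharply than column
    identity: the best-scoring segment of the per-column affine scores
    is extracted; a segment passing the identity/length filter is
    emitted (flanking non-match columns trimmed), one failing it —
    typically several blocks chained through background — is split at
    its internal cumulative-score minimum (the bridge bottom) and both
    halves are decomposed recursively.  Elements are reported 5'->3'
    on the reference, non-overlapping; ties go leftmost-then-longest.
    """
    params = params or ConservationParams()
    flags = alignment.match_flags
    n = len(flags)
    min_cols = params.min_length + 1  # strict "> min_length"
    if n < min_cols:
        return []
    prefix_m = np.concatenate(([0], np.cumsum(flags)))

    def identity(s: int, e: int) -> float:
        return (prefix_m[e] - prefix_m[s]) / (e - s)

    scores = _column_scores(alignment, params)
    prefix_s = np.concatenate(([0.0], np.cumsum(scores)))
    segments: list[tuple[int, int]] = []
    stack = [(0, n)]
    while stack:
        lo, hi = stack.pop()
        if hi - lo < min_cols:
            continue
        score, i, j = _max_subarray(prefix_s, lo, hi)
        if score <= _EPS:
            continue
        # boundary refinement: a max-score segment can drag tens of
        # near-neutral background columns in at its ends; advance each
        # end while its terminal window still fails the identity
        # threshold, then trim flanking non-match columns
        w = max(10, min_cols // 2)
        while j - i > min_cols and identity(i, min(i + w, j)) <= params.min_identity:
            i += 1
        while j - i > min_cols and identity(max(i, j - w), j) <= params.min_identity:
            j -= 1
        while i < j and not flags[i]:
            i += 1
        while j > i and not flags[j - 1]:
            j -= 1
        if j - i >= min_cols and identity(i, j) > params.min_identity:
            segments.append((i, j))
            stack.append((lo, i))
            stack.append((j, hi))
        elif j - i >= 2 * min_cols:
            # over-long non-qualifying segment: split at the deepest
            # internal score dip (maximum drawdown from the running
            # score maximum — the bottom of a background bridge
            # between chained blocks) and retry both halves
            inner = prefix_s[i + 1:j]
            drawdown = np.maximum.accumulate(inner) - inner
            k = int(i + 1 + np.argmax(drawdown))
            if drawdown.max() <= _EPS:
                k = (i + j) // 2
            stack.append((lo, k))
            stack.append((k, hi))
        else:
            stack.append((lo, i))
            stack.append((j, hi))
    segments.sort()
    return [_element_from_columns(alignment, cs, ce, identity(cs, ce),
                                  f"elem{k}", ref_name, query_name)
            for k, (cs, ce) in enumerate(segments, start=1)]


def _column_scores(alignment: PairwiseAlignment,
                   params: ConservationParams) -> np.ndarray:
    """Per-column affine score of an alignment (gap-open charged at the
    first column of each gap run)."""
    a = np.frombuffer(alignment.aligned_ref.encode(), dtype="S1")
    b = np.frombuffer(alignment.aligned_query.encode(), dtype="S1")
    gap = (a == b"-") | (b == b"-")
    scores = np.where(alignment.match_flags, float(params.match), float(params.mismatch))
    open_extra = float(params.gap_open) - float(params.gap_extend)
    run_start = gap & ~np.concatenate(([False], gap[:-1]))
    scores[gap] = float(params.gap_extend)
    scores[run_start] += open_extra
    return scores


def _element_from_columns(alignment: PairwiseAlignment, cs: int, ce: int,
                          ident: float, elem_id: str,
                          ref_name: str, query_name: str) -> ConservedElement:
    """Map an alignment-column range to reference/query intervals."""
    ref_coords = alignment.ref_coordinates()
    arr_ref = np.frombuffer(alignment.aligned_ref.encode(), dtype="S1")
    arr_query = np.frombuffer(alignment.aligned_query.encode(), dtype="S1")
    qry_inc = arr_query != b"-"
    qry_coords = alignment.query_start + np.concatenate(([0], np.cumsum(qry_inc)[:-1]))
    r0 = int(ref_coords[cs])
    r1 = int(ref_coords[ce - 1]) + int(arr_ref[ce - 1] != b"-")
    q0 = int(qry_coords[cs])
    q1 = int(qry_coords[ce - 1]) + int(qry_inc[ce - 1])
    return ConservedElement(
        id=elem_id,
        interval_ref=GenomicInterval(ref_name, r0, r1, name=elem_id),
        interval_query=GenomicInterval(query_name, q0, q1, name=elem_id),
        identity=ident,
        length=r1 - r0,
    )


def find_conserved_elements(seq_ref: str, seq_query: str,
                            params: ConservationParams | None = None,
                            ref_name: str = "ref", query_name: str = "query",
                            max_rounds: int = 64) -> list[ConservedElement]:
    """Call conserved elements between two genomic intervals.

    Local alignments are enumerated bl2seq-style: the best local
    affine-gap alignment is taken, qualifying blocks are called from
    it, the aligned region is masked with ``N`` in both sequences, and
    the search repeats while the alignment score can still contain a
    qualifying block (the score of a minimal gapless block at exactly
    ``min_length`` + 1 columns and ``min_identity``).  Local alignment
    keeps element boundaries tight: unlike a global alignment, random
    background is never forced to align.
    """
    params = params or ConservationParams()
    min_cols = params.min_length + 1
    min_score = min_cols * (params.match * params.min_identity
                            + params.mismatch * (1.0 - params.min_identity))
    masked_ref, masked_query = seq_ref.upper(), seq_query.upper()
    elements: list[ConservedElement] = []
    for _ in range(max_rounds):
        aln = pairwise_align(masked_ref, masked_query, params, mode="local")
        if aln.n_columns == 0 or aln.score < min_score:
            break
        elements.extend(call_conserved_elements(aln, params, ref_name, query_name))
        masked_ref = (masked_ref[:aln.ref_start]
                      + "N" * (aln.ref_end - aln.ref_start)
                      + masked_ref[aln.ref_end:])
        masked_query = (masked_query[:aln.query_start]
                        + "N" * (aln.query_end - aln.query_start)
                        + masked_query[aln.query_end:])
    elements.sort(key=lambda e: e.interval_ref.start)
    out = []
    for i, e in enumerate(elements, start=1):
        ir, iq = e.interval_ref, e.interval_query
        out.append(ConservedElement(
            id=f"elem{i}",
            interval_ref=GenomicInterval(ir.chrom, ir.start, ir.end, name=f"elem{i}"),
            interval_query=GenomicInterval(iq.chrom, iq.start, iq.end, name=f"elem{i}"),
            identity=e.identity, length=e.length))
    return out


def _seed_hits(probe: str, target: str, k: int) -> list[tuple[int, int]]:
    """(probe_offset, target_offset) pairs of exact shared k-mers.

    Words containing ``N`` are skipped, so long N runs naturally split
    the seeding.
    """
    index: dict[str, list[int]] = defaultdict(list)
    for i in range(len(target) - k + 1):
        word = target[i:i + k]
        if "N" not in word:
            index[word].append(i)
    hits = []
    for j in range(len(probe) - k + 1):
        word = probe[j:j + k]
        if "N" in word:
            continue
        for i in index.get(word, ()):
            hits.append((j, i))
    return hits


def ortholog_search(probe: str, target: str,
                    params: ConservationParams | None = None,
                    probe_id: str = "probe", species: str = "target",
                    target_name: str = "target") -> list[OrthologHit]:
    """Seed-and-extend search of ``probe`` against both strands of
    ``target``.

    Exact ``seed_word_length``-mers of the probe are looked up in a hash
    of the target; seeds clustered by diagonal are extended by local
    affine-gap alignment of the probe against a window around the
    cluster.  Hits scoring at least ``min_hit_score`` are deduplicated
    (best score per overlapping locus) and returned sorted by score
    descending.
    """
    params = params or ConservationParams()
    probe = validate_sequence(probe, name="probe")
    target = validate_sequence(target, name="target")
    k = params.seed_word_length
    if len(probe) < k:
        raise ValueError(f"probe ({len(probe)} bp) shorter than seed word ({k} bp)")
    candidates: list[OrthologHit] = []
    for strand in "+-":
        tseq = target if strand == "+" else reverse_complement(target)
        seeds = _seed_hits(probe, tseq, k)
        if not seeds:
            continue
        # cluster seeds on nearby diagonals
        seeds.sort(key=lambda h: (h[1] - h[0], h[1]))
        clusters: list[list[tuple[int, int]]] = []
        band = max(20, len(probe) // 5)
        for h in seeds:
            d = h[1] - h[0]
            if clusters and abs((clusters[-1][-1][1] - clusters[-1][-1][0]) - d) <= band:
                clusters[-1].append(h)
            else:
                clusters.append([h])
        for cl in clusters:
            t_lo = max(0, min(i - j for j, i in cl) - len(probe) // 2)
            t_hi = min(len(tseq), max(i - j for j, i in cl) + len(probe) + len(probe) // 2)
            window = tseq[t_lo:t_hi]
            aln = pairwise_align(probe, window, params, mode="local")
            if aln.score < params.min_hit_score or aln.n_columns == 0:
                continue
            w0, w1 = t_lo + aln.query_start, t_lo + aln.query_end
            if strand == "+":
                g0, g1 = w0, w1
            else:
                g0, g1 = len(target) - w1, len(target) - w0
            candidates.append(OrthologHit(
                probe_id=probe_id, species=species,
                interval=GenomicInterval(target_name, g0, g1, name=probe_id, strand=strand),
                strand=strand, score=aln.score, identity=aln.identity,
            ))
    # keep the best hit per overlapping locus
    candidates.sort(key=lambda h: (-h.score, h.interval.start, h.strand))
    kept: list[OrthologHit] = []
    for h in candidates:
        if not any(h.interval.overlaps(k_.interval) for k_ in kept):
            kept.append(h)
    return kept


def build_presence_matrix(hits: list[OrthologHit],
                          species: list[str] | None = None,
                          probes: list[str] | None = None) -> pd.DataFrame:
    """Species x probe matrix of best hit scores (NaN = absent).

    The cell records the maximum score among that species' hits for that
    probe; the frame carries ``attrs['species_count']`` (species with a
    hit, per probe) and ``attrs['mean_species_count']``.
    """
    species = list(species) if species is not None else sorted({h.species for h in hits})
    probes = list(probes) if probes is not None else sorted({h.probe_id for h in hits})
    if len(set(species)) != len(species) or len(set(probes)) != len(probes):
        raise ValueError("duplicate species or probe labels")
    matrix = pd.DataFrame(np.nan, index=species, columns=probes, dtype=float)
    for h in hits:
        if h.species not in matrix.index or h.probe_id not in matrix.columns:
            raise ValueError(f"hit references unknown labels: {h.species}/{h.probe_id}")
        cur = matrix.at[h.species, h.probe_id]
        if np.isnan(cur) or h.score > cur:
            matrix.at[h.species, h.probe_id] = h.score
    counts = matrix.notna().sum(axis=0)
    matrix.attrs["species_count"] = counts.to_dict()
    matrix.attrs["mean_species_count"] = float(counts.mean()) if len(probes) else 0.0
    return matrix
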