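"""Synthetic-data generators with known ground truth.

Every pipeline stage can be exercised without external downloads:

* ``generate_ortholog_set`` — ortholog sets diverged from one common
  ancestor along independent lineages (star phylogeny, Jukes-Cantor-
  like per-site substitution), with planted motif sites copied
  unmutated into every species.
* ``generate_genome_pair`` — two genomic intervals sharing planted
  conserved blocks of controlled identity inside independent random
  flanks (the two-genome comparison that defines conserved elements).
* ``generate_cobra_gel`` — a COBRA gel for an amplicon with known
  per-CpG methylation fractions: molecules sampled, converted,
  digested, binned by fragment length, with Gaussian densitometry
  noise.
* ``generate_tissue_tracks`` — per-tissue histone-mark and
  hypomethylation interval sets consistent with an assigned truth
  state per (element, tissue).
* ``reference_ortholog_collection`` — a fixed-composition synthetic
  cross-species collection (18 element probe sets over a 45-mammal
  panel, mean 20 species per element, with planted cis-regulatory
  motif content) used as the package's reference input.

All generators are deterministic: the same config and seed give
byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Any

import numpy as np

from .cobra import (EnzymeSpec, MethylationState, UNINFORMATIVE, classify_enzyme,
                    digest, BandTable)
from .epigenome import EnhancerState
from .intervals import GenomicInterval
from .seqs import mutate_sequence, random_sequence, reverse_complement, validate_sequence


@dataclass
class SimulationConfig:
    """Knobs of the sequence-evolution simulators.

    Defaults are the package's standard study conditions: per-lineage
    substitution rate 0.05 (moderate mammalian divergence at a
    conserved locus), planted-element identity 0.85, elements of
    100-300 bp embedded in 200 bp flanks.
    """

    seed: int = 0
    n_species: int = 20
    substitution_rate: float = 0.05
    indel_rate: float = 0.0
    ancestral_length: int = 200
    planted_motifs: list[tuple[str, int]] = field(default_factory=list)
    n_elements: int = 3
    element_identity: float = 0.85
    element_length: int = 150
    flank_length: int = 200

    def __post_init__(self) -> None:
        for name in ("substitution_rate", "indel_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if not 0.0 <= self.element_identity <= 1.0:
            raise ValueError("element_identity must be in [0,1]")
        if self.n_species < 0 or self.n_elements < 0:
            raise ValueError("counts must be non-negative")

    def rng(self, stream: str) -> np.random.Generator:
        """One seeded stream per operation call (platform-stable)."""
        return _stable_stream(self.seed, stream)


@dataclass
class TruthRecord:
    """Ground truth of one simulation, JSON-serialisable.

    All coordinates 0-based half-open on the host sequence.
    """

    seed: int = 0
    elements_ref: list[GenomicInterval] = field(default_factory=list)
    elements_query: list[GenomicInterval] = field(default_factory=list)
    motif_sites: dict[str, list[tuple[str, int, int]]] = field(default_factory=dict)
    cpg_fractions: dict[int, float] = field(default_factory=dict)
    tissue_states: dict[str, dict[str, tuple[str, bool]]] = field(default_factory=dict)

    def to_json_dict(self) -> dict[str, Any]:
        d = asdict(self)
        d["elements_ref"] = [vars(iv) for iv in self.elements_ref]
        d["elements_query"] = [vars(iv) for iv in self.elements_query]
        d["cpg_fractions"] = {str(k): v for k, v in self.cpg_fractions.items()}
        return d


def _stable_stream(seed: int, label: str) -> np.random.Generator:
    """Deterministic, platform-independent stream for (seed, label)."""
    key = [seed] + [ord(c) for c in label]
    return np.random.default_rng(np.random.SeedSequence(key))


def generate_ortholog_set(config: SimulationConfig,
                          species_names: list[str] | None = None
                          ) -> tuple[dict[str, str], TruthRecord]:
    """Simulate one element's ortholog set under a star phylogeny.

    An ancestral sequence of ``ancestral_length`` is drawn; each species
    descends along an independent lineage with per-site substitution at
    ``substitution_rate`` (equal probability to each of the other three
    bases).  Planted motifs are written into the ancestor at their
    stated positions and copied unmutated into every species, so they
    remain invariant across the set.  Indels default off; when
    ``indel_rate`` > 0, single-base indels are applied outside planted
    motifs only, keeping truth coordinates well-defined.
    """
    if config.n_species < 2:
        raise ValueError("n_species must be >= 2")
    motifs = [(validate_sequence(m, name="planted motif"), int(p))
              for m, p in config.planted_motifs]
    occupied: list[tuple[int, int]] = []
    for m, p in motifs:
        if p < 0 or p + len(m) > config.ancestral_length:
            raise ValueError(f"planted motif {m} at {p} outside ancestral sequence")
        for s, e in occupied:
            if p < e and s < p + len(m):
                raise ValueError("planted motifs overlap")
        occupied.append((p, p + len(m)))
    rng = _stable_stream(config.seed, "orthologs")
    ancestor = list(random_sequence(config.ancestral_length, rng))
    protected: set[int] = set()
    for m, p in motifs:
        ancestor[p:p + len(m)] = list(m)
        protected.update(range(p, p + len(m)))
    ancestor_seq = "".join(ancestor)
    if species_names is None:
        species_names = [f"species{i + 1}" for i in range(config.n_species)]
    if len(species_names) != config.n_species:
        raise ValueError("species_names length must equal n_species")
    sequences: dict[str, str] = {}
    truth = TruthRecord(seed=config.seed)
    for sp in species_names:
        seq = mutate_sequence(ancestor_seq, config.substitution_rate, rng,
                              protected=protected)
        if config.indel_rate > 0:
            seq = _apply_indels(seq, config.indel_rate, rng, protected)
        sequences[sp] = seq
        truth.motif_sites[sp] = [(m, p, p + len(m)) for m, p in motifs]
    return sequences, truth


def _apply_indels(seq: str, rate: float, rng: np.random.Generator,
                  protected: set[int]) -> str:
    """Single-base indels outside protected sites.

    Deletions and insertions shift downstream coordinates, so this mode
    is only safe when no truth coordinates beyond the protected motifs
    are needed; planted motifs themselves are kept intact by only
    editing strictly after the last protected position."""
    floor = max(protected) + 1 if protected else 0
    out = []
    for i, base in enumerate(seq):
        if i >= floor and rng.random() < rate:
            if rng.random() < 0.5:
                continue  # deletion
            out.append(base)
            out.append(random_sequence(1, rng))  # insertion after site
        else:
            out.append(base)
    return "".join(out)


def generate_genome_pair(config: SimulationConfig,
                         ref_name: str = "genomeA",
                         query_name: str = "genomeB"
                         ) -> tuple[str, str, TruthRecord]:
    """Two genomic intervals with planted conserved blocks.

    Both genomes are independent uniform-random sequences except for
    ``n_elements`` shared blocks of ``element_length`` bp planted in the
    same order (synteny) in both, the copy in the second genome mutated
    to ``element_identity`` per-base identity.  Identities below 0.25
    are rejected: such blocks are indistinguishable from the random
    background.
    """
    if 0 < config.element_identity < 0.25:
        raise ValueError("element_identity < 0.25 is indistinguishable from background")
    total = config.n_elements * (config.element_length + config.flank_length) + config.flank_length
    rng = _stable_stream(config.seed, "genomepair")
    truth = TruthRecord(seed=config.seed)
    partsA, partsB = [], []
    posA = posB = 0
    for k in range(config.n_elements):
        fA = random_sequence(config.flank_length, rng)
        fB = random_sequence(config.flank_length, rng)
        elem = random_sequence(config.element_length, rng)
        elemB = mutate_sequence(elem, 1.0 - config.element_identity, rng)
        partsA += [fA, elem]
        partsB += [fB, elemB]
        posA += config.flank_length
        posB += config.flank_length
        truth.elements_ref.append(GenomicInterval(ref_name, posA, posA + config.element_length,
                                                  name=f"elem{k + 1}"))
        truth.elements_query.append(GenomicInterval(query_name, posB, posB + config.element_length,
                                                    name=f"elem{k + 1}"))
        posA += config.element_length
        posB += config.element_length
    partsA.append(random_sequence(config.flank_length, rng))
    partsB.append(random_sequence(config.flank_length, rng))
    genomeA, genomeB = "".join(partsA), "".join(partsB)
    assert len(genomeA) == total
    return genomeA, genomeB, truth


def generate_cobra_gel(amplicon: str, methylation_fraction: float | dict[int, float],
                       enzyme: EnzymeSpec, n_molecules: int = 10_000,
                       noise_sd: float = 0.0, seed: int = 0) -> tuple[BandTable, TruthRecord]:
    """Simulate a COBRA gel for an amplicon with known methylation.

    ``n_molecules`` alleles are drawn, each CpG methylated independently
    at its fraction; each molecule is bisulfite-converted and digested,
    fragments are binned by exact length, and each band's intensity is
    the molecule count per fragment length times ``(1 + N(0, noise_sd))``
    (clipped at zero).  Molecules with identical methylation patterns
    share one digestion, so the simulation is fast at large n.
    """
    amplicon = validate_sequence(amplicon, name="amplicon")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if n_molecules < 1:
        raise ValueError("n_molecules must be >= 1")
    state = (MethylationState.uniform(amplicon, methylation_fraction)
             if isinstance(methylation_fraction, (int, float))
             else MethylationState(dict(methylation_fraction)))
    cls, _ = classify_enzyme(enzyme, amplicon)
    if cls == UNINFORMATIVE:
        raise ValueError(f"enzyme {enzyme.name} is uninformative for this amplicon")
    rng = _stable_stream(seed, "gel")
    positions = sorted(state.fractions)
    fracs = np.array([state.fractions[p] for p in positions])
    flags = rng.random((n_molecules, len(positions))) < fracs  # molecule x CpG
    counts: dict[int, int] = {}
    patterns, inverse = (np.unique(flags, axis=0, return_inverse=True)
                         if len(positions) else (np.zeros((1, 0), bool), np.zeros(n_molecules, int)))
    pattern_counts = np.bincount(inverse, minlength=len(patterns))
    for pat, n_pat in zip(patterns, pattern_counts):
        if n_pat == 0:
            continue
        meth = {positions[i] for i in range(len(positions)) if pat[i]}
        for frag in digest(amplicon, enzyme, meth):
            counts[frag] = counts.get(frag, 0) + int(n_pat)
    lengths = sorted(counts)
    intensities = []
    for l in lengths:
        noise = rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
        intensities.append(max(0.0, counts[l] * (1.0 + noise)))
    truth = TruthRecord(seed=seed, cpg_fractions=dict(state.fractions))
    return BandTable(tuple(lengths), tuple(intensities), enzyme=enzyme.name), truth


def generate_tissue_tracks(ecr_intervals: list[GenomicInterval], tissues: list[str],
                           state_assignment: dict[tuple[str, str], tuple[str, bool]],
                           seed: int = 0
                           ) -> tuple[dict[str, dict[str, list[GenomicInterval]]], TruthRecord]:
    """Per-tissue peak tracks consistent with an assigned truth state.

    ``state_assignment`` maps (element name, tissue) -> (state, hypomethylated)
    with state one of {'active', 'poised', 'acetyl_only', 'none'}.  For
    each element/tissue, peaks overlapping the element are emitted for
    exactly the marks its state implies (active: both; poised: H3K4me1;
    acetyl_only: H3K27ac), plus a hypomethylated region when flagged.
    A few decoy peaks are placed in inter-element gaps, never
    overlapping any element.
    """
    if not tissues:
        raise ValueError("tissue list is empty")
    if not ecr_intervals:
        raise ValueError("element list is empty")
    rng = _stable_stream(seed, "tracks")
    truth = TruthRecord(seed=seed)
    tracks: dict[str, dict[str, list[GenomicInterval]]] = {
        t: {"H3K4me1": [], "H3K27ac": [], "hypomethylation": []} for t in tissues}
    for tissue in tissues:
        truth.tissue_states[tissue] = {}
        for elem in ecr_intervals:
            key = (elem.name, tissue)
            state_name, hypo = state_assignment.get(key, ("none", False))
            state = EnhancerState(state_name if state_name != "acetyl-only" else "acetyl_only")
            marks = {EnhancerState.ACTIVE: ("H3K4me1", "H3K27ac"),
                     EnhancerState.POISED: ("H3K4me1",),
                     EnhancerState.ACETYL_ONLY: ("H3K27ac",),
                     EnhancerState.NONE: ()}[state]
            for mark in marks:
                pad_l, pad_r = int(rng.integers(0, 50)), int(rng.integers(0, 50))
                start = max(0, elem.start - pad_l)
                tracks[tissue][mark].append(GenomicInterval(elem.chrom, start, elem.end + pad_r,
                                                            name=f"{elem.name}.{mark}"))
            if hypo:
                tracks[tissue]["hypomethylation"].append(
                    GenomicInterval(elem.chrom, elem.start, elem.end, name=f"{elem.name}.hypo"))
            truth.tissue_states[tissue][elem.name] = (state.value, bool(hypo))
        # decoy peaks clear of all elements
        chrom = ecr_intervals[0].chrom
        span_end = max(e.end for e in ecr_intervals) + 5000
        for mark in ("H3K4me1", "H3K27ac"):
            for _ in range(2):
                for _attempt in range(50):
                    s = int(rng.integers(0, span_end))
                    decoy = GenomicInterval(chrom, s, s + 200, name="decoy")
                    # 60 bp guard band: emitted peaks may pad elements by up to 50 bp
                    if all(e.start - 260 > decoy.end or decoy.start > e.end + 260
                           for e in ecr_intervals):
                        tracks[tissue][mark].append(decoy)
                        break
    return tracks, truth


# ---------------------------------------------------------------------------
# Fixed-composition reference collection
# ---------------------------------------------------------------------------

#: 45-mammal panel used by the reference collection (eutherians only:
#: the elements of this domain are not found outside placental mammals).
MAMMAL_PANEL: tuple[str, ...] = (
    "mouse", "rat", "chinese_hamster", "naked_mole_rat", "kangaroo_rat",
    "squirrel", "guinea_pig", "rabbit", "pika", "human", "chimp", "gorilla",
    "orangutan", "gibbon", "rhesus", "baboon", "green_monkey", "marmoset",
    "squirrel_monkey", "bushbaby", "mouse_lemur", "tarsier", "tree_shrew",
    "cow", "sheep", "goat", "pig", "alpaca", "bactrian_camel", "dolphin",
    "killer_whale", "horse", "white_rhino", "cat", "dog", "ferret", "panda",
    "pacific_walrus", "weddell_seal", "microbat", "megabat", "hedgehog",
    "shrew", "elephant", "armadillo",
)

#: Species carrying each element's ortholog, per element (counts average
#: exactly 20 over the 18 elements; the best-conserved elements — 2, 5,
#: 8, 11, 14 — and the reference element 18 carry the most, while the
#: short elements 4, 6 and 7 carry the fewest).
_ELEMENT_SPECIES_COUNTS: tuple[int, ...] = (
    18, 30, 19, 12, 29, 13, 14, 28, 22, 18, 27, 21, 17, 28, 16, 18, 10, 20)

_ELEMENT_LENGTHS: tuple[int, ...] = (
    160, 240, 150, 100, 280, 110, 120, 260, 220, 170, 250, 200, 150, 270, 140, 180, 100, 300)

#: Motifs planted per element (one copy per species unless noted).
_PLANTED_MOTIFS: dict[int, tuple[str, ...]] = {
    2: ("E_box",), 3: ("E_box", "NF-kB", "RFX1"), 5: ("E_box", "PITX2"),
    6: ("E_box",), 7: ("E_box",), 8: ("E_box", "PITX2"), 9: ("E_box",),
    10: ("NF-kB", "RFX1"), 11: ("NF-kB", "RFX1"), 12: ("NF-kB", "RFX1"),
    14: ("NF-kB", "RFX1"), 16: ("NF-kB", "RFX1"), 17: ("E_box",),
    18: ("E_box", "PITX2"),
}

_MOTIF_SEQS = {"E_box": "CAGCTG", "PITX2": "GGGATTA", "NF-kB": "GGAATTTT",
               "RFX1": "CCATGG"}


def _scrub_patterns(seq: str, patterns: list[str], keep: list[tuple[int, int]],
                    rng: np.random.Generator) -> str:
    """Disrupt every occurrence of the patterns (either strand) outside
    the ``keep`` spans by point-mutating the middle base until clean."""
    targets = set()
    for p in patterns:
        targets.add(p)
        targets.add(reverse_complement(p))
    out = list(seq)
    for _round in range(20):
        dirty = []
        s = "".join(out)
        for pat in sorted(targets):
            start = 0
            while True:
                i = s.find(pat, start)
                if i < 0:
                    break
                span = (i, i + len(pat))
                if not any(k0 <= i and span[1] <= k1 for k0, k1 in keep):
                    dirty.append(span)
                start = i + 1
        if not dirty:
            return s
        for i0, i1 in dirty:
            mid = (i0 + i1) // 2
            if any(k0 <= mid < k1 for k0, k1 in keep):
                mid = i0 if not any(k0 <= i0 < k1 for k0, k1 in keep) else i1 - 1
            out[mid] = rng.choice([b for b in "ACGT" if b != out[mid]])
    raise RuntimeError("could not scrub accidental motif occurrences")


def reference_ortholog_collection(seed: int = 0
                                  ) -> tuple[dict[str, dict[str, str]], TruthRecord]:
    """The package's fixed-composition reference input (synthetic).

    A synthetic cross-species element sequence collection in the
    standard survey layout: 18 element ortholog sets (``ECR1``..``ECR18``)
    over a 45-mammal panel, averaging exactly 20 species per element.
    Motif content is planted and exclusive — accidental copies of the
    library motifs are scrubbed — so the collection's motif counts are
    exact ground truth.  In particular the 20 ECR18 orthologs carry 34
    E-box sites in total (two copies in 14 species, one in the other
    six: 1.7 per species) and one PITX2 site each.

    ``seed`` varies the sequences; the composition (species counts,
    motif counts) is fixed.
    """
    rng = _stable_stream(seed, "reference-collection")
    collection: dict[str, dict[str, str]] = {}
    truth = TruthRecord(seed=seed)
    all_patterns = list(_MOTIF_SEQS.values())
    for idx in range(1, 19):
        n_sp = _ELEMENT_SPECIES_COUNTS[idx - 1]
        length = _ELEMENT_LENGTHS[idx - 1]
        # mouse (probe source) always present; others drawn from the panel
        others = [sp for sp in MAMMAL_PANEL if sp != "mouse"]
        members = ["mouse"] + sorted(rng.choice(others, size=n_sp - 1, replace=False))
        motif_names = _PLANTED_MOTIFS.get(idx, ())
        planted: list[tuple[str, int]] = []
        pos = 10
        for name in motif_names:
            planted.append((_MOTIF_SEQS[name], pos))
            pos += len(_MOTIF_SEQS[name]) + 14
        extra_pos = pos + 6  # second E-box copy site (ECR18)
        cfg = SimulationConfig(seed=seed * 1000 + idx, n_species=n_sp,
                               substitution_rate=0.05, ancestral_length=length,
                               planted_motifs=planted)
        seqs, _ = generate_ortholog_set(cfg, species_names=members)
        keep = [(p, p + len(m)) for m, p in planted]
        if idx == 18:
            ebox = _MOTIF_SEQS["E_box"]
            for sp in members[:14]:
                s = list(seqs[sp])
                s[extra_pos:extra_pos + len(ebox)] = list(ebox)
                seqs[sp] = "".join(s)
            keep.append((extra_pos, extra_pos + len(ebox)))
        clean = {}
        for sp, s in seqs.items():
            sp_keep = keep if (idx != 18 or sp in members[:14]) else keep[:-1]
            clean[sp] = _scrub_patterns(s, all_patterns, sp_keep, rng)
        collection[f"ECR{idx}"] = clean
        truth.motif_sites[f"ECR{idx}"] = [(m, p, p + len(m)) for m, p in planted]
    return collection, truth
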