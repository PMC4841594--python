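"""In-silico COBRA (Combined Bisulfite Restriction Analysis).

The assay: bisulfite conversion deaminates unmethylated cytosine to
uracil (read as T after PCR) while 5-methylcytosine at CpG sites is
retained as C.  A restriction enzyme whose post-conversion recognition
site depends on a CpG's conversion state then reports methylation as a
digested/undigested band ratio on a gel:

* TG-class ("unmethylation-indicating", e.g. FokI GGATG, HphI GGTGA):
  the site is only completed when the CpG converts (CG -> TG), so
  digestion indicates the unmethylated allele.
* CG-class ("methylation-indicating", e.g. TaqI TCGA, BstUI CGCG):
  the site requires the retained CG, so digestion indicates the
  methylated allele.

The class is always *derived* per amplicon from the two conversion
extremes, never trusted from an enzyme label.  Percent methylation is
read from band intensities (densitometry), and hypo/hypermethylation
versus a matched normal sample is called from replicate measurements
with a Welch test plus a minimum-difference rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .seqs import (cpg_positions, iter_iupac_matches, reverse_complement,
                   validate_iupac, validate_sequence)

UNMETHYLATION_INDICATING = "unmethylation_indicating"
METHYLATION_INDICATING = "methylation_indicating"
UNINFORMATIVE = "uninformative"


class CobraDesignError(ValueError):
    """A primer or enzyme is unusable for the requested assay."""


@dataclass(frozen=True)
class EnzymeSpec:
    """A restriction enzyme: IUPAC recognition site and cut offset.

    ``cut_offset`` is the distance from the 3' end of the recognition
    site to the cut, measured on the strand carrying the site; it may
    be negative (cut inside the site, e.g. TaqI T^CGA -> -3) or
    positive (cut downstream, e.g. FokI GGATG(9) -> +9).  The duplex is
    modelled with a single cut point per site.
    """

    name: str
    recognition: str
    cut_offset: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "recognition", validate_iupac(self.recognition, name=f"{self.name} site"))


#: Enzymes commonly used for COBRA at this locus.  FokI and HphI are the
#: TG-class exemplars; the others are CG-class candidates.  The actual
#: informativeness class is always derived per amplicon.
DEFAULT_ENZYME_LIBRARY: tuple[EnzymeSpec, ...] = (
    EnzymeSpec("FokI", "GGATG", 9),
    EnzymeSpec("HphI", "GGTGA", 8),
    EnzymeSpec("TaqI", "TCGA", -3),
    EnzymeSpec("BstUI", "CGCG", -2),
    EnzymeSpec("HpyCH4IV", "ACGT", -3),
)


@dataclass
class MethylationState:
    """Per-CpG methylation on the unconverted top strand.

    ``fractions`` maps CpG start position -> methylated fraction in
    [0, 1]; for single-molecule operations a position is treated as
    methylated iff its fraction is 1 (use :meth:`sample` to draw
    molecules at intermediate fractions).
    """

    fractions: dict[int, float]

    def __post_init__(self) -> None:
        for pos, f in self.fractions.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"fraction at CpG {pos} out of [0,1]: {f}")

    @classmethod
    def uniform(cls, sequence: str, fraction: float) -> "MethylationState":
        return cls({p: fraction for p in cpg_positions(sequence)})

    def methylated_positions(self) -> set[int]:
        return {p for p, f in self.fractions.items() if f == 1.0}

    def sample(self, rng: np.random.Generator) -> set[int]:
        """One molecule's methylated positions, each CpG independent."""
        return {p for p, f in self.fractions.items() if rng.random() < f}


@dataclass(frozen=True)
class BandTable:
    """Gel bands: fragment length (bp) -> intensity (arbitrary units)."""

    fragment_lengths: tuple[int, ...]
    intensities: tuple[float, ...]
    enzyme: str = ""
    amplicon_id: str = ""

    def __post_init__(self) -> None:
        if len(self.fragment_lengths) != len(self.intensities):
            raise ValueError("lengths and intensities differ in count")
        if any(i < 0 for i in self.intensities):
            raise ValueError("negative band intensity")


@dataclass(frozen=True)
class MethylationCall:
    locus: str
    sample_mean: float
    normal_mean: float
    delta: float
    p_value: float
    verdict: str  # hypomethylation | hypermethylation | unchanged


def bisulfite_convert(sequence: str, methylated: set[int] | MethylationState | None = None,
                      strand: str = "top", failure_rate: float = 0.0,
                      rng: np.random.Generator | None = None) -> str:
    """Bisulfite-convert one strand of ``sequence``.

    Top strand: every C not at a methylated CpG becomes T.  Bottom
    strand: the reverse complement is converted on its own sense, with
    methylated CpGs mapped through the palindromic CpG.  ``failure_rate``
    models incomplete conversion as a per-C retention probability
    (default 0: complete conversion).
    """
    sequence = validate_sequence(sequence)
    if isinstance(methylated, MethylationState):
        methylated = methylated.methylated_positions()
    methylated = set(methylated or ())
    cpgs = set(cpg_positions(sequence))
    for pos in methylated:
        if pos not in cpgs:
            raise ValueError(f"methylated position {pos} is not a CpG start in the sequence")
    if strand == "bottom":
        rc = reverse_complement(sequence)
        mapped = {len(sequence) - p - 2 for p in methylated}
        return bisulfite_convert(rc, mapped, strand="top",
                                 failure_rate=failure_rate, rng=rng)
    if strand != "top":
        raise ValueError("strand must be 'top' or 'bottom'")
    if failure_rate and rng is None:
        raise ValueError("failure_rate > 0 requires an rng")
    out = list(sequence)
    for i, base in enumerate(out):
        if base != "C":
            continue
        if i in methylated:
            continue
        if failure_rate and rng.random() < failure_rate:
            continue
        out[i] = "T"
    return "".join(out)


def in_silico_pcr(converted_template: str, forward_primer: str, reverse_primer: str,
                  cpg_positions_template: list[int] | None = None) -> tuple[str, int, int]:
    """Amplicon between two primers on a converted template.

    Primers must match the converted template exactly and uniquely (the
    forward primer on the given strand, the reverse primer as its
    reverse complement).  A primer whose footprint overlaps a CpG is
    rejected: its annealing would depend on methylation state.  Returns
    ``(amplicon, start, end)`` with the primers included.
    """
    template = validate_sequence(converted_template, name="template")
    fwd = validate_sequence(forward_primer, name="forward primer")
    rev = validate_sequence(reverse_primer, name="reverse primer")
    fwd_sites = [i for i in range(len(template) - len(fwd) + 1)
                 if template[i:i + len(fwd)] == fwd]
    rev_rc = reverse_complement(rev)
    rev_sites = [i for i in range(len(template) - len(rev_rc) + 1)
                 if template[i:i + len(rev_rc)] == rev_rc]
    for label, sites in (("forward", fwd_sites), ("reverse", rev_sites)):
        if len(sites) == 0:
            raise CobraDesignError(f"{label} primer not found on template")
        if len(sites) > 1:
            raise CobraDesignError(f"non-unique {label} primer site ({len(sites)} matches)")
    start = fwd_sites[0]
    end = rev_sites[0] + len(rev_rc)
    if end <= start + len(fwd):
        raise CobraDesignError("reverse primer site does not lie downstream of forward primer")
    if cpg_positions_template:
        spans = [(start, start + len(fwd)), (rev_sites[0], end)]
        for p in cpg_positions_template:
            for s, e in spans:
                if s <= p < e or s <= p + 1 < e:
                    raise CobraDesignError(f"CpG in primer (CpG at template position {p})")
    return template[start:end], start, end


def _site_positions(seq: str, enzyme: EnzymeSpec) -> list[tuple[int, str]]:
    """(start, strand) of every recognition-site occurrence on the
    duplex of ``seq`` (forward pattern on +, its reverse complement on -;
    a palindromic site is reported once per position)."""
    sites = [(off, "+") for off in iter_iupac_matches(seq, enzyme.recognition)]
    rc = reverse_complement(enzyme.recognition)
    if rc != enzyme.recognition:
        sites += [(off, "-") for off in iter_iupac_matches(seq, rc)]
    return sorted(sites)


def classify_enzyme(enzyme: EnzymeSpec, amplicon: str,
                    cpgs: list[int] | None = None) -> tuple[str, list[int]]:
    """Derive the informativeness class of an enzyme for an amplicon.

    The amplicon (unconverted frame) is converted under the two
    extremes: fully unmethylated (U) and fully methylated (M).  Sites
    present only in U make the enzyme unmethylation-indicating
    (TG-class); sites present only in M make it methylation-indicating
    (CG-class); identical site sets (including none) or differential
    sites in both directions are uninformative.  Returns the class and
    the assayed CpG positions: CpGs overlapping a differential site (an
    enzyme may assay two CpGs jointly, e.g. BstUI CGCG).
    """
    amplicon = validate_sequence(amplicon, name="amplicon")
    if cpgs is None:
        cpgs = cpg_positions(amplicon)
    u_seq = bisulfite_convert(amplicon, set())
    m_seq = bisulfite_convert(amplicon, set(cpgs))
    sites_u = set(_site_positions(u_seq, enzyme))
    sites_m = set(_site_positions(m_seq, enzyme))
    only_u, only_m = sites_u - sites_m, sites_m - sites_u
    if only_u and not only_m:
        cls = UNMETHYLATION_INDICATING
    elif only_m and not only_u:
        cls = METHYLATION_INDICATING
    else:
        cls = UNINFORMATIVE
    # assayed CpGs: those overlapping a differential site (an enzyme may
    # assay two CpGs jointly, e.g. BstUI CGCG)
    L = len(enzyme.recognition)
    assayed = sorted({p for p in cpgs
                      for start, _strand in (only_u | only_m)
                      if start <= p + 1 and p < start + L})
    return cls, assayed


def digest(amplicon: str, enzyme: EnzymeSpec,
           methylated: set[int] | MethylationState | None = None) -> list[int]:
    """Fragment lengths after converting ``amplicon`` under the given
    per-molecule methylation and cutting at every recognition site on
    either strand.

    Cut positions falling outside the amplicon (site too near an end
    for the enzyme's reach) are skipped with a warning.  Fragment
    lengths always sum to the amplicon length.
    """
    amplicon = validate_sequence(amplicon, name="amplicon")
    converted = bisulfite_convert(amplicon, methylated)
    cuts = set()
    L = len(enzyme.recognition)
    for start, strand in _site_positions(converted, enzyme):
        cut = start + L + enzyme.cut_offset if strand == "+" else start - enzyme.cut_offset
        if 0 < cut < len(amplicon):
            cuts.add(cut)
        else:
            warnings.warn(
                f"{enzyme.name} site at {start}{strand}: cut position {cut} "
                f"outside amplicon, skipped", stacklevel=2)
    bounds = [0] + sorted(cuts) + [len(amplicon)]
    return sorted(b - a for a, b in zip(bounds, bounds[1:]))


def expected_fragments(amplicon: str, enzyme: EnzymeSpec) -> tuple[list[int], list[int]]:
    """Fragment lengths for the fully-unmethylated and fully-methylated
    alleles (the two gel references for band assignment)."""
    cpgs = set(cpg_positions(amplicon))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return digest(amplicon, enzyme, set()), digest(amplicon, enzyme, cpgs)


def quantify_methylation(bands: BandTable, enzyme_class: str,
                         digested_lengths: list[int], undigested_lengths: list[int],
                         tolerance_bp: int = 2) -> float:
    """Percent methylation from band densitometry.

    Bands are assigned to the digested or undigested allele by fragment
    length within +/- ``tolerance_bp`` (gel resolution); a band matching
    neither is an error.  Because each cut molecule contributes one
    fragment to *each* digested band (and co-migrating fragments pool),
    the digested-molecule signal is the mean over expected digested
    bands of intensity / fragment multiplicity, while the undigested
    signal is the full-length band intensity.  CG-class (methylation-
    indicating): percent = 100 * digested / total; TG-class: percent =
    100 * undigested / total.
    """
    if enzyme_class not in {METHYLATION_INDICATING, UNMETHYLATION_INDICATING}:
        raise ValueError(f"enzyme class {enzyme_class!r} is not quantifiable")
    undig_set = set(undigested_lengths)
    multiplicity = {l: digested_lengths.count(l)
                    for l in set(digested_lengths) - undig_set}
    if not multiplicity:
        raise ValueError("digested and undigested fragment sets are indistinguishable")
    dig_signal: dict[int, float] = {l: 0.0 for l in multiplicity}
    undig_signal = 0.0
    for length, inten in zip(bands.fragment_lengths, bands.intensities):
        near_dig = [l for l in multiplicity if abs(length - l) <= tolerance_bp]
        near_undig = [l for l in undig_set if abs(length - l) <= tolerance_bp]
        if near_dig and not near_undig:
            dig_signal[near_dig[0]] += inten
        elif near_undig and not near_dig:
            undig_signal += inten
        elif near_dig and near_undig:
            raise ValueError(f"band at {length} bp matches both allele patterns")
        else:
            raise ValueError(f"band at {length} bp matches no expected fragment")
    digested = float(np.mean([v / multiplicity[l] for l, v in dig_signal.items()]))
    total = digested + undig_signal
    if total <= 0:
        raise ValueError("total band intensity is zero")
    frac_digested = digested / total
    if enzyme_class == METHYLATION_INDICATING:
        return 100.0 * frac_digested
    return 100.0 * (1.0 - frac_digested)


def call_delta(sample_replicates: list[float], normal_replicates: list[float],
               alpha: float = 0.05, min_delta: float = 10.0,
               locus: str = "") -> MethylationCall:
    """Hypo/hypermethylation call for a sample versus matched normal.

    The verdict is hyper- or hypomethylation only when the mean percent
    difference exceeds ``min_delta`` in magnitude AND a two-sided Welch
    t-test rejects at ``alpha``; otherwise unchanged.  At least two
    replicates per group are required.
    """
    if len(sample_replicates) < 2 or len(normal_replicates) < 2:
        raise ValueError("need >= 2 replicates per group")
    sample = np.asarray(sample_replicates, dtype=float)
    normal = np.asarray(normal_replicates, dtype=float)
    delta = float(sample.mean() - normal.mean())
    if np.allclose(sample, sample[0]) and np.allclose(normal, normal[0]) and np.isclose(sample[0], normal[0]):
        p = 1.0  # identical constant groups: no evidence of change
    else:
        p = float(stats.ttest_ind(sample, normal, equal_var=False).pvalue)
        if np.isnan(p):
            p = 1.0
    if abs(delta) > min_delta and p < alpha:
        verdict = "hypermethylation" if delta > 0 else "hypomethylation"
    else:
        verdict = "unchanged"
    return MethylationCall(locus=locus, sample_mean=float(sample.mean()),
                           normal_mean=float(normal.mean()), delta=delta,
                           p_value=p, verdict=verdict)
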