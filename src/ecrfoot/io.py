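"""File formats: multi-FASTA ortholog collections, BED, TSV libraries.

The ortholog-collection layout is one multi-FASTA with headers
``species|ECRn``; records are grouped by element id.  BED output is
BED6, 0-based half-open.  Motif and enzyme libraries are TSV.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .cobra import EnzymeSpec
from .footprinting import Motif
from .intervals import GenomicInterval


def write_ortholog_fasta(collection: dict[str, dict[str, str]], path: str | Path,
                         header_comment: str = "") -> None:
    """Write a collection {element -> {species -> sequence}} as one
    multi-FASTA with ``species|element`` headers."""
    records = []
    for element, by_species in collection.items():
        for species, seq in by_species.items():
            records.append(SeqRecord(Seq(seq), id=f"{species}|{element}", description=""))
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f";{header_comment}\n")
        SeqIO.write(records, fh, "fasta")


def read_ortholog_fasta(path: str | Path) -> dict[str, dict[str, str]]:
    """Parse a ``species|element`` multi-FASTA into
    {element -> {species -> sequence}} (element order preserved)."""
    text = Path(path).read_text()
    # tolerate leading ';' comment lines
    text = "\n".join(l for l in text.splitlines() if not l.startswith(";"))
    collection: dict[str, dict[str, str]] = {}
    for rec in SeqIO.parse(_io.StringIO(text), "fasta"):
        if "|" not in rec.id:
            raise ValueError(f"header {rec.id!r} not in species|element layout")
        species, element = rec.id.split("|", 1)
        collection.setdefault(element, {})
        if species in collection[element]:
            raise ValueError(f"duplicate record for {species}|{element}")
        collection[element][species] = str(rec.seq).upper()
    return collection


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def write_bed(intervals: list[GenomicInterval], path: str | Path,
              scores: list[float] | None = None) -> None:
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            fh.write(iv.to_bed(scores[i] if scores else 0) + "\n")


def read_bed(path: str | Path) -> list[GenomicInterval]:
    out = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        f = line.split("\t")
        out.append(GenomicInterval(f[0], int(f[1]), int(f[2]),
                                   name=f[3] if len(f) > 3 else "",
                                   strand=f[5] if len(f) > 5 else "."))
    return out


def read_motif_library(path: str | Path) -> list[Motif]:
    """TSV with columns name, pattern[, revcomp_pattern]."""
    df = pd.read_csv(path, sep="\t", comment="#")
    motifs = []
    for _, row in df.iterrows():
        rc = row.get("revcomp_pattern", "")
        motifs.append(Motif(str(row["name"]), str(row["pattern"]),
                            "" if pd.isna(rc) else str(rc)))
    return motifs


def read_enzyme_library(path: str | Path) -> list[EnzymeSpec]:
    """TSV with columns name, recognition, cut_offset."""
    df = pd.read_csv(path, sep="\t", comment="#")
    return [EnzymeSpec(str(r["name"]), str(r["recognition"]), int(r["cut_offset"]))
            for _, r in df.iterrows()]


def write_band_table(lengths, intensities, path: str | Path) -> None:
    pd.DataFrame({"fragment_length_bp": lengths, "intensity": intensities}).to_csv(
        path, sep="\t", index=False)


def read_band_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    if not {"fragment_length_bp", "intensity"} <= set(df.columns):
        raise ValueError("band table needs columns fragment_length_bp, intensity")
    return df
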