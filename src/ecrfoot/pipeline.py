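"""End-to-end orchestration from a single YAML config.

Stages run in dependency order: simulate (or load real inputs) ->
conserved-element calling -> ortholog search / presence matrix ->
footprinting and motif enrichment -> COBRA methylation -> enhancer
profiling.  Every output file carries a header recording the package
version, seed and parameters; the summary JSON aggregates the headline
quantities of each stage.  Identical config + seed gives byte-identical
outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from . import cobra as cobra_mod
from . import conservation, epigenome, footprinting, synthetic
from .intervals import GenomicInterval
from .io import (write_band_table, write_bed, write_fasta, write_ortholog_fasta)

log = logging.getLogger("ecrfoot")

_KNOWN_TOP = {"seed", "outdir", "log_level", "simulate", "conservation",
              "footprinting", "cobra", "epigenome"}
_KNOWN_SIM = {"genome_pair", "orthologs", "tracks", "cobra_gel"}


class ConfigError(ValueError):
    """The run configuration is invalid."""


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    seed: int = 0
    outdir: str = "ecrfoot_run"
    log_level: str = "INFO"
    simulate: dict = field(default_factory=dict)
    conservation: dict = field(default_factory=dict)
    footprinting: dict = field(default_factory=dict)
    cobra: dict = field(default_factory=dict)
    epigenome: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        unknown = set(raw) - _KNOWN_TOP
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        sim = raw.get("simulate", {}) or {}
        unknown_sim = set(sim) - _KNOWN_SIM
        if unknown_sim:
            raise ConfigError(f"unknown simulate keys: {sorted(unknown_sim)}")
        for stage in ("conservation", "footprinting", "cobra", "epigenome"):
            block = raw.get(stage, {}) or {}
            sim_key = {"conservation": "genome_pair", "footprinting": "orthologs",
                       "cobra": "cobra_gel", "epigenome": "tracks"}[stage]
            if "inputs" in block and sim_key in sim:
                raise ConfigError(
                    f"stage {stage!r}: both real inputs and a simulation block given; "
                    f"exactly one is allowed")
        return cls(**raw)


def _header(seed: int, params: dict) -> str:
    return (f"# ecrfoot {__version__} seed={seed} "
            f"params={json.dumps(params, sort_keys=True)}\n")


def run(config: RunConfig) -> dict:
    """Execute all stages; returns the summary dict (also written to
    ``summary.json`` in the output directory)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(
        level=getattr(logging, str(config.log_level).upper(), logging.INFO),
        format="%(asctime)s %(name)s %(levelname)s %(message)s")
    fh = logging.FileHandler(outdir / "run.log")
    fh.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    log.addHandler(fh)
    summary: dict = {"version": __version__, "seed": config.seed}
    try:
        summary.update(_stage_conservation(config, outdir))
        summary.update(_stage_footprinting(config, outdir))
        summary.update(_stage_cobra(config, outdir))
        summary.update(_stage_epigenome(config, outdir))
    finally:
        log.removeHandler(fh)
        fh.close()
    (outdir / "summary.json").write_text(json.dumps(summary, sort_keys=True, indent=2) + "\n")
    return summary


def _stage_conservation(config: RunConfig, outdir: Path) -> dict:
    stage = "conservation"
    try:
        params = conservation.ConservationParams(
            **{k: v for k, v in config.conservation.items() if k != "inputs"})
        sim = dict(config.simulate.get("genome_pair", {}))
        cfg = synthetic.SimulationConfig(seed=config.seed, **sim)
        log.info("[conservation] simulating genome pair and calling elements")
        genomeA, genomeB, truth = synthetic.generate_genome_pair(cfg)
        elements = conservation.find_conserved_elements(genomeA, genomeB, params,
                                                        ref_name="genomeA",
                                                        query_name="genomeB")
        with open(outdir / "elements.tsv", "w") as out:
            out.write(_header(config.seed, {"min_length": params.min_length,
                                            "min_identity": params.min_identity}))
            out.write("id\tref_start\tref_end\tquery_start\tquery_end\tlength\tidentity\n")
            for e in elements:
                out.write(f"{e.id}\t{e.interval_ref.start}\t{e.interval_ref.end}\t"
                          f"{e.interval_query.start}\t{e.interval_query.end}\t"
                          f"{e.length}\t{e.identity:.4f}\n")
        write_bed([e.interval_ref for e in elements], outdir / "elements.bed")
        write_fasta({"genomeA": genomeA, "genomeB": genomeB}, outdir / "genomes.fa")
        recovered = sum(
            1 for t in truth.elements_ref
            if any(e.interval_ref.reciprocal_overlap(t) >= 0.8 for e in elements))
        return {"n_elements_called": len(elements),
                "n_elements_planted": len(truth.elements_ref),
                "planted_recovery": recovered / max(1, len(truth.elements_ref))}
    except (ConfigError,):
        raise
    except Exception as exc:  # pragma: no cover - failure path
        raise StageError(f"stage {stage} failed: {exc}") from exc


def _stage_footprinting(config: RunConfig, outdir: Path) -> dict:
    stage = "footprinting"
    try:
        sim = dict(config.simulate.get("orthologs", {}))
        n_sets = int(sim.pop("n_sets", 3))
        min_fp = int(config.footprinting.get("min_footprint_length", 6))
        log.info("[footprinting] simulating %d ortholog sets", n_sets)
        collection: dict[str, dict[str, str]] = {}
        for i in range(1, n_sets + 1):
            cfg = synthetic.SimulationConfig(
                seed=config.seed * 100 + i,
                planted_motifs=[("CAGCTG", 40), ("GGGATTA", 120)],
                **sim)
            seqs, _ = synthetic.generate_ortholog_set(cfg)
            collection[f"ECR{i}"] = seqs
        write_ortholog_fasta(collection, outdir / "ortholog_sets.fa",
                             header_comment=f"ecrfoot {__version__} seed={config.seed}")
        hits_by_element = {}
        n_footprints = 0
        presence_hits = []
        cons_params = conservation.ConservationParams(
            **{k: v for k, v in config.conservation.items() if k != "inputs"})
        for element, seqs in collection.items():
            reference = next(iter(seqs))
            msa = footprinting.align_ortholog_set(seqs, reference)
            n_footprints += len(footprinting.find_invariant_regions(msa, min_fp))
            hits_by_element[element] = {
                sp: footprinting.scan_motifs(s) for sp, s in seqs.items()}
            probe = seqs[reference]
            for sp, s in seqs.items():
                for h in conservation.ortholog_search(probe, s, cons_params,
                                                      probe_id=element, species=sp):
                    presence_hits.append(h)
        matrix = conservation.build_presence_matrix(presence_hits)
        matrix.to_csv(outdir / "presence_matrix.tsv", sep="\t")
        freq = footprinting.motif_frequency_matrix(hits_by_element)
        with open(outdir / "motif_matrix.tsv", "w") as out:
            out.write(_header(config.seed, {"min_footprint_length": min_fp}))
            freq.to_csv(out, sep="\t", index=False)
        enriched = freq[freq.enriched]
        return {"n_footprint_regions": n_footprints,
                "mean_species_count": matrix.attrs["mean_species_count"],
                "enriched_cells": sorted(map(tuple, enriched[["element", "motif"]].values.tolist()))}
    except Exception as exc:
        raise StageError(f"stage {stage} failed: {exc}") from exc


def _stage_cobra(config: RunConfig, outdir: Path) -> dict:
    stage = "cobra"
    try:
        block = dict(config.cobra)
        gel = dict(config.simulate.get("cobra_gel", {}))
        alpha = float(block.get("alpha", 0.05))
        min_delta = float(block.get("min_delta", 10.0))
        normal_fraction = float(gel.get("normal_fraction", 0.1))
        tumor_fraction = float(gel.get("tumor_fraction", 0.6))
        n_molecules = int(gel.get("n_molecules", 5000))
        noise_sd = float(gel.get("noise_sd", 0.02))
        n_replicates = int(gel.get("n_replicates", 3))
        rng = synthetic._stable_stream(config.seed, "cobra-stage")
        amplicon = design_single_cpg_amplicon(rng)
        enzyme = next(e for e in cobra_mod.DEFAULT_ENZYME_LIBRARY if e.name == "TaqI")
        cls, _ = cobra_mod.classify_enzyme(enzyme, amplicon)
        dig_u, dig_m = cobra_mod.expected_fragments(amplicon, enzyme)
        verdicts = {}
        reps = {}
        for label, frac in (("normal", normal_fraction), ("tumor", tumor_fraction)):
            vals = []
            for r in range(n_replicates):
                bands, _ = synthetic.generate_cobra_gel(
                    amplicon, frac, enzyme, n_molecules=n_molecules,
                    noise_sd=noise_sd, seed=config.seed * 10 + r + (0 if label == "normal" else 5))
                write_band_table(bands.fragment_lengths, bands.intensities,
                                 outdir / f"gel_{label}_rep{r}.tsv")
                vals.append(cobra_mod.quantify_methylation(bands, cls, dig_m, dig_u))
            reps[label] = vals
        call = cobra_mod.call_delta(reps["tumor"], reps["normal"], alpha=alpha,
                                    min_delta=min_delta, locus="sim_locus")
        verdicts["sim_locus"] = call.verdict
        log.info("[cobra] %s: normal %.1f%%, tumor %.1f%% -> %s",
                 call.locus, call.normal_mean, call.sample_mean, call.verdict)
        return {"methylation_verdicts": verdicts,
                "percent_methylation": {k: [round(v, 2) for v in vs] for k, vs in reps.items()},
                "enzyme_class": cls}
    except Exception as exc:
        raise StageError(f"stage {stage} failed: {exc}") from exc


def design_single_cpg_amplicon(rng, left_len: int = 80, right_len: int = 140) -> str:
    """A random amplicon whose only CpG sits inside one TaqI site
    (``TCGA``), placed off-centre so the digested fragments resolve
    from the undigested band; the flanks are CpG-free so primers can
    land anywhere in them."""
    from .seqs import random_sequence
    while True:
        left = random_sequence(left_len, rng).replace("CG", "CT")
        right = random_sequence(right_len, rng).replace("CG", "CT")
        amplicon = left + "TCGA" + right
        if amplicon.count("CG") == 1:  # only the planted assayed CpG
            return amplicon


def _stage_epigenome(config: RunConfig, outdir: Path) -> dict:
    stage = "epigenome"
    try:
        block = dict(config.epigenome)
        criterion = epigenome.BreadthCriterion(block.get("breadth_criterion", "either"))
        min_overlap = int(block.get("min_overlap", 1))
        tr = dict(config.simulate.get("tracks", {}))
        tissues = list(tr.get("tissues", ["brain", "liver", "thymus", "limb"]))
        n_elem = int(tr.get("n_elements", 4))
        elements = [GenomicInterval("chr7", 1000 + 2000 * i, 1200 + 2000 * i, name=f"ECR{i + 1}")
                    for i in range(n_elem)]
        rng = synthetic._stable_stream(config.seed, "epigenome-stage")
        state_names = ["active", "poised", "acetyl_only", "none"]
        assignment = {}
        for e in elements:
            for t in tissues:
                s = state_names[int(rng.integers(0, 4))]
                assignment[(e.name, t)] = (s, bool(rng.integers(0, 2)))
        tracks, truth = synthetic.generate_tissue_tracks(elements, tissues, assignment,
                                                         seed=config.seed)
        profile = epigenome.profile_elements(elements, tracks, min_overlap=min_overlap)
        with open(outdir / "state_matrix.tsv", "w") as out:
            out.write(_header(config.seed, {"breadth_criterion": criterion.value}))
            profile.to_csv(out, sep="\t", index=False)
        breadth = {}
        for e in elements:
            sub = profile[profile.element == e.name]
            states = {r.tissue: epigenome.EnhancerState(r.state) for r in sub.itertuples()}
            hypo = {r.tissue: bool(r.hypomethylated) for r in sub.itertuples()}
            breadth[e.name] = epigenome.call_breadth(states, hypo, element=e.name,
                                                     criterion=criterion).call
        exact = all(
            (truth.tissue_states[t][e.name] ==
             (profile[(profile.tissue == t) & (profile.element == e.name)].state.iloc[0],
              bool(profile[(profile.tissue == t) & (profile.element == e.name)].hypomethylated.iloc[0])))
            for t in tissues for e in elements)
        return {"breadth_calls": breadth, "state_truth_recovered": bool(exact)}
    except Exception as exc:
        raise StageError(f"stage {stage} failed: {exc}") from exc
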