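"""End-to-end orchestration: simulate/load -> trim -> map -> quantify ->
signatures -> copy number -> insertion & origin calls -> report.

Configuration is a single YAML document validated against a pydantic schema
before any compute; every module threshold has a config home with a
documented default. Runs are deterministic per seed and emit a JSON report
plus TSV tables and bedGraph tracks.

Reads are mapped twice on purpose: once against the TE consensus set
(fractional multi-mapper weighting; TE-level levels, profiles, signatures)
and once against the genome (unique-read discipline; insertion-level
attribution). Pooling both reference sets into one search would mark every
TE-derived read as a multi-mapper and void both analyses.
"""

from __future__ import annotations

import hashlib
import json
import os
from typing import Optional

import pandas as pd
import yaml
from pydantic import BaseModel, Field, model_validator

from . import __version__
from .copy_number import copy_number_table, estimate_copy_number, unique_region_coverage
from .io import (
    load_reference_set,
    read_reads,
    write_bedgraph,
    write_fastq,
    write_reference_set,
)
from .mapping import map_reads
from .models import ReferenceSet, SimConfig
from .quantify import (
    DEFAULT_REFERENCE_TES,
    NormalizationFactor,
    density_profile,
    deposition_index,
    te_pirna_level,
)
from .signatures import phasing_zscore, pingpong_zscore
from .source_loci import CallParams, call_insertion, classify_origin
from .strain import (
    build_synthetic_strain,
    simulate_embryo_library,
    simulate_genomic_library,
    simulate_ovary_library,
)
from .trim import collapse_reads, trim_adapter_and_random_nt


class SimulateSettings(BaseModel):
    """Synthetic-strain block: one antisense 3'-UTR unistrand source, one
    silent full-length copy, one dual-strand germline source, and six
    germline reference TEs (see `pirnakit.strain`)."""

    utr_orientation: str = "antisense"
    n_unistrand: int = 2500
    n_germ_pairs: int = 400
    n_reference_pairs: int = 250
    n_mirna: int = 20_000
    dna_coverage: float = 30.0
    dna_read_length: int = 100
    u1_bias: float = 0.75
    phasing_tightness: float = 0.8
    pingpong_pair_fraction: float = 0.8
    with_embryo: bool = True


class InputPaths(BaseModel):
    """File-driven run: pre-existing references, annotations and reads."""

    genome_fasta: str
    te_fasta: str
    insertions_bed: Optional[str] = None
    genes_gff3: Optional[str] = None
    unique_regions_bed: Optional[str] = None
    mirnas_bed: str  # normalisation is mandatory
    ovary_reads: str
    embryo_reads: Optional[str] = None
    dna_reads: Optional[str] = None
    adapter: Optional[str] = None  # set for untrimmed input
    random_nt: int = 4


class AnalysisParams(BaseModel):
    max_mismatches: int = 2
    min_len: int = 23
    max_len: int = 32
    weighting: str = "fractional"
    pingpong_d_max: int = 30
    phasing_d_max: int = 50
    min_pairs: float = 100.0
    flank_window: int = 2000
    antisense_min: float = 0.8
    dual_min_fraction: float = 0.2
    min_read_weight: float = 20.0
    deposition_somatic_max: float = 0.2
    deposition_germline_low: float = 0.5
    deposition_germline_high: float = 2.0
    reference_tes: tuple[str, ...] = DEFAULT_REFERENCE_TES

    def call_params(self) -> CallParams:
        return CallParams(
            flank_window=self.flank_window,
            min_len=self.min_len,
            max_len=self.max_len,
            antisense_min=self.antisense_min,
            dual_min_fraction=self.dual_min_fraction,
            min_read_weight=self.min_read_weight,
            min_pairs=self.min_pairs,
            deposition_somatic_max=self.deposition_somatic_max,
            deposition_germline_range=(
                self.deposition_germline_low,
                self.deposition_germline_high,
            ),
        )


class RunConfig(BaseModel):
    seed: int = 0
    outdir: str = "results/run"
    simulate: Optional[SimulateSettings] = None
    inputs: Optional[InputPaths] = None
    params: AnalysisParams = Field(default_factory=AnalysisParams)

    @model_validator(mode="after")
    def _exactly_one_source(self) -> "RunConfig":
        if (self.simulate is None) == (self.inputs is None):
            raise ValueError("config must set exactly one of 'simulate' or 'inputs'")
        return self

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))

    def config_hash(self) -> str:
        blob = json.dumps(self.model_dump(), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def count_mirna_reads(genome_alignments: pd.DataFrame, refset: ReferenceSet) -> float:
    """Reads attributable to annotated miRNA loci (strand-matched, within
    2 nt of the locus bounds): the normalisation denominator."""
    total = 0.0
    for m in refset.mirnas:
        sub = genome_alignments[
            (genome_alignments["ref_name"] == m.chrom)
            & (genome_alignments["strand"] == m.strand)
            & (genome_alignments["start"] >= m.start - 2)
            & (genome_alignments["end"] <= m.end + 2)
        ]
        total += float(sub["copies"].sum())
    if total == 0:
        raise ValueError("no reads map to annotated miRNA loci; cannot normalise")
    return total


def _check_inputs(inputs: InputPaths) -> None:
    for name, path in inputs.model_dump().items():
        if isinstance(path, str) and name.endswith(("_fasta", "_bed", "_gff3", "_reads")):
            if not os.path.exists(path):
                raise FileNotFoundError(f"input '{name}' not found: {path}")


def _acquire(config: RunConfig):
    """ReferenceSet + read libraries, either simulated or loaded."""
    if config.simulate is not None:
        s = config.simulate
        strain = build_synthetic_strain(config.seed, utr_orientation=s.utr_orientation)
        base = SimConfig(
            seed=config.seed,
            u1_bias=s.u1_bias,
            phasing_tightness=s.phasing_tightness,
            pingpong_pair_fraction=s.pingpong_pair_fraction,
        )
        ovary = simulate_ovary_library(
            strain, s.n_unistrand, s.n_germ_pairs, s.n_reference_pairs, s.n_mirna, base
        )
        embryo = (
            simulate_embryo_library(strain, s.n_germ_pairs, s.n_reference_pairs, s.n_mirna, base)
            if s.with_embryo
            else None
        )
        dna = (
            simulate_genomic_library(strain, s.dna_coverage, s.dna_read_length)
            if s.dna_coverage > 0
            else None
        )
        return strain.refset, ovary, embryo, dna, strain
    inputs = config.inputs
    _check_inputs(inputs)
    refset = load_reference_set(
        inputs.genome_fasta,
        inputs.te_fasta,
        inputs.insertions_bed,
        inputs.genes_gff3,
        inputs.unique_regions_bed,
        inputs.mirnas_bed,
    )
    if not refset.mirnas:
        raise ValueError("miRNA annotation is empty; cannot normalise")

    def load(path):
        if path is None:
            return None
        reads = read_reads(path)
        if inputs.adapter is not None:
            reads, _ = trim_adapter_and_random_nt(reads, inputs.adapter, inputs.random_nt)
        return reads

    return refset, load(inputs.ovary_reads), load(inputs.embryo_reads), load(inputs.dna_reads), None


def _library_tables(reads, refset: ReferenceSet, params: AnalysisParams):
    col = collapse_reads(reads)
    genome_aln = map_reads(col, refset.genome, params.max_mismatches)
    te_aln = map_reads(col, refset.te_consensi, params.max_mismatches)
    norm = NormalizationFactor(int(count_mirna_reads(genome_aln, refset)))
    return genome_aln, te_aln, norm


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; returns the report dict (also written to
    ``<outdir>/report.json`` with TSV/bedGraph side outputs)."""
    refset, ovary, embryo, dna, strain = _acquire(config)
    params = config.params
    os.makedirs(config.outdir, exist_ok=True)
    write_reference_set(refset, os.path.join(config.outdir, "references"))
    if config.simulate is not None:
        write_fastq(ovary, os.path.join(config.outdir, "references", "ovary.fastq"))

    g_ov, t_ov, norm_ov = _library_tables(ovary, refset, params)

    levels = []
    signatures = []
    profiles_dir = os.path.join(config.outdir, "profiles")
    os.makedirs(profiles_dir, exist_ok=True)
    per_te = {}
    for name, te in refset.te_consensi.items():
        sense = te_pirna_level(t_ov, te, norm_ov, "sense", params.min_len, params.max_len)
        anti = te_pirna_level(t_ov, te, norm_ov, "antisense", params.min_len, params.max_len)
        pp = pingpong_zscore(t_ov, name, params.weighting, params.pingpong_d_max, params.min_pairs)
        ph = phasing_zscore(t_ov, name, params.weighting, params.phasing_d_max, params.min_pairs)
        per_te[name] = (sense, anti, pp, ph)
        levels.append(
            {"te_name": name, "tissue": "ovary", "sense_level": sense, "antisense_level": anti}
        )
        signatures.append(
            {
                "te_name": name,
                "pingpong_z": pp.zscore,
                "pingpong_p": pp.pvalue,
                "pingpong_tier": pp.tier,
                "pingpong_percent": pp.pingpong_percent,
                "phasing_z": ph.zscore,
                "phasing_p": ph.pvalue,
                "phasing_tier": ph.tier,
                "n_pairs": pp.n_pairs,
            }
        )
        prof = density_profile(
            t_ov, te, norm_ov, "coverage", params.weighting, params.min_len, params.max_len
        )
        write_bedgraph(prof.sense, name, os.path.join(profiles_dir, f"{name}.sense.bedgraph"))
        write_bedgraph(-prof.antisense, name, os.path.join(profiles_dir, f"{name}.antisense.bedgraph"))

    deposition = None
    if embryo is not None:
        _, t_em, norm_em = _library_tables(embryo, refset, params)
        ov_lv = {
            n: te_pirna_level(t_ov, te, norm_ov, "both", params.min_len, params.max_len)
            for n, te in refset.te_consensi.items()
        }
        em_lv = {
            n: te_pirna_level(t_em, te, norm_em, "both", params.min_len, params.max_len)
            for n, te in refset.te_consensi.items()
        }
        deposition = deposition_index(ov_lv, em_lv, tuple(params.reference_tes))
        for row in levels.copy():
            levels.append(
                {
                    "te_name": row["te_name"],
                    "tissue": "embryo",
                    "sense_level": te_pirna_level(
                        t_em,
                        refset.te_consensi[row["te_name"]],
                        norm_em,
                        "sense",
                        params.min_len,
                        params.max_len,
                    ),
                    "antisense_level": em_lv[row["te_name"]],
                }
            )

    copy_numbers = None
    if dna is not None and refset.unique_regions:
        dna_col = collapse_reads(dna)
        d_te = map_reads(dna_col, refset.te_consensi, params.max_mismatches)
        d_g = map_reads(dna_col, refset.genome, params.max_mismatches)
        chrom_lengths = {c: len(s) for c, s in refset.genome.items()}
        uc = unique_region_coverage(d_g, refset.unique_regions, chrom_lengths)
        copy_numbers = estimate_copy_number(d_te, refset.te_consensi, uc)

    call_params = params.call_params()
    insertion_calls = []
    for ins in refset.insertions:
        c = call_insertion(
            ins, g_ov, refset.genes, norm_ov, call_params, len(refset.genome[ins.chrom])
        )
        insertion_calls.append(
            {
                "te_name": ins.te_name,
                "chrom": ins.chrom,
                "start": ins.start,
                "end": ins.end,
                "context": ins.context,
                "orientation": c.orientation,
                "host_gene": c.host_gene,
                "call": c.call,
                "antisense_fraction": c.antisense_fraction,
                "unique_ppm_inside": c.unique_ppm_inside,
                "unique_ppm_up": c.unique_ppm_up,
                "unique_ppm_down": c.unique_ppm_down,
                "phasing_z": c.phasing.zscore,
                "phasing_tier": c.phasing.tier,
            }
        )

    origin_calls = []
    for name, (sense, anti, pp, ph) in per_te.items():
        dep = deposition.get(name) if deposition is not None else None
        oc = classify_origin(name, sense, anti, pp, ph, dep, call_params)
        origin_calls.append(
            {
                "te_name": name,
                "origin": oc.origin,
                "antisense_fraction": oc.antisense_fraction,
                "pingpong_tier": pp.tier,
                "phasing_tier": ph.tier,
                "deposition_index": dep.index if dep is not None else None,
                "flags": ",".join(oc.flags),
            }
        )

    report = {
        "provenance": {
            "pirnakit_version": __version__,
            "config_hash": config.config_hash(),
            "seed": config.seed,
        },
        "normalization": {"ovary_mirna_reads": norm_ov.mirna_reads},
        "te_levels": levels,
        "signatures": signatures,
        "copy_numbers": (
            copy_number_table(copy_numbers).to_dict("records") if copy_numbers else None
        ),
        "insertion_calls": insertion_calls,
        "origin_calls": origin_calls,
        "deposition": (
            {
                n: {"ovary": d.ovary_ppm, "embryo": d.embryo_ppm, "index": d.index}
                for n, d in deposition.items()
            }
            if deposition is not None
            else None
        ),
    }

    def dump(name: str, rows):
        if rows:
            pd.DataFrame(rows).to_csv(
                os.path.join(config.outdir, name), sep="\t", index=False, float_format="%.6g"
            )

    dump("te_levels.tsv", levels)
    dump("signatures.tsv", signatures)
    dump("insertion_calls.tsv", insertion_calls)
    dump("origin_calls.tsv", origin_calls)
    if copy_numbers:
        copy_number_table(copy_numbers).to_csv(
            os.path.join(config.outdir, "copy_number.tsv"), sep="\t", index=False,
            float_format="%.6g",
        )
    with open(os.path.join(config.outdir, "report.json"), "w") as fh:
        json.dump(report, fh, indent=2, default=float)
    return report
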