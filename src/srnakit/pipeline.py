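"""End-to-end run orchestration: simulate or ingest, process, quantify, report.

A run is a pure function of (inputs, config, seed).  Stages execute in the
order the wet protocol implies — acquire reads (simulator or FASTQ) ->
demultiplex -> trim -> collapse -> quantify -> statistics — and produce a
JSON-serializable report: per-status read counts, dimer fraction, length
histograms (hierarchy tiers when a genome reference is given), replicate
dispersion summaries, truth correlations when simulating, and a DE table
when conditions are declared.  Identical seeds give identical reports.
"""

from __future__ import annotations

import configparser
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import readproc, simulate, stats
from .quantify import CountMatrix, ReferenceIndex, count_features, length_distribution
from .simulate import Dist, LibraryLayout, SimConfig

__all__ = ["RunConfig", "run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and offending record."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    # layout
    adapter3: str = simulate.DEFAULT_ADAPTER3
    barcode_len: int = 4
    umi_len: int = 8
    min_insert: int = 15
    read_length: int = 50
    # samples: name -> 4-nt barcode
    barcodes: dict[str, str] = field(
        default_factory=lambda: {"s1": "ACGT", "s2": "TGCA"}
    )
    # references (FASTA paths); optional — simulation derives a miRNA set
    mirna_fasta: str | None = None
    p21u_fasta: str | None = None
    genome_fasta: str | None = None
    # thresholds
    min_fold_change: float = 5.0
    max_padj: float = 0.01
    min_keep: float = 40.0
    max_remove: float = 5.0
    # simulation
    simulate: bool = True
    n_species: int = 150
    n_reads: int = 10_000
    pcr_cycles: int = 12
    dimer_fraction: float = 0.01
    seq_error_rate: float = 0.0
    class_mix: dict[str, float] = field(
        default_factory=lambda: {"miRNA": 0.6, "p21U": 0.2, "primary_siRNA": 0.2}
    )
    rpph_treated: bool = False
    # DE: condition -> list of sample names (optional)
    conditions: dict[str, list[str]] = field(default_factory=dict)
    seed: int = 0
    outdir: str | None = None

    def validate(self) -> None:
        for sample, bc in self.barcodes.items():
            if len(bc) != self.barcode_len:
                raise PipelineError("config", f"barcode {bc!r} for {sample}")
        if len(set(self.barcodes.values())) != len(self.barcodes):
            raise PipelineError("config", "duplicate barcodes")
        for label in ("mirna_fasta", "p21u_fasta", "genome_fasta"):
            path = getattr(self, label)
            if path is not None and not Path(path).exists():
                raise PipelineError("config", f"missing reference: {label}={path}")
        if not self.simulate and self.mirna_fasta is None:
            raise PipelineError(
                "config", "ingest mode needs a miRNA reference FASTA"
            )
        for cond, members in self.conditions.items():
            for s in members:
                if s not in self.barcodes:
                    raise PipelineError("config", f"unknown sample {s} in {cond}")

    @classmethod
    def from_ini(cls, path: str | Path) -> "RunConfig":
        """Load a sectioned key/value config file.

        Sections: [layout], [thresholds], [simulate], [samples] (name =
        barcode), [references], [conditions] (name = comma-separated
        samples), [run] (seed, outdir).
        """
        parser = configparser.ConfigParser()
        parser.read(path)
        kw: dict = {}
        g = lambda sec, key, cast, default: (
            cast(parser[sec][key]) if parser.has_option(sec, key) else default
        )
        kw["adapter3"] = g("layout", "adapter3", str, simulate.DEFAULT_ADAPTER3)
        kw["barcode_len"] = g("layout", "barcode_len", int, 4)
        kw["umi_len"] = g("layout", "umi_len", int, 8)
        kw["min_insert"] = g("layout", "min_insert", int, 15)
        kw["read_length"] = g("layout", "read_length", int, 50)
        kw["min_fold_change"] = g("thresholds", "min_fold_change", float, 5.0)
        kw["max_padj"] = g("thresholds", "max_padj", float, 0.01)
        kw["min_keep"] = g("thresholds", "min_keep", float, 40.0)
        kw["max_remove"] = g("thresholds", "max_remove", float, 5.0)
        kw["simulate"] = g("simulate", "enabled", lambda v: v.lower() == "true", True)
        kw["n_species"] = g("simulate", "n_species", int, 150)
        kw["n_reads"] = g("simulate", "n_reads", int, 10_000)
        kw["pcr_cycles"] = g("simulate", "pcr_cycles", int, 12)
        kw["dimer_fraction"] = g("simulate", "dimer_fraction", float, 0.01)
        kw["seq_error_rate"] = g("simulate", "seq_error_rate", float, 0.0)
        kw["rpph_treated"] = g(
            "simulate", "rpph_treated", lambda v: v.lower() == "true", False
        )
        if parser.has_section("samples"):
            kw["barcodes"] = {k: v.strip().upper() for k, v in parser["samples"].items()}
        for label in ("mirna_fasta", "p21u_fasta", "genome_fasta"):
            kw[label] = g("references", label, str, None)
        if parser.has_section("conditions"):
            kw["conditions"] = {
                k: [s.strip() for s in v.split(",")]
                for k, v in parser["conditions"].items()
            }
        kw["seed"] = g("run", "seed", int, 0)
        kw["outdir"] = g("run", "outdir", str, None)
        return cls(**kw)


def _simulate_samples(config: RunConfig):
    """One shared population, one library per sample barcode."""
    sim_seeds = np.random.SeedSequence(config.seed).generate_state(
        len(config.barcodes) + 1
    ) % (2**31)
    base = SimConfig(
        seed=int(sim_seeds[0]),
        pcr_cycles=config.pcr_cycles,
        n_reads=config.n_reads,
        dimer_fraction=config.dimer_fraction,
        seq_error_rate=config.seq_error_rate,
    )
    population = simulate.make_population(base, config.class_mix, config.n_species)
    reads: list[tuple[str, str]] = []
    truths: dict[str, dict] = {}
    for i, (sample, bc) in enumerate(sorted(config.barcodes.items())):
        layout = LibraryLayout(
            barcode=bc,
            umi_length=config.umi_len,
            adapter3=config.adapter3,
            read_length=config.read_length,
            rpph_treated=config.rpph_treated,
        )
        lib = simulate.simulate_library(
            population,
            layout,
            SimConfig(
                seed=int(sim_seeds[i + 1]),
                pcr_cycles=config.pcr_cycles,
                n_reads=config.n_reads,
                dimer_fraction=config.dimer_fraction,
                seq_error_rate=config.seq_error_rate,
            ),
        )
        reads.extend((f"{sample}:{n}", s) for n, s in lib.reads)
        truths[sample] = {t.seq_id: t for t in lib.truth}
    return population, reads, truths


def run_pipeline(config: RunConfig, fastq: str | Path | None = None) -> dict:
    """Execute the full pipeline and return the run report (a dict).

    ``fastq`` ingests an existing multiplexed library; otherwise the
    simulator provides reads plus ground truth, and truth correlations are
    added to the report.
    """
    config.validate()

    population = None
    truths: dict[str, dict] = {}
    if fastq is not None:
        reads = list(readproc.read_fastq(fastq))
    elif config.simulate:
        population, reads, truths = _simulate_samples(config)
    else:
        raise PipelineError("input", "no FASTQ given and simulation disabled")
    if not reads:
        raise PipelineError("input", "no reads")

    # demultiplex -> trim -> collapse
    bc_to_sample = {bc: s for s, bc in config.barcodes.items()}
    demuxed = readproc.demultiplex(reads, bc_to_sample)
    per_sample: dict[str, dict] = {}
    weights_raw: dict[str, dict[str, float]] = {}
    weights_col: dict[str, dict[str, float]] = {}
    for sample in sorted(config.barcodes):
        processed = readproc.process_reads(
            demuxed[sample],
            sample,
            config.adapter3,
            barcode_len=config.barcode_len,
            umi_len=config.umi_len,
            min_insert=config.min_insert,
        )
        ok = [r for r in processed if r.status == readproc.STATUS_OK]
        coll = readproc.collapse(ok, config.barcode_len, config.umi_len)
        status_counts = {
            s: sum(1 for r in processed if r.status == s)
            for s in ("ok", "dimer", "no_adapter", "too_short")
        }
        per_sample[sample] = {
            "reads": len(processed),
            "status_counts": status_counts,
            "dimer_fraction": (
                readproc.dimer_fraction(processed) if processed else 0.0
            ),
        }
        weights_raw[sample] = {k: float(v) for k, v in coll.raw_counts.items()}
        weights_col[sample] = {k: float(v) for k, v in coll.collapsed_counts.items()}

    # references
    if config.mirna_fasta is not None:
        mirna_index = ReferenceIndex.from_fasta(config.mirna_fasta, "miRNA")
    elif population is not None:
        mirna_index = ReferenceIndex(
            {
                sp.seq_id: sp.insert_dna
                for sp in population
                if sp.species_class == "miRNA"
            },
            name="miRNA",
        )
    else:
        mirna_index = None

    report: dict = {
        "seed": config.seed,
        "samples": per_sample,
        "undetermined_reads": len(demuxed.get("undetermined", [])),
        "length_distribution": {
            sample: {
                str(k): v
                for k, v in length_distribution(weights_raw[sample]).items()
            }
            for sample in sorted(config.barcodes)
        },
    }

    matrices: dict[str, CountMatrix] = {}
    if mirna_index is not None:
        for flavor, weights in (("raw", weights_raw), ("collapsed", weights_col)):
            matrices[flavor] = count_features(weights, mirna_index, flavor, max_hits=1)

        # replicate dispersion summary over all samples, both flavors
        disp_summary = {}
        for flavor, mat in matrices.items():
            if mat.counts.shape[1] >= 2 and len(mat.counts):
                norm = stats.normalize_counts(mat.counts, pseudocount=1.0)
                recs = stats.dispersion_table(norm)
                disp_summary[flavor] = {
                    "n_features": len(recs),
                    "mean_dispersion": (
                        float(
                            np.mean(
                                [r.dispersion for r in recs if np.isfinite(r.dispersion)]
                            )
                        )
                        if recs
                        else None
                    ),
                }
        report["dispersion"] = disp_summary

        if truths:
            report["truth_correlation"] = _truth_correlations(matrices, truths)

        if config.conditions and len(config.conditions) == 2:
            (name_a, cond_a), (name_b, cond_b) = sorted(config.conditions.items())
            de = stats.de_test(
                matrices["collapsed"].counts,
                cond_a,
                cond_b,
                min_fold_change=config.min_fold_change,
                max_padj=config.max_padj,
            )
            report["de"] = {
                "reference": name_a,
                "contrast": name_b,
                "n_up": sum(1 for r in de if r.call == "up"),
                "n_down": sum(1 for r in de if r.call == "down"),
                "results": [r.__dict__ for r in de],
            }

    if config.outdir:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for flavor, mat in matrices.items():
            mat.to_tsv(outdir / f"counts_{flavor}.tsv")
        (outdir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report


def _truth_correlations(matrices: dict[str, CountMatrix], truths: dict) -> dict:
    """Spearman correlation of per-sample counts against ligated truth."""
    out: dict = {}
    for flavor, mat in matrices.items():
        rhos = []
        for sample in mat.counts.columns:
            truth = truths.get(sample)
            if not truth:
                continue
            feats = [f for f in mat.counts.index if f in truth]
            if len(feats) < 3:
                continue
            observed = mat.counts.loc[feats, sample].to_numpy()
            expected = np.array([truth[f].ligated_count for f in feats], dtype=float)
            rho = sps.spearmanr(observed, expected).statistic
            if np.isfinite(rho):
                rhos.append(float(rho))
        out[flavor] = float(np.mean(rhos)) if rhos else None
    return out
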