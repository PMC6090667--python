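# srnakit

A toolkit for gel-free small RNA sequencing: planning SPRI-bead size
selections for fragments shorter than 100 nt, and processing the resulting
UMI-barcoded libraries from raw FASTQ to quantified, duplicate-corrected
expression with replicate and differential-expression statistics.

## Who this is for

Small RNAs (20–30 nt: miRNAs, siRNAs, piRNA/21U-RNAs) are hard to
sequence quantitatively. Gel purification is slow and lossy; the PCR
amplification every low-input protocol needs is biased per template; and
adapter ligation prefers some molecules over others. A gel-free protocol
addresses the first problem with two-step size selection on SPRI
paramagnetic beads (carboxylated beads that bind nucleic acid in a
PEG/isopropanol crowding mix, with a length-dependent efficiency tuned by
the isopropanol concentration), and the second with 8-nt unique molecular
identifiers (UMIs) ligated to each molecule before amplification, so PCR
duplicates can be collapsed back to molecule counts.

`srnakit` implements the computational side of such an experiment:

* **`srnakit.spri`** — an empirical calibration of ssDNA binding
  efficiency (19–66 nt × 30–54.5% isopropanol at fixed 7.5% PEG), the
  bench mixing equation `X + 5PV/100 + QV/100 = V` for a 20% PEG stock,
  a planner that picks the lowest isopropanol concentration binding the
  longer fragment at ≥ 40% while the shorter stays ≤ 5%, and a
  deterministic two-step selection simulator.
* **`srnakit.simulate`** — a ground-truth library simulator: reads laid
  out as `[4-nt barcode][8-nt UMI][insert][3′ adapter]`, species classes
  with their hallmark constraints (21U: 21 nt, 5′ U; primary siRNA:
  26 nt, 5′ G; secondary siRNA: 5′ triphosphate, only ligatable after
  RppH treatment), ligation bias, exact Galton–Watson PCR with
  per-template efficiency, UMI collisions, adapter dimers, sequencing
  errors.
* **`srnakit.readproc`** — demultiplexing on the exact 4-nt prefix,
  3′-adapter trimming by 1-nt scanning from the 3′ end, read status
  classification (ok / dimer / no-adapter / too-short), and UMI
  collapsing (merge identical sequences, then strip barcode + UMI).
* **`srnakit.quantify`** — exact no-mismatch alignment with the standard
  hit gates (≤ 1 alignment to a mature-miRNA set, ≤ 10 to a genome),
  raw/collapsed count matrices, 15–30-nt length distributions, nested
  genome → non-miRNA → non-21U classification tiers, first-nucleotide
  profiles.
* **`srnakit.stats`** — replicate dispersion (squared relative
  difference; replicas differing by 10% score 0.01), median-of-ratios
  size factors, a negative-binomial Wald test calling differential
  expression at ≥ 5-fold and BH-adjusted p < 0.01, the UMI
  label-saturation model `E[distinct] = K(1 − (1 − 1/K)^n)` with its
  log-inverse correction, adapter-bias metrics, and a 2×2 chi-square.
* **`srnakit.pipeline`** — an end-to-end seeded run
  (simulate-or-ingest → demux → trim → collapse → quantify → stats)
  producing a JSON report.

## Worked example

Each script in `examples/` demonstrates one capability. Planning a
separation of 3′-ligated sRNA (~58 nt) from free adapter (~37 nt)
(`examples/01_spri_planning.py`):

```
chosen isopropanol: 38.0%
  58 nt binds at 42.0%
  37 nt binds at 4.0%
recipe for 50 ul sample: 76.5 ul 20% PEG beads + 77.6 ul isopropanol -> 204.1 ul total
```

At 38% isopropanol the 58-mer binds the beads at 42% efficiency while
only 4% of the 37-mer co-binds — the recipe line is what you would
pipette to reach that condition from a 50 µl sample.

The full pipeline on two simulated 5000-read libraries
(`examples/07_full_pipeline.py`):

```
Spearman correlation with ground-truth molecule counts:
  raw reads       0.719
  collapsed (UMI) 0.872
mean replicate dispersion:
  raw       66.77
  collapsed 6.36
```

Collapsing PCR duplicates by UMI both tracks the true molecule counts
more faithfully and shrinks the spread between technical replicates —
the core quantitative payoff of UMI-based small RNA-seq.

A thin CLI mirrors the library (`srnakit plan-spri`, `spri-mix`,
`simulate`, `demux`, `collapse`, `dispersion`, `de`, `umi-correct`,
`run`); see `srnakit --help`.

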