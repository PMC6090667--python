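"""Synthetic small-RNA sequencing libraries with known ground truth.

Emulates a gel-free small-RNA library prep as seen by the sequencer: each
captured molecule yields a read laid out as

    [4-nt barcode][UMI][insert, U->T][3' adapter][filler...]

truncated to the read length.  The generator models the mechanisms that
distort small-RNA quantification so that downstream processing can be
validated against exact truth:

* species classes with their hallmark constraints — miRNA (22-23 nt),
  21U/piRNA (21 nt, 5' U), primary siRNA (26 nt, 5' G, monophosphate),
  secondary siRNA (21-22 nt, 5' triphosphate), rRNA degradation fragments;
* the 5'-phosphate gate: triphosphate species ligate only after
  pyrophosphatase (RppH) treatment;
* per-species ligation bias (adapter preference);
* per-template PCR amplification bias as an exact Galton-Watson branching
  process, so duplicate families have the structure UMI collapsing must
  undo;
* uniform random UMIs with replacement, so label collisions emerge
  naturally at high copy/label ratios;
* adapter-dimer reads (empty insert) and uniform substitution errors.

All randomness flows from a single seeded generator; equal seeds give
byte-identical libraries.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "SpeciesRecord",
    "LibraryLayout",
    "SimConfig",
    "Dist",
    "SimTruth",
    "SimulatedLibrary",
    "make_population",
    "simulate_library",
    "write_fastq",
    "write_truth",
    "DEFAULT_ADAPTER3",
]

RNA_BASES = "ACGU"
DNA_BASES = "ACGT"

# widely used small-RNA 3' sequencing adapter
DEFAULT_ADAPTER3 = "TGGAATTCTCGGGTGCCAAGG"

CLASSES = (
    "miRNA",
    "p21U",
    "primary_siRNA",
    "secondary_siRNA",
    "rRNA_fragment",
    "other",
)

# (length choices, forced 5' base, 5'-phosphate state) per species class
_CLASS_RULES: dict[str, tuple[tuple[int, ...], str | None, str]] = {
    "miRNA": ((22, 23), None, "monophosphate"),
    "p21U": ((21,), "U", "monophosphate"),
    "primary_siRNA": ((26,), "G", "monophosphate"),
    "secondary_siRNA": ((21, 22), None, "triphosphate"),
    "rRNA_fragment": (tuple(range(20, 41)), None, "monophosphate"),
    "other": (tuple(range(15, 31)), None, "monophosphate"),
}


@dataclass(frozen=True)
class Dist:
    """Tiny distribution spec: ``fixed``, ``uniform``, ``beta`` or ``lognormal``.

    Used for per-template PCR efficiencies, per-species ligation
    probabilities and species abundances; keeps configs serializable.
    """

    kind: str
    a: float
    b: float = 0.0

    def sample(self, rng: np.random.Generator, size: int | None = None):
        if self.kind == "fixed":
            return self.a if size is None else np.full(size, self.a)
        if self.kind == "uniform":
            return rng.uniform(self.a, self.b, size)
        if self.kind == "beta":
            return rng.beta(self.a, self.b, size)
        if self.kind == "lognormal":
            return rng.lognormal(self.a, self.b, size)
        raise ValueError(f"unknown distribution kind: {self.kind}")


@dataclass(frozen=True)
class SpeciesRecord:
    seq_id: str
    sequence: str  # RNA alphabet
    species_class: str
    five_prime_state: str  # monophosphate | triphosphate
    true_count: int

    def __post_init__(self):
        if self.species_class not in CLASSES:
            raise ValueError(f"unknown species class {self.species_class!r}")
        if self.true_count < 0:
            raise ValueError("true_count must be non-negative")

    @property
    def insert_dna(self) -> str:
        return self.sequence.replace("U", "T")


@dataclass(frozen=True)
class LibraryLayout:
    barcode: str = "ACGT"
    umi_length: int = 8
    adapter3: str = DEFAULT_ADAPTER3
    read_length: int = 50
    rpph_treated: bool = False

    def __post_init__(self):
        if len(self.barcode) != 4:
            raise ValueError("barcode must be 4 nt")
        if self.umi_length < 1:
            raise ValueError("umi_length must be >= 1")
        if not self.adapter3:
            raise ValueError("adapter3 must be non-empty")
        if self.read_length < len(self.barcode) + self.umi_length:
            raise ValueError("read_length shorter than barcode + UMI")


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated library.

    Defaults model a routine bench run: ~12 PCR cycles, substantial
    per-template efficiency spread (the source of amplification bias),
    broad ligation preference, ~1% adapter dimers (real libraries stay
    below 2%), and an Illumina-like 1e-3 substitution rate.
    """

    seed: int = 0
    pcr_cycles: int = 12
    per_template_efficiency: Dist = Dist("uniform", 0.5, 1.0)
    ligation_prob: Dist = Dist("uniform", 0.2, 1.0)
    n_reads: int | None = 10_000  # None: sequence the entire amplified pool
    dimer_fraction: float = 0.01
    seq_error_rate: float = 0.001
    abundance: Dist = Dist("lognormal", 3.0, 1.2)

    def __post_init__(self):
        if self.pcr_cycles < 0:
            raise ValueError("pcr_cycles must be >= 0")
        if not 0.0 <= self.dimer_fraction <= 1.0:
            raise ValueError("dimer_fraction must be in [0, 1]")
        if not 0.0 <= self.seq_error_rate <= 1.0:
            raise ValueError("seq_error_rate must be in [0, 1]")


@dataclass
class SimTruth:
    """Ground truth for one species in one simulated library."""

    seq_id: str
    species_class: str
    sequence: str
    true_count: int
    ligated_count: int
    distinct_umis: int


@dataclass
class SimulatedLibrary:
    """Reads plus per-species truth for one barcode's library."""

    reads: list[tuple[str, str]]  # (read name, sequence)
    truth: list[SimTruth]
    layout: LibraryLayout

    def truth_by_id(self) -> dict[str, SimTruth]:
        return {t.seq_id: t for t in self.truth}


def _random_seq(rng: np.random.Generator, length: int, first: str | None) -> str:
    bases = rng.integers(0, 4, size=length)
    seq = "".join(RNA_BASES[b] for b in bases)
    if first is not None:
        seq = first + seq[1:]
    return seq


def make_population(
    config: SimConfig,
    class_mix: dict[str, float],
    n_species: int,
) -> list[SpeciesRecord]:
    """Draw a species population honouring each class's sequence constraints.

    Class labels are drawn from the normalized ``class_mix`` weights;
    abundances (true molecule counts, >= 1) from ``config.abundance``.
    Reproducible under ``config.seed``.
    """
    if n_species <= 0:
        raise ValueError("n_species must be positive")
    classes = [c for c, w in class_mix.items() if w > 0]
    weights = np.array([class_mix[c] for c in classes], dtype=float)
    if not classes or weights.sum() <= 0:
        raise ValueError("class_mix needs at least one positive weight")
    for c in classes:
        if c not in CLASSES:
            raise ValueError(f"unknown species class {c!r}")
    weights /= weights.sum()
    rng = np.random.default_rng(config.seed)

    population: list[SpeciesRecord] = []
    seen: set[str] = set()
    for i in range(n_species):
        cls = classes[rng.choice(len(classes), p=weights)]
        lengths, first, phos = _CLASS_RULES[cls]
        seq = _random_seq(rng, int(rng.choice(lengths)), first)
        while seq in seen:  # species are distinct sequences
            seq = _random_seq(rng, int(rng.choice(lengths)), first)
        seen.add(seq)
        count = max(1, int(round(float(config.abundance.sample(rng)))))
        population.append(
            SpeciesRecord(
                seq_id=f"sp{i:05d}_{cls}",
                sequence=seq,
                species_class=cls,
                five_prime_state=phos,
                true_count=count,
            )
        )
    return population


def _umi_strings(rng: np.random.Generator, n: int, k: int) -> list[str]:
    codes = rng.integers(0, 4, size=(n, k))
    return ["".join(DNA_BASES[c] for c in row) for row in codes]


def _galton_watson(rng: np.random.Generator, cycles: int, p: float) -> int:
    """Copies of one template after PCR; each copy duplicates with prob p per cycle."""
    copies = 1
    for _ in range(cycles):
        copies += rng.binomial(copies, p)
    return copies


def _apply_errors(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0.0:
        return seq
    n_err = rng.binomial(len(seq), rate)
    if n_err == 0:
        return seq
    pos = rng.choice(len(seq), size=n_err, replace=False)
    out = list(seq)
    for p in pos:
        out[p] = DNA_BASES[(DNA_BASES.index(out[p]) + rng.integers(1, 4)) % 4]
    return "".join(out)


def simulate_library(
    population: Sequence[SpeciesRecord],
    layout: LibraryLayout,
    config: SimConfig,
) -> SimulatedLibrary:
    """Simulate ligation, UMI labeling, PCR and sequencing of a population.

    Triphosphate species are dropped unless ``layout.rpph_treated`` (direct
    5'-adapter ligation needs a monophosphate).  Every ligated molecule
    receives an independent uniform UMI, then amplifies as a branching
    process with its species' efficiency.  ``config.n_reads`` reads are
    sampled from the amplified pool (without replacement while the pool
    lasts), with adapter-dimer reads mixed in at ``config.dimer_fraction``.
    """
    if not population:
        raise ValueError("population is empty")
    rng = np.random.default_rng(config.seed)
    k = layout.umi_length

    # ligation + labeling + amplification
    pool_tags: list[tuple[int, str]] = []  # (species idx, umi) per amplified copy
    truth: list[SimTruth] = []
    for idx, sp in enumerate(population):
        if sp.five_prime_state == "triphosphate" and not layout.rpph_treated:
            truth.append(
                SimTruth(sp.seq_id, sp.species_class, sp.sequence, sp.true_count, 0, 0)
            )
            continue
        p_lig = float(np.clip(config.ligation_prob.sample(rng), 0.0, 1.0))
        ligated = int(rng.binomial(sp.true_count, p_lig))
        umis = _umi_strings(rng, ligated, k)
        eff = float(np.clip(config.per_template_efficiency.sample(rng), 1e-6, 1.0))
        for umi in umis:
            copies = _galton_watson(rng, config.pcr_cycles, eff)
            pool_tags.extend([(idx, umi)] * copies)
        truth.append(
            SimTruth(
                sp.seq_id,
                sp.species_class,
                sp.sequence,
                sp.true_count,
                ligated,
                len(set(umis)),
            )
        )

    # sequencing: sample reads from the amplified pool
    n_reads = len(pool_tags) if config.n_reads is None else config.n_reads
    n_dimer = int(rng.binomial(n_reads, config.dimer_fraction))
    n_insert = n_reads - n_dimer
    if pool_tags and n_insert > 0:
        if n_insert <= len(pool_tags):
            chosen = rng.choice(len(pool_tags), size=n_insert, replace=False)
        else:
            chosen = rng.choice(len(pool_tags), size=n_insert, replace=True)
    else:
        chosen = np.array([], dtype=int)

    reads: list[tuple[str, str]] = []
    for rnum, j in enumerate(chosen):
        idx, umi = pool_tags[j]
        insert = population[idx].insert_dna
        raw = layout.barcode + umi + insert + layout.adapter3
        raw = raw.ljust(layout.read_length, "A")[: layout.read_length]
        raw = _apply_errors(rng, raw, config.seq_error_rate)
        reads.append((f"read{rnum:07d}:{population[idx].seq_id}", raw))
    for d in range(n_dimer):
        umi = _umi_strings(rng, 1, k)[0]
        raw = layout.barcode + umi + layout.adapter3
        raw = raw.ljust(layout.read_length, "A")[: layout.read_length]
        raw = _apply_errors(rng, raw, config.seq_error_rate)
        reads.append((f"dimer{d:07d}", raw))

    # interleave deterministically so dimers are not a suffix block
    order = rng.permutation(len(reads))
    reads = [reads[i] for i in order]
    return SimulatedLibrary(reads=reads, truth=truth, layout=layout)


def write_fastq(reads: Iterable[tuple[str, str]], path: str | Path) -> None:
    """Write (name, sequence) pairs as 4-line FASTQ, gzipped if path ends .gz."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as fh:
        for name, seq in reads:
            fh.write(f"@{name}\n{seq}\n+\n{'I' * len(seq)}\n")


def write_truth(truth: Iterable[SimTruth], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("seq_id\tclass\tsequence\ttrue_count\tligated_count\tdistinct_umis\n")
        for t in truth:
            fh.write(
                f"{t.seq_id}\t{t.species_class}\t{t.sequence}\t"
                f"{t.true_count}\t{t.ligated_count}\t{t.distinct_umis}\n"
            )
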