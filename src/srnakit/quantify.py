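"""Exact-match quantification of small-RNA inserts against reference sets.

Mirrors the no-mismatch alignment policy typical for short, uniform
small-RNA reads: an insert either matches a reference substring exactly and
full-length, or it does not count.  Hit-count gates follow standard
practice for this assay: at most 1 alignment against a mature-annotation
set (multireads are ambiguous and excluded), at most 10 against a genome
(a keep/discard gate — a kept sequence counts once regardless of hit
multiplicity).

Annotation sets (mature miRNA, 21U) are stranded, so inserts match the
forward strand only; a genome index matches both strands.  References may
be RNA-alphabet FASTA (miRBase dialect, U allowed); sequences are
normalized to uppercase DNA.  The feature id is the first
whitespace-delimited token of the FASTA header.

Counting operates on distinct insert sequences with weights (read counts
for the raw flavor, distinct-UMI counts for the collapsed flavor) so both
flavors share one alignment pass.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "ReferenceIndex",
    "CountMatrix",
    "Hit",
    "align_exact",
    "count_features",
    "length_distribution",
    "classify_hierarchy",
    "first_nt_profile",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_SEED_K = 12  # seed length for the k-mer index; queries are >= 15 nt


def _normalize(seq: str) -> str:
    return seq.upper().replace("U", "T")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Hit:
    seq_id: str
    position: int
    strand: str  # '+' or '-'


class ReferenceIndex:
    """Substring index over a reference FASTA for exact full-length matching.

    ``stranded=True`` (annotation sets): forward strand only.
    ``stranded=False`` (genome): both strands; a hit on the minus strand
    reports the position of the match on the reverse-complemented entry.
    Lookup is seed-and-verify on 12-mers with a naive-scan fallback for
    short queries, and agrees with a naive scan by construction.
    """

    def __init__(
        self,
        entries: Mapping[str, str],
        name: str = "reference",
        stranded: bool = True,
    ):
        self.name = name
        self.stranded = stranded
        self.entries: dict[str, str] = {
            sid: _normalize(seq) for sid, seq in entries.items()
        }
        self._strands: list[tuple[str, str, str]] = [
            (sid, seq, "+") for sid, seq in self.entries.items()
        ]
        if not stranded:
            self._strands += [
                (sid, _revcomp(seq), "-") for sid, seq in self.entries.items()
            ]
        self._seeds: dict[str, list[tuple[int, int]]] = defaultdict(list)
        for si, (_, seq, _) in enumerate(self._strands):
            for pos in range(len(seq) - _SEED_K + 1):
                self._seeds[seq[pos : pos + _SEED_K]].append((si, pos))

    @classmethod
    def from_fasta(
        cls, path: str | Path, name: str | None = None, stranded: bool = True
    ) -> "ReferenceIndex":
        entries = {}
        for rec in SeqIO.parse(str(path), "fasta"):
            entries[rec.id] = str(rec.seq)
        return cls(entries, name=name or Path(path).stem, stranded=stranded)

    def find(self, query: str) -> list[Hit]:
        """All exact full-length occurrences of ``query`` in the reference."""
        q = _normalize(query)
        hits: list[Hit] = []
        if len(q) >= _SEED_K:
            seen: set[tuple[int, int]] = set()
            for si, pos in self._seeds.get(q[:_SEED_K], ()):
                if (si, pos) in seen:
                    continue
                seen.add((si, pos))
                sid, seq, strand = self._strands[si]
                if seq[pos : pos + len(q)] == q:
                    hits.append(Hit(sid, pos, strand))
        else:
            for sid, seq, strand in self._strands:
                start = seq.find(q)
                while start != -1:
                    hits.append(Hit(sid, start, strand))
                    start = seq.find(q, start + 1)
        return hits


def align_exact(
    insert: str, index: ReferenceIndex, max_hits: int = 1
) -> list[Hit] | str:
    """Exact alignment with a multiread gate.

    Returns the hit list, or ``"ambiguous"`` when the insert has more than
    ``max_hits`` alignments (excluded from counting, as an aligner's -m
    flag would), or ``"unaligned"`` for zero hits.
    """
    if not insert:
        raise ValueError("empty insert")
    hits = index.find(insert)
    if not hits:
        return "unaligned"
    if len(hits) > max_hits:
        return "ambiguous"
    return hits


@dataclass
class CountMatrix:
    """Integer feature x sample counts, in ``raw`` or ``collapsed`` flavor."""

    counts: pd.DataFrame  # features x samples
    flavor: str
    unassigned: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))
    ambiguous: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))

    def __post_init__(self):
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")

    @property
    def features(self) -> list[str]:
        return list(self.counts.index)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    def to_tsv(self, path) -> None:
        self.counts.to_csv(path, sep="\t", index_label="feature")

    @classmethod
    def from_tsv(cls, path, flavor: str = "raw") -> "CountMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df, flavor=flavor)


def count_features(
    weights: Mapping[str, Mapping[str, float]],
    index: ReferenceIndex,
    flavor: str,
    max_hits: int = 1,
) -> CountMatrix:
    """Aggregate per-insert weights into per-feature counts.

    ``weights`` maps sample -> insert -> weight (read count for ``raw``,
    distinct-UMI count for ``collapsed``).  An insert contributes its
    weight to the feature it aligns to uniquely; multireads go to the
    ``ambiguous`` tally, non-aligners to ``unassigned``.  Mass is
    conserved: assigned + ambiguous + unassigned == total weight.
    """
    samples = list(weights)
    feat_counts: dict[str, dict[str, float]] = defaultdict(dict)
    unassigned = {s: 0.0 for s in samples}
    ambiguous = {s: 0.0 for s in samples}
    # single alignment pass over distinct inserts across all samples
    assignments: dict[str, str | None] = {}
    all_inserts = {ins for sample in samples for ins in weights[sample]}
    for ins in all_inserts:
        res = align_exact(ins, index, max_hits=max_hits)
        if res == "unaligned":
            assignments[ins] = None
        elif res == "ambiguous":
            assignments[ins] = "__ambiguous__"
        else:
            assignments[ins] = res[0].seq_id
    for sample in samples:
        for ins, w in weights[sample].items():
            target = assignments[ins]
            if target is None:
                unassigned[sample] += w
            elif target == "__ambiguous__":
                ambiguous[sample] += w
            else:
                feat_counts[target][sample] = feat_counts[target].get(sample, 0.0) + w
    df = (
        pd.DataFrame(feat_counts).T.reindex(columns=samples).fillna(0.0)
        if feat_counts
        else pd.DataFrame(columns=samples, dtype=float)
    )
    df = df.sort_index()
    return CountMatrix(
        counts=df,
        flavor=flavor,
        unassigned=pd.Series(unassigned),
        ambiguous=pd.Series(ambiguous),
    )


def length_distribution(
    weights: Mapping[str, float],
    lo: int = 15,
    hi: int = 30,
) -> pd.Series:
    """Weighted insert counts per length over [lo, hi], plus an ``other`` bucket."""
    hist = {length: 0.0 for length in range(lo, hi + 1)}
    other = 0.0
    for ins, w in weights.items():
        L = len(ins)
        if lo <= L <= hi:
            hist[L] += w
        else:
            other += w
    ser = pd.Series(hist, dtype=float)
    ser.loc["other"] = other
    return ser


def classify_hierarchy(
    weights: Mapping[str, float],
    genome_index: ReferenceIndex,
    mirna_index: ReferenceIndex,
    p21u_index: ReferenceIndex,
    lo: int = 15,
    hi: int = 30,
    genome_max_hits: int = 10,
) -> pd.DataFrame:
    """Nested per-length tiers: genome-aligned; of those, not-miRNA; of those, not-21U.

    Tier 1 counts inserts with an exact genome alignment (kept once if the
    hit count is within ``genome_max_hits``); tier 2 removes the inserts
    that align to the mature-miRNA set; tier 3 additionally removes 21U
    alignments.  Under the annotation sets' single-hit policy a multiread
    is "not aligned", as an aligner run with -m 1 would report it.
    Tiers are strictly nested: tier3 <= tier2 <= tier1 per length.
    """
    rows = {L: {"genome_aligned": 0.0, "genome_not_miRNA": 0.0,
                "genome_not_miRNA_not_21U": 0.0} for L in range(lo, hi + 1)}
    for ins, w in weights.items():
        L = len(ins)
        if not lo <= L <= hi:
            continue
        g = align_exact(ins, genome_index, max_hits=genome_max_hits)
        if isinstance(g, str):  # unaligned or > max_hits
            continue
        rows[L]["genome_aligned"] += w
        m = align_exact(ins, mirna_index, max_hits=1)
        if not isinstance(m, str):
            continue
        rows[L]["genome_not_miRNA"] += w
        u = align_exact(ins, p21u_index, max_hits=1)
        if not isinstance(u, str):
            continue
        rows[L]["genome_not_miRNA_not_21U"] += w
    return pd.DataFrame(rows).T


def first_nt_profile(
    weights: Mapping[str, float],
    length: int | None = None,
) -> dict[str, float]:
    """Weighted first-base composition among inserts (optionally one length).

    Returns frequencies over {A, C, G, T} summing to 1, or an empty dict
    when no insert matches the filter.
    """
    totals = {b: 0.0 for b in "ACGT"}
    grand = 0.0
    for ins, w in weights.items():
        if not ins or (length is not None and len(ins) != length):
            continue
        base = ins[0].upper().replace("U", "T")
        if base in totals:
            totals[base] += w
            grand += w
    if grand == 0.0:
        return {}
    return {b: v / grand for b, v in totals.items()}
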