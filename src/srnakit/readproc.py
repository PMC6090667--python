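"""Demultiplexing, 3'-adapter trimming and UMI collapsing for small-RNA reads.

Reads carry an inline 4-nt sample barcode followed by a UMI, the insert and
the 3' sequencing adapter.  Processing follows the order real pipelines use
for this layout:

1. demultiplex on the exact 4-nt prefix (the prefix is retained — barcode
   and UMI are stripped later, at collapse time);
2. trim the 3' adapter by scanning candidate start positions from the 3'
   end of the read in 1-nt steps, exact matching only;
3. classify each read (ok / adapter dimer / no adapter / too short);
4. collapse: identical full trimmed sequences (barcode + UMI + insert)
   merge to one molecule, then the 12-nt prefix is stripped, yielding
   distinct-UMI ("collapsed") counts per insert next to plain read
   ("raw" / non-collapsed) counts.

Collapsing is exact-sequence only; error-tolerant UMI network dedup
(directional adjacency a la UMI-tools) is a deliberate extension point,
not implemented here.
"""

from __future__ import annotations

import gzip
from collections import Counter, defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

__all__ = [
    "ProcessedRead",
    "CollapseResult",
    "read_fastq",
    "load_barcode_sheet",
    "demultiplex",
    "trim_adapter3",
    "process_read",
    "process_reads",
    "collapse",
    "dimer_fraction",
]

STATUS_OK = "ok"
STATUS_DIMER = "dimer"
STATUS_NO_ADAPTER = "no_adapter"
STATUS_TOO_SHORT = "too_short"


@dataclass(frozen=True)
class ProcessedRead:
    sample: str
    barcode: str
    umi: str
    insert: str
    status: str


@dataclass
class CollapseResult:
    """Raw and UMI-collapsed counts per insert for one sample.

    ``raw_counts[insert]`` is the number of reads; ``collapsed_counts``
    counts distinct (UMI, insert) pairs, i.e. distinct original molecules
    up to UMI collisions.  ``per_insert_umi_multiset`` keeps the UMI read
    multiplicities for collision diagnostics.
    """

    raw_counts: dict[str, int]
    collapsed_counts: dict[str, int]
    per_insert_umi_multiset: dict[str, Counter]


def read_fastq(path: str | Path) -> Iterator[tuple[str, str]]:
    """Yield (name, sequence) from a FASTQ(.gz) file."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        while True:
            header = fh.readline()
            if not header:
                return
            seq = fh.readline().rstrip("\n")
            fh.readline()  # '+'
            fh.readline()  # quality
            yield header[1:].strip().split()[0], seq


def load_barcode_sheet(path: str | Path) -> dict[str, str]:
    """Read a TSV of ``sample\\tbarcode`` into barcode -> sample."""
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            sample, barcode = line.split("\t")[:2]
            if sample.lower() == "sample" and len(barcode) != 4:
                continue  # header row
            _validate_barcode(barcode)
            if barcode in mapping:
                raise ValueError(f"duplicate barcode {barcode}")
            mapping[barcode] = sample
    return mapping


def _validate_barcode(barcode: str) -> None:
    if len(barcode) != 4 or any(b not in "ACGT" for b in barcode):
        raise ValueError(f"barcode must be 4 nt of ACGT, got {barcode!r}")


def demultiplex(
    reads: Iterable[tuple[str, str]],
    barcodes: dict[str, str],
) -> dict[str, list[tuple[str, str]]]:
    """Route reads by exact match of the first 4 bases.

    ``barcodes`` maps barcode -> sample name.  Non-matching reads land in
    ``"undetermined"``.  The barcode prefix stays on the read; it is
    stripped during collapsing, after identical sequences are merged.
    """
    for bc in barcodes:
        _validate_barcode(bc)
    samples = set(barcodes.values())
    if len(samples) != len(barcodes):
        # two barcodes may intentionally share a sample; only identical
        # barcode strings are an error, and dict keys already forbid that
        pass
    out: dict[str, list[tuple[str, str]]] = {s: [] for s in barcodes.values()}
    out["undetermined"] = []
    for name, seq in reads:
        sample = barcodes.get(seq[:4], "undetermined")
        out[sample].append((name, seq))
    return out


def trim_adapter3(
    sequence: str,
    adapter3: str,
    min_partial: int = 5,
    allow_suffix_prefix: bool = True,
    rightmost: bool = True,
) -> tuple[str, bool]:
    """Trim the 3' adapter by scanning start positions from the 3' end.

    Candidate start positions are tried in 1-nt steps from the 3' end of
    the read toward the 5' end (set ``rightmost=False`` to scan from the
    5' end instead).  At each position the adapter is compared exactly;
    where it would run off the read end, a prefix of >= ``min_partial``
    bases may match instead (``allow_suffix_prefix``).  Everything 5' of
    the first match is retained.  Returns ``(retained, found)``; an absent
    adapter leaves the read untouched with ``found=False``.
    """
    if not adapter3:
        raise ValueError("adapter3 must be non-empty")
    n, m = len(sequence), len(adapter3)
    min_len = min(m, min_partial) if allow_suffix_prefix else m
    starts = range(n - min_len, -1, -1) if rightmost else range(0, n - min_len + 1)
    for start in starts:
        if start < 0:
            continue
        span = min(m, n - start)
        if span < m and not (allow_suffix_prefix and span >= min_partial):
            continue
        if sequence[start : start + span] == adapter3[:span]:
            return sequence[:start], True
    return sequence, False


def process_read(
    name_seq: tuple[str, str],
    sample: str,
    adapter3: str,
    barcode_len: int = 4,
    umi_len: int = 8,
    min_insert: int = 15,
    **trim_kwargs,
) -> ProcessedRead:
    """Trim one demultiplexed read and classify it.

    Statuses: ``dimer`` (empty insert — 3' adapter ligated straight onto
    the 5' adapter), ``no_adapter`` (3' adapter not found; kept and
    reported, never silently dropped), ``too_short`` (insert shorter than
    ``min_insert``, or retained part too short to contain barcode + UMI),
    else ``ok``.
    """
    _, seq = name_seq
    retained, found = trim_adapter3(seq, adapter3, **trim_kwargs)
    prefix_len = barcode_len + umi_len
    if not found:
        barcode = seq[:barcode_len]
        umi = seq[barcode_len:prefix_len]
        return ProcessedRead(sample, barcode, umi, seq[prefix_len:], STATUS_NO_ADAPTER)
    barcode = retained[:barcode_len]
    umi = retained[barcode_len:prefix_len]
    insert = retained[prefix_len:]
    if len(retained) < prefix_len:
        status = STATUS_TOO_SHORT
    elif len(insert) == 0:
        status = STATUS_DIMER
    elif len(insert) < min_insert:
        status = STATUS_TOO_SHORT
    else:
        status = STATUS_OK
    return ProcessedRead(sample, barcode, umi, insert, status)


def process_reads(
    reads: Iterable[tuple[str, str]],
    sample: str,
    adapter3: str,
    barcode_len: int = 4,
    umi_len: int = 8,
    min_insert: int = 15,
    **trim_kwargs,
) -> list[ProcessedRead]:
    return [
        process_read(r, sample, adapter3, barcode_len, umi_len, min_insert, **trim_kwargs)
        for r in reads
    ]


def collapse(
    trimmed: Sequence[str] | Sequence[ProcessedRead],
    barcode_len: int = 4,
    umi_len: int = 8,
) -> CollapseResult:
    """Merge identical trimmed sequences, then strip barcode + UMI.

    Accepts adapter-trimmed sequences (or ProcessedReads with status ok,
    from which barcode+UMI+insert is rebuilt).  Raw counts tally reads per
    insert after removing the prefix; collapsed counts tally distinct full
    sequences — equivalently distinct (UMI, insert) pairs within one
    barcode — per insert.  Order-independent by construction.  Sequences
    shorter than barcode + UMI are dropped.
    """
    prefix_len = barcode_len + umi_len
    raw: dict[str, int] = defaultdict(int)
    umi_multiset: dict[str, Counter] = defaultdict(Counter)
    for item in trimmed:
        if isinstance(item, ProcessedRead):
            if item.status not in (STATUS_OK, STATUS_DIMER):
                continue
            seq = item.barcode + item.umi + item.insert
        else:
            seq = item
        if len(seq) < prefix_len:
            continue
        insert = seq[prefix_len:]
        umi = seq[barcode_len:prefix_len]
        raw[insert] += 1
        umi_multiset[insert][umi] += 1
    collapsed = {ins: len(umis) for ins, umis in umi_multiset.items()}
    return CollapseResult(dict(raw), collapsed, dict(umi_multiset))


def dimer_fraction(processed: Sequence[ProcessedRead]) -> float:
    """Fraction of adapter-dimer reads (insert length 0 after trimming)."""
    if not processed:
        raise ValueError("no processed reads")
    n_dimer = sum(1 for r in processed if r.status == STATUS_DIMER)
    return n_dimer / len(processed)
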