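"""SPRI bead size-selection planning for short nucleic acids.

Solid-phase reversible immobilization (SPRI) binds nucleic acid to
carboxylated paramagnetic beads in the presence of crowding agents.  With a
fixed 7.5% PEG background, the isopropanol concentration tunes the shortest
fragment length that still binds, which makes a two-step (double-sided)
selection possible for fragments well under 100 nt — the size regime of
small-RNA library intermediates (adapter dimers, free adapters, ligated
sRNA, tRNA).

This module models that behaviour from an empirical calibration table of
binding efficiencies (percent recovered, indexed by oligo length and
isopropanol concentration), computes bench-ready mixing volumes for a target
PEG/isopropanol condition, and predicts the outcome of one- and two-step
selections on an arbitrary fragment-length pool.

The packaged calibration covers single-stranded oligos of 19-66 nt at
isopropanol concentrations of 30-54.5% (stock assumptions: 20% PEG solution,
100% isopropanol).  Untested cells are missing, never zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping

__all__ = [
    "SpriMix",
    "CalibrationTable",
    "SelectionPlan",
    "FragmentPool",
    "InfeasibleMixError",
    "UnknownLengthError",
    "NoSeparatingConditionError",
    "compute_mix",
    "binding_efficiency",
    "plan_separation",
    "simulate_two_step",
    "load_calibration",
    "default_calibration",
]

PEG_STOCK_FACTOR = 5  # 20% PEG stock: reaching P% final needs 5*P*V/100 ul


class InfeasibleMixError(ValueError):
    """Requested final concentrations exceed what the stocks can reach."""


class UnknownLengthError(KeyError):
    """Queried oligo length is not in the calibration table."""


class NoSeparatingConditionError(ValueError):
    """No tabulated concentration separates the two requested lengths."""

    def __init__(self, message: str, best: "SelectionPlan | None" = None):
        super().__init__(message)
        self.best = best


@dataclass(frozen=True)
class SpriMix:
    """Mixing recipe realizing final PEG/isopropanol concentrations.

    Volumes in microliters.  ``sample_volume + peg_solution_volume +
    iso_volume == total_volume`` by construction.
    """

    sample_volume: float
    peg_pct: float
    iso_pct: float
    total_volume: float
    peg_solution_volume: float
    iso_volume: float


@dataclass
class SelectionPlan:
    keep_length: int
    remove_length: int
    chosen_concentration: float
    predicted_keep_efficiency: float
    predicted_remove_efficiency: float


class FragmentPool(dict):
    """Map fragment length (nt) -> abundance (arbitrary non-negative units)."""

    def __init__(self, *args, **kwargs):
        super().__init__(*args, **kwargs)
        for length, abundance in self.items():
            if abundance < 0:
                raise ValueError(f"negative abundance for length {length}")

    def total(self) -> float:
        return float(sum(self.values()))


class CalibrationTable:
    """Binding efficiency (%) indexed by (oligo length nt, isopropanol %).

    Entries may be missing (untested conditions).  For each length the
    stored efficiencies are expected to be non-decreasing in isopropanol
    concentration; a violation at load time raises a warning, not an error.
    """

    def __init__(self, efficiency: Mapping[int, Mapping[float, float]]):
        self._eff: dict[int, dict[float, float]] = {
            int(L): {float(c): float(e) for c, e in row.items()}
            for L, row in efficiency.items()
        }
        concs: set[float] = set()
        for L, row in self._eff.items():
            for c, e in row.items():
                if not 0.0 <= e <= 100.0:
                    raise ValueError(
                        f"efficiency {e} for ({L} nt, {c}%) outside [0, 100]"
                    )
            concs.update(row)
        self.lengths: list[int] = sorted(self._eff)
        self.concentrations: list[float] = sorted(concs)
        self._check_monotone()

    def _check_monotone(self) -> None:
        for L in self.lengths:
            row = self._eff[L]
            ordered = [row[c] for c in sorted(row)]
            if any(b < a for a, b in zip(ordered, ordered[1:])):
                warnings.warn(
                    f"binding efficiencies for {L} nt are not non-decreasing "
                    "in isopropanol concentration",
                    stacklevel=3,
                )

    def get(self, length: int, iso_pct: float) -> float | None:
        """Exact cell lookup; None for a missing (untested) cell."""
        if length not in self._eff:
            raise UnknownLengthError(
                f"no calibration for {length} nt; available lengths: "
                f"{self.lengths}"
            )
        return self._eff[length].get(float(iso_pct))

    def row(self, length: int) -> dict[float, float]:
        if length not in self._eff:
            raise UnknownLengthError(
                f"no calibration for {length} nt; available lengths: "
                f"{self.lengths}"
            )
        return dict(self._eff[length])


def load_calibration(path: str | Path) -> CalibrationTable:
    """Read a calibration TSV: header ``length\\t<conc>...``, cells numeric or ``ND``."""
    eff: dict[int, dict[float, float]] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        concs = [float(c) for c in header[1:]]
        for line in fh:
            cells = line.rstrip("\n").split("\t")
            if not cells or cells == [""]:
                continue
            length = int(cells[0])
            row: dict[float, float] = {}
            for conc, cell in zip(concs, cells[1:]):
                if cell.strip().upper() != "ND":
                    row[conc] = float(cell)
            eff[length] = row
    return CalibrationTable(eff)


def default_calibration() -> CalibrationTable:
    """The packaged ssDNA oligo calibration (19-66 nt, 30-54.5% isopropanol)."""
    ref = resources.files("srnakit.data").joinpath("spri_calibration.tsv")
    with resources.as_file(ref) as path:
        return load_calibration(path)


def compute_mix(sample_volume: float, peg_pct: float, iso_pct: float) -> SpriMix:
    """Solve the binding-solution volume equation X + 5PV/100 + QV/100 = V.

    X is the sample volume (ul), P the final PEG % (from a 20% stock, hence
    the factor 5) and Q the final isopropanol % (100% stock).  Returns the
    unique total volume V and the two component volumes.
    """
    if sample_volume <= 0:
        raise ValueError("sample_volume must be positive")
    if peg_pct < 0 or iso_pct < 0:
        raise ValueError("concentrations must be non-negative")
    denom = 1.0 - PEG_STOCK_FACTOR * peg_pct / 100.0 - iso_pct / 100.0
    if denom <= 0:
        raise InfeasibleMixError(
            "infeasible mix: requires 5*peg_pct/100 + iso_pct/100 < 1 "
            f"(got {PEG_STOCK_FACTOR * peg_pct / 100.0 + iso_pct / 100.0:.3f})"
        )
    total = sample_volume / denom
    return SpriMix(
        sample_volume=sample_volume,
        peg_pct=peg_pct,
        iso_pct=iso_pct,
        total_volume=total,
        peg_solution_volume=PEG_STOCK_FACTOR * peg_pct * total / 100.0,
        iso_volume=iso_pct * total / 100.0,
    )


def binding_efficiency(
    table: CalibrationTable,
    length: int,
    iso_pct: float,
    interpolate: bool = False,
) -> float | None:
    """Binding efficiency (%) for an oligo length at an isopropanol concentration.

    Exact lookup at tabulated cells.  With ``interpolate``, linear
    interpolation along the concentration axis between the adjacent
    non-missing cells of the same length; no interpolation across lengths.
    Returns None when the cell is missing and cannot be bracketed.
    """
    exact = table.get(length, iso_pct)
    if exact is not None or not interpolate:
        return exact
    row = table.row(length)
    lower = [c for c in row if c < iso_pct]
    upper = [c for c in row if c > iso_pct]
    if not lower or not upper:
        return None
    lo, hi = max(lower), min(upper)
    frac = (iso_pct - lo) / (hi - lo)
    return row[lo] + frac * (row[hi] - row[lo])


def plan_separation(
    table: CalibrationTable,
    keep_length: int,
    remove_length: int,
    min_keep: float = 40.0,
    max_remove: float = 5.0,
) -> SelectionPlan:
    """Pick the isopropanol concentration separating two fragment lengths.

    Scans the table's concentrations in increasing order and returns the
    lowest at which the longer fragment binds at >= ``min_keep`` percent
    while the shorter binds at <= ``max_remove`` percent.  A concentration
    qualifies only when both efficiencies are tabulated: untested cells
    never support a separation claim.  The lowest qualifying concentration
    maximizes the purity margin for the shorter fragment.
    """
    if keep_length <= remove_length:
        raise ValueError("keep_length must exceed remove_length")
    keep_row = table.row(keep_length)
    remove_row = table.row(remove_length)
    best: SelectionPlan | None = None
    best_margin = -float("inf")
    for conc in table.concentrations:
        ek = keep_row.get(conc)
        er = remove_row.get(conc)
        if ek is None or er is None:
            continue
        plan = SelectionPlan(keep_length, remove_length, conc, ek, er)
        if ek >= min_keep and er <= max_remove:
            return plan
        margin = min(ek - min_keep, max_remove - er)
        if margin > best_margin:
            best, best_margin = plan, margin
    raise NoSeparatingConditionError(
        f"no separating condition for keep={keep_length} nt / "
        f"remove={remove_length} nt with min_keep={min_keep}, "
        f"max_remove={max_remove}",
        best=best,
    )


def simulate_two_step(
    pool: FragmentPool,
    table: CalibrationTable,
    step1_iso: float,
    step2_iso: float,
    interpolate: bool = False,
) -> tuple[FragmentPool, FragmentPool, FragmentPool]:
    """Expected outcome of a double-sided selection on a fragment pool.

    Step 1 binds at ``step1_iso``; bound material is eluted as ``elution1``
    (the longer-fragment fraction).  The supernatant is re-bound at
    ``step2_iso``; that elution is ``elution2`` and the final supernatant is
    ``discarded``.  Deterministic expectation mode: each length L
    partitions by the tabulated efficiencies, so mass is conserved exactly.
    """
    e1: dict[int, float] = {}
    e2: dict[int, float] = {}
    for length in pool:
        for target, iso in ((e1, step1_iso), (e2, step2_iso)):
            eff = binding_efficiency(table, length, iso, interpolate=interpolate)
            if eff is None:
                raise ValueError(
                    f"binding efficiency unavailable for {length} nt at "
                    f"{iso}% isopropanol"
                )
            target[length] = eff / 100.0
    elution1 = FragmentPool({L: a * e1[L] for L, a in pool.items()})
    supernatant = {L: a * (1.0 - e1[L]) for L, a in pool.items()}
    elution2 = FragmentPool({L: a * e2[L] for L, a in supernatant.items()})
    discarded = FragmentPool(
        {L: a * (1.0 - e2[L]) for L, a in supernatant.items()}
    )
    return elution1, elution2, discarded
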