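"""Motif-conservation profiling of homolog multiple sequence alignments.

Alignments (built externally, e.g. with Clustal Omega, and imported as
aligned FASTA or Clustal files) are projected onto the coordinates of a
reference sequence — conventionally KaiC of *Synechococcus elongatus* PCC
7942 — so that functional motif windows can be stated as reference residue
numbers. For each window a position frequency matrix (PFM) over the 20
amino acids plus the gap symbol is computed; consensus strings and
wildcard-pattern match fractions summarise conservation, e.g. of the
ATP-binding Walker A motif (GXXXXGKT; GATGTGKT in KaiC-7942), the
phosphorylation sites S431/T432 and the dephosphorylation-relevant T426.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from collections.abc import Sequence

import numpy as np
import pandas as pd
from Bio import AlignIO

from clockmine.datatypes import STANDARD_AA

GAP = "-"
PFM_ALPHABET = tuple(STANDARD_AA) + (GAP,)


@dataclass
class MSA:
    """A multiple sequence alignment: ids and equal-length gapped rows."""

    records: list[tuple[str, str]]

    def __post_init__(self) -> None:
        if len(self.records) < 2:
            raise ValueError("an alignment needs at least 2 records")
        widths = {len(seq) for _, seq in self.records}
        if len(widths) != 1:
            raise ValueError("aligned sequences must have equal length")
        self.records = [(rid, seq.upper()) for rid, seq in self.records]

    @property
    def width(self) -> int:
        return len(self.records[0][1])

    def row(self, record_id: str) -> str:
        for rid, seq in self.records:
            if rid == record_id:
                return seq
        raise KeyError(f"record {record_id!r} not in alignment")


def read_msa(path, fmt: str | None = None) -> MSA:
    """Read an alignment from aligned FASTA or Clustal format.

    The format is sniffed from the first line when not given.
    """
    if fmt is None:
        with open(path) as handle:
            first = handle.readline()
        fmt = "clustal" if first.upper().startswith("CLUSTAL") else "fasta"
    aln = AlignIO.read(path, fmt)
    return MSA([(rec.id, str(rec.seq)) for rec in aln])


@dataclass
class ReferenceMapping:
    """Column -> reference residue number (1-based; None at reference gaps)."""

    reference_id: str
    column_to_refpos: list[int | None]

    @property
    def reference_length(self) -> int:
        return sum(1 for p in self.column_to_refpos if p is not None)

    def columns_for(self, positions: Sequence[int]) -> dict[int, int]:
        """Map reference residue numbers to 0-based alignment columns."""
        inverse = {
            pos: col for col, pos in enumerate(self.column_to_refpos) if pos is not None
        }
        missing = [p for p in positions if p not in inverse]
        if missing:
            raise ValueError(f"reference positions outside alignment: {missing}")
        return {p: inverse[p] for p in positions}


@dataclass(frozen=True)
class MotifWindow:
    """A named motif as one or more reference residue ranges (inclusive)."""

    name: str
    ranges: tuple[tuple[int, int], ...]

    @property
    def positions(self) -> list[int]:
        out: list[int] = []
        for start, end in self.ranges:
            if start > end or start < 1:
                raise ValueError(f"invalid range ({start}, {end}) in window {self.name!r}")
            out.extend(range(start, end + 1))
        return out


@dataclass
class PFM:
    """Per-position residue frequencies for one motif window.

    ``frequencies`` is positions x (20 AA + gap), each row summing to 1.
    """

    window: str
    positions: list[int]
    frequencies: pd.DataFrame
    n_sequences: int = 0

    def dominant(self) -> list[tuple[int, str, float]]:
        """Per position: (refpos, most frequent symbol, its frequency)."""
        out = []
        for pos in self.positions:
            row = self.frequencies.loc[pos]
            best = row.idxmax()
            out.append((pos, str(best), float(row[best])))
        return out

    @property
    def consensus(self) -> str:
        return "".join(sym for _, sym, _ in self.dominant())


def map_to_reference(msa: MSA, reference_id: str) -> ReferenceMapping:
    """Project alignment columns onto reference residue numbers.

    Column *i* maps to the count of non-gap reference characters in columns
    ``<= i`` when the reference is non-gap at *i*, else to a gap (None). The
    mapping is a bijection between non-gap reference columns and
    ``1..len(reference)``.
    """
    ref_row = msa.row(reference_id)
    mapping: list[int | None] = []
    count = 0
    for char in ref_row:
        if char == GAP:
            mapping.append(None)
        else:
            count += 1
            mapping.append(count)
    return ReferenceMapping(reference_id=reference_id, column_to_refpos=mapping)


def column_frequencies(
    msa: MSA,
    mapping: ReferenceMapping,
    window: MotifWindow,
    include_reference: bool = True,
) -> PFM:
    """Position frequency matrix for a motif window in reference coordinates.

    Gap characters are counted as a 21st symbol. ``include_reference=False``
    profiles only the homologs, excluding the reference row itself.
    """
    positions = window.positions
    cols = mapping.columns_for(positions)
    records = msa.records
    if not include_reference:
        records = [(rid, seq) for rid, seq in records if rid != mapping.reference_id]
    n = len(records)
    freq = pd.DataFrame(0.0, index=positions, columns=list(PFM_ALPHABET))
    for pos in positions:
        col = cols[pos]
        for _, seq in records:
            symbol = seq[col]
            if symbol not in freq.columns:  # non-standard residue -> X pool
                symbol = GAP if symbol == GAP else "X"
                if "X" not in freq.columns:
                    freq["X"] = 0.0
            freq.loc[pos, symbol] += 1.0
    freq /= n
    return PFM(window=window.name, positions=positions, frequencies=freq, n_sequences=n)


def pattern_matches(sequence_window: str, pattern: str) -> bool:
    """Match an ungapped window against a motif pattern (X = any residue)."""
    if len(sequence_window) != len(pattern):
        return False
    return all(p == "X" or p == s for p, s in zip(pattern, sequence_window))


def motif_report(
    msa: MSA,
    mapping: ReferenceMapping,
    windows: Sequence[MotifWindow],
    consensus_patterns: dict[str, str] | None = None,
    include_reference: bool = True,
) -> pd.DataFrame:
    """Per-motif conservation summary.

    For each window: the consensus string (dominant residues), and — when a
    wildcard pattern is supplied for it — the fraction of sequences whose
    (gap-stripped) window matches the pattern. Record order is irrelevant.
    """
    patterns = consensus_patterns or {}
    rows = []
    for window in windows:
        pfm = column_frequencies(msa, mapping, window, include_reference=include_reference)
        pattern = patterns.get(window.name)
        match_fraction = float("nan")
        if pattern is not None:
            if len(pattern) != len(window.positions):
                raise ValueError(
                    f"pattern length {len(pattern)} != window length "
                    f"{len(window.positions)} for motif {window.name!r}"
                )
            cols = mapping.columns_for(window.positions)
            records = msa.records
            if not include_reference:
                records = [r for r in records if r[0] != mapping.reference_id]
            n_match = sum(
                1
                for _, seq in records
                if pattern_matches("".join(seq[cols[p]] for p in window.positions), pattern)
            )
            match_fraction = n_match / len(records)
        rows.append(
            {
                "motif": window.name,
                "positions": ",".join(str(p) for p in window.positions),
                "consensus": pfm.consensus,
                "pattern": pattern or "",
                "match_fraction": match_fraction,
                "n_sequences": pfm.n_sequences,
            }
        )
    return pd.DataFrame(rows)


def find_motif_window(
    ungapped_reference: str, pattern: str, name: str
) -> MotifWindow:
    """Locate a wildcard pattern in the reference and return its window.

    Useful for anchoring motifs whose exact coordinates differ between
    reference variants (e.g. the CII Walker A P-loop, GATGTGKT).
    """
    length = len(pattern)
    for start in range(len(ungapped_reference) - length + 1):
        if pattern_matches(ungapped_reference[start : start + length], pattern):
            return MotifWindow(name=name, ranges=((start + 1, start + length),))
    raise ValueError(f"pattern {pattern!r} not found in reference")


def default_kaic_windows(reference_ungapped: str | None = None) -> list[MotifWindow]:
    """Motif windows anchored at named KaiC-7942 residues.

    Ships the coordinates that are unambiguous in the reference numbering:
    the CII phosphorylation sites S431/T432, the dephosphorylation residue
    T426, and — when the ungapped reference sequence is supplied — the CII
    Walker A P-loop located by its GATGTGKT sequence. Windows without
    published coordinates (R-finger, catalytic EE, A-loop span, the 422- and
    438-444-loops) are left to user configuration.
    """
    windows = [
        MotifWindow(name="phosphosites_S431_T432", ranges=((431, 432),)),
        MotifWindow(name="dephosphorylation_T426", ranges=((426, 426),)),
    ]
    if reference_ungapped is not None:
        windows.append(find_motif_window(reference_ungapped, "GATGTGKT", "walker_A_CII"))
    return windows


def pfm_table(pfms: Sequence[PFM]) -> pd.DataFrame:
    """Long-format PFM table: (motif, refpos, residue, frequency)."""
    rows = []
    for pfm in pfms:
        for pos in pfm.positions:
            for residue in pfm.frequencies.columns:
                freq = float(pfm.frequencies.loc[pos, residue])
                if freq > 0:
                    rows.append(
                        {"motif": pfm.window, "refpos": pos, "residue": residue, "frequency": freq}
                    )
    return pd.DataFrame(rows, columns=["motif", "refpos", "residue", "frequency"])
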