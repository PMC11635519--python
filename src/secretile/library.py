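"""Tiled peptide library design.

A proteome is sliced into fixed-length peptide windows ("tiles") with a fixed
overlap between neighbours.  With tile length ``L`` and overlap ``v`` the
window step is ``s = L - v``; windows start at residues 1, 1+s, 1+2s, ...
(1-based inclusive coordinates).  If the last regular window does not reach
the protein C-terminus, one extra window anchored to end exactly at the
C-terminus is emitted, so every residue is covered while the tile length stays
fixed - a requirement of array-based oligo synthesis.  The overlap guarantees
that every linear epitope of up to ``v + 1`` residues is contained intact in
at least one tile.

Defaults (L=32, v=14) give an 18-residue step and a guaranteed epitope length
of 15.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

STANDARD_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")

SHORT_PROTEIN_POLICIES = ("skip", "emit_full_length")


@dataclass(frozen=True)
class ProteinRecord:
    """One source protein: accession, amino-acid sequence, free-text description."""

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("protein id must be non-empty")
        if not self.sequence:
            raise ValueError(f"protein {self.id!r}: empty sequence")


@dataclass(frozen=True)
class TileParams:
    """Tiling parameters.

    Parameters
    ----------
    tile_length : int
        Window length L in residues (default 32).
    overlap : int
        Overlap v between neighbouring windows, 0 <= v < L (default 14).
    short_protein_policy : {"skip", "emit_full_length"}
        What to do with proteins shorter than ``tile_length``.  ``skip``
        drops them with a logged warning; ``emit_full_length`` emits the whole
        protein as a single (short) tile.
    dedupe : bool
        Collapse identical peptide sequences across the proteome, merging
        provenance.
    """

    tile_length: int = 32
    overlap: int = 14
    short_protein_policy: str = "skip"
    dedupe: bool = True

    def __post_init__(self) -> None:
        if self.tile_length < 1:
            raise ValueError("tile_length must be >= 1")
        if not 0 <= self.overlap < self.tile_length:
            raise ValueError("require 0 <= overlap < tile_length")
        if self.short_protein_policy not in SHORT_PROTEIN_POLICIES:
            raise ValueError(
                f"short_protein_policy must be one of {SHORT_PROTEIN_POLICIES}"
            )

    @property
    def step(self) -> int:
        """Window step s = tile_length - overlap (>= 1 by construction)."""
        return self.tile_length - self.overlap


@dataclass
class PeptideTile:
    """One library member with provenance coordinates on its source protein.

    ``start``/``end`` are 1-based inclusive residue coordinates.
    ``provenance`` lists every (parent_id, start) that produced this sequence
    after deduplication.
    """

    parent_id: str
    start: int
    end: int
    sequence: str
    is_terminal_anchor: bool = False
    provenance: list[tuple[str, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.end - self.start + 1 != len(self.sequence):
            raise ValueError(
                f"tile {self.parent_id}|{self.start}-{self.end}: "
                f"coordinates span {self.end - self.start + 1} residues but "
                f"sequence has {len(self.sequence)}"
            )
        if not self.provenance:
            self.provenance = [(self.parent_id, self.start)]

    @property
    def tile_id(self) -> str:
        return f"{self.parent_id}|{self.start}-{self.end}"


@dataclass
class TileLibrary:
    """Ordered collection of tiles plus a sequence index and design QC tallies."""

    tiles: list[PeptideTile]
    params: TileParams
    qc: dict = field(default_factory=dict)
    index: dict[str, int] = field(init=False)

    def __post_init__(self) -> None:
        self.index = {t.sequence: i for i, t in enumerate(self.tiles)}

    def __len__(self) -> int:
        return len(self.tiles)

    def __iter__(self):
        return iter(self.tiles)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "tile_id": t.tile_id,
                "parent_id": t.parent_id,
                "start": t.start,
                "end": t.end,
                "sequence": t.sequence,
                "anchored": t.is_terminal_anchor,
                "provenance": ";".join(f"{p}:{s}" for p, s in t.provenance),
            }
            for t in self.tiles
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "tile_id",
                "parent_id",
                "start",
                "end",
                "sequence",
                "anchored",
                "provenance",
            ],
        )

    def write_fasta(self, path) -> None:
        """Write peptides as FASTA with ``>parentid|start-end`` headers (1-based inclusive)."""
        with open(path, "w") as fh:
            fh.write("; coordinates are 1-based inclusive\n")
            for t in self.tiles:
                fh.write(f">{t.tile_id}\n{t.sequence}\n")

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _window_starts(n: int, params: TileParams) -> list[tuple[int, bool]]:
    """Regular window starts plus an optional C-terminal anchored start.

    Returns (start, is_anchor) pairs, 1-based.  Assumes n >= tile_length.
    """
    L, s = params.tile_length, params.step
    starts = list(range(1, n - L + 2, s))
    last_end = starts[-1] + L - 1
    out = [(st, False) for st in starts]
    if last_end < n:
        out.append((n - L + 1, True))
    return out


def tile_protein(protein: ProteinRecord, params: TileParams) -> list[PeptideTile]:
    """Slice one protein into fixed-length overlapping tiles.

    Windows start at 1, 1+s, 1+2s, ...; if the last regular window stops short
    of the C-terminus an extra window anchored at the C-terminus is added
    (``is_terminal_anchor=True``).  Tiles containing a non-standard residue
    (X, U, B, Z, ...) are dropped and logged - a synthesis-bound library
    cannot encode ambiguity.  Proteins shorter than ``tile_length`` follow
    ``params.short_protein_policy``.
    """
    seq = protein.sequence
    n = len(seq)
    if n < params.tile_length:
        if params.short_protein_policy == "skip":
            logger.warning(
                "protein %s (%d aa) shorter than tile length %d: skipped",
                protein.id,
                n,
                params.tile_length,
            )
            return []
        windows = [(1, False)]
    else:
        windows = _window_starts(n, params)

    tiles: list[PeptideTile] = []
    for start, anchored in windows:
        end = min(start + params.tile_length - 1, n)
        pep = seq[start - 1 : end]
        bad = set(pep) - STANDARD_AA
        if bad:
            logger.warning(
                "tile %s|%d-%d dropped: non-standard residue(s) %s",
                protein.id,
                start,
                end,
                "".join(sorted(bad)),
            )
            continue
        tiles.append(
            PeptideTile(
                parent_id=protein.id,
                start=start,
                end=end,
                sequence=pep,
                is_terminal_anchor=anchored,
            )
        )
    return tiles


def tile_proteome(
    proteome: Iterable[ProteinRecord], params: TileParams | None = None
) -> TileLibrary:
    """Tile every protein and assemble the library.

    Ordering is deterministic: proteome order, then window start.  With
    ``params.dedupe`` identical peptide sequences are collapsed into a single
    tile whose ``provenance`` lists every origin; the representative keeps the
    coordinates of its first occurrence.
    """
    if params is None:
        params = TileParams()
    proteome = list(proteome)
    seen_ids: set[str] = set()
    for p in proteome:
        if p.id in seen_ids:
            raise ValueError(f"duplicate protein id {p.id!r} in proteome")
        seen_ids.add(p.id)

    qc = Counter(
        proteins_in=len(proteome),
        proteins_skipped_short=0,
        tiles_dropped_nonstandard=0,
        tiles_emitted=0,
        tiles_deduplicated=0,
    )

    all_tiles: list[PeptideTile] = []
    for protein in proteome:
        n = len(protein.sequence)
        if n < params.tile_length and params.short_protein_policy == "skip":
            qc["proteins_skipped_short"] += 1
            continue
        tiles = tile_protein(protein, params)
        n_windows = (
            1 if n < params.tile_length else len(_window_starts(n, params))
        )
        qc["tiles_dropped_nonstandard"] += n_windows - len(tiles)
        all_tiles.extend(tiles)

    if params.dedupe:
        by_seq: dict[str, PeptideTile] = {}
        for t in all_tiles:
            if t.sequence in by_seq:
                by_seq[t.sequence].provenance.append((t.parent_id, t.start))
                qc["tiles_deduplicated"] += 1
            else:
                by_seq[t.sequence] = t
        all_tiles = list(by_seq.values())

    qc["tiles_emitted"] = len(all_tiles)
    return TileLibrary(tiles=all_tiles, params=params, qc=dict(qc))


@dataclass
class CoverageStats:
    """Per-proteome coverage summary of a tile library."""

    fraction_covered: float
    depth_histogram: dict[int, int]
    guaranteed_epitope_length: int
    per_protein_fraction: dict[str, float]


def coverage_report(
    library: TileLibrary, proteome: Sequence[ProteinRecord]
) -> CoverageStats:
    """Per-residue coverage depth of the proteome by the library.

    Every tile contributes depth at each origin in its provenance, so a
    deduplicated library still covers all source proteins.  The guaranteed
    epitope length is ``overlap + 1``: the longest k such that every k-mer of
    any (fully tiled) source protein lies inside at least one tile.
    Proteins skipped as too short are excluded from the coverage fraction.
    """
    lengths = {p.id: len(p.sequence) for p in proteome}
    for t in library.tiles:
        for pid, _ in t.provenance:
            if pid not in lengths:
                raise ValueError(
                    f"library tile references protein {pid!r} absent from proteome"
                )

    depth: dict[str, list[int]] = {}
    for t in library.tiles:
        tlen = len(t.sequence)
        for pid, start in t.provenance:
            arr = depth.setdefault(pid, [0] * lengths[pid])
            for i in range(start - 1, start - 1 + tlen):
                arr[i] += 1

    hist: Counter = Counter()
    per_protein: dict[str, float] = {}
    covered = total = 0
    for pid, arr in depth.items():
        hist.update(arr)
        c = sum(1 for d in arr if d > 0)
        per_protein[pid] = c / len(arr)
        covered += c
        total += len(arr)

    return CoverageStats(
        fraction_covered=(covered / total) if total else 0.0,
        depth_histogram=dict(sorted(hist.items())),
        guaranteed_epitope_length=library.params.overlap + 1,
        per_protein_fraction=per_protein,
    )


def read_proteome_fasta(path) -> list[ProteinRecord]:
    """Load a multi-FASTA of proteins as ProteinRecords (ids must be unique)."""
    records = [
        ProteinRecord(id=r.id, sequence=str(r.seq).upper(), description=r.description)
        for r in SeqIO.parse(str(path), "fasta")
    ]
    ids = [r.id for r in records]
    dupes = {i for i in ids if ids.count(i) > 1}
    if dupes:
        raise ValueError(f"duplicate protein id(s) in FASTA: {sorted(dupes)}")
    return records
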