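"""Pooled sort-seq screen simulator.

Generates synthetic FACS-sorted sequencing pools with the statistical
structure the screening platform assumes:

* lentiviral integration counts per cell are Poisson with mean MOI
  (default 0.3, so ~26% of cells are infected and ~86% of infected cells
  carry a single integration);
* a cell is GFP-positive with probability ``p_gfp_active`` if any of its
  integrations encodes an activator peptide, else ``p_gfp_background``
  (binary CRE-reporter abstraction of the sort gate);
* the sorted pool is the tile multiset of GFP-positive infected cells and
  the naive pool that of all infected cells (optionally the plasmid
  library itself);
* per-tile read counts are drawn by a Dirichlet-multinomial whose
  overdispersion models PCR amplification noise, and reads are the
  arm-flanked inserts truncated/padded to the read length with i.i.d.
  substitution errors.

Everything is reproducible bit-for-bit under a fixed seed.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .library import ProteinRecord
from .oligo import OligoDesign

_AA20 = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


def random_proteome(
    n_proteins: int = 50,
    length: int = 200,
    seed: int = 0,
    id_prefix: str = "SYN",
) -> list[ProteinRecord]:
    """Synthetic proteome of uniform-random 20-letter proteins.

    Stands in for a real secretome in simulations and tests; it reproduces
    the combinatorial structure a tiling library needs (unique windows,
    realistic protein lengths) but none of the biological composition biases
    of real secreted proteins.
    """
    rng = np.random.default_rng(seed)
    lengths = (
        np.full(n_proteins, length)
        if np.isscalar(length)
        else np.asarray(length)
    )
    return [
        ProteinRecord(
            id=f"{id_prefix}{i:04d}",
            sequence="".join(rng.choice(_AA20, size=n)),
            description="synthetic random protein",
        )
        for i, n in enumerate(lengths)
    ]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASE_INDEX = np.zeros(256, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_INDEX[_b] = _i


@dataclass
class ScreenSimParams:
    """Study conditions for one simulated screen.

    Defaults mirror the platform: MOI 0.3, 150 bp single-end reads.  The GFP
    probabilities encode a strong reporter with low background
    (activator-carrying cells sort GFP-positive 90% of the time, others 1%).
    """

    n_cells: int = 100_000
    moi: float = 0.3
    activator_ids: frozenset = field(default_factory=frozenset)
    p_gfp_active: float = 0.9
    p_gfp_background: float = 0.01
    pcr_dispersion: float = 0.0
    n_reads_per_pool: int = 100_000
    seq_error_rate: float = 0.001
    read_length: int = 150
    seed: int = 0

    def __post_init__(self) -> None:
        if self.moi <= 0:
            raise ValueError("moi must be > 0")
        if not 0 <= self.p_gfp_background <= self.p_gfp_active <= 1:
            raise ValueError("require 0 <= p_gfp_background <= p_gfp_active <= 1")
        if self.pcr_dispersion < 0:
            raise ValueError("pcr_dispersion must be >= 0")
        if not 0 <= self.seq_error_rate < 1:
            raise ValueError("seq_error_rate must be in [0, 1)")
        self.activator_ids = frozenset(self.activator_ids)


@dataclass
class CellAssignment:
    """One cell: its integrated tiles (possibly none) and its sorted GFP state."""

    cell_id: int
    integrated_tile_ids: list[str]
    gfp_positive: bool = False


def simulate_integration(
    params: ScreenSimParams,
    library,
    rng: np.random.Generator | None = None,
    abundance=None,
) -> list[CellAssignment]:
    """Poisson(MOI) integrations per cell; tiles drawn with replacement.

    ``abundance`` optionally weights the tile draw (e.g. a skewed plasmid
    pool); default uniform.  The infected fraction converges to
    ``1 - exp(-moi)`` as n_cells grows.
    """
    tiles = [t.tile_id for t in library]
    if not tiles:
        raise ValueError("library is empty")
    if rng is None:
        rng = np.random.default_rng(params.seed)
    p = None
    if abundance is not None:
        p = np.asarray(abundance, dtype=float)
        p = p / p.sum()
    counts = rng.poisson(params.moi, params.n_cells)
    total = int(counts.sum())
    draws = rng.choice(len(tiles), size=total, replace=True, p=p)
    cells: list[CellAssignment] = []
    pos = 0
    for cid, k in enumerate(counts):
        cells.append(
            CellAssignment(
                cell_id=cid,
                integrated_tile_ids=[tiles[j] for j in draws[pos : pos + k]],
            )
        )
        pos += k
    return cells


def simulate_sort(
    assignments: list[CellAssignment],
    params: ScreenSimParams,
    rng: np.random.Generator | None = None,
) -> tuple[Counter, Counter]:
    """Bernoulli GFP gate, then pool tiles.

    A cell is GFP-positive with ``p_gfp_active`` if any integrated tile is an
    activator (dominant reporter activation), else ``p_gfp_background``.
    Returns (sorted_pool, naive_pool) as tile-id multisets; the naive pool is
    every tile of every infected cell.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed + 1)
    u = rng.random(len(assignments))
    sorted_pool: Counter = Counter()
    naive_pool: Counter = Counter()
    act = params.activator_ids
    for cell, ui in zip(assignments, u):
        if not cell.integrated_tile_ids:
            cell.gfp_positive = bool(ui < params.p_gfp_background)
            continue
        carries = any(t in act for t in cell.integrated_tile_ids)
        p = params.p_gfp_active if carries else params.p_gfp_background
        cell.gfp_positive = bool(ui < p)
        naive_pool.update(cell.integrated_tile_ids)
        if cell.gfp_positive:
            sorted_pool.update(cell.integrated_tile_ids)
    return sorted_pool, naive_pool


def _pool_read_counts(
    pool: Counter, params: ScreenSimParams, rng: np.random.Generator
) -> tuple[list[str], np.ndarray]:
    """Per-tile read counts: Dirichlet-multinomial over pool frequencies.

    ``pcr_dispersion`` -> 0 recovers a plain multinomial; larger values
    spread the amplification weights (concentration alpha_i = f_i / d).
    """
    tiles = sorted(pool)
    freqs = np.array([pool[t] for t in tiles], dtype=float)
    freqs /= freqs.sum()
    if params.pcr_dispersion > 0:
        alpha = freqs / params.pcr_dispersion
        freqs = rng.dirichlet(alpha)
    counts = rng.multinomial(params.n_reads_per_pool, freqs)
    return tiles, counts


def simulate_reads(
    pool: Counter,
    oligo_designs: dict[str, OligoDesign] | list[OligoDesign],
    params: ScreenSimParams,
    rng: np.random.Generator | None = None,
    pool_name: str = "pool",
) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Sequence a pool: (read_id, sequence) pairs plus a per-tile truth table.

    Each read is its tile's arm-flanked oligo truncated (or A-padded) to
    ``read_length``, with i.i.d. substitution errors at ``seq_error_rate``.
    """
    if not isinstance(oligo_designs, dict):
        oligo_designs = {d.tile_id: d for d in oligo_designs}
    if rng is None:
        rng = np.random.default_rng(params.seed + 2)
    missing = [t for t in pool if t not in oligo_designs]
    if missing:
        raise ValueError(f"no oligo design for tile(s): {missing[:3]}")
    L = params.read_length
    tiles, counts = _pool_read_counts(pool, params, rng)

    # templates as uint8 base indices, padded/truncated to read length
    templates = np.zeros((len(tiles), L), dtype=np.uint8)
    for i, t in enumerate(tiles):
        d = oligo_designs[t]
        arm5_len = d.oligo.index(d.cds)
        if L <= arm5_len:
            raise ValueError(
                f"read_length {L} does not reach the insert (5' arm is "
                f"{arm5_len} nt)"
            )
        s = d.oligo[:L].ljust(L, "A")
        templates[i] = _BASE_INDEX[np.frombuffer(s.encode(), dtype=np.uint8)]

    reads_idx = np.repeat(np.arange(len(tiles)), counts)
    mat = templates[reads_idx]
    if params.seq_error_rate > 0 and mat.size:
        err = rng.random(mat.shape) < params.seq_error_rate
        shift = rng.integers(1, 4, size=int(err.sum()), dtype=np.uint8)
        mat[err] = (mat[err] + shift) % 4
    seqs = _BASES[mat]

    reads = [
        (f"{pool_name}:{i}:{tiles[t]}".replace(" ", "_"), bytes(row).decode())
        for i, (t, row) in enumerate(zip(reads_idx, seqs))
    ]
    truth = pd.DataFrame(
        {
            "tile_id": tiles,
            "pool": pool_name,
            "pool_count": [pool[t] for t in tiles],
            "read_count": counts,
        }
    )
    return reads, truth


def write_fastq(reads: list[tuple[str, str]], path, qual_char: str = "I") -> None:
    """Write reads as Phred-33 FASTQ with constant quality."""
    with open(path, "w") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{qual_char * len(seq)}\n")


def simulate_screen(
    library,
    oligo_designs,
    params: ScreenSimParams,
    naive_from: str = "cells",
) -> dict:
    """End-to-end screen: integration, sort, sequencing of both pools.

    ``naive_from`` selects the reference pool: ``"cells"`` (pre-sort infected
    cells, default) or ``"plasmid"`` (the uniform designed library).
    Returns a dict with reads, truth tables, pools and cell assignments.
    """
    if naive_from not in ("cells", "plasmid"):
        raise ValueError("naive_from must be 'cells' or 'plasmid'")
    rng = np.random.default_rng(params.seed)
    if not isinstance(oligo_designs, dict):
        oligo_designs = {d.tile_id: d for d in oligo_designs}
    cells = simulate_integration(params, library, rng)
    sorted_pool, naive_pool = simulate_sort(cells, params, rng)
    if naive_from == "plasmid":
        naive_pool = Counter({t.tile_id: 1 for t in library})
    sorted_reads, sorted_truth = simulate_reads(
        sorted_pool, oligo_designs, params, rng, pool_name="sorted"
    )
    naive_reads, naive_truth = simulate_reads(
        naive_pool, oligo_designs, params, rng, pool_name="naive"
    )
    truth = pd.concat([sorted_truth, naive_truth], ignore_index=True)
    truth["is_activator"] = truth["tile_id"].isin(params.activator_ids)
    return {
        "cells": cells,
        "sorted_pool": sorted_pool,
        "naive_pool": naive_pool,
        "reads": {"sorted": sorted_reads, "naive": naive_reads},
        "truth": truth,
    }
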