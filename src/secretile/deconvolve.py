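"""Sort-seq pool deconvolution: FASTQ -> per-peptide counts -> ranked hits.

Reads are trimmed by locating the constant 5' flank (the assembly arm /
sequencing adapter region) with a small mismatch allowance, the fixed-length
insert is extracted, and inserts are matched to the designed library in three
tiers of decreasing stringency:

1. exact nucleotide match against the designed coding sequences,
2. exact amino-acid match after translation (absorbs synonymous divergence),
3. nearest designed CDS within ``max_nt_mismatches`` substitutions, provided
   the nearest neighbour is unique (ties are discarded, not split).

Enrichment of each tile in the sorted pool over the naive pool is scored by a
one-sided Fisher exact test on the 2x2 read-count table, with
Benjamini-Hochberg FDR control and a pseudocounted log2 frequency ratio; hits
require both q < q_threshold and log2fc >= fc_threshold.  The statistic
follows standard pooled-screen practice and every knob is exposed.
"""

from __future__ import annotations

import gzip
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .oligo import translate

REJECT_REASONS = ("no-flank", "too-short", "bad-length", "no-match", "ambiguous")


@dataclass
class TrimConfig:
    """Constant-region trimming parameters.

    ``five_prime_flank`` is the constant sequence immediately 5' of the
    insert; the insert is the ``insert_length`` bases that follow it
    (3 x tile length for a peptide library).
    """

    five_prime_flank: str
    insert_length: int
    three_prime_flank: str = ""
    max_flank_mismatches: int = 1

    def __post_init__(self) -> None:
        if not self.five_prime_flank:
            raise ValueError("five_prime_flank must be non-empty")
        self.five_prime_flank = self.five_prime_flank.upper()
        self.three_prime_flank = self.three_prime_flank.upper()

    @classmethod
    def from_cloning(cls, cloning_config, tile_length: int = 32, **kw) -> "TrimConfig":
        """Derive trimming from a CloningConfig: the 5' arm is the flank."""
        return cls(
            five_prime_flank=cloning_config.five_prime_arm,
            three_prime_flank=cloning_config.three_prime_arm,
            insert_length=3 * tile_length,
            **kw,
        )


def _find_flank(read: str, flank: str, max_mm: int) -> int:
    """Leftmost start of ``flank`` in ``read`` allowing <= max_mm mismatches; -1 if absent."""
    pos = read.find(flank)
    if pos != -1 or max_mm == 0:
        return pos
    k = len(flank)
    for start in range(len(read) - k + 1):
        mm = 0
        window = read[start : start + k]
        for a, b in zip(window, flank):
            if a != b:
                mm += 1
                if mm > max_mm:
                    break
        else:
            return start
    return -1


def trim_insert(read: str, config: TrimConfig) -> tuple[str | None, str | None]:
    """Extract the insert following the 5' flank.

    Returns ``(insert, None)`` on success, else ``(None, reason)`` with
    reason in {"no-flank", "too-short"}.  Rejections are data, not errors.
    """
    if not read:
        return None, "no-flank"
    read = read.upper()
    pos = _find_flank(read, config.five_prime_flank, config.max_flank_mismatches)
    if pos == -1:
        return None, "no-flank"
    start = pos + len(config.five_prime_flank)
    insert = read[start : start + config.insert_length]
    if len(insert) < config.insert_length:
        return None, "too-short"
    return insert, None


class InsertMatcher:
    """Three-tier insert-to-tile matching against a designed library."""

    def __init__(self, library, oligo_designs, max_nt_mismatches: int = 1):
        if not isinstance(oligo_designs, dict):
            oligo_designs = {d.tile_id: d for d in oligo_designs}
        self.max_nt_mismatches = max_nt_mismatches
        self.cds_to_tile: dict[str, str] = {}
        self.aa_to_tile: dict[str, str] = {}
        self._tile_ids: list[str] = []
        cds_list = []
        for tile in library:
            d = oligo_designs.get(tile.tile_id)
            if d is None:
                raise ValueError(f"no oligo design for tile {tile.tile_id}")
            self.cds_to_tile[d.cds] = tile.tile_id
            self.aa_to_tile.setdefault(tile.sequence, tile.tile_id)
            self._tile_ids.append(tile.tile_id)
            cds_list.append(d.cds)
        lengths = {len(c) for c in cds_list}
        if len(lengths) != 1:
            raise ValueError("designed CDS lengths are not uniform")
        self.insert_length = lengths.pop()
        self._cds_matrix = np.frombuffer(
            "".join(cds_list).encode(), dtype=np.uint8
        ).reshape(len(cds_list), self.insert_length)

    def match(self, insert: str) -> tuple[str | None, str | None]:
        """Return ``(tile_id, None)`` or ``(None, reason)``."""
        if len(insert) != self.insert_length:
            return None, "bad-length"
        tid = self.cds_to_tile.get(insert)
        if tid is not None:
            return tid, None
        if self.insert_length % 3 == 0:
            try:
                aa = translate(insert)
            except Exception:
                aa = None
            if aa is not None:
                tid = self.aa_to_tile.get(aa)
                if tid is not None:
                    return tid, None
        if self.max_nt_mismatches < 1:
            return None, "no-match"
        arr = np.frombuffer(insert.encode(), dtype=np.uint8)
        dists = (self._cds_matrix != arr).sum(axis=1)
        dmin = int(dists.min())
        if dmin > self.max_nt_mismatches:
            return None, "no-match"
        hits = np.flatnonzero(dists == dmin)
        if len(hits) > 1:
            return None, "ambiguous"
        return self._tile_ids[int(hits[0])], None

    def match_batch(self, inserts: list[str]) -> list[tuple[str | None, str | None]]:
        """Vectorised tier-3 for many inserts (tiers 1-2 stay dict lookups)."""
        out: list[tuple[str | None, str | None]] = []
        pending: list[int] = []
        for i, ins in enumerate(inserts):
            if len(ins) != self.insert_length:
                out.append((None, "bad-length"))
                continue
            tid = self.cds_to_tile.get(ins)
            if tid is None and self.insert_length % 3 == 0:
                try:
                    tid = self.aa_to_tile.get(translate(ins))
                except Exception:
                    tid = None
            if tid is not None:
                out.append((tid, None))
            else:
                out.append((None, "no-match"))
                if self.max_nt_mismatches >= 1:
                    pending.append(i)
        # chunked Hamming scan for the residue
        chunk = 2048
        for c0 in range(0, len(pending), chunk):
            idxs = pending[c0 : c0 + chunk]
            block = np.frombuffer(
                "".join(inserts[i] for i in idxs).encode(), dtype=np.uint8
            ).reshape(len(idxs), self.insert_length)
            dists = (
                block[:, None, :] != self._cds_matrix[None, :, :]
            ).sum(axis=2)
            for row, i in enumerate(idxs):
                dmin = int(dists[row].min())
                if dmin > self.max_nt_mismatches:
                    continue
                hits = np.flatnonzero(dists[row] == dmin)
                if len(hits) > 1:
                    out[i] = (None, "ambiguous")
                else:
                    out[i] = (self._tile_ids[int(hits[0])], None)
        return out


def match_insert(insert, library, oligo_designs, max_nt_mismatches: int = 1):
    """One-shot wrapper around :class:`InsertMatcher` for a single insert."""
    m = InsertMatcher(library, oligo_designs, max_nt_mismatches)
    return m.match(insert)


@dataclass
class CountTable:
    """Peptide x sample read counts with an ``unmatched`` catch-all row."""

    counts: pd.DataFrame  # rows: tile ids + "unmatched"; columns: samples
    qc: pd.DataFrame  # per sample: reads_in, trimmed, matched, rejections

    def sample_total(self, sample: str) -> int:
        return int(self.counts[sample].sum())

    def matched_total(self, sample: str) -> int:
        return int(self.counts.drop(index="unmatched")[sample].sum())


def _iter_fastq(source):
    """Yield (title, seq, qual) from a path (optionally .gz), handle, or record list."""
    if isinstance(source, (list, tuple)):
        for rec in source:
            if isinstance(rec, tuple) and len(rec) == 2:
                yield rec[0], rec[1], "I" * len(rec[1])
            else:
                yield rec
        return
    opener = gzip.open if str(source).endswith(".gz") else open
    with opener(str(source), "rt") as fh:
        yield from FastqGeneralIterator(fh)


def count_pools(
    samples: dict,
    trim_config: TrimConfig,
    library,
    oligo_designs,
    max_nt_mismatches: int = 1,
) -> CountTable:
    """Trim, match and count every read of every sample.

    ``samples`` maps sample name -> FASTQ path (optionally gzipped) or an
    in-memory list of reads.  Every input read lands in exactly one of:
    a library tile, or a rejection category (no-flank, too-short, bad-length,
    no-match, ambiguous); rejected reads are tallied in the ``unmatched`` row
    and itemised in the QC table.
    """
    matcher = InsertMatcher(library, oligo_designs, max_nt_mismatches)
    tile_ids = [t.tile_id for t in library]
    counts: dict[str, Counter] = {}
    qc_rows = []
    for sample, source in samples.items():
        c: Counter = Counter()
        reasons: Counter = Counter({r: 0 for r in REJECT_REASONS})
        n_in = n_trimmed = 0
        inserts: list[str] = []
        for i, (title, seq, _qual) in enumerate(_iter_fastq(source)):
            if not seq:
                raise ValueError(f"sample {sample}: unreadable FASTQ record {i}")
            n_in += 1
            insert, reason = trim_insert(seq, trim_config)
            if insert is None:
                reasons[reason] += 1
                continue
            n_trimmed += 1
            inserts.append(insert)
        for tid, reason in matcher.match_batch(inserts):
            if tid is None:
                reasons[reason] += 1
            else:
                c[tid] += 1
        counts[sample] = c
        n_matched = sum(c.values())
        assert n_in == n_matched + sum(reasons.values())
        qc_rows.append(
            {"sample": sample, "reads_in": n_in, "trimmed": n_trimmed,
             "matched": n_matched, **reasons}
        )
    frame = pd.DataFrame(
        {s: [counts[s].get(t, 0) for t in tile_ids] for s in samples},
        index=pd.Index(tile_ids, name="tile_id"),
        dtype=int,
    )
    qc = pd.DataFrame(qc_rows).set_index("sample")
    unmatched = qc["reads_in"] - qc["matched"]
    frame.loc["unmatched"] = [int(unmatched[s]) for s in samples]
    return CountTable(counts=frame, qc=qc)


def fisher_enrichment_pvalues(
    c_sorted: np.ndarray, c_naive: np.ndarray, total_sorted: int, total_naive: int
) -> np.ndarray:
    """One-sided Fisher exact p per tile (enrichment in the sorted pool).

    For the 2x2 table [[c_s, N_s - c_s], [c_n, N_n - c_n]] the one-sided
    p-value is the hypergeometric upper tail P(X >= c_s) with population
    N_s + N_n, c_s + c_n successes and N_s draws.
    """
    c_sorted = np.asarray(c_sorted)
    c_naive = np.asarray(c_naive)
    return hypergeom.sf(
        c_sorted - 1, total_sorted + total_naive, c_sorted + c_naive, total_sorted
    )


class EnrichmentAnalysis:
    """Sorted-vs-naive enrichment model over a count table.

    Parameters
    ----------
    table : CountTable
        Output of :func:`count_pools` (or any frame-backed equivalent).
    sorted_name, naive_name : str
        Column names of the sorted and reference pools.
    """

    def __init__(self, table: CountTable, sorted_name: str, naive_name: str):
        frame = table.counts if isinstance(table, CountTable) else table
        for name in (sorted_name, naive_name):
            if name not in frame.columns:
                raise ValueError(f"sample {name!r} not in count table")
        tiles = frame.drop(index="unmatched", errors="ignore")
        self.tile_ids = list(tiles.index)
        self.c_sorted = tiles[sorted_name].to_numpy()
        self.c_naive = tiles[naive_name].to_numpy()
        self.total_sorted = int(self.c_sorted.sum())
        self.total_naive = int(self.c_naive.sum())
        if self.total_sorted == 0 or self.total_naive == 0:
            raise ValueError("zero total reads in sorted or naive pool")
        self.sorted_name = sorted_name
        self.naive_name = naive_name

    def fit(
        self,
        pseudocount: float = 0.5,
        q_threshold: float = 0.05,
        fc_threshold: float = 1.0,
    ) -> "EnrichmentResults":
        """Score every tile; returns ranked results.

        log2fc uses pseudocounted frequencies
        ``(c + pc) / (N + 2 pc)``; p from the one-sided Fisher exact test;
        q by Benjamini-Hochberg across all tiles; a hit needs
        ``q < q_threshold`` and ``log2fc >= fc_threshold``.
        """
        pc = pseudocount
        f_s = (self.c_sorted + pc) / (self.total_sorted + 2 * pc)
        f_n = (self.c_naive + pc) / (self.total_naive + 2 * pc)
        log2fc = np.log2(f_s / f_n)
        p = fisher_enrichment_pvalues(
            self.c_sorted, self.c_naive, self.total_sorted, self.total_naive
        )
        _, q, _, _ = multipletests(p, method="fdr_bh")
        frame = pd.DataFrame(
            {
                "tile_id": self.tile_ids,
                "count_sorted": self.c_sorted,
                "count_naive": self.c_naive,
                "total_sorted": self.total_sorted,
                "total_naive": self.total_naive,
                "log2fc": log2fc,
                "p_value": p,
                "q_value": q,
            }
        )
        frame["is_hit"] = (frame["q_value"] < q_threshold) & (
            frame["log2fc"] >= fc_threshold
        )
        frame = frame.sort_values(
            ["q_value", "log2fc"], ascending=[True, False], kind="mergesort"
        ).reset_index(drop=True)
        frame.index = pd.RangeIndex(1, len(frame) + 1, name="rank")
        return EnrichmentResults(
            frame, q_threshold=q_threshold, fc_threshold=fc_threshold,
            sorted_name=self.sorted_name, naive_name=self.naive_name,
        )


class EnrichmentResults:
    """Ranked per-tile enrichment calls with thresholds used."""

    def __init__(self, frame, q_threshold, fc_threshold, sorted_name, naive_name):
        self.frame = frame
        self.q_threshold = q_threshold
        self.fc_threshold = fc_threshold
        self.sorted_name = sorted_name
        self.naive_name = naive_name

    @property
    def hits(self) -> pd.DataFrame:
        return self.frame[self.frame["is_hit"]]

    def top(self, n: int = 10) -> pd.DataFrame:
        return self.frame.head(n)

    def summary(self) -> str:
        f = self.frame
        lines = [
            "Sorted-vs-naive enrichment (one-sided Fisher exact, BH FDR)",
            f"  pools: sorted={self.sorted_name!r}  naive={self.naive_name!r}",
            f"  tiles tested: {len(f)}   reads: "
            f"{int(f['total_sorted'].iloc[0])} sorted / "
            f"{int(f['total_naive'].iloc[0])} naive",
            f"  hits (q < {self.q_threshold}, log2fc >= {self.fc_threshold}): "
            f"{int(f['is_hit'].sum())}",
            "",
            f.head(10).to_string(
                columns=["tile_id", "count_sorted", "count_naive", "log2fc",
                         "p_value", "q_value", "is_hit"],
                float_format=lambda x: f"{x:.3g}",
            ),
        ]
        return "\n".join(lines)

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index_label="rank")


def score_enrichment(
    table: CountTable,
    sorted_name: str,
    naive_name: str,
    pseudocount: float = 0.5,
    q_threshold: float = 0.05,
    fc_threshold: float = 1.0,
) -> EnrichmentResults:
    """Functional wrapper: build the analysis and fit in one call."""
    return EnrichmentAnalysis(table, sorted_name, naive_name).fit(
        pseudocount=pseudocount, q_threshold=q_threshold, fc_threshold=fc_threshold
    )
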