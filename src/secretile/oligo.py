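"""Reverse translation and clonable oligo assembly.

Each peptide tile is realised as a coding sequence (CDS) by weighted-random
codon sampling from a human codon-usage table, flanked by Gibson-assembly
arms.  Because the library insert is cloned with BsrGI and PstI, the insert
(and both arm junctions) must not contain either recognition site on either
strand; synonymous "scrubbing" removes any occurrence while preserving the
encoded peptide.

Weighted sampling (rather than always-best codon) keeps overlapping tiles
from producing long identical nucleotide stretches, which are hostile to
array synthesis; a fixed seed makes the whole pool byte-reproducible.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Seq import Seq

BSRGI_SITE = "TGTACA"
PSTI_SITE = "CTGCAG"

# Human codon-usage fractions (per amino acid); normalised at load.
_HUMAN_USAGE = {
    "A": [("GCC", 0.40), ("GCT", 0.26), ("GCA", 0.23), ("GCG", 0.11)],
    "R": [("CGG", 0.21), ("AGA", 0.20), ("AGG", 0.20), ("CGC", 0.19), ("CGA", 0.11), ("CGT", 0.08)],
    "N": [("AAC", 0.54), ("AAT", 0.46)],
    "D": [("GAC", 0.54), ("GAT", 0.46)],
    "C": [("TGC", 0.55), ("TGT", 0.45)],
    "Q": [("CAG", 0.75), ("CAA", 0.25)],
    "E": [("GAG", 0.58), ("GAA", 0.42)],
    "G": [("GGC", 0.34), ("GGA", 0.25), ("GGG", 0.25), ("GGT", 0.16)],
    "H": [("CAC", 0.59), ("CAT", 0.41)],
    "I": [("ATC", 0.48), ("ATT", 0.36), ("ATA", 0.16)],
    "L": [("CTG", 0.40), ("CTC", 0.20), ("TTG", 0.13), ("CTT", 0.13), ("TTA", 0.07), ("CTA", 0.07)],
    "K": [("AAG", 0.58), ("AAA", 0.42)],
    "M": [("ATG", 1.00)],
    "F": [("TTC", 0.55), ("TTT", 0.45)],
    "P": [("CCC", 0.33), ("CCT", 0.28), ("CCA", 0.27), ("CCG", 0.11)],
    "S": [("AGC", 0.24), ("TCC", 0.22), ("TCT", 0.18), ("TCA", 0.15), ("AGT", 0.15), ("TCG", 0.06)],
    "T": [("ACC", 0.36), ("ACA", 0.28), ("ACT", 0.24), ("ACG", 0.12)],
    "W": [("TGG", 1.00)],
    "Y": [("TAC", 0.57), ("TAT", 0.43)],
    "V": [("GTG", 0.47), ("GTC", 0.24), ("GTT", 0.18), ("GTA", 0.11)],
}

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def translate(cds: str) -> str:
    """Translate a CDS (length divisible by 3) to amino acids."""
    if len(cds) % 3:
        raise ValueError("CDS length not divisible by 3")
    return str(Seq(cds).translate())


@dataclass
class CodonTable:
    """Amino acid -> [(codon, weight)] with per-residue weights summing to 1."""

    usage: dict[str, list[tuple[str, float]]]

    def __post_init__(self) -> None:
        norm: dict[str, list[tuple[str, float]]] = {}
        for aa, entries in self.usage.items():
            if not entries:
                raise ValueError(f"amino acid {aa!r} has no codons")
            for codon, _ in entries:
                back = translate(codon)
                if back != aa:
                    raise ValueError(f"codon {codon} translates to {back}, not {aa}")
            total = sum(w for _, w in entries)
            norm[aa] = [(c, w / total) for c, w in entries]
        self.usage = norm

    def codons(self, aa: str) -> list[str]:
        return [c for c, _ in self.usage[aa]]

    def weights(self, aa: str) -> np.ndarray:
        return np.array([w for _, w in self.usage[aa]])


HUMAN_CODON_USAGE = CodonTable(_HUMAN_USAGE)


@dataclass
class CloningConfig:
    """Assembly arms, forbidden restriction motifs, and scrubbing limits.

    The default forbidden motifs are the BsrGI (TGTACA) and PstI (CTGCAG)
    recognition sites used to open the destination vector; both strands are
    scanned regardless of palindromicity.
    """

    five_prime_arm: str = ""
    three_prime_arm: str = ""
    forbidden_motifs: tuple[str, ...] = (BSRGI_SITE, PSTI_SITE)
    seed: int = 0
    max_scrub_attempts: int = 100

    def __post_init__(self) -> None:
        self.five_prime_arm = self.five_prime_arm.upper()
        self.three_prime_arm = self.three_prime_arm.upper()
        motifs = self.both_strand_motifs()
        for arm, name in ((self.five_prime_arm, "5'"), (self.three_prime_arm, "3'")):
            for m in motifs:
                if m in arm:
                    raise ValueError(f"{name} arm contains forbidden motif {m}")

    def both_strand_motifs(self) -> tuple[str, ...]:
        """Forbidden motifs plus their reverse complements, deduplicated."""
        out: list[str] = []
        for m in self.forbidden_motifs:
            for v in (m.upper(), revcomp(m.upper())):
                if v not in out:
                    out.append(v)
        return tuple(out)


@dataclass
class OligoDesign:
    """Nucleotide realisation of one tile: arms + scrubbed CDS."""

    tile_id: str
    cds: str
    oligo: str
    scrub_edits: int = 0


def reverse_translate(peptide: str, table: CodonTable | None = None, seed=0) -> str:
    """Sample one codon per residue, weighted by usage; deterministic per seed.

    ``seed`` may be an int or a ``numpy.random.Generator`` (the latter lets a
    caller thread one stream through a whole library).
    """
    if table is None:
        table = HUMAN_CODON_USAGE
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    parts: list[str] = []
    for pos, aa in enumerate(peptide, start=1):
        if aa not in table.usage:
            raise ValueError(f"non-standard residue {aa!r} at position {pos}")
        codons = table.codons(aa)
        parts.append(codons[rng.choice(len(codons), p=table.weights(aa))])
    return "".join(parts)


def _find_motif_spans(seq: str, motifs: tuple[str, ...]) -> list[tuple[int, int]]:
    """All (start, end) half-open spans of any motif in seq, sorted."""
    spans = []
    for m in motifs:
        start = seq.find(m)
        while start != -1:
            spans.append((start, start + len(m)))
            start = seq.find(m, start + 1)
    return sorted(spans)


def _scrub(
    cds: str,
    five_arm: str,
    three_arm: str,
    motifs: tuple[str, ...],
    table: CodonTable,
    max_attempts: int,
) -> tuple[str, int]:
    """Greedy left-to-right synonymous scrubbing of motifs in arm+cds+arm.

    For each motif occurrence the codons it overlaps are re-assigned by
    exhaustive search over synonymous combinations, preferring the fewest
    codon edits and then the highest-usage codons; a combination is accepted
    if it strictly reduces the total motif count without re-creating the
    occurrence.  Deterministic.
    """
    codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
    aas = [translate(c) for c in codons]
    off = len(five_arm)
    edits = 0

    for _ in range(max_attempts):
        full = five_arm + "".join(codons) + three_arm
        spans = _find_motif_spans(full, motifs)
        if not spans:
            return "".join(codons), edits
        s, e = spans[0]
        # codon indices overlapping the motif span (clipped to the CDS)
        lo = max(0, (s - off) // 3)
        hi = min(len(codons), (e - off + 2) // 3)
        idxs = list(range(lo, hi))
        if not idxs:
            raise ValueError(
                f"forbidden motif {full[s:e]} at {s} lies outside the coding "
                "sequence and cannot be scrubbed"
            )
        # candidate synonymous codons per position, usage-ordered
        options = [table.codons(aas[i]) for i in idxs]
        best = None
        for combo in itertools.product(*options):
            n_edit = sum(c != codons[i] for i, c in zip(idxs, combo))
            if n_edit == 0:
                continue
            trial = list(codons)
            for i, c in zip(idxs, combo):
                trial[i] = c
            t_full = five_arm + "".join(trial) + three_arm
            t_spans = _find_motif_spans(t_full, motifs)
            if any(ts < e and te > s for ts, te in t_spans):
                continue  # occurrence survives or re-forms in place
            if len(t_spans) >= len(spans):
                continue
            key = (n_edit,)  # itertools.product order already prefers high usage
            if best is None or key < best[0]:
                best = (key, trial, n_edit)
                if n_edit == 1:
                    break
        if best is None:
            raise ValueError(
                f"cannot remove forbidden motif {full[s:e]} at position {s} "
                "by synonymous substitution"
            )
        codons = best[1]
        edits += best[2]

    raise ValueError(
        f"scrubbing did not converge within {max_attempts} attempts"
    )


def scrub_forbidden_sites(
    cds: str,
    config: CloningConfig | None = None,
    table: CodonTable | None = None,
    with_arms: bool = False,
) -> str:
    """Return a synonymous CDS free of forbidden motifs on both strands.

    With ``with_arms`` the configured assembly arms are included in the scan
    so that junction-spanning motifs are also removed (only CDS codons are
    ever edited).
    """
    if config is None:
        config = CloningConfig()
    if table is None:
        table = HUMAN_CODON_USAGE
    if len(cds) % 3:
        raise ValueError("CDS length not divisible by 3")
    five = config.five_prime_arm if with_arms else ""
    three = config.three_prime_arm if with_arms else ""
    scrubbed, _ = _scrub(
        cds.upper(), five, three, config.both_strand_motifs(), table,
        config.max_scrub_attempts,
    )
    return scrubbed


def assemble_oligo(
    cds: str,
    config: CloningConfig,
    table: CodonTable | None = None,
    tile_id: str = "",
    prior_edits: int = 0,
) -> OligoDesign:
    """Flank a scrubbed CDS with the assembly arms, re-scrubbing junctions.

    Raises if a junction motif cannot be removed synonymously.
    """
    if table is None:
        table = HUMAN_CODON_USAGE
    motifs = config.both_strand_motifs()
    cds2, extra = _scrub(
        cds.upper(),
        config.five_prime_arm,
        config.three_prime_arm,
        motifs,
        table,
        config.max_scrub_attempts,
    )
    oligo = config.five_prime_arm + cds2 + config.three_prime_arm
    assert not _find_motif_spans(oligo, motifs)
    return OligoDesign(
        tile_id=tile_id, cds=cds2, oligo=oligo, scrub_edits=prior_edits + extra
    )


def design_oligos(library, config: CloningConfig | None = None,
                  table: CodonTable | None = None) -> list[OligoDesign]:
    """Design one oligo per library tile: reverse-translate, scrub, add arms.

    A single RNG seeded from ``config.seed`` is threaded through the tiles in
    library order, so the whole pool is byte-reproducible.
    """
    if config is None:
        config = CloningConfig()
    if table is None:
        table = HUMAN_CODON_USAGE
    rng = np.random.default_rng(config.seed)
    motifs = config.both_strand_motifs()
    designs: list[OligoDesign] = []
    for tile in library:
        raw = reverse_translate(tile.sequence, table, rng)
        cds, edits = _scrub(
            raw, config.five_prime_arm, config.three_prime_arm, motifs, table,
            config.max_scrub_attempts,
        )
        oligo = config.five_prime_arm + cds + config.three_prime_arm
        designs.append(
            OligoDesign(tile_id=tile.tile_id, cds=cds, oligo=oligo, scrub_edits=edits)
        )
    return designs


def oligos_to_frame(designs: list[OligoDesign]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"tile_id": d.tile_id, "cds": d.cds, "oligo": d.oligo, "edits": d.scrub_edits}
            for d in designs
        ],
        columns=["tile_id", "cds", "oligo", "edits"],
    )


def write_oligos_fasta(designs: list[OligoDesign], path) -> None:
    with open(path, "w") as fh:
        for d in designs:
            fh.write(f">{d.tile_id}\n{d.oligo}\n")
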