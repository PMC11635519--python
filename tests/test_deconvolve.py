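"""Deconvolution: trimming, tiered matching, counting conservation, enrichment."""

import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import fisher_exact

from secretile import (
    CountTable,
    EnrichmentAnalysis,
    ScreenSimParams,
    TrimConfig,
    count_pools,
    match_insert,
    score_enrichment,
    simulate_screen,
    trim_insert,
)
from secretile.deconvolve import InsertMatcher, fisher_enrichment_pvalues
from secretile.oligo import translate

import pandas as pd


# ---------------------------------------------------------------- trimming

TRIM = TrimConfig(five_prime_flank="ACGTACGTCC", insert_length=12,
                  max_flank_mismatches=1)


def test_trim_exact_flank():
    read = "TT" + TRIM.five_prime_flank + "AAACCCGGGTTT" + "GGGG"
    assert trim_insert(read, TRIM) == ("AAACCCGGGTTT", None)


def test_trim_missing_flank():
    assert trim_insert("A" * 40, TRIM) == (None, "no-flank")


def test_trim_flank_with_one_mismatch():
    flank = "ACGTACGACC"  # one substitution vs ACGTACGTCC
    read = flank + "AAACCCGGGTTT"
    assert trim_insert(read, TRIM) == ("AAACCCGGGTTT", None)
    strict = TrimConfig(five_prime_flank=TRIM.five_prime_flank,
                        insert_length=12, max_flank_mismatches=0)
    assert trim_insert(read, strict) == (None, "no-flank")


def test_trim_truncated_insert():
    read = TRIM.five_prime_flank + "AAACCC"
    assert trim_insert(read, TRIM) == (None, "too-short")


# ---------------------------------------------------------------- matching

def test_match_tiers(library_small, designs_small):
    matcher = InsertMatcher(library_small, designs_small)
    d0 = designs_small[0]
    # tier 1: exact nucleotide
    assert matcher.match(d0.cds) == (d0.tile_id, None)
    # tier 2: synonymous recoding still matches by translation
    from secretile import reverse_translate

    recoded = reverse_translate(translate(d0.cds), seed=999)
    if recoded != d0.cds:
        assert matcher.match(recoded) == (d0.tile_id, None)
    # tier 3: single substitution, unique nearest neighbour
    mutated = "G" + d0.cds[1:] if d0.cds[0] != "G" else "A" + d0.cds[1:]
    tid, reason = matcher.match(mutated)
    assert (tid, reason) == (d0.tile_id, None)
    # bad length
    assert matcher.match(d0.cds[:-1]) == (None, "bad-length")
    # hopeless insert
    junk = "A" * matcher.insert_length
    tid, reason = matcher.match(junk)
    assert tid is None


def test_match_ambiguous_tie():
    """An insert equidistant (1 mismatch) from two designed CDSs is discarded."""
    from secretile.library import PeptideTile, TileLibrary, TileParams
    from secretile.oligo import OligoDesign

    cds1 = "ATGTGGAAA"  # M W K
    cds2 = "TTGTGGATA"  # L W I  (differs at positions 0 and 7)
    tiles = [
        PeptideTile("A", 1, 3, translate(cds1)),
        PeptideTile("B", 1, 3, translate(cds2)),
    ]
    lib = TileLibrary(tiles=tiles, params=TileParams(tile_length=3, overlap=1))
    designs = [
        OligoDesign("A|1-3", cds1, cds1),
        OligoDesign("B|1-3", cds2, cds2),
    ]
    insert = "TTGTGGAAA"  # 1 mismatch from each, translates to LWK (neither)
    assert match_insert(insert, lib, designs) == (None, "ambiguous")


def test_match_batch_agrees_with_single(library_small, designs_small):
    matcher = InsertMatcher(library_small, designs_small)
    rng = np.random.default_rng(4)
    inserts = []
    for d in designs_small[:20]:
        s = list(d.cds)
        for _ in range(rng.integers(0, 3)):
            i = rng.integers(len(s))
            s[i] = "ACGT"[rng.integers(4)]
        inserts.append("".join(s))
    assert matcher.match_batch(inserts) == [matcher.match(i) for i in inserts]


# ---------------------------------------------------------------- counting

def _screen(library_small, designs_small, **kw):
    defaults = dict(
        n_cells=8_000,
        activator_ids={library_small.tiles[0].tile_id},
        n_reads_per_pool=5_000,
        seq_error_rate=0.0,
        seed=31,
    )
    defaults.update(kw)
    return simulate_screen(library_small, designs_small,
                           ScreenSimParams(**defaults))


def test_count_conservation_and_truth(library_small, designs_small, cloning):
    res = _screen(library_small, designs_small)
    trim = TrimConfig.from_cloning(cloning, tile_length=32)
    table = count_pools(
        {"sorted": res["reads"]["sorted"], "naive": res["reads"]["naive"]},
        trim, library_small, designs_small,
    )
    for s in ("sorted", "naive"):
        assert table.sample_total(s) == int(table.qc.loc[s, "reads_in"]) == 5_000
        reasons = table.qc.loc[s, ["no-flank", "too-short", "bad-length",
                                   "no-match", "ambiguous"]].sum()
        assert table.qc.loc[s, "matched"] + reasons == 5_000
    # error-free reads: counts reproduce the simulator truth exactly
    truth = res["truth"]
    for pool in ("sorted", "naive"):
        sub = truth[truth["pool"] == pool].set_index("tile_id")["read_count"]
        for tid, n in sub.items():
            assert table.counts.loc[tid, pool] == n
    assert table.counts.loc["unmatched"].sum() == 0


def test_noisy_reads_still_mostly_matched(library_small, designs_small, cloning):
    res = _screen(library_small, designs_small, seq_error_rate=0.002, seed=32)
    trim = TrimConfig.from_cloning(cloning, tile_length=32)
    table = count_pools(
        {"sorted": res["reads"]["sorted"], "naive": res["reads"]["naive"]},
        trim, library_small, designs_small,
    )
    assert (table.qc["matched"] / table.qc["reads_in"]).min() > 0.98


def test_empty_sample_gives_zero_column(library_small, designs_small, cloning):
    trim = TrimConfig.from_cloning(cloning, tile_length=32)
    table = count_pools({"empty": []}, trim, library_small, designs_small)
    assert table.counts["empty"].sum() == 0


def test_fastq_file_roundtrip(tmp_path, library_small, designs_small, cloning):
    from secretile.simulate import write_fastq

    res = _screen(library_small, designs_small, n_reads_per_pool=500)
    path = tmp_path / "sorted.fastq"
    write_fastq(res["reads"]["sorted"], path)
    trim = TrimConfig.from_cloning(cloning, tile_length=32)
    t_file = count_pools({"s": str(path)}, trim, library_small, designs_small)
    t_mem = count_pools({"s": res["reads"]["sorted"]}, trim, library_small,
                        designs_small)
    assert t_file.counts.equals(t_mem.counts)


# ---------------------------------------------------------------- enrichment

def hypergeom_tail_exact(c_s, c_n, N_s, N_n) -> Fraction:
    """Exact one-sided Fisher p by rational hypergeometric enumeration."""
    M, K, n = N_s + N_n, c_s + c_n, N_s
    total = Fraction(0)
    for k in range(c_s, min(K, n) + 1):
        if K - k > M - n:
            continue
        total += Fraction(math.comb(K, k) * math.comb(M - K, n - k),
                          math.comb(M, n))
    return total


@pytest.mark.parametrize(
    "c_s, c_n, N_s, N_n",
    [(10, 1, 100, 100), (0, 0, 50, 60), (5, 5, 50, 50), (20, 0, 40, 160),
     (1, 19, 100, 100)],
)
def test_fisher_matches_exact_enumeration(c_s, c_n, N_s, N_n):
    p = fisher_enrichment_pvalues(np.array([c_s]), np.array([c_n]), N_s, N_n)[0]
    exact = float(hypergeom_tail_exact(c_s, c_n, N_s, N_n))
    assert p == pytest.approx(exact, rel=1e-10, abs=1e-300)
    # independent library cross-check
    _, p_sp = fisher_exact([[c_s, N_s - c_s], [c_n, N_n - c_n]],
                           alternative="greater")
    assert p == pytest.approx(p_sp, rel=1e-9)


def test_spec_table_example():
    """2x2 table (10, 90; 1, 99): p equals the exhaustive hypergeometric tail."""
    p = fisher_enrichment_pvalues(np.array([10]), np.array([1]), 100, 100)[0]
    assert p == pytest.approx(float(hypergeom_tail_exact(10, 1, 100, 100)),
                              rel=1e-12)


def _table(c_s, c_n, extra_s=0, extra_n=0):
    frame = pd.DataFrame(
        {"sorted": list(c_s) + [extra_s], "naive": list(c_n) + [extra_n]},
        index=pd.Index([f"t{i}" for i in range(len(c_s))] + ["unmatched"],
                       name="tile_id"),
    )
    qc = pd.DataFrame(index=["sorted", "naive"])
    return CountTable(counts=frame, qc=qc)


def test_symmetric_counts_give_zero_log2fc():
    table = _table([10, 20, 70], [10, 20, 70])
    res = score_enrichment(table, "sorted", "naive")
    assert np.allclose(res.frame["log2fc"], 0.0)
    assert not res.frame["is_hit"].any()


def test_enrichment_ranking_and_hit_rule(library_small, designs_small, cloning):
    res = _screen(library_small, designs_small, n_cells=20_000,
                  n_reads_per_pool=20_000)
    trim = TrimConfig.from_cloning(cloning, tile_length=32)
    table = count_pools(
        {"sorted": res["reads"]["sorted"], "naive": res["reads"]["naive"]},
        trim, library_small, designs_small,
    )
    out = score_enrichment(table, "sorted", "naive")
    f = out.frame
    # q-values respect invariants and the planted activator ranks first
    assert (f["q_value"] >= f["p_value"] - 1e-15).all()
    assert f.iloc[0]["tile_id"] == library_small.tiles[0].tile_id
    assert bool(f.iloc[0]["is_hit"])
    hit_rows = f[f["is_hit"]]
    assert (hit_rows["q_value"] < out.q_threshold).all()
    assert (hit_rows["log2fc"] >= out.fc_threshold).all()
    assert "enrichment" in out.summary().lower()


@settings(max_examples=50, deadline=None)
@given(seed=st.integers(0, 10_000))
def test_bh_q_monotone_in_p_rank(seed):
    rng = np.random.default_rng(seed)
    c_s = rng.integers(0, 50, size=30)
    c_n = rng.integers(0, 50, size=30)
    table = _table(c_s, c_n)
    f = score_enrichment(table, "sorted", "naive").frame
    ordered = f.sort_values("p_value")
    assert (np.diff(ordered["q_value"]) >= -1e-15).all()
    assert (f["q_value"] <= 1.0 + 1e-15).all()


def test_zero_total_pool_rejected():
    table = _table([0, 0], [1, 2])
    with pytest.raises(ValueError, match="zero total"):
        EnrichmentAnalysis(table, "sorted", "naive")


def test_missing_sample_rejected():
    table = _table([1], [1])
    with pytest.raises(ValueError, match="not in count table"):
        EnrichmentAnalysis(table, "sorted", "missing")
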