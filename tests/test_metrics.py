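import numpy as np
import pytest
from hypothesis import given, strategies as st

from virobench.assembly import Assembly, Contig, PlacedRead
from virobench.community import TruthManifest, TruthRecord
from virobench.metrics import (
    Hsp,
    align_contig,
    compile_stats,
    contig_score,
    contig_taxonomy,
    detect_chimeras,
    genomes_recovered,
    n_statistic,
    pct_reads_on_original_genome,
    project_contig,
    read_stats_tsv,
    viral_bacterial_hits,
    write_stats_tsv,
)
from virobench.taxonomy import build_taxonomy


def brute_force_n_statistic(lengths, fraction):
    """Independent oracle: scan the sorted lengths accumulating bases."""
    lengths = sorted(lengths, reverse=True)
    total = sum(lengths)
    acc = 0
    for l in lengths:
        acc += l
        if acc >= fraction * total:
            return l
    return lengths[-1]


# ------------------------------------------------------------ N statistics

@pytest.mark.parametrize(
    "lengths,fraction,expected",
    [
        ([42], 0.3, 42),
        ([42], 0.9, 42),
        ([5, 4, 3, 2, 1], 0.5, 4),  # cum 5, 9 >= 7.5 at the 4
        ([4, 4, 4], 0.9, 4),  # cum 4, 8, 12 >= 10.8 at the third 4
    ],
)
def test_n_statistic_examples(lengths, fraction, expected):
    assert n_statistic(lengths, fraction) == expected


def test_n_statistic_empty_warns_and_returns_zero():
    with pytest.warns(UserWarning):
        assert n_statistic([], 0.5) == 0


def test_n_statistic_matches_brute_force_on_random_multisets():
    rng = np.random.default_rng(0)
    for _ in range(1000):
        n = int(rng.integers(1, 200))
        lengths = rng.integers(1, 10_000, size=n).tolist()
        for frac in (0.3, 0.5, 0.9):
            assert n_statistic(lengths, frac) == brute_force_n_statistic(lengths, frac)


# ----------------------------------------------------- chimeras / taxonomy

def _manifest(rows):
    return TruthManifest(TruthRecord(*row) for row in rows)


def _contig(cid, reads, consensus="A" * 500):
    return Contig(cid, consensus, [PlacedRead(r, 1, "+") for r in reads])


def test_single_genome_contigs_yield_no_chimeras(small_community):
    records = detect_chimeras(
        small_community["assembly"],
        small_community["manifest"],
        small_community["taxonomy"],
    )
    assert records == []


def test_chimera_lca_and_viral_bacterial_flag():
    tax = build_taxonomy(2, 2, 2, viral_fraction=0.5, seed=7)
    species = tax.species()
    viral = [s for s in species if tax.is_viral_taxon(s.taxon_id)]
    bact = [s for s in species if not tax.is_viral_taxon(s.taxon_id)]
    same_genus = [s for s in species if s.parent_id == species[0].parent_id]
    rows = [
        ("r1", "GA", same_genus[0].taxon_id, 1, 400, "+", 0),
        ("r2", "GB", same_genus[1].taxon_id, 1, 400, "+", 0),
        ("r3", "GV", viral[0].taxon_id, 1, 400, "+", 0),
        ("r4", "GX", bact[0].taxon_id, 1, 400, "+", 0),
    ]
    man = _manifest(rows)
    asm = Assembly(
        label="x",
        contigs=[_contig("c1", ["r1", "r2"]), _contig("c2", ["r3", "r4"])],
    )
    records = {r.contig_id: r for r in detect_chimeras(asm, man, tax)}
    assert records["c1"].lca_rank == "genus"
    assert not records["c1"].viral_bacterial
    assert records["c2"].lca_rank == "root"
    assert records["c2"].viral_bacterial


def test_missing_manifest_read_is_an_error(small_community):
    asm = Assembly(label="x", contigs=[_contig("c1", ["ghost", "r0"])])
    with pytest.raises(KeyError, match="ghost"):
        detect_chimeras(
            asm, small_community["manifest"], small_community["taxonomy"]
        )


def test_contig_taxonomy_majority_and_tie():
    man = _manifest(
        [
            ("r1", "A", 1, 1, 400, "+", 0),
            ("r2", "A", 1, 1, 400, "+", 0),
            ("r3", "A", 1, 1, 400, "+", 0),
            ("r4", "B", 2, 1, 400, "+", 0),
        ]
    )
    call = contig_taxonomy(_contig("c", ["r1", "r2", "r3", "r4"]), man)
    assert (call.genome_id, call.tie) == ("A", False)
    tie = contig_taxonomy(_contig("c", ["r3", "r4"]), man)
    assert (tie.genome_id, tie.tie) == ("A", True)
    single = contig_taxonomy(_contig("c", ["r4"]), man)
    assert (single.genome_id, single.tie) == ("B", False)


# ---------------------------------------------------------------- aligner

def test_align_exact_substring_scores_perfect(small_genomes):
    g = small_genomes[0]
    h = align_contig(g.sequence[100:700], g)
    assert h.aligned_contig_fraction == pytest.approx(1.0)
    assert h.identity == pytest.approx(100.0)
    assert contig_score(h) == pytest.approx(100.0)


def test_align_five_percent_substitutions(small_genomes):
    g = small_genomes[0]
    rng = np.random.default_rng(1)
    seq = list(g.sequence[0:600])
    sites = rng.choice(600, size=30, replace=False)  # exactly 5% of sites
    for i in sites:
        seq[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[seq[i]]
    h = align_contig("".join(seq), g)
    assert h.identity == pytest.approx(95.0, abs=1.0)


def test_align_unrelated_sequence_returns_none():
    rng = np.random.default_rng(2)
    a = "".join(rng.choice(list("ACGT"), 60))
    assert align_contig(a, "T" * 5000, min_score=30.0) is None


@pytest.mark.parametrize(
    "fraction,identity,expected",
    [(1.0, 100.0, 100.0), (0.8, 95.0, 76.0), (0.5, 50.0, 25.0)],
)
def test_contig_score_is_fraction_times_identity(fraction, identity, expected):
    h = Hsp("c", "g", fraction, identity)
    assert contig_score(h) == pytest.approx(expected)


def test_projection_agrees_with_aligner_on_optimal_contigs(small_community):
    genomes = {g.genome_id: g for g in small_community["genomes"]}
    c = small_community["assembly"].contigs[0]
    hsps = project_contig(c, small_community["manifest"], genomes)
    (gid,) = hsps
    proj = hsps[gid]
    aln = align_contig(c, genomes[gid])
    assert proj.identity == pytest.approx(aln.identity) == pytest.approx(100.0)
    assert proj.aligned_contig_fraction == pytest.approx(aln.aligned_contig_fraction)
    assert (proj.genome_start, proj.genome_end) == (aln.genome_start, aln.genome_end)


# ----------------------------------------------------------- read metrics

def test_pct_reads_on_original_genome_hand_tally():
    man = _manifest(
        [
            ("r1", "A", 1, 1, 400, "+", 0),
            ("r2", "A", 1, 1, 400, "+", 0),
            ("r3", "A", 1, 1, 400, "+", 0),
            ("r4", "B", 2, 1, 400, "+", 0),
        ]
    )
    asm = Assembly(label="x", contigs=[_contig("c1", ["r1", "r2", "r3", "r4"])])
    majority = {"c1": contig_taxonomy(asm.contigs[0], man)}
    # correctly assigned contig: 3 of its 4 reads match organism A
    assert pct_reads_on_original_genome(asm, man, majority, {"c1": "A"}) == 75.0
    # misassigned contig contributes nothing
    assert pct_reads_on_original_genome(asm, man, majority, {"c1": "B"}) == 0.0


def test_viral_bacterial_hit_requires_exact_score_tie():
    asm = Assembly(
        label="x", contigs=[_contig("c1", ["r1"]), _contig("c2", ["r2"])]
    )
    pct, hits = viral_bacterial_hits(
        asm, {"c1": 100.0, "c2": 95.0}, {"c1": 100.0, "c2": 94.9}
    )
    assert hits == ["c1"]
    assert pct == 50.0
    pct_none, _ = viral_bacterial_hits(asm, {"c1": 90.0, "c2": None}, {"c1": None, "c2": None})
    assert pct_none == 0.0


def test_genome_recovery_boundaries():
    class G:
        def __init__(self, gid, n):
            self.genome_id = gid
            self.sequence = "A" * n
            self.is_viral = True

        def __len__(self):
            return len(self.sequence)

    genomes = [G("g1", 1000), G("g2", 1000)]
    hsps = {
        "c1": {"g1": Hsp("c1", "g1", 1.0, 96.0, genome_start=1, genome_end=1000)},
        "c2": {"g2": Hsp("c2", "g2", 1.0, 99.0, genome_start=1, genome_end=990)},
    }
    assert genomes_recovered(hsps, genomes) == 1  # 99% span does not count
    hsps["c2"]["g2"] = Hsp("c2", "g2", 1.0, 95.0, genome_start=1, genome_end=1000)
    assert genomes_recovered(hsps, genomes) == 1  # identity must exceed 95


# ------------------------------------------------------------- full vector

def test_optimal_assembly_stats_invariants(small_community):
    stats = compile_stats(
        small_community["assembly"],
        small_community["manifest"],
        small_community["genomes"],
        small_community["taxonomy"],
    )
    assert stats.pct_chimeric == 0.0
    assert stats.pct_viral_bacterial_chimeric == 0.0
    assert stats.identity_median == pytest.approx(100.0)
    assert stats.pct_reads_on_original_genome == pytest.approx(100.0)
    assert stats.n90 <= stats.n50 <= stats.n30 <= stats.largest_contig


def test_empty_assembly_stats_are_zero(small_community):
    empty = Assembly(label="empty", contigs=[])
    with pytest.warns(UserWarning):
        stats = compile_stats(
            empty,
            small_community["manifest"],
            small_community["genomes"],
            small_community["taxonomy"],
        )
    assert stats.largest_contig == stats.n50 == stats.n_contigs == 0
    assert stats.pct_reads_assembled == 0.0


def test_stats_tsv_roundtrip(tmp_path, small_community):
    stats = compile_stats(
        small_community["assembly"],
        small_community["manifest"],
        small_community["genomes"],
        small_community["taxonomy"],
    )
    path = tmp_path / "stats.tsv"
    write_stats_tsv([stats], path)
    (loaded,) = read_stats_tsv(path)
    assert loaded == stats


@given(
    st.lists(st.integers(1, 100_000), min_size=1, max_size=60),
)
def test_n_statistic_ordering_property(lengths):
    n30 = n_statistic(lengths, 0.3)
    n50 = n_statistic(lengths, 0.5)
    n90 = n_statistic(lengths, 0.9)
    assert n90 <= n50 <= n30 <= max(lengths)
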