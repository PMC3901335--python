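import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from virobench.classify import (
    BestHitClassifier,
    ConfusionCounts,
    KmerClassifier,
    KmerProfile,
    Prediction,
    build_exclusion_db,
    classify_best_hit,
    evaluate_predictions,
    kl_distance,
    kmer_profile,
    sensitivity,
    specificity,
)
from virobench.community import (
    ErrorModel,
    SimulatedRead,
    TruthManifest,
    TruthRecord,
    generate_genomes,
)
from virobench.taxonomy import build_taxonomy


# ------------------------------------------------------------ k-mer profile

def test_kmer_profile_homopolymer():
    p = kmer_profile("AAAA", k=1, pseudocount=0.0)
    assert p.frequencies.tolist() == [1.0, 0.0, 0.0, 0.0]


def test_kmer_profile_uniform():
    p = kmer_profile("ACGT", k=1, pseudocount=0.0)
    assert p.frequencies.tolist() == [0.25] * 4


def test_kmer_profile_pseudocount_hand_count():
    # "ACGT", k=2: windows AC, CG, GT; 16 cells each +1 pseudocount
    p = kmer_profile("ACGT", k=2, pseudocount=1.0)
    idx = {"AC": 0 * 4 + 1, "CG": 1 * 4 + 2, "GT": 2 * 4 + 3}
    for mer, i in idx.items():
        assert p.frequencies[i] == pytest.approx(2 / 19)
    others = [i for i in range(16) if i not in idx.values()]
    assert all(p.frequencies[i] == pytest.approx(1 / 19) for i in others)


def test_kmer_profile_skips_ambiguous_and_validates():
    p = kmer_profile("ACNGT", k=2, pseudocount=0.0)
    # windows: AC, CN (skipped), NG (skipped), GT
    assert p.frequencies.sum() == pytest.approx(1.0)
    assert np.count_nonzero(p.frequencies) == 2
    with pytest.raises(ValueError):
        kmer_profile("AC", k=3)


# ------------------------------------------------------------- KL distance

def test_kl_identity_is_zero(small_genomes):
    p = kmer_profile(small_genomes[0].sequence, 3)
    assert kl_distance(p, p) == pytest.approx(0.0)


def test_kl_toy_value_and_asymmetry():
    p = KmerProfile(k=1, frequencies=np.array([0.5, 0.5, 0.0, 0.0]), pseudocount=0)
    q = KmerProfile(k=1, frequencies=np.array([0.25, 0.75, 0.0, 0.0]), pseudocount=0)
    expected = 0.5 * math.log(2) + 0.5 * math.log(2 / 3)
    assert kl_distance(p, q) == pytest.approx(expected)  # ~0.1438
    assert kl_distance(p, q) != pytest.approx(kl_distance(q, p))


def test_kl_mismatched_k_is_error():
    with pytest.raises(ValueError):
        kl_distance(kmer_profile("ACGT", 1), kmer_profile("ACGT", 2))


@given(st.text(alphabet="ACGT", min_size=20, max_size=200),
       st.text(alphabet="ACGT", min_size=20, max_size=200))
def test_kl_nonnegative_property(a, b):
    pa, pb = kmer_profile(a, 2), kmer_profile(b, 2)
    assert kl_distance(pa, pb) >= 0.0
    assert kl_distance(pa, pa) == pytest.approx(0.0)


# --------------------------------------------------------------- k-mer clf

def test_kmer_classifier_recovers_source(divergent_genomes):
    tax, genomes = divergent_genomes
    clf = KmerClassifier(genomes, k=4)
    g = genomes[3]
    read = g.sequence[500:900]
    pred = clf.classify(read, read_id="q")
    assert pred.predicted_genome_id == g.genome_id
    # brute-force check that the predicted genome minimizes the distance
    from virobench.community import revcomp

    dists = [
        min(
            kl_distance(kmer_profile(read, 4), kmer_profile(x.sequence, 4)),
            kl_distance(kmer_profile(revcomp(read), 4), kmer_profile(x.sequence, 4)),
        )
        for x in genomes
    ]
    assert genomes[int(np.argmin(dists))].genome_id == g.genome_id


def test_kmer_identical_db_genomes_tie(divergent_genomes):
    _, genomes = divergent_genomes
    g = genomes[0]
    clones = []
    for i in range(3):
        import copy

        c = copy.deepcopy(g)
        c.genome_id = f"clone{i}"
        clones.append(c)
    pred = KmerClassifier(clones, k=4).classify(g.sequence[100:500])
    assert not pred.assigned and pred.tie


def test_kmer_single_genome_db(divergent_genomes):
    _, genomes = divergent_genomes
    with pytest.warns(UserWarning, match="fewer than 3"):
        pred = KmerClassifier(genomes[:1], k=4).classify(genomes[0].sequence[:400])
    assert pred.predicted_genome_id == genomes[0].genome_id
    assert not pred.significant


# ------------------------------------------------------------ best-hit clf

def test_best_hit_exact_substring(divergent_genomes):
    _, genomes = divergent_genomes
    g = genomes[7]
    pred = classify_best_hit(g.sequence[1000:1400], genomes)
    assert pred.predicted_genome_id == g.genome_id


def test_best_hit_random_read_unassigned(divergent_genomes):
    _, genomes = divergent_genomes
    rng = np.random.default_rng(0)
    read = "".join(rng.choice(list("ACGT"), 400))
    assert not classify_best_hit(read, genomes).assigned


def test_best_hit_shared_segment_ties(divergent_genomes):
    _, genomes = divergent_genomes
    import copy

    a, b = copy.deepcopy(genomes[0]), copy.deepcopy(genomes[1])
    segment = "ACGTTGCA" * 50
    a.sequence = a.sequence[:1000] + segment + a.sequence[1000:]
    b.sequence = b.sequence[:2000] + segment + b.sequence[2000:]
    pred = classify_best_hit(segment, [a, b])
    assert not pred.assigned and pred.tie


def test_best_hit_engines_agree_on_decision(divergent_genomes):
    _, genomes = divergent_genomes
    db = genomes[:5]
    g = db[2]
    read = g.sequence[200:600]
    fast = BestHitClassifier(db, engine="edit").classify(read)
    exact = BestHitClassifier(db, engine="local", min_score=50).classify(read)
    assert fast.predicted_genome_id == exact.predicted_genome_id == g.genome_id


# -------------------------------------------------------- exclusion dbs

@pytest.fixture(scope="module")
def family_taxonomy():
    tax = build_taxonomy(4, 2, 2, viral_fraction=1.0, seed=21)
    genomes = generate_genomes(
        tax, length_range=(3000, 4000), n_shared_functions=0, seed=22
    )
    return tax, genomes


def _query_read(genome):
    return SimulatedRead(
        read_id=f"q_{genome.genome_id}", sequence=genome.sequence[:400],
        source_genome_id=genome.genome_id, start=1, end=400, strand="+",
        error_positions=[], taxon_id=genome.taxon_id,
    )


def test_species_exclusion_keeps_siblings(family_taxonomy):
    tax, genomes = family_taxonomy
    query = [_query_read(genomes[0])]
    db = build_exclusion_db(genomes, tax, query, "species")
    retained_ids = {g.genome_id for g in db.retained}
    assert genomes[0].genome_id not in retained_ids
    sibling = next(
        g for g in genomes[1:]
        if tax.ancestor_at(g.taxon_id, "genus")
        == tax.ancestor_at(genomes[0].taxon_id, "genus")
    )
    assert sibling.genome_id in retained_ids


def test_exclusion_removal_sets_nest(family_taxonomy):
    tax, genomes = family_taxonomy
    query = [_query_read(genomes[0]), _query_read(genomes[5])]
    removed = {
        rank: set(build_exclusion_db(genomes, tax, query, rank).removed_genome_ids)
        for rank in ("species", "genus", "family")
    }
    assert removed["species"] <= removed["genus"] <= removed["family"]


def test_exclusion_no_matching_lineages_leaves_db_unchanged(family_taxonomy):
    tax, genomes = family_taxonomy
    query = [_query_read(genomes[0])]
    db = build_exclusion_db(genomes[4:], tax, query, "genus")
    assert db.removed_genome_ids == []
    assert len(db.retained) == len(genomes[4:])


def test_exclusion_invalid_rank(family_taxonomy):
    tax, genomes = family_taxonomy
    with pytest.raises(ValueError):
        build_exclusion_db(genomes, tax, [], "order")


# ------------------------------------------------- evaluation & formulas

def test_evaluate_predictions_hand_tally(family_taxonomy):
    tax, genomes = family_taxonomy
    # one query species per genus so that every query read keeps a sibling
    # (same genus, different species) in the species-excluded database
    seen_genera: set[int] = set()
    query_genomes = []
    for g in genomes:
        genus = tax.ancestor_at(g.taxon_id, "genus")
        if genus not in seen_genera:
            seen_genera.add(genus)
            query_genomes.append(g)
        if len(query_genomes) == 4:
            break
    query = [_query_read(g) for g in query_genomes]
    manifest = TruthManifest.from_reads(query)
    db = build_exclusion_db(genomes, tax, query, "species")
    retained = {g.genome_id: g for g in db.retained}

    def sibling_of(g):
        return next(
            x for x in db.retained
            if tax.ancestor_at(x.taxon_id, "genus")
            == tax.ancestor_at(g.taxon_id, "genus")
        )

    def cousin_of(g):
        return next(
            x for x in db.retained
            if tax.ancestor_at(x.taxon_id, "genus")
            != tax.ancestor_at(g.taxon_id, "genus")
        )

    preds = [
        # correct genus via the sibling -> TP
        Prediction(query[0].read_id, sibling_of(query_genomes[0]).genome_id, "best_hit", 1, True),
        # wrong genus -> FP
        Prediction(query[1].read_id, cousin_of(query_genomes[1]).genome_id, "best_hit", 1, True),
        # unassigned, genus still in db (sibling retained) -> FN
        Prediction(query[2].read_id, None, "best_hit", 0, False),
        # unassigned again -> FN
        Prediction(query[3].read_id, None, "best_hit", 0, False),
    ]
    cc = evaluate_predictions(preds, manifest, tax, "genus", db)
    assert (cc.TP, cc.FP, cc.TN, cc.FN) == (1, 1, 0, 2)
    assert cc.total == len(preds)


def test_rank_not_evaluable_for_database(family_taxonomy):
    tax, genomes = family_taxonomy
    db = build_exclusion_db(genomes, tax, [_query_read(genomes[0])], "genus")
    with pytest.raises(ValueError, match="not evaluable"):
        evaluate_predictions([], TruthManifest([]), tax, "genus", db)


def test_sensitivity_specificity_formulas():
    assert sensitivity(ConfusionCounts("genus", TP=50, FP=0, TN=0, FN=50)) == 0.5
    assert specificity(ConfusionCounts("genus", TP=0, FP=0, TN=10, FN=0)) == 1.0
    assert sensitivity(ConfusionCounts("genus", TP=0, FP=3, TN=2, FN=0)) is None
    assert specificity(ConfusionCounts("genus", TP=1, FP=0, TN=0, FN=1)) is None
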