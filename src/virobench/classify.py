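"""Read-level taxonomic classification and its benchmark harness.

Two classifiers are provided.  The k-mer classifier assigns a read to the
reference genome whose oligonucleotide frequency profile minimizes the
Kullback-Leibler distance from the read's profile, and gates the call by a
significance test: a gamma distribution is fitted by maximum likelihood to
the read's distances to all *other* genomes, and the candidate is accepted
only when its distance falls in the extreme lower tail (p < alpha).  The
best-hit classifier assigns a read to the genome with the best alignment
score above a floor — the classic best-BLAST-hit decision structure, here
backed by a fast semi-global edit-distance engine (with an optional
Smith-Waterman engine for small runs).

Benchmarking follows the taxon-exclusion protocol: reads simulated from a
query set of genomes are classified against databases from which every
genome sharing the query's species / genus / family has been removed, and
per-rank sensitivity and specificity are computed from the resulting
confusion counts.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .community import ReferenceGenome, SimulatedRead, TruthManifest
from .taxonomy import RANK_DEPTH, TaxonomyTable

_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
    _CODE[ord(chr(_b).lower())] = _i


# --------------------------------------------------------------------------
# k-mer profiles and KL distance
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class KmerProfile:
    k: int
    frequencies: np.ndarray  # length 4**k, lexicographic k-mer order
    pseudocount: float

    def __post_init__(self):
        if len(self.frequencies) != 4 ** self.k:
            raise ValueError("frequency vector length must be 4**k")


def kmer_profile(sequence: str, k: int, pseudocount: float = 1.0) -> KmerProfile:
    """Frequencies of overlapping forward-strand k-mers.

    A pseudocount is added to every cell before normalization so that the
    profile is strictly positive (KL is undefined on zeros); windows
    containing ambiguous bases are skipped.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if len(sequence) < k:
        raise ValueError("sequence shorter than k")
    codes = _CODE[np.frombuffer(sequence.encode(), dtype=np.uint8)]
    n_win = len(codes) - k + 1
    idx = np.zeros(n_win, dtype=np.int64)
    valid = np.ones(n_win, dtype=bool)
    for j in range(k):
        c = codes[j : j + n_win]
        valid &= c < 4
        idx = idx * 4 + c
    counts = np.bincount(idx[valid], minlength=4 ** k).astype(float)
    counts += pseudocount
    total = counts.sum()
    if total == 0:
        raise ValueError("no valid k-mer windows and zero pseudocount")
    return KmerProfile(k=k, frequencies=counts / total, pseudocount=pseudocount)


def kl_distance(p: KmerProfile, q: KmerProfile) -> float:
    """Kullback-Leibler distance sum p_i ln(p_i/q_i), natural log.

    Non-negative, zero iff the profiles are identical; asymmetric in
    general.  Cells with p_i = 0 contribute nothing; q_i = 0 where
    p_i > 0 is an error (use a pseudocount).
    """
    if p.k != q.k:
        raise ValueError("profiles have different k")
    pi, qi = p.frequencies, q.frequencies
    mask = pi > 0
    if np.any(qi[mask] == 0):
        raise ValueError("q has zero cells where p is positive")
    return float(np.sum(pi[mask] * np.log(pi[mask] / qi[mask])))


# --------------------------------------------------------------------------
# Predictions
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Prediction:
    read_id: str
    predicted_genome_id: str | None
    method: str
    score: float
    significant: bool
    tie: bool = False

    @property
    def assigned(self) -> bool:
        return self.predicted_genome_id is not None


def predictions_frame(
    predictions: Iterable[Prediction], taxonomy: TaxonomyTable | None = None,
    genome_taxa: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    rows = []
    for p in predictions:
        path = ""
        if taxonomy is not None and genome_taxa and p.predicted_genome_id:
            lineage = taxonomy.lineage(genome_taxa[p.predicted_genome_id])
            path = ";".join(f"{r.rank}:{r.name}" for r in lineage[1:])
        rows.append(
            (p.read_id, p.method, p.predicted_genome_id or "unassigned", path,
             p.score, p.significant)
        )
    return pd.DataFrame(
        rows,
        columns=["read_id", "method", "predicted_genome", "predicted_taxon_path",
                 "score", "significant"],
    )


# --------------------------------------------------------------------------
# k-mer KL classifier
# --------------------------------------------------------------------------

class KmerClassifier:
    """Minimum-KL-distance classifier with a calibrated gamma null.

    The candidate genome is the one minimizing the KL distance from the
    read's k-mer profile (the closer orientation of the read is used per
    genome).  Significance: at construction, for every reference genome a
    gamma distribution is fitted by maximum likelihood to the KL distances
    of reads *simulated from that genome* (same length scale and error
    model as real queries) — the null distribution of the distance when
    the read truly originates from the genome.  The candidate is accepted
    when the upper-tail probability of its distance under that null
    exceeds ``alpha`` (i.e. the match is consistent with a same-source
    read); reads whose best distance is already implausibly large for the
    candidate stay unassigned, which is what keeps novel-taxon reads out.
    """

    method = "kmer_kl"

    def __init__(
        self,
        genomes: Sequence[ReferenceGenome],
        k: int = 4,
        pseudocount: float = 1.0,
        alpha: float = 0.05,
        tie_tol: float = 1e-12,
        calibration_reads: int = 50,
        calibration_length: int = 400,
        calibration_error_model=None,
        calibration_seed: int = 0,
    ):
        if not genomes:
            raise ValueError("empty reference database")
        self.k = k
        self.alpha = alpha
        self.pseudocount = pseudocount
        self.tie_tol = tie_tol
        self.genome_ids = [g.genome_id for g in genomes]
        self.profiles = [kmer_profile(g.sequence, k, pseudocount) for g in genomes]
        self._null_params = self._calibrate(
            genomes, calibration_reads, calibration_length,
            calibration_error_model, calibration_seed,
        )

    def _calibrate(self, genomes, n_reads, length, error_model, seed):
        """Per-genome gamma null of the same-source KL distance."""
        from scipy import stats

        from .community import ErrorModel, _apply_errors, _decode, _encode, revcomp

        model = error_model if error_model is not None else ErrorModel()
        rng = np.random.default_rng(seed)
        params = []
        for g, prof in zip(genomes, self.profiles):
            codes = _encode(g.sequence)
            L = len(codes)
            tlen = min(length, L)
            dists = []
            for _ in range(n_reads):
                s = int(rng.integers(0, L - tlen + 1))
                template = codes[s : s + tlen]
                if rng.random() < 0.5:
                    template = (3 - template)[::-1]
                read_codes, _ = _apply_errors(template, model, rng)
                seq = _decode(read_codes)
                d = min(
                    kl_distance(kmer_profile(seq, self.k, self.pseudocount), prof),
                    kl_distance(
                        kmer_profile(revcomp(seq), self.k, self.pseudocount), prof
                    ),
                )
                dists.append(d)
            shape, loc, scale = stats.gamma.fit(np.asarray(dists), floc=0.0)
            params.append((shape, loc, scale))
        return params

    def classify(self, read: SimulatedRead | str, read_id: str = "read") -> Prediction:
        from .community import revcomp

        seq = read.sequence if isinstance(read, SimulatedRead) else read
        rid = read.read_id if isinstance(read, SimulatedRead) else read_id
        # reads come from either strand: score both orientations, keep the
        # closer one per genome
        rp_f = kmer_profile(seq, self.k, self.pseudocount)
        rp_r = kmer_profile(revcomp(seq), self.k, self.pseudocount)
        dists = np.array(
            [min(kl_distance(rp_f, q), kl_distance(rp_r, q)) for q in self.profiles]
        )
        order = np.argsort(dists, kind="stable")
        best = int(order[0])
        dmin = float(dists[best])
        ties = np.sum(np.abs(dists - dmin) <= self.tie_tol) > 1
        if ties:
            return Prediction(rid, None, self.method, dmin, significant=False, tie=True)
        if len(dists) < 3:
            warnings.warn(
                "fewer than 3 reference genomes: significance test skipped",
                stacklevel=2,
            )
            return Prediction(rid, self.genome_ids[best], self.method, dmin,
                              significant=False)
        from scipy import stats

        shape, loc, scale = self._null_params[best]
        z = float(stats.gamma.sf(dmin, shape, loc=loc, scale=scale))
        if z > self.alpha:
            return Prediction(rid, self.genome_ids[best], self.method, dmin,
                              significant=True)
        return Prediction(rid, None, self.method, dmin, significant=False)


def classify_kmer(
    read: SimulatedRead | str,
    genomes: Sequence[ReferenceGenome],
    k: int = 4,
    alpha: float = 0.05,
    pseudocount: float = 1.0,
) -> Prediction:
    return KmerClassifier(genomes, k=k, pseudocount=pseudocount, alpha=alpha).classify(read)


# --------------------------------------------------------------------------
# Best-hit classifier
# --------------------------------------------------------------------------

class BestHitClassifier:
    """Best-alignment-hit classifier with a score floor.

    ``engine="edit"`` (default) scores each read against each genome as
    ``read_length - d`` where ``d`` is the semi-global (infix) edit
    distance of the read within the genome — fast enough for full
    exclusion-database benchmarks.  ``engine="local"`` uses Smith-Waterman
    (match +1, mismatch -2, gap open -5, gap extend -2).  The floor
    ``min_score_fraction * read_length`` stands in for an e-value cutoff;
    reads whose best score falls below it, or whose two best genomes tie,
    are left unassigned.
    """

    method = "best_hit"

    def __init__(
        self,
        genomes: Sequence[ReferenceGenome],
        min_score: float | None = None,
        min_score_fraction: float = 0.7,
        engine: str = "edit",
    ):
        if not genomes:
            raise ValueError("empty reference database")
        if engine not in ("edit", "local"):
            raise ValueError(f"unknown engine {engine!r}")
        self.genomes = list(genomes)
        self.min_score = min_score
        self.min_score_fraction = min_score_fraction
        self.engine = engine
        if engine == "local":
            from .metrics import _aligner

            self._aligner = _aligner()

    def _score(self, seq: str, genome: ReferenceGenome) -> float:
        # strand-aware: best score over the read and its reverse complement
        from .community import revcomp

        if self.engine == "edit":
            import edlib

            d = min(
                edlib.align(s, genome.sequence, mode="HW", task="distance")["editDistance"]
                for s in (seq, revcomp(seq))
            )
            return float(len(seq) - d)
        return max(
            float(self._aligner.score(genome.sequence, s))
            for s in (seq, revcomp(seq))
        )

    def classify(self, read: SimulatedRead | str, read_id: str = "read") -> Prediction:
        seq = read.sequence if isinstance(read, SimulatedRead) else read
        rid = read.read_id if isinstance(read, SimulatedRead) else read_id
        floor = (
            self.min_score
            if self.min_score is not None
            else self.min_score_fraction * len(seq)
        )
        scores = [self._score(seq, g) for g in self.genomes]
        best = max(scores)
        if best < floor:
            return Prediction(rid, None, self.method, best, significant=False)
        winners = [g.genome_id for g, s in zip(self.genomes, scores) if s == best]
        if len(winners) > 1:
            return Prediction(rid, None, self.method, best, significant=False, tie=True)
        return Prediction(rid, winners[0], self.method, best, significant=True)


def classify_best_hit(
    read: SimulatedRead | str,
    genomes: Sequence[ReferenceGenome],
    min_score: float | None = None,
    **kwargs,
) -> Prediction:
    return BestHitClassifier(genomes, min_score=min_score, **kwargs).classify(read)


# --------------------------------------------------------------------------
# Exclusion databases
# --------------------------------------------------------------------------

EXCLUDABLE_RANKS = ("species", "genus", "family")


@dataclass
class ExclusionDatabase:
    retained: list[ReferenceGenome]
    excluded_rank: str
    excluded_taxa: set[int]
    removed_genome_ids: list[str]

    @property
    def label(self) -> str:
        return f"{self.excluded_rank}-excluded"


def build_exclusion_db(
    genomes: Sequence[ReferenceGenome],
    taxonomy: TaxonomyTable,
    query_reads: Iterable[SimulatedRead | int],
    rank: str,
) -> ExclusionDatabase:
    """Remove every genome whose ancestor at ``rank`` matches a query
    read's lineage — the leave-taxon-out database used to probe classifier
    behaviour on novel viruses."""
    if rank not in EXCLUDABLE_RANKS:
        raise ValueError(f"rank must be one of {EXCLUDABLE_RANKS}")
    query_taxa = set()
    for q in query_reads:
        tid = q if isinstance(q, int) else q.taxon_id
        anc = taxonomy.ancestor_at(tid, rank)
        if anc is None:
            raise ValueError(f"query taxon {tid} has no {rank} ancestor")
        query_taxa.add(anc)
    retained, removed = [], []
    for g in genomes:
        anc = taxonomy.ancestor_at(g.taxon_id, rank)
        if anc in query_taxa:
            removed.append(g.genome_id)
        else:
            retained.append(g)
    return ExclusionDatabase(
        retained=retained,
        excluded_rank=rank,
        excluded_taxa=query_taxa,
        removed_genome_ids=removed,
    )


# --------------------------------------------------------------------------
# Confusion counts, sensitivity, specificity
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ConfusionCounts:
    rank: str
    TP: int
    FP: int
    TN: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


def evaluate_predictions(
    predictions: Sequence[Prediction],
    manifest: TruthManifest,
    taxonomy: TaxonomyTable,
    rank: str,
    db: ExclusionDatabase,
) -> ConfusionCounts:
    """Confusion counts at ``rank`` for predictions against an exclusion db.

    Per read with true ancestor C at ``rank``: an assignment whose
    predicted ancestor equals C is a TP, otherwise an FP; an unassigned
    read is an FN when some retained genome still carries C, and a TN when
    C is entirely absent from the database.  Ranks at or below the
    database's excluded rank are not evaluable.
    """
    if rank not in RANK_DEPTH:
        raise ValueError(f"unknown rank {rank!r}")
    if RANK_DEPTH[rank] >= RANK_DEPTH[db.excluded_rank]:
        raise ValueError(
            f"rank {rank!r} is not evaluable for a {db.label} database"
        )
    genome_taxon = {g.genome_id: g.taxon_id for g in db.retained}
    present = {
        taxonomy.ancestor_at(t, rank) for t in genome_taxon.values()
    } - {None}
    tp = fp = tn = fn = 0
    for p in predictions:
        truth = manifest[p.read_id]
        c = taxonomy.ancestor_at(truth.taxon_id, rank)
        if p.assigned:
            pred_taxon = genome_taxon.get(p.predicted_genome_id)
            if pred_taxon is None:
                raise ValueError(
                    f"prediction {p.read_id}: genome {p.predicted_genome_id} "
                    "not in the database"
                )
            if taxonomy.ancestor_at(pred_taxon, rank) == c:
                tp += 1
            else:
                fp += 1
        else:
            if c in present:
                fn += 1
            else:
                tn += 1
    return ConfusionCounts(rank=rank, TP=tp, FP=fp, TN=tn, FN=fn)


def sensitivity(cc: ConfusionCounts) -> float | None:
    """TP / (TP + FN); ``None`` when undefined."""
    denom = cc.TP + cc.FN
    return cc.TP / denom if denom else None


def specificity(cc: ConfusionCounts) -> float | None:
    """TN / (TN + FP); ``None`` when undefined."""
    denom = cc.TN + cc.FP
    return cc.TN / denom if denom else None


def confusion_frame(
    results: Iterable[tuple[str, str, ConfusionCounts]]
) -> pd.DataFrame:
    """Rows of (method, database, rank, TP, FP, TN, FN, sens, spec)."""
    rows = []
    for method, database, cc in results:
        rows.append(
            (method, database, cc.rank, cc.TP, cc.FP, cc.TN, cc.FN,
             sensitivity(cc), specificity(cc))
        )
    return pd.DataFrame(
        rows,
        columns=["method", "database", "rank", "TP", "FP", "TN", "FN",
                 "sensitivity", "specificity"],
    )


# --------------------------------------------------------------------------
# Query-set construction
# --------------------------------------------------------------------------

def sample_query_set(
    genomes: Sequence[ReferenceGenome],
    n_genomes: int = 19,
    n_reads: int = 200,
    seed: int = 0,
    include_genome_ids: Sequence[str] = (),
    **simulate_kwargs,
) -> tuple[list[SimulatedRead], list[ReferenceGenome]]:
    """Sample query genomes and simulate a read set from them.

    ``include_genome_ids`` forces particular genomes into the query (e.g.
    a lineage with no database relatives, emulating truly novel viruses);
    the remainder is drawn uniformly.  Reads use the same simulator and
    defaults as the full metagenome simulations.
    """
    from .community import profile_from_coverages, simulate_reads

    rng = np.random.default_rng(seed)
    forced = [g for g in genomes if g.genome_id in set(include_genome_ids)]
    pool = [g for g in genomes if g.genome_id not in set(include_genome_ids)]
    n_draw = n_genomes - len(forced)
    if n_draw < 0 or n_draw > len(pool):
        raise ValueError("cannot sample the requested number of query genomes")
    drawn = list(rng.choice(len(pool), size=n_draw, replace=False))
    query_genomes = sorted(forced + [pool[i] for i in drawn], key=lambda g: g.genome_id)
    profile = profile_from_coverages(
        {g.genome_id: 1.0 for g in query_genomes},
        {g.genome_id: len(g) for g in query_genomes},
        n_reads,
    )
    reads = simulate_reads(
        query_genomes, profile, seed=int(rng.integers(0, 2**31)), **simulate_kwargs
    )
    return reads, query_genomes
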