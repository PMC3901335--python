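"""Assembly evaluation against ground truth.

Computes the full statistic vector used to compare assemblies: contig
length statistics (largest, N30/N50/N90), chimera detection with
lowest-common-ancestor ranks, contig taxonomy and contig score, the
percentage of reads assembled on their original genome, viral-bacterial
hit ambiguity, and whole-genome recovery.

Two scoring routes are available.  The default "projection" route maps a
contig onto its source genomes through the ground-truth read coordinates
and compares sequences positionally — exact, fast, and free of alignment
noise.  The "align" route runs a local aligner (Smith-Waterman) of the
consensus against reference genomes, for cases where cross-genome homology
matters or ground truth is unavailable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, fields
from statistics import median
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .assembly import Assembly, Contig
from .community import ReferenceGenome, TruthManifest
from .taxonomy import TaxonomyTable

#: tolerance for calling two contig scores equal (viral-bacterial hits)
SCORE_TIE_TOL = 1e-9


@dataclass
class AssemblyStats:
    label: str
    largest_contig: int
    n30: int
    n50: int
    n90: int
    n_contigs: int
    pct_chimeric: float
    pct_viral_bacterial_chimeric: float
    pct_reads_assembled: float
    pct_reads_on_original_genome: float
    pct_reads_in_viral_bacterial_hit: float
    genomes_recovered: int
    identity_median: float


#: Stats TSV column order follows the published assembly-comparison tables
#: (largest contig, N50, contig count, chimera percentages, read
#: percentages, genomes recovered, identity median), with N30/N90 appended.
STATS_COLUMNS = [
    "label",
    "largest_contig",
    "n50",
    "n_contigs",
    "pct_chimeric",
    "pct_viral_bacterial_chimeric",
    "pct_reads_assembled",
    "pct_reads_on_original_genome",
    "pct_reads_in_viral_bacterial_hit",
    "genomes_recovered",
    "identity_median",
    "n30",
    "n90",
]


def stats_frame(stats: Iterable[AssemblyStats]) -> pd.DataFrame:
    rows = [{f.name: getattr(s, f.name) for f in fields(AssemblyStats)} for s in stats]
    return pd.DataFrame(rows)[STATS_COLUMNS]


def write_stats_tsv(stats: Iterable[AssemblyStats], path) -> None:
    stats_frame(stats).to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_stats_tsv(path) -> list[AssemblyStats]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        out.append(
            AssemblyStats(
                label=str(d["label"]),
                largest_contig=int(d["largest_contig"]),
                n30=int(d["n30"]),
                n50=int(d["n50"]),
                n90=int(d["n90"]),
                n_contigs=int(d["n_contigs"]),
                pct_chimeric=float(d["pct_chimeric"]),
                pct_viral_bacterial_chimeric=float(d["pct_viral_bacterial_chimeric"]),
                pct_reads_assembled=float(d["pct_reads_assembled"]),
                pct_reads_on_original_genome=float(d["pct_reads_on_original_genome"]),
                pct_reads_in_viral_bacterial_hit=float(d["pct_reads_in_viral_bacterial_hit"]),
                genomes_recovered=int(d["genomes_recovered"]),
                identity_median=float(d["identity_median"]),
            )
        )
    return out


@dataclass(frozen=True)
class ChimeraRecord:
    contig_id: str
    species_taxa: tuple[int, ...]
    lca_rank: str
    viral_bacterial: bool


@dataclass(frozen=True)
class Hsp:
    """Best local match of a contig against one reference genome."""

    contig_id: str
    genome_id: str
    aligned_contig_fraction: float
    identity: float
    genome_start: int | None = None
    genome_end: int | None = None


@dataclass(frozen=True)
class MajorityCall:
    genome_id: str
    taxon_id: int
    tie: bool


# --------------------------------------------------------------------------
# N statistics
# --------------------------------------------------------------------------

def n_statistic(contig_lengths: Sequence[int], fraction: float) -> int:
    """Length of the contig at which contigs sorted by decreasing size
    cumulatively reach ``fraction`` of the total assembled bases."""
    if not contig_lengths:
        warnings.warn("N statistic of an empty assembly is undefined; returning 0",
                      stacklevel=2)
        return 0
    if any(l <= 0 for l in contig_lengths):
        raise ValueError("contig lengths must be positive")
    lengths = sorted(contig_lengths, reverse=True)
    threshold = fraction * sum(lengths)
    acc = 0
    for l in lengths:
        acc += l
        if acc >= threshold:
            return l
    return lengths[-1]


# --------------------------------------------------------------------------
# Chimeras and taxonomy
# --------------------------------------------------------------------------

def contig_lca_rank(species_taxa: Iterable[int], taxonomy: TaxonomyTable) -> str:
    """Lowest rank at which all lineages share one ancestor."""
    return taxonomy.lca_rank(species_taxa)


def detect_chimeras(
    assembly: Assembly, manifest: TruthManifest, taxonomy: TaxonomyTable
) -> list[ChimeraRecord]:
    """One record per contig containing reads from >= 2 source genomes.

    A record is flagged viral-bacterial when the involved source taxa span
    both superkingdoms.
    """
    records: list[ChimeraRecord] = []
    for c in assembly.contigs:
        taxa = {manifest[pr.read_id].taxon_id for pr in c.reads}
        genomes = {manifest[pr.read_id].genome_id for pr in c.reads}
        if len(genomes) < 2:
            continue
        viral_flags = {taxonomy.is_viral_taxon(t) for t in taxa}
        records.append(
            ChimeraRecord(
                contig_id=c.contig_id,
                species_taxa=tuple(sorted(taxa)),
                lca_rank=contig_lca_rank(taxa, taxonomy),
                viral_bacterial=len(viral_flags) > 1,
            )
        )
    return records


def chimera_records_frame(records: Iterable[ChimeraRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (r.contig_id, r.lca_rank, ",".join(map(str, r.species_taxa)), r.viral_bacterial)
            for r in records
        ],
        columns=["contig_id", "lca_rank", "species_taxa", "viral_bacterial"],
    )


def contig_taxonomy(contig: Contig, manifest: TruthManifest) -> MajorityCall:
    """Majority source organism of a contig; ties go to the
    lexicographically smallest genome id and are flagged."""
    counts: dict[str, int] = {}
    for pr in contig.reads:
        counts[manifest[pr.read_id].genome_id] = counts.get(manifest[pr.read_id].genome_id, 0) + 1
    best = max(counts.values())
    winners = sorted(g for g, n in counts.items() if n == best)
    gid = winners[0]
    taxon = next(
        manifest[pr.read_id].taxon_id
        for pr in contig.reads
        if manifest[pr.read_id].genome_id == gid
    )
    return MajorityCall(genome_id=gid, taxon_id=taxon, tie=len(winners) > 1)


# --------------------------------------------------------------------------
# Alignment and contig scores
# --------------------------------------------------------------------------

def _aligner(match=1, mismatch=-2, gap_open=-5, gap_extend=-2):
    from Bio import Align

    al = Align.PairwiseAligner(mode="local")
    al.match_score = match
    al.mismatch_score = mismatch
    al.open_gap_score = gap_open
    al.extend_gap_score = gap_extend
    return al


def align_contig(
    contig: Contig | str,
    genome: ReferenceGenome | str,
    min_score: float = 30.0,
) -> Hsp | None:
    """Best local alignment (match +1, mismatch -2, gap open -5, gap
    extend -2) of a contig consensus against a genome.  Returns ``None``
    when the best score falls below ``min_score``."""
    consensus = contig.consensus if isinstance(contig, Contig) else contig
    gseq = genome.sequence if isinstance(genome, ReferenceGenome) else genome
    cid = contig.contig_id if isinstance(contig, Contig) else "contig"
    gid = genome.genome_id if isinstance(genome, ReferenceGenome) else "genome"
    al = _aligner()
    score = al.score(gseq, consensus)
    if score < min_score:
        return None
    aln = al.align(gseq, consensus)[0]
    counts = aln.counts()
    columns = aln.length
    identity = 100.0 * counts.identities / columns if columns else 0.0
    q_aligned = int(sum(b - a for a, b in aln.aligned[1]))
    t_start = int(aln.aligned[0][0][0]) + 1
    t_end = int(aln.aligned[0][-1][1])
    return Hsp(
        contig_id=cid,
        genome_id=gid,
        aligned_contig_fraction=q_aligned / len(consensus),
        identity=identity,
        genome_start=t_start,
        genome_end=t_end,
    )


def contig_score(hsp: Hsp) -> float:
    """Contig score in percent: aligned fraction of the contig times the
    alignment's percent identity.  A perfect full-length contig scores 100."""
    return 100.0 * hsp.aligned_contig_fraction * (hsp.identity / 100.0)


def project_contig(
    contig: Contig,
    manifest: TruthManifest,
    genomes_by_id: Mapping[str, ReferenceGenome],
) -> dict[str, Hsp]:
    """Truth-projection HSPs of a contig against each of its source genomes.

    For every genome contributing reads to the contig, the reads' contig
    offsets and genomic coordinates anchor a gap-free mapping; the mapped
    consensus stretch is compared positionally to the reference substring.
    """
    by_genome: dict[str, list] = {}
    for pr in contig.reads:
        rec = manifest[pr.read_id]
        by_genome.setdefault(rec.genome_id, []).append((pr, rec))
    hsps: dict[str, Hsp] = {}
    L = len(contig.consensus)
    for gid, pairs in by_genome.items():
        genome = genomes_by_id[gid]
        # anchor: the leftmost-placed read of this genome
        pr0, rec0 = min(pairs, key=lambda t: (t[0].offset, t[0].read_id))
        o_min = min(pr.offset for pr, _ in pairs)
        o_max = max(pr.offset + rec.template_length - 1 for pr, rec in pairs)
        o_max = min(o_max, L)
        g_anchor = rec0.start - (pr0.offset - 1)
        g_start = g_anchor + (o_min - 1)
        g_end = g_anchor + (o_max - 1)
        g_start_c = max(1, g_start)
        g_end_c = min(len(genome.sequence), g_end)
        if g_end_c < g_start_c:
            continue
        # clip the contig window identically
        o_start = o_min + (g_start_c - g_start)
        o_end = o_max - (g_end - g_end_c)
        seg_c = contig.consensus[o_start - 1 : o_end]
        seg_g = genome.sequence[g_start_c - 1 : g_end_c]
        m = min(len(seg_c), len(seg_g))
        if m == 0:
            continue
        a = np.frombuffer(seg_c[:m].encode(), dtype=np.uint8)
        b = np.frombuffer(seg_g[:m].encode(), dtype=np.uint8)
        matches = int((a == b).sum())
        hsps[gid] = Hsp(
            contig_id=contig.contig_id,
            genome_id=gid,
            aligned_contig_fraction=m / L,
            identity=100.0 * matches / m,
            genome_start=g_start_c,
            genome_end=g_start_c + m - 1,
        )
    return hsps


# --------------------------------------------------------------------------
# Read- and genome-level metrics
# --------------------------------------------------------------------------

def pct_reads_on_original_genome(
    assembly: Assembly,
    manifest: TruthManifest,
    majority: Mapping[str, MajorityCall],
    best_hsp_genome: Mapping[str, str | None],
) -> float:
    """Percentage of assembled reads that sit in a correctly assigned
    contig (majority organism equals best-HSP genome) and whose own source
    organism matches that assignment."""
    total = assembly.n_reads_placed
    if total == 0:
        return 0.0
    good = 0
    for c in assembly.contigs:
        call = majority[c.contig_id]
        if best_hsp_genome.get(c.contig_id) != call.genome_id:
            continue
        good += sum(
            1 for pr in c.reads if manifest[pr.read_id].genome_id == call.genome_id
        )
    return 100.0 * good / total


def viral_bacterial_hits(
    assembly: Assembly,
    best_viral_score: Mapping[str, float | None],
    best_bacterial_score: Mapping[str, float | None],
) -> tuple[float, list[str]]:
    """A contig is a viral-bacterial hit when its best viral and best
    bacterial contig scores are equal (within a strict tolerance); returns
    the percentage of assembled reads sitting in such contigs and their
    contig ids."""
    hits = []
    n_hit_reads = 0
    total = assembly.n_reads_placed
    for c in assembly.contigs:
        v = best_viral_score.get(c.contig_id)
        b = best_bacterial_score.get(c.contig_id)
        if v is not None and b is not None and abs(v - b) <= SCORE_TIE_TOL:
            hits.append(c.contig_id)
            n_hit_reads += len(c.reads)
    pct = 100.0 * n_hit_reads / total if total else 0.0
    return pct, hits


def genomes_recovered(
    hsps_by_contig: Mapping[str, Mapping[str, Hsp]],
    genomes: Sequence[ReferenceGenome],
) -> int:
    """Count of genomes fully spanned (100% of the genome length) by some
    contig's alignment with identity strictly above 95%."""
    recovered = set()
    lengths = {g.genome_id: len(g) for g in genomes}
    for hsps in hsps_by_contig.values():
        for gid, h in hsps.items():
            if h.genome_start == 1 and h.genome_end == lengths[gid] and h.identity > 95.0:
                recovered.add(gid)
    return len(recovered)


# --------------------------------------------------------------------------
# The full statistic vector
# --------------------------------------------------------------------------

def compile_stats(
    assembly: Assembly,
    manifest: TruthManifest,
    genomes: Sequence[ReferenceGenome],
    taxonomy: TaxonomyTable,
    mode: str = "projection",
    min_align_score: float = 30.0,
) -> AssemblyStats:
    """Compute the complete per-assembly statistic vector.

    ``mode="projection"`` (default) scores contigs by ground-truth
    projection; ``mode="align"`` runs the local aligner of every contig
    against every reference genome (only sensible for small problems).
    """
    if mode not in ("projection", "align"):
        raise ValueError(f"unknown mode {mode!r}")
    genomes_by_id = {g.genome_id: g for g in genomes}
    lengths = [len(c.consensus) for c in assembly.contigs]
    total_reads = len(manifest)
    n_contigs = assembly.n_contigs

    chimeras = detect_chimeras(assembly, manifest, taxonomy)
    pct_chim = 100.0 * len(chimeras) / n_contigs if n_contigs else 0.0
    pct_vb_chim = (
        100.0 * sum(r.viral_bacterial for r in chimeras) / n_contigs if n_contigs else 0.0
    )

    hsps_by_contig: dict[str, dict[str, Hsp]] = {}
    for c in assembly.contigs:
        if mode == "projection":
            hsps_by_contig[c.contig_id] = project_contig(c, manifest, genomes_by_id)
        else:
            hsps = {}
            for g in genomes:
                h = align_contig(c, g, min_score=min_align_score)
                if h is not None:
                    hsps[g.genome_id] = h
            hsps_by_contig[c.contig_id] = hsps

    majority = {c.contig_id: contig_taxonomy(c, manifest) for c in assembly.contigs}
    best_genome: dict[str, str | None] = {}
    best_viral: dict[str, float | None] = {}
    best_bact: dict[str, float | None] = {}
    scores: list[float] = []
    for cid, hsps in hsps_by_contig.items():
        if hsps:
            best = max(hsps.values(), key=lambda h: (contig_score(h), h.genome_id))
            best_genome[cid] = best.genome_id
            scores.append(contig_score(best))
        else:
            best_genome[cid] = None
        v = [contig_score(h) for h in hsps.values() if genomes_by_id[h.genome_id].is_viral]
        b = [contig_score(h) for h in hsps.values() if not genomes_by_id[h.genome_id].is_viral]
        best_viral[cid] = max(v) if v else None
        best_bact[cid] = max(b) if b else None

    pct_vb_hit, _ = viral_bacterial_hits(assembly, best_viral, best_bact)

    if not lengths:
        warnings.warn("empty assembly: length statistics set to 0", stacklevel=2)

    return AssemblyStats(
        label=assembly.label,
        largest_contig=max(lengths) if lengths else 0,
        n30=n_statistic(lengths, 0.3) if lengths else 0,
        n50=n_statistic(lengths, 0.5) if lengths else 0,
        n90=n_statistic(lengths, 0.9) if lengths else 0,
        n_contigs=n_contigs,
        pct_chimeric=pct_chim,
        pct_viral_bacterial_chimeric=pct_vb_chim,
        pct_reads_assembled=100.0 * assembly.n_reads_placed / total_reads
        if total_reads
        else 0.0,
        pct_reads_on_original_genome=pct_reads_on_original_genome(
            assembly, manifest, majority, best_genome
        ),
        pct_reads_in_viral_bacterial_hit=pct_vb_hit,
        genomes_recovered=genomes_recovered(hsps_by_contig, genomes),
        identity_median=float(median(scores)) if scores else 0.0,
    )
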