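"""Synthetic viral/bacterial communities with ground-truth-tracked reads.

This module stands in for the combination of curated reference genomes and
a pyrosequencing read simulator: it builds reference genomes hanging off a
ranked taxonomy, derives per-genome read counts from coverage values, and
simulates ~400 bp single-end reads with a 454-style error model
(substitutions plus homopolymer over/under-calls).  Every read header
carries its full provenance — source genome, forward-strand coordinates,
strand, and the positions of the errors introduced — so that downstream
assembly and classification scoring can be done against exact truth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .taxonomy import RANKS, RANK_DEPTH, TaxonomyTable

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
    _CODE[ord(chr(_b).lower())] = _i

_COMPLEMENT = bytes.maketrans(b"ACGTacgt", b"TGCAtgca")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _encode(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


def _decode(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode()


# --------------------------------------------------------------------------
# Domain types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Orf:
    """1-based inclusive ORF coordinates on the forward strand."""

    start: int
    end: int
    strand: str
    function_label: str


@dataclass
class ReferenceGenome:
    genome_id: str
    sequence: str
    taxon_id: int
    is_viral: bool
    orf_table: list[Orf] = field(default_factory=list)

    def __post_init__(self):
        for orf in self.orf_table:
            if not (1 <= orf.start <= orf.end <= len(self.sequence)):
                raise ValueError(
                    f"{self.genome_id}: ORF {orf.function_label} outside genome"
                )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class CommunityProfile:
    """Per-genome mean coverage and exact read counts."""

    coverage: dict[str, float]
    read_count: dict[str, int]

    @property
    def total_reads(self) -> int:
        return sum(self.read_count.values())

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (g, self.coverage[g], self.read_count[g]) for g in sorted(self.coverage)
        ]
        return pd.DataFrame(rows, columns=["genome_id", "coverage", "read_count"])

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass
class SimulatedRead:
    """A simulated read and its full provenance.

    ``start``/``end`` are 1-based inclusive coordinates of the error-free
    template on the forward strand of the source genome; ``end - start + 1``
    always equals the template length even when homopolymer indels change
    the read length.  ``error_positions`` are 1-based positions within the
    read (as sequenced) where an error was introduced.
    """

    read_id: str
    sequence: str
    source_genome_id: str
    start: int
    end: int
    strand: str
    error_positions: list[int]
    taxon_id: int

    @property
    def template_length(self) -> int:
        return self.end - self.start + 1

    @property
    def header(self) -> str:
        err = ",".join(str(p) for p in self.error_positions)
        return (
            f"{self.read_id}|gid={self.source_genome_id}|tid={self.taxon_id}"
            f"|start={self.start}|end={self.end}|strand={self.strand}|err={err}"
        )

    @classmethod
    def from_header(cls, header: str, sequence: str = "") -> "SimulatedRead":
        header = header.lstrip(">").strip()
        fields = header.split("|")
        read_id, kv = fields[0], dict(f.split("=", 1) for f in fields[1:])
        err = [int(p) for p in kv["err"].split(",") if p]
        return cls(
            read_id=read_id,
            sequence=sequence,
            source_genome_id=kv["gid"],
            start=int(kv["start"]),
            end=int(kv["end"]),
            strand=kv["strand"],
            error_positions=err,
            taxon_id=int(kv["tid"]),
        )


# --------------------------------------------------------------------------
# Genome generation
# --------------------------------------------------------------------------

#: Substitution proportion applied when deriving the children of a node of
#: the given rank.  Non-increasing towards the leaves (equivalently,
#: non-decreasing with rank height): deeper splits are more recent.
DEFAULT_DIVERGENCE: dict[str, float] = {
    "root": 0.30,
    "superkingdom": 0.28,
    "phylum": 0.24,
    "class": 0.20,
    "order": 0.16,
    "family": 0.10,
    "subfamily": 0.07,
    "genus": 0.04,
}

#: Conserved-function labels for shared segments, echoing the gene families
#: that commonly collapse related phage genomes into chimeric contigs.
SHARED_FUNCTION_LABELS = (
    "terminase_large_subunit",
    "portal_protein",
    "integrase",
    "dna_polymerase",
    "capsid_protein",
    "helicase",
    "tail_fiber_protein",
    "cell_wall_hydrolase",
    "primase",
    "recombinase",
)


def _mutate(
    codes: np.ndarray,
    rate: float,
    rng: np.random.Generator,
    protected: Sequence[tuple[int, int]] = (),
    protected_rate: float = 0.0,
) -> np.ndarray:
    """Per-site substitution at ``rate``; replacement uniform over the other
    three bases.  Intervals in ``protected`` (0-based half-open) mutate at
    ``protected_rate`` instead."""
    out = codes.copy()
    eff = np.full(len(codes), rate)
    for a, b in protected:
        eff[a:b] = protected_rate
    hit = rng.random(len(codes)) < eff
    n = int(hit.sum())
    if n:
        out[hit] = (out[hit] + rng.integers(1, 4, size=n).astype(np.uint8)) % 4
    return out


def _markov_sequence(
    length: int, rng: np.random.Generator, order: int = 2, concentration: float = 2.0
) -> np.ndarray:
    """Ancestral sequence from a random order-``order`` Markov chain.

    Real genomes carry a genome-wide oligonucleotide usage signature
    (dinucleotide/codon bias) that is consistent along the chromosome and
    clade-specific; drawing each family's ancestor from its own random
    transition kernel reproduces that property, which the k-mer-signature
    classification methods presume.  Dirichlet(``concentration``) rows give
    biases of realistic strength."""
    n_ctx = 4 ** order
    trans = rng.dirichlet([concentration] * 4, size=n_ctx)
    cum = np.cumsum(trans, axis=1)
    seq = np.empty(length, dtype=np.uint8)
    seq[:order] = rng.integers(0, 4, size=order)
    u = rng.random(length)
    ctx = 0
    for j in range(order):
        ctx = ctx * 4 + int(seq[j])
    mask = n_ctx // 4
    for i in range(order, length):
        row = cum[ctx]
        b = int(np.searchsorted(row, u[i], side="right"))
        b = min(b, 3)
        seq[i] = b
        ctx = (ctx % mask) * 4 + b if order > 0 else 0
    return seq


def expected_pairwise_mismatch(d: float) -> float:
    """Expected mismatch proportion between two sequences independently
    mutated from a common ancestor at per-site rate ``d`` (replacement
    uniform over the other three bases)."""
    return 2 * d * (1 - d) + d * d * (2.0 / 3.0)


def generate_genomes(
    taxonomy: TaxonomyTable,
    length_range: tuple[int, int] = (5_000, 10_000),
    n_shared_functions: int = 3,
    divergence_per_rank: Mapping[str, float] | None = None,
    seed: int = 0,
    shared_segment_length: int = 600,
    shared_divergence: float = 0.01,
    n_private_orfs: int = 4,
) -> list[ReferenceGenome]:
    """One reference genome per species of ``taxonomy``.

    Family ancestor sequences are drawn de novo (length from
    ``length_range``, base composition from a per-family Dirichlet draw);
    below the family the hierarchy is derived by per-site substitution at
    the rank-keyed divergence (no indels, so coordinates are exact across
    relatives).  ``n_shared_functions`` conserved segments — copies of a
    single community-wide template mutated at ``shared_divergence`` — are
    inserted at fixed relative positions in every family, giving closely
    related *and* distant genomes a shared homologous core that drives
    chimera formation in real assemblies.  Each genome also carries
    ``n_private_orfs`` private ORFs with genome-unique function labels.
    """
    if len(taxonomy.species()) == 0:
        raise ValueError("taxonomy contains no species")
    if length_range[0] < 1_000:
        raise ValueError("minimum genome length must be >= 1000")
    div = dict(DEFAULT_DIVERGENCE if divergence_per_rank is None else divergence_per_rank)
    for rank, d in div.items():
        if not 0.0 <= d < 1.0:
            raise ValueError(f"divergence for {rank} outside [0,1)")
    ordered = [div.get(r) for r in RANKS[:-1] if r in div]
    if any(a < b for a, b in zip(ordered, ordered[1:])):
        raise ValueError("divergence must be non-decreasing with rank height")

    rng = np.random.default_rng(seed)
    needed = n_shared_functions * (shared_segment_length + 50)
    if n_shared_functions and needed > length_range[0]:
        raise ValueError("shared segments do not fit the minimum genome length")

    labels = [
        SHARED_FUNCTION_LABELS[i % len(SHARED_FUNCTION_LABELS)]
        + ("" if i < len(SHARED_FUNCTION_LABELS) else f"_{i // len(SHARED_FUNCTION_LABELS)}")
        for i in range(n_shared_functions)
    ]
    shared_templates = [
        rng.integers(0, 4, size=shared_segment_length).astype(np.uint8)
        for _ in range(n_shared_functions)
    ]

    genomes: list[ReferenceGenome] = []
    for family in taxonomy.taxa_at_rank("family"):
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        fam_seq = _markov_sequence(length, rng)
        # conserved segments at fixed relative positions
        protected: list[tuple[int, int]] = []
        slot = length // (n_shared_functions + 1) if n_shared_functions else 0
        for i, tpl in enumerate(shared_templates):
            a = (i + 1) * slot - shared_segment_length // 2
            a = max(0, min(a, length - shared_segment_length))
            fam_seq[a : a + shared_segment_length] = _mutate(tpl, shared_divergence, rng)
            protected.append((a, a + shared_segment_length))

        # hierarchical substitution-derivation below the family
        subfam_ids = sorted(
            r.taxon_id
            for r in taxonomy.taxa_at_rank("subfamily")
            if taxonomy[r.taxon_id].parent_id == family.taxon_id
        )
        def slow(rate: float) -> float:
            # conserved segments never mutate faster than the background
            return min(shared_divergence, rate)

        for sf in subfam_ids:
            d = div.get("family", 0.0)
            sf_seq = _mutate(fam_seq, d, rng, protected, slow(d))
            genus_ids = sorted(
                r.taxon_id
                for r in taxonomy.taxa_at_rank("genus")
                if taxonomy[r.taxon_id].parent_id == sf
            )
            for gen in genus_ids:
                d = div.get("subfamily", 0.0)
                gen_seq = _mutate(sf_seq, d, rng, protected, slow(d))
                sp_ids = sorted(
                    r.taxon_id
                    for r in taxonomy.taxa_at_rank("species")
                    if taxonomy[r.taxon_id].parent_id == gen
                )
                for sp in sp_ids:
                    d = div.get("genus", 0.0)
                    sp_seq = _mutate(gen_seq, d, rng, protected, slow(d))
                    gid = f"G{sp:04d}"
                    orfs = [
                        Orf(a + 1, b, "+", labels[i])
                        for i, (a, b) in enumerate(protected)
                    ]
                    orfs.extend(
                        _private_orfs(gid, length, protected, n_private_orfs, rng)
                    )
                    orfs.sort(key=lambda o: o.start)
                    genomes.append(
                        ReferenceGenome(
                            genome_id=gid,
                            sequence=_decode(sp_seq),
                            taxon_id=sp,
                            is_viral=taxonomy.is_viral_taxon(sp),
                            orf_table=orfs,
                        )
                    )
    genomes.sort(key=lambda g: g.genome_id)
    return genomes


def _private_orfs(
    gid: str,
    length: int,
    protected: Sequence[tuple[int, int]],
    n: int,
    rng: np.random.Generator,
) -> list[Orf]:
    """Carve ``n`` non-shared ORFs into the gaps between conserved segments."""
    gaps: list[tuple[int, int]] = []
    prev = 0
    for a, b in sorted(protected):
        if a - prev >= 300:
            gaps.append((prev, a))
        prev = b
    if length - prev >= 300:
        gaps.append((prev, length))
    orfs: list[Orf] = []
    for j in range(n):
        if not gaps:
            break
        ga, gb = gaps[j % len(gaps)]
        span = gb - ga
        olen = int(min(span, rng.integers(300, 901)))
        a = ga + int(rng.integers(0, span - olen + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        orfs.append(Orf(a + 1, a + olen, strand, f"{gid}_orf{j + 1}"))
    return orfs


# --------------------------------------------------------------------------
# Coverage and community profiles
# --------------------------------------------------------------------------

def compute_coverage(read_lengths: Sequence[int], genome_length: int) -> float:
    """Mean sequencing depth: sum of mapped read lengths over genome length."""
    if genome_length <= 0:
        raise ValueError("genome_length must be positive")
    if any(l <= 0 for l in read_lengths):
        raise ValueError("read lengths must be positive")
    return float(sum(read_lengths)) / genome_length


def profile_from_coverages(
    coverages: Mapping[str, float],
    genome_lengths: Mapping[str, int],
    total_reads: int,
) -> CommunityProfile:
    """Allocate exact read counts from per-genome coverages.

    Coverages are standardized by the minimum positive value; expected
    counts are proportional to standardized coverage x genome length
    (which is what reproduces the requested per-genome depths for a fixed
    read length), and integers are allocated by largest-remainder rounding
    so the counts sum exactly to ``total_reads``.
    """
    if total_reads < 0:
        raise ValueError("total_reads must be >= 0")
    if any(c < 0 for c in coverages.values()):
        raise ValueError("coverages must be >= 0")
    positive = [c for c in coverages.values() if c > 0]
    if not positive:
        raise ValueError("at least one coverage must be positive")
    cmin = min(positive)
    std = {g: c / cmin for g, c in coverages.items()}
    weights = {g: std[g] * genome_lengths[g] for g in coverages}
    wsum = sum(weights.values())
    quotas = {g: total_reads * w / wsum for g, w in weights.items()}
    counts = {g: int(np.floor(q)) for g, q in quotas.items()}
    short = total_reads - sum(counts.values())
    # largest fractional remainder first; genome id breaks ties
    order = sorted(quotas, key=lambda g: (-(quotas[g] - counts[g]), g))
    for g in order[:short]:
        counts[g] += 1
    return CommunityProfile(coverage=dict(coverages), read_count=counts)


def sample_community_profile(
    genomes: Sequence[ReferenceGenome],
    total_reads: int,
    seed: int,
    lognormal_sigma: float = 1.0,
) -> CommunityProfile:
    """Draw a community abundance profile with log-normally distributed
    coverages (the canonical shape of metagenomic species-abundance
    distributions) and convert it to exact read counts."""
    rng = np.random.default_rng(seed)
    cov = {g.genome_id: float(rng.lognormal(0.0, lognormal_sigma)) for g in genomes}
    lengths = {g.genome_id: len(g) for g in genomes}
    return profile_from_coverages(cov, lengths, total_reads)


# --------------------------------------------------------------------------
# Read simulation
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ErrorModel:
    """454-style error model.

    ``substitution_rate`` applies per read base.  Each homopolymer run of
    length L >= 2 suffers an over- or under-call (one base inserted or
    deleted, equiprobable) with probability
    ``min(0.5, homopolymer_indel_coeff * (L - 1))`` — the characteristic
    flow-chemistry failure mode of pyrosequencing.
    """

    substitution_rate: float = 0.001
    homopolymer_indel_coeff: float = 0.005

    def __post_init__(self):
        if not (0.0 <= self.substitution_rate <= 1.0):
            raise ValueError("substitution_rate outside [0,1]")
        if not (0.0 <= self.homopolymer_indel_coeff <= 1.0):
            raise ValueError("homopolymer_indel_coeff outside [0,1]")


def _apply_errors(
    template: np.ndarray, model: ErrorModel, rng: np.random.Generator
) -> tuple[np.ndarray, list[int]]:
    """Return (read codes, sorted 1-based error positions in the read)."""
    errors: list[int] = []
    read = template
    if model.homopolymer_indel_coeff > 0 and len(template) > 1:
        change = np.nonzero(np.diff(template))[0] + 1
        starts = np.concatenate(([0], change))
        lengths = np.diff(np.concatenate((starts, [len(template)])))
        p = np.minimum(0.5, model.homopolymer_indel_coeff * (lengths - 1))
        hit = rng.random(len(lengths)) < p
        if hit.any():
            over = rng.random(int(hit.sum())) < 0.5
            new_len = lengths.copy()
            deltas = np.where(over, 1, -1)
            new_len[hit] += deltas
            new_len = np.maximum(new_len, 1)
            read = np.repeat(template[starts], new_len)
            # error position: last base of the affected (possibly extended) run
            ends = np.cumsum(new_len)
            for run_idx in np.nonzero(hit)[0]:
                errors.append(int(ends[run_idx]))  # 1-based
    if model.substitution_rate > 0 and len(read):
        read = read.copy()
        sub = rng.random(len(read)) < model.substitution_rate
        n = int(sub.sum())
        if n:
            read[sub] = (read[sub] + rng.integers(1, 4, size=n).astype(np.uint8)) % 4
            errors.extend((np.nonzero(sub)[0] + 1).tolist())
    return read, sorted(set(errors))


def simulate_reads(
    genomes: Sequence[ReferenceGenome],
    profile: CommunityProfile,
    mean_length: int = 400,
    length_sd: float = 30.0,
    error_model: ErrorModel | None = None,
    seed: int = 0,
) -> list[SimulatedRead]:
    """Simulate single-end reads with ground-truth headers.

    Template lengths are normal(mean_length, length_sd) truncated to
    [50, genome length]; start positions and strands are uniform.  The
    output is deterministic for a fixed seed.
    """
    model = error_model or ErrorModel()
    rng = np.random.default_rng(seed)
    by_id = {g.genome_id: g for g in genomes}
    missing = [g for g in profile.read_count if g not in by_id]
    if missing:
        raise ValueError(f"profile references unknown genomes: {missing}")
    total_bases = sum(len(g) for g in genomes)
    requested = profile.total_reads * mean_length
    if requested > 10 * total_bases:
        warnings.warn(
            "requested read volume exceeds 10x the community genome content",
            stacklevel=2,
        )

    reads: list[SimulatedRead] = []
    counter = 0
    for gid in sorted(profile.read_count):
        genome = by_id[gid]
        n = profile.read_count[gid]
        if n == 0:
            continue
        codes = _encode(genome.sequence)
        L = len(codes)
        if length_sd > 0:
            tlens = np.rint(rng.normal(mean_length, length_sd, size=n)).astype(int)
        else:
            tlens = np.full(n, mean_length, dtype=int)
        tlens = np.clip(tlens, 50, L)
        starts = rng.integers(1, L - tlens + 2)  # vectorized per-read bound
        strands = np.where(rng.random(n) < 0.5, "+", "-")
        for i in range(n):
            t, s = int(tlens[i]), int(starts[i])
            template = codes[s - 1 : s - 1 + t]
            if strands[i] == "-":
                template = (3 - template)[::-1]
            read_codes, errs = _apply_errors(template, model, rng)
            counter += 1
            reads.append(
                SimulatedRead(
                    read_id=f"read{counter:06d}",
                    sequence=_decode(read_codes),
                    source_genome_id=gid,
                    start=s,
                    end=s + t - 1,
                    strand=str(strands[i]),
                    error_positions=errs,
                    taxon_id=genome.taxon_id,
                )
            )
    return reads


# --------------------------------------------------------------------------
# Truth manifest and FASTA/TSV I/O
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class TruthRecord:
    read_id: str
    genome_id: str
    taxon_id: int
    start: int
    end: int
    strand: str
    n_errors: int

    @property
    def template_length(self) -> int:
        return self.end - self.start + 1


class TruthManifest:
    """Ground truth for every simulated read, keyed by read id."""

    def __init__(self, records: Iterable[TruthRecord]):
        self._records = {r.read_id: r for r in records}

    def __len__(self) -> int:
        return len(self._records)

    def __contains__(self, read_id: str) -> bool:
        return read_id in self._records

    def __getitem__(self, read_id: str) -> TruthRecord:
        try:
            return self._records[read_id]
        except KeyError:
            raise KeyError(f"read {read_id} missing from truth manifest") from None

    @classmethod
    def from_reads(cls, reads: Iterable[SimulatedRead]) -> "TruthManifest":
        return cls(
            TruthRecord(
                r.read_id, r.source_genome_id, r.taxon_id, r.start, r.end, r.strand,
                len(r.error_positions),
            )
            for r in reads
        )

    def to_frame(self) -> pd.DataFrame:
        cols = ["read_id", "genome_id", "taxon_id", "start", "end", "strand", "n_errors"]
        return pd.DataFrame(
            [tuple(getattr(r, c) for c in cols) for r in self._records.values()],
            columns=cols,
        )

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path) -> "TruthManifest":
        df = pd.read_csv(path, sep="\t")
        return cls(
            TruthRecord(str(r.read_id), str(r.genome_id), int(r.taxon_id),
                        int(r.start), int(r.end), str(r.strand), int(r.n_errors))
            for r in df.itertuples(index=False)
        )


def write_reads_fasta(reads: Iterable[SimulatedRead], path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f">{r.header}\n{r.sequence}\n")


def read_reads_fasta(path) -> list[SimulatedRead]:
    from Bio import SeqIO

    return [
        SimulatedRead.from_header(rec.description, str(rec.seq))
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_genomes_fasta(genomes: Iterable[ReferenceGenome], path) -> None:
    with open(path, "w") as fh:
        for g in genomes:
            fh.write(f">{g.genome_id} tid={g.taxon_id} viral={int(g.is_viral)}\n")
            seq = g.sequence
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def read_genomes_fasta(path, orf_table: pd.DataFrame | None = None) -> list[ReferenceGenome]:
    from Bio import SeqIO

    orfs_by_genome: dict[str, list[Orf]] = {}
    if orf_table is not None:
        for row in orf_table.itertuples(index=False):
            orfs_by_genome.setdefault(str(row.genome_id), []).append(
                Orf(int(row.start), int(row.end), str(row.strand), str(row.function_label))
            )
    genomes = []
    for rec in SeqIO.parse(str(path), "fasta"):
        kv = dict(f.split("=", 1) for f in rec.description.split()[1:])
        genomes.append(
            ReferenceGenome(
                genome_id=rec.id,
                sequence=str(rec.seq).upper(),
                taxon_id=int(kv.get("tid", 0)),
                is_viral=bool(int(kv.get("viral", 0))),
                orf_table=sorted(orfs_by_genome.get(rec.id, []), key=lambda o: o.start),
            )
        )
    return genomes


def orf_table_frame(genomes: Iterable[ReferenceGenome]) -> pd.DataFrame:
    rows = [
        (g.genome_id, o.start, o.end, o.strand, o.function_label)
        for g in genomes
        for o in g.orf_table
    ]
    return pd.DataFrame(
        rows, columns=["genome_id", "start", "end", "strand", "function_label"]
    )
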