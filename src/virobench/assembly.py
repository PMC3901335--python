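"""Assemblies: ACE and placement-TSV I/O, the coordinate-based optimal
assembly, and controlled perturbation fixtures.

The optimal assembly is the ground-truth oracle: reads are merged into
contigs purely from their true genomic coordinates, and each contig's
consensus is the error-free reference substring it spans, so it contains
no assembler artifacts by construction.  ``perturb_assembly`` injects
chimeras at a known rate and rank so the downstream evaluator can be
checked against known truth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence, TextIO

import numpy as np
import pandas as pd

from .community import ReferenceGenome, SimulatedRead, TruthManifest, revcomp
from .taxonomy import TaxonomyTable


@dataclass
class PlacedRead:
    """A read placed in a contig; ``offset`` is the 1-based start of the
    read in unpadded contig coordinates.  ``sequence`` is the read as it
    appears in the contig (reverse-complemented when orientation is '-');
    it may be absent for placements loaded from a bare placement table."""

    read_id: str
    offset: int
    orientation: str
    sequence: str | None = None


@dataclass
class Contig:
    contig_id: str
    consensus: str
    reads: list[PlacedRead]

    def __post_init__(self):
        if len(self.consensus) < 1:
            raise ValueError(f"{self.contig_id}: empty consensus")
        if not self.reads:
            raise ValueError(f"{self.contig_id}: contig without reads")
        for pr in self.reads:
            if pr.offset < 1:
                raise ValueError(f"{self.contig_id}: offset < 1 for {pr.read_id}")

    def __len__(self) -> int:
        return len(self.consensus)


@dataclass
class Assembly:
    label: str
    contigs: list[Contig]
    unassembled_read_ids: set[str] = field(default_factory=set)

    def __post_init__(self):
        seen: set[str] = set()
        for c in self.contigs:
            for pr in c.reads:
                if pr.read_id in seen or pr.read_id in self.unassembled_read_ids:
                    raise ValueError(f"read {pr.read_id} placed more than once")
                seen.add(pr.read_id)

    @property
    def n_contigs(self) -> int:
        return len(self.contigs)

    @property
    def n_reads_placed(self) -> int:
        return sum(len(c.reads) for c in self.contigs)

    def placed_read_ids(self) -> set[str]:
        return {pr.read_id for c in self.contigs for pr in c.reads}


class AceParseError(ValueError):
    pass


# --------------------------------------------------------------------------
# ACE I/O
# --------------------------------------------------------------------------

def write_ace(assembly: Assembly, stream: TextIO) -> None:
    """Write an unpadded-dialect ACE file.

    Consensus and read sequences are emitted without pads; read placements
    use unpadded offsets.  Unassembled read ids are preserved in a WA
    (whole-assembly) tag so that the file round-trips the full data model.
    """
    stream.write(f"AS {assembly.n_contigs} {assembly.n_reads_placed}\n\n")
    for c in assembly.contigs:
        stream.write(f"CO {c.contig_id} {len(c.consensus)} {len(c.reads)} 0 U\n")
        for i in range(0, len(c.consensus), 50):
            stream.write(c.consensus[i : i + 50] + "\n")
        stream.write("\n")
        for pr in c.reads:
            flag = "U" if pr.orientation == "+" else "C"
            stream.write(f"AF {pr.read_id} {flag} {pr.offset}\n")
        stream.write("\n")
        for pr in c.reads:
            seq = pr.sequence
            if seq is None:
                seq = c.consensus[pr.offset - 1 : pr.offset - 1 + 1]
            stream.write(f"RD {pr.read_id} {len(seq)} 0 0\n")
            for i in range(0, len(seq), 50):
                stream.write(seq[i : i + 50] + "\n")
            stream.write(f"QA 1 {len(seq)} 1 {len(seq)}\n\n")
    if assembly.unassembled_read_ids:
        stream.write("WA{\nvirobench_unassembled 00/00/00\n")
        for rid in sorted(assembly.unassembled_read_ids):
            stream.write(rid + "\n")
        stream.write("}\n")


def parse_ace(stream: TextIO, label: str = "assembly") -> Assembly:
    """Parse ACE text into an :class:`Assembly`.

    Pads (``*``) are removed from consensus sequences and AF offsets are
    remapped to unpadded coordinates; offsets <= 0 (left-overhanging reads)
    are clamped to 1.  Raises :class:`AceParseError` naming the offending
    line on malformed input.
    """
    lines = stream.read().splitlines()
    i, n = 0, len(lines)

    def skip_blank():
        nonlocal i
        while i < n and not lines[i].strip():
            i += 1

    skip_blank()
    if i >= n or not lines[i].startswith("AS"):
        raise AceParseError(f"line {i + 1}: missing AS header")
    parts = lines[i].split()
    if len(parts) != 3:
        raise AceParseError(f"line {i + 1}: malformed AS header")
    n_contigs_decl, _n_reads_decl = int(parts[1]), int(parts[2])
    i += 1

    contigs: list[Contig] = []
    unassembled: set[str] = set()

    def read_sequence_block() -> str:
        nonlocal i
        chunks = []
        while i < n and lines[i].strip() and not lines[i].split()[0] in (
            "CO", "AF", "RD", "BQ", "QA", "DS", "WA{", "AS",
        ):
            chunks.append(lines[i].strip())
            i += 1
        return "".join(chunks)

    while i < n:
        skip_blank()
        if i >= n:
            break
        tok = lines[i].split()[0]
        if tok == "CO":
            parts = lines[i].split()
            if len(parts) < 4:
                raise AceParseError(f"line {i + 1}: malformed CO line")
            co_line = i
            contig_id, _nbases, nreads_decl = parts[1], int(parts[2]), int(parts[3])
            i += 1
            padded = read_sequence_block()
            # unpadded offset of each padded position
            unpadded_before = np.cumsum([1 if ch != "*" else 0 for ch in padded])
            consensus = padded.replace("*", "")
            placements: list[tuple[str, str, int, int]] = []  # id, flag, offset, line
            rd_seqs: dict[str, str] = {}
            while i < n:
                skip_blank()
                if i >= n:
                    break
                t = lines[i].split()[0]
                if t == "AF":
                    p = lines[i].split()
                    if len(p) != 4:
                        raise AceParseError(f"line {i + 1}: malformed AF line")
                    placements.append((p[1], p[2], int(p[3]), i + 1))
                    i += 1
                elif t == "BQ":
                    i += 1
                    read_sequence_block()
                elif t == "RD":
                    p = lines[i].split()
                    if len(p) < 2:
                        raise AceParseError(f"line {i + 1}: malformed RD line")
                    rid = p[1]
                    i += 1
                    rd_seqs[rid] = read_sequence_block().replace("*", "")
                elif t in ("QA", "DS"):
                    i += 1
                else:
                    break
            if len(placements) != nreads_decl:
                raise AceParseError(
                    f"line {co_line + 1}: CO declares {nreads_decl} reads, "
                    f"found {len(placements)} AF lines"
                )
            reads = []
            for rid, flag, off, lineno in placements:
                if rid not in rd_seqs:
                    raise AceParseError(f"line {lineno}: AF references unknown read {rid}")
                if off >= 1:
                    # padded offset -> unpadded coordinates
                    idx = min(off, len(padded)) - 1
                    off_unpadded = int(unpadded_before[idx]) if len(padded) else off
                    if padded and padded[idx] == "*":
                        off_unpadded += 1
                else:
                    off_unpadded = 1  # clamp left overhang
                reads.append(
                    PlacedRead(
                        read_id=rid,
                        offset=max(1, off_unpadded),
                        orientation="+" if flag == "U" else "-",
                        sequence=rd_seqs[rid],
                    )
                )
            contigs.append(Contig(contig_id=contig_id, consensus=consensus, reads=reads))
        elif tok == "WA{":
            i += 1
            if i < n and lines[i].startswith("virobench_unassembled"):
                i += 1
                while i < n and lines[i].strip() != "}":
                    unassembled.add(lines[i].strip())
                    i += 1
                i += 1
            else:
                while i < n and lines[i].strip() != "}":
                    i += 1
                i += 1
        else:
            raise AceParseError(f"line {i + 1}: unexpected token {tok!r}")

    if len(contigs) != n_contigs_decl:
        raise AceParseError(
            f"AS header declares {n_contigs_decl} contigs, found {len(contigs)}"
        )
    return Assembly(label=label, contigs=contigs, unassembled_read_ids=unassembled)


# --------------------------------------------------------------------------
# Placement TSV alternative
# --------------------------------------------------------------------------

def write_placement_tsv(assembly: Assembly, path) -> None:
    rows = [
        (c.contig_id, pr.read_id, pr.offset, pr.orientation)
        for c in assembly.contigs
        for pr in c.reads
    ]
    pd.DataFrame(rows, columns=["contig_id", "read_id", "offset", "orientation"]).to_csv(
        path, sep="\t", index=False
    )


def read_placement_tsv(path, contig_fasta, label: str = "assembly") -> Assembly:
    from Bio import SeqIO

    consensus = {r.id: str(r.seq).upper() for r in SeqIO.parse(str(contig_fasta), "fasta")}
    df = pd.read_csv(path, sep="\t")
    by_contig: dict[str, list[PlacedRead]] = {}
    for row in df.itertuples(index=False):
        by_contig.setdefault(str(row.contig_id), []).append(
            PlacedRead(str(row.read_id), int(row.offset), str(row.orientation))
        )
    contigs = [
        Contig(cid, consensus[cid], sorted(reads, key=lambda p: (p.offset, p.read_id)))
        for cid, reads in sorted(by_contig.items())
    ]
    return Assembly(label=label, contigs=contigs)


# --------------------------------------------------------------------------
# Optimal assembly
# --------------------------------------------------------------------------

def optimal_assembly(
    reads: Sequence[SimulatedRead],
    genomes: Sequence[ReferenceGenome],
    min_contig_length: int = 350,
    label: str = "optimal",
) -> Assembly:
    """Ground-truth assembly from true read coordinates.

    Per genome, reads sorted by start (ties: end descending, then read id)
    are merged into maximal chains in which each read overlaps the running
    span by >= 1 bp; each chain becomes a contig whose consensus is the
    error-free reference substring it spans.  Contigs shorter than
    ``min_contig_length`` are discarded and their reads reported
    unassembled.
    """
    by_id = {g.genome_id: g for g in genomes}
    by_genome: dict[str, list[SimulatedRead]] = {}
    for r in reads:
        if r.source_genome_id not in by_id:
            raise ValueError(f"read {r.read_id}: unknown source genome {r.source_genome_id}")
        by_genome.setdefault(r.source_genome_id, []).append(r)

    contigs: list[Contig] = []
    unassembled: set[str] = set()
    for gid in sorted(by_genome):
        genome = by_id[gid]
        rs = sorted(by_genome[gid], key=lambda r: (r.start, -r.end, r.read_id))
        chain: list[SimulatedRead] = []
        span_end = -1
        k = 0

        def flush():
            nonlocal k
            if not chain:
                return
            a = chain[0].start
            b = max(r.end for r in chain)
            if b - a + 1 < min_contig_length:
                unassembled.update(r.read_id for r in chain)
                return
            k += 1
            placed = [
                PlacedRead(
                    read_id=r.read_id,
                    offset=r.start - a + 1,
                    orientation=r.strand,
                    sequence=revcomp(r.sequence) if r.strand == "-" else r.sequence,
                )
                for r in chain
            ]
            contigs.append(
                Contig(
                    contig_id=f"{gid}_c{k}",
                    consensus=genome.sequence[a - 1 : b],
                    reads=placed,
                )
            )

        for r in rs:
            if chain and r.start <= span_end:  # >= 1 bp overlap with running span
                chain.append(r)
                span_end = max(span_end, r.end)
            else:
                flush()
                chain = [r]
                span_end = r.end
        flush()
    return Assembly(label=label, contigs=contigs, unassembled_read_ids=unassembled)


# --------------------------------------------------------------------------
# Perturbation fixtures
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class InjectedChimera:
    contig_id: str
    donor_contig_id: str
    species_taxa: tuple[int, int]
    lca_rank: str


def perturb_assembly(
    assembly: Assembly,
    chimera_rate: float,
    fusion_rank: str,
    read_drop_rate: float,
    seed: int,
    manifest: TruthManifest,
    taxonomy: TaxonomyTable,
    junction_overlap: int = 100,
) -> tuple[Assembly, list[InjectedChimera]]:
    """Inject chimeras at a known rate and rank into an assembly.

    Each contig is selected independently with probability ``chimera_rate``
    (so the expected chimeric fraction equals the injected rate); a selected
    contig receives a block of reads donated by a partner contig whose
    source species' LCA with the selected contig's species is exactly
    ``fusion_rank``.  The partner's consensus is appended (with a
    ``junction_overlap`` bp overlap so donated reads physically overlap the
    junction) and the donated placements shifted; the partner survives with
    its remaining reads.  A fraction ``read_drop_rate`` of placed reads is
    moved to the unassembled pool.  Returns the perturbed assembly and the
    list of injected chimeras for truth checking.
    """
    if not (0.0 <= chimera_rate <= 1.0 and 0.0 <= read_drop_rate <= 1.0):
        raise ValueError("rates must be in [0, 1]")
    rng = np.random.default_rng(seed)

    def contig_species(c: Contig) -> set[int]:
        return {manifest[pr.read_id].taxon_id for pr in c.reads}

    new_contigs = [
        Contig(c.contig_id, c.consensus, [replace(pr) for pr in c.reads])
        for c in assembly.contigs
    ]
    species_of = {c.contig_id: contig_species(c) for c in new_contigs}
    selected = [c for c in new_contigs if rng.random() < chimera_rate]
    selected_ids = {c.contig_id for c in selected}
    injected: list[InjectedChimera] = []
    absorbed: set[str] = set()

    def find_donor(target: Contig, tsp: int) -> Contig | None:
        """Partner search in decreasing order of preference: unselected
        multi-read contigs, then still-single-species selected ones (they
        stay eligible for their own fusion), then whole single-read contigs
        (absorbed entirely)."""
        tiers: list[Contig] = [None, None, None]
        for cand in new_contigs:
            if cand.contig_id == target.contig_id or cand.contig_id in absorbed:
                continue
            sp_c = species_of[cand.contig_id]
            if len(sp_c) != 1:
                continue
            (csp,) = sp_c
            if csp == tsp or taxonomy.lca_rank({tsp, csp}) != fusion_rank:
                continue
            if cand.contig_id not in selected_ids and len(cand.reads) >= 2:
                return cand
            tier = 1 if len(cand.reads) >= 2 else 2
            if tiers[tier] is None:
                tiers[tier] = cand
        return tiers[1] or tiers[2]

    for target in selected:
        if target.contig_id in absorbed:
            continue
        sp_t = species_of[target.contig_id]
        if len(sp_t) != 1:
            warnings.warn(
                f"{target.contig_id}: already multi-species, left unfused", stacklevel=2
            )
            continue
        (tsp,) = sp_t
        donor = find_donor(target, tsp)
        if donor is None:
            warnings.warn(
                f"{target.contig_id}: no eligible partner at rank {fusion_rank}",
                stacklevel=2,
            )
            continue
        donor.reads.sort(key=lambda p: (p.offset, p.read_id))
        n_donate = len(donor.reads) // 2 or 1
        donated = donor.reads[-n_donate:]
        donor.reads = donor.reads[:-n_donate]
        if not donor.reads:
            absorbed.add(donor.contig_id)
        j = min(junction_overlap, len(target.consensus) - 1, min(p.offset for p in donated))
        shift = len(target.consensus) - j + 1 - min(p.offset for p in donated)
        for p in donated:
            p.offset += shift
        target.consensus = target.consensus + donor.consensus
        target.reads.extend(donated)
        (dsp,) = species_of[donor.contig_id]
        species_of[target.contig_id] = {tsp, dsp}
        injected.append(
            InjectedChimera(
                contig_id=target.contig_id,
                donor_contig_id=donor.contig_id,
                species_taxa=(tsp, dsp),
                lca_rank=fusion_rank,
            )
        )

    # read dropping
    unassembled = set(assembly.unassembled_read_ids)
    kept_contigs: list[Contig] = []
    new_contigs = [c for c in new_contigs if c.contig_id not in absorbed]
    for c in new_contigs:
        if read_drop_rate > 0:
            keep, drop = [], []
            for pr in c.reads:
                (drop if rng.random() < read_drop_rate else keep).append(pr)
            unassembled.update(pr.read_id for pr in drop)
            c.reads = keep
        if c.reads:
            kept_contigs.append(c)
        else:
            pass  # emptied contig disappears; its reads are already unassembled
    return (
        Assembly(
            label=f"{assembly.label}_perturbed",
            contigs=kept_contigs,
            unassembled_read_ids=unassembled,
        ),
        injected,
    )
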