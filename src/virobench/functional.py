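"""Ground-truth functional annotation and chimeric-collapse analysis.

Reads receive their "true annotation" from the ORF their genomic interval
overlaps best (requiring at least 60% of the read to be covered).  For
assembled reads, annotated contig regions — ORFs projected onto the contig
through ground-truth coordinates — propagate their label to every member
read with at least 1 bp inside the region, which is how assembly can
rescue function calls that individual reads are too short to support.

A chimeric collapse is a pairwise overlap, within a contig, between two
reads from different organisms; counting the function labels of collapse
regions reveals which (typically conserved) functions drive chimera
formation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .assembly import Assembly, Contig
from .community import Orf, ReferenceGenome, TruthManifest, TruthRecord
from .metrics import contig_taxonomy
from .taxonomy import TaxonomyTable

UNANNOTATED = "unannotated"


@dataclass(frozen=True)
class FunctionAssignment:
    read_id: str
    function_label: str | None
    source: str  # truth | unassembled | assembled
    overlap_fraction: float

    def __post_init__(self):
        if not (0.0 <= self.overlap_fraction <= 1.0):
            raise ValueError("overlap_fraction outside [0, 1]")


@dataclass(frozen=True)
class CollapseRecord:
    contig_id: str
    read_pair: tuple[str, str]
    lca_rank: str
    function_label: str


def _interval_overlap(a1: int, a2: int, b1: int, b2: int) -> int:
    return max(0, min(a2, b2) - max(a1, b1) + 1)


def _best_orf(start: int, end: int, orfs: Sequence[Orf]) -> tuple[Orf | None, int]:
    """ORF with maximal overlap with [start, end]; ties to smaller start."""
    best, best_ov = None, 0
    for orf in orfs:  # orf tables are sorted by start
        ov = _interval_overlap(start, end, orf.start, orf.end)
        if ov > best_ov:
            best, best_ov = orf, ov
    return best, best_ov


def true_annotation(
    read: TruthRecord,
    orf_table: Sequence[Orf],
    min_overlap: float = 0.6,
    source: str = "truth",
) -> FunctionAssignment:
    """Label a read by the ORF that overlaps its genomic interval best.

    The label is assigned only when the best overlap covers at least
    ``min_overlap`` of the read length; the recorded overlap_fraction is
    the best overlap regardless of whether the call was made.
    """
    rlen = read.template_length
    orf, ov = _best_orf(read.start, read.end, orf_table)
    frac = ov / rlen if rlen else 0.0
    label = orf.function_label if (orf is not None and frac >= min_overlap) else None
    return FunctionAssignment(
        read_id=read.read_id, function_label=label, source=source,
        overlap_fraction=frac,
    )


def annotate_contig(
    contig: Contig,
    manifest: TruthManifest,
    genomes_by_id: Mapping[str, ReferenceGenome],
) -> list[FunctionAssignment]:
    """Propagate contig-region annotations to member reads.

    The contig is projected onto its majority genome through the
    ground-truth coordinates of the majority reads; every ORF overlapping
    the projected span becomes an annotated contig region, and each read
    with >= 1 bp inside a region inherits that region's label with
    overlap_fraction = (read bases inside the region) / (read length).
    Reads overlapping several regions keep the best-covered one.
    """
    call = contig_taxonomy(contig, manifest)
    genome = genomes_by_id[call.genome_id]
    anchors = [
        (pr, manifest[pr.read_id])
        for pr in contig.reads
        if manifest[pr.read_id].genome_id == call.genome_id
    ]
    pr0, rec0 = min(anchors, key=lambda t: (t[0].offset, t[0].read_id))
    g_anchor = rec0.start - (pr0.offset - 1)  # genome coord of contig position 1
    L = len(contig.consensus)
    span_start, span_end = g_anchor, g_anchor + L - 1

    regions: list[tuple[int, int, str]] = []  # contig coords
    for orf in genome.orf_table:
        ov = _interval_overlap(span_start, span_end, orf.start, orf.end)
        if ov == 0:
            continue
        a = max(1, orf.start - g_anchor + 1)
        b = min(L, orf.end - g_anchor + 1)
        regions.append((a, b, orf.function_label))

    out: list[FunctionAssignment] = []
    for pr in contig.reads:
        rec = manifest[pr.read_id]
        r1, r2 = pr.offset, pr.offset + rec.template_length - 1
        best_label, best_ov = None, 0
        for a, b, label in regions:
            ov = _interval_overlap(r1, r2, a, b)
            if ov > best_ov:
                best_label, best_ov = label, ov
        if best_label is not None:
            out.append(
                FunctionAssignment(
                    read_id=pr.read_id,
                    function_label=best_label,
                    source="assembled",
                    overlap_fraction=best_ov / rec.template_length,
                )
            )
    return out


def annotate_assembly(
    assembly: Assembly,
    manifest: TruthManifest,
    genomes_by_id: Mapping[str, ReferenceGenome],
) -> list[FunctionAssignment]:
    out: list[FunctionAssignment] = []
    for c in assembly.contigs:
        out.extend(annotate_contig(c, manifest, genomes_by_id))
    return out


def annotation_accuracy(
    assignments: Iterable[FunctionAssignment],
    truth_assignments: Iterable[FunctionAssignment],
    cutoffs: Sequence[float] = (0.1, 0.3, 0.5, 1.0),
) -> pd.DataFrame:
    """Correct/incorrect call counts at each overlap cutoff.

    At cutoff c, an assignment with a label and overlap_fraction >= c is
    correct when its label equals the truth label for the same read (a
    truth of ``None`` makes any call incorrect); unlabeled assignments are
    not counted as calls.
    """
    truth = {t.read_id: t.function_label for t in truth_assignments}
    calls = [a for a in assignments if a.function_label is not None]
    rows = []
    for c in cutoffs:
        eligible = [a for a in calls if a.overlap_fraction >= c]
        correct = sum(1 for a in eligible if truth.get(a.read_id) == a.function_label)
        incorrect = len(eligible) - correct
        pct = 100.0 * correct / len(eligible) if eligible else 0.0
        rows.append((c, correct, incorrect, pct))
    return pd.DataFrame(rows, columns=["cutoff", "correct", "incorrect", "pct_correct"])


def chimeric_collapses(
    assembly: Assembly,
    manifest: TruthManifest,
    genomes_by_id: Mapping[str, ReferenceGenome],
    taxonomy: TaxonomyTable,
) -> list[CollapseRecord]:
    """All pairwise within-contig overlaps between reads of different
    organisms, with the pair's LCA rank and the function of the overlap
    region (``"unannotated"`` when no ORF covers it).

    The overlap interval is mapped to genome coordinates through the
    lower-offset read of the pair.
    """
    records: list[CollapseRecord] = []
    for contig in assembly.contigs:
        placed = sorted(
            ((pr, manifest[pr.read_id]) for pr in contig.reads),
            key=lambda t: (t[0].offset, t[0].read_id),
        )
        ends = [pr.offset + rec.template_length - 1 for pr, rec in placed]
        for i, (pa, ra) in enumerate(placed):
            for j in range(i + 1, len(placed)):
                pb, rb = placed[j]
                if pb.offset > ends[i]:
                    break  # sorted by offset: no later read can overlap read i
                if ra.genome_id == rb.genome_id:
                    continue
                o1 = max(pa.offset, pb.offset)
                o2 = min(ends[i], ends[j])
                # map overlap to the anchor (lower-offset) read's genome
                g1 = ra.start + (o1 - pa.offset)
                g2 = ra.start + (o2 - pa.offset)
                orf, ov = _best_orf(g1, g2, genomes_by_id[ra.genome_id].orf_table)
                label = orf.function_label if (orf is not None and ov >= 1) else UNANNOTATED
                records.append(
                    CollapseRecord(
                        contig_id=contig.contig_id,
                        read_pair=(pa.read_id, pb.read_id),
                        lca_rank=taxonomy.lca_rank({ra.taxon_id, rb.taxon_id}),
                        function_label=label,
                    )
                )
    return records


def overrepresented_functions(
    records: Iterable[CollapseRecord],
    min_abundance: float = 0.01,
) -> list[tuple[str, int]]:
    """Outlier function labels among chimeric collapses.

    Builds the frequency distribution of annotated collapse labels,
    flags labels whose count exceeds Q3 + 1.5*IQR of that distribution,
    and keeps outliers with relative abundance above ``min_abundance``
    (of annotated collapses), sorted by count descending.
    """
    counts: dict[str, int] = {}
    for r in records:
        if r.function_label == UNANNOTATED:
            continue
        counts[r.function_label] = counts.get(r.function_label, 0) + 1
    if not counts:
        return []
    values = np.array(list(counts.values()), dtype=float)
    q1, q3 = np.percentile(values, [25, 75])
    fence = q3 + 1.5 * (q3 - q1)
    total = values.sum()
    out = [
        (label, n)
        for label, n in counts.items()
        if n > fence and n / total > min_abundance
    ]
    out.sort(key=lambda t: (-t[1], t[0]))
    return out


# --------------------------------------------------------------------------
# TSV report writers
# --------------------------------------------------------------------------

def assignments_frame(assignments: Iterable[FunctionAssignment]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (a.read_id, a.source, a.function_label or "", a.overlap_fraction)
            for a in assignments
        ],
        columns=["read_id", "source", "function_label", "overlap_fraction"],
    )


def collapses_frame(records: Iterable[CollapseRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (r.contig_id, r.read_pair[0], r.read_pair[1], r.lca_rank, r.function_label)
            for r in records
        ],
        columns=["contig_id", "read_a", "read_b", "lca_rank", "function_label"],
    )
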