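"""Ranked synthetic taxonomy: a nine-rank hierarchy from root to species.

The table mirrors the rank ladder used when binning metagenomic reads
(root, superkingdom, phylum, class, order, family, subfamily, genus,
species).  Every species sits at the end of a complete root-to-species
path, which makes lowest-common-ancestor queries a simple lineage walk.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: Fixed rank order, highest first.  Index = depth.
RANKS: tuple[str, ...] = (
    "root",
    "superkingdom",
    "phylum",
    "class",
    "order",
    "family",
    "subfamily",
    "genus",
    "species",
)

RANK_DEPTH = {r: i for i, r in enumerate(RANKS)}

VIRAL_SUPERKINGDOM = "Viruses"
BACTERIAL_SUPERKINGDOM = "Bacteria"


@dataclass(frozen=True)
class TaxonRecord:
    taxon_id: int
    parent_id: int
    rank: str
    name: str


class TaxonomyTable:
    """Immutable collection of :class:`TaxonRecord` with lineage queries."""

    def __init__(self, records: Iterable[TaxonRecord]):
        self._records: dict[int, TaxonRecord] = {}
        for rec in records:
            if rec.taxon_id in self._records:
                raise ValueError(f"duplicate taxon_id {rec.taxon_id}")
            if rec.rank not in RANK_DEPTH:
                raise ValueError(f"unknown rank {rec.rank!r}")
            self._records[rec.taxon_id] = rec
        roots = [r for r in self._records.values() if r.rank == "root"]
        if len(roots) != 1:
            raise ValueError(f"expected exactly one root record, got {len(roots)}")
        root = roots[0]
        if root.parent_id != root.taxon_id:
            raise ValueError("root record must be its own parent")
        self.root_id = root.taxon_id
        for rec in self._records.values():
            if rec.rank == "root":
                continue
            parent = self._records.get(rec.parent_id)
            if parent is None:
                raise ValueError(f"taxon {rec.taxon_id}: parent {rec.parent_id} missing")
            if RANK_DEPTH[parent.rank] >= RANK_DEPTH[rec.rank]:
                raise ValueError(
                    f"taxon {rec.taxon_id} ({rec.rank}) under parent of rank {parent.rank}"
                )

    def __len__(self) -> int:
        return len(self._records)

    def __contains__(self, taxon_id: int) -> bool:
        return taxon_id in self._records

    def __getitem__(self, taxon_id: int) -> TaxonRecord:
        try:
            return self._records[taxon_id]
        except KeyError:
            raise KeyError(f"taxon {taxon_id} not in taxonomy") from None

    @property
    def records(self) -> list[TaxonRecord]:
        return sorted(self._records.values(), key=lambda r: r.taxon_id)

    def taxa_at_rank(self, rank: str) -> list[TaxonRecord]:
        return [r for r in self.records if r.rank == rank]

    def species(self) -> list[TaxonRecord]:
        return self.taxa_at_rank("species")

    def lineage(self, taxon_id: int) -> list[TaxonRecord]:
        """Lineage from root down to ``taxon_id`` inclusive."""
        path = []
        rec = self[taxon_id]
        while True:
            path.append(rec)
            if rec.rank == "root":
                break
            rec = self[rec.parent_id]
        return path[::-1]

    def ancestor_at(self, taxon_id: int, rank: str) -> int | None:
        """Taxon id of the ``rank`` ancestor of ``taxon_id`` (or itself)."""
        if rank not in RANK_DEPTH:
            raise ValueError(f"unknown rank {rank!r}")
        for rec in self.lineage(taxon_id):
            if rec.rank == rank:
                return rec.taxon_id
        return None

    def lca(self, taxa: Iterable[int]) -> TaxonRecord:
        """Lowest common ancestor record of a non-empty set of taxa."""
        taxa = list(taxa)
        if not taxa:
            raise ValueError("empty taxon set")
        lineages = [self.lineage(t) for t in taxa]
        lca = lineages[0][0]
        for depth in range(min(len(l) for l in lineages)):
            ids = {l[depth].taxon_id for l in lineages}
            if len(ids) > 1:
                break
            lca = lineages[0][depth]
        return lca

    def lca_rank(self, taxa: Iterable[int]) -> str:
        """Lowest rank at which all lineages share one ancestor.

        A singleton set returns its own rank; sets spanning superkingdoms
        return ``"root"``.
        """
        return self.lca(taxa).rank

    def is_viral_taxon(self, taxon_id: int) -> bool:
        sk = self.ancestor_at(taxon_id, "superkingdom")
        return sk is not None and self[sk].name == VIRAL_SUPERKINGDOM

    # ------------------------------------------------------------------ I/O
    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(r.taxon_id, r.parent_id, r.rank, r.name) for r in self.records],
            columns=["taxon_id", "parent_id", "rank", "name"],
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "TaxonomyTable":
        return cls(
            TaxonRecord(int(t), int(p), str(r), str(n))
            for t, p, r, n in df[["taxon_id", "parent_id", "rank", "name"]].itertuples(
                index=False
            )
        )

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path) -> "TaxonomyTable":
        return cls.from_frame(pd.read_csv(path, sep="\t"))

    def __eq__(self, other) -> bool:
        return isinstance(other, TaxonomyTable) and self.records == other.records


_SYLLABLES = (
    "va", "ro", "mi", "cu", "te", "lo", "pha", "gen", "si", "bra",
    "del", "ko", "ne", "ul", "ar", "tho", "ze", "qui", "mor", "fex",
)


def _make_namer(rng: np.random.Generator):
    seen: set[str] = set()

    def name(suffix: str) -> str:
        while True:
            n = "".join(rng.choice(_SYLLABLES) for _ in range(3)).capitalize() + suffix
            if n not in seen:
                seen.add(n)
                return n

    return name


def build_taxonomy(
    n_families: int,
    n_genera_per_family: int,
    n_species_per_genus: int,
    viral_fraction: float,
    seed: int,
    families_per_order: int = 3,
    genera_per_subfamily: int = 2,
) -> TaxonomyTable:
    """Build a complete ranked taxonomy with every rank on every path.

    Families are split between a viral and a bacterial superkingdom
    according to ``viral_fraction`` (rounded to whole families); within
    each superkingdom a single phylum and class hold the orders, orders
    group up to ``families_per_order`` families, and subfamilies group up
    to ``genera_per_subfamily`` genera.  Deterministic for a fixed seed.
    """
    if n_families < 1 or n_genera_per_family < 1 or n_species_per_genus < 1:
        raise ValueError("all counts must be >= 1")
    if not 0.0 <= viral_fraction <= 1.0:
        raise ValueError("viral_fraction must be in [0, 1]")
    if families_per_order < 1 or genera_per_subfamily < 1:
        raise ValueError("grouping sizes must be >= 1")

    rng = np.random.default_rng(seed)
    namer = _make_namer(rng)

    records = [TaxonRecord(1, 1, "root", "root")]
    next_id = 2

    def add(parent_id: int, rank: str, name: str) -> int:
        nonlocal next_id
        records.append(TaxonRecord(next_id, parent_id, rank, name))
        next_id += 1
        return next_id - 1

    n_viral = int(round(viral_fraction * n_families))
    sk_plan = []
    if n_viral > 0:
        sk_plan.append((VIRAL_SUPERKINGDOM, n_viral, "virus"))
    if n_families - n_viral > 0:
        sk_plan.append((BACTERIAL_SUPERKINGDOM, n_families - n_viral, "bacter"))

    for sk_name, n_fam, suffix in sk_plan:
        sk = add(1, "superkingdom", sk_name)
        ph = add(sk, "phylum", namer("phyla"))
        cl = add(ph, "class", namer("ia"))
        order_id = None
        for fi in range(n_fam):
            if fi % families_per_order == 0:
                order_id = add(cl, "order", namer("ales"))
            fam = add(order_id, "family", namer("viridae" if suffix == "virus" else "aceae"))
            subfam_id = None
            for gi in range(n_genera_per_family):
                if gi % genera_per_subfamily == 0:
                    subfam_id = add(fam, "subfamily", namer("inae"))
                gen = add(subfam_id, "genus", namer(suffix))
                for _ in range(n_species_per_genus):
                    add(gen, "species", namer(f" {suffix}"))

    return TaxonomyTable(records)
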