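"""Gene-overlap annotation of CNV calls and gene-set membership.

A call "overlaps" a gene when it shares at least 1 bp with the gene's full
genomic span (half-open intervals; abutment is not overlap).  Calls that
overlap no gene are retained with empty annotations — they still count for
the hypothesis-free "any call" burden.  Compound sets for the
lipid-by-tissue decomposition (intersection and tissue-minus-lipid) are
derived as first-class sets so downstream burden and regression code can
treat them uniformly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

from intervaltree import IntervalTree

from .types import CnvCall, GeneModel, GeneSetCollection

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class AnnotatedCall:
    """A CNV call with the genes it overlaps and the gene sets those hit."""

    call: CnvCall
    genes: frozenset[str]
    sets_hit: frozenset[str]


class GeneIndex:
    """Interval index over gene models for overlap queries.

    Queries return genes sharing >= 1 bp with the query interval, in
    deterministic (chrom, start, gene_id) order.
    """

    def __init__(self, genes: Sequence[GeneModel]):
        seen: dict[str, GeneModel] = {}
        for g in genes:
            prev = seen.get(g.gene_id)
            if prev is not None and (prev.chrom, prev.start, prev.end) != (
                g.chrom, g.start, g.end
            ):
                raise ValueError(
                    f"duplicate gene_id {g.gene_id!r} with conflicting coordinates"
                )
            seen[g.gene_id] = g
        self._genes = sorted(seen.values(), key=lambda g: (g.chrom, g.start, g.gene_id))
        self._trees: dict[str, IntervalTree] = {}
        for g in self._genes:
            self._trees.setdefault(g.chrom, IntervalTree()).addi(g.start, g.end, g)

    def query(self, chrom: str, start: int, end: int) -> list[GeneModel]:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        hits = [iv.data for iv in tree.overlap(start, end)]
        return sorted(hits, key=lambda g: (g.chrom, g.start, g.gene_id))

    def __len__(self) -> int:
        return len(self._genes)


def build_gene_index(genes: Sequence[GeneModel]) -> GeneIndex:
    """Build an interval index over gene models."""
    return GeneIndex(genes)


def _membership(collection: GeneSetCollection) -> dict[str, frozenset[str]]:
    by_gene: dict[str, set[str]] = {}
    for name in collection.names():
        for g in collection[name]:
            by_gene.setdefault(g, set()).add(name)
    return {g: frozenset(s) for g, s in by_gene.items()}


def annotate_calls(
    calls: Iterable[CnvCall],
    index: GeneIndex,
    collection: GeneSetCollection,
) -> list[AnnotatedCall]:
    """Annotate each call with overlapped genes and the induced set names.

    Gene-set members absent from the gene models are logged once and
    ignored for overlap purposes.
    """
    known = {g.gene_id for g in index._genes}
    missing = sorted(
        {g for name in collection.names() for g in collection[name]} - known
    )
    if missing:
        log.warning(
            "%d gene-set members absent from gene models (e.g. %s); ignored "
            "for overlap", len(missing), ", ".join(missing[:5])
        )
    membership = _membership(collection)
    out = []
    for c in calls:
        genes = frozenset(g.gene_id for g in index.query(c.chrom, c.start, c.end))
        sets_hit: set[str] = set()
        for g in genes:
            sets_hit |= membership.get(g, frozenset())
        out.append(AnnotatedCall(call=c, genes=genes, sets_hit=frozenset(sets_hit)))
    return out


#: Default names of the base and derived lipid/tissue sets.
LIPID_SET = "lipid"
SI_SET = "small_intestine"
LIPID_AND_SI_SET = "lipid_and_small_intestine"
SI_NOT_LIPID_SET = "small_intestine_not_lipid"


def derive_compound_sets(
    collection: GeneSetCollection,
    lipid: str = LIPID_SET,
    tissue: str = SI_SET,
) -> GeneSetCollection:
    """Add lipid∩tissue and tissue∖lipid as first-class gene sets.

    Returns a new collection; the inputs are not modified.  An empty
    intersection or difference is an error (the derived hypothesis would be
    vacuous).
    """
    for required in (lipid, tissue):
        if required not in collection:
            raise ValueError(f"base gene set {required!r} is missing")
    inter = collection[lipid] & collection[tissue]
    diff = collection[tissue] - collection[lipid]
    if not inter:
        raise ValueError(f"{lipid!r} and {tissue!r} are disjoint; compound set empty")
    if not diff:
        raise ValueError(f"{tissue!r} is a subset of {lipid!r}; compound set empty")
    out = GeneSetCollection(dict(collection.sets), dict(collection.provenance))
    out.add(LIPID_AND_SI_SET, inter, provenance=f"{lipid} ∩ {tissue}")
    out.add(SI_NOT_LIPID_SET, diff, provenance=f"{tissue} ∖ {lipid}")
    return out
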