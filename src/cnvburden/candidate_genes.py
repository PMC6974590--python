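"""Candidate-gene extraction: genes hit by case-exclusive CNVs.

The chain narrows a lipid-metabolism gene list to candidates in four
stages: (1) the full lipid set, (2) its tissue-expressed subset,
(3) members overlapped by a CNV in at least one case, and (4) members with
no control carrier anywhere (exclusivity is absolute: a single control
carrier in any cohort disqualifies the gene).  Output rows carry the
carrier call's printed (1-based inclusive) coordinates, type and cohort,
so multi-gene CNVs yield one row per qualifying gene; the serializer groups
genes that share identical call coordinates into one display row.

Loss-of-function-intolerance enrichment of the candidates against a
user-supplied intolerant-gene list uses the upper-tail hypergeometric test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import pandas as pd
from scipy.stats import hypergeom

from .overlap_annot import AnnotatedCall
from .types import CnvType, SampleRecord, Sex, Status


@dataclass(frozen=True)
class CandidateGene:
    """One gene × carrier-call record of the candidate table."""

    gene_id: str
    n_gsd_cases: int
    n_controls: int
    case_sex: frozenset[Sex]
    chrom: str
    cnv_start: int  # 1-based inclusive, for display
    cnv_end: int
    cnv_type: CnvType
    cohort: str

    def __post_init__(self) -> None:
        if self.n_controls != 0:
            raise ValueError("candidate genes must have zero control carriers")
        if self.n_gsd_cases < 1:
            raise ValueError("candidate genes need at least one case carrier")


@dataclass(frozen=True)
class StageCounts:
    """Sizes of the four filtering stages of the candidate chain."""

    n_lipid: int
    n_lipid_tissue: int
    n_case_hit: int
    n_case_exclusive: int

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.n_lipid, self.n_lipid_tissue, self.n_case_hit,
                self.n_case_exclusive)


def extract_candidates(
    annotated: Sequence[AnnotatedCall],
    samples: Sequence[SampleRecord],
    lipid_set: frozenset[str],
    tissue_set: frozenset[str],
) -> tuple[list[CandidateGene], StageCounts]:
    """Run the candidate chain and report stage counts.

    Candidate rows are sorted by (chrom, start, gene_id); the result is
    invariant to the order of the input calls.
    """
    if not lipid_set:
        raise ValueError("lipid gene set is empty")
    if not tissue_set:
        raise ValueError("tissue gene set is empty")
    status_of = {s.sample_id: s.status for s in samples}
    sex_of = {s.sample_id: s.sex for s in samples}
    eligible = frozenset(lipid_set & tissue_set)

    case_hit: set[str] = set()
    control_hit: set[str] = set()
    # carrier calls per gene, cases only
    case_calls: dict[str, list[AnnotatedCall]] = {}
    for ac in annotated:
        st = status_of.get(ac.call.sample_id)
        if st is None:
            continue
        genes = ac.genes & eligible
        if not genes:
            continue
        for g in genes:
            if st is Status.CASE:
                case_hit.add(g)
                case_calls.setdefault(g, []).append(ac)
            else:
                control_hit.add(g)

    exclusive = case_hit - control_hit
    counts = StageCounts(
        n_lipid=len(lipid_set),
        n_lipid_tissue=len(eligible),
        n_case_hit=len(case_hit),
        n_case_exclusive=len(exclusive),
    )
    candidates: list[CandidateGene] = []
    for gene in exclusive:
        for ac in case_calls[gene]:
            carriers = {ac.call.sample_id}
            candidates.append(
                CandidateGene(
                    gene_id=gene,
                    n_gsd_cases=len(carriers),
                    n_controls=0,
                    case_sex=frozenset(sex_of[s] for s in carriers),
                    chrom=ac.call.chrom,
                    cnv_start=ac.call.start + 1,
                    cnv_end=ac.call.end,
                    cnv_type=ac.call.cnv_type,
                    cohort=ac.call.cohort,
                )
            )
    candidates.sort(key=lambda c: (c.chrom, c.cnv_start, c.gene_id))
    return candidates, counts


def candidate_frame(candidates: Iterable[CandidateGene]) -> pd.DataFrame:
    """Display table; genes sharing identical call coordinates are grouped
    into one row, and rows for the same gene are aggregated over carriers."""
    rows = []
    for c in candidates:
        rows.append(
            {
                "gene_id": c.gene_id,
                "n_gsd_cases": c.n_gsd_cases,
                "n_controls": c.n_controls,
                "case_sex": ", ".join(sorted(s.value.title() for s in c.case_sex)),
                "chrom": c.chrom,
                "cnv_start": c.cnv_start,
                "cnv_end": c.cnv_end,
                "type": c.cnv_type.value.title(),
                "cohort": c.cohort,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=["gene_id", "n_gsd_cases", "n_controls", "case_sex", "chrom",
                 "cnv_start", "cnv_end", "type", "cohort"],
    )
    if df.empty:
        return df
    grouped = (
        df.groupby(["chrom", "cnv_start", "cnv_end", "type", "cohort"], sort=False)
        .agg(
            gene_id=("gene_id", lambda g: ", ".join(sorted(set(g)))),
            n_gsd_cases=("n_gsd_cases", "sum"),
            n_controls=("n_controls", "sum"),
            case_sex=("case_sex", lambda s: ", ".join(sorted(set(s)))),
        )
        .reset_index()
    )
    cols = ["gene_id", "n_gsd_cases", "n_controls", "case_sex", "chrom",
            "cnv_start", "cnv_end", "type", "cohort"]
    return grouped[cols].sort_values(["chrom", "cnv_start", "gene_id"]).reset_index(drop=True)


def hypergeom_enrichment(
    hits_in_set: int, set_size: int, hits_total: int, universe: int
) -> float:
    """Upper-tail hypergeometric enrichment p-value, P(X >= hits_in_set).

    *universe* genes of which *set_size* are in the annotated class;
    *hits_total* genes drawn (e.g. candidates), *hits_in_set* of them in
    the class.
    """
    if min(hits_in_set, set_size, hits_total, universe) < 0:
        raise ValueError("counts must be non-negative")
    if hits_in_set > min(set_size, hits_total):
        raise ValueError("hits_in_set exceeds set_size or hits_total")
    if max(set_size, hits_total) > universe:
        raise ValueError("set_size and hits_total must not exceed universe")
    return float(hypergeom.sf(hits_in_set - 1, universe, set_size, hits_total))
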