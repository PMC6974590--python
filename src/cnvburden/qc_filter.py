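"""Call-level and sample-level quality control for rare-CNV analysis.

The canonical chain, in order, is

1. size — keep calls strictly larger than ``min_size_bp`` (default 100 kb);
2. probes — keep calls with at least the per-cohort probe minimum
   (default 50; high-density platforms typically 100);
3. blacklist — drop calls sharing >= 1 bp with any signal-artifact region;
4. outlier samples — per cohort, drop samples whose call count exceeds the
   cohort mean by more than ``outlier_sd`` population standard deviations;
5. rarity — cluster same-type calls into CNV regions by single-linkage at
   >= 50% reciprocal overlap and drop regions carried by more than
   ``max_frequency`` of the cohort.

Each stage is exposed on its own and :func:`run_qc` applies the whole chain,
returning the filtered calls, the retained samples and a :class:`QcReport`
with per-stage counts.  The chain is idempotent.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd

from .types import CnvCall, CnvType, GeneModel, SampleRecord

log = logging.getLogger(__name__)


@dataclass
class QcConfig:
    min_size_bp: int = 100_000
    default_min_probes: int = 50
    min_probes: dict[str, int] = field(default_factory=dict)
    max_frequency: float = 0.01
    outlier_sd: float = 3.0
    blacklist: list[GeneModel] = field(default_factory=list)
    reciprocal_overlap: float = 0.50

    def __post_init__(self) -> None:
        if self.min_size_bp <= 0:
            raise ValueError("min_size_bp must be > 0")
        if not 0 < self.max_frequency <= 1:
            raise ValueError("max_frequency must be in (0, 1]")
        if self.outlier_sd <= 0:
            raise ValueError("outlier_sd must be > 0")
        if not 0 < self.reciprocal_overlap <= 1:
            raise ValueError("reciprocal_overlap must be in (0, 1]")

    def probe_threshold(self, cohort: str) -> int:
        return self.min_probes.get(cohort, self.default_min_probes)


@dataclass
class QcReport:
    """Per-stage call counts and sample exclusions of one QC run."""

    stage_counts: dict[str, int] = field(default_factory=dict)
    excluded_samples: dict[str, str] = field(default_factory=dict)
    per_cohort_type_counts: dict[str, dict[str, int]] = field(default_factory=dict)
    region_table: Optional[pd.DataFrame] = None

    def record_stage(self, name: str, n: int) -> None:
        self.stage_counts[name] = n

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"stage": list(self.stage_counts), "n_calls": list(self.stage_counts.values())}
        )


def filter_size(calls: Sequence[CnvCall], min_size_bp: int) -> list[CnvCall]:
    """Keep calls strictly larger than *min_size_bp*."""
    return [c for c in calls if c.size() > min_size_bp]


def filter_probes(calls: Sequence[CnvCall], config: QcConfig) -> list[CnvCall]:
    """Keep calls supported by at least the cohort's probe minimum."""
    return [c for c in calls if c.n_probes >= config.probe_threshold(c.cohort)]


def _overlaps(start: int, end: int, other_start: int, other_end: int) -> bool:
    return start < other_end and other_start < end


def filter_blacklist(
    calls: Sequence[CnvCall], blacklist: Sequence[GeneModel]
) -> list[CnvCall]:
    """Drop calls sharing at least 1 bp with any blacklist interval."""
    if not blacklist:
        return list(calls)
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for b in blacklist:
        by_chrom.setdefault(b.chrom, []).append((b.start, b.end))
    for ivs in by_chrom.values():
        ivs.sort()
    kept = []
    for c in calls:
        hit = any(
            _overlaps(c.start, c.end, s, e) for s, e in by_chrom.get(c.chrom, ())
        )
        if not hit:
            kept.append(c)
    return kept


def exclude_outlier_samples(
    calls: Sequence[CnvCall],
    samples: Sequence[SampleRecord],
    outlier_sd: float = 3.0,
) -> tuple[list[SampleRecord], dict[str, str]]:
    """Drop samples whose call count is an upper outlier within their cohort.

    The threshold is cohort mean + *outlier_sd* population standard
    deviations of per-sample call counts (samples with no calls count 0),
    computed in a single pass without re-computation after exclusions.
    Cohorts with fewer than two samples are skipped with a warning.

    Returns the retained samples and a mapping excluded sample_id -> reason.
    """
    counts: dict[str, int] = {s.sample_id: 0 for s in samples}
    for c in calls:
        if c.sample_id in counts:
            counts[c.sample_id] += 1
    excluded: dict[str, str] = {}
    by_cohort: dict[str, list[SampleRecord]] = {}
    for s in samples:
        by_cohort.setdefault(s.cohort, []).append(s)
    for cohort, members in by_cohort.items():
        if len(members) < 2:
            log.warning("cohort %s has <2 samples; outlier exclusion skipped", cohort)
            continue
        vals = [counts[s.sample_id] for s in members]
        m = sum(vals) / len(vals)
        sd = math.sqrt(sum((v - m) ** 2 for v in vals) / len(vals))
        cutoff = m + outlier_sd * sd
        for s in members:
            if counts[s.sample_id] > cutoff:
                excluded[s.sample_id] = (
                    f"{counts[s.sample_id]} calls > mean {m:.3g} + "
                    f"{outlier_sd:g} SD ({sd:.3g}) in cohort {cohort}"
                )
    retained = [s for s in samples if s.sample_id not in excluded]
    return retained, excluded


def _reciprocal_overlap(a: CnvCall, b: CnvCall) -> float:
    ov = min(a.end, b.end) - max(a.start, b.start)
    if ov <= 0:
        return 0.0
    return min(ov / a.size(), ov / b.size())


def _cluster_regions(
    calls: list[CnvCall], threshold: float
) -> list[list[int]]:
    """Single-linkage clusters of call indices at >= threshold reciprocal overlap."""
    order = sorted(range(len(calls)), key=lambda i: (calls[i].chrom, calls[i].start, calls[i].end))
    parent = list(range(len(calls)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    # Sweep per chromosome: a qualifying pair always overlaps, so only
    # calls whose spans intersect need the reciprocal-overlap check.
    for pos, i in enumerate(order):
        ci = calls[i]
        for j in order[pos + 1:]:
            cj = calls[j]
            if cj.chrom != ci.chrom or cj.start >= ci.end:
                break
            if _reciprocal_overlap(ci, cj) >= threshold:
                union(i, j)
    clusters: dict[int, list[int]] = {}
    for i in range(len(calls)):
        clusters.setdefault(find(i), []).append(i)
    return list(clusters.values())


def filter_rare(
    calls: Sequence[CnvCall],
    samples: Sequence[SampleRecord],
    config: QcConfig,
) -> tuple[list[CnvCall], pd.DataFrame]:
    """Drop calls belonging to CNV regions above the rarity threshold.

    Within each cohort and CNV type, calls are clustered into regions by
    single-linkage at >= ``config.reciprocal_overlap`` mutual overlap.  The
    region frequency is distinct carrier samples over the cohort sample
    count; regions with frequency strictly above ``config.max_frequency``
    are removed entirely.  Returns the retained calls and a region table
    with carrier counts and singleton flags.
    """
    cohort_n: dict[str, int] = {}
    for s in samples:
        cohort_n[s.cohort] = cohort_n.get(s.cohort, 0) + 1
    groups: dict[tuple[str, str], list[int]] = {}
    for i, c in enumerate(calls):
        groups.setdefault((c.cohort, c.cnv_type.value), []).append(i)
    drop: set[int] = set()
    rows = []
    for (cohort, cnv_type), idxs in sorted(groups.items()):
        sub = [calls[i] for i in idxs]
        n_cohort = cohort_n.get(cohort, 0)
        for cluster in _cluster_regions(sub, config.reciprocal_overlap):
            members = [sub[k] for k in cluster]
            carriers = {m.sample_id for m in members}
            freq = len(carriers) / n_cohort if n_cohort else 0.0
            removed = n_cohort > 0 and freq > config.max_frequency
            rows.append(
                {
                    "cohort": cohort,
                    "cnv_type": cnv_type,
                    "chrom": members[0].chrom,
                    "region_start": min(m.start for m in members),
                    "region_end": max(m.end for m in members),
                    "n_calls": len(members),
                    "n_carriers": len(carriers),
                    "frequency": freq,
                    "singleton": len(carriers) == 1,
                    "removed": removed,
                }
            )
            if removed:
                drop.update(idxs[k] for k in cluster)
    region_table = pd.DataFrame(
        rows,
        columns=["cohort", "cnv_type", "chrom", "region_start", "region_end",
                 "n_calls", "n_carriers", "frequency", "singleton", "removed"],
    ).sort_values(["cohort", "cnv_type", "chrom", "region_start"]).reset_index(drop=True)
    retained = [c for i, c in enumerate(calls) if i not in drop]
    return retained, region_table


def run_qc(
    calls: Sequence[CnvCall],
    samples: Sequence[SampleRecord],
    config: Optional[QcConfig] = None,
) -> tuple[list[CnvCall], list[SampleRecord], QcReport]:
    """Apply the full QC chain in canonical order and report stage counts."""
    config = config or QcConfig()
    report = QcReport()
    report.record_stage("input", len(calls))

    step = filter_size(list(calls), config.min_size_bp)
    report.record_stage("after_size", len(step))
    log.info("size filter: %d -> %d calls", len(calls), len(step))

    step2 = filter_probes(step, config)
    report.record_stage("after_probes", len(step2))
    log.info("probe filter: %d -> %d calls", len(step), len(step2))

    step3 = filter_blacklist(step2, config.blacklist)
    report.record_stage("after_blacklist", len(step3))
    log.info("blacklist filter: %d -> %d calls", len(step2), len(step3))

    retained_samples, excluded = exclude_outlier_samples(
        step3, samples, config.outlier_sd
    )
    report.excluded_samples = excluded
    kept_ids = {s.sample_id for s in retained_samples}
    step4 = [c for c in step3 if c.sample_id in kept_ids]
    report.record_stage("after_outlier_samples", len(step4))
    log.info("outlier-sample filter: %d -> %d calls (%d samples excluded)",
             len(step3), len(step4), len(excluded))

    step5, region_table = filter_rare(step4, retained_samples, config)
    report.record_stage("after_rarity", len(step5))
    report.region_table = region_table
    log.info("rarity filter: %d -> %d calls", len(step4), len(step5))

    per_cohort: dict[str, dict[str, int]] = {}
    for c in step5:
        d = per_cohort.setdefault(c.cohort, {"GAIN": 0, "LOSS": 0})
        d[c.cnv_type.value] += 1
    report.per_cohort_type_counts = per_cohort
    return step5, retained_samples, report
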