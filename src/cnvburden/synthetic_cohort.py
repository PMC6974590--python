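"""Synthetic multi-cohort CNV datasets with the structure the analysis assumes.

The generator emulates a multi-cohort case-control array-CNV study:
per-cohort sample sizes, sex/age/BMI marginals, per-sample call rates,
a roughly 3:1 gain:loss mix, 100 kb–3 Mb call sizes (log-uniform) and
mostly-singleton calls, over a synthetic genome of uniformly tiled genes
with named gene sets of configurable size and overlap.

A sex-specific carrier-enrichment effect can be injected over a designated
gene set: for samples in the effect stratum an extra set-overlapping call
is added with the probability that raises their *carrier* probability from
the baseline q to p1 = OR·q / (1 − q + OR·q), so the injected odds ratio
is exactly the carrier-based estimand of the burden and regression
analyses.  The baseline q is computed analytically from the genome
geometry and the cohort's Poisson call rate (q = 1 − exp(−rate · p̄),
where p̄ is the mean per-call probability of overlapping a set gene).

Everything is a pure function of the configuration: one seed sequence,
spawned into per-cohort child streams in documented order.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from . import io_formats
from .types import (
    CnvCall,
    CnvType,
    GeneModel,
    GeneSetCollection,
    SampleRecord,
    Sex,
    Status,
)

AGE_BOUNDS = (18.0, 95.0)    # years
BMI_BOUNDS = (15.0, 60.0)    # kg/m^2


@dataclass
class CohortConfig:
    name: str
    n_cases: int
    n_controls: int
    frac_women_cases: float
    frac_women_controls: float
    age_cases: tuple[float, float]      # (mean, sd), years
    age_controls: tuple[float, float]
    bmi_cases: tuple[float, float]      # (mean, sd), kg/m^2
    bmi_controls: tuple[float, float]
    cnv_rate: float                     # Poisson mean calls per sample
    min_probes: int = 50                # platform probe threshold

    def __post_init__(self) -> None:
        for frac in (self.frac_women_cases, self.frac_women_controls):
            if not 0 <= frac <= 1:
                raise ValueError("sex fractions must be in [0, 1]")
        if self.cnv_rate < 0:
            raise ValueError("cnv_rate must be >= 0")

    @property
    def n_total(self) -> int:
        return self.n_cases + self.n_controls


@dataclass
class GenomeConfig:
    n_chromosomes: int = 22
    chromosome_length: int = 130_000_000
    n_genes: int = 4400
    gene_length: int = 50_000
    n_blacklist: int = 20
    blacklist_length: int = 10_000


@dataclass
class EffectConfig:
    target_or: float = 1.0
    set_name: str = "lipid"
    sex: Sex = Sex.MALE
    status: Status = Status.CASE
    baseline_carrier_prob: Optional[float] = None  # analytic when None

    def __post_init__(self) -> None:
        if self.target_or <= 0:
            raise ValueError("target_or must be > 0")


#: Set sizes mirroring the study's gene-set catalogue, scaled to the
#: synthetic gene count (4400 of ~20000, factor 0.22).
DEFAULT_SET_SIZES = {
    "lipid": 343,
    "inflammatory": 134,
    "insulin_response": 64,
    "glucose": 48,
    "gallbladder": 833,
    "liver": 717,
    "small_intestine": 841,
    "random": 1033,
}
DEFAULT_LIPID_SI_OVERLAP = 81


@dataclass
class SimConfig:
    seed: int
    cohorts: list[CohortConfig]
    genome: GenomeConfig = field(default_factory=GenomeConfig)
    set_sizes: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_SET_SIZES))
    lipid_si_overlap: int = DEFAULT_LIPID_SI_OVERLAP
    gain_fraction: float = 0.742
    size_range: tuple[int, int] = (100_001, 3_000_000)
    probe_fail_fraction: float = 0.0
    avoid_blacklist: bool = True
    effect: EffectConfig = field(default_factory=EffectConfig)

    def __post_init__(self) -> None:
        if not 0 <= self.gain_fraction <= 1:
            raise ValueError("gain_fraction must be in [0, 1]")
        lo, hi = self.size_range
        if not 1 <= lo <= hi <= self.genome.chromosome_length:
            raise ValueError("size_range must lie within [1, chromosome length]")
        if not 0 <= self.probe_fail_fraction <= 1:
            raise ValueError("probe_fail_fraction must be in [0, 1]")


@dataclass
class GenomeBundle:
    genes: list[GeneModel]
    collection: GeneSetCollection
    blacklist: list[GeneModel]


@dataclass
class SimBundle:
    config: SimConfig
    genome: GenomeBundle
    samples: list[SampleRecord]
    calls: list[CnvCall]


# ---------------------------------------------------------------------------
# Genome
# ---------------------------------------------------------------------------

def simulate_genome(config: SimConfig) -> GenomeBundle:
    """Tile non-overlapping genes with gaps, sample gene sets, place a
    small blacklist in gene-free gaps.  Deterministic given the seed."""
    g = config.genome
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])
    per_chrom = g.n_genes // g.n_chromosomes
    if per_chrom * g.n_chromosomes != g.n_genes:
        raise ValueError("n_genes must be divisible by n_chromosomes")
    spacing = g.chromosome_length // per_chrom
    if g.gene_length >= spacing:
        raise ValueError(
            f"{g.n_genes} genes of {g.gene_length} bp do not fit "
            f"{g.n_chromosomes} chromosomes of {g.chromosome_length} bp"
        )
    offset = (spacing - g.gene_length) // 2
    genes: list[GeneModel] = []
    k = 0
    for ci in range(g.n_chromosomes):
        chrom = f"chr{ci + 1}"
        for gi in range(per_chrom):
            start = gi * spacing + offset
            genes.append(
                GeneModel(
                    gene_id=f"G{k:05d}", chrom=chrom,
                    start=start, end=start + g.gene_length,
                )
            )
            k += 1

    ids = np.array([gm.gene_id for gm in genes])
    collection = GeneSetCollection()
    sizes = dict(config.set_sizes)
    # lipid and small_intestine share a configured overlap, chosen first
    if "lipid" in sizes and "small_intestine" in sizes and config.lipid_si_overlap:
        ov = config.lipid_si_overlap
        if ov > min(sizes["lipid"], sizes["small_intestine"]):
            raise ValueError("lipid_si_overlap exceeds a base set size")
        shared = rng.choice(ids, size=ov, replace=False)
        rest = np.setdiff1d(ids, shared, assume_unique=False)
        lipid_extra = rng.choice(rest, size=sizes["lipid"] - ov, replace=False)
        rest2 = np.setdiff1d(rest, lipid_extra)
        si_extra = rng.choice(rest2, size=sizes["small_intestine"] - ov, replace=False)
        collection.add("lipid", set(shared) | set(lipid_extra), "synthetic lipid metabolic process")
        collection.add("small_intestine", set(shared) | set(si_extra), "synthetic small-intestine expression")
    for name, size in sizes.items():
        if name in collection:
            continue
        members = rng.choice(ids, size=size, replace=False)
        collection.add(name, set(members), f"synthetic {name}")

    # blacklist: sub-intervals of randomly chosen gene-free gaps
    blacklist: list[GeneModel] = []
    gap_len = spacing - g.gene_length
    if g.blacklist_length >= offset:
        raise ValueError("blacklist_length must fit in the inter-gene gap")
    for bi in range(g.n_blacklist):
        ci = int(rng.integers(g.n_chromosomes))
        gi = int(rng.integers(per_chrom - 1))
        gap_start = gi * spacing + offset + g.gene_length
        pos = gap_start + int(rng.integers(offset - g.blacklist_length))
        blacklist.append(
            GeneModel(
                gene_id=f"BL{bi:03d}", chrom=f"chr{ci + 1}",
                start=pos, end=pos + g.blacklist_length,
            )
        )
    return GenomeBundle(genes=genes, collection=collection, blacklist=blacklist)


# ---------------------------------------------------------------------------
# Carrier probability of the background call process
# ---------------------------------------------------------------------------

def _per_call_hit_probability(
    config: SimConfig, genome: GenomeBundle, members: frozenset[str], n_nodes: int = 96
) -> float:
    """Mean probability that one background call overlaps >= 1 member gene.

    Exact for a given size (integer union arithmetic over start positions),
    integrated over the log-uniform size law by Gauss–Legendre quadrature
    in log-size.
    """
    g = config.genome
    lo, hi = config.size_range
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for gm in genome.genes:
        if gm.gene_id in members:
            by_chrom.setdefault(gm.chrom, []).append((gm.start, gm.end))
    for iv in by_chrom.values():
        iv.sort()
    chroms = [f"chr{i + 1}" for i in range(g.n_chromosomes)]
    L = g.chromosome_length

    def p_of_size(s: int) -> float:
        total = 0.0
        for chrom in chroms:
            n_pos = L - s + 1
            count = 0
            cur_lo, cur_hi = None, None
            for gs, ge in by_chrom.get(chrom, ()):  # hit iff t in [gs-s+1, ge-1]
                a, b = max(0, gs - s + 1), min(L - s, ge - 1)
                if b < a:
                    continue
                if cur_lo is None:
                    cur_lo, cur_hi = a, b
                elif a <= cur_hi + 1:
                    cur_hi = max(cur_hi, b)
                else:
                    count += cur_hi - cur_lo + 1
                    cur_lo, cur_hi = a, b
            if cur_lo is not None:
                count += cur_hi - cur_lo + 1
            total += count / n_pos
        return total / len(chroms)

    if lo == hi:
        return p_of_size(lo)
    nodes, weights = np.polynomial.legendre.leggauss(n_nodes)
    a, b = math.log(lo), math.log(hi)
    u = 0.5 * (b - a) * nodes + 0.5 * (a + b)
    vals = np.array([p_of_size(int(round(math.exp(ui)))) for ui in u])
    return float((weights * vals).sum() * 0.5)


def baseline_carrier_probability(
    config: SimConfig, genome: GenomeBundle, cohort: CohortConfig, set_name: str
) -> float:
    """Analytic carrier probability of the background process for one set:
    1 − exp(−rate · p̄) by Poisson thinning."""
    members = genome.collection[set_name]
    p_bar = _per_call_hit_probability(config, genome, members)
    return 1.0 - math.exp(-cohort.cnv_rate * p_bar)


def injection_probability(target_or: float, baseline_q: float) -> float:
    """Probability of the extra carrier call that lifts the carrier odds by
    *target_or* over baseline *baseline_q*."""
    if target_or == 1.0:
        return 0.0
    if baseline_q <= 0:
        raise ValueError(
            "baseline carrier probability is 0; no finite odds ratio is "
            "injectable (feasible maximum OR = 1)"
        )
    p1 = target_or * baseline_q / (1 - baseline_q + target_or * baseline_q)
    if p1 >= 1:
        feasible = (1 - baseline_q) / baseline_q * 1e15
        raise ValueError(f"target carrier probability >= 1; feasible OR < {feasible:g}")
    return (p1 - baseline_q) / (1 - baseline_q)


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, bounds: tuple[float, float], n: int
) -> np.ndarray:
    lo, hi = bounds
    out = rng.normal(mean, sd, size=n)
    bad = (out < lo) | (out > hi)
    for _ in range(100):
        k = int(bad.sum())
        if not k:
            break
        out[bad] = rng.normal(mean, sd, size=k)
        bad = (out < lo) | (out > hi)
    return np.clip(out, lo, hi)


def _sample_size(rng: np.random.Generator, lo: int, hi: int) -> int:
    if lo == hi:
        return lo
    s = int(round(math.exp(rng.uniform(math.log(lo), math.log(hi)))))
    return min(max(s, lo), hi)


def simulate_cohort(
    config: SimConfig,
    genome: GenomeBundle,
    cohort: CohortConfig,
    rng: np.random.Generator,
) -> tuple[list[SampleRecord], list[CnvCall]]:
    """Draw one cohort's phenotypes and CNV calls.

    Sex counts are assigned deterministically (round(fraction × n) women in
    each case/control group) so group marginals are exact; ages and BMIs
    are truncated normals; per-sample call counts are Poisson.  When the
    effect configuration targets this cohort's stratum, extra carrier calls
    are injected at the analytically derived probability.
    """
    g = config.genome
    L = g.chromosome_length
    smin, smax = config.size_range
    bl_by_chrom: dict[str, list[tuple[int, int]]] = {}
    if config.avoid_blacklist:
        for b in genome.blacklist:
            bl_by_chrom.setdefault(b.chrom, []).append((b.start, b.end))

    def hits_blacklist(chrom: str, start: int, end: int) -> bool:
        return any(start < be and bs < end for bs, be in bl_by_chrom.get(chrom, ()))

    samples: list[SampleRecord] = []
    calls: list[CnvCall] = []

    groups = [
        (Status.CASE, cohort.n_cases, cohort.frac_women_cases,
         cohort.age_cases, cohort.bmi_cases),
        (Status.CONTROL, cohort.n_controls, cohort.frac_women_controls,
         cohort.age_controls, cohort.bmi_controls),
    ]
    idx = 0
    for status, n, frac_w, age_ms, bmi_ms in groups:
        n_women = int(round(frac_w * n))
        sexes = np.array([Sex.FEMALE] * n_women + [Sex.MALE] * (n - n_women))
        rng.shuffle(sexes)
        ages = _truncated_normal(rng, age_ms[0], age_ms[1], AGE_BOUNDS, n)
        bmis = _truncated_normal(rng, bmi_ms[0], bmi_ms[1], BMI_BOUNDS, n)
        for i in range(n):
            samples.append(
                SampleRecord(
                    sample_id=f"{cohort.name}_S{idx:05d}",
                    cohort=cohort.name,
                    status=status,
                    sex=sexes[i],
                    age=round(float(ages[i]), 1),
                    bmi=round(float(bmis[i]), 1),
                )
            )
            idx += 1

    thr = cohort.min_probes

    def draw_probes() -> int:
        if config.probe_fail_fraction > 0 and rng.random() < config.probe_fail_fraction:
            return int(rng.integers(0, thr))
        return int(rng.integers(thr, 4 * thr))

    n_calls = rng.poisson(cohort.cnv_rate, size=len(samples))
    for s, k in zip(samples, n_calls):
        for _ in range(k):
            for _attempt in range(1000):
                chrom = f"chr{int(rng.integers(g.n_chromosomes)) + 1}"
                size = _sample_size(rng, smin, smax)
                start = int(rng.integers(L - size + 1))
                if not hits_blacklist(chrom, start, start + size):
                    break
            calls.append(
                CnvCall(
                    sample_id=s.sample_id,
                    cohort=cohort.name,
                    chrom=chrom,
                    start=start,
                    end=start + size,
                    cnv_type=CnvType.GAIN if rng.random() < config.gain_fraction
                    else CnvType.LOSS,
                    n_probes=draw_probes(),
                    source="sim",
                )
            )

    eff = config.effect
    if eff.target_or != 1.0 and cohort.cnv_rate > 0:
        q = (
            eff.baseline_carrier_prob
            if eff.baseline_carrier_prob is not None
            else baseline_carrier_probability(config, genome, cohort, eff.set_name)
        )
        p_extra = injection_probability(eff.target_or, q)
        members = sorted(genome.collection[eff.set_name])
        gene_by_id = {gm.gene_id: gm for gm in genome.genes}
        targets = [gene_by_id[m] for m in members if m in gene_by_id]
        for s in samples:
            if s.sex is not eff.sex or s.status is not eff.status:
                continue
            if rng.random() >= p_extra:
                continue
            gm = targets[int(rng.integers(len(targets)))]
            size = _sample_size(rng, smin, smax)
            lo_pos = max(0, gm.start - size + 1)
            hi_pos = min(L - size, gm.end - 1)
            start = int(rng.integers(lo_pos, hi_pos + 1))
            calls.append(
                CnvCall(
                    sample_id=s.sample_id,
                    cohort=cohort.name,
                    chrom=gm.chrom,
                    start=start,
                    end=start + size,
                    cnv_type=CnvType.GAIN if rng.random() < config.gain_fraction
                    else CnvType.LOSS,
                    n_probes=int(rng.integers(thr, 4 * thr)),
                    source="sim:effect",
                )
            )
    return samples, calls


def simulate(config: SimConfig) -> SimBundle:
    """Generate the full bundle: genome, gene sets, blacklist, phenotypes
    and calls for every cohort.  A pure function of the configuration."""
    genome = simulate_genome(config)
    children = np.random.SeedSequence(config.seed).spawn(1 + len(config.cohorts))
    samples: list[SampleRecord] = []
    calls: list[CnvCall] = []
    for cohort, ss in zip(config.cohorts, children[1:]):
        rng = np.random.default_rng(ss)
        s, c = simulate_cohort(config, genome, cohort, rng)
        samples.extend(s)
        calls.extend(c)
    return SimBundle(config=config, genome=genome, samples=samples, calls=calls)


# ---------------------------------------------------------------------------
# Fixture bundles on disk
# ---------------------------------------------------------------------------

def write_fixture_bundle(config: SimConfig, outdir) -> dict[str, Path]:
    """Simulate and write calls (TSV + VCF), phenotypes, genes, sets,
    blacklist and the configuration.  Re-running with the same seed
    reproduces identical files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle = simulate(config)
    paths = {
        "calls_tsv": outdir / "calls.tsv",
        "calls_vcf": outdir / "calls.vcf",
        "phenotypes": outdir / "phenotypes.tsv",
        "genes": outdir / "genes.bed",
        "gene_sets": outdir / "gene_sets.gmt",
        "blacklist": outdir / "blacklist.bed",
        "config": outdir / "sim_config.json",
    }
    io_formats.write_cnv_tsv(bundle.calls, paths["calls_tsv"])
    io_formats.write_cnv_vcf(bundle.calls, paths["calls_vcf"])
    io_formats.write_phenotypes(bundle.samples, paths["phenotypes"])
    io_formats.write_bed(bundle.genome.genes, paths["genes"])
    io_formats.write_gmt(bundle.genome.collection, paths["gene_sets"])
    io_formats.write_bed(bundle.genome.blacklist, paths["blacklist"])
    with open(paths["config"], "w") as fh:
        json.dump(config_to_dict(config), fh, indent=2)
        fh.write("\n")
    return paths


def config_to_dict(config: SimConfig) -> dict:
    d = dataclasses.asdict(config)
    d["effect"]["sex"] = config.effect.sex.value
    d["effect"]["status"] = config.effect.status.value
    return d


def config_from_dict(d: dict) -> SimConfig:
    d = json.loads(json.dumps(d))  # deep copy
    cohorts = [
        CohortConfig(**{**c, "age_cases": tuple(c["age_cases"]),
                        "age_controls": tuple(c["age_controls"]),
                        "bmi_cases": tuple(c["bmi_cases"]),
                        "bmi_controls": tuple(c["bmi_controls"])})
        for c in d.pop("cohorts")
    ]
    genome = GenomeConfig(**d.pop("genome"))
    eff = d.pop("effect")
    effect = EffectConfig(
        target_or=eff["target_or"], set_name=eff["set_name"],
        sex=Sex(eff["sex"]), status=Status(eff["status"]),
        baseline_carrier_prob=eff.get("baseline_carrier_prob"),
    )
    d["size_range"] = tuple(d["size_range"])
    return SimConfig(cohorts=cohorts, genome=genome, effect=effect, **d)


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------

def paper_like_config(
    seed: int,
    effect: Optional[EffectConfig] = None,
) -> SimConfig:
    """Three-cohort study preset: sample sizes, sex/age/BMI marginals and
    per-sample call rates of the published cohort table."""
    cohorts = [
        CohortConfig(
            name="POPGEN", n_cases=1052, n_controls=905,
            frac_women_cases=0.615, frac_women_controls=0.422,
            age_cases=(45.7, 12.3), age_controls=(59.3, 12.8),
            bmi_cases=(27.6, 5.3), bmi_controls=(26.5, 4.1),
            cnv_rate=821 / 1957, min_probes=50,
        ),
        CohortConfig(
            name="SHIP-2", n_cases=355, n_controls=1390,
            frac_women_cases=0.645, frac_women_controls=0.491,
            age_cases=(48.4, 9.8), age_controls=(47.8, 12.1),
            bmi_cases=(28.6, 5.0), bmi_controls=(26.7, 4.2),
            cnv_rate=1168 / 1745, min_probes=100,
        ),
        CohortConfig(
            name="ANCORA", n_cases=522, n_controls=554,
            frac_women_cases=0.923, frac_women_controls=0.924,
            age_cases=(51.3, 10.7), age_controls=(49.8, 9.6),
            bmi_cases=(29.4, 4.3), bmi_controls=(28.6, 3.9),
            cnv_rate=947 / 1076, min_probes=50,
        ),
    ]
    return SimConfig(
        seed=seed,
        cohorts=cohorts,
        effect=effect if effect is not None else EffectConfig(),
    )


def tiny_config(seed: int, effect: Optional[EffectConfig] = None) -> SimConfig:
    """Small single-cohort preset for quick end-to-end runs."""
    return SimConfig(
        seed=seed,
        cohorts=[
            CohortConfig(
                name="TOY", n_cases=30, n_controls=30,
                frac_women_cases=0.5, frac_women_controls=0.5,
                age_cases=(50.0, 10.0), age_controls=(50.0, 10.0),
                bmi_cases=(27.0, 4.0), bmi_controls=(27.0, 4.0),
                cnv_rate=1.0, min_probes=50,
            )
        ],
        genome=GenomeConfig(
            n_chromosomes=2, chromosome_length=10_000_000,
            n_genes=40, gene_length=50_000,
            n_blacklist=2, blacklist_length=10_000,
        ),
        set_sizes={
            "lipid": 8, "inflammatory": 4, "insulin_response": 4, "glucose": 4,
            "gallbladder": 12, "liver": 12, "small_intestine": 12, "random": 12,
        },
        lipid_si_overlap=4,
        size_range=(100_001, 1_000_000),
        effect=effect if effect is not None else EffectConfig(),
    )
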