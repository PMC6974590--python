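"""End-to-end orchestration: QC → annotation → burden → GLM grid → candidates.

:func:`run_all` executes the stages in canonical order against files on
disk, writes every result table as TSV plus a markdown report, and returns
a :class:`RunManifest` with input checksums, per-stage row counts and
output paths so reruns on identical inputs are verifiable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from . import __version__, burden, candidate_genes, glm_assoc, io_formats, overlap_annot, qc_filter
from .types import GeneSetCollection

log = logging.getLogger(__name__)


@dataclass
class RunManifest:
    version: str
    seed: Optional[int]
    config: dict
    input_checksums: dict[str, str] = field(default_factory=dict)
    stage_counts: dict[str, int] = field(default_factory=dict)
    outputs: dict[str, str] = field(default_factory=dict)
    output_checksums: dict[str, str] = field(default_factory=dict)
    failed_stage: Optional[str] = None

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _fmt_p(p: float) -> str:
    return f"{p:.2g}"


def run_all(
    calls_path,
    phenotypes_path,
    genes_path,
    gene_sets_path,
    outdir,
    blacklist_path=None,
    alpha: float = 0.05,
    qc_config: Optional[qc_filter.QcConfig] = None,
    seed: Optional[int] = None,
) -> RunManifest:
    """Run the full pipeline on input files and write results under *outdir*."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    inputs = {
        "calls": Path(calls_path),
        "phenotypes": Path(phenotypes_path),
        "genes": Path(genes_path),
        "gene_sets": Path(gene_sets_path),
    }
    if blacklist_path is not None:
        inputs["blacklist"] = Path(blacklist_path)
    manifest = RunManifest(
        version=__version__,
        seed=seed,
        config={"alpha": alpha},
        input_checksums={k: _sha256(p) for k, p in inputs.items()},
    )
    stage = "load"
    try:
        calls = (
            io_formats.read_cnv_vcf(inputs["calls"])
            if inputs["calls"].suffix == ".vcf"
            else io_formats.read_cnv_tsv(inputs["calls"])
        )
        samples = io_formats.read_phenotypes(inputs["phenotypes"])
        genes = io_formats.read_bed(inputs["genes"])
        collection = io_formats.read_gmt(inputs["gene_sets"])
        blacklist = (
            io_formats.read_bed(inputs["blacklist"]) if "blacklist" in inputs else []
        )
        manifest.stage_counts["input_calls"] = len(calls)
        manifest.stage_counts["input_samples"] = len(samples)

        stage = "qc"
        cfg = qc_config or qc_filter.QcConfig()
        if blacklist and not cfg.blacklist:
            cfg.blacklist = blacklist
        qc_calls, qc_samples, report = qc_filter.run_qc(calls, samples, cfg)
        manifest.stage_counts.update(report.stage_counts)
        manifest.stage_counts["qc_samples"] = len(qc_samples)
        report.to_frame().to_csv(outdir / "qc_stages.tsv", sep="\t", index=False)
        if report.region_table is not None:
            report.region_table.to_csv(outdir / "cnv_regions.tsv", sep="\t", index=False)

        stage = "annotate"
        try:
            collection = overlap_annot.derive_compound_sets(collection)
        except ValueError as exc:
            log.warning("compound sets unavailable: %s", exc)
        index = overlap_annot.build_gene_index(genes)
        annotated = overlap_annot.annotate_calls(qc_calls, index, collection)
        manifest.stage_counts["annotated_calls"] = len(annotated)

        stage = "burden"
        base_sets = [
            n for n in collection.names()
            if n not in (overlap_annot.LIPID_AND_SI_SET, overlap_annot.SI_NOT_LIPID_SET)
        ]
        burden_results = burden.run_burden(
            annotated, qc_samples, collection, alpha=alpha, set_names=base_sets
        )
        bframe = burden.burden_frame(burden_results)
        bframe.to_csv(outdir / "burden.tsv", sep="\t", index=False)
        manifest.stage_counts["burden_tests"] = len(burden_results)

        stage = "glm"
        grid = glm_assoc.run_glm_grid(qc_samples, annotated, alpha=alpha)
        gframe = glm_assoc.grid_frame(grid, alpha=alpha)
        gframe.to_csv(outdir / "glm_grid.tsv", sep="\t", index=False)
        manifest.stage_counts["glm_models"] = len(grid)

        stage = "candidates"
        cands, counts = candidate_genes.extract_candidates(
            annotated, qc_samples,
            collection[overlap_annot.LIPID_SET]
            if overlap_annot.LIPID_SET in collection else frozenset(),
            collection[overlap_annot.SI_SET]
            if overlap_annot.SI_SET in collection else frozenset(),
        )
        cframe = candidate_genes.candidate_frame(cands)
        cframe.to_csv(outdir / "candidates.tsv", sep="\t", index=False)
        manifest.stage_counts["candidate_stage_lipid"] = counts.n_lipid
        manifest.stage_counts["candidate_stage_tissue"] = counts.n_lipid_tissue
        manifest.stage_counts["candidate_stage_case_hit"] = counts.n_case_hit
        manifest.stage_counts["candidate_genes"] = counts.n_case_exclusive

        stage = "report"
        _write_report(outdir / "report.md", bframe, gframe, cframe, counts, alpha)
    except Exception as exc:
        manifest.failed_stage = stage
        (outdir / "manifest.json").write_text(manifest.to_json() + "\n")
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    for p in sorted(outdir.iterdir()):
        if p.name == "manifest.json" or p.is_dir():
            continue
        manifest.outputs[p.name] = str(p)
        manifest.output_checksums[p.name] = _sha256(p)
    (outdir / "manifest.json").write_text(manifest.to_json() + "\n")
    return manifest


def _write_report(path: Path, bframe, gframe, cframe, counts, alpha: float) -> None:
    lines = ["# CNV burden analysis report", ""]
    lines.append("## Gene-set burden (per cohort, carrier-based Fisher exact)")
    lines.append("")
    any_type = bframe[bframe["stratum"] == "ANY"]
    if not any_type.empty:
        adj = any_type["alpha_adjusted"].iloc[0]
        lines.append(
            f"Bonferroni-adjusted threshold: {burden.format_alpha(adj)} "
            f"(alpha = {alpha:g} over {round(alpha / adj)} hypotheses per cohort)"
        )
        lines.append("")
        lines.append("| cohort | set | carriers (case/control) | OR | 95% CI | p | sig |")
        lines.append("|---|---|---|---|---|---|---|")
        for _, r in any_type.iterrows():
            lines.append(
                f"| {r['cohort']} | {r['set']} | {r['case_carriers']}/{r['control_carriers']} "
                f"| {r['or']:.2f} | {r['ci_low']:.2f}–{r['ci_high']:.2f} "
                f"| {_fmt_p(r['p'])} | {'*' if r['significant'] else ''} |"
            )
    lines.append("")
    lines.append("## Covariate-adjusted association grid (15 binomial GLMs)")
    lines.append("")
    if not gframe.empty:
        lines.append(
            f"Bonferroni-adjusted threshold: {burden.format_alpha(gframe['alpha_adjusted'].iloc[0])}"
        )
        lines.append("")
        lines.append("| stratum | predictor set | OR | 95% CI | p | sig |")
        lines.append("|---|---|---|---|---|---|")
        for _, r in gframe.iterrows():
            lines.append(
                f"| {r['stratum']} | {r['predictor_set']} | {r['or']:.2f} "
                f"| {r['ci_low']:.2f}–{r['ci_high']:.2f} | {_fmt_p(r['p'])} "
                f"| {'*' if r['significant'] else ''} |"
            )
    lines.append("")
    lines.append("## Candidate genes")
    lines.append("")
    lines.append(
        f"Filter chain: {counts.n_lipid} lipid-set genes → "
        f"{counts.n_lipid_tissue} tissue-expressed → {counts.n_case_hit} hit in "
        f"≥1 case → {counts.n_case_exclusive} case-exclusive candidates"
    )
    lines.append("")
    if not cframe.empty:
        lines.append("| gene(s) | cases | controls | sex | locus | type | cohort |")
        lines.append("|---|---|---|---|---|---|---|")
        for _, r in cframe.iterrows():
            lines.append(
                f"| {r['gene_id']} | {r['n_gsd_cases']} | {r['n_controls']} "
                f"| {r['case_sex']} | {r['chrom']}:{r['cnv_start']:,}–{r['cnv_end']:,} "
                f"| {r['type']} | {r['cohort']} |"
            )
    path.write_text("\n".join(lines) + "\n")
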