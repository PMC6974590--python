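"""Readers and writers for every external format the pipeline touches.

Internal convention is 0-based half-open coordinates everywhere; each
reader converts from its format's native convention on the way in and each
writer restores it on the way out:

* CNV call TSV — 1-based inclusive coordinates (the convention used for
  printed candidate tables), header-declared columns.
* VCF 4.2 — symbolic ``<DUP>``/``<DEL>`` ALTs with ``INFO/END``; 1-based POS.
* BED — natively 0-based half-open (genes and blacklist regions).
* GMT — tab-delimited gene sets (name, description, members).
* Phenotype TSV — header-declared columns, enum fields parsed
  case-insensitively.

Every writer produces files its own reader accepts and round-trips
losslessly at the level of parsed records.
"""

from __future__ import annotations

import csv
import logging
from pathlib import Path
from typing import Iterable, Sequence, Union

import pysam

from .types import (
    CnvCall,
    CnvType,
    GeneModel,
    GeneSetCollection,
    SampleRecord,
    Sex,
    Status,
    T2d,
    normalize_chrom,
)

log = logging.getLogger(__name__)

PathLike = Union[str, Path]


class FormatError(ValueError):
    """A file does not conform to its declared dialect."""


TSV_CALL_COLUMNS = ["sample", "cohort", "chrom", "start", "end", "type", "n_probes"]


# ---------------------------------------------------------------------------
# CNV call TSV (1-based inclusive coordinates)
# ---------------------------------------------------------------------------

def read_cnv_tsv(path: PathLike) -> list[CnvCall]:
    """Read per-sample CNV calls from a header-declared TSV.

    The dialect is 1-based inclusive, so a row ``start end`` becomes the
    half-open interval ``[start-1, end)``.
    """
    path = Path(path)
    calls: list[CnvCall] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise FormatError(f"{path}: empty file, expected a header line")
        header = [h.strip().lower() for h in header]
        for col in TSV_CALL_COLUMNS:
            if col not in header:
                raise FormatError(f"{path}: missing required column {col!r}")
        idx = {col: header.index(col) for col in TSV_CALL_COLUMNS}
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not f.strip() for f in row):
                continue
            try:
                start1 = int(row[idx["start"]])
                end1 = int(row[idx["end"]])
            except (ValueError, IndexError) as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinate") from exc
            try:
                cnv_type = CnvType.parse(row[idx["type"]])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            try:
                n_probes = int(row[idx["n_probes"]])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer probe count") from exc
            try:
                calls.append(
                    CnvCall(
                        sample_id=row[idx["sample"]].strip(),
                        cohort=row[idx["cohort"]].strip(),
                        chrom=normalize_chrom(row[idx["chrom"]]),
                        start=start1 - 1,
                        end=end1,
                        cnv_type=cnv_type,
                        n_probes=n_probes,
                        source=str(path),
                    )
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return calls


def write_cnv_tsv(calls: Iterable[CnvCall], path: PathLike) -> None:
    """Write calls in the 1-based inclusive TSV dialect read_cnv_tsv accepts."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(TSV_CALL_COLUMNS)
        for c in calls:
            writer.writerow(
                [c.sample_id, c.cohort, c.chrom, c.start + 1, c.end,
                 c.cnv_type.value, c.n_probes]
            )


# ---------------------------------------------------------------------------
# VCF with symbolic SV ALTs
# ---------------------------------------------------------------------------

def read_cnv_vcf(
    path: PathLike,
    probes_key: str = "PROBES",
    default_cohort: str = "",
) -> list[CnvCall]:
    """Read symbolic ``<DUP>``/``<DEL>`` records into CnvCalls.

    DUP maps to GAIN and DEL to LOSS; POS (1-based) becomes the 0-based
    start and ``INFO/END`` the exclusive end.  The sample identifier is
    taken from the ``SAMPLE`` INFO key when present, else from the single
    genotype column.  Probe counts come from *probes_key* and default to 0
    when absent, so that downstream probe filters fail closed.
    """
    path = Path(path)
    calls: list[CnvCall] = []

    def info_get(rec, key, default=None):
        # pysam raises for INFO keys absent from the header
        try:
            return rec.info.get(key, default)
        except (KeyError, ValueError):
            return default

    with pysam.VariantFile(str(path)) as vcf:
        sample_cols = list(vcf.header.samples)
        for i, rec in enumerate(vcf.fetch() if vcf.index is not None else vcf):
            alts = rec.alts or ()
            if len(alts) != 1 or alts[0] not in ("<DUP>", "<DEL>"):
                log.warning("%s: record %d ALT=%s is not <DUP>/<DEL>, skipped",
                            path, i + 1, ",".join(alts) or ".")
                continue
            # pysam parses INFO/END into rec.stop (0-based exclusive) and
            # removes it from rec.info; without an END, stop defaults to
            # start + len(REF), which can never hold for a symbolic CNV.
            rlen = len(rec.ref) if rec.ref else 1
            if rec.stop is None or rec.stop <= rec.start + rlen:
                raise FormatError(
                    f"{path}: record {i + 1} ({rec.chrom}:{rec.pos}) lacks INFO/END"
                )
            sample_id = info_get(rec, "SAMPLE")
            if sample_id is None:
                if len(sample_cols) == 1:
                    sample_id = sample_cols[0]
                else:
                    raise FormatError(
                        f"{path}: record {i + 1} has no SAMPLE INFO key and the "
                        "file does not have exactly one sample column"
                    )
            cohort = info_get(rec, "COHORT", default_cohort)
            n_probes = info_get(rec, probes_key, 0)
            calls.append(
                CnvCall(
                    sample_id=str(sample_id),
                    cohort=str(cohort),
                    chrom=normalize_chrom(rec.chrom),
                    start=rec.pos - 1,
                    end=int(rec.stop),
                    cnv_type=CnvType.GAIN if alts[0] == "<DUP>" else CnvType.LOSS,
                    n_probes=int(n_probes),
                    source=str(path),
                )
            )
    return calls


_VCF_HEADER = """\
##fileformat=VCFv4.2
##ALT=<ID=DUP,Description="Copy number gain">
##ALT=<ID=DEL,Description="Copy number loss">
##INFO=<ID=END,Number=1,Type=Integer,Description="End position of the variant">
##INFO=<ID=SVTYPE,Number=1,Type=String,Description="Type of structural variant">
##INFO=<ID=SAMPLE,Number=1,Type=String,Description="Carrier sample identifier">
##INFO=<ID=COHORT,Number=1,Type=String,Description="Cohort of the carrier sample">
##INFO=<ID=PROBES,Number=1,Type=Integer,Description="Number of array probes supporting the call">
"""


def write_cnv_vcf(calls: Sequence[CnvCall], path: PathLike) -> None:
    """Write calls as a sites-only VCF 4.2 with symbolic SV ALTs."""
    contigs = sorted({c.chrom for c in calls})
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        for contig in contigs:
            fh.write(f"##contig=<ID={contig}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for c in calls:
            alt = "<DUP>" if c.cnv_type is CnvType.GAIN else "<DEL>"
            svtype = "DUP" if c.cnv_type is CnvType.GAIN else "DEL"
            info = (
                f"END={c.end};SVTYPE={svtype};SAMPLE={c.sample_id};"
                f"COHORT={c.cohort};PROBES={c.n_probes}"
            )
            fh.write(
                f"{c.chrom}\t{c.start + 1}\t.\tN\t{alt}\t.\t.\t{info}\n"
            )


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------

def read_gmt(path: PathLike) -> GeneSetCollection:
    """Read a GMT file: per line a set name, a description, then members."""
    path = Path(path)
    coll = GeneSetCollection()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line needs name, description and "
                    f"at least one member (got {len(fields)} fields)"
                )
            name, desc = fields[0].strip(), fields[1].strip()
            members = [g.strip() for g in fields[2:] if g.strip()]
            if not members:
                raise FormatError(f"{path}:{lineno}: gene set {name!r} is empty")
            if name in coll:
                raise FormatError(f"{path}:{lineno}: duplicate set name {name!r}")
            coll.add(name, members, provenance=desc)
    return coll


def write_gmt(collection: GeneSetCollection, path: PathLike) -> None:
    with open(path, "w") as fh:
        for name in collection.names():
            members = sorted(collection[name])
            desc = collection.provenance.get(name, "")
            fh.write("\t".join([name, desc, *members]) + "\n")


# ---------------------------------------------------------------------------
# Phenotype TSV
# ---------------------------------------------------------------------------

PHENO_COLUMNS = ["sample", "cohort", "status", "sex", "age", "bmi"]


def read_phenotypes(path: PathLike) -> list[SampleRecord]:
    """Read the sample phenotype table (TSV with a header).

    Enum fields are case-insensitive; an optional ``t2d`` column maps
    unrecognised tokens to UNKNOWN.  Duplicate sample ids within a cohort
    are rejected.
    """
    path = Path(path)
    records: list[SampleRecord] = []
    seen: set[tuple[str, str]] = set()
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = [h.strip().lower() for h in next(reader)]
        except StopIteration:
            raise FormatError(f"{path}: empty file, expected a header line")
        for col in PHENO_COLUMNS:
            if col not in header:
                raise FormatError(f"{path}: missing required column {col!r}")
        idx = {col: header.index(col) for col in PHENO_COLUMNS}
        t2d_idx = header.index("t2d") if "t2d" in header else None
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not f.strip() for f in row):
                continue
            sample = row[idx["sample"]].strip()
            cohort = row[idx["cohort"]].strip()
            key = (cohort, sample)
            if key in seen:
                raise FormatError(
                    f"{path}:{lineno}: duplicate sample {sample!r} in cohort {cohort!r}"
                )
            seen.add(key)
            status_tok = row[idx["status"]].strip().upper()
            if status_tok not in Status.__members__:
                raise FormatError(f"{path}:{lineno}: unknown status {status_tok!r}")
            sex_tok = row[idx["sex"]].strip().upper()
            if sex_tok not in Sex.__members__:
                raise FormatError(f"{path}:{lineno}: unknown sex {sex_tok!r}")
            t2d = T2d.UNKNOWN
            if t2d_idx is not None and t2d_idx < len(row):
                tok = row[t2d_idx].strip().upper()
                t2d = T2d.__members__.get(tok, T2d.UNKNOWN)
            try:
                records.append(
                    SampleRecord(
                        sample_id=sample,
                        cohort=cohort,
                        status=Status[status_tok],
                        sex=Sex[sex_tok],
                        age=float(row[idx["age"]]),
                        bmi=float(row[idx["bmi"]]),
                        t2d=t2d,
                    )
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return records


def write_phenotypes(records: Iterable[SampleRecord], path: PathLike) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(PHENO_COLUMNS + ["t2d"])
        for r in records:
            writer.writerow(
                [r.sample_id, r.cohort, r.status.value, r.sex.value,
                 repr(r.age), repr(r.bmi), r.t2d.value]
            )


# ---------------------------------------------------------------------------
# BED (genes and blacklist)
# ---------------------------------------------------------------------------

def read_bed(path: PathLike) -> list[GeneModel]:
    """Read a BED file (0-based half-open) into GeneModels.

    A 4th column supplies the gene/region id; 3-column BEDs (e.g. a
    blacklist) get synthetic ``region_<n>`` ids.
    """
    path = Path(path)
    models: list[GeneModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: BED line needs >= 3 fields")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinate") from exc
            name = fields[3].strip() if len(fields) >= 4 and fields[3].strip() else f"region_{lineno}"
            try:
                models.append(
                    GeneModel(gene_id=name, chrom=normalize_chrom(fields[0]),
                              start=start, end=end)
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return models


def write_bed(models: Iterable[GeneModel], path: PathLike) -> None:
    with open(path, "w") as fh:
        for m in models:
            fh.write(f"{m.chrom}\t{m.start}\t{m.end}\t{m.gene_id}\n")
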