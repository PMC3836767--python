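"""Standard-format I/O: FASTQ, FASTA, SAM, VCF, BED, panel TSV, model JSON.

Coordinates are 1-based inclusive internally (matching the cDNA/genomic
interval convention of the amplicon definitions); conversion to 0-based
half-open happens only at the SAM/VCF/BED boundaries.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .amplicon import (
    AmpliconReference,
    IndexedRead,
    ReadAlignment,
    reference_map,
)
from .calling import SampleReport, TemporalSeries
from .error_model import ErrorModel, ErrorPanelMatrix

__all__ = [
    "read_fastq",
    "write_fastq",
    "write_reference_fasta",
    "read_panel_tsv",
    "write_panel_tsv",
    "write_models_json",
    "read_models_json",
    "models_version",
    "write_sam",
    "import_sam",
    "write_vcf",
    "write_bed",
    "write_report_tsv",
    "write_report_json",
    "write_temporal_json",
    "read_index_table",
]

GRCH37_CHR7 = ("chr7", 159_138_663)


# --------------------------------------------------------------------- FASTQ
def read_fastq(path: str | Path) -> list[IndexedRead]:
    return [
        IndexedRead(
            read_id=rec.id,
            bases=str(rec.seq),
            quality="".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"]),
        )
        for rec in SeqIO.parse(str(path), "fastq")
    ]


def write_fastq(reads: Iterable[IndexedRead], path: str | Path) -> None:
    records = []
    for r in reads:
        rec = SeqRecord(Seq(r.bases), id=r.read_id, description="")
        qual = r.quality if r.quality is not None else "I" * len(r.bases)
        rec.letter_annotations["phred_quality"] = [ord(c) - 33 for c in qual]
        records.append(rec)
    SeqIO.write(records, str(path), "fastq")


def write_reference_fasta(
    references: Sequence[AmpliconReference], path: str | Path
) -> None:
    records = [
        SeqRecord(
            Seq(r.sequence),
            id=r.amplicon_id,
            description=f"EGFR exon {r.exon} synthetic amplicon cDNA:{r.cdna_start}-{r.cdna_end}",
        )
        for r in references
    ]
    SeqIO.write(records, str(path), "fasta")


# ----------------------------------------------------------------- panel TSV
def read_panel_tsv(
    path: str | Path, excluded: Iterable[str] = ()
) -> ErrorPanelMatrix:
    """Panel TSV with columns amplicon, position, ref, alt, sample, count,
    depth; one row per (type, sample) cell."""
    table = pd.read_csv(path, sep="\t", dtype={"ref": str, "alt": str})
    try:
        return ErrorPanelMatrix.from_long(table, excluded=excluded)
    except ValueError as exc:
        raise ValueError(f"malformed panel TSV {path}: {exc}") from exc


def write_panel_tsv(panel: ErrorPanelMatrix, path: str | Path) -> None:
    panel.to_long().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------- models JSON
def write_models_json(
    models: Mapping[str, ErrorModel],
    path: str | Path,
    category_counts: Mapping[str, int] | None = None,
) -> None:
    payload = {
        "models": {label: m.to_dict() for label, m in models.items()},
    }
    if category_counts is not None:
        payload["category_counts"] = dict(category_counts)
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def read_models_json(path: str | Path) -> dict[str, ErrorModel]:
    payload = json.loads(Path(path).read_text())
    return {label: ErrorModel.from_dict(d) for label, d in payload["models"].items()}


def models_version(path: str | Path) -> str:
    """Short content hash used as the model version in reports/logs."""
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:12]


# ----------------------------------------------------------------------- SAM
_CIGAR_CODE = {"M": 0, "I": 1, "D": 2}
_CODE_CIGAR = {0: "M", 1: "I", 2: "D", 7: "M", 8: "M"}


def _sam_header(references: Sequence[AmpliconReference]) -> pysam.AlignmentHeader:
    return pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unknown"},
            "SQ": [
                {"SN": r.amplicon_id, "LN": len(r.sequence)} for r in references
            ],
        }
    )


def write_sam(
    alignments: Iterable[ReadAlignment],
    path: str | Path,
    references: Sequence[AmpliconReference] | None = None,
) -> None:
    refs = list(reference_map(references).values())
    header = _sam_header(refs)
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for aln in alignments:
            seg = pysam.AlignedSegment(header)
            seg.query_name = aln.read_id
            seg.query_sequence = aln.read_bases
            seg.flag = 16 if aln.reverse else 0
            seg.reference_id = header.get_tid(aln.reference_id)
            if seg.reference_id < 0:
                raise ValueError(f"unknown reference {aln.reference_id!r}")
            seg.reference_start = aln.ref_start  # pysam is 0-based
            seg.mapping_quality = 60
            seg.cigartuples = [(_CIGAR_CODE[op], n) for op, n in aln.operations]
            seg.set_tag("AS", int(aln.score))
            out.write(seg)


def import_sam(
    path: str | Path, references: Sequence[AmpliconReference] | None = None
) -> list[ReadAlignment]:
    """Read pre-aligned records into the internal alignment form.

    Records must reference known amplicons; CIGAR operations other than
    M/=/X/I/D are rejected (the glocal contract has no clipping).
    """
    known = reference_map(references)
    out: list[ReadAlignment] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for seg in sam:
            if seg.is_unmapped:
                continue
            ref_name = seg.reference_name
            if ref_name not in known:
                raise ValueError(f"SAM record references unknown amplicon {ref_name!r}")
            ops = []
            for code, n in seg.cigartuples or ():
                if code not in _CODE_CIGAR:
                    raise ValueError(
                        f"unsupported CIGAR operation code {code} in read {seg.query_name}"
                    )
                op = _CODE_CIGAR[code]
                if ops and ops[-1][0] == op:
                    ops[-1] = (op, ops[-1][1] + n)
                else:
                    ops.append((op, n))
            out.append(
                ReadAlignment(
                    read_id=seg.query_name,
                    reference_id=ref_name,
                    ref_start=seg.reference_start,
                    operations=tuple(ops),
                    read_bases=seg.query_sequence or "",
                    score=float(seg.get_tag("AS")) if seg.has_tag("AS") else 0.0,
                    reverse=seg.is_reverse,
                )
            )
    return out


# ----------------------------------------------------------------------- VCF
def _vcf_header(sample_id: str) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    header.add_line(f"##contig=<ID={GRCH37_CHR7[0]},length={GRCH37_CHR7[1]},assembly=GRCh37>")
    header.add_line('##INFO=<ID=EP100K,Number=1,Type=Float,Description="Events per 100,000 reads">')
    header.add_line('##INFO=<ID=THR,Number=1,Type=Integer,Description="Calling threshold per 100,000 reads">')
    header.add_line('##INFO=<ID=TAILP,Number=1,Type=Float,Description="Upper-tail probability P(X>=observed)">')
    header.add_line('##INFO=<ID=FRAC,Number=1,Type=Float,Description="Mutant fraction, percent">')
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    header.add_sample(sample_id)
    return header


def write_vcf(
    report: SampleReport,
    path: str | Path,
    references: Sequence[AmpliconReference] | None = None,
) -> None:
    """Called substitutions and deletions on GRCh37 chr7 coordinates.

    Deletion records use a one-base left anchor before the printed genomic
    interval, per VCF convention.
    """
    from .amplicon import deletion_templates

    refs = reference_map(references)
    templates = {t.template_id: t for t in deletion_templates(refs.get("exon19"))}
    header = _vcf_header(report.sample_id)
    calls = list(report.called_mutations.values()) + [
        c for c in report.scan_calls if c.called
    ]
    records = []
    for call in calls:
        if call.kind == "substitution" and call.sub_type is not None:
            st = call.sub_type
            ref_amp = refs[st.amplicon_id]
            pos = ref_amp.genomic_of(st.position)  # 1-based
            ref_allele, alt_allele = st.ref_base, st.alt_base
        elif call.kind == "deletion" and call.chosen_template is not None:
            tpl = templates[call.chosen_template]
            ref_amp = refs["exon19"]
            lo, hi = tpl.cdna_interval
            anchor_cdna = lo - 1
            pos = ref_amp.genomic_of(anchor_cdna)
            deleted = ref_amp.sequence[
                ref_amp.index_of(lo) : ref_amp.index_of(hi) + 1
            ]
            ref_allele = ref_amp.base_at(anchor_cdna) + deleted
            alt_allele = ref_amp.base_at(anchor_cdna)
        else:
            continue
        records.append((pos, ref_allele, alt_allele, call))
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for pos, ref_allele, alt_allele, call in sorted(records, key=lambda r: r[0]):
            rec = vcf.new_record(
                contig=GRCH37_CHR7[0],
                start=pos - 1,  # pysam is 0-based
                alleles=(ref_allele, alt_allele),
            )
            rec.id = call.locus
            rec.info["EP100K"] = float(call.events_per_100k)
            rec.info["THR"] = int(call.threshold)
            rec.info["TAILP"] = float(call.tail_prob)
            rec.info["FRAC"] = float(call.fraction_percent)
            rec.samples[report.sample_id]["GT"] = (0, 1)
            vcf.write(rec)


# ----------------------------------------------------------------------- BED
def write_bed(
    path: str | Path, references: Sequence[AmpliconReference] | None = None
) -> None:
    """Target windows as GRCh37 chr7 BED intervals (0-based half-open)."""
    refs = reference_map(references).values()
    lines = []
    for r in sorted(refs, key=lambda r: r.genomic_of(r.window[0])):
        start = r.genomic_of(r.window[0]) - 1
        end = r.genomic_of(r.window[1])
        lines.append(f"{GRCH37_CHR7[0]}\t{start}\t{end}\t{r.amplicon_id}_window")
    Path(path).write_text("\n".join(lines) + "\n")


# -------------------------------------------------------------------- reports
def write_report_tsv(report: SampleReport, path: str | Path) -> None:
    rows = [c.to_dict() | {"sample": report.sample_id} for c in report.calls.values()]
    rows += [
        c.to_dict() | {"sample": report.sample_id, "locus": f"scan:{c.locus}"}
        for c in report.scan_calls
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_report_json(report: SampleReport, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report.to_dict(), indent=1))


def write_temporal_json(series: TemporalSeries, path: str | Path) -> None:
    Path(path).write_text(json.dumps(series.to_dict(), indent=1))


# ---------------------------------------------------------------- index table
def read_index_table(path: str | Path) -> dict[str, str]:
    """Two-column TSV: 5-nt index, sample name.  Duplicate indexes are a
    configuration error."""
    table: dict[str, str] = {}
    for i, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValueError(f"{path}:{i}: expected 'index<TAB>sample'")
        idx, sample = parts[0].strip(), parts[1].strip()
        if idx in table:
            raise ValueError(f"{path}:{i}: duplicate index {idx!r}")
        table[idx] = sample
    return table
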