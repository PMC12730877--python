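"""Reading CDS sets, extracting spliced CDS from genome+GFF3, and quality filtering.

The quality filter applies four independent criteria to each spliced coding
sequence: minimum length (default 100 bp), no partial codons (length divisible
by 3), no internal stop codons, and presence of both a start (ATG) and a
terminal stop codon.  A fifth rule rejects sequences containing non-ACGT
characters (ambiguity codes) after U->T normalisation.  Rules are evaluated
independently so the report attributes every failure correctly; a record
failing several rules is tallied once per rule but once overall.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO

from .genetic_code import START_CODON, STOP_CODONS, reverse_complement

logger = logging.getLogger(__name__)

QC_RULES = (
    "min_length",
    "partial_codon",
    "internal_stop",
    "missing_start",
    "missing_stop",
    "non_acgt",
)

_ACGT = frozenset("ACGT")


@dataclass(frozen=True)
class GeneRecord:
    """One coding sequence (stop codon retained in ``sequence``)."""

    gene_id: str
    genome_id: str
    sequence: str
    source: str = "cds_fasta"  # or "gff_extracted"


@dataclass
class QcReport:
    genome_id: str
    n_input: int = 0
    n_passed: int = 0
    n_failed_by_rule: dict[str, int] = field(
        default_factory=lambda: {rule: 0 for rule in QC_RULES}
    )

    @property
    def n_failed(self) -> int:
        return self.n_input - self.n_passed


def _normalize(seq: str) -> str:
    """Uppercase and map RNA U to DNA T."""
    return str(seq).upper().replace("U", "T")


def read_cds_fasta(path: str | Path, genome_id: str | None = None) -> list[GeneRecord]:
    """Read a (possibly wrapped) multi-FASTA of coding sequences.

    IDs are the first whitespace-delimited token of each header; ``genome_id``
    defaults to the file stem.
    """
    path = Path(path)
    if genome_id is None:
        genome_id = path.stem
    records = [
        GeneRecord(rec.id, genome_id, _normalize(rec.seq), source="cds_fasta")
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        logger.warning("no FASTA records found in %s", path)
    return records


def write_cds_fasta(records: Iterable[GeneRecord], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.gene_id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


def _parse_gff_attributes(attr_field: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for part in attr_field.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        if "=" in part:
            key, _, value = part.partition("=")
            attrs[key.strip()] = value.strip()
    return attrs


def _segment_parent(attrs: dict[str, str]) -> str | None:
    # resolution order covers the common annotation flavours
    for key in ("Parent", "transcript_id", "ID"):
        if key in attrs:
            return attrs[key]
    return None


def extract_cds_from_gff(
    genome_fasta: str | Path,
    gff: str | Path,
    genome_id: str | None = None,
) -> list[GeneRecord]:
    """Extract spliced CDS from a genome FASTA plus a GFF3 annotation.

    Only ``CDS`` features are consulted; segments sharing a parent are
    concatenated in genomic order (reverse order with reverse-complementation
    on the minus strand).  The GFF ``phase`` of the first segment in
    transcription order is applied as a leading trim.  GFF3 coordinates are
    1-based inclusive.
    """
    genome_fasta = Path(genome_fasta)
    if genome_id is None:
        genome_id = genome_fasta.stem
    contigs = {
        rec.id: _normalize(rec.seq) for rec in SeqIO.parse(str(genome_fasta), "fasta")
    }

    # parent -> list of (contig, start, end, strand, phase)
    segments: dict[str, list[tuple[str, int, int, str, int]]] = {}
    order: list[str] = []
    with open(gff) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9 or fields[2] != "CDS":
                continue
            contig, _, _, start, end, _, strand, phase, attrs = fields[:9]
            parent = _segment_parent(_parse_gff_attributes(attrs))
            if parent is None:
                logger.warning("CDS feature without Parent/transcript_id/ID skipped")
                continue
            if parent not in segments:
                segments[parent] = []
                order.append(parent)
            phase_int = int(phase) if phase in ("0", "1", "2") else 0
            segments[parent].append((contig, int(start), int(end), strand, phase_int))

    records: list[GeneRecord] = []
    for parent in order:
        segs = sorted(segments[parent], key=lambda s: s[1])
        strands = {s[3] for s in segs}
        if len(strands) != 1:
            logger.warning("transcript %s has mixed strands; skipped", parent)
            continue
        strand = strands.pop()
        for contig, start, end, *_ in segs:
            if contig not in contigs:
                raise ValueError(
                    f"CDS feature of {parent} references missing contig {contig!r}"
                )
        if strand == "-":
            segs = segs[::-1]
            seq = "".join(
                reverse_complement(contigs[c][start - 1 : end]) for c, start, end, *_ in segs
            )
        else:
            seq = "".join(contigs[c][start - 1 : end] for c, start, end, *_ in segs)
        seq = seq[segs[0][4] :]  # phase of first segment in transcription order
        records.append(GeneRecord(parent, genome_id, seq, source="gff_extracted"))
    return records


def failing_rules(sequence: str, min_len_bp: int = 100) -> list[str]:
    """Return the QC rules violated by one (normalised) CDS."""
    failures: list[str] = []
    n = len(sequence)
    if n < min_len_bp:
        failures.append("min_length")
    if n % 3 != 0:
        failures.append("partial_codon")
    n_codons = n // 3
    codons = [sequence[3 * i : 3 * i + 3] for i in range(n_codons)]
    if any(c in STOP_CODONS for c in codons[:-1]):
        failures.append("internal_stop")
    if not codons or codons[0] != START_CODON:
        failures.append("missing_start")
    if not codons or codons[-1] not in STOP_CODONS:
        failures.append("missing_stop")
    if not _ACGT.issuperset(sequence):
        failures.append("non_acgt")
    return failures


def qc_filter(
    genes: list[GeneRecord],
    min_len_bp: int = 100,
    genome_id: str | None = None,
) -> tuple[list[GeneRecord], QcReport]:
    """Apply the four CDS quality criteria (plus the non-ACGT rule).

    A gene passes iff it is >= ``min_len_bp`` long, has no partial codon, no
    internal stop, starts with ATG, ends with a stop codon, and is pure ACGT.
    """
    if genome_id is None:
        genome_id = genes[0].genome_id if genes else ""
    report = QcReport(genome_id=genome_id, n_input=len(genes))
    passed: list[GeneRecord] = []
    for gene in genes:
        failures = failing_rules(gene.sequence, min_len_bp=min_len_bp)
        if failures:
            for rule in failures:
                report.n_failed_by_rule[rule] += 1
        else:
            passed.append(gene)
    report.n_passed = len(passed)
    logger.info(
        "%s: %d/%d CDS passed QC", genome_id, report.n_passed, report.n_input
    )
    return passed, report


def qc_report_table(reports: Iterable[QcReport]) -> pd.DataFrame:
    """Long-format QC table: genome_id, rule, count (plus input/passed rows)."""
    rows = []
    for rep in reports:
        rows.append({"genome_id": rep.genome_id, "rule": "input", "count": rep.n_input})
        rows.append({"genome_id": rep.genome_id, "rule": "passed", "count": rep.n_passed})
        for rule in QC_RULES:
            rows.append(
                {"genome_id": rep.genome_id, "rule": rule, "count": rep.n_failed_by_rule[rule]}
            )
    return pd.DataFrame(rows, columns=["genome_id", "rule", "count"])
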