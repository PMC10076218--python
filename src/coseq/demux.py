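"""Demultiplexing of cobarcoded paired reads.

Read 1 carries the genomic (or cDNA) sequence; read 2 carries the spatial
address as fixed-offset segments: barcode B, ligation linker 2, barcode A,
ligation linker 1 and — for the RNA library — a UMI. Demultiplexing
validates both linkers by Hamming distance, error-corrects each barcode
against its whitelist, and emits either a reformatted read pair whose
synthetic 16-base cell barcode (A 8-mer + B 8-mer) is consumable by
10x-style ATAC tooling, or an RNA triple (genomic read, pixel id, UMI).

Parsing is fixed-offset by design: the ligation chemistry produces
constant segment positions, so no indel scanning is attempted.
"""

from __future__ import annotations

import gzip
import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional

import pysam

from .schema import BarcodeSchema, PixelGrid, pixel_id

__all__ = [
    "FastqRead",
    "ReadAssignment",
    "DemuxReport",
    "BarcodeCorrector",
    "match_linker",
    "correct_barcode",
    "demux_atac_pair",
    "demux_rna_pair",
    "demux_pairs",
    "demux_fastq",
    "read_fastq_pairs",
]

STATUS_ASSIGNED = "assigned"
STATUS_LINKER_FAIL = "linker_fail"
STATUS_BARCODE_FAIL = "barcode_fail"
STATUS_AMBIGUOUS = "ambiguous"
STATUSES = (STATUS_ASSIGNED, STATUS_LINKER_FAIL, STATUS_BARCODE_FAIL, STATUS_AMBIGUOUS)


@dataclass(frozen=True)
class FastqRead:
    name: str
    sequence: str
    quality: str = ""


@dataclass(frozen=True)
class ReadAssignment:
    """Outcome of demultiplexing a single read pair."""

    read_id: str
    status: str
    a_index: Optional[int] = None
    b_index: Optional[int] = None
    umi: str = ""
    a_corrected: bool = False
    b_corrected: bool = False
    linker_mismatches: tuple[int, int] = (0, 0)

    @property
    def pixel(self) -> Optional[str]:
        if self.status != STATUS_ASSIGNED:
            return None
        return pixel_id(self.a_index, self.b_index)


@dataclass
class DemuxReport:
    """Aggregate demultiplexing statistics.

    Invariant: the status counts sum to the number of input read pairs.
    """

    status_counts: Counter = field(default_factory=Counter)
    pixel_counts: Counter = field(default_factory=Counter)
    linker_mismatch_hist: Counter = field(default_factory=Counter)

    @property
    def total(self) -> int:
        return sum(self.status_counts.values())

    def record(self, assignment: ReadAssignment) -> None:
        self.status_counts[assignment.status] += 1
        if assignment.status == STATUS_ASSIGNED:
            self.pixel_counts[assignment.pixel] += 1
            self.linker_mismatch_hist[assignment.linker_mismatches] += 1

    def to_dict(self) -> dict:
        return {
            "total": self.total,
            "status_counts": {s: self.status_counts.get(s, 0) for s in STATUSES},
            "pixel_counts": dict(self.pixel_counts),
            "linker_mismatch_hist": {
                f"{l1},{l2}": n for (l1, l2), n in sorted(self.linker_mismatch_hist.items())
            },
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def match_linker(observed: str, reference: str, max_mismatch: int = 2) -> tuple[bool, int]:
    """Fixed-position linker check by Hamming distance.

    ``N`` bases count as mismatches. Sequences must have equal length; the
    chemistry places linkers at constant offsets so no alignment is done.
    """
    if len(observed) != len(reference):
        raise ValueError(
            f"linker length mismatch: observed {len(observed)} vs reference {len(reference)}"
        )
    n_mismatch = sum(1 for o, r in zip(observed.upper(), reference.upper()) if o != r or o == "N")
    return n_mismatch <= max_mismatch, n_mismatch


def _hamming(a: str, b: str) -> int:
    return sum(1 for x, y in zip(a, b) if x != y)


def _correct_with_reason(
    seq: str, whitelist: Iterable[str], max_distance: int
) -> tuple[Optional[int], str]:
    """(index, reason) with reason in {"ok", "none", "ambiguous"}."""
    seq = seq.upper()
    best = None
    best_d = max_distance + 1
    tied = False
    for i, entry in enumerate(whitelist, start=1):
        if len(entry) != len(seq):
            raise ValueError("barcode length does not match whitelist entry length")
        d = _hamming(seq, entry)
        if d < best_d:
            best, best_d, tied = i, d, False
        elif d == best_d:
            tied = True
    if best_d > max_distance:
        return None, "none"
    if tied:
        return None, "ambiguous"
    return best, "ok"


def correct_barcode(
    seq: str, whitelist: Iterable[str], max_distance: int = 1
) -> Optional[int]:
    """Resolve a barcode to its 1-based whitelist index, or ``None``.

    Returns the unique whitelist entry within Hamming distance
    ``max_distance``; ambiguity (two or more entries tied at the minimum
    distance) or no entry within range yields ``None``.
    """
    return _correct_with_reason(seq, whitelist, max_distance)[0]


class BarcodeCorrector:
    """Whitelist lookup with an exact-match fast path.

    Behaviourally identical to :func:`correct_barcode`; precomputes the
    exact-sequence dictionary so error-free reads avoid the O(N) scan.
    Whitelists are duplicate-free by schema invariant, so an exact hit is
    always the unique distance-0 match.
    """

    def __init__(self, whitelist: Iterable[str], max_distance: int = 1):
        self.whitelist = [w.upper() for w in whitelist]
        self.max_distance = max_distance
        self._exact = {w: i for i, w in enumerate(self.whitelist, start=1)}

    def classify(self, seq: str) -> tuple[Optional[int], str]:
        seq = seq.upper()
        hit = self._exact.get(seq)
        if hit is not None:
            return hit, "ok"
        return _correct_with_reason(seq, self.whitelist, self.max_distance)

    def __call__(self, seq: str) -> Optional[int]:
        return self.classify(seq)[0]


def _parse_read2(
    read2_seq: str,
    schema: BarcodeSchema,
    correct_a: BarcodeCorrector,
    correct_b: BarcodeCorrector,
    max_linker_mismatch: int,
) -> tuple[str, Optional[int], Optional[int], str, bool, bool, tuple[int, int]]:
    """Shared read-2 parsing; returns (status, a, b, umi, a_corr, b_corr, linker_mms)."""
    if len(read2_seq) < schema.read2_length:
        return STATUS_LINKER_FAIL, None, None, "", False, False, (0, 0)

    off1, len1 = schema.segment("linker1")
    off2, len2 = schema.segment("linker2")
    ok1, mm1 = match_linker(read2_seq[off1 : off1 + len1], schema.linker1_seq, max_linker_mismatch)
    ok2, mm2 = match_linker(read2_seq[off2 : off2 + len2], schema.linker2_seq, max_linker_mismatch)
    if not (ok1 and ok2):
        return STATUS_LINKER_FAIL, None, None, "", False, False, (mm1, mm2)

    off_a, len_a = schema.segment("barcode_a")
    off_b, len_b = schema.segment("barcode_b")
    raw_a = read2_seq[off_a : off_a + len_a].upper()
    raw_b = read2_seq[off_b : off_b + len_b].upper()
    a, reason_a = correct_a.classify(raw_a)
    b, reason_b = correct_b.classify(raw_b)
    if a is None or b is None:
        status = (
            STATUS_AMBIGUOUS
            if "ambiguous" in (reason_a, reason_b)
            else STATUS_BARCODE_FAIL
        )
        return status, None, None, "", False, False, (mm1, mm2)

    umi = ""
    if schema.modality == "rna":
        off_u, len_u = schema.segment("umi")
        umi = read2_seq[off_u : off_u + len_u].upper()
    a_corr = schema.barcode_a_whitelist[a - 1] != raw_a
    b_corr = schema.barcode_b_whitelist[b - 1] != raw_b
    return STATUS_ASSIGNED, a, b, umi, a_corr, b_corr, (mm1, mm2)


def _assign(
    read1: FastqRead,
    read2: FastqRead,
    schema: BarcodeSchema,
    grid: PixelGrid,
    correct_a: BarcodeCorrector,
    correct_b: BarcodeCorrector,
    max_linker_mismatch: int,
) -> ReadAssignment:
    status, a, b, umi, a_corr, b_corr, mms = _parse_read2(
        read2.sequence, schema, correct_a, correct_b, max_linker_mismatch
    )
    if status == STATUS_ASSIGNED and not grid.contains(a, b):
        # whitelists larger than the grid would be a config error upstream
        status, a, b = STATUS_BARCODE_FAIL, None, None
    return ReadAssignment(
        read_id=read1.name,
        status=status,
        a_index=a,
        b_index=b,
        umi=umi,
        a_corrected=a_corr,
        b_corrected=b_corr,
        linker_mismatches=mms,
    )


def demux_atac_pair(
    read1: FastqRead,
    read2: FastqRead,
    schema: BarcodeSchema,
    grid: PixelGrid,
    max_linker_mismatch: int = 2,
    max_barcode_distance: int = 1,
    _correctors: Optional[tuple[BarcodeCorrector, BarcodeCorrector]] = None,
) -> tuple[ReadAssignment, Optional[tuple[FastqRead, FastqRead, str]]]:
    """Demultiplex one ATAC / CUT&Tag pair.

    On success returns the untouched genomic read 1, a synthetic barcode
    read carrying the corrected 16-base A+B concatenation, and the pixel
    id; on failure the output is ``None`` and the assignment carries the
    rejection status.
    """
    if schema.modality not in ("atac", "cuttag"):
        raise ValueError(f"demux_atac_pair requires ATAC/CUT&Tag schema, got {schema.modality}")
    ca, cb = _correctors or (
        BarcodeCorrector(schema.barcode_a_whitelist, max_barcode_distance),
        BarcodeCorrector(schema.barcode_b_whitelist, max_barcode_distance),
    )
    assignment = _assign(read1, read2, schema, grid, ca, cb, max_linker_mismatch)
    if assignment.status != STATUS_ASSIGNED:
        return assignment, None
    cell_barcode = (
        schema.barcode_a_whitelist[assignment.a_index - 1]
        + schema.barcode_b_whitelist[assignment.b_index - 1]
    )
    barcode_read = FastqRead(read1.name, cell_barcode, "I" * len(cell_barcode))
    return assignment, (read1, barcode_read, assignment.pixel)


def demux_rna_pair(
    read1: FastqRead,
    read2: FastqRead,
    schema: BarcodeSchema,
    grid: PixelGrid,
    max_linker_mismatch: int = 2,
    max_barcode_distance: int = 1,
    _correctors: Optional[tuple[BarcodeCorrector, BarcodeCorrector]] = None,
) -> tuple[ReadAssignment, Optional[tuple[FastqRead, str, str]]]:
    """Demultiplex one RNA pair into (genomic read, pixel id, raw UMI)."""
    if schema.modality != "rna":
        raise ValueError(f"demux_rna_pair requires RNA schema, got {schema.modality}")
    ca, cb = _correctors or (
        BarcodeCorrector(schema.barcode_a_whitelist, max_barcode_distance),
        BarcodeCorrector(schema.barcode_b_whitelist, max_barcode_distance),
    )
    assignment = _assign(read1, read2, schema, grid, ca, cb, max_linker_mismatch)
    if assignment.status != STATUS_ASSIGNED:
        return assignment, None
    return assignment, (read1, assignment.pixel, assignment.umi)


def demux_pairs(
    pairs: Iterable[tuple[FastqRead, FastqRead]],
    schema: BarcodeSchema,
    grid: PixelGrid,
    max_linker_mismatch: int = 2,
    max_barcode_distance: int = 1,
) -> tuple[list[ReadAssignment], list, DemuxReport]:
    """Demultiplex an iterable of read pairs; returns assignments, outputs, report."""
    ca = BarcodeCorrector(schema.barcode_a_whitelist, max_barcode_distance)
    cb = BarcodeCorrector(schema.barcode_b_whitelist, max_barcode_distance)
    fn = demux_rna_pair if schema.modality == "rna" else demux_atac_pair
    report = DemuxReport()
    assignments: list[ReadAssignment] = []
    outputs: list = []
    for r1, r2 in pairs:
        assignment, out = fn(
            r1, r2, schema, grid, max_linker_mismatch, max_barcode_distance,
            _correctors=(ca, cb),
        )
        report.record(assignment)
        assignments.append(assignment)
        if out is not None:
            outputs.append(out)
    return assignments, outputs, report


# ---------------------------------------------------------------------------
# streaming FASTQ interface


def _open_text(path: str | Path, mode: str = "rt"):
    path = str(path)
    return gzip.open(path, mode) if path.endswith(".gz") else open(path, mode)


def read_fastq_pairs(r1_path: str | Path, r2_path: str | Path) -> Iterator[tuple[FastqRead, FastqRead]]:
    with pysam.FastxFile(str(r1_path)) as f1, pysam.FastxFile(str(r2_path)) as f2:
        for e1, e2 in zip(f1, f2):
            yield (
                FastqRead(e1.name, e1.sequence, e1.quality or ""),
                FastqRead(e2.name, e2.sequence, e2.quality or ""),
            )


def _write_fastq(handle, read: FastqRead) -> None:
    qual = read.quality or "I" * len(read.sequence)
    handle.write(f"@{read.name}\n{read.sequence}\n+\n{qual}\n")


def demux_fastq(
    r1_path: str | Path,
    r2_path: str | Path,
    schema: BarcodeSchema,
    grid: PixelGrid,
    out_prefix: str | Path,
    max_linker_mismatch: int = 2,
    max_barcode_distance: int = 1,
    gzip_output: bool = False,
) -> DemuxReport:
    """Stream a FASTQ pair through demultiplexing.

    ATAC/CUT&Tag mode writes ``<prefix>_R1.fastq`` (genomic) and
    ``<prefix>_R2.fastq`` (16-base synthetic cell barcode read) plus a
    pixel-tag TSV; RNA mode writes ``<prefix>_R1.fastq`` plus a
    (read id, pixel, UMI) TSV. A JSON report is always written.
    """
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    suffix = ".fastq.gz" if gzip_output else ".fastq"
    ca = BarcodeCorrector(schema.barcode_a_whitelist, max_barcode_distance)
    cb = BarcodeCorrector(schema.barcode_b_whitelist, max_barcode_distance)
    report = DemuxReport()
    rna = schema.modality == "rna"
    fn = demux_rna_pair if rna else demux_atac_pair

    r1_out = _open_text(f"{out_prefix}_R1{suffix}", "wt")
    r2_out = None if rna else _open_text(f"{out_prefix}_R2{suffix}", "wt")
    tags_out = _open_text(f"{out_prefix}_tags.tsv", "wt")
    tags_out.write("read_id\tpixel\tumi\n" if rna else "read_id\tpixel\n")
    try:
        for r1, r2 in read_fastq_pairs(r1_path, r2_path):
            assignment, out = fn(
                r1, r2, schema, grid, max_linker_mismatch, max_barcode_distance,
                _correctors=(ca, cb),
            )
            report.record(assignment)
            if out is None:
                continue
            if rna:
                genomic, pixel, umi = out
                _write_fastq(r1_out, genomic)
                tags_out.write(f"{genomic.name}\t{pixel}\t{umi}\n")
            else:
                genomic, barcode_read, pixel = out
                _write_fastq(r1_out, genomic)
                _write_fastq(r2_out, barcode_read)
                tags_out.write(f"{genomic.name}\t{pixel}\n")
    finally:
        r1_out.close()
        if r2_out is not None:
            r2_out.close()
        tags_out.close()
    report.to_json(f"{out_prefix}_report.json")
    return report
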