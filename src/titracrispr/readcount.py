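"""Turn amplicon reads into a count tensor.

A read is counted iff its 20-nt spacer region exactly matches a library
spacer, every decision-relevant base has Phred quality strictly above 30,
and its 6-nt barcode exactly matches a configured barcode.  Everything
else lands in a per-reason discard report; counted + discarded always
equals the number of reads seen.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
from Bio import SeqIO

from .counts import CountTensor, read_count_table, write_count_table  # noqa: F401
from .design import LibrarySpec

__all__ = [
    "ReadRecord",
    "DiscardReport",
    "parse_fastq",
    "count_reads",
    "read_count_table",
    "write_count_table",
]


@dataclass(frozen=True)
class ReadRecord:
    sequence: str
    qualities: tuple[int, ...]

    def __post_init__(self):
        if len(self.sequence) != len(self.qualities):
            raise ValueError("sequence and qualities differ in length")


@dataclass
class DiscardReport:
    """Per-reason tallies of reads that were not counted."""

    reasons: Counter

    def total(self) -> int:
        return sum(self.reasons.values())


def parse_fastq(path):
    """Phred+33 FASTQ -> ReadRecord stream."""
    for rec in SeqIO.parse(str(path), "fastq"):
        yield ReadRecord(
            str(rec.seq).upper(),
            tuple(rec.letter_annotations["phred_quality"]),
        )


def count_reads(
    reads_by_hour,
    lib: LibrarySpec,
    layout,
    q_floor: int = 30,
    quality_scope: str = "spacer_barcode",
    environment: str = "",
) -> tuple[CountTensor, DiscardReport]:
    """Demultiplex and count reads into a (guide, barcode, hour) tensor.

    ``reads_by_hour`` maps each scheduled hour to an iterable of
    ReadRecord.  The quality filter (Q > ``q_floor``, strict) applies to
    the spacer and barcode bases by default, or to the whole read with
    ``quality_scope="whole_read"``.  Unknown barcodes and spacer
    mismatches are discarded, never errors; reads too short for the layout
    are malformed.
    """
    if quality_scope not in ("spacer_barcode", "whole_read"):
        raise ValueError("quality_scope must be 'spacer_barcode' or 'whole_read'")
    hours = np.sort(np.array([float(h) for h in reads_by_hour], dtype=float))
    guides = [v.guide_id for v in lib.variants]
    barcodes = list(lib.barcodes)
    spacer_map = lib.spacer_map()
    gi = {g: i for i, g in enumerate(guides)}
    bi = {b: i for i, b in enumerate(barcodes)}
    counts = np.zeros((len(guides), len(barcodes), len(hours)), dtype=np.int64)
    reasons: Counter = Counter()
    s0, b0 = layout.spacer_start, layout.barcode_start
    need = b0 + 6
    for t, hour in enumerate(hours):
        for read in reads_by_hour[hour]:
            if not isinstance(read, ReadRecord):
                raise TypeError(f"expected ReadRecord, got {type(read).__name__}")
            if len(read.sequence) < need:
                reasons["malformed"] += 1
                continue
            if quality_scope == "whole_read":
                qual_ok = min(read.qualities) > q_floor
            else:
                q = read.qualities
                qual_ok = (
                    min(q[s0 : s0 + 20]) > q_floor and min(q[b0 : b0 + 6]) > q_floor
                )
            if not qual_ok:
                reasons["low_quality"] += 1
                continue
            guide = spacer_map.get(read.sequence[s0 : s0 + 20])
            if guide is None:
                reasons["spacer_mismatch"] += 1
                continue
            barcode = read.sequence[b0 : b0 + 6]
            if barcode not in bi:
                reasons["unknown_barcode"] += 1
                continue
            counts[gi[guide], bi[barcode], t] += 1
    return (
        CountTensor(guides, barcodes, hours, counts, environment=environment),
        DiscardReport(reasons),
    )
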