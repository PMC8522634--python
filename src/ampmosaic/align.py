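"""Gapless placement of demultiplexed reads on an amplicon reference.

Amplicon reads come from PCR of a fixed short template, so a
desk-scale aligner that scores every gapless placement of the read (and
of its reverse complement) on the amplicon is exact and fully testable
against an exhaustive oracle.  The placement with the minimum mismatch
count wins; ties break to the smallest start, then the + strand, and a
non-unique best placement gets a mapping-quality proxy of 0 (mirroring
"zero or low mapping quality" read removal).  A read whose best
placement still exceeds ``max_mismatch_frac`` x read length — or that is
longer than the reference — is UNALIGNED (returned as ``None``), the
gapless analogue of an aberrant alignment.

Coordinates are 1-based and amplicon-local throughout.

:func:`clean_alignments` applies the exome-style read-cleaning rules as
predicates: drop PCR duplicates, reads without a proper pair flag, and
reads below a mapping-quality cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from ._seq import complement_ascii, seq_to_ascii
from .ampsim import AmpliconDesign
from .demux import ReadRecord


@dataclass(frozen=True)
class AlignmentFlags:
    is_duplicate: bool = False
    proper: bool = True
    mapq_proxy: int = 60

    def __post_init__(self) -> None:
        if not 0 <= self.mapq_proxy <= 60:
            raise ValueError("mapq_proxy outside 0..60")


@dataclass(frozen=True)
class AlignmentRecord:
    """A gapless read placement on an amplicon reference.

    ``read_bases`` are stored oriented to the reference (reverse-strand
    reads are reverse-complemented), so the base covering reference
    position ``p`` is ``read_bases[p - start]``.
    """

    read_id: str
    amplicon_id: str
    start: int  # 1-based inclusive
    strand: str  # "+" or "-"
    mismatch_count: int
    read_bases: str
    flags: AlignmentFlags = field(default_factory=AlignmentFlags)

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError("start must be >= 1")
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")

    @property
    def end(self) -> int:
        """1-based inclusive end position on the reference."""
        return self.start + len(self.read_bases) - 1

    def aligned_pairs(self) -> list[tuple[int, str]]:
        """(reference_position, read_base) pairs, positions strictly increasing."""
        return [
            (self.start + i, b) for i, b in enumerate(self.read_bases)
        ]

    def base_at(self, position: int) -> str | None:
        """Read base (reference orientation) covering *position*, or None."""
        if self.start <= position <= self.end:
            return self.read_bases[position - self.start]
        return None


def _placement_mismatches(
    ref_arr: np.ndarray, read_arr: np.ndarray
) -> np.ndarray:
    """Mismatch count of the read at every gapless offset (vectorised)."""
    windows = sliding_window_view(ref_arr, len(read_arr))
    return (windows != read_arr).sum(axis=1)


def align_read(
    read: ReadRecord, design: AmpliconDesign, max_mismatch_frac: float = 0.2
) -> AlignmentRecord | None:
    """Best gapless placement of *read* (either strand) on the amplicon.

    Returns ``None`` (UNALIGNED) for an empty read, a read longer than
    the reference, or a best placement with more than
    ``max_mismatch_frac * len(read)`` mismatches.
    """
    records = align_reads([read], design, max_mismatch_frac)
    return records[0]


def align_reads(
    reads: Sequence[ReadRecord],
    design: AmpliconDesign,
    max_mismatch_frac: float = 0.2,
) -> list[AlignmentRecord | None]:
    """Vectorised :func:`align_read` over many reads (same contract).

    Reads are grouped by length; within a group the mismatch counts of
    all placements x strands are computed in one array pass per offset.
    """
    ref_arr = seq_to_ascii(design.reference)
    results: list[AlignmentRecord | None] = [None] * len(reads)

    by_length: dict[int, list[int]] = {}
    for i, read in enumerate(reads):
        by_length.setdefault(len(read), []).append(i)

    for length, idxs in by_length.items():
        if length == 0 or length > len(ref_arr):
            continue  # UNALIGNED
        n_off = len(ref_arr) - length + 1
        mat = np.empty((len(idxs), length), dtype=np.uint8)
        for row, i in enumerate(idxs):
            mat[row] = seq_to_ascii(reads[i].sequence)
        rc_mat = complement_ascii(mat)[:, ::-1]

        # mismatch counts, columns ordered (start-major, '+' before '-')
        # so that argmin realises the tie-break directly
        mm = np.empty((len(idxs), 2 * n_off), dtype=np.int32)
        windows = sliding_window_view(ref_arr, length)
        for off in range(n_off):
            w = windows[off]
            mm[:, 2 * off] = (mat != w).sum(axis=1)
            mm[:, 2 * off + 1] = (rc_mat != w).sum(axis=1)

        best_col = mm.argmin(axis=1)
        best_mm = mm[np.arange(len(idxs)), best_col]
        n_best = (mm == best_mm[:, None]).sum(axis=1)
        max_mm = max_mismatch_frac * length

        for row, i in enumerate(idxs):
            if best_mm[row] > max_mm:
                continue  # UNALIGNED
            col = int(best_col[row])
            start = col // 2 + 1
            strand = "+" if col % 2 == 0 else "-"
            oriented = (mat if strand == "+" else rc_mat)[row]
            results[i] = AlignmentRecord(
                read_id=reads[i].read_id,
                amplicon_id=design.amplicon_id,
                start=start,
                strand=strand,
                mismatch_count=int(best_mm[row]),
                read_bases=oriented.tobytes().decode("ascii"),
                flags=AlignmentFlags(
                    mapq_proxy=60 if int(n_best[row]) == 1 else 0
                ),
            )
    return results


def clean_alignments(
    records: Iterable[AlignmentRecord], min_mapq: int = 1
) -> tuple[list[AlignmentRecord], dict[str, int]]:
    """Drop low-quality alignments; returns (survivors, removal tally).

    Removal rules, applied in order per record: PCR duplicate, not
    proper (no proper mate), mapping-quality proxy below ``min_mapq``.
    Survivor order is preserved; applying the filter twice is a no-op.
    """
    survivors: list[AlignmentRecord] = []
    tally = {"duplicate": 0, "not_proper": 0, "low_mapq": 0}
    for rec in records:
        if rec.flags.is_duplicate:
            tally["duplicate"] += 1
        elif not rec.flags.proper:
            tally["not_proper"] += 1
        elif rec.flags.mapq_proxy < min_mapq:
            tally["low_mapq"] += 1
        else:
            survivors.append(rec)
    return survivors, tally


# --- SAM output ------------------------------------------------------------

def write_sam(
    records: Iterable[AlignmentRecord],
    designs: Sequence[AmpliconDesign],
    path: str | Path,
) -> int:
    """Write survivors as minimal SAM (gapless: CIGAR is `<len>M`).

    Header carries one @SQ line per amplicon.  SEQ is emitted in
    reference orientation (as stored); reverse-strand reads set flag
    0x10.  Mismatches are not encoded as tags.  Returns records written.
    """
    n = 0
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unknown\n")
        for d in designs:
            fh.write(f"@SQ\tSN:{d.amplicon_id}\tLN:{len(d.reference)}\n")
        fh.write("@PG\tID:ampmosaic\tPN:ampmosaic\n")
        for rec in records:
            flag = 16 if rec.strand == "-" else 0
            fh.write(
                f"{rec.read_id}\t{flag}\t{rec.amplicon_id}\t{rec.start}\t"
                f"{rec.flags.mapq_proxy}\t{len(rec.read_bases)}M\t*\t0\t0\t"
                f"{rec.read_bases}\t*\n"
            )
            n += 1
    return n


def write_alignment_summary_tsv(
    records: Iterable[AlignmentRecord | None], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\tamplicon\tstart\tstrand\tmismatches\tmapq\taligned\n")
        for rec in records:
            if rec is None:
                continue
            fh.write(
                f"{rec.read_id}\t{rec.amplicon_id}\t{rec.start}\t{rec.strand}\t"
                f"{rec.mismatch_count}\t{rec.flags.mapq_proxy}\t1\n"
            )
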