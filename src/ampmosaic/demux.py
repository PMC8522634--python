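"""Barcode demultiplexing of amplicon reads.

Each sequencing read starts with a fixed-length sample barcode.  A read
is assigned to the unique sample whose barcode equals the read's prefix
*exactly* (zero mismatches by default; ``max_mismatch`` can relax this),
and the barcode is stripped before the read continues downstream.
Anything else — mismatched prefix, an N in the barcode region, a read
shorter than the barcode — goes to the ``UNASSIGNED`` bin, so the bins
always partition the input.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._seq import is_dna

logger = logging.getLogger(__name__)

#: Bin label for reads whose barcode matches no sample.
UNASSIGNED = "UNASSIGNED"


@dataclass(frozen=True)
class ReadRecord:
    """One sequencing read: identifier, bases and per-base qualities."""

    read_id: str
    sequence: str
    quality: str

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.quality):
            raise ValueError(
                f"read {self.read_id!r}: sequence length {len(self.sequence)} "
                f"!= quality length {len(self.quality)}"
            )
        if not is_dna(self.sequence, allow_n=True):
            raise ValueError(f"read {self.read_id!r}: non-ACGTN base in sequence")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class BarcodeMap:
    """sample_id -> barcode lookup; all barcodes equal length, pairwise distinct."""

    entries: dict[str, str]

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError("barcode map is empty")
        lengths = {len(b) for b in self.entries.values()}
        if len(lengths) != 1:
            raise ValueError(f"barcodes have unequal lengths: {sorted(lengths)}")
        if len(set(self.entries.values())) != len(self.entries):
            raise ValueError("barcodes are not pairwise distinct")
        for sample, bc in self.entries.items():
            if not is_dna(bc):
                raise ValueError(f"sample {sample!r}: barcode {bc!r} is not A/C/G/T")

    @property
    def barcode_length(self) -> int:
        return len(next(iter(self.entries.values())))

    @classmethod
    def from_tsv(cls, path: str | Path) -> "BarcodeMap":
        """Load a two-column TSV (sample_id, barcode); '#' lines are comments."""
        entries: dict[str, str] = {}
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                sample, barcode = line.split("\t")[:2]
                entries[sample] = barcode.upper()
        return cls(entries)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for sample, barcode in self.entries.items():
                fh.write(f"{sample}\t{barcode}\n")


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def assign_barcode(
    read: ReadRecord, barcode_map: BarcodeMap, max_mismatch: int = 0
) -> tuple[str, ReadRecord]:
    """Assign *read* to a sample by its barcode prefix.

    Returns ``(sample_id, read_without_barcode)`` on a match and
    ``(UNASSIGNED, read_unchanged)`` otherwise.  An N anywhere in the
    barcode region never matches.  A read shorter than the barcode is
    routed to UNASSIGNED with a logged warning rather than raising.

    With ``max_mismatch > 0`` the nearest barcode within that Hamming
    distance wins; a distance tie between two barcodes is unassigned.
    """
    k = barcode_map.barcode_length
    if len(read) < k:
        logger.warning(
            "read %s shorter (%d bp) than barcode length %d; unassigned",
            read.read_id,
            len(read),
            k,
        )
        return UNASSIGNED, read
    prefix = read.sequence[:k]
    hit: str | None = None
    if "N" not in prefix:
        if max_mismatch == 0:
            for sample, bc in barcode_map.entries.items():
                if bc == prefix:
                    hit = sample
                    break
        else:
            best, best_d, tied = None, max_mismatch + 1, False
            for sample, bc in barcode_map.entries.items():
                d = _hamming(bc, prefix)
                if d < best_d:
                    best, best_d, tied = sample, d, False
                elif d == best_d:
                    tied = True
            if best is not None and not tied:
                hit = best
    if hit is None:
        return UNASSIGNED, read
    stripped = ReadRecord(read.read_id, read.sequence[k:], read.quality[k:])
    return hit, stripped


def demultiplex(
    reads: Iterable[ReadRecord], barcode_map: BarcodeMap, max_mismatch: int = 0
) -> dict[str, list[ReadRecord]]:
    """Partition *reads* into per-sample bins plus an UNASSIGNED bin.

    Every sample in the map gets a (possibly empty) bin; every input read
    lands in exactly one bin, so bin sizes sum to the input count.
    """
    bins: dict[str, list[ReadRecord]] = {s: [] for s in barcode_map.entries}
    bins[UNASSIGNED] = []
    if max_mismatch == 0:
        # fast path: direct prefix lookup
        by_barcode = {bc: s for s, bc in barcode_map.entries.items()}
        k = barcode_map.barcode_length
        for read in reads:
            seq = read.sequence
            sample = by_barcode.get(seq[:k]) if len(seq) >= k else None
            if sample is None:
                if len(seq) < k:
                    logger.warning(
                        "read %s shorter (%d bp) than barcode length %d; unassigned",
                        read.read_id,
                        len(seq),
                        k,
                    )
                bins[UNASSIGNED].append(read)
            else:
                bins[sample].append(
                    ReadRecord(read.read_id, seq[k:], read.quality[k:])
                )
    else:
        for read in reads:
            sample, out = assign_barcode(read, barcode_map, max_mismatch)
            bins[sample].append(out)
    return bins


# --- FASTQ I/O -------------------------------------------------------------

def read_fastq(path: str | Path) -> Iterator[ReadRecord]:
    """Iterate ReadRecords from a (plain-text) FASTQ file."""
    for rec in SeqIO.parse(str(path), "fastq"):
        quals = rec.letter_annotations["phred_quality"]
        yield ReadRecord(
            rec.id, str(rec.seq).upper(), "".join(chr(q + 33) for q in quals)
        )


def write_fastq(reads: Iterable[ReadRecord], path: str | Path) -> int:
    """Write reads as 4-line FASTQ records; returns the number written."""

    def _records():
        for r in reads:
            rec = SeqRecord(Seq(r.sequence), id=r.read_id, description="")
            rec.letter_annotations["phred_quality"] = [
                ord(c) - 33 for c in r.quality
            ]
            yield rec

    return SeqIO.write(_records(), str(path), "fastq")


def write_demux_bins(
    bins: dict[str, list[ReadRecord]], out_dir: str | Path
) -> dict[str, Path]:
    """Write one FASTQ per sample plus unassigned.fastq; returns the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for sample, reads in bins.items():
        name = "unassigned.fastq" if sample == UNASSIGNED else f"{sample}.fastq"
        path = out_dir / name
        write_fastq(reads, path)
        paths[sample] = path
    return paths
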