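"""Per-position base tallies from cleaned gapless alignments.

This is the arithmetic behind every row of an ultra-deep amplicon
report: at a reference position, count how many aligned reads show each
of A/C/G/T (reverse-strand reads were already complemented back to
reference orientation by the aligner).  Counts are exact integers — no
sampling, no quality filtering, no rounding — so the depth at a
position always equals the sum of the four base counts plus any Ns.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from ._seq import DNA_BASES
from .align import AlignmentRecord
from .ampsim import AmpliconDesign


@dataclass(frozen=True)
class PileupCounts:
    """Base tally at one reference position of one amplicon."""

    amplicon_id: str
    position: int  # 1-based
    ref_base: str
    counts: Mapping[str, int]
    n_count: int = 0

    def __post_init__(self) -> None:
        if any(self.counts.get(b, 0) < 0 for b in DNA_BASES) or self.n_count < 0:
            raise ValueError("negative count")

    @property
    def depth(self) -> int:
        """Total covering reads: A+C+G+T counts plus Ns."""
        return sum(self.counts.get(b, 0) for b in DNA_BASES) + self.n_count


def count_bases_at(
    records: Iterable[AlignmentRecord],
    design: AmpliconDesign,
    position: int,
) -> PileupCounts:
    """Tally read bases covering one reference position.

    Each aligned read covering the position contributes exactly once;
    reads not covering it contribute nothing.  N bases are tallied
    separately in ``n_count`` (and included in depth).
    """
    if not 1 <= position <= len(design.reference):
        raise ValueError(
            f"position {position} outside 1..{len(design.reference)} "
            f"of amplicon {design.amplicon_id}"
        )
    counts = {b: 0 for b in DNA_BASES}
    n_count = 0
    for rec in records:
        base = rec.base_at(position)
        if base is None:
            continue
        if base == "N":
            n_count += 1
        else:
            counts[base] += 1
    return PileupCounts(
        amplicon_id=design.amplicon_id,
        position=position,
        ref_base=design.reference[position - 1],
        counts=counts,
        n_count=n_count,
    )


def pileup_all(
    records: Sequence[AlignmentRecord], design: AmpliconDesign
) -> list[PileupCounts]:
    """Base tallies for every reference position (one pass over reads).

    The total of all tallied bases equals the summed aligned length of
    the input records.
    """
    length = len(design.reference)
    grid = [[0, 0, 0, 0, 0] for _ in range(length)]  # A C G T N
    col = {b: i for i, b in enumerate(DNA_BASES + "N")}
    for rec in records:
        row = rec.start - 1
        for i, base in enumerate(rec.read_bases):
            grid[row + i][col[base]] += 1
    return [
        PileupCounts(
            amplicon_id=design.amplicon_id,
            position=pos + 1,
            ref_base=design.reference[pos],
            counts={b: grid[pos][col[b]] for b in DNA_BASES},
            n_count=grid[pos][4],
        )
        for pos in range(length)
    ]


def write_pileup_tsv(rows: Iterable[PileupCounts], path: str | Path) -> None:
    """TSV with fixed column order: amplicon, pos, ref, depth, A, C, G, T, N."""
    with open(path, "w") as fh:
        fh.write(pileup_tsv_string(rows))


def pileup_tsv_string(rows: Iterable[PileupCounts]) -> str:
    lines = ["amplicon\tpos\tref\tdepth\tA\tC\tG\tT\tN"]
    for r in rows:
        lines.append(
            f"{r.amplicon_id}\t{r.position}\t{r.ref_base}\t{r.depth}\t"
            + "\t".join(str(r.counts.get(b, 0)) for b in DNA_BASES)
            + f"\t{r.n_count}"
        )
    return "\n".join(lines) + "\n"
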