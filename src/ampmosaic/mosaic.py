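"""Mutant-allele-frequency estimation and mosaicism positivity calls.

A pileup row at the target locus yields:

* the **variant allele frequency** (VAF) ``alt_count / depth``, kept as
  an exact rational internally and reported as a percentage rounded
  half-up to two decimals (the convention of the published report
  tables);
* a **background error estimate**: the two bases that are neither
  reference nor alternative arise only from sequencing/PCR error, and a
  uniform substitution model spreads errors evenly over the three
  non-template bases, so their pooled rate over ``2 * depth`` estimates
  the per-substitution error — i.e. the rate at which error alone feeds
  the alternative base;
* a **positivity classification**: a sample is called mosaic-positive
  when the alternative-read count is inconsistent with error alone
  (one-sided binomial tail below ``alpha`` against the locally estimated
  per-substitution error, floored at ``floor_error``) *and* the measured
  VAF reaches a reporting floor ``min_vaf`` (default 0.2%, the lower end
  of the mutation-frequency range treated as positive in ultra-deep
  mosaic screens; statistically significant signal below it — e.g. a
  0.15% trace in a matched unaffected biopsy — stays negative).

``vaf_corrected`` additionally reports the background-subtracted
estimate ``max(0, vaf - error_rate_hat)``, which removes the upward bias
the error channel adds to the raw VAF (about one third of the per-base
error rate).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from scipy import stats

from ._seq import DNA_BASES
from .ampsim import AmpliconDesign
from .pileup import PileupCounts


@dataclass(frozen=True)
class MosaicCall:
    """Positivity call for one sample x locus."""

    sample_id: str
    locus: str
    vaf: Fraction
    vaf_percent_2dp: Decimal
    vaf_corrected: Fraction
    error_rate_hat: Fraction
    p_value: float
    classification: str  # "positive" | "negative"
    mutant_count: int
    depth: int
    alpha: float
    min_vaf: float

    def __post_init__(self) -> None:
        if self.classification not in ("positive", "negative"):
            raise ValueError("classification must be positive/negative")
        if self.classification == "positive" and self.mutant_count < 1:
            raise ValueError("positive call with zero mutant reads")


def percent_2dp(value: Fraction) -> Decimal:
    """Exact fraction -> percentage with 2 decimals, ties rounded up."""
    exact = Decimal(int(value.numerator)) * 100 / Decimal(int(value.denominator))
    return exact.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP)


def compute_vaf(counts: PileupCounts, alt_base: str) -> tuple[Fraction, Decimal]:
    """VAF of *alt_base* as an exact fraction plus the 2-dp percentage."""
    if alt_base not in DNA_BASES:
        raise ValueError(f"alt_base {alt_base!r} not one of A/C/G/T")
    depth = counts.depth
    if depth == 0:
        raise ZeroDivisionError(
            f"VAF undefined at zero depth ({counts.amplicon_id}:{counts.position})"
        )
    vaf = Fraction(int(counts.counts.get(alt_base, 0)), int(depth))
    return vaf, percent_2dp(vaf)


def estimate_error_rate(
    counts: PileupCounts, ref_base: str, alt_base: str
) -> Fraction:
    """Per-substitution background error from the two off-target bases.

    Off-target counts pool two of the three possible substitution
    products of the reference base, hence the ``2 * depth`` denominator:
    the estimate is directly comparable with the error contamination
    expected at the (single) alternative base.
    """
    if counts.depth == 0:
        raise ZeroDivisionError("error rate undefined at zero depth")
    others = [b for b in DNA_BASES if b not in (ref_base, alt_base)]
    off_target = sum(int(counts.counts.get(b, 0)) for b in others)
    return Fraction(off_target, 2 * int(counts.depth))


def classify_mosaic(
    counts: PileupCounts,
    ref_base: str,
    alt_base: str,
    alpha: float = 0.01,
    min_vaf: float = 0.002,
    floor_error: float = 1e-4,
    sample_id: str = "",
    locus: str = "",
    n_tests: int = 1,
) -> MosaicCall:
    """Call a sample positive or negative for the mosaic variant.

    Positive iff the one-sided binomial tail
    ``P[X >= mutant_count | n=depth, p=max(error_rate_hat, floor_error)]``
    falls below ``alpha`` (Bonferroni-divided by ``n_tests`` when more
    than one locus is tested per sample) AND the measured VAF is at
    least ``min_vaf``.  All inputs are echoed into the returned record.
    """
    vaf, pct = compute_vaf(counts, alt_base)
    err = estimate_error_rate(counts, ref_base, alt_base)
    mutant_count = counts.counts.get(alt_base, 0)
    depth = counts.depth
    p_null = max(float(err), floor_error)
    # P[X >= k] = sf(k - 1)
    p_value = float(stats.binom.sf(mutant_count - 1, depth, p_null))
    threshold = alpha / max(1, n_tests)
    positive = p_value < threshold and vaf >= Fraction(min_vaf).limit_denominator(
        10**9
    )
    corrected = max(Fraction(0), vaf - err)
    return MosaicCall(
        sample_id=sample_id,
        locus=locus or counts.amplicon_id,
        vaf=vaf,
        vaf_percent_2dp=pct,
        vaf_corrected=corrected,
        error_rate_hat=err,
        p_value=p_value,
        classification="positive" if positive else "negative",
        mutant_count=mutant_count,
        depth=depth,
        alpha=alpha,
        min_vaf=min_vaf,
    )


REPORT_COLUMNS = [
    "sample",
    "locus",
    "frequency_percent",
    "depth",
    "ref_count",
    "alt_count",
    "other_count_1",
    "other_count_2",
    "classification",
]


def make_report(
    calls: Sequence[MosaicCall],
    pileups: Sequence[PileupCounts] | None = None,
    designs: Sequence[AmpliconDesign] | None = None,
) -> pd.DataFrame:
    """One report row per call, shaped like the published mutation tables.

    Columns: sample, locus, frequency (2-dp percent), depth, reference
    and alternative counts, the two off-target base counts, and the
    classification; sorted by sample then locus.  ``pileups``/``designs``
    (parallel to ``calls``) supply the off-target counts; without them
    those columns are derived from depth - ref - alt pooled into one.
    """
    rows = []
    for i, call in enumerate(calls):
        ref_count = call.depth - call.mutant_count
        other1 = other2 = 0
        if pileups is not None and designs is not None:
            design = designs[i]
            pu = pileups[i]
            others = [
                b for b in DNA_BASES if b not in (design.ref_base, design.alt_base)
            ]
            ref_count = pu.counts.get(design.ref_base, 0)
            other1 = pu.counts.get(others[0], 0)
            other2 = pu.counts.get(others[1], 0)
        rows.append(
            {
                "sample": call.sample_id,
                "locus": call.locus,
                "frequency_percent": str(call.vaf_percent_2dp),
                "depth": call.depth,
                "ref_count": ref_count,
                "alt_count": call.mutant_count,
                "other_count_1": other1,
                "other_count_2": other2,
                "classification": call.classification,
            }
        )
    frame = pd.DataFrame(rows, columns=REPORT_COLUMNS)
    return frame.sort_values(["sample", "locus"], kind="stable").reset_index(
        drop=True
    )


def write_report_tsv(report: pd.DataFrame, path: str | Path, header_lines: Iterable[str] = ()) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        report.to_csv(fh, sep="\t", index=False)


def write_vcf(
    calls: Sequence[MosaicCall],
    designs: Sequence[AmpliconDesign],
    path: str | Path,
) -> int:
    """Minimal VCF 4.2 with one record per *positive* call.

    CHROM is the amplicon id, POS the amplicon-local target offset; INFO
    carries AF (measured VAF) and DP.  Returns the record count.
    """
    by_id = {d.amplicon_id: d for d in designs}
    n = 0
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=ampmosaic\n")
        for d in designs:
            fh.write(f"##contig=<ID={d.amplicon_id},length={len(d.reference)}>\n")
        fh.write(
            '##INFO=<ID=AF,Number=1,Type=Float,Description="Variant allele frequency">\n'
        )
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write('##INFO=<ID=SAMPLE,Number=1,Type=String,Description="Sample id">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for call in calls:
            if call.classification != "positive":
                continue
            design = by_id[call.locus]
            af = f"{float(call.vaf):.6f}"
            fh.write(
                f"{design.amplicon_id}\t{design.target_offset}\t.\t"
                f"{design.ref_base}\t{design.alt_base}\t.\tPASS\t"
                f"AF={af};DP={call.depth};SAMPLE={call.sample_id}\n"
            )
            n += 1
    return n
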