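"""Reusable end-to-end recovery study on fully synthetic data.

Runs the whole pipeline — simulate, demultiplex, align, clean, pile up,
call — over a ladder of spiked variant allele frequencies and replicate
seeds, and reports one row per sample x seed cell.  The default ladder
mirrors the tissue-enrichment pattern of a mosaic skin lesion
(unaffected ~0, trace levels at 0.1–0.2%, bulk dermis ~3%, endothelial
culture ~9–21%, microdissected endothelium ~30%) at ultra-deep but
desk-scale depth.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Sequence

from .align import align_reads, clean_alignments
from .ampsim import AmpliconDesign, SampleSpec, SimConfig, simulate_amplicon_reads
from .demux import BarcodeMap, demultiplex
from .mosaic import MosaicCall, classify_mosaic
from .pileup import count_bases_at

#: Synthetic 77 bp amplicon with a G>A SNV at offset 35 (stands in for a
#: real amplicon design; no genomic sequence is shipped).
DEFAULT_REFERENCE = (
    "AGTCCTGACTTCAACTCTGGGCATCCTGTTCTCAGTGCCCTCATAGGTGTTCAGACCAAGGTCGGAACAGCTTAAGC"
)
DEFAULT_DESIGN = AmpliconDesign(
    amplicon_id="AMP_SNV",
    reference=DEFAULT_REFERENCE,
    target_offset=35,
    ref_base="G",
    alt_base="A",
)

DEFAULT_BARCODES = (
    "ACGTAC", "TGCATG", "GATCGA", "CTAGCT", "GGCCAA", "TTAACC",
    "AACCGG", "CCGGTT", "AGAGTC", "TCTCAG", "GTGTCA", "CACAGT",
)

#: 12-sample VAF ladder: two mutation-free samples, one each at the
#: trace levels, and duplicated dermis / culture / microdissection tiers.
DEFAULT_VAF_LADDER = (
    0.0, 0.0, 0.001, 0.002, 0.03, 0.03, 0.09, 0.09, 0.21, 0.21, 0.30, 0.30
)


@dataclass(frozen=True)
class RecoveryCell:
    """One sample x seed outcome of the recovery study."""

    seed: int
    sample_id: str
    true_vaf: float
    realized_template_vaf: float
    call: MosaicCall


def run_recovery_study(
    base_seed: int,
    n_seeds: int = 20,
    depth: int = 20_000,
    vafs: Sequence[float] = DEFAULT_VAF_LADDER,
    error_rate: float = 1e-3,
    read_length: int = 50,
    design: AmpliconDesign = DEFAULT_DESIGN,
) -> list[RecoveryCell]:
    """Full-pipeline VAF recovery over ``n_seeds`` replicate runs.

    Replicate *i* uses simulation seed ``base_seed + i``.  Returns one
    cell per sample and replicate, carrying the realized ground truth
    and the pipeline's call.
    """
    if len(vafs) > len(DEFAULT_BARCODES):
        raise ValueError("not enough built-in barcodes for that many samples")
    cells: list[RecoveryCell] = []
    for i in range(n_seeds):
        seed = base_seed + i
        samples = [
            SampleSpec(f"S{j:02d}", DEFAULT_BARCODES[j], vaf, depth)
            for j, vaf in enumerate(vafs)
        ]
        config = SimConfig(
            designs=[design],
            samples=samples,
            error_rate=error_rate,
            read_length=read_length,
            seed=seed,
        )
        reads, truths = simulate_amplicon_reads(config)
        truth_by_sample = {t.sample_id: t for t in truths}
        bmap = BarcodeMap({s.sample_id: s.barcode for s in samples})
        bins = demultiplex(reads, bmap)
        for sample in samples:
            records = align_reads(bins[sample.sample_id], design)
            cleaned, _ = clean_alignments([r for r in records if r is not None])
            counts = count_bases_at(cleaned, design, design.target_offset)
            call = classify_mosaic(
                counts,
                design.ref_base,
                design.alt_base,
                sample_id=sample.sample_id,
                locus=design.amplicon_id,
            )
            truth = truth_by_sample[sample.sample_id]
            cells.append(
                RecoveryCell(
                    seed=seed,
                    sample_id=sample.sample_id,
                    true_vaf=sample.true_vaf,
                    realized_template_vaf=(
                        truth.n_mutant_templates / truth.n_reads_emitted
                    ),
                    call=call,
                )
            )
    return cells


def within_three_sigma(cell: RecoveryCell) -> bool:
    """Background-corrected VAF within 3 binomial sigma of the truth."""
    p = cell.true_vaf
    band = 3 * (p * (1 - p) / cell.call.depth) ** 0.5
    return abs(float(cell.call.vaf_corrected) - p) <= band


def measured_vaf_reaches(cell: RecoveryCell, floor: float) -> bool:
    return cell.call.vaf >= Fraction(floor).limit_denominator(10**9)
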