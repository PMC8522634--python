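"""Synthetic data generation for the full pipeline.

Two generators live here:

* :func:`simulate_amplicon_reads` emits barcoded single-end amplicon
  reads with a mosaic variant spiked in at a configurable variant allele
  frequency (VAF) and a uniform per-base substitution error, emulating
  ultra-deep (10^4–10^5x) MiSeq amplicon sequencing of a PCR product.
  The default conditions mirror the measured enrichment ladder of a
  mosaic lesion: unaffected tissue at error level, bulk lesional dermis
  at a few percent, cultured endothelial cells around 10–20%, and
  laser-capture-microdissected endothelium at 20–30%.

* :func:`simulate_variant_table` emits paired affected/unaffected
  exome-style site tables with annotations and a ground-truth list of
  the sites that survive the filtration cascade, computed by an
  independent row-by-row restatement of the thresholds.

Both are deterministic under a fixed seed.

Randomness discipline (documented so an independent implementation can
replay it): each sample x amplicon block uses
``numpy.random.default_rng([seed, sample_index, amplicon_index])`` and
draws, in order, (1) the mutant-template mask ``rng.random(depth) <
true_vaf``, (2) the reverse-strand mask ``rng.random(depth) <
frac_reverse``, (3) the per-base error mask over the full barcoded read,
(4) one uniform shift in {1,2,3} per error site (the erroneous base is
the original shifted cyclically in A<C<G<T order, i.e. uniform over the
three other bases).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from ._seq import (
    ASCII_TO_CODE,
    CODE_TO_ASCII,
    complement_ascii,
    is_dna,
    seq_to_ascii,
)
from .demux import ReadRecord
from .exome_filter import SiteAnnotation, SiteCounts, VariantKey

#: Placeholder Phred quality (Q30) — no stage consumes base qualities.
QUALITY_CHAR = chr(30 + 33)


@dataclass(frozen=True)
class AmpliconDesign:
    """One amplicon: reference sequence plus the interrogated SNV locus.

    ``target_offset`` is 1-based within the amplicon-local reference;
    mapping to genomic/HGVS coordinates is configuration metadata kept
    out of the pipeline arithmetic.
    """

    amplicon_id: str
    reference: str
    target_offset: int
    ref_base: str
    alt_base: str

    def __post_init__(self) -> None:
        if not is_dna(self.reference):
            raise ValueError(f"{self.amplicon_id}: reference is not pure A/C/G/T")
        if not 1 <= self.target_offset <= len(self.reference):
            raise ValueError(
                f"{self.amplicon_id}: target_offset {self.target_offset} outside "
                f"1..{len(self.reference)}"
            )
        if self.reference[self.target_offset - 1] != self.ref_base:
            raise ValueError(
                f"{self.amplicon_id}: reference base at offset "
                f"{self.target_offset} is {self.reference[self.target_offset - 1]}, "
                f"not declared ref_base {self.ref_base}"
            )
        if self.alt_base == self.ref_base or self.alt_base not in "ACGT":
            raise ValueError(f"{self.amplicon_id}: invalid alt_base {self.alt_base!r}")


@dataclass(frozen=True)
class SampleSpec:
    sample_id: str
    barcode: str
    true_vaf: float
    depth: int

    def __post_init__(self) -> None:
        if not is_dna(self.barcode):
            raise ValueError(f"{self.sample_id}: barcode is not pure A/C/G/T")
        if not 0.0 <= self.true_vaf <= 1.0:
            raise ValueError(f"{self.sample_id}: true_vaf outside [0, 1]")
        if self.depth < 1:
            raise ValueError(f"{self.sample_id}: depth must be >= 1")


@dataclass(frozen=True)
class SimConfig:
    designs: Sequence[AmpliconDesign]
    samples: Sequence[SampleSpec]
    error_rate: float
    read_length: int
    seed: int
    frac_reverse: float = 0.5

    def __post_init__(self) -> None:
        if not self.designs or not self.samples:
            raise ValueError("need at least one design and one sample")
        if not 0.0 <= self.error_rate <= 0.05:
            raise ValueError("error_rate outside [0, 0.05]")
        barcodes = [s.barcode for s in self.samples]
        if len(set(barcodes)) != len(barcodes):
            raise ValueError("barcodes are not unique across samples")
        if len({len(b) for b in barcodes}) != 1:
            raise ValueError("barcodes must share one length")
        if self.read_length < 1:
            raise ValueError("read_length must be >= 1")
        for d in self.designs:
            if self.read_length > len(d.reference):
                raise ValueError(
                    f"read_length {self.read_length} exceeds amplicon "
                    f"{d.amplicon_id} length {len(d.reference)}"
                )
        if not 0.0 <= self.frac_reverse <= 1.0:
            raise ValueError("frac_reverse outside [0, 1]")

    @property
    def barcode_length(self) -> int:
        return len(self.samples[0].barcode)


@dataclass(frozen=True)
class TruthRecord:
    """Realized per sample x amplicon ground truth."""

    sample_id: str
    amplicon_id: str
    true_vaf: float
    n_reads_emitted: int
    n_mutant_templates: int

    def __post_init__(self) -> None:
        if self.n_mutant_templates > self.n_reads_emitted:
            raise ValueError("n_mutant_templates exceeds n_reads_emitted")


def _simulate_block(
    config: SimConfig, s_idx: int, a_idx: int
) -> tuple[list[ReadRecord], TruthRecord]:
    """Reads + truth for one sample x amplicon block (vectorised)."""
    sample = config.samples[s_idx]
    design = config.designs[a_idx]
    depth, read_len = sample.depth, config.read_length
    rng = np.random.default_rng([config.seed, s_idx, a_idx])

    mutant = rng.random(depth) < sample.true_vaf  # draw 1
    reverse = rng.random(depth) < config.frac_reverse  # draw 2

    insert = np.tile(seq_to_ascii(design.reference[:read_len]), (depth, 1))
    target_col = design.target_offset - 1
    if target_col < read_len:
        insert[mutant, target_col] = ord(design.alt_base)
    if np.any(reverse):
        insert[reverse] = complement_ascii(insert[reverse])[:, ::-1]

    barcode = np.tile(seq_to_ascii(sample.barcode), (depth, 1))
    full = np.concatenate([barcode, insert], axis=1)

    if config.error_rate > 0:
        err = rng.random(full.shape) < config.error_rate  # draw 3
        n_err = int(err.sum())
        if n_err:
            shifts = rng.integers(1, 4, size=n_err)  # draw 4
            codes = ASCII_TO_CODE[full[err]].astype(np.int64)
            full[err] = CODE_TO_ASCII[(codes + shifts) % 4]

    quality = QUALITY_CHAR * full.shape[1]
    reads = [
        ReadRecord(
            f"{sample.sample_id}:{design.amplicon_id}:{i}",
            row.tobytes().decode("ascii"),
            quality,
        )
        for i, row in enumerate(full)
    ]
    truth = TruthRecord(
        sample_id=sample.sample_id,
        amplicon_id=design.amplicon_id,
        true_vaf=sample.true_vaf,
        n_reads_emitted=depth,
        n_mutant_templates=int(mutant.sum()),
    )
    return reads, truth


def simulate_amplicon_reads(
    config: SimConfig,
) -> tuple[list[ReadRecord], list[TruthRecord]]:
    """Simulate barcoded amplicon reads with a spiked mosaic variant.

    Per sample x amplicon, exactly ``depth`` reads are emitted.  Each
    read's template carries the alternative base at the target locus
    with probability ``true_vaf``; every base of the barcoded read is
    then independently substituted (uniformly to one of the three other
    bases) with probability ``error_rate``.  Roughly half the reads
    (``frac_reverse``) are emitted as the reverse complement of the
    template.  Identical config (including seed) reproduces identical
    output byte for byte.
    """
    reads: list[ReadRecord] = []
    truths: list[TruthRecord] = []
    for s_idx in range(len(config.samples)):
        for a_idx in range(len(config.designs)):
            block_reads, truth = _simulate_block(config, s_idx, a_idx)
            reads.extend(block_reads)
            truths.append(truth)
    return reads, truths


def write_truth_tsv(truths: Iterable[TruthRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "sample_id\tamplicon_id\ttrue_vaf\tn_reads_emitted\tn_mutant_templates\n"
        )
        for t in truths:
            fh.write(
                f"{t.sample_id}\t{t.amplicon_id}\t{t.true_vaf!r}\t"
                f"{t.n_reads_emitted}\t{t.n_mutant_templates}\n"
            )


# --- exome-style annotated site tables ------------------------------------

#: Site classes and their default mixture weights.  "survivor" sites are
#: constructed to pass every cascade rule; the rest populate the failure
#: modes (germline heterozygotes, common polymorphisms, weakly conserved
#: or under-supported somatic sites, and bare sequencing noise).
_SITE_CLASSES = (
    "survivor",
    "germline_het",
    "common_snp",
    "somatic_low_conservation",
    "somatic_low_alt",
    "noise",
)
_DEFAULT_WEIGHTS = (0.01, 0.25, 0.14, 0.05, 0.05, 0.50)

_CONTIGS = tuple(f"chr{i}" for i in range(1, 23))


@dataclass
class VariantTableSim:
    """Paired site tables + annotations + independently computed truth."""

    affected_sites: list[SiteCounts]
    unaffected_sites: list[SiteCounts]
    annotations: dict[VariantKey, SiteAnnotation]
    truth_survivor_keys: list[VariantKey]
    planted_survivor_keys: list[VariantKey] = field(default_factory=list)


def _truth_survivors(
    affected: Sequence[SiteCounts],
    unaffected: Sequence[SiteCounts],
    annotations: dict[VariantKey, SiteAnnotation],
) -> list[VariantKey]:
    """Independent row-by-row restatement of the default cascade.

    Deliberately written as straight-line threshold checks (literal
    numbers, no shared code with the filtration module) so it can serve
    as an oracle for it.
    """
    unaff_by_site = {(s.contig, s.position): s for s in unaffected}
    survivors: list[VariantKey] = []
    for site in affected:
        for base in "ACGT":
            if base == site.ref_base:
                continue
            alt = site.counts.get(base, 0)
            if alt < 3:  # calling rule: >= 3 reads
                continue
            if alt < 15:  # affected filter: at least 15
                continue
            key = (site.contig, site.position, base)
            ann = annotations.get(key)
            pop_af = 0.0 if ann is None or ann.pop_af is None else ann.pop_af
            if not pop_af < 0.01:  # below 1%
                continue
            cons = None if ann is None else ann.conservation_score
            if cons is None or not cons > 5:  # above 5; missing fails
                continue
            unaff = unaff_by_site.get((site.contig, site.position))
            unaff_alt = 0 if unaff is None else unaff.counts.get(base, 0)
            if unaff_alt > 5:  # matched-normal subtraction: over 5
                continue
            survivors.append(key)
    return survivors


def _make_counts(
    rng: np.random.Generator, ref: str, alt: str, depth: int, alt_count: int
) -> dict[str, int]:
    """Base tally with ``alt_count`` alt reads plus trace noise elsewhere."""
    counts = {b: 0 for b in "ACGT"}
    others = [b for b in "ACGT" if b not in (ref, alt)]
    noise = rng.binomial(depth, 3e-4, size=2)
    alt_count = min(alt_count, depth - int(noise.sum()))
    counts[alt] = alt_count
    for b, n in zip(others, noise):
        counts[b] = int(n)
    counts[ref] = depth - alt_count - int(noise.sum())
    return counts


def simulate_variant_table(
    n_sites: int,
    seed: int,
    class_weights: Sequence[float] = _DEFAULT_WEIGHTS,
    mean_depth: int = 400,
) -> VariantTableSim:
    """Simulate paired annotated site tables with known cascade truth.

    Emulates ~400x whole-exome base counts over ``n_sites`` positions in
    lesional ("affected") and matched non-lesional tissue, with a small
    planted fraction of genuine somatic survivors among germline
    heterozygotes, common polymorphisms and noise.  The returned
    ``truth_survivor_keys`` are recomputed per row by an independent
    threshold check; ``planted_survivor_keys`` are the sites constructed
    to survive.
    """
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    if len(class_weights) != len(_SITE_CLASSES):
        raise ValueError(f"class_weights must have {len(_SITE_CLASSES)} entries")
    rng = np.random.default_rng([seed, 2_000_003])
    weights = np.asarray(class_weights, dtype=float)
    weights = weights / weights.sum()
    classes = rng.choice(len(_SITE_CLASSES), size=n_sites, p=weights)

    affected: list[SiteCounts] = []
    unaffected: list[SiteCounts] = []
    annotations: dict[VariantKey, SiteAnnotation] = {}
    planted: list[VariantKey] = []

    for i in range(n_sites):
        cls = _SITE_CLASSES[classes[i]]
        contig = _CONTIGS[i % len(_CONTIGS)]
        position = 10_000 + 100 * (i // len(_CONTIGS) + 1)
        ref, alt = [str(b) for b in rng.choice(list("ACGT"), size=2, replace=False)]
        depth_a = max(50, int(rng.poisson(mean_depth)))
        depth_u = max(50, int(rng.poisson(mean_depth)))
        key = (contig, position, alt)

        pop_af: float | None = None
        cons: float | None = float(rng.uniform(-5, 6.5))
        if cls == "survivor":
            vaf = rng.uniform(0.05, 0.3)
            alt_a = max(15, int(rng.binomial(depth_a, vaf)))
            alt_u = min(5, int(rng.binomial(depth_u, 2e-3)))
            pop_af = None if rng.random() < 0.7 else float(rng.uniform(0, 0.009))
            cons = float(rng.uniform(5.05, 6.4))
            planted.append(key)
        elif cls == "germline_het":
            alt_a = int(rng.binomial(depth_a, 0.5))
            alt_u = int(rng.binomial(depth_u, 0.5))
            pop_af = float(rng.uniform(0, 0.6))
        elif cls == "common_snp":
            het = rng.random() < 0.7
            p = 0.5 if het else 1.0
            alt_a = int(rng.binomial(depth_a, p))
            alt_u = int(rng.binomial(depth_u, p))
            pop_af = float(rng.uniform(0.01, 0.5))
        elif cls == "somatic_low_conservation":
            alt_a = max(15, int(rng.binomial(depth_a, rng.uniform(0.05, 0.3))))
            alt_u = int(rng.binomial(depth_u, 2e-3))
            pop_af = None
            cons = float(rng.uniform(-5, 5.0))
        elif cls == "somatic_low_alt":
            alt_a = int(rng.binomial(depth_a, 0.015))
            alt_u = int(rng.binomial(depth_u, 1e-3))
            pop_af = None
            cons = float(rng.uniform(4, 6.4))
        else:  # noise
            alt_a = int(rng.binomial(depth_a, 1.5e-3))
            alt_u = int(rng.binomial(depth_u, 1.5e-3))
            pop_af = None
            if rng.random() < 0.3:
                cons = None

        affected.append(
            SiteCounts(contig, position, ref, _make_counts(rng, ref, alt, depth_a, alt_a))
        )
        unaffected.append(
            SiteCounts(contig, position, ref, _make_counts(rng, ref, alt, depth_u, alt_u))
        )
        annotations[key] = SiteAnnotation(
            pop_af=pop_af,
            conservation_score=cons,
            gene=f"GENE{i:04d}",
            effect="missense",
        )

    truth = _truth_survivors(affected, unaffected, annotations)
    return VariantTableSim(
        affected_sites=affected,
        unaffected_sites=unaffected,
        annotations=annotations,
        truth_survivor_keys=truth,
        planted_survivor_keys=planted,
    )
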