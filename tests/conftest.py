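"""Shared fixtures and independent oracles for the pipeline tests.

The oracle functions here are deliberately naive (plain Python loops,
literal thresholds) and share no code with the implementation they
check.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ampmosaic import (
    AmpliconDesign,
    BarcodeMap,
    SampleSpec,
    SimConfig,
    clean_alignments,
    count_bases_at,
    demultiplex,
    simulate_amplicon_reads,
)
from ampmosaic.align import align_reads

settings.register_profile(
    "ci",
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")

# 77 bp amplicon with the interrogated SNV (G>A) at offset 35.
REFERENCE = "AGTCCTGACTTCAACTCTGGGCATCCTGTTCTCAGTGCCCTCATAGGTGTTCAGACCAAGGTCGGAACAGCTTAAGC"
TARGET_OFFSET = 35
BARCODES = [
    "ACGTAC", "TGCATG", "GATCGA", "CTAGCT", "GGCCAA", "TTAACC",
    "AACCGG", "CCGGTT", "AGAGTC", "TCTCAG", "GTGTCA", "CACAGT",
]


@pytest.fixture(scope="session")
def design() -> AmpliconDesign:
    return AmpliconDesign(
        amplicon_id="GNAQ_c548",
        reference=REFERENCE,
        target_offset=TARGET_OFFSET,
        ref_base=REFERENCE[TARGET_OFFSET - 1],
        alt_base="A",
    )


def make_sim_config(
    design: AmpliconDesign,
    vafs: list[float],
    depth: int,
    error_rate: float,
    seed: int,
    read_length: int = 50,
) -> SimConfig:
    samples = [
        SampleSpec(f"S{i:02d}", BARCODES[i], vaf, depth)
        for i, vaf in enumerate(vafs)
    ]
    return SimConfig(
        designs=[design],
        samples=samples,
        error_rate=error_rate,
        read_length=read_length,
        seed=seed,
    )


def run_locus_pipeline(config: SimConfig):
    """simulate -> demux -> align -> clean -> pileup at the target locus.

    Returns (pileups: sample_id -> PileupCounts, truths: list[TruthRecord]).
    """
    reads, truths = simulate_amplicon_reads(config)
    bmap = BarcodeMap({s.sample_id: s.barcode for s in config.samples})
    bins = demultiplex(reads, bmap)
    pileups = {}
    for design in config.designs:
        for sample in config.samples:
            records = align_reads(bins[sample.sample_id], design)
            cleaned, _ = clean_alignments([r for r in records if r is not None])
            pileups[sample.sample_id] = count_bases_at(
                cleaned, design, design.target_offset
            )
    return pileups, truths


# --- independent oracles ---------------------------------------------------

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def oracle_revcomp(seq: str) -> str:
    return "".join(_COMP[c] for c in reversed(seq))


def oracle_align(read_seq: str, reference: str):
    """Exhaustive sliding-window placement: returns
    (start, strand, mismatches, n_best) or None if read does not fit."""
    n, m = len(reference), len(read_seq)
    if m == 0 or m > n:
        return None
    best = None
    n_best = 0
    # enumeration order realises the tie-break: starts ascending, '+' first
    for start in range(1, n - m + 2):
        window = reference[start - 1 : start - 1 + m]
        for strand, seq in (("+", read_seq), ("-", oracle_revcomp(read_seq))):
            mm = sum(a != b for a, b in zip(window, seq))
            if best is None or mm < best[2]:
                best = (start, strand, mm)
                n_best = 1
            elif mm == best[2]:
                n_best += 1
    return best[0], best[1], best[2], n_best


def oracle_count_bases(records, position: int):
    """Brute-force per-column recount over aligned_pairs."""
    counts = {"A": 0, "C": 0, "G": 0, "T": 0, "N": 0}
    for rec in records:
        for pos, base in rec.aligned_pairs():
            if pos == position:
                counts[base] += 1
    return counts


def oracle_cascade_row(
    aff_counts: dict, ref: str, unaff_counts: dict, ann
) -> list[str]:
    """Literal restatement of the filtration cascade for one site.

    Returns surviving alt bases.  ``ann`` maps alt base -> (pop_af,
    conservation) with None for MISSING.
    """
    survivors = []
    for base in "ACGT":
        if base == ref:
            continue
        alt = aff_counts.get(base, 0)
        if alt < 3 or alt < 15:
            continue
        pop_af, cons = ann.get(base, (None, None))
        if pop_af is not None and pop_af >= 0.01:
            continue
        if cons is None or cons <= 5:
            continue
        if unaff_counts.get(base, 0) > 5:
            continue
        survivors.append(base)
    return survivors


def oracle_salt_bridges(atoms, chain_a, chain_b, max_dist):
    """All-pairs search with the cation/anion atom whitelist."""
    cation = {"LYS": {"NZ"}, "ARG": {"NH1", "NH2", "NE"}, "HIS": {"ND1", "NE2"}}
    anion = {"ASP": {"OD1", "OD2"}, "GLU": {"OE1", "OE2"}}
    pairs = set()
    for a in atoms:
        for b in atoms:
            if {a.chain_id, b.chain_id} != {chain_a, chain_b}:
                continue
            if a.chain_id == b.chain_id:
                continue
            if a.residue_name in cation and a.atom_name in cation[a.residue_name] \
                    and b.residue_name in anion and b.atom_name in anion[b.residue_name]:
                d = float(
                    np.sqrt((a.x - b.x) ** 2 + (a.y - b.y) ** 2 + (a.z - b.z) ** 2)
                )
                if d <= max_dist:
                    pairs.add(
                        (
                            (a.chain_id, a.residue_name, a.residue_number, a.atom_name),
                            (b.chain_id, b.residue_name, b.residue_number, b.atom_name),
                        )
                    )
    return pairs
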