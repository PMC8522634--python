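"""Published ultra-deep amplicon tallies for the two mosaic SNV loci.

These are the reported MiSeq base counts at GNAQ (NM_002072.3):c.548
(ref G, mut A) and GNB2 (NM_005273.3):c.232 (ref A, mut G) from a
six-patient Sturge–Weber syndrome cohort: per sample, the total depth
and the reads supporting each of the four bases, together with the
mutation frequency the report printed (percent, two decimals) and —
where the report states it — whether the sample was deemed
mutation-positive.  They serve as ground truth for the VAF arithmetic
and for calibrating the positivity rule; the `stated_call` of samples
the report leaves ambiguous is ``None``.
"""

from __future__ import annotations

from dataclasses import dataclass

from .pileup import PileupCounts


@dataclass(frozen=True)
class PublishedRow:
    patient: str
    sample: str
    locus: str  # "GNAQ_c548" or "GNB2_c232"
    ref_base: str
    alt_base: str
    printed_percent: str  # as printed, 2 decimals
    depth: int
    ref_count: int
    alt_count: int
    t_count: int
    c_count: int
    stated_call: str | None  # "positive" | "negative" | None (not stated)

    def to_pileup(self) -> PileupCounts:
        counts = {b: 0 for b in "ACGT"}
        counts[self.ref_base] = self.ref_count
        counts[self.alt_base] = self.alt_count
        # off-target columns are printed as T and C for both loci
        counts["T"] += self.t_count
        counts["C"] += self.c_count
        return PileupCounts(
            amplicon_id=self.locus, position=1, ref_base=self.ref_base,
            counts=counts,
        )


def _gnaq(patient, sample, pct, depth, g, a, t, c, call) -> PublishedRow:
    return PublishedRow(patient, sample, "GNAQ_c548", "G", "A", pct,
                        depth, g, a, t, c, call)


def _gnb2(patient, sample, pct, depth, a, g, t, c, call) -> PublishedRow:
    return PublishedRow(patient, sample, "GNB2_c232", "A", "G", pct,
                        depth, a, g, t, c, call)


#: GNAQ:c.548G>A tallies across affected samples (12 rows).
GNAQ_ROWS: tuple[PublishedRow, ...] = (
    _gnaq("1", "Endothelial cell culture", "14.36", 130_299, 111_585, 18_709, 4, 1, "positive"),
    _gnaq("2", "Dermis", "7.08", 128_341, 119_233, 9_091, 16, 1, "positive"),
    _gnaq("2", "Endothelial cell culture", "9.28", 100_355, 91_036, 9_314, 5, 0, "positive"),
    _gnaq("2", "LCM endothelium", "29.88", 60_684, 42_552, 18_131, 1, 0, "positive"),
    _gnaq("3", "Endothelial cell culture", "0.01", 99_182, 99_159, 14, 6, 3, "negative"),
    _gnaq("3", "Dermis", "0.01", 131_325, 131_300, 16, 8, 1, "negative"),
    _gnaq("4", "Dermis", "7.39", 135_365, 125_357, 9_998, 8, 2, "positive"),
    _gnaq("4", "Endothelial cell culture 1", "0.24", 113_991, 113_714, 269, 5, 3, "positive"),
    _gnaq("4", "Endothelial cell culture 2", "0.13", 143_019, 142_825, 189, 4, 1, None),
    _gnaq("5", "Dermis", "8.98", 147_823, 134_533, 13_276, 12, 2, "positive"),
    _gnaq("6", "Dermis", "5.72", 99_490, 93_794, 5_694, 0, 2, "positive"),
    _gnaq("6", "LCM endothelium", "19.93", 192_942, 154_496, 38_444, 0, 2, "positive"),
)

#: GNB2:c.232A>G tallies in samples from the GNAQ-negative patient (6 rows).
GNB2_ROWS: tuple[PublishedRow, ...] = (
    _gnb2("3", "Affected dermis", "3.59", 91_041, 87_769, 3_265, 7, 0, "positive"),
    _gnb2("3", "Affected endothelial cell culture", "20.74", 71_630, 56_771, 14_858, 1, 0, "positive"),
    _gnb2("3", "Affected fibroblast cell culture", "0.02", 112_155, 112_128, 19, 8, 0, "negative"),
    _gnb2("3", "Affected keratinocyte cell culture", "0.01", 129_481, 129_464, 13, 4, 0, "negative"),
    _gnb2("3", "Unaffected dermis", "0.15", 133_486, 133_264, 206, 15, 1, "negative"),
    _gnb2("3", "Unaffected fibroblast cell culture", "0.01", 53_404, 53_400, 3, 1, 0, "negative"),
)

ALL_ROWS: tuple[PublishedRow, ...] = GNAQ_ROWS + GNB2_ROWS

#: Percentages quoted in running text at coarser rounding:
#: (alt_count, depth, decimals, printed value).
PROSE_PERCENTAGES: tuple[tuple[int, int, int, str], ...] = (
    (3_265, 91_041, 1, "3.6"),     # lesional dermis, GNB2 validation
    (14_858, 71_630, 0, "21"),     # lesional endothelial culture, GNB2
    (206, 133_486, 2, "0.15"),     # non-lesional dermis, GNB2
    (34, 564, 0, "6"),             # exome discovery read fraction, GNB2
    (18_131, 60_684, 0, "30"),     # LCM endothelium, patient 2, GNAQ
    (38_444, 192_942, 0, "20"),    # LCM endothelium, patient 6, GNAQ
)

#: Exome discovery site: the candidate was supported by 34 of 564 reads.
EXOME_CANDIDATE_ALT = 34
EXOME_CANDIDATE_DEPTH = 564
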