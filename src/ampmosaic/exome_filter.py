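"""Exome-stage candidate calling and paired affected/unaffected filtration.

This stage emulates the discovery route for a somatic candidate in deep
(~400x) whole-exome data from a lesional biopsy with a matched
non-lesional ("unaffected") biopsy from the same individual:

1. **Calling** — a variant is called at a site wherever three or more
   reads show the same non-reference allele (a site can therefore yield
   up to three variants, one per alternative base).
2. **Affected-tissue filters** — keep a variant only if its alternative
   read count is at least 15, its population allele frequency is below
   1%, and its conservation (GERP) score is above 5.
3. **Matched-normal subtraction** — drop any remaining variant whose
   (contig, position, alt) key appears in the unaffected tissue with an
   alternative read count over 5.

Boundary semantics are taken literally: "at least 15" is inclusive;
"below 1%", "above 5" and "over 5" are strict.  A missing population
frequency is treated as 0 (absence from the database implies rarity); a
missing conservation score fails the filter (an unscorable site cannot
certify the threshold).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

from ._seq import DNA_BASES

VariantKey = tuple[str, int, str]


@dataclass(frozen=True)
class SiteCounts:
    """Per-site base tally from a cleaned alignment (exome flavour)."""

    contig: str
    position: int  # 1-based
    ref_base: str
    counts: Mapping[str, int]

    def __post_init__(self) -> None:
        if self.ref_base not in DNA_BASES:
            raise ValueError(f"ref_base {self.ref_base!r} not one of A/C/G/T")
        if any(self.counts.get(b, 0) < 0 for b in DNA_BASES):
            raise ValueError("negative base count")

    @property
    def depth(self) -> int:
        return sum(self.counts.get(b, 0) for b in DNA_BASES)


@dataclass(frozen=True)
class AnnotatedVariant:
    """A candidate variant with the annotations the cascade consumes.

    ``pop_af`` / ``conservation_score`` are ``None`` while un-annotated
    (the calling step emits them MISSING; the annotation join fills them).
    """

    contig: str
    position: int
    ref_base: str
    alt_base: str
    alt_count: int
    depth: int
    pop_af: float | None = None
    conservation_score: float | None = None
    gene: str = ""
    effect: str = ""

    def __post_init__(self) -> None:
        if self.alt_base == self.ref_base:
            raise ValueError("alt_base equals ref_base")
        if self.alt_count > self.depth:
            raise ValueError("alt_count exceeds depth")
        if self.pop_af is not None and not 0.0 <= self.pop_af <= 1.0:
            raise ValueError(f"pop_af {self.pop_af} outside [0, 1]")

    @property
    def key(self) -> VariantKey:
        return (self.contig, self.position, self.alt_base)


@dataclass(frozen=True)
class SiteAnnotation:
    """External annotation for one (contig, position, alt) key."""

    pop_af: float | None = None
    conservation_score: float | None = None
    gene: str = ""
    effect: str = ""


@dataclass(frozen=True)
class FilterConfig:
    call_min_alt: int = 3
    affected_min_alt: int = 15  # inclusive ("at least")
    max_pop_af: float = 0.01  # strict ("below")
    min_conservation: float = 5.0  # strict ("above")
    unaffected_subtract_min_alt: int = 5  # strict ("over")

    def __post_init__(self) -> None:
        for name in (
            "call_min_alt",
            "affected_min_alt",
            "max_pop_af",
            "min_conservation",
            "unaffected_subtract_min_alt",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def call_candidate_sites(
    sites: Iterable[SiteCounts], call_min_alt: int = 3
) -> list[AnnotatedVariant]:
    """Call one variant per (site, non-reference base) with enough reads.

    The calling rule is a plain read-count threshold: a non-reference
    base seen on ``call_min_alt`` or more reads at a site becomes a
    candidate.  Annotations are left MISSING.
    """
    out: list[AnnotatedVariant] = []
    for site in sites:
        depth = site.depth
        for base in DNA_BASES:
            if base == site.ref_base:
                continue
            n = site.counts.get(base, 0)
            if n >= call_min_alt:
                out.append(
                    AnnotatedVariant(
                        contig=site.contig,
                        position=site.position,
                        ref_base=site.ref_base,
                        alt_base=base,
                        alt_count=n,
                        depth=depth,
                    )
                )
    return out


def annotate_variants(
    variants: Iterable[AnnotatedVariant],
    annotations: Mapping[VariantKey, SiteAnnotation],
) -> list[AnnotatedVariant]:
    """Join annotations onto variants by (contig, position, alt) key.

    Keys absent from the table leave the variant's annotations MISSING.
    """
    out = []
    for v in variants:
        ann = annotations.get(v.key)
        if ann is None:
            out.append(v)
        else:
            out.append(
                replace(
                    v,
                    pop_af=ann.pop_af,
                    conservation_score=ann.conservation_score,
                    gene=ann.gene,
                    effect=ann.effect,
                )
            )
    return out


def filter_affected(
    variants: Sequence[AnnotatedVariant], config: FilterConfig = FilterConfig()
) -> tuple[list[AnnotatedVariant], dict[str, int]]:
    """Apply the affected-tissue thresholds; returns (kept, removal tally).

    A variant failing several rules is tallied once under the first rule
    that rejects it (alt count, then population AF, then conservation).
    """
    kept: list[AnnotatedVariant] = []
    tally = {"low_alt_count": 0, "common_in_population": 0, "low_conservation": 0}
    for v in variants:
        if v.alt_count < config.affected_min_alt:
            tally["low_alt_count"] += 1
            continue
        pop_af = 0.0 if v.pop_af is None else v.pop_af
        if not pop_af < config.max_pop_af:
            tally["common_in_population"] += 1
            continue
        if v.conservation_score is None or not (
            v.conservation_score > config.min_conservation
        ):
            tally["low_conservation"] += 1
            continue
        kept.append(v)
    return kept, tally


def _check_unique_keys(variants: Sequence[AnnotatedVariant], label: str) -> None:
    seen: set[VariantKey] = set()
    for v in variants:
        if v.key in seen:
            raise ValueError(f"duplicate variant key {v.key} in {label} list")
        seen.add(v.key)


def subtract_unaffected(
    affected: Sequence[AnnotatedVariant],
    unaffected: Sequence[AnnotatedVariant],
    config: FilterConfig = FilterConfig(),
) -> list[AnnotatedVariant]:
    """Remove affected variants also present in the matched normal.

    An affected variant is dropped iff the same (contig, position, alt)
    key occurs in the unaffected list with ``alt_count`` strictly over
    ``unaffected_subtract_min_alt``.  Survivor order is preserved.
    """
    _check_unique_keys(affected, "affected")
    _check_unique_keys(unaffected, "unaffected")
    blocked = {
        v.key
        for v in unaffected
        if v.alt_count > config.unaffected_subtract_min_alt
    }
    return [v for v in affected if v.key not in blocked]


@dataclass
class CascadeResult:
    candidates: list[AnnotatedVariant]
    stage_tallies: dict[str, int] = field(default_factory=dict)


def run_cascade(
    affected_sites: Iterable[SiteCounts],
    unaffected_sites: Iterable[SiteCounts],
    annotations: Mapping[VariantKey, SiteAnnotation],
    config: FilterConfig = FilterConfig(),
) -> CascadeResult:
    """Full discovery cascade: call -> annotate -> filter -> subtract.

    The canonical order applies the affected-tissue filters before the
    matched-normal subtraction.  Per-stage survivor counts are logged in
    ``stage_tallies`` for reporting.
    """
    called = call_candidate_sites(affected_sites, config.call_min_alt)
    annotated = annotate_variants(called, annotations)
    filtered, removal = filter_affected(annotated, config)
    unaffected_called = call_candidate_sites(unaffected_sites, config.call_min_alt)
    survivors = subtract_unaffected(filtered, unaffected_called, config)
    tallies = {
        "called": len(called),
        "after_affected_filters": len(filtered),
        "after_unaffected_subtraction": len(survivors),
        **{f"removed_{k}": v for k, v in removal.items()},
        "removed_in_unaffected": len(filtered) - len(survivors),
    }
    return CascadeResult(candidates=survivors, stage_tallies=tallies)


# --- TSV I/O ---------------------------------------------------------------

def read_site_counts_tsv(path) -> list[SiteCounts]:
    """Read a site-count TSV: contig, pos, ref, A, C, G, T (header line)."""
    sites = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("contig"):
            raise ValueError("site-count TSV must start with a 'contig...' header")
        for line in fh:
            if not line.strip():
                continue
            contig, pos, ref, a, c, g, t = line.rstrip("\n").split("\t")[:7]
            sites.append(
                SiteCounts(
                    contig,
                    int(pos),
                    ref,
                    {"A": int(a), "C": int(c), "G": int(g), "T": int(t)},
                )
            )
    return sites


def write_site_counts_tsv(sites: Iterable[SiteCounts], path) -> None:
    with open(path, "w") as fh:
        fh.write("contig\tpos\tref\tA\tC\tG\tT\n")
        for s in sites:
            fh.write(
                f"{s.contig}\t{s.position}\t{s.ref_base}\t"
                + "\t".join(str(s.counts.get(b, 0)) for b in DNA_BASES)
                + "\n"
            )


def read_annotations_tsv(path) -> dict[VariantKey, SiteAnnotation]:
    """Read annotation TSV: contig, pos, alt, pop_af, conservation, gene, effect.

    Empty pop_af / conservation fields mean MISSING.
    """
    table: dict[VariantKey, SiteAnnotation] = {}
    with open(path) as fh:
        fh.readline()  # header
        for line in fh:
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            contig, pos, alt, pop_af, cons = fields[:5]
            gene = fields[5] if len(fields) > 5 else ""
            effect = fields[6] if len(fields) > 6 else ""
            table[(contig, int(pos), alt)] = SiteAnnotation(
                pop_af=float(pop_af) if pop_af else None,
                conservation_score=float(cons) if cons else None,
                gene=gene,
                effect=effect,
            )
    return table


def write_annotations_tsv(
    annotations: Mapping[VariantKey, SiteAnnotation], path
) -> None:
    with open(path, "w") as fh:
        fh.write("contig\tpos\talt\tpop_af\tconservation\tgene\teffect\n")
        for (contig, pos, alt), ann in annotations.items():
            af = "" if ann.pop_af is None else repr(ann.pop_af)
            cons = (
                ""
                if ann.conservation_score is None
                else repr(ann.conservation_score)
            )
            fh.write(
                f"{contig}\t{pos}\t{alt}\t{af}\t{cons}\t{ann.gene}\t{ann.effect}\n"
            )


def write_candidates_tsv(variants: Iterable[AnnotatedVariant], path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "contig\tpos\tref\talt\talt_count\tdepth\tpop_af\tconservation"
            "\tgene\teffect\n"
        )
        for v in variants:
            af = "" if v.pop_af is None else repr(v.pop_af)
            cons = (
                ""
                if v.conservation_score is None
                else repr(v.conservation_score)
            )
            fh.write(
                f"{v.contig}\t{v.position}\t{v.ref_base}\t{v.alt_base}\t"
                f"{v.alt_count}\t{v.depth}\t{af}\t{cons}\t{v.gene}\t{v.effect}\n"
            )
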