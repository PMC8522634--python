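"""Tests for candidate calling and the paired filtration cascade."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ampmosaic import (
    AnnotatedVariant,
    FilterConfig,
    SiteAnnotation,
    SiteCounts,
    call_candidate_sites,
    filter_affected,
    run_cascade,
    simulate_variant_table,
    subtract_unaffected,
)
from ampmosaic.exome_filter import (
    annotate_variants,
    read_annotations_tsv,
    read_site_counts_tsv,
    write_annotations_tsv,
    write_site_counts_tsv,
)


def _site(contig="chr1", pos=100, ref="A", **kw) -> SiteCounts:
    counts = {"A": 0, "C": 0, "G": 0, "T": 0}
    counts.update(kw)
    return SiteCounts(contig, pos, ref, counts)


def _variant(alt_count, depth=500, pop_af=None, cons=None, key=("chr1", 100, "G")):
    return AnnotatedVariant(
        contig=key[0], position=key[1], ref_base="A", alt_base=key[2],
        alt_count=alt_count, depth=depth, pop_af=pop_af,
        conservation_score=cons,
    )


def test_discovery_site_called_with_expected_support():
    """34 alt reads at a 564-read site yield one A>G candidate."""
    variants = call_candidate_sites([_site(A=530, G=34)], call_min_alt=3)
    assert len(variants) == 1
    v = variants[0]
    assert (v.ref_base, v.alt_base, v.alt_count, v.depth) == ("A", "G", 34, 564)


def test_two_reads_below_call_rule():
    assert call_candidate_sites([_site(A=562, G=2)]) == []


def test_site_can_yield_multiple_variants():
    """Two non-reference bases each with >= 3 reads give two variants;
    per-base enumeration agrees with a direct threshold check."""
    site = _site(A=500, G=3, T=3, C=2)
    variants = call_candidate_sites([site])
    assert {(v.alt_base, v.alt_count) for v in variants} == {("G", 3), ("T", 3)}
    for min_alt in range(1, 6):
        got = {v.alt_base for v in call_candidate_sites([site], min_alt)}
        expected = {
            b for b in "CGT" if site.counts[b] >= min_alt
        }
        assert got == expected


def test_affected_filter_boundary_semantics():
    """'at least 15' is inclusive; 'below 1%' and 'above 5' are strict."""
    kept, _ = filter_affected([_variant(15, pop_af=0.0, cons=5.01)])
    assert len(kept) == 1
    for bad in (
        _variant(14, pop_af=0.0, cons=6.0),
        _variant(15, pop_af=0.01, cons=6.0),  # exactly 1% is not below 1%
        _variant(15, pop_af=0.0, cons=5.0),  # exactly 5 is not above 5
    ):
        kept, _ = filter_affected([bad])
        assert kept == []


def test_missing_annotation_policy():
    """Missing population AF counts as rare; missing conservation fails."""
    kept, _ = filter_affected([_variant(34, pop_af=None, cons=5.5)])
    assert len(kept) == 1
    kept, tally = filter_affected([_variant(34, pop_af=None, cons=None)])
    assert kept == [] and tally["low_conservation"] == 1


def test_affected_filter_matches_predicate_oracle():
    """1000 random variants: survivors equal a row-wise brute-force
    recheck of the three thresholds."""
    rng = np.random.default_rng(31)
    variants = []
    for i in range(1_000):
        depth = int(rng.integers(30, 800))
        variants.append(
            AnnotatedVariant(
                contig="chr1", position=i + 1, ref_base="A", alt_base="G",
                alt_count=int(rng.integers(0, depth + 1)), depth=depth,
                pop_af=None if rng.random() < 0.3 else float(rng.uniform(0, 0.05)),
                conservation_score=(
                    None if rng.random() < 0.2 else float(rng.uniform(-5, 7))
                ),
            )
        )
    config = FilterConfig()
    kept, _ = filter_affected(variants, config)
    expected = [
        v for v in variants
        if v.alt_count >= 15
        and (v.pop_af or 0.0) < 0.01
        and v.conservation_score is not None
        and v.conservation_score > 5
    ]
    assert kept == expected


def test_subtraction_boundary_is_strictly_over_five():
    affected = [_variant(34, pop_af=0.0, cons=5.5)]
    for unaff_alt, survives in ((0, True), (5, True), (6, False)):
        unaffected = [_variant(unaff_alt)] if unaff_alt else []
        out = subtract_unaffected(affected, unaffected)
        assert (len(out) == 1) is survives


def test_subtraction_requires_matching_key():
    affected = [_variant(34, key=("chr1", 100, "G"))]
    unaffected = [_variant(50, key=("chr1", 100, "T"))]  # different alt
    assert subtract_unaffected(affected, unaffected) == affected


def test_duplicate_keys_rejected():
    with pytest.raises(ValueError, match="duplicate"):
        subtract_unaffected([_variant(20), _variant(30)], [])


def test_subtraction_matches_keyed_set_difference():
    """Random paired tables equal the keyed set-difference oracle."""
    rng = np.random.default_rng(37)
    keys = [("chr%d" % rng.integers(1, 5), int(p), "G") for p in rng.choice(10_000, 300, replace=False)]
    affected = [_variant(int(rng.integers(15, 100)), key=k) for k in keys[:200]]
    unaffected = [_variant(int(rng.integers(0, 30)), key=k) for k in keys[100:]]
    out = subtract_unaffected(affected, unaffected)
    blocked = {v.key for v in unaffected if v.alt_count > 5}
    assert out == [v for v in affected if v.key not in blocked]


def test_cascade_finds_planted_survivors():
    """With a fixed seed, exactly the planted somatic sites emerge from
    the full cascade on a 500-site paired table."""
    sim = simulate_variant_table(500, seed=123)
    result = run_cascade(sim.affected_sites, sim.unaffected_sites, sim.annotations)
    got = [v.key for v in result.candidates]
    assert got == sim.truth_survivor_keys
    assert set(got) == set(sim.planted_survivor_keys)
    assert result.stage_tallies["after_unaffected_subtraction"] == len(got)


def test_empty_cascade():
    result = run_cascade([], [], {})
    assert result.candidates == []
    assert result.stage_tallies["called"] == 0


@given(
    affected_min_alt=st.integers(15, 60),
    max_pop_af=st.floats(0.0, 0.01),
    min_conservation=st.floats(5.0, 7.0),
    unaffected_min=st.integers(0, 5),
    call_min=st.integers(3, 10),
)
def test_tightening_thresholds_never_adds_survivors(
    affected_min_alt, max_pop_af, min_conservation, unaffected_min, call_min
):
    """Monotonicity: any configuration at least as strict as the default
    yields a subset of the default survivors."""
    sim = simulate_variant_table(300, seed=77)
    base = run_cascade(sim.affected_sites, sim.unaffected_sites, sim.annotations)
    strict = run_cascade(
        sim.affected_sites,
        sim.unaffected_sites,
        sim.annotations,
        FilterConfig(
            call_min_alt=call_min,
            affected_min_alt=affected_min_alt,
            max_pop_af=max_pop_af,
            min_conservation=min_conservation,
            unaffected_subtract_min_alt=unaffected_min,
        ),
    )
    base_keys = {v.key for v in base.candidates}
    strict_keys = {v.key for v in strict.candidates}
    assert strict_keys <= base_keys


def test_annotation_join_and_tsv_roundtrip(tmp_path):
    sites = [_site(A=530, G=34)]
    variants = call_candidate_sites(sites)
    ann = {("chr1", 100, "G"): SiteAnnotation(0.001, 5.6, "GNB2", "missense")}
    annotated = annotate_variants(variants, ann)
    assert annotated[0].pop_af == 0.001
    assert annotated[0].gene == "GNB2"

    sp, ap = tmp_path / "sites.tsv", tmp_path / "ann.tsv"
    write_site_counts_tsv(sites, sp)
    write_annotations_tsv(ann, ap)
    assert read_site_counts_tsv(sp) == sites
    assert read_annotations_tsv(ap) == ann
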