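"""Context classification, upstream distances, replichore assignment, skew."""

import numpy as np
import pytest

from conftest import random_genome
from palcore import (
    Feature,
    FeatureTable,
    GenomeRecord,
    classify_contexts,
    classify_site_context,
    context_summary,
    cumulative_gc_skew,
    replichore_assign,
    replichore_dinucleotide_table,
    upstream_distance,
)
from palcore.motif import revcomp
from palcore.scan import SiteHit


def _site(start, end, mm=0, dinuc="GA"):
    return SiteHit(
        start=start, end=end, mismatches=mm, matched_seq="A" * (end - start + 1),
        central_dinuc=dinuc, orientation="forward",
    )


def _genome(L=1000):
    return GenomeRecord(id="g", sequence="A" * L, circular=True)


def brute_force_context(site, table, L):
    """Independent oracle: test the site against every feature directly."""
    cds = [f for f in table if f.ftype == "CDS"]
    for f in cds:
        if f.start <= site.end and f.end >= site.start:
            return "coding_overlap"
    feats = [f for f in table if f.ftype in ("CDS", "rRNA", "tRNA")]
    if not feats:
        return "edge"
    left = min(feats, key=lambda f: (site.start - f.end - 1) % L)
    right = min(feats, key=lambda f: (f.start - site.end - 1) % L)
    pair = (left.strand, right.strand)
    if pair == ("-", "+"):
        return "intergenic_divergent"
    if pair == ("+", "-"):
        return "intergenic_convergent"
    return "intergenic_codirectional"


class TestClassifySiteContext:
    def test_convergent_between_three_prime_ends(self):
        t = FeatureTable([Feature("a", "CDS", 100, 400, "+"), Feature("b", "CDS", 600, 900, "-")])
        call = classify_site_context(_site(450, 467), t, _genome())
        assert call.cls == "intergenic_convergent"
        assert (call.left_gene, call.right_gene) == ("a", "b")
        assert (call.dist_left, call.dist_right) == (49, 132)

    def test_divergent_between_five_prime_ends(self):
        t = FeatureTable([Feature("a", "CDS", 100, 400, "-"), Feature("b", "CDS", 600, 900, "+")])
        assert classify_site_context(_site(450, 467), t, _genome()).cls == "intergenic_divergent"

    def test_any_overlap_is_coding(self):
        t = FeatureTable([Feature("a", "CDS", 100, 400, "+"), Feature("b", "CDS", 600, 900, "-")])
        assert classify_site_context(_site(395, 412), t, _genome()).cls == "coding_overlap"

    def test_empty_table_is_edge_with_warning(self):
        with pytest.warns(UserWarning, match="edge"):
            call = classify_site_context(_site(10, 27), FeatureTable([]), _genome())
        assert call.cls == "edge"

    def test_matches_brute_force_oracle(self, rng):
        L = 10_000
        g = _genome(L)
        feats = []
        pos = 1
        i = 0
        while pos + 300 < L:
            gap = int(rng.integers(20, 120))
            glen = int(rng.integers(150, 500))
            s = pos + gap
            e = min(s + glen - 1, L - 10)
            feats.append(Feature(f"g{i}", "CDS", s, e, "+-"[int(rng.integers(2))]))
            pos = e + 1
            i += 1
        table = FeatureTable(feats)
        sites = [_site(int(s), int(s) + 17) for s in rng.integers(1, L - 20, size=200)]
        calls = classify_contexts(sites, table, g)
        for call in calls:
            assert call.cls == brute_force_context(call.site, table, L)

    def test_rotation_invariance(self, rng):
        L = 5000
        g = _genome(L)
        feats = [
            Feature("a", "CDS", 200, 900, "+"),
            Feature("b", "CDS", 1000, 1900, "-"),
            Feature("c", "CDS", 2100, 4400, "+"),
        ]
        sites = [_site(950, 967), _site(1950, 1967), _site(4500, 4517), _site(500, 517)]
        base = [c.cls for c in classify_contexts(sites, FeatureTable(feats), g)]
        for r in (100, 1234, 3000):
            coords = [
                (((f.start - 1 + r) % L) + 1, ((f.end - 1 + r) % L) + 1, f)
                for f in feats
            ]
            # skip rotations that split a feature across the origin
            if any(s > e for s, e, _ in coords):
                continue
            rot_feats = [
                Feature(f.locus_tag, f.ftype, s, e, f.strand) for s, e, f in coords
            ]
            rot_sites = [
                _site(((s.start - 1 + r) % L) + 1, ((s.start - 1 + r) % L) + 18)
                for s in sites
            ]
            rotated = [
                c.cls for c in classify_contexts(rot_sites, FeatureTable(rot_feats), g)
            ]
            assert rotated == base

    def test_partition_sums_to_site_count(self, rng):
        L = 5000
        g = _genome(L)
        feats = [Feature(f"g{i}", "CDS", 1 + i * 500, 400 + i * 500, "+") for i in range(9)]
        sites = [_site(int(s), int(s) + 17) for s in rng.integers(1, L - 20, size=77)]
        summary = context_summary(classify_contexts(sites, FeatureTable(feats), g))
        assert sum(summary.values()) == 77


class TestUpstreamDistance:
    def test_plus_strand_gap(self):
        gene = Feature("g", "CDS", 401, 800, "+")
        assert upstream_distance(_site(81, 100), gene) == 300

    def test_adjacent_is_zero(self):
        gene = Feature("g", "CDS", 401, 800, "+")
        assert upstream_distance(_site(383, 400), gene) == 0

    def test_minus_strand_gap(self):
        gene = Feature("g", "CDS", 100, 400, "-")
        assert upstream_distance(_site(501, 518), gene) == 100

    def test_overlap_rejected(self):
        gene = Feature("g", "CDS", 100, 400, "+")
        with pytest.raises(ValueError, match="coding_overlap"):
            upstream_distance(_site(395, 412), gene)


class TestReplichoreAssign:
    @pytest.mark.parametrize(
        "pos,ori,L,expect",
        [(250, 1, 1000, "first"), (501, 1, 1000, "second"),
         (100, 800, 1000, "first"), (500, 800, 1000, "second")],
    )
    def test_examples(self, pos, ori, L, expect):
        assert replichore_assign(pos, ori, L) == expect

    def test_half_sizes(self):
        for L in (10, 11, 1000, 999):
            for ori in (1, 3, L):
                n_first = sum(
                    replichore_assign(p, ori, L) == "first" for p in range(1, L + 1)
                )
                assert n_first == -(-L // 2)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            replichore_assign(0, 1, 100)


class TestReplichoreDinucTable:
    def test_strong_association_detected(self):
        hits = [_site(s, s + 17, dinuc="GA") for s in range(10, 400, 20)] + [
            _site(s, s + 17, dinuc="TC") for s in range(510, 900, 20)
        ]
        table, p = replichore_dinucleotide_table(hits, ori=1, L=1000)
        assert p < 0.01
        assert table.loc["first", "GA"] == 20 and table.loc["second", "TC"] == 20

    def test_independent_assignment_is_null(self, rng):
        pvals = []
        for _ in range(30):
            hits = [
                _site(int(s), int(s) + 17, dinuc=("GA", "TC")[int(rng.integers(2))])
                for s in rng.integers(1, 980, size=60)
            ]
            pvals.append(replichore_dinucleotide_table(hits, 1, 1000)[1])
        assert sum(p < 0.05 for p in pvals) <= 6

    def test_single_site_degenerate(self):
        table, p = replichore_dinucleotide_table([_site(10, 27)], 1, 1000)
        assert p == 1.0 and table.values.sum() == 1


class TestCumulativeGCSkew:
    def test_rise_then_fall(self):
        series, mn, mx = cumulative_gc_skew(GenomeRecord(id="x", sequence="GGGGCCCC"))
        assert mx == 4
        assert series[3] == pytest.approx(0.5)
        assert series[-1] == pytest.approx(0.0)

    def test_no_gc_is_flat(self):
        series, _, _ = cumulative_gc_skew(GenomeRecord(id="x", sequence="ATATAT"))
        assert (series == 0).all()

    def test_revcomp_mirrors_and_flips_sign(self, rng):
        g = random_genome(rng, 500)
        s1, _, _ = cumulative_gc_skew(g)
        s2, _, _ = cumulative_gc_skew(
            GenomeRecord(id="rc", sequence=revcomp(g.sequence))
        )
        # cumulative skew of the reverse complement retraces the original
        # from its far end with opposite sign
        total = s1[-1]
        assert np.allclose(s2[:-1], -(total - s1[:-1][::-1]), atol=1e-12)
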