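"""Genomic context of motif sites: coding overlap, intergenic orientation
classes, upstream distances, and replichore (replication-half) assignment.

Classification rules
--------------------
A site overlapping at least one CDS by one or more bp is ``coding_overlap``.
Otherwise the flanking gene pair (resolved circularly on circular
chromosomes) determines the intergenic class, reading left to right:

* ``(-, +)`` — divergent, a start-to-start interval (promoter-rich);
* ``(+, -)`` — convergent, a stop-to-stop interval (regulatory-poor);
* ``(+, +)`` or ``(-, -)`` — codirectional.

Coding overlap is judged against CDS features only, while flank
orientation uses CDS plus structural RNA genes: a gap bounded by a tRNA is
still a genuine intergenic gap.  Compound (join) loci are handled by their
envelope.  Linear genomes without a flank on one side yield ``edge``.
"""

from __future__ import annotations

import bisect
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .scan import SiteHit
from .seqio import Feature, FeatureTable, GenomeRecord

CONTEXT_CLASSES = (
    "coding_overlap",
    "intergenic_divergent",
    "intergenic_convergent",
    "intergenic_codirectional",
    "edge",
)


@dataclass(frozen=True)
class ContextCall:
    """A site's relation to the surrounding gene features."""

    site: SiteHit
    cls: str
    left_gene: str | None = None
    right_gene: str | None = None
    dist_left: int = 0
    dist_right: int = 0


class ContextClassifier:
    """Pre-indexed classifier mapping sites to context classes.

    Builds sorted envelope arrays once so that per-site classification is
    O(log n).  ``flank_types`` defaults to CDS plus rRNA/tRNA; overlap is
    always judged against CDS only.
    """

    def __init__(
        self,
        table: FeatureTable,
        genome: GenomeRecord,
        flank_types: tuple[str, ...] = ("CDS", "rRNA", "tRNA"),
    ):
        self.genome = genome
        self.cds = table.envelopes("CDS")
        self.flanks = table.envelopes(*flank_types)
        self._cds_starts = [f.start for f in self.cds]
        # max CDS end over the prefix, for O(log n) overlap queries
        self._cds_maxend = []
        m = 0
        for f in self.cds:
            m = max(m, f.end)
            self._cds_maxend.append(m)
        self._flank_starts = [f.start for f in self.flanks]
        self._flank_ends_sorted = sorted(
            range(len(self.flanks)), key=lambda i: self.flanks[i].end
        )
        self._flank_ends = [self.flanks[i].end for i in self._flank_ends_sorted]

    def _overlaps_cds(self, start: int, end: int) -> bool:
        # features with f.start <= end and f.end >= start
        i = bisect.bisect_right(self._cds_starts, end)
        return i > 0 and self._cds_maxend[i - 1] >= start

    def _site_intervals(self, site: SiteHit) -> list[tuple[int, int]]:
        L = self.genome.length
        if site.end <= L:
            return [(site.start, site.end)]
        return [(site.start, L), (1, site.end - L)]  # origin-wrapping site

    def classify(self, site: SiteHit) -> ContextCall:
        L = self.genome.length
        if any(
            self._overlaps_cds(s, e) for s, e in self._site_intervals(site)
        ):
            return ContextCall(site=site, cls="coding_overlap")
        if not self.flanks:
            return ContextCall(site=site, cls="edge")
        # a non-CDS feature overlapping the site acts as both flanks
        for s, e in self._site_intervals(site):
            for f in self.flanks:
                if f.start <= e and f.end >= s:
                    return ContextCall(
                        site=site,
                        cls="intergenic_codirectional",
                        left_gene=f.locus_tag,
                        right_gene=f.locus_tag,
                    )
        end_wrapped = site.end if site.end <= L else site.end - L
        left = self._left_flank(site.start)
        right = self._right_flank(end_wrapped)
        if left is None or right is None:
            return ContextCall(site=site, cls="edge")
        if self.genome.circular:
            dist_left = (site.start - left.end - 1) % L
            dist_right = (right.start - end_wrapped - 1) % L
        else:
            dist_left = site.start - left.end - 1
            dist_right = right.start - site.end - 1
        pair = (left.strand, right.strand)
        if pair == ("-", "+"):
            cls = "intergenic_divergent"
        elif pair == ("+", "-"):
            cls = "intergenic_convergent"
        else:
            cls = "intergenic_codirectional"
        return ContextCall(
            site=site,
            cls=cls,
            left_gene=left.locus_tag,
            right_gene=right.locus_tag,
            dist_left=int(dist_left),
            dist_right=int(dist_right),
        )

    def _left_flank(self, pos: int) -> Feature | None:
        """Nearest feature whose end is strictly left of pos (circular wrap)."""
        i = bisect.bisect_left(self._flank_ends, pos)
        if i > 0:
            return self.flanks[self._flank_ends_sorted[i - 1]]
        if self.genome.circular:
            return self.flanks[self._flank_ends_sorted[-1]]
        return None

    def _right_flank(self, pos: int) -> Feature | None:
        """Nearest feature whose start is strictly right of pos (circular wrap)."""
        i = bisect.bisect_right(self._flank_starts, pos)
        if i < len(self.flanks):
            return self.flanks[i]
        if self.genome.circular:
            return self.flanks[0]
        return None


def classify_site_context(
    site: SiteHit, table: FeatureTable, genome: GenomeRecord
) -> ContextCall:
    """Classify one site (convenience wrapper; for many sites build a
    :class:`ContextClassifier` once)."""
    if not len(table):
        warnings.warn("empty feature table; all sites classified as edge")
        return ContextCall(site=site, cls="edge")
    return ContextClassifier(table, genome).classify(site)


def classify_contexts(
    sites: list[SiteHit], table: FeatureTable, genome: GenomeRecord
) -> list[ContextCall]:
    """Classify a batch of sites against one pre-built feature index."""
    if not len(table):
        warnings.warn("empty feature table; all sites classified as edge")
        return [ContextCall(site=s, cls="edge") for s in sites]
    clf = ContextClassifier(table, genome)
    return [clf.classify(s) for s in sites]


def context_summary(calls: list[ContextCall]) -> dict[str, int]:
    """Counts per context class (all classes present, zero-filled)."""
    out = {c: 0 for c in CONTEXT_CLASSES}
    for call in calls:
        out[call.cls] += 1
    return out


def upstream_distance(site: SiteHit, gene: Feature) -> int:
    """Gap in bp between a site and a gene's 5' end (strand-aware).

    For a + strand gene the 5' end is ``start`` and the site must lie to
    its left; for a - strand gene the 5' end is ``end`` and the site must
    lie to its right.  Returns the number of bases strictly between; 0
    means immediately adjacent.
    """
    if site.start <= gene.end and site.end >= gene.start:
        raise ValueError(
            "site overlaps the gene; use the coding_overlap classification"
        )
    if gene.strand == "+":
        gap = gene.start - site.end - 1
    else:
        gap = site.start - gene.end - 1
    if gap < 0:
        raise ValueError("site is not on the upstream side of the gene's 5' end")
    return gap


def replichore_assign(position: int, ori: int, L: int) -> str:
    """Replication half of a position on a circular chromosome.

    ``first`` covers the half-open circular arc [ori, ori + ceil(L/2));
    every other position is ``second``.
    """
    if not (1 <= position <= L and 1 <= ori <= L):
        raise ValueError("position and ori must lie in [1, L]")
    half = math.ceil(L / 2)
    return "first" if (position - ori) % L < half else "second"


def replichore_dinucleotide_table(
    hits: list[SiteHit], ori: int, L: int
) -> tuple[pd.DataFrame, float]:
    """Cross-tabulate replication half against central dinucleotide.

    Returns the 2 x d contingency table (rows ``first``/``second``) and a
    chi-square association p-value (1.0 for degenerate tables).
    """
    halves = [replichore_assign(h.start, ori, L) for h in hits]
    dinucs = [h.central_dinuc for h in hits]
    table = pd.crosstab(
        pd.Series(halves, name="half"), pd.Series(dinucs, name="central_dinuc")
    )
    table = table.reindex(index=["first", "second"], fill_value=0)
    if table.shape[1] < 2 or (table.values.sum(axis=1) > 0).sum() < 2:
        return table, 1.0
    p = float(sps.chi2_contingency(table.values).pvalue)
    return table, p


def cumulative_gc_skew(genome: GenomeRecord) -> tuple[np.ndarray, int, int]:
    """Cumulative GC skew along the chromosome, with extremum positions.

    Returns (series, min_position, max_position) where ``series[i]`` is the
    running sum of +1 per G and -1 per C over bases 1..i+1, normalized by
    the total G+C count.  On circular chromosomes the global minimum is the
    classic replication-origin hint and the maximum the terminus hint; they
    are reported as hints only.
    """
    seq = np.frombuffer(genome.sequence.encode("ascii"), dtype=np.uint8)
    contrib = np.zeros(len(seq), dtype=np.float64)
    contrib[seq == ord("G")] = 1.0
    contrib[seq == ord("C")] = -1.0
    total_gc = np.count_nonzero(contrib)
    series = np.cumsum(contrib)
    if total_gc > 0:
        series /= total_gc
    min_pos = int(series.argmin()) + 1
    max_pos = int(series.argmax()) + 1
    return series, min_pos, max_pos
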