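"""Mismatch-tolerant genome scanning for degenerate patterns.

The scanner reports every forward-strand window whose Hamming distance to
the pattern (at non-wildcard positions) is within a mismatch budget.
Overlapping occurrences are all reported — occurrence counts are raw, with
no greedy masking.  On circular chromosomes, windows wrapping the
coordinate origin are included once.

Self-reverse-complementary (palindromic) patterns are scanned on the
forward strand only: a reverse-strand pass is provably identical because
``mismatch_count(p, W) == mismatch_count(p, revcomp(W))`` whenever
``p == revcomp(p)``.  Non-palindromic consensi are scanned on both
strands, with hits reported in forward-strand coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .motif import DegeneratePattern, parse_pattern, reverse_complement
from .seqio import GenomeRecord

_ENCODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _ENCODE[ord(_b)] = _i
_BASE_CODE = {b: i for i, b in enumerate("ACGT")}


def encode(seq: str) -> np.ndarray:
    """Encode A,C,G,T,N as 0,1,2,3,4 (uint8)."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass(frozen=True)
class SiteHit:
    """One motif occurrence in forward-strand coordinates.

    ``end`` may exceed the genome length for hits wrapping the origin of a
    circular coordinate system; ``start`` is always in ``1..L``.
    """

    start: int
    end: int
    mismatches: int
    matched_seq: str
    central_dinuc: str
    orientation: str  # forward / reverse / ambiguous
    strand: str = "+"  # strand the pattern matched on (consensus search)


def _mismatch_vector(
    seq_codes: np.ndarray, pattern: DegeneratePattern, n_starts: int
) -> np.ndarray:
    """Per-start mismatch counts for all windows [i, i+w)."""
    w = pattern.length
    mism = np.zeros(n_starts, dtype=np.int32)
    pu = pattern.upper
    for j in range(w):
        if pu[j] == "N":
            continue
        col = seq_codes[j : j + n_starts]
        mism += col != _BASE_CODE[pu[j]]
    return mism


def central_dinucleotide(matched_seq: str, core: DegeneratePattern) -> str:
    """The forward-strand 2-mer at the central pair of an even-length core
    (positions w/2 and w/2+1; 9-10 for an 18-mer)."""
    w = core.length
    if w % 2:
        raise ValueError(f"central pair undefined for odd pattern length {w}")
    if len(matched_seq) != w:
        raise ValueError("matched sequence length differs from core length")
    mid = w // 2
    return matched_seq[mid - 1 : mid + 1].upper()


def classify_orientation(central: str) -> str:
    """Strand direction read off the central dinucleotide.

    The motif's directionality is carried by the central pair: ``GA`` marks
    the forward orientation and its complement ``TC`` the reverse.  Any
    other dinucleotide is assigned to the Hamming-nearest of the two;
    equidistant pairs (and pairs containing N) are ``ambiguous``.
    """
    if len(central) != 2:
        raise ValueError("central dinucleotide must have length 2")
    c = central.upper()
    if "N" in c:
        return "ambiguous"
    d_fwd = (c[0] != "G") + (c[1] != "A")
    d_rev = (c[0] != "T") + (c[1] != "C")
    if d_fwd < d_rev:
        return "forward"
    if d_rev < d_fwd:
        return "reverse"
    return "ambiguous"


def _make_hit(
    genome_ext: str,
    start0: int,
    mism: int,
    core: DegeneratePattern,
    strand: str = "+",
) -> SiteHit:
    w = core.length
    matched = genome_ext[start0 : start0 + w]
    if w % 2 == 0:
        central = central_dinucleotide(matched, core)
        orient = classify_orientation(central)
    else:
        central, orient = "", "ambiguous"
    return SiteHit(
        start=start0 + 1,
        end=start0 + w,
        mismatches=mism,
        matched_seq=matched,
        central_dinuc=central,
        orientation=orient,
        strand=strand,
    )


def scan_genome(
    genome: GenomeRecord,
    core: DegeneratePattern | str,
    max_mismatch: int = 0,
    circular: bool | None = None,
) -> list[SiteHit]:
    """All forward-strand occurrences of ``core`` within a mismatch budget.

    Parameters
    ----------
    genome
        The chromosome to scan.
    core
        Degenerate pattern (typically palindromic).
    max_mismatch
        Inclusive Hamming budget at non-wildcard positions.
    circular
        Include windows wrapping the coordinate origin; defaults to the
        genome's own circularity flag.

    Returns
    -------
    Hits sorted by start coordinate.  Overlapping hits are all reported.
    """
    if isinstance(core, str):
        core = parse_pattern(core)
    if max_mismatch < 0:
        raise ValueError("max_mismatch must be >= 0")
    w = core.length
    if w > genome.length:
        raise ValueError(
            f"pattern length {w} exceeds genome length {genome.length}"
        )
    if circular is None:
        circular = genome.circular
    if circular:
        ext = genome.sequence + genome.sequence[: w - 1]
        n_starts = genome.length
    else:
        ext = genome.sequence
        n_starts = genome.length - w + 1
    codes = encode(ext)
    mism = _mismatch_vector(codes, core, n_starts)
    hits = [
        _make_hit(ext, int(i), int(mism[i]), core)
        for i in np.flatnonzero(mism <= max_mismatch)
    ]
    return hits


def consensus_site_search(
    genome: GenomeRecord,
    consensus: DegeneratePattern | str,
    max_dev: int = 0,
    circular: bool | None = None,
) -> list[SiteHit]:
    """Scan both strands for a (possibly non-palindromic) consensus.

    The reverse strand is searched by scanning the forward strand with the
    reverse-complemented consensus; hits are reported in forward-strand
    coordinates with ``strand='-'``.  For self-reverse-complementary
    consensi the duplicate pass is suppressed.
    """
    if isinstance(consensus, str):
        consensus = parse_pattern(consensus)
    fwd = scan_genome(genome, consensus, max_dev, circular)
    if consensus.is_self_reverse_complementary:
        return fwd
    rc = reverse_complement(consensus)
    rev = [
        replace(h, strand="-")
        for h in scan_genome(genome, rc, max_dev, circular)
    ]
    return sorted(fwd + rev, key=lambda h: (h.start, h.strand))


@dataclass
class ConservationProfile:
    """Per-position base composition of a stratum of hits.

    ``counts`` is a 5 x w matrix over rows A,C,G,T,N; each column sums to
    ``n_sites`` (the N row is normally all zero on unmasked genomes).
    """

    stratum: tuple[int, int]
    counts: np.ndarray
    n_sites: int
    threshold: float = 0.75

    @property
    def modal_base(self) -> list[str]:
        if self.n_sites == 0:
            return ["N"] * self.counts.shape[1]
        return ["ACGTN"[i] for i in self.counts.argmax(axis=0)]

    @property
    def modal_freq(self) -> np.ndarray:
        if self.n_sites == 0:
            return np.zeros(self.counts.shape[1])
        return self.counts.max(axis=0) / self.n_sites

    @property
    def conserved_positions(self) -> list[int]:
        """1-based positions whose modal base frequency meets the
        conservation threshold."""
        if self.n_sites == 0:
            return []
        return [int(i) + 1 for i in np.flatnonzero(self.modal_freq >= self.threshold)]


def conservation_profile(
    hits: list[SiteHit],
    stratum: int | tuple[int, int],
    threshold: float = 0.75,
) -> ConservationProfile:
    """Base-composition profile over the hits in a mismatch stratum.

    ``stratum`` is either a maximum mismatch count (meaning ``<= k``) or an
    inclusive ``(lo, hi)`` pair.  A position is called conserved when its
    modal base reaches ``threshold`` of the stratum's sites.
    """
    lo, hi = (0, stratum) if isinstance(stratum, int) else stratum
    kept = [h for h in hits if lo <= h.mismatches <= hi]
    if kept:
        lengths = {len(h.matched_seq) for h in kept}
        if len(lengths) != 1:
            raise ValueError("hits mix different pattern lengths")
        w = lengths.pop()
    else:
        w = len(hits[0].matched_seq) if hits else 0
    counts = np.zeros((5, w), dtype=np.int64)
    for h in kept:
        counts[encode(h.matched_seq), np.arange(w)] += 1
    return ConservationProfile(
        stratum=(lo, hi), counts=counts, n_sites=len(kept), threshold=threshold
    )
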