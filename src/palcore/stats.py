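"""Overrepresentation statistics against a Markov background.

The null model is an order-k Markov chain fit to the analyzed genome
itself (default order 2), which controls for local nucleotide composition
without modeling genes.  Expected occurrence counts for a degenerate
pattern — optionally expanded to a Hamming mismatch budget — are computed
exactly by dynamic programming over (context, mismatches-used) states, so
no word enumeration is ever required.  Observed counts are compared to the
expectation with a Poisson upper tail; word self-overlap autocorrelation
is ignored (the Poisson approximation), which is accurate for patterns
that cannot overlap themselves at small shifts.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .motif import DegeneratePattern, parse_pattern, revcomp
from .scan import encode
from .seqio import GenomeRecord

_BASES = "ACGT"


@dataclass
class MarkovBackground:
    """Order-k Markov null model of nucleotide sequence.

    ``transition_probs[c, b]`` is P(next base = b | previous k bases have
    context index c); ``initial_probs[c]`` is the marginal k-mer
    distribution (for k = 0 both collapse to the base distribution).
    """

    order: int
    transition_probs: np.ndarray  # (4^k, 4)
    initial_probs: np.ndarray  # (4^k,)
    trained_length: int = 0

    def __post_init__(self) -> None:
        if not np.allclose(self.transition_probs.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("transition rows must sum to 1")
        if (self.transition_probs < 0).any() or (self.initial_probs < 0).any():
            raise ValueError("probabilities must be non-negative")

    @property
    def n_contexts(self) -> int:
        return 4**self.order


def uniform_background(order: int = 0) -> MarkovBackground:
    """Uniform i.i.d. background (p = 1/4 per base) expressed at any order."""
    nc = 4**order
    return MarkovBackground(
        order=order,
        transition_probs=np.full((nc, 4), 0.25),
        initial_probs=np.full(nc, 1.0 / nc),
    )


def fit_markov(genome: GenomeRecord, order: int) -> MarkovBackground:
    """Maximum-likelihood order-k transition frequencies with pseudocount 1.

    Windows containing N are skipped.  If the genome is circular the
    context wraps across the coordinate origin.
    """
    if order < 0 or order > 8:
        raise ValueError("order must be in 0..8")
    L = genome.length
    if L < 4 ** (order + 1):
        raise ValueError(
            f"genome of length {L} too short to fit an order-{order} model"
        )
    codes = encode(genome.sequence)
    if genome.circular and order > 0:
        codes = np.concatenate([codes, codes[:order]])
    k = order
    nc = 4**k
    valid = codes < 4
    # context index of the k bases preceding each position
    ctx = np.zeros(len(codes) - k, dtype=np.int64)
    ok = np.ones(len(codes) - k, dtype=bool)
    for j in range(k):
        ctx = ctx * 4 + codes[j : len(codes) - k + j]
        ok &= valid[j : len(codes) - k + j]
    nxt = codes[k:]
    ok &= valid[k:]
    counts = np.ones((nc, 4), dtype=np.float64)  # pseudocount 1
    np.add.at(counts, (ctx[ok], nxt[ok]), 1.0)
    trans = counts / counts.sum(axis=1, keepdims=True)
    init = counts.sum(axis=1)
    init = init / init.sum()
    return MarkovBackground(
        order=k, transition_probs=trans, initial_probs=init, trained_length=L
    )


def _position_costs(pattern: DegeneratePattern) -> list[np.ndarray]:
    """Per-position mismatch cost of emitting each base (0/1; wildcards
    cost 0 for every base)."""
    costs = []
    for ch in pattern.upper:
        if ch == "N":
            costs.append(np.zeros(4, dtype=np.int64))
        else:
            c = np.ones(4, dtype=np.int64)
            c[_BASES.index(ch)] = 0
            costs.append(c)
    return costs


def pattern_probability(
    pattern: DegeneratePattern | str,
    bg: MarkovBackground,
    max_mismatch: int = 0,
) -> float:
    """Probability that a background-drawn w-mer lies within ``max_mismatch``
    of the pattern at its non-wildcard positions.

    Computed exactly by dynamic programming over (context, mismatches)
    states; wildcards marginalize out, so cost is O(w * 4^k * m).
    """
    if isinstance(pattern, str):
        pattern = parse_pattern(pattern)
    w = pattern.length
    k = bg.order
    m = max_mismatch
    costs = _position_costs(pattern)
    nc = bg.n_contexts
    # f[c, j] = prob of prefixes ending in context c with j mismatches so far
    f = np.zeros((nc, m + 1))
    if k == 0:
        f[0, 0] = 1.0
        start = 0
    else:
        # consume the first k positions jointly from the k-mer marginal
        for c in range(nc):
            digits = []  # context digits, most-significant first
            cc = c
            for _ in range(k):
                digits.append(cc % 4)
                cc //= 4
            digits.reverse()
            cost = sum(int(costs[j][digits[j]]) for j in range(min(k, w)))
            if cost <= m:
                f[c, cost] += bg.initial_probs[c]
        start = k
        if w <= k:
            # marginalize contexts beyond the pattern (pattern shorter than
            # the context order): sum over compatible prefixes
            return float(f.sum())
    for pos in range(start, w):
        g = np.zeros_like(f)
        for b in range(4):
            cost = int(costs[pos][b])
            tp = bg.transition_probs[:, b]  # (nc,)
            newc = (np.arange(nc) * 4 + b) % nc
            for j in range(m + 1 - cost):
                np.add.at(g[:, j + cost], newc, f[:, j] * tp)
        f = g
    return float(f.sum())


def expected_count(
    pattern: DegeneratePattern | str,
    bg: MarkovBackground,
    L: int,
    max_mismatch: int = 0,
    circular: bool = False,
) -> float:
    """Expected number of windows within the mismatch budget in a sequence
    of length L drawn from the background ((L - w + 1) windows, or L when
    circular)."""
    if isinstance(pattern, str):
        pattern = parse_pattern(pattern)
    if pattern.length > L:
        raise ValueError("pattern longer than sequence")
    n_windows = L if circular else L - pattern.length + 1
    return n_windows * pattern_probability(pattern, bg, max_mismatch)


@dataclass
class EnrichmentResult:
    """Observed-vs-expected occurrence statistics for one pattern."""

    pattern: DegeneratePattern
    observed: int
    expected: float
    z_score: float
    p_value: float
    adjusted_p: float = math.nan
    arm: str = ""
    spacer: int = 0


def enrichment(observed: int, expected: float, pattern: DegeneratePattern | str | None = None) -> EnrichmentResult:
    """Poisson overrepresentation test.

    z = (obs - exp) / sqrt(exp); p is the Poisson upper tail
    P(X >= obs | exp).
    """
    if expected <= 0:
        raise ValueError("expected count must be > 0")
    if isinstance(pattern, str):
        pattern = parse_pattern(pattern)
    z = (observed - expected) / math.sqrt(expected)
    p = float(sps.poisson.sf(observed - 1, expected))
    return EnrichmentResult(
        pattern=pattern, observed=observed, expected=expected, z_score=z, p_value=p
    )


def bh_adjust(pvals: np.ndarray | list[float], n_tests: int | None = None) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values.

    ``n_tests`` lets the caller account for hypotheses that were evaluated
    but not reported (e.g. arm words never observed, whose p is 1).
    """
    p = np.asarray(pvals, dtype=float)
    m = int(n_tests) if n_tests is not None else len(p)
    if m < len(p):
        raise ValueError("n_tests smaller than number of p-values given")
    order = np.argsort(p)
    ranked = p[order] * m / (np.arange(len(p)) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty_like(p)
    out[order] = np.minimum(ranked, 1.0)
    return out


def check_self_overlap(pattern: DegeneratePattern, max_shift: int | None = None) -> bool:
    """Warn if a pattern can overlap itself at a small shift (the Poisson
    expected-count approximation then understates clumping).  Returns True
    when the pattern is self-overlap-free."""
    pu = pattern.upper
    w = pattern.length
    if max_shift is None:
        max_shift = w // 2  # longer shifts overlap too few positions to clump
    for s in range(1, min(max_shift, w - 1) + 1):
        compatible = all(
            pu[i + s] == pu[i] or "N" in (pu[i], pu[i + s]) for i in range(w - s)
        )
        if compatible:
            warnings.warn(
                f"pattern {pattern.text} can overlap itself at shift {s}; "
                "Poisson expected counts ignore the resulting clumping"
            )
            return False
    return True


def _arm_codes(codes: np.ndarray, a: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Rolling integer codes of every a-mer and of its reverse complement,
    plus a validity mask (no N)."""
    L = len(codes)
    n = L - a + 1
    if n <= 0:
        return np.empty(0, np.int64), np.empty(0, np.int64), np.empty(0, bool)
    fwd = np.zeros(n, dtype=np.int64)
    rc = np.zeros(n, dtype=np.int64)
    valid = np.ones(n, dtype=bool)
    for t in range(a):
        col = codes[t : t + n].astype(np.int64)
        valid &= col < 4
        fwd = fwd * 4 + np.where(col < 4, col, 0)
        rc += (3 - np.where(col < 4, col, 0)) * (4**t)
    return fwd, rc, valid


def _decode_arm(code: int, a: int) -> str:
    out = []
    for _ in range(a):
        out.append(_BASES[code % 4])
        code //= 4
    return "".join(reversed(out))


def discover_palindromes(
    genome: GenomeRecord,
    bg: MarkovBackground | None = None,
    arm_len: range = range(6, 9),
    spacer_len: range = range(2, 5),
    top_n: int = 20,
    min_count: int = 2,
    bg_order: int = 2,
) -> list[EnrichmentResult]:
    """De novo search for overrepresented spaced palindromes X N^s rc(X).

    Every arm word of every (arm length, spacer) combination is counted in
    one vectorized pass; candidates observed at least ``min_count`` times
    are scored against the background and Benjamini-Hochberg adjusted over
    the full hypothesis family (all 4^a arm words per combination, not
    just the observed ones).  Candidates whose cores are substrings of a
    more significant candidate's core are merged away.

    Returns the ``top_n`` candidates ranked by adjusted p-value.
    """
    if bg is None:
        bg = fit_markov(genome, bg_order)
    codes = encode(genome.sequence)
    results: list[EnrichmentResult] = []
    n_hypotheses = 0
    for a in arm_len:
        fwd, rc, valid = _arm_codes(codes, a)
        for s in spacer_len:
            n_hypotheses += 4**a
            w = 2 * a + s
            if genome.length < w:
                continue
            n = genome.length - w + 1
            if n <= 0 or len(fwd) == 0:
                continue
            left = fwd[:n]
            right = rc[a + s : a + s + n]
            ok = valid[:n] & valid[a + s : a + s + n]
            match = ok & (left == right)
            if not match.any():
                continue
            words, counts = np.unique(left[match], return_counts=True)
            for word, obs in zip(words, counts):
                if obs < min_count:
                    continue
                arm = _decode_arm(int(word), a)
                core = parse_pattern(arm + "N" * s + revcomp(arm))
                exp = expected_count(core, bg, genome.length)
                res = enrichment(int(obs), exp, core)
                res.arm, res.spacer = arm, s
                results.append(res)
    if not results:
        return []
    adj = bh_adjust([r.p_value for r in results], n_tests=n_hypotheses)
    for r, q in zip(results, adj):
        r.adjusted_p = float(q)
    results.sort(key=lambda r: (r.adjusted_p, r.p_value, -r.observed))
    # merge cores nested inside one another (wildcard-aware), keeping the
    # most significant representative of each family
    kept: list[EnrichmentResult] = []
    for r in results:
        redundant = any(
            _core_nested(r.pattern.upper, k.pattern.upper)
            or _core_nested(k.pattern.upper, r.pattern.upper)
            for k in kept
        )
        if not redundant:
            kept.append(r)
    return kept[:top_n]


def _core_nested(inner: str, outer: str) -> bool:
    """True when ``inner`` matches somewhere inside ``outer`` with N
    treated as a wildcard on either side."""
    if len(inner) > len(outer):
        return False
    for off in range(len(outer) - len(inner) + 1):
        if all(
            a == b or a == "N" or b == "N"
            for a, b in zip(inner, outer[off : off + len(inner)])
        ):
            return True
    return False


@dataclass
class SpatialStats:
    """Uniformity statistics for site positions along the chromosome."""

    n_sites: int
    ks_distance: float
    ks_p: float
    cv_spacing: float


def spacing_uniformity(positions: list[int] | np.ndarray, L: int) -> SpatialStats:
    """Test site positions against spatial uniformity.

    Reports the one-sample Kolmogorov-Smirnov distance and p-value of
    positions/L against Uniform(0, 1], plus the coefficient of variation
    of the circular gaps between consecutive sites (CV 1 is the Poisson
    expectation; larger values indicate clustering).  Neither statistic is
    thresholded here.
    """
    pos = np.sort(np.asarray(positions, dtype=float))
    n = len(pos)
    if n < 2:
        raise ValueError("need at least two positions")
    if pos[0] < 1 or pos[-1] > L:
        raise ValueError("positions must lie in [1, L]")
    ks = sps.kstest(pos / L, "uniform")
    gaps = np.diff(pos)
    wrap = L - pos[-1] + pos[0]
    gaps = np.concatenate([gaps, [wrap]])
    mean = gaps.mean()
    cv = float(gaps.std(ddof=0) / mean) if mean > 0 else math.inf
    return SpatialStats(
        n_sites=n,
        ks_distance=float(ks.statistic),
        ks_p=float(ks.pvalue),
        cv_spacing=cv,
    )
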