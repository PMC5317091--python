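"""Synthetic genomes with planted palindrome sites and known ground truth.

The generator emulates the statistical structure of a small bacterial
chromosome carrying a REP-like repeat family:

* an order-k Markov nucleotide background at a target G+C (45.1 mol% by
  default, the composition of the genome the repeat family was found in);
* planted degenerate-palindrome sites with controlled per-site mismatch
  counts, central dinucleotides drawn from a replichore-dependent bias
  (GA-rich in the first replication half, TC-rich in the second), and
  weakly conserved flanking wildcard positions;
* a CDS feature table tiling a target fraction of the genome (88% by
  default) with a controlled mix of adjacent-pair strand orientations.

Every stochastic choice consumes one pseudo-random stream keyed by a
single integer seed, so fixtures are exactly reproducible.  After
planting, the background is scrubbed of accidental extra matches within
the largest mismatch budget by local re-rolling, so the truth table is
exhaustive for that budget.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .motif import (
    PALINDROME_CORE,
    REPEAT_CONSENSUS,
    DegeneratePattern,
    parse_pattern,
)
from .context import replichore_assign
from .scan import scan_genome
from .seqio import Feature, FeatureTable, GenomeRecord, write_gff3

_BASES = "ACGT"

#: Default central-dinucleotide bias per replication half: GA/AA-type
#: dinucleotides dominate the first replichore while TC/TT concentrate in
#: the second, with GA the most common overall — the strand asymmetry
#: characteristic of the modeled repeat family.
DEFAULT_DINUC_BIAS = {
    "first": {"GA": 0.78, "AA": 0.16, "TA": 0.03, "TC": 0.02, "TT": 0.01},
    "second": {"TC": 0.45, "TT": 0.14, "GA": 0.30, "AA": 0.07, "TA": 0.04},
}

#: Default intergenic placement preference: sites favor stop-to-stop
#: (convergent) intervals and avoid promoter-rich start-to-start
#: (divergent) intervals.
DEFAULT_CLASS_BIAS = {
    "intergenic_divergent": 0.04,
    "intergenic_convergent": 0.36,
    "intergenic_codirectional": 0.60,
}


@dataclass
class SimulationConfig:
    """Parameters of one synthetic-genome run.

    Defaults reproduce the study conditions this generator emulates: a
    ~100 kb chromosome at 45.1% G+C carrying 38 exact-core sites plus 5
    one-mismatch sites, 88% CDS coverage, and replichore-biased central
    dinucleotides.
    """

    length: int = 100_000
    markov_order: int = 0
    gc_target: float = 0.451
    mismatch_spec: tuple[int, ...] = tuple([0] * 38 + [1] * 5)
    dinuc_bias: dict[str, dict[str, float]] = field(
        default_factory=lambda: {h: dict(d) for h, d in DEFAULT_DINUC_BIAS.items()}
    )
    gene_density: float = 0.88
    mean_gene_len: int = 900
    min_gap: int = 30
    orientation_mix: dict[str, float] = field(
        default_factory=lambda: {"++": 0.35, "+-": 0.15, "-+": 0.15, "--": 0.35}
    )
    coding_fraction: float = 13 / 38  # fraction of sites planted inside CDSs
    intergenic_class_bias: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_BIAS)
    )
    wildcard_consensus: str | None = REPEAT_CONSENSUS
    wildcard_bias: float = 0.75
    ori: int = 1
    seed: int = 0

    @property
    def n_sites(self) -> int:
        return len(self.mismatch_spec)

    def validate(self) -> None:
        if not 0 < self.gc_target < 1:
            raise ValueError("gc_target must lie strictly inside (0, 1)")
        if not 0 < self.gene_density < 1:
            raise ValueError("gene_density must lie strictly inside (0, 1)")
        if abs(sum(self.orientation_mix.values()) - 1.0) > 1e-9:
            raise ValueError("orientation_mix must sum to 1")
        if self.length < 1000:
            raise ValueError("length must be >= 1000")


@dataclass(frozen=True)
class PlantedSite:
    """Ground truth for one planted occurrence."""

    start: int
    mismatches: int
    central_dinuc: str
    half: str
    context_cls: str


@dataclass
class SyntheticTruth:
    planted: list[PlantedSite]
    features: FeatureTable
    config: SimulationConfig


@dataclass
class SyntheticFixture:
    genome: GenomeRecord
    features: FeatureTable
    truth: SyntheticTruth


def _base_probs(gc: float) -> np.ndarray:
    return np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])


def generate_markov_genome(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> GenomeRecord:
    """Draw a genome from the order-k background at the target G+C.

    Order 0 is i.i.d. at the target composition.  For k >= 1 the
    transition distribution mildly favors repeating the previous base
    (delta = 0.2), which adds realistic short-range autocorrelation while
    keeping the stationary composition at the target to first order.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    L, k = config.length, config.markov_order
    p = _base_probs(config.gc_target)
    if k == 0:
        seq = rng.choice(4, size=L, p=p)
    else:
        delta = 0.2
        seq = np.empty(L, dtype=np.int64)
        seq[0] = rng.choice(4, p=p)
        # transition depends only on the immediately previous base
        trans = np.empty((4, 4))
        for prev in range(4):
            row = p.copy()
            row[prev] *= 1 + delta
            trans[prev] = row / row.sum()
        cum = trans.cumsum(axis=1)
        u = rng.random(L)
        for i in range(1, L):
            seq[i] = np.searchsorted(cum[seq[i - 1]], u[i])
    text = "".join(_BASES[b] for b in seq)
    return GenomeRecord(id=f"synthetic_{config.seed}", sequence=text, circular=True)


def _strand_chain(n: int, mix: dict[str, float], rng: np.random.Generator) -> list[str]:
    """Strand sequence whose adjacent-pair frequencies follow the mix."""
    p_plus_plus = mix["++"] / max(mix["++"] + mix["+-"], 1e-12)
    p_minus_plus = mix["-+"] / max(mix["-+"] + mix["--"], 1e-12)
    strands = ["+" if rng.random() < mix["++"] + mix["+-"] else "-"]
    for _ in range(1, n):
        stay = p_plus_plus if strands[-1] == "+" else p_minus_plus
        strands.append("+" if rng.random() < stay else "-")
    return strands


def generate_feature_table(
    config: SimulationConfig,
    genome: GenomeRecord,
    rng: np.random.Generator | None = None,
) -> FeatureTable:
    """Tile the genome with non-overlapping CDSs at the target density.

    Gene and gap lengths are gamma-distributed; gap lengths are rescaled
    so the realized CDS coverage equals ``gene_density`` up to rounding.
    Adjacent-pair strand orientations follow ``orientation_mix``.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    L, d = genome.length, config.gene_density
    target_gene_total = round(L * d)
    target_gap_total = L - target_gene_total
    mean_gap = config.mean_gene_len * (1 - d) / d
    if mean_gap < config.min_gap:
        raise ValueError(
            "gene_density too high to leave gaps above min_gap at this gene length"
        )
    gene_lens: list[int] = []
    while sum(gene_lens) < target_gene_total:
        g = int(rng.gamma(shape=12, scale=config.mean_gene_len / 12))
        gene_lens.append(max(150, min(g, 4000)))
    gene_lens[-1] -= sum(gene_lens) - target_gene_total
    if gene_lens[-1] < 150:
        gene_lens.pop()
        target_gap_total = L - sum(gene_lens)
    n = len(gene_lens)
    raw = rng.gamma(shape=4.0, scale=1.0, size=n)
    gaps = np.maximum(
        config.min_gap, np.round(raw / raw.sum() * target_gap_total).astype(int)
    )
    gaps[int(np.argmax(gaps))] += target_gap_total - int(gaps.sum())
    strands = _strand_chain(n, config.orientation_mix, rng)
    feats = []
    pos = 1
    for i in range(n):
        pos += int(gaps[i])
        feats.append(Feature(f"SYN_{i:04d}", "CDS", pos, pos + gene_lens[i] - 1, strands[i]))
        pos += gene_lens[i]
    if feats and feats[-1].end > L:
        feats.pop()
    return FeatureTable(features=feats, genome_id=genome.id)


def _gap_intervals(
    table: FeatureTable, L: int
) -> list[tuple[int, int, str, str]]:
    """(start, end, left_strand, right_strand) of each intergenic gap,
    including the wrap-around gap on the circular chromosome."""
    feats = table.features
    gaps = []
    for i in range(len(feats) - 1):
        a, b = feats[i], feats[i + 1]
        if b.start > a.end + 1:
            gaps.append((a.end + 1, b.start - 1, a.strand, b.strand))
    if feats:
        last, first = feats[-1], feats[0]
        length_wrap = (L - last.end) + (first.start - 1)
        if length_wrap > 0:
            gaps.append((last.end + 1, L + first.start - 1, last.strand, first.strand))
    return gaps


def _gap_class(left: str, right: str) -> str:
    if (left, right) == ("-", "+"):
        return "intergenic_divergent"
    if (left, right) == ("+", "-"):
        return "intergenic_convergent"
    return "intergenic_codirectional"


def _sample_discrete(dist: dict[str, float], rng: np.random.Generator) -> str:
    keys = sorted(dist)
    probs = np.array([dist[k] for k in keys], dtype=float)
    return keys[rng.choice(len(keys), p=probs / probs.sum())]


def plant_sites(
    genome: GenomeRecord,
    core: DegeneratePattern | str,
    config: SimulationConfig,
    features: FeatureTable | None = None,
    rng: np.random.Generator | None = None,
    max_scrub_rounds: int = 40,
) -> tuple[GenomeRecord, SyntheticTruth]:
    """Overwrite the genome with planted core occurrences and return the
    modified genome plus an exhaustive truth table.

    Each site instantiates the core, fills wildcard positions from the
    weak-consensus bias, sets the central dinucleotide from the
    replichore-half bias, and then mutates exactly the specified number of
    non-wildcard positions.  Sites avoid feature boundaries (fully inside
    a CDS or fully inside a gap) so the context truth is unambiguous.
    After planting, any accidental background hit within the largest
    requested mismatch budget is removed by re-rolling its non-planted
    bases.
    """
    if isinstance(core, str):
        core = parse_pattern(core)
    if rng is None:
        rng = np.random.default_rng(config.seed)
    w = core.length
    L = genome.length
    spec = list(config.mismatch_spec)
    if spec and max(spec) > len(core.upper) - len(core.wildcard_positions):
        raise ValueError("mismatch count exceeds number of non-wildcard positions")
    if config.n_sites * w * 4 > L:
        raise ValueError("too many sites for this genome length")
    seq = np.frombuffer(genome.sequence.encode("ascii"), dtype=np.uint8).copy()
    base_probs = _base_probs(config.gc_target)
    base_ords = np.frombuffer(b"ACGT", dtype=np.uint8)

    gaps = _gap_intervals(features, L) if features is not None and len(features) else []
    genes = (
        [f for f in features.envelopes("CDS") if f.length >= w + 6]
        if features is not None
        else []
    )
    fit_gaps = [g for g in gaps if g[1] - g[0] + 1 >= w + 6]
    gaps_by_class: dict[str, list] = {}
    for g_ in fit_gaps:
        gaps_by_class.setdefault(_gap_class(g_[2], g_[3]), []).append(g_)

    non_wild = sorted(set(range(1, w + 1)) - set(core.wildcard_positions))
    mid = w // 2
    central_is_wild = (
        w % 2 == 0 and mid in core.wildcard_positions and mid + 1 in core.wildcard_positions
    )

    planted: list[PlantedSite] = []
    used: list[tuple[int, int]] = []
    used_mask = np.zeros(L, dtype=bool)

    def overlaps_used(s: int) -> bool:
        idx = np.arange(s - 1 - 2, s - 1 + w + 2) % L  # 2-bp separation margin
        return bool(used_mask[idx].any())

    for m in spec:
        placed = False
        for _ in range(10_000):
            if fit_gaps and genes:
                in_gene = rng.random() < config.coding_fraction
            else:
                in_gene = bool(genes) and not fit_gaps
            if in_gene and genes:
                g = genes[rng.integers(len(genes))]
                start = int(rng.integers(g.start + 2, g.end - w - 1))
                cls = "coding_overlap"
            elif fit_gaps:
                avail = {
                    c: p
                    for c, p in config.intergenic_class_bias.items()
                    if gaps_by_class.get(c)
                }
                cls = _sample_discrete(avail, rng) if avail else _gap_class(
                    *fit_gaps[0][2:]
                )
                pool = gaps_by_class.get(cls, fit_gaps)
                gs, ge, ls, rs = pool[rng.integers(len(pool))]
                start = int(rng.integers(gs + 2, ge - w - 1))
                cls = _gap_class(ls, rs)
            else:
                start = int(rng.integers(1, L - w + 1))
                cls = "edge"
            start = ((start - 1) % L) + 1  # wrap-gap starts past L fold back
            if not overlaps_used(start):
                placed = True
                break
        if not placed:
            raise RuntimeError("could not place site without overlap")
        used_mask[np.arange(start - 1, start - 1 + w) % L] = True
        # instantiate the core
        site = list(core.upper)
        for pos in core.wildcard_positions:
            if config.wildcard_consensus and len(config.wildcard_consensus) == w and rng.random() < config.wildcard_bias:
                site[pos - 1] = config.wildcard_consensus[pos - 1].upper()
            else:
                site[pos - 1] = _BASES[rng.choice(4, p=base_probs)]
        half = replichore_assign(((start - 1) % L) + 1, config.ori, L)
        if central_is_wild:
            dinuc = _sample_discrete(config.dinuc_bias[half], rng)
            site[mid - 1], site[mid] = dinuc[0], dinuc[1]
        else:
            dinuc = "".join(site[mid - 1 : mid + 1]) if w % 2 == 0 else ""
        # mutate exactly m non-wildcard positions
        for pos in rng.choice(len(non_wild), size=m, replace=False):
            p = non_wild[int(pos)]
            old = site[p - 1]
            site[p - 1] = rng.choice([b for b in _BASES if b != old])
        word = np.frombuffer("".join(site).encode("ascii"), dtype=np.uint8)
        idx = (np.arange(start - 1, start - 1 + w)) % L
        seq[idx] = word
        used.append((start, start + w - 1))
        planted.append(
            PlantedSite(
                start=start, mismatches=m, central_dinuc=dinuc, half=half, context_cls=cls
            )
        )

    # scrub accidental background hits within the largest budget
    budget = max(spec) if spec else 0
    planted_starts = {p.start for p in planted}
    protected = np.zeros(L, dtype=bool)
    for a, e in used:
        protected[(np.arange(a - 1, e)) % L] = True
    for _ in range(max_scrub_rounds):
        g = GenomeRecord(id=genome.id, sequence=seq.tobytes().decode("ascii"), circular=True)
        extra = [
            h for h in scan_genome(g, core, budget) if h.start not in planted_starts
        ]
        if not extra:
            break
        for h in extra:
            idx = (np.arange(h.start - 1, h.start - 1 + w)) % L
            free = idx[~protected[idx]]
            if len(free) == 0:
                continue
            seq[free] = base_ords[rng.choice(4, size=len(free), p=base_probs)]
    else:
        raise RuntimeError("failed to scrub accidental matches from the background")
    out = GenomeRecord(id=genome.id, sequence=seq.tobytes().decode("ascii"), circular=True)
    truth = SyntheticTruth(
        planted=sorted(planted, key=lambda p: p.start),
        features=features if features is not None else FeatureTable([], genome.id),
        config=config,
    )
    return out, truth


def simulate(
    config: SimulationConfig | None = None,
    core: DegeneratePattern | str = PALINDROME_CORE,
) -> SyntheticFixture:
    """Generate a complete fixture (genome, features, planted truth) from
    one seed: background genome, CDS tiling, then site planting."""
    if config is None:
        config = SimulationConfig()
    rng = np.random.default_rng(config.seed)
    genome = generate_markov_genome(config, rng)
    features = generate_feature_table(config, genome, rng)
    genome, truth = plant_sites(genome, core, config, features, rng)
    return SyntheticFixture(genome=genome, features=features, truth=truth)


def emit_fixture(
    genome: GenomeRecord,
    table: FeatureTable,
    truth: SyntheticTruth,
    outdir: str | Path,
) -> dict[str, Path]:
    """Write FASTA, GFF3, truth TSV and a reproducibility manifest."""
    import pandas as pd

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": outdir / "genome.fasta",
        "gff3": outdir / "features.gff3",
        "truth": outdir / "truth.tsv",
        "manifest": outdir / "config.yaml",
    }
    with open(paths["fasta"], "w") as fh:
        fh.write(f">{genome.id}\n")
        for i in range(0, genome.length, 70):
            fh.write(genome.sequence[i : i + 70] + "\n")
    write_gff3(table, paths["gff3"], genome_length=genome.length)
    pd.DataFrame([dataclasses.asdict(p) for p in truth.planted]).to_csv(
        paths["truth"], sep="\t", index=False
    )
    cfg = dataclasses.asdict(truth.config)
    cfg["mismatch_spec"] = list(cfg["mismatch_spec"])
    with open(paths["manifest"], "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
    return paths


def load_config(path: str | Path) -> SimulationConfig:
    """Read a manifest written by :func:`emit_fixture` back into a config."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    data["mismatch_spec"] = tuple(data["mismatch_spec"])
    return SimulationConfig(**data)
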