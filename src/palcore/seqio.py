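"""Genome and feature I/O plus simple genome-level summaries.

Sequences are normalized on load: uppercased, with IUPAC ambiguity codes
other than ``N`` mapped to ``N`` (a logged warning reports how many).  All
external coordinates are 1-based inclusive, following GFF3 convention.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO

logger = logging.getLogger(__name__)

_VALID = set("ACGTN")
_AMBIGUOUS = set("RYSWKMBDHVU")  # non-N IUPAC codes collapsed to N

FEATURE_TYPES = ("CDS", "rRNA", "tRNA", "other")


@dataclass(frozen=True)
class GenomeRecord:
    """One chromosome: an uppercase A/C/G/T/N string plus a circularity flag."""

    id: str
    sequence: str
    circular: bool = True

    def __post_init__(self) -> None:
        bad = set(self.sequence) - _VALID
        if bad:
            raise ValueError(f"sequence contains invalid characters: {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(self.sequence)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True, order=True)
class Feature:
    """A gene-level feature with 1-based inclusive coordinates."""

    start: int
    end: int
    locus_tag: str = field(compare=False)
    ftype: str = field(compare=False)
    strand: str = field(compare=False)

    def __init__(self, locus_tag: str, ftype: str, start: int, end: int, strand: str):
        if ftype not in FEATURE_TYPES:
            ftype = "other"
        if strand not in "+-":
            raise ValueError(f"strand must be + or -, got {strand!r}")
        if not (1 <= start <= end):
            raise ValueError(f"need 1 <= start <= end, got {start}..{end}")
        object.__setattr__(self, "locus_tag", locus_tag)
        object.__setattr__(self, "ftype", ftype)
        object.__setattr__(self, "start", start)
        object.__setattr__(self, "end", end)
        object.__setattr__(self, "strand", strand)

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class FeatureTable:
    """Features sorted by (start, end, locus_tag)."""

    features: list[Feature]
    genome_id: str = ""

    def __post_init__(self) -> None:
        self.features = sorted(
            self.features, key=lambda f: (f.start, f.end, f.locus_tag)
        )

    def __len__(self) -> int:
        return len(self.features)

    def __iter__(self):
        return iter(self.features)

    def of_type(self, *ftypes: str) -> list[Feature]:
        want = set(ftypes)
        return [f for f in self.features if f.ftype in want]

    def envelopes(self, *ftypes: str) -> list[Feature]:
        """One interval per locus_tag: the envelope (min start, max end) of
        its parts.  Compound (join) locations are re-merged here."""
        want = set(ftypes) if ftypes else set(FEATURE_TYPES)
        by_tag: dict[str, list[Feature]] = {}
        for f in self.features:
            if f.ftype in want:
                by_tag.setdefault(f.locus_tag, []).append(f)
        out = []
        for tag, parts in by_tag.items():
            out.append(
                Feature(
                    tag,
                    parts[0].ftype,
                    min(p.start for p in parts),
                    max(p.end for p in parts),
                    parts[0].strand,
                )
            )
        return sorted(out, key=lambda f: (f.start, f.end, f.locus_tag))


def _normalize_sequence(raw: str) -> str:
    seq = raw.upper()
    extra = set(seq) & _AMBIGUOUS
    if extra:
        n_mapped = sum(seq.count(c) for c in extra)
        warnings.warn(
            f"mapped {n_mapped} ambiguous IUPAC bases ({sorted(extra)}) to N",
            stacklevel=3,
        )
        seq = seq.translate(str.maketrans({c: "N" for c in extra}))
    bad = set(seq) - _VALID
    if bad:
        raise ValueError(f"non-nucleotide characters in sequence: {sorted(bad)}")
    return seq


def read_fasta(
    path: str | Path,
    record_id: str | None = None,
    circular: bool = True,
) -> GenomeRecord:
    """Read one genome from a FASTA file.

    Multi-record files are rejected unless ``record_id`` selects a record.
    The sequence is uppercased; ambiguity codes other than N become N with
    a warning.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    if record_id is None:
        if len(records) > 1:
            raise ValueError(
                f"{path} holds {len(records)} records; pass record_id to choose one"
            )
        rec = records[0]
    else:
        matches = [r for r in records if r.id == record_id]
        if not matches:
            raise ValueError(f"record {record_id!r} not found in {path}")
        rec = matches[0]
    seq = _normalize_sequence(str(rec.seq))
    if not seq:
        raise ValueError(f"record {rec.id!r} in {path} has an empty sequence")
    return GenomeRecord(id=rec.id, sequence=seq, circular=circular)


def _features_from_genbank(path: str | Path) -> tuple[list[Feature], str]:
    rec = next(SeqIO.parse(str(path), "genbank"))
    feats: list[Feature] = []
    auto = 0
    for f in rec.features:
        if f.type in ("source", "gene"):
            continue
        ftype = f.type if f.type in ("CDS", "rRNA", "tRNA") else "other"
        quals = f.qualifiers
        tag = (quals.get("locus_tag") or quals.get("gene") or [None])[0]
        if tag is None:
            auto += 1
            tag = f"feat_{auto:05d}"
        strand = "-" if f.location.strand == -1 else "+"
        for part in f.location.parts:
            feats.append(
                Feature(tag, ftype, int(part.start) + 1, int(part.end), strand)
            )
    return feats, rec.id


def _features_from_gff3(path: str | Path) -> tuple[list[Feature], str]:
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    feats: list[Feature] = []
    genome_id = ""
    auto = 0
    for f in db.all_features():
        if f.featuretype in ("region", "gene", "chromosome"):
            continue
        ftype = f.featuretype if f.featuretype in ("CDS", "rRNA", "tRNA") else "other"
        tag = (
            f.attributes.get("locus_tag", [None])[0]
            or f.attributes.get("ID", [None])[0]
            or f.attributes.get("Name", [None])[0]
        )
        if tag is None:
            auto += 1
            tag = f"feat_{auto:05d}"
        if f.strand not in "+-":
            continue  # strandless features carry no orientation information
        genome_id = genome_id or f.seqid
        feats.append(Feature(tag, ftype, f.start, f.end, f.strand))
    return feats, genome_id


def read_features(path: str | Path, dialect: str | None = None) -> FeatureTable:
    """Read a feature table from GFF3 or a GenBank flat file.

    ``dialect`` is ``"gff3"`` or ``"genbank"``; when omitted it is guessed
    from the file suffix.  GenBank compound (join) locations are split into
    their parts, all sharing the parent locus_tag.
    """
    path = Path(path)
    if dialect is None:
        dialect = "genbank" if path.suffix.lower() in (".gb", ".gbk", ".gbff") else "gff3"
    if dialect == "genbank":
        feats, genome_id = _features_from_genbank(path)
    elif dialect == "gff3":
        feats, genome_id = _features_from_gff3(path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return FeatureTable(features=feats, genome_id=genome_id)


def write_gff3(table: FeatureTable, path: str | Path, genome_length: int | None = None) -> None:
    """Write a FeatureTable as 9-column GFF3."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        if genome_length:
            fh.write(f"##sequence-region {table.genome_id} 1 {genome_length}\n")
        for f in table.features:
            fh.write(
                "\t".join(
                    [
                        table.genome_id or "genome",
                        "palcore",
                        f.ftype,
                        str(f.start),
                        str(f.end),
                        ".",
                        f.strand,
                        ".",
                        f"ID={f.locus_tag};locus_tag={f.locus_tag}",
                    ]
                )
                + "\n"
            )


def gc_content(genome: GenomeRecord) -> float:
    """G+C fraction of the unambiguous bases; N is excluded from both
    numerator and denominator."""
    seq = genome.sequence
    gc = seq.count("G") + seq.count("C")
    acgt = gc + seq.count("A") + seq.count("T")
    if acgt == 0:
        raise ValueError("sequence holds no unambiguous bases")
    return gc / acgt


def _merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    ivs = sorted(intervals)
    merged: list[tuple[int, int]] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1] + 1:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def feature_coverage_fraction(
    genome: GenomeRecord,
    table: FeatureTable,
    ftypes: Iterable[str] = ("CDS",),
) -> float:
    """Fraction of the genome covered by the union of the selected feature
    intervals (overlapping features counted once)."""
    want = set(ftypes)
    ivs = []
    for f in table.features:
        if f.ftype not in want:
            continue
        if not (1 <= f.start <= f.end <= genome.length):
            raise ValueError(
                f"feature {f.locus_tag} {f.start}..{f.end} outside genome of "
                f"length {genome.length}"
            )
        ivs.append((f.start, f.end))
    covered = sum(e - s + 1 for s, e in _merge_intervals(ivs))
    return covered / genome.length


def count_features_by_type(table: FeatureTable) -> dict[str, int]:
    """Distinct loci per feature type (join parts counted once)."""
    counts = {t: 0 for t in FEATURE_TYPES}
    seen: set[tuple[str, str]] = set()
    for f in table.features:
        key = (f.locus_tag, f.ftype)
        if key in seen:
            continue
        seen.add(key)
        counts[f.ftype] += 1
    return counts
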