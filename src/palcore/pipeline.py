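"""End-to-end characterization of a palindromic repeat family.

``run_characterization`` chains the whole analysis — mismatch-stratified
scanning, per-stratum conservation profiling, genomic-context
classification, replichore asymmetry of the central dinucleotide, spatial
uniformity, and Markov-background enrichment — into one structured,
serializable report.  Every number in the report can be recomputed from
the emitted sites/context TSVs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import __version__
from .context import (
    classify_contexts,
    context_summary,
    replichore_dinucleotide_table,
)
from .motif import DegeneratePattern, parse_pattern
from .scan import ConservationProfile, SiteHit, conservation_profile, scan_genome
from .seqio import (
    FeatureTable,
    GenomeRecord,
    count_features_by_type,
    feature_coverage_fraction,
    gc_content,
)
from .stats import (
    bh_adjust,
    check_self_overlap,
    enrichment,
    expected_count,
    fit_markov,
    spacing_uniformity,
)

logger = logging.getLogger(__name__)


@dataclass
class AnalysisReport:
    """Assembled results of one characterization run."""

    genome_summary: dict[str, Any]
    core: str
    stratum_counts: dict[int, int]  # budget -> number of sites with <= budget
    profiles: dict[int, ConservationProfile]
    context_by_stratum: dict[int, dict[str, int]]
    central_dinuc_counts: dict[str, int]
    replichore_table: pd.DataFrame
    replichore_p: float
    spatial: dict[str, float]
    enrichment_rows: list[dict[str, Any]]
    hits: list[SiteHit]
    provenance: dict[str, Any]

    def to_dict(self) -> dict[str, Any]:
        return {
            "genome_summary": self.genome_summary,
            "core": self.core,
            "stratum_counts": {str(k): v for k, v in self.stratum_counts.items()},
            "conservation": {
                str(k): {
                    "n_sites": p.n_sites,
                    "modal_base": p.modal_base,
                    "modal_freq": [round(float(x), 6) for x in p.modal_freq],
                    "conserved_positions": p.conserved_positions,
                }
                for k, p in self.profiles.items()
            },
            "context_by_stratum": {
                str(k): v for k, v in self.context_by_stratum.items()
            },
            "central_dinuc_counts": self.central_dinuc_counts,
            "replichore": {
                "table": {
                    half: {d: int(c) for d, c in row.items()}
                    for half, row in self.replichore_table.to_dict("index").items()
                },
                "association_p": self.replichore_p,
            },
            "spatial": self.spatial,
            "enrichment": self.enrichment_rows,
            "provenance": self.provenance,
        }

    def to_json(self, **kwargs: Any) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True, **kwargs)


def run_characterization(
    genome: GenomeRecord,
    features: FeatureTable,
    core: DegeneratePattern | str,
    ori: int = 1,
    max_mismatch: int = 4,
    dinuc_stratum: int = 1,
    conservation_threshold: float = 0.75,
    bg_order: int = 2,
    seed: int = 0,
) -> AnalysisReport:
    """Run the full repeat-characterization pipeline.

    Parameters
    ----------
    genome, features
        The chromosome and its gene feature table.
    core
        Degenerate (typically palindromic) core pattern.
    ori
        Replication-origin coordinate defining the replichore split; this
        is an input, never guessed.
    max_mismatch
        Largest mismatch budget scanned; strata 0..max are reported.
    dinuc_stratum
        Mismatch budget whose sites feed the central-dinucleotide and
        replichore sections (default <= 1, the well-populated strata).
    bg_order
        Order of the Markov background fit to the genome for enrichment.
    """
    if isinstance(core, str):
        core = parse_pattern(core)
    logger.info("scanning %s (%d bp) for %s", genome.id, genome.length, core)

    summary = {
        "genome_id": genome.id,
        "length_bp": genome.length,
        "gc_content": round(gc_content(genome), 4),
        "cds_coverage": (
            round(feature_coverage_fraction(genome, features), 4)
            if len(features)
            else None
        ),
        "feature_counts": count_features_by_type(features),
    }

    hits = scan_genome(genome, core, max_mismatch)
    stratum_counts = {
        k: sum(1 for h in hits if h.mismatches <= k) for k in range(max_mismatch + 1)
    }
    profiles = {
        k: conservation_profile(hits, k, threshold=conservation_threshold)
        for k in range(max_mismatch + 1)
    }

    if len(features) == 0:
        logger.warning("no features supplied; context section degraded to edge calls")
    calls = classify_contexts(hits, features, genome)
    context_by_stratum = {}
    for k in range(max_mismatch + 1):
        context_by_stratum[k] = context_summary(
            [c for c in calls if c.site.mismatches <= k]
        )

    dinuc_hits = [h for h in hits if h.mismatches <= dinuc_stratum]
    central_counts: dict[str, int] = {}
    for h in dinuc_hits:
        central_counts[h.central_dinuc] = central_counts.get(h.central_dinuc, 0) + 1
    rep_table, rep_p = replichore_dinucleotide_table(dinuc_hits, ori, genome.length)

    exact_positions = [h.start for h in hits if h.mismatches == 0]
    if len(exact_positions) >= 2:
        sp = spacing_uniformity(exact_positions, genome.length)
        spatial = {
            "n_sites": sp.n_sites,
            "ks_distance": sp.ks_distance,
            "ks_p": sp.ks_p,
            "cv_spacing": sp.cv_spacing,
        }
    else:
        spatial = {"n_sites": len(exact_positions)}

    check_self_overlap(core)
    bg = fit_markov(genome, bg_order)
    enr_rows = []
    results = []
    for k in range(max_mismatch + 1):
        exp = expected_count(core, bg, genome.length, max_mismatch=k, circular=genome.circular)
        results.append(enrichment(stratum_counts[k], exp, core))
    adj = bh_adjust([r.p_value for r in results])
    for k, (r, q) in enumerate(zip(results, adj)):
        enr_rows.append(
            {
                "max_mismatch": k,
                "observed": r.observed,
                "expected": round(r.expected, 6),
                "z_score": round(r.z_score, 4),
                "p_value": r.p_value,
                "adjusted_p": float(q),
            }
        )

    provenance = {
        "tool": "palcore",
        "version": __version__,
        "core": core.text,
        "ori": ori,
        "max_mismatch": max_mismatch,
        "dinuc_stratum": dinuc_stratum,
        "conservation_threshold": conservation_threshold,
        "bg_order": bg_order,
        "seed": seed,
        "circular": genome.circular,
    }
    return AnalysisReport(
        genome_summary=summary,
        core=core.text,
        stratum_counts=stratum_counts,
        profiles=profiles,
        context_by_stratum=context_by_stratum,
        central_dinuc_counts=central_counts,
        replichore_table=rep_table,
        replichore_p=rep_p,
        spatial=spatial,
        enrichment_rows=enr_rows,
        hits=hits,
        provenance=provenance,
    )


def sites_dataframe(report: AnalysisReport, genome_id: str | None = None) -> pd.DataFrame:
    """The sites TSV: one row per hit in forward-strand coordinates."""
    gid = genome_id or report.genome_summary["genome_id"]
    return pd.DataFrame(
        [
            {
                "genome_id": gid,
                "start": h.start,
                "end": h.end,
                "strand_class": h.orientation,
                "mismatches": h.mismatches,
                "matched_seq": h.matched_seq,
                "central_dinuc": h.central_dinuc,
            }
            for h in report.hits
        ]
    )


def write_report(report: AnalysisReport, outdir: str | Path) -> dict[str, Path]:
    """Write report.json plus sites/profile/enrichment TSVs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "report": outdir / "report.json",
        "sites": outdir / "sites.tsv",
        "profile": outdir / "profile.tsv",
        "enrichment": outdir / "enrichment.tsv",
    }
    paths["report"].write_text(report.to_json() + "\n")
    sites_dataframe(report).to_csv(paths["sites"], sep="\t", index=False)
    prof_rows = []
    for k, p in report.profiles.items():
        for pos in range(p.counts.shape[1]):
            prof_rows.append(
                {
                    "stratum_max_mismatch": k,
                    "position": pos + 1,
                    **{b: int(p.counts["ACGTN".index(b), pos]) for b in "ACGTN"},
                    "modal_base": p.modal_base[pos],
                    "modal_freq": round(float(p.modal_freq[pos]), 6) if p.n_sites else 0.0,
                    "conserved": (pos + 1) in p.conserved_positions,
                }
            )
    pd.DataFrame(prof_rows).to_csv(paths["profile"], sep="\t", index=False)
    pd.DataFrame(report.enrichment_rows).to_csv(paths["enrichment"], sep="\t", index=False)
    return paths
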