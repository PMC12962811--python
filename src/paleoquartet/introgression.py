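"""Archaic-introgression segment overlap and carrier frequencies.

Segments are BED-like rows (0-based, half-open) with individual, haplotype,
ancestry, population panel and continental region annotations.  A gene
"carries the archaic version" in a haplotype when any introgressed segment
of that haplotype overlaps the gene interval by at least one base; carrier
frequencies are counted at the chromosome (haplotype) level by default —
distinct (individual, haplotype) pairs over the panel's chromosome count —
with an individual-level option.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import IntervalError

SEGMENT_COLUMNS = [
    "chromosome",
    "start",
    "end",
    "individual",
    "haplotype",
    "ancestry",
    "panel",
    "region",
]

ANCESTRIES = ("archaic", "Neanderthal", "Denisovan", "ambiguous")

__all__ = [
    "GeneInterval",
    "load_segments",
    "overlapping_segments",
    "archaic_frequency",
    "segment_report",
    "synthetic_segment_table",
]


@dataclass(frozen=True)
class GeneInterval:
    """0-based half-open gene interval."""

    gene: str
    chromosome: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise IntervalError(
                f"gene {self.gene!r}: need 0 <= start < end, got [{self.start}, {self.end})"
            )


def load_segments(path_or_frame, one_based: bool = False) -> pd.DataFrame:
    """Load and validate a segment table (TSV path or DataFrame).

    ``one_based=True`` converts 1-based inclusive coordinates to the
    internal 0-based half-open convention at load.
    """
    if isinstance(path_or_frame, pd.DataFrame):
        df = path_or_frame.copy()
    else:
        df = pd.read_csv(Path(path_or_frame), sep="\t", comment="#")
    missing = [c for c in SEGMENT_COLUMNS if c not in df.columns]
    if missing:
        raise IntervalError(f"segment table lacks columns {missing}")
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    if one_based:
        df["start"] = df["start"] - 1
    if (df["start"] < 0).any() or (df["start"] >= df["end"]).any():
        bad = df[(df["start"] < 0) | (df["start"] >= df["end"])]
        raise IntervalError(f"malformed intervals in rows {bad.index.tolist()}")
    if not df["haplotype"].isin([0, 1]).all():
        raise IntervalError("haplotype must be 0 or 1")
    return df


def overlapping_segments(segments: pd.DataFrame, gene: GeneInterval) -> pd.DataFrame:
    """Segments with a non-empty half-open intersection with the gene."""
    mask = (
        (segments["chromosome"].astype(str) == gene.chromosome)
        & (segments["start"] < gene.end)
        & (segments["end"] > gene.start)
    )
    return segments[mask]


def archaic_frequency(
    segments: pd.DataFrame,
    gene: GeneInterval,
    panel_chromosome_counts: Mapping[str, int],
    level: str = "chromosome",
) -> pd.DataFrame:
    """Per-panel and global archaic-carrier frequencies at a gene.

    Frequency = distinct carrying (individual, haplotype) pairs divided by
    the panel's chromosome count (``level="individual"`` counts distinct
    individuals over individual counts instead).  The ``GLOBAL`` row pools
    all panels, so the global frequency is the size-weighted mean of the
    panel frequencies.
    """
    if level not in ("chromosome", "individual"):
        raise IntervalError(f"unknown counting level {level!r}")
    for panel, size in panel_chromosome_counts.items():
        if size <= 0:
            raise IntervalError(f"panel {panel!r} has non-positive size {size}")
    hits = overlapping_segments(segments, gene)
    rows = []
    total_carriers = 0
    total_size = 0
    for panel, size in panel_chromosome_counts.items():
        sub = hits[hits["panel"] == panel]
        if level == "chromosome":
            carriers = sub.drop_duplicates(["individual", "haplotype"]).shape[0]
        else:
            carriers = sub["individual"].nunique()
        rows.append(
            {
                "gene": gene.gene,
                "panel": panel,
                "carriers": carriers,
                "size": size,
                "frequency": carriers / size,
            }
        )
        total_carriers += carriers
        total_size += size
    rows.append(
        {
            "gene": gene.gene,
            "panel": "GLOBAL",
            "carriers": total_carriers,
            "size": total_size,
            "frequency": total_carriers / total_size,
        }
    )
    return pd.DataFrame(rows)


def segment_report(
    segments: pd.DataFrame, gene: GeneInterval, flank: int = 0
) -> pd.DataFrame:
    """Figure-style table of segments overlapping gene ± flank: grouped by
    region, sorted by descending length within region."""
    if flank < 0:
        raise IntervalError("flank must be >= 0")
    window = GeneInterval(
        gene=gene.gene,
        chromosome=gene.chromosome,
        start=max(0, gene.start - flank),
        end=gene.end + flank,
    )
    hits = overlapping_segments(segments, window).copy()
    if hits.empty:
        return pd.DataFrame(columns=SEGMENT_COLUMNS + ["length"])
    hits["length"] = hits["end"] - hits["start"]
    hits = hits.sort_values(
        ["region", "length"], ascending=[True, False], kind="mergesort"
    )
    return hits.reset_index(drop=True)


def synthetic_segment_table(
    panel,
    target_taxon: str,
    locus_spacing: int = 200_000,
    chromosome: str = "chr1",
    ancestry: str = "Neanderthal",
    flank: int = 20_000,
    rng_seed=0,
) -> tuple[pd.DataFrame, dict[str, GeneInterval], dict[str, int]]:
    """Build a segment table and gene intervals from a simulated panel.

    Loci are laid out along one synthetic chromosome (3 bp per codon,
    ``locus_spacing`` apart); every ground-truth introgression carrier of
    *target_taxon* contributes one segment covering the gene with random
    flanks.  Returns (segments, gene intervals, panel chromosome counts);
    individuals are haploid here, so each individual is one chromosome.
    """
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) else np.random.default_rng(rng_seed)
    genes: dict[str, GeneInterval] = {}
    rows = []
    pos = locus_spacing
    for name, ld in panel.loci.items():
        any_tip = next(iter(ld.protein))
        length_nt = 3 * len(ld.protein[any_tip])
        genes[name] = GeneInterval(
            gene=name, chromosome=chromosome, start=pos, end=pos + length_nt
        )
        if ld.truth is not None:
            for tip in sorted(ld.truth.carriers):
                taxon, individual = tip.split("|")[:2]
                if taxon != target_taxon:
                    continue
                lo = pos - int(rng.integers(1, flank))
                hi = pos + length_nt + int(rng.integers(1, flank))
                rows.append(
                    {
                        "chromosome": chromosome,
                        "start": max(0, lo),
                        "end": hi,
                        "individual": individual,
                        "haplotype": 0,
                        "ancestry": ancestry,
                        "panel": panel.panels.get(tip, "P1"),
                        "region": panel.panels.get(tip, "P1"),
                    }
                )
        pos += locus_spacing
    segments = pd.DataFrame(rows, columns=SEGMENT_COLUMNS)
    panel_sizes: dict[str, int] = {}
    for ind in panel.individuals[target_taxon]:
        label = panel.panels.get(f"{target_taxon}|{ind}", "P1")
        panel_sizes[label] = panel_sizes.get(label, 0) + 1
    return segments, genes, panel_sizes
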