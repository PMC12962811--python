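"""The iterative protein-subsampling concatenation experiment.

For each panel size N, repeatedly: sample N loci without replacement, draw
one individual per taxon (independently per locus by default), concatenate
the pre-aligned quartets, fit the quartet by maximum likelihood, optionally
bootstrap, collapse short/unsupported internal branches to a polytomy, and
classify the rooted tree against the reference population tree as
#1 (concordant), #2/#3 (alternative arrangements) or #4 (polytomy).  Each
replicate also counts the amino-acid (or nucleotide) variants among the
ingroup rows, excluding sites variable only in the outgroup.

``IterativeConcatenation.run`` returns an :class:`IterativeResults` holding
every :class:`IterationRecord` plus per-N summaries: label frequencies,
box-plot statistics of the variant counts (type-7 quantiles, whiskers at
q25 − 1.5·IQR and q75 + 1.5·IQR) and bootstrap support grouped by
(N, label), polytomies excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .alignio import Alignment, concatenate
from .errors import AlignmentError, SimulationError, TreeError
from .panel import ProteinPanel
from .quartet import QuartetML, QuartetMLResults, ReferenceTreeSpec

AMBIGUOUS = frozenset("XN?")
GAP = "-"

__all__ = [
    "IterationRecord",
    "IterativeConcatenation",
    "IterativeResults",
    "count_ingroup_variants",
    "boxplot_stats",
    "run_iteration",
    "run_analysis",
    "support_summary",
    "filter_panel",
]


def count_ingroup_variants(concat: Alignment, outgroup: str) -> int:
    """Number of columns with >= 2 distinct non-gap, non-ambiguous states
    among the three ingroup rows; outgroup-only variation is not counted."""
    taxa = concat.taxa
    if outgroup not in taxa:
        raise AlignmentError(f"outgroup {outgroup!r} not in alignment")
    rows = [s for s, t in zip(concat.seqs, taxa) if t != outgroup]
    if len(rows) != 3:
        raise AlignmentError("expected exactly three ingroup rows")
    mat = np.array([np.frombuffer(s.encode(), dtype=np.uint8) for s in rows])
    skip = np.zeros(128, dtype=bool)
    for ch in AMBIGUOUS | {GAP}:
        skip[ord(ch)] = True
    valid = ~skip[mat]
    masked = np.where(valid, mat, 0)
    n_states = np.zeros(mat.shape[1], dtype=int)
    for j in range(mat.shape[1]):
        n_states[j] = len(set(masked[valid[:, j], j]))
    return int((n_states >= 2).sum())


def boxplot_stats(values: Sequence[float]) -> dict[str, float]:
    """Box-plot summary: type-7 quantiles, Tukey-style whisker bounds."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise AlignmentError("boxplot_stats needs at least one value")
    q25, q50, q75 = np.quantile(arr, [0.25, 0.5, 0.75])  # linear (type 7)
    iqr = q75 - q25
    return {
        "mean": float(arr.mean()),
        "median": float(q50),
        "q25": float(q25),
        "q75": float(q75),
        "whisker_lo": float(q25 - 1.5 * iqr),
        "whisker_hi": float(q75 + 1.5 * iqr),
        "min": float(arr.min()),
        "max": float(arr.max()),
        "n": int(arr.size),
    }


@dataclass
class IterationRecord:
    """One replicate of the subsampling experiment."""

    N: int
    rep: int
    loci_used: tuple[str, ...]
    individuals_used: dict[str, tuple[str, ...]]  # taxon -> per-locus ids
    label: str
    n_variants: int
    support: float | None
    topology: str
    llf: float

    def __post_init__(self) -> None:
        if len(set(self.loci_used)) != len(self.loci_used):
            raise SimulationError("loci_used must be distinct")
        if self.n_variants < 0:
            raise SimulationError("n_variants must be non-negative")


class IterativeConcatenation:
    """Model object for the iterative concatenation experiment.

    Parameters
    ----------
    panel : ProteinPanel
        Pre-aligned multi-individual panel.
    ref : ReferenceTreeSpec, optional
        Reference population tree; defaults to the panel's own species tree
        (first two taxa as the expected sister pair).
    data_type : {"protein", "exon", "intron+exon"}
    min_length, min_support : collapse thresholds (defaults 1e-6, 50).
    bootstrap_B : int
        Bootstrap replicates per tree; 0 disables the bootstrap (support
        absent, only the short-branch collapse applies).
    individual_draw : {"per-locus", "per-rep"}
        Whether individuals are redrawn for every locus within a replicate
        or drawn once per replicate.
    """

    def __init__(
        self,
        panel: ProteinPanel,
        ref: ReferenceTreeSpec | None = None,
        data_type: str = "protein",
        min_length: float = 1e-6,
        min_support: float = 50.0,
        bootstrap_B: int = 0,
        individual_draw: str = "per-locus",
    ):
        if individual_draw not in ("per-locus", "per-rep"):
            raise SimulationError(f"unknown individual_draw {individual_draw!r}")
        self.panel = panel
        if ref is None:
            if panel.spec is None:
                raise SimulationError("panel has no species tree; pass ref")
            ref = ReferenceTreeSpec.from_spec(panel.spec)
        if set(ref.taxa) != set(panel.taxa):
            raise TreeError("reference taxa do not match panel taxa")
        self.ref = ref
        self.data_type = data_type
        self.min_length = min_length
        self.min_support = min_support
        self.bootstrap_B = bootstrap_B
        self.individual_draw = individual_draw

    # -- single replicate --------------------------------------------------
    def run_iteration(self, N: int, rng: np.random.Generator, rep: int = 0) -> IterationRecord:
        panel = self.panel
        if not 1 <= N <= panel.n_loci:
            raise SimulationError(f"N={N} outside 1..{panel.n_loci}")
        loci = [
            panel.locus_names[i]
            for i in rng.choice(panel.n_loci, size=N, replace=False)
        ]
        per_rep = panel.sample_individuals(rng) if self.individual_draw == "per-rep" else None
        alignments = []
        used: dict[str, list[str]] = {t: [] for t in panel.taxa}
        for locus in loci:
            chosen = per_rep if per_rep is not None else panel.sample_individuals(rng)
            for t in panel.taxa:
                used[t].append(chosen[t])
            alignments.append(panel.quartet_alignment(locus, chosen, self.data_type))
        concat = concatenate(alignments)
        n_variants = count_ingroup_variants(concat, self.ref.outgroup)
        result = QuartetML(concat).fit()
        if self.bootstrap_B > 0:
            result.bootstrap(self.bootstrap_B, rng, outgroup=self.ref.outgroup)
        result = result.collapse(self.min_length, self.min_support if self.bootstrap_B else None)
        label = result.classify(self.ref)
        return IterationRecord(
            N=N,
            rep=rep,
            loci_used=tuple(loci),
            individuals_used={t: tuple(v) for t, v in used.items()},
            label=label,
            n_variants=n_variants,
            support=result.support,
            topology=result.topology,
            llf=result.llf,
        )

    # -- full experiment ---------------------------------------------------
    def run(self, N_range: Sequence[int], reps: int = 1000, rng_seed=0) -> "IterativeResults":
        if reps < 1:
            raise SimulationError("reps must be >= 1")
        N_range = list(N_range)
        if not N_range:
            raise SimulationError("empty N range")
        if isinstance(rng_seed, (int, np.integer)):
            master = np.random.SeedSequence(int(rng_seed))
        elif isinstance(rng_seed, np.random.SeedSequence):
            master = rng_seed
        else:
            raise SimulationError("rng_seed must be an integer or SeedSequence")
        records: list[IterationRecord] = []
        for N, seed_n in zip(N_range, master.spawn(len(N_range))):
            for rep, seed_rep in enumerate(seed_n.spawn(reps)):
                rng = np.random.default_rng(seed_rep)
                records.append(self.run_iteration(N, rng, rep=rep))
        return IterativeResults(records=records, reps=reps, N_range=N_range, model=self)


@dataclass
class IterativeResults:
    """All replicates plus per-N summaries of the iterative experiment."""

    records: list[IterationRecord]
    reps: int
    N_range: list[int]
    model: IterativeConcatenation | None = None

    LABELS = ("#1", "#2", "#3", "#4")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "N": [r.N for r in self.records],
                "rep": [r.rep for r in self.records],
                "label": [r.label for r in self.records],
                "n_variants": [r.n_variants for r in self.records],
                "support": [r.support for r in self.records],
                "topology": [r.topology for r in self.records],
                "loci_used": [",".join(r.loci_used) for r in self.records],
            }
        )

    def label_frequencies(self) -> pd.DataFrame:
        """Per-N label counts (summing to reps) and percentages."""
        df = self.to_frame()
        rows = []
        for N, grp in df.groupby("N"):
            counts = {lab: int((grp["label"] == lab).sum()) for lab in self.LABELS}
            row = {"N": int(N), **counts}
            for lab in self.LABELS:
                row[f"pct{lab}"] = 100.0 * counts[lab] / len(grp)
            rows.append(row)
        return pd.DataFrame(rows).sort_values("N").reset_index(drop=True)

    def variant_stats(self) -> pd.DataFrame:
        df = self.to_frame()
        rows = []
        for N, grp in df.groupby("N"):
            rows.append({"N": int(N), **boxplot_stats(grp["n_variants"])})
        return pd.DataFrame(rows).sort_values("N").reset_index(drop=True)

    def support_summary(self) -> pd.DataFrame:
        """Bootstrap support stats grouped by (N, label); polytomies excluded."""
        return support_summary(self.records)

    def frequency(self, N: int, label: str) -> float:
        """Fraction of replicates at panel size N with the given label."""
        sub = [r for r in self.records if r.N == N]
        if not sub:
            raise SimulationError(f"no records at N={N}")
        return sum(r.label == label for r in sub) / len(sub)

    def summary(self) -> str:
        freq = self.label_frequencies()
        var = self.variant_stats()
        lines = [
            "Iterative concatenation analysis",
            "=" * 40,
            f"replicates per N: {self.reps}   N grid: {self.N_range}",
            "",
            "label frequencies (% of replicates):",
        ]
        for _, row in freq.iterrows():
            lines.append(
                f"  N={int(row['N']):>3d}  "
                + "  ".join(f"{lab} {row['pct' + lab]:5.1f}%" for lab in self.LABELS)
            )
        lines.append("")
        lines.append("ingroup variant counts:")
        for _, row in var.iterrows():
            lines.append(
                f"  N={int(row['N']):>3d}  mean {row['mean']:6.1f}  "
                f"median {row['median']:6.1f}  IQR [{row['q25']:.1f}, {row['q75']:.1f}]"
            )
        return "\n".join(lines)


def support_summary(records: Sequence[IterationRecord]) -> pd.DataFrame:
    resolved = [r for r in records if r.support is not None and r.label != "#4"]
    rows = []
    seen = sorted({(r.N, r.label) for r in resolved})
    for N, label in seen:
        vals = [r.support for r in resolved if r.N == N and r.label == label]
        rows.append({"N": N, "label": label, **boxplot_stats(vals)})
    return pd.DataFrame(rows)


def filter_panel(panel: ProteinPanel, individual_whitelist: Mapping[str, Sequence[str]]) -> ProteinPanel:
    """Restrict a panel to whitelisted individuals (other taxa untouched)."""
    return panel.filter_individuals(individual_whitelist)


def run_iteration(
    panel: ProteinPanel,
    N: int,
    rng,
    ref: ReferenceTreeSpec | None = None,
    **kwargs,
) -> IterationRecord:
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    return IterativeConcatenation(panel, ref=ref, **kwargs).run_iteration(N, rng)


def run_analysis(
    panel: ProteinPanel,
    N_range: Sequence[int],
    reps: int = 1000,
    rng_seed=0,
    ref: ReferenceTreeSpec | None = None,
    **kwargs,
) -> IterativeResults:
    return IterativeConcatenation(panel, ref=ref, **kwargs).run(
        N_range, reps=reps, rng_seed=rng_seed
    )
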