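"""Per-site conservation scoring: Shannon entropy and evolutionary rates.

Entropy is computed per alignment column in bits over observed state
frequencies; gaps are excluded by default (``as_state`` treats ``-`` as a
21st/5th state) and ambiguity codes never enter the frequencies.  Scores are
aggregated to a total, a per-length average, and a codon-corrected per-length
average that makes nucleotide and amino-acid data types comparable (a codon
is three sites wide): by default the nucleotide per-length score is divided
by three while the protein score is kept intact; the converse convention is
available via ``side="protein"``.

The evolutionary-rate score is a deliberately simple stand-in for
empirical-Bayes site-rate programs: for each site the branch lengths of a
fixed quartet tree are rescaled by a site-specific factor ``r`` estimated by
maximum likelihood (JC69 / Poisson amino-acid model), and rates are
normalized to mean 1 across sites.  It is validated at the ranking level
only.

``resampled_scores`` implements the multi-individual protocol: draw one
individual per taxon, score the quartet, repeat, and report the mean profile
with its Monte-Carlo standard error.
"""

from __future__ import annotations

import math
from collections import Counter, OrderedDict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .alignio import Alignment
from .errors import AlignmentError, TreeError
from .quartet import SPLITS, _loglike, encode_patterns

DATA_TYPES = ("protein", "exon", "intron+exon")
AMBIGUOUS = frozenset("XN?")
GAP = "-"

__all__ = [
    "ConservationProfile",
    "column_entropy",
    "profile_entropy",
    "codon_correct",
    "site_rates",
    "resampled_scores",
    "rank_loci",
]


def _check_data_type(data_type: str) -> None:
    if data_type not in DATA_TYPES:
        raise AlignmentError(
            f"unknown data type {data_type!r}; expected one of {DATA_TYPES}"
        )


def column_entropy(column: str | Iterable[str], gap_policy: str = "exclude") -> float:
    """Shannon entropy of one alignment column in bits.

    Frequencies are over observed states; ambiguity codes are always
    dropped.  ``gap_policy="exclude"`` drops gaps too (an all-gap column is
    reported as 0); ``"as_state"`` counts the gap as a state of its own.
    """
    h, _ = _column_entropy_flag(column, gap_policy)
    return h


def _column_entropy_flag(column, gap_policy: str) -> tuple[float, bool]:
    if gap_policy not in ("exclude", "as_state"):
        raise AlignmentError(f"unknown gap policy {gap_policy!r}")
    residues = [c.upper() for c in column]
    if not residues:
        raise AlignmentError("empty column")
    counted = [
        c
        for c in residues
        if c not in AMBIGUOUS and (gap_policy == "as_state" or c != GAP)
    ]
    if not counted:
        return 0.0, True  # undefined (all gap/ambiguous), flagged
    n = len(counted)
    h = 0.0
    for cnt in Counter(counted).values():
        p = cnt / n
        h -= p * math.log2(p)
    return h, False


@dataclass
class ConservationProfile:
    """Per-site conservation scores of one locus and data type."""

    locus: str
    data_type: str
    metric: str  # "entropy" (bits) or "rate" (relative, mean 1)
    per_site: np.ndarray
    undefined_sites: np.ndarray = field(default_factory=lambda: np.zeros(0, bool))
    gap_policy: str = "exclude"
    mc_se_per_length: float | None = None  # set by resampled_scores

    @property
    def n_sites(self) -> int:
        return int(self.per_site.size)

    @property
    def total(self) -> float:
        return float(self.per_site.sum())

    @property
    def per_length(self) -> float:
        return self.total / self.n_sites

    @property
    def codon_corrected_per_length(self) -> float:
        return codon_correct(self.per_length, self.data_type)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "site": np.arange(self.n_sites),
                "score": self.per_site,
                "undefined": self.undefined_sites
                if self.undefined_sites.size
                else np.zeros(self.n_sites, bool),
            }
        )


def profile_entropy(
    aln: Alignment, data_type: str, gap_policy: str = "exclude"
) -> ConservationProfile:
    """Column-wise entropy profile with total and per-length summaries."""
    _check_data_type(data_type)
    if aln.width < 1:
        raise AlignmentError("zero-width alignment")
    scores = np.empty(aln.width)
    flags = np.zeros(aln.width, dtype=bool)
    for j, col in enumerate(aln.columns()):
        scores[j], flags[j] = _column_entropy_flag(col, gap_policy)
    return ConservationProfile(
        locus=aln.name or "locus",
        data_type=data_type,
        metric="entropy",
        per_site=scores,
        undefined_sites=flags,
        gap_policy=gap_policy,
    )


def codon_correct(per_length_score: float, data_type: str, side: str = "nucleotide") -> float:
    """Apply the divide-by-3 codon length correction to a per-site score.

    ``side="nucleotide"`` (default): nucleotide data types are divided by 3
    and protein kept intact; ``side="protein"``: the converse.  Both yield
    the same between-type comparison, on different absolute scales.
    """
    _check_data_type(data_type)
    if per_length_score < 0:
        raise AlignmentError("scores must be non-negative")
    if side not in ("nucleotide", "protein"):
        raise AlignmentError(f"unknown correction side {side!r}")
    is_nt = data_type in ("exon", "intron+exon")
    if (side == "nucleotide") == is_nt:
        return per_length_score / 3.0
    return per_length_score


def site_rates(aln: Alignment, fixed_tree, data_type: str | None = None) -> ConservationProfile:
    """Per-site ML rate scaling of a fixed quartet tree, normalized to mean 1.

    *fixed_tree* is a fitted :class:`~paleoquartet.quartet.QuartetMLResults`
    (or any object with ``split``, ``taxa`` and ``branch_lengths``); its
    taxa must match the alignment rows.  Sites with no data keep rate 1.
    """
    if data_type is None:
        data_type = "protein" if aln.alphabet == "protein" else "exon"
    _check_data_type(data_type)
    taxa = tuple(i.split("|")[0] for i in aln.ids)
    if set(taxa) != set(fixed_tree.taxa):
        raise TreeError(
            f"tree taxa {sorted(fixed_tree.taxa)} do not match alignment "
            f"taxa {sorted(taxa)}"
        )
    split = fixed_tree.split if fixed_tree.split is not None else SPLITS[0]
    # express the tree's split in terms of this alignment's row order
    row_of = {t: i for i, t in enumerate(taxa)}
    split_rows = tuple(
        tuple(row_of[fixed_tree.taxa[i]] for i in side) for side in split
    )
    base = [
        fixed_tree.branch_lengths[fixed_tree.taxa[i]]
        for side in split
        for i in side
    ] + [fixed_tree.branch_lengths.get("internal", 0.0)]
    base = np.maximum(np.asarray(base, dtype=float), 1e-6)

    tips, counts, k = encode_patterns(aln, aln.alphabet)
    n_pat = len(counts)
    rates = np.ones(n_pat)
    one = np.ones(1)
    for p in range(n_pat):
        pat_tips = [t[p : p + 1] for t in tips]
        if all(row.min() == 1.0 for row in pat_tips):
            rates[p] = 1.0  # all-missing column: no information
            continue

        def neg(r):
            return -_loglike(pat_tips, one, split_rows, list(r * base), k)

        res = minimize_scalar(neg, bounds=(0.0, 50.0), method="bounded",
                              options={"xatol": 1e-6})
        rates[p] = float(res.x) if res.x > 1e-8 else 0.0

    # expand pattern rates back to sites
    per_site = _expand_pattern_values(aln, rates)
    mean = per_site.mean()
    if mean > 0:
        per_site = per_site / mean
    else:
        per_site = np.ones_like(per_site)
    return ConservationProfile(
        locus=aln.name or "locus",
        data_type=data_type,
        metric="rate",
        per_site=per_site,
    )


def _expand_pattern_values(aln: Alignment, pattern_values: np.ndarray) -> np.ndarray:
    mat = np.array([np.frombuffer(s.encode(), dtype=np.uint8) for s in aln.seqs])
    patterns, inverse = np.unique(mat.T, axis=0, return_inverse=True)
    # encode_patterns uses the same np.unique ordering on mapped codes; map
    # raw columns to the same ordering by re-deriving codes identically
    from .quartet import _states_for

    states = _states_for(aln.alphabet)
    lut = np.full(128, -1, dtype=np.int64)
    for i, ch in enumerate(states):
        lut[ord(ch)] = i
    codes = lut[mat]
    _, inverse = np.unique(codes.T, axis=0, return_inverse=True)
    return pattern_values[inverse]


@dataclass
class ResampledProfile:
    """Mean conservation profile over individual-resampling replicates."""

    locus: str
    data_type: str
    metric: str
    reps: int
    mean_per_site: np.ndarray
    mean_total: float
    mean_per_length: float
    se_per_length: float

    @property
    def codon_corrected_per_length(self) -> float:
        return codon_correct(self.mean_per_length, self.data_type)


def resampled_scores(
    panel,
    data_type: str = "protein",
    metric: str = "entropy",
    reps: int = 1000,
    rng_seed=0,
    gap_policy: str = "exclude",
) -> "OrderedDict[str, ResampledProfile]":
    """Mean conservation profile per locus over quartet resampling replicates.

    Each replicate draws one individual per taxon (independently per locus),
    scores the resulting 4-sequence alignment, and the mean per-site profile
    and Monte-Carlo SE of the per-length score are reported.
    """
    from .quartet import QuartetML  # local import to avoid cycle at import time

    if reps < 1:
        raise AlignmentError("reps must be >= 1")
    if metric not in ("entropy", "rate"):
        raise AlignmentError(f"unknown metric {metric!r}")
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) else np.random.default_rng(rng_seed)
    out: "OrderedDict[str, ResampledProfile]" = OrderedDict()
    for locus in panel.locus_names:
        sums = None
        totals = []
        for _ in range(reps):
            chosen = panel.sample_individuals(rng)
            aln = panel.quartet_alignment(locus, chosen, data_type)
            if metric == "entropy":
                prof = profile_entropy(aln, data_type, gap_policy)
            else:
                tree = QuartetML(aln).fit()
                prof = site_rates(aln, tree, data_type)
            sums = prof.per_site if sums is None else sums + prof.per_site
            totals.append(prof.per_length)
        totals = np.asarray(totals)
        mean_site = sums / reps
        out[locus] = ResampledProfile(
            locus=locus,
            data_type=data_type,
            metric=metric,
            reps=reps,
            mean_per_site=mean_site,
            mean_total=float(mean_site.sum()),
            mean_per_length=float(totals.mean()),
            se_per_length=float(totals.std(ddof=1) / math.sqrt(reps)) if reps > 1 else 0.0,
        )
    return out


def rank_loci(
    profiles: Sequence[ConservationProfile | ResampledProfile],
    normalize: bool = False,
    codon_corrected: bool = False,
) -> pd.DataFrame:
    """Rank loci from most to least variable.

    ``normalize=False`` ranks by total score, ``normalize=True`` by the
    per-length average (optionally codon-corrected).  Ties are broken
    lexicographically by locus name and flagged.
    """
    if not profiles:
        raise AlignmentError("nothing to rank")
    data_types = {p.data_type for p in profiles}
    if len(data_types) > 1:
        raise AlignmentError(
            f"cannot rank mixed data types {sorted(data_types)} together"
        )
    rows = []
    for p in profiles:
        total = getattr(p, "mean_total", None)
        if total is None:
            total = p.total
        per_len = getattr(p, "mean_per_length", None)
        if per_len is None:
            per_len = p.per_length
        corrected = codon_correct(per_len, p.data_type)
        rows.append(
            {
                "locus": p.locus,
                "data_type": p.data_type,
                "total": total,
                "per_length": per_len,
                "codon_corrected": corrected,
            }
        )
    df = pd.DataFrame(rows)
    if normalize:
        key = "codon_corrected" if codon_corrected else "per_length"
    else:
        key = "total"
    df = df.sort_values([key, "locus"], ascending=[False, True], kind="mergesort")
    df["rank"] = np.arange(1, len(df) + 1)
    df["tied"] = df.duplicated(subset=[key], keep=False)
    return df.reset_index(drop=True)
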