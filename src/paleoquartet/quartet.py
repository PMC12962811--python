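"""Exhaustive maximum-likelihood inference of 4-leaf gene trees.

All trees in this pipeline have exactly four leaves, so instead of heuristic
tree search the three possible unrooted topologies are each fitted exactly
(Felsenstein pruning, five branch lengths optimized by cyclic bounded
one-dimensional search) and the best is kept.  Substitution models are
equal-rates multistate models: JC69 for nucleotides and a Poisson model
(uniform frequencies and exchangeabilities) for amino acids — at hominid
divergences topology choice is driven by shared derived states, not by
exchangeability detail.

Exact likelihood ties between topologies, or an internal branch below the
collapse threshold, yield a hard polytomy rather than a random winner.  A
fitted quartet is classified against a reference population tree by rooting
on the outgroup and mapping the ingroup sister pair to the labels
#1 (concordant), #2/#3 (the two alternative arrangements) or #4 (polytomy).

The public surface is statsmodels-flavoured: :class:`QuartetML` is the model
object, :meth:`QuartetML.fit` returns a :class:`QuartetMLResults` carrying
estimates, bootstrap support, collapse and classification; the module-level
functions are thin wrappers over that pair.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import minimize_scalar

from .alignio import Alignment
from .errors import TreeError

DNA_STATES = "ACGT"
AA_STATES = "ACDEFGHIKLMNPQRSTVWY"

#: the three unrooted splits of rows (0,1,2,3)
SPLITS = (((0, 1), (2, 3)), ((0, 2), (1, 3)), ((0, 3), (1, 2)))

MAX_BRANCH = 10.0
TIE_TOL = 1e-6


def transition_matrix(t: float, k: int) -> np.ndarray:
    """Equal-rates k-state transition probabilities for branch length *t*
    (expected substitutions per site)."""
    if t < 0 or not math.isfinite(t):
        raise TreeError(f"branch length must be finite and non-negative, got {t}")
    e = math.exp(-k * t / (k - 1))
    p_same = 1.0 / k + (1.0 - 1.0 / k) * e
    p_diff = (1.0 - e) / k
    out = np.full((k, k), p_diff)
    np.fill_diagonal(out, p_same)
    return out


def _states_for(alphabet: str) -> str:
    if alphabet == "dna":
        return DNA_STATES
    if alphabet == "protein":
        return AA_STATES
    raise TreeError(f"no substitution model for alphabet {alphabet!r}")


def encode_patterns(aln: Alignment, model: str | None = None):
    """Collapse an alignment into unique site patterns.

    Returns (tips, counts, k): ``tips`` is a list of 4 arrays of shape
    (n_patterns, k) of partial likelihoods at the leaves; gaps and ambiguity
    codes are missing data (all-ones rows).
    """
    if aln.n != 4:
        raise TreeError(f"quartet inference needs exactly 4 rows, got {aln.n}")
    if aln.width < 1:
        raise TreeError("alignment has no columns")
    alphabet = model or aln.alphabet
    states = _states_for(alphabet)
    k = len(states)
    lut = np.full(128, -1, dtype=np.int64)
    for i, ch in enumerate(states):
        lut[ord(ch)] = i
    mat = np.array(
        [np.frombuffer(s.encode(), dtype=np.uint8) for s in aln.seqs]
    )
    codes = lut[mat]  # (4, width); -1 = missing
    patterns, counts = np.unique(codes.T, axis=0, return_counts=True)
    tips = []
    for row in range(4):
        col = patterns[:, row]
        part = np.ones((len(patterns), k))
        known = col >= 0
        part[known] = 0.0
        part[known, col[known]] = 1.0
        tips.append(part)
    return tips, counts.astype(float), k


def _site_likelihoods(tips, split, bl, k) -> np.ndarray:
    (i, j), (l, m) = split
    p_i = transition_matrix(bl[0], k)
    p_j = transition_matrix(bl[1], k)
    p_l = transition_matrix(bl[2], k)
    p_m = transition_matrix(bl[3], k)
    p_int = transition_matrix(bl[4], k)
    up_x = (tips[i] @ p_i.T) * (tips[j] @ p_j.T)
    up_y = (tips[l] @ p_l.T) * (tips[m] @ p_m.T)
    return (up_x * (up_y @ p_int.T)).sum(axis=1) / k


def _loglike(tips, counts, split, bl, k) -> float:
    site = _site_likelihoods(tips, split, bl, k)
    if (site <= 0).any():
        return -np.inf
    return float(counts @ np.log(site))


def quartet_log_likelihood(
    aln: Alignment,
    topology: Sequence[Sequence[int]] | int,
    branch_lengths: Sequence[float],
    model: str | None = None,
) -> float:
    """Log-likelihood of one unrooted quartet topology.

    *topology* is a split index (0..2) or an explicit pair-of-pairs of row
    indices; *branch_lengths* are the 4 pendant lengths (ordered as the split
    lists the rows) followed by the internal length.
    """
    tips, counts, k = encode_patterns(aln, model)
    split = SPLITS[topology] if isinstance(topology, int) else topology
    bl = [float(b) for b in branch_lengths]
    if len(bl) != 5:
        raise TreeError("need 5 branch lengths (4 pendant + internal)")
    return _loglike(tips, counts, split, bl, k)


def _optimize_split(tips, counts, split, k, tol=1e-8, max_cycles=30):
    """Cyclic bounded 1-D optimization of the five branch lengths."""
    bl = [0.1] * 5
    best = _loglike(tips, counts, split, bl, k)
    for _ in range(max_cycles):
        prev = best
        for b in range(5):
            def obj(x, b=b):
                trial = list(bl)
                trial[b] = x
                return -_loglike(tips, counts, split, trial, k)

            res = minimize_scalar(
                obj, bounds=(0.0, MAX_BRANCH), method="bounded",
                options={"xatol": 1e-7},
            )
            if -res.fun > best:
                bl[b] = float(res.x)
                best = -res.fun
        if best - prev <= tol * max(1.0, abs(best)):
            break
    # snap numerically-zero lengths
    bl = [0.0 if b < 1e-9 else b for b in bl]
    best = _loglike(tips, counts, split, bl, k)
    return bl, best


@dataclass
class ReferenceTreeSpec:
    """Reference population tree for quartet classification.

    ``ingroup_pair`` is the sister pair expected under topology #1; the
    remaining ingroup taxon is paired with the first / second element of
    ``ingroup_pair`` under #2 / #3 respectively.
    """

    ingroup_pair: tuple[str, str]
    third: str
    outgroup: str

    def __post_init__(self) -> None:
        names = set(self.ingroup_pair) | {self.third, self.outgroup}
        if len(names) != 4:
            raise TreeError("reference tree needs four distinct taxa")

    @property
    def taxa(self) -> frozenset[str]:
        return frozenset(self.ingroup_pair) | {self.third, self.outgroup}

    def label_of(self, sister_pair: frozenset[str]) -> str:
        x, y = self.ingroup_pair
        mapping = {
            frozenset((x, y)): "#1",
            frozenset((self.third, x)): "#2",
            frozenset((self.third, y)): "#3",
        }
        if sister_pair not in mapping:
            raise TreeError(f"pair {sorted(sister_pair)} not an ingroup pair")
        return mapping[sister_pair]

    @classmethod
    def hominid(cls) -> "ReferenceTreeSpec":
        return cls(ingroup_pair=("Homo", "Pan"), third="Gorilla", outgroup="Pongo")

    @classmethod
    def hominin(cls) -> "ReferenceTreeSpec":
        return cls(
            ingroup_pair=("Neanderthal", "Denisovan"),
            third="Sapiens",
            outgroup="Pan",
        )

    @classmethod
    def from_spec(cls, spec) -> "ReferenceTreeSpec":
        a, b, c, out = spec.taxa
        return cls(ingroup_pair=(a, b), third=c, outgroup=out)


@dataclass
class QuartetMLResults:
    """Fitted quartet: estimates, uncertainty and classification hooks."""

    taxa: tuple[str, str, str, str]
    split: tuple[tuple[int, int], tuple[int, int]] | None  # None = polytomy
    branch_lengths: dict[str, float]
    llf: float
    llf_by_split: tuple[float, float, float]
    model: str
    n_sites: int
    support: float | None = None
    _tips: object = None
    _counts: object = None
    _k: int = 0

    # -- basic properties --------------------------------------------------
    @property
    def is_polytomy(self) -> bool:
        return self.split is None

    @property
    def topology(self) -> str:
        if self.is_polytomy:
            return "POLYTOMY"
        (i, j), (l, m) = self.split
        return (
            f"(({self.taxa[i]},{self.taxa[j]}),({self.taxa[l]},{self.taxa[m]}))"
        )

    @property
    def internal_length(self) -> float:
        return self.branch_lengths.get("internal", 0.0)

    def sister_pair(self, outgroup: str) -> frozenset[str] | None:
        """The resolved ingroup cherry after rooting on *outgroup*."""
        if self.is_polytomy:
            return None
        if outgroup not in self.taxa:
            raise TreeError(f"outgroup {outgroup!r} not among quartet taxa")
        for side in self.split:
            names = {self.taxa[i] for i in side}
            if outgroup not in names:
                return frozenset(names)
        raise TreeError("internal inconsistency in split")

    def newick(self) -> str:
        if self.is_polytomy:
            tips = ",".join(f"{t}:0.0" for t in self.taxa)
            return f"({tips});"
        (i, j), (l, m) = self.split
        bl = self.branch_lengths
        half = bl["internal"] / 2.0
        sup = "" if self.support is None else f"{self.support:g}"
        return (
            f"(({self.taxa[i]}:{bl[self.taxa[i]]:.6f},"
            f"{self.taxa[j]}:{bl[self.taxa[j]]:.6f}){sup}:{half:.6f},"
            f"({self.taxa[l]}:{bl[self.taxa[l]]:.6f},"
            f"{self.taxa[m]}:{bl[self.taxa[m]]:.6f}):{half:.6f});"
        )

    # -- post-fit operations ----------------------------------------------
    def bootstrap(self, B: int = 100, rng_seed=0, outgroup: str | None = None) -> float | None:
        """Nonparametric column-bootstrap support of the inferred split.

        Support = percentage of B column-resamples whose refitted ML
        topology recovers the same ingroup pair (or the same split when no
        outgroup is given).  Polytomies carry no support (None).  The value
        is cached on ``self.support``.
        """
        if B < 1:
            raise TreeError("B must be >= 1")
        if self.is_polytomy:
            self.support = None
            return None
        rng = np.random.default_rng(rng_seed) if not isinstance(
            rng_seed, np.random.Generator
        ) else rng_seed
        n = int(self._counts.sum())
        probs = self._counts / n
        hits = 0
        target = self.split
        for _ in range(B):
            counts_b = rng.multinomial(n, probs).astype(float)
            keep = counts_b > 0
            fit_b = _fit_patterns(
                [t[keep] for t in self._tips], counts_b[keep], self._k,
                self.taxa, self.model, n,
            )
            if fit_b.split is None:
                continue
            if outgroup is None:
                hits += fit_b.split == target
            else:
                hits += fit_b.sister_pair(outgroup) == self.sister_pair(outgroup)
        self.support = 100.0 * hits / B
        return self.support

    def collapse(self, min_length: float = 1e-6, min_support: float | None = 50.0) -> "QuartetMLResults":
        """Collapse a short or unsupported internal branch into a polytomy.

        Pendant branches are never collapsed.  ``min_support`` only applies
        when bootstrap support has been computed.
        """
        if min_length < 0 or (min_support is not None and min_support < 0):
            raise TreeError("collapse thresholds must be non-negative")
        if self.is_polytomy:
            return self
        short = self.internal_length < min_length
        unsupported = (
            min_support is not None
            and self.support is not None
            and self.support < min_support
        )
        if not (short or unsupported):
            return self
        return replace(self, split=None, support=None)

    def classify(self, ref: ReferenceTreeSpec) -> str:
        """Label #1-#4 relative to the reference population tree."""
        if set(self.taxa) != set(ref.taxa):
            raise TreeError(
                f"taxa {sorted(self.taxa)} do not match reference {sorted(ref.taxa)}"
            )
        # Rooting on the outgroup pendant edge makes the cherry that excludes
        # the outgroup the resolved ingroup sister pair, whichever side of
        # the split the outgroup fell on.
        pair = self.sister_pair(ref.outgroup)
        if pair is None:
            return "#4"
        return ref.label_of(pair)

    def summary(self) -> str:
        lines = [
            "Quartet maximum-likelihood fit",
            "=" * 34,
            f"model:            {self.model}",
            f"sites:            {self.n_sites}",
            f"topology:         {self.topology}",
            f"log-likelihood:   {self.llf:.4f}",
        ]
        for name, val in self.branch_lengths.items():
            lines.append(f"  branch {name:<12s} {val:.6f}")
        if self.support is not None:
            lines.append(f"bootstrap support: {self.support:.1f}%")
        lls = ", ".join(f"{v:.3f}" for v in self.llf_by_split)
        lines.append(f"lnL by topology:  [{lls}]")
        return "\n".join(lines)


def _fit_patterns(tips, counts, k, taxa, model, n_sites) -> QuartetMLResults:
    fits = [_optimize_split(tips, counts, s, k) for s in SPLITS]
    lls = np.array([f[1] for f in fits])
    order = np.argsort(lls)[::-1]
    best = int(order[0])
    tie = lls[order[0]] - lls[order[1]] < TIE_TOL
    bl_best, ll_best = fits[best]
    split = SPLITS[best]
    branch_lengths = {}
    flat = [idx for side in split for idx in side]
    for pos, row in enumerate(flat):
        branch_lengths[taxa[row]] = bl_best[pos]
    branch_lengths["internal"] = bl_best[4]
    return QuartetMLResults(
        taxa=taxa,
        split=None if tie else split,
        branch_lengths=branch_lengths,
        llf=float(ll_best),
        llf_by_split=tuple(float(v) for v in lls),
        model=model,
        n_sites=n_sites,
        _tips=tips,
        _counts=counts,
        _k=k,
    )


class QuartetML:
    """Maximum-likelihood quartet model for one 4-row alignment.

    Parameters
    ----------
    alignment : Alignment
        Exactly four rows; gaps and ambiguity codes are treated as missing.
    model : {"JC69", "poisson-aa", None}
        None selects JC69 for DNA and the Poisson amino-acid model for
        protein alignments.
    """

    def __init__(self, alignment: Alignment, model: str | None = None):
        self.alignment = alignment
        if model in ("JC69", "jc69", "dna"):
            self._alphabet = "dna"
        elif model in ("poisson-aa", "poisson", "aa"):
            self._alphabet = "protein"
        elif model is None:
            self._alphabet = alignment.alphabet
        else:
            raise TreeError(f"unknown model {model!r}")
        self.model = "JC69" if self._alphabet == "dna" else "poisson-aa"
        self.taxa = tuple(i.split("|")[0] for i in alignment.ids)
        self._tips, self._counts, self._k = encode_patterns(
            alignment, self._alphabet
        )

    def loglike(self, topology, branch_lengths) -> float:
        split = SPLITS[topology] if isinstance(topology, int) else topology
        return _loglike(
            self._tips, self._counts, split, list(branch_lengths), self._k
        )

    def fit(self) -> QuartetMLResults:
        return _fit_patterns(
            self._tips,
            self._counts,
            self._k,
            self.taxa,
            self.model,
            self.alignment.width,
        )


# ---------------------------------------------------------------------------
# Functional wrappers
# ---------------------------------------------------------------------------


def fit_quartet(aln: Alignment, model: str | None = None) -> QuartetMLResults:
    return QuartetML(aln, model=model).fit()


def bootstrap_support(
    aln: Alignment,
    model: str | None = None,
    B: int = 100,
    rng_seed=0,
    outgroup: str | None = None,
) -> float | None:
    return fit_quartet(aln, model=model).bootstrap(B=B, rng_seed=rng_seed, outgroup=outgroup)


def collapse_branches(
    result: QuartetMLResults, min_length: float = 1e-6, min_support: float | None = 50.0
) -> QuartetMLResults:
    return result.collapse(min_length=min_length, min_support=min_support)


def classify(result: QuartetMLResults, ref: ReferenceTreeSpec) -> str:
    return result.classify(ref)
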