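"""Coalescent simulation of quartet gene trees and codon sequence evolution.

Time is measured in coalescent units (2N generations of a reference
population) throughout.  The species tree is a fixed 4-taxon shape
``((a, b), c, outgroup)``: *a* and *b* split at ``t1``, their ancestor joins
*c* at ``t2`` and the ingroup joins the outgroup at ``t3``.  Each branch of
the species tree is one population; per-branch effective sizes enter as
relative scaling factors of the pairwise coalescence rate.

With one sampled lineage per taxon the probability that the gene tree is
discordant with the species tree is the classic ``(2/3) * exp(-T)`` where
``T = (t2 - t1)`` rescaled by the sister-ancestor population size — this
closed form is the primary correctness check of the engine.

Introgression is modelled at the haplotype level: a sampled lineage carrying
an archaic haplotype belongs, from the present back to the pulse time, to a
private population that merges into the source taxon's branch at the pulse
time.  For a single sampled lineage per taxon this is distributionally
identical to reassigning the target lineage to the source branch with
probability *m* at the event time; with several sampled individuals it
additionally prevents the archaic haplotype from coalescing with
non-introgressed haplotypes more recently than the pulse, which is the
correct genealogy of an introgressed segment.

Sequences evolve codon-wise under a simplified GY94-style process: each of
the three codon positions mutates at rate ``mu`` per coalescent unit
(uniformly to one of the three alternative bases), nonsynonymous changes are
accepted with relative rate ``omega``, proposed stop codons are rejected,
and per-codon relative rates come from the locus rate profile.  At
``omega = 1`` with stops ignored this is exactly JC69 with substitution rate
``mu`` per site, so branch lengths convert to expected substitutions per
site by multiplying with ``mu`` (per codon: ``3 * mu``).  Neutral intron
flanks evolve under exact JC69 endpoint sampling.
"""

from __future__ import annotations

from collections import OrderedDict
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from Bio.Data import CodonTable

from .errors import SimulationError

__all__ = [
    "AdmixtureEvent",
    "SpeciesTreeSpec",
    "LocusModel",
    "GeneTreeSample",
    "Node",
    "simulate_gene_tree",
    "evolve_sequences",
    "discordance_probability",
    "hominid_like",
    "hominin_like",
    "conserved_locus_models",
]


# ---------------------------------------------------------------------------
# Species-tree specification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AdmixtureEvent:
    """A single admixture pulse: *target* receives a fraction *m* of its
    lineages from *source* at *time* (coalescent units before present).

    ``panels`` optionally restricts eligibility to sampled individuals whose
    population panel label is in the set (used to emulate admixed vs
    unadmixed present-day panels)."""

    source: str
    target: str
    time: float
    proportion: float
    panels: tuple[str, ...] | None = None


@dataclass(frozen=True)
class SpeciesTreeSpec:
    """Population tree for four taxa ``(a, b, c, outgroup)`` with ``(a, b)``
    as the expected sister pair.

    ``split_times = (t1, t2, t3)`` in coalescent units; ``pop_sizes`` maps a
    branch to its relative effective size (keys: taxon names plus
    ``anc_sister``, ``anc_ingroup``, ``root``; default 1.0 each).
    """

    taxa: tuple[str, str, str, str]
    split_times: tuple[float, float, float]
    pop_sizes: Mapping[str, float] = field(default_factory=dict)
    admixture: tuple[AdmixtureEvent, ...] = ()

    def __post_init__(self) -> None:
        if len(self.taxa) != 4 or len(set(self.taxa)) != 4:
            raise SimulationError("need four distinct taxon names")
        t1, t2, t3 = self.split_times
        if not (0 < t1 <= t2 < t3):
            raise SimulationError(
                f"split times must satisfy 0 < t1 <= t2 < t3, got {self.split_times}"
            )
        for pop, ne in self.pop_sizes.items():
            if pop not in self._valid_pops():
                raise SimulationError(f"unknown population {pop!r}")
            if ne <= 0:
                raise SimulationError(f"population size factor for {pop!r} must be > 0")
        for ev in self.admixture:
            if not 0.0 <= ev.proportion <= 1.0:
                raise SimulationError("admixture proportion must be in [0, 1]")
            if ev.source not in self.taxa or ev.target not in self.taxa:
                raise SimulationError("admixture source/target must be sampled taxa")
            if ev.source == ev.target:
                raise SimulationError("admixture source and target must differ")
            limit = min(self._merge_time(ev.source), self._merge_time(ev.target))
            if not 0 < ev.time < limit:
                raise SimulationError(
                    f"admixture time {ev.time} outside the joint lifetime of "
                    f"{ev.source!r} and {ev.target!r} (< {limit})"
                )

    def _valid_pops(self) -> set[str]:
        return set(self.taxa) | {"anc_sister", "anc_ingroup", "root"}

    def _merge_time(self, taxon: str) -> float:
        t1, t2, t3 = self.split_times
        a, b, c, out = self.taxa
        return {a: t1, b: t1, c: t2, out: t3}[taxon]

    @property
    def outgroup(self) -> str:
        return self.taxa[3]

    @property
    def sister_pair(self) -> tuple[str, str]:
        return (self.taxa[0], self.taxa[1])

    def pop_size(self, pop: str) -> float:
        return float(self.pop_sizes.get(pop, 1.0))

    @property
    def internal_branch_T(self) -> float:
        """Duration of the sister-ancestor branch in its own coalescent units."""
        t1, t2, _ = self.split_times
        return (t2 - t1) / self.pop_size("anc_sister")


def discordance_probability(spec: SpeciesTreeSpec) -> float:
    """Closed-form gene-tree discordance probability (no admixture)."""
    return (2.0 / 3.0) * float(np.exp(-spec.internal_branch_T))


# ---------------------------------------------------------------------------
# Gene trees
# ---------------------------------------------------------------------------


@dataclass
class Node:
    """Rooted gene-tree node; ``time`` in coalescent units before present."""

    time: float
    name: str | None = None
    children: list["Node"] = field(default_factory=list)

    def leaves(self) -> list["Node"]:
        if not self.children:
            return [self]
        out: list[Node] = []
        for ch in self.children:
            out.extend(ch.leaves())
        return out

    def leaf_names(self) -> frozenset[str]:
        return frozenset(leaf.name for leaf in self.leaves())

    def newick(self) -> str:
        return self._newick(self.time) + ";"

    def _newick(self, parent_time: float) -> str:
        bl = parent_time - self.time
        if not self.children:
            return f"{self.name}:{bl:.6f}"
        inner = ",".join(ch._newick(self.time) for ch in self.children)
        if parent_time == self.time and self.name is None and bl == 0.0:
            return f"({inner})"  # root
        return f"({inner}):{bl:.6f}"


def mrca_time(root: Node, a: str, b: str) -> float:
    """Time of the most recent common ancestor of leaves *a* and *b*."""
    best = root.time
    node = root
    while True:
        nxt = None
        for ch in node.children:
            names = ch.leaf_names()
            if a in names and b in names:
                nxt = ch
                break
        if nxt is None:
            return node.time
        node = nxt


@dataclass
class GeneTreeSample:
    """One simulated gene tree with its ground truth."""

    newick: str
    topology_class: str  # concordant | discordant-A | discordant-B
    ils_flag: bool
    introgressed_flag: bool
    root: Node
    introgressed_tips: frozenset[str]
    tip_names: tuple[str, ...]


def _as_rng(rng_seed) -> np.random.Generator:
    if isinstance(rng_seed, np.random.Generator):
        return rng_seed
    if isinstance(rng_seed, np.random.SeedSequence):
        return np.random.default_rng(rng_seed)
    if not isinstance(rng_seed, (int, np.integer)) or rng_seed < 0:
        raise SimulationError(f"seed must be a non-negative integer, got {rng_seed!r}")
    return np.random.default_rng(int(rng_seed))


def _coalesce_interval(
    lineages: list[tuple[Node, str]],
    t0: float,
    t_end: float,
    pop_size,
    rng: np.random.Generator,
) -> float:
    """Run the multi-population coalescent from *t0* to *t_end* (may be inf)."""
    t = t0
    while True:
        pops: dict[str, list[int]] = {}
        for i, (_, pop) in enumerate(lineages):
            pops.setdefault(pop, []).append(i)
        rates = {
            p: len(idx) * (len(idx) - 1) / 2.0 / pop_size(p)
            for p, idx in pops.items()
            if len(idx) >= 2
        }
        total = sum(rates.values())
        if total == 0.0:
            return t_end
        dt = rng.exponential(1.0 / total)
        if t + dt > t_end:
            return t_end
        t += dt
        pick = rng.random() * total
        acc = 0.0
        chosen = None
        for p in sorted(rates):
            acc += rates[p]
            if pick <= acc:
                chosen = p
                break
        idx = pops[chosen]
        i, j = rng.choice(len(idx), size=2, replace=False)
        i, j = idx[min(i, j)], idx[max(i, j)]
        parent = Node(time=t, children=[lineages[i][0], lineages[j][0]])
        lineages[i] = (parent, chosen)
        del lineages[j]


def _simulate_tree(
    spec: SpeciesTreeSpec,
    tips_by_taxon: Mapping[str, Sequence[str]],
    rng: np.random.Generator,
    panel_of: Mapping[str, str] | None = None,
) -> tuple[Node, frozenset[str]]:
    """Structured coalescent over the species tree; returns root and the set
    of tips sampled inside an introgressed (archaic) haplotype."""
    a, b, c, out = spec.taxa
    t1, t2, t3 = spec.split_times

    # archaic-haplotype carrier assignment (at most one event per tip)
    carriers: dict[str, AdmixtureEvent] = {}
    for ev in spec.admixture:
        for tip in tips_by_taxon.get(ev.target, ()):  # deterministic order
            if tip in carriers:
                continue
            if ev.panels is not None:
                panel = (panel_of or {}).get(tip)
                if panel not in ev.panels:
                    continue
            if rng.random() < ev.proportion:
                carriers[tip] = ev

    lineages: list[tuple[Node, str]] = []
    for taxon in spec.taxa:
        for tip in tips_by_taxon.get(taxon, ()):  # keeps declared order
            if tip in carriers:
                pop = f"__arc{spec.admixture.index(carriers[tip])}"
            else:
                pop = taxon
            lineages.append((Node(time=0.0, name=tip), pop))

    def pop_size(pop: str) -> float:
        if pop.startswith("__arc"):
            ev = spec.admixture[int(pop[5:])]
            return spec.pop_size(ev.source)
        return spec.pop_size(pop)

    events: list[tuple[float, int, str, str]] = []  # (time, order, from, to)
    for k, ev in enumerate(spec.admixture):
        events.append((ev.time, k, f"__arc{k}", ev.source))
    events.append((t1, 100, a, "anc_sister"))
    events.append((t1, 101, b, "anc_sister"))
    events.append((t2, 102, "anc_sister", "anc_ingroup"))
    events.append((t2, 103, c, "anc_ingroup"))
    events.append((t3, 104, "anc_ingroup", "root"))
    events.append((t3, 105, out, "root"))
    events.sort(key=lambda e: (e[0], e[1]))

    t = 0.0
    for ev_time, _, src_pop, dst_pop in events:
        t = _coalesce_interval(lineages, t, ev_time, pop_size, rng)
        lineages = [
            (node, dst_pop if pop == src_pop else pop) for node, pop in lineages
        ]
    _coalesce_interval(lineages, t3, np.inf, pop_size, rng)
    assert len(lineages) == 1
    return lineages[0][0], frozenset(carriers)


def _classify_backbone(
    spec: SpeciesTreeSpec, root: Node, ref_tips: Mapping[str, str]
) -> tuple[str, bool]:
    """Topology class and ILS flag from one reference lineage per taxon."""
    a, b, c, _ = spec.taxa
    ra, rb, rc = ref_tips[a], ref_tips[b], ref_tips[c]
    times = {
        "concordant": mrca_time(root, ra, rb),
        "discordant-A": mrca_time(root, ra, rc),
        "discordant-B": mrca_time(root, rb, rc),
    }
    topo = min(times, key=lambda k: (times[k], k))
    ils = times["concordant"] > spec.split_times[1] + 1e-12
    return topo, ils


def simulate_gene_tree(spec: SpeciesTreeSpec, rng_seed) -> GeneTreeSample:
    """Draw one gene tree with a single sampled lineage per taxon."""
    rng = _as_rng(rng_seed)
    tips = {taxon: [taxon] for taxon in spec.taxa}
    root, introgressed = _simulate_tree(spec, tips, rng)
    topo, ils = _classify_backbone(spec, root, {t: t for t in spec.taxa})
    return GeneTreeSample(
        newick=root.newick(),
        topology_class=topo,
        ils_flag=ils,
        introgressed_flag=bool(introgressed),
        root=root,
        introgressed_tips=introgressed,
        tip_names=tuple(spec.taxa),
    )


# ---------------------------------------------------------------------------
# Codon model
# ---------------------------------------------------------------------------

_BASES = "ACGT"
_TABLE = CodonTable.unambiguous_dna_by_id[1]


def _codon_str(code: int) -> str:
    return _BASES[code >> 4] + _BASES[(code >> 2) & 3] + _BASES[code & 3]


_STOPS = frozenset(
    (_BASES.index(s[0]) << 4) | (_BASES.index(s[1]) << 2) | _BASES.index(s[2])
    for s in _TABLE.stop_codons
)
AA_OF = np.array(
    [
        "*" if c in _STOPS else _TABLE.forward_table[_codon_str(c)]
        for c in range(64)
    ],
    dtype="U1",
)
SENSE_CODONS = np.array([c for c in range(64) if c not in _STOPS], dtype=np.int64)

# 9 single-nucleotide neighbours of each codon; stop neighbours masked out.
_NB_CODON = np.zeros((64, 9), dtype=np.int64)
_NB_SYN = np.zeros((64, 9), dtype=bool)
_NB_OK = np.zeros((64, 9), dtype=bool)
for _c in range(64):
    _k = 0
    for _pos, _shift in enumerate((4, 2, 0)):
        _cur = (_c >> _shift) & 3
        for _alt in range(4):
            if _alt == _cur:
                continue
            _c2 = (_c & ~(3 << _shift)) | (_alt << _shift)
            _NB_CODON[_c, _k] = _c2
            if _c2 not in _STOPS and _c not in _STOPS:
                _NB_OK[_c, _k] = True
                _NB_SYN[_c, _k] = AA_OF[_c2] == AA_OF[_c]
            _k += 1
N_SYN = (_NB_OK & _NB_SYN).sum(axis=1).astype(float)
N_NONSYN = (_NB_OK & ~_NB_SYN).sum(axis=1).astype(float)


@dataclass(frozen=True)
class LocusModel:
    """Per-locus substitution model.

    ``mu``: per-nucleotide-site mutation rate per coalescent unit;
    ``omega``: nonsynonymous/synonymous acceptance ratio; ``rate_profile``:
    optional per-codon relative rates (mean 1); ``n_intron``: length of a
    neutral JC69 flank used for the intron+exon data type.
    """

    name: str
    n_codons: int
    mu: float = 2e-3
    omega: float = 0.3
    rate_profile: tuple[float, ...] | None = None
    n_intron: int = 0

    def __post_init__(self) -> None:
        if self.n_codons <= 0:
            raise SimulationError("n_codons must be positive")
        if self.mu < 0 or self.omega < 0 or self.n_intron < 0:
            raise SimulationError("rates and lengths must be non-negative")
        if self.rate_profile is not None:
            prof = np.asarray(self.rate_profile, dtype=float)
            if prof.shape != (self.n_codons,):
                raise SimulationError("rate_profile length must equal n_codons")
            if (prof < 0).any():
                raise SimulationError("rate_profile must be non-negative")

    def profile(self) -> np.ndarray:
        if self.rate_profile is None:
            return np.ones(self.n_codons)
        return np.asarray(self.rate_profile, dtype=float)


def _codon_leave_rate(codons: np.ndarray, mu: float, omega: float, prof: np.ndarray) -> np.ndarray:
    return (mu / 3.0) * prof * (N_SYN[codons] + omega * N_NONSYN[codons])


def _evolve_codons(
    codons: np.ndarray,
    length: float,
    mu: float,
    omega: float,
    prof: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """CTMC endpoint of the codon process along one branch."""
    out = codons.copy()
    if length <= 0 or mu <= 0:
        return out
    rate = _codon_leave_rate(out, mu, omega, prof)
    with np.errstate(divide="ignore"):
        first = np.where(rate > 0, rng.exponential(size=out.size) / np.maximum(rate, 1e-300), np.inf)
    for i in np.nonzero(first < length)[0]:
        t = first[i]
        c = int(out[i])
        while t < length:
            w = np.where(_NB_OK[c], np.where(_NB_SYN[c], 1.0, omega), 0.0)
            total = w.sum()
            if total <= 0:
                break
            c = int(rng.choice(_NB_CODON[c], p=w / total))
            leave = (mu / 3.0) * prof[i] * (N_SYN[c] + omega * N_NONSYN[c])
            if leave <= 0:
                break
            t += rng.exponential(1.0 / leave)
        out[i] = c
    return out


def _evolve_jc(
    sites: np.ndarray, length: float, mu: float, rng: np.random.Generator
) -> np.ndarray:
    """Exact JC69 endpoint sampling for neutral nucleotide sites."""
    if length <= 0 or mu <= 0:
        return sites.copy()
    p_change = 0.75 * (1.0 - np.exp(-4.0 / 3.0 * mu * length))
    change = rng.random(sites.size) < p_change
    out = sites.copy()
    if change.any():
        shift = rng.integers(1, 4, size=int(change.sum()))
        out[change] = (out[change] + shift) % 4
    return out


def _codons_to_dna(codons: np.ndarray) -> str:
    return "".join(_codon_str(int(c)) for c in codons)


def _sites_to_dna(sites: np.ndarray) -> str:
    return "".join(_BASES[int(s)] for s in sites)


def _dna_to_codons(dna: str) -> np.ndarray:
    idx = np.frombuffer(dna.encode(), dtype=np.uint8)
    lut = np.zeros(128, dtype=np.int64)
    for k, base in enumerate(_BASES):
        lut[ord(base)] = k
    b = lut[idx].reshape(-1, 3)
    return (b[:, 0] << 4) | (b[:, 1] << 2) | b[:, 2]


@dataclass
class LocusSequences:
    """Tip sequences of one simulated locus (pre-aligned by construction)."""

    protein: "OrderedDict[str, str]"
    exon: "OrderedDict[str, str]"
    intron: "OrderedDict[str, str] | None"

    def intron_exon(self) -> "OrderedDict[str, str] | None":
        if self.intron is None:
            return None
        return OrderedDict(
            (tip, self.intron[tip] + self.exon[tip]) for tip in self.exon
        )


def evolve_sequences(tree: GeneTreeSample, locus: LocusModel, rng_seed) -> LocusSequences:
    """Evolve DNA down *tree* and translate the tips.

    Protein tips are exact standard-code translations of the exon DNA tips
    for every seed; the root coding sequence is drawn stop-codon-free.
    """
    rng = _as_rng(rng_seed)
    prof = locus.profile()
    root_codons = rng.choice(SENSE_CODONS, size=locus.n_codons)
    root_intron = rng.integers(0, 4, size=locus.n_intron) if locus.n_intron else None

    exon: "OrderedDict[str, str]" = OrderedDict()
    intron: "OrderedDict[str, str]" = OrderedDict()

    def walk(node: Node, codons: np.ndarray, sites: np.ndarray | None, parent_time: float) -> None:
        length = parent_time - node.time
        codons = _evolve_codons(codons, length, locus.mu, locus.omega, prof, rng)
        if sites is not None:
            sites = _evolve_jc(sites, length, locus.mu, rng)
        if not node.children:
            exon[node.name] = _codons_to_dna(codons)
            if sites is not None:
                intron[node.name] = _sites_to_dna(sites)
            return
        for ch in node.children:
            walk(ch, codons, sites, node.time)

    walk(tree.root, root_codons, root_intron, tree.root.time)
    protein = OrderedDict(
        (tip, "".join(AA_OF[_dna_to_codons(s)])) for tip, s in exon.items()
    )
    return LocusSequences(
        protein=protein, exon=exon, intron=intron if locus.n_intron else None
    )


# ---------------------------------------------------------------------------
# Presets — hominid-like and hominin-like study conditions
# ---------------------------------------------------------------------------

#: canonical-isoform lengths (amino acids) of the 12 deep-time proteins
_DEEP_TIME_LENGTHS = {
    "AHSG": 367,
    "ALB": 609,
    "AMBN": 447,
    "AMELX": 205,
    "AMELY": 206,
    "AMTN": 209,
    "COL17A1": 1497,
    "COL1A1": 1464,
    "COL1A2": 1366,
    "ENAM": 1142,
    "MMP20": 483,
    "ODAM": 279,
}

#: stylized purifying-selection strengths mirroring the observed conservation
#: ranking (collagens and AMELX highly conserved, ODAM/AMELY variable)
_DEEP_TIME_OMEGA = {
    "AHSG": 0.30,
    "ALB": 0.25,
    "AMBN": 0.35,
    "AMELX": 0.05,
    "AMELY": 0.60,
    "AMTN": 0.40,
    "COL17A1": 0.15,
    "COL1A1": 0.03,
    "COL1A2": 0.03,
    "ENAM": 0.30,
    "MMP20": 0.20,
    "ODAM": 0.55,
}


def deep_time_locus_models(mu: float, n_intron: int = 0) -> list[LocusModel]:
    """The 12 enamel/collagen loci at their canonical lengths."""
    return [
        LocusModel(
            name=name,
            n_codons=_DEEP_TIME_LENGTHS[name],
            mu=mu,
            omega=_DEEP_TIME_OMEGA[name],
            n_intron=n_intron,
        )
        for name in sorted(_DEEP_TIME_LENGTHS)
    ]


def hominid_like(
    admixture: tuple[AdmixtureEvent, ...] = (),
) -> tuple[SpeciesTreeSpec, list[LocusModel]]:
    """Great-ape-like preset: Homo/Pan sister pair, Gorilla, Pongo outgroup.

    Split times (coalescent units of a ~50k reference 2N): internal branch
    T = 1.2, giving ~20% true gene-tree discordance, in the range reported
    for the African great apes.  ``mu`` is chosen so a locus carries on the
    order of ten ingroup amino-acid variants, the scale of the observed
    hominid panels.
    """
    spec = SpeciesTreeSpec(
        taxa=("Homo", "Pan", "Gorilla", "Pongo"),
        split_times=(2.4, 3.6, 6.4),
        pop_sizes={"Homo": 0.15, "Pan": 0.15, "Gorilla": 0.15, "Pongo": 0.15},
        admixture=admixture,
    )
    return spec, deep_time_locus_models(mu=2.6e-3)


def hominin_like(
    admixture: tuple[AdmixtureEvent, ...] = (),
) -> tuple[SpeciesTreeSpec, list[LocusModel]]:
    """Hominin-like preset: Neanderthal/Denisovan sister pair, H. sapiens,
    Pan outgroup.

    The internal branch is very short (T = 0.05 coalescent units), so most
    gene trees are discordant by ILS, and the ingroup carries roughly ten
    times fewer amino-acid variants than the hominid preset — the regime in
    which protein quartets are frequently uninformative.
    """
    spec = SpeciesTreeSpec(
        taxa=("Neanderthal", "Denisovan", "Sapiens", "Pan"),
        split_times=(0.45, 0.50, 6.0),
        pop_sizes={
            "Neanderthal": 0.05,
            "Denisovan": 0.05,
            "Sapiens": 0.1,
            "Pan": 0.15,
            "anc_sister": 1.0,
            "anc_ingroup": 0.5,
        },
        admixture=admixture,
    )
    return spec, deep_time_locus_models(mu=1.2e-3)


def hominin_admixture_event(
    proportion: float = 0.35, panels: tuple[str, ...] | None = ("ADMIXED",)
) -> AdmixtureEvent:
    """Recent Neanderthal-into-Sapiens pulse used by the introgression runs."""
    return AdmixtureEvent(
        source="Neanderthal",
        target="Sapiens",
        time=0.02,
        proportion=proportion,
        panels=panels,
    )


def conserved_locus_models(
    n_loci: int = 12, n_codons: int = 300, mu: float = 2.0e-3, omega: float = 0.05,
    n_intron: int = 0,
) -> list[LocusModel]:
    """Strongly conserved short loci (low omega) for the information-loss
    comparisons between DNA and protein classification."""
    return [
        LocusModel(name=f"CONS{i:02d}", n_codons=n_codons, mu=mu, omega=omega,
                   n_intron=n_intron)
        for i in range(1, n_loci + 1)
    ]
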