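"""The ProteinPanel dataset object and its coalescent generator.

A panel is the in-memory analogue of a per-protein FASTA directory: for each
locus, one pre-aligned sequence per (taxon, individual), in protein, exon-DNA
and optionally intron+exon-DNA form, together with the ground-truth gene tree
when the panel was simulated.

``build_panel`` draws one gene tree per locus (no intra-locus recombination)
with every sampled individual's lineage included, so within-taxon
polymorphism arises from genuine terminal-branch coalescence and introgressed
individuals are the tips sampled inside archaic haplotypes.
"""

from __future__ import annotations

from collections import OrderedDict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .alignio import Alignment, read_fasta, write_fasta
from .errors import SimulationError
from .simulate import (
    GeneTreeSample,
    LocusModel,
    SpeciesTreeSpec,
    _as_rng,
    _classify_backbone,
    _simulate_tree,
    evolve_sequences,
)

DATA_TYPES = ("protein", "exon", "intron+exon")


@dataclass
class LocusTruth:
    topology_class: str
    ils_flag: bool
    introgressed_flag: bool
    carriers: frozenset[str]
    newick: str


@dataclass
class LocusData:
    name: str
    protein: "OrderedDict[str, str]"  # tip id "taxon|individual" -> sequence
    exon: "OrderedDict[str, str] | None" = None
    intron_exon: "OrderedDict[str, str] | None" = None
    truth: LocusTruth | None = None

    def sequences(self, data_type: str) -> "OrderedDict[str, str]":
        if data_type == "protein":
            return self.protein
        if data_type == "exon":
            if self.exon is None:
                raise SimulationError(f"locus {self.name!r} has no exon DNA")
            return self.exon
        if data_type == "intron+exon":
            if self.intron_exon is None:
                raise SimulationError(f"locus {self.name!r} has no intron+exon DNA")
            return self.intron_exon
        raise SimulationError(f"unknown data type {data_type!r}")


@dataclass
class ProteinPanel:
    """Per-protein, per-taxon collections of individual sequences."""

    taxa: tuple[str, str, str, str]
    outgroup: str
    individuals: "OrderedDict[str, list[str]]"  # taxon -> individual ids
    loci: "OrderedDict[str, LocusData]"
    panels: dict[str, str] = field(default_factory=dict)  # tip id -> panel label
    spec: SpeciesTreeSpec | None = None

    def __post_init__(self) -> None:
        if self.outgroup not in self.taxa:
            raise SimulationError("outgroup must be one of the four taxa")
        for taxon in self.taxa:
            if not self.individuals.get(taxon):
                raise SimulationError(f"taxon {taxon!r} has no individuals")

    # -- accessors ---------------------------------------------------------
    @property
    def locus_names(self) -> list[str]:
        return list(self.loci)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def ingroup(self) -> tuple[str, ...]:
        return tuple(t for t in self.taxa if t != self.outgroup)

    def tip_id(self, taxon: str, individual: str) -> str:
        return f"{taxon}|{individual}"

    def sample_individuals(self, rng: np.random.Generator) -> dict[str, str]:
        """One random individual per taxon."""
        return {
            taxon: inds[int(rng.integers(len(inds)))]
            for taxon, inds in self.individuals.items()
        }

    def quartet_alignment(
        self,
        locus: str,
        chosen: Mapping[str, str],
        data_type: str = "protein",
    ) -> Alignment:
        """4-row alignment of one individual per taxon at one locus."""
        data = self.loci[locus].sequences(data_type)
        ids, seqs = [], []
        for taxon in self.taxa:
            tip = self.tip_id(taxon, chosen[taxon])
            ids.append(f"{tip}|{locus}")
            seqs.append(data[tip])
        alphabet = "protein" if data_type == "protein" else "dna"
        return Alignment(ids=ids, seqs=seqs, alphabet=alphabet, name=locus)

    def full_alignment(self, locus: str, data_type: str = "protein") -> Alignment:
        data = self.loci[locus].sequences(data_type)
        alphabet = "protein" if data_type == "protein" else "dna"
        return Alignment(
            ids=[f"{tip}|{locus}" for tip in data],
            seqs=list(data.values()),
            alphabet=alphabet,
            name=locus,
        )

    def filter_individuals(self, whitelist: Mapping[str, Iterable[str]]) -> "ProteinPanel":
        """Restrict listed taxa to whitelisted individuals; others untouched."""
        new_inds: "OrderedDict[str, list[str]]" = OrderedDict()
        for taxon, inds in self.individuals.items():
            if taxon in whitelist:
                keep = [i for i in inds if i in set(whitelist[taxon])]
                if not keep:
                    raise SimulationError(
                        f"whitelist removes every individual of taxon {taxon!r}"
                    )
                new_inds[taxon] = keep
            else:
                new_inds[taxon] = list(inds)
        keep_tips = {
            self.tip_id(taxon, ind)
            for taxon, inds in new_inds.items()
            for ind in inds
        }
        new_loci: "OrderedDict[str, LocusData]" = OrderedDict()
        for name, ld in self.loci.items():
            def _sub(d):
                if d is None:
                    return None
                return OrderedDict((k, v) for k, v in d.items() if k in keep_tips)

            new_loci[name] = LocusData(
                name=name,
                protein=_sub(ld.protein),
                exon=_sub(ld.exon),
                intron_exon=_sub(ld.intron_exon),
                truth=ld.truth,
            )
        return ProteinPanel(
            taxa=self.taxa,
            outgroup=self.outgroup,
            individuals=new_inds,
            loci=new_loci,
            panels={k: v for k, v in self.panels.items() if k in keep_tips},
            spec=self.spec,
        )

    def unadmixed_individuals(self, taxon: str) -> list[str]:
        """Individuals of *taxon* carrying no introgressed haplotype at any locus."""
        carriers: set[str] = set()
        for ld in self.loci.values():
            if ld.truth is not None:
                carriers |= set(ld.truth.carriers)
        return [
            ind
            for ind in self.individuals[taxon]
            if self.tip_id(taxon, ind) not in carriers
        ]

    def truth_table(self) -> pd.DataFrame:
        rows = []
        for name, ld in self.loci.items():
            t = ld.truth
            rows.append(
                {
                    "locus": name,
                    "topology_class": t.topology_class if t else "",
                    "ils_flag": t.ils_flag if t else "",
                    "introgressed_flag": t.introgressed_flag if t else "",
                    "carriers": ",".join(sorted(t.carriers)) if t else "",
                    "newick": t.newick if t else "",
                }
            )
        return pd.DataFrame(rows)

    # -- persistence -------------------------------------------------------
    def write_dir(self, path) -> None:
        """One FASTA per locus and data type, truth sidecar TSV, config YAML."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        for name, ld in self.loci.items():
            for data_type, tag in (("protein", "protein"), ("exon", "exon"),
                                   ("intron+exon", "intron_exon")):
                try:
                    data = ld.sequences(data_type)
                except SimulationError:
                    continue
                if data is None:
                    continue
                records = [(f"{tip}|{name}", seq) for tip, seq in data.items()]
                write_fasta(records, path / f"{name}.{tag}.fasta")
        self.truth_table().to_csv(path / "truth.tsv", sep="\t", index=False)
        config = {
            "taxa": list(self.taxa),
            "outgroup": self.outgroup,
            "individuals": {t: list(v) for t, v in self.individuals.items()},
            "panels": dict(self.panels),
            "loci": self.locus_names,
        }
        (path / "panel.yaml").write_text(yaml.safe_dump(config, sort_keys=True))

    @classmethod
    def read_dir(cls, path) -> "ProteinPanel":
        path = Path(path)
        config = yaml.safe_load((path / "panel.yaml").read_text())
        taxa = tuple(config["taxa"])
        truth_df = None
        truth_path = path / "truth.tsv"
        if truth_path.exists():
            truth_df = pd.read_csv(truth_path, sep="\t").set_index("locus")
        loci: "OrderedDict[str, LocusData]" = OrderedDict()
        for name in config["loci"]:
            parts = {}
            for data_type, tag in (("protein", "protein"), ("exon", "exon"),
                                   ("intron+exon", "intron_exon")):
                fasta = path / f"{name}.{tag}.fasta"
                if fasta.exists():
                    records = read_fasta(fasta)
                    parts[data_type] = OrderedDict(
                        ("|".join((r.description or r.id).split("|")[:2]), str(r.seq))
                        for r in records
                    )
            truth = None
            if truth_df is not None and name in truth_df.index:
                row = truth_df.loc[name]
                carriers = row.get("carriers", "")
                carriers = (
                    frozenset(str(carriers).split(","))
                    if isinstance(carriers, str) and carriers
                    else frozenset()
                )
                truth = LocusTruth(
                    topology_class=str(row["topology_class"]),
                    ils_flag=bool(row["ils_flag"]),
                    introgressed_flag=bool(row["introgressed_flag"]),
                    carriers=carriers,
                    newick=str(row["newick"]),
                )
            loci[name] = LocusData(
                name=name,
                protein=parts.get("protein"),
                exon=parts.get("exon"),
                intron_exon=parts.get("intron+exon"),
                truth=truth,
            )
        return cls(
            taxa=taxa,
            outgroup=config["outgroup"],
            individuals=OrderedDict(
                (t, list(config["individuals"][t])) for t in taxa
            ),
            loci=loci,
            panels=dict(config.get("panels", {})),
        )


def build_panel(
    spec: SpeciesTreeSpec,
    loci: Sequence[LocusModel],
    individuals_per_taxon: int,
    rng_seed,
    panel_labels: Mapping[str, Sequence[str]] | None = None,
) -> ProteinPanel:
    """Simulate a complete multi-individual panel.

    One gene tree per locus; all individuals of all taxa are leaves of that
    tree.  ``panel_labels`` optionally assigns population-panel labels per
    taxon, cycled over individuals (used for admixture eligibility and
    introgression bookkeeping); default label is ``"P1"``.

    A master seed drives per-locus substreams, so identical (spec, loci,
    seed) yields byte-identical panels.
    """
    if not loci:
        raise SimulationError("need at least one locus")
    names = [m.name for m in loci]
    if len(set(names)) != len(names):
        raise SimulationError("duplicate locus names")
    if individuals_per_taxon < 1:
        raise SimulationError("need at least one individual per taxon")
    if isinstance(rng_seed, (int, np.integer)):
        master = np.random.SeedSequence(int(rng_seed))
    elif isinstance(rng_seed, np.random.SeedSequence):
        master = rng_seed
    else:
        raise SimulationError("build_panel needs an integer seed or SeedSequence")

    individuals = OrderedDict(
        (taxon, [f"i{k}" for k in range(1, individuals_per_taxon + 1)])
        for taxon in spec.taxa
    )
    panels: dict[str, str] = {}
    for taxon in spec.taxa:
        labels = list((panel_labels or {}).get(taxon, ["P1"]))
        for k, ind in enumerate(individuals[taxon]):
            panels[f"{taxon}|{ind}"] = labels[k % len(labels)]

    tips_by_taxon = {
        taxon: [f"{taxon}|{ind}" for ind in individuals[taxon]]
        for taxon in spec.taxa
    }
    ref_tips = {taxon: tips_by_taxon[taxon][0] for taxon in spec.taxa}

    loci_data: "OrderedDict[str, LocusData]" = OrderedDict()
    for model, child_seed in zip(loci, master.spawn(len(loci))):
        tree_seed, seq_seed = child_seed.spawn(2)
        rng = np.random.default_rng(tree_seed)
        root, carriers = _simulate_tree(spec, tips_by_taxon, rng, panel_of=panels)
        topo, ils = _classify_backbone(spec, root, ref_tips)
        sample = GeneTreeSample(
            newick=root.newick(),
            topology_class=topo,
            ils_flag=ils,
            introgressed_flag=bool(carriers),
            root=root,
            introgressed_tips=carriers,
            tip_names=tuple(
                tip for taxon in spec.taxa for tip in tips_by_taxon[taxon]
            ),
        )
        seqs = evolve_sequences(sample, model, np.random.default_rng(seq_seed))
        order = sample.tip_names
        intron_exon = seqs.intron_exon() if model.n_intron else None
        loci_data[model.name] = LocusData(
            name=model.name,
            protein=OrderedDict((t, seqs.protein[t]) for t in order),
            exon=OrderedDict((t, seqs.exon[t]) for t in order),
            intron_exon=(
                OrderedDict((t, intron_exon[t]) for t in order)
                if intron_exon is not None
                else None
            ),
            truth=LocusTruth(
                topology_class=topo,
                ils_flag=ils,
                introgressed_flag=bool(carriers),
                carriers=carriers,
                newick=sample.newick,
            ),
        )
    return ProteinPanel(
        taxa=spec.taxa,
        outgroup=spec.outgroup,
        individuals=individuals,
        loci=loci_data,
        panels=panels,
        spec=spec,
    )
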