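"""Coalescent engine and codon evolver: closed-form discordance, msprime
cross-check, translation consistency, omega monotonicity, determinism."""

import numpy as np
import pytest

import paleoquartet as pq
from paleoquartet.errors import SimulationError
from paleoquartet.simulate import AA_OF, mrca_time


def make_spec(T, t1=2.0, t3=10.0, **kw):
    return pq.SpeciesTreeSpec(
        taxa=("A", "B", "C", "O"), split_times=(t1, t1 + T, t3), **kw
    )


def discordant_fraction(spec, n, seed):
    rng = np.random.default_rng(seed)
    return (
        sum(
            pq.simulate_gene_tree(spec, rng).topology_class != "concordant"
            for _ in range(n)
        )
        / n
    )


class TestGeneTreeDiscordance:
    def test_huge_internal_branch_never_discordant(self):
        spec = make_spec(T=50.0, t3=60.0)
        assert discordant_fraction(spec, 2000, 0) == 0.0

    def test_zero_internal_branch_symmetric_thirds(self):
        spec = pq.SpeciesTreeSpec(taxa=("A", "B", "C", "O"), split_times=(2.0, 2.0, 10.0))
        rng = np.random.default_rng(1)
        n = 6000
        counts = {"concordant": 0, "discordant-A": 0, "discordant-B": 0}
        for _ in range(n):
            counts[pq.simulate_gene_tree(spec, rng).topology_class] += 1
        for c in counts.values():
            assert abs(c / n - 1 / 3) < 3 * np.sqrt((1 / 3) * (2 / 3) / n)

    def test_analytic_discordance_T1(self):
        spec = make_spec(T=1.0)
        p = pq.discordance_probability(spec)
        assert p == pytest.approx((2 / 3) * np.exp(-1), abs=1e-12)
        n = 6000
        obs = discordant_fraction(spec, n, 2)
        assert abs(obs - p) < 3 * np.sqrt(p * (1 - p) / n)

    def test_pop_size_rescales_internal_branch(self):
        spec = make_spec(T=1.0, pop_sizes={"anc_sister": 2.0})
        assert spec.internal_branch_T == pytest.approx(0.5)

    def test_msprime_cross_check(self):
        """Independent multispecies-coalescent oracle for the discordance rate."""
        msprime = pytest.importorskip("msprime")
        T = 1.0
        spec = make_spec(T=T)
        n = 2000
        demography = msprime.Demography()
        for name in ("A", "B", "C", "O", "AB", "ABC", "ROOT"):
            # ploidy-1 pairwise coalescence rate is 1/size, so size 1 puts
            # msprime time directly in our coalescent units
            demography.add_population(name=name, initial_size=1.0)
        demography.add_population_split(time=2.0, derived=["A", "B"], ancestral="AB")
        demography.add_population_split(time=3.0, derived=["AB", "C"], ancestral="ABC")
        demography.add_population_split(time=10.0, derived=["ABC", "O"], ancestral="ROOT")
        disc = 0
        for rep, ts in enumerate(
            msprime.sim_ancestry(
                samples={"A": 1, "B": 1, "C": 1, "O": 1},
                demography=demography,
                ploidy=1,
                num_replicates=n,
                random_seed=7,
            )
        ):
            tree = ts.first()
            t_ab = tree.time(tree.mrca(0, 1))
            t_ac = tree.time(tree.mrca(0, 2))
            t_bc = tree.time(tree.mrca(1, 2))
            if not (t_ab < t_ac and t_ab < t_bc):
                disc += 1
        mine = discordant_fraction(spec, n, 3)
        se = np.sqrt(2 * 0.245 * 0.755 / n)  # paired binomial scale
        assert abs(disc / n - mine) < 3 * se

    def test_ils_flag_consistency(self):
        spec = make_spec(T=1.0)
        rng = np.random.default_rng(4)
        for _ in range(300):
            g = pq.simulate_gene_tree(spec, rng)
            if not g.ils_flag:
                assert g.topology_class == "concordant"
            t_ab = mrca_time(g.root, "A", "B")
            assert g.ils_flag == (t_ab > spec.split_times[1] + 1e-12)


class TestSpecValidation:
    def test_bad_split_order_rejected(self):
        with pytest.raises(SimulationError):
            pq.SpeciesTreeSpec(taxa=("A", "B", "C", "O"), split_times=(3.0, 2.0, 10.0))

    def test_bad_admixture_rejected(self):
        with pytest.raises(SimulationError):
            make_spec(
                T=1.0,
                admixture=(pq.AdmixtureEvent("C", "A", time=5.0, proportion=0.5),),
            )
        with pytest.raises(SimulationError):
            make_spec(
                T=1.0,
                admixture=(pq.AdmixtureEvent("C", "A", time=0.5, proportion=1.5),),
            )

    def test_bad_seed_rejected(self):
        with pytest.raises(SimulationError):
            pq.simulate_gene_tree(make_spec(T=1.0), -3)
        with pytest.raises(SimulationError):
            pq.simulate_gene_tree(make_spec(T=1.0), "seed")


class TestAdmixture:
    def test_full_pulse_moves_target_to_source(self):
        # m=1 from sister C into A at a recent time: A then coalesces with C
        # far more often than with B
        spec = make_spec(
            T=1.0,
            admixture=(pq.AdmixtureEvent("C", "A", time=0.5, proportion=1.0),),
        )
        rng = np.random.default_rng(5)
        n = 1500
        ac = 0
        for _ in range(n):
            g = pq.simulate_gene_tree(spec, rng)
            assert g.introgressed_flag
            ac += g.topology_class == "discordant-A"
        assert ac / n > 0.8

    def test_zero_pulse_is_no_op_in_distribution(self):
        spec0 = make_spec(T=1.0)
        spec_m0 = make_spec(
            T=1.0,
            admixture=(pq.AdmixtureEvent("C", "A", time=0.5, proportion=0.0),),
        )
        f0 = discordant_fraction(spec0, 3000, 11)
        f1 = discordant_fraction(spec_m0, 3000, 11)
        assert abs(f0 - f1) < 3 * np.sqrt(2 * 0.245 * 0.755 / 3000)


class TestEvolveSequences:
    def setup_method(self):
        self.spec = make_spec(T=1.0)
        self.tree = pq.simulate_gene_tree(self.spec, 9)

    def test_mu_zero_all_tips_identical(self):
        locus = pq.LocusModel(name="L", n_codons=50, mu=0.0, omega=1.0)
        seqs = pq.evolve_sequences(self.tree, locus, 1)
        assert len(set(seqs.exon.values())) == 1
        assert len(set(seqs.protein.values())) == 1

    def test_omega_zero_proteins_identical_dna_may_differ(self):
        locus = pq.LocusModel(name="L", n_codons=400, mu=5e-3, omega=0.0)
        seqs = pq.evolve_sequences(self.tree, locus, 2)
        assert len(set(seqs.protein.values())) == 1
        assert len(set(seqs.exon.values())) > 1  # synonymous variation

    def test_translation_consistency_every_tip(self):
        locus = pq.LocusModel(name="L", n_codons=120, mu=8e-3, omega=0.8)
        for seed in (1, 2, 3):
            seqs = pq.evolve_sequences(self.tree, locus, seed)
            for tip, dna in seqs.exon.items():
                assert pq.translate(dna, allow_internal_stop=True) == seqs.protein[tip]

    def test_no_stop_codons_ever(self):
        locus = pq.LocusModel(name="L", n_codons=200, mu=2e-2, omega=1.0)
        seqs = pq.evolve_sequences(self.tree, locus, 5)
        assert not any("*" in p for p in seqs.protein.values())

    def test_intron_divergence_matches_jc69(self):
        """Mean pairwise identity of the neutral flank vs the JC69 closed
        form for the tip-to-tip path length."""
        mu = 4e-3
        locus = pq.LocusModel(name="L", n_codons=1, mu=mu, omega=1.0, n_intron=40000)
        tree = pq.simulate_gene_tree(self.spec, 21)
        seqs = pq.evolve_sequences(tree, locus, 6)
        a, b = seqs.intron["A"], seqs.intron["B"]
        path = 2 * mrca_time(tree.root, "A", "B")
        expected_diff = 0.75 * (1 - np.exp(-4 / 3 * mu * path))
        observed = np.mean([x != y for x, y in zip(a, b)])
        se = np.sqrt(expected_diff * (1 - expected_diff) / locus.n_intron)
        assert abs(observed - expected_diff) < 4 * se

    def test_omega_monotonicity_in_protein_variants(self):
        """Mean realized protein variant count is non-decreasing in omega."""
        counts = []
        for omega in (0.01, 0.3, 1.0):
            total = 0
            for seed in range(15):
                tree = pq.simulate_gene_tree(self.spec, 100 + seed)
                locus = pq.LocusModel(name="L", n_codons=300, mu=3e-3, omega=omega)
                seqs = pq.evolve_sequences(tree, locus, 200 + seed)
                prots = list(seqs.protein.values())
                total += sum(
                    len({p[i] for p in prots}) > 1 for i in range(len(prots[0]))
                )
            counts.append(total)
        assert counts[0] <= counts[1] <= counts[2]
        assert counts[0] < counts[2]

    def test_zero_length_rejected(self):
        with pytest.raises(SimulationError):
            pq.LocusModel(name="L", n_codons=0)


class TestBuildPanel:
    def test_shapes_and_headers(self, hominid_panel):
        assert hominid_panel.n_loci == 12
        for name in hominid_panel.locus_names:
            aln = hominid_panel.full_alignment(name)
            assert aln.n == 8  # 4 taxa x 2 individuals
            parsed = pq.parse_header(aln.ids[0])
            assert parsed["locus"] == name

    def test_same_seed_byte_identical_panels(self, tmp_path):
        spec, loci = pq.hominid_like()
        p1 = pq.build_panel(spec, loci[:3], 2, 42)
        p2 = pq.build_panel(spec, loci[:3], 2, 42)
        d1, d2 = tmp_path / "p1", tmp_path / "p2"
        p1.write_dir(d1)
        p2.write_dir(d2)
        for f1 in sorted(d1.iterdir()):
            assert f1.read_bytes() == (d2 / f1.name).read_bytes()

    def test_duplicate_locus_names_rejected(self):
        spec, loci = pq.hominid_like()
        with pytest.raises(SimulationError):
            pq.build_panel(spec, [loci[0], loci[0]], 2, 1)

    def test_round_trip_through_directory(self, tmp_path, hominin_panel):
        hominin_panel.write_dir(tmp_path / "panel")
        back = pq.ProteinPanel.read_dir(tmp_path / "panel")
        assert back.taxa == hominin_panel.taxa
        assert back.locus_names == hominin_panel.locus_names
        for name in back.locus_names:
            assert back.loci[name].protein == hominin_panel.loci[name].protein
            assert (
                back.loci[name].truth.topology_class
                == hominin_panel.loci[name].truth.topology_class
            )

    def test_omega_profile_orders_variant_counts(self):
        """Loci with omega 0.01 vs 1.0 in one panel: realized ingroup protein
        variant counts ordered accordingly."""
        spec, _ = pq.hominid_like()
        loci = [
            pq.LocusModel(name="LOW", n_codons=400, mu=3e-3, omega=0.01),
            pq.LocusModel(name="HIGH", n_codons=400, mu=3e-3, omega=1.0),
        ]
        low = high = 0
        for seed in range(8):
            panel = pq.build_panel(spec, loci, 1, 500 + seed)
            for name, acc in (("LOW", "low"), ("HIGH", "high")):
                aln = panel.quartet_alignment(name, {t: "i1" for t in spec.taxa})
                v = pq.count_ingroup_variants(
                    pq.concatenate([aln]), outgroup=spec.outgroup
                )
                if acc == "low":
                    low += v
                else:
                    high += v
        assert low < high

    def test_truth_table_columns(self, hominid_panel):
        df = hominid_panel.truth_table()
        assert set(df.columns) >= {
            "locus", "topology_class", "ils_flag", "introgressed_flag", "newick",
        }
        assert len(df) == 12

    def test_newick_parses_with_dendropy(self, hominid_panel):
        dendropy = pytest.importorskip("dendropy")
        truth = hominid_panel.loci["AHSG"].truth
        tree = dendropy.Tree.get(data=truth.newick, schema="newick")
        labels = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
        assert len(labels) == 8
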