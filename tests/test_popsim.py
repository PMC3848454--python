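"""Population-simulator unit tests: maps, founders, meiosis, populations,
phenotypes, and the adversarial linkage-phase flip."""

import numpy as np
import pytest

import beetgs as b
from beetgs.core import GeneticMap
from beetgs.popsim import SimulatedStudy


# ---------------------------------------------------------------------------
# genetic maps


@pytest.mark.parametrize(
    "n_chrom,n_markers,length,max_gap",
    [(9, 677, 698.0, 23.0), (3, 30, 300.0, 15.0), (1, 2, 10.0, 23.0)],
)
def test_simulated_map_geometry(n_chrom, n_markers, length, max_gap):
    gmap = b.simulate_map(n_chrom, n_markers, length, max_gap, seed=1)
    assert gmap.n_markers == n_markers
    assert gmap.total_length == pytest.approx(length, abs=1e-9)
    gaps = gmap.adjacent_gaps()
    assert len(gaps) == n_markers - n_chrom
    assert gaps.max() <= max_gap + 1e-9
    # chromosome endpoints pin the mean gap exactly
    assert gaps.mean() == pytest.approx(length / (n_markers - n_chrom), rel=1e-9)


def test_map_positions_strictly_increasing_within_chromosome():
    gmap = b.simulate_map(5, 120, 400.0, 20.0, seed=7)
    for c in gmap.chromosome_ids:
        assert np.all(np.diff(gmap.positions[gmap.chromosomes == c]) > 0)


def test_infeasible_map_raises():
    # 10 markers on one 300 cM chromosome cannot respect a 5 cM gap cap
    with pytest.raises(ValueError, match="infeasible"):
        b.simulate_map(1, 10, 300.0, 5.0, seed=1)
    with pytest.raises(ValueError):
        b.simulate_map(3, 2, 100.0, 30.0, seed=1)


# ---------------------------------------------------------------------------
# founders


@pytest.fixture(scope="module")
def map100():
    return b.simulate_map(3, 100, 120.0, 10.0, seed=3)


def test_founder_maf_within_requested_range(map100):
    founders = b.simulate_founders(20, map100, (0.1, 0.5), seed=5)
    assert founders.shape == (20, 2, 100)
    maf = founders.reshape(40, 100).mean(axis=0)
    maf = np.minimum(maf, 1 - maf)
    assert np.all(maf >= 0.1 - 1e-12)
    assert np.all(maf <= 0.5 + 1e-12)


def test_forced_half_frequency_is_exact(map100):
    founders = b.simulate_founders(10, map100, (0.5, 0.5), seed=5)
    freq = founders.reshape(20, 100).mean(axis=0)
    assert np.all(freq == 0.5)


def test_minimal_founder_pool_and_errors(map100):
    assert b.simulate_founders(2, map100, (0.5, 0.5), seed=1).shape == (2, 2, 100)
    with pytest.raises(ValueError):
        b.simulate_founders(1, map100, (0.5, 0.5), seed=1)
    with pytest.raises(ValueError):
        b.simulate_founders(5, map100, (0.0, 0.6), seed=1)


# ---------------------------------------------------------------------------
# meiosis


def test_homozygous_parent_transmits_identically(map100):
    hap = np.zeros((2, 100), dtype=np.int8)
    hap[:, ::3] = 1  # identical haplotypes
    gamete = b.meiosis(hap, map100, seed=11)
    assert np.array_equal(gamete, hap[0])


def test_crossover_rate_matches_haldane_expectation():
    # 100 cM chromosome, 1 cM marker spacing; the observable switch count
    # per adjacent interval has expectation (1 - exp(-2d))/2 under Haldane
    pos = np.arange(101.0)
    gmap = GeneticMap([f"m{i}" for i in range(101)], np.ones(101, int), pos)
    hap = np.stack([np.zeros(101, np.int8), np.ones(101, np.int8)])
    rng = np.random.default_rng(13)
    n = 10_000
    switches = np.empty(n)
    for k in range(n):
        gamete = b.meiosis(hap, gmap, rng)
        switches[k] = np.sum(np.abs(np.diff(gamete)))
    d = 0.01  # Morgans per interval
    expected = 100 * (1 - np.exp(-2 * d)) / 2
    se = switches.std(ddof=1) / np.sqrt(n)
    assert abs(switches.mean() - expected) < 3 * se
    # detectable switches slightly undercount the Poisson(1) crossover rate
    assert expected == pytest.approx(1.0, abs=0.02)


def test_single_marker_chromosome_never_recombines():
    gmap = GeneticMap(["a", "b"], [1, 2], [0.0, 0.0])
    hap = np.array([[0, 0], [1, 1]], dtype=np.int8)
    rng = np.random.default_rng(2)
    for _ in range(50):
        gamete = b.meiosis(hap, gmap, rng)
        assert gamete[0] in (0, 1) and gamete[1] in (0, 1)


def test_meiosis_shape_mismatch_raises(map100):
    with pytest.raises(ValueError, match="shape"):
        b.meiosis(np.zeros((2, 99), dtype=np.int8), map100, seed=1)


def test_heterozygosity_halves_per_selfing_generation(map100):
    # F1 of two fully inbred opposite parents is heterozygous everywhere;
    # selfing with single-seed descent halves heterozygosity each generation
    f1 = np.stack([np.zeros(100, np.int8), np.ones(100, np.int8)])
    rng = np.random.default_rng(17)
    for g, expected in [(1, 0.5), (3, 0.125)]:
        het = []
        for _ in range(400):
            ind = f1
            for _ in range(g):
                ind = np.stack([b.meiosis(ind, map100, rng), b.meiosis(ind, map100, rng)])
            het.append((ind[0] != ind[1]).mean())
        mean = np.mean(het)
        se = np.std(het, ddof=1) / np.sqrt(len(het))
        assert abs(mean - expected) < 4 * se


# ---------------------------------------------------------------------------
# population construction


def test_default_design_composition():
    design = b.PopulationDesign()
    assert design.n_lines == 924
    assert design.n_diversity == 676
    assert design.n_family_lines == 248


def test_population_membership_and_coding(small_study):
    pop = small_study.population
    member = pop.membership
    assert (member == "diversity").sum() == 200
    assert (member == "Family1").sum() == 40
    assert (member == "Family2").sum() == 40
    mm = small_study.marker_matrix()
    assert np.isin(mm.X, (0.0, 1.0, 2.0)).all()
    assert mm.n_markers == 250
    assert set(pop.selfing_gen) <= {1, 2, 3}


def test_empty_families_gives_diversity_only(map100):
    founders = b.simulate_founders(6, map100, (0.2, 0.5), seed=1)
    design = b.PopulationDesign(n_diversity=15, families=())
    pop = b.make_population(design, founders, map100, seed=2)
    assert pop.n_lines == 15
    assert set(pop.membership) == {"diversity"}


def test_unknown_family_parent_raises(map100):
    founders = b.simulate_founders(6, map100, (0.2, 0.5), seed=1)
    design = b.PopulationDesign(
        n_diversity=10,
        families=(b.FamilySpec("FamilyX", 5, parent_a="DIV_9999"),),
    )
    with pytest.raises(KeyError, match="DIV_9999"):
        b.make_population(design, founders, map100, seed=2)


def test_families_share_named_common_parent(map100):
    founders = b.simulate_founders(6, map100, (0.3, 0.5), seed=1)
    design = b.PopulationDesign(
        n_diversity=10,
        families=(b.FamilySpec("F1", 6), b.FamilySpec("F2", 6)),
        common_parent="DIV_0003",
    )
    pop = b.make_population(design, founders, map100, seed=4)
    assert pop.n_lines == 22  # runs; the common parent is DIV_0003 for both


# ---------------------------------------------------------------------------
# phenotypes


def test_noiseless_single_location_recovers_genetic_values(small_study):
    pop = small_study.population
    qtl = small_study.qtl
    trial = b.TrialDesign(
        n_locations_total=1,
        locations_per_line=(1,),
        location_effect_sd=0.0,
        gxe_plus_error_sd=0.0,
        target_h2=None,
        mu=5.0,
    )
    rec = b.simulate_phenotypes(pop, qtl, trial, seed=3)
    g = pop.qtl_dosages() @ qtl.effects
    y = rec.df.set_index("line_id")["value"].loc[pop.line_ids].to_numpy()
    assert np.allclose(y - 5.0, g)


def test_target_h2_recovered_by_reml():
    """Parameter recovery: simulated entry-mean h2 = 0.6 is re-estimated by
    the phenotypic mixed model within +/- 0.05 averaged over replicates."""
    gmap = b.simulate_map(3, 90, 200.0, 15.0, seed=5)
    qtl = b.draw_qtl(gmap, 10, seed=6)
    from beetgs.popsim import _merge_loci

    loci, qtl_mask, qtl_cols = _merge_loci(gmap, qtl)
    qtl = b.QTLModel(loci.chromosomes[qtl_mask], loci.positions[qtl_mask],
                     qtl.effects[np.argsort(qtl_cols)])
    trial = b.TrialDesign(n_locations_total=4, locations_per_line=(4,), target_h2=0.6)
    h2s = []
    rng = np.random.default_rng(8)
    for _ in range(50):
        founders = b.simulate_founders(8, loci, (0.1, 0.5), rng)
        pop = b.make_population(
            b.PopulationDesign(n_diversity=500, families=()), founders, loci, rng,
            qtl_mask=qtl_mask,
        )
        rec = b.simulate_phenotypes(pop, qtl, trial, rng)
        h2s.append(b.heritability(b.fit_variance_components(rec)))
    assert abs(np.mean(h2s) - 0.6) < 0.05


def test_null_trait_has_no_genotypic_variance(small_study):
    pop = small_study.population
    null_qtl = b.QTLModel(
        small_study.qtl.chromosomes,
        small_study.qtl.positions,
        np.zeros(small_study.qtl.n_qtl),
    )
    trial = b.TrialDesign(n_locations_total=4, locations_per_line=(4,),
                          target_h2=None)
    rec = b.simulate_phenotypes(pop, null_qtl, trial, seed=9)
    vc = b.fit_variance_components(rec)
    assert vc.sigma2_G < 0.05 * vc.sigma2_e
    stat, p = b.lrt_genotypic_variance(rec)
    assert p > 0.01


def test_target_h2_requires_positive_error_sd(small_study):
    trial = b.TrialDesign(gxe_plus_error_sd=0.0, target_h2=0.5)
    with pytest.raises(ValueError, match="target_h2"):
        b.simulate_phenotypes(small_study.population, small_study.qtl, trial, seed=1)
    with pytest.raises(ValueError):
        b.TrialDesign(target_h2=1.5)


# ---------------------------------------------------------------------------
# linkage-phase flip


def test_phase_flip_is_an_involution(small_study):
    pop, qtl = small_study.population, small_study.qtl
    flipped = b.flip_linkage_phase(pop, qtl, "Family1", window_cM=15.0)
    X0 = pop.marker_matrix().X
    X1 = flipped.marker_matrix().X
    fam = pop.lines_in("Family1")
    div = pop.lines_in("diversity")
    assert not np.array_equal(X0[fam], X1[fam])  # family changed
    assert np.array_equal(X0[div], X1[div])  # everyone else untouched
    assert np.array_equal(pop.qtl_dosages(), flipped.qtl_dosages())
    back = b.flip_linkage_phase(flipped, qtl, "Family1", window_cM=15.0)
    assert np.array_equal(X0, back.marker_matrix().X)


def test_phase_flip_without_qtl_is_a_noop(small_study):
    pop = small_study.population
    empty = b.QTLModel(np.empty(0, int), np.empty(0), np.empty(0))
    assert b.flip_linkage_phase(pop, empty, "Family1") is pop


def test_phase_flip_unknown_family_raises(small_study):
    with pytest.raises(KeyError, match="Family9"):
        b.flip_linkage_phase(small_study.population, small_study.qtl, "Family9")


def test_phase_flip_monomorphic_family_raises(small_study):
    pop, qtl = small_study.population, small_study.qtl
    clone = b.Population(
        pop.loci, pop.qtl_mask, pop.haplotypes.copy(), pop.line_ids,
        pop.membership, pop.selfing_gen,
    )
    fam = clone.lines_in("Family1")
    clone.haplotypes[fam] = 0  # family fixed for the reference allele everywhere
    with pytest.raises(ValueError, match="monomorphic"):
        b.flip_linkage_phase(clone, qtl, "Family1")


# ---------------------------------------------------------------------------
# study-level structure


def test_study_bundle_layout(small_study):
    assert isinstance(small_study, SimulatedStudy)
    assert set(small_study.phenotypes) == {"T"}
    rec = small_study.phenotypes["T"]
    counts = rec.locations_per_line()
    assert counts.min() >= 1 and counts.max() <= 7
    assert rec.n_records == counts.sum()
    # hidden QTL never leak into the marker matrix
    assert not any(str(m).startswith("QTL") for m in small_study.marker_matrix().marker_ids)
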