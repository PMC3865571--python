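"""Generator behaviour: frequency spectrum, Mendelian transmission,
autozygosity calibration, planted variants, determinism."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from founderscan import (MISSING, SimParams, quad_family, realized_autozygosity,
                         simulate_cohort, simulate_founder_frequencies,
                         simulate_pedigree_genotypes, simulate_screen_counts)
from founderscan.genmap import GeneticMap
from founderscan.pedigree import Individual, Pedigree
from founderscan.simulate import default_map


def test_degenerate_beta_concentrates_at_half():
    params = SimParams(n_variants=500, n_chromosomes=2, beta_shape_a=1e6,
                       beta_shape_b=1e6, seed=0)
    _, freqs = simulate_founder_frequencies(params)
    assert np.allclose(freqs.table["q"], 0.5, atol=1e-2)


def test_beta_sample_mean_matches_moment():
    params = SimParams(n_variants=10_000, n_chromosomes=4, beta_shape_a=0.2,
                       beta_shape_b=2.0, seed=0)
    _, freqs = simulate_founder_frequencies(params)
    mean = 0.2 / 2.2
    sd = np.sqrt(0.2 * 2.0 / (2.2 ** 2 * 3.2))
    se = sd / np.sqrt(10_000)
    # q is floored at q_floor, which shifts the mean by < 1e-3
    assert abs(freqs.table["q"].mean() - mean) < 3 * se + params.q_floor


def test_nonpositive_beta_shapes_rejected():
    with pytest.raises(ValueError, match="positive"):
        SimParams(beta_shape_a=0.0)


def test_db_af_model(small_params):
    _, freqs = simulate_founder_frequencies(
        dataclasses.replace(small_params, n_variants=5000))
    absent = (freqs.table["db_af"] == 0).mean()
    assert 0.02 < absent < 0.10  # ~5% database-private variants
    assert (freqs.table["db_af"] <= 1).all()


def test_seed_determinism_end_to_end(small_params):
    a = simulate_cohort(small_params)
    b = simulate_cohort(dataclasses.replace(small_params))
    assert a.cohort.equals(b.cohort)
    assert a.freqs.table.equals(b.freqs.table)
    assert a.annotations.table.equals(b.annotations.table)
    assert np.array_equal(a.cohort.hap_labels, b.cohort.hap_labels)
    assert a.screen_counts == b.screen_counts
    c = simulate_cohort(dataclasses.replace(small_params, seed=99))
    assert not np.array_equal(a.cohort.dosage, c.cohort.dosage)


def _attainable(f, m):
    """Offspring dosages attainable from parental dosages (no error)."""
    half = {0: {0}, 1: {0, 1}, 2: {1}}
    return {a + b for a in half[f] for b in half[m]}


def test_mendelian_consistency_all_trios(small_sim):
    cohort = small_sim.cohort
    for child, father, mother in cohort.pedigree.trios():
        dc = cohort.dosage_of(child.iid)
        df_ = cohort.dosage_of(father.iid)
        dm = cohort.dosage_of(mother.iid)
        for v in range(cohort.n_variants):
            assert dc[v] in _attainable(int(df_[v]), int(dm[v])), (
                f"variant {cohort.variant_ids[v]} child {child.iid}")


def test_het_x_het_segregates_1_2_1():
    """Pooled across many offspring and het×het markers, dosages are 1:2:1."""
    inds = [Individual("FA", sex=1), Individual("MO", sex=2)]
    inds += [Individual(f"K{i}", "FA", "MO") for i in range(60)]
    ped = Pedigree(inds)
    params = SimParams(n_variants=800, n_chromosomes=4, map_length_cm=80.0,
                       beta_shape_a=5, beta_shape_b=5,  # common alleles
                       genotyping_error_rate=0.0, missing_rate=0.0, seed=2)
    variants, freqs = simulate_founder_frequencies(params)
    cohort = simulate_pedigree_genotypes(ped, variants, freqs, default_map(params), params)
    both_het = (cohort.dosage_of("FA") == 1) & (cohort.dosage_of("MO") == 1)
    kids = cohort.dosage[both_het][:, 2:]
    n = kids.size
    counts = np.array([(kids == d).sum() for d in (0, 1, 2)]) / n
    assert n > 3000
    assert np.allclose(counts, [0.25, 0.5, 0.25], atol=0.03)


def test_label_identity_implies_homozygous(small_sim):
    lab = small_sim.cohort.hap_labels
    ibd = lab[:, :, 0] == lab[:, :, 1]
    assert (small_sim.cohort.dosage[ibd] != 1).all()


@pytest.mark.parametrize("loop,expected,n_rep,tol", [
    ("avuncular", 1 / 8, 150, 0.02),
    ("second_cousin", 1 / 64, 150, 0.02),
])
def test_realized_autozygosity_matches_pedigree_expectation(loop, expected, n_rep, tol):
    """Mean realized IBD fraction converges to the analytic kinship value."""
    vals = []
    gmap = GeneticMap.uniform(20, 100.0)
    chrom = np.repeat([f"chr{i + 1}" for i in range(20)], 50)
    pos = np.tile((np.linspace(0, 100, 50) * 1e6 + 1).astype(int), 20)
    variants = pd.DataFrame({"chrom": chrom, "pos": pos, "ref": "A", "alt": "G"})
    variants.index = pd.Index([f"{c}:{p}:A:G" for c, p in zip(chrom, pos)])
    for seed in range(n_rep):
        params = SimParams(n_variants=len(variants), n_chromosomes=20,
                           map_length_cm=100.0, consanguinity_loop=loop,
                           founder_pool_size=40, genotyping_error_rate=0.0,
                           missing_rate=0.0, seed=seed)
        _, freqs = simulate_founder_frequencies(params, variants)
        ped = quad_family(loop, n_affected=1)
        cohort = simulate_pedigree_genotypes(ped, variants, freqs, gmap, params)
        vals.append(realized_autozygosity(cohort)["AFF1"])
    assert abs(np.mean(vals) - expected) < tol


def test_planted_variant_geometry(small_sim):
    cohort, planted = small_sim.cohort, small_sim.planted
    ped = cohort.pedigree
    for vid in (planted.causal_id, planted.confounder_id):
        row = cohort.variant_ids.get_loc(vid)
        for aff in ped.affecteds:
            assert cohort.dosage[row, cohort.sample_index(aff.iid)] == 2
        for par in ped.by_role("parent"):
            assert cohort.dosage[row, cohort.sample_index(par.iid)] == 1
    ctrl = cohort.dosage_by_role("pop_control")
    causal_row = cohort.variant_ids.get_loc(planted.causal_id)
    conf_row = cohort.variant_ids.get_loc(planted.confounder_id)
    assert (ctrl[causal_row] == 0).all()          # private mutation
    assert (ctrl[conf_row] < 2).all()             # confounder: carriers only
    ann = small_sim.annotations.table
    assert ann.loc[planted.causal_id, "class"] == "missense"
    assert ann.loc[planted.causal_id, "db_af"] == 0.0


def test_planting_stays_mendelian(small_sim):
    """The planted allele descends a real ancestor chain: trios stay consistent."""
    cohort = small_sim.cohort
    for vid in (small_sim.planted.causal_id, small_sim.planted.confounder_id):
        row = cohort.variant_ids.get_loc(vid)
        for child, father, mother in cohort.pedigree.trios():
            dc = int(cohort.dosage[row, cohort.sample_index(child.iid)])
            df_ = int(cohort.dosage[row, cohort.sample_index(father.iid)])
            dm = int(cohort.dosage[row, cohort.sample_index(mother.iid)])
            assert dc in _attainable(df_, dm)


def test_confounder_carrier_fraction_zero_means_absent(small_params):
    params = dataclasses.replace(small_params, confounder_carrier_fraction=0.0)
    sim = simulate_cohort(params)
    row = sim.cohort.variant_ids.get_loc(sim.planted.confounder_id)
    assert (sim.cohort.dosage_by_role("pop_control")[row] == 0).all()


def test_screen_counts_match_emulated_frequencies(rng):
    counts = simulate_screen_counts(721, 0.14, 0.011, rng)
    assert counts.n_total == 721
    # binomial noise around the emulated 101 carriers / 8 homozygotes
    assert abs(counts.n_het - 101) < 4 * np.sqrt(721 * 0.14 * 0.86)
    assert abs(counts.n_hom - 8) < 4 * np.sqrt(721 * 0.011 * 0.989) + 1


def test_genotyping_error_rate_is_respected():
    base = SimParams(n_variants=4000, n_chromosomes=4, genotyping_error_rate=0.0,
                     missing_rate=0.0, seed=5)
    noisy = dataclasses.replace(base, genotyping_error_rate=0.05)
    variants, freqs = simulate_founder_frequencies(base)
    ped = quad_family("none", n_affected=1, n_pop_controls=0)
    gmap = default_map(base)
    clean = simulate_pedigree_genotypes(ped, variants, freqs, gmap, base)
    perturbed = simulate_pedigree_genotypes(ped, variants, freqs, gmap, noisy)
    flips = (clean.dosage != perturbed.dosage).mean()
    assert 0.03 < flips < 0.07


def test_missingness_rate(small_params):
    params = dataclasses.replace(small_params, missing_rate=0.1)
    sim = simulate_cohort(params)
    frac = (sim.cohort.dosage == MISSING).mean()
    assert 0.07 < frac < 0.13
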