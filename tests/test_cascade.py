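"""Filter cascade: 20-variant truth table, brute-force oracle equivalence,
missing-genotype policies, stage-order commutation, trace invariants."""

import dataclasses
import itertools

import numpy as np
import pandas as pd
import pytest

from founderscan import (AnnotationTable, CascadeConfig, CohortGenotypes,
                         SimParams, run_cascade, simulate_cohort)
from founderscan.cascade import (stage_control_exomes, stage_homozygous_affected,
                                 stage_parents_het, stage_rare_deleterious)
from founderscan.pedigree import Individual, Pedigree

M = -1  # missing dosage

# variant rows: class, db_af, pph2, sift, AFF1, AFF2, FA, MO, C1, C2, C3
_FIXTURE = {
    "v01": ("missense", 0.000, 1.00, 0.00, 2, 2, 1, 1, 0, 0, 0),  # causal-like
    "v02": ("missense", 0.000, 1.00, 0.05, 2, 2, 1, 1, 1, 1, 0),  # het controls ok
    "v03": ("synonymous", 0.000, None, None, 2, 2, 1, 1, 0, 0, 0),
    "v04": ("missense", 0.050, 1.00, 0.00, 2, 2, 1, 1, 0, 0, 0),  # common
    "v05": ("missense", 0.010, 1.00, 0.00, 2, 2, 1, 1, 0, 0, 0),  # at threshold
    "v06": ("missense", 0.000, 0.50, 0.00, 2, 2, 1, 1, 0, 0, 0),  # pph2 benign
    "v07": ("missense", 0.000, 1.00, 0.50, 2, 2, 1, 1, 0, 0, 0),  # sift tolerated
    "v08": ("nonsense", 0.005, None, None, 2, 2, 1, 1, 0, 1, 0),  # class-based keep
    "v09": ("frameshift_indel", 0.0, None, None, 2, 1, 1, 1, 0, 0, 0),
    "v10": ("splice_site", 0.000, None, None, 2, M, 1, 1, 0, 0, 0),
    "v11": ("inframe_indel", 0.0, None, None, 0, 0, 1, 1, 0, 0, 0),
    "v12": ("nonsense", 0.000, None, None, 2, 2, 2, 1, 0, 0, 0),  # hom parent
    "v13": ("nonsense", 0.000, None, None, 2, 2, 1, 0, 0, 0, 0),  # ref parent
    "v14": ("nonsense", 0.000, None, None, 2, 2, 1, M, 0, 0, 0),  # missing parent
    "v15": ("nonsense", 0.000, None, None, 2, 2, 1, 1, 2, 0, 0),  # hom control
    "v16": ("missense", 0.009, 0.85, 0.05, 2, 2, 1, 1, 0, 1, 1),  # inclusive cutoffs
    "v17": ("other", 0.000, None, None, 2, 2, 1, 1, 0, 0, 0),
    "v18": ("missense", 0.000, 0.84, 0.00, 2, 2, 1, 1, 0, 0, 0),  # just below pph2
    "v19": ("nonsense", 0.500, None, None, 2, 2, 1, 1, 0, 0, 0),  # common nonsense
    "v20": ("splice_site", 0.000, None, None, 1, 1, 1, 1, 0, 0, 0),
}
_SAMPLES = ["AFF1", "AFF2", "FA", "MO", "C1", "C2", "C3"]
_EXPECTED_SURVIVORS = ["v01", "v02", "v08", "v16"]


def _fixture_cohort():
    ped = Pedigree(
        [Individual("FA", sex=1, role="parent"),
         Individual("MO", sex=2, role="parent"),
         Individual("AFF1", "FA", "MO", affected=True, role="affected"),
         Individual("AFF2", "FA", "MO", affected=True, role="affected")]
        + [Individual(f"C{i}", role="pop_control", fid=f"CF{i}") for i in (1, 2, 3)]
    )
    ids = list(_FIXTURE)
    variants = pd.DataFrame({
        "chrom": "chr1", "pos": np.arange(100, 100 + 10 * len(ids), 10),
        "ref": "A", "alt": "G"}, index=pd.Index(ids, name="variant_id"))
    dosage = np.array([row[4:] for row in _FIXTURE.values()], dtype=np.int8)
    ann = pd.DataFrame(
        [(r[0], r[1], np.nan if r[2] is None else r[2],
          np.nan if r[3] is None else r[3]) for r in _FIXTURE.values()],
        columns=["class", "db_af", "score_pph2", "score_sift"],
        index=variants.index)
    return CohortGenotypes(variants, _SAMPLES, dosage, ped), AnnotationTable(ann)


def _oracle_survivors(config: CascadeConfig) -> set:
    """Independent brute-force evaluation: plain-python set intersection."""
    keep_classes = {"nonsense", "frameshift_indel", "inframe_indel", "splice_site"}

    def rare_del(r):
        cls, db, pph2, sift = r[0], r[1], r[2], r[3]
        if not db < config.rarity_threshold:
            return False
        if cls in keep_classes:
            return True
        if cls != "missense" or pph2 is None:
            return False
        hits = (pph2 >= config.pph2_min, sift <= config.sift_max)
        return all(hits) if config.deleterious_rule == "both" else any(hits)

    def zyg(values, wanted):
        if config.missing_genotype_policy == "permissive":
            return all(v in (wanted, M) for v in values)
        return all(v == wanted for v in values)

    sets = [
        {v for v, r in _FIXTURE.items() if rare_del(r)},
        {v for v, r in _FIXTURE.items() if zyg(r[4:6], 2)},
        {v for v, r in _FIXTURE.items() if zyg(r[6:8], 1)},
        {v for v, r in _FIXTURE.items() if not any(c == 2 for c in r[8:11])},
    ]
    return set.intersection(*sets)


@pytest.mark.parametrize("config", [
    CascadeConfig(),
    CascadeConfig(deleterious_rule="either"),
    CascadeConfig(missing_genotype_policy="permissive"),
    CascadeConfig(rarity_threshold=0.02, pph2_min=0.9, sift_max=0.01),
])
def test_cascade_equals_bruteforce_oracle(config):
    cohort, ann = _fixture_cohort()
    trace = run_cascade(cohort, ann, config=config)
    assert set(trace.candidates) == _oracle_survivors(config)


def test_default_truth_table_survivors():
    cohort, ann = _fixture_cohort()
    trace = run_cascade(cohort, ann)
    assert trace.candidates == _EXPECTED_SURVIVORS
    names = [s.name for s in trace.stages]
    assert names == ["rare_deleterious", "homozygous_affected", "parents_het",
                     "control_exomes"]
    counts = [s.surviving_count for s in trace.stages]
    assert counts == sorted(counts, reverse=True)          # monotone
    assert trace.stages[0].input_count == len(_FIXTURE)
    # per-patient load metadata: both readings of the candidate count
    assert trace.metadata["rare_deleterious_hom_shared"] >= len(trace.candidates)
    for s_prev, s_next in zip(trace.stages, trace.stages[1:]):
        assert set(s_next.survivors) <= set(s_prev.survivors)


def test_stage_examples():
    cohort, ann = _fixture_cohort()
    ids = cohort.variant_ids
    kept = stage_rare_deleterious(ids, ann)
    assert "v01" in kept and "v03" not in kept and "v04" not in kept
    hom, _ = stage_homozygous_affected(ids, cohort, cohort.pedigree)
    assert "v01" in hom and "v09" not in hom and "v10" not in hom
    het, _ = stage_parents_het(ids, cohort, cohort.pedigree)
    assert "v01" in het and "v12" not in het and "v14" not in het
    ctrl = cohort.subset_samples(["C1", "C2", "C3"])
    ex = stage_control_exomes(ids, ctrl)
    assert "v02" in ex and "v15" not in ex


def test_missing_policy_truth_table():
    cohort, ann = _fixture_cohort()
    ids = cohort.variant_ids
    strict, _ = stage_homozygous_affected(ids, cohort, cohort.pedigree,
                                          CascadeConfig())
    assert "v10" not in strict
    loose, flagged = stage_homozygous_affected(
        ids, cohort, cohort.pedigree,
        CascadeConfig(missing_genotype_policy="permissive"))
    assert "v10" in loose and "v10" in flagged
    strict_p, _ = stage_parents_het(ids, cohort, cohort.pedigree, CascadeConfig())
    assert "v14" not in strict_p
    loose_p, flagged_p = stage_parents_het(
        ids, cohort, cohort.pedigree,
        CascadeConfig(missing_genotype_policy="permissive"))
    assert "v14" in loose_p and "v14" in flagged_p


def test_stage_order_commutation():
    """The four per-variant predicates commute: any order, same final set."""
    cohort, ann = _fixture_cohort()
    ped = cohort.pedigree
    ctrl = cohort.subset_samples(["C1", "C2", "C3"])
    cfg = CascadeConfig()

    def s_rare(ids):
        return stage_rare_deleterious(ids, ann, cfg)

    def s_hom(ids):
        return stage_homozygous_affected(ids, cohort, ped, cfg)[0]

    def s_het(ids):
        return stage_parents_het(ids, cohort, ped, cfg)[0]

    def s_ctrl(ids):
        return stage_control_exomes(ids, ctrl)

    reference = None
    for order in itertools.permutations([s_rare, s_hom, s_het, s_ctrl]):
        ids = cohort.variant_ids
        for stage in order:
            ids = stage(ids)
        final = set(ids)
        reference = final if reference is None else reference
        assert final == reference


def test_empty_variant_set():
    cohort, ann = _fixture_cohort()
    empty = cohort.subset_variants([])
    trace = run_cascade(empty, ann)
    assert trace.candidates == []
    assert all(s.input_count == 0 and s.surviving_count == 0 for s in trace.stages)


def test_unannotated_variant_handling():
    cohort, ann = _fixture_cohort()
    partial = AnnotationTable(ann.table.drop(index="v05"))
    with pytest.raises(RuntimeError, match="v05"):
        run_cascade(cohort, partial)
    trace = run_cascade(cohort, partial,
                        config=CascadeConfig(unannotated_policy="drop"))
    assert trace.candidates == _EXPECTED_SURVIVORS


def test_no_affected_errors():
    cohort, ann = _fixture_cohort()
    ped = Pedigree([Individual("FA", sex=1), Individual("MO", sex=2)])
    sub = cohort.subset_samples(["FA", "MO"])
    sub.pedigree = ped
    with pytest.raises(RuntimeError, match="affected"):
        run_cascade(sub, ann, ped)


def test_control_stage_skipped_without_controls():
    cohort, ann = _fixture_cohort()
    family = cohort.subset_samples(["AFF1", "AFF2", "FA", "MO"])
    trace = run_cascade(family, ann)
    ctrl_stage = [s for s in trace.stages if s.name == "control_exomes"][0]
    assert "SKIPPED" in ctrl_stage.note
    assert "v15" in trace.candidates  # nothing excluded without controls


@pytest.mark.parametrize("seed", range(4))
def test_planted_causal_always_survives(seed):
    """With clean genotypes the planted causal variant passes every stage."""
    params = SimParams(n_variants=1200, n_chromosomes=4, map_length_cm=60.0,
                       n_pop_controls=8, genotyping_error_rate=0.0,
                       missing_rate=0.0, seed=seed)
    sim = simulate_cohort(params)
    trace = run_cascade(sim.cohort, sim.annotations)
    assert sim.planted.causal_id in trace.candidates
    assert sim.planted.confounder_id in trace.candidates
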