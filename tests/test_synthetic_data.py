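from collections import Counter

import pytest

import oracles
from marinerscan import (
    CopyPlan,
    GenomePlan,
    PlantConfig,
    build_panel,
    default_paper_config,
    find_tir_pair,
    find_best_orf,
    pairwise_identity,
    plant_copies,
)
from marinerscan.synthetic_data import SUBFAMILIES, _mutate_copy
from marinerscan.transposase_analysis import (
    classify_triad,
    fuzzy_motif_scan,
    nls_heuristic,
)

# published per-species count structure the default config must reproduce
PUBLISHED_COUNTS = {
    "S_chinensis": dict(total=33, subfam=(4, 9, 8, 12), active=0, complete=28),
    "S_peitan": dict(total=26, subfam=(2, 2, 6, 16), active=0, complete=23),
    "N_ibofushi": dict(total=16, subfam=(3, 5, 4, 4), active=0, complete=15),
    "M_flavogallis": dict(total=10, subfam=(4, 3, 2, 1), active=1, complete=8),
    "F_choui": dict(total=10, subfam=(3, 4, 3, 0), active=1, complete=8),
    "K_rhusicola": dict(total=10, subfam=(4, 2, 4, 0), active=3, complete=8),
    "M_rhois": dict(total=16, subfam=(9, 1, 6, 0), active=0, complete=16),
}


@pytest.mark.parametrize("sub", SUBFAMILIES)
def test_consensus_passes_every_detector(consensi, sub):
    cons = consensi[sub]
    pair = find_tir_pair(cons.element)
    assert (pair.length, pair.mismatches) == (cons.tir_len, 0)
    orf = find_best_orf(cons.element)
    assert orf.aa_seq == cons.protein
    assert not orf.has_internal_stop
    assert 310 <= len(orf.aa_seq) <= 345
    assert classify_triad(orf.aa_seq).triad_class == "DD34D"
    assert fuzzy_motif_scan(orf.aa_seq, "WVPHEL")[1] == 0
    assert fuzzy_motif_scan(orf.aa_seq, "YSPDL")[1] == 0
    assert nls_heuristic(orf.aa_seq) is not None


def test_consensi_are_mutually_divergent(consensi):
    names = list(consensi)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            assert pairwise_identity(consensi[a].element, consensi[b].element) < 0.70


@pytest.mark.parametrize("sub", SUBFAMILIES)
def test_exactly_one_catalytic_triad(consensi, sub):
    assert len(oracles.count_triads(consensi[sub].protein)) == 1


def test_intact_mutation_plan_is_synonymous(consensi, rng):
    cons = consensi["Mauritiana"]
    seq, ledger = _mutate_copy(
        cons, CopyPlan(subfamily="Mauritiana", activity="intact", divergence=0.02),
        rng,
    )
    assert len(seq) == len(cons.element)
    orf = find_best_orf(seq)
    assert orf.aa_seq == cons.protein  # protein unchanged
    assert len(ledger) > 0


def test_decayed_plan_plants_exact_stop_count(consensi, rng):
    cons = consensi["Drosophila"]
    seq, _ = _mutate_copy(
        cons, CopyPlan(subfamily="Drosophila", activity="decayed",
                       n_premature_stops=2), rng,
    )
    orf = find_best_orf(seq)
    assert orf.has_internal_stop
    assert orf.n_premature_stops == 2


def test_nls_ablated_copies_lose_the_basic_window(consensi, rng):
    cons = consensi["Vertumana"]
    seq, _ = _mutate_copy(
        cons, CopyPlan(subfamily="Vertumana", activity="decayed",
                       divergence=0.0, nls_ablated=True), rng,
    )
    orf = find_best_orf(seq)
    assert nls_heuristic(orf.aa_seq) is None
    assert nls_heuristic(cons.protein) is not None


def test_same_seed_reproduces_bytes():
    cfg = PlantConfig(genomes=[GenomePlan(
        species="g", prefix="g",
        copies=[CopyPlan(subfamily="Mauritiana")],
        n_large_contigs=1, large_contig_len=30_000, n_small_contigs=3)],
        seed=5)
    g1, t1 = plant_copies(cfg)
    g2, t2 = plant_copies(cfg)
    assert g1[0].contigs == g2[0].contigs
    assert t1.records == t2.records


def test_planted_spans_inside_contigs(small_sim):
    _, genomes, truth, _ = small_sim
    lengths = {(g.genome_id, cid): len(seq)
               for g in genomes for cid, seq in g.items()}
    for r in truth.records:
        assert 0 <= r.start < r.end <= lengths[(r.genome_id, r.contig_id)]


def test_default_config_reproduces_published_structure():
    genomes, truth = plant_copies(default_paper_config(seed=2))
    assert len(truth) == 121
    by_genome = Counter(r.genome_id for r in truth.records)
    for species, row in PUBLISHED_COUNTS.items():
        recs = [r for r in truth.records if r.genome_id == species]
        assert by_genome[species] == row["total"]
        subfam = Counter(r.subfamily for r in recs)
        assert tuple(subfam.get(s, 0) for s in SUBFAMILIES) == row["subfam"]
        assert sum(1 for r in recs if r.activity == "potentially_active") \
            == row["active"]
        assert sum(1 for r in recs if r.completeness == "complete") \
            == row["complete"]
    acts = Counter(r.activity for r in truth.records)
    assert acts["potentially_active"] == 5
    assert acts["intact_orf_truncated"] == 2
    comp = Counter(r.completeness for r in truth.records)
    assert comp["complete"] == 106
    assert sum(v for k, v in comp.items() if k != "complete") == 15
    # TA duplication on both flanks of complete copies except the two
    # designated one-sided cases
    complete = [r for r in truth.records if r.completeness == "complete"]
    one_sided = [r for r in complete if not r.tsd_left and r.tsd_right]
    assert len(one_sided) == 2
    assert all(r.genome_id == "K_rhusicola" for r in one_sided)
    assert all(r.tsd_left and r.tsd_right for r in complete
               if r not in one_sided)


def test_panel_layout():
    panel = build_panel(default_paper_config(seed=0))
    assert len(panel.by_role("query")) == 4
    assert len(panel.by_role("phylo_reference")) == 8
    assert panel.outgroup is not None and panel.outgroup.family == "Tc1"
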