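import numpy as np
import pytest

import degenpanel as dp
from degenpanel import iupac
from degenpanel.codon import ProteinAlignment, translate
from degenpanel.design import (
    DesignError,
    Panel,
    TargetSeq,
    abundance_weighted_coverage,
    build_guide_distances,
    design_panel,
    grow_cluster,
    prune_outgroup_only_pairs,
    select_seed,
)
from degenpanel.pcr import CoverageMap
from degenpanel.primers import PrimerConstraints
from degenpanel.simulate import (
    FamilySpec,
    simulate_family,
    simulate_incompatible_clades,
)

SMALL = PrimerConstraints(target_window=(105, 214))


def test_select_seed_rules():
    a = TargetSeq("a", "ATG", abundance=5.0)
    b = TargetSeq("b", "ATG", abundance=2.0)
    assert select_seed([b, a]) is a
    # all-equal abundances: lexicographically smallest id
    c = TargetSeq("c", "ATG", abundance=2.0)
    assert select_seed([c, b]) is b
    assert select_seed([c]) is c
    with pytest.raises(DesignError):
        select_seed([])


def test_guide_distances():
    pal = ProteinAlignment([("a", "AAAA"), ("b", "AAAT"), ("c", "AAAA"),
                            ("d", "----")])
    g = build_guide_distances(pal)
    assert g.distance("a", "c") == 0.0
    assert g.distance("a", "b") == pytest.approx(0.25)
    assert g.distance("a", "d") == 1.0  # no mutually non-gap columns
    assert np.allclose(g.dist, g.dist.T)
    assert np.all(np.diag(g.dist) == 0)
    # a seed's 0-distance duplicates come first
    order = g.ordering("a", ["b", "c", "d"], {"b": 9.0, "c": 1.0, "d": 1.0})
    assert order[0] == "c"


def test_ordering_tie_breaks_by_abundance_then_id():
    pal = ProteinAlignment([("s", "AAAA"), ("x", "AAAT"), ("y", "AAAT"),
                            ("z", "AAAT")])
    g = build_guide_distances(pal)
    order = g.ordering("s", ["x", "y", "z"], {"x": 1.0, "y": 5.0, "z": 1.0})
    assert order == ["y", "x", "z"]


def _identical_collection(n=5, seed=3):
    spec = FamilySpec(n_clades=1, members_per_clade=n, gene_len=300,
                      conserved_windows=((35, 75),), p_cons=0.0,
                      p_var_between=0.0, p_var_within=0.0, rng_seed=seed)
    return simulate_family(spec)


def test_grow_cluster_gathers_identical_sequences():
    collection, pal, _ = _identical_collection()
    remaining = {t.id: t for t in collection}
    guide = build_guide_distances(pal)
    seed = select_seed(collection)
    members, pair, rejected = grow_cluster(seed, remaining, guide, SMALL)
    assert sorted(members) == sorted(remaining)
    assert rejected == []
    assert pair is not None
    assert pair.fwd.degeneracy == pair.rev.degeneracy == 1


def test_design_panel_on_identical_sequences_gives_one_pair():
    collection, pal, _ = _identical_collection()
    panel = design_panel(collection, pal)
    assert len(panel.pairs) == 1
    assert panel.pairs[0].pair_id == "PP1"
    assert panel.coverage.covered == {t.id for t in collection}
    assert panel.undesignable == set()


@pytest.mark.parametrize("k", [2, 3])
def test_incompatible_clades_recovered_exactly(k):
    collection, pal, truth = simulate_incompatible_clades(
        k, members_per_clade=4, gene_len=300, rng_seed=5
    )
    panel = design_panel(collection, pal)
    assert len(panel.pairs) == k
    assert panel.undesignable == set()
    # each pair's amplified set is exactly one clade
    for pid, ids in panel.coverage.by_pair.items():
        assert len({truth[i] for i in ids}) == 1


def test_design_panel_guard_errors():
    collection, pal, _ = _identical_collection(n=3)
    with pytest.raises(DesignError, match="empty"):
        design_panel([], pal)
    bad = collection + [TargetSeq("zz_missing", collection[0].cds)]
    with pytest.raises(DesignError, match="zz_missing"):
        design_panel(bad, pal)


def test_design_is_deterministic_and_input_order_free():
    spec = FamilySpec(n_clades=2, members_per_clade=5, gene_len=300,
                      conserved_windows=((35, 75),), rng_seed=11)
    collection, pal, _ = simulate_family(spec)
    p1 = design_panel(collection, pal)
    p2 = design_panel(list(reversed(collection)), pal)
    assert [(p.pair_id, p.fwd.seq, p.rev.seq) for p in p1.pairs] == [
        (p.pair_id, p.fwd.seq, p.rev.seq) for p in p2.pairs
    ]
    assert p1.log == p2.log
    assert p1.coverage.by_pair == p2.coverage.by_pair


def test_duplicate_target_never_changes_primer_sequences():
    spec = FamilySpec(n_clades=2, members_per_clade=4, gene_len=300,
                      conserved_windows=((35, 75),), rng_seed=19)
    collection, pal, _ = simulate_family(spec)
    base = design_panel(collection, pal)
    dup_of = collection[2]
    dup = TargetSeq("zdup", dup_of.cds, abundance=0.0)
    pal2 = ProteinAlignment(
        list(zip(pal.ids, pal.rows)) + [("zdup", pal.row(dup_of.id))]
    )
    with_dup = design_panel(collection + [dup], pal2)
    assert [(p.fwd.seq, p.rev.seq) for p in base.pairs] == [
        (p.fwd.seq, p.rev.seq) for p in with_dup.pairs
    ]
    assert "zdup" in with_dup.coverage.covered


def test_every_target_lands_in_exactly_one_bucket_even_when_undesignable():
    """Impossible product bounds make every sequence undesignable; the
    bookkeeping must still partition the collection."""
    collection, pal, _ = _identical_collection(n=3)
    impossible = PrimerConstraints(
        target_window=(105, 214), product_min=5000, product_max=6000
    )
    panel = design_panel(collection, pal, impossible)
    assert panel.pairs == []
    assert panel.undesignable == {t.id for t in collection}
    assert panel.coverage.covered == set()


def _fake_panel(coverage_by_pair, pair):
    by_target: dict[str, set] = {}
    for pid, ids in coverage_by_pair.items():
        for t in ids:
            by_target.setdefault(t, set()).add(pid)
    cov = CoverageMap(
        by_pair={k: set(v) for k, v in coverage_by_pair.items()},
        by_target=by_target,
    )
    pairs = [pair.with_id(pid) for pid in coverage_by_pair]
    return Panel(pairs=pairs, coverage=cov, undesignable=set())


def test_prune_outgroup_only_pairs_rules(panel_small):
    donor = panel_small.pairs[0]
    collection = [
        TargetSeq("in1", "ATGGCA"), TargetSeq("in2", "ATGGCA"),
        TargetSeq("og1", "ATGGCA", outgroup=True),
        TargetSeq("og2", "ATGGCA", outgroup=True),
    ]
    panel = _fake_panel(
        {"PP1": {"in1", "in2"}, "PP2": {"og1", "og2"}, "PP3": {"og1", "in2"}},
        donor,
    )
    pruned = prune_outgroup_only_pairs(panel, collection)
    ids = [p.pair_id for p in pruned.pairs]
    assert ids == ["PP1", "PP3"]  # outgroup-only PP2 dropped, no renumbering
    assert pruned.outgroup_only == ("og2",)  # og1 still covered via PP3
    # boundary: a pair with 1 outgroup + 1 ingroup target is kept (PP3)
    assert "PP3" in pruned.coverage.by_pair
    # panel without outgroup targets is unchanged
    no_og = [TargetSeq(t.id, t.cds) for t in collection]
    same = prune_outgroup_only_pairs(panel, no_og)
    assert [p.pair_id for p in same.pairs] == ["PP1", "PP2", "PP3"]


def test_abundance_weighted_coverage_examples(panel_small):
    donor = panel_small.pairs[0]
    collection = [
        TargetSeq("a", "ATGGCA", abundance=3.0),
        TargetSeq("b", "ATGGCA", abundance=1.0),
    ]
    covering_a = _fake_panel({"PP1": {"a"}}, donor)
    assert abundance_weighted_coverage(covering_a, collection) == pytest.approx(0.75)
    covering_all = _fake_panel({"PP1": {"a", "b"}}, donor)
    assert abundance_weighted_coverage(covering_all, collection) == 1.0
    empty = Panel(pairs=[], coverage=CoverageMap(), undesignable=set())
    assert abundance_weighted_coverage(empty, collection) == 0.0
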