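import numpy as np
import pytest
from Bio.Align import PairwiseAligner

from polyhybrid import simulate_ortholog_sequences
from polyhybrid.orthosim import (
    LinkedOrthologSet,
    SequenceSet,
    base_composition,
    find_shared_orthologs,
    identity_matrix,
    nj_tree,
    reciprocal_best_hits,
    trim_and_link,
)


def _rand_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


def _mutate(rng, seq, rate):
    out = list(seq)
    for i in range(len(out)):
        if rng.random() < rate:
            out[i] = rng.choice([b for b in "ACGT" if b != out[i]])
    return "".join(out)


# ------------------------------------------------------------------ RBH
def test_rbh_identical_single_sequences():
    rng = np.random.default_rng(0)
    s = _rand_seq(rng, 400)
    pairs = reciprocal_best_hits(
        SequenceSet({"a1": s}), SequenceSet({"b1": s})
    )
    assert pairs == [("a1", "b1")]


def test_rbh_length_filter_excludes_short_perfect_match():
    rng = np.random.default_rng(1)
    short = _rand_seq(rng, 150)
    keeper = _rand_seq(rng, 400)
    set_a = SequenceSet({"short": short, "long": keeper})
    set_b = SequenceSet({"short": short, "long": keeper})
    pairs = reciprocal_best_hits(set_a, set_b)
    assert pairs == [("long", "long")]


def test_rbh_matches_exhaustive_alignment_oracle():
    # 5x5 sets with planted 2% divergence: prefiltered search equals the
    # brute-force all-pairs best-scoring assignment
    rng = np.random.default_rng(2)
    originals = {f"a{i}": _rand_seq(rng, 500) for i in range(5)}
    partners = {f"b{i}": _mutate(rng, originals[f"a{i}"], 0.02) for i in range(5)}
    set_a, set_b = SequenceSet(originals), SequenceSet(partners)
    pairs = reciprocal_best_hits(set_a, set_b)

    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score, aligner.mismatch_score = 1, -1
    aligner.open_gap_score, aligner.extend_gap_score = -5, -2
    expected = []
    for a, sa in originals.items():
        scores = {b: aligner.score(sa, sb) for b, sb in partners.items()}
        best_b = max(sorted(scores), key=lambda k: scores[k])
        back = {a2: aligner.score(partners[best_b], s2) for a2, s2 in originals.items()}
        if max(sorted(back), key=lambda k: back[k]) == a and scores[best_b] >= 100:
            expected.append((a, best_b))
    assert pairs == sorted(expected)


def test_rbh_empty_after_filter_raises():
    with pytest.raises(ValueError, match="200"):
        reciprocal_best_hits(
            SequenceSet({"a": "ACGT" * 10}), SequenceSet({"b": "ACGT" * 10})
        )


# ------------------------------------------------------------ trim & link
def test_link_identical_alleles_is_plain_concatenation():
    rng = np.random.default_rng(3)
    seqs = {f"o{i}": _rand_seq(rng, 200) for i in range(3)}
    alleles = {oid: {"s1": s, "s2": s} for oid, s in seqs.items()}
    linked = trim_and_link(alleles, ["s1", "s2"])
    expected = "".join(seqs[k] for k in sorted(seqs))
    assert linked.sequences["s1"] == expected
    assert linked.sequences["s2"] == expected


def test_link_trims_reference_end_overhang():
    rng = np.random.default_rng(4)
    core = _rand_seq(rng, 300)
    overhang = _rand_seq(rng, 10)
    alleles = {"o1": {"s1": overhang + core, "s2": core}}
    linked = trim_and_link(alleles, ["s1", "s2"])
    assert linked.length == 300
    assert linked.sequences["s1"] == core
    assert linked.sequences["s2"] == core


def test_link_drops_short_cores_and_missing_samples():
    rng = np.random.default_rng(5)
    good = _rand_seq(rng, 250)
    alleles = {
        "keep": {"s1": good, "s2": good},
        "short": {"s1": _rand_seq(rng, 60), "s2": _rand_seq(rng, 60)},
        "missing": {"s1": _rand_seq(rng, 250)},
    }
    linked = trim_and_link(alleles, ["s1", "s2"])
    assert [s[0] for s in linked.segments] == ["keep"]


def test_linked_set_invariants():
    with pytest.raises(ValueError, match="length"):
        LinkedOrthologSet({"a": "ACGT", "b": "ACG"})
    ok = LinkedOrthologSet({"a": "ACGT", "b": "ACGA"}, [("o1", 0, 4)])
    assert ok.length == 4


# --------------------------------------------------------------- identity
def test_identity_trivial_values():
    linked = LinkedOrthologSet({"a": "ACGT", "b": "ACGA", "c": "ACGT"})
    m = identity_matrix(linked)
    assert m.loc["a", "b"] == pytest.approx(0.75)
    assert m.loc["a", "c"] == pytest.approx(1.0)
    assert np.allclose(m, m.T) and np.allclose(np.diag(m), 1.0)


def test_identity_matches_positional_loop_oracle():
    rng = np.random.default_rng(6)
    s1 = _rand_seq(rng, 1000)
    s2 = _mutate(rng, s1, 0.03)
    s3 = _mutate(rng, s1, 0.10)
    linked = LinkedOrthologSet({"x": s1, "y": s2, "z": s3})
    m = identity_matrix(linked)
    for a, b in (("x", "y"), ("x", "z"), ("y", "z")):
        sa, sb = linked.sequences[a], linked.sequences[b]
        same = total = 0
        for ca, cb in zip(sa, sb):
            if ca != "N" and cb != "N":
                total += 1
                same += ca == cb
        assert m.loc[a, b] == pytest.approx(same / total)


def test_identity_excludes_n_positions():
    linked = LinkedOrthologSet({"a": "ACGTNN", "b": "ACGANN"})
    assert identity_matrix(linked).loc["a", "b"] == pytest.approx(0.75)
    with pytest.raises(ValueError, match="comparable"):
        identity_matrix(LinkedOrthologSet({"a": "NN", "b": "NN"}))


# --------------------------------------------------------- base composition
def test_base_composition_simple():
    comp = base_composition(LinkedOrthologSet({"a": "ACGT", "b": "AAAA"}))
    assert comp.loc["a", "AT_pct"] == pytest.approx(50.0)
    assert comp.loc["b", "AT_pct"] == pytest.approx(100.0)
    np.testing.assert_allclose(comp["AT_pct"] + comp["GC_pct"], 100.0)


def test_gc_biased_lineage_shifts_composition_with_source_parent():
    sets = simulate_ortholog_sequences(
        20, length_range=(400, 600), divergence=0.08, seed=7,
        gc_bias_yb=1.0, replicate_divergence=0.0,
        hybrid_source={"2nBY": "YB", "3nBY": "BSB"}, n_reps=1,
    )
    linked = LinkedOrthologSet(
        {k: "".join(v.sequences[o] for o in sorted(v.sequences)) for k, v in sets.items()}
    )
    comp = base_composition(linked)
    # the GC-pushed YB lineage and its hybrid copy cluster together
    assert comp.loc["YB", "GC_pct"] > comp.loc["BSB", "GC_pct"]
    d_yb = abs(comp.loc["2nBY_1", "GC_pct"] - comp.loc["YB", "GC_pct"])
    d_bsb = abs(comp.loc["2nBY_1", "GC_pct"] - comp.loc["BSB", "GC_pct"])
    assert d_yb < d_bsb


# -------------------------------------------------------------------- NJ
def test_nj_three_taxa():
    import pandas as pd

    ident = pd.DataFrame(
        [[1.0, 0.9, 0.8], [0.9, 1.0, 0.85], [0.8, 0.85, 1.0]],
        index=list("ABC"), columns=list("ABC"),
    )
    newick = nj_tree(ident)
    assert all(t in newick for t in "ABC") and newick.endswith(";")


def test_nj_requires_three_samples():
    import pandas as pd

    ident = pd.DataFrame([[1.0, 0.9], [0.9, 1.0]], index=["A", "B"], columns=["A", "B"])
    with pytest.raises(ValueError):
        nj_tree(ident)


def test_nj_recovers_additive_four_taxon_topology():
    import io

    import pandas as pd
    from skbio import TreeNode

    # additive distances from ((A:1,B:2):3,(C:1,D:2)) scaled to identities
    d = {
        ("A", "B"): 3, ("C", "D"): 3,
        ("A", "C"): 5, ("A", "D"): 6, ("B", "C"): 6, ("B", "D"): 7,
    }
    taxa = list("ABCD")
    mat = np.zeros((4, 4))
    for i, a in enumerate(taxa):
        for j, b in enumerate(taxa):
            if i != j:
                mat[i, j] = d[tuple(sorted((a, b)))] / 100.0
    ident = pd.DataFrame(1 - mat, index=taxa, columns=taxa)
    tree = TreeNode.read(io.StringIO(nj_tree(ident)))
    dist = tree.tip_tip_distances()
    assert dist["A", "B"] < dist["A", "C"] < dist["A", "D"] - 0.005
    assert dist["C", "D"] < dist["B", "C"]
    # branch lengths reproduce the additive input
    assert dist["A", "B"] == pytest.approx(0.03, abs=1e-9)


# ----------------------------------------------------------- full pipeline
def test_simulated_eight_sample_pipeline_equal_lengths_and_clustering():
    import io

    from skbio import TreeNode

    sets = simulate_ortholog_sequences(
        15, length_range=(300, 700), divergence=0.03, seed=8,
        hybrid_source={"2nBY": "YB", "3nBY": "BSB"},
    )
    alleles = find_shared_orthologs(sets)
    linked = trim_and_link(alleles, list(sets))
    lengths = {len(s) for s in linked.sequences.values()}
    assert len(lengths) == 1  # all eight linked sequences equal length
    ident = identity_matrix(linked)
    tree = TreeNode.read(io.StringIO(nj_tree(ident)))
    dist = tree.tip_tip_distances()
    for rep in ("3nBY_1", "3nBY_2", "3nBY_3"):
        assert dist[rep, "BSB"] < dist[rep, "YB"]
    for rep in ("2nBY_1", "2nBY_2", "2nBY_3"):
        assert dist[rep, "YB"] < dist[rep, "BSB"]


def test_fasta_roundtrip(tmp_path):
    rng = np.random.default_rng(9)
    ss = SequenceSet({f"o{i}": _rand_seq(rng, 100) for i in range(4)}, label="x")
    ss.to_fasta(tmp_path / "x.fasta")
    back = SequenceSet.from_fasta(tmp_path / "x.fasta", label="x")
    assert back.sequences == ss.sequences
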