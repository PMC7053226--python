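"""Virtual founder construction and marker recoding."""

import numpy as np
import pandas as pd
import pytest

from ccpevolve.founder import (
    CrossingScheme,
    allele_frequencies,
    build_virtual_fnd,
    build_virtual_fnd_parent_mix,
    collapse_to_biallelic,
    concat_tables,
    filter_nonparental_alleles,
)
from ccpevolve.io_formats import (
    GenotypeTable,
    LocusMeta,
    MarkerType,
    ValidationError,
)


def _parents(genos: dict[str, dict[str, str]], marker_type=MarkerType.SSR):
    """Homozygous parents from {parent: {locus: allele}}."""
    rows = []
    loci = sorted({l for g in genos.values() for l in g})
    labels = {l: sorted({g[l] for g in genos.values() if l in g}) for l in loci}
    for p, g in genos.items():
        for l in loci:
            rows.append((p, "PARENTS", 0, "PARENTS", l, g[l], g[l]))
    df = pd.DataFrame(rows, columns=["individual_id", "population", "generation",
                                     "location", "locus_id", "allele_a", "allele_b"])
    panel = [LocusMeta(l, marker_type, labels[l]) for l in loci]
    return GenotypeTable(df, panel)


def test_virtual_counts_proportional_to_seeds():
    parents = _parents({"A": {"L1": "1"}, "B": {"L1": "2"}, "C": {"L1": "3"}})
    scheme = CrossingScheme([("A", "B", 100), ("A", "C", 300)])
    fnd = build_virtual_fnd(scheme, parents, 10000)
    assert scheme.n_virtual == [2500, 7500]
    assert fnd.data["individual_id"].nunique() == 10000


def test_single_cross_gives_identical_heterozygotes():
    parents = _parents({"A": {"L1": "1"}, "B": {"L1": "2"}})
    scheme = CrossingScheme([("A", "B", 57)])
    fnd = build_virtual_fnd(scheme, parents, 1000)
    assert fnd.data["individual_id"].nunique() == 1000
    assert (fnd.data["allele_a"] == "1").all() and (fnd.data["allele_b"] == "2").all()
    assert (fnd.data["population"] == "FND").all()
    assert (fnd.data["generation"] == 0).all()


def test_rounding_slack_bounded_by_half_n_crosses(sim_neutral):
    scheme = sim_neutral.scheme
    fnd = build_virtual_fnd(scheme, sim_neutral.parents, 10000)
    total = sum(scheme.n_virtual)
    assert abs(total - 10000) <= scheme.n_crosses / 2
    # pre-rounding proportions are exact by construction
    exact = [s / scheme.total_seeds * 10000 for _, _, s in scheme.crosses]
    assert np.allclose(np.round(exact), scheme.n_virtual, atol=0.5 + 1e-9)


def test_heterozygous_parent_rejected_unless_overridden():
    parents = _parents({"A": {"L1": "1"}, "B": {"L1": "2"}})
    d = parents.data.copy()
    d.loc[0, "allele_b"] = "2"
    het = GenotypeTable(d, parents.panel)
    scheme = CrossingScheme([("A", "B", 10)])
    with pytest.raises(ValidationError, match="heterozygous"):
        build_virtual_fnd(scheme, het, 100)
    fnd = build_virtual_fnd(scheme, het, 100, strict_parents=False)
    assert fnd.data["individual_id"].nunique() == 100


def test_parent_missing_locus_is_an_error():
    parents = _parents({"A": {"L1": "1", "L2": "5"}, "B": {"L1": "2", "L2": "6"}})
    d = parents.data[~((parents.data["individual_id"] == "B") &
                       (parents.data["locus_id"] == "L2"))]
    broken = GenotypeTable(d.reset_index(drop=True), parents.panel)
    with pytest.raises(ValidationError, match="missing locus"):
        build_virtual_fnd(CrossingScheme([("A", "B", 10)]), broken, 100)


def test_nonparental_allele_removed_at_locus_only():
    parents = _parents({"A": {"L1": "1", "L2": "5"}, "B": {"L1": "2", "L2": "6"}})
    rows = [
        ("s1", "P1", 3, "X", "L1", "1", "Z"),   # novel Z at L1
        ("s1", "P1", 3, "X", "L2", "5", "6"),
        ("s2", "P1", 3, "X", "L1", "1", "2"),
        ("s2", "P1", 3, "X", "L2", "5", "5"),
    ]
    df = pd.DataFrame(rows, columns=["individual_id", "population", "generation",
                                     "location", "locus_id", "allele_a", "allele_b"])
    import dataclasses
    panel = [dataclasses.replace(lm,
                                 allele_labels=lm.allele_labels + (["Z"] if lm.locus_id == "L1" else []))
             for lm in parents.panel]
    table = GenotypeTable(df, panel)
    filtered, report = filter_nonparental_alleles(table, parents)
    assert report.per_locus == {"L1": 1, "L2": 0}
    assert len(filtered.data) == 3
    kept = filtered.data[filtered.data["individual_id"] == "s1"]
    assert list(kept["locus_id"]) == ["L2"]   # other locus of s1 retained


def test_no_novel_alleles_identity(sim_neutral):
    filtered, report = filter_nonparental_alleles(sim_neutral.genotypes,
                                                  sim_neutral.parents)
    assert report.total == 0   # simulator guarantee: no mutation
    assert len(filtered.data) == len(sim_neutral.genotypes.data)


def test_collapse_pools_minor_alleles():
    parents = _parents({"A": {"L1": "a"}, "B": {"L1": "b"}, "C": {"L1": "c"}})
    # FND freqs: a=0.5, b=0.3, c=0.2
    scheme = CrossingScheme([("A", "B", 60), ("A", "C", 40)])
    fnd = build_virtual_fnd(scheme, parents, 1000)
    rows = [("x1", "P1", 3, "X", "L1", "b", "c")]
    df = pd.DataFrame(rows, columns=["individual_id", "population", "generation",
                                     "location", "locus_id", "allele_a", "allele_b"])
    obs = GenotypeTable(df, parents.panel)
    coll = collapse_to_biallelic(concat_tables(fnd, obs), fnd)
    lm = coll.panel[0]
    assert lm.frequent_allele == "a"
    assert set(lm.allele_labels) == {"a", "OTHER"}
    rec = coll.data[coll.data["individual_id"] == "x1"].iloc[0]
    assert (rec["allele_a"], rec["allele_b"]) == ("OTHER", "OTHER")


def test_collapse_tie_broken_lexicographically():
    parents = _parents({"A": {"L1": "a"}, "B": {"L1": "b"}})
    fnd = build_virtual_fnd(CrossingScheme([("A", "B", 100)]), parents, 500)
    coll = collapse_to_biallelic(fnd, fnd)   # freqs a=0.5, b=0.5
    assert coll.panel[0].frequent_allele == "a"
    assert any("tie" in w for w in coll.load_report.warnings)


def test_snp_locus_passes_through_collapse():
    parents = _parents({"A": {"S1": "wt"}, "B": {"S1": "mut"}},
                       marker_type=MarkerType.SNP)
    fnd = build_virtual_fnd(CrossingScheme([("A", "B", 10)]), parents, 100)
    coll = collapse_to_biallelic(fnd, fnd)
    assert coll.panel[0].allele_labels == ["mut", "wt"] or \
        coll.panel[0].allele_labels == ["wt", "mut"]
    assert set(coll.data["allele_a"]) <= {"wt", "mut"}


def test_allele_frequencies_gene_counting():
    parents = _parents({"A": {"L1": "a"}, "B": {"L1": "b"}})
    fnd = build_virtual_fnd(CrossingScheme([("A", "B", 10)]), parents, 100)
    rows = ([(f"h{i}", "P1", 3, "X", "L1", "a", "b") for i in range(4)] +
            [(f"o{i}", "P1", 3, "X", "L1", "b", "b") for i in range(6)])
    df = pd.DataFrame(rows, columns=["individual_id", "population", "generation",
                                     "location", "locus_id", "allele_a", "allele_b"])
    obs = GenotypeTable(df, parents.panel)
    coll = collapse_to_biallelic(concat_tables(fnd, obs), fnd)
    freqs = allele_frequencies(coll)
    f_obs = freqs[freqs["population"] == "P1"].iloc[0]
    assert f_obs["p"] == pytest.approx(4 / 20)       # 4 het copies of 20
    assert f_obs["n_obs"] == 20
    f_fnd = freqs[freqs["population"] == "FND"].iloc[0]
    assert f_fnd["p"] == pytest.approx(0.5)          # F1 heterozygotes exactly


def test_frequent_allele_is_modal_in_fnd(collapsed_selected, freqs_selected):
    """Definitional invariant: p_FND of the frequent allele >= 0.5 at
    collapsed SSR loci (it beats the pooled rest only if it is modal)."""
    fnd = freqs_selected[freqs_selected["population"] == "FND"]
    ssr = {lm.locus_id for lm in collapsed_selected.panel
           if lm.marker_type == MarkerType.SSR}
    modal = fnd[fnd["locus_id"].isin(ssr)]["p"]
    # frequent allele beats every single competitor; after pooling it may
    # fall below 0.5 only when more than 2 alleles were common -- but it
    # must always beat 1/k for k original alleles (here k<=4)
    assert (modal > 0.25).all()


def test_parent_mix_equivalence_with_balanced_contributions():
    """Cross-proportional FND equals parent-proportional mixing when each
    parent contributes equally to its crosses."""
    parents = _parents({p: {"L1": a} for p, a in
                        [("A", "1"), ("B", "2"), ("C", "3"), ("D", "4")]})
    # round-robin: every parent appears in exactly 2 crosses at equal seeds
    scheme = CrossingScheme([("A", "B", 100), ("B", "C", 100),
                             ("C", "D", 100), ("D", "A", 100)])
    fnd = build_virtual_fnd(scheme, parents, 8000)
    mix = build_virtual_fnd_parent_mix(parents, {p: 1.0 for p in "ABCD"}, 8000)
    coll_a = collapse_to_biallelic(fnd, fnd)
    coll_b = collapse_to_biallelic(mix, mix)
    fa = allele_frequencies(coll_a).set_index("locus_id")["p"]
    fb = allele_frequencies(coll_b).set_index("locus_id")["p"]
    assert np.allclose(fa, fb, atol=1e-12)


def test_collapse_commutes_with_frequency(collapsed_selected, sim_selected):
    """Frequency of the frequent allele is the same computed before or
    after pooling the minor alleles."""
    import dataclasses
    from ccpevolve.founder import build_virtual_fnd as bvf

    fnd = bvf(sim_selected.scheme, sim_selected.parents, 10000)
    pre_panel = [dataclasses.replace(lm, frequent_allele=nm.frequent_allele)
                 for lm, nm in zip(fnd.panel, collapsed_selected.panel)]
    pre = GenotypeTable(fnd.data, pre_panel)
    f_pre = allele_frequencies(pre).set_index("locus_id")["p"]
    post = collapsed_selected
    f_post = allele_frequencies(post)
    f_post = f_post[f_post["population"] == "FND"].set_index("locus_id")["p"]
    assert np.allclose(f_pre.sort_index(), f_post.sort_index(), atol=1e-12)
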