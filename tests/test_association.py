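"""Mixed-model marker effects, LS-means and effect correlations.

The REML/Satterthwaite engine is checked against values frozen from
R lme4/lmerTest/emmeans fits of the identically generated fixtures.
"""

import numpy as np
import pandas as pd
import pytest

from ccpevolve._reml import fit_reml
from ccpevolve.association import (
    correlate_dp_vs_effect,
    correlate_effect_vs_effect,
    mixed_stand_effect,
    pure_stand_effect,
    pure_stand_ls_means,
)
from ccpevolve.io_formats import (
    GenotypeTable,
    LocusMeta,
    MarkerType,
    TraitTable,
    ValidationError,
)

from helpers import flip_frequent_allele


# ---------------------------------------------------------------------------
# REML engine against frozen R oracles


def _interaction_fixture():
    """Same stream as the R-fitted fixture: 6 trials, 2 classes, real
    trial and interaction variance."""
    rng = np.random.default_rng(7)
    trials = [f"T{i}" for i in range(1, 7)]
    rows = []
    t_eff = rng.normal(0, 3, 6)
    i_eff = rng.normal(0, 2.5, (6, 2))
    for ti, t in enumerate(trials):
        for cls in (0, 1):
            n = int(rng.integers(15, 40))
            y = 50 + 4.0 * cls + t_eff[ti] + i_eff[ti, cls] + rng.normal(0, 5, n)
            rows += [(t, cls, v) for v in y]
    return pd.DataFrame(rows, columns=["trial", "cls", "y"]), np.array(trials)


def test_reml_matches_lmertest_frozen_values():
    """Estimate/SE/Satterthwaite df/p frozen from lmerTest on this fixture."""
    df, trials = _interaction_fixture()
    y = df["y"].to_numpy()
    x = df["cls"].to_numpy().astype(float)
    X = np.column_stack([np.ones_like(y), x])
    zt = (df["trial"].to_numpy()[:, None] == trials[None, :]).astype(float)
    inter = [(t, j) for t in trials for j in (0, 1)]
    zi = np.array([[(a == t) and (b == j) for (t, j) in inter]
                   for a, b in zip(df["trial"], df["cls"])], dtype=float)
    fit = fit_reml(y, X, {"trial": zt, "inter": zi})
    c = np.array([0.0, 1.0])
    est, se, ddf = fit.contrast(c)
    f, _, p = fit.f_test(c)
    assert est == pytest.approx(5.192582, abs=2e-5)      # lmerTest Estimate
    assert se == pytest.approx(1.205139, rel=2e-3)       # lmerTest Std. Error
    assert ddf == pytest.approx(4.8887, rel=2e-2)        # Satterthwaite DenDF
    assert p == pytest.approx(0.008051, rel=2e-2)        # Pr(>F)
    assert fit.sigma2["residual"] == pytest.approx(22.233, rel=1e-2)


def test_ls_means_match_emmeans_frozen_values():
    rng2 = np.random.default_rng(11)
    varieties = [f"V{i:02d}" for i in range(1, 11)]
    trials = [f"J{i}" for i in range(1, 5)]
    rows = []
    veff = rng2.normal(0, 4, 10)
    teff = rng2.normal(0, 3, 4)
    vte = rng2.normal(0, 1.5, (10, 4))
    for j, t in enumerate(trials):
        beff = rng2.normal(0, 1.0, 3)
        for b in range(3):
            for i, v in enumerate(varieties):
                yv = 100 + veff[i] + teff[j] + beff[b] + vte[i, j] + rng2.normal(0, 2)
                rows.append((f"u{len(rows)}", "pure_plot", t, f"B{b + 1}", v,
                             "height", yv))
    tt = TraitTable(pd.DataFrame(rows, columns=[
        "unit_id", "stand", "trial", "replicate_block", "variety", "trait",
        "value"]))
    ls = pure_stand_ls_means(tt, "height")
    frozen = {"V01": 102.10425, "V02": 106.33299, "V03": 106.01656,
              "V04": 98.66829, "V05": 101.31257, "V06": 99.57835,
              "V07": 103.94300, "V08": 101.74035, "V09": 103.37575,
              "V10": 94.87876}                            # emmeans output
    for v, expect in frozen.items():
        assert ls[v] == pytest.approx(expect, abs=2e-3)


# ---------------------------------------------------------------------------
# marker effects on constructed tables


def _one_locus_table(class_of: dict[str, int]) -> GenotypeTable:
    rows = []
    for ind, c in class_of.items():
        allele = "A" if c == 1 else "B"
        rows.append((ind, "P1", 6, "X", "L1", allele, allele))
    df = pd.DataFrame(rows, columns=["individual_id", "population", "generation",
                                     "location", "locus_id", "allele_a", "allele_b"])
    panel = [LocusMeta("L1", MarkerType.SNP, ["A", "B"], frequent_allele="A")]
    return GenotypeTable(df, panel)


def _mixed_traits(values: dict[str, float], trial="T1", trait="height") -> pd.DataFrame:
    return pd.DataFrame({
        "unit_id": list(values), "stand": "mixed_single_plant", "trial": trial,
        "replicate_block": None, "variety": None, "trait": trait,
        "value": list(values.values())})


def test_balanced_single_trial_is_half_class_difference():
    class_of = {f"a{i}": 1 for i in range(5)} | {f"b{i}": 0 for i in range(5)}
    geno = _one_locus_table(class_of)
    vals = {f"a{i}": 90.0 + i for i in range(5)} | {f"b{i}": 80.0 + i
                                                    for i in range(5)}
    traits = TraitTable(_mixed_traits(vals))
    est = mixed_stand_effect(traits, geno, "L1", "height")
    assert est.additive_effect == pytest.approx(5.0)      # (90-80)/2
    assert est.stand == "mixed"


def test_identical_class_means_effect_zero_p_one():
    class_of = {f"a{i}": 1 for i in range(4)} | {f"b{i}": 0 for i in range(4)}
    geno = _one_locus_table(class_of)
    vals = {k: 70.0 for k in class_of}
    est = mixed_stand_effect(TraitTable(_mixed_traits(vals)), geno, "L1", "height")
    assert est.additive_effect == pytest.approx(0.0)
    assert est.p_value == pytest.approx(1.0)


def test_missing_homozygote_class_recorded_not_raised():
    class_of = {f"a{i}": 1 for i in range(6)}
    geno = _one_locus_table(class_of)
    vals = {k: 70.0 for k in class_of}
    est = mixed_stand_effect(TraitTable(_mixed_traits(vals)), geno, "L1", "height")
    assert not est.defined
    assert "class" in est.note


def test_heterozygotes_excluded_at_tested_locus_only():
    class_of = {f"a{i}": 1 for i in range(4)} | {f"b{i}": 0 for i in range(4)}
    geno = _one_locus_table(class_of)
    d = geno.data.copy()
    d.loc[d["individual_id"] == "a0", "allele_b"] = "B"   # a0 heterozygous
    geno = GenotypeTable(d, geno.panel)
    vals = {k: (85.0 if v == 1 else 75.0) for k, v in class_of.items()}
    est = mixed_stand_effect(TraitTable(_mixed_traits(vals)), geno, "L1", "height")
    assert est.n_used == 7


def test_pure_stand_recovers_noiseless_dosage_effect():
    """Variety values of exactly 2 units per allele copy: the two-stage
    estimate returns 2 to numerical precision."""
    varieties = {f"V{i}": (1 if i < 5 else 0) for i in range(10)}
    geno = _one_locus_table(varieties)
    rows = []
    for t in ("T1", "T2"):
        for b in ("B1", "B2"):
            for v, cls in varieties.items():
                rows.append((f"{v}.{t}.{b}", "pure_plot", t, b, v, "height",
                             50.0 + 2.0 * (2 * cls)))
    tt = TraitTable(pd.DataFrame(rows, columns=[
        "unit_id", "stand", "trial", "replicate_block", "variety", "trait",
        "value"]))
    est = pure_stand_effect(tt, geno, "L1", "height")
    assert est.additive_effect == pytest.approx(2.0, abs=1e-9)


def test_pure_stand_single_class_errors():
    varieties = {f"V{i}": 1 for i in range(6)}
    geno = _one_locus_table(varieties)
    rows = [(f"{v}.T1.B1", "pure_plot", "T1", "B1", v, "height", 50.0)
            for v in varieties]
    rows += [(f"{v}.T1.B2", "pure_plot", "T1", "B2", v, "height", 51.0)
             for v in varieties]
    tt = TraitTable(pd.DataFrame(rows, columns=[
        "unit_id", "stand", "trial", "replicate_block", "variety", "trait",
        "value"]))
    with pytest.raises(ValidationError, match="single class"):
        pure_stand_effect(tt, geno, "L1", "height")


def test_effect_recovery_from_simulator(sim_selected, collapsed_selected):
    """The mixed-stand estimate lands within 3 s.e. of the simulator's true
    additive effect for the Rht loci (signed for the frequent allele)."""
    from ccpevolve.io_formats import panel_by_id

    truth = {"Rht-B1": 4.0, "Rht-D1": 6.0}
    by_id = panel_by_id(collapsed_selected.panel)
    for locus, eff in truth.items():
        signed = eff if by_id[locus].frequent_allele == "wt" else -eff
        est = mixed_stand_effect(sim_selected.traits, collapsed_selected,
                                 locus, "height")
        assert est.defined
        assert abs(est.additive_effect - signed) <= 3 * est.se


# ---------------------------------------------------------------------------
# correlations


def test_correlations_trivial_identities():
    dp = {f"L{j}": 0.01 * j for j in range(10)}
    eff = {l: 3.0 * v for l, v in dp.items()}     # exactly proportional
    c = correlate_dp_vs_effect(dp, eff)
    assert c.r == pytest.approx(1.0)
    assert c.df == 8
    c2 = correlate_effect_vs_effect(eff, {l: -v for l, v in eff.items()})
    assert c2.r == pytest.approx(-1.0)
    c3 = correlate_effect_vs_effect(eff, eff)
    assert c3.r == pytest.approx(1.0)


def test_correlation_needs_three_loci():
    with pytest.raises(ValidationError):
        correlate_dp_vs_effect({"L1": 0.1, "L2": 0.2}, {"L1": 1.0, "L2": 2.0})


def test_sign_flip_antisymmetry_and_designation_invariance(
        sim_selected, collapsed_selected, freqs_selected):
    """Re-designating the frequent allele at a locus flips that locus's
    effect (and its delta-p) exactly; re-designating the whole panel leaves
    every correlation unchanged."""
    from ccpevolve.association import delta_p_vectors

    loci = [lm.locus_id for lm in collapsed_selected.panel
            if lm.marker_type == MarkerType.SNP][:6]
    geno = collapsed_selected
    flip_at = loci[0]
    flipped_table = flip_frequent_allele(geno, flip_at)
    e = mixed_stand_effect(sim_selected.traits, geno, flip_at, "height")
    ef = mixed_stand_effect(sim_selected.traits, flipped_table, flip_at, "height")
    assert ef.additive_effect == pytest.approx(-e.additive_effect, rel=1e-5)
    assert ef.p_value == pytest.approx(e.p_value, rel=1e-3)
    other = loci[1]
    eo = mixed_stand_effect(sim_selected.traits, geno, other, "height")
    eo2 = mixed_stand_effect(sim_selected.traits, flipped_table, other, "height")
    assert eo2.additive_effect == pytest.approx(eo.additive_effect)

    # whole-panel re-designation negates both vectors -> r exactly invariant
    dp = delta_p_vectors(freqs_selected, final_gen=10)["overall"]
    effects = {}
    for locus in loci:
        est = mixed_stand_effect(sim_selected.traits, geno, locus, "height")
        if est.defined:
            effects[locus] = est.additive_effect
    use = sorted(set(effects) & set(dp))
    c1 = correlate_dp_vs_effect({l: dp[l] for l in use},
                                {l: effects[l] for l in use})
    c2 = correlate_dp_vs_effect({l: -dp[l] for l in use},
                                {l: -effects[l] for l in use})
    assert c1.r == pytest.approx(c2.r, abs=1e-12)
    assert c1.p_value == pytest.approx(c2.p_value, abs=1e-12)


def test_selection_signal_appears_in_dp_effect_correlation(
        sim_selected, collapsed_selected, freqs_selected):
    """Height-effect loci under shared selection: delta-p correlates
    positively with the additive height effects."""
    from ccpevolve.association import delta_p_vectors

    dp = delta_p_vectors(freqs_selected, final_gen=10)["overall"]
    effects = {}
    for lm in collapsed_selected.panel:
        e = mixed_stand_effect(sim_selected.traits, collapsed_selected,
                               lm.locus_id, "height")
        if e.defined:
            effects[lm.locus_id] = e.additive_effect
    c = correlate_dp_vs_effect(dp, effects)
    assert c.r > 0
    assert c.p_value < 0.05
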