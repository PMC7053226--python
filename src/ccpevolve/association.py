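"""Marker-trait association in mixed and pure stands, and effect correlations.

Mixed stand (single plants inside the evolving population): for one locus
and one trait, y_ijk = mu + m_j + t_k + mt_jk + e_ijk with the allele-class
effect m_j fixed and trial, allele x trial and residual random; only
homozygous individuals at the tested locus enter, and the additive allele
effect is half the fitted frequent-homozygote minus other-homozygote
difference.  Significance is an F test with Satterthwaite denominator
degrees of freedom.

Pure stand (parent varieties in plot trials): variety LS-means are first
estimated from y_jln = mu + tr_jn + v_l + t_j + vt_lj + e_jln (variety
fixed, the rest random), then the marker effect is the fixed one-way
regression of the LS-means on allele class.

Effect-vs-frequency-change and effect-vs-effect Pearson correlations are
t-tested on df = L - 2 and reported with significance stars
(*, **, *** at 0.05, 0.01, 0.001).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._reml import fit_reml
from .io_formats import (
    MISSING,
    GenotypeTable,
    Stand,
    TraitTable,
    ValidationError,
    panel_by_id,
)
from .ne_drift import pearson_t_test, significance_stars


@dataclass
class EffectEstimate:
    locus_id: str
    trait: str
    stand: Literal["mixed", "pure"]
    additive_effect: float
    se: float
    f_stat: float
    df_num: float
    df_den: float
    p_value: float
    n_used: int
    note: str = ""

    @property
    def defined(self) -> bool:
        return np.isfinite(self.additive_effect)


@dataclass
class EffectCorrelation:
    trait: str
    scope: str
    r: float
    p_value: float
    n_loci: int

    @property
    def df(self) -> int:
        return self.n_loci - 2

    @property
    def stars(self) -> str:
        return significance_stars(self.p_value)


def _missing(locus: str, trait: str, stand: str, reason: str, n: int = 0) -> EffectEstimate:
    return EffectEstimate(locus, trait, stand, np.nan, np.nan, np.nan, 1.0,
                          np.nan, np.nan, n, note=reason)


def _homozygote_classes(genotypes: GenotypeTable, locus: str) -> pd.Series:
    """individual -> 1 (frequent homozygote) / 0 (other homozygote).

    Heterozygotes and missing calls are excluded at this locus only; the
    frequent-in-FND allele must already be recorded on the panel.
    """
    lm = panel_by_id(genotypes.panel)[locus]
    if lm.frequent_allele is None:
        raise ValidationError(f"locus {locus}: frequent allele not set; collapse first")
    d = genotypes.data[genotypes.data["locus_id"] == locus]
    hom = d[(d["allele_a"] == d["allele_b"]) & (d["allele_a"] != MISSING)]
    cls = (hom["allele_a"] == lm.frequent_allele).astype(int)
    return pd.Series(cls.to_numpy(), index=hom["individual_id"].to_numpy())


def mixed_stand_effect(traits: TraitTable, genotypes: GenotypeTable,
                       locus: str, trait: str) -> EffectEstimate:
    """Additive effect of the frequent allele from single plants in mixed stands.

    With a single trial the random terms vanish and the fit reduces to the
    fixed two-class model (the balanced case then returns exactly half the
    class-mean difference).  A missing homozygote class yields an undefined
    estimate recorded with its reason rather than an error.
    """
    cls = _homozygote_classes(genotypes, locus)
    t = traits.data
    t = t[(t["stand"] == Stand.MIXED.value) & (t["trait"] == trait)]
    t = t[t["unit_id"].isin(cls.index)]
    if t.empty:
        return _missing(locus, trait, "mixed", "no phenotyped homozygotes")
    x = cls.loc[t["unit_id"]].to_numpy()
    counts = np.bincount(x, minlength=2)
    if counts.min() < 2:
        absent = "frequent" if counts[1] < 2 else "other"
        return _missing(locus, trait, "mixed",
                        f"{absent}-homozygote class absent or <2 plants", int(len(t)))
    y = t["value"].to_numpy(dtype=float)
    trials = t["trial"].to_numpy()
    trial_levels = np.unique(trials)
    X = np.column_stack([np.ones_like(y), x.astype(float)])
    c = np.array([0.0, 1.0])
    if len(trial_levels) < 2:
        est, se, f, df_den, p = _ols_contrast(y, X, c)
    else:
        z_trial = (trials[:, None] == trial_levels[None, :]).astype(float)
        inter_levels = [(k, j) for k in trial_levels for j in (0, 1)]
        z_inter = np.array(
            [[(tr == k) and (xi == j) for (k, j) in inter_levels]
             for tr, xi in zip(trials, x)], dtype=float)
        fit = fit_reml(y, X, {"trial": z_trial, "allele_x_trial": z_inter})
        est = float(c @ fit.beta)
        se = float(np.sqrt(max(c @ fit.cov_beta @ c, 0.0)))
        f, df_den, p = fit.f_test(c)
        note = f"dropped zero-variance term(s): {','.join(fit.dropped)}" if fit.dropped else ""
        return EffectEstimate(locus, trait, "mixed", est / 2.0, se / 2.0, f, 1.0,
                              df_den, p, int(len(y)), note)
    return EffectEstimate(locus, trait, "mixed", est / 2.0, se / 2.0, f, 1.0,
                          df_den, p, int(len(y)))


def _ols_contrast(y, X, c):
    n, p = X.shape
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    df = n - p
    s2 = float(resid @ resid) / df if df > 0 else 0.0
    xtxi = np.linalg.pinv(X.T @ X)
    var = s2 * float(c @ xtxi @ c)
    est = float(c @ beta)
    se = np.sqrt(max(var, 0.0))
    scale = max(1.0, float(np.max(np.abs(y), initial=1.0)))
    if se <= 1e-10 * scale:   # zero-noise data: F-test degenerates
        if abs(est) <= 1e-8 * scale:
            return 0.0, 0.0, 0.0, float(df), 1.0
        return est, 0.0, np.inf, float(df), 0.0
    f = (est / se) ** 2
    return est, se, float(f), float(df), float(stats.f.sf(f, 1, df))


def pure_stand_ls_means(traits: TraitTable, trait: str) -> pd.Series:
    """Variety LS-means from the plot-trial mixed model (equal trial weights)."""
    t = traits.data
    t = t[(t["stand"] == Stand.PURE.value) & (t["trait"] == trait)]
    if t.empty:
        raise ValidationError(f"no pure-stand records for trait {trait!r}")
    varieties = np.array(sorted(t["variety"].unique()))
    trials = np.array(sorted(t["trial"].unique()))
    y = t["value"].to_numpy(dtype=float)
    v = t["variety"].to_numpy()
    tr = t["trial"].to_numpy()
    blk = (t["trial"].astype(str) + "/" + t["replicate_block"].astype(str)).to_numpy()
    X = (v[:, None] == varieties[None, :]).astype(float)  # cell-means coding
    z_trial = (tr[:, None] == trials[None, :]).astype(float)
    blocks = np.unique(blk)
    z_block = (blk[:, None] == blocks[None, :]).astype(float)
    vt = np.array([f"{a}|{b}" for a, b in zip(v, tr)])
    vt_levels = np.unique(vt)
    z_vt = (vt[:, None] == vt_levels[None, :]).astype(float)
    fit = fit_reml(y, X, {"trial": z_trial, "block_in_trial": z_block,
                          "variety_x_trial": z_vt})
    return pd.Series(fit.beta, index=varieties)


def pure_stand_effect(traits: TraitTable, parent_genotypes: GenotypeTable,
                      locus: str, trait: str,
                      ls_means: pd.Series | None = None) -> EffectEstimate:
    """Additive effect of the frequent allele on variety LS-means.

    Varieties heterozygous or missing at the locus are excluded; all
    varieties falling into one allele class is an error ("single class").
    Precomputed LS-means may be passed to avoid refitting per locus.
    """
    if ls_means is None:
        ls_means = pure_stand_ls_means(traits, trait)
    cls = _homozygote_classes(parent_genotypes, locus)
    shared = ls_means.index.intersection(cls.index)
    if len(shared) < 3:
        return _missing(locus, trait, "pure", "fewer than 3 genotyped varieties")
    x = cls.loc[shared].to_numpy(dtype=float)
    if len(np.unique(x)) < 2:
        raise ValidationError(f"locus {locus}: single class among varieties")
    if min((x == 0).sum(), (x == 1).sum()) < 2:
        return _missing(locus, trait, "pure", "an allele class has <2 varieties",
                        len(shared))
    y = ls_means.loc[shared].to_numpy(dtype=float)
    X = np.column_stack([np.ones_like(y), x])
    est, se, f, df, p = _ols_contrast(y, X, np.array([0.0, 1.0]))
    return EffectEstimate(locus, trait, "pure", est / 2.0, se / 2.0, f, 1.0,
                          df, p, len(shared))


def all_effects(traits: TraitTable, genotypes: GenotypeTable, *,
                parents_collapsed: GenotypeTable | None = None,
                loci: Sequence[str] | None = None,
                trait_names: Sequence[str] | None = None) -> list[EffectEstimate]:
    """Every locus x trait effect, mixed stand always, pure stand when the
    collapsed parental genotypes are supplied."""
    out: list[EffectEstimate] = []
    names = (sorted(traits.data["trait"].unique())
             if trait_names is None else list(trait_names))
    loci = list(loci) if loci is not None else genotypes.loci
    has_mixed = (traits.data["stand"] == Stand.MIXED.value).any()
    has_pure = (traits.data["stand"] == Stand.PURE.value).any()
    for trait in names:
        ls = None
        if has_pure and parents_collapsed is not None:
            ls = pure_stand_ls_means(traits, trait)
        for locus in loci:
            if has_mixed:
                out.append(mixed_stand_effect(traits, genotypes, locus, trait))
            if ls is not None:
                try:
                    out.append(pure_stand_effect(traits, parents_collapsed,
                                                 locus, trait, ls_means=ls))
                except ValidationError as exc:
                    out.append(_missing(locus, trait, "pure", str(exc)))
    return out


# ---------------------------------------------------------------------------
# correlations


def correlate_dp_vs_effect(dp: Mapping[str, float], effects: Mapping[str, float],
                           *, trait: str = "", scope: str = "overall"
                           ) -> EffectCorrelation:
    """Pearson r between per-locus frequency change and additive effects."""
    shared = sorted(set(dp) & {l for l, v in effects.items() if np.isfinite(v)})
    if len(shared) < 3:
        raise ValidationError("fewer than 3 loci with both quantities")
    x = np.array([dp[l] for l in shared])
    y = np.array([effects[l] for l in shared])
    r, p, _ = pearson_t_test(y, x)
    return EffectCorrelation(trait, scope, r, p, len(shared))


def correlate_effect_vs_effect(effects_a: Mapping[str, float],
                               effects_b: Mapping[str, float],
                               *, trait: str = "", scope: str = ""
                               ) -> EffectCorrelation:
    finite_a = {l for l, v in effects_a.items() if np.isfinite(v)}
    finite_b = {l for l, v in effects_b.items() if np.isfinite(v)}
    shared = sorted(finite_a & finite_b)
    if len(shared) < 3:
        raise ValidationError("fewer than 3 shared loci")
    a = np.array([effects_a[l] for l in shared])
    b = np.array([effects_b[l] for l in shared])
    r, p, _ = pearson_t_test(a, b)
    return EffectCorrelation(trait, scope, r, p, len(shared))


def delta_p_vectors(freqs: pd.DataFrame, final_gen: int) -> dict[str, dict[str, float]]:
    """Per-location and overall (across-location mean) frequency changes
    from FND to the final generation."""
    fnd = freqs[freqs["population"] == "FND"].set_index("locus_id")["p"]
    fin = freqs[(freqs["generation"] == final_gen) & (freqs["population"] != "FND")]
    out: dict[str, dict[str, float]] = {}
    per_loc = {}
    for loc, sub in fin.groupby("location"):
        s = sub.set_index("locus_id")["p"]
        shared = s.index.intersection(fnd.index)
        per_loc[loc] = (s.loc[shared] - fnd.loc[shared]).to_dict()
        out[loc] = per_loc[loc]
    if per_loc:
        overall = pd.DataFrame(per_loc).mean(axis=1).dropna()
        out["overall"] = overall.to_dict()
    return out


def effects_table(effects: Sequence[EffectEstimate]) -> pd.DataFrame:
    rows = [{
        "locus_id": e.locus_id, "trait": e.trait, "stand": e.stand,
        "additive_effect": e.additive_effect, "se": e.se,
        "f_stat": e.f_stat, "df_num": e.df_num, "df_den": e.df_den,
        "p_value": e.p_value, "n_used": e.n_used, "note": e.note,
    } for e in effects]
    return pd.DataFrame(rows)


def correlation_report(effects: Sequence[EffectEstimate], freqs: pd.DataFrame,
                       final_gen: int) -> pd.DataFrame:
    """The two correlation grids as one long table.

    ``dp_vs_effect`` rows: mixed-stand effects against frequency change,
    one row per trait x scope (overall + each location).  ``height_pleiotropy``
    rows: mixed- and pure-stand effects of every other trait against the
    same stand's height effects.
    """
    eff = {("mixed", e.trait): {} for e in effects if e.stand == "mixed"}
    for e in effects:
        eff.setdefault((e.stand, e.trait), {})[e.locus_id] = e.additive_effect
    dps = delta_p_vectors(freqs, final_gen)
    rows = []
    for (stand, trait), per_locus in sorted(eff.items()):
        if stand != "mixed":
            continue
        for scope, dp in sorted(dps.items()):
            try:
                c = correlate_dp_vs_effect(dp, per_locus, trait=trait, scope=scope)
            except ValidationError:
                continue
            rows.append({"table": "dp_vs_effect", "trait": trait, "stand": stand,
                         "scope": scope, "r": c.r, "p_value": c.p_value,
                         "df": c.df, "stars": c.stars})
    for stand in ("mixed", "pure"):
        height = eff.get((stand, "height"))
        if not height:
            continue
        for (st2, trait), per_locus in sorted(eff.items()):
            if st2 != stand or trait == "height":
                continue
            try:
                c = correlate_effect_vs_effect(height, per_locus,
                                               trait=trait, scope=stand)
            except ValidationError:
                continue
            rows.append({"table": "height_pleiotropy", "trait": trait,
                         "stand": stand, "scope": stand, "r": c.r,
                         "p_value": c.p_value, "df": c.df, "stars": c.stars})
    return pd.DataFrame(rows, columns=["table", "trait", "stand", "scope",
                                       "r", "p_value", "df", "stars"])
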