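"""Effective population size and drift-null bands for allele-frequency change.

Two N_e routes are provided.  The differentiation route converts an F_ST
sampled from pairs of populations that diverged t generations ago via

    N_e = t / (4 * ln(1 / (1 - F_ST)))

where the pair F_ST is the moment estimator (among-pair variance with
divisor 2 over the mean p(1-p)), whose drift expectation is ~ t/(4*N_e) --
the form under which the equation above recovers N_e.  The temporal route
uses the standardized variance of allele-frequency change between two
sampled generations (Nei-Tajima Fc, sampling plan II):

    N_e = t / (2 * (Fc - 1/(2*S_early) - 1/(2*S_late))).

The drift null band for a locus with founder frequency p_FND after t
generations at effective size N_e is

    p_FND +/- z * sqrt(p_FND*(1-p_FND) * [1 - (1 - 1/(2*N_e))^t]),

clipped to [0, 1]; observed frequencies outside the band flag selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import GenotypeTable, ValidationError
from .popgen_stats import bootstrap_ci, genotype_counts


@dataclass
class DriftModel:
    ne: float
    t: int
    p_fnd: float

    def __post_init__(self) -> None:
        if self.ne <= 0:
            raise ValidationError("Ne must be positive")
        if self.t < 1:
            raise ValidationError("t must be >= 1")
        if not 0.0 <= self.p_fnd <= 1.0:
            raise ValidationError("p_FND must lie in [0, 1]")

    @property
    def drift_variance(self) -> float:
        return self.p_fnd * (1.0 - self.p_fnd) * (
            1.0 - (1.0 - 1.0 / (2.0 * self.ne)) ** self.t
        )


@dataclass
class NeEstimate:
    method: str                     # "fst_pairs" or "temporal"
    point: float
    ci_low: float | None = None
    ci_high: float | None = None
    inputs: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# F_ST-based N_e


def ne_from_fst(fst: float, t: int,
                fst_ci: tuple[float, float] | None = None) -> NeEstimate:
    """N_e = t / (4 ln(1/(1-F_ST))); CI bounds mapped from the F_ST CI.

    The map is strictly decreasing in F_ST, so the upper F_ST bound gives
    the lower N_e bound.
    """
    if fst <= 0.0:
        raise ValidationError("non-positive differentiation: Ne undefined/infinite")
    if fst >= 1.0:
        raise ValidationError("F_ST must be < 1")
    if t < 1:
        raise ValidationError("t must be >= 1")

    def _map(f: float) -> float:
        return t / (4.0 * np.log(1.0 / (1.0 - f)))

    est = NeEstimate(method="fst_pairs", point=_map(fst), inputs={"fst": fst, "t": t})
    if fst_ci is not None:
        lo_f, hi_f = fst_ci
        est.ci_low = _map(hi_f) if hi_f < 1 else 0.0
        est.ci_high = _map(lo_f) if lo_f > 0 else np.inf
        est.inputs["fst_ci"] = (lo_f, hi_f)
    return est


def fst_pair_moment(p1: np.ndarray, p2: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """Pair-sampling moment F_ST over loci (ratio of sums).

    Per locus the among-pair variance (p1-p2)^2/4 over the heterozygosity
    p_bar(1-p_bar) of the pooled pair; multilocus value is the ratio of
    sums.  Returns (fst, numerators, denominators).
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    num = (p1 - p2) ** 2 / 4.0
    pbar = (p1 + p2) / 2.0
    den = pbar * (1.0 - pbar)
    keep = den > 0
    if not keep.any():
        raise ValidationError("all loci monomorphic in the pooled pair")
    return float(num[keep].sum() / den[keep].sum()), num, den


def ne_fst_pairs(table: GenotypeTable, t: int, *,
                 populations: Sequence[str] | None = None,
                 loci: Sequence[str] | None = None,
                 n_bootstrap: int = 0, ci_level: float = 0.95,
                 rng: np.random.Generator | None = None) -> NeEstimate:
    """Pair-sampled F_ST over all population pairs, mapped to N_e.

    The multilocus pair F_ST is averaged over the pairs and pushed through
    ne_from_fst; the CI comes from a locus bootstrap of the averaged F_ST.
    """
    pops = list(populations) if populations is not None else table.populations
    loc = list(loci) if loci is not None else table.loci
    if len(pops) < 2:
        raise ValidationError("need at least 2 populations")
    n, p, h = genotype_counts(table, pops, loc)
    pairs = list(combinations(range(len(pops)), 2))
    per_pair = []
    for i, j in pairs:
        fst, num, den = fst_pair_moment(p[i], p[j])
        per_pair.append((fst, num, den))
    fbar = float(np.mean([f for f, _, _ in per_pair]))
    est = ne_from_fst(fbar, t)
    est.inputs.update({"n_pairs": len(pairs), "populations": pops, "n_loci": len(loc)})
    if n_bootstrap:
        if rng is None:
            rng = np.random.default_rng()
        stacked = np.stack(
            [np.column_stack([num, den]) for _, num, den in per_pair]
        )  # (n_pairs, L, 2)

        def stat(a: np.ndarray) -> float:
            # a: resampled (L, n_pairs*2) -> reshape back per pair
            vals = []
            for k in range(len(pairs)):
                num, den = a[:, 2 * k], a[:, 2 * k + 1]
                if den.sum() > 0:
                    vals.append(num.sum() / den.sum())
            return float(np.mean(vals))

        flat = np.concatenate([s for s in stacked.transpose(1, 0, 2)], axis=0)
        flat = stacked.transpose(1, 0, 2).reshape(len(loc), -1)
        lo_f, hi_f = bootstrap_ci(flat, stat, n_bootstrap, ci_level, rng)
        est.ci_low = ne_from_fst(max(hi_f, 1e-12), t).point
        est.ci_high = ne_from_fst(lo_f, t).point if lo_f > 0 else np.inf
    return est


# ---------------------------------------------------------------------------
# temporal method


def temporal_fc(p_early: pd.DataFrame, p_late: pd.DataFrame,
                loci: Iterable[str] | None = None) -> float:
    """Mean Nei-Tajima Fc over shared loci.

    Per locus Fc = (x - y)^2 / ((x + y)/2 - x*y); loci fixed at the same
    frequency in both samples (x = y in {0, 1}) are 0/0 and are excluded.
    """
    e = p_early.set_index("locus_id")["p"]
    l = p_late.set_index("locus_id")["p"]
    shared = e.index.intersection(l.index)
    if loci is not None:
        shared = shared.intersection(pd.Index(loci))
    if len(shared) == 0:
        raise ValidationError("no shared loci between the two time points")
    x = e.loc[shared].to_numpy(dtype=float)
    y = l.loc[shared].to_numpy(dtype=float)
    den = (x + y) / 2.0 - x * y
    keep = den > 0
    if not keep.any():
        raise ValidationError("all loci fixed identically at both time points")
    fc = (x[keep] - y[keep]) ** 2 / den[keep]
    return float(fc.mean())


def ne_temporal(fc: float, t: int, s_early: int, s_late: int) -> NeEstimate:
    """Temporal N_e with sampling-plan-II correction for finite samples."""
    if t < 1:
        raise ValidationError("t must be >= 1")
    if s_early < 2 or s_late < 2:
        raise ValidationError("sample sizes must be >= 2")
    corrected = fc - 1.0 / (2.0 * s_early) - 1.0 / (2.0 * s_late)
    if corrected <= 0:
        raise ValidationError("drift signal below sampling noise")
    return NeEstimate(
        method="temporal", point=t / (2.0 * corrected),
        inputs={"fc": fc, "t": t, "s_early": s_early, "s_late": s_late},
    )


def ne_temporal_from_tables(freqs: pd.DataFrame, table: GenotypeTable,
                            loci: Sequence[str] | None = None) -> list[NeEstimate]:
    """Per-location temporal estimates between the first and last sampled
    generations, from an allele-frequency table (FND rows ignored)."""
    obs = freqs[freqs["population"] != "FND"]
    out: list[NeEstimate] = []
    for loc in sorted(obs["location"].unique()):
        sub = obs[obs["location"] == loc]
        gens = sorted(sub["generation"].unique())
        if len(gens) < 2:
            continue
        g0, g1 = gens[0], gens[-1]
        early = sub[sub["generation"] == g0]
        late = sub[sub["generation"] == g1]
        try:
            fc = temporal_fc(early, late, loci)
            s0 = int(early["n_obs"].median() // 2)
            s1 = int(late["n_obs"].median() // 2)
            est = ne_temporal(fc, int(g1 - g0), s0, s1)
        except ValidationError:
            continue
        est.inputs["location"] = loc
        out.append(est)
    return out


# ---------------------------------------------------------------------------
# drift bands and selection flags


def drift_ci(model: DriftModel, ci_level: float = 0.95) -> tuple[float, float]:
    """Drift-null band p_FND +/- z*sqrt(drift variance), clipped to [0, 1]."""
    if not 0.0 < ci_level < 1.0:
        raise ValidationError("ci_level must lie in (0, 1)")
    z = stats.norm.ppf(0.5 + ci_level / 2.0)
    half = z * np.sqrt(model.drift_variance)
    return (float(np.clip(model.p_fnd - half, 0.0, 1.0)),
            float(np.clip(model.p_fnd + half, 0.0, 1.0)))


@dataclass
class SelectionFlagTable:
    table: pd.DataFrame        # locus, population, generation, ne, bands, status
    consistency: pd.DataFrame  # locus, ne, status shared by all populations


def flag_selection(freqs: pd.DataFrame, *, ne_values: Sequence[float],
                   t: int | None = None, ci_level: float = 0.95,
                   panel: Sequence | None = None) -> SelectionFlagTable:
    """Classify observed frequencies against drift bands around p_FND.

    For every locus x population x N_e the sampled frequency is classified
    as below/inside/above the band after the sample's own generation count
    (or a fixed ``t``).  Loci outside the band in the same direction in all
    populations of the final generation are listed in the consistency
    summary; for annotated functional loci a toward/away-from-wild-type
    direction is attached (wild-type = first-listed allele label).
    """
    fnd = freqs[freqs["population"] == "FND"].set_index("locus_id")["p"]
    obs = freqs[freqs["population"] != "FND"]
    wt_first: dict[str, bool] = {}
    annotated: dict[str, str] = {}
    if panel is not None:
        for lm in panel:
            annotated[lm.locus_id] = lm.annotation
            if lm.frequent_allele is not None:
                wt_first[lm.locus_id] = lm.frequent_allele == lm.allele_labels[0]
    rows = []
    for row in obs.itertuples(index=False):
        if row.locus_id not in fnd.index:
            continue
        p0 = float(fnd[row.locus_id])
        gens = int(row.generation) if t is None else int(t)
        for ne in ne_values:
            lo, hi = drift_ci(DriftModel(ne=ne, t=max(gens, 1), p_fnd=p0), ci_level)
            if row.p < lo:
                status = "below"
            elif row.p > hi:
                status = "above"
            else:
                status = "inside"
            direction = ""
            if status != "inside" and annotated.get(row.locus_id):
                freq_is_wt = wt_first.get(row.locus_id)
                if freq_is_wt is not None:
                    up = status == "above"
                    toward_wt = (up and freq_is_wt) or (not up and not freq_is_wt)
                    direction = "toward_wild_type" if toward_wt else "away_from_wild_type"
            rows.append({
                "locus_id": row.locus_id, "population": row.population,
                "location": row.location, "generation": int(row.generation),
                "ne": float(ne), "p_fnd": p0, "p_obs": float(row.p),
                "band_low": lo, "band_high": hi, "status": status,
                "direction": direction,
            })
    table = pd.DataFrame(rows)
    cons_rows = []
    if len(table):
        final_gen = table["generation"].max()
        fin = table[table["generation"] == final_gen]
        for (locus, ne), sub in fin.groupby(["locus_id", "ne"]):
            statuses = set(sub["status"])
            if len(statuses) == 1 and statuses != {"inside"}:
                cons_rows.append({"locus_id": locus, "ne": ne,
                                  "status": statuses.pop(),
                                  "n_populations": len(sub)})
    return SelectionFlagTable(table, pd.DataFrame(
        cons_rows, columns=["locus_id", "ne", "status", "n_populations"]))


# ---------------------------------------------------------------------------
# delta-p correlations between locations


def pearson_t_test(x: np.ndarray, y: np.ndarray) -> tuple[float, float, int]:
    """Pearson r with the two-sided t-test on df = L - 2."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    L = len(x)
    if L < 3:
        raise ValidationError("need at least 3 loci for a correlation test")
    if np.std(x) == 0 or np.std(y) == 0:
        return np.nan, np.nan, L - 2
    r = float(np.corrcoef(x, y)[0, 1])
    df = L - 2
    if abs(r) >= 1.0:
        return r, 0.0, df
    tstat = r * np.sqrt(df / (1.0 - r * r))
    p = 2.0 * stats.t.sf(abs(tstat), df)
    return r, float(p), df


@dataclass
class DeltaPCorrelation:
    table: pd.DataFrame    # pop_a, pop_b, r, p_value, df, n_loci
    matrix: pd.DataFrame   # r above diagonal, significance stars below


def delta_p_correlation(freqs: pd.DataFrame, populations: Sequence[str]
                        ) -> DeltaPCorrelation:
    """Pearson correlation of per-locus delta-p (p_pop - p_FND) between
    population pairs, t-tested on df = L - 2 (Table-2 logic)."""
    fnd = freqs[freqs["population"] == "FND"].set_index("locus_id")["p"]
    dps: dict[str, pd.Series] = {}
    for pop in populations:
        sub = freqs[freqs["population"] == pop].set_index("locus_id")["p"]
        shared = sub.index.intersection(fnd.index)
        dps[pop] = sub.loc[shared] - fnd.loc[shared]
    rows = []
    pops = list(populations)
    m = pd.DataFrame("", index=pops, columns=pops)
    for a, b in combinations(pops, 2):
        shared = dps[a].index.intersection(dps[b].index)
        if len(shared) < 3:
            raise ValidationError("fewer than 3 shared loci")
        r, p, df = pearson_t_test(dps[a].loc[shared], dps[b].loc[shared])
        rows.append({"pop_a": a, "pop_b": b, "r": r, "p_value": p,
                     "df": df, "n_loci": len(shared)})
        m.loc[a, b] = "" if np.isnan(r) else f"{r:.2f}"
        m.loc[b, a] = significance_stars(p)
    return DeltaPCorrelation(pd.DataFrame(rows), m)


def significance_stars(p: float) -> str:
    if np.isnan(p):
        return "NA"
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def ne_table(estimates: Sequence[NeEstimate]) -> pd.DataFrame:
    rows = []
    for e in estimates:
        rows.append({
            "method": e.method,
            "location": e.inputs.get("location", "all"),
            "ne": round(e.point),
            "ne_exact": e.point,
            "ci_low": None if e.ci_low is None else round(e.ci_low),
            "ci_high": None if e.ci_high is None else round(e.ci_high),
            "fst_or_fc": e.inputs.get("fst", e.inputs.get("fc")),
            "t": e.inputs.get("t"),
        })
    return pd.DataFrame(rows)
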