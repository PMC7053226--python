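"""Gene diversity, Weir–Cockerham differentiation, locus bootstrap.

Diversity is Nei's gene diversity H_e = 1 − Σ p_k² (the expected
heterozygosity under Hardy–Weinberg equilibrium), computed per locus on the
locus's full allele set and averaged over loci.  Differentiation is the
Weir–Cockerham variance-components estimator θ for diploid data: per-locus
components a (among populations), b (among individuals within populations),
c (within individuals), with the multilocus θ the ratio of sums Σa/Σ(a+b+c).
Confidence intervals come from a percentile bootstrap over loci.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .io_formats import MISSING, GenotypeTable, ValidationError


@dataclass
class DiversityResult:
    population: str
    generation: int
    he_by_locus: dict[str, float]
    he_mean: float
    ci_low: float | None = None
    ci_high: float | None = None
    n_bootstrap: int = 0


@dataclass
class DifferentiationResult:
    scope: Literal["overall", "pair", "group_contrast"]
    populations: tuple
    loci: list[str]
    fst_by_locus: dict[str, float]
    fst_multilocus: float
    components: dict[str, tuple[float, float, float]]
    ci_low: float | None = None
    ci_high: float | None = None
    excluded_monomorphic: list[str] = field(default_factory=list)

    @property
    def label(self) -> str:
        if self.scope == "overall":
            return "overall(" + "+".join(map(str, self.populations)) + ")"
        if self.scope == "pair":
            return f"{self.populations[0]} vs {self.populations[1]}"
        g1, g2 = self.populations
        return "{" + "+".join(g1) + "} vs {" + "+".join(g2) + "}"


# ---------------------------------------------------------------------------
# gene diversity


def _locus_allele_freqs(table: GenotypeTable, population: str) -> dict[str, np.ndarray]:
    """Per locus, the allele frequency vector over non-missing calls."""
    d = table.data[table.data["population"] == population]
    out: dict[str, np.ndarray] = {}
    for locus, sub in d.groupby("locus_id", observed=True):
        calls = pd.concat([sub["allele_a"], sub["allele_b"]])
        calls = calls[calls != MISSING]
        if calls.empty:
            continue
        out[locus] = (calls.value_counts() / len(calls)).to_numpy()
    return out


def gene_diversity(table: GenotypeTable, population: str, *,
                   generation: int | None = None,
                   loci: Iterable[str] | None = None,
                   corrected: bool = False,
                   n_bootstrap: int = 0, ci_level: float = 0.95,
                   rng: np.random.Generator | None = None) -> DiversityResult:
    """H_e per locus and its mean over loci for one population sample.

    ``corrected`` applies the small-sample factor 2n/(2n−1); the default is
    the uncorrected 1 − Σp² (see the methods note).  With ``n_bootstrap`` > 0
    a percentile CI over loci is attached.
    """
    d = table.data[table.data["population"] == population]
    if generation is not None:
        d = d[d["generation"] == generation]
    if d.empty:
        raise ValidationError(f"no data for population {population!r}")
    gen = int(d["generation"].iloc[0])
    he: dict[str, float] = {}
    for locus, sub in d.groupby("locus_id", observed=True):
        if loci is not None and locus not in set(loci):
            continue
        calls = pd.concat([sub["allele_a"], sub["allele_b"]])
        calls = calls[calls != MISSING]
        n = len(calls)
        if n == 0:
            continue
        p = (calls.value_counts() / n).to_numpy()
        h = 1.0 - float(np.sum(p * p))
        if corrected and n > 1:
            h *= n / (n - 1)
        he[str(locus)] = h
    if not he:
        raise ValidationError(f"population {population!r}: zero observations at all loci")
    values = np.array(list(he.values()))
    res = DiversityResult(population, gen, he, float(values.mean()))
    if n_bootstrap:
        if rng is None:
            rng = np.random.default_rng()
        res.ci_low, res.ci_high = bootstrap_ci(values, "mean", n_bootstrap, ci_level, rng)
        res.n_bootstrap = n_bootstrap
    return res


# ---------------------------------------------------------------------------
# bootstrap over loci


def bootstrap_ci(per_locus_values: Sequence, statistic: str | Callable,
                 n_bootstrap: int, ci_level: float,
                 rng: np.random.Generator) -> tuple[float, float]:
    """Percentile bootstrap over loci.

    ``statistic`` is ``"mean"`` for a vector of per-locus values, or
    ``"ratio_of_sums"`` for an (L, 2) array of (numerator, denominator)
    pairs; a callable taking the resampled array is also accepted.
    """
    arr = np.asarray(per_locus_values, dtype=float)
    L = arr.shape[0]
    if L < 2:
        raise ValidationError("bootstrap over loci needs at least 2 loci")
    idx = rng.integers(0, L, size=(n_bootstrap, L))
    if statistic == "mean":
        stats = arr[idx].mean(axis=1)
    elif statistic == "ratio_of_sums":
        res = arr[idx]                      # (B, L, 2)
        with np.errstate(invalid="ignore", divide="ignore"):
            stats = res[:, :, 0].sum(axis=1) / res[:, :, 1].sum(axis=1)
    elif callable(statistic):
        stats = np.array([statistic(arr[row]) for row in idx])
    else:
        raise ValueError(f"unknown statistic {statistic!r}")
    stats = stats[np.isfinite(stats)]
    alpha = (1.0 - ci_level) / 2.0
    low, high = np.quantile(stats, [alpha, 1.0 - alpha])
    return float(low), float(high)


# ---------------------------------------------------------------------------
# Weir–Cockerham theta


def wc_components(n: np.ndarray, p: np.ndarray, h: np.ndarray
                  ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Weir–Cockerham (a, b, c) for biallelic diploid samples.

    Vectorized over loci: ``n`` (individuals sampled), ``p`` (reference
    allele frequency) and ``h`` (observed heterozygote proportion) all have
    shape (r, L) for r populations.  Negative component values are retained
    (estimator property).
    """
    n = np.asarray(n, dtype=float)
    p = np.asarray(p, dtype=float)
    h = np.asarray(h, dtype=float)
    r = n.shape[0]
    if r < 2:
        raise ValidationError("theta needs at least 2 populations")
    nsum = n.sum(axis=0)
    nbar = nsum / r
    nc = (nsum - (n ** 2).sum(axis=0) / nsum) / (r - 1)
    pbar = (n * p).sum(axis=0) / nsum
    s2 = (n * (p - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
    hbar = (n * h).sum(axis=0) / nsum
    a = (nbar / nc) * (
        s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
    )
    c = hbar / 2
    return a, b, c


def genotype_counts(table: GenotypeTable, populations: Sequence[str],
                    loci: Sequence[str]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(n, p, h) arrays of shape (r, L) for the biallelic reference allele."""
    from .io_formats import panel_by_id

    by_id = panel_by_id(table.panel)
    r, L = len(populations), len(loci)
    n = np.zeros((r, L))
    p = np.zeros((r, L))
    h = np.zeros((r, L))
    d = table.data
    for j, locus in enumerate(loci):
        ref = by_id[locus].frequent_allele
        if ref is None:
            ref = by_id[locus].allele_labels[0]
        dl = d[d["locus_id"] == locus]
        for i, pop in enumerate(populations):
            sub = dl[dl["population"] == pop]
            a = sub["allele_a"].to_numpy()
            b = sub["allele_b"].to_numpy()
            ok = (a != MISSING) & (b != MISSING)
            a, b = a[ok], b[ok]
            ni = len(a)
            n[i, j] = ni
            if ni:
                p[i, j] = ((a == ref).sum() + (b == ref).sum()) / (2 * ni)
                h[i, j] = (a != b).mean()
    return n, p, h


def fst_wc(table: GenotypeTable, populations: Sequence[str] | None = None,
           loci: Sequence[str] | None = None,
           scope: str = "overall") -> DifferentiationResult:
    """Multilocus and per-locus Weir–Cockerham θ for the included samples.

    Loci monomorphic across all included populations have undefined
    components and are excluded with a note on the result.
    """
    pops = list(populations) if populations is not None else table.populations
    loc = list(loci) if loci is not None else table.loci
    if len(pops) < 2:
        raise ValidationError("theta needs at least 2 populations")
    n, p, h = genotype_counts(table, pops, loc)
    if (n < 2).any():
        small = [pops[i] for i in np.argwhere(n < 2)[:, 0]]
        raise ValidationError(f"per-population sample sizes must be >= 2 (got {small[0]})")
    poly = ~(np.all(p == 0, axis=0) | np.all(p == 1, axis=0))
    excluded = [loc[j] for j in np.flatnonzero(~poly)]
    keep = np.flatnonzero(poly)
    if keep.size == 0:
        raise ValidationError("all loci monomorphic across the included populations")
    a, b, c = wc_components(n[:, keep], p[:, keep], h[:, keep])
    denom = a + b + c
    theta = np.divide(a, denom, out=np.full_like(a, np.nan), where=denom != 0)
    kept_loci = [loc[j] for j in keep]
    return DifferentiationResult(
        scope=scope,
        populations=tuple(pops),
        loci=kept_loci,
        fst_by_locus={l: float(t) for l, t in zip(kept_loci, theta)},
        fst_multilocus=float(a.sum() / denom.sum()),
        components={l: (float(x), float(y), float(z))
                    for l, x, y, z in zip(kept_loci, a, b, c)},
        excluded_monomorphic=excluded,
    )


def attach_bootstrap_ci(result: DifferentiationResult, n_bootstrap: int,
                        ci_level: float, rng: np.random.Generator) -> None:
    """Percentile CI of the ratio-of-sums θ over resampled loci, in place."""
    pairs = np.array([[a, a + b + c] for a, b, c in
                      (result.components[l] for l in result.loci)])
    result.ci_low, result.ci_high = bootstrap_ci(
        pairs, "ratio_of_sums", n_bootstrap, ci_level, rng
    )


def pairwise_and_grouped_fst(table: GenotypeTable, *, pairs="all",
                             groups: Sequence[tuple[list[str], list[str]]] = (),
                             loci: Sequence[str] | None = None,
                             n_bootstrap: int = 0, ci_level: float = 0.95,
                             rng: np.random.Generator | None = None
                             ) -> list[DifferentiationResult]:
    """θ for every population pair and every two-group contrast.

    For a contrast the populations of each group are pooled into one sample
    before the two-sample θ is computed.
    """
    from itertools import combinations

    pops = table.populations
    if pairs == "all":
        pairs = list(combinations(pops, 2))
    results: list[DifferentiationResult] = []
    for p1, p2 in pairs:
        res = fst_wc(table, [p1, p2], loci, scope="pair")
        results.append(res)
    for g1, g2 in groups:
        if len(g1) < 1 or len(g2) < 1:
            raise ValidationError("group contrast with an empty group")
        pooled = _pool_groups(table, g1, g2)
        res = fst_wc(pooled, ["G1", "G2"], loci, scope="group_contrast")
        res.populations = (tuple(g1), tuple(g2))
        results.append(res)
    if n_bootstrap:
        if rng is None:
            rng = np.random.default_rng()
        for res in results:
            attach_bootstrap_ci(res, n_bootstrap, ci_level, rng)
    return results


def _pool_groups(table: GenotypeTable, g1: Sequence[str], g2: Sequence[str]) -> GenotypeTable:
    import dataclasses as dc

    d = table.data[table.data["population"].isin(list(g1) + list(g2))].copy()
    d["population"] = np.where(d["population"].isin(list(g1)), "G1", "G2")
    # pooled samples may span generations; collapse the label to the pool's
    d["generation"] = d.groupby("population")["generation"].transform("max")
    return GenotypeTable(d.reset_index(drop=True),
                         [dc.replace(lm) for lm in table.panel])


# ---------------------------------------------------------------------------
# report shaping


def diversity_table(results: Sequence[DiversityResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append({
            "population": r.population,
            "generation": r.generation,
            "n_loci": len(r.he_by_locus),
            "He_mean": r.he_mean,
            "ci_low": r.ci_low,
            "ci_high": r.ci_high,
            "n_bootstrap": r.n_bootstrap,
        })
    return pd.DataFrame(rows)


def differentiation_table(results: Sequence[DifferentiationResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append({
            "scope": r.scope,
            "comparison": r.label,
            "n_loci": len(r.loci),
            "fst": r.fst_multilocus,
            "ci_low": r.ci_low,
            "ci_high": r.ci_high,
        })
    return pd.DataFrame(rows)


def pairwise_matrix(results: Sequence[DifferentiationResult]) -> pd.DataFrame:
    """Square matrix with θ above the diagonal and the CI below (Table-1 shape)."""
    pairs = [r for r in results if r.scope == "pair"]
    pops = sorted({p for r in pairs for p in r.populations})
    m = pd.DataFrame("", index=pops, columns=pops)
    for r in pairs:
        p1, p2 = sorted(r.populations)
        m.loc[p1, p2] = f"{r.fst_multilocus:.3f}"
        if r.ci_low is not None:
            m.loc[p2, p1] = f"({r.ci_low:.3f}-{r.ci_high:.3f})"
    return m
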