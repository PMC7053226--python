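"""FDIST-style F_ST outlier scan.

Loci under differential selection are flagged by comparing each locus's
observed Weir-Cockerham theta with a neutral null distribution simulated
under a finite island model (drift + migration among n_demes demes),
conditional on heterozygosity.  The migration rate is calibrated so the
quasi-equilibrium differentiation equals the observed neutral multilocus
theta: from the drift-migration recursion

    F' = (1-m)^2 (1 - 1/(2N)) F + 1/(2N),

the equilibrium is F* = (1/(2N)) / (1 - (1-m)^2 (1 - 1/(2N))), solved for m.
A locus is flagged when its empirical p-value (share of conditional null
loci with theta at least as large, (r+1)/(n+1) convention) falls below alpha
AND its theta exceeds the multilocus average -- the high-differentiation
tail only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .io_formats import GenotypeTable, ValidationError
from .popgen_stats import DifferentiationResult, genotype_counts, wc_components


@dataclass
class NullCloud:
    he: np.ndarray      # pooled-sample heterozygosity per simulated locus
    theta: np.ndarray   # Weir-Cockerham theta per simulated locus
    settings: dict
    a: np.ndarray | None = None    # among-population variance component
    abc: np.ndarray | None = None  # total a+b+c (for ratio-of-sums thetas)


@dataclass
class OutlierScanResult:
    table: pd.DataFrame            # locus, theta, he, p_value, flagged
    null_cloud: NullCloud
    multilocus_theta: float
    alpha: float
    widened: dict[str, float] = field(default_factory=dict)

    @property
    def flagged(self) -> list[str]:
        return list(self.table.loc[self.table["flagged"], "locus_id"])


def island_migration_rate(target_fst: float, deme_size: int) -> float:
    """Migration rate whose quasi-equilibrium differentiation is target_fst."""
    if not 0.0 < target_fst < 1.0:
        raise ValidationError("target_fst must lie in (0, 1)")
    two_n = 2.0 * deme_size
    # (1-m)^2 = (1 - 1/(2N)/F*) / (1 - 1/(2N))
    num = 1.0 - 1.0 / (two_n * target_fst)
    if num <= 0:
        raise ValidationError(
            f"target_fst={target_fst} below the drift floor 1/(2N)={1 / two_n:.4g} "
            "for this deme size; no migration rate can reach it"
        )
    sq = num / (1.0 - 1.0 / two_n)
    m = 1.0 - np.sqrt(sq)
    if not 0.0 < m <= 0.5:
        raise ValidationError(
            f"required migration rate {m:.4g} outside (0, 0.5] for "
            f"target_fst={target_fst}, deme size {deme_size}"
        )
    return float(m)


def simulate_null_fst(target_fst: float, n_sims: int, n_demes: int,
                      n_sampled_demes: int, sample_size: int,
                      rng: np.random.Generator, *, deme_size: int = 100,
                      warmup_generations: int = 50,
                      migration_rate: float | None = None) -> NullCloud:
    """Simulate (He, theta) pairs for n_sims neutral loci.

    Each locus: ancestral frequency uniform on (0.02, 0.98), all demes
    started there, warmup_generations rounds of migration (toward the
    metapopulation mean) and binomial drift of 2*deme_size gene copies;
    then sample_size diploids are sampled in n_sampled_demes demes under
    within-deme Hardy-Weinberg and (He, theta) computed with the same
    Weir-Cockerham estimator used for the observed data.
    """
    if n_sampled_demes > n_demes:
        raise ValidationError("cannot sample more demes than simulated")
    m = island_migration_rate(target_fst, deme_size) if migration_rate is None \
        else float(migration_rate)
    if not 0.0 < m <= 0.5:
        raise ValidationError("migration rate must lie in (0, 0.5]")
    two_n = 2 * deme_size
    p0 = rng.uniform(0.02, 0.98, size=n_sims)
    p = np.repeat(p0[:, None], n_demes, axis=1)  # (n_sims, n_demes)
    for _ in range(warmup_generations):
        pbar = p.mean(axis=1, keepdims=True)
        p = (1.0 - m) * p + m * pbar
        p = rng.binomial(two_n, p) / two_n
    take = rng.choice(n_demes, size=n_sampled_demes, replace=False)
    psub = p[:, take]                             # (n_sims, r)
    # multinomial genotype sampling per deme via sequential binomials
    paa = psub ** 2
    pab = 2.0 * psub * (1.0 - psub)
    n_aa = rng.binomial(sample_size, paa)
    denom = np.clip(1.0 - paa, 1e-12, None)
    n_ab = rng.binomial(sample_size - n_aa, np.clip(pab / denom, 0.0, 1.0))
    phat = (2 * n_aa + n_ab) / (2.0 * sample_size)  # (n_sims, r)
    hhat = n_ab / sample_size
    r = n_sampled_demes
    n = np.full((r, n_sims), float(sample_size))
    a, b, c = wc_components(n, phat.T, hhat.T)
    denom_abc = a + b + c
    theta = np.divide(a, denom_abc, out=np.zeros_like(a), where=denom_abc != 0)
    pbar_s = phat.mean(axis=1)
    he = 2.0 * pbar_s * (1.0 - pbar_s)
    keep = denom_abc != 0
    return NullCloud(
        he=he[keep], theta=theta[keep], a=a[keep], abc=denom_abc[keep],
        settings={"target_fst": target_fst, "migration_rate": m,
                  "n_sims": n_sims, "n_demes": n_demes,
                  "n_sampled_demes": n_sampled_demes,
                  "deme_size": deme_size, "sample_size": sample_size,
                  "warmup_generations": warmup_generations},
    )


def pooled_heterozygosity(table: GenotypeTable, populations: Sequence[str],
                          loci: Sequence[str]) -> dict[str, float]:
    """He = 2*pbar*(1-pbar) of the biallelic reference allele pooled over
    the included samples (the conditioning axis of the scan)."""
    n, p, _ = genotype_counts(table, populations, loci)
    nsum = n.sum(axis=0)
    pbar = (n * p).sum(axis=0) / np.where(nsum > 0, nsum, 1)
    return {l: float(2 * pb * (1 - pb)) for l, pb in zip(loci, pbar)}


def outlier_pvalues(observed: DifferentiationResult,
                    genotypes: "GenotypeTable | dict[str, float]",
                    null_cloud: NullCloud, *, he_window: float = 0.05,
                    alpha: float = 0.05, min_window_points: int = 100
                    ) -> OutlierScanResult:
    """Conditional empirical p-values and the selection flags.

    Per locus, p = share of null loci with He within +/-he_window of the
    observed He having theta >= the observed theta ((r+1)/(n+1)
    convention).  Windows holding fewer than min_window_points null loci
    are widened stepwise (logged).  Flag rule: p < alpha and theta above
    the multilocus value.
    """
    if he_window <= 0:
        raise ValidationError("he_window must be positive")
    if null_cloud.theta.size == 0:
        raise ValidationError("empty null cloud")
    if isinstance(genotypes, GenotypeTable):
        he_obs = pooled_heterozygosity(
            genotypes,
            list(observed.populations) if observed.scope != "group_contrast"
            else [p for g in observed.populations for p in g],
            observed.loci)
    else:
        he_obs = dict(genotypes)   # precomputed locus -> He
    rows = []
    widened: dict[str, float] = {}
    for locus in observed.loci:
        th = observed.fst_by_locus[locus]
        he = he_obs[locus]
        w = he_window
        while True:
            mask = np.abs(null_cloud.he - he) <= w
            if mask.sum() >= min_window_points or w >= 1.0:
                break
            w += he_window
        if w > he_window:
            widened[locus] = w
        sub = null_cloud.theta[mask]
        r_ge = int((sub >= th).sum())
        p = (r_ge + 1.0) / (sub.size + 1.0)
        rows.append({"locus_id": locus, "theta": th, "he": he,
                     "p_value": p, "n_null_window": int(sub.size)})
    table = pd.DataFrame(rows)
    table["flagged"] = (table["p_value"] < alpha) & \
                       (table["theta"] > observed.fst_multilocus)
    return OutlierScanResult(table=table, null_cloud=null_cloud,
                             multilocus_theta=observed.fst_multilocus,
                             alpha=alpha, widened=widened)


def loci_for_ne(scan: OutlierScanResult) -> list[str]:
    """The putatively neutral loci (everything not flagged) for N_e work."""
    flagged = set(scan.flagged)
    neutral = [l for l in scan.table["locus_id"] if l not in flagged]
    if not neutral:
        raise ValidationError("all loci flagged as outliers; no neutral loci left")
    return neutral


def scan_table(scan: OutlierScanResult) -> pd.DataFrame:
    t = scan.table.copy()
    t["multilocus_theta"] = scan.multilocus_theta
    t["alpha"] = scan.alpha
    return t
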