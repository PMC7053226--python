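"""Shared test utilities: independent oracles and small table builders."""

from __future__ import annotations

import numpy as np
import pandas as pd

from ccpevolve.io_formats import GenotypeTable, LocusMeta, MarkerType


def wc_theta_anova_oracle(pop_counts: list[tuple[int, int, int]]) -> float:
    """Weir-Cockerham theta via the nested gene-copy ANOVA route.

    Independent of the package's closed-form component expressions: builds
    the raw 0/1 allele indicators for every gene copy, computes the
    population / individual-within-population / within-individual mean
    squares with explicit loops, and assembles a, b, c from the mean
    squares.  ``pop_counts``: per population (n_AA, n_Aa, n_aa).
    """
    pops = []
    for n_aa, n_ab, n_bb in pop_counts:
        inds = [(1, 1)] * n_aa + [(1, 0)] * n_ab + [(0, 0)] * n_bb
        pops.append(inds)
    r = len(pops)
    n = [len(p) for p in pops]
    nsum = sum(n)
    xbar_pop = [sum(a + b for a, b in p) / (2 * len(p)) for p in pops]
    xbar = sum(a + b for p in pops for a, b in p) / (2 * nsum)

    ssg = sum((a - (a + b) / 2) ** 2 + (b - (a + b) / 2) ** 2
              for p in pops for a, b in p)
    msg = ssg / nsum
    ssi = sum(2 * ((a + b) / 2 - xbar_pop[i]) ** 2
              for i, p in enumerate(pops) for a, b in p)
    msi = ssi / (nsum - r)
    ssp = sum(2 * n[i] * (xbar_pop[i] - xbar) ** 2 for i in range(r))
    msp = ssp / (r - 1)

    nc = (nsum - sum(v * v for v in n) / nsum) / (r - 1)
    a = (msp - msi) / (2 * nc)
    b = (msi - msg) / 2
    c = msg
    return a / (a + b + c)


def genotypes_from_counts(pop_counts: dict[str, tuple[int, int, int]],
                          locus: str = "L1") -> GenotypeTable:
    """One-locus table with the given (AA, Aa, aa) counts per population."""
    rows = []
    for pop, (n_aa, n_ab, n_bb) in pop_counts.items():
        k = 0
        for cnt, (x, y) in [(n_aa, ("A", "A")), (n_ab, ("A", "B")),
                            (n_bb, ("B", "B"))]:
            for _ in range(cnt):
                k += 1
                rows.append((f"{pop}_{k:03d}", pop, 1, pop, locus, x, y))
    df = pd.DataFrame(rows, columns=["individual_id", "population", "generation",
                                     "location", "locus_id", "allele_a", "allele_b"])
    panel = [LocusMeta(locus, MarkerType.SNP, ["A", "B"], frequent_allele="A")]
    return GenotypeTable(df, panel)


def table_from_freqs(freq_by_pop: dict[str, list[float]], n_ind: int,
                     rng: np.random.Generator, f_is: float = 0.0) -> GenotypeTable:
    """Multi-locus biallelic samples drawn at the given frequencies."""
    n_loci = len(next(iter(freq_by_pop.values())))
    loci = [f"L{j + 1:02d}" for j in range(n_loci)]
    rows = []
    for pop, freqs in freq_by_pop.items():
        for i in range(n_ind):
            ind = f"{pop}_{i + 1:04d}"
            for j, p in enumerate(freqs):
                if rng.random() < f_is:       # inbred: one gene copy doubled
                    a = b = "A" if rng.random() < p else "B"
                else:
                    a = "A" if rng.random() < p else "B"
                    b = "A" if rng.random() < p else "B"
                rows.append((ind, pop, 1, pop, loci[j], a, b))
    df = pd.DataFrame(rows, columns=["individual_id", "population", "generation",
                                     "location", "locus_id", "allele_a", "allele_b"])
    panel = [LocusMeta(l, MarkerType.SNP, ["A", "B"], frequent_allele="A")
             for l in loci]
    return GenotypeTable(df, panel)


def flip_frequent_allele(table: GenotypeTable, locus: str) -> GenotypeTable:
    """Designate the other allele as 'frequent' at one biallelic locus."""
    import dataclasses

    panel = []
    for lm in table.panel:
        if lm.locus_id == locus:
            other = [a for a in lm.allele_labels if a != lm.frequent_allele][0]
            panel.append(dataclasses.replace(lm, frequent_allele=other))
        else:
            panel.append(dataclasses.replace(lm))
    return GenotypeTable(table.data.copy(), panel)
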