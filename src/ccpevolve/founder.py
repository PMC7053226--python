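"""Virtual founding population (FND) and marker recoding.

The seed of the analysis chain: because no seed of the original pooled
founding population is kept, FND is reconstructed *in silico* by stacking the
F1-heterozygote genotype of every cross in proportion to its recorded seed
count, n_ij = round(s_ij / sum(s_ij) * virtual_pop_size).  All downstream
frequency work is phrased relative to the allele that is most frequent in
FND, after SSR loci are collapsed to two alleles (frequent vs. pooled OTHER).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import (
    MISSING,
    GenotypeTable,
    LocusMeta,
    MarkerType,
    ValidationError,
    panel_by_id,
)

OTHER = "OTHER"


@dataclass
class CrossingScheme:
    """Unordered parent pairs with per-cross F2 seed counts s_ij."""

    crosses: list[tuple[str, str, int]]
    warnings: list[str] = field(default_factory=list)
    n_virtual: list[int] | None = None  # filled by build_virtual_fnd

    def __post_init__(self) -> None:
        seen = set()
        for pi, pj, s in self.crosses:
            if s < 1:
                raise ValidationError(f"cross {pi}x{pj}: non-positive seed count {s}")
            key = tuple(sorted((pi, pj)))
            if key in seen:
                raise ValidationError(f"duplicate cross after merging: {pi}x{pj}")
            seen.add(key)

    @property
    def n_crosses(self) -> int:
        return len(self.crosses)

    @property
    def total_seeds(self) -> int:
        return sum(s for _, _, s in self.crosses)

    def write(self, path) -> None:
        pd.DataFrame(
            self.crosses, columns=["parent_i", "parent_j", "seed_count"]
        ).to_csv(path, sep="\t", index=False)


@dataclass
class RemovalReport:
    """Per-locus counts of genotype records dropped as non-parental."""

    per_locus: dict[str, int] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return sum(self.per_locus.values())


def _parent_alleles(parents: GenotypeTable, strict: bool = True) -> dict[tuple[str, str], str]:
    """Map (parent, locus) -> the single homozygous allele.

    Parents are fixed inbred lines; a heterozygous parental call is an error
    unless ``strict`` is off, in which case the first-listed allele is used.
    """
    out: dict[tuple[str, str], str] = {}
    for row in parents.data.itertuples(index=False):
        a, b = row.allele_a, row.allele_b
        if MISSING in (a, b):
            continue
        if a != b:
            if strict:
                raise ValidationError(
                    f"parent {row.individual_id} heterozygous at {row.locus_id} "
                    f"({a}/{b}); parents are expected to be fixed lines"
                )
            b = a
        out[(row.individual_id, row.locus_id)] = a
    return out


def build_virtual_fnd(scheme: CrossingScheme, parents: GenotypeTable,
                      virtual_pop_size: int = 10000, *,
                      strict_parents: bool = True) -> GenotypeTable:
    """Stack n_ij copies of each cross's F1 heterozygote into FND.

    n_ij is rounded half-to-even to the nearest integer and recorded back on
    the scheme; the total may therefore miss virtual_pop_size by at most
    n_crosses/2.  The returned population is labeled FND, generation 0.
    """
    lookup = _parent_alleles(parents, strict=strict_parents)
    loci = parents.loci
    total = scheme.total_seeds
    n_ij = [int(np.round(s / total * virtual_pop_size)) for _, _, s in scheme.crosses]
    if sum(n_ij) == 0:
        raise ValidationError("degenerate scheme: all virtual counts round to zero")
    scheme.n_virtual = n_ij

    rows = []
    k = 0
    for (pi, pj, _), n in zip(scheme.crosses, n_ij):
        for locus in loci:
            if (pi, locus) not in lookup or (pj, locus) not in lookup:
                missing_parent = pi if (pi, locus) not in lookup else pj
                raise ValidationError(f"parent {missing_parent} missing locus {locus}")
        for _ in range(n):
            k += 1
            ind = f"FND_{k:05d}"
            for locus in loci:
                rows.append((ind, "FND", 0, "FND", locus,
                             lookup[(pi, locus)], lookup[(pj, locus)]))
    df = pd.DataFrame(rows, columns=["individual_id", "population", "generation",
                                     "location", "locus_id", "allele_a", "allele_b"])
    return GenotypeTable(df, [dataclasses.replace(lm) for lm in parents.panel])


def build_virtual_fnd_parent_mix(parents: GenotypeTable,
                                 parent_weights: Mapping[str, float],
                                 virtual_pop_size: int = 10000) -> GenotypeTable:
    """Comparison variant: mix parental genotypes proportionally (no crosses).

    n_i = round(s_i / sum(s_i) * virtual_pop_size) homozygous copies of each
    parent.  With each parent contributing equally to its crosses this yields
    the same allele frequencies as the cross-based construction.
    """
    lookup = _parent_alleles(parents)
    loci = parents.loci
    total = float(sum(parent_weights.values()))
    rows = []
    k = 0
    for parent, w in parent_weights.items():
        n = int(np.round(w / total * virtual_pop_size))
        for _ in range(n):
            k += 1
            ind = f"FNDP_{k:05d}"
            for locus in loci:
                a = lookup[(parent, locus)]
                rows.append((ind, "FND", 0, "FND", locus, a, a))
    df = pd.DataFrame(rows, columns=["individual_id", "population", "generation",
                                     "location", "locus_id", "allele_a", "allele_b"])
    return GenotypeTable(df, [dataclasses.replace(lm) for lm in parents.panel])


def filter_nonparental_alleles(genotypes: GenotypeTable, parents: GenotypeTable
                               ) -> tuple[GenotypeTable, RemovalReport]:
    """Drop genotype records carrying alleles absent from the parental set.

    Novel alleles arise from mutation or migration (pollen/seed contamination)
    and are treated as unbiased noise: the individual's record at the affected
    locus is removed, its other loci are retained.
    """
    parental: dict[str, set[str]] = {}
    for row in parents.data.itertuples(index=False):
        s = parental.setdefault(row.locus_id, set())
        for a in (row.allele_a, row.allele_b):
            if a != MISSING:
                s.add(a)
    d = genotypes.data
    ok_a = [
        (a == MISSING or a in parental.get(loc, set())) and
        (b == MISSING or b in parental.get(loc, set()))
        for a, b, loc in zip(d["allele_a"], d["allele_b"], d["locus_id"])
    ]
    keep = np.asarray(ok_a, dtype=bool)
    report = RemovalReport()
    removed = d.loc[~keep]
    for locus, n in removed.groupby("locus_id", observed=True).size().items():
        report.per_locus[str(locus)] = int(n)
    for lm in genotypes.panel:
        report.per_locus.setdefault(lm.locus_id, 0)
    panel = []
    for lm in genotypes.panel:
        kept = [a for a in lm.allele_labels if a in parental.get(lm.locus_id, set())]
        panel.append(dataclasses.replace(lm, allele_labels=kept or lm.allele_labels))
    return GenotypeTable(d.loc[keep].reset_index(drop=True), panel), report


def _fnd_frequent_allele(fnd: GenotypeTable, locus: str) -> tuple[str, bool]:
    """Most frequent allele in FND at a locus; lexicographic on ties."""
    sub = fnd.data[fnd.data["locus_id"] == locus]
    calls = pd.concat([sub["allele_a"], sub["allele_b"]])
    calls = calls[calls != MISSING]
    if calls.empty:
        raise ValidationError(f"locus {locus}: no FND calls to rank alleles")
    counts = calls.value_counts()
    top = counts.max()
    tied = sorted(counts[counts == top].index)
    return tied[0], len(tied) > 1


def collapse_to_biallelic(genotypes: GenotypeTable, fnd: GenotypeTable) -> GenotypeTable:
    """Recode every SSR locus to {frequent-in-FND, OTHER}.

    The frequent allele is fixed once on FND and the same recoding map is
    applied to all populations and generations; SNP loci pass through with
    their frequent allele recorded but labels unchanged.  Ties for the most
    frequent allele are broken lexicographically (logged on the table's
    load report).
    """
    recoding: dict[str, str] = {}
    tie_log: list[str] = []
    by_id = panel_by_id(genotypes.panel)
    for lm in genotypes.panel:
        freq, tied = _fnd_frequent_allele(fnd, lm.locus_id)
        recoding[lm.locus_id] = freq
        if tied:
            tie_log.append(f"locus {lm.locus_id}: frequency tie resolved to {freq!r}")
    out = apply_recoding(genotypes, recoding)
    out.load_report.warnings.extend(tie_log)
    return out


def apply_recoding(genotypes: GenotypeTable, recoding: Mapping[str, str]) -> GenotypeTable:
    """Apply a fixed locus -> frequent-allele map (SSR pooling to OTHER)."""
    d = genotypes.data.copy()
    panel = []
    for lm in genotypes.panel:
        freq = recoding.get(lm.locus_id)
        if freq is None:
            panel.append(dataclasses.replace(lm))
            continue
        if lm.marker_type is MarkerType.SSR:
            mask = d["locus_id"] == lm.locus_id
            for col in ("allele_a", "allele_b"):
                vals = d.loc[mask, col]
                d.loc[mask, col] = np.where(
                    (vals == freq) | (vals == MISSING), vals, OTHER
                )
            labels = [freq, OTHER]
        else:
            labels = list(lm.allele_labels)
        panel.append(dataclasses.replace(lm, allele_labels=labels, frequent_allele=freq))
    return GenotypeTable(d, panel)


def allele_frequencies(genotypes: GenotypeTable) -> pd.DataFrame:
    """Frequency of the frequent-in-FND allele per population x locus.

    Gene counting on non-missing calls only (complete-case per locus):
    p = frequent copies / (2 x non-missing individuals).  Returns columns
    population, generation, location, locus_id, p, n_obs (gene copies).
    Requires the recoding (frequent_allele) to be set on the panel.
    """
    rows = []
    by_id = panel_by_id(genotypes.panel)
    d = genotypes.data
    for (pop, locus), sub in d.groupby(["population", "locus_id"], observed=True):
        lm = by_id[locus]
        if lm.frequent_allele is None:
            raise ValidationError(f"locus {locus}: frequent allele not set; collapse first")
        a = sub["allele_a"].to_numpy()
        b = sub["allele_b"].to_numpy()
        ok = (a != MISSING) & (b != MISSING)
        n_obs = 2 * int(ok.sum())
        if n_obs == 0:
            continue
        count = int((a[ok] == lm.frequent_allele).sum() + (b[ok] == lm.frequent_allele).sum())
        rows.append({
            "population": pop,
            "generation": int(sub["generation"].iloc[0]),
            "location": sub["location"].iloc[0],
            "locus_id": locus,
            "p": count / n_obs,
            "n_obs": n_obs,
        })
    return pd.DataFrame(rows, columns=["population", "generation", "location",
                                       "locus_id", "p", "n_obs"])


def concat_tables(*tables: GenotypeTable) -> GenotypeTable:
    """Stack genotype tables sharing a panel (e.g. FND plus field samples)."""
    base = tables[0]
    frames = [t.data for t in tables]
    return GenotypeTable(pd.concat(frames, ignore_index=True),
                         [dataclasses.replace(lm) for lm in base.panel])
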