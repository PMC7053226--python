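"""Forward-time simulator of composite cross populations (CCPs).

Emulates the study system: ~20 fully homozygous parent varieties crossed in
~93 unequal-seed-count crosses, the pooled F2 sown at several locations, and
each location's population re-sown for 10 generations as a predominantly
selfing diploid with a large census but a much smaller effective size.

Effective size is imposed directly so that parameter-recovery tests have a
known truth: each generation, m = round(target_Ne * (1 + F)) parent slots are
drawn with replacement (fecundity-weighted when selection coefficients are
set) and given equal offspring numbers, where F is the census inbreeding
coefficient.  Sampling whole individuals from a partially inbred population
inflates drift by (1 + F); the correction keeps the per-generation variance
of allele frequency at p(1-p)/(2*target_Ne) for any selfing rate.

No mutation and no migration: an allele absent from the parents never
appears, matching the analysis assumption that novel alleles are removable
noise.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import (
    GenotypeTable,
    LocusMeta,
    MarkerType,
    Stand,
    TraitTable,
    ValidationError,
)

# The SSR panel: marker name -> number of loci it amplifies (two markers
# each produce two loci, so 18 markers yield 20 loci); values are the locus
# ids used in reports.
DEFAULT_SSR_MARKERS: dict[str, tuple[str, ...]] = {
    "gwm44": ("gwm44-7D", "gwm44-7A"),
    "gwm46": ("gwm46-7B",),
    "gwm165": ("gwm165-4B", "gwm165-4D"),
    "gwm186": ("gwm186-5A",),
    "gwm190": ("gwm190",),
    "gwm213": ("gwm213",),
    "gwm234": ("gwm234",),
    "gwm325": ("gwm325-6D",),
    "gwm337": ("gwm337",),
    "gwm469": ("gwm469",),
    "gwm539": ("gwm539-2D",),
    "gwm583": ("gwm583",),
    "gwm610": ("gwm610",),
    "gwm626": ("gwm626",),
    "psp3100": ("psp3100",),
    "psp3103": ("psp3103",),
    "wmc56": ("wmc56",),
    "barc134": ("barc134",),
}

# Functional (gene-diagnostic) biallelic loci; first label is the wild-type
# allele, the second the modern mutant/introgressed allele.
DEFAULT_SNP_LOCI: dict[str, str] = {
    "Rht-B1": "plant height (wild-type = tall)",
    "Rht-D1": "plant height (wild-type = tall)",
    "Vrn-A1": "vernalization requirement",
    "Ppd-A1": "photoperiod response (wild-type = sensitive)",
    "Ppd-B1": "photoperiod response (wild-type = sensitive)",
    "Ppd-D1": "photoperiod response (wild-type = sensitive)",
    "Ppd-D1-D2": "photoperiod response",
    "1B.1R": "rye chromosome-arm translocation (wild-type = absent)",
}

WT, MUT = "wt", "mut"


def expand_marker_loci(markers: Mapping[str, Sequence[str]]) -> list[str]:
    """Flatten a marker -> locus-ids map to the locus list (panel bookkeeping)."""
    out: list[str] = []
    for ids in markers.values():
        out.extend(ids)
    return out


@dataclass
class TraitSpec:
    """Additive genetic architecture of one trait.

    ``effects`` maps locus id to the effect (trait units) of one copy of the
    locus's first-listed allele (the wild-type allele at functional loci).
    """

    mu: float
    effects: dict[str, float]
    resid_sd: float
    trial_sd: float
    block_sd: float | None = None      # pure-stand block-in-trial; default trial_sd/2
    plot_resid_sd: float | None = None  # pure-stand plot residual; default resid_sd/2

    def __post_init__(self) -> None:
        if self.block_sd is None:
            self.block_sd = self.trial_sd / 2.0
        if self.plot_resid_sd is None:
            self.plot_resid_sd = self.resid_sd / 2.0


def default_trait_model() -> dict[str, TraitSpec]:
    # Height in cm: the two Rht wild-type (tall) alleles add ~5-6 cm per
    # copy, Ppd-D1 wild-type a smaller pleiotropic increase.  Heading date
    # in days: photoperiod-sensitive (wild-type) alleles delay heading.
    return {
        "height": TraitSpec(
            mu=95.0,
            effects={"Rht-B1": 5.0, "Rht-D1": 6.0, "Ppd-D1": 2.0},
            resid_sd=10.0, trial_sd=5.0,
        ),
        "heading": TraitSpec(
            mu=155.0,
            effects={"Ppd-D1": 3.0, "Ppd-B1": 1.5},
            resid_sd=4.0, trial_sd=3.0,
        ),
    }


def height_selection(scale: float = 1.0) -> dict[str, float]:
    """Shared directional selection on the height/phenology wild-type alleles."""
    return {"Rht-B1": 0.12 * scale, "Rht-D1": 0.15 * scale, "Ppd-D1": 0.08 * scale}


@dataclass
class SimParams:
    n_parents: int = 20
    n_crosses: int = 93
    seed_count_mean: float = 957.0
    seed_count_min: int = 37
    seed_count_max: int = 2569
    n_loci_ssr: int = 20
    n_loci_snp: int = 8
    alleles_per_ssr: int = 4
    census_size: int = 32000
    target_ne: int = 200
    selfing_rate: float = 0.98
    selection_coefficients: dict[str, float] = field(default_factory=dict)
    trait_model: dict[str, TraitSpec] = field(default_factory=default_trait_model)
    locations: tuple[str, ...] = ("MET", "MOR", "SOF", "WAF")
    organic_locations: tuple[str, ...] = ("SOF", "WAF")
    n_generations: int = 10
    sample_sizes: dict[int, int] = field(default_factory=lambda: {3: 150, 6: 250, 10: 500})
    phenotyped_generations: tuple[int, ...] = (6, 10)
    pure_stand_years: int = 3
    pure_stand_replicates: int = 3

    def __post_init__(self) -> None:
        if not 0.0 <= self.selfing_rate <= 1.0:
            raise ValidationError("selfing_rate must lie in [0, 1]")
        if self.target_ne > self.census_size:
            raise ValidationError("target_ne cannot exceed census_size")
        if self.alleles_per_ssr < 2:
            raise ValidationError("alleles_per_ssr must be >= 2")
        max_pairs = self.n_parents * (self.n_parents - 1) // 2
        if self.n_crosses > max_pairs:
            raise ValidationError(
                f"n_crosses={self.n_crosses} exceeds the {max_pairs} distinct pairs "
                f"of {self.n_parents} parents"
            )


@dataclass
class SimOutput:
    genotypes: GenotypeTable       # sampled individuals, all populations
    parents: GenotypeTable
    scheme: object                 # founder.CrossingScheme
    traits: TraitTable | None
    truth: pd.DataFrame            # location, generation, locus_id, allele, p
    parent_counts: pd.DataFrame    # location, generation, m_parents, f_hat
    params: SimParams


# ---------------------------------------------------------------------------
# panel and parents


def build_panel(params: SimParams) -> list[LocusMeta]:
    """Marker panel: the named study panel at default sizes, generic otherwise."""
    panel: list[LocusMeta] = []
    if params.n_loci_ssr == len(expand_marker_loci(DEFAULT_SSR_MARKERS)):
        ssr_ids = expand_marker_loci(DEFAULT_SSR_MARKERS)
    else:
        ssr_ids = [f"ssr{i + 1:02d}" for i in range(params.n_loci_ssr)]
    for i, locus_id in enumerate(ssr_ids):
        base = 120 + 7 * i
        labels = [str(base + 2 * k) for k in range(params.alleles_per_ssr)]
        panel.append(LocusMeta(locus_id, MarkerType.SSR, labels))
    if params.n_loci_snp == len(DEFAULT_SNP_LOCI):
        snp_items = list(DEFAULT_SNP_LOCI.items())
    else:
        snp_items = [(f"snp{i + 1:02d}", "") for i in range(params.n_loci_snp)]
    for locus_id, annot in snp_items:
        panel.append(LocusMeta(locus_id, MarkerType.SNP, [WT, MUT], annotation=annot))
    return panel


def make_parents(params: SimParams, rng: np.random.Generator) -> GenotypeTable:
    """Fully homozygous parental genotypes with every locus segregating.

    SSR allele frequencies among parents are Dirichlet-drawn; SNP mutant
    alleles are common (U(0.3, 0.8)) as in modern variety panels.
    """
    panel = build_panel(params)
    names = [f"P{i + 1:02d}" for i in range(params.n_parents)]
    rows = []
    for lm in panel:
        K = len(lm.allele_labels)
        for _ in range(200):
            if lm.marker_type is MarkerType.SSR:
                freqs = rng.dirichlet(np.full(K, 1.2))
            else:
                f_mut = rng.uniform(0.3, 0.8)
                freqs = np.array([1 - f_mut, f_mut])
            draws = rng.choice(K, size=params.n_parents, p=freqs)
            if len(np.unique(draws)) >= 2:
                break
        else:
            raise ValidationError(f"could not make locus {lm.locus_id} segregate")
        for name, k in zip(names, draws):
            a = lm.allele_labels[k]
            rows.append((name, "PARENTS", 0, "PARENTS", lm.locus_id, a, a))
    df = pd.DataFrame(rows, columns=["individual_id", "population", "generation",
                                     "location", "locus_id", "allele_a", "allele_b"])
    return GenotypeTable(df, panel)


def make_crossing_scheme(params: SimParams, rng: np.random.Generator):
    """Distinct unordered parent pairs with seed counts in the study's range.

    Counts are Beta-distributed on [seed_count_min, seed_count_max] with the
    Beta parameters placed so the expected count equals seed_count_mean; the
    realized mean is forced within 10% of the target by redrawing.
    """
    from .founder import CrossingScheme

    names = [f"P{i + 1:02d}" for i in range(params.n_parents)]
    all_pairs = list(combinations(names, 2))
    idx = rng.choice(len(all_pairs), size=params.n_crosses, replace=False)
    lo, hi = params.seed_count_min, params.seed_count_max
    if not lo <= params.seed_count_mean <= hi:
        raise ValidationError("seed_count_mean outside [min, max]")
    span = hi - lo
    if span == 0:
        counts = np.full(params.n_crosses, lo)
    else:
        frac = (params.seed_count_mean - lo) / span
        a = 1.2
        b = a * (1.0 / frac - 1.0) if 0 < frac < 1 else 1.0
        for _ in range(100):
            draw = lo + span * rng.beta(a, max(b, 1e-3), size=params.n_crosses)
            counts = np.clip(np.round(draw), lo, hi).astype(int)
            if abs(counts.mean() - params.seed_count_mean) <= 0.1 * params.seed_count_mean:
                break
        else:
            raise ValidationError("could not match the target mean seed count")
    crosses = [(all_pairs[i][0], all_pairs[i][1], int(c)) for i, c in zip(idx, counts)]
    return CrossingScheme(crosses=crosses)


# ---------------------------------------------------------------------------
# forward simulation


def _parent_matrix(parents: GenotypeTable) -> tuple[np.ndarray, list[str], list[list[str]]]:
    """(n_parents, L) allele-index matrix plus locus ids and label lists."""
    loci = parents.loci
    label_lists = [lm.allele_labels for lm in parents.panel]
    index = {lm.locus_id: {a: k for k, a in enumerate(lm.allele_labels)}
             for lm in parents.panel}
    names = sorted(parents.data["individual_id"].unique())
    mat = np.zeros((len(names), len(loci)), dtype=np.int16)
    d = parents.data.set_index(["individual_id", "locus_id"])
    for i, name in enumerate(names):
        for j, locus in enumerate(loci):
            a = d.loc[(name, locus), "allele_a"]
            mat[i, j] = index[locus][a]
    return mat, loci, label_lists


def _f2_pool(parent_mat: np.ndarray, scheme, names: list[str],
             rng: np.random.Generator) -> np.ndarray:
    """F2 genotypes (N, L, 2): two independent gametes of each cross's F1."""
    name_idx = {n: i for i, n in enumerate(names)}
    L = parent_mat.shape[1]
    blocks = []
    for pi, pj, s in scheme.crosses:
        ai = parent_mat[name_idx[pi]]
        aj = parent_mat[name_idx[pj]]
        # gamete = allele from parent i or j with probability 1/2, unlinked
        pick = rng.integers(0, 2, size=(s, L, 2)).astype(bool)
        block = np.where(pick, ai[None, :, None], aj[None, :, None])
        blocks.append(block.astype(np.int16))
    return np.concatenate(blocks, axis=0)


def _census_freqs(G: np.ndarray, n_alleles: Sequence[int]) -> list[np.ndarray]:
    out = []
    for j, K in enumerate(n_alleles):
        calls = G[:, j, :].ravel()
        out.append(np.bincount(calls, minlength=K) / calls.size)
    return out


def _inbreeding_coefficient(G: np.ndarray, n_alleles: Sequence[int]) -> float:
    h_obs = (G[:, :, 0] != G[:, :, 1]).mean(axis=0)
    h_exp = np.array([1.0 - np.sum(f ** 2) for f in _census_freqs(G, n_alleles)])
    use = h_exp > 0.02
    if not use.any():
        return 0.0
    f = 1.0 - h_obs[use].sum() / h_exp[use].sum()
    return float(np.clip(f, -0.9, 0.98))


def _fecundity(G: np.ndarray, sel_idx: np.ndarray, sel_s: np.ndarray) -> np.ndarray:
    if sel_idx.size == 0:
        return np.ones(G.shape[0])
    dosage = (G[:, sel_idx, 0] == 0).astype(np.int8) + (G[:, sel_idx, 1] == 0)
    w = np.exp(dosage @ sel_s)
    if not np.any(w > 0) or not np.all(np.isfinite(w)):
        raise ValidationError("simulation error: degenerate fecundities")
    return w


def _next_generation(G: np.ndarray, params: SimParams, n_alleles: Sequence[int],
                     sel_idx: np.ndarray, sel_s: np.ndarray,
                     rng: np.random.Generator) -> tuple[np.ndarray, int, float]:
    """One round of reproduction at a location (drift imposed at target_ne)."""
    N, L, _ = G.shape
    census = params.census_size
    f_hat = _inbreeding_coefficient(G, n_alleles)
    m = int(np.clip(np.round(params.target_ne * (1.0 + f_hat)), 2, None))
    w = _fecundity(G, sel_idx, sel_s)
    slots = rng.choice(N, size=m, replace=True, p=w / w.sum())
    counts = np.full(m, census // m)
    counts[: census % m] += 1
    dam = np.repeat(slots, counts)            # seed parent of each offspring
    selfed = rng.random(census) < params.selfing_rate
    sire = dam.copy()
    n_out = int((~selfed).sum())
    if n_out:
        sire[~selfed] = slots[rng.integers(0, m, size=n_out)]
    out = np.empty((census, L, 2), dtype=np.int16)
    for parent, k in ((dam, 0), (sire, 1)):
        pick = rng.integers(0, 2, size=(census, L))
        out[:, :, k] = np.take_along_axis(G[parent], pick[:, :, None], axis=2)[:, :, 0]
    return out, m, f_hat


def simulate_generations(parents: GenotypeTable, scheme, params: SimParams,
                         rng: np.random.Generator) -> SimOutput:
    """Run the CCP forward: F1 -> pooled F2 -> per-location evolution.

    The pooled F2 (generation 2) is shared by all locations; each location
    then reproduces independently for generations 3..n_generations, so two
    locations at generation g have drifted apart for g-2 generations.
    Samples of params.sample_sizes[g] individuals are genotyped at the
    listed generations; truth tables record census allele frequencies.
    """
    parent_mat, loci, label_lists = _parent_matrix(parents)
    names = sorted(parents.data["individual_id"].unique())
    n_alleles = [len(ls) for ls in label_lists]
    sel_idx = np.array([loci.index(l) for l in params.selection_coefficients], dtype=int)
    missing_sel = [l for l in params.selection_coefficients if l not in loci]
    if missing_sel:
        raise ValidationError(f"selection on unknown locus {missing_sel[0]!r}")
    sel_s = np.array([params.selection_coefficients[loci[i]] for i in sel_idx])

    pool = _f2_pool(parent_mat, scheme, names, rng)
    truth_rows = []
    pc_rows = []
    sample_frames = []

    def record_truth(loc: str, gen: int, G: np.ndarray) -> None:
        for j, freqs in enumerate(_census_freqs(G, n_alleles)):
            for k, p in enumerate(freqs):
                truth_rows.append((loc, gen, loci[j], label_lists[j][k], float(p)))

    for loc in params.locations:
        if pool.shape[0] >= params.census_size:
            start = rng.choice(pool.shape[0], size=params.census_size, replace=False)
        else:
            start = rng.choice(pool.shape[0], size=params.census_size, replace=True)
        G = pool[start]
        record_truth(loc, 2, G)
        for gen in range(3, params.n_generations + 1):
            G, m, f_hat = _next_generation(G, params, n_alleles, sel_idx, sel_s, rng)
            record_truth(loc, gen, G)
            pc_rows.append((loc, gen, m, f_hat))
            if gen in params.sample_sizes:
                n_s = min(params.sample_sizes[gen], G.shape[0])
                take = rng.choice(G.shape[0], size=n_s, replace=False)
                sample_frames.append(_genotype_frame(G[take], loc, gen, loci, label_lists))

    if sample_frames:
        geno_frame = pd.concat(sample_frames, ignore_index=True)
    else:
        geno_frame = pd.DataFrame(columns=["individual_id", "population", "generation",
                                           "location", "locus_id", "allele_a", "allele_b"])
    geno = GenotypeTable(geno_frame,
                         [dataclasses.replace(lm) for lm in parents.panel])
    truth = pd.DataFrame(truth_rows,
                         columns=["location", "generation", "locus_id", "allele", "p"])
    bad = ~truth["p"].between(0.0, 1.0)
    assert not bad.any()
    parent_counts = pd.DataFrame(pc_rows,
                                 columns=["location", "generation", "m_parents", "f_hat"])
    return SimOutput(genotypes=geno, parents=parents, scheme=scheme, traits=None,
                     truth=truth, parent_counts=parent_counts, params=params)


def _genotype_frame(G: np.ndarray, loc: str, gen: int, loci: list[str],
                    label_lists: list[list[str]]) -> pd.DataFrame:
    n, L, _ = G.shape
    pop = f"{loc}_g{gen}"
    ids = [f"{pop}_{i + 1:04d}" for i in range(n)]
    rows = []
    for j in range(L):
        labels = label_lists[j]
        for i in range(n):
            rows.append((ids[i], pop, gen, loc, loci[j],
                         labels[G[i, j, 0]], labels[G[i, j, 1]]))
    return pd.DataFrame(rows, columns=["individual_id", "population", "generation",
                                       "location", "locus_id", "allele_a", "allele_b"])


# ---------------------------------------------------------------------------
# phenotypes


def _dosage(table: GenotypeTable, locus: str, allele: str) -> pd.Series:
    d = table.data[table.data["locus_id"] == locus]
    dos = (d["allele_a"] == allele).astype(int) + (d["allele_b"] == allele).astype(int)
    return pd.Series(dos.to_numpy(), index=d["individual_id"].to_numpy())


def _genetic_values(table: GenotypeTable, spec: TraitSpec) -> pd.Series:
    """mu + sum of effect * dosage of the first-listed allele per individual."""
    loci = {lm.locus_id: lm.allele_labels[0] for lm in table.panel}
    ids = table.data["individual_id"].unique()
    g = pd.Series(spec.mu, index=ids, dtype=float)
    for locus, eff in spec.effects.items():
        if locus not in loci:
            raise ValidationError(f"trait effect on unknown locus {locus!r}")
        g = g.add(eff * _dosage(table, locus, loci[locus]), fill_value=0.0)
    return g


def simulate_phenotypes(output: SimOutput, params: SimParams,
                        rng: np.random.Generator) -> TraitTable:
    """Single-plant (mixed stand) and plot-trial (pure stand) phenotypes.

    Mixed stand: every genotyped individual at the organic locations in the
    phenotyped generations gets y = genetic value + trial effect + residual;
    the trial is the location x generation combination.  Pure stand: each
    parent variety x trial (years x locations) x replicate block plot gets
    the variety's genetic value plus trial, block-in-trial and plot
    residual effects.
    """
    if not params.trait_model:
        raise ValidationError("trait_model is empty")
    rows = []
    geno = output.genotypes
    mixed_mask = (
        geno.data["location"].isin(params.organic_locations)
        & geno.data["generation"].isin(params.phenotyped_generations)
    )
    mixed_inds = geno.data.loc[mixed_mask, ["individual_id", "location", "generation"]]
    mixed_inds = mixed_inds.drop_duplicates("individual_id")
    trials_mixed = sorted(
        {(l, g) for l, g in zip(mixed_inds["location"], mixed_inds["generation"])}
    )
    pure_trials = [f"{loc}_Y{y + 1}" for y in range(params.pure_stand_years)
                   for loc in params.locations]
    for trait, spec in params.trait_model.items():
        gv = _genetic_values(geno, spec)
        t_eff = {t: rng.normal(0.0, spec.trial_sd) for t in trials_mixed}
        for ind, loc, gen in mixed_inds.itertuples(index=False):
            y = gv[ind] + t_eff[(loc, gen)] + rng.normal(0.0, spec.resid_sd)
            rows.append((ind, Stand.MIXED.value, f"{loc}_g{gen}", None, None, trait, y))
        gv_par = _genetic_values(output.parents, spec)
        pt_eff = {t: rng.normal(0.0, spec.trial_sd) for t in pure_trials}
        for t in pure_trials:
            b_eff = rng.normal(0.0, spec.block_sd, size=params.pure_stand_replicates)
            for b in range(params.pure_stand_replicates):
                for variety, v in gv_par.items():
                    y = v + pt_eff[t] + b_eff[b] + rng.normal(0.0, spec.plot_resid_sd)
                    rows.append((f"{variety}.{t}.B{b + 1}", Stand.PURE.value, t,
                                 f"B{b + 1}", variety, trait, y))
    df = pd.DataFrame(rows, columns=["unit_id", "stand", "trial", "replicate_block",
                                     "variety", "trait", "value"])
    traits = TraitTable(df)
    output.traits = traits
    return traits


def simulate_ccp(params: SimParams | None = None,
                 rng: np.random.Generator | int | None = None,
                 phenotypes: bool = True) -> SimOutput:
    """One-call convenience: parents -> scheme -> generations -> phenotypes."""
    params = params or SimParams()
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    parents = make_parents(params, rng)
    scheme = make_crossing_scheme(params, rng)
    out = simulate_generations(parents, scheme, params, rng)
    if phenotypes and params.trait_model:
        simulate_phenotypes(out, params, rng)
    return out
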