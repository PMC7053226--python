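"""Tabular input/output, run configuration, and the pipeline driver.

All files are UTF-8, tab-delimited, with a mandatory header row; the missing
allele code is ``NA``.  Genotypes are stored long (one row per individual and
locus) with two allele columns, which avoids separator ambiguity in SSR allele
names; a converter accepts the compact ``a/b`` slash form.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

MISSING = "NA"

GENOTYPE_COLUMNS = [
    "individual_id",
    "population",
    "generation",
    "location",
    "locus_id",
    "allele_a",
    "allele_b",
]

TRAIT_COLUMNS = [
    "unit_id",
    "stand",
    "trial",
    "replicate_block",
    "variety",
    "trait",
    "value",
]


class FormatError(ValueError):
    """A file does not conform to the declared dialect."""


class ValidationError(ValueError):
    """A file parses but violates a content invariant."""


class MarkerType(str, Enum):
    SSR = "SSR"
    SNP = "SNP"


class Stand(str, Enum):
    MIXED = "mixed_single_plant"
    PURE = "pure_plot"


@dataclass
class LocusMeta:
    """Identity and allele dictionary of one marker locus."""

    locus_id: str
    marker_type: MarkerType
    allele_labels: list[str]
    frequent_allele: str | None = None
    annotation: str = ""

    def __post_init__(self) -> None:
        self.marker_type = MarkerType(self.marker_type)
        if not self.allele_labels:
            raise ValidationError(f"locus {self.locus_id}: empty allele_labels")
        if self.frequent_allele is not None and self.frequent_allele not in self.allele_labels:
            raise ValidationError(
                f"locus {self.locus_id}: frequent_allele {self.frequent_allele!r} "
                "not among allele_labels"
            )


def panel_by_id(panel: Sequence[LocusMeta]) -> dict[str, LocusMeta]:
    out: dict[str, LocusMeta] = {}
    for lm in panel:
        if lm.locus_id in out:
            raise ValidationError(f"duplicate locus_id in panel: {lm.locus_id}")
        out[lm.locus_id] = lm
    return out


@dataclass
class LoadReport:
    """What a loader changed or flagged: novel alleles and dropped records."""

    novel_alleles: dict[str, list[str]] = field(default_factory=dict)
    dropped_records: int = 0
    warnings: list[str] = field(default_factory=list)

    @property
    def n_novel(self) -> int:
        return sum(len(v) for v in self.novel_alleles.values())


@dataclass
class GenotypeTable:
    """Long-format allele-pair calls plus the marker panel.

    ``data`` columns: individual_id, population, generation, location,
    locus_id, allele_a, allele_b.  ``population`` is the sample label (one
    generation per population label); ``location``/``generation`` carry the
    design factors.
    """

    data: pd.DataFrame
    panel: list[LocusMeta]
    load_report: LoadReport = field(default_factory=LoadReport)

    def __post_init__(self) -> None:
        missing = [c for c in GENOTYPE_COLUMNS if c not in self.data.columns]
        if missing:
            raise FormatError(f"genotype table missing column(s): {', '.join(missing)}")
        self.data = self.data[GENOTYPE_COLUMNS].copy()
        self.data["generation"] = self.data["generation"].astype(int)
        if (self.data["generation"] < 0).any():
            raise ValidationError("negative generation label")
        dup = self.data.duplicated(subset=["individual_id", "locus_id"])
        if dup.any():
            first = self.data.loc[dup, ["individual_id", "locus_id"]].iloc[0]
            raise ValidationError(
                f"duplicate (individual, locus) record: "
                f"({first['individual_id']}, {first['locus_id']})"
            )
        gens = self.data.groupby("population", observed=True)["generation"].nunique()
        bad = gens[gens > 1]
        if len(bad):
            raise ValidationError(
                f"population {bad.index[0]!r} spans multiple generations"
            )
        panel_by_id(self.panel)  # uniqueness check

    @property
    def populations(self) -> list[str]:
        return sorted(self.data["population"].unique())

    @property
    def loci(self) -> list[str]:
        return [lm.locus_id for lm in self.panel]

    def subset(self, populations: Iterable[str] | None = None,
               loci: Iterable[str] | None = None) -> "GenotypeTable":
        d = self.data
        panel = self.panel
        if populations is not None:
            pops = set(populations)
            d = d[d["population"].isin(pops)]
        if loci is not None:
            keep = set(loci)
            d = d[d["locus_id"].isin(keep)]
            panel = [lm for lm in panel if lm.locus_id in keep]
        return GenotypeTable(d.reset_index(drop=True), [dataclasses.replace(lm) for lm in panel])

    def write(self, path: str | Path, panel_path: str | Path | None = None) -> None:
        self.data.to_csv(path, sep="\t", index=False)
        if panel_path is not None:
            write_panel(self.panel, panel_path)


@dataclass
class TraitTable:
    """Single-plant (mixed stand) and plot-trial (pure stand) phenotypes."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in TRAIT_COLUMNS if c not in self.data.columns]
        if missing:
            raise FormatError(f"trait table missing column(s): {', '.join(missing)}")
        self.data = self.data[TRAIT_COLUMNS].copy()
        bad_stand = ~self.data["stand"].isin([s.value for s in Stand])
        if bad_stand.any():
            raise ValidationError(
                f"unknown stand label {self.data.loc[bad_stand, 'stand'].iloc[0]!r}"
            )
        vals = pd.to_numeric(self.data["value"], errors="coerce")
        if vals.isna().any():
            row = int(np.flatnonzero(vals.isna().to_numpy())[0])
            raise FormatError(
                f"non-numeric trait value {self.data['value'].iloc[row]!r} in row {row}"
            )
        self.data["value"] = vals.astype(float)
        mixed = self.data["stand"] == Stand.MIXED.value
        if (self.data.loc[mixed, "unit_id"].isin([MISSING, ""]) |
                self.data.loc[mixed, "unit_id"].isna()).any():
            raise ValidationError("mixed_single_plant record lacking individual_id")
        pure = self.data["stand"] == Stand.PURE.value
        for col in ("variety", "replicate_block"):
            if (self.data.loc[pure, col].isin([MISSING, ""]) |
                    self.data.loc[pure, col].isna()).any():
                raise ValidationError(f"pure_plot record lacking {col}")

    def write(self, path: str | Path) -> None:
        self.data.to_csv(path, sep="\t", index=False, na_rep=MISSING)


@dataclass
class RunConfig:
    """Knobs of the stochastic stages; all randomness flows from rng_seed."""

    t_generations: int = 8
    rng_seed: int = 0
    n_bootstrap: int = 5000
    n_null_sims: int = 20000
    n_demes: int = 100
    ci_level: float = 0.95
    virtual_pop_size: int = 10000
    drift_ne_grid: tuple[int, ...] = (150, 250)

    def __post_init__(self) -> None:
        for name in ("n_bootstrap", "n_null_sims", "n_demes", "t_generations",
                     "virtual_pop_size"):
            if int(getattr(self, name)) <= 0:
                raise ValidationError(f"{name} must be positive")
        if not 0.0 < self.ci_level < 1.0:
            raise ValidationError("ci_level must lie strictly inside (0, 1)")
        self.drift_ne_grid = tuple(int(v) for v in self.drift_ne_grid)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise FormatError(f"unknown config key(s): {', '.join(sorted(unknown))}")
        return cls(**raw)

    def spawn_rngs(self, stages: Sequence[str]) -> dict[str, np.random.Generator]:
        """One child generator per named stage, all derived from rng_seed."""
        ss = np.random.SeedSequence(self.rng_seed)
        children = ss.spawn(len(stages))
        return {name: np.random.default_rng(c) for name, c in zip(stages, children)}


# ---------------------------------------------------------------------------
# panel i/o


def write_panel(panel: Sequence[LocusMeta], path: str | Path) -> None:
    rows = [
        {
            "locus_id": lm.locus_id,
            "marker_type": lm.marker_type.value,
            "allele_labels": ",".join(lm.allele_labels),
            "frequent_allele": lm.frequent_allele if lm.frequent_allele else MISSING,
            "annotation": lm.annotation or MISSING,
        }
        for lm in panel
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def load_panel(path: str | Path) -> list[LocusMeta]:
    df = _read_tsv(path, ["locus_id", "marker_type", "allele_labels"])
    panel = []
    for _, row in df.iterrows():
        freq = row.get("frequent_allele", MISSING)
        ann = row.get("annotation", MISSING)
        panel.append(
            LocusMeta(
                locus_id=str(row["locus_id"]),
                marker_type=MarkerType(row["marker_type"]),
                allele_labels=[a for a in str(row["allele_labels"]).split(",") if a],
                frequent_allele=None if pd.isna(freq) or freq == MISSING else str(freq),
                annotation="" if pd.isna(ann) or ann == MISSING else str(ann),
            )
        )
    return panel


def _read_tsv(path: str | Path, mandatory: Sequence[str]) -> pd.DataFrame:
    if not Path(path).exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, na_values=[])
    missing = [c for c in mandatory if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing mandatory column(s): {', '.join(missing)}")
    return df


# ---------------------------------------------------------------------------
# loaders


def load_genotypes(path: str | Path, panel_path: str | Path) -> GenotypeTable:
    """Read a genotype file against its panel.

    Accepts either two allele columns or a single ``genotype`` column in
    ``a/b`` form.  Allele labels unknown to the panel are appended to the
    locus's allele dictionary and enumerated in the load report.
    """
    panel = load_panel(panel_path)
    df = _read_tsv(path, ["individual_id", "population", "generation",
                          "location", "locus_id"])
    if "genotype" in df.columns and "allele_a" not in df.columns:
        parts = df["genotype"].str.split("/", n=1, expand=True)
        if parts.shape[1] != 2 or parts.isna().any().any():
            raise FormatError(f"{path}: genotype column is not in a/b form")
        df = df.assign(allele_a=parts[0], allele_b=parts[1]).drop(columns="genotype")
    for col in ("allele_a", "allele_b"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing mandatory column(s): {col}")

    report = LoadReport()
    by_id = panel_by_id(panel)
    unknown_loci = sorted(set(df["locus_id"]) - set(by_id))
    if unknown_loci:
        raise ValidationError(f"{path}: locus not in panel: {unknown_loci[0]}")
    for locus_id, sub in df.groupby("locus_id", observed=True):
        lm = by_id[locus_id]
        seen = set(sub["allele_a"]) | set(sub["allele_b"])
        novel = sorted(seen - set(lm.allele_labels) - {MISSING})
        if novel:
            lm.allele_labels.extend(novel)
            report.novel_alleles[locus_id] = novel
            report.warnings.append(
                f"locus {locus_id}: {len(novel)} allele label(s) not in panel: "
                + ",".join(novel)
            )
    table = GenotypeTable(df, panel, load_report=report)
    return table


def load_traits(path: str | Path) -> TraitTable:
    df = _read_tsv(path, TRAIT_COLUMNS)
    return TraitTable(df)


def load_crossing_scheme(path: str | Path, parents: GenotypeTable | None = None):
    """Read (parent_i, parent_j, seed_count) rows into a CrossingScheme.

    Reversed duplicates of the same unordered pair are merged with summed
    seed counts (warned); the scheme is cross-checked against the parental
    genotype table when one is given.
    """
    from .founder import CrossingScheme

    df = _read_tsv(path, ["parent_i", "parent_j", "seed_count"])
    counts = pd.to_numeric(df["seed_count"], errors="coerce")
    if counts.isna().any() or (counts <= 0).any() or (counts % 1 != 0).any():
        raise ValidationError(f"{path}: seed_count must be a positive integer")
    merged: dict[tuple[str, str], int] = {}
    warnings: list[str] = []
    for (pi, pj), s in zip(zip(df["parent_i"], df["parent_j"]), counts.astype(int)):
        key = tuple(sorted((str(pi), str(pj))))
        if key in merged:
            warnings.append(f"duplicate cross {key[0]}x{key[1]} merged (counts summed)")
        merged[key] = merged.get(key, 0) + int(s)
    scheme = CrossingScheme(
        crosses=[(pi, pj, s) for (pi, pj), s in merged.items()], warnings=warnings
    )
    if parents is not None:
        known = set(parents.data["individual_id"])
        for pi, pj, _ in scheme.crosses:
            for p in (pi, pj):
                if p not in known:
                    raise ValidationError(f"cross parent {p!r} absent from parental genotypes")
    return scheme


# ---------------------------------------------------------------------------
# pipeline driver


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


RESULT_TABLES = [
    "diversity.tsv",
    "fst_pairwise.tsv",
    "outlier_scan.tsv",
    "ne_estimates.tsv",
    "drift_flags.tsv",
    "assoc_effects.tsv",
    "assoc_correlations.tsv",
]


def run_pipeline(config: RunConfig, *, genotypes_path: str | Path,
                 panel_path: str | Path, parents_path: str | Path,
                 scheme_path: str | Path, traits_path: str | Path | None = None,
                 out_dir: str | Path) -> dict[str, Path]:
    """Run the full inference chain and write one table per stage.

    Stages: virtual founder -> marker recoding -> allele frequencies ->
    gene diversity -> pairwise/grouped F_ST -> outlier scan -> Ne (pair-based
    and temporal) -> drift bands and selection flags -> marker-effect
    association and correlations.  Returns the mapping result name -> path.
    """
    from . import association, founder, ne_drift, outlier_scan, popgen_stats

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rngs = config.spawn_rngs(
        ["bootstrap_div", "bootstrap_fst", "null_sim", "bootstrap_misc"]
    )
    written: dict[str, Path] = {}
    log: dict[str, object] = {
        "rng_seed": config.rng_seed,
        "config": dataclasses.asdict(config),
    }

    def stage(name):
        def deco(fn):
            try:
                return fn()
            except Exception as exc:  # noqa: BLE001 - report stage and cause
                raise PipelineError(name, exc) from exc
        return deco

    @stage("load")
    def _loaded():
        parents = load_genotypes(parents_path, panel_path)
        geno = load_genotypes(genotypes_path, panel_path)
        scheme = load_crossing_scheme(scheme_path, parents)
        traits = load_traits(traits_path) if traits_path else None
        return parents, geno, scheme, traits

    parents, geno, scheme, traits = _loaded

    @stage("founder")
    def _founder():
        fnd = founder.build_virtual_fnd(scheme, parents, config.virtual_pop_size)
        geno_f, removal = founder.filter_nonparental_alleles(geno, parents)
        both = founder.concat_tables(fnd, geno_f)
        collapsed = founder.collapse_to_biallelic(both, fnd)
        freqs = founder.allele_frequencies(collapsed)
        return fnd, geno_f, collapsed, freqs, removal

    fnd, geno_f, collapsed, freqs, removal = _founder
    log["nonparental_removals"] = removal.per_locus

    @stage("diversity")
    def _div():
        rows = []
        for pop in sorted(set(geno_f.data["population"]) | {"FND"}):
            src = fnd if pop == "FND" else geno_f
            res = popgen_stats.gene_diversity(
                src, pop, n_bootstrap=config.n_bootstrap,
                ci_level=config.ci_level, rng=rngs["bootstrap_div"],
            )
            rows.append(res)
        df = popgen_stats.diversity_table(rows)
        p = out / "diversity.tsv"
        df.to_csv(p, sep="\t", index=False)
        return p

    written["diversity"] = _div

    final_gen = int(geno_f.data["generation"].max())
    final_pops = sorted(
        collapsed.data.loc[collapsed.data["generation"] == final_gen, "population"].unique()
    )

    @stage("fst")
    def _fst():
        results = popgen_stats.pairwise_and_grouped_fst(
            collapsed.subset(populations=final_pops),
            pairs="all", groups=_management_groups(final_pops),
            n_bootstrap=config.n_bootstrap, ci_level=config.ci_level,
            rng=rngs["bootstrap_fst"],
        )
        overall = popgen_stats.fst_wc(collapsed.subset(populations=final_pops))
        popgen_stats.attach_bootstrap_ci(
            overall, config.n_bootstrap, config.ci_level, rngs["bootstrap_fst"]
        )
        df = popgen_stats.differentiation_table([overall] + results)
        p = out / "fst_pairwise.tsv"
        df.to_csv(p, sep="\t", index=False)
        return overall, results, p

    overall_fst, fst_results, written["fst_pairwise"] = _fst

    @stage("outliers")
    def _outliers():
        target = max(overall_fst.fst_multilocus, 1e-4)
        cloud = outlier_scan.simulate_null_fst(
            target_fst=target, n_sims=config.n_null_sims, n_demes=config.n_demes,
            n_sampled_demes=len(final_pops),
            sample_size=_median_sample_size(collapsed, final_pops),
            rng=rngs["null_sim"],
        )
        scan = outlier_scan.outlier_pvalues(overall_fst, collapsed, cloud)
        p = out / "outlier_scan.tsv"
        outlier_scan.scan_table(scan).to_csv(p, sep="\t", index=False)
        return scan, p

    scan, written["outlier_scan"] = _outliers

    @stage("ne")
    def _ne():
        neutral = outlier_scan.loci_for_ne(scan)
        est_fst = ne_drift.ne_fst_pairs(
            collapsed.subset(populations=final_pops, loci=neutral),
            t=config.t_generations,
            n_bootstrap=config.n_bootstrap, ci_level=config.ci_level,
            rng=rngs["bootstrap_misc"],
        )
        estimates = [est_fst]
        temporal = ne_drift.ne_temporal_from_tables(
            freqs, collapsed, loci=_ssr_loci(collapsed, neutral)
        )
        estimates.extend(temporal)
        df = ne_drift.ne_table(estimates)
        p = out / "ne_estimates.tsv"
        df.to_csv(p, sep="\t", index=False)
        return neutral, est_fst, p

    neutral_loci, ne_est, written["ne_estimates"] = _ne

    @stage("driftscan")
    def _drift():
        flags = ne_drift.flag_selection(
            freqs, ne_values=config.drift_ne_grid, t=config.t_generations,
            ci_level=config.ci_level, panel=collapsed.panel,
        )
        p = out / "drift_flags.tsv"
        flags.table.to_csv(p, sep="\t", index=False)
        return flags, p

    flags, written["drift_flags"] = _drift

    @stage("assoc")
    def _assoc():
        if traits is None:
            for name in ("assoc_effects", "assoc_correlations"):
                p = out / f"{name}.tsv"
                pd.DataFrame().to_csv(p, sep="\t", index=False)
                written[name] = p
            return None
        effects = association.all_effects(traits, collapsed, parents_collapsed=_collapse_parents(parents, collapsed))
        eff_p = out / "assoc_effects.tsv"
        association.effects_table(effects).to_csv(eff_p, sep="\t", index=False)
        corr = association.correlation_report(effects, freqs, final_gen=final_gen)
        cor_p = out / "assoc_correlations.tsv"
        corr.to_csv(cor_p, sep="\t", index=False)
        written["assoc_effects"] = eff_p
        written["assoc_correlations"] = cor_p
        return effects

    _assoc

    @stage("report")
    def _report():
        dpcorr = ne_drift.delta_p_correlation(freqs, populations=final_pops)
        p = out / "delta_p_correlation.tsv"
        dpcorr.table.to_csv(p, sep="\t", index=False)
        written["delta_p_correlation"] = p
        log_path = out / "run_log.json"
        import ccpevolve

        log["version"] = ccpevolve.__version__
        log["neutral_loci"] = sorted(neutral_loci)
        log["ne_fst_pairs"] = ne_est.point
        with open(log_path, "w") as fh:
            json.dump(log, fh, indent=2, sort_keys=True, default=str)
        written["run_log"] = log_path
        return None

    _report
    return written


def _management_groups(pops: Sequence[str]) -> list[tuple[list[str], list[str]]]:
    """Two-group contrasts: every split of the populations into two halves."""
    pops = list(pops)
    if len(pops) != 4:
        return []
    from itertools import combinations

    out = []
    for pair in combinations(pops, 2):
        if pops[0] in pair:
            other = [p for p in pops if p not in pair]
            out.append((list(pair), other))
    return out


def _median_sample_size(table: GenotypeTable, pops: Sequence[str]) -> int:
    counts = [
        table.data[table.data["population"] == p]["individual_id"].nunique()
        for p in pops
    ]
    return int(np.median(counts)) if counts else 50


def _ssr_loci(table: GenotypeTable, restrict: Iterable[str]) -> list[str]:
    keep = set(restrict)
    return [lm.locus_id for lm in table.panel
            if lm.marker_type is MarkerType.SSR and lm.locus_id in keep]


def _collapse_parents(parents: GenotypeTable, collapsed: GenotypeTable) -> GenotypeTable:
    """Recode the parental table with the recoding already fixed on FND."""
    from .founder import apply_recoding

    recoding = {lm.locus_id: lm.frequent_allele for lm in collapsed.panel
                if lm.frequent_allele is not None}
    return apply_recoding(parents, recoding)
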