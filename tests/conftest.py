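"""Session fixtures: one scaled synthetic CCP dataset shared across tests.

The simulated conditions mirror the study design (4 locations, 28-locus
panel, generations 3/6/10 sampled, directional selection on the height
loci, selfing rate 0.98) at reduced census and seed counts so the whole
suite stays fast; the drift target Ne = 200 is the quantity the inference
tests try to recover.
"""

from __future__ import annotations

import numpy as np
import pytest

from ccpevolve import founder as founder_mod
from ccpevolve.io_formats import RunConfig
from ccpevolve.synthetic_ccp import SimParams, TraitSpec, simulate_ccp


def scaled_params(**overrides) -> SimParams:
    base = dict(
        census_size=3000,
        target_ne=200,
        n_crosses=40,
        seed_count_mean=200,
        seed_count_min=37,
        seed_count_max=500,
        sample_sizes={3: 100, 6: 150, 10: 200},
    )
    base.update(overrides)
    return SimParams(**base)


@pytest.fixture(scope="session")
def sim_selected():
    """Dataset with shared directional selection on the height loci."""
    params = scaled_params(
        selection_coefficients={"Rht-B1": 0.12, "Rht-D1": 0.15, "Ppd-D1": 0.08},
        trait_model={
            "height": TraitSpec(mu=95.0, effects={"Rht-B1": 4.0, "Rht-D1": 6.0},
                                resid_sd=5.0, trial_sd=4.0),
            "heading": TraitSpec(mu=155.0, effects={"Ppd-D1": 3.0},
                                 resid_sd=4.0, trial_sd=3.0),
        },
    )
    return simulate_ccp(params, rng=101)


@pytest.fixture(scope="session")
def sim_neutral():
    """Dataset with no selection (drift only)."""
    return simulate_ccp(scaled_params(), rng=202, phenotypes=False)


@pytest.fixture(scope="session")
def collapsed_selected(sim_selected):
    """FND + samples, non-parental filter applied, SSRs collapsed."""
    out = sim_selected
    fnd = founder_mod.build_virtual_fnd(out.scheme, out.parents, 10000)
    geno_f, _ = founder_mod.filter_nonparental_alleles(out.genotypes, out.parents)
    both = founder_mod.concat_tables(fnd, geno_f)
    collapsed = founder_mod.collapse_to_biallelic(both, fnd)
    return collapsed


@pytest.fixture(scope="session")
def freqs_selected(collapsed_selected):
    return founder_mod.allele_frequencies(collapsed_selected)


@pytest.fixture(scope="session")
def pipeline_run(sim_selected, tmp_path_factory):
    """One full pipeline run on disk (small stochastic stage sizes)."""
    from ccpevolve.io_formats import run_pipeline

    d = tmp_path_factory.mktemp("pipeline")
    out = sim_selected
    out.genotypes.write(d / "genotypes.tsv", d / "panel.tsv")
    out.parents.write(d / "parents.tsv")
    out.scheme.write(d / "scheme.tsv")
    out.traits.write(d / "traits.tsv")
    cfg = RunConfig(rng_seed=7, n_bootstrap=300, n_null_sims=2000)
    written = run_pipeline(
        cfg, genotypes_path=d / "genotypes.tsv", panel_path=d / "panel.tsv",
        parents_path=d / "parents.tsv", scheme_path=d / "scheme.tsv",
        traits_path=d / "traits.tsv", out_dir=d / "results")
    return {"dir": d, "written": written, "config": cfg}
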