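"""Shared fixtures: one moderately sized admixture simulation reused by the
ancestry, association, and acceptance tests."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import hapintro as hi
from hapintro.simulate import SimulationConfig, TraitSpec


@pytest.fixture(scope="session")
def admix_bundle():
    """Panels at F_ST 0.3, an alpha=0.2 admixed cohort of 250 samples, and
    the classifier's paint, with per-site and per-block truth."""
    cfg = SimulationConfig(seed=11, m_snps=5000, n_per_panel=50, panel_fst=0.3,
                           admix_fraction=0.2)
    panels = hi.simulate_panels(cfg)
    outgroup = hi.simulate_outgroup(cfg, panels)
    donors = {k: panels[k] for k in ("DONOR1", "DONOR2")}
    cohort, truth_sites = hi.simulate_admixed_cohort(
        cfg, panels["EUR"], donors, n_samples=250
    )
    paint = hi.classify_local_ancestry(cohort, panels)
    truth_blocks = hi.truth_block_labels(truth_sites, cfg.block_size_snps)
    return {
        "cfg": cfg,
        "panels": panels,
        "outgroup": outgroup,
        "cohort": cohort,
        "truth_sites": truth_sites,
        "truth_blocks": truth_blocks,
        "paint": paint,
    }


@pytest.fixture(scope="session")
def trait_bundle(admix_bundle):
    """Phenotypes with one causal ancestry block on the admixed cohort."""
    cfg = admix_bundle["cfg"]
    tb = admix_bundle["truth_blocks"]
    cfg2 = SimulationConfig(
        seed=cfg.seed,
        m_snps=cfg.m_snps,
        n_per_panel=cfg.n_per_panel,
        panel_fst=cfg.panel_fst,
        admix_fraction=cfg.admix_fraction,
        trait_specs=[TraitSpec(causal_block=200, variance_fraction=0.05, h2=0.5)],
    )
    pheno, truth = hi.simulate_traits(cfg2, tb, admix_bundle["cohort"].sample_ids)
    return {"cfg": cfg2, "pheno": pheno, "truth": truth}


def block_dosages(truth_blocks: np.ndarray) -> np.ndarray:
    """Combined-donor ancestry dosage (samples x blocks)."""
    carrier = truth_blocks > 0
    n_hap, n_blocks = truth_blocks.shape
    return carrier.reshape(n_hap // 2, 2, n_blocks).sum(1).astype(float)


def covariate_frame(pheno: pd.DataFrame) -> pd.DataFrame:
    cov = pheno[["year", "parity", "weight_start", "weight_end"]].copy()
    cov["year"] = cov["year"].astype("category")
    cov["parity"] = cov["parity"].astype("category")
    return cov
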