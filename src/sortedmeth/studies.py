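"""Reference simulation studies at desk scale.

Reproduces the two headline simulation experiments on synthetic cohorts
mirroring the reference study's structure (three fractions with 182/168/
164 samples over ~218 donors, log-normal site-SD distributions matched to
the printed per-cell-type moments, individual-level ~50/50 case
assignment):

* a null false-positive study — repeated null EWAS on a 50,000-site
  cohort, scoring within-cell-type regression (ctLR) and cluster-robust
  regression (CRR) at the epigenome-wide threshold 9e-8 and the relaxed
  discovery threshold 1e-6;
* a spiked true-positive study — repeated EWAS on a cohort of 1,000
  spiked DMPs (5 percentage-point case-control difference, half
  cell-specific) plus 5,000 null sites, scoring ctLR per cell type over
  the DMPs affecting that cell type and the pooled CRR / mixed-model
  frameworks over all DMPs (main effect or any interaction significant).

Site counts are scaled down from the array's ~846k sites to keep a full
study tractable on one CPU; false-positive bounds are conservative under
this scaling, and true-positive rates are per-DMP so unaffected by it.
"""

from __future__ import annotations

import numpy as np

from .benchmark import SimulationConfig, run_null_benchmark, \
    run_spiked_benchmark, summarize_benchmark
from .simulate import CohortConfig, generate_cohort

__all__ = ["null_false_positive_study", "spiked_tpr_study"]

EPIGENOME_WIDE = 9e-8


def _derive_seeds(seed: int, n: int):
    state = np.random.SeedSequence(seed).generate_state(n)
    return [int(s) & 0x7FFFFFFF for s in state]


def null_false_positive_study(seed: int, n_simulations: int = 100,
                              n_sites: int = 50_000) -> dict:
    """Mean false-positive DMP counts per null simulation.

    Returns per-framework means at 9e-8 and 1e-6: ctLR is summarized as
    the *maximum* over the three per-cell-type models (the conservative
    reading of a per-model bound), CRR with the any-term policy.
    """
    cohort_seed, master_seed = _derive_seeds(seed, 2)
    config = CohortConfig(n_sites=n_sites, seed=cohort_seed)
    sheet, beta, _ = generate_cohort(config)
    sim = SimulationConfig(n_simulations=n_simulations,
                           frameworks=("ctlr", "crr"),
                           master_seed=master_seed)
    outcome = run_null_benchmark(beta, sheet, sim)
    c = outcome.counts
    ct = c[(c.framework == "ctlr") & (c.term == "case")]
    ct_means = ct.groupby(["cell_type", "threshold"]).fp_count.mean()
    crr = c[(c.framework == "crr") & (c.term == "any")]
    crr_means = crr.groupby("threshold").fp_count.mean()
    return {
        "ctlr_mean_fp_at_9e-8": float(ct_means.xs(EPIGENOME_WIDE, level="threshold").max()),
        "ctlr_mean_fp_at_1e-6": float(ct_means.xs(1e-6, level="threshold").max()),
        "crr_mean_fp_at_9e-8": float(crr_means.loc[EPIGENOME_WIDE]),
        "crr_mean_fp_at_1e-6": float(crr_means.loc[1e-6]),
        "n_sites": n_sites,
        "n_simulations": n_simulations,
    }


def spiked_tpr_study(seed: int, n_simulations: int = 100,
                     n_sites: int = 6_000, n_dmps: int = 1_000,
                     delta: float = 0.05, prop_specific: float = 0.5) -> dict:
    """Mean true-positive rates over spiked simulations.

    ctLR TPRs are per cell type over DMPs affecting that cell type; CRR
    and the mixed model are scored over all DMPs (any-term policy).
    """
    cohort_seed, master_seed = _derive_seeds(seed, 2)
    config = CohortConfig(n_sites=n_sites, seed=cohort_seed)
    sheet, beta, annotation = generate_cohort(config)
    sim = SimulationConfig(n_simulations=n_simulations,
                           frameworks=("ctlr", "crr", "mer"),
                           n_dmps=n_dmps, delta=delta,
                           prop_specific=prop_specific,
                           master_seed=master_seed)
    outcome = run_spiked_benchmark(beta, sheet, sim, annotation=annotation)
    summ = summarize_benchmark(outcome)

    def tpr(framework, threshold, stratum, cell_type=None):
        sel = summ[(summ.framework == framework)
                   & (summ.threshold == threshold)
                   & (summ.stratum == stratum)]
        if cell_type is not None:
            sel = sel[sel.cell_type == cell_type]
        return float(sel.tpr_mean.iloc[0])

    return {
        "ctlr_tpr_NeuNPos": tpr("ctlr", EPIGENOME_WIDE, "affecting", "NeuNPos"),
        "ctlr_tpr_Sox10Pos": tpr("ctlr", EPIGENOME_WIDE, "affecting", "Sox10Pos"),
        "ctlr_tpr_DoubleNeg": tpr("ctlr", EPIGENOME_WIDE, "affecting", "DoubleNeg"),
        "crr_tpr": tpr("crr", EPIGENOME_WIDE, "all"),
        "mer_tpr": tpr("mer", EPIGENOME_WIDE, "all"),
        "crr_tpr_at_1e-5": tpr("crr", 1e-5, "all"),
        "n_sites": n_sites,
        "n_dmps": n_dmps,
        "n_simulations": n_simulations,
    }
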