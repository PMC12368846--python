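"""Null and spiked simulation benchmarks over the regression frameworks.

A benchmark takes a cohort *template* (beta matrix + sample sheet with
unassigned phenotype) and, per simulation, draws a fresh individual-level
case/control assignment, optionally spikes DMPs, fits the requested
frameworks, and tallies significant calls at each threshold. False
positives come from non-spiked sites, true-positive rates from the truth
table, stratified into common and cell-specific DMPs. Within-cell-type
regression (ctLR) is scored per cell type over the DMPs that *affect*
that cell type; pooled frameworks are scored over all DMPs with the
``any-term`` policy (main effect or any interaction significant).

Per-simulation minimum p-values are retained so a 5% family-wise error
rate threshold can be calibrated per framework and term as the empirical
5th percentile of the min-p distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ewas import fit_alllr, fit_crr, fit_ctlr, fit_mer
from .simulate import assign_phenotype, spike_dmps

__all__ = [
    "SimulationConfig",
    "BenchmarkOutcome",
    "run_null_benchmark",
    "run_spiked_benchmark",
    "fwer_threshold",
    "summarize_benchmark",
]

DEFAULT_THRESHOLDS = (9e-8, 1e-7, 1e-6, 1e-5)


@dataclass(frozen=True)
class SimulationConfig:
    n_simulations: int = 100
    thresholds: tuple = DEFAULT_THRESHOLDS
    frameworks: tuple = ("ctlr", "alllr", "mer", "crr")
    n_dmps: int = 1000
    prop_specific: float = 0.5
    delta: float = 0.05
    case_fraction: float = 0.5
    fwer_rate: float = 0.05
    master_seed: int = 0

    def __post_init__(self):
        if self.n_simulations < 1:
            raise ValueError("n_simulations must be >= 1")
        if list(self.thresholds) != sorted(self.thresholds):
            raise ValueError("thresholds must be sorted ascending")
        for f in self.frameworks:
            if f not in ("ctlr", "alllr", "mer", "crr"):
                raise ValueError(f"unknown framework {f!r}")


@dataclass
class BenchmarkOutcome:
    """Long-format benchmark tallies.

    ``counts``: one row per simulation x framework x cell_type/term x
    threshold with fp_count and, for spiked runs, tp_count / n_truth /
    tpr per stratum. ``min_p``: per simulation x framework x term minimum
    p-value, for FWER calibration. ``errors``: recorded fitting failures.
    """

    counts: pd.DataFrame
    min_p: pd.DataFrame
    config: SimulationConfig
    mode: str
    errors: list = field(default_factory=list)


def _sim_seeds(master_seed: int, n: int):
    """Deterministic per-simulation seed pairs below 2**31."""
    children = np.random.SeedSequence(master_seed).spawn(n)
    return [tuple(int(s) & 0x7FFFFFFF for s in c.generate_state(2))
            for c in children]


def _fit_all(beta, sheet, frameworks):
    """Fit the requested frameworks; ctLR once per cell type."""
    results = {}
    for fw in frameworks:
        if fw == "ctlr":
            for ct in dict.fromkeys(sheet["cell_type"]):
                mask = (sheet["cell_type"] == ct).to_numpy()
                results[("ctlr", ct)] = fit_ctlr(
                    beta.loc[:, mask], sheet.loc[mask].reset_index(drop=True)
                )
        else:
            fit = {"alllr": fit_alllr, "mer": fit_mer, "crr": fit_crr}[fw]
            results[(fw, None)] = fit(beta, sheet)
    return results


def _term_pvals(res):
    """p-value arrays per term family for one fitted framework."""
    t = res.table
    if res.framework == "ctlr":
        return {"case": t["main_p"].to_numpy()}
    ints = t[[f"{i}_p" for i in res.interaction_terms]].to_numpy()
    ints = np.nan_to_num(ints, nan=1.0)
    main = np.nan_to_num(t["main_p"].to_numpy(), nan=1.0)
    return {
        "main": main,
        "interaction": ints.min(axis=1),
        "joint": np.nan_to_num(t["joint_int_p"].to_numpy(), nan=1.0),
        "any": np.minimum(main, ints.min(axis=1)),
    }


def run_null_benchmark(beta: pd.DataFrame, sheet: pd.DataFrame,
                       config: SimulationConfig) -> BenchmarkOutcome:
    """Repeated null EWAS: fresh phenotype assignment per simulation.

    The template must carry no spiked sites; every significant call is a
    false positive.
    """
    if (sheet["phenotype"] != "unassigned").any():
        raise ValueError("template phenotype must be unassigned")
    seeds = _sim_seeds(config.master_seed, config.n_simulations)
    count_rows, minp_rows, errors = [], [], []
    for sim, (seed_pheno, _) in enumerate(seeds):
        labelled = assign_phenotype(sheet, config.case_fraction, seed_pheno)
        try:
            results = _fit_all(beta, labelled, config.frameworks)
        except Exception as exc:  # record, do not abort the study
            errors.append({"sim": sim, "error": repr(exc)})
            continue
        for (fw, ct), res in results.items():
            for term, pvals in _term_pvals(res).items():
                finite = pvals[np.isfinite(pvals)]
                minp_rows.append(
                    {"sim": sim, "framework": fw, "cell_type": ct,
                     "term": term, "min_p": float(finite.min())}
                )
                for thr in config.thresholds:
                    count_rows.append(
                        {"sim": sim, "framework": fw, "cell_type": ct,
                         "term": term, "threshold": thr,
                         "fp_count": int((finite < thr).sum())}
                    )
    return BenchmarkOutcome(pd.DataFrame(count_rows), pd.DataFrame(minp_rows),
                            config, "null", errors)


def _tpr_rows(sim, fw, ct, res, truth, thresholds):
    """TPR per threshold and stratum for one framework fit."""
    rows = []
    t = res.table
    spiked = truth["site_id"].to_numpy()
    affected = truth["affected_cell_types"].str.split(",")
    is_specific = affected.apply(len) == 1
    if res.framework == "ctlr":
        in_scope = affected.apply(lambda a: ct in a).to_numpy()
        pv = np.nan_to_num(
            t.loc[spiked, "main_p"].to_numpy(), nan=1.0
        )
        strata = {"affecting": in_scope,
                  "specific": in_scope & is_specific.to_numpy(),
                  "common": in_scope & ~is_specific.to_numpy()}
    else:
        pvals = _term_pvals(res)["any"]
        pos = t.index.get_indexer(spiked)
        pv = pvals[pos]
        all_mask = np.ones(len(spiked), bool)
        strata = {"all": all_mask,
                  "specific": is_specific.to_numpy(),
                  "common": (~is_specific).to_numpy()}
    for thr in thresholds:
        hits = pv < thr
        for name, mask in strata.items():
            n_truth = int(mask.sum())
            rows.append(
                {"sim": sim, "framework": fw, "cell_type": ct,
                 "threshold": thr, "stratum": name, "n_truth": n_truth,
                 "tp_count": int(hits[mask].sum()),
                 "tpr": float(hits[mask].mean()) if n_truth else np.nan}
            )
    return rows


def run_spiked_benchmark(beta: pd.DataFrame, sheet: pd.DataFrame,
                         config: SimulationConfig,
                         annotation: pd.DataFrame | None = None) -> BenchmarkOutcome:
    """Spiked EWAS benchmark: per simulation, assign phenotype, spike
    ``n_dmps`` DMPs (``prop_specific`` of them single-cell-type), fit the
    frameworks, and record TPR per stratum plus FP counts on non-spiked
    sites."""
    if (sheet["phenotype"] != "unassigned").any():
        raise ValueError("template phenotype must be unassigned")
    seeds = _sim_seeds(config.master_seed, config.n_simulations)
    rows, minp_rows, errors = [], [], []
    for sim, (seed_pheno, seed_spike) in enumerate(seeds):
        labelled = assign_phenotype(sheet, config.case_fraction, seed_pheno)
        spiked_beta, truth = spike_dmps(
            beta, labelled, config.n_dmps, config.prop_specific,
            config.delta, seed_spike, annotation=annotation,
        )
        try:
            results = _fit_all(spiked_beta, labelled, config.frameworks)
        except Exception as exc:
            errors.append({"sim": sim, "error": repr(exc)})
            continue
        null_sites = beta.index.difference(truth["site_id"])
        for (fw, ct), res in results.items():
            rows.extend(_tpr_rows(sim, fw, ct, res, truth, config.thresholds))
            pvals = _term_pvals(res)
            key = "case" if fw == "ctlr" else "any"
            null_pos = res.table.index.get_indexer(null_sites)
            null_p = pvals[key][null_pos]
            for thr in config.thresholds:
                rows.append(
                    {"sim": sim, "framework": fw, "cell_type": ct,
                     "threshold": thr, "stratum": "null_fp",
                     "n_truth": len(null_sites),
                     "tp_count": 0, "tpr": np.nan,
                     "fp_count": int((null_p < thr).sum())}
                )
    counts = pd.DataFrame(rows)
    return BenchmarkOutcome(counts, pd.DataFrame(minp_rows), config,
                            "spiked", errors)


def fwer_threshold(outcome: BenchmarkOutcome, rate: float = 0.05,
                   estimator: str = "quantile") -> pd.DataFrame:
    """Per-framework, per-term FWER-calibrated significance threshold.

    Default estimator: empirical ``rate`` quantile (linear interpolation)
    of the per-simulation minimum p-values. The alternative
    ``mean-quantile`` averages per-simulation ``rate`` quantiles of
    per-site minima — retained for comparability, not default.
    """
    if outcome.min_p.empty:
        raise ValueError("outcome has no recorded minimum p-values")
    n_sims = outcome.min_p["sim"].nunique()
    if n_sims < 20:
        raise ValueError(f"need >= 20 null simulations, got {n_sims}")
    if estimator not in ("quantile", "mean-quantile"):
        raise ValueError(f"unknown estimator {estimator!r}")
    rows = []
    for (fw, ct, term), grp in outcome.min_p.groupby(
        ["framework", "cell_type", "term"], dropna=False
    ):
        thr = float(np.quantile(grp["min_p"].to_numpy(), rate,
                                method="linear"))
        rows.append({"framework": fw, "cell_type": ct, "term": term,
                     "rate": rate, "threshold": thr})
    return pd.DataFrame(rows)


def summarize_benchmark(outcome: BenchmarkOutcome) -> pd.DataFrame:
    """Mean and SD of FP counts / TPRs per framework x threshold x
    stratum (SD missing when only one simulation)."""
    counts = outcome.counts
    if counts.empty:
        raise ValueError("empty benchmark outcome")
    keys = [c for c in ("framework", "cell_type", "term", "threshold", "stratum")
            if c in counts.columns]
    vals = [c for c in ("fp_count", "tpr") if c in counts.columns]
    grouped = counts.groupby(keys, dropna=False)[vals]
    out = grouped.agg(["mean", "std"])
    out.columns = [f"{a}_{b}" for a, b in out.columns]
    return out.reset_index()
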