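"""Between-sample quantile normalization and strategy scoring.

Compares normalizing all cell types jointly against normalizing each cell
type separately, using three signal-to-noise summaries (lower is better):

* **DMRSE** — standard error across samples of the per-sample mean beta
  over imprinted-DMR sites, which should be tightly centred at 0.5;
* **GCOSE** — mean squared deviation of SNP-probe betas from the nearest
  genotype centre {0, 0.5, 1};
* **seabird** — 1 - AUC for separating the sexes by the per-sample mean
  over X-linked sites (0 = perfect separation, 0.5 = uninformative).

The magnitude of the normalization transformation is summarised per
sample as the mean and SD of |normalized - raw| across sites. Plain
between-sample quantile normalization stands in for probe-type-stratified
methods, since probe chemistry is not modelled here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "quantile_normalize",
    "dmrse",
    "gcose",
    "seabird",
    "transformation_magnitude",
    "compare_strategies",
    "MetricReport",
]


def quantile_normalize(beta: pd.DataFrame, groups=None) -> pd.DataFrame:
    """Between-sample quantile normalization within sample groups.

    Every sample's values are replaced rank-wise by the mean of its
    group's order statistics; ties get the value interpolated at the
    average rank. ``groups`` maps sample id -> group label (a dict or
    Series); None normalizes all samples as one group.
    """
    if groups is None:
        groups = pd.Series("all", index=beta.columns)
    else:
        groups = pd.Series(groups).reindex(beta.columns)
        if groups.isna().any():
            missing = list(beta.columns[groups.isna()])
            raise ValueError(f"samples missing from groups: {missing}")
    out = beta.copy()
    n = beta.shape[0]
    positions = np.arange(1, n + 1, dtype=float)
    for g in groups.unique():
        cols = beta.columns[(groups == g).to_numpy()]
        if len(cols) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 samples")
        block = beta[cols].to_numpy(dtype=float)
        ref = np.sort(block, axis=0).mean(axis=1)
        for j, c in enumerate(cols):
            ranks = stats.rankdata(block[:, j], method="average")
            out[c] = np.interp(ranks, positions, ref)
    return out


def _class_sites(annotation: pd.DataFrame, cls: str) -> pd.Index:
    sites = annotation.loc[annotation["site_class"] == cls, "site_id"]
    if len(sites) == 0:
        raise ValueError(f"no sites of class {cls!r} in the annotation")
    return pd.Index(sites)


def dmrse(beta: pd.DataFrame, annotation: pd.DataFrame) -> float:
    """Imprinted-DMR standard error: SE across samples of the per-sample
    mean beta over imprinted sites."""
    sites = _class_sites(annotation, "imprinted_dmr")
    means = beta.loc[beta.index.intersection(sites)].mean(axis=0)
    return float(means.std(ddof=1) / np.sqrt(len(means)))


def gcose(beta: pd.DataFrame, annotation: pd.DataFrame) -> float:
    """SNP-probe genotype-cluster score: mean squared deviation from the
    nearest of {0, 0.5, 1} over all (site, sample)."""
    sites = _class_sites(annotation, "snp_probe")
    vals = beta.loc[beta.index.intersection(sites)].to_numpy(dtype=float)
    centres = np.array([0.0, 0.5, 1.0])
    nearest = centres[np.argmin(np.abs(vals[..., None] - centres), axis=-1)]
    return float(np.mean((vals - nearest) ** 2))


def seabird(beta: pd.DataFrame, annotation: pd.DataFrame,
            sheet: pd.DataFrame) -> float:
    """X-inactivation sex-separation score: 1 - AUC of separating the two
    sexes by the per-sample mean over X-linked sites, oriented so the
    score is <= 0.5 and 0 means perfect separation."""
    sites = _class_sites(annotation, "x_linked")
    summary = beta.loc[beta.index.intersection(sites)].mean(axis=0)
    sex = sheet.set_index("sample_id").loc[summary.index, "sex"]
    levels = sex.unique()
    if len(levels) < 2:
        raise ValueError("seabird requires both sexes in the cohort")
    a = summary[(sex == levels[0]).to_numpy()].to_numpy()
    b = summary[(sex == levels[1]).to_numpy()].to_numpy()
    u = stats.mannwhitneyu(a, b, alternative="two-sided").statistic
    auc = u / (len(a) * len(b))
    return float(min(auc, 1.0 - auc))


def transformation_magnitude(raw: pd.DataFrame,
                             normalized: pd.DataFrame) -> pd.DataFrame:
    """Per-sample mean and SD across sites of |normalized - raw|."""
    if raw.shape != normalized.shape or list(raw.columns) != list(normalized.columns):
        raise ValueError("matrices are not aligned")
    diff = np.abs(normalized.to_numpy(dtype=float)
                  - raw.loc[normalized.index].to_numpy(dtype=float))
    return pd.DataFrame(
        {"mean_abs_change": diff.mean(axis=0), "sd_abs_change": diff.std(axis=0, ddof=1)},
        index=raw.columns,
    )


@dataclass
class MetricReport:
    """Normalization-strategy comparison.

    ``scores``: rows raw / joint / per_cell_type, columns dmrse / gcose /
    seabird. ``magnitudes``: per sample x strategy mean and SD of the
    absolute transformation.
    """

    scores: pd.DataFrame
    magnitudes: pd.DataFrame

    def best_strategy(self, metric: str) -> str:
        return str(self.scores[metric].idxmin())

    def to_csv(self, path):
        self.scores.rename_axis("strategy").to_csv(path)


def compare_strategies(beta: pd.DataFrame, annotation: pd.DataFrame,
                       sheet: pd.DataFrame) -> MetricReport:
    """Score raw, jointly-normalized and per-cell-type-normalized data."""
    strategies = {
        "raw": beta,
        "joint": quantile_normalize(beta),
        "per_cell_type": quantile_normalize(
            beta, dict(zip(sheet["sample_id"], sheet["cell_type"]))
        ),
    }
    rows = {}
    mags = []
    for name, mat in strategies.items():
        rows[name] = {
            "dmrse": dmrse(mat, annotation),
            "gcose": gcose(mat, annotation),
            "seabird": seabird(mat, annotation, sheet),
        }
        if name != "raw":
            m = transformation_magnitude(beta, mat)
            m.insert(0, "strategy", name)
            m.insert(0, "cell_type",
                     sheet.set_index("sample_id").loc[m.index, "cell_type"])
            mags.append(m)
    scores = pd.DataFrame(rows).T[["dmrse", "gcose", "seabird"]]
    return MetricReport(scores, pd.concat(mags).rename_axis("sample_id"))
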