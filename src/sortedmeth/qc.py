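"""Stage-3 quality control: confirming the correctly labelled cell type.

Cell-type identity dominates the variance of sorted methylation profiles,
so the leading principal components of the site-centered beta matrix
cluster samples by fraction. Two metrics are computed in PC space:

* an individual-level *isolation efficiency score* — the maximum, over a
  donor's samples, of the Euclidean norm of per-PC z-distances to the
  sample's labelled cell-type centroid (max, not mean, so that one failed
  fraction flags the whole sort); donors above a threshold (default 5 SD
  units) are flagged;
* a per-sample *cell-type distance filter* retaining samples within a
  threshold (default 2 SD) of their labelled cell-type mean separately on
  each of the first two PCs, in a single pass.

Stage 1 (array quality) and Stage 2 (sex/genotype concordance) need raw
array channels and are represented only by not-evaluated placeholders in
the report.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

__all__ = [
    "QCConfig",
    "PCScores",
    "QCReport",
    "compute_pcs",
    "isolation_efficiency_score",
    "celltype_distance_filter",
    "run_stage3",
]


class DegenerateInputError(ValueError):
    pass


class InsufficientGroupError(ValueError):
    pass


@dataclass(frozen=True)
class QCConfig:
    n_pcs: int = 2
    score_threshold: float = 5.0
    sd_threshold: float = 2.0
    max_variable_sites: int | None = None  # e.g. 20_000 for speed; default all

    def __post_init__(self):
        if self.score_threshold <= 0 or self.sd_threshold <= 0 or self.n_pcs < 1:
            raise ValueError("QC thresholds and n_pcs must be positive")


@dataclass
class PCScores:
    sample_ids: pd.Index
    scores: np.ndarray  # samples x k
    explained_variance: np.ndarray  # fraction per component

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.scores,
            index=self.sample_ids,
            columns=[f"PC{i + 1}" for i in range(self.scores.shape[1])],
        )


def compute_pcs(beta: pd.DataFrame, n_components: int = 2,
                max_variable_sites: int | None = None) -> PCScores:
    """PCA of the site-centered beta matrix over all samples.

    Sign convention: each component is flipped so that its
    largest-magnitude site loading is positive, making scores
    reproducible across site/sample orderings.
    """
    n_samples = beta.shape[1]
    if n_samples < 2:
        raise ValueError("need at least 2 samples")
    if n_components > min(beta.shape):
        raise ValueError("n_components exceeds min(sites, samples)")
    mat = beta.to_numpy(dtype=float)
    if max_variable_sites is not None and max_variable_sites < mat.shape[0]:
        var = mat.var(axis=1)
        keep = np.sort(np.argsort(var, kind="stable")[::-1][:max_variable_sites])
        mat = mat[keep]
    if np.allclose(mat, mat[:, [0]]):
        raise DegenerateInputError("beta matrix is constant across samples")
    centered = (mat - mat.mean(axis=1, keepdims=True)).T  # samples x sites
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(centered)
    # deterministic sign: largest |loading| positive
    for j in range(n_components):
        load = pca.components_[j]
        if load[np.argmax(np.abs(load))] < 0:
            scores[:, j] *= -1.0
    return PCScores(beta.columns, scores, pca.explained_variance_ratio_.copy())


def _z_distances(pcs: PCScores, sheet: pd.DataFrame, n_pcs: int) -> pd.DataFrame:
    """Per-sample per-PC z-scores relative to the labelled cell-type
    centroid and SD (computed over that cell type's samples)."""
    k = min(n_pcs, pcs.scores.shape[1])
    frame = pcs.frame().iloc[:, :k]
    ct = sheet.set_index("sample_id").loc[frame.index, "cell_type"]
    out = pd.DataFrame(index=frame.index)
    for c in ct.unique():
        mask = (ct == c).to_numpy()
        if mask.sum() < 3:
            raise InsufficientGroupError(
                f"cell type {c!r} has fewer than 3 samples"
            )
        grp = frame.loc[mask]
        # zero SD (all samples at the centroid) maps to z = 0, not NaN
        sd = grp.std(axis=0, ddof=1).replace(0.0, np.inf)
        z = (grp - grp.mean(axis=0)) / sd
        out.loc[mask, [f"z_PC{i + 1}" for i in range(k)]] = z.to_numpy()
    out["cell_type"] = ct
    return out


def isolation_efficiency_score(pcs: PCScores, sheet: pd.DataFrame,
                               config: QCConfig = QCConfig()) -> pd.DataFrame:
    """Per-individual isolation efficiency score.

    Score = max over the donor's samples of the Euclidean norm of per-PC
    z-distances (first ``config.n_pcs`` PCs); donors with score above
    ``config.score_threshold`` are flagged.
    """
    z = _z_distances(pcs, sheet, config.n_pcs)
    zcols = [c for c in z.columns if c.startswith("z_PC")]
    dist = np.sqrt((z[zcols] ** 2).sum(axis=1))
    ind = sheet.set_index("sample_id").loc[dist.index, "individual_id"]
    score = dist.groupby(ind).max()
    return pd.DataFrame(
        {
            "individual_id": score.index,
            "isolation_score": score.to_numpy(),
            "flagged": (score > config.score_threshold).to_numpy(),
        }
    ).reset_index(drop=True)


def celltype_distance_filter(pcs: PCScores, sheet: pd.DataFrame,
                             config: QCConfig = QCConfig()) -> pd.DataFrame:
    """Retain samples within ``sd_threshold`` SDs of their cell-type mean
    on each of the first two PCs (per-PC rule, statistics computed once
    on the full sample set)."""
    z = _z_distances(pcs, sheet, n_pcs=2)
    zcols = [c for c in z.columns if c.startswith("z_PC")]
    retained = (z[zcols].abs() <= config.sd_threshold).all(axis=1)
    out = z.copy()
    out["retained"] = retained
    return out.reset_index().rename(columns={"index": "sample_id"})


@dataclass
class QCReport:
    samples: pd.DataFrame      # per-sample distances + retained flag
    individuals: pd.DataFrame  # per-individual score + flagged
    summary: dict = field(default_factory=dict)
    stage1: str = "not_evaluated"  # array quality: needs raw intensities
    stage2: str = "not_evaluated"  # sex/genotype concordance: needs raw data

    def to_csv(self, path):
        tab = self.samples.copy()
        ind = self.individuals.set_index("individual_id")
        tab["isolation_score"] = (
            tab["sample_id"].map(self._sample_individual).map(ind["isolation_score"])
        )
        tab["individual_flagged"] = (
            tab["sample_id"].map(self._sample_individual).map(ind["flagged"])
        )
        tab["stage1"] = self.stage1
        tab["stage2"] = self.stage2
        tab.to_csv(path, index=False)

    _sample_individual: dict = field(default_factory=dict, repr=False)


def run_stage3(beta: pd.DataFrame, sheet: pd.DataFrame,
               config: QCConfig = QCConfig()) -> QCReport:
    """Compose the isolation score and distance filter into one report."""
    if list(beta.columns) != list(sheet["sample_id"]):
        raise ValueError("beta columns must match sheet sample_id order")
    pcs = compute_pcs(beta, n_components=max(config.n_pcs, 2),
                      max_variable_sites=config.max_variable_sites)
    samples = celltype_distance_filter(pcs, sheet, config)
    individuals = isolation_efficiency_score(pcs, sheet, config)
    summary = {
        "n_samples": int(len(samples)),
        "n_retained": int(samples["retained"].sum()),
        "n_individuals": int(len(individuals)),
        "n_flagged_individuals": int(individuals["flagged"].sum()),
        "explained_variance": [float(v) for v in pcs.explained_variance],
    }
    report = QCReport(samples, individuals, summary)
    report._sample_individual = dict(
        zip(sheet["sample_id"], sheet["individual_id"])
    )
    return report
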