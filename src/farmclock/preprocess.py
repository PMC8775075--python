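"""Beta-value computation, masking/imputation and sample-level QC.

Methylation level at a CpG probe is summarized as a beta value,
``beta = M / (M + U + a)`` with methylated/unmethylated intensities M, U
and a small stabilizing offset ``a`` (typically 100).  Failed measurements
(e.g. flagged by a detection p-value) are represented as masked entries
(NaN) and either mean-imputed or, when a probe fails in too many samples,
dropped entirely: the penalized regressions downstream need complete
predictor matrices.

Sample-level QC follows standard methylation-array practice: an
average-linkage hierarchical clustering of sample beta profiles (distance
1 - Pearson correlation) to reveal structure such as species groups, and a
sex check that predicts each sample's sex from sex-informative probes and
flags samples whose recorded sex disagrees — a common symptom of sample
swaps or contamination.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

__all__ = [
    "SAMPLE_SHEET_COLUMNS",
    "MethylationDataset",
    "QCReport",
    "compute_beta",
    "apply_mask",
    "impute_masked",
    "cluster_samples",
    "sex_check",
]

SAMPLE_SHEET_COLUMNS = ("sample_id", "species", "sex", "age_days", "batch")
_BINARY_SEXES = ("female", "male")


def compute_beta(methylated, unmethylated, offset: float = 100.0):
    """Beta value ``M / (M + U + offset)`` from signal intensities.

    Scalar or array inputs (broadcast together).  With ``offset > 0`` the
    result is strictly below 1; it is always within ``[0, 1)`` for valid
    inputs (or exactly 1 only when U and offset are both 0).

    Raises
    ------
    ValueError
        On negative intensities or offset, or when M + U + offset is zero
        (undefined ratio).
    """
    m = np.asarray(methylated, dtype=float)
    u = np.asarray(unmethylated, dtype=float)
    if offset < 0:
        raise ValueError(f"offset must be non-negative, got {offset!r}")
    if np.any(m < 0) or np.any(u < 0):
        raise ValueError("signal intensities must be non-negative")
    denom = m + u + offset
    if np.any(denom == 0):
        raise ValueError("M + U + offset is zero: beta value undefined")
    out = m / denom
    return out if out.ndim else float(out)


@dataclass
class MethylationDataset:
    """A beta matrix (samples x probes) with an aligned sample sheet.

    ``beta`` is indexed by sample_id with probe ids as columns; masked
    entries are NaN.  ``samples`` carries one row per sample with columns
    species, sex (female / male / other), age_days and batch, indexed by
    sample_id in the same order as ``beta``.
    """

    beta: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if len(self.beta) != len(self.samples):
            raise ValueError(
                f"sample sheet has {len(self.samples)} rows but beta matrix "
                f"has {len(self.beta)}"
            )
        if not self.beta.index.equals(self.samples.index):
            raise ValueError("beta matrix and sample sheet must share sample ids in order")
        missing = [c for c in ("species", "sex", "age_days", "batch") if c not in self.samples]
        if missing:
            raise ValueError(f"sample sheet missing required columns: {missing}")
        values = self.beta.to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            bad = (values < 0) | (values > 1)
        if np.any(bad):
            raise ValueError("beta values must lie in [0, 1] (or NaN when masked)")
        ages = self.samples["age_days"].to_numpy(dtype=float)
        if np.any(~np.isfinite(ages)) or np.any(ages < 0):
            raise ValueError("age_days must be finite and non-negative for all samples")

    @property
    def n_samples(self) -> int:
        return len(self.beta)

    @property
    def n_probes(self) -> int:
        return self.beta.shape[1]

    @property
    def probe_ids(self) -> pd.Index:
        return self.beta.columns

    @property
    def sample_ids(self) -> pd.Index:
        return self.beta.index

    @property
    def species(self) -> pd.Series:
        return self.samples["species"]

    @property
    def age_days(self) -> pd.Series:
        return self.samples["age_days"].astype(float)

    def species_names(self) -> list[str]:
        """Distinct species, in order of first appearance."""
        return list(dict.fromkeys(self.samples["species"]))

    def subset_samples(self, sample_ids: Sequence) -> "MethylationDataset":
        ids = pd.Index(sample_ids)
        return MethylationDataset(self.beta.loc[ids].copy(), self.samples.loc[ids].copy())

    def drop_samples(self, sample_ids: Sequence) -> "MethylationDataset":
        keep = self.beta.index.difference(pd.Index(sample_ids), sort=False)
        return self.subset_samples(keep)

    def is_complete(self) -> bool:
        return not self.beta.isna().any().any()


@dataclass
class QCReport:
    """Per-sample QC outcomes.

    ``excluded_samples`` maps sample_id -> reason; exclusion is always
    explicit and logged, never silent.
    """

    cluster_assignments: Optional[pd.Series] = None
    predicted_sex: Optional[pd.Series] = None
    excluded_samples: dict[str, str] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        """Tabular report: one row per sample seen by any check."""
        parts = {}
        if self.cluster_assignments is not None:
            parts["cluster"] = self.cluster_assignments
        if self.predicted_sex is not None:
            parts["predicted_sex"] = self.predicted_sex
        frame = pd.DataFrame(parts)
        frame["excluded"] = frame.index.isin(self.excluded_samples)
        frame["reason"] = [self.excluded_samples.get(s, "") for s in frame.index]
        frame.index.name = "sample_id"
        return frame


def apply_mask(
    dataset: MethylationDataset,
    detection_p: pd.DataFrame | np.ndarray,
    threshold: float = 0.05,
) -> MethylationDataset:
    """Mask beta entries whose detection p-value is >= ``threshold``.

    Entries below the threshold are left untouched; the operation is
    idempotent.  ``detection_p`` must have the same shape as the beta
    matrix (a DataFrame is aligned positionally).
    """
    p = np.asarray(detection_p, dtype=float)
    if p.shape != dataset.beta.shape:
        raise ValueError(
            f"detection_p shape {p.shape} does not match beta shape {dataset.beta.shape}"
        )
    masked = dataset.beta.where(p < threshold)
    return MethylationDataset(masked, dataset.samples.copy())


def impute_masked(
    dataset: MethylationDataset,
    by_species: bool = True,
    max_masked_frac: float = 0.5,
) -> MethylationDataset:
    """Fill masked entries with per-probe means; drop mostly-masked probes.

    Probes masked in more than ``max_masked_frac`` of samples are removed
    (imputation would dominate any signal there).  Remaining NaNs are
    replaced with the probe mean computed within each sample's species
    (``by_species=True``, appropriate for species-specific clocks) or over
    all samples (for pooled multi-species fits).  A probe whose values are
    all masked within one species falls back to the global probe mean.
    """
    beta = dataset.beta
    frac_masked = beta.isna().mean(axis=0)
    keep = frac_masked[frac_masked <= max_masked_frac].index
    beta = beta[keep]
    if beta.isna().any().any():
        if by_species:
            filled = beta.groupby(dataset.species, sort=False).transform(
                lambda g: g.fillna(g.mean())
            )
        else:
            filled = beta
        filled = filled.fillna(beta.mean(axis=0))
        beta = filled
    return MethylationDataset(beta.copy(), dataset.samples.copy())


def cluster_samples(
    dataset: MethylationDataset,
    n_clusters: Optional[int] = None,
) -> QCReport:
    """Average-linkage hierarchical clustering of sample beta profiles.

    Distance is 1 - Pearson correlation between sample rows.  The tree is
    cut at ``n_clusters`` (default: the number of distinct species), which
    on well-behaved data recovers the species partition.  Masked entries
    are mean-imputed first.  Deterministic given the input.
    """
    if dataset.n_samples < 2:
        raise ValueError("clustering requires at least 2 samples")
    if n_clusters is None:
        n_clusters = len(dataset.species_names())
    work = impute_masked(dataset, by_species=False) if not dataset.is_complete() else dataset
    values = work.beta.to_numpy(dtype=float)
    # correlation of constant rows is undefined; jitter-free guard via std
    stds = values.std(axis=1)
    corr = np.corrcoef(values)
    corr[~np.isfinite(corr)] = 0.0
    np.fill_diagonal(corr, 1.0)
    if np.any(stds == 0):
        # identical constant rows are perfectly similar
        zero = np.where(stds == 0)[0]
        for i in zero:
            same = np.all(values == values[i], axis=1)
            corr[i, same] = 1.0
            corr[same, i] = 1.0
    dist = np.clip(1.0 - corr, 0.0, None)
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2.0
    tree = linkage(squareform(dist, checks=False), method="average")
    labels = fcluster(tree, t=n_clusters, criterion="maxclust")
    assignments = pd.Series(labels, index=dataset.sample_ids, name="cluster")
    return QCReport(cluster_assignments=assignments)


def sex_check(
    dataset: MethylationDataset,
    sex_probe_ids: Sequence[str],
) -> QCReport:
    """Predict sample sex from sex-informative probes; flag mismatches.

    Within each species, female and male centroids are computed on the
    sex-probe submatrix from samples with a binary recorded sex; every
    sample is assigned the sex of its nearest centroid (Euclidean
    distance).  Samples whose recorded sex is binary and disagrees with the
    prediction are listed in ``excluded_samples`` with reason
    ``"sex_mismatch"``; samples recorded as anything other than
    female/male are reported but never excluded by this check.
    """
    probes = [p for p in sex_probe_ids if p in dataset.beta.columns]
    if not probes:
        raise ValueError("none of the supplied sex probes are present in the dataset")
    sub = dataset.beta[probes]
    if sub.isna().any().any():
        sub = impute_masked(
            MethylationDataset(sub, dataset.samples), by_species=False, max_masked_frac=1.0
        ).beta
    recorded = dataset.samples["sex"].astype(str).str.lower()
    predicted = pd.Series(index=dataset.sample_ids, dtype=object, name="predicted_sex")
    excluded: dict[str, str] = {}
    for species, idx in dataset.samples.groupby("species", sort=False).groups.items():
        block = sub.loc[idx]
        rec = recorded.loc[idx]
        centroids = {}
        for sex in _BINARY_SEXES:
            members = block[rec == sex]
            if members.empty:
                raise ValueError(
                    f"species {species!r} has no recorded {sex} samples; "
                    "sex check needs both sexes represented"
                )
            centroids[sex] = members.mean(axis=0).to_numpy()
        values = block.to_numpy(dtype=float)
        dists = np.stack(
            [np.linalg.norm(values - centroids[s], axis=1) for s in _BINARY_SEXES], axis=1
        )
        calls = np.array(_BINARY_SEXES)[dists.argmin(axis=1)]
        predicted.loc[idx] = calls
        mismatch = (rec.isin(_BINARY_SEXES)) & (rec != calls)
        for sid in rec.index[mismatch]:
            excluded[sid] = "sex_mismatch"
    return QCReport(predicted_sex=predicted, excluded_samples=excluded)
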