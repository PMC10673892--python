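"""Expression-atlas preparation and QC.

Covers the pre-network steps: the TPM expression filter, parts-per-million
normalization of the metabolite matrix, within-tissue replicate concordance,
and a classical MDS (PCoA) ordination of samples on correlation distance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import DistanceMatrix
from skbio.stats.ordination import pcoa


class ParameterError(ValueError):
    pass


class ValidationError(ValueError):
    pass


@dataclass
class ExpressionAtlas:
    """A transcripts x samples TPM matrix with per-sample tissue/replicate metadata."""

    matrix: pd.DataFrame
    sample_meta: pd.DataFrame  # index = sample id; columns tissue_type, replicate

    def __post_init__(self) -> None:
        if (self.matrix.values < 0).any():
            raise ValidationError("TPM values must be non-negative")
        if self.matrix.index.has_duplicates:
            raise ValidationError("duplicate transcript ids")
        missing = [s for s in self.matrix.columns if s not in self.sample_meta.index]
        if missing:
            raise ValidationError(f"samples without metadata: {missing[:5]}")
        if "tissue_type" not in self.sample_meta.columns:
            raise ValidationError("sample_meta must carry a tissue_type column")

    @property
    def n_transcripts(self) -> int:
        return self.matrix.shape[0]

    @property
    def samples(self) -> list[str]:
        return list(self.matrix.columns)

    def tissues_of(self) -> pd.Series:
        return self.sample_meta.loc[self.matrix.columns, "tissue_type"]


@dataclass
class MetaboliteMatrix:
    """A metabolites x samples abundance matrix, optionally ppm-normalized."""

    matrix: pd.DataFrame
    normalized: bool = False
    zero_samples: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if (self.matrix.values < 0).any():
            raise ValidationError("metabolite abundances must be non-negative")
        if self.normalized:
            sums = self.matrix.sum(axis=0)
            nonzero = sums[sums > 0]
            if not np.allclose(nonzero, 1e6, rtol=1e-6):
                raise ValidationError("normalized columns must each sum to 1e6")


def tpm_filter(
    atlas: ExpressionAtlas, min_tpm: float = 10.0, min_samples: int = 6
) -> ExpressionAtlas:
    """Keep transcripts with TPM strictly above ``min_tpm`` in strictly more
    than ``min_samples`` samples (defaults reproduce the published filter:
    above 10 TPM in at least 7 of the samples).  The sample set is unchanged.
    """
    if min_tpm < 0:
        raise ParameterError(f"min_tpm must be >= 0, got {min_tpm}")
    if min_samples < 0:
        raise ParameterError(f"min_samples must be >= 0, got {min_samples}")
    exceed = (atlas.matrix.values > min_tpm).sum(axis=1)
    keep = exceed > min_samples
    return ExpressionAtlas(atlas.matrix.loc[keep].copy(), atlas.sample_meta)


def metabolites_to_ppm(raw: MetaboliteMatrix) -> MetaboliteMatrix:
    """Convert each sample column to parts per million of its column sum.

    All-zero columns are left as zeros and reported in ``zero_samples``.
    Idempotent (up to float tolerance) on already-normalized input.
    """
    if (raw.matrix.values < 0).any():
        raise ValidationError("negative metabolite abundance")
    sums = raw.matrix.sum(axis=0)
    zero_cols = tuple(sums.index[sums == 0])
    if zero_cols:
        warnings.warn(f"all-zero metabolite columns left untouched: {zero_cols[:5]}")
    safe = sums.replace(0.0, np.nan)
    ppm = raw.matrix.div(safe, axis=1).fillna(0.0) * 1e6
    return MetaboliteMatrix(ppm, normalized=True, zero_samples=zero_cols)


def replicate_correlation(atlas: ExpressionAtlas) -> dict:
    """Within-tissue replicate concordance on log2(TPM+1) profiles.

    For each tissue, Pearson r is computed across transcripts for every
    replicate pair and averaged; the overall figure is the unweighted mean
    and sd over tissues.  Tissues with a single replicate are excluded with
    a warning.
    """
    log = np.log2(atlas.matrix.values + 1.0)
    cols = {s: i for i, s in enumerate(atlas.matrix.columns)}
    per_tissue: dict[str, float] = {}
    for tissue, group in atlas.sample_meta.loc[atlas.matrix.columns].groupby(
        "tissue_type", sort=True
    ):
        samples = [s for s in group.index]
        if len(samples) < 2:
            warnings.warn(f"tissue {tissue!r} has a single replicate; excluded")
            continue
        rs = []
        for i in range(len(samples)):
            for j in range(i + 1, len(samples)):
                a, b = log[:, cols[samples[i]]], log[:, cols[samples[j]]]
                rs.append(float(np.corrcoef(a, b)[0, 1]))
        per_tissue[tissue] = float(np.mean(rs))
    vals = np.array(list(per_tissue.values()))
    return {
        "per_tissue": per_tissue,
        "mean": float(vals.mean()) if vals.size else float("nan"),
        "sd": float(vals.std(ddof=1)) if vals.size > 1 else float("nan"),
    }


def mds_projection(atlas: ExpressionAtlas, n_dims: int = 2) -> pd.DataFrame:
    """Classical MDS (PCoA) of samples on 1 - Pearson r distance.

    Correlations are computed across transcripts on log2(TPM+1).  Constant
    sample vectors are excluded with a warning.  Coordinates are centered at
    the origin by construction.
    """
    if atlas.matrix.shape[1] < 3:
        raise ValidationError("MDS needs at least 3 samples")
    log = np.log2(atlas.matrix.values + 1.0)
    sd = log.std(axis=0)
    keep = sd > 0
    if not keep.all():
        dropped = [s for s, k in zip(atlas.matrix.columns, keep) if not k]
        warnings.warn(f"constant sample vectors excluded from MDS: {dropped[:5]}")
    cols = [s for s, k in zip(atlas.matrix.columns, keep) if k]
    corr = np.corrcoef(log[:, keep], rowvar=False)
    dist = np.clip(1.0 - corr, 0.0, None)
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # pcoa warns on negative eigenvalues
        res = pcoa(DistanceMatrix(dist, ids=cols), number_of_dimensions=n_dims)
    coords = res.samples.iloc[:, :n_dims].copy()
    coords.columns = [f"dim{i + 1}" for i in range(coords.shape[1])]
    coords.index.name = "sample"
    return coords
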