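"""Median-of-ratios size-factor normalization and the log2(x+1) transform.

Sequencing depth differs across subjects, so raw transcript counts are not
comparable between columns. The median-of-ratios estimator builds a
reference pseudo-sample (the per-transcript geometric mean across
subjects) and takes, for each subject, the median ratio of its counts to
that reference over all transcripts expressed in every subject. It is
implemented here directly from that definition.

Scaled counts are then variance-compressed with log2(count/factor + 1),
which maps zeros to zero and spans the ~6-log abundance range of plaque
taxa onto a comparable scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import CountMatrix, NormalizationError


@dataclass
class ScalingFactors:
    """Per-subject size factors plus the reference pseudo-sample used."""

    factors: pd.Series  # indexed by subject id, all > 0
    reference: pd.Series  # per-transcript geometric mean (eligible transcripts only)

    def to_tsv(self, path: str | Path) -> None:
        df = self.factors.rename("size_factor").to_frame()
        df.index.name = "subject_id"
        df.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ScalingFactors":
        df = pd.read_csv(path, sep="\t", index_col="subject_id")
        return cls(factors=df["size_factor"], reference=pd.Series(dtype=float))


def size_factors(counts: CountMatrix | pd.DataFrame) -> ScalingFactors:
    """Median-of-ratios size factors.

    Only transcripts with strictly positive counts in *every* subject enter
    the estimate (the log geometric mean is undefined otherwise); the
    factor for subject j is the median over those transcripts of
    count[i, j] / geomean_i. The even-length median is the mean of the two
    central ratios.
    """
    mat = counts.counts if isinstance(counts, CountMatrix) else counts
    if mat.shape[1] < 2:
        raise NormalizationError("size factors need at least 2 subjects")
    values = mat.to_numpy(dtype=float)
    eligible = (values > 0).all(axis=1)
    if not eligible.any():
        raise NormalizationError(
            "no transcript has strictly positive counts in all subjects; "
            "the median-of-ratios reference is undefined"
        )
    pos = values[eligible]
    log_geomean = np.log(pos).mean(axis=1)
    ratios = pos / np.exp(log_geomean)[:, None]
    factors = np.median(ratios, axis=0)
    return ScalingFactors(
        factors=pd.Series(factors, index=mat.columns, name="size_factor"),
        reference=pd.Series(np.exp(log_geomean), index=mat.index[eligible]),
    )


def scale_and_log(
    counts: CountMatrix | pd.DataFrame, factors: ScalingFactors
) -> pd.DataFrame:
    """Elementwise log2(count / size_factor + 1); zero counts map to 0."""
    mat = counts.counts if isinstance(counts, CountMatrix) else counts
    f = factors.factors.reindex(mat.columns)
    if f.isna().any():
        missing = list(f.index[f.isna()])
        raise NormalizationError(f"no size factor for subjects: {missing}")
    if (f <= 0).any():
        raise NormalizationError("size factors must be strictly positive")
    return np.log2(mat.div(f, axis=1) + 1.0)
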