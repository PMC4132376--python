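"""Taxon abundance profiles, the core microbiota, and variability statistics.

Transcript counts are summed within species or genus, converted to
per-subject relative abundances, and screened for the *functional core
microbiota*: taxa expressed above a presence threshold in every subject.
Cross-subject variability of scaled-log2 abundances is summarized with
box-plot statistics (Tukey fences at 1.5 x IQR) and a 2-SD
extreme-variation flag.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datatypes import CountMatrix, ProfileError, TaxonProfile
from .normalize import ScalingFactors, scale_and_log


def aggregate(counts: CountMatrix, level: str = "species") -> TaxonProfile:
    """Sum transcript counts within each taxon at the requested level.

    Per-subject totals are unchanged by aggregation. Transcripts lacking an
    annotation at the level are an error (listed by id).
    """
    if level not in ("species", "genus"):
        raise ProfileError(f"level must be 'species' or 'genus', got {level!r}")
    labels = counts.annotations[level]
    missing = labels.isna() | (labels.astype(str).str.len() == 0)
    if missing.any():
        ids = list(counts.counts.index[missing])
        raise ProfileError(f"transcripts missing {level} annotation: {ids[:20]}")
    raw = counts.counts.groupby(labels).sum()
    raw.index.name = level
    return TaxonProfile(level=level, layers={"raw": raw})


def relative_abundance(profile: TaxonProfile) -> TaxonProfile:
    """Add a ``relative`` layer: per-subject proportions of the raw layer."""
    raw = profile.layer("raw")
    totals = raw.sum(axis=0)
    zero = totals[totals <= 0]
    if len(zero):
        raise ProfileError(f"subjects with all-zero counts: {list(zero.index)}")
    profile.layers["relative"] = raw.div(totals, axis=1)
    return profile


def add_scaled_log2(profile: TaxonProfile, factors: ScalingFactors) -> TaxonProfile:
    """Add a ``scaled_log2`` layer: log2(count/size_factor + 1) on the raw layer."""
    profile.layers["scaled_log2"] = scale_and_log(profile.layer("raw"), factors)
    return profile


def core_taxa(profile: TaxonProfile, min_count: int = 10) -> list[str]:
    """Taxa with raw count >= min_count in *every* subject (prevalence = all).

    This is the functional core microbiota definition: a taxon must be
    detected above the presence threshold in each subject of the cohort.
    """
    if min_count < 1:
        raise ProfileError("min_count must be >= 1")
    raw = profile.layer("raw")
    keep = (raw >= min_count).all(axis=1)
    return list(raw.index[keep])


def variability(profile: TaxonProfile) -> pd.DataFrame:
    """Box-plot statistics of scaled-log2 abundance per taxon across subjects.

    Quartiles use linear interpolation of the empirical CDF. A subject is an
    outlier for a taxon when its value lies beyond 1.5 x IQR outside the
    quartiles (Tukey fences); a taxon carries the ``extreme_variation`` flag
    when any value lies beyond mean +/- 2 SD (SD with n-1 denominator).
    """
    log2 = profile.layer("scaled_log2")
    if log2.shape[1] < 4:
        raise ProfileError("quartile statistics need at least 4 subjects")
    vals = log2.to_numpy()
    q1, med, q3 = np.percentile(vals, [25, 50, 75], axis=1)
    iqr = q3 - q1
    lo_fence = q1 - 1.5 * iqr
    hi_fence = q3 + 1.5 * iqr
    mean = vals.mean(axis=1)
    sd = vals.std(axis=1, ddof=1)

    outlier_mask = (vals < lo_fence[:, None]) | (vals > hi_fence[:, None])
    n_extreme = np.zeros(len(vals), dtype=int)
    nz = sd > 0
    n_extreme[nz] = (np.abs(vals[nz] - mean[nz, None]) > 2 * sd[nz, None]).sum(axis=1)
    extreme = n_extreme > 0

    subjects = np.array(log2.columns)
    report = pd.DataFrame(
        {
            "median": med,
            "q1": q1,
            "q3": q3,
            "iqr": iqr,
            "n_outliers": outlier_mask.sum(axis=1),
            "outlier_subjects": [
                ",".join(subjects[row]) for row in outlier_mask
            ],
            "n_extreme": n_extreme,
            "extreme_variation": extreme,
        },
        index=log2.index,
    )
    report.index.name = profile.level
    return report
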