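"""Functional role-category aggregation.

Expressed transcripts are summarized through a three-level functional
hierarchy (function -> subsystem -> role category), the way SEED-style
subsystem annotations summarize a metatranscriptome. The hierarchy is an
input table, so any annotation source can be plugged in; a default
hierarchy covering the dominant plaque-biofilm functions (translation,
RNA metabolism, carbohydrate utilization, stress response with an
oxidative-stress subsystem, resistance to antibiotics and toxic
compounds) ships with the package and is what the synthetic generator
uses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import CountMatrix, ProfileError

logger = logging.getLogger(__name__)

UNASSIGNED = "unassigned"

LEVELS = ("function", "subsystem", "category")

# (function, subsystem, category, sampling weight for the generator)
DEFAULT_ROLE_TABLE: list[tuple[str, str, str, float]] = [
    ("ribosomal protein biogenesis", "Ribosome", "Protein translation", 9.0),
    ("translation elongation factor EF-Tu", "Elongation", "Protein translation", 2.5),
    ("translation elongation factor EF-G", "Elongation", "Protein translation", 1.5),
    ("aminoacyl-tRNA synthetase", "tRNA charging", "Protein translation", 2.0),
    ("RNA polymerase subunit", "Transcription", "RNA metabolism", 3.0),
    ("ribonuclease", "RNA processing", "RNA metabolism", 1.0),
    ("glyceraldehyde-3-phosphate dehydrogenase", "Glycolysis", "Carbohydrate utilization", 3.0),
    ("fructose-bisphosphate aldolase", "Glycolysis", "Carbohydrate utilization", 1.0),
    ("phosphoglycerate kinase", "Glycolysis", "Carbohydrate utilization", 1.0),
    ("tagatose metabolism", "Monosaccharide utilization", "Carbohydrate utilization", 1.5),
    ("sorbitol-sorbose metabolism", "Monosaccharide utilization", "Carbohydrate utilization", 1.0),
    ("ribose metabolism", "Monosaccharide utilization", "Carbohydrate utilization", 0.8),
    ("lactose-galactose metabolism", "Disaccharide utilization", "Carbohydrate utilization", 3.0),
    ("trehalose metabolism", "Disaccharide utilization", "Carbohydrate utilization", 1.2),
    ("superoxide dismutase", "Oxidative stress", "Stress response", 0.9),
    ("peroxiredoxin", "Oxidative stress", "Stress response", 0.4),
    ("catalase", "Oxidative stress", "Stress response", 0.1),
    ("ferroxidase", "Oxidative stress", "Stress response", 0.2),
    ("chaperone GroEL", "Heat shock", "Stress response", 0.5),
    ("chaperone DnaK", "Heat shock", "Stress response", 0.4),
    ("mercuric reductase", "Metal homeostasis", "Resistance to antibiotics and toxic compounds", 0.5),
    ("copper-translocating P-type ATPase", "Metal homeostasis", "Resistance to antibiotics and toxic compounds", 0.4),
    ("acriflavin resistance complex AcrAB", "Multidrug efflux", "Resistance to antibiotics and toxic compounds", 0.2),
    ("macrolide-specific efflux system", "Multidrug efflux", "Resistance to antibiotics and toxic compounds", 0.1),
    ("membrane transport protein", "Transport", "Membrane transport", 3.0),
    ("hypothetical protein", "Uncharacterized", "Uncharacterized", 4.0),
]


@dataclass
class RoleHierarchy:
    """Three-level functional mapping: function -> subsystem -> category.

    Each function maps to exactly one (subsystem, category); a function
    listed under several subsystems keeps its first listing (logged).
    """

    table: pd.DataFrame

    _fn_map: dict[str, tuple[str, str]] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        missing = [c for c in ("function", "subsystem", "category") if c not in self.table.columns]
        if missing:
            raise ProfileError(f"hierarchy table missing columns: {missing}")
        dup = self.table["function"].duplicated()
        if dup.any():
            dropped = sorted(self.table.loc[dup, "function"].unique())
            logger.warning("functions mapped to multiple subsystems; keeping first: %s", dropped)
            self.table = self.table[~dup].reset_index(drop=True)
        self._fn_map = {
            r["function"]: (r["subsystem"], r["category"]) for _, r in self.table.iterrows()
        }

    @classmethod
    def default(cls) -> "RoleHierarchy":
        df = pd.DataFrame(
            [(f, s, c) for f, s, c, _ in DEFAULT_ROLE_TABLE],
            columns=["function", "subsystem", "category"],
        )
        return cls(df)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "RoleHierarchy":
        return cls(pd.read_csv(path, sep="\t"))

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    def lookup(self, function: str) -> tuple[str, str]:
        """(subsystem, category) for a function; unassigned if unknown."""
        return self._fn_map.get(function, (UNASSIGNED, UNASSIGNED))

    def members(self, group: str) -> tuple[str | None, set[str]]:
        """Resolve a named group to (its level, the set of functions under it)."""
        for level in ("category", "subsystem", "function"):
            sel = self.table[self.table[level] == group]
            if len(sel):
                return level, set(sel["function"])
        return None, set()

    def is_nested(self, group: str, subgroup: str) -> bool:
        g_level, g_fns = self.members(group)
        s_level, s_fns = self.members(subgroup)
        if g_level is None or s_level is None:
            return False
        return s_fns <= g_fns


@dataclass
class FunctionalProfile:
    """Per-subject functional composition at each hierarchy level."""

    counts: dict[str, pd.DataFrame]  # level -> labels x subjects summed counts
    proportions: dict[str, pd.DataFrame]
    totals: pd.Series  # denominator per subject
    hierarchy: RoleHierarchy
    denominator: str  # "all" or "assigned"

    @property
    def subjects(self) -> list[str]:
        return list(self.totals.index)


def role_proportions(
    counts: CountMatrix,
    hierarchy: RoleHierarchy | None = None,
    denominator: str = "all",
) -> FunctionalProfile:
    """Aggregate transcript counts into functional proportions per subject.

    Each transcript's ``function`` annotation is mapped through the
    hierarchy to a subsystem and role category; functions the hierarchy
    does not list fall into an explicit ``unassigned`` bucket at every
    level, so proportions at each level sum to 1 per subject. With
    ``denominator="assigned"`` the unassigned bucket is dropped and
    proportions are over functionally assigned counts only.
    """
    if denominator not in ("all", "assigned"):
        raise ProfileError(f"denominator must be 'all' or 'assigned', got {denominator!r}")
    if hierarchy is None:
        hierarchy = RoleHierarchy.default()

    fns = counts.annotations["function"].fillna(UNASSIGNED)
    mapped = fns.map(lambda f: hierarchy.lookup(f) if f != UNASSIGNED else (UNASSIGNED, UNASSIGNED))
    labels = pd.DataFrame(
        {
            "function": [f if f in hierarchy._fn_map else UNASSIGNED for f in fns],
            "subsystem": [m[0] for m in mapped],
            "category": [m[1] for m in mapped],
        },
        index=counts.counts.index,
    )

    level_counts: dict[str, pd.DataFrame] = {}
    for level in LEVELS:
        level_counts[level] = counts.counts.groupby(labels[level]).sum()

    if denominator == "assigned":
        for level in LEVELS:
            level_counts[level] = level_counts[level].drop(index=UNASSIGNED, errors="ignore")
        totals = level_counts["function"].sum(axis=0)
    else:
        totals = counts.counts.sum(axis=0)

    props = {level: lc.div(totals, axis=1) for level, lc in level_counts.items()}
    return FunctionalProfile(
        counts=level_counts,
        proportions=props,
        totals=totals.astype(float),
        hierarchy=hierarchy,
        denominator=denominator,
    )


def within_group_fraction(
    profile: FunctionalProfile, group: str, subgroup: str
) -> pd.DataFrame:
    """Nested share of a functional subgroup within a group, per subject.

    Returns one row per subject with ``fraction_of_group`` (subgroup counts
    over group counts; NaN where the group total is zero) and
    ``fraction_of_total`` (subgroup counts over the profile denominator).
    E.g. the superoxide-dismutase share of oxidative-stress transcripts,
    and its share of the whole transcriptome.
    """
    hier = profile.hierarchy
    if not hier.is_nested(group, subgroup):
        raise ProfileError(f"{subgroup!r} is not nested within {group!r} in the hierarchy")
    g_level, _ = hier.members(group)
    s_level, _ = hier.members(subgroup)
    g_counts = profile.counts[g_level].loc[group]
    s_counts = profile.counts[s_level].loc[subgroup]
    frac = s_counts / g_counts.where(g_counts > 0, np.nan)
    return pd.DataFrame(
        {
            "fraction_of_group": frac,
            "fraction_of_total": s_counts / profile.totals,
        }
    )


def homogeneity_summary(profile: FunctionalProfile, level: str = "category") -> pd.DataFrame:
    """Across-subject spread of each functional label's proportion.

    Reports min, max, range and coefficient of variation (sd with n-1
    denominator over mean) per label — the summary used to compare how
    conserved functional composition is relative to taxonomic composition.
    """
    props = profile.proportions[level]
    if props.shape[1] < 2:
        raise ProfileError("homogeneity summary needs at least 2 subjects")
    mean = props.mean(axis=1)
    sd = props.std(axis=1, ddof=1)
    out = pd.DataFrame(
        {
            "min": props.min(axis=1),
            "max": props.max(axis=1),
            "range": props.max(axis=1) - props.min(axis=1),
            "cv": sd / mean.where(mean > 0, np.nan),
        }
    )
    out.index.name = level
    return out
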