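"""Core containers and TSV I/O for the plaque metatranscriptome pipeline.

The pipeline's in-memory lingua franca is the pandas DataFrame:

* a **count matrix** holds non-negative integer transcript counts
  (transcripts x subjects) together with per-transcript annotations
  (species, genus, and a three-level functional role assignment);
* a **taxon profile** holds one or more named layers (raw counts,
  relative abundance, scaled log2) of a taxa x subjects table at a single
  taxonomic level;
* **subject metadata** is a plain DataFrame keyed by subject id with the
  twin-pair id, zygosity, and caries phenotype.

All on-disk formats are headered TSV so every stage can be inspected and
re-run in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

ANNOTATION_COLUMNS = ["species", "genus", "role_category", "subsystem", "function"]

METADATA_COLUMNS = ["subject_id", "pair_id", "zygosity", "caries_status", "decayed_surfaces"]


class PlaquetxError(Exception):
    """Base class for pipeline errors."""


class ConfigError(PlaquetxError):
    """Invalid configuration (bad proportions, negative scales, ...)."""


class NormalizationError(PlaquetxError):
    """Size-factor estimation is impossible on the given counts."""


class ProfileError(PlaquetxError):
    """Invalid taxon/functional profile operation."""


class MetadataError(PlaquetxError):
    """Subject metadata violates the twin-pair structure."""


class NetworkError(PlaquetxError):
    """Invalid correlation-network parameter or input."""


@dataclass
class CountMatrix:
    """Transcript-level counts with taxonomy and functional annotations.

    Parameters
    ----------
    counts
        DataFrame indexed by transcript id, one integer column per subject.
    annotations
        DataFrame indexed identically, with columns ``species``, ``genus``,
        ``role_category``, ``subsystem``, ``function``.
    """

    counts: pd.DataFrame
    annotations: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.counts.index.equals(self.annotations.index):
            raise PlaquetxError("counts and annotations must share the same transcript index")
        missing = [c for c in ANNOTATION_COLUMNS if c not in self.annotations.columns]
        if missing:
            raise PlaquetxError(f"annotation columns missing: {missing}")
        if (self.counts.to_numpy() < 0).any():
            raise PlaquetxError("counts must be non-negative")

    @property
    def subjects(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_transcripts(self) -> int:
        return self.counts.shape[0]

    def to_tsv(self, path: str | Path) -> None:
        """Write a single TSV: annotation columns first, then one column per subject."""
        table = pd.concat([self.annotations[ANNOTATION_COLUMNS], self.counts], axis=1)
        table.index.name = "transcript_id"
        table.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CountMatrix":
        table = pd.read_csv(path, sep="\t", index_col="transcript_id")
        ann = table[ANNOTATION_COLUMNS]
        counts = table.drop(columns=ANNOTATION_COLUMNS)
        counts.columns = counts.columns.astype(str)
        return cls(counts=counts.astype(np.int64), annotations=ann)


@dataclass
class TaxonProfile:
    """Taxa x subjects table at one taxonomic level, with named layers.

    Layers are added as the pipeline progresses: ``raw`` (summed counts),
    ``relative`` (per-subject proportions), ``scaled_log2``
    (log2(count/size_factor + 1)). Taxonomic levels are never mixed within
    one profile.
    """

    level: str
    layers: dict[str, pd.DataFrame] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.level not in ("species", "genus"):
            raise ProfileError(f"unknown taxonomic level {self.level!r}")
        shapes = {name: df.shape for name, df in self.layers.items()}
        if len({s for s in shapes.values()}) > 1:
            raise ProfileError(f"layer shapes disagree: {shapes}")

    def layer(self, name: str) -> pd.DataFrame:
        if name not in self.layers:
            raise ProfileError(f"profile has no layer {name!r} (have {sorted(self.layers)})")
        return self.layers[name]

    @property
    def taxa(self) -> list[str]:
        any_layer = next(iter(self.layers.values()))
        return list(any_layer.index)

    @property
    def subjects(self) -> list[str]:
        any_layer = next(iter(self.layers.values()))
        return list(any_layer.columns)

    def write_layer(self, name: str, path: str | Path) -> None:
        df = self.layer(name).copy()
        df.index.name = self.level
        df.to_csv(path, sep="\t")


def validate_metadata(metadata: pd.DataFrame) -> pd.DataFrame:
    """Check the twin-pair structure: every pair has exactly two subjects."""
    missing = [c for c in METADATA_COLUMNS if c not in metadata.columns]
    if missing:
        raise MetadataError(f"metadata columns missing: {missing}")
    sizes = metadata.groupby("pair_id").size()
    bad = sizes[sizes != 2]
    if len(bad):
        raise MetadataError(f"pairs without exactly 2 members: {dict(bad)}")
    zyg = metadata.groupby("pair_id")["zygosity"].nunique()
    if (zyg != 1).any():
        raise MetadataError("pair members disagree on zygosity")
    return metadata


def pair_table(metadata: pd.DataFrame) -> pd.DataFrame:
    """Collapse subject metadata to one row per twin pair.

    Concordance follows the caries-experience reading: a pair is
    *concordant* when both twins are caries-free or both are
    caries-experienced (active CA or inactive CI), *discordant* otherwise.
    """
    validate_metadata(metadata)
    rows = []
    for pair_id, grp in metadata.groupby("pair_id", sort=False):
        statuses = list(grp["caries_status"])
        experienced = [s in ("CA", "CI") for s in statuses]
        concordance = "concordant" if experienced[0] == experienced[1] else "discordant"
        rows.append(
            {
                "pair_id": pair_id,
                "zygosity": grp["zygosity"].iloc[0],
                "subject_1": grp["subject_id"].iloc[0],
                "subject_2": grp["subject_id"].iloc[1],
                "concordance": concordance,
            }
        )
    return pd.DataFrame(rows).set_index("pair_id")


def read_metadata(path: str | Path) -> pd.DataFrame:
    md = pd.read_csv(path, sep="\t", dtype={"subject_id": str, "pair_id": str})
    return validate_metadata(md)


def write_metadata(metadata: pd.DataFrame, path: str | Path) -> None:
    metadata.to_csv(path, sep="\t", index=False)


def read_matrix_tsv(path: str | Path, index_name: str | None = None) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if index_name is not None:
        df.index.name = index_name
    df.columns = df.columns.astype(str)
    return df
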