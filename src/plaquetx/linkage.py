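"""Twin-pair dendrogram linkage analysis.

Subjects are clustered hierarchically on their expression profiles and a
twin pair is called *linked* when its two subjects are sister leaves of
the dendrogram (a cherry: their first merge is with each other) — the
strictest reading of "most similar to each other". A mutual
nearest-neighbor definition is available behind a flag. Linked fractions
are stratified by zygosity (MZ/DZ) and caries concordance, and a
permutation test re-partitions subjects into random pairs to obtain a
null distribution for the observed linked count.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .datatypes import MetadataError, PlaquetxError, TaxonProfile, pair_table
from .network import rank_correlation

STRATA = [
    "overall", "MZ", "DZ", "concordant", "discordant",
    "MZ_concordant", "MZ_discordant", "DZ_concordant", "DZ_discordant",
]


def _profile_matrix(profile: TaxonProfile | pd.DataFrame, layer: str = "scaled_log2") -> pd.DataFrame:
    if isinstance(profile, TaxonProfile):
        return profile.layer(layer)
    return profile


def distance_matrix(
    profile: TaxonProfile | pd.DataFrame, metric: str = "correlation"
) -> pd.DataFrame:
    """Pairwise subject distances from a taxa x subjects table.

    ``correlation`` is 1 - Spearman rho between subject profiles (range
    [0, 2]); ``euclidean`` is the usual L2 distance between profile
    columns. A constant subject profile has no defined rank correlation
    and raises.
    """
    mat = _profile_matrix(profile)
    if mat.shape[1] < 2:
        raise PlaquetxError("distance matrix needs at least 2 subjects")
    if metric == "correlation":
        constant = mat.nunique(axis=0) <= 1
        if constant.any():
            raise PlaquetxError(
                f"constant subject profiles have undefined rank correlation: "
                f"{list(mat.columns[constant])}"
            )
        rho = rank_correlation(mat.to_numpy().T)
        dist = 1.0 - rho
        np.fill_diagonal(dist, 0.0)
        dist = np.maximum(dist, 0.0)
    elif metric == "euclidean":
        arr = mat.to_numpy().T
        dist = np.sqrt(((arr[:, None, :] - arr[None, :, :]) ** 2).sum(axis=2))
    else:
        raise PlaquetxError(f"unknown metric {metric!r}")
    dist = (dist + dist.T) / 2.0  # enforce exact symmetry
    return pd.DataFrame(dist, index=mat.columns, columns=mat.columns)


@dataclass
class DendrogramResult:
    """Agglomerative merge tree over subjects (scipy linkage encoding)."""

    labels: list[str]
    merge: np.ndarray  # scipy linkage matrix, (n-1) x 4
    method: str
    distances: pd.DataFrame

    def cherry_pairs(self) -> set[frozenset]:
        """Subject pairs whose first merge is with each other (sister leaves)."""
        n = len(self.labels)
        out = set()
        for a, b, _, _ in self.merge:
            if a < n and b < n:
                out.add(frozenset((self.labels[int(a)], self.labels[int(b)])))
        return out

    def to_newick(self) -> str:
        """Newick string; branch lengths are merge-height differences."""
        tree = hierarchy.to_tree(self.merge)

        def fmt(node, parent_height):
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{self.labels[node.id]}:{length:.6g}"
            left = fmt(node.left, node.dist)
            right = fmt(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        left = fmt(tree.left, tree.dist)
        right = fmt(tree.right, tree.dist)
        return f"({left},{right});"

    def write_newick(self, path: str | Path) -> None:
        Path(path).write_text(self.to_newick() + "\n")


def cluster(distances: pd.DataFrame, method: str = "average") -> DendrogramResult:
    """Agglomerative clustering (UPGMA by default) of a subject distance matrix."""
    if method not in ("average", "complete", "single"):
        raise PlaquetxError(f"unsupported linkage method {method!r}")
    arr = distances.to_numpy(dtype=float)
    if arr.shape[0] != arr.shape[1] or not np.allclose(arr, arr.T):
        raise PlaquetxError("distance matrix must be square and symmetric")
    if (np.diag(arr) != 0).any() or (arr < 0).any():
        raise PlaquetxError("distance matrix must have zero diagonal and be nonnegative")
    condensed = squareform(arr, checks=False)
    merge = hierarchy.linkage(condensed, method=method)
    return DendrogramResult(
        labels=list(distances.columns), merge=merge, method=method, distances=distances
    )


@dataclass
class LinkageResult:
    """Per-pair linked flags with stratified counts and fractions."""

    pair_flags: pd.Series  # bool, indexed by pair id
    strata: dict[str, dict[str, float]]  # stratum -> {linked, total, fraction}
    linked_def: str = "cherry"
    p_value: float | None = None

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "linked_def": self.linked_def,
            "pair_flags": {k: bool(v) for k, v in self.pair_flags.items()},
            "strata": self.strata,
        }
        if self.p_value is not None:
            payload["p_value"] = self.p_value
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    def to_tsv(self, path: str | Path) -> None:
        rows = [
            {"stratum": name, **{k: v for k, v in d.items()}}
            for name, d in self.strata.items()
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def stratify_linkage(pair_flags: pd.Series, pairs: pd.DataFrame) -> LinkageResult:
    """Stratified linked counts/fractions from per-pair flags.

    ``pairs`` is the pair-level table (zygosity, concordance); strata are
    overall, by zygosity, by concordance, and the four zygosity x
    concordance cells. Fractions of empty strata are NaN.
    """
    pair_flags = pair_flags.reindex(pairs.index)
    if pair_flags.isna().any():
        raise MetadataError("linked flags missing for some pairs")

    def cell(mask: pd.Series) -> dict[str, float]:
        total = int(mask.sum())
        linked = int(pair_flags[mask].sum())
        return {
            "linked": linked,
            "total": total,
            "fraction": linked / total if total else float("nan"),
        }

    all_true = pd.Series(True, index=pairs.index)
    strata = {"overall": cell(all_true)}
    for z in ("MZ", "DZ"):
        strata[z] = cell(pairs["zygosity"] == z)
    for c in ("concordant", "discordant"):
        strata[c] = cell(pairs["concordance"] == c)
    for z in ("MZ", "DZ"):
        for c in ("concordant", "discordant"):
            strata[f"{z}_{c}"] = cell(
                (pairs["zygosity"] == z) & (pairs["concordance"] == c)
            )
    return LinkageResult(pair_flags=pair_flags.astype(bool), strata=strata)


def _matching_linked_flags(
    matching: list[tuple[str, str]],
    tree: DendrogramResult,
    linked_def: str,
) -> list[bool]:
    if linked_def == "cherry":
        cherries = tree.cherry_pairs()
        return [frozenset(p) in cherries for p in matching]
    if linked_def == "nearest":
        d = tree.distances.to_numpy().copy()
        np.fill_diagonal(d, np.inf)
        idx = {s: i for i, s in enumerate(tree.labels)}
        nn = np.argmin(d, axis=1)
        return [nn[idx[a]] == idx[b] and nn[idx[b]] == idx[a] for a, b in matching]
    raise PlaquetxError(f"unknown linked_def {linked_def!r}")


def pair_linkage(
    tree: DendrogramResult, metadata: pd.DataFrame, linked_def: str = "cherry"
) -> LinkageResult:
    """Twin-pair linkage on a subject dendrogram, stratified by zygosity and
    concordance.

    With the default ``cherry`` definition a pair is linked iff its two
    subjects are sister leaves; ``nearest`` instead requires the two
    subjects to be mutual nearest neighbors in the distance matrix.
    """
    pairs = pair_table(metadata)
    missing = set(metadata["subject_id"]) - set(tree.labels)
    if missing:
        raise MetadataError(f"subjects absent from dendrogram: {sorted(missing)}")
    matching = [(r["subject_1"], r["subject_2"]) for _, r in pairs.iterrows()]
    flags = _matching_linked_flags(matching, tree, linked_def)
    result = stratify_linkage(pd.Series(flags, index=pairs.index), pairs)
    result.linked_def = linked_def
    return result


def permutation_null(
    profile: TaxonProfile | pd.DataFrame,
    metadata: pd.DataFrame,
    n_perm: int = 999,
    seed: int = 0,
    metric: str = "correlation",
    method: str = "average",
    linked_def: str = "cherry",
) -> dict:
    """Permutation test of the observed twin-pair linked count.

    The dendrogram is built once from the profiles (it does not depend on
    pair labels); each permutation re-partitions the subjects into random
    pairs and counts how many land as sister leaves. The p-value uses the
    add-one estimator p = (1 + #{null >= observed}) / (1 + n_perm).
    """
    if n_perm < 1:
        raise PlaquetxError("n_perm must be >= 1")
    mat = _profile_matrix(profile)
    subjects = list(mat.columns)
    if len(subjects) % 2:
        raise PlaquetxError("permutation null needs an even number of subjects")
    tree = cluster(distance_matrix(profile, metric=metric), method=method)
    observed = int(sum(
        _matching_linked_flags(
            [(r["subject_1"], r["subject_2"]) for _, r in pair_table(metadata).iterrows()],
            tree,
            linked_def,
        )
    ))
    rng = np.random.default_rng(seed)
    null_counts = np.empty(n_perm, dtype=int)
    arr = np.array(subjects)
    for k in range(n_perm):
        perm = rng.permutation(arr)
        matching = list(zip(perm[0::2], perm[1::2]))
        null_counts[k] = sum(_matching_linked_flags(matching, tree, linked_def))
    p = (1 + int((null_counts >= observed).sum())) / (1 + n_perm)
    return {
        "observed": observed,
        "null_counts": null_counts,
        "null_mean": float(null_counts.mean()),
        "p_value": float(p),
        "n_perm": n_perm,
    }
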