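"""End-to-end orchestration: input -> normalize -> profiles -> linkage ->
network -> functional roles, with every stage's output flushed to TSV /
Newick / JSON so any downstream stage can be re-run in isolation."""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd
import yaml

from . import linkage as tl
from . import network as cn
from . import profiles as tp
from . import roles as fr
from .datatypes import ConfigError, CountMatrix, PlaquetxError, read_metadata, write_metadata
from .normalize import size_factors
from .simulate import SynthConfig, simulate

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything one pipeline run needs.

    Input is either a synthetic-cohort configuration (``synth``) or a pair
    of TSV paths (``counts_tsv`` + ``metadata_tsv``).
    """

    outdir: str = "plaquetx_out"
    counts_tsv: str | None = None
    metadata_tsv: str | None = None
    synth: dict = field(default_factory=dict)
    seed: int = 0

    core_min_count: int = 10
    linkage_level: str = "species"
    metric: str = "correlation"
    method: str = "average"
    linked_def: str = "cherry"
    n_perm: int = 0

    network_level: str = "genus"
    min_abs_rho: float = 0.5
    fdr_q: float | None = 0.05

    role_denominator: str = "all"
    role_groups: list = field(
        default_factory=lambda: [["Stress response", "Oxidative stress"]]
    )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def validate(self) -> None:
        file_input = self.counts_tsv is not None or self.metadata_tsv is not None
        if file_input and (self.counts_tsv is None or self.metadata_tsv is None):
            raise ConfigError("file input needs both counts_tsv and metadata_tsv")
        for p in (self.counts_tsv, self.metadata_tsv):
            if p is not None and not Path(p).exists():
                raise ConfigError(f"input file does not exist: {p}")
        if self.n_perm < 0:
            raise ConfigError("n_perm must be >= 0")


def load_report_schema() -> dict:
    ref = resources.files("plaquetx.data").joinpath("report_schema.json")
    return json.loads(ref.read_text())


def validate_report(report: dict, schema: dict | None = None) -> None:
    """Minimal structural validation of a report against the shipped schema
    (required keys and primitive types; no external validator needed)."""
    if schema is None:
        schema = load_report_schema()

    type_map = {
        "object": dict,
        "array": list,
        "string": str,
        "integer": int,
        "boolean": bool,
        "number": (int, float),
    }

    def check(obj, sch, path="report"):
        expected = sch.get("type")
        if expected and not isinstance(obj, type_map[expected]):
            raise PlaquetxError(f"{path}: expected {expected}, got {type(obj).__name__}")
        for key in sch.get("required", []):
            if key not in obj:
                raise PlaquetxError(f"{path}: missing required key {key!r}")
        for key, sub in sch.get("properties", {}).items():
            if isinstance(obj, dict) and key in obj:
                check(obj[key], sub, f"{path}.{key}")

    check(report, schema)


def _stage(name: str):
    """Log a stage with a wall-clock timer; re-raise failures with the stage name."""

    class _Ctx:
        def __enter__(self):
            self.t0 = time.perf_counter()
            logger.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            if exc is not None:
                logger.error("stage %s: failed after %.2fs", name, dt)
                raise PlaquetxError(f"stage {name!r} failed: {exc}") from exc
            logger.info("stage %s: done in %.2fs", name, dt)
            return False

    return _Ctx()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages and return the machine-readable report.

    Outputs (TSV tables, Newick dendrogram, edge list, JSON report) land in
    ``config.outdir``. The same config and seed give a byte-identical
    report.
    """
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)

    with _stage("input"):
        if config.counts_tsv is not None:
            counts = CountMatrix.from_tsv(config.counts_tsv)
            metadata = read_metadata(config.metadata_tsv)
        else:
            synth_kwargs = dict(config.synth)
            synth_kwargs.setdefault("seed", config.seed)
            scfg = SynthConfig(**synth_kwargs)
            metadata, counts, truth = simulate(scfg)
            counts.to_tsv(out / "counts.tsv")
            write_metadata(metadata, out / "metadata.tsv")
            truth.to_json(out / "truth.json")

    with _stage("normalize"):
        factors = size_factors(counts)
        factors.to_tsv(out / "size_factors.tsv")

    profiles: dict[str, tp.TaxonProfile] = {}
    with _stage("profile"):
        for level in ("species", "genus"):
            prof = tp.aggregate(counts, level=level)
            tp.relative_abundance(prof)
            tp.add_scaled_log2(prof, factors)
            for layer in ("raw", "relative", "scaled_log2"):
                prof.write_layer(layer, out / f"{level}_{layer}.tsv")
            profiles[level] = prof
        core = tp.core_taxa(profiles["species"], min_count=config.core_min_count)
        pd.Series(core, name="species").to_csv(out / "core_species.tsv", sep="\t", index=False)
        var = tp.variability(profiles["species"])
        var.to_csv(out / "variability_species.tsv", sep="\t")

    with _stage("linkage"):
        prof = profiles[config.linkage_level]
        dist = tl.distance_matrix(prof, metric=config.metric)
        tree = tl.cluster(dist, method=config.method)
        tree.write_newick(out / "dendrogram.nwk")
        linkage_result = tl.pair_linkage(tree, metadata, linked_def=config.linked_def)
        if config.n_perm > 0:
            perm = tl.permutation_null(
                prof, metadata, n_perm=config.n_perm, seed=config.seed,
                metric=config.metric, method=config.method, linked_def=config.linked_def,
            )
            linkage_result.p_value = perm["p_value"]
        linkage_result.to_json(out / "linkage.json")
        linkage_result.to_tsv(out / "linkage.tsv")

    with _stage("network"):
        nprof = profiles[config.network_level]
        rho = cn.spearman_matrix(nprof)
        net = cn.extract_network(
            rho, min_abs_rho=config.min_abs_rho, fdr_q=config.fdr_q,
            n_subjects=len(nprof.subjects),
        )
        complexes = cn.find_complexes(net)
        net.write_rho(out / f"rho_{config.network_level}.tsv")
        net.write_edges(out / f"edges_{config.network_level}.tsv")
        net.write_complexes(out / "complexes.json")
        net.write_graphml(out / "network.graphml")
        signs = cn.node_sign_profile(net)
        signs.to_csv(out / "node_signs.tsv", sep="\t")

    with _stage("functions"):
        fprofile = fr.role_proportions(counts, denominator=config.role_denominator)
        for level in fr.LEVELS:
            df = fprofile.proportions[level].copy()
            df.index.name = level
            df.to_csv(out / f"roles_{level}_proportions.tsv", sep="\t")
        homog = fr.homogeneity_summary(fprofile, level="category")
        homog.to_csv(out / "roles_homogeneity.tsv", sep="\t")
        group_fracs = {}
        for group, subgroup in config.role_groups:
            wf = fr.within_group_fraction(fprofile, group, subgroup)
            slug = f"{group}_{subgroup}".lower().replace(" ", "_")
            wf.to_csv(out / f"fraction_{slug}.tsv", sep="\t")
            group_fracs[f"{subgroup} / {group}"] = {
                "mean_fraction_of_group": float(wf["fraction_of_group"].mean()),
                "mean_fraction_of_total": float(wf["fraction_of_total"].mean()),
            }

    with _stage("report"):
        cat_means = fprofile.proportions["category"].mean(axis=1).sort_values(ascending=False)
        report = {
            "seed": config.seed,
            "n_subjects": len(counts.subjects),
            "n_pairs": metadata["pair_id"].nunique(),
            "n_transcripts": counts.n_transcripts,
            "n_species": int(counts.annotations["species"].nunique()),
            "size_factors": {k: round(float(v), 6) for k, v in factors.factors.items()},
            "core": {
                "level": "species",
                "min_count": config.core_min_count,
                "n_core": len(core),
                "taxa": core,
            },
            "linkage": {
                "metric": config.metric,
                "method": config.method,
                "linked_def": config.linked_def,
                "strata": linkage_result.strata,
            },
            "network": {
                "level": config.network_level,
                "min_abs_rho": config.min_abs_rho,
                "fdr_q": config.fdr_q,
                "n_edges": int(len(net.edges)),
                "n_complexes": len(complexes),
                "complexes": complexes,
            },
            "functional": {
                "denominator": config.role_denominator,
                "top_categories": {k: round(float(v), 6) for k, v in cat_means.head(5).items()},
                "group_fractions": group_fracs,
            },
        }
        if config.n_perm > 0:
            report["linkage"]["p_value"] = linkage_result.p_value
            report["linkage"]["n_perm"] = config.n_perm
        validate_report(report)
        (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report
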