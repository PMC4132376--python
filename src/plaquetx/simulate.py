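"""Twin-structured synthetic metatranscriptome generator.

Emulates the statistical structure the downstream analysis assumes: a
cohort of twin pairs (default 19 pairs, 6 monozygotic / 13 dizygotic,
with a 4/6/9 split of concordant caries-free / concordant
caries-experienced / discordant pairs), species whose baseline expression
spans ~6 orders of magnitude, twin-shared covariance in log abundance,
planted signed co-abundance complexes, and per-transcript functional
annotations drawn from the default role hierarchy.

Model (per species s, subject j in pair p, natural-log space):

    eta[s, j] = ln(10) * b[s]                    # baseline, b ~ U(range)
              + u[p, s]                          # pair-shared, N(0, pair_effect_sd)
              + v[p, s] * 1[p is MZ]             # extra MZ-shared, N(0, mz_extra_effect_sd)
              + sum_c  L[c, s] * f[c, j]         # planted complex factors, f ~ N(0, factor_sd)
              + e[s, j]                          # subject noise, N(0, subject_noise_sd)

Expected relative species abundance is softmax(eta) per subject; subject
sequencing depth is lognormal around ``depth_mean``; transcript counts
are negative binomial around depth x abundance x within-species
transcript weight, with Poisson as the dispersion -> 0 limit.

The generator returns the exact ground truth (effects, factors, expected
abundances, expected correlation signs among planted members) so every
downstream stage can be tested for recovery.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import ConfigError, CountMatrix, validate_metadata
from .roles import DEFAULT_ROLE_TABLE

# Genera observed in supragingival plaque transcriptomes; species ids carry
# the genus as a prefix so genus is a deterministic function of species id.
ORAL_GENERA = [
    "Streptococcus", "Veillonella", "Capnocytophaga", "Gemella", "Neisseria",
    "Aggregatibacter", "Fusobacterium", "Haemophilus", "Lachnoanaerobaculum",
    "Lachnospiraceae", "Leptotrichia", "Parvimonas", "Actinomyces", "Lautropia",
    "Campylobacter", "Granulicatella", "Rothia", "Bacteroides", "Eubacterium",
    "Filifactor", "Johnsonella", "Peptostreptococcus", "Prevotella",
    "Porphyromonas", "Corynebacterium", "Kingella", "Selenomonas",
]


def species_names(n_species: int) -> list[str]:
    """Deterministic species ids, genus prefix + running species number."""
    names = []
    for i in range(n_species):
        genus = ORAL_GENERA[i % len(ORAL_GENERA)]
        names.append(f"{genus}_sp{i // len(ORAL_GENERA) + 1:02d}")
    return names


def genus_of(species: str) -> str:
    return species.split("_", 1)[0]


@dataclass
class PlantedComplex:
    """A latent co-abundance factor shared by a set of member species.

    The sign of the expected correlation between two members equals the
    sign of the product of their loadings: same-sign loadings co-vary,
    opposite-sign loadings anti-correlate.
    """

    member_taxa: list[str]
    loadings: list[float]
    factor_sd: float = 1.5

    def __post_init__(self) -> None:
        if len(self.member_taxa) < 2:
            raise ConfigError("a planted complex needs at least 2 members")
        if len(self.loadings) != len(self.member_taxa):
            raise ConfigError("one loading per member is required")
        if any(l == 0 for l in self.loadings):
            raise ConfigError("loadings must be nonzero")
        if self.factor_sd < 0:
            raise ConfigError("factor_sd must be >= 0")


def default_complexes(n_species: int = 60) -> list[PlantedComplex]:
    """Planted complexes mirroring the qualitative network motifs observed
    in plaque co-abundance analysis: an all-positive group, a mixed-sign
    group, an anti-correlated pair, and a group with a single antagonist
    member whose edges are all negative. Members are spread across the
    species list; complexes that do not fit a small ``n_species`` are
    dropped from the tail."""
    sp = species_names(n_species)
    motifs = [
        [1.0, 1.0, 1.0, 1.0],
        [1.0, 1.0, -1.0],
        [1.0, -1.0],
        [1.0, 1.0, 1.0, 1.0, -1.0],
    ]
    total = sum(len(m) for m in motifs)
    gap = max(1, (n_species - total) // len(motifs))
    out, start = [], 0
    for loadings in motifs:
        if start + len(loadings) > n_species:
            break
        out.append(PlantedComplex(sp[start:start + len(loadings)], list(loadings)))
        start += len(loadings) + gap
    return out


@dataclass
class SynthConfig:
    """Study conditions for the synthetic cohort.

    Defaults emulate the twin cohort the pipeline targets: 19 pairs
    (6 MZ / 13 DZ), a 4/6/9 concordant-CF / concordant-CA / discordant
    split, species baselines spanning six log10, and sequencing depth
    around 2 million mapped reads per subject.
    """

    n_pairs: int = 19
    n_mz: int = 6
    n_species: int = 60
    transcripts_per_species: int = 20
    baseline_log_mean_range: tuple[float, float] = (0.0, 6.0)
    pair_effect_sd: float = 1.0
    mz_extra_effect_sd: float = 0.5
    subject_noise_sd: float = 0.5
    complexes: list[PlantedComplex] | None = None  # None -> default_complexes(n_species)
    depth_mean: int = 2_000_000
    depth_dispersion: float = 0.05
    depth_log_sd: float = 0.4
    caries_split: tuple[int, int, int] = (4, 6, 9)  # concordant-CF, concordant-CA, discordant
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pairs < 1:
            raise ConfigError("n_pairs must be >= 1")
        if not 0 <= self.n_mz <= self.n_pairs:
            raise ConfigError("need 0 <= n_mz <= n_pairs")
        if self.n_species < 1 or self.transcripts_per_species < 1:
            raise ConfigError("n_species and transcripts_per_species must be >= 1")
        lo, hi = self.baseline_log_mean_range
        if not hi > lo:
            raise ConfigError("baseline_log_mean_range span must be positive")
        for name in ("pair_effect_sd", "mz_extra_effect_sd", "subject_noise_sd",
                     "depth_dispersion", "depth_log_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.depth_mean <= 0:
            raise ConfigError("depth_mean must be > 0")
        if sum(self.caries_split) != self.n_pairs:
            raise ConfigError(
                f"caries_split {self.caries_split} must sum to n_pairs={self.n_pairs}"
            )
        if self.complexes is None:
            self.complexes = default_complexes(self.n_species)
        valid = set(species_names(self.n_species))
        seen: set[str] = set()
        for cx in self.complexes:
            for t in cx.member_taxa:
                if t not in valid:
                    raise ConfigError(f"complex member {t!r} is not a generated species")
                if t in seen:
                    raise ConfigError(f"species {t!r} belongs to more than one complex")
                seen.add(t)


@dataclass
class SynthTruth:
    """Ground truth of one simulated cohort."""

    baseline_log10: pd.Series  # per species
    pair_effects: pd.DataFrame  # pairs x species (shared-environment, ln scale)
    mz_extra_effects: pd.DataFrame  # pairs x species (zero rows for DZ)
    subject_noise: pd.DataFrame  # species x subjects
    factor_values: pd.DataFrame  # complex id x subjects
    expected_abundance: pd.DataFrame  # species x subjects, relative, cols sum to 1
    expected_sign: pd.DataFrame  # species x species: sign of planted correlation, 0 otherwise
    complex_members: dict[str, list[str]]
    transcript_map: pd.DataFrame  # transcript annotations

    def planted_edges(self) -> list[tuple[str, str, int]]:
        """All within-complex pairs with their expected correlation sign."""
        edges = []
        for members in self.complex_members.values():
            for i in range(len(members)):
                for j in range(i + 1, len(members)):
                    a, b = members[i], members[j]
                    edges.append((a, b, int(self.expected_sign.loc[a, b])))
        return edges

    def to_json(self, path: str | Path) -> None:
        payload = {
            "baseline_log10": self.baseline_log10.to_dict(),
            "complex_members": self.complex_members,
            "expected_sign": {
                f"{a}|{b}": s for a, b, s in self.planted_edges()
            },
            "expected_abundance": self.expected_abundance.to_dict(),
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def _substreams(seed: int, n: int = 8) -> list[np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(n)
    return [np.random.default_rng(c) for c in children]


def generate_cohort(config: SynthConfig) -> pd.DataFrame:
    """Generate subject metadata for a twin cohort.

    Pairs are laid out deterministically: MZ pairs first, then DZ; the
    discordant quota is split between zygosities proportionally (so the
    default cohort has 3 discordant MZ and 6 discordant DZ pairs);
    concordant pairs fill the caries-free quota first. Decayed-surface
    counts for caries-active subjects are drawn uniformly from 1-17.
    """
    rng = _substreams(config.seed)[0]
    n_cf, n_ca, n_disc = config.caries_split
    n_disc_mz = min(config.n_mz, round(n_disc * config.n_mz / config.n_pairs))
    n_disc_dz = n_disc - n_disc_mz
    if n_disc_dz > config.n_pairs - config.n_mz:
        raise ConfigError("discordant quota cannot be satisfied by the zygosity split")

    rows = []
    cf_left, ca_left = n_cf, n_ca
    disc_left = {"MZ": n_disc_mz, "DZ": n_disc_dz}
    for p in range(config.n_pairs):
        zyg = "MZ" if p < config.n_mz else "DZ"
        # concordant pairs come first within each zygosity block
        n_conc_here = (config.n_mz - n_disc_mz) if zyg == "MZ" else (
            config.n_pairs - config.n_mz - n_disc_dz
        )
        idx_in_block = p if zyg == "MZ" else p - config.n_mz
        if idx_in_block < n_conc_here:
            if cf_left > 0:
                statuses = ("CF", "CF")
                cf_left -= 1
            else:
                statuses = ("CA", "CA")
                ca_left -= 1
        else:
            statuses = ("CF", "CA")
            disc_left[zyg] -= 1
        pair_id = f"P{p + 1:02d}"
        for k, status in enumerate(statuses):
            ds = int(rng.integers(1, 18)) if status == "CA" else 0
            rows.append(
                {
                    "subject_id": f"{pair_id}{'ab'[k]}",
                    "pair_id": pair_id,
                    "zygosity": zyg,
                    "caries_status": status,
                    "decayed_surfaces": ds,
                }
            )
    if cf_left or ca_left or any(disc_left.values()):
        raise ConfigError("caries_split could not be realized")  # pragma: no cover
    return validate_metadata(pd.DataFrame(rows))


def generate_counts(
    config: SynthConfig, metadata: pd.DataFrame
) -> tuple[CountMatrix, SynthTruth]:
    """Draw a transcript x subject count matrix plus its ground truth."""
    validate_metadata(metadata)
    (_, rng_base, rng_pair, rng_factor, rng_noise,
     rng_depth, rng_obs, rng_roles) = _substreams(config.seed)

    species = species_names(config.n_species)
    subjects = list(metadata["subject_id"])
    pairs = list(dict.fromkeys(metadata["pair_id"]))
    n_sp, n_sub = len(species), len(subjects)
    pair_of = dict(zip(metadata["subject_id"], metadata["pair_id"]))
    zyg_of = metadata.drop_duplicates("pair_id").set_index("pair_id")["zygosity"]

    lo, hi = config.baseline_log_mean_range
    baseline_log10 = pd.Series(rng_base.uniform(lo, hi, n_sp), index=species)

    pair_eff = pd.DataFrame(
        rng_pair.normal(0.0, config.pair_effect_sd, (len(pairs), n_sp)),
        index=pairs, columns=species,
    )
    mz_extra = pd.DataFrame(
        rng_pair.normal(0.0, config.mz_extra_effect_sd, (len(pairs), n_sp)),
        index=pairs, columns=species,
    )
    mz_extra.loc[zyg_of != "MZ", :] = 0.0

    factor_ids = [f"complex_{i + 1}" for i in range(len(config.complexes))]
    factors = pd.DataFrame(
        np.stack([rng_factor.normal(0.0, cx.factor_sd, n_sub) for cx in config.complexes])
        if config.complexes else np.zeros((0, n_sub)),
        index=factor_ids, columns=subjects,
    )

    noise = pd.DataFrame(
        rng_noise.normal(0.0, config.subject_noise_sd, (n_sp, n_sub)),
        index=species, columns=subjects,
    )

    eta = np.log(10.0) * baseline_log10.to_numpy()[:, None] + noise.to_numpy()
    for j, sub in enumerate(subjects):
        p = pair_of[sub]
        eta[:, j] += pair_eff.loc[p].to_numpy() + mz_extra.loc[p].to_numpy()
    loading_mat = np.zeros((n_sp, len(config.complexes)))
    sp_index = {s: i for i, s in enumerate(species)}
    for c, cx in enumerate(config.complexes):
        for t, l in zip(cx.member_taxa, cx.loadings):
            loading_mat[sp_index[t], c] = l
    if config.complexes:
        eta += loading_mat @ factors.to_numpy()

    intensity = np.exp(eta - eta.max(axis=0, keepdims=True))
    abundance = intensity / intensity.sum(axis=0, keepdims=True)

    depths = config.depth_mean * np.exp(
        rng_depth.normal(-0.5 * config.depth_log_sd**2, config.depth_log_sd, n_sub)
    )

    # fixed within-species transcript weights; transcripts differ in expression
    tps = config.transcripts_per_species
    t_weights = rng_obs.lognormal(0.0, 1.0, (n_sp, tps))
    t_weights /= t_weights.sum(axis=1, keepdims=True)

    mean_counts = (
        abundance[:, None, :] * t_weights[:, :, None] * depths[None, None, :]
    ).reshape(n_sp * tps, n_sub)
    if config.depth_dispersion > 1e-12:
        shape = 1.0 / config.depth_dispersion
        lam = rng_obs.gamma(shape, mean_counts * config.depth_dispersion)
        counts_arr = rng_obs.poisson(lam)
    else:
        counts_arr = rng_obs.poisson(mean_counts)

    transcript_ids = [f"{s}_t{k + 1:03d}" for s in species for k in range(tps)]
    sp_col = np.repeat(species, tps)
    fn_names = [r[0] for r in DEFAULT_ROLE_TABLE]
    fn_weights = np.array([r[3] for r in DEFAULT_ROLE_TABLE])
    fn_weights = fn_weights / fn_weights.sum()
    fn_assign = rng_roles.choice(fn_names, size=len(transcript_ids), p=fn_weights)
    fn_lookup = {r[0]: (r[1], r[2]) for r in DEFAULT_ROLE_TABLE}
    annotations = pd.DataFrame(
        {
            "species": sp_col,
            "genus": [genus_of(s) for s in sp_col],
            "role_category": [fn_lookup[f][1] for f in fn_assign],
            "subsystem": [fn_lookup[f][0] for f in fn_assign],
            "function": fn_assign,
        },
        index=pd.Index(transcript_ids, name="transcript_id"),
    )
    counts = pd.DataFrame(
        counts_arr.astype(np.int64), index=annotations.index, columns=subjects
    )

    expected_sign = pd.DataFrame(0, index=species, columns=species, dtype=int)
    members = {}
    for fid, cx in zip(factor_ids, config.complexes):
        members[fid] = list(cx.member_taxa)
        for i, (ti, li) in enumerate(zip(cx.member_taxa, cx.loadings)):
            for tj, lj in list(zip(cx.member_taxa, cx.loadings))[i + 1:]:
                s = int(np.sign(li * lj))
                expected_sign.loc[ti, tj] = s
                expected_sign.loc[tj, ti] = s

    truth = SynthTruth(
        baseline_log10=baseline_log10,
        pair_effects=pair_eff,
        mz_extra_effects=mz_extra,
        subject_noise=noise,
        factor_values=factors,
        expected_abundance=pd.DataFrame(abundance, index=species, columns=subjects),
        expected_sign=expected_sign,
        complex_members=members,
        transcript_map=annotations,
    )
    return CountMatrix(counts=counts, annotations=annotations), truth


def simulate(config: SynthConfig) -> tuple[pd.DataFrame, CountMatrix, SynthTruth]:
    """Cohort metadata + counts + truth in one call."""
    metadata = generate_cohort(config)
    counts, truth = generate_counts(config, metadata)
    return metadata, counts, truth
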