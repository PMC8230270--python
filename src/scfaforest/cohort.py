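"""Synthetic two-diet cohort generator with known ground truth.

Emulates a cross-sectional gut-microbiome study: two diet groups (vegan /
omnivore), an over-dispersed species read-count table in which a core of
highly prevalent, high-abundance species passes the downstream inclusion
filter, lifestyle/diet confounders, and fermentation-marker outcomes
(SCFA/BCFA, ammonia, umol/g wet weight) assembled from planted species
effects, confounder effects and Gaussian noise.  Every planted effect is
recorded so recovery can be tested against ground truth.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tables import (
    CONFOUNDERS,
    OUTCOMES,
    RANKS,
    AbundanceTable,
    read_abundance_table,
    read_metadata,
    validate_metadata,
    write_abundance_table,
    write_metadata,
)


class ConfigurationError(ValueError):
    """Raised when a simulation configuration field is invalid."""


# integer encodings used both when planting confounder effects and when
# building random-forest feature matrices
SEX_CODES = {"female": 0, "male": 1}
SMOKING_CODES = {"non_smoker": 0, "ex_smoker": 1, "smoker": 2}


@dataclass
class SimulationConfig:
    """All knobs of the synthetic cohort.

    ``prevalence`` and ``mean_log_abundance`` may be scalars or per-species
    arrays of length ``n_species``; ``prevalence`` may also be a
    ``{"vegan": ..., "omnivore": ...}`` mapping for group-specific presence.
    ``planted_effects`` maps an outcome name to ``[(species_id, coefficient)]``
    applied to log1p(read count); ``confounder_effects`` maps an outcome to
    ``[(covariate, coefficient)]`` on the (integer-encoded) covariate.
    """

    n_vegan: int = 36
    n_omnivore: int = 36
    n_species: int = 1200
    prevalence: object = 0.5
    mean_log_abundance: object = 3.0
    dispersion: float = 1.5
    planted_effects: dict = field(default_factory=dict)
    confounder_effects: dict = field(default_factory=dict)
    intercepts: dict = field(default_factory=dict)
    noise_sd: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_vegan < 2 or self.n_omnivore < 2:
            raise ConfigurationError("n_vegan and n_omnivore must be >= 2")
        if self.n_species < 1:
            raise ConfigurationError("n_species must be >= 1")
        if self.dispersion <= 0:
            raise ConfigurationError("dispersion must be > 0")
        for outcome, sd in self.noise_sd.items():
            if sd < 0:
                raise ConfigurationError(f"noise_sd must be >= 0 (outcome {outcome!r})")
        for arr in self._prevalence_arrays().values():
            if np.any((arr < 0) | (arr > 1)):
                raise ConfigurationError("prevalence must lie in [0, 1]")

    def _expand(self, value) -> np.ndarray:
        arr = np.broadcast_to(np.asarray(value, dtype=float), (self.n_species,))
        return np.array(arr)

    def _prevalence_arrays(self) -> dict[str, np.ndarray]:
        if isinstance(self.prevalence, dict):
            extra = set(self.prevalence) - {"vegan", "omnivore"}
            if extra:
                raise ConfigurationError(f"unknown prevalence group(s) {sorted(extra)}")
            return {g: self._expand(v) for g, v in self.prevalence.items()}
        arr = self._expand(self.prevalence)
        return {"vegan": arr, "omnivore": arr.copy()}


def species_ids(n: int) -> list[str]:
    return [f"sp{i + 1:04d}" for i in range(n)]


def _synthetic_lineage(ids: list[str]) -> pd.DataFrame:
    """Deterministic nested mock taxonomy: 3 species/genus, 9/family, ..."""
    rows = []
    for i in range(len(ids)):
        rows.append(
            {
                "phylum": f"Phylum_{i // 150 + 1:02d}",
                "class": f"Class_{i // 40 + 1:02d}",
                "family": f"Family_{i // 9 + 1:03d}",
                "genus": f"Genus_{i // 3 + 1:03d}",
                "species": f"Species_{i + 1:04d}",
            }
        )
    return pd.DataFrame(rows, index=ids, columns=list(RANKS))


def default_config(
    seed: int = 0,
    n_vegan: int = 36,
    n_omnivore: int = 36,
    n_species: int = 1200,
    n_core: int = 50,
) -> SimulationConfig:
    """Study-shaped defaults: 36+36 samples, 1200 species, ~50 passing the filter.

    The first ``n_core`` species form a prevalent (90%), abundant core (mean
    ~600 reads); mid-tier and rare species fall below the 50%-prevalence rule.
    Five core species are planted per fatty-acid outcome; the BCFA share their
    planted species with ammonia (positive BCFA-ammonia correlation) and fecal
    pH carries a negative effect on the SCFA (inverse pH-SCFA correlation).
    Effect and noise scales are set so the final-tier forest explains roughly
    0.2-0.45 of outcome variance at n = 72.
    """
    if n_species < n_core or n_core < 30:
        raise ConfigurationError("default config needs n_species >= n_core >= 30")
    n_mid = max(0, min(n_species, 600) - n_core)
    prevalence = np.full(n_species, 0.05)
    prevalence[:n_core] = 0.80
    prevalence[n_core:n_core + n_mid] = 0.25
    mean_log = np.full(n_species, np.log(8.0))
    mean_log[:n_core] = np.log(600.0)
    mean_log[n_core:n_core + n_mid] = np.log(40.0)
    ids = species_ids(n_species)

    def planted(start: int, coef: float) -> list:
        return [(ids[i], coef) for i in range(start, start + 5)]

    planted_effects = {
        "acetate": planted(0, 8.0),
        "propionate": planted(5, 3.0),
        "butyrate": planted(10, 3.2),
        "valerate": planted(15, 0.9),
        "isobutyrate": planted(20, 0.8),
        "isovalerate": planted(25, 0.9),
        # ammonia shares the BCFA species: protein-fermentation co-products
        "ammonia": planted(20, 1.1) + planted(25, 1.1),
    }
    confounder_effects = {
        "acetate": [("fecal_ph", -14.0), ("fiber", 0.12)],
        "propionate": [("fecal_ph", -6.0)],
        "butyrate": [("fecal_ph", -7.0), ("fiber", 0.06)],
        "valerate": [("fecal_ph", -1.2), ("protein", 0.012)],
        "isobutyrate": [("protein", 0.008)],
        "isovalerate": [("protein", 0.010)],
        "ammonia": [("protein", 0.06)],
    }
    intercepts = {
        "acetate": 40.0,
        "propionate": 15.0,
        "butyrate": 25.0,
        "valerate": 3.0,
        "isobutyrate": -4.0,
        "isovalerate": -4.0,
        "ammonia": -20.0,
    }
    noise_sd = {
        "acetate": 12.0,
        "propionate": 6.0,
        "butyrate": 7.0,
        "valerate": 2.0,
        "isobutyrate": 1.8,
        "isovalerate": 2.0,
        "ammonia": 5.0,
    }
    return SimulationConfig(
        n_vegan=n_vegan,
        n_omnivore=n_omnivore,
        n_species=n_species,
        prevalence={"vegan": prevalence, "omnivore": prevalence},
        mean_log_abundance=mean_log,
        dispersion=1.0,
        planted_effects=planted_effects,
        confounder_effects=confounder_effects,
        intercepts=intercepts,
        noise_sd=noise_sd,
        seed=seed,
    )


def null_config(seed: int = 0) -> SimulationConfig:
    """Default cohort with every planted species effect removed.

    Intercepts are raised to stand in for the mean level the planted species
    would otherwise contribute, keeping concentrations positive and on the
    same scale as the default cohort.
    """
    cfg = default_config(seed=seed)
    cfg.planted_effects = {}
    cfg.intercepts = {
        "acetate": 140.0,
        "propionate": 60.0,
        "butyrate": 75.0,
        "valerate": 25.0,
        "isobutyrate": 14.0,
        "isovalerate": 16.0,
        "ammonia": 30.0,
    }
    return cfg


def config_from_file(path) -> SimulationConfig:
    """Load a SimulationConfig from a YAML (or JSON) mapping mirroring its fields.

    ``prevalence`` and ``mean_log_abundance`` may be scalars, lists, or (for
    prevalence) a ``{vegan: ..., omnivore: ...}`` mapping; ``planted_effects``
    and ``confounder_effects`` are ``{outcome: [[name, coefficient], ...]}``.
    """
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigurationError(f"{path}: expected a mapping of config fields")
    known = {f.name for f in dataclasses.fields(SimulationConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigurationError(f"{path}: unknown field(s) {sorted(unknown)}")
    for key in ("planted_effects", "confounder_effects"):
        if key in raw:
            raw[key] = {
                outcome: [(str(name), float(coef)) for name, coef in pairs]
                for outcome, pairs in raw[key].items()
            }
    return SimulationConfig(**raw)


def _child_rng(seed: int, label: str) -> np.random.Generator:
    import zlib

    return np.random.default_rng(np.random.SeedSequence((seed, zlib.crc32(label.encode()))))


def _draw_counts(cfg: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    prev = cfg._prevalence_arrays()
    mean = np.exp(cfg._expand(cfg.mean_log_abundance))
    k = cfg.dispersion
    blocks = []
    index = []
    for group, n in (("vegan", cfg.n_vegan), ("omnivore", cfg.n_omnivore)):
        present = rng.random((n, cfg.n_species)) < prev[group][None, :]
        # negative binomial with mean m and shape k: p = k / (k + m)
        p = k / (k + mean)
        counts = rng.negative_binomial(k, p[None, :], size=(n, cfg.n_species))
        counts = np.where(present, np.maximum(counts, 1), 0)
        blocks.append(counts)
        prefix = "V" if group == "vegan" else "O"
        index.extend(f"{prefix}{i + 1:03d}" for i in range(n))
    return pd.DataFrame(
        np.vstack(blocks), index=index, columns=species_ids(cfg.n_species), dtype=np.int64
    )


def _draw_confounders(cfg: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Confounders with group contrasts shaped like a Western vegan/omnivore cohort."""
    rows = []
    specs = {
        # (vegan mean, omnivore mean, sd, low, high)
        "bmi": (22.9, 24.0, 2.5, 18.0, 30.0),
        "fiber": (46.0, 24.0, 10.0, 5.0, 90.0),
        "protein": (74.0, 89.0, 20.0, 20.0, 180.0),
        "fat": (88.0, 110.0, 25.0, 20.0, 220.0),
        "carbohydrates": (285.0, 243.0, 65.0, 80.0, 550.0),
        "fecal_ph": (6.41, 6.73, 0.47, 4.5, 8.5),
    }
    for group, n in (("vegan", cfg.n_vegan), ("omnivore", cfg.n_omnivore)):
        gi = 0 if group == "vegan" else 1
        df = pd.DataFrame(index=range(n))
        df["age"] = np.round(rng.uniform(30, 60, n), 1)
        df["sex"] = rng.choice(["female", "male"], size=n)
        for name, (mv, mo, sd, lo, hi) in specs.items():
            mu = mv if group == "vegan" else mo
            df[name] = np.clip(rng.normal(mu, sd, n), lo, hi).round(2)
        df["physical_activity"] = np.clip(rng.lognormal(np.log(2.5), 0.6, n), 0.0, 15.0).round(2)
        smoking_p = [(0.67, 0.22, 0.11), (0.58, 0.17, 0.25)][gi]
        df["smoking_status"] = rng.choice(
            ["non_smoker", "ex_smoker", "smoker"], size=n, p=smoking_p
        )
        df["alcohol"] = np.clip(rng.lognormal(np.log(4.0), 1.0, n), 0.0, 80.0).round(2)
        df["diet_group"] = group
        rows.append(df)
    out = pd.concat(rows, ignore_index=True)
    prefix = ["V"] * cfg.n_vegan + ["O"] * cfg.n_omnivore
    nums = list(range(1, cfg.n_vegan + 1)) + list(range(1, cfg.n_omnivore + 1))
    out.index = [f"{p}{i:03d}" for p, i in zip(prefix, nums)]
    cols = ["diet_group", *CONFOUNDERS]
    return out[cols]


def encode_covariates(metadata: pd.DataFrame, columns=CONFOUNDERS) -> pd.DataFrame:
    """Integer-encode sex and smoking status; passthrough numeric covariates."""
    enc = metadata[list(columns)].copy()
    if "sex" in enc.columns:
        enc["sex"] = enc["sex"].map(SEX_CODES)
        if enc["sex"].isna().any():
            raise ConfigurationError("sex levels must be 'female' or 'male'")
    if "smoking_status" in enc.columns:
        enc["smoking_status"] = enc["smoking_status"].map(SMOKING_CODES)
        if enc["smoking_status"].isna().any():
            raise ConfigurationError(f"smoking levels must be {list(SMOKING_CODES)}")
    return enc.astype(float)


def plant_outcomes(
    table: AbundanceTable, metadata: pd.DataFrame, config: SimulationConfig
) -> pd.DataFrame:
    """Assemble outcomes from planted species/confounder effects plus noise.

    outcome = intercept + sum coef*log1p(count) + sum coef*covariate
    + N(0, noise_sd), clipped at zero.  The realised effect maps are stored in
    ``metadata.attrs['ground_truth']``.
    """
    md = metadata.copy()
    log_counts = np.log1p(table.counts.astype(float))
    enc = encode_covariates(md)
    rng = _child_rng(config.seed, "outcomes")
    ground_truth = {"planted_effects": {}, "confounder_effects": {}, "clipped": {}}
    for outcome in OUTCOMES:
        y = np.full(table.n_samples, float(config.intercepts.get(outcome, 0.0)))
        for sp, coef in config.planted_effects.get(outcome, []):
            if sp not in table.counts.columns:
                raise ConfigurationError(f"unknown species id {sp!r} in planted_effects")
            y = y + coef * log_counts[sp].to_numpy()
        for cov, coef in config.confounder_effects.get(outcome, []):
            if cov not in enc.columns:
                raise ConfigurationError(f"unknown covariate {cov!r} in confounder_effects")
            y = y + coef * enc[cov].to_numpy()
        sd = float(config.noise_sd.get(outcome, 0.0))
        if sd > 0:
            y = y + rng.normal(0.0, sd, size=y.shape)
        clipped = int((y < 0).sum())
        y = np.clip(y, 0.0, None)
        md[outcome] = y
        ground_truth["planted_effects"][outcome] = [
            [sp, float(c)] for sp, c in config.planted_effects.get(outcome, [])
        ]
        ground_truth["confounder_effects"][outcome] = [
            [cov, float(c)] for cov, c in config.confounder_effects.get(outcome, [])
        ]
        ground_truth["clipped"][outcome] = clipped
    md.attrs["ground_truth"] = ground_truth
    return md


def generate_cohort(config: SimulationConfig) -> tuple[AbundanceTable, pd.DataFrame]:
    """Draw the count table, confounders and outcomes for one synthetic cohort."""
    counts = _draw_counts(config, _child_rng(config.seed, "counts"))
    table = AbundanceTable(counts=counts, lineage=_synthetic_lineage(list(counts.columns)))
    metadata = _draw_confounders(config, _child_rng(config.seed, "confounders"))
    metadata = plant_outcomes(table, metadata, config)
    return table, validate_metadata(metadata)


def write_fixture(table: AbundanceTable, metadata: pd.DataFrame, directory) -> dict[str, str]:
    """Write abundance + metadata TSVs (and ground truth, if present) to ``directory``."""
    os.makedirs(directory, exist_ok=True)
    paths = {
        "abundance": os.path.join(directory, "abundance.tsv"),
        "metadata": os.path.join(directory, "metadata.tsv"),
    }
    write_abundance_table(table, paths["abundance"])
    write_metadata(metadata, paths["metadata"])
    truth = metadata.attrs.get("ground_truth")
    if truth is not None:
        paths["ground_truth"] = os.path.join(directory, "ground_truth.json")
        with open(paths["ground_truth"], "w") as fh:
            json.dump(truth, fh, indent=2, sort_keys=True)
    return paths


def read_fixture(directory) -> tuple[AbundanceTable, pd.DataFrame]:
    table = read_abundance_table(os.path.join(directory, "abundance.tsv"))
    metadata = read_metadata(os.path.join(directory, "metadata.tsv"))
    truth_path = os.path.join(directory, "ground_truth.json")
    if os.path.exists(truth_path):
        with open(truth_path) as fh:
            metadata.attrs["ground_truth"] = json.load(fh)
    return table, metadata
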