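"""End-to-end orchestration: simulate/load -> filter -> diversity -> stats -> forests.

A :class:`RunManifest` captures everything needed to reproduce a run
byte-identically: input paths or a simulation config, per-stage settings and
one master seed fanned out to stages through a stable hash derivation.  All
tables are written as TSV at full precision; display rounding happens only in
rendered summaries.
"""

from __future__ import annotations

import dataclasses
import json
import os
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml

from . import cohort, diversity, forest, stats, tables
from .tables import FATTY_ACID_OUTCOMES, OUTCOMES

FLOAT_FMT = "%.10g"


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage, partial outputs are kept."""


def stage_seed(master: int, stage: str) -> int:
    """Stable per-stage seed derivation from the master seed."""
    return int(
        np.random.SeedSequence((master, zlib.crc32(stage.encode()))).generate_state(1)[0]
        % (2**31 - 1)
    )


@dataclass
class RunManifest:
    """Inputs, per-stage settings and the master seed of one pipeline run."""

    out_dir: str
    seed: int = 0
    # either simulate=True (synthetic cohort) or paths to existing TSVs
    simulate: bool = True
    abundance_path: str | None = None
    metadata_path: str | None = None
    n_vegan: int = 36
    n_omnivore: int = 36
    n_species: int = 1200
    outcomes: tuple = FATTY_ACID_OUTCOMES
    groups: tuple = forest.GROUPS
    n_runs: int = 100
    n_trees: int = 2000
    train_fraction: float = 0.75
    importance_threshold: float = 2.0
    nmds_starts: int = 20
    nmds_dimensions: int = 2
    shannon_base: float | None = None

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["outcomes"] = list(self.outcomes)
        d["groups"] = list(self.groups)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunManifest":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise PipelineError(f"manifest: unknown keys {sorted(unknown)}")
        d = dict(d)
        for key in ("outcomes", "groups"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunManifest":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def rfr_config(self) -> forest.RFRConfig:
        return forest.RFRConfig(
            n_runs=self.n_runs,
            n_trees=self.n_trees,
            train_fraction=self.train_fraction,
            importance_threshold=self.importance_threshold,
            seed=stage_seed(self.seed, "rfr"),
        )

    def validate(self) -> None:
        if not self.simulate:
            for name in ("abundance_path", "metadata_path"):
                path = getattr(self, name)
                if path is None or not os.path.exists(path):
                    raise PipelineError(f"manifest: {name} missing or not found: {path!r}")


def render_importance_grid(
    selections, threshold: float = 2.0, outcomes=FATTY_ACID_OUTCOMES
) -> pd.DataFrame:
    """Species x outcome grid of mean %IncMSE, blank below the threshold.

    Rows are ordered by each species' maximum importance across outcomes,
    mirroring the heat-grid presentation of the selection model.
    """
    cells: dict[str, dict[str, float]] = {}
    for sel in selections:
        for sp, v in sel.mean_importance.items():
            cells.setdefault(sp, {})[sel.outcome] = float(v)
    grid = pd.DataFrame.from_dict(cells, orient="index").reindex(columns=list(outcomes))
    if grid.empty:
        return pd.DataFrame(columns=list(outcomes))
    grid = grid.loc[grid.max(axis=1).sort_values(ascending=False).index]
    return grid


def _write(df: pd.DataFrame, path, index_label: str) -> None:
    out = df.copy()
    out.index.name = index_label
    out.to_csv(path, sep="\t", float_format=FLOAT_FMT)


def run_full_analysis(manifest: RunManifest) -> dict[str, str]:
    """Execute every stage and write all report tables; returns artifact paths."""
    manifest.validate()
    os.makedirs(manifest.out_dir, exist_ok=True)
    paths: dict[str, str] = {}

    def out(name: str) -> str:
        p = os.path.join(manifest.out_dir, name)
        paths[name.split(".")[0]] = p
        return p

    stage = "load"
    try:
        if manifest.simulate:
            cfg = cohort.default_config(
                seed=stage_seed(manifest.seed, "simulate"),
                n_vegan=manifest.n_vegan,
                n_omnivore=manifest.n_omnivore,
                n_species=manifest.n_species,
            )
            table, metadata = cohort.generate_cohort(cfg)
            cohort.write_fixture(table, metadata, manifest.out_dir)
            paths["abundance"] = os.path.join(manifest.out_dir, "abundance.tsv")
            paths["metadata"] = os.path.join(manifest.out_dir, "metadata.tsv")
        else:
            table = tables.read_abundance_table(manifest.abundance_path)
            metadata = tables.read_metadata(manifest.metadata_path)

        stage = "filter"
        filt = tables.filter_species_for_rfr(table, metadata)
        _write(filt.report, out("filter_report.tsv"), "taxon_id")
        tables.write_abundance_table(filt.table, out("abundance_filtered.tsv"))

        stage = "sharing_summary"
        sharing = tables.sharing_summary(table, metadata)
        _write(sharing.table, out("sharing_summary.tsv"), "rank")

        stage = "diversity"
        alpha = pd.DataFrame(
            {
                "shannon": diversity.alpha_diversity(
                    table, "shannon", base=manifest.shannon_base
                ),
                "simpson": diversity.alpha_diversity(table, "simpson"),
            }
        )
        _write(alpha, out("alpha_diversity.tsv"), "sample_id")
        ordinations = {}
        for metric in diversity.METRICS:
            dm = diversity.distance_matrix(table, metric=metric)
            _write(
                pd.DataFrame(dm.data, index=list(dm.ids), columns=list(dm.ids)),
                out(f"distance_{metric}.tsv"),
                "sample_id",
            )
            ord_ = diversity.nmds(
                dm,
                k=manifest.nmds_dimensions,
                n_starts=manifest.nmds_starts,
                seed=stage_seed(manifest.seed, f"nmds/{metric}"),
            )
            _write(ord_.frame, out(f"nmds_{metric}.tsv"), "sample_id")
            ordinations[metric] = ord_

        stage = "group_comparisons"
        variables = [c for c in metadata.columns if c != "diet_group"]
        comparisons = stats.compare_groups_table(metadata, variables)
        _write(comparisons, out("group_comparisons.tsv"), "variable")

        stage = "correlations"
        corr_vars = [c for c in list(OUTCOMES) + ["fecal_ph", "fiber", "protein", "fat",
                                                  "carbohydrates"] if c in metadata.columns]
        corr = stats.spearman_matrix(metadata[corr_vars])
        _write(corr.r, out("spearman_r.tsv"), "variable")
        _write(corr.p, out("spearman_p.tsv"), "variable")
        _write(corr.flags, out("spearman_flags.tsv"), "variable")

        stage = "rfr"
        analyses = forest.run_group_analyses(
            filt.table,
            metadata,
            config=manifest.rfr_config(),
            outcomes=manifest.outcomes,
            groups=manifest.groups,
        )
        _write(
            analyses.performance.set_index(["group", "outcome", "tier"]),
            out("rfr_performance.tsv"),
            "group",
        )
        for group in manifest.groups:
            sels = [analyses.selections[(group, o)] for o in manifest.outcomes]
            grid = render_importance_grid(
                sels, manifest.importance_threshold, outcomes=manifest.outcomes
            )
            _write(grid, out(f"importance_grid_{group}.tsv"), "species")
        archive_rows = []
        for (group, outcome), imp in analyses.importances.items():
            long = imp.grid.stack().rename("inc_mse_pct").reset_index()
            long.columns = ["run", "feature", "inc_mse_pct"]
            long.insert(0, "outcome", outcome)
            long.insert(0, "group", group)
            archive_rows.append(long)
        archive = pd.concat(archive_rows, ignore_index=True)
        archive.to_csv(out("importance_runs.tsv"), sep="\t", index=False,
                       float_format=FLOAT_FMT)

        stage = "manifest"
        with open(out("manifest.json"), "w") as fh:
            json.dump(manifest.to_dict(), fh, indent=2, sort_keys=True)
        log = {
            "seed": manifest.seed,
            "rfr": dataclasses.asdict(manifest.rfr_config()),
            "nmds_stress": {m: o.stress for m, o in ordinations.items()},
            "nmds_converged": {m: bool(o.converged) for m, o in ordinations.items()},
            "n_samples": int(table.n_samples),
            "n_species_total": int(table.n_taxa),
            "n_species_filtered": int(filt.table.n_taxa),
            "versions": _versions(),
        }
        log["rfr"]["confounders"] = list(log["rfr"]["confounders"])
        with open(out("run_log.json"), "w") as fh:
            json.dump(log, fh, indent=2, sort_keys=True)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
    return paths


def _versions() -> dict[str, str]:
    import sklearn
    import scipy
    import skbio

    import scfaforest

    return {
        "scfaforest": getattr(scfaforest, "__version__", "0"),
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "scipy": scipy.__version__,
        "scikit-learn": sklearn.__version__,
        "scikit-bio": skbio.__version__,
    }
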