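"""Cross-validated random-forest regression and predictive-species selection.

The procedure: for each fermentation-marker outcome, repeat ``n_runs`` times a
random 75/25 train/test split, fit a random forest with ``n_trees`` on the
training part, record test-set predictions, and measure per-feature
permutation importance as the percentage increase in test MSE (%IncMSE).
Species whose mean %IncMSE across runs exceeds a threshold (default 2) are
"predictive".  Three feature tiers are compared per outcome: *baseline*
(confounders only), *full* (confounders + all filtered species, the tier that
drives selection) and *final* (confounders + selected species), each scored by
mean RMSE, mean R-squared, and RMSE as a percent of the outcome mean.

Organised statsmodels-style: :class:`MicrobiotaForestModel` is built from data
and ``fit()`` returns a :class:`MicrobiotaForestResults` with the estimates and
a ``summary()`` table; the underlying steps are available as functions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

from .cohort import encode_covariates
from .tables import CONFOUNDERS, FATTY_ACID_OUTCOMES, AbundanceTable

GROUPS = ("vegan", "omnivore", "total")
TIERS = ("baseline", "full", "final")


def rmse(predicted, actual) -> float:
    """Root mean squared error sqrt(mean((x - y)^2))."""
    x = np.asarray(predicted, dtype=float)
    y = np.asarray(actual, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("predicted and actual must be 1-D vectors of equal length")
    if x.size == 0:
        raise ValueError("empty vectors")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values")
    return float(np.sqrt(np.mean((x - y) ** 2)))


def r_squared(predicted, actual) -> float:
    """Explained variance 1 - SSE/SST; may be negative.  NaN when actual is constant."""
    x = np.asarray(predicted, dtype=float)
    y = np.asarray(actual, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValueError("predicted and actual must be equal-length vectors (n >= 2)")
    sst = float(((y - y.mean()) ** 2).sum())
    if sst == 0.0:
        warnings.warn("constant actual vector: R^2 undefined", stacklevel=2)
        return float("nan")
    sse = float(((y - x) ** 2).sum())
    return 1.0 - sse / sst


@dataclass
class RFRConfig:
    """Configuration of the cross-validated forest procedure.

    Defaults mirror the study conditions (100 runs of 2000 trees, 75/25
    splits, selection at mean %IncMSE > 2) and R randomForest's regression
    defaults for the per-split hyperparameters (mtry = p/3, node size 5).
    """

    n_runs: int = 100
    n_trees: int = 2000
    train_fraction: float = 0.75
    importance_threshold: float = 2.0
    confounders: tuple = CONFOUNDERS
    n_permutation_repeats: int = 5
    selection_mode: str = "mean"  # "mean" | "frequency" (> threshold in >50% of runs)
    max_features: float = 1.0 / 3.0
    min_samples_leaf: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must lie strictly between 0 and 1")
        if self.n_runs < 1 or self.n_trees < 1:
            raise ValueError("n_runs and n_trees must be >= 1")
        if not np.isfinite(self.importance_threshold):
            raise ValueError("importance_threshold must be finite")
        if self.selection_mode not in ("mean", "frequency"):
            raise ValueError("selection_mode must be 'mean' or 'frequency'")


@dataclass
class CVRunResult:
    run_index: int
    train_ids: list
    test_ids: list
    importance: pd.Series  # %IncMSE per feature on this run's test set
    predicted: np.ndarray
    actual: np.ndarray


def train_size(n: int, fraction: float) -> int:
    """Training-set size: fraction of n rounded to the nearest integer."""
    return int(np.floor(n * fraction + 0.5))


def permutation_importance(model, X_test, y_test, seed: int = 0, n_repeats: int = 5):
    """Per-feature %IncMSE: percent increase of test MSE when the feature is permuted.

    Averaged over ``n_repeats`` independent permutations per feature; may be
    negative.  A zero baseline MSE leaves importances undefined (NaN, with a
    warning).  Returns a Series when ``X_test`` is a DataFrame.
    """
    names = list(X_test.columns) if isinstance(X_test, pd.DataFrame) else None
    X = np.asarray(X_test, dtype=float)
    y = np.asarray(y_test, dtype=float)
    n, p = X.shape
    if n < 2:
        raise ValueError("need at least 2 test samples")
    base_mse = float(np.mean((model.predict(X) - y) ** 2))
    if base_mse == 0.0:
        warnings.warn("zero baseline MSE: %IncMSE undefined", stacklevel=2)
        out = np.full(p, np.nan)
        return pd.Series(out, index=names) if names is not None else out
    rng = np.random.default_rng(seed)
    blocks = np.empty((n_repeats * p, n, X.shape[1]), dtype=float)
    for r in range(n_repeats):
        for j in range(p):
            Xp = X.copy()
            Xp[:, j] = X[rng.permutation(n), j]
            blocks[r * p + j] = Xp
    preds = model.predict(blocks.reshape(-1, X.shape[1])).reshape(n_repeats, p, n)
    mses = ((preds - y[None, None, :]) ** 2).mean(axis=2)
    pct = 100.0 * (mses - base_mse) / base_mse
    out = pct.mean(axis=0)
    return pd.Series(out, index=names) if names is not None else out


def run_cv_rfr(X: pd.DataFrame, y, config: RFRConfig) -> list[CVRunResult]:
    """Repeated random-split forest fits with test-set predictions and %IncMSE."""
    y = pd.Series(np.asarray(y, dtype=float), index=X.index)
    if X.isna().to_numpy().any() or y.isna().any():
        raise ValueError("missing values in features or outcome")
    n = len(X)
    if n < 8:
        raise ValueError("need at least 8 samples for 75/25 cross-validation")
    if y.nunique() == 1:
        raise ValueError("constant outcome: nothing to regress")
    n_train = train_size(n, config.train_fraction)
    if n - n_train < 2:
        raise ValueError(
            "fewer than 2 test samples per split; increase the group size or "
            "lower train_fraction"
        )
    root = np.random.SeedSequence(config.seed)
    children = root.spawn(config.n_runs)
    results = []
    Xv = X.to_numpy(dtype=float)
    yv = y.to_numpy()
    for i, child in enumerate(children):
        split_seed, rf_seed, perm_seed = child.generate_state(3)
        rng = np.random.default_rng(split_seed)
        perm = rng.permutation(n)
        train_idx, test_idx = perm[:n_train], perm[n_train:]
        rf = RandomForestRegressor(
            n_estimators=config.n_trees,
            max_features=config.max_features,
            min_samples_leaf=config.min_samples_leaf,
            random_state=int(rf_seed % (2**31 - 1)),
            n_jobs=1,
        )
        rf.fit(Xv[train_idx], yv[train_idx])
        predicted = rf.predict(Xv[test_idx])
        imp = permutation_importance(
            rf,
            pd.DataFrame(Xv[test_idx], columns=X.columns),
            yv[test_idx],
            seed=int(perm_seed % (2**31 - 1)),
            n_repeats=config.n_permutation_repeats,
        )
        results.append(
            CVRunResult(
                run_index=i,
                train_ids=list(X.index[train_idx]),
                test_ids=list(X.index[test_idx]),
                importance=imp,
                predicted=predicted,
                actual=yv[test_idx].copy(),
            )
        )
    return results


@dataclass
class ImportanceMatrix:
    """Runs x features grid of %IncMSE values for one (group, outcome) model."""

    outcome: str
    group: str
    grid: pd.DataFrame  # index = run, columns = features

    @property
    def features(self) -> list[str]:
        return list(self.grid.columns)

    @property
    def mean(self) -> pd.Series:
        return self.grid.mean(axis=0)


def importance_matrix(runs: list[CVRunResult], outcome: str = "", group: str = "total"):
    grid = pd.DataFrame([r.importance for r in runs]).reset_index(drop=True)
    grid.index.name = "run"
    return ImportanceMatrix(outcome=outcome, group=group, grid=grid)


@dataclass
class SelectionResult:
    """Predictive species for one (group, outcome): ids plus their mean %IncMSE."""

    outcome: str
    group: str
    selected: list
    mean_importance: pd.Series  # over selected species only
    threshold: float


def select_predictive_species(
    imp: ImportanceMatrix,
    threshold: float = 2.0,
    species=None,
    mode: str = "mean",
) -> SelectionResult:
    """Select species with mean %IncMSE strictly greater than ``threshold``.

    ``mode='frequency'`` instead requires a per-run %IncMSE above the threshold
    in more than half of the runs.  Confounder columns are excluded via
    ``species`` (defaults to all grid columns).
    """
    cols = list(species) if species is not None else imp.features
    grid = imp.grid[cols]
    if grid.isna().to_numpy().any():
        raise ValueError("importance grid is incomplete")
    means = grid.mean(axis=0)
    if mode == "mean":
        chosen = means.index[means > threshold]
    elif mode == "frequency":
        freq = (grid > threshold).mean(axis=0)
        chosen = freq.index[freq > 0.5]
    else:
        raise ValueError("mode must be 'mean' or 'frequency'")
    return SelectionResult(
        outcome=imp.outcome,
        group=imp.group,
        selected=list(chosen),
        mean_importance=means.loc[chosen],
        threshold=threshold,
    )


@dataclass
class ModelPerformance:
    group: str
    outcome: str
    tier: str
    rmse_mean: float
    r2_mean: float
    rmse_percent: float

    def as_row(self) -> dict:
        return {
            "group": self.group,
            "outcome": self.outcome,
            "tier": self.tier,
            "rmse": self.rmse_mean,
            "r2": self.r2_mean,
            "rmse_percent": self.rmse_percent,
        }


def _score_runs(runs, group, outcome, tier, y_mean) -> ModelPerformance:
    rmses = [rmse(r.predicted, r.actual) for r in runs]
    r2s = [r_squared(r.predicted, r.actual) for r in runs]
    mean_rmse = float(np.mean(rmses))
    return ModelPerformance(
        group=group,
        outcome=outcome,
        tier=tier,
        rmse_mean=mean_rmse,
        r2_mean=float(np.nanmean(r2s)),
        rmse_percent=100.0 * mean_rmse / y_mean,
    )


@dataclass
class TierEvaluation:
    """Baseline/full/final performances plus the full model's importance grid."""

    performances: list  # three ModelPerformance records, tier order as TIERS
    importance: ImportanceMatrix
    selection: SelectionResult
    empty_selection: bool
    runs: dict = field(default_factory=dict)  # tier -> list[CVRunResult]

    @property
    def performance_frame(self) -> pd.DataFrame:
        return pd.DataFrame([p.as_row() for p in self.performances])


def evaluate_model_tiers(
    X_species: pd.DataFrame,
    X_confounders: pd.DataFrame,
    y,
    config: RFRConfig,
    outcome: str = "outcome",
    group: str = "total",
) -> TierEvaluation:
    """Run the baseline/full/final tier comparison for one outcome.

    Selection is computed once from the full tier's importance grid and reused
    for the final tier.  All tiers share the same per-run splits (same seed),
    so tiers are compared on identical resamples.  An empty selection makes
    the final tier identical to baseline (flagged).
    """
    y = pd.Series(np.asarray(y, dtype=float), index=X_species.index)
    y_mean = float(y.mean())
    baseline_runs = run_cv_rfr(X_confounders, y, config)
    full_X = pd.concat([X_confounders, X_species], axis=1)
    full_runs = run_cv_rfr(full_X, y, config)
    imp = importance_matrix(full_runs, outcome=outcome, group=group)
    selection = select_predictive_species(
        imp,
        threshold=config.importance_threshold,
        species=list(X_species.columns),
        mode=config.selection_mode,
    )
    empty = len(selection.selected) == 0
    if empty:
        warnings.warn(
            f"empty selection for {group}/{outcome}: final tier equals baseline",
            stacklevel=2,
        )
        final_runs = baseline_runs
    else:
        final_X = pd.concat([X_confounders, X_species[selection.selected]], axis=1)
        final_runs = run_cv_rfr(final_X, y, config)
    performances = [
        _score_runs(baseline_runs, group, outcome, "baseline", y_mean),
        _score_runs(full_runs, group, outcome, "full", y_mean),
        _score_runs(final_runs, group, outcome, "final", y_mean),
    ]
    return TierEvaluation(
        performances=performances,
        importance=imp,
        selection=selection,
        empty_selection=empty,
        runs={"baseline": baseline_runs, "full": full_runs, "final": final_runs},
    )


class MicrobiotaForestModel:
    """Random-forest stability-selection model for one outcome in one group.

    Parameters
    ----------
    y
        Outcome concentrations (umol/g), one value per sample.
    species
        Samples x species feature frame (read counts, already filtered).
    confounders
        Samples x covariates frame, categorical covariates integer-encoded.
    config
        :class:`RFRConfig`; defaults to the study conditions.
    """

    def __init__(
        self,
        y,
        species: pd.DataFrame,
        confounders: pd.DataFrame,
        config: RFRConfig | None = None,
        outcome: str = "outcome",
        group: str = "total",
    ) -> None:
        self.config = config if config is not None else RFRConfig()
        self.y = pd.Series(np.asarray(y, dtype=float), index=species.index)
        self.species = species
        self.confounders = confounders
        self.outcome = outcome
        self.group = group
        if list(species.index) != list(confounders.index):
            raise ValueError("species and confounder frames must share sample order")

    @classmethod
    def from_tables(
        cls,
        table: AbundanceTable,
        metadata: pd.DataFrame,
        outcome: str,
        group: str = "total",
        config: RFRConfig | None = None,
    ) -> "MicrobiotaForestModel":
        """Build the model from an abundance table and metadata.

        ``group`` restricts to one diet group ('vegan'/'omnivore') or pools
        all samples ('total').
        """
        if group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}")
        cfg = config if config is not None else RFRConfig()
        ids = [s for s in table.sample_ids if s in metadata.index]
        md = metadata.loc[ids]
        if group != "total":
            ids = [s for s in ids if md.loc[s, "diet_group"] == group]
            md = metadata.loc[ids]
        species = table.counts.loc[ids].astype(float)
        conf = encode_covariates(md, columns=cfg.confounders)
        return cls(
            md[outcome], species, conf, config=cfg, outcome=outcome, group=group
        )

    def fit(self) -> "MicrobiotaForestResults":
        evaluation = evaluate_model_tiers(
            self.species,
            self.confounders,
            self.y,
            self.config,
            outcome=self.outcome,
            group=self.group,
        )
        return MicrobiotaForestResults(self, evaluation)


class MicrobiotaForestResults:
    """Fitted tier comparison: performances, importance grid, selected species."""

    def __init__(self, model: MicrobiotaForestModel, evaluation: TierEvaluation) -> None:
        self.model = model
        self.evaluation = evaluation
        self.performance = evaluation.performance_frame
        self.importance = evaluation.importance
        self.selection = evaluation.selection
        self.empty_selection = evaluation.empty_selection

    @property
    def selected_species(self) -> list:
        return list(self.selection.selected)

    @property
    def mean_importance(self) -> pd.Series:
        """Mean %IncMSE per species across CV runs (full model)."""
        return self.importance.grid[list(self.model.species.columns)].mean(axis=0)

    def summary(self) -> str:
        cfg = self.model.config
        lines = [
            "Random-forest tier comparison",
            "=" * 64,
            f"outcome: {self.model.outcome}    group: {self.model.group}    "
            f"n = {len(self.model.y)}",
            f"runs: {cfg.n_runs}   trees: {cfg.n_trees}   "
            f"split: {cfg.train_fraction:.0%}/{1 - cfg.train_fraction:.0%}   "
            f"threshold: >{cfg.importance_threshold:g} %IncMSE ({cfg.selection_mode})",
            "-" * 64,
            f"{'tier':<10}{'RMSE':>10}{'R2':>10}{'RMSE%':>10}",
        ]
        for p in self.evaluation.performances:
            lines.append(
                f"{p.tier:<10}{p.rmse_mean:>10.2f}{p.r2_mean:>10.2f}{p.rmse_percent:>9.1f}%"
            )
        lines.append("-" * 64)
        if self.selected_species:
            lines.append("selected species (mean %IncMSE):")
            for sp, v in self.selection.mean_importance.sort_values(ascending=False).items():
                lines.append(f"  {sp:<24}{v:>8.2f}")
        else:
            lines.append("selected species: none (final tier equals baseline)")
        return "\n".join(lines)

    def plot_importance(self, ax=None, top: int = 20):
        """Horizontal bar chart of the top mean %IncMSE species."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 0.3 * top + 1))
        vals = self.mean_importance.sort_values().tail(top)
        ax.barh(vals.index, vals.to_numpy())
        ax.axvline(self.model.config.importance_threshold, ls="--", color="grey")
        ax.set_xlabel("mean %IncMSE")
        ax.set_title(f"{self.model.outcome} ({self.model.group})")
        return ax


@dataclass
class GroupAnalyses:
    """Per-group, per-outcome tier performances and selections."""

    performance: pd.DataFrame  # group x outcome x tier rows
    selections: dict  # (group, outcome) -> SelectionResult
    importances: dict  # (group, outcome) -> ImportanceMatrix
    results: dict  # (group, outcome) -> MicrobiotaForestResults


def run_group_analyses(
    table: AbundanceTable,
    metadata: pd.DataFrame,
    config: RFRConfig | None = None,
    outcomes=FATTY_ACID_OUTCOMES,
    groups=GROUPS,
) -> GroupAnalyses:
    """Tier evaluation and selection per diet group and pooled, per outcome.

    Each (group, outcome) model gets its own seed derived stably from the
    master seed, so single models can be reproduced in isolation.
    """
    import zlib

    cfg = config if config is not None else RFRConfig()
    rows, selections, importances, results = [], {}, {}, {}
    for group in groups:
        for outcome in outcomes:
            child = zlib.crc32(f"{group}/{outcome}".encode())
            model_cfg = replace(cfg, seed=int(np.random.SeedSequence((cfg.seed, child)).generate_state(1)[0] % (2**31 - 1)))
            model = MicrobiotaForestModel.from_tables(
                table, metadata, outcome, group=group, config=model_cfg
            )
            res = model.fit()
            rows.append(res.performance)
            selections[(group, outcome)] = res.selection
            importances[(group, outcome)] = res.importance
            results[(group, outcome)] = res
    performance = pd.concat(rows, ignore_index=True)
    return GroupAnalyses(
        performance=performance,
        selections=selections,
        importances=importances,
        results=results,
    )
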