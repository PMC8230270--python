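"""Abundance tables, sample metadata, the species-inclusion filter and taxon sharing.

The central containers are :class:`AbundanceTable` (samples x taxa read counts
with a five-rank taxonomic lineage per taxon) and a validated sample-metadata
``pandas.DataFrame``.  Files are plain TSV: taxa as rows, lineage ranks as the
first columns, one column per sample; metadata one row per sample.
"""

from __future__ import annotations

import decimal
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

RANKS = ("phylum", "class", "family", "genus", "species")

DIET_GROUPS = ("vegan", "omnivore")

#: Confounder covariates adjusted for in the random-forest models.
CONFOUNDERS = (
    "age",
    "sex",
    "bmi",
    "physical_activity",
    "smoking_status",
    "fecal_ph",
    "protein",
    "fat",
    "carbohydrates",
    "fiber",
    "alcohol",
)

#: Fermentation-marker outcomes (umol/g wet weight).
SCFA_OUTCOMES = ("acetate", "propionate", "butyrate", "valerate")
BCFA_OUTCOMES = ("isobutyrate", "isovalerate")
FATTY_ACID_OUTCOMES = SCFA_OUTCOMES + BCFA_OUTCOMES
OUTCOMES = FATTY_ACID_OUTCOMES + ("ammonia",)

METADATA_COLUMNS = ("diet_group",) + CONFOUNDERS + OUTCOMES

SEX_LEVELS = ("female", "male")
SMOKING_LEVELS = ("non_smoker", "ex_smoker", "smoker")


class ValidationError(ValueError):
    """Raised when a table or metadata file violates its invariants."""


def _round_half_up(x: float, ndigits: int = 2) -> float:
    q = decimal.Decimal(10) ** -ndigits
    return float(decimal.Decimal(repr(float(x))).quantize(q, rounding=decimal.ROUND_HALF_UP))


@dataclass
class AbundanceTable:
    """Samples x taxa integer read counts plus per-taxon lineage.

    Parameters
    ----------
    counts
        DataFrame indexed by sample id with one integer column per taxon id.
    lineage
        DataFrame indexed by taxon id with the columns in :data:`RANKS`.
        Unknown ranks are empty strings (explicit placeholders).
    """

    counts: pd.DataFrame
    lineage: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.counts.index.is_unique:
            raise ValidationError("duplicate sample ids in abundance table")
        if not self.counts.columns.is_unique:
            raise ValidationError("duplicate taxon ids in abundance table")
        if list(self.lineage.index) != list(self.counts.columns):
            raise ValidationError("lineage index must match count columns")
        if list(self.lineage.columns) != list(RANKS):
            raise ValidationError(f"lineage columns must be {RANKS}")
        vals = self.counts.to_numpy()
        if vals.size:
            if not np.issubdtype(vals.dtype, np.integer):
                if not np.all(np.equal(np.mod(vals, 1), 0)):
                    raise ValidationError("counts must be integers")
                self.counts = self.counts.astype(np.int64)
                vals = self.counts.to_numpy()
            if (vals < 0).any():
                raise ValidationError("counts must be non-negative")
        lin = self.lineage.to_numpy()
        if lin.size and not (self.lineage.astype(str) != "nan").to_numpy().all():
            raise ValidationError("lineage entries must be strings ('' for unknown)")
        if self.lineage.shape[0] and (self.lineage == "").all(axis=1).any():
            raise ValidationError("every taxon needs a non-empty rank path")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.counts.shape[1]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AbundanceTable):
            return NotImplemented
        return self.counts.equals(other.counts) and self.lineage.equals(other.lineage)


def write_abundance_table(table: AbundanceTable, path) -> None:
    """Write taxa-as-rows TSV: taxon_id, five lineage columns, one column per sample."""
    out = pd.concat(
        [table.lineage, table.counts.T], axis=1
    )
    out.index.name = "taxon_id"
    out.to_csv(path, sep="\t")


def read_abundance_table(path) -> AbundanceTable:
    """Read and validate a TSV abundance table written by :func:`write_abundance_table`."""
    try:
        raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except Exception as exc:  # pragma: no cover - passthrough context
        raise ValidationError(f"{path}: cannot parse abundance table: {exc}") from exc
    required = ["taxon_id", *RANKS]
    missing = [c for c in required if c not in raw.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    sample_cols = [c for c in raw.columns if c not in required]
    lineage = raw.set_index("taxon_id")[list(RANKS)]
    counts_t = raw.set_index("taxon_id")[sample_cols]
    parsed = {}
    for sample in sample_cols:
        col = counts_t[sample]
        try:
            numeric = pd.to_numeric(col)
        except ValueError as exc:
            bad = col[pd.to_numeric(col, errors="coerce").isna()]
            line = raw.index[raw["taxon_id"] == bad.index[0]][0] + 2
            raise ValidationError(
                f"{path}: non-numeric count at line {line}, sample {sample!r}"
            ) from exc
        if (numeric < 0).any():
            bad_taxon = numeric.index[numeric < 0][0]
            line = raw.index[raw["taxon_id"] == bad_taxon][0] + 2
            raise ValidationError(f"{path}: negative count at line {line}")
        if not np.all(np.equal(np.mod(numeric.to_numpy(dtype=float), 1), 0)):
            raise ValidationError(f"{path}: non-integer count in sample {sample!r}")
        parsed[sample] = numeric.astype(np.int64)
    counts = pd.DataFrame(parsed, index=lineage.index).T
    counts.index.name = None
    counts.columns.name = None
    lineage.index.name = None
    return AbundanceTable(counts=counts, lineage=lineage)


def read_biom_table(path) -> AbundanceTable:
    """Optional adapter: read a BIOM 1.0/2.x table (observations = taxa).

    Lineage is taken from the per-observation ``taxonomy`` metadata (a list of
    up to five rank names, phylum first); missing ranks become placeholders.
    """
    import biom

    bt = biom.load_table(str(path))
    counts = pd.DataFrame(
        bt.matrix_data.toarray().T,
        index=list(bt.ids("sample")),
        columns=list(bt.ids("observation")),
    )
    rows = {}
    for obs in bt.ids("observation"):
        md = bt.metadata(obs, axis="observation")
        taxonomy = list(md.get("taxonomy", [])) if md else []
        taxonomy = [str(t).strip() for t in taxonomy[: len(RANKS)]]
        taxonomy += [""] * (len(RANKS) - len(taxonomy))
        if not any(taxonomy):
            taxonomy[-1] = str(obs)
        rows[obs] = taxonomy
    lineage = pd.DataFrame.from_dict(rows, orient="index", columns=list(RANKS))
    return AbundanceTable(counts=counts, lineage=lineage)


def write_metadata(metadata: pd.DataFrame, path) -> None:
    out = metadata.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t", float_format="%.10g")


def read_metadata(path) -> pd.DataFrame:
    """Read and validate sample metadata (one row per sample, TSV)."""
    raw = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    if "sample_id" not in raw.columns:
        raise ValidationError(f"{path}: missing 'sample_id' column")
    if raw["sample_id"].duplicated().any():
        dup = raw["sample_id"][raw["sample_id"].duplicated()].iloc[0]
        raise ValidationError(f"{path}: duplicated sample id {dup!r}")
    raw = raw.set_index("sample_id")
    raw.index.name = None
    for col in OUTCOMES + ("age", "bmi", "physical_activity", "fecal_ph",
                           "fiber", "protein", "fat", "carbohydrates", "alcohol"):
        if col in raw.columns:
            raw[col] = raw[col].astype(float)
    return validate_metadata(raw)


def validate_metadata(metadata: pd.DataFrame) -> pd.DataFrame:
    """Validate and canonicalise a metadata frame in place-compatible copy."""
    md = metadata.copy()
    if "diet_group" not in md.columns:
        raise ValidationError("metadata lacks 'diet_group'")
    if md["diet_group"].isna().any():
        sample = md.index[md["diet_group"].isna()][0]
        raise ValidationError(f"missing diet_group for sample {sample!r}")
    md["diet_group"] = md["diet_group"].astype(str).str.strip().str.lower()
    unknown = set(md["diet_group"]) - set(DIET_GROUPS)
    if unknown:
        raise ValidationError(f"unknown diet label(s): {sorted(unknown)}")
    if not md.index.is_unique:
        raise ValidationError("duplicated sample ids in metadata")
    for col in ("sex", "smoking_status"):
        if col in md.columns and md[col].dtype == object:
            md[col] = md[col].astype(str).str.strip().str.lower().str.replace("-", "_")
    for col in OUTCOMES:
        if col in md.columns and (pd.to_numeric(md[col]) < 0).any():
            raise ValidationError(f"negative concentration in {col!r}")
    if "fecal_ph" in md.columns:
        ph = pd.to_numeric(md["fecal_ph"])
        if ((ph <= 0) | (ph >= 14)).any():
            raise ValidationError("fecal_ph must lie in (0, 14)")
    return md


def group_masks(metadata: pd.DataFrame, sample_ids) -> dict[str, np.ndarray]:
    groups = metadata.loc[list(sample_ids), "diet_group"]
    return {g: (groups == g).to_numpy() for g in DIET_GROUPS}


def aggregate_to_rank(table: AbundanceTable, rank: str) -> AbundanceTable:
    """Sum counts of taxa sharing the same name at ``rank``.

    Taxa with an empty placeholder at ``rank`` are dropped, so per-sample totals
    are conserved only when every taxon has the rank assigned.
    """
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}; expected one of {RANKS}")
    depth = RANKS.index(rank)
    names = table.lineage[rank]
    keep = names != ""
    counts = table.counts.loc[:, keep.to_numpy()]
    grouped = counts.T.groupby(names[keep], sort=False).sum().T
    lineage_rows = {}
    for name in grouped.columns:
        first = table.lineage.index[(names == name).to_numpy()][0]
        row = table.lineage.loc[first].copy()
        row[list(RANKS[depth + 1:])] = ""
        lineage_rows[name] = row
    lineage = pd.DataFrame(lineage_rows).T.reindex(columns=list(RANKS))
    lineage = lineage.loc[list(grouped.columns)]
    grouped.columns.name = None
    lineage.index.name = None
    return AbundanceTable(counts=grouped, lineage=lineage)


@dataclass
class FilterResult:
    """Outcome of the species-inclusion filter with a per-species report."""

    table: AbundanceTable
    report: pd.DataFrame  # per species: prevalence per group, max reads, kept, reason


def filter_species_for_rfr(
    table: AbundanceTable,
    metadata: pd.DataFrame,
    min_prevalence: float = 0.5,
    min_reads: int = 100,
) -> FilterResult:
    """Keep species present in >=50% of either diet group AND reaching >=100 reads once.

    Both thresholds are inclusive.  Column order is preserved.  An empty
    surviving set raises a warning, not an exception.
    """
    masks = group_masks(metadata, table.sample_ids)
    counts = table.counts.to_numpy()
    prev = {}
    for g, mask in masks.items():
        if mask.sum() == 0:
            prev[g] = np.zeros(table.n_taxa)
        else:
            prev[g] = (counts[mask] > 0).mean(axis=0)
    max_reads = counts.max(axis=0) if counts.size else np.zeros(table.n_taxa)
    prevalent = (prev["vegan"] >= min_prevalence) | (prev["omnivore"] >= min_prevalence)
    abundant = max_reads >= min_reads
    kept = prevalent & abundant
    reasons = np.where(
        kept,
        "kept",
        np.where(
            ~prevalent & ~abundant,
            "below prevalence and abundance thresholds",
            np.where(~prevalent, "below prevalence threshold", "below abundance threshold"),
        ),
    )
    report = pd.DataFrame(
        {
            "prevalence_vegan": prev["vegan"],
            "prevalence_omnivore": prev["omnivore"],
            "max_reads": max_reads,
            "kept": kept,
            "reason": reasons,
        },
        index=table.taxon_ids,
    )
    if kept.sum() == 0:
        warnings.warn("no species survive the inclusion filter", stacklevel=2)
    sub = AbundanceTable(
        counts=table.counts.loc[:, kept],
        lineage=table.lineage.loc[kept],
    )
    return FilterResult(table=sub, report=report)


@dataclass
class SharingSummary:
    """Per-rank shared/unique taxon counts between the two diet groups."""

    table: pd.DataFrame = field(default_factory=pd.DataFrame)
    degenerate: bool = False  # set when a rank had zero named taxa

    def __getitem__(self, rank: str) -> pd.Series:
        return self.table.loc[rank]


def sharing_summary(table: AbundanceTable, metadata: pd.DataFrame) -> SharingSummary:
    """Count taxa shared between and unique to the diet groups at each rank.

    A taxon is "present" in a group when any sample of that group has count > 0;
    unnamed (placeholder) ranks are not counted.  Percentages are rounded
    half-up to 2 decimals.
    """
    masks = group_masks(metadata, table.sample_ids)
    for g in DIET_GROUPS:
        if masks[g].sum() == 0:
            raise ValidationError(f"diet group {g!r} absent from metadata")
    rows = {}
    degenerate = False
    for rank in RANKS:
        agg = aggregate_to_rank(table, rank)
        counts = agg.counts.to_numpy()
        if counts.size == 0:
            degenerate = True
            rows[rank] = dict(total=0, shared=0, vegan_only=0, omnivore_only=0, shared_pct=0.0)
            continue
        present = {g: (counts[masks[g]] > 0).any(axis=0) for g in DIET_GROUPS}
        both = present["vegan"] & present["omnivore"]
        vegan_only = present["vegan"] & ~present["omnivore"]
        omni_only = present["omnivore"] & ~present["vegan"]
        total = int((present["vegan"] | present["omnivore"]).sum())
        if total == 0:
            degenerate = True
            rows[rank] = dict(total=0, shared=0, vegan_only=0, omnivore_only=0, shared_pct=0.0)
        else:
            rows[rank] = dict(
                total=total,
                shared=int(both.sum()),
                vegan_only=int(vegan_only.sum()),
                omnivore_only=int(omni_only.sum()),
                shared_pct=_round_half_up(100.0 * both.sum() / total),
            )
    df = pd.DataFrame(rows).T.reindex(list(RANKS))
    for col in ("total", "shared", "vegan_only", "omnivore_only"):
        df[col] = df[col].astype(int)
    return SharingSummary(table=df, degenerate=degenerate)
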