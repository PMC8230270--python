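import numpy as np
import pandas as pd
import pytest

from scfaforest import cohort, default_config, generate_cohort
from scfaforest.tables import RANKS, AbundanceTable


@pytest.fixture(scope="session")
def small_cohort():
    """Reduced synthetic cohort (12+12 samples, 80 species) for cheap tests."""
    cfg = default_config(seed=11, n_vegan=12, n_omnivore=12, n_species=80, n_core=30)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def small_config():
    return default_config(seed=11, n_vegan=12, n_omnivore=12, n_species=80, n_core=30)


def make_table(counts: np.ndarray, sample_ids=None, taxon_ids=None) -> AbundanceTable:
    """Hand-rolled abundance table with a fully named synthetic lineage."""
    counts = np.asarray(counts)
    n, p = counts.shape
    sample_ids = sample_ids or [f"S{i}" for i in range(n)]
    taxon_ids = taxon_ids or [f"t{j}" for j in range(p)]
    lineage = pd.DataFrame(
        {
            "phylum": [f"ph{j % 2}" for j in range(p)],
            "class": [f"cl{j % 4}" for j in range(p)],
            "family": [f"fa{j % 8}" for j in range(p)],
            "genus": [f"ge{j // 2}" for j in range(p)],
            "species": [f"spx{j}" for j in range(p)],
        },
        index=taxon_ids,
        columns=list(RANKS),
    )
    return AbundanceTable(
        counts=pd.DataFrame(counts, index=sample_ids, columns=taxon_ids),
        lineage=lineage,
    )


def two_group_metadata(n_vegan: int, n_omnivore: int, sample_ids) -> pd.DataFrame:
    groups = ["vegan"] * n_vegan + ["omnivore"] * n_omnivore
    return pd.DataFrame({"diet_group": groups}, index=sample_ids)
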