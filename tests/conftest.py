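import numpy as np
import pandas as pd
import pytest

import namrecomb as nr
from namrecomb import codes


@pytest.fixture(scope="session")
def small_model():
    return nr.uniform_genome(n_chrom=3, length_cm=100.0, n_markers=101)


@pytest.fixture(scope="session")
def small_family(small_model):
    """One noise-free F7 family on the small genome (all markers informative)."""
    panel = nr.divergent_panel(small_model)
    genos, truth_cos, truth = nr.simulate_ssd_family(
        panel, "F01", 120, n_generations=7, model=small_model, seed=11
    )
    return {
        "model": small_model,
        "panel": panel,
        "genos": genos.recode_het_missing(),
        "truth_cos": truth_cos,
        "truth": truth,
        "gmap": small_model.marker_table(),
    }


def toy_genotypes(calls_by_marker: dict[str, str], rils: list[str] | None = None,
                  family: str = "fam") -> nr.RILGenotypes:
    """Build a RILGenotypes from {'m1': 'AABN', ...} call strings."""
    markers = list(calls_by_marker)
    n = len(next(iter(calls_by_marker.values())))
    rils = rils or [f"r{i}" for i in range(n)]
    mat = np.array([codes.encode(np.array(list(calls_by_marker[m]))) for m in markers])
    return nr.RILGenotypes(
        family=family, common_parent="P1", alt_parent="P2",
        markers=markers, rils=rils, calls=mat,
    )


def toy_map(markers: list[str], chrom: str = "c1", spacing: float = 1.0,
            start: float = 0.0) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "marker": markers,
            "chrom": chrom,
            "cm": [start + i * spacing for i in range(len(markers))],
        }
    )
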