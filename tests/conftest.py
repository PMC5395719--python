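import numpy as np
import pandas as pd
import pytest

import tmbkit as tk


@pytest.fixture(scope="session")
def panel():
    return tk.default_cgp_panel()


@pytest.fixture(scope="session")
def locus_panel():
    return tk.default_locus_panel()


@pytest.fixture(scope="session")
def small_cohort():
    """Fully generated 80-specimen cohort shared across read-only tests."""
    cfg = tk.CohortConfig(n_specimens=80, seed=11)
    return tk.generate_cohort(cfg)


@pytest.fixture
def base_variant():
    """A coding missense variant with every exclusion flag off."""
    return {
        "specimen_id": "S1",
        "chrom": "chr1",
        "pos": 100,
        "ref": "C",
        "alt": "T",
        "gene": "TP53",
        "effect": "missense",
        "coding": True,
        "known_somatic_hotspot": False,
        "ts_truncation": False,
        "dbsnp": False,
        "population_count": 0,
        "recurrent_germline": False,
        "zygosity_call": "somatic",
        "allele_fraction": 0.3,
        "homopolymer_len": 0,
    }


def make_variants(n, specimen_id="S1", **overrides):
    """n copies of the clean base variant with column overrides."""
    df = pd.DataFrame(
        {
            "specimen_id": specimen_id,
            "chrom": "chr1",
            "pos": np.arange(1, n + 1),
            "ref": "C",
            "alt": "T",
            "gene": "TP53",
            "effect": "missense",
            "coding": True,
            "known_somatic_hotspot": False,
            "ts_truncation": False,
            "dbsnp": False,
            "population_count": 0,
            "recurrent_germline": False,
            "zygosity_call": "somatic",
            "allele_fraction": 0.3,
            "homopolymer_len": 0,
        }
    )
    for k, v in overrides.items():
        df[k] = v
    return df
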