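import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from resistkit.io import VariantTable

settings.register_profile("default", derandomize=True, deadline=None)
settings.load_profile("default")
from resistkit.simulate import SimConfig, make_panel_sites, sample_sequencing, simulate_parental


def make_variant_table(records, sample_names):
    """records: list of (chrom, pos, ref, alt, {sample: (ad_ref, ad_alt, dp)})."""
    rows = []
    for chrom, pos, ref, alt, per_sample in records:
        row = {"chrom": chrom, "pos": pos, "ref": ref, "alt": alt}
        for s in sample_names:
            ar, aa, dp = per_sample[s]
            row[f"{s}.ad_ref"], row[f"{s}.ad_alt"], row[f"{s}.dp"] = ar, aa, dp
        rows.append(row)
    return VariantTable(pd.DataFrame(rows), list(sample_names))


@pytest.fixture
def small_config():
    return SimConfig(
        seed=7,
        chromosomes=(("chr1", 2_000_000),),
        base_ploidy=2,
        n_het_sites_per_chrom=200,
        n_somatic_snvs=50,
        mean_depth=60.0,
    )


@pytest.fixture
def sequenced_sample(small_config):
    clone = simulate_parental(small_config)
    panel = make_panel_sites(small_config)
    return sample_sequencing(clone, panel, small_config, "s1")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
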