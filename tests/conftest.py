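"""Shared fixtures: the planted WGBS fixture and the pipeline run over it.

Everything is generated at test time from fixed seeds; nothing is read from
disk.  The heavyweight end-to-end products are session-scoped so the
differential-calling, enrichment and selection tests share one run.
"""

import numpy as np
import pandas as pd
import pytest

from demethtf.binned_methylome import aggregate_bins
from demethtf.differential_methylation import call_diff_bins
from demethtf.motif_enrichment import enrich_dataset
from demethtf.synthetic_fixtures import make_default_fixture


@pytest.fixture(scope="session")
def wgbs_fixture():
    return make_default_fixture(seed=17)


@pytest.fixture(scope="session")
def pipeline(wgbs_fixture):
    fx = wgbs_fixture
    ref = aggregate_bins(fx.ref_calls, fx.chrom_sizes, dataset_id="ESC")
    tgt = aggregate_bins(fx.tgt_calls, fx.chrom_sizes, dataset_id="target")
    diff = call_diff_bins(ref, tgt)
    demeth = diff[diff["direction"] == "demethylated"]
    results, curves = enrich_dataset(demeth, fx.genome_index, fx.pwms,
                                     dataset_id="target", return_curves=True)
    return {"ref": ref, "tgt": tgt, "diff": diff, "demeth": demeth,
            "results": results, "curves": curves}


@pytest.fixture()
def rng():
    return np.random.default_rng(20_240_101)
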