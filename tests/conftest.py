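import numpy as np
import pytest

import fragdms as fd
from fragdms import scoring
from fragdms.pipeline import PipelineConfig, demo_config, run_pipeline
from fragdms.reference import ReferenceAmplicon


@pytest.fixture(scope="session")
def ref():
    """The bundled 1341 bp CDS demo amplicon."""
    return fd.demo_reference()


@pytest.fixture(scope="session")
def catalog(ref):
    return scoring.mutation_catalog(ref)


@pytest.fixture(scope="session")
def mini_ref():
    """Tiny hand-built amplicon: 4 bp flanks around the CDS ATG GCT TGG TAA."""
    return ReferenceAmplicon("ACGT" + "ATGGCTTGGTAA" + "ACGT", 4, 16)


@pytest.fixture(scope="session")
def full_run():
    """One full default synthetic experiment (study-scale, fixed seed).

    Shared by the acceptance tests; this is the expensive fixture.
    """
    import time

    t0 = time.time()
    result = run_pipeline(PipelineConfig(seed=1))
    result.summary["runtime_s"] = time.time() - t0
    return result


@pytest.fixture(scope="session")
def demo_run(tmp_path_factory):
    """Minutes-scale demo pipeline run with outputs written to disk."""
    outdir = tmp_path_factory.mktemp("demo_out")
    result = run_pipeline(demo_config(seed=3), outdir)
    return result, outdir
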