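import numpy as np
import pytest

from mothmir import readqc, synthdata


@pytest.fixture(scope="session")
def study():
    """A zero-noise synthetic study shared across tests (fixed seed)."""
    config = synthdata.SynthConfig(rng_seed=20170203)
    genome, truth = synthdata.generate_genome(config)
    rfam = synthdata.generate_rfam_reference(config)
    reads, labels = synthdata.generate_reads(truth, config, genome=genome,
                                             rfam_reference=rfam)
    return {
        "config": config,
        "genome": genome,
        "truth": truth,
        "rfam": rfam,
        "reads": reads,
        "labels": labels,
    }


@pytest.fixture(scope="session")
def qc_result(study):
    raw = [seq for _, seq in study["reads"]]
    uniques, summary, dispositions = readqc.run_readqc(
        raw, study["config"].adapter, rfam_reference=study["rfam"])
    return {"uniques": uniques, "summary": summary,
            "dispositions": dispositions}


@pytest.fixture()
def rng():
    return np.random.default_rng(97531)
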