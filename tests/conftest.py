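import pytest
from hypothesis import settings

from slseeker.simulate import (
    scenario,
    build_genome,
    transcribe,
    sample_reads,
    gene_proteins,
)
from slseeker.records import SequenceRecord

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


class Dataset:
    def __init__(self, cfg):
        self.cfg = cfg
        self.contigs, self.truth = build_genome(cfg)
        self.transcripts = transcribe(cfg, self.truth, self.contigs)
        self.reads = sample_reads(self.transcripts, cfg, self.truth)
        self.proteins = gene_proteins(self.truth, self.contigs)
        self.contaminant_refs = [
            SequenceRecord("contaminant_1", self.truth.aux_refs["contaminant"]),
            SequenceRecord("rrna_1", self.truth.aux_refs["rrna"]),
        ]

    @property
    def contig_by_id(self):
        return {c.id: c.seq for c in self.contigs}


@pytest.fixture(scope="session")
def tiny():
    return Dataset(scenario("tiny", seed=1))


@pytest.fixture(scope="session")
def default():
    return Dataset(scenario("default", seed=7))


@pytest.fixture(scope="session")
def default_noiseless():
    return Dataset(scenario("default", seed=7, read_error_rate=0.0))
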