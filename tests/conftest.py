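"""Shared fixtures: a synthetic TE library and a small error-free
diploid simulation (30x per haplotype) reused across modules."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pytest

import longte.simulate as sim
from longte.pipeline import PipelineConfig, run_pipeline
from longte.seqs import write_fasta


@pytest.fixture(scope="session")
def te_library():
    return sim.synthetic_te_library()


@dataclass
class SimFixture:
    config: sim.SimConfig
    reference: str
    haplotypes: list[str]
    truths: list[sim.TruthRecord]
    reference_fa: Path
    library_fa: Path
    reads_fq: Path
    outdir: Path


def build_sim(tmpdir: Path, te_library, **overrides) -> SimFixture:
    params = dict(
        reference_length=150_000,
        ploidy=2,
        n_insertions=4,
        depth_total=60.0,  # 30x per haplotype
        read_length_mean=7_000.0,
        read_length_sd=2_000.0,
        error_rate=0.0,
        seed=5,
    )
    params.update(overrides)
    config = sim.SimConfig(**params)
    reference = sim.make_reference(config.reference_length, config.seed)
    haplotypes, truths = sim.plant_insertions(reference, te_library, config)
    tmpdir.mkdir(parents=True, exist_ok=True)
    reference_fa = write_fasta(tmpdir / "reference.fa",
                               [(sim.REFERENCE_NAME, reference)])
    library_fa = te_library.to_fasta(tmpdir / "te_library.fa")
    reads_fq = sim.simulate_reads(haplotypes, config, tmpdir / "reads.fq")
    return SimFixture(config, reference, haplotypes, truths,
                      reference_fa, library_fa, reads_fq, tmpdir)


@pytest.fixture(scope="session")
def clean_sim(tmp_path_factory, te_library) -> SimFixture:
    """Error-free diploid simulation, 30x per haplotype."""
    return build_sim(tmp_path_factory.mktemp("clean_sim"), te_library)


@pytest.fixture(scope="session")
def clean_run(clean_sim):
    """Full pipeline result on the error-free simulation."""
    return run_pipeline(
        PipelineConfig(
            reads=clean_sim.reads_fq,
            reference=clean_sim.reference_fa,
            te_library=clean_sim.library_fa,
            outdir=clean_sim.outdir / "run",
            default_ploidy=clean_sim.config.ploidy,
        )
    )
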