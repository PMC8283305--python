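import pytest

from glycodag.pipeline import PipelineConfig, run_pipeline
from glycodag.proteome_model import ProteinRecord
from glycodag.synthetic_data import SimConfig, simulate_study


@pytest.fixture
def toy_proteins() -> list[ProteinRecord]:
    # P1 carries a canonical sequon split across a tryptic boundary
    # (...N K | V S...) and an internal canonical NVT; P2 shares the AAGNVTK
    # peptide with P1 so that peptide maps non-uniquely.
    return [
        ProteinRecord("P1", "MAAGNVTKVSLLNKTRAAGWDDK"),
        ProteinRecord("P2", "GGAAGNVTKPPPWWR"),
        ProteinRecord("P3", "MNPSAAAKLLLNATR"),
    ]


@pytest.fixture(scope="session")
def small_bundle(tmp_path_factory):
    """A written-to-disk synthetic study small enough for fast pipeline runs."""
    outdir = tmp_path_factory.mktemp("bundle")
    cfg = SimConfig(seed=11, n_proteins=40)
    proteins, evidence, truth = simulate_study(cfg, outdir)
    return dict(
        cfg=cfg, proteins=proteins, evidence=evidence, truth=truth, dir=outdir
    )


@pytest.fixture(scope="session")
def small_result(small_bundle):
    d = small_bundle["dir"]
    cfg = PipelineConfig(
        fasta=str(d / "proteome.fasta"),
        evidence=str(d / "evidence.tsv"),
        outdir=str(d / "out"),
    )
    return run_pipeline(cfg)
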