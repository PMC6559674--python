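import numpy as np
import pytest

from riboflux.model import STOP_CODONS, TranscriptModel


def make_model(
    n_codons: int = 101,
    omega: float | np.ndarray = 5.0,
    alpha: float = 0.1,
    beta: float = 35.0,
    ell: int = 10,
    gene_id: str = "toy",
) -> TranscriptModel:
    codons = ("ATG",) + ("GCT",) * (n_codons - 2) + ("TAA",)
    om = np.full(n_codons - 1, omega, dtype=float) if np.isscalar(omega) else omega
    return TranscriptModel(
        gene_id, codons, alpha=alpha, omega=om, beta=beta, ell=ell,
        a_site_offset=min(5, ell - 1),
    )


@pytest.fixture
def toy_model() -> TranscriptModel:
    return make_model()


@pytest.fixture(scope="session")
def small_transcriptome():
    from riboflux.synth import SyntheticSpec, generate_transcriptome

    return generate_transcriptome(SyntheticSpec(n_transcripts=8, seed=42))
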