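import numpy as np
import pytest

from estsurvey import simulate as sim
from estsurvey import trim as trm


def random_errors(rng: np.random.Generator, n: int) -> list[float]:
    """Error profiles with blocky high/low-quality structure, as Sanger
    traces show: good middle, noisy ends, occasional bad bases."""
    errors = np.empty(n)
    i = 0
    while i < n:
        block = int(rng.integers(1, 12))
        level = rng.choice([1e-5, 5e-4, 2e-3, 0.05, 0.4], p=[0.3, 0.25, 0.2, 0.15, 0.1])
        errors[i : i + block] = level * rng.uniform(0.5, 1.5, min(block, n - i))
        i += block
    return [float(min(e, 1.0)) for e in errors]


def random_quals(rng: np.random.Generator, n: int) -> np.ndarray:
    q = np.concatenate([
        np.full(int(rng.integers(1, n + 1)), v)
        for v in rng.integers(2, 55, size=8)
    ])[:n]
    if q.size < n:
        q = np.concatenate([q, rng.integers(2, 55, size=n - q.size)])
    return q.astype(np.int64)


@pytest.fixture(scope="session")
def survey():
    """A moderate synthetic survey with known truth, shared across tests.

    Normalized transcriptome (40-fold reduction of the dominant gene),
    3,000 reads; returns the model, raw reads, truth table and trimmed
    reads.
    """
    model = sim.build_transcriptome(n_genes=2000, seed=11)
    top = int(model.abundances.argmax())
    params = sim.calibrate_theta(model.abundances, top, 40.0)
    model.abundances = sim.dsn_normalize(model.abundances, params)
    reads, truth = sim.simulate_reads(model, sim.ReadModel(), n_reads=3000, seed=11)
    trimmed = [trm.trim_read(r) for r in reads]
    return {"model": model, "reads": reads, "truth": truth, "trimmed": trimmed,
            "theta": params.theta, "top_gene": top}
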