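import numpy as np
import pytest

from pcskit import synthetic


@pytest.fixture(scope="session")
def small_dataset():
    """15 scaffolds (5 per subtype) with ground truth."""
    return synthetic.generate_dataset(5, seed=11)


@pytest.fixture(scope="session")
def random_scaffolds():
    """200 scaffolds spanning the full Cys-His spacing range, with truth."""
    rng = np.random.default_rng(7)
    out = []
    for i in range(200):
        spec = synthetic.ScaffoldSpec(
            subtype="NED"[i % 3],
            nterm_len=int(rng.integers(20, 70)),
            ch_spacing=int(rng.integers(94, 156)),
            include_thr7=bool(rng.integers(0, 2)),
            include_cc=bool(rng.integers(0, 2)),
            include_cxxxc=bool(rng.integers(0, 2)),
            cterm_len=int(rng.integers(0, 120)),
            cterm_cys_frac=float(rng.uniform(0, 0.3)),
            seed=int(rng.integers(0, 2**31)),
        )
        out.append(synthetic.generate_pcs_sequence(spec, seq_id=f"scaf_{i:03d}"))
    return out
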