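import numpy as np
import pytest

from shssd.config import default_config
from shssd.model import SHSSD


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_model():
    """Width-reduced SH-SSD for fast structural tests (same topology)."""
    return SHSSD(default_config(width_mult=0.25, image_size=320), seed=0)


def gradcheck(module, x, eps=1e-3, tol=2e-2, n_probes=5, seed=0):
    """Finite-difference check of a module's input/parameter gradients."""
    probe_rng = np.random.default_rng(seed)
    y = module.forward(x)
    dy = probe_rng.normal(size=y.shape).astype(np.float32)
    module.zero_grad()
    dx = module.backward(dy.copy())
    for _ in range(n_probes):
        idx = tuple(int(probe_rng.integers(0, s)) for s in x.shape)
        xp = x.copy(); xp[idx] += eps
        xm = x.copy(); xm[idx] -= eps
        num = (float((module.forward(xp) * dy).sum())
               - float((module.forward(xm) * dy).sum())) / (2 * eps)
        assert abs(num - dx[idx]) < tol * max(1.0, abs(num)), \
            f"input grad mismatch at {idx}: fd={num}, analytic={dx[idx]}"
    for name, p in module.named_parameters():
        flat = p.data.reshape(-1)
        gflat = p.grad.reshape(-1)
        for i in probe_rng.choice(flat.size, size=min(3, flat.size), replace=False):
            orig = flat[i]
            flat[i] = orig + eps
            lp = float((module.forward(x) * dy).sum())
            flat[i] = orig - eps
            lm = float((module.forward(x) * dy).sum())
            flat[i] = orig
            num = (lp - lm) / (2 * eps)
            assert abs(num - gflat[i]) < tol * max(1.0, abs(num)), \
                f"param grad mismatch {name}[{i}]: fd={num}, analytic={gflat[i]}"
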