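import numpy as np
import pytest

from pscloop import TraceGenConfig, WLCParams, baseline_stats, gen_mt_trace


@pytest.fixture(scope="session")
def wlc() -> WLCParams:
    return WLCParams()


@pytest.fixture(scope="session")
def baseline() -> tuple[float, float]:
    """Baseline (mean, SD) from a protein-free synthetic tether record."""
    trace, _ = gen_mt_trace(TraceGenConfig(event_count=0, seed=424242))
    return baseline_stats(trace)


def lfr_rejection_oracle(mu, sigma, fold, n, seed):
    """Brute-force loop-formation-rate reference: draw velocity pairs,
    discard any pair with a negative velocity, take |v1 - v2|.

    Independent of the implementation's draw order (pairwise rejection
    rather than per-channel redraw); used to cross-check the sampler.
    """
    rng = np.random.default_rng(seed)
    out = np.empty(n)
    filled = 0
    while filled < n:
        v1 = rng.normal(mu, sigma, n) if sigma else np.full(n, mu)
        v2 = rng.normal(fold * mu, sigma, n) if sigma else np.full(n, fold * mu)
        ok = (v1 >= 0) & (v2 >= 0)
        take = min(int(ok.sum()), n - filled)
        out[filled:filled + take] = np.abs(v1[ok] - v2[ok])[:take]
        filled += take
    return out


@pytest.fixture(scope="session")
def rejection_oracle():
    return lfr_rejection_oracle
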