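import numpy as np
import pytest

from hepatex.phantom import PhantomParams, generate_phantom


# ---------------------------------------------------------------------------
# independent brute-force oracles (kept deliberately naive)


def brute_force_otsu(values):
    """Exhaustive argmax of between-class variance over cut points 0..62."""
    values = np.asarray(values, dtype=float)
    best_k, best_sigma = None, -1.0
    for k in range(63):
        lo = values[values <= k]
        hi = values[values > k]
        if lo.size == 0 or hi.size == 0:
            continue
        w0 = lo.size / values.size
        w1 = hi.size / values.size
        sigma = w0 * w1 * (lo.mean() - hi.mean()) ** 2
        if sigma > best_sigma + 1e-12:
            best_sigma, best_k = sigma, k
    return best_k


def pair_counting_auc(scores_normal, scores_abnormal):
    """Mann-Whitney AUC by exhaustive pair enumeration (abnormal scores lower)."""
    total = 0.0
    for a in scores_abnormal:
        for n in scores_normal:
            if a < n:
                total += 1.0
            elif a == n:
                total += 0.5
    return total / (len(scores_abnormal) * len(scores_normal))


# ---------------------------------------------------------------------------
# fixtures


@pytest.fixture(scope="session")
def default_params():
    return PhantomParams(seed=0)


@pytest.fixture(scope="session")
def phantom_pair(default_params):
    """One abnormal and one normal phantom at the default study conditions."""
    return (
        generate_phantom(default_params, "abnormal", seed=11),
        generate_phantom(default_params, "normal", seed=12),
    )
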