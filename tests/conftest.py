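import dataclasses

import numpy as np
import pytest

import equiwtp as ew


@pytest.fixture
def rng():
    return np.random.default_rng(20200701)


@pytest.fixture
def preset():
    return ew.preset_table1_like(seed=11)


def make_intercept_data(n, mu, sigma, seed):
    """Intercept-only interval data simulated from the latent-normal model."""
    r = np.random.default_rng(seed)
    w = mu + sigma * r.standard_normal(n)
    lower = np.empty(n)
    upper = np.empty(n)
    for i in range(n):
        sched = ew.draw_schedule(r)
        r1, r2 = ew.simulate_responses(w[i], sched)
        iv = ew.map_to_interval(r1, r2, sched.c2y_frac if r1 == "yes" else sched.c2n_frac)
        lower[i], upper[i] = iv.lower, iv.upper
    return ew.EstimationDataset(lower=lower, upper=upper,
                                X=np.ones((n, 1)), names=["const"])


def grid_loglik_argmax(data, b_grid, s_grid):
    """Independent brute-force oracle for the intercept-only objective.

    Plain normal-CDF evaluation (orientation-stable) on a (beta0, ln
    sigma) grid; returns the grid argmax.
    """
    from scipy import stats

    best, best_ll = None, -np.inf
    lower = data.lower[None, :]
    upper = data.upper[None, :]
    b = np.asarray(b_grid)[:, None]
    for ls in s_grid:
        s = np.exp(ls)
        zl = (lower - b) / s
        zu = (upper - b) / s
        p = np.where(zl + zu > 0,
                     stats.norm.sf(zl) - stats.norm.sf(zu),
                     stats.norm.cdf(zu) - stats.norm.cdf(zl))
        with np.errstate(divide="ignore"):
            ll = np.where(p > 0, np.log(np.maximum(p, 1e-300)), -np.inf).sum(axis=1)
        j = int(np.argmax(ll))
        if ll[j] > best_ll:
            best, best_ll = (float(b_grid[j]), float(ls)), float(ll[j])
    return best


@pytest.fixture
def owner_records(preset):
    """A small simulated owner population as RespondentRecord objects."""
    cfg = dataclasses.replace(preset.groups["owner"], n=400)
    from equiwtp.simulate import _draw_group, _records_from_draws

    d = _draw_group(cfg, np.random.default_rng(5))
    return _records_from_draws(cfg, d)
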