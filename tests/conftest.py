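import numpy as np
import pytest

from nrfkit.model_selection import (default_nrf_lambda, make_splits)
from nrfkit.nrf_model import NRFHyper, train
from nrfkit.responses import rescale_targets
from nrfkit.synthetic_data import make_dataset

#: hidden-unit count and optimizer budget for desk-scale fits
DESK_J = 10
DESK_MAX_ITER = 20


def desk_hyper(seed, lam=0.0, **kw):
    return NRFHyper(J=DESK_J, lam=lam, seed=seed, max_iter=DESK_MAX_ITER, **kw)


def fit_nrf_default(data, seed, k=3):
    """Train an NRF on the cross-validation portion at the default penalty.

    Returns (params, splits, lam, signal pieces needed by recovery checks).
    """
    splits = make_splits(data.clip_ids, [len(y) for y in data.y], k=k,
                         seed=seed)
    Xcv = np.concatenate([data.X[c][splits.cv_slice(c)]
                          for c in range(data.n_clips)])
    ycv = np.concatenate([data.y[c][splits.cv_slice(c)]
                          for c in range(data.n_clips)])
    lam = default_nrf_lambda(Xcv, rescale_targets(ycv))
    params = train(Xcv, rescale_targets(ycv), desk_hyper(seed, lam))
    return params, splits, lam


@pytest.fixture(scope="session")
def bifeature():
    """Desk-scale two-feature synthetic neuron (ground truth, data, raw)."""
    return make_dataset("bifeature", seed=0)


@pytest.fixture(scope="session")
def bifeature_fit(bifeature):
    """A fitted NRF for the desk-scale bi-feature neuron."""
    gt, data, sds = bifeature
    params, splits, lam = fit_nrf_default(data, seed=0)
    return {"gt": gt, "data": data, "sds": sds, "params": params,
            "splits": splits, "lam": lam}


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
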