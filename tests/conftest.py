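"""Shared fixtures: small synthetic datasets and a session-scoped
trained classifier reused across classifier/decomposition tests."""

from __future__ import annotations

import numpy as np
import pytest

from deepstroma import (TextureParams, TissueClassifier, generate_patch_set,
                        split_dataset)


@pytest.fixture(scope="session")
def texture_params() -> TextureParams:
    return TextureParams(seed=1)


@pytest.fixture(scope="session")
def patch_bank(texture_params):
    """Balanced labeled patch set: 40 patches per class."""
    return generate_patch_set(40, texture_params)


@pytest.fixture(scope="session")
def patch_split(patch_bank):
    _, y = patch_bank
    return split_dataset(y, seed=0)


@pytest.fixture(scope="session")
def trained_classifier(patch_bank, patch_split):
    X, y = patch_bank
    tr, va, _ = patch_split
    clf = TissueClassifier(epochs=30, seed=0)
    clf.fit(X[tr], y[tr], X_val=X[va], y_val=y[va])
    return clf


def brute_force_youden(values, labels) -> float:
    """Independent exhaustive maximizer of sensitivity + specificity - 1.

    Evaluates every midpoint candidate by direct counting; ties go to the
    candidate closest to the median of the values, then to the smaller
    cutoff.  Used as the oracle for the fast implementation.
    """
    v = np.asarray(values, float)
    y = np.asarray(labels, int)
    uniq = sorted(set(v.tolist()))
    candidates = [(a + b) / 2 for a, b in zip(uniq[:-1], uniq[1:])]
    med = float(np.median(v))
    best = None
    for tau in candidates:
        tp = sum(1 for vi, yi in zip(v, y) if vi > tau and yi == 1)
        fn = sum(1 for vi, yi in zip(v, y) if vi <= tau and yi == 1)
        tn = sum(1 for vi, yi in zip(v, y) if vi <= tau and yi == 0)
        fp = sum(1 for vi, yi in zip(v, y) if vi > tau and yi == 0)
        j = tp / (tp + fn) + tn / (tn + fp) - 1
        key = (-round(j, 12), round(abs(tau - med), 12), tau)
        if best is None or key < best[0]:
            best = (key, tau)
    return best[1]


@pytest.fixture(scope="session")
def youden_oracle():
    return brute_force_youden
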