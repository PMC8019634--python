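import numpy as np
import pytest
from scipy.stats import spearmanr

from dlgrlmf import (
    HyperParams,
    SyntheticConfig,
    evaluate_fold,
    fit,
    generate,
    predict_scores,
    random_cell_mask,
)

RECOVERY_SEEDS = range(5)
HOLDOUT_FRACTION = 0.10


@pytest.fixture(scope="session")
def small_bundle():
    """A quick-to-fit synthetic dataset for smoke-level tests."""
    return generate(SyntheticConfig(d=24, t=18, k_true=3, seed=7)).bundle


@pytest.fixture(scope="session")
def recovery_runs():
    """Parameter-recovery study: fit on 90% of cells, score the held-out 10%.

    Five independent synthetic datasets (planted k=5 factors, positive rate
    0.1) are fitted at the planted dimension with the model defaults; the
    same splits are rerun with label-shuffled interactions and identity
    similarities as a no-signal null. Chance-level AUPR for the null is the
    permutation expectation (average precision is upward-biased at this
    sample size, so the raw positive rate understates chance).
    """
    auprs, spears, nulls, null_rates = [], [], [], []
    chance_samples = []
    for seed in RECOVERY_SEEDS:
        truth = generate(SyntheticConfig(seed=seed))
        b = truth.bundle
        A = b.interactions.values
        d, t = A.shape
        held = random_cell_mask(d, t, HOLDOUT_FRACTION, seed=1000 + seed)
        train_w = (~held).astype(float)
        hp = HyperParams(k=5, n_weight=5, K=5, alpha=0.1, beta=0.1, seed=seed)
        res = fit(A, b.drug_sim, b.target_sim, hp, weight_mask=train_w)
        probs = predict_scores(res.factors).probs
        auprs.append(evaluate_fold(probs[held], A[held]).aupr)
        spears.append(float(spearmanr(probs[held], truth.true_probs[held]).statistic))

        rng = np.random.default_rng(5000 + seed)
        A_shuf = rng.permutation(A.ravel()).reshape(A.shape)
        res_null = fit(A_shuf, np.eye(d), np.eye(t), hp, weight_mask=train_w)
        probs_null = predict_scores(res_null.factors).probs
        nulls.append(evaluate_fold(probs_null[held], A_shuf[held]).aupr)
        null_rates.append(float(A_shuf[held].mean()))
        for rep in range(40):  # permutation chance level for this fold's truth
            perm = rng.permutation(A_shuf[held])
            chance_samples.append(evaluate_fold(rng.random(perm.size), perm).aupr)
    return {
        "auprs": auprs,
        "spearmans": spears,
        "null_auprs": nulls,
        "null_pos_rates": null_rates,
        "positive_rate": 0.1,
        "chance_aupr": float(np.mean(chance_samples)),
    }
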