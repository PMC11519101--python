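import warnings

import numpy as np
import pytest

from recoverml.config import GeneratorConfig
from recoverml.features import build_feature_table
from recoverml.preprocess import (
    apply_inclusion_rules,
    impute_features,
    impute_missing,
    markov_unfold,
    prune_correlated,
    select_variable_set,
)
from recoverml.synthetic import generate_cohort

warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def small_cohort():
    """8 athletes x 56 days, default effect sizes: shared across tests."""
    cfg = GeneratorConfig(n_participants=8, n_days=56, seed=42)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def small_features(small_cohort):
    sessions, daily, _ = small_cohort
    sessions, daily, _ = apply_inclusion_rules(sessions, daily)
    daily = impute_missing(daily)
    table, manifest = build_feature_table(sessions, daily)
    table, outcome_missing = impute_features(table, manifest)
    return table, manifest, outcome_missing


@pytest.fixture(scope="session")
def small_main_prs(small_features):
    """Pruned MAIN design matrix for the AM PRS outcome."""
    table, manifest, om = small_features
    ds = markov_unfold(table, manifest, "am_prs", 7, outcome_missing=om)
    ds = select_variable_set(ds, "MAIN")
    ds.X, _ = prune_correlated(ds.X)
    return ds


def naive_rolling_load(tl: np.ndarray, window: int = 7):
    """Independent brute-force recomputation of the 7-day load metrics."""
    n = len(tl)
    out = {k: np.full(n, np.nan) for k in ("monotony7", "strain7", "ma7_tl", "max_tl7")}
    for t in range(n):
        if t >= window - 1:
            w = tl[t - window + 1 : t + 1]
            mean = sum(w) / window
            var = sum((x - mean) ** 2 for x in w) / (window - 1)
            sd = var**0.5
            out["ma7_tl"][t] = mean
            out["max_tl7"][t] = max(w)
            if sd > 0:
                out["monotony7"][t] = mean / sd
                out["strain7"][t] = sum(w) * (mean / sd)
    ewma = np.empty(n)
    alpha = 2.0 / (window + 1)
    for t in range(n):
        ewma[t] = tl[t] if t == 0 else alpha * tl[t] + (1 - alpha) * ewma[t - 1]
    out["ewma_tl"] = ewma
    return out
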