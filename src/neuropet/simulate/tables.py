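"""Tabular simulators: lesion feature tables with sparse discriminative
structure, exponential survival records, and lognormal metabolite matrices
with class-dependent acyl-carnitine elevation."""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["simulate_feature_table", "simulate_survival", "simulate_metabolomics"]


def simulate_feature_table(
    n_lesions: int = 200,
    n_features: int = 20,
    support: int = 3,
    effect_size: float = 5.0,
    class_balance: float = 0.5,
    seed: int = 0,
):
    """Two-class lesion table: standard-normal features with a mean shift of
    ``effect_size`` on the first ``support`` features for class 1.

    Returns ``(table, labels, true_weights)``; only the support carries
    signal, so a selector recovering it (and little else) behaves correctly.
    """
    if support > n_features:
        raise ValueError("support cannot exceed n_features")
    rng = np.random.default_rng(seed)
    y = (rng.random(n_lesions) < class_balance).astype(int)
    x = rng.standard_normal((n_lesions, n_features))
    x[:, :support] += effect_size * y[:, None]
    true_w = np.zeros(n_features)
    true_w[:support] = effect_size
    cols = [f"feat_{i:02d}" for i in range(n_features)]
    return pd.DataFrame(x, columns=cols), y, true_w


def simulate_survival(
    n: int,
    rate_per_month: float,
    censoring_rate: float = 0.0,
    seed: int = 0,
    group: str = "",
) -> pd.DataFrame:
    """Exponential survival times (true median = ln2 / rate) with independent
    exponential censoring; ``censoring_rate = 1`` censors every record."""
    if rate_per_month <= 0:
        raise ValueError("rate must be positive")
    if not 0 <= censoring_rate <= 1:
        raise ValueError("censoring_rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    t_event = rng.exponential(1.0 / rate_per_month, n)
    if censoring_rate >= 1.0:
        time, event = t_event, np.zeros(n, dtype=bool)
    elif censoring_rate <= 0.0:
        time, event = t_event, np.ones(n, dtype=bool)
    else:
        # censoring hazard chosen so that P(censored) = censoring_rate
        c_rate = rate_per_month * censoring_rate / (1.0 - censoring_rate)
        t_cens = rng.exponential(1.0 / c_rate, n)
        time = np.minimum(t_event, t_cens)
        event = t_event <= t_cens
    return pd.DataFrame(
        {"time_months": time, "event": event, "group": group or "all"}
    )


def simulate_metabolomics(
    n_per_group: dict | None = None,
    n_metabolites: int = 200,
    n_carnitine: int = 20,
    fold_change: float = 6.0,
    sigma_log: float = 0.5,
    seed: int = 0,
):
    """Lognormal metabolite abundances for LGG / HGG / METS groups.

    The first ``n_carnitine`` metabolites form the acyl-carnitine block,
    elevated by ``fold_change`` in the two higher-grade groups (HGG and
    METS); the rest are exchangeable across groups.  Returns
    ``(matrix, groups, truth)`` with ``matrix`` metabolites x samples.
    """
    n_per_group = n_per_group or {"LGG": 8, "HGG": 25, "METS": 12}
    for g, n in n_per_group.items():
        if n < 2:
            raise ValueError(f"group {g} needs >= 2 samples for a variance")
    if n_carnitine > n_metabolites:
        raise ValueError("carnitine block larger than panel")
    rng = np.random.default_rng(seed)
    groups, cols = [], []
    for g, n in n_per_group.items():
        groups += [g] * n
        cols += [f"{g}_{i:02d}" for i in range(n)]
    groups = np.array(groups)
    base_log = rng.normal(0.0, 1.0, n_metabolites)  # per-metabolite baseline
    log_abund = (base_log[:, None]
                 + rng.normal(0.0, sigma_log, (n_metabolites, groups.size)))
    elevated = np.isin(groups, ["HGG", "METS"])
    log_abund[:n_carnitine, :][:, elevated] += np.log(fold_change)
    names = [f"carnitine_{i:02d}" if i < n_carnitine else f"metab_{i:03d}"
             for i in range(n_metabolites)]
    matrix = pd.DataFrame(np.exp(log_abund), index=names, columns=cols)
    truth = {"carnitine_block": names[:n_carnitine], "fold_change": fold_change}
    return matrix, groups, truth
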