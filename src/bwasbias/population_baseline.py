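"""Ground-truth comparators: fresh null samples and closed-form expectations.

Resampling a large sample treats it as a population. The honest comparator
is to actually sample from the population: generate a brand-new null sample
for every replication attempt ("sampling from an infinite-size population")
and evaluate the same estimators against the same fixed full-sample table.
Under the null the fresh-sample expectations have closed forms — power and
false positive rate equal alpha, the false negative rate equals 1 - alpha,
sign errors sit at 50% — so the fresh-sample sweep doubles as a calibration
check and the contrast with the resampling sweep isolates the bias.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .error_estimation import (
    ESTIMATORS,
    ResamplingConfig,
    _child_rng,
    _mean_record,
    _sign_mismatch,
    estimate_false_negative_rate,
    estimate_false_positive_rate,
    estimate_inflation_rate,
    estimate_power,
    estimate_sign_error_rate,
    prob_replication_from_tables,
)
from .synthetic_data import (
    EffectTable,
    compute_brain_behaviour_effects,
    generate_subject_null_sample,
)

__all__ = ["analytic_null_expectations", "run_fresh_sample_sweep"]


def run_fresh_sample_sweep(
    full: EffectTable,
    config: ResamplingConfig,
    n_nodes: int = 50,
    ts_length: int = 100,
) -> pd.DataFrame:
    """Evaluate every estimator against freshly generated null samples.

    For each ``(size, iteration)`` cell a brand-new null sample of that size
    is generated (never resampled) with the same node count and time-series
    length as the reference sample, its brain–behaviour correlations are
    computed at ``n = size``, and all estimators are evaluated against the
    fixed full-sample table ``full``. The probability-of-replication
    comparator uses two independent fresh samples per cell. Records are
    iteration averages in the same schema as the resampling sweep, plus a
    ``source`` column set to ``fresh_sample``.
    """
    records = []
    for size in config.sizes:
        per_alpha = {
            alpha: {est: [] for est in ESTIMATORS} for alpha in config.alphas
        }
        per_inflation = {
            (alpha, m): [] for alpha in config.alphas for m in config.inflation_magnitudes
        }
        eligible = {key: [] for key in list(per_alpha) + list(per_inflation)}
        for it in range(config.n_iterations):
            fresh = generate_subject_null_sample(
                size, n_nodes, ts_length,
                seed=_child_rng(config.seed, size, it, 2).integers(0, 2**31),
            )
            rep = compute_brain_behaviour_effects(fresh)
            rep.label = "fresh_sample"
            fresh_out = generate_subject_null_sample(
                size, n_nodes, ts_length,
                seed=_child_rng(config.seed, size, it, 3).integers(0, 2**31),
            )
            out_table = compute_brain_behaviour_effects(fresh_out)
            out_table.label = "out_of_sample"
            for alpha in config.alphas:
                sig = full.p < alpha
                per_alpha[alpha]["false_negative_rate"].append(
                    estimate_false_negative_rate(full, rep, alpha)
                )
                per_alpha[alpha]["power"].append(estimate_power(full, rep, alpha))
                per_alpha[alpha]["sign_error_rate"].append(
                    estimate_sign_error_rate(full, rep, alpha)
                )
                per_alpha[alpha]["false_positive_rate"].append(
                    estimate_false_positive_rate(full, rep, alpha)
                )
                per_alpha[alpha]["prob_replication"].append(
                    prob_replication_from_tables(
                        rep, out_table, alpha, config.prob_replication_require_sign
                    )
                )
                eligible[alpha].append(int(sig.sum()))
                replicated = (
                    (full.p < alpha) & (rep.p < alpha) & ~_sign_mismatch(full.r, rep.r)
                )
                for m in config.inflation_magnitudes:
                    per_inflation[(alpha, m)].append(
                        estimate_inflation_rate(full, rep, alpha, m)
                    )
                    eligible[(alpha, m)].append(int(replicated.sum()))
        for alpha in config.alphas:
            for est in ESTIMATORS:
                if est == "inflation_rate":
                    continue
                values = np.asarray(per_alpha[alpha][est], dtype=float)
                records.append(
                    _mean_record(est, size, alpha, None, values,
                                 np.asarray(eligible[alpha], dtype=float))
                )
            for m in config.inflation_magnitudes:
                values = np.asarray(per_inflation[(alpha, m)], dtype=float)
                records.append(
                    _mean_record("inflation_rate", size, alpha, m, values,
                                 np.asarray(eligible[(alpha, m)], dtype=float))
                )
    frame = pd.DataFrame.from_records(records)
    frame["source"] = "fresh_sample"
    return frame


def analytic_null_expectations(
    alpha: float,
    require_sign: bool = True,
    magnitudes=(0.0,),
) -> pd.DataFrame:
    """Closed-form fresh-sample expectations under the null.

    For replication samples genuinely drawn from the null population, each
    effect is significant with probability exactly alpha, independently of
    the full sample, so: false negative rate ``1 - alpha``, power ``alpha``,
    false positive rate ``alpha``, sign error rate ``0.5``. Probability of
    replication is ``alpha / 2`` when replication requires sign agreement
    (the default convention) and ``alpha`` otherwise. Inflation at relative
    magnitude 0 averages to 0.5 by symmetry of the replicated pair; nonzero
    magnitudes have no closed form and are reported as missing.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    rows = [
        {"estimator": "false_negative_rate", "alpha": alpha,
         "magnitude": float("nan"), "value": 1.0 - alpha},
        {"estimator": "power", "alpha": alpha,
         "magnitude": float("nan"), "value": alpha},
        {"estimator": "sign_error_rate", "alpha": alpha,
         "magnitude": float("nan"), "value": 0.5},
        {"estimator": "prob_replication", "alpha": alpha,
         "magnitude": float("nan"),
         "value": alpha / 2.0 if require_sign else alpha},
        {"estimator": "false_positive_rate", "alpha": alpha,
         "magnitude": float("nan"), "value": alpha},
    ]
    for m in magnitudes:
        rows.append(
            {"estimator": "inflation_rate", "alpha": alpha, "magnitude": float(m),
             "value": 0.5 if m == 0.0 else float("nan")}
        )
    frame = pd.DataFrame.from_records(rows)
    frame["source"] = "analytic"
    return frame
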