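"""Resampling-with-replacement engine and the six statistical-error estimators.

The estimators reproduce the data-driven replicability machinery used in
large-scale brain-wide association studies: a single "large sample" is
treated as the population, replication samples are drawn from it by
resampling subjects with replacement, and error rates are estimated by
comparing significance calls between the full-sample effect table and each
replication table.

Estimator conventions (each is documented on its function):

* power / false-negative rate condition on the full-sample significant set
  and do **not** require sign consistency; sign errors are a separate
  estimator.
* the false-positive-rate denominator is the set of effects *not*
  significant in the full sample, which makes its fresh-sample expectation
  exactly alpha.
* an exactly-zero correlation counts as a sign mismatch against any sign.
* an empty denominator yields ``nan`` (a missing value), never zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .synthetic_data import EffectTable, SubjectSample, compute_brain_behaviour_effects

__all__ = [
    "ESTIMATORS",
    "ResamplingConfig",
    "draw_subsample_tables",
    "estimate_false_negative_rate",
    "estimate_false_positive_rate",
    "estimate_inflation_rate",
    "estimate_power",
    "estimate_prob_replication",
    "estimate_sign_error_rate",
    "log_spaced_sizes",
    "prob_replication_from_tables",
    "resample_subjects",
    "resample_summary_effect",
    "resample_summary_effects",
    "run_resampling_sweep",
]

ESTIMATORS = (
    "false_negative_rate",
    "power",
    "sign_error_rate",
    "inflation_rate",
    "prob_replication",
    "false_positive_rate",
)


def log_spaced_sizes(lo: int = 25, hi: int = 1000, num: int = 10) -> tuple[int, ...]:
    """Logarithmically spaced integer sample sizes, deduplicated, ascending."""
    sizes = np.unique(np.round(np.geomspace(lo, hi, num)).astype(int))
    return tuple(int(s) for s in sizes)


@dataclass(frozen=True)
class ResamplingConfig:
    """Configuration of a resampling sweep.

    ``sizes`` defaults to 10 log-spaced bins from 25 to 1,000; ``alphas``
    span the uncorrected 0.05 down to 1e-7 (sorted descending);
    ``inflation_magnitudes`` are relative thresholds m, an effect counting
    as inflated when ``|r_rep| > (1 + m) * |r_full|``.
    """

    sizes: tuple[int, ...] = field(default_factory=log_spaced_sizes)
    n_iterations: int = 100
    alphas: tuple[float, ...] = (0.05, 0.01, 0.001, 1e-4, 1e-5, 1e-6, 1e-7)
    inflation_magnitudes: tuple[float, ...] = (0.0, 0.2, 0.4, 0.6, 0.8, 1.0)
    seed: int = 0
    prob_replication_mode: str = "independent"
    prob_replication_require_sign: bool = True

    def __post_init__(self) -> None:
        if any(s < 4 for s in self.sizes):
            raise ValueError("all resample sizes must be >= 4")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if any(not 0.0 < a < 1.0 for a in self.alphas):
            raise ValueError("alphas must lie in (0, 1)")
        if list(self.alphas) != sorted(self.alphas, reverse=True):
            raise ValueError("alphas must be sorted descending")
        if any(m < 0 for m in self.inflation_magnitudes):
            raise ValueError("inflation magnitudes must be >= 0")
        if self.prob_replication_mode not in ("independent", "disjoint"):
            raise ValueError("prob_replication_mode must be 'independent' or 'disjoint'")

    def with_seed(self, seed: int) -> "ResamplingConfig":
        return replace(self, seed=seed)


# ---------------------------------------------------------------------------
# resampling primitives


def resample_subjects(sample: SubjectSample, size: int, seed=0) -> SubjectSample:
    """Draw ``size`` subjects uniformly with replacement.

    Edge rows and behaviour entries stay paired: the same subject indices are
    applied to both. ``seed`` may be an int, a sequence of ints, or an
    existing :class:`numpy.random.Generator`.
    """
    if not 4 <= size <= sample.n_subjects:
        raise ValueError(
            f"resample size must lie in [4, {sample.n_subjects}], got {size}"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    idx = rng.integers(0, sample.n_subjects, size=size)
    return SubjectSample(
        edges=sample.edges[idx],
        behaviour=sample.behaviour[idx],
        n_nodes=sample.n_nodes,
        ts_length=sample.ts_length,
        seed=None,
    )


def resample_summary_effects(r_star, size: int, seed=0) -> np.ndarray:
    """Summary-level analogue of resampling: perturb each correlation on the z scale.

    Treating each observed full-sample correlation ``r*`` as the population
    value, a resampled effect is ``tanh(z)`` with
    ``z ~ Normal(atanh(r*), 1/sqrt(size - 3))``. P values for the result are
    computed at ``n = size``.
    """
    if size < 4:
        raise ValueError(f"size must be >= 4, got {size}")
    r_star = np.asarray(r_star, dtype=float)
    if np.any(np.abs(r_star) >= 1.0):
        raise ValueError("resampling requires |r*| < 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    z = rng.normal(np.arctanh(r_star), 1.0 / np.sqrt(size - 3))
    return np.tanh(z)


def resample_summary_effect(r_star: float, size: int, seed=0) -> float:
    """Scalar convenience wrapper around :func:`resample_summary_effects`."""
    return float(resample_summary_effects(np.asarray([r_star]), size, seed)[0])


# ---------------------------------------------------------------------------
# estimators


def _check_pair(full: EffectTable, rep: EffectTable) -> None:
    if len(full) != len(rep):
        raise ValueError(
            f"effect tables describe different effects: {len(full)} vs {len(rep)}"
        )


def _sign_mismatch(r_a: np.ndarray, r_b: np.ndarray) -> np.ndarray:
    # an exactly zero correlation mismatches any sign (measure-zero event,
    # but the convention must be fixed)
    s_a, s_b = np.sign(r_a), np.sign(r_b)
    return (s_a != s_b) | (s_a == 0) | (s_b == 0)


def estimate_false_negative_rate(full: EffectTable, rep: EffectTable, alpha: float) -> float:
    """Among full-sample-significant effects, the share non-significant in ``rep``.

    Returns ``nan`` when no full-sample effect is significant at ``alpha``.
    """
    _check_pair(full, rep)
    sig = full.p < alpha
    if not sig.any():
        return float("nan")
    return float((rep.p[sig] >= alpha).mean())


def estimate_power(full: EffectTable, rep: EffectTable, alpha: float) -> float:
    """Complement of the false negative rate (same denominator convention)."""
    fnr = estimate_false_negative_rate(full, rep, alpha)
    return 1.0 - fnr if np.isfinite(fnr) else float("nan")


def estimate_sign_error_rate(full: EffectTable, rep: EffectTable, alpha: float) -> float:
    """Among full-sample-significant effects, the share whose sign flips in ``rep``."""
    _check_pair(full, rep)
    sig = full.p < alpha
    if not sig.any():
        return float("nan")
    return float(_sign_mismatch(full.r[sig], rep.r[sig]).mean())


def estimate_inflation_rate(
    full: EffectTable, rep: EffectTable, alpha: float, magnitude: float
) -> float:
    """Among replicated effects, the share inflated beyond a relative margin.

    Replicated means significant in both tables with the same sign; inflated
    means ``|r_rep| > (1 + magnitude) * |r_full|`` (strict inequality).
    Returns ``nan`` when nothing replicated.
    """
    if magnitude < 0:
        raise ValueError("magnitude must be >= 0")
    _check_pair(full, rep)
    replicated = (
        (full.p < alpha) & (rep.p < alpha) & ~_sign_mismatch(full.r, rep.r)
    )
    if not replicated.any():
        return float("nan")
    inflated = np.abs(rep.r[replicated]) > (1.0 + magnitude) * np.abs(full.r[replicated])
    return float(inflated.mean())


def estimate_false_positive_rate(full: EffectTable, rep: EffectTable, alpha: float) -> float:
    """Among effects *not* significant in the full sample, the share significant in ``rep``."""
    _check_pair(full, rep)
    nonsig = full.p >= alpha
    if not nonsig.any():
        return float("nan")
    return float((rep.p[nonsig] < alpha).mean())


def prob_replication_from_tables(
    in_table: EffectTable,
    out_table: EffectTable,
    alpha: float,
    require_sign: bool = True,
) -> float:
    """Share of in-sample-significant effects replicating in the out-of-sample table."""
    _check_pair(in_table, out_table)
    sig_in = in_table.p < alpha
    if not sig_in.any():
        return float("nan")
    sig_out = out_table.p[sig_in] < alpha
    if require_sign:
        sig_out &= ~_sign_mismatch(in_table.r[sig_in], out_table.r[sig_in])
    return float(sig_out.mean())


def estimate_prob_replication(
    full_sample: SubjectSample,
    size: int,
    alpha: float,
    seed=0,
    mode: str = "independent",
    require_sign: bool = True,
) -> float:
    """Probability of replication between two equally sized subsamples.

    Draws an "in-sample" and an "out-of-sample" subsample of ``size``
    subjects from the full dataset and returns the share of effects
    significant in the in-sample that are significant (by default with the
    same sign) in the out-of-sample. ``mode='independent'`` draws two
    independent with-replacement subsamples; ``mode='disjoint'`` splits a
    without-replacement permutation into two disjoint halves (requires
    ``2 * size <= n_subjects``).
    """
    in_table, out_table = draw_subsample_tables(full_sample, size, seed, mode)
    return prob_replication_from_tables(in_table, out_table, alpha, require_sign)


def draw_subsample_tables(
    full_sample: SubjectSample, size: int, seed=0, mode: str = "independent"
) -> tuple[EffectTable, EffectTable]:
    """Draw the in-sample / out-of-sample pair used by probability of replication."""
    if not 4 <= size <= full_sample.n_subjects:
        raise ValueError(f"size must lie in [4, {full_sample.n_subjects}]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if mode == "independent":
        idx_in = rng.integers(0, full_sample.n_subjects, size=size)
        idx_out = rng.integers(0, full_sample.n_subjects, size=size)
    elif mode == "disjoint":
        if 2 * size > full_sample.n_subjects:
            raise ValueError("disjoint mode requires 2 * size <= n_subjects")
        perm = rng.permutation(full_sample.n_subjects)
        idx_in, idx_out = perm[:size], perm[size : 2 * size]
    else:
        raise ValueError("mode must be 'independent' or 'disjoint'")

    tables = []
    for idx, label in ((idx_in, "in_sample"), (idx_out, "out_of_sample")):
        sub = SubjectSample(
            edges=full_sample.edges[idx],
            behaviour=full_sample.behaviour[idx],
            n_nodes=full_sample.n_nodes,
            ts_length=full_sample.ts_length,
        )
        table = compute_brain_behaviour_effects(sub)
        table.label = label
        tables.append(table)
    return tables[0], tables[1]


# ---------------------------------------------------------------------------
# the sweep


def _child_rng(seed: int, *key: int) -> np.random.Generator:
    # one independent stream per (size, iteration, purpose): reproducible and
    # order-independent under any execution order
    return np.random.default_rng(np.random.SeedSequence((seed, *key)))


def run_resampling_sweep(sample: SubjectSample, config: ResamplingConfig) -> pd.DataFrame:
    """Run the full resampling experiment over sizes, iterations, alphas.

    For every ``(size, iteration)`` cell a with-replacement resample is drawn,
    its brain–behaviour correlations are recomputed at the resample size, and
    every estimator is evaluated at every alpha (and every inflation
    magnitude). Returned records are iteration averages; cells whose
    denominator was always empty carry ``nan``, never zero.

    Returns a tidy frame with columns ``estimator, size, alpha, magnitude,
    value, n_iterations, n_eligible``.
    """
    full = compute_brain_behaviour_effects(sample)
    records = []
    for size in config.sizes:
        per_alpha = {
            alpha: {est: [] for est in ESTIMATORS} for alpha in config.alphas
        }
        per_inflation = {
            (alpha, m): [] for alpha in config.alphas for m in config.inflation_magnitudes
        }
        eligible = {
            key: [] for key in list(per_alpha) + list(per_inflation)
        }
        for it in range(config.n_iterations):
            rep_sample = resample_subjects(
                sample, size, _child_rng(config.seed, size, it, 0)
            )
            rep = compute_brain_behaviour_effects(rep_sample)
            rep.label = "resample"
            in_table, out_table = draw_subsample_tables(
                sample, size, _child_rng(config.seed, size, it, 1),
                config.prob_replication_mode,
            )
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
                        in_table, out_table, alpha,
                        config.prob_replication_require_sign,
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
    return pd.DataFrame.from_records(records)


def _mean_record(
    estimator: str,
    size: int,
    alpha: float,
    magnitude: float | None,
    values: np.ndarray,
    eligible: np.ndarray,
) -> dict:
    finite = np.isfinite(values)
    return {
        "estimator": estimator,
        "size": int(size),
        "alpha": float(alpha),
        "magnitude": float("nan") if magnitude is None else float(magnitude),
        "value": float(values[finite].mean()) if finite.any() else float("nan"),
        "mc_se": (
            float(values[finite].std(ddof=1) / np.sqrt(finite.sum()))
            if finite.sum() > 1
            else float("nan")
        ),
        "n_iterations": int(len(values)),
        "n_eligible": float(eligible.mean()) if len(eligible) else float("nan"),
    }
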