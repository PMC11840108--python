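"""Orchestration of the three experiments, bias computation, and diagnostics.

The pipeline ties the modules together into the study's three arms:

1. **Null experiment** — one large null subject-level sample; statistical
   errors estimated both by resampling with replacement (the data-driven
   method under scrutiny) and from freshly generated null samples (the
   infinite-population ground truth), plus the closed-form expectations.
2. **Variance diagnostic** — the mechanism behind the bias: correlations
   recomputed on a resample vary around the already-random full-sample
   correlations, so the pooled distribution is a convolution with variance
   sigma1^2 + sigma2^2 instead of the nominal sigma1^2.
3. **Power-bias experiment** — summary-level ground-truth scenarios in which
   a known fraction of effects carry a true effect size chosen by inverse
   power analysis; resampling-based power estimates are compared with
   analytical power curves to yield bias = estimated - analytical.

CSV tables are the canonical outputs; plotting is an optional extra.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .error_estimation import (
    ResamplingConfig,
    _child_rng,
    log_spaced_sizes,
    resample_subjects,
    resample_summary_effects,
    run_resampling_sweep,
)
from .population_baseline import analytic_null_expectations, run_fresh_sample_sweep
from .stats_core import analytical_power, bonferroni_alpha, critical_r
from .synthetic_data import (
    ScenarioSpec,
    SubjectSample,
    compute_brain_behaviour_effects,
    generate_subject_null_sample,
    generate_summary_effects,
)

__all__ = [
    "PipelineConfig",
    "VarianceDiagnostic",
    "run_null_experiment",
    "run_power_bias_experiment",
    "run_variance_diagnostic",
    "summarise_bias",
    "write_table",
]

logger = logging.getLogger("bwasbias")

DEFAULT_POWER_LEVELS = (0.01, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 0.99)


@dataclass(frozen=True)
class PipelineConfig:
    """Every knob of the study in one (file-serialisable) place.

    Defaults reproduce the study conditions: a null sample of 1,000 subjects
    with 1,225 edges, 100 subject-level iterations over 10 log-spaced sizes,
    and 11 summary-level scenarios of 55,278 effects (500 true) at the
    Bonferroni-corrected threshold 0.05/55,278 with 1,000 iterations.
    """

    n_subjects: int = 1000
    n_nodes: int = 50
    ts_length: int = 100
    sizes: tuple[int, ...] = field(default_factory=log_spaced_sizes)
    alphas: tuple[float, ...] = (0.05, 0.01, 0.001, 1e-4, 1e-5, 1e-6, 1e-7)
    n_iterations_subject: int = 100
    n_iterations_summary: int = 1000
    power_levels: tuple[float, ...] = DEFAULT_POWER_LEVELS
    n_total_effects: int = 55278
    n_true_effects: int = 500
    n_full: int = 1000
    scenario_alpha: float | None = None
    inflation_magnitudes: tuple[float, ...] = (0.0, 0.2, 0.4, 0.6, 0.8, 1.0)
    prob_replication_mode: str = "independent"
    prob_replication_require_sign: bool = True
    seed: int = 0

    @property
    def effective_scenario_alpha(self) -> float:
        if self.scenario_alpha is not None:
            return self.scenario_alpha
        return bonferroni_alpha(0.05, self.n_total_effects)

    def resampling_config(self) -> ResamplingConfig:
        return ResamplingConfig(
            sizes=self.sizes,
            n_iterations=self.n_iterations_subject,
            alphas=self.alphas,
            inflation_magnitudes=self.inflation_magnitudes,
            seed=self.seed,
            prob_replication_mode=self.prob_replication_mode,
            prob_replication_require_sign=self.prob_replication_require_sign,
        )

    def scaled_down(self) -> "PipelineConfig":
        """A reduced preset showing the same qualitative contrasts in seconds."""
        return dataclasses.replace(
            self,
            n_subjects=200,
            n_nodes=20,
            ts_length=60,
            sizes=(25, 50, 100, 200),
            alphas=(0.05, 0.01, 0.001),
            n_iterations_subject=20,
            n_iterations_summary=100,
            n_total_effects=3000,
            n_true_effects=60,
            n_full=200,
        )

    def to_file(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data = {k: (list(v) if isinstance(v, tuple) else v) for k, v in data.items()}
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} must contain a flat mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config key(s) in {path}: {sorted(unknown)}")
        data = {k: (tuple(v) if isinstance(v, list) else v) for k, v in data.items()}
        return cls(**data)

    def content_hash(self) -> str:
        data = dataclasses.asdict(self)
        data = {k: (list(v) if isinstance(v, tuple) else v) for k, v in data.items()}
        return hashlib.sha1(
            yaml.safe_dump(data, sort_keys=True).encode()
        ).hexdigest()[:12]


def write_table(frame: pd.DataFrame, path: str | Path, config: PipelineConfig) -> None:
    """Write a CSV with a versioned header naming the package and config hash."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as handle:
        handle.write(f"# bwasbias={__version__} config={config.content_hash()}\n")
        frame.to_csv(handle, index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


# ---------------------------------------------------------------------------
# experiment 1: the null sample


def run_null_experiment(
    config: PipelineConfig, out_dir: str | Path | None = None
) -> dict[str, pd.DataFrame]:
    """Resampling vs fresh-sample error estimates on one large null sample.

    Returns (and optionally writes) three tables: the resampling sweep, the
    fresh-sample baseline sweep, and the analytic null expectations.
    """
    t0 = time.perf_counter()
    sample_seed = _derive_seed(config.seed, 101)
    sample = generate_subject_null_sample(
        config.n_subjects, config.n_nodes, config.ts_length, seed=sample_seed
    )
    logger.info(
        "null experiment: sample n=%d, %d edges (seed %d)",
        sample.n_subjects, sample.n_edges, sample_seed,
    )
    rs_config = config.resampling_config()
    resampling = run_resampling_sweep(sample, rs_config)
    resampling["source"] = "resample"
    logger.info("resampling sweep done in %.1fs", time.perf_counter() - t0)

    t1 = time.perf_counter()
    full = compute_brain_behaviour_effects(sample)
    fresh = run_fresh_sample_sweep(full, rs_config, config.n_nodes, config.ts_length)
    logger.info("fresh-sample sweep done in %.1fs", time.perf_counter() - t1)

    analytic = pd.concat(
        [
            analytic_null_expectations(
                alpha,
                require_sign=config.prob_replication_require_sign,
                magnitudes=config.inflation_magnitudes,
            )
            for alpha in config.alphas
        ],
        ignore_index=True,
    )
    frames = {
        "null_resampling_errors": resampling,
        "fresh_baseline_errors": fresh,
        "analytic_null_expectations": analytic,
    }
    if out_dir is not None:
        for name, frame in frames.items():
            write_table(frame, Path(out_dir) / f"{name}.csv", config)
    return frames


# ---------------------------------------------------------------------------
# experiment 2: variance convolution diagnostic


@dataclass(frozen=True)
class VarianceDiagnostic:
    """Summary of the additive-variance mechanism at one resample size.

    ``sigma1_sq`` is the empirical variance of the full-sample null
    correlations; ``sigma2_sq = 1/(size - 3)`` the resampling variance on the
    Fisher scale; ``empirical_var`` the variance of the pooled resampled
    correlations, to be compared with ``predicted_var = sigma1_sq +
    sigma2_sq``. ``share_p_below_alpha`` quantifies the inflation of small
    P values in the pooled resamples (nominal value: alpha). The tracked
    effect is the largest-|r| full-sample correlation with its per-iteration
    resampled values, whose spread illustrates the second variance source.
    """

    size: int
    n_iterations: int
    sigma1_sq: float
    sigma2_sq: float
    empirical_var: float
    share_p_below_alpha: float
    alpha: float
    tracked_effect_id: int
    tracked_effect_r: float
    tracked_effect_values: np.ndarray = field(repr=False)

    @property
    def predicted_var(self) -> float:
        return self.sigma1_sq + self.sigma2_sq

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame.from_records(
            [
                {
                    "size": self.size,
                    "n_iterations": self.n_iterations,
                    "sigma1_sq": self.sigma1_sq,
                    "sigma2_sq": self.sigma2_sq,
                    "empirical_var": self.empirical_var,
                    "predicted_var": self.predicted_var,
                    "share_p_below_alpha": self.share_p_below_alpha,
                    "alpha": self.alpha,
                    "tracked_effect_id": self.tracked_effect_id,
                    "tracked_effect_r": self.tracked_effect_r,
                    "tracked_effect_mean": float(self.tracked_effect_values.mean()),
                    "tracked_effect_var": float(self.tracked_effect_values.var(ddof=1)),
                }
            ]
        )


def run_variance_diagnostic(
    sample: SubjectSample,
    size: int | None = None,
    n_iterations: int = 100,
    seed: int = 0,
    alpha: float = 0.05,
) -> VarianceDiagnostic:
    """Pool resampled correlations and compare their variance with sigma1^2 + sigma2^2."""
    if size is None:
        size = sample.n_subjects
    if not 4 <= size <= sample.n_subjects:
        raise ValueError(f"size must lie in [4, {sample.n_subjects}]")
    full = compute_brain_behaviour_effects(sample)
    tracked_pos = int(np.argmax(np.abs(full.r)))

    pooled_r, pooled_p, tracked = [], [], []
    for it in range(n_iterations):
        rep_sample = resample_subjects(sample, size, _child_rng(seed, size, it, 0))
        rep = compute_brain_behaviour_effects(rep_sample)
        pooled_r.append(rep.r)
        pooled_p.append(rep.p)
        tracked.append(rep.r[tracked_pos])
    pooled_r = np.concatenate(pooled_r)
    pooled_p = np.concatenate(pooled_p)

    return VarianceDiagnostic(
        size=int(size),
        n_iterations=int(n_iterations),
        sigma1_sq=float(full.r.var(ddof=1)),
        sigma2_sq=1.0 / (size - 3),
        empirical_var=float(pooled_r.var(ddof=1)),
        share_p_below_alpha=float((pooled_p < alpha).mean()),
        alpha=float(alpha),
        tracked_effect_id=int(full.effect_id[tracked_pos]),
        tracked_effect_r=float(full.r[tracked_pos]),
        tracked_effect_values=np.asarray(tracked),
    )


# ---------------------------------------------------------------------------
# experiment 3: ground-truth power scenarios


def run_power_bias_experiment(
    config: PipelineConfig, out_dir: str | Path | None = None
) -> dict[str, pd.DataFrame]:
    """Bias of resampling-based power estimates in ground-truth scenarios.

    For each power level a summary-level large sample is generated with the
    matching true effect size; power is then estimated at each resample size
    as the share of full-sample-significant effects that are significant
    again in a summary-level resample (P values at the resample size,
    Bonferroni threshold), averaged over iterations, and compared with the
    analytical power curve: ``bias = estimated - analytical``.

    Only the full-sample-significant effects are ever resampled: the
    estimator's numerator and denominator involve no other effect, and the
    per-effect draws are independent, so restricting the simulation to that
    subset is exact.

    Returns ``{"bias": ..., "recovery": ...}`` where ``recovery`` records the
    empirical full-sample power over the true effects against its nominal
    level (the end-to-end check of the inverse power analysis).
    """
    alpha = config.effective_scenario_alpha
    bias_rows, recovery_rows = [], []
    for scenario_idx, level in enumerate(config.power_levels):
        t0 = time.perf_counter()
        spec = ScenarioSpec.from_power_level(
            level,
            n_total_effects=config.n_total_effects,
            n_true_effects=config.n_true_effects,
            n_full=config.n_full,
            alpha=alpha,
        )
        table = generate_summary_effects(
            spec, seed=_derive_seed(config.seed, 211, scenario_idx)
        )
        sig = table.p < alpha
        n_sig = int(sig.sum())
        r_sig = table.r[sig]
        true_mask = table.is_true_effect
        empirical_full_power = float(
            (table.p[true_mask] < alpha).mean()
        ) if true_mask.any() else float("nan")
        recovery_rows.append(
            {
                "scenario_power_level": level,
                "rho_true": spec.rho_true,
                "nominal_power": level,
                "empirical_full_power": empirical_full_power,
                "n_true_effects": int(true_mask.sum()),
                "n_sig_full": n_sig,
            }
        )
        for size in config.sizes:
            if n_sig == 0:
                estimated, mc_se = float("nan"), float("nan")
            else:
                crit = critical_r(size, alpha)
                values = np.empty(config.n_iterations_summary)
                for it in range(config.n_iterations_summary):
                    rng = _child_rng(config.seed, scenario_idx, size, it)
                    r_rep = resample_summary_effects(r_sig, size, rng)
                    values[it] = float((np.abs(r_rep) > crit).mean())
                estimated = float(values.mean())
                mc_se = float(values.std(ddof=1) / np.sqrt(len(values)))
            analytic = analytical_power(spec.rho_true, size, alpha)
            bias_rows.append(
                {
                    "scenario_power_level": level,
                    "rho_true": spec.rho_true,
                    "size": int(size),
                    "estimated_power": estimated,
                    "analytical_power": analytic,
                    "bias": estimated - analytic,
                    "mc_se": mc_se,
                    "alpha": alpha,
                    "n_iterations": config.n_iterations_summary,
                    "n_sig_full": n_sig,
                }
            )
        logger.info(
            "scenario power=%.0f%% (rho=%.4f, %d significant) done in %.1fs",
            100 * level, spec.rho_true, n_sig, time.perf_counter() - t0,
        )
    frames = {
        "bias": pd.DataFrame.from_records(bias_rows),
        "recovery": pd.DataFrame.from_records(recovery_rows),
    }
    if out_dir is not None:
        write_table(frames["bias"], Path(out_dir) / "power_bias.csv", config)
        write_table(frames["recovery"], Path(out_dir) / "power_recovery.csv", config)
        write_table(
            summarise_bias(frames["bias"]),
            Path(out_dir) / "power_bias_summary.csv",
            config,
        )
    return frames


def summarise_bias(records: pd.DataFrame) -> pd.DataFrame:
    """Aggregate bias records into one row per (scenario, size) cell.

    The mean of ``bias`` is taken over whatever rows fall in a cell (a single
    averaged row passes through unchanged); Monte-Carlo standard errors are
    combined quadratically.
    """
    columns = [
        "scenario_power_level", "size", "bias", "mc_se", "n_rows",
    ]
    if len(records) == 0:
        return pd.DataFrame(columns=columns)

    def _agg(group: pd.DataFrame) -> pd.Series:
        se = group["mc_se"].to_numpy(dtype=float)
        return pd.Series(
            {
                "bias": group["bias"].mean(),
                "mc_se": float(np.sqrt(np.nansum(se**2)) / len(se)),
                "n_rows": len(group),
            }
        )

    out = (
        records.groupby(["scenario_power_level", "size"], sort=True)
        .apply(_agg, include_groups=False)
        .reset_index()
    )
    out["n_rows"] = out["n_rows"].astype(int)
    return out[columns]


def _derive_seed(master: int, *key: int) -> int:
    """A deterministic 31-bit child seed from the master seed and a key path."""
    return int(
        np.random.SeedSequence((master, *key)).generate_state(1, np.uint32)[0] // 2
    )
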