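"""Synthetic data generators for the simulation study.

Two kinds of inputs are produced, both under full seed control:

* **Subject-level null samples** (:class:`SubjectSample`): each subject
  carries a vector of "edges" — all pairwise Pearson correlations between
  independent white-noise node time series — plus one standard-normal
  behavioural score. Edges and behaviour come from independent random
  streams, so every edge–behaviour correlation across subjects has
  population effect size rho = 0 by construction.

* **Summary-statistic samples** (:func:`generate_summary_effects`): large
  tables of Pearson correlations drawn directly through the Fisher-z normal
  approximation, with a known subset replaced by true effects of a chosen
  effect size. These are used for the ground-truth power scenarios where
  subject-level simulation would be needlessly expensive.

The generators emulate the *statistical* structure of a mass-univariate
brain-wide association study (many noisy correlations against one behaviour),
not real fMRI signal: there is no temporal autocorrelation, motion, or
parcellation structure, because none of it matters when the null is true.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from . import stats_core

__all__ = [
    "EffectTable",
    "ScenarioSpec",
    "SubjectSample",
    "compute_brain_behaviour_effects",
    "generate_subject_null_sample",
    "generate_summary_effects",
    "n_edges_for_nodes",
]

Seed = "int | Sequence[int]"


def n_edges_for_nodes(n_nodes: int) -> int:
    """Number of distinct node pairs: ``n_nodes choose 2``."""
    if n_nodes < 2:
        raise ValueError(f"n_nodes must be >= 2, got {n_nodes}")
    return n_nodes * (n_nodes - 1) // 2


@dataclass
class SubjectSample:
    """A subject-level sample: per-subject edge values plus one behavioural score.

    ``edges`` has shape ``(n_subjects, n_edges)`` with every entry in
    ``[-1, 1]`` (each is a Pearson correlation between two node time series);
    ``behaviour`` has shape ``(n_subjects,)``.
    """

    edges: np.ndarray = field(repr=False)
    behaviour: np.ndarray = field(repr=False)
    n_nodes: int
    ts_length: int | None = None
    seed: object | None = None

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=float)
        self.behaviour = np.asarray(self.behaviour, dtype=float)
        if self.edges.ndim != 2:
            raise ValueError("edges must be a 2-d array (subjects x edges)")
        if self.behaviour.shape != (self.edges.shape[0],):
            raise ValueError("behaviour length must equal the number of subjects")

    @property
    def n_subjects(self) -> int:
        return self.edges.shape[0]

    @property
    def n_edges(self) -> int:
        return self.edges.shape[1]

    def save(self, path: str | Path) -> None:
        """Write the sample as CSV plus a plain-text metadata sidecar."""
        import pandas as pd

        path = Path(path)
        frame = pd.DataFrame(
            self.edges, columns=[f"edge_{i}" for i in range(self.n_edges)]
        )
        frame.insert(0, "behaviour", self.behaviour)
        frame.to_csv(path, index=False)
        meta = {
            "n_subjects": self.n_subjects,
            "n_nodes": self.n_nodes,
            "n_edges": self.n_edges,
            "ts_length": self.ts_length,
            "seed": self.seed,
        }
        _write_metadata(path.with_suffix(path.suffix + ".meta"), meta)


@dataclass
class EffectTable:
    """A set of Pearson correlations with two-tailed parametric P values.

    The table is the common currency of the analysis: the full sample, every
    resample, and every fresh replication sample all reduce to one. The
    optional ``is_true_effect`` mask records ground truth for simulated
    scenarios; estimators never look at it.
    """

    r: np.ndarray
    p: np.ndarray
    n: int
    label: str = "full_sample"
    is_true_effect: np.ndarray | None = field(default=None, repr=False)
    effect_id: np.ndarray | None = field(default=None, repr=False)

    LABELS = ("full_sample", "resample", "fresh_sample", "in_sample", "out_of_sample")

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        self.p = np.asarray(self.p, dtype=float)
        if self.r.shape != self.p.shape or self.r.ndim != 1:
            raise ValueError("r and p must be 1-d arrays of equal length")
        if self.label not in self.LABELS:
            raise ValueError(f"unknown label {self.label!r}")
        if np.any(np.abs(self.r) > 1.0):
            raise ValueError("correlations must lie in [-1, 1]")
        if self.effect_id is None:
            self.effect_id = np.arange(len(self.r))
        else:
            self.effect_id = np.asarray(self.effect_id, dtype=int)
        if self.is_true_effect is not None:
            self.is_true_effect = np.asarray(self.is_true_effect, dtype=bool)
            if self.is_true_effect.shape != self.r.shape:
                raise ValueError("is_true_effect must match r in length")

    def __len__(self) -> int:
        return len(self.r)

    @classmethod
    def from_correlations(
        cls,
        r,
        n: int,
        label: str = "full_sample",
        is_true_effect=None,
        effect_id=None,
    ) -> "EffectTable":
        """Build a table from raw correlations, deriving the P values."""
        r = np.asarray(r, dtype=float)
        p = np.atleast_1d(stats_core.p_two_tailed(r, n))
        return cls(r=r, p=p, n=int(n), label=label,
                   is_true_effect=is_true_effect, effect_id=effect_id)

    def to_frame(self):
        import pandas as pd

        frame = pd.DataFrame(
            {
                "effect_id": self.effect_id,
                "r": self.r,
                "p": self.p,
                "n": self.n,
                "label": self.label,
                "is_true_effect": (
                    self.is_true_effect
                    if self.is_true_effect is not None
                    else np.zeros(len(self), dtype=bool)
                ),
            }
        )
        return frame

    def to_csv(self, path: str | Path, metadata: dict | None = None) -> None:
        path = Path(path)
        self.to_frame().to_csv(path, index=False)
        meta = {"n": self.n, "label": self.label, "n_effects": len(self)}
        if metadata:
            meta.update(metadata)
        _write_metadata(path.with_suffix(path.suffix + ".meta"), meta)

    @classmethod
    def from_csv(cls, path: str | Path) -> "EffectTable":
        import pandas as pd

        frame = pd.read_csv(path)
        mask = frame["is_true_effect"].to_numpy(dtype=bool)
        return cls(
            r=frame["r"].to_numpy(),
            p=frame["p"].to_numpy(),
            n=int(frame["n"].iloc[0]),
            label=str(frame["label"].iloc[0]),
            is_true_effect=mask if mask.any() else None,
            effect_id=frame["effect_id"].to_numpy(),
        )


@dataclass(frozen=True)
class ScenarioSpec:
    """One ground-truth power scenario for the summary-level simulation.

    A large sample of ``n_total_effects`` correlations at sample size
    ``n_full`` in which ``n_true_effects`` entries carry a common true effect
    ``rho_true``, chosen so that the two-tailed test at ``alpha`` has the
    requested ``power_level`` at the full sample size.
    """

    power_level: float
    rho_true: float
    n_total_effects: int = 55278
    n_true_effects: int = 500
    n_full: int = 1000
    alpha: float = 0.05 / 55278

    def __post_init__(self) -> None:
        if not 0.0 < self.power_level < 1.0:
            raise ValueError("power_level must lie in (0, 1)")
        if not 0.0 < self.rho_true < 1.0:
            raise ValueError("rho_true must lie in (0, 1)")
        if not 0 <= self.n_true_effects < self.n_total_effects:
            raise ValueError("need n_true_effects < n_total_effects")
        if self.n_full < 4:
            raise ValueError("n_full must be >= 4")

    @classmethod
    def from_power_level(
        cls,
        power_level: float,
        n_total_effects: int = 55278,
        n_true_effects: int = 500,
        n_full: int = 1000,
        alpha: float | None = None,
    ) -> "ScenarioSpec":
        """Derive ``rho_true`` by inverse power analysis at the full sample size."""
        if alpha is None:
            alpha = stats_core.bonferroni_alpha(0.05, n_total_effects)
        rho = stats_core.r_critical_for_power(n_full, alpha, power_level)
        return cls(
            power_level=power_level,
            rho_true=rho,
            n_total_effects=n_total_effects,
            n_true_effects=n_true_effects,
            n_full=n_full,
            alpha=alpha,
        )


def generate_subject_null_sample(
    n_subjects: int,
    n_nodes: int = 50,
    ts_length: int = 100,
    seed=0,
) -> SubjectSample:
    """Generate a null subject-level sample.

    For each subject, ``n_nodes`` independent standard-normal time series of
    length ``ts_length`` are drawn and all pairwise Pearson correlations form
    the subject's edge vector (``n_nodes choose 2`` edges). The behavioural
    score is an independent standard-normal draw per subject, from a separate
    sub-stream of the master seed, so every edge–behaviour correlation is
    null by construction.

    The default 50 nodes yield 1,225 edges. ``ts_length`` only shapes the
    (nuisance) marginal distribution of edge values; the brain–behaviour
    correlations are null for any length >= 3.
    """
    if n_subjects < 4:
        raise ValueError(f"n_subjects must be >= 4, got {n_subjects}")
    if n_nodes < 2:
        raise ValueError(f"n_nodes must be >= 2, got {n_nodes}")
    if ts_length < 3:
        raise ValueError(f"ts_length must be >= 3, got {ts_length}")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    edges_rng, behaviour_rng = (np.random.default_rng(s) for s in ss.spawn(2))

    ts = edges_rng.standard_normal((n_subjects, n_nodes, ts_length))
    ts -= ts.mean(axis=-1, keepdims=True)
    norms = np.sqrt((ts**2).sum(axis=-1, keepdims=True))
    ts /= norms
    corr = ts @ ts.transpose(0, 2, 1)
    iu = np.triu_indices(n_nodes, k=1)
    edges = np.clip(corr[:, iu[0], iu[1]], -1.0, 1.0)

    behaviour = behaviour_rng.standard_normal(n_subjects)
    return SubjectSample(
        edges=edges,
        behaviour=behaviour,
        n_nodes=n_nodes,
        ts_length=ts_length,
        seed=seed,
    )


def compute_brain_behaviour_effects(sample: SubjectSample) -> EffectTable:
    """Correlate every edge with behaviour across subjects.

    Returns one Pearson r per edge with two-tailed parametric P values at
    ``n = n_subjects`` and label ``full_sample``. Edge columns with zero
    variance (possible only in degenerate configurations) have no defined
    correlation; they are excluded with a warning and the surviving
    ``effect_id`` values index into the original edge order.
    """
    if sample.n_subjects < 4:
        raise ValueError("need at least 4 subjects to correlate")
    edges = sample.edges
    behaviour = sample.behaviour

    edges_c = edges - edges.mean(axis=0)
    behaviour_c = behaviour - behaviour.mean()
    edge_ss = np.sqrt((edges_c**2).sum(axis=0))
    behaviour_ss = np.sqrt((behaviour_c**2).sum())
    if behaviour_ss == 0.0:
        raise ValueError("behaviour has zero variance")

    valid = edge_ss > 0.0
    if not valid.all():
        n_bad = int((~valid).sum())
        warnings.warn(
            f"excluding {n_bad} zero-variance edge(s) with undefined correlation",
            RuntimeWarning,
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (edges_c * behaviour_c[:, None]).sum(axis=0) / (edge_ss * behaviour_ss)
    r = np.clip(r[valid], -1.0, 1.0)
    return EffectTable.from_correlations(
        r, n=sample.n_subjects, label="full_sample",
        effect_id=np.flatnonzero(valid),
    )


def generate_summary_effects(spec: ScenarioSpec, seed=0) -> EffectTable:
    """Draw a summary-level large sample for one ground-truth scenario.

    All ``n_total_effects`` correlations are drawn via the Fisher-z normal
    approximation at sample size ``n_full``: z ~ Normal(atanh(rho),
    1/sqrt(n_full - 3)), then r = tanh(z). First every effect is drawn null
    (rho = 0); afterwards ``n_true_effects`` randomly chosen entries are
    replaced with draws at ``rho_true``. The ground-truth mask is carried on
    the returned table as metadata only.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)
    sd = 1.0 / np.sqrt(spec.n_full - 3)
    z = rng.normal(0.0, sd, size=spec.n_total_effects)
    mask = np.zeros(spec.n_total_effects, dtype=bool)
    if spec.n_true_effects > 0:
        true_idx = rng.choice(
            spec.n_total_effects, size=spec.n_true_effects, replace=False
        )
        z[true_idx] = rng.normal(np.arctanh(spec.rho_true), sd, size=spec.n_true_effects)
        mask[true_idx] = True
    r = np.tanh(z)
    return EffectTable.from_correlations(
        r, n=spec.n_full, label="full_sample", is_true_effect=mask
    )


def _write_metadata(path: Path, meta: dict) -> None:
    lines = [f"{key} = {value}" for key, value in meta.items()]
    Path(path).write_text("\n".join(lines) + "\n")
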