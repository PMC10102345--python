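"""Synthetic cohorts with a stroke (IS) and healthy-control (HC) group.

The simulator draws per-subject variables from a multivariate normal with
configurable means, SDs and pairwise correlation targets, then clips bounded
clinical scores to their scales. Defaults encode the published group
structure this package was built around: 20 ischemic-stroke patients with a
single left-subcortical lesion imaged 7–40 days post onset, 30 healthy
controls; left/right ALPS indices of 1.424 ± 0.132 and 1.381 ± 0.172 (IS)
versus 1.565 ± 0.197 and 1.454 ± 0.107 (HC); a positive ALPS–motor-score
association and a negative ALPS–contralateral-CST association in the IS
group. Controls carry no motor scores and no onset time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

__all__ = ["GroupParams", "CohortParams", "default_params", "simulate_cohort",
           "load_params", "COLUMN_BOUNDS"]

# clip limits for bounded scores; None = unbounded side
COLUMN_BOUNDS = {
    "alps_left": (0.05, None),
    "alps_right": (0.05, None),
    "fma_motor": (0.0, 100.0),
    "fma_sensory": (0.0, 24.0),
    "cst_fa_left": (0.0, 1.0),
    "cst_fa_right": (0.0, 1.0),
    "cst_md_left": (1e-5, None),
    "cst_md_right": (1e-5, None),
    "cc_fa_left": (0.0, 1.0),
    "cc_fa_right": (0.0, 1.0),
    "age": (18.0, None),
    "days_post_onset": (7.0, 40.0),
}


@dataclass(frozen=True)
class GroupParams:
    """Means/SDs per column plus pairwise correlation targets for one group."""

    means: dict[str, float]
    sds: dict[str, float]
    correlations: dict[tuple[str, str], float] = field(default_factory=dict)
    male_fraction: float = 0.5

    def __post_init__(self) -> None:
        for c, s in self.sds.items():
            if s <= 0:
                raise ValueError(f"SD for {c!r} must be > 0")
        if set(self.means) != set(self.sds):
            raise ValueError("means and sds must cover the same columns")
        if not (0.0 <= self.male_fraction <= 1.0):
            raise ValueError("male_fraction must lie in [0, 1]")

    @property
    def columns(self) -> list[str]:
        return list(self.means)

    def correlation_matrix(self) -> np.ndarray:
        cols = self.columns
        k = len(cols)
        corr = np.eye(k)
        pos = {c: i for i, c in enumerate(cols)}
        for (a, b), r in self.correlations.items():
            i, j = pos[a], pos[b]
            corr[i, j] = corr[j, i] = r
        eig = np.linalg.eigvalsh(corr)
        if eig.min() < -1e-10:
            clipped = _nearest_psd(corr)
            raise ValueError(
                "correlation targets are not positive semidefinite "
                f"(min eigenvalue {eig.min():.3g}); nearest PSD matrix:\n{clipped}"
            )
        return corr


def _nearest_psd(corr: np.ndarray) -> np.ndarray:
    vals, vecs = np.linalg.eigh(corr)
    fixed = (vecs * np.maximum(vals, 0)) @ vecs.T
    d = np.sqrt(np.diag(fixed))
    return np.round(fixed / np.outer(d, d), 4)


@dataclass(frozen=True)
class CohortParams:
    is_group: GroupParams
    hc_group: GroupParams
    n_is: int = 20
    n_hc: int = 30


def default_params() -> CohortParams:
    """Published group structure: the simulator's study conditions."""
    is_means = {
        "alps_left": 1.424, "alps_right": 1.381,
        "fma_motor": 80.0, "fma_sensory": 20.0,
        "cst_fa_left": 0.52, "cst_fa_right": 0.55,
        "cst_md_left": 0.80e-3, "cst_md_right": 0.75e-3,
        "cc_fa_left": 0.65, "cc_fa_right": 0.65,
        "age": 59.2, "days_post_onset": 14.0,
    }
    is_sds = {
        "alps_left": 0.132, "alps_right": 0.172,
        "fma_motor": 20.0, "fma_sensory": 4.0,
        "cst_fa_left": 0.05, "cst_fa_right": 0.05,
        "cst_md_left": 0.06e-3, "cst_md_right": 0.06e-3,
        "cc_fa_left": 0.05, "cc_fa_right": 0.05,
        "age": 12.1, "days_post_onset": 8.0,
    }
    is_corr = {
        ("alps_left", "fma_motor"): 0.5,
        ("alps_left", "cst_fa_right"): -0.55,
        ("alps_left", "cst_md_right"): -0.45,
        ("alps_left", "fma_sensory"): 0.4,
    }
    hc_means = {
        "alps_left": 1.565, "alps_right": 1.454,
        "cst_fa_left": 0.56, "cst_fa_right": 0.56,
        "cst_md_left": 0.72e-3, "cst_md_right": 0.72e-3,
        "cc_fa_left": 0.66, "cc_fa_right": 0.66,
        "age": 54.6,
    }
    hc_sds = {
        "alps_left": 0.197, "alps_right": 0.107,
        "cst_fa_left": 0.04, "cst_fa_right": 0.04,
        "cst_md_left": 0.05e-3, "cst_md_right": 0.05e-3,
        "cc_fa_left": 0.04, "cc_fa_right": 0.04,
        "age": 7.4,
    }
    hc_corr = {("alps_left", "alps_right"): 0.4}
    return CohortParams(
        is_group=GroupParams(is_means, is_sds, is_corr, male_fraction=0.80),
        hc_group=GroupParams(hc_means, hc_sds, hc_corr, male_fraction=20 / 30),
        n_is=20,
        n_hc=30,
    )


_ALL_COLUMNS = [
    "alps_left", "alps_right", "fma_motor", "fma_sensory",
    "cst_fa_left", "cst_fa_right", "cst_md_left", "cst_md_right",
    "cc_fa_left", "cc_fa_right", "age", "days_post_onset",
]


def _draw_group(
    params: GroupParams, n: int, group: str, rng: np.random.Generator
) -> pd.DataFrame:
    cols = params.columns
    corr = params.correlation_matrix()
    sds = np.array([params.sds[c] for c in cols])
    cov = corr * np.outer(sds, sds)
    means = np.array([params.means[c] for c in cols])
    draws = rng.multivariate_normal(means, cov, size=n, method="cholesky")
    df = pd.DataFrame(draws, columns=cols)
    for c in cols:
        lo, hi = COLUMN_BOUNDS.get(c, (None, None))
        df[c] = df[c].clip(lower=lo, upper=hi)
    df["sex"] = np.where(rng.random(n) < params.male_fraction, "M", "F")
    df["group"] = group
    return df


def simulate_cohort(
    params: Optional[CohortParams] = None, seed: int = 0
) -> pd.DataFrame:
    """Draw a full cohort table; identical seeds give identical tables.

    Columns the group design leaves undefined (motor scores and onset time
    for controls) are NaN. Bounded scores are clipped to their scales after
    the multivariate-normal draw, which preserves the targeted monotone
    associations that the rank-based analyses consume.
    """
    if params is None:
        params = default_params()
    rng = np.random.default_rng(seed)
    frames = [
        _draw_group(params.is_group, params.n_is, "IS", rng),
        _draw_group(params.hc_group, params.n_hc, "HC", rng),
    ]
    df = pd.concat(frames, ignore_index=True)
    for c in _ALL_COLUMNS:
        if c not in df.columns:
            df[c] = np.nan
    df.insert(0, "id", [f"S{i + 1:03d}" for i in range(len(df))])
    return df[["id", "group", "sex"] + _ALL_COLUMNS]


def load_params(path: str | Path) -> CohortParams:
    """Cohort parameters from a YAML file (see data/cohort_defaults.yaml)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)

    def group(d: dict) -> GroupParams:
        corr = {
            (str(item["a"]), str(item["b"])): float(item["r"])
            for item in d.get("correlations", [])
        }
        return GroupParams(
            means={k: float(v) for k, v in d["means"].items()},
            sds={k: float(v) for k, v in d["sds"].items()},
            correlations=corr,
            male_fraction=float(d.get("male_fraction", 0.5)),
        )

    return CohortParams(
        is_group=group(raw["is_group"]),
        hc_group=group(raw["hc_group"]),
        n_is=int(raw.get("n_is", 20)),
        n_hc=int(raw.get("n_hc", 30)),
    )
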