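"""End-to-end orchestration: phantom → fit → ALPS → cohort statistics.

A "subject" is one synthetic DWI dataset with its own per-hemisphere
glymphatic coefficients and (optionally) a lesion; the image pipeline runs
shell selection, tensor fitting, ROI placement and ALPS extraction per
subject and accumulates results plus exclusions. The table pipeline runs
the full statistical plan on a cohort table — group comparisons of left and
right ALPS, within-group lateralization (paired t), demographic tests,
rank correlations with motor scores, and partial correlations with CST
integrity controlling age and time since onset.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .alps import (
    AlpsResult,
    auto_roi_definitions,
    extract_axis_diffusivities,
    extract_roi_metrics,
    place_rois,
)
from .cohort import CohortParams, default_params
from .phantom import (
    REGION_LABELS,
    PhantomSpec,
    add_rician_noise,
    build_phantom,
    synthesize_signals,
)
from .stats import (
    StatResult,
    adjust_pvalues,
    chi_square_2x2,
    paired_t,
    pearson_partial,
    spearman,
    two_sample_t,
)
from .tensor import DEFAULT_B_MAX, compute_metrics, fit_tensor, select_shells
from .scheme import AcquisitionScheme, default_scheme

__all__ = [
    "SubjectResult",
    "RunReport",
    "run_single_subject",
    "run_cohort_statistics",
    "run_image_cohort",
]


@dataclass
class SubjectResult:
    """Per-subject output: both hemispheres' ALPS plus tract ROI metrics."""

    subject_id: str
    excluded: bool
    exclusion_reason: Optional[str]
    alps: dict[str, AlpsResult] = field(default_factory=dict)
    roi_metrics: Optional[pd.DataFrame] = None

    def rows(self) -> list[dict]:
        if self.excluded:
            return [
                {
                    "subject_id": self.subject_id,
                    "hemisphere": h,
                    "alps_index": np.nan,
                    "excluded_flag": True,
                }
                for h in ("left", "right")
            ]
        return [
            r.to_row(self.subject_id, excluded=False) for r in self.alps.values()
        ]


@dataclass
class RunReport:
    """Cohort-level accounting: results, exclusions, statistics, provenance."""

    alps_table: pd.DataFrame
    exclusions: pd.DataFrame
    stats_table: pd.DataFrame
    seed: int
    n_recruited: int
    n_analyzed: int
    n_excluded: int
    version: str = __version__
    config_echo: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_recruited != self.n_analyzed + self.n_excluded:
            raise ValueError(
                f"accounting violated: {self.n_recruited} recruited ≠ "
                f"{self.n_analyzed} analyzed + {self.n_excluded} excluded"
            )

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.alps_table.to_csv(out / "alps_results.csv", index=False)
        self.exclusions.to_csv(out / "exclusions.csv", index=False)
        self.stats_table.to_csv(out / "statistics.csv", index=False)
        meta = {
            "seed": self.seed,
            "version": self.version,
            "n_recruited": self.n_recruited,
            "n_analyzed": self.n_analyzed,
            "n_excluded": self.n_excluded,
            "config": self.config_echo,
        }
        (out / "report.json").write_text(json.dumps(meta, indent=2, default=str))


def run_single_subject(
    spec: PhantomSpec,
    scheme: Optional[AcquisitionScheme] = None,
    subject_id: str = "S001",
    b_max: float = DEFAULT_B_MAX,
) -> SubjectResult:
    """Phantom → signals (+ Rician noise if spec.noise_sigma > 0) → shell
    selection → tensor fit → auto ROIs → per-hemisphere ALPS and ROI metrics.

    A lesion overlapping any ROI yields an exclusion record, not an error.
    """
    if scheme is None:
        scheme = default_scheme()
    truth = build_phantom(spec)
    data = synthesize_signals(truth, scheme)
    if spec.noise_sigma > 0:
        data = add_rician_noise(data, spec.noise_sigma, spec.seed)
    data = select_shells(data, b_max=b_max)
    fitted = fit_tensor(data)
    fitted.region_map = truth.region_map

    lesion_mask = truth.region_map == REGION_LABELS["lesion"]
    defs = auto_roi_definitions(truth)
    rois = place_rois(
        defs,
        truth.grid_shape,
        spec.voxel_size_mm,
        lesion_mask=lesion_mask if lesion_mask.any() else None,
    )
    if rois.excluded:
        return SubjectResult(
            subject_id=subject_id,
            excluded=True,
            exclusion_reason="lesion overlaps ROI: " + ", ".join(rois.overlap_rois),
        )
    metrics = compute_metrics(fitted)
    return SubjectResult(
        subject_id=subject_id,
        excluded=False,
        exclusion_reason=None,
        alps={
            h: extract_axis_diffusivities(fitted, rois, h)
            for h in ("left", "right")
        },
        roi_metrics=extract_roi_metrics(metrics, rois),
    )


def _corr_row(name: str, res: StatResult) -> dict:
    return {"comparison": name, **res.to_dict()}


def run_cohort_statistics(
    cohort: pd.DataFrame,
    adjust: str = "bh",
) -> pd.DataFrame:
    """The full statistical plan on a cohort table.

    Group comparisons use Welch's t; sex uses Yates-corrected χ²; ALPS–FMA
    associations use Spearman (IS only); ALPS–CST associations use Pearson
    partial correlation controlling age and days post onset (IS only).
    Correlation-family p-values get a multiple-comparison adjustment column.
    """
    for col in ("group", "alps_left", "alps_right", "age", "sex"):
        if col not in cohort.columns:
            raise ValueError(f"cohort table lacks required column {col!r}")
    is_df = cohort[cohort["group"] == "IS"]
    hc_df = cohort[cohort["group"] == "HC"]
    rows: list[dict] = []

    for side in ("left", "right"):
        rows.append(
            _corr_row(
                f"alps_{side}_is_vs_hc",
                two_sample_t(is_df[f"alps_{side}"], hc_df[f"alps_{side}"]),
            )
        )
    for label, df_g in (("is", is_df), ("hc", hc_df)):
        try:
            rows.append(
                _corr_row(
                    f"alps_left_vs_right_{label}",
                    paired_t(df_g["alps_left"], df_g["alps_right"]),
                )
            )
        except ValueError as err:  # degenerate group: record, keep going
            rows.append(
                {"comparison": f"alps_left_vs_right_{label}", "error": str(err)}
            )
    rows.append(_corr_row("age_is_vs_hc", two_sample_t(is_df["age"], hc_df["age"])))
    sex_counts = [
        [(is_df["sex"] == "M").sum(), (is_df["sex"] == "F").sum()],
        [(hc_df["sex"] == "M").sum(), (hc_df["sex"] == "F").sum()],
    ]
    rows.append(_corr_row("sex_is_vs_hc", chi_square_2x2(sex_counts, yates=True)))

    corr_rows: list[dict] = []
    if len(is_df) >= 5 and is_df["fma_motor"].notna().all():
        for side in ("left", "right"):
            for score in ("fma_motor", "fma_sensory"):
                corr_rows.append(
                    _corr_row(
                        f"spearman_alps_{side}_{score}",
                        spearman(is_df[f"alps_{side}"], is_df[score]),
                    )
                )
        cov = (is_df["age"], is_df["days_post_onset"])
        for side in ("left", "right"):
            for metric in ("cst_fa_left", "cst_fa_right", "cst_md_left",
                           "cst_md_right"):
                corr_rows.append(
                    _corr_row(
                        f"partial_alps_{side}_{metric}",
                        pearson_partial(is_df[f"alps_{side}"], is_df[metric], cov),
                    )
                )
    if corr_rows:
        adj = adjust_pvalues([r["p_value"] for r in corr_rows], method=adjust)
        for r, a in zip(corr_rows, adj):
            r["p_adjusted"] = float(a)
    rows.extend(corr_rows)
    return pd.DataFrame(rows)


def run_image_cohort(
    n_is: int = 4,
    n_hc: int = 6,
    seed: int = 0,
    grid_shape: tuple[int, int, int] = (40, 40, 10),
    noise_sigma: float = 0.0,
    lesion_fraction_is: float = 0.25,
    params: Optional[CohortParams] = None,
    b_max: float = DEFAULT_B_MAX,
) -> RunReport:
    """Image-level cohort experiment at reduced n.

    Each subject gets a phantom whose per-hemisphere glymphatic coefficients
    are drawn from the group-level ALPS distributions (ground-truth ALPS of
    the phantom equals the coefficient when λ2 = λ3, so the drawn value IS
    the subject's target index). A fraction of IS subjects receive a lesion
    overlapping the left ROIs and are excluded, mirroring the recruited →
    analyzed + excluded accounting.
    """
    if params is None:
        params = default_params()
    rng = np.random.default_rng(seed)
    scheme = default_scheme()
    results: list[SubjectResult] = []
    groups: dict[str, str] = {}

    def draw_coeff(group: str, side: str) -> float:
        g = params.is_group if group == "IS" else params.hc_group
        val = rng.normal(g.means[f"alps_{side}"], g.sds[f"alps_{side}"])
        return float(np.clip(val, 0.3, 3.0))

    sid = 0
    for group, n in (("IS", n_is), ("HC", n_hc)):
        for i in range(n):
            sid += 1
            subject_id = f"{group}{i + 1:03d}"
            groups[subject_id] = group
            lesioned = group == "IS" and rng.random() < lesion_fraction_is
            spec = PhantomSpec(
                grid_shape=grid_shape,
                glymphatic_coefficient=(
                    draw_coeff(group, "left"),
                    draw_coeff(group, "right"),
                ),
                noise_sigma=noise_sigma,
                seed=int(rng.integers(0, 2**31 - 1)),
                lesion_center=(
                    (grid_shape[0] // 2 - 6, grid_shape[1] // 2, grid_shape[2] // 2)
                    if lesioned
                    else None
                ),
            )
            results.append(
                run_single_subject(spec, scheme, subject_id, b_max=b_max)
            )

    alps_rows = [row for r in results if not r.excluded for row in r.rows()]
    excl_rows = [
        {"subject_id": r.subject_id, "reason": r.exclusion_reason}
        for r in results
        if r.excluded
    ]
    alps_table = pd.DataFrame(alps_rows)
    if not alps_table.empty:
        alps_table.insert(1, "group", alps_table["subject_id"].map(groups))

    # table-level statistics on the analyzed subjects (wide per-subject form)
    stats_table = pd.DataFrame()
    if not alps_table.empty:
        wide = alps_table.pivot(
            index="subject_id", columns="hemisphere", values="alps_index"
        ).rename(columns={"left": "alps_left", "right": "alps_right"})
        wide["group"] = wide.index.map(groups)
        rows = []
        for side in ("left", "right"):
            a = wide.loc[wide["group"] == "IS", f"alps_{side}"]
            b = wide.loc[wide["group"] == "HC", f"alps_{side}"]
            if len(a) >= 2 and len(b) >= 2:
                rows.append(
                    _corr_row(f"alps_{side}_is_vs_hc", two_sample_t(a, b))
                )
        stats_table = pd.DataFrame(rows)

    n_excluded = len(excl_rows)
    return RunReport(
        alps_table=alps_table,
        exclusions=pd.DataFrame(excl_rows, columns=["subject_id", "reason"]),
        stats_table=stats_table,
        seed=seed,
        n_recruited=n_is + n_hc,
        n_analyzed=n_is + n_hc - n_excluded,
        n_excluded=n_excluded,
        config_echo={
            "n_is": n_is,
            "n_hc": n_hc,
            "grid_shape": list(grid_shape),
            "noise_sigma": noise_sigma,
            "b_max": b_max,
        },
    )
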