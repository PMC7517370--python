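"""Cohort orchestration: per-subject analysis, stage comparison, CSV output.

For each subject the paired third-trimester (TT) and parturition (P)
recordings are reduced to four tables: Phase Entropy across the k grid,
multiscale SampEn across scales, per-k surrogate-test decisions, and PhEn
of the time-reversed series.  Stage comparison then runs, per k (or scale):

* a paired two-sided location test on PhEn / SampEn (Student t when the
  paired differences pass a Shapiro normality check, Wilcoxon signed-rank
  otherwise), Bonferroni-corrected over the grid;
* a 2x2 chi-squared test (no continuity correction) on the counts of
  nonlinear vs linear decisions by stage;
* a Wilcoxon signed-rank test of original vs time-reversed PhEn within
  each stage (the time-irreversibility comparison).

The comparison stage consumes only the per-subject tables, never the
signal files, so the two stages are independently testable.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DegenerateSignalError, ParameterError
from .multiscale import MSECurve, mse_curve
from .phase_entropy import PhEnCurve, default_k_grid, phen_curve
from .preprocess import Signal
from .surrogate import nonlinearity_tests, time_reverse

logger = logging.getLogger(__name__)

__all__ = [
    "AnalysisParams",
    "SubjectRecord",
    "CohortResult",
    "analyze_subject",
    "run_cohort",
    "compare_stages",
    "compare_tables",
    "write_results",
    "export_sodp",
]

STAGES = ("TT", "P")


@dataclass(frozen=True)
class AnalysisParams:
    """Analysis settings shared by every subject of a run.

    ``n_surrogates = 0`` skips the surrogate testing step (the nonlinearity
    table is then empty); the published protocol uses 200 surrogates.
    """

    k_grid: tuple[int, ...] = field(default_factory=default_k_grid)
    tau_max: int = 21
    m: int = 2
    r_factor: float = 0.15
    n_surrogates: int = 200
    max_iter: int = 100
    alpha: float = 0.05
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.tau_max < 1:
            raise ParameterError("tau_max must be >= 1")
        if not 0 < self.alpha < 1:
            raise ParameterError("alpha must be in (0, 1)")
        if self.n_surrogates < 0:
            raise ParameterError("n_surrogates must be >= 0")


@dataclass
class SubjectRecord:
    """All per-subject, per-stage curves and decisions."""

    subject_id: str
    phen: dict[str, PhEnCurve]
    mse: dict[str, MSECurve]
    nonlinear: dict[str, dict[int, bool]]
    phen_reversed: dict[str, PhEnCurve]
    excluded: bool = False
    exclusion_reason: str = ""


@dataclass
class CohortResult:
    """Tidy tables for the whole cohort plus the per-k/per-scale statistics."""

    phen_table: pd.DataFrame
    mse_table: pd.DataFrame
    nonlinearity_table: pd.DataFrame
    reversal_table: pd.DataFrame
    stats: pd.DataFrame
    alpha: float
    n_subjects: int


def analyze_subject(
    tt: Signal,
    p: Signal,
    params: AnalysisParams,
    seed: int | np.random.SeedSequence | None = None,
) -> SubjectRecord:
    """Run the full single-subject analysis on a paired (TT, P) recording.

    A degenerate signal flags the record as excluded instead of raising, so
    one bad recording cannot abort a cohort run.
    """
    subject_id = tt.subject_id or p.subject_id
    if seed is None:
        seed = params.seed
    master = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    stage_seeds = dict(zip(STAGES, master.spawn(2)))
    record = SubjectRecord(
        subject_id=subject_id, phen={}, mse={}, nonlinear={}, phen_reversed={}
    )
    try:
        for stage, sig in (("TT", tt), ("P", p)):
            sig = sig.replace(stage=stage, subject_id=subject_id)
            record.phen[stage] = phen_curve(sig, params.k_grid)
            record.mse[stage] = mse_curve(
                sig, tau_max=params.tau_max, m=params.m, r_factor=params.r_factor
            )
            record.phen_reversed[stage] = phen_curve(time_reverse(sig), params.k_grid)
            if params.n_surrogates:
                tests = nonlinearity_tests(
                    sig,
                    params.k_grid,
                    n_surrogates=params.n_surrogates,
                    seed=stage_seeds[stage],
                    max_iter=params.max_iter,
                )
                record.nonlinear[stage] = {k: t.nonlinear for k, t in tests.items()}
            else:
                record.nonlinear[stage] = {}
    except DegenerateSignalError as exc:
        record.excluded = True
        record.exclusion_reason = str(exc)
        logger.warning("subject %s excluded: %s", subject_id, exc)
    return record


def run_cohort(
    pairs: list[tuple[Signal, Signal]], params: AnalysisParams
) -> list[SubjectRecord]:
    """Analyze every (TT, P) pair with independent per-subject sub-seeds."""
    master = np.random.SeedSequence(params.seed)
    children = master.spawn(len(pairs))
    return [
        analyze_subject(tt, p, params, seed=child)
        for (tt, p), child in zip(pairs, children)
    ]


# ---------------------------------------------------------------------------
# table construction


def _records_to_tables(
    records: list[SubjectRecord],
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    phen_rows, mse_rows, nl_rows, rev_rows = [], [], [], []
    for rec in records:
        if rec.excluded:
            continue
        for stage in STAGES:
            curve = rec.phen[stage]
            for k, v in zip(curve.k_values, curve.phen):
                phen_rows.append(
                    dict(
                        subject_id=rec.subject_id,
                        stage=stage,
                        k=k,
                        phen=v,
                        n_points=curve.n_points,
                        n_excluded=curve.n_excluded,
                    )
                )
            mse = rec.mse[stage]
            for tau, v in zip(mse.scales, mse.sampen):
                mse_rows.append(
                    dict(
                        subject_id=rec.subject_id,
                        stage=stage,
                        tau=tau,
                        sampen=v,
                        defined=bool(np.isfinite(v)),
                    )
                )
            for k, nl in rec.nonlinear[stage].items():
                nl_rows.append(
                    dict(subject_id=rec.subject_id, stage=stage, k=k, nonlinear=bool(nl))
                )
            rcurve = rec.phen_reversed[stage]
            for k, orig, revv in zip(curve.k_values, curve.phen, rcurve.phen):
                rev_rows.append(
                    dict(
                        subject_id=rec.subject_id,
                        stage=stage,
                        k=k,
                        phen_original=orig,
                        phen_reversed=revv,
                    )
                )
    return (
        pd.DataFrame(phen_rows),
        pd.DataFrame(mse_rows),
        pd.DataFrame(nl_rows),
        pd.DataFrame(rev_rows),
    )


# ---------------------------------------------------------------------------
# statistics


def _paired_test(tt: np.ndarray, p: np.ndarray) -> tuple[float, str, bool]:
    """Two-sided paired test; returns (p-value, test name, degenerate flag)."""
    diff = p - tt
    if np.allclose(diff, 0.0):
        return float("nan"), "degenerate", True
    # Shapiro on the paired differences decides t-test vs signed-rank;
    # below 3 pairs normality is untestable, fall back to the rank test
    normal = False
    if diff.size >= 3:
        try:
            normal = stats.shapiro(diff).pvalue > 0.05
        except ValueError:
            pass
    if normal:
        return float(stats.ttest_rel(p, tt).pvalue), "paired-t", False
    return (
        float(stats.wilcoxon(p, tt, zero_method="wilcox").pvalue),
        "wilcoxon",
        False,
    )


def _chi2_2x2(nl_tt: int, lin_tt: int, nl_p: int, lin_p: int) -> tuple[float, float]:
    table = np.array([[nl_tt, lin_tt], [nl_p, lin_p]])
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return 0.0, 1.0  # a margin is empty: proportions carry no contrast
    if (stats.contingency.expected_freq(table) < 5).any():
        logger.warning("chi-squared expected count < 5; result is approximate")
    res = stats.chi2_contingency(table, correction=False)
    return float(res.statistic), float(res.pvalue)


def _wilcoxon_safe(a: np.ndarray, b: np.ndarray) -> float:
    if np.allclose(a, b):
        return float("nan")
    return float(stats.wilcoxon(a, b, zero_method="wilcox").pvalue)


def compare_tables(
    phen_table: pd.DataFrame,
    mse_table: pd.DataFrame,
    nonlinearity_table: pd.DataFrame,
    reversal_table: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-k / per-scale statistics from the tidy cohort tables.

    Returns one row per (comparison, grid point) with raw and
    Bonferroni-adjusted p-values; ``p_adj = min(1, p * n_grid)``.
    """
    rows = []

    def _paired_block(table, value_col, grid_col, comparison):
        grid = sorted(table[grid_col].unique())
        wide = table.pivot_table(
            index="subject_id", columns=["stage", grid_col], values=value_col
        )
        for g in grid:
            try:
                tt = wide[("TT", g)]
                p = wide[("P", g)]
            except KeyError:
                continue
            ok = tt.notna() & p.notna()
            pval, test, degenerate = _paired_test(tt[ok].values, p[ok].values)
            rows.append(
                dict(
                    comparison=comparison,
                    grid=g,
                    statistic_test=test,
                    p_raw=pval,
                    p_adj=min(1.0, pval * len(grid)) if np.isfinite(pval) else float("nan"),
                    n=int(ok.sum()),
                    degenerate=degenerate,
                )
            )

    if len(phen_table):
        _paired_block(phen_table, "phen", "k", "phen_TT_vs_P")
    if len(mse_table):
        _paired_block(mse_table, "sampen", "tau", "mse_TT_vs_P")

    if len(nonlinearity_table):
        for k in sorted(nonlinearity_table["k"].unique()):
            sub = nonlinearity_table[nonlinearity_table["k"] == k]
            counts = {}
            for stage in STAGES:
                s = sub[sub["stage"] == stage]["nonlinear"]
                counts[stage] = (int(s.sum()), int((~s).sum()))
            statistic, pval = _chi2_2x2(*counts["TT"], *counts["P"])
            rows.append(
                dict(
                    comparison="nonlinear_proportion",
                    grid=k,
                    statistic_test="chi2",
                    p_raw=pval,
                    p_adj=pval,  # reported per k, uncorrected
                    n=int(len(sub)),
                    degenerate=bool(np.isnan(pval)),
                )
            )

    if len(reversal_table):
        for stage in STAGES:
            sub = reversal_table[reversal_table["stage"] == stage]
            for k in sorted(sub["k"].unique()):
                at_k = sub[sub["k"] == k]
                pval = _wilcoxon_safe(
                    at_k["phen_original"].values, at_k["phen_reversed"].values
                )
                rows.append(
                    dict(
                        comparison=f"reversal_{stage}",
                        grid=k,
                        statistic_test="wilcoxon",
                        p_raw=pval,
                        p_adj=pval,  # reported per k, uncorrected
                        n=int(len(at_k)),
                        degenerate=not np.isfinite(pval),
                    )
                )

    stats_df = pd.DataFrame(rows)
    if len(stats_df):
        stats_df["significant"] = stats_df["p_adj"] < alpha
    return stats_df


def compare_stages(
    records: list[SubjectRecord], alpha: float = 0.05
) -> CohortResult:
    """Cohort-level comparison of the TT and P stages.

    Excluded subjects are dropped (with their logged reason); at least two
    complete subjects are required.
    """
    complete = [r for r in records if not r.excluded]
    if len(complete) < 2:
        raise ParameterError(
            f"need at least 2 complete subjects, got {len(complete)}"
        )
    phen_t, mse_t, nl_t, rev_t = _records_to_tables(complete)
    stats_df = compare_tables(phen_t, mse_t, nl_t, rev_t, alpha=alpha)
    return CohortResult(
        phen_table=phen_t,
        mse_table=mse_t,
        nonlinearity_table=nl_t,
        reversal_table=rev_t,
        stats=stats_df,
        alpha=alpha,
        n_subjects=len(complete),
    )


def export_sodp(signal: Signal, k: int, path: str | Path) -> pd.DataFrame:
    """Write the SODP point cloud (x, y, theta, sector) as CSV for plotting.

    Sector indices are 1-based, matching the counterclockwise sector
    numbering of the profile.
    """
    from .phase_entropy import build_sodp, sector_profile

    sodp = build_sodp(signal)
    sector_profile(sodp, k)  # validates k
    sector = np.minimum(
        np.floor(sodp.theta * (k / (2 * np.pi))).astype(int), k - 1
    ) + 1
    table = pd.DataFrame(
        {"x": sodp.x, "y": sodp.y, "theta": sodp.theta, "sector": sector}
    )
    table.to_csv(path, index=False)
    return table


def write_results(
    result: CohortResult,
    outdir: str | Path,
    params: AnalysisParams | None = None,
) -> None:
    """Write phen/mse/nonlinearity/reversal/stats CSVs and a run manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result.phen_table.to_csv(outdir / "phen.csv", index=False)
    result.mse_table.to_csv(outdir / "mse.csv", index=False)
    result.nonlinearity_table.to_csv(outdir / "nonlinearity.csv", index=False)
    result.reversal_table.to_csv(outdir / "reversal.csv", index=False)
    result.stats.to_csv(outdir / "stats.csv", index=False)
    manifest = {
        "n_subjects": result.n_subjects,
        "alpha": result.alpha,
        "params": dataclasses.asdict(params) if params is not None else None,
    }
    from . import __version__

    manifest["version"] = __version__
    with (outdir / "manifest.json").open("w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
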