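"""Study-level statistics for electrode-reduction results.

Operates on a *study table*: one row per subject with accuracy (%) and ITR
(bits/min) per condition, where a missing entry means the closed-loop system
was non-functional for that participant in that round.  The package ships a
transcription of the 38-participant results table of the online study it
models (``packaged_study_table``); the same functions apply to tables
produced by :func:`cvepsim.study.run_three_condition_study`.

Implemented here: per-condition summaries, functionality counts and
transitions, the McNemar chi-square for paired binary outcomes (uncorrected
by default; a continuity-corrected variant is available), Cochran's Q across
the three conditions, paired Cohen's d with a seeded percentile-bootstrap CI,
and Pearson / point-biserial correlations.  Distributional checks
(Shapiro-Wilk) and mixed-effects modelling are deliberately delegated to
scipy/statsmodels when a user wants them; they are not re-implemented.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "CONDITION_COLUMNS",
    "load_study_table",
    "packaged_study_table",
    "long_to_wide",
    "condition_summary",
    "functionality_matrix",
    "functionality_and_transitions",
    "mcnemar_chi2",
    "cochran_q",
    "cohen_d_paired",
    "bootstrap_ci",
    "pearson_r",
    "point_biserial_r",
    "reproduce_report",
]

#: Wide-table column suffixes per condition, in protocol order.
CONDITION_COLUMNS = ("baseline", "noretrain", "retrained")


def load_study_table(path: str | Path) -> pd.DataFrame:
    """Read a subject x condition results CSV.

    Expected columns: ``subject`` plus ``acc_<cond>`` and ``itr_<cond>`` for
    the three conditions; dashes or empty cells mark missing (non-functional)
    rounds.  Raises a ValueError naming the offending line for malformed rows.
    """
    df = pd.read_csv(path, dtype=str).apply(lambda s: s.str.strip())
    expected = {"subject"} | {
        f"{kind}_{cond}" for kind in ("acc", "itr") for cond in CONDITION_COLUMNS
    }
    missing = expected - set(df.columns)
    if missing:
        raise ValueError(f"study table misses columns {sorted(missing)}")
    out = pd.DataFrame({"subject": pd.to_numeric(df["subject"], errors="raise")})
    for col in sorted(expected - {"subject"}):
        vals = df[col].replace({"-": None, "": None})
        try:
            out[col] = pd.to_numeric(vals)
        except (ValueError, TypeError) as exc:
            bad = vals[pd.to_numeric(vals, errors="coerce").isna() & vals.notna()]
            line = int(bad.index[0]) + 2  # header + 1-based
            raise ValueError(f"malformed value {bad.iloc[0]!r} in column "
                             f"{col} at line {line}") from exc
    for cond in CONDITION_COLUMNS:
        if (out[f"acc_{cond}"].isna() != out[f"itr_{cond}"].isna()).any():
            raise ValueError(f"inconsistent missingness in condition {cond}")
    return out


def packaged_study_table() -> pd.DataFrame:
    """The packaged 38-subject results table (accuracy % and ITR bits/min)."""
    with resources.as_file(
        resources.files("cvepsim.data").joinpath("electrode_reduction_study.csv")
    ) as p:
        return load_study_table(p)


def long_to_wide(table: pd.DataFrame) -> pd.DataFrame:
    """Convert a simulated long study table to the wide fixture layout."""
    mapping = dict(zip(("baseline16", "reduced6_noretrain", "reduced6_retrained"),
                       CONDITION_COLUMNS))
    wide = pd.DataFrame({"subject": sorted(table["subject"].unique())})
    wide = wide.set_index("subject")
    for long_name, cond in mapping.items():
        sub = table[table["condition"] == long_name].set_index("subject")
        wide[f"acc_{cond}"] = sub["accuracy"]
        wide[f"itr_{cond}"] = sub["itr"]
    return wide.reset_index()


def condition_summary(table: pd.DataFrame, condition: str, measure: str
                      ) -> tuple[float, float]:
    """Mean and sample SD of ``measure`` (``acc`` or ``itr``) over present values."""
    if condition not in CONDITION_COLUMNS:
        raise ValueError(f"condition must be one of {CONDITION_COLUMNS}")
    if measure not in ("acc", "itr"):
        raise ValueError("measure must be 'acc' or 'itr'")
    vals = table[f"{measure}_{condition}"].dropna().to_numpy(dtype=float)
    if len(vals) < 2:
        raise ValueError(f"need >= 2 present values in {measure}_{condition}")
    return float(vals.mean()), float(vals.std(ddof=1))


def functionality_matrix(table: pd.DataFrame) -> np.ndarray:
    """Binary subject x condition matrix (1 = functional, from missingness)."""
    return np.column_stack(
        [table[f"acc_{c}"].notna().to_numpy(dtype=int) for c in CONDITION_COLUMNS]
    )


def functionality_and_transitions(table: pd.DataFrame) -> dict:
    """Functionality counts, no-retrain -> retrained transitions, failure rates."""
    f = functionality_matrix(table)
    n = f.shape[0]
    base, nore, retr = f.T
    counts = {c: int(f[:, j].sum()) for j, c in enumerate(CONDITION_COLUMNS)}
    return {
        "n_subjects": n,
        "functional": counts,
        "regained": int(((nore == 0) & (retr == 1)).sum()),
        "lost": int(((nore == 1) & (retr == 0)).sum()),
        "remained_failed": int(((nore == 0) & (retr == 0)).sum()),
        "failure_rate_pct": {
            c: 100.0 * (n - counts[c]) / n for c in CONDITION_COLUMNS
        },
    }


def mcnemar_chi2(b: int, c: int, corrected: bool = False) -> float:
    """McNemar chi-square from the two discordant-pair counts.

    Uncorrected ``(b - c)^2 / (b + c)`` by default; ``corrected=True`` applies
    the continuity correction ``(|b - c| - 1)^2 / (b + c)``.
    """
    if b < 0 or c < 0:
        raise ValueError("discordant counts must be nonnegative")
    if b + c == 0:
        raise ValueError("McNemar statistic undefined for b = c = 0")
    if corrected:
        return (abs(b - c) - 1) ** 2 / (b + c)
    return (b - c) ** 2 / (b + c)


def discordant_counts(binary: np.ndarray, i: int, j: int) -> tuple[int, int]:
    """Discordant pair counts (b, c) between two columns of a binary matrix."""
    x, y = np.asarray(binary)[:, i], np.asarray(binary)[:, j]
    return int(((x == 1) & (y == 0)).sum()), int(((x == 0) & (y == 1)).sum())


def cochran_q(binary: np.ndarray) -> tuple[float, int]:
    """Cochran's Q statistic and degrees of freedom for a subject x condition
    binary matrix.

    ``Q = (k - 1) * (k * sum(C_j^2) - T^2) / (k * T - sum(R_i^2))`` with
    column sums ``C_j``, row sums ``R_i`` and grand total ``T``; df = k - 1.
    """
    m = np.asarray(binary, dtype=float)
    if m.ndim != 2 or m.shape[1] < 2 or m.shape[0] < 1:
        raise ValueError("need a subjects x conditions matrix with >= 2 conditions")
    if not np.isin(m, (0.0, 1.0)).all():
        raise ValueError("matrix entries must be binary")
    k = m.shape[1]
    col = m.sum(axis=0)
    row = m.sum(axis=1)
    total = m.sum()
    denom = k * total - np.sum(row**2)
    if denom <= 0:
        raise ValueError("degenerate matrix: all rows constant")
    q = (k - 1) * (k * np.sum(col**2) - total**2) / denom
    return float(q), k - 1


def cohen_d_paired(x: np.ndarray, y: np.ndarray) -> float:
    """Paired Cohen's d: mean of differences over their sample SD."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("need paired 1-D vectors of equal length >= 3")
    diff = x - y
    sd = diff.std(ddof=1)
    if sd == 0:
        if np.allclose(diff, 0):
            return 0.0
        raise ValueError("zero-variance differences with nonzero mean")
    return float(diff.mean() / sd)


def bootstrap_ci(
    x: np.ndarray,
    y: np.ndarray,
    statistic=cohen_d_paired,
    n_resamples: int = 10_000,
    level: float = 0.95,
    seed: int | None = 0,
) -> tuple[float, float]:
    """Seeded percentile-bootstrap CI for a paired statistic (pairs resampled)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    rng = np.random.default_rng(seed)
    n = len(x)
    reps = np.empty(n_resamples)
    for i in range(n_resamples):
        idx = rng.integers(0, n, n)
        try:
            reps[i] = statistic(x[idx], y[idx])
        except ValueError:
            reps[i] = np.nan
    lo, hi = np.nanpercentile(reps, [100 * (1 - level) / 2, 100 * (1 + level) / 2])
    return float(lo), float(hi)


def pearson_r(x, y) -> tuple[float, float]:
    """Pearson correlation and two-sided p-value."""
    r = sps.pearsonr(np.asarray(x, float), np.asarray(y, float))
    return float(r.statistic), float(r.pvalue)


def point_biserial_r(binary, y) -> tuple[float, float]:
    """Point-biserial correlation (Pearson with 0/1 coding) and p-value."""
    b = np.asarray(binary, dtype=float)
    if not np.isin(b, (0.0, 1.0)).all():
        raise ValueError("first argument must be 0/1 coded")
    r = sps.pointbiserialr(b, np.asarray(y, float))
    return float(r.correlation), float(r.pvalue)


def reproduce_report(table: pd.DataFrame | None = None) -> dict:
    """All recomputable study-table statistics in one JSON-ready dict.

    Uses the packaged 38-subject table when none is given: per-condition mean
    and SD of accuracy and ITR, functionality counts and transitions, failure
    rates, Cochran's Q over the functionality matrix, and the McNemar
    chi-squares for the three pairwise functionality contrasts.
    """
    if table is None:
        table = packaged_study_table()
    f = functionality_matrix(table)
    trans = functionality_and_transitions(table)
    report: dict = {
        "n_subjects": trans["n_subjects"],
        "summary": {},
        "functional": trans["functional"],
        "regained": trans["regained"],
        "lost": trans["lost"],
        "remained_failed": trans["remained_failed"],
        "failure_rate_pct": trans["failure_rate_pct"],
    }
    for cond in CONDITION_COLUMNS:
        for measure in ("acc", "itr"):
            mean, sd = condition_summary(table, cond, measure)
            report["summary"][f"{measure}_{cond}"] = {"mean": mean, "sd": sd}
    q, df = cochran_q(f)
    report["cochran_q"] = {"Q": q, "df": df}
    report["mcnemar"] = {}
    pairs = {(0, 1): "baseline_vs_noretrain", (0, 2): "baseline_vs_retrained",
             (1, 2): "noretrain_vs_retrained"}
    for (i, j), name in pairs.items():
        b, c = discordant_counts(f, i, j)
        report["mcnemar"][name] = {"b": b, "c": c,
                                   "chi2": mcnemar_chi2(b, c)}
    return report
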