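"""Agreement and validity statistics for paired volume measurements.

Mirrors the evaluation a plaque-volumetry study runs on rater tables:
intraclass correlation for inter-/intra-rater reproducibility,
Bland–Altman bias with 95% limits of agreement, and Spearman rank
correlation for validity against a reference method.

The ICC form is ICC(2,1): two-way random effects, absolute agreement,
single measurement — the standard choice for test–retest and
inter-rater reliability of single readings. Alternative forms can be
requested through ``form``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import ContractError, DataError

__all__ = [
    "AgreementReport",
    "load_rater_table",
    "validate_rater_table",
    "paired_volumes",
    "icc",
    "bland_altman",
    "spearman",
    "agreement_report",
]

TABLE_COLUMNS = ("lesion_id", "rater", "session", "volume_mm3")


@dataclass(frozen=True)
class AgreementReport:
    """One pairing's agreement summary (ICC, Bland–Altman, Spearman)."""

    icc_value: float
    icc_ci_low: float
    icc_ci_high: float
    bias: float
    loa_low: float
    loa_high: float
    spearman_rho: float
    n: int
    mode: str = "absolute"
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not (self.loa_low <= self.bias <= self.loa_high):
            raise ContractError("limits of agreement must bracket the bias")
        # CI bounds come back at 2-decimal printed precision; allow that slack
        if np.isfinite(self.icc_ci_low) and not (
            self.icc_ci_low - 5.1e-3 <= self.icc_value <= self.icc_ci_high + 5.1e-3
        ):
            raise ContractError("ICC value must lie within its confidence interval")
        if not -1.0 <= self.spearman_rho <= 1.0:
            raise ContractError("Spearman rho must be in [-1, 1]")

    def to_dict(self) -> dict:
        return asdict(self)


def validate_rater_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check the (lesion_id, rater, session, volume_mm3) schema and invariants."""
    missing = [c for c in TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise DataError(f"rater table is missing columns: {missing}")
    tab = table.loc[:, list(TABLE_COLUMNS)].copy()
    tab["volume_mm3"] = pd.to_numeric(tab["volume_mm3"], errors="raise")
    if (tab["volume_mm3"] < 0).any() or not np.isfinite(tab["volume_mm3"]).all():
        raise DataError("volumes must be finite and non-negative")
    if tab.duplicated(subset=["lesion_id", "rater", "session"]).any():
        raise DataError("each (lesion, rater, session) may appear at most once")
    if tab["lesion_id"].nunique() < 3:
        raise DataError("at least 3 lesions are required for any statistic")
    return tab


def load_rater_table(path) -> pd.DataFrame:
    """Read a CSV with header (lesion_id, rater, session, volume_mm3)."""
    try:
        table = pd.read_csv(path)
    except (pd.errors.EmptyDataError, pd.errors.ParserError, UnicodeDecodeError) as exc:
        raise DataError(f"{path}: not a readable CSV table: {exc}") from exc
    return validate_rater_table(table)


def paired_volumes(
    table: pd.DataFrame, pair: Tuple[str, str], by: str = "rater"
) -> pd.DataFrame:
    """Pivot the long table into two aligned measurement columns.

    ``by`` selects whether the pair names raters (inter-rater) or
    sessions (intra-rater); the other factor must be constant or is
    averaged out by requiring a unique cell per lesion.
    """
    if by not in ("rater", "session"):
        raise ContractError("by must be 'rater' or 'session'")
    tab = validate_rater_table(table)
    sub = tab[tab[by].astype(str).isin([str(p) for p in pair])]
    wide = sub.pivot_table(
        index="lesion_id", columns=by, values="volume_mm3", aggfunc="first"
    )
    wide.columns = wide.columns.astype(str)
    want = [str(p) for p in pair]
    missing = [p for p in want if p not in wide.columns]
    if missing:
        raise DataError(f"no measurements found for {by}(s): {missing}")
    wide = wide.loc[:, want]
    if wide.isna().any().any():
        raise DataError("incomplete design: some lesions lack one of the paired measurements")
    return wide


def _icc_mean_squares(values: np.ndarray) -> Tuple[float, float, float, float]:
    """(MSR, MSC, MSE, grand mean) for an n x k two-way layout."""
    n, k = values.shape
    mean = values.mean()
    row_means = values.mean(axis=1)
    col_means = values.mean(axis=0)
    ssr = k * np.sum((row_means - mean) ** 2)
    ssc = n * np.sum((col_means - mean) ** 2)
    sst = np.sum((values - mean) ** 2)
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    return msr, msc, mse, mean


def icc(
    wide: pd.DataFrame, form: str = "ICC2", ci: float = 0.95
) -> Tuple[float, Tuple[float, float]]:
    """ICC with an F-based confidence interval on a complete wide table.

    ``wide`` has one row per lesion and one column per rater (or
    session). Degenerate tables with zero total variance return
    ``(1.0, (1.0, 1.0))`` with a warning — there is no disagreement to
    measure.
    """
    values = np.asarray(wide, dtype=float)
    if values.ndim != 2 or values.shape[1] < 2:
        raise ContractError("ICC needs a complete n x k table with k >= 2 columns")
    if values.shape[0] < 3:
        raise ContractError("ICC needs at least 3 lesions")
    if np.isnan(values).any():
        raise ContractError("ICC table must be complete (no missing cells)")

    if np.ptp(values) == 0:
        warnings.warn("zero total variance: ICC is degenerate, reporting 1.0")
        return 1.0, (1.0, 1.0)

    msr, msc, mse, _ = _icc_mean_squares(values)
    if mse == 0 and msc == 0:
        # perfect absolute agreement between columns
        warnings.warn("zero residual variance: ICC is degenerate, reporting 1.0")
        return 1.0, (1.0, 1.0)

    import pingouin as pg  # deferred: pingouin import is slow

    n, k = values.shape
    long = pd.DataFrame(
        {
            "target": np.repeat(np.arange(n), k),
            "judge": np.tile(np.arange(k), n),
            "score": values.ravel(),
        }
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = pg.intraclass_corr(
            data=long, targets="target", raters="judge", ratings="score"
        ).set_index("Type")
    # pingouin labels the forms per Shrout–Fleiss ("ICC2") in some releases and
    # per McGraw–Wong ("ICC(A,1)") in others; accept both spellings.
    aliases = {
        "ICC1": ["ICC1", "ICC(1,1)"],
        "ICC2": ["ICC2", "ICC(A,1)"],
        "ICC3": ["ICC3", "ICC(C,1)"],
        "ICC1k": ["ICC1k", "ICC(1,k)"],
        "ICC2k": ["ICC2k", "ICC(A,k)"],
        "ICC3k": ["ICC3k", "ICC(C,k)"],
    }
    row = None
    for label in aliases.get(form, [form]):
        if label in res.index:
            row = res.loc[label]
            break
    if row is None:
        raise ContractError(f"unknown ICC form {form!r}; available: {list(res.index)}")
    value = float(row["ICC"])
    ci_col = "CI95%" if "CI95%" in res.columns else "CI95"
    lo, hi = (float(x) for x in row[ci_col])
    if not np.isfinite(lo):
        lo = -1.0
    if not np.isfinite(hi):
        hi = 1.0
    return value, (lo, hi)


def bland_altman(
    a: Sequence[float], b: Sequence[float], mode: str = "absolute"
) -> Tuple[float, float, float]:
    """Bland–Altman bias and 95% limits of agreement.

    ``absolute`` works on differences ``a - b`` (same units as the
    measurements); ``percent`` on ``100 * (a - b) / pairmean``. The
    limits use the sample (n-1) standard deviation and the 1.96
    multiplier: ``bias +/- 1.96 * sd``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ContractError("series must be 1D and of equal length")
    if a.size < 3:
        raise ContractError("at least 3 pairs are required")
    if mode == "absolute":
        d = a - b
    elif mode == "percent":
        pairmean = (a + b) / 2.0
        if np.any(pairmean == 0):
            raise ContractError("percent mode undefined when a pair mean is zero")
        d = 100.0 * (a - b) / pairmean
    else:
        raise ContractError(f"unknown Bland–Altman mode {mode!r}")
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return bias, bias - 1.96 * sd, bias + 1.96 * sd


def spearman(a: Sequence[float], b: Sequence[float]) -> float:
    """Spearman rank correlation (Pearson on mid-ranks; ties averaged)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ContractError("series must be 1D and of equal length")
    if a.size < 3:
        raise ContractError("at least 3 pairs are required")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise DataError("Spearman correlation is undefined for a constant series")
    rho = sps.spearmanr(a, b).statistic
    return float(rho)


def agreement_report(
    table: pd.DataFrame,
    pair: Tuple[str, str],
    by: str = "rater",
    mode: str = "absolute",
    form: str = "ICC2",
) -> AgreementReport:
    """Full agreement summary for one measurement pairing."""
    wide = paired_volumes(table, pair, by=by)
    a = wide.iloc[:, 0].to_numpy()
    b = wide.iloc[:, 1].to_numpy()
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        value, (lo, hi) = icc(wide, form=form)
        degenerate = any("degenerate" in str(w.message) for w in caught)
    bias, loa_lo, loa_hi = bland_altman(a, b, mode=mode)
    rho = spearman(a, b)
    return AgreementReport(
        icc_value=value,
        icc_ci_low=lo,
        icc_ci_high=hi,
        bias=bias,
        loa_low=loa_lo,
        loa_high=loa_hi,
        spearman_rho=rho,
        n=len(a),
        mode=mode,
        degenerate=degenerate,
    )
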