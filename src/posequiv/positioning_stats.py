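"""Per-direction positioning differences and TOST equivalence testing.

The scientific question: does positioning against a synthetic CT give
the same couch correction as positioning against the CT?  For each case
(and observer) the difference sCT-based minus CT-based result is taken
per direction — translations along R-L, P-A, I-S and rotations pitch,
yaw, roll — keeping sign.  Summaries report mean ± SD and the observed
range.  Equivalence is assessed with the paired two one-sided t-tests
(TOST) procedure on an equivalence interval of (-1, +1) mm: the null
hypothesis of a difference at least 1 mm in magnitude is rejected when
both one-sided tests are significant.

The headline test pools the three translation axes per modality (one 3D
and one 2D test); per-direction TOSTs are reported as diagnostics.
Rotations are summarized but not equivalence-tested.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import DIRECTIONS, TRANSLATION_DIRECTIONS
from .errors import ValidationError
from .geometry import PairedRegResult

DIFF_COLUMNS = ("case", "observer", "modality", "direction", "difference")


@dataclass
class TostResult:
    """Paired TOST outcome on one sample of differences.

    ``p_overall = max(p_lower, p_upper)``; equivalence is declared when
    both one-sided p-values (hence p_overall) fall below alpha.  The
    90% CI corresponds to the alpha = 0.05 TOST by the usual duality;
    the 95% CI is reported alongside.
    """

    n: int
    mean: float
    sd: float
    t_lower: float
    t_upper: float
    p_lower: float
    p_upper: float
    p_overall: float
    equivalent: bool
    bounds: tuple[float, float]
    ci90: tuple[float, float]
    ci95: tuple[float, float]


def dof_differences(results: Iterable[PairedRegResult]) -> pd.DataFrame:
    """Long-format table of per-direction differences, sCT minus CT.

    For 2D orthogonal-projection rows the roll difference is recorded as
    NaN: roll is not an available degree of freedom there.
    """
    rows = []
    for r in results:
        if r.ct is None or r.sct is None:
            raise ValidationError(f"case {r.case}: missing member of the pair")
        diff = r.sct.as_array() - r.ct.as_array()
        for k, direction in enumerate(DIRECTIONS):
            value = diff[k]
            if direction == "roll" and r.modality == "2D-orth":
                value = np.nan
            rows.append((r.case, r.observer, r.modality, direction, value))
    if not rows:
        raise ValidationError("no paired registration results provided")
    df = pd.DataFrame(rows, columns=DIFF_COLUMNS)
    finite = df["difference"].dropna()
    if not np.isfinite(finite).all():
        raise ValidationError("non-finite difference values")
    return df


def summarize_differences(table: pd.DataFrame) -> pd.DataFrame:
    """Per-modality, per-direction mean, SD (n-1), min and max.

    Directions with no observations (e.g. roll in 2D) are omitted with
    a warning; a single observation yields mean only with SD NaN.
    """
    out = []
    for (modality, direction), grp in table.groupby(
        ["modality", "direction"], sort=False
    ):
        vals = grp["difference"].dropna().to_numpy()
        if vals.size == 0:
            warnings.warn(
                f"direction {direction!r} has no observations for "
                f"{modality!r}; omitted from summary"
            )
            continue
        if vals.size == 1:
            warnings.warn(
                f"direction {direction!r} ({modality!r}): single value, SD undefined"
            )
        out.append(
            {
                "modality": modality,
                "direction": direction,
                "n": vals.size,
                "mean": float(vals.mean()),
                "sd": float(vals.std(ddof=1)) if vals.size > 1 else np.nan,
                "min": float(vals.min()),
                "max": float(vals.max()),
            }
        )
    return pd.DataFrame(out)


def tost_paired(
    diffs: Sequence[float],
    low: float = -1.0,
    high: float = 1.0,
    alpha: float = 0.05,
) -> TostResult:
    """Paired TOST on a sample of within-pair differences.

    Tests H0: mean <= low OR mean >= high against H1: low < mean < high
    with two one-sided t-tests at level ``alpha`` each:
    ``t_lower = (mean - low) / (sd/sqrt(n))`` with p from the upper tail
    of t(n-1), and ``t_upper = (mean - high) / (sd/sqrt(n))`` with p
    from the lower tail.

    With zero sample SD the t statistics are degenerate; equivalence is
    then decided directly by whether the (exactly known) mean lies
    strictly inside the bounds, with p-values reported as 0/1.
    """
    d = np.asarray(diffs, dtype=float)
    if d.ndim != 1 or d.size < 2:
        raise ValidationError("need at least 2 paired differences")
    if not np.all(np.isfinite(d)):
        raise ValidationError("differences contain non-finite values")
    if not low < high:
        raise ValidationError("require low < high equivalence bounds")
    n = d.size
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    df = n - 1
    if np.ptp(d) == 0.0:  # all differences identical: zero true variance
        sd = 0.0
        warnings.warn("zero variance in differences: degenerate TOST")
        inside = low < mean < high
        p = 0.0 if inside else 1.0
        return TostResult(
            n=n, mean=mean, sd=sd,
            t_lower=np.inf if mean > low else -np.inf,
            t_upper=-np.inf if mean < high else np.inf,
            p_lower=p, p_upper=p, p_overall=p,
            equivalent=inside, bounds=(low, high),
            ci90=(mean, mean), ci95=(mean, mean),
        )
    se = sd / np.sqrt(n)
    t_lower = (mean - low) / se
    t_upper = (mean - high) / se
    p_lower = float(stats.t.sf(t_lower, df))
    p_upper = float(stats.t.cdf(t_upper, df))
    p_overall = max(p_lower, p_upper)
    tcrit90 = stats.t.ppf(1 - 0.05, df)
    tcrit95 = stats.t.ppf(1 - 0.025, df)
    return TostResult(
        n=n, mean=mean, sd=sd,
        t_lower=float(t_lower), t_upper=float(t_upper),
        p_lower=p_lower, p_upper=p_upper, p_overall=float(p_overall),
        equivalent=bool(p_overall < alpha),
        bounds=(low, high),
        ci90=(mean - tcrit90 * se, mean + tcrit90 * se),
        ci95=(mean - tcrit95 * se, mean + tcrit95 * se),
    )


def equivalence_report(
    table: pd.DataFrame,
    low: float = -1.0,
    high: float = 1.0,
    alpha: float = 0.05,
) -> dict:
    """Headline pooled-translation TOST per modality plus per-direction
    diagnostics.

    The pooled test concatenates the R-L, P-A and I-S differences of a
    modality into one sample (axes treated as exchangeable), mirroring
    the reporting of a single equivalence verdict per modality.
    """
    trans = table[table["direction"].isin(TRANSLATION_DIRECTIONS)]
    if trans.empty:
        raise ValidationError("difference table has no translation rows")
    report: dict = {}
    for modality, grp in trans.groupby("modality", sort=False):
        pooled = grp["difference"].dropna().to_numpy()
        per_direction = {}
        for direction in TRANSLATION_DIRECTIONS:
            vals = grp.loc[grp["direction"] == direction, "difference"].dropna()
            if len(vals) >= 2:
                per_direction[direction] = tost_paired(vals, low, high, alpha)
        report[modality] = {
            "pooled": tost_paired(pooled, low, high, alpha),
            "per_direction": per_direction,
        }
    return report
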